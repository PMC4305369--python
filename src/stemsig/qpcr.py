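"""Comparative delta-Ct relative quantification and microarray concordance.

RQ = 2^(-ddCt), where dCt = Ct_target - Ct_reference within a sample and
ddCt subtracts the mean dCt of the calibrator group.  Amplification
efficiency is fixed at 2, the comparative method's assumption.  By
construction the calibrator group's geometric-mean RQ is exactly 1 per gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import DesignTable


@dataclass
class CtTable:
    """samples x genes cycle-threshold values with reference and calibrator."""

    values: pd.DataFrame        # samples x genes (cycles)
    reference_gene: str
    design: DesignTable
    calibrator_group: str

    def __post_init__(self) -> None:
        if self.reference_gene not in self.values.columns:
            raise ValueError(f"reference gene {self.reference_gene!r} absent from table")
        if list(self.values.index) != self.design.samples:
            if set(self.values.index) != set(self.design.samples):
                raise ValueError("Ct table samples do not match design")
            self.values = self.values.loc[self.design.samples]
        if self.calibrator_group not in self.design.groups:
            raise ValueError(f"calibrator group {self.calibrator_group!r} not in design")


def relative_quantification(t: CtTable) -> pd.DataFrame:
    """Per-sample, per-gene RQ values by the comparative delta-Ct method.

    The reference gene cancels any per-sample additive shift of all Ct values
    (loading/efficiency differences), and centering on the calibrator group's
    mean dCt pins that group's geometric-mean RQ at 1.
    """
    ref = t.values[t.reference_gene]
    missing = ref.index[~np.isfinite(ref.to_numpy(dtype=float))]
    if len(missing):
        raise ValueError(f"missing reference Ct for sample(s): {list(missing)}")
    dct = t.values.sub(ref, axis=0)
    calibrators = t.design.samples_in(t.calibrator_group)
    if not calibrators:
        raise ValueError(f"calibrator group {t.calibrator_group!r} has no samples")
    ddct = dct.sub(dct.loc[calibrators].mean(axis=0), axis=1)
    return 2.0 ** (-ddct)


def concordance(rq: pd.DataFrame, design: DesignTable, group: str,
                array_lfc: pd.Series) -> float:
    """Sign-agreement rate between qPCR and microarray fold changes.

    ``array_lfc`` maps gene symbol -> microarray log2FC of ``group`` versus
    the calibrator.  The qPCR side is log2 of the group's mean RQ per gene.
    Returns the fraction of shared genes whose signs agree.
    """
    shared = [g for g in rq.columns if g in array_lfc.index]
    if not shared:
        raise ValueError("no shared genes between RQ table and microarray contrasts")
    samples = design.samples_in(group)
    if not samples:
        raise ValueError(f"group {group!r} has no samples")
    qpcr_lfc = np.log2(rq.loc[samples, shared].mean(axis=0).to_numpy(dtype=float))
    arr = array_lfc.loc[shared].to_numpy(dtype=float)
    agree = np.sign(qpcr_lfc) == np.sign(arr)
    return float(np.mean(agree))
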