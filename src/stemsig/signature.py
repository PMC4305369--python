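"""FC-score signatures: cell-type-specific, shared-stem and germ gene sets.

For one reference cell type, every probe retained in its profile carries an
ordered U/D/n call and a log2 fold change against each other group.  The
FC score sums the log2 fold changes over the significant (non-n) comparisons
only; in a five-group design it has at most four terms, so a probe up at
exactly 2 log2 against all four other types scores exactly +8 — the threshold
used for signature membership.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd


@dataclass
class CellTypeProfile:
    """Differential-expression profile of one reference cell type.

    ``table`` is indexed by probe_id with columns ``symbol`` (object, None if
    unannotated), ``call_<g>`` and ``lfc_<g>`` for each other group g (log2FC
    oriented reference - other), and ``fc_score``.  Only probes with at least
    one non-n call are retained.
    """

    reference: str
    others: list[str]
    table: pd.DataFrame

    def call_strings(self) -> pd.Series:
        """Ordered U/D/n string over the other groups, e.g. ``"UUnD"``."""
        cols = [f"call_{g}" for g in self.others]
        return self.table[cols].agg("".join, axis=1)

    def annotated(self) -> pd.DataFrame:
        return self.table[self.table["symbol"].notna()]


def fc_scores(calls: pd.DataFrame, lfcs: pd.DataFrame) -> pd.Series:
    """Vectorized FC score: sum of log2FC where the call is not 'n'."""
    contrib = lfcs.to_numpy(dtype=float) * (calls.to_numpy() != "n")
    return pd.Series(contrib.sum(axis=1), index=lfcs.index, name="fc_score")


def fc_score(calls: Sequence[str], lfcs: Sequence[float]) -> float:
    """FC score of a single profile row.

    Comparisons called 'n' contribute zero; 'U' and 'D' contribute their
    signed log2 fold change.
    """
    if len(calls) != len(lfcs):
        raise ValueError("calls and log2FCs differ in length")
    return float(sum(l for c, l in zip(calls, lfcs) if c != "n"))


class SpecificSelection(NamedTuple):
    probes: list[str]     # all probes up against every other group
    genes: list[str]      # annotated-only view (unique symbols, sorted)


def select_specific(profiles: Mapping[str, CellTypeProfile], cell: str) -> SpecificSelection:
    """Probes up-regulated in ``cell`` against every other group."""
    if cell not in profiles:
        raise KeyError(f"no profile for group {cell!r}")
    prof = profiles[cell]
    cols = [f"call_{g}" for g in prof.others]
    mask = (prof.table[cols] == "U").all(axis=1)
    hits = prof.table[mask]
    genes = sorted(set(hits["symbol"].dropna()))
    return SpecificSelection(probes=list(hits.index), genes=genes)


def select_shared_stem(
    profiles: Mapping[str, CellTypeProfile],
    somatic_refs: Sequence[str],
    threshold: float = 8.0,
) -> list[str]:
    """Genes strongly depleted in every somatic reference profile.

    A gene qualifies when its FC score is <= -threshold in the profile of each
    somatic reference cell type — i.e. it is much lower in every somatic type
    than in the remaining (stem-like) types.  Returns the sorted intersection
    over annotated genes.
    """
    if not (threshold > 0):
        raise ValueError("threshold must be positive")
    sets = []
    for ref in somatic_refs:
        if ref not in profiles:
            raise KeyError(f"no profile for somatic reference {ref!r}")
        ann = profiles[ref].annotated()
        sets.append(set(ann.loc[ann["fc_score"] <= -threshold, "symbol"]))
    if not sets:
        return []
    common = set.intersection(*sets)
    return sorted(common)


def select_germ(profile: CellTypeProfile, threshold: float = 8.0) -> pd.DataFrame:
    """Annotated genes with FC score >= threshold in the germ-analog profile.

    Returns a frame (index probe_id; columns symbol, fc_score) sorted by
    descending score, ties broken by probe_id for a stable ranking.
    """
    ann = profile.annotated()
    hits = ann.loc[ann["fc_score"] >= threshold, ["symbol", "fc_score"]].copy()
    # descending score, ties broken by ascending probe_id
    hits["_pid"] = hits.index
    hits = hits.sort_values(by=["fc_score", "_pid"], ascending=[False, True])
    return hits.drop(columns="_pid")


def venn_partition(de_lists: Mapping[str, Iterable[str]]) -> dict[str, int]:
    """Counts of every non-empty membership pattern across the given sets.

    Keys are fixed-order bitstrings following the mapping's key order, e.g.
    ``"10"`` = only in the first list.  Counts sum to the union size.
    """
    names = list(de_lists)
    if len(names) < 2:
        raise ValueError("need at least 2 lists for a Venn partition")
    sets = {n: set(de_lists[n]) for n in names}
    union = set().union(*sets.values())
    counts: dict[str, int] = {}
    for el in union:
        key = "".join("1" if el in sets[n] else "0" for n in names)
        counts[key] = counts.get(key, 0) + 1
    return counts


@dataclass
class SignatureReport:
    """Bundle of the signature lists produced from one set of profiles."""

    specific: dict[str, SpecificSelection]
    shared_stem: list[str]
    germ: pd.DataFrame
    venn: dict[str, int]
    thresholds: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "specific": {
                g: {"probes": sel.probes, "genes": sel.genes}
                for g, sel in self.specific.items()
            },
            "shared_stem": self.shared_stem,
            "germ": [
                {"probe_id": pid, "symbol": row["symbol"], "fc_score": row["fc_score"]}
                for pid, row in self.germ.iterrows()
            ],
            "venn": self.venn,
            "thresholds": self.thresholds,
        }


def signature_report(
    profiles: Mapping[str, CellTypeProfile],
    somatic_refs: Sequence[str],
    germ_group: str,
    score_threshold: float = 8.0,
) -> SignatureReport:
    """Compute every signature list plus the Venn partition of the DE lists."""
    specific = {g: select_specific(profiles, g) for g in profiles}
    shared = select_shared_stem(profiles, somatic_refs, threshold=score_threshold)
    germ = select_germ(profiles[germ_group], threshold=score_threshold)
    venn = venn_partition({g: set(p.table.index) for g, p in profiles.items()})
    return SignatureReport(
        specific=specific,
        shared_stem=shared,
        germ=germ,
        venn=venn,
        thresholds={"score": score_threshold, "somatic_refs": list(somatic_refs),
                    "germ_group": germ_group},
    )
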