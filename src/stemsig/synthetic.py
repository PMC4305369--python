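"""Planted-truth simulation of a multi-cell-type single-channel array study.

The generator emulates the structure of a five-cell-type, three-replicate
chicken stem-cell experiment: tens of thousands of probes with duplicate
spots, ~58% of probes carrying a gene symbol, spot intensities formed as an
exponentially distributed true signal plus a normal scanner background, a
smooth array-specific intensity-dependent bias, and a companion
"foreign-platform" gene-level dataset (a mouse-analog) sharing part of the
symbol universe with an additive batch offset.

Planted classes give every downstream stage ground truth:

* ``specific:<group>`` — elevated in one group only;
* ``shared_stem`` — equally elevated in every stem-analog group
  (cES/cBC/PGC analogs), baseline in the somatic analogs;
* ``germ`` — elevated in the germ-analog group against all others (the germ
  signature of the study is precisely its top germ-cell-specific list);
* ``null`` — no effect anywhere.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .io_formats import (
    AnnotationTable,
    ArrayScan,
    ConfigError,
    DesignTable,
    ExpressionMatrix,
    write_annotation,
    write_design,
    write_gpr,
)
from .qpcr import CtTable

DEFAULT_GROUPS = ("CEF", "BM2", "cES", "PGC", "cBC")

#: Planted counts mirroring the scale of the study's specific/shared lists.
DEFAULT_PLANTED_5GROUP = {
    "specific:CEF": 500,
    "specific:BM2": 650,
    "specific:cES": 40,
    "specific:cBC": 110,
    "shared_stem": 88,
    "germ": 180,
}


@dataclass
class SimulationConfig:
    """All knobs of the simulated experiment; defaults are the study design."""

    n_probes: int = 44000
    duplicate_fraction: float = 0.05
    groups: tuple = DEFAULT_GROUPS
    replicates_per_group: int = 3
    fraction_annotated: float = 0.578
    planted_counts: Optional[dict] = None
    effect_size_log2: Union[float, Mapping[str, float]] = 3.0
    residual_sd_log2: float = 0.3
    signal_alpha: float = 800.0       # exponential mean of true signal (a.u.)
    background_mu: float = 100.0
    background_sd: float = 15.0
    array_bias_amplitude: float = 0.3  # max |log2 distortion| per array
    batch_offset_log2: float = 2.0     # companion-dataset platform shift
    seed: int = 0
    somatic_groups: Optional[tuple] = None   # default: first two groups
    stem_groups: Optional[tuple] = None      # default: remaining groups
    germ_group: Optional[str] = None         # default: "PGC" if present
    germ_secondary_level: float = 0.0  # fraction of the germ effect leaking
                                       # into the blastoderm analog

    def __post_init__(self) -> None:
        self.groups = tuple(self.groups)
        if self.somatic_groups is None:
            self.somatic_groups = self.groups[:2]
        else:
            self.somatic_groups = tuple(self.somatic_groups)
        if self.stem_groups is None:
            self.stem_groups = tuple(g for g in self.groups if g not in self.somatic_groups)
        else:
            self.stem_groups = tuple(self.stem_groups)
        if self.germ_group is None and self.stem_groups:
            self.germ_group = "PGC" if "PGC" in self.stem_groups else self.stem_groups[-1]
        if self.planted_counts is None:
            self.planted_counts = (
                dict(DEFAULT_PLANTED_5GROUP) if self.groups == DEFAULT_GROUPS else {}
            )
        self.validate()

    def validate(self) -> None:
        if self.n_probes < 1:
            raise ConfigError("n_probes must be positive")
        if not (0 <= self.duplicate_fraction <= 1):
            raise ConfigError("duplicate_fraction must be a proportion")
        if not (0 <= self.fraction_annotated <= 1):
            raise ConfigError("fraction_annotated must be a proportion")
        if self.replicates_per_group < 1:
            raise ConfigError("replicates_per_group must be >= 1")
        for name, val in (("residual_sd_log2", self.residual_sd_log2),
                          ("background_sd", self.background_sd),
                          ("signal_alpha", self.signal_alpha)):
            if not (val > 0):
                raise ConfigError(f"{name} must be > 0")
        if len(set(self.groups)) != len(self.groups):
            raise ConfigError("group labels must be unique")
        for klass, count in self.planted_counts.items():
            if count < 0:
                raise ConfigError(f"negative planted count for {klass!r}")
            if klass.startswith("specific:"):
                g = klass.split(":", 1)[1]
                if g not in self.groups:
                    raise ConfigError(f"planted class {klass!r} names unknown group")
            elif klass == "shared_stem":
                if count > 0 and (not self.stem_groups or not self.somatic_groups):
                    raise ConfigError("shared_stem requires stem and somatic groups")
            elif klass == "germ":
                if count > 0 and self.germ_group is None:
                    raise ConfigError("germ class requires a germ-analog group")
            else:
                raise ConfigError(f"unknown planted class {klass!r}")
        if sum(self.planted_counts.values()) > self.n_probes:
            raise ConfigError("planted counts exceed n_probes")

    def effect_of(self, klass: str) -> float:
        if isinstance(self.effect_size_log2, Mapping):
            eff = float(self.effect_size_log2.get(klass, 0.0))
        else:
            eff = float(self.effect_size_log2)
        if eff <= 0:
            raise ConfigError(f"effect size for {klass!r} must be positive")
        return eff

    @property
    def sample_ids(self) -> list[str]:
        return [f"{g}_{r + 1}" for g in self.groups
                for r in range(self.replicates_per_group)]


@dataclass
class SyntheticTruth:
    """Ground truth: per-probe class, symbol, spot count and true group means."""

    table: pd.DataFrame        # index probe_id; columns klass, gene_symbol,
                               # n_spots, baseline_log2
    group_means: pd.DataFrame  # probe x group true log2 means
    config: SimulationConfig

    def probes_of(self, klass: str) -> list[str]:
        return list(self.table.index[self.table["klass"] == klass])

    def symbols_of(self, klass: str) -> list[str]:
        sub = self.table[(self.table["klass"] == klass) & self.table["gene_symbol"].notna()]
        return list(sub["gene_symbol"])

    @property
    def annotation(self) -> AnnotationTable:
        symbols = {p: s for p, s in self.table["gene_symbol"].items() if s is not None}
        return AnnotationTable(symbols=symbols, version_tag="synthetic")


def _class_deltas(cfg: SimulationConfig, klasses: pd.Series) -> pd.DataFrame:
    """Per-probe true log2 offsets from the baseline, one column per group."""
    delta = pd.DataFrame(0.0, index=klasses.index, columns=list(cfg.groups))
    for klass in sorted(set(klasses) - {"null"}):
        probes = klasses.index[klasses == klass]
        eff = cfg.effect_of(klass)
        if klass.startswith("specific:"):
            delta.loc[probes, klass.split(":", 1)[1]] = eff
        elif klass == "shared_stem":
            for g in cfg.stem_groups:
                delta.loc[probes, g] = eff
        elif klass == "germ":
            delta.loc[probes, cfg.germ_group] = eff
            if cfg.germ_secondary_level > 0:
                secondary = [g for g in cfg.stem_groups if g != cfg.germ_group]
                if secondary:
                    delta.loc[probes, secondary[-1]] = cfg.germ_secondary_level * eff
    return delta


def _array_bias(rng: np.random.Generator, log_intensity: np.ndarray,
                amplitude: float) -> np.ndarray:
    """A smooth, per-array low-order polynomial distortion in log intensity."""
    if amplitude == 0:
        return np.zeros_like(log_intensity)
    lo, hi = np.min(log_intensity), np.max(log_intensity)
    t = np.zeros_like(log_intensity) if hi == lo else (
        2.0 * (log_intensity - lo) / (hi - lo) - 1.0
    )
    c1, c2 = rng.uniform(-1.0, 1.0, size=2)
    norm = abs(c1) + abs(c2)
    if norm == 0:
        return np.zeros_like(log_intensity)
    return amplitude * (c1 * t + c2 * (2.0 * t**2 - 1.0)) / norm


def generate_experiment(
    cfg: SimulationConfig,
) -> tuple[list[ArrayScan], AnnotationTable, DesignTable, SyntheticTruth]:
    """Simulate one full experiment: scans, annotation, design and truth.

    Deterministic given ``cfg.seed``.  Planted probes draw their baseline
    signal from the exponential conditioned to exceed half its mean
    (memoryless shift), since signature genes sitting inside the background
    band would be unrecoverable by construction; null probes keep the plain
    exponential marginal that the normexp model assumes.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_probes
    probe_ids = np.array([f"A87_P{i:06d}" for i in range(n)], dtype=object)

    # planted classes on a random probe subset
    klasses = np.array(["null"] * n, dtype=object)
    planted_items = sorted(cfg.planted_counts.items())
    total_planted = sum(c for _, c in planted_items)
    chosen = rng.choice(n, size=total_planted, replace=False)
    offset = 0
    for klass, count in planted_items:
        klasses[chosen[offset:offset + count]] = klass
        offset += count
    klass_series = pd.Series(klasses, index=probe_ids, name="klass")

    # annotation: planted probes are always annotated; null probes fill in so
    # the marginal annotated fraction stays ~ fraction_annotated
    annotated = klasses != "null"
    n_planted_annotated = int(annotated.sum())
    n_null = n - n_planted_annotated
    target = cfg.fraction_annotated * n
    q = (target - n_planted_annotated) / n_null if n_null else 0.0
    if q < 0:
        warnings.warn("planted probes alone exceed the annotated fraction",
                      RuntimeWarning)
        q = 0.0
    annotated[~(klasses != "null")] = rng.random(n_null) < q
    symbols = np.array([None] * n, dtype=object)
    symbols[annotated] = [f"GSYM{i:06d}" for i in range(int(annotated.sum()))]
    symbol_series = pd.Series(symbols, index=probe_ids, name="gene_symbol")

    # baseline signal levels (intensity a.u.)
    baseline = rng.exponential(cfg.signal_alpha, size=n)
    planted_mask = klasses != "null"
    baseline[planted_mask] = cfg.signal_alpha / 2.0 + rng.exponential(
        cfg.signal_alpha, size=int(planted_mask.sum())
    )
    baseline_log2 = np.log2(np.maximum(baseline, 1e-9))

    delta = _class_deltas(cfg, klass_series)
    group_means = delta.add(baseline_log2, axis=0)

    # duplicate spots: a fixed subset of probes appears twice on every array
    n_dup = int(round(cfg.duplicate_fraction * n))
    dup_idx = np.sort(rng.choice(n, size=n_dup, replace=False))
    spot_probe_idx = np.concatenate([np.arange(n), dup_idx])
    n_spots_per_probe = np.ones(n, dtype=int)
    n_spots_per_probe[dup_idx] = 2

    design = DesignTable(pd.Series(
        [g for g in cfg.groups for _ in range(cfg.replicates_per_group)],
        index=cfg.sample_ids, name="group",
    ))

    scans: list[ArrayScan] = []
    spot_ids = probe_ids[spot_probe_idx]
    spot_symbols = symbols[spot_probe_idx]
    for sample_id in design.samples:
        group = design.assignments[sample_id]
        expr_log2 = (
            group_means[group].to_numpy()
            + rng.normal(0.0, cfg.residual_sd_log2, size=n)
        )
        signal = 2.0 ** expr_log2[spot_probe_idx]
        bg = rng.normal(cfg.background_mu, cfg.background_sd, size=len(spot_probe_idx))
        x = signal + bg
        bias = _array_bias(rng, np.log2(np.maximum(x, 1.0)), cfg.array_bias_amplitude)
        x = x * 2.0 ** bias
        local_bg = cfg.background_mu + rng.normal(
            0.0, cfg.background_sd / 3.0, size=len(spot_probe_idx)
        )
        probes = pd.DataFrame({
            "probe_id": spot_ids,
            "gene_symbol": spot_symbols,
            "foreground": np.round(x, 4),
            "background": np.round(local_bg, 4),
            "flag": 0,
        })
        scans.append(ArrayScan(sample_id, probes))

    truth = SyntheticTruth(
        table=pd.DataFrame({
            "klass": klass_series,
            "gene_symbol": symbol_series,
            "n_spots": pd.Series(n_spots_per_probe, index=probe_ids),
            "baseline_log2": pd.Series(baseline_log2, index=probe_ids),
        }),
        group_means=group_means,
        config=cfg,
    )
    annotation = truth.annotation
    return scans, annotation, design, truth


# ---------------------------------------------------------------------------
# Companion "foreign platform" dataset
# ---------------------------------------------------------------------------

FOREIGN_PROFILES = ("stem", "somatic", "germ")


def generate_companion_dataset(
    cfg: SimulationConfig,
    truth: SyntheticTruth,
    shared_symbol_count: int,
    foreign_groups: Sequence[str] = ("mES", "mEF"),
    profile_map: Optional[Mapping[str, str]] = None,
    replicates: int = 3,
    n_extra_symbols: int = 300,
    seed: Optional[int] = None,
) -> tuple[ExpressionMatrix, DesignTable, pd.DataFrame]:
    """A gene-level dataset from another platform sharing part of the symbols.

    The intersection with the truth's symbol universe has exactly
    ``shared_symbol_count`` genes (planted-class symbols are included first so
    biological structure survives the intersection).  Foreign groups reuse the
    planted classes via ``profile_map``: ``"stem"`` elevates shared-stem
    genes, ``"germ"`` elevates germ plus shared-stem genes, ``"somatic"``
    stays at baseline.  The whole dataset is shifted by
    ``cfg.batch_offset_log2`` and carries independent noise.
    """
    if profile_map is None:
        profile_map = {g: ("stem" if i == 0 else "somatic")
                       for i, g in enumerate(foreign_groups)}
    for g, prof in profile_map.items():
        if prof not in FOREIGN_PROFILES:
            raise ConfigError(f"unknown foreign profile {prof!r} for group {g!r}")
    ann = truth.table[truth.table["gene_symbol"].notna()]
    available = list(ann["gene_symbol"])
    if shared_symbol_count > len(available):
        raise ConfigError(
            f"shared_symbol_count={shared_symbol_count} exceeds the "
            f"{len(available)} annotated genes"
        )
    rng = np.random.default_rng(cfg.seed + 104729 if seed is None else seed)

    planted = ann[ann["klass"] != "null"]
    nulls = ann[ann["klass"] == "null"]
    if shared_symbol_count >= len(planted):
        n_null = shared_symbol_count - len(planted)
        pick_null = rng.choice(len(nulls), size=n_null, replace=False)
        shared = pd.concat([planted, nulls.iloc[np.sort(pick_null)]])
    else:
        pick = rng.choice(len(planted), size=shared_symbol_count, replace=False)
        shared = planted.iloc[np.sort(pick)]

    shared_symbols = list(shared["gene_symbol"])
    extra_symbols = [f"MG{i:05d}" for i in range(n_extra_symbols)]
    gene_ids = shared_symbols + extra_symbols

    base = np.concatenate([
        shared["baseline_log2"].to_numpy(dtype=float),
        np.log2(np.maximum(rng.exponential(cfg.signal_alpha, size=n_extra_symbols), 1e-9)),
    ])
    klass = np.concatenate([
        shared["klass"].to_numpy(dtype=object),
        np.array(["null"] * n_extra_symbols, dtype=object),
    ])

    sample_ids = [f"{g}_{r + 1}" for g in foreign_groups for r in range(replicates)]
    design = DesignTable(pd.Series(
        [g for g in foreign_groups for _ in range(replicates)],
        index=sample_ids, name="group",
    ))

    cols = {}
    true_means = {}
    for g in foreign_groups:
        profile = profile_map.get(g, "somatic")
        delta = np.zeros(len(gene_ids))
        if profile in ("stem", "germ"):
            stem_mask = klass == "shared_stem"
            if stem_mask.any():
                delta[stem_mask] = cfg.effect_of("shared_stem")
        if profile == "germ":
            germ_mask = klass == "germ"
            if germ_mask.any():
                delta[germ_mask] = cfg.effect_of("germ")
        mean_g = base + delta + cfg.batch_offset_log2
        true_means[g] = mean_g
        for r in range(replicates):
            cols[f"{g}_{r + 1}"] = mean_g + rng.normal(
                0.0, cfg.residual_sd_log2, size=len(gene_ids)
            )
    values = pd.DataFrame(cols, index=gene_ids)[design.samples]
    matrix = ExpressionMatrix(values, design, level="gene")
    extension = pd.DataFrame(
        {"klass": klass, "shared": [s in set(shared_symbols) for s in gene_ids],
         **{f"true_mean_{g}": true_means[g] for g in foreign_groups}},
        index=gene_ids,
    )
    return matrix, design, extension


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------


def generate_ct_table(
    truth: SyntheticTruth,
    genes: Sequence[str],
    reference_gene: str,
    seed: Optional[int] = None,
    calibrator_group: Optional[str] = None,
    ct0: float = 30.0,
    noise_sd: float = 0.25,
    replicates: Optional[int] = None,
) -> CtTable:
    """Simulate a samples x genes Ct table from the planted truth.

    Ct = ct0 - (true log2 expression) + noise; the reference gene must be
    planted flat (equal true means in all groups) so it can cancel per-sample
    shifts the way a housekeeping control does.
    """
    cfg = truth.config
    rng = np.random.default_rng(cfg.seed + 15485863 if seed is None else seed)
    replicates = cfg.replicates_per_group if replicates is None else replicates
    if calibrator_group is None:
        calibrator_group = "cES" if "cES" in cfg.groups else cfg.groups[0]

    sym_to_probe: dict[str, str] = {}
    for pid, sym in truth.table["gene_symbol"].items():
        if sym is not None and sym not in sym_to_probe:
            sym_to_probe[sym] = pid
    for gene in [*genes, reference_gene]:
        if gene not in sym_to_probe:
            raise ValueError(f"unknown gene symbol {gene!r}")
    ref_means = truth.group_means.loc[sym_to_probe[reference_gene]]
    if float(ref_means.max() - ref_means.min()) > 1e-9:
        raise ValueError(
            f"reference gene {reference_gene!r} is not planted flat across groups"
        )

    all_genes = list(dict.fromkeys([*genes, reference_gene]))
    sample_ids = [f"{g}_q{r + 1}" for g in cfg.groups for r in range(replicates)]
    design = DesignTable(pd.Series(
        [g for g in cfg.groups for _ in range(replicates)],
        index=sample_ids, name="group",
    ))
    rows = []
    for g in cfg.groups:
        for _ in range(replicates):
            cts = [
                ct0
                - float(truth.group_means.loc[sym_to_probe[gene], g])
                + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                for gene in all_genes
            ]
            rows.append(cts)
    values = pd.DataFrame(rows, index=sample_ids, columns=all_genes, dtype=float)
    return CtTable(values=values, reference_gene=reference_gene, design=design,
                   calibrator_group=calibrator_group)


# ---------------------------------------------------------------------------
# On-disk experiment export (used by the CLI)
# ---------------------------------------------------------------------------


def write_experiment(
    out_dir: str | Path,
    scans: Sequence[ArrayScan],
    annotation: AnnotationTable,
    design: DesignTable,
    truth: SyntheticTruth,
) -> None:
    """Write GPR files, the annotation, the design and the truth tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gpr_dir = out / "gpr"
    gpr_dir.mkdir(exist_ok=True)
    for scan in scans:
        write_gpr(scan, gpr_dir / f"{scan.array_id}.gpr")
    write_annotation(annotation, out / "annotation.gal",
                     all_probes=list(truth.table.index))
    write_design(design, out / "design.tsv")
    truth.table.to_csv(out / "truth.tsv", sep="\t", index_label="probe_id")
    truth.group_means.to_csv(out / "truth_group_means.tsv", sep="\t",
                             index_label="probe_id")
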