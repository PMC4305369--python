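"""Empirical-Bayes moderated-t differential expression with dual thresholds.

Per probe, a one-way group-means model is fitted and the residual variance is
pooled across groups.  An inverse-chi-square prior (d0, s0^2) is estimated
across probes by matching the first two moments of log s_g^2 (the classic
trigamma-matching scheme), and each probe's variance is shrunk to

    s_tilde^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g).

The moderated t for a pairwise contrast is log2FC / (s_tilde * sqrt(1/n_a +
1/n_b)) with d0 + d_g degrees of freedom.  P-values are Benjamini-Hochberg
adjusted per contrast, and a probe is called U (up) / D (down) only when both
the adjusted p-value and the |log2 fold change| pass their cutoffs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .io_formats import AnnotationTable, DesignTable, ExpressionMatrix
from .signature import CellTypeProfile, fc_scores

#: Estimated prior df above this value are treated as infinite (no residual
#: variability of the true variances around s0^2).
D0_INFINITY_CAP = 1e6


@dataclass
class GeneFit:
    """Per-row group means, pooled residual variance and its df."""

    means: pd.DataFrame        # rows x groups (log2)
    s2: pd.Series              # pooled residual variance per row
    df_residual: int           # N - k, shared by all rows
    n_per_group: pd.Series     # samples per group


@dataclass(frozen=True)
class ModerationPrior:
    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        # d0 = 0 is the no-shrinkage limit (ordinary pooled t); negative df is invalid
        if not (self.d0 >= 0):
            raise ValueError("prior df must be nonnegative")
        if not (self.s0_sq > 0):
            raise ValueError("prior variance must be positive")

    @property
    def is_infinite(self) -> bool:
        return math.isinf(self.d0) or self.d0 >= D0_INFINITY_CAP


@dataclass
class ContrastTable:
    """Moderated-t results for one ordered group pair (a, b); log2FC = a - b."""

    pair: tuple[str, str]
    table: pd.DataFrame  # columns: log2FC, t, p, and later p_adj, call

    def reversed(self) -> "ContrastTable":
        """Swap the contrast orientation: negates log2FC and t, keeps p."""
        t = self.table.copy()
        t["log2FC"] = -t["log2FC"]
        t["t"] = -t["t"]
        if "call" in t.columns:
            t["call"] = t["call"].map({"U": "D", "D": "U", "n": "n"})
        return ContrastTable(pair=(self.pair[1], self.pair[0]), table=t)


def fit_group_model(m: ExpressionMatrix) -> GeneFit:
    """Group means and pooled within-group variance with df = N - k."""
    design = m.design
    groups = design.groups
    n_per_group = {}
    means = {}
    ss = np.zeros(m.n_rows)
    n_total = 0
    for g in groups:
        cols = design.samples_in(g)
        if len(cols) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 replicates")
        sub = m.values[cols].to_numpy(dtype=float)
        mu = sub.mean(axis=1)
        means[g] = mu
        ss += ((sub - mu[:, None]) ** 2).sum(axis=1)
        n_per_group[g] = len(cols)
        n_total += len(cols)
    df_resid = n_total - len(groups)
    s2 = ss / df_resid
    return GeneFit(
        means=pd.DataFrame(means, index=m.values.index),
        s2=pd.Series(s2, index=m.values.index, name="s2"),
        df_residual=df_resid,
        n_per_group=pd.Series(n_per_group),
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the inverse scale)."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def estimate_prior(fit: GeneFit, min_rows: int = 10) -> ModerationPrior:
    """Trigamma-matching estimate of the variance prior (d0, s0^2).

    With s_g^2 | sigma_g^2 ~ sigma_g^2 chi^2_d / d and sigma_g^2 drawn from a
    scaled inverse chi-square(d0, s0^2), the statistic e_g = log s_g^2 -
    digamma(d/2) + log(d/2) has variance trigamma(d/2) + trigamma(d0/2), so
    the excess dispersion of e identifies d0 and its mean identifies s0^2.
    Zero excess dispersion returns an infinite-d0 sentinel.
    """
    s2 = fit.s2[fit.s2 > 0]
    if len(s2) < min_rows:
        raise ValueError(
            f"need at least {min_rows} rows with positive variance, got {len(s2)}"
        )
    d = fit.df_residual
    z = np.log(s2.to_numpy())
    if np.ptp(z) < 1e-12:
        # all variances identical: no shrinkage target dispersion at all
        return ModerationPrior(d0=math.inf, s0_sq=float(s2.iloc[0]))
    e = z - float(special.digamma(d / 2.0)) + math.log(d / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, d / 2.0))
    if evar <= 0:
        return ModerationPrior(d0=math.inf, s0_sq=float(np.exp(emean)))
    d0 = 2.0 * _trigamma_inverse(evar)
    if d0 >= D0_INFINITY_CAP:
        return ModerationPrior(d0=math.inf, s0_sq=float(np.exp(emean)))
    s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0)))
    return ModerationPrior(d0=d0, s0_sq=s0_sq)


def moderated_t(fit: GeneFit, prior: ModerationPrior,
                pair: tuple[str, str]) -> ContrastTable:
    """Moderated t and two-sided p for one ordered group pair (a, b)."""
    a, b = pair
    for g in (a, b):
        if g not in fit.means.columns:
            raise KeyError(f"group {g!r} not in fitted model")
    lfc = fit.means[a].to_numpy() - fit.means[b].to_numpy()
    d_g = fit.df_residual
    s2 = fit.s2.to_numpy()
    if prior.is_infinite:
        s_tilde_sq = np.full_like(s2, prior.s0_sq)
        df_total = math.inf
    else:
        s_tilde_sq = (prior.d0 * prior.s0_sq + d_g * s2) / (prior.d0 + d_g)
        df_total = prior.d0 + d_g
    scale = np.sqrt(1.0 / fit.n_per_group[a] + 1.0 / fit.n_per_group[b])
    se = np.sqrt(s_tilde_sq) * scale

    t = np.zeros_like(lfc)
    p = np.ones_like(lfc)
    zero_se = se == 0
    ok = ~zero_se
    t[ok] = lfc[ok] / se[ok]
    if math.isinf(df_total):
        p[ok] = 2.0 * stats.norm.sf(np.abs(t[ok]))
    else:
        p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df=df_total)
    # degenerate rows: zero residual spread everywhere
    deg_sig = zero_se & (lfc != 0)
    t[deg_sig] = np.sign(lfc[deg_sig]) * np.inf
    p[deg_sig] = 0.0
    table = pd.DataFrame({"log2FC": lfc, "t": t, "p": p}, index=fit.means.index)
    return ContrastTable(pair=pair, table=table)


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    m = arr.size
    order = np.argsort(arr, kind="mergesort")
    ranked = arr[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def call_de(ct: ContrastTable, alpha: float = 0.05, lfc: float = 2.0,
            strict: bool = True) -> ContrastTable:
    """Attach U/D/n calls using the dual adjusted-p and fold-change cutoffs."""
    if "p_adj" not in ct.table.columns:
        raise ValueError("adjusted p-values missing; run bh_adjust first")
    t = ct.table
    if strict:
        sig = t["p_adj"] < alpha
        up = sig & (t["log2FC"] > lfc)
        down = sig & (t["log2FC"] < -lfc)
    else:
        sig = t["p_adj"] <= alpha
        up = sig & (t["log2FC"] >= lfc)
        down = sig & (t["log2FC"] <= -lfc)
    call = np.where(up, "U", np.where(down, "D", "n"))
    out = t.copy()
    out["call"] = call
    return ContrastTable(pair=ct.pair, table=out)


def all_contrasts(
    m: ExpressionMatrix,
    alpha: float = 0.05,
    lfc: float = 2.0,
    strict: bool = True,
    pool_bh: bool = False,
) -> dict[tuple[str, str], ContrastTable]:
    """Fit, moderate, adjust and call every pairwise contrast of the design.

    BH adjustment is applied within each contrast by default; ``pool_bh``
    pools all raw p-values across contrasts before adjusting.
    """
    fit = fit_group_model(m)
    prior = estimate_prior(fit)
    groups = m.design.groups
    tables = {
        (a, b): moderated_t(fit, prior, (a, b))
        for a, b in itertools.combinations(groups, 2)
    }
    if pool_bh:
        stacked = np.concatenate([ct.table["p"].to_numpy() for ct in tables.values()])
        adj = bh_adjust(stacked)
        offset = 0
        for ct in tables.values():
            n = len(ct.table)
            ct.table["p_adj"] = adj[offset:offset + n]
            offset += n
    else:
        for ct in tables.values():
            ct.table["p_adj"] = bh_adjust(ct.table["p"].to_numpy())
    return {
        pair: call_de(ct, alpha=alpha, lfc=lfc, strict=strict)
        for pair, ct in tables.items()
    }


def _oriented(tables: Mapping[tuple[str, str], ContrastTable],
              a: str, b: str) -> ContrastTable:
    if (a, b) in tables:
        return tables[(a, b)]
    if (b, a) in tables:
        return tables[(b, a)].reversed()
    raise KeyError(f"missing contrast between {a!r} and {b!r}")


def build_profile(
    reference: str,
    tables: Mapping[tuple[str, str], ContrastTable],
    group_order: Sequence[str],
    annotation: Optional[AnnotationTable] = None,
) -> CellTypeProfile:
    """Assemble one cell type's profile from the called contrast tables.

    Rows with at least one non-n call against the other groups are retained;
    log2FC is oriented reference - other and the FC score is attached.
    """
    others = [g for g in group_order if g != reference]
    if not others:
        raise ValueError("profile needs at least one non-reference group")
    calls = {}
    lfcs = {}
    index = None
    for g in others:
        ct = _oriented(tables, reference, g)
        if index is None:
            index = ct.table.index
        if "call" not in ct.table.columns:
            raise ValueError("contrast tables must be called before profiling")
        calls[g] = ct.table["call"]
        lfcs[g] = ct.table["log2FC"]
    calls_df = pd.DataFrame(calls, index=index)
    lfcs_df = pd.DataFrame(lfcs, index=index)
    keep = (calls_df != "n").any(axis=1)
    calls_df, lfcs_df = calls_df[keep], lfcs_df[keep]

    table = pd.DataFrame(index=calls_df.index)
    if annotation is not None:
        table["symbol"] = [annotation.symbol_of(p) for p in table.index]
    else:
        table["symbol"] = None
    for g in others:
        table[f"call_{g}"] = calls_df[g]
    for g in others:
        table[f"lfc_{g}"] = lfcs_df[g]
    table["fc_score"] = fc_scores(calls_df, lfcs_df)
    return CellTypeProfile(reference=reference, others=others, table=table)


def pairwise_de_count(tables: Mapping[tuple[str, str], ContrastTable],
                      a: str, b: str) -> int:
    """Number of probes called differentially expressed between a and b."""
    if a == b:
        return 0
    ct = _oriented(tables, a, b)
    if "call" not in ct.table.columns:
        raise ValueError("contrast tables must be called before counting")
    return int((ct.table["call"] != "n").sum())


def pairwise_count_matrix(tables: Mapping[tuple[str, str], ContrastTable],
                          groups: Sequence[str]) -> pd.DataFrame:
    """Symmetric matrix of pairwise DE counts (diagonal zero)."""
    out = pd.DataFrame(0, index=list(groups), columns=list(groups), dtype=int)
    for a, b in itertools.combinations(groups, 2):
        n = pairwise_de_count(tables, a, b)
        out.loc[a, b] = n
        out.loc[b, a] = n
    return out
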