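"""Raw intensity -> normalized log2 expression.

The chain is: normexp background correction per array, log2 transform,
within-array lowess normalization against a pseudo-reference, between-array
average-quantile normalization, and duplicate-spot averaging.  The normexp
model treats an observed spot intensity X as S + B with S ~ Exponential(alpha)
(true signal) and B ~ Normal(mu, sigma^2) (background); the corrected value is
E[S | X = x], which is strictly positive and strictly increasing in x.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import log_ndtr
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .io_formats import ArrayScan, DesignTable, ExpressionMatrix

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


class EstimationError(RuntimeError):
    """Raised when a model fit is impossible on the given data."""


@dataclass(frozen=True)
class NormexpParams:
    """Exponential-plus-normal convolution parameters (intensity units)."""

    mu: float
    sigma: float
    alpha: float

    def __post_init__(self) -> None:
        if not (self.sigma > 0):
            raise ValueError("sigma must be > 0")
        if not (self.alpha > 0):
            raise ValueError("alpha must be > 0")


def _moment_estimates(x: np.ndarray) -> NormexpParams:
    """Method-of-moments start values for the exponential+normal convolution.

    For X = S + B: E[X] = mu + alpha, Var = sigma^2 + alpha^2, and the third
    central moment is 2 alpha^3 (the normal part is symmetric).
    """
    m1 = float(np.mean(x))
    m2 = float(np.var(x))
    m3 = float(np.mean((x - m1) ** 3))
    sd = float(np.std(x))
    alpha = max(m3 / 2.0, (0.1 * sd) ** 3) ** (1.0 / 3.0)
    sigma = float(np.sqrt(max(m2 - alpha**2, (0.05 * sd) ** 2)))
    mu = m1 - alpha
    return NormexpParams(mu=mu, sigma=sigma, alpha=alpha)


def _normexp_negloglik(theta: np.ndarray, x: np.ndarray) -> float:
    mu, log_sigma, log_alpha = theta
    sigma = np.exp(log_sigma)
    alpha = np.exp(log_alpha)
    # density: f(x) = (1/a) exp((mu-x)/a + s^2/(2a^2)) Phi((x-mu)/s - s/a)
    z = (x - mu) / sigma - sigma / alpha
    ll = -log_alpha + (mu - x) / alpha + sigma**2 / (2.0 * alpha**2) + log_ndtr(z)
    val = -float(np.sum(ll))
    return val if np.isfinite(val) else 1e300


def estimate_normexp(intensities: Sequence[float], max_iter: int = 200) -> NormexpParams:
    """Maximum-likelihood fit of the normexp convolution, moment-initialized.

    Requires at least 50 finite values.  If the optimizer does not converge
    within ``max_iter`` iterations, the moment estimates are returned with a
    warning — they are consistent, just less efficient.
    """
    x = np.asarray(intensities, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 50:
        raise EstimationError(f"need >= 50 finite intensities, got {x.size}")
    if np.ptp(x) == 0:
        raise EstimationError("degenerate input: constant intensity vector")
    start = _moment_estimates(x)
    theta0 = np.array([start.mu, np.log(start.sigma), np.log(start.alpha)])
    res = optimize.minimize(
        _normexp_negloglik,
        theta0,
        args=(x,),
        method="Nelder-Mead",
        options={"maxiter": max_iter * 3, "xatol": 1e-6, "fatol": 1e-8},
    )
    if not res.success:
        warnings.warn(
            "normexp MLE did not converge; falling back to moment estimates",
            RuntimeWarning,
        )
        return start
    mu, log_sigma, log_alpha = res.x
    return NormexpParams(mu=float(mu), sigma=float(np.exp(log_sigma)),
                         alpha=float(np.exp(log_alpha)))


def normexp_correct(x: Sequence[float], p: NormexpParams) -> np.ndarray:
    """Posterior mean E[S | X = x] under the exponential+normal model.

    Closed form: with mu_s = x - mu - sigma^2/alpha and z = mu_s/sigma,
    E[S|x] = mu_s + sigma * phi(z) / Phi(z).  Strictly positive and strictly
    increasing in x.
    """
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite intensities passed to normexp_correct")
    mu_s = arr - p.mu - p.sigma**2 / p.alpha
    z = mu_s / p.sigma
    # log( sigma * phi(z) ) - log( Phi(z) ), stable for very negative z
    log_mills = (-0.5 * z**2 - _LOG_SQRT_2PI) - log_ndtr(z)
    signal = mu_s + p.sigma * np.exp(log_mills)
    # numerical floor: the exact expression is positive; clip guards rounding
    return np.maximum(signal, 1e-12)


# ---------------------------------------------------------------------------
# Normalization on the log2 scale
# ---------------------------------------------------------------------------


def lowess_within_array(m: ExpressionMatrix, span: float = 0.3,
                        iterations: int = 3) -> ExpressionMatrix:
    """Remove each array's smooth intensity-dependent deviation.

    For a single-channel design the MA-plot partner of each array is a
    pseudo-reference: the per-probe mean across all arrays.  The lowess trend
    of (array - reference) against the reference is fitted and subtracted.
    """
    if not (0 < span <= 1):
        raise ValueError(f"span must be in (0, 1], got {span}")
    if m.n_samples < 2:
        raise ValueError("need at least 2 arrays for within-array normalization")
    values = m.values.to_numpy(dtype=float)
    ref = values.mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        dev = values[:, j] - ref
        trend = _sm_lowess(dev, ref, frac=span, it=iterations, return_sorted=False)
        out[:, j] = values[:, j] - trend
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.values.index, columns=m.values.columns),
        m.design, level=m.level,
    )


def quantile_between_arrays(m: ExpressionMatrix) -> ExpressionMatrix:
    """Average-quantile normalization: rank k maps to the mean rank-k value.

    After the operation every column has the identical sorted vector.  Tied
    values within a column receive the mean of the reference values their
    ranks span, so the map stays well defined and order preserving.
    """
    values = m.values.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("missing values are not allowed in quantile normalization")
    n_rows, n_cols = values.shape
    if n_cols == 1:
        warnings.warn("single array: quantile normalization is the identity",
                      RuntimeWarning)
        return m
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(n_cols):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        mapped = np.empty(n_rows)
        mapped[order] = reference
        # ties: average the reference values spanned by each tied run
        s = pd.Series(mapped)
        out[:, j] = s.groupby(col, sort=False).transform("mean").to_numpy()
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.values.index, columns=m.values.columns),
        m.design, level=m.level,
    )


def average_duplicates(m: ExpressionMatrix) -> ExpressionMatrix:
    """Collapse duplicate spots: rows sharing a probe_id become their mean.

    First-occurrence row order is preserved.
    """
    if not m.values.index.has_duplicates:
        return m
    collapsed = m.values.groupby(level=0, sort=False).mean()
    return ExpressionMatrix(collapsed, m.design, level=m.level)


# ---------------------------------------------------------------------------
# The full chain
# ---------------------------------------------------------------------------


def preprocess_experiment(
    scans: Sequence[ArrayScan],
    design: DesignTable,
    config: Optional[dict] = None,
    return_report: bool = False,
):
    """Run normexp -> log2 -> lowess -> quantile -> duplicate averaging.

    All scans must share the identical ordered probe_id sequence.  Returns a
    probe-level ExpressionMatrix; with ``return_report=True`` also returns a
    per-array report of fitted normexp parameters.
    """
    from .io_formats import DEFAULT_CONFIG

    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)

    if not scans:
        raise ValueError("no arrays given")
    probe_ids = scans[0].probe_ids
    for scan in scans[1:]:
        if scan.probe_ids != probe_ids:
            raise ValueError(
                f"array {scan.array_id} probe order differs from {scans[0].array_id}"
            )
    order = [s.array_id for s in scans]
    if set(order) != set(design.samples):
        raise ValueError("scan array_ids do not match design sample_ids")

    keep = np.ones(len(probe_ids), dtype=bool)
    if cfg["exclude_flagged"]:
        flags = np.stack([np.asarray(s.probes["flag"]) for s in scans], axis=1)
        keep = ~(flags < 0).any(axis=1)

    cols = {}
    report_rows = []
    for scan in scans:
        x = np.asarray(scan.probes["foreground"], dtype=float)
        if cfg["use_local_background"]:
            x = x - np.asarray(scan.probes["background"], dtype=float)
        x = x[keep]
        params = estimate_normexp(x)
        signal = normexp_correct(x, params)
        cols[scan.array_id] = np.log2(signal + cfg["log_offset"])
        report_rows.append(
            {"array_id": scan.array_id, "mu": params.mu, "sigma": params.sigma,
             "alpha": params.alpha}
        )

    index = pd.Index(np.asarray(probe_ids, dtype=object)[keep])
    values = pd.DataFrame(cols, index=index)[design.samples]
    matrix = ExpressionMatrix(values, design, level="probe")
    matrix = lowess_within_array(matrix, span=cfg["lowess_span"],
                                 iterations=cfg["lowess_iterations"])
    matrix = quantile_between_arrays(matrix)
    matrix = average_duplicates(matrix)
    if return_report:
        return matrix, pd.DataFrame(report_rows).set_index("array_id")
    return matrix
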