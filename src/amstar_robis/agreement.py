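"""Gwet's chance-corrected agreement coefficients with confidence intervals.

For two raters assigning *n* subjects to *q* ordered categories with an
agreement-weight matrix ``W`` (identity weights give the unweighted AC1;
quadratic weights give the weighted AC2), the coefficient is

    AC = (pa - pe) / (1 - pe)

with observed agreement ``pa = (1/n) sum_i w[a_i, b_i]`` and chance
agreement based on the average category propensities
``pi_k = (1/2n) sum_i [1(a_i = k) + 1(b_i = k)]``:

    pe = (T_w / (q (q - 1))) * sum_k pi_k (1 - pi_k),   T_w = sum_{k,l} w_kl.

Unlike kappa-type statistics, the chance term shrinks when the marginal
distribution is extreme, which keeps the coefficient stable for the highly
skewed verdict distributions typical of methodological-quality appraisal.

Standard errors come from the delete-one jackknife; 95% intervals are Wald
intervals with the upper bound truncated at 1 (the lower bound is left
untruncated, so slightly negative bounds are reported as such).  A paired
nonparametric bootstrap is provided as a cross-check.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .harmonization import HarmonizedPairs

__all__ = [
    "WeightMatrix",
    "AgreementResult",
    "Band",
    "InsufficientDataError",
    "DegenerateSampleError",
    "identity_weights",
    "quadratic_weights",
    "gwet_ac",
    "jackknife_ci",
    "bootstrap_se",
    "classify_band",
    "Z_95",
]

#: Normal 97.5% quantile used for all 95% Wald intervals.
Z_95 = 1.959964


class InsufficientDataError(ValueError):
    """Fewer pairs than the statistic or its variance estimator requires."""


class DegenerateSampleError(ValueError):
    """Chance agreement reached 1, leaving the coefficient undefined."""


@dataclass(frozen=True)
class WeightMatrix:
    """Symmetric agreement weights over q ordered categories, unit diagonal."""

    q: int
    w: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        if w.shape != (self.q, self.q):
            raise ValueError(f"weight matrix must be {self.q}x{self.q}")
        if not np.allclose(w, w.T):
            raise ValueError("weight matrix must be symmetric")
        if not np.allclose(np.diag(w), 1.0):
            raise ValueError("weight matrix must have unit diagonal")
        if w.min() < 0.0 or w.max() > 1.0:
            raise ValueError("weights must lie in [0, 1]")
        object.__setattr__(self, "w", w)

    @property
    def total_weight(self) -> float:
        return float(self.w.sum())


def identity_weights(q: int) -> WeightMatrix:
    """Identity weights: full credit for exact agreement only (AC1)."""
    if q < 2:
        raise ValueError("need at least 2 categories")
    return WeightMatrix(q=q, w=np.eye(q))


def quadratic_weights(q: int) -> WeightMatrix:
    """Quadratic weights w_kl = 1 - (k - l)^2 / (q - 1)^2.

    For q = 2 this reduces to identity weights.
    """
    if q < 2:
        raise ValueError("need at least 2 categories")
    k = np.arange(q, dtype=float)
    w = 1.0 - np.subtract.outer(k, k) ** 2 / (q - 1) ** 2
    return WeightMatrix(q=q, w=w)


class Band(str, enum.Enum):
    """Qualitative agreement bands (Landis–Koch-style thresholds)."""

    POOR = "POOR"
    SLIGHT = "SLIGHT"
    FAIR = "FAIR"
    MODERATE = "MODERATE"
    SUBSTANTIAL = "SUBSTANTIAL"
    ALMOST_PERFECT = "ALMOST_PERFECT"


# half-open intervals (lo, hi]; POOR covers everything <= 0
_BAND_EDGES = (
    (0.0, Band.POOR),
    (0.20, Band.SLIGHT),
    (0.40, Band.FAIR),
    (0.60, Band.MODERATE),
    (0.80, Band.SUBSTANTIAL),
    (1.0, Band.ALMOST_PERFECT),
)


def classify_band(estimate: float) -> Band:
    """Label a coefficient: poor (<= 0), slight (0, 0.2], fair (0.2, 0.4],
    moderate (0.4, 0.6], substantial (0.6, 0.8], almost perfect (0.8, 1]."""
    if estimate > 1.0:
        raise ValueError(f"agreement coefficient cannot exceed 1, got {estimate}")
    for hi, band in _BAND_EDGES:
        if estimate <= hi:
            return band
    raise AssertionError("unreachable")  # pragma: no cover


@dataclass(frozen=True)
class AgreementResult:
    """Coefficient with its uncertainty and qualitative band."""

    estimate: float
    pa: float
    pe: float
    se: float
    ci_low: float
    ci_high: float
    n: int
    q: int
    band: Band
    weighting: str


def _encode(
    pairs: HarmonizedPairs | Sequence[tuple[str, str]],
    scale: Sequence[str] | None,
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    if isinstance(pairs, HarmonizedPairs):
        scale = pairs.scale if scale is None else tuple(scale)
        raw = pairs.pairs
    else:
        raw = list(pairs)
        if scale is None:
            raise ValueError("scale is required when passing bare pairs")
        scale = tuple(scale)
    index = {c: i for i, c in enumerate(scale)}
    try:
        a = np.array([index[x] for x, _ in raw], dtype=np.intp)
        b = np.array([index[y] for _, y in raw], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(f"category {exc.args[0]!r} not on scale {scale}") from None
    return a, b, scale


def _ac_from_stats(
    pa: float, counts: np.ndarray, n: int, weights: WeightMatrix
) -> tuple[float, float]:
    q = weights.q
    pi = counts / (2.0 * n)
    pe = weights.total_weight / (q * (q - 1.0)) * float(np.sum(pi * (1.0 - pi)))
    if pe >= 1.0 - 1e-12:
        raise DegenerateSampleError(
            f"chance agreement pe = {pe:.6f}; coefficient undefined "
            f"(category counts: {counts.tolist()})"
        )
    return (pa - pe) / (1.0 - pe), pe


def gwet_ac(
    pairs: HarmonizedPairs | Sequence[tuple[str, str]],
    weights: WeightMatrix | None = None,
    scale: Sequence[str] | None = None,
    alpha: float = 0.05,
    ci: bool = True,
) -> AgreementResult:
    """Gwet's agreement coefficient for paired categorical ratings.

    ``scale`` fixes the full ordered category set (q is design-fixed, not
    data-driven: unobserved categories contribute pi_k = 0 to the chance
    term).  With ``weights=None`` identity weights are used, giving the
    unweighted AC1.  Requires n >= 2; the jackknife CI requires n >= 3 and
    is skipped when ``ci=False`` (se and bounds are then NaN).
    """
    a, b, scale_t = _encode(pairs, scale)
    n = a.size
    if n < 2:
        raise InsufficientDataError(f"need at least 2 pairs, got {n}")
    q = len(scale_t)
    if q < 2:
        raise ValueError("need at least 2 categories on the scale")
    weights = identity_weights(q) if weights is None else weights
    if weights.q != q:
        raise ValueError(f"weight matrix is {weights.q}x{weights.q}, scale has q={q}")

    w_obs = weights.w[a, b]
    pa = float(w_obs.mean())
    counts = np.bincount(a, minlength=q) + np.bincount(b, minlength=q)
    est, pe = _ac_from_stats(pa, counts.astype(float), n, weights)

    if ci:
        se, lo, hi = jackknife_ci(pairs, weights=weights, scale=scale_t, alpha=alpha)
    else:
        se = lo = hi = float("nan")
    return AgreementResult(
        estimate=est, pa=pa, pe=pe, se=se, ci_low=lo, ci_high=hi,
        n=n, q=q, band=classify_band(est),
        weighting="IDENTITY" if np.allclose(weights.w, np.eye(q)) else "QUADRATIC",
    )


def jackknife_ci(
    pairs: HarmonizedPairs | Sequence[tuple[str, str]],
    weights: WeightMatrix | None = None,
    scale: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> tuple[float, float, float]:
    """Delete-one jackknife standard error and Wald interval.

    ``se = sqrt(((n-1)/n) * sum_i (AC_(-i) - mean)^2)``; the interval is
    ``estimate ± z_{1-alpha/2} se`` with the upper bound truncated at 1 and
    the lower bound left untruncated.  Leave-one-out replicates are grouped
    by the (a, b) category combination of the removed pair, so the cost is
    O(q^2) regardless of n.
    """
    a, b, scale_t = _encode(pairs, scale)
    n = a.size
    if n < 3:
        raise InsufficientDataError(f"jackknife needs at least 3 pairs, got {n}")
    q = len(scale_t)
    weights = identity_weights(q) if weights is None else weights

    w_obs = weights.w[a, b]
    pa_sum = float(w_obs.sum())
    counts = (np.bincount(a, minlength=q) + np.bincount(b, minlength=q)).astype(float)
    estimate, _ = _ac_from_stats(pa_sum / n, counts, n, weights)

    combo = Counter(zip(a.tolist(), b.tolist()))
    loo_vals: list[float] = []
    loo_mult: list[int] = []
    degenerate: list[tuple[int, int]] = []
    for (ka, kb), mult in sorted(combo.items()):
        c = counts.copy()
        c[ka] -= 1
        c[kb] -= 1
        pa_i = (pa_sum - weights.w[ka, kb]) / (n - 1)
        try:
            ac_i, _ = _ac_from_stats(pa_i, c, n - 1, weights)
        except DegenerateSampleError:
            degenerate.append((ka, kb))
            continue
        loo_vals.append(ac_i)
        loo_mult.append(mult)
    if degenerate:
        combos = [(scale_t[ka], scale_t[kb]) for ka, kb in degenerate]
        raise DegenerateSampleError(
            f"leave-one-out subsets degenerate when removing pairs {combos}"
        )

    vals = np.asarray(loo_vals)
    mult = np.asarray(loo_mult, dtype=float)
    mean = float((vals * mult).sum() / n)
    ss = float((mult * (vals - mean) ** 2).sum())
    se = float(np.sqrt((n - 1) / n * ss))
    z = _z_quantile(alpha)
    return se, estimate - z * se, min(1.0, estimate + z * se)


def _z_quantile(alpha: float) -> float:
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if abs(alpha - 0.05) < 1e-12:
        return Z_95
    # Acklam's rational approximation of the normal quantile; plenty for CIs.
    p = 1.0 - alpha / 2.0
    a = (-3.969683028665376e01, 2.209460984245205e02, -2.759285104469687e02,
         1.383577518672690e02, -3.066479806614716e01, 2.506628277459239e00)
    bq = (-5.447609879822406e01, 1.615858368580409e02, -1.556989798598866e02,
          6.680131188771972e01, -1.328068155288572e01)
    c = (-7.784894002430293e-03, -3.223964580411365e-01, -2.400758277161838e00,
         -2.549732539343734e00, 4.374664141464968e00, 2.938163982698783e00)
    d = (7.784695709041462e-03, 3.224671290700398e-01, 2.445134137142996e00,
         3.754408661907416e00)
    plow = 0.02425
    if p < plow:
        qv = np.sqrt(-2 * np.log(p))
        return (((((c[0] * qv + c[1]) * qv + c[2]) * qv + c[3]) * qv + c[4]) * qv + c[5]) / \
            ((((d[0] * qv + d[1]) * qv + d[2]) * qv + d[3]) * qv + 1)
    if p <= 1 - plow:
        qv = p - 0.5
        r = qv * qv
        return (((((a[0] * r + a[1]) * r + a[2]) * r + a[3]) * r + a[4]) * r + a[5]) * qv / \
            (((((bq[0] * r + bq[1]) * r + bq[2]) * r + bq[3]) * r + bq[4]) * r + 1)
    qv = np.sqrt(-2 * np.log(1 - p))
    return -(((((c[0] * qv + c[1]) * qv + c[2]) * qv + c[3]) * qv + c[4]) * qv + c[5]) / \
        ((((d[0] * qv + d[1]) * qv + d[2]) * qv + d[3]) * qv + 1)


def bootstrap_se(
    pairs: HarmonizedPairs | Sequence[tuple[str, str]],
    weights: WeightMatrix | None = None,
    scale: Sequence[str] | None = None,
    n_boot: int = 10_000,
    seed: int = 0,
) -> float:
    """Paired nonparametric bootstrap standard error (cross-check only).

    Resamples pairs with replacement; degenerate resamples (undefined
    coefficient) are dropped from the replicate set.
    """
    a, b, scale_t = _encode(pairs, scale)
    n = a.size
    if n < 2:
        raise InsufficientDataError(f"need at least 2 pairs, got {n}")
    q = len(scale_t)
    weights = identity_weights(q) if weights is None else weights
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    reps: list[float] = []
    for row in idx:
        aa, bb = a[row], b[row]
        pa = float(weights.w[aa, bb].mean())
        counts = (np.bincount(aa, minlength=q) + np.bincount(bb, minlength=q)).astype(float)
        try:
            ac, _ = _ac_from_stats(pa, counts, n, weights)
        except DegenerateSampleError:
            continue
        reps.append(ac)
    if len(reps) < 2:
        raise InsufficientDataError("all bootstrap resamples degenerate")
    return float(np.std(reps, ddof=1))
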