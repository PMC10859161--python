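"""Causal-effect estimators and heterogeneity diagnostics for two-sample MR.

All estimators operate on harmonized instruments: per-SNP exposure effects
``beta_exp`` (log odds per effect allele), outcome effects ``beta_out`` and
their standard errors. Causal effects are reported on the log-odds-per-
log-odds scale, with odds ratios obtained by exponentiation.

The estimator suite mirrors standard two-sample MR practice:

* ``wald_ratio`` — single-SNP estimate ``beta_out / beta_exp``.
* ``ivw_mre`` — inverse-variance-weighted regression through the origin with
  a multiplicative random-effects scale floored at 1 (the under-dispersion
  correction), plus Cochran's Q.
* ``egger`` — weighted regression with an intercept; the intercept is the
  directional-pleiotropy test.
* ``weighted_median`` / ``weighted_mode`` — pleiotropy-robust estimators with
  parametric-bootstrap standard errors.
* ``leave_one_out`` / ``single_snp`` — per-SNP influence diagnostics.

First-order weights are used throughout (the SE of a ratio estimate is
approximated by ``se_out / |beta_exp|``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy.stats import chi2, median_abs_deviation, norm, t as t_dist

__all__ = [
    "MREstimate",
    "HeterogeneityStats",
    "NotEstimableError",
    "wald_ratio",
    "ivw_mre",
    "egger",
    "weighted_median",
    "weighted_mode",
    "leave_one_out",
    "single_snp",
]

Z95 = float(norm.ppf(0.975))


class NotEstimableError(ValueError):
    """Raised when an estimator's minimum instrument count is not met."""

    def __init__(self, method: str, n_snp: int, required: int):
        self.method, self.n_snp, self.required = method, n_snp, required
        super().__init__(f"{method} requires >= {required} instruments, got {n_snp}")


@dataclass(frozen=True)
class MREstimate:
    """One estimator's causal effect (log-odds per log-odds scale)."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)

    @property
    def or_ci(self) -> tuple[float, float]:
        return math.exp(self.ci_low), math.exp(self.ci_high)

    def as_dict(self) -> dict:
        return {
            "method": self.method, "n_snp": self.n_snp, "beta": self.beta,
            "se": self.se, "ci_low": self.ci_low, "ci_high": self.ci_high,
            "pval": self.pval, "or": self.odds_ratio,
            "or_ci_low": self.or_ci[0], "or_ci_high": self.or_ci[1],
        }


@dataclass(frozen=True)
class HeterogeneityStats:
    """Cochran's Q for the per-SNP ratio estimates."""

    q: float
    df: int
    pval: float

    def as_dict(self) -> dict:
        return {"q": self.q, "df": self.df, "pval": self.pval}


def _arrays(instruments) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Extract (beta_exp, se_exp, beta_out, se_out, ids) from instruments.

    Accepts a sequence of objects with the harmonized-instrument attributes,
    an :class:`~thrombomr.instruments.InstrumentSet`, or a 4-tuple/list of
    arrays ``(beta_exp, se_exp, beta_out, se_out)``.
    """
    inner = getattr(instruments, "instruments", instruments)
    if (
        isinstance(inner, (tuple, list)) and len(inner) == 4
        and np.ndim(inner[0]) == 1 and not hasattr(inner[0], "beta_exp")
    ):
        bx, sx, by, sy = (np.asarray(a, dtype=float) for a in inner)
        ids = [f"snp{i}" for i in range(bx.size)]
    else:
        bx = np.array([i.beta_exp for i in inner], dtype=float)
        sx = np.array([i.se_exp for i in inner], dtype=float)
        by = np.array([i.beta_out for i in inner], dtype=float)
        sy = np.array([i.se_out for i in inner], dtype=float)
        ids = [i.snp_id for i in inner]
    if np.any(sy <= 0) or np.any(sx <= 0):
        raise ValueError("standard errors must be positive")
    return bx, sx, by, sy, ids


def _normal_estimate(method: str, beta: float, se: float, n_snp: int) -> MREstimate:
    p = float(2 * norm.sf(abs(beta) / se)) if se > 0 else float(beta == 0.0)
    return MREstimate(method, float(beta), float(se),
                      float(beta - Z95 * se), float(beta + Z95 * se), p, n_snp)


def wald_ratio(beta_exp: float, se_exp: float, beta_out: float, se_out: float) -> MREstimate:
    """Single-SNP causal estimate ``beta_out / beta_exp``.

    The SE uses the first-order delta method, ``|se_out / beta_exp|``; the
    exposure-side uncertainty is ignored, as is standard for strong
    instruments.
    """
    if beta_exp == 0:
        raise ValueError("wald_ratio requires a non-zero exposure effect")
    if se_out <= 0:
        raise ValueError("se_out must be positive")
    beta = beta_out / beta_exp
    se = abs(se_out / beta_exp)
    return _normal_estimate("wald", beta, se, 1)


def ivw_mre(instruments) -> tuple[MREstimate, HeterogeneityStats]:
    """Inverse-variance-weighted estimate, multiplicative random effects.

    Weighted regression of ``beta_out`` on ``beta_exp`` through the origin
    with weights ``1/se_out²``. The fixed-effect SE is inflated by
    ``max(1, sqrt(Q/(n-1)))`` — the multiplicative random-effects scale with
    the under-dispersion floor — and the p-value is two-sided normal.
    Raises :class:`NotEstimableError` for a single instrument (callers fall
    back to the Wald ratio).
    """
    bx, sx, by, sy, _ = _arrays(instruments)
    n = bx.size
    if n < 2:
        raise NotEstimableError("ivw_mre", n, 2)
    w = 1.0 / sy**2
    s2 = float(np.sum(w * bx**2))
    beta = float(np.sum(w * bx * by)) / s2
    se_fixed = math.sqrt(1.0 / s2)
    # Q with first-order weights: sum_j (beta_out_j - beta*beta_exp_j)^2/se_out_j^2
    q = float(np.sum(w * (by - beta * bx) ** 2))
    df = n - 1
    phi = q / df
    se = se_fixed * max(1.0, math.sqrt(phi))
    het = HeterogeneityStats(q, df, float(chi2.sf(q, df)))
    return _normal_estimate("ivw_mre", beta, se, n), het


def _reorient(bx, sx, by, sy):
    sign = np.where(bx < 0, -1.0, 1.0)
    return bx * sign, sx, by * sign, sy


def egger(instruments, reorient: bool = True) -> tuple[MREstimate, MREstimate]:
    """MR-Egger regression; returns ``(slope, intercept)`` estimates.

    Each SNP is first orientated so its exposure effect is positive (both
    effect signs flipped where needed), then ``beta_out`` is regressed on
    ``beta_exp`` with an intercept and weights ``1/se_out²`` via the closed-
    form weighted normal equations. Both SEs carry the multiplicative
    under-dispersion floor ``max(1, sqrt(RSS_w/(n-2)))``; p-values use a t
    distribution with ``n-2`` degrees of freedom. The intercept is the
    directional-pleiotropy test.
    """
    bx, sx, by, sy, _ = _arrays(instruments)
    n = bx.size
    if n < 3:
        raise NotEstimableError("egger", n, 3)
    if reorient:
        bx, sx, by, sy = _reorient(bx, sx, by, sy)
    w = 1.0 / sy**2
    sw, swx = float(np.sum(w)), float(np.sum(w * bx))
    swxx, swy, swxy = float(np.sum(w * bx**2)), float(np.sum(w * by)), float(np.sum(w * bx * by))
    det = sw * swxx - swx**2
    if det <= 0:
        raise ValueError("degenerate design: exposure effects have no weighted spread")
    intercept = (swxx * swy - swx * swxy) / det
    slope = (sw * swxy - swx * swy) / det
    resid = by - intercept - slope * bx
    rss_w = float(np.sum(w * resid**2))
    phi = rss_w / (n - 2)
    scale = max(1.0, math.sqrt(phi))
    se_slope = math.sqrt(sw / det) * scale
    se_int = math.sqrt(swxx / det) * scale
    tq = float(t_dist.ppf(0.975, n - 2))

    def _t_estimate(method, b, se):
        p = float(2 * t_dist.sf(abs(b) / se, n - 2))
        return MREstimate(method, float(b), float(se), float(b - tq * se),
                          float(b + tq * se), p, n)

    return _t_estimate("egger_slope", slope, se_slope), _t_estimate("egger_intercept", intercept, se_int)


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Weighted 50th percentile with linear interpolation over cumulative weights."""
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    w = w / w.sum()
    cum = np.cumsum(w) - 0.5 * w  # midpoint cumulative weight of each SNP
    if cum[0] >= 0.5:
        return float(v[0])
    if cum[-1] < 0.5:
        return float(v[-1])
    k = int(np.searchsorted(cum, 0.5, side="left"))
    if cum[k] == 0.5:
        return float(v[k])
    lo = k - 1
    return float(v[lo] + (v[k] - v[lo]) * (0.5 - cum[lo]) / (cum[k] - cum[lo]))


def _bootstrap_se(estimator, bx, sx, by, sy, n_boot, seed) -> float:
    rng = np.random.default_rng(seed)
    est = np.empty(n_boot)
    for b in range(n_boot):
        bxb = rng.normal(bx, sx)
        byb = rng.normal(by, sy)
        est[b] = estimator(bxb, byb)
    return float(np.std(est, ddof=1))


def weighted_median(instruments, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted-median estimator with a parametric-bootstrap SE.

    Per-SNP ratio estimates are ordered and the weighted 50th percentile is
    interpolated over cumulative weights ``w_j = beta_exp_j² / se_out_j²``
    (normalized). The SE is the SD of the estimate across ``n_boot``
    parametric resamples of the summary statistics (weights held fixed);
    deterministic given ``seed``. Consistent when at least half the weight
    comes from valid instruments.
    """
    bx, sx, by, sy, _ = _arrays(instruments)
    n = bx.size
    if n < 3:
        raise NotEstimableError("weighted_median", n, 3)
    weights = bx**2 / sy**2
    beta = _weighted_median(by / bx, weights)
    se = _bootstrap_se(lambda bxb, byb: _weighted_median(byb / bxb, weights),
                       bx, sx, by, sy, n_boot, seed)
    return _normal_estimate("weighted_median", beta, se, n)


def _mode_bandwidth(ratios: np.ndarray, phi: float) -> float:
    sd = float(np.std(ratios, ddof=1))
    mad = float(median_abs_deviation(ratios, scale="normal"))
    s = 0.9 * min(sd, mad if mad > 0 else sd) / len(ratios) ** 0.2
    return max(1e-8, phi * s)


def _mode_estimate(ratios: np.ndarray, weights: np.ndarray, h: float) -> float:
    # argmax of the weighted Gaussian kernel density: coarse grid + local refinement
    lo, hi = ratios.min() - 3 * h, ratios.max() + 3 * h
    grid = np.linspace(lo, hi, 1024)
    dens = (weights[None, :] * np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2)).sum(axis=1)
    k = int(np.argmax(dens))
    a, b = grid[max(k - 1, 0)], grid[min(k + 1, grid.size - 1)]
    from scipy.optimize import minimize_scalar

    def neg_density(x):
        return -float((weights * np.exp(-0.5 * ((x - ratios) / h) ** 2)).sum())

    res = minimize_scalar(neg_density, bounds=(a, b), method="bounded",
                          options={"xatol": 1e-10})
    return float(res.x)


def weighted_mode(instruments, phi: float = 1.0, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted-mode estimator (mode of the smoothed ratio distribution).

    The estimate is the argmax of a Gaussian-kernel-weighted density of the
    per-SNP ratios with inverse-variance weights (first-order ratio SEs) and
    bandwidth ``phi`` times a modified-Silverman scale
    ``0.9 · min(sd, mad) · n^{-1/5}``. SE by parametric bootstrap as for the
    weighted median. Consistent when the largest weight cluster comes from
    valid instruments (the ZEMPA assumption).
    """
    if phi <= 0:
        raise ValueError("phi must be positive")
    bx, sx, by, sy, _ = _arrays(instruments)
    n = bx.size
    if n < 3:
        raise NotEstimableError("weighted_mode", n, 3)
    ratios = by / bx
    se_ratio = sy / np.abs(bx)
    weights = se_ratio**-2
    weights = weights / weights.sum()
    if np.allclose(ratios, ratios[0]):
        beta = float(ratios[0])
    else:
        beta = _mode_estimate(ratios, weights, _mode_bandwidth(ratios, phi))

    def boot(bxb, byb):
        r = byb / bxb
        if np.allclose(r, r[0]):
            return float(r[0])
        return _mode_estimate(r, weights, _mode_bandwidth(r, phi))

    se = _bootstrap_se(boot, bx, sx, by, sy, n_boot, seed)
    return _normal_estimate("weighted_mode", beta, se, n)


def leave_one_out(instruments) -> list[tuple[str, MREstimate]]:
    """IVW estimate after deleting each instrument in turn (input order)."""
    bx, sx, by, sy, ids = _arrays(instruments)
    n = bx.size
    if n < 3:
        raise NotEstimableError("leave_one_out", n, 3)
    out = []
    for j in range(n):
        keep = np.arange(n) != j
        est, _ = ivw_mre((bx[keep], sx[keep], by[keep], sy[keep]))
        out.append((ids[j], est))
    return out


def single_snp(instruments) -> tuple[list[tuple[str, MREstimate]], pd.DataFrame]:
    """Per-SNP Wald ratios plus the funnel table (ratio vs precision).

    The funnel table columns are ``snp``, ``ratio`` and ``precision``
    (1 / SE of the ratio); under no pleiotropy, points scatter symmetrically
    about the pooled estimate with spread shrinking as precision grows.
    """
    bx, sx, by, sy, ids = _arrays(instruments)
    if bx.size < 1:
        raise NotEstimableError("single_snp", 0, 1)
    estimates = [(ids[j], wald_ratio(bx[j], sx[j], by[j], sy[j])) for j in range(bx.size)]
    funnel = pd.DataFrame({
        "snp": ids,
        "ratio": by / bx,
        "precision": np.abs(bx) / sy,
    })
    return estimates, funnel
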