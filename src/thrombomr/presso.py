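"""MR-PRESSO: resampling-based horizontal-pleiotropy diagnostics.

The pleiotropy residual sum of squares (PRESSO) framework detects horizontal
pleiotropy by comparing observed leave-one-out regression residuals against
their parametric-bootstrap distribution under the no-pleiotropy model:

* **Global test** — for each SNP ``j`` the fixed-effect IVW estimate is
  computed on the set excluding ``j``; the weighted squared residual
  ``(beta_out_j - beta_(-j)·beta_exp_j)² / se_out_j²`` accumulates into the
  observed RSS. Simulated datasets draw ``beta_exp* ~ N(beta_exp, se_exp)``
  and ``beta_out* ~ N(beta_(-j)·beta_exp_j, se_out)``, and the Monte-Carlo
  tail probability of the observed RSS is reported.
* **Outlier test** — each SNP's observed weighted squared residual is
  referred to its own simulated distribution, Bonferroni-adjusted across
  SNPs; flagged SNPs are removed and the IVW estimate recomputed.
* **Distortion test** — the shift in the causal estimate caused by removing
  the flagged outliers is compared against the shifts produced by removing
  equally many randomly chosen non-outlier SNPs.

All resampling is vectorized and deterministic given the seed. A minimum of
three instruments is required; the distortion test is unstable below four.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .estimators import MREstimate, NotEstimableError, _arrays, ivw_mre

__all__ = ["PressoResult", "presso_global", "presso_outlier", "presso_distortion", "run_presso"]


@dataclass
class PressoResult:
    """Outputs of the PRESSO global, outlier and distortion tests."""

    rss_obs: float
    global_p: float
    n_sim: int
    seed: int
    snp_ids: list[str] = field(default_factory=list)
    outlier_p_raw: list[float] = field(default_factory=list)
    outlier_p: list[float] = field(default_factory=list)   # Bonferroni-adjusted
    outliers: list[str] = field(default_factory=list)
    corrected: MREstimate | None = None
    distortion_p: float | None = None

    def as_dict(self) -> dict:
        return {
            "rss_obs": self.rss_obs,
            "global_p": self.global_p,
            "n_sim": self.n_sim,
            "seed": self.seed,
            "outlier_table": [
                {"snp": s, "raw_p": rp, "adj_p": ap, "flagged": s in self.outliers}
                for s, rp, ap in zip(self.snp_ids, self.outlier_p_raw, self.outlier_p)
            ],
            "outliers": list(self.outliers),
            "corrected": self.corrected.as_dict() if self.corrected else None,
            "distortion_p": self.distortion_p,
        }


def _loo_fixed_ivw(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out fixed-effect IVW estimates, one per excluded SNP.

    Works on 1-D arrays or batches with shape (n_sim, n_snp); weights are
    1-D over SNPs.
    """
    s1 = np.sum(w * bx * by, axis=-1, keepdims=True)
    s2 = np.sum(w * bx * bx, axis=-1, keepdims=True)
    return (s1 - w * bx * by) / (s2 - w * bx * bx)


def _presso_core(instruments, n_sim: int, seed: int):
    bx, sx, by, sy, ids = _arrays(instruments)
    n = bx.size
    if n < 3:
        raise NotEstimableError("presso", n, 3)
    if n_sim < 100:
        raise ValueError("n_sim must be at least 100")
    w = 1.0 / sy**2

    beta_loo = _loo_fixed_ivw(bx, by, w)           # (n,)
    resid = by - beta_loo * bx
    stat_obs = w * resid**2                         # per-SNP weighted squared residual
    rss_obs = float(stat_obs.sum())

    rng = np.random.default_rng(seed)
    expected = beta_loo * bx                        # no-pleiotropy expectation per SNP
    bx_sim = rng.normal(bx, sx, size=(n_sim, n))
    by_sim = rng.normal(expected, sy, size=(n_sim, n))
    beta_loo_sim = _loo_fixed_ivw(bx_sim, by_sim, w)
    resid_sim = by_sim - beta_loo_sim * bx_sim
    stat_sim = w * resid_sim**2                     # (n_sim, n)
    rss_sim = stat_sim.sum(axis=1)

    return bx, sx, by, sy, ids, stat_obs, rss_obs, stat_sim, rss_sim


def presso_global(instruments, n_sim: int = 1000, seed: int = 0) -> PressoResult:
    """Global horizontal-pleiotropy test.

    Returns a :class:`PressoResult` with the observed RSS and its
    Monte-Carlo tail probability ``(1 + #{RSS* >= RSS_obs}) / (n_sim + 1)``
    (granularity ``1/(n_sim+1)``); deterministic given ``seed``.
    """
    *_, ids, _stat_obs, rss_obs, _stat_sim, rss_sim = _presso_core(instruments, n_sim, seed)
    global_p = (1 + int(np.sum(rss_sim >= rss_obs))) / (n_sim + 1)
    return PressoResult(rss_obs=rss_obs, global_p=float(global_p),
                        n_sim=n_sim, seed=seed, snp_ids=list(ids))


def presso_outlier(instruments, n_sim: int = 1000, seed: int = 0, alpha: float = 0.05) -> PressoResult:
    """Per-SNP outlier test with Bonferroni adjustment and corrected estimate.

    Re-runs the same seeded simulation as :func:`presso_global`, refers each
    SNP's observed weighted squared residual to its simulated distribution,
    multiplies the tail probability by the SNP count (capped at 1) and flags
    SNPs below ``alpha``. The corrected estimate is the multiplicative
    random-effects IVW on the unflagged SNPs (``None`` if fewer than two
    remain).
    """
    bx, sx, by, sy, ids, stat_obs, rss_obs, stat_sim, rss_sim = _presso_core(instruments, n_sim, seed)
    n = bx.size
    raw = (1 + np.sum(stat_sim >= stat_obs[None, :], axis=0)) / (n_sim + 1)
    adj = np.minimum(1.0, raw * n)
    flagged = [ids[j] for j in range(n) if adj[j] < alpha]
    keep = np.array([s not in flagged for s in ids])
    corrected = None
    if keep.sum() >= 2:
        corrected, _ = ivw_mre((bx[keep], sx[keep], by[keep], sy[keep]))
    result = PressoResult(
        rss_obs=rss_obs,
        global_p=float((1 + int(np.sum(rss_sim >= rss_obs))) / (n_sim + 1)),
        n_sim=n_sim, seed=seed, snp_ids=list(ids),
        outlier_p_raw=[float(x) for x in raw],
        outlier_p=[float(x) for x in adj],
        outliers=flagged, corrected=corrected,
    )
    return result


def presso_distortion(instruments, outliers: list[str], n_sim: int = 1000, seed: int = 0) -> float:
    """Distortion test: is the outlier-driven estimate shift unusual?

    The observed shift is the difference between the IVW estimate without
    the flagged outliers and the full-set estimate. The null distribution is
    built by removing ``|outliers|`` randomly chosen non-outlier SNPs (one
    draw per replicate) and recording the resulting shift; the two-sided
    Monte-Carlo tail probability of the observed shift is returned.
    Raises :class:`ValueError` when no outliers are supplied.
    """
    if not outliers:
        raise ValueError("distortion test is not applicable without outliers")
    bx, sx, by, sy, ids = _arrays(instruments)
    n = bx.size
    is_out = np.array([s in set(outliers) for s in ids])
    if is_out.sum() == 0:
        raise ValueError("supplied outlier ids are not among the instruments")
    inlier_idx = np.flatnonzero(~is_out)
    k = int(is_out.sum())
    if inlier_idx.size - k < 2:
        raise ValueError("too few non-outlier SNPs for the distortion test")

    full, _ = ivw_mre((bx, sx, by, sy))
    corrected, _ = ivw_mre((bx[~is_out], sx[~is_out], by[~is_out], sy[~is_out]))
    d_obs = corrected.beta - full.beta

    rng = np.random.default_rng(seed)
    d_null = np.empty(n_sim)
    for b in range(n_sim):
        drop = rng.choice(inlier_idx, size=k, replace=False)
        keep = np.ones(n, dtype=bool)
        keep[drop] = False
        sub, _ = ivw_mre((bx[keep], sx[keep], by[keep], sy[keep]))
        d_null[b] = sub.beta - full.beta
    p = (1 + int(np.sum(np.abs(d_null) >= abs(d_obs)))) / (n_sim + 1)
    return float(p)


def run_presso(
    instruments,
    n_sim: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    distortion: bool = True,
) -> PressoResult:
    """Global + outlier tests, plus the distortion test when outliers exist."""
    result = presso_outlier(instruments, n_sim=n_sim, seed=seed, alpha=alpha)
    if distortion and result.outliers:
        try:
            result.distortion_p = presso_distortion(
                instruments, result.outliers, n_sim=n_sim, seed=seed
            )
        except ValueError:
            result.distortion_p = None
    return result
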