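"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the statistical structure of a bidirectional MR study
of two binary traits: a large exposure GWAS (thrombosis-scale: ~72k cases,
~1.06M controls, prevalence 0.2%) and a smaller outcome GWAS
(pancreatic-cancer-scale: ~9k cases, ~7k controls). Effects are generated
directly on the log-odds scale — the pipeline consumes summary statistics
only, so no individual-level genotypes are simulated — and instruments are
independent, matching the post-clumping state a real analysis operates on.

Per SNP ``j``:

* allele frequency ``p_j ~ U(eaf_range)``;
* true instrument effect ``gamma_j = floor + |N(0, scale)|`` (the effect
  allele is the exposure-risk allele, the orientation pleiotropy-direction
  tests assume);
* sampling noise SE ``se = 1 / sqrt(2 p (1-p) n_eff)`` with
  ``n_eff = 4 / (1/n_cases + 1/n_controls)`` — the standard binary-GWAS
  variance approximation;
* true outcome effect ``theta·gamma_j + alpha_j`` where ``alpha_j`` is the
  horizontal-pleiotropy term: zero (``none``), ``N(0, tau)`` (``balanced``)
  or ``N(mu, tau)`` (``directional``), plus a planted offset for designated
  outlier SNPs (the single-dominant-pleiotropic-variant scenario).

Observed effects add normal noise with those SEs; p-values come from the
Wald z. The truth record carries everything needed to score recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .gwas_io import AssociationRecord

__all__ = ["SimulationConfig", "simulate_pair", "simulate_outlier_scenario"]

_ALLELE_PAIRS = [  # non-palindromic pairs; generator may also emit palindromes
    ("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("C", "G")]


@dataclass
class SimulationConfig:
    """Generative parameters for a synthetic two-sample binary-trait study.

    Defaults mirror the study conditions the package targets: exposure GWAS
    at venous-thromboembolism scale, outcome at pancreatic-cancer scale,
    instrument effects strong enough to pass genome-wide significance
    (mean F of a few hundred).
    """

    n_snp: int = 60
    theta: float = 0.0                      # true causal effect, log-odds per log-odds
    eaf_range: tuple[float, float] = (0.05, 0.95)
    n_cases_exp: int = 71_771
    n_controls_exp: int = 1_059_740
    n_cases_out: int = 9_055
    n_controls_out: int = 7_203
    prevalence_exp: float = 0.002
    prevalence_out: float = 0.01
    instrument_floor: float = 0.03          # minimum |true exposure effect|
    instrument_scale: float = 0.035         # half-normal scale on top of the floor
    pleiotropy: str = "none"                # none | balanced | directional
    pleiotropy_mu: float = 0.0
    pleiotropy_tau: float = 0.0
    n_outliers: int = 0
    outlier_scale: float = 10.0             # offset in units of the median outcome SE
    palindrome_fraction: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_snp < 1:
            raise ValueError("n_snp must be at least 1")
        for name in ("n_cases_exp", "n_controls_exp", "n_cases_out", "n_controls_out"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("prevalence_exp", "prevalence_out"):
            if not (0 < getattr(self, name) < 1):
                raise ValueError(f"{name} must lie in (0, 1)")
        lo, hi = self.eaf_range
        if not (0 < lo < hi < 1):
            raise ValueError("eaf_range must satisfy 0 < lo < hi < 1")
        if self.pleiotropy not in ("none", "balanced", "directional"):
            raise ValueError("pleiotropy must be none, balanced or directional")
        if self.pleiotropy_tau < 0:
            raise ValueError("pleiotropy_tau must be non-negative")
        if self.n_outliers < 0 or self.n_outliers > self.n_snp:
            raise ValueError("n_outliers must lie in [0, n_snp]")


def _se_binary(eaf: np.ndarray, n_cases: int, n_controls: int) -> np.ndarray:
    n_eff = 4.0 / (1.0 / n_cases + 1.0 / n_controls)
    return 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n_eff)


def simulate_pair(
    config: SimulationConfig,
) -> tuple[list[AssociationRecord], list[AssociationRecord], dict]:
    """Generate matched exposure and outcome summary-statistics tables.

    Returns ``(exposure_records, outcome_records, truth)``. The outcome
    table presents each SNP with a randomly swapped allele order and/or
    complemented strand so the harmonizer is exercised end-to-end; the truth
    record is expressed in the exposure orientation.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_snp

    eaf = rng.uniform(*config.eaf_range, size=n)
    gamma = config.instrument_floor + np.abs(rng.normal(0.0, config.instrument_scale, size=n))

    if config.pleiotropy == "none":
        alpha = np.zeros(n)
    elif config.pleiotropy == "balanced":
        alpha = rng.normal(0.0, config.pleiotropy_tau, size=n)
    else:
        alpha = rng.normal(config.pleiotropy_mu, config.pleiotropy_tau, size=n)

    se_exp = _se_binary(eaf, config.n_cases_exp, config.n_controls_exp)
    se_out = _se_binary(eaf, config.n_cases_out, config.n_controls_out)

    outlier_ids: list[str] = []
    offset = np.zeros(n)
    if config.n_outliers:
        chosen = rng.choice(n, size=config.n_outliers, replace=False)
        offset[chosen] = config.outlier_scale * float(np.median(se_out))
        outlier_ids = [f"rs{j + 1}" for j in sorted(chosen)]

    true_out = config.theta * gamma + alpha + offset
    beta_exp_hat = gamma + rng.normal(0.0, se_exp)
    beta_out_hat = true_out + rng.normal(0.0, se_out)

    # allele pairs; a small fraction are palindromic to exercise harmonization
    is_palin = rng.uniform(size=n) < config.palindrome_fraction
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n)
    palin_idx = rng.integers(0, len(_PALINDROMIC_PAIRS), size=n)

    p_exp_all = 2 * norm.sf(np.abs(beta_exp_hat) / se_exp)
    p_out_all = 2 * norm.sf(np.abs(beta_out_hat) / se_out)

    exposure: list[AssociationRecord] = []
    outcome: list[AssociationRecord] = []
    for j in range(n):
        snp = f"rs{j + 1}"
        ea, oa = (_PALINDROMIC_PAIRS[palin_idx[j]] if is_palin[j] else _ALLELE_PAIRS[pair_idx[j]])
        p_exp = float(p_exp_all[j])
        p_out = float(p_out_all[j])
        exposure.append(AssociationRecord(
            snp, ea, oa, float(beta_exp_hat[j]), float(se_exp[j]), p_exp,
            float(eaf[j]), config.n_cases_exp, config.n_controls_exp, "exposure",
        ))
        # present the outcome row in a random (but truth-preserving) orientation
        ea_o, oa_o, b_o, f_o = ea, oa, float(beta_out_hat[j]), float(eaf[j])
        if not is_palin[j]:
            if rng.uniform() < 0.5:  # swap allele labels
                ea_o, oa_o, b_o, f_o = oa_o, ea_o, -b_o, 1.0 - f_o
            if rng.uniform() < 0.3:  # report the other strand
                comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
                ea_o, oa_o = comp[ea_o], comp[oa_o]
        outcome.append(AssociationRecord(
            snp, ea_o, oa_o, b_o, float(se_out[j]), p_out,
            f_o, config.n_cases_out, config.n_controls_out, "outcome",
        ))

    truth = {
        "theta": config.theta,
        "gamma": gamma.tolist(),
        "pleiotropy": alpha.tolist(),
        "outlier_offset": offset.tolist(),
        "outlier_ids": outlier_ids,
        "eaf": eaf.tolist(),
        "config": asdict(config),
    }
    return exposure, outcome, truth


def simulate_outlier_scenario(
    config: SimulationConfig | None = None, **overrides
) -> tuple[list[AssociationRecord], list[AssociationRecord], dict]:
    """A pair with one (or more) dominant pleiotropic SNPs planted.

    Models the empirical situation where a single strand-unambiguous variant
    with a large extraneous outcome effect drives the pooled IVW estimate:
    leave-one-out deletion of the planted SNP moves the estimate toward the
    true ``theta`` and the PRESSO outlier test should flag it. With the
    offset at zero the scenario reduces exactly to :func:`simulate_pair`.
    """
    if config is None:
        config = SimulationConfig(**overrides)
    if config.n_outliers < 1:
        config = SimulationConfig(**{**asdict(config), "n_outliers": 1})
    config.validate()
    return simulate_pair(config)
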