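"""Instrument selection and validation for two-sample MR on binary traits.

Covers the pre-estimation stages: genome-wide-significance thresholding,
greedy LD clumping against a user-supplied LD matrix, instrument-strength
F statistics, liability-scale variance explained (r²) for case-control
traits, and Steiger directionality filtering.

Liability-scale r²
------------------
For a binary trait analysed by logistic regression, the per-allele log odds
ratio ``b`` and effect-allele frequency ``p`` are converted to the variance
in the latent liability explained by the SNP. The default (``scale='logit'``)
places the liability on the standard logistic scale: the genetic variance is
``vg = 2 p (1-p) b²`` and ``r² = vg / (vg + π²/3)``, with ``p`` first
de-ascertained from the case-control sample frequency to a population
frequency using the disease prevalence ``K``. A probit-threshold variant
(``scale='probit'``), which transforms an observed-scale R² through the
ascertainment correction of the classical liability-threshold model, is also
provided.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .gwas_io import AssociationRecord, DataError, HarmonizedInstrument

logger = logging.getLogger("thrombomr")

__all__ = [
    "LDMatrix",
    "InstrumentSet",
    "select_by_pvalue",
    "clump",
    "f_statistic",
    "r2_binary",
    "population_allele_frequency",
    "steiger_filter",
    "build_instrument_set",
]


@dataclass
class LDMatrix:
    """Pairwise LD (r²) between candidate instruments.

    The matrix is symmetric with unit diagonal and entries in [0, 1]; it is
    supplied by the user (e.g. computed from a reference panel elsewhere).
    """

    snp_ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        n = len(self.snp_ids)
        if self.r2.shape != (n, n):
            raise DataError("LD matrix shape does not match the SNP id list")
        if not np.allclose(self.r2, self.r2.T, atol=1e-8):
            raise DataError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-6):
            raise DataError("LD matrix diagonal must be 1")
        if self.r2.min() < -1e-9 or self.r2.max() > 1 + 1e-9:
            raise DataError("LD r2 values must lie in [0, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def pairwise(self, snp_a: str, snp_b: str) -> float:
        return float(self.r2[self._index[snp_a], self._index[snp_b]])

    @classmethod
    def read_tsv(cls, path) -> "LDMatrix":
        """Read a square TSV with a SNP-id header row and index column."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index) != list(df.columns):
            raise DataError("LD matrix row and column SNP ids differ")
        return cls(list(df.columns), df.to_numpy(dtype=float))


@dataclass
class InstrumentSet:
    """Validated instruments for one exposure-outcome analysis."""

    instruments: list[HarmonizedInstrument]
    exposure_prevalence: float | None = None
    outcome_prevalence: float | None = None
    total_r2_exp: float | None = None
    mean_f: float | None = None

    def __len__(self) -> int:
        return len(self.instruments)


def select_by_pvalue(
    records: Sequence[AssociationRecord], threshold: float = 5e-8
) -> list[AssociationRecord]:
    """Keep records with ``pval < threshold`` (order preserved)."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("p-value threshold must lie in (0, 1)")
    return [r for r in records if r.pval < threshold]


def clump(
    records: Sequence[AssociationRecord],
    ld: LDMatrix,
    r2_threshold: float = 0.001,
) -> list[AssociationRecord]:
    """Greedy LD clumping: retain index SNPs, discard their LD partners.

    Repeatedly select the remaining SNP with the smallest p-value and remove
    every remaining SNP whose LD r² with it exceeds ``r2_threshold``. The
    output is sorted by p-value and always contains the globally most
    significant SNP.
    """
    missing = [r.snp_id for r in records if r.snp_id not in ld._index]
    if missing:
        raise DataError(f"SNPs absent from LD matrix: {missing}")
    # stable order: p-value, then id, so ties resolve deterministically
    pool = sorted(records, key=lambda r: (r.pval, r.snp_id))
    kept: list[AssociationRecord] = []
    while pool:
        index = pool.pop(0)
        kept.append(index)
        pool = [r for r in pool if ld.pairwise(index.snp_id, r.snp_id) <= r2_threshold]
    return kept


def f_statistic(beta: float, se: float) -> float:
    """Summary-data instrument-strength F: squared effect over squared SE."""
    if not (se > 0):
        raise ValueError("se must be positive")
    return (beta / se) ** 2


def population_allele_frequency(
    eaf: float, case_fraction: float, odds_ratio: float, prevalence: float
) -> float:
    """De-ascertain a case-control sample allele frequency.

    The sample frequency is ``v·p_case + (1-v)·p_control`` with case
    fraction ``v``; under a per-allele odds ratio the case frequency is
    ``OR·p_control / (1 + p_control·(OR-1))``. Solving for ``p_control`` and
    re-mixing with the population prevalence ``K`` gives the frequency in the
    general population.
    """
    if not (0 < eaf < 1):
        raise ValueError("eaf must lie in (0, 1)")
    if not (0 < case_fraction < 1):
        raise ValueError("case fraction must lie in (0, 1)")
    if not (0 < prevalence < 1):
        raise ValueError("prevalence must lie in (0, 1)")

    def sample_af(p_control: float) -> float:
        p_case = odds_ratio * p_control / (1 + p_control * (odds_ratio - 1))
        return case_fraction * p_case + (1 - case_fraction) * p_control

    lo, hi = 1e-12, 1 - 1e-12
    for _ in range(200):  # bisection: sample_af is monotone in p_control
        mid = 0.5 * (lo + hi)
        if sample_af(mid) < eaf:
            lo = mid
        else:
            hi = mid
    p_control = 0.5 * (lo + hi)
    p_case = odds_ratio * p_control / (1 + p_control * (odds_ratio - 1))
    return prevalence * p_case + (1 - prevalence) * p_control


def r2_binary(
    beta: float,
    eaf: float,
    prevalence: float,
    n_cases: int,
    n_controls: int,
    scale: str = "logit",
) -> float:
    """Liability-scale variance explained by one SNP for a binary trait.

    Parameters
    ----------
    beta : per-allele log odds ratio.
    eaf : effect-allele frequency in the case-control sample.
    prevalence : population prevalence ``K`` of the trait.
    n_cases, n_controls : study counts (set the ascertainment level).
    scale : ``'logit'`` (default) or ``'probit'``; see module docstring.
    """
    if not (0 < eaf < 1):
        raise ValueError("eaf must lie in (0, 1)")
    if not (0 < prevalence < 1):
        raise ValueError("prevalence must lie in (0, 1)")
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("case and control counts must be positive")
    if beta == 0.0:
        return 0.0

    v = n_cases / (n_cases + n_controls)
    if scale == "logit":
        popaf = population_allele_frequency(eaf, v, math.exp(beta), prevalence)
        vg = 2.0 * popaf * (1.0 - popaf) * beta * beta
        r2 = vg / (vg + math.pi**2 / 3.0)
    elif scale == "probit":
        # observed-scale R2 in the ascertained sample via the linear
        # probability approximation, then the threshold-model ascertainment
        # transformation to the liability scale
        k = prevalence
        r2_obs = beta * beta * 2.0 * eaf * (1.0 - eaf) * v * (1.0 - v)
        t = norm.isf(k)
        z = norm.pdf(t)
        m = z / k  # mean liability of cases
        c = k * (1 - k) / z**2 * k * (1 - k) / (v * (1 - v))
        u = m * (v - k) / (1 - k)
        theta = u * (u - t)
        r2 = c * r2_obs / (1 + c * theta * r2_obs)
    else:
        raise ValueError(f"unknown scale {scale!r}")
    return float(min(max(r2, 0.0), 1.0))


def steiger_filter(
    instruments: Sequence[HarmonizedInstrument],
    prevalence_exp: float,
    prevalence_out: float,
    scale: str = "logit",
    z_test: bool = False,
) -> tuple[list[HarmonizedInstrument], list[HarmonizedInstrument]]:
    """Directionality filter: drop SNPs explaining more outcome than exposure.

    For each kept instrument the liability-scale r² is computed for both
    traits (requiring per-SNP allele frequencies and case/control counts); a
    SNP is excluded iff ``r2_out > r2_exp`` (ties kept). SNPs lacking the
    data for the comparison are kept and flagged ``steiger_unfiltered``. The
    default test is the plain r² comparison; ``z_test=True`` additionally
    requires the difference of liability correlations to be significant at
    5% under an independent two-sample z-test before excluding.

    Returns ``(kept, excluded)``; excluded SNPs get status ``dropped_steiger``.
    Effect estimates are never modified, only membership.
    """
    kept: list[HarmonizedInstrument] = []
    excluded: list[HarmonizedInstrument] = []
    for inst in instruments:
        if inst.status != "kept":
            kept.append(inst)
            continue
        have = (
            inst.eaf_exp is not None and inst.eaf_out is not None
            and inst.n_cases_exp and inst.n_controls_exp
            and inst.n_cases_out and inst.n_controls_out
        )
        if not have:
            logger.warning("%s: missing EAF or counts; kept without Steiger filtering", inst.snp_id)
            inst.steiger_unfiltered = True
            kept.append(inst)
            continue
        inst.r2_exp = r2_binary(
            inst.beta_exp, inst.eaf_exp, prevalence_exp,
            inst.n_cases_exp, inst.n_controls_exp, scale=scale,
        )
        inst.r2_out = r2_binary(
            inst.beta_out, inst.eaf_out, prevalence_out,
            inst.n_cases_out, inst.n_controls_out, scale=scale,
        )
        exclude = inst.r2_out > inst.r2_exp
        if exclude and z_test:
            n_exp = inst.n_cases_exp + inst.n_controls_exp
            n_out = inst.n_cases_out + inst.n_controls_out
            z_exp = math.atanh(min(math.sqrt(inst.r2_exp), 1 - 1e-15))
            z_out = math.atanh(min(math.sqrt(inst.r2_out), 1 - 1e-15))
            z = (z_out - z_exp) / math.sqrt(1 / (n_exp - 3) + 1 / (n_out - 3))
            exclude = z > norm.isf(0.05)
        if exclude:
            inst.status = "dropped_steiger"
            excluded.append(inst)
        else:
            kept.append(inst)
    return kept, excluded


def build_instrument_set(
    instruments: Sequence[HarmonizedInstrument],
    prevalence_exp: float | None = None,
    prevalence_out: float | None = None,
    scale: str = "logit",
) -> InstrumentSet:
    """Collect kept instruments and their strength/variance summaries."""
    kept = [i for i in instruments if i.status == "kept"]
    for inst in kept:
        if inst.f_stat is None:
            inst.f_stat = f_statistic(inst.beta_exp, inst.se_exp)
        if (
            inst.r2_exp is None and prevalence_exp is not None
            and inst.eaf_exp is not None and inst.n_cases_exp and inst.n_controls_exp
        ):
            inst.r2_exp = r2_binary(
                inst.beta_exp, inst.eaf_exp, prevalence_exp,
                inst.n_cases_exp, inst.n_controls_exp, scale=scale,
            )
    r2s = [i.r2_exp for i in kept if i.r2_exp is not None]
    fs = [i.f_stat for i in kept if i.f_stat is not None]
    return InstrumentSet(
        instruments=kept,
        exposure_prevalence=prevalence_exp,
        outcome_prevalence=prevalence_out,
        total_r2_exp=float(np.sum(r2s)) if r2s else None,
        mean_f=float(np.mean(fs)) if fs else None,
    )
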