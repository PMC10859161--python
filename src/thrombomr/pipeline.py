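"""Orchestration of the full bidirectional MR analysis and its report.

A *direction* is a family of exposure→outcome analyses sharing one FDR
correction (e.g. one exposure against 18 outcomes, or 18 exposures against
one outcome in the reverse direction). For each pair the pipeline runs:

    select (p < threshold) → clump (if an LD matrix is supplied) →
    harmonize → Steiger filter → instrument accounting →
    primary estimate (IVW-MRE, or the Wald ratio for a single instrument) →
    sensitivity suite (Egger / weighted median / weighted mode / PRESSO for
    ≥3 SNPs; leave-one-out; per-SNP Wald + funnel) →
    Benjamini-Hochberg FDR across the direction's primary p-values.

Reports are deterministic: rows follow the configured outcome order, every
stochastic component draws its seed from the single recorded master seed,
and serializations use fixed formatting, so identical runs are
byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import estimators, presso as presso_mod
from .gwas_io import (
    AssociationRecord,
    ConfigurationError,
    HarmonizedInstrument,
    harmonize,
)
from .instruments import LDMatrix, build_instrument_set, clump, select_by_pvalue, steiger_filter

logger = logging.getLogger("thrombomr")

__all__ = [
    "AnalysisConfig",
    "AnalysisReport",
    "DEFAULT_PREVALENCE",
    "bh_fdr",
    "run_direction",
    "run_bidirectional",
    "named_variant_wald",
    "load_harmonized_table",
]

#: Bundled default population prevalences (overridable placeholders, not
#: study-specific values): the thrombosis exposure uses its assumed 0.2%;
#: cancers default to registry-style lifetime-risk magnitudes.
DEFAULT_PREVALENCE: dict[str, float] = {
    "vte": 0.002,
    "breast_cancer": 0.06, "prostate_cancer": 0.06, "endometrial_cancer": 0.02,
    "colorectal_cancer": 0.035, "melanoma": 0.02, "lung_cancer": 0.045,
    "ovarian_cancer": 0.012, "kidney_cancer": 0.015, "oesophageal_cancer": 0.008,
    "pancreatic_cancer": 0.01, "dlbcl": 0.006, "cll": 0.005,
    "follicular_lymphoma": 0.003, "oral_cancer": 0.007, "oropharyngeal_cancer": 0.005,
    "glioma": 0.004, "marginal_zone_lymphoma": 0.002, "bladder_cancer": 0.02,
}


@dataclass
class AnalysisConfig:
    """Run parameters for one bidirectional analysis.

    ``prevalence`` maps trait ids to population prevalences for the
    liability-scale r² computations; traits absent from the map fall back to
    :data:`DEFAULT_PREVALENCE` and, failing that, disable Steiger filtering
    for that pair with a warning.
    """

    p_threshold: float = 5e-8
    clump_r2: float = 0.001
    palindrome_policy: str = "infer_by_eaf"
    eaf_threshold: float = 0.42
    steiger: bool = True
    r2_scale: str = "logit"
    prevalence: dict[str, float] = field(default_factory=dict)
    replicated_only: list[str] | None = None
    named_variants: list[str] = field(default_factory=list)
    n_boot: int = 1000
    phi: float = 1.0
    n_sim: int = 1000
    presso_alpha: float = 0.05
    fdr_method: str = "fdr_bh"
    seed: int = 0

    def prevalence_for(self, trait_id: str) -> float | None:
        if trait_id in self.prevalence:
            return self.prevalence[trait_id]
        return DEFAULT_PREVALENCE.get(trait_id)


@dataclass
class AnalysisReport:
    """Per-direction results: one row per exposure-outcome pair."""

    direction: str
    rows: list[dict]
    seed: int

    def to_frame(self) -> pd.DataFrame:
        """Flatten the primary columns of each row into a DataFrame."""
        flat = []
        for r in self.rows:
            rec = {
                "exposure": r["exposure"], "outcome": r["outcome"], "status": r["status"],
                "n_available": r["n_available"], "n_excluded": r["n_excluded"],
                "n_used": r["n_used"], "total_r2_exp": r["total_r2_exp"],
                "mean_f": r["mean_f"],
            }
            primary = r.get("primary")
            if primary:
                rec.update({f"primary_{k}": v for k, v in primary.items()})
            het = r.get("heterogeneity")
            if het:
                rec.update({f"het_{k}": v for k, v in het.items()})
            rec["fdr_p"] = r.get("fdr_p")
            flat.append(rec)
        return pd.DataFrame(flat)

    def to_json(self) -> str:
        payload = {"direction": self.direction, "seed": self.seed, "rows": self.rows}
        return json.dumps(payload, sort_keys=True, indent=1)

    def write(self, tsv_path=None, json_path=None) -> None:
        if tsv_path is not None:
            self.to_frame().to_csv(tsv_path, sep="\t", index=False, float_format="%.10g")
        if json_path is not None:
            with open(json_path, "w") as fh:
                fh.write(self.to_json())


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _component_seed(master: int, pair_index: int, component: int) -> int:
    ss = np.random.SeedSequence([int(master), int(pair_index), int(component)])
    return int(ss.generate_state(1)[0] % (2**31))


def _analyse_pair(
    cfg: AnalysisConfig,
    pair_index: int,
    exposure_id: str,
    outcome_id: str,
    exposure_records: Sequence[AssociationRecord],
    outcome_records: Sequence[AssociationRecord],
    ld: LDMatrix | None,
) -> dict:
    row: dict = {"exposure": exposure_id, "outcome": outcome_id, "status": "ok",
                 "n_available": 0, "n_excluded": 0, "n_used": 0,
                 "total_r2_exp": None, "mean_f": None}

    selected = select_by_pvalue(exposure_records, cfg.p_threshold)
    if cfg.replicated_only is not None:
        allowed = set(cfg.replicated_only)
        selected = [r for r in selected if r.snp_id in allowed]
    if ld is not None and selected:
        selected = clump(selected, ld, cfg.clump_r2)

    harmonized = harmonize(selected, outcome_records,
                           palindrome_policy=cfg.palindrome_policy,
                           eaf_threshold=cfg.eaf_threshold)
    prev_exp = cfg.prevalence_for(exposure_id)
    prev_out = cfg.prevalence_for(outcome_id)
    if cfg.steiger:
        if prev_exp is None or prev_out is None:
            logger.warning("%s->%s: missing prevalence, Steiger filtering skipped",
                           exposure_id, outcome_id)
        else:
            steiger_filter(harmonized, prev_exp, prev_out, scale=cfg.r2_scale)

    used = [h for h in harmonized if h.status == "kept"]
    row["n_available"] = len(harmonized)
    row["n_used"] = len(used)
    row["n_excluded"] = len(harmonized) - len(used)

    iset = build_instrument_set(harmonized, prev_exp, prev_out, scale=cfg.r2_scale)
    row["total_r2_exp"] = iset.total_r2_exp
    row["mean_f"] = iset.mean_f

    n = len(used)
    if n == 0:
        row["status"] = "no-instruments"
        row["primary"] = None
        return row

    if n >= 2:
        primary, het = estimators.ivw_mre(used)
        row["heterogeneity"] = het.as_dict()
    else:
        h = used[0]
        primary = estimators.wald_ratio(h.beta_exp, h.se_exp, h.beta_out, h.se_out)
    row["primary"] = primary.as_dict()

    snp_estimates, funnel = estimators.single_snp(used)
    row["single_snp"] = [{"snp": s, **e.as_dict()} for s, e in snp_estimates]
    row["funnel"] = funnel.to_dict(orient="records")

    if n >= 3:
        slope, intercept = estimators.egger(used)
        wm = estimators.weighted_median(used, n_boot=cfg.n_boot,
                                        seed=_component_seed(cfg.seed, pair_index, 0))
        wmode = estimators.weighted_mode(used, phi=cfg.phi, n_boot=cfg.n_boot,
                                         seed=_component_seed(cfg.seed, pair_index, 1))
        row["sensitivity"] = {
            "egger_slope": slope.as_dict(),
            "egger_intercept": intercept.as_dict(),
            "weighted_median": wm.as_dict(),
            "weighted_mode": wmode.as_dict(),
        }
        row["leave_one_out"] = [
            {"dropped": s, **e.as_dict()} for s, e in estimators.leave_one_out(used)
        ]
        pres = presso_mod.run_presso(used, n_sim=cfg.n_sim,
                                     seed=_component_seed(cfg.seed, pair_index, 2),
                                     alpha=cfg.presso_alpha)
        row["presso"] = pres.as_dict()
    else:
        row["sensitivity"] = None
        row["leave_one_out"] = None
        row["presso"] = None
    return row


def run_direction(
    cfg: AnalysisConfig,
    pairs: Sequence[tuple[str, str]],
    records_by_trait: Mapping[str, Sequence[AssociationRecord]],
    ld_by_trait: Mapping[str, LDMatrix] | None = None,
    label: str = "",
) -> AnalysisReport:
    """Run one direction (an FDR family of exposure→outcome analyses).

    ``pairs`` lists ``(exposure_id, outcome_id)`` in report order; each
    exposure's instruments are selected from its own GWAS table. A pair with
    zero surviving instruments yields a ``no-instruments`` row rather than
    an error. One BH-FDR pass is applied across the primary p-values.
    """
    ld_by_trait = ld_by_trait or {}
    rows = []
    for i, (exp_id, out_id) in enumerate(pairs):
        if exp_id not in records_by_trait or out_id not in records_by_trait:
            raise ConfigurationError(f"records missing for pair {exp_id}->{out_id}")
        rows.append(_analyse_pair(
            cfg, i, exp_id, out_id,
            records_by_trait[exp_id], records_by_trait[out_id],
            ld_by_trait.get(exp_id),
        ))
    pvals = [(i, r["primary"]["pval"]) for i, r in enumerate(rows) if r.get("primary")]
    if pvals:
        adj = bh_fdr([p for _, p in pvals])
        for (i, _), q in zip(pvals, adj):
            rows[i]["fdr_p"] = float(q)
    for r in rows:
        r.setdefault("fdr_p", None)
    return AnalysisReport(direction=label or "direction", rows=rows, seed=cfg.seed)


def run_bidirectional(
    cfg: AnalysisConfig,
    records_by_trait: Mapping[str, Sequence[AssociationRecord]],
    exposure_id: str,
    outcome_ids: Sequence[str],
    ld_by_trait: Mapping[str, LDMatrix] | None = None,
) -> tuple[AnalysisReport, AnalysisReport]:
    """Forward (exposure→each outcome) and reverse (each outcome→exposure).

    Instruments are re-selected from the relevant exposure GWAS in each
    direction, with the same thresholds; each direction forms its own FDR
    family.
    """
    forward = run_direction(
        cfg, [(exposure_id, o) for o in outcome_ids], records_by_trait,
        ld_by_trait, label=f"{exposure_id}->outcomes",
    )
    reverse = run_direction(
        cfg, [(o, exposure_id) for o in outcome_ids], records_by_trait,
        ld_by_trait, label=f"outcomes->{exposure_id}",
    )
    return forward, reverse


def named_variant_wald(
    cfg: AnalysisConfig,
    snp_id: str,
    exposure_id: str,
    outcome_ids: Sequence[str],
    records_by_trait: Mapping[str, Sequence[AssociationRecord]],
) -> AnalysisReport:
    """Single-variant Wald-ratio analysis across every outcome.

    Used for strong biologically named instruments (e.g. Factor V Leiden
    rs6025 or Prothrombin G20210A rs1799963 when the exposure is venous
    thromboembolism). Outcomes lacking the SNP produce first-class ``NA``
    rows; the estimated rows form their own FDR family.
    """
    exposure_records = [r for r in records_by_trait[exposure_id] if r.snp_id == snp_id]
    if not exposure_records:
        raise ConfigurationError(f"{snp_id} absent from exposure table {exposure_id}")
    rows = []
    for out_id in outcome_ids:
        row = {"exposure": exposure_id, "outcome": out_id, "snp": snp_id,
               "status": "ok", "n_available": 0, "n_excluded": 0, "n_used": 0,
               "total_r2_exp": None, "mean_f": None, "primary": None}
        out_records = [r for r in records_by_trait[out_id] if r.snp_id == snp_id]
        if not out_records:
            row["status"] = "NA"
            rows.append(row)
            continue
        harmonized = harmonize(exposure_records, out_records,
                               palindrome_policy=cfg.palindrome_policy,
                               eaf_threshold=cfg.eaf_threshold)
        row["n_available"] = len(harmonized)
        used = [h for h in harmonized if h.status == "kept"]
        row["n_used"] = len(used)
        row["n_excluded"] = len(harmonized) - len(used)
        if not used:
            row["status"] = "NA"
            rows.append(row)
            continue
        h = used[0]
        row["primary"] = estimators.wald_ratio(h.beta_exp, h.se_exp, h.beta_out, h.se_out).as_dict()
        rows.append(row)
    pvals = [(i, r["primary"]["pval"]) for i, r in enumerate(rows) if r["primary"]]
    if pvals:
        adj = bh_fdr([p for _, p in pvals])
        for (i, _), q in zip(pvals, adj):
            rows[i]["fdr_p"] = float(q)
    for r in rows:
        r.setdefault("fdr_p", None)
    return AnalysisReport(direction=f"{snp_id}:{exposure_id}->outcomes", rows=rows, seed=cfg.seed)


_DEFAULT_HARMONIZED_MAP = {
    "snp": "snp_id", "effect_allele": "effect_allele", "other_allele": "other_allele",
    "beta_exp": "beta_exp", "se_exp": "se_exp", "beta_out": "beta_out", "se_out": "se_out",
    "eaf_exp": "eaf_exp", "eaf_out": "eaf_out",
}


def load_harmonized_table(path, column_map: Mapping[str, str] | None = None) -> list[HarmonizedInstrument]:
    """Load an already-harmonized instrument table (TSV).

    Accepts this package's own harmonized-table output as well as external
    pre-harmonized per-SNP tables (e.g. published supplementary data), via a
    column map with keys ``snp, effect_allele, other_allele, beta_exp,
    se_exp, beta_out, se_out`` and optional ``eaf_exp, eaf_out``. Rows with a
    non-``kept`` status column are skipped.
    """
    cmap = dict(_DEFAULT_HARMONIZED_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep="\t")
    missing = [v for k, v in cmap.items() if k in ("snp", "beta_exp", "se_exp", "beta_out", "se_out")
               and v not in df.columns]
    if missing:
        raise ConfigurationError(f"harmonized table missing columns: {missing}")
    out: list[HarmonizedInstrument] = []
    for _, r in df.iterrows():
        if "status" in df.columns and str(r["status"]) != "kept":
            continue
        out.append(HarmonizedInstrument(
            snp_id=str(r[cmap["snp"]]),
            effect_allele=str(r.get(cmap.get("effect_allele"), "A")),
            other_allele=str(r.get(cmap.get("other_allele"), "G")),
            beta_exp=float(r[cmap["beta_exp"]]),
            se_exp=float(r[cmap["se_exp"]]),
            beta_out=float(r[cmap["beta_out"]]),
            se_out=float(r[cmap["se_out"]]),
            eaf_exp=float(r[cmap["eaf_exp"]]) if cmap.get("eaf_exp") in df.columns else None,
            eaf_out=float(r[cmap["eaf_out"]]) if cmap.get("eaf_out") in df.columns else None,
        ))
    return out
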