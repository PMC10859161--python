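"""Reading, validation and harmonization of GWAS summary statistics.

Two-sample MR consumes per-SNP association summaries from two independent
genome-wide association studies: one for the exposure trait and one for the
outcome. Before any causal estimation the two tables must be *harmonized* so
that, for every shared SNP, the exposure and outcome effect sizes refer to the
same effect allele on the same strand. This module provides the record types,
a tab-delimited reader with a configurable column map, and the harmonizer.

Conventions
-----------
* Effects are log odds ratios per copy of the effect allele.
* Alleles are uppercased single bases; indels are dropped with a warning.
* Palindromic SNPs (A/T or C/G) cannot be strand-resolved from allele labels;
  they are either dropped outright or resolved from allele frequencies when
  the minor-allele frequency is far enough from 0.5.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("thrombomr")

__all__ = [
    "AssociationRecord",
    "HarmonizedInstrument",
    "ConfigurationError",
    "DataError",
    "EmptyInputError",
    "read_summary_table",
    "harmonize",
    "write_harmonized_table",
    "is_palindromic",
    "COMPLEMENT",
]


class ConfigurationError(ValueError):
    """A run configuration problem (e.g. an unresolvable column map)."""


class DataError(ValueError):
    """Malformed input data (e.g. duplicate SNP identifiers)."""


class EmptyInputError(DataError):
    """An input table contained no data rows."""


COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column names the reader must resolve
REQUIRED_COLUMNS = ("snp", "effect_allele", "other_allele", "beta", "se", "pval")
#: canonical column names that may be absent
OPTIONAL_COLUMNS = ("eaf", "n_cases", "n_controls")


@dataclass(frozen=True)
class AssociationRecord:
    """One SNP's summary association with one binary trait."""

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float | None = None
    n_cases: int | None = None
    n_controls: int | None = None
    trait_id: str = ""

    def validate(self) -> None:
        """Raise :class:`DataError` if any field invariant is violated."""
        if not self.snp_id:
            raise DataError("empty SNP identifier")
        ea, oa = self.effect_allele.upper(), self.other_allele.upper()
        if not ea or not oa or ea == oa:
            raise DataError(f"{self.snp_id}: alleles must be non-empty and distinct")
        if not (self.se > 0) or not math.isfinite(self.se):
            raise DataError(f"{self.snp_id}: se must be positive and finite")
        if not math.isfinite(self.beta):
            raise DataError(f"{self.snp_id}: beta must be finite")
        if not (0.0 <= self.pval <= 1.0):
            raise DataError(f"{self.snp_id}: p-value outside [0, 1]")
        if self.eaf is not None and not (0.0 < self.eaf < 1.0):
            raise DataError(f"{self.snp_id}: eaf outside (0, 1)")


@dataclass
class HarmonizedInstrument:
    """One SNP with exposure and outcome effects aligned to a shared allele.

    ``status`` records the harmonization / filtering fate of the SNP:
    ``kept``, ``dropped_ambiguous`` (unresolvable palindrome),
    ``dropped_incompatible`` (allele mismatch or indel) or ``dropped_steiger``
    (removed by directionality filtering downstream).
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta_exp: float
    se_exp: float
    beta_out: float = float("nan")
    se_out: float = float("nan")
    eaf_exp: float | None = None
    eaf_out: float | None = None
    palindromic: bool = False
    strand_flipped: bool = False
    status: str = "kept"
    f_stat: float | None = None
    r2_exp: float | None = None
    r2_out: float | None = None
    n_cases_exp: int | None = None
    n_controls_exp: int | None = None
    n_cases_out: int | None = None
    n_controls_out: int | None = None
    steiger_unfiltered: bool = field(default=False, repr=False)


def _resolve_columns(columns: Sequence[str], column_map: Mapping[str, object]):
    resolved: dict[str, str] = {}
    for key in REQUIRED_COLUMNS:
        name = column_map.get(key)
        if name is None or name not in columns:
            raise ConfigurationError(
                f"column map does not resolve required column '{key}' "
                f"(mapped to {name!r}; available: {list(columns)})"
            )
        resolved[key] = str(name)
    for key in OPTIONAL_COLUMNS:
        name = column_map.get(key)
        if name is not None and name in columns:
            resolved[key] = str(name)
    return resolved


def read_summary_table(
    path,
    column_map: Mapping[str, object],
    trait_id: str = "",
) -> list[AssociationRecord]:
    """Read a tab-delimited GWAS summary-statistics table.

    ``column_map`` maps the canonical keys ``snp, effect_allele, other_allele,
    beta, se, pval`` (required) and ``eaf, n_cases, n_controls`` (optional) to
    column names in the file. The extra boolean key ``or_to_log`` declares
    that the effect column holds odds ratios, to be converted with the
    natural log. Rows violating record invariants are logged and skipped.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[0] == 0:
        raise EmptyInputError(f"{path}: no data rows")
    cols = _resolve_columns(df.columns, column_map)
    or_to_log = bool(column_map.get("or_to_log", False))

    records: list[AssociationRecord] = []
    positions = {key: df.columns.get_loc(name) for key, name in cols.items()}
    for i, row in enumerate(df.itertuples(index=False)):
        raw = {key: row[pos] for key, pos in positions.items()}
        try:
            beta = float(raw["beta"])
            if or_to_log:
                if beta <= 0:
                    raise DataError(f"{raw['snp']}: odds ratio must be > 0 to take log")
                beta = math.log(beta)
            rec = AssociationRecord(
                snp_id=str(raw["snp"]).strip(),
                effect_allele=str(raw["effect_allele"]).strip().upper(),
                other_allele=str(raw["other_allele"]).strip().upper(),
                beta=beta,
                se=float(raw["se"]),
                pval=float(raw["pval"]),
                eaf=float(raw["eaf"]) if "eaf" in raw and not _isna(raw["eaf"]) else None,
                n_cases=int(float(raw["n_cases"])) if "n_cases" in raw and not _isna(raw["n_cases"]) else None,
                n_controls=int(float(raw["n_controls"])) if "n_controls" in raw and not _isna(raw["n_controls"]) else None,
                trait_id=trait_id,
            )
            rec.validate()
        except (DataError, ValueError) as exc:
            logger.warning("%s row %d skipped: %s", path, i + 1, exc)
            continue
        records.append(rec)
    return records


def _isna(value) -> bool:
    if value is None:
        return True
    try:
        return value != value or str(value).strip() in ("", "NA", "nan", "NaN")
    except Exception:  # pragma: no cover - defensive
        return False


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is {A,T} or {C,G} (strand-ambiguous)."""
    pair = {effect_allele.upper(), other_allele.upper()}
    return pair == {"A", "T"} or pair == {"C", "G"}


def _check_duplicates(records: Iterable[AssociationRecord], label: str) -> dict[str, AssociationRecord]:
    by_id: dict[str, AssociationRecord] = {}
    dupes = []
    for rec in records:
        if rec.snp_id in by_id:
            dupes.append(rec.snp_id)
        by_id[rec.snp_id] = rec
    if dupes:
        raise DataError(f"duplicate SNP ids in {label} records: {sorted(set(dupes))}")
    return by_id


def _minor_af(eaf: float) -> float:
    return min(eaf, 1.0 - eaf)


def harmonize(
    exposure: Sequence[AssociationRecord],
    outcome: Sequence[AssociationRecord],
    palindrome_policy: str = "infer_by_eaf",
    eaf_threshold: float = 0.42,
) -> list[HarmonizedInstrument]:
    """Align exposure and outcome effects to a shared effect allele per SNP.

    Only SNPs present in both trait tables are emitted (one row per shared
    SNP, including dropped rows with an explanatory ``status``). Allele-label
    swaps flip the outcome effect sign and complement its frequency; alleles
    that match only after base complementing are treated as a strand flip.
    Palindromic SNPs are dropped under ``palindrome_policy='drop_all'``; under
    ``'infer_by_eaf'`` they are orientated from allele frequencies, and
    dropped as ambiguous when either trait's minor-allele frequency lies in
    ``[eaf_threshold, 0.5]`` or a frequency is missing.

    Harmonization only ever changes effect signs and allele labels, never
    effect magnitudes, and is idempotent.
    """
    if palindrome_policy not in ("drop_all", "infer_by_eaf"):
        raise ConfigurationError(f"unknown palindrome policy {palindrome_policy!r}")
    if not (0.0 < eaf_threshold < 0.5):
        raise ConfigurationError("eaf_threshold must lie in (0, 0.5)")

    exp_by_id = _check_duplicates(exposure, "exposure")
    out_by_id = _check_duplicates(outcome, "outcome")

    result: list[HarmonizedInstrument] = []
    for snp_id, ex in exp_by_id.items():
        if snp_id not in out_by_id:
            continue
        ou = out_by_id[snp_id]
        inst = _harmonize_one(ex, ou, palindrome_policy, eaf_threshold)
        result.append(inst)
    return result


def _harmonize_one(
    ex: AssociationRecord,
    ou: AssociationRecord,
    policy: str,
    eaf_threshold: float,
) -> HarmonizedInstrument:
    ea_x, oa_x = ex.effect_allele.upper(), ex.other_allele.upper()
    ea_y, oa_y = ou.effect_allele.upper(), ou.other_allele.upper()

    inst = HarmonizedInstrument(
        snp_id=ex.snp_id,
        effect_allele=ea_x,
        other_allele=oa_x,
        beta_exp=ex.beta,
        se_exp=ex.se,
        eaf_exp=ex.eaf,
        n_cases_exp=ex.n_cases,
        n_controls_exp=ex.n_controls,
        n_cases_out=ou.n_cases,
        n_controls_out=ou.n_controls,
    )

    bases = set("ACGT")
    if not ({ea_x, oa_x} <= bases and {ea_y, oa_y} <= bases):
        logger.warning("%s: indel or non-ACGT alleles dropped", ex.snp_id)
        inst.status = "dropped_incompatible"
        return inst

    inst.palindromic = is_palindromic(ea_x, oa_x)
    beta_out, se_out, eaf_out = ou.beta, ou.se, ou.eaf

    if inst.palindromic:
        if {ea_y, oa_y} != {ea_x, oa_x}:
            inst.status = "dropped_incompatible"
            return inst
        if policy == "drop_all":
            inst.status = "dropped_ambiguous"
            return inst
        # infer_by_eaf: allele labels cannot distinguish strands for a
        # palindrome, so orient by label first, then check frequency concordance
        if ex.eaf is None or ou.eaf is None:
            inst.status = "dropped_ambiguous"
            return inst
        if _minor_af(ex.eaf) >= eaf_threshold or _minor_af(ou.eaf) >= eaf_threshold:
            inst.status = "dropped_ambiguous"
            return inst
        if ea_y != ea_x:  # label swap
            beta_out, eaf_out = -beta_out, 1.0 - ou.eaf
        if (ex.eaf - 0.5) * (eaf_out - 0.5) < 0:
            # frequencies disagree: the outcome study reported the other strand
            beta_out, eaf_out = -beta_out, 1.0 - eaf_out
            inst.strand_flipped = True
    else:
        comp_ea_y, comp_oa_y = COMPLEMENT[ea_y], COMPLEMENT[oa_y]
        if (ea_y, oa_y) == (ea_x, oa_x):
            pass
        elif (ea_y, oa_y) == (oa_x, ea_x):
            beta_out = -beta_out
            eaf_out = None if eaf_out is None else 1.0 - eaf_out
        elif (comp_ea_y, comp_oa_y) == (ea_x, oa_x):
            inst.strand_flipped = True
        elif (comp_ea_y, comp_oa_y) == (oa_x, ea_x):
            inst.strand_flipped = True
            beta_out = -beta_out
            eaf_out = None if eaf_out is None else 1.0 - eaf_out
        else:
            inst.status = "dropped_incompatible"
            return inst

    inst.beta_out = beta_out
    inst.se_out = se_out
    inst.eaf_out = eaf_out
    inst.f_stat = (ex.beta / ex.se) ** 2
    return inst


def instrument_to_records(
    inst: HarmonizedInstrument, exposure_trait: str = "exposure", outcome_trait: str = "outcome"
) -> tuple[AssociationRecord, AssociationRecord]:
    """Project a kept instrument back into a pair of association records.

    Useful for idempotence checks and for re-running analyses on
    already-harmonized tables; p-values are recomputed from the Wald z.
    """
    from scipy.stats import norm

    if inst.status != "kept":
        raise DataError(f"{inst.snp_id}: cannot project a dropped instrument")
    p_exp = float(2 * norm.sf(abs(inst.beta_exp / inst.se_exp)))
    p_out = float(2 * norm.sf(abs(inst.beta_out / inst.se_out)))
    ex = AssociationRecord(
        inst.snp_id, inst.effect_allele, inst.other_allele, inst.beta_exp,
        inst.se_exp, p_exp, inst.eaf_exp, inst.n_cases_exp, inst.n_controls_exp,
        exposure_trait,
    )
    ou = AssociationRecord(
        inst.snp_id, inst.effect_allele, inst.other_allele, inst.beta_out,
        inst.se_out, p_out, inst.eaf_out, inst.n_cases_out, inst.n_controls_out,
        outcome_trait,
    )
    return ex, ou


_HARMONIZED_COLUMNS = [
    "snp_id", "effect_allele", "other_allele", "beta_exp", "se_exp",
    "beta_out", "se_out", "eaf_exp", "eaf_out", "palindromic",
    "strand_flipped", "status", "f_stat", "r2_exp", "r2_out",
]


def harmonized_frame(instruments: Sequence[HarmonizedInstrument]) -> pd.DataFrame:
    """Tabulate instruments (kept and dropped) as a DataFrame."""
    rows = [{c: getattr(inst, c) for c in _HARMONIZED_COLUMNS} for inst in instruments]
    return pd.DataFrame(rows, columns=_HARMONIZED_COLUMNS)


def write_harmonized_table(instruments: Sequence[HarmonizedInstrument], path) -> None:
    """Write the harmonized table (one row per SNP, dropped rows included)."""
    harmonized_frame(instruments).to_csv(path, sep="\t", index=False, float_format="%.10g")
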