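"""Summary-table reading and allele harmonization."""

import itertools
import logging
import math

import numpy as np
import pandas as pd
import pytest

from thrombomr import (
    ConfigurationError,
    DataError,
    EmptyInputError,
    harmonize,
    read_summary_table,
    simulate_pair,
    SimulationConfig,
)
from thrombomr.gwas_io import COMPLEMENT, instrument_to_records, is_palindromic

from conftest import kept_instruments, record

COLMAP = {
    "snp": "snp", "effect_allele": "ea", "other_allele": "oa",
    "beta": "beta", "se": "se", "pval": "p", "eaf": "eaf",
    "n_cases": "ncase", "n_controls": "ncontrol",
}


def _write(tmp_path, rows, name="table.tsv"):
    path = tmp_path / name
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


class TestReader:
    def test_parses_well_formed_rows(self, tmp_path):
        rows = [
            {"snp": "rs1", "ea": "a", "oa": "g", "beta": 0.1, "se": 0.01, "p": 1e-9,
             "eaf": 0.3, "ncase": 100, "ncontrol": 200},
            {"snp": "rs2", "ea": "T", "oa": "C", "beta": -0.2, "se": 0.02, "p": 1e-8,
             "eaf": 0.6, "ncase": 100, "ncontrol": 200},
            {"snp": "rs3", "ea": "G", "oa": "A", "beta": 0.05, "se": 0.03, "p": 0.5,
             "eaf": 0.1, "ncase": 100, "ncontrol": 200},
        ]
        recs = read_summary_table(_write(tmp_path, rows), COLMAP, trait_id="x")
        assert len(recs) == 3
        assert recs[0].effect_allele == "A"  # uppercased
        assert recs[1].beta == pytest.approx(-0.2)
        assert recs[2].n_controls == 200
        assert all(r.trait_id == "x" for r in recs)

    def test_invalid_rows_skipped_with_warning(self, tmp_path, caplog):
        rows = [
            {"snp": "rs1", "ea": "A", "oa": "G", "beta": 0.1, "se": 0.0, "p": 0.1},
            {"snp": "rs2", "ea": "A", "oa": "G", "beta": 0.1, "se": 0.01, "p": 0.1},
        ]
        cmap = {k: v for k, v in COLMAP.items() if k not in ("eaf", "n_cases", "n_controls")}
        with caplog.at_level(logging.WARNING, logger="thrombomr"):
            recs = read_summary_table(_write(tmp_path, rows), cmap)
        assert [r.snp_id for r in recs] == ["rs2"]
        assert sum("rs1" in m or "row 1" in m for m in caplog.messages) == 1

    def test_odds_ratio_column_converted_with_log(self, tmp_path):
        ors = [1.5, 0.8, 1.0]
        rows = [{"snp": f"rs{i}", "ea": "A", "oa": "G", "beta": o, "se": 0.01, "p": 0.1}
                for i, o in enumerate(ors)]
        cmap = {**{k: v for k, v in COLMAP.items() if k not in ("eaf", "n_cases", "n_controls")},
                "or_to_log": True}
        recs = read_summary_table(_write(tmp_path, rows), cmap)
        assert [r.beta for r in recs] == pytest.approx([math.log(o) for o in ors])

    def test_missing_required_column_named_in_error(self, tmp_path):
        path = _write(tmp_path, [{"snp": "rs1", "ea": "A", "oa": "G", "beta": 0.1, "se": 0.01}])
        with pytest.raises(ConfigurationError, match="pval"):
            read_summary_table(path, {k: v for k, v in COLMAP.items() if k != "pval"} | {"pval": "p"})

    def test_empty_table_raises(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("snp\tea\toa\tbeta\tse\tp\n")
        with pytest.raises(EmptyInputError):
            read_summary_table(path, COLMAP)


class TestHarmonize:
    @pytest.mark.parametrize(
        "out_alleles,expected_beta,expected_eaf,strand",
        [
            (("A", "G"), 0.05, 0.3, False),   # identical orientation
            (("G", "A"), -0.05, 0.7, False),  # allele swap flips sign
            (("T", "C"), 0.05, 0.3, True),    # strand complement
            (("C", "T"), -0.05, 0.7, True),   # complement + swap
        ],
    )
    def test_nonpalindromic_alignment(self, out_alleles, expected_beta, expected_eaf, strand):
        exp = [record("rs1", "A", "G", 0.1, eaf=0.2)]
        out = [record("rs1", *out_alleles, 0.05, eaf=0.3)]
        (h,) = harmonize(exp, out)
        assert h.status == "kept"
        assert h.beta_out == pytest.approx(expected_beta)
        assert h.eaf_out == pytest.approx(expected_eaf)
        assert h.strand_flipped is strand
        assert (h.effect_allele, h.other_allele) == ("A", "G")

    def test_incompatible_alleles_dropped(self):
        (h,) = harmonize([record("rs1", "A", "G", 0.1)], [record("rs1", "A", "C", 0.05)])
        assert h.status == "dropped_incompatible"

    def test_indel_dropped_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING, logger="thrombomr"):
            (h,) = harmonize([record("rs1", "AT", "G", 0.1)], [record("rs1", "AT", "G", 0.05)])
        assert h.status == "dropped_incompatible"
        assert any("indel" in m for m in caplog.messages)

    def test_palindrome_inside_ambiguity_window_dropped(self):
        exp = [record("rs1", "A", "T", 0.1, eaf=0.50)]
        out = [record("rs1", "A", "T", 0.05, eaf=0.50)]
        (h,) = harmonize(exp, out, palindrome_policy="infer_by_eaf", eaf_threshold=0.42)
        assert h.status == "dropped_ambiguous"
        assert h.palindromic

    def test_palindrome_drop_all_policy(self):
        exp = [record("rs1", "C", "G", 0.1, eaf=0.1)]
        out = [record("rs1", "C", "G", 0.05, eaf=0.1)]
        (h,) = harmonize(exp, out, palindrome_policy="drop_all")
        assert h.status == "dropped_ambiguous"

    def test_palindrome_missing_eaf_dropped(self):
        exp = [record("rs1", "A", "T", 0.1, eaf=0.1)]
        out = [record("rs1", "A", "T", 0.05, eaf=None)]
        (h,) = harmonize(exp, out)
        assert h.status == "dropped_ambiguous"

    @pytest.mark.parametrize(
        "out_alleles,out_eaf,expected_beta,expected_eaf,strand",
        [
            (("A", "T"), 0.2, 0.05, 0.2, False),   # concordant frequencies
            (("A", "T"), 0.8, -0.05, 0.2, True),   # discordant: inferred strand flip
            (("T", "A"), 0.8, -0.05, 0.2, False),  # swap with concordant result
            (("T", "A"), 0.2, 0.05, 0.2, True),    # swap then frequency flip
        ],
    )
    def test_palindrome_frequency_inference(self, out_alleles, out_eaf,
                                            expected_beta, expected_eaf, strand):
        exp = [record("rs1", "A", "T", 0.1, eaf=0.2)]
        out = [record("rs1", *out_alleles, 0.05, eaf=out_eaf)]
        (h,) = harmonize(exp, out, eaf_threshold=0.42)
        assert h.status == "kept"
        assert h.beta_out == pytest.approx(expected_beta)
        assert h.eaf_out == pytest.approx(expected_eaf)
        assert h.strand_flipped is strand

    def test_duplicate_snp_ids_raise(self):
        exp = [record("rs1", "A", "G", 0.1), record("rs1", "A", "G", 0.2)]
        with pytest.raises(DataError, match="rs1"):
            harmonize(exp, [record("rs1", "A", "G", 0.05)])

    def test_only_shared_snps_emitted(self):
        exp = [record("rs1", "A", "G", 0.1), record("rs2", "A", "G", 0.1)]
        out = [record("rs2", "A", "G", 0.05), record("rs3", "A", "G", 0.05)]
        result = harmonize(exp, out)
        assert [h.snp_id for h in result] == ["rs2"]

    def test_all_orientations_match_complement_oracle(self):
        """Exhaustive check of every non-palindromic ordered pair x transform."""
        bases = "ACGT"
        pairs = [(a, b) for a, b in itertools.product(bases, bases)
                 if a != b and not is_palindromic(a, b)]
        transforms = {
            "identity": (lambda ea, oa: (ea, oa), +1),
            "swap": (lambda ea, oa: (oa, ea), -1),
            "complement": (lambda ea, oa: (COMPLEMENT[ea], COMPLEMENT[oa]), +1),
            "comp_swap": (lambda ea, oa: (COMPLEMENT[oa], COMPLEMENT[ea]), -1),
        }
        for ea, oa in pairs:
            for name, (fn, sign) in transforms.items():
                out_ea, out_oa = fn(ea, oa)
                (h,) = harmonize(
                    [record("rs1", ea, oa, 0.1, eaf=0.2)],
                    [record("rs1", out_ea, out_oa, 0.05, eaf=0.3)],
                )
                assert h.status == "kept", (ea, oa, name)
                assert h.beta_out == pytest.approx(sign * 0.05), (ea, oa, name)


class TestHarmonizeProperties:
    def _pair(self, seed=3):
        cfg = SimulationConfig(n_snp=30, theta=0.2, seed=seed)
        exposure, outcome, _ = simulate_pair(cfg)
        return exposure, outcome

    def test_idempotent(self):
        exposure, outcome, = self._pair()
        kept = kept_instruments(exposure, outcome)
        re_exp, re_out = zip(*(instrument_to_records(h) for h in kept))
        again = harmonize(list(re_exp), list(re_out))
        assert all(h.status == "kept" and not h.strand_flipped for h in again)
        for h0, h1 in zip(kept, again):
            assert h1.beta_out == pytest.approx(h0.beta_out)
            assert h1.beta_exp == pytest.approx(h0.beta_exp)
            assert h1.eaf_out == pytest.approx(h0.eaf_out)

    def test_role_swap_exchanges_fields(self):
        exposure, outcome = self._pair(seed=5)
        fwd = {h.snp_id: h for h in harmonize(exposure, outcome) if h.status == "kept"}
        rev = {h.snp_id: h for h in harmonize(outcome, exposure) if h.status == "kept"}
        assert set(fwd) == set(rev)
        for snp, f in fwd.items():
            r = rev[snp]
            assert abs(r.beta_exp) == pytest.approx(abs(f.beta_out))
            assert abs(r.beta_out) == pytest.approx(abs(f.beta_exp))
            # joint orientation is consistent: the effect product is invariant
            assert r.beta_exp * r.beta_out == pytest.approx(f.beta_exp * f.beta_out)

    def test_abs_outcome_beta_multiset_preserved(self):
        exposure, outcome = self._pair(seed=11)
        kept = kept_instruments(exposure, outcome)
        raw = {r.snp_id: abs(r.beta) for r in outcome}
        harmonized = sorted(abs(h.beta_out) for h in kept)
        expected = sorted(raw[h.snp_id] for h in kept)
        assert np.allclose(harmonized, expected)
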