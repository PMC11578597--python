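"""Summary-statistic reading, validation and harmonization."""

import dataclasses

import pytest

from mrcorge import (DataError, FormatError, harmonize, read_instruments,
                     read_summary_table, split_instruments, write_instruments)
from mrcorge.summary_io import VariantAssociation

from conftest import make_association


def _write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestReadSummaryTable:
    def test_column_map_remaps_foreign_headers(self, tmp_path):
        path = _write(tmp_path, "sumstats.tsv",
                      "rsid\tea\toa\tbeta\tse\n"
                      "rs1\tA\tG\t0.1\t0.01\n")
        records, rejections = read_summary_table(
            path, column_map={"rsid": "variant_id", "ea": "effect_allele",
                              "oa": "other_allele"})
        assert rejections == []
        assert len(records) == 1
        assert records[0].variant_id == "rs1"
        assert records[0].effect_allele == "A"
        assert records[0].eaf is None  # optional column absent

    def test_invalid_rows_collected_not_dropped_silently(self, tmp_path):
        path = _write(tmp_path, "s.tsv",
                      "variant_id\teffect_allele\tother_allele\tbeta\tse\teaf\n"
                      "rs1\tA\tG\t0.1\t0.0\t0.3\n"       # nonpositive se
                      "rs2\tA\tA\t0.1\t0.01\t0.3\n"      # identical alleles
                      "rs3\tA\tG\t0.1\t0.01\t1.5\n"      # eaf out of range
                      "rs4\tA\tG\t0.1\t0.01\t0.3\n")
        records, rejections = read_summary_table(path)
        assert [r.variant_id for r in records] == ["rs4"]
        reasons = {r.variant_id: r.reason for r in rejections}
        assert reasons["rs1"] == "nonpositive se"
        assert reasons["rs2"] == "identical alleles"
        assert "eaf" in reasons["rs3"]

    def test_duplicate_variant_id_is_an_error(self, tmp_path):
        path = _write(tmp_path, "s.tsv",
                      "variant_id\teffect_allele\tother_allele\tbeta\tse\n"
                      "rs1\tA\tG\t0.1\t0.01\n"
                      "rs1\tA\tG\t0.2\t0.01\n")
        with pytest.raises(DataError, match="rs1"):
            read_summary_table(path)

    def test_missing_required_column_names_it(self, tmp_path):
        path = _write(tmp_path, "s.tsv",
                      "variant_id\teffect_allele\tbeta\tse\nrs1\tA\t0.1\t0.01\n")
        with pytest.raises(FormatError, match="other_allele"):
            read_summary_table(path)

    def test_comma_delimited_accepted(self, tmp_path):
        path = _write(tmp_path, "s.csv",
                      "variant_id,effect_allele,other_allele,beta,se\n"
                      "rs1,A,G,0.1,0.01\n")
        records, _ = read_summary_table(path)
        assert records[0].beta == 0.1


class TestHarmonize:
    def test_allele_swap_flips_outcome_sign_and_frequency(self):
        exposure = [make_association(effect_allele="A", other_allele="G",
                                     beta=0.10)]
        outcome = [make_association(effect_allele="G", other_allele="A",
                                    beta=0.05, eaf=0.7)]
        records, rejections = harmonize(exposure, outcome)
        assert rejections == []
        (rec,) = records
        assert rec.effect_allele == "A"
        assert rec.beta_outcome == -0.05
        assert rec.eaf_outcome == pytest.approx(0.3)

    def test_strand_complement_alignment(self):
        exposure = [make_association(effect_allele="A", other_allele="G")]
        # outcome reported on the opposite strand, swapped labels
        outcome = [make_association(effect_allele="C", other_allele="T",
                                    beta=0.02)]
        records, _ = harmonize(exposure, outcome)
        (rec,) = records
        assert rec.beta_outcome == -0.02

    @pytest.mark.parametrize("eaf,kept", [(0.45, False), (0.30, True)])
    def test_palindrome_maf_rule(self, eaf, kept):
        exposure = [make_association(effect_allele="A", other_allele="T",
                                     eaf=eaf)]
        outcome = [make_association(effect_allele="A", other_allele="T",
                                    beta=0.05, eaf=eaf)]
        records, rejections = harmonize(exposure, outcome,
                                        palindrome_maf_threshold=0.42)
        assert (len(records) == 1) == kept
        if not kept:
            assert rejections[0].reason == "palindromic, ambiguous frequency"

    def test_palindrome_discordant_frequency_assumes_strand_flip(self):
        # exposure minor allele A (eaf 0.1); outcome labels A/T but eaf 0.9
        # for A: concordance forces a flip.
        exposure = [make_association(effect_allele="A", other_allele="T",
                                     eaf=0.1)]
        outcome = [make_association(effect_allele="A", other_allele="T",
                                    beta=0.05, eaf=0.9)]
        (rec,), _ = harmonize(exposure, outcome)
        assert rec.beta_outcome == -0.05
        assert rec.eaf_outcome == pytest.approx(0.1)

    def test_missing_in_outcome_reported(self):
        exposure = [make_association("rs1"), make_association("rs3")]
        outcome = [make_association("rs1", beta=0.05)]
        records, rejections = harmonize(exposure, outcome)
        assert [r.variant_id for r in records] == ["rs1"]
        missing = [r for r in rejections if r.reason == "missing in outcome"]
        assert [r.variant_id for r in missing] == ["rs3"]

    def test_incompatible_alleles_rejected(self):
        exposure = [make_association(effect_allele="A", other_allele="G")]
        outcome = [make_association(effect_allele="A", other_allele="C")]
        records, rejections = harmonize(exposure, outcome)
        assert records == []
        assert rejections[0].reason == "incompatible alleles"

    def test_zero_exposure_beta_rejected(self):
        exposure = [make_association(beta=0.0)]
        outcome = [make_association(beta=0.05)]
        records, rejections = harmonize(exposure, outcome)
        assert records == []
        assert rejections[0].reason == "zero exposure effect"

    def test_indels_rejected(self):
        exposure = [make_association(effect_allele="AT", other_allele="A")]
        outcome = [make_association(effect_allele="AT", other_allele="A")]
        records, rejections = harmonize(exposure, outcome)
        assert records == []
        assert rejections[0].reason == "indel or non-ACGT alleles"

    def test_empty_intersection_is_error(self):
        with pytest.raises(DataError, match="no shared instruments"):
            harmonize([make_association("rs1")], [make_association("rs2")])

    def test_record_conservation(self, rng):
        exposure, outcome = _random_pair(rng, 40)
        records, rejections = harmonize(exposure, outcome)
        shared = {v.variant_id for v in exposure} & {
            v.variant_id for v in outcome}
        harmonize_rejects = [r for r in rejections if r.stage == "harmonize"]
        assert len(records) + len(harmonize_rejects) == len(shared)

    def test_idempotence(self, rng):
        exposure, outcome = _random_pair(rng, 40)
        records, _ = harmonize(exposure, outcome)
        re_exp, re_out = split_instruments(records)
        records2, rejections2 = harmonize(re_exp, re_out)
        assert records2 == records
        assert rejections2 == []

    def test_strand_flip_invariance(self, rng):
        exposure, outcome = _random_pair(rng, 40, palindromes=False)
        baseline, _ = harmonize(exposure, outcome)
        flipped = [v.complemented() for v in outcome]
        records, _ = harmonize(exposure, flipped)
        assert records == baseline

    def test_sign_consistency_under_exposure_reorientation(self, rng):
        exposure, outcome = _random_pair(rng, 40)
        baseline, _ = harmonize(exposure, outcome)
        reoriented = [v.flipped() for v in exposure]
        records, _ = harmonize(reoriented, outcome)
        base_ratios = {r.variant_id: r.beta_outcome / r.beta_exposure
                       for r in baseline}
        for rec in records:
            assert rec.beta_outcome / rec.beta_exposure == pytest.approx(
                base_ratios[rec.variant_id])


class TestInstrumentRoundTrip:
    def test_write_read_round_trip(self, tmp_path, rng):
        exposure, outcome = _random_pair(rng, 10)
        records, _ = harmonize(exposure, outcome)
        path = tmp_path / "instruments.tsv"
        write_instruments(records, path)
        assert read_instruments(path) == records

    def test_missing_optional_field_uses_na(self, tmp_path):
        records, _ = harmonize(
            [dataclasses.replace(make_association(), eaf=None)],
            [make_association(beta=0.05)])
        path = tmp_path / "instruments.tsv"
        write_instruments(records, path)
        assert "NA" in path.read_text()
        assert read_instruments(path)[0].eaf_exposure is None

    def test_empty_records_yield_header_only_file(self, tmp_path):
        path = tmp_path / "instruments.tsv"
        write_instruments([], path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1
        assert lines[0].startswith("variant_id\t")


def _random_pair(rng, n, palindromes=True):
    """Random exposure/outcome association pairs exercising swaps,
    strand flips and (optionally) palindromes."""
    pairs = [("A", "G"), ("T", "C"), ("G", "C"), ("A", "T")]
    exposure, outcome = [], []
    for j in range(n):
        ea, oa = pairs[j % (4 if palindromes else 2)]
        eaf = float(rng.uniform(0.05, 0.40))  # unambiguous palindromes
        exp = VariantAssociation(
            f"rs{j:04d}", ea, oa,
            beta=float(rng.normal(0, 0.1)) or 0.01,
            se=float(rng.uniform(0.005, 0.05)),
            eaf=eaf, pval=float(rng.uniform(0, 1)), n=100_000.0)
        out = VariantAssociation(
            f"rs{j:04d}", ea, oa,
            beta=float(rng.normal(0, 0.05)),
            se=float(rng.uniform(0.005, 0.05)),
            eaf=eaf, pval=float(rng.uniform(0, 1)), n=80_000.0)
        mode = int(rng.integers(0, 3))
        if mode == 1:
            out = out.flipped()
        elif mode == 2 and not out.is_palindromic:
            out = out.complemented()
        exposure.append(exp)
        outcome.append(out)
    return exposure, outcome
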