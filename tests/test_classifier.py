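"""Substitution classification: oracle equivalence, orientation, invariants."""

import itertools

import pandas as pd
import pytest

from cpgvar.classifier import (
    BASES,
    CgClass,
    SnpRecord,
    SubstitutionClass,
    classify_frame,
    classify_snp_record,
    classify_substitution,
    cpg_present,
    enumerate_scenarios,
    orient_gain_loss,
    reverse_complement,
    scenario_counts,
    summarize_classes,
)
from cpgvar.errors import (
    DegenerateVariantError,
    InconsistentAncestralError,
    InvalidBaseError,
)

ALL_CONTEXTS = [
    (left, a, b, right)
    for left, a, b, right in itertools.product(BASES, BASES, BASES, BASES)
    if a != b
]


def oracle_classify(left: str, a: str, b: str, right: str) -> SubstitutionClass:
    """Independent brute-force oracle: build both trinucleotide strings and
    literally search them for "CG"."""
    has_a = "CG" in f"{left}{a}{right}"
    has_b = "CG" in f"{left}{b}{right}"
    if has_a and has_b:
        return SubstitutionClass.CG_SHIFT
    if has_a or has_b:
        return SubstitutionClass.CG_POLYMORPHIC
    return SubstitutionClass.NON_CG


class TestCpgPresent:
    @pytest.mark.parametrize(
        "tri,expected",
        [(("C", "G", "A"), True), (("A", "C", "G"), True), (("A", "A", "A"), False)],
    )
    def test_examples(self, tri, expected):
        assert cpg_present(*tri) is expected

    def test_invalid_base_rejected(self):
        with pytest.raises(InvalidBaseError):
            cpg_present("N", "C", "G")


class TestClassifySubstitution:
    def test_agrees_with_bruteforce_oracle_on_all_cases(self):
        for left, a, b, right in ALL_CONTEXTS:
            assert classify_substitution(left, a, b, right) == oracle_classify(
                left, a, b, right
            ), (left, a, b, right)

    @pytest.mark.parametrize(
        "case,expected",
        [
            (("C", "C", "T", "G"), SubstitutionClass.CG_POLYMORPHIC),
            (("C", "C", "G", "G"), SubstitutionClass.CG_SHIFT),
            (("A", "A", "T", "A"), SubstitutionClass.NON_CG),
        ],
        ids=["c_to_t_loss", "ccg_shift", "no_cpg"],
    )
    def test_worked_examples(self, case, expected):
        assert classify_substitution(*case) == expected

    def test_identical_alleles_rejected(self):
        with pytest.raises(DegenerateVariantError):
            classify_substitution("A", "C", "C", "G")

    def test_strand_complement_invariance_on_all_cases(self):
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for left, a, b, right in ALL_CONTEXTS:
            fwd = classify_substitution(left, a, b, right)
            rev = classify_substitution(comp[right], comp[a], comp[b], comp[left])
            assert fwd == rev, (left, a, b, right)


class TestOrientGainLoss:
    @pytest.mark.parametrize(
        "ancestral,expected",
        [("C", CgClass.CG_LOSS), ("T", CgClass.CG_GAIN), (None, CgClass.CG_UNORIENTED)],
    )
    def test_cct_g_orientation(self, ancestral, expected):
        sub = classify_substitution("C", "C", "T", "G")
        assert orient_gain_loss(sub, "C", "T", ancestral, "C", "G") == expected

    def test_shift_and_noncg_pass_through(self):
        assert (
            orient_gain_loss(SubstitutionClass.CG_SHIFT, "C", "G", "C", "C", "G")
            == CgClass.CG_SHIFT_EXCLUDED
        )
        assert (
            orient_gain_loss(SubstitutionClass.NON_CG, "A", "T", "A", "A", "A")
            == CgClass.NON_CG
        )

    def test_inconsistent_ancestral_rejected(self):
        sub = classify_substitution("C", "C", "T", "G")
        with pytest.raises(InconsistentAncestralError):
            orient_gain_loss(sub, "C", "T", "G", "C", "G")

    def test_ancestral_swap_mirrors_gain_and_loss(self):
        """Swapping the ancestral allele maps every gain to a loss and back."""
        for left, a, b, right in ALL_CONTEXTS:
            sub = classify_substitution(left, a, b, right)
            if sub is not SubstitutionClass.CG_POLYMORPHIC:
                continue
            with_a = orient_gain_loss(sub, a, b, a, left, right)
            with_b = orient_gain_loss(sub, a, b, b, left, right)
            assert {with_a, with_b} == {CgClass.CG_GAIN, CgClass.CG_LOSS}


def _record(**kwargs) -> SnpRecord:
    defaults = dict(
        snp_id="rs1",
        chrom="chr1",
        pos=100,
        strand="+",
        allele_a="C",
        allele_b="T",
        ancestral="C",
        maf=0.2,
        flank5="TTAC",
        flank3="GAAT",
    )
    defaults.update(kwargs)
    return SnpRecord(**defaults)


class TestClassifySnpRecord:
    def test_uses_only_adjacent_context_bases(self):
        rec = _record(flank5="GGGGGAC", flank3="GTTTTT")
        assert classify_snp_record(rec).cg_class == CgClass.CG_LOSS

    def test_reverse_complemented_record_classifies_identically(self):
        rec = _record()
        assert (
            classify_snp_record(rec).cg_class
            == classify_snp_record(rec.reverse_complemented()).cg_class
        )

    def test_ambiguous_context_gives_noncg_with_warning(self):
        rec = _record(flank3="NAAT", ancestral=None)
        result = classify_snp_record(rec)
        assert result.cg_class == CgClass.NON_CG
        assert result.warning and result.warning.startswith("ambiguous_context")

    def test_degenerate_record_rejected_at_construction(self):
        with pytest.raises(DegenerateVariantError):
            _record(allele_b="C")

    def test_frame_classification_matches_per_record(self, small_panel):
        frame = classify_frame(small_panel.snps.head(200))
        for row, cls in zip(frame.itertuples(index=False), frame["cg_class"]):
            rec = SnpRecord(
                snp_id=row.snp_id,
                chrom=row.chrom,
                pos=row.pos,
                strand=row.strand,
                allele_a=row.allele_a,
                allele_b=row.allele_b,
                ancestral=row.ancestral or None,
                maf=row.maf,
                flank5=row.flank5,
                flank3=row.flank3,
            )
            assert classify_snp_record(rec).cg_class.value == cls


class TestEnumerateScenarios:
    def test_table_covers_all_ordered_substitutions_once(self):
        table = enumerate_scenarios()
        assert len(table) == 192
        key_cols = ["left_base", "ancestral_allele", "derived_allele", "right_base"]
        assert not table.duplicated(key_cols).any()

    def test_gain_and_loss_scenarios_are_equinumerous(self):
        counts = scenario_counts()
        assert counts["n_gain"] == counts["n_loss"]

    def test_counts_match_independent_enumeration(self):
        """The boolean-change rule yields 22 gains + 22 losses (44 ordered
        gain/loss scenarios) and 2 ordered shift scenarios, frozen from the
        brute-force string-search oracle."""
        n_gain = n_loss = n_shift = 0
        for left, anc, der, right in ALL_CONTEXTS:
            has_anc = "CG" in f"{left}{anc}{right}"
            has_der = "CG" in f"{left}{der}{right}"
            if has_anc and has_der:
                n_shift += 1
            elif has_anc:
                n_loss += 1
            elif has_der:
                n_gain += 1
        assert (n_gain, n_loss, n_shift) == (22, 22, 2)
        counts = scenario_counts()
        assert counts["n_gain"] == n_gain
        assert counts["n_loss"] == n_loss
        assert counts["n_shift"] == n_shift
        assert counts["n_gain_loss"] == 44

    def test_shift_rows_are_flagged_and_are_the_ccg_cases(self):
        table = enumerate_scenarios()
        shifts = table[table["is_shift"]]
        assert set(
            map(
                tuple,
                shifts[
                    ["left_base", "ancestral_allele", "derived_allele", "right_base"]
                ].to_numpy(),
            )
        ) == {("C", "C", "G", "G"), ("C", "G", "C", "G")}


class TestSummarizeClasses:
    def _frame(self, counts):
        rows = []
        for region, cls, n in counts:
            rows += [{"cpg_region": region, "cg_class": cls}] * n
        return pd.DataFrame(rows)

    def test_balanced_gains_and_losses(self):
        frame = self._frame([("island", "cg_gain", 10), ("island", "cg_loss", 10)])
        out = summarize_classes(frame).set_index("cpg_region")
        assert out.loc["island", "pct_gain"] == 50.0
        assert out.loc["island", "pct_loss"] == 50.0

    def test_unoriented_counts_in_denominator(self):
        frame = self._frame(
            [
                ("sea", "cg_gain", 2),
                ("sea", "cg_loss", 2),
                ("sea", "cg_unoriented", 1),
            ]
        )
        out = summarize_classes(frame).set_index("cpg_region")
        assert out.loc["sea", "n_cgsnp"] == 5
        assert out.loc["sea", "pct_gain"] == pytest.approx(40.0)
        assert out.loc["sea", "pct_loss"] == pytest.approx(40.0)

    def test_empty_input_gives_empty_table(self):
        out = summarize_classes(pd.DataFrame(columns=["cpg_region", "cg_class"]))
        assert out.empty
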