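"""Genetic-code primitives: translation, change classes, site counts."""

import itertools
from fractions import Fraction

import pytest
from Bio.Seq import Seq

from omegacontrast import codon_core as cc
from omegacontrast.codon_core import ChangeClass, InvalidSequenceError


def bio_aa(codon: str) -> str:
    """Independent translation oracle (Biopython, standard table)."""
    return str(Seq(codon).translate())


class TestGeneticCode:
    def test_partition_into_sense_and_stop(self):
        code = cc.STANDARD_CODE
        assert len(code.codon_to_aa) == 64
        assert set(code.stop_codons) == {"TAA", "TAG", "TGA"}
        assert len(code.sense_codons) == 61
        assert len({code.codon_to_aa[c] for c in code.sense_codons}) == 20

    def test_table_agrees_with_biopython(self):
        for codon in cc.STANDARD_CODE.codon_to_aa:
            assert cc.STANDARD_CODE.codon_to_aa[codon] == bio_aa(codon)


class TestTranslate:
    @pytest.mark.parametrize(
        "cds,protein",
        [("ATG", "M"), ("ATGTAA", "M*"), ("TTTGTA", "FV"), ("uuuGUA", "FV")],
    )
    def test_examples(self, cds, protein):
        assert cc.translate(cds) == protein

    def test_length_not_multiple_of_three_rejected(self):
        with pytest.raises(InvalidSequenceError, match="multiple of 3"):
            cc.translate("ATGA")

    def test_invalid_character_reports_position(self):
        with pytest.raises(InvalidSequenceError, match="position 4"):
            cc.translate("ATGANA")


class TestClassifyChange:
    @pytest.mark.parametrize(
        "codon,pos,base,expected",
        [
            ("TTT", 3, "C", ChangeClass.SYNONYMOUS),
            ("TTT", 1, "G", ChangeClass.NONSYNONYMOUS),
            ("CAA", 1, "T", ChangeClass.NONSENSE),
        ],
    )
    def test_examples(self, codon, pos, base, expected):
        assert cc.classify_change(codon, pos, base) is expected

    def test_same_base_is_invalid_call(self):
        with pytest.raises(ValueError, match="equals existing base"):
            cc.classify_change("TTT", 1, "T")

    def test_stop_codon_rejected(self):
        with pytest.raises(InvalidSequenceError):
            cc.classify_change("TAA", 1, "C")

    def test_reverse_changes_between_sense_codons_share_class(self):
        # symmetric except NONSENSE, which by construction needs a stop endpoint
        for codon in cc.STANDARD_CODE.sense_codons:
            for pos in (1, 2, 3):
                for base in cc.BASES:
                    if base == codon[pos - 1]:
                        continue
                    mutated = codon[: pos - 1] + base + codon[pos:]
                    if cc.STANDARD_CODE.is_stop(mutated):
                        continue
                    forward = cc.classify_change(codon, pos, base)
                    backward = cc.classify_change(mutated, pos, codon[pos - 1])
                    assert forward is backward


class TestPositionFractions:
    def test_first_position_rounds_to_96_percent(self):
        value = cc.first_position_nonsynonymous_fraction()
        assert value == pytest.approx(100 * 175 / 183)
        assert round(value) == 96

    def test_second_position_always_changes_amino_acid(self):
        assert cc.position_nonsynonymous_fraction(2) == 100.0

    def test_fraction_excluding_nonsense_changes(self):
        # among first-position changes that do not create a stop codon,
        # 166 of 174 alter the amino acid
        classes = [
            cc.classify_change(codon, 1, base)
            for codon in cc.STANDARD_CODE.sense_codons
            for base in cc.BASES
            if base != codon[0]
        ]
        assert len(classes) == 183
        non_nonsense = [c for c in classes if c is not ChangeClass.NONSENSE]
        assert len(non_nonsense) == 174
        changing = sum(1 for c in non_nonsense if c is ChangeClass.NONSYNONYMOUS)
        assert Fraction(changing, len(non_nonsense)) == Fraction(166, 174)


class TestSynonymousSites:
    @pytest.mark.parametrize(
        "codon,expected",
        [("ATG", Fraction(0)), ("TTT", Fraction(1, 3)), ("CTG", Fraction(4, 3))],
    )
    def test_examples(self, codon, expected):
        assert cc.synonymous_site_count(codon) == expected

    def test_stop_codon_rejected(self):
        with pytest.raises(InvalidSequenceError):
            cc.synonymous_site_count("TGA")

    def test_sites_sum_to_three_and_match_neighbour_enumeration(self):
        # oracle: enumerate all 9 single-base neighbours with Biopython
        for codon in cc.STANDARD_CODE.sense_codons:
            syn = 0
            for pos, base in itertools.product(range(3), cc.BASES):
                if base == codon[pos]:
                    continue
                mutated = codon[:pos] + base + codon[pos + 1 :]
                if bio_aa(mutated) != "*" and bio_aa(mutated) == bio_aa(codon):
                    syn += 1
            assert cc.synonymous_site_count(codon) == Fraction(syn, 3)
            assert cc.synonymous_site_count(codon) + cc.nonsynonymous_site_count(codon) == 3
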