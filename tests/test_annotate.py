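"""Genetic code, feature lookup and codon-level effect prediction."""

import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from chloroclade import (
    STOP,
    GenomeFeature,
    ReferenceGenome,
    ReferenceMismatchError,
    locate_feature,
    predict_effect,
    read_feature_map,
    reverse_complement,
    translate_codon,
    write_feature_map,
)

BASES = "ACGT"
ALL_CODONS = [a + b + c for a in BASES for b in BASES for c in BASES]


def test_translate_codon_matches_standard_code_on_all_64():
    for codon in ALL_CODONS:
        expected = str(Seq(codon).translate())
        assert translate_codon(codon) == (STOP if expected == "*" else expected)


@pytest.mark.parametrize("codon", ["TG", "TGGA", "TGN", "tgg", "U.."])
def test_translate_codon_rejects_invalid_input(codon):
    with pytest.raises(ValueError):
        translate_codon(codon)


@pytest.mark.parametrize(
    "ref_codon,alt_codon,aa_ref,aa_alt",
    [
        ("TGG", "TTG", "W", "L"),   # tryptophan -> leucine
        ("AAT", "GAT", "N", "D"),   # asparagine -> aspartic acid
        ("TCT", "CCT", "S", "P"),   # serine -> proline
        ("GCT", "GTT", "A", "V"),   # alanine -> valine
    ],
)
def test_published_substitution_effects(ref_codon, alt_codon, aa_ref, aa_alt):
    assert translate_codon(ref_codon) == aa_ref
    assert translate_codon(alt_codon) == aa_alt


class TestLocateFeature:
    def test_every_position_maps_to_exactly_one_feature(
        self, mini_reference, mini_features
    ):
        for pos in range(1, mini_reference.length + 1):
            feature = locate_feature(mini_features, pos, mini_reference.length)
            assert feature.feature_class in (
                "CDS", "tRNA", "rRNA", "intron", "intergenic"
            )

    @pytest.mark.parametrize(
        "position,expected_class,expected_gene",
        [
            (15, "CDS", "geneP"),
            (35, "CDS", "geneM"),
            (55, "tRNA", "trnX"),
            (68, "intron", "trnY-intron"),
            (80, "rRNA", "rrn16"),
            (3, "intergenic", None),
            (100, "intergenic", None),
        ],
    )
    def test_known_positions(
        self, mini_features, position, expected_class, expected_gene
    ):
        feature = locate_feature(mini_features, position)
        assert feature.feature_class == expected_class
        assert feature.gene_name == expected_gene

    def test_cds_beats_overlapping_annotations(self):
        features = [
            GenomeFeature("trnZ", "tRNA", "+", ((10, 30),)),
            GenomeFeature("geneX", "CDS", "+", ((20, 25),)),
        ]
        assert locate_feature(features, 22).feature_class == "CDS"
        assert locate_feature(features, 12).feature_class == "tRNA"

    def test_out_of_range_position(self, mini_features):
        with pytest.raises(IndexError):
            locate_feature(mini_features, 0)
        with pytest.raises(IndexError):
            locate_feature(mini_features, 101, genome_length=100)


class TestPredictEffect:
    def test_plus_strand_nonsynonymous(self, mini_reference, mini_features):
        # codon TGG at 17..19; G->T at 18 gives TTG: W -> L
        call = predict_effect(mini_reference, mini_features, 18, "G", "T")
        assert call.verdict == "nonsynonymous"
        assert (call.codon_ref, call.codon_alt) == ("TGG", "TTG")
        assert (call.aa_ref, call.aa_alt) == ("W", "L")
        assert call.describe() == "Tryptophan to leucine"

    def test_plus_strand_synonymous_wobble(self, mini_reference, mini_features):
        # codon GCT at 14..16; T->C at 16 gives GCC: both alanine
        call = predict_effect(mini_reference, mini_features, 16, "T", "C")
        assert call.verdict == "synonymous"
        assert call.describe() == "no"

    def test_minus_strand_codon_reconstruction(self, mini_reference, mini_features):
        # geneM coding TCT at coding idx 3..5 = genomic 36,35,34; genomic
        # A->G at 36 is coding T->C: TCT -> CCT, serine -> proline
        call = predict_effect(mini_reference, mini_features, 36, "A", "G")
        assert call.verdict == "nonsynonymous"
        assert (call.codon_ref, call.codon_alt) == ("TCT", "CCT")
        assert call.describe() == "Serine to proline"

    @pytest.mark.parametrize(
        "position,ref,verdict",
        [(55, None, "tRNA_change"), (68, None, "intron_change"),
         (80, None, "rRNA_change"), (3, None, "intergenic")],
    )
    def test_non_cds_verdicts(self, mini_reference, mini_features, position,
                              ref, verdict):
        ref_base = mini_reference.base(position)
        alt = "A" if ref_base != "A" else "C"
        call = predict_effect(mini_reference, mini_features, position, ref_base, alt)
        assert call.verdict == verdict

    def test_gap_allele_is_indel_without_codon_analysis(
        self, mini_reference, mini_features
    ):
        call = predict_effect(
            mini_reference, mini_features, 18, mini_reference.base(18), "-"
        )
        assert call.verdict == "indel"
        assert call.codon_ref is None and call.aa_ref is None

    def test_reference_mismatch_names_position(self, mini_reference, mini_features):
        wrong = "A" if mini_reference.base(18) != "A" else "C"
        with pytest.raises(ReferenceMismatchError, match="18"):
            predict_effect(mini_reference, mini_features, 18, wrong, "T")

    def test_no_change_is_rejected(self, mini_reference, mini_features):
        base = mini_reference.base(18)
        with pytest.raises(ValueError):
            predict_effect(mini_reference, mini_features, 18, base, base)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    codon=st.sampled_from(ALL_CODONS),
    offset=st.integers(0, 2),
    alt=st.sampled_from(BASES),
    pad=st.integers(0, 5),
)
def test_strand_symmetry_of_effect_prediction(codon, offset, alt, pad):
    """A substitution seen on the + strand and its mirrored - strand
    construction must give identical codons, amino acids and verdicts."""
    flank = "ACGTA" * 3
    plus_seq = flank[:pad] + codon + flank[pad:]
    start = pad + 1
    plus_ref = ReferenceGenome("p", plus_seq)
    plus_feat = [GenomeFeature("g", "CDS", "+", ((start, start + 2),))]
    position = start + offset
    if plus_ref.base(position) == alt:
        return
    call_plus = predict_effect(plus_ref, plus_feat, position, codon[offset], alt)

    minus_seq = reverse_complement(plus_seq)
    length = len(minus_seq)
    m_start = length - (start + 2) + 1
    minus_ref = ReferenceGenome("m", minus_seq)
    minus_feat = [GenomeFeature("g", "CDS", "-", ((m_start, m_start + 2),))]
    m_position = length - position + 1
    call_minus = predict_effect(
        minus_ref, minus_feat, m_position,
        reverse_complement(codon[offset]), reverse_complement(alt),
    )
    assert call_plus.verdict == call_minus.verdict
    assert call_plus.codon_ref == call_minus.codon_ref
    assert call_plus.codon_alt == call_minus.codon_alt
    assert call_plus.aa_ref == call_minus.aa_ref
    assert call_plus.aa_alt == call_minus.aa_alt


def test_feature_map_roundtrip(tmp_path, mini_features):
    path = tmp_path / "features.tsv"
    write_feature_map(mini_features, path)
    recovered = read_feature_map(path)
    assert {f.gene_name for f in recovered} == {f.gene_name for f in mini_features}
    by_name = {f.gene_name: f for f in recovered}
    for feature in mini_features:
        other = by_name[feature.gene_name]
        assert other.exons == feature.exons
        assert other.strand == feature.strand
        assert other.feature_class == feature.feature_class


def test_cds_length_invariant_enforced():
    with pytest.raises(ValueError):
        GenomeFeature("bad", "CDS", "+", ((1, 10),), phase=0)
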