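"""Feature extraction: codon counting, RSCU, CAI, and the 89-value layout."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from essgene.corpus import GeneRecord
from essgene.errors import ConfigurationError, InvalidInputError
from essgene.features import (
    AMINO_ACIDS,
    CODONS,
    FEATURE_NAMES,
    AdaptednessTable,
    CodonCounts,
    aa_frequencies,
    build_feature_vector,
    cai,
    codon_frequencies,
    count_codons,
    feature_table,
    gc_content,
    relative_adaptedness,
    rscu,
    rscu_max,
    _synonymous_families,
)

# random codon-count tables for property tests
codon_counts_st = st.dictionaries(
    st.sampled_from(CODONS), st.integers(min_value=1, max_value=50), min_size=1
).map(lambda d: CodonCounts(dict(d), sum(d.values())))


class TestCountCodons:
    @pytest.mark.parametrize(
        "dna, expected, total",
        [
            ("ATGAAATGA", {"ATG": 1, "AAA": 1, "TGA": 1}, 3),
            ("ATGAAAT", {"ATG": 1, "AAA": 1}, 2),  # trailing base discarded
            ("ATGNNNAAA", {"ATG": 1, "AAA": 1}, 2),  # ambiguous triplet skipped
            ("atgaaa", {"ATG": 1, "AAA": 1}, 2),  # case-insensitive
        ],
    )
    def test_in_frame_counting(self, dna, expected, total):
        counts = count_codons(dna)
        assert counts.counts == expected
        assert counts.total == total

    @pytest.mark.parametrize("dna", ["", "NNN", "AT"])
    def test_degenerate_sequences_error(self, dna):
        with pytest.raises(InvalidInputError):
            count_codons(dna, "gene_x")

    def test_error_names_the_record(self):
        with pytest.raises(InvalidInputError, match="gene_x"):
            count_codons("NNN", "gene_x")


class TestCodonFrequencies:
    def test_hand_counted_normalization(self):
        freq = codon_frequencies(CodonCounts({"ATG": 1, "AAA": 1, "TGA": 2}, 4))
        assert freq[CODONS.index("ATG")] == 0.25
        assert freq[CODONS.index("AAA")] == 0.25
        assert freq[CODONS.index("TGA")] == 0.5
        assert freq.sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_codon(self):
        freq = codon_frequencies(CodonCounts({"AAA": 5}, 5))
        assert freq[CODONS.index("AAA")] == 1.0
        assert freq.sum() == 1.0

    def test_zero_total_errors(self):
        with pytest.raises(InvalidInputError):
            codon_frequencies(CodonCounts({}, 0))

    @given(codon_counts_st)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_frequencies_nonnegative_and_sum_to_one(self, counts):
        if counts.total == 0:
            return
        freq = codon_frequencies(counts)
        assert (freq >= 0).all()
        assert abs(freq.sum() - 1.0) < 1e-9


class TestGcContent:
    @pytest.mark.parametrize(
        "dna, expected", [("GGCC", 1.0), ("ATAT", 0.0), ("ATGC", 0.5)]
    )
    def test_hand_counts(self, dna, expected):
        assert gc_content(dna) == expected

    def test_ambiguity_codes_excluded(self):
        assert gc_content("GCNN") == 1.0

    def test_no_unambiguous_bases_errors(self):
        with pytest.raises(InvalidInputError):
            gc_content("NNNN")


class TestRscu:
    def test_uniform_usage_gives_all_ones(self):
        counts = CodonCounts({c: 1 for c in CODONS}, 64)
        table = rscu(counts)
        assert all(v == pytest.approx(1.0) for v in table.rscu.values())

    def test_two_fold_family_hand_value(self):
        # Lys family AAA/AAG with counts (3, 1)
        table = rscu(CodonCounts({"AAA": 3, "AAG": 1}, 4))
        assert table.rscu["AAA"] == pytest.approx(1.5)
        assert table.rscu["AAG"] == pytest.approx(0.5)

    def test_unobserved_family_is_zero(self):
        table = rscu(CodonCounts({"AAA": 3}, 3))
        assert table.rscu["GGG"] == 0.0  # Gly family unobserved

    def test_unknown_code_errors(self):
        with pytest.raises(ConfigurationError):
            rscu(CodonCounts({"AAA": 1}, 1), code=9999)

    @given(codon_counts_st)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_observed_family_mean_is_one(self, counts):
        table = rscu(counts)
        for _aa, family in _synonymous_families(11).items():
            if sum(counts[c] for c in family) > 0:
                mean = sum(table.rscu[c] for c in family) / len(family)
                assert abs(mean - 1.0) < 1e-9


class TestRscuMax:
    def test_uniform_usage(self):
        assert rscu_max(rscu(CodonCounts({c: 1 for c in CODONS}, 64))) == 1.0

    def test_hand_table(self):
        table = rscu(CodonCounts({"AAA": 3, "AAG": 1}, 4))
        assert rscu_max(table) == pytest.approx(1.5)

    def test_all_zero_table(self):
        assert rscu_max(rscu(CodonCounts({}, 0))) == 0.0

    def test_stop_codons_excluded(self):
        # only stops observed: their RSCU is 3.0 for TGA but must not count
        table = rscu(CodonCounts({"TGA": 6}, 6))
        assert rscu_max(table) == 0.0


class TestRelativeAdaptedness:
    def test_family_counts_hand_values(self):
        table = relative_adaptedness(CodonCounts({"AAA": 3, "AAG": 1}, 4))
        assert table.r["AAA"] == pytest.approx(1.0)
        assert table.r["AAG"] == pytest.approx(1 / 3)

    def test_unobserved_codon_pseudo_count(self):
        table = relative_adaptedness(CodonCounts({"AAA": 4}, 4))
        assert table.r["AAG"] == pytest.approx(0.5 / 4)

    def test_met_trp_stops_excluded(self):
        table = relative_adaptedness(
            CodonCounts({"ATG": 2, "TGG": 1, "TGA": 1, "AAA": 1}, 5)
        )
        assert {"ATG", "TGG", "TGA", "TAA", "TAG"} <= set(table.excluded)
        assert "ATG" not in table.r

    def test_zero_total_reference_errors(self):
        with pytest.raises(InvalidInputError):
            relative_adaptedness(CodonCounts({}, 0))

    @given(codon_counts_st)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_values_in_unit_interval_and_family_max_is_one(self, counts):
        table = relative_adaptedness(counts)
        assert all(0 < v <= 1 for v in table.r.values())
        for _aa, family in _synonymous_families(11).items():
            scored = [c for c in family if c in table.r]
            if scored:
                assert max(table.r[c] for c in scored) == pytest.approx(1.0)


class TestCai:
    def test_geometric_mean_hand_value(self):
        table = AdaptednessTable({"AAA": 1.0, "GGG": 0.25}, frozenset())
        value = cai(CodonCounts({"AAA": 1, "GGG": 1}, 2), table)
        assert value == pytest.approx(math.sqrt(1.0 * 0.25))

    def test_family_maximal_gene_reaches_one(self):
        reference = CodonCounts({"AAA": 3, "AAG": 1, "GGC": 5, "GGG": 2}, 11)
        table = relative_adaptedness(reference)
        gene = CodonCounts({"AAA": 4, "GGC": 2}, 6)
        assert cai(gene, table) == 1.0

    def test_all_excluded_codons_error(self):
        table = relative_adaptedness(CodonCounts({"AAA": 1}, 1))
        with pytest.raises(InvalidInputError):
            cai(count_codons("ATGTGA"), table)  # Met + stop only

    @given(codon_counts_st)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_duplication_invariance(self, counts):
        table = relative_adaptedness(counts)
        scored = [c for c in counts.counts if c in table.r]
        if not scored:
            return
        doubled = CodonCounts(
            {c: 2 * n for c, n in counts.counts.items()}, 2 * counts.total
        )
        assert cai(doubled, table) == pytest.approx(cai(counts, table), rel=1e-12)

    def test_self_reference_is_one_iff_only_maximal_codons(self):
        maximal_only = CodonCounts({"AAA": 3, "GGC": 2}, 5)
        assert cai(maximal_only, relative_adaptedness(maximal_only)) == 1.0
        mixed = CodonCounts({"AAA": 3, "AAG": 1}, 4)
        assert cai(mixed, relative_adaptedness(mixed)) < 1.0


class TestAaFrequencies:
    def test_hand_counts(self):
        freq = aa_frequencies("MK")
        assert freq[AMINO_ACIDS.index("M")] == 0.5
        assert freq[AMINO_ACIDS.index("K")] == 0.5

    def test_single_residue(self):
        freq = aa_frequencies("AAAA")
        assert freq[AMINO_ACIDS.index("A")] == 1.0

    def test_nonstandard_letters_skipped(self):
        freq = aa_frequencies("AXUA")
        assert freq[AMINO_ACIDS.index("A")] == 1.0

    def test_trailing_stop_ignored(self):
        assert np.array_equal(aa_frequencies("MK*"), aa_frequencies("MK"))

    def test_no_standard_residues_errors(self):
        with pytest.raises(InvalidInputError):
            aa_frequencies("XXXX")


class TestFeatureVector:
    def test_exactly_89_values_with_fixed_layout(self, tiny_records):
        vec = build_feature_vector(tiny_records[0])
        assert vec.values.shape == (89,)
        assert len(FEATURE_NAMES) == 89
        assert sum(n.startswith("codon_") for n in FEATURE_NAMES) == 64
        assert sum(n.startswith("aa_") for n in FEATURE_NAMES) == 20

    def test_deterministic(self, tiny_records):
        a = build_feature_vector(tiny_records[0]).values
        b = build_feature_vector(tiny_records[0]).values
        assert np.array_equal(a, b)

    def test_hand_computed_entries(self):
        rec = GeneRecord("g", "SP", "ATGAAAAAATGA", "MKK", True)
        d = build_feature_vector(rec).as_dict()
        assert d["gene_length"] == 12.0
        assert d["protein_length"] == 3.0
        assert d["gc_content"] == pytest.approx(2 / 12)  # G at positions 3 and 11
        codon_sum = sum(v for k, v in d.items() if k.startswith("codon_"))
        aa_sum = sum(v for k, v in d.items() if k.startswith("aa_"))
        assert codon_sum == pytest.approx(1.0, abs=1e-9)
        assert aa_sum == pytest.approx(1.0, abs=1e-9)
        assert 0 < d["cai"] <= 1

    def test_error_carries_record_id(self):
        rec = GeneRecord("broken_gene", "SP", "NN", "MK", True)
        with pytest.raises(InvalidInputError, match="broken_gene"):
            build_feature_vector(rec)


class TestFeatureTable:
    def test_shape_and_columns(self, tiny_records):
        frame = feature_table(tiny_records)
        assert frame.shape == (3, 4 + 89)
        assert list(frame.columns[:4]) == ["gene_id", "species", "essential", "cluster_id"]

    def test_species_pooled_reference(self, small_corpus):
        records = small_corpus[0][:50]
        frame_self = feature_table(records, reference="self")
        frame_sp = feature_table(records, reference="species")
        # pooling changes CAI but nothing else
        assert not np.allclose(frame_self["cai"], frame_sp["cai"])
        assert np.allclose(frame_self["gc_content"], frame_sp["gc_content"])
        assert np.allclose(frame_self["rscu_max"], frame_sp["rscu_max"])

    def test_unknown_reference_mode(self, tiny_records):
        with pytest.raises(ConfigurationError):
            feature_table(tiny_records, reference="global")
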