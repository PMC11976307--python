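"""Exact-identity haplotype collapsing, code assignment and combination."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from cordytrace.haplotypes import (
    HaplotypeEncoder,
    assign_codes,
    collapse_haplotypes,
    combine,
    format_code,
    haplotype_spectrum,
    singleton_fraction,
)
from cordytrace.io import Locality, Specimen

short_seqs = st.lists(
    st.text(alphabet="ACGT", min_size=1, max_size=6), min_size=0, max_size=50
)


def pairs(seqs):
    return [(f"S{i}", s) for i, s in enumerate(seqs)]


class TestCollapse:
    @pytest.mark.parametrize(
        "seqs, n_haplotypes",
        [
            (["AAA", "AAA"], 1),  # identical sequences merge
            (["AAA", "AAT"], 2),  # a single substitution splits
            (["AAA", "AAAA"], 2),  # no alignment: length difference splits
            ([], 0),
        ],
    )
    def test_identity_classes(self, seqs, n_haplotypes):
        catalog = collapse_haplotypes(pairs(seqs), marker="ITS")
        assert len(catalog) == n_haplotypes
        assert catalog.n_sequences == len(seqs)

    def test_case_and_rna_variants_merge(self):
        catalog = collapse_haplotypes(pairs(["acgu", "ACGT"]), marker="ITS")
        assert len(catalog) == 1

    def test_ambiguity_codes_are_not_expanded(self):
        catalog = collapse_haplotypes(pairs(["ACGN", "ACGT"]), marker="ITS")
        assert len(catalog) == 2

    @given(seqs=short_seqs)
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_pairwise_equality_clustering(self, seqs):
        catalog = collapse_haplotypes(pairs(seqs), marker="COI")
        # oracle: all-pairs string-equality clustering
        oracle: list[list[str]] = []
        for sid, s in pairs(seqs):
            for group in oracle:
                if group[0][1] == s:
                    group.append((sid, s))
                    break
            else:
                oracle.append([(sid, s)])
        expected = {frozenset(sid for sid, _ in g) for g in oracle}
        observed = {frozenset(r.member_ids) for r in catalog.records}
        assert observed == expected
        assert catalog.n_sequences == len(seqs)  # conservation

    @given(seqs=short_seqs, seed=st.integers(0, 2**16))
    @settings(max_examples=40, deadline=None)
    def test_partition_is_permutation_stable(self, seqs, seed):
        base = collapse_haplotypes(pairs(seqs), marker="COI")
        order = np.random.default_rng(seed).permutation(len(seqs))
        shuffled = [pairs(seqs)[i] for i in order]
        perm = collapse_haplotypes(shuffled, marker="COI")
        partition = lambda cat: {frozenset(r.member_ids) for r in cat.records}
        assert partition(base) == partition(perm)


class TestAssignCodes:
    def test_codes_follow_descending_frequency(self):
        seqs = ["A"] * 5 + ["C"] * 3 + ["G"]
        catalog = assign_codes(collapse_haplotypes(pairs(seqs), "COI"), prefix="H")
        by_code = {r.code: r.sequence for r in catalog.records}
        assert by_code == {"H01": "A", "H02": "C", "H03": "G"}

    def test_reference_codes_take_precedence_over_rank(self):
        seqs = ["A"] * 5 + ["C"]
        catalog = assign_codes(
            collapse_haplotypes(pairs(seqs), "ITS"), prefix="F", reference={"C": "F07"}
        )
        by_seq = {r.sequence: r.code for r in catalog.records}
        assert by_seq["C"] == "F07"
        # novel codes are numbered after the reference maximum
        assert by_seq["A"] == "F08"

    def test_reference_gaps_are_tolerated(self):
        # inherited numbering may skip codes; fresh codes continue past the max
        reference = {"AA": "F13", "CC": "F15"}
        catalog = assign_codes(
            collapse_haplotypes(pairs(["AA", "CC", "GG"]), "ITS"),
            prefix="F",
            reference=reference,
        )
        assert {r.code for r in catalog.records} == {"F13", "F15", "F16"}

    def test_equal_counts_break_ties_by_first_occurrence(self):
        seqs = ["T", "G", "T", "G"]  # both seen twice; T first
        catalog = assign_codes(collapse_haplotypes(pairs(seqs), "COI"), prefix="H")
        by_code = {r.code: r.sequence for r in catalog.records}
        assert by_code == {"H01": "T", "H02": "G"}

    def test_duplicate_reference_code_is_a_configuration_error(self):
        with pytest.raises(ValueError, match="reference"):
            assign_codes(
                collapse_haplotypes(pairs(["A", "C"]), "ITS"),
                prefix="F",
                reference={"A": "F01", "C": "F01"},
            )

    def test_code_width_grows_beyond_99_without_renumbering(self):
        assert format_code("F", 7) == "F07"
        assert format_code("F", 100) == "F100"


def make_specimen(sid, its, coi, county="Maqên"):
    return Specimen(sid, Locality("Qinghai", "Guoluo", county), its, coi)


class TestCombine:
    def fit(self, specimens):
        its = assign_codes(
            collapse_haplotypes([(s.specimen_id, s.its_seq) for s in specimens], "ITS"),
            "F",
        )
        coi = assign_codes(
            collapse_haplotypes([(s.specimen_id, s.coi_seq) for s in specimens], "COI"),
            "H",
        )
        return its, coi

    def test_same_its_different_coi_yields_two_combined(self):
        specimens = [make_specimen("S1", "AAA", "TTT"), make_specimen("S2", "AAA", "GGG")]
        combined = combine(*self.fit(specimens), specimens)
        assert sorted(ch.code for ch in combined) == ["F01H01", "F01H02"]

    def test_identical_specimens_collapse_to_one_combined(self):
        specimens = [make_specimen(f"S{i}", "AAA", "TTT") for i in range(4)]
        combined = combine(*self.fit(specimens), specimens)
        assert len(combined) == 1 and combined[0].count == 4

    def test_missing_specimen_is_reported_by_id(self):
        specimens = [make_specimen("S1", "AAA", "TTT")]
        its, coi = self.fit(specimens)
        stranger = make_specimen("S9", "AAA", "TTT")
        with pytest.raises(KeyError, match="S9"):
            combine(its, coi, specimens + [stranger])

    @given(
        data=st.lists(
            st.tuples(st.sampled_from("AC"), st.sampled_from("GT")),
            min_size=1,
            max_size=40,
        )
    )
    @settings(max_examples=40, deadline=None)
    def test_combined_count_bounds(self, data):
        specimens = [
            make_specimen(f"S{i}", its, coi) for i, (its, coi) in enumerate(data)
        ]
        its, coi = self.fit(specimens)
        combined = combine(its, coi, specimens)
        assert max(len(its), len(coi)) <= len(combined)
        assert len(combined) <= min(len(its) * len(coi), len(specimens))
        assert sum(ch.count for ch in combined) == len(specimens)


class TestSpectrum:
    def test_tally_and_singleton_fraction(self):
        seqs = ["A"] * 5 + ["C"] * 3 + ["G", "T"]
        catalog = collapse_haplotypes(pairs(seqs), "COI")
        assert haplotype_spectrum(catalog) == {1: 2, 3: 1, 5: 1}
        assert singleton_fraction(catalog) == 0.5

    def test_single_haplotype_spectrum(self):
        catalog = collapse_haplotypes(pairs(["A"] * 7), "COI")
        assert haplotype_spectrum(catalog) == {7: 1}

    def test_empty_catalog_has_no_spectrum(self):
        with pytest.raises(ValueError):
            haplotype_spectrum(collapse_haplotypes([], "COI"))


class TestHaplotypeEncoder:
    def test_fit_transform_round_trip(self):
        X = [("S1", "AAA"), ("S2", "AAA"), ("S3", "CCC")]
        enc = HaplotypeEncoder(marker="COI").fit(X)
        assert enc.n_haplotypes_ == 2
        assert list(enc.transform(["AAA", "CCC"])) == ["H01", "H02"]

    def test_unseen_sequence_raises(self):
        enc = HaplotypeEncoder(marker="ITS").fit(["AAA"])
        with pytest.raises(ValueError, match="not present"):
            enc.transform(["TTT"])

    def test_sklearn_clone_compatibility(self):
        enc = HaplotypeEncoder(marker="COI", reference={"AAA": "H05"})
        cloned = clone(enc)
        assert cloned.get_params()["marker"] == "COI"
        assert list(cloned.fit(["AAA", "CCC"]).transform(["AAA"])) == ["H05"]
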