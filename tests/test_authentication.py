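"""Locality table construction, sharing scopes, traceability, origin tracing."""

import pytest

from cordytrace.authentication import (
    LocalityTable,
    OriginAuthenticator,
    UnknownHaplotypeError,
    build_locality_table,
    classify_counties,
    discriminability_summary,
    sharing_footnote,
    sharing_scope,
    trace_origin,
)
from cordytrace.haplotypes import CombinedHaplotype
from cordytrace.io import Locality, Specimen


def loc(province, prefecture, county):
    return Locality(province, prefecture, county)


class TestBuildTable:
    def test_single_specimen_yields_one_county_one_code(self):
        ch = CombinedHaplotype("F01", "H01", ["S1"], frozenset({loc("A", "B", "C")}))
        table = build_locality_table([ch])
        assert table.codes == ["F01H01"]
        assert table.counties == [loc("A", "B", "C")]

    def test_fixture_table_headline_dimensions(self, reference_table):
        assert len(reference_table.county_index) == 75
        assert len(reference_table.incidence) == 99
        assert len(reference_table.its_to_counties) == 24
        assert len(reference_table.coi_to_counties) == 78

    def test_transpose_consistency(self, reference_table):
        rebuilt = {}
        for code, locs in reference_table.incidence.items():
            for l in locs:
                rebuilt.setdefault(l, set()).add(code)
        assert {k: frozenset(v) for k, v in rebuilt.items()} == reference_table.county_index

    def test_incidence_pair_conservation(self, reference_table):
        by_code = sum(len(v) for v in reference_table.incidence.values())
        by_county = sum(len(v) for v in reference_table.county_index.values())
        assert by_code == by_county == 129


class TestSharingScope:
    def test_cross_province_sharing(self, reference_table):
        scope = sharing_scope(reference_table, "F01H03")  # Xiahe (Gansu) + Maqên (Qinghai)
        assert scope.shared_across_provinces
        assert not scope.county_unique

    def test_county_unique_code(self, reference_table):
        scope = sharing_scope(reference_table, "F23H18")  # Ledu only
        assert scope.county_unique
        assert not scope.shared_across_provinces
        assert not scope.shared_across_prefectures_within_province

    def test_cross_prefecture_within_province(self, reference_table):
        # F01H02 spans Darlag, Gadê, Maqên (Guoluo) and Zadoi (Yushu), all Qinghai
        assert trace_origin(reference_table, "F01H02") == frozenset(
            {
                loc("Qinghai", "Guoluo", "Darlag"),
                loc("Qinghai", "Guoluo", "Gadê"),
                loc("Qinghai", "Guoluo", "Maqên"),
                loc("Qinghai", "Yushu", "Zadoi"),
            }
        )
        scope = sharing_scope(reference_table, "F01H02")
        assert scope.shared_across_prefectures_within_province
        assert not scope.shared_across_provinces

    def test_footnotes_render_per_province_context(self, reference_table):
        # F02H01 spans one Gansu prefecture but five Qinghai prefectures
        assert sharing_footnote(reference_table, "F02H01", "Gansu") == "a"
        assert sharing_footnote(reference_table, "F02H01", "Qinghai") == "ab"
        # F01H04 sits in one Qinghai prefecture but three Xizang prefectures
        assert sharing_footnote(reference_table, "F01H04", "Qinghai") == "a"
        assert sharing_footnote(reference_table, "F01H04", "Xizang") == "ab"

    def test_fixture_annotations_are_reproduced(self, reference_fixture, reference_table):
        """Every stored shared/unique flag and footnote matches the computed one."""
        for row in reference_fixture.rows:
            for code in row.combined_codes:
                shared = not reference_table.is_unique(code)
                assert shared == (code in row.shared_codes), (row.locality, code)
                if shared:
                    note = sharing_footnote(
                        reference_table, code, row.locality.province
                    )
                    assert note == row.shared_codes[code], (row.locality, code)

    def test_sharing_implies_not_unique_monotonicity(self, reference_table):
        for code in reference_table.codes:
            scope = sharing_scope(reference_table, code)
            if scope.shared_across_provinces or scope.shared_across_prefectures_within_province:
                assert not scope.county_unique
        # adding a county can only widen scope
        base = LocalityTable.from_pairs([("F01H01", loc("P1", "Q1", "C1"))])
        widened = LocalityTable.from_pairs(
            [("F01H01", loc("P1", "Q1", "C1")), ("F01H01", loc("P2", "Q2", "C2"))]
        )
        s0, s1 = sharing_scope(base, "F01H01"), sharing_scope(widened, "F01H01")
        assert s1.shared_across_provinces >= s0.shared_across_provinces
        assert not s1.county_unique


class TestCountyClassification:
    def test_published_example_labels(self, reference_table):
        labels = {c.locality.county: c for c in classify_counties(reference_table)}
        assert labels["Maqên"].label == "13 Unique+2 Shared"
        assert labels["Maqên"].traceability == "conditionally-traceable"
        assert labels["Baxoi"].label == "Shared"
        assert labels["Baxoi"].traceability == "untraceable"
        assert labels["Maqu"].label == "Unique"
        assert labels["Maqu"].traceability == "traceable"

    def test_all_75_labels_match_the_reference_rows(self, reference_fixture, reference_table):
        computed = {c.locality: c.label for c in classify_counties(reference_table)}
        mismatches = [
            (row.locality, computed[row.locality], row.classification)
            for row in reference_fixture.rows
            if computed[row.locality] != row.classification
        ]
        assert mismatches == []

    def test_tallies_partition_the_counties(self, reference_table):
        cls = classify_counties(reference_table)
        assert len(cls) == 75
        for c in cls:
            assert c.n_unique + c.n_shared == len(reference_table.county_index[c.locality])


class TestTraceOrigin:
    def test_unique_code_traces_to_single_county(self, reference_table):
        assert trace_origin(reference_table, "F23H18") == frozenset(
            {loc("Qinghai", "Haidong", "Ledu")}
        )

    def test_widespread_core_code_spans_ten_counties(self, reference_table):
        counties = trace_origin(reference_table, "F01H04")
        assert len(counties) == 10
        provinces = {l.province for l in counties}
        assert provinces == {"Qinghai", "Xizang"}

    def test_unknown_code_raises_with_component_candidates(self, reference_table):
        with pytest.raises(UnknownHaplotypeError) as err:
            trace_origin(reference_table, "F01H99")
        assert "F01H04" in err.value.candidates


class TestSummary:
    def test_fixture_tallies(self, reference_table):
        s = discriminability_summary(reference_table)
        assert (s.n_counties, s.n_its, s.n_coi, s.n_combined) == (75, 24, 78, 99)
        # 12 combined haplotypes are shared between counties; the rest are
        # confined to a single county
        assert s.n_single_county_codes == 87
        assert s.n_single_code_counties == 48
        assert (s.n_traceable, s.n_conditionally_traceable, s.n_untraceable) == (39, 18, 18)
        assert s.per_province_its == {
            "Gansu": 2, "Qinghai": 8, "Sichuan": 7, "Xizang": 14, "Yunnan": 2
        }
        assert s.per_province_coi == {
            "Gansu": 4, "Qinghai": 20, "Sichuan": 15, "Xizang": 41, "Yunnan": 2
        }

    def test_all_unique_table_is_fully_traceable(self):
        pairs = [(f"F0{i}H0{i}", loc("P", "Q", f"C{i}")) for i in range(1, 4)]
        s = discriminability_summary(LocalityTable.from_pairs(pairs))
        assert s.n_single_county_codes == s.n_combined == 3
        assert s.n_traceable == s.n_counties == 3


class TestOriginAuthenticator:
    def test_fit_predict_on_a_toy_collection(self):
        specimens = [
            Specimen("S1", loc("P1", "Q1", "C1"), "AAA", "TTT"),
            Specimen("S2", loc("P1", "Q1", "C1"), "AAA", "TTT"),
            Specimen("S3", loc("P2", "Q2", "C2"), "AAA", "GGG"),
        ]
        auth = OriginAuthenticator().fit(specimens)
        assert auth.summary_.n_combined == 2
        (counties,) = auth.predict(["F01H01"])
        assert counties == frozenset({loc("P1", "Q1", "C1")})

    def test_unfitted_predict_raises(self):
        with pytest.raises(ValueError, match="not fitted"):
            OriginAuthenticator().predict(["F01H01"])
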