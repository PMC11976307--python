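"""County-level origin authentication from combined-haplotype incidence.

The central structure is the :class:`LocalityTable`: which combined
haplotypes were detected in which counties.  A combined haplotype is
*unique* when detected in exactly one county and *shared* otherwise; a
county whose haplotypes are all unique is fully traceable (a market sample
bearing one of them pins the county), a county with only shared haplotypes
can be traced only to the multi-county area holding the haplotype, and a
county with both is conditionally traceable.

Sharing is annotated at the two administrative scopes used in the trade:
across provinces, and across prefectures within one province.  Sharing
between counties of a single prefecture carries no annotation and is
reported as plain "shared".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from sklearn.base import BaseEstimator

from cordytrace.haplotypes import (
    CombinedHaplotype,
    HaplotypeEncoder,
    code_number,
)
from cordytrace.io import (
    FixtureRow,
    Locality,
    ReferenceFixture,
    Specimen,
    SpecimenSet,
    split_combined_code,
)

TRACEABLE = "traceable"
CONDITIONALLY_TRACEABLE = "conditionally-traceable"
UNTRACEABLE = "untraceable"


class UnknownHaplotypeError(KeyError):
    """A queried combined code is absent from the reference table.

    ``candidates`` lists reference codes sharing the query's ITS or COI
    component — a convenience hint, not an assignment method.
    """

    def __init__(self, code: str, candidates: Sequence[str]):
        self.code = code
        self.candidates = tuple(candidates)
        msg = f"combined haplotype {code} not in the reference table"
        if candidates:
            msg += f"; codes sharing a component: {', '.join(candidates)}"
        super().__init__(msg)


def _sort_key(code: str) -> tuple[int, int]:
    its_c, coi_c = split_combined_code(code)
    return code_number(its_c), code_number(coi_c)


@dataclass(frozen=True)
class LocalityTable:
    """Incidence of combined haplotypes across counties, plus marker projections."""

    incidence: dict[str, frozenset[Locality]]
    county_index: dict[Locality, frozenset[str]]

    @staticmethod
    def from_pairs(pairs: Iterable[tuple[str, Locality]]) -> "LocalityTable":
        inc: dict[str, set[Locality]] = {}
        cty: dict[Locality, set[str]] = {}
        for code, loc in pairs:
            split_combined_code(code)  # validates shape
            inc.setdefault(code, set()).add(loc)
            cty.setdefault(loc, set()).add(code)
        if not inc:
            raise ValueError("cannot build a locality table from empty input")
        return LocalityTable(
            incidence={c: frozenset(v) for c, v in inc.items()},
            county_index={l: frozenset(v) for l, v in cty.items()},
        )

    @property
    def codes(self) -> list[str]:
        return sorted(self.incidence, key=_sort_key)

    @property
    def counties(self) -> list[Locality]:
        return sorted(self.county_index)

    @property
    def its_to_counties(self) -> dict[str, frozenset[Locality]]:
        out: dict[str, set[Locality]] = {}
        for code, locs in self.incidence.items():
            its_c, _ = split_combined_code(code)
            out.setdefault(its_c, set()).update(locs)
        return {c: frozenset(v) for c, v in out.items()}

    @property
    def coi_to_counties(self) -> dict[str, frozenset[Locality]]:
        out: dict[str, set[Locality]] = {}
        for code, locs in self.incidence.items():
            _, coi_c = split_combined_code(code)
            out.setdefault(coi_c, set()).update(locs)
        return {c: frozenset(v) for c, v in out.items()}

    def is_unique(self, code: str) -> bool:
        """True when the combined code was detected in exactly one county."""
        return len(self.incidence[code]) == 1


@dataclass(frozen=True)
class SharingScope:
    """Administrative scope of a combined haplotype's distribution."""

    code: str
    shared_across_provinces: bool
    shared_across_prefectures_within_province: bool
    county_unique: bool


@dataclass(frozen=True)
class CountyClassification:
    locality: Locality
    n_unique: int
    n_shared: int
    label: str
    traceability: str


@dataclass(frozen=True)
class DiscriminabilitySummary:
    n_counties: int
    n_its: int
    n_coi: int
    n_combined: int
    n_single_county_codes: int
    n_single_code_counties: int
    n_traceable: int
    n_conditionally_traceable: int
    n_untraceable: int
    per_province_its: dict[str, int]
    per_province_coi: dict[str, int]
    per_province_combined: dict[str, int]


def build_locality_table(combined: Sequence[CombinedHaplotype]) -> LocalityTable:
    """Build the incidence table from combined haplotypes of a specimen set."""
    pairs = [(ch.code, loc) for ch in combined for loc in ch.counties]
    return LocalityTable.from_pairs(pairs)


def build_locality_table_from_fixture(fixture: ReferenceFixture) -> LocalityTable:
    """Build the incidence table from the packaged 75-county reference table."""
    pairs = [
        (code, row.locality) for row in fixture.rows for code in row.combined_codes
    ]
    return LocalityTable.from_pairs(pairs)


def sharing_scope(table: LocalityTable, code: str) -> SharingScope:
    """Compute the administrative sharing flags for one combined haplotype."""
    if code not in table.incidence:
        raise UnknownHaplotypeError(code, _component_candidates(table, code))
    locs = table.incidence[code]
    provinces = {l.province for l in locs}
    cross_prefecture = any(
        len({l.prefecture for l in locs if l.province == prov}) > 1
        for prov in provinces
    )
    return SharingScope(
        code=code,
        shared_across_provinces=len(provinces) > 1,
        shared_across_prefectures_within_province=cross_prefecture,
        county_unique=len(locs) == 1,
    )


def sharing_footnote(table: LocalityTable, code: str, province: str) -> str:
    """Render the sharing footnote for a code as printed in a given province's rows.

    ``"a"`` marks cross-province sharing (a global property); ``"b"`` marks
    sharing across prefectures *within the stated province* — a code spread
    over several Qinghai prefectures but present in only one Gansu prefecture
    carries ``"ab"`` in Qinghai rows and only ``"a"`` in the Gansu row.
    """
    locs = table.incidence[code]
    note = ""
    if len({l.province for l in locs}) > 1:
        note += "a"
    if len({l.prefecture for l in locs if l.province == province}) > 1:
        note += "b"
    return note


def classify_counties(table: LocalityTable) -> list[CountyClassification]:
    """Per-county unique/shared tallies, display label and traceability level.

    Counties are ordered province -> prefecture -> county for reproducible
    output.  The label renders as ``"Unique"`` (all codes unique),
    ``"Shared"`` (all shared) or ``"k Unique+m Shared"``.
    """
    out = []
    for loc in table.counties:
        codes = table.county_index[loc]
        n_unique = sum(table.is_unique(c) for c in codes)
        n_shared = len(codes) - n_unique
        if n_shared == 0:
            label, trace = "Unique", TRACEABLE
        elif n_unique == 0:
            label, trace = "Shared", UNTRACEABLE
        else:
            label = f"{n_unique} Unique+{n_shared} Shared"
            trace = CONDITIONALLY_TRACEABLE
        out.append(CountyClassification(loc, n_unique, n_shared, label, trace))
    return out


def _component_candidates(table: LocalityTable, code: str) -> list[str]:
    try:
        its_c, coi_c = split_combined_code(code)
    except ValueError:
        return []
    return [
        c
        for c in table.codes
        if split_combined_code(c)[0] == its_c or split_combined_code(c)[1] == coi_c
    ]


def trace_origin(table: LocalityTable, code: str) -> frozenset[Locality]:
    """Candidate origin counties for a market sample bearing ``code``.

    The method is presence/absence lookup: the answer is the full set of
    reference counties where the combined haplotype was detected.  A code
    absent from the table raises :class:`UnknownHaplotypeError` listing codes
    that share its ITS or COI component.
    """
    if code not in table.incidence:
        raise UnknownHaplotypeError(code, _component_candidates(table, code))
    return table.incidence[code]


def discriminability_summary(table: LocalityTable) -> DiscriminabilitySummary:
    """Headline discriminability and traceability tallies of a reference table."""
    classifications = classify_counties(table)
    trace_counts = {TRACEABLE: 0, CONDITIONALLY_TRACEABLE: 0, UNTRACEABLE: 0}
    for c in classifications:
        trace_counts[c.traceability] += 1
    its_proj = table.its_to_counties
    coi_proj = table.coi_to_counties

    def per_province(proj: Mapping[str, frozenset[Locality]]) -> dict[str, int]:
        provs: dict[str, set[str]] = {}
        for code, locs in proj.items():
            for l in locs:
                provs.setdefault(l.province, set()).add(code)
        return {p: len(codes) for p, codes in sorted(provs.items())}

    return DiscriminabilitySummary(
        n_counties=len(table.county_index),
        n_its=len(its_proj),
        n_coi=len(coi_proj),
        n_combined=len(table.incidence),
        n_single_county_codes=sum(table.is_unique(c) for c in table.incidence),
        n_single_code_counties=sum(
            len(codes) == 1 for codes in table.county_index.values()
        ),
        n_traceable=trace_counts[TRACEABLE],
        n_conditionally_traceable=trace_counts[CONDITIONALLY_TRACEABLE],
        n_untraceable=trace_counts[UNTRACEABLE],
        per_province_its=per_province(its_proj),
        per_province_coi=per_province(coi_proj),
        per_province_combined=per_province(
            {c: locs for c, locs in table.incidence.items()}
        ),
    )


def render_table(table: LocalityTable) -> pd.DataFrame:
    """Render the incidence table in the reference-table layout.

    One row per county (sorted province -> prefecture -> county) with marker
    code lists, combined codes annotated with sharing footnotes, sample-free
    classification label and traceability.
    """
    classifications = {c.locality: c for c in classify_counties(table)}
    rows = []
    for loc in table.counties:
        codes = sorted(table.county_index[loc], key=_sort_key)
        its_codes = sorted(
            {split_combined_code(c)[0] for c in codes}, key=code_number
        )
        coi_codes = sorted(
            {split_combined_code(c)[1] for c in codes}, key=code_number
        )
        rendered = []
        for c in codes:
            if table.is_unique(c):
                rendered.append(c)
            else:
                note = sharing_footnote(table, c, loc.province)
                rendered.append(f"{c}*{note}" if note else f"{c}*")
        cls = classifications[loc]
        rows.append(
            {
                "province": loc.province,
                "prefecture": loc.prefecture,
                "county": loc.county,
                "its_haplotypes": ", ".join(its_codes),
                "coi_haplotypes": ", ".join(coi_codes),
                "combined_haplotypes": ", ".join(rendered),
                "classification": cls.label,
                "traceability": cls.traceability,
            }
        )
    return pd.DataFrame(rows)


class OriginAuthenticator(BaseEstimator):
    """Fit a combined-haplotype reference database; predict candidate origins.

    ``fit`` runs the full pipeline on a reference collection of specimens:
    collapse each marker into haplotypes, assign codes (honouring optional
    published numbering references), form combined haplotypes and build the
    locality table.  ``predict`` performs the presence/absence lookup for
    query combined codes.

    Parameters
    ----------
    its_reference, coi_reference:
        Optional numbering references (sequence -> code) passed to the
        per-marker encoders.
    """

    def __init__(self, its_reference: Optional[Mapping[str, str]] = None,
                 coi_reference: Optional[Mapping[str, str]] = None):
        self.its_reference = its_reference
        self.coi_reference = coi_reference

    def fit(self, X: SpecimenSet | Sequence[Specimen], y=None) -> "OriginAuthenticator":
        specimens = list(X)
        if not specimens:
            raise ValueError("cannot fit an authenticator on zero specimens")
        self.its_encoder_ = HaplotypeEncoder(marker="ITS", reference=self.its_reference)
        self.coi_encoder_ = HaplotypeEncoder(marker="COI", reference=self.coi_reference)
        self.its_encoder_.fit([(s.specimen_id, s.its_seq) for s in specimens])
        self.coi_encoder_.fit([(s.specimen_id, s.coi_seq) for s in specimens])
        self.combined_ = combine_from_encoders(
            self.its_encoder_, self.coi_encoder_, specimens
        )
        self.table_ = build_locality_table(self.combined_)
        self.summary_ = discriminability_summary(self.table_)
        return self

    def predict(self, X: Sequence[str]) -> list[frozenset[Locality]]:
        """Candidate county sets for a sequence of combined codes."""
        if not hasattr(self, "table_"):
            raise ValueError("OriginAuthenticator is not fitted yet")
        return [trace_origin(self.table_, code) for code in X]

    def county_classifications(self) -> list[CountyClassification]:
        return classify_counties(self.table_)


def combine_from_encoders(
    its_encoder: HaplotypeEncoder,
    coi_encoder: HaplotypeEncoder,
    specimens: Sequence[Specimen],
) -> list[CombinedHaplotype]:
    from cordytrace.haplotypes import combine

    return combine(its_encoder.catalog_, coi_encoder.catalog_, specimens)
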