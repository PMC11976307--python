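"""Delimitation of core and non-core production regions.

The trade recognises a "core" production belt — the adjacent high-altitude
regions of Qinghai and Xizang plus a few refinements — whose caterpillar
fungus commands the highest prices.  Operationally, a set of hallmark core
marker haplotypes is fixed (explicitly configured, or derived from clade
membership and presence in the core reference regions), a combined haplotype
is core when *both* of its components are core, and a county is

* ``core`` when every combined haplotype observed there is core,
* ``non-core`` when none is,
* ``mixed`` otherwise.

The both-components rule exactly reproduces the published list of 26 core
combined haplotypes from the published core marker sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

import yaml
from sklearn.base import BaseEstimator

from cordytrace.authentication import LocalityTable
from cordytrace.haplotypes import HaplotypeCatalog
from cordytrace.io import Locality, split_combined_code

CORE = "core"
NON_CORE = "non-core"
MIXED = "mixed"

REGION_RULES = ("and", "or", "ignore")


class DerivationError(ValueError):
    """Raised when core-set derivation lacks required clade information."""


@dataclass(frozen=True)
class RegionKey:
    """A core reference region: a whole prefecture, or specific counties of one."""

    province: str
    prefecture: str
    counties: Optional[tuple[str, ...]] = None  # None = whole prefecture

    def contains(self, loc: Locality) -> bool:
        if (loc.province, loc.prefecture) != (self.province, self.prefecture):
            return False
        return self.counties is None or loc.county in self.counties


@dataclass(frozen=True)
class CoreCriteria:
    """Configuration for core/non-core delimitation."""

    core_reference_regions: tuple[RegionKey, ...] = ()
    explicit_core_its: Optional[frozenset[str]] = None
    explicit_core_coi: Optional[frozenset[str]] = None
    core_its_clades: frozenset[str] = frozenset()
    core_coi_clades: frozenset[str] = frozenset()
    clade_map: Mapping[str, str] = field(default_factory=dict)
    region_rule: str = "and"
    name: str = "criteria"

    def __post_init__(self) -> None:
        if self.region_rule not in REGION_RULES:
            raise ValueError(
                f"region_rule must be one of {REGION_RULES}, got {self.region_rule!r}"
            )

    @staticmethod
    def from_yaml(path: str | Path) -> "CoreCriteria":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return CoreCriteria._from_mapping(raw)

    @staticmethod
    def _from_mapping(raw: Mapping) -> "CoreCriteria":
        regions = tuple(
            RegionKey(
                province=r["province"],
                prefecture=r["prefecture"],
                counties=tuple(r["counties"]) if r.get("counties") else None,
            )
            for r in raw.get("core_reference_regions", [])
        )
        def opt_set(key: str) -> Optional[frozenset[str]]:
            val = raw.get(key)
            return None if val in (None, []) else frozenset(val)

        return CoreCriteria(
            core_reference_regions=regions,
            explicit_core_its=opt_set("explicit_core_its"),
            explicit_core_coi=opt_set("explicit_core_coi"),
            core_its_clades=frozenset(raw.get("core_its_clades") or ()),
            core_coi_clades=frozenset(raw.get("core_coi_clades") or ()),
            clade_map=dict(raw.get("clade_map") or {}),
            region_rule=raw.get("region_rule", "and"),
            name=raw.get("name", "criteria"),
        )


@dataclass(frozen=True)
class CoreSets:
    """Resolved core haplotype sets for both markers and their combinations."""

    core_its: frozenset[str]
    core_coi: frozenset[str]
    core_combined: frozenset[str]

    def is_core(self, combined_code: str) -> bool:
        return combined_code in self.core_combined


@dataclass(frozen=True)
class RegionStatus:
    locality: Locality
    status: str  # core | non-core | mixed


def paper_criteria() -> CoreCriteria:
    """The packaged published core criteria (explicit hallmark haplotype sets)."""
    ref = resources.files("cordytrace.data").joinpath("core_criteria.yaml")
    with resources.as_file(ref) as path:
        return CoreCriteria.from_yaml(path)


def _marker_codes(
    catalog: Optional[HaplotypeCatalog], table: LocalityTable, component: int
) -> set[str]:
    if catalog is not None:
        return set(catalog.by_code)
    return {split_combined_code(c)[component] for c in table.incidence}


def resolve_core_sets(
    criteria: CoreCriteria,
    its_catalog: Optional[HaplotypeCatalog] = None,
    coi_catalog: Optional[HaplotypeCatalog] = None,
    table: Optional[LocalityTable] = None,
) -> CoreSets:
    """Resolve the core marker sets and the induced core combined set.

    Explicit sets, when configured, take precedence and are validated against
    the observed codes.  Otherwise a marker code is core according to its
    clade membership and/or its presence in a core reference region,
    controlled by ``criteria.region_rule`` ("and" demands both, "or" either,
    "ignore" clade membership alone).  A combined haplotype is core when both
    components are core; only observed combined codes are returned.
    """
    if table is None:
        raise ValueError("a locality table is required to resolve core sets")
    its_codes = _marker_codes(its_catalog, table, 0)
    coi_codes = _marker_codes(coi_catalog, table, 1)

    def resolve(
        codes: set[str],
        explicit: Optional[frozenset[str]],
        clades: frozenset[str],
        proj: Mapping[str, frozenset[Locality]],
    ) -> frozenset[str]:
        if explicit is not None:
            unknown = explicit - codes
            if unknown:
                raise ValueError(
                    f"explicit core codes not observed in the data: {sorted(unknown)}"
                )
            return explicit
        if not criteria.core_reference_regions and criteria.region_rule != "ignore":
            return frozenset()
        out = set()
        for code in codes:
            if code not in criteria.clade_map:
                raise DerivationError(f"clade_map does not cover haplotype {code}")
            clade_ok = criteria.clade_map[code] in clades
            region_ok = any(
                region.contains(loc)
                for region in criteria.core_reference_regions
                for loc in proj.get(code, ())
            )
            keep = {
                "and": clade_ok and region_ok,
                "or": clade_ok or region_ok,
                "ignore": clade_ok,
            }[criteria.region_rule]
            if keep:
                out.add(code)
        return frozenset(out)

    core_its = resolve(
        its_codes, criteria.explicit_core_its, criteria.core_its_clades,
        table.its_to_counties,
    )
    core_coi = resolve(
        coi_codes, criteria.explicit_core_coi, criteria.core_coi_clades,
        table.coi_to_counties,
    )
    core_combined = frozenset(
        code
        for code in table.incidence
        if split_combined_code(code)[0] in core_its
        and split_combined_code(code)[1] in core_coi
    )
    return CoreSets(core_its=core_its, core_coi=core_coi, core_combined=core_combined)


def classify_region_status(
    table: LocalityTable, core_sets: CoreSets
) -> list[RegionStatus]:
    """Assign each county core / non-core / mixed by the all/none/mixed rule."""
    out = []
    for loc in table.counties:
        codes = table.county_index[loc]
        n_core = sum(c in core_sets.core_combined for c in codes)
        if n_core == len(codes):
            status = CORE
        elif n_core == 0:
            status = NON_CORE
        else:
            status = MIXED
        out.append(RegionStatus(locality=loc, status=status))
    return out


class CoreRegionClassifier(BaseEstimator):
    """Sklearn-style classifier from county incidence to core/non-core/mixed.

    ``fit`` resolves the core haplotype sets against a fitted
    :class:`LocalityTable`; ``predict`` returns the status of query counties.

    Parameters
    ----------
    criteria:
        A :class:`CoreCriteria`; defaults to the packaged published criteria.
    """

    def __init__(self, criteria: Optional[CoreCriteria] = None):
        self.criteria = criteria

    def fit(self, X: LocalityTable, y=None) -> "CoreRegionClassifier":
        criteria = self.criteria if self.criteria is not None else paper_criteria()
        self.core_sets_ = resolve_core_sets(criteria, table=X)
        self.statuses_ = classify_region_status(X, self.core_sets_)
        self._status_by_locality_ = {s.locality: s.status for s in self.statuses_}
        return self

    def predict(self, X: Sequence[Locality]) -> list[str]:
        if not hasattr(self, "core_sets_"):
            raise ValueError("CoreRegionClassifier is not fitted yet")
        return [self._status_by_locality_[loc] for loc in X]
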