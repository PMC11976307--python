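"""Synthetic specimen-set generator with ground truth.

The generator emulates the statistical structure of the real collection the
pipeline was designed for: 215 specimens over 75 counties in five provinces
(43 Xizang, 14 Qinghai, 13 Sichuan, 3 Gansu, 2 Yunnan), fixed marker
sequence lengths (ITS 580 bp, COI 1009 bp), two dominant fungal haplotypes
(57.2% and 20.5% of specimens), a host-insect marker with a long singleton
tail (75.6% of COI haplotypes seen once), and county-restricted haplotype
compositions mimicking geographic structure.  Within-county haplotype
frequencies of the real collection are unpublished, so the non-dominant
spectrum masses are fixed plausible values calibrated only to those global
statistics.

Geography is specified, not modelled: no spatial or coalescent process is
simulated.  County compositions (which combined haplotypes may occur where)
are part of the profile, and in fixture-mimicking mode every allowed
(county, haplotype) pair is drawn at least once, so the incidence table —
the information content of the reference table — is reproduced
deterministically while counts remain stochastic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from cordytrace.authentication import LocalityTable
from cordytrace.io import (
    Locality,
    ReferenceFixture,
    Specimen,
    SpecimenSet,
    load_reference_fixture,
    split_combined_code,
    write_specimens,
)

ITS_LENGTH = 580
COI_LENGTH = 1009

# Global marker spectra (specimen counts per haplotype code, n = 215).
# Leading masses follow the published global statistics: ITS F01 = 123
# (57.2%), F02 = 44 (20.5%), remaining 22 haplotypes 1-10 specimens each;
# COI H01..H04 = 45/34/17/14, H05..H19 between 2 and 8, H20..H78 singletons
# (59/78 = 75.6% singleton haplotypes).
DEFAULT_ITS_COUNTS: dict[str, int] = {
    code: count
    for code, count in zip(
        ["F01", "F02", "F03", "F04", "F05", "F06", "F07", "F08", "F09", "F10",
         "F11", "F12", "F13", "F15", "F16", "F17", "F19", "F20", "F21", "F22",
         "F23", "F24", "F25", "F26"],
        [123, 44, 10, 6, 4, 3, 3, 2, 2, 2, 2, 2] + [1] * 12,
    )
}

DEFAULT_COI_COUNTS: dict[str, int] = {
    f"H{i:02d}": c
    for i, c in enumerate(
        [45, 34, 17, 14]
        + [8, 6, 4, 4, 3, 3, 2, 2, 2, 2, 2, 2, 2, 2, 2]
        + [1] * 59,
        start=1,
    )
}


@dataclass(frozen=True)
class GenerationProfile:
    """Parameters of the synthetic-data generator.

    ``county_composition`` maps a county to the combined haplotypes allowed
    there (as (ITS code, COI code) pairs); ``None`` leaves all counties
    unrestricted, in which case the two marker codes of each specimen are
    drawn independently from the global spectra.  With a composition and
    ``guarantee_incidence`` every allowed pair is drawn at least once per
    county (requires county sample size >= number of allowed pairs).
    """

    counties: tuple[tuple[Locality, int], ...]
    its_spectrum: dict[str, float]
    coi_spectrum: dict[str, float]
    county_composition: Optional[dict[Locality, tuple[tuple[str, str], ...]]] = None
    its_length: int = ITS_LENGTH
    coi_length: int = COI_LENGTH
    mutation_rate: float = 0.003
    guarantee_incidence: bool = False

    def validate(self) -> None:
        if not self.counties:
            raise ValueError("profile must contain at least one county")
        for spectrum, name in ((self.its_spectrum, "ITS"), (self.coi_spectrum, "COI")):
            if not spectrum:
                raise ValueError(f"{name} spectrum is empty")
            total = sum(spectrum.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} spectrum sums to {total}, expected 1")
            if any(p < 0 for p in spectrum.values()):
                raise ValueError(f"{name} spectrum has negative mass")
        if self.its_length <= 0 or self.coi_length <= 0:
            raise ValueError("sequence lengths must be positive")
        if not 0 <= self.mutation_rate < 1:
            raise ValueError("mutation_rate must be in [0, 1)")
        sizes = {loc: n for loc, n in self.counties}
        if any(n < 1 for n in sizes.values()):
            raise ValueError("every county needs at least one specimen")
        if self.county_composition is not None:
            for loc, allowed in self.county_composition.items():
                if not allowed:
                    raise ValueError(f"empty haplotype composition for {loc}")
                for its_c, coi_c in allowed:
                    if its_c not in self.its_spectrum or coi_c not in self.coi_spectrum:
                        raise ValueError(
                            f"{loc}: composition code ({its_c}, {coi_c}) not in spectra"
                        )
            missing = set(sizes) - set(self.county_composition)
            if missing:
                raise ValueError(f"counties without composition: {sorted(missing)}")
            if self.guarantee_incidence:
                for loc, allowed in self.county_composition.items():
                    if sizes[loc] < len(allowed):
                        raise ValueError(
                            f"{loc}: {sizes[loc]} specimens cannot cover "
                            f"{len(allowed)} allowed haplotypes"
                        )

    @property
    def n_specimens(self) -> int:
        return sum(n for _, n in self.counties)


@dataclass
class TruthSet:
    """Ground truth emitted alongside a synthetic specimen set."""

    its_assignments: dict[str, str]  # specimen ID -> true ITS code
    coi_assignments: dict[str, str]
    its_pool: dict[str, str]  # code -> sequence
    coi_pool: dict[str, str]
    localities: dict[str, Locality]

    @property
    def its_reference(self) -> dict[str, str]:
        """Numbering reference (sequence -> code) for the ITS marker."""
        return {seq: code for code, seq in self.its_pool.items()}

    @property
    def coi_reference(self) -> dict[str, str]:
        return {seq: code for code, seq in self.coi_pool.items()}

    @property
    def combined_assignments(self) -> dict[str, str]:
        return {
            sid: self.its_assignments[sid] + self.coi_assignments[sid]
            for sid in self.its_assignments
        }

    def locality_table(self) -> LocalityTable:
        """The true combined-haplotype incidence table."""
        pairs = [
            (code, self.localities[sid])
            for sid, code in self.combined_assignments.items()
        ]
        return LocalityTable.from_pairs(pairs)

    def partition(self, marker: str) -> set[frozenset[str]]:
        """True haplotype partition of specimen IDs for one marker."""
        assignments = self.its_assignments if marker == "ITS" else self.coi_assignments
        groups: dict[str, set[str]] = {}
        for sid, code in assignments.items():
            groups.setdefault(code, set()).add(sid)
        return {frozenset(g) for g in groups.values()}


def generate_haplotype_pool(
    n: int, length: int, rng: np.random.Generator, mutation_rate: float = 0.0
) -> list[str]:
    """Derive ``n`` pairwise-distinct equal-length sequences from one ancestor.

    Haplotype 0 is a random ancestor; each other haplotype carries a
    substitution at its own private marker position (guaranteeing pairwise
    distinctness) plus optional extra substitutions at non-marker positions
    at ``mutation_rate`` per site.
    """
    if n < 1:
        raise ValueError("need n >= 1 haplotypes")
    if n - 1 > length:
        raise ValueError(
            f"cannot place {n - 1} distinguishing positions in {length} sites"
        )
    bases = np.array(list("ACGT"))
    ancestor = rng.choice(bases, size=length)
    marker_positions = rng.choice(length, size=n - 1, replace=False)
    free = np.setdiff1d(np.arange(length), marker_positions)
    pool = ["".join(ancestor)]
    for k in range(n - 1):
        seq = ancestor.copy()
        pos = marker_positions[k]
        alternatives = [b for b in "ACGT" if b != seq[pos]]
        seq[pos] = alternatives[rng.integers(0, 3)]
        if mutation_rate > 0 and len(free):
            n_extra = rng.binomial(len(free), mutation_rate)
            if n_extra:
                extra = rng.choice(free, size=n_extra, replace=False)
                for p in extra:
                    alt = [b for b in "ACGT" if b != seq[p]]
                    seq[p] = alt[rng.integers(0, 3)]
        pool.append("".join(seq))
    assert len(set(pool)) == n
    return pool


def _draw_codes(
    profile: GenerationProfile, rng: np.random.Generator
) -> list[tuple[Locality, str, str]]:
    """Draw per-specimen (locality, ITS code, COI code) assignments."""
    its_codes = list(profile.its_spectrum)
    its_p = np.array([profile.its_spectrum[c] for c in its_codes])
    coi_codes = list(profile.coi_spectrum)
    coi_p = np.array([profile.coi_spectrum[c] for c in coi_codes])
    out: list[tuple[Locality, str, str]] = []
    for loc, n in profile.counties:
        if profile.county_composition is None:
            its_draw = rng.choice(len(its_codes), size=n, p=its_p / its_p.sum())
            coi_draw = rng.choice(len(coi_codes), size=n, p=coi_p / coi_p.sum())
            for i, j in zip(its_draw, coi_draw):
                out.append((loc, its_codes[i], coi_codes[j]))
        else:
            allowed = list(profile.county_composition[loc])
            weights = np.array(
                [
                    profile.its_spectrum[a] * profile.coi_spectrum[b]
                    for a, b in allowed
                ]
            )
            weights = weights / weights.sum()
            draws: list[tuple[str, str]] = []
            remaining = n
            if profile.guarantee_incidence:
                draws.extend(allowed)
                remaining -= len(allowed)
            if remaining:
                idx = rng.choice(len(allowed), size=remaining, p=weights)
                draws.extend(allowed[i] for i in idx)
            for its_c, coi_c in draws:
                out.append((loc, its_c, coi_c))
    return out


def generate_dataset(
    profile: GenerationProfile, seed: int
) -> tuple[SpecimenSet, TruthSet]:
    """Generate a specimen set plus its ground truth, deterministic given seed."""
    profile.validate()
    rng = np.random.default_rng(seed)
    its_codes = list(profile.its_spectrum)
    coi_codes = list(profile.coi_spectrum)
    its_pool = dict(
        zip(
            its_codes,
            generate_haplotype_pool(
                len(its_codes), profile.its_length, rng, profile.mutation_rate
            ),
        )
    )
    coi_pool = dict(
        zip(
            coi_codes,
            generate_haplotype_pool(
                len(coi_codes), profile.coi_length, rng, profile.mutation_rate
            ),
        )
    )
    assignments = _draw_codes(profile, rng)
    specimens = SpecimenSet()
    truth = TruthSet(
        its_assignments={}, coi_assignments={},
        its_pool=its_pool, coi_pool=coi_pool, localities={},
    )
    for i, (loc, its_c, coi_c) in enumerate(assignments, start=1):
        sid = f"S{i:04d}"
        specimens.specimens.append(
            Specimen(sid, loc, its_pool[its_c], coi_pool[coi_c])
        )
        truth.its_assignments[sid] = its_c
        truth.coi_assignments[sid] = coi_c
        truth.localities[sid] = loc
    return specimens, truth


def _fixture_counties(fixture: ReferenceFixture) -> tuple[tuple[Locality, int], ...]:
    return tuple((row.locality, row.sample_size) for row in fixture.rows)


def default_profile(fixture: Optional[ReferenceFixture] = None) -> GenerationProfile:
    """The standard study-scale profile: 215 specimens over 75 counties.

    County geography and sample sizes follow the packaged reference table
    (43/14/13/3/2 counties in Xizang/Qinghai/Sichuan/Gansu/Yunnan); each
    specimen's marker codes are drawn independently from the global spectra,
    so the leading-haplotype frequencies are calibrated by construction.
    """
    fixture = fixture or load_reference_fixture()
    n = sum(DEFAULT_ITS_COUNTS.values())
    its_spectrum = {c: k / n for c, k in DEFAULT_ITS_COUNTS.items()}
    coi_spectrum = {c: k / n for c, k in DEFAULT_COI_COUNTS.items()}
    return GenerationProfile(
        counties=_fixture_counties(fixture),
        its_spectrum=its_spectrum,
        coi_spectrum=coi_spectrum,
    )


def fixture_profile(fixture: Optional[ReferenceFixture] = None) -> GenerationProfile:
    """A profile whose county compositions copy the packaged reference table.

    Every county allows exactly its published combined haplotypes, weighted
    by the global spectra renormalized to the county's composition, and every
    allowed (county, haplotype) pair is drawn at least once — the generated
    incidence table equals the reference incidence exactly.
    """
    fixture = fixture or load_reference_fixture()
    n = sum(DEFAULT_ITS_COUNTS.values())
    composition = {
        row.locality: tuple(
            split_combined_code(code) for code in row.combined_codes
        )
        for row in fixture.rows
    }
    return GenerationProfile(
        counties=_fixture_counties(fixture),
        its_spectrum={c: k / n for c, k in DEFAULT_ITS_COUNTS.items()},
        coi_spectrum={c: k / n for c, k in DEFAULT_COI_COUNTS.items()},
        county_composition=composition,
        guarantee_incidence=True,
    )


def write_dataset(
    specimens: SpecimenSet,
    truth: TruthSet,
    outdir: str | Path,
    basename: str = "synthetic",
) -> None:
    """Write a generated dataset as FASTA + metadata TSV + truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_specimens(
        specimens,
        outdir / f"{basename}_its.fasta",
        outdir / f"{basename}_coi.fasta",
        outdir / f"{basename}_metadata.tsv",
    )
    payload = {
        "its_assignments": truth.its_assignments,
        "coi_assignments": truth.coi_assignments,
        "its_pool": truth.its_pool,
        "coi_pool": truth.coi_pool,
        "localities": {
            sid: [loc.province, loc.prefecture, loc.county]
            for sid, loc in truth.localities.items()
        },
    }
    with open(outdir / f"{basename}_truth.json", "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
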