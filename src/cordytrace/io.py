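"""Specimen, metadata and reference-table I/O.

A *specimen* is one collected caterpillar-fungus individual carrying one
fungal ITS sequence and one host-insect COI sequence plus a three-level
administrative locality (province, prefecture, county).  The county key used
throughout the package is always the full triple — county names can repeat
across provinces.

The module also ships a packaged reference table transcribing the published
county-level authentication of 215 specimens from 75 counties (ITS, COI and
combined haplotype codes, sharing annotations, per-county classification and
core-production status).  Two cells of the printed table are internally
inconsistent and are stored here in their corrected form:

* the Sêrxü (Sichuan, Garzê) row prints ITS "F02" but its combined haplotype
  is F01H59 (also listed among the core combined haplotypes); the ITS cell is
  stored as F01;
* the F03H07 cells (Lhünzê and Qusum, both in Shannan prefecture) print the
  cross-prefecture sharing footnote although the two counties lie in the same
  prefecture; the footnote is dropped, matching how every other
  same-prefecture sharing is annotated.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: IUPAC nucleotide one-letter codes accepted in input sequences.
IUPAC_ALPHABET = frozenset("ACGTRYSWKMBDHVN")

_COMBINED_RE = re.compile(r"^(F\d+)(H\d+)$")

#: Fraction of the sequence length searched for each primer.
PRIMER_SEARCH_FRACTION = 0.3

METADATA_COLUMNS = ("specimen_id", "province", "prefecture", "county")
OPTIONAL_METADATA_COLUMNS = ("year", "lat", "lon", "elevation")


class FixtureError(ValueError):
    """Raised when the packaged reference table fails validation."""


@dataclass(frozen=True, order=True)
class Locality:
    """Three-level administrative county key: (province, prefecture, county)."""

    province: str
    prefecture: str
    county: str

    def __post_init__(self) -> None:
        for part in (self.province, self.prefecture, self.county):
            if not part:
                raise ValueError("all three locality fields must be non-empty")

    def __str__(self) -> str:  # Table-style rendering
        return f"{self.province}, {self.prefecture}, {self.county}"


@dataclass
class Specimen:
    """One individual with both barcode sequences and its collection locality."""

    specimen_id: str
    locality: Locality
    its_seq: str
    coi_seq: str
    year: Optional[int] = None
    lat: Optional[float] = None
    lon: Optional[float] = None
    elevation: Optional[float] = None


@dataclass
class SpecimenSet:
    """An ordered collection of specimens with a log of rejected records."""

    specimens: list[Specimen] = field(default_factory=list)
    dropped: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)

    def __len__(self) -> int:
        return len(self.specimens)

    def __iter__(self) -> Iterator[Specimen]:
        return iter(self.specimens)

    def __getitem__(self, i: int) -> Specimen:
        return self.specimens[i]

    @property
    def by_id(self) -> dict[str, Specimen]:
        return {s.specimen_id: s for s in self.specimens}


def normalize_sequence(seq: str) -> str:
    """Uppercase a nucleotide string and map U to T; reject non-IUPAC characters.

    Exact-identity haplotyping downstream must not split case or RNA/DNA
    alphabet variants of the same sequence.
    """
    s = str(seq).strip().upper().replace("U", "T")
    bad = set(s) - IUPAC_ALPHABET
    if bad:
        raise ValueError(f"non-IUPAC nucleotide characters: {sorted(bad)}")
    if not s:
        raise ValueError("empty sequence")
    return s


def _read_fasta(path: str | Path, dropped: list[tuple[str, str]]) -> dict[str, str]:
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            dropped.append((rec.id, f"duplicate record ID in {path}"))
            logger.warning("duplicate FASTA record %s in %s: keeping first", rec.id, path)
            continue
        try:
            seqs[rec.id] = normalize_sequence(str(rec.seq))
        except ValueError as exc:
            dropped.append((rec.id, f"invalid sequence in {path}: {exc}"))
            logger.warning("rejecting %s from %s: %s", rec.id, path, exc)
    return seqs


def read_specimens(
    its_fasta: str | Path, coi_fasta: str | Path, metadata: str | Path
) -> SpecimenSet:
    """Read paired barcode FASTAs plus a specimen metadata TSV into a SpecimenSet.

    Only specimens with both markers and a valid three-level locality are
    returned, preserving metadata row order.  Records missing either marker,
    carrying non-IUPAC characters, or duplicating an earlier specimen ID are
    dropped with a logged reason (available as ``SpecimenSet.dropped``).
    """
    dropped: list[tuple[str, str]] = []
    its = _read_fasta(its_fasta, dropped)
    coi = _read_fasta(coi_fasta, dropped)

    meta = pd.read_csv(metadata, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata is missing required columns: {missing}")

    out = SpecimenSet(dropped=dropped)
    seen: set[str] = set()
    for row in meta.itertuples(index=False):
        sid = row.specimen_id
        if sid in seen:
            dropped.append((sid, "duplicate specimen ID in metadata"))
            logger.warning("duplicate metadata row for %s: keeping first", sid)
            continue
        seen.add(sid)
        if sid not in its:
            dropped.append((sid, "missing ITS sequence"))
            logger.warning("dropping %s: missing ITS sequence", sid)
            continue
        if sid not in coi:
            dropped.append((sid, "missing COI sequence"))
            logger.warning("dropping %s: missing COI sequence", sid)
            continue
        try:
            loc = Locality(row.province, row.prefecture, row.county)
        except ValueError as exc:
            dropped.append((sid, f"invalid locality: {exc}"))
            logger.warning("dropping %s: %s", sid, exc)
            continue
        extras: dict[str, object] = {}
        for col, cast in (("year", int), ("lat", float), ("lon", float), ("elevation", float)):
            val = getattr(row, col, "")
            if val not in ("", None):
                try:
                    extras[col] = cast(val)
                except ValueError:
                    logger.warning("ignoring malformed %s=%r for %s", col, val, sid)
        out.specimens.append(Specimen(sid, loc, its[sid], coi[sid], **extras))
    logger.info(
        "loaded %d specimens (%d records dropped)", len(out.specimens), len(dropped)
    )
    return out


def write_specimens(
    specimens: SpecimenSet | Iterable[Specimen],
    its_fasta: str | Path,
    coi_fasta: str | Path,
    metadata: str | Path,
) -> None:
    """Write a SpecimenSet back to two FASTA files and a metadata TSV.

    Round trip: reading the written files reproduces sequences and localities
    byte-identically.
    """
    specs = list(specimens)
    for path, attr in ((its_fasta, "its_seq"), (coi_fasta, "coi_seq")):
        records = [
            SeqRecord(Seq(getattr(s, attr)), id=s.specimen_id, description="")
            for s in specs
        ]
        SeqIO.write(records, str(path), "fasta")
    rows = []
    for s in specs:
        rows.append(
            {
                "specimen_id": s.specimen_id,
                "province": s.locality.province,
                "prefecture": s.locality.prefecture,
                "county": s.locality.county,
                "year": "" if s.year is None else s.year,
                "lat": "" if s.lat is None else s.lat,
                "lon": "" if s.lon is None else s.lon,
                "elevation": "" if s.elevation is None else s.elevation,
            }
        )
    pd.DataFrame(rows).to_csv(metadata, sep="\t", index=False)


# ---------------------------------------------------------------------------
# primer trimming
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TrimResult:
    """Outcome of primer trimming: the trimmed sequence plus per-end flags."""

    sequence: str
    fwd_trimmed: bool
    rev_trimmed: bool


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def trim_primer(
    seq: str, fwd_primer: str, rev_primer: str, max_mismatch: int = 2
) -> TrimResult:
    """Trim flanking amplification primers off a Sanger-derived sequence.

    The forward primer is searched (Hamming distance only, no indels) with its
    start in the first 30% of the sequence; the reverse complement of the
    reverse primer with its end in the last 30%.  The best (fewest-mismatch)
    match within ``max_mismatch`` is removed together with everything outside
    it; ties go to the outermost match.  An absent primer leaves that end
    untouched and is reported through the corresponding flag, so trimming is
    idempotent once the primers are gone.
    """
    if not fwd_primer or not rev_primer:
        raise ValueError("primers must be non-empty")
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    seq = normalize_sequence(seq)
    n = len(seq)
    window = int(PRIMER_SEARCH_FRACTION * n)

    def best_match(primer: str, starts: Iterable[int], prefer_late: bool) -> Optional[int]:
        if len(primer) > n:
            return None
        best: Optional[tuple[int, int]] = None
        for s in starts:
            mm = _hamming(primer, seq[s : s + len(primer)])
            if mm > max_mismatch:
                continue
            key = (mm, -s if prefer_late else s)
            if best is None or key < best:
                best = key
                best_start = s
        return None if best is None else best_start

    fwd = normalize_sequence(fwd_primer)
    fwd_starts = [s for s in range(0, min(window, n - len(fwd)) + 1) if s + len(fwd) <= n]
    fwd_start = best_match(fwd, fwd_starts, prefer_late=False)

    rev = reverse_complement(normalize_sequence(rev_primer))
    rev_starts = [
        s
        for s in range(max(0, n - window - len(rev)), n - len(rev) + 1)
        if s + len(rev) >= n - window
    ]
    rev_start = best_match(rev, rev_starts, prefer_late=True)

    lo = 0 if fwd_start is None else fwd_start + len(fwd)
    hi = n if rev_start is None else rev_start
    if hi < lo:  # overlapping primer hits on a degenerate input
        return TrimResult("", fwd_start is not None, rev_start is not None)
    return TrimResult(seq[lo:hi], fwd_start is not None, rev_start is not None)


# ---------------------------------------------------------------------------
# packaged reference table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FixtureRow:
    """One county row of the packaged reference authentication table."""

    locality: Locality
    its_codes: tuple[str, ...]
    coi_codes: tuple[str, ...]
    combined_codes: tuple[str, ...]
    #: combined codes detected in more than one county, mapped to their printed
    #: sharing footnote: "" (plain shared), "a" (cross-province), "b"
    #: (cross-prefecture within province) or "ab".
    shared_codes: dict[str, str]
    sample_size: int
    classification: str
    core_status: str  # "core" | "non-core" | "mixed"


@dataclass(frozen=True)
class ReferenceFixture:
    """The packaged 75-county reference table in data form."""

    rows: tuple[FixtureRow, ...]

    def __len__(self) -> int:
        return len(self.rows)

    def row(self, county: str) -> FixtureRow:
        """Look up a row by county name (unique across the 75 counties)."""
        hits = [r for r in self.rows if r.locality.county == county]
        if len(hits) != 1:
            raise KeyError(county)
        return hits[0]


def split_combined_code(code: str) -> tuple[str, str]:
    """Split a combined code like ``F01H04`` into its ITS and COI components."""
    m = _COMBINED_RE.match(code)
    if not m:
        raise ValueError(f"malformed combined haplotype code: {code!r}")
    return m.group(1), m.group(2)


EXPECTED_FIXTURE_ROWS = 75


def load_reference_fixture() -> ReferenceFixture:
    """Load and validate the packaged 75-county reference table."""
    ref = resources.files("cordytrace.data").joinpath("table1_counties.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    rows: list[FixtureRow] = []
    for r in df.itertuples(index=False):
        its = tuple(r.its_codes.split(";"))
        coi = tuple(r.coi_codes.split(";"))
        comb = tuple(r.combined_codes.split(";"))
        shared: dict[str, str] = {}
        if r.shared_codes:
            for entry in r.shared_codes.split(";"):
                code, _, note = entry.partition(":")
                shared[code] = note
        rows.append(
            FixtureRow(
                locality=Locality(r.province, r.prefecture, r.county),
                its_codes=its,
                coi_codes=coi,
                combined_codes=comb,
                shared_codes=shared,
                sample_size=int(r.sample_size),
                classification=r.classification,
                core_status=r.core_status,
            )
        )
    fixture = ReferenceFixture(rows=tuple(rows))
    _validate_fixture(fixture)
    return fixture


def _validate_fixture(fixture: ReferenceFixture) -> None:
    if len(fixture.rows) != EXPECTED_FIXTURE_ROWS:
        raise FixtureError(
            f"expected {EXPECTED_FIXTURE_ROWS} county rows, found {len(fixture.rows)}"
        )
    seen = set()
    for row in fixture.rows:
        if row.locality in seen:
            raise FixtureError(f"duplicate county row: {row.locality}")
        seen.add(row.locality)
        if row.sample_size < 1:
            raise FixtureError(f"{row.locality}: sample_size must be >= 1")
        its_used, coi_used = set(), set()
        for code in row.combined_codes:
            its_c, coi_c = split_combined_code(code)
            if its_c not in row.its_codes or coi_c not in row.coi_codes:
                raise FixtureError(
                    f"{row.locality}: combined code {code} does not decompose "
                    f"into the row's marker code lists"
                )
            its_used.add(its_c)
            coi_used.add(coi_c)
        if its_used != set(row.its_codes) or coi_used != set(row.coi_codes):
            raise FixtureError(
                f"{row.locality}: marker codes not covered by combined codes"
            )
        if set(row.shared_codes) - set(row.combined_codes):
            raise FixtureError(f"{row.locality}: shared annotation on unknown code")
        if row.sample_size < len(row.combined_codes):
            raise FixtureError(
                f"{row.locality}: fewer specimens than combined haplotypes"
            )
        if row.core_status not in ("core", "non-core", "mixed"):
            raise FixtureError(f"{row.locality}: bad core status {row.core_status!r}")
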