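"""Haplotype collapsing, code assignment and combined (ITS x COI) haplotypes.

A haplotype is an exact-identity class of sequences: only byte-identical
sequences (after uppercase/U->T normalization) belong to the same haplotype.
No alignment is performed, so sequences of different length are always
distinct haplotypes, and IUPAC ambiguity codes are *not* expanded — a
sequence containing N is distinct from its resolved variant.  Ambiguity
resolution is an upstream chromatogram-editing task, and downstream identity
must be deterministic.

Codes follow the field convention for this system: fungal ITS haplotypes are
numbered ``F01, F02, ...`` and host-insect COI haplotypes ``H01, H02, ...``,
in decreasing order of observed frequency, except where a numbering
reference (codes inherited from earlier work) pins a sequence to its
published code.  Reference numbering may contain gaps (e.g. F14 and F18
absent); novel sequences are numbered after the reference maximum.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from cordytrace.io import Locality, Specimen, normalize_sequence

_CODE_RE = re.compile(r"^([A-Za-z]+)(\d+)$")


def code_number(code: str) -> int:
    """Numeric part of a haplotype code (``F07`` -> 7)."""
    m = _CODE_RE.match(code)
    if not m:
        raise ValueError(f"malformed haplotype code: {code!r}")
    return int(m.group(2))


def format_code(prefix: str, number: int) -> str:
    """Render a haplotype code, zero-padded to width 2 and growing beyond 99."""
    return f"{prefix}{number:02d}"


@dataclass
class HaplotypeRecord:
    marker: str
    code: Optional[str]
    sequence: str
    member_ids: list[str]

    @property
    def count(self) -> int:
        return len(self.member_ids)


@dataclass
class HaplotypeCatalog:
    """The marker-specific partition of specimens into identity classes."""

    marker: str
    records: list[HaplotypeRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def n_sequences(self) -> int:
        return sum(r.count for r in self.records)

    @property
    def by_code(self) -> dict[str, HaplotypeRecord]:
        return {r.code: r for r in self.records if r.code is not None}

    @property
    def by_sequence(self) -> dict[str, HaplotypeRecord]:
        return {r.sequence: r for r in self.records}

    def code_of(self) -> dict[str, str]:
        """Map specimen ID -> haplotype code (requires codes assigned)."""
        out: dict[str, str] = {}
        for r in self.records:
            if r.code is None:
                raise ValueError("codes not assigned; call assign_codes first")
            for sid in r.member_ids:
                out[sid] = r.code
        return out


@dataclass
class CombinedHaplotype:
    """A specimen-level pairing of one ITS and one COI haplotype code."""

    its_code: str
    coi_code: str
    member_ids: list[str]
    counties: frozenset[Locality]

    @property
    def code(self) -> str:
        return self.its_code + self.coi_code

    @property
    def count(self) -> int:
        return len(self.member_ids)


def collapse_haplotypes(
    seqs: Iterable[tuple[str, str]], marker: str
) -> HaplotypeCatalog:
    """Partition (specimen_id, sequence) pairs into exact-identity classes.

    Records are ordered by first occurrence of each distinct sequence; codes
    are left unassigned (see :func:`assign_codes`).  Empty input yields an
    empty catalog.
    """
    catalog = HaplotypeCatalog(marker=marker)
    index: dict[str, HaplotypeRecord] = {}
    for sid, seq in seqs:
        s = normalize_sequence(seq)
        rec = index.get(s)
        if rec is None:
            rec = HaplotypeRecord(marker=marker, code=None, sequence=s, member_ids=[])
            index[s] = rec
            catalog.records.append(rec)
        rec.member_ids.append(sid)
    return catalog


def assign_codes(
    catalog: HaplotypeCatalog,
    prefix: str,
    reference: Optional[Mapping[str, str]] = None,
) -> HaplotypeCatalog:
    """Assign stable haplotype codes to a collapsed catalog.

    Sequences present in ``reference`` (sequence -> code) keep their reference
    code regardless of frequency rank.  Novel sequences receive fresh codes
    numbered after the reference maximum, in decreasing order of count; ties
    are broken by first occurrence in the input.  Returns a new catalog with
    records sorted by code number.
    """
    reference = dict(reference or {})
    ref_codes = list(reference.values())
    if len(set(ref_codes)) != len(ref_codes):
        raise ValueError("numbering reference maps two sequences to one code")
    next_number = max((code_number(c) for c in ref_codes), default=0) + 1

    coded: list[HaplotypeRecord] = []
    novel: list[tuple[int, HaplotypeRecord]] = []
    for i, rec in enumerate(catalog.records):
        if rec.sequence in reference:
            coded.append(replace(rec, code=reference[rec.sequence], member_ids=list(rec.member_ids)))
        else:
            novel.append((i, rec))
    novel.sort(key=lambda item: (-item[1].count, item[0]))
    for _, rec in novel:
        coded.append(replace(rec, code=format_code(prefix, next_number), member_ids=list(rec.member_ids)))
        next_number += 1

    codes = [r.code for r in coded]
    if len(set(codes)) != len(codes):
        raise ValueError("duplicate haplotype codes after assignment")
    coded.sort(key=lambda r: code_number(r.code))
    return HaplotypeCatalog(marker=catalog.marker, records=coded)


def frequency_reference(
    catalog: HaplotypeCatalog, prefix: str
) -> dict[str, str]:
    """Build a sequence -> code numbering reference from an assigned catalog."""
    return {r.sequence: r.code for r in catalog.records}


def combine(
    its_catalog: HaplotypeCatalog,
    coi_catalog: HaplotypeCatalog,
    specimens: Iterable[Specimen],
) -> list[CombinedHaplotype]:
    """Form one combined haplotype per observed (ITS code, COI code) pair.

    Every specimen must carry a code in both catalogs; a missing specimen is
    reported by ID.  Output is sorted by (ITS number, COI number).
    """
    its_of = its_catalog.code_of()
    coi_of = coi_catalog.code_of()
    groups: dict[tuple[str, str], list[Specimen]] = {}
    for sp in specimens:
        if sp.specimen_id not in its_of:
            raise KeyError(f"specimen {sp.specimen_id} missing from the ITS catalog")
        if sp.specimen_id not in coi_of:
            raise KeyError(f"specimen {sp.specimen_id} missing from the COI catalog")
        groups.setdefault((its_of[sp.specimen_id], coi_of[sp.specimen_id]), []).append(sp)
    out = [
        CombinedHaplotype(
            its_code=its_c,
            coi_code=coi_c,
            member_ids=[sp.specimen_id for sp in members],
            counties=frozenset(sp.locality for sp in members),
        )
        for (its_c, coi_c), members in groups.items()
    ]
    out.sort(key=lambda ch: (code_number(ch.its_code), code_number(ch.coi_code)))
    return out


def haplotype_spectrum(catalog: HaplotypeCatalog) -> dict[int, int]:
    """Frequency spectrum: how many haplotypes are seen 1, 2, ... times."""
    if not catalog.records:
        raise ValueError("empty catalog has no spectrum")
    return dict(sorted(Counter(r.count for r in catalog.records).items()))


def singleton_fraction(catalog: HaplotypeCatalog) -> float:
    """Fraction of haplotypes represented by a single individual."""
    spectrum = haplotype_spectrum(catalog)
    return spectrum.get(1, 0) / len(catalog)


class HaplotypeEncoder(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer from sequences to haplotype codes.

    ``fit`` collapses the training sequences into exact-identity classes and
    assigns codes (honouring an optional published numbering reference);
    ``transform`` maps sequences to their fitted codes.

    Parameters
    ----------
    marker:
        Marker name, ``"ITS"`` or ``"COI"`` (free-form for other markers).
    prefix:
        Code prefix; defaults to ``"F"`` for ITS and ``"H"`` for COI.
    reference:
        Optional numbering reference mapping sequence -> published code.
    """

    _PREFIXES = {"ITS": "F", "COI": "H"}

    def __init__(self, marker: str = "ITS", prefix: Optional[str] = None,
                 reference: Optional[Mapping[str, str]] = None):
        self.marker = marker
        self.prefix = prefix
        self.reference = reference

    def _resolved_prefix(self) -> str:
        if self.prefix is not None:
            return self.prefix
        try:
            return self._PREFIXES[self.marker]
        except KeyError:
            raise ValueError(
                f"no default code prefix for marker {self.marker!r}; pass prefix="
            ) from None

    @staticmethod
    def _as_pairs(X: Sequence) -> list[tuple[str, str]]:
        pairs = []
        for i, item in enumerate(X):
            if isinstance(item, str):
                pairs.append((f"seq{i}", item))
            else:
                sid, seq = item
                pairs.append((str(sid), seq))
        return pairs

    def fit(self, X: Sequence, y=None) -> "HaplotypeEncoder":
        """Collapse and code the training sequences.

        ``X`` is a sequence of nucleotide strings or (specimen_id, sequence)
        pairs.
        """
        pairs = self._as_pairs(X)
        raw = collapse_haplotypes(pairs, marker=self.marker)
        self.catalog_ = assign_codes(raw, self._resolved_prefix(), self.reference)
        self.n_haplotypes_ = len(self.catalog_)
        self._seq_to_code_ = {r.sequence: r.code for r in self.catalog_.records}
        return self

    def transform(self, X: Sequence) -> np.ndarray:
        """Map sequences to fitted haplotype codes; unseen sequences raise."""
        if not hasattr(self, "catalog_"):
            raise ValueError("HaplotypeEncoder is not fitted yet")
        codes = []
        for _, seq in self._as_pairs(X):
            s = normalize_sequence(seq)
            if s not in self._seq_to_code_:
                raise ValueError(f"sequence not present in the fitted catalog: {s[:30]}...")
            codes.append(self._seq_to_code_[s])
        return np.asarray(codes, dtype=object)
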