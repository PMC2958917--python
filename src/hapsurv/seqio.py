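"""Alignment input, region partitioning and haplotype collapsing.

An :class:`Alignment` holds an already-aligned set of sequences together
with a codon-aware coding mask (intervals with a reading-frame offset), an
optional noncoding (intron) mask and an optional outgroup designation.  All
coordinates are 0-based half-open internally; user-facing exports report
1-based inclusive positions.

Columns containing a gap or an ``N`` in any ingroup sequence are excluded
from every downstream site statistic (complete deletion).  Haplotype
identity is defined on those analyzed columns of the region under study,
so exon and intron haplotypes collapse independently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO

logger = logging.getLogger("hapsurv")

VALID_CHARS = frozenset("ACGTN-")
#: IUPAC ambiguity codes are demoted to N on input.
_AMBIGUOUS = frozenset("RYSWKMBDHVU")


class HapsurvError(Exception):
    """Base class for all package errors."""


class InputError(HapsurvError):
    """Malformed input records (duplicate ids, unparsable files)."""


class AlignmentError(HapsurvError):
    """Sequences do not form a valid alignment."""


class MaskError(HapsurvError):
    """Region mask out of bounds or frame-inconsistent."""


class RegionError(HapsurvError):
    """A requested region is empty."""


class EmptyInputError(HapsurvError):
    """An operation received no sequences."""


Interval = tuple[int, int, int]  # (start, end, frame)


@dataclass(frozen=True)
class Alignment:
    """Aligned sequences with coding/noncoding masks and an outgroup.

    ``coding_mask`` intervals are half-open ``(start, end, frame)`` where
    ``frame`` is the offset of the first complete codon within the
    interval; after trimming the frame offset the interval span must be a
    multiple of three.
    """

    ids: tuple[str, ...]
    seqs: tuple[str, ...]
    coding_mask: tuple[Interval, ...] = ()
    noncoding_mask: tuple[Interval, ...] = ()
    outgroup_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise AlignmentError("ids and seqs length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise InputError("duplicate sequence identifiers")
        if self.seqs:
            L = len(self.seqs[0])
            for sid, s in zip(self.ids, self.seqs):
                if len(s) != L:
                    raise AlignmentError(
                        f"sequence {sid!r} has length {len(s)}, expected {L}"
                    )
                bad = set(s) - VALID_CHARS
                if bad:
                    raise AlignmentError(
                        f"sequence {sid!r} contains invalid characters {sorted(bad)}"
                    )
        if self.outgroup_id is not None and self.outgroup_id not in self.ids:
            raise InputError(f"outgroup id {self.outgroup_id!r} not among sequence ids")
        for name, mask in (("coding", self.coding_mask), ("noncoding", self.noncoding_mask)):
            prev_end = -1
            for start, end, frame in sorted(mask):
                if not (0 <= start < end <= self.length):
                    raise MaskError(f"{name} interval ({start},{end}) out of range")
                if start < prev_end:
                    raise MaskError(f"{name} intervals overlap")
                if frame not in (0, 1, 2):
                    raise MaskError(f"invalid frame {frame}")
                if name == "coding" and (end - start - frame) % 3 != 0:
                    raise MaskError(
                        f"coding interval ({start},{end}) frame {frame} is not "
                        "codon-complete after frame trimming"
                    )
                prev_end = end

    # -- basic geometry ---------------------------------------------------

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    @property
    def ingroup_ids(self) -> tuple[str, ...]:
        return tuple(i for i in self.ids if i != self.outgroup_id)

    @property
    def ingroup_seqs(self) -> tuple[str, ...]:
        return tuple(s for i, s in zip(self.ids, self.seqs) if i != self.outgroup_id)

    @property
    def n(self) -> int:
        """Number of ingroup sequences."""
        return len(self.ingroup_ids)

    @property
    def outgroup_seq(self) -> str | None:
        if self.outgroup_id is None:
            return None
        return self.seqs[self.ids.index(self.outgroup_id)]

    # -- masks ------------------------------------------------------------

    def coding_columns(self) -> np.ndarray:
        """Columns covered by complete codons, in ascending order."""
        cols: list[int] = []
        for start, end, frame in sorted(self.coding_mask):
            cols.extend(range(start + frame, end))
        return np.asarray(cols, dtype=int)

    def noncoding_columns(self) -> np.ndarray:
        cols: list[int] = []
        for start, end, _ in sorted(self.noncoding_mask):
            cols.extend(range(start, end))
        return np.asarray(cols, dtype=int)

    def codon_map(self) -> dict[int, tuple[int, int, tuple[int, int, int]]]:
        """Map column -> (codon_index, position_in_codon, codon_columns)."""
        out: dict[int, tuple[int, int, tuple[int, int, int]]] = {}
        codon_index = 0
        for start, end, frame in sorted(self.coding_mask):
            for c0 in range(start + frame, end, 3):
                cols = (c0, c0 + 1, c0 + 2)
                for pos, c in enumerate(cols):
                    out[c] = (codon_index, pos, cols)
                codon_index += 1
        return out

    def analyzed_columns(self) -> np.ndarray:
        """Columns free of gaps and Ns in every ingroup sequence."""
        if not self.ingroup_seqs:
            raise EmptyInputError("alignment has no ingroup sequences")
        mat = np.frombuffer(
            "".join(self.ingroup_seqs).encode(), dtype="S1"
        ).reshape(self.n, self.length)
        clean = ~np.any((mat == b"-") | (mat == b"N"), axis=0)
        return np.nonzero(clean)[0]


def _clean_seq(raw: str, sid: str) -> str:
    s = raw.upper().replace(".", "-")
    if set(s) - VALID_CHARS:
        demoted = "".join("N" if c in _AMBIGUOUS else c for c in s)
        if set(demoted) - VALID_CHARS:
            raise AlignmentError(f"sequence {sid!r} contains invalid characters")
        logger.warning("sequence %s: ambiguity codes demoted to N", sid)
        s = demoted
    return s


def read_fasta(
    path,
    coding_spec: tuple[Interval, ...] | list[Interval] | None = None,
    outgroup_id: str | None = None,
    noncoding_spec: tuple[Interval, ...] | list[Interval] | None = None,
) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`.

    ``coding_spec``/``noncoding_spec`` are iterables of ``(start, end,
    frame)`` half-open 0-based intervals (frame ignored for noncoding,
    pass 0).
    """
    ids: list[str] = []
    seqs: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in ids:
            raise InputError(f"duplicate sequence id {rec.id!r}")
        ids.append(rec.id)
        seqs.append(_clean_seq(str(rec.seq), rec.id))
    if not ids:
        raise InputError(f"no FASTA records in {path}")
    return Alignment(
        ids=tuple(ids),
        seqs=tuple(seqs),
        coding_mask=tuple(tuple(iv) for iv in (coding_spec or ())),
        noncoding_mask=tuple(tuple(iv) for iv in (noncoding_spec or ())),
        outgroup_id=outgroup_id,
    )


def extract_region(aln: Alignment, which: str = "all") -> Alignment:
    """Slice an alignment to its coding or noncoding columns.

    The returned alignment's columns are exactly the requested intervals,
    in ascending order, with masks re-indexed.  ``which='all'`` returns an
    identity copy.
    """
    if which == "all":
        return replace(aln)
    if which == "coding":
        if not aln.coding_mask:
            raise RegionError("coding mask is empty")
        cols = aln.coding_columns()
        new_mask = ((0, len(cols), 0),)
        return Alignment(
            ids=aln.ids,
            seqs=tuple("".join(s[c] for c in cols) for s in aln.seqs),
            coding_mask=new_mask,
            noncoding_mask=(),
            outgroup_id=aln.outgroup_id,
        )
    if which == "noncoding":
        if not aln.noncoding_mask:
            raise RegionError("noncoding mask is empty")
        cols = aln.noncoding_columns()
        return Alignment(
            ids=aln.ids,
            seqs=tuple("".join(s[c] for c in cols) for s in aln.seqs),
            coding_mask=(),
            noncoding_mask=((0, len(cols), 0),),
            outgroup_id=aln.outgroup_id,
        )
    raise ValueError(f"unknown region {which!r}")


@dataclass(frozen=True)
class HaplotypeTable:
    """Distinct ingroup haplotypes on the analyzed columns of a region.

    ``haplotypes`` are the distinct sequences restricted to
    ``site_index`` (analyzed columns, original coordinates), ordered by
    descending count then lexicographic sequence so every downstream
    structure is byte-for-byte reproducible.
    """

    haplotypes: tuple[str, ...]
    counts: tuple[int, ...]
    members: tuple[tuple[str, ...], ...]
    n: int
    h: int
    site_index: tuple[int, ...]
    source: Alignment | None = field(default=None, compare=False, repr=False)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(f"H{i + 1}" for i in range(self.h))

    @property
    def outgroup_restricted(self) -> str | None:
        """Outgroup sequence restricted to the analyzed columns."""
        if self.source is None or self.source.outgroup_seq is None:
            return None
        og = self.source.outgroup_seq
        return "".join(og[c] for c in self.site_index)


def collapse_haplotypes(aln: Alignment) -> HaplotypeTable:
    """Group identical ingroup sequences (on analyzed columns) into haplotypes."""
    if aln.n == 0:
        raise EmptyInputError("no ingroup sequences to collapse")
    cols = aln.analyzed_columns()
    groups: dict[str, list[str]] = {}
    for sid, seq in zip(aln.ingroup_ids, aln.ingroup_seqs):
        key = "".join(seq[c] for c in cols)
        groups.setdefault(key, []).append(sid)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    return HaplotypeTable(
        haplotypes=tuple(k for k, _ in ordered),
        counts=tuple(len(v) for _, v in ordered),
        members=tuple(tuple(v) for _, v in ordered),
        n=aln.n,
        h=len(ordered),
        site_index=tuple(int(c) for c in cols),
        source=aln,
    )


def write_haplotype_table(ht: HaplotypeTable, path) -> None:
    """Export a haplotype table as TSV (id, count, member ids, sequence)."""
    with open(path, "w") as fh:
        fh.write("haplotype_id\tcount\tmember_ids\tsequence\n")
        for hid, cnt, mem, seq in zip(ht.ids, ht.counts, ht.members, ht.haplotypes):
            fh.write(f"{hid}\t{cnt}\t{','.join(mem)}\t{seq}\n")
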