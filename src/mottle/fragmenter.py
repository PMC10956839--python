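"""Flank-fragment generation and origin-pair bookkeeping.

Every nucleotide of an input sequence is treated as an *origin*: the
fixed-length subsequence immediately 3' of it is the forward flank fragment,
and the reverse complement of the subsequence immediately 5' of it is the
reverse flank fragment.  The origin base itself is excluded from both
fragments, so that its match state across a mapping is an identity signal
free of alignment bias.

Coordinates are 0-based with half-open intervals throughout; SAM I/O converts
from 1-based at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import reverse_complement

ACGT = frozenset("ACGT")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: uint8 lookup: True for unambiguous bases (ASCII codes of A, C, G, T)
IS_ACGT = np.zeros(256, dtype=bool)
for _b in b"ACGT":
    IS_ACGT[_b] = True

GAP = ord("-")


def complement_base(base: str) -> str:
    """Complement of a single base; ambiguity codes pass through unchanged."""
    return _COMPLEMENT.get(base, base)


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence over {A,C,G,T} (+ IUPAC ambiguity codes).

    ``seq`` is upper-case with U normalised to T, so RNA and DNA inputs are
    treated identically.
    """

    id: str
    seq: str

    @classmethod
    def from_raw(cls, id: str, seq: str) -> "SequenceRecord":
        seq = seq.upper().replace("U", "T")
        if len(seq) < 1:
            raise ValueError(f"sequence {id!r} is empty")
        return cls(id=id, seq=seq)

    @property
    def length(self) -> int:
        return len(self.seq)


def read_fasta(path) -> list[SequenceRecord]:
    """Read a (possibly multi-record, wrapped, mixed-case) FASTA file."""
    records = [
        SequenceRecord.from_raw(rec.id, str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


@dataclass(frozen=True)
class FlankFragment:
    """A flank fragment anchored to (and excluding) its origin nucleotide.

    ``bases`` always reads away from the origin: for a forward fragment this
    is the genomic forward strand ``[origin_pos+1, origin_pos+1+flank_size)``;
    for a reverse fragment it is the reverse complement of
    ``[origin_pos-flank_size, origin_pos)``.
    """

    record_id: str
    origin_pos: int
    orientation: str  # "forward" | "reverse"
    flank_size: int
    bases: str
    origin_base: str  # genomic (forward-strand) base at origin_pos

    @property
    def key(self) -> tuple:
        return (self.record_id, self.origin_pos, self.orientation)

    @property
    def region(self) -> tuple[int, int]:
        """Half-open genomic interval covered by the fragment."""
        if self.orientation == "forward":
            return (self.origin_pos + 1, self.origin_pos + 1 + self.flank_size)
        return (self.origin_pos - self.flank_size, self.origin_pos)

    @property
    def stored_origin_base(self) -> str:
        """Origin base read in the same strand frame as ``bases``."""
        if self.orientation == "forward":
            return self.origin_base
        return complement_base(self.origin_base)


def generate_fragments(record: SequenceRecord, flank_size: int) -> list[FlankFragment]:
    """All flank fragments of ``record`` at the given flank size.

    Every origin with room for a full flank yields exactly one fragment per
    feasible orientation: ``L - n`` forward plus ``L - n`` reverse fragments
    for a length-``L`` sequence.
    """
    if flank_size < 1:
        raise ValueError("flank_size must be >= 1")
    L = record.length
    if flank_size >= L:
        raise ValueError(
            f"sequence {record.id!r} (length {L}) is shorter than "
            f"flank size {flank_size}: cannot generate fragments"
        )
    seq = record.seq
    frags: list[FlankFragment] = []
    for p in range(0, L - flank_size):
        frags.append(
            FlankFragment(
                record_id=record.id,
                origin_pos=p,
                orientation="forward",
                flank_size=flank_size,
                bases=seq[p + 1 : p + 1 + flank_size],
                origin_base=seq[p],
            )
        )
    for p in range(flank_size, L):
        frags.append(
            FlankFragment(
                record_id=record.id,
                origin_pos=p,
                orientation="reverse",
                flank_size=flank_size,
                bases=reverse_complement(seq[p - flank_size : p]),
                origin_base=seq[p],
            )
        )
    return frags


def generate_fragments_pooled(
    records: Sequence[SequenceRecord], flank_size: int
) -> list[FlankFragment]:
    """One pooled fragment set for a multi-record input file.

    Records are fragmented independently (no concatenation is invented for
    segmented genomes); origin coordinates carry the record id.
    """
    pooled: list[FlankFragment] = []
    for rec in records:
        pooled.extend(generate_fragments(rec, flank_size))
    return pooled


def fragment_id(frag: FlankFragment) -> str:
    tag = "F" if frag.orientation == "forward" else "R"
    return f"{frag.record_id}|{frag.origin_pos}|{tag}"


def parse_fragment_id(name: str) -> tuple[str, int, str]:
    """Invert :func:`fragment_id`; record ids may themselves contain '|'."""
    try:
        record_id, pos, tag = name.rsplit("|", 2)
        orientation = {"F": "forward", "R": "reverse"}[tag]
        return record_id, int(pos), orientation
    except (ValueError, KeyError) as exc:
        raise ValueError(f"not a fragment id: {name!r}") from exc


def write_fragments_fasta(fragments: Iterable[FlankFragment], path) -> None:
    """Export fragments so external short-read mappers can consume them."""
    with open(path, "w") as fh:
        for frag in fragments:
            fh.write(f">{fragment_id(frag)}\n{frag.bases}\n")


def fragments_to_matrix(fragments: Sequence[FlankFragment]) -> np.ndarray:
    """Stack fragment bases into a (n_fragments, flank_size) uint8 matrix."""
    if not fragments:
        raise ValueError("no fragments")
    n = fragments[0].flank_size
    buf = "".join(f.bases for f in fragments).encode("ascii")
    return np.frombuffer(buf, dtype=np.uint8).reshape(len(fragments), n)


def pair_origins(mapping, query: SequenceRecord, target: SequenceRecord) -> str:
    """Match state of the origin pair implied by a genomic region mapping.

    The mapped region starts where the fragment's first base landed, so the
    target base homologous to the origin sits just outside the region on the
    origin side: position ``start - 1`` for a forward-strand mapping, or the
    complement of position ``end`` for a reverse-strand one.  Returns
    ``"match"``, ``"mismatch"``, or ``"undefined"`` when the implied position
    falls outside the target (such mappings are discarded upstream) or either
    base is ambiguous.
    """
    frag = mapping.query_fragment
    q_base = frag.stored_origin_base
    if mapping.strand == "forward":
        pos = mapping.target_start - 1
        if pos < 0:
            return "undefined"
        t_base = target.seq[pos]
    else:
        pos = mapping.target_end
        if pos >= target.length:
            return "undefined"
        t_base = complement_base(target.seq[pos])
    if q_base not in ACGT or t_base not in ACGT:
        return "undefined"
    return "match" if q_base == t_base else "mismatch"
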