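"""Global alignment of mapped region pairs and per-window statistics.

Mapped fragment pairs are re-aligned with Needleman-Wunsch global alignment
regardless of which mapper produced them, so downstream statistics are
mapper-independent.  Alignments whose origin-adjacent end contains gaps are
discarded (the gap may have shifted the homologous frame of the origin), the
remainder are truncated at the first sliding window whose identity is
incompatible with the first window's (two-tailed binomial test), and the
surviving columns are tiled into fixed-size windows from which identity and
indel statistics are taken.

The indel statistic models runs of indel events between adjacent homologous
sites as geometric: P(L = l) = p^l * (1 - p), where p is the per-site indel
event fraction.  q = 1 - p is estimated as the fraction of adjacent aligned
(non-gap) base pairs with no intervening gap columns.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from typing import Optional

import numpy as np
from Bio import Align
from scipy.stats import binom

from .fragmenter import (
    GAP,
    IS_ACGT,
    FlankFragment,
    SequenceRecord,
    complement_base,
    parse_fragment_id,
    reverse_complement,
)

# chance identity of GC-corrected nucleic-acid sequences
CHANCE_IDENTITY = 0.25


@dataclass(frozen=True)
class AlignParams:
    """Alignment scoring and window-filtering parameters.

    Gap scoring follows the open-includes-first-base convention: a gap of
    length k scores ``gap_open + (k - 1) * gap_extend``.
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0
    leading_gap_n: int = 5
    window: int = 50
    binthres: float = 0.75  # central acceptance mass of the two-tailed test
    min_clipped: int = 100

    def __post_init__(self):
        if self.window < 10:
            raise ValueError("window must be >= 10 columns")
        if self.min_clipped < self.window:
            raise ValueError("min_clipped must be >= window")
        if not 0.0 < self.binthres < 1.0:
            raise ValueError("binthres must lie in (0, 1)")


@dataclass
class RegionMapping:
    """A mapped fragment pair (or fragment-to-genome hit from external SAM).

    ``query_bases`` / ``target_bases`` are the two region sequences in the
    frame in which they aligned (the target already reverse-complemented for
    reverse-strand hits), so the origin-adjacent end is always column 0.
    """

    query_fragment: FlankFragment
    query_bases: str
    target_bases: str
    strand: str  # "forward" | "reverse" relative strand of the hit
    origin_state: str  # "match" | "mismatch" | "undefined"
    source: str  # "mottle-map" | "external-sam"
    target_fragment: Optional[FlankFragment] = None
    target_record_id: Optional[str] = None
    target_start: Optional[int] = None
    target_end: Optional[int] = None
    embed_distance: float = 0.0

    @property
    def canonical_key(self) -> tuple:
        """Direction-independent identity of the mapping (for dedup/sorting)."""
        if self.target_fragment is not None:
            a, b = sorted([self.query_fragment.key, self.target_fragment.key])
            return ("pair", a, b)
        return (
            "sam",
            self.query_fragment.key,
            (self.target_record_id, self.target_start, self.target_end, self.strand),
        )

    def alignable_pair(self) -> tuple[str, str]:
        """Region sequences in canonical order (symmetric in input order)."""
        if (
            self.target_fragment is not None
            and self.target_fragment.key < self.query_fragment.key
        ):
            return self.target_bases, self.query_bases
        return self.query_bases, self.target_bases


@dataclass
class PairwiseAlignment:
    """A gapped global alignment stored as two equal-length byte rows."""

    query_row: np.ndarray  # uint8, gap = ord('-')
    target_row: np.ndarray
    score: float
    origin_state: str = "undefined"

    def __len__(self) -> int:
        return len(self.query_row)

    @property
    def columns(self) -> list[tuple[str, str]]:
        q = self.query_row.tobytes().decode("ascii")
        t = self.target_row.tobytes().decode("ascii")
        return list(zip(q, t))

    @property
    def query_text(self) -> str:
        return self.query_row.tobytes().decode("ascii")

    @property
    def target_text(self) -> str:
        return self.target_row.tobytes().decode("ascii")


@dataclass(frozen=True)
class WindowStats:
    """Identity/indel statistics of one fixed-size alignment window."""

    identity_raw: float
    identity_gc: float
    indel_frac: float
    chance_match: float  # composition-derived chance match rate e
    n_cols: int


@functools.lru_cache(maxsize=8)
def _aligner(match, mismatch, gap_open, gap_extend) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = match
    al.mismatch_score = mismatch
    al.open_gap_score = gap_open
    al.extend_gap_score = gap_extend
    return al


def needleman_wunsch(a: str, b: str, params: AlignParams) -> PairwiseAlignment:
    """Optimal-score global alignment of two region sequences.

    Deterministic: of the co-optimal alignments the first one enumerated by
    the aligner is always returned.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    al = _aligner(params.match, params.mismatch, params.gap_open, params.gap_extend)
    aln = al.align(a, b)[0]
    q = np.frombuffer(str(aln[0]).encode("ascii"), dtype=np.uint8)
    t = np.frombuffer(str(aln[1]).encode("ascii"), dtype=np.uint8)
    return PairwiseAlignment(query_row=q, target_row=t, score=float(aln.score))


def filter_leading_gaps(aln: PairwiseAlignment, params: AlignParams) -> bool:
    """Keep the alignment unless its first ``leading_gap_n`` columns contain a gap.

    Column 0 is the origin-adjacent end; a gap there may shift the homologous
    frame of the origin nucleotide.
    """
    n = min(params.leading_gap_n, len(aln))
    head_q = aln.query_row[:n]
    head_t = aln.target_row[:n]
    return not bool(np.any(head_q == GAP) or np.any(head_t == GAP))


@functools.lru_cache(maxsize=4096)
def binomial_acceptance_region(
    n: int, p: float, central_mass: float
) -> tuple[int, int]:
    """[lo, hi] match counts inside the central ``central_mass`` of Binomial(n, p).

    A window whose match count falls outside this region rejects the
    two-tailed test at significance 1 - central_mass.
    """
    if n <= 0:
        return (0, 0)
    alpha = 1.0 - central_mass
    lo = int(binom.ppf(alpha / 2.0, n, p))
    hi = int(binom.ppf(1.0 - alpha / 2.0, n, p))
    return lo, hi


def _column_masks(aln: PairwiseAlignment):
    q, t = aln.query_row, aln.target_row
    valid = IS_ACGT[q] & IS_ACGT[t]  # both unambiguous bases (excludes gaps)
    match = valid & (q == t)
    return valid, match


def truncate_on_identity_change(
    aln: PairwiseAlignment, params: AlignParams
) -> Optional[PairwiseAlignment]:
    """Clip the alignment at the first window incompatible with the first one.

    The first window's match fraction (Laplace-clamped away from 0 and 1)
    parameterises a binomial null; a sliding window (step 1) is then moved
    through the alignment and the first window whose match count falls in the
    two-tailed rejection region triggers clipping at that window's start.
    Results shorter than ``min_clipped`` are discarded (None).
    """
    w = params.window
    L = len(aln)
    if L < w:
        return None
    valid, match = _column_masks(aln)
    cv = np.concatenate(([0], np.cumsum(valid)))
    cm = np.concatenate(([0], np.cumsum(match)))
    n0 = int(cv[w])
    m0 = int(cm[w])
    p0 = (m0 / n0) if n0 > 0 else 0.5
    lo_clamp = 1.0 / (w + 2)
    p0 = min(max(p0, lo_clamp), 1.0 - lo_clamp)

    starts = np.arange(1, L - w + 1)
    keep = L
    if starts.size:
        ns = cv[starts + w] - cv[starts]
        ms = cm[starts + w] - cm[starts]
        # acceptance bounds depend only on the window's non-gap count
        bounds = np.array(
            [binomial_acceptance_region(int(n), round(p0, 12), params.binthres)
             for n in range(w + 1)],
            dtype=np.int64,
        )
        reject = (ms < bounds[ns, 0]) | (ms > bounds[ns, 1])
        hits = np.nonzero(reject)[0]
        if hits.size:
            keep = int(starts[hits[0]])
    if keep < params.min_clipped:
        return None
    if keep == L:
        return aln
    return PairwiseAlignment(
        query_row=aln.query_row[:keep],
        target_row=aln.target_row[:keep],
        score=aln.score,
        origin_state=aln.origin_state,
    )


def gc_corrected_identity(identity_raw: float, chance: float) -> float:
    """Renormalise raw identity so composition-driven chance maps to 0.25."""
    if 1.0 - chance < 1e-9:
        return CHANCE_IDENTITY
    excess = max(0.0, (identity_raw - chance) / (1.0 - chance))
    return CHANCE_IDENTITY + (1.0 - CHANCE_IDENTITY) * min(excess, 1.0)


def _window_stats_arrays(q: np.ndarray, t: np.ndarray) -> WindowStats:
    """Statistics of a single window given its two byte rows."""
    valid = IS_ACGT[q] & IS_ACGT[t]
    match = valid & (q == t)
    nv = int(valid.sum())
    identity_raw = float(match.sum()) / nv if nv else 0.0

    # chance match rate from the window's pooled per-side base composition
    chance = CHANCE_IDENTITY
    fq = np.array([(q == b).sum() for b in b"ACGT"], dtype=float)
    ft = np.array([(t == b).sum() for b in b"ACGT"], dtype=float)
    if fq.sum() > 0 and ft.sum() > 0:
        chance = float(np.dot(fq / fq.sum(), ft / ft.sum()))

    identity_gc = gc_corrected_identity(identity_raw, chance)
    indel_frac = indel_fraction(q, t)
    return WindowStats(
        identity_raw=identity_raw,
        identity_gc=identity_gc,
        indel_frac=indel_frac,
        chance_match=chance,
        n_cols=len(q),
    )


def indel_fraction(q: np.ndarray, t: np.ndarray) -> float:
    """p = 1 - q with q the fraction of adjacent aligned base pairs without
    intervening gap columns.  Ambiguous columns count as gaps here."""
    nongap = IS_ACGT[q] & IS_ACGT[t]
    m = int(nongap.sum())
    if m <= 1:
        return 0.0
    unbroken = int((nongap[:-1] & nongap[1:]).sum())
    return 1.0 - unbroken / (m - 1)


def geometric_indel_pmf(l: int, p: float) -> float:
    """P(L = l) = p^l * (1 - p): probability of l adjacent indel events
    between two neighbouring homologous sites."""
    if l < 0:
        return 0.0
    return (p**l) * (1.0 - p)


def window_statistics(aln: PairwiseAlignment, params: AlignParams) -> list[WindowStats]:
    """Per-window statistics over contiguous non-overlapping windows.

    The trailing partial window is dropped.
    """
    w = params.window
    k = len(aln) // w
    out = []
    for i in range(k):
        sl = slice(i * w, (i + 1) * w)
        out.append(_window_stats_arrays(aln.query_row[sl], aln.target_row[sl]))
    return out


def mappings_from_sam(
    sam_path,
    fragments_by_id: dict[str, FlankFragment],
    target_records: dict[str, SequenceRecord],
    flank_size: int,
) -> list[RegionMapping]:
    """Region mappings from an external mapper's SAM output.

    CIGAR strings are only used for the reference span; the regions are
    re-aligned by Needleman-Wunsch downstream, so the mapping stage is
    mapper-independent.  Unmapped records are dropped; secondary and
    supplementary records are kept (all mapping is kept).
    """
    import pysam

    from .fragmenter import pair_origins

    mappings: list[RegionMapping] = []
    unknown: list[str] = []
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as fh:
        for read in fh:
            if read.is_unmapped:
                continue
            frag = fragments_by_id.get(read.query_name)
            if frag is None:
                unknown.append(read.query_name)
                continue
            rname = read.reference_name
            target = target_records.get(rname)
            if target is None:
                unknown.append(f"{read.query_name} -> unknown reference {rname}")
                continue
            start = read.reference_start
            end = read.reference_end
            if end is None:
                end = start + flank_size
            end = min(end, target.length)
            if end <= start:
                continue
            strand = "reverse" if read.is_reverse else "forward"
            region = target.seq[start:end]
            if strand == "reverse":
                region = reverse_complement(region)
            m = RegionMapping(
                query_fragment=frag,
                query_bases=frag.bases,
                target_bases=region,
                strand=strand,
                origin_state="undefined",
                source="external-sam",
                target_record_id=rname,
                target_start=start,
                target_end=end,
            )
            m.origin_state = pair_origins(m, None, target)
            mappings.append(m)
    if unknown:
        shown = ", ".join(unknown[:10])
        raise ValueError(
            f"{len(unknown)} SAM record(s) do not match exported fragments: {shown}"
        )
    return mappings


def write_sam(mappings, target_records, path) -> None:
    """Export mappings as minimal SAM (QNAME=fragment id, 1-based POS)."""
    from .fragmenter import fragment_id

    names = list(target_records)
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for name in names:
            fh.write(f"@SQ\tSN:{name}\tLN:{target_records[name].length}\n")
        for m in mappings:
            if m.target_fragment is not None:
                rname = m.target_fragment.record_id
                start, _ = m.target_fragment.region
            else:
                rname = m.target_record_id
                start = m.target_start
            flag = 16 if m.strand == "reverse" else 0
            seq = m.query_bases
            fh.write(
                f"{fragment_id(m.query_fragment)}\t{flag}\t{rname}\t{start + 1}\t"
                f"255\t{len(seq)}M\t*\t0\t0\t{seq}\t*\n"
            )
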