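"""Mottle-map: a bespoke fragment mapper that maps every fragment.

Each flank fragment is embedded on the complex plane (G -> +1, C -> -1,
A -> +i, T/U -> -i, ambiguity codes -> 0), the real and imaginary axes are
divided by the mean of their absolute values to correct for GC content, the
embedding is moved to frequency space with an (unnormalised forward) FFT and
scaled to unit L2 norm.  Euclidean distance between frequency embeddings is
then a fragment dissimilarity that tolerates small indel-driven frame shifts,
and an exact many-to-many nearest-neighbour search returns the top N hits for
every fragment — so every fragment is mapped, even at extreme divergence.

Designed for small, highly divergent sequences: the search is brute force by
default (exact, deterministic), with no genome-scale indexing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .align import RegionMapping
from .fragmenter import FlankFragment, fragments_to_matrix

#: complex-plane base embedding (MAFFT convention); index by ASCII code
BASE_EMBEDDING = np.zeros(256, dtype=np.complex128)
BASE_EMBEDDING[ord("G")] = 1.0
BASE_EMBEDDING[ord("C")] = -1.0
BASE_EMBEDDING[ord("A")] = 1.0j
BASE_EMBEDDING[ord("T")] = -1.0j


@dataclass(frozen=True)
class MapParams:
    """Mottle-map parameters: neighbours per fragment and the GC-correction
    floor used when an axis has no signal (all-purine/all-pyrimidine)."""

    top_n: int = 2
    eps_axis: float = 1e-12
    block_rows: int = 1024  # rows per distance-matrix block (memory bound)

    def __post_init__(self):
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")


@dataclass
class FragmentEmbedding:
    """Unit-norm frequency-space embedding of one fragment."""

    fragment_ref: FlankFragment
    values: np.ndarray  # complex, length == flank_size


def embed_matrix(codes: np.ndarray, params: MapParams) -> np.ndarray:
    """Embed a (n, L) uint8 base matrix into unit-norm frequency space."""
    E = BASE_EMBEDDING[codes]
    re = E.real
    im = E.imag
    mre = np.maximum(np.abs(re).mean(axis=1, keepdims=True), params.eps_axis)
    mim = np.maximum(np.abs(im).mean(axis=1, keepdims=True), params.eps_axis)
    F = np.fft.fft(re / mre + 1j * (im / mim), axis=1)
    norms = np.linalg.norm(F, axis=1, keepdims=True)
    if np.any(norms == 0.0):
        bad = np.nonzero(norms[:, 0] == 0.0)[0]
        raise ValueError(
            f"fragment(s) {bad.tolist()} contain no embeddable (A/C/G/T) content"
        )
    return F / norms


def embed_fragment(fragment: FlankFragment, params: MapParams | None = None) -> FragmentEmbedding:
    """Embed a single fragment; errors on all-ambiguous content."""
    params = params or MapParams()
    if not fragment.bases:
        raise ValueError("fragment has no bases")
    codes = np.frombuffer(fragment.bases.encode("ascii"), dtype=np.uint8)[None, :]
    return FragmentEmbedding(fragment_ref=fragment, values=embed_matrix(codes, params)[0])


def embed_fragments(
    fragments: Sequence[FlankFragment], params: MapParams
) -> np.ndarray:
    """Embeddings for a fragment set as an (n, flank_size) complex matrix."""
    return embed_matrix(fragments_to_matrix(fragments), params)


def _real_stack(F: np.ndarray) -> np.ndarray:
    """Stack Re/Im so real dot products give Re<a, conj(b)>."""
    return np.ascontiguousarray(
        np.hstack([F.real, F.imag]).astype(np.float32)
    )


def top_neighbours(
    query_emb: np.ndarray,
    ref_emb: np.ndarray,
    params: MapParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact top-N nearest references per query in frequency space.

    Returns (indices, distances) of shape (n_queries, k) with
    k = min(top_n, n_refs), rows ordered by ascending Euclidean distance,
    ties broken by ascending reference index (callers pass references sorted
    by origin coordinate, making the tie-break the spec'd one).
    """
    if query_emb.shape[1] != ref_emb.shape[1]:
        raise ValueError(
            f"embedding length mismatch: {query_emb.shape[1]} != {ref_emb.shape[1]}"
        )
    nq, nr = len(query_emb), len(ref_emb)
    k = min(params.top_n, nr)
    Q = _real_stack(query_emb)
    R = _real_stack(ref_emb)
    idx_out = np.empty((nq, k), dtype=np.int64)
    d_out = np.empty((nq, k), dtype=np.float64)
    for lo in range(0, nq, params.block_rows):
        hi = min(lo + params.block_rows, nq)
        sim = Q[lo:hi] @ R.T
        # unit vectors: squared distance = 2 - 2*Re<a, conj(b)>
        d2 = np.maximum(2.0 - 2.0 * sim.astype(np.float64), 0.0)
        if k < nr:
            part = np.argpartition(d2, k - 1, axis=1)[:, :k]
        else:
            part = np.broadcast_to(np.arange(nr), (hi - lo, nr)).copy()
        rows = np.arange(hi - lo)[:, None]
        dpart = d2[rows, part]
        # order by (distance, reference index) for deterministic ties
        order = np.lexsort((part, dpart), axis=1)[:, :k]
        idx_out[lo:hi] = np.take_along_axis(part, order, axis=1)
        d_out[lo:hi] = np.take_along_axis(dpart, order, axis=1)
    return idx_out, np.sqrt(d_out)


def _sorted_by_key(fragments: Sequence[FlankFragment]) -> list[FlankFragment]:
    return sorted(fragments, key=lambda f: f.key)


def mapping_from_fragment_pair(
    qfrag: FlankFragment, tfrag: FlankFragment, distance: float
) -> RegionMapping:
    """Build the region mapping implied by a fragment-to-fragment hit.

    The stored query bases align to the target region forward strand exactly
    when the target fragment is a forward flank, so the SAM-sense strand of
    the hit is the target fragment's orientation.  Both stored sequences read
    away from their origins, so origin match state is equality of the two
    stored-frame origin bases (ambiguity -> undefined).
    """
    sq = qfrag.stored_origin_base
    st = tfrag.stored_origin_base
    if sq not in "ACGT" or st not in "ACGT":
        state = "undefined"
    else:
        state = "match" if sq == st else "mismatch"
    start, end = tfrag.region
    return RegionMapping(
        query_fragment=qfrag,
        query_bases=qfrag.bases,
        target_bases=tfrag.bases,
        strand="forward" if tfrag.orientation == "forward" else "reverse",
        origin_state=state,
        source="mottle-map",
        target_fragment=tfrag,
        target_record_id=tfrag.record_id,
        target_start=start,
        target_end=end,
        embed_distance=float(distance),
    )


def nearest_neighbours(
    queries: Sequence[FlankFragment],
    refs: Sequence[FlankFragment],
    params: MapParams,
    query_emb: Optional[np.ndarray] = None,
    ref_emb: Optional[np.ndarray] = None,
    reciprocal: bool = False,
) -> list[RegionMapping]:
    """Top-N mappings for every query fragment (many-to-many, exact).

    With ``reciprocal=True`` the reverse direction (top-N per reference
    fragment) is computed from the same distance matrix and pooled, with
    query/target sides kept fixed so duplicated pairs deduplicate upstream.
    """
    if not queries or not refs:
        raise ValueError("both fragment sets must be non-empty")
    queries = _sorted_by_key(queries)
    refs = _sorted_by_key(refs)
    q_emb = embed_fragments(queries, params) if query_emb is None else query_emb
    r_emb = embed_fragments(refs, params) if ref_emb is None else ref_emb

    idx, dist = top_neighbours(q_emb, r_emb, params)
    mappings = [
        mapping_from_fragment_pair(queries[i], refs[j], dist[i, c])
        for i in range(len(queries))
        for c, j in enumerate(idx[i])
    ]
    if reciprocal:
        ridx, rdist = top_neighbours(r_emb, q_emb, params)
        mappings.extend(
            mapping_from_fragment_pair(queries[j], refs[i], rdist[i, c])
            for i in range(len(refs))
            for c, j in enumerate(ridx[i])
        )
    return mappings
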