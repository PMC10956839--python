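"""End-to-end distance estimation: configuration, mapper backends, pipeline.

``estimate_distance`` runs fragmentation -> mapping (Mottle-map or external
SAM) -> global alignment + filtering -> windowed statistics -> monotone GBDT
true identity -> two-centre clustering -> Jukes-Cantor conversion.

The two mapping directions (A fragments onto B and B fragments onto A) are
pooled, and every mapping is reduced to a direction-independent canonical
form before alignment, so estimate_distance(A, B) == estimate_distance(B, A)
by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from . import align as _align
from . import cluster as _cluster
from . import mottle_map as _mmap
from .align import AlignParams, RegionMapping, WindowStats
from .cluster import (
    AlignmentStats,
    ClusterConfig,
    DistanceResult,
    GBDTConfig,
    distance_from_stats,
    fit_true_identity_model,
    stabilise,
)
from .fragmenter import (
    FlankFragment,
    SequenceRecord,
    fragment_id,
    generate_fragments_pooled,
    read_fasta,
)
from .mottle_map import MapParams

logger = logging.getLogger("mottle")


@dataclass
class MottleConfig:
    """Every tunable parameter of the pipeline, by its published name where
    one exists, with the published defaults."""

    # fragmentation / mapping
    flank_size: int = 100
    top_n: int = 2
    mapper_backend: str = "mottle-map"  # "mottle-map" | "sam:FILE[,FILE2]"
    # alignment processing
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0
    leading_gap_n: int = 5
    window: int = 50
    binthres: float = 0.75
    min_clipped: int = 100
    # GBDT
    ntrees: int = 100
    nleaves: int = 32
    learn_rate: float = 0.1
    subsamp: float = 1.0
    prior_size: int = 10
    # clustering
    binpow: float = 64.0
    eps: float = float(np.finfo(float).eps)
    learn_mult: float = 0.001
    reltol: float = 1e-20
    maxiter: int = 100
    # reproducibility
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.flank_size < 1:
            raise ValueError("flank_size must be >= 1")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if self.ntrees < 1 or self.nleaves < 2:
            raise ValueError("ntrees must be >= 1 and nleaves >= 2")
        if not 0.0 < self.subsamp <= 1.0:
            raise ValueError("subsamp must lie in (0, 1]")
        # AlignParams enforces the window/min_clipped/binthres invariants
        self.align_params()

    def align_params(self) -> AlignParams:
        return AlignParams(
            match=self.match, mismatch=self.mismatch,
            gap_open=self.gap_open, gap_extend=self.gap_extend,
            leading_gap_n=self.leading_gap_n, window=self.window,
            binthres=self.binthres, min_clipped=self.min_clipped,
        )

    def map_params(self) -> MapParams:
        return MapParams(top_n=self.top_n)

    def gbdt_config(self) -> GBDTConfig:
        return GBDTConfig(
            ntrees=self.ntrees, nleaves=self.nleaves,
            learn_rate=self.learn_rate, subsamp=self.subsamp,
            prior_size=self.prior_size, seed=self.seed,
        )

    def cluster_config(self) -> ClusterConfig:
        return ClusterConfig(
            binpow=self.binpow, eps=self.eps, learn_mult=self.learn_mult,
            reltol=self.reltol, maxiter=self.maxiter,
        )

    @classmethod
    def from_file(cls, path) -> "MottleConfig":
        """Read a key=value config file mirroring the parameter names."""
        kwargs = {}
        types = {f.name: f.type for f in fields(cls)}
        casts = {"int": int, "float": float, "str": str}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key=value")
                key, value = (s.strip() for s in line.split("=", 1))
                if key not in types:
                    raise ValueError(f"{path}:{lineno}: unknown parameter {key!r}")
                kwargs[key] = casts[types[key]](value)
        return cls(**kwargs)


def _as_records(source) -> list[SequenceRecord]:
    if isinstance(source, SequenceRecord):
        return [source]
    if isinstance(source, (list, tuple)) and all(
        isinstance(r, SequenceRecord) for r in source
    ):
        return list(source)
    return read_fasta(source)


def map_with_backend(
    query_fragments: Sequence[FlankFragment],
    target_fragments: Sequence[FlankFragment],
    target_records: Sequence[SequenceRecord],
    config: MottleConfig,
    reciprocal: bool = True,
) -> list[RegionMapping]:
    """Uniform RegionMapping stream from the configured mapper backend.

    ``mottle-map`` searches fragments against fragments in both directions.
    ``sam:FILE[,FILE2]`` reads mappings produced by an external mapper run on
    the exported fragment FASTA (optionally one file per direction).
    """
    backend = config.mapper_backend
    if backend == "mottle-map":
        return _mmap.nearest_neighbours(
            query_fragments, target_fragments, config.map_params(),
            reciprocal=reciprocal,
        )
    if backend.startswith("sam:"):
        paths = [p for p in backend[4:].split(",") if p]
        if not paths:
            raise ValueError("sam backend requires at least one SAM path")
        frag_index = {fragment_id(f): f for f in query_fragments}
        frag_index.update({fragment_id(f): f for f in target_fragments})
        rec_index = {r.id: r for r in target_records}
        mappings: list[RegionMapping] = []
        for path in paths:
            mappings.extend(
                _align.mappings_from_sam(
                    path, frag_index, rec_index, config.flank_size
                )
            )
        return mappings
    raise ValueError(f"unknown mapper backend {backend!r}")


def _dedup_sorted(mappings: Sequence[RegionMapping]) -> list[RegionMapping]:
    """Collapse duplicated reciprocal hits and order canonically."""
    best: dict[tuple, RegionMapping] = {}
    for m in mappings:
        key = m.canonical_key
        prev = best.get(key)
        if prev is None or m.embed_distance < prev.embed_distance:
            best[key] = m
    return [best[k] for k in sorted(best)]


def _alignment_windows(
    mappings: Sequence[RegionMapping], params: AlignParams
) -> tuple[list[tuple], dict]:
    """NW-align, filter, truncate, and window every mapping.

    Returns (alignments, counts) with one (canonical_key, origin_state,
    [WindowStats]) triple per surviving alignment.
    """
    counts = {
        "mappings": len(mappings), "origin_defined": 0,
        "kept_leading_gap": 0, "kept_truncation": 0, "windowed": 0,
    }
    out = []
    for m in mappings:
        if m.origin_state == "undefined":
            continue
        counts["origin_defined"] += 1
        a, b = m.alignable_pair()
        aln = _align.needleman_wunsch(a, b, params)
        aln.origin_state = m.origin_state
        if not _align.filter_leading_gaps(aln, params):
            continue
        counts["kept_leading_gap"] += 1
        clipped = _align.truncate_on_identity_change(aln, params)
        if clipped is None:
            continue
        counts["kept_truncation"] += 1
        windows = _align.window_statistics(clipped, params)
        if not windows:
            continue
        counts["windowed"] += 1
        out.append((m.canonical_key, m.origin_state, windows))
    return out, counts


def _cross_fit_predictions(
    alignments: list[tuple],
    ident: np.ndarray,
    indel: np.ndarray,
    labels: np.ndarray,
    config: MottleConfig,
) -> np.ndarray:
    """Out-of-fold true-identity predictions (2 folds split by alignment).

    Predicting each window with a model that never saw its own alignment's
    origin label keeps cluster selection independent of the labels for
    non-homologous mappings, so the homologous cluster's origin match rate
    stays an unbiased identity estimate.  Folds alternate over the
    canonically sorted alignments, which is direction-independent.
    """
    import warnings as _warnings

    fold_of_alignment = np.arange(len(alignments)) % 2
    fold = np.concatenate([
        np.full(len(ws), fold_of_alignment[i], dtype=int)
        for i, (_, _, ws) in enumerate(alignments)
    ])
    t_raw = np.empty(len(ident))
    for f in (0, 1):
        train = fold != f
        test = ~train
        if not test.any():
            continue
        if not train.any():
            t_raw[test] = float(labels[test].mean())
            continue
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # single-class folds are expected
            model = fit_true_identity_model(
                ident[train], indel[train], labels[train], config.gbdt_config()
            )
        t_raw[test] = model.predict(ident[test], indel[test])
    return t_raw


def _summarise_batch(
    alignments: list[tuple], t_raw: np.ndarray
) -> list[AlignmentStats]:
    """Per-alignment stabilised summaries from precomputed predictions."""
    from .align import CHANCE_IDENTITY

    ident = np.array([w.identity_gc for _, _, ws in alignments for w in ws])
    indel = np.array([w.indel_frac for _, _, ws in alignments for w in ws])
    chance = np.array([w.chance_match for _, _, ws in alignments for w in ws])
    t_gc = np.where(
        1.0 - chance < 1e-9,
        CHANCE_IDENTITY,
        CHANCE_IDENTITY
        + 0.75 * np.clip((t_raw - chance) / np.maximum(1.0 - chance, 1e-9), 0.0, 1.0),
    )
    sI = stabilise(ident, CHANCE_IDENTITY)
    sD = stabilise(indel, 0.0)
    sT = stabilise(t_gc, CHANCE_IDENTITY)

    stats = []
    pos = 0
    for key, state, ws in alignments:
        n = len(ws)
        sl = slice(pos, pos + n)
        pos += n
        mI, vI = float(sI[sl].mean()), float(max(sI[sl].var(), _cluster.VARIANCE_FLOOR))
        mD, vD = float(sD[sl].mean()), float(max(sD[sl].var(), _cluster.VARIANCE_FLOOR))
        mT, vT = float(sT[sl].mean()), float(max(sT[sl].var(), _cluster.VARIANCE_FLOOR))
        stats.append(AlignmentStats(
            mean_I=mI, var_I=vI, mean_D=mD, var_D=vD, mean_T=mT, var_T=vT,
            mean_true_identity=float(t_gc[sl].mean()),
            origin_state=state, n_windows=n,
            chance_match=float(chance[sl].mean()), key=key,
        ))
    return stats


def estimate_distance(
    query: Union[str, Path, SequenceRecord, Sequence[SequenceRecord]],
    target: Union[str, Path, SequenceRecord, Sequence[SequenceRecord]],
    config: Optional[MottleConfig] = None,
) -> DistanceResult:
    """Estimated substitution distance between two FASTA inputs.

    Accepts FASTA paths or in-memory :class:`SequenceRecord` objects.  The
    result is symmetric in its two inputs (reciprocal mapping directions are
    pooled and canonicalised before statistics are taken).
    """
    config = config or MottleConfig()
    q_records = _as_records(query)
    t_records = _as_records(target)
    params = config.align_params()

    min_len = config.flank_size + config.window
    for rec in (*q_records, *t_records):
        if rec.length <= min_len:
            raise ValueError(
                f"sequence {rec.id!r} (length {rec.length}) must be longer "
                f"than flank_size + window = {min_len}"
            )

    q_frags = generate_fragments_pooled(q_records, config.flank_size)
    t_frags = generate_fragments_pooled(t_records, config.flank_size)
    logger.info("fragments: query=%d target=%d", len(q_frags), len(t_frags))

    mappings = map_with_backend(q_frags, t_frags, t_records, config)
    mappings = _dedup_sorted(mappings)
    logger.info("unique mappings: %d", len(mappings))

    alignments, counts = _alignment_windows(mappings, params)
    logger.info(
        "alignments: origin-defined=%d after-leading-gap=%d after-truncation=%d",
        counts["origin_defined"], counts["kept_leading_gap"],
        counts["kept_truncation"],
    )
    if not alignments:
        return DistanceResult(
            distance=float("inf"), mean_true_identity=float("nan"),
            n_homologous=0, n_null=0, converged=False,
            diagnostics=counts,
        )

    ident = np.array([w.identity_gc for _, _, ws in alignments for w in ws])
    indel = np.array([w.indel_frac for _, _, ws in alignments for w in ws])
    labels = np.concatenate([
        np.full(len(ws), 1 if state == "match" else 0, dtype=int)
        for _, state, ws in alignments
    ])
    t_raw = _cross_fit_predictions(alignments, ident, indel, labels, config)

    stats = _summarise_batch(alignments, t_raw)
    result = distance_from_stats(stats, config.cluster_config())
    counts["n_windows"] = int(len(ident))
    result.diagnostics = counts
    logger.info(
        "clusters: homologous=%d null=%d distance=%s",
        result.n_homologous, result.n_null, result.distance,
    )
    return result
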