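"""Evaluation machinery: sequence-evolution simulator and benchmark metrics.

The simulator applies a fixed number of substitution events,
N_sub = round(N_nuc * D_sub), each picking a site uniformly with replacement
and replacing the current base with one of the three alternatives — so
multiple hits per site occur and the expected raw identity of the mutated
pair follows the Jukes-Cantor closed form 1/4 + 3/4 exp(-4 D / 3) exactly.

The stability benchmark runs a distance tool over an ascending ladder of
true distances, tracks the running mean absolute error, and reports the
maximum stable distance: the furthest true divergence reached before the
running MAE first exceeds the tolerance (0.05 sub/bp by convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .cluster import jukes_cantor
from .fragmenter import SequenceRecord

logger = logging.getLogger("mottle")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class EvolutionSpec:
    """Target divergence and reproducibility of one simulated evolution."""

    target_distance: float
    seed: int = 0
    indel_rate: float = 0.0  # indel events per site (0 for the simple model)

    def __post_init__(self):
        if self.target_distance < 0:
            raise ValueError("target_distance must be >= 0")
        if self.indel_rate < 0:
            raise ValueError("indel_rate must be >= 0")


def n_substitution_events(length: int, target_distance: float) -> int:
    """N_sub = round(N_nuc * D_sub)."""
    return int(round(length * target_distance))


def jc_expected_identity(distance: float) -> float:
    """Expected raw identity after `distance` substitution events per site."""
    return 0.25 + 0.75 * np.exp(-4.0 * distance / 3.0)


def random_genome(length: int, seed: int = 0, id: str = "random") -> SequenceRecord:
    """Uniform-composition random genome (synthetic study substrate)."""
    rng = np.random.default_rng(seed)
    seq = rng.choice(_BASES, size=length).tobytes().decode("ascii")
    return SequenceRecord.from_raw(id, seq)


def mutate_sequence(record: SequenceRecord, spec: EvolutionSpec) -> SequenceRecord:
    """Apply the specified number of substitution events (and optional
    geometric-length indels) to a copy of the sequence.  Seeded and
    bit-reproducible."""
    rng = np.random.default_rng(spec.seed)
    codes = np.frombuffer(record.seq.encode("ascii"), dtype=np.uint8).copy()
    L = len(codes)
    base_index = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(_BASES):
        base_index[b] = i

    n_events = n_substitution_events(L, spec.target_distance)
    sites = rng.integers(0, L, size=n_events)
    offsets = rng.integers(1, 4, size=n_events)  # never a silent self-substitution
    for site, off in zip(sites, offsets):
        cur = base_index[codes[site]]
        if cur < 0:  # ambiguous base: substitute to a uniform random base
            codes[site] = _BASES[rng.integers(0, 4)]
            continue
        codes[site] = _BASES[(cur + off) % 4]

    if spec.indel_rate > 0:
        seq = list(codes.tobytes().decode("ascii"))
        n_indels = int(round(L * spec.indel_rate))
        for _ in range(n_indels):
            pos = int(rng.integers(0, max(len(seq), 1)))
            size = int(rng.geometric(1.0 / 3.0))  # mean event length 3
            if rng.random() < 0.5:  # insertion
                ins = rng.choice(_BASES, size=size).tobytes().decode("ascii")
                seq[pos:pos] = list(ins)
            else:  # deletion
                del seq[pos : pos + size]
        mutated = "".join(seq)
    else:
        mutated = codes.tobytes().decode("ascii")
    return SequenceRecord.from_raw(f"{record.id}|mut", mutated)


@dataclass
class StabilityResult:
    """Predictions, running MAE, and maximum stable distance of one sweep."""

    series: list[tuple[float, float]]  # (true distance, prediction)
    running_mae: list[float]
    max_stable_distance: Optional[float]
    threshold: float

    def to_tsv(self) -> str:
        lines = ["true_distance\tpredicted\trunning_mae"]
        for (t, p), mae in zip(self.series, self.running_mae):
            lines.append(f"{t:.6g}\t{p:.6g}\t{mae:.6g}")
        msd = "none" if self.max_stable_distance is None else f"{self.max_stable_distance:.6g}"
        lines.append(f"# max_stable_distance\t{msd}")
        return "\n".join(lines) + "\n"


def running_mae(errors: Sequence[float]) -> list[float]:
    """Running mean of absolute errors: mae[k] = sum_{i<=k} |e_i| / (k + 1)."""
    abs_err = np.abs(np.asarray(errors, dtype=float))
    return list(np.cumsum(abs_err) / np.arange(1, len(abs_err) + 1))


def max_stable_distance(
    distances: Sequence[float], maes: Sequence[float], threshold: float
) -> Optional[float]:
    """Furthest true distance before the running MAE first exceeds the
    threshold; None when already out of tolerance at the first trial."""
    for k, mae in enumerate(maes):
        if mae > threshold:
            return distances[k - 1] if k > 0 else None
    return distances[-1] if len(distances) else None


def stability_curve(
    tool: Callable[[SequenceRecord, SequenceRecord], float],
    genome: SequenceRecord,
    distances: Sequence[float],
    threshold: float = 0.05,
    seed: int = 0,
    indel_rate: float = 0.0,
) -> StabilityResult:
    """Mutate-and-estimate sweep over an ascending ladder of true distances.

    Tool failures and NaN outputs count as infinite predictions; predictions
    are clipped to [0, 1] before entering the error, as in the benchmark's
    plotting convention.
    """
    distances = list(distances)
    if any(b < a for a, b in zip(distances, distances[1:])):
        raise ValueError("distances must be ascending")
    series: list[tuple[float, float]] = []
    errors: list[float] = []
    for k, d in enumerate(distances):
        spec = EvolutionSpec(
            target_distance=d,
            seed=(seed * 1_000_003 + k) % (2**31),
            indel_rate=indel_rate,
        )
        mutated = mutate_sequence(genome, spec)
        try:
            pred = float(tool(genome, mutated))
        except Exception:  # tool failure: record as saturated, keep running
            logger.exception("distance tool failed at true distance %.3g", d)
            pred = float("inf")
        if np.isnan(pred):
            pred = float("inf")
        clipped = float(np.clip(pred, 0.0, 1.0))
        series.append((d, pred))
        errors.append(abs(d - clipped))
        logger.info("stability: true=%.3g predicted=%.4g", d, pred)
    maes = running_mae(errors)
    return StabilityResult(
        series=series,
        running_mae=maes,
        max_stable_distance=max_stable_distance(distances, maes, threshold),
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# concatenation of known-divergence alignments

@dataclass(frozen=True)
class AlignmentCandidate:
    """A pairwise alignment summarised by its identity and aligned length."""

    identity: float
    length: int
    label: str = ""

    @property
    def jc_distance(self) -> float:
        return jukes_cantor(self.identity)


@dataclass
class ConcatenatedAlignment:
    """Greedy concatenation of candidates around a target divergence."""

    members: list[AlignmentCandidate]
    identity: float
    length: int
    distance: float
    reached_min_length: bool


def concatenate_alignments(
    candidates: Sequence[AlignmentCandidate],
    target_distance: float,
    min_length: int,
) -> ConcatenatedAlignment:
    """Concatenate alignments of similar divergence until ``min_length``.

    Starts from the candidate whose JC distance is closest to the target;
    while the pooled JC distance is below the target, the closest unused
    candidate above it is added (and vice versa), without replacement, until
    the target length is reached or no valid candidate remains.
    """
    pool = list(candidates)
    if not pool:
        raise ValueError("candidate set is empty")

    def dist_of(c: AlignmentCandidate) -> float:
        return c.jc_distance

    first = min(pool, key=lambda c: (abs(dist_of(c) - target_distance), dist_of(c)))
    pool.remove(first)
    members = [first]
    matches = first.identity * first.length
    length = first.length

    while length < min_length:
        pooled_identity = matches / length
        pooled_d = jukes_cantor(pooled_identity)
        if pooled_d < target_distance:
            side = [c for c in pool if dist_of(c) > target_distance]
        else:
            side = [c for c in pool if dist_of(c) < target_distance]
        if not side:
            break  # ran out of valid candidates
        nxt = min(side, key=lambda c: abs(dist_of(c) - target_distance))
        pool.remove(nxt)
        members.append(nxt)
        matches += nxt.identity * nxt.length
        length += nxt.length

    identity = matches / length
    return ConcatenatedAlignment(
        members=members,
        identity=identity,
        length=length,
        distance=jukes_cantor(identity),
        reached_min_length=length >= min_length,
    )


def outgroup_call(d_comparator: float, d_outgroup: float) -> str:
    """Outgroup-identification verdict from two reference distances.

    NaN (no homology found) counts as the maximal distance, stored as
    infinity; the call is correct when the outgroup is farther from the
    reference than the comparator, incorrect when nearer, ambiguous on ties
    (including inf vs inf).
    """
    dc = float("inf") if np.isnan(d_comparator) else d_comparator
    do = float("inf") if np.isnan(d_outgroup) else d_outgroup
    if do > dc:
        return "correct"
    if do < dc:
        return "incorrect"
    return "ambiguous"
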