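"""True-identity estimation, homologous/null clustering, and JC distance.

Window identity and indel statistics vary widely even within genuinely
homologous alignments.  Three steps make them usable for distance
estimation:

1. A gradient-boosted decision tree, monotonically increasing in window
   identity and decreasing in indel fraction, is trained to predict the
   origin-pair match state of each window.  Because origin nucleotides are
   excluded from the fragments, their match rate is an identity signal free
   of alignment bias, and the fitted surface ("true identity") estimates the
   proportion of matching origins at each statistic combination.
2. Per-alignment means/variances of the arcsine variance-stabilised
   statistics place every alignment in a 3-D space where two cluster centres
   (homologous, null) are fitted by minimising a weighted normalised-distance
   loss with BFGS.  The null centre's true identity is pinned at the chance
   value (-1 after stabilisation).
3. The mean true identity of the homologous cluster is converted to
   substitutions per base with the Jukes-Cantor model,
   D = -(3/4) ln(1 - (4/3)(1 - I)), saturating (infinite) at I <= 1/4.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import binom

from .align import CHANCE_IDENTITY, WindowStats, gc_corrected_identity

logger = logging.getLogger("mottle")

#: variance floor applied to per-alignment variances (prevents blow-ups for
#: single-window alignments in the normalised cluster distance)
VARIANCE_FLOOR = 1e-4

#: one-sided significance level for the saturation test of the homologous
#: cluster's origin match count against chance
SATURATION_ALPHA = 0.01


# ---------------------------------------------------------------------------
# variance-stabilising transform

def stabilise(p, l: float):
    """Arcsine variance-stabilising transform mapping [l, 1] onto [-1, 1].

    f(p; l) = arcsin(2 (max(p, l) - l) / (1 - l) - 1) * 2/pi, so the chance
    level l maps to -1 and a perfect statistic to +1.  l is 0.25 for
    GC-corrected identities and 0 for indel fractions.
    """
    if not 0.0 <= l < 1.0:
        raise ValueError("lower bound l must satisfy 0 <= l < 1")
    p = np.clip(np.maximum(p, l), l, 1.0)
    x = 2.0 * (p - l) / (1.0 - l) - 1.0
    return np.arcsin(x) * (2.0 / np.pi)


def stabilise_inverse(v, l: float):
    """Inverse of :func:`stabilise` on [-1, 1] (round-trips p >= l)."""
    x = np.sin(np.asarray(v) * (np.pi / 2.0))
    return l + (1.0 - l) * (x + 1.0) / 2.0


# ---------------------------------------------------------------------------
# monotone GBDT true identity

@dataclass(frozen=True)
class GBDTConfig:
    """Published training configuration for the true-identity GBDT."""

    ntrees: int = 100
    nleaves: int = 32
    learn_rate: float = 0.1
    subsamp: float = 1.0
    prior_size: int = 10
    seed: int = 0


class TrueIdentityModel:
    """Monotone surface (identity_gc, indel_frac) -> P(origin match).

    Wraps either a trained LightGBM booster or, when the training labels are
    single-class, a degenerate constant surface.
    """

    def __init__(self, booster=None, constant: Optional[float] = None,
                 config: Optional[GBDTConfig] = None):
        if (booster is None) == (constant is None):
            raise ValueError("exactly one of booster/constant required")
        self._booster = booster
        self._constant = constant
        self.config = config or GBDTConfig()

    @property
    def is_constant(self) -> bool:
        return self._constant is not None

    def predict(self, identity_gc, indel_frac) -> np.ndarray:
        identity_gc = np.atleast_1d(np.asarray(identity_gc, dtype=float))
        indel_frac = np.atleast_1d(np.asarray(indel_frac, dtype=float))
        if self._constant is not None:
            return np.full(identity_gc.shape, self._constant)
        X = np.column_stack([identity_gc, indel_frac])
        return np.clip(self._booster.predict(X), 0.0, 1.0)


def fit_true_identity_model(
    identity_gc: np.ndarray,
    indel_frac: np.ndarray,
    origin_match: np.ndarray,
    config: Optional[GBDTConfig] = None,
) -> TrueIdentityModel:
    """Train the monotone GBDT on windowed statistics with origin labels.

    ``prior_size`` pseudo-observations are appended at the surface extremes
    (matches at identity 1/indel 0, mismatches at chance identity/indel 0.5)
    to regularise regions with little data.  Single-class labels yield a
    constant model with a warning.
    """
    import lightgbm as lgb

    config = config or GBDTConfig()
    y = np.asarray(origin_match, dtype=int)
    if len(np.unique(y)) < 2:
        value = float(y[0]) if len(y) else 1.0
        warnings.warn(
            "origin labels are single-class; true-identity model is a "
            f"constant {value}",
            stacklevel=2,
        )
        return TrueIdentityModel(constant=value, config=config)

    X = np.column_stack([
        np.asarray(identity_gc, dtype=float),
        np.asarray(indel_frac, dtype=float),
    ])
    if config.prior_size > 0:
        k = config.prior_size
        X_prior = np.vstack([
            np.tile([1.0, 0.0], (k, 1)),
            np.tile([CHANCE_IDENTITY, 0.5], (k, 1)),
        ])
        X = np.vstack([X, X_prior])
        y = np.concatenate([y, np.ones(k, dtype=int), np.zeros(k, dtype=int)])

    params = {
        "objective": "binary",
        "num_leaves": config.nleaves,
        "learning_rate": config.learn_rate,
        "bagging_fraction": config.subsamp,
        "bagging_freq": 1 if config.subsamp < 1.0 else 0,
        "monotone_constraints": [1, -1],
        "min_data_in_leaf": 20,
        "min_data_in_bin": 1,
        "verbosity": -1,
        "seed": config.seed,
        "deterministic": True,
        "force_row_wise": True,
        "num_threads": 1,
    }
    data = lgb.Dataset(X, label=y, params={"min_data_in_bin": 1, "verbosity": -1})
    booster = lgb.train(params, data, num_boost_round=config.ntrees)
    return TrueIdentityModel(booster=booster, config=config)


# ---------------------------------------------------------------------------
# per-alignment summaries

@dataclass
class AlignmentStats:
    """Stabilised window-statistic moments of one alignment.

    mean/var pairs are over the alignment's windows, on the stabilised
    [-1, 1] scale; ``mean_true_identity`` is kept on the probability scale
    (GC-normalised, chance = 0.25) for the final JC conversion.
    """

    mean_I: float
    var_I: float
    mean_D: float
    var_D: float
    mean_T: float
    var_T: float
    mean_true_identity: float
    origin_state: str
    n_windows: int
    chance_match: float = CHANCE_IDENTITY
    key: tuple = ()


def _moments(values: np.ndarray) -> tuple[float, float]:
    return float(values.mean()), float(max(values.var(), VARIANCE_FLOOR))


def summarise_alignment(
    windows: Sequence[WindowStats],
    origin_state: str,
    model: TrueIdentityModel,
    key: tuple = (),
) -> AlignmentStats:
    """Stabilised means/variances of one alignment's windows."""
    if not windows:
        raise ValueError("alignment has no windows")
    ident = np.array([w.identity_gc for w in windows])
    indel = np.array([w.indel_frac for w in windows])
    chance = np.array([w.chance_match for w in windows])
    t_raw = model.predict(ident, indel)
    t_gc = np.array([
        gc_corrected_identity(t, e) for t, e in zip(t_raw, chance)
    ])
    mI, vI = _moments(stabilise(ident, CHANCE_IDENTITY))
    mD, vD = _moments(stabilise(indel, 0.0))
    mT, vT = _moments(stabilise(t_gc, CHANCE_IDENTITY))
    return AlignmentStats(
        mean_I=mI, var_I=vI, mean_D=mD, var_D=vD, mean_T=mT, var_T=vT,
        mean_true_identity=float(t_gc.mean()),
        origin_state=origin_state,
        n_windows=len(windows),
        chance_match=float(chance.mean()),
        key=key,
    )


# ---------------------------------------------------------------------------
# gradient-descent clustering

@dataclass(frozen=True)
class ClusterConfig:
    """Optimiser configuration for the two-centre clustering."""

    binpow: float = 64.0
    eps: float = float(np.finfo(float).eps)
    learn_mult: float = 0.001  # accepted for interface parity (see docs)
    reltol: float = 1e-20
    maxiter: int = 100

    @property
    def null_true_identity(self) -> float:
        """Stabilised true identity of chance mappings (pinned)."""
        return -1.0


@dataclass
class ClusterModel:
    """Fitted two-cluster model in stabilised (I, D, T) space."""

    null_centre: np.ndarray  # (I, D, T); T pinned at -1
    homologous_centre: np.ndarray
    assignments: np.ndarray  # bool, True = homologous
    loss_init: float
    loss_final: float
    converged: bool


def cluster_distance(stats: AlignmentStats, centre: Sequence[float]) -> float:
    """Normalised Euclidean distance of an alignment to a cluster centre:
    each dimension's (mean - centre) is scaled by the alignment's (floored)
    variance in that dimension."""
    c = np.asarray(centre, dtype=float)
    m = np.array([stats.mean_I, stats.mean_D, stats.mean_T])
    v = np.maximum(np.array([stats.var_I, stats.var_D, stats.var_T]),
                   VARIANCE_FLOOR)
    return float(np.sqrt(np.sum(((m - c) / v) ** 2)))


def _stats_arrays(stats: Sequence[AlignmentStats]):
    M = np.array([[s.mean_I, s.mean_D, s.mean_T] for s in stats])
    V = np.maximum(
        np.array([[s.var_I, s.var_D, s.var_T] for s in stats]), VARIANCE_FLOOR
    )
    return M, V


def _pair_distances(M, V, c_null, c_hom):
    d0 = np.sqrt(np.sum(((M - c_null) / V) ** 2, axis=1))
    d1 = np.sqrt(np.sum(((M - c_hom) / V) ** 2, axis=1))
    return d0, d1


def optimise_clusters(
    stats: Sequence[AlignmentStats],
    config: Optional[ClusterConfig] = None,
) -> ClusterModel:
    """Fit the null and homologous cluster centres by weighted BFGS descent.

    Five free parameters (null I, D; homologous I, D, T); the null centre's
    true identity stays pinned at the chance value.  The loss is the
    weight-normalised sum of alignment-to-centre distances with weights
    (1 / max(dist, eps))^(1/binpow).  If the optimiser fails to improve on
    the initialisation, the initialisation is returned with converged=False.
    """
    config = config or ClusterConfig()
    if len(stats) < 2:
        raise ValueError("clustering requires at least 2 alignments")
    M, V = _stats_arrays(stats)
    t_null = config.null_true_identity

    mean_T = M[:, 2]
    i_null = int(np.argmin(np.abs(mean_T - t_null)))
    order = np.argsort(mean_T, kind="stable")
    i_hom = int(order[int(round(0.9 * (len(stats) - 1)))])
    x0 = np.array([
        M[i_null, 0], M[i_null, 1],
        M[i_hom, 0], M[i_hom, 1], M[i_hom, 2],
    ])

    inv_binpow = 1.0 / config.binpow

    def loss(x):
        c0 = np.array([x[0], x[1], t_null])
        c1 = np.array([x[2], x[3], x[4]])
        d0, d1 = _pair_distances(M, V, c0, c1)
        d = np.concatenate([d0, d1])
        w = np.maximum(d, config.eps) ** (-inv_binpow)
        return float(np.sum(d * w) / np.sum(w))

    loss_init = loss(x0)
    res = minimize(
        loss, x0, method="BFGS",
        options={"maxiter": config.maxiter, "gtol": 1e-8},
    )
    if np.isfinite(res.fun) and res.fun <= loss_init:
        x = res.x
        loss_final = float(res.fun)
        converged = True
    else:  # optimiser failure: fall back to the initialisation
        x = x0
        loss_final = loss_init
        converged = False

    c_null = np.array([x[0], x[1], t_null])
    c_hom = np.array([x[2], x[3], x[4]])
    d0, d1 = _pair_distances(M, V, c_null, c_hom)
    # ties go to the null cluster (conservative)
    assignments = d1 < d0
    return ClusterModel(
        null_centre=c_null,
        homologous_centre=c_hom,
        assignments=assignments,
        loss_init=loss_init,
        loss_final=loss_final,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Jukes-Cantor conversion and the final distance

def jukes_cantor(I: float) -> float:
    """Substitutions per base from identity I under the Jukes-Cantor model:
    D = -(3/4) ln(1 - (4/3)(1 - I)); saturates (infinite) at I <= 0.25."""
    if I <= CHANCE_IDENTITY:
        return float("inf")
    I = min(I, 1.0)
    return -0.75 * np.log(1.0 - (4.0 / 3.0) * (1.0 - I))


@dataclass
class DistanceResult:
    """Final substitution-distance estimate with cluster diagnostics."""

    distance: float
    mean_true_identity: float
    n_homologous: int
    n_null: int
    converged: bool
    n_alignments: int = 0
    n_windows: int = 0
    saturation_pvalue: float = float("nan")
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = self.distance
        return {
            "schema": "mottle-distance/1",
            "distance": "inf" if np.isinf(d) else float(d),
            "mean_true_identity": float(self.mean_true_identity),
            "n_homologous": int(self.n_homologous),
            "n_null": int(self.n_null),
            "n_alignments": int(self.n_alignments),
            "n_windows": int(self.n_windows),
            "converged": bool(self.converged),
            "saturation_pvalue": (
                None if np.isnan(self.saturation_pvalue)
                else float(self.saturation_pvalue)
            ),
            "diagnostics": self.diagnostics,
        }


def _saturation_pvalue(stats: Sequence[AlignmentStats]) -> float:
    """One-sided exact binomial p-value that the cluster's origin match count
    exceeds chance.  Origin states are independent of the clustering features
    under the null, so selection into the cluster does not bias this test."""
    n = len(stats)
    if n == 0:
        return 1.0
    m = sum(1 for s in stats if s.origin_state == "match")
    chance = float(np.mean([s.chance_match for s in stats]))
    return float(binom.sf(m - 1, n, chance))


def distance_from_stats(
    stats: Sequence[AlignmentStats],
    config: Optional[ClusterConfig] = None,
) -> DistanceResult:
    """Cluster alignment summaries and convert the homologous cluster's mean
    true identity to a substitution distance.

    Saturated outcomes (no surviving alignments, an empty homologous cluster,
    or a homologous cluster whose origin match rate is not significantly
    above chance) are reported as infinite distance with converged=False.
    """
    stats = list(stats)
    n_windows = sum(s.n_windows for s in stats)
    if len(stats) == 0:
        return DistanceResult(
            distance=float("inf"), mean_true_identity=float("nan"),
            n_homologous=0, n_null=0, converged=False,
            n_alignments=0, n_windows=0,
        )
    if len(stats) == 1:
        # degenerate: a single alignment cannot be clustered; call it
        # homologous only if clearly away from the null true identity
        s = stats[0]
        hom = [s] if s.mean_T > -0.5 else []
        model = None
    else:
        model = optimise_clusters(stats, config)
        hom = [s for s, a in zip(stats, model.assignments) if a]

    n_hom, n_null = len(hom), len(stats) - len(hom)
    pval = _saturation_pvalue(hom)
    if n_hom == 0 or pval > SATURATION_ALPHA:
        logger.info(
            "homologous cluster empty or at chance (n=%d, p=%.3g): saturated",
            n_hom, pval,
        )
        return DistanceResult(
            distance=float("inf"), mean_true_identity=float("nan"),
            n_homologous=n_hom, n_null=n_null, converged=False,
            n_alignments=len(stats), n_windows=n_windows,
            saturation_pvalue=pval,
        )
    I = float(np.mean([s.mean_true_identity for s in hom]))
    D = jukes_cantor(I)
    converged = bool(model.converged) if model is not None else True
    if np.isinf(D):
        converged = False
    return DistanceResult(
        distance=D,
        mean_true_identity=I,
        n_homologous=n_hom,
        n_null=n_null,
        converged=converged,
        n_alignments=len(stats),
        n_windows=n_windows,
        saturation_pvalue=pval,
    )


def __getattr__(name):
    # estimate_distance orchestrates the full pipeline; it lives in
    # mottle.pipeline but is reachable from here for convenience.
    if name == "estimate_distance":
        from .pipeline import estimate_distance

        return estimate_distance
    raise AttributeError(name)
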