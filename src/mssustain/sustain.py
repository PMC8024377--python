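"""z-score SuStaIn: mixture of event-sequence progression models.

The model expresses a patient population as a mixture of ``C`` subtypes.
Each subtype is a strict ordering (a *sequence*) of biomarker events, where
an event is a biomarker crossing a z-score threshold (1, 2 or 3 control
standard deviations of abnormality).  A subject at stage ``k`` of subtype
``c`` has experienced the first ``k`` events of sequence ``S_c``; between
events the expected biomarker value interpolates linearly, rising towards
``z_max`` after the biomarker's last threshold event.  Observed z-scores are
modelled as Gaussian around the expected trajectory.

Stages are discrete, ``k = 0..E`` where ``E`` is the number of events;
stage 0 means no abnormality has occurred.  Within one biomarker the
threshold events are constrained to occur in increasing order (z=1 before
z=2 before z=3); every optimizer and sampler in this module preserves that
constraint.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "EventGrid",
    "SubtypeModel",
    "SustainOptions",
    "McmcSamples",
    "SubjectAssignment",
    "build_event_grid",
    "expected_value",
    "expected_values",
    "stage_likelihoods",
    "total_loglik",
    "optimize_sequence",
    "fit_sustain",
    "fit_sustain_path",
    "mcmc_sample",
    "positional_distribution",
    "assign",
    "random_valid_sequence",
    "is_valid_sequence",
]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass(frozen=True)
class EventGrid:
    """Ordered grid of (biomarker, z-threshold) events.

    Events are numbered feature-major: event ``e`` refers to feature
    ``e // T`` crossing threshold ``thresholds[e % T]`` where ``T`` is the
    number of thresholds.
    """

    features: tuple[str, ...]
    thresholds: tuple[float, ...] = (1.0, 2.0, 3.0)
    z_max: float = 5.0

    def __post_init__(self):
        if len(self.features) == 0:
            raise ValueError("event grid needs at least one feature")
        if len(set(self.features)) != len(self.features):
            raise ValueError("duplicate features in event grid")
        th = np.asarray(self.thresholds, dtype=float)
        if th.size == 0 or np.any(th <= 0) or np.any(np.diff(th) <= 0):
            raise ValueError("thresholds must be strictly increasing and positive")
        if self.z_max < th[-1]:
            raise ValueError("z_max must be at least the top threshold")

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_events(self) -> int:
        return len(self.features) * len(self.thresholds)

    def event_feature(self, e: int) -> int:
        return int(e) // len(self.thresholds)

    def event_threshold(self, e: int) -> float:
        return self.thresholds[int(e) % len(self.thresholds)]

    def to_dict(self) -> dict:
        return {
            "features": list(self.features),
            "thresholds": list(self.thresholds),
            "z_max": self.z_max,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EventGrid":
        return cls(tuple(d["features"]), tuple(d["thresholds"]), float(d["z_max"]))


def build_event_grid(
    features, thresholds=(1.0, 2.0, 3.0), z_max: float = 5.0
) -> EventGrid:
    """Build the canonical feature-major event grid."""
    return EventGrid(tuple(features), tuple(float(t) for t in thresholds), float(z_max))


def is_valid_sequence(grid: EventGrid, sequence) -> bool:
    """True if ``sequence`` is a permutation of the events respecting the
    within-feature threshold ordering."""
    seq = np.asarray(sequence)
    E = grid.n_events
    if seq.shape != (E,) or not np.array_equal(np.sort(seq), np.arange(E)):
        return False
    pos = np.empty(E, dtype=int)
    pos[seq] = np.arange(E)
    T = len(grid.thresholds)
    for i in range(grid.n_features):
        p = pos[i * T : (i + 1) * T]
        if np.any(np.diff(p) <= 0):
            return False
    return True


def random_valid_sequence(grid: EventGrid, rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish random permutation respecting within-feature ordering.

    Draws an unconstrained random permutation, then within each feature
    reassigns that feature's occupied positions to its events in threshold
    order (a measure-preserving repair, so every valid order is reachable).
    """
    E = grid.n_events
    T = len(grid.thresholds)
    perm = rng.permutation(E)
    pos = np.empty(E, dtype=int)
    pos[perm] = np.arange(E)
    seq = np.empty(E, dtype=int)
    for i in range(grid.n_features):
        events = np.arange(i * T, (i + 1) * T)
        seq[np.sort(pos[events])] = events
    return seq


def expected_values(grid: EventGrid, sequence) -> np.ndarray:
    """Expected-trajectory matrix ``G`` of shape (n_features, E + 1).

    ``G[i, k]`` is the expected z-score of feature ``i`` at stage ``k``:
    piecewise-linear through (0, 0), each threshold event of feature ``i``
    at its 1-based sequence position, and (E, z_max) unless the feature's
    last event already sits at position E.
    """
    seq = np.asarray(sequence)
    E = grid.n_events
    T = len(grid.thresholds)
    pos = np.empty(E, dtype=int)
    pos[seq] = np.arange(E)
    stages = np.arange(E + 1, dtype=float)
    G = np.empty((grid.n_features, E + 1))
    for i in range(grid.n_features):
        p = pos[i * T : (i + 1) * T] + 1  # 1-based event positions
        xp = [0.0, *p.astype(float)]
        fp = [0.0, *grid.thresholds]
        if p[-1] < E:
            xp.append(float(E))
            fp.append(grid.z_max)
        G[i] = np.interp(stages, xp, fp)
    return G


def expected_value(grid: EventGrid, feature: int, stage: int, sequence) -> float:
    """Expected z-score of one feature at one stage under a sequence."""
    if not 0 <= stage <= grid.n_events:
        raise ValueError(f"stage {stage} out of range 0..{grid.n_events}")
    return float(expected_values(grid, sequence)[feature, int(stage)])


def _as_z_matrix(Z, grid: EventGrid) -> np.ndarray:
    """Accept an (N, F) array or a DataFrame carrying the grid's features."""
    if hasattr(Z, "loc") and hasattr(Z, "columns"):  # DataFrame
        missing = [f for f in grid.features if f not in Z.columns]
        if missing:
            raise ValueError(f"z-score table lacks grid features: {missing}")
        Z = Z[list(grid.features)].to_numpy(dtype=float)
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[None, :]
    if Z.shape[1] != grid.n_features:
        raise ValueError("z matrix width does not match event grid")
    if not np.all(np.isfinite(Z)):
        raise ValueError("non-finite z-scores")
    return Z


def _sigma_vector(grid: EventGrid, sigma) -> np.ndarray:
    s = np.broadcast_to(np.asarray(sigma, dtype=float), (grid.n_features,)).copy()
    if np.any(s <= 0):
        raise ValueError("sigma must be positive")
    return s


def _loglik_matrix(Z: np.ndarray, grid: EventGrid, sequence, sigma) -> np.ndarray:
    """(N, E+1) matrix of log L(k) = sum_i log N(z_i; g_i(k), sigma_i)."""
    s2 = _sigma_vector(grid, sigma) ** 2
    G = expected_values(grid, sequence)
    const = -0.5 * (Z * Z / s2).sum(axis=1) - (
        grid.n_features * _LOG_SQRT_2PI + 0.5 * np.log(s2).sum()
    )
    return const[:, None] + (Z / s2) @ G - 0.5 * ((G * G) / s2[:, None]).sum(axis=0)


def stage_likelihoods(z, sequence, grid: EventGrid, sigma=1.0) -> np.ndarray:
    """Per-stage likelihood vector L(k), k = 0..E, for one visit.

    Computed in log-space and exponentiated; the Gaussian emission noise
    ``sigma`` may be scalar or per-feature.
    """
    Z = _as_z_matrix(z, grid)
    if Z.shape[0] != 1:
        raise ValueError("stage_likelihoods expects a single visit")
    return np.exp(_loglik_matrix(Z, grid, sequence, sigma)[0])


@dataclass
class SubtypeModel:
    """C event sequences with mixture fractions over a shared event grid."""

    grid: EventGrid
    sequences: np.ndarray  # (C, E) int
    fractions: np.ndarray  # (C,)
    sigma: np.ndarray | float = 1.0

    def __post_init__(self):
        self.sequences = np.atleast_2d(np.asarray(self.sequences, dtype=int))
        self.fractions = np.asarray(self.fractions, dtype=float).ravel()
        if self.sequences.shape[0] != self.fractions.size:
            raise ValueError("one fraction per sequence required")
        if abs(self.fractions.sum() - 1.0) > 1e-12 or np.any(self.fractions < 0):
            raise ValueError("fractions must be a probability vector (sum 1)")
        for s in self.sequences:
            if not is_valid_sequence(self.grid, s):
                raise ValueError("invalid event sequence in model")
        self.sigma = _sigma_vector(self.grid, self.sigma)

    @property
    def n_subtypes(self) -> int:
        return self.sequences.shape[0]

    def to_dict(self) -> dict:
        return {
            "grid": self.grid.to_dict(),
            "sequences": self.sequences.tolist(),
            "fractions": self.fractions.tolist(),
            "sigma": np.asarray(self.sigma).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SubtypeModel":
        return cls(
            grid=EventGrid.from_dict(d["grid"]),
            sequences=np.asarray(d["sequences"], dtype=int),
            fractions=np.asarray(d["fractions"], dtype=float),
            sigma=np.asarray(d["sigma"], dtype=float),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "SubtypeModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _subtype_visit_logliks(Z: np.ndarray, model: SubtypeModel) -> np.ndarray:
    """(N, C) matrix of per-visit log p(x | c) under a uniform stage prior."""
    E = model.grid.n_events
    out = np.empty((Z.shape[0], model.n_subtypes))
    for c in range(model.n_subtypes):
        M = _loglik_matrix(Z, model.grid, model.sequences[c], model.sigma)
        out[:, c] = logsumexp(M, axis=1) - np.log(E + 1)
    return out


def total_loglik(Z, model: SubtypeModel) -> float:
    """Total mixture log-likelihood of a z-score table.

    ``sum_n log sum_c f_c (1/(E+1)) sum_k L_c(k | z_n)``.
    """
    Zm = _as_z_matrix(Z, model.grid)
    if Zm.shape[0] == 0:
        raise ValueError("empty z-score table")
    m = _subtype_visit_logliks(Zm, model)
    with np.errstate(divide="ignore"):
        lw = np.log(model.fractions)
    return float(logsumexp(m + lw[None, :], axis=1).sum())


def _admissible_slots(grid: EventGrid, seq_without: np.ndarray, event: int) -> np.ndarray:
    """Insertion slots for ``event`` into a length-(E-1) sequence that keep
    the within-feature threshold ordering."""
    T = len(grid.thresholds)
    feat = event // T
    rank = event % T
    lo, hi = 0, len(seq_without)
    feats = seq_without // T
    ranks = seq_without % T
    own = np.nonzero(feats == feat)[0]
    for idx in own:
        if ranks[idx] < rank:
            lo = max(lo, idx + 1)
        else:
            hi = min(hi, idx)
    return np.arange(lo, hi + 1)


try:  # fused max/exp/sum kernel; numba is optional, numpy path is exact too
    from numba import njit as _njit

    @_njit(cache=False, fastmath=False)
    def _wlse_kernel(U, b, w):  # pragma: no cover - exercised via wrapper
        N, PK = U.shape
        P, K = b.shape
        out = np.zeros(P)
        for n in range(N):
            for p in range(P):
                base = p * K
                m = -1e300
                for k in range(K):
                    v = U[n, base + k] + b[p, k]
                    if v > m:
                        m = v
                s = 0.0
                for k in range(K):
                    d = U[n, base + k] + b[p, k] - m
                    if d > -36.0:  # exp underflow guard; error < K*2e-16
                        s += np.exp(d)
                out[p] += w[n] * (m + np.log(s))
        return out

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _weighted_seq_loglik_batch(
    Z: np.ndarray, grid: EventGrid, sequences: list[np.ndarray], sigma, weights
) -> np.ndarray:
    """Weighted single-sequence log-likelihood for a batch of sequences.

    Returns ``sum_n w_n log[(1/(E+1)) sum_k L(k | z_n)]`` for each candidate,
    batched through one matrix product plus a fused log-sum-exp kernel.
    """
    E = grid.n_events
    K = E + 1
    s2 = _sigma_vector(grid, sigma) ** 2
    P = len(sequences)
    Gs = np.empty((grid.n_features, P * K))
    b = np.empty((P, K))
    for j, s in enumerate(sequences):
        G = expected_values(grid, s)
        Gs[:, j * K : (j + 1) * K] = G
        b[j] = -0.5 * ((G * G) / s2[:, None]).sum(axis=0)
    const = -0.5 * (Z * Z / s2).sum(axis=1) - (
        grid.n_features * _LOG_SQRT_2PI + 0.5 * np.log(s2).sum()
    )
    U = (Z / s2) @ Gs  # (N, P*K)
    w = np.ones(Z.shape[0]) if weights is None else np.asarray(weights, float)
    if _HAVE_NUMBA:
        out = _wlse_kernel(U, b, w)
    else:
        M = U.reshape(Z.shape[0], P, K) + b[None, :, :]
        out = w @ logsumexp(M, axis=2)
    return out + float(w @ const) - float(w.sum()) * np.log(K)


def _greedy_ascent(
    Z: np.ndarray,
    grid: EventGrid,
    seq: np.ndarray,
    sigma,
    weights,
    rng: np.random.Generator,
    max_sweeps: int,
) -> tuple[np.ndarray, float]:
    """Coordinate ascent: repeatedly pull each event out and reinsert it at
    its best admissible position until no move improves the likelihood."""
    seq = np.asarray(seq, dtype=int).copy()
    best = _weighted_seq_loglik_batch(Z, grid, [seq], sigma, weights)[0]
    E = grid.n_events
    for _ in range(max_sweeps):
        improved = False
        for event in rng.permutation(E):
            cur = int(np.nonzero(seq == event)[0][0])
            rest = np.delete(seq, cur)
            slots = _admissible_slots(grid, rest, event)
            cands = [np.insert(rest, p, event) for p in slots]
            lls = _weighted_seq_loglik_batch(Z, grid, cands, sigma, weights)
            j = int(np.argmax(lls))
            if lls[j] > best + 1e-6:
                seq = cands[j]
                best = lls[j]
                improved = True
        if not improved:
            break
    return seq, float(best)


def optimize_sequence(
    Z,
    grid: EventGrid,
    starts: int = 25,
    sigma=1.0,
    weights=None,
    rng: np.random.Generator | int | None = None,
    init=None,
    max_sweeps: int = 50,
) -> np.ndarray:
    """Maximum-likelihood single-subtype sequence by multi-start greedy
    event reinsertion.

    Each start draws a random valid permutation (or uses ``init`` for the
    first start) and ascends by removing each event in turn and reinserting
    it at its best admissible position.  ``weights`` (per-visit, optional)
    make this the M-step of the mixture EM.
    """
    if starts < 1:
        raise ValueError("starts must be >= 1")
    rng = np.random.default_rng(rng)
    Zm = _as_z_matrix(Z, grid)
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
    best_seq, best_ll = None, -np.inf
    for s in range(starts):
        if s == 0 and init is not None:
            seq0 = np.asarray(init, dtype=int)
        else:
            seq0 = random_valid_sequence(grid, rng)
        seq, ll = _greedy_ascent(Zm, grid, seq0, sigma, weights, rng, max_sweeps)
        if ll > best_ll:
            best_seq, best_ll = seq, ll
    return best_seq


@dataclass
class SustainOptions:
    """Tunables for model fitting.

    starts: random restarts for the single-subtype optimizer.
    split_starts: restarts when fitting the halves of a cluster split.
    em_tol: EM convergence threshold on the total log-likelihood.
    """

    starts: int = 25
    split_starts: int = 5
    em_tol: float = 1e-4
    em_max_iter: int = 100
    em_sweeps: int = 2  # reinsertion sweeps per M-step (generalized EM)
    sigma: float = 1.0
    seed: int | None = None
    max_sweeps: int = 50


def _responsibilities(Z: np.ndarray, model: SubtypeModel) -> np.ndarray:
    m = _subtype_visit_logliks(Z, model)
    with np.errstate(divide="ignore"):
        a = m + np.log(model.fractions)[None, :]
    a -= a.max(axis=1, keepdims=True)
    r = np.exp(a)
    return r / r.sum(axis=1, keepdims=True)


def _em(
    Z: np.ndarray,
    grid: EventGrid,
    sequences: np.ndarray,
    fractions: np.ndarray,
    opts: SustainOptions,
    rng: np.random.Generator,
) -> tuple[SubtypeModel, float, list[float]]:
    """Alternate soft assignment and weighted sequence re-optimization."""
    model = SubtypeModel(grid, sequences, fractions / fractions.sum(), opts.sigma)
    trace = [total_loglik(Z, model)]
    for _ in range(opts.em_max_iter):
        r = _responsibilities(Z, model)
        new_seqs = []
        for c in range(model.n_subtypes):
            # rows with negligible responsibility do not move the M-step
            active = r[:, c] > 1e-12 * r[:, c].sum()
            new_seqs.append(
                optimize_sequence(
                    Z[active],
                    grid,
                    starts=1,
                    sigma=opts.sigma,
                    weights=r[active, c],
                    rng=rng,
                    init=model.sequences[c],
                    max_sweeps=opts.em_sweeps,
                )
            )
        f = r.mean(axis=0)
        model = SubtypeModel(grid, np.array(new_seqs), f / f.sum(), opts.sigma)
        trace.append(total_loglik(Z, model))
        if trace[-1] - trace[-2] < opts.em_tol:
            break
    else:
        warnings.warn(
            f"EM stopped at max_iter={opts.em_max_iter} before reaching "
            f"tol={opts.em_tol}; returning best-so-far", stacklevel=2)
    return model, trace[-1], trace


def fit_sustain_path(
    Z, grid: EventGrid, max_subtypes: int, opts: SustainOptions | None = None
) -> list[SubtypeModel]:
    """Hierarchical fit: models with 1..max_subtypes subtypes.

    The ``c``-subtype model is initialized from the ``(c-1)``-subtype model
    by splitting each cluster in two (random bipartition of its visits,
    one-subtype fit on each half), keeping the best split after EM.
    """
    opts = opts or SustainOptions()
    rng = np.random.default_rng(opts.seed)
    Zm = _as_z_matrix(Z, grid)
    if max_subtypes < 1:
        raise ValueError("max_subtypes must be >= 1")
    if Zm.shape[0] < 10 * max_subtypes:
        raise ValueError("not enough visits for the requested subtype count")
    models: list[SubtypeModel] = []
    seq1 = optimize_sequence(
        Zm, grid, starts=opts.starts, sigma=opts.sigma, rng=rng,
        max_sweeps=opts.max_sweeps,
    )
    models.append(SubtypeModel(grid, seq1[None, :], np.array([1.0]), opts.sigma))
    for c in range(2, max_subtypes + 1):
        prev = models[-1]
        r = _responsibilities(Zm, prev)
        hard = r.argmax(axis=1)
        best_model, best_ll = None, -np.inf
        for j in range(prev.n_subtypes):
            members = np.nonzero(hard == j)[0]
            if members.size < 8:
                continue
            split = _split_cluster(Zm[members], grid, opts, rng)
            if split is None:
                continue
            seqs = np.vstack([np.delete(prev.sequences, j, axis=0), split])
            fr = np.concatenate(
                [
                    np.delete(prev.fractions, j),
                    [prev.fractions[j] / 2, prev.fractions[j] / 2],
                ]
            )
            model, ll, _ = _em(Zm, grid, seqs, fr, opts, rng)
            if ll > best_ll:
                best_model, best_ll = model, ll
        if best_model is None:
            raise RuntimeError(f"could not split any cluster to reach C={c}")
        models.append(best_model)
    return models


def _split_cluster(
    Zc: np.ndarray, grid: EventGrid, opts: SustainOptions, rng
) -> np.ndarray | None:
    """Best two-sequence bipartition of one cluster's visits.

    Runs a small two-subtype EM on the cluster's own data from
    ``split_starts`` random bipartitions (each half seeded by a
    single-start sequence fit) and returns the best pair of sequences.
    """
    best_seqs, best_ll = None, -np.inf
    for _ in range(opts.split_starts):
        order = rng.permutation(Zc.shape[0])
        a, b = order[: order.size // 2], order[order.size // 2 :]
        try:
            seq_a = optimize_sequence(
                Zc[a], grid, starts=1, sigma=opts.sigma, rng=rng,
                max_sweeps=opts.max_sweeps)
            seq_b = optimize_sequence(
                Zc[b], grid, starts=1, sigma=opts.sigma, rng=rng,
                max_sweeps=opts.max_sweeps)
        except ValueError:
            return None
        model, ll, _ = _em(
            Zc, grid, np.vstack([seq_a, seq_b]), np.array([0.5, 0.5]),
            opts, rng)
        if ll > best_ll:
            best_seqs, best_ll = model.sequences, ll
    return best_seqs


def fit_sustain(
    Z, grid: EventGrid, n_subtypes: int, opts: SustainOptions | None = None
) -> SubtypeModel:
    """Fit the subtype mixture with ``n_subtypes`` subtypes (hierarchical
    initialization from smaller models; see :func:`fit_sustain_path`)."""
    return fit_sustain_path(Z, grid, n_subtypes, opts)[-1]


@dataclass
class McmcSamples:
    """Thinned post-burn-in posterior samples over sequences.

    sequences: (n_samples, C, E) integer array.
    fractions: (n_samples, C).
    loglik_trace: per-iteration total log-likelihood (full chain).
    """

    grid: EventGrid
    sequences: np.ndarray
    fractions: np.ndarray
    loglik_trace: np.ndarray
    iterations: int
    burn_in: float
    thinning: int

    @property
    def n_samples(self) -> int:
        return self.sequences.shape[0]

    @property
    def n_subtypes(self) -> int:
        return self.sequences.shape[1]

    def to_dict(self) -> dict:
        return {
            "grid": self.grid.to_dict(),
            "sequences": self.sequences.tolist(),
            "fractions": self.fractions.tolist(),
            "loglik_trace": np.asarray(self.loglik_trace).tolist(),
            "iterations": self.iterations,
            "burn_in": self.burn_in,
            "thinning": self.thinning,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "McmcSamples":
        return cls(
            grid=EventGrid.from_dict(d["grid"]),
            sequences=np.asarray(d["sequences"], dtype=int),
            fractions=np.asarray(d["fractions"], dtype=float),
            loglik_trace=np.asarray(d["loglik_trace"], dtype=float),
            iterations=int(d["iterations"]),
            burn_in=float(d["burn_in"]),
            thinning=int(d["thinning"]),
        )


def mcmc_sample(
    Z,
    model: SubtypeModel,
    iterations: int = 100_000,
    seed: int | np.random.Generator | None = None,
    burn_in: float = 0.1,
    thinning: int = 10,
) -> McmcSamples:
    """Metropolis–Hastings over sequences around a fitted model.

    The proposal moves one uniformly chosen event of one uniformly chosen
    subtype to a uniformly chosen admissible position (symmetric, since the
    admissible bracket is unchanged by moves within it); acceptance is
    ``min(1, exp(delta log-likelihood))``.  Mixture fractions are refreshed
    each iteration by responsibility re-normalization rather than sampled.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if not 0 <= burn_in < 1 or thinning < 1:
        raise ValueError("invalid burn-in/thinning combination")
    rng = np.random.default_rng(seed)
    grid = model.grid
    Zm = _as_z_matrix(Z, grid)
    E, C = grid.n_events, model.n_subtypes
    K = E + 1

    seqs = model.sequences.copy()
    # cached per-visit per-subtype marginal log-likelihoods
    m = _subtype_visit_logliks(Zm, model)

    def refresh_fractions(m):
        a = m - m.max(axis=1, keepdims=True)
        r = np.exp(a)
        r /= r.sum(axis=1, keepdims=True)
        f = r.mean(axis=0)
        return f / f.sum()

    def total(m, f):
        with np.errstate(divide="ignore"):
            return float(logsumexp(m + np.log(f)[None, :], axis=1).sum())

    f = refresh_fractions(m)
    cur_ll = total(m, f)

    n_burn = int(round(burn_in * iterations))
    keep_iters = range(n_burn, iterations, thinning)
    n_keep = len(keep_iters)
    out_seq = np.empty((n_keep, C, E), dtype=np.int16)
    out_frac = np.empty((n_keep, C))
    trace = np.empty(iterations)
    keep_set = set(keep_iters)
    ki = 0

    for it in range(iterations):
        c = int(rng.integers(C))
        event = int(rng.integers(E))
        seq = seqs[c]
        cur = int(np.nonzero(seq == event)[0][0])
        rest = np.delete(seq, cur)
        slots = _admissible_slots(grid, rest, event)
        p = int(slots[rng.integers(slots.size)])
        new_seq = np.insert(rest, p, event)
        if p == cur:
            new_m_c = m[:, c]
            accept = True  # identity proposal: delta = 0
        else:
            new_m_c = (
                logsumexp(_loglik_matrix(Zm, grid, new_seq, model.sigma), axis=1)
                - np.log(K)
            )
            m_new = m.copy()
            m_new[:, c] = new_m_c
            f_new = refresh_fractions(m_new)
            new_ll = total(m_new, f_new)
            accept = np.log(rng.uniform()) < new_ll - cur_ll
        if accept and p != cur:
            seqs[c] = new_seq
            m[:, c] = new_m_c
            f = f_new
            cur_ll = new_ll
        trace[it] = cur_ll
        if it in keep_set:
            out_seq[ki] = seqs
            out_frac[ki] = f
            ki += 1

    return McmcSamples(
        grid=grid,
        sequences=out_seq,
        fractions=out_frac,
        loglik_trace=trace,
        iterations=iterations,
        burn_in=burn_in,
        thinning=thinning,
    )


def positional_distribution(samples: McmcSamples, subtype: int) -> np.ndarray:
    """(E, E) matrix: entry (e, p) = posterior fraction of samples placing
    event ``e`` at sequence position ``p``.  Rows sum to 1."""
    if samples.n_samples == 0:
        raise ValueError("no retained samples")
    E = samples.grid.n_events
    seqs = samples.sequences[:, subtype, :]  # (S, E): seqs[s, p] = event
    out = np.zeros((E, E))
    for s in range(seqs.shape[0]):
        out[seqs[s], np.arange(E)] += 1.0
    return out / seqs.shape[0]


@dataclass
class SubjectAssignment:
    """Per-visit posterior subtype membership and stage.

    ``table`` carries, per visit: key columns (if the input was a
    DataFrame), ``prob_subtype_<c>`` posterior membership, ``modal_subtype``
    (0-based, ties to the lowest index), ``modal_stage``/``expected_stage``
    conditional on the modal subtype.  Stage 0 means no events; patients in
    progression figures are conventionally shown on 1..E.
    """

    table: "object"  # pandas DataFrame
    stage_posteriors: np.ndarray  # (N, E+1), conditional on modal subtype


def assign(Z, model: SubtypeModel, keys=None) -> SubjectAssignment:
    """Posterior subtype and stage for every visit of a z-score table."""
    import pandas as pd

    Zm = _as_z_matrix(Z, model.grid)
    m = _subtype_visit_logliks(Zm, model)
    with np.errstate(divide="ignore"):
        a = m + np.log(model.fractions)[None, :]
    a -= a.max(axis=1, keepdims=True)
    post = np.exp(a)
    post /= post.sum(axis=1, keepdims=True)
    modal_c = post.argmax(axis=1)

    E = model.grid.n_events
    stage_post = np.empty((Zm.shape[0], E + 1))
    for c in range(model.n_subtypes):
        rows = np.nonzero(modal_c == c)[0]
        if rows.size == 0:
            continue
        M = _loglik_matrix(Zm[rows], model.grid, model.sequences[c], model.sigma)
        M -= M.max(axis=1, keepdims=True)
        P = np.exp(M)
        stage_post[rows] = P / P.sum(axis=1, keepdims=True)
    modal_stage = stage_post.argmax(axis=1)
    expected_stage = stage_post @ np.arange(E + 1)

    if keys is None and hasattr(Z, "columns"):
        key_cols = [
            c for c in ("subject_id", "dataset_id", "visit_time", "arm")
            if c in Z.columns
        ]
        keys = Z[key_cols].reset_index(drop=True) if key_cols else None
    tab = pd.DataFrame(
        {f"prob_subtype_{c}": post[:, c] for c in range(model.n_subtypes)}
    )
    tab["modal_subtype"] = modal_c
    tab["modal_stage"] = modal_stage
    tab["expected_stage"] = expected_stage
    if keys is not None:
        tab = pd.concat([keys.reset_index(drop=True), tab], axis=1)
    return SubjectAssignment(table=tab, stage_posteriors=stage_post)
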