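"""Subtype-and-stage inference.

Greedy multi-start sequence optimisation, hierarchical cluster
splitting with EM over (fractions, sequences), Metropolis MCMC over
event orderings, positional-variance diagrams, and per-subject
subtype/stage posteriors.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .config import RunConfig
from .event_model import (
    EventGrid,
    random_valid_sequence,
    stage_log_likelihoods,
)

logger = logging.getLogger("zsustain")

__all__ = [
    "SubtypeModel",
    "SubjectPosteriors",
    "McmcSamples",
    "optimize_sequence",
    "fit_sustain",
    "mcmc_sample",
    "subject_posteriors",
    "positional_variance",
]

UNASSIGNED = -1


@dataclass
class McmcSamples:
    """Retained post-burn-in MCMC samples."""

    sequences: np.ndarray  # (n_samples, C, E) event indices
    fractions: np.ndarray  # (n_samples, C)
    log_likelihoods: np.ndarray  # (n_samples,)
    acceptance_rate: float

    @property
    def n_samples(self) -> int:
        return self.sequences.shape[0]


@dataclass
class SubtypeModel:
    """Fitted mixture of progression patterns."""

    sequences: list[np.ndarray]
    fractions: np.ndarray
    log_likelihood: float
    grid: EventGrid
    sigma: float = 1.0
    samples: McmcSamples | None = None
    pvds: list[np.ndarray] | None = None

    @property
    def n_subtypes(self) -> int:
        return len(self.sequences)

    def modal_sequences(self) -> list[np.ndarray]:
        """Per subtype, the most frequent sequence among MCMC samples."""
        if self.samples is None:
            raise ValueError("model has no MCMC samples")
        out = []
        for c in range(self.n_subtypes):
            counts = Counter(map(tuple, self.samples.sequences[:, c, :]))
            out.append(np.asarray(counts.most_common(1)[0][0], dtype=np.intp))
        return out


@dataclass
class SubjectPosteriors:
    """Per-subject subtype/stage posteriors and derived assignments."""

    subject_ids: list[str]
    subtype_probs: np.ndarray  # (n, C), rows sum to 1
    stage_posteriors: np.ndarray  # (n, C, E+1), each row sums to 1
    weighted_stage: np.ndarray  # (n,)
    assigned_subtype: np.ndarray  # (n,) 0-based index or UNASSIGNED
    stage_zero: np.ndarray  # (n,) bool
    cutoff: float = 0.5

    def to_frame(self):
        import pandas as pd

        n, C = self.subtype_probs.shape
        data = {"subject_id": list(self.subject_ids)}
        for c in range(C):
            data[f"p_subtype_{c + 1}"] = self.subtype_probs[:, c]
        data["weighted_stage"] = self.weighted_stage
        data["assigned_subtype"] = [
            "unclassified" if a == UNASSIGNED else str(a + 1)
            for a in self.assigned_subtype
        ]
        data["stage_zero"] = self.stage_zero.astype(int)
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# fast likelihood engine (hot path for greedy ascent and MCMC)


class _Engine:
    """Precomputed state for repeated marginal-likelihood evaluation.

    Same quantity as :func:`zsustain.event_model.sequence_log_marginals`
    but skips per-call validation and uses a matmul expansion of the
    squared residuals.
    """

    def __init__(self, X: np.ndarray, grid: EventGrid, sigma: float) -> None:
        self.X = np.ascontiguousarray(X, dtype=float)
        self.grid = grid
        self.sigma = float(sigma)
        self.E = grid.n_events
        self.R = grid.n_regions
        self.region_events = [grid.region_events(i) for i in range(self.R)]
        self.t = np.arange(self.E + 1, dtype=float)
        self.x2 = (self.X**2).sum(axis=1)
        self.const = (
            -0.5 * self.R * (np.log(2.0 * np.pi) + 2.0 * np.log(self.sigma))
            - np.log(self.E + 1)
        )
        self._pos = np.empty(self.E, dtype=np.intp)
        self._arange1 = np.arange(1, self.E + 1)
        # vectorized anchor table when every region has the same number
        # of thresholds: anchors are [0, p_1..p_T, terminal], with the
        # terminal at E (value z_max) or, when the last threshold sits at
        # E itself, pushed to E+1 so the threshold anchor wins at t = E
        counts = {len(evs) for evs in self.region_events}
        if len(counts) == 1:
            T = counts.pop()
            self._RE = np.vstack(self.region_events)  # (R, T) event ids
            ys = np.empty((self.R, T + 2))
            ys[:, 0] = 0.0
            ys[:, 1:-1] = self.grid.event_value[self._RE]
            ys[:, -1] = np.asarray(self.grid.z_max)
            self._ys = ys
        else:
            self._RE = None

    def trajectories(self, seq: np.ndarray) -> np.ndarray:
        pos = self._pos
        pos[seq] = self._arange1
        E = self.E
        if self._RE is not None:
            P = pos[self._RE]  # (R, T) positions in threshold order
            A = P.shape[1] + 2
            xs = np.empty((self.R, A))
            xs[:, 0] = 0.0
            xs[:, 1:-1] = P
            xs[:, -1] = np.where(P[:, -1] == E, E + 1, E)
            # segment index per (region, stage): count of anchors <= t
            idx = (xs[:, :, None] <= self.t[None, None, :]).sum(axis=1) - 1
            idx = np.minimum(idx, A - 2)
            r = np.arange(self.R)[:, None]
            x0 = xs[r, idx]
            x1 = xs[r, idx + 1]
            y0 = self._ys[r, idx]
            y1 = self._ys[r, idx + 1]
            return y0 + (y1 - y0) * (self.t[None, :] - x0) / (x1 - x0)
        G = np.empty((self.R, E + 1))
        for i, evs in enumerate(self.region_events):
            p = pos[evs].astype(float)
            xs = np.concatenate(([0.0], p))
            ys = np.concatenate(([0.0], self.grid.event_value[evs]))
            if p[-1] < E:
                xs = np.append(xs, float(E))
                ys = np.append(ys, self.grid.z_max[i])
            G[i] = np.interp(self.t, xs, ys)
        return G

    def marginals(self, seq) -> np.ndarray:
        """Per-subject log marginal likelihood under a uniform stage prior."""
        seq = np.asarray(seq, dtype=np.intp)
        G = self.trajectories(seq)
        sq = self.x2[:, None] - 2.0 * (self.X @ G) + (G * G).sum(axis=0)[None, :]
        ll = -0.5 * sq / self.sigma**2
        m = ll.max(axis=1)
        return m + np.log(np.exp(ll - m[:, None]).sum(axis=1)) + self.const


# ---------------------------------------------------------------------------
# greedy sequence optimisation


def _move_bounds(rest: list[int], event: int, grid: EventGrid) -> tuple[int, int]:
    """Valid insertion-slot range for ``event`` into ``rest``.

    Slot p means inserting before rest[p]; the event must land after its
    region's lower threshold and before its higher one.
    """
    region = grid.event_region[event]
    level = grid.event_level[event]
    lo, hi = 0, len(rest)
    for idx, e in enumerate(rest):
        if grid.event_region[e] == region:
            if grid.event_level[e] < level:
                lo = max(lo, idx + 1)
            elif grid.event_level[e] > level:
                hi = min(hi, idx)
    return lo, hi


def _objective(engine: _Engine, seq, weights) -> float:
    lm = engine.marginals(seq)
    if weights is None:
        return float(lm.sum())
    return float(weights @ lm)


def _greedy_ascend(engine: _Engine, seq, weights, rng) -> tuple[np.ndarray, float]:
    """Coordinate ascent: repeatedly relocate single events until no
    relocation improves the (weighted) log-likelihood."""
    grid = engine.grid
    seq = [int(e) for e in seq]
    best = _objective(engine, seq, weights)
    improved = True
    while improved:
        improved = False
        for e in rng.permutation(grid.n_events):
            e = int(e)
            rest = [x for x in seq if x != e]
            lo, hi = _move_bounds(rest, e, grid)
            best_seq = None
            for p in range(lo, hi + 1):
                cand = rest[:p] + [e] + rest[p:]
                if cand == seq:
                    continue
                val = _objective(engine, cand, weights)
                if val > best + 1e-12:
                    best = val
                    best_seq = cand
            if best_seq is not None:
                seq = best_seq
                improved = True
    return np.asarray(seq, dtype=np.intp), best


def optimize_sequence(
    X: np.ndarray,
    grid: EventGrid,
    n_startpoints: int = 25,
    rng: np.random.Generator | None = None,
    sigma: float = 1.0,
    weights: np.ndarray | None = None,
    _engine: _Engine | None = None,
) -> tuple[np.ndarray, float]:
    """Best sequence across ``n_startpoints`` random greedy ascents."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 0:
        raise ValueError("X must contain at least one subject")
    rng = np.random.default_rng() if rng is None else rng
    engine = _Engine(X, grid, sigma) if _engine is None else _engine
    best_seq, best_ll = None, -np.inf
    for _ in range(max(1, int(n_startpoints))):
        start = random_valid_sequence(grid, rng)
        seq, ll = _greedy_ascend(engine, start, weights, rng)
        if ll > best_ll:
            best_seq, best_ll = seq, ll
    return best_seq, best_ll


# ---------------------------------------------------------------------------
# mixture fitting (hierarchical split + EM)


def _marginal_matrix(engine: _Engine, sequences) -> np.ndarray:
    return np.column_stack([engine.marginals(s) for s in sequences])


def _mixture_ll(L: np.ndarray, f: np.ndarray) -> float:
    with np.errstate(divide="ignore"):
        A = L + np.log(f)[None, :]
    m = A.max(axis=1)
    return float((m + np.log(np.exp(A - m[:, None]).sum(axis=1))).sum())


def _responsibilities(L: np.ndarray, f: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        logp = L + np.log(f)[None, :]
    logp -= logp.max(axis=1, keepdims=True)
    p = np.exp(logp)
    return p / p.sum(axis=1, keepdims=True)


def _em(engine: _Engine, sequences, fractions, config, rng, trace=None, max_iter=None):
    """Alternate fraction updates and responsibility-weighted sequence
    re-optimisation until the mixture log-likelihood stalls."""
    sequences = [np.asarray(s, dtype=np.intp) for s in sequences]
    f = np.asarray(fractions, dtype=float)
    f = f / f.sum()
    L = _marginal_matrix(engine, sequences)
    ll = _mixture_ll(L, f)
    if trace is not None:
        trace.append(ll)
    n = engine.X.shape[0]
    for _ in range(config.em_max_iter if max_iter is None else max_iter):
        resp = _responsibilities(L, f)
        f = resp.mean(axis=0)
        # empty-cluster rescue: re-seed from the worst-fit subjects
        for c in range(len(sequences)):
            if f[c] < 1.0 / (10.0 * n):
                worst = np.argsort(L.max(axis=1))[: max(2, n // 20)]
                sub = _Engine(engine.X[worst], engine.grid, engine.sigma)
                sequences[c], _ = _greedy_ascend(sub, sequences[c], None, rng)
                L[:, c] = engine.marginals(sequences[c])
                f[c] = 1.0 / n
                f = f / f.sum()
                logger.warning(
                    "empty cluster %d re-seeded from %d worst-fit subjects",
                    c,
                    worst.size,
                )
                resp = _responsibilities(L, f)
        for c in range(len(sequences)):
            sequences[c], _ = _greedy_ascend(engine, sequences[c], resp[:, c], rng)
            L[:, c] = engine.marginals(sequences[c])
        new_ll = _mixture_ll(L, f)
        if trace is not None:
            trace.append(new_ll)
        if new_ll - ll < config.em_tol:
            ll = max(ll, new_ll)
            break
        ll = new_ll
    return sequences, f, ll


def fit_sustain(
    X: np.ndarray,
    grid: EventGrid,
    C_target: int,
    config: RunConfig | None = None,
    rng: np.random.Generator | None = None,
) -> SubtypeModel:
    """Fit a C-subtype model by hierarchical splitting.

    C=1 is plain multi-start optimisation.  Each further subtype is
    introduced by bipartitioning one existing cluster's subjects,
    re-optimising a sequence inside each half, keeping the best-likelihood
    split, then running EM to convergence.
    """
    config = RunConfig() if config is None else config
    if not 1 <= C_target <= config.max_subtypes:
        raise ValueError("C_target must lie in 1..max_subtypes")
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    X = np.atleast_2d(np.asarray(X, dtype=float))
    sigma = config.sigma
    engine = _Engine(X, grid, sigma)

    seq, ll = optimize_sequence(
        X, grid, config.n_startpoints, rng, sigma, _engine=engine
    )
    sequences, f = [seq], np.array([1.0])
    if C_target == 1:
        return SubtypeModel(sequences, f, ll, grid, sigma)

    for C in range(2, C_target + 1):
        L = _marginal_matrix(engine, sequences)
        resp = _responsibilities(L, f)
        hard = resp.argmax(axis=1)
        best = None  # (ll, sequences, fractions)
        for c in range(len(sequences)):
            members = np.flatnonzero(hard == c)
            if members.size < 4:
                continue
            for attempt in range(config.n_split_tries):
                if attempt == 0:
                    # plain random bipartition
                    mask = rng.random(members.size) < 0.5
                else:
                    # anchor split: partition members by which of two
                    # random orderings explains them better; plain random
                    # halves of a mixed cluster both learn the same
                    # compromise sequence and EM stalls at the symmetric
                    # fixed point
                    r_a = random_valid_sequence(grid, rng)
                    r_b = random_valid_sequence(grid, rng)
                    la = engine.marginals(r_a)[members]
                    lb = engine.marginals(r_b)[members]
                    mask = la >= lb
                if mask.all() or not mask.any():
                    continue
                half_a, half_b = members[mask], members[~mask]
                seq_a, _ = optimize_sequence(
                    X[half_a], grid, max(1, config.n_startpoints // 5), rng, sigma
                )
                seq_b, _ = optimize_sequence(
                    X[half_b], grid, max(1, config.n_startpoints // 5), rng, sigma
                )
                cand_seqs = [s for k, s in enumerate(sequences) if k != c]
                cand_seqs += [seq_a, seq_b]
                cand_f = np.append(
                    np.delete(f, c),
                    [
                        f[c] * half_a.size / members.size,
                        f[c] * half_b.size / members.size,
                    ],
                )
                cand_f = cand_f / cand_f.sum()
                # a short EM burst reveals each candidate's basin; picking
                # on the raw split likelihood alone is prone to symmetric
                # stalls where both halves learn the same compromise order
                seqs_r, f_r, ll_r = _em(
                    engine, cand_seqs, cand_f, config, rng, max_iter=3
                )
                if best is None or ll_r > best[0]:
                    best = (ll_r, seqs_r, f_r)
        if best is None:
            raise ValueError(
                f"no cluster large enough to split when moving to C={C}"
            )
        sequences, f, ll = _em(engine, best[1], best[2], config, rng)
    return SubtypeModel(list(sequences), np.asarray(f), ll, grid, sigma)


# ---------------------------------------------------------------------------
# MCMC over orderings


def mcmc_sample(
    X: np.ndarray,
    init: SubtypeModel,
    n_iter: int,
    rng: np.random.Generator,
    sample_fractions: bool = True,
    dirichlet_scale: float = 100.0,
    burn_in_frac: float = 0.1,
) -> SubtypeModel:
    """Metropolis chain over (sequences, fractions).

    Each iteration relocates one uniformly chosen event of one uniformly
    chosen subtype to a uniformly chosen valid position; with
    ``sample_fractions`` the fractions are jointly perturbed by a small
    Dirichlet step.  Acceptance is min(1, exp(delta log-likelihood))
    under flat priors.  The first ``burn_in_frac`` of iterations is
    discarded; positional-variance diagrams are computed from the rest.
    """
    if n_iter < 100:
        raise ValueError("n_iter < 100 gives an uninformative chain")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    grid, sigma = init.grid, init.sigma
    C, E = init.n_subtypes, grid.n_events
    engine = _Engine(X, grid, sigma)

    seqs = [list(map(int, s)) for s in init.sequences]
    cur = np.asarray(seqs, dtype=np.int16)  # (C, E) mirror for sampling
    f = np.asarray(init.fractions, dtype=float).copy()
    L = _marginal_matrix(engine, [np.asarray(s) for s in seqs])
    ll = _mixture_ll(L, f)

    best = (ll, [np.asarray(s, dtype=np.intp) for s in seqs], f.copy())
    seq_samples = np.empty((n_iter, C, E), dtype=np.int16)
    frac_samples = np.empty((n_iter, C))
    ll_samples = np.empty(n_iter)
    n_accept = 0

    subtype_draws = rng.integers(C, size=n_iter)
    event_draws = rng.integers(E, size=n_iter)
    accept_draws = np.log(rng.random(n_iter))

    for it in range(n_iter):
        c = int(subtype_draws[it])
        e = int(event_draws[it])
        rest = [x for x in seqs[c] if x != e]
        lo, hi = _move_bounds(rest, e, grid)
        p = int(rng.integers(lo, hi + 1))
        cand = rest[:p] + [e] + rest[p:]
        cand_col = engine.marginals(cand)
        if sample_fractions and C > 1:
            f_cand = rng.dirichlet(dirichlet_scale * f + 1.0)
        else:
            f_cand = f
        old_col = L[:, c].copy()
        L[:, c] = cand_col
        ll_cand = _mixture_ll(L, f_cand)
        if accept_draws[it] < ll_cand - ll:
            seqs[c], f, ll = cand, f_cand, ll_cand
            cur[c] = cand
            n_accept += 1
            if ll > best[0]:
                best = (ll, [np.asarray(s, dtype=np.intp) for s in seqs], f.copy())
        else:
            L[:, c] = old_col
        seq_samples[it] = cur
        frac_samples[it] = f
        ll_samples[it] = ll

    burn = int(burn_in_frac * n_iter)
    samples = McmcSamples(
        sequences=seq_samples[burn:].astype(np.intp),
        fractions=frac_samples[burn:],
        log_likelihoods=ll_samples[burn:],
        acceptance_rate=n_accept / n_iter,
    )
    model = SubtypeModel(
        sequences=best[1],
        fractions=best[2],
        log_likelihood=best[0],
        grid=grid,
        sigma=sigma,
        samples=samples,
    )
    model.pvds = positional_variance(model)
    logger.info(
        "MCMC: %d iterations, acceptance rate %.3f, best loglik %.3f",
        n_iter,
        samples.acceptance_rate,
        best[0],
    )
    return model


def positional_variance(model: SubtypeModel) -> list[np.ndarray]:
    """Per subtype, P[e, k] = fraction of retained samples placing event
    e at position k+1.  Rows sum to 1."""
    if model.samples is None or model.samples.n_samples == 0:
        raise ValueError("model has no MCMC samples")
    grid = model.grid
    E = grid.n_events
    out = []
    for c in range(model.n_subtypes):
        P = np.zeros((E, E))
        seqs = model.samples.sequences[:, c, :]
        for s in seqs:
            P[s, np.arange(E)] += 1.0
        P /= seqs.shape[0]
        out.append(P)
    return out


# ---------------------------------------------------------------------------
# per-subject posteriors


def subject_posteriors(
    X: np.ndarray,
    model: SubtypeModel,
    cutoff: float = 0.5,
    subject_ids: list[str] | None = None,
    stage_zero_threshold: float = 0.5,
) -> SubjectPosteriors:
    """Subtype probabilities, stage posteriors and weighted stage.

    Assignment requires the maximal subtype probability to exceed
    ``cutoff`` strictly.  Subjects showing no abnormality are flagged
    stage-zero and left unassigned: either their weighted stage falls
    below ``stage_zero_threshold`` or the majority of their posterior
    stage mass (aggregated over subtypes) sits exactly at stage 0.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    grid, sigma = model.grid, model.sigma
    n, C, E = X.shape[0], model.n_subtypes, grid.n_events
    if subject_ids is None:
        subject_ids = [f"s{j:05d}" for j in range(n)]

    stage_ll = np.empty((n, C, E + 1))
    for c, s in enumerate(model.sequences):
        stage_ll[:, c, :] = stage_log_likelihoods(X, s, grid, sigma)
    lmarg = logsumexp(stage_ll, axis=2) - np.log(E + 1)  # (n, C)
    with np.errstate(divide="ignore"):
        logp = lmarg + np.log(model.fractions)[None, :]
    logp -= logp.max(axis=1, keepdims=True)
    probs = np.exp(logp)
    probs /= probs.sum(axis=1, keepdims=True)

    stage_ll -= stage_ll.max(axis=2, keepdims=True)
    stage_post = np.exp(stage_ll)
    stage_post /= stage_post.sum(axis=2, keepdims=True)

    k = np.arange(E + 1, dtype=float)
    exp_stage = stage_post @ k  # (n, C)
    weighted = (probs * exp_stage).sum(axis=1)

    agg_p0 = (probs * stage_post[:, :, 0]).sum(axis=1)
    stage_zero = (weighted < stage_zero_threshold) | (agg_p0 > 0.5)
    maxp = probs.max(axis=1)
    assigned = np.where(maxp > cutoff, probs.argmax(axis=1), UNASSIGNED)
    assigned = np.where(stage_zero, UNASSIGNED, assigned)
    return SubjectPosteriors(
        subject_ids=list(subject_ids),
        subtype_probs=probs,
        stage_posteriors=stage_post,
        weighted_stage=weighted,
        assigned_subtype=assigned.astype(np.intp),
        stage_zero=stage_zero,
        cutoff=cutoff,
    )
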