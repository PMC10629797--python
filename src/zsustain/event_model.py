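"""Piecewise-linear z-score progression model.

A progression pattern is a permutation of *events*: (region, threshold)
pairs, where the threshold is a z-score level the region crosses as the
pattern unfolds.  A subject at discrete stage ``k`` is modelled as
Gaussian noise around the per-region expected z-score obtained by linear
interpolation between the event anchors.  This module is the pure
computational core: trajectories, per-stage likelihoods, and the mixture
log-likelihood over several patterns.  No I/O happens here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence as TSequence

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "EventGrid",
    "validate_sequence",
    "random_valid_sequence",
    "enumerate_valid_sequences",
    "trajectory_matrix",
    "trajectory_value",
    "stage_log_likelihoods",
    "stage_posteriors",
    "sequence_log_marginals",
    "dataset_log_likelihood",
]

LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class EventGrid:
    """Immutable description of the event set.

    Parameters
    ----------
    region_names:
        Ordered region labels; one trajectory per region.
    thresholds:
        Per-region strictly increasing z-score thresholds.  Each
        threshold contributes one event, so ``n_events`` is the total
        threshold count.
    z_max:
        Per-region terminal z-score, strictly above the last threshold.
    """

    region_names: tuple[str, ...]
    thresholds: tuple[tuple[float, ...], ...]
    z_max: tuple[float, ...]

    # derived, filled in __post_init__
    event_region: np.ndarray = field(init=False, repr=False, compare=False)
    event_level: np.ndarray = field(init=False, repr=False, compare=False)
    event_value: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.thresholds) != len(self.region_names):
            raise ValueError("one threshold list per region required")
        if len(self.z_max) != len(self.region_names):
            raise ValueError("one z_max per region required")
        reg, lev, val = [], [], []
        for i, (ths, zm) in enumerate(zip(self.thresholds, self.z_max)):
            if len(ths) == 0:
                raise ValueError(f"region {self.region_names[i]} has no thresholds")
            if any(b <= a for a, b in zip(ths, ths[1:])):
                raise ValueError("thresholds must be strictly increasing")
            if zm <= ths[-1]:
                raise ValueError("z_max must exceed the last threshold")
            for r, z in enumerate(ths):
                reg.append(i)
                lev.append(r)
                val.append(float(z))
        object.__setattr__(self, "event_region", np.asarray(reg, dtype=np.intp))
        object.__setattr__(self, "event_level", np.asarray(lev, dtype=np.intp))
        object.__setattr__(self, "event_value", np.asarray(val, dtype=float))

    @classmethod
    def from_defaults(
        cls,
        region_names: TSequence[str],
        thresholds: TSequence[float] = (1.0, 2.0, 3.0),
        z_max: float = 5.0,
    ) -> "EventGrid":
        names = tuple(str(n) for n in region_names)
        return cls(
            region_names=names,
            thresholds=tuple(tuple(float(t) for t in thresholds) for _ in names),
            z_max=tuple(float(z_max) for _ in names),
        )

    @property
    def n_regions(self) -> int:
        return len(self.region_names)

    @property
    def n_events(self) -> int:
        return int(self.event_region.size)

    @property
    def n_stages(self) -> int:
        """Number of discrete stages, 0..E inclusive."""
        return self.n_events + 1

    def region_events(self, i: int) -> np.ndarray:
        """Event indices of region *i*, ordered by threshold level."""
        idx = np.flatnonzero(self.event_region == i)
        return idx[np.argsort(self.event_level[idx])]


def _as_sequence(seq, n_events: int) -> np.ndarray:
    s = np.asarray(seq, dtype=np.intp)
    if s.shape != (n_events,):
        raise ValueError(f"sequence must contain exactly {n_events} events")
    if not np.array_equal(np.sort(s), np.arange(n_events)):
        raise ValueError("sequence is not a permutation of the event set")
    return s


def event_positions(seq, grid: EventGrid) -> np.ndarray:
    """1-based position of each event under sequence ``seq``."""
    s = _as_sequence(seq, grid.n_events)
    pos = np.empty(grid.n_events, dtype=np.intp)
    pos[s] = np.arange(1, grid.n_events + 1)
    return pos


def validate_sequence(seq, grid: EventGrid) -> bool:
    """True iff each region crosses its thresholds in increasing order."""
    pos = event_positions(seq, grid)
    for i in range(grid.n_regions):
        p = pos[grid.region_events(i)]
        if np.any(np.diff(p) <= 0):
            return False
    return True


def random_valid_sequence(grid: EventGrid, rng: np.random.Generator) -> np.ndarray:
    """Uniform draw of a valid sequence.

    A uniform permutation is drawn, then within each region the occupied
    positions are re-filled in threshold order; every valid sequence
    corresponds to the same number of raw permutations, so the result is
    uniform over valid sequences.
    """
    perm = rng.permutation(grid.n_events)
    seq = np.array(perm, dtype=np.intp)
    order = np.empty(grid.n_events, dtype=np.intp)
    order[perm] = np.arange(grid.n_events)  # order[e] = slot of event e
    for i in range(grid.n_regions):
        evs = grid.region_events(i)
        slots = np.sort(order[evs])
        seq[slots] = evs
    return seq


def enumerate_valid_sequences(grid: EventGrid) -> list[np.ndarray]:
    """All valid sequences (exponential; only for tiny grids)."""
    from itertools import permutations

    if grid.n_events > 8:
        raise ValueError("enumeration is only supported for n_events <= 8")
    out = []
    for perm in permutations(range(grid.n_events)):
        seq = np.asarray(perm, dtype=np.intp)
        if validate_sequence(seq, grid):
            out.append(seq)
    return out


def trajectory_matrix(seq, grid: EventGrid) -> np.ndarray:
    """Expected z-score per (region, stage) for a sequence.

    Returns an ``(n_regions, n_events + 1)`` array ``G`` with
    ``G[i, t]`` the piecewise-linear interpolant through the anchors
    ``(0, 0)``, ``(pos(z_{i,r}), z_{i,r})`` and ``(E, z_max_i)``.  When a
    region's last threshold sits at position E the terminal anchor is
    dropped (the threshold anchor wins).
    """
    E = grid.n_events
    pos = event_positions(seq, grid)
    t = np.arange(E + 1, dtype=float)
    G = np.empty((grid.n_regions, E + 1))
    for i in range(grid.n_regions):
        evs = grid.region_events(i)
        p = pos[evs]
        if np.any(np.diff(p) <= 0):
            raise ValueError("invalid sequence: threshold order violated")
        xs = np.concatenate(([0.0], p.astype(float)))
        ys = np.concatenate(([0.0], grid.event_value[evs]))
        if p[-1] < E:
            xs = np.append(xs, float(E))
            ys = np.append(ys, grid.z_max[i])
        G[i] = np.interp(t, xs, ys)
    return G


def trajectory_value(region: int, stage: int, seq, grid: EventGrid) -> float:
    """Expected z-score of ``region`` at integer ``stage``."""
    if not 0 <= stage <= grid.n_events:
        raise ValueError(f"stage must lie in 0..{grid.n_events}")
    return float(trajectory_matrix(seq, grid)[region, stage])


def _check_sigma(sigma: float) -> float:
    sigma = float(sigma)
    if sigma <= 0:
        raise ValueError("noise SD sigma must be positive")
    return sigma


def stage_log_likelihoods(
    X: np.ndarray, seq, grid: EventGrid, sigma: float = 1.0
) -> np.ndarray:
    """log p(x_j | stage k, S) for every subject and stage.

    ``X`` is ``(n_subjects, n_regions)``; the result is
    ``(n_subjects, n_events + 1)``.
    """
    sigma = _check_sigma(sigma)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != grid.n_regions:
        raise ValueError("X must have one column per region")
    G = trajectory_matrix(seq, grid)
    # (n, R, E+1) residuals; exact (no cancellation-prone expansion)
    sq = ((X[:, :, None] - G[None, :, :]) ** 2).sum(axis=1)
    return -0.5 * sq / sigma**2 - 0.5 * grid.n_regions * (
        LOG_2PI + 2.0 * np.log(sigma)
    )


def stage_posteriors(
    X: np.ndarray, seq, grid: EventGrid, sigma: float = 1.0
) -> np.ndarray:
    """Posterior over stages under a uniform stage prior; rows sum to 1."""
    ll = stage_log_likelihoods(X, seq, grid, sigma)
    ll -= ll.max(axis=1, keepdims=True)
    w = np.exp(ll)
    return w / w.sum(axis=1, keepdims=True)


def sequence_log_marginals(
    X: np.ndarray, seq, grid: EventGrid, sigma: float = 1.0
) -> np.ndarray:
    """Per-subject log marginal likelihood under a uniform stage prior."""
    ll = stage_log_likelihoods(X, seq, grid, sigma)
    return logsumexp(ll, axis=1) - np.log(grid.n_stages)


def _check_fractions(fractions, n: int) -> np.ndarray:
    f = np.asarray(fractions, dtype=float)
    if f.shape != (n,):
        raise ValueError("one mixture fraction per sequence required")
    if np.any(f < -1e-12) or abs(f.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must be non-negative and sum to 1")
    return np.clip(f, 0.0, None)


def dataset_log_likelihood(
    X: np.ndarray,
    sequences: TSequence[np.ndarray],
    fractions,
    grid: EventGrid,
    sigma: float = 1.0,
) -> float:
    """Total mixture log-likelihood sum_j log sum_c f_c exp(l_j(S_c))."""
    f = _check_fractions(fractions, len(sequences))
    L = np.column_stack(
        [sequence_log_marginals(X, s, grid, sigma) for s in sequences]
    )
    with np.errstate(divide="ignore"):
        return float(logsumexp(L + np.log(f)[None, :], axis=1).sum())
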