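"""Independent brute-force oracles used to freeze expected values.

Everything here is deliberately naive (pure-python enumeration, direct
probability sums) and never calls into the package's likelihood or
optimisation paths.
"""

from __future__ import annotations

import math
from itertools import permutations


def oracle_valid_orderings(events):
    """All orderings of ``events`` (list of (region, level) tuples) where
    each region's levels appear in increasing order."""
    out = []
    for perm in permutations(range(len(events))):
        ordered = [events[i] for i in perm]
        ok = True
        seen: dict = {}
        for region, level in ordered:
            if region in seen and level <= seen[region]:
                ok = False
                break
            if region in seen:
                seen[region] = level
            else:
                if level != min(l for r, l in events if r == region):
                    ok = False
                    break
                seen[region] = level
        if ok:
            out.append(perm)
    return out


def oracle_trajectory(region, stage, ordered_events, n_events, z_max):
    """Pure-python piecewise-linear interpolation.

    ``ordered_events`` is the sequence as a list of (region, z_value)
    pairs; position of the p-th entry is p+1.
    """
    anchors = [(0.0, 0.0)]
    for p, (r, v) in enumerate(ordered_events, start=1):
        if r == region:
            anchors.append((float(p), float(v)))
    if anchors[-1][0] < n_events:
        anchors.append((float(n_events), float(z_max)))
    t = float(stage)
    for (x0, y0), (x1, y1) in zip(anchors, anchors[1:]):
        if x0 <= t <= x1:
            if x1 == x0:
                return y1
            return y0 + (y1 - y0) * (t - x0) / (x1 - x0)
    return anchors[-1][1]


def _normal_pdf(x, mu, sigma):
    return math.exp(-0.5 * ((x - mu) / sigma) ** 2) / (sigma * math.sqrt(2 * math.pi))


def oracle_stage_likelihood(x_row, stage, ordered_events, n_events, z_max, sigma):
    """p(x | stage) as a direct product of normal densities."""
    p = 1.0
    for region, value in enumerate(x_row):
        mu = oracle_trajectory(region, stage, ordered_events, n_events, z_max)
        p *= _normal_pdf(value, mu, sigma)
    return p


def oracle_subject_marginal(x_row, ordered_events, n_events, z_max, sigma):
    """log p(x | S) under a uniform stage prior, via direct summation."""
    total = math.fsum(
        oracle_stage_likelihood(x_row, k, ordered_events, n_events, z_max, sigma)
        for k in range(n_events + 1)
    )
    return math.log(total / (n_events + 1))


def oracle_dataset_loglik(X, orderings, fractions, n_events, z_max, sigma):
    """Mixture log-likelihood by exhaustive (sequence, stage) summation."""
    total = 0.0
    for x_row in X:
        mix = math.fsum(
            f * math.exp(oracle_subject_marginal(x_row, ordered, n_events, z_max, sigma))
            for f, ordered in zip(fractions, orderings)
        )
        total += math.log(mix)
    return total


def oracle_best_sequence(X, events, values, n_events, z_max, sigma):
    """Exhaustive argmax over all valid orderings for a single pattern.

    ``events`` are (region, level) tuples, ``values`` the matching
    z-thresholds.  Returns (best ordering as event-index tuple, loglik).
    """
    best, best_ll = None, -math.inf
    for perm in oracle_valid_orderings(events):
        ordered = [(events[i][0], values[i]) for i in perm]
        ll = math.fsum(
            oracle_subject_marginal(x, ordered, n_events, z_max, sigma) for x in X
        )
        if ll > best_ll:
            best, best_ll = perm, ll
    return best, best_ll
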