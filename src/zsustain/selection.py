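"""Cross-validated choice of the number of subtypes.

CIC(C) is held-out deviance: -2 times the summed out-of-fold mixture
log-likelihood.  Fold-to-reference subtype similarity is the expected
per-event overlap of positional-variance distributions after optimal
one-to-one matching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .config import RunConfig
from .event_model import EventGrid, dataset_log_likelihood
from .fit import SubtypeModel, fit_sustain, mcmc_sample

logger = logging.getLogger("zsustain")

__all__ = ["CvReport", "crossval", "select_n_subtypes", "cv_similarity", "pvd_overlap"]


@dataclass
class CvReport:
    """Per-C held-out log-likelihoods and derived information criterion."""

    c_values: list[int]
    heldout_loglik: dict[int, np.ndarray]  # C -> per-fold out-of-fold loglik
    cic: dict[int, float]  # C -> -2 * sum of held-out loglik
    fold_assignments: np.ndarray  # fold index per subject
    fold_models: dict[int, list[SubtypeModel]] = field(default_factory=dict)
    chosen_c: int | None = None
    similarity: dict | None = None


def _make_folds(n: int, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    if n < 2 * n_folds:
        raise ValueError("need at least 2 subjects per fold; reduce folds")
    perm = rng.permutation(n)
    folds = np.empty(n, dtype=np.intp)
    for k, chunk in enumerate(np.array_split(perm, n_folds)):
        if chunk.size < 2:
            raise ValueError("fold with < 2 subjects; reduce folds")
        folds[chunk] = k
    return folds


def crossval(
    X: np.ndarray,
    grid: EventGrid,
    config: RunConfig | None = None,
    rng: np.random.Generator | None = None,
    c_values: list[int] | None = None,
) -> CvReport:
    """k-fold cross-validation over C = 1..max_subtypes.

    For every fold and every C the model is fitted on the training split
    and scored on the held-out split; fold models are retained for the
    similarity analysis.
    """
    config = RunConfig() if config is None else config
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    folds = _make_folds(n, config.cv_folds, rng)
    if c_values is None:
        c_values = list(range(1, config.max_subtypes + 1))

    heldout: dict[int, np.ndarray] = {}
    fold_models: dict[int, list[SubtypeModel]] = {}
    for C in c_values:
        per_fold = np.empty(config.cv_folds)
        models = []
        for k in range(config.cv_folds):
            train, test = folds != k, folds == k
            model = fit_sustain(X[train], grid, C, config, rng)
            per_fold[k] = dataset_log_likelihood(
                X[test], model.sequences, model.fractions, grid, config.sigma
            )
            models.append(model)
        heldout[C] = per_fold
        fold_models[C] = models
        logger.info("crossval C=%d: CIC=%.3f", C, -2.0 * per_fold.sum())
    cic = {C: -2.0 * float(heldout[C].sum()) for C in c_values}
    report = CvReport(
        c_values=list(c_values),
        heldout_loglik=heldout,
        cic=cic,
        fold_assignments=folds,
        fold_models=fold_models,
    )
    report.chosen_c = select_n_subtypes(report, config.parsimony_delta)
    return report


def select_n_subtypes(report: CvReport, parsimony_delta: float = 6.0) -> int:
    """argmin CIC, preferring any smaller C within ``parsimony_delta``."""
    cic = report.cic
    best = min(cic.values())
    candidates = [C for C in sorted(cic) if cic[C] - best < parsimony_delta]
    chosen = min(candidates)
    if chosen != min(cic, key=cic.get):
        logger.info(
            "parsimony rule: C=%d within %.1f of minimum, preferred over C=%d",
            chosen,
            parsimony_delta,
            min(cic, key=cic.get),
        )
    return chosen


def pvd_overlap(P: np.ndarray, Q: np.ndarray) -> float:
    """Mean over events of the per-position distribution overlap
    sum_k min(P[e,k], Q[e,k]); symmetric, in [0, 1]."""
    if P.shape != Q.shape:
        raise ValueError("PVDs must have identical shapes")
    return float(np.minimum(P, Q).sum(axis=1).mean())


def cv_similarity(
    fold_models: list[SubtypeModel],
    reference: SubtypeModel,
    mcmc_iter: int = 2000,
    rng: np.random.Generator | None = None,
    X_folds: list[np.ndarray] | None = None,
) -> dict:
    """Per-reference-subtype similarity across folds.

    Fold subtypes are matched to reference subtypes by maximising total
    PVD overlap (optimal one-to-one assignment); the similarity of a
    matched pair is :func:`pvd_overlap`.  Fold models lacking MCMC
    samples are sampled here (``X_folds`` supplies their training data).

    Returns a dict with ``per_subtype`` (n_folds x C matrix of matched
    similarities), ``mean`` and percentile 95% CI per subtype.
    """
    if reference.pvds is None:
        raise ValueError("reference model has no positional-variance diagrams")
    C = reference.n_subtypes
    rng = np.random.default_rng() if rng is None else rng
    rows = []
    for i, fm in enumerate(fold_models):
        if fm.n_subtypes != C:
            raise ValueError("fold model subtype count differs from reference")
        if fm.pvds is None:
            if X_folds is None:
                raise ValueError("fold model lacks samples and no X_folds given")
            fm = mcmc_sample(X_folds[i], fm, mcmc_iter, rng)
            fold_models[i] = fm
        overlap = np.empty((C, C))
        for a in range(C):
            for b in range(C):
                overlap[a, b] = pvd_overlap(fm.pvds[a], reference.pvds[b])
        fold_idx, ref_idx = linear_sum_assignment(-overlap)
        row = np.empty(C)
        row[ref_idx] = overlap[fold_idx, ref_idx]
        rows.append(row)
    per_subtype = np.vstack(rows)  # (n_folds, C), columns follow reference order
    mean = per_subtype.mean(axis=0)
    lo = np.percentile(per_subtype, 2.5, axis=0)
    hi = np.percentile(per_subtype, 97.5, axis=0)
    return {
        "per_subtype": per_subtype,
        "mean": mean,
        "ci_low": lo,
        "ci_high": hi,
    }
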