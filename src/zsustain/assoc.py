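"""Clinical characterization of subtypes.

Correlation-matrix PCA with Kaiser retention, seeded percentile-bootstrap
Spearman correlations, chi-squared and Kruskal-Wallis group tests, and a
combined per-subtype report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("zsustain")

__all__ = [
    "PcaResult",
    "AssociationResult",
    "pca_severity",
    "spearman_bootstrap",
    "contingency_test",
    "kruskal_test",
    "characterize_subtypes",
    "FOCAL_PCA_FEATURES",
    "GENERALIZED_PCA_FEATURES",
]

FOCAL_PCA_FEATURES = (
    "convulsions_prior_year",
    "seizure_frequency",
    "asm_count",
    "duration_years",
)
GENERALIZED_PCA_FEATURES = (
    "convulsions_prior_year",
    "asm_count",
    "duration_years",
)


@dataclass
class PcaResult:
    feature_names: list[str]
    loadings: np.ndarray  # (p, p) eigenvectors as columns, eigenvalue order
    eigenvalues: np.ndarray  # non-increasing
    retained: list[int]  # component indices with eigenvalue > 1
    scores: np.ndarray  # (n, p) subject scores on all components
    explained_variance: np.ndarray
    subject_ids: list[str] | None = None

    def retained_scores(self) -> np.ndarray:
        return self.scores[:, self.retained]


@dataclass
class AssociationResult:
    rho: float
    p_value: float
    ci_low: float
    ci_high: float
    n: int
    reps: int


def pca_severity(
    features: pd.DataFrame,
    feature_names=None,
    id_column: str = "subject_id",
) -> PcaResult:
    """Correlation-matrix PCA of clinical severity features.

    Complete cases only; eigenvalue > 1 components retained (Kaiser);
    component signs fixed so the largest-magnitude loading is positive.
    """
    if feature_names is None:
        feature_names = [c for c in features.columns if c != id_column]
    feature_names = list(feature_names)
    cols = feature_names + ([id_column] if id_column in features.columns else [])
    df = features[cols].dropna(subset=feature_names).reset_index(drop=True)
    if len(df) < 3:
        raise ValueError("PCA needs at least 3 complete cases")
    M = df[feature_names].to_numpy(dtype=float)
    sd = M.std(axis=0, ddof=1)
    if np.any(sd < 1e-12):
        bad = [feature_names[i] for i in np.flatnonzero(sd < 1e-12)]
        raise ValueError(f"zero-variance feature(s): {bad}")
    Zstd = (M - M.mean(axis=0)) / sd
    R = np.corrcoef(Zstd, rowvar=False)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    for k in range(eigvec.shape[1]):
        if eigvec[np.abs(eigvec[:, k]).argmax(), k] < 0:
            eigvec[:, k] = -eigvec[:, k]
    scores = Zstd @ eigvec
    retained = [int(k) for k in np.flatnonzero(eigval > 1.0)]
    if not retained:
        logger.warning("no PCA component with eigenvalue > 1 (null structure)")
    return PcaResult(
        feature_names=feature_names,
        loadings=eigvec,
        eigenvalues=eigval,
        retained=retained,
        scores=scores,
        explained_variance=eigval / eigval.sum(),
        subject_ids=df[id_column].tolist() if id_column in df.columns else None,
    )


def spearman_bootstrap(
    x, y, reps: int = 5000, seed: int = 0
) -> AssociationResult:
    """Spearman rho with t-approximation p and percentile bootstrap CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 paired complete observations")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("constant vector: Spearman correlation undefined")
    rho, p = stats.spearmanr(x, y)
    rng = np.random.default_rng(seed)
    # vectorized paired resampling: rank within each replicate, then
    # Pearson correlation of the ranks (average ranks for ties)
    idx = rng.integers(0, n, size=(reps, n))
    rx = stats.rankdata(x[idx], axis=1)
    ry = stats.rankdata(y[idx], axis=1)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx**2).sum(axis=1) * (ry**2).sum(axis=1))
    valid = denom > 0  # degenerate resamples (a constant vector) dropped
    boot = (rx * ry).sum(axis=1)[valid] / denom[valid]
    lo, hi = np.percentile(boot, [2.5, 97.5])
    lo, hi = float(np.clip(lo, -1, 1)), float(np.clip(hi, -1, 1))
    # tie-handling float noise can leave rho at 1 - 1e-16; snap to +/-1
    lo = round(lo, 12) if abs(abs(lo) - 1.0) < 1e-12 else lo
    hi = round(hi, 12) if abs(abs(hi) - 1.0) < 1e-12 else hi
    return AssociationResult(
        rho=float(rho), p_value=float(p), ci_low=lo, ci_high=hi, n=n, reps=reps
    )


def contingency_test(table) -> tuple[float, int, float]:
    """Pearson chi-squared without continuity correction."""
    T = np.asarray(table, dtype=float)
    if T.ndim != 2 or T.shape[0] < 2 or T.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (T < 0).any():
        raise ValueError("counts must be non-negative")
    chi2, p, dof, expected = stats.chi2_contingency(T, correction=False)
    if (expected < 1).any():
        logger.warning(
            "expected cell count < 1; an exact test would be preferable"
        )
    return float(chi2), int(dof), float(p)


def kruskal_test(*groups) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) across groups."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if all(np.array_equal(arrays[0], a) for a in arrays[1:]) and np.unique(
        np.concatenate(arrays)
    ).size == 1:
        return 0.0, 1.0  # scipy refuses all-identical input
    try:
        H, p = stats.kruskal(*arrays)
    except ValueError:
        return 0.0, 1.0
    return float(H), float(p)


def characterize_subtypes(
    posteriors,
    clinical,
    pca: PcaResult | None = None,
    reps: int = 5000,
    seed: int = 0,
) -> dict:
    """Per-subtype prevalence and clinical associations.

    ``posteriors`` is a :class:`~zsustain.fit.SubjectPosteriors`;
    ``clinical`` a :class:`~zsustain.io.ClinicalTable`.  Returns a dict
    of result tables/statistics; missing clinical values propagate as
    missing (never imputed).
    """
    pframe = posteriors.to_frame()
    merged = pframe.merge(clinical.frame, on="subject_id", how="inner")
    if len(merged) < 10:
        raise ValueError("fewer than 10 joined subjects; cannot characterize")
    C = posteriors.subtype_probs.shape[1]

    prevalence = (
        merged["assigned_subtype"].value_counts(normalize=True).sort_index()
    )
    out: dict = {"n": len(merged), "prevalence": prevalence}

    def _maybe_spearman(key, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < 10:
            return
        if np.unique(x[ok]).size < 2 or np.unique(y[ok]).size < 2:
            logger.info("skipping %s: constant input", key)
            return
        out[key] = spearman_bootstrap(x, y, reps=reps, seed=seed)

    for var in ("duration_years", "onset_age_years", "seizure_frequency"):
        if var in merged:
            _maybe_spearman(
                f"stage_vs_{var}", merged["weighted_stage"], merged[var]
            )

    if pca is not None and pca.subject_ids is not None and pca.retained:
        score_df = pd.DataFrame(
            pca.retained_scores(),
            columns=[f"PC{k + 1}" for k in range(len(pca.retained))],
        )
        score_df["subject_id"] = pca.subject_ids
        pm = merged.merge(score_df, on="subject_id", how="inner")
        for c in range(C):
            for k in range(len(pca.retained)):
                _maybe_spearman(
                    f"subtype{c + 1}_expression_vs_PC{k + 1}",
                    pm[f"p_subtype_{c + 1}"],
                    pm[f"PC{k + 1}"],
                )

    if "convulsions_prior_year" in merged:
        assigned = merged[merged["assigned_subtype"] != "unclassified"]
        counts = pd.crosstab(
            assigned["assigned_subtype"], assigned["convulsions_prior_year"]
        )
        if counts.shape[0] >= 2 and counts.shape[1] >= 2:
            out["convulsions_by_subtype_chi2"] = contingency_test(counts.to_numpy())
    if "seizure_frequency" in merged:
        assigned = merged[merged["assigned_subtype"] != "unclassified"]
        groups = [
            g["seizure_frequency"].dropna().to_numpy()
            for _, g in assigned.groupby("assigned_subtype")
        ]
        if len(groups) >= 2 and all(len(g) for g in groups):
            out["frequency_by_subtype_kruskal"] = kruskal_test(*groups)
    return out
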