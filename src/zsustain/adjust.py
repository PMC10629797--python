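"""Control-referenced covariate adjustment and z-scoring.

Per (region, scanner stratum) a conjugate Gaussian linear model with a
vague prior (posterior mean ~ least squares) is fitted on controls with
intercept, TIV, sex, centred age and centred age squared.  Subject
measures are converted to residual z-scores against their own stratum
and sign-flipped so that positive values mean more atrophy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ClinicalTable, RoiMeasureTable

logger = logging.getLogger("zsustain")

__all__ = [
    "ControlNormModel",
    "ZMatrix",
    "fit_control_model",
    "compute_zscores",
    "regroup_ipsi_contra",
]

PRIOR_PRECISION = 1e-6
MIN_RESIDUAL_SD = 1e-8


@dataclass
class StratumRegionFit:
    beta: np.ndarray  # intercept, tiv, sex, age_c, age_c^2
    resid_mean: float
    resid_sd: float
    n_controls: int


@dataclass
class ControlNormModel:
    fits: dict[tuple[str, str], StratumRegionFit]  # (region, stratum) -> fit
    stratum_age_mean: dict[str, float]
    regions: list[str]
    include_tiv: bool = True

    @property
    def strata(self) -> list[str]:
        return sorted(self.stratum_age_mean)

    def design(self, age, sex, tiv, stratum: str) -> np.ndarray:
        """Design row(s) for given covariates in a stratum.

        Age is centred at the stratum's control mean before squaring.
        When TIV is excluded its column is zeroed, keeping a fixed
        5-coefficient layout.
        """
        age = np.asarray(age, dtype=float)
        sex = np.asarray(sex, dtype=float)
        tiv = np.asarray(tiv, dtype=float)
        age_c = age - self.stratum_age_mean[stratum]
        tiv_col = tiv if self.include_tiv else np.zeros_like(tiv)
        return np.column_stack(
            [np.ones_like(age), tiv_col, sex, age_c, age_c**2]
        )


@dataclass
class ZMatrix:
    """Subjects x regions adjusted z-scores, sign-flipped exactly once."""

    values: np.ndarray
    subject_ids: list[str]
    regions: list[str]
    strata: list[str]  # stratum per subject
    flipped: bool = True

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.regions)
        df.insert(0, "subject_id", self.subject_ids)
        return df


def _posterior_mean(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Posterior-mean coefficients under a vague conjugate prior.

    Columns are equilibrated before solving so that covariates on very
    different scales (TIV ~1e6 vs sex ~1) do not degrade conditioning.
    """
    # standardize the non-intercept columns so the intercept is decoupled
    # and the system is well conditioned; map coefficients back afterwards
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    mean[0], scale[0] = 0.0, 1.0  # leave the intercept column alone
    scale[scale < 1e-12] = 1.0
    Xs = (X - mean) / scale
    XtX = Xs.T @ Xs + PRIOR_PRECISION * np.eye(X.shape[1])
    beta_s = np.linalg.solve(XtX, Xs.T @ y)
    beta = beta_s / scale
    beta[0] = beta_s[0] - float((beta_s[1:] * mean[1:] / scale[1:]).sum())
    return beta


def fit_control_model(
    controls: RoiMeasureTable,
    min_per_stratum: int = 20,
    include_tiv: bool = True,
) -> ControlNormModel:
    """Fit the per-(region, stratum) control normalisation model.

    Raises when a stratum has fewer controls than ``min_per_stratum``
    or when a region's residual SD degenerates to zero.
    """
    df = controls.frame
    if (df["group"] != "control").any():
        raise ValueError("fit_control_model expects control rows only")
    strata = sorted(df["scanner"].unique())
    stratum_age_mean = {
        s: float(df.loc[df["scanner"] == s, "age"].mean()) for s in strata
    }
    model = ControlNormModel(
        fits={},
        stratum_age_mean=stratum_age_mean,
        regions=list(controls.regions),
        include_tiv=include_tiv,
    )
    for s in strata:
        sub = df[df["scanner"] == s]
        if len(sub) < min_per_stratum:
            raise ValueError(
                f"stratum {s!r} has {len(sub)} controls (< {min_per_stratum}); "
                "pool strata or lower the floor"
            )
        X = model.design(sub["age"], sub["sex"], sub["tiv"], s)
        # TIV column may be all-zero when excluded; the vague prior keeps
        # the system solvable, but a genuinely collinear design is refused
        used = X if include_tiv else X[:, [0, 2, 3, 4]]
        if np.linalg.matrix_rank(used) < used.shape[1]:
            raise ValueError(f"singular design matrix in stratum {s!r}")
        for region in controls.regions:
            y = sub[region].to_numpy(dtype=float)
            beta = _posterior_mean(X, y)
            resid = y - X @ beta
            sd = float(resid.std(ddof=1))
            if sd < MIN_RESIDUAL_SD:
                raise ValueError(
                    f"zero residual SD for region {region!r} in stratum {s!r}"
                )
            model.fits[(region, s)] = StratumRegionFit(
                beta=beta,
                resid_mean=float(resid.mean()),
                resid_sd=sd,
                n_controls=len(sub),
            )
    return model


def compute_zscores(
    subjects: RoiMeasureTable, model: ControlNormModel
) -> ZMatrix:
    """Adjusted, sign-flipped z-scores using each subject's own stratum.

    z = (observed - predicted - residual_mean) / residual_SD, returned
    as z* = -z so that larger values mean more atrophy.
    """
    df = subjects.frame
    unknown = set(df["scanner"].unique()) - set(model.stratum_age_mean)
    if unknown:
        raise KeyError(f"unknown scanner stratum: {sorted(unknown)}")
    n = len(df)
    regions = model.regions
    Z = np.empty((n, len(regions)))
    strata_col = df["scanner"].astype(str).to_numpy()
    for s in np.unique(strata_col):
        rows = np.flatnonzero(strata_col == s)
        sub = df.iloc[rows]
        X = model.design(sub["age"], sub["sex"], sub["tiv"], s)
        for j, region in enumerate(regions):
            fit = model.fits[(region, s)]
            pred = X @ fit.beta
            obs = sub[region].to_numpy(dtype=float)
            z = (obs - pred - fit.resid_mean) / fit.resid_sd
            Z[rows, j] = -z
    return ZMatrix(
        values=Z,
        subject_ids=df["subject_id"].tolist(),
        regions=list(regions),
        strata=strata_col.tolist(),
        flipped=True,
    )


def regroup_ipsi_contra(z: ZMatrix, clinical: ClinicalTable) -> ZMatrix:
    """Relabel left/right regions as ipsi-/contralateral to the seizure
    focus; only subjects with proven left or right lateralization are
    kept (others dropped with a logged count)."""
    lat = clinical.frame.set_index("subject_id")["laterality"]
    keep_rows, sides = [], []
    n_excluded = 0
    for j, sid in enumerate(z.subject_ids):
        side = lat.get(sid)
        if side in ("left", "right"):
            keep_rows.append(j)
            sides.append(side)
        else:
            n_excluded += 1
    if not keep_rows:
        raise ValueError("no subjects with proven left/right lateralization")
    if n_excluded:
        logger.info(
            "ipsi/contra regrouping excluded %d subjects without proven "
            "lateralization",
            n_excluded,
        )

    def split(name: str) -> tuple[str, str]:
        hemi, base = name.split("_", 1)
        return hemi, base

    left_idx = {split(r)[1]: i for i, r in enumerate(z.regions) if split(r)[0] == "left"}
    right_idx = {split(r)[1]: i for i, r in enumerate(z.regions) if split(r)[0] == "right"}
    if set(left_idx) != set(right_idx):
        raise ValueError("regions are not fully left/right paired")
    bases = sorted(left_idx)
    new_regions = [f"ipsi_{b}" for b in bases] + [f"contra_{b}" for b in bases]

    out = np.empty((len(keep_rows), len(new_regions)))
    for r, (j, side) in enumerate(zip(keep_rows, sides)):
        for k, b in enumerate(bases):
            li, ri = left_idx[b], right_idx[b]
            ipsi, contra = (li, ri) if side == "left" else (ri, li)
            out[r, k] = z.values[j, ipsi]
            out[r, k + len(bases)] = z.values[j, contra]
    return ZMatrix(
        values=out,
        subject_ids=[z.subject_ids[j] for j in keep_rows],
        regions=new_regions,
        strata=[z.strata[j] for j in keep_rows],
        flipped=z.flipped,
    )
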