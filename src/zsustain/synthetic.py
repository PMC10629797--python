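"""Synthetic cohorts with known subtype/stage ground truth.

Patients are drawn from the piecewise-linear z-score model itself:
latent z* = trajectory(true subtype, true stage) + Gaussian noise, then
mapped back to raw measurement units by inverting a known control
normalisation model, so the full adjust -> fit path is exercised.
Every dataset carries its generating truth for later scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .adjust import ControlNormModel, StratumRegionFit
from .event_model import EventGrid, random_valid_sequence, trajectory_matrix
from .io import (
    ClinicalTable,
    RoiDictionary,
    RoiMeasureTable,
    default_roi_dictionary,
    generic_roi_dictionary,
)

logger = logging.getLogger("zsustain")

__all__ = [
    "ClinicalEffectParams",
    "SyntheticTruth",
    "simulate_zmatrix",
    "simulate_cohort",
    "simulate_clinical",
]


@dataclass
class ClinicalEffectParams:
    """Ground-truth clinical effects re-detected by the assoc stage."""

    duration_scale: float = 1.0  # a: duration = a * (stage/E) * 30 + noise
    duration_sd: float = 5.0
    convulsion_intercept: float = -1.0  # b0 (log-odds)
    convulsion_subtype_logodds: float = 2.0  # b1 for the designated subtype
    designated_subtype: int = 0  # 0-based index
    freq_subtype_shift: float = 1.0  # proportional-odds latent shift
    freq_cutpoints: tuple[float, ...] = (-1.0, 0.0, 1.0, 2.0)
    asm_base_log_rate: float = 0.2
    asm_per_freq: float = 0.3
    laterality_probs: tuple[float, ...] = (0.45, 0.35, 0.10, 0.10)  # L/R/B/U


@dataclass
class SyntheticTruth:
    """Everything needed to score a fit against the generator."""

    grid: EventGrid
    sequences: list[np.ndarray]
    fractions: np.ndarray
    subtype: np.ndarray  # (n_patients,) 0-based
    stage: np.ndarray  # (n_patients,) 0..E
    zstar: np.ndarray  # (n_patients, n_regions) latent noisy z*
    sigma_gen: float
    seed: int
    patient_ids: list[str]
    patient_age: np.ndarray
    control_model: ControlNormModel | None = None
    clinical_params: ClinicalEffectParams | None = None


def _draw_distinct_sequences(
    grid: EventGrid, K: int, rng: np.random.Generator, max_tries: int = 100
) -> list[np.ndarray]:
    seqs: list[np.ndarray] = []
    seen: set[tuple[int, ...]] = set()
    tries = 0
    while len(seqs) < K:
        s = random_valid_sequence(grid, rng)
        key = tuple(int(x) for x in s)
        if key in seen:
            tries += 1
            if tries > max_tries:
                raise ValueError(
                    f"could not draw {K} distinct sequences in {max_tries} tries"
                )
            continue
        seen.add(key)
        seqs.append(s)
    return seqs


def _draw_stages(
    n: int, E: int, stage_dist, rng: np.random.Generator
) -> np.ndarray:
    """uniform (default), point mass (int), ('beta', a, b), or an
    explicit probability vector over 0..E."""
    if stage_dist is None or stage_dist == "uniform":
        return rng.integers(0, E + 1, size=n)
    if isinstance(stage_dist, (int, np.integer)):
        k = int(stage_dist)
        if not 0 <= k <= E:
            raise ValueError("point-mass stage outside 0..E")
        return np.full(n, k, dtype=np.intp)
    if isinstance(stage_dist, tuple) and stage_dist and stage_dist[0] == "beta":
        _, a, b = stage_dist
        return np.rint(rng.beta(a, b, size=n) * E).astype(np.intp)
    p = np.asarray(stage_dist, dtype=float)
    if p.shape != (E + 1,) or abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
        raise ValueError("stage_dist must be a probability vector over 0..E")
    return rng.choice(E + 1, size=n, p=p)


def simulate_zmatrix(
    grid: EventGrid,
    sequences: list[np.ndarray],
    fractions,
    n: int,
    sigma_gen: float,
    rng: np.random.Generator,
    stage_dist=None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Latent z* draws: (Z, subtype, stage)."""
    f = np.asarray(fractions, dtype=float)
    if abs(f.sum() - 1.0) > 1e-9 or (f < 0).any():
        raise ValueError("fractions must form a simplex")
    E = grid.n_events
    subtype = rng.choice(len(sequences), size=n, p=f)
    stage = _draw_stages(n, E, stage_dist, rng)
    G = [trajectory_matrix(s, grid) for s in sequences]
    Z = np.empty((n, grid.n_regions))
    for j in range(n):
        Z[j] = G[subtype[j]][:, stage[j]]
    if sigma_gen > 0:
        Z += rng.normal(0.0, sigma_gen, size=Z.shape)
    return Z, subtype.astype(np.intp), stage.astype(np.intp)


# plausible raw-unit scales; config constants, not claims
_THICKNESS_MEAN, _THICKNESS_SD = 2.5, 0.15
_VOLUME_MEAN, _VOLUME_SD = 4000.0, 400.0
_TIV_MEAN, _TIV_SD = 1.45e6, 1.2e5


def _truth_control_model(
    dictionary: RoiDictionary,
    scanners: tuple[str, ...],
    stratum_age_mean: dict[str, float],
    rng: np.random.Generator,
    include_tiv: bool = True,
) -> ControlNormModel:
    """Known generating coefficients per (region, stratum)."""
    fits: dict[tuple[str, str], StratumRegionFit] = {}
    for region in dictionary.regions:
        cortical = region.tissue_class == "cortical_thickness"
        mu = _THICKNESS_MEAN if cortical else _VOLUME_MEAN
        sd = _THICKNESS_SD if cortical else _VOLUME_SD
        mu = mu * (1.0 + 0.1 * rng.standard_normal())
        for s in scanners:
            beta = np.array(
                [
                    mu * (1.0 + 0.02 * rng.standard_normal()),  # per-scanner offset
                    (0.3 * sd / _TIV_SD if (include_tiv and not cortical) else 0.0),
                    0.05 * mu * rng.standard_normal() * 0.1,  # small sex effect
                    -0.002 * mu * (1.0 + 0.2 * rng.standard_normal()),  # age slope
                    0.0,
                ]
            )
            fits[(region.name, s)] = StratumRegionFit(
                beta=beta, resid_mean=0.0, resid_sd=sd, n_controls=0
            )
    return ControlNormModel(
        fits=fits,
        stratum_age_mean=dict(stratum_age_mean),
        regions=dictionary.region_names,
        include_tiv=include_tiv,
    )


def simulate_cohort(
    n_patients: int = 400,
    n_controls: int = 200,
    n_regions: int = 10,
    n_subtypes: int = 2,
    fractions=(0.6, 0.4),
    thresholds=(1.0, 2.0, 3.0),
    z_max: float = 5.0,
    stage_dist=None,
    sigma_gen: float = 1.0,
    seed: int = 0,
    sequences: list[np.ndarray] | None = None,
    scanners: tuple[str, ...] = ("scannerA",),
    distinct: bool = True,
) -> tuple[RoiMeasureTable, SyntheticTruth]:
    """Generate a full raw-unit cohort plus its ground truth.

    ``n_regions=40`` uses the default ROI dictionary; other (even)
    counts use a generic paired dictionary.  Raw measures are obtained
    by inverting the known control model: raw = prediction - z* * SD.
    """
    rng = np.random.default_rng(seed)
    dictionary = (
        default_roi_dictionary() if n_regions == 40 else generic_roi_dictionary(n_regions)
    )
    grid = EventGrid.from_defaults(dictionary.region_names, thresholds, z_max)
    f = np.asarray(fractions, dtype=float)
    if len(f) != n_subtypes:
        raise ValueError("fractions length must equal n_subtypes")
    if sequences is None:
        if distinct:
            sequences = _draw_distinct_sequences(grid, n_subtypes, rng)
        else:
            sequences = [random_valid_sequence(grid, rng) for _ in range(n_subtypes)]
    else:
        sequences = [np.asarray(s, dtype=np.intp) for s in sequences]

    Z, subtype, stage = simulate_zmatrix(
        grid, sequences, f, n_patients, sigma_gen, rng, stage_dist
    )

    n_total = n_patients + n_controls
    age = rng.uniform(18.0, 65.0, size=n_total)
    sex = rng.integers(0, 2, size=n_total)
    tiv = rng.normal(_TIV_MEAN, _TIV_SD, size=n_total)
    scanner = np.array([scanners[i % len(scanners)] for i in range(n_total)])
    is_patient = np.arange(n_total) < n_patients
    ctl_mask = ~is_patient
    stratum_age_mean = {
        s: float(age[ctl_mask & (scanner == s)].mean()) for s in scanners
    }
    truth_model = _truth_control_model(dictionary, scanners, stratum_age_mean, rng)

    measures = np.empty((n_total, len(dictionary.region_names)))
    for s in scanners:
        rows = np.flatnonzero(scanner == s)
        X = truth_model.design(age[rows], sex[rows], tiv[rows], s)
        for j, region in enumerate(dictionary.region_names):
            fit = truth_model.fits[(region, s)]
            pred = X @ fit.beta
            vals = np.empty(rows.size)
            pat = is_patient[rows]
            pat_rows = rows[pat]
            vals[pat] = pred[pat] - Z[pat_rows, j] * fit.resid_sd
            n_ctl = int((~pat).sum())
            vals[~pat] = pred[~pat] + fit.resid_sd * rng.standard_normal(n_ctl)
            measures[rows, j] = vals

    ids = [f"pat{i + 1:05d}" for i in range(n_patients)] + [
        f"ctl{i + 1:05d}" for i in range(n_controls)
    ]
    frame = pd.DataFrame(
        {
            "subject_id": ids,
            "group": np.where(is_patient, "patient", "control"),
            "scanner": scanner,
            "age": age,
            "sex": sex,
            "tiv": tiv,
        }
    )
    for j, region in enumerate(dictionary.region_names):
        frame[region] = measures[:, j]
    table = RoiMeasureTable(frame, dictionary)
    truth = SyntheticTruth(
        grid=grid,
        sequences=sequences,
        fractions=f,
        subtype=subtype,
        stage=stage,
        zstar=Z,
        sigma_gen=sigma_gen,
        seed=seed,
        patient_ids=ids[:n_patients],
        patient_age=age[:n_patients].copy(),
        control_model=truth_model,
    )
    logger.info(
        "simulated cohort: %d patients, %d controls, %d regions, K=%d, seed=%d",
        n_patients,
        n_controls,
        n_regions,
        n_subtypes,
        seed,
    )
    return table, truth


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_clinical(
    truth: SyntheticTruth,
    params: ClinicalEffectParams | None = None,
    seed: int = 0,
) -> ClinicalTable:
    """Clinical covariates statistically linked to true stage and subtype.

    Duration grows with stage; convulsions and seizure frequency are
    elevated in the designated subtype; ASM count follows frequency.
    """
    params = ClinicalEffectParams() if params is None else params
    rng = np.random.default_rng(seed)
    n = len(truth.patient_ids)
    E = truth.grid.n_events
    rel_stage = truth.stage / E

    duration = params.duration_scale * rel_stage * 30.0 + rng.normal(
        0.0, params.duration_sd, size=n
    )
    duration = np.clip(duration, 0.0, None)
    onset = np.clip(truth.patient_age - duration, 0.5, None)

    designated = truth.subtype == params.designated_subtype
    conv_p = _sigmoid(
        params.convulsion_intercept
        + params.convulsion_subtype_logodds * designated
    )
    convulsions = (rng.random(n) < conv_p).astype(int)

    latent = params.freq_subtype_shift * designated + rng.logistic(size=n)
    freq = np.searchsorted(np.asarray(params.freq_cutpoints), latent)
    asm = rng.poisson(np.exp(params.asm_base_log_rate + params.asm_per_freq * freq))

    lat_labels = np.array(["left", "right", "bilateral", "undetermined"])
    p = np.asarray(params.laterality_probs, dtype=float)
    laterality = rng.choice(lat_labels, size=n, p=p / p.sum())

    frame = pd.DataFrame(
        {
            "subject_id": truth.patient_ids,
            "duration_years": duration,
            "onset_age_years": onset,
            "seizure_frequency": freq.astype(int),
            "convulsions_prior_year": convulsions,
            "asm_count": asm.astype(int),
            "laterality": laterality,
            "surgery_outcome": pd.array([pd.NA] * n),
        }
    )
    truth.clinical_params = params
    return ClinicalTable(frame)
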