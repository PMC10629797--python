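"""Cohort table I/O, the ROI dictionary, result export and logging.

Input tables are UTF-8 CSV or TSV (dialect auto-detected); outputs are
always TSV with a deterministic column order and fixed float precision,
so identical runs produce byte-identical files.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig  # noqa: F401  (re-exported: part of this module's surface)

logger = logging.getLogger("zsustain")

__all__ = [
    "RoiRegion",
    "RoiDictionary",
    "RoiMeasureTable",
    "ClinicalTable",
    "RunConfig",
    "default_roi_dictionary",
    "load_cohort_tables",
    "export_results",
    "write_measure_table",
    "write_clinical_table",
    "setup_logging",
]

FLOAT_FMT = "%.17g"  # full double round-trip; byte-stable across re-exports

# 14 left/right cortical-thickness pairs and 6 subcortical-volume pairs
CORTICAL_PAIRS = (
    "superiorfrontal",
    "caudalmiddlefrontal",
    "parstriangularis",
    "precentral",
    "paracentral",
    "superiortemporal",
    "transversetemporal",
    "middletemporal",
    "inferiortemporal",
    "supramarginal",
    "precuneus",
    "posteriorcingulate",
    "lingual",
    "cuneus",
)
SUBCORTICAL_PAIRS = (
    "hippocampus",
    "amygdala",
    "thalamus",
    "caudate",
    "pallidum",
    "putamen",
)

REQUIRED_COVARIATES = ("subject_id", "group", "scanner", "age", "sex", "tiv")
CLINICAL_COLUMNS = (
    "subject_id",
    "duration_years",
    "onset_age_years",
    "seizure_frequency",
    "convulsions_prior_year",
    "asm_count",
    "laterality",
    "surgery_outcome",
)
LATERALITY_VALUES = {"left", "right", "bilateral", "undetermined", "not_applicable"}


@dataclass(frozen=True)
class RoiRegion:
    name: str
    hemisphere: str  # "left" | "right"
    tissue_class: str  # "cortical_thickness" | "subcortical_volume"


@dataclass(frozen=True)
class RoiDictionary:
    regions: tuple[RoiRegion, ...]

    def __post_init__(self) -> None:
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise ValueError("region names must be unique")
        for r in self.regions:
            if r.hemisphere not in ("left", "right"):
                raise ValueError(f"bad hemisphere for {r.name}")
            if self.counterpart(r.name) is None:
                raise ValueError(f"region {r.name} has no left/right counterpart")

    @property
    def region_names(self) -> list[str]:
        return [r.name for r in self.regions]

    @property
    def n_cortical(self) -> int:
        return sum(r.tissue_class == "cortical_thickness" for r in self.regions)

    @property
    def n_subcortical(self) -> int:
        return sum(r.tissue_class == "subcortical_volume" for r in self.regions)

    def counterpart(self, name: str) -> str | None:
        """The homologous region in the opposite hemisphere."""
        region = next((r for r in self.regions if r.name == name), None)
        if region is None:
            return None
        other = "right" if region.hemisphere == "left" else "left"
        base = region.name.split("_", 1)[1]
        cand = f"{other}_{base}"
        return cand if any(r.name == cand for r in self.regions) else None


def default_roi_dictionary() -> RoiDictionary:
    """The 40-region dictionary: 28 cortical + 12 subcortical entries."""
    regions = []
    for base in CORTICAL_PAIRS:
        for hemi in ("left", "right"):
            regions.append(RoiRegion(f"{hemi}_{base}", hemi, "cortical_thickness"))
    for base in SUBCORTICAL_PAIRS:
        for hemi in ("left", "right"):
            regions.append(RoiRegion(f"{hemi}_{base}", hemi, "subcortical_volume"))
    return RoiDictionary(tuple(regions))


def generic_roi_dictionary(n_regions: int) -> RoiDictionary:
    """Paired synthetic dictionary with ``n_regions`` entries (even)."""
    if n_regions % 2 != 0 or n_regions < 2:
        raise ValueError("n_regions must be a positive even number")
    regions = []
    for p in range(n_regions // 2):
        tissue = "cortical_thickness" if p % 2 == 0 else "subcortical_volume"
        for hemi in ("left", "right"):
            regions.append(RoiRegion(f"{hemi}_roi{p + 1:02d}", hemi, tissue))
    return RoiDictionary(tuple(regions))


@dataclass
class RoiMeasureTable:
    """Validated per-subject measure table.

    ``frame`` holds subject_id, group, scanner, age, sex (0/1), tiv,
    optional syndrome, then one column per dictionary region.
    """

    frame: pd.DataFrame
    dictionary: RoiDictionary

    @property
    def regions(self) -> list[str]:
        return self.dictionary.region_names

    @property
    def n_subjects(self) -> int:
        return len(self.frame)

    def subset(self, mask) -> "RoiMeasureTable":
        return RoiMeasureTable(self.frame.loc[mask].reset_index(drop=True), self.dictionary)

    def patients(self) -> "RoiMeasureTable":
        return self.subset(self.frame["group"] == "patient")

    def controls(self) -> "RoiMeasureTable":
        return self.subset(self.frame["group"] == "control")

    def measures(self) -> np.ndarray:
        return self.frame[self.regions].to_numpy(dtype=float)


@dataclass
class ClinicalTable:
    frame: pd.DataFrame

    @property
    def n_subjects(self) -> int:
        return len(self.frame)


def _canon(name: str) -> str:
    return "".join(ch for ch in name.lower() if ch.isalnum())


_SEX_CODES = {"m": 1, "male": 1, "1": 1, "f": 0, "female": 0, "0": 0}


def _read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", encoding="utf-8")


def infer_roi_dictionary(columns) -> RoiDictionary:
    """Build a dictionary from paired ``left_*``/``right_*`` columns."""
    canon = {_canon(c): c for c in columns}
    bases = []
    for key in canon:
        if key.startswith("left"):
            base = key[4:]
            if f"right{base}" in canon:
                bases.append(base)
    if not bases:
        raise ValueError("no paired left/right region columns found")
    regions = []
    for base in sorted(bases):
        tissue = (
            "subcortical_volume"
            if base in SUBCORTICAL_PAIRS
            else "cortical_thickness"
        )
        for hemi in ("left", "right"):
            regions.append(RoiRegion(f"{hemi}_{base}", hemi, tissue))
    return RoiDictionary(tuple(regions))


def load_cohort_tables(
    roi_path: str | Path,
    clinical_path: str | Path | None = None,
    dictionary: RoiDictionary | None = None,
) -> tuple[RoiMeasureTable, ClinicalTable | None]:
    """Read and validate the ROI measure table and optional clinical table.

    Header matching is case-insensitive and separator-tolerant.  Rows
    with missing required covariates or missing region values are
    dropped (count logged).  Clinical rows whose subject_id is not a
    patient in the ROI table are dropped (count logged).  With no
    explicit dictionary the default 40-region one is used when all its
    regions are present, otherwise the dictionary is inferred from the
    paired left/right columns in the file.
    """
    raw = _read_table(roi_path)
    if dictionary is None:
        default = default_roi_dictionary()
        canon_cols = {_canon(c) for c in raw.columns}
        if all(_canon(r) in canon_cols for r in default.region_names):
            dictionary = default
        else:
            dictionary = infer_roi_dictionary(raw.columns)

    canon_to_col = {_canon(c): c for c in raw.columns}
    rename: dict[str, str] = {}
    for want in REQUIRED_COVARIATES + ("syndrome",):
        key = _canon(want)
        if key in canon_to_col:
            rename[canon_to_col[key]] = want
        elif want != "syndrome":
            raise ValueError(f"required covariate absent: {want}")
    region_cols: dict[str, str] = {}
    for region in dictionary.region_names:
        key = _canon(region)
        if key not in canon_to_col:
            raise ValueError(f"region column absent: {region}")
        region_cols[canon_to_col[key]] = region
    rename.update(region_cols)
    known = set(rename)
    for col in raw.columns:
        if col not in known:
            logger.warning("ignoring unknown column %r in %s", col, roi_path)
    df = raw[list(rename)].rename(columns=rename)

    df["subject_id"] = df["subject_id"].astype(str)
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicated subject_id values: {dupes}")
    df["group"] = df["group"].astype(str).str.strip().str.lower()
    bad_group = ~df["group"].isin(["patient", "control"])
    if bad_group.any():
        raise ValueError("group must be 'patient' or 'control'")
    df["scanner"] = df["scanner"].astype(str)
    df["sex"] = (
        df["sex"].astype(str).str.strip().str.lower().map(_SEX_CODES)
    )
    required = ["age", "sex", "tiv"] + dictionary.region_names
    n_before = len(df)
    df = df.dropna(subset=required)
    n_dropped = n_before - len(df)
    if n_dropped:
        logger.warning("dropped %d rows with missing required fields", n_dropped)
    df = df.reset_index(drop=True)
    if (df["age"] <= 0).any() or (df["tiv"] <= 0).any():
        raise ValueError("age and tiv must be positive")
    table = RoiMeasureTable(df, dictionary)

    clinical = None
    if clinical_path is not None:
        craw = _read_table(clinical_path)
        canon_to_col = {_canon(c): c for c in craw.columns}
        crename = {}
        for want in CLINICAL_COLUMNS:
            key = _canon(want)
            if key in canon_to_col:
                crename[canon_to_col[key]] = want
            elif want in ("subject_id",):
                raise ValueError(f"required covariate absent: {want}")
        cdf = craw[list(crename)].rename(columns=crename)
        cdf["subject_id"] = cdf["subject_id"].astype(str)
        patient_ids = set(df.loc[df["group"] == "patient", "subject_id"])
        keep = cdf["subject_id"].isin(patient_ids)
        if (~keep).any():
            logger.warning(
                "dropped %d clinical rows with unknown subject_id", int((~keep).sum())
            )
        cdf = cdf.loc[keep].reset_index(drop=True)
        if "laterality" in cdf:
            lat = cdf["laterality"].dropna().astype(str)
            bad = set(lat) - LATERALITY_VALUES
            if bad:
                raise ValueError(f"unknown laterality values: {sorted(bad)}")
        for col, hi in (("seizure_frequency", 4), ("convulsions_prior_year", 1)):
            if col in cdf:
                vals = cdf[col].dropna()
                if ((vals < 0) | (vals > hi)).any():
                    raise ValueError(f"{col} outside declared range 0..{hi}")
        clinical = ClinicalTable(cdf)
    return table, clinical


# ---------------------------------------------------------------------------
# writers


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT, lineterminator="\n")


def write_measure_table(table: RoiMeasureTable, path: str | Path) -> None:
    cols = [c for c in ("subject_id", "group", "scanner", "age", "sex", "tiv", "syndrome") if c in table.frame]
    _write_tsv(table.frame[cols + table.regions], Path(path))


def write_clinical_table(clinical: ClinicalTable, path: str | Path) -> None:
    cols = [c for c in CLINICAL_COLUMNS if c in clinical.frame]
    _write_tsv(clinical.frame[cols], Path(path))


def severity_band(z: float) -> str:
    """Band label for an expected z-score: none / 1-2 / 2-3 / >3."""
    if z < 1.0:
        return "none"
    if z < 2.0:
        return "1-2"
    if z < 3.0:
        return "2-3"
    return ">3"


def export_results(model, posteriors, out_dir: str | Path) -> list[Path]:
    """Write fitted-model artefacts as TSV.

    Emits per-subtype positional-variance diagrams, the subject
    assignment/stage table, and per-subtype severity bands reached by
    every region at every stage.  Deterministic column order and fixed
    float precision make re-exports byte-identical.
    """
    from .event_model import trajectory_matrix

    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory not writable: {out}") from exc

    grid = model.grid
    written: list[Path] = []
    if model.pvds is not None:
        for c, P in enumerate(model.pvds):
            labels = [
                f"{grid.region_names[grid.event_region[e]]}_z{grid.event_value[e]:g}"
                for e in range(grid.n_events)
            ]
            df = pd.DataFrame(
                P, columns=[f"pos_{k + 1}" for k in range(grid.n_events)]
            )
            df.insert(0, "event", labels)
            p = out / f"pvd_subtype{c + 1}.tsv"
            _write_tsv(df, p)
            written.append(p)

    if posteriors is not None:
        p = out / "subject_posteriors.tsv"
        _write_tsv(posteriors.to_frame(), p)
        written.append(p)

    rows = []
    for c, seq in enumerate(model.sequences):
        G = trajectory_matrix(seq, grid)
        for i, region in enumerate(grid.region_names):
            for t in range(grid.n_stages):
                rows.append(
                    {
                        "subtype": c + 1,
                        "region": region,
                        "stage": t,
                        "expected_z": G[i, t],
                        "band": severity_band(G[i, t]),
                    }
                )
    p = out / "severity_bands.tsv"
    _write_tsv(pd.DataFrame(rows), p)
    written.append(p)

    frac = pd.DataFrame(
        {
            "subtype": np.arange(1, model.n_subtypes + 1),
            "fraction": model.fractions,
        }
    )
    p = out / "subtype_fractions.tsv"
    _write_tsv(frac, p)
    written.append(p)
    return written


def setup_logging(logfile: str | Path | None = None, level: int = logging.INFO) -> None:
    """Structured log to stderr and, optionally, a logfile."""
    log = logging.getLogger("zsustain")
    log.setLevel(level)
    log.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    sh = logging.StreamHandler(sys.stderr)
    sh.setFormatter(fmt)
    log.addHandler(sh)
    if logfile is not None:
        fh = logging.FileHandler(logfile)
        fh.setFormatter(fmt)
        log.addHandler(fh)
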