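"""Synthetic radiological cohort: generation, statistics and agreement.

The verification protocol measured flexion, extension and lateral bending
on standing radiographs of 25 healthy young men (mean age 27.4 years,
range 23-33; mean weight 78.6 kg, range 72.1-81.7), reading per-vertebra
cumulative angles from endplate lines.  Torsion has no radiological arm
(it cannot be read reliably from planar images), so the generator covers
FLX/EXT/LB only.

This module generates per-subject angle datasets around the packaged
reference means/SDs, with a shared subject-level mobility factor (default
intraclass correlation 0.5) so that per-level angles are correlated within
a subject, followed by an isotonic correction enforcing the anatomical
ordering L1 >= L2 >= ... >= L5 of cumulative angles.  It can also emit
noisy endplate landmark coordinates whose angle readout (through the same
direction-cosine code path as the model) reproduces the generated angles
exactly when the noise is zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression
from scipy.stats import truncnorm

from ._rotations import rotate_about
from .kinematics import AngleTable, ReferenceLine, angles_from_landmarks

__all__ = [
    "CohortSpec",
    "SubjectRecord",
    "load_reference_table",
    "generate_cohort",
    "cohort_stats",
    "agreement_report",
    "subject_landmarks",
    "landmarks_to_frame",
    "RADIOLOGICAL_MOVEMENTS",
]

RADIOLOGICAL_MOVEMENTS = ("FLX", "EXT", "LB")
VERTEBRAE = ("L1", "L2", "L3", "L4", "L5")


def load_reference_table(file: str | Path | None = None) -> pd.DataFrame:
    """Packaged radiological means/SDs per vertebra per movement (degrees)."""
    path = (
        Path(file)
        if file is not None
        else Path(str(resources.files("lumbokin").joinpath("data", "radiology_reference.csv")))
    )
    table = pd.read_csv(path)
    expected = {"vertebra", "movement", "mean_deg", "sd_deg"}
    if set(table.columns) != expected:
        raise ValueError(f"reference table must have columns {sorted(expected)}")
    return table


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic verification cohort."""

    n_subjects: int = 25
    age_mean: float = 27.4
    age_range: tuple[float, float] = (23.0, 33.0)
    weight_mean: float = 78.6
    weight_range: tuple[float, float] = (72.1, 81.7)
    angle_table: pd.DataFrame | None = None      # defaults to the packaged table
    landmark_noise_sd: float = 0.5               # mm
    subject_icc: float = 0.5
    monotone_correction: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("cohort needs at least two subjects")
        if self.landmark_noise_sd < 0:
            raise ValueError("landmark noise SD must be nonnegative")
        if not 0.0 <= self.subject_icc <= 1.0:
            raise ValueError("subject ICC must lie in [0, 1]")
        for mean, (lo, hi) in ((self.age_mean, self.age_range), (self.weight_mean, self.weight_range)):
            if not lo <= mean <= hi:
                raise ValueError("range must contain the mean")

    def table(self) -> pd.DataFrame:
        table = self.angle_table if self.angle_table is not None else load_reference_table()
        if (table["sd_deg"] < 0).any():
            raise ValueError("reference SDs must be nonnegative")
        return table


@dataclass
class SubjectRecord:
    """One synthetic subject: demographics and per-movement angle profiles."""

    id: int
    age: float
    weight: float
    angles: Mapping[str, Mapping[str, float]]   # movement -> vertebra -> deg
    raw_angles: Mapping[str, Mapping[str, float]] = field(default_factory=dict)


def _truncated_normal(rng: np.random.Generator, mean: float, lo: float, hi: float, n: int) -> np.ndarray:
    sd = (hi - lo) / 4.0
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def generate_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Deterministic synthetic cohort for a spec and seed.

    Per-level angles are drawn from normal(mean, SD) with a shared
    subject-level factor (ICC) and then isotonic-corrected so cumulative
    angles decrease from L1 to L5.  ``raw_angles`` keeps the uncorrected
    draws (the distributional ground truth for parameter-recovery checks).
    """
    table = spec.table()
    rng = np.random.default_rng(spec.seed)
    ages = _truncated_normal(rng, spec.age_mean, *spec.age_range, n=spec.n_subjects)
    weights = _truncated_normal(rng, spec.weight_mean, *spec.weight_range, n=spec.n_subjects)

    movements = [m for m in RADIOLOGICAL_MOVEMENTS if m in set(table["movement"])]
    mean_piv = table.pivot(index="vertebra", columns="movement", values="mean_deg")
    sd_piv = table.pivot(index="vertebra", columns="movement", values="sd_deg")
    means = {m: mean_piv.loc[list(VERTEBRAE), m].to_numpy(dtype=float) for m in movements}
    sds = {m: sd_piv.loc[list(VERTEBRAE), m].to_numpy(dtype=float) for m in movements}

    records: list[SubjectRecord] = []
    rho = spec.subject_icc
    for i in range(spec.n_subjects):
        mobility = rng.standard_normal()       # shared subject factor
        angles: dict[str, dict[str, float]] = {}
        raw: dict[str, dict[str, float]] = {}
        for m in movements:
            eps = rng.standard_normal(len(VERTEBRAE))
            draw = means[m] + sds[m] * (np.sqrt(rho) * mobility + np.sqrt(1.0 - rho) * eps)
            raw[m] = dict(zip(VERTEBRAE, draw.astype(float)))
            if spec.monotone_correction:
                # enforce L1 >= L2 >= ... >= L5 (nonincreasing caudally)
                draw = isotonic_regression(draw, increasing=False).x
            angles[m] = dict(zip(VERTEBRAE, np.asarray(draw, dtype=float)))
        records.append(
            SubjectRecord(id=i + 1, age=float(ages[i]), weight=float(weights[i]), angles=angles, raw_angles=raw)
        )
    return records


def cohort_stats(records: Sequence[SubjectRecord], movement: str, raw: bool = False) -> AngleTable:
    """Sample mean and (n-1)-denominator SD per vertebra for one movement."""
    if len(records) < 2:
        raise ValueError("cohort statistics need at least two subjects")
    source = "raw_angles" if raw else "angles"
    data = np.array([[getattr(r, source)[movement][v] for v in VERTEBRAE] for r in records])
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    return AngleTable(
        movement=movement,
        cumulative=dict(zip(VERTEBRAE, mean.astype(float))),
        sd=dict(zip(VERTEBRAE, sd.astype(float))),
        n=len(records),
    )


def agreement_report(model: AngleTable, cohort: AngleTable) -> pd.DataFrame:
    """Per-level agreement of model angles with the cohort mean +/- 1 SD.

    Flags whether the model lies within one and within two standard
    deviations and reports the absolute deviation from the cohort mean.
    """
    if model.movement != cohort.movement:
        raise ValueError("movement mismatch between model and cohort tables")
    if set(model.cumulative) != set(cohort.cumulative):
        raise ValueError("level mismatch between model and cohort tables")
    if cohort.sd is None:
        raise ValueError("cohort table carries no standard deviations")
    rows = []
    for v in cohort.cumulative:
        deviation = model.cumulative[v] - cohort.cumulative[v]
        sd = cohort.sd[v]
        rows.append(
            {
                "vertebra": v,
                "model_deg": model.cumulative[v],
                "cohort_mean_deg": cohort.cumulative[v],
                "cohort_sd_deg": sd,
                "deviation_deg": deviation,
                "within_1sd": bool(abs(deviation) <= sd),
                "within_2sd": bool(abs(deviation) <= 2.0 * sd),
            }
        )
    return pd.DataFrame(rows)


# -- landmark emission -----------------------------------------------------

_LINE_HALF_LENGTH = 25.0  # mm


def _neutral_lines() -> dict[str, ReferenceLine]:
    return {
        "frontal": ReferenceLine(
            "frontal", [-_LINE_HALF_LENGTH, 0.0, 0.0], [_LINE_HALF_LENGTH, 0.0, 0.0]
        ),
        "sagittal": ReferenceLine(
            "sagittal", [0.0, -_LINE_HALF_LENGTH, 0.0], [0.0, _LINE_HALF_LENGTH, 0.0]
        ),
    }


_MOVEMENT_LINE = {"FLX": "sagittal", "EXT": "sagittal", "LB": "frontal"}
_MOVEMENT_AXIS = {
    "FLX": np.array([1.0, 0.0, 0.0]),
    "EXT": np.array([1.0, 0.0, 0.0]),
    "LB": np.array([0.0, 1.0, 0.0]),
}


def subject_landmarks(
    record: SubjectRecord,
    movement: str,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, ReferenceLine], ReferenceLine]:
    """Endplate reference lines realizing a subject's cumulative angles.

    Each vertebra's line is the neutral sacrum line rotated by the
    subject's cumulative angle in the movement plane, plus isotropic
    Gaussian landmark noise on both endpoints.  With zero noise the angle
    readout through the direction-cosine formulas reproduces the generated
    angles exactly.
    """
    if movement not in _MOVEMENT_LINE:
        raise ValueError(f"no radiological landmarks for movement {movement!r}")
    rng = rng if rng is not None else np.random.default_rng(0)
    neutral = _neutral_lines()[_MOVEMENT_LINE[movement]]
    axis = _MOVEMENT_AXIS[movement]
    sense = -1.0 if movement == "EXT" else 1.0
    lines: dict[str, ReferenceLine] = {}
    for v in VERTEBRAE:
        angle = np.radians(sense * record.angles[movement][v])
        R = rotate_about(axis, angle)
        start = R @ neutral.start
        end = R @ neutral.end
        if noise_sd > 0:
            start = start + rng.normal(0.0, noise_sd, 3)
            end = end + rng.normal(0.0, noise_sd, 3)
        lines[v] = ReferenceLine(neutral.plane, start, end)
    return lines, neutral


def landmark_angles(lines: Mapping[str, ReferenceLine], sacrum: ReferenceLine, movement: str) -> AngleTable:
    """Angle readout of landmark lines (same code path as the model)."""
    return angles_from_landmarks(lines, sacrum, movement)


def landmarks_to_frame(
    records: Sequence[SubjectRecord],
    movement: str,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Landmark CSV dialect: subject_id, vertebra, plane, x1..z2 (mm)."""
    rng = np.random.default_rng(seed)
    rows = []
    for rec in records:
        lines, sacrum = subject_landmarks(rec, movement, noise_sd=noise_sd, rng=rng)
        for v, line in [("S", sacrum)] + [(v, lines[v]) for v in VERTEBRAE]:
            rows.append(
                {
                    "subject_id": rec.id,
                    "vertebra": v,
                    "plane": line.plane,
                    "x1": line.start[0],
                    "y1": line.start[1],
                    "z1": line.start[2],
                    "x2": line.end[0],
                    "y2": line.end[1],
                    "z2": line.end[2],
                }
            )
    return pd.DataFrame(rows)
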