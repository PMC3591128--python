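"""Pipeline assembly: simulate -> calibrate -> verify -> degenerate.

`run_pipeline` executes the four-movement healthy verification (muscle
calibration against the packaged targets), the radiological agreement
report, the synthetic cohort emission and the L5-S1 degeneration
comparison, writing CSV/JSON artifacts plus a checksummed manifest.  Every
output carries the configuration hash so runs are traceable; identical
config and seed give identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._model import ChainModel
from .degeneration import (
    MOVEMENTS,
    DegenerationConfig,
    calibrate_degeneration,
    global_mobility_report,
    run_comparison,
)
from .geometry import build_default_spine
from .kinematics import AngleTable
from .materials import load_card
from .muscles import calibrate, load_targets
from .radiology import CohortSpec, agreement_report, cohort_stats, generate_cohort, landmarks_to_frame, load_reference_table

logger = logging.getLogger("lumbokin")

__all__ = ["RunConfig", "run_pipeline", "reference_angle_table"]


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    output_dir: Path
    geometry_overrides: dict = field(default_factory=dict)
    seed: int = 0
    n_subjects: int = 25
    movements: tuple[str, ...] = MOVEMENTS
    fit_degeneration: bool = True
    degeneration: DegenerationConfig | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)

    def config_hash(self) -> str:
        payload = {
            "geometry_overrides": self.geometry_overrides,
            "seed": self.seed,
            "n_subjects": self.n_subjects,
            "movements": list(self.movements),
            "fit_degeneration": self.fit_degeneration,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def reference_angle_table(movement: str) -> AngleTable:
    """Radiological reference means/SDs as an AngleTable."""
    table = load_reference_table()
    sub = table[table["movement"] == movement]
    if sub.empty:
        raise KeyError(f"no radiological reference for movement {movement!r}")
    return AngleTable(
        movement=movement,
        cumulative=dict(zip(sub["vertebra"], sub["mean_deg"].astype(float))),
        sd=dict(zip(sub["vertebra"], sub["sd_deg"].astype(float))),
        n=25,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the artifact manifest."""
    logging.basicConfig(level=config.log_level)
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    written: list[Path] = []

    def write_frame(frame: pd.DataFrame, name: str) -> None:
        path = out / name
        frame.to_csv(path, index=False)
        written.append(path)

    def write_json(payload: dict, name: str) -> None:
        path = out / name
        path.write_text(json.dumps({"config_hash": chash, **payload}, indent=1, sort_keys=True))
        written.append(path)

    geometry = build_default_spine(config.geometry_overrides or None)
    healthy = load_card("healthy")
    cards = {level: healthy for level in geometry.joints}
    chain = ChainModel(geometry, cards)

    # 1. healthy calibrations (verification arm)
    calibrated: dict[str, AngleTable] = {}
    convergence: dict[str, dict] = {}
    for movement in config.movements:
        logger.info("calibrating %s", movement)
        result = calibrate(movement, load_targets(movement), geometry, cards, chain=chain)
        calibrated[movement] = result.achieved
        convergence[movement] = {
            "calibration_iterations": result.iterations,
            "objective_J": result.objective.W,
            **result.state.convergence_record(),
        }
        frame = result.achieved.to_frame()
        write_frame(frame, f"angles_healthy_{movement}.csv")
    write_json({"convergence": convergence}, "convergence_log.json")

    # 2. radiological agreement (flexion, extension, lateral bending)
    agreement_frames = []
    for movement in ("FLX", "EXT", "LB"):
        if movement not in calibrated:
            continue
        report = agreement_report(calibrated[movement], reference_angle_table(movement))
        report.insert(0, "movement", movement)
        agreement_frames.append(report)
    if agreement_frames:
        write_frame(pd.concat(agreement_frames, ignore_index=True), "agreement_report.csv")

    # 3. synthetic cohort
    spec = CohortSpec(n_subjects=config.n_subjects, seed=config.seed)
    records = generate_cohort(spec)
    angle_rows = [
        {"subject_id": r.id, "age": r.age, "weight": r.weight, "movement": m, "vertebra": v, "angle_deg": a}
        for r in records
        for m, per in r.angles.items()
        for v, a in per.items()
    ]
    write_frame(pd.DataFrame(angle_rows), "cohort_angles.csv")
    write_frame(landmarks_to_frame(records, "FLX", noise_sd=spec.landmark_noise_sd, seed=config.seed), "cohort_landmarks_FLX.csv")
    stats_rows = []
    for movement in ("FLX", "EXT", "LB"):
        st = cohort_stats(records, movement)
        for v in st.cumulative:
            stats_rows.append(
                {"movement": movement, "vertebra": v, "mean_deg": st.cumulative[v], "sd_deg": st.sd[v]}
            )
    write_frame(pd.DataFrame(stats_rows), "cohort_stats.csv")

    # 4. degeneration comparison
    if config.degeneration is not None:
        degen_cfg = config.degeneration
    elif config.fit_degeneration:
        logger.info("fitting degeneration parameters on flexion")
        degen_cfg = calibrate_degeneration(geometry, cards)
    else:
        degen_cfg = DegenerationConfig()
    comparisons = []
    for movement in MOVEMENTS:
        comp = run_comparison(movement, geometry, cards, degen_cfg, healthy_chain=chain)
        comparisons.append(comp)
        write_frame(comp.to_frame(), f"comparison_{movement}.csv")
    summary = global_mobility_report(comparisons)
    write_frame(summary, "mobility_summary.csv")
    write_json(
        {
            "height_loss_fraction": degen_cfg.height_loss_fraction,
            "slack_pre_strain": degen_cfg.slack_pre_strain,
            "percent_increase": {
                row["movement"]: row["percent_increase"] for _, row in summary.iterrows()
            },
        },
        "mobility_summary.json",
    )

    manifest = {
        "config_hash": chash,
        "files": {p.name: _sha256(p) for p in sorted(written)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
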