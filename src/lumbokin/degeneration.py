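"""L5-S1 disc degeneration study.

The degenerated level swaps in the degenerated material card (stiffer but
less confined annulus matrix, compressible elastic nucleus, fibre moduli
reduced tenfold) and adds the two geometric signatures of degeneration the
material card cannot carry: a loss of disc height and a loss of ligament
tension, chiefly in the anterior and posterior longitudinal ligaments.
Height loss is applied by rebuilding the column with the reduced disc
height while keeping every trans-disc soft tissue's rest length from the
healthy geometry, which slackens fibres and ligaments exactly as a
collapsed disc does; the extra longitudinal-ligament slack is a
(nonpositive) pre-strain offset.

Both models are loaded identically: the 400 N follower preload plus a pure
moment at L1 of 15 N*m (6 N*m for axial rotation).  The mobility metric is
the cumulative L1-sacrum angle; the headline number is its percent increase
over the healthy model.  The two free parameters (height-loss fraction,
slack pre-strain) are calibrated once, on flexion only, and then held fixed
for the other three movements, so extension, lateral bending and axial
rotation are genuine predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from ._model import ChainModel
from .geometry import SpineGeometry, build_default_spine
from .kinematics import measure_state
from .materials import MaterialCard, load_card
from .solver import LoadCase, solve_chain

__all__ = [
    "DegenerationConfig",
    "MobilityComparison",
    "build_degenerated_model",
    "run_comparison",
    "global_mobility_report",
    "calibrate_degeneration",
    "MOVEMENTS",
]

MOVEMENTS = ("FLX", "EXT", "LB", "AR")


@dataclass(frozen=True)
class DegenerationConfig:
    """Parameterization of one degenerated level."""

    level: str = "L5-S1"
    card: MaterialCard | None = None          # defaults to the packaged Table of degenerated properties
    height_loss_fraction: float = 0.2
    slackened_ligaments: tuple[str, ...] = ("ALL", "PLL")
    slack_pre_strain: float = -0.02

    def __post_init__(self) -> None:
        if not 0.0 <= self.height_loss_fraction < 1.0:
            raise ValueError("height_loss_fraction must lie in [0, 1)")
        if self.slack_pre_strain > 0.0:
            raise ValueError("slack pre-strain must be <= 0 (tension onset delayed)")

    def resolved_card(self) -> MaterialCard:
        return self.card if self.card is not None else load_card("degenerated")


@dataclass
class MobilityComparison:
    """Healthy vs degenerated cumulative angles for one movement."""

    movement: str
    healthy: Mapping[str, float]
    degenerated: Mapping[str, float]
    meta: dict = field(default_factory=dict)

    @property
    def global_percent_difference(self) -> float:
        """Percent change of the L1 cumulative angle (degenerated vs healthy)."""
        h = self.healthy["L1"]
        if h == 0.0:
            raise ZeroDivisionError("healthy L1 angle is zero; percent difference undefined")
        return 100.0 * (self.degenerated["L1"] - h) / h

    @property
    def per_level_difference(self) -> dict[str, float]:
        return {v: self.degenerated[v] - self.healthy[v] for v in self.healthy}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "vertebra": v,
                "healthy_deg": self.healthy[v],
                "degenerated_deg": self.degenerated[v],
                "difference_deg": self.degenerated[v] - self.healthy[v],
            }
            for v in self.healthy
        ]
        return pd.DataFrame(rows)


def build_degenerated_model(
    geometry: SpineGeometry,
    healthy_cards: Mapping[str, MaterialCard],
    config: DegenerationConfig,
) -> tuple[ChainModel, SpineGeometry]:
    """Chain model with the degenerated level swapped in.

    The column is rebuilt with the reduced disc height; rest lengths of all
    fibres and ligaments come from the healthy geometry (slackening), and
    the configured longitudinal ligaments receive the extra slack offset.
    """
    if config.level not in geometry.discs:
        raise KeyError(f"degenerated level {config.level!r} not present in geometry")
    cfg = geometry.config
    heights = dict(cfg["disc_height"])
    heights[config.level] = heights[config.level] * (1.0 - config.height_loss_fraction)
    degen_geometry = build_default_spine({**cfg, "disc_height": heights})
    cards = dict(healthy_cards)
    cards[config.level] = config.resolved_card()
    chain = ChainModel(
        degen_geometry,
        cards,
        rest_geometry=geometry,
        extra_pre_strain={
            config.level: {name: config.slack_pre_strain for name in config.slackened_ligaments}
        },
    )
    return chain, degen_geometry


def _moment_case(movement: str, preload: float = 400.0) -> LoadCase:
    # pure normalized moment at L1 (15 N*m; 6 N*m in axial rotation), with
    # the follower preload applied in both arms of the comparison
    return LoadCase(preload=preload, movement=movement)


def run_comparison(
    movement: str,
    geometry: SpineGeometry,
    healthy_cards: Mapping[str, MaterialCard] | MaterialCard,
    degen_config: DegenerationConfig,
    preload: float = 400.0,
    healthy_chain: ChainModel | None = None,
) -> MobilityComparison:
    """Solve healthy and degenerated models under identical pure moments."""
    if isinstance(healthy_cards, MaterialCard):
        healthy_cards = {level: healthy_cards for level in geometry.joints}
    if healthy_chain is None:
        healthy_chain = ChainModel(geometry, healthy_cards)
    degen_chain, degen_geometry = build_degenerated_model(geometry, healthy_cards, degen_config)
    case = _moment_case(movement, preload)
    state_h = solve_chain(healthy_chain, case)
    state_d = solve_chain(degen_chain, case)
    healthy = measure_state(state_h, geometry, movement=movement).cumulative
    degenerated = measure_state(state_d, degen_geometry, movement=movement).cumulative
    return MobilityComparison(
        movement=movement,
        healthy=healthy,
        degenerated=degenerated,
        meta={
            "healthy_convergence": state_h.convergence_record(),
            "degenerated_convergence": state_d.convergence_record(),
            "height_loss_fraction": degen_config.height_loss_fraction,
            "slack_pre_strain": degen_config.slack_pre_strain,
        },
    )


def global_mobility_report(comparisons: Sequence[MobilityComparison]) -> pd.DataFrame:
    """Percent mobility increase by movement (the headline summary)."""
    have = {c.movement for c in comparisons}
    missing = set(MOVEMENTS) - have
    if missing:
        raise ValueError(f"missing movements in comparison set: {sorted(missing)}")
    rows = [
        {
            "movement": c.movement,
            "healthy_L1_deg": c.healthy["L1"],
            "degenerated_L1_deg": c.degenerated["L1"],
            "percent_increase": c.global_percent_difference,
        }
        for c in sorted(comparisons, key=lambda c: MOVEMENTS.index(c.movement))
    ]
    return pd.DataFrame(rows)


def calibrate_degeneration(
    geometry: SpineGeometry,
    healthy_cards: Mapping[str, MaterialCard] | MaterialCard,
    target_flexion_percent: float = 19.4,
    level: str = "L5-S1",
    card: MaterialCard | None = None,
    preload: float = 400.0,
    x0: tuple[float, float] = (0.2, -0.02),
) -> DegenerationConfig:
    """Fit the two free degeneration parameters on flexion only.

    A regularized Nelder-Mead search adjusts (height-loss fraction, slack
    pre-strain) until the flexion mobility increase matches the target; the
    regularization keeps the underdetermined pair near its defaults.  The
    returned config is then used unchanged for all four movements.
    """
    if isinstance(healthy_cards, MaterialCard):
        healthy_cards = {l: healthy_cards for l in geometry.joints}
    healthy_chain = ChainModel(geometry, healthy_cards)
    case = _moment_case("FLX", preload)
    state_h = solve_chain(healthy_chain, case)
    h_l1 = measure_state(state_h, geometry, movement="FLX").cumulative["L1"]

    def percent(params: np.ndarray) -> float:
        hl = float(np.clip(params[0], 0.0, 0.6))
        slack = float(np.clip(params[1], -0.10, 0.0))
        cfg = DegenerationConfig(
            level=level, card=card, height_loss_fraction=hl, slack_pre_strain=slack
        )
        chain, geo_d = build_degenerated_model(geometry, healthy_cards, cfg)
        state_d = solve_chain(chain, case)
        d_l1 = measure_state(state_d, geo_d, movement="FLX").cumulative["L1"]
        return 100.0 * (d_l1 - h_l1) / h_l1

    def objective(params: np.ndarray) -> float:
        p = percent(params)
        reg = (params[0] - x0[0]) ** 2 + (50.0 * (params[1] - x0[1])) ** 2
        return (p - target_flexion_percent) ** 2 + 0.05 * reg

    res = optimize.minimize(
        objective,
        np.asarray(x0, dtype=float),
        method="Nelder-Mead",
        options={"xatol": 2e-3, "fatol": 1e-3, "maxfev": 60},
    )
    hl = float(np.clip(res.x[0], 0.0, 0.6))
    slack = float(np.clip(res.x[1], -0.10, 0.0))
    return DegenerationConfig(
        level=level, card=card, height_loss_fraction=hl, slack_pre_strain=slack
    )
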