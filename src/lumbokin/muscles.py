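"""Muscle-force calibration by energy minimization.

Segmental rotations of the model are driven by three muscular groups
(psoas major as the local muscle, rectus abdominis and erector spinae as
global ones, with obliques and multifidus added for lateral bending and
axial rotation).  The work of a local muscle force along its movement path
is

    W_F = integral_C  F . ds                    (path integral)

and of a global muscle moment over the achieved rotation

    W_M = integral_0^alpha  M . dtheta ,

and the calibration minimizes the total  W = sum W_F + sum W_M  subject to
all force and moment magnitudes being nonnegative, while the equilibrium
solution meets the per-segment rotation targets.

The implementation inverts the problem in two stages.  An outer Newton
iteration finds the per-vertebra driving moments that make the converged
chain meet the targets; a linear program (with a squared-magnitude
tie-break for redundant muscle sets) then distributes those moments over
the nonnegative muscle magnitudes at minimum total energy.  Global muscles
act as per-vertebra moment fascicles, the psoas as per-level slips, which
mirrors the adjustment of forces and moments on each vertebra during the
calibration and makes all five segmental targets reachable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy import optimize

from ._model import ChainModel
from .kinematics import AngleTable, measure_state
from .materials import MaterialCard
from .solver import MOVEMENT_AXES, LoadCase, SpineState, solve_chain

__all__ = [
    "LocalMuscle",
    "GlobalMuscle",
    "EnergyObjective",
    "RotationTargets",
    "CalibrationResult",
    "InfeasibleTargetsError",
    "local_work",
    "global_work",
    "calibrate",
    "load_targets",
    "load_muscle_config",
]


class InfeasibleTargetsError(RuntimeError):
    """Raised when the chain cannot reach the rotation targets."""


@dataclass
class LocalMuscle:
    """Local muscle: per-level slips from vertebral attachments to an anchor."""

    name: str
    path: Sequence[np.ndarray]          # polyline of attachment points, mm
    force: float = 0.0                  # design magnitude, N
    anchor: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.path) < 2:
            raise ValueError("muscle path needs at least two points")
        if self.force < 0:
            raise ValueError("muscle force must be nonnegative")


@dataclass
class GlobalMuscle:
    """Global muscle: nonnegative moment magnitude about a movement axis."""

    name: str
    axis: np.ndarray
    moment: float = 0.0                 # N*m

    def __post_init__(self) -> None:
        if self.moment < 0:
            raise ValueError("muscle moment must be nonnegative")


@dataclass
class EnergyObjective:
    """Total calibration energy W (J) with its per-muscle terms."""

    W: float
    local_terms: Mapping[str, float]
    global_terms: Mapping[str, float]

    def __post_init__(self) -> None:
        total = sum(self.local_terms.values()) + sum(self.global_terms.values())
        if abs(total - self.W) > 1e-9:
            raise ValueError("objective terms do not sum to W")


@dataclass
class RotationTargets:
    """Per-vertebra cumulative rotation targets (degrees) for one movement."""

    movement: str
    cumulative: Mapping[str, float]
    tolerance_deg: float = 0.25

    def __post_init__(self) -> None:
        if self.movement not in MOVEMENT_AXES:
            raise ValueError(f"unknown movement {self.movement!r}")
        if any(v < 0 for v in self.cumulative.values()):
            raise ValueError("targets are magnitudes in the movement's positive sense")
        if any(v > 60.0 for v in self.cumulative.values()):
            raise ValueError("targets outside the physiological range")

    def segmental(self, vertebrae_bottom_up: Sequence[str]) -> np.ndarray:
        """Segmental targets bottom-up (difference of cumulative entries)."""
        cum = [self.cumulative[v] for v in vertebrae_bottom_up]
        below = [0.0] + cum[:-1]
        return np.array(cum) - np.array(below)


@dataclass
class CalibrationResult:
    forces: dict[str, dict[str, float]]     # local muscle -> vertebra -> N
    moments: dict[str, dict[str, float]]    # global muscle -> vertebra -> N*m
    state: SpineState
    achieved: AngleTable
    objective: EnergyObjective
    descent_history: list[float]
    iterations: int

    @property
    def total_moments(self) -> dict[str, float]:
        return {m: float(sum(v.values())) for m, v in self.moments.items()}

    @property
    def total_forces(self) -> dict[str, float]:
        return {m: float(sum(v.values())) for m, v in self.forces.items()}


# -- Eq-style work integrals ----------------------------------------------

def local_work(muscle: LocalMuscle, trajectory: Sequence[np.ndarray]) -> float:
    """Work (J) of a local muscle force along its movement trajectory.

    ``trajectory`` is the sequence of attachment positions (mm) sampled
    along the movement.  The force vector at each sample has the muscle's
    magnitude and points toward the anchor (or along the muscle's slip line
    when no anchor is set); the discrete line integral of F . ds uses the
    trapezoidal rule.
    """
    pts = [np.asarray(p, dtype=float) for p in trajectory]
    if len(pts) < 2:
        raise ValueError("trajectory needs at least two sampled configurations")

    def force_at(p: np.ndarray) -> np.ndarray:
        if muscle.anchor is not None:
            d = np.asarray(muscle.anchor, dtype=float) - p
        else:
            d = np.asarray(muscle.path[-1], dtype=float) - np.asarray(muscle.path[0], dtype=float)
        n = np.linalg.norm(d)
        return muscle.force * d / n if n > 0 else np.zeros(3)

    W = 0.0
    for before, after in zip(pts[:-1], pts[1:]):
        W += float(0.5 * (force_at(before) + force_at(after)) @ (after - before))
    return W / 1000.0  # N*mm -> J


def global_work(muscle: GlobalMuscle, rotation: float, moments=None, thetas=None) -> float:
    """Work (J) of a global muscle moment over a rotation (radians).

    Constant moment: ``M * alpha``.  If per-sample ``moments`` and
    ``thetas`` are given, the trapezoidal integral of M dtheta is used.
    """
    if moments is not None:
        m = np.asarray(moments, dtype=float)
        th = np.asarray(thetas, dtype=float)
        return float(np.trapezoid(m, th))
    return float(muscle.moment * rotation)


# -- config loading --------------------------------------------------------

def _data_path(name: str) -> Path:
    return Path(str(resources.files("lumbokin").joinpath("data", name)))


def load_muscle_config(file: str | Path | None = None) -> dict:
    path = Path(file) if file is not None else _data_path("muscles_default.yaml")
    return yaml.safe_load(path.read_text())


def load_targets(movement: str, file: str | Path | None = None) -> RotationTargets:
    path = Path(file) if file is not None else _data_path("targets_healthy.yaml")
    raw = yaml.safe_load(path.read_text())
    if movement not in raw:
        raise KeyError(f"no targets for movement {movement!r} in {path}")
    return RotationTargets(
        movement=movement,
        cumulative=dict(raw[movement]),
        tolerance_deg=float(raw.get("tolerance_deg", 0.25)),
    )


# -- calibration ------------------------------------------------------------

def _psoas_geometry(geometry, muscle_cfg: dict) -> tuple[dict[str, np.ndarray], np.ndarray]:
    p_cfg = muscle_cfg["local"]["psoas_major"]
    offset = float(p_cfg["attachment_anterior_offset"])
    anchor = geometry.frames["S"].origin + np.asarray(p_cfg["anchor"], dtype=float)
    attachments = {}
    for v in geometry.levels:
        frame = geometry.frames[v]
        depth = geometry.config["body_depth"][v]
        attachments[v] = frame.origin - frame.axes[:, 1] * (depth / 2.0 + offset)
    return attachments, anchor


def _active_muscles(movement: str, muscle_cfg: dict) -> tuple[list[str], dict[str, float]]:
    """Active local muscles and global fascicle families for a movement.

    Global families are keyed ``name`` (single action sign) or ``name(+)`` /
    ``name(-)`` for bilateral groups; the value is the action sign about the
    movement axis.  Magnitudes are always nonnegative.
    """
    locals_ = [
        name
        for name, m in muscle_cfg.get("local", {}).items()
        if movement in m.get("movements", ())
    ]
    globals_: dict[str, float] = {}
    for name, m in muscle_cfg.get("global", {}).items():
        signs = m.get("actions", {}).get(movement)
        if not signs:
            continue
        if len(signs) == 1:
            globals_[name] = float(signs[0])
        else:
            for s in signs:
                globals_[f"{name}({'+' if s > 0 else '-'})"] = float(s)
    return locals_, globals_


def _measured_segmentals(state: SpineState, geometry, movement: str) -> np.ndarray:
    table = measure_state(state, geometry, movement=movement)
    return np.array([table.segmental[v] for v in state.chain.vertebrae])


def _distribute(
    m_joint: np.ndarray,
    chain: ChainModel,
    geometry,
    movement: str,
    locals_: list[str],
    globals_: Mapping[str, float],
    targets: RotationTargets,
    muscle_cfg: dict,
) -> tuple[np.ndarray, list[tuple[str, str]], np.ndarray, np.ndarray, list[float]]:
    """Minimum-energy nonnegative muscle magnitudes reproducing the joint
    moments.  Returns (x, variable index, A, c, accepted-energy history).

    Costs are the work magnitudes |M * alpha| (or |F * ds|): eccentric
    (antagonist) action costs effort rather than returning energy, which
    keeps the program bounded and penalizes redundant co-activation.
    """
    axis = MOVEMENT_AXES[movement]
    nj = chain.n_joints
    cols: list[np.ndarray] = []
    index: list[tuple[str, str]] = []
    costs: list[float] = []
    cum_rad = np.radians([targets.cumulative[v] for v in chain.vertebrae])

    for g, sign in globals_.items():
        for k, v in enumerate(chain.vertebrae):
            col = np.zeros(nj)
            col[: k + 1] = sign  # a vertebra moment loads every joint below it
            cols.append(col)
            index.append((g, v))
            costs.append(max(cum_rad[k], 0.0))

    if locals_:
        attachments, anchor = _psoas_geometry(geometry, muscle_cfg)
        for name in locals_:
            for k, v in enumerate(chain.vertebrae):
                p = attachments[v]
                f_dir = anchor - p
                f_dir = f_dir / np.linalg.norm(f_dir)
                col = np.zeros(nj)
                for i in range(k + 1):
                    c_i = chain.joints[i].center_world
                    col[i] = float(np.cross(p - c_i, f_dir) @ axis) / 1000.0  # N*m per N
                cols.append(col)
                index.append((name, v))
                # effort per unit force: |slip shortening| at the target pose,
                # approximated by the target rotation about the joint arms
                costs.append(abs(float(col @ _segment_fractions(cum_rad))))

    A = np.column_stack(cols)
    c = np.asarray(costs)
    history: list[float] = []
    # feasible starting candidate (least-squares, nonnegative)
    nn, nn_res = optimize.nnls(A, m_joint)
    nn_feasible = np.allclose(A @ nn, m_joint, atol=1e-8)
    if nn_feasible:
        history.append(float(c @ nn))
    res = optimize.linprog(c, A_eq=A, b_eq=m_joint, bounds=[(0, None)] * A.shape[1], method="highs")
    if not res.success:
        # targets not reachable with nonnegative magnitudes along these
        # columns; return the closest nonnegative fit for the outer loop
        return nn, index, A, c, history or [float(c @ nn)]
    x = res.x
    W_lp = float(c @ x)
    if not history or W_lp <= history[-1] + 1e-12:
        history.append(W_lp)
    # tie-break: among (near-)energy-equal solutions prefer the smallest
    # squared magnitudes — deterministic split of redundant muscles;
    # accepted only if feasible and not increasing the energy
    cons = [
        {"type": "eq", "fun": lambda z, A=A, m=m_joint: A @ z - m},
        {"type": "ineq", "fun": lambda z, c=c, W=W_lp: W + 1e-9 + 1e-9 * abs(W) - c @ z},
    ]
    qp = optimize.minimize(
        lambda z: z @ z,
        x,
        jac=lambda z: 2.0 * z,
        constraints=cons,
        bounds=[(0.0, None)] * len(x),
        method="SLSQP",
        options={"maxiter": 200, "ftol": 1e-12},
    )
    if (
        qp.success
        and np.all(qp.x >= -1e-9)
        and np.allclose(A @ qp.x, m_joint, atol=1e-8)
        and float(c @ qp.x) <= history[-1] + 1e-9 + 1e-9 * abs(history[-1])
    ):
        x = np.clip(qp.x, 0.0, None)
        history.append(min(float(c @ x), history[-1]))
    return x, index, A, c, history


def _segment_fractions(cum_rad: np.ndarray) -> np.ndarray:
    """Per-joint rotation increments implied by cumulative targets."""
    below = np.concatenate([[0.0], cum_rad[:-1]])
    return cum_rad - below


def _loadcase_from_x(
    x: np.ndarray,
    index: list[tuple[str, str]],
    locals_: list[str],
    globals_: Mapping[str, float],
    movement: str,
    geometry,
    muscle_cfg: dict,
    preload: float,
) -> LoadCase:
    vert_moments: dict[str, float] = {}
    slips: list[tuple] = []
    attachments = anchor = None
    for (name, v), mag in zip(index, x):
        if mag <= 1e-12:
            continue
        if name in locals_:
            if attachments is None:
                attachments, anchor = _psoas_geometry(geometry, muscle_cfg)
            slips.append((v, float(mag), attachments[v], anchor))
        else:
            vert_moments[v] = vert_moments.get(v, 0.0) + float(globals_[name] * mag)
    return LoadCase(
        preload=preload,
        movement=movement,
        apply_top_moment=False,
        vertebra_moments=vert_moments,
        muscle_slips=tuple(slips),
    )


def calibration_energy(
    state: SpineState,
    geometry,
    movement: str,
    forces: Mapping[str, Mapping[str, float]],
    moments: Mapping[str, Mapping[str, float]],
    muscle_cfg: dict | None = None,
) -> EnergyObjective:
    """Recompute the calibration objective W (J) from a converged state.

    Global terms: sum_k M_k * alpha_k with alpha_k the measured cumulative
    rotation (rad) of vertebra k in the movement sense.  Local terms: slip
    force times slip shortening from the neutral to the converged pose.
    """
    muscle_cfg = muscle_cfg or load_muscle_config()
    table = measure_state(state, geometry, movement=movement)
    alpha = {v: abs(np.radians(table.cumulative[v])) for v in table.cumulative}
    global_terms = {
        g: float(sum(m * alpha[v] for v, m in per.items())) for g, per in moments.items()
    }
    local_terms: dict[str, float] = {}
    if forces:
        attachments, anchor = _psoas_geometry(geometry, muscle_cfg)
        maps = state.vertebra_maps()
        for name, per in forces.items():
            W = 0.0
            for v, F in per.items():
                p0 = attachments[v]
                R, d = maps[v]
                p1 = R @ p0 + d
                L0 = float(np.linalg.norm(p0 - anchor))
                L1 = float(np.linalg.norm(p1 - anchor))
                W += F * abs(L0 - L1) / 1000.0  # |shortening| as effort
            local_terms[name] = float(W)
    W = float(sum(global_terms.values()) + sum(local_terms.values()))
    return EnergyObjective(W=W, local_terms=local_terms, global_terms=global_terms)


def calibrate(
    movement: str,
    targets: RotationTargets,
    geometry,
    cards: Mapping[str, MaterialCard] | MaterialCard,
    muscle_cfg: dict | None = None,
    preload: float = 400.0,
    max_outer: int = 14,
    chain: ChainModel | None = None,
) -> CalibrationResult:
    """Calibrate nonnegative muscle magnitudes to meet rotation targets.

    Outer Newton iteration on the per-vertebra driving moments (converged
    equilibrium per evaluation), energy-minimizing distribution over the
    movement's muscle set per iteration; stops when every segmental
    rotation is within the target tolerance (driven to ~tol/5 so cumulative
    angles stay sharp).
    """
    muscle_cfg = muscle_cfg or load_muscle_config()
    if isinstance(cards, MaterialCard):
        cards = {level: cards for level in geometry.joints}
    if chain is None:
        chain = ChainModel(geometry, cards)
    locals_, globals_ = _active_muscles(movement, muscle_cfg)
    if not locals_ and not globals_:
        raise ValueError(f"no muscles configured for movement {movement!r}")

    seg_t = targets.segmental(chain.vertebrae)
    tol = targets.tolerance_deg
    tol_stop = tol / 5.0

    if np.allclose(seg_t, 0.0):
        state = solve_chain(chain, LoadCase(preload=preload, movement=movement, apply_top_moment=False))
        achieved = measure_state(state, geometry, movement=movement)
        zero_f = {m: {v: 0.0 for v in chain.vertebrae} for m in locals_}
        zero_m = {m: {v: 0.0 for v in chain.vertebrae} for m in globals_}
        obj = EnergyObjective(W=0.0, local_terms={m: 0.0 for m in locals_}, global_terms={m: 0.0 for m in globals_})
        return CalibrationResult(zero_f, zero_m, state, achieved, obj, [0.0], 0)

    nj = chain.n_joints
    mu = np.zeros(nj)              # per-vertebra driving moments, N*m
    q_warm = None
    J = None
    descent: list[float] = []
    x = np.zeros(0)
    index: list[tuple[str, str]] = []
    state = None

    def solve_mu(mu_vec: np.ndarray, warm):
        m_joint = np.array([mu_vec[i:].sum() for i in range(nj)])
        xx, idx, A, c, history = _distribute(
            m_joint, chain, geometry, movement, locals_, globals_, targets, muscle_cfg
        )
        case = _loadcase_from_x(xx, idx, locals_, globals_, movement, geometry, muscle_cfg, preload)
        st = solve_chain(chain, case, q0=warm)
        return st, xx, idx, history

    err = None
    for outer in range(1, max_outer + 1):
        state, x, index, descent = solve_mu(mu, q_warm)
        q_warm = state.q
        seg = _measured_segmentals(state, geometry, movement)
        err = seg_t - seg
        if np.max(np.abs(err)) < tol_stop:
            break
        if J is None or outer % 3 == 0:
            J = np.zeros((nj, nj))
            d_mu = max(0.25, 0.05 * max(np.max(np.abs(mu)), 1.0))
            for k in range(nj):
                mu_p = mu.copy()
                mu_p[k] += d_mu
                st_p, *_ = solve_mu(mu_p, q_warm)
                seg_p = _measured_segmentals(st_p, geometry, movement)
                J[:, k] = (seg_p - seg) / d_mu
        try:
            step = np.linalg.solve(J, err)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(J, err, rcond=None)[0]
        max_step = 10.0 + 0.5 * np.max(np.abs(mu))
        norm = np.max(np.abs(step))
        if norm > max_step:
            step = step * (max_step / norm)
        mu = mu + step
    else:
        worst = int(np.argmax(np.abs(err)))
        raise InfeasibleTargetsError(
            f"calibration failed to reach targets for {movement}: worst segment "
            f"{chain.joint_levels[worst]} error {err[worst]:.3f} deg after {max_outer} iterations"
        )

    forces: dict[str, dict[str, float]] = {m: {} for m in locals_}
    moments: dict[str, dict[str, float]] = {m: {} for m in globals_}
    for (name, v), mag in zip(index, x):
        target_map = forces if name in locals_ else moments
        if mag > 1e-12:
            target_map[name][v] = target_map[name].get(v, 0.0) + float(mag)
    if np.any(x < -1e-12):
        raise AssertionError("nonnegativity violated in muscle distribution")

    achieved = measure_state(state, geometry, movement=movement)
    objective = calibration_energy(state, geometry, movement, forces, moments, muscle_cfg)
    return CalibrationResult(
        forces=forces,
        moments=moments,
        state=state,
        achieved=achieved,
        objective=objective,
        descent_history=descent,
        iterations=outer,
    )
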