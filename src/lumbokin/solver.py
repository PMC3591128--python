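"""Quasi-static equilibrium of the assembled L1-sacrum chain.

The sacrum is fixed (wings constrained); each joint contributes six relative
DOFs.  Loads are a follower compressive preload (force pairs along the
current lines joining adjacent body centroids, so the load direction tracks
the deformed axis), external moments at the top vertebra, optional
per-vertebra muscle moments and muscle slip forces.  All loads derive from
potentials, so equilibrium is found by minimizing the total potential with
a damped Newton iteration under incremental load stepping; gradients and
Hessians come from batched central finite differences of the energy.

Convergence is declared when every residual force component is below
``tol_force`` (N) and every residual moment component below ``tol_moment``
(N*mm).  The iteration schedule is fixed and deterministic: identical
inputs give identical convergence paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from ._model import ChainModel, ResolvedLoad
from .kinematics import AngleTable, measure_state
from .materials import MaterialCard
from .segment import SegmentState

__all__ = [
    "LoadCase",
    "SpineState",
    "NonConvergenceError",
    "MOVEMENT_AXES",
    "solve_equilibrium",
    "range_of_motion",
    "solve_chain",
]

# world-frame rotation axis of each movement (flexion positive about +x,
# right lateral bending +y, right axial rotation +z)
MOVEMENT_AXES = {
    "FLX": np.array([1.0, 0.0, 0.0]),
    "EXT": np.array([-1.0, 0.0, 0.0]),
    "LB": np.array([0.0, 1.0, 0.0]),
    "AR": np.array([0.0, 0.0, 1.0]),
}
DEFAULT_MOMENTS_NM = {"FLX": 15.0, "EXT": 15.0, "LB": 15.0, "AR": 6.0}


class NonConvergenceError(RuntimeError):
    def __init__(self, message: str, residual: float, step: float):
        super().__init__(f"{message} (last residual {residual:.3e}, load fraction {step:.3f})")
        self.residual = residual
        self.step = step


@dataclass(frozen=True)
class LoadCase:
    """External loading of one simulated movement.

    ``moment_nm`` overrides the per-movement default (15 N*m, 6 N*m for
    axial rotation); ``vertebra_moments`` are additional per-vertebra muscle
    moments (N*m, about the movement axis) and ``muscle_slips`` are
    (vertebra, force N, attachment point, anchor point) tuples in world mm.
    """

    preload: float = 400.0
    preload_type: str = "follower"
    movement: str | None = None
    moment_nm: float | None = None
    apply_top_moment: bool = True
    vertebra_moments: Mapping[str, float] = field(default_factory=dict)
    muscle_slips: Sequence[tuple] = ()

    def __post_init__(self) -> None:
        if self.preload < 0:
            raise ValueError("preload must be nonnegative")
        if self.preload_type not in ("follower", "vertical"):
            raise ValueError("preload_type must be 'follower' or 'vertical'")
        if self.movement is not None and self.movement not in MOVEMENT_AXES:
            raise ValueError(f"movement must be one of {sorted(MOVEMENT_AXES)}")


def resolve_load(case: LoadCase, chain: ChainModel) -> ResolvedLoad:
    """Convert a LoadCase (N*m, movement names) to world-frame primitives."""
    moments: list[tuple[str, np.ndarray]] = []
    if case.movement is not None:
        axis = MOVEMENT_AXES[case.movement]
        top = chain.vertebrae[-1]
        if case.apply_top_moment:
            mag = DEFAULT_MOMENTS_NM[case.movement] if case.moment_nm is None else case.moment_nm
            if mag:
                moments.append((top, axis * mag * 1000.0))
        for label, m_nm in case.vertebra_moments.items():
            if m_nm:
                moments.append((label, axis * m_nm * 1000.0))
    slips = tuple(
        (label, float(force), np.asarray(attach, dtype=float), np.asarray(anchor, dtype=float))
        for label, force, attach, anchor in case.muscle_slips
    )
    return ResolvedLoad(
        preload=case.preload,
        preload_type=case.preload_type,
        moments=tuple(moments),
        slips=slips,
    )


@dataclass
class SpineState:
    """Converged generalized coordinates plus the convergence record."""

    q: np.ndarray                     # (n_joints, 6) local (t mm, theta rad)
    chain: ChainModel
    converged: bool
    residual_force: float             # max |dU/dt|, N
    residual_moment: float            # max |dU/dtheta|, N*mm
    iterations: int
    load_steps: int

    def vertebra_maps(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """World affine map (R, d) per vertebra label (neutral -> deformed)."""
        poses = self.chain.poses(self.q[None])
        return {v: (R[0], d[0]) for v, (R, d) in zip(self.chain.vertebrae, poses)}

    def segment_states(self) -> list[SegmentState]:
        out = []
        for level, qk in zip(self.chain.joint_levels, self.q):
            out.append(
                SegmentState(level=level, translation=qk[:3], rotation=np.degrees(qk[3:]))
            )
        return out

    def segment_rotations_about(self, movement: str) -> np.ndarray:
        """Rotation of each joint about the movement axis, degrees, bottom-up."""
        axis = MOVEMENT_AXES[movement]
        out = []
        for joint, qk in zip(self.chain.joints, self.q):
            local_axis = joint.axes_world.T @ axis
            out.append(np.degrees(qk[3:] @ local_axis))
        return np.asarray(out)

    def nucleus_volume_changes(self) -> dict[str, float]:
        return {
            joint.level: joint.volume_change_ratio(float(qk[2]))
            for joint, qk in zip(self.chain.joints, self.q)
        }

    def convergence_record(self) -> dict:
        return {
            "converged": bool(self.converged),
            "residual_force_N": float(self.residual_force),
            "residual_moment_Nmm": float(self.residual_moment),
            "iterations": int(self.iterations),
            "load_steps": int(self.load_steps),
        }


# -- Newton machinery -----------------------------------------------------

_H_GRAD = (3e-5, 3e-7)   # FD half-steps: translations mm, rotations rad
_H_HESS = (1e-4, 1e-6)


def _gradient(chain: ChainModel, q: np.ndarray, load: ResolvedLoad, scale: float) -> np.ndarray:
    """Gradient of the total potential: exact-at-kink internal gradients per
    joint plus central differences of the (smooth) external potential."""
    n = chain.ndof
    g = np.concatenate([joint.gradient_from_q(q[k]) for k, joint in enumerate(chain.joints)])
    steps = np.tile(np.array([_H_GRAD[0]] * 3 + [_H_GRAD[1]] * 3), chain.n_joints)
    Q = np.repeat(q.reshape(1, -1), 2 * n, axis=0)
    idx = np.arange(n)
    Q[2 * idx, idx] += steps
    Q[2 * idx + 1, idx] -= steps
    E = chain.external_potential(Q.reshape(2 * n, chain.n_joints, 6), load, scale)
    return g + (E[0::2] - E[1::2]) / (2.0 * steps)


def _hessian(chain: ChainModel, q: np.ndarray, load: ResolvedLoad, scale: float) -> np.ndarray:
    n = chain.ndof
    H = np.zeros((n, n))
    hsteps = np.array([_H_HESS[0]] * 3 + [_H_HESS[1]] * 3)

    # internal energy: exactly block-diagonal over joints; differenced from
    # the exact-at-kink gradient so Hessian and gradient stay consistent
    for k, joint in enumerate(chain.joints):
        qk = q[k]
        block = np.zeros((6, 6))
        for i in range(6):
            qp, qm = qk.copy(), qk.copy()
            qp[i] += hsteps[i]
            qm[i] -= hsteps[i]
            block[:, i] = (joint.gradient_from_q(qp) - joint.gradient_from_q(qm)) / (2.0 * hsteps[i])
        base = 6 * k
        H[base : base + 6, base : base + 6] += 0.5 * (block + block.T)

    # external potential: dense but cheap (no constituent arrays involved)
    steps = np.tile(hsteps, chain.n_joints)
    rows = [q.reshape(-1)]
    for i in range(n):
        for s in (+1.0, -1.0):
            r = q.reshape(-1).copy()
            r[i] += s * steps[i]
            rows.append(r)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    for i, j in pairs:
        for si, sj in ((+1, +1), (+1, -1), (-1, +1), (-1, -1)):
            r = q.reshape(-1).copy()
            r[i] += si * steps[i]
            r[j] += sj * steps[j]
            rows.append(r)
    E = chain.external_potential(np.asarray(rows).reshape(-1, chain.n_joints, 6), load, scale)
    e0 = E[0]
    for i in range(n):
        ep, em = E[1 + 2 * i], E[2 + 2 * i]
        H[i, i] += (ep - 2.0 * e0 + em) / steps[i] ** 2
    off = E[1 + 2 * n :]
    for p, (i, j) in enumerate(pairs):
        epp, epm, emp, emm = off[4 * p : 4 * p + 4]
        val = (epp - epm - emp + emm) / (4.0 * steps[i] * steps[j])
        H[i, j] += val
        H[j, i] += val
    return H


def _residual_split(chain: ChainModel, g: np.ndarray) -> tuple[float, float]:
    G = g.reshape(chain.n_joints, 6)
    return float(np.max(np.abs(G[:, :3]))), float(np.max(np.abs(G[:, 3:])))


def _newton(
    chain: ChainModel,
    q: np.ndarray,
    load: ResolvedLoad,
    scale: float,
    tol_force: float,
    tol_moment: float,
    max_iter: int,
) -> tuple[np.ndarray, float, float, int, bool]:
    it = 0
    for it in range(1, max_iter + 1):
        g = _gradient(chain, q, load, scale)
        rf, rm = _residual_split(chain, g)
        if rf < tol_force and rm < tol_moment:
            return q, rf, rm, it, True
        H = _hessian(chain, q, load, scale)
        lam = 0.0
        diag_scale = float(np.max(np.abs(np.diag(H)))) or 1.0
        delta = None
        for _ in range(8):
            try:
                delta = np.linalg.solve(H + lam * np.eye(chain.ndof), -g)
                if np.all(np.isfinite(delta)):
                    break
            except np.linalg.LinAlgError:
                pass
            lam = max(lam * 10.0, 1e-8 * diag_scale)
        if delta is None or not np.all(np.isfinite(delta)):
            return q, rf, rm, it, False
        e0 = float(chain.total_potential(q[None], load, scale)[0])
        slope = float(g @ delta)
        step = 1.0
        accepted = False
        for _ in range(25):
            q_try = q + step * delta.reshape(chain.n_joints, 6)
            e_try = float(chain.total_potential(q_try[None], load, scale)[0])
            if e_try <= e0 + 1e-4 * step * slope or e_try < e0 + 1e-12 * max(1.0, abs(e0)):
                q = q_try
                accepted = True
                break
            step *= 0.5
        if not accepted:
            # gradient is nonzero but no descent found: report best effort
            return q, rf, rm, it, False
    g = _gradient(chain, q, load, scale)
    rf, rm = _residual_split(chain, g)
    return q, rf, rm, it, rf < tol_force and rm < tol_moment


def solve_chain(
    chain: ChainModel,
    case: LoadCase,
    q0: np.ndarray | None = None,
    n_steps: int = 10,
    tol_force: float = 1e-6,
    tol_moment: float = 1e-3,
    max_iter: int = 60,
    max_halvings: int = 4,
) -> SpineState:
    """Solve equilibrium on an already-built chain (warm start via q0)."""
    load = resolve_load(case, chain)
    q = np.zeros((chain.n_joints, 6)) if q0 is None else np.array(q0, dtype=float)
    total_iters = 0
    steps_done = 0

    # trivially converged? (zero loads at the neutral state)
    g = _gradient(chain, q, load, 1.0)
    rf, rm = _residual_split(chain, g)
    if rf < tol_force and rm < tol_moment:
        return SpineState(q, chain, True, rf, rm, 1, 0)

    scales = list(np.linspace(1.0 / n_steps, 1.0, n_steps))
    prev = 0.0
    halvings = 0
    while scales:
        s = scales[0]
        q_new, rf, rm, it, ok = _newton(chain, q, load, s, tol_force, tol_moment, max_iter)
        total_iters += it
        if ok:
            q = q_new
            prev = s
            scales.pop(0)
            steps_done += 1
            continue
        if halvings >= max_halvings:
            raise NonConvergenceError(
                "equilibrium iteration failed to converge", max(rf, rm), s
            )
        # halve the failing increment
        scales.insert(0, 0.5 * (prev + s))
        halvings += 1
    return SpineState(q, chain, True, rf, rm, total_iters, steps_done)


def solve_equilibrium(
    loadcase: LoadCase,
    geometry,
    card_map: Mapping[str, MaterialCard] | MaterialCard,
    chain: ChainModel | None = None,
    **options,
) -> SpineState:
    """Build the chain (one material card per level or a single shared card)
    and solve quasi-static equilibrium under the load case."""
    if chain is None:
        if isinstance(card_map, MaterialCard):
            card_map = {level: card_map for level in geometry.joints}
        missing = set(geometry.joints) - set(card_map)
        if missing:
            raise KeyError(f"missing material card for levels {sorted(missing)}")
        chain = ChainModel(geometry, card_map)
    return solve_chain(chain, loadcase, **options)


def range_of_motion(
    movement: str,
    loadcase: LoadCase,
    geometry,
    card_map: Mapping[str, MaterialCard] | MaterialCard,
    variant: str = "projected",
    chain: ChainModel | None = None,
    state: SpineState | None = None,
) -> AngleTable:
    """Cumulative (and segmental) angles of every vertebra vs the sacrum.

    Solves equilibrium for the movement's load case and measures the state
    through the endplate reference-line formulas, the same code path used
    for radiological landmark data.
    """
    case = replace(loadcase, movement=movement) if loadcase.movement != movement else loadcase
    if state is None:
        state = solve_equilibrium(case, geometry, card_map, chain=chain)
    table = measure_state(state, geometry, movement=movement, variant=variant)
    table.meta["convergence"] = state.convergence_record()
    return table
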