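"""Single motion-segment mechanics: restoring wrench and tangent stiffness.

A segment state is the 6-DOF displacement of the upper vertebra relative to
the lower one, expressed in the disc-local frame at the disc centroid
(translations mm; rotations degrees about x = flexion(+)/extension(-),
y = lateral bending, z = axial rotation).  The restoring wrench is the
negative gradient of the segment's stored energy and is reported with a
per-constituent breakdown (annulus ground substance, nucleus, fibre layers,
ligaments, facet contacts), so sign patterns such as "posterior ligaments
tension in flexion" can be asserted directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from ._model import JointModel, build_joint_model
from .materials import MaterialCard

__all__ = [
    "SegmentState",
    "SegmentWrench",
    "segment_wrench",
    "nucleus_volume_change",
    "tangent_stiffness",
    "ligament_tensions",
    "fiber_tensions",
]

_CONSTITUENTS = ("annulus", "nucleus", "fibers", "ligaments", "facets")


@dataclass(frozen=True)
class SegmentState:
    """Relative pose of the upper vertebra of one segment (mm, degrees)."""

    level: str
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rotation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float))
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float))
        if np.any(np.abs(self.rotation) >= 90.0):
            raise ValueError("segment rotations must stay within the quasi-static range (|deg| < 90)")

    @property
    def q(self) -> np.ndarray:
        """Internal 6-vector (t mm, theta rad)."""
        return np.concatenate([self.translation, np.radians(self.rotation)])


@dataclass(frozen=True)
class SegmentWrench:
    """Restoring force (N) and moment (N*m) with per-constituent breakdown."""

    force: np.ndarray
    moment: np.ndarray
    breakdown: Mapping[str, tuple[np.ndarray, np.ndarray]]

    @property
    def total(self) -> np.ndarray:
        return np.concatenate([self.force, self.moment])


def _joint_for(state_level: str, geometry, card: MaterialCard) -> JointModel:
    if state_level not in geometry.discs:
        raise KeyError(f"unknown segment level {state_level!r}; geometry has {sorted(geometry.discs)}")
    return build_joint_model(geometry, card, state_level)


def _constituent_gradients(joint: JointModel, q: np.ndarray) -> dict:
    """Per-constituent energy gradients, exact at tension-onset kinks."""
    return joint.constituent_gradients(q)


def segment_wrench(state: SegmentState, geometry, card: MaterialCard) -> SegmentWrench:
    """Restoring wrench of one segment at a given state.

    The wrench is the negative energy gradient: forces in N, moments in N*m
    (about the disc-local axes at the disc centroid).  The breakdown sums
    exactly to the total.
    """
    joint = _joint_for(state.level, geometry, card)
    grads = _constituent_gradients(joint, state.q)
    breakdown = {}
    for name in _CONSTITUENTS:
        g = grads[name]
        breakdown[name] = (-g[:3], -g[3:] / 1000.0)  # N*mm -> N*m
    force = np.sum([b[0] for b in breakdown.values()], axis=0)
    moment = np.sum([b[1] for b in breakdown.values()], axis=0)
    return SegmentWrench(force=force, moment=moment, breakdown=breakdown)


def nucleus_volume_change(state: SegmentState, geometry, card: MaterialCard) -> float:
    """Relative nucleus volume change (V - V0)/V0 at a segment state.

    Zero at neutral; negative under net axial compression.  For the
    incompressible (penalty) card the converged magnitude stays below the
    penalty tolerance; for compressible elastic nuclei it reflects the
    material's bulk modulus in series with the annulus-wall confinement.
    """
    joint = _joint_for(state.level, geometry, card)
    return joint.volume_change_ratio(float(state.q[2]))


def ligament_tensions(state: SegmentState, geometry, card: MaterialCard) -> dict[str, float]:
    """Total tensile force (N) per ligament family at a segment state.

    Tension-only by construction: slack or compressed strands report zero.
    """
    joint = _joint_for(state.level, geometry, card)
    return joint.ligament_forces(state.q)


def fiber_tensions(state: SegmentState, geometry, card: MaterialCard) -> "np.ndarray":
    """Per-sample fibre tensile forces (N) with sample metadata.

    Returns a structured view: (positions (n,3) disc-local, directions
    (n,3), layer indices (n,), tensions (n,)).
    """
    joint = _joint_for(state.level, geometry, card)
    tensions = joint.fiber_tensions(state.q)
    mid = 0.5 * (joint.fib_pl + joint.fib_pu)
    directions = joint.fib_pu - joint.fib_pl
    directions = directions / np.linalg.norm(directions, axis=1, keepdims=True)
    return mid, directions, joint.fib_layer, tensions


def tangent_stiffness(state: SegmentState, geometry, card: MaterialCard, h: float = 1e-4) -> np.ndarray:
    """Symmetric 6x6 tangent stiffness by central differencing of the wrench.

    Internal units (N, mm, rad): rows/cols ordered (tx, ty, tz, rx, ry, rz);
    force rows are N per unit DOF, moment rows N*mm per unit DOF.
    """
    if h <= 0:
        raise ValueError("finite-difference step h must be positive")
    joint = _joint_for(state.level, geometry, card)
    q0 = state.q
    steps = np.array([h] * 3 + [h * 1e-2] * 3)

    def grad(q: np.ndarray) -> np.ndarray:
        g = _constituent_gradients(joint, q)
        return np.sum([g[name] for name in _CONSTITUENTS], axis=0)

    K = np.zeros((6, 6))
    for j in range(6):
        qp, qm = q0.copy(), q0.copy()
        qp[j] += steps[j]
        qm[j] -= steps[j]
        K[:, j] = (grad(qp) - grad(qm)) / (2.0 * steps[j])
    return 0.5 * (K + K.T)
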