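"""Vertebral mobility measurement from endplate reference lines.

Every vertebra (and the sacrum) carries two perpendicular reference lines on
its superior endplate: a *frontal* line joining the mediolateral endplate
nodes and a *sagittal* line joining the anteroposterior ones.  Relative
angles with respect to the sacrum are computed from the direction cosines
of those lines, pairing the components of the measurement plane:

* flexion-extension — sagittal lines, (m, n) components (YZ plane);
* lateral bending  — frontal lines, (l, n) components (XZ plane);
* axial rotation   — frontal lines, (l, m) components (XY plane).

Two variants are provided.  The *literal* variant forms the inner product of
the raw in-plane cosine pairs (cos a = m1 m2 + n1 n2, etc.), which equals
the in-plane angle exactly only when both lines lie in the plane.  The
*projected* variant normalizes the in-plane projections first and is robust
to out-of-plane contamination of 3-D states; it is the default.

Sign convention: positive angles correspond to positive rotation about the
movement axis (x for flexion, y for lateral bending, z for axial rotation),
so flexion, right lateral bending and right axial rotation are positive.
The same code path measures model states and radiological landmark data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ReferenceLine",
    "DirectionCosines",
    "AngleTable",
    "line_length",
    "direction_cosines",
    "relative_angle",
    "measure_state",
    "DegenerateLineError",
]

LUMBAR_LABELS = ("L1", "L2", "L3", "L4", "L5")

# measurement plane per movement: (component indices, sign orientation)
_PLANES = {
    "FE": ((1, 2), "sagittal"),   # (m, n) of the sagittal line
    "LB": ((0, 2), "frontal"),    # (l, n) of the frontal line
    "AR": ((0, 1), "frontal"),    # (l, m) of the frontal line
}
_MOVEMENT_PLANE = {"FLX": "FE", "EXT": "FE", "LB": "LB", "AR": "AR"}
# 2-D cross-product orientation making the measured sign equal the rotation
# angle about the movement axis (+x, +y, +z respectively).
_CROSS_SIGN = {"FE": 1.0, "LB": -1.0, "AR": 1.0}


class DegenerateLineError(ValueError):
    """Raised when a reference line has (numerically) coincident nodes."""


@dataclass(frozen=True)
class ReferenceLine:
    """Oriented endplate reference line (mm)."""

    plane: str  # 'frontal' | 'sagittal'
    start: np.ndarray
    end: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "start", np.asarray(self.start, dtype=float))
        object.__setattr__(self, "end", np.asarray(self.end, dtype=float))
        if self.plane not in ("frontal", "sagittal"):
            raise ValueError("plane must be 'frontal' or 'sagittal'")

    @property
    def vector(self) -> np.ndarray:
        return self.end - self.start


@dataclass(frozen=True)
class DirectionCosines:
    l: float
    m: float
    n: float

    def __post_init__(self) -> None:
        norm = self.l**2 + self.m**2 + self.n**2
        if abs(norm - 1.0) > 1e-9:
            raise ValueError("direction cosines must satisfy l^2+m^2+n^2 = 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.l, self.m, self.n])


def line_length(line: ReferenceLine) -> float:
    """Euclidean length of a reference line (mm); 0 flags a degenerate line."""
    return float(np.linalg.norm(line.vector))


def direction_cosines(line: ReferenceLine) -> DirectionCosines:
    """Unit-vector components (l, m, n) along the line."""
    length = line_length(line)
    if length <= 1e-12:
        raise DegenerateLineError("reference line has coincident nodes")
    v = line.vector / length
    return DirectionCosines(float(v[0]), float(v[1]), float(v[2]))


def _signed_plane_angle(u2: np.ndarray, v2: np.ndarray, plane: str) -> float:
    dot = float(u2 @ v2)
    cross = float(u2[0] * v2[1] - u2[1] * v2[0]) * _CROSS_SIGN[plane]
    return float(np.degrees(np.arctan2(cross, dot)))


def relative_angle(
    vertebra_line: ReferenceLine,
    sacrum_line: ReferenceLine,
    plane: str,
    variant: str = "projected",
) -> float:
    """Signed angle (degrees) between a vertebra line and the sacrum line.

    ``plane`` is ``'FE'``, ``'LB'`` or ``'AR'`` and selects the component
    pair.  ``variant='literal'`` evaluates the raw inner product of the
    in-plane direction-cosine pairs; ``'projected'`` (default) normalizes
    the in-plane projections.  The sign comes from the 2-D cross product in
    the measurement plane for both variants.
    """
    if plane not in _PLANES:
        raise ValueError(f"plane must be one of {sorted(_PLANES)}, got {plane!r}")
    if variant not in ("projected", "literal"):
        raise ValueError("variant must be 'projected' or 'literal'")
    idx, _expected = _PLANES[plane]
    u = direction_cosines(sacrum_line).as_array()
    v = direction_cosines(vertebra_line).as_array()
    u2, v2 = u[list(idx)], v[list(idx)]
    if variant == "literal":
        inner = float(u2 @ v2)
        if abs(inner) > 1.0 + 1e-9:
            raise ValueError("direction-cosine inner product exceeds 1: unnormalized input")
        magnitude = float(np.degrees(np.arccos(np.clip(inner, -1.0, 1.0))))
        sign = np.sign(_signed_plane_angle(u2, v2, plane)) or 1.0
        return float(sign * magnitude)
    nu, nv = np.linalg.norm(u2), np.linalg.norm(v2)
    if nu <= 1e-12 or nv <= 1e-12:
        raise DegenerateLineError("line projects to a point in the measurement plane")
    return _signed_plane_angle(u2 / nu, v2 / nv, plane)


@dataclass
class AngleTable:
    """Per-vertebra cumulative (and segmental) angles for one movement."""

    movement: str
    cumulative: Mapping[str, float]
    segmental: Mapping[str, float] | None = None
    sd: Mapping[str, float] | None = None
    n: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sd is not None and any(s < 0 for s in self.sd.values()):
            raise ValueError("standard deviations must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label in self.cumulative:
            row = {"vertebra": label, "cumulative_deg": self.cumulative[label]}
            if self.segmental is not None:
                row["segmental_deg"] = self.segmental.get(label, np.nan)
            if self.sd is not None:
                row["sd_deg"] = self.sd.get(label, np.nan)
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _transform_line(line: ReferenceLine, R: np.ndarray, d: np.ndarray) -> ReferenceLine:
    return ReferenceLine(line.plane, R @ line.start + d, R @ line.end + d)


def measure_state(
    state,
    geometry,
    movement: str = "FLX",
    variant: str = "projected",
    line_provider=None,
) -> AngleTable:
    """Measure per-vertebra cumulative angles of a converged spine state.

    ``state`` must expose ``vertebra_maps()`` returning, per vertebra label,
    the affine map ``(R, d)`` from neutral to deformed coordinates (sacrum
    maps to the identity).  Reference lines are taken from the geometry's
    frames, transformed by the pose, and compared with the sacrum lines via
    the plane formulas.  Segmental angles compare adjacent vertebrae.
    """
    plane = _MOVEMENT_PLANE.get(movement)
    if plane is None:
        raise ValueError(f"unknown movement {movement!r}")
    from .geometry import reference_lines  # local import; no cycle at module load

    if line_provider is None:
        line_provider = lambda label: reference_lines(geometry.frames[label])
    which = 0 if plane in ("LB", "AR") else 1  # frontal vs sagittal line
    maps = state.vertebra_maps()
    labels = tuple(l for l in LUMBAR_LABELS if l in maps)

    neutral = {label: line_provider(label)[which] for label in ("S",) + labels}
    deformed = {}
    for label in neutral:
        if label == "S":
            deformed[label] = neutral[label]
        else:
            R, d = maps[label]
            deformed[label] = _transform_line(neutral[label], R, d)

    # Angles are measured as change from the neutral posture so that the
    # lordotic wedge angles do not contaminate the mobility values.
    def angle_vs(label_hi: str, label_lo: str) -> float:
        moved = relative_angle(deformed[label_hi], deformed[label_lo], plane, variant)
        rest = relative_angle(neutral[label_hi], neutral[label_lo], plane, variant)
        return moved - rest

    # report in the movement's own positive sense (extension positive for EXT)
    sense = -1.0 if movement == "EXT" else 1.0
    cumulative = {label: sense * angle_vs(label, "S") for label in labels}
    order = list(labels) + ["S"]
    segmental = {
        order[i]: sense * angle_vs(order[i], order[i + 1]) for i in range(len(order) - 1)
    }
    return AngleTable(movement=movement, cumulative=cumulative, segmental=segmental)


def angles_from_landmarks(
    lines: Mapping[str, ReferenceLine],
    sacrum_line: ReferenceLine,
    movement: str,
    variant: str = "projected",
    neutral_lines: Mapping[str, ReferenceLine] | None = None,
    neutral_sacrum: ReferenceLine | None = None,
) -> AngleTable:
    """Cumulative angles from explicit landmark lines (radiological path).

    When neutral (standing) lines are supplied the angle is the change from
    neutral, mirroring the radiographic protocol of comparing the moved line
    with the standing one.
    """
    plane = _MOVEMENT_PLANE.get(movement)
    if plane is None:
        raise ValueError(f"unknown movement {movement!r}")
    sense = -1.0 if movement == "EXT" else 1.0
    cumulative: dict[str, float] = {}
    for label, line in lines.items():
        ang = relative_angle(line, sacrum_line, plane, variant)
        if neutral_lines is not None:
            ref = neutral_sacrum if neutral_sacrum is not None else sacrum_line
            ang -= relative_angle(neutral_lines[label], ref, plane, variant)
        cumulative[label] = sense * ang
    return AngleTable(movement=movement, cumulative=cumulative)
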