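"""Parametric L1-sacrum geometry builder.

The builder produces an anatomically plausible, bilaterally symmetric
stand-in for a scanned lumbar column: vertebra reference frames stacked
with lordotic wedge angles, elliptical disc cross-sections split into
nucleus and annulus, crossed annulus fibre-layer samples, ligament
attachment pairs for the eight ligament families, and facet contact pairs.
Every dimension is a named config parameter (YAML), so sensitivity studies
never require code changes.

Coordinates: x mediolateral (mirror plane x = 0), y anteroposterior with
anterior at -y, z cranial; mm throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from ._rotations import rotate_about
from .kinematics import ReferenceLine

__all__ = [
    "VertebraFrame",
    "DiscGeometry",
    "FiberLayerSpec",
    "LigamentAttachment",
    "FacetPair",
    "SpineGeometry",
    "default_config",
    "build_default_spine",
    "fiber_directions",
    "reference_lines",
]

LUMBAR = ("L1", "L2", "L3", "L4", "L5")
JOINTS = ("L5-S1", "L4-L5", "L3-L4", "L2-L3", "L1-L2")  # bottom-up
X = np.array([1.0, 0.0, 0.0])
Y = np.array([0.0, 1.0, 0.0])
Z = np.array([0.0, 0.0, 1.0])


@dataclass(frozen=True)
class VertebraFrame:
    """Rigid vertebra frame: body centroid origin and orthonormal triad."""

    label: str
    origin: np.ndarray
    axes: np.ndarray  # columns: x (mediolateral), y (anteroposterior), z (cranial)
    endplate_nodes_sup: np.ndarray  # (4, 3): +x, -x, anterior, posterior
    endplate_nodes_inf: np.ndarray

    def __post_init__(self) -> None:
        A = np.asarray(self.axes, dtype=float)
        if not np.allclose(A.T @ A, np.eye(3), atol=1e-10):
            raise ValueError(f"frame {self.label}: axes not orthonormal")


@dataclass(frozen=True)
class DiscGeometry:
    """Elliptical intervertebral disc between two frames."""

    level: str
    height: float
    annulus_outer_radius_ml: float
    annulus_outer_radius_ap: float
    nucleus_area_fraction: float
    centroid: np.ndarray
    axes: np.ndarray  # disc mid-plane frame (mean of adjacent frames)

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise ValueError(f"disc {self.level}: height must be positive")
        if not 0.0 < self.nucleus_area_fraction < 1.0:
            raise ValueError(f"disc {self.level}: nucleus_area_fraction must be in (0,1)")

    @property
    def area(self) -> float:
        return float(np.pi * self.annulus_outer_radius_ml * self.annulus_outer_radius_ap)

    @property
    def nucleus_area(self) -> float:
        return self.area * self.nucleus_area_fraction

    @property
    def annulus_area(self) -> float:
        return self.area * (1.0 - self.nucleus_area_fraction)


@dataclass(frozen=True)
class FiberLayerSpec:
    """Sampled fibre sheet of the annulus.

    ``sample_points`` holds ``(position, direction)`` pairs on the annulus
    mid-surface in disc-local coordinates; crossed layers carry both +/-
    families.  The outermost sheet is a single physical layer and is sampled
    with half the fibre count split evenly between the two handedness
    families to preserve bilateral symmetry of the default geometry.
    """

    layer_index: int
    orientation_deg: float
    sample_points: tuple[tuple[np.ndarray, np.ndarray], ...]
    crossed: bool = True

    def __post_init__(self) -> None:
        if not 1 <= self.layer_index <= 5:
            raise ValueError("layer_index must be 1..5")
        if not 35.0 - 1e-9 <= self.orientation_deg <= 80.0 + 1e-9:
            raise ValueError("fibre orientation must lie in [35, 80] degrees")


@dataclass(frozen=True)
class LigamentAttachment:
    """One ligament strand: lower origin, upper insertion, rest length."""

    name: str
    level: str
    origin: np.ndarray      # world, on/below the lower vertebra (or ground)
    insertion: np.ndarray   # world, on the upper vertebra
    rest_length: float
    cross_section: float
    pre_strain: float = 0.0  # <= 0 delays tension onset (slackening)

    def __post_init__(self) -> None:
        if self.cross_section <= 0:
            raise ValueError(f"{self.name}@{self.level}: cross_section must be positive")
        if self.rest_length <= 0:
            raise ValueError(f"{self.name}@{self.level}: rest_length must be positive")


@dataclass(frozen=True)
class FacetPair:
    level: str
    side: str  # 'left' | 'right'
    contact_point: np.ndarray
    normal: np.ndarray
    gap: float
    stiffness: float

    def __post_init__(self) -> None:
        if self.gap < 0:
            raise ValueError(f"facet {self.level}/{self.side}: gap must be >= 0")


@dataclass
class SpineGeometry:
    """Complete parametric column: frames, discs, fibres, ligaments, facets."""

    frames: dict[str, VertebraFrame]
    discs: dict[str, DiscGeometry]
    fiber_layers: dict[str, list[FiberLayerSpec]]
    ligaments: list[LigamentAttachment]
    facets: list[FacetPair]
    config: dict = field(default_factory=dict)
    joints: tuple[str, ...] = JOINTS

    @property
    def levels(self) -> tuple[str, ...]:
        """Lumbar levels present, bottom-up."""
        return tuple(self.config["levels"])

    @property
    def column_height(self) -> float:
        """Sum of lumbar body heights and disc heights (bookkeeping)."""
        bh = self.config["body_height"]
        dh = self.config["disc_height"]
        return float(sum(bh[v] for v in self.levels) + sum(dh[j] for j in self.joints))

    def dump_json(self, path) -> None:
        def arr(a):
            return np.asarray(a).round(6).tolist()

        payload = {
            "frames": {
                k: {"origin": arr(f.origin), "axes": arr(f.axes)} for k, f in self.frames.items()
            },
            "discs": {
                k: {
                    "height": d.height,
                    "centroid": arr(d.centroid),
                    "radius_ml": d.annulus_outer_radius_ml,
                    "radius_ap": d.annulus_outer_radius_ap,
                }
                for k, d in self.discs.items()
            },
            "ligaments": [
                {
                    "name": l.name,
                    "level": l.level,
                    "origin": arr(l.origin),
                    "insertion": arr(l.insertion),
                    "rest_length": l.rest_length,
                }
                for l in self.ligaments
            ],
            "facets": [
                {"level": f.level, "side": f.side, "point": arr(f.contact_point), "gap": f.gap}
                for f in self.facets
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def default_config() -> dict:
    """Packaged default geometry parameters."""
    path = resources.files("lumbokin").joinpath("data", "geometry_default.yaml")
    return yaml.safe_load(Path(str(path)).read_text())


def _check_positive(config: dict) -> None:
    for key in ("body_height", "body_width", "body_depth", "disc_height"):
        for name, value in config[key].items():
            if not value > 0:
                raise ValueError(f"geometry config: {key}[{name}] must be positive, got {value}")
    for key in ("radius_fraction", "nucleus_area_fraction", "nucleus_penalty_bulk_factor"):
        if not config["disc"][key] > 0:
            raise ValueError(f"geometry config: disc.{key} must be positive")
    if not 0 < config["disc"]["nucleus_area_fraction"] < 1:
        raise ValueError("geometry config: disc.nucleus_area_fraction must be in (0, 1)")


def _ellipse_point(a: float, b: float, phi: float) -> np.ndarray:
    return np.array([a * np.cos(phi), b * np.sin(phi), 0.0])


def _ellipse_tangent(a: float, b: float, phi: float) -> np.ndarray:
    t = np.array([-a * np.sin(phi), b * np.cos(phi), 0.0])
    return t / np.linalg.norm(t)


def _layer_angles(config: dict) -> np.ndarray:
    fib = config["fibers"]
    return np.linspace(float(fib["angle_inner_deg"]), float(fib["angle_outer_deg"]), int(fib["n_layers"]))


def _build_fiber_layers(disc: DiscGeometry, config: dict) -> list[FiberLayerSpec]:
    fib = config["fibers"]
    n_layers = int(fib["n_layers"])
    n_fam = int(fib["samples_per_family"])
    angles = _layer_angles(config)
    r_n = np.sqrt(disc.nucleus_area_fraction)  # radial fraction of the nucleus edge
    layers = []
    for i in range(n_layers):
        layer_index = i + 1
        crossed = layer_index < n_layers
        n_per_family = n_fam if crossed else max(2, n_fam // 2)
        frac = r_n + (i + 0.5) / n_layers * (1.0 - r_n)
        a = disc.annulus_outer_radius_ml * frac
        b = disc.annulus_outer_radius_ap * frac
        alpha = np.radians(angles[i])
        samples = []
        for fam in (+1.0, -1.0):
            # offset the two families so the union stays mirror-symmetric
            phis = 2.0 * np.pi * (np.arange(n_per_family) + (0.25 if fam > 0 else 0.75)) / n_per_family
            for phi in phis:
                pos = _ellipse_point(a, b, phi)
                tangent = _ellipse_tangent(a, b, phi)
                direction = fam * np.cos(alpha) * tangent + np.sin(alpha) * Z
                direction = direction / np.linalg.norm(direction)
                samples.append((pos, direction))
        layers.append(
            FiberLayerSpec(
                layer_index=layer_index,
                orientation_deg=float(angles[i]),
                sample_points=tuple(samples),
                crossed=crossed,
            )
        )
    return layers


def fiber_directions(
    disc: DiscGeometry,
    layer: FiberLayerSpec,
    n_samples: int,
    orientation_deg: float | None = None,
) -> list[np.ndarray]:
    """Unit fibre directions sampled on a layer's mid-surface.

    Crossed layers return both +/- families (``2 * n_samples`` directions);
    the single outer sheet returns ``n_samples`` split across families.
    Every direction makes the layer's stated angle with the local transverse
    plane.  ``orientation_deg`` overrides the layer's angle for limit-case
    analysis (0 degrees gives purely circumferential directions).
    """
    if n_samples < 4:
        raise ValueError("n_samples must be >= 4")
    if not 1 <= layer.layer_index <= 5:
        raise ValueError("layer index outside 1..5")
    alpha = np.radians(layer.orientation_deg if orientation_deg is None else orientation_deg)
    frac = 0.5 * (np.sqrt(disc.nucleus_area_fraction) + 1.0)
    a = disc.annulus_outer_radius_ml * frac
    b = disc.annulus_outer_radius_ap * frac
    families = (+1.0, -1.0)
    n_per = n_samples if layer.crossed else max(2, n_samples // 2)
    out = []
    for fam in families:
        for phi in 2.0 * np.pi * np.arange(n_per) / n_per:
            tangent = _ellipse_tangent(a, b, phi)
            d = fam * np.cos(alpha) * tangent + np.sin(alpha) * Z
            out.append(d / np.linalg.norm(d))
    return out


def reference_lines(frame: VertebraFrame) -> tuple[ReferenceLine, ReferenceLine]:
    """Frontal and sagittal superior-endplate reference lines of a frame.

    The frontal line joins the two mediolateral nodes (-x to +x); the
    sagittal line joins the anterior node to the posterior one.  In the
    neutral configuration the two are perpendicular by construction.
    """
    nodes = frame.endplate_nodes_sup
    frontal = ReferenceLine("frontal", nodes[1], nodes[0])
    sagittal = ReferenceLine("sagittal", nodes[2], nodes[3])
    if line_len(frontal) <= 1e-12 or line_len(sagittal) <= 1e-12:
        raise ValueError(f"frame {frame.label}: degenerate reference line")
    return frontal, sagittal


def line_len(line: ReferenceLine) -> float:
    return float(np.linalg.norm(line.end - line.start))


def _endplate_nodes(origin: np.ndarray, axes: np.ndarray, width: float, depth: float, dz: float) -> np.ndarray:
    x, y, z = axes[:, 0], axes[:, 1], axes[:, 2]
    c = origin + z * dz
    return np.stack(
        [
            c + x * (width / 2.0),
            c - x * (width / 2.0),
            c - y * (depth / 2.0),  # anterior
            c + y * (depth / 2.0),  # posterior
        ]
    )


def build_default_spine(config: dict | None = None) -> SpineGeometry:
    """Build the parametric five-segment column from a config mapping."""
    cfg = default_config()
    if config:
        # shallow two-level merge so partial overrides are convenient
        for key, value in config.items():
            if isinstance(value, Mapping) and isinstance(cfg.get(key), dict):
                cfg[key] = {**cfg[key], **value}
            else:
                cfg[key] = value
    _check_positive(cfg)

    bh, bw, bd = cfg["body_height"], cfg["body_width"], cfg["body_depth"]
    dh, lord = cfg["disc_height"], cfg["lordosis_deg"]
    levels = tuple(cfg["levels"])  # bottom-up, e.g. (L5, L4, L3, L2, L1)
    lowers = ("S",) + levels[:-1]
    joint_names = tuple(
        f"{up}-{'S1' if lo == 'S' else lo}" for up, lo in zip(levels, lowers)
    )

    frames: dict[str, VertebraFrame] = {}
    discs: dict[str, DiscGeometry] = {}
    axes = np.eye(3)
    origin = np.zeros(3)
    frames["S"] = VertebraFrame(
        "S",
        origin.copy(),
        axes.copy(),
        _endplate_nodes(origin, axes, bw["S"], bd["S"], bh["S"] / 2.0),
        _endplate_nodes(origin, axes, bw["S"], bd["S"], -bh["S"] / 2.0),
    )

    lower = "S"
    for joint, upper in zip(joint_names, levels):
        h = float(dh[joint])
        wedge = np.radians(float(lord[joint]))
        lower_axes = frames[lower].axes
        # extension-direction wedge (top tilts posteriorly): negative rotation
        # about the mediolateral axis in the flexion-positive convention
        R_half = lower_axes @ rotate_about(X, -wedge / 2.0) @ lower_axes.T
        mid_axes = R_half @ lower_axes
        upper_axes = R_half @ mid_axes
        top_lower = frames[lower].origin + lower_axes[:, 2] * (bh[lower] / 2.0)
        centroid = top_lower + mid_axes[:, 2] * (h / 2.0)
        bottom_upper = top_lower + mid_axes[:, 2] * h
        upper_origin = bottom_upper + upper_axes[:, 2] * (bh[upper] / 2.0)
        frames[upper] = VertebraFrame(
            upper,
            upper_origin,
            upper_axes,
            _endplate_nodes(upper_origin, upper_axes, bw[upper], bd[upper], bh[upper] / 2.0),
            _endplate_nodes(upper_origin, upper_axes, bw[upper], bd[upper], -bh[upper] / 2.0),
        )
        frac = float(cfg["disc"]["radius_fraction"])
        discs[joint] = DiscGeometry(
            level=joint,
            height=h,
            annulus_outer_radius_ml=bw[lower] / 2.0 * frac,
            annulus_outer_radius_ap=bd[lower] / 2.0 * frac,
            nucleus_area_fraction=float(cfg["disc"]["nucleus_area_fraction"]),
            centroid=centroid,
            axes=mid_axes,
        )
        lower = upper

    # z ordering sanity (strictly increasing from sacrum to the top vertebra)
    zs = [frames[v].origin[2] for v in ("S",) + levels]
    if np.any(np.diff(zs) <= 0):
        raise ValueError("vertebra origins must increase strictly in z from S upward")

    fiber_layers = {joint: _build_fiber_layers(discs[joint], cfg) for joint in joint_names}

    ligaments: list[LigamentAttachment] = []
    lig_cfg = cfg["ligaments"]
    pairs = list(zip(joint_names, levels, lowers))
    for joint, upper, lower_v in pairs:
        disc = discs[joint]
        A = disc.axes
        for name, p in lig_cfg.items():
            if name == "ILL" and not joint.endswith("S1"):
                continue
            depth_lo, depth_up = bd[lower_v], bd[upper]
            width_lo, width_up = bw[lower_v], bw[upper]
            sides = (+1.0, -1.0) if p["bilateral"] else (0.0,)
            for side in sides:
                def anchor_xy(depth: float, width: float) -> np.ndarray:
                    if p["anchor"] == "anterior":
                        return np.array([side * p["lateral"], -depth / 2.0 - p["ap_offset"], 0.0])
                    if p["anchor"] == "posterior":
                        return np.array([side * p["lateral"], depth / 2.0 + p["ap_offset"], 0.0])
                    # lateral anchor: x from the half-width, y absolute
                    return np.array([side * (width / 2.0 + p["lateral"]), p["ap_offset"], 0.0])

                dz = disc.height / 2.0 + p["z_span_extra"]
                lo_local = anchor_xy(depth_lo, width_lo) - Z * dz
                up_local = anchor_xy(depth_up, width_up) + Z * dz
                origin_w = disc.centroid + A @ lo_local
                insertion_w = disc.centroid + A @ up_local
                if name == "ILL":
                    # ground anchor on the iliac crest, lateral and caudal
                    origin_w = disc.centroid + A @ (
                        np.array([side * (width_lo / 2.0 + 2.0 * p["lateral"]), p["ap_offset"], 0.0])
                        - Z * (dz + 15.0)
                    )
                ligaments.append(
                    LigamentAttachment(
                        name=name,
                        level=joint,
                        origin=origin_w,
                        insertion=insertion_w,
                        rest_length=float(np.linalg.norm(insertion_w - origin_w)),
                        cross_section=float(p["cross_section"]),
                    )
                )

    facets: list[FacetPair] = []
    f = cfg["facets"]
    for joint, upper, lower_v in pairs:
        disc = discs[joint]
        A = disc.axes
        for side, sname in ((+1.0, "left"), (-1.0, "right")):
            p_local = np.array(
                [side * f["lateral_offset"], bd[lower_v] / 2.0 + f["posterior_offset"], 0.0]
            )
            # unilateral restraint tangential to the twist at the contact point
            tangent = np.array([-p_local[1], p_local[0], 0.0])
            tangent /= np.linalg.norm(tangent)
            normal = -tangent  # gap closes under positive axial rotation on this side
            facets.append(
                FacetPair(
                    level=joint,
                    side=sname,
                    contact_point=disc.centroid + A @ p_local,
                    normal=A @ normal,
                    gap=float(f["gap"]),
                    stiffness=float(f["stiffness"]),
                )
            )

    return SpineGeometry(
        frames=frames,
        discs=discs,
        fiber_layers=fiber_layers,
        ligaments=ligaments,
        facets=facets,
        config=cfg,
        joints=joint_names,
    )
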