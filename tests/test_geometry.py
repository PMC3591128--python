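"""Parametric geometry builder: counts, symmetry, fibre orientations."""

import numpy as np
import pytest

from lumbokin._rotations import rotate_about
from lumbokin.geometry import (
    build_default_spine,
    default_config,
    fiber_directions,
    reference_lines,
)
from lumbokin.kinematics import ReferenceLine

MIRROR = np.diag([-1.0, 1.0, 1.0])


def test_default_counts(geometry):
    assert len(geometry.discs) == 5
    assert set(geometry.frames) == {"S", "L1", "L2", "L3", "L4", "L5"}
    # eight ligament families at each applicable level (ILL only lumbosacral)
    for level in geometry.joints:
        names = {l.name for l in geometry.ligaments if l.level == level}
        expected = {"ALL", "PLL", "LF", "ITL", "CL", "ISL", "SSL"}
        if level == "L5-S1":
            expected |= {"ILL"}
        assert names == expected
    assert len(geometry.facets) == 10
    for level in geometry.joints:
        assert len(geometry.fiber_layers[level]) == 5


def test_rejects_nonpositive_dimensions():
    with pytest.raises(ValueError, match="disc_height"):
        build_default_spine({"disc_height": {"L3-L4": 0.0}})
    with pytest.raises(ValueError, match="body_height"):
        build_default_spine({"body_height": {"L2": -1.0}})


def test_facets_mirror_symmetric(geometry):
    """x -> -x maps the facet system onto itself (double-sided contacts)."""
    facets = {level: {} for level in geometry.joints}
    for f in geometry.facets:
        facets[f.level][f.side] = f
    for level, pair in facets.items():
        left, right = pair["left"], pair["right"]
        assert np.allclose(MIRROR @ left.contact_point, right.contact_point, atol=1e-9)
        # the double-sided restraint makes +/- normal equivalent
        mirrored = MIRROR @ left.normal
        assert min(
            np.linalg.norm(mirrored - right.normal), np.linalg.norm(mirrored + right.normal)
        ) < 1e-9
        assert left.gap == right.gap


def test_ligaments_mirror_symmetric(geometry):
    """The strand set is invariant under sagittal reflection."""
    strands = {
        (l.name, l.level, tuple(np.round(MIRROR @ l.origin, 6)), tuple(np.round(MIRROR @ l.insertion, 6)))
        for l in geometry.ligaments
    }
    originals = {
        (l.name, l.level, tuple(np.round(l.origin, 6)), tuple(np.round(l.insertion, 6)))
        for l in geometry.ligaments
    }
    assert strands == originals


def test_fiber_sample_set_mirror_symmetric(geometry):
    for level in geometry.joints:
        for layer in geometry.fiber_layers[level]:
            pts = {tuple(np.round(np.concatenate([p, d]), 6)) for p, d in layer.sample_points}
            mirrored = {
                tuple(np.round(np.concatenate([MIRROR @ p, MIRROR @ d]), 6))
                for p, d in layer.sample_points
            }
            assert pts == mirrored


def test_fiber_angles_and_monotone_profile(geometry):
    disc = geometry.discs["L3-L4"]
    layers = geometry.fiber_layers["L3-L4"]
    angles = [l.orientation_deg for l in layers]
    assert angles[0] == pytest.approx(35.0) and angles[-1] == pytest.approx(80.0)
    assert all(np.diff(angles) > 0)  # outermost steeper than innermost
    for layer in layers:
        dirs = fiber_directions(disc, layer, n_samples=8)
        for d in dirs:
            ang = np.degrees(np.arcsin(np.clip(d[2], -1, 1)))
            assert ang == pytest.approx(layer.orientation_deg, abs=1e-8 * 180 / np.pi)
        assert 35.0 - 1e-9 <= layer.orientation_deg <= 80.0 + 1e-9


def test_fiber_crossed_pairing(geometry):
    disc = geometry.discs["L3-L4"]
    crossed = geometry.fiber_layers["L3-L4"][0]
    dirs = fiber_directions(disc, crossed, n_samples=8)
    assert len(dirs) == 16  # both families, 8 per family
    outer = geometry.fiber_layers["L3-L4"][4]
    assert not outer.crossed
    assert len(fiber_directions(disc, outer, n_samples=8)) == 8


def test_fiber_zero_angle_limit(geometry):
    """A hypothetical 0-degree layer is purely circumferential."""
    disc = geometry.discs["L3-L4"]
    layer = geometry.fiber_layers["L3-L4"][0]
    for d in fiber_directions(disc, layer, 8, orientation_deg=0.0):
        assert abs(d[2]) < 1e-12


def test_reference_lines_perpendicular_and_rigid(geometry):
    frontal, sagittal = reference_lines(geometry.frames["L3"])
    fd = frontal.vector / np.linalg.norm(frontal.vector)
    sd = sagittal.vector / np.linalg.norm(sagittal.vector)
    assert abs(fd @ sd) < 1e-9
    # rigid translation leaves directions unchanged
    shift = np.array([3.0, -2.0, 7.0])
    moved = ReferenceLine(frontal.plane, frontal.start + shift, frontal.end + shift)
    assert np.allclose(moved.vector, frontal.vector)


def test_reference_line_rotates_with_frame(geometry):
    """10-degree rotation about x rotates the sagittal line direction by 10
    degrees (compared against the explicit rotation matrix)."""
    frame = geometry.frames["L3"]
    R = rotate_about([1.0, 0.0, 0.0], np.radians(10.0))
    _, sagittal = reference_lines(frame)
    origin = frame.origin
    rotated = ReferenceLine(
        "sagittal", R @ (sagittal.start - origin) + origin, R @ (sagittal.end - origin) + origin
    )
    d0 = sagittal.vector / np.linalg.norm(sagittal.vector)
    d1 = rotated.vector / np.linalg.norm(rotated.vector)
    assert np.degrees(np.arccos(np.clip(d0 @ d1, -1, 1))) == pytest.approx(10.0, abs=1e-9)


def test_column_height_bookkeeping(geometry):
    cfg = geometry.config
    expected = sum(cfg["body_height"][v] for v in geometry.levels) + sum(
        cfg["disc_height"][j] for j in geometry.joints
    )
    assert geometry.column_height == pytest.approx(expected)


def test_origins_increase_in_z(geometry):
    zs = [geometry.frames[v].origin[2] for v in ("S", "L5", "L4", "L3", "L2", "L1")]
    assert np.all(np.diff(zs) > 0)


def test_frames_orthonormal(geometry):
    for frame in geometry.frames.values():
        assert np.allclose(frame.axes.T @ frame.axes, np.eye(3), atol=1e-10)


def test_subset_levels():
    toy = build_default_spine({"levels": ["L5", "L4"]})
    assert toy.joints == ("L5-S1", "L4-L5")
    assert set(toy.frames) == {"S", "L5", "L4"}


def test_geometry_dump(tmp_path, geometry):
    path = tmp_path / "geometry.json"
    geometry.dump_json(path)
    assert path.exists() and path.stat().st_size > 1000


def test_default_config_roundtrip():
    cfg = default_config()
    assert cfg["disc"]["nucleus_area_fraction"] == pytest.approx(0.4)
    geo = build_default_spine(cfg)
    assert len(geo.discs) == 5
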