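"""Direction-cosine angle measurement: lengths, cosines, plane angles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lumbokin._rotations import matrix_to_rotvec, rotate_about
from lumbokin.kinematics import (
    AngleTable,
    DegenerateLineError,
    ReferenceLine,
    direction_cosines,
    line_length,
    measure_state,
    relative_angle,
)
from lumbokin.solver import LoadCase, solve_equilibrium


def line(start, end, plane="sagittal"):
    return ReferenceLine(plane, np.asarray(start, float), np.asarray(end, float))


@pytest.mark.parametrize(
    "start, end, expected",
    [((0, 0, 0), (0, 0, 10), 10.0), ((1, 2, 2), (0, 0, 0), 3.0), ((1, 1, 1), (1, 1, 1), 0.0)],
)
def test_line_length(start, end, expected):
    assert line_length(line(start, end)) == pytest.approx(expected)


def test_direction_cosines():
    dc = direction_cosines(line((0, 0, 0), (0, 0, 5)))
    assert (dc.l, dc.m, dc.n) == (0.0, 0.0, 1.0)
    dc = direction_cosines(line((0, 0, 0), (1, 1, 0)))
    assert dc.l == pytest.approx(0.70710678) and dc.m == pytest.approx(0.70710678)
    neg = direction_cosines(line((1, 1, 0), (0, 0, 0)))
    assert (neg.l, neg.m, neg.n) == pytest.approx((-dc.l, -dc.m, -dc.n))
    with pytest.raises(DegenerateLineError):
        direction_cosines(line((1, 1, 1), (1, 1, 1)))


@pytest.mark.parametrize("variant", ["literal", "projected"])
def test_relative_angle_pure_rotations(variant):
    """Rotating a sagittal line about x by a known angle is measured exactly
    in the flexion-extension plane (nodes built by the rotation matrix)."""
    sacrum = line((0, -25, 0), (0, 25, 0))
    for deg in (0.0, 30.0, 90.0, -20.0):
        R = rotate_about([1, 0, 0], np.radians(deg))
        vert = line(R @ sacrum.start, R @ sacrum.end)
        measured = relative_angle(vert, sacrum, "FE", variant)
        assert measured == pytest.approx(deg, abs=1e-9)


def test_relative_angle_lb_ar_signs():
    frontal_s = line((-25, 0, 0), (25, 0, 0), "frontal")
    for plane, axis in (("LB", [0, 1, 0]), ("AR", [0, 0, 1])):
        R = rotate_about(axis, np.radians(12.0))
        vert = line(R @ frontal_s.start, R @ frontal_s.end, "frontal")
        assert relative_angle(vert, frontal_s, plane) == pytest.approx(12.0, abs=1e-9)


def test_relative_angle_out_of_plane_variants():
    """With out-of-plane tilt the literal formula and the plane-projected
    variant disagree; both are evaluated from explicit trigonometry."""
    sacrum0 = line((0, -25, 0), (0, 25, 0))
    tilt = rotate_about([0, 0, 1], np.radians(5.0))       # out-of-plane tilt
    inplane = rotate_about([1, 0, 0], np.radians(20.0))   # in-plane rotation
    sacrum = line(tilt @ sacrum0.start, tilt @ sacrum0.end)
    vert = line(inplane @ tilt @ sacrum0.start, inplane @ tilt @ sacrum0.end)
    projected = relative_angle(vert, sacrum, "FE", "projected")
    literal = relative_angle(vert, sacrum, "FE", "literal")
    assert projected == pytest.approx(20.0, abs=1e-9)
    # literal: arccos of the unnormalized (m, n) pair product
    u = direction_cosines(sacrum).as_array()[[1, 2]]
    v = direction_cosines(vert).as_array()[[1, 2]]
    assert abs(literal) == pytest.approx(np.degrees(np.arccos(u @ v)), abs=1e-9)
    assert abs(projected - literal) > 0.01


@settings(max_examples=100, deadline=None)
@given(
    deg=st.floats(-60, 60),
    scale=st.floats(0.1, 10),
    tx=st.floats(-50, 50),
    tz=st.floats(-50, 50),
)
def test_relative_angle_invariances(deg, scale, tx, tz):
    """Symmetric in its arguments (sign flip), invariant to line scaling and
    to rigid in-plane translation."""
    sacrum = line((0, -25, 0), (0, 25, 0))
    R = rotate_about([1, 0, 0], np.radians(deg))
    vert = line(R @ sacrum.start, R @ sacrum.end)
    base = relative_angle(vert, sacrum, "FE")
    swapped = relative_angle(sacrum, vert, "FE")
    assert swapped == pytest.approx(-base, abs=1e-9)
    scaled = line(scale * vert.start, scale * vert.end)
    assert relative_angle(scaled, sacrum, "FE") == pytest.approx(base, abs=1e-9)
    shift = np.array([tx, 0.0, tz])
    moved = line(vert.start + shift, vert.end + shift)
    assert relative_angle(moved, sacrum, "FE") == pytest.approx(base, abs=1e-9)


def test_inner_product_guard():
    sacrum = line((0, -25, 0), (0, 25, 0))
    with pytest.raises(ValueError):
        relative_angle(sacrum, sacrum, "XY")


class _RigidState:
    """Minimal state stub: the same rigid map applied to every vertebra."""

    def __init__(self, R, d=np.zeros(3)):
        self._map = (R, np.asarray(d, float))

    def vertebra_maps(self):
        return {v: self._map for v in ("L1", "L2", "L3", "L4", "L5")}


def test_measure_state_neutral_and_rigid(geometry):
    neutral = _RigidState(np.eye(3))
    table = measure_state(neutral, geometry, movement="FLX")
    assert all(abs(v) < 1e-9 for v in table.cumulative.values())
    # rigid 10-degree flexion of the whole lumbar block
    R = rotate_about([1, 0, 0], np.radians(10.0))
    table = measure_state(_RigidState(R), geometry, movement="FLX")
    assert all(v == pytest.approx(10.0, abs=1e-6) for v in table.cumulative.values())


def test_measured_angles_match_rotation_log_oracle(geometry, healthy_card):
    """Converged in-plane states: the direction-cosine readout agrees with an
    independent axis-angle (rotation log) extraction within 0.05 degrees."""
    for movement, comp in (("FLX", 0), ("LB", 1), ("AR", 2)):
        state = solve_equilibrium(LoadCase(movement=movement, moment_nm=8.0), geometry, healthy_card)
        table = measure_state(state, geometry, movement=movement)
        maps = state.vertebra_maps()
        for v in ("L1", "L3", "L5"):
            R, _ = maps[v]
            oracle = np.degrees(matrix_to_rotvec(R)[comp])
            assert table.cumulative[v] == pytest.approx(oracle, abs=0.05)


def test_cumulative_equals_sum_of_segmentals(moment_states, geometry):
    for movement, state in moment_states.items():
        table = measure_state(state, geometry, movement=movement)
        order = ["L1", "L2", "L3", "L4", "L5"]
        running = 0.0
        for v in reversed(order):
            running += table.segmental[v]
            assert table.cumulative[v] == pytest.approx(running, abs=0.05)


def test_angle_table_validation():
    with pytest.raises(ValueError):
        AngleTable(movement="FLX", cumulative={"L1": 10.0}, sd={"L1": -1.0})
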