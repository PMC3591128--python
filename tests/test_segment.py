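"""Motion-segment mechanics: wrench signs, tension-only discipline, energy."""

import numpy as np
import pytest

from lumbokin.segment import (
    SegmentState,
    fiber_tensions,
    ligament_tensions,
    nucleus_volume_change,
    segment_wrench,
    tangent_stiffness,
)

POSTERIOR = ("ISL", "SSL", "LF", "PLL")


def test_neutral_state_zero_wrench(geometry, healthy_card):
    w = segment_wrench(SegmentState("L3-L4"), geometry, healthy_card)
    assert np.allclose(w.force, 0.0, atol=1e-8)
    assert np.allclose(w.moment, 0.0, atol=1e-8)
    for name, (f, m) in w.breakdown.items():
        assert np.allclose(f, 0.0, atol=1e-8), name
        assert np.allclose(m, 0.0, atol=1e-8), name


def test_breakdown_sums_to_total(geometry, healthy_card):
    state = SegmentState("L4-L5", translation=[0.1, -0.2, -0.5], rotation=[4.0, 1.0, 2.0])
    w = segment_wrench(state, geometry, healthy_card)
    f_sum = np.sum([b[0] for b in w.breakdown.values()], axis=0)
    m_sum = np.sum([b[1] for b in w.breakdown.values()], axis=0)
    assert np.allclose(f_sum, w.force, atol=1e-9)
    assert np.allclose(m_sum, w.moment, atol=1e-9)


def test_axial_compression_sign_pattern(geometry, healthy_card):
    """1 mm axial compression: nucleus and annulus push back cranially,
    vertical ligaments stay slack."""
    state = SegmentState("L3-L4", translation=[0.0, 0.0, -1.0])
    w = segment_wrench(state, geometry, healthy_card)
    assert w.breakdown["nucleus"][0][2] > 0
    assert w.breakdown["annulus"][0][2] > 0
    assert w.force[2] > 0
    tensions = ligament_tensions(state, geometry, healthy_card)
    assert all(t < 1e-9 for t in tensions.values())


def test_flexion_extension_ligament_recruitment(geometry, healthy_card):
    """Flexion tensions the posterior ligaments and posterior fibres; the
    anterior longitudinal ligament engages in extension instead."""
    flex = SegmentState("L3-L4", rotation=[5.0, 0.0, 0.0])
    t_flex = ligament_tensions(flex, geometry, healthy_card)
    assert all(t_flex[name] > 0 for name in POSTERIOR)
    assert t_flex["ALL"] == 0.0

    ext = SegmentState("L3-L4", rotation=[-5.0, 0.0, 0.0])
    t_ext = ligament_tensions(ext, geometry, healthy_card)
    assert t_ext["ALL"] > 0
    assert t_ext["ISL"] == 0.0 and t_ext["SSL"] == 0.0

    for state, want_posterior in ((flex, True), (ext, False)):
        mid, _, _, tension = fiber_tensions(state, geometry, healthy_card)
        posterior = mid[:, 1] > 5.0
        anterior = mid[:, 1] < -5.0
        tensioned = tension > 1e-6
        if want_posterior:
            assert tension[posterior].max() > tension[anterior].max()
        else:
            assert tension[anterior].max() > tension[posterior].max()


def test_tension_only_discipline(geometry, healthy_card, rng):
    """No ligament or fibre ever reports a compressive (negative) force."""
    for _ in range(20):
        state = SegmentState(
            "L4-L5",
            translation=rng.uniform(-1, 1, 3),
            rotation=rng.uniform(-6, 6, 3),
        )
        assert all(t >= 0.0 for t in ligament_tensions(state, geometry, healthy_card).values())
        assert np.all(fiber_tensions(state, geometry, healthy_card)[3] >= 0.0)


def test_mirror_symmetry_of_wrench(geometry, healthy_card):
    """Reflecting the state about the sagittal plane reflects the wrench."""
    state = SegmentState("L3-L4", translation=[0.3, -0.1, -0.4], rotation=[2.0, 3.0, -1.5])
    mirrored = SegmentState(
        "L3-L4", translation=[-0.3, -0.1, -0.4], rotation=[2.0, -3.0, 1.5]
    )
    w = segment_wrench(state, geometry, healthy_card)
    wm = segment_wrench(mirrored, geometry, healthy_card)
    assert np.allclose(wm.force, [-w.force[0], w.force[1], w.force[2]], atol=1e-7)
    assert np.allclose(wm.moment, [w.moment[0], -w.moment[1], -w.moment[2]], atol=1e-9)


def test_helix_property_under_axial_rotation(geometry, healthy_card):
    """Pure twist tensions exactly the fibre family whose circumferential
    component follows the twist — the torsion-resisting helix."""
    state = SegmentState("L3-L4", rotation=[0.0, 0.0, 4.0])
    mid, dirs, _, tension = fiber_tensions(state, geometry, healthy_card)
    phi_hat = np.stack([-mid[:, 1], mid[:, 0], np.zeros(len(mid))], axis=1)
    phi_hat /= np.linalg.norm(phi_hat, axis=1, keepdims=True)
    follows = np.einsum("ij,ij->i", dirs, phi_hat) > 0
    assert tension[follows].min() > 0
    assert np.all(tension[~follows] < 1e-9)


def test_energy_consistency_closed_loop(geometry, healthy_card):
    """The wrench is the gradient of a stored energy: work around a small
    closed loop in state space vanishes."""
    base_t = np.array([0.1, -0.1, -0.3])
    base_r = np.array([2.0, 0.5, 1.0])
    corners = [
        (base_t, base_r),
        (base_t + [0.05, 0, 0], base_r),
        (base_t + [0.05, 0, 0], base_r + [0.1, 0, 0]),
        (base_t, base_r + [0.1, 0, 0]),
        (base_t, base_r),
    ]
    n_sub = 12
    work = 0.0
    for (t0, r0), (t1, r1) in zip(corners[:-1], corners[1:]):
        for i in range(n_sub):
            a, b = i / n_sub, (i + 1) / n_sub
            qa = SegmentState("L3-L4", t0 + a * (t1 - t0), r0 + a * (r1 - r0))
            qb = SegmentState("L3-L4", t0 + b * (t1 - t0), r0 + b * (r1 - r0))
            wa = segment_wrench(qa, geometry, healthy_card)
            wb = segment_wrench(qb, geometry, healthy_card)
            dt = qb.translation - qa.translation            # mm
            dr = np.radians(qb.rotation - qa.rotation)      # rad
            work += 0.5 * (wa.force + wb.force) @ dt / 1000.0
            work += 0.5 * (wa.moment + wb.moment) @ dr
    assert abs(work) < 1e-6  # J


def test_tangent_stiffness_positive_definite_and_accurate(geometry, healthy_card):
    state = SegmentState("L3-L4")
    K = tangent_stiffness(state, geometry, healthy_card)
    sub = K[np.ix_([2, 3, 4], [2, 3, 4])]  # compression + bending block
    assert np.all(np.linalg.eigvalsh(sub) > 0)

    # directional-derivative oracle (Richardson-extrapolated secants) away
    # from the tension-onset kinks
    smooth = SegmentState("L3-L4", translation=[0.0, 0.0, -0.4], rotation=[3.0, 0.0, 0.0])
    K = tangent_stiffness(smooth, geometry, healthy_card)
    v = np.array([0.1, -0.05, 0.2, 0.3, 0.1, -0.2])
    v /= np.linalg.norm(v)

    def wrench_grad_along(h):
        def w(q6):
            st = SegmentState("L3-L4", q6[:3], np.degrees(q6[3:]))
            wr = segment_wrench(st, geometry, healthy_card)
            return np.concatenate([wr.force, wr.moment * 1000.0])

        q0 = smooth.q
        return (w(q0 + h * v) - w(q0 - h * v)) / (2 * h)

    d1, d2 = wrench_grad_along(2e-4), wrench_grad_along(1e-4)
    oracle = (4 * d2 - d1) / 3.0  # Richardson
    # wrench = -grad U, stiffness = +d(grad U): compare signs accordingly
    assert np.linalg.norm(K @ v + oracle) / np.linalg.norm(oracle) < 1e-5

    with pytest.raises(ValueError):
        tangent_stiffness(state, geometry, healthy_card, h=-1.0)


def test_degenerated_axial_stiffness_lower(geometry, healthy_card, degenerated_card):
    """The compressible degenerated nucleus softens the axial response."""
    state = SegmentState("L5-S1")
    k_h = tangent_stiffness(state, geometry, healthy_card)[2, 2]
    k_d = tangent_stiffness(state, geometry, degenerated_card)[2, 2]
    assert k_d < k_h


def test_nucleus_volume_change(geometry, healthy_card, comparison_card):
    assert nucleus_volume_change(SegmentState("L3-L4"), geometry, healthy_card) == 0.0
    squeezed = SegmentState("L3-L4", translation=[0.0, 0.0, -0.5])
    assert nucleus_volume_change(squeezed, geometry, comparison_card) < 0.0
    # the incompressible (penalty) card changes volume far less than the
    # compressible comparison card at the same state
    ratio_pen = abs(nucleus_volume_change(squeezed, geometry, healthy_card))
    ratio_cmp = abs(nucleus_volume_change(squeezed, geometry, comparison_card))
    assert ratio_pen < 0.05 * ratio_cmp


def test_unknown_level_rejected(geometry, healthy_card):
    with pytest.raises(KeyError):
        segment_wrench(SegmentState("T12-L1"), geometry, healthy_card)


def test_rotation_range_guard():
    with pytest.raises(ValueError):
        SegmentState("L3-L4", rotation=[95.0, 0.0, 0.0])
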