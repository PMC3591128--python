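"""Synthetic radiological cohort: recovery, monotonicity, agreement."""

import numpy as np
import pandas as pd
import pytest

from lumbokin.kinematics import AngleTable
from lumbokin.radiology import (
    CohortSpec,
    agreement_report,
    cohort_stats,
    generate_cohort,
    landmark_angles,
    landmarks_to_frame,
    load_reference_table,
    subject_landmarks,
)

VERTEBRAE = ("L1", "L2", "L3", "L4", "L5")


def reference_values(movement):
    table = load_reference_table()
    sub = table[table["movement"] == movement].set_index("vertebra")
    return sub["mean_deg"].to_dict(), sub["sd_deg"].to_dict()


def test_reference_table_bookkeeping():
    table = load_reference_table()
    l1 = table[table["vertebra"] == "L1"].set_index("movement")["mean_deg"]
    assert l1["FLX"] + l1["EXT"] == pytest.approx(72.67)
    l5 = table[(table["vertebra"] == "L5") & (table["movement"] == "FLX")]["mean_deg"].iloc[0]
    assert l5 == pytest.approx(9.69)


def test_spec_validation():
    with pytest.raises(ValueError):
        CohortSpec(n_subjects=1)
    with pytest.raises(ValueError):
        CohortSpec(age_mean=40.0)  # outside the stated range
    with pytest.raises(ValueError):
        CohortSpec(landmark_noise_sd=-0.1)


def test_zero_sd_degenerate_distribution():
    """With all SDs zero every subject reproduces the reference means."""
    table = load_reference_table().copy()
    table["sd_deg"] = 0.0
    records = generate_cohort(CohortSpec(angle_table=table, seed=5))
    means, _ = reference_values("FLX")
    for record in records:
        for v in VERTEBRAE:
            assert record.angles["FLX"][v] == pytest.approx(means[v], abs=1e-12)


def test_seeded_determinism_and_demographics():
    spec = CohortSpec(seed=11)
    a, b = generate_cohort(spec), generate_cohort(spec)
    for ra, rb in zip(a, b):
        assert ra.angles == rb.angles and ra.age == rb.age and ra.weight == rb.weight
    for record in a:
        assert 23.0 <= record.age <= 33.0
        assert 72.1 <= record.weight <= 81.7


def test_monotone_correction():
    for record in generate_cohort(CohortSpec(seed=2)):
        for movement, per in record.angles.items():
            values = [per[v] for v in VERTEBRAE]
            assert np.all(np.diff(values) <= 1e-9), (movement, values)


def test_default_cohort_recovers_l1_flexion_mean():
    """n=25: the sample mean of L1 flexion falls within 3 SD/sqrt(25) of
    the reference mean."""
    records = generate_cohort(CohortSpec(seed=0))
    stats = cohort_stats(records, "FLX")
    means, sds = reference_values("FLX")
    assert abs(stats.cumulative["L1"] - means["L1"]) < 3.0 * sds["L1"] / np.sqrt(25)
    assert stats.n == 25


@pytest.fixture(scope="module")
def big_cohort():
    return generate_cohort(CohortSpec(n_subjects=10000, seed=42))


def test_large_n_parameter_recovery(big_cohort):
    """n=10,000: raw draws recover every reference mean and SD within
    standard-error bounds; the corrected lateral-bending SD stays within 5%
    of the reference."""
    n = 10000
    for movement in ("FLX", "EXT", "LB"):
        means, sds = reference_values(movement)
        raw = cohort_stats(big_cohort, movement, raw=True)
        for v in VERTEBRAE:
            se_mean = sds[v] / np.sqrt(n)
            assert abs(raw.cumulative[v] - means[v]) < 4.0 * se_mean, (movement, v)
            se_sd = sds[v] / np.sqrt(2 * (n - 1))
            assert abs(raw.sd[v] - sds[v]) < 4.0 * se_sd, (movement, v)
    corrected = cohort_stats(big_cohort, "LB")
    _, sds_lb = reference_values("LB")
    assert corrected.sd["L1"] == pytest.approx(sds_lb["L1"], rel=0.05)


def test_cohort_stats_closed_form():
    rec = generate_cohort(CohortSpec(seed=1, n_subjects=2))
    for r, val in zip(rec, (10.0, 20.0)):
        r.angles = {"FLX": {v: val for v in VERTEBRAE}}
    stats = cohort_stats(rec, "FLX")
    assert stats.cumulative["L1"] == pytest.approx(15.0)
    assert stats.sd["L1"] == pytest.approx(7.0711, abs=1e-4)
    with pytest.raises(ValueError):
        cohort_stats(rec[:1], "FLX")


def test_agreement_report_flags():
    means, sds = reference_values("FLX")
    cohort = AngleTable("FLX", cumulative=means, sd=sds, n=25)
    exact = AngleTable("FLX", cumulative=dict(means))
    report = agreement_report(exact, cohort)
    assert report["within_1sd"].all()
    assert np.allclose(report["deviation_deg"], 0.0)

    shifted = AngleTable(
        "FLX", cumulative={v: means[v] + 2.1 * sds[v] for v in means}
    )
    report = agreement_report(shifted, cohort)
    assert not report["within_1sd"].any()
    assert not report["within_2sd"].any()

    # the model flexion maximum vs the radiological band
    model = AngleTable("FLX", cumulative={**means, "L1": 34.40})
    row = agreement_report(model, cohort).set_index("vertebra").loc["L1"]
    assert row["within_1sd"]
    assert row["deviation_deg"] == pytest.approx(0.46, abs=1e-9)

    with pytest.raises(ValueError):
        agreement_report(AngleTable("LB", cumulative=means), cohort)


def test_landmark_path_equivalence():
    """Angles read from noise-free synthetic landmarks equal the generated
    angles through the direction-cosine code path."""
    records = generate_cohort(CohortSpec(seed=9, n_subjects=5))
    for movement in ("FLX", "EXT", "LB"):
        for record in records:
            lines, sacrum = subject_landmarks(record, movement, noise_sd=0.0)
            table = landmark_angles(lines, sacrum, movement)
            for v in VERTEBRAE:
                assert table.cumulative[v] == pytest.approx(
                    record.angles[movement][v], abs=1e-6
                )


def test_landmark_csv_dialect():
    records = generate_cohort(CohortSpec(seed=3, n_subjects=3))
    frame = landmarks_to_frame(records, "FLX", noise_sd=0.5, seed=3)
    assert list(frame.columns) == [
        "subject_id", "vertebra", "plane", "x1", "y1", "z1", "x2", "y2", "z2"
    ]
    assert len(frame) == 3 * 6  # five vertebrae + sacrum per subject
    # deterministic given the seed
    again = landmarks_to_frame(records, "FLX", noise_sd=0.5, seed=3)
    pd.testing.assert_frame_equal(frame, again)


def test_torsion_has_no_radiological_arm():
    records = generate_cohort(CohortSpec(seed=4))
    assert "AR" not in records[0].angles
    with pytest.raises(ValueError):
        subject_landmarks(records[0], "AR")
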