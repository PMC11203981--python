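"""Exposure assessment: timelines, percentages, aggregation and differences."""

import numpy as np
import pandas as pd
import pytest

from ergozone import (
    STRESSED_PARTS,
    ExposureSummary,
    Segment,
    Zone,
    assess_recording,
    average_recordings,
    average_summaries,
    cohort_average,
    compute_zone_timeline,
    default_task_profile,
    difference_table,
    dump_ruleset,
    exposure_summary,
    fixture_recording,
    generate_recording,
    load_ruleset,
    mean_differences,
    square_wave_fixture,
    worker_overall_summary,
    worst_zone_share,
)
from ergozone.assessment import ZONES, AssessmentError


def summary_from(table_dict, method="L"):
    table = pd.DataFrame.from_dict(table_dict, orient="index", columns=list(ZONES))
    return ExposureSummary(method=method, table=table)


def random_summaries(rng):
    """Random but valid (partition-of-100) summaries for L, S, C."""
    labels = [f"P{i}" for i in range(6)]
    out = {}
    for method in ("L", "S", "C"):
        raw = rng.dirichlet(np.ones(3), size=len(labels)) * 100.0
        out[method] = summary_from(
            {lab: raw[i] for i, lab in enumerate(labels)}, method
        )
    return out


class TestZoneTimeline:
    def test_neutral_posture_all_green(self, rulesets):
        rec = fixture_recording(
            [square_wave_fixture(0.0, 0.0, 0.5, 30.0, 60.0)], work_type="dynamic"
        )
        for rs in rulesets.values():
            tl = compute_zone_timeline(rec, rs)
            for part, zones in tl.zones.items():
                assert np.all(zones == Zone.GREEN), (rs.standard_id, part)

    def test_square_wave_neck_flexion_under_stn(self, rulesets):
        """0<->70 deg square at 2/min: unacceptable while raised (flexion
        40 deg at f >= 2/min), acceptable while neutral."""
        s = square_wave_fixture(0.0, 70.0, duty=0.5, period=30.0, duration=300.0)
        rec = fixture_recording([s], work_type="dynamic")
        tl = compute_zone_timeline(rec, rulesets["S"])
        zones = tl.zones["N1"]
        high = s.samples == 70.0
        assert np.all(zones[high] == Zone.RED)
        assert np.all(zones[~high] == Zone.GREEN)

    def test_unassessed_segments_not_in_timeline(self, rulesets):
        rec = fixture_recording([square_wave_fixture(0.0, 0.0, 0.5, 30.0, 30.0)])
        for rs in rulesets.values():
            tl = compute_zone_timeline(rec, rs)
            for part in ("RE1", "RE3/4", "LE1", "LE3/4"):
                assert part in tl.not_assessed
                assert part not in tl.zones

    def test_missing_channel_names_segment_and_standard(self, rulesets):
        rec = fixture_recording([square_wave_fixture(0.0, 0.0, 0.5, 30.0, 30.0)],
                                fill_segments=False)
        with pytest.raises(AssessmentError, match="standard S"):
            compute_zone_timeline(rec, rulesets["S"])

    def test_mirrored_directions_pool_worst_of(self, rulesets):
        """Lateral sway to both sides: the pooled part N3/4 is orange/red
        whenever either direction is."""
        rate, t = 20.0, np.arange(0, 120, 1 / 20.0)
        sway = np.where(np.mod(t, 40.0) < 10.0, 25.0,
                        np.where(np.mod(t, 40.0) < 20.0, -25.0, 0.0))
        from ergozone import JointAngleSeries
        s = JointAngleSeries(Segment.NECK, "lateral_flexion", rate, sway)
        rec = fixture_recording([s], work_type="dynamic")
        tl = compute_zone_timeline(rec, rulesets["C"])
        zones = tl.zones["N3/4"]
        assert np.all(zones[np.abs(sway) >= 20.0] == Zone.RED)
        assert np.all(zones[sway == 0.0] == Zone.GREEN)

    def test_static_work_uses_static_rules(self, rulesets):
        s = square_wave_fixture(30.0, 30.0, 1.0, 30.0, 60.0)  # constant 30 deg
        rec = fixture_recording([s], work_type="static")
        tl = compute_zone_timeline(rec, rulesets["L"])
        # legislative static rule: forward neck flexion without support
        # beyond 25 deg is unacceptable
        assert np.all(tl.zones["N1"] == Zone.RED)
        # with back support the same posture is conditionally acceptable
        rec.context.support[Segment.NECK] = True
        tl2 = compute_zone_timeline(rec, rulesets["L"])
        assert np.all(tl2.zones["N1"] == Zone.ORANGE)


class TestExposureSummary:
    def test_all_green_partition(self, rulesets):
        rec = fixture_recording([square_wave_fixture(0.0, 0.0, 0.5, 30.0, 60.0)])
        summ = exposure_summary(compute_zone_timeline(rec, rulesets["C"]))
        assert np.allclose(summ.table["green"], 100.0)
        assert np.allclose(summ.table.sum(axis=1), 100.0)

    def test_duty_cycle_ground_truth_recovery(self, rulesets):
        """50/50 and 82/18 split fixtures recover their analytic occupancy."""
        s = square_wave_fixture(0.0, 70.0, duty=0.5, period=30.0, duration=300.0)
        summ = exposure_summary(
            compute_zone_timeline(fixture_recording([s]), rulesets["S"])
        )
        assert summ.table.loc["N1"].tolist() == pytest.approx([50.0, 0.0, 50.0])

        s2 = square_wave_fixture(
            0.0, 35.0, duty=0.18, period=50.0, duration=300.0,
            segment=Segment.LOWER_BACK,
        )
        summ2 = exposure_summary(
            compute_zone_timeline(fixture_recording([s2]), rulesets["C"])
        )
        assert summ2.table.loc["LB1"].tolist() == pytest.approx([82.0, 18.0, 0.0])

    def test_partition_invariant_on_noisy_recording(self, rulesets):
        rec = generate_recording(default_task_profile(), duration=60.0)
        for rs in rulesets.values():
            summ = exposure_summary(compute_zone_timeline(rec, rs))
            assert np.allclose(summ.table.sum(axis=1), 100.0, atol=0.01)
            assert ((summ.table >= 0) & (summ.table <= 100)).all().all()

    def test_noise_far_from_thresholds_barely_moves_exposure(self, rulesets):
        """Levels >= 10 deg away from every threshold: 2 deg noise changes
        the zone shares by less than one percentage point."""
        from ergozone import JointAngleSeries
        s = square_wave_fixture(0.0, 70.0, duty=0.5, period=30.0, duration=300.0)
        clean = fixture_recording([s])
        rng = np.random.default_rng(9)
        noisy_series = JointAngleSeries(
            s.segment, s.channel, s.sampling_rate,
            s.samples + rng.normal(0.0, 2.0, len(s)),
        )
        noisy = fixture_recording([noisy_series])
        rs = load_ruleset("S")
        z_clean = exposure_summary(compute_zone_timeline(clean, rs)).table.loc["N1"]
        z_noisy = exposure_summary(compute_zone_timeline(noisy, rs)).table.loc["N1"]
        assert np.max(np.abs(z_clean - z_noisy)) < 1.0

    def test_tightening_red_threshold_never_decreases_red_share(self, rulesets):
        rec = generate_recording(default_task_profile(), duration=60.0)
        doc = rulesets["C"].to_dict()
        base_red = None
        for thr in (45.0, 35.0, 25.0, 15.0):
            for rule in doc["rules"]:
                if rule["axis"] == "LB1" and rule["zone"] == "red":
                    rule["angle"]["lo"] = thr
            rs = load_ruleset(doc)
            red = exposure_summary(compute_zone_timeline(rec, rs)).table.loc[
                "LB1", "red"
            ]
            if base_red is not None:
                assert red >= base_red - 1e-12
            base_red = red


class TestAggregation:
    def test_single_label_summary_is_identity(self):
        summ = summary_from({"N1": (60.0, 30.0, 10.0)})
        ws = worker_overall_summary({"L": summ}, "W1")
        assert ws.table.loc["L"].tolist() == pytest.approx([60.0, 30.0, 10.0])

    def test_two_label_mean(self):
        summ = summary_from({"A": (100.0, 0.0, 0.0), "B": (0.0, 0.0, 100.0)})
        ws = worker_overall_summary({"L": summ}, "W1")
        assert ws.table.loc["L"].tolist() == pytest.approx([50.0, 0.0, 50.0])

    def test_worst_zone_share_partitions_time(self, rulesets):
        rec = generate_recording(default_task_profile(), duration=60.0)
        share = worst_zone_share(compute_zone_timeline(rec, rulesets["C"]))
        assert share.sum() == pytest.approx(100.0)
        # worst-of aggregation is at least as red as the mean aggregation
        summ = exposure_summary(compute_zone_timeline(rec, rulesets["C"]))
        assert share["red"] >= summ.table["red"].mean() - 1e-9

    def test_trial_averaging_modes(self):
        profile = default_task_profile()
        recs = [generate_recording(profile, duration=30.0, trial=t) for t in (1, 2, 3)]
        rulesets = {"C": load_ruleset("C")}
        per_trial = [assess_recording(r, rulesets)["C"] for r in recs]
        mean_of_pct = average_summaries(per_trial)
        assert np.allclose(mean_of_pct.table.sum(axis=1), 100.0, atol=0.01)
        pct_of_mean = assess_recording(average_recordings(recs), rulesets)["C"]
        assert list(pct_of_mean.table.index) == list(mean_of_pct.table.index)

    def test_cohort_average_is_columnwise_mean(self):
        a = worker_overall_summary({"L": summary_from({"A": (80.0, 10.0, 10.0)})}, "W1")
        b = worker_overall_summary({"L": summary_from({"A": (60.0, 30.0, 10.0)})}, "W2")
        avg = cohort_average([a, b])
        assert avg.loc["L"].tolist() == pytest.approx([70.0, 20.0, 10.0])


class TestDifferences:
    def test_printed_example_differences(self):
        """Green-share example: Captiv 82% vs legislation 95% gives -13;
        STN 50% vs legislation 95% gives -45."""
        summaries = {
            "L": summary_from({"LB5/6": (95.0, 5.0, 0.0)}, "L"),
            "C": summary_from({"LB5/6": (82.0, 18.0, 0.0)}, "C"),
            "S": summary_from({"LB5/6": (50.0, 0.0, 50.0)}, "S"),
        }
        dt = difference_table(summaries, "W1")
        assert dt.table.loc[("LB5/6", "green"), "d1"] == pytest.approx(-13.0)
        assert dt.table.loc[("LB5/6", "green"), "d3"] == pytest.approx(-45.0)

    def test_identical_summaries_give_zero(self):
        s = summary_from({"A": (50.0, 30.0, 20.0)})
        summaries = {m: ExposureSummary(m, s.table.copy()) for m in ("L", "S", "C")}
        dt = difference_table(summaries)
        assert np.allclose(dt.table.to_numpy(), 0.0)

    def test_difference_identities_over_random_summaries(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            dt = difference_table(random_summaries(rng)).table
            np.testing.assert_allclose(dt["d1"], dt["d2"] + dt["d3"], atol=1e-9)
            per_pair = dt.groupby(level="part").sum()
            np.testing.assert_allclose(per_pair.to_numpy(), 0.0, atol=1e-9)

    def test_mean_differences_identity_and_linearity(self):
        rng = np.random.default_rng(7)
        tables = [difference_table(random_summaries(rng), f"W{i}") for i in range(2)]
        single = mean_differences(tables[:1])
        pd.testing.assert_frame_equal(single, tables[0].table)
        mean2 = mean_differences(tables)
        np.testing.assert_allclose(
            mean2.to_numpy(),
            (tables[0].table.to_numpy() + tables[1].table.to_numpy()) / 2.0,
        )

    def test_plus_minus_ten_averages_to_zero(self):
        base = random_summaries(np.random.default_rng(0))
        t1 = difference_table(base, "W1")
        t2 = difference_table(base, "W2")
        t2.table = -t1.table
        assert np.allclose(mean_differences([t1, t2]).to_numpy(), 0.0)

    def test_label_mismatch_rejected(self):
        summaries = {
            "L": summary_from({"A": (100.0, 0.0, 0.0)}, "L"),
            "S": summary_from({"B": (100.0, 0.0, 0.0)}, "S"),
            "C": summary_from({"B": (100.0, 0.0, 0.0)}, "C"),
        }
        with pytest.raises(ValueError, match="common"):
            difference_table(summaries)
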