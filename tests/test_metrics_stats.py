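import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nursetag as nt
from nursetag import intervals as iv
from nursetag.metrics_stats import round_seconds


class TestCircularMean:
    @pytest.mark.parametrize("angles_deg, expected_deg", [
        ([350.0, 10.0], 0.0),
        ([0.0, 90.0], 45.0),
        ([170.0, -170.0], 180.0),
        ([10.0, 20.0, 30.0], 20.0),
    ])
    def test_known_values(self, angles_deg, expected_deg):
        got = nt.circular_mean(np.deg2rad(angles_deg))
        diff = np.angle(np.exp(1j * (got - np.deg2rad(expected_deg))))
        assert abs(diff) < 1e-12

    def test_full_turn_invariance(self):
        a = np.deg2rad([33.0, 95.0, 201.0])
        assert nt.circular_mean(a) == pytest.approx(
            nt.circular_mean(a + 2 * np.pi), abs=1e-12)

    def test_vanishing_resultant_rejected(self):
        with pytest.raises(nt.ParameterError, match="undefined"):
            nt.circular_mean([0.0, np.pi])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(-3.0, 3.0), st.integers(2, 30), st.integers(0, 99))
    def test_reduces_to_arithmetic_mean_for_tight_clusters(self, center, n,
                                                           key):
        rng = np.random.default_rng(key)
        angles = center + rng.uniform(-5e-4, 5e-4, n)
        assert nt.circular_mean(angles) == pytest.approx(
            np.angle(np.exp(1j * angles.mean())), abs=1e-6)


class TestSegmentMetrics:
    def test_constant_channels(self):
        n = 600
        rec = nt.TagRecord("c-01", "calf", 10.0,
                           acc=np.tile([0.0, 0.0, -9.81], (n, 1)),
                           depth=np.full(n, 12.0),
                           speed=np.full(n, 1.5))
        proc = nt.process_record(rec)
        seg = nt.AnalysisSegment("c-01", "calf", 10.0, 40.0, "horizontal",
                                 False, "sampled")
        m = nt.segment_metrics(seg, proc)
        assert m.min_depth == m.max_depth == m.mean_depth == 12.0
        assert m.mean_speed == pytest.approx(1.5)
        assert m.fsr == 0.0
        assert m.mean_odba == pytest.approx(0.0, abs=1e-9)
        assert m.circ_mean_pitch == pytest.approx(0.0, abs=1e-9)

    def test_fsr_tracks_gait_frequency(self, sim_deployment, processed):
        seg = nt.AnalysisSegment("sim-01", "calf", 250.0, 280.0,
                                 "horizontal", False, "sampled")
        m = nt.segment_metrics(seg, processed)
        assert m.fsr == pytest.approx(0.25, abs=1 / 30.0)

    def test_too_short_segment_rejected(self, processed):
        seg = nt.AnalysisSegment("sim-01", "calf", 10.0, 10.05,
                                 "surface", False, "sampled")
        with pytest.raises(nt.ValidationError):
            nt.segment_metrics(seg, processed)

    def test_fixture_mean_nursing_duration(self):
        t2 = nt.load_nursing_event_metrics()
        durs = t2.loc[t2["role"] == "calf", "duration_s"]
        assert round_seconds(durs.mean()) == 23
        assert durs.std(ddof=1) == pytest.approx(7.0, abs=0.5)


class _NullDesign:
    """Calf-study-shaped design: 4 individuals, 116 segments, 2x3 cells."""

    PLAN = {"A": [("descending", 1), ("horizontal", 2)],
            "B": [("descending", 2), ("horizontal", 1)],
            "C": [("descending", 1), ("horizontal", 3)],
            "D": [("ascending", 1)]}

    @classmethod
    def frame(cls):
        rows = []
        for dep, phases in cls.PLAN.items():
            for ph, k in phases:
                rows += [(dep, ph, True)] * k + [(dep, ph, False)] * 15
        return pd.DataFrame(rows, columns=["deployment_id", "phase",
                                           "is_nursing"])

    @classmethod
    def simulate(cls, rng, effect=0.0, sd_ind=0.03, sd_res=0.06):
        df = cls.frame()
        ind = dict(zip(cls.PLAN, rng.normal(0.0, sd_ind, len(cls.PLAN))))
        df["mean_odba"] = (0.18 + effect * df["is_nursing"]
                           + df["deployment_id"].map(ind)
                           + rng.normal(0.0, sd_res, len(df)))
        return df


class TestNursingModel:
    def test_df_convention_reproduces_107(self):
        rng = np.random.default_rng(1)
        r = nt.fit_nursing_model(_NullDesign.simulate(rng, effect=0.09),
                                 "mean_odba")
        assert r.n_segments == 116
        assert (r.df_num, r.df_den) == (1, 107)

    def test_constant_response_gives_zero_effect(self):
        df = _NullDesign.frame()
        df["mean_odba"] = 0.2
        r = nt.fit_nursing_model(df, "mean_odba")
        assert abs(r.nursing_effect) < 1e-8

    def test_single_nursing_level_rejected(self):
        df = _NullDesign.frame()
        df["is_nursing"] = False
        df["mean_odba"] = 0.2
        with pytest.raises(nt.ValidationError):
            nt.fit_nursing_model(df, "mean_odba")

    def test_single_individual_rejected(self):
        df = _NullDesign.frame()
        df = df[df["deployment_id"] == "A"].copy()
        df["mean_odba"] = 0.2
        with pytest.raises(nt.ValidationError):
            nt.fit_nursing_model(df, "mean_odba")

    def test_power_at_observed_effect_size(self):
        """A +0.09 m/s^2 nursing shift (the observed calf ODBA contrast)
        is detected at alpha = 0.05 in >= 90 of 100 replicates."""
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(100):
            r = nt.fit_nursing_model(_NullDesign.simulate(rng, effect=0.09),
                                     "mean_odba")
            hits += (r.nursing_effect > 0) and (r.p_value < 0.05)
        assert hits >= 90


class TestBudgets:
    def test_reference_deployment_totals(self):
        log = nt.load_fixture_event_log()
        b = nt.nursing_budget(log, "mn170612-30", 6.7 * 3600)
        assert b.n_events == 3
        assert b.total_nursing_s == 64.0
        assert round_seconds(b.mean_duration_s) == 21
        b2 = nt.nursing_budget(log, "mn180831-30", 2.8 * 3600)
        assert round(b2.percent_of_good_video, 2) == 0.13

    def test_empty_log(self):
        b = nt.nursing_budget(nt.make_event_log([]), "x", 3600.0)
        assert (b.n_events, b.total_nursing_s, b.percent_of_good_video) == \
            (0, 0.0, 0.0)

    def test_nonpositive_video_rejected(self):
        with pytest.raises(nt.ValidationError):
            nt.nursing_budget(nt.make_event_log([]), "x", 0.0)

    def test_proximity_equal_to_nursing_gives_zero(self):
        log = nt.make_event_log([("d", "nursing", 10, 40),
                                 ("d", "proximity", 10, 40)])
        b = nt.proximity_budget(log, "d", 3600.0)
        assert b.proximity_nonnursing_s == 0.0

    def test_proximity_minus_nursing_percent(self):
        log = nt.make_event_log([("d", "proximity", 1000, 1600),
                                 ("d", "nursing", 1200, 1260)])
        b = nt.proximity_budget(log, "d", 3600.0)
        assert b.percent_nonnursing_proximity == pytest.approx(15.0)

    def test_budget_conservation_identity(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            rows = []
            t = 0.0
            for etype in ("proximity", "nursing"):
                t = 0.0
                for _ in range(rng.integers(0, 8)):
                    t += rng.uniform(1, 200)
                    d = rng.uniform(1, 120)
                    rows.append(("d", etype, t, t + d))
                    t += d
            log = nt.make_event_log(rows)
            b = nt.proximity_budget(log, "d", 10_000.0)
            assert b.nursing_s + b.proximity_nonnursing_s + b.remainder_s \
                == pytest.approx(10_000.0, abs=1e-9)

    def test_random_interval_sets_match_discretized_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            rows, grid = [], np.zeros((2, 60_000), dtype=bool)
            for j, etype in enumerate(("proximity", "nursing")):
                t = 0.0
                for _ in range(rng.integers(1, 8)):
                    t += rng.uniform(1, 300)
                    d = rng.uniform(1, 150)
                    if t + d >= 6000:
                        break
                    rows.append(("d", etype, round(t, 1), round(t + d, 1)))
                    i0, i1 = int(round(t * 10)), int(round((t + d) * 10))
                    grid[j, i0:i1] = True
                    t += d
            log = nt.make_event_log(rows)
            b = nt.proximity_budget(log, "d", 6000.0)
            oracle = np.sum(grid[0] & ~grid[1]) / 10.0
            assert b.proximity_nonnursing_s == pytest.approx(oracle, abs=0.1)


class TestForagingGaps:
    def test_simple_gap(self):
        log = nt.make_event_log([("d", "nursing", 100, 120),
                                 ("d", "lunge", 300, 305)])
        g = nt.nursing_foraging_gaps(log)
        assert g["gap_s"].iloc[0] == 180.0

    def test_overlap_gives_zero(self):
        log = nt.make_event_log([("d", "nursing", 100, 120),
                                 ("d", "bottom_feeding", 110, 130)])
        assert nt.nursing_foraging_gaps(log)["gap_s"].iloc[0] == 0.0

    def test_no_foraging_is_undetermined(self):
        log = nt.make_event_log([("d", "nursing", 100, 120)])
        assert np.isnan(nt.nursing_foraging_gaps(log)["gap_s"].iloc[0])

    def test_matches_all_pairs_bruteforce(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            rows, nurs, forg = [], [], []
            t = 0.0
            for _ in range(rng.integers(1, 6)):
                t += rng.uniform(30, 400)
                d = rng.uniform(5, 40)
                rows.append(("d", "nursing", t, t + d))
                nurs.append((t, t + d))
                t += d
            t = 7.0
            for _ in range(rng.integers(0, 6)):
                etype = ["lunge", "dragging", "bottom_feeding"][
                    rng.integers(3)]
                t += rng.uniform(30, 400)
                d = rng.uniform(2, 20)
                rows.append(("d", etype, t, t + d))
                forg.append((t, t + d))
                t += d
            g = nt.nursing_foraging_gaps(nt.make_event_log(rows))
            for (s, e), got in zip(sorted(nurs), g["gap_s"]):
                if not forg:
                    assert np.isnan(got)
                else:
                    expected = min(max(fs - e, s - fe, 0.0)
                                   for fs, fe in forg)
                    assert got == expected

    def test_fixture_minimum_gap_is_13s(self):
        log = nt.load_fixture_event_log()
        calf_deps = ["mn170612-30", "mn170613-40", "mn180620-40",
                     "mn180831-30"]
        gaps = pd.concat([nt.nursing_foraging_gaps(log, d)
                          for d in calf_deps])
        assert gaps["gap_s"].min() == 13.0
        assert gaps["gap_s"].max() <= 12 * 60


class TestReportTables:
    def test_empty_inputs_give_header_only_tables(self, tmp_path):
        paths = nt.report_tables(pd.DataFrame(), [], [], tmp_path)
        seg = pd.read_csv(paths["segments"], sep="\t")
        assert len(seg) == 0 and "mean_odba" in seg.columns

    def test_duration_rounding_half_to_even(self):
        assert round_seconds(64 / 3) == 21      # 21.33 -> 21
        assert round_seconds(23.5) == 24        # half to even
        assert round_seconds(22.5) == 22

    def test_budget_table_contents(self, tmp_path):
        log = nt.load_fixture_event_log()
        t1 = nt.load_deployment_summary()
        budgets = [nt.nursing_budget(log, r.individual_id,
                                     r.good_video_h * 3600)
                   for r in t1.itertuples()]
        paths = nt.report_tables(pd.DataFrame(), [], budgets, tmp_path,
                                 metadata={"seed": 0})
        out = pd.read_csv(paths["budget"], sep="\t")
        assert out["n_events"].sum() == 11
        assert out["total_nursing_s"].sum() == 254
        row = out[out["individual_id"] == "mn170613-40"].iloc[0]
        assert row["mean_duration_s"] == 27  # 82 s over 3 events


def test_interval_arithmetic_against_bruteforce():
    rng = np.random.default_rng(11)
    for _ in range(200):
        a = [(s, s + d) for s, d in
             zip(rng.uniform(0, 900, 5), rng.uniform(1, 80, 5))]
        b = [(s, s + d) for s, d in
             zip(rng.uniform(0, 900, 4), rng.uniform(1, 80, 4))]
        grid = np.arange(0, 1000, 0.01)
        in_a = np.zeros_like(grid, dtype=bool)
        in_b = np.zeros_like(grid, dtype=bool)
        for s, e in a:
            in_a |= (grid >= s) & (grid < e)
        for s, e in b:
            in_b |= (grid >= s) & (grid < e)
        assert iv.total_length(iv.subtract(a, b)) == pytest.approx(
            np.sum(in_a & ~in_b) * 0.01, abs=0.25)
        assert iv.total_length(iv.intersect(a, b)) == pytest.approx(
            np.sum(in_a & in_b) * 0.01, abs=0.25)
        assert iv.total_length(iv.merge(a)) == pytest.approx(
            np.sum(in_a) * 0.01, abs=0.25)
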