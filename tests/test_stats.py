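import numpy as np
import pandas as pd
import pytest

from ripplelock import stats as st


class TestZVsControls:
    def test_empirical_equal_to_mean_gives_zero(self, rng):
        controls = rng.standard_normal(100) + 5
        z = st.z_vs_controls(controls.mean(), controls)
        assert z.value == pytest.approx(0.0, abs=1e-12)

    def test_arithmetic_example(self):
        controls = np.array([2.0, 4.0])  # mean 3, sd
        z = st.z_vs_controls(5.0, np.array([2.0, 3.0, 4.0]))
        assert z.value == pytest.approx(2.0)
        assert z.significant

    def test_zero_spread_rejected(self):
        with pytest.raises(ValueError):
            st.z_vs_controls(1.0, np.full(100, 3.0))

    def test_null_rejection_rate_near_nominal(self, rng):
        n_rej = 0
        n_sim = 2000
        for _ in range(n_sim):
            controls = rng.standard_normal(100)
            z = st.z_vs_controls(rng.standard_normal(), controls)
            n_rej += z.significant
        # |z|>1.96 under the null with estimated moments: close to 5%
        assert 0.03 < n_rej / n_sim < 0.09


class TestClusterPermutation:
    def test_identical_stacks_give_no_clusters(self, rng):
        x = rng.standard_normal((10, 6, 8))
        res = st.cluster_permutation(x, x.copy(), n_permutations=128)
        assert res.significant() == []

    def test_injected_rectangle_recovered(self, rng):
        ev = rng.standard_normal((20, 12, 20))
        ct = rng.standard_normal((20, 12, 20))
        ev[:, 3:7, 5:12] += 2.5
        res = st.cluster_permutation(ev, ct, n_permutations=256, seed=1)
        sig = res.significant()
        assert len(sig) >= 1
        mask = np.zeros((12, 20), bool)
        for c in sig:
            mask |= c["cells"]
        target = np.zeros((12, 20), bool)
        target[3:7, 5:12] = True
        assert (mask & target).sum() / target.sum() >= 0.8

    def test_too_few_pairs_rejected(self, rng):
        x = rng.standard_normal((3, 4, 4))
        with pytest.raises(ValueError):
            st.cluster_permutation(x, x + 1)

    def test_pvalues_invariant_to_amplitude_scaling(self, rng):
        ev = rng.standard_normal((12, 6, 9))
        ct = rng.standard_normal((12, 6, 9))
        r1 = st.cluster_permutation(ev, ct, n_permutations=128, seed=3)
        r2 = st.cluster_permutation(10 * ev, 10 * ct, n_permutations=128,
                                    seed=3)
        p1 = [c["p_corrected"] for c in r1.clusters]
        p2 = [c["p_corrected"] for c in r2.clusters]
        assert p1 == p2


class TestOnsetHistogram:
    def _spindles(self, onsets):
        return pd.DataFrame({
            "id": range(len(onsets)), "channel": "NC", "kind": "spindle",
            "onset_s": onsets, "offset_s": np.asarray(onsets) + 1.0,
            "peak_s": np.asarray(onsets) + 0.5,
            "duration_s": 1.0, "peak_amp_uv": 10.0})

    def test_normalisation_formula(self):
        # 10 onsets total, 2 in one bin -> bin value 20.0
        onsets = [100.02, 100.03] + [500.0 + 10 * i for i in range(8)]
        out = st.spindle_onset_histogram(self._spindles(onsets),
                                         np.array([100.2]))
        # both onsets fall at -0.18/-0.17 relative to the lock
        idx = np.flatnonzero(out["hist"])
        assert len(idx) == 1
        assert out["hist"][idx[0]] == pytest.approx(20.0)

    def test_no_onsets_near_ripples_all_zero(self):
        out = st.spindle_onset_histogram(self._spindles([10.0, 20.0]),
                                         np.array([500.0]))
        assert np.all(out["hist"] == 0)

    def test_bin_sum_recovers_in_range_count(self, rng):
        onsets = rng.uniform(0, 1000, size=200)
        locks = rng.uniform(0, 1000, size=40)
        out = st.spindle_onset_histogram(self._spindles(onsets), locks)
        rel = (onsets[None, :] - locks[:, None]).ravel()
        in_range = ((rel >= -0.5) & (rel < 0.5)).sum()
        assert out["hist"].sum() * len(onsets) / 100 == pytest.approx(
            in_range, abs=1e-9)

    def test_zero_spindles_rejected(self):
        with pytest.raises(ValueError):
            st.spindle_onset_histogram(self._spindles([]), np.array([1.0]))

    def test_per_bin_z_flags_concentration(self, rng):
        locks = np.arange(50.0, 1000.0, 17.0)
        onsets = locks - 0.22 + rng.normal(0, 0.005, size=len(locks))
        ctl = [rng.uniform(0, 1000, size=len(locks)) for _ in range(50)]
        out = st.spindle_onset_histogram(self._spindles(onsets), locks, ctl)
        peak = np.argmax(out["hist"])
        assert out["bin_centers"][peak] == pytest.approx(-0.225, abs=0.026)
        assert out["z"][peak] > 1.96
        assert out["significant"][peak]


class TestTertiles:
    def _ripples(self, durations):
        d = np.asarray(durations, float)
        return pd.DataFrame({
            "id": range(len(d)), "channel": "HIPP", "kind": "ripple",
            "onset_s": np.arange(len(d)) * 10.0,
            "offset_s": np.arange(len(d)) * 10.0 + d,
            "peak_s": np.arange(len(d)) * 10.0 + d / 2,
            "duration_s": d, "peak_amp_uv": 30.0})

    def test_one_to_nine_splits_cleanly(self):
        short, long, (lo, hi) = st.tertile_split(self._ripples(range(1, 10)))
        assert sorted(short["duration_s"]) == [1, 2, 3]
        assert sorted(long["duration_s"]) == [7, 8, 9]

    def test_all_equal_durations_discard_everything(self):
        short, long, _ = st.tertile_split(self._ripples([0.05] * 9))
        assert len(short) == 0 and len(long) == 0

    def test_group_sizes_near_third(self, rng):
        n = 100
        short, long, _ = st.tertile_split(
            self._ripples(rng.uniform(0.04, 0.2, size=n)))
        assert abs(len(short) - n / 3) <= 1
        assert abs(len(long) - n / 3) <= 1

    def test_boundaries_match_quantile_oracle(self, rng):
        d = rng.uniform(0.04, 0.3, size=50)
        _, _, (lo, hi) = st.tertile_split(self._ripples(d))
        assert lo == pytest.approx(np.quantile(d, 1 / 3))
        assert hi == pytest.approx(np.quantile(d, 2 / 3))

    def test_fewer_than_three_rejected(self):
        with pytest.raises(ValueError):
            st.tertile_split(self._ripples([0.05, 0.06]))


class TestLongVsShort:
    def test_identical_groups_p_half(self, rng):
        g = rng.standard_normal(50)
        out = st.long_vs_short_power_test(g, g.copy())
        assert out["p"] == pytest.approx(0.5)

    def test_shifted_group_significant(self, rng):
        short = rng.standard_normal(100)
        long = rng.standard_normal(100) + 1.0
        assert st.long_vs_short_power_test(long, short)["p"] < 0.001

    def test_null_rejection_rate(self, rng):
        n_rej = 0
        for _ in range(400):
            a, b = rng.standard_normal(40), rng.standard_normal(40)
            n_rej += st.long_vs_short_power_test(a, b)["p"] < 0.05
        assert 0.02 < n_rej / 400 < 0.09

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            st.long_vs_short_power_test(np.full(5, 1.0), np.full(5, 0.0))


class TestDurationPowerCorrelation:
    def test_perfect_monotone_relation_clipped_not_infinite(self, rng):
        per_patient = []
        for _ in range(5):
            d = np.sort(rng.uniform(0.04, 0.3, size=30))
            per_patient.append((d, d ** 2))  # monotone -> r = 1
        out = st.duration_power_correlation(per_patient)
        assert out["mean_r"] == pytest.approx(1.0, abs=1e-6)
        assert np.isfinite(out["t"])

    def test_positive_effect_detected(self, rng):
        per_patient = []
        for _ in range(6):
            d = rng.uniform(0.04, 0.3, size=60)
            p = d + rng.normal(0, 0.1, size=60)
            per_patient.append((d, p))
        out = st.duration_power_correlation(per_patient)
        assert out["mean_r"] > 0.3
        assert out["p"] < 0.01

    def test_shuffled_null_rejection_rate(self, rng):
        n_rej = 0
        for _ in range(300):
            per_patient = [(rng.uniform(0, 1, 30), rng.uniform(0, 1, 30))
                           for _ in range(5)]
            n_rej += st.duration_power_correlation(per_patient)["p"] < 0.05
        assert 0.02 < n_rej / 300 < 0.1

    def test_constant_duration_patient_excluded(self, rng):
        good = [(rng.uniform(0, 1, 20), rng.uniform(0, 1, 20))
                for _ in range(3)]
        bad = [(np.full(20, 0.05), rng.uniform(0, 1, 20))]
        out = st.duration_power_correlation(good + bad)
        assert out["n_patients"] == 3
        assert out["n_excluded"] == 1


class TestContingency:
    def _events(self, onsets, durs, kind, ch):
        onsets = np.asarray(onsets, float)
        durs = np.asarray(durs, float)
        return pd.DataFrame({
            "id": range(len(onsets)), "channel": ch, "kind": kind,
            "onset_s": onsets, "offset_s": onsets + durs,
            "peak_s": onsets + durs / 2, "duration_s": durs,
            "peak_amp_uv": 10.0})

    def test_far_apart_events_give_zero(self):
        sp = self._events([10.0, 20.0], [1.0, 1.0], "spindle", "NC")
        rp = self._events([500.0], [0.1], "ripple", "HIPP")
        out = st.event_contingency(sp, rp)
        assert out == dict(pct_spindles_near_ripples=0.0,
                           pct_ripples_with_spindle=0.0)

    def test_every_ripple_overlapped(self):
        rp = self._events([10.0, 20.0, 30.0], [0.1] * 3, "ripple", "HIPP")
        sp = self._events([9.85, 19.85, 29.85], [1.0] * 3, "spindle", "NC")
        out = st.event_contingency(sp, rp)
        assert out["pct_ripples_with_spindle"] == 100.0
        assert out["pct_spindles_near_ripples"] == 100.0

    def test_matches_double_loop_oracle(self, rng):
        sp = self._events(rng.uniform(0, 500, 40), np.full(40, 1.2),
                          "spindle", "NC")
        rp = self._events(rng.uniform(0, 500, 15), np.full(15, 0.1),
                          "ripple", "HIPP")
        out = st.event_contingency(sp, rp, window_s=1.0)
        n_near = sum(
            any(abs(s.onset_s - r.peak_s) <= 1.0 for r in rp.itertuples())
            for s in sp.itertuples())
        n_olap = sum(
            any(s.onset_s < r.offset_s and r.onset_s < s.offset_s
                for s in sp.itertuples())
            for r in rp.itertuples())
        assert out["pct_spindles_near_ripples"] == pytest.approx(
            100 * n_near / 40)
        assert out["pct_ripples_with_spindle"] == pytest.approx(
            100 * n_olap / 15)
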