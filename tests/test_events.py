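import numpy as np
import pytest

from helix_unravel.events import (
    classify_group,
    column_stats,
    detect_salt_bridge,
    detect_steps,
    summarize_ensemble,
    window_average,
)
from helix_unravel.geometry import TimeSeries
from helix_unravel.reference import (
    LAST2NS_TABLES,
    PRINTED_STATS,
    SALT_BRIDGE_FORMED_A,
    SALT_BRIDGE_INITIAL_A,
    iter_label_rows,
)


def ts(values, stride_ps=10.0):
    values = np.asarray(values, dtype=float)
    return TimeSeries(stride_ps * np.arange(1, len(values) + 1), values)


class TestWindowAverage:
    def test_constant_series(self):
        assert window_average(ts([3.7] * 100), 0.5, 1.0) == pytest.approx(3.7)

    def test_half_open_window(self):
        """(from, to] keeps the endpoint and drops the start."""
        s = ts([1.0, 2.0, 3.0, 4.0])  # times 10..40 ps
        assert window_average(s, 0.02, 0.04) == pytest.approx(3.5)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            window_average(ts([1.0, 2.0]), 5.0, 6.0)


class TestClassifier:
    @pytest.mark.parametrize("rmsd, hbs, expected", [
        (5.25, 0.0, "C"),  # completely unfolded
        (1.24, 4.2, "A"),  # refolded
        (3.84, 0.9, "B"),  # low bond count but RMSD below 4 stays partial
        (4.72, 1.9, "B"),  # high RMSD but bonds clearly present stays partial
        (4.0, 0.5, "C"),   # boundary values fall to C
        (1.99, 2.0, "A"),
        (2.0, 2.0, "B"),
    ])
    def test_rule(self, rmsd, hbs, expected):
        assert classify_group(rmsd, hbs).label == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_group(-0.1, 3.0)
        with pytest.raises(ValueError):
            classify_group(2.0, 6.5)

    def test_total_function_single_label(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            lab = classify_group(rng.uniform(0, 8), rng.uniform(0, 6)).label
            assert lab in ("A", "B", "C")

    def test_reproduces_all_reported_labels(self):
        """Rule reproduces the 40 reported group labels exactly."""
        for variant, traj, prot, rmsd, hbs, group in iter_label_rows():
            assert classify_group(rmsd, hbs).label == group, (
                variant, traj, prot)


class TestColumnStats:
    def test_reported_wt_columns(self):
        """Recomputed means/SDs agree with the reported rows to their printed
        precision (half a unit in the last printed digit)."""
        rows = list(LAST2NS_TABLES["WT"].values())
        mean, sd = column_stats([r[0] for r in rows])
        ref_m, ref_s = PRINTED_STATS["WT"]["rmsd", "+"]
        assert mean == pytest.approx(ref_m, abs=0.01)
        assert sd == pytest.approx(ref_s, abs=0.01)
        mean, sd = column_stats([r[2] for r in rows])
        ref_m, ref_s = PRINTED_STATS["WT"]["hbs", "+"]
        assert mean == pytest.approx(ref_m, abs=0.1)
        assert sd == pytest.approx(ref_s, abs=0.1)

    def test_sample_sd_denominator(self):
        mean, sd = column_stats([1.0, 2.0, 3.0, 4.0])
        assert mean == pytest.approx(2.5)
        assert sd == pytest.approx(np.sqrt(5.0 / 3.0))

    def test_constant_vector_sd_zero(self):
        assert column_stats([2.2, 2.2, 2.2])[1] == 0.0

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            column_stats([1.0])


class TestSaltBridge:
    def test_reported_distances(self):
        formed, first = detect_salt_bridge(ts([SALT_BRIDGE_FORMED_A] * 5))
        assert formed.all() and first == pytest.approx(0.01)
        formed, first = detect_salt_bridge(ts([SALT_BRIDGE_INITIAL_A] * 5))
        assert not formed.any() and first is None

    def test_first_crossing_frame(self):
        d = np.full(20, 9.0)
        d[7:] = 3.5  # crosses below the cutoff at frame index 7
        formed, first = detect_salt_bridge(ts(d))
        assert first == pytest.approx((7 + 1) * 10.0 / 1000.0)

    def test_positive_cutoff_required(self):
        with pytest.raises(ValueError):
            detect_salt_bridge(ts([3.0]), cutoff=0.0)


def _synthetic_series(n=2000, t1=430, t2=460, t3=530, noise=0.0, seed=0):
    """Hand-scripted piecewise series mimicking a complete unfolding run
    (indices are frames at 10 ps)."""
    rng = np.random.default_rng(seed)
    hb = np.full(n, 6.0)
    hb[t1:] = 1.0
    rmsd = np.full(n, 1.0)
    rmsd[t1:] = 3.0
    rmsd[t3:] = 6.0
    enp = np.full(n, -100.0)
    enp[t2 - 10: t2 + 10] = -100.0 + np.concatenate(
        [np.linspace(0, -40, 10), np.linspace(-40, 0, 10)])
    epp = np.full(n, -80.0)
    epp[t3 - 10: t3 + 10] = -80.0 + np.concatenate(
        [np.linspace(0, -50, 10), np.linspace(-50, 0, 10)])
    if noise:
        hb = np.clip(np.round(hb + rng.normal(0, noise, n)), 0, 6)
        enp = enp + rng.normal(0, noise * 4, n)
        epp = epp + rng.normal(0, noise * 4, n)
    return ts(hb), ts(rmsd), ts(enp), ts(epp)


class TestStepDetector:
    def test_noise_free_recovery_within_one_stride(self):
        hb, rmsd, enp, epp = _synthetic_series()
        rep = detect_steps(hb, rmsd, enp, epp)
        assert rep.verdict == "complete_three_step"
        assert rep.t1_ns == pytest.approx(4.31, abs=0.06)
        assert rep.t2_ns == pytest.approx(4.60, abs=0.02)
        assert rep.t3_ns == pytest.approx(5.30, abs=0.02)
        assert rep.t1_ns <= rep.t2_ns <= rep.t3_ns

    def test_stable_series_yield_incomplete(self):
        n = 1000
        rep = detect_steps(ts(np.full(n, 6.0)), ts(np.full(n, 0.5)),
                           ts(np.full(n, -100.0)), ts(np.full(n, -80.0)))
        assert rep.verdict == "incomplete"
        assert rep.times == (None, None, None)

    def test_cluster_without_hb_loss_gives_no_step1(self):
        """An E_np-np excursion alone (no sustained αHB loss) must not
        produce a step-1 call."""
        hb, rmsd, enp, epp = _synthetic_series()
        n = len(hb.values)
        rep = detect_steps(ts(np.full(n, 5.0)), rmsd, enp, epp)
        assert rep.t1_ns is None
        assert rep.verdict == "incomplete"

    def test_hb_loss_without_energy_excursion_is_incomplete(self):
        hb, rmsd, _, _ = _synthetic_series()
        n = len(hb.values)
        rep = detect_steps(hb, rmsd, ts(np.full(n, -100.0)),
                           ts(np.full(n, -80.0)))
        assert rep.t1_ns is not None
        assert rep.t2_ns is None and rep.t3_ns is None
        assert rep.verdict == "incomplete"

    def test_mismatched_time_bases_rejected(self):
        hb, rmsd, enp, epp = _synthetic_series()
        short = ts(np.full(10, -80.0))
        with pytest.raises(ValueError):
            detect_steps(hb, rmsd, enp, short)

    def test_ordering_invariant_under_noise(self):
        for seed in range(5):
            hb, rmsd, enp, epp = _synthetic_series(noise=0.3, seed=seed)
            rep = detect_steps(hb, rmsd, enp, epp)
            if rep.verdict == "complete_three_step":
                assert rep.t1_ns <= rep.t2_ns <= rep.t3_ns


class TestSummarize:
    def test_reported_pairs_reproduce_group_columns(self):
        """Feeding the reported averages through the classifier recovers the
        reported group membership counts."""
        labels = [classify_group(r, h).label
                  for _, _, _, r, h, _ in iter_label_rows()]
        wt = labels[:20]
        assert (wt.count("A"), wt.count("B"), wt.count("C")) == (7, 8, 5)
        ma, ml = labels[20:30], labels[30:40]
        assert ma.count("A") == 7 and ml.count("A") == 7
        assert "C" not in ma + ml

    def test_single_stable_trajectory(self, helix_trajectory):
        import pandas as pd

        coords = np.repeat(helix_trajectory.coords[:1], 400, axis=0)
        from helix_unravel.trajectory import Trajectory

        traj = Trajectory(helix_trajectory.topology, coords, stride_ps=10.0)
        df = summarize_ensemble([traj])
        assert isinstance(df, pd.DataFrame)
        assert df.iloc[0]["group"] == "A"
        assert df.attrs["group_counts"] == {"A": 1, "B": 0, "C": 0}
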