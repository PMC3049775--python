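"""Unfolding-event detection, trajectory classification and summary tables.

Complete unfolding of the central helix proceeds through three ordered
steps: (1) loss of α-helical backbone hydrogen bonds, (2) a pronounced
minimum in the nonpolar-nonpolar interaction energy as the nonpolar
sidechains collapse into a hydrophobic cluster, and (3) a pronounced
excursion of the polar-polar interaction energy as polar sidechains (in
particular the K16-D23 salt bridge) lock in.  The detector below
operationalises "changes larger than the high-frequency fluctuations" with
a smoothed threshold/z-score rule; every threshold is configurable and
echoed in the report.

Trajectories are classified from their last-2-ns window averages:
group C (completely unfolded) if RMSD ≥ 4.0 Å and αHBs ≈ 0 (≤ 0.5),
else group A (helical/refolded) if RMSD < 2.0 Å and αHBs ≥ 2,
else group B (partially unfolded).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import TimeSeries

__all__ = [
    "StepConfig",
    "StepReport",
    "GroupLabel",
    "window_average",
    "classify_group",
    "column_stats",
    "detect_salt_bridge",
    "detect_steps",
    "summarize_ensemble",
    "SALT_BRIDGE_CUTOFF",
]

#: Nζ(K16)-Cγ(D23) distance below which the salt bridge is called formed (Å).
SALT_BRIDGE_CUTOFF = 4.5


# ----------------------------------------------------------------------
# window statistics


def window_average(series: TimeSeries, from_ns: float, to_ns: float) -> float:
    """Arithmetic mean of values with times in (from_ns, to_ns] (inclusive end)."""
    t = series.times_ns
    mask = (t > from_ns) & (t <= to_ns)
    if not mask.any():
        raise ValueError(f"no samples in window ({from_ns}, {to_ns}] ns")
    return float(np.mean(np.asarray(series.values, dtype=float)[mask]))


def column_stats(values) -> tuple[float, float]:
    """Mean and sample standard deviation (n−1 denominator)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two values for mean/SD")
    return float(arr.mean()), float(arr.std(ddof=1))


# ----------------------------------------------------------------------
# classification


@dataclass(frozen=True)
class GroupLabel:
    label: str  # "A" | "B" | "C"
    avg_rmsd: float  # Å, last-2-ns window average
    avg_hbs: float  # αHB count, last-2-ns window average


def classify_group(avg_rmsd: float, avg_hbs: float) -> GroupLabel:
    """Classify a trajectory from last-2-ns average RMSD and αHB count.

    Precedence is C, then A, then B; "αHBs ≈ 0" is taken as ≤ 0.5.
    """
    if not np.isfinite(avg_rmsd) or avg_rmsd < 0:
        raise ValueError(f"average RMSD must be >= 0, got {avg_rmsd}")
    if not np.isfinite(avg_hbs) or not 0 <= avg_hbs <= 6:
        raise ValueError(f"average αHB count must lie in [0, 6], got {avg_hbs}")
    if avg_rmsd >= 4.0 and avg_hbs <= 0.5:
        label = "C"
    elif avg_rmsd < 2.0 and avg_hbs >= 2.0:
        label = "A"
    else:
        label = "B"
    return GroupLabel(label, float(avg_rmsd), float(avg_hbs))


# ----------------------------------------------------------------------
# salt bridge


def detect_salt_bridge(
    distance: TimeSeries, cutoff: float = SALT_BRIDGE_CUTOFF
) -> tuple[np.ndarray, float | None]:
    """Boolean formed-series and first-formation time (ns, or None)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    formed = np.asarray(distance.values, dtype=float) < cutoff
    first = float(distance.times_ns[np.argmax(formed)]) if formed.any() else None
    return formed, first


# ----------------------------------------------------------------------
# three-step detector


@dataclass(frozen=True)
class StepConfig:
    """Detector thresholds (all times in ps unless noted).

    ``smooth_ps``: centred boxcar window applied to every series before
    thresholding.  ``hb_threshold``: step 1 fires when the smoothed αHB
    count first drops to this value or below and stays there for
    ``sustain_ps``.  ``z``: energy excursions qualify when the smoothed
    series undershoots its pre-step-1 baseline mean by ``z`` baseline
    standard deviations (mean and SD of the smoothed baseline segment).
    ``horizon2_ns``/``horizon3_ns``: search horizons for steps 2 and 3
    after the preceding step.
    """

    smooth_ps: float = 100.0
    hb_threshold: float = 3.0
    sustain_ps: float = 50.0
    z: float = 3.0
    horizon2_ns: float = 2.0
    horizon3_ns: float = 3.0
    min_baseline_frames: int = 5


@dataclass
class StepReport:
    """Detected three-step timetable and verdict for one trajectory."""

    t1_ns: float | None = None
    rmsd1: float | None = None
    hbs1: int | None = None
    t2_ns: float | None = None
    rmsd2: float | None = None
    e_npnp2: float | None = None
    t3_ns: float | None = None
    rmsd3: float | None = None
    e_pp3: float | None = None
    verdict: str = "incomplete"
    config: StepConfig = field(default_factory=StepConfig)

    @property
    def times(self) -> tuple:
        return (self.t1_ns, self.t2_ns, self.t3_ns)


def _smooth(values: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return values.astype(float)
    kernel = np.ones(w) / w
    pad = w // 2
    padded = np.pad(values.astype(float), pad, mode="edge")
    out = np.convolve(padded, kernel, mode="valid")
    return out[: len(values)]


def _common_times(*series: TimeSeries) -> np.ndarray:
    t0 = series[0].times_ps
    for s in series[1:]:
        if len(s.times_ps) != len(t0) or not np.allclose(s.times_ps, t0):
            raise ValueError("series do not share a common time base")
    return t0


def _qualifying_minimum(smoothed: np.ndarray, lo: int, hi: int,
                        threshold: float) -> int | None:
    """First interior local minimum below threshold in [lo, hi)."""
    for i in range(max(lo, 1), min(hi, len(smoothed) - 1)):
        if smoothed[i] >= threshold:
            continue
        if smoothed[i] <= smoothed[i - 1] and smoothed[i] <= smoothed[i + 1]:
            return i
    return None


def detect_steps(
    hb_series: TimeSeries,
    rmsd_series: TimeSeries,
    e_npnp_series: TimeSeries,
    e_pp_series: TimeSeries,
    config: StepConfig = StepConfig(),
) -> StepReport:
    """Run the three-step detector on per-frame analysis series.

    All four series must share one time base.  Returns a
    :class:`StepReport` whose verdict is ``complete_three_step`` exactly
    when all three steps are found in order.
    """
    times_ps = _common_times(hb_series, rmsd_series, e_npnp_series, e_pp_series)
    t_ns = times_ps / 1000.0
    dt = float(times_ps[1] - times_ps[0]) if len(times_ps) > 1 else config.smooth_ps
    w = max(1, int(round(config.smooth_ps / dt)))
    sustain = max(1, int(round(config.sustain_ps / dt)))

    hb = np.asarray(hb_series.values, dtype=float)
    rmsd = np.asarray(rmsd_series.values, dtype=float)
    enp = np.asarray(e_npnp_series.values, dtype=float)
    epp = np.asarray(e_pp_series.values, dtype=float)

    hb_s = _smooth(hb, w)
    enp_s = _smooth(enp, w)
    epp_s = _smooth(epp, w)

    report = StepReport(config=config)

    # --- step 1: sustained loss of αHBs
    below = hb_s <= config.hb_threshold
    i1 = None
    run = 0
    for i, b in enumerate(below):
        run = run + 1 if b else 0
        if run >= sustain:
            i1 = i - sustain + 1
            break
    if i1 is None:
        return report
    report.t1_ns = float(t_ns[i1])
    report.rmsd1 = float(rmsd[i1])
    report.hbs1 = int(round(hb[i1]))

    # --- baseline fluctuations from the pre-step-1 segment; statistics are
    # taken on the smoothed series, the same signal searched for minima.
    # Step-1 detection lags the underlying transition by up to one smoothing
    # window, so that window is trimmed from the baseline end when possible.
    if i1 < config.min_baseline_frames:
        return report
    end = i1 - w if i1 - w >= config.min_baseline_frames else i1
    base_np_mean, base_np_sd = enp_s[:end].mean(), enp_s[:end].std(ddof=1)
    base_pp_mean, base_pp_sd = epp_s[:end].mean(), epp_s[:end].std(ddof=1)

    # --- step 2: first qualifying E_np-np minimum after t1
    hi2 = int(np.searchsorted(t_ns, report.t1_ns + config.horizon2_ns,
                              side="right"))
    thr2 = base_np_mean - config.z * base_np_sd
    i2 = _qualifying_minimum(enp_s, i1 + 1, hi2, thr2)
    if i2 is None:
        return report
    report.t2_ns = float(t_ns[i2])
    report.rmsd2 = float(rmsd[i2])
    report.e_npnp2 = float(enp[i2])

    # --- step 3: first qualifying E_p-p excursion after t2
    hi3 = int(np.searchsorted(t_ns, report.t2_ns + config.horizon3_ns,
                              side="right"))
    thr3 = base_pp_mean - config.z * base_pp_sd
    i3 = _qualifying_minimum(epp_s, i2 + 1, hi3, thr3)
    if i3 is None:
        return report
    report.t3_ns = float(t_ns[i3])
    report.rmsd3 = float(rmsd[i3])
    report.e_pp3 = float(epp[i3])
    report.verdict = "complete_three_step"
    return report


# ----------------------------------------------------------------------
# ensemble summaries


def summarize_ensemble(
    trajectories,
    reference=None,
    window_ns: float = 2.0,
) -> pd.DataFrame:
    """Last-window averages, group labels and column stats for an ensemble.

    Accepts either ``Trajectory`` objects (analysed against ``reference``,
    or against the ideal helix of their own topology when ``reference`` is
    None) or pre-computed ``(rmsd_series, hbond_series)`` pairs.  Returns a
    DataFrame with one row per trajectory plus ``mean``/``SD`` footer rows;
    group counts are stored in ``df.attrs["group_counts"]``.
    """
    from .builder import build_ideal_helix
    from .geometry import rmsd_series as _rmsd
    from .hbonds import hbond_count_series as _hbc

    if not trajectories:
        raise ValueError("need at least one trajectory")
    rows = []
    for i, item in enumerate(trajectories, start=1):
        if isinstance(item, tuple):
            r_ts, h_ts = item
        else:
            ref = reference or build_ideal_helix(item.topology)
            r_ts, h_ts = _rmsd(item, ref), _hbc(item)
        end_ns = float(r_ts.times_ns[-1])
        avg_r = window_average(r_ts, end_ns - window_ns, end_ns)
        avg_h = window_average(h_ts, end_ns - window_ns, end_ns)
        grp = classify_group(avg_r, avg_h)
        rows.append((str(i), round(avg_r, 2), round(avg_h, 1), grp.label))

    df = pd.DataFrame(rows, columns=["trajectory", "avg_rmsd", "avg_hbs", "group"])
    counts = df["group"].value_counts().to_dict()
    if len(df) >= 2:
        mr, sr = column_stats(df["avg_rmsd"])
        mh, sh = column_stats(df["avg_hbs"])
        footer = pd.DataFrame(
            [("mean", round(mr, 2), round(mh, 1), ""),
             ("SD", round(sr, 2), round(sh, 1), "")],
            columns=df.columns,
        )
        df = pd.concat([df, footer], ignore_index=True)
    df.attrs["group_counts"] = {g: counts.get(g, 0) for g in "ABC"}
    return df
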