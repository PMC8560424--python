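"""Metrics over stimulus-aligned EPSC trains and sampled current sweeps.

Covers the standard short-term-plasticity readouts for high-frequency
trains at a depressing synapse: success classification against a per-cell
threshold, rolling success percentage, time to the first pair of
consecutive failures, paired-pulse ratio, single-exponential depression and
recovery fits, steady-state depression, readily-releasable-pool (RRP)
charge from the train current integral, spontaneous-event detection, and
cohort summary statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "EpscTrain",
    "SweepTrace",
    "RecoveryMeasurement",
    "classify_successes",
    "rolling_success",
    "time_to_first_failure",
    "paired_pulse_ratio",
    "fit_depression",
    "steady_state_depression",
    "rrp_from_integral",
    "fit_recovery_time_course",
    "fractional_recovery",
    "detect_spontaneous_events",
    "cohort_summary",
]


@dataclass
class EpscTrain:
    """One sweep of stimulus times and EPSC peak amplitudes.

    Amplitudes are magnitudes (>= 0); values at or below the per-cell
    success threshold are failure candidates.  ``train_role`` distinguishes
    depletion, recovery and sustained trains within a protocol.
    """

    stim_times: np.ndarray
    amplitudes: np.ndarray
    frequency: float
    cell_id: str = "cell0"
    condition: str = "control"
    run_index: int = 1
    train_role: str = "sustained"

    def __post_init__(self) -> None:
        t = np.asarray(self.stim_times, dtype=float)
        a = np.asarray(self.amplitudes, dtype=float)
        if t.shape != a.shape:
            raise ValueError("stim_times and amplitudes lengths differ")
        if len(t) >= 2:
            isi = np.diff(t)
            expected = 1.0 / self.frequency
            if np.any(np.abs(isi - expected) > 0.01 * expected):
                raise ValueError(
                    "stimulus spacing inconsistent with stated frequency")
        self.stim_times = t
        self.amplitudes = a


@dataclass
class SweepTrace:
    """Continuously sampled current with stimulus times and artifact windows."""

    sampling_rate: float
    samples: np.ndarray
    stim_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    artifact_window: float = 0.0
    t_start: float = 0.0  # time of the first sample

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.artifact_window < 0:
            raise ValueError("artifact_window must be >= 0")
        self.samples = np.asarray(self.samples, dtype=float)
        self.stim_times = np.asarray(self.stim_times, dtype=float)

    @property
    def times(self) -> np.ndarray:
        return self.t_start + np.arange(len(self.samples)) / self.sampling_rate


@dataclass
class RecoveryMeasurement:
    """Fractional recovery at increasing rest intervals after depletion."""

    intervals: np.ndarray
    fractional: np.ndarray
    tau: float | None = None

    def __post_init__(self) -> None:
        i = np.asarray(self.intervals, dtype=float)
        f = np.asarray(self.fractional, dtype=float)
        if i.shape != f.shape:
            raise ValueError("intervals and fractional lengths differ")
        if np.any(np.diff(i) <= 0):
            raise ValueError("intervals must be strictly ascending")
        if np.any(f < 0):
            raise ValueError("fractional recovery must be >= 0")
        self.intervals = i
        self.fractional = f


def classify_successes(train: EpscTrain, threshold_frac: float = 0.05,
                       baseline_amp: float | None = None) -> np.ndarray:
    """Success flags: amplitude at or above a fraction of the baseline EPSC.

    The threshold is set per cell, by default 5 % of the initial EPSC; an
    amplitude exactly at threshold counts as a success (>= convention).
    """
    if baseline_amp is None:
        baseline_amp = float(train.amplitudes[0])
    if baseline_amp <= 0:
        raise ValueError("baseline_amp must be > 0")
    if not 0 < threshold_frac < 1:
        raise ValueError("threshold_frac must be in (0, 1)")
    return train.amplitudes >= threshold_frac * baseline_amp


def rolling_success(successes, window: int = 25) -> np.ndarray:
    """Trailing rolling success percentage per stimulus.

    Emits one value per stimulus from index ``window - 1`` onward: the mean
    of the current and previous ``window - 1`` success flags, times 100.
    The causal (trailing) window timestamps each value at the last stimulus
    it covers.
    """
    s = np.asarray(successes, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if len(s) < window:
        raise ValueError(f"series of length {len(s)} shorter than window {window}")
    kernel = np.ones(window) / window
    return np.convolve(s, kernel, mode="valid") * 100.0


def time_to_first_failure(successes, stim_times) -> float | None:
    """Time of the first of the earliest two consecutive failed stimuli.

    A transmission failure event requires two subsequent stimuli with no
    postsynaptic response; isolated single failures do not qualify.
    Returns ``None`` when no such pair occurs.
    """
    s = np.asarray(successes, dtype=bool)
    t = np.asarray(stim_times, dtype=float)
    if s.shape != t.shape:
        raise ValueError("successes and stim_times lengths differ")
    pair = (~s[:-1]) & (~s[1:])
    idx = np.flatnonzero(pair)
    if len(idx) == 0:
        return None
    return float(t[idx[0]])


def paired_pulse_ratio(train: EpscTrain) -> float:
    """Second over first EPSC peak amplitude."""
    if len(train.amplitudes) < 2:
        raise ValueError("need at least two stimuli for a paired-pulse ratio")
    if train.amplitudes[0] <= 0:
        raise ValueError("paired-pulse ratio undefined for zero first EPSC")
    return float(train.amplitudes[1] / train.amplitudes[0])


_FIT_WINDOWS = {100.0: (3, 20), 300.0: (3, 46)}  # 1-based pulse ranges


def fit_depression(train: EpscTrain,
                   window: tuple[int, int] | None = None) -> dict:
    """Single-exponential depression fit over the standard pulse window.

    Amplitudes are normalized to the first pulse and fit with
    ``a(t) = ss + (1 - ss) exp(-t / tau)`` over 1-based pulses 3–20 at
    100 Hz or 3–46 at 300 Hz (time measured from train onset).  Returns
    ``tau`` (s), the steady-state fraction ``ss``, the window used, and a
    ``flag`` that is set for degenerate input (no decay) or a fit that did
    not converge.
    """
    if window is None:
        if train.frequency not in _FIT_WINDOWS:
            raise ValueError(
                f"no default fit window for {train.frequency} Hz; supply one")
        lo, hi = _FIT_WINDOWS[train.frequency]
        # default window clamps to the train (a 150-ms 300 Hz burst holds
        # 45 stimuli); an explicitly supplied window must fit as given
        window = (lo, min(hi, len(train.amplitudes)))
    lo, hi = window
    if hi > len(train.amplitudes):
        raise ValueError(
            f"fit window {window} exceeds train length {len(train.amplitudes)}")
    if train.amplitudes[0] <= 0:
        raise ValueError("cannot normalize to a zero first amplitude")
    norm = train.amplitudes / train.amplitudes[0]
    t = train.stim_times[lo - 1:hi] - train.stim_times[0]
    y = norm[lo - 1:hi]
    result = {"fit_window": (lo, hi), "flag": None}
    if np.ptp(y) < 1e-12:
        result.update(tau=np.nan, steady_state_frac=float(y.mean()),
                      flag="degenerate_constant")
        return result

    def model(tt, ss, tau):
        return ss + (1.0 - ss) * np.exp(-tt / tau)

    try:
        popt, _ = curve_fit(model, t, y, p0=[max(y.min(), 1e-3), 0.02],
                            bounds=([0.0, 1e-5], [2.0, 10.0]), maxfev=10000)
        result.update(steady_state_frac=float(popt[0]), tau=float(popt[1]))
    except RuntimeError:
        result.update(tau=np.nan, steady_state_frac=np.nan,
                      flag="no_convergence")
    return result


def steady_state_depression(train: EpscTrain, tau: float) -> float:
    """Mean normalized amplitude over stimuli later than 3 tau from onset."""
    if tau <= 0:
        raise ValueError("tau must be > 0")
    t = train.stim_times - train.stim_times[0]
    mask = t > 3.0 * tau
    if not np.any(mask):
        raise ValueError("train does not extend beyond 3 tau")
    return float(np.mean(train.amplitudes[mask] / train.amplitudes[0]))


def rrp_from_integral(sweep: SweepTrace, train_window: tuple[float, float],
                      baseline_window: float = 0.05) -> float:
    """RRP proxy: current integral over the train, artifacts blanked.

    The baseline is the median current over the ``baseline_window`` seconds
    immediately preceding the train.  Stimulation-artifact windows around
    each stimulus are blanked and bridged by linear interpolation, so the
    integral captures synchronous and asynchronous release but not the
    stimulus transients.  Returns charge in current units x seconds.
    """
    t0, t1 = train_window
    times = sweep.times
    if t0 < times[0] - 1e-12 or t1 > times[-1] + 1e-12 or t1 <= t0:
        raise ValueError("train_window outside the sampled sweep")
    y = sweep.samples.astype(float).copy()
    # blank artifact windows, bridge by linear interpolation
    if sweep.artifact_window > 0 and len(sweep.stim_times):
        blank = np.zeros(len(y), dtype=bool)
        for st in sweep.stim_times:
            blank |= (times >= st) & (times < st + sweep.artifact_window)
        if blank.any() and not blank.all():
            y[blank] = np.interp(times[blank], times[~blank], y[~blank])
    pre = (times >= t0 - baseline_window) & (times < t0)
    baseline = float(np.median(y[pre])) if pre.any() else 0.0
    sel = (times >= t0) & (times <= t1)
    return float(np.trapezoid(y[sel] - baseline, times[sel]))


def fit_recovery_time_course(rec: RecoveryMeasurement,
                             exclude_before: float = 0.0) -> dict:
    """Single-exponential recovery fit ``f(dt) = 1 - (1 - f0) exp(-dt/tau)``.

    Intervals shorter than ``exclude_before`` are dropped before fitting
    (RRP recovery facilitates transiently at short intervals, so points
    before 0.4 s are conventionally excluded for RRP; 0 for single EPSCs).
    Cells whose time course cannot be fit are flagged, not dropped.
    """
    mask = rec.intervals >= exclude_before
    x = rec.intervals[mask]
    y = rec.fractional[mask]
    if len(x) < 3:
        raise ValueError("need at least 3 points after exclusion to fit")
    result = {"n_points": int(len(x)), "flag": None}
    if np.ptp(y) < 1e-12 or np.all(y > 0.99):
        result.update(tau=np.nan, f0=float(y.mean()), flag="degenerate_full_recovery")
        return result

    def model(dt, f0, tau):
        return 1.0 - (1.0 - f0) * np.exp(-dt / tau)

    try:
        popt, _ = curve_fit(model, x, y, p0=[max(min(y[0], 0.99), 0.0), 1.0],
                            bounds=([0.0, 1e-4], [1.0, 1e3]), maxfev=10000)
        result.update(f0=float(popt[0]), tau=float(popt[1]))
    except RuntimeError:
        result.update(tau=np.nan, f0=np.nan, flag="no_convergence")
    return result


def fractional_recovery(pre_amp: float, post_amp: float) -> float:
    """Recovered response as a fraction of the pre-train response."""
    if pre_amp <= 0:
        raise ValueError("pre-train amplitude must be > 0")
    return float(post_amp / pre_amp)


def detect_spontaneous_events(sweep: SweepTrace, amp_threshold: float,
                              min_interval: float = 0.005,
                              exclude_windows=()) -> dict:
    """Threshold-crossing spontaneous-event detection with refractoriness.

    Scans the sweep outside ``exclude_windows`` (stimulus/test-pulse spans,
    as (start, stop) second pairs) for upward threshold crossings; after
    each event the detector is refractory for ``min_interval`` seconds.
    Event amplitude is the peak within the refractory span.  Reports event
    times, amplitudes, frequency over the analyzed duration, and the median
    amplitude.
    """
    times = sweep.times
    y = np.abs(sweep.samples.astype(float))
    excluded = np.zeros(len(y), dtype=bool)
    for (a, b) in exclude_windows:
        excluded |= (times >= a) & (times < b)
    analyzed = float(np.sum(~excluded)) / sweep.sampling_rate
    if analyzed <= 0:
        raise ValueError("no analyzable duration after exclusions")
    refractory = max(1, int(round(min_interval * sweep.sampling_rate)))
    ev_times, ev_amps = [], []
    i = 0
    n = len(y)
    while i < n:
        if not excluded[i] and y[i] >= amp_threshold:
            j = min(n, i + refractory)
            seg = y[i:j]
            k = int(np.argmax(seg))
            ev_times.append(float(times[i + k]))
            ev_amps.append(float(seg[k]))
            i = j
        else:
            i += 1
    return {
        "times": np.asarray(ev_times),
        "amplitudes": np.asarray(ev_amps),
        "frequency": len(ev_times) / analyzed,
        "median_amplitude": float(np.median(ev_amps)) if ev_amps else np.nan,
        "analyzed_duration": analyzed,
    }


def cohort_summary(values) -> dict:
    """Mean, standard error and coefficient of variation across cells."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 cells for a cohort summary")
    mean = float(np.mean(v))
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    sd = float(np.std(v, ddof=1))
    return {"mean": mean, "se": sd / np.sqrt(len(v)), "cv": sd / mean,
            "n": int(len(v))}
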