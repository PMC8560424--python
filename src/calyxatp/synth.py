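"""Synthetic stimulation protocols, EPSC trains, sweeps and cohorts.

Generates the study's stimulation protocols (brief 100/300 Hz bursts,
paired depletion/recovery trains, and the sustained 100 Hz trains lasting
tens of seconds) and stochastic data emulating recordings from calyx of
Held terminals: per-stimulus EPSC amplitudes following exponential
short-term depression with multiplicative quantal noise, Bernoulli
transmission failures whose probability is driven by the ATP bioenergetics
model, Poisson spontaneous events, continuously sampled sweeps with
stimulation artifacts, and cohorts with lognormal between-cell
variability.  Every generator is a pure function of its parameters and an
explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .bioenergetics import (
    BaseParams,
    TrainConsumption,
    simulate_relative_atp,
    failure_rate_from_atp,
)
from .fitting import FailureRateSeries
from .trains import EpscTrain, SweepTrace

__all__ = [
    "TrainSchedule",
    "Protocol",
    "CellParams",
    "CohortSpec",
    "build_protocol",
    "recovery_intervals",
    "printed_base_params",
    "gamma_max_for_end_ratio",
    "mature_oxphos_consumption",
    "mature_cell",
    "immature_cell",
    "simulate_epsc_train",
    "simulate_sweep_trace",
    "simulate_spontaneous_events",
    "simulate_cohort",
    "binomial_failure_series",
]

# failed stimuli still show a small residual deflection (noise floor),
# expressed as a fraction of the baseline EPSC — keeps the 5 %-threshold
# success classifier honestly exercised
_FAILURE_RESIDUAL_FRAC = 0.01

TEST_PULSE_TIMES = (0.1, 1.0, 4.0, 9.0, 19.0)  # s after train end


@dataclass(frozen=True)
class TrainSchedule:
    """One stimulus train: onset (s), frequency (Hz), count and role."""

    onset: float
    frequency: float
    n_stimuli: int
    role: str = "sustained"
    train_index: int = 1

    @property
    def stim_times(self) -> np.ndarray:
        return self.onset + np.arange(self.n_stimuli) / self.frequency

    @property
    def duration(self) -> float:
        return self.n_stimuli / self.frequency


@dataclass(frozen=True)
class Protocol:
    """A resolved stimulation protocol: a sequence of trains."""

    name: str
    trains: tuple[TrainSchedule, ...]
    recovery_intervals: tuple[float, ...] = ()
    test_pulse_times: tuple[float, ...] = ()


def recovery_intervals(preset: str = "figures") -> tuple[float, ...]:
    """Rest intervals between depletion and recovery trains (s).

    Two presets ship: ``figures`` starts at 10 ms, ``methods`` at 20 ms;
    both span to 13 s on a roughly geometric ladder of nine intervals.
    """
    if preset == "figures":
        return (0.01, 0.03, 0.1, 0.3, 1.0, 2.0, 4.0, 8.0, 13.0)
    if preset == "methods":
        return (0.02, 0.05, 0.1, 0.3, 1.0, 2.0, 4.0, 8.0, 13.0)
    raise ValueError(f"unknown recovery-interval preset {preset!r}")


def build_protocol(preset: str) -> Protocol:
    """Resolve a named stimulation protocol into explicit trains.

    Presets:
      HFS100             one 100 Hz x 200 ms burst (20 stimuli)
      HFS300             one 300 Hz x 150 ms burst (45 stimuli)
      sustained_mature   three 100 Hz x 150 s trains (15,000 stimuli each),
                         2 min rest between trains, test pulses after each
      sustained_immature three 100 Hz x 30 s trains, 2 min rests
      recovery_mature    nine HFS300 depletion/recovery pairs at increasing
                         intervals (10 ms - 13 s), 30 s between pairs
      recovery_immature  the same ladder with HFS100 pairs
    """
    if preset == "HFS100":
        return Protocol(preset, (TrainSchedule(0.0, 100.0, 20, "depletion"),))
    if preset == "HFS300":
        return Protocol(preset, (TrainSchedule(0.0, 300.0, 45, "depletion"),))
    if preset in ("sustained_mature", "sustained_immature"):
        dur = 150.0 if preset == "sustained_mature" else 30.0
        rest = 120.0
        trains = []
        t = 0.0
        for i in range(1, 4):
            trains.append(TrainSchedule(t, 100.0, int(round(100.0 * dur)),
                                        "sustained", train_index=i))
            t += dur + rest
        return Protocol(preset, tuple(trains),
                        test_pulse_times=TEST_PULSE_TIMES)
    if preset in ("recovery_mature", "recovery_immature"):
        freq, n = (300.0, 45) if preset == "recovery_mature" else (100.0, 20)
        ivals = recovery_intervals("figures")
        trains = []
        t = 0.0
        for k, iv in enumerate(ivals, start=1):
            dep = TrainSchedule(t, freq, n, "depletion", train_index=k)
            rec = TrainSchedule(dep.onset + dep.duration + iv, freq, n,
                                "recovery", train_index=k)
            trains += [dep, rec]
            t = rec.onset + rec.duration + 30.0
        return Protocol(preset, tuple(trains), recovery_intervals=ivals)
    raise ValueError(f"unknown protocol preset {preset!r}")


# --------------------------------------------------------------------------
# bioenergetics presets

def printed_base_params() -> BaseParams:
    """Shared model parameters for the mature -OxPhos condition.

    Basal consumption 0.0065 1/s rising to 0.11 1/s during the first
    sustained train (a ~17-fold increase), Hill coefficient 6 and
    half-failure ATP at 4.6 % of basal.
    """
    return BaseParams(gamma_b=0.0065, gamma_1=0.11, h=6.0, K_rel=0.046)


def gamma_max_for_end_ratio(gamma_1: float, end_ratio: float, h_t: float,
                            K_t: float, duration: float) -> float:
    """Asymptotic rate making gamma_i(duration) == end_ratio * gamma_1."""
    th = duration ** h_t
    return gamma_1 + (end_ratio - 1.0) * gamma_1 * (K_t ** h_t + th) / th


def mature_oxphos_consumption(base: BaseParams | None = None,
                              duration: float = 150.0,
                              h_t: float = 4.0,
                              K_t: float = 75.0) -> list[TrainConsumption]:
    """Per-train consumption schedules for the mature -OxPhos condition.

    Train 1 runs at a constant rate from rest.  Trains 2 and 3 start from
    10 % and 4.7 % of basal ATP and their demand climbs sigmoidally so the
    end-of-train rate exceeds the first-train rate by 26 % and 40 %
    respectively.  The sigmoid shape (steepness 4, half-time at the train
    midpoint) is a generator choice; only the onset ATP and end-of-train
    ratios are constrained.
    """
    base = base or printed_base_params()
    g1 = base.gamma_1
    return [
        TrainConsumption.constant(g1),
        TrainConsumption(2, gamma_max_for_end_ratio(g1, 1.26, h_t, K_t, duration),
                         h_t=h_t, K_t=K_t, atp0_rel=0.10),
        TrainConsumption(3, gamma_max_for_end_ratio(g1, 1.40, h_t, K_t, duration),
                         h_t=h_t, K_t=K_t, atp0_rel=0.047),
    ]


@dataclass(frozen=True)
class CellParams:
    """Generating parameters for one synthetic cell.

    Amplitude dynamics are phenomenological: exponential depression to a
    steady-state fraction within each train, multiplicative lognormal
    quantal noise.  The failure process, when ``bioenergetics`` is set, is
    an independent per-stimulus Bernoulli draw with probability given by
    the ATP model for that train.
    """

    baseline_amp: float = 10.0       # nA, initial EPSC magnitude
    dep_ss: float = 0.35             # steady-state depression fraction
    dep_tau: float = 0.05            # depression time constant, s
    rec_tau: float = 2.0             # recovery time constant, s
    rec_floor: float = 0.2           # fractional recovery at zero interval
    noise_cv: float = 0.1            # quantal (within-cell) amplitude CV
    bioenergetics: BaseParams | None = None
    consumption: tuple[TrainConsumption, ...] = ()
    sepsc_rate: float = 2.0          # spontaneous event rate, Hz
    sepsc_amp_mean: float = 0.4      # nA
    sepsc_amp_cv: float = 0.3

    def __post_init__(self) -> None:
        for name in ("baseline_amp", "dep_ss", "dep_tau", "rec_tau",
                     "rec_floor", "sepsc_rate", "sepsc_amp_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.noise_cv < 1:
            raise ValueError("noise_cv must be in [0, 1)")


def mature_cell(condition: str = "control") -> CellParams:
    """Mature (P16-18) cell preset for a given metabolic condition.

    ``minus_oxphos`` attaches the fitted bioenergetics model (failures
    emerge after ~30 s of sustained stimulation and worsen across trains);
    ``control`` and ``minus_glycolysis`` produce essentially no failures,
    as observed at this age.
    """
    if condition in ("control", "minus_glycolysis"):
        return CellParams()
    if condition == "minus_oxphos":
        return CellParams(bioenergetics=printed_base_params(),
                          consumption=tuple(mature_oxphos_consumption()))
    raise ValueError(f"unknown condition {condition!r}")


def immature_cell(condition: str = "control") -> CellParams:
    """Immature (P8-10) cell preset; illustrative failure model only.

    At this age sustained transmission needs glycolysis: the
    ``minus_glycolysis`` preset attaches an illustrative bioenergetics
    parameter set (no quantitative model exists for immature terminals)
    tuned to produce failures within the 30-s trains.
    """
    if condition in ("control", "minus_oxphos"):
        return CellParams(dep_ss=0.25, dep_tau=0.03)
    if condition == "minus_glycolysis":
        base = BaseParams(gamma_b=0.01, gamma_1=0.25, h=4.0, K_rel=0.08)
        cons = [
            TrainConsumption.constant(base.gamma_1),
            TrainConsumption(2, gamma_max_for_end_ratio(
                base.gamma_1, 1.3, 4.0, 15.0, 30.0), h_t=4.0, K_t=15.0,
                atp0_rel=0.3),
            TrainConsumption(3, gamma_max_for_end_ratio(
                base.gamma_1, 1.5, 4.0, 15.0, 30.0), h_t=4.0, K_t=15.0,
                atp0_rel=0.15),
        ]
        return CellParams(dep_ss=0.25, dep_tau=0.03, bioenergetics=base,
                          consumption=tuple(cons))
    raise ValueError(f"unknown condition {condition!r}")


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean lognormal multipliers with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv ** 2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def _failure_probability(cell: CellParams, sched: TrainSchedule,
                         rel_times: np.ndarray) -> np.ndarray:
    """Per-stimulus failure probability from the ATP model (0 without one)."""
    if cell.bioenergetics is None:
        return np.zeros(len(rel_times))
    tcs = {tc.train_index: tc for tc in cell.consumption}
    tc = tcs.get(sched.train_index)
    if tc is None:
        return np.zeros(len(rel_times))
    traj = simulate_relative_atp(cell.bioenergetics, tc,
                                 duration=max(sched.duration, 1e-3), dt=0.05)
    atp = np.interp(rel_times, traj.times, traj.atp_rel)
    return failure_rate_from_atp(atp, cell.bioenergetics.K_rel,
                                 cell.bioenergetics.h) / 100.0


def simulate_epsc_train(sched: TrainSchedule, cell: CellParams,
                        seed: int, condition: str = "control",
                        cell_id: str = "cell0",
                        run_index: int = 1) -> EpscTrain:
    """Simulate one EPSC train: depression + noise + ATP-driven failures.

    Mean amplitude follows ``baseline * (ss + (1-ss) exp(-t/tau))`` within
    the train, multiplied by unit-mean lognormal quantal noise.  Each
    stimulus fails independently with the probability given by the ATP
    model at that time; failed stimuli emit a small residual amplitude
    (1 % of baseline) rather than an exact zero.
    """
    rng = np.random.default_rng(seed)
    t = sched.stim_times - sched.onset
    mean = cell.baseline_amp * (cell.dep_ss
                                + (1.0 - cell.dep_ss) * np.exp(-t / cell.dep_tau))
    amps = mean * _lognormal_factors(rng, cell.noise_cv, len(t))
    p_fail = _failure_probability(cell, sched, t)
    failed = rng.random(len(t)) < p_fail
    residual = (_FAILURE_RESIDUAL_FRAC * cell.baseline_amp
                * _lognormal_factors(rng, 0.3, len(t)))
    amps = np.where(failed, residual, amps)
    return EpscTrain(stim_times=sched.stim_times, amplitudes=amps,
                     frequency=sched.frequency, cell_id=cell_id,
                     condition=condition, run_index=run_index,
                     train_role=sched.role)


def simulate_spontaneous_events(rate: float, duration: float,
                                amp_mean: float, amp_cv: float,
                                seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Poisson spontaneous-event times and lognormal amplitudes."""
    rng = np.random.default_rng(seed)
    n = rng.poisson(rate * duration)
    times = np.sort(rng.uniform(0.0, duration, size=n))
    amps = amp_mean * _lognormal_factors(rng, amp_cv, n)
    return times, amps


def simulate_sweep_trace(train: EpscTrain, seed: int,
                         kernel_tau: float = 0.003,
                         synaptic_delay: float = 0.001,
                         noise_sd: float = 0.02,
                         artifact_amp: float = 50.0,
                         artifact_width: float = 0.0005,
                         sampling_rate: float = 10_000.0,
                         pre_time: float = 0.1,
                         post_time: float = 0.1) -> tuple[SweepTrace, float]:
    """Render a train as a sampled current sweep with artifacts and noise.

    Each stimulus contributes an exponentially decaying EPSC kernel of
    integral ``amplitude * kernel_tau``, onset delayed by the synaptic
    latency so it clears the stimulation artifact, plus a brief biphasic
    artifact at the stimulus itself; Gaussian noise is added throughout.
    Returns the sweep and the ground-truth release charge (sum of kernel
    integrals), the oracle for integral-based RRP estimates.
    """
    rng = np.random.default_rng(seed)
    t0 = train.stim_times[0] - pre_time
    t_end = train.stim_times[-1] + post_time
    n = int(round((t_end - t0) * sampling_rate)) + 1
    times = t0 + np.arange(n) / sampling_rate
    y = np.zeros(n)
    for st, amp in zip(train.stim_times, train.amplitudes):
        rel = times - (st + synaptic_delay)
        m = rel >= 0
        y[m] += amp * np.exp(-rel[m] / kernel_tau)
        rel = times - st
        # biphasic artifact confined to artifact_width after the stimulus
        a = (rel >= 0) & (rel < artifact_width)
        y[a] += artifact_amp * np.sin(2 * np.pi * rel[a] / artifact_width)
    y += rng.normal(0.0, noise_sd, size=n)
    truth = float(np.sum(train.amplitudes) * kernel_tau)
    sweep = SweepTrace(sampling_rate=sampling_rate, samples=y,
                       stim_times=train.stim_times,
                       artifact_window=artifact_width, t_start=t0)
    return sweep, truth


@dataclass(frozen=True)
class CohortSpec:
    """Between-cell variability: lognormal CV per CellParams field."""

    n_cells: int = 14
    cv: dict = field(default_factory=lambda: {"baseline_amp": 0.31})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if any(v < 0 for v in self.cv.values()):
            raise ValueError("CVs must be >= 0")


_PERTURBABLE = ("baseline_amp", "dep_ss", "dep_tau", "rec_tau", "noise_cv",
                "sepsc_rate", "sepsc_amp_mean")


def simulate_cohort(spec: CohortSpec, template: CellParams,
                    protocol: Protocol, condition: str = "control"
                    ) -> dict[str, dict[int, EpscTrain]]:
    """Simulate a cohort of cells over a protocol.

    Per-cell parameters are drawn lognormally (unit-mean multipliers)
    around the template with the CVs in ``spec.cv``; per-cell and per-train
    seeds are spawned deterministically from ``spec.seed``.  Returns
    ``{cell_id: {train position: EpscTrain}}``.
    """
    master = np.random.SeedSequence(spec.seed)
    cell_seqs = master.spawn(spec.n_cells)
    dataset: dict[str, dict[int, EpscTrain]] = {}
    for ci, seq in enumerate(cell_seqs):
        rng = np.random.default_rng(seq)
        overrides = {}
        for name in _PERTURBABLE:
            cv = spec.cv.get(name, 0.0)
            if cv > 0:
                overrides[name] = float(getattr(template, name)
                                        * _lognormal_factors(rng, cv, None))
        cell = replace(template, **overrides) if overrides else template
        cell_id = f"cell{ci:03d}"
        train_seeds = seq.spawn(len(protocol.trains))
        trains = {}
        for k, (sched, ts) in enumerate(zip(protocol.trains, train_seeds)):
            seed_k = int(ts.generate_state(1)[0] % (2 ** 31))
            trains[k] = simulate_epsc_train(sched, cell, seed_k,
                                            condition=condition,
                                            cell_id=cell_id,
                                            run_index=sched.train_index)
        dataset[cell_id] = trains
    return dataset


def binomial_failure_series(base: BaseParams, tc: TrainConsumption,
                            duration: float, seed: int,
                            frequency: float = 100.0,
                            n_per_bin: int = 25,
                            n_cells: int = 14) -> FailureRateSeries:
    """Binomially noisy binned failure series straight from the ATP model.

    Emulates the sampling noise of averaging 25-stimulus bins across a
    cohort without simulating amplitudes: each bin's failure count is a
    Binomial(n_per_bin * n_cells, p) draw at the model's failure
    probability for the bin center.
    """
    rng = np.random.default_rng(seed)
    bin_dt = n_per_bin / frequency
    centers = np.arange(bin_dt / 2.0, duration, bin_dt)
    traj = simulate_relative_atp(base, tc, duration, dt=min(0.05, bin_dt / 2))
    atp = np.interp(centers, traj.times, traj.atp_rel)
    p = failure_rate_from_atp(atp, base.K_rel, base.h) / 100.0
    n_trials = n_per_bin * n_cells
    counts = rng.binomial(n_trials, p)
    return FailureRateSeries(train_index=tc.train_index, times=centers,
                             failure_pct=100.0 * counts / n_trials,
                             n_per_bin=n_per_bin)
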