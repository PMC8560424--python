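"""Parameter estimation for the ATP-failure model by bounded least squares.

The observable is a per-train failure-rate time course obtained by
subtracting the success percentage recorded with oxidative phosphorylation
blocked from the success percentage in control glucose, on matched time
bins — transmission failures attributable specifically to OxPhos-dependent
ATP production.

Fitting is sequential, mirroring the structure of the model: the first
train (constant consumption, resting start) determines the four shared
parameters (gamma_b, gamma_1, h, K_rel); those are then frozen and each
later train contributes four of its own (onset ATP, asymptotic consumption
rate, sigmoid steepness and half-time).  The optimizer is bounded
trust-region least squares restarted from log-uniformly perturbed initial
guesses; the best sum of squared errors wins, and the spread of estimates
across starts is kept as an identifiability diagnostic (the Hill pair
h–K_rel trades off when the data only sample one flank of the sigmoid).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .bioenergetics import (
    BaseParams,
    TrainConsumption,
    FailureCurve,
    failure_rate_from_atp,
    relative_atp_closed_form,
    simulate_relative_atp,
    consumption_rate_sigmoid,
)

__all__ = [
    "FailureRateSeries",
    "FitConfig",
    "FitResult",
    "UnidentifiableError",
    "oxphos_dependent_failure",
    "fit_first_train",
    "fit_subsequent_train",
    "fit_diagnostics",
    "predict_series",
]


class UnidentifiableError(ValueError):
    """Raised when the observed series carries no information on the parameters."""


@dataclass(frozen=True)
class FailureRateSeries:
    """Binned failure percentages against time within one train.

    ``n_per_bin`` records how many stimuli each bin aggregates (25 by
    default, i.e. 0.25 s at 100 Hz); times are bin centers in seconds from
    train onset.
    """

    train_index: int
    times: np.ndarray
    failure_pct: np.ndarray
    n_per_bin: int = 25

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.failure_pct, dtype=float)
        if t.shape != f.shape:
            raise ValueError("times and failure_pct lengths differ")
        if t.ndim != 1 or len(t) == 0:
            raise ValueError("series must be a nonempty 1-D array")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly ascending")
        if np.any((f < 0) | (f > 100)):
            raise ValueError("failure_pct must lie in [0, 100]")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "failure_pct", f)


# default bounds: wide but physical (rates in 1/s, K_rel/atp0 as fractions)
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "gamma_b": (1e-4, 1.0),
    "gamma_1": (1e-3, 10.0),
    "h": (0.5, 20.0),
    "K_rel": (1e-3, 0.5),
    "atp0_rel": (1e-3, 1.0),
    "gamma_max": (np.nan, 10.0),  # lower bound filled with gamma_1 at fit time
    "h_t": (0.5, 20.0),
    "K_t": (1.0, 300.0),
}


@dataclass
class FitConfig:
    """Optimizer settings: bounds, multi-start count and RNG seed."""

    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS))
    n_starts: int = 20
    seed: int = 17
    xtol: float = 1e-12
    ftol: float = 1e-12
    gtol: float = 1e-12

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")


@dataclass
class FitResult:
    """Best-of-starts estimate with residuals and multi-start diagnostics."""

    params: dict[str, float]
    sse: float
    residuals: np.ndarray
    start_dispersion: dict[str, float]
    converged: bool
    n_starts_converged: int

    def to_json(self) -> str:
        doc = {
            "params": self.params,
            "sse": self.sse,
            "converged": self.converged,
            "n_starts_converged": self.n_starts_converged,
            "start_dispersion": self.start_dispersion,
        }
        return json.dumps(doc, indent=2)


def oxphos_dependent_failure(
    success_ctrl,
    success_block,
    times,
    train_index: int = 1,
    n_per_bin: int = 25,
) -> FailureRateSeries:
    """OxPhos-dependent failure percentage from paired success curves.

    Element-wise control-minus-blocked success difference on identical time
    bins, clamped to [0, 100]; bins where the blocked condition outperforms
    control (sampling noise) clamp to zero.
    """
    c = np.asarray(success_ctrl, dtype=float)
    b = np.asarray(success_block, dtype=float)
    t = np.asarray(times, dtype=float)
    if not (c.shape == b.shape == t.shape):
        raise ValueError("success series and times must align bin-for-bin")
    if np.any((c < 0) | (c > 100)) or np.any((b < 0) | (b > 100)):
        raise ValueError("success percentages must lie in [0, 100]")
    diff = np.clip(c - b, 0.0, 100.0)
    return FailureRateSeries(train_index=train_index, times=t,
                             failure_pct=diff, n_per_bin=n_per_bin)


def _predict_first_train(times, gamma_b, gamma_1, h, K_rel):
    atp = relative_atp_closed_form(times, gamma_b, gamma_1)
    return failure_rate_from_atp(atp, K_rel, h)


def _predict_later_train(times, base: BaseParams, tc: TrainConsumption):
    # integrate once over the span and read off bin centers
    duration = float(times[-1])
    dt = min(0.25, duration / max(len(times), 4))
    traj = simulate_relative_atp(base, tc, duration, dt)
    atp = np.interp(times, traj.times, traj.atp_rel)
    return failure_rate_from_atp(atp, base.K_rel, base.h)


def predict_series(series_times, base: BaseParams,
                   tc: TrainConsumption | None = None) -> np.ndarray:
    """Model failure prediction at the series' bin centers."""
    times = np.asarray(series_times, dtype=float)
    if tc is None or tc.train_index == 1:
        return _predict_first_train(times, base.gamma_b, base.gamma_1,
                                    base.h, base.K_rel)
    return _predict_later_train(times, base, tc)


def _multistart(residual_fn, x0, lb, ub, cfg: FitConfig):
    """Run bounded least squares from log-perturbed starts; keep them all."""
    rng = np.random.default_rng(cfg.seed)
    starts = [np.asarray(x0, dtype=float)]
    for _ in range(cfg.n_starts - 1):
        fac = np.exp(rng.uniform(-np.log(3.0), np.log(3.0), size=len(x0)))
        starts.append(np.clip(x0 * fac, lb * 1.0000001, ub * 0.9999999))
    solutions = []
    for s in starts:
        try:
            sol = least_squares(residual_fn, s, bounds=(lb, ub), method="trf",
                                xtol=cfg.xtol, ftol=cfg.ftol, gtol=cfg.gtol)
        except Exception:
            continue
        if sol.success and np.all(np.isfinite(sol.x)):
            solutions.append(sol)
    if not solutions:
        raise RuntimeError(
            "no optimizer start converged; check bounds and data scaling")
    solutions.sort(key=lambda s: float(np.sum(s.fun ** 2)))
    return solutions


def _dispersion(solutions, names):
    xs = np.array([s.x for s in solutions])
    return {n: float(np.ptp(xs[:, i])) for i, n in enumerate(names)}


def fit_first_train(series: FailureRateSeries, cfg: FitConfig | None = None) -> FitResult:
    """Estimate (gamma_b, gamma_1, h, K_rel) from a first-train failure curve.

    The forward prediction is the constant-rate closed form composed with
    the Hill link.  Raises :class:`UnidentifiableError` when the series is
    identically zero (no failures constrain the Hill parameters).
    """
    if series.train_index != 1:
        raise ValueError("fit_first_train expects train_index == 1")
    if len(series.times) < 8:
        raise ValueError("need at least 8 bins to fit four parameters")
    if np.all(series.failure_pct == 0):
        raise UnidentifiableError(
            "failure series is identically zero; h and K_rel unconstrained")
    cfg = cfg or FitConfig()
    names = ["gamma_b", "gamma_1", "h", "K_rel"]
    lb = np.array([cfg.bounds[n][0] for n in names])
    ub = np.array([cfg.bounds[n][1] for n in names])
    obs = series.failure_pct
    t = series.times

    def resid(x):
        return _predict_first_train(t, *x) - obs

    x0 = np.array([0.01, 0.1, 4.0, 0.05])
    sols = _multistart(resid, x0, lb, ub, cfg)
    best = sols[0]
    params = dict(zip(names, (float(v) for v in best.x)))
    return FitResult(
        params=params,
        sse=float(np.sum(best.fun ** 2)),
        residuals=best.fun.copy(),
        start_dispersion=_dispersion(sols, names),
        converged=bool(best.success),
        n_starts_converged=len(sols),
    )


def fit_subsequent_train(
    series: FailureRateSeries,
    base: BaseParams,
    cfg: FitConfig | None = None,
) -> FitResult:
    """Estimate (atp0_rel, gamma_max, h_t, K_t) for train 2 or 3.

    The shared parameters estimated from the first train are held fixed;
    the forward prediction integrates the ATP balance with the sigmoidal
    consumption schedule.  The onset ATP guess is seeded by inverting the
    Hill link at the first observed bin, which pins ``atp0_rel`` tightly.
    """
    if series.train_index not in (2, 3):
        raise ValueError("fit_subsequent_train expects train_index in {2, 3}")
    if len(series.times) < 8:
        raise ValueError("need at least 8 bins to fit four parameters")
    if np.all(series.failure_pct == 0):
        raise UnidentifiableError(
            "failure series is identically zero; onset ATP unconstrained")
    cfg = cfg or FitConfig()
    names = ["atp0_rel", "gamma_max", "h_t", "K_t"]
    lb = np.array([cfg.bounds["atp0_rel"][0], base.gamma_1,
                   cfg.bounds["h_t"][0], cfg.bounds["K_t"][0]])
    ub = np.array([cfg.bounds["atp0_rel"][1], cfg.bounds["gamma_max"][1],
                   cfg.bounds["h_t"][1], cfg.bounds["K_t"][1]])
    obs = series.failure_pct
    t = series.times
    idx = series.train_index

    def resid(x):
        atp0, gmax, ht, kt = x
        tc = TrainConsumption(train_index=idx, gamma_max=gmax, h_t=ht,
                              K_t=kt, atp0_rel=atp0)
        return _predict_later_train(t, base, tc) - obs

    # invert the Hill link at the first bin for an onset-ATP guess
    f0 = float(np.clip(obs[0], 0.5, 99.5))
    atp0_guess = float(np.clip(
        base.K_rel * ((100.0 - f0) / f0) ** (1.0 / base.h), lb[0] * 2, 1.0))
    x0 = np.array([atp0_guess, max(1.5 * base.gamma_1, lb[1] * 1.01),
                   2.0, max(t[-1] / 2.0, lb[3] * 1.01)])
    sols = _multistart(resid, x0, lb, ub, cfg)
    best = sols[0]
    params = dict(zip(names, (float(v) for v in best.x)))
    return FitResult(
        params=params,
        sse=float(np.sum(best.fun ** 2)),
        residuals=best.fun.copy(),
        start_dispersion=_dispersion(sols, names),
        converged=bool(best.success),
        n_starts_converged=len(sols),
    )


def fit_diagnostics(
    fit: FitResult,
    series: FailureRateSeries,
    base: BaseParams | None = None,
    sweep_points: int = 21,
    sweep_span: float = 2.0,
) -> dict:
    """Residual summary plus 1-D SSE sweeps per fitted parameter.

    Each sweep evaluates the SSE on a log-spaced grid spanning
    ``[estimate/sweep_span, estimate*sweep_span]`` with the other
    parameters held at their estimates (no re-optimization) — a cheap
    profile-likelihood-style identifiability picture.  ``base`` must be
    supplied for train 2/3 fits.
    """
    if not fit.converged:
        raise ValueError("diagnostics require a converged fit")
    t = series.times
    obs = series.failure_pct

    def predict(params: dict[str, float]) -> np.ndarray:
        if series.train_index == 1:
            return _predict_first_train(t, params["gamma_b"],
                                        params["gamma_1"], params["h"],
                                        params["K_rel"])
        if base is None:
            raise ValueError("base parameters required for train 2/3 sweeps")
        tc = TrainConsumption(train_index=series.train_index,
                              gamma_max=params["gamma_max"],
                              h_t=params["h_t"], K_t=params["K_t"],
                              atp0_rel=params["atp0_rel"])
        return _predict_later_train(t, base, tc)

    sweeps = {}
    for name, val in fit.params.items():
        grid = np.geomspace(val / sweep_span, val * sweep_span, sweep_points)
        sse = []
        for g in grid:
            p = dict(fit.params)
            p[name] = float(g)
            try:
                sse.append(float(np.sum((predict(p) - obs) ** 2)))
            except ValueError:
                sse.append(np.nan)
        sweeps[name] = {"grid": grid.tolist(), "sse": sse}
    return {
        "sse": fit.sse,
        "residuals": fit.residuals.tolist(),
        "start_dispersion": fit.start_dispersion,
        "sweeps": sweeps,
    }
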