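"""Relative presynaptic ATP dynamics and the ATP → transmission-failure link.

The model describes ATP turnover at a presynaptic terminal driven at high
frequency for tens of seconds.  ATP is produced at a constant rate and
consumed both basally (rate ``gamma_b``) and in an activity-dependent way
(rate ``gamma_i`` during the *i*-th sustained stimulation train)::

    d[ATP]/dt = k - gamma_b * [ATP] - gamma_i(t) * [ATP]

Everything is expressed relative to the resting ATP level, so the basal
fixed point is 1 and the production constant is eliminated (``k = gamma_b``
in relative units).  The probability that a stimulus fails to evoke a
postsynaptic current is a Hill function of the instantaneous relative ATP
level: failure = 100 / (1 + (atp/K)^h) percent, with half-failure point
``K`` (a fraction of basal ATP) and cooperativity ``h``.

During the first sustained train a constant consumption rate suffices and
the ODE has a closed-form monoexponential solution.  Later trains need a
consumption rate that itself grows during the train; that growth is
modelled as a sigmoid in time (``consumption_rate_sigmoid``) and the ODE is
then integrated numerically.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, field

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "BaseParams",
    "TrainConsumption",
    "AtpTrajectory",
    "FailureCurve",
    "relative_atp_closed_form",
    "consumption_rate_sigmoid",
    "simulate_relative_atp",
    "failure_rate_from_atp",
    "predict_failure_curve",
    "steady_state_atp",
]

# solver tolerances: scalar linear ODE, so tight tolerances are cheap and
# make closed-form comparisons meaningful
_RTOL = 1e-9
_ATOL = 1e-12


@dataclass(frozen=True)
class BaseParams:
    """Parameters shared by all trains, in relative-ATP units.

    gamma_b   basal (stimulation-independent) ATP consumption rate, 1/s
    gamma_1   activity-dependent consumption rate during the first train, 1/s
    h         Hill coefficient of the ATP -> failure link (dimensionless)
    K_rel     relative ATP level at which the failure rate is 50 %
    atp1_rel  resting ATP level; identically 1 by normalization
    """

    gamma_b: float
    gamma_1: float
    h: float
    K_rel: float
    atp1_rel: float = 1.0

    def __post_init__(self) -> None:
        if not self.gamma_b > 0:
            raise ValueError(f"gamma_b must be > 0, got {self.gamma_b}")
        if self.gamma_1 < 0:
            raise ValueError(f"gamma_1 must be >= 0, got {self.gamma_1}")
        if not self.h > 0:
            raise ValueError(f"h must be > 0, got {self.h}")
        if not 0 < self.K_rel < 1:
            raise ValueError(f"K_rel must be in (0, 1), got {self.K_rel}")
        if self.atp1_rel != 1.0:
            raise ValueError("atp1_rel is fixed at 1 by normalization")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, doc: str) -> "BaseParams":
        return cls(**json.loads(doc))


@dataclass(frozen=True)
class TrainConsumption:
    """Per-train consumption schedule and initial condition.

    For train 1 the consumption rate is constant (``gamma_max == gamma_1``
    of the linked :class:`BaseParams`) and the train starts from rest
    (``atp0_rel == 1``).  For later trains the rate climbs sigmoidally from
    gamma_1 toward ``gamma_max`` with half-time ``K_t`` (s) and steepness
    ``h_t``, and the train starts from a depleted level ``atp0_rel``.
    """

    train_index: int
    gamma_max: float
    h_t: float = 1.0
    K_t: float = 1.0
    atp0_rel: float = 1.0

    def __post_init__(self) -> None:
        if self.train_index < 1:
            raise ValueError("train_index is 1-based")
        if not self.K_t > 0:
            raise ValueError(f"K_t must be > 0, got {self.K_t}")
        if not self.h_t > 0:
            raise ValueError(f"h_t must be > 0, got {self.h_t}")
        if not 0 < self.atp0_rel <= 1:
            raise ValueError(f"atp0_rel must be in (0, 1], got {self.atp0_rel}")
        if self.gamma_max < 0:
            raise ValueError("gamma_max must be >= 0")

    @classmethod
    def constant(cls, gamma_1: float) -> "TrainConsumption":
        """Train-1 schedule: constant rate gamma_1 from rest."""
        return cls(train_index=1, gamma_max=gamma_1, atp0_rel=1.0)

    def validate_against(self, base: BaseParams) -> None:
        if self.gamma_max < base.gamma_1 - 1e-12:
            raise ValueError("gamma_max must be >= gamma_1")
        if self.train_index == 1:
            if not math.isclose(self.gamma_max, base.gamma_1, rel_tol=1e-9):
                raise ValueError("train 1 requires gamma_max == gamma_1")
            if self.atp0_rel != 1.0:
                raise ValueError("train 1 starts from rest (atp0_rel == 1)")


@dataclass(frozen=True)
class AtpTrajectory:
    """Time-resolved relative ATP level over one train."""

    times: np.ndarray
    atp_rel: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.atp_rel, dtype=float)
        if t.shape != a.shape:
            raise ValueError("times and atp_rel must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly ascending")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "atp_rel", a)

    def to_delimited(self, path, header: str = "time_s\tatp_rel") -> None:
        np.savetxt(path, np.column_stack([self.times, self.atp_rel]),
                   delimiter="\t", header=header, comments="")


@dataclass(frozen=True)
class FailureCurve:
    """Predicted failure percentage against time within one train."""

    times: np.ndarray
    failure_pct: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.failure_pct, dtype=float)
        if t.shape != f.shape:
            raise ValueError("times and failure_pct must have equal length")
        if np.any((f < 0) | (f > 100)):
            raise ValueError("failure_pct must lie in [0, 100]")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "failure_pct", f)

    def to_delimited(self, path, header: str = "time_s\tfailure_pct") -> None:
        np.savetxt(path, np.column_stack([self.times, self.failure_pct]),
                   delimiter="\t", header=header, comments="")


def steady_state_atp(gamma_b: float, gamma_stim: float) -> float:
    """Asymptotic relative ATP under a constant consumption rate.

    Balancing production against consumption gives 1 / (1 + gamma_stim/gamma_b).
    """
    if gamma_b <= 0:
        raise ValueError("gamma_b must be > 0")
    return 1.0 / (1.0 + gamma_stim / gamma_b)


def relative_atp_closed_form(t, gamma_b: float, gamma_stim: float):
    """Closed-form relative ATP decay under constant consumption from rest.

    [ATP](t) = (1 + r e^{-(gamma_stim+gamma_b) t}) / (1 + r),  r = gamma_stim/gamma_b,

    starting at the basal level 1 and relaxing monoexponentially to the
    steady state 1/(1+r).  Valid only for a constant consumption rate and a
    train that starts from rest.

    Parameters accept scalars or arrays of times (s); negative times and a
    nonpositive basal rate are rejected.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if gamma_b <= 0:
        raise ValueError("gamma_b must be > 0")
    if gamma_stim < 0:
        raise ValueError("gamma_stim must be >= 0")
    r = gamma_stim / gamma_b
    out = (1.0 + r * np.exp(-(gamma_stim + gamma_b) * t)) / (1.0 + r)
    return out if out.ndim else float(out)


def consumption_rate_sigmoid(t, gamma_1: float, tc: TrainConsumption):
    """Time-varying activity-dependent consumption rate during a train.

    gamma_i(t) = gamma_1 + (gamma_max - gamma_1) * t^h_t / (K_t^h_t + t^h_t)

    Starts at gamma_1 (same demand as the first train), is halfway to
    ``gamma_max`` at ``t == K_t`` and saturates at ``gamma_max``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    th = np.power(t, tc.h_t)
    out = gamma_1 + (tc.gamma_max - gamma_1) * th / (tc.K_t ** tc.h_t + th)
    return out if out.ndim else float(out)


def simulate_relative_atp(
    base: BaseParams,
    tc: TrainConsumption,
    duration: float,
    dt: float = 0.25,
) -> AtpTrajectory:
    """Numerically integrate the ATP balance over one train.

    Solves d a/dt = gamma_b (1 - a) - gamma_i(t) a from ``tc.atp0_rel`` on a
    uniform grid of spacing ``dt``.  With a constant rate and a resting
    start this agrees with :func:`relative_atp_closed_form` to solver
    tolerance (an invariant exercised by the test suite).
    """
    if duration <= 0 or dt <= 0 or dt > duration:
        raise ValueError("require 0 < dt <= duration")
    tc.validate_against(base)

    def rhs(t, a):
        g = consumption_rate_sigmoid(t, base.gamma_1, tc)
        return base.gamma_b * (1.0 - a[0]) - g * a[0]

    n = int(round(duration / dt))
    times = np.linspace(0.0, n * dt, n + 1)
    sol = solve_ivp(
        rhs, (0.0, times[-1]), [tc.atp0_rel], t_eval=times,
        method="LSODA", rtol=_RTOL, atol=_ATOL,
    )
    if not sol.success:
        raise RuntimeError(f"ATP ODE solver failed: {sol.message}")
    atp = sol.y[0]
    if not np.all(np.isfinite(atp)):
        raise RuntimeError("ATP ODE produced non-finite values")
    return AtpTrajectory(times=times, atp_rel=atp)


def failure_rate_from_atp(atp_rel, K_rel: float, h: float):
    """Hill mapping from relative ATP to transmission-failure percentage.

    100 / (1 + (atp/K)^h): exactly 50 % at ``atp_rel == K_rel``, strictly
    decreasing in ATP, negligible at rest for the fitted parameters.
    """
    atp = np.asarray(atp_rel, dtype=float)
    if np.any(atp <= 0):
        raise ValueError("atp_rel must be > 0 (model undefined at zero ATP)")
    if not 0 < K_rel < 1:
        raise ValueError("K_rel must be in (0, 1)")
    if h <= 0:
        raise ValueError("h must be > 0")
    # evaluate in log space to avoid overflow for extreme atp/K ratios
    logratio = h * (np.log(atp) - np.log(K_rel))
    out = 100.0 / (1.0 + np.exp(logratio))
    return out if out.ndim else float(out)


def predict_failure_curve(
    base: BaseParams,
    tc: TrainConsumption,
    duration: float,
    dt: float = 0.25,
) -> FailureCurve:
    """Predicted failure-rate time course for one train.

    Composition of the ATP simulation and the Hill failure link; for a
    constant-rate first train the result is monotone nondecreasing.
    """
    traj = simulate_relative_atp(base, tc, duration, dt)
    pct = failure_rate_from_atp(traj.atp_rel, base.K_rel, base.h)
    return FailureCurve(times=traj.times, failure_pct=pct)
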