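"""One-compartment saturable dose-response model.

The concentration C(t) of an arbitrary analyte follows

    dC/dt = -k * C / (1 + beta * C) + (U_N + U_x(t)) / V

where ``k`` is a first-order decay rate (1/min), ``U_N`` an endogenous
production rate (amount/min), ``V`` the volume of distribution, and ``beta``
a saturation coefficient (1/concentration) giving Michaelis-Menten style
elimination when positive.  ``U_x(t)`` is an external bolus, modelled as a
constant input rate over a short interval.  The system starts at its
pre-bolus equilibrium C0 = U_N / (k*V - beta*U_N) and is integrated with
fixed-step forward Euler so results are bit-for-bit reproducible.

Three reference parameter scenarios are provided, resembling the progression
towards a saturated biological response; three model "cases" of increasing
complexity define which parameters are treated as unknown:

* Case 1: theta = {k, U_N}, beta = 0 fixed, V a priori.
* Case 2: theta = {k, U_N, V}, beta = 0 fixed.
* Case 3: theta = {k, U_N, V, beta}, beta = 1 (saturable kinetics).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from . import _kernels

PARAM_NAMES = ("k", "u_n", "v", "beta")

#: (k, u_n, v) for parameter scenarios 1-3; beta is case-dependent.
SCENARIO_TABLE = {
    1: (4.0e-3, 1.0e-2, 400.0),
    2: (2.0e-3, 5.0e-3, 400.0),
    3: (1.0e-3, 2.5e-3, 400.0),
}

#: free-parameter names per model case
CASE_FREE = {
    1: ("k", "u_n"),
    2: ("k", "u_n", "v"),
    3: ("k", "u_n", "v", "beta"),
}

#: value of beta per model case
CASE_BETA = {1: 0.0, 2: 0.0, 3: 1.0}

#: minimum number of samples considered per case (one per free parameter,
#: plus one); the common maximum is 20
CASE_NS_MIN = {1: 3, 2: 4, 3: 5}
NS_MAX = 20


@dataclass(frozen=True)
class ParameterScenario:
    """A point in parameter space plus which components are free.

    ``free_mask`` marks, in the order (k, u_n, v, beta), the parameters that
    the active model case identifies from data; the rest are a priori.
    """

    k: float
    u_n: float
    v: float
    beta: float = 0.0
    free_mask: tuple[bool, bool, bool, bool] = (True, True, False, False)
    label: str = ""

    def __post_init__(self):
        if not (self.k > 0 and self.u_n > 0 and self.v > 0):
            raise ValueError("k, U_N and V must be strictly positive")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if self.k * self.v - self.beta * self.u_n <= 0:
            raise ValueError("k*V - beta*U_N <= 0: no positive equilibrium")
        if len(self.free_mask) != 4 or not any(self.free_mask):
            raise ValueError("free_mask must flag at least one of 4 parameters")

    @property
    def theta(self) -> np.ndarray:
        """Full parameter vector (k, u_n, v, beta)."""
        return np.array([self.k, self.u_n, self.v, self.beta], dtype=float)

    @property
    def free_idx(self) -> np.ndarray:
        """Indices of the free parameters within the full vector."""
        return np.flatnonzero(np.asarray(self.free_mask)).astype(np.int64)

    @property
    def free_theta(self) -> np.ndarray:
        """Values of the free parameters."""
        return self.theta[self.free_idx]

    @property
    def free_names(self) -> tuple[str, ...]:
        return tuple(PARAM_NAMES[i] for i in self.free_idx)


def scenario(case: int, number: int) -> ParameterScenario:
    """Reference scenario ``number`` (1-3) configured for model ``case`` (1-3)."""
    if case not in CASE_FREE:
        raise ValueError(f"unknown model case {case!r}")
    if number not in SCENARIO_TABLE:
        raise ValueError(f"unknown parameter scenario {number!r}")
    k, u_n, v = SCENARIO_TABLE[number]
    mask = tuple(name in CASE_FREE[case] for name in PARAM_NAMES)
    return ParameterScenario(k=k, u_n=u_n, v=v, beta=CASE_BETA[case],
                             free_mask=mask,
                             label=f"case{case}-scenario{number}")


@dataclass(frozen=True)
class SimulationConfig:
    """Euler integration settings and bolus description (times in minutes)."""

    t_end: float = 600.0
    dt: float = 1.0
    bolus_time: float = 60.0
    bolus_magnitude: float = 4.0
    bolus_duration: float = 1.0

    def __post_init__(self):
        if self.dt <= 0 or self.t_end <= 0:
            raise ValueError("dt and t_end must be positive")
        for name in ("t_end", "bolus_time", "bolus_duration"):
            val = getattr(self, name)
            if abs(round(val / self.dt) - val / self.dt) > 1e-9:
                raise ValueError(f"dt must divide {name}")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_end / self.dt))

    @property
    def bolus_off(self) -> float:
        return self.bolus_time + self.bolus_duration

    @property
    def grid(self) -> np.ndarray:
        return np.arange(self.n_steps + 1) * self.dt


DEFAULT_SIM = SimulationConfig()


@dataclass(frozen=True)
class Trajectory:
    """Concentration curve on the Euler grid."""

    times: np.ndarray
    conc: np.ndarray
    dt: float

    def to_csv(self, path: str | Path) -> None:
        """Write a two-column (time_min, concentration) CSV."""
        arr = np.column_stack([self.times, self.conc])
        np.savetxt(path, arr, delimiter=",", header="time_min,concentration",
                   comments="")


def steady_state(scen: ParameterScenario) -> float:
    """Pre-bolus equilibrium concentration C0 = U_N / (k*V - beta*U_N)."""
    c0 = _kernels.steady_state(scen.k, scen.u_n, scen.v, scen.beta)
    if c0 <= 0:
        raise ValueError("no physical equilibrium: k*V - beta*U_N <= 0")
    return c0


def simulate(scen: ParameterScenario,
             config: SimulationConfig = DEFAULT_SIM) -> Trajectory:
    """Forward-Euler trajectory of the scenario from its equilibrium."""
    conc = np.empty(config.n_steps + 1)
    ok = _kernels.simulate(scen.k, scen.u_n, scen.v, scen.beta,
                           config.dt, config.n_steps,
                           config.bolus_time, config.bolus_off,
                           config.bolus_magnitude, conc)
    if not ok:
        raise ValueError("no physical equilibrium: k*V - beta*U_N <= 0")
    return Trajectory(times=config.grid, conc=conc, dt=config.dt)


def observe(traj: Trajectory, schedule: Iterable[float]) -> np.ndarray:
    """Model concentrations at schedule times, by linear interpolation.

    Exact grid hits return node values; times outside the simulated horizon
    raise ValueError.
    """
    t = np.ascontiguousarray(schedule, dtype=float)
    t_end = traj.times[-1]
    if t.size and (t.min() < 0.0 or t.max() > t_end + 1e-12):
        raise ValueError(f"schedule times must lie in [0, {t_end}]")
    out = np.empty(t.size)
    _kernels.interp_observe(traj.conc, traj.dt, t, out)
    return out
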