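"""Profile-likelihood confidence intervals and the PLB_crit design metric.

Each free parameter theta_i is "profiled" by fixing it along a range of
values while refitting the remaining free parameters to data.  The pointwise
confidence interval [theta_i-, theta_i+] collects the values where the
profiled objective stays within chi^2(alpha, dof) of its minimum; with the
default alpha = 0.68 and one degree of freedom the threshold is 0.9889
(~0.99).  A parameter is practically identifiable when its interval is
finite.

The design metric is the root-sum-square of normalised interval half-widths,

    PLB_crit = sqrt( sum_i ((theta_i+ - theta_i-) / (2 * theta_hat_i))^2 ),

evaluated on noise-free data generated at the scenario's nominal parameters,
so the best estimate is the truth, psi_min = 0, and the metric is fully
deterministic.  Any non-finite bound maps the metric to +inf, which ranks
such schedules last in the genetic algorithm.

Two implementations coexist: a generic walker over a user-supplied profile
objective (used for closed-form oracles and diagnostics) and a compiled
fast path for the PK model (used by the optimisation loop); the test suite
checks they agree.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from . import _kernels
from .estimation import Dataset, FitResult, default_sigma, fit_fast
from .model import DEFAULT_SIM, ParameterScenario, SimulationConfig, PARAM_NAMES


@dataclass(frozen=True)
class ThresholdSpec:
    """Chi-squared likelihood-ratio threshold for pointwise intervals."""

    alpha: float = 0.68
    dof: int = 1

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.dof < 1:
            raise ValueError("dof must be >= 1")

    @property
    def delta_chi2(self) -> float:
        """Inverse chi-squared CDF at (alpha, dof); ~0.9889 for defaults."""
        return float(stats.chi2.ppf(self.alpha, self.dof))


DEFAULT_THRESHOLD = ThresholdSpec()

#: profile-walk numerics: initial step as a fraction of |theta_hat_i|,
#: range cap as a multiple of |theta_hat_i| (upward) and a fraction of
#: theta_hat_i (downward), and the maximum grid points per direction.
DEFAULT_WALK = dict(step_frac=0.01, cap_factor=100.0, lo_cap_frac=0.01,
                    max_pts=200)


@dataclass
class ProfileCurve:
    """Profiled objective along one parameter, both directions combined."""

    parameter_index: int
    theta_hat: float
    psi_min: float
    grid: np.ndarray
    psi_profile: np.ndarray
    nuisance_paths: np.ndarray | None = None

    def to_csv(self, path: str | Path) -> None:
        np.savetxt(path, np.column_stack([self.grid, self.psi_profile]),
                   delimiter=",", header="theta_value,psi", comments="")


@dataclass(frozen=True)
class ConfidenceInterval:
    """Likelihood-threshold interval with finiteness/feasibility flags."""

    lower: float
    upper: float
    lower_finite: bool = True
    upper_finite: bool = True
    lower_feasible: bool = True

    def __post_init__(self):
        if self.lower_finite and self.upper_finite and self.lower > self.upper:
            raise ValueError("lower bound exceeds upper bound")

    @property
    def finite(self) -> bool:
        return self.lower_finite and self.upper_finite

    @property
    def width(self) -> float:
        if not self.finite:
            return math.inf
        return self.upper - self.lower


def _walk_direction(psi_fn: Callable[[float], float], theta_hat: float,
                    psi_min: float, dchi2: float, direction: float, *,
                    step_frac: float, cap_factor: float, lo_cap_frac: float,
                    max_pts: int, allow_negative: bool, overshoot: float):
    """Dense outward walk targeting ~dchi2/10 objective increments."""
    sc = abs(theta_hat) or 1.0
    if direction > 0:
        cap = cap_factor * sc if cap_factor * sc > theta_hat else theta_hat + cap_factor * sc
    else:
        cap = theta_hat - cap_factor * sc if allow_negative else lo_cap_frac * theta_hat
    target_inc = dchi2 / 10.0
    stop = psi_min + dchi2 * overshoot
    step = step_frac * sc
    grid, psis = [], []
    t_prev, p_prev = theta_hat, psi_min
    for _ in range(max_pts):
        t_i = t_prev + direction * step
        capped = (t_i >= cap) if direction > 0 else (t_i <= cap)
        if capped:
            t_i = cap
        p_i = psi_fn(t_i)
        if not np.isfinite(p_i):
            break
        grid.append(t_i)
        psis.append(p_i)
        if p_i >= stop:
            break
        if capped:
            break
        inc = p_i - p_prev
        if inc > 1.5 * target_inc:
            step *= 0.5
        elif inc < 0.5 * target_inc:
            step *= 2.0
        t_prev, p_prev = t_i, p_i
    return np.array(grid), np.array(psis)


def walk_profile(psi_fn: Callable[[float], float], theta_hat: float,
                 psi_min: float, spec: ThresholdSpec = DEFAULT_THRESHOLD, *,
                 parameter_index: int = 0, allow_negative: bool = False,
                 overshoot: float = 1.2, **walk) -> ProfileCurve:
    """Profile an arbitrary scalar objective around its minimiser.

    ``psi_fn(theta_i)`` must return the profiled objective (already minimised
    over any nuisance parameters).  The walk proceeds outward in both
    directions with adaptive steps until the objective exceeds
    ``psi_min + overshoot * delta_chi2`` or a range cap is hit.
    """
    opts = {**DEFAULT_WALK, **walk}
    dchi2 = spec.delta_chi2
    g_dn, p_dn = _walk_direction(psi_fn, theta_hat, psi_min, dchi2, -1.0,
                                 allow_negative=allow_negative,
                                 overshoot=overshoot, **opts)
    g_up, p_up = _walk_direction(psi_fn, theta_hat, psi_min, dchi2, +1.0,
                                 allow_negative=allow_negative,
                                 overshoot=overshoot, **opts)
    grid = np.concatenate([g_dn[::-1], [theta_hat], g_up])
    psis = np.concatenate([p_dn[::-1], [psi_min], p_up])
    return ProfileCurve(parameter_index=parameter_index, theta_hat=theta_hat,
                        psi_min=psi_min, grid=grid, psi_profile=psis)


def confidence_interval(profile: ProfileCurve, psi_min: float | None = None,
                        spec: ThresholdSpec = DEFAULT_THRESHOLD
                        ) -> ConfidenceInterval:
    """Threshold crossings of a profile curve by linear interpolation.

    A direction with no crossing before the end of the walked range yields a
    non-finite flag (reported as +-inf).  The lower bound is additionally
    flagged infeasible when negative.
    """
    psi_min = profile.psi_min if psi_min is None else psi_min
    target = psi_min + spec.delta_chi2
    grid, psis = profile.grid, profile.psi_profile
    ih = int(np.argmin(np.abs(grid - profile.theta_hat)))

    def cross(idx_range):
        prev_t, prev_p = grid[ih], psis[ih]
        for i in idx_range:
            t_i, p_i = grid[i], psis[i]
            if prev_p < target <= p_i:
                f = (target - prev_p) / (p_i - prev_p)
                return prev_t + f * (t_i - prev_t)
            prev_t, prev_p = t_i, p_i
        return None

    lo = cross(range(ih - 1, -1, -1))
    hi = cross(range(ih + 1, len(grid)))
    return ConfidenceInterval(
        lower=-math.inf if lo is None else lo,
        upper=math.inf if hi is None else hi,
        lower_finite=lo is not None,
        upper_finite=hi is not None,
        lower_feasible=(lo is None) or (lo >= 0.0),
    )


def plb_crit(intervals: Sequence[ConfidenceInterval],
             theta_hat: np.ndarray) -> float:
    """Root-sum-square of normalised interval half-widths; +inf if any
    interval is non-finite."""
    theta_hat = np.asarray(theta_hat, dtype=float)
    if len(intervals) != theta_hat.size:
        raise ValueError("one interval per free parameter required")
    if np.any(theta_hat == 0):
        raise ValueError("normalisation undefined for theta_hat_i = 0")
    s = 0.0
    for ci, th in zip(intervals, theta_hat):
        if not ci.finite:
            return math.inf
        s += ((ci.upper - ci.lower) / (2.0 * th)) ** 2
    return math.sqrt(s)


def _sigma_array(scen: ParameterScenario, n: int,
                 sigma: float | np.ndarray | None) -> np.ndarray:
    if sigma is None:
        return np.full(n, default_sigma(scen))
    sigma = np.asarray(sigma, dtype=float)
    if sigma.ndim == 0:
        return np.full(n, float(sigma))
    return np.ascontiguousarray(sigma)


def profile_parameter(i: int, data: Dataset, scen: ParameterScenario,
                      fit_result: FitResult,
                      spec: ThresholdSpec = DEFAULT_THRESHOLD, *,
                      config: SimulationConfig = DEFAULT_SIM,
                      **walk) -> ProfileCurve:
    """Profile free parameter ``i`` (index into the free vector) of the model.

    Generic path: nuisance refits are warm-started compiled LM fits at each
    grid value.  ``fit_result`` supplies the best estimate and psi_min.
    """
    free_idx = scen.free_idx
    pi = int(free_idx[i])
    nuis_mask = [bool(m) and j != pi for j, m in enumerate(scen.free_mask)]
    warm = {"theta": fit_result.theta_full.copy()}

    def psi_fn(theta_i: float) -> float:
        th = warm["theta"].copy()
        th[pi] = theta_i
        sub = ParameterScenario(k=th[0], u_n=th[1], v=th[2], beta=th[3],
                                free_mask=tuple(nuis_mask)) \
            if any(nuis_mask) else None
        if sub is None:
            from .estimation import wssr as _wssr
            full_free = np.array([theta_i])
            one = ParameterScenario(k=th[0], u_n=th[1], v=th[2], beta=th[3],
                                    free_mask=tuple(j == pi for j in range(4)))
            return _wssr(full_free, data, one, config)
        try:
            res = fit_fast(data, sub, config=config)
        except ValueError:
            return math.inf
        warm["theta"] = res.theta_full.copy()
        return res.psi_hat

    curve = walk_profile(psi_fn, float(fit_result.theta_full[pi]),
                         float(fit_result.psi_hat), spec,
                         parameter_index=pi, allow_negative=(pi == 3), **walk)
    return curve


@dataclass
class ScreenReport:
    """Per-parameter identifiability screen for one scenario and schedule."""

    scenario_label: str
    schedule: np.ndarray
    parameter_names: tuple[str, ...]
    intervals: list[ConfidenceInterval]
    theta_hat: np.ndarray

    @property
    def passed(self) -> bool:
        return all(ci.finite and ci.lower_feasible for ci in self.intervals)

    @property
    def metric(self) -> float:
        return plb_crit(self.intervals, self.theta_hat)

    def to_json(self, path: str | Path | None = None) -> dict:
        doc = {
            "scenario": self.scenario_label,
            "schedule": list(map(float, self.schedule)),
            "passed": self.passed,
            "plb_crit": self.metric if math.isfinite(self.metric) else None,
            "parameters": {
                name: {
                    "theta_hat": float(th),
                    "lower": ci.lower if ci.lower_finite else None,
                    "upper": ci.upper if ci.upper_finite else None,
                    "lower_finite": ci.lower_finite,
                    "upper_finite": ci.upper_finite,
                    "lower_feasible": ci.lower_feasible,
                }
                for name, ci, th in zip(self.parameter_names, self.intervals,
                                        self.theta_hat)
            },
        }
        if path is not None:
            Path(path).write_text(json.dumps(doc, indent=2))
        return doc


def _kernel_bounds(scen: ParameterScenario, times: np.ndarray,
                   sig: np.ndarray, spec: ThresholdSpec,
                   config: SimulationConfig, walk: dict):
    """Per-free-parameter confidence bounds on noise-free data (fast path)."""
    from .model import observe, simulate

    theta = scen.theta
    free_idx = scen.free_idx
    meas = observe(simulate(scen, config), times)
    dchi2 = spec.delta_chi2
    out = []
    max_pts = int(walk["max_pts"])
    grid = np.empty(max_pts + 45)
    psis = np.empty(max_pts + 45)
    for a, pi in enumerate(free_idx):
        nuis = np.array([q for q in free_idx if q != pi], dtype=np.int64)
        nsc = np.where(np.abs(theta[nuis]) > 0, np.abs(theta[nuis]), 1.0)
        nlb = np.where(nuis == 3, 0.0, 1e-8).astype(float)
        res = {}
        for direction in (-1.0, 1.0):
            b, fin, npts = _kernels.profile_bound(
                theta, int(pi), nuis, nsc, nlb, times, meas, sig,
                config.dt, config.n_steps, config.bolus_time,
                config.bolus_off, config.bolus_magnitude,
                0.0, dchi2, direction, walk["step_frac"],
                walk["cap_factor"], walk["lo_cap_frac"],
                bool(pi == 3), max_pts, grid, psis)
            res[direction] = (b, bool(fin))
        lo, lo_fin = res[-1.0]
        hi, hi_fin = res[1.0]
        out.append(ConfidenceInterval(
            lower=lo if lo_fin else -math.inf,
            upper=hi if hi_fin else math.inf,
            lower_finite=lo_fin, upper_finite=hi_fin,
            lower_feasible=(not lo_fin) or (lo >= 0.0)))
    return out


def identifiability_screen(scen: ParameterScenario, schedule: np.ndarray, *,
                           sigma: float | np.ndarray | None = None,
                           spec: ThresholdSpec = DEFAULT_THRESHOLD,
                           config: SimulationConfig = DEFAULT_SIM,
                           **walk) -> ScreenReport:
    """Pre-optimisation identifiability screen on noise-free data.

    Profiles every free parameter of the scenario at the given schedule and
    reports finite/feasible flags; ``passed`` requires all intervals finite
    and the lower bounds physically feasible (>= 0).
    """
    opts = {**DEFAULT_WALK, **walk}
    times = np.ascontiguousarray(schedule, dtype=float)
    sig = _sigma_array(scen, times.size, sigma)
    intervals = _kernel_bounds(scen, times, sig, spec, config, opts)
    return ScreenReport(scenario_label=scen.label or "custom",
                        schedule=times,
                        parameter_names=scen.free_names,
                        intervals=intervals,
                        theta_hat=scen.free_theta)


def plb_crit_noise_free(scen: ParameterScenario, schedule: np.ndarray, *,
                        sigma: float | np.ndarray | None = None,
                        spec: ThresholdSpec = DEFAULT_THRESHOLD,
                        config: SimulationConfig = DEFAULT_SIM,
                        **walk) -> float:
    """Deterministic PLB_crit of a schedule for one scenario (fast path)."""
    opts = {**DEFAULT_WALK, **walk}
    times = np.ascontiguousarray(schedule, dtype=float)
    sig = _sigma_array(scen, times.size, sigma)
    return float(_kernels.plb_noise_free(
        scen.theta, scen.free_idx, times, sig,
        config.dt, config.n_steps, config.bolus_time, config.bolus_off,
        config.bolus_magnitude, spec.delta_chi2,
        opts["step_frac"], opts["cap_factor"], opts["lo_cap_frac"],
        int(opts["max_pts"])))
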