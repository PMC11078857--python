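"""Weighted least-squares parameter identification and noise generation.

The objective is the weighted sum of squared residuals

    psi(theta) = sum_i ((C(theta, t_i) - C_M,i) / sigma_M,i)^2

which serves as the negative log-likelihood surrogate under additive
zero-mean Gaussian measurement noise.  Fitting uses a bounded trust-region
least-squares solver with step and optimality tolerances of 1e-7 and an open
lower bound of zero on every free parameter.

The measurement-noise level is a configuration scalar: by default the
standard deviation is a constant 5% of the scenario's pre-bolus equilibrium
concentration, but a proportional-to-signal alternative is available.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import _kernels
from .model import DEFAULT_SIM, ParameterScenario, SimulationConfig

log = logging.getLogger(__name__)

#: default noise level as a fraction of the equilibrium concentration
DEFAULT_NOISE_FRACTION = 0.05


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise magnitude.

    ``kind`` is "absolute" (sigma_i = level for all i) or "proportional"
    (sigma_i = level * C(theta, t_i)).  ``level=None`` with kind "absolute"
    resolves to 5% of the generating scenario's equilibrium concentration.
    """

    kind: str = "absolute"
    level: float | None = None

    def __post_init__(self):
        if self.kind not in ("absolute", "proportional"):
            raise ValueError("noise kind must be 'absolute' or 'proportional'")
        if self.level is not None and self.level <= 0:
            raise ValueError("noise level must be positive")

    def sigma_for(self, scen: ParameterScenario,
                  model_values: np.ndarray) -> np.ndarray:
        from .model import steady_state

        if self.kind == "proportional":
            level = DEFAULT_NOISE_FRACTION if self.level is None else self.level
            return np.maximum(level * model_values, 1e-300)
        level = (DEFAULT_NOISE_FRACTION * steady_state(scen)
                 if self.level is None else self.level)
        return np.full(model_values.shape, level)


def default_sigma(scen: ParameterScenario) -> float:
    """Default absolute noise s.d.: 5% of the scenario's equilibrium."""
    from .model import steady_state

    return DEFAULT_NOISE_FRACTION * steady_state(scen)


@dataclass(frozen=True)
class Dataset:
    """Measurements C_M,i with per-point noise s.d. at schedule times t_i."""

    times: np.ndarray
    measurements: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        t = np.ascontiguousarray(self.times, dtype=float)
        m = np.ascontiguousarray(self.measurements, dtype=float)
        s = np.ascontiguousarray(self.sigma, dtype=float)
        if not (t.shape == m.shape == s.shape) or t.ndim != 1:
            raise ValueError("times, measurements and sigma must be equal-length 1-d")
        if np.any(s <= 0):
            raise ValueError("sigma must be strictly positive")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "measurements", m)
        object.__setattr__(self, "sigma", s)

    @property
    def n_s(self) -> int:
        return self.times.size

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time_min": self.times,
                      "measurement": self.measurements,
                      "sigma": self.sigma}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Dataset":
        df = pd.read_csv(path)
        return cls(df["time_min"].to_numpy(),
                   df["measurement"].to_numpy(),
                   df["sigma"].to_numpy())


@dataclass(frozen=True)
class FitResult:
    """Outcome of a least-squares identification."""

    theta_hat: np.ndarray        # free-parameter values
    theta_full: np.ndarray       # full 4-vector with fixed entries filled in
    psi_hat: float
    converged: bool
    n_evaluations: int = 0
    message: str = ""

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "theta_hat": list(map(float, self.theta_hat)),
            "theta_full": list(map(float, self.theta_full)),
            "psi_hat": float(self.psi_hat),
            "converged": bool(self.converged),
            "n_evaluations": int(self.n_evaluations),
            "message": self.message,
        }, indent=2))


def _full_theta(scen: ParameterScenario, theta_free: np.ndarray) -> np.ndarray:
    th = scen.theta
    th[scen.free_idx] = theta_free
    return th


def wssr(theta_free: np.ndarray, data: Dataset, scen: ParameterScenario,
         config: SimulationConfig = DEFAULT_SIM) -> float:
    """psi(theta) for the free parameters, fixed entries from the scenario.

    Returns +inf (with a warning) when the candidate admits no physical
    equilibrium, so population evaluation never aborts.
    """
    th = _full_theta(scen, np.asarray(theta_free, dtype=float))
    psi = _kernels.wssr(th, config.dt, config.n_steps, config.bolus_time,
                        config.bolus_off, config.bolus_magnitude,
                        data.times, data.measurements, data.sigma)
    if not np.isfinite(psi):
        log.warning("wssr: no physical equilibrium at theta=%s", th)
    return psi


def fit(data: Dataset, scen: ParameterScenario,
        theta_init: np.ndarray | None = None, *,
        config: SimulationConfig = DEFAULT_SIM,
        xtol: float = 1e-7, gtol: float = 1e-7,
        bound_cap: float = 1e4) -> FitResult:
    """Trust-region least squares over the scenario's free parameters.

    ``theta_init`` defaults to the scenario's own values (the natural warm
    start when evaluating candidate designs at nominal parameters).  Lower
    bounds are open at zero; an upper cap of ``bound_cap`` times the start
    stops runaway steps on flat objectives.
    """
    free_idx = scen.free_idx
    x0 = (scen.free_theta if theta_init is None
          else np.asarray(theta_init, dtype=float).copy())
    if np.any(x0 < 0) or np.any((x0 <= 0) & (free_idx != 3)):
        raise ValueError("initial free parameters must be positive (beta >= 0)")
    scale = np.where(np.abs(x0) > 0, np.abs(x0), 1.0)
    lb = np.where(free_idx == 3, 0.0, 1e-8 * scale)
    ub = bound_cap * scale
    conc = np.empty(config.n_steps + 1)
    r = np.empty(data.n_s)

    def residuals(x):
        th = _full_theta(scen, x)
        ok = _kernels.weighted_residuals(
            th, config.dt, config.n_steps, config.bolus_time,
            config.bolus_off, config.bolus_magnitude,
            data.times, data.measurements, data.sigma, conc, r)
        if not ok:
            return np.full(data.n_s, 1e8)
        return r.copy()

    res = least_squares(residuals, x0, bounds=(lb, ub), method="trf",
                        x_scale=scale, xtol=xtol, gtol=gtol, ftol=1e-12)
    theta_hat = res.x
    return FitResult(theta_hat=theta_hat,
                     theta_full=_full_theta(scen, theta_hat),
                     psi_hat=2.0 * res.cost,
                     converged=bool(res.status > 0),
                     n_evaluations=int(res.nfev),
                     message=str(res.message))


def fit_fast(data: Dataset, scen: ParameterScenario,
             theta_init: np.ndarray | None = None, *,
             config: SimulationConfig = DEFAULT_SIM) -> FitResult:
    """Same objective as :func:`fit` via the compiled Levenberg-Marquardt.

    Used on hot paths (Monte-Carlo ensembles, profiling); cross-checked
    against :func:`fit` in the test suite.
    """
    free_idx = scen.free_idx
    x0 = (scen.free_theta if theta_init is None
          else np.asarray(theta_init, dtype=float).copy())
    scales = np.where(np.abs(x0) > 0, np.abs(x0), 1.0)
    lbx = np.where(free_idx == 3, 0.0, 1e-8)
    th0 = _full_theta(scen, x0)
    thf, psi, status = _kernels.lm_fit(
        th0, free_idx, scales, lbx.astype(float),
        data.times, data.measurements, data.sigma,
        config.dt, config.n_steps, config.bolus_time,
        config.bolus_off, config.bolus_magnitude, 1e-7, 1e-7, 120)
    return FitResult(theta_hat=thf[free_idx], theta_full=thf, psi_hat=psi,
                     converged=status == _kernels.LM_CONVERGED,
                     message=f"lm status {status}")


def generate_noisy_data(scen: ParameterScenario, schedule: np.ndarray,
                        noise: NoiseSpec | None = None, seed=0, *,
                        config: SimulationConfig = DEFAULT_SIM) -> Dataset:
    """Synthetic measurements: model curve plus N(0, sigma_i^2) noise.

    Deterministic for a fixed ``seed`` (anything accepted by
    ``numpy.random.default_rng``).
    """
    from .model import observe, simulate

    noise = noise or NoiseSpec()
    t = np.ascontiguousarray(schedule, dtype=float)
    clean = observe(simulate(scen, config), t)
    sigma = noise.sigma_for(scen, clean)
    rng = np.random.default_rng(seed)
    meas = clean + rng.normal(0.0, 1.0, t.size) * sigma
    return Dataset(times=t, measurements=meas, sigma=sigma)
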