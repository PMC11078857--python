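"""Monte-Carlo quantile metrics and the PLB-vs-QB correlation study.

The Q-criterion measures parameter uncertainty as the summed squared widths
of the 10th-90th quantile band of refitted parameters over noisy replicate
datasets,

    Q_crit = sum_i (Q_{theta_i, 0.9} - Q_{theta_i, 0.1})^2 .

Its normalised counterpart QB_crit uses the 16th/84th quantiles (capturing
0.68 of the ensemble, matching the profile-likelihood threshold) inside the
same root-sum-square form as PLB_crit:

    QB_crit = sqrt( sum_i ((Q_{i,0.84} - Q_{i,0.16}) / (2 theta_hat_i))^2 ).

Quantiles use linear interpolation between order statistics throughout.
The correlation study reproduces the first-generation comparison between the
two metrics: random schedule populations are scored with both, and the
per-setting Pearson (and Spearman) correlations are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import _kernels
from .estimation import NoiseSpec, default_sigma
from .ga import random_schedule, _org_rng
from .model import DEFAULT_SIM, ParameterScenario, SimulationConfig, \
    observe, scenario, simulate
from .profiles import plb_crit_noise_free

MIN_REPLICATES = 20


@dataclass
class MCEnsemble:
    """Refitted free-parameter ensemble over noisy replicate datasets."""

    theta_fits: np.ndarray      # (n_reps, n_free)
    ok: np.ndarray              # per-replicate success flags
    theta_true: np.ndarray      # free-parameter truth used for generation
    seed: int

    @property
    def n_reps(self) -> int:
        return self.theta_fits.shape[0]

    @property
    def n_failed(self) -> int:
        return int(np.sum(~self.ok))

    @property
    def good_fits(self) -> np.ndarray:
        return self.theta_fits[self.ok]

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.theta_fits)
        df["ok"] = self.ok
        df.to_csv(path, index=False)


def mc_ensemble(scen: ParameterScenario, schedule: np.ndarray, *,
                n_reps: int = 500, noise: NoiseSpec | None = None,
                seed: int = 0, start_jitter: float = 0.1,
                config: SimulationConfig = DEFAULT_SIM) -> MCEnsemble:
    """Generate-and-refit ensemble, fully reproducible for a fixed seed.

    Each replicate receives fresh Gaussian measurement noise and is refitted
    from the truth perturbed by +-``start_jitter`` uniform jitter (so fit
    failures are rare but the start is not exactly the optimum).
    """
    noise = noise or NoiseSpec()
    times = np.ascontiguousarray(schedule, dtype=float)
    clean = observe(simulate(scen, config), times)
    sig = noise.sigma_for(scen, clean)
    free_idx = scen.free_idx
    nf = free_idx.size

    rng = np.random.default_rng([seed, 101])
    meas = clean[None, :] + rng.normal(size=(n_reps, times.size)) * sig[None, :]
    starts = scen.free_theta[None, :] * (
        1.0 + rng.uniform(-start_jitter, start_jitter, size=(n_reps, nf)))

    out_theta = np.empty((n_reps, nf))
    out_psi = np.empty(n_reps)
    out_status = np.empty(n_reps, dtype=np.int64)
    _kernels.mc_fit_batch(scen.theta, free_idx, starts, times,
                          np.ascontiguousarray(meas), sig,
                          config.dt, config.n_steps, config.bolus_time,
                          config.bolus_off, config.bolus_magnitude,
                          out_theta, out_psi, out_status)
    ok = (out_status != _kernels.LM_FAILED) & np.isfinite(out_psi) \
        & np.all(np.isfinite(out_theta), axis=1)
    if not ok.any():
        raise RuntimeError("all Monte-Carlo replicates failed to fit")
    return MCEnsemble(theta_fits=out_theta, ok=ok,
                      theta_true=scen.free_theta, seed=seed)


def _quantile_band(ensemble: MCEnsemble, q_lo: float, q_hi: float):
    good = ensemble.good_fits
    if good.shape[0] < MIN_REPLICATES:
        raise ValueError(
            f"need at least {MIN_REPLICATES} successful replicates, "
            f"have {good.shape[0]}")
    lo = np.quantile(good, q_lo, axis=0, method="linear")
    hi = np.quantile(good, q_hi, axis=0, method="linear")
    return lo, hi


def q_crit(ensemble: MCEnsemble) -> float:
    """Summed squared 10-90 quantile widths (unnormalised)."""
    lo, hi = _quantile_band(ensemble, 0.1, 0.9)
    return float(np.sum((hi - lo) ** 2))


def qb_crit(ensemble: MCEnsemble,
            theta_hat: np.ndarray | None = None) -> float:
    """Root-sum-square of normalised 16-84 quantile half-widths."""
    lo, hi = _quantile_band(ensemble, 0.16, 0.84)
    th = ensemble.theta_true if theta_hat is None else np.asarray(theta_hat)
    if np.any(th == 0):
        raise ValueError("normalisation undefined for theta_hat_i = 0")
    return float(np.sqrt(np.sum(((hi - lo) / (2.0 * th)) ** 2)))


def correlation_study(case: int, scenario_numbers=(1, 2, 3),
                      ns_values=(5, 10, 15), *, n_org: int = 50,
                      n_reps: int = 200, seed: int = 0,
                      noise: NoiseSpec | None = None,
                      config: SimulationConfig = DEFAULT_SIM) -> pd.DataFrame:
    """Per-setting correlation between PLB_crit and QB_crit.

    For each (scenario, n_s): draw ``n_org`` random valid schedules (a
    first-generation population), score each with the deterministic
    profile-likelihood metric and with the Monte-Carlo quantile metric, and
    report Pearson and Spearman correlations over schedules.  Non-finite
    metric values are excluded pairwise (count reported); settings with no
    metric variance yield NaN correlations.
    """
    rows = []
    for sn in scenario_numbers:
        scen = scenario(case, sn)
        for ns in ns_values:
            sub_seed = int(np.random.SeedSequence(
                [seed, case, sn, ns]).generate_state(1)[0] % 2**31)
            pop = [random_schedule(ns, _org_rng(sub_seed, 0, k))
                   for k in range(n_org)]
            plb = np.array([plb_crit_noise_free(scen, t, config=config)
                            for t in pop])
            qb = np.array([
                qb_crit(mc_ensemble(scen, t, n_reps=n_reps, noise=noise,
                                    seed=sub_seed + 1 + k, config=config))
                for k, t in enumerate(pop)])
            mask = np.isfinite(plb) & np.isfinite(qb)
            n_valid = int(mask.sum())
            if n_valid >= 3 and np.ptp(plb[mask]) > 0 and np.ptp(qb[mask]) > 0:
                r_p = float(stats.pearsonr(plb[mask], qb[mask]).statistic)
                r_s = float(stats.spearmanr(plb[mask], qb[mask]).statistic)
            else:
                r_p = r_s = float("nan")
            rows.append(dict(case=case, scenario=sn, n_s=ns,
                             r_pearson=r_p, r_spearman=r_s,
                             n_valid=n_valid))
    return pd.DataFrame(rows)
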