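"""Compiled numerical core.

Hot-path routines shared by the public modules: forward-Euler simulation of
the one-compartment saturable model, weighted-residual evaluation, a compact
Levenberg-Marquardt refitter, profile-likelihood bound location, and batched
Monte-Carlo refits.  Everything here is restricted to plain floats and
contiguous float64 arrays so numba can compile it; the public modules wrap
these in validated, documented APIs.

Parameter vectors are always the full 4-vector ``(k, u_n, v, beta)``; which
entries are free is communicated through integer index arrays.  Free
parameters are optimised in units of a per-parameter scale (typically the
starting value) so the normal equations stay well conditioned across the five
orders of magnitude separating ``k`` and ``v``.
"""

import numpy as np
from numba import njit

# LM return status codes
LM_FAILED = 0       # simulation infeasible at the starting point
LM_CONVERGED = 1
LM_MAXITER = 2


@njit(cache=True)
def steady_state(k, u_n, v, beta):
    """Equilibrium concentration u_n/(k*v - beta*u_n); -1.0 if none exists."""
    den = k * v - beta * u_n
    if den <= 0.0:
        return -1.0
    return u_n / den


@njit(cache=True)
def simulate(k, u_n, v, beta, dt, n_steps, b_on, b_off, b_rate, out):
    """Fixed-step Euler trajectory from equilibrium; returns False if infeasible.

    ``out`` must have length n_steps + 1.  The bolus is a constant input rate
    ``b_rate`` active while b_on <= t < b_off.  The saturable denominator is
    clamped at 1e-9 so profile walks into beta < -1/C territory stay finite.
    """
    c = steady_state(k, u_n, v, beta)
    if c <= 0.0:
        return False
    out[0] = c
    for i in range(n_steps):
        t = i * dt
        ux = b_rate if (t >= b_on) and (t < b_off) else 0.0
        den = 1.0 + beta * c
        if den < 1e-9:
            den = 1e-9
        c = c + dt * (-k * c / den + (u_n + ux) / v)
        out[i + 1] = c
    return True


@njit(cache=True)
def interp_observe(conc, dt, times, out):
    """Linear interpolation of a grid trajectory at arbitrary times in range."""
    n = conc.shape[0]
    for j in range(times.shape[0]):
        x = times[j] / dt
        i0 = int(np.floor(x))
        if i0 < 0:
            i0 = 0
        if i0 >= n - 1:
            out[j] = conc[n - 1]
        else:
            f = x - i0
            out[j] = conc[i0] * (1.0 - f) + conc[i0 + 1] * f


@njit(cache=True)
def _ipow(base, n):
    """base**n for integer n >= 0 by binary exponentiation."""
    r = 1.0
    b = base
    m = n
    while m > 0:
        if m & 1:
            r *= b
        b *= b
        m >>= 1
    return r


@njit(cache=True)
def _node_linear(n, i_on, i_off, c0, c_end, decay, bolus_vals):
    """Euler node value for the beta = 0 (linear) recurrence.

    Before the bolus the scheme sits exactly at its fixed point c0; during
    the bolus window the few node values are tabulated in ``bolus_vals``;
    afterwards the deviation from c0 contracts geometrically by
    (1 - k*dt) per step.  This is an algebraic identity of the same
    forward-Euler recurrence the simulator iterates.
    """
    if n <= i_on:
        return c0
    if n <= i_off:
        return bolus_vals[n - i_on]
    return c0 + (c_end - c0) * _ipow(decay, n - i_off)


@njit(cache=True)
def weighted_residuals(theta, dt, n_steps, b_on, b_off, b_rate,
                       times, meas, sig, conc_buf, out):
    """(C(theta, t_i) - C_M,i)/sigma_i into ``out``; False if sim infeasible.

    For beta = 0 the linear Euler recurrence is evaluated in closed form at
    the requested nodes only (hot path); otherwise the full trajectory is
    integrated.
    """
    k = theta[0]
    u_n = theta[1]
    v = theta[2]
    beta = theta[3]
    if beta == 0.0:
        if k <= 0.0 or u_n <= 0.0 or v <= 0.0:
            return False
        c0 = u_n / (k * v)
        decay = 1.0 - k * dt
        i_on = int(round(b_on / dt))
        i_off = int(round(b_off / dt))
        c = c0
        conc_buf[0] = c
        for m in range(i_off - i_on):
            c = c * decay + dt * (u_n + b_rate) / v
            conc_buf[m + 1] = c
        c_end = c
        for j in range(times.shape[0]):
            x = times[j] / dt
            n0 = int(np.floor(x))
            if n0 < 0:
                n0 = 0
            if n0 > n_steps:
                n0 = n_steps
            f = x - n0
            cv = _node_linear(n0, i_on, i_off, c0, c_end, decay, conc_buf)
            if f > 0.0 and n0 < n_steps:
                cb = _node_linear(n0 + 1, i_on, i_off, c0, c_end, decay,
                                  conc_buf)
                cv = cv * (1.0 - f) + cb * f
            out[j] = (cv - meas[j]) / sig[j]
        return True

    ok = simulate(k, u_n, v, beta, dt, n_steps, b_on, b_off, b_rate, conc_buf)
    if not ok:
        return False
    n = conc_buf.shape[0]
    for j in range(times.shape[0]):
        x = times[j] / dt
        i0 = int(np.floor(x))
        if i0 < 0:
            i0 = 0
        if i0 >= n - 1:
            c = conc_buf[n - 1]
        else:
            f = x - i0
            c = conc_buf[i0] * (1.0 - f) + conc_buf[i0 + 1] * f
        out[j] = (c - meas[j]) / sig[j]
    return True


@njit(cache=True)
def wssr(theta, dt, n_steps, b_on, b_off, b_rate, times, meas, sig):
    """Weighted sum of squared residuals; +inf when no equilibrium exists."""
    conc = np.empty(n_steps + 1)
    r = np.empty(times.shape[0])
    ok = weighted_residuals(theta, dt, n_steps, b_on, b_off, b_rate,
                            times, meas, sig, conc, r)
    if not ok:
        return np.inf
    s = 0.0
    for j in range(r.shape[0]):
        s += r[j] * r[j]
    return s


@njit(cache=True)
def lm_fit(theta_start, free_idx, scales, lbx,
           times, meas, sig, dt, n_steps, b_on, b_off, b_rate,
           xtol, gtol, max_iter):
    """Levenberg-Marquardt minimisation of the weighted SSR over ``free_idx``.

    Works in scaled coordinates x = theta/scale with elementwise lower bounds
    ``lbx`` (scaled units) enforced by projection.  Finite-difference
    Jacobian.  Returns (theta_full, psi, status).
    """
    p = free_idx.shape[0]
    n = times.shape[0]
    th = theta_start.copy()
    conc = np.empty(n_steps + 1)
    r = np.empty(n)
    r_h = np.empty(n)
    r_new = np.empty(n)

    ok = weighted_residuals(th, dt, n_steps, b_on, b_off, b_rate,
                            times, meas, sig, conc, r)
    if not ok:
        return th, np.inf, LM_FAILED
    psi = 0.0
    for j in range(n):
        psi += r[j] * r[j]
    if p == 0:
        return th, psi, LM_CONVERGED

    x = np.empty(p)
    for a in range(p):
        x[a] = th[free_idx[a]] / scales[a]

    lam = 1e-3
    J = np.empty((n, p))
    g = np.empty(p)
    A = np.empty((p, p))
    M = np.empty((p, p))
    x_new = np.empty(p)
    status = LM_MAXITER

    for _it in range(max_iter):
        # forward-difference Jacobian in scaled coordinates
        for a in range(p):
            xa = x[a]
            h = 1e-6 * (abs(xa) if abs(xa) > 1e-2 else 1e-2)
            x[a] = xa + h
            th[free_idx[a]] = x[a] * scales[a]
            okh = weighted_residuals(th, dt, n_steps, b_on, b_off, b_rate,
                                     times, meas, sig, conc, r_h)
            if okh:
                for j in range(n):
                    J[j, a] = (r_h[j] - r[j]) / h
            else:
                # forward step infeasible: use a backward difference
                x[a] = xa - h
                th[free_idx[a]] = x[a] * scales[a]
                okh = weighted_residuals(th, dt, n_steps, b_on, b_off, b_rate,
                                         times, meas, sig, conc, r_h)
                if okh:
                    for j in range(n):
                        J[j, a] = (r[j] - r_h[j]) / h
                else:
                    for j in range(n):
                        J[j, a] = 0.0
            x[a] = xa
            th[free_idx[a]] = xa * scales[a]

        gmax = 0.0
        for a in range(p):
            s = 0.0
            for j in range(n):
                s += J[j, a] * r[j]
            g[a] = s
            if abs(s) > gmax:
                gmax = abs(s)
        if gmax < gtol:
            status = LM_CONVERGED
            break
        for a in range(p):
            for b in range(p):
                s = 0.0
                for j in range(n):
                    s += J[j, a] * J[j, b]
                A[a, b] = s

        accepted = False
        for _try in range(15):
            for a in range(p):
                for b in range(p):
                    M[a, b] = A[a, b]
            for a in range(p):
                d = A[a, a]
                if d <= 0.0:
                    d = 1.0
                M[a, a] = A[a, a] + lam * d + 1e-300
            dx = np.linalg.solve(M, -g)
            snorm = 0.0
            xnorm = 0.0
            for a in range(p):
                xn = x[a] + dx[a]
                if xn < lbx[a]:
                    xn = lbx[a]
                x_new[a] = xn
                snorm += (xn - x[a]) ** 2
                xnorm += x[a] * x[a]
                th[free_idx[a]] = xn * scales[a]
            rel = np.sqrt(snorm) / (np.sqrt(xnorm) + 1e-30)
            if rel < xtol:
                # proposed step already below the step tolerance
                status = LM_CONVERGED
                break
            ok2 = weighted_residuals(th, dt, n_steps, b_on, b_off, b_rate,
                                     times, meas, sig, conc, r_new)
            psi_new = np.inf
            if ok2:
                psi_new = 0.0
                for j in range(n):
                    psi_new += r_new[j] * r_new[j]
            if psi_new < psi:
                gain = psi - psi_new
                for a in range(p):
                    x[a] = x_new[a]
                for j in range(n):
                    r[j] = r_new[j]
                psi = psi_new
                lam *= 0.33
                if lam < 1e-12:
                    lam = 1e-12
                accepted = True
                if rel < xtol or gain <= 1e-9 * psi + 1e-14:
                    status = LM_CONVERGED
                break
            lam *= 3.0
            if lam > 1e11:
                break
        for a in range(p):
            th[free_idx[a]] = x[a] * scales[a]
        if not accepted:
            # no improving step exists at any damping: local minimum
            status = LM_CONVERGED
            break
        if status == LM_CONVERGED:
            break

    for a in range(p):
        th[free_idx[a]] = x[a] * scales[a]
    return th, psi, status


@njit(cache=True)
def profile_bound(theta_hat, prof_idx, nuis_idx, nuis_scales, nuis_lbx,
                  times, meas, sig, dt, n_steps, b_on, b_off, b_rate,
                  psi_min, dchi2, direction, step_frac, cap_factor,
                  lo_cap_frac, allow_negative, max_pts,
                  grid_out, psi_out):
    """Locate one profile-likelihood confidence bound of parameter ``prof_idx``.

    Walks outward from theta_hat[prof_idx] in ``direction`` (+1/-1) with
    adaptive steps (quadratic extrapolation of the profile toward the
    threshold), refitting the nuisance parameters ``nuis_idx`` warm-started
    from the previous grid point.  Once psi crosses psi_min + dchi2 the
    crossing is refined by regula falsi.  Evaluated (theta_i, psi) pairs are
    recorded into grid_out/psi_out.

    Returns (bound, finite, n_points).  ``finite`` is False when the walk hits
    the range cap (cap_factor*|theta_hat_i| upward; lo_cap_frac*theta_hat_i
    downward, or theta_hat_i - cap_factor*|theta_hat_i| when negative values
    are allowed) or a nuisance refit fails.
    """
    th0 = theta_hat[prof_idx]
    sc = abs(th0)
    if sc == 0.0:
        sc = 1.0
    target = psi_min + dchi2
    if direction > 0.0:
        cap = cap_factor * sc
        if cap <= th0:
            cap = th0 + cap_factor * sc
    else:
        if allow_negative:
            cap = th0 - cap_factor * sc
        else:
            cap = lo_cap_frac * th0
    step = step_frac * sc
    prev_t = th0
    prev_psi = psi_min
    th_warm = theta_hat.copy()
    npts = 0
    cap_hit = False

    for _ in range(max_pts):
        t_i = prev_t + direction * step
        if direction > 0.0:
            if t_i >= cap:
                t_i = cap
                cap_hit = True
        else:
            if t_i <= cap:
                t_i = cap
                cap_hit = True
        th_warm[prof_idx] = t_i
        th_fit, psi, stat = lm_fit(th_warm, nuis_idx, nuis_scales, nuis_lbx,
                                   times, meas, sig, dt, n_steps,
                                   b_on, b_off, b_rate, 1e-8, 1e-8, 30)
        if stat == LM_FAILED:
            return np.nan, False, npts
        th_warm = th_fit
        if npts < grid_out.shape[0]:
            grid_out[npts] = t_i
            psi_out[npts] = psi
            npts += 1

        if psi >= target:
            a_t = prev_t
            a_p = prev_psi
            b_t = t_i
            b_p = psi
            bound = t_i
            for _r in range(40):
                den = b_p - a_p
                if den <= 0.0:
                    break
                m_t = a_t + (target - a_p) / den * (b_t - a_t)
                lo_g = min(a_t, b_t)
                hi_g = max(a_t, b_t)
                if (m_t <= lo_g) or (m_t >= hi_g):
                    m_t = 0.5 * (a_t + b_t)
                th_warm[prof_idx] = m_t
                th_fit, m_p, stat = lm_fit(th_warm, nuis_idx, nuis_scales,
                                           nuis_lbx, times, meas, sig, dt,
                                           n_steps, b_on, b_off, b_rate,
                                           1e-8, 1e-8, 30)
                if stat == LM_FAILED:
                    break
                th_warm = th_fit
                if npts < grid_out.shape[0]:
                    grid_out[npts] = m_t
                    psi_out[npts] = m_p
                    npts += 1
                bound = m_t
                if abs(m_p - target) < 1e-6 * dchi2 or abs(b_t - a_t) < 1e-10 * sc:
                    break
                if m_p < target:
                    a_t = m_t
                    a_p = m_p
                else:
                    b_t = m_t
                    b_p = m_p
            return bound, True, npts

        if cap_hit:
            return np.nan, False, npts

        dpsi = psi - psi_min
        if dpsi > 0.005 * dchi2:
            # quadratic extrapolation of the profile towards the threshold
            a_est = dpsi / ((t_i - th0) * (t_i - th0))
            t_pred = th0 + direction * 1.05 * np.sqrt(dchi2 / a_est)
            remaining = direction * (t_pred - t_i)
            if remaining > step:
                if remaining > 10.0 * step:
                    step = 10.0 * step
                else:
                    step = remaining
            # profile rising slower than quadratic near here: keep the step
        else:
            step *= 2.0
        prev_t = t_i
        prev_psi = psi

    return np.nan, False, npts


@njit(cache=True)
def plb_noise_free(theta_true, free_idx, times, sig,
                   dt, n_steps, b_on, b_off, b_rate, dchi2,
                   step_frac, cap_factor, lo_cap_frac, max_pts):
    """PLB_crit of a schedule for noise-free data generated at ``theta_true``.

    The best estimate is the truth and psi_min = 0 by construction, so the
    metric is deterministic.  Returns +inf as soon as any confidence bound is
    non-finite.  Index 3 (beta) is allowed to profile below zero so physical
    infeasibility can be detected downstream.
    """
    n = times.shape[0]
    conc = np.empty(n_steps + 1)
    ok = simulate(theta_true[0], theta_true[1], theta_true[2], theta_true[3],
                  dt, n_steps, b_on, b_off, b_rate, conc)
    if not ok:
        return np.inf
    meas = np.empty(n)
    interp_observe(conc, dt, times, meas)

    nf = free_idx.shape[0]
    grid = np.empty(max_pts + 45)
    psis = np.empty(max_pts + 45)
    s = 0.0
    for a in range(nf):
        pi = free_idx[a]
        nuis = np.empty(nf - 1, dtype=np.int64)
        c = 0
        for b in range(nf):
            if b != a:
                nuis[c] = free_idx[b]
                c += 1
        nsc = np.empty(nf - 1)
        nlb = np.empty(nf - 1)
        for b in range(nf - 1):
            w = abs(theta_true[nuis[b]])
            nsc[b] = w if w > 0.0 else 1.0
            nlb[b] = 0.0 if nuis[b] == 3 else 1e-8
        allow_neg = pi == 3
        lo, lo_fin, _ = profile_bound(theta_true, pi, nuis, nsc, nlb,
                                      times, meas, sig, dt, n_steps,
                                      b_on, b_off, b_rate, 0.0, dchi2, -1.0,
                                      step_frac, cap_factor, lo_cap_frac,
                                      allow_neg, max_pts, grid, psis)
        if not lo_fin:
            return np.inf
        hi, hi_fin, _ = profile_bound(theta_true, pi, nuis, nsc, nlb,
                                      times, meas, sig, dt, n_steps,
                                      b_on, b_off, b_rate, 0.0, dchi2, 1.0,
                                      step_frac, cap_factor, lo_cap_frac,
                                      allow_neg, max_pts, grid, psis)
        if not hi_fin:
            return np.inf
        w = (hi - lo) / (2.0 * theta_true[pi])
        s += w * w
    return np.sqrt(s)


@njit(cache=True)
def mc_fit_batch(theta_true, free_idx, starts, times, meas_matrix, sig,
                 dt, n_steps, b_on, b_off, b_rate,
                 out_theta, out_psi, out_status):
    """Refit every Monte-Carlo replicate dataset; results into out_* arrays.

    ``starts`` holds per-replicate initial free-parameter values in natural
    units; ``meas_matrix`` is (n_reps, n_times).
    """
    n_reps = meas_matrix.shape[0]
    nf = free_idx.shape[0]
    scales = np.empty(nf)
    lbx = np.empty(nf)
    for a in range(nf):
        w = abs(theta_true[free_idx[a]])
        scales[a] = w if w > 0.0 else 1.0
        lbx[a] = 0.0 if free_idx[a] == 3 else 1e-8
    th0 = theta_true.copy()
    for r in range(n_reps):
        for a in range(nf):
            th0[free_idx[a]] = starts[r, a]
        thf, psi, st = lm_fit(th0, free_idx, scales, lbx, times,
                              meas_matrix[r], sig, dt, n_steps,
                              b_on, b_off, b_rate, 1e-7, 1e-7, 120)
        for a in range(nf):
            out_theta[r, a] = thf[free_idx[a]]
        out_psi[r] = psi
        out_status[r] = st
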