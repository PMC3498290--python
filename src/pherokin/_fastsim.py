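"""Numba-compiled specialization of the reactor RK4 used inside fitting loops.

Same classical RK4 update and same right-hand sides as
:func:`pherokin.reactor.rk4_integrate` (a test asserts agreement); the only
additions are a stability-limited step size and a step budget so that a
least-squares objective evaluated at extreme rate constants fails fast instead
of integrating forever.  Status codes: 0 = ok, 1 = step budget exceeded,
2 = non-finite / negative state beyond tolerance.
"""

import numpy as np
from numba import njit

#: Fraction of the stability-limited step actually taken (accuracy margin).
STABILITY_SAFETY = 0.5


@njit(cache=False)
def integrate_reactor(k_f, k_b, k_r, f_ad, e_active, s0, p0, taus, h_max, max_steps):
    """Integrate the 3-state reactor ODE, sampling (S, P) at each τ in ``taus``.

    ``taus`` must be sorted ascending (may start above 0).  Returns
    (S_samples, P_samples, status).
    """
    n_obs = taus.shape[0]
    s_out = np.empty(n_obs)
    p_out = np.empty(n_obs)
    # conservative local Jacobian scale for the RK4 stability limit
    lam = k_f * (e_active + s0) + k_b + k_r
    h_stab = STABILITY_SAFETY / lam if lam > 0 else h_max
    h_lim = min(h_max, h_stab)

    # fail fast before stepping if the budget cannot cover the span
    if taus[n_obs - 1] / h_lim > max_steps:
        return s_out, p_out, 1

    s = s0
    es = 0.0
    p = p0
    t = 0.0
    steps_used = 0
    kbr = k_b + k_r
    for i in range(n_obs):
        span = taus[i] - t
        if span > 0.0:
            n_sub = int(np.ceil(span / h_lim))
            steps_used += n_sub
            if steps_used > max_steps:
                return s_out, p_out, 1
            h = span / n_sub
            for _ in range(n_sub):
                # k1
                ef = e_active - es
                if ef < 0.0:
                    ef = 0.0
                b = k_f * ef * s
                d1s = -b + k_b * es
                d1e = b - kbr * es
                d1p = (1.0 - f_ad) * k_r * es
                # k2
                s2 = s + 0.5 * h * d1s
                e2 = es + 0.5 * h * d1e
                ef = e_active - e2
                if ef < 0.0:
                    ef = 0.0
                b = k_f * ef * s2
                d2s = -b + k_b * e2
                d2e = b - kbr * e2
                d2p = (1.0 - f_ad) * k_r * e2
                # k3
                s3 = s + 0.5 * h * d2s
                e3 = es + 0.5 * h * d2e
                ef = e_active - e3
                if ef < 0.0:
                    ef = 0.0
                b = k_f * ef * s3
                d3s = -b + k_b * e3
                d3e = b - kbr * e3
                d3p = (1.0 - f_ad) * k_r * e3
                # k4
                s4 = s + h * d3s
                e4 = es + h * d3e
                ef = e_active - e4
                if ef < 0.0:
                    ef = 0.0
                b = k_f * ef * s4
                d4s = -b + k_b * e4
                d4e = b - kbr * e4
                d4p = (1.0 - f_ad) * k_r * e4

                s = s + h / 6.0 * (d1s + 2.0 * d2s + 2.0 * d3s + d4s)
                es = es + h / 6.0 * (d1e + 2.0 * d2e + 2.0 * d3e + d4e)
                p = p + h / 6.0 * (d1p + 2.0 * d2p + 2.0 * d3p + d4p)

                if not (np.isfinite(s) and np.isfinite(es) and np.isfinite(p)):
                    return s_out, p_out, 2
                if s < -1e-9 or es < -1e-9 or p < -1e-9:
                    return s_out, p_out, 2
                if s < 0.0:
                    s = 0.0
                if es < 0.0:
                    es = 0.0
                if p < 0.0:
                    p = 0.0
            t = taus[i]
        s_out[i] = s
        p_out[i] = p
    return s_out, p_out, 0
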