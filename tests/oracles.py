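"""Independent brute-force reference implementations used as test oracles.

These deliberately avoid the package's vectorized code paths: plain Python
loops over events and sites, translating the model's defining formulas
directly.
"""

import numpy as np


def brute_force_log_likelihood(dataset, state, maskH, pbias, arena, theta):
    """Masked log-likelihood via an explicit per-event, per-site loop."""
    D = arena.distance_matrix()
    S = arena.n_sites
    total = 0.0
    sites = dataset.events["site"].to_numpy()
    for i in np.flatnonzero(maskH.H):
        logp = np.empty(S)
        for s in range(S):
            a = 0.0
            # proximity to the previous site (zero at the site itself)
            prev = state.prev_site[i]
            if prev >= 0 and s != prev:
                a += theta.gamma_prv * gauss(D[prev, s], theta.sigma_prv)
            # occupied sites
            for sp in range(S):
                if state.occupancy[i, sp]:
                    a += (
                        theta.gamma_occ
                        * gauss(D[s, sp], theta.sigma_occ)
                        * decay(state.time_since[i, sp], theta.inv_tau_occ)
                        * np.exp(-state.total_occupancy[i] * theta.inv_nu_occ)
                    )
                if state.checked_empty[i, sp]:
                    a += (
                        theta.gamma_emp
                        * gauss(D[s, sp], theta.sigma_emp)
                        * decay(state.time_since[i, sp], theta.inv_tau_emp)
                        * np.exp(
                            -state.total_checked_empty[i] * theta.inv_nu_emp
                        )
                    )
            a += theta.gamma_occr * state.recache[i, s]
            a += theta.gamma_occc * (
                state.occupancy[i, s] - state.recache[i, s]
            )
            logp[s] = np.log(pbias.p[s]) + a * np.log(10.0) if pbias.p[s] > 0 else -np.inf
        z = np.logaddexp.reduce(logp)
        total += logp[sites[i]] - z
    return total


def gauss(d, sigma):
    if sigma < 1e-6:
        return 1.0 if d == 0 else 0.0
    return np.exp(-(d**2) / (2 * sigma**2))


def decay(t, inv_tau):
    if np.isinf(t):
        return 0.0
    return np.exp(-t * inv_tau)
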