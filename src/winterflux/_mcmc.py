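"""Numba kernels for the multistate-model likelihood.

State space: indices 0-7 are the eight wintering regions, 8 is the
absorbing dead state.  Observation space: 0-7 seen in region, 8 not
observed.  The forward algorithm is conditioned on the first observed
state and marginalises all alive/dead latent paths.
"""

import numpy as np
from numba import njit

N_REGIONS = 8
S = 9  # true states: 8 regions + dead


@njit(cache=True)
def forward_loglik_one(y, f, Omega, Theta):
    """Log P(y[f+1:] | y[f]) for one history.

    y : int array of observation codes 1..9 per week (9 = not observed)
    f : index of the first observed week (y[f] in 1..8)
    """
    T = y.shape[0]
    alpha = np.zeros(S)
    alpha[y[f] - 1] = 1.0
    ll = 0.0
    for t in range(f + 1, T):
        obs = y[t] - 1
        nxt = np.zeros(S)
        for s in range(S):
            a = alpha[s]
            if a > 0.0:
                for s2 in range(S):
                    nxt[s2] += a * Omega[s, s2]
        c = 0.0
        for s2 in range(S):
            nxt[s2] *= Theta[s2, obs]
            c += nxt[s2]
        if c <= 0.0:
            return -np.inf
        ll += np.log(c)
        for s2 in range(S):
            alpha[s2] = nxt[s2] / c
    return ll


@njit(cache=True)
def forward_loglik_all(Y, first, Omega, Theta):
    """Summed forward log-likelihood over all histories (first < 0 skipped)."""
    total = 0.0
    for i in range(Y.shape[0]):
        if first[i] >= 0:
            total += forward_loglik_one(Y[i], first[i], Omega, Theta)
            if np.isinf(total):
                return -np.inf
    return total


@njit(cache=True)
def build_matrices(psi, phi, p):
    """State-transition (Omega) and observation (Theta) matrices.

    Omega[r, s] = phi_r * psi[r, s] for regions, Omega[r, 8] = 1 - phi_r,
    dead absorbing; Theta[r, r] = p_r, Theta[r, 8] = 1 - p_r, dead emits
    "not observed" with probability 1.
    """
    Omega = np.zeros((S, S))
    Theta = np.zeros((S, S))
    for r in range(N_REGIONS):
        for s in range(N_REGIONS):
            Omega[r, s] = phi[r] * psi[r, s]
        Omega[r, S - 1] = 1.0 - phi[r]
        Theta[r, r] = p[r]
        Theta[r, S - 1] = 1.0 - p[r]
    Omega[S - 1, S - 1] = 1.0
    Theta[S - 1, S - 1] = 1.0
    return Omega, Theta


@njit(cache=True)
def theta_to_matrices(theta):
    """Unpack the 72-vector of logit-scale parameters.

    Layout: 8 rows x 7 multinomial logits of moving to each other region
    relative to staying (destinations in increasing region order), then 8
    survival logits, then 8 detection logits.
    """
    psi = np.zeros((N_REGIONS, N_REGIONS))
    k = 0
    for r in range(N_REGIONS):
        denom = 1.0
        j = 0
        for s in range(N_REGIONS):
            if s != r:
                e = np.exp(theta[k + j])
                psi[r, s] = e
                denom += e
                j += 1
        for s in range(N_REGIONS):
            if s == r:
                psi[r, s] = 1.0 / denom
            else:
                psi[r, s] /= denom
        k += N_REGIONS - 1
    phi = 1.0 / (1.0 + np.exp(-theta[56:64]))
    p = 1.0 / (1.0 + np.exp(-theta[64:72]))
    return psi, phi, p


@njit(cache=True)
def log_posterior(theta, Y, first, psi_prior_sd, probe_uniform):
    """Unnormalised log posterior of the 72-parameter vector.

    Transition logits get Normal(0, psi_prior_sd) priors.  Survival and
    detection logits get Normal(0, 1) priors, or (probe_uniform) a
    Uniform(0, 1) prior on the probability scale realised through the
    logistic Jacobian.
    """
    psi, phi, p = theta_to_matrices(theta)
    Omega, Theta = build_matrices(psi, phi, p)
    ll = forward_loglik_all(Y, first, Omega, Theta)
    if np.isinf(ll):
        return -np.inf
    lp = 0.0
    for k in range(56):
        lp += -0.5 * (theta[k] / psi_prior_sd) ** 2
    for k in range(56, 72):
        if probe_uniform:
            # logistic log-Jacobian: uniform prior on the probability scale
            lp += theta[k] - 2.0 * np.log1p(np.exp(theta[k]))
        else:
            lp += -0.5 * theta[k] ** 2
    return ll + lp
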