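"""Numba inner loops: scaled forward/backward recursions and chain sampling."""

import numpy as np
from numba import njit


@njit(cache=False)
def forward_scaled(P, B, pi):
    """Scaled forward pass.

    Parameters: transition P (n,n), per-position state likelihoods B (L,n),
    initial pi (n,).  Returns (alpha, scale, bad) where alpha rows are the
    normalized forward variables, scale the per-position normalizers, and
    bad the first position with zero/non-finite total probability (-1 if
    none).
    """
    L, n = B.shape
    alpha = np.empty((L, n))
    scale = np.empty(L)
    a = pi * B[0]
    s = a.sum()
    if s <= 0 or not np.isfinite(s):
        return alpha, scale, 0
    alpha[0] = a / s
    scale[0] = s
    for l in range(1, L):
        a = np.dot(alpha[l - 1], P) * B[l]
        s = a.sum()
        if s <= 0 or not np.isfinite(s):
            return alpha, scale, l
        alpha[l] = a / s
        scale[l] = s
    return alpha, scale, -1


@njit(cache=False)
def forward_loglik(P, B, pi):
    """Forward log-likelihood only (no stored variables)."""
    L, n = B.shape
    a = pi * B[0]
    s = a.sum()
    if s <= 0 or not np.isfinite(s):
        return -np.inf
    a = a / s
    ll = np.log(s)
    for l in range(1, L):
        a = np.dot(a, P) * B[l]
        s = a.sum()
        if s <= 0 or not np.isfinite(s):
            return -np.inf
        a = a / s
        ll += np.log(s)
    return ll


@njit(cache=False)
def backward_scaled(P, B, scale):
    L, n = B.shape
    beta = np.empty((L, n))
    beta[L - 1] = 1.0
    for l in range(L - 2, -1, -1):
        beta[l] = np.dot(P, B[l + 1] * beta[l + 1]) / scale[l + 1]
    return beta


@njit(cache=False)
def sample_chain(trans_cdf, init_cdf, p_het, u_state, u_emit):
    """Sample hidden states and HET/HOM emissions along the sequence.

    trans_cdf: row-wise cumulative transition matrix; init_cdf: cumulative
    initial distribution; p_het: per-state heterozygosity probability;
    u_state/u_emit: iid U(0,1) draws, one pair per bin.
    """
    L = u_state.shape[0]
    states = np.empty(L, np.int64)
    obs = np.empty(L, np.int8)
    s = np.searchsorted(init_cdf, u_state[0])
    states[0] = s
    obs[0] = 1 if u_emit[0] < p_het[s] else 0
    for l in range(1, L):
        s = np.searchsorted(trans_cdf[s], u_state[l])
        states[l] = s
        obs[l] = 1 if u_emit[l] < p_het[s] else 0
    return states, obs
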