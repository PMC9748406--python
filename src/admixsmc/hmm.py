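r"""The discrete-state coalescent HMM: matrices and inference.

Hidden states are discrete TMRCA intervals; observations are per-bin
heterozygosity codes (HOM / HET / MISSING).  With state representative time
``t`` and per-bin scaled mutation rate ``theta``, emissions are

    e(HOM | t) = exp(-theta * t),   e(HET | t) = 1 - exp(-theta * t),
    e(MISSING | t) = 1.

Conditional on a recombination event, the TMRCA moves from ``s`` to ``t``
with kernel (single population, relative size ``lam``)

    q(t | s) = (1 / lam(t)) * int_0^{min(s,t)} (1/s)
               * exp(-int_u^t dv / lam(v)) du,

the classic SMC transition: the recombination breakpoint falls uniformly on
the branch of length ``s`` and the floating lineage re-coalesces at rate
1/lam.  With an admixture event at time ``t_a`` (two populations with sizes
lambda_a and lambda_b = c * lambda_a merging, looking backwards, at t_a)
the kernel splits into three cases by where the new coalescence lands:

* ``t >  t_a``: single population P1 -> q with lambda_a;
* ``t <= t_a <  s``: the lineage recombines in exactly one of the two
  not-yet-merged populations: ``q_a + q_b - 2 q_a q_b``;
* ``t, s <= t_a``: fully merged population -> q with lambda' = (1+c) lambda_a.

The full one-bin transition mixes this conditional kernel with the
no-recombination self-transition,

    p(t | s) = (1 - exp(-rho * s)) * q'(t | s) + exp(-rho * s) * delta(t, s),

where ``rho`` is the scaled per-bin recombination rate and ``delta`` the
Kronecker delta on interval indices.  Discretized rows of ``q'`` are
renormalized before mixing (the continuous kernel integrates to one only in
exact arithmetic, and the admixture case combination is itself not exactly
normalized).

All integrals are evaluated in closed form per grid interval.  With the
cumulative hazard H(t) = int_0^t dv/lam(v) (piecewise linear) the quantities

    g_k = e^{-H(b_k)} * G(b_k),   G(x) = int_0^x e^{H(u)} du

obey the overflow-free recurrence ``g_{k+1} = g_k e^{-dH_k} +
lam_k (1 - e^{-dH_k})``, and every matrix entry is a short expression in
``g``, ``H`` differences (always exponentiated with non-positive argument)
and interval widths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .grid import ConfigurationError, TimeGrid
from .io import HET, HOM, MISSING, TernarySequence
from .model import AdmixtureModel

__all__ = [
    "HmmMatrices",
    "NumericalError",
    "emission_matrix",
    "q_single",
    "q_single_matrix",
    "q_admix",
    "q_admix_matrix",
    "transition_matrix",
    "initial_distribution",
    "build_matrices",
    "forward_backward",
    "posterior_decode",
    "ForwardBackwardResult",
]


class NumericalError(FloatingPointError):
    """Zero-probability observation or non-finite recursion state."""


# ---------------------------------------------------------------------------
# hazard tables


def _tables(grid: TimeGrid, lam: np.ndarray):
    """Cumulative hazard H at boundaries (H[n] = inf) and g_k table."""
    n = grid.n_intervals
    w = np.diff(grid.boundaries)
    dH = w / lam
    H = np.empty(n + 1)
    H[0] = 0.0
    np.cumsum(dH, out=H[1:])
    H[n] = np.inf
    e = np.exp(-dH)
    g = np.empty(n + 1)
    g[0] = 0.0
    for k in range(n):
        g[k + 1] = g[k] * e[k] + lam[k] * (1.0 - e[k])
    return H, g, w, e


# ---------------------------------------------------------------------------
# transition kernels


def q_single_matrix(grid: TimeGrid, lam, reps=None) -> np.ndarray:
    """Interval-discretized single-population recombination kernel.

    Entry (i, j) is the probability, given a recombination event while the
    TMRCA sits at the representative time of interval i, that the new TMRCA
    lands in interval j.  Rows integrate to 1 analytically (the last
    interval extends to infinity); tiny floating-point defects remain.

    Parameters
    ----------
    grid : TimeGrid
    lam : ndarray, shape (n_intervals,)
        Per-atomic-interval relative population size.
    reps : ndarray, optional
        Representative source times; conditional means under ``lam`` if
        omitted.
    """
    lam = np.asarray(lam, dtype=float)
    n = grid.n_intervals
    if lam.shape != (n,):
        raise ConfigurationError("lam must have one entry per atomic interval")
    if np.any(lam <= 0):
        raise ConfigurationError("lam must be positive")
    b = grid.boundaries
    if reps is None:
        reps = grid.representatives(lam)
    s = np.asarray(reps, dtype=float)

    H, g, w, e = _tables(grid, lam)
    one_me = 1.0 - e

    # within-interval quantities at the source representative
    d = (s - b[:-1]) / lam
    ed = np.exp(-d)
    g_s = g[:-1] * ed + lam * (1.0 - ed)
    H_s = H[:-1] + d

    inv_s = 1.0 / s
    Q = np.zeros((n, n))

    # destination fully below the source interval (j < i): column term
    colB = g[:-1] * one_me + w - lam * one_me
    Q += np.tril(np.outer(inv_s, colB), k=-1)

    # destination fully above (j > i)
    expo = H_s[:, None] - H[None, :]
    E1 = np.exp(np.minimum(expo, 0.0))  # positive args occur only at masked (j<=i) entries
    D = E1[:, :-1] - E1[:, 1:]
    Q += np.triu((g_s * inv_s)[:, None] * D, k=1)

    # source interval itself: split at s
    wlo = s - b[:-1]
    part1 = g[:-1] * (1.0 - ed) + wlo - lam * (1.0 - ed)
    part2 = g_s * (1.0 - np.exp(-(H[1:] - H_s)))
    np.fill_diagonal(Q, inv_s * (part1 + part2))
    return Q


def q_single(s_index: int, t_index: int, lam, grid: TimeGrid) -> float:
    """Single entry of :func:`q_single_matrix` (representatives under lam)."""
    return float(q_single_matrix(grid, lam)[s_index, t_index])


def q_admix_matrix(model: AdmixtureModel, reps=None) -> np.ndarray:
    """Admixture-aware conditional transition kernel q'(t | s).

    Assembles the three cases by interval index relative to the admixture
    boundary ``k = model.t_a_index`` (an interval is below the event iff its
    index is < k):

    * columns j >= k: single-population kernel with lambda_a;
    * rows i >= k, columns j < k: ``q_a + q_b - 2 q_a q_b``;
    * rows i < k, columns j < k: merged kernel with lambda' = (1+c) lambda_a.

    Rows are *not* renormalized here.
    """
    grid = model.grid
    n = grid.n_intervals
    lam_a = model.lambda_a_atomic
    if reps is None:
        reps = grid.representatives(model.lambda_combined())
    Qa = q_single_matrix(grid, lam_a, reps)
    k = model.t_a_index
    c = model.admix_ratio
    if k == 0 or c == 0.0:
        return Qa
    Qm = q_single_matrix(grid, model.lambda_combined(), reps)
    Qb = q_single_matrix(grid, c * lam_a, reps)
    Q = Qa.copy()
    below = np.arange(n) < k
    above = ~below
    comb = Qa + Qb - 2.0 * Qa * Qb
    Q[np.ix_(above, below)] = comb[np.ix_(above, below)]
    Q[np.ix_(below, below)] = Qm[np.ix_(below, below)]
    return Q


def q_admix(s_index: int, t_index: int, model: AdmixtureModel) -> float:
    """Single entry of :func:`q_admix_matrix`."""
    return float(q_admix_matrix(model)[s_index, t_index])


def transition_matrix(model: AdmixtureModel, reps=None) -> np.ndarray:
    """Row-stochastic one-bin transition matrix p'(t | s)."""
    if reps is None:
        reps = model.grid.representatives(model.lambda_combined())
    Q = q_admix_matrix(model, reps)
    Q = Q / Q.sum(axis=1, keepdims=True)
    stay = np.exp(-model.rho * reps)
    P = (1.0 - stay)[:, None] * Q
    P[np.diag_indices_from(P)] += stay
    return P


# ---------------------------------------------------------------------------
# emission and prior


def emission_matrix(theta: float, grid: TimeGrid, reps=None) -> np.ndarray:
    """(n_intervals, 3) matrix of P(obs | state) for {HOM, HET, MISSING}."""
    if theta <= 0:
        raise ConfigurationError("theta must be positive")
    if reps is None:
        reps = grid.representatives()
    reps = np.asarray(reps, dtype=float)
    E = np.empty((reps.size, 3))
    E[:, HOM] = np.exp(-theta * reps)
    E[:, HET] = -np.expm1(-theta * reps)
    E[:, MISSING] = 1.0
    return E


def initial_distribution(model: AdmixtureModel) -> np.ndarray:
    """Coalescent prior on TMRCA intervals under lambda'(t).

    The TMRCA density is the pure-death coalescent exp(-H'(t)) / lambda'(t),
    so interval i receives mass exp(-H'(b_i)) - exp(-H'(b_{i+1})), with the
    last interval absorbing the tail.
    """
    H, _, _, _ = _tables(model.grid, model.lambda_combined())
    surv = np.exp(-H)
    pi = surv[:-1] - surv[1:]
    return pi / pi.sum()


@dataclass
class HmmMatrices:
    """Matrices of the discrete HMM plus the state representative times."""

    emission: np.ndarray
    transition: np.ndarray
    initial: np.ndarray
    state_times: np.ndarray

    def validate(self, atol: float = 1e-10) -> None:
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=atol):
            raise NumericalError("transition rows do not sum to 1")
        if not np.isclose(self.initial.sum(), 1.0, atol=atol):
            raise NumericalError("initial distribution does not sum to 1")
        if not np.allclose(self.emission[:, [HOM, HET]].sum(axis=1), 1.0, atol=atol):
            raise NumericalError("HOM and HET emissions do not sum to 1")


def build_matrices(model: AdmixtureModel) -> HmmMatrices:
    """Assemble emission, transition and initial distribution for a model."""
    reps = model.grid.representatives(model.lambda_combined())
    return HmmMatrices(
        emission=emission_matrix(model.theta, model.grid, reps),
        transition=transition_matrix(model, reps),
        initial=initial_distribution(model),
        state_times=reps,
    )


# ---------------------------------------------------------------------------
# inference


@dataclass
class ForwardBackwardResult:
    """Log-likelihood, posteriors and Baum-Welch sufficient statistics."""

    loglik: float
    posterior: np.ndarray  # (L, n), rows sum to 1
    trans_counts: np.ndarray  # (n, n) expected transition counts
    emit_counts: np.ndarray  # (n, 3) expected emission counts


def _codes_of(obs) -> np.ndarray:
    if isinstance(obs, TernarySequence):
        return obs.codes
    return np.asarray(obs, dtype=np.int8)


def forward_backward(obs, matrices: HmmMatrices) -> ForwardBackwardResult:
    """Scaled forward-backward with pair-marginal sufficient statistics.

    Parameters
    ----------
    obs : TernarySequence or integer code array
    matrices : HmmMatrices

    Raises
    ------
    NumericalError
        If some position has zero probability under every state.
    """
    codes = _codes_of(obs)
    if codes.size == 0:
        raise ValueError("empty observation sequence")
    E, P, pi = matrices.emission, matrices.transition, matrices.initial
    B = np.ascontiguousarray(E[:, codes].T)
    alpha, scale, bad = _kernels.forward_scaled(P, B, pi)
    if bad >= 0:
        raise NumericalError(f"zero-probability observation at bin {bad}")
    beta = _kernels.backward_scaled(P, B, scale)
    gamma = alpha * beta
    # xi summed over positions: P o (alpha[:-1]^T . (B * beta / c)[1:])
    weighted = B[1:] * beta[1:] / scale[1:, None]
    A = P * (alpha[:-1].T @ weighted)
    emit = np.empty((P.shape[0], 3))
    for k in (HOM, HET, MISSING):
        sel = codes == k
        emit[:, k] = gamma[sel].sum(axis=0) if sel.any() else 0.0
    return ForwardBackwardResult(
        loglik=float(np.log(scale).sum()),
        posterior=gamma,
        trans_counts=A,
        emit_counts=emit,
    )


def sequence_loglik(obs, matrices: HmmMatrices) -> float:
    """Forward log-likelihood of a sequence (no posteriors computed)."""
    codes = _codes_of(obs)
    if codes.size == 0:
        raise ValueError("empty observation sequence")
    B = np.ascontiguousarray(matrices.emission[:, codes].T)
    ll = _kernels.forward_loglik(matrices.transition, B, matrices.initial)
    if not np.isfinite(ll):
        raise NumericalError("zero-probability observation sequence")
    return float(ll)


def posterior_decode(obs, matrices: HmmMatrices) -> np.ndarray:
    """Marginal-MAP state index per bin (ties break to the smaller index)."""
    fb = forward_backward(obs, matrices)
    return fb.posterior.argmax(axis=1)
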