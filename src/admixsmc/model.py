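"""Model parameters for the admixture-aware coalescent HMM.

Two populations P1 and P2, with relative effective sizes lambda_a(t) and
lambda_b(t) (both in units of the baseline diploid size N0), merged into one
population at admixture time ``t_a``.  Looking backwards from the present,
the relevant relative size is

    lambda'(t) = lambda_a(t)                  for t >  t_a
    lambda'(t) = lambda_a(t) + lambda_b(t)    for t <= t_a

lambda_b is parameterized as a single scalar multiple of lambda_a,
``lambda_b = admix_ratio * lambda_a`` on the merged epoch, which is the
identifiable reduction of the second population's size history (the HMM only
sees the sum below ``t_a``).  ``t_a`` is restricted to grid boundaries, so an
interval is "below the admixture event" exactly when its index is below the
boundary index of ``t_a``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .grid import ConfigurationError, TimeGrid

__all__ = ["AdmixtureModel", "FitResult", "combined_lambda", "scale_to_physical"]


@dataclass
class AdmixtureModel:
    """Full parameter vector of the admixture-aware HMM.

    Attributes
    ----------
    theta : float
        Population-scaled mutation rate per observation bin (4*N0*mu*bin).
    rho : float
        Population-scaled recombination rate per bin (4*N0*r*bin).
    lambda_a : ndarray, shape (n_groups,)
        Relative effective size of P1 per parameter group.
    admix_ratio : float
        Scalar c >= 0 with lambda_b = c * lambda_a below the admixture time.
        A ratio of "r:1" between the two merging populations corresponds to
        c = 1/r; c = 0 disables admixture.
    t_a_index : int
        Boundary index of the admixture time: t_a = boundaries[t_a_index].
        0 means "no admixture"; n means every interval lies in the merged
        epoch.
    grid : TimeGrid
    """

    theta: float
    rho: float
    lambda_a: np.ndarray
    admix_ratio: float
    t_a_index: int
    grid: TimeGrid

    def __post_init__(self):
        self.lambda_a = np.asarray(self.lambda_a, dtype=float)
        if self.theta <= 0 or self.rho <= 0:
            raise ConfigurationError("theta and rho must be positive")
        if np.any(self.lambda_a <= 0):
            raise ConfigurationError("lambda_a must be positive")
        if self.admix_ratio < 0:
            raise ConfigurationError("admix_ratio must be nonnegative")
        if self.lambda_a.size != self.grid.n_groups:
            raise ConfigurationError("lambda_a length must equal number of groups")
        if not (0 <= self.t_a_index <= self.grid.n_intervals):
            raise ConfigurationError("t_a_index must index a grid boundary")

    @property
    def t_a(self) -> float:
        """Admixture time in coalescent units (a grid boundary)."""
        return float(self.grid.boundaries[self.t_a_index])

    @property
    def lambda_a_atomic(self) -> np.ndarray:
        return self.grid.expand_groups(self.lambda_a)

    def merged_mask(self) -> np.ndarray:
        """Boolean mask of atomic intervals in the merged epoch (t <= t_a).

        Because t_a sits on a boundary and every representative lies strictly
        inside its interval, "representative <= t_a" is exactly
        "interval index < t_a_index".
        """
        return np.arange(self.grid.n_intervals) < self.t_a_index

    def lambda_combined(self) -> np.ndarray:
        """Per-atomic-interval relevant size lambda'(t)."""
        lam = self.lambda_a_atomic.copy()
        mask = self.merged_mask()
        lam[mask] *= 1.0 + self.admix_ratio
        return lam

    def copy(self, **changes) -> "AdmixtureModel":
        if "lambda_a" not in changes:
            changes["lambda_a"] = self.lambda_a.copy()
        return replace(self, **changes)


def combined_lambda(model: AdmixtureModel, interval_index: int) -> float:
    """Relevant relative size lambda'(t) on one atomic interval.

    Returns ``lambda_a * (1 + admix_ratio)`` when the interval's
    representative time is at or below the admixture time, else ``lambda_a``.
    """
    n = model.grid.n_intervals
    if not (0 <= interval_index < n):
        raise IndexError(f"interval index {interval_index} out of range [0, {n})")
    return float(model.lambda_combined()[interval_index])


@dataclass
class FitResult:
    """Outcome of an EM fit.

    ``n0_estimate``, ``t_a_years`` and ``ne_curve`` are in physical units
    derived from theta via :func:`scale_to_physical`; they are NaN/empty
    until that conversion has been applied.
    """

    model: AdmixtureModel
    loglik_trace: np.ndarray
    converged: bool
    mu: float = np.nan
    gen_years: float = np.nan
    bin_size: float = np.nan
    n0_estimate: float = np.nan
    t_a_years: float = np.nan
    ne_curve: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])


def scale_to_physical(
    result: FitResult,
    mu: float,
    gen_years: float,
    bin_size: int = 100,
) -> FitResult:
    """Convert a fit from coalescent-scaled to physical units, in place.

    The baseline diploid effective size is recovered from the scaled
    per-bin mutation rate, N0 = theta / (4 * mu * bin_size); coalescent
    times convert to years via t_years = t * 2 * N0 * gen_years and
    relative sizes to N_e = lambda' * N0.

    Parameters
    ----------
    result : FitResult
    mu : float
        Per-site per-generation mutation rate.
    gen_years : float
        Years per generation.
    bin_size : int
        Bases per observation bin.
    """
    if mu <= 0 or gen_years <= 0 or bin_size < 1:
        raise ConfigurationError("mu, gen_years must be positive and bin_size >= 1")
    model = result.model
    n0 = model.theta / (4.0 * mu * bin_size)
    years_per_coal = 2.0 * n0 * gen_years
    grid = model.grid
    group_start = np.concatenate(([0], np.cumsum(grid.group_sizes)))[:-1]
    start_times = grid.boundaries[group_start] * years_per_coal
    ne = model.lambda_a * n0
    result.mu = mu
    result.gen_years = gen_years
    result.bin_size = bin_size
    result.n0_estimate = n0
    result.t_a_years = model.t_a * years_per_coal
    result.ne_curve = np.column_stack([start_times, ne])
    return result
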