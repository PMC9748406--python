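"""Simulation of binned heterozygosity tracks under the split-then-merge
demography.

The generative process is the model's own sequentially Markovian kernel on a
discrete grid: the TMRCA at the first bin is drawn from the coalescent prior
under lambda'(t), subsequent bins follow the one-bin transition matrix, and
each bin emits HET with probability 1 - exp(-theta * t).  The true admixture
time is inserted as an extra grid boundary, so the simulated demography
changes size exactly at the requested time even when it falls between the
standard boundaries (the *fitted* grid stays the standard one, which is what
produces the characteristic horizontal steps in estimated times).

Physical units convert to coalescent units via theta = 4*N0*mu*bin,
rho = 4*N0*rec*bin, t = years / (2*N0*gen_years).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import _kernels, em
from .grid import ConfigurationError, TimeGrid, build_time_grid
from .hmm import HET, build_matrices
from .io import TernarySequence
from .model import AdmixtureModel

__all__ = ["SimulationSpec", "simulate_sequence", "run_experiment_grid"]

EXPERIMENT_COLUMNS = [
    "time_true_years",
    "ratio",
    "rep",
    "time_est_years",
    "loglik",
    "converged",
]


@dataclass
class SimulationSpec:
    """Study conditions for one simulated diploid genome.

    Defaults are the human-analog simulation settings: baseline diploid
    effective size 1e5, 5 years per generation, mutation rate 2.5e-8 and
    recombination rate 5e-9 per site per generation, 100-bp bins.

    ``admix_ratio`` is the size ratio r of the two merging populations
    (P1 : P2 = r : 1, so the minor population has relative size c = 1/r);
    ``admix_time_years = 0`` simulates a single constant-size population.
    """

    n0: float = 1e5
    gen_years: float = 5.0
    mu: float = 2.5e-8
    rec: float = 5e-9
    admix_time_years: float = 0.0
    admix_ratio: float = 1.0
    length_bp: int = 10_000_000
    bin_size: int = 100
    seed: int = 0

    def __post_init__(self):
        if min(self.n0, self.gen_years, self.mu, self.rec) <= 0:
            raise ConfigurationError("rates and sizes must be positive")
        if self.admix_time_years < 0 or self.admix_ratio <= 0:
            raise ConfigurationError("admix_time_years >= 0 and admix_ratio > 0 required")
        if self.length_bp < self.bin_size:
            raise ConfigurationError("length_bp must be >= bin_size")

    @property
    def years_per_coal(self) -> float:
        """Years per coalescent time unit (2 * N0 generations)."""
        return 2.0 * self.n0 * self.gen_years

    @property
    def theta(self) -> float:
        return 4.0 * self.n0 * self.mu * self.bin_size

    @property
    def rho(self) -> float:
        return 4.0 * self.n0 * self.rec * self.bin_size

    @property
    def t_a_coal(self) -> float:
        return self.admix_time_years / self.years_per_coal

    @property
    def n_bins(self) -> int:
        return self.length_bp // self.bin_size


def _simulation_grid(spec: SimulationSpec, n_intervals: int, t_max: float) -> tuple:
    """Standard grid with the true admixture time inserted as a boundary."""
    base = build_time_grid(n_intervals, t_max)
    b = base.boundaries
    ta = spec.t_a_coal
    if ta == 0.0:
        return base, 0
    if ta >= b[-1]:
        raise ConfigurationError("admixture time beyond the simulated time grid")
    k = int(np.searchsorted(b, ta))
    if np.isclose(b[min(k, b.size - 1)], ta) or np.isclose(b[k - 1], ta):
        k = int(np.argmin(np.abs(b - ta)))
        return base, k
    bb = np.insert(b, k, ta)
    n = bb.size - 1
    grid = TimeGrid(boundaries=bb, group_sizes=(1,) * n, pattern=f"{n}*1")
    return grid, k


def simulate_sequence(
    spec: SimulationSpec, n_intervals: int = 64, t_max: float = 15.0
):
    """Simulate one ternary sequence with its true TMRCA path.

    Returns
    -------
    seq : TernarySequence
    tmrca : ndarray
        True TMRCA per bin, in coalescent units (representative times of the
        simulation grid).
    model : AdmixtureModel
        The generating model (on the simulation grid, with the true
        admixture boundary).
    """
    grid, k = _simulation_grid(spec, n_intervals, t_max)
    c = 1.0 / spec.admix_ratio if k > 0 else 0.0
    model = AdmixtureModel(
        theta=spec.theta,
        rho=spec.rho,
        lambda_a=np.ones(grid.n_groups),
        admix_ratio=c,
        t_a_index=k,
        grid=grid,
    )
    matrices = build_matrices(model)
    rng = np.random.default_rng(spec.seed)
    L = spec.n_bins
    u_state = rng.random(L)
    u_emit = rng.random(L)
    trans_cdf = np.cumsum(matrices.transition, axis=1)
    init_cdf = np.cumsum(matrices.initial)
    states, obs = _kernels.sample_chain(
        trans_cdf, init_cdf, matrices.emission[:, HET], u_state, u_emit
    )
    seq = TernarySequence(
        name=f"sim_t{spec.admix_time_years:.0f}_r{spec.admix_ratio:g}_s{spec.seed}",
        codes=obs,
        bin_size=spec.bin_size,
    )
    return seq, matrices.state_times[states], model


def run_experiment_grid(
    times,
    ratios,
    reps: int,
    base_spec: SimulationSpec | None = None,
    seed: int = 0,
    config: em.FitConfig | None = None,
    grid: TimeGrid | None = None,
) -> pd.DataFrame:
    """Simulate-and-fit over a grid of admixture times and ratios.

    Parameters
    ----------
    times : sequence of float
        True admixture times in years.
    ratios : sequence of float
        Size ratios r ("r : 1") of the merging populations.
    reps : int
        Replicates per (time, ratio) cell.
    base_spec : SimulationSpec, optional
        Template for all other study conditions.
    seed : int
        Master seed; each cell gets an independent deterministic child seed.
    config : FitConfig, optional
        EM settings used for every fit.
    grid : TimeGrid, optional
        Fitting grid (default: standard 64-interval grouped grid).

    Returns
    -------
    DataFrame with columns time_true_years, ratio, rep, time_est_years,
    loglik, converged.  Failed fits keep their row with NaN estimate.
    """
    times = list(times)
    ratios = list(ratios)
    if not times or not ratios or reps < 1:
        raise ValueError("times and ratios must be nonempty and reps >= 1")
    base_spec = base_spec or SimulationSpec()
    rows = []
    for it, time in enumerate(times):
        for ir, ratio in enumerate(ratios):
            for rep in range(reps):
                child = int(
                    np.random.SeedSequence([seed, it, ir, rep]).generate_state(1)[0]
                    % (2**31)
                )
                spec = replace(
                    base_spec,
                    admix_time_years=float(time),
                    admix_ratio=float(ratio),
                    seed=child,
                )
                seq, _, _ = simulate_sequence(spec)
                row = {
                    "time_true_years": float(time),
                    "ratio": float(ratio),
                    "rep": rep,
                    "time_est_years": np.nan,
                    "loglik": np.nan,
                    "converged": False,
                }
                try:
                    result = em.fit(
                        seq,
                        config=config,
                        grid=grid,
                        mu=spec.mu,
                        gen_years=spec.gen_years,
                        bin_size=spec.bin_size,
                    )
                    row["time_est_years"] = result.t_a_years
                    row["loglik"] = result.loglik
                    row["converged"] = bool(result.converged)
                except Exception:  # noqa: BLE001 - record failure, keep going
                    pass
                rows.append(row)
    return pd.DataFrame(rows, columns=EXPERIMENT_COLUMNS)
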