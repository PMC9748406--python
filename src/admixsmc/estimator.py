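"""Scikit-learn style front end.

``AdmixtureSMC`` is the package's main user-facing object, in the mold of
``hmmlearn``'s estimators: construct with hyperparameters, ``fit`` on one or
more binned heterozygosity sequences, then read fitted attributes
(``t_a_years_``, ``ne_curve_``, ...), ``score`` held-out sequences, or
``predict`` the per-bin TMRCA interval track.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import em
from .grid import build_time_grid
from .hmm import build_matrices, forward_backward, posterior_decode
from .io import TernarySequence

__all__ = ["AdmixtureSMC"]


class AdmixtureSMC(BaseEstimator):
    """Coalescent HMM over binned heterozygosity with a free admixture time.

    Parameters
    ----------
    n_intervals : int
        Number of atomic TMRCA intervals.
    pattern : str
        PSMC-style grouping of intervals into shared-size parameters.
    t_max : float
        Largest finite grid boundary, in units of 2*N0 generations.
    mu : float
        Per-site per-generation mutation rate (physical rescaling only).
    gen_years : float
        Years per generation (physical rescaling only).
    bin_size : int or None
        Bases per observation bin; taken from the input if None.
    max_iter, tol : EM stopping rule (relative log-likelihood change).
    fit_admixture : bool
        If False the admixture time is pinned to 0 (vanilla PSMC fit).
    t_a_search : tuple or None
        Candidate boundary indices for the admixture time (None = all).
    ratio_search : tuple
        Candidate size ratios c = lambda_b / lambda_a.
    activation_penalty : float or None
        ECLL margin to move t_a off 0; None = BIC default.
    random_state : int or None
        Reserved for randomized restarts; the fit itself is deterministic.

    Attributes
    ----------
    result_ : FitResult
    theta_, rho_ : fitted scaled per-bin rates
    lambda_ : ndarray, per-group relative sizes of P1
    admix_ratio_ : fitted c
    t_a_index_, t_a_, t_a_years_ : admixture time (boundary index,
        coalescent units, years)
    n0_ : baseline diploid effective size implied by theta
    ne_curve_ : (n_groups, 2) array of (years, N_e)
    loglik_trace_ : per-iteration log-likelihood
    converged_ : bool

    Examples
    --------
    >>> from admixsmc import AdmixtureSMC, SimulationSpec, simulate_sequence
    >>> seq, _, _ = simulate_sequence(SimulationSpec(
    ...     admix_time_years=60_000, admix_ratio=4.0,
    ...     length_bp=2_000_000, seed=7))
    >>> est = AdmixtureSMC(max_iter=10, tol=1e-4).fit(seq)
    >>> bool(est.t_a_years_ > 0)
    True
    """

    def __init__(
        self,
        n_intervals: int = 64,
        pattern: str = "4+25*2+4+6",
        t_max: float = 15.0,
        mu: float = 2.5e-8,
        gen_years: float = 5.0,
        bin_size: int | None = None,
        max_iter: int = 25,
        tol: float = 1e-6,
        fit_admixture: bool = True,
        t_a_search: tuple | None = None,
        ratio_search: tuple = (0.0, 0.25, 1.0 / 3.0, 0.5, 1.0),
        activation_penalty: float | None = None,
        random_state: int | None = None,
    ):
        self.n_intervals = n_intervals
        self.pattern = pattern
        self.t_max = t_max
        self.mu = mu
        self.gen_years = gen_years
        self.bin_size = bin_size
        self.max_iter = max_iter
        self.tol = tol
        self.fit_admixture = fit_admixture
        self.t_a_search = t_a_search
        self.ratio_search = ratio_search
        self.activation_penalty = activation_penalty
        self.random_state = random_state

    # -- plumbing ---------------------------------------------------------

    def _sequences(self, X) -> list:
        if isinstance(X, TernarySequence):
            return [X]
        if isinstance(X, np.ndarray):
            if X.ndim == 1:
                return [np.asarray(X, dtype=np.int8)]
            if X.ndim == 2:
                return [np.asarray(row, dtype=np.int8) for row in X]
            raise ValueError("array input must be 1- or 2-dimensional")
        seqs = list(X)
        if not seqs:
            raise ValueError("need at least one sequence")
        return seqs

    def _config(self) -> em.FitConfig:
        t_a_search = (0,) if not self.fit_admixture else self.t_a_search
        return em.FitConfig(
            max_iter=self.max_iter,
            tol=self.tol,
            t_a_search=t_a_search,
            ratio_search=tuple(self.ratio_search),
            activation_penalty=self.activation_penalty,
            seed=self.random_state,
        )

    # -- sklearn API ------------------------------------------------------

    def fit(self, X, y=None):
        """Run EM on one or more ternary sequences."""
        seqs = self._sequences(X)
        grid = build_time_grid(self.n_intervals, self.t_max, self.pattern)
        result = em.fit(
            seqs,
            config=self._config(),
            grid=grid,
            mu=self.mu,
            gen_years=self.gen_years,
            bin_size=self.bin_size,
        )
        self.result_ = result
        model = result.model
        self.model_ = model
        self.theta_ = model.theta
        self.rho_ = model.rho
        self.lambda_ = model.lambda_a.copy()
        self.admix_ratio_ = model.admix_ratio
        self.t_a_index_ = model.t_a_index
        self.t_a_ = model.t_a
        self.t_a_years_ = result.t_a_years
        self.n0_ = result.n0_estimate
        self.ne_curve_ = result.ne_curve.copy()
        self.loglik_trace_ = result.loglik_trace.copy()
        self.converged_ = result.converged
        self.matrices_ = build_matrices(model)
        return self

    def score(self, X, y=None) -> float:
        """Total log-likelihood of sequences under the fitted model."""
        check_is_fitted(self, "model_")
        return float(
            sum(forward_backward(s, self.matrices_).loglik for s in self._sequences(X))
        )

    def predict(self, X):
        """Marginal-MAP TMRCA interval index per bin.

        Returns a single array for a single sequence, else a list of arrays.
        """
        check_is_fitted(self, "model_")
        seqs = self._sequences(X)
        tracks = [posterior_decode(s, self.matrices_) for s in seqs]
        single = isinstance(X, TernarySequence) or (
            isinstance(X, np.ndarray) and X.ndim == 1
        )
        return tracks[0] if single else tracks

    def predict_proba(self, X):
        """Posterior TMRCA interval probabilities per bin."""
        check_is_fitted(self, "model_")
        seqs = self._sequences(X)
        posts = [forward_backward(s, self.matrices_).posterior for s in seqs]
        single = isinstance(X, TernarySequence) or (
            isinstance(X, np.ndarray) and X.ndim == 1
        )
        return posts[0] if single else posts
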