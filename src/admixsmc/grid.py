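"""Discretization of coalescent time for the hidden-state space.

Time is measured in coalescent units of 2*N0 generations.  The TMRCA of the
two alleles of a diploid individual is discretized into ``n_intervals``
atomic intervals whose boundaries follow the log-uniform scheme used
throughout the PSMC model family,

    b_i = 0.1 * (exp((i/n) * log(1 + 10 * t_max)) - 1),   i = 0..n,

so that b_0 = 0 and b_n = t_max.  The last interval is treated as unbounded
(``[b_{n-1}, inf)``) in every integral; ``t_max`` is only the largest finite
boundary that is written out.

A PSMC-style *pattern* string ("4+25*2+4+6") ties consecutive atomic
intervals into groups that share one free population-size parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TimeGrid", "build_time_grid", "parse_pattern", "ConfigurationError"]


class ConfigurationError(ValueError):
    """Raised for inconsistent grid / model configuration."""


def parse_pattern(pattern: str) -> list[int]:
    """Expand a grouping pattern into a list of group sizes.

    ``"4+25*2+4+6"`` means: one group of 4 atomic intervals, then 25 groups
    of 2 intervals each, then a group of 4 and a group of 6 -- 64 atomic
    intervals in 28 groups.

    Parameters
    ----------
    pattern : str
        ``+``-separated terms; each term is either ``k`` (one group of k
        intervals) or ``m*k`` (m groups of k intervals each).

    Returns
    -------
    list of int
        Size (number of atomic intervals) of each group, in order.
    """
    sizes: list[int] = []
    for term in pattern.split("+"):
        term = term.strip()
        if not term:
            raise ConfigurationError(f"empty term in pattern {pattern!r}")
        try:
            if "*" in term:
                m_str, k_str = term.split("*")
                m, k = int(m_str), int(k_str)
            else:
                m, k = 1, int(term)
        except ValueError as exc:
            raise ConfigurationError(f"bad pattern term {term!r}") from exc
        if m < 1 or k < 1:
            raise ConfigurationError(f"non-positive pattern term {term!r}")
        sizes.extend([k] * m)
    return sizes


@dataclass(frozen=True)
class TimeGrid:
    """Discrete coalescent-time grid with free-parameter grouping.

    Attributes
    ----------
    boundaries : ndarray, shape (n_intervals + 1,)
        Strictly increasing interval boundaries in coalescent units;
        ``boundaries[0] == 0``.  ``boundaries[-1]`` is the largest finite
        boundary but the final interval is unbounded for integration.
    group_sizes : tuple of int
        Atomic intervals per parameter group.
    pattern : str
        The grouping pattern string the grid was built from.
    """

    boundaries: np.ndarray
    group_sizes: tuple
    pattern: str
    group_of: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        b = np.asarray(self.boundaries, dtype=float)
        if b.ndim != 1 or b.size < 3:
            raise ConfigurationError("need at least 2 intervals")
        if b[0] != 0.0 or np.any(np.diff(b) <= 0):
            raise ConfigurationError("boundaries must start at 0 and strictly increase")
        n = b.size - 1
        if sum(self.group_sizes) != n:
            raise ConfigurationError(
                f"pattern {self.pattern!r} covers {sum(self.group_sizes)} intervals, "
                f"grid has {n}"
            )
        object.__setattr__(self, "boundaries", b)
        group_of = np.repeat(np.arange(len(self.group_sizes)), self.group_sizes)
        object.__setattr__(self, "group_of", group_of)

    @property
    def n_intervals(self) -> int:
        return self.boundaries.size - 1

    @property
    def n_groups(self) -> int:
        return len(self.group_sizes)

    def expand_groups(self, per_group: np.ndarray) -> np.ndarray:
        """Map a per-group parameter vector to a per-atomic-interval vector."""
        per_group = np.asarray(per_group, dtype=float)
        if per_group.size != self.n_groups:
            raise ConfigurationError("per-group vector has wrong length")
        return per_group[self.group_of]

    def representatives(self, lam_atomic=None) -> np.ndarray:
        """Representative (discrete hidden-state) time of each interval.

        For a bounded interval ``[a, b)`` with constant relative size
        ``lam``, the representative is the conditional mean coalescent time
        given coalescence inside the interval,

            a + lam - w / (exp(w/lam) - 1),   w = b - a,

        which always lies strictly inside the interval.  The unbounded last
        interval uses the fallback ``b_{n-1} + 1``.

        Parameters
        ----------
        lam_atomic : ndarray or None
            Per-atomic-interval relative sizes; constant 1 if omitted.
        """
        b = self.boundaries
        n = self.n_intervals
        lam = np.ones(n) if lam_atomic is None else np.asarray(lam_atomic, float)
        w = np.diff(b)
        reps = np.empty(n)
        # w/(exp(w/lam)-1) via expm1 for small w/lam stability
        ratio = w[:-1] / lam[:-1]
        reps[:-1] = b[:-1][:-1] + lam[:-1] - w[:-1] / np.expm1(ratio)
        reps[-1] = b[-2] + 1.0
        return reps


def build_time_grid(
    n_intervals: int = 64,
    t_max: float = 15.0,
    pattern: str | None = None,
) -> TimeGrid:
    """Build the log-uniform coalescent time grid.

    Parameters
    ----------
    n_intervals : int
        Number of atomic intervals (>= 2).
    t_max : float
        Largest finite boundary, in units of 2*N0 generations.
    pattern : str, optional
        Free-parameter grouping; defaults to one group per atomic interval.

    Returns
    -------
    TimeGrid
    """
    if n_intervals < 2:
        raise ConfigurationError("n_intervals must be >= 2")
    if t_max <= 0:
        raise ConfigurationError("t_max must be positive")
    if pattern is None:
        pattern = f"{n_intervals}*1"
    sizes = parse_pattern(pattern)
    if sum(sizes) != n_intervals:
        raise ConfigurationError(
            f"pattern {pattern!r} implies {sum(sizes)} intervals, requested {n_intervals}"
        )
    i = np.arange(n_intervals + 1)
    boundaries = 0.1 * (np.exp((i / n_intervals) * np.log(1.0 + 10.0 * t_max)) - 1.0)
    boundaries[0] = 0.0
    boundaries[-1] = t_max
    return TimeGrid(boundaries=boundaries, group_sizes=tuple(sizes), pattern=pattern)


DEFAULT_PATTERN = "4+25*2+4+6"


def default_grid() -> TimeGrid:
    """The conventional 64-interval grid with the "4+25*2+4+6" grouping."""
    return build_time_grid(64, 15.0, DEFAULT_PATTERN)
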