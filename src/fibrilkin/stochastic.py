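"""Event-driven stochastic simulation of fibril assembly with explicit lengths.

A direct (Gillespie) realisation of the nucleation / growth / end-joining
scheme at single-monomer resolution.  The state is the number of free
monomers plus the multiset of fibril lengths (in monomer units), so the
simulator produces the per-fibril length distributions that atomic-force
microscopy measures, not just bulk concentrations.

Events and propensities (counts; Omega = system_size / A0 converts the
second-order concentration rate constants to count space):

* nucleation:   a1 = k1 * n_free                 -> one new fibril of length 1
* elongation:   a2 = (k2/Omega) * n_free * W     -> +1 monomer on one fibril,
  where W is the number of fibrils ("end-catalytic", the default: each
  fibril grows from its ends) or the total fibrillar monomer count
  ("mass-autocatalytic": growth anywhere on the fibril surface)
* end-joining:  a3 = (k3/Omega) * F*(F-1)        -> an unordered pair of
  fibrils, chosen uniformly, merges into one of summed length.

The critical nucleus is one monomer.  Total monomer count is conserved
exactly (integer arithmetic) at every event.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, NoFibrilsError
from .kinetics import RateConstants, _check_variant

__all__ = [
    "FibrilPopulation",
    "GeometryParams",
    "simulate_ssa",
    "population_stats",
    "length_distribution",
]


@dataclass(frozen=True)
class FibrilPopulation:
    """Snapshot of the particle-level assembly state at one time point."""

    free: int
    lengths: np.ndarray
    time: float
    system_size: int

    def __post_init__(self):
        lengths = np.asarray(self.lengths, dtype=np.int64)
        object.__setattr__(self, "lengths", lengths)
        if self.free < 0:
            raise DomainError("free monomer count must be non-negative")
        if lengths.size and lengths.min() < 1:
            raise DomainError("fibril lengths must be >= 1 monomer")
        if self.free + int(lengths.sum()) != self.system_size:
            raise DomainError(
                "monomer conservation violated: "
                f"free ({self.free}) + fibrillar ({int(lengths.sum())}) "
                f"!= system_size ({self.system_size})"
            )

    @property
    def n_fibrils(self) -> int:
        return int(self.lengths.size)

    @property
    def converted_fraction(self) -> float:
        """Fraction of all monomers that are fibrillar (the SSA analogue of B/A0)."""
        return float(self.lengths.sum()) / self.system_size


@dataclass(frozen=True)
class GeometryParams:
    """Map monomer-unit lengths to AFM-scale geometry.

    rise_per_monomer: contour length contributed per monomer, nm.
    diameter: fibril diameter, nm (constant; lateral growth is not modelled).
    """

    rise_per_monomer: float
    diameter: float

    def __post_init__(self):
        if self.rise_per_monomer <= 0 or self.diameter <= 0:
            raise DomainError("rise_per_monomer and diameter must be positive")


def simulate_ssa(
    rates: RateConstants,
    system_size: int,
    A0: float,
    t_max: float,
    snapshot_times,
    seed: int,
    variant: str = "end-catalytic",
) -> list[FibrilPopulation]:
    """Run one exact stochastic trajectory and return population snapshots.

    Parameters
    ----------
    rates : RateConstants
        Concentration-scale rate constants (min^-1, mM^-1 min^-1).
    system_size : int
        Total monomer count at t = 0 (>= 10).
    A0 : float
        The concentration (mM) that ``system_size`` monomers represent;
        sets the volume factor Omega = system_size / A0.
    t_max : float
        Simulation horizon, min.
    snapshot_times : array-like
        Times (min, within [0, t_max]) at which to record the population.
    seed : int
        RNG seed; identical inputs and seed give identical output.
    variant : str
        Elongation weighting, see module docstring.

    Returns
    -------
    list of FibrilPopulation, one per requested snapshot time (the state
    at the last event before that time).
    """
    _check_variant(variant)
    if system_size < 10:
        raise DomainError("system_size must be >= 10")
    if A0 <= 0:
        raise DomainError("A0 must be positive")
    if t_max <= 0:
        raise DomainError("t_max must be positive")
    snapshot_times = np.sort(np.asarray(snapshot_times, dtype=float))
    if snapshot_times.size == 0:
        raise DomainError("snapshot_times must be non-empty")
    if snapshot_times[0] < 0 or snapshot_times[-1] > t_max:
        raise DomainError("snapshot times must lie within [0, t_max]")

    rng = np.random.default_rng(seed)
    omega = system_size / A0  # monomers per mM
    k2_c = rates.k2 / omega
    k3_c = rates.k3 / omega

    free = system_size
    lengths: list[int] = []
    fib_mass = 0  # sum(lengths), tracked incrementally
    t = 0.0
    snapshots: list[FibrilPopulation] = []
    next_snap = 0

    while t < t_max:
        n_fib = len(lengths)
        a1 = rates.k1 * free
        weight = n_fib if variant == "end-catalytic" else fib_mass
        a2 = k2_c * free * weight
        a3 = k3_c * n_fib * (n_fib - 1)
        a_tot = a1 + a2 + a3
        if a_tot <= 0.0:
            break
        t_next = t + rng.exponential(1.0 / a_tot)
        if t_next > t_max:
            t = t_max
            break
        # snapshots record the state immediately before the crossing time
        while next_snap < snapshot_times.size and snapshot_times[next_snap] < t_next:
            snapshots.append(
                FibrilPopulation(free, np.array(lengths, dtype=np.int64),
                                 float(snapshot_times[next_snap]), system_size)
            )
            next_snap += 1
        t = t_next
        u = rng.random() * a_tot
        if u < a1:  # nucleation: one free monomer becomes a length-1 fibril
            free -= 1
            lengths.append(1)
            fib_mass += 1
        elif u < a1 + a2:  # elongation: +1 monomer on a chosen fibril
            if variant == "end-catalytic":
                i = int(rng.integers(n_fib))
            else:  # weight fibrils by their current length
                cum = np.cumsum(lengths)
                i = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
            lengths[i] += 1
            free -= 1
            fib_mass += 1
        else:  # end-joining: merge an unordered pair chosen uniformly
            i = int(rng.integers(n_fib))
            j = int(rng.integers(n_fib - 1))
            if j >= i:
                j += 1
            lengths[i] += lengths[j]
            lengths[j] = lengths[-1]
            lengths.pop()

    # flush snapshots at or after the final time reached
    while next_snap < snapshot_times.size:
        snapshots.append(
            FibrilPopulation(free, np.array(lengths, dtype=np.int64),
                             float(snapshot_times[next_snap]), system_size)
        )
        next_snap += 1
    return snapshots


def population_stats(pop: FibrilPopulation, geom: GeometryParams) -> dict:
    """AFM-comparable summary: mean/SD contour length (nm) and mean aspect ratio.

    Contour length per fibril is ``length * rise_per_monomer``; aspect
    ratio is contour length / diameter.  SD is the sample (n-1) standard
    deviation, reported as NaN for a single fibril.
    """
    if pop.n_fibrils == 0:
        raise NoFibrilsError("population contains no fibrils")
    contour = pop.lengths * geom.rise_per_monomer
    sd = float(np.std(contour, ddof=1)) if pop.n_fibrils > 1 else float("nan")
    return {
        "n_fibrils": pop.n_fibrils,
        "mean_contour_nm": float(np.mean(contour)),
        "sd_contour_nm": sd,
        "mean_aspect_ratio": float(np.mean(contour / geom.diameter)),
    }


def length_distribution(pop: FibrilPopulation, bin_width: float, geom: GeometryParams):
    """Histogram of contour lengths (nm) with fixed-width bins from 0.

    Returns a DataFrame with columns bin_lo_nm, bin_hi_nm, count; counts
    sum to the number of fibrils.
    """
    import pandas as pd

    if bin_width <= 0:
        raise DomainError("bin_width must be positive")
    contour = pop.lengths * geom.rise_per_monomer
    n_bins = int(np.floor(contour.max() / bin_width)) + 1 if contour.size else 1
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(contour, bins=edges)
    return pd.DataFrame(
        {"bin_lo_nm": edges[:-1], "bin_hi_nm": edges[1:], "count": counts}
    )
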