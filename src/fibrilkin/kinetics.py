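"""Deterministic kinetics of nucleated, autocatalytic nanofibril self-assembly.

The model is a three-reaction scheme for the conversion of a soluble
polypeptide monomer A into fibrillar material B:

    nucleation        A      --k1-->  B          (first order in A)
    growth            A + B  --k2-->  2B         (second order)
    end-joining       B + B  --k3-->  2B         (second order in fibrils)

Nucleation creates new fibrils; growth converts monomer onto existing
fibrillar material; end-joining merges two fibrils into one, leaving the
converted mass unchanged but reducing the number of fibrils.  The state is
therefore tracked as three concentrations: free monomer ``A`` (mM),
fibrillar monomer ``B`` (mM), and fibril number ``N`` (mM of fibril ends,
i.e. number concentration).

Two readings of the growth step are supported:

``"mass-autocatalytic"``
    elongation flux proportional to fibrillar mass, dA/dt gains -k2*A*B.
    This is the classical Finke-Watzky two-step reading, which admits the
    closed form :func:`finke_watzky_closed_form` when k3 = 0.
``"end-catalytic"``
    elongation flux proportional to fibril number, dA/dt gains -k2*A*N.
    Here end-joining feeds back on the observable mass curve, so k3 is
    identifiable from a turbidity measurement; this is the default for
    fitting.

Units are minutes and mM throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .curves import KineticCurve
from .errors import ConfigurationError, DomainError, IntegrationError

__all__ = [
    "VARIANTS",
    "RateConstants",
    "AssemblyState",
    "Trajectory",
    "reaction_rhs",
    "integrate_assembly",
    "finke_watzky_closed_form",
    "mean_length_trajectory",
    "mg_per_ml_to_mM",
    "time_to_half_conversion",
]

#: Recognised model-variant tags.
VARIANTS = ("mass-autocatalytic", "end-catalytic")

#: Default solver tolerances: sigmoid curves with widely separated rate
#: constants are mildly stiff, so a stiff-capable method with tight
#: tolerances is used everywhere.
RTOL = 1e-8
ATOL = 1e-12


def _check_variant(variant: str) -> None:
    if variant not in VARIANTS:
        raise ConfigurationError(
            f"unknown model variant {variant!r}; expected one of {VARIANTS}"
        )


@dataclass(frozen=True)
class RateConstants:
    """Rate constants of the three-reaction assembly scheme.

    Attributes
    ----------
    k1 : float
        Nucleation rate constant, min^-1.
    k2 : float
        Growth (monomer addition) rate constant, mM^-1 min^-1.
    k3 : float
        Fibril end-joining rate constant, mM^-1 min^-1.
    """

    k1: float
    k2: float
    k3: float

    def __post_init__(self):
        for name in ("k1", "k2", "k3"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise DomainError(f"{name} must be finite and non-negative, got {v}")


@dataclass(frozen=True)
class AssemblyState:
    """Concentrations of free monomer A, fibrillar monomer B, fibril number N (mM)."""

    A: float
    B: float
    N: float

    def __post_init__(self):
        for name in ("A", "B", "N"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise DomainError(f"{name} must be finite and non-negative, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([self.A, self.B, self.N], dtype=float)


@dataclass(frozen=True)
class Trajectory:
    """An integrated assembly time course on a fixed time grid.

    ``A + B`` is conserved at ``A0`` (within solver tolerance) and
    ``N <= B`` at all times: a fibril contains at least one monomer.
    """

    times: np.ndarray
    A: np.ndarray
    B: np.ndarray
    N: np.ndarray
    A0: float
    variant: str

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise DomainError("trajectory times must be strictly increasing")
        for name in ("A", "B", "N"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != t.shape:
                raise DomainError(f"{name} must match the time grid shape")
            object.__setattr__(self, name, arr)
        object.__setattr__(self, "times", t)
        _check_variant(self.variant)

    def __len__(self) -> int:
        return self.times.size

    def state_at(self, i: int) -> AssemblyState:
        return AssemblyState(
            float(max(self.A[i], 0.0)),
            float(max(self.B[i], 0.0)),
            float(max(self.N[i], 0.0)),
        )

    @property
    def converted_fraction(self) -> np.ndarray:
        """B(t)/A0, the fraction of monomer converted to fibrils."""
        return self.B / self.A0

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"time_min": self.times, "A_mM": self.A, "B_mM": self.B, "N_mM": self.N}
        )


def reaction_rhs(state, rates: RateConstants, variant: str = "end-catalytic") -> np.ndarray:
    """Time derivative (dA/dt, dB/dt, dN/dt) of the assembly scheme, mM/min.

    ``dB/dt`` is computed as exactly ``-dA/dt`` so that total monomer
    ``A + B`` is conserved to the last bit.

    Parameters
    ----------
    state : AssemblyState or array-like (A, B, N)
    rates : RateConstants
    variant : {"mass-autocatalytic", "end-catalytic"}
        Whether the growth flux is k2*A*B (proportional to fibrillar mass)
        or k2*A*N (proportional to fibril number).
    """
    _check_variant(variant)
    if isinstance(state, AssemblyState):
        A, B, N = state.A, state.B, state.N
    else:
        A, B, N = (float(x) for x in state)
        if min(A, B, N) < 0:
            raise DomainError("concentrations must be non-negative")
    catalyst = B if variant == "mass-autocatalytic" else N
    dB = rates.k1 * A + rates.k2 * A * catalyst
    dN = rates.k1 * A - rates.k3 * N * N
    return np.array([-dB, dB, dN])


def integrate_assembly(
    rates: RateConstants,
    A0: float,
    times,
    variant: str = "end-catalytic",
    rtol: float = RTOL,
    atol: float = ATOL,
) -> Trajectory:
    """Integrate the assembly scheme from (A0, 0, 0) on the given time grid.

    Parameters
    ----------
    rates : RateConstants
    A0 : float
        Initial free-monomer concentration, mM (> 0).
    times : array-like
        Strictly increasing sample times in minutes, starting at 0.
    variant : str
        Model variant, see module docstring.

    Returns
    -------
    Trajectory
        With A non-increasing, B non-decreasing and |A+B-A0| <= 1e-6*A0
        at every sample.
    """
    _check_variant(variant)
    times = np.asarray(times, dtype=float)
    if not np.isfinite(A0) or A0 <= 0:
        raise DomainError(f"A0 must be positive and finite, got {A0}")
    if times.size < 1 or times[0] != 0 or (times.size > 1 and not np.all(np.diff(times) > 0)):
        raise DomainError("times must be strictly increasing and start at 0")

    def rhs(_t, y):
        A, B, N = y
        catalyst = B if variant == "mass-autocatalytic" else N
        dB = rates.k1 * A + rates.k2 * A * catalyst
        dN = rates.k1 * A - rates.k3 * N * N
        return (-dB, dB, dN)

    sol = solve_ivp(
        rhs,
        (0.0, float(times[-1]) if times[-1] > 0 else 1e-12),
        [A0, 0.0, 0.0],
        method="LSODA",
        t_eval=times if times[-1] > 0 else None,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"ODE solver failed: {sol.message}")
    if times[-1] > 0:
        A, B, N = sol.y
    else:  # degenerate single-point grid at t = 0
        A = np.array([A0])
        B = np.array([0.0])
        N = np.array([0.0])
    # clip solver round-off below zero, then restore exact conservation
    A = np.clip(A, 0.0, None)
    B = np.clip(B, 0.0, None)
    N = np.clip(N, 0.0, None)
    err = np.max(np.abs(A + B - A0))
    if err > 1e-6 * A0:
        raise IntegrationError(
            f"monomer conservation violated by {err:.3e} mM (tolerance {1e-6 * A0:.3e})"
        )
    return Trajectory(times=times, A=A, B=B, N=N, A0=A0, variant=variant)


def finke_watzky_closed_form(k1: float, k2: float, A0: float, t) -> np.ndarray:
    """Free-monomer concentration A(t) of the two-reaction nucleation +
    mass-autocatalysis scheme (the k3 = 0, mass-autocatalytic limit).

        A(t) = (k1/k2 + A0) / (1 + (k1/(k2*A0)) * exp((k1 + k2*A0) * t))

    Parameters are k1 (min^-1), k2 (mM^-1 min^-1), A0 (mM), t (min,
    scalar or array).  Raises :class:`DomainError` when k2 = 0 or A0 = 0,
    where the expression is undefined; the pure first-order limit is *not*
    silently substituted.
    """
    if not (np.isfinite(k1) and k1 > 0):
        raise DomainError(f"k1 must be positive, got {k1}")
    if not (np.isfinite(k2) and k2 > 0):
        raise DomainError(f"k2 must be positive (closed form undefined at k2=0), got {k2}")
    if not (np.isfinite(A0) and A0 > 0):
        raise DomainError(f"A0 must be positive (closed form undefined at A0=0), got {A0}")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DomainError("t must be non-negative")
    r = k1 + k2 * A0
    with np.errstate(over="ignore"):
        return (k1 / k2 + A0) / (1.0 + (k1 / (k2 * A0)) * np.exp(r * t))


def mean_length_trajectory(traj: Trajectory) -> KineticCurve:
    """Mean fibril length L(t) = B(t)/N(t) in monomer units.

    Where no fibrils exist yet (B = N = 0, e.g. at t = 0) the mean length
    is undefined and reported as NaN rather than 0.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        L = np.where(traj.N > 0, traj.B / np.where(traj.N > 0, traj.N, 1.0), np.nan)
    return KineticCurve(traj.times, L, label="mean fibril length (monomer units)")


def mg_per_ml_to_mM(c_mg_per_ml: float, mw_da: float) -> float:
    """Convert a mass concentration (mg/ml) to mM given the molar mass (Da).

    1 mg/ml of a 9700 Da monomer is 0.1031 mM.
    """
    if not np.isfinite(mw_da) or mw_da <= 0:
        raise DomainError(f"molecular weight must be positive, got {mw_da}")
    if not np.isfinite(c_mg_per_ml) or c_mg_per_ml < 0:
        raise DomainError(f"concentration must be non-negative, got {c_mg_per_ml}")
    return c_mg_per_ml * 1000.0 / mw_da


def time_to_half_conversion(
    rates: RateConstants,
    A0: float,
    variant: str = "end-catalytic",
    t_guess: float = 100.0,
    t_cap: float = 1e9,
) -> float:
    """Time t50 (min) at which half of the monomer has converted (B = A0/2).

    Found by doubling the integration horizon until B crosses A0/2, then
    interpolating on a dense grid.  Raises :class:`IntegrationError` if no
    crossing occurs below ``t_cap`` (e.g. k1 = 0).
    """
    t_max = t_guess
    while t_max < t_cap:
        times = np.linspace(0.0, t_max, 400)
        traj = integrate_assembly(rates, A0, times, variant)
        half = A0 / 2.0
        idx = np.nonzero(traj.B >= half)[0]
        if idx.size:
            i = idx[0]
            if i == 0:
                return 0.0
            t0, t1 = traj.times[i - 1], traj.times[i]
            b0, b1 = traj.B[i - 1], traj.B[i]
            return float(t0 + (half - b0) / (b1 - b0) * (t1 - t0))
        t_max *= 2.0
    raise IntegrationError(f"conversion never reached 50% below t = {t_cap} min")
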