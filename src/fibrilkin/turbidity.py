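"""Turbidity (OD340) observation model and rate-constant estimation.

Assembly is followed by light attenuation at 340 nm sampled every few
minutes.  Turbidity is modelled as linear in fibrillar monomer
concentration (small-particle Rayleigh limit):

    OD(t) = baseline + alpha * B(t)

so a measured sigmoid carries five unknowns: the three rate constants
(k1, k2, k3), the optical coefficient alpha and the baseline.  The
estimation strategy mirrors classical practice for sigmoidal assembly
curves: a smoothed-derivative analysis of the raw curve supplies initial
estimates (initial slope -> k1, maximum growth rate -> k2, plateau ->
alpha), and a multi-start nonlinear least-squares refinement against the
full ODE solution produces the reported values with approximate standard
errors.

The user-facing entry point is :class:`TurbidityKineticsModel`, whose
``fit`` returns a :class:`TurbidityKineticsResults`; ``fit_kinetics`` is a
one-call functional wrapper.
"""

from __future__ import annotations

from dataclasses import dataclass

import lmfit
import numpy as np
from scipy.signal import savgol_filter

from .curves import KineticCurve
from .errors import DomainError, FitConvergenceError, NotSaturatedError
from .kinetics import RateConstants, Trajectory, _check_variant, integrate_assembly

__all__ = [
    "ObservationModel",
    "observe_turbidity",
    "smooth_derivative",
    "initial_guess_from_derivative",
    "sigmoid_descriptors",
    "TurbidityKineticsModel",
    "TurbidityKineticsResults",
    "fit_kinetics",
]

LN10 = np.log(10.0)


@dataclass(frozen=True)
class ObservationModel:
    """Linear turbidity readout: OD = baseline + alpha * B.

    alpha is in OD per mM of fibrillar monomer; baseline in OD units.
    ``variant`` records which kinetic variant the observation refers to.
    """

    alpha: float
    baseline: float = 0.0
    variant: str = "end-catalytic"

    def __post_init__(self):
        if not np.isfinite(self.alpha) or self.alpha < 0:
            raise DomainError(f"alpha must be non-negative, got {self.alpha}")
        if not np.isfinite(self.baseline):
            raise DomainError("baseline must be finite")
        _check_variant(self.variant)


def observe_turbidity(traj: Trajectory, obs: ObservationModel) -> KineticCurve:
    """Map an assembly trajectory to an OD340 curve via OD = baseline + alpha*B."""
    return KineticCurve(traj.times, obs.baseline + obs.alpha * traj.B, label="OD340")


def smooth_derivative(curve: KineticCurve, window: int = 5, polyorder: int = 3) -> KineticCurve:
    """Savitzky-Golay smoothed first derivative dOD/dt on a uniform grid.

    Endpoints are handled by the filter's one-sided polynomial fits
    (``mode="interp"``).  A non-uniform grid raises with a message asking
    for resampling first.
    """
    if window % 2 == 0 or window <= polyorder:
        raise DomainError("window must be odd and greater than polyorder")
    if window > len(curve):
        raise DomainError("window exceeds curve length")
    dt = curve.sampling_interval  # raises on non-uniform grid
    d = savgol_filter(curve.values, window, polyorder, deriv=1, delta=dt, mode="interp")
    return KineticCurve(curve.times, d, label=f"d({curve.label})/dt")


def _plateau_and_baseline(curve: KineticCurve):
    n = len(curve)
    n_tail = max(n // 10, 2)
    plateau = float(np.mean(curve.values[-n_tail:]))
    baseline = float(np.mean(curve.values[: max(2, min(3, n))][:2]))
    return plateau, baseline, n_tail


def _require_saturated(curve: KineticCurve, deriv: KineticCurve):
    """Plateau detection: the last-decile slope must be < 1% of v_max.

    The tail slope is taken from a least-squares line through the last
    decile of the raw curve, with a two-standard-error allowance so that
    measurement noise alone does not masquerade as residual growth.
    """
    plateau, baseline, n_tail = _plateau_and_baseline(curve)
    amplitude = plateau - baseline
    v_max = float(np.max(deriv.values))
    t_tail = curve.times[-n_tail:]
    y_tail = curve.values[-n_tail:]
    X = np.column_stack([np.ones(n_tail), t_tail - t_tail[0]])
    coef, res_ss, *_ = np.linalg.lstsq(X, y_tail, rcond=None)
    tail_slope = float(coef[1])
    if n_tail > 2 and res_ss.size:
        sigma2 = float(res_ss[0]) / (n_tail - 2)
        se = np.sqrt(sigma2 / np.sum((t_tail - t_tail.mean()) ** 2))
    else:
        se = 0.0
    if v_max <= 0 or amplitude <= 0 or tail_slope >= 0.01 * v_max + 2.0 * se:
        raise NotSaturatedError(
            "curve not saturated: no plateau detected "
            f"(amplitude={amplitude:.3g}, v_max={v_max:.3g}, tail slope={tail_slope:.3g})"
        )
    return plateau, baseline, amplitude, v_max


def initial_guess_from_derivative(curve: KineticCurve, A0: float):
    """Derivative-based starting estimates for (k1, k2, k3, alpha, baseline).

    Heuristics, assuming a saturated sigmoid:

    * ``alpha ~ (plateau - baseline)/A0`` — all monomer converts;
    * ``k1 ~ (dOD/dt at t=0)/(alpha*A0)`` — the small-t expansion gives
      dB/dt(0) = k1*A0;
    * ``k2`` from the apparent growth rate of the rise: for a logistic
      sigmoid the 10-90% rise time is ln(81)/r with r ~ k1 + k2*A0 at the
      inflection (falls back to r = 4*v_max/amplitude when the crossings
      are not resolvable);
    * ``k3 = k2/2`` (no direct readout; joining is of the same order as
      growth).

    Returns ``(RateConstants, ObservationModel)``; raises
    :class:`NotSaturatedError` when no plateau is detectable.
    """
    if A0 <= 0:
        raise DomainError("A0 must be positive")
    if len(curve) < 5:
        raise DomainError("need at least 5 samples for a derivative-based guess")
    window = min(5, len(curve) - (1 - len(curve) % 2))
    deriv = smooth_derivative(curve, window=window, polyorder=min(3, window - 1))
    plateau, baseline, amplitude, v_max = _require_saturated(curve, deriv)
    alpha = amplitude / A0
    slope0 = max(float(deriv.values[0]), 1e-3 * v_max)
    k1 = slope0 / (alpha * A0)

    def first_crossing(q):
        level = baseline + q * amplitude
        idx = np.nonzero(curve.values >= level)[0]
        if idx.size == 0 or idx[0] == 0:
            return None
        i = idx[0]
        t0, t1 = curve.times[i - 1], curve.times[i]
        y0, y1 = curve.values[i - 1], curve.values[i]
        return float(t0 + (level - y0) / (y1 - y0) * (t1 - t0))

    t10, t90 = first_crossing(0.1), first_crossing(0.9)
    if t10 is not None and t90 is not None and t90 > t10:
        r = np.log(81.0) / (t90 - t10)
    else:
        r = 4.0 * v_max / amplitude
    k2 = max((r - k1) / A0, 0.1 * k1 / A0)
    k3 = k2 / 2.0
    return RateConstants(k1, k2, k3), ObservationModel(alpha, baseline)


def sigmoid_descriptors(curve: KineticCurve, window: int = 5, polyorder: int = 3) -> dict:
    """Empirical descriptors of a saturated sigmoidal curve.

    Returns a dict with:

    * ``t50`` — first time the signal crosses baseline + half the
      amplitude (linear interpolation between samples), min;
    * ``v_max`` — maximum smoothed derivative, OD/min;
    * ``lag_time`` — intercept of the tangent at maximum growth with the
      baseline, min;
    * ``plateau`` — mean of the last decile, OD.
    """
    window = min(window, len(curve) - (1 - len(curve) % 2))
    deriv = smooth_derivative(curve, window=window, polyorder=polyorder)
    plateau, baseline, amplitude, v_max = _require_saturated(curve, deriv)
    half = baseline + amplitude / 2.0
    above = np.nonzero(curve.values >= half)[0]
    i = above[0]
    if i == 0:
        t50 = float(curve.times[0])
    else:
        t0, t1 = curve.times[i - 1], curve.times[i]
        y0, y1 = curve.values[i - 1], curve.values[i]
        t50 = float(t0 + (half - y0) / (y1 - y0) * (t1 - t0))
    i_vmax = int(np.argmax(deriv.values))
    t_vmax = float(curve.times[i_vmax])
    lag = t_vmax - (float(curve.values[i_vmax]) - baseline) / v_max
    return {"lag_time": lag, "t50": t50, "v_max": v_max, "plateau": plateau}


class TurbidityKineticsModel:
    """Nonlinear least-squares model for an OD340 assembly curve.

    Fits the five parameters (k1, k2, k3, alpha, baseline) of the
    ODE-plus-linear-readout model to a measured curve.  Rate constants and
    alpha are optimised on a log10 scale, which enforces positivity; the
    baseline is fitted on its natural scale.

    Parameters
    ----------
    curve : KineticCurve
        Measured OD340 curve, >= 10 uniformly spaced samples.
    a0_mM : float
        Total monomer concentration, mM.
    variant : str
        Kinetic variant; the default "end-catalytic" makes k3 identifiable
        from turbidity (under the mass-autocatalytic reading the joining
        step does not affect B(t)).

    Examples
    --------
    >>> model = TurbidityKineticsModel(curve, a0_mM=0.103)
    >>> res = model.fit(n_starts=16, seed=0)
    >>> res.rates.k1
    """

    def __init__(self, curve: KineticCurve, a0_mM: float, variant: str = "end-catalytic",
                 rtol: float = 1e-8, atol: float = 1e-12):
        _check_variant(variant)
        if a0_mM <= 0 or not np.isfinite(a0_mM):
            raise DomainError("a0_mM must be positive and finite")
        if len(curve) < 10:
            raise DomainError("need at least 10 samples to fit five parameters")
        if not np.all(np.isfinite(curve.values)):
            raise DomainError("curve values must be finite")
        self.curve = curve
        self.a0_mM = float(a0_mM)
        self.variant = variant
        self.rtol = rtol
        self.atol = atol
        self._times = curve.times if curve.times[0] == 0 else np.concatenate(([0.0], curve.times))
        self._t_offset = 0 if curve.times[0] == 0 else 1

    @classmethod
    def from_dataframe(cls, df, a0_mM: float, time_col: str = "time_min",
                       od_col: str = "od340", **kwargs) -> "TurbidityKineticsModel":
        curve = KineticCurve(df[time_col].to_numpy(), df[od_col].to_numpy(), label="OD340")
        return cls(curve, a0_mM, **kwargs)

    def predict(self, rates: RateConstants, obs: ObservationModel) -> np.ndarray:
        """Model OD at the curve's sample times for the given parameters."""
        traj = integrate_assembly(rates, self.a0_mM, self._times, self.variant,
                                  rtol=self.rtol, atol=self.atol)
        return obs.baseline + obs.alpha * traj.B[self._t_offset:]

    def _residual(self, params) -> np.ndarray:
        rates = RateConstants(10.0 ** params["log_k1"].value,
                              10.0 ** params["log_k2"].value,
                              10.0 ** params["log_k3"].value)
        obs = ObservationModel(10.0 ** params["log_alpha"].value,
                               params["baseline"].value, self.variant)
        try:
            return self.predict(rates, obs) - self.curve.values
        except Exception:
            return np.full_like(self.curve.values, 1e6)

    def _make_params(self, rates: RateConstants, obs: ObservationModel) -> lmfit.Parameters:
        p = lmfit.Parameters()
        p.add("log_k1", value=np.log10(max(rates.k1, 1e-12)), min=-12, max=3)
        p.add("log_k2", value=np.log10(max(rates.k2, 1e-12)), min=-12, max=6)
        p.add("log_k3", value=np.log10(max(rates.k3, 1e-12)), min=-12, max=6)
        p.add("log_alpha", value=np.log10(max(obs.alpha, 1e-12)), min=-12, max=6)
        p.add("baseline", value=obs.baseline)
        return p

    def fit(self, n_starts: int = 16, seed: int = 0, guess=None,
            ftol: float = 1e-12, xtol: float = 1e-12) -> "TurbidityKineticsResults":
        """Multi-start nonlinear least squares.

        Start 0 is the derivative-based guess; the remaining starts jitter
        the four log-scale parameters log-uniformly within +-1 decade
        (seeded, so the whole fit is deterministic).  Iteration stops early
        once a start reaches a residual RMS below 1e-9 of the curve
        amplitude, which a noise-free curve at the true parameters does.

        Raises :class:`FitConvergenceError` (carrying the best partial
        result) if no start converges.
        """
        if guess is None:
            guess = initial_guess_from_derivative(self.curve, self.a0_mM)
        rates0, obs0 = guess
        rng = np.random.default_rng(seed)
        amplitude = float(np.max(self.curve.values) - np.min(self.curve.values))
        stop_rms = 1e-9 * max(amplitude, 1e-12)

        best = None
        n_used = 0
        for i in range(n_starts):
            params = self._make_params(rates0, obs0)
            if i > 0:
                for name in ("log_k1", "log_k2", "log_k3", "log_alpha"):
                    params[name].value = float(
                        np.clip(params[name].value + rng.uniform(-1.0, 1.0),
                                params[name].min + 0.1, params[name].max - 0.1))
            try:
                out = lmfit.minimize(self._residual, params, method="leastsq",
                                     ftol=ftol, xtol=xtol, max_nfev=5000)
            except Exception:
                continue
            n_used = i + 1
            if not out.success:
                continue
            rnorm = float(np.sqrt(np.sum(out.residual ** 2)))
            if best is None or rnorm < best[0]:
                best = (rnorm, out)
            if rnorm / np.sqrt(len(self.curve)) < stop_rms:
                break

        if best is None:
            raise FitConvergenceError("no optimisation start converged", partial_result=None)
        return TurbidityKineticsResults(self, best[1], n_starts_used=n_used, seed=seed)


class TurbidityKineticsResults:
    """Estimates, uncertainties and diagnostics from a turbidity fit.

    Attributes
    ----------
    rates : RateConstants
        Fitted rate constants (min^-1, mM^-1 min^-1, mM^-1 min^-1).
    obs : ObservationModel
        Fitted optical coefficient and baseline.
    bse : dict
        Approximate standard errors on the natural scale (delta method
        from the log10-scale covariance); NaN where the covariance is
        unavailable.
    residual_norm : float
        Euclidean norm of the best fit's residual vector.
    converged : bool
    n_starts_used : int
    """

    _NATURAL = {"log_k1": "k1", "log_k2": "k2", "log_k3": "k3", "log_alpha": "alpha"}

    def __init__(self, model: TurbidityKineticsModel, minimizer_result,
                 n_starts_used: int, seed: int):
        self.model = model
        self.minimizer_result = minimizer_result
        self.n_starts_used = n_starts_used
        self.seed = seed
        p = minimizer_result.params
        self.rates = RateConstants(10.0 ** p["log_k1"].value,
                                   10.0 ** p["log_k2"].value,
                                   10.0 ** p["log_k3"].value)
        self.obs = ObservationModel(10.0 ** p["log_alpha"].value,
                                    p["baseline"].value, model.variant)
        self.converged = bool(minimizer_result.success)
        self.residual_norm = float(np.sqrt(np.sum(minimizer_result.residual ** 2)))
        self.bse = {}
        for log_name, name in self._NATURAL.items():
            se_log = p[log_name].stderr
            value = 10.0 ** p[log_name].value
            self.bse[name] = value * LN10 * se_log if se_log is not None else float("nan")
        se_b = p["baseline"].stderr
        self.bse["baseline"] = se_b if se_b is not None else float("nan")

    @property
    def params(self) -> dict:
        return {"k1": self.rates.k1, "k2": self.rates.k2, "k3": self.rates.k3,
                "alpha": self.obs.alpha, "baseline": self.obs.baseline}

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.model.predict(self.rates, self.obs)

    @property
    def resid(self) -> np.ndarray:
        return self.fittedvalues - self.model.curve.values

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        units = {"k1": "min^-1", "k2": "mM^-1 min^-1", "k3": "mM^-1 min^-1",
                 "alpha": "OD/mM", "baseline": "OD"}
        lines = [
            "Turbidity assembly kinetics fit",
            "=" * 55,
            f"variant:        {self.model.variant}",
            f"A0:             {self.model.a0_mM:.4g} mM",
            f"n observations: {len(self.model.curve)}",
            f"residual norm:  {self.residual_norm:.4g}",
            f"converged:      {self.converged}  (starts used: {self.n_starts_used}, seed {self.seed})",
            "-" * 55,
            f"{'param':<10}{'estimate':>14}{'std err':>14}  unit",
        ]
        for name, value in self.params.items():
            lines.append(f"{name:<10}{value:>14.5g}{self.bse[name]:>14.3g}  {units[name]}")
        lines.append("=" * 55)
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "variant": self.model.variant,
            "a0_mM": self.model.a0_mM,
            "params": self.params,
            "stderr": {k: (None if np.isnan(v) else float(v)) for k, v in self.bse.items()},
            "residual_norm": self.residual_norm,
            "converged": self.converged,
            "n_starts_used": self.n_starts_used,
            "seed": self.seed,
        }

    def plot(self, ax=None):
        """Data, fitted curve and residuals on a matplotlib axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.model.curve.times, self.model.curve.values, "o", ms=3, label="data")
        ax.plot(self.model.curve.times, self.fittedvalues, "-", label="fit")
        ax.set_xlabel("time (min)")
        ax.set_ylabel("OD340")
        ax.legend()
        return ax


def fit_kinetics(curve: KineticCurve, A0: float, variant: str = "end-catalytic",
                 n_starts: int = 16, seed: int = 0) -> TurbidityKineticsResults:
    """One-call wrapper: build a :class:`TurbidityKineticsModel` and fit it."""
    return TurbidityKineticsModel(curve, A0, variant).fit(n_starts=n_starts, seed=seed)
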