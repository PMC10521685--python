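"""Seeded synthetic-data generators for every input the analysis consumes.

The generators emulate the study conditions of the assembly experiments:
OD340 turbidity curves sampled every 10 min at three monomer
concentrations (1, 5 and 10 mg/ml of a 9.7 kDa monomer), CD spectral
series following the coil-to-helix transition, AFM-scale fibril length
samples, and triplicate qPCR Ct tables with known group effects.  Rate
constants for the three concentrations are stored exactly as measured
(``RATE_PRESETS``), so any stage of the pipeline can be exercised against
a known ground truth without downloading data.

All generators are pure functions of their parameters and a seed.
Noise is additive Gaussian everywhere; defaults are 1% of the turbidity
plateau, 2% of the CD band amplitude and 0.1 Ct cycles.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cd import BasisSet, CDSpectrum
from .curves import KineticCurve
from .errors import DomainError
from .kinetics import (RateConstants, Trajectory, integrate_assembly,
                       mg_per_ml_to_mM, time_to_half_conversion)
from .turbidity import ObservationModel, observe_turbidity

__all__ = [
    "GeneratorConfig",
    "RATE_PRESETS",
    "LENGTH_PRESETS",
    "DIAMETER_NM",
    "MONOMER_MW_DA",
    "preset_a0_mM",
    "gen_turbidity",
    "gen_cd_series",
    "gen_fibril_lengths",
    "gen_ct_table",
]

#: Monomer molar mass (Da); the MS-resolved monomer species.
MONOMER_MW_DA = 9700.0

#: Fibril diameter observed by AFM, nm (constant across concentrations).
DIAMETER_NM = 10.0

#: Measured rate constants (k1 min^-1; k2, k3 mM^-1 min^-1) keyed by the
#: monomer mass concentration in mg/ml.
RATE_PRESETS: dict[float, RateConstants] = {
    1.0: RateConstants(k1=1.4e-3, k2=6.5e-3, k3=3.4e-3),
    5.0: RateConstants(k1=1.6e-3, k2=1.6e-2, k3=4.8e-3),
    10.0: RateConstants(k1=9.9e-3, k2=7.4e-3, k3=4.9e-3),
}

#: Equilibrium contour-length statistics (mean nm, SD nm) per mg/ml.
LENGTH_PRESETS: dict[float, tuple[float, float]] = {
    1.0: (579.0, 115.0),
    5.0: (578.0, 86.0),
    10.0: (628.0, 94.0),
}


def preset_a0_mM(c_mg_per_ml: float) -> float:
    """Molar concentration (mM) of a preset mass concentration."""
    return mg_per_ml_to_mM(c_mg_per_ml, MONOMER_MW_DA)


@dataclass(frozen=True)
class GeneratorConfig:
    """Shared knobs of the synthetic-data generators.

    Attributes
    ----------
    seed : int
        Seed for all randomness; a fixed seed gives byte-identical output.
    noise_sd : float
        Additive Gaussian noise SD in the generator's observation units
        (OD for turbidity, ellipticity units for CD, cycles for Ct).
    sampling_interval : float
        Observation spacing, min (acquisition every 10 min by default).
    a0_mg_per_ml, mw_da : float
        Mass concentration and molar mass used for mM conversion.
    """

    seed: int = 0
    noise_sd: float = 0.01
    sampling_interval: float = 10.0
    a0_mg_per_ml: float = 1.0
    mw_da: float = MONOMER_MW_DA

    @property
    def a0_mM(self) -> float:
        return mg_per_ml_to_mM(self.a0_mg_per_ml, self.mw_da)

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=seed)


def gen_turbidity(
    rates: RateConstants,
    A0: float,
    obs: ObservationModel,
    t_max: float | None = None,
    cfg: GeneratorConfig = GeneratorConfig(),
    variant: str = "end-catalytic",
) -> KineticCurve:
    """Synthetic OD340 curve: integrate, observe, add Gaussian noise.

    ``t_max`` defaults to 10 * t50 so the plateau is well established;
    sampling is every ``cfg.sampling_interval`` minutes starting at 0.
    With ``cfg.noise_sd = 0`` the output equals the noise-free
    observation exactly.
    """
    if t_max is None:
        t_max = 10.0 * time_to_half_conversion(rates, A0, variant)
    n = int(np.floor(t_max / cfg.sampling_interval))
    times = np.arange(n + 1) * cfg.sampling_interval
    traj = integrate_assembly(rates, A0, times, variant)
    curve = observe_turbidity(traj, obs)
    if cfg.noise_sd == 0:
        return curve
    rng = np.random.default_rng(cfg.seed)
    noisy = curve.values + rng.normal(0.0, cfg.noise_sd, size=curve.values.shape)
    return KineticCurve(curve.times, noisy, label=curve.label)


def gen_cd_series(
    kinetics: Trajectory,
    basis: BasisSet,
    cfg: GeneratorConfig = GeneratorConfig(noise_sd=0.0),
) -> list[CDSpectrum]:
    """CD spectra along an assembly trajectory.

    The helix fraction tracks conversion, f(t) = B(t)/A0, so the t = 0
    spectrum is the coil basis and the late-time spectrum approaches the
    helix basis.  Gaussian noise of SD ``cfg.noise_sd`` (ellipticity
    units) is added independently per wavelength.
    """
    rng = np.random.default_rng(cfg.seed)
    series = []
    f = kinetics.converted_fraction
    for i, t in enumerate(kinetics.times):
        values = basis.combine(float(f[i]))
        if cfg.noise_sd > 0:
            values = values + rng.normal(0.0, cfg.noise_sd, size=values.shape)
        series.append(CDSpectrum(basis.wavelengths, values, time=float(t)))
    return series


def gen_fibril_lengths(mean_nm: float, sd_nm: float, n: int,
                       cfg: GeneratorConfig = GeneratorConfig()) -> np.ndarray:
    """Lognormal contour-length sample (nm) with moments matched to (mean, sd).

    The lognormal respects positivity and the right skew of AFM length
    histograms.  ``sd_nm = 0`` degenerates to a constant sample.
    """
    if mean_nm <= 0 or sd_nm < 0 or n < 1:
        raise DomainError("need mean_nm > 0, sd_nm >= 0, n >= 1")
    if sd_nm == 0:
        return np.full(n, mean_nm)
    cv2 = (sd_nm / mean_nm) ** 2
    sigma2 = np.log1p(cv2)
    mu = np.log(mean_nm) - sigma2 / 2.0
    rng = np.random.default_rng(cfg.seed)
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)


def gen_ct_table(
    genes,
    groups,
    true_log2_effects: dict,
    n_replicates: int = 3,
    noise_sd_cycles: float = 0.1,
    cfg: GeneratorConfig = GeneratorConfig(),
    ref_gene: str = "actin",
    base_ct: float = 20.0,
) -> pd.DataFrame:
    """Balanced Ct table with specified log2 expression effects.

    ``true_log2_effects`` maps ``(gene, group)`` to the log2 fold change
    relative to the control; unspecified cells default to 0.  A gene
    up-regulated by e log2 units amplifies e cycles earlier, so
    ct = base_ct - effect + noise.  The reference gene must not carry an
    effect (its role is to be invariant).
    """
    genes = list(genes)
    groups = list(groups)
    if ref_gene not in genes:
        genes = [ref_gene] + genes
    for (g, grp), eff in true_log2_effects.items():
        if g == ref_gene and eff != 0:
            raise DomainError("the reference gene must have zero effect")
        if g not in genes or grp not in groups:
            raise DomainError(f"effect specified for unknown cell ({g!r}, {grp!r})")
    rng = np.random.default_rng(cfg.seed)
    records = []
    for gene in genes:
        for group in groups:
            effect = true_log2_effects.get((gene, group), 0.0)
            for rep in range(1, n_replicates + 1):
                noise = rng.normal(0.0, noise_sd_cycles) if noise_sd_cycles > 0 else 0.0
                records.append({"gene": gene, "group": group, "replicate": rep,
                                "ct": base_ct - effect + noise})
    return pd.DataFrame.from_records(records)
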