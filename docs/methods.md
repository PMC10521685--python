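# Methods

## The kinetic scheme

fibrilkin models the self-assembly of a polypeptide monomer into
nanofibrils with three elementary reactions:

| reaction | rate constant | meaning |
|---|---|---|
| A → B | k1 (min⁻¹) | nucleation: a free monomer becomes the smallest fibril (critical nucleus = 1 monomer) |
| A + B → 2B | k2 (mM⁻¹ min⁻¹) | autocatalytic growth: monomer addition onto fibrillar material |
| B + B → 2B | k3 (mM⁻¹ min⁻¹) | end-joining: two fibrils coalesce into one |

State variables are concentrations in mM: free monomer `A`, fibrillar
monomer `B`, and fibril number `N`. End-joining is stoichiometrically
neutral on `A` and `B` — written on concentrations it only removes one
fibril per event, so it appears as `dN/dt −= k3·N²` and leaves the mass
balance untouched. Mass conservation `A + B = A0` is built into the
right-hand side exactly (`dB/dt := −dA/dt`).

The printed units of k2 and k3 (mM·min⁻¹) are dimensionally inconsistent
with second-order reactions; the package treats both as second-order
constants in mM⁻¹·min⁻¹ throughout.

### Two readings of the growth step

The scheme does not say whether elongation scales with fibrillar *mass*
or with the number of fibril *ends*. Both are implemented:

- `mass-autocatalytic`: `dA/dt = −k1·A − k2·A·B`. This is the classical
  Finke–Watzky two-step reading. With k3 = 0 it has the closed form
  `A(t) = (k1/k2 + A0) / (1 + (k1/(k2·A0))·exp((k1 + k2·A0)·t))`,
  which the solver is verified against to 1 × 10⁻⁶ relative. Under this
  reading k3 never enters `B(t)`, so it cannot be estimated from a
  turbidity curve.
- `end-catalytic` (default for fitting): `dA/dt = −k1·A − k2·A·N`.
  End-joining reduces `N` and therefore feeds back on the observable
  mass curve, making all three constants identifiable from turbidity.
  This is why the default fitting variant is end-catalytic: a k3 value
  reported from turbidity data is only meaningful under this reading.

Integration uses LSODA with rtol 1 × 10⁻⁸, atol 1 × 10⁻¹² (the curves are
mildly stiff when the rate constants are widely separated). The initial
condition is (A0, 0, 0) unless the caller seeds nuclei.

A useful consequence of the model worth knowing when reading curves: the
conversion `B(t)/A0` is sigmoidal (single inflection at t > 0) only when
autocatalysis outruns nucleation, k2·A0 > k1. At the 1 and 10 mg/ml
rate-constant presets k2·A0 < k1, so those model curves are concave,
saturating rather than lag-phased; the 5 mg/ml preset is genuinely
sigmoidal. The fitting machinery does not assume an inflection.

## Turbidity observation and fitting

Turbidity is modelled as linear in fibrillar monomer concentration,
`OD(t) = baseline + α·B(t)` (small-particle Rayleigh limit). A
length-weighted readout (OD ∝ Σ length²) is deliberately not
implemented.

Fitting estimates all five of (k1, k2, k3, α, baseline) by nonlinear
least squares against the full ODE solution:

1. **Derivative-based initial guess.** The plateau gives α; the initial
   smoothed slope gives k1 via `dB/dt(0) = k1·A0`; the 10–90% rise time
   gives the apparent logistic rate r = ln(81)/(t90−t10) and
   k2 ≈ (r − k1)/A0; k3 starts at k2/2. Derivatives use a
   Savitzky–Golay filter (window 5, cubic), whose peak value is accurate
   to ~0.2% on a logistic sampled every 10 min.
2. **Plateau detection.** A curve is accepted for sigmoid analysis when
   the least-squares slope of its last decile is below 1% of the maximum
   growth rate, plus a two-standard-error allowance so that measurement
   noise alone does not read as residual growth. Unsaturated curves
   raise an explicit error rather than returning extrapolated constants.
3. **Multi-start refinement.** Rate constants and α are optimised as
   log10-parameters (positivity by construction); the baseline is linear.
   Default 16 starts: the guess itself plus 15 jitters drawn
   log-uniformly within ±1 decade (seeded, so fits are deterministic).
   The loop stops early once a start reaches a residual RMS below 10⁻⁹
   of the curve amplitude — attainable only in the noise-free regime,
   where further starts cannot improve the optimum. Standard errors on
   the natural scale come from the delta method applied to the
   log10-scale covariance.

On noise-free synthetic curves this recovers all three generating
constants to better than 10⁻⁹ relative at every concentration preset;
with Gaussian noise of 1% of the plateau, the median relative error of
k1 over 20 replicates stays below 10%.

Empirical descriptors (lag time by tangent intercept, t50 by
half-amplitude crossing, v_max, plateau) are exposed separately and make
no parametric assumption beyond saturation.

## Stochastic fibril simulator

`simulate_ssa` is a direct Gillespie realisation of the same scheme at
single-monomer resolution, tracking every fibril's length. Propensities
use the volume factor Ω = system_size/A0 to convert the second-order
concentration constants to count space, which makes SSA ensembles
directly comparable to the ODE: at system size 5000 the ensemble mean
converted fraction at t50 agrees with the ODE value within Monte-Carlo
error, and the ensemble spread shrinks as the system grows.

Design choices at particle scale: the critical nucleus is one monomer;
elongation adds exactly one monomer per event to a fibril chosen
uniformly (end-catalytic) or length-weighted (mass-autocatalytic);
joining merges a uniformly chosen unordered pair. Monomer count is
conserved exactly — in integers — at every event. The direct method with
per-event propensity recomputation is adequate at desk scale (≤10⁵
monomers); no fragmentation, depolymerisation or lateral growth is
modelled (fibril diameter is observed to stay ~10 nm).

Geometry: monomer-unit lengths are mapped to AFM-comparable contour
lengths by a user-supplied rise per monomer (nm) and fixed diameter
(default 10 nm); the rise is not known from the data, so fixtures choose
values that put equilibrium contour lengths in the observed
several-hundred-nm range. Aspect ratio = contour length / diameter.

## CD coil→helix analysis

Spectra are treated in arbitrary ellipticity units (mdeg in fixtures);
no path-length or mean-residue normalisation is applied because the two
readouts are a ratio and a fraction, both scale-free.

- **Band ratio** |θ(222)|/|θ(198)|, each band averaged over a ±2 nm
  window (robust to 1 nm grids without blurring the bands). The
  numerator band tracks α-helix, the denominator random coil, so the
  ratio rises monotonically as assembly converts coil to helix.
- **Two-state decomposition** solves spec ≈ f·helix + (1−f)·coil in
  closed form and clips f to [0, 1]; it is exact to machine precision on
  noiseless mixtures. A β-sheet component is intentionally absent — the
  transition modelled is coil→helix only.
- **Transition kinetics** reduces a timestamped series to f(t) and fits
  the single-exponential relaxation f(t) = f∞ + (f0−f∞)e^(−kt);
  non-monotone series are flagged but still fitted.

The reference basis spectra are synthetic Gaussian bands (coil: negative
198 nm band; helix: positive 191 nm, negative 208 and 222 nm bands).
The positive helix band is kept narrow (σ 2.5 nm) so the helix signal in
the 198 nm window remains negative; this keeps the band ratio finite and
strictly monotone along any coil→helix series, which real helix spectra
(strongly positive near 195 nm) would not guarantee. Fractions and
ratios are unaffected by this stylisation; users with measured basis
spectra can supply their own `BasisSet`.

## qPCR fold changes

The 2^(−ΔΔCt) readout uses the Livak convention: ΔCt is computed within
replicate against the reference gene (actin by default), ΔΔCt against
the *mean* ΔCt of the control group, fold = 2^(−ΔΔCt). Amplification
efficiency is fixed at 2; no efficiency correction. Whether the original
analysis paired replicates or used group means is not stated — under a
balanced design both give identical group means, so the documented
convention is used throughout. Significance testing (ANOVA) is left to
standard statistics packages.

## Synthetic data generators

All generators are pure functions of their parameters and a seed.
Defaults encode the study conditions: 10-min sampling; A0 from mg/ml at
the 9.7 kDa monomer mass (the MS-resolved monomer; the 19.3 kDa species
is the +1 charge state of the dimer-mass ambiguity, resolved in favour
of the monomer and configurable); rate-constant presets per
concentration stored exactly as measured

| c (mg/ml) | k1 (min⁻¹) | k2 (mM⁻¹min⁻¹) | k3 (mM⁻¹min⁻¹) | A0 (mM) |
|---|---|---|---|---|
| 1 | 1.4e−3 | 6.5e−3 | 3.4e−3 | 0.1031 |
| 5 | 1.6e−3 | 1.6e−2 | 4.8e−3 | 0.5155 |
| 10 | 9.9e−3 | 7.4e−3 | 4.9e−3 | 1.0309 |

Noise is additive Gaussian everywhere (no error model is available to
emulate): defaults 1% of plateau for turbidity, 2% of band amplitude
for CD, 0.1 cycles for Ct tables. Fibril-length samples are lognormal
with moments matched to the observed mean ± SD (579 ± 115 nm at
1 mg/ml, etc.), respecting positivity and right skew. CD series tie the
helix fraction to conversion, f(t) = B(t)/A0.

What the generators do *not* emulate — and hence what passing tests do
not show about real data: instrument drift and correlated noise in
turbidity; scattering contributions to CD below 200 nm; AFM tip
convolution and surface-deposition bias in length distributions;
pipetting/plate effects and efficiency differences in qPCR. Round-trip
tests demonstrate that the estimators are correct under the stated
model, not that the model is correct for any particular instrument.

## Problem sizes

Default test and acceptance runs use curves of 60–450 samples (10-min
sampling over 10·t50), SSA ensembles of 200 replicates at 5000 monomers,
10⁵-draw length samples, and triplicate Ct tables — sizes chosen so the
statistical claims (3-SE agreement, 1%/3% moment recovery) are sharp at
desk scale.

## Known limitations

- k3 is identifiable from turbidity only under the end-catalytic
  reading; a mass-autocatalytic fit of k3 returns the lower bound.
- The weakly sigmoidal presets (k2·A0 < k1) make k2 and k3 nearly flat
  directions under strong noise; standard errors from the fit reflect
  this and should be read before quoting the constants.
- No global multi-curve fitting across concentrations; curves are fitted
  one at a time.
- The closed form applies only to the mass-autocatalytic, k3 = 0 limit;
  no closed form exists for the end-catalytic variant.
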