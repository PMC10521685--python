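# fibrilkin

Kinetic analysis of polypeptide nanofibril self-assembly.

Designed biomimetic polypeptides (spidroin-derived backbones fused to
RGD/IKVAV cell-binding motifs) assemble from soluble monomer into
elongated nanofibrils. This package implements the quantitative pipeline
around such an experiment: a mechanistic model of the assembly reaction,
estimation of its rate constants from turbidity (OD340) time courses,
a particle-level stochastic simulator producing AFM-comparable fibril
length statistics, circular-dichroism analysis of the accompanying
coil→helix transition, and the 2^(−ΔΔCt) readout for downstream gene
expression — plus seeded generators for synthetic versions of every
input, so the whole pipeline is testable without instrument data.

## The model

Assembly of monomer A into fibrillar material B follows three reactions:

```
nucleation      A     --k1-->  B        k1  [min⁻¹]
growth          A + B --k2-->  2B       k2  [mM⁻¹ min⁻¹]
end-joining     B + B --k3-->  2B       k3  [mM⁻¹ min⁻¹]
```

tracked as three concentrations: free monomer A, fibrillar monomer B,
and fibril number N, with A + B = A0 conserved. End-joining merges two
fibrils (dN/dt gains −k3·N²) without changing the converted mass. Two
readings of the growth step are provided — elongation proportional to
fibrillar mass (the classical Finke–Watzky two-step model, with its
closed-form sigmoid as a verified limit) or to fibril number
(end-catalytic, the default, under which k3 is identifiable from
turbidity). Turbidity is modelled as OD(t) = baseline + α·B(t), and
(k1, k2, k3, α, baseline) are estimated by multi-start nonlinear least
squares seeded from a smoothed-derivative analysis of the curve.
See `docs/methods.md` for the full account.

## Worked example

Generate a noisy synthetic OD340 curve at the 5 mg/ml condition
(A0 = 0.5155 mM of a 9.7 kDa monomer, 10-min sampling, 1% plateau
noise) and refit it:

```python
import fibrilkin as fk

rates, a0 = fk.RATE_PRESETS[5.0], fk.preset_a0_mM(5.0)
obs = fk.ObservationModel(alpha=1.0 / a0, baseline=0.02)
curve = fk.gen_turbidity(rates, a0, obs,
                         cfg=fk.GeneratorConfig(seed=42, noise_sd=0.01))

res = fk.fit_kinetics(curve, a0, n_starts=16, seed=0)
print(res.summary())
```

```
Turbidity assembly kinetics fit
=======================================================
variant:        end-catalytic
A0:             0.5155 mM
n observations: 240
residual norm:  0.1384
converged:      True  (starts used: 16, seed 0)
-------------------------------------------------------
param           estimate       std err  unit
k1             0.0015816      9.97e-05  min^-1
k2              0.016911       0.00212  mM^-1 min^-1
k3             0.0063659       0.00166  mM^-1 min^-1
alpha             1.9433        0.0096  OD/mM
baseline        0.018227       0.00504  OD
=======================================================
```

The generating constants were (k1, k2, k3) = (1.6e−3, 1.6e−2, 4.8e−3):
k1 and k2 come back within their standard errors, while k3 — the most
weakly identified parameter — is recovered to the right order with an
honest ~25% uncertainty. Model-free curve descriptors are available
separately:

```python
fk.sigmoid_descriptors(curve)
# {'lag_time': 28.97, 't50': 242.97, 'v_max': 0.0035, 'plateau': 1.0188}
```

i.e. a ~29 min lag, half-conversion at ~243 min, and a maximum growth
rate of 0.0035 OD/min. The same rate constants drive the particle-level
simulator, whose snapshots carry every fibril's length:

```python
snaps = fk.simulate_ssa(rates, system_size=5000, A0=a0, t_max=2400.0,
                        snapshot_times=[2400.0], seed=1)
geom = fk.GeometryParams(rise_per_monomer=150.0, diameter=10.0)
fk.population_stats(snaps[-1], geom)
# {'n_fibrils': 717, 'mean_contour_nm': 1045.8,
#  'sd_contour_nm': 990.0, 'mean_aspect_ratio': 104.6}
```

CD spectra series, qPCR Ct tables and fibril-length samples have
analogous generator/analysis pairs (`gen_cd_series` /
`decompose_two_state` / `transition_kinetics`, `gen_ct_table` /
`delta_delta_ct`, `gen_fibril_lengths`). All file formats are headered
delimited text; see `fibrilkin.io`.

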