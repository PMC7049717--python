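# smtkinetics

Analysis of single-molecule tracking (SMT) experiments on DNA-binding
proteins in live bacteria — built around the kind of experiment in
which a photoconvertible-tagged transcription regulator (e.g. the
zinc-uptake regulator Zur, a homodimeric Fur-family metalloregulator in
*E. coli*) is tracked stroboscopically until photobleaching, while the
per-cell protein concentration is measured by bulk photoconversion
(SCQPC).  The package resolves the molecule's diffusion states,
extracts chromosome residence times, and quantifies how the apparent
unbinding rate constant depends on the cellular protein concentration —
including the *biphasic* regime in which unbinding is first impeded
(protein oligomerization on DNA) and then facilitated (ternary-complex
formation) as concentration rises.

## What it computes

**Diffusion-state deconvolution.**  Under stroboscopic time-lapse
imaging (4 ms excitation pulses every 40 ms), the per-lapse
displacement length *r* of a Brownian state with diffusion constant *D*
obeys a Rayleigh law; *r*² is exponential with mean
4 *D* *T*<sub>tl</sub> + 4σ², where σ is the localization precision.
`DisplacementMixtureModel` fits a mixture of such components by
maximum likelihood (EM), with the *D*'s shared globally across
concentration groups and the fractional populations free per group —
resolving freely diffusing (FD), nonspecifically bound (NB) and
tightly bound (TB) states.

**Residence-time kinetics.**  Runs of consecutive displacements below
a threshold *r*₀ = 0.2 μm (capturing >99.5% of TB displacements) give
residence times τ.  `DwellTimeModel` fits their distribution with a
three-component discrete dwell model that deconvolves chance FD/NB
sub-threshold runs, corrects for photobleaching/blinking (rate measured
from the track on-time distribution), and handles runs censored by
track ends — yielding the apparent unbinding rate constant *k*₋₁.

**Biphasic unbinding rate law.**  Across concentration groups,
`BiphasicUnbindingModel` fits

  *k*₋₁([P]) = *k*ₒ<sup>off</sup> + *k*ᵣ (e^(−[P]_FD/*K*ₘ) − 1) + *k*_f [P]_FD

where *k*ₒ<sup>off</sup> = *k*ₒ + *k*ᵣ is the spontaneous unbinding
rate at zero concentration, the exponential term is the
oligomerization-impeded component with effective oligomer dissociation
constant *K*ₘ, and *k*_f [P]_FD is the facilitated component.  The
curve has an interior minimum at *P*_min = *K*ₘ ln(*k*ᵣ/(*k*_f *K*ₘ))
iff *k*ᵣ > *k*_f *K*ₘ — the biphasic signature.  A nested linear
(facilitated-only) fit and an information criterion decide whether the
impeded term is warranted.

**Populations and concentrations.**  `EquilibriumPopulationModel` fits
the FD/NB/TB fractions versus total concentration with a competitive
site-depletion isotherm (K_d1, K_d2, site capacities), supplying the
free-dimer concentrations; `scqpc` converts tracked counts + residual
photoconverted fluorescence into per-cell dimer concentrations using
the spherocylinder cell volume; `spatial` tests residence sites for
molecular-scale clustering against a uniform random null in the same
cell geometry.

**Simulation.**  `simulate_tracks` generates the whole observation
chain — three-state Markov switching, Brownian motion confined to a
spherocylinder, stroboscopic sampling, localization noise, and
exponential bleaching — so every stage is validated by parameter
recovery on data with known truth.

## Worked example

```python
import numpy as np
from smtkinetics import (BiphasicParams, BiphasicUnbindingModel,
                         DisplacementMixtureModel, DisplacementSet,
                         bootstrap_sd, rate_apparent)

rng = np.random.default_rng(0)

# resolve three diffusion states from 50k synthetic displacements
D_true, f_true = np.array([6.7, 0.82, 0.033]), np.array([0.181, 0.472, 0.347])
comp = rng.choice(3, size=50_000, p=f_true)
r = np.sqrt(rng.exponential(4 * D_true[comp] * 0.040))
model = DisplacementMixtureModel(DisplacementSet(r, t_lapse=0.040),
                                 n_states=3, sigma_loc=0.0)
print(bootstrap_sd(model, 50, seed=1, fit=model.fit()).summary())

# fit the biphasic unbinding law to noisy rate-vs-concentration data
truth = BiphasicParams(k_o_off=22, k_r=12, k_f=0.018, K_m=12)
P = np.geomspace(8, 1500, 8)
k = rate_apparent(truth, P) * (1 + 0.05 * rng.standard_normal(8))
print(BiphasicUnbindingModel(P, k, 0.05 * k).fit(n_boot=200, seed=2).summary())
```

prints

```
Displacement mixture fit (3 states, 50000 displacements, logL = 56602.9, converged)
 state   D (um^2/s)        sd
    FD        6.761     0.113
    NB       0.8161    0.0113
    TB      0.03308  0.000404
fractions per group:
  all: FD=0.181+-0.003, NB=0.469+-0.004, TB=0.350+-0.003

Biphasic unbinding fit (apparent rate law, weighted NLS)
  k_o_off = 21.53 +- 3.24 1/s
  k_r     = 11.79 +- 3.1 1/s
  k_f     = 0.0172 +- 0.00119 1/(nM s)
  K_m     = 14.81 +- 5.32 nM
  chi2 = 1.93 (n = 8), AIC = 9.9 vs linear 67.2 -> biphasic
  rate minimum at P_FD = 56.8 nM
```

The mixture fit recovers the three diffusion constants and fractions
it was handed (within bootstrap error), and the rate-law fit recovers
the generating kinetic parameters, prefers the biphasic over the
linear model, and places the unbinding-rate minimum at ~57 nM free
dimer — i.e. unbinding is impeded below that concentration and
facilitated above it.

The end-to-end driver chains everything on simulated or supplied data:

```
smtkin run-all --seed 1 --out results/
```

writes `summary.json` (condensed kinetic/thermodynamic parameter
table), the per-group `k_minus1_table.tsv`, state-fraction and spatial
ratio tables.  `smtkin simulate`, `scqpc`, `fit-diffusion`,
`fit-residence`, `fit-unbinding`, `fit-population` and `spatial` run
the stages individually.

## Layout

```
src/smtkinetics/
  geometry.py    spherocylinder volume, uniform sampling, reflection
  simulate.py    three-state CTMC + confined Brownian + imaging model
  diffusion.py   displacement statistics, mixture fit, bootstrap
  residence.py   tau extraction, bleach rate, dwell-time model
  unbinding.py   biphasic rate law, minimum location, weighted fit
  scqpc.py       per-cell concentration, concentration grouping
  population.py  equilibrium site-binding isotherm fit
  spatial.py     PWDD, random-site null, fraction-within-R ratios
  pipeline.py    end-to-end driver; config.py; cli.py
docs/methods.md  model details, assumptions, limitations
```
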