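# Methods

This note records the models implemented, the assumptions and numerical
choices behind them, what the synthetic-data generator does and does
not emulate, and the known limitations.

## Observation model

A tagged protein is imaged stroboscopically: short excitation pulses
(default t_exposure = 4 ms) separated by a time lapse (default
t_lapse = 40 ms), 30 frames per photoconversion cycle, with isotropic
Gaussian localization error (default sigma_loc = 20 nm).  The camera
sees the (x, y) projection of 3D motion inside the cell.  Tracks end
at the first photobleach/blink event; blinking is pooled with
bleaching into a single effective termination rate k_bleach and tracks
are never gap-closed, so a blink looks like a track end.  k_bleach is
defined on the elapsed-time axis: the per-frame survival probability
is exp(-k_bleach * t_lapse), and it is estimated by exponential
maximum likelihood on the on-time distribution (frames x t_lapse) of
all tracks.  Motion blur within the short pulse is neglected — at the
diffusion constants of the bound states the within-pulse displacement
is below the localization error; for the freely diffusing state this
approximation understates blur, which is one reason the fast-state D
from confined-cell data is treated as *effective*.

## Cell geometry

Cells are spherocylinders (cylinder of radius r with hemispherical
caps; long axis = x, origin at the cell center).  Volume is
pi r^2 (L - 2r) + (4/3) pi r^3 and is used both for concentration
conversion (1 molecule in 1.66 fL is ~1 nM) and for the spatial null.
Uniform sampling inside the cell is by rejection from the bounding box
— exactly uniform, at a ~50% acceptance cost that is irrelevant at the
sizes used.  A seed is mandatory everywhere randomness enters.
Default dimensions (L = 3.0 um, r = 0.5 um) are typical rod-shaped
*E. coli* values; they are configuration, not claims.

## Trajectory simulator

Each molecule carries a hidden state in {FD, NB, TB} evolving as a
continuous-time Markov chain with pseudo-first-order effective binding
rates (no explicit site bookkeeping; the per-molecule scheme is FD<->TB,
FD<->NB and optionally NB<->TB).  Propagation uses a 1 ms step: per
step the molecule switches state with probability 1 - exp(-q_i dt)
(destination by branching ratios; exact for at most one event per
step, an error of order (q dt)^2 ~ 1e-3 at the rates of interest) and
takes a Brownian step with the current state's D, mirror-reflected at
the membrane.  Observed positions add localization noise to the true
position at the frame time.  The generator reproduces, by
construction, the stationary occupancy of the rate matrix, the
single-state displacement law, and geometric track lengths — each is
verified against an independent oracle in the tests.

What it does not emulate: camera images and spot detection (the
pipeline starts from localized tracks), z-dependent detection
efficiency, motion blur, gap closing, chromosome structure (binding
sites are implicit, so simulated residence sites are spatially
uniform), and cell growth during acquisition.  Passing recovery tests
therefore validates the *estimators* under the stated observation
model, not the upstream image processing of real data.

## Diffusion-state deconvolution

For a 2D Brownian state the squared per-lapse displacement r^2 is
exponential with mean 4 D t_lapse + 4 sigma_loc^2; localization error
enters as a fixed +4 sigma^2 variance inflation (sigma is measured
upstream; floating it trades off against the slowest D).  A population
in k states gives a k-component exponential mixture.  The fit is
maximum likelihood via EM with component scales shared across all
concentration groups and weights free per group; this "global
analysis" is what makes the slow, rare states identifiable in
low-concentration groups.  Scales are floored at the pure-noise value
4 sigma^2 (a state cannot appear narrower than the localization
error).  Initialization is by log-quantiles of r^2; convergence on
relative log-likelihood change < 1e-10 (cap 2000 iterations); states
are reported sorted by D descending (FD, NB, TB) and near-duplicate
scales (within 5%) are flagged.  An empirical-CDF least-squares mode
(`fit_cdf`) is provided as a cross-check; the two agree on
well-separated mixtures.  Uncertainties are cell-level bootstrap
(resampling cells with replacement within groups, falling back to
displacement-level resampling when cell labels are absent), warm-started
at the point estimate.

## Residence-time model

A residence time starts when r drops below r0 and ends when it jumps
back above; tau = (run length) x t_lapse, quantized to whole lapses,
so the likelihood is discrete (geometric), avoiding small-tau binning
bias.  r0 = 0.2 um captures >99.5% of TB displacements at
D_TB = 0.033 um^2/s.  The tau distribution is a three-component
mixture:

* per-frame continuation probabilities c_i: for FD and NB, the chance
  the state's displacement falls below r0 (from the fitted D's); for
  TB, that chance times exp(-k_minus1 t_lapse);
* each observed continuation also requires bleach survival
  a = exp(-k_bleach t_lapse); an observed exit contributes a (1 - c_i);
  a run cut off by a track end is censored and contributes only its
  survival factor (dropping censored runs would bias k_minus1 upward);
* mixture weights are tied to the diffusion fit, proportional to
  f_i x c_i(0) — the rate at which state i starts sub-threshold runs.
  A float mode refits the weights as a robustness check; the tied mode
  is the default because it adds no free parameters.

k_minus1 is the single free kinetic parameter, found by bounded 1D
likelihood maximization on (1e-6, 10/t_lapse); estimates at either
bound are flagged non-identifiable.  The construction of this mixture
(which states contribute and how bleaching enters) is this package's
own; it is validated the same way it would be used — by parameter
recovery on simulated data, including the bleach-correction check
(k_minus1 = 5 1/s recovered under k_bleach = 2 1/s while the naive
inverse-mean rate sits near 7 1/s) and insensitivity of k_minus1 to r0
over 0.15–0.25 um.

## Biphasic unbinding rate law

The occupancy-resolved unbinding rate constant of a dimer inside an
n-mer on DNA is k(n) = k_o + k_r alpha^n + k_f [P]_FD; averaging over
occupancy in the weak-oligomerization, low-concentration limit gives
the apparent law

    k_app = k_o_off + k_r (exp(-[P]_FD / K_m) - 1) + k_f [P]_FD

with k_o_off = k_o + k_r and K_m = k_o_off / (k_1 (1 - alpha)).  The
package implements the stated averaged law rather than re-deriving it.
Properties used as tests: k_app -> k_o_off as P -> 0; slope -> k_f as
P -> infinity; an interior minimum at P_min = K_m ln(k_r / (k_f K_m))
exists iff k_r > k_f K_m.  The fit is weighted nonlinear least squares
(weights 1/sd^2 from the dwell fits) in the (k_o, k_r, k_f, K_m)
parameterization with non-negativity bounds — this keeps the fitted
law non-negative everywhere — from three starts; a nested linear
(k_r = 0) fit is compared by AIC.  Uncertainties are parametric
bootstrap (resampling Gaussian noise at the reported point sd's).
K_m pinned at its bounds, or falling below half the smallest sampled
concentration (the impeded phase then being unobserved), is flagged as
poorly identified.  alpha is not separately identifiable from the
apparent law; inverting the K_m relation for alpha is provided as a
diagnostic and can be infeasible with rounded inputs — it is reported,
never clipped.  n_o (default 5) does not enter the apparent law; it is
carried in the parameter set for occupancy-resolved calculations.

The free concentration is [P]_FD = f_FD x [P]_cell with f_FD from the
diffusion fit of the same concentration group.  Rate minima can be
mapped to either the free or the total axis; the two differ
substantially when most protein is bound, so both are available.

## Single-cell concentration and grouping

Monomer count N = (n_tracked + residual_fluorescence / f_single) /
eta_pc; dimers = N/2; concentration = dimers / (N_A x volume).  The
photoconversion efficiency eta_pc is configurable (tests use 1.0 to
keep the arithmetic assumption-free; literature values for common
green-to-red tags are near 0.4).  Cells are sorted by concentration
into equal-count groups (default 8); groups report mean ± s.d.

## Equilibrium populations

Fractions versus total concentration are fitted with the simplest
competitive site-depletion isotherm consistent with the parameter set
(K_d1, K_d2, capacities [D0]_NB and [D0]_TB·n_o): two saturable site
classes plus conservation, solved for the free concentration by
Brent's method on a guaranteed bracket (0, P_total].  f_FD rises and
f_TB falls monotonically with total concentration for every valid
parameter set (verified property).  The NB<->TB partition ratio K_d3
is carried as a derived diagnostic, not a free isotherm parameter —
with desk-scale data a third coupled equilibrium is not identifiable,
and how the occupancy-resolved oligomer capacity couples into the
isotherm is a genuinely open modelling choice; the fitted capacities
should be read with that caveat.  Fitting is least squares in log
parameters (positivity by construction) with parametric bootstrap.

## Spatial clustering

One residence site per maximal sub-threshold run, at the run's mean
localization.  The null is an equal number of sites per cell drawn
uniformly in a spherocylinder of that cell's size and projected to the
imaging plane (a 2D-footprint mode is available; the 3D-projected
default matches what imaging would see for geometry-uniform sites).
Statistics: the normalized pair-wise distance distribution (all
within-cell pairs, pooled across cells, never across cells), the
fraction of pair distances within R (a nearest-neighbour variant is
behind a flag), and the observed/reference ratio averaged over
concentration groups as a function of R.  Under the uniform null the
ratio is flat at 1 within Monte-Carlo error; nanometre-scale clusters
(30 nm Gaussians) push it above 1 at R = 100 nm, growing as R shrinks.
Reference fractions of zero make the ratio undefined; those R are
reported missing rather than interpolated.  95% bounds on the PWDD
difference come from a cell-level bootstrap.  Note that repeated
rebinding of one molecule near the same place produces genuine
short-distance correlations even without oligomerization; the
simulator reproduces this, which is why the end-to-end pipeline's
ratio curve sits slightly above 1 while the calibration tests use
directly drawn uniform sites.

## Pipeline, sizes and determinism

The driver chains simulate -> SCQPC -> grouping -> diffusion fit ->
bleach fit -> per-group dwell fits -> rate-law fit -> isotherm fit ->
spatial analysis, and writes a condensed parameter table (JSON) plus
per-stage TSVs.  The default synthetic experiment uses 80 cells x 40
molecules with lognormal total concentrations spanning roughly
80 nM–2 uM (median 400 nM), the non-repressor-like truth set
(k_o_off = 22 1/s, k_r = 12 1/s, k_f = 0.018 1/(nM s), K_m = 12 nM;
K_d1 = 28 nM, K_d2 = 830 nM, capacities 82/2300 nM) and completes in
about two minutes on one CPU; the test suite uses a 20-cell
configuration.  Every stochastic stage derives its generator from the
single run seed, so reruns are byte-identical.

Known limitations: apparent D's from confined cells are
confinement-reduced (no correction is applied; the fast state in the
default pipeline fits near 3 um^2/s although the free-space truth is
6.7), HMM-style per-frame state assignment is out of scope, bleaching
is single-exponential, and the isotherm's functional coupling of
oligomer occupancy is the simplest member of its family rather than a
derived result.
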