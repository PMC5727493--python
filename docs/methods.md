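# Methods

## The kinetic model

`liverperf` implements a dual-input two-compartment distributed-parameter
model of hepatic tracer kinetics. The liver receives blood from the hepatic
artery and the portal vein; the tissue contrast-concentration curve is

    Ct(t) = F [ alpha Ca(t - tau_a) + (1 - alpha) Cp(t - tau_p) ] * R(t)

where `*` is temporal convolution, `F` is total blood flow, `alpha` the
arterial flow fraction, `Ca`/`Cp` the arterial and portal input functions,
and `tau_a`/`tau_p` their arrival delays at the tissue.

The impulse residue function `R(t)` has two phases. During the vascular
transit phase (`0 <= t < t1`) the whole bolus is inside the sinusoidal
(vascular) space and `R = 1`. At the end of the transit the intravascular
tracer has washed out except for the extracted fraction
`E = 1 - exp(-PS/F)`, which has crossed into the interstitial space (the
Space of Disse) through the endothelial fenestrations. The subsequent
back-flux of that fraction follows the distributed-parameter solution

    R(t) = 1 - exp(-PS/F) [ 1 + \int_0^{t - t1}
              exp(-(PS/v2) tau) sqrt((PS/v2)(PS/F)/tau)
              I1(2 sqrt((PS/v2)(PS/F) tau)) dtau ]      for t >= t1,

with `I1` the modified Bessel function of the first kind, `v2` the
fractional interstitial volume, and `PS` the permeability-surface area
product. The back-flux phase is evaluated at the shifted time `t - t1` so
that it begins when the vascular transit ends: this yields `R(0) = 1`, a
jump from 1 down to `E` at `t1`, monotone decay to zero, and the
central-volume identity `\int R dt = t1 + v2 / F_frac` (verified in the
test suite to within 1 % and invariant to `PS`). A literal reading in which the
back-flux phase starts at `t = 0` would give `R(0) = 1 + E > 1`, which is
not an admissible residue function.

Units follow the clinical convention: `F` and `PS` in mL/min/100 mL tissue
(converted internally to fractional per-second rates by dividing by 6000),
times in seconds, volumes as dimensionless fractions. The fractional
vascular volume is derived, not fitted: `v1 = F_frac * t1` (central-volume
theorem), with an optional haematocrit factor `v1 * (1 - hct)` for a
plasma-volume convention. With `hct = 0.40` the worked-example values
(`F = 81.0`, `t1 = 23.3 s`) give `v1 = 18.9 %`; without it, `31.5 %`. The
haematocrit factor is off by default and exposed as an argument, because
whole-blood and plasma conventions coexist in the literature and the choice
does not affect the forward model (which never consumes `v1`).

### Numerical evaluation

Both the back-flux integral and the tissue convolution use rectangular
sums at the acquisition temporal resolution `dt` (default 2.0 s).
Rectangles are evaluated at their midpoints: the midpoint form converges at
second order, so halving the step moves the back-flux phase by well under
1 % of its scale, while a left-rectangle sum moves by several percent. A
trailing partial rectangle (also midpoint-evaluated) makes the integral
continuous in its upper limit, which matters for the fitter (below). The
Bessel term is computed through the exponentially scaled `i1e` to remain
finite at large arguments; the `tau -> 0` integrand limit `k_e k_t` is used
analytically. A fine-step override (`quadrature_dt`) exists for reference
evaluations and is used by the conservation tests at 0.01 s.

Arrival delays are continuous: a delay of `m + f` samples is realised as
the convex combination `(1-f) shift(m) + f shift(m+1)` of integer-sample
shifts with front zero-padding. This conserves tracer mass exactly and
makes the model output continuous in the delay, so the optimiser can move
through fractional delays smoothly.

## Voxelwise fitting

Each voxel is fitted by bounded trust-region least squares
(`scipy.optimize.least_squares`, TRF, finite-difference gradients) over
seven parameters `(F, alpha, t1, v2, PS, tau_a, tau_p)` with default bounds
F 1–500, alpha 0–1, t1 1–120 s, v2 0.005–0.8, PS 0.1–300, delays 0–30 s.

Because `R` is *sampled* on the acquisition grid, the model output changes
branch whenever `t1` crosses a grid time: the least-squares objective is
smooth within each `dt`-wide `t1` interval but jumps between intervals, and
it is additionally multi-modal in the remaining kinetic parameters. The
fitter therefore proceeds in three deterministic stages:

1. **Interval scan** — fit all parameters from a centre start with `t1`
   confined to each grid-spacing interval in turn.
2. **Corner refinement** — re-fit the best three intervals from six fixed
   starting points spanning arterial/portal-dominant and fast/slow-exchange
   corners of parameter space.
3. **Joint polish** — unconstrained (full-bounds) refits seeded by the
   stage-2 winners and the corner starts; the converged solution with the
   lowest sum of squared errors wins.

The procedure is deterministic (no random restarts), recovers random
noiseless truths to machine precision (~2–3 s per voxel on one core), and
was verified to reach lower objective values than descent started at the
true parameters on noisy data, i.e. it effectively attains the maximum-
likelihood estimate.

Voxels whose peak enhancement is below 3 baseline standard deviations
(first 5 samples) are skipped and flagged; non-fitted voxels carry NaN in
the maps, distinguishing "not fitted" from "fitted zero".

### Identifiability

With 5 %-of-peak Gaussian noise on the worked-example curve, the attained
median absolute relative errors are about 6 % (F), 3 % (alpha) and 6 %
(t1). These figures depend strongly on the arterial and portal inputs
being as distinct as they are in vivo: in experiments with an artificially
portal-like arterial input (or vice versa), the likelihood flattens along
ridges trading `alpha`, `t1` and the delays, and maximum-likelihood errors
grow several-fold. Input-function quality, not optimiser quality, is the
binding constraint on noisy parameter recovery.

## Synthetic data

No clinical dataset accompanies the model, so all pipeline stages are
exercised on synthetic data.

**Input functions.** The arterial input is a gamma-variate first pass
`A ((t-t0)/s)^k exp(-(t-t0)/s)` with bolus arrival `t0 = 10 s`, shape
`k = 3` and scale `s = 2.5 s` (time-to-peak 7.5 s after arrival, FWHM
about 9 s, consistent with a 3 mL/s antecubital bolus observed in the
aorta), plus a recirculation tail: a copy dispersed through a normalised
exponential kernel (30 s) and delayed 25 s, carrying 35 % of the
first-pass area. The portal input is the arterial curve convolved with a
normalised exponential dispersion kernel of 25 s and delayed 15 s,
emulating transit through the splanchnic circulation; its peak lags the
aortic peak by roughly 25 s and reaches about 30 % of its height. Both
kernels are discretely normalised, so tracer mass is conserved (verified
to 1 %). Amplitude units are arbitrary concentration units, consistent
across all curves.

**Tissue classes.** Four classes with per-parameter means and SDs:
volunteer parenchyma, cirrhotic parenchyma, hepatocellular carcinoma and
metastatic adenocarcinoma. Where the reference cohort does not constrain a
value (cirrhosis `alpha`, `t1`; HCC `F`, `PS`; metastasis `F`, `PS`), the
defaults are free choices informed by published liver perfusion ranges
(cirrhotic arterialisation `alpha = 0.41 ± 0.15`; HCC hypervascular flow
`100 ± 30`; metastasis `80 ± 25` with `PS = 30 ± 10`, below healthy
parenchyma) and are marked as such in the source.

**Sampling.** Parameters are drawn independently per voxel/subject from
truncated normals on physical bounds. The truncation location is
moment-matched (solved so the *truncated* mean equals the class mean),
because plain truncation would bias classes whose SD is large relative to
the distance to a bound (HCC `v1`, `v2`) by more than the Monte-Carlo
noise of the verification tests. Classes that specify a transit time
sample `t1` directly and derive `v1 = F_frac t1`; cirrhosis, specified via
`v1`, samples `v1` and inverts the relation. Noise is additive Gaussian on
concentration — the pipeline operates downstream of MR signal conversion,
so Rician signal statistics are out of scope.

**What passing tests do not show.** The phantoms contain no motion, no
undersampling artefacts, no signal-to-concentration nonlinearity, no
partial-volume mixing at lesion borders, and input functions are known
exactly rather than measured from small noisy ROIs. Recovery accuracy on
real data will be worse in proportion to these effects.

## Group statistics

ROI summaries report per-parameter mean and sample SD (ddof = 1) over
converged in-mask voxels. Group comparisons use the classical
pooled-variance two-sample t-test (two-sided, `n_a + n_b - 2` df,
significance at P < 0.05, no multiple-testing correction); a Welch option
exists behind a flag. The unit of analysis is one row per subject or
lesion in the input tables; the synthetic cohort generator emits one draw
per subject. Significance classification agrees with an exact permutation
test in over 95 % of seeded small-sample draws.

At the encoded effect sizes, a 7-vs-5 volunteer/cirrhosis comparison of
total flow is correctly signed in every simulated cohort but reaches
significance in only about half of them (the volunteer flow SD is large
relative to the group shift); the permeability-surface area product
separates in over 90 %. Qualitative contrast directions (arterial fraction
HCC > metastasis > volunteer; transit time metastasis > HCC; interstitial
volume metastasis highest; cirrhosis vs volunteer lower F, v1, PS and
higher v2) are reproduced by construction in large cohorts and by
significant contrasts in small replicate cohorts.

## Problem sizes

Default grid 120 volumes at 2.0 s. Reference quadrature for conservation
checks at 0.01 s over 3600 s. Forward-model oracle comparisons on 100
random parameter sets at 256 samples. Noisy-recovery statistics over 100
replicates; cohort replication over 200 seeded cohorts; permutation
comparisons at n = 7 per group (3432 exact splits). These sizes were
chosen so the full suite runs in minutes on a single core while keeping
Monte-Carlo margins comfortably wider than the assertion tolerances.

## Known limitations

- The model assumes an instantaneous, well-mixed vascular plug-flow phase
  and first-order exchange; it does not implement the adiabatic
  tissue-homogeneity approximation or closed-form Laplace-domain variants.
- `v1` inherits whatever convention (whole-blood vs plasma) the caller
  selects; the two differ by `1 - hct` and the package does not attempt to
  infer haematocrit.
- Fitted delays absorb genuine input-function timing errors; with heavily
  dispersed inputs they become weakly identifiable and trade against `t1`.
- The residue-function horizon check `R < 0.01` at
  `t1 + 20 (v2 100/PS) 60` s presumes back-exchange-limited decay; for
  `PS >> F` the tail is washout-limited (`v2/F`) and clears later.
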