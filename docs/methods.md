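# Methods

## The coupled-trait model

`sysmap` models n jointly measured dynamic traits as a system of ordinary
differential equations in which trait i's instantaneous rate of change is
the sum of an independent term, a function of its own state, and one
dependent (interaction) term per other trait, a function of that trait's
state:

    dp_i/dt = f_i(p_i; θ_i) + Σ_{i'≠i} f_{i|i'}(p_{i'}; θ_{ii'})

The f's are functions of *state*, not of time; time enters only through
the trajectory.  Each f is a basis expansion — unnormalized Legendre
polynomials P_0..P_r (P_r(1)=1) on the trait's state domain mapped
affinely to [−1, 1], or cubic B-splines with r interior knots.  Defaults:
degree 3 for independent terms, degree 2 for interaction terms (fewer
degrees of freedom for interactions).  The sign of an interaction function
carries the biology: positive = cooperation (the driver trait accelerates
the target), negative = competition.

**Identifiability.**  An additive decomposition f_i(p_i) + Σ f_{i|i'}(p_{i'})
is invariant to moving constants between terms, so the naive regression
design contains one exactly collinear constant column per interaction
term.  We pin the decomposition by requiring every interaction function to
vanish at a reference driver state, default 0: a trait at level zero
contributes nothing to any other trait's rate (zero transpiration draws no
water; zero soil water confers no uptake).  This removes exactly one
degree of freedom per interaction term, makes the design full rank, and
keeps the interaction's mean level — hence the cooperation/competition
reading — meaningful.  The anchored coordinates are P_k(u) − P_k(u_ref),
k ≥ 1.

**State domains.**  Each trait's basis lives on [observed min, observed
max] padded 5% per side (or user-fixed physical bounds).  During
integration states are clipped to the domain edge — polynomial
extrapolation outside the fitted range is meaningless — and clip events
are counted and logged.

**Integration.**  Classic fixed-step RK4 with step = min(3 min, output
interval)/3.  A numba-compiled kernel (states and coefficients converted
once to standard polynomial form) handles all-Legendre models; a pure
numpy path is the reference implementation and the two agree to machine
precision.  Against closed-form linear systems the solver is accurate to
< 1e−7 at the default step.

**Decomposition.**  The full system is integrated, then re-integrated with
all interaction coefficients zeroed; the net interactive effect is stored
as the pointwise difference, so full = independent + net holds exactly by
construction.

## Estimation

1. **Genotype means.**  By default fitting operates on pointwise replicate
   means per genotype (missing excluded pairwise); replicate-level fitting
   is a flag.
2. **Diurnal deflation.**  Flux-like traits (default: TR) carry a
   multiplicative daily cycle.  The mean daily profile is estimated as the
   clock-binned mean of observation/envelope ratios across days, smoothed
   circularly (90-min window) and normalized to unit day-mean, then
   divided out.  The corrected series equals the underlying state up to
   one global scale factor, so rate-function signs and shapes are
   preserved; without this step the daily ripple that leaks through the
   envelope smoother can corrupt the small interaction terms.
3. **Smoothing.**  Least-squares cubic regression splines with interior
   knots spaced `bandwidth_minutes` apart (default 1440: the multi-day
   drydown envelope; ~120 resolves sub-daily structure).  Derivatives come
   from the spline's analytic derivative.
4. **Gradient matching.**  Because the rate model is linear in θ,
   regressing estimated derivatives on the concatenated state bases is a
   single OLS solve per trait.  Rank is checked by pivoted QR and
   collinear columns are reported by name.  When derivatives are exact and
   the generating model lies in the basis span the estimate is exact to
   machine precision.
5. **Pooled per-line fitting (scan stage 1).**  Along a single drydown
   trajectory each trait's state is a function of the others' states, so a
   line-by-line fit cannot separate independent from dependent terms (we
   measured ~12× attenuation of the soil-drawdown coefficient).  The scan
   therefore fits one pooled design: independent coefficients shared
   across lines, interaction coefficients line-specific — exactly the
   alternative-hypothesis structure — identified by the between-line
   diversity of starting states.
6. **Likelihood refinement (optional).**  All coefficients, the initial
   state, per-trait innovation variances (log scale) and a shared
   correlation parameter (atanh scale) are optimized jointly with L-BFGS-B
   on internally standardized parameters.  Residual covariance models:
   iid; AR(1) (sigma2 = marginal variance, lag-one correlation rho on the
   sampling grid); SAD(1), the stationary first-order antedependence
   process (sigma2 = innovation variance, marginal sigma2/(1−phi²)).  On
   irregular grids the lag exponent is time-scaled by the median spacing.
   Likelihoods use the exact sequential factorization, O(T), with NaN gaps
   conditioned across.  The refiner returns the warm start whenever the
   optimizer fails to improve on it, so refinement never degrades the
   objective.  The objective may be evaluated on a thinned grid
   (`thin_minutes`); for the smooth drydown curves used here, 30–120-min
   thinning changes fits negligibly.

The EM mixture (`CurveGaussianMixture`) fits a full-covariance Gaussian
mixture over per-sample curve-summary vectors with k-means++ seeding from
a caller seed, stops on < 1e−8 log-likelihood improvement or 500
iterations, and restarts with a derived seed (≤ 5 times) if a component's
variance collapses below 1e−12.

## Genome scan

Stage 2 tests, per SNP, whether dosage classes differ in the line-specific
coefficient vectors (default: the anchored interaction coefficients,
q = 4 for the two-trait defaults).  Dosage classes with fewer than
`min_class_size = 3` lines are merged into the nearest dosage class; a SNP
with one remaining class is reported untested, as are SNPs whose scatter
matrices cannot support the test.  Lines missing a genotype code are
dropped for that SNP only.

The test is the likelihood-ratio test of a multivariate Gaussian model
with class-specific versus common means and common covariance — one-way
Wilks' Λ — with the Bartlett small-sample scale:

    LRT = −(n − 1 − (q + g)/2) · log Λ,   df = q·(g − 1)

referred to chi-square.  On null panels of 32 lines the empirical
rejection rate at α = 0.05 is 0.04–0.06 (measured over thousands of null
SNPs), which is what the Bartlett scale buys at this sample size.
Benjamini–Hochberg q-values are computed over *tested* SNPs only
(statsmodels' step-up behind the package's `bh_fdr` surface); permutation
p-values, (1 + #{perm ≥ obs})/(n_perm + 1) with n_perm ≥ 100, are an
opt-in exact alternative for small panels.  `delta_*` columns report the
change in interaction score (mean of the interaction function over its
domain) from the lowest to the highest dosage class.

## Critical soil water content

θ_cri is the VWC breakpoint below which midday transpiration declines with
further drying.  Midday pairs (default clock window 11:00–13:00,
half-open) are fitted with the standard continuous two-segment
broken-stick: flat wet segment (free wet slope is a flag), declining dry
segment, breakpoint by grid search over interior VWC quantiles
(2.5%–97.5%, 200 candidates; ties broken toward the smaller breakpoint)
with golden-section refinement, segment parameters by conditional least
squares.  A perfectly flat response has no identifiable breakpoint and is
reported as such.  An optional pair-resampling bootstrap gives the
breakpoint SE.

## The simulator

The reference scenario reproduces the structure of a lysimeter drydown
experiment: 32 inbred lines × 5 replicate pots, TR and VWC every 3 minutes
for 6 days after withholding water, pots covered so soil evaporation is
nil.  Baseline dynamics (per minute; TR in g/min, VWC volume fraction):

    dX/dt = a − kX + k(18Y − 10Y²)      k = 1/1440, a = −2k
    dY/dt =       − cX                  c = 1e−5

TR relaxes with a one-day time constant toward a saturating water-
dependent target X*(Y) = −2 + 18Y − 10Y², while transpiration draws soil
water down; both interaction terms vanish at a zero driver state, matching
the anchoring convention.  Starting states vary by genotype (truncated
normal: TR 2.6 ± 0.15 clipped to [2.35, 2.85] g/min, VWC 0.42 ± 0.015
clipped to [0.405, 0.45]), representing plant-size and initial-moisture
differences; this between-line path diversity is also what identifies the
additive split.  With these values every line shows the two-phase drydown
pattern — TR rises while water is ample, peaks on day 2–3, declines from
about day 4, VWC falls monotonically from ~0.42 to ~0.19.

Observations add a multiplicative diurnal factor on TR only,
1 + A·max(0, sin(2π(clock − 6 h)/24 h)) with A = 0.6 (zero at night), and
Gaussian noise per trait (TR 0.15 g/min ≈ 5% of signal; VWC 0.005, a
typical sensor resolution).  SNP dosages are binomial(2, MAF) per line
with MAF ~ U(0.1, 0.5); causal SNPs shift named anchored interaction
coefficients additively per dosage copy.  Random streams are split per pot
([seed, 2, genotype, replicate]), so growing the replicate count leaves
earlier pots byte-identical.  Scenarios whose noise-free dynamics touch a
basis-domain edge or leave VWC's physical [0, 1] are rejected before any
data are produced.

**What the simulator does not emulate:** weather-driven VPD fluctuation,
soil evaporation, sensor drift and dropouts, population structure and
linkage disequilibrium between markers, and day-to-day variation of the
diurnal profile.  Passing tests therefore demonstrate correctness of the
machinery under the stated generative assumptions, not performance on any
particular field dataset.

## Problem sizes and numerical choices

The test suite and the acceptance script run the scan calibration on one
1000-SNP null panel, power and FDR experiments over 10–20 simulated
replicates of the 32 × 5 design, coefficient-recovery Monte Carlo over
10–20 seeds, and refinement on hourly-thinned single-genotype data —
sizes chosen so each property is measured with useful precision on a
single CPU in minutes.  Realized-FDR estimates at these panel sizes are
intrinsically noisy (a scan often rejects 0–3 SNPs, so single false
rejections move the per-scan ratio a lot); across 60 independent scans
the mean realized FDR of BH at 0.05 measured 0.06 ± 0.02.

Other numerics: out-of-domain basis arguments raise unless within 1e−8 of
the edge (integration clips instead, with logging); interaction-score
neutrality tolerance is 1e−9 × range width; EM regularizes covariances by
1e−10 on the diagonal; the refiner treats non-finite likelihoods as +∞ and
keeps the best-so-far parameter vector.

## Known limitations

- Gradient matching inherits smoother bias; with the 24-h envelope
  default, population-level coefficients on noisy diurnal data are
  recovered to a few percent (norm-relative), not exactly.
- The chi-square calibration of the scan is asymptotic in the number of
  lines; below ~20 lines the permutation option should be preferred.
- Heavily heterogeneous populations (strong-effect loci) violate the
  single-shared-model assumption of the population-average fit; the scan
  is built for that setting, the average fit is not.
- SAD(1) is implemented in its stationary form; time-varying
  antedependence parameters and kinship/structure corrections are out of
  scope.
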