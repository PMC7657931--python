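# Methods

This note documents the models implemented in `chronomove`, the numerical
choices behind them, what the synthetic-data generator does and does not
emulate, and the design decisions taken where the problem was genuinely
open. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Movement model and preprocessing

Positions are planar metres (telemetry projected before ingestion; no
geodesy is performed). The **speed filter** iteratively removes fixes
whose implied speed to every existing neighbour exceeds `max_speed`
(default 15 000 m/h, generous for a large ungulate and exposed as a flag);
iterating guarantees an isolated spike is removed without discarding the
genuine fixes around it.

Step length is the Euclidean distance between consecutive fixes; hourly
net displacement is that same distance, log-transformed as `ln(d + 1 m)`
to stabilize variance. The +1 m offset is a documented convention: it is
monotone, maps a zero displacement to exactly 0, and the offset constant
is configurable. Turning angle is the signed heading change in (−π, π];
it is undefined (and flagged) for the first step of a segment, after a
zero-length step, and after a gap. Steps spanning a missed fix are flagged
as gaps and **excluded** from HMM emissions rather than interpolated —
the Lomb–Scargle stage tolerates the resulting uneven sampling, which is
why it, and not an FFT periodogram, is the classification engine.

## 2. Behavioural hidden Markov model

Conditional on the latent state, step length and turning angle are
independent; the step model is a gamma distribution (parameterized by
mean and sd) with an explicit point mass at exactly 0 m (zero inflation —
necessary for resting bouts), the turn model is von Mises. The likelihood
is the scaled forward algorithm over each contiguous gap-free segment,
each segment starting from the stationary distribution of the transition
matrix. Parameters are estimated by quasi-Newton (L-BFGS-B) maximization
on unconstrained working parameters (log means/sds/concentrations, logit
zero-mass, multinomial-logit transition rows); the default is 10 restarts
from perturbed moment-based initial values, with every restart's optimum
recorded. Label switching is resolved by sorting states by gamma mean
step length, giving the resting < foraging < transiting semantics.

Degenerate inputs: an all-identical step series is rejected; a
zero-probability observation cannot occur because the zero-mass logit is
bounded in ±12, keeping every emission density strictly positive.

Decoding uses forward–backward posteriors (the per-fix state
probabilities consumed downstream) and Viterbi. **Pseudo-residuals** map
each step through its one-step-ahead forecast CDF and the standard normal
quantile; the atom at zero is handled by randomizing uniformly within the
CDF jump (the standard treatment for mixed distributions). Well-specified
fits give ≈ N(0,1) residuals with low autocorrelation; the test suite
verifies both the calibration and that a deliberately misspecified
single-state fit inflates lag-1 autocorrelation.

Models with 2–5 states are supported with AIC and pseudo-residual
diagnostics; 3 states is the documented default. HMMs are fitted jointly
across individuals, separately per snow season (snow-covered vs snow-free
by thresholded snow depth, with a 7-day minimum run length so brief melt
events do not fragment the seasons); a per-individual mode is available
by subsetting the step table.

## 3. Periodicity

**Lomb–Scargle.** Input series are the per-fix posterior probability of
one state, or log net displacement, at 1 h nominal resolution. The
periodogram is evaluated on an oversampled frequency grid (default
oversampling 4; grid spacing 1/(4 × span)) over a period band, with the
classical Lomb formulation (scipy's implementation), mean-subtracted
input, and normalization raw power / (2 × sample variance) — a
full-variance sinusoid on an evenly sampled series of length n attains
power ≈ n/2. This normalized power is *exactly* the explained sum of
squares of a per-frequency least-squares sinusoid fit divided by twice the
sample variance; the acceptance suite verifies the identity to 1e-8
against an independent OLS oracle.

**Peak significance.** The default is a permutation test: values are
shuffled over the fixed observation times, the band-maximum power is
recomputed `n_perm` times (default 999), and
p = (1 + #{perm ≥ obs}) / (n_perm + 1). This is exact under
exchangeability and remains calibrated under uneven sampling, where the
classical exponential false-alarm approximation (retained as
`method="analytic"` with an independent-frequency count M = band width ×
span) is only asymptotic. Type-I calibration at α = 0.05 on white noise
is verified empirically.

**Wavelets.** The continuous Morlet transform (ω₀ = 6) over log-spaced
periods between 1 and 256 h asks whether periodicity is constant or
clustered in epochs; power is divided by scale for comparability across
periods, the cone of influence uses the √2-scale e-folding time, and
significance is a white-noise bootstrap (default 100 simulations; the
pointwise 95th percentile of null power per period). The wavelet stage is
exploratory — it feeds no classification — and is intended for
individuals with a complete year of data; short gaps (< 1% of the grid)
are linearly interpolated for wavelets only, never for the LSP.

## 4. Rhythm classification

Windows are calendar-aligned: weeks numbered from 1 January (week 1 =
days 1–7), months calendar. Eligibility requires ≥ 6 days of data per
week and ≥ 28 per month. Per window, the band maximum and its p-value are
computed separately for the ultradian band [2, 18) h and the circadian
band [18, 36] h — the bands share the 18 h boundary, so the half-open
convention (18 h counts as circadian) removes the ambiguity and is
configurable in one place. With one candidate peak per band at most two
candidates exist; if both are significant, within 18 h of each other *in
period*, and the smaller is below one third the larger's power, the
smaller is rejected as a likely artefact. Classification is then a pure
function of the retained peaks: ultradian only → *ultradian*, circadian
only → *circadian*, both → *ultradian & circadian*, none → *arrhythmic*.
A zero-variance window (no movement information at all) is reported
arrhythmic. No attempt is made to distinguish a genuine 12 h rhythm from
the first harmonic of a 24 h rhythm; the classifier reports what the
periodogram shows.

## 5. Class transitions

The 4×4 transition matrix over (arrhythmic, ultradian & circadian,
circadian, ultradian) is the pooled maximum-likelihood count ratio
count(i→j)/count(i→·), counting only transitions between *consecutive*
eligible windows of the same individual — a dropped window breaks the
chain; nothing is bridged. Rows whose origin class never occurs are left
NaN, never fabricated. Uncertainty is an individual-level block
bootstrap (individuals resampled with replacement, default 1000
replicates; 100 available) with percentile CIs.

At the validation design of 10 individuals × 50 windows, each diagonal
cell rests on ~120 transitions (binomial se ≈ 0.04), so recovery of a
0.7 self-transition probability is asserted at ±0.05 for the *pooled*
diagonal (se ≈ 0.02) and via per-cell CI coverage; a per-cell ±0.05 point
check would fail a correct estimator a third of the time at this sample
size.

## 6. Environmental model

The binary outcome groups the three rhythmic classes against arrhythmic.
Covariates (photoperiod, elevation, proportion of fixes in dense
vegetation, snow depth, NDVI) are averaged per individual-window and
scaled to mean 0 / sd 1 within the analysis set. Pairwise Pearson
correlations are reported and pairs with |r| ≥ 0.5 are *flagged* for an
explicit decision, never dropped silently; the model always reports all
five terms. Note that photoperiod, NDVI and snow depth are strongly
seasonally confounded in any high-latitude dataset (and in the synthetic
data), so their coefficients must be read jointly.

The GLMM is a Bernoulli model with logit link and independent Gaussian
random intercepts for year and for individual-within-year (id × year
cells), estimated by maximizing the Laplace-approximate marginal
likelihood jointly over fixed effects and log random-effect sds: an inner
Newton solve (with step halving) finds the random-effect mode, the outer
L-BFGS-B works on the Laplace objective, and fixed-effect covariances
come from the (β, β) block of the inverse joint Hessian at the mode. A
component observed at a single level is dropped (it carries no variance
information) rather than fabricated; |coefficient| > 15 raises a
separation flag. With the random-effect variance at zero the objective
reduces analytically to plain logistic regression, which the tests verify
against statsmodels to 1e-4, and the full model is cross-checked against
lme4's Laplace `glmer` on a simulated dataset.

Prediction curves hold all other (scaled) covariates at 0 and draw the 95%
band from a parametric bootstrap of the fixed effects (default 100 draws);
the band is clipped to contain the point prediction. The growing-season
contrast (default weeks 23–37) partitions individuals each week by their
foraging-metric rhythm class and compares mean NDVI over their fixes with
a normal-approximation CI; empty groups are reported as missing.

## 7. Synthetic-data generator

The generator is the package's test bed and emulates the study conditions
of a year-round high-Arctic deployment: hourly fixes, 74.47° N
photoperiod (polar night/day), 19 individuals by default, < 0.1 % missing
fixes (per-fix deletion probability 0.001), three behavioural states with
distinct step/turn emissions, and rhythm forcing whose strength follows
the season.

- **Photoperiod** uses the standard sunrise equation with a Spencer
  Fourier-series solar declination and the conventional −0.833° solar
  altitude threshold (refraction + semidiameter); this reproduces the
  polar-day and polar-night calendar at the study latitude to within two
  days, which a plain no-refraction formula does not.
- **Forcing** enters the transition log-odds (not the emissions): the
  log-odds of entering foraging are offset by +f(t) and of entering
  resting by −f(t), with f(t) = A_u cos(2πt/12 h) + A_c cos(2πt/24 h).
  The ultradian amplitude interpolates from its winter value (default
  1.5) to its summer value (default 0) as photoperiod rises; the
  circadian amplitude ∝ s(1−s) with s = photoperiod/24 peaks at the
  equinoxes, when a real light–dark cycle exists, and vanishes under
  continuous light or dark. Because forcing is in the transition odds,
  the downstream HMM's emission model remains correctly specified.
- **Baseline dynamics**: the unforced transition matrix has mean state
  dwell times of ~1.8 h (diagonal 0.45), the hourly-resolution
  discretization of a ruminant's fast foraging–rumination alternation.
  This matters statistically: a much stickier chain produces red-noise
  activity spectra whose 18–36 h band power defeats any white-noise null,
  so an "unforced" condition would never actually be arrhythmic, and the
  generator could not realize its own design.
- **Phenotypes**: a configurable fraction of individuals
  (`summer_forced_fraction`, default 0.25) keeps winter-strength
  ultradian forcing through mid-summer — a persistently rhythmic
  phenotype — and their NDVI exposure is scaled down
  (`ndvi_rhythmic_scale`, default 0.6), planting the contrast in which
  arrhythmic animals occupy more productive vegetation.
- **Covariates**: NDVI is a Gaussian bump over weeks (peak week 28,
  amplitude 0.8, zero under snow); snow depth ramps up from week 40,
  plateaus, and melts by week 22 so the snow-free season starts in week
  23, the conventional start of the growing season at this latitude;
  elevation is a per-individual constant; dense vegetation a per-fix
  Bernoulli flag.
- **Emissions**: resting (mean 8 m, zero-mass 0.25), foraging (60 m),
  transiting (450 m) with von Mises turns (reversal-centred, diffuse for
  resting; directed and concentrated for transiting). A turning angle
  drawn alongside a zero-length step has no geometric effect.

What the generator does **not** emulate: terrain, home ranges, herding or
any spatial covariate structure beyond the per-individual NDVI scaling;
weather beyond the covariate curves; collar-specific error models;
behavioural states beyond three. Consequently, passing tests demonstrate
that the analysis chain recovers the statistical structure it assumes —
states from emissions, periods from forcing, covariate effects from the
planted design — not that muskox biology follows this generative model.

## 8. Problem sizes and determinism

The validation harnesses use deliberately moderate problem sizes chosen
for tight feedback loops: ~10⁴ steps for HMM recovery, 5–10 individuals ×
1 year for the end-to-end seasonal harnesses, 100 replicates for coverage
and period-recovery rates, 999 permutations for calibration (199 inside
the end-to-end runs, whose classification threshold is 0.05). All
randomness flows from integer seeds through `numpy.random.SeedSequence`
spawning, so every run — simulator, restarts, permutations, bootstraps —
is exactly reproducible, and the pipeline writes its configuration and
seeds to a manifest sufficient to reproduce any run.

## 9. Known limitations

- The permutation null assumes exchangeability; strongly autocorrelated
  but aperiodic activity (red noise) inflates band significance for any
  white-noise-referenced method, wavelet or LSP alike. Interpreting
  rhythm classes on real data therefore requires the fast-switching
  regime (or an explicit AR null, which is out of scope).
- The analytic false-alarm p-value is approximate for gappy series; it is
  retained for speed, not inference.
- The GLMM uses a Laplace approximation; with very few random-effect
  levels (e.g. two years) the variance components are weakly identified,
  though fixed effects remain well behaved.
- Harmonic ambiguity (12 h peak vs first harmonic of 24 h) is not
  resolved, by design.
- The NDVI contrast uses a normal-approximation CI over fixes, ignoring
  within-individual autocorrelation; it matches the descriptive use it
  serves.
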