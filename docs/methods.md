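# Methods

This note documents the models behind `chronolux`, the defaults and why they
were chosen, what the synthetic data do and do not emulate, and the
numerical choices that matter for reproducibility.

## Spectral model and photoreceptor basis

All spectral quantities are trapezoidal integrals on a canonical
380–780 nm grid at 1 nm. For the band-limited spectra handled here
(Gaussian bands with σ ≥ 5 nm, smooth sensitivity templates) the 1-nm
trapezoid is accurate to machine precision; the dominant numerical choice
is therefore not quadrature but *normalization*: nomogram channels are
peak-normalized by their continuum (fine-grid) maximum, so refining the
grid changes excitations only through quadrature error, not through a
grid-dependent rescale. Spectra are linearly interpolated when regridded
and treated as zero outside their measured support (no extrapolation); an
SPD must cover ≥ 90% of a requested grid's span before resampling.

The default `PhotoreceptorBasis` is built from closed forms:

- **Photoreceptors** — Govardovskii et al. A1 pigment nomograms at retinal
  λmax 558.9 (L), 530.3 (M), 420.7 (S), 478 (melanopsin) and 496.3 nm
  (rhodopsin/scotopic), multiplied by an exponential young-observer lens
  density template `d(λ) = 0.53 · exp(−(λ−450)/41.5)` (density ~1.8 at
  400 nm, ~0.5 at 450 nm) and re-normalized. The corneal peaks land at
  563/537/449/493/508 nm; melanopsin at its conventional 493 nm corneal
  peak. An unfiltered variant (`lens_filtered=False`, raw nomograms placed
  directly at the corneal peaks) is available and flagged in the basis
  provenance, since published melanopic sensitivity tabulations differ in
  exactly this respect.
- **Chromaticity** — the CIE 1931 2° matching functions via the
  Wyman–Sloan–Shirley multi-lobe Gaussian fits (accurate to ~1% of peak;
  the equal-energy white lands within 0.005 of (1/3, 1/3)).
- **Luminous efficiency** — photopic V(λ) is constructed as the weighted
  cone sum `1.98·L̄ + M̄` (peak-normalized), the cone-fundamental
  definition of luminance. This is load-bearing: because luminance is then
  an exact linear functional of L and M excitations, any cone-silent
  substitution is luminance-silent *identically*, not approximately.
  Scotopic V′(λ) is the lens-filtered rhodopsin nomogram (peak 508 nm).
  Maximum luminous efficacies are 683 lm/W (photopic) and 1700 lm/W
  (scotopic); scotopic trolands are scotopic luminance × pupil area with a
  3.0-mm default pupil, and conditions flag rod saturation above 100
  scotopic td.

These analytic templates approximate, but are not identical to, the
standardized tabulated fundamentals. Quantities defined *within* the basis
(metamer contracts, excitation ratios, linearity) are exact; quantities
that compare against measurements of real lights (a printed melanopsin
ratio or chromaticity of a particular lamp) can only be reproduced with
the measured spectra themselves, which is why those checks load spectra
from `data/` and skip when absent.

## Silent-substitution design

Receptor excitations are linear in primary drive weights, `e = M w`. The
4×4 system (L, M, S, mel × four primaries) is solved exactly; with more
than four primaries the minimum-norm least-squares solution is used for
determinism. A melanopsin-scaled metamer solves for the target
`(L, M, S, k·mel)`; infeasible targets (negative drive) raise an error
naming the largest feasible k, computed from the linearity of weights in k.
The metamer verifier reports per-receptor ratios and checks cones within
0.1% (relative), luminance within 0.5%, and the mel ratio within 0.1% —
the cone tolerance sits well below both human discrimination and any
numerical noise in the solve.

Synthetic primaries are Gaussian bands (σ = 15 nm) at 455/530/580/595 nm,
mimicking interference-filtered projector primaries whose absolute outputs
are unspecified. The melanopic gamut of such a system at a fixed
chromaticity and luminance is a closed interval: pinning (x, y, Y) leaves
one degree of freedom, along which weights are linear in melanopsin
excitation. Mapping that interval over the chromaticity plane shows the
achievable melanopsin ratio between the gamut's floor and ceiling is
~1.5 at a neutral (0.40, 0.38) gray under these template fundamentals,
rising above 2.4 only for warm whites. The default three-condition fixture
therefore places its gray at the warm-white point (0.50, 0.47) at
110 cd/m², and puts the Control condition 2% above the melanopic floor, the standard strategy for maximizing melanopsin contrast
in a multi-primary stimulator. At that operating point the 2.1× melanopsin
metamer exists with non-negative weights and exact cone silence; the
light-flux condition scales all weights by 228/110, multiplying every
excitation and the luminance by exactly that factor while leaving
chromaticity bit-identical. Real projector spectra with steeper cone
fundamentals afford the 2.1 ratio closer to neutral; the displaced fixture
gray is a property of the synthetic basis, not of the design algorithm.

## Synthetic observer and session structure

A session presents nine oddball durations (750–1350 ms, standard 1050 ms)
42 times each (378 oddballs), with 7–12 standards between oddballs and
inter-stimulus intervals of 900/1050/1200 ms. Between-standard counts and
ISIs are generated for raw-data fidelity but never influence responses —
the analysis does not use them, and modeling sequential effects is out of
scope.

Responses are Bernoulli draws from a Weibull psychometric function, the
same family the fitting stage estimates, so recovery studies are exact by
construction; model-mismatch robustness (e.g. a logistic generator) is not
the default. The observer is parameterized by PSE and shape β (default 8,
giving a ~100-ms difference limen and ~0.0026/ms slope at a 1050-ms PSE —
the magnitudes typical of duration comparison) plus an optional lapse
mixture `λ/2 + (1−λ)F(d)` with λ ≤ 0.06. Arousal enters as a pacemaker
gain g mapping to PSE = standard/g: a faster pacemaker accumulates more
ticks during the oddball, so subjective equality needs less physical
duration.

Cohorts draw a participant-level PSE shift (SD 47 ms) shared across
conditions, plus an independent per-condition session jitter (SD 9 ms).
Both were set from the descriptive statistics such designs report: a group
SE of ~16.6 ms at n = 8 implies a ~47-ms between-participant SD, and
pairwise-difference SEs of ~5.5 ms imply within-participant variability
beyond binomial noise of roughly 9 ms per condition. A master seed spawns
one stream per participant × condition, so any margin is reproducible in
isolation.

## Psychometric fitting

The two-parameter Weibull CDF is fit by penalized maximum likelihood on
(log α, log β) with damped Fisher scoring from a moment start (α from the
empirical 50% crossing, β = 8), iterated to a 1e-9 step tolerance with
parameter bounds (α within e^±1 of the duration range, β ∈ [0.5, 60]).
No guess-rate floor is imposed — in a comparison task the "longer"
probability genuinely spans 0 to 1 — and the lapse, when used, is fixed
rather than estimated. Degenerate duration levels (0/n or n/n) receive
Jeffreys pseudo-counts (+0.5 successes, +1 trial) when penalization is
requested; a dataset whose responses are *all* identical refuses to fit
without it. Non-convergence falls back to Nelder–Mead and is reported,
never silent. The same scoring loop runs vectorized over batches
(`fit_weibull_batch`), which is what makes bootstraps and the simulation
studies below cost milliseconds. Tests verify the optimizer against a
brute-force grid search (α 600–1600 × β 1–40 at 0.5/0.05 steps).

Summary parameters: PSE = α·(ln 2)^(1/β); threshold = half the 25–75%
quantile span; slope = the analytic derivative at the PSE,
`0.5·β·ln 2/PSE` for lapse 0. Threshold and slope definitions vary across
labs; these are recorded in every fit summary's `definitions` block so
alternates can be swapped without ambiguity. Group-level analysis fits per
participant per condition and averages parameters, rather than fitting
pooled data (pooling is available explicitly via
`aggregate_trials(..., participant="pooled")`).

Uncertainty is a nonparametric bootstrap: trials are resampled within each
duration level (equivalently, level counts are redrawn from
Binomial(n, p̂)), each resample refit with penalization where degenerate,
and 2.5/97.5 percentiles reported per parameter. A minimum of 1000
replicates is enforced; 2000 is the default.

## Group inference

Each parameter (PSE, threshold, slope) is screened per condition with
Shapiro–Wilk (supported for 3 ≤ n ≤ 50). Two conditions: both a paired t
and a paired bootstrap are always computed; the report headlines the
bootstrap when any condition fails normality at α = 0.05, the t otherwise.
Three conditions: one-way repeated-measures ANOVA by the univariate
within-subject decomposition, F = MS_cond/MS_error with uncorrected dfs
(c−1, (c−1)(s−1)) — sphericity correction is deliberately off to match the
integer dfs such designs report — partial η² = SS_cond/(SS_cond+SS_error),
and Bonferroni pairwise paired t tests (corrected p = m·p capped at 1,
with uncorrected 95% CIs alongside).

The paired bootstrap resamples difference scores with replacement
(default 100,000 iterations, seeded). The 95% CI is the percentile
interval of the resampled means. The p-value is the equal-tailed
*studentized* (bootstrap-t) p — each centered resample contributes
t* = mean*/se*, and p = 2·min(tail fractions) with a +1 continuity
correction so p > 0 always. The studentized form was chosen over the
plain shifted-null mean comparison because at n = 8 the latter rejects a
true null about 11% of the time at nominal α = 0.05, while the
equal-tailed bootstrap-t measures 5.0% over 10,000 Gaussian-null
replications — matching the calibration the package's acceptance suite
asserts ([0.035, 0.065]).

Between-experiment comparisons of effect estimates use a Welch t built
from group summaries (means, SEs, ns) with Satterthwaite degrees of
freedom.

## Problem sizes in the test and acceptance runs

The stochastic studies run at sizes chosen to keep Monte-Carlo error well
inside the asserted bands: 200 cohorts of n = 8 for PSE-difference
recovery (asserted |bias| < 5 ms; measured ≈ 0.7 ms), 200 sessions × 1000
bootstrap replicates for CI coverage (asserted within [90%, 99%]), and
10,000 null replications × 2000 bootstrap iterations for type-I
calibration. The group-level bootstrap uses the full 100,000 iterations.

## Known limitations

- The basis is analytic-template, not tabulated-standard: absolute
  excitations and chromaticities of *measured* lights will differ from
  values computed with the standardized fundamentals at the few-percent
  level, and a narrow 628-nm synthetic band has essentially zero melanopic
  overlap, so the blue/red melanopsin ratio of the Gaussian fixtures is
  orders of magnitude larger than that of the broad measured lights it
  stands in for.
- Rods are reported (scotopic trolands, saturation flag) but not
  controlled as a fifth channel; the four-primary system has no spare
  degree of freedom for them.
- The observer has no sequential, attentional or feedback dynamics, and
  the generating and fitted psychometric families coincide — passing
  recovery tests demonstrates correctness of the estimation machinery, not
  robustness to model mismatch in real data.
- No projector gamma, temporal modulation, bit-depth quantization, or
  observer-age corrections are modeled.
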