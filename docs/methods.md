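# Methods

`beanbolus` re-creates, as tested reusable code, the computational chain
of a bean-bolus mastication/digestion study: image-based particle-area
quantification of masticated black-bean boluses with seed-coat/cotyledon
classification, Rosin-Rammler distribution modelling, in vitro starch
and protein digestion kinetics with starch-fraction accounting,
pulsed-electric-field (PEF) and texture-profile computations, and
chewer-group classification with cross-metric correlations. No raw study
data are available, so every analysis is exercised on synthetic inputs
with known ground truth; the embedded reference tables
(`beanbolus.datasets`) provide realistic published-style parameter
values for worked examples.

## Particle-size model

The cumulative particle-area distribution of a bolus is modelled by the
Rosin-Rammler law

    C_area(x) = 1 − exp(−(x / x50)^b · ln 2),

where `x50` (mm²) is the area below which half of the total particle
area lies and `b` (dimensionless) is the breadth exponent — larger `b`,
narrower spread. The empirical curve (`psd.build_cumulative`) is
**area-weighted**: particles are sorted ascending and the value at
particle *i* is Σ_{j≤i} a_j / Σ a_j. Area weighting is chosen over count
weighting because `x50` is defined as the 50%-of-total-area cut, and it
is the convention under which seed-coat fragments (few, large) and
cotyledon fragments (many, small) are comparable.

A subtlety follows from that choice. Drawing particle areas i.i.d. by
inverting C_area (as `synth.sample_rosin_rammler` does) produces draws
at uniformly random *area quantiles*: their count-ECDF estimates the
law, which is exactly what that sampler's Kolmogorov test checks. But a
physical particle *population* whose area-weighted curve follows the law
must be drawn from the size-debiased number density f(x)/x. With
y = (x/λ)^b and λ = x50 / (ln 2)^{1/b}, that density is Gamma(1 − 1/b)
in y, which `synth.sample_particle_areas` samples (random or
stratified/deterministic count-quantiles; requires b > 1, which holds
for masticated bean boluses, b ≈ 1.5–1.9). Plate rendering and all
parameter-recovery tests use the debiased sampler; weighting inverse-CDF
draws by their own areas would inflate the apparent median by ~46% at
b = 1.63.

Fitting (`psd.fit_rosin_rammler`) minimises the unweighted squared
deviation of the cumulative fractions over (x50, b), both kept positive
by a log re-parameterisation (Levenberg-Marquardt, xtol = ftol = 1e−10,
max 500 iterations, default init: empirical area-weighted median and
b = 1.5). Non-convergence is surfaced as a flag. Recovery checks: exact
model curves are recovered to machine precision and agree with a
brute-force grid search; a stratified 500-particle population recovers
(x50 = 5.0, b = 1.63) within 2%/5%; with Gaussian measurement noise
(sd 0.02) on the cumulative fractions of a 200-particle bolus the median
x50 error stays within 5%. Random 200-particle draws alone carry ~4–6%
median x50 error in the area-weighted curve (the debiased areas are
heavy-tailed), so the noise test treats sampling and measurement noise
separately rather than compounding them.

## Synthetic plates and segmentation

`synth.render_plate` draws a blue plate disc (177 mm default) on a grey
backdrop, a dark calibration bar of known millimetre length outside the
disc, and non-overlapping particles as perturbed ellipses (aspect ratio
U(1, 3), low-order radial wobble ≤ 5%) — the real particles are only
known to be "irregularly shaped", so these are stand-ins that exercise
edge handling, not claims about real boluses. Cotyledon blobs are cream
(225, 214, 182), seed-coat blobs near-black (35, 30, 30); optional
specular reflections are near-white, low-saturation discs under 1 mm².
Placement is rejection sampling with a 2 px clearance; requesting more
than 60% of the plate area raises `PackingError`. Each blob is
rasterised iteratively until its pixel count matches the sampled target
area (within ~0.5 px, i.e. well under 2% for ≥ 2 mm² particles at the
default 1200 px frame), and the ground truth records the *exact* painted
pixel count, centroid and class. The pixel scale is defined through the
marker (mm_per_px = marker_mm / marker_px) so measured and true areas
share one calibration. Mild Gaussian sensor noise (sd 1.5 grey levels)
is added, small enough never to flip a colour classification.
Everything is bit-reproducible under a fixed seed. The renderer does not
attempt photorealism (no optics, shadows, or wet-surface effects), so
segmentation results on it bound algorithmic correctness, not
performance on real photographs.

Segmentation (`imaging`) proceeds: plate isolation by HSV hue window
(default 225° ± 40°, saturation ≥ 0.25) taking the largest connected
component with holes filled; reflection removal as connected regions
that are simultaneously bright (V ≥ 0.9), low-saturation (S ≤ 0.12) and
small (< 1 mm²); particle support as plate pixels whose Euclidean RGB
distance from the background median exceeds 60, labelled with
8-connectivity. A Canny edge map (σ = 1.4) is computed alongside and
each particle's boundary is scored against it (`edge_support`); the
colour-distance support is used as the measurement support because
closing-and-filling raw edge rings cannot guarantee exact counts (broken
rings lose particles, morphological closing bridges 1 px gaps). On flat
backgrounds this makes pixel counts exact; on textured real images the
colour threshold would need tuning, which is why it is a parameter.
Areas convert as pixel_count × mm_per_px²; the 1 mm wash sieve is
emulated by equivalent circular diameter d = 2√(A/π) ≥ 1 mm (no exact
image-space counterpart of a physical sieve exists). Classification is
2-means on per-particle mean RGB (k-means++, n_init = 10, fixed seed),
the darker centroid labelled "black"; degenerate single-colour inputs
collapse to one class with a warning. Rim-touching particles are
retained but flagged. Multi-photograph boluses are pooled with re-keyed
ids and classified jointly.

## Digestion kinetics and starch fractions

Intestinal starch curves follow the fractional conversion model
S(t) = Sf + (S0 − Sf)·exp(−ks·t), rising from S0 to the plateau Sf with
rate ks (1/min). The decaying exponential with positive ks is used —
rate tables for rising curves report positive rate constants, and the
model is only sensible in that orientation. Fitting is nonlinear least
squares on log-parameters (positivity without clamping), initialised
from the first/last observations and a log-linear slope; adjusted R²,
residual and parity tables come from `fit_diagnostics`. Noiseless
curves generated at the nine standard intestinal sampling times
(0–240 min) from all 18 reference parameter sets are recovered within
0.5%; under 5 mg additive noise the median ks error over 200 replicates
stays within 10%. Protein curves are zero order, P(t) = P0 + kp·t,
fitted by closed-form OLS (kp in mg/min; reference tables print the
conventional ×10⁻² presentation). The gastric phase is summarised by its
0 and 120 min samples only — no kinetic model is fitted there.

Starch fractions use RDS% = 90·G20/TS, SDS% = 90·(G120 − G20)/TS and
RS% = 100 − RDS% − SDS%, with 0.9 = 162/180 the glucose→anhydroglucose
mass ratio. The resistant fraction is computed as the complement so the
three fractions conserve exactly; the reference rows sum to 100.0
within print precision, confirming the convention. Preconditions
(TS > 0, G120 ≥ G20 ≥ 0, 0.9·G120 ≤ TS) raise errors naming the
violated condition.

## Texture and PEF

Specific energy input is pulse energy × pulse count / treated mass
(kJ/kg) and treatment time is pulse count × pulse width (ms); both are
exactly linear in pulse count. The per-pulse energy of the generator is
not published, so the headline 8 and 13 kJ/kg settings are illustrative
only. TPA parameters follow the standard Bourne conventions on
force-time curves: hardness = first-cycle peak; cohesiveness =
area₂/area₁; springiness = compression-stroke duration ratio (the
distance-ratio alternative is not recoverable from force-time data
alone); chewiness = product of the three; resilience = withdrawal/
compression area ratio of cycle 1. Cycles are trigger-threshold runs
(0.049 N) extended along the monotone approach to zero force, which
removes the trigger-level bias from durations and areas. The quadratic
response-surface model (intercept, 3 main effects, 3 interactions, 3
quadratics) is fitted by OLS on raw factor scales (optional centring),
with standard errors from the residual variance and per-coefficient
two-sided t-tests, screening-style without multiplicity adjustment.

## Cohort classification

A participant below the reference median duration of every sample is
"fast", above every median "slow", otherwise (including exact ties)
"inconsistent"; the labels partition the panel and are invariant under
monotone rescaling of a sample column. The reference medians default to
within-panel per-sample medians (midpoint convention for even counts),
but note a structural fact: with an odd panel the sample median *is*
one participant's value, so at most (n−1)/2 participants can be strictly
below it — a 9-fast partition of 17 participants is unattainable against
within-panel medians. Panels designed around known group thresholds
(such as those from `synth.generate_panel`, which places fast strictly
below and slow strictly above its designed medians and alternates sides
for inconsistent chewers) should therefore classify against the design
medians the generator returns. Amylase activity is generated as a linear
function of mean duration plus Gaussian noise whose variance is solved
from the target Pearson correlation (r = 1 gives exactly collinear
data; r = 0.88 at n = 1000 lands within ±0.05). Correlations are
computed on per-participant sample-averaged metrics (the pooling level
is configurable) with pairwise-complete observations.

## Pipeline

`pipeline.run_pipeline` chains panel generation → plate rendering →
segmentation → per-class Rosin-Rammler fits → digestion curve
generation and fitting → starch fractions → chewer classification →
correlation report, persisting every intermediate CSV, a JSON report
and a log with per-stage seeds (spawned from one seed via
`SeedSequence`, so reruns are byte-identical). Latent per-participant
parameters are linked to chewing duration (longer chewing ⇒ smaller
x50, higher b, more released glucose/serine) so the designed
correlation signs are recoverable end to end. The default demo uses 6
participants, 24 particles per plate at 900 px and runs in well under a
minute; these sizes are the package's demonstration defaults and scale
up linearly.

## Known limitations

* The renderer's flat colours make segmentation near-exact; real
  photographs (gloss, shadows, touching particles) would need threshold
  tuning and possibly watershed splitting, which is out of scope.
* `sample_particle_areas` requires b > 1; broader-than-exponential area
  distributions (b ≤ 1) have no normalisable size-debiased density at 0.
* The response-surface module screens coefficients; it does not attempt
  to reproduce any particular published optimum, since the underlying
  screening data are not available.
* Correlations among synthetic metrics reflect the generator's designed
  links, not biology; passing tests validate the estimators, not the
  study's empirical claims.
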