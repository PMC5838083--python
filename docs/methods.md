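# Methods

This note documents the models and procedures implemented in `cpforage`,
the choices made where the design was genuinely open, and what the
synthetic test bed does and does not establish about real data.

## Problem and model

For a central-place forager, presence-only telemetry cannot be contrasted
against true absences; the package follows the pseudoabsence strategy of
contrasting each observed foraging trip against correlated random walks
(CRWs) — trajectories the animal could plausibly have taken had it moved
independently of the environment. The probability that a daily position is
an observed presence rather than a CRW position is then modelled as

  logit P(presence) = β₀ + Σⱼ fⱼ(xⱼ) + b_individual

with smooth functions fⱼ of the environmental covariates and an
individual-level intercept b. The covariates are SST (°C), log₁₀ Chl-a
(mg m⁻³), log₁₀ EKE (cm² s⁻²) with EKE = (u² + v²)/2 from geostrophic
currents, SLA (cm), SLA SD, SST SD, meridional wind (m s⁻¹), bathymetry
(m, negative below sea level), √bathymetry SD, and great-circle distance
from the colony (km).

### Fitting

Smooths are penalized cubic B-splines with basis dimension 4 (so each
term's effective degrees of freedom, edf, is at most ≈3), fit by penalized
IRLS (statsmodels `GLMGam`, binomial family, logit link). The individual
intercept is realized as a ridge-penalized group-indicator term — an
identity-penalty "smoother" whose penalty weight plays the role of the
variance-component ratio, which is the classical shrinkage estimator of a
random intercept. Population-level predictions set the group effect to its
mean (zero).

Penalty weights (one per smooth plus the group ridge) are selected by
AIC-based numerical search (Nelder–Mead). Three numerical guards matter at
the sample sizes this package targets (a few hundred rows):

- the search can land in a degenerate optimum; the fit falls back to unit
  penalty weights whenever the selected weights do not improve AIC;
- selected smooth-term weights are floored at 3.0 (a smoothing floor that
  suppresses boundary wiggle in data-sparse covariate ranges) and the group
  ridge at 10⁻³;
- per-term edf is computed directly as diag((XᵀWX + S)⁻¹XᵀWX), which stays
  finite and stable when a penalty weight sits at a search boundary, and
  AIC is computed as deviance + 2·(total edf) from probabilities clipped
  away from 0/1, which remains finite under quasi-separation.

Per-term significance uses Wald chi-square tests on the smooth
coefficients; a term shrunk to (essentially) zero edf reports p = 1, since
its Wald reference distribution degenerates. An optional double-penalty
(term-selection) ridge on the spline null space is available
(`ModelSpec.shrink`) but off by default. Deviance explained is
1 − D/D₀ on the clipped deviances (an adjusted-R² analogue for binomial
models). AUC is in-sample, on the conditional fitted probabilities.

### CRW null model

For each trip phase (outgoing: start→apex; incoming: apex→end, apex =
position farthest from the colony, earliest index on ties), simulations
preserve the observed step-length sequence and per-step durations exactly;
turning angles are drawn from a wrapped normal with the circular mean and
SD of the phase's observed angles; the initial heading is uniform. A step
landing on land triggers resampling of a replacement length (drawn with
replacement from the phase's step-length pool) plus a fresh angle, up to
100 retries, then a full restart (up to 20) before the simulation is
flagged as a land violation.

The dissimilarity weight is implemented literally as
2(d_track − d_CRW)/d_track + Δθ/90 with Δθ the absolute difference of
start→end initial bearings wrapped into [0°, 180°]. Two readings of the
printed formula are ambiguous; both alternatives (leading factor applied
to the whole sum; absolute distance difference) are exposed as keyword
switches without changing the default. Consequences of the literal form:
the bearing term lies in [0, 2]; the weight decreases without bound as
d_CRW grows past d_track, so the quartile filter predominantly removes
short-and-misdirected simulations. The 75th-percentile cutoff is the
linear-interpolation quantile within each trip's own (clean) simulation
set; land violators are removed first.

Because each phase's simulation starts at that phase's first observed
position, the concatenated null trip (outgoing sim + incoming sim) is
discontinuous at the apex; this is acceptable for environmental sampling,
which is positionwise. The duplicated apex date keeps the outgoing
simulation's position.

### Dataset assembly

One trip per individual (most daily locations; ties broken by duration,
then trip id) is paired with one randomly selected retained CRW per phase,
giving a 1:1 presence:pseudoabsence design per trip. When matchup
exclusions (missing covariates, nonpositive values under a log transform)
unbalance the classes, the larger class is down-sampled per trip with a
seeded draw so the modeling table is exactly balanced. The replicate
ensemble re-draws only the CRW per trip (40 refits by default) and reuses
the first refit's penalty weights; per-refit selection changes the
aggregates negligibly at ~8× the cost.

## Synthetic test bed

The generator produces a winter coastal-upwelling domain: a straight
meridional coast with land to the east, an analytic shelf-to-abyss
bathymetry (depth monotone in distance from the coast), a cool SST band
whose width grows poleward and whose intensity pulses on a ~45-day cycle,
optional mesoscale SST texture and an optional offshore cold front, Chl-a
anticorrelated with SST plus an SST-independent productivity pattern,
drifting Gaussian eddies in SLA whose u, v are the anomaly's analytic
spatial derivatives (so EKE = 0 exactly where there is no flow), and SD
layers computed as local 3×3 spatial standard deviations. All fields are
generated on a one-cell halo and cropped, so the SD layers carry no
array-edge bias. All randomness flows from one integer seed through
`numpy.random.SeedSequence.spawn`.

Tracks alternate rookery haul-outs (1.5–3 days) with out-and-back trips
whose durations are lognormal (median 8 days) clipped to 2–23 days. At
each 6-hour step the heading is drawn from a ±180° fan (15° increments)
with probability ∝ exp(η) evaluated at a look-ahead point 5 step-lengths
ahead — the walker responds to broader-scale structure, a perceptual-range
assumption — plus an outward bias early in the trip and a homeward drift
that latches into a forced return when the remaining time requires it.
Geometry guarantees make trips exactly recoverable by segmentation: once a
walker has left the rookery neighbourhood, step endpoints and midpoints
must stay >10 km from the colony (steps are clipped at 25 km), so no daily
interpolate can re-enter the 5 km haul-out radius mid-trip.

### The packaged experiments

Two frozen experiments define the package's ground-truth checks.

**Recovery.** Ten individuals, six trips each, forage under a strong known
preference (linear in SST, coefficient −2.5 per °C, and in bathymetry,
+0.0008 per m) in a domain whose cold SST core sits on an offshore
upwelling front. The front matters: the CRW weight filter retains
simulations matched to each trip's net distance *and direction*, which
erases broad along-shore covariate contrasts, and depth already absorbs
any purely cross-shore signal. A cold core that is cross-shore but
*non-monotone* in distance from the coast is thermally distinct from depth
and survives the conditioning — without it the two preferences are not
jointly identifiable at this sample size and the fitted SST effect flips
sign between realizations. Success criteria: in-sample AUC ≥ 0.8 and
Spearman rank correlation ≥ 0.9 between each fitted partial response and
the truth, evaluated over the central 90% of the covariate's observed
range (the outer 5% tails are data-poor and their wiggle is uninformative).
At the packaged conditions the experiment yields AUC 0.855 and rank
correlations 1.00 (SST) and 0.91 (bathymetry).

**Null preference.** Fifteen individuals, four trips each, move with no
environmental preference through fields that are spatially unstructured
noise (flat SST, SST-independent Chl-a, no eddies, an unstructured current
background so EKE stays positive). This isolates the statistical null:
even with zero preference, central-place trips and uniform-heading CRWs
differ systematically in *accessibility-linked* covariates (measured here:
bathymetry ≈ 0.4 SD, colony distance ≈ 0.3 SD, because out-and-back coastal
trips hug shallower water than unconstrained walks) — a genuine property
of the sampling geometry, not a false positive of the statistics. The
type-I check therefore fits the five dynamic covariates (SST, Chl-a, EKE,
SLA, SLA SD) and excludes depth. At the packaged conditions no covariate
is significant at p < .001 in any of 40 refits and the mean in-sample AUC
is 0.543.

### What the synthetic tests do and do not show

They establish that the pipeline is internally correct: the weight, box
mean and AUC match independent oracles to near machine precision; step
lengths are conserved exactly; a strong, identifiable preference is
recovered in shape and sign; and no preference is invented where none
exists. They do not establish performance on real telemetry: ARGOS
location error (beyond optional Gaussian jitter), gappy duty cycles,
behaviourally heterogeneous trips, and real covariate fields with
cross-correlated mesoscale structure are all absent. The accessibility
confound quantified above is a real-world caveat as well: in any
central-place design, depth- and distance-like covariates are partly
significant because of where the animal *must* be, not only where it
*prefers* to be.

## Other numerical choices

- Great-circle distances use the haversine form with Earth radius
  6371.0 km; bearings are initial bearings; angle differences wrap to
  (−180°, 180°] (turning angles) or [0°, 180°] (bearing differences).
  Coincident points have bearing 0 by convention.
- Daily regularization interpolates longitude and latitude linearly in
  time at 00:00 UTC epochs, omits epochs whose bracketing observations are
  more than 3 days apart, and removes positions on land (bathymetry ≥ 0 at
  the nearest grid cell — the single land test shared with CRW rejection
  and prediction masking).
- The speed filter (default 3 m s⁻¹ sustained) removes interior positions
  implying excess speed against both neighbours, iteratively; only when no
  interior spike remains is the trailing position judged by its single
  incoming speed.
- Box membership uses cell centres in half-open intervals
  [lon−b/2, lon+b/2) so edge counts are reproducible; temporal matching is
  nearest-slice within the variable's native window, not window averaging.
- log₁₀ is used where a logarithmic transform is required (the ocean-colour
  convention); records with nonpositive Chl-a or EKE are excluded.
- The kernel UD uses an isotropic Gaussian kernel with the classical
  reference bandwidth h = σ·n^(−1/6) (σ² the mean coordinate variance) on
  a local equirectangular km projection about the points' centroid;
  contour levels are the smallest-area regions holding the stated mass.
- Suitability is the predicted probability itself (already in [0, 1]); an
  optional per-surface min–max rescale is available behind a flag.
- Prediction covariates are sampled at 0.25° cell centres with the same 1°
  box-mean operator and transforms as training; covariate values outside
  the training range are clipped to it (B-spline bases do not
  extrapolate).
- Pipeline stage seeds derive from the master seed by `SeedSequence`
  spawning; identical config + seed reproduces byte-identical outputs.

## Known limitations

- The additive model's smoothing-parameter search is AIC-based, not REML;
  at small n the smoothing floor substitutes for the extra regularization
  REML would provide.
- In-sample AUC is reported (no held-out evaluation); it is optimistic by
  the fitted degrees of freedom, which is why the null experiment's AUC
  band was sized at n ≈ 550 rows.
- The CRW null is environmentally blind by construction; it cannot
  distinguish preference from accessibility for covariates aligned with
  the colony-distance gradient (see above).
- Simulated haul-out behaviour is simplified (no wet/dry sensor
  semantics); the haul-out radius rule is a proxy, and trips shorter than
  ~2 days may contribute too few daily positions to enter the model.
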