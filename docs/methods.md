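# Methods

## Data model and binning

The raw input is a long-format detection table: one row per
(site, sample, taxon), each sample carrying a calibrated age in years BP and
each site longitude/latitude. Detections are presence/absence; abundance is
deliberately out of scope. Validation collapses duplicated
(site, sample, taxon) rows, requires each sample to map to exactly one site
and one age, and rejects negative ages.

Samples are binned into half-open intervals [k·w, (k+1)·w) anchored at 0 BP
with width w = 500 years by default; an age exactly on an edge belongs to
the older bin. The anchor-at-zero, half-open convention is a package choice:
it is deterministic, independent of the observed age range, and matches the
"per 500-year interval" framing; no other convention changes any conclusion,
only bin labels. Within a bin, a site's samples are pooled by set union into
one *community*; the per-sample taxon sets are retained because alpha
diversity is defined per sample. A bin's communities form a *metacommunity
slice*; slices with fewer than 2 communities are flagged excluded rather
than dropped, so no data disappears silently.

## Diversity metrics

Mean alpha ᾱ is the arithmetic mean of per-sample richness. Two pooling
modes exist because a site can contribute several samples to one bin:
`per_sample_mean` (default) pools every sample across sites;
`per_site_then_mean` averages within site first. With one sample per site
per bin they coincide.

Gamma γ is the richness of the slice union, and additive beta is the Lande
partition β_add = γ − ᾱ, reported on the same slice so the identity
γ = ᾱ + β_add holds to machine precision by construction.

Zeta diversity ζ_n is the mean intersection size over community subsets of
size n. All subsets are enumerated exactly whenever C(k, n) ≤ 100,000 —
always at study scale (k ≤ 10, max 252 subsets) — with a seeded Monte-Carlo
estimator for larger metacommunities; the estimator's subset-level standard
deviation is reported as an uncertainty extension (no uncertainty is defined
for exact enumeration of a census). ζ₁ equals mean community richness and is
used only as an internal test identity, not reported. Zeta ratios
ζ_{n+1}/ζ_n are emitted for consecutive orders and set to missing where the
denominator is zero. The maximum order defaults to the number of communities
present in the bin, overridable.

## Temporal turnover

Between consecutive bins (older → younger; appearance = immigration,
disappearance = extirpation), the species exchange ratio is
β_d = (S_imm + S_ext)/S_tot with S_tot the union of the two sets. A 0/0
comparison yields *missing*, never 0, since 0 would fabricate stability.
"Consecutive" means temporally adjacent bins; comparisons across gaps are
off by default (`bridge_gaps` enables them) because nothing principled is
known about what a gap-spanning rate would estimate.

The partition has three levels: per community (one series per site, then
the per-bin-pair arithmetic mean, with missing values excluded and counted),
on the metacommunity unions, and within the shared-taxa subset. The shared
set of a bin defaults to the intersection of *all* communities present —
the single full-order zeta combination — so the order may differ between the
two bins of a pair as the number of communities does. When a lower order is
requested explicitly, the shared set is defined as the taxa occurring in at
least that many communities (which reduces to the full intersection at the
top order); this is the package's definition, adopted because a partial
order does not single out one subset.

## Subsampling adjustment

To control for the growing number of communities, each included bin has
`n_communities` communities drawn uniformly without replacement per
iteration (default 3 communities — the headline adjusted-gamma setting —
and 100 iterations; the 1–5 sweep is a config list). Metrics are recomputed
per draw and averaged. Sampling starts at the oldest bin that holds enough
communities; earlier bins are excluded and listed, and a later bin falling
below the requested size is a configuration error rather than a silent
skip. Drawing all communities reproduces full-data values exactly, which is
tested, as is Monte-Carlo convergence to enumerated expectations at 3
standard errors.

## Distance decay

Sites are pooled over each climate-related Holocene subdivision (defaults:
Early [11,700, 7,700), Middle [7,700, 3,700), Late [3,700, 0] years BP,
the literal 4,000-year division of the Holocene; older Late Glacial samples
belong to no subdivision). For every community subset of every zeta order,
one record pairs the subset's shared-taxon count with its mean pairwise
distance. Distances are great-circle (haversine) kilometres by default:
raw lon/lat Euclidean distances are unit-inconsistent at 67–70° N, where a
longitude degree is ~40% of a latitude degree. A planar Euclidean option
exists for user-projected coordinates. The subset distance for orders > 2
is the mean of pairwise distances, the standard multi-site convention.

## Trend fitting

Metric series (age vs value) are fitted with penalized B-spline smooths
(statsmodels GLMGam; basis dimension min(6, n−2), cubic splines). The
penalty weight is selected by grid search over 10⁻³…10⁵ minimizing an AIC
with effective degrees of freedom (the trace of the influence matrix).
Series with fewer than 5 points, and smooths that degenerate to exact fits,
fall back to a linear predictor in the same family, flagged on the fit.

Families follow the response type: counts start Poisson and escalate to
negative binomial (dispersion estimated by moments from the Poisson fit)
and then Tweedie (variance power 1.5) when the Pearson dispersion statistic
exceeds 1.5; averages used as count responses may be rounded to whole
numbers first to retain count-like mean-variance scaling. Proportions use
binomial, Gaussian or beta regression (boundary values compressed into
(0,1) by the usual Smithson–Verkuilen transform). The reported trend test
compares against the intercept-only model of the same family: chi-square
where the dispersion is fixed, an F-type statistic where it is estimated,
and a likelihood ratio for beta regression; the reported R² is a
deviance-based adjusted pseudo-R². These statistics characterise *this*
smoother; effective-df, F and R² values from other GAM implementations
(e.g. mgcv's REML smoothness selection) are implementation-dependent and
not comparable number-for-number — fitted shapes and directions are the
reproducible quantity. Trend *direction* compares the fitted values at the
youngest and oldest observed ages (age runs backwards), declared flat when
the trend test is non-significant at 0.05; no multiple-testing correction
is applied, and p-values are reported per fit. Site-specific data
exceptions (dropping a named site's most recent sample; per-site family
overrides) are explicit pipeline-config entries, never silent behaviour.

## Synthetic metacommunity generator

The generator emulates a postglacial occurrence record at the level the
analysis assumes: *site occupancy* evolves by a per-taxon Markov chain
(unoccupied → occupied with immigration probability p_imm, occupied →
unoccupied with extirpation probability p_ext, optionally ramped linearly
across the record), sites activate at staggered onset bins spread over the
first third of the record (ice-retreat style), and sediment samples are
independent thinnings of the latent community with per-taxon detection
probability p_detect. The regional pool splits into core taxa reachable
from every site with shared probabilities (driving zeta) and site-restricted
taxa (driving β_add). Defaults mirror the study scale: 10 sites, 13 ka in
500-year steps (26 bins), 290 taxa (50 core + 24 per site), one sample per
site-bin, p_detect = 0.8 reflecting a deep-replicate detection protocol.
Regime presets: additive homogenisation ramps immigration
(core 0.05→0.5, unique 0.02→0.2 per step) over constant extirpation 0.05;
diversifying-only sets core immigration to 0; static holds constant rates
started at the stationary occupancy p_imm/(p_imm+p_ext); subtractive
homogenisation ramps unique-taxon extirpation up while core sharing
persists. The single-taxon occupancy recursion
P(t+1) = P(t)(1−p_ext) + (1−P(t))·p_imm is exposed as an analytic oracle
and the ensemble-mean simulated occupancy is tested against it.

Randomness derives from one global seed through per-site child streams, so
output is byte-reproducible and independent of site iteration order.

What the generator does *not* emulate: DNA degradation or age-dependent
detection bias, taxonomic mis-assignment, spatial autocorrelation of
community composition (pools are distance-independent, which is exactly what
makes the flat distance-decay null testable), abundance structure, and
within-bin age uncertainty. Passing tests therefore demonstrate that the
*computations* are correct and that the analysis recovers known occupancy
dynamics — not that any particular real-world record satisfies the model's
assumptions.

## Problem sizes and test design

Verification runs at desk scale by choice: oracle-equivalence over 200
randomized metacommunities of up to 12 communities and 40 taxa (exhaustive
enumeration stays trivially cheap), Monte-Carlo checks at 10,000 iterations
against enumerated expectations at 3 standard errors, and regime-recovery
ensembles of 100 replicates of 8 sites × 26 bins (direction classification
by the linear-trend fast path, required correct in ≥ 95% of replicates).
The zeta implementation is cross-checked against an algebraically
independent route, the incidence-count identity
ζ_n = Σ_t C(m_t, n) / C(k, n) with m_t the number of communities holding
taxon t.

## Known limitations

- Zeta uncertainty (sd over combinations) is descriptive, not an estimator
  of a sampling distribution; the combinations of one bin are not
  independent.
- The negative-binomial dispersion is moment-estimated rather than profiled,
  which is robust at the short series lengths involved but not efficient.
- Beta-regression smooths are unpenalized spline bases (modest df), since
  no penalized IRLS path exists for that likelihood in the backend.
- The turnover partition assumes detection completeness is stable between
  consecutive bins; a strong detection trend would masquerade as turnover.
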