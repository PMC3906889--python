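# Methods

## Growth model

Each spot culture's background-subtracted pixel density over time is
modelled as logistic growth,

G(t) = baseline + K / (1 + e^(−r·(t − L))),

with four free parameters: an additive baseline (intensity units), the
above-background carrying capacity K (intensity units), the maximum
specific rate r (1/h), and L (h), the time at which the culture reaches
half its carrying capacity. The baseline is fitted by default because
real plate images carry nonzero background even after subtraction; fixing
it at the first observation is available by config (`FitConfig.fit_baseline`).

Fitting is bounded least squares (`scipy.optimize.curve_fit`, trust-region
reflective; K, r ≥ 0) from a deterministic starting point: K₀ = intensity
range, L₀ = interpolated half-range crossing time, r₀ = 4·(slope at
L₀)/K₀ clipped to [10⁻³, 10]. The default termination tolerance of 1e-12
recovers noiseless model-generated parameters to well under 1e-6.
Optimizer failure is reported as a non-converged, non-grown fit, never an
exception.

95% confidence bounds for K, r and L come from the curvature of the
least-squares objective at the optimum (the covariance returned by the
fit), reported as symmetric ±1.96·SE intervals. Profile-likelihood
intervals would be more accurate for strongly correlated parameters but
are not needed for the downstream scoring, which uses only the point
estimate of L.

The area under the curve A over the observation window integrates the
fitted curve, baseline excluded, via the closed form
(K/r)·ln((1 + e^(r(t₁−L)))/(1 + e^(r(t₀−L)))), evaluated with
log-sum-exp for numerical safety. Integrating the fit rather than the raw
data makes A a smooth curve parameter on the same footing as K, r, L.

**No-growth detection.** A culture is called non-grown when its fitted K
falls below a cut (default: the pipeline sets 5% of the plate-wide median
fitted K) or its R² falls below 0.7 — flat or noise-dominated series fail
one or both. The boundary is inclusive: K exactly at the cut still counts
as growth. Both cuts are config-exposed (`FitConfig.k_min`, `r2_min`);
they are operational definitions, since "no measurable growth" is a
qualitative notion.

**Dose-trend standardization.** To compare the dose sensitivity of
different curve parameters on one scale, per-dose groups of a parameter
are z-standardized against the untreated (zero-dose) group: every value
becomes (x − mean₀)/sd₀ (sample sd). The untreated group then sits at
exactly mean 0, sd 1, and dose trends in L, K, r and A become directly
comparable. A zero-variance untreated group is an error naming the group.

## Image quantification

Plates are a rigid rows × cols grid (default 16 × 24 = 384 spots) of
known pitch and origin. Per frame and cell, density = (pixel sum inside a
square window of side 0.9·pitch centred on the nominal spot position) −
(frame background × window area), where background is the median
intensity of all inter-spot pixels. Densities may be slightly negative
under noise; that is left uncorrected so the fit sees unbiased errors.
There is no per-spot re-centring or plate-warp correction: the synthetic
plates this front end is exercised on are rigid, and registration of real
plates is out of scope.

## Interaction scoring

With Y_i the strain's fitted L at dose D_i and RD_i the reference's
central value:

1. RD_i = per-dose median of the grown reference replicates (mean
   available by config). The median is the default because it is robust
   to censoring and outliers among hundreds of replicates; the reference
   band is the empirical central 95% (2.5/97.5 percentiles).
2. K_i = Y_i − RD_i removes the drug's dose effect.
3. L_i = K_i − K₀ removes the deletion's drug-independent growth effect,
   with K₀ = K at dose 0 (the "ORF effect"). L₀ = 0 holds exactly, by
   construction.
4. L_i = A + B·D_i + C·D_i² is fitted by unweighted least squares over
   the doses with measurable growth only (censored doses are excluded,
   not imputed). The intercept A is fitted freely even though L₀ = 0 by
   construction; with the dose-0 point included, A absorbs only fit
   residual and the evaluation below stays faithful to the fitted curve.
5. INT = A + B·D_max + C·D_max², with D_max the highest dose with
   measurable growth.

INT and K₀ are in hours. INT > 0 (longer half-capacity time, slower
growth) is a deletion enhancer of drug sensitivity, INT < 0 a deletion
suppressor. Calling thresholds are strict inequalities, by default
INT > 10 or INT < −16 for the misfolded-allele screen and > 10 / < −12
for the wild-type screen — tail cuts of the respective interaction-score
distributions, config-exposed.

**Tiers.** The number of doses without measurable growth is the strain's
tier. Strains with fewer than three grown doses get no quadratic
(INT = not applicable) but remain rankable: ranking is by tier
descending, then INT descending (unscoreable no-growth strains first
within their tier), then strain id — fully deterministic. Tiers are kept
as a separate ranking key rather than mapped onto the INT scale.

**Gene-drug scoring.** Conditions with too few concentrations for a
quadratic are scored singly:
score = (deletion_L − reference_L)_drug − (deletion_L − reference_L)_control,
i.e. the deletion-attributable shift adjusted for its control-media
growth effect. Any censored input propagates a not-applicable score.

**Overlapping-ORF diagnostic.** Deletion pairs whose open reading frames
overlap remove shared sequence, so their scores should agree; the Pearson
correlation of INT across such pairs is a reproducibility diagnostic of
the whole measurement chain.

**QC flags** (all cuts config-exposed, defaults in parentheses):
`large_zero_dose_effect` (|K₀| > 10 h), `poor_quadratic_fit`
(quadratic R² < 0.8), `plateau_response` (|B + 2C·D_max| < 5 h·mL/µg
while |INT| ≥ 10 h), `weak_effect` (|INT| < 10 h), and
`wildtype_context_interaction` (the companion wild-type screen also calls
the gene). High-confidence = called and flag-free.

## Profile clustering

Profiles are fixed-order vectors over perturbation columns (default 15,
labelled A–O: the two screens, control growth, and twelve gene-drug
conditions). Missing entries are imputed to column medians, with the mask
retained.

REMc fits diagonal-covariance Gaussian mixtures for k = 1..6 (10 seeded
EM restarts each), picks k by BIC, and re-clusters each resulting cluster
recursively until BIC prefers k = 1 or the cluster has fewer than 9
members. Candidate k is additionally capped at n divided by the minimum
cluster size, so a node is never offered more components than could each
hold a minimum-size cluster — without this cap BIC chases singleton
components in small high-dimensional nodes. Node names encode round and lineage ("2-0.1-1" style). Each
node's log-likelihood (the summed sample log-density under its fit) is an
indication of cluster quality. Every EM restart's random state derives
from the configured seed and the node's lineage, so trees are exactly
reproducible. The per-dimension variance floor (`reg_covar`, default
1e-2) matters: without it EM collapses components onto near-duplicate
points in high-dimensional, small-n clusters and BIC then over-splits
homogeneous data.

Within-cluster display order comes from agglomerative hierarchical
clustering with Euclidean distance and complete linkage.

Enrichment per term is the exact upper-tail hypergeometric probability of
the observed overlap between cluster and term, Benjamini–Hochberg
adjusted across terms within a cluster. Aggregate cluster-level
enrichment ("GOid_z-style") is a permutation z-score: the observed summed
−log₁₀ p over terms, standardized against the same statistic for random
same-size gene sets (default 200 draws). Gene sets are flat term → gene
tables; ontology DAG propagation is out of scope.

## Synthetic screens

The generator plants the structure the analysis assumes, with defaults
chosen to mirror the modelled screen's stated design and otherwise set to
realistic desk-scale values:

- dose ladder {0, 0.05, 0.1, 0.15, 0.2, 0.25} µg/mL; 768 reference
  replicates per dose;
- reference dose response RD(D) = 30 + 20·D + 100·D² h — a monotone
  growth delay reaching ≈ 41 h at the top dose, matching the qualitative
  shape of the modelled screen's reference band;
- strain logistic parameters K ∈ [80, 120] intensity units,
  r ∈ [0.3, 0.5] /h, observed 0–96 h every 4 h;
- planted effects: K₀ ~ N(0, 2 h) for all strains; enhancers draw a
  target INT from U(15, 40) h and suppressors from U(−40, −24) h (both at
  least 1.5× the calling threshold), split between B·D and C·D² by a
  random curvature fraction; null genes have B = C = 0;
- noise at two levels: intensity noise (sd 2, on a ~100-unit signal) and
  L noise (sd 0.5 h), so both the fitting and the scoring stage see
  realistic error;
- censoring: a strain whose noise-free composed L exceeds 70 h at a dose
  is emitted as a flat-at-baseline series there (exercising the
  no-growth detector); applying the rule to the noise-free L makes
  censoring monotone in dose;
- overlapping-ORF pairs share a planted effect (shared INT ~ N(0, 15 h))
  plus small independent jitter.

The generator emulates dose structure, main effects, censoring and
replication. It does not emulate plate spatial artifacts, edge effects,
batch effects, or non-logistic growth; passing tests therefore validate
the analysis logic and its statistical behaviour under the assumed model,
not robustness to those real-data pathologies.

Problem sizes in the test suite are chosen for desk-scale verification:
the end-to-end classification check runs a full 500-gene screen with
rendered time series (about 3,500 culture fits plus 4,608 reference
fits), while identity and determinism properties use smaller screens
since they are size-independent.

## Numerical choices and degenerate inputs

- Quadratic fits need ≥ 3 grown doses; below that INT is not applicable.
- A perfectly flat time series short-circuits to a non-grown fit.
- R² of a zero-variance series is 1 when residuals are zero, −∞ otherwise.
- Ranking ties break lexicographically by strain id.
- Tables are TSV, UTF-8, "NA" for missing, floats at %.17g with
  round-trip parsing, and a header comment with seed and config hash —
  byte-identical across reruns of the same config and seed.

## Known limitations

- Confidence bounds are curvature-based and can be optimistic when K and
  r are poorly identified (truncated curves).
- The quadratic is descriptive, not mechanistic; strongly non-quadratic
  dose responses are flagged (`poor_quadratic_fit`) rather than modelled.
- BIC-guided recursion can still over- or under-split clusters whose
  size sits near the minimum-size stopping rule.
- No p-values are attached to individual interaction calls; calling is
  threshold-based as in the modelled screen.
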