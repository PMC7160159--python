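# Methods

This note documents the models behind `otodiet`, the parameter choices
that matter, what the synthetic-data generator does and does not emulate,
and the numerical conventions. Units throughout: otolith/sulcus/cauda
lengths (OL, SL, CL) in mm at 0.01 mm stored precision; fish total length
(FTL) in mm; fish weight (FW) in g; predator (dolphin) length in cm.

## Data model and derivation rules

Stomach records carry a stranding date and predator length; season is a
total function of calendar month (Dec–Feb winter, Mar–May spring, Jun–Aug
summer, Sep–Nov fall) and age class partitions positive length into
young-of-year < 184 cm, older calves 184–211, subadults 212–240, adults
> 240, with fractional lengths floored to whole cm so the integer interval
labels are honoured exactly. Erosion grades 0–2 (sulcus fully visible) are
kept individually but pooled to category "0–2" for analysis; moderate to
severe erosion is a single pooled grade "3–5" that is never split back out
— broken otoliths belong to it and carry no measurements.

Prey number per stomach and species is the larger of the left and right
otolith counts; a tie counts the right side, since reference measurements
were primarily of right otoliths. Downstream grading, measurement and
biomass counting operate on that side only (`restrict_to_counted_side`),
so each fish contributes at most one otolith.

Measurement subsampling of the abundant heavily eroded otoliths is
stratified by predator age class (unknown is its own stratum):
largest-remainder (Hamilton) rounding of proportional quotas computed in
exact rational arithmetic, so remainder ties are genuine ties. Ties are
broken toward the stratum with the smaller floored allocation, then by
stratum name — a convention this package fixes because no standard
exists. Within strata, dolphins and then otoliths are drawn uniformly
under the supplied seed.

## Species discrimination from the sulcus ratio

The classifier is a univariate recursive partition on the ratio CL:SL.
Candidate cuts are the midpoints of consecutive distinct ratios; the
primary cut minimizes training misclassification of the two-leaf majority
rule (smallest minimizing midpoint on ties). A second, forced split is
then chosen to minimize three-leaf misclassification, with ties broken
toward the cut nearest the primary one so the middle leaf — the ambiguous
band — stays tight around the class boundary.

Cut-points and the band are expressed at two-decimal resolution, the
precision at which such rules are reported in practice; the band is the
closed interval [cut_low, cut_high] on the rounded ratio, and a ratio of
exactly .49 or .50 is therefore ambiguous rather than assigned. When the
two cuts round to the same value the band collapses and classification is
a strict two-way rule (ratio < cut goes low, ≥ cut goes high), so a
collapsed rule can never return "ambiguous". Leaf class probabilities are
add-one (Laplace) smoothed and floored at 0.003 before renormalization,
so no probability is ever zero. Ambiguous-band otoliths are apportioned
between species as expected counts n·p, largest-remainder rounded.

Reported fit statistics: `accuracy` is resubstitution accuracy (ambiguous
rows scored as the band-majority species); `cv_r2` is the cross-validated
proportional reduction in classification error relative to the
majority-class baseline, with folds assigned by seeded permutation
stratified by species. Nodule prominence (the crenulated bumps on
*Cynoscion* otoliths) is carried as data and summarized per species but is
not a classifier covariate by default; an option offers it to the split
search, where it loses to the ratio under any reasonable configuration.
Broken otoliths bypass the rule and are flagged `visual_unresolvable`.

## Size models

Three mean functions (linear, logistic, Gompertz, as written in the
README) are fitted by least squares on the raw response scale. The AIC is
the least-squares form n·ln(RSS/n) + 2(p+1), p the number of mean-function
parameters and +1 for the error variance; the small-sample corrected AICc
is available behind a flag but plain AIC is the default. Selection applies
two caveats in order: per predictor, the simpler linear model is chosen
whenever its ΔAIC ≤ 2 from the best; then, if one form won at least two of
the three predictors for a species/response, that form is imposed on all
three for consistency (recorded as `majority_form`).

Sigmoid fits self-start deterministically — A₀ = 1.05·max(y), x₀ at the
observation nearest the curve midpoint (A₀/2 logistic, A₀/e Gompertz), k₀
from an OLS fit of the linearizing transform — with three seeded restarts
that progressively inflate A₀, because weight fits frequently place the
asymptote far above the observed range (the fitted data cover only the
rising limb). If all restarts fail, the asymptote is profiled out: for
fixed (k, x₀) the optimal A has a closed form, leaving a 2-D Nelder–Mead
search over (log k, x₀). `r²` is 1 − RSS/TSS clipped to [0, 1]; a constant
response yields the degenerate slope-0 linear fit with r² = 0.

Predictions are exact evaluations of the stored form, vectorized; x ≤ 0
raises unless the non-strict mode is requested for analytic boundary
checks. Predictions outside the fitted predictor range are permitted but
flaggable (`extrapolates`) — eroded prey otoliths are below-range in OL by
construction. The 24 published equations ship as a JSON fixture verified
by SHA-256 checksum on load.

The per-fish residual comparison uses measured − predicted (positive
residual = model underpredicts). Differences across the three predictors
are tested by permuting predictor labels within fish: the global statistic
is the largest absolute pairwise difference of mean residuals, per-pair
p-values use that pair's difference, and all permutation p-values follow
the add-one convention (1 + #{perm ≥ obs})/(B + 1).

## Differential erosion

Because pre-ingestion lengths are unknowable, erosion is inferred from
structure: pairwise baselines among OL, SL, CL fitted on pristine
reference otoliths, with the faster-eroding feature as the response
(OL on CL, OL on SL, SL on CL). The deviation of a prey otolith is its
observed response minus the baseline prediction at its observed x; a
negative mean deviation means the response eroded more than the predictor
anticipates. Deviations are summarized per feature pair and grade category
with a seeded percentile-bootstrap 95% CI (B = 2,000 default); cells under
5 rows are reported as insufficient rather than estimated. The prey-side
regression lines are also emitted for overlay plotting. A classical
ANCOVA comparison is deliberately avoided — eroded prey violate the
common-slope assumption — in favour of these assumption-light signed
deviations.

The size-scale comparison estimates fish size from each of the three
features of the same otolith and tests the predictor effect by
within-otolith label permutation per grade category (Holm over the three
pairwise contrasts), and the grade-category effect by permuting category
labels over per-otolith mean estimates. The headline effect size is
100·(CL-based − OL-based)/OL-based. Permutation tests canonicalize row
order internally, so p-values are exactly invariant to how the caller
ordered the otoliths and reproducible under a fixed seed. The
repeated-measures ANOVA machinery of statistics packages is replaced by
this fully specified permutation scheme, and Tukey-style post hoc
adjustment by Holm; both substitutions trade a little power for exact
reproducibility without external test semantics.

## Biomass scenarios

For a stomach *St* and species, with W the estimated weights and N counts:

- Standard: `B_St = Σ W_{G0–2,St} + N_{G3–5,St} · mean(W_{G0–2, study})`
- Iterative: the same with the mean taken at the first non-empty level of
  stomach → month → season → study; the level used is recorded.
- Inclusive: `B_St = Σ W_{measured,St} + N_{unmeasured,St} · mean(W_measured)`
  with the same fallback; "unmeasured" covers broken otoliths and those
  not subsampled for measurement.

"Month" pools calendar months across years by default, mirroring the
seasonal pooling and avoiding empty cells in multi-year studies; a switch
keys months within year. A species with Grade 3–5 otoliths but no Grade
0–2 otolith anywhere raises an explicit error (the Standard mean is
undefined) rather than silently dropping the species. Weight estimation
defaults to sulcus length for croaker (its cauda is too variable) and
cauda length for spot, weakfish and spotted seatrout — the least
erosion-biased predictor per species — with an override hook and a
CL → SL → OL fallback when the preferred feature is unmeasured.

When every otolith is measured Grade 0–2, all three scenarios coincide
exactly; adding a Grade 3–5 otolith strictly increases biomass under each
scenario; totals are invariant to stomach processing order.

Seasonal differences in estimated weight are screened per species and
grade category with the tie-corrected Kruskal–Wallis test and Holm-
adjusted two-sided rank (Mann–Whitney) pairwise contrasts. Scenario
differences are tested by the same within-unit permutation scheme as
above, one unit per stomach.

## Synthetic-data generator

The generator produces data with the statistical structure the analysis
assumes; its parameter values are simulation choices for realistic
marginals, not estimates of any real digestive process.

Per species, fish length is lognormal per season; default medians place
larger croaker and spot in fall and larger weakfish in winter (croaker
and spot mostly 100–300 mm, weakfish wider and larger) — the seasonal
shifts the biomass scaling must contend with. Otolith length follows by
inverting the species' designated generating model (the packaged OL→FTL
equation), with lognormal response noise around the curve; sulcus length
is a noisy fraction of otolith length (mean 0.85, consistent with the
sulcus spanning most of a sciaenid otolith) and cauda length a noisy
fraction of sulcus length. The CL:SL fractions are the discrimination
lever: spotted seatrout 0.46 ± 0.015 and weakfish 0.53 ± 0.015, so the
tails straddle the 0.49–0.50 band; croaker (0.47) and spot (0.45) sit
away from it. Weight follows a length–weight power law FW = a·FTL^b
(a = 10⁻⁵, b = 3, lognormal noise σ = 0.08), the standard isometric
allometry for fusiform fishes.

Erosion acts multiplicatively — surface abrasion scales with size.
Otolith-length shrinkage is Beta-distributed scaled to [0, 0.20]; sulcus
shrinkage is a Beta fraction of it and cauda shrinkage a Beta fraction of
that, so shrink_OL ≥ shrink_SL ≥ shrink_CL holds draw by draw, encoding
that the sulcus features sit inside the abraded margin. The grade is
assigned from realized OL shrinkage via fixed thresholds (< 1% grade 0,
< 3% grade 1, < 8% grade 2, else 3–5), making grade and shrinkage
consistent by construction; thresholds are configurable. The 0.20 cap
(inside the configurable [0, 0.5] bound) keeps measured orderings valid
given the 0.85 sulcus fraction; an otolith whose measured ordering still
inverts is marked broken and unmeasured, mirroring the protocol of not
measuring obviously compromised otoliths. Recovery losses: independent
per-side loss (p = 0.2), complete digestion per grade (up to 0.25 for
grade 3–5, optionally certain for fish under a size threshold), breakage
per grade, and partial measurement of the grade 3–5 pool (p = 0.5),
which supplies the "not subsampled" unmeasured otoliths the Inclusive
scenario scales.

All randomness flows from one root seed through named substreams (stable
CRC-based keys), so stages regenerate independently and identically
across processes. Ground truth (each simulated fish with its true size,
weight and pre-erosion lengths) is returned alongside the observables,
and every recovered otolith links to exactly one fish.

What the generator does **not** emulate: visual misidentification (prey
species labels are true up to the ratio-based reassignment the pipeline
itself performs), otolith-shape variation beyond the three lengths,
measurement error correlated within reader or session, digestive-compartment
structure, and any calibrated erosion kinetics. Passing tests therefore
demonstrate that the pipeline recovers structure it is designed for when
that structure is present — not that the published field estimates are
reproduced, which would require the archived stranding data.

## Numerical conventions and problem sizes

Permutation and bootstrap replicates default to B = 2,000 with mandatory
seeds; p-values use the add-one convention and ≥ comparisons with a 1e-12
slack against float jitter. Apportionment arithmetic is exact-rational.
The test suite runs its simulations at deliberate desk scale — reference
collections of ~110 otoliths per species, 120-stomach pipelines, 200-seed
calibration and recovery experiments — chosen as the smallest sizes at
which the stochastic properties under test are stable.

## Known limitations

- The discrimination rule is univariate by design; it will not extend to
  species pairs whose sulcus ratio distributions overlap heavily.
- Weight-model forms are the three published ones; a length–weight power
  law composed with the length model is not among them, so direct weight
  fits on synthetic data carry mild approximation bias (empirically ~2%
  on totals, well inside the 10% truth-recovery bound tested).
- The exact AIC variant and optimizer of the original statistics package
  are unknowable; packaged equations are treated as ground truth and
  refitting is validated by parameter recovery on self-generated data.
- Biomass reconstructions cover only fish that left a recoverable
  otolith; no correction for complete digestion is attempted.
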