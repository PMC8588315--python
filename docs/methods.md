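# Methods

This note documents the statistical model behind each pipeline stage, the
conventions adopted where the field's usage is ambiguous, and what the
bundled synthetic data can and cannot establish.

## Community indices

CD and EP operate on a 10-slot colony-emergence series whose entries are the
*daily increments* of newly visible colonies (N₁…N₁₀), not cumulative
counts: only the incremental reading makes the 1/i weights of CD span the
documented [10, 100] range.  Proportions are taken against the cumulative
total after day 10; a plate with no colonies has no defined index and raises
`UndefinedIndexError` rather than returning 0, which would silently fake a
"slowest possible growth" signal.

EP is Shannon entropy over appearance days.  The log base is a free
parameter, default 10, because with 10 observation bins base 10 normalizes
EP to [0, 1]; 0·log 0 contributes 0.  For replicated plates both a
compute-then-average path (default) and a pool-then-compute path are
provided — entropy is concave, so the two differ on noisy data, and the
per-replicate path is the default because it weights each pot equally.

The r/K classification from CD uses a configurable threshold, default 35,
inclusive at the boundary.  No canonical cut-off exists in the literature;
35 separates the back-loaded presets (CD ≈ 10–30) from the front-loaded
ones (CD ≈ 45–100) and should be read as a reporting convenience, not a
biological constant.

## Impact factor IF_Pc

IF_Pc = A_Pc / A_C, with A values the arithmetic means over replicates
(median selectable).  Two denominator conventions are implemented behind
`baseline_mode`:

* `paired` (default): A_C is the same (dose, day) cell without the
  biostimulant, so IF isolates the amendment effect at each dose;
* `control-soil`: A_C is the uncontaminated biostimulated cell of the same
  day, so IF compares each dose against clean amended soil.

The default is `paired` because the stimulation/inhibition reading of
IF ≷ 1 is only meaningful against a same-dose baseline; the `control-soil`
mode is the literal transcription of the "control, non-contaminated,
biostimulated" phrasing common in this literature and is reported alongside.
The two agree on the dose-0 column exactly when uncontaminated soil is
unaffected by the amendment.  Zero or missing denominators — and zero
numerators, which would encode IF = 0 outside the > 0 contract — yield NaN
(flagged missing), never ±inf.  Swapping the input tables inverts the
matrix elementwise under `paired`; no such identity exists for
`control-soil`, whose denominator comes from the numerator table.

## Post-hoc grouping

Tukey HSD p-values are computed in-package from the studentized-range
distribution (`scipy.stats.studentized_range`): one-way ANOVA mean-square
error, q = |mᵢ − mⱼ| / √(MSE/2 · (1/nᵢ + 1/nⱼ)), i.e. the Tukey-Kramer
harmonic correction under unequal replication.  Groups need ≥ 2 replicates.
If the pooled within-group variance is exactly zero the comparison is
degenerate: equal means get p = 1, unequal means p = 0 (any difference is
infinitely many standard errors wide).  The default alpha for homogeneous
groups is 0.01.

Letters come from the insert-and-absorb compact letter display: start with
one all-inclusive letter column, split it on each significant pair, absorb
subset columns, and order the final columns by descending group mean so
'a' sits on the highest mean.  The invariant — two levels share a letter
iff they are not significantly different — is enforced by construction and
re-verified in tests against a brute-force checker.

## PCA of IF matrices

Treatment cells are cases, responses are variables.  Default is
correlation-matrix PCA (center, scale to unit variance with ddof = 1),
because IF ratios of different responses are not on a common scale;
covariance PCA is selectable.  The decomposition is an SVD of the scaled
data; explained percentages cover all components and sum to 100.  Loading
signs are arbitrary in any PCA, so each component is oriented to make its
largest-magnitude loading positive — printed loading signs from other
software are reproducible only up to this choice.  Cases with missing IF
cells are dropped and listed in the report.

## Two-proportion tests

Profiles are compared between pooled treatment-cell libraries (replicate-
level libraries are not modelled).  The 2×2 table is tested with the
Yates-corrected G-test against χ²(1); whenever any expected cell falls
below `fisher_threshold` (default 20, the convention of common profiling
software; exposed as a parameter) the two-sided Fisher exact p is reported
instead, and the result records which branch ran.  The Fisher p is computed
by exact integer enumeration of the hypergeometric support — numerators
C(n₁, x)·C(n₂, k−x) compared exactly, summed over tables no more probable
than the observed one — so results are reproducible to machine precision
and free of floating-point tie ambiguity.  The confidence interval for the
proportion difference is the asymptotic normal (Wald) interval with
continuity correction ½(1/n₁ + 1/n₂), clipped to [−1, 1]; the Newcombe
hybrid interval would be a reasonable alternative but is not the default.

Abundance filters: a taxon is eliminated when its relative abundance is
strictly below 1 % in every sample (boundary inclusive on retention), and
the "dominant" listing keeps taxa whose proportion difference between two
samples is ≥ 1 %.  Filters run at the aggregated analysis rank, and removed
read mass is returned, never silently dropped; retained proportions stay
referenced to the original library sizes.  Aggregation pools OTUs with an
empty slot at the target rank into an explicit "Unclassified" bucket so
column totals are conserved exactly.

## Synthetic data

The generator emulates the factorial pot design (5 doses × 3 days × 2
biostimulant levels, 3 replicates by default) with the standard
overdispersed families for each data kind:

* plate totals: negative binomial (size 25 by default; ∞ = deterministic)
  around baseline × dose-effect × biostimulant multiplier, spread over
  days 1–10 by a truncated-geometric appearance distribution (any
  10-vector accepted).  The organotroph preset uses p = 0.2555, chosen by
  root-finding so the expected CD is 49 — the anchor used to place the r/K
  threshold — and the actinobacteria preset reverses a p = 0.3 geometric
  (expected CD ≈ 15);
* enzyme activities: lognormal multiplicative noise with unit mean
  (CV 0.08 by default);
* OTU libraries: composition softmax(base logits + log-scaled dose ×
  shift), a Dirichlet draw at concentration 500, then a multinomial at
  library size 20 000, over a built-in 22-OTU, 5-rank mock taxonomy of
  common soil lineages;
* residues: dose·exp(−k·t), k = ln 25 / 15 ≈ 0.2146 d⁻¹ by default so
  exactly 96 % of the dose is gone by day 15; measurement noise optional
  and off by default.

Headline effect sizes are calibration anchors, configured once: the fungal
top-dose multiplier 0.24 (−76 % at day 15), the urease 1.65× at the 0.1 mg
dose on day 15 (+65 %), a near-linear β-glucosidase dose response
(r ≈ 0.99), mild phosphatase inhibition at the top dose, and a 1.15×
biostimulant multiplier on enzymes.  Within-cell variance levels are not
constrained by any published value and are set to plausible assay-scale
magnitudes; conclusions that depend on the noise level (e.g. which
contrasts reach significance at n = 3) should be read as illustrative.

What the generator does *not* emulate: replicate-level sequencing
libraries, taxon–taxon interaction structure, temporal autocorrelation
within a pot, enzyme–microbe coupling, and any mechanistic soil chemistry.
Passing tests therefore demonstrate the correctness and calibration of the
*analysis machinery*, not the biology of any particular soil.

A minimal null scenario (two groups, two enzymes, one day, 10 replicates,
no effects, no compositional overdispersion) is bundled for negative
controls.  It is deliberately small: Tukey controls the family-wise error
rate at alpha per family, so an "everything non-significant" expectation is
statistically robust only when few families are tested at once.

## Determinism and problem sizes

All randomness flows through `numpy.random.default_rng` seeded from the
scenario seed plus a fixed stream tag per generator, so identical
(config, seed) pairs give identical datasets and byte-identical report
directories; report provenance records the config hash, seed and package
version and deliberately omits wall-clock timestamps.  The test suite and
the reproduction script size their simulations to desk scale: 10⁴ random
series for index bounds, 10³ Monte-Carlo replicates for effect recovery
(assessed within two delta-method standard errors), 100 random layouts for
the Tukey and PCA oracles, exhaustive 2×2 enumeration up to per-sample
totals of 30 for Fisher, and the default 3-replicate factorial for
end-to-end runs.

## Known limitations

* Tukey HSD assumes a one-way layout; the pipeline slices the factorial
  into one-way comparisons (dose within day × amendment) rather than
  fitting a full factorial ANOVA.
* The Wald-with-CC interval can be conservative at extreme proportions;
  the p-value and the CI come from different procedures and can disagree
  near the significance boundary.
* Pooled-library proportion tests treat each library as one multinomial
  draw; true replicate-level overdispersion would widen the intervals.
* CD/EP averaging across replicates is not identical to pooled-count
  indices (entropy concavity); both are available, and reports state which
  path produced a number.
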