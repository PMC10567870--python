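# Methods

## Problem and model

A stain of unknown cellular origin yields DNA whose methylation state at
tissue-discriminating CpG sites reflects the secretion(s) it came from.
The workflow implemented here identifies seven body fluids — nasal
secretion, nasal blood, peripheral blood, menstrual blood, saliva, vaginal
secretion, sperm secretion — and their mixtures from pyrosequencing
methylation percentages at six CpG markers, conditioned on the three
conventional rapid pre-tests (hemoglobin for blood, amylase for saliva,
seminal markers for sperm).

The method is deliberately rule-based, not probabilistic: each marker
carries a small ordered set of threshold *tiers*, and each tier is either
unconditional or applicable only under confirmed-negative pre-tests. The
rationale is that a negative pre-test removes whole secretions from
consideration, shrinking the set of non-target distributions a threshold
must clear and therefore permitting a more permissive cutoff. The clearest
instance is the N27SE nasal band: the upper bound stays at 70% while the
lower bound relaxes from >40 (sperm negative) to >30 (also blood negative)
to >22 (also saliva negative).

Three decision rules are worth calling out because they are choices, not
consequences:

* **Strict comparison.** All cutoffs are compared strictly (`>` / `<`); a
  value exactly on a cutoff does not fire. The published cutoffs are stated
  as strict inequalities, and strictness is the conservative reading.
* **`not_done` is uninformative.** A pre-test that was not performed never
  activates a tier that requires a negative result. Threshold relaxation is
  only justified by confirmed exclusion.
* **Exclusion beats methylation.** If a tier names a fluid that a negative
  pre-test has excluded (possible for off-distribution values), the
  exclusion wins and a warning is recorded, since the rapid tests are the
  more direct evidence of presence/absence.

### Composite and partial calls

NB21 below 67% identifies "nasal secretion *or* nasal blood"; the pair is
separated only by the blood pre-test (positive → nasal blood, negative →
nasal secretion, not done → the ambiguous pair label). V2 above 25% proves
vaginal-*tract* secretion (vaginal secretion or menstrual blood); with a
negative blood pre-test this resolves to vaginal secretion as a component.
SA4 between 18 and 35% reports saliva as a partial mixture component rather
than a full call.

Positive pre-tests contribute components of their own: a positive sperm
test with N27SE below the pure-sperm cutoff still implies sperm as a
sub-component, because sperm-containing mixtures were observed down to
about 33% at N27SE — that value is used as the contradiction floor (a
positive sperm test with N27SE measured below 33% is flagged as
contradicted instead). A positive saliva test is supported whenever SA4 is
missing or above 18%. A positive blood test alone cannot say *which*
blood-containing secretion is present; if no blood-containing fluid was
otherwise identified, the result carries a warning rather than a guess.
Likewise, a blood-positive stain with V2 above 25% and B7 at or below 80%
is flagged "menstrual blood or peripheral-blood/vaginal mixture" — the
assays cannot separate these.

### Marker selection

Given pre-test results, `select_markers` returns the assays worth running.
The three canonical constellations follow casework logic: all tests
negative → V2 and N27SE (only the no-pre-test fluids remain in play);
blood and sperm positive → NB21, B7, MB4, N27SE (which blood-containing
secretion accompanies the sperm?); saliva positive with blood and sperm
negative → SA4, V2, N27SE. Any other constellation falls back to every
marker retaining at least one non-excluded target fluid (so three
`not_done` tests select the full panel).

## Calibration

Cutoffs are set the way the panel was originally established: locate the
gap between the target fluid's methylation range and the pooled non-target
ranges. For a hypomethylated target the cutoff is
`floor(min(non-target)) − 1 − margin` (call fires below it); for a
hypermethylated target `ceil(max(non-target)) + margin` (call fires above
it). Derived cutoffs are integers, as all published cutoffs are. The
published panel mixes margins (0 for B7, effectively 0 for NB21, 4 points
for MB4 — the last is preserved as configured data, not rationalized), so
no single margin reproduces the shipped defaults; the defaults in
`methylfluid.panel` therefore remain authoritative and derivation serves
validation and new markers. Conditional cutoffs are derived by dropping the
pre-test-excluded fluids' values from the non-target pool and re-running
the same rule. When target and non-target ranges overlap (the weak nasal
assays), the result reports the fraction of target values the rule misses
instead of pretending separation.

## Quality control

Duplicate assays must agree within 5 percentage *points* (absolute; a
relative rule would fail any disagreement near 0% methylation). A failing
marker is excluded, not imputed, and not re-run — the reference procedure
never needed the branch, so exclusion is the stated assumption here — and
the classifier tolerates the resulting partial profile with a coverage
warning. A failed bisulfite-conversion control invalidates the whole
sample; DNA concentration below 2.5 ng/µl (the minimum conversion input)
flags the sample. Passing duplicates collapse to their arithmetic mean.
Single replicates are accepted only behind an explicit `allow_single`
policy flag, default off.

## Synthetic cohort generator

The generator emulates the reference study's measurement-level data:

* **Single sources.** Each (fluid, marker) cell is a normal distribution
  with the reference cohort's mean and SD, clipped to [0, 100]. The parent
  normal is recentred (by solving for the location at which the clipped
  draw's expectation equals the published mean) so near-boundary cells —
  NB21 in sperm sits at 98.21% with SD 1.91 — keep the published mean; the
  shift is negligible elsewhere, and an SD of zero degenerates to the mean
  exactly. Nasal secretion and nasal blood share one distribution, as the
  reference cohort pooled them.
* **Outliers.** The documented off-distribution values are injected as an
  explicit component: B7 peripheral blood at rate 7/42 uniform on
  [60, 87.43]; N27SE sperm at rate 2/18 on {81, 73}; N27SE nasal at rate
  1/52 at 8. This reproduces the published *ranges*, including skew the
  normal bulk cannot carry, not just the moments. An optional
  post-menopausal vaginal subpopulation (V2 mean 22%, SD 7%) is available
  behind a flag, default off.
* **Mixtures.** A mixed stain's value is the DNA-mass-weighted arithmetic
  mean of independent single-source draws — the standard behaviour of
  methylation percentages in pooled DNA. The reference study did not state
  its lab-mixture proportions, and its empirical nasal+vaginal mixtures at
  N27SE (17–21%) sit below the equal-weight mean of the component means
  (23.01), so no default weight reproduces them; weights are left fully
  configurable.
* **Duplicates and QC injection.** Replicates are a latent value plus
  independent uniform noise on ±2.5 points, so pairwise deviation stays
  within the 5-point rule; excess-deviation and conversion-control failures
  are injectable at configurable rates for exercising the QC path.
* **Pre-tests.** Derived from composition: a test is positive iff a
  triggering component's weight exceeds a detection floor (default 0),
  idealising the rapid tests as perfectly sensitive and specific.
* **Seeding.** One master seed; per-sample generators are spawned by
  counter from a `SeedSequence`, so identical (design, seed) give
  byte-identical cohorts.

What passing tests on this generator do **not** show about real data: real
assays have correlated markers within a sample, imperfect rapid tests,
degraded/inhibited DNA, and distribution shapes the mean/SD summary cannot
capture; results on synthetic cohorts bound the workflow's arithmetic, not
its field performance.

## Validation metrics

Per marker and truth cohort, firings of the marker's target-identifying
tiers are tallied into TP/FP/TN/FN; sensitivity and specificity are
percentages rounded half-up to two decimals and recompute exactly from the
counts. N27SE is scored as two target rows (nasal, sperm). Sensitivity of
an empty target cohort is reported as not applicable, never 0. Validation
cohorts must be single-source labeled; mixtures are rejected.

## Problem sizes and numerical choices

The statistical test cohorts use 10 000 draws per (fluid, marker) cell for
the law-of-large-numbers checks (tolerance 3 SEM of the cell SD), 1000–2000
samples for generator-convergence examples, and a few hundred mixed stains
for classification-invariant sweeps; these sizes make the Monte Carlo error
small against every tolerance used. Methylation values are compared to
thresholds at full precision — no rounding before comparison. Degenerate
inputs are defined rather than left to chance: empty tier resolutions are
valid (no call), an empty collapsed profile classifies as undetermined,
and a missing concentration fails the concentration gate.

## Known limitations

* Nasal assays are intrinsically weak (published sensitivities 61% and 85%)
  and nasal mixtures with vaginal or sperm components land at 71–95% on
  NB21 — unrecognisable as nasal; the package reproduces this blind spot
  rather than papering over it.
* Menstrual blood cannot be fully separated from peripheral-blood/vaginal
  mixtures, nor vaginal secretion from menstrual blood below V2 50% without
  pre-test support; these surface as ambiguity flags.
* The decision logic is validated against the three published casework
  walk-throughs and the threshold chart; branches of the published
  flowchart not exercised by those cases are implemented conservatively
  (fallback marker selection, warnings instead of guesses) and not
  invented.
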