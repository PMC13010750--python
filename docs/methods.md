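# Methods

This note documents the models, defaults and numerical choices behind
`audiosem`, and what the synthetic experiments do and do not establish.

## Audiometric features

A record carries air-conduction thresholds at 500/1000/2000/3000/4000/6000/
8000 Hz per ear (dB HL, valid range −10..120), optional bone-conduction
thresholds, an optional binary tympanogram-quality flag per ear,
demographics (age, sex, ethnicity) and six comorbidity/lifestyle flags
(diabetes, hypertension, cardiovascular disease, noise exposure, smoking,
alcohol).

- **PTA** defaults to the standard four-frequency average (0.5/1/2/4 kHz).
  The frequency set is configurable because no single recipe is universal.
- **Air-bone gap** is averaged per frequency with negative per-frequency
  gaps clamped to zero: a bone threshold above air is measurement noise,
  not a physiologic signal.
- **Severity bands** use the conventional cutoffs 25/40/70/90 dB HL. The
  profound boundary is read strictly: PTA = 90 is severe, PTA > 90 is
  profound. Bands partition the whole real line, so banding is total and
  monotone.
- **Evidence predicates.** With usable bone conduction, conductive evidence
  is `ABG ≥ 15 dB` and sensorineural evidence is bone PTA > 25 dB HL. When
  bone conduction is missing — the normal situation in survey audiometry —
  an abnormal tympanogram with elevated air PTA stands in for the
  conductive pathway, and elevated air PTA with a normal (or missing)
  tympanogram defaults to sensorineural evidence, the most prevalent adult
  etiology. Both pathways are implemented; a record uses the bone pathway
  exactly when its bone map covers the configured PTA frequencies.

## Rule engine

The labeling stage is a forward-chaining engine over declarative
`condition → assertion` rules. Conditions are written in a small total
expression language (boolean connectives, numeric/string comparisons, set
membership) over named context features; rules carry integer priorities and
are resolved first-match within each of the four dimensions
(type → severity → laterality → treatment), iterating to a fixpoint so
treatment rules can reference the earlier labels. The shipped base has 18
rules in four families (4 type, 5 severity, 4 laterality, 5 treatment) and
lives in `src/audiosem/data/default_rules.txt`; users can edit it without
touching code, and the loader round-trips the canonical text bit-exactly.

Two deliberate closure rules make the base total on arbitrary inputs: a
lowest-priority type rule assigns *sensorineural* to hearing loss without
any specific evidence (the default-etiology reading), and a lowest-priority
treatment rule assigns *monitoring* to combinations such as subclinical
evidence without measurable loss. Type is classified at the patient level:
one conductive ear plus one sensorineural ear yields *mixed*, a literal
reading of "both characteristics detected in the same patient". Severity
and laterality are patient-level worse-ear summaries; a per-ear reading
would be equally defensible but is not implemented. The cochlear-implant
rule encodes candidacy only: "limited hearing-aid benefit" is not
measurable in these data, so it is noted in the rule description rather
than in the condition; unilateral profound sensorineural loss is grouped
with the hearing-aid recommendation.

**Validation** replaces description-logic consistency checking with a
brute-force sweep: per-ear PTAs 0–120 dB in 1 dB steps crossed with all 16
evidence-flag combinations (234,256 points). The report lists
exhaustiveness gaps (a dimension left unlabeled), equal-priority
contradictions, and rules that never fire first. Match results are memoized
on the context features each dimension's rules actually reference, which
keeps the full sweep around a second. On incoherent grid points that no
physical record produces (evidence flags set without hearing loss), the
type follows the evidence while severity stays *normal*; the invariant
"severity normal ⇔ type normal" therefore holds on coherent records (it is
property-tested on generated cohorts) but not on the raw grid.

An independent straight-line formulation of the four classification steps
(plain Python conditionals, no engine, no rule file) ships alongside the
engine and serves as its oracle: both are compared on 10,000 random ear
profiles in the test suite.

## SNOMED CT mapping

The mapping table is plain tab-separated text. Only the three
hearing-loss-type concepts are asserted (sensorineural 60700002, conductive
44057008, mixed 36885005); all other vocabulary entries — severities,
lateralities, treatment categories, normal hearing — are carried as
*provisional* with an empty concept id rather than inventing codes.
Annotation therefore leaves those cells empty while never dropping rows or
touching existing cells.

## Synthetic cohorts

The generator emulates an adult survey-style audiometry table and is the
test bed for every downstream stage. Defaults (all configurable):

| parameter | default | rationale |
|---|---|---|
| type mix | normal .45, sensorineural .30, conductive .15, mixed .10 | adult population: most normal; sensorineural the dominant etiology; mixed rarest |
| severity mix (affected) | mild .45, moderate .35, severe .12, profound .08 | severity prevalence decreasing |
| laterality mix | bilateral .60, unilateral .20/.20 | age-related loss is typically bilateral |
| noise_sd | 5 dB | test-retest variability of clinical audiometry |
| quantization step | 5 dB | audiometer resolution |
| comorbidity prevalences | diabetes .13, hypertension .33, cardiovascular .08, noise exposure .25, smoking .20, alcohol .55 | adult survey ballpark |

Shapes: sensorineural ears slope upward above 2 kHz (offsets +10/+20/+25/
+30 dB at 3/4/6/8 kHz) with bone tracking air; conductive ears are flat
elevated air over normal (5–10 dB) bone; mixed ears combine the slope with
a constant 20 dB air-bone gap over elevated bone; normal ears sit at
0–15 dB. Noise-free levels are drawn on the 5 dB grid at least 2 dB inside
the target severity band, so generative labels are unambiguous at
`noise_sd = 0` and the rule engine recovers type, severity and laterality
exactly there (the oracle-closure property). Tympanogram flags read
abnormal with probability 0.95 on ears with a conductive component and 0.05
otherwise. Because a mixed ear needs bone PTA > 25 *and* a 20 dB gap, its
air PTA cannot fall in the mild band; the severity mixture is renormalized
over moderate/severe/profound for mixed patients.

What the generator does **not** emulate: age-dependent threshold drift,
asymmetric or notched audiograms, severity differing between the two
affected ears, correlated comorbidities, longitudinal change. Passing tests
therefore demonstrate internal consistency of the pipeline on idealized
data, not clinical performance on real populations.

`inject_missingness` blanks audiometric cells independently at a given
rate (demographics untouched), feeding the complete-case filter, which
retains only records with all 14 air-conduction thresholds and logs each
exclusion with its missing fields.

## Clustering baseline

K-Means (scikit-learn, k-means++ seeding, 10 restarts, seeded) is applied
independently per task on standardized feature subsets: type uses the 14
thresholds plus per-ear air-bone gap and tympanogram flags (k=4); severity
uses the per-ear and worse-ear PTAs (k=5); laterality uses the per-ear PTAs
and their difference (k=4). Elbow/silhouette diagnostics are reported per
k; the diagnostic fit for each k is additionally warm-started from the
previous solution extended by the farthest point, which guarantees the
reported inertia is non-increasing in k. Anonymous clusters are named by
Hungarian assignment on the contingency table against the rule-engine
labels of the same records — a choice made for evaluation comparability,
since no naming procedure is published for this step; surplus clusters fall
back to their majority label with a warning.

## Classifier harness

Random Forests (scikit-learn) with defaults of 300 trees, unlimited depth,
`min_samples_split = 2`, `sqrt` feature subsampling, fixed seed, one job.
The split is 80/20 stratified; cross-validation is stratified 5-fold with
the *population* standard deviation (ddof 0) to match single-number
"mean ± sd" reporting. Grid search covers n_estimators
{100..500}, max_depth {10..50}, min_samples_split {2,5,10,20},
max_features {sqrt, log2}; ties break toward fewer trees, then shallower
depth. Grid search is exposed as its own operation and is not nested inside
the reported cross-validation. Log loss clips probabilities at 1e−15.
Feature importances are normalized mean impurity decreases.

The four prediction dimensions are trained as separate single-output
classifiers; headline metrics are reported for the type task. The
comparison runs the pipeline twice — K-Means type labels as targets with
raw features (age, comorbidity flags, 14 air thresholds, tympanogram
flags), versus rule-engine type labels as targets with the semantic
severity and laterality labels appended as categorical codes — and emits
both metric sets in one table. Bone-conduction thresholds are deliberately
absent from the classifier features, mirroring survey data in which they
are not collected.

A structural consequence, visible in the comparison on synthetic cohorts:
the K-Means targets are functions of (essentially) the classifier's own
feature space and are therefore learnable almost perfectly, while the
rule-engine targets carry bone-conduction information the classifier cannot
observe (about 1–2% of patients — chiefly tympanogram misreads on
conductive or mixed ears — are unresolvable from the observed features
alone). On this idealized test bed the K-Means arm's raw accuracy can
therefore match or exceed the ontology arm's, unlike on real survey data
where both labelings are imperfect proxies; the ontology arm still shows
the expected qualitative signatures (lower cross-validation variability,
higher log loss from more conservative probabilities, and semantic features
ranking among the top predictors).

## Determinism

Every stochastic step (generation, missingness, clustering restarts,
splits, folds, forests) consumes an explicit seed; identical seeds
reproduce cohorts, labeled CSVs, splits and comparison reports
byte-for-byte. The acceptance script derives all of its randomness from a
single `--seed`.

## Problem sizes

The shipped experiments use desk-scale sizes chosen to exercise every code
path with stable statistics: 500 noise-free patients for oracle closure,
10,000 random ear profiles for engine/oracle equivalence, the full
234,256-point grid for rule validation, 5,000 patients for mixture
recovery, and 4,000 patients at 5 dB noise for the two-arm comparison.
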