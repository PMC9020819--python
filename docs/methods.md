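# Methods

This note documents the models, conventions, and numerical choices behind
`percsim`: what the synthetic-study generator emulates, how each statistic
is defined, which defaults matter, and what the test suite's passing does
and does not establish about real data.

## Perceived-similarity RDMs from arena arrangements

An observer arranges the 4 exemplars of each of 10 categories in a
unit-radius circular arena; closer placement means higher perceived
similarity. `distances_from_arrangement` extracts the 6 pairwise Euclidean
distances per category (pairs stored with `exemplar_i < exemplar_j`,
lexicographic order). `to_percentiles` converts raw dissimilarities to
percentiles via average ranks, `p = (rank − 1)/(n − 1)`, which makes RDMs
invariant to any strictly monotone distortion of distances and comparable
across observers and modalities (behaviour, neural, model). Ties receive
averaged ranks; an all-equal input maps to 0.5 with a warning.

**Pooling scope.** Percentiles are pooled over the observer's full set of
60 within-category pairs, not per category. Per-category pooling would
quantize each category to the same 6 values and destroy all
between-category rank information; the cross-RDM correlations used
throughout operate on the 60-entry support and need that information. This
is a genuine design choice: single-arena tasks do not fix a spatial scale
across categories, so the simulated observer is given a consistent scale
across their 10 arenas (see Generator below), which makes pooled
percentiles faithful to the underlying structure.

**Similarity levels.** Per category the 6 percentiles are rank-ordered and
split 2-2-2: two smallest dissimilarities → *high* similarity, middle two
→ *medium*, two largest → *low*. At each of the two level boundaries, if
the two straddling percentiles are closer than `min_gap` (default 0.1),
*both* entries are marked excluded — exclusion removes the offending
values from both adjacent levels, keeping levels non-overlapping without
discarding whole categories. Ties in the 2-2-2 sort break by canonical
pair order (stable sort), which is recorded implicitly in the output
ordering. Under the default generator roughly a quarter to a third of
pairs are excluded; level-wise analyses operate on the retained support.

**Intersubject agreement.** For each observer, Pearson *r* between their
percentile entries and the element-wise mean of all other observers'
entries (leave-one-out). Level-restricted agreement uses the observer's
own partition to pick the entry support. The group test is a one-sample
t-test on Fisher-z values (one-sided, *r* > 0).

## The 1-back task and similarity slopes

The trial generator builds, per run, 3 no-response presentations and 1
catch presentation of every one of the 40 exemplars (160 trials, 75%
no-response). Catch trials immediately follow a presentation of their own
category — the identical exemplar (same-exemplar catch) or a different one
(same-category catch, type assigned with equal probability) — and never
open a run; consecutive no-response trials always differ in category, so
no unintended 1-back repeats occur. Sequencing is a greedy randomized
constraint-satisfaction with bounded restarts; an unsatisfiable
configuration raises an error naming the violated constraint.

Scoring counts, on same-category catch trials, same-exemplar key presses
as confusion errors; the error rate per similarity level is confusions
divided by same-category trials at that level. Misses (no press) are
tracked but not part of this numerator, matching the confusion-focused
definition of the error measure. RTs enter only from correct same-category
responses. The similarity slope is the OLS slope of the measure against
level index (low = 1, medium = 2, high = 3); the own-vs-other contrast
re-bins each observer's trials under every other observer's partition
(n − 1 iterations, averaged) and compares own vs other-mean slopes with a
paired one-sided t-test. Pairs excluded by the gap rule are dropped from
binning under every partition. Observers missing a level under some
partition are skipped for that iteration with a warning; the paired test
runs on the retained observers.

## Brain RDMs

Exemplar-specific patterns are means over no-response trials (catch trials
involve button presses and are excluded); the main RDM uses means over all
runs, run-wise means are reserved for decoding and stability. Dissimilarity
is 1 − Pearson *r* between mean patterns, computed within category only
(60 entries) and percentile-converted with the same pooled convention as
behaviour RDMs — conversion happens once, before any level restriction.
Zero-variance patterns make correlation undefined and raise a data error.
Split-half stability correlates RDMs computed on odd vs even runs (the
partition is a package choice; any balanced split would do).

## Brain–behaviour statistics

`brain_behaviour_correlation` aligns the two RDMs on the pair key and
computes Pearson *r* over percentiles; for level subsets the *behaviour*
owner's partition defines the support, and excluded pairs drop from both
sides. Group inference applies the Fisher z-transform before a one-sample
t-test (one-sided where the hypothesis is directional: *r* > 0, *i* > 0,
accuracy > chance; two-sided for region contrasts), Bonferroni-corrected
over the stated family (regions for whole-range tests, regions × levels
for level families). Degenerate zero-variance samples report the machine
floor rather than a fabricated statistic.

**i-index.** For one region, the cross-correlation matrix
`R[o, o'] = corr(brain RDM of o, behaviour RDM of o')` is computed with
each column restricted to the behaviour owner's subset support. Then
`i_o = R[o, o] − mean_{o'≠o} R[o, o']` and the group statistic is the mean
over observers. The null randomly relabels which observer each behaviour
RDM belongs to (permutations may fix labels; derangements are not
enforced) and recomputes the group mean from the same matrix, so the null
costs O(n²) per draw. `p = (1 + #{null ≥ observed}) / (1 + n_perm)` — the
add-one convention keeps p in (0, 1] — and the reported SEM is the null
distribution's standard deviation. Default `n_perm` is 10,000 for the CLI
and examples; the calibration suite uses 199 per cohort, which is
sufficient resolution at α = 0.05.

## Decoding

Pairwise (two-class) linear SVC per retained exemplar pair, C = 1,
features standardized with training-fold statistics, folds = runs
(leave-one-run-out on run-wise mean patterns). Pairwise classification was
chosen over 4-way-within-category or 40-way schemes because it maps
one-to-one onto the RDM's pair support, letting level partitions select
exactly the pairs they select everywhere else. Identical training classes
are undecidable and score 0.5 with a warning. Level accuracy is the mean
over the level's retained pairs, tested one-tailed against 0.5 with
Bonferroni over regions × levels.

## The lite HMAX model

Four layers: S1 applies zero-mean, unit-norm Gabor filters (4 orientations
× 8 sizes, 7–21 px; envelope and wavelength scale with size) by normalized
cross-correlation, so responses are contrast-normalized and invariant to
affine intensity changes. C1 takes, per orientation, the max over the two
sizes of each scale band (centre-cropped to common dimensions) followed by
a local spatial max (8×8 windows, stride 4, truncated at edges). S2
compares every C1 window with a dictionary of prototype patches sampled at
random positions/bands/images under a seed (default 200 patches, sizes
{4, 8, 12} C1 units), with Gaussian radial-basis similarity
`exp(−‖X − P‖² / |P|)`; C2 keeps the best match per prototype over all
positions and bands, giving values in (0, 1] that peak at 1 on an exact
match. The model RDM is 1 − Pearson *r* between C2 vectors, within
category, percentile-converted. The parameterization follows common HMAX
practice; no attempt is made to match any specific external
implementation numerically, so model-RDM comparisons are meaningful at the
rank/correlation level, not entry-by-entry.

## The synthetic-study generator

The generator defines the study conditions under which everything above is
exercised.

**Latent structure.** Each category has a centre in an 8-dimensional
latent space (centres normalized to a common norm — see Numerical choices)
and a random 2D plane through it. The 4 exemplars live in that plane:
exemplar 1 anchors the category and exemplars 2–4 sit at three
characteristic spacings (0.18, 0.75, 1.8 latent units, lognormal jitter
σ = 0.2) in random directions, producing six pair distances that span fine
to coarse so the three similarity levels are non-degenerate. Observer
*o*'s structure adds an in-plane Gaussian perturbation (σ_observer = 0.35
per coordinate) to every exemplar. Because perturbations stay in the
category plane, every observer's true within-category geometry is exactly
2D, so the arena can represent it exactly and the noiseless-recovery
contract (placement and pattern noise → 0 ⇒ downstream RDMs converge to
true distance ranks, Spearman → 1) holds exactly rather than
approximately. A consequence worth noting: with a uniform perturbation
scale, *relative* distortion is automatically largest for the
fine-spacing pairs, so high-similarity structure is the most
observer-specific — the gradient the analyses are designed to detect —
without any level-specific machinery.

**Arrangements.** The observer's true 4-point distances are embedded by
classical (Torgerson) scaling, all 10 categories are rescaled by one
common factor to fit the unit arena (max radius 0.95), and placement noise
(σ_place = 0.03 arena units) is added; if noise pushes a point outside,
that arrangement shrinks uniformly (monotone, percentile-invariant). The
single spatial scale across arenas is an idealization — real observers
renormalize each arena — and is what licenses pooled percentile
conversion.

**Behaviour.** On same-category catch trials the probability of a
confusion error follows a logistic in the observer's *own* similarity of
the pair, `p = σ(logit(0.08) + 3.0 · (s − 0.5))` with
`s = 1 − own percentile`; correct-response RT is
`0.7 + 0.35 s` seconds plus Gaussian noise (σ = 0.15, floored at 0.15 s).
Misses occur at 2%, same-exemplar catches are answered wrongly at 3%, and
no-response trials draw false alarms at 2% — the false-alarm structure of
real observers is not constrained by the task description, so this is a
free parameter kept small enough not to dominate scoring.

**Voxel patterns.** Each trial's pattern is a fixed random linear read-out
(per observer × region, entries N(0, 1/√D)) of
`w_shared · latent + w_observer · (latent + offset) + w_intermediate · f`
plus i.i.d. Gaussian noise; `f` is a fixed nonlinear mix (tanh of a random
projection) of the shared latent, standing in for intermediate visual
features. The read-out is constant across runs, so patterns are stable up
to noise. One pattern per trial; run-level averaging is downstream.

**Region archetypes.** The three defaults operationalize a
posterior-to-medial-temporal fidelity gradient:

| name | w_shared | w_observer | w_intermediate | σ_noise | encodes |
|---|---|---|---|---|---|
| noise | 0 | 0 | 0 | 1.0 | nothing (negative control) |
| LOC-like | 1.0 | 0 | 0.5 | 6.0 | shared structure, coarse scale only |
| PrC-like | 0.2 | 1.0 | 0 | 1.0 | the observer's own structure, fine scale |

σ_noise for LOC-like is set high enough that only coarse (low-similarity)
exemplar differences survive run-level averaging — its whole-range
brain–behaviour correlation stays robustly positive while high-similarity
correlation and decoding sit at chance; PrC-like keeps enough fidelity to
resolve even the finest pairs. These are the study conditions for all
parameter-recovery tests and were fixed once, as the definition of the
archetypes, across multiple generator seeds.

**What the generator does not emulate.** No haemodynamic dynamics, trial
autocorrelation, motion or physiological confounds; no voxel correlation
structure (noise is i.i.d.); stimuli are procedural textures, not object
photographs; behaviour has no lapses, fatigue, or speed–accuracy trading
beyond the parameters above. Passing parameter-recovery tests therefore
shows the *statistics* do what they claim under the stated generative
model — it does not certify sensitivity or specificity under realistic
fMRI noise.

## Numerical choices

- Category centres are normalized to a common norm (√D). Correlation
  distance divides by pattern magnitudes, so centre-norm variation would
  rescale a category's dissimilarities wholesale and scramble
  *within-level* rank alignment across categories; a common norm keeps
  brain-RDM ranks faithful to latent distances.
- Fisher z is applied before every t-test on correlations, uniformly, with
  inputs clipped away from ±1 by 1e-12 to keep atanh finite.
- Randomness: every draw derives from the study seed through named
  streams (crc32-hashed labels), so artifacts are bit-reproducible and
  independent of call order; derived seeds stay below 2³¹.
- Significance flags use p ≤ α, so α = 1 marks everything significant.
- Degenerate cases: all-equal dissimilarities → percentile 0.5 + warning;
  zero-variance patterns → error; identical SVM training classes → chance
  + warning; empty decoding levels → skipped + warning.

## Problem sizes

The acceptance suite runs the native design (23 observers, 10 × 4
exemplars, 8 runs, 60 voxels per region) for parameter recovery and
behavioural recovery; statistical calibration uses 200 independent null
cohorts of 8 observers, 2 runs, and 30 voxels with 199-permutation
i-index tests, sizes chosen so the binomial check at α = 0.05 is
well-powered while the whole suite stays lightweight. Unit and property
tests use 6-observer cohorts and 32–48 px images.

## Known limitations

- Exclusion-rule reading ("both straddling entries") and pooled percentile
  scope are documented choices among defensible alternatives; both are
  isolated behind `stratify_levels` / `to_percentiles` if a user needs the
  per-category or inner-entry-only variants.
- The level-restricted i-index inherits a selection effect: the observer's
  own partition picks the support, which can bias level-wise between-
  subject correlations slightly downward; whole-range i is the primary
  statistic.
- With heavy exclusion (tightly clustered percentiles) level supports can
  shrink below the 3-entry minimum and raise statistics errors rather than
  returning unstable numbers.
- HMAX here is a faithful but minimal reconstruction; its RDM should be
  compared to others only through correlations, never assumed to
  reproduce a particular published implementation's feature values.
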