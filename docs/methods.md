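# Methods

## Pose model and RMSD

All structures are reduced to ordered heavy-atom point sets (element symbol
+ Å coordinates). Hydrogens are dropped on input and RMSD is heavy-atom
throughout: decoy RMSDs in the docking-power literature are conventionally
heavy-atom, and hydrogen placement is a modelling artifact of preparation
tools rather than of the crystal structure. RMSD pairs atoms by index and
performs **no superposition** — docking decoys share the receptor
coordinate frame with the native pose, and aligning them would erase
exactly the displacement the statistic is meant to measure. No
graph-automorphism symmetry correction is applied (whether published decoy
RMSDs used one is not documented); a pluggable `atom_matching` hook exists
for callers who need a symmetry-aware matcher.

Receptor reading keeps standard amino-acid residues, always drops waters,
and drops other HETATM records by default (ligands arrive in separate
files); `keep_hetero=True` overrides this. Coordinates are used as stored —
no recentring.

## Features

The geometric family R counts occurrences of protein–ligand element pairs
({C,N,O,S} × {C,N,O,F,P,S,Cl,Br,I} = 36 keys) whose distance d satisfies
0 < d ≤ cutoff. The upper bound is **inclusive** ("within 12 Å" is read as
≤ 12; boundary cases are tested); d = 0 (coincident atoms, degenerate
input) never counts. The binned variant uses half-open-at-left intervals
(lo, hi]; the default five 4 Å bins over (0, 20] give 36 × 5 = 180
features. Elements outside the two sets are retained in structures but
contribute nothing to the counts — the 36-key schema is fixed, not adaptive.

Families X (6), A (30) and G (14) are descriptors of external empirical
scoring tools and are ingested as CSV/TSV tables keyed by
(complex_id, pose_id), never recomputed: recomputing them would amount to
re-implementing three scoring functions. Width mismatches warn (tables in
the wild vary); missing values and duplicate keys are hard errors — silent
imputation corrupts benchmarks. Note an arithmetic quirk: the combined pool
with the binned geometric family is 6 + 30 + 14 + 180 = 230 columns,
although the pool is often quoted as 220. Both widths are simply exposed;
experiments pick the pool explicitly.

In BA-response mode, training tables contain native rows only (one record
per complex): affinities can be measured only for native poses, and this
asymmetry — BA tables fixed in size, RMSD tables scaling with poses per
complex — is the mechanism the whole design turns on.

## Decoy construction

Candidates further than `max_rmsd` (10 Å) from the native pose are
discarded; bin k covers ((k−1)w, kw] with w = 1 Å. Each bin is clustered on
the pairwise pose–pose heavy-atom RMSD matrix with **complete linkage**,
cut to at most `clusters_per_bin` clusters. The published protocol says
only that poses were clustered "by similarity"; pairwise-RMSD
complete-linkage is the most defensible deterministic reading, and the
metric is pluggable. From each cluster the pose with the lowest interaction
energy is kept (ties → lowest pose index). Presets: `test100`
(10 clusters/bin → up to 100 decoys) and `train50` (5/bin → up to 50);
under-populated bins simply contribute fewer representatives, so totals
below 100/50 on sparse pools are expected behaviour, not an error. Whether
the native pose occupies a bin slot is exposed as `include_native`
(default off).

Representative selection needs a per-pose energy. Real pipelines provide
one (docking scores); for self-contained runs a deterministic
Lennard-Jones-like pair sum (4((r0/d)^12 − (r0/d)^6), r0 = 3.5 Å, 8 Å
cutoff, d clamped at 1 Å) is available. It is a *surrogate* with no
physical calibration — its only job is to be a deterministic, smooth
tie-breaker so the pipeline is runnable and testable end to end.

## Models

| method | backing | tuned parameters | fixed |
|---|---|---|---|
| MLR | least squares | — | — |
| MARS | in-house Friedman implementation | degree, penalty | terms auto-selected by GCV |
| kNN | Minkowski k-NN regression | k, q | — |
| SVM | ε-SVR, RBF kernel | C, ε, σ | gamma = 1/(2σ²) |
| RF | random forest | mtry (OOB error) | 2000 trees |
| BRT | gradient-boosted trees | interaction depth | shrinkage 0.005; tree count by internal 5-fold CV |

MARS is implemented in-package: forward selection of mirrored hinge pairs
(knots at quantiles of the parent's support, 16 candidates per variable;
interactions allowed up to `degree`), then backward deletion keeping the
subset minimising GCV = RSS/n / (1 − C(M)/n)² with C(M) = M + penalty(M−1)/2.
`penalty` is therefore the knot-cost parameter, matching the conventional
MARS parameterisation. Degree-1 models provably contain no interaction
terms (asserted via model introspection in tests).

BRT's interaction depth maps to trees with depth+1 leaves
(`max_leaf_nodes`), the same meaning as the R gbm parameter (number of
splits), rather than to tree *height* — at the published depths of 15–20 a
height-limited tree would be effectively unlimited.

Features are standardised (train-table mean/variance) for kNN and SVM
only; distances and RBF kernels are scale-sensitive while linear and tree
methods are not. Whether the original protocol standardised is unstated;
this choice is recorded here rather than guessed as equivalent. Published
tuned values for every method × 15 feature combinations ship in
`data/tuned_params.json` and are retrievable via `table1_params`.

Tuning minimises MSE by 10-fold CV grid search (MARS, kNN, SVM, BRT) or
out-of-bag error (RF mtry). Ties resolve to the smallest parameter tuple in
grid-key order. Every stochastic step takes an explicit seed (default
20070101); identical table + params + seed gives bitwise-identical
predictions, which the persistence round-trip test also relies on.

Ranking: RMSD-response models rank poses by ascending prediction,
BA-response by descending; ties keep input order (stable sort), so
optimistic/pessimistic re-analysis of ties is possible downstream.

## Evaluation

A complex is a hit at (C, N) if the minimum true RMSD among the N
top-ranked poses is ≤ C; C = 0 is implemented as RMSD ≤ 1e-6 Å so "the top
pose is the native" is robust to float noise. The cutoff comparison is
inclusive (the source convention — "within C Å" — does not specify; the
choice is documented and boundary-tested). Every report asserts
monotonicity of S_C^N in both C and N. Native-pose exclusion removes rows
with RMSD ≤ the zero tolerance before ranking.

Learning curves subsample complexes (10–100 %) or poses per complex
(2–50), refit, and average S_1^1 over repeats; feature curves draw feature
subsets without replacement from a chosen pool. Both harnesses derive
per-repeat seeds from one master seed.

## Novel-target splits

Inputs are a symmetric percentage similarity matrix (diagonal 100) — in the
original protocol BLAST binding-site similarity; computing it is out of
scope and the matrix abstraction hides the definition. A split draws
`n_test` complexes at random, then scans the remainder in random order for
`T` complexes whose similarity to *every* test complex is ≤ S; if fewer
than T qualify the test set is redrawn (bounded by `max_retries`, with the
best achievable T reported on failure). Larger S can only enlarge the
feasible pool for a fixed test set (set inclusion — property-tested). The
built-in `sequence_identity` (Needleman–Wunsch, match +1/mismatch 0/gap −1,
identity over alignment columns) is a deterministic testing surrogate, not
a claim of equivalence to BLAST.

## Synthetic data

`synthdata` emulates the *data regime* of a docking-power benchmark, not
its physics: receptors are element-typed points on an 8–14 Å shell around
the pocket; native ligands are points in the pocket; candidate poses apply
a random rigid translation plus per-atom jitter rescaled so the achieved
RMSD equals the target to < 1e-6 Å (exactness preferred over realism —
rejection sampling would make RMSD stochastic). Default scenario: 200
complexes, 20 poses per complex with targets uniform on (0, 12] Å (so the
10 Å filter and all ten bins are exercised), ligand sizes varying around 12
atoms. R features are computed from the actual geometry; the X/A/G families
are emulated by 50 columns of which 20 carry an RMSD-linked signal
(c·RMSD + d·RMSD² + N(0, sd²), sd = 1 by default) and the rest are pure
noise. The affinity label exists on native rows only and depends on ligand
size plus noise — deliberately informative about *affinity* but not about
*pose*, reproducing the structural reason BA-response models have weak
docking power.

What passing tests on this generator do show: the pipeline arithmetic
(bin/cluster/representative counts, feature widths, S_C^N), the direction
of the RMSD-vs-BA gap, and the direction of learning-curve effects. What
they do not show: absolute success rates on real complexes (synthetic
descriptors are far more informative than real ones — rates here saturate
near 100 %), feature-family rankings, or robustness to real chemical
diversity. Published benchmark-scale numbers additionally require the
original curated structures, decoy sets and proprietary descriptor tools,
and are out of scope.

## Problem sizes and numerical choices

The shipped tests run the central-claim comparison at the default scenario
scale (200 × 20; RF with its fixed 2000 trees dominates the runtime at
roughly two minutes) and the learning-curve direction checks at endpoint
sizes with 10 repeats using kNN. Oracle-equivalence suites use 100 random
small instances per primitive at 1e-10 (counts exact). Complete-linkage
tie-breaks, representative tie-breaks and ranking tie-breaks are all
lowest-index; cluster labels are renumbered by first appearance so output
is stable under deterministic input order.
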