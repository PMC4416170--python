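# poseforge

Machine-learning scoring functions for identifying native ligand binding
poses, built around the idea of modelling RMSD directly.

## The problem

In structure-based drug design, a docking program generates hundreds of
candidate binding poses for a ligand in a receptor's binding site and a
*scoring function* (SF) must pick the pose closest to the experimentally
observed (*native*) one. Conventional SFs score poses by predicted binding
affinity (BA), which carries the implicit assumption that higher predicted
affinity means lower deviation from the native pose. poseforge implements
the alternative: regression models trained to predict the pose's
root-mean-square deviation (RMSD, Å, heavy-atom, no superposition) from the
native pose, using decoy poses with computationally known RMSDs as training
data. Because every generated pose contributes a training record — while
affinities exist only for natives — RMSD-response training tables scale
with poses per complex, and the resulting models rank poses far more
accurately.

Docking power is quantified by the success-rate statistic

> **S_C^N** — the percentage of complexes for which at least one of the N
> top-ranked poses lies within C Å RMSD of the native pose,

over a grid of cutoffs C ∈ {0, 1, 2, 3} Å and depths N ∈ {1, 2, 3, 5}.
S_0^1 (the top pose *is* the native) is the most stringent variant.

## What is in the package

- `structio` — PDB receptors, multi-record SDF/MOL2 ligand poses, a common
  heavy-atom coordinate model, pose-set assembly.
- `posemetrics` — pose-pair RMSD in the shared receptor frame.
- `geomfeat` — geometric atom-pair count features: 36 protein–ligand element
  pair counts within 12 Å (family R), or 36 per distance bin (five 4 Å bins
  → 180 features); ingestion of externally computed descriptor families
  X (6 X-Score features), A (30 AffiScore/SLIDE), G (14 GOLD); the 15
  non-empty family combinations; feature-table assembly.
- `decoygen` — decoy construction: discard poses > 10 Å, bin into ten 1 Å
  RMSD bins, complete-linkage cluster each bin into ten clusters, keep the
  lowest-energy pose per cluster (10 × 10 = 100 diverse decoys per complex;
  a `train50` preset keeps 5 per bin).
- `sfmodels` — the six regressors MLR, MARS (in-house Friedman
  implementation with GCV pruning), kNN, SVM (RBF), RF (2000 trees, mtry
  tuned out-of-bag) and BRT (shrinkage 0.005, tree count by internal CV),
  each in BA- and RMSD-response modes, with published tuned hyperparameters
  per feature combination shipped as package data.
- `docking_eval` — S_C^N reports, native-pose exclusion, learning curves
  over complexes or poses per complex, feature-count curves.
- `simsplit` — novel-target protocol: train/test splits constrained so
  every train–test binding-site similarity is ≤ a cutoff S, from a
  precomputed similarity matrix.
- `synthdata` — a fully synthetic benchmark generator (receptor shells,
  exact-RMSD perturbed poses, RMSD-linked descriptors with tunable noise,
  native-only affinities) so the entire pipeline runs without any external
  data.

## Worked example

Generate the default synthetic benchmark (200 complexes × 20 poses), train
MARS and kNN in both response modes on 70 % of the complexes, and evaluate
S_1^1 on the rest:

```bash
poseforge bench --seed 20070101 --out bench_out/
```

```
     model response        S11
mars::XARG     RMSD 100.000000
mars::XARG       BA   3.333333
 knn::XARG     RMSD 100.000000
 knn::XARG       BA   5.000000
```

Reading: the RMSD-response models place a pose within 1 Å of the native
pose at rank 1 for every held-out complex, while the same learners trained
on native-only affinities almost never do — the affinity label carries no
information about which *pose* of a complex is correct, which is exactly
the gap the RMSD-response design exploits. (Synthetic descriptors are
strongly RMSD-linked, so the absolute rates are optimistic; the direction
of the gap is the point.)

The equivalent library calls:

```python
from poseforge import SynthScenario, make_benchmark, fit, evaluate, table1_params

scenario = SynthScenario()                 # 200 complexes x 20 poses
pose_sets, table = make_benchmark(scenario)
ids = table.index.get_level_values("complex_id").unique()
train = table.loc[table.index.get_level_values("complex_id").isin(ids[:140])]
test = table.loc[table.index.get_level_values("complex_id").isin(ids[140:])]

model = fit(train, "rf", response="RMSD", params=table1_params("rf", "XARG"))
report = evaluate(model, test)
print(report.rates)                        # S_C^N grid in %
```

Other subcommands: `poseforge validate`, `rmsd`, `featurize`, `decoys`,
`train`, `score`, `evaluate`, `split`, `synth` (see `poseforge --help`).

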