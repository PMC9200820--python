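# conformens

Analysis of protein **conformational ensembles** produced by structure
prediction: given a set of predicted models (decoys) for one sequence and a
per-model energy table from an external rescoring step, `conformens`
identifies the distinct conformational states the prediction explored and
characterises their internal motions against a reference (MD) ensemble.

It is aimed at structural bioinformaticians studying proteins with more than
one functional conformation — hinge-bending enzymes such as adenylate
kinase, open/closed integrin domains, apo/holo pairs — where the question is
not "is the fold right?" but "which states, and in what proportions, does
the predicted ensemble cover?".

## The method

Starting from an ensemble of `n` topology-consistent models with energies
`E_i` (kcal/mol):

1. **Energy triage.** Discard every model with `E_i > Ē` (the arithmetic
   mean of the set); ties with the threshold are kept. A Pearson
   energy-vs-RMSD correlation against a reference structure diagnoses
   whether the energy function discriminates near-native decoys.
2. **RMSD clustering.** Compute the pairwise minimised backbone RMSD matrix
   (Kabsch superposition per pair) and cluster it agglomeratively
   (average linkage by default). The cluster count `k` is chosen by a
   deterministic elbow criterion on the dispersion curve
   `W(k) = (1/n) Σ_c (1/n_c) Σ_{i,j∈c} d_ij²`
   (size-weighted mean within-cluster squared RMSD): `k` maximises the
   second difference `W(k−1) − 2W(k) + W(k+1)`, with `k = 1` short-circuited
   when `W(1)` is below a flatness floor.
3. **Centroids.** Each cluster is represented by its **lowest-energy
   member** — not a geometric average.
4. **Ensemble characterisation.** Per cluster and for the whole kept set:
   iterative alignment to the mean, per-residue RMSF (nm), Cartesian PCA of
   the aligned coordinates, projection of both the models and the reference
   ensemble onto PC1 with a kernel-density **overlap coefficient**
   (∫ min(f, g) ∈ [0, 1]), hinge descriptors (aperture angle at a hinge
   region, inter-domain distance), nearest-reference classification with
   population fractions, and the ensemble spread ΔRMSD (maximum pairwise
   backbone RMSD).

A seeded synthetic module generates ground-truthed stand-ins for all inputs:
a Cα hinge chain whose open/closed endpoints are connected by a
one-dimensional morph `x(λ) = (1−λ)·x_open + λ·x_closed`, decoys drawn from
a two-state mixture over λ with a double-well energy
`E(λ) = −E₀ + 16hλ²(1−λ)² + cλ + ε`, and a pseudo-MD trajectory as a
reflected mean-reverting (Ornstein-Uhlenbeck) walk on λ.

The clustering, PCA and classification stages are scikit-learn style
estimators (`RMSDHierarchicalClustering`, `EnsemblePCA`,
`NearestReferenceClassifier`) and compose with sklearn pipelines; module
functions are thin wrappers over them.

## Worked example

Run the full pipeline on the built-in synthetic two-state system (1000
decoys, 30 %/70 % open/closed mixture, double-well energies, pseudo-MD
reference):

```python
from conformens import RunConfig, SyntheticSpec, run_pipeline

config = RunConfig(
    synthetic=True,
    synthetic_spec=SyntheticSpec(n_models=1000),
    seed=1,
    out_dir="demo_out",
)
summary = run_pipeline(config)
```

which writes every stage's CSV into `demo_out/` and returns (abridged):

```json
{
  "energy_threshold_kcal_mol": -699.89,
  "n_models": 1000, "n_kept": 499, "n_removed": 501,
  "k": 2,
  "centroids": {
    "1": {"model_id": "m0799", "energy_kcal_mol": -732.16},
    "2": {"model_id": "m0117", "energy_kcal_mol": -725.74}
  },
  "populations": {"open-like": 0.3146, "closed-like": 0.6854},
  "ensemble_pc1_variance_fraction": 0.9989,
  "ensemble_pc1_overlap_vs_md": 0.431,
  "delta_rmsd_A": 24.26
}
```

Reading the numbers: the mean-energy filter kept 499 of 1000 decoys
(threshold −699.9 kcal/mol, right at the symmetric well depth); the elbow
found `k = 2` clusters whose representatives are the lowest-energy member of
each; nearest-reference classification recovered the generating 30/70
open/closed mixture (31.5 %/68.5 %); PC1 of the kept ensemble carries 99.9 %
of the variance — the single open↔closed morph mode by construction — and
its score distribution overlaps the pseudo-MD reference at 0.43; the decoy
set spans a diameter of 24.3 Å backbone RMSD.

The same run is available from the shell:

```bash
conformens run --synthetic --seed 1 --out demo_out
```

and each stage separately via `conformens synth | triage | cluster |
motions | descriptors` (see `--help`).

For real data, `conformens.datasets.conformer_pair_deviation("2EB8",
"2JHO", RegionSpec("alpha6", "A", 82, 98))` fetches the apo/holo myoglobin
pair and measures how far the α6 helix moves between the two crystal forms
after global backbone superposition.

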