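# Methods

This note documents the models, numerical choices and limitations behind
`conformens`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Problem setting

Modern structure predictors emit large decoy sets for a single sequence.
For proteins with several functional conformations (hinge-bending enzymes,
apo/holo pairs, open/closed receptor domains) the interesting question is
which conformational states the decoys cover and in what proportions, and
whether their internal motions resemble those of a reference ensemble —
typically an MD trajectory started from an experimental structure. The
package implements the post-prediction half of that workflow: energies are
**ingested**, never computed (force-field rescoring is an external step),
and model building itself is out of scope.

## Pipeline stages

### Energy triage

The filter threshold is the arithmetic mean energy of exactly the models
the caller lists; models strictly above it are removed and ties are kept.
Two deliberate consequences:

- For any energy distribution symmetric about its mean, about half the
  models survive; the filter is a coarse halving, not an outlier test.
- Re-applying the filter to the kept subset recomputes a lower mean and
  removes more models. The filter is therefore applied **once** per decoy
  set; iterated refiltering is not offered.

The Pearson energy-vs-RMSD correlation (to a chosen reference) is provided
as the standard diagnostic of whether the energy function ranks
near-reference decoys lower; it is reported, never asserted.

### Superposition and RMSD

All RMSDs are minimised over proper rigid motions (Kabsch via SVD, det +1
enforced so chirality is preserved; `scipy`'s `Rotation.align_vectors`
supplies the solver). Superposition is unweighted by default — no mass
weighting anywhere; a weights argument exists for extension. Pairwise
matrices are computed by a vectorised batch of 3×3 cross-covariance SVDs,
algebraically identical to per-pair fits (the test suite checks this
against per-pair calls, and the closed form against a Nelder-Mead
minimiser over rotation vector + translation to 1e−6 Å).

RMSD between independently superposed pairs is not guaranteed to be a
Euclidean metric; nothing downstream assumes the triangle inequality, and
Ward-style linkages that embed the matrix are deliberately not offered as
defaults.

### Ensemble alignment and RMSF

`align_to_mean` iterates "superpose all models onto the current mean,
recompute the mean" starting from the first model, stopping when the mean
moves less than `tol` (plain RMSD between successive means; default
1e−6 Å, `max_iter` 10). Non-convergence warns rather than fails — the
quantity degrades gracefully.

RMSF is computed per residue from the Cα atom by default (backbone-centroid
variant available), as the root mean squared displacement from the
ensemble-mean position, and reported in **nm** (coordinates stay in Å
internally; the nm convention matches how fluctuation profiles are usually
plotted). Closed forms used as oracles: two frames at ±d give exactly d;
isotropic per-axis jitter σ gives σ√3.

### Clustering and the elbow

Agglomerative clustering runs on the precomputed RMSD matrix
(`scipy.cluster.hierarchy`; average linkage by default, complete/single
configurable). Cluster labels are renumbered 1..k by decreasing size with
ties broken by the smallest member index, so partitions are stable under
input permutation up to that documented renumbering.

"Choose k by the elbow" is made deterministic as follows. The dispersion

    W(k) = (1/n) · Σ_clusters (1/n_c) · Σ_{i,j ∈ c} d_ij²

is the size-weighted mean within-cluster squared RMSD; on squared
distances this is the direct analogue of the k-means within-cluster sum of
squares, which is why it is non-increasing along nested cuts of one tree
(verified on fuzzed ensembles for all three linkages). The selected k
maximises the discrete curvature `W(k−1) − 2W(k) + W(k+1)` over
2..k_max−1, smallest k on ties. A **flatness floor** (default 0.25 Å² at
k = 1) short-circuits to k = 1 for ensembles that are already homogeneous,
where curvature would otherwise amplify noise.

Known property of the curvature criterion: when separations are strongly
unequal (e.g. three states at λ = 0, ½, 1, where adjacent states are half
as far apart as the extremes), the largest curvature sits at the first
split and k = 2 is returned. The three-state recovery guarantee therefore
holds for *equidistant* well-separated states, and that is what the tests
construct (blob centres on a regular simplex in conformation space).

Each cluster's representative is its lowest-energy member (smallest input
index on exact ties) — a physically-scored exemplar, not a mean structure.

### Collective motions and overlap

Cartesian PCA is the eigendecomposition of the covariance of flattened,
aligned coordinates (Cα selection by default; `sklearn.decomposition.PCA`
backs the computation, variances with ddof = 1). Components follow a fixed
sign convention — the largest-magnitude entry of each component is made
positive — so projections are reproducible across runs. Projection of any
ensemble (including an external one) superposes each conformation onto the
PCA mean first; cross-ensemble comparison requires a common frame and this
is the convention chosen here.

Agreement between two score distributions is the overlap coefficient of
their Gaussian KDEs (Silverman bandwidth as implemented in
`scipy.stats.gaussian_kde`): the integral of the pointwise minimum on a
512-point grid spanning `min − 3h` to `max + 3h`. Doubling the grid changes
the value by < 1e−3 (tested). Each KDE is normalised, so unequal sample
counts are left uncorrected by design. A zero-variance series has no KDE
and falls back to a point-mass reading: the other density's mass within a
±1e−6 tolerance window (1/0 when both are degenerate).

The pipeline fits PCA per cluster *and* on the whole kept ensemble. Under
two-state conditions the whole-ensemble PC1 is the open↔closed mode and is
the axis on which decoys and the reference ensemble are compared; a
single cluster's PC1 reflects only within-state motion and can be
noise-dominated — both are reported, neither is asserted. The fraction of
variance PC1 captures is a property of the data, not an invariant
(real-ensemble values around 80 % are typical but not guaranteed).

### Descriptors, classification, spread

The aperture angle is measured at the hinge region's centre of geometry
(unweighted Cα centroid; the simplest construction consistent with
region-level descriptors — regions are user-specified, never auto-detected)
between the two arm centres, as `arccos` of the clamped normalised dot
product; the inter-domain distance is the Euclidean distance between the
arm centres. Both are rigid-motion invariant.

Classification assigns each model the label of its nearest reference by
minimised RMSD, suffixed `-like`; with a positive `intermediate_margin`,
models whose two best references differ by less than the margin become
`intermediate-like`. The default margin is 0, reproducing binary
open/closed fractions; exact ties go to the first listed reference.

ΔRMSD, the ensemble spread, is formalised as the **diameter**: the maximum
entry of the pairwise RMSD matrix (0 for a single model). An alternative
reading — the range of RMSDs to a fixed reference — is available behind
`method="range_to_reference"`.

## The synthetic generator

The generator is the package's ground-truthed test article, not a physical
model. A Cα-only chain (3.8 Å spacing) has two straight `arm_len`-residue
arms joined at a short hinge; the arms subtend `theta_open` (default 120°)
or `theta_closed` (60°) at the hinge, whose residues straddle the origin so
the hinge centre of geometry is exactly the hinge vertex. Every
conformation is the linear Cartesian morph `x(λ) = (1−λ)x_open + λx_closed`
— deliberately *not* an internal-coordinate interpolation, so the system
has exactly one collective degree of freedom and PCA/descriptor tests have
an exact target; mid-morph bond-length distortion is accepted for a
geometric test article.

Decoys: state ~ mixture (default 30 % open / 70 % closed), λ ~ N(state,
`state_sd` = 0.02), isotropic coordinate noise 0.2 Å per axis — noise three
orders of magnitude below the ~24 Å endpoint separation, so state
membership is unambiguous. Energies emulate a rescoring step:
`E(λ) = −E₀ + 16hλ²(1−λ)² + cλ + ε` with E₀ = 700, h = 60, c = 0,
σ_ε = 10 kcal/mol — minima of −E₀ at both wells, barrier +h at λ = ½,
symmetric by default so filtering is state-independent, and scaled so
thresholds land in the hundreds of kcal/mol as real coarse-grained
rescoring does. The pseudo-MD trajectory is the discrete mean-reverting
walk `λ_{t+1} = λ_t + κ(μ−λ_t)dt + σ√dt·ξ_t` reflected into [−0.2, 1.2]
(slight over-opening beyond the crystallographic endpoints is allowed on
purpose), with stationary variance `σ²dt / (2κdt − κ²dt²)` used as the
closed-form check. All generators are pure functions of (spec, seed).

One subtlety the tests respect: with unbounded Normal λ draws, conformers
*beyond* the wells are penalised even more steeply by the quartic than
barrier conformers are (at equal distance from a well, `16hλ²(1−λ)²` is
larger outward than inward). The "filter discards the barrier region"
property is therefore assessed among conformers between the wells
(λ ∈ [0, 1]), where the notion is defined; over-extended outliers are
removed too, for the different reason of quartic growth.

What the generator does **not** emulate: real decoy sets have correlated,
anisotropic errors, many soft degrees of freedom, and energies that are
imperfectly coupled to conformation; chains have side chains and full
backbones. Passing tests show the machinery is correct on a system with
known truth — they do not certify recovery rates on real decoy sets.

## Statistical test design

Sample sizes in the suite are chosen so that tolerances sit far from the
sampling noise: population-recovery checks compare the **mean** recovered
fraction over a fixed 10-seed set against the generating weight
(a single n = 1000 draw has binomial σ ≈ 0.0145, so a ±0.03 per-seed bound
would fail on noise alone ~once per three runs of a perfect classifier;
the 10-seed mean has σ ≈ 0.005). k-recovery and partition recovery are
per-seed and exact (20/20 seeds, adjusted Rand index 1.0). The OU
stationary-variance check burns in 1000 steps and uses 10⁵ steps with a
10 % tolerance (autocorrelation-adjusted effective sample ≈ 5·10³). The
pipeline's own study size — 1000 decoys, ~500 surviving the filter — runs
the full analysis in seconds and is the size used by the acceptance
script.

## Real-data mode and limitations

`conformens.datasets` fetches PDB entries by accession and measures how far
a named region moves between two conformers of the same protein: global
backbone superposition on shared `(residue, atom)` keys, then RMSD over the
region *without refitting*. This isolates regional motion but is sensitive
to the exact region bounds and matching policy (chains can be matched by
id or by residue number only); deviations of a few Å for a mobile helix
between apo and holo forms are the expected scale. Fetching requires
network access; no experimental coordinates ship with the package.

Other limitations, by design: no mmCIF or binary trajectory formats; no
insertion codes (rejected with a clear error, keeping residue keys
integer-valued); altlocs resolved to the highest-occupancy conformer
(blank preferred on ties) at parse time; no sequence alignment — ensembles
must be topology-consistent, and mismatches are an error naming the
offending models; no side-chain analysis; regions are user-specified. The
backbone definition includes the carbonyl O and is configurable to
exclude it; whether published "backbone RMSD" values include O is often
unstated, so both conventions are supported (default: include).
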