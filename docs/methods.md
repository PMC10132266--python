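# Methods

## Data model and preprocessing

The unit of analysis is a subjects × features matrix assembled from
several modalities (proteins, lipids, acylcarnitines, echocardiographic
imaging variables, clinical biomarkers), each possibly measured on its own
scale and with its own missingness. Preprocessing proceeds per feature:

- **Unit harmonization** is purely multiplicative (e.g. natriuretic
  peptides assayed in pmol/L converted to pg/ml); factors are supplied in
  a conversion table and are exactly invertible.
- **Completeness filter**: features observed in fewer than a configurable
  fraction of subjects (default 0.70, boundary inclusive) are dropped.
- **Log transform**: molecular modalities (protein, lipid, acylcarnitine)
  are log2-transformed with an optional pseudo-offset (default 0).
  Imaging and clinical variables are left on their native scale by
  default — they include ratios and velocities that can be negative — but
  the set of transformed modalities is configurable.
- **Outlier filter**: observed entries beyond median ± k·MAD
  (MAD × 1.4826, k default 5) are set to missing, per feature; a feature
  with zero MAD is skipped with a warning. Filtering individual entries
  rather than dropping subjects preserves the rest of a subject's profile.
- **Pareto scaling**: x′ = (x − x̄)/√s with the sample standard deviation
  (n−1) computed over observed entries. Dividing by √s rather than s is
  the metabolomics convention: it damps high-variance features without
  flattening them to unit variance. Note the standardized features then
  have variance s, not 1, which is intentional.
- A **simple imputation** utility (feature median, or mean of k nearest
  subjects by Euclidean distance on shared observed features) is provided
  as plumbing for complete-data consumers. It is not a substitute for
  principled multiple imputation and no downstream stage requires it:
  the network and signature stages consume missing data directly.

## Network inference

The background network is a Gaussian graphical model: features are
modelled as jointly Gaussian and a zero entry in the precision matrix Ω
means conditional independence given all other features.

- **Covariance**: S is computed over all pairwise-complete observations,
  with means recomputed on each pair's joint subset (n−1 denominator).
  Pairs with fewer than 3 joint observations are zeroed with a warning.
  Such a matrix need not be positive semidefinite; eigenvalues are clipped
  at 1e-6 and the matrix reconstructed before optimization
  (`psd_repaired` records whether clipping occurred).
- **Estimator**: graphical LASSO with the *diagonal unpenalized*, so an
  identity covariance maps to an identity precision. λ = 0 returns the
  direct inverse (the unpenalized MLE). For λ > 0 the solver is block
  coordinate descent over columns of W = Ω⁻¹ with a coordinate-descent
  lasso inner solver (numba-compiled), convergence declared when the mean
  absolute change of off-diagonal W entries falls below 1e-5 (inner
  tolerance 100× tighter), at most 200 sweeps. Non-convergence raises an
  error reporting the duality gap. Every solution carries a checkable KKT
  certificate: |[Ω⁻¹ − S]_ab| ≤ λ off-diagonal, with equality
  λ·sign(Ω_ab) on active entries.
- **Model selection**: 30 log-spaced λ values from
  λ_max = max|S_offdiag| down to 0.01·λ_max, swept in decreasing order
  with warm starts; the extended BIC
  n·(tr(SΩ) − log det Ω) + E·log n + 4·E·γ·log p (γ default 0.5) selects
  λ*, ties broken toward the larger λ. γ = 0 recovers ordinary BIC;
  γ = 0.5 is the usual compromise for p of the same order as n.
- **Edges**: r_ab = −ω_ab/√(ω_aa·ω_bb); exports include an edge TSV, a
  Cytoscape SIF file, and JSON metadata with the full eBIC path.

## Co-expression scores and signature search

Each edge (a, b) with a < b in feature order yields per-subject scores
(z_a + z_b)/√2 for positive partial correlation and (z_a − z_b)/√2 for
negative. The 1/√2 normalization makes independent unit-variance nodes
produce unit-variance scores; the recorded orientation (lower-index node
first) makes negative-edge scores reproducible. A score is missing iff
either node value is missing; edges observed in fewer than 50% of
subjects are excluded from the signature search.

The signature is a nearest-shrunken-centroid classifier on edge scores:

- d_ik = (x̄_ik − x̄_i)/(m_k·(s_i + s0)) with m_k = √(1/n_k − 1/n),
  pooled within-class sd s_i (observed-count minus class-count
  denominator under missingness), and offset s0 = median of s_i.
- Soft threshold d′_ik = sign(d_ik)·max(|d_ik| − Δ, 0); shrunken
  centroids x̄′_ik = x̄_i + m_k·(s_i + s0)·d′_ik. An edge is in the
  signature iff some class keeps a nonzero d′.
- **Δ selection**: 30 equally spaced Δ from 0 to max|d_ik|; stratified,
  seeded 10-fold CV refits all statistics per training fold and classifies
  held-out subjects by the discriminant rule below. Class priors are
  empirical by default (equal priors by flag).

**Sparsity-favoring selection.** Two safeguards sit on top of the raw CV
curve. First a *no-information gate*: the signature is reported non-empty
only when the best CV error beats the largest-prior error rate
1 − max_k π_k by a one-sided binomial margin at level 0.05, Bonferroni
corrected for the grid size. The pointwise minimum of a ~flat error curve
over 30 grid points is optimistically biased by roughly 2–3 standard
errors, so without the gate a label-independent dataset would almost
always receive a spurious small signature; with it, permuted or
signal-free data shrink to the empty classifier. Second, among
admissible Δ the *one-standard-error rule* picks the largest Δ whose
error is within one SE (over folds) of the minimum — the sparsest
classifier compatible with the data. Setting `se_factor=0` and
`noninfo_alpha=1` recovers the plain argmin with ties toward larger Δ.

## Prediction on external cohorts

A new cohort is standardized **within itself** (its own means and √sd);
training-cohort scale parameters are never applied to external data, so
the two cohorts may differ in units or calibration as long as each is
internally consistent. Constant features in the new data are set missing
with a warning rather than failing.

Per subject, δ_k = Σ_i (x*_i − x̄′_ik)²/(s_i + s0)² − 2·log π_k over the
signature edges with both nodes observed. Because each class's sum runs
over the same available edge set, the class comparison needs no
rescaling; a consequence is that δ magnitudes are not comparable between
subjects with different edge availability, only the resulting
probabilities are. p_k = exp(−δ_k/2)/Σ_l exp(−δ_l/2) with
max-subtraction. Subjects with no computable edge receive the priors and
a flag; subjects with under half the signature available are flagged but
scored. Risk strata are quantile cuts of the outcome-class probability
(tertiles by default, boundary ties to the lower stratum). AUCs use the
rank (Mann–Whitney) formulation with ties counted ½ and a seeded
class-stratified percentile bootstrap (2000 replicates) for 95% CIs.

## Synthetic data generator

The generator provides the ground-truthed surface all tests run on. It
emulates: a known sparse precision matrix (tridiagonal bands with seeded
± entries of fixed magnitude, or random sparse support with diagonal
inflation to a 0.1 eigenvalue floor); zero-mean Gaussian sampling from
its inverse; a two-class mean shift placed on designated network edges
(±effect/√2 on the two nodes, oriented by the edge's partial-correlation
sign, so the edge co-expression centroid moves by ≈ the stated effect on
the edge-score scale); modality block labels, with molecular blocks
exponentiated (2^z) so the log2 preprocessing path is exercised; and
MCAR missingness.

Default study conditions, fixed once: 150 subjects per class, 50
features (30 protein, 10 lipid, 6 imaging, 4 clinical), band strength
0.4 (partial correlations ≈ ∓0.4), 10 signal edges on disjoint nodes,
effect 1.0, 5% missingness. The larger signature study used by the
acceptance script runs a 501-feature band (500 edges) with 20 signal
edges at n = 300. These sizes keep the full pipeline in seconds while
leaving the estimation problems non-trivial.

What the generator does **not** emulate — and hence what passing tests
do not show about real cohorts: missingness is MCAR only (no
MAR/informative patterns), marginals are exactly Gaussian after the log
inverse (no heavy tails, batch effects or assay floors), class effects
live purely in edge-level mean shifts (no variance or correlation
differences between groups), and there is no confounding by covariates
such as age, sex or medication. Event times, censoring and survival
modelling are out of scope throughout.

## Numerical choices and degenerate inputs

- Structural zeros in Ω are entries below 1e-10; the inner lasso produces
  exact zeros, and an entry is zeroed only when both column solutions
  agree.
- Pairwise covariance requires ≥ 3 observations per feature (error) and
  per pair (warning + 0).
- Constant features: error in training pareto scaling, warning +
  all-missing in new-cohort standardization.
- Empty signature: a structured warning, files with headers only, and
  prediction refuses to run on a 0-edge model.
- All stochastic components (fold assignment, bootstrap, generators) take
  explicit seeds; repeated calls are bit-identical.

## Known limitations

- The glasso solver targets the dense-matrix regime (hundreds of
  features); no sparse-matrix or screening-rule optimizations are
  implemented.
- eBIC with γ = 0.5 is conservative; on weak-signal data it can
  under-select edges, and the signature search can only recover what the
  network retains.
- The no-information gate is binomial-approximate; for very small
  cohorts (tens of subjects) its margin is coarse.
- Multiple imputation (MICE-style) and survival analysis are explicitly
  out of scope; the imputation utility is a convenience only.
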