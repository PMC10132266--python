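# netomicspass

Partial-correlation network inference and edge-level subnetwork signatures
for multi-modal clinical omics cohorts.

## The problem

Post-event patient cohorts are increasingly profiled on several data types
at once — plasma proteins, lipids and acylcarnitines, echocardiographic
imaging variables, clinical biomarkers. Single markers discriminate future
outcomes only modestly; the joint behaviour of *pairs* of features often
carries more information. `netomicspass` integrates such heterogeneous
feature tables into a single conditional-dependence network, then searches
the network's edges for a sparse, cross-validated signature that separates
outcome groups, and finally scores new patients — even when many features
are missing in the new cohort.

## The method

**1. Background network (Gaussian graphical model).** After per-modality
harmonization, log2 transformation of molecular features, mean centering
and pareto scaling (x′ = (x − x̄)/√s), a covariance matrix S is computed
over all pairwise-complete observations and repaired to positive
definiteness by eigenvalue clipping. The sparse precision matrix Ω is the
graphical-LASSO estimate

  Ω̂ = argmax  log det Ω − tr(SΩ) − λ·Σ_{a≠b} |Ω_ab|,

solved by block coordinate descent (diagonal unpenalized), with λ selected
along a warm-started path by the extended BIC,
n·(tr(SΩ) − log det Ω) + E·log n + 4·E·γ·log p. Each nonzero Ω_ab becomes
a network edge weighted by the partial correlation
r_ab = −ω_ab/√(ω_aa·ω_bb).

**2. Edge co-expression scores.** Every edge gives each subject a score:
(z_a + z_b)/√2 for a positively correlated pair, (z_a − z_b)/√2 for a
negatively correlated pair, so that concordant (or discordant) movement of
the two features is captured in one number.

**3. Subnetwork signature (nearest shrunken centroids).** Per edge i and
class k, the d-score d_ik = (x̄_ik − x̄_i)/(m_k·(s_i + s0)) contrasts the
class centroid of the edge scores with the overall centroid. Soft
thresholding |d| by Δ zeroes uninformative edges; Δ is chosen by
stratified 10-fold cross-validation with a no-information gate and the
one-standard-error rule, so that label-independent data yield an empty
signature.

**4. Prediction.** A new cohort is standardized within itself; per subject
the discriminant score δ_k = Σ_i (x*_i − x̄′_ik)²/(s_i + s0)² − 2·log π_k
is summed over the signature edges whose nodes are observed, and class
probabilities follow from p_k ∝ exp(−δ_k/2). Subjects missing all
signature nodes fall back to the class priors and are flagged. Risk strata
(tertiles by default) and rank-based AUCs with bootstrap CIs complete the
evaluation.

## Worked example

```python
import netomicspass as nop
from netomicspass.simulate import SimConfig, generate

# ground-truthed two-class cohort: 300 subjects, 50 features across four
# modalities, banded precision, 10 discriminative edges
ds = generate(SimConfig(seed=1))
table = nop.pareto_scale(nop.log_transform(ds.table))

net = nop.infer_network(table, gamma=0.5)
model = nop.fit_signature(table, net, ds.labels, n_folds=10, seed=1)

# validation cohort from the same population, fresh subjects
dsv = generate(SimConfig(seed=7), precision=ds.true_precision,
               signal_edges=ds.signal_edges)
val = nop.standardize_new(nop.log_transform(dsv.table))
res = nop.predict(model, val)
auc, lo, hi = nop.auc(res.probabilities["event"], dsv.labels,
                      positive="event", seed=0)
```

This prints (seed 1):

```
network: 76 edges at lambda*=0.195 (density 6.2%)
signature: 23 edges at delta*=2.43, min CV error 22.3%
validation AUC 0.893 (95% CI 0.855-0.927)
signal-edge recovery: 8/10
```

The inferred network holds 76 of the 1,225 possible feature pairs; the
cross-validated shrinkage keeps 23 edges, 8 of the 10 truly discriminative
edges among them, and the signature transfers to an independent cohort
with an AUC near 0.9.

The same pipeline is available from the shell:

```sh
netomicspass simulate --out sim/
netomicspass preprocess --matrix sim/matrix.tsv --modality-map sim/modality_map.tsv --out table.tsv
netomicspass network --table table.tsv --modality-map sim/modality_map.tsv --out net/
netomicspass signature --table table.tsv --modality-map sim/modality_map.tsv \
    --network net/edges.tsv --labels sim/labels.tsv --out sig/
netomicspass predict --model sig/model.json --table sim/matrix.tsv \
    --modality-map sim/modality_map.tsv --out pred.tsv
netomicspass evaluate --pred pred.tsv --labels sim/labels.tsv --out metrics.json
```

Network and signature exports include Cytoscape-ready files (`.sif`, edge
attributes keyed by d-score sign → colour and |d| → width).

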