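"""Applying a fitted subnetwork signature to a new cohort.

The prediction rule tolerates missing features: the new cohort is
standardized within itself, co-expression scores are computed for whatever
signature edges have both nodes observed, and each subject's discriminant
score per class sums over that subject's available edges only —

    δ_k = Σ_i (x*_i − x̄'_ik)² / (s_i + s0)²  −  2·log π_k,
    p_k = exp(−δ_k/2) / Σ_l exp(−δ_l/2).

Since every class sums over the same available edges, the class comparison
needs no rescaling.  A subject with no computable edge gets the prior
probabilities and a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core_data import FeatureTable, FeatureTableError
from .signature import SignatureModel, discriminant_scores

__all__ = [
    "PredictionResult",
    "standardize_new",
    "signature_scores",
    "predict",
    "stratify",
    "auc",
    "edge_auc_table",
]


@dataclass
class PredictionResult:
    """Per-subject discriminant scores, class probabilities and flags."""

    subject_ids: list
    classes: list
    delta: pd.DataFrame          # subjects × classes
    probabilities: pd.DataFrame  # subjects × classes
    predicted_class: pd.Series
    edges_used: pd.Series
    flags: pd.Series             # free-text warning per subject ("" if none)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(index=pd.Index(self.subject_ids, name="subject_id"))
        for c in self.classes:
            out[f"delta_{c}"] = self.delta[c]
        for c in self.classes:
            out[f"prob_{c}"] = self.probabilities[c]
        out["predicted_class"] = self.predicted_class
        out["edges_used"] = self.edges_used
        out["flag"] = self.flags
        return out


def standardize_new(table: FeatureTable) -> FeatureTable:
    """Pareto-scale a new cohort using its *own* means and sds.

    Training-cohort scale parameters are never applied to external data.
    Constant features cannot be scaled and are set entirely missing with a
    warning instead of failing.
    """
    if table.scale_state == "standardized":
        return table
    if len(table.subject_ids) < 2:
        raise FeatureTableError("standardizing a cohort requires >= 2 subjects")
    out = table.copy()
    vals = out.values
    sd = vals.std(axis=0, ddof=1)
    n_obs = vals.notna().sum(axis=0)
    const = list(sd.index[(sd == 0) | (n_obs < 2)])
    if const:
        warnings.warn(f"constant/degenerate features set to missing: {const}")
    scaled = (vals - vals.mean(axis=0)) / np.sqrt(sd.where(sd > 0))
    scaled[const] = np.nan
    out.values = scaled
    out.scale_state = "standardized"
    return out


def signature_scores(model: SignatureModel, table: FeatureTable) -> pd.DataFrame:
    """Co-expression scores of the signature edges on a standardized table.

    Edges whose nodes are absent from the table yield all-missing columns.
    """
    vals = table.values
    n = len(table.subject_ids)
    cols = {}
    for a, b, sign in model.edges:
        label = f"{a}|{b}"
        if a in vals.columns and b in vals.columns:
            cols[label] = (vals[a] + sign * vals[b]) / np.sqrt(2.0)
        else:
            cols[label] = pd.Series(np.nan, index=vals.index)
    if not cols:
        return pd.DataFrame(index=vals.index)
    return pd.DataFrame(cols, index=vals.index)


def predict(model: SignatureModel, table: FeatureTable) -> PredictionResult:
    """Classify a standardized cohort with a fitted signature."""
    if table.scale_state != "standardized":
        raise ValueError("predict expects a standardized table (see standardize_new)")
    if model.n_edges == 0:
        raise ValueError("signature model has no edges")
    scores = signature_scores(model, table)
    X = scores.to_numpy()
    observed = (~np.isnan(X)).sum(axis=1)
    if observed.sum() == 0:
        raise ValueError("no signature edge is computable for any subject")
    scale = model.pooled_sd + model.s0
    delta = discriminant_scores(X, model.shrunken_centroids, scale, model.priors)
    # numerically stable softmax of -delta/2
    z = -delta / 2.0
    z -= z.max(axis=1, keepdims=True)
    probs = np.exp(z)
    probs /= probs.sum(axis=1, keepdims=True)

    flags = []
    for i, nobs in enumerate(observed):
        if nobs == 0:
            # fallback: probabilities equal the priors
            probs[i] = model.priors
            delta[i] = -2.0 * np.log(model.priors)
            flags.append("no signature edges observed; prior fallback")
        elif nobs < 0.5 * model.n_edges:
            flags.append(f"only {nobs}/{model.n_edges} signature edges observed")
        else:
            flags.append("")
    pred = np.asarray(model.classes, object)[np.argmin(delta, axis=1)]
    idx = scores.index
    return PredictionResult(
        subject_ids=list(idx),
        classes=list(model.classes),
        delta=pd.DataFrame(delta, index=idx, columns=model.classes),
        probabilities=pd.DataFrame(probs, index=idx, columns=model.classes),
        predicted_class=pd.Series(pred, index=idx),
        edges_used=pd.Series(observed, index=idx),
        flags=pd.Series(flags, index=idx),
    )


def stratify(probabilities: pd.Series, n_groups: int = 3):
    """Quantile-based risk strata (tertiles by default) on outcome probability.

    Returns (assignment Series with groups 1..n_groups, inner boundaries).
    Ties on a boundary go to the lower stratum; fully degenerate (all-equal)
    probabilities give one stratum with a warning.
    """
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    if len(probabilities) < n_groups:
        raise ValueError(
            f"cannot form {n_groups} strata from {len(probabilities)} subjects"
        )
    p = probabilities.to_numpy(float)
    if n_groups == 1:
        return pd.Series(1, index=probabilities.index), []
    bounds = [float(np.quantile(p, q / n_groups)) for q in range(1, n_groups)]
    if p.min() == p.max():
        warnings.warn("all probabilities identical; single stratum")
        return pd.Series(1, index=probabilities.index), bounds
    groups = 1 + np.array([sum(x > b for b in bounds) for x in p])
    return pd.Series(groups, index=probabilities.index), bounds


def auc(
    scores,
    labels,
    positive=None,
    n_boot: int = 2000,
    seed: int = 0,
    ci: float = 0.95,
):
    """ROC AUC by the rank (Mann–Whitney) formulation, ties counted ½.

    The confidence interval is a seeded class-stratified bootstrap
    (percentile method).  Returns (auc, ci_low, ci_high).
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"AUC needs exactly two classes, got {list(uniq)}")
    if positive is None:
        positive = uniq[0]
    pos = labels == positive
    s_pos, s_neg = scores[pos], scores[~pos]

    def _auc(sp, sn):
        r = rankdata(np.concatenate([sp, sn]))
        return (r[: len(sp)].sum() - len(sp) * (len(sp) + 1) / 2) / (len(sp) * len(sn))

    point = float(_auc(s_pos, s_neg))
    if n_boot <= 0:
        return point, np.nan, np.nan
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        reps[b] = _auc(
            rng.choice(s_pos, len(s_pos), replace=True),
            rng.choice(s_neg, len(s_neg), replace=True),
        )
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(reps, [alpha, 1.0 - alpha])
    return point, float(lo), float(hi)


def edge_auc_table(
    model: SignatureModel,
    scores: pd.DataFrame,
    labels: pd.Series,
    positive=None,
    n_boot: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-edge discrimination of the signature's co-expression scores.

    One row per signature edge with the score AUC (and bootstrap CI) and the
    per-class d-scores, sorted by AUC descending; edges with no usable
    scores get a missing AUC and a warning.
    """
    labels = labels.reindex(scores.index)
    uniq = list(pd.unique(labels.dropna()))
    if len(uniq) != 2:
        raise ValueError("edge-level AUC requires binary labels")
    rows = []
    for i, (a, b, sign) in enumerate(model.edges):
        label = f"{a}|{b}"
        col = scores[label] if label in scores.columns else pd.Series(dtype=float)
        mask = col.notna() & labels.notna()
        row = {"node_a": a, "node_b": b, "sign": sign}
        for k, c in enumerate(model.classes):
            row[f"d_{c}"] = model.d_scores[i, k]
        sub_labels = labels[mask]
        if mask.sum() >= 2 and sub_labels.nunique() == 2:
            a_hat, lo, hi = auc(
                col[mask], sub_labels, positive=positive, n_boot=n_boot, seed=seed
            )
            row.update({"auc": a_hat, "ci_low": lo, "ci_high": hi})
        else:
            warnings.warn(f"edge {label} has no usable scores for AUC")
            row.update({"auc": np.nan, "ci_low": np.nan, "ci_high": np.nan})
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values("auc", ascending=False, na_position="last").reset_index(drop=True)
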