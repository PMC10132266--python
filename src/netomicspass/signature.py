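"""Edge-level subnetwork signatures discriminating outcome groups.

Each network edge with a nonzero partial correlation yields a per-subject
*co-expression score*: the sum of the two standardized node values for a
positively correlated pair, their difference for a negatively correlated
pair (both divided by √2 so independent unit-variance nodes give a
unit-variance score).  On these edge scores a nearest-shrunken-centroid
search is run: per class k and edge i a d-score

    d_ik = (x̄_ik − x̄_i) / (m_k · (s_i + s0)),   m_k = sqrt(1/n_k − 1/n)

contrasts the class centroid with the overall centroid; soft-thresholding
|d| by Δ zeroes uninformative edges, and Δ is chosen by stratified 10-fold
cross-validation to minimize misclassification error (ties → largest Δ,
i.e. the sparsest classifier).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core_data import FeatureTable
from .ggm import PrecisionNetwork

__all__ = [
    "EdgeScoreMatrix",
    "ClassStatistics",
    "SignatureModel",
    "coexpression_scores",
    "class_statistics",
    "soft_threshold",
    "shrunken_centroids",
    "discriminant_scores",
    "stratified_folds",
    "cross_validate",
    "fit_signature",
    "export_signature",
    "load_signature",
]


@dataclass
class EdgeScoreMatrix:
    """Per-subject, per-edge co-expression scores.

    ``edges`` is an ordered list of (node_a, node_b, sign) with a before b
    in the source table's canonical feature order; ``scores`` is subjects ×
    edges with NaN wherever either node value is missing.
    """

    edges: list  # of (node_a, node_b, sign)
    scores: pd.DataFrame  # columns "a|b"
    network_id: str = ""

    @property
    def subject_ids(self) -> list:
        return list(self.scores.index)

    @property
    def edge_labels(self) -> list:
        return list(self.scores.columns)


@dataclass
class ClassStatistics:
    """Shrunken-centroid building blocks on an edge-score matrix."""

    classes: list
    priors: np.ndarray          # π_k = n_k / n
    n_k: np.ndarray
    overall_centroid: np.ndarray  # x̄_i, per edge
    class_centroids: np.ndarray   # x̄_ik, edges × classes
    pooled_sd: np.ndarray         # s_i
    s0: float
    m_k: np.ndarray
    d_scores: np.ndarray          # d_ik, edges × classes


@dataclass
class SignatureModel:
    """A fitted sparse subnetwork classifier."""

    classes: list
    priors: np.ndarray
    edges: list                   # selected (node_a, node_b, sign)
    overall_centroid: np.ndarray  # per selected edge
    class_centroids: np.ndarray
    shrunken_centroids: np.ndarray
    pooled_sd: np.ndarray
    s0: float
    d_scores: np.ndarray
    shrunken_d: np.ndarray
    threshold: float
    cv_error_curve: list = field(default_factory=list)  # of (delta, error)
    n_folds: int = 10
    seed: int = 1

    @property
    def n_edges(self) -> int:
        return len(self.edges)


# ---------------------------------------------------------------------------
# co-expression scores

def coexpression_scores(
    table: FeatureTable, network: PrecisionNetwork
) -> EdgeScoreMatrix:
    """Standardized table + network → per-subject edge scores.

    Positive edge: (z_a + z_b)/√2; negative edge: (z_a − z_b)/√2 with a
    before b in the table's feature order.  The score is missing iff either
    node value is missing.  Edges whose nodes are absent from the table are
    dropped with a warning.
    """
    if table.scale_state != "standardized":
        raise ValueError("co-expression scores require standardized input")
    order = {f: i for i, f in enumerate(table.feature_ids)}
    vals = table.values
    cols = {}
    edges = []
    dropped = 0
    for a, b, r, *_ in network.edges:
        if a not in order or b not in order:
            dropped += 1
            continue
        if order[a] > order[b]:
            a, b = b, a
        sign = 1 if r > 0 else -1
        za, zb = vals[a], vals[b]
        score = (za + sign * zb) / np.sqrt(2.0)
        edges.append((a, b, sign))
        cols[f"{a}|{b}"] = score
    if dropped:
        warnings.warn(f"{dropped} network edges dropped: node(s) absent from table")
    scores = pd.DataFrame(cols, index=vals.index) if cols else pd.DataFrame(index=vals.index)
    return EdgeScoreMatrix(edges=edges, scores=scores, network_id=f"lambda={network.lambda_star}")


# ---------------------------------------------------------------------------
# shrunken-centroid statistics

def class_statistics(E: EdgeScoreMatrix, labels: pd.Series, classes=None) -> ClassStatistics:
    """Centroids, pooled scales and d-scores per edge and class.

    Statistics are computed over observed scores.  The pooled within-class
    variance uses the observed count minus the class count in the
    denominator, s0 is the median pooled sd over edges, and class sizes for
    m_k and the priors are nominal subject counts.
    """
    labels = labels.reindex(E.scores.index)
    if labels.isna().any():
        raise ValueError("labels missing for some subjects")
    if classes is None:
        classes = list(dict.fromkeys(labels))
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    n = len(labels)
    n_k = np.array([(labels == c).sum() for c in classes], float)
    small = [c for c, nk in zip(classes, n_k) if nk < 2]
    if small:
        raise ValueError(f"classes with < 2 subjects: {small}")

    X = E.scores.to_numpy()
    obs = ~np.isnan(X)
    n_edges = X.shape[1]
    K = len(classes)
    class_cent = np.full((n_edges, K), np.nan)
    ss = np.zeros(n_edges)
    n_obs_total = obs.sum(axis=0).astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        overall = np.nanmean(X, axis=0)
        for k, c in enumerate(classes):
            rows = (labels == c).to_numpy()
            class_cent[:, k] = np.nanmean(X[rows], axis=0)
            dev = X[rows] - class_cent[:, k]
            ss += np.nansum(dev ** 2, axis=0)
    denom = np.maximum(n_obs_total - K, 1.0)
    pooled_sd = np.sqrt(ss / denom)
    s0 = float(np.median(pooled_sd)) if n_edges else 0.0
    m_k = np.sqrt(1.0 / n_k - 1.0 / n)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = (class_cent - overall[:, None]) / (m_k[None, :] * (pooled_sd + s0)[:, None])
    d = np.nan_to_num(d)
    return ClassStatistics(
        classes=list(classes),
        priors=n_k / n,
        n_k=n_k,
        overall_centroid=np.nan_to_num(overall),
        class_centroids=np.nan_to_num(class_cent),
        pooled_sd=pooled_sd,
        s0=s0,
        m_k=m_k,
        d_scores=d,
    )


def soft_threshold(d: np.ndarray, delta: float) -> np.ndarray:
    """Sign-preserving soft threshold: sign(d)·max(|d| − Δ, 0)."""
    if delta < 0:
        raise ValueError("delta must be >= 0")
    return np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)


def shrunken_centroids(stats: ClassStatistics, delta: float) -> tuple[np.ndarray, np.ndarray]:
    """Shrunken d-scores and the centroids x̄'_ik = x̄_i + m_k·(s_i+s0)·d'_ik."""
    d_shr = soft_threshold(stats.d_scores, delta)
    cent = (
        stats.overall_centroid[:, None]
        + stats.m_k[None, :] * (stats.pooled_sd + stats.s0)[:, None] * d_shr
    )
    return d_shr, cent


def discriminant_scores(
    X: np.ndarray,
    centroids: np.ndarray,
    scale: np.ndarray,
    priors: np.ndarray,
    active: np.ndarray | None = None,
) -> np.ndarray:
    """δ_k per subject: Σ_i (x_i − x̄'_ik)²/(s_i+s0)² − 2·log π_k.

    Missing scores are skipped; the same available-edge set enters every
    class's sum, so δ values remain comparable across classes.  ``active``
    restricts the sum to a subset of edges (the signature).
    """
    n, p = X.shape
    K = centroids.shape[1]
    if active is None:
        active = np.ones(p, bool)
    delta = np.tile(-2.0 * np.log(priors), (n, 1))
    if active.any():
        Xa = X[:, active]
        obs = ~np.isnan(Xa)
        Z = np.nan_to_num(Xa)
        for k in range(K):
            dev = (Z - centroids[active, k][None, :]) / scale[active][None, :]
            delta[:, k] += ((dev ** 2) * obs).sum(axis=1)
    return delta


def _classify(delta: np.ndarray, classes) -> np.ndarray:
    return np.asarray(classes, object)[np.argmin(delta, axis=1)]


# ---------------------------------------------------------------------------
# cross-validation

def stratified_folds(labels: pd.Series, n_folds: int, seed: int) -> np.ndarray:
    """Seeded stratified fold assignment (0..n_folds−1) per subject."""
    rng = np.random.default_rng(seed)
    fold = np.empty(len(labels), int)
    for c in labels.unique():
        idx = np.where((labels == c).to_numpy())[0]
        rng.shuffle(idx)
        fold[idx] = np.arange(len(idx)) % n_folds
    return fold


def cross_validate(
    E: EdgeScoreMatrix,
    labels: pd.Series,
    grid=None,
    n_folds: int = 10,
    seed: int = 1,
    classes=None,
    equal_priors: bool = False,
    se_factor: float = 1.0,
    noninfo_alpha: float = 0.05,
):
    """CV error curve over the Δ grid; returns (curve, delta_star).

    Folds are stratified and seeded; within each fold the class statistics
    are refit on the training subjects and held-out subjects are classified
    by the discriminant rule at every Δ.  A held-out subject with no
    observed edge falls back to the largest-prior class.

    Selection of Δ* favors sparsity twice over.  First a no-information
    gate: unless the best CV error beats the largest-prior error rate
    1 − max_k π_k by a one-sided binomial margin (level ``noninfo_alpha``,
    Bonferroni-corrected for the grid size — the minimum of a noisy curve
    is optimistically biased), the fully shrunken classifier wins and Δ* is
    the top of the grid.  Otherwise Δ* is the largest Δ whose error is
    within ``se_factor`` standard errors (over folds) of the minimum — the
    one-standard-error rule; ``se_factor=0`` gives the exact argmin with
    ties broken toward the largest Δ.  ``noninfo_alpha=1`` disables the
    gate.
    """
    labels = labels.reindex(E.scores.index)
    if classes is None:
        classes = list(dict.fromkeys(labels))
    if len(classes) < 2:
        raise ValueError("need at least two classes for cross-validation")
    min_class = min((labels == c).sum() for c in classes)
    if min_class < n_folds:
        warnings.warn(
            f"smallest class has {min_class} subjects; reducing folds from {n_folds}"
        )
        n_folds = max(2, int(min_class))
    if grid is None:
        stats_all = class_statistics(E, labels, classes)
        grid = np.linspace(0.0, float(np.abs(stats_all.d_scores).max()), 30)
    grid = np.asarray(grid, float)

    fold = stratified_folds(labels, n_folds, seed)
    X = E.scores.to_numpy()
    y = labels.to_numpy()
    errors = np.zeros((n_folds, grid.size))
    counts = np.zeros(n_folds)
    for f in range(n_folds):
        test = fold == f
        train = ~test
        E_train = EdgeScoreMatrix(E.edges, E.scores.iloc[train])
        stats = class_statistics(E_train, labels.iloc[train], classes)
        priors = (
            np.full(len(classes), 1.0 / len(classes)) if equal_priors else stats.priors
        )
        scale = stats.pooled_sd + stats.s0
        counts[f] = test.sum()
        for g, dl in enumerate(grid):
            _, cent = shrunken_centroids(stats, dl)
            delta = discriminant_scores(X[test], cent, scale, priors)
            pred = _classify(delta, classes)
            errors[f, g] = (pred != y[test]).sum()
    n_total = counts.sum()
    curve = errors.sum(axis=0) / n_total
    fold_rates = errors / counts[:, None]
    best_err = curve.min()
    i_min = int(max(np.where(curve == best_err)[0], key=lambda i: grid[i]))

    n_k = np.array([(labels == c).sum() for c in classes], float)
    p0 = 1.0 - n_k.max() / n_k.sum()  # no-information error rate
    if noninfo_alpha < 1 and grid.size > 0:
        z = float(norm.ppf(1.0 - noninfo_alpha / grid.size))
        margin = z * np.sqrt(max(p0 * (1.0 - p0), 1e-12) / n_total)
        if best_err > p0 - margin:
            return (
                [(float(d), float(e)) for d, e in zip(grid, curve)],
                float(grid.max()),
            )
    se = float(fold_rates[:, i_min].std(ddof=1) / np.sqrt(n_folds))
    admissible = np.where(curve <= best_err + se_factor * se)[0]
    best = max(admissible, key=lambda i: grid[i])
    return [(float(d), float(e)) for d, e in zip(grid, curve)], float(grid[best])


# ---------------------------------------------------------------------------
# fitting / export

def fit_signature(
    table: FeatureTable,
    network: PrecisionNetwork,
    labels: pd.Series,
    n_folds: int = 10,
    seed: int = 1,
    grid=None,
    classes=None,
    equal_priors: bool = False,
    min_edge_obs: float = 0.5,
    se_factor: float = 1.0,
    noninfo_alpha: float = 0.05,
) -> SignatureModel:
    """End-to-end signature search: scores → d-scores → CV → soft threshold.

    Edges observed in fewer than ``min_edge_obs`` of subjects are excluded
    from the search.  The returned model keeps only the edges with a nonzero
    shrunken d-score in some class; an empty signature triggers a warning.
    """
    E = coexpression_scores(table, network)
    if E.scores.shape[1] == 0:
        raise ValueError("network contributes no scorable edges")
    obs_frac = E.scores.notna().mean(axis=0).to_numpy()
    usable = obs_frac >= min_edge_obs
    if not usable.all():
        warnings.warn(
            f"{int((~usable).sum())} edges observed in < {min_edge_obs:.0%} "
            "of subjects excluded from the signature search"
        )
        E = EdgeScoreMatrix(
            [e for e, u in zip(E.edges, usable) if u],
            E.scores.loc[:, usable],
            E.network_id,
        )
    labels = labels.reindex(E.scores.index)
    stats = class_statistics(E, labels, classes)
    if grid is None:
        grid = np.linspace(0.0, float(np.abs(stats.d_scores).max()), 30)
    curve, delta_star = cross_validate(
        E, labels, grid=grid, n_folds=n_folds, seed=seed,
        classes=stats.classes, equal_priors=equal_priors, se_factor=se_factor,
        noninfo_alpha=noninfo_alpha,
    )
    d_shr, cent = shrunken_centroids(stats, delta_star)
    keep = (d_shr != 0).any(axis=1)
    if not keep.any():
        warnings.warn("signature is empty at the selected threshold")
    priors = (
        np.full(len(stats.classes), 1.0 / len(stats.classes))
        if equal_priors else stats.priors
    )
    return SignatureModel(
        classes=stats.classes,
        priors=priors,
        edges=[e for e, k in zip(E.edges, keep) if k],
        overall_centroid=stats.overall_centroid[keep],
        class_centroids=stats.class_centroids[keep],
        shrunken_centroids=cent[keep],
        pooled_sd=stats.pooled_sd[keep],
        s0=stats.s0,
        d_scores=stats.d_scores[keep],
        shrunken_d=d_shr[keep],
        threshold=float(delta_star),
        cv_error_curve=curve,
        n_folds=n_folds,
        seed=seed,
    )


def export_signature(model: SignatureModel, path) -> dict:
    """Write signature TSV, Cytoscape edge-attribute TSV, and model JSON."""
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (a, b, sign) in enumerate(model.edges):
        row = {"node_a": a, "node_b": b, "sign": sign}
        for k, c in enumerate(model.classes):
            row[f"d_{c}"] = model.d_scores[i, k]
            row[f"shrunken_d_{c}"] = model.shrunken_d[i, k]
            row[f"centroid_{c}"] = model.shrunken_centroids[i, k]
        row["overall_centroid"] = model.overall_centroid[i]
        row["pooled_sd"] = model.pooled_sd[i]
        rows.append(row)
    cols = ["node_a", "node_b", "sign"]
    for c in model.classes:
        cols += [f"d_{c}", f"shrunken_d_{c}", f"centroid_{c}"]
    cols += ["overall_centroid", "pooled_sd"]
    sig_path = out / "signature.tsv"
    pd.DataFrame(rows, columns=cols).to_csv(sig_path, sep="\t", index=False)

    attr_path = out / "cytoscape_edges.tsv"
    k1 = 1 if len(model.classes) > 1 else 0
    attrs = []
    for i, (a, b, _s) in enumerate(model.edges):
        d = model.shrunken_d[i, k1]
        attrs.append(
            {
                "edge": f"{a} (pp) {b}",
                "color": "red" if d > 0 else "blue",
                "width": abs(float(d)),
            }
        )
    pd.DataFrame(attrs, columns=["edge", "color", "width"]).to_csv(
        attr_path, sep="\t", index=False
    )

    model_path = out / "model.json"
    payload = {
        "classes": model.classes,
        "priors": model.priors.tolist(),
        "edges": [list(e) for e in model.edges],
        "overall_centroid": model.overall_centroid.tolist(),
        "class_centroids": model.class_centroids.tolist(),
        "shrunken_centroids": model.shrunken_centroids.tolist(),
        "pooled_sd": model.pooled_sd.tolist(),
        "s0": model.s0,
        "d_scores": model.d_scores.tolist(),
        "shrunken_d": model.shrunken_d.tolist(),
        "threshold": model.threshold,
        "cv_error_curve": model.cv_error_curve,
        "n_folds": model.n_folds,
        "seed": model.seed,
    }
    model_path.write_text(json.dumps(payload, indent=2))
    return {"signature": sig_path, "attributes": attr_path, "model": model_path}


def load_signature(path) -> SignatureModel:
    """Reload a model serialized by :func:`export_signature`."""
    payload = json.loads(Path(path).read_text())
    return SignatureModel(
        classes=payload["classes"],
        priors=np.asarray(payload["priors"]),
        edges=[tuple(e) for e in payload["edges"]],
        overall_centroid=np.asarray(payload["overall_centroid"]),
        class_centroids=np.asarray(payload["class_centroids"]),
        shrunken_centroids=np.asarray(payload["shrunken_centroids"]),
        pooled_sd=np.asarray(payload["pooled_sd"]),
        s0=payload["s0"],
        d_scores=np.asarray(payload["d_scores"]),
        shrunken_d=np.asarray(payload["shrunken_d"]),
        threshold=payload["threshold"],
        cv_error_curve=[tuple(x) for x in payload["cv_error_curve"]],
        n_folds=payload["n_folds"],
        seed=payload["seed"],
    )
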