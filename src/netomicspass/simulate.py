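"""Ground-truthed synthetic multi-modal cohorts.

Emulates the structure the pipeline assumes — multivariate-Gaussian
features with a known sparse precision matrix, two outcome classes whose
mean difference lives on designated network edges, modality blocks
(molecular modalities exponentiated to a positive raw scale so the
log-transform path is exercised), and MCAR missingness.  Every generator is
deterministic under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import FeatureTable

__all__ = [
    "SimConfig",
    "SyntheticDataset",
    "make_precision",
    "sample_mvn",
    "inject_signal",
    "inject_missing",
    "choose_signal_edges",
    "generate",
]


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe a compact two-class cohort (150 subjects per class,
    50 features across four modalities, tridiagonal precision of strength
    0.4, 10 signal edges of effect 1.0 on the edge-score scale, 5% MCAR
    missingness) sized so the full pipeline including network inference
    runs in seconds.
    """

    n_per_class: int = 150
    modality_sizes: dict = field(
        default_factory=lambda: {"protein": 30, "lipid": 10, "imaging": 6, "clinical": 4}
    )
    structure: str = "banded"
    density: float = 0.04
    strength: float = 0.4
    n_signal_edges: int = 10
    effect: float = 1.0
    missing_rate: float = 0.05
    classes: tuple = ("event_free", "event")
    seed: int = 1

    @property
    def p(self) -> int:
        return sum(self.modality_sizes.values())


@dataclass
class SyntheticDataset:
    """A generated cohort plus its ground truth."""

    table: FeatureTable
    true_precision: np.ndarray
    true_edges: set        # of (i, j) index pairs, i < j
    signal_edges: list     # of (i, j, sign) — sign of the partial correlation
    labels: pd.Series
    effect_size: float
    missing_rate: float
    seed: int

    def edge_feature_pairs(self, edges=None) -> set:
        """Index pairs → feature-id pairs (for comparing against networks)."""
        feats = self.table.feature_ids
        if edges is None:
            edges = self.true_edges
        return {(feats[i], feats[j]) for i, j, *_ in (tuple(e) for e in edges)}


def make_precision(
    p: int,
    structure: str = "banded",
    density: float = 0.04,
    strength: float = 0.4,
    seed: int = 0,
    max_inflate: int = 50,
) -> np.ndarray:
    """Sparse symmetric positive-definite precision matrix.

    ``banded``: tridiagonal, unit diagonal, off-diagonal entries of
    magnitude ``strength`` with seeded random signs (a diagonal ±1
    similarity leaves the eigenvalues of the unsigned tridiagonal intact,
    so positive definiteness needs only strength < 1/(2·cos(π/(p+1)))).
    ``random_sparse``: symmetric support at the given density with ±strength
    entries and the diagonal inflated until the smallest eigenvalue is
    at least 0.1.
    """
    if p < 2:
        raise ValueError("p must be >= 2")
    rng = np.random.default_rng(seed)
    if structure == "banded":
        signs = rng.choice([-1.0, 1.0], size=p - 1)
        omega = np.eye(p)
        off = strength * signs
        omega[np.arange(p - 1), np.arange(1, p)] = off
        omega[np.arange(1, p), np.arange(p - 1)] = off
    elif structure == "random_sparse":
        if not 0 <= density <= 1:
            raise ValueError("density must be in [0, 1]")
        omega = np.eye(p)
        iu = np.triu_indices(p, 1)
        support = rng.random(iu[0].size) < density
        vals = strength * rng.choice([-1.0, 1.0], size=iu[0].size) * support
        omega[iu] = vals
        omega.T[iu] = vals
        for _ in range(max_inflate):
            w_min = np.linalg.eigvalsh(omega).min()
            if w_min >= 0.1:
                break
            omega[np.diag_indices(p)] += 0.1 - w_min
        else:
            raise ValueError("could not reach positive definiteness by inflation")
    else:
        raise ValueError(f"unknown structure {structure!r}")
    w_min = np.linalg.eigvalsh(omega).min()
    if w_min <= 0:
        raise ValueError(
            f"precision not positive definite (min eigenvalue {w_min:.3f}); "
            "reduce strength"
        )
    return omega


def precision_edges(omega: np.ndarray, tol: float = 1e-12) -> set:
    """Upper-triangle support of a precision matrix as (i, j) pairs."""
    iu = np.triu_indices(omega.shape[0], 1)
    return {(int(i), int(j)) for i, j in zip(*iu) if abs(omega[i, j]) > tol}


def sample_mvn(precision: np.ndarray, n: int, seed: int = 0) -> np.ndarray:
    """n iid draws from N(0, Σ) with Σ = precision⁻¹ (seeded)."""
    w = np.linalg.eigvalsh(precision)
    if w.min() <= 0:
        raise ValueError("precision must be positive definite")
    cov = np.linalg.inv(precision)
    cov = (cov + cov.T) / 2.0
    rng = np.random.default_rng(seed)
    return rng.multivariate_normal(np.zeros(precision.shape[0]), cov, size=n, method="cholesky")


def choose_signal_edges(omega: np.ndarray, n_signal: int, seed: int = 0) -> list:
    """Pick signal edges from the precision support, preferring disjoint nodes.

    Returns (i, j, sign) with sign the partial-correlation sign
    (−sign(ω_ij)), so the injected shift matches the co-expression scoring
    convention downstream.
    """
    edges = sorted(precision_edges(omega))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(edges))
    chosen: list = []
    used: set = set()
    for idx in order:
        i, j = edges[idx]
        if i in used or j in used:
            continue
        chosen.append((i, j))
        used |= {i, j}
        if len(chosen) == n_signal:
            break
    if len(chosen) < n_signal:  # not enough disjoint edges: allow sharing
        for idx in order:
            e = edges[idx]
            if e not in chosen:
                chosen.append(e)
            if len(chosen) == n_signal:
                break
    if len(chosen) < n_signal:
        raise ValueError(
            f"requested {n_signal} signal edges but the precision has only "
            f"{len(edges)} edges"
        )
    return [(i, j, int(np.sign(-omega[i, j]))) for i, j in chosen]


def inject_signal(
    data: np.ndarray,
    edges: list,
    effect: float,
    labels: np.ndarray,
    mode: str = "coexpression_shift",
) -> np.ndarray:
    """Shift class-1 node means so each signal edge's co-expression centroid
    moves by ≈ ``effect``.

    For a positive edge both nodes gain effect/√2; for a negative edge the
    lower-index node gains +effect/√2 and the other −effect/√2 (matching the
    z_a − z_b orientation of negative-edge scores).  Class 0 is untouched.
    """
    if mode != "coexpression_shift":
        raise ValueError(f"unknown mode {mode!r}")
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("labels must be binary")
    counts = [(labels == u).sum() for u in uniq]
    if counts[0] != counts[1]:
        warnings.warn("unbalanced classes; signal still injected on class 1")
    out = np.array(data, float, copy=True)
    case = labels == uniq[1]
    shift = effect / np.sqrt(2.0)
    for i, j, sign in edges:
        out[case, i] += shift
        out[case, j] += sign * shift
    return out


def inject_missing(data: np.ndarray, rate: float, seed: int = 0) -> np.ndarray:
    """Independent (MCAR) missingness at the given rate (seeded)."""
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    out = np.array(data, float, copy=True)
    if rate > 0:
        rng = np.random.default_rng(seed)
        out[rng.random(out.shape) < rate] = np.nan
    return out


def generate(
    config: SimConfig | None = None,
    precision: np.ndarray | None = None,
    signal_edges: list | None = None,
    **overrides,
) -> SyntheticDataset:
    """End-to-end synthetic cohort with ground truth.

    Feature blocks are labelled by modality in the order of
    ``modality_sizes``; molecular modalities (protein, lipid, acylcarnitine)
    are exponentiated (2^z) to a positive raw scale so the log2 path of the
    preprocessing pipeline inverts them exactly.

    Passing ``precision`` (and optionally ``signal_edges``) reuses an
    existing population structure — the way to draw a validation cohort from
    the same population as a training cohort.
    """
    if config is None:
        config = SimConfig(**overrides)
    elif overrides:
        raise ValueError("pass either a config or keyword overrides, not both")
    rng = np.random.default_rng(config.seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=4)

    p = config.p
    if precision is not None:
        omega = np.asarray(precision, float)
        if omega.shape != (p, p):
            raise ValueError("precision shape does not match modality sizes")
    else:
        omega = make_precision(
            p, config.structure, config.density, config.strength, seed=int(sub_seeds[0])
        )
    n = 2 * config.n_per_class
    z = sample_mvn(omega, n, seed=int(sub_seeds[1]))
    labels_arr = np.array(
        [config.classes[0]] * config.n_per_class + [config.classes[1]] * config.n_per_class,
        object,
    )
    if signal_edges is not None:
        signal = [tuple(e) for e in signal_edges]
    elif config.n_signal_edges > 0:
        signal = choose_signal_edges(omega, config.n_signal_edges, seed=int(sub_seeds[2]))
    else:
        signal = []
    z = inject_signal(z, signal, config.effect, labels_arr) if signal else z

    feature_ids, modalities = [], []
    for mod, size in config.modality_sizes.items():
        for i in range(size):
            feature_ids.append(f"{mod}_{i + 1}")
            modalities.append(mod)
    molecular = np.array([m in ("protein", "lipid", "acylcarnitine") for m in modalities])
    raw = z.copy()
    raw[:, molecular] = 2.0 ** raw[:, molecular]
    raw = inject_missing(raw, config.missing_rate, seed=int(sub_seeds[3]))

    subjects = [f"S{i + 1:04d}" for i in range(n)]
    table = FeatureTable(
        pd.DataFrame(raw, index=subjects, columns=feature_ids),
        pd.Series(modalities, index=feature_ids),
        scale_state="raw",
        provenance=f"synthetic seed={config.seed}",
    )
    return SyntheticDataset(
        table=table,
        true_precision=omega,
        true_edges=precision_edges(omega),
        signal_edges=signal,
        labels=pd.Series(labels_arr, index=subjects, name="class"),
        effect_size=config.effect,
        missing_rate=config.missing_rate,
        seed=config.seed,
    )
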