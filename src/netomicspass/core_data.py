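"""Loading, harmonization and standardization of multi-modal feature tables.

A :class:`FeatureTable` is the container every downstream stage consumes:
a subjects × features numeric matrix (missing entries are NaN) together with
a feature → modality map and a scale state recording how far along the
normalization pipeline the values are (``raw`` → ``log`` → ``standardized``).

The normalization convention is the one standard in metabolomics-style
integration: per-feature mean centering followed by pareto scaling, i.e.
division by the *square root* of the sample standard deviation — milder
than unit-variance scaling, so high-variance features keep some weight.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Accepted modality labels for features.
MODALITIES = frozenset({"protein", "lipid", "acylcarnitine", "imaging", "clinical"})

#: Modalities measured on a positive abundance scale, log-transformed by default.
MOLECULAR_MODALITIES = ("protein", "lipid", "acylcarnitine")

#: Cell contents treated as missing when parsing delimited text.
MISSING_SENTINELS = ("NA", "NaN", "", ".")

SCALE_STATES = ("raw", "log", "standardized")


class FeatureTableError(ValueError):
    """Raised for structural problems in a feature table or its inputs."""


@dataclass
class FeatureTable:
    """Subjects × features matrix with modality labels and scale state.

    Parameters
    ----------
    values
        DataFrame indexed by subject id, columns are feature ids; NaN marks
        a missing measurement.
    modality
        Series mapping every feature id to one of :data:`MODALITIES`.
    scale_state
        One of ``raw``, ``log``, ``standardized``.
    provenance
        Free-text note on where the table came from.
    """

    values: pd.DataFrame
    modality: pd.Series
    scale_state: str = "raw"
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.scale_state not in SCALE_STATES:
            raise FeatureTableError(f"unknown scale_state {self.scale_state!r}")
        subj = self.values.index
        feats = self.values.columns
        dup_s = subj[subj.duplicated()].unique().tolist()
        if dup_s:
            raise FeatureTableError(f"duplicate subject ids: {dup_s}")
        dup_f = feats[feats.duplicated()].unique().tolist()
        if dup_f:
            raise FeatureTableError(f"duplicate feature ids: {dup_f}")
        missing_mod = [f for f in feats if f not in self.modality.index]
        if missing_mod:
            raise FeatureTableError(
                f"features absent from modality map: {missing_mod}"
            )
        bad = set(self.modality.loc[list(feats)]) - MODALITIES
        if bad:
            raise FeatureTableError(f"unknown modalities: {sorted(bad)}")
        self.modality = self.modality.loc[list(feats)]
        self.values = self.values.astype(float)

    # -- convenience accessors -------------------------------------------
    @property
    def subject_ids(self) -> list:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list:
        return list(self.values.columns)

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def observed_fraction(self) -> pd.Series:
        """Fraction of subjects with an observed value, per feature."""
        return self.values.notna().mean(axis=0)

    def copy(self) -> "FeatureTable":
        return replace(self, values=self.values.copy(), modality=self.modality.copy())


@dataclass
class UnitConversionMap:
    """Multiplicative unit conversions, e.g. pmol/L → pg/ml for peptides."""

    entries: list  # of (feature_id, factor, from_unit, to_unit)

    def __post_init__(self) -> None:
        for fid, factor, *_ in self.entries:
            if not factor > 0:
                raise FeatureTableError(
                    f"conversion factor for {fid!r} must be positive, got {factor}"
                )

    def inverse(self) -> "UnitConversionMap":
        return UnitConversionMap(
            [(fid, 1.0 / factor, to_u, from_u) for fid, factor, from_u, to_u in self.entries]
        )

    @classmethod
    def from_tsv(cls, path) -> "UnitConversionMap":
        df = pd.read_csv(path, sep="\t")
        return cls(
            [
                (r.feature_id, float(r.factor), str(r.from_unit), str(r.to_unit))
                for r in df.itertuples()
            ]
        )


# ---------------------------------------------------------------------------
# reading

def _sniff_sep(path) -> str:
    text = Path(path).read_text().splitlines()[0]
    return "\t" if "\t" in text else ","


def read_modality_map(path) -> pd.Series:
    df = pd.read_csv(path, sep=_sniff_sep(path))
    if not {"feature_id", "modality"} <= set(df.columns):
        raise FeatureTableError("modality map needs columns feature_id, modality")
    return pd.Series(df["modality"].values, index=df["feature_id"].values)


def read_feature_table(
    path,
    modality_map,
    orientation: str = "subjects_in_rows",
) -> FeatureTable:
    """Read a delimited numeric matrix into a raw-scale :class:`FeatureTable`.

    ``modality_map`` may be a path to a two-column TSV/CSV
    (feature_id, modality) or a Series. Cells equal to one of
    :data:`MISSING_SENTINELS` become missing; any other unparseable cell is
    an error rather than silent missingness.
    """
    if orientation not in ("subjects_in_rows", "features_in_rows"):
        raise FeatureTableError(f"unknown orientation {orientation!r}")
    sep = _sniff_sep(path)
    with open(path, newline="") as fh:
        header = next(csv.reader(fh, delimiter=sep))[1:]
    dups = sorted({h for h in header if header.count(h) > 1})
    if dups:
        raise FeatureTableError(f"duplicate identifiers in header: {dups}")

    df = pd.read_csv(
        path, sep=sep, index_col=0,
        na_values=list(MISSING_SENTINELS), keep_default_na=False, dtype=str,
    )
    dup_idx = df.index[df.index.duplicated()].unique().tolist()
    if dup_idx:
        raise FeatureTableError(f"duplicate identifiers in first column: {dup_idx}")
    try:
        df = df.apply(pd.to_numeric, errors="raise")
    except (ValueError, TypeError) as exc:
        raise FeatureTableError(f"unparseable cell in {path}: {exc}") from exc
    if orientation == "features_in_rows":
        df = df.T
    df.index.name = None
    df.columns.name = None

    if not isinstance(modality_map, pd.Series):
        modality_map = read_modality_map(modality_map)
    return FeatureTable(df, modality_map, scale_state="raw", provenance=str(path))


# ---------------------------------------------------------------------------
# merging / harmonization

def merge_modalities(tables: Sequence[FeatureTable]) -> FeatureTable:
    """Concatenate per-modality tables into one matrix over the subject union.

    Entries for subjects absent from a source table are missing.
    """
    if not tables:
        raise FeatureTableError("no tables to merge")
    if len(tables) == 1:
        return tables[0].copy()
    states = {t.scale_state for t in tables}
    if len(states) > 1:
        raise FeatureTableError(f"incompatible scale states: {sorted(states)}")
    seen: dict = {}
    for t in tables:
        overlap = [f for f in t.feature_ids if f in seen]
        if overlap:
            raise FeatureTableError(f"feature ids occur in multiple tables: {overlap}")
        seen.update(dict.fromkeys(t.feature_ids))
    subjects: list = []
    for t in tables:
        for s in t.subject_ids:
            if s not in subjects:
                subjects.append(s)
    values = pd.concat([t.values.reindex(subjects) for t in tables], axis=1)
    modality = pd.concat([t.modality for t in tables])
    prov = "; ".join(t.provenance for t in tables if t.provenance)
    return FeatureTable(values, modality, scale_state=tables[0].scale_state, provenance=prov)


def harmonize_units(table: FeatureTable, conv: UnitConversionMap) -> FeatureTable:
    """Apply multiplicative unit conversions to the mapped features."""
    if table.scale_state != "raw":
        raise FeatureTableError("unit harmonization requires raw-scale values")
    out = table.copy()
    for fid, factor, _from, _to in conv.entries:
        if fid not in out.values.columns:
            raise FeatureTableError(f"conversion map references unknown feature {fid!r}")
        out.values[fid] = out.values[fid] * factor
    return out


def filter_completeness(table: FeatureTable, min_fraction: float) -> FeatureTable:
    """Keep features observed in at least ``min_fraction`` of subjects.

    The boundary is inclusive (7/10 observed passes 0.7). Dropped features
    are logged.
    """
    if not 0 < min_fraction <= 1:
        raise FeatureTableError("min_fraction must be in (0, 1]")
    frac = table.observed_fraction()
    keep = frac[frac >= min_fraction].index
    dropped = [f for f in table.feature_ids if f not in set(keep)]
    if not len(keep):
        raise FeatureTableError("completeness filter would drop every feature")
    if dropped:
        logger.info("completeness filter dropped %d features: %s", len(dropped), dropped)
    out = table.copy()
    out.values = out.values[list(keep)]
    out.modality = out.modality.loc[list(keep)]
    return out


def log_transform(
    table: FeatureTable,
    offset: float = 0.0,
    modalities: Iterable[str] = MOLECULAR_MODALITIES,
) -> FeatureTable:
    """log2-transform the designated modalities (molecular ones by default).

    Imaging and clinical variables (ratios, velocities, possibly negative)
    are left on their native scale unless explicitly listed.
    """
    if table.scale_state != "raw":
        raise FeatureTableError("log transform requires raw-scale values")
    if offset < 0:
        raise FeatureTableError("offset must be >= 0")
    modalities = set(modalities)
    out = table.copy()
    for fid in out.feature_ids:
        if out.modality[fid] not in modalities:
            continue
        col = out.values[fid]
        bad = col[col + offset <= 0]
        if len(bad):
            subj = bad.index[0]
            raise FeatureTableError(
                f"nonpositive value for feature {fid!r} (subject {subj!r}) "
                f"with offset {offset}"
            )
        out.values[fid] = np.log2(col + offset)
    out.scale_state = "log"
    return out


def pareto_scale(table: FeatureTable) -> FeatureTable:
    """Mean-center and pareto-scale every feature: x' = (x − mean) / sqrt(sd).

    Means and sample standard deviations (n−1 denominator) are computed over
    observed entries only; missing entries stay missing.
    """
    if table.scale_state not in ("raw", "log"):
        raise FeatureTableError("pareto scaling expects raw or log scale input")
    vals = table.values
    n_obs = vals.notna().sum(axis=0)
    few = n_obs[n_obs < 2].index.tolist()
    if few:
        raise FeatureTableError(f"features with < 2 observed values: {few}")
    sd = vals.std(axis=0, ddof=1)
    const = sd[sd == 0].index.tolist()
    if const:
        raise FeatureTableError(f"constant features cannot be pareto scaled: {const}")
    out = table.copy()
    out.values = (vals - vals.mean(axis=0)) / np.sqrt(sd)
    out.scale_state = "standardized"
    return out


def flag_outliers(table: FeatureTable, k: float = 5.0) -> tuple[FeatureTable, int]:
    """Set entries beyond median ± k·MAD (MAD scaled by 1.4826) to missing.

    Features with zero MAD are skipped with a warning. Returns the filtered
    table and the number of entries flagged.
    """
    if not k > 0:
        raise FeatureTableError("k must be positive")
    if table.scale_state not in ("raw", "log"):
        raise FeatureTableError("outlier filtering expects raw or log scale input")
    out = table.copy()
    n_flagged = 0
    for fid in out.feature_ids:
        col = out.values[fid]
        obs = col.dropna()
        if obs.empty:
            continue
        med = obs.median()
        mad = 1.4826 * (obs - med).abs().median()
        if mad == 0:
            warnings.warn(f"feature {fid!r} has zero MAD; outlier filter skipped")
            continue
        mask = (col - med).abs() > k * mad
        n_flagged += int(mask.sum())
        out.values.loc[mask, fid] = np.nan
    logger.info("outlier filter flagged %d entries", n_flagged)
    return out, n_flagged


def impute_simple(table: FeatureTable, method: str = "median", k: int = 5) -> FeatureTable:
    """Fill missing entries by feature median or k-nearest-subject mean.

    Plumbing only — a convenience for complete-data consumers, not a
    substitute for principled multiple imputation.
    """
    fully_missing = [f for f, n in table.values.notna().sum(axis=0).items() if n == 0]
    if fully_missing:
        raise FeatureTableError(f"features entirely missing: {fully_missing}")
    out = table.copy()
    if method == "median":
        out.values = out.values.fillna(out.values.median(axis=0))
    elif method == "knn":
        X = out.values.to_numpy()
        obs = ~np.isnan(X)
        for i in range(X.shape[0]):
            miss_j = np.where(~obs[i])[0]
            if miss_j.size == 0:
                continue
            shared = obs & obs[i]
            diff = np.where(shared, X - X[i], 0.0)
            n_shared = shared.sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                dist = np.sqrt((diff ** 2).sum(axis=1) / n_shared)
            dist[i] = np.inf
            dist[n_shared == 0] = np.inf
            order = np.argsort(dist)
            for j in miss_j:
                donors = [o for o in order if obs[o, j] and np.isfinite(dist[o])][:k]
                if donors:
                    X[i, j] = X[donors, j].mean()
                else:  # no subject shares this feature: fall back to median
                    X[i, j] = np.nanmedian(X[:, j])
        out.values = pd.DataFrame(X, index=out.values.index, columns=out.values.columns)
    else:
        raise FeatureTableError(f"unknown imputation method {method!r}")
    return out


def write_feature_table(table: FeatureTable, path) -> None:
    """Write the matrix as TSV (subjects in rows, NA for missing)."""
    table.values.to_csv(path, sep="\t", na_rep="NA", index_label="subject_id")
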