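"""Data preparation: log2 quantification matrices, filtering, normalization
and the three imputation strategies of the default analytical pipeline.

Intensities are log2-transformed on load (zeros and blanks become missing).
Missing values in label-free proteomics mix two mechanisms: cells missing
completely at random (MCAR, e.g. sporadic identification failures) and cells
missing not at random (MNAR, low-abundance proteins below the detection
limit).  KNN imputation targets MCAR; MinProb draws left-censored replacement
values near each sample's detection limit and targets MNAR; the mixed
strategy dispatches per feature on its missing fraction (strictly below the
threshold, default 50%, counts as MCAR).

Pipeline order is fixed: filter -> normalize -> impute.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

__all__ = [
    "ExperimentMatrix",
    "ImputationConfig",
    "load_wide_tsv",
    "load_protein_groups",
    "filter_features",
    "normalize",
    "impute",
]


@dataclass
class ExperimentMatrix:
    """Samples x features matrix of log2 intensities with design metadata.

    ``values``: DataFrame, rows = samples, columns = features, NaN = missing.
    ``sample_meta``: DataFrame indexed like ``values`` with at least a
    ``group`` column and optionally ``subject`` / ``timepoint``.
    ``feature_meta``: optional DataFrame indexed by feature with a ``type``
    column (protein|peptide|phosphosite|clinical).
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    feature_meta: pd.DataFrame | None = None

    def __post_init__(self):
        if not self.values.columns.is_unique:
            raise ValueError("feature identifiers must be unique")
        if "group" not in self.sample_meta.columns:
            raise ValueError("sample_meta must carry a 'group' column")
        if list(self.sample_meta.index) != list(self.values.index):
            self.sample_meta = self.sample_meta.loc[self.values.index]
        if self.sample_meta["group"].isna().any() or (self.sample_meta["group"] == "").any():
            raise ValueError("group labels must be non-empty")

    @property
    def groups(self) -> pd.Series:
        return self.sample_meta["group"]

    @property
    def subjects(self) -> pd.Series | None:
        return self.sample_meta["subject"] if "subject" in self.sample_meta.columns else None

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: pd.DataFrame) -> "ExperimentMatrix":
        fmeta = self.feature_meta
        if fmeta is not None:
            fmeta = fmeta.loc[fmeta.index.intersection(values.columns)]
        return ExperimentMatrix(values=values, sample_meta=self.sample_meta.copy(),
                                feature_meta=fmeta)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="sample")


@dataclass
class ImputationConfig:
    """Parameters of the imputation step.

    ``minprob_quantile`` q locates the per-sample Gaussian at the q-quantile
    of that sample's observed values (detection-limit proxy, default 0.01);
    ``minprob_width`` w scales its s.d. as w x sample s.d. (default 0.3).
    ``mixed_threshold`` is the strict MCAR missing-fraction bound (default
    0.5: features missing in <50% of samples use KNN, the rest MinProb).
    """

    method: str = "minprob"
    k: int = 5
    minprob_quantile: float = 0.01
    minprob_width: float = 0.3
    mixed_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.method not in ("knn", "minprob", "mixed"):
            raise ValueError(f"unknown imputation method {self.method!r}")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0 < self.minprob_quantile < 0.5:
            raise ValueError("minprob_quantile must be in (0, 0.5)")
        if self.minprob_width <= 0:
            raise ValueError("minprob_width must be > 0")
        if not 0 < self.mixed_threshold < 1:
            raise ValueError("mixed_threshold must be in (0, 1)")


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------


def _log2_missing(values: pd.DataFrame, already_log2: bool) -> pd.DataFrame:
    values = values.apply(pd.to_numeric, errors="coerce")
    if already_log2:
        return values
    values = values.where(values > 0)  # zeros/negatives -> missing
    return np.log2(values)


def load_wide_tsv(path, sample_meta: pd.DataFrame, already_log2: bool = False
                  ) -> ExperimentMatrix:
    """Read a wide sample x feature TSV (first column = sample id)."""
    values = pd.read_csv(path, sep="\t", index_col=0)
    return ExperimentMatrix(values=_log2_missing(values, already_log2),
                            sample_meta=sample_meta.loc[values.index])


def load_protein_groups(path, sample_meta: pd.DataFrame, feature_column: str = "Protein IDs",
                        intensity_prefix: str = "LFQ intensity ") -> ExperimentMatrix:
    """Read a proteinGroups-style table: one row per protein group, one
    ``LFQ intensity <sample>`` column per sample; rows flagged '+' in
    ``Reverse`` or ``Potential contaminant`` columns are dropped."""
    table = pd.read_csv(path, sep="\t")
    if feature_column not in table.columns:
        raise ValueError(f"missing feature column {feature_column!r}")
    for flag in ("Reverse", "Potential contaminant", "Only identified by site"):
        if flag in table.columns:
            table = table[table[flag].fillna("") != "+"]
    sample_cols = [c for c in table.columns if c.startswith(intensity_prefix)]
    if not sample_cols:
        raise ValueError(f"no columns with prefix {intensity_prefix!r}")
    wide = table.set_index(feature_column)[sample_cols]
    wide.columns = [c[len(intensity_prefix):] for c in sample_cols]
    values = _log2_missing(wide.T, already_log2=False)
    values.index.name = "sample"
    return ExperimentMatrix(values=values, sample_meta=sample_meta.loc[values.index])


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def filter_features(matrix: ExperimentMatrix, mode: str = "max_missing",
                    threshold: float = 0.3):
    """Drop features violating a missing-value rule.

    ``max_missing``: keep features whose missing fraction <= threshold.
    ``min_per_group``: keep features with >= threshold observed values in
    every group.  ``min_total``: >= threshold observed values overall.
    Returns (filtered matrix, list of dropped feature ids).
    """
    values = matrix.values
    if mode == "max_missing":
        if not 0 <= threshold <= 1:
            raise ValueError("max_missing threshold must be a fraction in [0, 1]")
        frac = values.isna().mean(axis=0)
        keep = frac <= threshold
    elif mode == "min_per_group":
        if threshold < 0 or int(threshold) != threshold:
            raise ValueError("min_per_group threshold must be a non-negative count")
        counts = values.notna().groupby(matrix.groups, observed=True).sum()
        keep = (counts >= threshold).all(axis=0)
    elif mode == "min_total":
        if threshold < 0 or int(threshold) != threshold:
            raise ValueError("min_total threshold must be a non-negative count")
        keep = values.notna().sum(axis=0) >= threshold
    else:
        raise ValueError(f"unknown filter mode {mode!r}")
    dropped = list(values.columns[~keep])
    return matrix.with_values(values.loc[:, keep]), dropped


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def normalize(matrix: ExperimentMatrix, method: str = "median") -> ExperimentMatrix:
    """Per-sample normalization on the log2 scale; missing cells ignored."""
    values = matrix.values
    observed_per_sample = values.notna().sum(axis=1)
    if (observed_per_sample == 0).any():
        bad = list(values.index[observed_per_sample == 0])
        raise ValueError(f"samples with no observed values: {bad}")
    if method == "none":
        return matrix.with_values(values.copy())
    if method == "median":
        centered = values.sub(values.median(axis=1, skipna=True), axis=0)
        return matrix.with_values(centered)
    if method == "quantile":
        return matrix.with_values(_quantile_normalize(values))
    raise ValueError(f"unknown normalization method {method!r}")


def _quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    # Reference distribution = mean of per-sample empirical quantiles on a
    # common grid; each sample's observed values are mapped through their
    # plotting positions, so samples with missing cells are supported.
    arr = values.to_numpy(dtype=float)
    n_samples, n_features = arr.shape
    grid = (np.arange(n_features) + 0.5) / n_features
    per_sample_q = np.empty((n_samples, n_features))
    for i in range(n_samples):
        obs = arr[i][~np.isnan(arr[i])]
        per_sample_q[i] = np.quantile(obs, grid)
    reference = per_sample_q.mean(axis=0)
    out = np.full_like(arr, np.nan)
    for i in range(n_samples):
        mask = ~np.isnan(arr[i])
        obs = arr[i][mask]
        order = np.argsort(obs, kind="mergesort")
        ranks = np.empty(len(obs), dtype=float)
        ranks[order] = np.arange(len(obs))
        pos = (ranks + 0.5) / len(obs)
        out[i, mask] = np.interp(pos, grid, reference)
    return pd.DataFrame(out, index=values.index, columns=values.columns)


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------


def impute(matrix: ExperimentMatrix, config: ImputationConfig | None = None
           ) -> ExperimentMatrix:
    """Replace every missing cell; observed cells are returned untouched."""
    config = config or ImputationConfig()
    values = matrix.values
    if (values.notna().sum(axis=1) == 0).any():
        raise ValueError("every sample needs at least one observed value")
    if not values.isna().any().any():
        return matrix.with_values(values.copy())
    if config.method == "knn":
        filled = _impute_knn(values, config.k)
    elif config.method == "minprob":
        filled = _impute_minprob(values, config)
    else:  # mixed
        miss_frac = values.isna().mean(axis=0)
        mcar = miss_frac < config.mixed_threshold  # strict "<" bound
        filled = values.copy()
        if bool(mcar.any()) and values.loc[:, mcar].isna().any().any():
            filled.loc[:, mcar] = _impute_knn(values, config.k).loc[:, mcar]
        if bool((~mcar).any()):
            filled.loc[:, ~mcar] = _impute_minprob(values, config).loc[:, ~mcar]
    # observed cells are bit-identical to the input by construction
    filled = values.where(values.notna(), filled)
    return matrix.with_values(filled)


def _impute_knn(values: pd.DataFrame, k: int) -> pd.DataFrame:
    if k > values.shape[0] - 1:
        raise ValueError(f"k={k} exceeds available neighbor samples ({values.shape[0] - 1})")
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    filled = imputer.fit_transform(values.to_numpy(dtype=float))
    return pd.DataFrame(filled, index=values.index, columns=values.columns)


def _impute_minprob(values: pd.DataFrame, config: ImputationConfig) -> pd.DataFrame:
    rng = np.random.default_rng(config.seed)
    arr = values.to_numpy(dtype=float).copy()
    for i in range(arr.shape[0]):  # per sample: left-censored Gaussian draws
        row = arr[i]
        missing = np.isnan(row)
        if not missing.any():
            continue
        obs = row[~missing]
        center = np.quantile(obs, config.minprob_quantile)
        sd = np.std(obs, ddof=1) if len(obs) > 1 else 1.0
        if sd == 0 or np.isnan(sd):
            sd = 1.0
        arr[i, missing] = rng.normal(center, config.minprob_width * sd, missing.sum())
    return pd.DataFrame(arr, index=values.index, columns=values.columns)


def prepare(matrix: ExperimentMatrix, filter_mode: str = "max_missing",
            filter_threshold: float = 0.3, normalize_method: str = "median",
            imputation: ImputationConfig | None = None) -> tuple:
    """The fixed default preparation chain: filter -> normalize -> impute.

    Returns (processed matrix, dropped feature list).
    """
    filtered, dropped = filter_features(matrix, mode=filter_mode, threshold=filter_threshold)
    normalized = normalize(filtered, method=normalize_method)
    processed = impute(normalized, imputation)
    return processed, dropped
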