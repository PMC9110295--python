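"""Exploration summaries, PCA, hypothesis testing with automatic design
detection, FDR control, enrichment and survival analysis.

The differential-regulation entry point picks the test from the design: two
independent groups -> t-test (pooled variance by default, matching the SAM
denominator; Welch available), two groups sharing subject ids -> paired
t-test, more than two groups -> one-way ANOVA with pairwise post hoc
t-tests (BH across all pairs and features jointly), repeated subjects
across all conditions -> repeated-measures ANOVA with subject as blocking
factor.  Multiple testing is controlled with Benjamini-Hochberg step-up
FDR (default) or a label-permutation FDR; regulation flags follow the
fold-change > 2 and FDR < 0.05 defaults (|log2FC| > 1, two-sided).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .prep import ExperimentMatrix

__all__ = [
    "SignificanceThresholds",
    "SurvivalResult",
    "summarize_matrix",
    "pca",
    "differential_regulation",
    "sam_statistic",
    "bh_fdr",
    "permutation_fdr",
    "fisher_enrichment",
    "km_logrank",
]


@dataclass(frozen=True)
class SignificanceThresholds:
    """Regulation flags: |fold change| > fold_change_min and FDR < fdr_max."""

    fold_change_min: float = 2.0  # linear scale
    fdr_max: float = 0.05

    def __post_init__(self):
        if self.fold_change_min < 1:
            raise ValueError("fold_change_min must be >= 1")
        if not 0 < self.fdr_max < 1:
            raise ValueError("fdr_max must be in (0, 1)")

    def flag(self, log2fc, padj) -> np.ndarray:
        log2fc = np.asarray(log2fc, dtype=float)
        padj = np.asarray(padj, dtype=float)
        bound = np.log2(self.fold_change_min)
        out = np.full(log2fc.shape, "ns", dtype=object)
        sig = padj < self.fdr_max
        out[sig & (log2fc > bound)] = "up"
        out[sig & (log2fc < -bound)] = "down"
        return out


# ---------------------------------------------------------------------------
# exploration
# ---------------------------------------------------------------------------


def summarize_matrix(matrix: ExperimentMatrix) -> dict:
    """Per-group counts, dynamic-range ranking and protein CVs.

    CV% is computed on linear-scale intensities (100 * sd / mean); the
    dynamic-range table ranks features by average linear intensity
    (rank 1 = most abundant).
    """
    values = matrix.values
    linear = np.power(2.0, values)
    group_counts = pd.DataFrame({
        "n_samples": matrix.groups.value_counts().sort_index(),
        "n_features_observed": values.notna().any(axis=0).sum(),
    })
    mean_linear = linear.mean(axis=0, skipna=True)
    dynamic_range = pd.DataFrame({
        "mean_intensity": mean_linear,
        "rank": mean_linear.rank(ascending=False, method="min"),
    }).sort_values("rank")
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = 100.0 * linear.std(axis=0, ddof=1, skipna=True) / mean_linear
    cv_table = pd.DataFrame({"cv_percent": cv})
    for group, sub in linear.groupby(matrix.groups, observed=True):
        with np.errstate(invalid="ignore", divide="ignore"):
            cv_table[f"cv_percent_{group}"] = (
                100.0 * sub.std(axis=0, ddof=1, skipna=True) / sub.mean(axis=0, skipna=True)
            )
    return {"group_counts": group_counts, "dynamic_range": dynamic_range, "cv": cv_table}


@dataclass
class PCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray


def pca(matrix: ExperimentMatrix, n_components: int = 2) -> PCAResult:
    """Principal component analysis of the complete (imputed) matrix."""
    from sklearn.decomposition import PCA

    values = matrix.values
    if values.isna().any().any():
        raise ValueError("matrix contains missing values; run impute() first")
    n_components = min(n_components, min(values.shape))
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(values.to_numpy(dtype=float))
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=values.index, columns=cols),
        loadings=pd.DataFrame(model.components_.T, index=values.columns, columns=cols),
        explained_variance_ratio=model.explained_variance_ratio_,
    )


# ---------------------------------------------------------------------------
# test statistics
# ---------------------------------------------------------------------------


def sam_statistic(group_a, group_b, s0: float = 0.0) -> np.ndarray:
    """Moderated difference statistic d = (mean_a - mean_b) / (SE + s0).

    ``group_a``/``group_b`` are (samples x features) arrays; SE is the
    pooled-variance standard error of the mean difference, so at s0 = 0 the
    statistic reduces to the ordinary pooled-variance t.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if b.ndim == 1:
        b = b[:, None]
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("both groups need >= 2 values per feature")
    diff = a.mean(axis=0) - b.mean(axis=0)
    sp2 = ((na - 1) * a.var(axis=0, ddof=1) + (nb - 1) * b.var(axis=0, ddof=1)) / (na + nb - 2)
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    if s0 == 0 and np.any(se == 0):
        raise ZeroDivisionError("zero pooled variance with s0=0: statistic undefined")
    return diff / (se + s0)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# differential regulation
# ---------------------------------------------------------------------------


def _paired_frames(values: pd.DataFrame, meta: pd.DataFrame, ga: str, gb: str):
    """Align two groups on shared subject ids; None when not pairable."""
    if "subject" not in meta.columns:
        return None
    sub_a = meta[meta["group"] == ga]
    sub_b = meta[meta["group"] == gb]
    if sub_a["subject"].duplicated().any() or sub_b["subject"].duplicated().any():
        return None
    shared = sorted(set(sub_a["subject"]) & set(sub_b["subject"]))
    if len(shared) != len(sub_a) or len(shared) != len(sub_b) or len(shared) < 2:
        return None
    a = values.loc[sub_a.index].set_axis(sub_a["subject"].to_numpy(), axis=0).loc[shared]
    b = values.loc[sub_b.index].set_axis(sub_b["subject"].to_numpy(), axis=0).loc[shared]
    return a, b


def _ttest_frame(a: pd.DataFrame, b: pd.DataFrame, paired: bool, variance: str):
    if paired:
        stat, p = sps.ttest_rel(a.to_numpy(), b.to_numpy(), axis=0)
    else:
        stat, p = sps.ttest_ind(a.to_numpy(), b.to_numpy(), axis=0,
                                equal_var=(variance == "pooled"))
    stat = np.asarray(stat, dtype=float)
    p = np.asarray(p, dtype=float)
    # constant identical inputs yield 0/0 -> define as no effect
    p = np.where(np.isnan(p) & (a.mean(0).to_numpy() == b.mean(0).to_numpy()), 1.0, p)
    stat = np.where(np.isnan(stat), 0.0, stat)
    return stat, np.nan_to_num(p, nan=1.0)


def _rm_anova(values: pd.DataFrame, meta: pd.DataFrame, groups: list):
    """Repeated-measures one-way ANOVA with subject as blocking factor.

    Requires a balanced design: every subject measured exactly once per
    condition.
    """
    wide = {}
    for g in groups:
        sub = meta[meta["group"] == g]
        if sub["subject"].duplicated().any():
            raise ValueError("repeated-measures design must have one sample per subject/condition")
        wide[g] = values.loc[sub.index].set_axis(sub["subject"].to_numpy(), axis=0)
    subjects = sorted(set.intersection(*(set(w.index) for w in wide.values())))
    if any(len(w) != len(subjects) for w in wide.values()):
        raise ValueError("unbalanced repeated-measures design rejected")
    cube = np.stack([wide[g].loc[subjects].to_numpy(dtype=float) for g in groups])  # k,n,F
    k, n, _ = cube.shape
    grand = cube.mean(axis=(0, 1))
    ss_total = ((cube - grand) ** 2).sum(axis=(0, 1))
    ss_treat = n * ((cube.mean(axis=1) - grand) ** 2).sum(axis=0)
    ss_subj = k * ((cube.mean(axis=0) - grand) ** 2).sum(axis=0)
    ss_err = ss_total - ss_treat - ss_subj
    df_treat, df_err = k - 1, (k - 1) * (n - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (ss_treat / df_treat) / (ss_err / df_err)
    f = np.where(np.isnan(f), 0.0, f)
    p = sps.f.sf(f, df_treat, df_err)
    return f, np.nan_to_num(p, nan=1.0)


def detect_design(matrix: ExperimentMatrix) -> str:
    """Classify the design: two_group | two_group_paired | multi_group |
    multi_group_repeated."""
    groups = sorted(matrix.groups.unique())
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    meta = matrix.sample_meta
    if len(groups) == 2:
        paired = _paired_frames(matrix.values, meta, groups[0], groups[1])
        return "two_group_paired" if paired is not None else "two_group"
    if "subject" in meta.columns:
        per_group = [set(meta.loc[meta["group"] == g, "subject"]) for g in groups]
        counts_ok = not meta.duplicated(["group", "subject"]).any()
        if counts_ok and all(s == per_group[0] for s in per_group[1:]):
            return "multi_group_repeated"
    return "multi_group"


def differential_regulation(matrix: ExperimentMatrix,
                            thresholds: SignificanceThresholds | None = None,
                            fdr: str = "bh", permutations: int = 250,
                            seed: int = 0, variance: str = "pooled",
                            s0: float = 0.0) -> pd.DataFrame:
    """Feature-wise group comparison with automatic test selection.

    Returns one row per feature per contrast with columns: feature,
    contrast, test, mean per compared group, log2fc, statistic, pvalue,
    padj, padj_method, regulation.  ``fdr='permutation'`` replaces BH by the
    label-permutation estimate for two-group independent designs.
    """
    thresholds = thresholds or SignificanceThresholds()
    if fdr not in ("bh", "permutation"):
        raise ValueError("fdr must be 'bh' or 'permutation'")
    values = matrix.values
    if values.isna().any().any():
        raise ValueError("matrix contains missing values; run impute() first")
    meta = matrix.sample_meta
    groups = sorted(matrix.groups.unique())
    if any((matrix.groups == g).sum() < 2 for g in groups):
        raise ValueError("every group needs >= 2 samples")
    design = detect_design(matrix)
    features = list(values.columns)
    rows = []

    def pairwise_row(ga, gb, stat, p, test):
        a = values.loc[meta["group"] == ga]
        b = values.loc[meta["group"] == gb]
        return pd.DataFrame({
            "feature": features,
            "contrast": f"{gb}_vs_{ga}",
            "test": test,
            "mean_a": a.mean(0).to_numpy(),
            "mean_b": b.mean(0).to_numpy(),
            "log2fc": (b.mean(0) - a.mean(0)).to_numpy(),
            "statistic": stat,
            "pvalue": p,
        })

    if design in ("two_group", "two_group_paired"):
        ga, gb = groups
        if design == "two_group_paired":
            a, b = _paired_frames(values, meta, ga, gb)
            stat, p = _ttest_frame(b, a, paired=True, variance=variance)
            test = "paired_ttest"
        else:
            a = values.loc[meta["group"] == ga]
            b = values.loc[meta["group"] == gb]
            stat, p = _ttest_frame(b, a, paired=False, variance=variance)
            test = "ttest" if variance == "pooled" else "welch_ttest"
        frame = pairwise_row(ga, gb, stat, p, test)
        if fdr == "permutation" and design == "two_group":
            perm = permutation_fdr(matrix, permutations=permutations, seed=seed, s0=s0)
            frame["padj"] = perm.set_index("feature").loc[features, "qvalue"].to_numpy()
            frame["padj_method"] = perm.attrs.get("method", "permutation")
        else:
            if fdr == "permutation":
                warnings.warn("permutation FDR requires an independent two-group design; "
                              "falling back to BH")
            frame["padj"] = bh_fdr(frame["pvalue"].to_numpy())
            frame["padj_method"] = "bh"
        frame["regulation"] = thresholds.flag(frame["log2fc"], frame["padj"])
        rows.append(frame)
    else:
        if design == "multi_group_repeated":
            f, p = _rm_anova(values, meta, groups)
            omni_test = "anova_rm"
        else:
            arrays = [values.loc[meta["group"] == g].to_numpy() for g in groups]
            f, p = sps.f_oneway(*arrays, axis=0)
            f = np.where(np.isnan(f), 0.0, np.asarray(f, dtype=float))
            p = np.nan_to_num(np.asarray(p, dtype=float), nan=1.0)
            omni_test = "anova"
        omnibus = pd.DataFrame({
            "feature": features, "contrast": "omnibus", "test": omni_test,
            "mean_a": np.nan, "mean_b": np.nan, "log2fc": np.nan,
            "statistic": f, "pvalue": p,
        })
        omnibus["padj"] = bh_fdr(omnibus["pvalue"].to_numpy())
        omnibus["padj_method"] = "bh"
        omnibus["regulation"] = "ns"
        rows.append(omnibus)
        posthoc = []
        for ga, gb in itertools.combinations(groups, 2):
            a = values.loc[meta["group"] == ga]
            b = values.loc[meta["group"] == gb]
            stat, pp = _ttest_frame(b, a, paired=False, variance=variance)
            posthoc.append(pairwise_row(ga, gb, stat, pp, "posthoc_ttest"))
        posthoc = pd.concat(posthoc, ignore_index=True)
        # BH jointly across all pairs and features
        posthoc["padj"] = bh_fdr(posthoc["pvalue"].to_numpy())
        posthoc["padj_method"] = "bh"
        posthoc["regulation"] = thresholds.flag(posthoc["log2fc"], posthoc["padj"])
        rows.append(posthoc)
    out = pd.concat(rows, ignore_index=True)
    out.attrs["design"] = design
    return out


# ---------------------------------------------------------------------------
# permutation FDR
# ---------------------------------------------------------------------------


def permutation_fdr(matrix: ExperimentMatrix, permutations: int = 250, seed: int = 0,
                    s0: float = 0.0, min_permutations: int = 10) -> pd.DataFrame:
    """Label-permutation FDR for a two-group independent design.

    For each feature's observed |d| cutoff, the estimated FDR is the mean
    number of null exceedances per permutation divided by the observed
    exceedance count, clipped to [0, 1] and made monotone in |d|.  When the
    number of achievable distinct label permutations is below the configured
    floor the estimate would be unstable, so the function falls back to BH
    with a warning (method recorded in ``result.attrs``).
    """
    if permutations < 10:
        raise ValueError("permutations must be >= 10")
    groups = sorted(matrix.groups.unique())
    if len(groups) != 2:
        raise ValueError("permutation FDR requires exactly two groups")
    labels = matrix.groups.to_numpy()
    values = matrix.values.to_numpy(dtype=float)
    n_a = int((labels == groups[0]).sum())
    n = len(labels)
    mask_a = labels == groups[0]
    obs = sam_statistic(values[mask_a], values[~mask_a], s0=s0)

    distinct = comb(n, n_a)
    if distinct < min_permutations:
        warnings.warn(
            f"only {distinct} distinct label permutations available "
            f"(< {min_permutations}); falling back to BH"
        )
        _, p = sps.ttest_ind(values[mask_a], values[~mask_a], axis=0, equal_var=True)
        out = pd.DataFrame({"feature": matrix.values.columns, "statistic": obs,
                            "qvalue": bh_fdr(np.nan_to_num(p, nan=1.0))})
        out.attrs["method"] = "bh_fallback"
        return out

    rng = np.random.default_rng(seed)
    null_abs = np.empty((permutations, values.shape[1]))
    for b in range(permutations):
        perm = rng.permutation(n)
        pa = values[perm[:n_a]]
        pb = values[perm[n_a:]]
        null_abs[b] = np.abs(sam_statistic(pa, pb, s0=s0))
    abs_obs = np.abs(obs)
    order = np.argsort(abs_obs, kind="mergesort")  # ascending |d|
    null_sorted = np.sort(null_abs.ravel())
    fdr = np.empty_like(abs_obs)
    m = values.shape[1]
    for rank, ix in enumerate(order):
        cut = abs_obs[ix]
        observed_exceed = m - np.searchsorted(abs_obs[order], cut, side="left")
        null_exceed = len(null_sorted) - np.searchsorted(null_sorted, cut, side="left")
        expected_false = null_exceed / permutations
        fdr[ix] = min(1.0, expected_false / max(observed_exceed, 1))
    # q-value: best achievable FDR at any cutoff still rejecting the feature
    running = np.inf
    q = np.empty_like(fdr)
    for ix in order:
        running = min(running, fdr[ix])
        q[ix] = running
    out = pd.DataFrame({"feature": matrix.values.columns, "statistic": obs, "qvalue": q})
    out.attrs["method"] = "permutation"
    return out


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------


def fisher_enrichment(hit_set, annotation_sets: dict, universe) -> pd.DataFrame:
    """Two-sided Fisher exact test per annotation term, BH across terms.

    ``annotation_sets`` maps term -> feature ids; every set is intersected
    with the universe before testing.  Results are sorted by adjusted p,
    then term id.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    hits = set(hit_set) & universe
    rows = []
    for term in sorted(annotation_sets):
        members = set(annotation_sets[term]) & universe
        a = len(hits & members)
        b = len(hits - members)
        c = len(members - hits)
        d = len(universe) - a - b - c
        odds, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append((term, a, len(members), len(hits), odds, p))
    out = pd.DataFrame(rows, columns=["term", "hits_in_term", "term_size",
                                      "n_hits", "odds_ratio", "pvalue"])
    out["padj"] = bh_fdr(out["pvalue"].to_numpy()) if len(out) else []
    return out.sort_values(["padj", "term"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------


@dataclass
class SurvivalResult:
    curves: dict  # group -> DataFrame(time, survival, at_risk)
    statistic: float
    pvalue: float
    groups: pd.Series = field(repr=False, default=None)
    rule: str = ""
    note: str = ""


def km_logrank(times, events, expression, split: float = 0.25) -> SurvivalResult:
    """Kaplan-Meier curves and two-sided log-rank test for a marker split.

    Samples with marker expression above the (1 - split) quantile form the
    "high" group (default: top 25%), the remainder "low".
    """
    times = pd.Series(np.asarray(times, dtype=float))
    events = pd.Series(np.asarray(events, dtype=int))
    expression = pd.Series(np.asarray(expression, dtype=float))
    if not 0 < split < 1:
        raise ValueError("split must be in (0, 1)")
    if (times < 0).any():
        raise ValueError("times must be >= 0")
    cut = expression.quantile(1.0 - split)
    high = expression > cut
    if high.sum() == 0 or (~high).sum() == 0:
        raise ValueError("expression split produced an empty group")
    labels = pd.Series(np.where(high, "high", "low"), index=expression.index)
    rule = f"top{int(round(split * 100))}pct"
    curves = {}
    for name, mask in (("high", high), ("low", ~high)):
        km = KaplanMeierFitter()
        km.fit(times[mask], events[mask], label=name)
        frame = km.survival_function_.reset_index()
        frame.columns = ["time", "survival"]
        at_risk = km.event_table["at_risk"].reindex(frame["time"]).to_numpy()
        frame["at_risk"] = at_risk
        curves[name] = frame
    if events.sum() == 0:
        return SurvivalResult(curves=curves, statistic=float("nan"),
                              pvalue=float("nan"), groups=labels, rule=rule,
                              note="no-events")
    res = logrank_test(times[high], times[~high], events[high], events[~high])
    return SurvivalResult(curves=curves, statistic=float(res.test_statistic),
                          pvalue=float(res.p_value), groups=labels, rule=rule)
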