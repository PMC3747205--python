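"""Class-vs-feature association statistics.

Feature distributions are compared between translational classes with the
two-sample Kolmogorov-Smirnov test (sup-norm distance between empirical
CDFs), Class II serving as the reference class; genome-wide comparisons use
the full gene universe as reference.  Summaries mirror a per-class median
table with uAUG prevalence rows and an asterisk marking features that are
both highly significant (p below threshold in both flanking classes) and
monotone in the class ordering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

EXACT_LIMIT_DEFAULT = 100


@dataclass(frozen=True)
class KSResult:
    d_stat: float
    p_value: float
    n1: int
    n2: int
    method: str


def _ecdf_at(sorted_sample: np.ndarray, points: np.ndarray) -> np.ndarray:
    return np.searchsorted(sorted_sample, points, side="right") / sorted_sample.size


def _ks_d(x: np.ndarray, y: np.ndarray) -> float:
    pooled = np.concatenate([x, y])
    return float(np.max(np.abs(_ecdf_at(np.sort(x), pooled) - _ecdf_at(np.sort(y), pooled))))


def _ks_exact_p(x: np.ndarray, y: np.ndarray, d_obs: float) -> float:
    """P(D >= d_obs) by enumeration of all splits of the pooled sample."""
    pooled = np.sort(np.concatenate([x, y]))
    n, n1 = pooled.size, x.size
    n2 = n - n1
    count = total = 0
    for idx in combinations(range(n), n1):
        ind = np.zeros(n)
        ind[list(idx)] = 1.0
        cdf1 = np.cumsum(ind) / n1
        cdf2 = np.cumsum(1.0 - ind) / n2
        d = np.max(np.abs(cdf1 - cdf2))
        total += 1
        if d >= d_obs - 1e-12:
            count += 1
    return count / total


def ks_two_sample(x, y, exact_limit: int = EXACT_LIMIT_DEFAULT) -> KSResult:
    """Two-sample KS test: D = sup |F1 - F2| with a two-sided p-value.

    For small samples (n1*n2 <= ``exact_limit``) the p-value is the exact
    permutation probability of a distance at least as large, enumerated over
    all splits of the pooled sample; otherwise the Kolmogorov statistic's
    distribution is evaluated at the effective sample size
    n = round(n1*n2/(n1+n2)), the standard two-sample asymptotic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    d = _ks_d(x, y)
    n1, n2 = x.size, y.size
    if n1 * n2 <= exact_limit:
        p = _ks_exact_p(x, y, d)
        method = "exact"
    else:
        en = round(n1 * n2 / (n1 + n2))
        p = float(_scipy_stats.kstwo.sf(d, en))
        method = "asymptotic"
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return KSResult(d_stat=d, p_value=p, n1=n1, n2=n2, method=method)


def ecdf_curve(values) -> pd.DataFrame:
    """Right-continuous ECDF as sorted (value, cumulative fraction) pairs."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    uniq, counts = np.unique(v, return_counts=True)
    return pd.DataFrame(
        {"value": uniq, "cumulative_fraction": np.cumsum(counts) / v.size}
    )


def percent_difference(value_a: float, value_b: float) -> float:
    """Signed percent difference of a relative to b: 100 * (a - b) / b."""
    if value_b == 0:
        raise ValueError("reference value must be nonzero")
    return 100.0 * (value_a - value_b) / value_b


def percent_of(count: float, total: float) -> float:
    """Plain percentage 100 * count / total."""
    if total <= 0:
        raise ValueError("total must be positive")
    return 100.0 * count / total


NUMERIC_FEATURES = (
    "cdna_len",
    "cds_len",
    "utr5_len",
    "utr5_gc",
    "utr5_gc_first10",
    "utr3_len",
    "utr3_gc",
    "dg_utr5",
    "dg_utr3",
)


@dataclass(frozen=True)
class ClassFeatureSummary:
    """Per-class medians, uAUG prevalence, KS p-values and asterisk flags."""

    medians: pd.DataFrame       # feature x class
    uaug_percent: pd.DataFrame  # "uAUG >= k" x class
    ks_p: pd.DataFrame          # feature x flanking class (vs reference)
    asterisk: pd.Series         # feature -> bool
    class_sizes: dict

    def to_frame(self) -> pd.DataFrame:
        med = self.medians.copy()
        med.insert(0, "row_type", "median")
        ua = self.uaug_percent.copy()
        ua.insert(0, "row_type", "percent")
        out = pd.concat([med, ua])
        out["asterisk"] = [
            bool(self.asterisk.get(f, False)) for f in out.index
        ]
        return out


def class_feature_summary(
    features: pd.DataFrame,
    labels: pd.Series,
    reference: str = "II",
    p_threshold: float = 0.001,
    max_uaug: int = 4,
) -> ClassFeatureSummary:
    """Summarize feature distributions across translational classes.

    Medians per class for every available numeric feature, percentage of
    genes with >= k uAUGs (k = 1..max_uaug), and KS tests of the flanking
    classes against the reference class.  A feature earns an asterisk when
    both flanking-class p-values fall below ``p_threshold`` and the class
    medians are strictly monotone across I -> II -> III.  Classes with fewer
    than 3 genes are summarized but not tested (with a warning).
    """
    common = features.index.intersection(labels.index)
    if len(common) < len(features):
        raise ValueError("class labels do not cover the feature table")
    labels = labels.loc[features.index]
    classes = ("I", "II", "III")
    feature_cols = [c for c in NUMERIC_FEATURES if c in features.columns]
    groups = {c: features[labels == c] for c in classes}
    sizes = {c: len(groups[c]) for c in classes}
    small = [c for c in classes if sizes[c] < 3]
    if small:
        warnings.warn(
            f"classes {small} have < 3 genes; KS tests skipped", stacklevel=2
        )

    medians = pd.DataFrame(
        {c: groups[c][feature_cols].median() for c in classes}
    )
    uaug_rows = {}
    for k in range(1, max_uaug + 1):
        uaug_rows[f"uAUG>={k}"] = {
            c: (
                percent_of((groups[c]["n_uaug"] >= k).sum(), sizes[c])
                if sizes[c] > 0
                else np.nan
            )
            for c in classes
        }
    uaug_percent = pd.DataFrame(uaug_rows).T[list(classes)]

    flanking = [c for c in classes if c != reference]
    ks_p = pd.DataFrame(index=feature_cols, columns=flanking, dtype=float)
    testable = sizes[reference] >= 3
    for feat in feature_cols:
        ref_vals = groups[reference][feat].dropna().to_numpy()
        for c in flanking:
            vals = groups[c][feat].dropna().to_numpy()
            if testable and vals.size >= 3 and ref_vals.size >= 3:
                ks_p.loc[feat, c] = ks_two_sample(vals, ref_vals).p_value

    asterisk = pd.Series(False, index=feature_cols)
    for feat in feature_cols:
        ps = ks_p.loc[feat].to_numpy(dtype=float)
        if np.any(np.isnan(ps)) or not np.all(ps < p_threshold):
            continue
        m = medians.loc[feat, list(classes)].to_numpy(dtype=float)
        if np.all(np.diff(m) > 0) or np.all(np.diff(m) < 0):
            asterisk[feat] = True

    return ClassFeatureSummary(
        medians=medians,
        uaug_percent=uaug_percent,
        ks_p=ks_p,
        asterisk=asterisk,
        class_sizes=sizes,
    )


def te_by_length_bins(
    te, bin_labels, reference: str = "mid"
) -> tuple[dict, dict]:
    """ECDF per cDNA-length bin and KS of each other bin against the reference.

    ``te`` is a Series of linear translation efficiencies at one condition,
    ``bin_labels`` the short/mid/long assignment from
    :func:`translatome.seqfeatures.assign_length_bins`.
    """
    te = pd.Series(te, dtype=float)
    bins = pd.Series(bin_labels).loc[te.index]
    occupied = [b for b in pd.unique(bins) if (bins == b).any()]
    if len(occupied) < 2:
        raise ValueError("need at least 2 nonempty length bins")
    if reference not in occupied:
        raise ValueError(f"reference bin {reference!r} is empty")
    ecdfs = {b: ecdf_curve(te[bins == b]) for b in occupied}
    ref_vals = te[bins == reference].to_numpy()
    ks = {
        b: ks_two_sample(te[bins == b].to_numpy(), ref_vals)
        for b in occupied
        if b != reference
    }
    return ecdfs, ks


def subset_cumulative_compare(
    values: pd.Series, subset_ids, universe_ids
) -> tuple[pd.DataFrame, pd.DataFrame, KSResult]:
    """Compare a gene subset's feature ECDF against the whole-universe ECDF.

    Returns (subset ECDF, universe ECDF, KS result) with the universe as
    reference.  The subset must be contained in the universe and have at
    least 3 genes.
    """
    subset = set(subset_ids)
    universe = set(universe_ids)
    if not subset <= universe:
        raise ValueError("subset is not contained in the universe")
    if len(subset) < 3:
        raise ValueError("subset must contain at least 3 genes")
    values = pd.Series(values, dtype=float)
    sub_vals = values.loc[sorted(subset)].dropna().to_numpy()
    uni_vals = values.loc[sorted(universe)].dropna().to_numpy()
    ks = ks_two_sample(sub_vals, uni_vals)
    return ecdf_curve(sub_vals), ecdf_curve(uni_vals), ks
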