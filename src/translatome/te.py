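"""Translation efficiency and translational-class partitioning.

Translation efficiency (TE) at one condition is the linear ratio of a gene's
polysome-bound abundance to its total abundance.  The relative TE under
stress is the fold change in polysome binding divided by the fold change in
total mRNA (algebraically, TE_stress / TE_control); it is the ranking
statistic for the class partition.

Genes are split into three classes around the arithmetic mean of the linear
relative-TE distribution: Class I (hypersensitive) at <= mean/fold, Class III
(resistant) at >= mean*fold, Class II (average) in between, with fold = 1.5
by default.  Boundary values belong to the flanking classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CLASS_LABELS = ("I", "II", "III")


def translation_efficiency(pb_mean, tot_mean):
    """Linear TE = 2**(PB - TOT) from log2 mean abundances."""
    pb = np.asarray(pb_mean, dtype=float)
    tot = np.asarray(tot_mean, dtype=float)
    out = 2.0 ** (pb - tot)
    return float(out) if out.ndim == 0 else out


def relative_te(delta_pb, delta_tot):
    """Relative TE = (linear fold change in PB) / (linear fold change in TOT)."""
    dpb = np.asarray(delta_pb, dtype=float)
    dtot = np.asarray(delta_tot, dtype=float)
    if np.any(dpb <= 0) or np.any(dtot <= 0):
        raise ValueError("fold changes must be positive linear ratios")
    out = dpb / dtot
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ClassPartition:
    """Result of the three-class split of the relative-TE distribution."""

    labels: pd.Series
    average_rel_te: float
    fold_threshold: float
    lower: float
    upper: float

    @property
    def sizes(self) -> dict:
        counts = self.labels.value_counts()
        return {c: int(counts.get(c, 0)) for c in CLASS_LABELS}

    def genes(self, label: str) -> set:
        return set(self.labels.index[self.labels == label])


def classify(
    rel_te, fold_threshold: float = 1.5, scale: str = "linear"
) -> ClassPartition:
    """Partition genes by relative TE around the distribution average.

    ``rel_te`` is a Series (or array) of positive linear relative TEs;
    genes with missing values are dropped before averaging.  ``scale``
    selects the averaging scale: "linear" (arithmetic mean of the linear
    values, the default) or "log" (geometric mean).  Class labels are scale
    invariant: rescaling every value by c > 0 leaves the partition unchanged.
    """
    if scale not in ("linear", "log"):
        raise ValueError("scale must be 'linear' or 'log'")
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must exceed 1")
    s = pd.Series(rel_te, dtype=float)
    s = s.dropna()
    if s.size < 3:
        raise ValueError("need at least 3 genes with relative TE values")
    if (s <= 0).any():
        raise ValueError("relative TE values must be positive")
    if scale == "linear":
        average = float(s.mean())
    else:
        average = float(np.exp(np.log(s).mean()))
    lower = average / fold_threshold
    upper = average * fold_threshold
    labels = pd.Series("II", index=s.index, dtype=object)
    labels[s <= lower] = "I"
    labels[s >= upper] = "III"
    return ClassPartition(
        labels=labels,
        average_rel_te=average,
        fold_threshold=float(fold_threshold),
        lower=lower,
        upper=upper,
    )


def translation_profile(matrix, pc_factors=None) -> pd.DataFrame:
    """Per-gene TE table from a PC-adjusted expression matrix.

    Computes te_control, te_stress, rel_te from the per-population,
    per-condition replicate means of an :class:`~translatome.diffexpr.ExpressionMatrix`.
    If ``pc_factors`` is given the matrix is PC-adjusted first.
    """
    from . import diffexpr

    if pc_factors is not None:
        matrix = diffexpr.pc_adjust(matrix, pc_factors)
    means = {
        (cond, pop): matrix.submatrix(cond, pop).mean(axis=1)
        for cond in ("control", "stress")
        for pop in ("TOT", "PB")
    }
    te_control = translation_efficiency(means[("control", "PB")], means[("control", "TOT")])
    te_stress = translation_efficiency(means[("stress", "PB")], means[("stress", "TOT")])
    out = pd.DataFrame(
        {
            "te_control": te_control,
            "te_stress": te_stress,
            "rel_te": np.asarray(te_stress) / np.asarray(te_control),
        },
        index=matrix.gene_ids,
    )
    return out
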