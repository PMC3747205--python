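"""PC-corrected normalization and per-gene differential statistics.

Expression data are gene x sample log2 intensities over a 2x2 design:
condition in {control, stress} crossed with RNA population in {TOT, PB}
(total versus polysome-bound), with >=2 replicates per cell.  Because equal
RNA amounts are hybridized per sample, the global reduction in polysome
loading under stress is invisible in the raw PB(stress) values; it is
restored by shifting each stress-PB replicate by log2 of its PC
normalization factor (see :mod:`translatome.polysome`).

Differential calls per population (stress vs control) use an empirical-Bayes
moderated t statistic: per-gene pooled variances are shrunk toward a prior
(d0, s0^2) fitted across all genes by moment matching of log s^2, the
moderated t is log2FC / (s_tilde * sqrt(1/n1 + 1/n2)) with d0 + d_g degrees
of freedom, p-values are BH-adjusted, and genes with >= fold-threshold
variation and FDR below threshold are called significant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

CONDITIONS = ("control", "stress")
POPULATIONS = ("TOT", "PB")


@dataclass
class ExpressionMatrix:
    """Gene x sample log2 expression with sample metadata.

    ``values`` is a DataFrame indexed by unique gene IDs with sample IDs as
    columns; ``samples`` is a DataFrame with columns sample_id, condition,
    population, replicate (1-based within each condition x population cell).
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        required = {"sample_id", "condition", "population", "replicate"}
        missing = required - set(self.samples.columns)
        if missing:
            raise ValueError(f"sample metadata missing columns: {sorted(missing)}")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene IDs in expression matrix")
        if set(self.values.columns) != set(self.samples["sample_id"]):
            raise ValueError("matrix columns and metadata sample_ids differ")
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError("expression values must be finite")
        bad_cond = set(self.samples["condition"]) - set(CONDITIONS)
        bad_pop = set(self.samples["population"]) - set(POPULATIONS)
        if bad_cond or bad_pop:
            raise ValueError(
                f"unknown condition/population labels: {bad_cond | bad_pop}"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    def sample_ids(self, condition: str, population: str) -> list[str]:
        m = self.samples
        sel = m[(m["condition"] == condition) & (m["population"] == population)]
        return list(sel.sort_values("replicate")["sample_id"])

    def submatrix(self, condition: str, population: str) -> pd.DataFrame:
        return self.values[self.sample_ids(condition, population)]


@dataclass(frozen=True)
class VariancePrior:
    """Empirical-Bayes variance prior: d0 degrees of freedom (may be inf), s0^2.

    d0 = 0 is the no-shrinkage limit (ordinary pooled-variance t); d0 = inf
    is complete shrinkage to s0^2.
    """

    d0: float
    s0_sq: float

    def __post_init__(self):
        if math.isnan(self.d0) or self.d0 < 0:
            raise ValueError("d0 must be non-negative or infinite")
        if not self.s0_sq > 0:
            raise ValueError("s0_sq must be positive")


def pc_adjust(matrix: ExpressionMatrix, factors) -> ExpressionMatrix:
    """Shift stress-PB samples by log2 of their per-replicate PC factor.

    ``factors`` is a sequence of positive ratios, one per stress-PB replicate
    in replicate order (or a mapping replicate index -> factor).  All other
    samples are untouched.  Applying the reciprocal factors afterwards
    restores the original matrix.
    """
    stress_pb = matrix.sample_ids("stress", "PB")
    meta = matrix.samples.set_index("sample_id")
    if isinstance(factors, dict):
        try:
            factors = [factors[int(meta.loc[s, "replicate"])] for s in stress_pb]
        except KeyError as e:
            raise ValueError(f"no PC factor for replicate {e}") from None
    factors = [float(f) for f in factors]
    if len(factors) != len(stress_pb):
        raise ValueError(
            f"{len(factors)} PC factors for {len(stress_pb)} stress-PB replicates"
        )
    if any(f <= 0 for f in factors):
        raise ValueError("PC factors must be positive")
    values = matrix.values.copy()
    for sample, f in zip(stress_pb, factors):
        values[sample] = values[sample] + math.log2(f)
    prov = dict(matrix.provenance)
    prov["pc_factors"] = dict(zip(stress_pb, factors))
    return ExpressionMatrix(values=values, samples=matrix.samples.copy(), provenance=prov)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration on 1/trigamma."""
    if y <= 0:
        raise ValueError("trigamma inverse requires y > 0")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-8 * x:
            break
    return float(x)


def fit_variance_prior(sample_variances, residual_df) -> VariancePrior:
    """Fit (d0, s0^2) by moment matching of log sample variances.

    Under the hierarchical model s_g^2 | sigma_g^2 ~ sigma_g^2 chi2_{d_g}/d_g
    with scaled-inverse-chi2 prior on sigma_g^2, the statistic
    e_g = log s_g^2 - digamma(d_g/2) + log(d_g/2) has mean
    log s0^2 + digamma(d0/2) - log(d0/2) and excess variance trigamma(d0/2)
    beyond the sampling term trigamma(d_g/2).  d0 is recovered by inverting
    the trigamma function (Newton, tolerance 1e-8); if the observed dispersion
    of log s^2 does not exceed its theoretical sampling minimum, d0 is
    infinite (complete shrinkage) and s0^2 = exp(mean(e_g)).
    """
    s2 = np.asarray(sample_variances, dtype=float)
    df = np.broadcast_to(np.asarray(residual_df, dtype=float), s2.shape)
    ok = np.isfinite(s2) & (s2 > 0) & (df >= 1)
    s2, df = s2[ok], df[ok]
    if s2.size < 10:
        raise ValueError(
            f"need >= 10 genes with positive variance and df >= 1, got {s2.size}"
        )
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1))
    excess = evar - float(np.mean(special.polygamma(1, df / 2.0)))
    if excess <= 0:
        return VariancePrior(d0=math.inf, s0_sq=float(math.exp(emean)))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = math.exp(emean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    return VariancePrior(d0=float(d0), s0_sq=float(s0_sq))


def moderated_t_test(
    matrix: ExpressionMatrix,
    population: str,
    prior: VariancePrior | None = None,
    fold_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Stress-vs-control moderated t test for one RNA population.

    Returns a per-gene DataFrame with columns log2fc, t, p, fdr, significant,
    direction.  ``prior`` overrides the fitted variance prior (d0=0 recovers
    the ordinary pooled-variance two-sample t; d0=inf gives complete
    shrinkage with a normal reference).
    """
    if population not in POPULATIONS:
        raise ValueError(f"population must be one of {POPULATIONS}")
    x_stress = matrix.submatrix("stress", population).to_numpy()
    x_control = matrix.submatrix("control", population).to_numpy()
    n1, n2 = x_stress.shape[1], x_control.shape[1]
    if min(n1, n2) < 2:
        raise ValueError("need >= 2 replicates per condition")

    log2fc = x_stress.mean(axis=1) - x_control.mean(axis=1)
    ss = x_stress.var(axis=1, ddof=1) * (n1 - 1) + x_control.var(axis=1, ddof=1) * (
        n2 - 1
    )
    d_g = n1 + n2 - 2
    s2 = ss / d_g
    if prior is None and np.all(s2 == 0):
        # noise-free limit (exact replicates): any nonzero change is certain
        t = np.where(log2fc == 0, 0.0, np.sign(log2fc) * np.inf)
        p = np.where(log2fc == 0, 1.0, 0.0)
        result = pd.DataFrame(
            {"log2fc": log2fc, "t": t, "p": p, "fdr": bh_adjust(p)},
            index=matrix.gene_ids,
        )
        result.attrs["prior"] = None
        result.attrs["population"] = population
        return call_significant(result, fold_threshold, fdr_threshold)
    if prior is None:
        prior = fit_variance_prior(s2, d_g)

    if prior.d0 == 0:
        s2_post = s2
        df_total = float(d_g)
    elif math.isinf(prior.d0):
        s2_post = np.full_like(s2, prior.s0_sq)
        df_total = math.inf
    else:
        s2_post = (prior.d0 * prior.s0_sq + d_g * s2) / (prior.d0 + d_g)
        df_total = prior.d0 + d_g

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = log2fc / se
    if not np.all(np.isfinite(t)):
        raise ValueError("zero posterior variance encountered (d0 = 0 with s_g = 0)")
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)

    result = pd.DataFrame(
        {"log2fc": log2fc, "t": t, "p": p, "fdr": bh_adjust(p)},
        index=matrix.gene_ids,
    )
    result.attrs["prior"] = prior
    result.attrs["population"] = population
    return call_significant(result, fold_threshold, fdr_threshold)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_significant(
    result: pd.DataFrame, fold_threshold: float = 2.0, fdr_threshold: float = 0.05
) -> pd.DataFrame:
    """Flag genes with |log2FC| >= log2(fold) and FDR strictly below threshold."""
    if fold_threshold <= 0 or fdr_threshold <= 0:
        raise ValueError("thresholds must be positive")
    out = result.copy()
    lfc_cut = math.log2(fold_threshold)
    sig = (np.abs(out["log2fc"]) >= lfc_cut) & (out["fdr"] < fdr_threshold)
    out["significant"] = sig
    direction = np.where(out["log2fc"] > 0, "up", "down")
    out["direction"] = np.where(sig, direction, "none")
    out.attrs.update(result.attrs)
    out.attrs["fold_threshold"] = fold_threshold
    out.attrs["fdr_threshold"] = fdr_threshold
    return out


@dataclass(frozen=True)
class RegulationPartition:
    """Venn partition of significant gene sets from the TOT and PB contrasts."""

    both: frozenset
    only_tot: frozenset
    only_pb: frozenset

    @property
    def counts(self) -> dict:
        return {
            "both": len(self.both),
            "only_TOT": len(self.only_tot),
            "only_PB": len(self.only_pb),
        }


def venn_partition(sig_tot, sig_pb) -> RegulationPartition:
    """Split significant genes into both / TOT-only / PB-only sets."""
    sig_tot, sig_pb = set(sig_tot), set(sig_pb)
    both = sig_tot & sig_pb
    return RegulationPartition(
        both=frozenset(both),
        only_tot=frozenset(sig_tot - both),
        only_pb=frozenset(sig_pb - both),
    )


def significant_sets(result: pd.DataFrame) -> dict:
    """Up- and down-regulated significant gene ID sets from a contrast result."""
    sig = result[result["significant"]]
    return {
        "up": set(sig.index[sig["direction"] == "up"]),
        "down": set(sig.index[sig["direction"] == "down"]),
    }
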