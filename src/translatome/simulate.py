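"""Synthetic translatome experiments with planted ground truth.

The generator emulates a two-condition (control / heat stress) x two RNA
population (total / polysome-bound) microarray-style experiment on a gene
universe with three planted translational classes:

* Class II ("average") genes follow the global polysome-loading reduction:
  their linear relative translation efficiency centres on the configured
  global loading factor (default 0.564, i.e. stress roughly halves polysome
  association).
* Class I ("sensitive") and Class III ("resistant") genes multiply that
  factor by 1/2.5 and 2.5 respectively, placing them well beyond the 1.5-fold
  classification window.

Per-class mRNA feature distributions (cDNA length log-normal with class
medians 1204/1641/2323 nt; 5'UTR G+C Beta with class means 42.33/37.61/36.07%)
couple sequence features to the classes generatively — features are drawn per
class, with no causal claim.

Crucially, the simulated polysome-bound stress samples are sum-rescaled so
each replicate carries the same total library signal as its control
counterpart: the global loading reduction is invisible in the raw matrix and
can only be restored through the polysome-content (PC) correction path.  The
planted per-replicate PC values (and gradient profiles reproducing them
exactly) are emitted alongside the matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .diffexpr import ExpressionMatrix
from .polysome import PolysomeProfile
from .seqfeatures import GeneModel, GeneModelSet, build_feature_table

CLASSES = ("I", "II", "III")

# class proportions mirroring 696 / 14946 / 456 of a 16098-gene universe
DEFAULT_PROPORTIONS = (696 / 16098, 14946 / 16098, 456 / 16098)


@dataclass(frozen=True)
class FeatureParams:
    """Per-class feature distributions (order: Class I, II, III)."""

    cdna_median: tuple = (1204, 1641, 2323)
    cdna_log_sd: float = 0.45
    utr5_len_median: tuple = (121, 139, 126)
    utr5_log_sd: float = 0.6
    utr3_len_median: tuple = (226, 223, 216)
    utr3_log_sd: float = 0.5
    utr5_gc_mean: tuple = (42.33, 37.61, 36.07)
    utr3_gc_mean: tuple = (32.29, 31.64, 31.02)
    gc_concentration: float = 40.0
    # Poisson rates matching uAUG >= 1 prevalences of ~24.6 / 32.2 / 30.9 %
    uaug_lambda: tuple = (0.282, 0.388, 0.370)
    min_cds_len: int = 75


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic experiment."""

    n_genes: int = 20000
    seed: int = 0
    n_replicates: int = 2
    class_proportions: tuple = DEFAULT_PROPORTIONS
    global_loading_factor: float = 0.564
    class_multipliers: tuple = (1 / 2.5, 2.5)  # (sensitive, resistant)
    replicate_noise_sd: float = 0.15
    transcriptional_effect_sd: float = 0.8
    te_scatter_sd: float = 0.0
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    baseline_te_sd: float = 0.4
    pc_control: float = 20.0
    feature_params: FeatureParams = field(default_factory=FeatureParams)

    def __post_init__(self):
        if self.n_genes < 10:
            raise ValueError("n_genes must be at least 10")
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if any(p < 0 for p in self.class_proportions):
            raise ValueError("class proportions must be non-negative")
        if any(m <= 0 for m in self.class_multipliers):
            raise ValueError("class multipliers must be positive")
        if self.global_loading_factor <= 0:
            raise ValueError("global loading factor must be positive")
        if self.n_replicates < 2:
            raise ValueError(
                "need >= 2 replicates per condition x population "
                "(moderated t undefined otherwise)"
            )
        if not 0 < self.pc_control < 100:
            raise ValueError("pc_control must lie in (0, 100)")

    def rng(self, stream: int) -> np.random.Generator:
        """Named substream of the config seed."""
        return np.random.default_rng([self.seed, stream])


@dataclass(frozen=True)
class GroundTruth:
    """Planted per-gene truth: class label, linear rel TE, total-mRNA change."""

    table: pd.DataFrame  # columns: class_label, rel_te, log2_total_change

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    def class_genes(self, label: str) -> set:
        return set(self.table.index[self.table["class_label"] == label])


def _class_multiplier(config: SimulationConfig) -> dict:
    sens, resist = config.class_multipliers
    return {"I": sens, "II": 1.0, "III": resist}


def simulate_gene_universe(config: SimulationConfig):
    """Draw the gene universe: features and planted truth per gene.

    Returns ``(features, truth)`` where ``features`` is a per-gene DataFrame
    with the numeric feature roster (lengths, G+C percentages, uAUG count)
    drawn from the per-class distributions, and ``truth`` records class
    labels, planted linear relative TEs and planted log2 total-mRNA changes.
    Same seed, same output.
    """
    n = config.n_genes
    fp = config.feature_params
    rng = config.rng(1)
    gene_ids = pd.Index([f"G{i:06d}" for i in range(1, n + 1)], name="gene_id")
    labels = rng.choice(CLASSES, size=n, p=np.asarray(config.class_proportions))
    idx = np.searchsorted(np.array(CLASSES), labels)  # CLASSES sorted: I, II, III

    def lognorm_len(medians, log_sd, minimum):
        med = np.asarray(medians, dtype=float)[idx]
        draw = med * np.exp(log_sd * rng.standard_normal(n))
        return np.maximum(np.round(draw).astype(int), minimum)

    utr5_len = lognorm_len(fp.utr5_len_median, fp.utr5_log_sd, 3)
    utr3_len = lognorm_len(fp.utr3_len_median, fp.utr3_log_sd, 3)
    cdna_target = lognorm_len(fp.cdna_median, fp.cdna_log_sd, 200)
    # frame divisibility is not forced (annotation medians need not be codon
    # multiples); downstream feature extraction flags out-of-frame CDSs
    cds_len = np.maximum(cdna_target - utr5_len - utr3_len, fp.min_cds_len)
    cdna_len = utr5_len + cds_len + utr3_len

    def beta_pct(means):
        m = np.asarray(means, dtype=float)[idx] / 100.0
        if not math.isfinite(fp.gc_concentration):
            return 100.0 * m
        a, b = m * fp.gc_concentration, (1.0 - m) * fp.gc_concentration
        return 100.0 * rng.beta(a, b)

    utr5_gc = beta_pct(fp.utr5_gc_mean)
    utr3_gc = beta_pct(fp.utr3_gc_mean)
    lam = np.asarray(fp.uaug_lambda, dtype=float)[idx]
    n_uaug = np.minimum(rng.poisson(lam), np.maximum((utr5_len - 2) // 3, 0))

    features = pd.DataFrame(
        {
            "cdna_len": cdna_len,
            "cds_len": cds_len,
            "utr5_len": utr5_len,
            "utr3_len": utr3_len,
            "utr5_gc": utr5_gc,
            "utr5_gc_first10": utr5_gc,  # refined when sequences are realized
            "utr3_gc": utr3_gc,
            "n_uaug": n_uaug,
        },
        index=gene_ids,
    )

    mult = np.vectorize(_class_multiplier(config).get)(labels).astype(float)
    rel_te = config.global_loading_factor * mult
    if config.te_scatter_sd > 0:
        rel_te = rel_te * 2.0 ** (config.te_scatter_sd * rng.standard_normal(n))
    log2_total_change = config.transcriptional_effect_sd * rng.standard_normal(n)
    truth = GroundTruth(
        table=pd.DataFrame(
            {
                "class_label": labels,
                "rel_te": rel_te,
                "log2_total_change": log2_total_change,
            },
            index=gene_ids,
        )
    )
    return features, truth


@dataclass(frozen=True)
class SimulatedExperiment:
    """Expression matrix plus the planted per-replicate polysome contents."""

    matrix: ExpressionMatrix
    pc_control: np.ndarray  # per replicate, percent
    pc_stress: np.ndarray   # per replicate, percent
    factors: np.ndarray     # pc_stress / pc_control, the planted PC factors


def simulate_expression(truth: GroundTruth, config: SimulationConfig) -> SimulatedExperiment:
    """Generate the log2 expression matrix for all condition x population cells.

    The polysome-bound stress replicates are built from the planted relative
    TEs and then sum-rescaled (linear scale) so each carries the same total
    signal as its paired control PB replicate, erasing the global loading
    reduction from the matrix; the erased per-replicate linear factor is
    returned as the planted PC ratio so that PC adjustment restores it
    exactly.  Gaussian noise of sd ``replicate_noise_sd`` (log2 scale) is
    added independently per cell.
    """
    if len(truth.table) == 0:
        raise ValueError("empty ground truth")
    rng = config.rng(2)
    genes = truth.gene_ids
    n = len(genes)
    reps = config.n_replicates
    base = config.baseline_mean + config.baseline_sd * rng.standard_normal(n)
    lte0 = config.baseline_te_sd * rng.standard_normal(n)
    dtot = truth.table["log2_total_change"].to_numpy()
    lrel = np.log2(truth.table["rel_te"].to_numpy())

    def noise():
        if config.replicate_noise_sd == 0:
            return np.zeros(n)
        return config.replicate_noise_sd * rng.standard_normal(n)

    columns, meta_rows = {}, []
    factors = np.empty(reps)
    for r in range(1, reps + 1):
        tot22 = base + noise()
        tot38 = base + dtot + noise()
        pb22 = base + lte0 + noise()
        pb38_true = base + dtot + lte0 + lrel + noise()
        c_r = float(np.sum(2.0 ** pb38_true) / np.sum(2.0 ** pb22))
        pb38 = pb38_true - math.log2(c_r)
        factors[r - 1] = c_r
        for pop, cond, vals in (
            ("TOT", "control", tot22),
            ("TOT", "stress", tot38),
            ("PB", "control", pb22),
            ("PB", "stress", pb38),
        ):
            sid = f"{pop}_{cond}_{r}"
            columns[sid] = vals
            meta_rows.append(
                {"sample_id": sid, "condition": cond, "population": pop, "replicate": r}
            )
    matrix = ExpressionMatrix(
        values=pd.DataFrame(columns, index=genes),
        samples=pd.DataFrame(meta_rows),
        provenance={"simulated": True, "seed": config.seed},
    )
    pc_stress = config.pc_control * factors
    if np.any(pc_stress >= 100):
        raise ValueError("planted stress PC reached 100%; lower pc_control")
    return SimulatedExperiment(
        matrix=matrix,
        pc_control=np.full(reps, config.pc_control),
        pc_stress=pc_stress,
        factors=factors,
    )


def simulate_polysome_profile(
    pc_target: float,
    n_fractions: int = 16,
    seed: int = 0,
    uniform: bool = False,
    baseline: float = 0.0,
    sample_id: str = "",
    condition: str = "",
) -> PolysomeProfile:
    """Construct a gradient profile whose computed PC equals ``pc_target``.

    The non-polysomal block (all fractions outside the polysomal set, which
    defaults to the last six fractions) and the polysomal block are scaled so
    their net signals sum to ``100 - pc_target`` and ``pc_target``
    respectively; a constant ``baseline`` is then added, which constant-min
    baseline subtraction removes exactly.  With ``uniform`` the net shape is
    flat instead of randomly drawn (at pc_target = 37.5 with 16 fractions the
    whole net profile is uniform).
    """
    if not 0 < pc_target < 100:
        raise ValueError("pc_target must lie strictly between 0 and 100")
    if n_fractions < 12:
        raise ValueError("need at least 12 fractions")
    if baseline < 0:
        raise ValueError("baseline must be non-negative")
    p_fractions = frozenset(range(n_fractions - 5, n_fractions + 1))
    np_fractions = frozenset(range(1, 9))
    p_mask = np.zeros(n_fractions, dtype=bool)
    p_mask[[i - 1 for i in p_fractions]] = True

    if uniform:
        shape = np.ones(n_fractions)
    else:
        rng = np.random.default_rng([seed, 3])
        # monosome peak near the top, decaying tail, light polysome bump
        pos = np.arange(n_fractions)
        envelope = 1.0 + 4.0 * np.exp(-0.5 * ((pos - 3) / 1.5) ** 2) + 0.8 * p_mask
        shape = envelope * rng.gamma(4.0, 0.25, size=n_fractions)
        shape = shape - shape.min()
        if shape[p_mask].sum() <= 0 or shape[~p_mask].sum() <= 0:
            shape = shape + 0.01
            shape[int(np.argmin(shape))] = 0.0
    net = shape.astype(float).copy()
    net[p_mask] *= pc_target / net[p_mask].sum()
    net[~p_mask] *= (100.0 - pc_target) / net[~p_mask].sum()
    return PolysomeProfile(
        signal=net + baseline,
        np_fractions=np_fractions,
        p_fractions=p_fractions,
        sample_id=sample_id,
        condition=condition,
        baseline_subtracted=(baseline == 0.0),
        baseline_mode="constant-min" if baseline == 0.0 else None,
    )


# --- sequence realization -------------------------------------------------

_BASES = np.array(list("ACGT"))


def _draw_seq(rng, length: int, gc: float) -> np.ndarray:
    g = gc / 100.0
    probs = [(1 - g) / 2, g / 2, g / 2, (1 - g) / 2]
    return rng.choice(_BASES, size=length, p=probs)


def _scrub_atg(seq: np.ndarray) -> None:
    """Replace the A of every ATG with T (G+C preserved), in place."""
    i = 0
    while i <= len(seq) - 3:
        if seq[i] == "A" and seq[i + 1] == "T" and seq[i + 2] == "G":
            seq[i] = "T"
        i += 1


def _plant_atgs(rng, seq: np.ndarray, count: int) -> None:
    if count == 0:
        return
    candidates = rng.permutation(len(seq) - 2)
    taken: list[int] = []
    for pos in candidates:
        if all(abs(pos - t) >= 3 for t in taken):
            taken.append(int(pos))
            if len(taken) == count:
                break
    for pos in taken:
        seq[pos : pos + 3] = ["A", "T", "G"]


def realize_sequences(features: pd.DataFrame, seed: int = 0):
    """Generate nucleotide sequences matching the planted numeric features.

    5'UTRs are i.i.d. draws at the planted G+C fraction, scrubbed of
    accidental AUGs and re-seeded with exactly ``n_uaug`` planted AUGs; CDSs
    start with ATG and end with TAA; 3'UTRs are i.i.d. at the planted G+C.
    Returns ``(models, realized_features)`` where the realized table is
    recomputed from the final sequences (so G+C percentages reflect the
    sequences actually emitted).
    """
    rng = np.random.default_rng([seed, 4])
    models = []
    for gene_id, row in features.iterrows():
        utr5 = _draw_seq(rng, int(row["utr5_len"]), float(row["utr5_gc"]))
        _scrub_atg(utr5)
        _plant_atgs(rng, utr5, int(row["n_uaug"]))
        cds = _draw_seq(rng, int(row["cds_len"]), 44.0)
        cds[:3] = ["A", "T", "G"]
        cds[-3:] = ["T", "A", "A"]
        utr3 = _draw_seq(rng, int(row["utr3_len"]), float(row["utr3_gc"]))
        models.append(
            GeneModel(
                gene_id=str(gene_id),
                utr5="".join(utr5),
                cds="".join(cds),
                utr3="".join(utr3),
            )
        )
    model_set = GeneModelSet(models=tuple(models), dropped_genes=())
    return model_set, build_feature_table(model_set)


def simulate_term_annotation(
    truth: GroundTruth,
    seed: int = 0,
    n_random_terms: int = 10,
    coupled_rate: float = 0.5,
    background_rate: float = 0.005,
):
    """Synthetic annotation terms coupled to the planted classes.

    Emulates functional categories that co-segregate with translational
    behaviour: ``TERM:sensitive`` samples Class I genes (plus background),
    ``TERM:resistant`` samples Class III genes, and ``n_random_terms``
    uncoupled terms sample the universe uniformly.  Returned as
    :class:`~translatome.enrichment.TermAnnotation` objects.
    """
    from .enrichment import TermAnnotation

    rng = np.random.default_rng([seed, 5])
    genes = truth.gene_ids.to_numpy()
    labels = truth.table["class_label"].to_numpy()
    terms = []
    for term_id, label in (("TERM:sensitive", "I"), ("TERM:resistant", "III")):
        in_class = genes[labels == label]
        members = set(in_class[rng.random(in_class.size) < coupled_rate])
        members |= set(genes[rng.random(genes.size) < background_rate])
        if members:
            terms.append(TermAnnotation(term_id=term_id, gene_ids=frozenset(members)))
    for k in range(n_random_terms):
        size = int(rng.integers(30, 200))
        members = rng.choice(genes, size=min(size, genes.size), replace=False)
        terms.append(
            TermAnnotation(term_id=f"TERM:random{k:02d}", gene_ids=frozenset(members))
        )
    return terms


def balanced_accuracy(true_labels: pd.Series, predicted_labels: pd.Series) -> float:
    """Mean per-class recall of predicted class labels against planted ones."""
    true_labels = pd.Series(true_labels)
    predicted_labels = pd.Series(predicted_labels).loc[true_labels.index]
    recalls = []
    for label in pd.unique(true_labels):
        mask = true_labels == label
        recalls.append(float((predicted_labels[mask] == label).mean()))
    return float(np.mean(recalls))
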