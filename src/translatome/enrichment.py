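"""Gene-set enrichment: singular over-representation and ranked segmentation.

Singular mode tests one gene class against the analysis universe with an
upper-tail hypergeometric test per annotation term, BH-adjusted across
terms.

Ranked mode scans the gene list ordered by decreasing relative translation
efficiency: at each of a series of equal-count quantile cuts, term
membership above versus below the cut is tested with one-sided
hypergeometric tails in both directions (enrichment at the top or at the
bottom of the list), and the smaller tail is kept with its direction.  BH
adjustment is applied jointly across all term x cut tests; per term the best
adjusted p, its cut and its direction are reported.  When a term occupies
exactly a rank prefix and a cut isolates it, the ranked-mode p at that cut
equals the singular-mode p for the same set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust


@dataclass(frozen=True)
class TermAnnotation:
    """One annotation term (e.g. a GO biological process) and its gene set."""

    term_id: str
    gene_ids: frozenset
    term_name: str = ""

    def __post_init__(self):
        if not self.gene_ids:
            raise ValueError(f"term {self.term_id} has an empty gene set")
        object.__setattr__(self, "gene_ids", frozenset(self.gene_ids))


def read_term_table(path) -> list[TermAnnotation]:
    """Read term annotations from a two-column TSV (term_id, gene_id) or GAF.

    GAF lines (17 tab-separated fields, '!' comments) contribute
    (GO ID, DB object ID) pairs; two-column TSVs may carry an optional
    header line starting with 'term'.
    """
    pairs = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            fields = line.split("\t")
            if len(fields) >= 15:  # GAF
                pairs.append((fields[4], fields[1]))
            elif len(fields) >= 2:
                if fields[0].lower().startswith("term"):
                    continue
                pairs.append((fields[0], fields[1]))
    grouped: dict[str, set] = {}
    for term, gene in pairs:
        grouped.setdefault(term, set()).add(gene)
    return [TermAnnotation(term_id=t, gene_ids=g) for t, g in sorted(grouped.items())]


def _hypergeom_upper(overlap: int, universe: int, term: int, sample: int) -> float:
    """P(X >= overlap) for X ~ Hypergeom(universe, term, sample)."""
    return float(stats.hypergeom.sf(overlap - 1, universe, term, sample))


def singular_enrichment(class_genes, universe, terms) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of a class per term.

    Terms are intersected with the universe before testing; BH adjustment
    runs across all tested terms.  Returns a DataFrame indexed by term_id
    with columns overlap, term_size, p, adjusted_p.
    """
    class_genes = set(class_genes)
    universe = set(universe)
    if not class_genes <= universe:
        raise ValueError("class genes must be contained in the universe")
    terms = list(terms)
    if not terms:
        raise ValueError("no annotation terms supplied")
    rows = []
    for term in terms:
        members = term.gene_ids & universe
        overlap = len(members & class_genes)
        p = _hypergeom_upper(overlap, len(universe), len(members), len(class_genes))
        rows.append(
            {
                "term_id": term.term_id,
                "overlap": overlap,
                "term_size": len(members),
                "p": p,
            }
        )
    out = pd.DataFrame(rows).set_index("term_id")
    out["adjusted_p"] = bh_adjust(out["p"].to_numpy())
    out["mode"] = "singular"
    return out


def ranked_segmentation_enrichment(
    ranked_genes, terms, n_partitions: int = 30
) -> pd.DataFrame:
    """Scan a ranked gene list for terms enriched at the top or bottom.

    ``ranked_genes`` is the full universe ordered by decreasing relative
    translation efficiency.  Cuts are placed at the n_partitions - 1 internal
    equal-count quantile boundaries; at each cut the term overlap above the
    cut is tested with one-sided hypergeometric tails for both enrichment
    above ("top") and below ("bottom"), keeping the smaller tail.  BH runs
    jointly over all term x cut tests.  Returns per term the best adjusted p
    with its cut position (number of genes above the cut) and direction.
    """
    ranked = list(ranked_genes)
    if len(set(ranked)) != len(ranked):
        raise ValueError("ranking contains duplicate genes")
    if n_partitions < 2:
        raise ValueError("need at least 2 partitions")
    terms = list(terms)
    if not terms:
        raise ValueError("no annotation terms supplied")
    n = len(ranked)
    universe = set(ranked)
    rank_of = {g: i for i, g in enumerate(ranked)}
    cuts = sorted(
        {round(i * n / n_partitions) for i in range(1, n_partitions)} - {0, n}
    )
    if not cuts:
        raise ValueError("universe too small for the requested partitions")

    rows = []
    for term in terms:
        members = term.gene_ids & universe
        k = len(members)
        ranks = np.sort([rank_of[g] for g in members])
        for cut in cuts:
            above = int(np.searchsorted(ranks, cut))
            p_top = _hypergeom_upper(above, n, k, cut)
            p_bottom = _hypergeom_upper(k - above, n, k, n - cut)
            if p_top <= p_bottom:
                p, direction = p_top, "top"
            else:
                p, direction = p_bottom, "bottom"
            rows.append(
                {
                    "term_id": term.term_id,
                    "cut": cut,
                    "p": p,
                    "direction": direction,
                    "overlap_above": above,
                    "term_size": k,
                }
            )
    all_tests = pd.DataFrame(rows)
    all_tests["adjusted_p"] = bh_adjust(all_tests["p"].to_numpy())
    best = (
        all_tests.sort_values(["adjusted_p", "p", "cut"], kind="stable")
        .groupby("term_id", sort=True)
        .first()
    )
    best = best.rename(columns={"cut": "best_partition"})
    best["mode"] = "ranked"
    return best[
        ["mode", "best_partition", "direction", "overlap_above", "term_size", "p", "adjusted_p"]
    ]
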