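"""Gene-model parsing and per-gene mRNA sequence features.

Each gene is represented by one gene model split into 5'UTR, CDS and 3'UTR
sequences in mRNA (5'->3') orientation; the cDNA is their concatenation.
The feature set per gene covers region lengths, G+C percentages of the
5'UTR (full and first 10 nt) and 3'UTR, the number of upstream AUGs in the
5'UTR, and optional externally computed folding energies (kcal/mol) for the
UTRs.  Genes missing any region are dropped and counted, so downstream
analyses run on a complete-information universe.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

VALID_BASES = set("ACGTN")
REGION_SUFFIXES = {"5utr": "utr5", "cds": "cds", "3utr": "utr3"}
_GFF_REGION_TYPES = {
    "five_prime_UTR": "utr5",
    "CDS": "cds",
    "three_prime_UTR": "utr3",
}


def _check_alphabet(seq: str, gene_id: str, region: str) -> str:
    seq = seq.upper()
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(
            f"{gene_id} {region}: unsupported characters {sorted(bad)}; "
            "only A, C, G, T, N are accepted"
        )
    return seq


@dataclass(frozen=True)
class GeneModel:
    """One representative gene model, regions in mRNA orientation."""

    gene_id: str
    utr5: str
    cds: str
    utr3: str

    def __post_init__(self):
        for region in ("utr5", "cds", "utr3"):
            object.__setattr__(
                self, region, _check_alphabet(getattr(self, region), self.gene_id, region)
            )

    @property
    def cdna(self) -> str:
        return self.utr5 + self.cds + self.utr3

    @property
    def cds_frame_ok(self) -> bool:
        return len(self.cds) % 3 == 0


@dataclass(frozen=True)
class GeneModelSet:
    models: tuple
    dropped_genes: tuple

    def __iter__(self):
        return iter(self.models)

    def __len__(self):
        return len(self.models)


def load_gene_models(fasta_path, gff3_path) -> GeneModelSet:
    """Extract one gene model per gene from a genome FASTA and a GFF3.

    GFF3 coordinates are 1-based inclusive; region segments are concatenated
    in genomic order and reverse-complemented for minus-strand genes so that
    returned sequences read 5'->3' in mRNA orientation.  Exactly one mRNA per
    gene is required (representative models); genes missing a 5'UTR, CDS or
    3'UTR are dropped and reported in ``dropped_genes``.
    """
    import gffutils

    genome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="error",
    )
    models, dropped = [], []
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if len(mrnas) > 1:
            raise ValueError(
                f"gene {gene.id} has {len(mrnas)} mRNAs; one representative "
                "model per gene is required"
            )
        parent = mrnas[0] if mrnas else gene
        regions = {}
        for ftype, key in _GFF_REGION_TYPES.items():
            segs = sorted(db.children(parent, featuretype=ftype), key=lambda f: f.start)
            if not segs:
                continue
            seq = "".join(
                genome[s.seqid][s.start - 1 : s.end] for s in segs
            )
            if gene.strand == "-":
                seq = str(Seq(seq).reverse_complement())
            regions[key] = seq
        if set(regions) != {"utr5", "cds", "utr3"}:
            dropped.append(gene.id)
            continue
        models.append(GeneModel(gene_id=gene.id, **regions))
    ids = [m.gene_id for m in models]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene IDs among gene models")
    return GeneModelSet(models=tuple(models), dropped_genes=tuple(dropped))


def load_region_fastas(paths) -> GeneModelSet:
    """Build gene models from per-region FASTA records named GENEID.5utr etc.

    ``paths`` is one or more FASTA files (or a directory of .fa/.fasta files)
    whose record IDs end in .5utr, .cds or .3utr.  Genes missing any of the
    three regions are dropped and reported.
    """
    if isinstance(paths, (str, Path)):
        p = Path(paths)
        paths = sorted(p.glob("*.fa*")) if p.is_dir() else [p]
    regions: dict[str, dict[str, str]] = {}
    for path in paths:
        for rec in SeqIO.parse(str(path), "fasta"):
            m = re.match(r"^(?P<gene>.+)\.(?P<suffix>5utr|cds|3utr)$", rec.id)
            if not m:
                raise ValueError(
                    f"record {rec.id!r} lacks a .5utr/.cds/.3utr suffix"
                )
            slot = regions.setdefault(m["gene"], {})
            key = REGION_SUFFIXES[m["suffix"]]
            if key in slot:
                raise ValueError(f"duplicate {m['suffix']} record for gene {m['gene']}")
            slot[key] = str(rec.seq)
    models, dropped = [], []
    for gene_id in regions:
        slot = regions[gene_id]
        if set(slot) != {"utr5", "cds", "utr3"}:
            dropped.append(gene_id)
            continue
        models.append(GeneModel(gene_id=gene_id, **slot))
    return GeneModelSet(models=tuple(models), dropped_genes=tuple(dropped))


def gc_content(seq: str) -> float:
    """Percent G+C among unambiguous bases (N excluded from both counts)."""
    if not seq:
        raise ValueError("empty sequence")
    seq = _check_alphabet(seq, "<seq>", "")
    counted = len(seq) - seq.count("N")
    if counted == 0:
        raise ValueError("sequence contains only N bases")
    return 100.0 * (seq.count("G") + seq.count("C")) / counted


def gc_first10(utr5: str) -> float:
    """G+C percent of the first 10 nt of the 5'UTR (full UTR if shorter)."""
    if not utr5:
        raise ValueError("empty 5'UTR")
    return gc_content(utr5[:10])


def count_uaugs(utr5: str) -> int:
    """Number of AUG triplets anywhere in the 5'UTR (all frames, overlapping)."""
    if not utr5:
        return 0
    seq = _check_alphabet(utr5, "<seq>", "utr5")
    return sum(1 for i in range(len(seq) - 2) if seq[i : i + 3] == "ATG")


def build_feature_table(models, dg_table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-gene feature records: lengths, G+C metrics, uAUG count, optional dG.

    ``dg_table`` is a DataFrame indexed by gene_id (or with a gene_id column)
    with columns dg_utr5, dg_utr3 in kcal/mol; its gene IDs must be a subset
    of the models.  Without it the dG columns are absent and downstream
    dG comparisons are skipped.
    """
    models = list(models)
    if not models:
        raise ValueError("empty gene-model set")
    rows = []
    for m in models:
        rows.append(
            {
                "gene_id": m.gene_id,
                "cdna_len": len(m.cdna),
                "cds_len": len(m.cds),
                "utr5_len": len(m.utr5),
                "utr3_len": len(m.utr3),
                "utr5_gc": gc_content(m.utr5),
                "utr5_gc_first10": gc_first10(m.utr5),
                "utr3_gc": gc_content(m.utr3),
                "n_uaug": count_uaugs(m.utr5),
                "utr5_short": len(m.utr5) < 10,
                "cds_frame_ok": m.cds_frame_ok,
            }
        )
    table = pd.DataFrame(rows).set_index("gene_id")
    if table.index.duplicated().any():
        raise ValueError("duplicate gene IDs among gene models")
    if dg_table is not None:
        dg = dg_table.set_index("gene_id") if "gene_id" in dg_table.columns else dg_table
        extra = set(dg.index) - set(table.index)
        if extra:
            raise ValueError(
                f"dG table contains {len(extra)} gene IDs absent from the models"
            )
        table = table.join(dg[["dg_utr5", "dg_utr3"]])
    return table


LENGTH_BINS = ("short", "mid", "long")


def assign_length_bins(cdna_len) -> pd.Series:
    """cDNA length bins: [1,1000) short, [1000,2000] mid, (2000,inf) long."""
    lengths = pd.Series(cdna_len, dtype=float)
    if (lengths <= 0).any():
        raise ValueError("cDNA lengths must be positive")
    labels = pd.Series("mid", index=lengths.index, dtype=object)
    labels[lengths < 1000] = "short"
    labels[lengths > 2000] = "long"
    return labels
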