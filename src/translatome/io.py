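"""Readers and writers for the flat-file formats used across the pipeline.

All tabular formats are TSV: expression matrices (genes x samples with a
sidecar sample-metadata table), fraction-level gradient tables, Ct tables,
polysome-content tables, per-gene feature and ground-truth tables, and
contrast results.  Sequences travel as per-region FASTA records named
``GENEID.5utr`` / ``GENEID.cds`` / ``GENEID.3utr`` or as a genome FASTA plus
GFF3 (1-based inclusive coordinates).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .diffexpr import ExpressionMatrix
from .polysome import DEFAULT_NP_FRACTIONS, DEFAULT_P_FRACTIONS, PolysomeProfile

FLOAT_FORMAT = "%.10g"


def write_expression(matrix: ExpressionMatrix, expression_path, samples_path) -> None:
    matrix.values.rename_axis("gene_id").to_csv(
        expression_path, sep="\t", float_format=FLOAT_FORMAT
    )
    matrix.samples.to_csv(samples_path, sep="\t", index=False)


def read_expression(expression_path, samples_path) -> ExpressionMatrix:
    values = pd.read_csv(expression_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t")
    return ExpressionMatrix(values=values, samples=samples)


def write_fraction_table(profiles, path) -> None:
    """Write one or more profiles as a TSV with columns fraction, signal, sample_id."""
    if isinstance(profiles, PolysomeProfile):
        profiles = [profiles]
    rows = []
    for prof in profiles:
        for i, s in enumerate(prof.signal, start=1):
            rows.append(
                {
                    "fraction": i,
                    "signal": s,
                    "sample_id": prof.sample_id,
                    "condition": prof.condition,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_fraction_table(
    path,
    np_fractions=DEFAULT_NP_FRACTIONS,
    p_fractions=DEFAULT_P_FRACTIONS,
) -> list[PolysomeProfile]:
    """Read profiles from a fraction TSV, one per sample_id (in file order)."""
    table = pd.read_csv(path, sep="\t")
    if "sample_id" not in table.columns:
        table["sample_id"] = ""
    if "condition" not in table.columns:
        table["condition"] = ""
    profiles = []
    for sid in pd.unique(table["sample_id"]):
        sub = table[table["sample_id"] == sid].sort_values("fraction")
        expected = np.arange(1, len(sub) + 1)
        if not np.array_equal(sub["fraction"].to_numpy(), expected):
            raise ValueError(f"sample {sid!r}: fractions must be contiguous from 1")
        profiles.append(
            PolysomeProfile(
                signal=sub["signal"].to_numpy(dtype=float),
                np_fractions=np_fractions,
                p_fractions=p_fractions,
                sample_id=str(sid),
                condition=str(sub["condition"].iloc[0]),
            )
        )
    return profiles


def read_ct_table(path) -> pd.DataFrame:
    """Ct table with columns gene, fraction, ct[, condition]."""
    table = pd.read_csv(path, sep="\t")
    required = {"gene", "fraction", "ct"}
    if not required <= set(table.columns):
        raise ValueError(f"Ct table must have columns {sorted(required)}")
    return table


def write_table(df: pd.DataFrame, path, index=True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_region_fasta(models, path, width: int = 70) -> None:
    """Per-region FASTA: three records per gene, IDs GENEID.{5utr,cds,3utr}."""
    with open(path, "w") as fh:
        for m in models:
            for suffix, seq in (("5utr", m.utr5), ("cds", m.cds), ("3utr", m.utr3)):
                fh.write(f">{m.gene_id}.{suffix}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def write_genome_fasta_gff3(models, fasta_path, gff3_path, spacer: int = 20) -> None:
    """Lay gene models on one synthetic chromosome, alternating strands.

    Even-numbered genes go on the plus strand, odd-numbered on the minus
    strand (genomic sequence reverse-complemented), exercising strand
    resolution on re-parse.  Coordinates are 1-based inclusive GFF3.
    """
    from Bio.Seq import Seq

    chrom = "chr1"
    chunks, gff_lines = [], ["##gff-version 3"]
    pos = 1  # next free 1-based coordinate
    for k, m in enumerate(models):
        cdna = m.cdna
        strand = "+" if k % 2 == 0 else "-"
        genomic = cdna if strand == "+" else str(Seq(cdna).reverse_complement())
        start, end = pos, pos + len(genomic) - 1
        l5, lc, l3 = len(m.utr5), len(m.cds), len(m.utr3)
        if strand == "+":
            spans = [("five_prime_UTR", start, start + l5 - 1),
                     ("CDS", start + l5, start + l5 + lc - 1),
                     ("three_prime_UTR", start + l5 + lc, end)]
        else:
            spans = [("three_prime_UTR", start, start + l3 - 1),
                     ("CDS", start + l3, start + l3 + lc - 1),
                     ("five_prime_UTR", start + l3 + lc, end)]
        gid, mid = m.gene_id, f"{m.gene_id}.m"
        gff_lines.append(
            f"{chrom}\tsim\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={gid}"
        )
        gff_lines.append(
            f"{chrom}\tsim\tmRNA\t{start}\t{end}\t.\t{strand}\t.\tID={mid};Parent={gid}"
        )
        for ftype, s, e in spans:
            phase = "0" if ftype == "CDS" else "."
            gff_lines.append(
                f"{chrom}\tsim\t{ftype}\t{s}\t{e}\t.\t{strand}\t{phase}\t"
                f"ID={mid}.{ftype};Parent={mid}"
            )
        chunks.append(genomic)
        chunks.append("N" * spacer)
        pos = end + spacer + 1
    sequence = "".join(chunks)
    with open(fasta_path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(sequence), 70):
            fh.write(sequence[i : i + 70] + "\n")
    Path(gff3_path).write_text("\n".join(gff_lines) + "\n")


def write_pc_table(pc_control, pc_stress, path) -> None:
    """Per-replicate polysome contents (percent) as a TSV."""
    reps = np.arange(1, len(pc_control) + 1)
    pd.DataFrame(
        {
            "replicate": reps,
            "pc_control": np.asarray(pc_control, dtype=float),
            "pc_stress": np.asarray(pc_stress, dtype=float),
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_pc_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    required = {"replicate", "pc_control", "pc_stress"}
    if not required <= set(table.columns):
        raise ValueError(f"PC table must have columns {sorted(required)}")
    return table.sort_values("replicate").reset_index(drop=True)


def read_dg_table(path) -> pd.DataFrame:
    """Optional externally computed folding energies: gene_id, dg_utr5, dg_utr3."""
    table = pd.read_csv(path, sep="\t")
    required = {"gene_id", "dg_utr5", "dg_utr3"}
    if not required <= set(table.columns):
        raise ValueError(f"dG table must have columns {sorted(required)}")
    return table.set_index("gene_id")
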