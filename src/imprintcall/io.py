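"""Readers and writers for the pipeline's plain-text formats.

Genotypes, SNP counts, gene counts, FPKM and motif tables travel as TSV;
gene models as GFF3 (1-based inclusive coordinates); promoters as FASTA;
clusters as BED (0-based half-open, converted from the GFF convention).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .allele_counts import SnpRecord
from .conservation import ImprintCluster

_GENOTYPE_FIXED_COLUMNS = ("snp_id", "chrom", "pos", "gene_id")


def read_genotypes(path: str | Path) -> list[SnpRecord]:
    """Founder genotype TSV -> SnpRecords.

    Fixed columns snp_id, chrom, pos, gene_id; every remaining column is a
    founder.  A SNP id appearing under more than one gene is rejected: counts
    must be attributable to a single gene.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(_GENOTYPE_FIXED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: genotype table lacks columns {sorted(missing)}")
    if df["snp_id"].duplicated().any():
        dup = df.loc[df["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise ValueError(f"{path}: SNP {dup!r} listed more than once (multi-gene SNP?)")
    founders = [c for c in df.columns if c not in _GENOTYPE_FIXED_COLUMNS]
    if not founders:
        raise ValueError(f"{path}: no founder columns found")
    return [
        SnpRecord(
            snp_id=str(row.snp_id),
            chrom=str(row.chrom),
            pos=int(row.pos),
            gene_id=str(row.gene_id),
            alleles={f: str(getattr(row, f)) for f in founders},
        )
        for row in df.itertuples(index=False)
    ]


def write_genotypes(snps: Sequence[SnpRecord], path: str | Path) -> None:
    founders = sorted({f for s in snps for f in s.alleles})
    rows = [
        {
            "snp_id": s.snp_id,
            "chrom": s.chrom,
            "pos": s.pos,
            "gene_id": s.gene_id,
            **{f: s.alleles.get(f, "") for f in founders},
        }
        for s in snps
    ]
    pd.DataFrame(rows, columns=[*_GENOTYPE_FIXED_COLUMNS, *founders]).to_csv(
        path, sep="\t", index=False
    )


def read_snp_counts(path: str | Path) -> dict[str, dict[str, int]]:
    """Per-sample SNP count TSV (snp_id, allele, count) -> nested mapping."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, dict[str, int]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.snp_id), {})[str(row.allele)] = int(row.count)
    return out


def write_snp_counts(
    counts: Mapping[str, Mapping[str, int]] | Iterable[tuple[str, str, int]],
    path: str | Path,
) -> None:
    if isinstance(counts, Mapping):
        rows = [
            (sid, allele, n)
            for sid in counts
            for allele, n in counts[sid].items()
        ]
    else:
        rows = list(counts)
    pd.DataFrame(rows, columns=["snp_id", "allele", "count"]).to_csv(
        path, sep="\t", index=False
    )


def read_gene_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "gene_id", "maternal_reads", "paternal_reads"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: gene count table lacks columns {sorted(missing)}")
    return df


def write_gene_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index=False)


def read_gff3_genes(path: str | Path) -> pd.DataFrame:
    """Gene features of a GFF3 file -> frame(gene_id, chrom, start, end, strand)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9 or fields[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID")
            if gene_id is None:
                raise ValueError(f"{path}: gene feature without ID attribute")
            rows.append(
                (gene_id, fields[0], int(fields[3]), int(fields[4]), fields[6])
            )
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


def write_gff3_genes(genes: pd.DataFrame, path: str | Path) -> None:
    """Write gene models as GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            strand = getattr(row, "strand", "+")
            fh.write(
                f"{row.chrom}\timprintcall\tgene\t{int(row.start)}\t{int(row.end)}"
                f"\t.\t{strand}\t.\tID={row.gene_id}\n"
            )


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fpkm(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene_id"
    return df


def write_fpkm(fpkm: pd.DataFrame, path: str | Path) -> None:
    fpkm.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_clusters_bed(clusters: Sequence[ImprintCluster], path: str | Path) -> None:
    """Clusters as BED: chrom, 0-based start, exclusive end, member list."""
    with open(path, "w") as fh:
        for c in clusters:
            name = ",".join(c.member_gene_ids)
            fh.write(f"{c.chrom}\t{c.start - 1}\t{c.end}\t{name}\n")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_motif_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"name", "consensus", "category"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: motif table lacks columns {sorted(missing)}")
    return df
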