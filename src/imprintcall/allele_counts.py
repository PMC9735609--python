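"""Informative-SNP selection and per-gene parental read aggregation.

In a triparental cross such as (B73 x Mo17) x CAU5, a SNP assigns a read to
the maternal or paternal genome only if every maternal founder carries one
allele, every paternal founder carries one allele, and the two differ.  For
the hybrid-by-inducer crosses this is the "shared in B73 and Mo17, different
in CAU5" rule; for two-parent crosses it reduces to the usual biparental
contrast.  Reads at informative SNPs are partitioned by allele and summed per
gene to give the maternal/paternal totals the imprinting test consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .crosses import CrossSpec

logger = logging.getLogger(__name__)

_NUCLEOTIDES = frozenset("ACGT")


@dataclass(frozen=True)
class SnpRecord:
    """A founder-genotyped SNP assigned to exactly one gene."""

    snp_id: str
    chrom: str
    pos: int
    gene_id: str
    alleles: Mapping[str, str]  # founder name -> nucleotide

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"SNP {self.snp_id}: pos must be >= 1, got {self.pos}")
        for founder, allele in self.alleles.items():
            if allele not in _NUCLEOTIDES:
                raise ValueError(
                    f"SNP {self.snp_id}: founder {founder} has allele {allele!r}, "
                    "expected one of A/C/G/T"
                )


@dataclass(frozen=True)
class GeneAlleleCount:
    """Per-gene maternal/paternal read totals for one sample."""

    gene_id: str
    sample_id: str
    maternal_reads: int
    paternal_reads: int
    n_informative_snps: int

    @property
    def total(self) -> int:
        return self.maternal_reads + self.paternal_reads


def parental_alleles(snp: SnpRecord, cross: CrossSpec) -> tuple[str, str] | None:
    """(maternal, paternal) allele of an informative SNP, or None if uninformative.

    Raises KeyError naming the SNP and founder if a founder in the cross is
    missing from the record.
    """
    mats, pats = set(), set()
    for founder in cross.maternal_founders:
        if founder not in snp.alleles:
            raise KeyError(f"SNP {snp.snp_id}: no genotype for founder {founder}")
        mats.add(snp.alleles[founder])
    for founder in cross.paternal_founders:
        if founder not in snp.alleles:
            raise KeyError(f"SNP {snp.snp_id}: no genotype for founder {founder}")
        pats.add(snp.alleles[founder])
    if len(mats) == 1 and len(pats) == 1 and mats != pats:
        return next(iter(mats)), next(iter(pats))
    return None


def informative_snps(snps: Iterable[SnpRecord], cross: CrossSpec) -> list[SnpRecord]:
    """SNPs whose alleles unambiguously separate the two parental genomes.

    All maternal founders must share one allele, all paternal founders another,
    and the two must differ.  Input order is preserved.  Informativeness does
    not depend on the cross direction, only on the founder sets.
    """
    return [s for s in snps if parental_alleles(s, cross) is not None]


@dataclass
class AssignResult:
    """Per-SNP parental counts plus bookkeeping tallies."""

    per_snp: pd.DataFrame  # snp_id, gene_id, maternal_reads, paternal_reads
    discarded_reads: int  # reads carrying neither parental allele
    skipped_snps: int  # counted SNP ids absent from the informative set


def assign_reads(
    snp_counts: Mapping[str, Mapping[str, int]],
    snps: Sequence[SnpRecord],
    cross: CrossSpec,
) -> AssignResult:
    """Partition per-SNP allele counts into maternal and paternal reads.

    ``snp_counts`` maps SNP id -> {nucleotide: read count}.  Reads carrying
    the maternal-side allele go to the maternal tally, paternal-side to
    paternal; reads with any third allele are dropped and counted in
    ``discarded_reads``.  Counted SNP ids not in the informative set are
    skipped (tallied in ``skipped_snps``); informative SNPs with no counts
    contribute (0, 0) so low-coverage genes still appear downstream.
    """
    rows = []
    informative_ids = set()
    discarded = 0
    for snp in snps:
        pair = parental_alleles(snp, cross)
        if pair is None:
            continue
        mat_allele, pat_allele = pair
        informative_ids.add(snp.snp_id)
        counts = snp_counts.get(snp.snp_id, {})
        m = int(counts.get(mat_allele, 0))
        p = int(counts.get(pat_allele, 0))
        discarded += sum(
            int(c) for a, c in counts.items() if a not in (mat_allele, pat_allele)
        )
        rows.append((snp.snp_id, snp.gene_id, m, p))
    skipped = sum(1 for sid in snp_counts if sid not in informative_ids)
    if skipped:
        logger.warning(
            "%d counted SNP(s) absent from the informative set for cross %s; skipped",
            skipped,
            cross.name,
        )
    per_snp = pd.DataFrame(
        rows, columns=["snp_id", "gene_id", "maternal_reads", "paternal_reads"]
    )
    return AssignResult(per_snp=per_snp, discarded_reads=discarded, skipped_snps=skipped)


def aggregate_gene(per_snp: pd.DataFrame, sample_id: str) -> pd.DataFrame:
    """Sum per-SNP parental counts to one row per gene.

    Returns a frame with columns gene_id, sample_id, maternal_reads,
    paternal_reads, n_informative_snps.  Genes with zero informative SNPs are
    absent by construction (they contribute no per-SNP rows); genes whose SNPs
    all have zero reads are kept.
    """
    if per_snp.empty:
        return pd.DataFrame(
            columns=[
                "gene_id",
                "sample_id",
                "maternal_reads",
                "paternal_reads",
                "n_informative_snps",
            ]
        )
    agg = (
        per_snp.groupby("gene_id", sort=True)
        .agg(
            maternal_reads=("maternal_reads", "sum"),
            paternal_reads=("paternal_reads", "sum"),
            n_informative_snps=("snp_id", "size"),
        )
        .reset_index()
    )
    agg.insert(1, "sample_id", sample_id)
    return agg


def count_sample(
    snps: Sequence[SnpRecord],
    snp_counts: Mapping[str, Mapping[str, int]],
    cross: CrossSpec,
) -> tuple[pd.DataFrame, AssignResult]:
    """Informative-SNP selection, read assignment and per-gene aggregation
    for one sample; the full counting path of the pipeline."""
    assigned = assign_reads(snp_counts, snps, cross)
    return aggregate_gene(assigned.per_snp, cross.sample_id), assigned
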