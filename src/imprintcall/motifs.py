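"""IUPAC consensus scanning of promoter sequences for cis-regulatory elements.

Promoters are the 1.5 kb immediately upstream of the translation start
(ATG); offsets are 0-based from the promoter 5' end, and
``offset_from_atg`` converts a hit to distance upstream of the ATG.

The default table holds thirteen element classes grouped by the response
they are associated with -- hormones (ABRE, CGTCA-motif, TGACG-motif, ERE,
TGA-element, TCA-element), light (G-box, GT1-motif, TCT-motif, Box-4) and
stress (ARE, W-box, LTR).  The consensus strings are PlantCARE-style core
sequences and are deliberately configurable (via a TSV of name, consensus,
category): different motif databases disagree on the exact cores, so the
defaults are a reasonable working set rather than canonical values.

Matching is position-by-position over IUPAC classes, overlapping matches are
all reported, and an N in the sequence never matches any consensus symbol.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

HORMONE = "hormone"
LIGHT = "light"
STRESS = "stress"

IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_IUPAC_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

_SEQ_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class MotifDef:
    name: str
    consensus: str
    category: str

    def __post_init__(self) -> None:
        if not self.consensus:
            raise ValueError(f"motif {self.name}: empty consensus")
        bad = set(self.consensus.upper()) - set(IUPAC)
        if bad:
            raise ValueError(
                f"motif {self.name}: non-IUPAC symbols {sorted(bad)} in consensus"
            )
        object.__setattr__(self, "consensus", self.consensus.upper())

    @property
    def reverse_complement(self) -> str:
        return "".join(_IUPAC_COMPLEMENT[c] for c in reversed(self.consensus))

    @property
    def is_palindromic(self) -> bool:
        return self.consensus == self.reverse_complement


@dataclass(frozen=True)
class MotifHit:
    gene_id: str | None
    motif_name: str
    offset: int  # 0-based from promoter 5' end
    strand: str  # "+" or "-"


DEFAULT_MOTIFS: tuple[MotifDef, ...] = (
    MotifDef("ABRE", "ACGTG", HORMONE),
    MotifDef("CGTCA-motif", "CGTCA", HORMONE),
    MotifDef("TGACG-motif", "TGACG", HORMONE),
    MotifDef("ERE", "ATTTCAAA", HORMONE),
    MotifDef("TGA-element", "AACGAC", HORMONE),
    MotifDef("TCA-element", "CCATCTTTTT", HORMONE),
    MotifDef("G-box", "CACGTG", LIGHT),
    MotifDef("GT1-motif", "GGTTAA", LIGHT),
    MotifDef("TCT-motif", "TCTTAC", LIGHT),
    MotifDef("Box-4", "ATTAAT", LIGHT),
    MotifDef("ARE", "AAACCA", STRESS),
    MotifDef("W-box", "TTGACC", STRESS),
    MotifDef("LTR", "CCGAAA", STRESS),
)


def _compiled(consensus: str) -> re.Pattern:
    # lookahead so overlapping matches are all reported; classes contain only
    # A/C/G/T, so sequence Ns can never match (including against consensus N)
    body = "".join(f"[{IUPAC[c]}]" for c in consensus)
    return re.compile(f"(?=({body}))")


def scan_promoter(
    seq: str,
    motifs: Sequence[MotifDef] = DEFAULT_MOTIFS,
    both_strands: bool = True,
    dedup_palindromes: bool = False,
    gene_id: str | None = None,
) -> list[MotifHit]:
    """All occurrences of each consensus in a promoter, in ascending offset.

    With ``both_strands`` the reverse complement of each consensus is also
    scanned; a minus-strand hit's offset is the match's leftmost position on
    the forward sequence.  For palindromic consensi the plus and minus hits
    coincide; ``dedup_palindromes`` keeps only the plus-strand record.
    """
    seq = seq.upper()
    bad = set(seq) - _SEQ_ALPHABET
    if bad:
        raise ValueError(f"sequence contains non-nucleotide characters: {sorted(bad)}")
    hits: list[MotifHit] = []
    for motif in motifs:
        for m in _compiled(motif.consensus).finditer(seq):
            hits.append(MotifHit(gene_id, motif.name, m.start(), "+"))
        if both_strands and not (dedup_palindromes and motif.is_palindromic):
            for m in _compiled(motif.reverse_complement).finditer(seq):
                hits.append(MotifHit(gene_id, motif.name, m.start(), "-"))
    hits.sort(key=lambda h: (h.offset, h.motif_name, h.strand))
    return hits


def offset_from_atg(hit: MotifHit, promoter_length: int, consensus_length: int) -> int:
    """Distance from the ATG to the hit's 3'-most base (1 = immediately upstream)."""
    return promoter_length - (hit.offset + consensus_length) + 1


def scan_promoters(
    promoters: Mapping[str, str],
    motifs: Sequence[MotifDef] = DEFAULT_MOTIFS,
    both_strands: bool = True,
    dedup_palindromes: bool = False,
) -> pd.DataFrame:
    """Scan a gene -> promoter mapping; tidy frame of all hits."""
    rows = []
    for gene_id in sorted(promoters):
        for h in scan_promoter(
            promoters[gene_id], motifs, both_strands, dedup_palindromes, gene_id
        ):
            rows.append((h.gene_id, h.motif_name, h.offset, h.strand))
    return pd.DataFrame(rows, columns=["gene_id", "motif_name", "offset", "strand"])


def group_profile(
    hits: pd.DataFrame,
    groups: Mapping[str, Iterable[str]],
    motifs: Sequence[MotifDef] = DEFAULT_MOTIFS,
    scanned_genes: Iterable[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-group element presence ratios and per-gene distinct class counts.

    For each motif and group: the fraction of the group's genes with at
    least one hit.  Genes not among ``scanned_genes`` (no promoter available)
    are excluded from the denominators; an empty group yields NaN ratios.
    Returns (ratios frame indexed by motif, per-gene distinct-class counts).
    """
    motif_names = [m.name for m in motifs]
    present = {
        (g, m): True
        for g, m in hits[["gene_id", "motif_name"]].drop_duplicates().itertuples(
            index=False
        )
    }
    scanned = set(scanned_genes) if scanned_genes is not None else set(hits["gene_id"])
    ratios = {}
    for group_name, gene_list in groups.items():
        genes = [g for g in gene_list if g in scanned]
        if not genes:
            ratios[group_name] = {m: float("nan") for m in motif_names}
            continue
        ratios[group_name] = {
            m: sum(present.get((g, m), False) for g in genes) / len(genes)
            for m in motif_names
        }
    ratio_frame = pd.DataFrame(ratios).reindex(motif_names)
    ratio_frame.index.name = "motif_name"
    per_gene = (
        hits.drop_duplicates(["gene_id", "motif_name"])
        .groupby("gene_id")["motif_name"]
        .size()
        .rename("n_element_classes")
    )
    return ratio_frame, per_gene


def motif_table(motifs: Sequence[MotifDef] = DEFAULT_MOTIFS) -> pd.DataFrame:
    return pd.DataFrame(
        [(m.name, m.consensus, m.category) for m in motifs],
        columns=["name", "consensus", "category"],
    )


def motifs_from_table(table: pd.DataFrame) -> list[MotifDef]:
    return [
        MotifDef(r["name"], r["consensus"], r["category"])
        for _, r in table.iterrows()
    ]
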