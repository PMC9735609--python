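"""Imprinting conservation across cross pairs, clusters, and summaries.

When a third parent is introduced into a reciprocal cross, a gene's
imprinted status may change.  The comparison is organised into twelve sets
over four reciprocal pairs.  For the "Mo17-added" group the reference is the
two-parent pair BC/CB and the test pairs are the hybrid pairs:

  I:   imprinted in BM-C/C-BM but not in BC/CB
  II:  imprinted in BC/CB but not in BM-C/C-BM
  III: imprinted in both BM-C/C-BM and BC/CB
  IV:  imprinted in MB-C/C-MB but not in BC/CB
  V:   imprinted in BC/CB but not in MB-C/C-MB
  VI:  imprinted in both MB-C/C-MB and BC/CB

The "B73-added" group mirrors this with MC/CM as the reference (sets
VII-XII).  Non-conserved genes are those whose status differs in both
comparisons, (I u II) n (IV u V); conserved genes are imprinted everywhere,
III n VI (resp. (VII u VIII) n (X u XI) and IX n XII).  A gene enters the set
logic only if it is testable in every compared pair; otherwise it is
unclassified -- absence of evidence is not a status change.

Also here: single-linkage chaining of imprinted genes into clusters
(consecutive genes at most 1 Mb apart, at least two members), per-chromosome
tallies, and joins against user-supplied cross-species imprinting tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .calling import MEG, PEG, UNTESTABLE

logger = logging.getLogger(__name__)

IMPRINTED = "imprinted"
NOT_IMPRINTED = "not_imprinted"

CONSERVED = "conserved"
NON_CONSERVED = "non_conserved"
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class GroupSpec:
    """Which pairs a conservation group compares, and its set labels."""

    name: str
    test_pairs: tuple[str, str]
    reference_pair: str
    set_labels: tuple[tuple[str, str, str], tuple[str, str, str]]


GROUPS: dict[str, GroupSpec] = {
    "Mo17-added": GroupSpec(
        name="Mo17-added",
        test_pairs=("BM-C/C-BM", "MB-C/C-MB"),
        reference_pair="BC/CB",
        set_labels=(("I", "II", "III"), ("IV", "V", "VI")),
    ),
    "B73-added": GroupSpec(
        name="B73-added",
        test_pairs=("BM-C/C-BM", "MB-C/C-MB"),
        reference_pair="MC/CM",
        set_labels=(("VII", "VIII", "IX"), ("X", "XI", "XII")),
    ),
}


@dataclass(frozen=True)
class ConservationAssignment:
    gene_id: str
    group: str
    sets: frozenset[str]
    label: str  # conserved / non_conserved / unclassified


@dataclass(frozen=True)
class ImprintCluster:
    """>= 2 imprinted genes whose consecutive spacing is within the window."""

    chrom: str
    start: int  # 1-based inclusive span over member genes
    end: int
    member_gene_ids: tuple[str, ...]
    tissue: str | None = None


def imprint_status_by_pair(
    calls: pd.DataFrame, tissue: str | None = None
) -> dict[str, dict[str, str]]:
    """Collapse a calls table to per-pair gene -> imprinted/not/untestable.

    With a tissue given, a gene is imprinted if called MEG or PEG in that
    tissue.  With ``tissue=None`` tissues are pooled: imprinted if imprinted
    in any tissue, untestable only if untestable in all tissues.
    """
    sub = calls if tissue is None else calls[calls["tissue"] == tissue]
    out: dict[str, dict[str, str]] = {}
    for pair, grp in sub.groupby("cross_pair"):
        statuses: dict[str, str] = {}
        for gene, g in grp.groupby("gene_id"):
            ss = set(g["status"])
            if ss & {MEG, PEG}:
                statuses[gene] = IMPRINTED
            elif ss == {UNTESTABLE}:
                statuses[gene] = UNTESTABLE
            else:
                statuses[gene] = NOT_IMPRINTED
        out[pair] = statuses
    return out


def assign_sets(
    status_by_pair: Mapping[str, Mapping[str, str]], group: str | GroupSpec
) -> list[ConservationAssignment]:
    """Per-gene set memberships and conserved/non-conserved labels for a group."""
    spec = GROUPS[group] if isinstance(group, str) else group
    needed = (*spec.test_pairs, spec.reference_pair)
    for pair in needed:
        if pair not in status_by_pair:
            raise ValueError(f"missing calls for cross pair {pair!r}")
    genes = sorted(set().union(*(status_by_pair[p].keys() for p in needed)))
    ref = status_by_pair[spec.reference_pair]
    out = []
    for gene in genes:
        statuses = [status_by_pair[p].get(gene, UNTESTABLE) for p in needed]
        if any(s == UNTESTABLE for s in statuses):
            out.append(
                ConservationAssignment(gene, spec.name, frozenset(), UNCLASSIFIED)
            )
            continue
        r = ref[gene] == IMPRINTED
        sets = set()
        differs = []  # per comparison: status differs between test pair and reference
        both = []
        for (only_test, only_ref, in_both), pair in zip(
            spec.set_labels, spec.test_pairs
        ):
            t = status_by_pair[pair][gene] == IMPRINTED
            if t and not r:
                sets.add(only_test)
            elif r and not t:
                sets.add(only_ref)
            elif t and r:
                sets.add(in_both)
            differs.append(t != r)
            both.append(t and r)
        if all(both):
            label = CONSERVED
        elif all(differs):
            label = NON_CONSERVED
        else:
            label = UNCLASSIFIED
        out.append(ConservationAssignment(gene, spec.name, frozenset(sets), label))
    return out


def assignments_frame(assignments: Iterable[ConservationAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": a.gene_id,
                "group": a.group,
                "sets": ",".join(sorted(a.sets)),
                "label": a.label,
            }
            for a in assignments
        ]
    )


def overlap_groups(
    assignments_a: Sequence[ConservationAssignment],
    assignments_b: Sequence[ConservationAssignment],
) -> dict:
    """Overlap of conserved and of non-conserved gene lists between two groups.

    On real data the non-conserved/non-conserved overlap is where the
    high-confidence allele-specific imprinting candidates come from.
    """

    def by_label(assignments, label):
        return {a.gene_id for a in assignments if a.label == label}

    report = {}
    for label in (CONSERVED, NON_CONSERVED):
        a = by_label(assignments_a, label)
        b = by_label(assignments_b, label)
        inter = sorted(a & b)
        report[label] = {
            "n_a": len(a),
            "n_b": len(b),
            "n_overlap": len(inter),
            "overlap": inter,
            "fraction_of_a": len(inter) / len(a) if a else None,
            "fraction_of_b": len(inter) / len(b) if b else None,
        }
    return report


def interspecies_join(
    assignments: Sequence[ConservationAssignment], orthologs: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join assignments against a user-supplied cross-species imprinting table.

    ``orthologs`` needs columns gene_id, species, ortholog_id, imprinted
    (boolean-like).  Returns (per_gene, rates): per-gene flags per species,
    and per-species conservation rates with the join's genes as denominator
    (NaN when no gene joins).  Ortholog rows for unknown genes are logged and
    excluded.
    """
    known = {a.gene_id: a.label for a in assignments}
    if orthologs.empty:
        per_gene = pd.DataFrame(
            columns=["gene_id", "label", "species", "ortholog_id", "imprinted"]
        )
        rates = pd.DataFrame(columns=["species", "n_genes", "n_imprinted", "rate"])
        return per_gene, rates
    tab = orthologs.copy()
    unknown = ~tab["gene_id"].isin(known)
    if unknown.any():
        logger.warning(
            "%d ortholog row(s) reference unknown gene ids; excluded", int(unknown.sum())
        )
        tab = tab[~unknown]
    tab["imprinted"] = tab["imprinted"].astype(bool)
    tab["label"] = tab["gene_id"].map(known)
    rates = (
        tab.groupby("species")
        .agg(
            n_genes=("gene_id", "nunique"),
            n_imprinted=("imprinted", lambda s: int(s.sum())),
        )
        .reset_index()
    )
    rates["rate"] = rates["n_imprinted"] / rates["n_genes"]
    return tab, rates


def find_clusters(
    genes: pd.DataFrame,
    window: int = 1_000_000,
    anchor: str = "start",
    tissue: str | None = None,
) -> list[ImprintCluster]:
    """Chain imprinted genes into clusters of >= 2 within a genomic window.

    ``genes`` needs columns gene_id, chrom, start, end (1-based inclusive).
    Genes on one chromosome are sorted by anchor position (gene start by
    default, or "midpoint") and chained single-linkage: consecutive genes
    whose anchors are at most ``window`` apart join one cluster, so a chained
    cluster may span more than one window overall.  Chains of length 1 are
    dropped.
    """
    required = {"gene_id", "chrom", "start", "end"}
    missing = required - set(genes.columns)
    if missing:
        raise ValueError(f"gene table lacks columns: {sorted(missing)}")
    if genes[["start", "end"]].isna().any().any():
        raise ValueError("gene coordinates contain missing values")
    if anchor == "start":
        anchors = genes["start"].astype(int)
    elif anchor == "midpoint":
        anchors = ((genes["start"] + genes["end"]) // 2).astype(int)
    else:
        raise ValueError(f"unknown anchor {anchor!r}")
    work = genes.assign(_anchor=anchors).sort_values(
        ["chrom", "_anchor", "gene_id"], kind="mergesort"
    )
    clusters = []
    for chrom, sub in work.groupby("chrom", sort=True):
        chain: list[pd.Series] = []
        prev_anchor = None
        for _, row in sub.iterrows():
            if prev_anchor is not None and row["_anchor"] - prev_anchor > window:
                if len(chain) >= 2:
                    clusters.append(_make_cluster(chrom, chain, tissue))
                chain = []
            chain.append(row)
            prev_anchor = row["_anchor"]
        if len(chain) >= 2:
            clusters.append(_make_cluster(chrom, chain, tissue))
    return clusters


def _make_cluster(chrom: str, chain: list[pd.Series], tissue: str | None) -> ImprintCluster:
    return ImprintCluster(
        chrom=str(chrom),
        start=int(min(r["start"] for r in chain)),
        end=int(max(r["end"] for r in chain)),
        member_gene_ids=tuple(r["gene_id"] for r in chain),
        tissue=tissue,
    )


def summarize_chromosomes(calls: pd.DataFrame, gene_models: pd.DataFrame) -> dict:
    """Per-chromosome imprinted-gene counts per tissue plus tissue overlap.

    ``gene_models`` needs columns gene_id, chrom.  A gene counts once per
    tissue however many cross pairs call it imprinted.
    """
    coords = gene_models.set_index("gene_id")["chrom"]
    imprinted = calls[calls["status"].isin([MEG, PEG])]
    per_chrom: dict[str, dict[str, int]] = {
        str(c): {"embryo": 0, "endosperm": 0} for c in sorted(coords.unique())
    }
    tissue_genes: dict[str, set] = {"embryo": set(), "endosperm": set()}
    for tissue, sub in imprinted.groupby("tissue"):
        genes = set(sub["gene_id"])
        tissue_genes[tissue] = genes
        for gene in genes:
            chrom = coords.get(gene)
            if chrom is not None:
                per_chrom[str(chrom)][tissue] += 1
    overlap = sorted(tissue_genes["embryo"] & tissue_genes["endosperm"])
    return {"per_chromosome": per_chrom, "embryo_endosperm_overlap": overlap}
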