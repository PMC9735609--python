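"""Scan 1.5-kb promoters for the thirteen cis-element classes and compare
element profiles between conserved and non-conserved genes.

Writes results/motif_hits.tsv and results/motif_group_ratios.tsv, and
verifies that every motif instance the generator planted is recovered.
"""

import json
from pathlib import Path

import pandas as pd

from imprintcall import io as icio
from imprintcall.motifs import DEFAULT_MOTIFS, group_profile, scan_promoters

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    fixture = ROOT / "fixture"
    promoters = icio.read_fasta(fixture / "promoters.fasta")
    hits = scan_promoters(promoters, DEFAULT_MOTIFS, both_strands=True)
    hits.to_csv(ROOT / "motif_hits.tsv", sep="\t", index=False)
    print(f"{len(hits)} hits over {hits['gene_id'].nunique()} promoters")

    planted = json.loads((fixture / "manifest.json").read_text())["planted_motifs"]
    found = set(
        map(tuple, hits[["gene_id", "motif_name", "offset"]].itertuples(index=False))
    )
    recovered = sum(
        1 for r in planted if (r["gene_id"], r["motif_name"], r["offset"]) in found
    )
    print(f"planted motifs recovered: {recovered}/{len(planted)}")

    assignments = pd.read_csv(ROOT / "conservation_assignments.tsv", sep="\t")
    mo17 = assignments[assignments["group"] == "Mo17-added"]
    groups = {
        "conserved": list(mo17.loc[mo17["label"] == "conserved", "gene_id"]),
        "non_conserved": list(mo17.loc[mo17["label"] == "non_conserved", "gene_id"]),
    }
    ratios, per_gene = group_profile(hits, groups, scanned_genes=promoters)
    ratios.to_csv(ROOT / "motif_group_ratios.tsv", sep="\t")
    print("element presence ratios by group:")
    print(ratios.round(2).to_string())
    if len(per_gene):
        print(f"median distinct element classes per gene: {per_gene.median():.0f}")


if __name__ == "__main__":
    main()
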