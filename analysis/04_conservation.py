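"""Conservation sets, group overlaps, imprinted-gene clusters and
chromosome summaries.

Assigns every gene to the twelve conservation sets (Mo17-added I-VI against
BC/CB; B73-added VII-XII against MC/CM), labels genes conserved /
non-conserved, intersects the two groups, chains imprinted genes into 1-Mb
clusters per tissue, and tallies imprinted genes per chromosome.  Writes
results/conservation_assignments.tsv, results/clusters.bed and
results/conservation_summary.json.
"""

from pathlib import Path

import pandas as pd

from imprintcall import io as icio
from imprintcall.conservation import (
    GROUPS,
    assign_sets,
    assignments_frame,
    find_clusters,
    imprint_status_by_pair,
    overlap_groups,
    summarize_chromosomes,
)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    calls = pd.read_csv(ROOT / "calls.tsv", sep="\t")
    genes = icio.read_gff3_genes(ROOT / "fixture" / "genes.gff3")

    status = imprint_status_by_pair(calls, tissue=None)
    per_group = {g: assign_sets(status, g) for g in GROUPS}
    frame = pd.concat(
        [assignments_frame(a) for a in per_group.values()], ignore_index=True
    )
    frame.to_csv(ROOT / "conservation_assignments.tsv", sep="\t", index=False)
    for g, assignments in per_group.items():
        labels = pd.Series([a.label for a in assignments]).value_counts().to_dict()
        print(f"{g}: {labels}")

    overlap = overlap_groups(per_group["Mo17-added"], per_group["B73-added"])
    print(
        f"conserved overlap between groups: {overlap['conserved']['n_overlap']} genes; "
        f"non-conserved overlap: {overlap['non_conserved']['n_overlap']} genes"
    )

    clusters = []
    for tissue, sub in calls.groupby("tissue"):
        imprinted = sorted(set(sub.loc[sub["status"].isin(["MEG", "PEG"]), "gene_id"]))
        coords = genes[genes["gene_id"].isin(imprinted)]
        found = find_clusters(coords, window=1_000_000, tissue=tissue)
        clusters.extend(found)
        print(f"{tissue}: {len(found)} cluster(s) among {len(imprinted)} imprinted genes")
    icio.write_clusters_bed(clusters, ROOT / "clusters.bed")

    chrom_summary = summarize_chromosomes(calls, genes)
    icio.write_json(
        {"overlap": overlap, "chromosomes": chrom_summary},
        ROOT / "conservation_summary.json",
    )
    busiest = max(
        chrom_summary["per_chromosome"].items(),
        key=lambda kv: kv[1]["embryo"] + kv[1]["endosperm"],
    )
    print(f"most imprinted genes on {busiest[0]}: {busiest[1]}")


if __name__ == "__main__":
    main()
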