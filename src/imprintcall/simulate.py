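"""Synthetic triparental imprinting studies with known ground truth.

The generator emulates what the real pipeline consumes, without sequencing:
founder genotypes at informative and uninformative SNPs over three founders
(B73, Mo17, CAU5), reciprocal-cross samples for embryo (1:1 expected
maternal:paternal dosage) and endosperm (2:1), per-gene allelic read counts
with binomial or beta-binomial noise around each gene's true maternal
fraction, genes driven below the 20-read testability rule, promoter
sequences with planted cis-element instances, and an FPKM matrix carrying
endosperm-primary and constitutive expression profiles.

True maternal fractions default to 0.95/0.05 for MEGs/PEGs in the embryo
and 0.95/0.20 in the endosperm; biallelic genes sit exactly on the dosage
null (1/2 embryo, 2/3 endosperm).  Counts are beta-binomial with a common
overdispersion rho (plain binomial at rho = 0).  Replicates are not
modelled individually: the counts represent replicate-merged totals.
All outputs are deterministic functions of the configuration seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as icio
from .allele_counts import SnpRecord, parental_alleles
from .calling import BIALLELIC, MEG, PEG, UNTESTABLE
from .crosses import (
    B73,
    CAU5,
    EMBRYO,
    ENDOSPERM,
    MO17,
    CrossSpec,
    ReciprocalPair,
    default_design,
    expected_maternal_fraction,
    samples as design_samples,
    write_cross_config,
)
from .expression import CONSTITUTIVE, ENDOSPERM_PRIMARY
from .motifs import DEFAULT_MOTIFS, IUPAC, MotifDef

_FOUNDERS = (B73, MO17, CAU5)
_BASES = np.array(list("ACGT"))

# sub-stream tags so each component draws from an independent, reproducible stream
_S_TRUTH, _S_SNPS, _S_COUNTS, _S_PROMOTERS, _S_FPKM, _S_SPLIT = range(6)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of a synthetic run.

    Proportions frac_meg/frac_peg/frac_untestable must sum to at most 1;
    the remainder of genes is biallelic.  depth_mean is the mean summed
    allelic read depth per gene and sample; untestable genes instead draw a
    low depth strictly below min_reads.  overdispersion is the beta-binomial
    intra-class correlation rho (0 = binomial).
    """

    n_genes: int = 1000
    n_chromosomes: int = 10
    snps_per_gene: int = 3
    frac_meg: float = 0.05
    frac_peg: float = 0.05
    frac_untestable: float = 0.05
    theta_meg_embryo: float = 0.95
    theta_peg_embryo: float = 0.05
    theta_meg_endo: float = 0.95
    theta_peg_endo: float = 0.20
    depth_mean: float = 100.0
    low_depth_mean: float = 8.0
    overdispersion: float = 0.0
    min_reads: int = 20
    promoter_length: int = 1500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_chromosomes < 1:
            raise ValueError("n_genes and n_chromosomes must be positive")
        if self.snps_per_gene < 0:
            raise ValueError("snps_per_gene must be >= 0")
        fracs = (self.frac_meg, self.frac_peg, self.frac_untestable)
        if any(f < 0 or f > 1 for f in fracs):
            raise ValueError("status fractions must lie in [0, 1]")
        if sum(fracs) > 1 + 1e-12:
            raise ValueError("frac_meg + frac_peg + frac_untestable must be <= 1")
        for name in (
            "theta_meg_embryo",
            "theta_peg_embryo",
            "theta_meg_endo",
            "theta_peg_endo",
        ):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if not 0.0 <= self.overdispersion < 1.0:
            raise ValueError("overdispersion must lie in [0, 1)")
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng((int(config.seed), stream))


def _theta(status: str, tissue: str, config: SimConfig) -> float:
    if status == MEG:
        return (
            config.theta_meg_embryo if tissue == EMBRYO else config.theta_meg_endo
        )
    if status == PEG:
        return (
            config.theta_peg_embryo if tissue == EMBRYO else config.theta_peg_endo
        )
    # biallelic and low-coverage genes sit on the dosage null
    return expected_maternal_fraction(tissue)


def generate_truth(config: SimConfig) -> pd.DataFrame:
    """Ground-truth table: status, coordinates and true maternal fractions.

    Statuses are drawn i.i.d. per the configured fractions.  Genes are laid
    out non-overlapping along each chromosome (1-based inclusive spans) with
    random intergenic gaps, so imprinted-gene clusters arise naturally.
    """
    rng = _rng(config, _S_TRUTH)
    n = config.n_genes
    draws = rng.random(n)
    edges = np.cumsum([config.frac_meg, config.frac_peg, config.frac_untestable])
    status = np.select(
        [draws < edges[0], draws < edges[1], draws < edges[2]],
        [MEG, PEG, UNTESTABLE],
        default=BIALLELIC,
    )
    chrom_idx = rng.integers(0, config.n_chromosomes, size=n)
    lengths = rng.integers(2_000, 6_001, size=n)
    gaps = rng.integers(20_000, 300_001, size=n)
    starts = np.empty(n, dtype=np.int64)
    cursor = {c: 1 for c in range(config.n_chromosomes)}
    for i in range(n):
        c = int(chrom_idx[i])
        starts[i] = cursor[c] + int(gaps[i])
        cursor[c] = starts[i] + int(lengths[i])
    gene_ids = [f"gene{i + 1:05d}" for i in range(n)]
    truth = pd.DataFrame(
        {
            "status": status,
            "chrom": [f"chr{c + 1}" for c in chrom_idx],
            "start": starts,
            "end": starts + lengths - 1,
            "theta_embryo": [_theta(s, EMBRYO, config) for s in status],
            "theta_endosperm": [_theta(s, ENDOSPERM, config) for s in status],
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return truth


def swap_parental_roles(truth: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Truth with maternal and paternal roles exchanged.

    Statuses swap MEG <-> PEG and true maternal fractions are recomputed, so
    embryo fractions map theta -> 1 - theta under the symmetric defaults
    while endosperm biallelic genes re-apply the 2:1 dosage.
    """
    swapped = truth.copy()
    swapped["status"] = truth["status"].map({MEG: PEG, PEG: MEG}).fillna(truth["status"])
    swapped["theta_embryo"] = [
        _theta(s, EMBRYO, config) for s in swapped["status"]
    ]
    swapped["theta_endosperm"] = [
        _theta(s, ENDOSPERM, config) for s in swapped["status"]
    ]
    return swapped


def draw_maternal_counts(
    rng: np.random.Generator,
    depth: np.ndarray,
    theta: np.ndarray,
    overdispersion: float,
) -> np.ndarray:
    """Beta-binomial maternal read counts (binomial at rho = 0).

    theta may include the degenerate 0 and 1 endpoints, which force all-
    paternal / all-maternal counts.
    """
    depth = np.asarray(depth, dtype=np.int64)
    theta = np.asarray(theta, dtype=float)
    rho = float(overdispersion)
    if rho == 0.0:
        return rng.binomial(depth, theta)
    scale = (1.0 - rho) / rho
    interior = (theta > 0.0) & (theta < 1.0)
    p = theta.copy()
    if interior.any():
        p[interior] = rng.beta(theta[interior] * scale, (1.0 - theta[interior]) * scale)
    return rng.binomial(depth, p)


def _flatten_design(
    design: Sequence[ReciprocalPair | CrossSpec],
) -> list[tuple[str | None, CrossSpec]]:
    flat: list[tuple[str | None, CrossSpec]] = []
    for item in design:
        if isinstance(item, ReciprocalPair):
            flat.append((item.name, item.direction1))
            flat.append((item.name, item.direction2))
        else:
            flat.append((None, item))
    return flat


def simulate_counts(
    truth: pd.DataFrame,
    design: Sequence[ReciprocalPair | CrossSpec],
    config: SimConfig,
    swap_roles: bool = False,
) -> pd.DataFrame:
    """Per-gene maternal/paternal read counts for every sample of a design.

    Depth is Poisson(depth_mean) per gene and sample, except truth-untestable
    genes whose depth is clipped strictly below min_reads.  Maternal reads
    are beta-binomial around the gene's tissue-specific true fraction.  With
    ``swap_roles`` the generating truth has parental roles exchanged (see
    :func:`swap_parental_roles`) while the random streams are reused, giving
    matched samples for anti-symmetry checks.
    """
    gen_truth = swap_parental_roles(truth, config) if swap_roles else truth
    rng = _rng(config, _S_COUNTS)
    low = gen_truth["status"].to_numpy() == UNTESTABLE
    theta_col = {EMBRYO: "theta_embryo", ENDOSPERM: "theta_endosperm"}
    frames = []
    for pair_name, cross in _flatten_design(design):
        if cross.tissue not in theta_col:
            raise ValueError(f"unknown tissue {cross.tissue!r} in cross {cross.name!r}")
        n = len(gen_truth)
        depth = rng.poisson(config.depth_mean, size=n)
        low_depth = np.minimum(
            rng.poisson(config.low_depth_mean, size=n), config.min_reads - 1
        )
        depth = np.where(low, low_depth, depth)
        theta = gen_truth[theta_col[cross.tissue]].to_numpy(dtype=float)
        maternal = draw_maternal_counts(rng, depth, theta, config.overdispersion)
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": cross.sample_id,
                    "cross_pair": pair_name,
                    "cross_name": cross.name,
                    "tissue": cross.tissue,
                    "gene_id": gen_truth.index,
                    "maternal_reads": maternal,
                    "paternal_reads": depth - maternal,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# SNP founder-genotype patterns: the guaranteed pattern (hybrid founders
# share an allele that differs from the inducer) is informative for every
# default cross pair; the others exercise the informativeness filter.
_PATTERNS = ("shared_vs_inducer", "b73_diff", "mo17_diff", "monomorphic")
_PATTERN_P = (0.5, 0.2, 0.2, 0.1)


def generate_snps(truth: pd.DataFrame, config: SimConfig) -> list[SnpRecord]:
    """Founder-genotyped SNPs within each gene's span.

    Every gene receives at least one SNP informative for all default crosses
    (B73 = Mo17 != CAU5); additional SNPs (Poisson around snps_per_gene - 1)
    draw mixed patterns, including uninformative ones.
    """
    rng = _rng(config, _S_SNPS)
    snps: list[SnpRecord] = []
    for gene_id, row in truth.iterrows():
        extra = int(rng.poisson(max(config.snps_per_gene - 1, 0)))
        n_snps = 1 + extra
        span = int(row["end"]) - int(row["start"]) + 1
        offsets = rng.choice(span, size=min(n_snps, span), replace=False)
        offsets.sort()
        for j, off in enumerate(offsets):
            pattern = (
                "shared_vs_inducer"
                if j == 0
                else _PATTERNS[rng.choice(len(_PATTERNS), p=_PATTERN_P)]
            )
            x, y = rng.choice(4, size=2, replace=False)
            a, b = _BASES[x], _BASES[y]
            if pattern == "shared_vs_inducer":
                alleles = {B73: a, MO17: a, CAU5: b}
            elif pattern == "b73_diff":
                alleles = {B73: b, MO17: a, CAU5: a}
            elif pattern == "mo17_diff":
                alleles = {B73: a, MO17: b, CAU5: a}
            else:
                alleles = {B73: a, MO17: a, CAU5: a}
            snps.append(
                SnpRecord(
                    snp_id=f"{gene_id}_snp{j + 1}",
                    chrom=str(row["chrom"]),
                    pos=int(row["start"]) + int(off),
                    gene_id=str(gene_id),
                    alleles=alleles,
                )
            )
    return snps


def distribute_counts_to_snps(
    gene_counts: pd.DataFrame,
    snps: Sequence[SnpRecord],
    design: Sequence[ReciprocalPair | CrossSpec],
    config: SimConfig,
) -> dict[str, dict[str, dict[str, int]]]:
    """Split per-gene totals over each gene's informative SNPs per sample.

    Returns sample_id -> snp_id -> {allele: count}.  Reads are spread
    multinomially with equal weight per informative SNP and keyed by the
    SNP's maternal/paternal nucleotide for that cross, so aggregation through
    the counting pipeline recovers the per-gene totals exactly.
    """
    rng = _rng(config, _S_SPLIT)
    crosses = {c.sample_id: c for _, c in _flatten_design(design)}
    # cache informative-SNP lists per founder-set configuration
    by_config: dict[tuple, dict[str, list[tuple[str, str, str]]]] = {}
    out: dict[str, dict[str, dict[str, int]]] = {}
    for sample_id, sub in gene_counts.groupby("sample_id"):
        cross = crosses[sample_id]
        key = (cross.maternal_founders, cross.paternal_founders)
        if key not in by_config:
            gene_map: dict[str, list[tuple[str, str, str]]] = {}
            for snp in snps:
                pair = parental_alleles(snp, cross)
                if pair is not None:
                    gene_map.setdefault(snp.gene_id, []).append(
                        (snp.snp_id, *pair)
                    )
            by_config[key] = gene_map
        gene_map = by_config[key]
        sample_counts: dict[str, dict[str, int]] = {}
        for row in sub.itertuples(index=False):
            informative = gene_map.get(row.gene_id)
            if not informative:
                continue
            k = len(informative)
            m_split = rng.multinomial(int(row.maternal_reads), [1.0 / k] * k)
            p_split = rng.multinomial(int(row.paternal_reads), [1.0 / k] * k)
            for (snp_id, mat_allele, pat_allele), m, p in zip(
                informative, m_split, p_split
            ):
                if m == 0 and p == 0:
                    continue
                entry = sample_counts.setdefault(snp_id, {})
                if m:
                    entry[mat_allele] = entry.get(mat_allele, 0) + int(m)
                if p:
                    entry[pat_allele] = entry.get(pat_allele, 0) + int(p)
        out[str(sample_id)] = sample_counts
    return out


def simulate_promoters(
    truth: pd.DataFrame,
    config: SimConfig,
    motifs: Sequence[MotifDef] = DEFAULT_MOTIFS,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Uniform-random promoters with explicitly planted motif instances.

    One to three distinct motifs are planted per gene at non-overlapping
    recorded offsets (forward strand, ambiguous consensus positions
    instantiated concretely).  Background hits can occur by chance; only the
    planted instances carry a guarantee of being found.
    """
    rng = _rng(config, _S_PROMOTERS)
    length = config.promoter_length
    promoters: dict[str, str] = {}
    planted_rows = []
    for gene_id in truth.index:
        seq = rng.choice(4, size=length)
        chars = _BASES[seq]
        n_plant = int(rng.integers(1, 4))
        chosen = rng.choice(len(motifs), size=n_plant, replace=False)
        occupied: list[tuple[int, int]] = []
        for mi in chosen:
            motif = motifs[int(mi)]
            w = len(motif.consensus)
            if w > length:
                continue
            for _ in range(50):
                off = int(rng.integers(0, length - w + 1))
                if all(off + w <= s or off >= e for s, e in occupied):
                    break
            else:
                continue
            occupied.append((off, off + w))
            instance = "".join(
                str(rng.choice(list(IUPAC[c]))) for c in motif.consensus
            )
            chars[off : off + w] = list(instance)
            planted_rows.append((gene_id, motif.name, off, "+", instance))
        promoters[str(gene_id)] = "".join(chars)
    planted = pd.DataFrame(
        planted_rows, columns=["gene_id", "motif_name", "offset", "strand", "sequence"]
    )
    return promoters, planted


def simulate_fpkm(
    truth: pd.DataFrame,
    design: Sequence[ReciprocalPair | CrossSpec],
    config: SimConfig,
    noise_sd: float = 0.05,
) -> tuple[pd.DataFrame, pd.Series]:
    """FPKM matrix over the design's samples plus subgroup ground truth.

    Imprinted genes split evenly between an endosperm-primary profile (full
    expression in endosperm samples, ~5% elsewhere) and a constitutive one
    (flat across tissues); all other genes are constitutive.  Multiplicative
    Gaussian noise (sd ``noise_sd``) perturbs every entry.
    """
    rng = _rng(config, _S_FPKM)
    crosses = [c for _, c in _flatten_design(design)]
    sample_ids = [c.sample_id for c in crosses]
    is_endo = np.array([c.tissue == ENDOSPERM for c in crosses])
    imprinted = truth["status"].isin([MEG, PEG]).to_numpy()
    endo_primary = imprinted & (rng.random(len(truth)) < 0.5)
    base = rng.uniform(5.0, 50.0, size=len(truth))
    profile = np.where(
        endo_primary[:, None],
        np.where(is_endo[None, :], 1.0, 0.05),
        1.0,
    )
    noise = np.clip(1.0 + rng.normal(0.0, noise_sd, size=profile.shape), 0.0, None)
    fpkm = pd.DataFrame(
        base[:, None] * profile * noise, index=truth.index, columns=sample_ids
    )
    subgroup = pd.Series(
        np.where(endo_primary, ENDOSPERM_PRIMARY, CONSTITUTIVE),
        index=truth.index,
        name="subgroup",
    )
    return fpkm, subgroup


@dataclass
class Study:
    """Everything one synthetic study produced, with its ground truth."""

    config: SimConfig
    design: list[ReciprocalPair]
    truth: pd.DataFrame
    snps: list[SnpRecord]
    gene_counts: pd.DataFrame
    snp_counts: dict[str, dict[str, dict[str, int]]]
    promoters: dict[str, str]
    planted_motifs: pd.DataFrame
    fpkm: pd.DataFrame
    subgroup_truth: pd.Series

    @property
    def samples(self) -> list[CrossSpec]:
        return design_samples(self.design)


def simulate_study(
    config: SimConfig,
    design: Sequence[ReciprocalPair] | None = None,
    swap_roles: bool = False,
) -> Study:
    """Run the full generator: truth, SNPs, counts, promoters and FPKM."""
    design = list(design) if design is not None else default_design()
    truth = generate_truth(config)
    snps = generate_snps(truth, config)
    gene_counts = simulate_counts(truth, design, config, swap_roles=swap_roles)
    snp_counts = distribute_counts_to_snps(gene_counts, snps, design, config)
    promoters, planted = simulate_promoters(truth, config)
    fpkm, subgroup = simulate_fpkm(truth, design, config)
    return Study(
        config=config,
        design=design,
        truth=truth,
        snps=snps,
        gene_counts=gene_counts,
        snp_counts=snp_counts,
        promoters=promoters,
        planted_motifs=planted,
        fpkm=fpkm,
        subgroup_truth=subgroup,
    )


def emit_fixture_files(study: Study, outdir: str | Path) -> dict[str, Path]:
    """Write a study to disk as the pipeline's input formats plus a manifest.

    Emits founder genotypes (TSV), per-sample SNP counts (TSV), gene models
    (GFF3), promoters (FASTA), the motif table, an FPKM matrix with sample
    metadata, the cross design (YAML), and ``manifest.json`` recording the
    ground truth for assertions.  Output bytes are a deterministic function
    of the study.
    """
    outdir = Path(outdir)
    counts_dir = outdir / "counts"
    counts_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["genotypes"] = outdir / "genotypes.tsv"
    icio.write_genotypes(study.snps, paths["genotypes"])

    genes = study.truth.reset_index()[["gene_id", "chrom", "start", "end"]]
    paths["gff3"] = outdir / "genes.gff3"
    icio.write_gff3_genes(genes, paths["gff3"])

    for sample_id in sorted(study.snp_counts):
        p = counts_dir / f"{sample_id}.counts.tsv"
        rows = [
            (snp_id, allele, n)
            for snp_id in sorted(study.snp_counts[sample_id])
            for allele, n in sorted(study.snp_counts[sample_id][snp_id].items())
        ]
        icio.write_snp_counts(rows, p)
        paths[f"counts/{sample_id}"] = p

    paths["promoters"] = outdir / "promoters.fasta"
    icio.write_fasta(study.promoters, paths["promoters"])

    paths["motifs"] = outdir / "motifs.tsv"
    from .motifs import motif_table

    motif_table().to_csv(paths["motifs"], sep="\t", index=False)

    paths["fpkm"] = outdir / "fpkm.tsv"
    icio.write_fpkm(study.fpkm, paths["fpkm"])

    paths["samples"] = outdir / "samples.tsv"
    pd.DataFrame(
        [
            (c.sample_id, c.name, c.tissue)
            for c in study.samples
        ],
        columns=["sample_id", "cross_name", "tissue"],
    ).to_csv(paths["samples"], sep="\t", index=False)

    paths["crosses"] = outdir / "crosses.yaml"
    write_cross_config(study.design, paths["crosses"])

    manifest = {
        "config": dataclasses.asdict(study.config),
        "truth": {
            gene: {
                "status": row["status"],
                "chrom": row["chrom"],
                "start": int(row["start"]),
                "end": int(row["end"]),
                "theta_embryo": row["theta_embryo"],
                "theta_endosperm": row["theta_endosperm"],
            }
            for gene, row in study.truth.iterrows()
        },
        "planted_motifs": study.planted_motifs.to_dict(orient="records"),
        "subgroup_truth": study.subgroup_truth.to_dict(),
        "samples": [c.sample_id for c in study.samples],
    }
    paths["manifest"] = outdir / "manifest.json"
    icio.write_json(manifest, paths["manifest"])
    return paths
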