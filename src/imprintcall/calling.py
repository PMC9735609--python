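"""MEG/PEG calling from per-gene parental read counts.

The caller tests each gene, in each cross direction, for deviation of the
maternal:paternal read ratio from the tissue null -- 1:1 in the diploid
embryo, 2:1 in the triploid endosperm -- with a Pearson chi-square test
(1 df, no continuity correction).  A gene with fewer than ``min_reads``
allelic reads (default 20) is untestable.  A testable gene is provisionally

* embryo:    MEG if p < alpha and maternal fraction > 2/3;
             PEG if p < alpha and paternal fraction > 2/3;
* endosperm: MEG if p < alpha and maternal fraction > 0.80;
             PEG if p < alpha and paternal fraction > 0.50;

and biallelic otherwise.  Thresholds are strict inequalities.  The two
directions of a reciprocal pair are then combined: by default a gene is
called MEG (PEG) only if both directions independently call MEG (PEG), which
separates parent-of-origin effects from founder-allele effects -- an allele
favoured regardless of its parent of origin produces opposite maternal
fractions in the two directions and is not called imprinted.  If either
direction is untestable the combined call is untestable.  A pooled mode that
sums the two directions' counts before testing is available via
``CallerConfig.combine_mode``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .allele_counts import GeneAlleleCount
from .crosses import ReciprocalPair, expected_maternal_fraction

MEG = "MEG"
PEG = "PEG"
BIALLELIC = "biallelic"
UNTESTABLE = "untestable"
STATUSES = (MEG, PEG, BIALLELIC, UNTESTABLE)


@dataclass(frozen=True)
class CallerConfig:
    """Thresholds of the imprinting caller.

    min_reads: minimum summed allelic reads for a gene to be testable.
    alpha: chi-square significance level (raw p, no multiple-testing
        correction by default; set ``fdr=True`` for Benjamini-Hochberg).
    embryo_fraction: parental fraction a transcript pool must exceed in the
        embryo (2/3, i.e. the ">66%" / 2:1 threshold).
    endo_meg_fraction / endo_peg_paternal_fraction: maternal (paternal)
        fraction thresholds in the endosperm, 0.80 and 0.50.
    combine_mode: "strict_and" (both directions must call the same status)
        or "pooled" (directions' counts summed before one test).
    """

    min_reads: int = 20
    alpha: float = 0.05
    embryo_fraction: float = 2.0 / 3.0
    endo_meg_fraction: float = 0.80
    endo_peg_paternal_fraction: float = 0.50
    combine_mode: str = "strict_and"
    fdr: bool = False

    def __post_init__(self) -> None:
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")
        for name in (
            "alpha",
            "embryo_fraction",
            "endo_meg_fraction",
            "endo_peg_paternal_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.combine_mode not in ("strict_and", "pooled"):
            raise ValueError(f"unknown combine_mode {self.combine_mode!r}")


@dataclass(frozen=True)
class ImprintTestResult:
    """One direction's test: fraction, chi-square, p, and provisional status."""

    gene_id: str
    cross_name: str
    tissue: str
    maternal_reads: int
    paternal_reads: int
    maternal_fraction: float
    chi2: float
    p_value: float
    testable: bool
    status: str


@dataclass(frozen=True)
class ImprintCall:
    """Combined call for one gene over a reciprocal cross pair."""

    gene_id: str
    cross_pair: str
    tissue: str
    status: str
    direction1: ImprintTestResult
    direction2: ImprintTestResult


def chi2_dosage_test(maternal, paternal, tissue: str):
    """Pearson chi-square (1 df) of observed parental counts against the
    tissue dosage null.

    Expected counts are (n*f, n*(1-f)) with f = 1/2 in embryo and 2/3 in
    endosperm.  Accepts scalars or arrays; returns (chi2, p_value) of the
    same shape.  A zero total is an error: untestable genes must be filtered
    before testing.
    """
    f = expected_maternal_fraction(tissue)
    m = np.asarray(maternal, dtype=float)
    p = np.asarray(paternal, dtype=float)
    n = m + p
    if np.any(n < 1):
        raise ValueError("chi2_dosage_test requires maternal + paternal >= 1")
    exp_m = n * f
    exp_p = n * (1.0 - f)
    chi2 = (m - exp_m) ** 2 / exp_m + (p - exp_p) ** 2 / exp_p
    pval = stats.chi2.sf(chi2, df=1)
    if np.isscalar(maternal) and np.isscalar(paternal):
        return float(chi2), float(pval)
    return chi2, pval


def _classify_arrays(
    maternal: np.ndarray, paternal: np.ndarray, tissue: str, cfg: CallerConfig
) -> pd.DataFrame:
    """Vectorised single-direction classification."""
    m = np.asarray(maternal, dtype=float)
    p = np.asarray(paternal, dtype=float)
    total = m + p
    testable = total >= cfg.min_reads

    frac = np.full_like(total, np.nan)
    pfrac = np.full_like(total, np.nan)  # p/n directly, so exact threshold
    chi2 = np.full_like(total, np.nan)  # ties resolve identically for both
    pval = np.full_like(total, np.nan)  # parents (1 - m/n rounds differently)
    nz = total >= 1
    np.divide(m, total, out=frac, where=nz)
    np.divide(p, total, out=pfrac, where=nz)
    if nz.any():
        chi2[nz], pval[nz] = chi2_dosage_test(m[nz], p[nz], tissue)

    p_sig = pval
    if cfg.fdr and nz.any():
        p_sig = np.full_like(pval, np.nan)
        p_sig[nz] = stats.false_discovery_control(pval[nz])
    sig = p_sig < cfg.alpha
    if tissue == "embryo":
        is_meg = sig & (frac > cfg.embryo_fraction)
        is_peg = sig & (pfrac > cfg.embryo_fraction)
    else:
        is_meg = sig & (frac > cfg.endo_meg_fraction)
        is_peg = sig & (pfrac > cfg.endo_peg_paternal_fraction)

    status = np.select(
        [~testable, is_meg, is_peg],
        [UNTESTABLE, MEG, PEG],
        default=BIALLELIC,
    )
    return pd.DataFrame(
        {
            "maternal_reads": m.astype(int),
            "paternal_reads": p.astype(int),
            "maternal_fraction": frac,
            "chi2": chi2,
            "p_value": pval,
            "testable": testable,
            "status": status,
        }
    )


def classify_direction(
    count: GeneAlleleCount, tissue: str, cfg: CallerConfig | None = None
) -> ImprintTestResult:
    """Classify one gene in one cross direction (MEG/PEG/biallelic/untestable)."""
    cfg = cfg or CallerConfig()
    row = _classify_arrays(
        np.array([count.maternal_reads]),
        np.array([count.paternal_reads]),
        tissue,
        cfg,
    ).iloc[0]
    return ImprintTestResult(
        gene_id=count.gene_id,
        cross_name=count.sample_id,
        tissue=tissue,
        maternal_reads=count.maternal_reads,
        paternal_reads=count.paternal_reads,
        maternal_fraction=float(row["maternal_fraction"]),
        chi2=float(row["chi2"]),
        p_value=float(row["p_value"]),
        testable=bool(row["testable"]),
        status=str(row["status"]),
    )


def combine_reciprocal(
    dir1: ImprintTestResult,
    dir2: ImprintTestResult,
    cfg: CallerConfig | None = None,
    cross_pair: str | None = None,
) -> ImprintCall:
    """Combine the two directions of a reciprocal pair for one gene.

    MEG iff both directions call MEG; PEG iff both call PEG; untestable iff
    either direction is untestable; otherwise biallelic.  Because maternal
    fraction is computed per direction, a founder-allele effect (the same
    founder's allele favoured in both directions) shows opposite fractions
    and falls through to biallelic.
    """
    cfg = cfg or CallerConfig()
    if dir1.gene_id != dir2.gene_id or dir1.tissue != dir2.tissue:
        raise ValueError(
            f"cannot combine mismatched directions: "
            f"{dir1.gene_id}/{dir1.tissue} vs {dir2.gene_id}/{dir2.tissue}"
        )
    status = _combine_statuses(dir1.status, dir2.status)
    return ImprintCall(
        gene_id=dir1.gene_id,
        cross_pair=cross_pair or f"{dir1.cross_name}/{dir2.cross_name}",
        tissue=dir1.tissue,
        status=status,
        direction1=dir1,
        direction2=dir2,
    )


def _combine_statuses(s1: str, s2: str) -> str:
    if s1 == UNTESTABLE or s2 == UNTESTABLE:
        return UNTESTABLE
    if s1 == s2 and s1 in (MEG, PEG):
        return s1
    return BIALLELIC


def _direction_frame(
    counts: pd.DataFrame, sample_id: str, pair: ReciprocalPair
) -> pd.DataFrame:
    sub = counts.loc[counts["sample_id"] == sample_id]
    if sub.empty:
        raise ValueError(
            f"missing direction {sample_id!r} for cross pair {pair.name!r} "
            f"({pair.tissue})"
        )
    if sub["gene_id"].duplicated().any():
        dups = sorted(sub.loc[sub["gene_id"].duplicated(), "gene_id"].unique())
        raise ValueError(
            f"duplicate gene rows in sample {sample_id!r}: {dups[:5]}"
        )
    return sub.set_index("gene_id")


def call_pair(
    counts: pd.DataFrame, pair: ReciprocalPair, cfg: CallerConfig | None = None
) -> pd.DataFrame:
    """Vectorised calls for every gene of one reciprocal pair.

    ``counts`` is a tidy frame with columns sample_id, gene_id,
    maternal_reads, paternal_reads.  A gene present in only one direction is
    treated as having zero reads (hence untestable) in the other.
    """
    cfg = cfg or CallerConfig()
    d1 = _direction_frame(counts, pair.direction1.sample_id, pair)
    d2 = _direction_frame(counts, pair.direction2.sample_id, pair)
    genes = d1.index.union(d2.index)
    m1 = d1["maternal_reads"].reindex(genes, fill_value=0).to_numpy()
    p1 = d1["paternal_reads"].reindex(genes, fill_value=0).to_numpy()
    m2 = d2["maternal_reads"].reindex(genes, fill_value=0).to_numpy()
    p2 = d2["paternal_reads"].reindex(genes, fill_value=0).to_numpy()

    c1 = _classify_arrays(m1, p1, pair.tissue, cfg)
    c2 = _classify_arrays(m2, p2, pair.tissue, cfg)

    if cfg.combine_mode == "pooled":
        pooled = _classify_arrays(m1 + m2, p1 + p2, pair.tissue, cfg)
        status = pooled["status"].to_numpy()
    else:
        status = np.array(
            [_combine_statuses(a, b) for a, b in zip(c1["status"], c2["status"])]
        )

    out = pd.DataFrame({"gene_id": genes, "cross_pair": pair.name, "tissue": pair.tissue})
    out["status"] = status
    for tag, frame in (("1", c1), ("2", c2)):
        for col in ("maternal_reads", "paternal_reads", "maternal_fraction", "chi2", "p_value", "testable", "status"):
            out[f"{col}_{tag}"] = frame[col].to_numpy()
    return out


def call_all(
    counts: pd.DataFrame,
    design: Sequence[ReciprocalPair],
    cfg: CallerConfig | None = None,
) -> pd.DataFrame:
    """Calls for every gene in every reciprocal pair of a design."""
    cfg = cfg or CallerConfig()
    frames = [call_pair(counts, pair, cfg) for pair in design]
    return pd.concat(frames, ignore_index=True)


def summarize_calls(calls: pd.DataFrame) -> dict:
    """MEG/PEG tallies per (cross pair, tissue) and embryo/endosperm overlap.

    The overlap lists genes called imprinted in both tissues of the same
    cross pair.
    """
    summary: dict = {"pairs": {}, "tissue_overlap": {}}
    for (pair, tissue), sub in calls.groupby(["cross_pair", "tissue"]):
        tallies = sub["status"].value_counts().to_dict()
        summary["pairs"][f"{pair}|{tissue}"] = {s: int(tallies.get(s, 0)) for s in STATUSES}
    imprinted = calls[calls["status"].isin([MEG, PEG])]
    for pair, sub in imprinted.groupby("cross_pair"):
        by_tissue = {
            t: set(g["gene_id"]) for t, g in sub.groupby("tissue")
        }
        both = sorted(
            by_tissue.get("embryo", set()) & by_tissue.get("endosperm", set())
        )
        summary["tissue_overlap"][pair] = {
            "embryo": sorted(by_tissue.get("embryo", set())),
            "endosperm": sorted(by_tissue.get("endosperm", set())),
            "both": both,
        }
    return summary
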