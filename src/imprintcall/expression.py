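"""Relative expression and endosperm-primary vs constitutive subgrouping.

A gene's relative expression is its FPKM divided by its maximum FPKM over
all samples, so every row lies in [0, 1] with a maximum of 1 (all-zero rows
stay zero).  Imprinted genes are then split into two subgroups by
agglomerative hierarchical clustering of the relative-expression rows
(average linkage, Euclidean distance, tree cut at k clusters, default 2):
the cluster whose mean relative expression in endosperm samples most exceeds
its mean elsewhere -- provided that margin is positive -- is labelled
endosperm-primary, all other genes constitutive.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

ENDOSPERM_PRIMARY = "endosperm_primary"
CONSTITUTIVE = "constitutive"


def relative_expression(fpkm: pd.DataFrame) -> pd.DataFrame:
    """Row-normalise an FPKM matrix by each gene's maximum over samples."""
    if fpkm.empty:
        raise ValueError("expression matrix is empty")
    values = fpkm.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError("FPKM values must be non-negative")
    row_max = values.max(axis=1, keepdims=True)
    safe = np.where(row_max > 0, row_max, 1.0)  # all-zero rows stay zero
    return pd.DataFrame(values / safe, index=fpkm.index, columns=fpkm.columns)


def cluster_subgroups(
    rel: pd.DataFrame,
    sample_tissues: Mapping[str, str],
    k: int = 2,
    endosperm_tissue: str = "endosperm",
) -> pd.Series:
    """Assign each gene to the endosperm-primary or constitutive subgroup.

    ``rel`` is a relative-expression matrix (genes x samples);
    ``sample_tissues`` maps each sample id to its tissue.  Genes are sorted
    by id before linkage so the result is invariant to input order; the
    returned Series follows the input order.
    """
    missing = [s for s in rel.columns if s not in sample_tissues]
    if missing:
        raise ValueError(f"samples without tissue labels: {missing}")
    if len(rel) < 2:
        warnings.warn("fewer than 2 genes; all assigned constitutive")
        return pd.Series(CONSTITUTIVE, index=rel.index, name="subgroup")

    ordered = rel.sort_index(kind="mergesort")
    x = ordered.to_numpy(dtype=float)
    dist = pdist(x, metric="euclidean")
    link = hierarchy.linkage(dist, method="average")
    labels = hierarchy.fcluster(link, t=k, criterion="maxclust")

    is_endo = np.array(
        [sample_tissues[s] == endosperm_tissue for s in ordered.columns]
    )
    if not is_endo.any() or is_endo.all():
        raise ValueError("need both endosperm and non-endosperm samples")

    margins = {}
    for cl in np.unique(labels):
        rows = x[labels == cl]
        margins[cl] = rows[:, is_endo].mean() - rows[:, ~is_endo].mean()
    best = max(sorted(margins), key=lambda cl: margins[cl])
    assignment = np.where(
        (labels == best) & (margins[best] > 0), ENDOSPERM_PRIMARY, CONSTITUTIVE
    )
    out = pd.Series(assignment, index=ordered.index, name="subgroup")
    return out.reindex(rel.index)


def average_linkage_heights(rel: pd.DataFrame) -> np.ndarray:
    """Merge heights of the average-linkage dendrogram (sorted ascending)."""
    ordered = rel.sort_index(kind="mergesort")
    link = hierarchy.linkage(pdist(ordered.to_numpy(float)), method="average")
    return np.sort(link[:, 2])
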