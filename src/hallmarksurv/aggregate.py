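"""Cross-tumor aggregation of scan results.

Builds the hallmark-by-tumor significance matrix (percentage of each
hallmark's scanned genes that are prognostic in each tumor type), clusters
it hierarchically on either axis, and lists features that are prognostic in
many tumor types.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .containers import GeneSetCollection
from .errors import EstimationError
from .survival import CutoffScanResult

__all__ = [
    "SignificanceMatrix",
    "Dendrogram",
    "significance_matrix",
    "hierarchical_cluster",
    "recurrent_features",
]

logger = logging.getLogger(__name__)

#: scans are keyed tumor -> feature -> CutoffScanResult
ScanCollection = Mapping[str, Mapping[str, CutoffScanResult]]


@dataclass(frozen=True)
class SignificanceMatrix:
    """Hallmark-by-tumor percentages with their numerators/denominators.

    ``percent`` holds 100 * numerator / denominator; cells where no member
    gene of the hallmark was scanned in the tumor are missing (NaN), never
    zero.
    """

    percent: pd.DataFrame
    numerator: pd.DataFrame
    denominator: pd.DataFrame


def significance_matrix(
    scans: ScanCollection, sets: GeneSetCollection
) -> SignificanceMatrix:
    """Percentage of each hallmark's scanned genes significant per tumor.

    A gene belonging to several hallmarks counts in each of them; only
    evaluable scans enter the denominator.
    """
    tumors = sorted(scans.keys())
    names = list(sets.names)
    numerator = pd.DataFrame(0.0, index=names, columns=tumors)
    denominator = pd.DataFrame(0.0, index=names, columns=tumors)
    for tumor in tumors:
        per_gene = scans[tumor]
        for name in names:
            members = sets[name].genes
            scanned = [
                per_gene[g] for g in members if g in per_gene and per_gene[g].evaluable
            ]
            denominator.loc[name, tumor] = len(scanned)
            numerator.loc[name, tumor] = sum(1 for s in scanned if s.significant)
    with np.errstate(invalid="ignore", divide="ignore"):
        percent = 100.0 * numerator / denominator
    percent = percent.where(denominator > 0)  # unscanned cells stay missing
    percent.index.name = numerator.index.name = denominator.index.name = "hallmark"
    return SignificanceMatrix(percent=percent, numerator=numerator, denominator=denominator)


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge history over labeled leaves."""

    labels: tuple[str, ...]
    linkage: np.ndarray  # scipy linkage matrix
    leaf_order: tuple[int, ...]

    def to_newick(self) -> str:
        """Serialize the merge tree with branch lengths derived from merge
        heights (each child branch spans the height difference)."""
        n = len(self.labels)
        heights = {i: 0.0 for i in range(n)}
        newick = {i: self.labels[i] for i in range(n)}
        for k, (a, b, height, _) in enumerate(self.linkage):
            a, b = int(a), int(b)
            la = max(height - heights[a], 0.0)
            lb = max(height - heights[b], 0.0)
            node = n + k
            newick[node] = f"({newick[a]}:{la:.6g},{newick[b]}:{lb:.6g})"
            heights[node] = float(height)
        return newick[n + len(self.linkage) - 1] + ";"


def hierarchical_cluster(
    matrix: SignificanceMatrix,
    axis: str = "hallmarks",
    distance: str = "euclidean",
    linkage: str = "average",
) -> Dendrogram:
    """Agglomeratively cluster the significance matrix on one axis.

    ``axis='hallmarks'`` clusters rows, ``axis='tumors'`` clusters columns.
    Missing cells are imputed as 0 for the distance computation only (with a
    warning); the stored matrix is untouched. ``distance='correlation'``
    uses 1 - Pearson correlation.
    """
    if axis == "hallmarks":
        frame = matrix.percent
    elif axis == "tumors":
        frame = matrix.percent.T
    else:
        raise ValueError(f"axis must be 'hallmarks' or 'tumors', got {axis!r}")
    if frame.shape[0] < 2:
        raise EstimationError("need at least 2 rows to cluster")
    if distance not in ("euclidean", "correlation"):
        raise ValueError(f"unsupported distance {distance!r}")
    if linkage not in ("average", "complete", "single"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    values = frame.to_numpy(dtype=float)
    if np.isnan(values).any():
        logger.warning(
            "imputing %d missing cells as 0 for clustering", int(np.isnan(values).sum())
        )
        values = np.nan_to_num(values, nan=0.0)
    dists = pdist(values, metric=distance)
    dists = np.nan_to_num(dists, nan=0.0)  # correlation of constant rows
    link = hierarchy.linkage(dists, method=linkage)
    order = hierarchy.leaves_list(link)
    return Dendrogram(
        labels=tuple(frame.index),
        linkage=link,
        leaf_order=tuple(int(i) for i in order),
    )


def recurrent_features(
    scans: ScanCollection,
    min_tumors: int = 10,
) -> pd.DataFrame:
    """Features significant in at least ``min_tumors`` tumor types.

    Returns a frame indexed by feature with columns ``n_significant``
    (tumor types where the feature was called significant), ``n_scanned``
    and ``best_p`` (the smallest best-cutoff p across tumors), sorted by
    count descending then best p ascending.
    """
    if len(scans) < min_tumors:
        raise EstimationError(
            f"{len(scans)} tumor types present, fewer than min_tumors={min_tumors}"
        )
    features: dict[str, dict] = {}
    for tumor, per_gene in scans.items():
        for feature, scan in per_gene.items():
            entry = features.setdefault(
                feature, {"n_significant": 0, "n_scanned": 0, "best_p": np.inf}
            )
            if scan.evaluable:
                entry["n_scanned"] += 1
                if scan.significant:
                    entry["n_significant"] += 1
                if scan.best_p is not None:
                    entry["best_p"] = min(entry["best_p"], scan.best_p)
    frame = pd.DataFrame.from_dict(features, orient="index")
    if frame.empty:
        frame = pd.DataFrame(columns=["n_significant", "n_scanned", "best_p"])
    frame.index.name = "feature"
    frame = frame[frame["n_significant"] >= min_tumors]
    frame = frame.sort_values(
        by=["n_significant", "best_p"], ascending=[False, True], kind="stable"
    )
    return frame
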