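"""Two-phenotype gene set enrichment analysis keyed to the survival cutoff.

Phenotype labels come from dichotomizing a selected gene's expression at a
cutoff (by design the best cutoff found by the survival scan, so the GSEA
groups coincide with the survival groups). Genes are ranked by the
signal-to-noise metric between the high and low classes, and each set's
enrichment score (ES) is the signed extremum of the weighted
Kolmogorov-Smirnov running sum: set members ("hits") add their
|metric|^p weight normalized by the total hit weight, non-members
("misses") subtract 1/(N - Nh). Significance is assessed by phenotype
permutation with a same-sign, add-one p-value estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .errors import EstimationError

__all__ = [
    "RankedGeneList",
    "EnrichmentResult",
    "phenotype_labels",
    "rank_genes",
    "enrichment_score",
    "permutation_pvalue",
]

#: Relative floor on each class standard deviation, as in the classic
#: signal-to-noise metric: sd >= max(0.2 * |class mean|, tiny constant).
SD_FLOOR_FRACTION = 0.2
SD_FLOOR_MIN = 1e-8


@dataclass(frozen=True)
class RankedGeneList:
    """Genes ordered by ranking metric, descending; ties break by gene id."""

    gene_ids: tuple[str, ...]
    metric: np.ndarray
    phenotype: str = ""

    def __post_init__(self) -> None:
        if len(self.gene_ids) != len(self.metric):
            raise EstimationError("gene ids and metric values differ in length")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise EstimationError("duplicate gene ids in ranked list")

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    es: float
    nominal_p: float
    n_permutations: int
    seed: int | None = None


def phenotype_labels(expr: ExpressionMatrix, gene: str, cutoff: float) -> pd.Series:
    """High/low sample labels at a cutoff: high iff expression > cutoff
    (same tie convention as the survival scan: ties go low)."""
    if gene not in expr.data.index:
        raise EstimationError(f"gene {gene!r} not in expression matrix")
    values = expr.data.loc[gene]
    labels = pd.Series(
        np.where(values > cutoff, "high", "low"), index=values.index, name=gene
    )
    return labels


def _signal_to_noise(values: np.ndarray, high_mask: np.ndarray) -> np.ndarray:
    """Per-gene signal-to-noise: (mean_high - mean_low)/(sd_high + sd_low),
    with each class sd floored at max(0.2 |class mean|, tiny)."""
    high = values[:, high_mask]
    low = values[:, ~high_mask]
    mean_h = high.mean(axis=1)
    mean_l = low.mean(axis=1)
    sd_h = high.std(axis=1, ddof=1)
    sd_l = low.std(axis=1, ddof=1)
    sd_h = np.maximum(sd_h, np.maximum(SD_FLOOR_FRACTION * np.abs(mean_h), SD_FLOOR_MIN))
    sd_l = np.maximum(sd_l, np.maximum(SD_FLOOR_FRACTION * np.abs(mean_l), SD_FLOOR_MIN))
    return (mean_h - mean_l) / (sd_h + sd_l)


def rank_genes(expr: ExpressionMatrix, labels: pd.Series) -> RankedGeneList:
    """Rank all genes by signal-to-noise between high and low classes.

    Raises
    ------
    EstimationError
        If either class has fewer than 3 samples.
    """
    labels = labels.reindex(expr.data.columns)
    if labels.isna().any():
        raise EstimationError("labels missing for some samples")
    high_mask = (labels == "high").to_numpy()
    if high_mask.sum() < 3 or (~high_mask).sum() < 3:
        raise EstimationError("each phenotype class needs >= 3 samples")
    metric = _signal_to_noise(expr.data.to_numpy(dtype=float), high_mask)
    order = np.lexsort((np.asarray(expr.gene_ids), -metric))
    return RankedGeneList(
        gene_ids=tuple(np.asarray(expr.gene_ids)[order]),
        metric=metric[order],
        phenotype=str(labels.name or ""),
    )


def enrichment_score(
    ranked: RankedGeneList,
    gene_set: Sequence[str] | set[str],
    weight_p: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Weighted KS enrichment score and the full running sum.

    Hits increment the running sum by |metric|^p normalized by the sum over
    hits; misses decrement by 1/(N - Nh). The ES is the running sum value
    of largest magnitude (sign kept).

    Raises
    ------
    EstimationError
        If no set member is in the ranked list, or the set covers it
        entirely (the miss penalty is then undefined).
    """
    members = set(gene_set)
    hit = np.array([g in members for g in ranked.gene_ids])
    n = len(ranked)
    n_hits = int(hit.sum())
    if n_hits == 0:
        raise EstimationError("no gene set member present in the ranked list")
    if n_hits == n:
        raise EstimationError("gene set covers the entire ranked list")
    weights = np.abs(ranked.metric) ** weight_p
    hit_weights = np.where(hit, weights, 0.0)
    total_hit_weight = hit_weights.sum()
    if total_hit_weight <= 0:
        # all hit metrics are exactly zero: fall back to equal hit weights
        hit_weights = hit.astype(float)
        total_hit_weight = hit_weights.sum()
    steps = hit_weights / total_hit_weight - (~hit) / (n - n_hits)
    running = np.cumsum(steps)
    # signed extremum; a magnitude tie (to float tolerance) resolves to the
    # positive peak so the sign is deterministic
    peak = float(running.max())
    trough = float(running.min())
    es = peak if peak + trough >= -1e-9 else trough
    return es, running


def permutation_pvalue(
    expr: ExpressionMatrix,
    labels: pd.Series,
    gene_set: Sequence[str] | set[str],
    n_permutations: int = 1000,
    seed: int | None = None,
    weight_p: float = 1.0,
    set_name: str = "",
) -> EnrichmentResult:
    """Phenotype-permutation nominal p-value for one gene set.

    The observed ES is compared with the ES distribution under random
    reassignment of the high/low labels (class sizes preserved). The
    nominal p is the add-one estimator over same-sign permutations:
    p = (1 + #{ES_perm same sign, |ES_perm| >= |ES|}) / (1 + #same-sign).

    Raises
    ------
    EstimationError
        If ``n_permutations`` < 100 (the estimator is too coarse below).
    """
    if n_permutations < 100:
        raise EstimationError("need at least 100 permutations")
    labels = labels.reindex(expr.data.columns)
    ranked = rank_genes(expr, labels)
    observed, _ = enrichment_score(ranked, gene_set, weight_p=weight_p)

    values = expr.data.to_numpy(dtype=float)
    gene_ids = np.asarray(expr.gene_ids)
    members = set(gene_set)
    high_mask = (labels == "high").to_numpy()
    n_high = int(high_mask.sum())
    rng = np.random.default_rng(seed)
    same_sign = 0
    as_extreme = 0
    for _ in range(n_permutations):
        perm = np.zeros(len(high_mask), dtype=bool)
        perm[rng.choice(len(high_mask), size=n_high, replace=False)] = True
        metric = _signal_to_noise(values, perm)
        order = np.lexsort((gene_ids, -metric))
        perm_ranked = RankedGeneList(
            gene_ids=tuple(gene_ids[order]), metric=metric[order]
        )
        es_perm, _ = enrichment_score(perm_ranked, members, weight_p=weight_p)
        if np.sign(es_perm) == np.sign(observed) or observed == 0.0:
            same_sign += 1
            if abs(es_perm) >= abs(observed):
                as_extreme += 1
    nominal_p = (1 + as_extreme) / (1 + same_sign)
    return EnrichmentResult(
        set_name=set_name or "gene_set",
        es=observed,
        nominal_p=float(nominal_p),
        n_permutations=n_permutations,
        seed=seed,
    )
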