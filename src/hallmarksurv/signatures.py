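"""Hallmark signature scoring.

A hallmark's surrogate expression signature in a sample is the unweighted
arithmetic mean of the normalized expression of the hallmark's member genes
(those present in the matrix). Scores stay on the linear mean-rescaled
scale: no z-scoring and no log transform, so a score of 1000 means the
hallmark's genes sit at the average expression of the sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .containers import ExpressionMatrix, GeneSetCollection
from .errors import EstimationError

__all__ = ["SignatureMatrix", "signature_scores"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SignatureMatrix:
    """Per-set, per-sample signature scores.

    ``scores`` is set-by-sample; ``genes_used`` counts the member genes
    found in the expression matrix for each scored set; ``skipped`` maps
    each unscored set to the members that were missing.
    """

    scores: pd.DataFrame
    genes_used: pd.Series
    skipped: dict[str, list[str]]

    @property
    def set_names(self) -> list[str]:
        return list(self.scores.index)


def signature_scores(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    min_genes: int = 2,
) -> SignatureMatrix:
    """Score every gene set as the mean expression of its present members.

    Sets with fewer than ``min_genes`` members present in ``expr`` are
    excluded (with a logged warning listing the missing symbols) rather
    than scored on too little evidence.

    Raises
    ------
    EstimationError
        If no set has at least ``min_genes`` present members.
    """
    if len(sets) == 0:
        raise EstimationError("empty gene set collection")
    present = set(expr.gene_ids)
    rows = {}
    genes_used = {}
    skipped: dict[str, list[str]] = {}
    for name in sets:
        members = sets[name].genes
        found = [g for g in members if g in present]
        if len(found) < min_genes:
            missing = [g for g in members if g not in present]
            skipped[name] = missing
            logger.warning(
                "signature %r skipped: %d member(s) present (< %d); missing: %s",
                name, len(found), min_genes, ", ".join(missing),
            )
            continue
        rows[name] = expr.data.loc[found].mean(axis=0)
        genes_used[name] = len(found)
    if not rows:
        raise EstimationError(
            f"no gene set has >= {min_genes} members in the expression matrix"
        )
    scores = pd.DataFrame(rows).T
    scores.index.name = "set_name"
    return SignatureMatrix(
        scores=scores,
        genes_used=pd.Series(genes_used, name="genes_used"),
        skipped=skipped,
    )
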