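"""Tumor mutation burden (TMB) from MAF-derived mutation tables.

TMB here is the raw per-sample count of qualifying somatic variants; by
default the qualifying classes are the non-silent MAF classes (missense,
nonsense, nonstop, frameshift and in-frame indels, splice site, translation
start). No per-megabase normalization is applied unless an exome size is
supplied. The burden is then treated like any other continuous feature in
the cutoff scan.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .containers import MAF_VARIANT_CLASSES, NON_SILENT_CLASSES, MutationTable
from .errors import ConfigurationError
from .survival import CutoffScanResult, SurvivalEndpoint, cutoff_scan

__all__ = ["TmbVector", "compute_tmb", "tmb_scan"]


@dataclass(frozen=True)
class TmbVector:
    """Per-sample qualifying-variant counts and the class filter used."""

    counts: pd.Series
    qualifying_classes: frozenset[str]

    def per_megabase(self, target_size_mb: float) -> pd.Series:
        if target_size_mb <= 0:
            raise ConfigurationError("target size must be positive (megabases)")
        return self.counts / target_size_mb


def compute_tmb(
    mutations: MutationTable,
    samples: Sequence[str],
    qualifying_classes: Sequence[str] | frozenset[str] = NON_SILENT_CLASSES,
) -> TmbVector:
    """Count qualifying variants per sample.

    Every sample in ``samples`` is present in the result (zero when it has
    no records). Multiple records for the same sample-gene-class triple all
    count: a MAF may legitimately hold several distinct positions.

    Raises
    ------
    ConfigurationError
        If a qualifying class is not in the MAF vocabulary.
    """
    classes = frozenset(qualifying_classes)
    unknown = classes - MAF_VARIANT_CLASSES
    if unknown:
        raise ConfigurationError(
            f"unknown variant classes {sorted(unknown)}; "
            "must come from the MAF vocabulary"
        )
    records = mutations.data
    qualifying = records[records["variant_classification"].isin(classes)]
    counts = qualifying.groupby("sample_id").size()
    counts = counts.reindex(pd.Index(samples, name="sample_id"), fill_value=0).astype(int)
    counts.name = "tmb"
    return TmbVector(counts=counts, qualifying_classes=classes)


def tmb_scan(
    tmb: TmbVector,
    endpoint: SurvivalEndpoint,
    fdr_threshold: float = 0.10,
    min_group: int = 1,
) -> CutoffScanResult:
    """Run the optimal-cutoff scan on the mutation burden."""
    return cutoff_scan(
        tmb.counts.astype(float),
        endpoint,
        fdr_threshold=fdr_threshold,
        min_group=min_group,
        feature_id="TMB",
    )
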