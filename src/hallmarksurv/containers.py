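"""In-memory containers for the pipeline's domain objects.

All tabular containers wrap a :class:`pandas.DataFrame` and validate their
invariants on construction, so downstream stages can assume well-formed
input. Matrices are gene-by-sample (genes on rows).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "ClinicalTable",
    "MutationTable",
    "GeneSet",
    "GeneSetCollection",
    "MAF_VARIANT_CLASSES",
    "NON_SILENT_CLASSES",
    "CLINICAL_COLUMNS",
]

#: Controlled Variant_Classification vocabulary of the MAF standard.
MAF_VARIANT_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Frame_Shift_Ins",
        "Frame_Shift_Del",
        "In_Frame_Ins",
        "In_Frame_Del",
        "Splice_Site",
        "Splice_Region",
        "Translation_Start_Site",
        "Silent",
        "Intron",
        "3'UTR",
        "5'UTR",
        "3'Flank",
        "5'Flank",
        "IGR",
        "RNA",
        "Targeted_Region",
        "De_novo_Start_InFrame",
        "De_novo_Start_OutOfFrame",
    }
)

#: Default "qualifying" (non-silent) classes used for mutation burden and
#: mutant/wild-type grouping.
NON_SILENT_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Frame_Shift_Ins",
        "Frame_Shift_Del",
        "In_Frame_Ins",
        "In_Frame_Del",
        "Splice_Site",
        "Translation_Start_Site",
    }
)

#: Canonical clinical column order (sample_id is the index).
CLINICAL_COLUMNS = [
    "os_time",
    "os_event",
    "rfs_time",
    "rfs_event",
    "sex",
    "race",
    "stage",
    "grade",
    "age",
]


def _check_unique(values, what: str) -> None:
    seen = pd.Index(values)
    if seen.has_duplicates:
        dupes = seen[seen.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dupes[:5]}")


@dataclass(frozen=True)
class CountMatrix:
    """Raw nonnegative integer gene-by-sample counts."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        _check_unique(df.index, "gene ids")
        _check_unique(df.columns, "sample ids")
        if df.shape[0] < 1 or df.shape[1] < 2:
            raise ValidationError(
                f"count matrix needs >= 1 gene and >= 2 samples, got {df.shape}"
            )
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if np.any(~np.isfinite(values)):
            raise ValidationError("counts must be finite")
        if np.any(values < 0):
            raise ValidationError("counts must be nonnegative")
        if np.any(values != np.floor(values)):
            raise ValidationError("counts must be integral")
        object.__setattr__(self, "data", df.astype(np.int64))

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass(frozen=True)
class ExpressionMatrix:
    """Normalized gene-by-sample expression values.

    ``stage`` records how far through the two-step normalization the
    matrix is: ``size_factor_normalized`` (depth-corrected) or
    ``mean_rescaled`` (each sample's mean over all genes set to a common
    target, 1000 by default).
    """

    data: pd.DataFrame
    stage: str

    _STAGES = ("size_factor_normalized", "mean_rescaled")

    def __post_init__(self) -> None:
        if self.stage not in self._STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}")
        _check_unique(self.data.index, "gene ids")
        _check_unique(self.data.columns, "sample ids")
        values = self.data.to_numpy(dtype=float)
        if np.any(~np.isfinite(values)) or np.any(values < 0):
            raise ValidationError("expression values must be finite and nonnegative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass(frozen=True)
class ClinicalTable:
    """Per-sample survival endpoints and clinical covariates.

    The underlying frame is indexed by sample id, with months-scale
    ``os_time``/``rfs_time``, 0/1 event indicators, ``sex`` in {F, M},
    free-text ``race``, ordinal ``stage`` in 0..4, ``grade`` in
    {low, high}, and ``age`` in years. Any field may be missing (NaN/None).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        _check_unique(df.index, "sample ids")
        missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"clinical table lacks columns {missing}")
        for time_col, event_col in (("os_time", "os_event"), ("rfs_time", "rfs_event")):
            t = df[time_col]
            e = df[event_col]
            bad = t.notna() & e.isna()
            if bad.any():
                raise ValidationError(
                    f"{time_col} present but {event_col} missing for "
                    f"samples {list(df.index[bad])[:5]}"
                )
            if (t.dropna() < 0).any():
                raise ValidationError(f"negative {time_col}")
            if np.isinf(t.dropna().to_numpy(dtype=float)).any():
                raise ValidationError(f"non-finite {time_col}")
            events = e.dropna()
            if not events.isin([0, 1]).all():
                raise ValidationError(f"{event_col} must be 0/1")
        stage = df["stage"].dropna()
        if len(stage) and not stage.isin([0, 1, 2, 3, 4]).all():
            raise ValidationError("stage must be ordinal 0..4")
        age = df["age"].dropna()
        if len(age) and (age <= 0).any():
            raise ValidationError("age must be positive")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def endpoint(self, name: str) -> pd.DataFrame:
        """Return the (time, event) frame for endpoint ``'os'`` or ``'rfs'``,
        restricted to samples where both are present."""
        name = name.lower()
        if name not in ("os", "rfs"):
            raise ValueError(f"unknown endpoint {name!r}")
        sub = self.data[[f"{name}_time", f"{name}_event"]].dropna()
        sub.columns = ["time", "event"]
        return sub


@dataclass(frozen=True)
class MutationTable:
    """Somatic mutation records: one row per (sample, gene, variant class)."""

    data: pd.DataFrame

    REQUIRED = ("sample_id", "gene_symbol", "variant_classification")

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"mutation table lacks columns {missing}")
        unknown = set(df["variant_classification"]) - MAF_VARIANT_CLASSES
        if unknown:
            raise ValidationError(
                f"variant_classification outside the MAF vocabulary: {sorted(unknown)[:5]}"
            )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def samples(self) -> list[str]:
        return sorted(self.data["sample_id"].unique())


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


@dataclass(frozen=True)
class GeneSetCollection(Mapping):
    """Named gene sets; membership may overlap between sets."""

    sets: tuple[GeneSet, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        _check_unique([s.name for s in self.sets], "gene set names")

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    def __iter__(self) -> Iterator[str]:
        return iter(s.name for s in self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]
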