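"""Shared fixtures: small synthetic cohorts and toy tables, all generated
programmatically at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hallmarksurv.containers import ClinicalTable, CountMatrix, ExpressionMatrix, MutationTable
from hallmarksurv.io import example_hallmarks
from hallmarksurv.survival import SurvivalEndpoint
from hallmarksurv.synthetic import PlantedEffect, SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def hallmark_sets():
    return example_hallmarks()


@pytest.fixture(scope="session")
def planted_cohort():
    """120-sample cohort with one strong planted prognostic gene (G00001,
    HR 3 above its 0.6 expression quantile) and one mutated gene."""
    config = SimulationConfig(
        n_samples=120,
        n_genes=60,
        seed=11,
        censoring_fraction_target=0.3,
        planted_effects=(PlantedEffect("G00001", 0.6, 3.0),),
    )
    counts, clinical, mutations, truth = simulate_cohort(config, {"G00002": 0.3})
    return {
        "config": config,
        "counts": counts,
        "clinical": clinical,
        "mutations": mutations,
        "truth": truth,
    }


@pytest.fixture()
def toy_endpoint():
    """Six samples with mixed censoring (times in months)."""
    ids = [f"S{i}" for i in range(1, 7)]
    return SurvivalEndpoint(
        time=pd.Series([2.0, 3.0, 3.0, 5.0, 8.0, 10.0], index=ids),
        event=pd.Series([1.0, 1.0, 0.0, 1.0, 0.0, 1.0], index=ids),
    )


@pytest.fixture()
def toy_counts():
    return CountMatrix(
        pd.DataFrame(
            {"A": [10, 0, 7], "B": [20, 5, 7]},
            index=["g1", "g2", "g3"],
        )
    )


@pytest.fixture()
def toy_mutations():
    return MutationTable(
        pd.DataFrame(
            {
                "sample_id": ["S1", "S1", "S1", "S2"],
                "gene_symbol": ["TP53", "KRAS", "TP53", "MYC"],
                "variant_classification": [
                    "Missense_Mutation",
                    "Missense_Mutation",
                    "Silent",
                    "Nonsense_Mutation",
                ],
            }
        )
    )


def make_expression(values: np.ndarray, genes=None, samples=None,
                    stage: str = "mean_rescaled") -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), stage=stage)


def make_clinical(n: int, rng: np.random.Generator | None = None,
                  times=None, events=None) -> ClinicalTable:
    """Minimal valid clinical table with independent covariates."""
    rng = rng or np.random.default_rng(0)
    ids = [f"S{i:04d}" for i in range(1, n + 1)]
    frame = pd.DataFrame(
        {
            "os_time": times if times is not None else rng.exponential(30, n) + 0.1,
            "os_event": events if events is not None else rng.integers(0, 2, n).astype(float),
            "rfs_time": np.nan,
            "rfs_event": np.nan,
            "sex": rng.choice(["F", "M"], n),
            "race": rng.choice(["white", "black", "asian"], n, p=[0.6, 0.25, 0.15]),
            "stage": rng.choice([1.0, 2.0, 3.0, 4.0], n),
            "grade": rng.choice(["low", "high"], n),
            "age": np.round(rng.normal(60, 10, n), 1).clip(min=20),
        },
        index=pd.Index(ids, name="sample_id"),
    )
    return ClinicalTable(frame)
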