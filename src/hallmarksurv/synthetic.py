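"""Synthetic cohorts with the statistical structure the pipeline assumes.

Three generators cover the pipeline's inputs: a negative-binomial count
matrix with sample-specific size factors (sequencing-depth surrogates), a
right-censored survival outcome in which chosen genes carry a dichotomous
hazard effect planted at a chosen expression quantile, and a sparse
per-sample mutation table. Event times are exponential (constant baseline
hazard, so proportional hazards holds by construction) and censoring is
independent exponential with its rate solved numerically to hit a target
censored fraction.

All generators derive independent random streams deterministically from one
global seed, so an entire cohort is reproducible from a single integer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .containers import CLINICAL_COLUMNS, ClinicalTable, CountMatrix, ExpressionMatrix, MutationTable
from .errors import ConfigurationError

__all__ = [
    "PlantedEffect",
    "CovariateModel",
    "SimulationConfig",
    "simulate_counts",
    "simulate_survival",
    "simulate_maf",
    "simulate_cohort",
    "DEFAULT_CLASS_MIX",
]

# sub-stream tags, so each generator has its own reproducible stream
_STREAM_BASE = 0
_STREAM_COUNTS = 1
_STREAM_SURVIVAL = 2
_STREAM_MAF = 3
_STREAM_COVARIATES = 4
_STREAM_SIZE_FACTORS = 5

#: Default variant-class mix for simulated MAFs; includes silent classes so
#: the non-silent filters have something to exclude.
DEFAULT_CLASS_MIX = {
    "Missense_Mutation": 0.55,
    "Nonsense_Mutation": 0.10,
    "Frame_Shift_Del": 0.08,
    "Frame_Shift_Ins": 0.05,
    "Splice_Site": 0.07,
    "Silent": 0.15,
}


@dataclass(frozen=True)
class PlantedEffect:
    """A dichotomous hazard effect on one gene.

    Samples whose expression of ``gene_id`` exceeds the
    ``cutoff_quantile``-quantile have their hazard multiplied by
    ``hazard_ratio``.
    """

    gene_id: str
    cutoff_quantile: float
    hazard_ratio: float

    def __post_init__(self) -> None:
        if not 0.0 < self.cutoff_quantile < 1.0:
            raise ConfigurationError("cutoff quantile must lie strictly inside (0, 1)")
        if self.hazard_ratio <= 0:
            raise ConfigurationError("hazard ratio must be positive")


@dataclass(frozen=True)
class CovariateModel:
    """Categorical probabilities and an age distribution for the clinical
    covariates (all independent of survival unless planted otherwise)."""

    sex: dict = field(default_factory=lambda: {"F": 0.5, "M": 0.5})
    race: dict = field(default_factory=lambda: {"white": 0.7, "black": 0.2, "asian": 0.1})
    stage: dict = field(default_factory=lambda: {1: 0.3, 2: 0.3, 3: 0.25, 4: 0.15})
    grade: dict = field(default_factory=lambda: {"low": 0.5, "high": 0.5})
    age_mean: float = 62.0
    age_sd: float = 11.0
    age_min: float = 18.0


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to simulate one cohort from one seed.

    ``nb_dispersion`` is the negative-binomial dispersion alpha
    (variance = mu + alpha * mu^2); zero gives the Poisson limit. Base
    expressions are drawn log-uniformly over ``base_expression_range`` so
    quartile-based cutoffs are well populated. ``baseline_hazard`` is in
    events per month.
    """

    n_samples: int = 200
    n_genes: int = 100
    size_factor_range: tuple[float, float] = (0.5, 2.0)
    nb_dispersion: float = 0.1
    base_expression_range: tuple[float, float] = (5.0, 5000.0)
    baseline_hazard: float = 0.02
    planted_effects: tuple[PlantedEffect, ...] = ()
    censoring_fraction_target: float = 0.3
    covariates: CovariateModel = field(default_factory=CovariateModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise ConfigurationError("need at least 4 samples")
        if self.n_genes < 1:
            raise ConfigurationError("need at least 1 gene")
        lo, hi = self.size_factor_range
        if lo <= 0 or hi < lo:
            raise ConfigurationError("size factor range must be a positive interval")
        lo, hi = self.base_expression_range
        if lo <= 0 or hi < lo:
            raise ConfigurationError("base expression range must be a positive interval")
        if self.nb_dispersion < 0:
            raise ConfigurationError("dispersion must be nonnegative")
        if self.baseline_hazard <= 0:
            raise ConfigurationError("baseline hazard must be positive")
        if not 0.0 <= self.censoring_fraction_target < 1.0:
            raise ConfigurationError("censoring target must be in [0, 1)")
        gene_ids = self.gene_ids
        for effect in self.planted_effects:
            if effect.gene_id not in gene_ids:
                raise ConfigurationError(
                    f"planted gene {effect.gene_id!r} not in the simulated matrix"
                )

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i:05d}" for i in range(1, self.n_genes + 1)]

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{i:04d}" for i in range(1, self.n_samples + 1)]

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stream]))


def _base_expression(config: SimulationConfig) -> np.ndarray:
    rng = config.rng(_STREAM_BASE)
    lo, hi = config.base_expression_range
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=config.n_genes))


def _size_factors(config: SimulationConfig) -> np.ndarray:
    rng = config.rng(_STREAM_SIZE_FACTORS)
    lo, hi = config.size_factor_range
    return rng.uniform(lo, hi, size=config.n_samples)


def simulate_counts(config: SimulationConfig) -> CountMatrix:
    """Negative-binomial counts: mean = size_factor(sample) x base(gene).

    With ``nb_dispersion`` == 0 the draw is Poisson (the NB limit).
    Identical seeds produce identical matrices.
    """
    base = _base_expression(config)
    sf = _size_factors(config)
    mu = np.outer(base, sf)
    rng = config.rng(_STREAM_COUNTS)
    alpha = config.nb_dispersion
    if alpha < 1e-12:
        counts = rng.poisson(mu)
    else:
        shape = 1.0 / alpha
        # NB as a gamma-Poisson mixture keeps the parametrization explicit
        lam = rng.gamma(shape, mu / shape)
        counts = rng.poisson(lam)
    df = pd.DataFrame(counts, index=config.gene_ids, columns=config.sample_ids)
    return CountMatrix(df)


def _sample_hazards(expr: ExpressionMatrix, config: SimulationConfig) -> np.ndarray:
    hazards = np.full(len(expr.sample_ids), config.baseline_hazard, dtype=float)
    for effect in config.planted_effects:
        if effect.gene_id not in expr.data.index:
            raise ConfigurationError(
                f"planted gene {effect.gene_id!r} absent from the expression matrix"
            )
        values = expr.data.loc[effect.gene_id].to_numpy(dtype=float)
        cutoff = np.quantile(values, effect.cutoff_quantile)
        hazards[values > cutoff] *= effect.hazard_ratio
    return hazards


def _censoring_rate(hazards: np.ndarray, target: float) -> float:
    """Exponential censoring rate c with mean_i c/(c + lambda_i) = target."""
    if target <= 0:
        return 0.0

    def realized(c: float) -> float:
        return float(np.mean(c / (c + hazards))) - target

    lo, hi = 1e-12, float(hazards.max())
    while realized(hi) < 0:
        hi *= 10
        if hi > 1e12:  # pragma: no cover - target < 1 guarantees a root
            break
    return float(brentq(realized, lo, hi))


def _draw_covariates(config: SimulationConfig) -> pd.DataFrame:
    rng = config.rng(_STREAM_COVARIATES)
    cov = config.covariates
    n = config.n_samples

    def categorical(dist: dict) -> np.ndarray:
        keys = list(dist.keys())
        probs = np.asarray([dist[k] for k in keys], dtype=float)
        probs = probs / probs.sum()
        return rng.choice(np.asarray(keys, dtype=object), size=n, p=probs)

    age = rng.normal(cov.age_mean, cov.age_sd, size=n)
    age = np.maximum(age, cov.age_min)
    return pd.DataFrame(
        {
            "sex": categorical(cov.sex),
            "race": categorical(cov.race),
            "stage": categorical(cov.stage).astype(float),
            "grade": categorical(cov.grade),
            "age": np.round(age, 1),
        },
        index=config.sample_ids,
    )


def simulate_survival(expr: ExpressionMatrix, config: SimulationConfig) -> ClinicalTable:
    """Right-censored overall survival with the configured planted effects.

    Event times are exponential with per-sample hazard
    baseline x prod(HR ** [expression > planted cutoff]); censoring times
    are independent exponential with rate calibrated so the expected
    censored fraction matches the target.
    """
    sample_ids = list(expr.sample_ids)
    if sample_ids != config.sample_ids:
        raise ConfigurationError("expression matrix samples do not match the config")
    hazards = _sample_hazards(expr, config)
    rng = config.rng(_STREAM_SURVIVAL)
    event_times = rng.exponential(1.0 / hazards)
    rate = _censoring_rate(hazards, config.censoring_fraction_target)
    if rate > 0:
        censor_times = rng.exponential(1.0 / rate, size=len(hazards))
        observed = np.minimum(event_times, censor_times)
        events = (event_times <= censor_times).astype(float)
    else:
        observed = event_times
        events = np.ones(len(hazards))
    observed = np.maximum(observed, 1e-6)  # keep times strictly positive

    frame = _draw_covariates(config)
    frame["os_time"] = np.round(observed, 4)
    frame["os_event"] = events
    frame["rfs_time"] = np.nan
    frame["rfs_event"] = np.nan
    frame = frame[CLINICAL_COLUMNS]
    frame.index.name = "sample_id"
    return ClinicalTable(frame)


def simulate_maf(
    config: SimulationConfig,
    per_gene_mutation_prob: dict[str, float],
    class_mix: dict[str, float] | None = None,
) -> MutationTable:
    """Sparse mutation records: each (sample, gene) mutates independently
    with its gene's probability; the variant class is drawn from
    ``class_mix`` (silent classes included by default)."""
    for gene, prob in per_gene_mutation_prob.items():
        if not 0.0 <= prob <= 1.0:
            raise ConfigurationError(f"mutation probability for {gene!r} outside [0, 1]")
    mix = class_mix if class_mix is not None else DEFAULT_CLASS_MIX
    classes = list(mix.keys())
    probs = np.asarray([mix[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    rng = config.rng(_STREAM_MAF)
    rows = []
    for gene in sorted(per_gene_mutation_prob):
        prob = per_gene_mutation_prob[gene]
        mutated = rng.uniform(size=config.n_samples) < prob
        drawn = rng.choice(classes, size=config.n_samples, p=probs)
        for sample, hit, vc in zip(config.sample_ids, mutated, drawn):
            if hit:
                rows.append((sample, gene, vc))
    frame = pd.DataFrame(
        rows, columns=["sample_id", "gene_symbol", "variant_classification"]
    )
    return MutationTable(frame)


def simulate_cohort(
    config: SimulationConfig,
    per_gene_mutation_prob: dict[str, float] | None = None,
):
    """Simulate counts, survival and mutations in one call.

    Returns ``(counts, clinical, mutations, truth)`` where ``truth`` records
    the planted ground truth (per-gene cutoff quantiles and hazard ratios)
    for downstream recovery checks. Survival is planted on the normalized
    (mean-rescaled) expression scale — the same scale the scan consumes —
    so recovery checks compare like with like.
    """
    from .normalization import normalize

    counts = simulate_counts(config)
    expr, _ = normalize(counts)
    clinical = simulate_survival(expr, config)
    mutations = simulate_maf(config, per_gene_mutation_prob or {})
    truth = {
        "seed": config.seed,
        "baseline_hazard": config.baseline_hazard,
        "censoring_fraction_target": config.censoring_fraction_target,
        "planted_effects": [
            {
                "gene_id": e.gene_id,
                "cutoff_quantile": e.cutoff_quantile,
                "hazard_ratio": e.hazard_ratio,
            }
            for e in config.planted_effects
        ],
    }
    return counts, clinical, mutations, truth
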