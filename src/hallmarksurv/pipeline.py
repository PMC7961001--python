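"""End-to-end orchestration: per-tumor analysis and pan-cancer aggregation.

Per tumor the pipeline normalizes the count matrix, scores the hallmark
signatures, runs the optimal-cutoff scan for every hallmark member gene,
every signature and the mutation burden, and fits multivariate Cox models
of each signature against the clinical covariates. Across tumors it builds
the hallmark-by-tumor significance matrix, clusters both axes, lists
recurrently prognostic genes and emits forest-plot data for the signature
scans.

All outputs are deterministic tab-separated text keyed only by the inputs,
configuration and seed; rerunning with the same config produces
byte-identical files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aggregate import hierarchical_cluster, recurrent_features, significance_matrix
from .containers import ClinicalTable, CountMatrix, GeneSetCollection, MutationTable
from .errors import ConfigurationError, EstimationError, InsufficientDataError
from .io import read_clinical, read_counts, read_gmt, read_maf
from .normalization import normalize
from .signatures import SignatureMatrix, signature_scores
from .survival import (
    CutoffScanResult,
    bh_qvalues,
    cutoff_scan,
    endpoint_from_clinical,
    km_curve,
    multivariate_cox,
    scan_table,
)
from .tmb import compute_tmb, tmb_scan

__all__ = ["PipelineConfig", "TumorInputs", "TumorResult", "run_tumor", "run_pancancer"]

logger = logging.getLogger(__name__)

_FLOAT_FORMAT = "%.10g"


@dataclass(frozen=True)
class TumorInputs:
    counts: str
    clinical: str
    maf: str | None = None


@dataclass(frozen=True)
class PipelineConfig:
    """Run-wide configuration; see the YAML schema in the README."""

    tumors: dict[str, TumorInputs]
    gmt: str
    output_dir: str = "results"
    endpoint: str = "os"
    fdr_threshold: float = 0.10
    min_cohort_size: int = 100
    min_group: int = 1
    min_tumors: int = 10
    target_mean: float = 1000.0
    across_features_fdr: bool = False
    tmb_per_mb: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.fdr_threshold < 1:
            raise ConfigurationError("fdr_threshold must be in (0, 1)")
        if self.min_cohort_size < 1 or self.min_group < 1 or self.min_tumors < 1:
            raise ConfigurationError("size thresholds must be positive")
        if self.endpoint not in ("os", "rfs"):
            raise ConfigurationError("endpoint must be 'os' or 'rfs'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        tumors = {
            name: TumorInputs(**paths) for name, paths in raw.pop("tumors").items()
        }
        return cls(tumors=tumors, **raw)

    def as_dict(self) -> dict:
        return {
            "tumors": {t: vars(i) for t, i in sorted(self.tumors.items())},
            "gmt": self.gmt,
            "output_dir": self.output_dir,
            "endpoint": self.endpoint,
            "fdr_threshold": self.fdr_threshold,
            "min_cohort_size": self.min_cohort_size,
            "min_group": self.min_group,
            "min_tumors": self.min_tumors,
            "target_mean": self.target_mean,
            "across_features_fdr": self.across_features_fdr,
            "tmb_per_mb": self.tmb_per_mb,
            "seed": self.seed,
        }


@dataclass
class TumorResult:
    """Everything computed for one tumor type."""

    tumor: str
    n_samples: int
    size_factors: pd.Series
    signatures: SignatureMatrix
    gene_scans: dict[str, CutoffScanResult]
    signature_scans: dict[str, CutoffScanResult]
    tmb_result: CutoffScanResult | None
    multivariate: dict[str, pd.DataFrame]
    multivariate_dropped: dict[str, dict[str, str]] = field(default_factory=dict)
    skipped_signatures: dict[str, str] = field(default_factory=dict)


def _scan_features(
    frame: pd.DataFrame, endpoint, fdr_threshold: float, min_group: int
) -> dict[str, CutoffScanResult]:
    """Scan every row of a feature-by-sample frame."""
    return {
        feature: cutoff_scan(
            frame.loc[feature],
            endpoint,
            fdr_threshold=fdr_threshold,
            min_group=min_group,
            feature_id=feature,
        )
        for feature in frame.index
    }


def _scan_frame(scans: dict[str, CutoffScanResult], across: bool, fdr: float) -> pd.DataFrame:
    table = scan_table(list(scans.values())).sort_index()
    if across and len(table):
        best_p = table["p"].to_numpy(dtype=float)
        usable = np.isfinite(best_p)
        q_across = np.full(len(table), np.nan)
        if usable.any():
            q_across[usable] = bh_qvalues(best_p[usable])
        table["q_across_features"] = q_across
        table["significant_across_features"] = (
            pd.Series(q_across, index=table.index) < fdr
        ) & table["evaluable"]
    return table


def run_tumor_analysis(
    tumor: str,
    counts: CountMatrix,
    clinical: ClinicalTable,
    sets: GeneSetCollection,
    config: PipelineConfig,
    mutations: MutationTable | None = None,
) -> TumorResult | None:
    """Run the per-tumor stages on in-memory inputs.

    Returns ``None`` (with a logged reason) when the cohort fails the
    minimum-size filter; this mirrors the study design of only analyzing
    tumor types with a robust sample count.
    """
    cohort = [s for s in counts.sample_ids if s in set(clinical.sample_ids)]
    if len(cohort) < config.min_cohort_size:
        logger.warning(
            "tumor %s skipped: %d samples with counts and clinical data "
            "(minimum %d)", tumor, len(cohort), config.min_cohort_size,
        )
        return None

    expr, size_factors = normalize(counts, target=config.target_mean)
    endpoint = endpoint_from_clinical(clinical, config.endpoint)
    signatures = signature_scores(expr, sets)

    hallmark_genes = sorted({g for name in sets for g in sets[name].genes})
    present = [g for g in hallmark_genes if g in expr.data.index]
    gene_scans = _scan_features(
        expr.data.loc[present], endpoint, config.fdr_threshold, config.min_group
    )
    signature_scans = _scan_features(
        signatures.scores, endpoint, config.fdr_threshold, config.min_group
    )

    tmb_result = None
    if mutations is not None:
        tmb = compute_tmb(mutations, samples=list(expr.sample_ids))
        values = (
            tmb.per_megabase(config.tmb_per_mb) if config.tmb_per_mb else tmb.counts
        )
        tmb_result = cutoff_scan(
            values.astype(float),
            endpoint,
            fdr_threshold=config.fdr_threshold,
            min_group=config.min_group,
            feature_id="TMB",
        )

    multivariate: dict[str, pd.DataFrame] = {}
    dropped: dict[str, dict[str, str]] = {}
    skipped: dict[str, str] = {}
    for name, scan in signature_scans.items():
        if not scan.evaluable or scan.best_cutoff is None:
            skipped[name] = "scan not evaluable"
            continue
        values = signatures.scores.loc[name].reindex(endpoint.sample_ids).dropna()
        group = values > scan.best_cutoff
        try:
            result = multivariate_cox(
                group,
                clinical,
                endpoint.subset(values.index),
                feature_name=f"{name}_high",
            )
        except InsufficientDataError as exc:
            skipped[name] = str(exc)
            continue
        multivariate[name] = result.terms
        dropped[name] = result.dropped

    return TumorResult(
        tumor=tumor,
        n_samples=len(cohort),
        size_factors=size_factors,
        signatures=signatures,
        gene_scans=gene_scans,
        signature_scans=signature_scans,
        tmb_result=tmb_result,
        multivariate=multivariate,
        multivariate_dropped=dropped,
        skipped_signatures=skipped,
    )


def _write_tsv(frame: pd.DataFrame, path: Path, index_label=None) -> None:
    frame.to_csv(path, sep="\t", float_format=_FLOAT_FORMAT, index_label=index_label)


def _write_tumor_outputs(result: TumorResult, outdir: Path, config: PipelineConfig,
                         clinical: ClinicalTable) -> None:
    tumor_dir = outdir / result.tumor
    tumor_dir.mkdir(parents=True, exist_ok=True)
    _write_tsv(result.size_factors.to_frame(), tumor_dir / "size_factors.tsv",
               index_label="sample_id")
    _write_tsv(result.signatures.scores, tumor_dir / "signature_scores.tsv")
    _write_tsv(
        _scan_frame(result.gene_scans, config.across_features_fdr, config.fdr_threshold),
        tumor_dir / "gene_scan.tsv",
    )
    _write_tsv(
        _scan_frame(result.signature_scans, False, config.fdr_threshold),
        tumor_dir / "signature_scan.tsv",
    )
    if result.tmb_result is not None:
        _write_tsv(_scan_frame({"TMB": result.tmb_result}, False, config.fdr_threshold),
                   tumor_dir / "tmb_scan.tsv")
    if result.multivariate:
        frames = []
        for name in sorted(result.multivariate):
            frame = result.multivariate[name].copy()
            frame.insert(0, "signature", name)
            frames.append(frame)
        _write_tsv(pd.concat(frames), tumor_dir / "mvcox_signatures.tsv",
                   index_label="term")

    # KM plot data at each signature's best cutoff
    endpoint = endpoint_from_clinical(clinical, config.endpoint)
    km_rows = []
    for name in sorted(result.signature_scans):
        scan = result.signature_scans[name]
        if scan.best_cutoff is None:
            continue
        values = result.signatures.scores.loc[name].reindex(endpoint.sample_ids).dropna()
        sub = endpoint.subset(values.index)
        groups = np.where(values > scan.best_cutoff, "high", "low")
        for curve in km_curve(pd.Series(groups, index=values.index), sub).values():
            frame = curve.as_frame()
            frame.insert(0, "signature", name)
            frame["median_survival"] = curve.median
            km_rows.append(frame)
    if km_rows:
        _write_tsv(pd.concat(km_rows, ignore_index=True), tumor_dir / "km_signatures.tsv")


def run_tumor(config: PipelineConfig, tumor: str) -> TumorResult | None:
    """Load one tumor's inputs, run the analysis, and write its outputs."""
    inputs = config.tumors[tumor]
    counts = read_counts(inputs.counts)
    clinical = read_clinical(inputs.clinical)
    mutations = read_maf(inputs.maf) if inputs.maf else None
    sets = read_gmt(config.gmt)
    result = run_tumor_analysis(tumor, counts, clinical, sets, config, mutations)
    if result is not None:
        _write_tumor_outputs(result, Path(config.output_dir), config, clinical)
    return result


def run_pancancer(config: PipelineConfig) -> dict:
    """Run every configured tumor, then aggregate across tumor types.

    Requires at least two tumors to pass the cohort filter. Returns a
    bundle with per-tumor results, the significance matrix, dendrograms,
    the recurrent-feature table and the signature forest-plot data; all of
    it is also written under ``config.output_dir``.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    sets = read_gmt(config.gmt)

    results: dict[str, TumorResult] = {}
    skipped: dict[str, str] = {}
    for tumor in sorted(config.tumors):
        result = run_tumor(config, tumor)
        if result is None:
            skipped[tumor] = "cohort below minimum size"
        else:
            results[tumor] = result
    if len(results) < 2:
        raise EstimationError(
            f"pan-cancer aggregation needs >= 2 tumor types, got {len(results)}"
        )

    gene_scans = {t: r.gene_scans for t, r in results.items()}
    matrix = significance_matrix(gene_scans, sets)
    _write_tsv(matrix.percent, outdir / "significance_matrix.tsv")
    _write_tsv(matrix.numerator, outdir / "significance_numerator.tsv")
    _write_tsv(matrix.denominator, outdir / "significance_denominator.tsv")

    dendrograms = {}
    for axis, filename in (("hallmarks", "dendrogram_hallmarks.newick"),
                           ("tumors", "dendrogram_tumors.newick")):
        n_rows = matrix.percent.shape[0] if axis == "hallmarks" else matrix.percent.shape[1]
        if n_rows >= 2:
            dendro = hierarchical_cluster(matrix, axis=axis)
            (outdir / filename).write_text(dendro.to_newick() + "\n", encoding="utf-8")
            dendrograms[axis] = dendro

    if len(results) >= config.min_tumors:
        recurrent = recurrent_features(gene_scans, min_tumors=config.min_tumors)
    else:
        logger.warning(
            "recurrent-feature table skipped: %d tumors analyzed, min_tumors=%d",
            len(results), config.min_tumors,
        )
        recurrent = pd.DataFrame(columns=["n_significant", "n_scanned", "best_p"])
        recurrent.index.name = "feature"
    _write_tsv(recurrent, outdir / "recurrent_features.tsv")

    # forest-plot data: signature scans with p < 0.05, one row per
    # (tumor, signature)
    forest_rows = []
    for tumor in sorted(results):
        for name in sorted(results[tumor].signature_scans):
            scan = results[tumor].signature_scans[name]
            fit = scan.best_fit
            if fit is None or fit.degenerate or not (fit.p < 0.05):
                continue
            forest_rows.append(
                {
                    "tumor": tumor,
                    "signature": name,
                    "hr": fit.hr,
                    "ci_low": fit.ci_low,
                    "ci_high": fit.ci_high,
                    "p": fit.p,
                    "q": scan.best_q,
                }
            )
    forest = pd.DataFrame(
        forest_rows, columns=["tumor", "signature", "hr", "ci_low", "ci_high", "p", "q"]
    )
    forest.to_csv(outdir / "forest_signatures.tsv", sep="\t", index=False,
                  float_format=_FLOAT_FORMAT)

    manifest = {
        "package_version": __version__,
        "config": config.as_dict(),
        "tumors_analyzed": sorted(results),
        "tumors_skipped": skipped,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return {
        "results": results,
        "skipped": skipped,
        "significance": matrix,
        "dendrograms": dendrograms,
        "recurrent": recurrent,
        "forest": forest,
    }
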