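"""Optimal-cutoff survival analysis.

The central procedure dichotomizes a continuous per-sample feature (gene
expression, signature score, or mutation burden) at every distinct observed
value between the lower and upper quartiles, tests each split with a
two-group Cox / log-rank analysis, corrects the scan's p-values with
Benjamini-Hochberg, and keeps the best-performing cutoff (lowest p). A
feature is called significant only when the FDR q-value at its best cutoff
is below 10%.

Group convention throughout: low = {x <= cutoff}, high = {x > cutoff}; the
hazard ratio is reported for the high group versus the low group. The
reported p-value is the score (log-rank) test; the hazard ratio and its 95%
confidence interval come from a single-covariate Cox fit with Efron tie
handling, estimated by Newton iteration on the partial likelihood (the
binary covariate reduces every Efron term to at-risk and event counts per
group, which keeps full scans cheap).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ClinicalTable, MutationTable, NON_SILENT_CLASSES
from .errors import EstimationError, InsufficientDataError

__all__ = [
    "SurvivalEndpoint",
    "CoxFitResult",
    "CutoffScanResult",
    "MultivariateResult",
    "KMCurve",
    "endpoint_from_clinical",
    "candidate_cutoffs",
    "fit_cox_binary",
    "cutoff_scan",
    "bh_qvalues",
    "multivariate_cox",
    "binary_group_from_mutations",
    "km_curve",
]

_Z975 = stats.norm.ppf(0.975)
_COEF_CAP = 15.0  # |log HR| bound; monotone likelihoods stop here


# ---------------------------------------------------------------------------
# endpoint container and per-endpoint precomputation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SurvivalEndpoint:
    """Right-censored survival outcome for a set of samples.

    ``time`` is in months, ``event`` is 1 for an observed event and 0 for
    censoring; both are indexed by sample id. ``label`` names the endpoint
    (OS or RFS).
    """

    time: pd.Series
    event: pd.Series
    label: str = "OS"

    def __post_init__(self) -> None:
        if not self.time.index.equals(self.event.index):
            raise EstimationError("time and event must share a sample index")
        t = self.time.to_numpy(dtype=float)
        if np.any(~np.isfinite(t)) or np.any(t <= 0):
            raise EstimationError("survival times must be positive and finite")
        e = self.event.to_numpy(dtype=float)
        if not np.isin(e, (0.0, 1.0)).all():
            raise EstimationError("event indicators must be 0/1")

    @property
    def sample_ids(self) -> pd.Index:
        return self.time.index

    def __len__(self) -> int:
        return len(self.time)

    def subset(self, sample_ids) -> "SurvivalEndpoint":
        return SurvivalEndpoint(
            self.time.loc[sample_ids], self.event.loc[sample_ids], self.label
        )


def endpoint_from_clinical(clinical: ClinicalTable, endpoint: str = "os") -> SurvivalEndpoint:
    """Extract an OS or RFS endpoint, keeping samples with positive time."""
    frame = clinical.endpoint(endpoint)
    frame = frame[frame["time"] > 0]
    if frame.empty:
        raise InsufficientDataError(f"no usable {endpoint.upper()} observations")
    return SurvivalEndpoint(frame["time"], frame["event"], endpoint.upper())


class _EndpointData:
    """Sorted arrays and per-event-time bookkeeping shared across cutoffs.

    Sorting and event-time segmentation cost O(n log n) once; every
    group-dependent quantity afterwards is O(n) per cutoff.
    """

    def __init__(self, time: np.ndarray, event: np.ndarray):
        order = np.argsort(time, kind="stable")
        self.order = order
        self.t = time[order]
        self.e = event[order].astype(float)
        self.n = len(self.t)
        self.event_times = np.unique(self.t[self.e == 1])
        # slice [lo, hi) of sorted samples tied at each event time
        self.lo = np.searchsorted(self.t, self.event_times, side="left")
        self.hi = np.searchsorted(self.t, self.event_times, side="right")
        self.n_risk = self.n - self.lo
        cum_e = np.concatenate([[0.0], np.cumsum(self.e)])
        self.d = cum_e[self.hi] - cum_e[self.lo]  # events per event time
        # flattened (event time j, within-tie index l) pairs for Efron terms
        d_int = self.d.astype(int)
        self.efron_j = np.repeat(np.arange(len(self.d)), d_int)
        self.efron_frac = np.concatenate(
            [np.arange(dj) / dj for dj in d_int]
        ) if len(d_int) else np.empty(0)

    def group_counts(self, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """At-risk and event counts of the z==1 group at each event time."""
        zs = z[self.order].astype(float)
        suffix = np.concatenate([np.cumsum(zs[::-1])[::-1], [0.0]])
        n1 = suffix[self.lo]
        cum_ze = np.concatenate([[0.0], np.cumsum(zs * self.e)])
        d1 = cum_ze[self.hi] - cum_ze[self.lo]
        return n1, d1


def _logrank_p(data: _EndpointData, n1: np.ndarray, d1: np.ndarray) -> float:
    """Two-group log-rank test p-value from per-event-time counts."""
    n, d = data.n_risk, data.d
    expected = d * n1 / n
    with np.errstate(invalid="ignore", divide="ignore"):
        var = d * (n1 / n) * (1.0 - n1 / n) * (n - d) / (n - 1.0)
    var = np.where(n > 1, var, 0.0)
    v = var.sum()
    if v <= 0:
        return 1.0
    chi2 = (d1 - expected).sum() ** 2 / v
    return float(stats.chi2.sf(chi2, 1))


def _efron_loglik_terms(data: _EndpointData, n1, d1, beta: float):
    """Log-likelihood, gradient and negative Hessian of the Efron partial
    likelihood for a binary covariate, as functions of group counts."""
    r = np.exp(beta)
    j = data.efron_j
    frac = data.efron_frac
    n0 = data.n_risk - n1
    d0 = data.d - d1
    # A_l = sum of risks in the adjusted risk set; B_l its z-weighted part
    b_l = n1[j] - frac * d1[j]
    a_l = n0[j] - frac * d0[j] + b_l * r
    br = b_l * r
    loglik = float((d1 * beta).sum() - np.log(a_l).sum())
    grad = float(d1.sum() - (br / a_l).sum())
    info = float((br * (a_l - br) / a_l**2).sum())
    return loglik, grad, info


def _efron_newton(data: _EndpointData, n1, d1) -> tuple[float, float]:
    """Maximize the Efron partial likelihood; returns (beta, se)."""
    beta = 0.0
    ll, grad, info = _efron_loglik_terms(data, n1, d1, beta)
    for _ in range(60):
        if info <= 0:
            break
        step = grad / info
        step = np.clip(step, -2.0, 2.0)  # damped for stability far from optimum
        new_beta = float(np.clip(beta + step, -_COEF_CAP, _COEF_CAP))
        new_ll, new_grad, new_info = _efron_loglik_terms(data, n1, d1, new_beta)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 30:
            new_beta = (beta + new_beta) / 2.0
            new_ll, new_grad, new_info = _efron_loglik_terms(data, n1, d1, new_beta)
            halvings += 1
        converged = abs(new_beta - beta) < 1e-10 or abs(new_grad) < 1e-10
        beta, ll, grad, info = new_beta, new_ll, new_grad, new_info
        if converged:
            break
    se = 1.0 / np.sqrt(info) if info > 0 else np.nan
    return beta, se


# ---------------------------------------------------------------------------
# public single-fit API
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CoxFitResult:
    """Two-group Cox fit: hazard ratio of high vs low expression.

    ``p`` is the score (log-rank) test p-value. When one group has no
    events the fit is degenerate: ``hr`` is reported as a one-sided extreme
    (0 or inf) and the confidence interval is suppressed (NaN).
    """

    hr: float
    ci_low: float
    ci_high: float
    p: float
    n_low: int
    n_high: int
    events_low: int
    events_high: int
    degenerate: bool = False

    @property
    def log_hr(self) -> float:
        return float(np.log(self.hr))


def _as_high_indicator(group) -> np.ndarray:
    arr = np.asarray(group)
    if arr.dtype.kind in "bif":
        return arr.astype(bool)
    mapping = {"high": True, "low": False, "mutant": True, "wild-type": False}
    try:
        return np.array([mapping[str(g)] for g in arr])
    except KeyError as exc:
        raise ValueError(f"unrecognized group label {exc}") from exc


def fit_cox_binary(group, endpoint: SurvivalEndpoint) -> CoxFitResult:
    """Fit a single-covariate Cox model on the high-group indicator.

    Efron tie handling; HR = exp(coefficient) with a 95% CI from the normal
    approximation on the log scale; p from the score (log-rank) test.

    Raises
    ------
    EstimationError
        If either group is empty (zero events overall is rejected by the
        endpoint container itself).
    """
    z = _as_high_indicator(group)
    if len(z) != len(endpoint):
        raise EstimationError("group labels and endpoint differ in length")
    time = endpoint.time.to_numpy(dtype=float)
    event = endpoint.event.to_numpy(dtype=float)
    n_high = int(z.sum())
    n_low = int(len(z) - n_high)
    if n_high == 0 or n_low == 0:
        raise EstimationError("both groups must be non-empty")
    if event.sum() < 1:
        raise EstimationError("at least one event is required for a fit")
    data = _EndpointData(time, event)
    n1, d1 = data.group_counts(z)
    events_high = int(d1.sum())
    events_low = int((data.d - d1).sum())
    p = _logrank_p(data, n1, d1)
    if events_high == 0 or events_low == 0:
        return CoxFitResult(
            hr=np.inf if events_low == 0 else 0.0,
            ci_low=np.nan,
            ci_high=np.nan,
            p=p,
            n_low=n_low,
            n_high=n_high,
            events_low=events_low,
            events_high=events_high,
            degenerate=True,
        )
    beta, se = _efron_newton(data, n1, d1)
    with np.errstate(over="ignore"):  # huge se on near-degenerate data -> inf CI
        ci_low = float(np.exp(beta - _Z975 * se))
        ci_high = float(np.exp(beta + _Z975 * se))
    return CoxFitResult(
        hr=float(np.exp(beta)),
        ci_low=ci_low,
        ci_high=ci_high,
        p=p,
        n_low=n_low,
        n_high=n_high,
        events_low=events_low,
        events_high=events_high,
        degenerate=False,
    )


# ---------------------------------------------------------------------------
# cutoff scan
# ---------------------------------------------------------------------------


def candidate_cutoffs(values, min_group: int = 1) -> np.ndarray:
    """Distinct observed values between the quartiles, usable as cutoffs.

    Quartiles use linear interpolation. A value v qualifies when
    Q1 <= v <= Q3 and both {x <= v} and {x > v} have at least
    ``min_group`` samples. Returns an ascending array (possibly empty when
    all values tie).

    Raises
    ------
    InsufficientDataError
        With fewer than 8 non-missing values.
    """
    arr = np.asarray(pd.Series(values).dropna(), dtype=float)
    if len(arr) < 8:
        raise InsufficientDataError(
            f"cutoff scan needs >= 8 non-missing values, got {len(arr)}"
        )
    q1, q3 = np.quantile(arr, [0.25, 0.75])
    distinct = np.unique(arr)
    inside = distinct[(distinct >= q1) & (distinct <= q3)]
    sorted_arr = np.sort(arr)
    n = len(arr)
    keep = []
    for v in inside:
        n_low = np.searchsorted(sorted_arr, v, side="right")
        if n_low >= min_group and (n - n_low) >= min_group:
            keep.append(v)
    return np.asarray(keep, dtype=float)


def bh_qvalues(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class CutoffScanResult:
    """Outcome of scanning all candidate cutoffs for one feature."""

    feature_id: str
    cutoffs: np.ndarray
    p_values: np.ndarray
    q_values: np.ndarray
    best_cutoff: float | None
    best_fit: CoxFitResult | None
    significant: bool
    evaluable: bool
    n_samples: int
    best_cutoff_quantile: float | None = None
    note: str = ""

    @property
    def best_p(self) -> float | None:
        return None if self.best_fit is None else self.best_fit.p

    @property
    def best_q(self) -> float | None:
        if self.best_cutoff is None:
            return None
        idx = int(np.argmin(np.abs(self.cutoffs - self.best_cutoff)))
        return float(self.q_values[idx])


def _not_evaluable(feature_id: str, n: int, note: str) -> CutoffScanResult:
    empty = np.empty(0)
    return CutoffScanResult(
        feature_id=feature_id,
        cutoffs=empty,
        p_values=empty,
        q_values=empty,
        best_cutoff=None,
        best_fit=None,
        significant=False,
        evaluable=False,
        n_samples=n,
        note=note,
    )


def cutoff_scan(
    values: pd.Series,
    endpoint: SurvivalEndpoint,
    fdr_threshold: float = 0.10,
    min_group: int = 1,
    feature_id: str | None = None,
) -> CutoffScanResult:
    """Scan every candidate cutoff of ``values`` against ``endpoint``.

    Missing values are dropped pairwise with the endpoint. Each cutoff's
    p-value is the log-rank test of {x <= cutoff} vs {x > cutoff};
    q-values are Benjamini-Hochberg over the scan. The best cutoff is the
    one with the smallest p (ties broken toward the smaller cutoff;
    degenerate splits — no events in one group — can never beat a
    non-degenerate one). Insufficient data yields ``evaluable=False``
    rather than an exception.
    """
    name = feature_id if feature_id is not None else str(values.name)
    values = pd.Series(values).dropna()
    shared = values.index.intersection(endpoint.sample_ids)
    values = values.loc[shared]
    if len(shared) < 8:
        return _not_evaluable(name, len(shared), "fewer than 8 samples with data")
    sub = endpoint.subset(shared)
    try:
        cuts = candidate_cutoffs(values, min_group=min_group)
    except InsufficientDataError as exc:
        return _not_evaluable(name, len(shared), str(exc))
    if len(cuts) == 0:
        return _not_evaluable(name, len(shared), "no candidate cutoff between quartiles")

    x = values.to_numpy(dtype=float)
    time = sub.time.to_numpy(dtype=float)
    event = sub.event.to_numpy(dtype=float)
    if event.sum() < 1:
        return _not_evaluable(name, len(shared), "no events in the cohort")
    data = _EndpointData(time, event)
    total_events = data.d.sum()
    p_values = np.empty(len(cuts))
    degenerate = np.empty(len(cuts), dtype=bool)
    for i, cutoff in enumerate(cuts):
        z = x > cutoff
        n1, d1 = data.group_counts(z)
        eh = d1.sum()
        p_values[i] = _logrank_p(data, n1, d1)
        degenerate[i] = (eh == 0) or (eh == total_events)
    q_values = bh_qvalues(p_values)

    if (~degenerate).any():
        pool = np.where(~degenerate)[0]
    else:
        pool = np.arange(len(cuts))
    best_idx = pool[int(np.argmin(p_values[pool]))]  # argmin takes first = smallest cutoff
    best_cutoff = float(cuts[best_idx])
    best_fit = fit_cox_binary(x > best_cutoff, sub)
    significant = bool(q_values[best_idx] < fdr_threshold) and not best_fit.degenerate
    quantile = float((x <= best_cutoff).mean())
    return CutoffScanResult(
        feature_id=name,
        cutoffs=cuts,
        p_values=p_values,
        q_values=q_values,
        best_cutoff=best_cutoff,
        best_fit=best_fit,
        significant=significant,
        evaluable=bool((~degenerate).any()),
        n_samples=len(shared),
        best_cutoff_quantile=quantile,
    )


def scan_table(scans: Sequence[CutoffScanResult]) -> pd.DataFrame:
    """Flatten scan results into the standard per-feature result table."""
    rows = []
    for s in scans:
        fit = s.best_fit
        rows.append(
            {
                "feature": s.feature_id,
                "n": s.n_samples,
                "n_cutoffs": len(s.cutoffs),
                "best_cutoff": s.best_cutoff if s.best_cutoff is not None else np.nan,
                "cutoff_quantile": s.best_cutoff_quantile
                if s.best_cutoff_quantile is not None
                else np.nan,
                "n_low": fit.n_low if fit else np.nan,
                "n_high": fit.n_high if fit else np.nan,
                "events_low": fit.events_low if fit else np.nan,
                "events_high": fit.events_high if fit else np.nan,
                "hr": fit.hr if fit else np.nan,
                "ci_low": fit.ci_low if fit else np.nan,
                "ci_high": fit.ci_high if fit else np.nan,
                "p": fit.p if fit else np.nan,
                "q": s.best_q if s.best_q is not None else np.nan,
                "significant": s.significant,
                "degenerate": fit.degenerate if fit else False,
                "evaluable": s.evaluable,
                "note": s.note,
            }
        )
    return pd.DataFrame(rows).set_index("feature")


# ---------------------------------------------------------------------------
# multivariate Cox
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MultivariateResult:
    """Multivariate Cox fit of the feature group plus clinical covariates.

    ``terms`` has one row per retained model term (hr, ci_low, ci_high, p);
    ``dropped`` maps excluded terms to the reason (constant, collinear,
    all-missing).
    """

    terms: pd.DataFrame
    dropped: dict[str, str] = field(default_factory=dict)
    n: int = 0
    n_events: int = 0


def _covariate_columns(clinical: ClinicalTable, covariates: Sequence[str]) -> pd.DataFrame:
    """Numeric design columns: age continuous, stage ordinal, sex/grade
    binary, race one-hot against its largest category."""
    df = clinical.data
    out = {}
    for cov in covariates:
        if cov == "age":
            out["age"] = df["age"].astype(float)
        elif cov == "stage":
            out["stage"] = df["stage"].astype(float)
        elif cov == "sex":
            out["sex_M"] = df["sex"].map({"M": 1.0, "F": 0.0})
        elif cov == "grade":
            out["grade_high"] = df["grade"].map({"high": 1.0, "low": 0.0})
        elif cov == "race":
            race = df["race"]
            counts = race.value_counts()
            if counts.empty:
                out["race"] = pd.Series(np.nan, index=df.index)
                continue
            reference = counts.idxmax()
            for level in sorted(c for c in counts.index if c != reference):
                col = race.map(lambda r, lv=level: np.nan if pd.isna(r) else float(r == lv))
                out[f"race_{level}"] = col
        else:
            raise ValueError(f"unknown covariate {cov!r}")
    return pd.DataFrame(out, index=df.index)


def multivariate_cox(
    feature_group,
    clinical: ClinicalTable,
    endpoint: SurvivalEndpoint,
    covariates: Sequence[str] = ("sex", "race", "stage", "grade", "age"),
    feature_name: str = "feature_high",
    min_events: int = 10,
) -> MultivariateResult:
    """Cox model of the dichotomized feature adjusted for clinical covariates.

    ``feature_group`` is a per-sample high/low labeling (bool or
    "high"/"low"), indexed by sample id. Samples missing any requested
    covariate are dropped (complete-case); constant and perfectly collinear
    design columns are removed and reported in ``dropped``.

    Raises
    ------
    InsufficientDataError
        If fewer than ``min_events`` events remain after complete-case
        filtering.
    """
    from lifelines import CoxPHFitter

    feature = pd.Series(_as_high_indicator(feature_group), index=pd.Series(feature_group).index,
                        dtype=float, name=feature_name)
    design = _covariate_columns(clinical, covariates)
    frame = pd.concat(
        [endpoint.time.rename("time"), endpoint.event.rename("event"), feature, design],
        axis=1,
        join="inner",
    )
    dropped: dict[str, str] = {}
    for col in list(frame.columns):
        if col in ("time", "event"):
            continue
        if frame[col].isna().all():
            dropped[col] = "all-missing"
            frame = frame.drop(columns=col)
    frame = frame.dropna()
    n_events = int(frame["event"].sum()) if len(frame) else 0
    if n_events < min_events:
        raise InsufficientDataError(
            f"{n_events} events after complete-case filtering (< {min_events})"
        )
    covariate_cols = [c for c in frame.columns if c not in ("time", "event")]
    kept: list[str] = []
    for col in covariate_cols:
        if frame[col].nunique() <= 1:
            dropped[col] = "constant"
            continue
        trial = frame[kept + [col]].to_numpy(dtype=float)
        if np.linalg.matrix_rank(trial) <= len(kept):
            dropped[col] = "collinear"
            continue
        kept.append(col)
    if not kept:
        raise InsufficientDataError("no usable model terms after filtering")

    fitter = CoxPHFitter()
    fitter.fit(frame[["time", "event", *kept]], duration_col="time", event_col="event")
    summary = fitter.summary
    terms = pd.DataFrame(
        {
            "hr": np.exp(summary["coef"]),
            "ci_low": np.exp(summary["coef lower 95%"]),
            "ci_high": np.exp(summary["coef upper 95%"]),
            "p": summary["p"],
        }
    )
    terms.index.name = "term"
    return MultivariateResult(terms=terms, dropped=dropped, n=len(frame), n_events=n_events)


# ---------------------------------------------------------------------------
# mutation grouping and Kaplan-Meier curves
# ---------------------------------------------------------------------------


def binary_group_from_mutations(
    mutations: MutationTable,
    gene: str,
    samples: Sequence[str],
    qualifying_classes: frozenset[str] | set[str] = NON_SILENT_CLASSES,
) -> pd.Series:
    """Mutant/wild-type labeling: mutant iff the sample has at least one
    qualifying (by default non-silent) record for ``gene``. A gene absent
    from the table yields all wild-type."""
    records = mutations.data
    hits = records[
        (records["gene_symbol"] == gene)
        & records["variant_classification"].isin(qualifying_classes)
    ]
    mutant = set(hits["sample_id"])
    return pd.Series(
        [s in mutant for s in samples], index=pd.Index(samples, name="sample_id"),
        name=f"{gene}_mutant",
    )


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate for one group: step coordinates and median.

    ``median`` is the smallest time with S(t) <= 0.5, NaN when the curve
    never reaches 0.5.
    """

    group: str
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.group,
                "time": self.times,
                "survival": self.survival,
                "at_risk": self.at_risk,
            }
        )


def km_curve(group, endpoint: SurvivalEndpoint) -> dict[str, KMCurve]:
    """Kaplan-Meier curves per group with per-group median survival."""
    labels = pd.Series(group)
    if len(labels) != len(endpoint):
        raise EstimationError("group labels and endpoint differ in length")
    curves = {}
    for value in sorted(map(str, labels.unique())):
        mask = labels.astype(str).to_numpy() == value
        time = endpoint.time.to_numpy(dtype=float)[mask]
        event = endpoint.event.to_numpy(dtype=float)[mask]
        data = _EndpointData(time, event)
        surv = np.cumprod(1.0 - data.d / data.n_risk)
        below = np.where(surv <= 0.5)[0]
        median = float(data.event_times[below[0]]) if len(below) else float("nan")
        curves[value] = KMCurve(
            group=value,
            times=data.event_times.copy(),
            survival=surv,
            at_risk=data.n_risk.astype(int),
            median=median,
        )
    return curves
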