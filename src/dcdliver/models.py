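"""Outcome and utilization models: Cox proportional hazards (graft
survival, patient survival, time-to-discharge) and logistic regression
(early graft loss, utilization), with restricted-cubic-spline terms,
log2-transformed right-skewed covariates, interactions, and Kaplan-Meier
curves.

Continuous covariates flagged ``rcs`` are expanded through
:mod:`dcdliver.splines`; right-skewed covariates not splined are
log2-transformed so their effect estimates read "per doubling".
Categorical covariates are dummy-coded against a stated reference level.
Cox fits use the Efron approximation for tied event times (day-granularity
registry data tie heavily).  Time-to-discharge is a Cox model where
discharge is the event, so a higher hazard means a shorter stay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError

from .impute import PooledFit, pool
from .splines import EffectCurve, SplineSpec, WaldTest, effect_curve, wald_group_test

__all__ = [
    "Term",
    "ModelSpec",
    "FitResult",
    "MIResult",
    "encode_covariates",
    "fit_cox",
    "fit_logistic",
    "km_curve",
    "run_mi_analysis",
]

KINDS = ("linear", "log2", "rcs", "categorical")


@dataclass(frozen=True)
class Term:
    """One covariate and how it enters the model.

    ``scale`` divides a linear covariate so effects read per ``scale`` units
    (e.g. 10 for "per 10 years").  ``log2_offset`` optionally shifts a log2
    covariate before the transform; by default a nonpositive value is a hard
    error rather than silently offset.
    """

    name: str
    kind: str = "linear"
    spline: SplineSpec | None = None
    reference: str | None = None
    scale: float = 1.0
    log2_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown term kind {self.kind!r} for {self.name}")


@dataclass(frozen=True)
class ModelSpec:
    """Declarative model description.

    ``outcome_type`` is ``time-to-event`` (duration/event columns) or
    ``binary`` (a 0/1 outcome column).  ``horizon_days`` administratively
    truncates follow-up (1-year vs 5-year analyses).
    """

    name: str
    outcome_type: str
    terms: tuple[Term, ...]
    outcome: str | None = None  # binary outcome column
    duration_col: str | None = None
    event_col: str | None = None
    interactions: tuple[tuple[str, str], ...] = ()
    horizon_days: float | None = None
    curve_terms: tuple[str, ...] = ()  # rcs terms to extract effect curves for

    def __post_init__(self) -> None:
        names = [t.name for t in self.terms]
        if len(set(names)) != len(names):
            raise ValueError("each covariate may appear once in a model spec")
        if self.outcome_type not in ("time-to-event", "binary"):
            raise ValueError(f"unknown outcome type {self.outcome_type!r}")
        if self.outcome_type == "binary" and self.outcome is None:
            raise ValueError("binary models need an outcome column")
        if self.outcome_type == "time-to-event" and (
            self.duration_col is None or self.event_col is None
        ):
            raise ValueError("time-to-event models need duration and event columns")

    def term(self, name: str) -> Term:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    def resolve(self, data: pd.DataFrame) -> "ModelSpec":
        """Fix spline knots from this cohort's observed values.

        Knots are computed once on the analysis cohort and reused across
        imputed datasets so pooled spline coefficients are commensurable.
        """
        terms = []
        for t in self.terms:
            if t.kind == "rcs":
                spec = t.spline or SplineSpec(t.name)
                if not spec.knots:
                    spec = spec.with_knots_from(data[t.name].to_numpy(dtype=float))
                terms.append(replace(t, spline=spec))
            else:
                terms.append(t)
        return replace(self, terms=tuple(terms))


def encode_covariates(
    data: pd.DataFrame, spec: ModelSpec
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Build the design matrix (no intercept) and the term-to-columns map."""
    blocks: dict[str, pd.DataFrame] = {}
    for t in spec.terms:
        x = data[t.name]
        if t.kind == "linear":
            blocks[t.name] = pd.DataFrame({t.name: x.to_numpy(dtype=float) / t.scale})
        elif t.kind == "log2":
            v = x.to_numpy(dtype=float) + t.log2_offset
            if np.nanmin(v) <= 0:
                raise ValueError(
                    f"{t.name}: log2 of a nonpositive value; set log2_offset "
                    "(e.g. 1.0) to shift zeros if appropriate"
                )
            blocks[t.name] = pd.DataFrame({f"log2_{t.name}": np.log2(v)})
        elif t.kind == "rcs":
            if t.spline is None or not t.spline.knots:
                raise ValueError(f"{t.name}: rcs term lacks knots; call spec.resolve(data)")
            basis = rcs = t.spline
            mat = _rcs(x.to_numpy(dtype=float), rcs)
            cols = [f"{t.name}_rcs{j}" for j in range(mat.shape[1])]
            blocks[t.name] = pd.DataFrame(mat, columns=cols)
        elif t.kind == "categorical":
            levels = pd.unique(x.dropna())
            ref = t.reference if t.reference is not None else sorted(map(str, levels))[0]
            if ref not in set(map(str, levels)):
                raise ValueError(f"{t.name}: reference level {ref!r} not present in data")
            dummies = pd.get_dummies(x.astype(str), prefix=t.name, dtype=float)
            keep = [c for c in dummies.columns if c != f"{t.name}_{ref}"]
            blocks[t.name] = dummies[keep]
    for df in blocks.values():
        df.index = data.index

    for a, b in spec.interactions:
        left, right = blocks[a], blocks[b]
        prod = {}
        for ca in left.columns:
            for cb in right.columns:
                prod[f"{ca}:{cb}"] = left[ca] * right[cb]
        blocks[f"{a}:{b}"] = pd.DataFrame(prod, index=data.index)

    X = pd.concat(blocks.values(), axis=1)
    groups = {name: list(df.columns) for name, df in blocks.items()}
    return X, groups


def _rcs(x: np.ndarray, spec: SplineSpec) -> np.ndarray:
    from .splines import rcs_basis

    return rcs_basis(x, spec)


@dataclass
class FitResult:
    """Coefficients and covariance of one model fit, with term grouping."""

    params: pd.Series
    cov: pd.DataFrame
    groups: dict[str, list[str]]
    n: int
    n_events: int
    model_type: str
    converged: bool = True
    flags: list[str] = field(default_factory=list)

    def group_wald(self, group: str) -> WaldTest:
        cols = self.groups[group]
        beta = self.params[cols].to_numpy()
        cov = self.cov.loc[cols, cols].to_numpy()
        return wald_group_test(beta, cov)

    def ratios(self) -> pd.DataFrame:
        """exp(coefficient) with 95% CI — hazard or odds ratios."""
        se = np.sqrt(np.diag(self.cov.to_numpy()))
        lo = self.params.to_numpy() - 1.959963984540054 * se
        hi = self.params.to_numpy() + 1.959963984540054 * se
        return pd.DataFrame(
            {
                "ratio": np.exp(self.params.to_numpy()),
                "lo": np.exp(lo),
                "hi": np.exp(hi),
            },
            index=self.params.index,
        )


def _truncate(time: np.ndarray, event: np.ndarray, horizon: float | None):
    if horizon is None:
        return time, event
    t = np.minimum(time, horizon)
    e = np.where(time > horizon, 0, event)
    return t, e


def _check_design(X: pd.DataFrame) -> None:
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ValueError(f"design matrix has missing values in {bad}; impute first")
    nunique = X.nunique()
    constant = nunique[nunique <= 1].index.tolist()
    if constant:
        raise ValueError(f"constant covariate column(s) after encoding: {constant}")


def fit_cox(data: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Cox partial-likelihood fit (Efron ties) of a resolved ModelSpec."""
    spec = spec.resolve(data)
    X, groups = encode_covariates(data, spec)
    _check_design(X)
    time, event = _truncate(
        data[spec.duration_col].to_numpy(dtype=float),
        data[spec.event_col].to_numpy(dtype=float).astype(int),
        spec.horizon_days,
    )
    n_events = int(event.sum())
    if n_events == 0:
        raise ValueError("no events in the fitting data")

    frame = X.copy()
    frame["_time"] = time
    frame["_event"] = event
    cph = CoxPHFitter()
    flags = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(frame, duration_col="_time", event_col="_event")
        except ConvergenceError as err:
            raise ValueError(f"Cox model failed to converge: {err}") from err
    if np.any(np.abs(cph.params_.to_numpy()) > 15):
        flags.append("possible monotone likelihood / separation")
    return FitResult(
        params=cph.params_.copy(),
        cov=cph.variance_matrix_.copy(),
        groups=groups,
        n=len(frame),
        n_events=n_events,
        model_type="cox",
        flags=flags,
    )


def fit_logistic(data: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Maximum-likelihood logistic fit of a resolved ModelSpec."""
    spec = spec.resolve(data)
    y = data[spec.outcome].to_numpy(dtype=float)
    classes = np.unique(y[np.isfinite(y)])
    if not np.all(np.isin(classes, [0.0, 1.0])):
        raise ValueError(f"outcome {spec.outcome!r} must be 0/1, saw {classes}")
    if classes.size < 2:
        raise ValueError(f"outcome {spec.outcome!r} has a single class")
    if spec.terms:
        X, groups = encode_covariates(data, spec)
        _check_design(X)
        Xc = sm.add_constant(X, has_constant="add")
    else:
        Xc = pd.DataFrame({"const": np.ones(len(data))}, index=data.index)
        groups = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, Xc, family=sm.families.Binomial()).fit()
    flags = []
    if np.any(np.abs(res.params.to_numpy()) > 15):
        flags.append("possible complete separation")
    return FitResult(
        params=res.params.copy(),
        cov=res.cov_params().copy(),
        groups=groups,
        n=len(data),
        n_events=int(y.sum()),
        model_type="logistic",
        flags=flags,
    )


def km_curve(
    time: np.ndarray,
    event: np.ndarray,
    labels: np.ndarray | None = None,
    at_risk_times: np.ndarray | None = None,
) -> pd.DataFrame:
    """Product-limit survival estimate per group, with number-at-risk counts.

    Returns a long-format frame (group, time, survival, n_at_risk) where the
    n_at_risk rows are evaluated at ``at_risk_times`` (default: quintiles of
    the follow-up span).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float).astype(int)
    if labels is None:
        labels = np.repeat("all", time.size)
    labels = np.asarray(labels)
    if at_risk_times is None:
        at_risk_times = np.linspace(0, time.max() if time.size else 1.0, 5)
    rows = []
    for g in pd.unique(labels):
        mask = labels == g
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask])
        surv = kmf.survival_function_
        n_at_risk = {
            float(t): int((time[mask] >= t).sum()) for t in at_risk_times
        }
        for t_val, s in zip(surv.index.to_numpy(), surv.iloc[:, 0].to_numpy()):
            rows.append(
                {
                    "group": g,
                    "time": float(t_val),
                    "survival": float(s),
                    "n_at_risk": n_at_risk.get(float(t_val)),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class MIResult:
    """Pooled fit plus spline Wald tests and effect curves."""

    pooled: PooledFit
    wald: dict[str, WaldTest]
    curves: dict[str, EffectCurve]
    spec: ModelSpec


def run_mi_analysis(
    datasets: list[pd.DataFrame],
    spec: ModelSpec,
    curve_grid: dict[str, np.ndarray] | None = None,
) -> MIResult:
    """Fit the spec on every completed dataset, pool by Rubin's rules, and
    derive spline-block Wald tests and effect curves.

    Any single-dataset fit failure aborts with the dataset index — datasets
    are never silently dropped.
    """
    spec = spec.resolve(datasets[0])
    fits = []
    for i, d in enumerate(datasets):
        try:
            if spec.outcome_type == "time-to-event":
                fits.append(fit_cox(d, spec))
            else:
                fits.append(fit_logistic(d, spec))
        except Exception as err:
            raise RuntimeError(f"model fit failed on imputed dataset {i}: {err}") from err

    if len(fits) == 1:
        f = fits[0]
        pooled = PooledFit(
            terms=list(f.params.index),
            beta=f.params.to_numpy(dtype=float),
            cov=f.cov.to_numpy(dtype=float),
            within=f.cov.to_numpy(dtype=float),
            between=np.zeros_like(f.cov.to_numpy(dtype=float)),
            m=1,
            groups=f.groups,
        )
    else:
        pooled = pool(fits)
        pooled.groups = fits[0].groups

    wald: dict[str, WaldTest] = {}
    curves: dict[str, EffectCurve] = {}
    scale = "hazard" if spec.outcome_type == "time-to-event" else "odds"
    for t in spec.terms:
        if t.kind != "rcs":
            continue
        wald[t.name] = pooled.group_wald(t.name)
        if t.name in spec.curve_terms or not spec.curve_terms:
            x = datasets[0][t.name].to_numpy(dtype=float)
            x = x[np.isfinite(x)]
            grid = (
                curve_grid.get(t.name)
                if curve_grid and t.name in curve_grid
                else np.linspace(np.percentile(x, 1), np.percentile(x, 99), 101)
            )
            idx = pooled.term_index(pooled.groups[t.name])
            curves[t.name] = effect_curve(
                pooled.beta,
                pooled.cov,
                idx,
                t.spline,
                grid,
                scale=scale,
                training_range=(float(np.percentile(x, 1)), float(np.percentile(x, 99))),
            )
    return MIResult(pooled=pooled, wald=wald, curves=curves, spec=spec)
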