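"""Cohort assembly: derived warm-ischemia intervals, recovery-pathway
classification, inclusion/exclusion rules, length-of-stay censoring and TTD
stratification.

Terminology (all times in minutes unless noted):

* TTD — time to death: withdrawal of life-sustaining treatment (WLST) to
  asystole.
* Asystolic time — asystole to abdominal aortic cold flush (the end of NRP
  in NRP cases).
* FTTD — functional TTD: systolic blood pressure first <50 mm Hg until cold
  flush.  As printed this interval runs to cold flush and therefore subsumes
  the asystolic period; ``fttd_end="asystole"`` switches to the stricter
  reading that stops the clock at asystole.
* SRR vs NRP — recovery pathway inferred from asystolic time: >30 min is
  NRP, <=30 min (boundary included) is SRR.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CohortSpec",
    "derive_times",
    "classify_pathway",
    "apply_inclusion",
    "censor_los",
    "stratify_ttd",
    "ttd_stratum_bounds",
]


@dataclass(frozen=True)
class CohortSpec:
    """Analysis-cohort rules and thresholds."""

    adult_age_min: float = 18.0
    pathway_rule_threshold: float = 30.0  # minutes, asystole to flush
    los_censor_days: float = 90.0
    early_graft_loss_days: float = 30.0
    fttd_sbp_threshold: float = 50.0  # mm Hg (documentation of the definition)
    ttd_strata: tuple[float, ...] = (0.0, 10.0, 15.0, 30.0, 45.0, float("inf"))
    year_min: int | None = None
    year_max: int | None = None
    fttd_end: str = "flush"  # "flush" (as defined) or "asystole"

    def __post_init__(self) -> None:
        edges = np.asarray(self.ttd_strata, dtype=float)
        if np.any(np.diff(edges) <= 0):
            raise ValueError(f"ttd_strata edges must be strictly increasing: {edges}")
        for name in ("adult_age_min", "pathway_rule_threshold", "los_censor_days",
                     "early_graft_loss_days", "fttd_sbp_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fttd_end not in ("flush", "asystole"):
            raise ValueError("fttd_end must be 'flush' or 'asystole'")


def _minutes_between(later: pd.Series, earlier: pd.Series) -> pd.Series:
    return (pd.to_datetime(later) - pd.to_datetime(earlier)).dt.total_seconds() / 60.0


def derive_times(
    donors: pd.DataFrame, spec: CohortSpec = CohortSpec()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Attach ``ttd_min``, ``asystolic_min`` and ``fttd_min`` to the donor
    table, from numeric intervals when present, else from the
    WLST/asystole/flush timestamp triple.

    Returns ``(donors, errors)``: records with negative intervals (or
    out-of-order timestamps) are dropped from the first frame and logged in
    the second with a reason, mirroring a registry-cleaning audit trail.
    """
    out = donors.copy()
    if "ttd_min" not in out.columns or "asystolic_min" not in out.columns:
        for col in ("wlst_time", "asystole_time", "flush_time"):
            if col not in out.columns:
                raise ValueError(
                    "donor table needs either ttd_min/asystolic_min or the "
                    f"timestamp triple; missing {col!r}"
                )
        out["ttd_min"] = _minutes_between(out["asystole_time"], out["wlst_time"])
        out["asystolic_min"] = _minutes_between(out["flush_time"], out["asystole_time"])
        if "sbp50_time" in out.columns:
            out["sbp50_to_asystole_min"] = _minutes_between(
                out["asystole_time"], out["sbp50_time"]
            )

    if "sbp50_to_asystole_min" in out.columns:
        pre = out["sbp50_to_asystole_min"]
        if spec.fttd_end == "flush":
            out["fttd_min"] = pre + out["asystolic_min"]
        else:
            out["fttd_min"] = pre
    else:
        out["fttd_min"] = np.nan

    bad_ttd = out["ttd_min"] < 0
    bad_asys = out["asystolic_min"] < 0
    errors = []
    for mask, reason in [
        (bad_ttd, "asystole precedes WLST (negative TTD)"),
        (bad_asys & ~bad_ttd, "cold flush precedes asystole (negative asystolic time)"),
    ]:
        for donor_id in out.loc[mask, "donor_id"] if "donor_id" in out else out.index[mask]:
            errors.append({"donor_id": donor_id, "reason": reason})
    out = out[~(bad_ttd | bad_asys)].copy()
    return out, pd.DataFrame(errors, columns=["donor_id", "reason"])


def classify_pathway(
    asystolic_min: pd.Series | np.ndarray | float,
    threshold: float = 30.0,
) -> pd.Series | str:
    """Recovery pathway from asystole-to-flush time: NRP if strictly greater
    than the threshold (30 min), SRR at or below it, "unknown" if missing."""
    scalar = np.isscalar(asystolic_min)
    a = pd.Series(np.atleast_1d(np.asarray(asystolic_min, dtype=float)))
    result = pd.Series(
        np.where(a.isna(), "unknown", np.where(a > threshold, "NRP", "SRR")),
        index=a.index,
    )
    return result.iloc[0] if scalar else result


def apply_inclusion(
    donors: pd.DataFrame,
    transplants: pd.DataFrame,
    spec: CohortSpec = CohortSpec(),
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Apply inclusion/exclusion rules and build the two analysis cohorts.

    The utilization cohort holds every eligible potential donor regardless
    of whether the liver was used; the outcome cohort holds transplants to
    adult recipients linked to eligible donors.  The exclusion log counts
    each rule's removals in application order, so counts sum to the
    input-minus-output sizes.
    """
    log: dict[str, int] = {}
    d = donors

    if "pathway" not in d.columns:
        d = d.assign(pathway=classify_pathway(d["asystolic_min"], spec.pathway_rule_threshold))

    n0 = len(d)
    if "uncontrolled" in d.columns:
        d = d[(d["uncontrolled"].fillna(0) == 0)]
    log["uncontrolled_dcd"] = n0 - len(d)

    n0 = len(d)
    d = d[d["ttd_min"].notna() & d["asystolic_min"].notna()]
    log["missing_ttd_or_asystolic"] = n0 - len(d)

    if spec.year_min is not None and "donation_year" in d.columns:
        n0 = len(d)
        d = d[(d["donation_year"] >= spec.year_min)]
        log["before_window"] = n0 - len(d)
    if spec.year_max is not None and "donation_year" in d.columns:
        n0 = len(d)
        d = d[(d["donation_year"] <= spec.year_max)]
        log["after_window"] = n0 - len(d)

    utilization_cohort = d.copy()

    t = transplants.merge(utilization_cohort, on="donor_id", how="inner")
    log["transplant_donor_excluded"] = len(transplants) - len(t)

    n0 = len(t)
    t = t[t["recipient_age"] >= spec.adult_age_min]
    log["recipient_under_age"] = n0 - len(t)

    if "multiorgan" in t.columns:
        n0 = len(t)
        t = t[t["multiorgan"].fillna(0) == 0]
        log["multiorgan"] = n0 - len(t)

    outcome_cohort = t.copy()
    return utilization_cohort, outcome_cohort, log


def censor_los(
    los_days: pd.Series | np.ndarray,
    discharged: pd.Series | np.ndarray,
    spec: CohortSpec = CohortSpec(),
) -> tuple[np.ndarray, np.ndarray]:
    """Length-of-stay as a time-to-discharge pair (time, event).

    Discharge is the event.  Stays are censored at ``los_censor_days``
    (90 d); patients who died or lost their graft before discharge are
    censored at that time (``discharged`` false with ``los_days`` the days
    to death/graft loss).
    """
    los = np.asarray(los_days, dtype=float)
    if np.any(los < 0):
        raise ValueError("length of stay cannot be negative")
    event = np.asarray(discharged, dtype=float).astype(int)
    cap = spec.los_censor_days
    time = np.minimum(los, cap)
    event = np.where(los > cap, 0, event)
    return time, event


def ttd_stratum_bounds(spec: CohortSpec = CohortSpec()) -> list[tuple[float, float, str]]:
    edges = list(spec.ttd_strata)
    out = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if lo <= 0:
            label = f"<{hi:g}"
        elif np.isinf(hi):
            label = f">={lo:g}"
        else:
            label = f"{lo:g}-{hi:g}"
        out.append((lo, hi, label))
    return out


def stratify_ttd(
    ttd_min: pd.Series | np.ndarray | float, spec: CohortSpec = CohortSpec()
) -> pd.Series | str:
    """Assign TTD values to half-open strata [lo, hi); a value on a shared
    edge belongs to the upper stratum (30 min falls in "30-45")."""
    scalar = np.isscalar(ttd_min)
    x = np.atleast_1d(np.asarray(ttd_min, dtype=float))
    bounds = ttd_stratum_bounds(spec)
    labels = np.array([b[2] for b in bounds] + [None], dtype=object)
    edges = np.asarray(spec.ttd_strata, dtype=float)
    idx = np.searchsorted(edges[1:], x, side="right")
    idx = np.clip(idx, 0, len(bounds) - 1)
    result = pd.Series(labels[idx])
    result[~np.isfinite(x)] = None
    return result.iloc[0] if scalar else result


def write_exclusion_log(log: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(log, indent=2))
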