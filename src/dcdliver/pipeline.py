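"""End-to-end orchestration: simulate/read -> assemble -> impute -> fit ->
counterfactual, with reproducible seeding and publication-style outputs.

All randomness flows from one global seed through named substreams, so each
stage is independently reproducible; every artifact records the seed in the
run manifest.  Outputs are plain text: CSV tables, CSV effect-curve and
Kaplan-Meier data, and JSON for the exclusion log, counterfactual results
and manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import version as pkg_version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import registry as registry_mod
from .counterfactual import CounterfactualSpec, bootstrap_ci
from .impute import ImputationConfig, PooledFit, nelson_aalen, impute
from .models import MIResult, ModelSpec, km_curve, run_mi_analysis
from .specs import builtin_spec, drop_term, load_model_spec

log = logging.getLogger("dcdliver")

__all__ = ["RunConfig", "run_pipeline", "render_table"]

_STAGES = ("generate", "missingness", "impute", "bootstrap")


def _stage_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(_STAGES, ss.spawn(len(_STAGES)))
    }


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    seed: int = 0
    outdir: Path = Path("dcdliver_run")
    generator: registry_mod.GeneratorConfig | None = None
    donors_path: Path | None = None
    transplants_path: Path | None = None
    cohort: cohort_mod.CohortSpec = field(default_factory=cohort_mod.CohortSpec)
    m_imputations: int = 20
    k_pmm: int = 3
    outcome_spec: ModelSpec | None = None
    utilization_spec: ModelSpec | None = None
    counterfactual_targets: tuple[tuple[float, float], ...] = (
        (15.0, 30.0),
        (30.0, 45.0),
    )
    counterfactual_reference: tuple[float, float] = (0.0, 10.0)
    bootstrap_reps: int = 10_000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        cfg = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        for key in ("seed", "m_imputations", "k_pmm", "bootstrap_reps"):
            if key in cfg:
                kwargs[key] = cfg[key]
        if "outdir" in cfg:
            kwargs["outdir"] = Path(cfg["outdir"])
        for key in ("donors_path", "transplants_path"):
            if cfg.get(key):
                p = Path(cfg[key])
                if not p.exists():
                    raise FileNotFoundError(f"{key}: no such file {p}")
                kwargs[key] = p
        if "generator" in cfg:
            gen = dict(cfg["generator"])
            kwargs["generator"] = registry_mod.GeneratorConfig(**gen)
        if "cohort" in cfg:
            kwargs["cohort"] = cohort_mod.CohortSpec(**cfg["cohort"])
        for key, attr in (
            ("outcome_model", "outcome_spec"),
            ("utilization_model", "utilization_spec"),
        ):
            if cfg.get(key):
                kwargs[attr] = load_model_spec(cfg[key])
        if "counterfactual_targets" in cfg:
            kwargs["counterfactual_targets"] = tuple(
                tuple(t) for t in cfg["counterfactual_targets"]
            )
        if "counterfactual_reference" in cfg:
            kwargs["counterfactual_reference"] = tuple(cfg["counterfactual_reference"])
        return cls(**kwargs)


def _hash_frame(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the report bundle to ``config.outdir``.

    Returns the manifest dict.  Any stage failure raises with the stage
    named in the message.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest: dict = {
        "seed": config.seed,
        "stage_seeds": seeds,
        "version": pkg_version("dcdliver"),
    }

    # -- stage: simulate or read -------------------------------------------
    stage = "simulate"
    try:
        if config.generator is not None:
            gen = config.generator
            if gen.seed != seeds["generate"]:
                from dataclasses import replace as dc_replace

                gen = dc_replace(gen, seed=seeds["generate"])
            donors, transplants, truth = registry_mod.generate_registry(gen)
            donors = registry_mod.inject_missingness(
                donors, gen.missingness, seeds["missingness"]
            )
            registry_mod.write_registry(donors, transplants, truth, outdir / "registry")
        else:
            if config.donors_path is None or config.transplants_path is None:
                raise FileNotFoundError(
                    "no generator config and no input table paths provided"
                )
            donors = registry_mod.read_donor_table(config.donors_path)
            transplants = registry_mod.read_transplant_table(config.transplants_path)
        manifest["n_donors_raw"] = len(donors)
        manifest["n_transplants_raw"] = len(transplants)
        manifest["donors_hash"] = _hash_frame(donors)
        log.info("stage=%s donors=%d transplants=%d", stage, len(donors), len(transplants))

        # -- stage: assemble ----------------------------------------------
        stage = "assemble"
        donors, time_errors = cohort_mod.derive_times(donors, config.cohort)
        util_cohort, outcome_cohort, excl = cohort_mod.apply_inclusion(
            donors, transplants, config.cohort
        )
        excl["invalid_timing"] = len(time_errors)
        cohort_mod.write_exclusion_log(excl, outdir / "exclusion_log.json")
        los_time, los_event = cohort_mod.censor_los(
            outcome_cohort["los_days"], outcome_cohort["discharged"], config.cohort
        )
        outcome_cohort = outcome_cohort.assign(los_time=los_time, los_event=los_event)
        manifest["n_utilization_cohort"] = len(util_cohort)
        manifest["n_outcome_cohort"] = len(outcome_cohort)
        manifest["exclusions"] = excl
        log.info(
            "stage=%s utilization=%d outcome=%d exclusions=%s",
            stage, len(util_cohort), len(outcome_cohort), excl,
        )

        # -- stage: impute -------------------------------------------------
        stage = "impute"
        util_spec = config.utilization_spec or builtin_spec("utilization")
        outcome_spec = config.outcome_spec or builtin_spec("graft_survival")
        srr = util_cohort[util_cohort["pathway"] == "SRR"].reset_index(drop=True)

        util_missing = tuple(
            t.name for t in util_spec.terms if srr[t.name].isna().any()
        )
        util_datasets = _impute_cohort(
            srr, util_missing, ("utilized",), config, seeds["impute"]
        )

        outcome_cohort = outcome_cohort.assign(
            graft_cumhaz=nelson_aalen(
                outcome_cohort["graft_time_days"], outcome_cohort["graft_event"]
            )
        )
        outcome_missing = tuple(
            t.name
            for t in outcome_spec.terms
            if outcome_cohort[t.name].isna().any()
        )
        outcome_datasets = _impute_cohort(
            outcome_cohort,
            outcome_missing,
            ("graft_event", "graft_cumhaz"),
            config,
            seeds["impute"] + 1,
        )
        manifest["m_imputations"] = len(util_datasets)
        log.info("stage=%s util_missing=%s outcome_missing=%s",
                 stage, util_missing, outcome_missing)

        # -- stage: fit ------------------------------------------------------
        stage = "fit-utilization"
        util_fit = run_mi_analysis(util_datasets, util_spec)
        _write_mi_result(util_fit, outdir, "utilization")

        stage = "fit-outcomes"
        outcome_fit = run_mi_analysis(outcome_datasets, outcome_spec)
        _write_mi_result(outcome_fit, outdir, "graft_survival")

        km = km_curve(
            outcome_cohort["graft_time_days"].to_numpy(),
            outcome_cohort["graft_event"].to_numpy(),
            cohort_mod.stratify_ttd(outcome_cohort["ttd_min"], config.cohort).to_numpy(),
            at_risk_times=np.array([0.0, 91.0, 182.0, 273.0, 365.0]),
        )
        km.to_csv(outdir / "km_graft_by_ttd.csv", index=False)

        manifest["utilization_ttd_spline_p"] = float(util_fit.wald["ttd_min"].p)
        manifest["graft_ttd_spline_p"] = float(outcome_fit.wald["ttd_min"].p)

        # -- stage: counterfactual ------------------------------------------
        stage = "counterfactual"
        cf_model = drop_term(drop_term(util_spec, "ttd_min"), "asystolic_min")
        cf_data = util_datasets[0]  # designated completed dataset
        cf_results = {}
        for i, target in enumerate(config.counterfactual_targets):
            cf_spec = CounterfactualSpec(
                model=cf_model,
                reference=config.counterfactual_reference,
                target=tuple(target),
                reps=config.bootstrap_reps,
                seed=seeds["bootstrap"] + i,
            )
            res = bootstrap_ci(cf_data, cf_spec)
            label = f"ttd_{target[0]:g}_{target[1]:g}"
            cf_results[label] = res.to_dict()
            log.info("stage=%s target=%s extra=%.1f", stage, label, res.extra)
        (outdir / "counterfactual.json").write_text(json.dumps(cf_results, indent=2))
        manifest["counterfactual"] = cf_results
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _impute_cohort(
    data: pd.DataFrame,
    variables: tuple[str, ...],
    auxiliaries: tuple[str, ...],
    config: RunConfig,
    seed: int,
) -> list[pd.DataFrame]:
    if not variables:
        return [data]
    imp = ImputationConfig(
        variables=variables,
        m=config.m_imputations,
        k_pmm=config.k_pmm,
        seed=seed,
        auxiliaries=auxiliaries,
    )
    return impute(data, imp)


def _write_mi_result(result: MIResult, outdir: Path, label: str) -> None:
    render_table(result).to_csv(outdir / f"{label}_table.csv", index=False)
    for name, curve in result.curves.items():
        curve.to_frame().to_csv(outdir / f"{label}_curve_{name}.csv", index=False)


def _fmt_p(p: float) -> str:
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def render_table(result: MIResult) -> pd.DataFrame:
    """Publication-style results table: one row per term, spline blocks
    collapsed to a joint Wald-test row, categorical reference rows marked
    with an em-dash, log2 terms annotated "per doubling"."""
    pooled = result.pooled
    spec = result.spec
    scale_label = "HR" if spec.outcome_type == "time-to-event" else "OR"
    se = pooled.se
    z = 1.959963984540054
    rows = []
    for t in spec.terms:
        cols = pooled.groups.get(t.name, [])
        if t.kind == "rcs":
            wt = result.wald.get(t.name) or pooled.group_wald(t.name)
            rows.append(
                {
                    "variable": f"RCS term: {t.name}",
                    f"{scale_label} (95% CI)": "Wald test",
                    "P": _fmt_p(wt.p),
                }
            )
            continue
        if t.kind == "categorical":
            ref = t.reference
            rows.append({"variable": t.name, f"{scale_label} (95% CI)": "", "P": ""})
            rows.append(
                {"variable": f"  {ref}", f"{scale_label} (95% CI)": "Ref", "P": "–"}
            )
        for col in cols:
            i = pooled.terms.index(col)
            with np.errstate(over="ignore"):
                est = np.exp(pooled.beta[i])
                lo = np.exp(pooled.beta[i] - z * se[i])
                hi = np.exp(pooled.beta[i] + z * se[i])
            p = pooled.p[i]
            label = col
            if t.kind == "categorical":
                label = "  " + col.removeprefix(f"{t.name}_")
            elif t.kind == "log2":
                label = f"{t.name} (per doubling)"
            elif t.scale != 1.0:
                label = f"{t.name} (per {t.scale:g} units)"
            rows.append(
                {
                    "variable": label,
                    f"{scale_label} (95% CI)": f"{est:.3f} ({lo:.3f}-{hi:.3f})",
                    "P": _fmt_p(p),
                }
            )
    return pd.DataFrame(rows)
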