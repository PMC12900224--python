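"""YAML model-spec loading.

Model specs (outcome, covariates, per-covariate treatment) are declarative
YAML documents; the package ships defaults for the graft-survival Cox model
and the utilization logistic model under ``dcdliver/configs/``.
"""

from __future__ import annotations

from dataclasses import replace
from importlib import resources
from pathlib import Path

import yaml

from .models import ModelSpec, Term
from .splines import SplineSpec

__all__ = ["load_model_spec", "builtin_spec", "drop_term"]


def _term_from_dict(d: dict) -> Term:
    d = dict(d)
    spline = None
    if d.get("kind") == "rcs":
        spline_cfg = d.pop("spline", {}) or {}
        spline = SplineSpec(
            variable=d["name"],
            knots=tuple(spline_cfg.get("knots", ())),
            x_ref=spline_cfg.get("x_ref"),
            percentiles=tuple(spline_cfg.get("percentiles", (5, 35, 65, 95))),
        )
    return Term(
        name=d["name"],
        kind=d.get("kind", "linear"),
        spline=spline,
        reference=d.get("reference"),
        scale=float(d.get("scale", 1.0)),
        log2_offset=float(d.get("log2_offset", 0.0)),
    )


def load_model_spec(source: str | Path | dict) -> ModelSpec:
    """Build a :class:`ModelSpec` from a YAML path or an already-parsed dict."""
    if isinstance(source, (str, Path)):
        cfg = yaml.safe_load(Path(source).read_text())
    else:
        cfg = dict(source)
    return ModelSpec(
        name=cfg["name"],
        outcome_type=cfg["outcome_type"],
        outcome=cfg.get("outcome"),
        duration_col=cfg.get("duration_col"),
        event_col=cfg.get("event_col"),
        horizon_days=cfg.get("horizon_days"),
        terms=tuple(_term_from_dict(t) for t in cfg.get("terms", [])),
        interactions=tuple(tuple(pair) for pair in cfg.get("interactions", [])),
        curve_terms=tuple(cfg.get("curve_terms", [])),
    )


def builtin_spec(name: str) -> ModelSpec:
    """Load one of the shipped model specs ("graft_survival", "utilization")."""
    ref = resources.files("dcdliver.configs").joinpath(f"{name}.yaml")
    return load_model_spec(yaml.safe_load(ref.read_text()))


def drop_term(spec: ModelSpec, name: str) -> ModelSpec:
    """Return a copy of the spec without the named covariate (e.g. the TTD
    term when building the counterfactual reference model)."""
    terms = tuple(t for t in spec.terms if t.name != name)
    curve_terms = tuple(c for c in spec.curve_terms if c != name)
    interactions = tuple(p for p in spec.interactions if name not in p)
    return replace(
        spec,
        name=f"{spec.name}_no_{name}",
        terms=terms,
        curve_terms=curve_terms,
        interactions=interactions,
    )
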