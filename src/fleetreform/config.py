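"""Structured config files: model parameters, weights, proposals, synthetic worlds.

All configs are YAML (JSON is a YAML subset and also accepted).  Each
loader validates the document and raises :class:`ConfigurationError`
naming the offending field.  ``load_*`` functions accept a path;
``parse_*`` functions accept an already-decoded mapping, which is what the
tests and programmatic callers use.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigurationError
from .policy import (
    CapBasis,
    CapRule,
    Discipline,
    DisciplineCategory,
    Predicate,
    PredicateKind,
    Proposal,
    RemovalScope,
)
from .projection import ModelParams
from .synthetic import HighSeasMixture, SyntheticConfig
from .vessels import EffectiveSubsidyWeights


def _read_yaml(path: str | Path) -> Any:
    try:
        with open(path, encoding="utf-8") as fh:
            return yaml.safe_load(fh)
    except FileNotFoundError as exc:
        raise ConfigurationError("path", f"config file not found: {path}") from exc
    except yaml.YAMLError as exc:
        raise ConfigurationError("path", f"malformed YAML in {path}: {exc}") from exc


def _require_mapping(doc: Any, what: str) -> Mapping[str, Any]:
    if not isinstance(doc, Mapping):
        raise ConfigurationError(what, "document must be a mapping")
    return doc


def _pop_number(doc: dict, field: str, required: bool = True, default=None):
    if field not in doc:
        if required:
            raise ConfigurationError(field, "missing required field")
        return default
    value = doc.pop(field)
    if isinstance(value, str):
        # YAML 1.1 reads exponent forms like 2.5e9 as strings; coerce them
        try:
            value = float(value)
        except ValueError:
            raise ConfigurationError(field, f"expected a number, got {value!r}")
    if not isinstance(value, (int, float)) or isinstance(value, bool):
        raise ConfigurationError(field, f"expected a number, got {value!r}")
    return value


# ---------------------------------------------------------------------------
# Model parameters
# ---------------------------------------------------------------------------

def parse_model_params(doc: Mapping[str, Any]) -> ModelParams:
    d = dict(_require_mapping(doc, "params"))
    kwargs = {
        "phi": _pop_number(d, "phi"),
        "k": _pop_number(d, "k"),
        "b0": _pop_number(d, "b0"),
        "p0": _pop_number(d, "p0"),
        "epsilon": _pop_number(d, "epsilon"),
        "beta": _pop_number(d, "beta"),
        "eta": _pop_number(d, "eta"),
        "omega": _pop_number(d, "omega"),
        "msy": _pop_number(d, "msy", required=False),
        "g": _pop_number(d, "g", required=False),
        "base_year": int(_pop_number(d, "base_year", required=False, default=2018)),
        "horizon_year": int(_pop_number(d, "horizon_year", required=False, default=2050)),
    }
    d.pop("description", None)
    if d:
        raise ConfigurationError(next(iter(d)), "unknown field in params config")
    try:
        return ModelParams(**kwargs)
    except Exception as exc:
        raise ConfigurationError("params", str(exc)) from exc


def load_model_params(path: str | Path) -> ModelParams:
    return parse_model_params(_read_yaml(path))


# ---------------------------------------------------------------------------
# Effective-subsidy weights
# ---------------------------------------------------------------------------

def parse_weights(doc: Mapping[str, Any]) -> EffectiveSubsidyWeights:
    d = dict(_require_mapping(doc, "weights"))
    d.pop("description", None)
    multiplier = d.pop("multiplier", {})
    default = d.pop("default", None)
    if d:
        raise ConfigurationError(next(iter(d)), "unknown field in weights config")
    if not isinstance(multiplier, Mapping):
        raise ConfigurationError("multiplier", "must be a mapping of type -> number")
    for t, m in multiplier.items():
        if not isinstance(m, (int, float)) or isinstance(m, bool) or m < 0:
            raise ConfigurationError(f"multiplier.{t}", "must be a number >= 0")
    if default is not None and (not isinstance(default, (int, float)) or default < 0):
        raise ConfigurationError("default", "must be a number >= 0")
    return EffectiveSubsidyWeights(multiplier=dict(multiplier), default=default)


def load_weights(path: str | Path) -> EffectiveSubsidyWeights:
    return parse_weights(_read_yaml(path))


# ---------------------------------------------------------------------------
# Proposals
# ---------------------------------------------------------------------------

def _parse_predicate(doc: Mapping[str, Any]) -> Predicate:
    d = dict(doc)
    kind_raw = d.pop("kind", None)
    try:
        kind = PredicateKind(kind_raw)
    except ValueError:
        raise ConfigurationError("predicate.kind", f"unknown predicate kind {kind_raw!r}")
    threshold = d.pop("threshold", None)
    statuses = frozenset(d.pop("statuses", []) or [])
    if d:
        raise ConfigurationError(f"predicate.{next(iter(d))}", "unknown predicate field")
    return Predicate(kind=kind, threshold=threshold, statuses=statuses)


def _parse_discipline(doc: Mapping[str, Any], index: int) -> Discipline:
    d = dict(_require_mapping(doc, f"disciplines[{index}]"))
    try:
        category = DisciplineCategory(d.pop("category", None))
    except ValueError:
        raise ConfigurationError(f"disciplines[{index}].category", "must be IUU, overfished or OFOC")
    if "predicate" not in d:
        raise ConfigurationError(f"disciplines[{index}].predicate", "missing predicate")
    predicate = _parse_predicate(_require_mapping(d.pop("predicate"), "predicate"))
    scope_doc = d.pop("removal_scope", "all_capacity_enhancing")
    if scope_doc == "all_capacity_enhancing":
        scope = RemovalScope(all_capacity_enhancing=True)
    elif isinstance(scope_doc, Mapping) and "listed_types" in scope_doc:
        scope = RemovalScope(
            all_capacity_enhancing=False,
            listed_types=frozenset(scope_doc["listed_types"]),
        )
    else:
        raise ConfigurationError(
            f"disciplines[{index}].removal_scope",
            "must be 'all_capacity_enhancing' or {listed_types: [...]}",
        )
    exemptions = frozenset(d.pop("exemptions", []) or [])
    name = str(d.pop("name", ""))
    if d:
        raise ConfigurationError(f"disciplines[{index}].{next(iter(d))}", "unknown field")
    return Discipline(
        category=category,
        predicate=predicate,
        removal_scope=scope,
        exemptions=exemptions,
        name=name,
    )


def _parse_cap_rule(doc: Mapping[str, Any]) -> CapRule:
    d = dict(_require_mapping(doc, "cap_rule"))
    try:
        basis = CapBasis(d.pop("cap_basis", None))
    except ValueError:
        raise ConfigurationError(
            "cap_rule.cap_basis",
            "must be percent_of_current_subsidies or percent_of_landed_value",
        )
    tiers = d.pop("tier_criterion", None)
    pcts = d.pop("cap_percent_by_tier", None)
    green = frozenset(d.pop("green_box_types", []) or [])
    if not isinstance(tiers, Mapping) or not tiers:
        raise ConfigurationError("cap_rule.tier_criterion", "must map development status -> tier")
    if not isinstance(pcts, Mapping) or not pcts:
        raise ConfigurationError("cap_rule.cap_percent_by_tier", "must map tier -> percentage")
    if d:
        raise ConfigurationError(f"cap_rule.{next(iter(d))}", "unknown field")
    return CapRule(
        tier_criterion=dict(tiers),
        cap_basis=basis,
        cap_percent_by_tier={k: float(v) for k, v in pcts.items()},
        green_box_types=green,
    )


def parse_proposal(doc: Mapping[str, Any]) -> Proposal:
    d = dict(_require_mapping(doc, "proposal"))
    name = str(d.pop("name", "unnamed proposal"))
    d.pop("description", None)
    disciplines = tuple(
        _parse_discipline(item, i) for i, item in enumerate(d.pop("disciplines", []) or [])
    )
    cap_doc = d.pop("cap_rule", None)
    cap_rule = _parse_cap_rule(cap_doc) if cap_doc is not None else None
    if d:
        raise ConfigurationError(next(iter(d)), "unknown field in proposal config")
    try:
        return Proposal(name=name, disciplines=disciplines, cap_rule=cap_rule)
    except ConfigurationError:
        raise
    except Exception as exc:
        raise ConfigurationError("proposal", str(exc)) from exc


def load_proposal(path: str | Path) -> Proposal:
    return parse_proposal(_read_yaml(path))


# ---------------------------------------------------------------------------
# Synthetic config
# ---------------------------------------------------------------------------

def parse_synthetic_config(doc: Mapping[str, Any]) -> SyntheticConfig:
    d = dict(_require_mapping(doc, "synthetic"))
    d.pop("description", None)
    hs = d.pop("high_seas_fraction_dist", None)
    kwargs: dict[str, Any] = {}
    if hs is not None:
        hs = dict(_require_mapping(hs, "high_seas_fraction_dist"))
        kwargs["high_seas_fraction_dist"] = HighSeasMixture(**hs)
    for field in (
        "n_vessels",
        "n_flag_states",
        "n_fao_regions",
        "iuu_fraction",
        "disputed_fraction",
        "management_score_alpha",
        "management_score_beta",
        "stock_status_sigma",
        "effort_median_kwh",
        "effort_sigma",
        "price_usd_per_t",
        "seed",
    ):
        if field in d:
            kwargs[field] = d.pop(field)
    for field in ("subsidy_type_shares", "development_status_shares"):
        if field in d:
            kwargs[field] = dict(d.pop(field))
    for field in ("catch_rate_range", "subsidy_rate_range"):
        if field in d:
            kwargs[field] = tuple(d.pop(field))
    if d:
        raise ConfigurationError(next(iter(d)), "unknown field in synthetic config")
    try:
        return SyntheticConfig(**kwargs)
    except ConfigurationError:
        raise
    except Exception as exc:
        raise ConfigurationError("synthetic", str(exc)) from exc


def load_synthetic_config(path: str | Path) -> SyntheticConfig:
    return parse_synthetic_config(_read_yaml(path))


# ---------------------------------------------------------------------------
# Shipped defaults
# ---------------------------------------------------------------------------

def _data_path(*parts: str) -> Path:
    return Path(resources.files("fleetreform").joinpath("data", *parts))  # type: ignore[arg-type]


def default_model_params() -> ModelParams:
    """The shipped illustrative global parameterisation."""
    return load_model_params(_data_path("params_default.yaml"))


def default_weights() -> EffectiveSubsidyWeights:
    """Shipped effective-subsidy weights (identity for every type)."""
    return load_weights(_data_path("weights_default.yaml"))


def shipped_proposals() -> dict[str, Path]:
    """Name -> path of the example proposal configs shipped with the package."""
    root = _data_path("proposals")
    return {p.stem: p for p in sorted(root.glob("*.yaml"))}


def load_shipped_proposal(name: str) -> Proposal:
    paths = shipped_proposals()
    if name not in paths:
        raise ConfigurationError("proposal", f"no shipped proposal named {name!r}; "
                                 f"available: {sorted(paths)}")
    return load_proposal(paths[name])
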