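"""Model parameterisation and configuration handling.

The default parameter set describes an invasive sea-lamprey system of 20
larval tributaries draining into a single lake, treated annually with the
lampricide TFM from year 50 onward, with a single resistant adult introduced
at year 70.  All defaults can be overridden through a flat key-value config
document (YAML/JSON mapping) or keyword arguments; the growth sub-model is
the only nested block.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional

import yaml

__all__ = [
    "GrowthParams",
    "ModelParams",
    "ParameterError",
    "load_params",
    "serialize_params",
]


class ParameterError(ValueError):
    """Raised when a configuration value is malformed or out of range."""


@dataclass(frozen=True)
class GrowthParams:
    """Von Bertalanffy growth model settings.

    Each individual carries a lifelong growth coefficient ``k`` (per day),
    drawn once at creation from a normal distribution.  ``k_spread`` is the
    published dispersion figure; ``spread_is`` selects whether it is read as
    a variance (default) or as a standard deviation.  Because the literal
    variance implies a dispersion far wider than any biologically possible
    growth rate, draws are restricted to ``transform_window_years`` — the
    age window within which metamorphosis from larva to parasitic juvenile
    is allowed to occur (resampling outside it).  Set the window to ``None``
    to disable truncation (draws are then only required to be positive).
    """

    L_inf_larva: float = 150.0
    L_inf_juvenile: float = 800.0
    t0: float = -15.0
    k_mean: float = 0.001
    k_spread: float = 0.0002
    spread_is: str = "variance"  # "variance" | "sd"
    transform_window_years: Optional[tuple[float, float]] = (2.0, 7.0)
    k_floor: float = 1e-6

    def __post_init__(self) -> None:
        if not self.L_inf_larva < self.L_inf_juvenile:
            raise ParameterError(
                "L_inf_larva must be smaller than L_inf_juvenile "
                f"(got {self.L_inf_larva} >= {self.L_inf_juvenile})"
            )
        if self.k_mean <= 0:
            raise ParameterError(f"k_mean must be positive (got {self.k_mean})")
        if self.k_spread < 0:
            raise ParameterError(f"k_spread must be >= 0 (got {self.k_spread})")
        if self.spread_is not in ("variance", "sd"):
            raise ParameterError(
                f"spread_is must be 'variance' or 'sd' (got {self.spread_is!r})"
            )
        if self.transform_window_years is not None:
            lo, hi = self.transform_window_years
            if not (0 < lo < hi):
                raise ParameterError(
                    f"transform_window_years must be increasing and positive (got {lo}, {hi})"
                )

    @property
    def k_sd(self) -> float:
        """Standard deviation of the (untruncated) growth-coefficient draw."""
        return math.sqrt(self.k_spread) if self.spread_is == "variance" else self.k_spread


_PRIORITIES = ("rank", "weighted", "uniform")
_MIGRATION_MODES = ("no_homing", "stepping_stone")
_COST_MODES = ("per_parent", "max_parent")
_LARVAL_SCOPES = ("recruits", "pool")


@dataclass(frozen=True)
class ModelParams:
    """Complete simulation parameter set (defaults mirror the study system)."""

    n_years: int = 200
    tfm_start_year: int = 50
    tfm_stop_year: Optional[int] = None
    resistant_intro_year: int = 70
    tfm_mortality: float = 0.9
    treated_fraction: float = 0.2
    migration_mode: str = "no_homing"
    gene_flow: float = 0.0
    resistance_cost: float = 0.0
    n_tributaries: int = 20
    larval_K: int = 1200
    juvenile_K: int = 8000
    dd_weight: float = 50.0       # n_m: density-dependent fecundity constant
    di_offset: float = 0.0        # n_a: density-independent fecundity constant
    mortality_sd: float = 70.0
    juvenile_mortality_sd: Optional[float] = None
    growth: GrowthParams = field(default_factory=GrowthParams)
    transform_length_mm: float = 120.0
    mature_length_mm: float = 450.0
    # Policy knobs (documented design choices, not sweep parameters).
    treatment_priority: str = "rank"        # rank | weighted | uniform
    larval_mortality_scope: str = "recruits"  # recruits | pool
    cost_mode: str = "per_parent"           # per_parent | max_parent
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("n_years", "n_tributaries", "larval_K", "juvenile_K"):
            v = getattr(self, name)
            if not isinstance(v, int) or isinstance(v, bool) or v <= 0:
                raise ParameterError(f"{name} must be a positive integer (got {v!r})")
        for name in ("tfm_mortality", "treated_fraction", "gene_flow", "resistance_cost"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and 0.0 <= v <= 1.0):
                raise ParameterError(f"{name} must lie in [0, 1] (got {v!r})")
        if self.migration_mode not in _MIGRATION_MODES:
            raise ParameterError(
                f"migration_mode must be one of {_MIGRATION_MODES} (got {self.migration_mode!r})"
            )
        if self.treatment_priority not in _PRIORITIES:
            raise ParameterError(
                f"treatment_priority must be one of {_PRIORITIES} (got {self.treatment_priority!r})"
            )
        if self.cost_mode not in _COST_MODES:
            raise ParameterError(
                f"cost_mode must be one of {_COST_MODES} (got {self.cost_mode!r})"
            )
        if self.larval_mortality_scope not in _LARVAL_SCOPES:
            raise ParameterError(
                f"larval_mortality_scope must be one of {_LARVAL_SCOPES} "
                f"(got {self.larval_mortality_scope!r})"
            )
        if self.mortality_sd < 0:
            raise ParameterError(f"mortality_sd must be >= 0 (got {self.mortality_sd})")
        if self.juvenile_mortality_sd is not None and self.juvenile_mortality_sd < 0:
            raise ParameterError(
                f"juvenile_mortality_sd must be >= 0 (got {self.juvenile_mortality_sd})"
            )
        if self.tfm_stop_year is not None and self.tfm_stop_year <= self.tfm_start_year:
            raise ParameterError(
                "tfm_stop_year must exceed tfm_start_year "
                f"(got {self.tfm_stop_year} <= {self.tfm_start_year})"
            )
        if not (0 < self.transform_length_mm < self.growth.L_inf_larva):
            raise ParameterError(
                "transform_length_mm must lie below the larval asymptotic length"
            )
        if not (0 < self.mature_length_mm < self.growth.L_inf_juvenile):
            raise ParameterError(
                "mature_length_mm must lie below the juvenile asymptotic length"
            )
        # Note: resistant_intro_year may precede tfm_start_year; both orders
        # are valid study designs.

    @property
    def treated_count(self) -> int:
        """Number of tributaries treated per year: round(fraction * count)."""
        return int(round(self.treated_fraction * self.n_tributaries))

    @property
    def effective_juvenile_sd(self) -> float:
        sd = self.juvenile_mortality_sd
        return self.mortality_sd if sd is None else sd

    def replace(self, **changes: Any) -> "ModelParams":
        """Return a copy with the given fields replaced (validated)."""
        growth_changes = changes.pop("growth", None)
        if isinstance(growth_changes, Mapping):
            growth_changes = dataclasses.replace(self.growth, **dict(growth_changes))
        if growth_changes is not None:
            changes["growth"] = growth_changes
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        """Flat JSON-serialisable dict (growth nested)."""
        d = dataclasses.asdict(self)
        w = d["growth"]["transform_window_years"]
        if w is not None:
            d["growth"]["transform_window_years"] = list(w)
        return d


_GROWTH_KEYS = {f.name for f in dataclasses.fields(GrowthParams)}
_PARAM_KEYS = {f.name for f in dataclasses.fields(ModelParams)}


def _build_growth(doc: Mapping[str, Any]) -> GrowthParams:
    unknown = set(doc) - _GROWTH_KEYS
    if unknown:
        raise ParameterError(f"unknown growth key(s): {sorted(unknown)}")
    doc = dict(doc)
    w = doc.get("transform_window_years")
    if isinstance(w, (list, tuple)):
        doc["transform_window_years"] = tuple(float(x) for x in w)
    try:
        return GrowthParams(**doc)
    except TypeError as exc:  # pragma: no cover - defensive
        raise ParameterError(str(exc)) from exc


def load_params(source: Any = None, /, **overrides: Any) -> ModelParams:
    """Build a validated :class:`ModelParams` from a flat key-value document.

    ``source`` may be ``None``, a mapping, a YAML/JSON text, or a path to a
    YAML/JSON file.  Missing keys take the study defaults; unknown keys are
    an error.  Keyword ``overrides`` are applied on top of the document.
    """
    doc: dict[str, Any] = {}
    if source is not None:
        if isinstance(source, Mapping):
            doc = dict(source)
        elif isinstance(source, (str, Path)):
            text = Path(source).read_text() if Path(str(source)).is_file() else str(source)
            try:
                loaded = json.loads(text)  # YAML 1.1 reads "1e-06" as a string
            except json.JSONDecodeError:
                loaded = yaml.safe_load(text)
            if loaded is None:
                loaded = {}
            if not isinstance(loaded, Mapping):
                raise ParameterError("config document must be a key-value mapping")
            doc = dict(loaded)
        else:
            raise ParameterError(f"unsupported config source type: {type(source)!r}")
    doc.update({k: v for k, v in overrides.items() if v is not None})

    unknown = set(doc) - _PARAM_KEYS
    if unknown:
        raise ParameterError(f"unknown parameter key(s): {sorted(unknown)}")
    growth_doc = doc.pop("growth", None)
    if growth_doc is not None:
        if not isinstance(growth_doc, (Mapping, GrowthParams)):
            raise ParameterError("growth must be a mapping of growth keys")
        if isinstance(growth_doc, Mapping):
            doc["growth"] = _build_growth(growth_doc)
        else:
            doc["growth"] = growth_doc
    try:
        return ModelParams(**doc)
    except TypeError as exc:
        raise ParameterError(str(exc)) from exc


def serialize_params(params: ModelParams, path: Optional[Path] = None) -> str:
    """Serialise to a JSON document (round-trips through :func:`load_params`)."""
    text = json.dumps(params.to_dict(), indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
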