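"""Domain types, configuration and tabular I/O for the assessment engine.

Every input and derived quantity travels as a *tall* table — one row per
(layer, region, year[, category]) — mirroring the layer-file convention of
ocean-health toolboxes.  Dimension scores are written long
(goal, dimension, region_id, year, value) so downstream analyses never need
to know the engine's internal wide layout.

All internal dimensionless quantities live on [0, 1]; status and score are
presented on [0, 100] only at the output boundary.
"""

from __future__ import annotations

import logging
import sys
import time
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger("oceanhealth")
if not logger.handlers:  # stderr by default; applications may reconfigure
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


@contextmanager
def stage_timer(stage: str):
    """Log wall-clock time of a pipeline stage to stderr."""
    t0 = time.perf_counter()
    yield
    logger.info("%s: %.2fs", stage, time.perf_counter() - t0)


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class OceanHealthError(Exception):
    """Base class for engine errors."""


class SchemaError(OceanHealthError):
    """A table is missing required columns or declares an unknown layer."""


class IntegrityError(OceanHealthError):
    """Duplicate keys or mutually inconsistent rows."""


class BoundsError(OceanHealthError):
    """A value violates its layer-declared bounds."""


class LayerError(OceanHealthError):
    """A required layer (or layer field) is absent or unusable."""


class EstimationError(OceanHealthError):
    """A statistical estimation step failed (e.g. zero feasible draws)."""


class GapfillError(OceanHealthError):
    """An imputation model is underdetermined."""


class WorldSpecError(OceanHealthError):
    """Infeasible synthetic-world specification."""


# ---------------------------------------------------------------------------
# Goal tree and dimension vocabulary
# ---------------------------------------------------------------------------

#: Ten top-level goals; four are split into subgoals.
GOALS: tuple[str, ...] = (
    "FP", "AO", "NP", "CS", "CP", "TR", "LE", "SP", "CW", "BD",
)

#: parent goal -> subgoals.  FP food provision, SP sense of place,
#: BD biodiversity, LE livelihoods & economies.
SUBGOALS: Mapping[str, tuple[str, ...]] = {
    "FP": ("FIS", "MAR"),
    "SP": ("ICO", "LSP"),
    "BD": ("SPP", "HAB"),
    "LE": ("LIV", "ECO"),
}

#: subgoal -> parent goal (derived).
SUBGOAL_PARENT: dict[str, str] = {
    sub: parent for parent, subs in SUBGOALS.items() for sub in subs
}

#: Every unit that carries its own status/trend/pressure/resilience.
SCORED_UNITS: tuple[str, ...] = tuple(
    g for g in GOALS if g not in SUBGOALS
) + tuple(s for subs in SUBGOALS.values() for s in subs)

DIMENSIONS: tuple[str, ...] = (
    "status", "trend", "pressures", "resilience", "future", "score",
)

ECOLOGICAL_CATEGORIES: tuple[str, ...] = (
    "pollution", "alien species", "habitat destruction",
    "fishing pressure", "climate change",
)
SOCIAL_CATEGORY = "social"


# ---------------------------------------------------------------------------
# Layer schemas and region table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LayerSchema:
    """Declaration of one tall layer table.

    bounds, when given, are inclusive and enforced at read time; ``annual``
    layers must have contiguous years within each (region, category) group.
    """

    layer_id: str
    units: str = "dimensionless"
    bounds: tuple[float, float] | None = None
    annual: bool = True
    has_category: bool = False


REGION_COLUMNS = ("region_id", "name", "eez_area_km2", "inhabited", "un_georegion")

LAYER_KEY = ("layer", "region_id", "year", "category")


def validate_regions(regions: pd.DataFrame) -> pd.DataFrame:
    missing = set(REGION_COLUMNS) - set(regions.columns)
    if missing:
        raise SchemaError(f"region table missing columns: {sorted(missing)}")
    if regions["region_id"].duplicated().any():
        dups = regions.loc[regions["region_id"].duplicated(), "region_id"].tolist()
        raise IntegrityError(f"duplicate region_id values: {dups}")
    if (regions["eez_area_km2"] <= 0).any():
        raise BoundsError("eez_area_km2 must be positive")
    if regions["un_georegion"].isna().any() or (regions["un_georegion"] == "").any():
        raise SchemaError("un_georegion must be non-empty for every region")
    return regions


def validate_layer(df: pd.DataFrame, schema: LayerSchema) -> pd.DataFrame:
    """Validate one tall layer table against its declaration.

    Returns the table with a ``layer`` column set and keys sorted.
    """
    required = {"region_id", "year", "value"}
    if schema.has_category:
        required.add("category")
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(
            f"layer {schema.layer_id!r} missing columns: {sorted(missing)}"
        )
    df = df.copy()
    df["layer"] = schema.layer_id
    key_cols = ["layer", "region_id", "year"]
    if schema.has_category:
        key_cols.append("category")
    dup = df.duplicated(subset=key_cols, keep=False)
    if dup.any():
        offending = df.loc[dup, key_cols].to_dict("records")[:5]
        raise IntegrityError(
            f"layer {schema.layer_id!r}: duplicate keys, e.g. {offending}"
        )
    if schema.bounds is not None:
        lo, hi = schema.bounds
        bad = df["value"].dropna()
        bad = bad[(bad < lo) | (bad > hi)]
        if len(bad):
            raise BoundsError(
                f"layer {schema.layer_id!r}: {len(bad)} values outside "
                f"declared bounds [{lo}, {hi}] (first: {bad.iloc[0]!r})"
            )
    if schema.annual:
        group_cols = ["region_id"] + (["category"] if schema.has_category else [])
        for key, grp in df.groupby(group_cols):
            years = sorted(grp["year"].unique())
            if years and years != list(range(years[0], years[-1] + 1)):
                raise IntegrityError(
                    f"layer {schema.layer_id!r}: non-contiguous years for "
                    f"group {key}"
                )
    return df.sort_values(key_cols).reset_index(drop=True)


def read_layers(
    paths: Iterable[str | Path],
    schemas: Mapping[str, LayerSchema],
) -> dict[str, pd.DataFrame]:
    """Read and validate a set of tall CSV layer files.

    Each file name (stem) must match a declared layer id; unknown layers are
    rejected rather than silently carried.
    """
    out: dict[str, pd.DataFrame] = {}
    for path in paths:
        path = Path(path)
        layer_id = path.stem
        if layer_id not in schemas:
            raise SchemaError(f"unknown layer {layer_id!r} ({path})")
        df = pd.read_csv(path)
        out[layer_id] = validate_layer(df, schemas[layer_id])
    return out


def write_layers(layers: Mapping[str, pd.DataFrame], out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for layer_id, df in layers.items():
        df.to_csv(out_dir / f"{layer_id}.csv", index=False)


# ---------------------------------------------------------------------------
# Pressure / resilience matrices
# ---------------------------------------------------------------------------

PRESSURE_MATRIX_COLUMNS = ("goal_id", "layer_id", "weight", "category")
RESILIENCE_MATRIX_COLUMNS = ("goal_id", "layer_id", "rtype", "addresses_category")


def validate_pressure_matrix(pm: pd.DataFrame) -> pd.DataFrame:
    missing = set(PRESSURE_MATRIX_COLUMNS) - set(pm.columns)
    if missing:
        raise SchemaError(f"pressure matrix missing columns: {sorted(missing)}")
    bad_w = set(pm["weight"].unique()) - {1, 2, 3}
    if bad_w:
        raise BoundsError(f"pressure weights must be ranks 1-3, got {bad_w}")
    valid = set(ECOLOGICAL_CATEGORIES) | {SOCIAL_CATEGORY}
    bad_c = set(pm["category"].unique()) - valid
    if bad_c:
        raise SchemaError(f"unknown pressure categories: {bad_c}")
    return pm


def validate_resilience_matrix(rm: pd.DataFrame) -> pd.DataFrame:
    missing = set(RESILIENCE_MATRIX_COLUMNS) - set(rm.columns)
    if missing:
        raise SchemaError(f"resilience matrix missing columns: {sorted(missing)}")
    bad_t = set(rm["rtype"].unique()) - {"regulatory", "ecological", "social"}
    if bad_t:
        raise SchemaError(f"unknown resilience types: {bad_t}")
    return rm


@dataclass
class ValidationReport:
    """Report-only consistency check of the two matrices against the layers.

    The engine refuses to run on a failing report but this function never
    raises: listing every violation at once is more useful than stopping at
    the first.
    """

    unreferenced_layers: list[str] = field(default_factory=list)
    regulatory_without_category: list[str] = field(default_factory=list)
    goals_without_pressure: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (self.unreferenced_layers or self.regulatory_without_category)

    @property
    def entries(self) -> list[str]:
        out = [f"matrix references unknown layer {x!r}" for x in self.unreferenced_layers]
        out += [
            f"regulatory resilience layer {x!r} lacks addresses_category"
            for x in self.regulatory_without_category
        ]
        out += [f"goal {x!r} has no pressure layers (warning)" for x in self.goals_without_pressure]
        return out


def validate_matrices(
    pm: pd.DataFrame,
    rm: pd.DataFrame,
    layers: Mapping[str, pd.DataFrame] | Sequence[str],
) -> ValidationReport:
    """Cross-check matrices against the declared layer set.  Side-effect free."""
    known = set(layers.keys()) if isinstance(layers, Mapping) else set(layers)
    report = ValidationReport()
    for lid in pd.concat([pm["layer_id"], rm["layer_id"]]).unique():
        if lid not in known:
            report.unreferenced_layers.append(str(lid))
    reg = rm[rm["rtype"] == "regulatory"]
    for _, row in reg.iterrows():
        cat = row["addresses_category"]
        if pd.isna(cat) or cat not in ECOLOGICAL_CATEGORIES:
            report.regulatory_without_category.append(str(row["layer_id"]))
    goals_with = set(pm["goal_id"].unique())
    for unit in SCORED_UNITS:
        if unit not in goals_with:
            report.goals_without_pressure.append(unit)
    return report


# ---------------------------------------------------------------------------
# Dimension scores
# ---------------------------------------------------------------------------

SCORE_WIDE_COLUMNS = ("region_id", "goal_id", "year") + DIMENSIONS

#: column name in the long dialect -> internal wide column
_LONG_DIM = {d: d for d in DIMENSIONS}


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    """Write dimension scores as long CSV (goal, dimension, region_id, year, value).

    Accepts either the internal wide layout or an already-long frame.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if "dimension" in scores.columns:
        long = scores.loc[:, ["goal", "dimension", "region_id", "year", "value"]]
    else:
        long = scores.melt(
            id_vars=["region_id", "goal_id", "year"],
            value_vars=list(DIMENSIONS),
            var_name="dimension",
            value_name="value",
        ).rename(columns={"goal_id": "goal"})
    long = long.loc[:, ["goal", "dimension", "region_id", "year", "value"]]
    long = long.sort_values(["goal", "dimension", "region_id", "year"])
    long.to_csv(path, index=False, float_format="%.9g")


def read_scores(path: str | Path) -> pd.DataFrame:
    """Read a long scores CSV back into the internal wide layout."""
    long = pd.read_csv(path)
    missing = {"goal", "dimension", "region_id", "year", "value"} - set(long.columns)
    if missing:
        raise SchemaError(f"scores file missing columns: {sorted(missing)}")
    wide = (
        long.pivot_table(
            index=["region_id", "goal", "year"],
            columns="dimension",
            values="value",
            aggfunc="first",
            dropna=False,
        )
        .reset_index()
        .rename(columns={"goal": "goal_id"})
    )
    wide.columns.name = None
    for d in DIMENSIONS:
        if d not in wide.columns:
            wide[d] = float("nan")
    return wide.loc[:, list(SCORE_WIDE_COLUMNS)]


# ---------------------------------------------------------------------------
# Engine configuration
# ---------------------------------------------------------------------------

@dataclass
class EngineConfig:
    """Tunable parameters of the scoring model.

    beta weights trend against the resilience-minus-pressure term in the
    likely-future-status model; gamma weights ecological against social
    pressure; discount is an optional future-status discount rate.  The
    defaults follow the published index framework and are deliberately
    configurable.
    """

    beta: float = 0.67
    gamma: float = 0.5
    discount: float = 0.0
    goal_weights: dict[str, float] = field(
        default_factory=lambda: {g: 1.0 for g in GOALS}
    )
    subgoal_weights: dict[str, float] = field(
        default_factory=lambda: {s: 1.0 for subs in SUBGOALS.values() for s in subs}
    )
    subgoal_map: dict[str, str] = field(default_factory=lambda: dict(SUBGOAL_PARENT))
    trend_clamp: tuple[float, float] = (-1.0, 1.0)
    status_scale: tuple[float, float] = (0.0, 100.0)
    lsp_reference_fraction: float = 0.30
    include_uninhabited_in_global: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.beta <= 1.0):
            raise BoundsError(f"beta must be in [0,1], got {self.beta}")
        if not (0.0 <= self.gamma <= 1.0):
            raise BoundsError(f"gamma must be in [0,1], got {self.gamma}")
        weights = list(self.goal_weights.values())
        if any(w < 0 for w in weights) or not any(w > 0 for w in weights):
            raise BoundsError("goal weights must be non-negative, at least one positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EngineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "trend_clamp" in raw:
            raw["trend_clamp"] = tuple(raw["trend_clamp"])
        if "status_scale" in raw:
            raw["status_scale"] = tuple(raw["status_scale"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "beta": self.beta,
            "gamma": self.gamma,
            "discount": self.discount,
            "goal_weights": dict(self.goal_weights),
            "subgoal_weights": dict(self.subgoal_weights),
            "subgoal_map": dict(self.subgoal_map),
            "trend_clamp": list(self.trend_clamp),
            "status_scale": list(self.status_scale),
            "lsp_reference_fraction": self.lsp_reference_fraction,
            "include_uninhabited_in_global": self.include_uninhabited_in_global,
            "rng_seed": self.rng_seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
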