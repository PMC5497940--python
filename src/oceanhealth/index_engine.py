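"""Core scoring model: likely future status, goal scores, region and global
Index, plus the orchestration that runs a whole assessment on a world bundle.

For each goal the current status x (0–100) combines with the proportional
five-year trend T (−1..1), aggregate pressure p (0–1) and resilience r (0–1)
into the likely future status

    x_F = x · (1 + δ) · [1 + β·T + (1 − β)·(r − p)]

clamped to [0, 100].  The goal score is the even split (x + x_F)/2; subgoals
average into parent goals, the ten goal scores average (weighted) into a
region Index, and region Indices average into the global score either
unweighted or weighted by EEZ area.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import goal_models as gm
from . import pressure_resilience as pr
from .core_data import (
    DIMENSIONS,
    GOALS,
    SUBGOALS,
    BoundsError,
    EngineConfig,
    logger,
    stage_timer,
)
from .synthetic_world import CARBON_RANKS, PROTECTION_RANKS, World

# ---------------------------------------------------------------------------
# Scoring primitives
# ---------------------------------------------------------------------------

def likely_future_status(
    x: float | np.ndarray,
    trend: float | np.ndarray,
    pressure: float | np.ndarray,
    resilience: float | np.ndarray,
    cfg: EngineConfig | None = None,
) -> float | np.ndarray:
    """Predicted status five years ahead, clamped to [0, 100].

    Missing trend is treated as 0 (with a warning); if either pressure or
    resilience is missing the (r − p) term is dropped, which makes the trend
    weight effectively 1.
    """
    cfg = cfg or EngineConfig()
    scalar = np.isscalar(x)
    x = np.asarray(x, dtype=float)
    T = np.asarray(trend, dtype=float)
    p = np.asarray(pressure, dtype=float)
    r = np.asarray(resilience, dtype=float)
    if np.nanmin(x, initial=0.0) < 0 or np.nanmax(x, initial=0.0) > 100:
        raise BoundsError("status must be on [0, 100]")
    if np.nanmax(np.abs(T), initial=0.0) > 1:
        raise BoundsError("trend must be on [-1, 1]")
    for name, v in (("pressure", p), ("resilience", r)):
        if np.nanmin(v, initial=0.0) < 0 or np.nanmax(v, initial=0.0) > 1:
            raise BoundsError(f"{name} must be on [0, 1]")
    if np.isnan(T).any():
        logger.warning("missing trend treated as 0 for %d entries", int(np.isnan(T).sum()))
        T = np.where(np.isnan(T), 0.0, T)
    rp = r - p
    drop = np.isnan(rp)
    if drop.any():
        logger.warning("missing pressure/resilience: (r - p) term dropped for %d entries", int(drop.sum()))
    beta = np.where(drop, 1.0, cfg.beta)
    rp = np.where(drop, 0.0, rp)
    xf = x * (1.0 + cfg.discount) * (1.0 + beta * T + (1.0 - beta) * rp)
    xf = np.clip(xf, 0.0, 100.0)
    return float(xf) if scalar else xf


def goal_score(x: float | np.ndarray, xf: float | np.ndarray) -> float | np.ndarray:
    """Equal-weight mean of current and likely future status."""
    return (np.asarray(x, dtype=float) + np.asarray(xf, dtype=float)) / 2.0


def region_index(
    goal_scores: pd.DataFrame, cfg: EngineConfig | None = None
) -> pd.Series:
    """Region Index: subgoals average into parents, then a weighted mean over
    the ten goals; undefined goals are dropped with weight renormalisation."""
    cfg = cfg or EngineConfig()
    wide = goal_scores.pivot_table(
        index="region_id", columns="goal_id", values="score", aggfunc="first", dropna=False
    )
    parents = _roll_up_subgoals(wide, cfg)
    weights = pd.Series(cfg.goal_weights, dtype=float).reindex(parents.columns)
    vals = parents.to_numpy(dtype=float)
    w = np.broadcast_to(weights.to_numpy(), vals.shape).copy()
    w[np.isnan(vals)] = 0.0
    wsum = w.sum(axis=1)
    dead = wsum == 0
    if dead.any():
        logger.warning("regions with no defined goals excluded: %s", parents.index[dead].tolist())
    with np.errstate(invalid="ignore"):
        idx = np.nansum(vals * w, axis=1) / np.where(wsum > 0, wsum, np.nan)
    return pd.Series(idx, index=parents.index, name="index")[~dead]


def _roll_up_subgoals(wide: pd.DataFrame, cfg: EngineConfig) -> pd.DataFrame:
    """Average subgoal columns into their parent goals (weighted, NaN-aware)."""
    out = {}
    for goal in GOALS:
        if goal in SUBGOALS:
            subs = [s for s in SUBGOALS[goal] if s in wide.columns]
            if not subs:
                out[goal] = pd.Series(np.nan, index=wide.index)
                continue
            sw = np.array([cfg.subgoal_weights.get(s, 1.0) for s in subs], dtype=float)
            vals = wide[subs].to_numpy(dtype=float)
            w = np.broadcast_to(sw, vals.shape).copy()
            w[np.isnan(vals)] = 0.0
            wsum = w.sum(axis=1)
            with np.errstate(invalid="ignore"):
                out[goal] = pd.Series(
                    np.nansum(vals * w, axis=1) / np.where(wsum > 0, wsum, np.nan),
                    index=wide.index,
                )
        elif goal in wide.columns:
            out[goal] = wide[goal]
        else:
            out[goal] = pd.Series(np.nan, index=wide.index)
    return pd.DataFrame(out)


def global_index(
    region_indices: pd.Series,
    regions: pd.DataFrame,
    weighting: str = "eez_area",
    include_uninhabited: bool = True,
) -> float:
    """Global score: mean of region Indices, unweighted or EEZ-area-weighted."""
    if weighting not in ("eez_area", "unweighted"):
        raise ValueError(f"unknown weighting {weighting!r}")
    meta = regions.set_index("region_id")
    idx = region_indices.dropna()
    if not include_uninhabited:
        idx = idx[idx.index.map(meta["inhabited"]).to_numpy(dtype=bool)]
    if weighting == "unweighted":
        return float(idx.mean())
    w = idx.index.map(meta["eez_area_km2"]).to_numpy(dtype=float)
    return float(np.average(idx.to_numpy(), weights=w))


# ---------------------------------------------------------------------------
# Full assessment pipeline
# ---------------------------------------------------------------------------

def compute_status_panels(world: World, cfg: EngineConfig) -> dict[str, pd.DataFrame]:
    """Status time series per scored unit from the world's input layers."""
    L = world.layers
    panels: dict[str, pd.DataFrame] = {}

    with stage_timer("fisheries catch-MSY"):
        cmsy = gm.estimate_bbmsy_panel(
            world.stock_panel, gm.CatchMsyConfig(rng_seed=cfg.rng_seed)
        )
        estimates = gm.merge_ram(cmsy, L["ram_bbmsy"]) if "ram_bbmsy" in L else cmsy
        panels["FIS"] = gm.fisheries_status(world.stock_panel, estimates)

    for unit, lid in (("MAR", "mar_status"), ("TR", "tr_status"),
                      ("LIV", "liv_status"), ("ECO", "eco_status")):
        panels[unit] = L[lid].rename(columns={"value": "status"})[
            ["region_id", "year", "status"]
        ]

    panels["AO"] = gm.artisanal_status(L["ao_need"])
    panels["NP"] = gm.natural_products_status(L["np_harvest"], panels["FIS"])
    panels["LSP"] = gm.lasting_special_places_status(
        L["lsp_protected"], L["lsp_zone_area"], cfg.lsp_reference_fraction
    )
    panels["SPP"] = gm.species_status(L["spp_risk"])
    ico_status, _ = gm.iconic_status_series(L["ico_risk"])
    panels["ICO"] = ico_status
    hab = gm.habitat_goal_status(
        L["hab_extent"], L["hab_condition"], L["hab_condition_ref"],
        PROTECTION_RANKS, CARBON_RANKS,
    )
    panels.update(hab)
    panels["CW"] = gm.clean_waters_status(
        {k: L[k] for k in ("cw_nutrient", "cw_chemical", "cw_pathogen", "cw_trash")}
    )
    return panels


def compute_pressure_layers(world: World) -> tuple[dict[str, pd.DataFrame], dict[str, pd.DataFrame]]:
    """Build every pressure and resilience layer the matrices reference."""
    L, G = world.layers, world.grids
    cells = world.cells
    p_layers: dict[str, pd.DataFrame] = {}

    with stage_timer("climate pressure layers"):
        p_layers["cc_oa"] = pr.oa_pressure(G["oa_omega_base"], G["oa_omega"], cells)
        p_layers["cc_slr"] = pr.slr_pressure(G["slr_anom_mm"], cells)
        p_layers["cc_uv"] = pr.anomaly_pressure(G["uv_mw_m2"], cells, kind="UV")
        p_layers["cc_sst"] = pr.anomaly_pressure(G["sst_c"], cells, kind="SST")

    with stage_timer("fishing pressure layers"):
        p_layers.update(
            pr.fishing_pressure(
                G["fp_catch_industrial"], G["fp_catch_artisanal"], G["fp_npp"],
                L["gear_split"], cells,
            )
        )

    # pollution pressures are the clean-waters contamination components
    for src, dst in (("cw_nutrient", "po_nutrient"), ("cw_chemical", "po_chemical"),
                     ("cw_pathogen", "po_pathogen"), ("cw_trash", "po_trash")):
        p_layers[dst] = L[src].loc[:, ["region_id", "year", "value"]]
    for lid in ("sp_alien", "sp_genetic", "sp_harvest", "hd_subtidal", "hd_intertidal"):
        p_layers[lid] = L[lid].loc[:, ["region_id", "year", "value"]]

    with stage_timer("social layers"):
        spi = pr.spi_layer(L["spi_components"], L["wgi"], world.regions)
    p_layers["ss_wgi"] = L["wgi"].assign(value=lambda d: 1.0 - d["value"])[
        ["region_id", "year", "value"]
    ]
    p_layers["ss_spi"] = spi.rename(columns={"pressure": "value"})[
        ["region_id", "year", "value"]
    ]

    r_layers: dict[str, pd.DataFrame] = {
        lid: L[lid].loc[:, ["region_id", "year", "value"]]
        for lid in ("reg_fishing", "reg_pollution", "reg_alien", "reg_habitat",
                    "reg_climate", "reg_mpa", "eco_integrity")
    }
    r_layers["res_wgi"] = L["wgi"].loc[:, ["region_id", "year", "value"]]
    r_layers["res_spi"] = spi.rename(columns={"resilience": "value"})[
        ["region_id", "year", "value"]
    ]
    return p_layers, r_layers


def _value_at(df: pd.DataFrame, value_col: str, year: int) -> pd.Series:
    """Per (goal_id, region_id) value at ``year``: exact, else latest before,
    else earliest after (layers are slow-moving; this mirrors layer reuse
    across scenario years when a source is not updated annually)."""
    key = [c for c in ("goal_id", "region_id") if c in df.columns]
    out = {}
    for k, grp in df.groupby(key):
        grp = grp.sort_values("year")
        before = grp[grp["year"] <= year]
        row = before.iloc[-1] if len(before) else grp.iloc[0]
        out[k if len(key) > 1 else (k,)] = row[value_col]
    idx = pd.MultiIndex.from_tuples(out.keys(), names=key)
    return pd.Series(out.values(), index=idx, name=value_col, dtype=float)


def compute_assessment(
    world: World,
    cfg: EngineConfig | None = None,
    years: list[int] | None = None,
) -> pd.DataFrame:
    """Run the full assessment and return wide dimension scores.

    Output rows cover every scored unit, the parent goals (dimension-wise
    weighted means of their subgoals) and an ``Index`` row per region-year
    carrying the region Index in ``score`` (and the weighted mean status in
    ``status``).
    """
    cfg = cfg or EngineConfig()
    if years is None:
        y1 = world.spec.years[1]
        years = [y1]
    panels = compute_status_panels(world, cfg)
    p_layers, r_layers = compute_pressure_layers(world)
    pressures = pr.aggregate_pressures(p_layers, world.pressure_matrix, cfg, world.regions)
    resilience = pr.aggregate_resilience(r_layers, world.resilience_matrix, cfg, world.regions)

    all_rows = []
    for y in years:
        p_y = _value_at(pressures, "pressure", y)
        r_y = _value_at(resilience, "resilience", y)
        unit_rows = []
        for unit, panel in panels.items():
            sub = panel[panel["year"] == y]
            if sub.empty:
                logger.warning("unit %s: no status for year %d", unit, y)
                continue
            if unit == "ICO":
                hist = world.layers["ico_risk"]
                _, tr = gm.iconic_status_series(hist[hist["year"] <= y])
                trend = tr.set_index("region_id")["trend"]
            else:
                trend = gm.trend_panel(panel, year=y).set_index("region_id")["trend"]
            df = sub.loc[:, ["region_id", "status"]].copy()
            df["goal_id"] = unit
            df["year"] = y
            df["trend"] = df["region_id"].map(trend)
            df["pressures"] = [
                p_y.get((unit, rid), np.nan) for rid in df["region_id"]
            ]
            df["resilience"] = [
                r_y.get((unit, rid), np.nan) for rid in df["region_id"]
            ]
            df["future"] = likely_future_status(
                df["status"].to_numpy(), df["trend"].to_numpy(),
                df["pressures"].to_numpy(), df["resilience"].to_numpy(), cfg,
            )
            df["score"] = goal_score(df["status"].to_numpy(), df["future"].to_numpy())
            unit_rows.append(df)
        units = pd.concat(unit_rows, ignore_index=True)

        # roll subgoal dimensions up into parent goals
        parent_rows = []
        for parent, subs in SUBGOALS.items():
            sub = units[units["goal_id"].isin(subs)]
            if sub.empty:
                continue
            sw = sub["goal_id"].map(lambda s: cfg.subgoal_weights.get(s, 1.0))
            agg = {}
            for dim in DIMENSIONS:
                vals = sub[dim].to_numpy(dtype=float)
                w = sw.to_numpy(dtype=float).copy()
                g = pd.DataFrame({"region_id": sub["region_id"], "v": vals, "w": np.where(np.isnan(vals), 0.0, w)})
                g["wv"] = g["v"].fillna(0.0) * g["w"]
                s = g.groupby("region_id")[["wv", "w"]].sum()
                agg[dim] = s["wv"] / s["w"].replace(0.0, np.nan)
            pdf = pd.DataFrame(agg).reset_index()
            pdf["goal_id"] = parent
            pdf["year"] = y
            parent_rows.append(pdf)
        parents = pd.concat(parent_rows, ignore_index=True)

        goal_level = pd.concat(
            [parents, units[~units["goal_id"].isin(sum(map(list, SUBGOALS.values()), []))]],
            ignore_index=True,
        )
        ridx = region_index(goal_level.loc[:, ["region_id", "goal_id", "score"]], cfg)
        rstat = region_index(
            goal_level.loc[:, ["region_id", "goal_id", "status"]].rename(columns={"status": "score"}),
            cfg,
        )
        index_rows = pd.DataFrame(
            {
                "region_id": ridx.index,
                "goal_id": "Index",
                "year": y,
                "status": rstat.reindex(ridx.index).to_numpy(),
                "trend": np.nan,
                "pressures": np.nan,
                "resilience": np.nan,
                "future": np.nan,
                "score": ridx.to_numpy(),
            }
        )
        all_rows += [units, parents, index_rows]
    cols = ["region_id", "goal_id", "year", *DIMENSIONS]
    out = pd.concat(all_rows, ignore_index=True).loc[:, cols]
    return out.sort_values(["year", "goal_id", "region_id"]).reset_index(drop=True)
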