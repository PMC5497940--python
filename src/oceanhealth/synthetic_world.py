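"""Self-contained synthetic assessment world with emitted ground truth.

The generator builds everything a full assessment needs — a region table,
tall goal-input layers, gridded climate/fishing pressure inputs, pressure and
resilience matrices — together with a :class:`SyntheticTruth` record holding
the parameters used (per-region status slopes, per-stock Schaefer parameters
and true B/B_MSY trajectories, injected climate anomalies, gapfill
coefficients), so every estimation step downstream can be tested as a
parameter-recovery problem.

The grid is abstract: a cell is (cell_id, region_id, area_km2, coastal_flag)
with no geographic coordinates, because every gridded operation in the engine
reduces to per-cell time series plus area-weighted region means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_data import (
    ECOLOGICAL_CATEGORIES,
    SOCIAL_CATEGORY,
    LayerSchema,
    WorldSpecError,
    logger,
)

# ---------------------------------------------------------------------------
# Specification
# ---------------------------------------------------------------------------

#: six traded natural products tracked per region
PRODUCTS = ("sponges", "shells", "fish_oil", "corals", "ornamentals", "seaweeds")

#: five coastal habitats; rank weights for shoreline protection and carbon burial
HABITATS = ("seaice", "mangrove", "saltmarsh", "seagrass", "coral")
PROTECTION_RANKS = {"seaice": 4.0, "mangrove": 4.0, "saltmarsh": 3.0, "seagrass": 1.0, "coral": 4.0}
CARBON_RANKS = {"mangrove": 1.0, "saltmarsh": 1.0, "seagrass": 1.0}

#: IUCN-style risk-category weights (least concern .. extinct)
RISK_WEIGHTS = {"LC": 0.0, "NT": 0.2, "VU": 0.4, "EN": 0.6, "CR": 0.8, "EX": 1.0}
RISK_LEVELS = tuple(RISK_WEIGHTS.values())

UN_GEOREGIONS = ("Africa", "Americas", "Asia", "Europe", "Oceania")

SPI_COMPONENTS = tuple(f"comp_{d}_{c}" for d in (1, 2, 3) for c in (1, 2, 3, 4))


@dataclass(frozen=True)
class WorldSpec:
    """Knobs of the synthetic world; defaults give a mid-sized assessment.

    mean_slope / trend_sd control the per-region linear drift of the
    observed status panels (points per year); level_slope_corr switches on
    the "good get better" coupling between a region's status level and its
    slope.  anomaly_rate is the per-cell-week probability of an injected
    climate anomaly; missingness is the fraction of SPI / need entries
    blanked at random.
    """

    n_regions: int = 20
    years: tuple[int, int] = (2005, 2016)
    rng_seed: int = 0
    mean_slope: float = 0.2
    trend_sd: float = 1.0
    status_noise_sd: float = 1.0
    level_slope_corr: float = 0.0
    n_stocks_per_region: int = 5
    n_cells_per_region: int = 3
    anomaly_rate: float = 0.02
    missingness: float = 0.1
    uninhabited_fraction: float = 0.15

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise WorldSpecError("n_regions must be >= 2")
        y0, y1 = self.years
        if y1 - y0 + 1 < 6:
            raise WorldSpecError("years must span >= 6 (5-year trend window + 1)")
        for name in ("anomaly_rate", "missingness", "uninhabited_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise WorldSpecError(f"{name} must be in [0,1]")

    @property
    def year_range(self) -> range:
        return range(self.years[0], self.years[1] + 1)


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside the generated world."""

    status_slopes: pd.DataFrame      # region_id, slope (points/yr)
    stocks: pd.DataFrame             # stock_id, region_id, r, K, taxon_level, target_bbmsy
    bbmsy: pd.DataFrame              # stock_id, year, true_bbmsy
    anomalies: pd.DataFrame          # layer, cell_id, year, week
    gapfill_coefficients: pd.DataFrame  # component, intercept, wgi_coef, georegion effects
    fixed_slope: float = 0.0         # mean of the slope distribution
    slope_sd: float = 0.0


@dataclass
class World:
    spec: WorldSpec
    regions: pd.DataFrame
    cells: pd.DataFrame
    stock_panel: pd.DataFrame
    layers: dict[str, pd.DataFrame]
    grids: dict[str, pd.DataFrame]
    pressure_matrix: pd.DataFrame
    resilience_matrix: pd.DataFrame
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# Schaefer surplus-production dynamics
# ---------------------------------------------------------------------------

@dataclass
class StockTrajectory:
    """Forward simulation of B_{t+1} = B_t + r B_t (1 - B_t/K) - C_t.

    biomass has one more entry than catch (includes B0); bbmsy is the true
    B/B_MSY = 2 B_t / K at the end of each catch year.  hit_floor flags a
    schedule the stock could not sustain (biomass clipped at K/1000).
    """

    biomass: np.ndarray
    catch: np.ndarray
    bbmsy: np.ndarray
    hit_floor: bool


def simulate_stock(
    r: float, K: float, harvest_schedule: np.ndarray | list[float], B0: float
) -> StockTrajectory:
    if r <= 0 or K <= 0:
        raise ValueError("r and K must be positive")
    if not 0 < B0 <= K:
        raise ValueError("B0 must satisfy 0 < B0 <= K")
    catch = np.asarray(harvest_schedule, dtype=float)
    floor = K * 1e-3
    biomass = np.empty(len(catch) + 1)
    biomass[0] = B0
    realized = np.empty(len(catch))
    hit_floor = False
    for t, c in enumerate(catch):
        b = biomass[t]
        nxt = b + r * b * (1.0 - b / K) - c
        if nxt < floor:
            nxt = floor
            hit_floor = True
        realized[t] = c
        biomass[t + 1] = nxt
    bbmsy = 2.0 * biomass[1:] / K  # B_MSY = K/2
    return StockTrajectory(biomass=biomass, catch=realized, bbmsy=bbmsy, hit_floor=hit_floor)


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------

def _regions(spec: WorldSpec, rng: np.random.Generator) -> pd.DataFrame:
    n = spec.n_regions
    # heavy-tailed EEZ areas (spans small islands to large maritime nations)
    area = np.exp(rng.normal(12.0, 1.5, n))
    n_uninhabited = int(round(spec.uninhabited_fraction * n))
    inhabited = np.ones(n, dtype=bool)
    if n_uninhabited:
        inhabited[rng.choice(n, size=n_uninhabited, replace=False)] = False
    return pd.DataFrame(
        {
            "region_id": np.arange(1, n + 1),
            "name": [f"region_{i:03d}" for i in range(1, n + 1)],
            "eez_area_km2": area,
            "inhabited": inhabited,
            "un_georegion": rng.choice(UN_GEOREGIONS, size=n),
        }
    )


def _cells(spec: WorldSpec, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    cid = 0
    for rid in range(1, spec.n_regions + 1):
        for j in range(spec.n_cells_per_region):
            cid += 1
            rows.append(
                {
                    "cell_id": cid,
                    "region_id": rid,
                    "area_km2": float(np.exp(rng.normal(8.0, 0.5))),
                    "coastal_flag": j == 0,  # at least one coastal cell per region
                }
            )
    return pd.DataFrame(rows)


def _panel(
    spec: WorldSpec,
    rng: np.random.Generator,
    level: np.ndarray,
    slope: np.ndarray,
    noise_sd: float,
    lo: float,
    hi: float,
) -> pd.DataFrame:
    """region × year panel  level + slope·(year − midyear) + noise, clipped."""
    years = np.array(list(spec.year_range))
    mid = years.mean()
    vals = (
        level[:, None]
        + slope[:, None] * (years[None, :] - mid)
        + rng.normal(0.0, noise_sd, (len(level), len(years)))
    )
    vals = np.clip(vals, lo, hi)
    return pd.DataFrame(
        {
            "region_id": np.repeat(np.arange(1, spec.n_regions + 1), len(years)),
            "year": np.tile(years, spec.n_regions),
            "value": vals.ravel(),
        }
    )


def _bounded_walk(
    spec: WorldSpec, rng: np.random.Generator, start_lo: float, start_hi: float,
    step_sd: float, drift: float = 0.0,
) -> pd.DataFrame:
    """Persistent region × year series on [0,1] (AR walk, reflected at bounds)."""
    years = list(spec.year_range)
    vals = rng.uniform(start_lo, start_hi, spec.n_regions)
    rows = []
    for year in years:
        vals = np.clip(vals + drift + rng.normal(0.0, step_sd, spec.n_regions), 0.0, 1.0)
        rows.append(pd.DataFrame({"region_id": np.arange(1, spec.n_regions + 1), "year": year, "value": vals}))
    return pd.concat(rows, ignore_index=True)


def _stocks(
    spec: WorldSpec, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Schaefer stocks driven toward a target terminal B/B_MSY ∈ [0.3, 1.9].

    Two qualitatively realistic harvest regimes.  Overfished stocks
    (target < 1) follow a prescribed smooth depletion path from unfished
    biomass down to the target, with the implied catch
    C_t = B_t + r B_t (1 − B_t/K) − B_{t+1} extracted — the rise-and-fall
    history of a collapsing fishery.  Lightly/fully exploited stocks
    (target ≥ 1) follow a developing fishery: the harvest rate ramps up to
    h = r (1 − τ/2), whose Schaefer equilibrium sits at the target, giving a
    monotonically rising catch.  Lognormal noise multiplies catch and the
    trajectory is re-simulated, keeping the emitted B/B_MSY exactly 2B/K.
    """
    n_catch_years = max(20, spec.years[1] - spec.years[0] + 1)
    catch_years = np.arange(spec.years[1] - n_catch_years + 1, spec.years[1] + 1)
    meta_rows, panel_rows, truth_rows = [], [], []
    sid = 0
    taxon_levels = np.array([1, 2, 3, 4, 5, 6])
    taxon_p = np.array([0.08, 0.06, 0.08, 0.10, 0.12, 0.56])
    for rid in range(1, spec.n_regions + 1):
        for _ in range(spec.n_stocks_per_region):
            sid += 1
            r = float(np.exp(rng.uniform(np.log(0.1), np.log(0.6))))
            K = float(np.exp(rng.uniform(np.log(1e3), np.log(1e5))))
            target = float(rng.uniform(0.3, 1.9))
            taxon = int(rng.choice(taxon_levels, p=taxon_p))
            if target < 1.0:
                # collapse regime: smoothstep depletion path and implied catch
                d_final = target / 2.0
                u = np.arange(1, n_catch_years + 1) / n_catch_years
                s = 3 * u**2 - 2 * u**3
                b_path = K * (1.0 - (1.0 - d_final) * s)
                b_path = np.concatenate([[K], b_path])
                planned = (
                    b_path[:-1]
                    + r * b_path[:-1] * (1.0 - b_path[:-1] / K)
                    - b_path[1:]
                )
                planned = np.maximum(planned, 0.02 * r * K)
                catches = planned * np.exp(rng.normal(0.0, 0.1, n_catch_years))
            else:
                # developing regime: harvest rate ramps toward the target's
                # equilibrium rate, catch rises with effort
                h_final = r * (1.0 - target / 2.0)
                b = K
                catches = np.empty(n_catch_years)
                for t in range(n_catch_years):
                    h = h_final * (0.1 + 0.9 * t / (n_catch_years - 1))
                    c = h * b * float(np.exp(rng.normal(0.0, 0.1)))
                    catches[t] = max(c, 1e-9 * K)
                    b = max(K * 1e-3, b + r * b * (1.0 - b / K) - catches[t])
            traj = simulate_stock(r, K, catches, K)
            catches = traj.catch
            bb = traj.bbmsy
            meta_rows.append(
                {"stock_id": sid, "region_id": rid, "r": r, "K": K,
                 "taxon_level": taxon, "target_bbmsy": target}
            )
            panel_rows.append(
                pd.DataFrame(
                    {"stock_id": sid, "region_id": rid, "year": catch_years,
                     "catch_tonnes": catches, "taxon_level": taxon}
                )
            )
            truth_rows.append(
                pd.DataFrame({"stock_id": sid, "year": catch_years, "true_bbmsy": bb})
            )
    return (
        pd.DataFrame(meta_rows),
        pd.concat(panel_rows, ignore_index=True),
        pd.concat(truth_rows, ignore_index=True),
    )


def _ram_assessments(
    stocks: pd.DataFrame, truth_bbmsy: pd.DataFrame, rng: np.random.Generator,
    fraction: float = 0.15,
) -> pd.DataFrame:
    """Formal stock assessments for a fraction of stocks: truth + small noise."""
    ids = stocks["stock_id"].to_numpy()
    n_ram = max(1, int(round(fraction * len(ids))))
    chosen = rng.choice(ids, size=n_ram, replace=False)
    sub = truth_bbmsy[truth_bbmsy["stock_id"].isin(chosen)].copy()
    sub["bbmsy"] = np.maximum(
        1e-3, sub["true_bbmsy"] * np.exp(rng.normal(0.0, 0.05, len(sub)))
    )
    sub["source"] = "ram"
    return sub.loc[:, ["stock_id", "year", "bbmsy", "source"]].reset_index(drop=True)


def _species_histories(
    spec: WorldSpec, rng: np.random.Generator, n_species: int, prefix: str,
    drift_p: float,
) -> pd.DataFrame:
    """Step-interpolated yearly risk weights per (region, species).

    Assessments arrive every 3–6 years; between assessments the category is
    carried forward, occasionally stepping one risk level up or down.
    """
    years = np.array(list(spec.year_range))
    rows = []
    for s in range(n_species):
        w = float(rng.choice(RISK_LEVELS, p=[0.45, 0.2, 0.15, 0.1, 0.07, 0.03]))
        hosts = rng.choice(
            np.arange(1, spec.n_regions + 1),
            size=max(2, spec.n_regions // 2),
            replace=False,
        )
        weights = np.empty(len(years))
        next_assessment = years[0] + int(rng.integers(0, 4))
        for i, y in enumerate(years):
            if y >= next_assessment:
                if rng.uniform() < drift_p:
                    step = 0.2 if rng.uniform() < 0.6 else -0.2
                    w = float(np.clip(w + step, 0.0, 1.0))
                next_assessment = y + int(rng.integers(3, 7))
            weights[i] = w
        for rid in hosts:
            rows.append(
                pd.DataFrame(
                    {"region_id": rid, "year": years,
                     "category": f"{prefix}{s:03d}", "value": weights}
                )
            )
    return pd.concat(rows, ignore_index=True)


def generate_pressure_fields(
    spec: WorldSpec,
    cells: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], pd.DataFrame]:
    """Gridded climate inputs: aragonite Ω, monthly SLR, weekly UV and SST.

    Each field is per-cell climatology + seasonal cycle + noise, with
    anomalies injected at rate ``anomaly_rate`` (a +3.5 SD spike in a random
    cell-week).  Returns (cells, grids, truth anomaly table).
    """
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    if cells is None:
        cells = _cells(spec, rng)
    years = np.array(list(spec.year_range))
    n_years = len(years)
    cid = cells["cell_id"].to_numpy()
    n_cells = len(cid)
    grids: dict[str, pd.DataFrame] = {}
    anomaly_rows = []

    # aragonite saturation state: pre-industrial baseline and annual means
    omega_base = rng.normal(3.0, 0.3, n_cells).clip(1.5)
    decline = rng.uniform(0.0, 0.04, n_cells)  # per-year loss of Ω
    grids["oa_omega_base"] = pd.DataFrame({"cell_id": cid, "value": omega_base})
    oa = []
    for i, y in enumerate(years):
        val = omega_base - decline * (y - years[0] + 20) + rng.normal(0, 0.02, n_cells)
        oa.append(pd.DataFrame({"cell_id": cid, "year": y, "value": val}))
    grids["oa_omega"] = pd.concat(oa, ignore_index=True)

    # monthly sea-level anomalies (mm), rising trend + seasonal cycle
    slr_trend = rng.uniform(1.0, 5.0, n_cells)  # mm per year
    months = np.arange(1, 13)
    slr = []
    for i, y in enumerate(years):
        base = slr_trend * (y - years[0]) - 10.0
        for m in months:
            val = base + 8.0 * np.sin(2 * np.pi * m / 12) + rng.normal(0, 4.0, n_cells)
            slr.append(pd.DataFrame({"cell_id": cid, "year": y, "month": m, "value": val}))
    grids["slr_anom_mm"] = pd.concat(slr, ignore_index=True)

    # weekly UV irradiance and SST with injected anomalies
    for layer, mean0, season_amp, sd in (
        ("uv_mw_m2", 120.0, 30.0, 6.0),
        ("sst_c", 18.0, 5.0, 0.8),
    ):
        cell_mean = rng.normal(mean0, mean0 * 0.1, n_cells)
        weeks = np.arange(1, 53)
        season = season_amp * np.sin(2 * np.pi * weeks / 52)
        vals = (
            cell_mean[:, None, None]
            + season[None, None, :]
            + rng.normal(0.0, sd, (n_cells, n_years, 52))
        )
        if spec.anomaly_rate > 0:
            hits = rng.uniform(size=(n_cells, n_years, 52)) < spec.anomaly_rate
            vals = vals + hits * (3.5 * sd)
            ci, yi, wi = np.nonzero(hits)
            anomaly_rows.append(
                pd.DataFrame(
                    {"layer": layer, "cell_id": cid[ci], "year": years[yi],
                     "week": wi + 1}
                )
            )
        grids[layer] = pd.DataFrame(
            {
                "cell_id": np.repeat(cid, n_years * 52),
                "year": np.tile(np.repeat(years, 52), n_cells),
                "week": np.tile(weeks, n_cells * n_years),
                "value": vals.ravel(),
            }
        )

    # fishing inputs: cell-level catch by sector and net primary productivity
    npp = np.exp(rng.normal(0.0, 0.4, n_cells))
    effort = np.exp(rng.normal(0.0, 0.8, n_cells))
    fish = []
    art = []
    for y in years:
        growth = 1.0 + 0.02 * (y - years[0])
        fish.append(pd.DataFrame({
            "cell_id": cid, "year": y,
            "value": effort * growth * np.exp(rng.normal(0, 0.2, n_cells)) * 1e3,
        }))
        art.append(pd.DataFrame({
            "cell_id": cid, "year": y,
            "value": 0.3 * effort * np.exp(rng.normal(0, 0.3, n_cells)) * 1e3,
        }))
    grids["fp_catch_industrial"] = pd.concat(fish, ignore_index=True)
    grids["fp_catch_artisanal"] = pd.concat(art, ignore_index=True)
    grids["fp_npp"] = pd.DataFrame({"cell_id": cid, "value": npp})

    anomalies = (
        pd.concat(anomaly_rows, ignore_index=True)
        if anomaly_rows
        else pd.DataFrame(columns=["layer", "cell_id", "year", "week"])
    )
    return cells, grids, anomalies


# ---------------------------------------------------------------------------
# Matrices
# ---------------------------------------------------------------------------

def default_pressure_matrix() -> pd.DataFrame:
    """Rank-weighted (1–3) goal × pressure-layer matrix over five ecological
    categories plus a social column shared by every goal."""
    P, A, H, F, C = ECOLOGICAL_CATEGORIES
    rows: list[tuple[str, str, int, str]] = []

    def add(goal, *entries):
        for layer, w, cat in entries:
            rows.append((goal, layer, w, cat))

    fishing = [("fp_com_hb", 3, F), ("fp_com_lb", 2, F), ("fp_art_lb", 1, F)]
    climate = [("cc_oa", 2, C), ("cc_slr", 1, C), ("cc_uv", 1, C), ("cc_sst", 2, C)]
    pollution = [("po_nutrient", 2, P), ("po_chemical", 2, P), ("po_pathogen", 1, P), ("po_trash", 1, P)]
    habitat = [("hd_subtidal", 2, H), ("hd_intertidal", 1, H)]
    alien = [("sp_alien", 2, A), ("sp_genetic", 1, A)]
    social = [("ss_wgi", 1, SOCIAL_CATEGORY), ("ss_spi", 1, SOCIAL_CATEGORY)]

    add("FIS", *fishing, ("cc_sst", 1, C), ("po_chemical", 1, P), *social)
    add("MAR", ("po_nutrient", 2, P), ("po_chemical", 2, P), ("po_pathogen", 2, P),
        ("sp_alien", 2, A), ("sp_genetic", 2, A), ("cc_sst", 1, C), *social)
    add("AO", *fishing, *habitat, ("po_chemical", 1, P), *social)
    add("NP", ("sp_harvest", 3, F), ("fp_com_lb", 1, F), *habitat, ("cc_oa", 1, C), *social)
    add("CS", *habitat, *climate, ("po_nutrient", 1, P), *social)
    add("CP", *habitat, *climate, ("po_nutrient", 1, P), ("sp_alien", 1, A), *social)
    add("TR", ("po_trash", 3, P), ("po_pathogen", 2, P), ("cc_slr", 1, C), *social)
    add("LIV", *pollution[:2], ("cc_slr", 1, C), *social)
    add("ECO", ("po_chemical", 1, P), ("cc_slr", 1, C), *social)
    add("ICO", ("sp_harvest", 3, F), *fishing[:2], *climate, ("po_chemical", 1, P), *social)
    add("LSP", *habitat, ("po_trash", 2, P), ("cc_slr", 1, C), *social)
    add("CW", *pollution, ("sp_alien", 1, A), *social)
    add("SPP", *fishing, ("sp_harvest", 2, F), *climate, *pollution[:2], *habitat, *alien, *social)
    add("HAB", *habitat, *climate, ("po_nutrient", 2, P), ("po_chemical", 1, P), *social)

    pm = pd.DataFrame(rows, columns=["goal_id", "layer_id", "weight", "category"])
    return pm.drop_duplicates(subset=["goal_id", "layer_id"]).reset_index(drop=True)


def default_resilience_matrix() -> pd.DataFrame:
    """Regulatory layers tied to the five ecological pressure categories, an
    ecological-integrity layer, and two social layers, for every goal."""
    P, A, H, F, C = ECOLOGICAL_CATEGORIES
    reg = {
        "reg_fishing": F, "reg_pollution": P, "reg_alien": A,
        "reg_habitat": H, "reg_climate": C, "reg_mpa": H,
    }
    goal_reg = {
        "FIS": ["reg_fishing", "reg_mpa"],
        "MAR": ["reg_pollution", "reg_alien"],
        "AO": ["reg_fishing", "reg_habitat"],
        "NP": ["reg_fishing", "reg_habitat", "reg_mpa"],
        "CS": ["reg_habitat", "reg_climate", "reg_mpa"],
        "CP": ["reg_habitat", "reg_climate", "reg_mpa"],
        "TR": ["reg_pollution", "reg_mpa"],
        "LIV": ["reg_pollution"],
        "ECO": ["reg_pollution"],
        "ICO": ["reg_fishing", "reg_mpa", "reg_climate"],
        "LSP": ["reg_habitat", "reg_mpa"],
        "CW": ["reg_pollution"],
        "SPP": ["reg_fishing", "reg_alien", "reg_habitat", "reg_climate", "reg_mpa"],
        "HAB": ["reg_habitat", "reg_climate", "reg_mpa"],
    }
    rows = []
    for goal, regs in goal_reg.items():
        for layer in regs:
            rows.append((goal, layer, "regulatory", reg[layer]))
        rows.append((goal, "eco_integrity", "ecological", None))
        rows.append((goal, "res_wgi", "social", None))
        rows.append((goal, "res_spi", "social", None))
    return pd.DataFrame(
        rows, columns=["goal_id", "layer_id", "rtype", "addresses_category"]
    )


# ---------------------------------------------------------------------------
# Layer schema registry
# ---------------------------------------------------------------------------

def layer_schemas() -> dict[str, LayerSchema]:
    """Declarations for every tall (region, year) layer the engine reads."""
    s: dict[str, LayerSchema] = {}

    def reg(layer_id, **kw):
        s[layer_id] = LayerSchema(layer_id=layer_id, **kw)

    reg("np_harvest", units="tonnes", has_category=True, annual=False)
    reg("ao_need", units="index", annual=True)
    reg("lsp_protected", units="km2", annual=True)
    reg("lsp_zone_area", units="km2", annual=True)
    reg("spp_risk", units="risk weight", bounds=(0.0, 1.0), has_category=True)
    reg("ico_risk", units="risk weight", bounds=(0.0, 1.0), has_category=True)
    reg("hab_extent", units="km2", has_category=True)
    reg("hab_condition", units="fraction", has_category=True)
    reg("hab_condition_ref", units="fraction", has_category=True)
    for cw in ("cw_nutrient", "cw_chemical", "cw_pathogen", "cw_trash"):
        reg(cw, units="contamination", bounds=(0.0, 1.0))
    for st in ("tr_status", "mar_status", "liv_status", "eco_status"):
        reg(st, units="status", bounds=(0.0, 100.0))
    for pl in ("sp_alien", "sp_genetic", "sp_harvest", "hd_subtidal", "hd_intertidal"):
        reg(pl, units="pressure", bounds=(0.0, 1.0))
    for rl in ("reg_fishing", "reg_pollution", "reg_alien", "reg_habitat",
               "reg_climate", "reg_mpa", "eco_integrity"):
        reg(rl, units="resilience", bounds=(0.0, 1.0))
    reg("wgi", units="governance", bounds=(0.0, 1.0))
    reg("gear_split", units="proportion high bycatch", bounds=(0.0, 1.0))
    reg("spi_components", units="score", bounds=(0.0, 100.0), has_category=True, annual=False)
    return s


# ---------------------------------------------------------------------------
# World generation
# ---------------------------------------------------------------------------

def generate_world(spec: WorldSpec) -> World:
    """Deterministically generate a full synthetic assessment world."""
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.n_regions
    years = np.array(list(spec.year_range))
    regions = _regions(spec, rng)
    cells, grids, anomalies = generate_pressure_fields(spec, _cells(spec, rng), rng)

    # per-region status level and slope (optionally correlated: good get better)
    rho = spec.level_slope_corr
    z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
    level = np.clip(70.0 + 10.0 * z[:, 0], 10.0, 95.0)
    slope = spec.mean_slope + spec.trend_sd * z[:, 1]
    truth_slopes = pd.DataFrame({"region_id": regions["region_id"], "slope": slope})

    layers: dict[str, pd.DataFrame] = {}

    # observed-status panels (goals whose internal model is out of scope)
    for lid in ("tr_status", "mar_status", "liv_status", "eco_status"):
        lvl = np.clip(level + rng.normal(0.0, 5.0, n), 5.0, 95.0)
        layers[lid] = _panel(spec, rng, lvl, slope, spec.status_noise_sd, 0.0, 100.0)

    # natural products: smooth harvests with decline, some sporadic series
    rows = []
    for rid in range(1, n + 1):
        n_products = int(rng.integers(2, len(PRODUCTS) + 1))
        prods = rng.choice(PRODUCTS, size=n_products, replace=False)
        for p in prods:
            peak = float(np.exp(rng.normal(6.0, 1.5)))
            peak_year = int(rng.choice(years[: max(1, len(years) // 2)]))
            decline = rng.uniform(0.0, 0.12)
            sporadic = rng.uniform() < 0.2
            vals = peak * np.exp(-decline * np.maximum(0, years - peak_year)) * np.exp(
                rng.normal(0.0, 0.15, len(years))
            )
            vals[years < peak_year] = peak * rng.uniform(0.5, 1.0, (years < peak_year).sum())
            if sporadic:
                vals[rng.uniform(size=len(years)) < 0.5] = 0.0
            rows.append(pd.DataFrame({"region_id": rid, "year": years, "category": p, "value": vals}))
    layers["np_harvest"] = pd.concat(rows, ignore_index=True)

    # artisanal-opportunity economic need (poverty proxy, falling slowly)
    need0 = np.exp(rng.normal(0.0, 1.0, n))
    rows = []
    for i, y in enumerate(years):
        rows.append(pd.DataFrame({
            "region_id": np.arange(1, n + 1), "year": y,
            "value": need0 * np.exp(-0.01 * i) * np.exp(rng.normal(0, 0.05, n)),
        }))
    layers["ao_need"] = pd.concat(rows, ignore_index=True)

    # lasting special places: step-change cumulative protected area
    zone = np.exp(rng.normal(7.0, 0.8, n))
    prot = zone * rng.uniform(0.0, 0.15, n)
    rows, zrows = [], []
    for y in years:
        jump = (rng.uniform(size=n) < 0.15) * zone * rng.uniform(0.02, 0.2, n)
        prot = np.minimum(zone, prot + jump)
        rows.append(pd.DataFrame({"region_id": np.arange(1, n + 1), "year": y, "value": prot.copy()}))
        zrows.append(pd.DataFrame({"region_id": np.arange(1, n + 1), "year": y, "value": zone}))
    layers["lsp_protected"] = pd.concat(rows, ignore_index=True)
    layers["lsp_zone_area"] = pd.concat(zrows, ignore_index=True)

    # species and iconic risk-category histories
    layers["spp_risk"] = _species_histories(spec, rng, n_species=30, prefix="spp", drift_p=0.15)
    layers["ico_risk"] = _species_histories(spec, rng, n_species=8, prefix="ico", drift_p=0.25)

    # habitats: extent, condition and reference condition per habitat
    hrows_e, hrows_c, hrows_r = [], [], []
    for h in HABITATS:
        present = rng.uniform(size=n) < (0.9 if h != "seaice" else 0.4)
        if not present.any():
            present[rng.integers(0, n)] = True
        rids = np.arange(1, n + 1)[present]
        ext = np.exp(rng.normal(5.0, 1.0, len(rids)))
        cond0 = rng.uniform(0.6, 1.0, len(rids))
        loss = rng.uniform(0.0, 0.04 if h == "seaice" else 0.01, len(rids))
        for i, y in enumerate(years):
            cond = np.clip(cond0 - loss * i + rng.normal(0, 0.01, len(rids)), 0.01, 1.2)
            hrows_e.append(pd.DataFrame({"region_id": rids, "year": y, "category": h, "value": ext}))
            hrows_c.append(pd.DataFrame({"region_id": rids, "year": y, "category": h, "value": cond}))
            hrows_r.append(pd.DataFrame({"region_id": rids, "year": y, "category": h, "value": 1.0}))
    layers["hab_extent"] = pd.concat(hrows_e, ignore_index=True)
    layers["hab_condition"] = pd.concat(hrows_c, ignore_index=True)
    layers["hab_condition_ref"] = pd.concat(hrows_r, ignore_index=True)

    # clean-waters contamination components (doubling as pollution pressures)
    for cw, hi in (("cw_nutrient", 0.6), ("cw_chemical", 0.5),
                   ("cw_pathogen", 0.5), ("cw_trash", 0.4)):
        layers[cw] = _bounded_walk(spec, rng, 0.05, hi, 0.03)

    # direct pressure layers
    for pl in ("sp_alien", "sp_genetic", "sp_harvest", "hd_subtidal", "hd_intertidal"):
        layers[pl] = _bounded_walk(spec, rng, 0.05, 0.6, 0.03)

    # regulatory and ecological-integrity resilience layers (slowly improving)
    for rl in ("reg_fishing", "reg_pollution", "reg_alien", "reg_habitat",
               "reg_climate", "reg_mpa", "eco_integrity"):
        layers[rl] = _bounded_walk(spec, rng, 0.3, 0.8, 0.02, drift=0.005)

    # governance and gear split
    layers["wgi"] = _bounded_walk(spec, rng, 0.2, 0.9, 0.01)
    layers["gear_split"] = _bounded_walk(spec, rng, 0.2, 0.5, 0.01)

    # SPI components: linear in a governance/georegion signal + noise, with
    # missing-at-random gaps and uninhabited regions blanked entirely
    geo_effect = {g: e for g, e in zip(UN_GEOREGIONS, rng.normal(0.0, 8.0, len(UN_GEOREGIONS)))}
    wgi_last = layers["wgi"].groupby("region_id")["value"].mean().reindex(regions["region_id"]).to_numpy()
    base = 50.0 + 30.0 * wgi_last + regions["un_georegion"].map(geo_effect).to_numpy()
    comp_rows = []
    gap_rows = []
    for k, comp in enumerate(SPI_COMPONENTS):
        a_k = rng.normal(0.0, 3.0)
        vals = np.clip(base + a_k + rng.normal(0.0, 3.0, n), 0.0, 100.0)
        gap_rows.append({"component": comp, "intercept": 50.0 + a_k, "wgi_coef": 30.0,
                         **{f"geo_{g}": e for g, e in geo_effect.items()}})
        comp_rows.append(pd.DataFrame({
            "region_id": regions["region_id"], "year": spec.years[1],
            "category": comp, "value": vals,
            "inhabited": regions["inhabited"].to_numpy(),
        }))
    spi = pd.concat(comp_rows, ignore_index=True)
    spi = spi[spi["inhabited"]].drop(columns="inhabited").reset_index(drop=True)
    if spec.missingness > 0 and len(spi):
        drop = rng.uniform(size=len(spi)) < spec.missingness
        spi = spi[~drop].reset_index(drop=True)
    layers["spi_components"] = spi

    stocks_meta, stock_panel, truth_bbmsy = _stocks(spec, rng)
    ram = _ram_assessments(stocks_meta, truth_bbmsy, rng)

    truth = SyntheticTruth(
        status_slopes=truth_slopes,
        stocks=stocks_meta,
        bbmsy=truth_bbmsy,
        anomalies=anomalies,
        gapfill_coefficients=pd.DataFrame(gap_rows),
        fixed_slope=spec.mean_slope,
        slope_sd=spec.trend_sd,
    )
    world = World(
        spec=spec,
        regions=regions,
        cells=cells,
        stock_panel=stock_panel,
        layers=layers,
        grids=grids,
        pressure_matrix=default_pressure_matrix(),
        resilience_matrix=default_resilience_matrix(),
        truth=truth,
    )
    world.layers["ram_bbmsy"] = ram
    return world


def write_world(world: World, out_dir: str | Path) -> None:
    """Write the full layer bundle + truth file as CSVs."""
    import yaml

    out = Path(out_dir)
    (out / "layers").mkdir(parents=True, exist_ok=True)
    (out / "grids").mkdir(exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    world.regions.to_csv(out / "regions.csv", index=False)
    world.cells.to_csv(out / "cells.csv", index=False)
    world.stock_panel.to_csv(out / "stock_panel.csv", index=False)
    world.pressure_matrix.to_csv(out / "pressure_matrix.csv", index=False)
    world.resilience_matrix.to_csv(out / "resilience_matrix.csv", index=False)
    for lid, df in world.layers.items():
        df.to_csv(out / "layers" / f"{lid}.csv", index=False)
    for gid, df in world.grids.items():
        df.to_csv(out / "grids" / f"{gid}.csv", index=False)
    world.truth.status_slopes.to_csv(out / "truth" / "status_slopes.csv", index=False)
    world.truth.stocks.to_csv(out / "truth" / "stocks.csv", index=False)
    world.truth.bbmsy.to_csv(out / "truth" / "bbmsy.csv", index=False)
    world.truth.anomalies.to_csv(out / "truth" / "anomalies.csv", index=False)
    world.truth.gapfill_coefficients.to_csv(out / "truth" / "gapfill_coefficients.csv", index=False)
    spec = world.spec
    with open(out / "spec.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "n_regions": spec.n_regions,
                "years": list(spec.years),
                "rng_seed": spec.rng_seed,
                "mean_slope": spec.mean_slope,
                "trend_sd": spec.trend_sd,
                "status_noise_sd": spec.status_noise_sd,
                "level_slope_corr": spec.level_slope_corr,
                "n_stocks_per_region": spec.n_stocks_per_region,
                "n_cells_per_region": spec.n_cells_per_region,
                "anomaly_rate": spec.anomaly_rate,
                "missingness": spec.missingness,
                "uninhabited_fraction": spec.uninhabited_fraction,
                "fixed_slope": world.truth.fixed_slope,
            },
            fh,
            sort_keys=False,
        )
    logger.info("wrote world bundle to %s", out)


def load_spec(path: str | Path) -> WorldSpec:
    """Read a WorldSpec from a YAML file (unknown keys ignored)."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "years" in raw:
        raw["years"] = tuple(raw["years"])
    known = set(WorldSpec.__dataclass_fields__)
    return WorldSpec(**{k: v for k, v in raw.items() if k in known})


def read_world(in_dir: str | Path) -> World:
    """Read a world bundle written by :func:`write_world`."""
    src = Path(in_dir)
    spec = load_spec(src / "spec.yaml")
    layers = {
        p.stem: pd.read_csv(p) for p in sorted((src / "layers").glob("*.csv"))
    }
    grids = {p.stem: pd.read_csv(p) for p in sorted((src / "grids").glob("*.csv"))}
    truth = SyntheticTruth(
        status_slopes=pd.read_csv(src / "truth" / "status_slopes.csv"),
        stocks=pd.read_csv(src / "truth" / "stocks.csv"),
        bbmsy=pd.read_csv(src / "truth" / "bbmsy.csv"),
        anomalies=pd.read_csv(src / "truth" / "anomalies.csv"),
        gapfill_coefficients=pd.read_csv(src / "truth" / "gapfill_coefficients.csv"),
        fixed_slope=spec.mean_slope,
        slope_sd=spec.trend_sd,
    )
    return World(
        spec=spec,
        regions=pd.read_csv(src / "regions.csv"),
        cells=pd.read_csv(src / "cells.csv"),
        stock_panel=pd.read_csv(src / "stock_panel.csv"),
        layers=layers,
        grids=grids,
        pressure_matrix=pd.read_csv(src / "pressure_matrix.csv"),
        resilience_matrix=pd.read_csv(src / "resilience_matrix.csv"),
        truth=truth,
    )
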