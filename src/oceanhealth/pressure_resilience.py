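"""Pressure-layer construction and per-goal pressure/resilience aggregation.

Gridded climate inputs (aragonite saturation, sea-level anomalies, weekly UV
and SST) and cell-level fishing inputs are reduced to per-region layers on
[0, 1]; the social layer derives from a Social Progress Index with
regression gapfilling.  Per-goal aggregation runs through rank-weighted
matrices: pressures combine five ecological categories with a social
component, resilience combines regulatory (tied to the same five
categories), ecological-integrity and social components.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_data import (
    ECOLOGICAL_CATEGORIES,
    SOCIAL_CATEGORY,
    EngineConfig,
    GapfillError,
    LayerError,
    logger,
)

# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def _region_mean(
    cell_values: pd.DataFrame, cells: pd.DataFrame, by: tuple[str, ...] = ("year",)
) -> pd.DataFrame:
    """Area-weighted mean of per-cell values within each region."""
    merged = cell_values.merge(
        cells.loc[:, ["cell_id", "region_id", "area_km2"]], on="cell_id"
    )
    merged["wv"] = merged["value"] * merged["area_km2"]
    g = merged.groupby(["region_id", *by])
    out = (g["wv"].sum() / g["area_km2"].sum()).rename("value").reset_index()
    return out


def _q9999(values: np.ndarray) -> float:
    return float(np.quantile(values, 0.9999))


# ---------------------------------------------------------------------------
# Climate pressure layers
# ---------------------------------------------------------------------------

def oa_pressure(
    base: pd.DataFrame, annual: pd.DataFrame, cells: pd.DataFrame
) -> pd.DataFrame:
    """Ocean-acidification pressure from aragonite saturation state Ω.

    Cells currently at or below the biological threshold Ω = 1 take pressure
    1.  Otherwise the decline from the pre-industrial baseline is rescaled by
    the baseline's distance from the threshold,
    ΔΩ = (Ω_base − Ω_year) / (Ω_base − 1), so the same absolute loss counts
    for more the closer the cell already sits to undersaturation; negative
    ΔΩ (Ω increased) takes pressure 0.  Cells whose baseline is itself ≤ 1
    while the current value is above it are indeterminate under this scaling
    and are excluded with a warning.
    """
    merged = annual.merge(base.rename(columns={"value": "base"}), on="cell_id")
    omega = merged["value"].to_numpy()
    ob = merged["base"].to_numpy()
    indeterminate = (ob <= 1.0) & (omega > 1.0)
    if indeterminate.any():
        logger.warning("OA: %d indeterminate cell-years excluded (baseline <= 1)", int(indeterminate.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = (ob - omega) / (ob - 1.0)
    pressure = np.clip(delta, 0.0, 1.0)
    pressure = np.where(omega <= 1.0, 1.0, pressure)
    merged["value"] = pressure
    merged = merged[~indeterminate]
    return _region_mean(merged.loc[:, ["cell_id", "year", "value"]], cells)


def slr_pressure(
    monthly: pd.DataFrame,
    cells: pd.DataFrame,
    ref_years: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Sea-level-rise pressure from monthly anomalies, coastal cells only.

    Annual cell value = mean of monthly anomalies floored at 0 (falling seas
    are no pressure); rescaled by the single maximum annual cell anomaly over
    the reference window (default: the five most recent years).
    """
    coastal = cells[cells["coastal_flag"]]
    missing = set(cells["region_id"]) - set(coastal["region_id"])
    if missing:
        logger.warning("SLR undefined for regions without coastal cells: %s", sorted(missing))
    sub = monthly[monthly["cell_id"].isin(coastal["cell_id"])]
    annual = (
        sub.groupby(["cell_id", "year"])["value"].mean().clip(lower=0.0).rename("value").reset_index()
    )
    years = sorted(annual["year"].unique())
    if ref_years is None:
        ref_years = (years[max(0, len(years) - 5)], years[-1])
    window = annual[(annual["year"] >= ref_years[0]) & (annual["year"] <= ref_years[1])]
    ref = float(window["value"].max())
    if ref <= 0:
        annual["value"] = 0.0
    else:
        annual["value"] = np.minimum(1.0, annual["value"] / ref)
    out = _region_mean(annual, coastal)
    out.attrs["reference"] = ref
    return out


def count_anomalous_weeks(weekly: pd.DataFrame) -> pd.DataFrame:
    """Yearly count of anomalous weeks per cell.

    A week is anomalous when its value exceeds the cell's climatological
    mean plus one standard deviation (climatology over the full series);
    with weekly data the count is capped at 52 events per cell-year by
    construction.  A constant series (SD = 0) has no anomalies.
    """
    stats = weekly.groupby("cell_id")["value"].agg(["mean", "std"])
    stats["std"] = stats["std"].fillna(0.0)
    merged = weekly.merge(stats, on="cell_id")
    merged["anom"] = merged["value"] > merged["mean"] + merged["std"]
    return merged.groupby(["cell_id", "year"])["anom"].sum().rename("count").reset_index()


def anomaly_pressure(
    weekly: pd.DataFrame, cells: pd.DataFrame, kind: str = "SST", window: int = 5
) -> pd.DataFrame:
    """Anomalous-week pressure for weekly UV or SST series.

    The pressure for a year is the count of anomalous weeks
    (:func:`count_anomalous_weeks`) summed over the trailing five years,
    rescaled by the 99.99th quantile of all five-year sums across cells and
    windows, capped at 1.
    """
    yearly = count_anomalous_weeks(weekly)
    counts = yearly.pivot(index="year", columns="cell_id", values="count").fillna(0.0).sort_index()
    sums = counts.rolling(window).sum().dropna()
    if sums.empty:
        raise LayerError(f"{kind}: series shorter than the {window}-year window")
    ref = _q9999(sums.to_numpy().ravel())
    scaled = sums if ref <= 0 else np.minimum(1.0, sums / ref)
    if ref <= 0:
        scaled = sums * 0.0
    long = scaled.reset_index().melt(id_vars="year", var_name="cell_id", value_name="value")
    out = _region_mean(long, cells)
    out.attrs["reference"] = ref
    return out


# ---------------------------------------------------------------------------
# Fishing pressure layers
# ---------------------------------------------------------------------------

def fishing_pressure(
    industrial: pd.DataFrame,
    artisanal: pd.DataFrame,
    npp: pd.DataFrame,
    gear_split: pd.DataFrame,
    cells: pd.DataFrame,
) -> dict[str, pd.DataFrame]:
    """Commercial high/low-bycatch and artisanal low-bycatch fishing pressure.

    Cell catch is standardised by net primary productivity; industrial catch
    splits into high/low-bycatch gear by the regional gear proportion; each
    layer is rescaled by its own 99.99th quantile across cell-years.
    """
    npp_s = npp.set_index("cell_id")["value"]
    bad_npp = npp_s[npp_s <= 0].index.tolist()
    region_of = cells.set_index("cell_id")["region_id"]

    def standardize(catch: pd.DataFrame) -> pd.DataFrame:
        df = catch.copy()
        df["npp"] = df["cell_id"].map(npp_s)
        missing = df["npp"].isna() | (df["npp"] <= 0)
        if missing.any():
            logger.warning("fishing pressure: %d cell-years without usable NPP excluded", int(missing.sum()))
        df = df[~missing]
        df["value"] = df["value"] / df["npp"]
        return df.loc[:, ["cell_id", "year", "value"]]

    ind = standardize(industrial)
    art = standardize(artisanal)
    ind["region_id"] = ind["cell_id"].map(region_of)
    split = gear_split.rename(columns={"value": "split"})
    ind = ind.merge(split.loc[:, ["region_id", "year", "split"]], on=["region_id", "year"], how="left")
    ind["split"] = ind["split"].fillna(0.5)
    layers_raw = {
        "fp_com_hb": ind.assign(value=ind["value"] * ind["split"]),
        "fp_com_lb": ind.assign(value=ind["value"] * (1.0 - ind["split"])),
        "fp_art_lb": art,
    }
    out: dict[str, pd.DataFrame] = {}
    for lid, df in layers_raw.items():
        vals = df["value"].to_numpy()
        ref = _q9999(vals) if len(vals) else 0.0
        df = df.loc[:, ["cell_id", "year", "value"]].copy()
        df["value"] = np.minimum(1.0, df["value"] / ref) if ref > 0 else 0.0
        res = _region_mean(df, cells)
        res.attrs["reference"] = ref
        out[lid] = res
    return out


# ---------------------------------------------------------------------------
# Social Progress Index layer with gapfilling
# ---------------------------------------------------------------------------

def _fit_predict_ols(X: np.ndarray, y: np.ndarray, Xnew: np.ndarray) -> np.ndarray:
    A = np.column_stack([np.ones(len(X)), X])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return np.column_stack([np.ones(len(Xnew)), Xnew]) @ coef


def spi_layer(
    components: pd.DataFrame,
    wgi: pd.DataFrame,
    regions: pd.DataFrame,
) -> pd.DataFrame:
    """Social Progress Index: mean of 3 dimension means of 4 components each.

    Regions missing some components have them imputed by linear regression on
    the components they do have (fit on complete regions); regions with no
    components at all are predicted from UN geopolitical region and
    governance (WGI).  Uninhabited regions receive no score.  Returns
    (region_id, year, spi, pressure, resilience): pressure = 1 − SPI/100,
    resilience = SPI/100.
    """
    comp_names = sorted(components["category"].unique())
    dims: dict[str, list[str]] = {}
    for c in comp_names:
        dim = c.split("_")[1] if c.count("_") >= 2 else "1"
        dims.setdefault(dim, []).append(c)
    inhabited = regions.set_index("region_id")["inhabited"]
    out_rows = []
    for year, comp_y in components.groupby("year"):
        wide = comp_y.pivot(index="region_id", columns="category", values="value")
        wide = wide.reindex(columns=comp_names)
        wide = wide.reindex(regions.loc[regions["inhabited"], "region_id"])
        partial = wide[wide.isna().any(axis=1) & wide.notna().any(axis=1)]
        # impute each missing component by regressing it on the mean of the
        # region's observed components, fit on regions that have both
        for rid, row in partial.iterrows():
            obs = row.dropna().index.tolist()
            mis = row[row.isna()].index.tolist()
            for m in mis:
                others = wide.loc[wide.index != rid]
                fit = others[obs + [m]].dropna()
                if len(fit) >= 3:
                    x_fit = fit[obs].mean(axis=1).to_numpy()
                    y_fit = fit[m].to_numpy()
                else:
                    # fall back to every region carrying the component, each
                    # averaged over whatever part of the observed set it has
                    fb = others[others[m].notna()]
                    x_full = fb[obs].mean(axis=1)
                    keep = x_full.notna()
                    if keep.sum() < 3:
                        raise GapfillError(
                            f"SPI gapfill underdetermined: {int(keep.sum())} regions "
                            f"carry component {m!r} plus any of region {rid}'s observed set"
                        )
                    x_fit = x_full[keep].to_numpy()
                    y_fit = fb.loc[keep, m].to_numpy()
                pred = _fit_predict_ols(
                    x_fit[:, None], y_fit, np.array([[row[obs].mean()]])
                )
                wide.loc[rid, m] = float(np.clip(pred[0], 0.0, 100.0))
        dim_means = pd.concat(
            {d: wide[cols].mean(axis=1) for d, cols in dims.items()}, axis=1
        )
        spi = dim_means.mean(axis=1).rename("spi")
        # regions with nothing observed: predict from georegion + WGI
        empty = spi[spi.isna()].index
        if len(empty):
            have = spi.dropna()
            meta = regions.set_index("region_id")
            wgi_y = wgi[wgi["year"] == year] if "year" in wgi.columns else wgi
            wgi_s = wgi_y.set_index("region_id")["value"]
            geo = pd.get_dummies(meta["un_georegion"], dtype=float)
            # keep only georegion indicators with support among scored regions
            supported = [c for c in geo.columns if geo.loc[have.index, c].sum() > 0]
            X_all = pd.concat([geo[supported], wgi_s.rename("wgi")], axis=1)
            fit_idx = have.index.intersection(X_all.dropna().index)
            if len(fit_idx) < 3:
                raise GapfillError(
                    f"SPI region gapfill underdetermined: only {len(fit_idx)} scored regions"
                )
            pred_idx = [r for r in empty if r in X_all.dropna().index]
            if pred_idx:
                pred = _fit_predict_ols(
                    X_all.loc[fit_idx].to_numpy(),
                    have.loc[fit_idx].to_numpy(),
                    X_all.loc[pred_idx].to_numpy(),
                )
                spi.loc[pred_idx] = np.clip(pred, 0.0, 100.0)
        spi = spi.dropna()
        out_rows.append(
            pd.DataFrame(
                {
                    "region_id": spi.index,
                    "year": year,
                    "spi": spi.to_numpy(),
                    "pressure": 1.0 - spi.to_numpy() / 100.0,
                    "resilience": spi.to_numpy() / 100.0,
                }
            )
        )
    out = pd.concat(out_rows, ignore_index=True)
    # uninhabited regions carry no social score by construction
    return out[out["region_id"].map(inhabited).fillna(False)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Per-goal aggregation
# ---------------------------------------------------------------------------

def _layers_long(layers: dict[str, pd.DataFrame]) -> pd.DataFrame:
    frames = []
    for lid, df in layers.items():
        frames.append(df.loc[:, ["region_id", "year", "value"]].assign(layer_id=lid))
    return pd.concat(frames, ignore_index=True)


def aggregate_pressures(
    layers: dict[str, pd.DataFrame],
    matrix: pd.DataFrame,
    cfg: EngineConfig,
    regions: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-goal pressure p ∈ [0, 1] via the rank-weighted matrix.

    Within each of the five ecological categories the member layers combine
    by rank-weighted mean; the ecological pressure is the mean over
    categories with at least one layer present; p = γ·p_ecol +
    (1 − γ)·p_social.  Layers absent for a region-year are dropped with
    reweighting; uninhabited regions omit the social term entirely.
    """
    missing = set(matrix["layer_id"]) - set(layers)
    if missing:
        logger.warning("pressure layers missing entirely, dropped with reweighting: %s", sorted(missing))
    long = _layers_long({k: v for k, v in layers.items() if k in set(matrix["layer_id"])})
    merged = long.merge(matrix, on="layer_id")
    merged = merged.dropna(subset=["value"])
    merged["wv"] = merged["value"] * merged["weight"]
    g = merged.groupby(["goal_id", "region_id", "year", "category"])
    cat = (g["wv"].sum() / g["weight"].sum()).rename("cat_value").reset_index()
    ecol = (
        cat[cat["category"] != SOCIAL_CATEGORY]
        .groupby(["goal_id", "region_id", "year"])["cat_value"]
        .mean()
        .rename("p_ecol")
    )
    soc = (
        cat[cat["category"] == SOCIAL_CATEGORY]
        .set_index(["goal_id", "region_id", "year"])["cat_value"]
        .rename("p_social")
    )
    out = pd.concat([ecol, soc], axis=1).reset_index()
    if regions is not None:
        inhabited = regions.set_index("region_id")["inhabited"]
        uninh = ~out["region_id"].map(inhabited).fillna(True)
        out.loc[uninh.to_numpy(), "p_social"] = np.nan
    gamma = cfg.gamma
    p = np.where(
        out["p_social"].isna(),
        out["p_ecol"],
        gamma * out["p_ecol"] + (1.0 - gamma) * out["p_social"],
    )
    p = np.where(out["p_ecol"].isna(), out["p_social"], p)
    out["pressure"] = p
    out = out.dropna(subset=["pressure"])
    return out.loc[:, ["goal_id", "region_id", "year", "pressure"]].reset_index(drop=True)


def aggregate_resilience(
    layers: dict[str, pd.DataFrame],
    matrix: pd.DataFrame,
    cfg: EngineConfig,
    regions: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-goal resilience r ∈ [0, 1].

    Regulatory layers average within the ecological pressure category they
    address, then across categories; r is the equal-weight mean of the
    regulatory, ecological-integrity and social components present.
    Uninhabited regions omit the social component.
    """
    missing = set(matrix["layer_id"]) - set(layers)
    if missing:
        logger.warning("resilience layers missing entirely, dropped with reweighting: %s", sorted(missing))
    long = _layers_long({k: v for k, v in layers.items() if k in set(matrix["layer_id"])})
    merged = long.merge(matrix, on="layer_id").dropna(subset=["value"])

    reg = merged[merged["rtype"] == "regulatory"]
    reg_cat = (
        reg.groupby(["goal_id", "region_id", "year", "addresses_category"])["value"]
        .mean()
        .groupby(["goal_id", "region_id", "year"])
        .mean()
        .rename("regulatory")
    )
    comps = [reg_cat]
    for rtype in ("ecological", "social"):
        sub = merged[merged["rtype"] == rtype]
        comps.append(
            sub.groupby(["goal_id", "region_id", "year"])["value"].mean().rename(rtype)
        )
    out = pd.concat(comps, axis=1).reset_index()
    if regions is not None:
        inhabited = regions.set_index("region_id")["inhabited"]
        uninh = ~out["region_id"].map(inhabited).fillna(True)
        out.loc[uninh.to_numpy(), "social"] = np.nan
    out["resilience"] = out[["regulatory", "ecological", "social"]].mean(axis=1, skipna=True)
    out = out.dropna(subset=["resilience"])
    return out.loc[:, ["goal_id", "region_id", "year", "resilience"]].reset_index(drop=True)
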