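"""Per-goal status and trend models.

Status is computed relative to a goal-specific reference point and reported
on 0–100.  The trend is the *proportional* expected change in status over
five years: the OLS slope over the five most recent status years, multiplied
by 5 and divided by the status at the earliest year used, clamped to [−1, 1].

The fisheries model estimates stock condition (B/B_MSY) from catch series
with a data-limited catch-MSY procedure — Schaefer dynamics run forward under
log-uniform (r, K) priors with feasibility filtering — overridden by formal
stock-assessment values where available.  Catch not resolved to species level
is penalised, most severely (×0.1) for catch reported only as
"miscellaneous".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import EstimationError, IntegrityError, LayerError, logger

# ---------------------------------------------------------------------------
# Catch-MSY (data-limited B/B_MSY estimation)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CatchMsyConfig:
    """Priors and draw count for the catch-MSY procedure.

    r and K are drawn log-uniformly (K in multiples of the maximum observed
    catch); initial depletion B0/K is uniform; a draw is feasible when the
    simulated biomass stays strictly positive throughout and the final
    depletion B_T/K lands inside the final-depletion window.

    When ``initial_depletion`` / ``final_depletion`` are None (the default)
    the windows follow the standard catch-based heuristics: the initial
    window is [0.5, 0.9] when the first catch is below half the maximum
    (fishery still developing) and [0.2, 0.6] otherwise; the final window is
    [0.01, 0.4] when recent catch has collapsed below 35% of the maximum,
    [0.4, 0.8] when it is still above 80%, and [0.2, 0.6] in between.  Fixed
    windows can be supplied instead.
    """

    n_draws: int = 5000
    r_bounds: tuple[float, float] = (0.05, 1.0)
    k_bounds_mult: tuple[float, float] = (1.0, 100.0)
    initial_depletion: tuple[float, float] | None = None
    final_depletion: tuple[float, float] | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("r_bounds", "k_bounds_mult", "initial_depletion", "final_depletion"):
            bounds = getattr(self, name)
            if bounds is None:
                continue
            lo, hi = bounds
            if not (0 < lo < hi):
                raise ValueError(f"{name} must be positive and ordered, got ({lo}, {hi})")
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")


def _depletion_windows(
    catch: np.ndarray, cfg: CatchMsyConfig
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Initial/final depletion priors, conditioned on the catch trajectory
    unless fixed windows were configured."""
    c_max = catch.max()
    init = cfg.initial_depletion
    if init is None:
        init = (0.5, 0.9) if catch[0] < 0.5 * c_max else (0.2, 0.6)
    final = cfg.final_depletion
    if final is None:
        # Continuous version of the classic catch-based heuristic, on a
        # 3-year-smoothed series.  A fishery whose catch is still at its
        # historical peak in the last years is treated as developing, with
        # the stock on the abundant side ([0.4, 0.8], the standard bin).
        # A post-peak fishery gets a window centred at 0.5 × (recent/peak):
        # under a roughly constant exploitation rate catch tracks biomass,
        # so catch at its peak ~ fully fished (0.5 K) and a collapsed catch
        # ~ a collapsed stock.
        smoothed = np.convolve(catch, np.ones(3) / 3.0, mode="valid")
        peak_at = int(np.argmax(smoothed))
        ratio = float(np.clip(catch[-3:].mean() / smoothed.max(), 0.0, 1.0))
        if peak_at >= 0.8 * (len(smoothed) - 1):
            final = (0.4, 0.8)
        else:
            center = 0.5 * ratio
            final = (max(0.01, center - 0.2), min(0.7, center + 0.2))
    return init, final


#: taxonomic-resolution penalty, level 1 ("miscellaneous") .. 6 (species).
#: Only the level-1 value is fixed by convention; the rest interpolate
#: monotonically to 1.0 and are configurable.
DEFAULT_TAXON_PENALTY: dict[int, float] = {1: 0.1, 2: 0.25, 3: 0.5, 4: 0.8, 5: 0.9, 6: 1.0}


def estimate_bbmsy_catchmsy(
    years: np.ndarray | list[int],
    catch: np.ndarray | list[float],
    cfg: CatchMsyConfig | None = None,
    stock_id: object = None,
) -> pd.DataFrame:
    """Estimate B/B_MSY per year for one stock from its catch series.

    Returns a frame (year, bbmsy, n_feasible) where bbmsy is the per-year
    median of 2B/K across feasible (r, K, B0) draws.

    Raises :class:`EstimationError` when no draw is feasible, and
    ``ValueError`` on an unusable catch series (< 10 years or all zero).
    """
    cfg = cfg or CatchMsyConfig()
    years = np.asarray(years, dtype=int)
    catch = np.asarray(catch, dtype=float)
    if len(years) < 10:
        raise ValueError(f"stock {stock_id!r}: need >= 10 catch years, got {len(years)}")
    if not (catch > 0).any():
        raise ValueError(f"stock {stock_id!r}: catch is all zero")
    order = np.argsort(years)
    years, catch = years[order], catch[order]

    rng = np.random.default_rng(cfg.rng_seed)
    n = cfg.n_draws
    init_window, final_window = _depletion_windows(catch, cfg)
    r = np.exp(rng.uniform(np.log(cfg.r_bounds[0]), np.log(cfg.r_bounds[1]), n))
    max_catch = catch.max()
    k = np.exp(
        rng.uniform(
            np.log(cfg.k_bounds_mult[0] * max_catch),
            np.log(cfg.k_bounds_mult[1] * max_catch),
            n,
        )
    )
    b = rng.uniform(*init_window, n) * k
    floor = k * 1e-3
    feasible = np.ones(n, dtype=bool)
    depletion = np.empty((len(years), n))
    for t, c in enumerate(catch):
        b = b + r * b * (1.0 - b / k) - c
        feasible &= b > floor
        b = np.maximum(b, floor)  # park crashed draws; they are already infeasible
        depletion[t] = b / k
    lo, hi = final_window
    feasible &= (depletion[-1] >= lo) & (depletion[-1] <= hi)
    n_feasible = int(feasible.sum())
    if n_feasible == 0:
        raise EstimationError(f"catch-MSY: zero feasible draws for stock {stock_id!r}")
    bbmsy = np.median(2.0 * depletion[:, feasible], axis=1)
    return pd.DataFrame({"year": years, "bbmsy": bbmsy, "n_feasible": n_feasible})


def estimate_bbmsy_panel(
    stock_panel: pd.DataFrame, cfg: CatchMsyConfig | None = None
) -> pd.DataFrame:
    """Run catch-MSY for every stock in a catch panel.

    Per-stock seeds are derived from ``cfg.rng_seed`` so the panel estimate
    is deterministic but stocks are independent.  Stocks whose estimation
    fails are skipped with a warning (they fall back to no estimate).
    """
    cfg = cfg or CatchMsyConfig()
    out = []
    for sid, grp in stock_panel.groupby("stock_id"):
        scfg = CatchMsyConfig(
            n_draws=cfg.n_draws,
            r_bounds=cfg.r_bounds,
            k_bounds_mult=cfg.k_bounds_mult,
            initial_depletion=cfg.initial_depletion,
            final_depletion=cfg.final_depletion,
            rng_seed=int((cfg.rng_seed * 1_000_003 + int(sid)) % (2**31 - 1)),
        )
        try:
            est = estimate_bbmsy_catchmsy(
                grp["year"].to_numpy(), grp["catch_tonnes"].to_numpy(), scfg, stock_id=sid
            )
        except (EstimationError, ValueError) as exc:
            logger.warning("catch-MSY skipped: %s", exc)
            continue
        est.insert(0, "stock_id", sid)
        est["source"] = "catchmsy"
        out.append(est)
    if not out:
        return pd.DataFrame(columns=["stock_id", "year", "bbmsy", "n_feasible", "source"])
    return pd.concat(out, ignore_index=True)


def merge_ram(catchmsy: pd.DataFrame, ram: pd.DataFrame) -> pd.DataFrame:
    """Overlay formal stock-assessment B/B_MSY values onto catch-MSY estimates.

    Assessment rows win on (stock_id, year) collisions; provenance is kept in
    the ``source`` column.  Conflicting duplicate assessment rows raise.
    """
    ram = ram.copy()
    dup = ram.duplicated(subset=["stock_id", "year"], keep=False)
    if dup.any():
        conflicting = ram.loc[dup].groupby(["stock_id", "year"])["bbmsy"].nunique()
        if (conflicting > 1).any():
            raise IntegrityError(
                f"conflicting duplicate assessment rows: {conflicting[conflicting > 1].index.tolist()}"
            )
        ram = ram.drop_duplicates(subset=["stock_id", "year"])
    ram["source"] = "ram"
    cm = catchmsy.copy()
    cm["source"] = cm.get("source", "catchmsy")
    keys = set(map(tuple, ram[["stock_id", "year"]].itertuples(index=False)))
    keep = ~cm.set_index(["stock_id", "year"]).index.isin(keys)
    cols = ["stock_id", "year", "bbmsy", "source"]
    merged = pd.concat([cm.loc[keep, cols], ram.loc[:, cols]], ignore_index=True)
    return merged.sort_values(["stock_id", "year"]).reset_index(drop=True)


def stock_score(bbmsy: float | np.ndarray) -> float | np.ndarray:
    """Score stock condition on (0, 1] from B/B_MSY.

    Both over- and under-exploitation are penalised: a linear ramp up to the
    plateau [0.95, 1.05] (score 1), then a linear decline to a floor of 0.25
    at B/B_MSY = 3 and beyond.
    """
    b = np.asarray(bbmsy, dtype=float)
    if (b <= 0).any():
        raise ValueError("B/B_MSY must be positive")
    under = np.minimum(1.0, b / 0.95)
    over = np.maximum(0.25, 1.0 - (1.0 - 0.25) * (b - 1.05) / (3.0 - 1.05))
    score = np.where(b < 0.95, under, np.where(b <= 1.05, 1.0, over))
    return float(score) if np.isscalar(bbmsy) else score


def fisheries_status(
    stock_panel: pd.DataFrame,
    estimates: pd.DataFrame,
    penalties: dict[int, float] | None = None,
) -> pd.DataFrame:
    """Regional fisheries status: catch-weighted geometric mean of stock scores.

    Each catch group contributes stock_score(B/B_MSY) × taxon penalty with a
    weight equal to its mean catch over the available years.  Estimates are
    carried forward from the most recent year when a year is unassessed.
    Regions with zero total catch are excluded (status undefined).
    """
    penalties = penalties or DEFAULT_TAXON_PENALTY
    bad = set(stock_panel["taxon_level"].unique()) - set(penalties)
    if bad:
        raise LayerError(f"no taxon penalty declared for levels {sorted(bad)}")
    weights = (
        stock_panel.groupby(["region_id", "stock_id", "taxon_level"])["catch_tonnes"]
        .mean()
        .rename("weight")
        .reset_index()
    )
    weights = weights[weights["weight"] > 0]
    est = estimates.sort_values(["stock_id", "year"])
    years = sorted(est["year"].unique())
    rows = []
    # forward-fill estimates so every assessment year >= first estimate scores
    pivot = est.pivot_table(index="year", columns="stock_id", values="bbmsy", aggfunc="last")
    pivot = pivot.reindex(years).ffill()
    for year in years:
        by_stock = pivot.loc[year].dropna()
        merged = weights.merge(
            by_stock.rename("bbmsy").reset_index(), on="stock_id", how="inner"
        )
        if merged.empty:
            continue
        score = stock_score(merged["bbmsy"].to_numpy())
        penalty = merged["taxon_level"].map(penalties).to_numpy()
        s = np.maximum(score * penalty, 1e-12)
        w = merged["weight"].to_numpy()
        logmean = (
            merged.assign(lw=np.log(s) * w, w=w)
            .groupby("region_id")[["lw", "w"]]
            .sum()
        )
        status = 100.0 * np.exp(logmean["lw"] / logmean["w"])
        rows.append(
            pd.DataFrame({"region_id": logmean.index, "year": year, "status": status.to_numpy()})
        )
    if not rows:
        return pd.DataFrame(columns=["region_id", "year", "status"])
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Other goal status models
# ---------------------------------------------------------------------------

def natural_products_status(
    harvest: pd.DataFrame,
    fisheries_scores: pd.DataFrame | None = None,
    buffer: float = 0.35,
    min_years: int = 4,
    smooth_window: int = 5,
) -> pd.DataFrame:
    """Sustainable natural-product harvest relative to a buffered peak.

    Per product: a trailing ``smooth_window``-year running mean of harvest;
    the reference point is (1 − buffer) × the historical peak of the smoothed
    series; the product score is the smoothed current harvest over that
    reference, capped at 1.  Products with fewer than ``min_years`` years of
    data are excluded.  The fish-oil score is multiplied by the region's
    fisheries score (0–1) as its sustainability component.  The regional
    status is the peak-weighted mean over retained products, × 100.
    """
    fis = None
    if fisheries_scores is not None and len(fisheries_scores):
        fis = fisheries_scores.set_index(["region_id", "year"])["status"] / 100.0
    rows = []
    for (rid, product), grp in harvest.groupby(["region_id", "category"]):
        grp = grp.sort_values("year")
        if grp["value"].notna().sum() < min_years:
            continue
        smoothed = grp["value"].rolling(smooth_window, min_periods=1).mean()
        peak = smoothed.cummax()
        ref = (1.0 - buffer) * peak
        with np.errstate(divide="ignore", invalid="ignore"):
            score = np.where(ref > 0, np.minimum(1.0, smoothed / ref), np.nan)
        if fis is not None and product == "fish_oil":
            sust = np.array(
                [fis.get((rid, y), np.nan) for y in grp["year"]], dtype=float
            )
            score = score * np.where(np.isnan(sust), 1.0, sust)
        rows.append(
            pd.DataFrame(
                {"region_id": rid, "year": grp["year"].to_numpy(), "category": product,
                 "score": score, "weight": peak.to_numpy()}
            )
        )
    if not rows:
        return pd.DataFrame(columns=["region_id", "year", "status"])
    per_product = pd.concat(rows, ignore_index=True).dropna(subset=["score"])
    per_product = per_product[per_product["weight"] > 0]

    def wmean(g: pd.DataFrame) -> float:
        return float(np.average(g["score"], weights=g["weight"]))

    status = (
        per_product.groupby(["region_id", "year"])
        .apply(wmean, include_groups=False)
        .rename("status")
        .reset_index()
    )
    status["status"] *= 100.0
    return status


def lasting_special_places_status(
    protected: pd.DataFrame,
    zone_area: pd.DataFrame,
    ref_fraction: float = 0.30,
) -> pd.DataFrame:
    """Protected fraction of the coastal zone against a reference fraction."""
    merged = protected.merge(
        zone_area, on=["region_id", "year"], suffixes=("_prot", "_zone")
    )
    if (merged["value_prot"] > merged["value_zone"] * (1 + 1e-9)).any():
        bad = merged[merged["value_prot"] > merged["value_zone"]]
        raise IntegrityError(
            f"protected area exceeds zone area for {len(bad)} region-years"
        )
    frac = merged["value_prot"] / merged["value_zone"]
    merged["status"] = 100.0 * np.minimum(1.0, frac / ref_fraction)
    return merged.loc[:, ["region_id", "year", "status"]]


def species_status(assessments: pd.DataFrame) -> pd.DataFrame:
    """Species-condition status from risk-category weights.

    status = 100 × max(0, ((1 − mean risk weight) − 0.25) / 0.75): a region
    whose species average 75% of the way to extinction scores 0, an all
    least-concern region scores 100.
    """
    if assessments.empty:
        return pd.DataFrame(columns=["region_id", "year", "status"])
    mean_w = assessments.groupby(["region_id", "year"])["value"].mean()
    status = 100.0 * np.maximum(0.0, ((1.0 - mean_w) - 0.25) / 0.75)
    return status.rename("status").reset_index()


def iconic_status_series(
    histories: pd.DataFrame, trend_years: int = 10
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Status series for the iconic-species subset plus its risk-model trend.

    The yearly status applies the species-condition formula to the iconic
    subset.  The trend comes from a linear model of mean risk weight over the
    most recent ten years, mapped through the status formula and converted to
    the proportional five-year convention.
    """
    if histories.empty:
        raise LayerError("iconic species list is empty")
    status = species_status(histories)
    mean_risk = histories.groupby(["region_id", "year"])["value"].mean().reset_index()
    rows = []
    for rid, grp in mean_risk.groupby("region_id"):
        grp = grp.sort_values("year").tail(trend_years)
        if len(grp) < 2:
            continue
        slope_w = np.polyfit(grp["year"], grp["value"], 1)[0]
        status_slope = -100.0 * slope_w / 0.75  # d(status)/d(mean risk) = −100/0.75
        first_year = int(grp["year"].iloc[0])
        s0 = status.loc[
            (status["region_id"] == rid) & (status["year"] == first_year), "status"
        ]
        s0 = float(s0.iloc[0]) if len(s0) else np.nan
        if not np.isfinite(s0) or s0 <= 0:
            logger.warning("iconic trend undefined for region %s (zero status); set 0", rid)
            trend = 0.0
        else:
            trend = float(np.clip(5.0 * status_slope / s0, -1.0, 1.0))
        rows.append({"region_id": rid, "trend": trend})
    return status, pd.DataFrame(rows)


def habitat_goal_status(
    extent: pd.DataFrame,
    condition: pd.DataFrame,
    condition_ref: pd.DataFrame,
    protection_ranks: dict[str, float],
    carbon_ranks: dict[str, float],
) -> dict[str, pd.DataFrame]:
    """Status for the habitat subgoal, coastal protection and carbon storage.

    Habitat condition relative to reference, capped at 1: the habitat subgoal
    averages it across habitats; coastal protection and carbon storage weight
    it by rank × extent over the habitats relevant to each service.
    """
    merged = condition.merge(
        condition_ref, on=["region_id", "year", "category"], suffixes=("", "_ref")
    ).merge(extent, on=["region_id", "year", "category"], suffixes=("", "_ext"))
    if (merged["value_ref"] <= 0).any():
        raise LayerError("missing or non-positive reference condition")
    merged["health"] = np.minimum(1.0, merged["value"] / merged["value_ref"])
    merged = merged.rename(columns={"value_ext": "extent"})

    out: dict[str, pd.DataFrame] = {}
    hab = merged.groupby(["region_id", "year"])["health"].mean() * 100.0
    out["HAB"] = hab.rename("status").reset_index()

    for goal, ranks in (("CP", protection_ranks), ("CS", carbon_ranks)):
        sub = merged[merged["category"].isin(ranks)].copy()
        sub["w"] = sub["category"].map(ranks) * sub["extent"]
        sub = sub[sub["w"] > 0]
        if sub.empty:
            out[goal] = pd.DataFrame(columns=["region_id", "year", "status"])
            continue
        g = sub.groupby(["region_id", "year"])
        status = 100.0 * g.apply(
            lambda x: np.average(x["health"], weights=x["w"]), include_groups=False
        )
        out[goal] = status.rename("status").reset_index()
    return out


def artisanal_status(need: pd.DataFrame, quantile: float = 0.95) -> pd.DataFrame:
    """Artisanal-fishing opportunity from an economic-need proxy.

    The reference point is the cross-region 95th quantile of need in each
    year (not the maximum, which a single outlier would own).
    """
    if need["value"].dropna().empty:
        raise LayerError("need layer is entirely missing")
    out = []
    for year, grp in need.groupby("year"):
        vals = grp["value"].dropna()
        q = float(np.quantile(vals, quantile))
        if q <= 0:
            status = np.full(len(grp), 100.0)
        else:
            status = 100.0 * (1.0 - np.minimum(1.0, grp["value"] / q))
        out.append(pd.DataFrame({"region_id": grp["region_id"], "year": year, "status": status}))
    return pd.concat(out, ignore_index=True).dropna(subset=["status"]).reset_index(drop=True)


def clean_waters_status(components: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Geometric mean of (1 − contamination) over the four pollution components.

    The geometric mean makes any fully-contaminated component (value 1)
    annihilate the status.  Region-years missing any component are dropped
    with a warning (status undefined).
    """
    if len(components) != 4:
        raise LayerError(f"expected 4 clean-waters components, got {len(components)}")
    frames = []
    for name, df in components.items():
        frames.append(df.set_index(["region_id", "year"])["value"].rename(name))
    wide = pd.concat(frames, axis=1)
    incomplete = wide.isna().any(axis=1)
    if incomplete.any():
        logger.warning("clean waters undefined for %d region-years (missing component)", int(incomplete.sum()))
        wide = wide[~incomplete]
    clean = 1.0 - wide
    with np.errstate(divide="ignore"):
        status = 100.0 * np.exp(np.log(np.maximum(clean, 0.0)).mean(axis=1))
    status = status.where(~(clean <= 0).any(axis=1), 0.0)
    return status.rename("status").reset_index()


# ---------------------------------------------------------------------------
# Proportional trend
# ---------------------------------------------------------------------------

def goal_trend(
    status: pd.Series, window: int = 5, clamp: tuple[float, float] = (-1.0, 1.0)
) -> float:
    """Proportional five-year trend of one status series (indexed by year).

    OLS slope over the ≤``window`` most recent years, × 5, ÷ status at the
    earliest year used; clamped.  A zero earliest status makes the
    proportional change undefined; it is flagged and treated as 0.
    """
    s = status.dropna().sort_index()
    s = s.iloc[-window:]
    if len(s) < 2:
        raise ValueError("trend needs >= 2 status years")
    slope = np.polyfit(s.index.to_numpy(dtype=float), s.to_numpy(dtype=float), 1)[0]
    first = float(s.iloc[0])
    if first <= 0:
        logger.warning("trend undefined (earliest status %.3g <= 0); treated as 0", first)
        return 0.0
    return float(np.clip(slope * window / first, clamp[0], clamp[1]))


def trend_panel(
    status: pd.DataFrame, window: int = 5, year: int | None = None
) -> pd.DataFrame:
    """Per-region proportional trend from a (region_id, year, status) panel,
    using the ≤window years ending at ``year`` (default: latest per region)."""
    rows = []
    for rid, grp in status.groupby("region_id"):
        s = grp.set_index("year")["status"].sort_index()
        if year is not None:
            s = s[s.index <= year]
        if len(s.dropna()) < 2:
            logger.warning("region %s: single status year, trend dropped", rid)
            continue
        rows.append({"region_id": rid, "trend": goal_trend(s, window=window)})
    return pd.DataFrame(rows, columns=["region_id", "trend"])
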