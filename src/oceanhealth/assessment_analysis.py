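"""Statistical analyses on score panels.

Given per-region score panels across assessment years these routines compute
per-region linear change, a random-intercept mixed-effects trend (REML),
predictive-validity regressions of the likely-future-status model, the
rank-versus-score comparison, and the decomposition of Index change into
goal contributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core_data import GOALS, EngineConfig, EstimationError, logger

# ---------------------------------------------------------------------------
# Per-region change and mixed-effects trend
# ---------------------------------------------------------------------------

def per_region_change(panel: pd.DataFrame, value_col: str = "score") -> pd.DataFrame:
    """OLS slope of score on year per region (points per year)."""
    rows = []
    for rid, grp in panel.groupby("region_id"):
        grp = grp.dropna(subset=[value_col])
        if grp["year"].nunique() < 2:
            logger.warning("region %s has a single score year; dropped from change analysis", rid)
            continue
        slope = np.polyfit(grp["year"].to_numpy(dtype=float), grp[value_col].to_numpy(dtype=float), 1)[0]
        rows.append({"region_id": rid, "slope": float(slope)})
    return pd.DataFrame(rows, columns=["region_id", "slope"])


@dataclass
class MixedTrendResult:
    fixed_slope: float
    ci_low: float
    ci_high: float
    random_intercept_sd: float
    residual_sd: float
    mean_slope_unweighted: float
    mean_slope_weighted: float | None
    n_regions: int
    n_obs: int

    def covers(self, true_slope: float) -> bool:
        return self.ci_low <= true_slope <= self.ci_high


def mixed_model_trend(
    panel: pd.DataFrame,
    regions: pd.DataFrame | None = None,
    value_col: str = "score",
) -> MixedTrendResult:
    """Random-intercept mixed model score ~ year, region as random effect.

    Fit by REML; returns the fixed-effect slope with its 95% CI and the
    random-intercept SD, alongside the unweighted and EEZ-area-weighted means
    of per-region OLS slopes (the weighting applies only to the slope
    summaries, not to the REML fit).
    """
    df = panel.dropna(subset=[value_col]).copy()
    if df["year"].nunique() < 3 or df["region_id"].nunique() < 5:
        raise ValueError("mixed model needs >= 3 years and >= 5 regions")
    year_c = df["year"] - df["year"].mean()  # centering stabilises the optimiser
    exog = sm.add_constant(year_c.to_numpy(dtype=float))
    model = sm.MixedLM(df[value_col].to_numpy(dtype=float), exog, groups=df["region_id"].to_numpy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = None
        errors = []
        for method in ("lbfgs", "powell"):  # powell rescues boundary fits (RE var ~ 0)
            try:
                res = model.fit(reml=True, method=method)
                break
            except Exception as exc:
                errors.append(f"{method}: {exc}")
        if res is None:
            raise EstimationError(f"mixed model failed to converge: {errors}")
    if not np.isfinite(res.fe_params).all():
        raise EstimationError(f"mixed model non-convergence: {res.summary()}")
    slope = float(res.fe_params[1])
    se = float(res.bse_fe[1])
    z = stats.norm.ppf(0.975)
    re_sd = float(np.sqrt(np.asarray(res.cov_re)[0, 0]))
    resid_sd = float(np.sqrt(res.scale))
    slopes = per_region_change(df, value_col=value_col)
    weighted = None
    if regions is not None:
        area = regions.set_index("region_id")["eez_area_km2"]
        w = slopes["region_id"].map(area)
        ok = w.notna()
        if ok.any():
            weighted = float(np.average(slopes.loc[ok, "slope"], weights=w[ok]))
    return MixedTrendResult(
        fixed_slope=slope,
        ci_low=slope - z * se,
        ci_high=slope + z * se,
        random_intercept_sd=re_sd,
        residual_sd=resid_sd,
        mean_slope_unweighted=float(slopes["slope"].mean()),
        mean_slope_weighted=weighted,
        n_regions=int(df["region_id"].nunique()),
        n_obs=len(df),
    )


# ---------------------------------------------------------------------------
# Predictive validity of the likely-future-status model
# ---------------------------------------------------------------------------

def _ols_row(x: pd.Series, y: pd.Series) -> dict | None:
    pair = pd.concat([x.rename("x"), y.rename("y")], axis=1).dropna()
    if len(pair) < 3:
        return None
    if pair["x"].nunique() < 2:
        return None
    fit = stats.linregress(pair["x"], pair["y"])
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r2": float(fit.rvalue**2),
        "p_value": float(fit.pvalue),
        "n": len(pair),
    }


@dataclass
class ValidityReport:
    """Regression table plus identity-line bias summaries by score tercile."""

    regressions: pd.DataFrame  # goal_id, comparison, slope, intercept, r2, p_value, n
    tercile_bias: pd.DataFrame  # goal_id, tercile, mean_bias (predicted - observed), n


_COMPONENT_COMPARISONS = (
    ("trend", "trend"),
    ("pressure", "pressures"),
    ("resilience", "resilience"),
    ("resilience_minus_pressure", None),
)


def predictive_validity(
    panel_first: pd.DataFrame, panel_last: pd.DataFrame
) -> ValidityReport:
    """Evaluate which model components predict realised future status.

    Four families of OLS comparisons per goal (and the Index): last-year
    score against first-year score; observed status against the first
    assessment's likely future status; observed change in status against the
    predicted change (future − status); and observed change against each
    model component (trend, pressure, resilience, resilience − pressure).
    Comparisons with fewer than 3 paired regions are skipped and flagged.
    """
    reg_rows, bias_rows = [], []
    goals = sorted(set(panel_first["goal_id"]) & set(panel_last["goal_id"]))
    for goal in goals:
        a = panel_first[panel_first["goal_id"] == goal].set_index("region_id")
        b = panel_last[panel_last["goal_id"] == goal].set_index("region_id")
        comparisons: dict[str, tuple[pd.Series, pd.Series]] = {
            "score_vs_score": (a["score"], b["score"]),
        }
        if goal != "Index":
            observed_change = b["status"] - a["status"]
            comparisons["predicted_vs_realized_status"] = (a["future"], b["status"])
            comparisons["predicted_vs_observed_change"] = (
                a["future"] - a["status"], observed_change,
            )
            for name, col in _COMPONENT_COMPARISONS:
                x = (
                    a["resilience"] - a["pressures"]
                    if col is None
                    else a[col]
                )
                comparisons[f"change_vs_{name}"] = (x, observed_change)
        for comp, (x, y) in comparisons.items():
            row = _ols_row(x, y)
            if row is None:
                logger.warning("%s/%s: < 3 paired regions or degenerate x; skipped", goal, comp)
                continue
            reg_rows.append({"goal_id": goal, "comparison": comp, **row})
        # over/under-prediction along the identity line, by first-year tercile
        if goal != "Index":
            pair = pd.concat(
                [a["future"].rename("pred"), b["status"].rename("obs"), a["score"].rename("s0")],
                axis=1,
            ).dropna()
            if len(pair) >= 6:
                try:
                    pair["tercile"] = pd.qcut(pair["s0"], 3, labels=["low", "mid", "high"], duplicates="drop")
                except ValueError:
                    continue
                for terc, grp in pair.groupby("tercile", observed=True):
                    bias_rows.append(
                        {"goal_id": goal, "tercile": str(terc),
                         "mean_bias": float((grp["pred"] - grp["obs"]).mean()), "n": len(grp)}
                    )
    return ValidityReport(
        regressions=pd.DataFrame(reg_rows),
        tercile_bias=pd.DataFrame(bias_rows, columns=["goal_id", "tercile", "mean_bias", "n"]),
    )


# ---------------------------------------------------------------------------
# Rank versus score
# ---------------------------------------------------------------------------

def _rank_desc(scores: pd.Series) -> pd.Series:
    """Descending rank, 1 = best; ties broken by region_id (stable)."""
    df = pd.DataFrame({"score": scores}).reset_index()
    df = df.sort_values(["score", "region_id"], ascending=[False, True], kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.set_index("region_id")["rank"]


def rank_analysis(
    panel: pd.DataFrame, first_year: int, last_year: int
) -> tuple[pd.DataFrame, dict]:
    """Δscore against Δrank between two assessment years.

    Δrank = rank_first − rank_last, so a positive Δrank is an improvement
    (moving toward rank 1).  Regions where score and rank move in opposite
    directions are flagged.  Returns the per-region table and an OLS summary
    of Δrank on Δscore.
    """
    first = panel[panel["year"] == first_year].set_index("region_id")["score"].dropna()
    last = panel[panel["year"] == last_year].set_index("region_id")["score"].dropna()
    common = first.index.intersection(last.index)
    first, last = first.loc[common], last.loc[common]
    r_first, r_last = _rank_desc(first), _rank_desc(last)
    table = pd.DataFrame(
        {
            "region_id": common,
            "score_first": first.to_numpy(),
            "score_last": last.to_numpy(),
            "delta_score": (last - first).to_numpy(),
            "rank_first": r_first.loc[common].to_numpy(),
            "rank_last": r_last.loc[common].to_numpy(),
        }
    )
    table["delta_rank"] = table["rank_first"] - table["rank_last"]
    table["mismatch"] = np.sign(table["delta_score"]) * np.sign(table["delta_rank"]) < 0
    summary = _ols_row(table.set_index("region_id")["delta_score"],
                       table.set_index("region_id")["delta_rank"]) or {}
    return table, summary


# ---------------------------------------------------------------------------
# Goal contributions to Index change
# ---------------------------------------------------------------------------

def change_decomposition(
    goal_panel: pd.DataFrame,
    first_year: int,
    last_year: int,
    cfg: EngineConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Decompose each region's Index change into per-goal contributions.

    contribution_g = w_g / Σw × (score_g,last − score_g,first).  On complete
    panels the contributions sum exactly to the Index change; goals defined
    in only one of the two years force weight renormalisation, and the
    unexplained residual is reported per region with a flag.
    """
    cfg = cfg or EngineConfig()
    top = goal_panel[goal_panel["goal_id"].isin(GOALS)]
    wide_f = top[top["year"] == first_year].pivot(index="region_id", columns="goal_id", values="score")
    wide_l = top[top["year"] == last_year].pivot(index="region_id", columns="goal_id", values="score")
    common = wide_f.index.intersection(wide_l.index)
    wide_f, wide_l = wide_f.reindex(common), wide_l.reindex(common)
    weights = pd.Series(cfg.goal_weights, dtype=float)

    def windex(row: pd.Series) -> float:
        ok = row.dropna().index
        if not len(ok):
            return np.nan
        w = weights.reindex(ok)
        return float(np.average(row[ok], weights=w))

    contrib_rows, summary_rows = [], []
    for rid in common:
        f, l = wide_f.loc[rid], wide_l.loc[rid]
        both = f.dropna().index.intersection(l.dropna().index)
        only_one = (f.dropna().index.symmetric_difference(l.dropna().index))
        w_both = weights.reindex(both)
        wsum = w_both.sum()
        d_index = windex(l) - windex(f)
        for g in both:
            contrib_rows.append(
                {"region_id": rid, "goal_id": g,
                 "contribution": float(w_both[g] / wsum * (l[g] - f[g])),
                 "flagged": g in only_one}
            )
        explained = sum(
            w_both[g] / wsum * (l[g] - f[g]) for g in both
        ) if len(both) else np.nan
        summary_rows.append(
            {"region_id": rid, "delta_index": d_index,
             "explained": float(explained) if len(both) else np.nan,
             "residual": float(d_index - explained) if len(both) else np.nan,
             "renormalized": len(only_one) > 0}
        )
    return (
        pd.DataFrame(contrib_rows, columns=["region_id", "goal_id", "contribution", "flagged"]),
        pd.DataFrame(summary_rows),
    )
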