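"""Site-level standardization, continental mixed models, site trends,
trend-on-trend association models, bootstrap, and index correlations.

The stage mirrors how long-running count schemes are analysed:

1. every metric is z-scored within each site (subtract the site mean
   over years, divide by the site standard deviation), absorbing
   between-site differences in detectability, protocol and baseline
   community;
2. continental change is estimated with a Gaussian linear mixed model
   of the standardized values on latitude, longitude and year, with
   crossed random intercepts for site, year, stratum (state/country)
   and, where present, route; fixed terms are judged by likelihood-
   ratio tests between nested ML fits;
3. each site additionally gets an independent OLS trend (slope of its
   standardized series on year);
4. site-level index trends are regressed on site-level trends in total
   individuals and species richness (stratum random intercept), with a
   parametric bootstrap propagating the site-trend standard errors;
5. the four indices' site trends are compared pairwise by Pearson
   correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from ._lmm import LMMFit, fit_lmm, indicator_matrix, lrt
from ._seeds import child_rng
from .errors import FitError, InclusionError, ParameterError

INDEX_METRICS = ("adi", "aei", "bi", "h")


# ---------------------------------------------------------------------------
# standardization and site trends


def standardize_panel(
    panel: pd.DataFrame,
    metrics: tuple[str, ...] = INDEX_METRICS,
    min_years: int = 3,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Z-score each metric within each site.

    Sites with fewer than ``min_years`` surveyed years, or with zero
    variance in any metric (a constant series carries no trend
    information), are dropped and listed in the report.
    """
    report: dict[str, list[str]] = {"too_few_years": [], "zero_variance": []}
    keep = []
    for site, grp in panel.groupby("site_id", sort=True):
        if grp["year"].nunique() < min_years:
            report["too_few_years"].append(str(site))
            continue
        sds = grp[list(metrics)].std(ddof=1)
        if (sds <= 0).any() or sds.isna().any():
            report["zero_variance"].append(str(site))
            continue
        keep.append(site)
    if report["zero_variance"]:
        warnings.warn(
            f"{len(report['zero_variance'])} site(s) dropped for zero variance: "
            f"{report['zero_variance'][:5]}...",
            stacklevel=2,
        )
    out = panel[panel["site_id"].isin(keep)].copy()
    for m in metrics:
        grouped = out.groupby("site_id")[m]
        out[m] = (out[m] - grouped.transform("mean")) / grouped.transform(lambda s: s.std(ddof=1))
    return out.reset_index(drop=True), report


@dataclass(frozen=True)
class SiteTrend:
    """Least-squares rate of change of one metric at one site."""

    site_id: str
    metric: str
    slope: float
    intercept: float
    se_slope: float
    n_years: int


def fit_site_trend(
    years: np.ndarray,
    values: np.ndarray,
    site_id: str = "",
    metric: str = "",
) -> SiteTrend:
    """OLS slope of a site's standardized series on year.

    Requires at least three surveyed years. The slope standard error is
    ``sqrt(RSS / (n-2) / sum((year - mean)^2))``; an exact fit yields 0.
    """
    x = np.asarray(years, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InclusionError("site trends need >= 3 surveyed years")
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0.0:
        raise InclusionError("years are all identical")
    slope = float(xc @ (y - y.mean()) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    rss = float(resid @ resid)
    se = float(np.sqrt(max(rss, 0.0) / (x.size - 2) / sxx))
    return SiteTrend(site_id, metric, slope, intercept, se, int(x.size))


def site_trend_table(std_panel: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Per-site trends of one standardized metric, with site metadata."""
    rows = []
    meta_cols = [c for c in ("stratum", "route", "latitude", "longitude") if c in std_panel.columns]
    for site, grp in std_panel.groupby("site_id", sort=True):
        tr = fit_site_trend(grp["year"].to_numpy(), grp[metric].to_numpy(), str(site), metric)
        row = {
            "site_id": tr.site_id,
            "metric": metric,
            "slope": tr.slope,
            "se": tr.se_slope,
            "n_years": tr.n_years,
        }
        for c in meta_cols:
            row[c] = grp[c].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)


def community_metric_panel(counts: pd.DataFrame) -> pd.DataFrame:
    """Total individuals and species richness per site-year."""
    agg = counts.groupby(["site_id", "year"], as_index=False).agg(
        individuals=("count", "sum"), species=("species_code", "nunique")
    )
    meta_cols = [c for c in ("latitude", "longitude", "stratum", "route") if c in counts.columns]
    if meta_cols:
        meta = counts.groupby("site_id", as_index=False)[meta_cols].first()
        agg = agg.merge(meta, on="site_id", how="left")
    return agg


# ---------------------------------------------------------------------------
# mixed models


@dataclass
class MixedModelFit:
    """A fitted mixed model plus its per-term likelihood-ratio tests."""

    fixed: pd.DataFrame  # term, estimate, se
    lrt: pd.DataFrame  # term, chi2, df, p
    vc: dict[str, float]
    sigma2: float
    loglik: float
    converged: bool
    year_mode: str | None = None
    year_predictions: pd.DataFrame | None = None
    interaction_retained: bool | None = None
    _fit: LMMFit | None = field(default=None, repr=False)

    def coef(self, term: str) -> float:
        return float(self.fixed.set_index("term").loc[term, "estimate"])

    def pvalue(self, term: str) -> float:
        return float(self.lrt.set_index("term").loc[term, "p"])


def _random_designs(df: pd.DataFrame, want_route: bool = True):
    Zs, names = [], []
    for col in ("site_id", "year", "stratum", "route"):
        if col == "route" and not want_route:
            continue
        if col not in df.columns:
            continue
        vals = df[col].astype(str)
        if col == "route" and (vals == "").all():
            continue
        if vals.nunique() < 2:
            warnings.warn(f"random grouping {col!r} has < 2 levels; dropped", stacklevel=3)
            continue
        Zs.append(indicator_matrix(vals.to_numpy()))
        names.append("year_re" if col == "year" else col)
    return Zs, names


def fit_continental_model(
    std_panel: pd.DataFrame,
    metric: str,
    year_mode: str = "continuous",
    geo_year_interactions: bool = False,
    include_route: bool = True,
    lrt_terms: list[str] | None = None,
) -> MixedModelFit:
    """Large-scale change in one standardized index.

    Fixed effects: latitude, longitude and year (continuous by default,
    categorical for per-year predictions); covariates are centred for
    conditioning, which leaves slopes and interaction terms unchanged.
    Random intercepts: site and year crossed, plus stratum
    (state/country analogue) and route where route labels exist. Each
    fixed term is judged by an ML likelihood-ratio test against the
    model without it.
    """
    if year_mode not in ("continuous", "categorical"):
        raise ParameterError("year_mode must be 'continuous' or 'categorical'")
    if std_panel["year"].nunique() < 3:
        raise ParameterError("need >= 3 years")
    df = std_panel
    y = df[metric].to_numpy(float)
    lat = df["latitude"].to_numpy(float)
    lon = df["longitude"].to_numpy(float)
    yr = df["year"].to_numpy(float)
    latc, lonc, yrc = lat - lat.mean(), lon - lon.mean(), yr - yr.mean()

    cols: dict[str, np.ndarray] = {"intercept": np.ones_like(y), "latitude": latc, "longitude": lonc}
    term_cols: dict[str, list[str]] = {"latitude": ["latitude"], "longitude": ["longitude"]}
    if year_mode == "continuous":
        cols["year"] = yrc
        term_cols["year"] = ["year"]
    else:
        years = np.sort(df["year"].unique())
        yd = []
        for yv in years[1:]:
            nm = f"year_{int(yv)}"
            cols[nm] = (yr == yv).astype(float)
            yd.append(nm)
        term_cols["year"] = yd
    if geo_year_interactions:
        if year_mode != "continuous":
            raise ParameterError("geographic interactions need continuous year")
        cols["latitude:year"] = latc * yrc
        cols["longitude:year"] = lonc * yrc
        term_cols["latitude:year"] = ["latitude:year"]
        term_cols["longitude:year"] = ["longitude:year"]

    names = list(cols)
    X = np.column_stack([cols[c] for c in names])
    Zs, vc_names = _random_designs(df, want_route=include_route)
    full = fit_lmm(y, X, Zs, fixed_names=names, vc_names=vc_names)
    if not full.converged:
        raise FitError(f"continental model for {metric!r} did not converge")

    lrt_rows = []
    for term, tcols in term_cols.items():
        if lrt_terms is not None and term not in lrt_terms:
            continue
        keep = [c for c in names if c not in tcols]
        Xr = np.column_stack([cols[c] for c in keep])
        reduced = fit_lmm(y, Xr, Zs, fixed_names=keep, vc_names=vc_names)
        chi2, dfree, p = lrt(full, reduced)
        lrt_rows.append({"term": term, "chi2": chi2, "df": dfree, "p": p})

    year_pred = None
    if year_mode == "categorical":
        years = np.sort(df["year"].unique())
        base = full.coef("intercept")
        preds = [base]
        for yv in years[1:]:
            preds.append(base + full.coef(f"year_{int(yv)}"))
        year_pred = pd.DataFrame({"year": years.astype(int), "predicted": preds})

    fixed = pd.DataFrame({"term": names, "estimate": full.beta, "se": full.se})
    return MixedModelFit(
        fixed=fixed,
        lrt=pd.DataFrame(lrt_rows),
        vc=full.vc,
        sigma2=full.sigma2,
        loglik=full.loglik,
        converged=full.converged,
        year_mode=year_mode,
        year_predictions=year_pred,
        _fit=full,
    )


def _assoc_design(df: pd.DataFrame, with_interaction: bool):
    ti = df["trend_individuals"].to_numpy(float)
    ts = df["trend_species"].to_numpy(float)
    cols = [np.ones_like(ti), ti, ts]
    names = ["intercept", "individuals", "species"]
    if with_interaction:
        cols.append(ti * ts)
        names.append("individuals:species")
    return np.column_stack(cols), names


def _assoc_fit(df: pd.DataFrame, with_interaction: bool):
    X, names = _assoc_design(df, with_interaction)
    y = df["trend_index"].to_numpy(float)
    if "stratum" in df.columns and df["stratum"].astype(str).nunique() >= 2:
        Zs = [indicator_matrix(df["stratum"].astype(str).to_numpy())]
        vc_names = ["stratum"]
    else:
        warnings.warn("fewer than 2 strata: association model falls back to a fixed intercept")
        Zs, vc_names = [], []
    return fit_lmm(y, X, Zs, fixed_names=names, vc_names=vc_names), Zs, vc_names


def _merge_trends(
    index_trends: pd.DataFrame,
    indiv_trends: pd.DataFrame,
    species_trends: pd.DataFrame,
) -> pd.DataFrame:
    def _sub(t: pd.DataFrame, slope: str, se: str) -> pd.DataFrame:
        cols = {"site_id": t["site_id"], slope: t["slope"], se: t["se"]}
        if "stratum" in t.columns:
            cols["stratum"] = t["stratum"]
        return pd.DataFrame(cols)

    df = _sub(index_trends, "trend_index", "se_index")
    df = df.merge(
        _sub(indiv_trends, "trend_individuals", "se_individuals").drop(columns="stratum", errors="ignore"),
        on="site_id",
    )
    df = df.merge(
        _sub(species_trends, "trend_species", "se_species").drop(columns="stratum", errors="ignore"),
        on="site_id",
    )
    if df.empty:
        raise ParameterError("no common sites between trend tables")
    return df


def fit_trend_association(
    index_trends: pd.DataFrame,
    indiv_trends: pd.DataFrame,
    species_trends: pd.DataFrame,
    alpha: float = 0.05,
) -> MixedModelFit:
    """Site-level index trends on community-trend predictors.

    ``trend_index ~ trend_individuals + trend_species (+ interaction)``
    with a stratum random intercept. The interaction is removed and the
    model refitted when its LRT p-value is >= ``alpha``. Inputs are
    trend tables from :func:`site_trend_table` aligned on ``site_id``.
    """
    df = _merge_trends(index_trends, indiv_trends, species_trends)
    full, Zs, vc_names = _assoc_fit(df, with_interaction=True)
    reduced, _, _ = _assoc_fit(df, with_interaction=False)
    chi2_int, df_int, p_int = lrt(full, reduced)
    retained = p_int < alpha
    final = full if retained else reduced

    lrt_rows = []
    X_final, names_final = _assoc_design(df, retained)
    y = df["trend_index"].to_numpy(float)
    for term in names_final:
        if term == "intercept":
            continue
        keep_idx = [i for i, nm in enumerate(names_final) if nm != term]
        sub = fit_lmm(y, X_final[:, keep_idx], Zs, [names_final[i] for i in keep_idx], vc_names)
        chi2, dfree, p = lrt(final, sub)
        lrt_rows.append({"term": term, "chi2": chi2, "df": dfree, "p": p})

    fixed = pd.DataFrame({"term": names_final, "estimate": final.beta, "se": final.se})
    return MixedModelFit(
        fixed=fixed,
        lrt=pd.DataFrame(lrt_rows),
        vc=final.vc,
        sigma2=final.sigma2,
        loglik=final.loglik,
        converged=final.converged,
        interaction_retained=retained,
        _fit=final,
    )


def bootstrap_significance(
    index_trends: pd.DataFrame,
    indiv_trends: pd.DataFrame,
    species_trends: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Proportion of bootstrap replicates in which each term is significant.

    Each replicate redraws every site-level trend (response and both
    predictors) from Normal(trend, SE), refits the association model
    with the final model's term structure, and records whether each
    fixed term's LRT p-value falls below ``alpha``.
    """
    if (index_trends["se"] < 0).any() or (indiv_trends["se"] < 0).any() or (
        species_trends["se"] < 0
    ).any():
        raise ParameterError("standard errors must be >= 0")
    base = fit_trend_association(index_trends, indiv_trends, species_trends, alpha=alpha)
    retained = bool(base.interaction_retained)
    df = _merge_trends(index_trends, indiv_trends, species_trends)
    terms = [t for t in base.fixed["term"] if t != "intercept"]
    hits = {t: 0 for t in terms}
    y0 = df["trend_index"].to_numpy(float)
    ti0 = df["trend_individuals"].to_numpy(float)
    ts0 = df["trend_species"].to_numpy(float)
    se_y = df["se_index"].to_numpy(float)
    se_i = df["se_individuals"].to_numpy(float)
    se_s = df["se_species"].to_numpy(float)
    for b in range(n_boot):
        rng = child_rng(seed, "bootstrap", b)
        rep = df.copy()
        rep["trend_index"] = y0 + se_y * rng.standard_normal(y0.size)
        rep["trend_individuals"] = ti0 + se_i * rng.standard_normal(y0.size)
        rep["trend_species"] = ts0 + se_s * rng.standard_normal(y0.size)
        fit, Zs, vc_names = _assoc_fit(rep, with_interaction=retained)
        X, names = _assoc_design(rep, retained)
        yb = rep["trend_index"].to_numpy(float)
        for term in terms:
            keep_idx = [i for i, nm in enumerate(names) if nm != term]
            sub = fit_lmm(yb, X[:, keep_idx], Zs, [names[i] for i in keep_idx], vc_names)
            _, _, p = lrt(fit, sub)
            if p < alpha:
                hits[term] += 1
    return {t: hits[t] / n_boot for t in terms}


def correlate_index_trends(
    trend_tables: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """Pearson correlation of site trends for every index pair.

    ``trend_tables`` maps metric name to its :func:`site_trend_table`
    output; the four default indices yield C(4,2) = 6 rows. Pairs with
    fewer than three common sites or a zero-variance vector get ``NaN``.
    """
    metrics = list(trend_tables)
    rows = []
    for a, b in combinations(metrics, 2):
        merged = trend_tables[a][["site_id", "slope"]].merge(
            trend_tables[b][["site_id", "slope"]], on="site_id", suffixes=("_a", "_b")
        )
        va = merged["slope_a"].to_numpy(float)
        vb = merged["slope_b"].to_numpy(float)
        if len(merged) < 3 or va.std() == 0 or vb.std() == 0:
            r = float("nan")
        else:
            r = float(stats.pearsonr(va, vb).statistic)
        rows.append({"metric_a": a, "metric_b": b, "r": r, "n_sites": len(merged)})
    return pd.DataFrame(rows)
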