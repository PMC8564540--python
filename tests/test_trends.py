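"""Standardization, site trends, mixed models, bootstrap, correlations."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from resound import (
    InclusionError,
    bootstrap_significance,
    community_metric_panel,
    correlate_index_trends,
    fit_continental_model,
    fit_site_trend,
    fit_trend_association,
    site_trend_table,
    standardize_panel,
)
from resound._lmm import fit_lmm, indicator_matrix


def _panel(nsite=20, nyr=8, seed=0, year_effect=0.0, noise=0.5, site_sd=0.4, yr_sd=0.15):
    """Synthetic raw index panel with known structure."""
    rng = np.random.default_rng(seed)
    site = np.repeat(np.arange(nsite), nyr)
    year = np.tile(np.arange(nyr), nsite)
    base = (
        rng.normal(0, site_sd, nsite)[site]
        + rng.normal(0, yr_sd, nyr)[year]
        + year_effect * year
        + rng.normal(0, noise, site.size)
    )
    df = pd.DataFrame(
        {
            "site_id": [f"s{i:03d}" for i in site],
            "year": 2000 + year,
            "adi": 2.0 + base,
            "aei": 0.5 - 0.3 * base,
            "bi": 100.0 + 10 * base,
            "h": 0.6 + 0.1 * base,
            "latitude": np.round(35 + (site % 10) * 2.0, 3),
            "longitude": np.round(-5 + (site // 10) * 3.0, 3),
            "stratum": [f"ST{i % 3}" for i in site],
            "route": ["" for _ in site],
        }
    )
    return df


class TestStandardizePanel:
    def test_closed_form_z(self):
        df = pd.DataFrame(
            {"site_id": ["a"] * 3, "year": [1, 2, 3], "adi": [1.0, 2.0, 3.0],
             "aei": [3.0, 2.0, 1.0], "bi": [1.0, 2.0, 4.0], "h": [0.1, 0.2, 0.4]}
        )
        std, report = standardize_panel(df)
        assert np.allclose(std["adi"], [-1.0, 0.0, 1.0])
        assert np.allclose(std["aei"], [1.0, 0.0, -1.0])
        assert not report["zero_variance"]

    def test_per_site_mean_zero_sd_one(self):
        std, _ = standardize_panel(_panel())
        for _, grp in std.groupby("site_id"):
            for m in ("adi", "aei", "bi", "h"):
                assert grp[m].mean() == pytest.approx(0.0, abs=1e-9)
                assert grp[m].std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    @given(a=st.floats(0.1, 50.0), b=st.floats(-100.0, 100.0))
    def test_affine_invariance(self, a, b):
        df = _panel(nsite=4, nyr=5)
        std1, _ = standardize_panel(df)
        df2 = df.copy()
        df2["adi"] = a * df2["adi"] + b
        std2, _ = standardize_panel(df2)
        assert np.allclose(std1["adi"], std2["adi"], atol=1e-9)

    def test_constant_series_dropped_and_reported(self):
        df = _panel(nsite=3, nyr=4)
        df.loc[df["site_id"] == "s000", "bi"] = 7.0
        with pytest.warns(UserWarning, match="zero variance"):
            std, report = standardize_panel(df)
        assert report["zero_variance"] == ["s000"]
        assert "s000" not in set(std["site_id"])

    def test_too_few_years_dropped(self):
        df = _panel(nsite=3, nyr=4)
        df = df[~((df["site_id"] == "s001") & (df["year"] > 2001))]
        std, report = standardize_panel(df)
        assert report["too_few_years"] == ["s001"]


class TestSiteTrend:
    def test_exact_unit_slope(self):
        tr = fit_site_trend(np.array([1, 2, 3]), np.array([1.0, 2.0, 3.0]))
        assert tr.slope == pytest.approx(1.0, abs=1e-12)
        assert tr.se_slope == pytest.approx(0.0, abs=1e-9)

    def test_matches_normal_equations_oracle(self):
        years = np.arange(1, 6, dtype=float)
        z = np.array([-1.2, -0.4, 0.1, 0.6, 0.9])
        # oracle: solve the 2x2 normal equations directly
        A = np.array([[len(years), years.sum()], [years.sum(), (years**2).sum()]])
        b = np.array([z.sum(), (years * z).sum()])
        _, slope_ref = np.linalg.solve(A, b)
        tr = fit_site_trend(years, z)
        assert slope_ref == pytest.approx(0.52, abs=1e-12)
        assert tr.slope == pytest.approx(slope_ref, abs=1e-10)

    def test_random_series_match_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            n = int(rng.integers(3, 15))
            x = np.sort(rng.choice(np.arange(1990, 2020), n, replace=False)).astype(float)
            y = rng.normal(size=n)
            A = np.array([[n, x.sum()], [x.sum(), (x**2).sum()]])
            b = np.array([y.sum(), (x * y).sum()])
            _, slope_ref = np.linalg.solve(A, b)
            assert fit_site_trend(x, y).slope == pytest.approx(slope_ref, abs=1e-10)

    def test_two_points_rejected(self):
        with pytest.raises(InclusionError):
            fit_site_trend(np.array([1, 2]), np.array([0.0, 1.0]))


class TestMixedModelCore:
    def test_matches_lme4_on_fixture(self, tmp_path):
        rng = np.random.default_rng(3)
        nsite, nyr = 20, 8
        site = np.repeat(np.arange(nsite), nyr)
        year = np.tile(np.arange(nyr), nsite)
        lat = rng.uniform(35, 60, nsite)[site]
        lon = rng.uniform(-10, 30, nsite)[site]
        y = (0.5 - 0.08 * year + 0.01 * lat + rng.normal(0, 0.4, nsite)[site]
             + rng.normal(0, 0.3, nyr)[year] + rng.normal(0, 0.6, site.size))
        df = pd.DataFrame({"y": y, "site": site, "year": year, "lat": lat, "lon": lon,
                           "stratum": site % 3})
        df.to_csv(tmp_path / "fixture.csv", index=False)
        X = np.column_stack([np.ones(site.size), lat, lon, year])
        fit = fit_lmm(
            y, X, [indicator_matrix(site), indicator_matrix(year), indicator_matrix(site % 3)],
            fixed_names=["intercept", "lat", "lon", "year"],
        )
        rscript = tmp_path / "check.R"
        rscript.write_text(
            'd <- read.csv("%s")\n'
            "suppressMessages(library(lme4))\n"
            "m <- lmer(y ~ lat + lon + year + (1|site) + (1|as.factor(year)) + (1|stratum),"
            " data=d, REML=FALSE)\n"
            'cat(fixef(m), -2*as.numeric(logLik(m)), sep="\\n")\n' % (tmp_path / "fixture.csv")
        )
        out = subprocess.run(
            ["Rscript", str(rscript)], capture_output=True, text=True, check=True
        )
        vals = [float(v) for v in out.stdout.strip().splitlines()]
        assert np.allclose(fit.beta, vals[:4], atol=1e-4)
        assert fit.m2ll == pytest.approx(vals[4], abs=1e-3)

    def test_matches_statsmodels_single_grouping(self):
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(4)
        n = 300
        g = rng.integers(0, 6, n)
        x = rng.normal(size=n)
        y = 1.0 + 0.5 * x + rng.normal(0, 0.7, 6)[g] + rng.normal(0, 1.0, n)
        df = pd.DataFrame({"y": y, "x": x, "g": g})
        ours = fit_lmm(y, np.column_stack([np.ones(n), x]), [indicator_matrix(g)],
                       fixed_names=["intercept", "x"])
        theirs = smf.mixedlm("y ~ x", df, groups=df["g"]).fit(reml=False)
        assert ours.coef("x") == pytest.approx(theirs.params["x"], abs=1e-4)
        assert ours.loglik == pytest.approx(theirs.llf, abs=1e-3)


class TestContinentalModel:
    def test_recovers_known_year_effect(self):
        df = _panel(nsite=100, nyr=10, seed=1, year_effect=-0.05, noise=0.5,
                    site_sd=0.0, yr_sd=0.0)
        # analyse the raw panel (already on a common scale here)
        fit = fit_continental_model(df, "adi")
        est = fit.coef("year")
        se = float(fit.fixed.set_index("term").loc["year", "se"])
        assert est == pytest.approx(-0.05, abs=2 * se)
        assert fit.pvalue("year") < 0.05

    def test_categorical_mode_gives_per_year_predictions(self):
        df = _panel(nsite=30, nyr=10, seed=2)
        fit = fit_continental_model(df, "adi", year_mode="categorical")
        assert fit.year_predictions is not None
        assert len(fit.year_predictions) == 10

    def test_geo_interaction_terms_present(self):
        df = _panel(nsite=30, nyr=6, seed=3)
        fit = fit_continental_model(df, "adi", geo_year_interactions=True)
        assert {"latitude:year", "longitude:year"} <= set(fit.lrt["term"])

    def test_route_grouping_only_when_labelled(self):
        df = _panel(nsite=20, nyr=5, seed=4)
        fit = fit_continental_model(df, "adi")
        assert "route" not in fit.vc
        df2 = df.copy()
        df2["route"] = "r" + (pd.factorize(df2["site_id"])[0] // 4).astype(str)
        fit2 = fit_continental_model(df2, "adi")
        assert "route" in fit2.vc


class TestTrendAssociation:
    def _tables(self, nsite=80, seed=0, b_ind=0.5, b_sp=0.7, noise=0.02):
        rng = np.random.default_rng(seed)
        ti = rng.normal(0, 0.1, nsite)
        ts = rng.normal(0, 0.1, nsite)
        yy = b_ind * ti + b_sp * ts + rng.normal(0, noise, nsite)
        ids = [f"s{i:03d}" for i in range(nsite)]
        strat = [f"ST{i % 3}" for i in range(nsite)]

        def tab(slope, se=0.01):
            return pd.DataFrame({"site_id": ids, "slope": slope,
                                 "se": np.full(nsite, se), "stratum": strat})

        return tab(yy), tab(ti), tab(ts)

    def test_recovers_positive_coefficients(self):
        idx, ti, ts = self._tables()
        fit = fit_trend_association(idx, ti, ts)
        assert fit.coef("individuals") == pytest.approx(0.5, abs=0.05)
        assert fit.coef("species") == pytest.approx(0.7, abs=0.05)
        assert fit.pvalue("individuals") < 0.001
        assert fit.pvalue("species") < 0.001

    def test_identity_response_gives_unit_species_coefficient(self):
        idx, ti, ts = self._tables()
        idx["slope"] = ts["slope"]
        fit = fit_trend_association(idx, ti, ts)
        assert fit.coef("species") == pytest.approx(1.0, abs=1e-6)
        assert abs(fit.coef("individuals")) < 1e-6

    def test_nonsignificant_interaction_removed(self):
        idx, ti, ts = self._tables(noise=0.05)
        fit = fit_trend_association(idx, ti, ts)
        assert not fit.interaction_retained
        assert "individuals:species" not in set(fit.fixed["term"])


class TestBootstrap:
    def test_zero_se_degenerate_matches_base_model(self):
        rng = np.random.default_rng(1)
        nsite = 60
        ti = rng.normal(0, 0.1, nsite)
        ts = rng.normal(0, 0.1, nsite)
        yy = 0.6 * ti + 0.8 * ts + rng.normal(0, 0.02, nsite)
        ids = [f"s{i}" for i in range(nsite)]
        strat = [f"ST{i % 2}" for i in range(nsite)]

        def tab(v):
            return pd.DataFrame({"site_id": ids, "slope": v, "se": 0.0, "stratum": strat})

        props = bootstrap_significance(tab(yy), tab(ti), tab(ts), n_boot=20, seed=0)
        base = fit_trend_association(tab(yy), tab(ti), tab(ts))
        for term, prop in props.items():
            assert prop in (0.0, 1.0)
            assert prop == float(base.pvalue(term) < 0.05)

    def test_huge_ses_drown_true_effects(self):
        rng = np.random.default_rng(2)
        nsite = 50
        ti = rng.normal(0, 0.1, nsite)
        ts = rng.normal(0, 0.1, nsite)
        yy = 0.6 * ti + 0.8 * ts + rng.normal(0, 0.02, nsite)
        ids = [f"s{i}" for i in range(nsite)]
        strat = [f"ST{i % 2}" for i in range(nsite)]

        def tab(v, se):
            return pd.DataFrame({"site_id": ids, "slope": v, "se": se, "stratum": strat})

        big = 100 * np.abs(yy).mean()
        props = bootstrap_significance(tab(yy, big), tab(ti, big), tab(ts, big),
                                       n_boot=40, seed=3)
        assert all(p < 0.5 for p in props.values())

    def test_deterministic_given_seed(self):
        idx, ti, ts = TestTrendAssociation()._tables(nsite=40, seed=5)
        p1 = bootstrap_significance(idx, ti, ts, n_boot=10, seed=9)
        p2 = bootstrap_significance(idx, ti, ts, n_boot=10, seed=9)
        assert p1 == p2


class TestCorrelations:
    def _tab(self, slopes):
        return pd.DataFrame({"site_id": [f"s{i}" for i in range(len(slopes))],
                             "slope": slopes, "se": 0.01})

    def test_six_pairs_and_sign_structure(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=30)
        tables = {"adi": self._tab(base), "aei": self._tab(-base),
                  "bi": self._tab(base * 2 + 1), "h": self._tab(base)}
        out = correlate_index_trends(tables)
        assert len(out) == 6
        r = out.set_index(["metric_a", "metric_b"])["r"]
        assert r[("adi", "h")] == pytest.approx(1.0, abs=1e-12)
        assert r[("adi", "aei")] == pytest.approx(-1.0, abs=1e-12)

    def test_zero_variance_reported_missing(self):
        tables = {"adi": self._tab(np.zeros(10)), "aei": self._tab(np.arange(10.0)),
                  "bi": self._tab(np.arange(10.0)), "h": self._tab(np.arange(10.0))}
        r = correlate_index_trends(tables).set_index(["metric_a", "metric_b"])["r"]
        assert np.isnan(r.loc[("adi", "aei")])
        assert r.loc[("aei", "bi")] == pytest.approx(1.0)


class TestCommunityMetrics:
    def test_totals_and_richness(self):
        counts = pd.DataFrame({
            "site_id": ["a", "a", "a", "b"], "year": [1, 1, 2, 1],
            "species_code": ["x", "y", "x", "x"], "count": [2, 3, 4, 5],
            "latitude": [1.0] * 4, "longitude": [2.0] * 4,
            "stratum": ["s"] * 4, "route": [""] * 4,
        })
        panel = community_metric_panel(counts)
        row = panel[(panel["site_id"] == "a") & (panel["year"] == 1)].iloc[0]
        assert row["individuals"] == 5 and row["species"] == 2

    def test_site_trend_table_carries_metadata(self):
        std, _ = standardize_panel(_panel(nsite=5, nyr=6))
        tab = site_trend_table(std, "adi")
        assert {"site_id", "slope", "se", "n_years", "stratum"} <= set(tab.columns)
        assert len(tab) == 5
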