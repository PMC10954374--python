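"""Additive-model engine: shrinkage selection, calibration, the model
suite, the metabolic-theory predictor, and correlations.

One test cross-checks effective degrees of freedom against R's mgcv
(REML + extra shrinkage penalty) on shared data, as an independent
implementation of the same estimator class.
"""

import shutil
import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from diatombiogeo import gam
from diatombiogeo.gam import (
    ModelSpec,
    correlation_matrix,
    fit_additive,
    fit_gam,
    latitude_richness_gam,
    mark_best_set,
    mte_predictor,
    run_model_suite,
    table_model_specs,
)


class TestFitAdditive:
    def test_constant_response_nothing_to_explain(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x": rng.uniform(0, 1, 50)})
        fit = fit_additive(np.full(50, 7.0), df, ["x"], [])
        assert fit["deviance_explained"] == 0.0
        assert (fit["terms"]["p"] >= 1.0).all()

    def test_linear_signal_shrinks_to_one_edf_and_recovers_slope(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 10, 200)
        y = 3.0 * x + rng.normal(0, 0.3, 200)
        fit = fit_additive(y, pd.DataFrame({"x": x}), ["x"], [])
        edf = fit["terms"].iloc[0]["edf"]
        assert edf == pytest.approx(1.0, abs=0.3)
        slope = np.polyfit(x, fit["fitted"], 1)[0]
        assert slope == pytest.approx(3.0, rel=0.05)

    def test_wiggly_signal_keeps_high_edf(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 1, 300)
        y = 2 * np.sin(6 * np.pi * x) + rng.normal(0, 0.5, 300)
        fit = fit_additive(y, pd.DataFrame({"x": x}), ["x"], [])
        assert fit["terms"].iloc[0]["edf"] > 5
        assert fit["deviance_explained"] > 70

    def test_noise_term_shrinkage_and_nominal_rejection(self):
        # REML with the null-space penalty drops most pure-noise smooths and
        # rejects at roughly the nominal 5% level
        rejections, edfs = 0, []
        for rep in range(40):
            rng = np.random.default_rng(500 + rep)
            x = rng.uniform(0, 1, 300)
            y = rng.normal(0, 1, 300)
            fit = fit_additive(y, pd.DataFrame({"x": x}), ["x"], [])
            edfs.append(fit["terms"].iloc[0]["edf"])
            rejections += fit["terms"].iloc[0]["p"] < 0.05
        assert np.median(edfs) < 0.5
        assert rejections <= 8  # <= 20% of 40 reps (3 SE above nominal 5%)

    def test_unpenalized_superset_never_explains_less(self):
        rng = np.random.default_rng(3)
        n = 150
        df = pd.DataFrame({"a": rng.uniform(0, 1, n), "b": rng.uniform(0, 1, n)})
        y = np.sin(4 * df["a"]) + rng.normal(0, 0.5, n)
        small = fit_additive(y.to_numpy(), df, ["a"], [], penalized=False)
        big = fit_additive(y.to_numpy(), df, ["a", "b"], [], penalized=False)
        assert big["deviance_explained"] >= small["deviance_explained"] - 1e-8

    def test_too_many_coefficients_rejected(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"x": rng.uniform(0, 1, 5)})
        with pytest.raises(ValueError):
            fit_additive(rng.normal(size=5), df, ["x"], [])


class TestMgcvAgreement:
    def test_edf_matches_mgcv_on_shared_data(self, tmp_path):
        rscript = shutil.which("Rscript")
        assert rscript, "Rscript is part of the supported toolchain"
        frames = []
        ours = []
        for rep, kind in enumerate(["noise", "linear", "wiggly"]):
            rng = np.random.default_rng(900 + rep)
            x = rng.uniform(0, 1, 250)
            if kind == "noise":
                y = rng.normal(0, 1, 250)
            elif kind == "linear":
                y = 2 * x + rng.normal(0, 0.5, 250)
            else:
                y = np.sin(5 * np.pi * x) + rng.normal(0, 0.4, 250)
            frames.append(pd.DataFrame({"rep": rep, "x": x, "y": y}))
            fit = fit_additive(y, pd.DataFrame({"x": x}), ["x"], [])
            ours.append(fit["terms"].iloc[0]["edf"])
        csv = tmp_path / "reps.csv"
        pd.concat(frames).to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            'library(mgcv)\n'
            f'd <- read.csv("{csv}")\n'
            'edfs <- sapply(split(d, d$rep), function(s) {\n'
            '  m <- gam(y ~ s(x, bs="ps", k=10), data=s, method="REML", select=TRUE)\n'
            '  sum(m$edf[-1])\n'
            '})\n'
            'cat(edfs, sep="\\n")\n'
        )
        out = subprocess.run([rscript, str(script)], capture_output=True, text=True,
                             check=True)
        theirs = [float(v) for v in out.stdout.split()][-3:]
        for mine, ref in zip(ours, theirs):
            assert mine == pytest.approx(ref, abs=0.75)


class TestMTE:
    def test_known_value_and_monotonicity(self):
        assert mte_predictor(10.0) == pytest.approx(40.99, abs=0.005)
        assert mte_predictor(10.0) > mte_predictor(11.0)
        with pytest.raises(ValueError):
            mte_predictor(-273.15)

    def test_activation_energy_recovery(self):
        # ln S = a - E * (1/kT): the linear fit recovers E within 2 SE
        rng = np.random.default_rng(8)
        E_true = 0.32
        t_mean = rng.uniform(3, 15, 300)
        inv_kt = mte_predictor(t_mean)
        ln_s = 16.0 - E_true * inv_kt + rng.normal(0, 0.25, 300)
        df = pd.DataFrame({"T_mean": t_mean,
                           "richness": np.round(np.exp(ln_s)).astype(int)})
        spec = ModelSpec("Metabolic theory", "Formal hypothesis", "complete",
                         "ln_richness", [("inv_kT", False)], aic_comparable=False)
        res = fit_gam(spec, df)
        X = np.column_stack([np.ones(300), inv_kt])
        beta, res_ls, *_ = np.linalg.lstsq(X, np.log(df["richness"].clip(lower=1)), rcond=None)
        resid = np.log(df["richness"].clip(lower=1)) - X @ beta
        se = np.sqrt(float(resid @ resid) / 298 / ((inv_kt - inv_kt.mean()) ** 2).sum())
        assert abs(-beta[1] - E_true) < 2 * se
        assert "inv_kT" in res.significant_terms

    def test_zero_richness_sites_excluded(self):
        df = pd.DataFrame({"T_mean": [5.0, 6.0, 7.0, 8.0, 9.0, 10.0] * 5,
                           "richness": [0, 3, 4, 5, 6, 7] * 5})
        spec = ModelSpec("Metabolic theory", "Formal hypothesis", "complete",
                         "ln_richness", [("inv_kT", False)], aic_comparable=False)
        res = fit_gam(spec, df)
        assert res.n == 25


class TestSuite:
    def test_complete_variant_has_no_chemistry_rows(self):
        names = [s.name for s in table_model_specs("complete")]
        assert "Chemical effect" not in names
        assert "Niche dimensionality" not in names
        assert len(names) == 10
        chem_names = [s.name for s in table_model_specs("chemical")]
        assert "Chemical effect" in chem_names and "Niche dimensionality" in chem_names
        assert len(chem_names) == 12

    def test_best_set_rule(self):
        assert mark_best_set([100.0, 101.5, 103.0]) == [True, True, False]
        assert mark_best_set([]) == []

    def test_mte_excluded_from_best_set(self, small_dataset):
        sites = small_dataset.sites.copy()
        sites["Glac"] = 0.3
        sites["Fglac"] = (sites["Lat"] < -43).astype(int)
        table = run_model_suite(sites, "complete")
        mte_row = table.loc[table["model"] == "Metabolic theory"].iloc[0]
        assert not mte_row["aic_comparable"]
        assert not mte_row["best"]
        assert table["best"].any()

    def test_chemistry_driven_richness_prefers_chemical_model(self):
        # richness built from SiO2 and Vel only: over seeds, the chemical
        # equation should out-explain the climatic one
        from diatombiogeo import SimulationConfig, generate_sites
        wins = 0
        for seed in range(8):
            cfg = SimulationConfig(n_sites=180, seed=seed, chem_subset_fraction=1.0,
                                   richness_effects={"SiO2": 1.2, "Vel": -12.0},
                                   richness_noise_sd=3.0, richness_intercept=20.0)
            sites = generate_sites(cfg)
            from diatombiogeo.synthetic import generate_richness_response
            sites, _ = generate_richness_response(sites, cfg)
            sites["Cel_den"] = 1000.0 + sites["richness"]
            sites["Glac"], sites["Fglac"] = 0.2, 0
            chem = fit_gam(ModelSpec("Chemical effect", "Exploratory model", "chemical",
                                     "richness", [(t, True) for t in gam.CHEMISTRY_TERMS]),
                           sites)
            clim = fit_gam(ModelSpec("Climatical effect", "Exploratory model", "chemical",
                                     "richness", [(t, True) for t in gam.CLIMATE_TERMS]),
                           sites)
            wins += chem.deviance_explained > clim.deviance_explained
        assert wins >= 7

    def test_per_model_errors_propagated_not_fatal(self):
        df = pd.DataFrame({"Lat": np.linspace(-52, -35, 50),
                           "richness": np.random.default_rng(0).integers(5, 30, 50)})
        table = run_model_suite(df, "complete")
        lat = table.loc[table["model"] == "Latitudinal effect"].iloc[0]
        assert lat["error"] == ""
        missing = table.loc[table["model"] == "Climatical effect"].iloc[0]
        assert missing["error"] != ""


class TestCorrelationMatrix:
    def test_self_correlation_unity(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"a": rng.normal(size=20), "b": rng.normal(size=20)})
        cm = correlation_matrix(df, ["a", "b"])
        assert cm.r.loc["a", "a"] == 1.0

    def test_orthogonal_contrasts_zero(self):
        df = pd.DataFrame({"a": [1, 1, -1, -1.0], "b": [1, -1.0, 1, -1]})
        cm = correlation_matrix(df, ["a", "b"])
        assert cm.r.loc["a", "b"] == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_10_pairs_and_stars(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=10)
        y = 0.9 * x + rng.normal(0, 0.2, 10)
        df = pd.DataFrame({"x": x, "y": y})
        cm = correlation_matrix(df, ["x", "y"])
        r = np.corrcoef(x, y)[0, 1]
        assert cm.r.loc["x", "y"] == pytest.approx(r, abs=1e-12)
        t = r * np.sqrt(8 / (1 - r * r))
        from scipy import stats as ss
        assert cm.p.loc["x", "y"] == pytest.approx(2 * ss.t.sf(abs(t), 8), rel=1e-9)
        assert cm.stars.loc["x", "y"] in ("***", "**", "*")
        if r * r > 0.9:
            assert ("x", "y") in cm.strong_pairs

    def test_zero_variance_rejected(self):
        df = pd.DataFrame({"a": np.ones(10), "b": np.arange(10.0)})
        with pytest.raises(ValueError):
            correlation_matrix(df, ["a", "b"])


class TestLatitudeGam:
    def test_constant_richness_non_significant(self):
        df = pd.DataFrame({"Lat": np.linspace(-52, -35, 100),
                           "richness": np.full(100, 12)})
        res = latitude_richness_gam(df, level="site")
        assert res.significant_terms == []
        assert res.deviance_explained == 0.0

    def test_strong_gradient_detected(self):
        detected = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            lat = rng.uniform(-52, -35, 373)
            rich = np.clip(np.round(30 + 1.2 * (lat + 52) + rng.normal(0, 4, 373)), 0, None)
            res = latitude_richness_gam(pd.DataFrame({"Lat": lat, "richness": rich}))
            detected += res.term_table.iloc[0]["p"] < 0.001
        assert detected >= 9

    def test_band_levels_and_minimum_size(self):
        rng = np.random.default_rng(1)
        bands = pd.DataFrame({"mean_lat": np.linspace(-52, -35, 30),
                              "S_obs": rng.integers(20, 60, 30),
                              "S_est": rng.uniform(30, 70, 30)})
        for level in ("band", "band_estimated"):
            res = latitude_richness_gam(bands, level=level)
            assert res.n == 30
        with pytest.raises(ValueError):
            latitude_richness_gam(bands.head(4), level="band")
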