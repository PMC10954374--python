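#!/usr/bin/env python
"""Model comparison: predictor correlations and the 12-equation suite.

Computes the pairwise Pearson correlation matrix of predictors and richness,
then fits every applicable additive-model equation for the complete dataset
(all sites) and the chemical dataset (sites with full water chemistry),
marking the best set by the delta-AIC < 2 rule.
"""

from pathlib import Path

import pandas as pd

from diatombiogeo.gam import CHEMISTRY_TERMS, correlation_matrix, run_model_suite
from diatombiogeo.io import load_sites

RES = Path(__file__).resolve().parent.parent / "results"

sites, _ = load_sites(RES / "sites_enriched.csv")

corr_vars = [v for v in ["richness", "Lat", "Lon", "Elev", "T_mean", "T_max",
                         "T_min", "T_sd", "T_insitu", "pH", "EC", "Osat", "Ca",
                         "TP", "SiO2", "Vel", "NLR", "Glac"] if v in sites.columns]
cm = correlation_matrix(sites, corr_vars)
cm.r.round(3).to_csv(RES / "correlation_r.csv")
cm.p.to_csv(RES / "correlation_p.csv")
lat_corr = cm.r["Lat"].drop("Lat").sort_values()
print("correlation with latitude (negative = stronger southward):")
print(lat_corr.round(2).to_string())
if cm.strong_pairs:
    print("collinearity flags (r^2 > .90):", cm.strong_pairs)
else:
    print("no predictor pair exceeds r^2 = .90")

for variant, frame in (("complete", sites),
                       ("chemical", sites.dropna(subset=list(CHEMISTRY_TERMS)))):
    table = run_model_suite(frame, variant)
    table.to_csv(RES / f"models_{variant}.csv", index=False)
    print(f"\n{variant} dataset (n={len(frame)}):")
    print(table[["model", "significant_predictors", "deviance_explained",
                 "aic", "best"]].to_string(index=False))
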