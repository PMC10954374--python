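"""End-to-end analysis runner.

Stages, in order: load or simulate the three tables; detection-limit
substitution; predictor construction (NLR, Glac, Fglac); per-site richness;
latitudinal bands with standardized richness; latitude GAMs at site and band
level; the predictor correlation matrix; the model-comparison suites for the
complete and chemical dataset variants; and the metacommunity (EMS) analysis
with site-order correlations. Every output embeds the config hash and seeds,
and site accounting (used vs excluded, with reasons) is written to the log.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import gam, io, metacommunity, predictors, richness
from .synthetic import SimulationConfig, generate_dataset


@dataclass
class PipelineConfig:
    sites_csv: str | None = None
    community_csv: str | None = None
    ice_csv: str | None = None
    simulate: dict[str, Any] | None = None
    out_dir: str = "results"
    band_target_size: int = 12
    isolation_gap: float = 1.0
    common_size: int | None = None
    n_sim: int = 1000
    n_boot: int = 200
    alpha: float = 0.05
    seed: int = 0
    ems_mode: str = "both"
    ems_burn_in: int = 30_000
    ems_thin: int = 1_000
    reordinate_nulls: bool = True
    family: str = "gaussian"
    detection_limit_method: str = "half_dl"
    detection_limits: dict[str, float] = field(default_factory=dict)
    lgm_timestamps: tuple[float, ...] = predictors.DEFAULT_LGM_TIMESTAMPS

    def __post_init__(self) -> None:
        has_paths = all(x is not None for x in (self.sites_csv, self.community_csv, self.ice_csv))
        if not has_paths and self.simulate is None:
            raise ValueError("config needs either the three input paths or a simulate block")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage(log: dict, name: str, **info) -> None:
    log.setdefault("stages", []).append({"stage": name, **info})


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the full analysis and write the report bundle to out_dir."""
    out = io.ensure_dir(config.out_dir)
    log: dict[str, Any] = {"config": asdict(config), "config_hash": config.hash(),
                           "seed": config.seed}
    flags = None

    # -- load or simulate -------------------------------------------------
    if config.simulate is not None:
        sim_cfg = SimulationConfig(**{**config.simulate, "seed": config.simulate.get("seed", config.seed)})
        ds = generate_dataset(sim_cfg)
        sites, community, ice = ds.sites, ds.community, ds.ice
        _stage(log, "simulate", n_sites=len(sites), structure=sim_cfg.structure,
               seed=sim_cfg.seed)
    else:
        sites, flags = io.load_sites(config.sites_csv)
        community = io.load_community(config.community_csv)
        ice = io.load_ice(config.ice_csv)
        if not sites.index.equals(community.index):
            raise ValueError("sites and community tables disagree on site ids")
        _stage(log, "load", n_sites=len(sites))
    n_in = len(sites)

    # -- detection limits --------------------------------------------------
    if flags is not None and flags.to_numpy().any():
        for col, dl in config.detection_limits.items():
            if col in sites.columns and flags[col].any():
                sites[col] = predictors.substitute_below_detection(
                    sites[col], flags[col], dl,
                    method=config.detection_limit_method, seed=config.seed)
        _stage(log, "detection_limits", method=config.detection_limit_method,
               columns={c: int(flags[c].sum()) for c in flags.columns if flags[c].any()})

    # -- predictors --------------------------------------------------------
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        nlr, nlr_excluded = predictors.compute_nlr(sites)
    sites["NLR"] = nlr.reindex(sites.index)
    sites["Glac"] = predictors.compute_glac(ice).reindex(sites.index).fillna(0.0)
    sites["Fglac"] = predictors.compute_fglac(ice, config.lgm_timestamps).reindex(sites.index).fillna(0).astype(int)
    _stage(log, "predictors", nlr_excluded=[str(s) for s in nlr_excluded])

    # -- per-site richness -------------------------------------------------
    if "richness" not in sites.columns or sites["richness"].isna().all():
        sites["richness"] = (community.loc[sites.index] > 0).sum(axis=1)

    # -- bands and standardized richness ------------------------------------
    bands = predictors.build_latitudinal_bands(
        sites, target_size=config.band_target_size, isolation_gap=config.isolation_gap)
    bands = richness.estimate_band_richness(
        bands, community, common_size=config.common_size,
        n_boot=config.n_boot, seed=config.seed)
    bands_df = predictors.bands_to_frame(bands)
    _stage(log, "bands", n_bands=len(bands))

    # -- latitude GAMs -----------------------------------------------------
    lat_gams = {}
    for level, frame in (("site", sites), ("band", bands_df), ("band_estimated", bands_df)):
        try:
            res = gam.latitude_richness_gam(frame, level=level)
            row = res.term_table.iloc[0]
            lat_gams[level] = {"edf": float(row["edf"]), "statistic": float(row["statistic"]),
                               "p": float(row["p"]), "deviance_explained": res.deviance_explained}
        except ValueError as exc:
            lat_gams[level] = {"error": str(exc)}
    _stage(log, "latitude_gams", **{k: v.get("p", v.get("error")) for k, v in lat_gams.items()})

    # -- correlation matrix ------------------------------------------------
    corr_vars = [v for v in ["richness", "Lat", "Lon", "Elev", "T_mean", "T_max",
                             "T_min", "T_sd", "T_insitu", "pH", "EC", "Osat", "Ca",
                             "TP", "SiO2", "Vel", "NLR", "Glac"] if v in sites.columns]
    corr = gam.correlation_matrix(sites, corr_vars)

    # -- model suites --------------------------------------------------------
    suites = {}
    suites["complete"] = gam.run_model_suite(sites, "complete", family=config.family)
    chem_sites = sites.loc[sites[list(gam.CHEMISTRY_TERMS)].notna().all(axis=1)]
    if len(chem_sites) >= 30:
        suites["chemical"] = gam.run_model_suite(chem_sites, "chemical", family=config.family)
    else:
        _stage(log, "models", notice="chemical columns absent or too sparse; chemical-variant suite skipped")
    _stage(log, "models", variants=list(suites))

    # -- metacommunity ------------------------------------------------------
    ems_result, om = metacommunity.ems_analysis(
        community, n_sim=config.n_sim, seed=config.seed,
        burn_in=config.ems_burn_in, thin=config.ems_thin,
        mode=config.ems_mode, reordinate_nulls=config.reordinate_nulls,
        alpha=config.alpha)
    ems_report = ems_result.to_dict()
    for cov in ("Lat", "richness"):
        r, t, dfree, p = metacommunity.site_order_correlation(om, sites[cov])
        ems_report[f"order_vs_{cov}"] = {"r": r, "t": t, "df": dfree, "p": p}
    ems_report.update({"mode": config.ems_mode, "seed": config.seed,
                       "reordinate_nulls": config.reordinate_nulls,
                       "config_hash": config.hash()})
    _stage(log, "ems", label=ems_result.structure_label)

    # -- site accounting and outputs ----------------------------------------
    used = len(sites)
    log["site_accounting"] = {"in": n_in, "used": used,
                              "nlr_excluded_from_nlr_only": len(nlr_excluded)}
    meta_cols = {"config_hash": config.hash(), "seed": config.seed}

    sites_out = sites.copy()
    for k, v in meta_cols.items():
        sites_out.attrs[k] = v
    sites_out.to_csv(out / "sites_enriched.csv")
    bands_df.assign(**meta_cols).to_csv(out / "bands.csv", index=False)
    for variant, table in suites.items():
        table.assign(**meta_cols).to_csv(out / f"models_{variant}.csv", index=False)
    corr.r.to_csv(out / "correlation_r.csv")
    corr.p.to_csv(out / "correlation_p.csv")
    with open(out / "ems.json", "w") as fh:
        json.dump(ems_report, fh, indent=2)
    log["latitude_gams"] = lat_gams
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=str)

    return {"sites": sites, "bands": bands_df, "suites": suites, "corr": corr,
            "ems": ems_report, "latitude_gams": lat_gams, "log": log,
            "ordination": om}
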