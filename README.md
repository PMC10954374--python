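# diatombiogeo

Tools for analysing biogeographical patterns of stream-diatom species
richness along the southwestern South American latitudinal gradient
(35–52° S), and for any survey with the same shape of data: a sites table
(coordinates, climate, water physicochemistry), a sites × species count
matrix, and a per-site ice-sheet history.

The package is aimed at community ecologists asking three linked questions:

1. **Is there a latitudinal diversity gradient?** Per-site and per-band
   richness against latitude, with band richness standardized to a common
   number of sites by incidence-based rarefaction/extrapolation
   (Chao-type estimator from the uniques/duplicates frequencies Q1, Q2).
2. **Which mechanism explains richness best?** A 12-equation comparison
   suite of penalized-spline additive models — spatial, climatic,
   physicochemical, species–energy (temperature and cell-density forms),
   energy variability, climatic tolerance, metabolic theory
   (ln S ~ 1/kT), glaciation history (Glac, Fglac), and niche
   dimensionality via the number of limiting resources (NLR, a 0–8
   tercile rank of Ca, TP, SiO₂ and conductivity) — compared by deviance
   explained and the ΔAIC < 2 best-set rule.
3. **How is the metacommunity structured?** Elements of metacommunity
   structure: reciprocal-averaging ordination, coherence (embedded
   absences), turnover (range-filled species replacements) and boundary
   clumping (Morisita's index) against a fixed-margin checkerboard-swap
   null, classified into Clementsian / Gleasonian / nested / random /
   checkerboard structures and their quasi- variants.

A seeded synthetic-data generator reproduces the survey's statistical
structure (373 sites, a ~182-site chemistry subset, covariates trending
northward, a glaciated far south, and community matrices with controllable
metacommunity architecture), so the entire pipeline runs and is tested
without any external data.

## Core quantities

* Glaciation exposure: `Glac = 1 − t_last/35`, the proportion of the last
  35 ka a site spent under the ice sheet, where `t_last` is the most recent
  of the nine reconstruction timestamps (35, 30, 25, 20, 15, 13, 10, 5,
  0.2 ka) with ice present; `Fglac` is binary presence at the 20 ka layer.
* NLR: per resource variable, score 2 below the 0.33 sample quantile, 1
  inside [q0.33, q0.66], 0 above; the four scores sum to a 0–8 rank.
* Rarefaction: `E[S(m)] = Σᵢ [1 − C(T−Yᵢ, m)/C(T, m)]` over incidence
  frequencies `Yᵢ`; extrapolation approaches `S_obs + Q̂₀` with
  `Q̂₀ = ((T−1)/T)·Q1²/(2Q2)`.
* Additive models: cubic B-spline smooths with a curvature penalty plus a
  null-space shrinkage penalty; smoothing parameters by REML, so
  uninformative terms are dropped (edf → 0) rather than kept.

## Worked example

```python
from diatombiogeo import SimulationConfig, generate_dataset, ems_analysis

cfg = SimulationConfig(n_sites=60, n_species=40,
                       structure="clementsian", n_compartments=3, seed=7)
ds = generate_dataset(cfg)
result, om = ems_analysis(ds.community, n_sim=200, seed=3,
                          burn_in=10_000, thin=500)
print(result.structure_label, round(result.z_coherence, 2),
      round(result.z_turnover, 2), round(result.morisita, 2))
```

prints

```
Clementsian -49.17 43.51 4.22
```

i.e. the matrix has far fewer embedded absences than its fixed-margin nulls
(strong coherence, negative z), far more species replacements (positive
turnover z), and strongly clumped range boundaries (Morisita ≫ 1) — the
compartmented, Clementsian signature the generator was asked for.

The full analysis sequence lives in `analysis/` as numbered scripts:

```bash
python analysis/01_simulate_dataset.py      # sites/community/ice CSVs
python analysis/02_build_predictors.py      # NLR, Glac, Fglac, richness
python analysis/03_richness_gradient.py     # bands + latitude GAMs
python analysis/04_model_comparison.py      # correlations + 12-model suites
python analysis/05_metacommunity_structure.py
```

Each step prints what it found and writes its tables under `results/`.
The same stages are available as CLI subcommands
(`diatombiogeo simulate|nlr|bands|rarefy|ems|models|corr|run`).

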