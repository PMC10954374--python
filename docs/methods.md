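# Methods

This note documents the models and numerical choices behind the package, in
the spirit of a statistical-software methods appendix: what is computed, under
which assumptions, which defaults matter, and what the synthetic data do and
do not establish.

## Study system and data model

The analyses target stream-diatom incidence surveys along a single dominant
spatial gradient (latitude, stored as signed decimal degrees with south
negative, so "increases with latitude" always means increases northward).
Three tables describe a study: a sites table (coordinates, elevation, four
climate summaries, nine water-physicochemistry variables, cell density), a
sites × species count matrix (incidence is derived as counts > 0), and a
per-site ice-sheet history at nine reconstruction timestamps
(35, 30, 25, 20, 15, 13, 10, 5, 0.2 ka). Chemistry is typically measured on a
subset of sites only, giving a "complete" dataset (all sites, no chemistry
models) and a "chemical" dataset (chemistry-complete sites, all models).

## Derived predictors

**Glaciation exposure (Glac).** The proportion of the last 35 ka a site spent
under ice: `Glac = 1 − t_last/35`, with `t_last` the most recent timestamp at
which ice was present and `Glac = 0` for never-glaciated sites. With the nine
available layers and deglaciation complete by 10 ka the attainable maximum is
`1 − 10/35 = 0.714`. The alternative reading "divide the age by 35 and
subtract 1" yields negative values and is rejected; the implemented form is
the one consistent with the worked value 0.714.

**LGM indicator (Fglac).** Binary ice presence at the 20 ka layer — the
reconstruction timestamp closest to the Last Glacial Maximum. The defining
layer is configurable because reasonable analysts could pick 25–15 ka.

**Number of limiting resources (NLR).** For each of Ca, TP, SiO₂ and
electrical conductivity (a base-cation proxy), sites score 2 below that
variable's 0.33 sample quantile, 1 on the closed interval between the 0.33
and 0.66 quantiles, 0 above. The sum is a 0–8 rank: 8 = all four resources
scarce (strong limitation, low niche dimensionality). Quantiles are the
linear-interpolation sample quantiles of the scored (chemistry-complete)
sites themselves; both the estimator and the boundary rule are configurable
because neither is canonical. Scoring is rank-based, hence invariant under
strictly monotone transforms of any resource variable. Sites missing any
resource value are excluded from scoring and reported, never silently
dropped.

**Below-detection values.** Censored measurements are replaced inside
(0, DL): deterministically by DL/2 (default, reproducible) or uniformly at
random with a recorded seed. TN is excluded outright (mostly censored) and
never modelled.

**Latitudinal bands.** Sites sorted south→north are chunked greedily into
bands of a target size (default 12). Two adjustments replace the manual band
editing a field analyst would do: (i) any run of sites separated from its
neighbours by more than `isolation_gap` degrees (default 1°) forms its own
band regardless of size — the motivating case is a five-site far-south
cluster spanning 1.3°; (ii) a small terminal remainder is rebalanced with the
preceding chunk so band sizes stay near the target. The band latitude is the
mean member latitude. Manual band editing, the field norm, is not
reproducible by construction; this deterministic rule is the package's
replacement for it.

## Richness standardization

Bands differ in site count, so pooled band richness is standardized by
incidence-based rarefaction/extrapolation with the site as the sampling unit.
Rarefaction is the exact hypergeometric expectation
`E[S(m)] = Σᵢ [1 − C(T−Yᵢ, m)/C(T, m)]`; extrapolation uses the
uniques/duplicates estimate of undetected richness
`Q̂₀ = ((T−1)/T)·Q1²/(2Q2)` (bias-corrected form when `Q2 = 0`) and the
standard exponential approach to the asymptote `S_obs + Q̂₀`. The default
common sample size is the largest band, so smaller bands are purely
extrapolated. Intervals are percentile bootstraps over sites within band
(default 200 replicates, seeded). Abundance-based and coverage-based
standardization are out of scope.

## Elements of metacommunity structure

The incidence matrix (singleton species removed, then any emptied sites
removed and reported) is reordered by reciprocal averaging — the first
non-trivial correspondence-analysis axis computed by iterative averaging with
weighted deflation of the trivial axis, renormalized each sweep to a
convergence tolerance of 1e−10. The axis sign is fixed by a lexicographic rule
on the extreme-score sites so orderings are reproducible; scores agree with a
direct eigen-decomposition to 1e−8 on small matrices (tested).

Three statistics are referred to a fixed-margin null:

* **Coherence** — embedded absences (zeros strictly inside a species' range
  along ordered sites); by default the row (site) gaps are added as well,
  since the counting mode is not canonical; the mode is a flag. Fewer gaps
  than null (negative z) = coherent.
* **Turnover** — after filling each species' range, the sum over species
  pairs of `Dᵢ·Dⱼ`, where `Dᵢ` counts sites holding species i but not j.
  More replacements than null (positive z) = turnover.
* **Boundary clumping** — Morisita's index `I = T·Σ nᵢ(nᵢ−1)/(N(N−1))` of the
  first/last range endpoints over ordered sites, with a chi-square test of
  the endpoint counts against uniform. `I > 1` = clumped.

The null ensemble is the sequential checkerboard-swap chain: random 2×2
submatrices of the form [[1,0],[0,1]] are flipped, preserving all row and
column sums exactly (asserted on every emission in tests). The chain is
symmetric, so its stationary distribution is uniform over the fixed-margin
set; uniformity is verified against an exhaustively enumerated 12-member
ensemble. Defaults: 1000 null draws, 30 000 burn-in swaps, 1000 swaps between
emissions — ample mixing at the study's matrix size; all tunable. Each null
matrix is independently re-ordinated before its statistics are measured
(conservative; a flag can skip this for speed). z-scores use the null mean
and SD with two-tailed normal p-values.

The classifier follows the standard decision tree: significant excess of
embedded absences → Checkerboard; non-significant coherence → Random;
otherwise significant positive turnover splits on clumping into Clementsian
(clumped) / Gleasonian (clumping non-significant) / evenly spaced, and
significant negative turnover gives the nested subtypes; non-significant
turnover yields the corresponding Quasi- label keyed on the turnover z sign,
so the classifier is total.

**Degenerate ensemble.** A perfectly nested matrix (site communities forming
a chain under inclusion) contains no checkerboard, so its fixed-margin
ensemble is the single observed configuration and a Monte Carlo test is
impossible. The package detects this case, classifies through the nested
branch with infinite-magnitude z-scores, and reports `n_sim = 0` — nestedness
then holds by construction, not by simulation. This matters mainly for
synthetic data; empirical matrices are essentially never perfectly nested.

**Known bias.** Ranges truncated at the matrix edges pile range endpoints
onto the first and last ordered sites, which inflates Morisita's index for
edge-heavy gradients; a strongly Gleasonian gradient can therefore drift
toward a Clementsian label. This is a property of the boundary-count
statistic itself, shared with the reference implementations, not a defect of
the null.

**Site-order correlations.** The ordination rank of each site is correlated
(Pearson) with latitude and with richness, reporting `r`,
`t = r·√(df/(1−r²))`, `df = n−2`, and the two-tailed p.

## Additive models

Each smoothed term uses a cubic B-spline basis (default 10 basis functions)
on unclamped, equally spaced knots — the Eilers–Marx P-spline setup, chosen
because the second-order coefficient-difference penalty then has exactly the
constant and linear functions as its null space. Bases are sum-to-zero
constrained against the intercept. Every smooth carries two penalties: the
curvature penalty and a separate penalty on its null space, so restricted
maximum likelihood can shrink an uninformative term's effective degrees of
freedom toward zero — the term-dropping behaviour needed when many candidate
predictors meet modest sample sizes. Smoothing parameters minimize the
Gaussian profile-REML criterion (L-BFGS-B on log smoothing parameters,
bounded in [e⁻¹⁰, e¹⁸], multi-started from a neutral and a heavily smoothed
point to avoid the under-smoothed local optimum). The Poisson option runs
penalized IRLS with the fixed-scale REML criterion on the working model; the
default family is Gaussian on untransformed richness, with Poisson available
since richness is a count.

Reported per model: per-term edf (trace of the corresponding block of
`(XᵀX + S_λ)⁻¹XᵀX`), an approximate Wald test on the fitted function values
with a rank-`max(1, round(edf))` pseudo-inverse (the formulation with
near-nominal behaviour for shrinkage smooths; linear terms get t-tests),
percent deviance explained, and AIC computed from total edf (+1 for the
Gaussian scale). On shared data the engine's edf matches R's
`mgcv::gam(..., method="REML", select=TRUE)` to a few hundredths, and this
agreement is pinned by a test. Pure-noise smooths are rejected at roughly the
nominal 5% level; their edf falls below 0.5 in somewhat over half of
replicates (the same fraction mgcv produces), so "the term is dropped" should
be read as a strong tendency, not a guarantee.

The comparison suite fits the twelve equations (spatial, climatic,
physicochemical, combined, two species–energy forms, energy variability,
climatic tolerance, metabolic theory, glaciation history, niche
dimensionality); Glac, Fglac and NLR enter linearly (their low numerical
variability makes smooths degenerate), and the metabolic-theory model is
`ln S ~ 1/(kT)` with `k = 8.617×10⁻⁵ eV K⁻¹`, T in kelvin, zero-richness
sites excluded and reported, and its AIC flagged non-comparable because the
response is transformed. Best models are those within 2 AIC units of the
comparable minimum. Per-model failures are recorded in the suite table, not
raised. The suite is validated by its statistical properties (slope
recovery, calibration, superset monotonicity) rather than by matching any
published results table, whose deviance/AIC values hinge on family and basis
internals that a reimplementation cannot pin down.

## Synthetic data

The generator encodes the study conditions: 373 sites uniform on
[−52°, −35°], chemistry on a 182/373 subset, climate variables and SiO₂, pH,
T_insitu increasing northward with independent Gaussian noise, Vel and Osat
latitude-independent, and an ice history glaciated south of −38° in which
deglaciation is older toward the northern edge (last ice 35 ka) and youngest
in the far south (10 ka). Default slopes and noise levels are conventions
chosen to give realistic magnitudes and the expected correlation sign
pattern; they are not estimates fitted to any dataset.

Community structure is generated by Gaussian-response occupancy along
latitude: independent optima (Gleasonian); optima in tight, evenly spaced
clusters with near-deterministic windows (Clementsian); prefix subsets of a
fixed species ranking along a richness gradient (nested — exactly nested by
construction, hence the degenerate-ensemble path above); iid Bernoulli
occupancy (random); and mutually exclusive species pairs (checkerboard).
Counts are shifted-Poisson on occupancy, and per-site cell density is
log-normal with log-mean tied to realized richness, reproducing the positive
richness–density association without asserting causality. A separate
richness-response generator overwrites richness with a linear-Gaussian
function of chosen predictors (default: a negative NLR effect) for
effect-recovery tests.

What passing tests show: the estimators are internally correct (enumeration
and eigen oracles), the null is exact and uniform, structure recovery works
on idealized matrices, and the model machinery is calibrated. What they do
not show: robustness to the features real surveys add — detection error,
spatially autocorrelated environments beyond one gradient, abundance
dynamics, taxonomic inconsistency — none of which the generator emulates.

## Reproducibility and problem sizes

Every stochastic component takes an explicit seed, recorded in all outputs
together with a hash of the scientific configuration; identical configuration
and seed reproduce report bundles byte-for-byte (tested). Default test-suite
problem sizes (60×40 matrices, 200 null draws, 20 seeds for structure
recovery; n = 300 calibration replicates) were chosen as the smallest sizes
at which the statistical claims are stable. The analysis scripts run the
full study scale (373 sites, 1000 null draws) in well under a minute per
stage.
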