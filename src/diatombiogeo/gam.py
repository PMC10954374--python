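"""Penalized-spline additive models for the richness–environment analyses.

Each smoothed term is represented by a cubic B-spline basis (default 10 basis
functions, quantile-spaced knots, sum-to-zero constrained) with two penalties:
a second-order difference (curvature) penalty and a separate penalty on the
curvature penalty's null space. The second penalty lets restricted maximum
likelihood (REML) shrink an uninformative term's effective degrees of freedom
toward zero, i.e. drop it from the model, which is how the suite copes with
many candidate predictors at modest sample sizes.

Smoothing parameters are chosen by minimizing the Gaussian profile-REML
criterion; the Poisson option runs penalized IRLS with the same criterion on
the working model. Reported per-model quantities mirror the standard additive
-model summary: per-term effective degrees of freedom (edf), an approximate
Wald test, percent deviance explained, and an AIC based on total edf.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve, null_space
from scipy.special import gammaln

#: Boltzmann constant in eV/K, as conventionally rounded in metabolic-theory work
BOLTZMANN_EV = 8.617e-5

SIGNIFICANCE_ALPHA = 0.05


# ---------------------------------------------------------------------------
# model specification


@dataclass
class ModelSpec:
    """One row of the model-comparison suite."""

    name: str
    group: str = "Exploratory model"
    dataset_variant: str = "complete"
    response: str = "richness"          # or "ln_richness"
    terms: list[tuple[str, bool]] = field(default_factory=list)  # (predictor, smoothed)
    family: str = "gaussian"
    aic_comparable: bool = True


@dataclass
class ModelFitResult:
    spec: ModelSpec
    term_table: pd.DataFrame            # term, smoothed, edf, statistic, p
    deviance_explained: float           # percent
    aic: float
    aic_comparable: bool
    significant_terms: list[str]
    n: int
    edf_total: float
    fitted: np.ndarray | None = None
    scale: float = float("nan")
    dropped_rows: int = 0


# ---------------------------------------------------------------------------
# basis construction


def _bspline_basis(x: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Cubic B-spline design matrix (n x k) and its knot vector."""
    xmin, xmax = float(x.min()), float(x.max())
    if xmax <= xmin:
        raise ValueError("smoothed predictor is constant")
    # unclamped, equally spaced knots (Eilers-Marx): Greville sites are then
    # equally spaced everywhere, so the coefficient-difference penalty has the
    # constant and linear functions as its exact null space
    h = (xmax - xmin) / (k - 3)
    t = xmin + h * (np.arange(k + 4) - 3.0)
    B = BSpline.design_matrix(x, t, 3, extrapolate=True).toarray()
    return B, t


@dataclass
class _SmoothBlock:
    name: str
    cols: slice
    X: np.ndarray
    S: np.ndarray          # curvature penalty (constrained space, unit norm)
    N: np.ndarray          # null-space penalty (projection)


def _build_smooth(name: str, x: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    B, _ = _bspline_basis(x, k)
    # sum-to-zero constraint removes confounding with the intercept
    C = B.sum(axis=0, keepdims=True)
    Q = null_space(C)
    Z = B @ Q
    D = np.diff(np.eye(B.shape[1]), n=2, axis=0)
    S = Q.T @ (D.T @ D) @ Q
    S = S / np.linalg.norm(S, 2)
    vals, vecs = np.linalg.eigh(S)
    null_mask = vals < 1e-9
    U0 = vecs[:, null_mask]
    N = U0 @ U0.T
    return Z, S, N


# ---------------------------------------------------------------------------
# REML machinery (Gaussian working model)


class _Design:
    def __init__(self, y, linear: dict[str, np.ndarray], smooth: dict[str, np.ndarray], k: int):
        n = len(y)
        self.y = np.asarray(y, dtype=float)
        cols = [np.ones((n, 1))]
        self.linear_names = list(linear)
        self.lin_scale = {}
        for name, x in linear.items():
            sd = x.std()
            sd = sd if sd > 0 else 1.0
            self.lin_scale[name] = sd
            cols.append(((x - x.mean()) / sd)[:, None])
        self.blocks: list[_SmoothBlock] = []
        pos = 1 + len(linear)
        n_smooth = len(smooth)
        if n_smooth:
            # keep the total basis size safely below n
            max_per = max(5, (n - pos - 1) // n_smooth)
            k = min(k, max_per)
        for name, x in smooth.items():
            n_unique = len(np.unique(x))
            k_eff = min(k, max(5, n_unique))
            if n_unique < 5:
                raise ValueError(
                    f"predictor {name!r} has too few distinct values to smooth")
            Z, S, N = _build_smooth(name, x, k_eff)
            self.blocks.append(_SmoothBlock(name, slice(pos, pos + Z.shape[1]), Z, S, N))
            cols.append(Z)
            pos += Z.shape[1]
        self.X = np.hstack(cols)
        self.p = pos
        self.Mp = 1 + len(linear)     # unpenalized coefficient count
        if n <= self.p:
            raise ValueError(f"n = {n} too small for {self.p} coefficients")

    def penalty(self, rho: np.ndarray) -> tuple[np.ndarray, float]:
        """Total penalty matrix and log pseudo-determinant for log-smoothing
        parameters rho (two per smooth block)."""
        P = np.zeros((self.p, self.p))
        logdet = 0.0
        for i, blk in enumerate(self.blocks):
            lam1, lam2 = np.exp(rho[2 * i]), np.exp(rho[2 * i + 1])
            Pb = lam1 * blk.S + lam2 * blk.N
            P[blk.cols, blk.cols] = Pb
            sign, ld = np.linalg.slogdet(Pb)
            if sign <= 0:
                return P, -np.inf
            logdet += ld
        return P, logdet


def _reml_score(design: _Design, rho: np.ndarray, w: np.ndarray | None = None, fixed_scale: float | None = None) -> float:
    X, y = design.X, design.y
    if w is not None:
        sw = np.sqrt(w)
        X = X * sw[:, None]
        y = y * sw
    n = len(y)
    P, logdetP = design.penalty(rho)
    if not np.isfinite(logdetP):
        return np.inf
    A = X.T @ X + P
    try:
        cf = cho_factor(A)
    except np.linalg.LinAlgError:
        return np.inf
    beta = cho_solve(cf, X.T @ y)
    resid = y - X @ beta
    rss_p = float(resid @ resid + beta @ P @ beta)
    logdetA = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    if fixed_scale is not None:
        return 0.5 * (rss_p / fixed_scale + logdetA - logdetP)
    nm = n - design.Mp
    sigma2 = rss_p / nm
    if sigma2 <= 0:
        return np.inf
    return 0.5 * (nm * np.log(2 * np.pi * sigma2) + nm + logdetA - logdetP)


def _solve(design: _Design, rho: np.ndarray, w: np.ndarray | None = None):
    X, y = design.X, design.y
    if w is not None:
        sw = np.sqrt(w)
        X = X * sw[:, None]
        y = y * sw
    P, _ = design.penalty(rho)
    A = X.T @ X + P
    cf = cho_factor(A)
    beta = cho_solve(cf, X.T @ y)
    F = cho_solve(cf, X.T @ X)         # edf matrix: A^{-1} X'WX
    Ainv = cho_solve(cf, np.eye(design.p))
    return beta, F, Ainv


def _optimize_rho(design: _Design, w=None, fixed_scale=None) -> np.ndarray:
    """Minimize the REML criterion over log smoothing parameters.

    Multi-start (a neutral and a heavily-smoothed start) guards against the
    local optimum where an uninformative term keeps residual wiggliness."""
    d = 2 * len(design.blocks)
    if d == 0:
        return np.zeros(0)
    fun = lambda r: _reml_score(design, r, w=w, fixed_scale=fixed_scale)
    best = None
    for start in (np.zeros(d), np.full(d, 8.0)):
        res = optimize.minimize(fun, start, method="L-BFGS-B",
                                bounds=[(-10.0, 18.0)] * d)
        if best is None or res.fun < best.fun:
            best = res
    return best.x


# ---------------------------------------------------------------------------
# fitting


def _term_tests(design: _Design, beta, F, Ainv, scale, resid_df, smoothed_terms,
                penalized: bool) -> pd.DataFrame:
    rows = []
    Vb = scale * Ainv
    edf_diag = np.diag(F)
    # linear terms: t test
    for j, name in enumerate(design.linear_names):
        idx = 1 + j
        se = np.sqrt(max(Vb[idx, idx], 1e-300))
        tval = beta[idx] / se
        p = 2 * stats.t.sf(abs(tval), df=max(resid_df, 1))
        rows.append({"term": name, "smoothed": False, "edf": 1.0,
                     "statistic": float(tval), "p": float(p)})
    for blk in design.blocks:
        idx = np.arange(blk.cols.start, blk.cols.stop)
        edf = float(edf_diag[idx].sum())
        b = beta[idx]
        V = Vb[np.ix_(idx, idx)]
        pj = len(idx)
        r = pj if not penalized else max(1, min(pj, int(round(edf + 0.45))))
        # function-space Wald: T = f' (Xj V Xj')^{rank-r pseudo-inverse} f
        # evaluated via the economy decomposition of Xj L, V = L L'
        vals, vecs = np.linalg.eigh(V)
        vals = np.clip(vals, 0.0, None)
        L = vecs * np.sqrt(vals)
        G = blk.X @ L                       # n x pj, Vf = G G'
        U, D, _ = np.linalg.svd(G, full_matrices=False)
        f = blk.X @ b
        good = D > 1e-8 * D.max() if D.size else np.array([], bool)
        Ur, Dr = U[:, good][:, :r], D[good][:r]
        if Dr.size == 0:
            stat_val, p = 0.0, 1.0
        else:
            proj = (Ur.T @ f) / Dr
            chi2 = float(proj @ proj)
            stat_val = chi2 / r
            p = float(stats.f.sf(stat_val, r, max(resid_df, 1)))
        rows.append({"term": blk.name, "smoothed": True, "edf": edf,
                     "statistic": stat_val, "p": p})
    return pd.DataFrame(rows)


def fit_additive(
    y: np.ndarray,
    data: pd.DataFrame,
    smooth_terms: list[str],
    linear_terms: list[str],
    family: str = "gaussian",
    k: int = 10,
    penalized: bool = True,
) -> dict:
    """Fit the penalized additive model and return the raw fit pieces.

    ``penalized=False`` fits the same bases unpenalized (ordinary least
    squares on the full design), which is useful for nested-model
    comparisons.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    design = _Design(
        y,
        {t: data[t].to_numpy(float) for t in linear_terms},
        {t: data[t].to_numpy(float) for t in smooth_terms},
        k=k,
    )

    if np.var(y) == 0:
        # degenerate response: nothing to explain
        terms = pd.DataFrame(
            [{"term": t, "smoothed": False, "edf": 1.0, "statistic": 0.0, "p": 1.0}
             for t in linear_terms]
            + [{"term": t, "smoothed": True, "edf": 0.0, "statistic": 0.0, "p": 1.0}
               for t in smooth_terms])
        return {"terms": terms, "deviance_explained": 0.0, "aic": float("nan"),
                "edf_total": 1.0, "fitted": np.full(n, y[0] if n else 0.0),
                "scale": 0.0, "n": n}

    if family == "gaussian":
        rho = _optimize_rho(design) if (penalized and design.blocks) else np.full(2 * len(design.blocks), -30.0)
        if not penalized:
            rho = np.full(2 * len(design.blocks), -30.0)
        beta, F, Ainv = _solve(design, rho)
        fitted = design.X @ beta
        resid = y - fitted
        rss = float(resid @ resid)
        tss = float(((y - y.mean()) ** 2).sum())
        edf_total = float(np.trace(F))
        resid_df = n - edf_total
        scale = rss / max(resid_df, 1e-8)
        dev_expl = 100.0 * (1.0 - rss / tss)
        sigma2_ml = max(rss / n, 1e-300)
        loglik = -0.5 * n * (np.log(2 * np.pi * sigma2_ml) + 1.0)
        aic = -2.0 * loglik + 2.0 * (edf_total + 1.0)
    elif family == "poisson":
        eta = np.log(np.maximum(y, 0.5))
        rho = np.zeros(2 * len(design.blocks))
        beta = None
        for _ in range(30):
            mu = np.exp(eta)
            w = mu
            z = eta + (y - mu) / mu
            design.y = z
            if penalized and design.blocks:
                rho = _optimize_rho(design, w=w, fixed_scale=1.0)
            beta_new, F, Ainv = _solve(design, rho, w=w)
            eta_new = design.X @ beta_new
            step_done = beta is not None and np.max(np.abs(eta_new - eta)) < 1e-8
            beta, eta = beta_new, eta_new
            if step_done:
                break
        mu = np.exp(eta)
        fitted = mu
        with np.errstate(divide="ignore", invalid="ignore"):
            dev_terms = np.where(y > 0, y * np.log(y / mu), 0.0) - (y - mu)
        deviance = 2.0 * float(dev_terms.sum())
        mu0 = y.mean()
        with np.errstate(divide="ignore", invalid="ignore"):
            null_terms = np.where(y > 0, y * np.log(y / mu0), 0.0) - (y - mu0)
        null_dev = 2.0 * float(null_terms.sum())
        edf_total = float(np.trace(F))
        resid_df = n - edf_total
        scale = 1.0
        dev_expl = 100.0 * (1.0 - deviance / null_dev) if null_dev > 0 else 0.0
        loglik = float(np.sum(y * np.log(mu) - mu - gammaln(y + 1.0)))
        aic = -2.0 * loglik + 2.0 * edf_total
    else:
        raise ValueError(f"unknown family {family!r}")

    terms = _term_tests(design, beta, F, Ainv, scale, resid_df,
                        smooth_terms, penalized)
    return {"terms": terms, "deviance_explained": float(np.clip(dev_expl, 0.0, 100.0)),
            "aic": float(aic), "edf_total": edf_total, "fitted": fitted,
            "scale": scale, "n": n}


def mte_predictor(t_mean) -> np.ndarray | float:
    """Metabolic-theory energy term 1/(k·T) with T in kelvin and k the
    Boltzmann constant in eV/K; strictly decreasing in temperature."""
    t = np.asarray(t_mean, dtype=float)
    if np.any(t <= -273.15):
        raise ValueError("temperature at or below absolute zero")
    out = 1.0 / (BOLTZMANN_EV * (t + 273.15))
    return float(out) if out.ndim == 0 else out


def fit_gam(spec: ModelSpec, data: pd.DataFrame, k: int = 10) -> ModelFitResult:
    """Fit one suite model: resolve derived predictors and the response,
    drop incomplete rows (reported, not silent), fit, and summarize."""
    df = data.copy()
    needed = []
    for term, _ in spec.terms:
        if term == "ln_Cel_den":
            df["ln_Cel_den"] = np.log(df["Cel_den"].astype(float) + 1.0)
        elif term == "inv_kT":
            df["inv_kT"] = mte_predictor(df["T_mean"])
        needed.append(term)

    if spec.response == "ln_richness":
        zero = df["richness"] <= 0
        if zero.any():
            df = df.loc[~zero]
        y_raw = np.log(df["richness"].astype(float))
    else:
        y_raw = df["richness"].astype(float)

    use = df[needed].assign(_y=y_raw)
    complete = use.notna().all(axis=1)
    dropped = int((~complete).sum())
    use = use.loc[complete]

    smooth = [t for t, s in spec.terms if s]
    linear = [t for t, s in spec.terms if not s]
    fit = fit_additive(use["_y"].to_numpy(), use, smooth, linear,
                       family=spec.family, k=k)
    sig = fit["terms"].loc[fit["terms"]["p"] < SIGNIFICANCE_ALPHA, "term"].tolist()
    return ModelFitResult(
        spec=spec,
        term_table=fit["terms"],
        deviance_explained=fit["deviance_explained"],
        aic=fit["aic"],
        aic_comparable=spec.aic_comparable,
        significant_terms=sig,
        n=fit["n"],
        edf_total=fit["edf_total"],
        fitted=fit["fitted"],
        scale=fit["scale"],
        dropped_rows=dropped,
    )


# ---------------------------------------------------------------------------
# the model suite

CLIMATE_TERMS = ["T_min", "T_max", "T_sd", "T_mean"]
CHEMISTRY_TERMS = ["T_insitu", "pH", "EC", "Osat", "Ca", "TP", "SiO2", "Vel"]


def table_model_specs(variant: str, family: str = "gaussian") -> list[ModelSpec]:
    """The 12-equation comparison suite; chemistry-dependent rows only exist
    for the chemical variant."""
    if variant not in ("complete", "chemical"):
        raise ValueError(f"unknown variant {variant!r}")
    sm = lambda names: [(t, True) for t in names]
    ln = lambda names: [(t, False) for t in names]
    specs = [
        ModelSpec("Latitudinal effect", "Exploratory model", variant, "richness", sm(["Lat"]), family),
        ModelSpec("Spatial effect", "Exploratory model", variant, "richness", sm(["Lat", "Lon", "Elev"]), family),
        ModelSpec("Climatical effect", "Exploratory model", variant, "richness", sm(CLIMATE_TERMS), family),
    ]
    if variant == "chemical":
        specs.append(ModelSpec("Chemical effect", "Exploratory model", variant, "richness",
                               sm(CHEMISTRY_TERMS), family))
        total_terms = sm(CHEMISTRY_TERMS) + sm(CLIMATE_TERMS) + ln(["Glac", "Fglac"])
    else:
        total_terms = sm(CLIMATE_TERMS) + ln(["Glac", "Fglac"])
    specs.append(ModelSpec("Total effect", "Exploratory model", variant, "richness", total_terms, family))
    specs += [
        ModelSpec("Species-energy theory via temperature", "Formal hypothesis", variant,
                  "richness", sm(["T_mean"]), family),
        ModelSpec("Species-energy theory via cell density", "Formal hypothesis", variant,
                  "richness", sm(["ln_Cel_den"]), family),
        ModelSpec("Energy variability hypothesis", "Formal hypothesis", variant,
                  "richness", sm(["T_sd"]), family),
        ModelSpec("Climatical tolerance hypothesis", "Formal hypothesis", variant,
                  "richness", sm(["T_min", "T_max"]), family),
        ModelSpec("Metabolic theory", "Formal hypothesis", variant,
                  "ln_richness", ln(["inv_kT"]), "gaussian", aic_comparable=False),
        ModelSpec("Historical effect", "Formal hypothesis", variant,
                  "richness", ln(["Glac", "Fglac"]), family),
    ]
    if variant == "chemical":
        specs.append(ModelSpec("Niche dimensionality", "Formal hypothesis", variant,
                               "richness", ln(["NLR"]), family))
    return specs


def run_model_suite(data: pd.DataFrame, variant: str, family: str = "gaussian",
                    k: int = 10) -> pd.DataFrame:
    """Fit every applicable suite equation and flag the best set by the
    delta-AIC < 2 rule (AIC-incomparable rows excluded from the rule)."""
    rows = []
    for spec in table_model_specs(variant, family):
        try:
            res = fit_gam(spec, data, k=k)
            rows.append({
                "model_group": spec.group,
                "model": spec.name,
                "significant_predictors": " + ".join(res.significant_terms) or "N.S.",
                "deviance_explained": round(res.deviance_explained, 2),
                "aic": round(res.aic, 2),
                "aic_comparable": res.aic_comparable,
                "n": res.n,
                "edf_total": round(res.edf_total, 2),
                "error": "",
            })
        except Exception as exc:  # propagate per-model, keep the suite running
            rows.append({
                "model_group": spec.group, "model": spec.name,
                "significant_predictors": "", "deviance_explained": np.nan,
                "aic": np.nan, "aic_comparable": spec.aic_comparable,
                "n": 0, "edf_total": np.nan, "error": f"{type(exc).__name__}: {exc}",
            })
    table = pd.DataFrame(rows)
    comparable = table["aic_comparable"] & table["aic"].notna()
    table["best"] = False
    if comparable.any():
        best_aic = table.loc[comparable, "aic"].min()
        table.loc[comparable & (table["aic"] < best_aic + 2.0), "best"] = True
    return table


def mark_best_set(aics: list[float]) -> list[bool]:
    """Delta-AIC < 2 best-set rule on a plain list of comparable AICs."""
    if not aics:
        return []
    lo = min(aics)
    return [a < lo + 2.0 for a in aics]


# ---------------------------------------------------------------------------
# correlation matrix and the latitude GAMs


@dataclass
class CorrelationMatrix:
    r: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame
    strong_pairs: list[tuple[str, str]]   # pairs with r^2 > 0.90


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def correlation_matrix(data: pd.DataFrame, variables: list[str]) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlations with two-tailed p values and
    the conventional significance stars; collinearity flagged at r² > 0.90."""
    k = len(variables)
    r = np.eye(k)
    p = np.zeros((k, k))
    strong = []
    for i in range(k):
        for j in range(i + 1, k):
            sub = data[[variables[i], variables[j]]].dropna()
            if len(sub) < 3:
                raise ValueError(f"fewer than 3 complete pairs for {variables[i]}/{variables[j]}")
            x, yv = sub.iloc[:, 0].to_numpy(float), sub.iloc[:, 1].to_numpy(float)
            if np.std(x) == 0 or np.std(yv) == 0:
                raise ValueError("zero-variance column")
            rr, pp = stats.pearsonr(x, yv)
            r[i, j] = r[j, i] = rr
            p[i, j] = p[j, i] = pp
            if rr * rr > 0.90:
                strong.append((variables[i], variables[j]))
    rdf = pd.DataFrame(r, index=variables, columns=variables)
    pdf = pd.DataFrame(p, index=variables, columns=variables)
    sdf = pdf.map(_stars)
    np.fill_diagonal(sdf.values, "")
    return CorrelationMatrix(r=rdf, p=pdf, stars=sdf, strong_pairs=strong)


def latitude_richness_gam(data: pd.DataFrame, level: str = "site", k: int = 10) -> ModelFitResult:
    """Richness ~ s(latitude) at site or band level.

    ``level='site'`` uses per-site richness against ``Lat``; band levels use
    the band table (``mean_lat`` with observed ``S_obs`` or estimated
    ``S_est`` richness).
    """
    if level == "site":
        df = data[["Lat", "richness"]].dropna()
        lat_col = "Lat"
    elif level in ("band", "band_estimated"):
        resp = "S_obs" if level == "band" else "S_est"
        df = data[["mean_lat", resp]].dropna().rename(columns={resp: "richness"})
        lat_col = "mean_lat"
    else:
        raise ValueError(f"unknown level {level!r}")
    if len(df) < 5:
        raise ValueError("need at least 5 observations")
    k_eff = min(k, max(5, len(df) // 3))
    spec = ModelSpec(f"latitude ({level})", "Exploratory model", "complete",
                     "richness", [(lat_col, True)])
    return fit_gam(spec, df, k=k_eff)
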