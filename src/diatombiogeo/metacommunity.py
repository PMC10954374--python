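"""Elements of Metacommunity Structure (EMS).

Workflow: the incidence matrix (singletons removed) is reordered by
reciprocal averaging (the first non-trivial correspondence-analysis axis for
sites and species); three statistics are then tested against a fixed-margin
null ensemble generated by the sequential checkerboard-swap chain:

* coherence — embedded absences (gaps inside species ranges along the
  ordination); fewer than null means coherent species distributions;
* turnover — pairwise species replacements counted on range-filled matrices;
* boundary clumping — Morisita's index of the dispersion of range endpoints
  over ordered sites, tested against uniform with a chi-square.

The three outcomes feed a decision tree that labels the metacommunity
(Checkerboard, Random, Nested subtypes, Clementsian, Gleasonian, evenly
spaced, and their Quasi- variants when turnover is not significant).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class OrdinatedMatrix:
    matrix: np.ndarray        # binary, rows/cols in ordination order
    row_order: np.ndarray     # permutation of original row indices
    col_order: np.ndarray
    row_scores: np.ndarray    # first-axis scores, ordination order
    col_scores: np.ndarray
    row_ids: list = field(default_factory=list)
    col_ids: list = field(default_factory=list)


@dataclass
class EMSResult:
    embAbs: int
    null_mean: float
    null_sd: float
    z_coherence: float
    p_coherence: float
    turnover: int
    turn_null_mean: float
    turn_null_sd: float
    z_turnover: float
    p_turnover: float
    morisita: float
    p_clumping: float
    n_sim: int
    structure_label: str

    def to_dict(self) -> dict:
        return {
            "embAbs": self.embAbs,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "z_coherence": self.z_coherence,
            "p_coherence": self.p_coherence,
            "turnover": self.turnover,
            "turn_null_mean": self.turn_null_mean,
            "turn_null_sd": self.turn_null_sd,
            "z_turnover": self.z_turnover,
            "p_turnover": self.p_turnover,
            "morisita": self.morisita,
            "p_clumping": self.p_clumping,
            "n_sim": self.n_sim,
            "structure_label": self.structure_label,
        }


def prepare_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Counts -> incidence; drop singleton species (exactly one occurrence),
    then drop and report any rows left empty."""
    if matrix.size == 0:
        raise ValueError("empty community matrix")
    inc = (matrix.to_numpy() > 0).astype(int)
    occ = inc.sum(axis=0)
    keep_cols = occ >= 2
    if not keep_cols.any():
        raise ValueError("all species are singletons; nothing to ordinate")
    inc = inc[:, keep_cols]
    keep_rows = inc.sum(axis=1) > 0
    out = pd.DataFrame(
        inc[keep_rows],
        index=matrix.index[keep_rows],
        columns=matrix.columns[keep_cols],
    )
    out.attrs["dropped_species"] = list(matrix.columns[~keep_cols])
    out.attrs["dropped_sites"] = list(matrix.index[~keep_rows])
    return out


def reciprocal_averaging(
    matrix: pd.DataFrame | np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> OrdinatedMatrix:
    """First non-trivial correspondence-analysis axis by iterative averaging.

    Site scores are the weighted mean of their species' scores and vice versa;
    after each sweep the trivial (constant) axis is removed by weighted
    centering and the scores renormalized. Rows and columns are then sorted by
    score. The axis sign is fixed so that, of the two extreme-score sites, the
    lexicographically smaller id gets the negative score; ties break on
    original index.
    """
    if isinstance(matrix, pd.DataFrame):
        ids_r, ids_c = list(matrix.index), list(matrix.columns)
        M = matrix.to_numpy().astype(float)
    else:
        M = np.asarray(matrix, dtype=float)
        ids_r = list(range(M.shape[0]))
        ids_c = list(range(M.shape[1]))
    if (M.sum(axis=1) == 0).any() or (M.sum(axis=0) == 0).any():
        raise ValueError("matrix has an all-zero row or column margin")
    n, m = M.shape
    r = M.sum(axis=1)
    c = M.sum(axis=0)
    N = M.sum()

    x = np.arange(n, dtype=float)  # deterministic start
    x -= (r @ x) / N
    x /= np.sqrt((r * x * x).sum())
    ev = 0.0
    for _ in range(max_iter):
        v = (M.T @ x) / c
        x_new = (M @ v) / r
        x_new -= (r @ x_new) / N          # deflate trivial axis
        norm = np.sqrt((r * x_new * x_new).sum())
        if norm < 1e-14:
            raise RuntimeError("degenerate matrix: first axis collapsed")
        x_new /= norm
        delta = min(np.abs(x_new - x).max(), np.abs(x_new + x).max())
        x, ev = x_new, norm
        if delta < tol:
            break
    else:
        raise RuntimeError("reciprocal averaging did not converge")
    v = (M.T @ x) / c

    row_order = np.lexsort((np.arange(n), x))
    # sign convention on the extreme-score sites
    lo_id, hi_id = ids_r[row_order[0]], ids_r[row_order[-1]]
    if str(hi_id) < str(lo_id):
        x, v = -x, -v
        row_order = np.lexsort((np.arange(n), x))
    col_order = np.lexsort((np.arange(m), v))
    return OrdinatedMatrix(
        matrix=M[np.ix_(row_order, col_order)].astype(int),
        row_order=row_order,
        col_order=col_order,
        row_scores=x[row_order],
        col_scores=v[col_order],
        row_ids=[ids_r[i] for i in row_order],
        col_ids=[ids_c[j] for j in col_order],
    )


def _embedded_absences_cols(M: np.ndarray) -> int:
    """Zeros strictly between each column's first and last presence."""
    total = 0
    n = M.shape[0]
    idx = np.arange(n)
    for j in range(M.shape[1]):
        col = M[:, j]
        pres = idx[col > 0]
        if len(pres) >= 2:
            total += int((pres[-1] - pres[0] + 1) - len(pres))
    return total


def count_embedded_absences(om: OrdinatedMatrix | np.ndarray, mode: str = "both") -> int:
    """Embedded-absence count over species ranges (columns), site community
    extents (rows), or their sum (default)."""
    M = om.matrix if isinstance(om, OrdinatedMatrix) else np.asarray(om)
    if mode == "columns":
        return _embedded_absences_cols(M)
    if mode == "rows":
        return _embedded_absences_cols(M.T)
    if mode == "both":
        return _embedded_absences_cols(M) + _embedded_absences_cols(M.T)
    raise ValueError(f"unknown mode {mode!r}")


def swap_null(
    matrix: np.ndarray,
    n_sim: int,
    seed: int | None = None,
    burn_in: int = 30_000,
    thin: int = 1_000,
) -> Iterator[np.ndarray]:
    """Fixed-margin null stream via the sequential checkerboard-swap chain.

    Each step picks a random row pair and column pair; if the 2x2 submatrix is
    a checkerboard it is swapped, which preserves every row and column sum
    exactly. ``burn_in`` attempts precede the first emission and ``thin``
    attempts separate emissions. The chain is symmetric, so its stationary
    distribution is uniform over the fixed-margin configuration set.
    """
    M = np.array(matrix, dtype=np.int8, copy=True)
    n, m = M.shape
    if n < 2 or m < 2:
        raise ValueError("matrix too small for swaps")
    rng = np.random.default_rng(seed)
    if not _has_checkerboard(M):
        raise ValueError("no swappable 2x2 checkerboard submatrix; null test impossible")

    def run(attempts: int) -> None:
        rows = rng.integers(0, n, size=2 * attempts)
        cols = rng.integers(0, m, size=2 * attempts)
        for t in range(attempts):
            r1, r2 = rows[2 * t], rows[2 * t + 1]
            c1, c2 = cols[2 * t], cols[2 * t + 1]
            if r1 == r2 or c1 == c2:
                continue
            a, b, c, d = M[r1, c1], M[r1, c2], M[r2, c1], M[r2, c2]
            if a == d and b == c and a != b:
                M[r1, c1], M[r1, c2], M[r2, c1], M[r2, c2] = b, a, d, c

    run(burn_in)
    for _ in range(n_sim):
        run(thin)
        yield M.copy()


def _has_checkerboard(M: np.ndarray) -> bool:
    X = M.astype(np.int16)
    # rows i, j share a checkerboard iff (i has 1 where j has 0) and converse
    P = X @ (1 - X).T
    return bool(((P > 0) & (P.T > 0)).any())


def _fill_ranges(M: np.ndarray) -> np.ndarray:
    """Set embedded absences to presence within each species' range."""
    out = M.copy()
    n = M.shape[0]
    idx = np.arange(n)
    for j in range(M.shape[1]):
        pres = idx[M[:, j] > 0]
        if len(pres) >= 2:
            out[pres[0]:pres[-1] + 1, j] = 1
    return out


def turnover_statistic(M: np.ndarray) -> int:
    """Species-pair replacement count on the range-filled ordered matrix:
    Σ_{i<j} |sites with i not j| · |sites with j not i|."""
    R = _fill_ranges(np.asarray(M))
    n_i = R.sum(axis=0).astype(np.int64)
    O = R.T.astype(np.int64) @ R
    a = n_i[:, None] - O
    prod = a * a.T
    return int(np.triu(prod, k=1).sum())


def _null_stats(
    matrix: np.ndarray,
    n_sim: int,
    seed: int | None,
    burn_in: int,
    thin: int,
    mode: str,
    reordinate: bool,
) -> tuple[np.ndarray, np.ndarray]:
    emb = np.empty(n_sim)
    turn = np.empty(n_sim)
    for k, null in enumerate(swap_null(matrix, n_sim, seed=seed, burn_in=burn_in, thin=thin)):
        if reordinate:
            try:
                om = reciprocal_averaging(null)
                ordered = om.matrix
            except RuntimeError:
                ordered = null
        else:
            ordered = null
        emb[k] = count_embedded_absences(ordered, mode=mode)
        turn[k] = turnover_statistic(ordered)
    return emb, turn


def _z_p(obs: float, null: np.ndarray) -> tuple[float, float]:
    mu, sd = float(null.mean()), float(null.std(ddof=1))
    if sd == 0:
        raise ZeroDivisionError("null distribution has zero spread")
    z = (obs - mu) / sd
    return z, float(2 * stats.norm.sf(abs(z)))


def _null_values(nulls, statistic) -> np.ndarray:
    """Accept either precomputed null statistics or an iterable of null
    matrices (each re-ordinated before measuring)."""
    nulls = list(nulls)
    if nulls and np.ndim(nulls[0]) == 2:
        vals = []
        for nm in nulls:
            try:
                ordered = reciprocal_averaging(np.asarray(nm)).matrix
            except (RuntimeError, ValueError):
                ordered = np.asarray(nm)
            vals.append(statistic(ordered))
        return np.asarray(vals, dtype=float)
    return np.asarray(nulls, dtype=float)


def coherence_test(om: OrdinatedMatrix, null_matrices, mode: str = "both") -> tuple[int, float, float]:
    """(embAbs, z, p): negative z = fewer embedded absences than null
    (positive coherence). ``null_matrices`` may be raw null matrices or
    precomputed embedded-absence counts."""
    null_emb = _null_values(null_matrices, lambda M: count_embedded_absences(M, mode=mode))
    if len(null_emb) < 2:
        raise ValueError("need at least 2 null matrices")
    obs = count_embedded_absences(om, mode=mode)
    z, p = _z_p(obs, null_emb)
    return obs, z, p


def turnover_test(om: OrdinatedMatrix, null_matrices) -> tuple[int, float, float]:
    """(turnover, z, p): positive z = more replacements than null.
    ``null_matrices`` may be raw null matrices or precomputed statistics."""
    null_turn = _null_values(null_matrices, turnover_statistic)
    if len(null_turn) < 2:
        raise ValueError("need at least 2 null matrices")
    obs = turnover_statistic(om.matrix)
    z, p = _z_p(obs, null_turn)
    return obs, z, p


def boundary_clumping(om: OrdinatedMatrix | np.ndarray) -> tuple[float, float]:
    """Morisita index of range-boundary dispersion and its chi-square p.

    Boundaries are the first and last ordered-site positions of each filled
    species range; I = T·Σ nᵢ(nᵢ−1)/(N(N−1)) over the T ordered sites with nᵢ
    boundaries each, N boundaries total. I > 1 means clumped range edges.
    """
    M = om.matrix if isinstance(om, OrdinatedMatrix) else np.asarray(om)
    n, m = M.shape
    if m < 2:
        raise ValueError("need at least 2 species ranges")
    counts = np.zeros(n, dtype=np.int64)
    idx = np.arange(n)
    for j in range(m):
        pres = idx[M[:, j] > 0]
        if len(pres) == 0:
            continue
        counts[pres[0]] += 1
        counts[pres[-1]] += 1
    N = int(counts.sum())
    if N < 2:
        raise ValueError("fewer than 2 boundary events")
    I = n * float((counts * (counts - 1)).sum()) / (N * (N - 1))
    expected = N / n
    chisq = float(((counts - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chisq, df=n - 1))
    return I, p


def classify_structure(
    coh: tuple[float, float],
    turn: tuple[float, float],
    clump: tuple[float, float],
    alpha: float = 0.05,
) -> str:
    """Decision tree over (z, p) of coherence and turnover plus (I, p) of
    boundary clumping.

    Significant positive coherence z (an excess of embedded absences) is a
    checkerboard; non-significant coherence is random. Given coherence,
    significant positive turnover splits on clumping into Clementsian /
    Gleasonian / evenly spaced, significant negative turnover gives the
    nested subtypes, and non-significant turnover the Quasi- variants keyed
    on the turnover z sign.
    """
    z_c, p_c = coh
    z_t, p_t = turn
    I, p_I = clump

    if p_c >= alpha:
        return "Random"
    if z_c > 0:
        return "Checkerboard"

    if p_I < alpha:
        sub = "clumped" if I > 1 else "evenly spaced"
    else:
        sub = "random"

    if p_t < alpha:
        if z_t < 0:
            return f"Nested ({sub})"
        return {"clumped": "Clementsian", "random": "Gleasonian", "evenly spaced": "EvenlySpaced"}[sub]
    prefix = "Quasi-"
    if z_t < 0:
        return f"{prefix}Nested ({sub})"
    return prefix + {"clumped": "Clementsian", "random": "Gleasonian", "evenly spaced": "EvenlySpaced"}[sub]


def site_order_correlation(om: OrdinatedMatrix, covariate: pd.Series) -> tuple[float, float, int, float]:
    """Pearson correlation of ordination rank against a per-site covariate.

    Returns (r, t, df, p) with t = r·sqrt(df/(1−r²)), df = n − 2.
    """
    vals = covariate.reindex(om.row_ids).to_numpy(float)
    if np.isnan(vals).any():
        raise ValueError("covariate missing for some ordinated sites")
    ranks = np.arange(len(vals), dtype=float)
    if np.std(vals) == 0 or np.std(ranks) == 0:
        raise ValueError("zero variance")
    r, p = stats.pearsonr(ranks, vals)
    df = len(vals) - 2
    t = r * np.sqrt(df / (1 - r * r)) if abs(r) < 1 else np.inf * np.sign(r)
    return float(r), float(t), df, float(p)


def is_chain_nested(M: np.ndarray) -> bool:
    """True when site communities form a chain under set inclusion (every
    poorer community a subset of every richer one)."""
    M = np.asarray(M) > 0
    order = np.argsort(M.sum(axis=1))[::-1]
    R = M[order]
    for i in range(1, len(R)):
        # each row must be a subset of the previous (richer or equal) row
        if np.any(R[i] & ~R[i - 1]):
            return False
    return True


def ems_analysis(
    matrix: pd.DataFrame,
    n_sim: int = 1000,
    seed: int | None = None,
    burn_in: int = 30_000,
    thin: int = 1_000,
    mode: str = "both",
    reordinate_nulls: bool = True,
    alpha: float = 0.05,
) -> tuple[EMSResult, OrdinatedMatrix]:
    """Full EMS pipeline on a count or incidence matrix.

    Prepares the matrix (incidence, singleton removal), ordinates it, draws
    ``n_sim`` fixed-margin nulls (each re-ordinated by default before its
    statistics are measured), and runs the three tests and the classifier.

    A perfectly nested matrix is a degenerate case: its fixed-margin ensemble
    contains only the observed configuration (no 2x2 checkerboard exists), so
    the swap null cannot move. Nestedness then holds by definition and the
    result carries infinite-magnitude z scores through the nested branch of
    the classifier rather than a Monte Carlo comparison.
    """
    prepared = prepare_matrix(matrix)
    om = reciprocal_averaging(prepared)
    if is_chain_nested(prepared.to_numpy()):
        embAbs = count_embedded_absences(om, mode=mode)
        turn = turnover_statistic(om.matrix)
        I, p_I = boundary_clumping(om)
        label = classify_structure((-np.inf, 0.0), (-np.inf, 0.0), (I, p_I), alpha=alpha)
        result = EMSResult(
            embAbs=embAbs, null_mean=float(embAbs), null_sd=0.0,
            z_coherence=-np.inf, p_coherence=0.0,
            turnover=turn, turn_null_mean=float(turn), turn_null_sd=0.0,
            z_turnover=-np.inf, p_turnover=0.0,
            morisita=I, p_clumping=p_I, n_sim=0, structure_label=label,
        )
        return result, om
    null_emb, null_turn = _null_stats(
        prepared.to_numpy(), n_sim, seed, burn_in, thin, mode, reordinate_nulls,
    )
    embAbs, z_c, p_c = coherence_test(om, null_emb, mode=mode)
    turn, z_t, p_t = turnover_test(om, null_turn)
    I, p_I = boundary_clumping(om)
    label = classify_structure((z_c, p_c), (z_t, p_t), (I, p_I), alpha=alpha)
    result = EMSResult(
        embAbs=embAbs,
        null_mean=float(null_emb.mean()),
        null_sd=float(null_emb.std(ddof=1)),
        z_coherence=z_c,
        p_coherence=p_c,
        turnover=turn,
        turn_null_mean=float(null_turn.mean()),
        turn_null_sd=float(null_turn.std(ddof=1)),
        z_turnover=z_t,
        p_turnover=p_t,
        morisita=I,
        p_clumping=p_I,
        n_sim=n_sim,
        structure_label=label,
    )
    return result, om
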