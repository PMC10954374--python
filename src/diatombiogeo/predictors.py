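"""Predictor construction: limiting-resource ranks, glaciation exposure,
detection-limit handling, and latitudinal bands.

NLR (number of limiting resources) scores four resource variables — calcium,
total phosphorus, silica, and electrical conductivity as a base-cation proxy —
against their sample terciles: 2 below the 0.33 quantile (strongly limiting),
1 between the 0.33 and 0.66 quantiles, 0 above. The per-site sum is a 0–8
rank, 8 meaning all four resources scarce.

Glac is the proportion of the last 35 ka a site spent under the ice sheet,
computed from the most recent timestamp with ice as 1 − t_last/35; Fglac is
binary ice presence at the Last Glacial Maximum layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import ICE_TIMESTAMPS_KA

NLR_VARIABLES = ("Ca", "TP", "SiO2", "EC")

#: reconstruction layer(s) taken to represent the Last Glacial Maximum
DEFAULT_LGM_TIMESTAMPS = (20,)


def compute_nlr(
    chem: pd.DataFrame,
    variables: tuple[str, ...] = NLR_VARIABLES,
    lower_q: float = 0.33,
    upper_q: float = 0.66,
) -> tuple[pd.Series, list]:
    """Score niche dimensionality as the number of limiting resources.

    Quantiles are the linear-interpolation sample quantiles of the scored
    sites themselves (sites with any missing resource value are excluded and
    returned, never silently dropped). Values exactly on a quantile boundary
    score 1, i.e. the middle tercile is the closed interval [q_lower, q_upper].

    Returns ``(scores, excluded_site_ids)``.
    """
    missing = [v for v in variables if v not in chem.columns]
    if missing:
        raise KeyError(f"missing resource columns: {missing}")
    sub = chem.loc[:, list(variables)].astype(float)
    complete = sub.notna().all(axis=1)
    excluded = list(sub.index[~complete])
    if excluded:
        warnings.warn(f"compute_nlr: {len(excluded)} site(s) excluded for missing chemistry")
    scored = sub.loc[complete]
    if len(scored) < 3:
        raise ValueError("need at least 3 complete sites to estimate quantiles")
    total = np.zeros(len(scored), dtype=int)
    for v in variables:
        x = scored[v].to_numpy()
        ql, qu = np.quantile(x, [lower_q, upper_q])
        score = np.where(x < ql, 2, np.where(x > qu, 0, 1))
        total += score
    return pd.Series(total, index=scored.index, name="NLR"), excluded


def _validate_ice(ice: pd.DataFrame) -> pd.DataFrame:
    cols = [str(t) for t in ICE_TIMESTAMPS_KA]
    if list(ice.columns) != cols:
        try:
            ice = ice.loc[:, cols]
        except KeyError as exc:
            raise KeyError(f"ice history must have the nine timestamp columns {cols}") from exc
    vals = ice.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("ice presence must be binary")
    return ice


def compute_glac(ice: pd.DataFrame) -> pd.Series:
    """Proportion of the last 35 ka spent under ice: 1 − t_last/35.

    ``t_last`` is the most recent timestamp (smallest age) at which ice was
    present; sites never under ice score 0. With the nine reconstruction
    layers and no ice persisting past 10 ka, the maximum is 1 − 10/35 = 0.714.
    """
    ice = _validate_ice(ice)
    times = np.asarray(ICE_TIMESTAMPS_KA, dtype=float)
    vals = ice.to_numpy().astype(bool)
    glac = np.zeros(len(ice))
    any_ice = vals.any(axis=1)
    if any_ice.any():
        # columns are ordered old -> young; last True column = most recent ice
        last_idx = vals.shape[1] - 1 - vals[:, ::-1].argmax(axis=1)
        glac[any_ice] = 1.0 - times[last_idx[any_ice]] / 35.0
    return pd.Series(glac, index=ice.index, name="Glac")


def compute_fglac(
    ice: pd.DataFrame,
    lgm_timestamps: tuple[float, ...] = DEFAULT_LGM_TIMESTAMPS,
) -> pd.Series:
    """Binary ice presence at the configured Last-Glacial-Maximum layer(s)."""
    if not lgm_timestamps:
        raise ValueError("lgm_timestamps must be nonempty")
    ice = _validate_ice(ice)
    cols = [str(t) for t in lgm_timestamps]
    missing = [c for c in cols if c not in ice.columns]
    if missing:
        raise KeyError(f"timestamps not in ice history: {missing}")
    out = (ice.loc[:, cols].to_numpy().sum(axis=1) > 0).astype(int)
    return pd.Series(out, index=ice.index, name="Fglac")


def substitute_below_detection(
    values: pd.Series,
    flags: pd.Series,
    detection_limit: float,
    method: str = "half_dl",
    seed: int | None = None,
) -> pd.Series:
    """Replace below-detection-limit values with a value in (0, DL).

    ``half_dl`` substitutes DL/2 (deterministic); ``uniform_random`` draws
    uniformly on (0, DL) with the given seed. Non-flagged values pass through
    untouched.
    """
    if detection_limit <= 0:
        raise ValueError("detection_limit must be > 0")
    if method not in ("half_dl", "uniform_random"):
        raise ValueError(f"unknown method {method!r}")
    vals = values.astype(float).copy()
    if (vals.dropna() < 0).any():
        raise ValueError("negative measured values")
    flags = flags.reindex(values.index).fillna(False).astype(bool)
    n_flagged = int(flags.sum())
    if n_flagged == 0:
        return vals
    if method == "half_dl":
        vals.loc[flags] = detection_limit / 2.0
    else:
        rng = np.random.default_rng(seed)
        vals.loc[flags] = rng.uniform(0.0, detection_limit, size=n_flagged)
    return vals


@dataclass
class LatitudinalBand:
    """A contiguous run of sites along the latitudinal gradient."""

    band_id: int
    member_site_ids: list = field(default_factory=list)
    mean_lat: float = float("nan")
    extension: float = float("nan")
    n_sites: int = 0
    S_obs: int | None = None
    S_est: float | None = None
    S_est_lo: float | None = None
    S_est_hi: float | None = None


def build_latitudinal_bands(
    sites: pd.DataFrame,
    target_size: int = 12,
    isolation_gap: float = 1.0,
    min_extension: float = 0.0,
) -> list[LatitudinalBand]:
    """Partition sites into consecutive latitudinal bands of ~target_size.

    Sites are sorted south to north. Runs separated from their neighbours by
    more than ``isolation_gap`` degrees form their own bands regardless of
    size (the study's far-south five-site band is the motivating case). Within
    each run, sites are chunked greedily into groups of ``target_size``; a
    small remainder is rebalanced with the preceding chunk so band sizes stay
    near the target. Bands narrower than ``min_extension`` degrees are merged
    with their nearest neighbour within the run.
    """
    if len(sites) == 0:
        raise ValueError("need at least one site")
    order = sites["Lat"].sort_values(kind="mergesort")
    lats = order.to_numpy()
    ids = list(order.index)

    # split at isolation gaps
    breaks = [0]
    for i in range(1, len(lats)):
        if lats[i] - lats[i - 1] > isolation_gap:
            breaks.append(i)
    breaks.append(len(lats))

    bands: list[LatitudinalBand] = []
    bid = 0
    for s, e in zip(breaks[:-1], breaks[1:]):
        seg_ids = ids[s:e]
        seg_lats = lats[s:e]
        n = len(seg_ids)
        sizes: list[int]
        if n <= target_size:
            sizes = [n]
        else:
            n_full, rem = divmod(n, target_size)
            sizes = [target_size] * n_full
            if rem:
                if rem >= max(2, (3 * target_size) // 4):
                    sizes.append(rem)
                else:
                    # rebalance the last two chunks to near-equal sizes
                    pool = sizes.pop() + rem
                    sizes.extend([(pool + 1) // 2, pool // 2])
        # chunk, then merge narrow bands with a neighbour
        chunks: list[tuple[list, np.ndarray]] = []
        pos = 0
        for sz in sizes:
            chunks.append((seg_ids[pos:pos + sz], seg_lats[pos:pos + sz]))
            pos += sz
        if min_extension > 0 and len(chunks) > 1:
            merged: list[tuple[list, np.ndarray]] = []
            for chunk in chunks:
                if merged and (chunk[1].max() - chunk[1].min()) < min_extension:
                    prev = merged.pop()
                    merged.append((prev[0] + chunk[0], np.concatenate([prev[1], chunk[1]])))
                else:
                    merged.append(chunk)
            chunks = merged
        for member_ids, member_lats in chunks:
            bands.append(LatitudinalBand(
                band_id=bid,
                member_site_ids=list(member_ids),
                mean_lat=float(np.mean(member_lats)),
                extension=float(member_lats.max() - member_lats.min()),
                n_sites=len(member_ids),
            ))
            bid += 1
    return bands


def bands_to_frame(bands: list[LatitudinalBand]) -> pd.DataFrame:
    """One row per band: id, mean latitude, extension, size, richness columns."""
    return pd.DataFrame([
        {
            "band_id": b.band_id,
            "mean_lat": b.mean_lat,
            "extension": b.extension,
            "n_sites": b.n_sites,
            "S_obs": b.S_obs,
            "S_est": b.S_est,
            "S_est_lo": b.S_est_lo,
            "S_est_hi": b.S_est_hi,
        }
        for b in bands
    ])
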