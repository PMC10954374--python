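"""CSV interchange for the three tables: sites, community, ice history.

Sites CSVs may encode below-detection-limit values as ``<0.1`` strings (the
value is the detection limit) or with companion ``<var>_below_dl`` columns;
``load_sites`` returns the numeric table plus an aligned boolean flag frame.
``CE`` is accepted as an alias of ``EC`` (electrical conductivity appears
under both abbreviations in field datasets).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import ICE_TIMESTAMPS_KA

COLUMN_ALIASES = {"CE": "EC"}


def _parse_cell(value):
    """Return (numeric value, below_dl flag); '<x' stores the DL as value."""
    if isinstance(value, str):
        s = value.strip()
        if s.startswith("<"):
            return float(s[1:]), True
        if s == "":
            return np.nan, False
        return float(s), False
    return value, False


def load_sites(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a sites CSV keyed by ``site_id``.

    Returns ``(sites, below_dl_flags)``. Unparseable cells raise with their
    row number; duplicate site ids are an error.
    """
    raw = pd.read_csv(path, dtype=str)
    if "site_id" not in raw.columns:
        raise ValueError("sites CSV must have a site_id column")
    raw = raw.rename(columns=COLUMN_ALIASES)
    if raw["site_id"].duplicated().any():
        dups = raw.loc[raw["site_id"].duplicated(), "site_id"].tolist()
        raise ValueError(f"duplicate site ids: {dups[:5]}")

    companion = [c for c in raw.columns if c.endswith("_below_dl")]
    value_cols = [c for c in raw.columns if c != "site_id" and c not in companion]
    data = {}
    flags = {}
    for col in value_cols:
        if col == "chem":
            data[col] = raw[col].map(lambda s: str(s).strip().lower() in ("true", "1"))
            continue
        vals = np.empty(len(raw))
        flg = np.zeros(len(raw), dtype=bool)
        for i, cell in enumerate(raw[col]):
            try:
                vals[i], flg[i] = _parse_cell(cell)
            except ValueError as exc:
                raise ValueError(f"unparseable value {cell!r} in column {col}, row {i + 2}") from exc
        data[col] = vals
        flags[col] = flg
    for comp in companion:
        base = comp[: -len("_below_dl")]
        if base in flags:
            flags[base] |= raw[comp].astype(float).fillna(0).astype(bool).to_numpy()
    sites = pd.DataFrame(data, index=pd.Index(raw["site_id"], name="site_id"))
    flag_df = pd.DataFrame(flags, index=sites.index).reindex(columns=sites.columns, fill_value=False)
    return sites, flag_df


def write_sites(sites: pd.DataFrame, path, flags: pd.DataFrame | None = None) -> None:
    """Write the sites CSV, re-encoding flagged cells as ``<DL`` notation so a
    round trip preserves both values and flags."""
    out = sites.copy().astype(object)
    if flags is not None:
        for col in sites.columns:
            if col in flags.columns:
                mask = flags[col].reindex(sites.index).fillna(False).astype(bool)
                out.loc[mask, col] = ["<" + repr(float(v)) for v in sites.loc[mask, col]]
    out.to_csv(path, index=True)


def load_community(path) -> pd.DataFrame:
    """Sites-by-species count matrix; first column is the site id."""
    df = pd.read_csv(path, index_col=0)
    df.index.name = "site_id"
    mat = df.to_numpy()
    if not np.isfinite(mat).all():
        raise ValueError("community matrix has missing values")
    if (mat < 0).any():
        raise ValueError("negative counts in community matrix")
    if (mat != np.round(mat)).any():
        raise ValueError("non-integer counts in community matrix")
    return df.astype(int)


def write_community(community: pd.DataFrame, path) -> None:
    community.to_csv(path, index=True)


def load_ice(path) -> pd.DataFrame:
    """Ice-history CSV: site_id plus one binary column per timestamp."""
    df = pd.read_csv(path, index_col=0)
    df.index.name = "site_id"
    cols = [str(t) for t in ICE_TIMESTAMPS_KA]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"ice CSV missing timestamp columns: {missing}")
    return df.loc[:, cols].astype(int)


def write_ice(ice: pd.DataFrame, path) -> None:
    ice.to_csv(path, index=True)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
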