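"""Survey-level sibship summaries: per-tow tables, cohort composition,
and intra-pair geographic distances."""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "haversine_km",
    "tabulate_by_tow",
    "sibship_summary",
    "pair_distances",
]

EARTH_RADIUS_KM = 6371.0


def haversine_km(lon1, lat1, lon2, lat2) -> float:
    """Great-circle distance between two points (decimal degrees) in km."""
    lon1, lat1, lon2, lat2 = map(math.radians, (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = math.sin(dlat / 2) ** 2 + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def _pair_iter(kin_pairs: pd.DataFrame, classes=("FSP", "HSP")):
    for row in kin_pairs.itertuples(index=False):
        if row.kin_class in classes:
            yield row


def tabulate_by_tow(kin_pairs: pd.DataFrame, sample_meta: pd.DataFrame) -> pd.DataFrame:
    """Per-tow sibling-pair counts.

    A within-tow pair increments that tow's ``intra_*`` column once; a
    pair spanning two tows of the same cohort increments the ``inter_*``
    column of *both* tows; a cross-cohort HSP increments ``cross_hsp`` of
    both tows (this double-counting convention is declared here rather
    than left implicit).
    """
    meta = sample_meta.set_index("sample_id")
    missing = set()
    for col in ("tow_id", "cohort_year"):
        if col not in meta.columns:
            raise ValueError(f"sample metadata lacks {col!r}")
    tows = (
        sample_meta.groupby("tow_id")
        .agg(
            lon=("lon", "first"),
            lat=("lat", "first"),
            n_retained=("sample_id", "count"),
            cohort_year=("cohort_year", "first"),
        )
        .reset_index()
    )
    cols = ["intra_fsp", "intra_hsp", "inter_fsp", "inter_hsp", "cross_hsp"]
    counts = {t: dict.fromkeys(cols, 0) for t in tows["tow_id"]}
    for row in _pair_iter(kin_pairs):
        for s in (row.sample_i, row.sample_j):
            if s not in meta.index:
                missing.add(s)
        if missing:
            raise ValueError(f"samples without tow assignment: {sorted(missing)[:5]}")
        ti, tj = meta.loc[row.sample_i, "tow_id"], meta.loc[row.sample_j, "tow_id"]
        ci, cj = meta.loc[row.sample_i, "cohort_year"], meta.loc[row.sample_j, "cohort_year"]
        low = row.kin_class.lower()
        if ci != cj:
            if row.kin_class == "HSP":
                counts[ti]["cross_hsp"] += 1
                counts[tj]["cross_hsp"] += 1
            continue
        if ti == tj:
            counts[ti][f"intra_{low}"] += 1
        else:
            counts[ti][f"inter_{low}"] += 1
            counts[tj][f"inter_{low}"] += 1
    for col in cols:
        tows[col] = [counts[t][col] for t in tows["tow_id"]]
    return tows


def sibship_summary(kin_pairs: pd.DataFrame, sample_meta: pd.DataFrame) -> pd.DataFrame:
    """Per-cohort counts of larvae by sibling status.

    Categories (mutually exclusive, exhaustive): no sibling, half-sibs
    only, both full- and half-sibs, full-sibs only -- judged from
    within-cohort partners; cross-cohort half-siblings do not confer
    sibling status here, which reproduces the per-cohort arithmetic of
    the published summary exactly.
    """
    meta = sample_meta.set_index("sample_id")
    has_fs: dict = {}
    has_hs: dict = {}
    for row in _pair_iter(kin_pairs):
        ci = meta.loc[row.sample_i, "cohort_year"]
        cj = meta.loc[row.sample_j, "cohort_year"]
        if ci != cj:
            continue
        d = has_fs if row.kin_class == "FSP" else has_hs
        d[row.sample_i] = True
        d[row.sample_j] = True
    rows = []
    for cohort, group in sample_meta.groupby("cohort_year"):
        ids = group["sample_id"]
        fs = ids.map(lambda s: has_fs.get(s, False))
        hs = ids.map(lambda s: has_hs.get(s, False))
        n = len(ids)
        n_none = int((~fs & ~hs).sum())
        rows.append(
            {
                "cohort": cohort,
                "n_none": n_none,
                "n_hs_no_fs": int((hs & ~fs).sum()),
                "n_fs_and_hs": int((fs & hs).sum()),
                "n_fs_no_hs": int((fs & ~hs).sum()),
                "total": n,
                "fraction_with_sibling": (n - n_none) / n if n else 0.0,
            }
        )
    return pd.DataFrame(rows)


def summary_from_counts(cohort, n_none, n_hs_no_fs, n_fs_and_hs, n_fs_no_hs) -> dict:
    """Sibling-status summary row computed from printed category counts."""
    total = n_none + n_hs_no_fs + n_fs_and_hs + n_fs_no_hs
    return {
        "cohort": cohort,
        "n_none": n_none,
        "n_hs_no_fs": n_hs_no_fs,
        "n_fs_and_hs": n_fs_and_hs,
        "n_fs_no_hs": n_fs_no_hs,
        "total": total,
        "fraction_with_sibling": (total - n_none) / total,
    }


def pair_distances(
    kin_pairs: pd.DataFrame,
    sample_meta: pd.DataFrame,
    classes=("FSP", "HSP", "UP"),
) -> pd.DataFrame:
    """Great-circle distance (km) between the tow positions of each pair.

    Within-tow pairs are at distance zero by construction.  Pairs whose
    tow coordinates are missing are excluded with a warning.
    """
    meta = sample_meta.set_index("sample_id")
    rows = []
    n_dropped = 0
    sub = kin_pairs[kin_pairs["kin_class"].isin(classes)]
    for row in sub.itertuples(index=False):
        a, b = meta.loc[row.sample_i], meta.loc[row.sample_j]
        coords = [a["lon"], a["lat"], b["lon"], b["lat"]]
        if any(pd.isna(c) for c in coords):
            n_dropped += 1
            continue
        if a["tow_id"] == b["tow_id"]:
            dist = 0.0
        else:
            dist = haversine_km(*coords)
        rows.append(
            {
                "sample_i": row.sample_i,
                "sample_j": row.sample_j,
                "kin_class": row.kin_class,
                "distance_km": dist,
            }
        )
    if n_dropped:
        warnings.warn(f"{n_dropped} pair(s) dropped for missing coordinates", stacklevel=2)
    return pd.DataFrame(rows, columns=["sample_i", "sample_j", "kin_class", "distance_km"])
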