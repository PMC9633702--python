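"""CSV dialects for every artifact the pipeline reads or writes.

All tables are plain CSV with mandatory headers; missing genotype calls
are written as the literal token ``NA``.  Every writer/reader pair is a
round-trip identity.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    LOCUS_COLUMNS,
    MISSING,
    SAMPLE_META_COLUMNS,
    GenotypeMatrix,
    LocusSet,
    SchemaError,
    validate_sample_meta,
)

__all__ = [
    "write_genotypes",
    "read_genotypes",
    "write_loci",
    "read_loci",
    "write_sample_meta",
    "read_sample_meta",
    "write_kin_pairs",
    "read_kin_pairs",
    "write_tabulation",
    "read_tabulation",
    "write_truth",
    "read_truth",
]

NA = "NA"


def write_genotypes(geno: GenotypeMatrix, path) -> None:
    """Genotype matrix CSV: rows = samples, columns = loci, values 0/1/2/NA."""
    df = pd.DataFrame(geno.calls, index=geno.sample_ids, columns=geno.locus_ids)
    df = df.astype(object).where(df != MISSING, NA)
    df.index.name = "sample_id"
    df.to_csv(path)


def read_genotypes(path) -> GenotypeMatrix:
    df = pd.read_csv(path, index_col=0, keep_default_na=False, na_values=[NA], dtype=str)
    try:
        calls = df.apply(pd.to_numeric).fillna(MISSING).to_numpy(dtype=np.int8)
    except ValueError as err:
        raise SchemaError(f"{path}: non-genotype value in matrix: {err}") from err
    return GenotypeMatrix(df.index.to_numpy(object), df.columns.to_numpy(object), calls)


def write_loci(loci: LocusSet, path) -> None:
    loci.table.to_csv(path, index=False)


def read_loci(path) -> LocusSet:
    tab = pd.read_csv(path)
    missing = [c for c in LOCUS_COLUMNS if c not in tab.columns]
    if missing:
        raise SchemaError(f"{path}: locus table missing columns {missing}")
    tab["polyploid_flag"] = tab["polyploid_flag"].astype(bool)
    return LocusSet(tab)


def write_sample_meta(meta: pd.DataFrame, path) -> None:
    validate_sample_meta(meta).to_csv(path, index=False)


def read_sample_meta(path) -> pd.DataFrame:
    meta = pd.read_csv(path)
    missing = [c for c in SAMPLE_META_COLUMNS if c not in meta.columns]
    if missing:
        raise SchemaError(f"{path}: sample table missing columns {missing}")
    return meta


KIN_COLUMNS = ("sample_i", "sample_j", "plod", "n_shared_loci", "kin_class")


def write_kin_pairs(pairs: pd.DataFrame, path) -> None:
    missing = [c for c in KIN_COLUMNS if c not in pairs.columns]
    if missing:
        raise SchemaError(f"kin-pair table missing columns {missing}")
    pairs.loc[:, KIN_COLUMNS].to_csv(path, index=False)


def read_kin_pairs(path) -> pd.DataFrame:
    pairs = pd.read_csv(path)
    missing = [c for c in KIN_COLUMNS if c not in pairs.columns]
    if missing:
        raise SchemaError(f"{path}: kin-pair table missing columns {missing}")
    return pairs


def write_tabulation(tabs: list, path) -> None:
    """Tabulation CSV: one row per (cohort, s) with count g_s."""
    pd.concat([t.to_frame() for t in tabs], ignore_index=True).to_csv(path, index=False)


def read_tabulation(path) -> list:
    from .sibgraph import DPGTabulation

    df = pd.read_csv(path)
    for col in ("cohort", "s", "g_s"):
        if col not in df.columns:
            raise SchemaError(f"{path}: tabulation missing column {col!r}")
    out = []
    for cohort, grp in df.groupby("cohort", sort=True):
        smax = int(grp["s"].max())
        g = np.zeros(smax, dtype=np.int64)
        for _, row in grp.iterrows():
            g[int(row["s"]) - 1] = int(row["g_s"])
        m_j = int((np.arange(1, smax + 1) * g).sum()) // 2
        out.append(DPGTabulation(cohort, g, m_j))
    return out


def write_truth(larvae: pd.DataFrame, path) -> None:
    larvae.loc[:, ["larva_id", "mother_id", "father_id", "birth_night"]].to_csv(
        path, index=False
    )


def read_truth(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = ["larva_id", "mother_id", "father_id", "birth_night"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: truth table missing columns {missing}")
    return df


def ensure_outdir(path) -> Path:
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    return out
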