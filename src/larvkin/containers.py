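"""Core in-memory containers shared by every analysis stage.

Genotypes are biallelic SNP calls coded as the number of copies of the
alternate allele (0, 1, 2) with ``-1`` for a missing call.  Per-locus
metadata (fragment of origin, allele frequency, read depth, ploidy flag)
travels in a :class:`LocusSet`; per-sample metadata (tow, coordinates,
cohort) travels as a plain :class:`pandas.DataFrame` with a fixed schema.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1  # sentinel for a missing genotype call

#: mandatory columns of a sample-metadata frame
SAMPLE_META_COLUMNS = (
    "sample_id",
    "tow_id",
    "lon",
    "lat",
    "date",
    "cohort_year",
    "species",
)


class SchemaError(ValueError):
    """A delimited-text table does not match its declared schema."""


@dataclass
class GenotypeMatrix:
    """Samples x loci matrix of biallelic calls.

    Parameters
    ----------
    sample_ids :
        Row labels, one per sample.
    locus_ids :
        Column labels, one per locus.
    calls :
        ``int8`` array of shape ``(n_samples, n_loci)`` with values in
        ``{0, 1, 2, -1}``; ``-1`` marks a missing call.
    """

    sample_ids: np.ndarray
    locus_ids: np.ndarray
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.locus_ids = np.asarray(self.locus_ids, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sample_ids), len(self.locus_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.locus_ids)} loci"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype calls must be 0, 1, 2 or -1 (missing)")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask of non-missing calls."""
        return self.calls != MISSING

    def missing_fraction(self) -> np.ndarray:
        """Per-sample fraction of missing calls."""
        return 1.0 - self.observed.mean(axis=1)

    def take_samples(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(self.sample_ids[index], self.locus_ids, self.calls[index])

    def take_loci(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(self.sample_ids, self.locus_ids[index], self.calls[:, index])

    def sample_index(self, sample_id) -> int:
        hits = np.nonzero(self.sample_ids == sample_id)[0]
        if len(hits) != 1:
            raise KeyError(f"sample {sample_id!r} not found exactly once")
        return int(hits[0])


LOCUS_COLUMNS = ("locus_id", "fragment_id", "p", "maf", "mean_depth", "polyploid_flag")


@dataclass
class LocusSet:
    """Per-locus metadata table.

    ``table`` must carry the columns of :data:`LOCUS_COLUMNS`; ``p`` is the
    alternate-allele frequency and ``maf = min(p, 1 - p)``.  A
    ``reproducibility`` column (fraction of concordant technical-replicate
    calls) is optional.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in LOCUS_COLUMNS if c not in self.table.columns]
        if missing:
            raise SchemaError(f"locus table missing columns: {missing}")
        self.table = self.table.reset_index(drop=True)
        p = self.table["p"].to_numpy(dtype=float)
        maf = self.table["maf"].to_numpy(dtype=float)
        ok = np.isnan(p) | (np.abs(np.minimum(p, 1.0 - p) - maf) < 1e-9)
        if not ok.all():
            raise ValueError("maf inconsistent with p at some loci")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def locus_ids(self) -> np.ndarray:
        return self.table["locus_id"].to_numpy(dtype=object)

    @property
    def p(self) -> np.ndarray:
        return self.table["p"].to_numpy(dtype=float)

    def subset(self, mask_or_index) -> "LocusSet":
        return LocusSet(self.table.iloc[np.asarray(mask_or_index).nonzero()[0]
                                        if np.asarray(mask_or_index).dtype == bool
                                        else mask_or_index].reset_index(drop=True))

    def align_to(self, geno: GenotypeMatrix) -> "LocusSet":
        """Reorder/subset the table to match ``geno.locus_ids`` exactly."""
        tab = self.table.set_index("locus_id")
        missing = [l for l in geno.locus_ids if l not in tab.index]
        if missing:
            raise KeyError(f"loci without metadata: {missing[:5]}")
        out = tab.loc[list(geno.locus_ids)].reset_index()
        return LocusSet(out)


def validate_sample_meta(meta: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SAMPLE_META_COLUMNS if c not in meta.columns]
    if missing:
        raise SchemaError(f"sample table missing columns: {missing}")
    return meta.reset_index(drop=True)
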