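"""Locus- and sample-level quality control for genotyping-by-sequencing calls.

The pipeline order is fixed: locus filters (MAF, depth, ploidy) ->
secondary-SNP thinning (one SNP per sequenced fragment) -> allele-frequency
estimation on the heterozygosity-interquartile subset -> duplicate-sample
removal -> sample-outlier removal (genotype likelihood and observed/expected
heterozygosity).  Every stage reports removed/retained counts and is
idempotent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, LocusSet

__all__ = [
    "QCReport",
    "OutlierPolicy",
    "filter_loci",
    "thin_secondary_snps",
    "estimate_allele_freqs",
    "find_duplicates",
    "filter_sample_outliers",
    "replicate_concordance",
    "run_qc",
]


@dataclass
class QCReport:
    """Per-stage removal bookkeeping: removed + retained = input, always."""

    stages: list = field(default_factory=list)

    def add(self, stage: str, threshold, n_input: int, n_removed: int) -> None:
        if n_removed < 0 or n_removed > n_input:
            raise ValueError(f"stage {stage}: removed {n_removed} of {n_input}")
        self.stages.append(
            {
                "stage": stage,
                "threshold": threshold,
                "n_input": n_input,
                "n_removed": n_removed,
                "n_retained": n_input - n_removed,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.stages,
            columns=["stage", "threshold", "n_input", "n_removed", "n_retained"],
        )

    def extend(self, other: "QCReport") -> None:
        self.stages.extend(other.stages)


def filter_loci(
    geno: GenotypeMatrix,
    loci: LocusSet,
    maf_min: float = 0.05,
    depth_min: float = 25.0,
) -> tuple[GenotypeMatrix, LocusSet, QCReport]:
    """Drop uninformative loci: MAF strictly below ``maf_min``, mean read
    depth strictly below ``depth_min``, and polyploid-flagged loci.

    Boundary semantics are strict-inequality removal: a locus at exactly
    ``maf_min`` or ``depth_min`` is retained.
    """
    loci = loci.align_to(geno)
    tab = loci.table
    report = QCReport()
    n = len(tab)

    low_maf = tab["maf"].to_numpy(dtype=float) < maf_min
    report.add("locus_maf", maf_min, n, int(low_maf.sum()))
    low_depth = tab["mean_depth"].to_numpy(dtype=float) < depth_min
    report.add("locus_depth", depth_min, n, int(low_depth.sum()))
    poly = tab["polyploid_flag"].to_numpy(dtype=bool)
    report.add("locus_polyploid", True, n, int(poly.sum()))

    keep = ~(low_maf | low_depth | poly)
    report.add("locus_filters_combined", None, n, int((~keep).sum()))
    return geno.take_loci(np.nonzero(keep)[0]), loci.subset(np.nonzero(keep)[0]), report


def thin_secondary_snps(
    loci: LocusSet, mode: str = "random", seed: int = 0, geno: GenotypeMatrix | None = None
) -> LocusSet:
    """Retain exactly one SNP per sequenced fragment.

    ``random`` mode keeps a seeded uniform draw within each fragment;
    ``best_callrate`` keeps the locus with the fewest missing calls
    (requires ``geno``), breaking ties by locus order.
    """
    tab = loci.table
    rng = np.random.default_rng(seed)
    keep = np.zeros(len(tab), dtype=bool)
    if mode == "best_callrate":
        if geno is None:
            raise ValueError("best_callrate thinning needs the genotype matrix")
        aligned = loci.align_to(geno)
        callrate = pd.Series(
            (geno.calls != MISSING).mean(axis=0), index=aligned.table["locus_id"]
        )
    for _, idx in sorted(tab.groupby("fragment_id").indices.items()):
        idx = np.sort(idx)
        if mode == "random":
            keep[rng.choice(idx)] = True
        elif mode == "best_callrate":
            rates = callrate.loc[tab["locus_id"].iloc[idx]].to_numpy()
            keep[idx[int(np.argmax(rates))]] = True
        else:
            raise ValueError(f"unknown thinning mode {mode!r}")
    return loci.subset(np.nonzero(keep)[0])


def _mean_heterozygosity(geno: GenotypeMatrix) -> np.ndarray:
    obs = geno.observed
    het = (geno.calls == 1) & obs
    with np.errstate(invalid="ignore"):
        return np.where(obs.sum(axis=1) > 0, het.sum(axis=1) / obs.sum(axis=1), np.nan)


def estimate_allele_freqs(geno: GenotypeMatrix, loci: LocusSet | None = None) -> LocusSet:
    """Estimate per-locus alternate-allele frequencies.

    Samples whose mean observed heterozygosity lies outside the sample
    interquartile range [Q1, Q3] are temporarily excluded (candidates for
    cross-contamination above Q3, degradation below Q1); frequencies are
    estimated on the remaining middle set as
    ``p = alt-allele count / (2 x non-missing samples)`` per locus, and
    every sample is re-incorporated afterwards.  Loci with no usable call
    in the middle set get ``p = NaN`` and are excluded downstream.
    """
    if geno.n_samples < 4:
        raise ValueError("allele-frequency estimation needs at least 4 samples")
    het = _mean_heterozygosity(geno)
    q1, q3 = np.nanquantile(het, [0.25, 0.75])
    middle = (het >= q1) & (het <= q3)

    calls = geno.calls[middle]
    obs = calls != MISSING
    n_obs = obs.sum(axis=0)
    alt = np.where(obs, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_obs > 0, alt / (2.0 * n_obs), np.nan)

    if loci is not None:
        tab = loci.align_to(geno).table.copy()
    else:
        tab = pd.DataFrame(
            {
                "locus_id": geno.locus_ids,
                "fragment_id": geno.locus_ids,
                "mean_depth": np.nan,
                "polyploid_flag": False,
            }
        )
    tab["p"] = p
    tab["maf"] = np.minimum(p, 1.0 - p)
    return LocusSet(tab)


def find_duplicates(
    geno: GenotypeMatrix,
    concordance_min: float = 0.95,
    min_shared_loci: int = 100,
) -> list[tuple[str, str, float, str]]:
    """Find inadvertently duplicated samples by pairwise call concordance.

    Returns ``(sample_i, sample_j, concordance, marked_for_removal)``
    tuples for pairs whose concordance over co-observed loci is at least
    ``concordance_min``; the member with more missing data is the one
    marked.  Pairs with fewer than ``min_shared_loci`` co-observed loci
    are not called (a warning is issued).
    """
    obs = geno.observed
    shared = obs.astype(np.int32) @ obs.T.astype(np.int32)
    match = np.zeros_like(shared)
    for g in (0, 1, 2):
        ind = ((geno.calls == g) & obs).astype(np.int32)
        match += ind @ ind.T
    n = geno.n_samples
    iu = np.triu_indices(n, k=1)
    out = []
    thin_pairs = (shared[iu] < min_shared_loci).sum()
    if thin_pairs:
        warnings.warn(
            f"{thin_pairs} pair(s) with < {min_shared_loci} co-observed loci "
            "excluded from duplicate calling",
            stacklevel=2,
        )
    miss = geno.missing_fraction()
    with np.errstate(invalid="ignore", divide="ignore"):
        conc = np.where(shared > 0, match / np.maximum(shared, 1), 0.0)
    hit = (conc[iu] >= concordance_min) & (shared[iu] >= min_shared_loci)
    for a, b in zip(iu[0][hit], iu[1][hit]):
        drop = geno.sample_ids[a] if miss[a] >= miss[b] else geno.sample_ids[b]
        out.append(
            (str(geno.sample_ids[a]), str(geno.sample_ids[b]), float(conc[a, b]), str(drop))
        )
    return out


HWE_LOG_FLOOR = 1e-12


@dataclass(frozen=True)
class OutlierPolicy:
    """Robust-z thresholds for the two per-sample outlier statistics.

    A sample is removed when its robust z-score (median +/- z * scaled
    MAD) is beyond threshold on (a) mean per-locus genotype log-probability
    under HWE (low side only: improbable genotypes, e.g. wrong species) or
    (b) observed/expected heterozygosity ratio (high side: contamination;
    low side: degradation).
    """

    z_loglik: float = 3.5
    z_het_high: float = 3.5
    z_het_low: float = 3.5


def _robust_z(x: np.ndarray) -> np.ndarray:
    med = np.nanmedian(x)
    mad = np.nanmedian(np.abs(x - med)) * 1.4826
    if mad == 0 or np.isnan(mad):
        return np.zeros_like(x)
    return (x - med) / mad


def sample_outlier_stats(geno: GenotypeMatrix, loci: LocusSet) -> pd.DataFrame:
    """Per-sample mean HWE genotype log-probability and het ratio."""
    loci = loci.align_to(geno)
    p = loci.p
    usable = np.isfinite(p) & (p > 0) & (p < 1)
    calls = geno.calls[:, usable]
    p = p[usable]
    hwe = np.stack([(1 - p) ** 2, 2 * p * (1 - p), p**2])  # (3, L)
    log_hwe = np.log(np.maximum(hwe, HWE_LOG_FLOOR))
    obs = calls != MISSING
    n_obs = obs.sum(axis=1)
    logp = np.zeros(geno.n_samples)
    for g in (0, 1, 2):
        mask = (calls == g) & obs
        logp += mask @ log_hwe[g]
    exp_het_l = 2 * p * (1 - p)
    obs_het = ((calls == 1) & obs).sum(axis=1)
    exp_het = obs @ exp_het_l
    with np.errstate(invalid="ignore", divide="ignore"):
        return pd.DataFrame(
            {
                "sample_id": geno.sample_ids,
                "mean_loglik": np.where(n_obs > 0, logp / np.maximum(n_obs, 1), np.nan),
                "het_ratio": np.where(exp_het > 0, obs_het / np.maximum(exp_het, 1e-12), np.nan),
            }
        )


def filter_sample_outliers(
    geno: GenotypeMatrix, loci: LocusSet, policy: OutlierPolicy = OutlierPolicy()
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove genotype-likelihood and heterozygosity outlier samples."""
    stats = sample_outlier_stats(geno, loci)
    z_ll = _robust_z(stats["mean_loglik"].to_numpy())
    z_het = _robust_z(stats["het_ratio"].to_numpy())

    bad_ll = z_ll < -policy.z_loglik
    bad_het_high = z_het > policy.z_het_high
    bad_het_low = z_het < -policy.z_het_low

    report = QCReport()
    n = geno.n_samples
    report.add("sample_loglik_outlier", policy.z_loglik, n, int(bad_ll.sum()))
    report.add("sample_het_high", policy.z_het_high, n, int(bad_het_high.sum()))
    report.add("sample_het_low", policy.z_het_low, n, int(bad_het_low.sum()))
    keep = ~(bad_ll | bad_het_high | bad_het_low)
    report.add("sample_outliers_combined", None, n, int((~keep).sum()))
    return geno.take_samples(np.nonzero(keep)[0]), report


def replicate_concordance(
    geno: GenotypeMatrix, replicate_pairs: list[tuple[str, str]]
) -> tuple[pd.Series, pd.Series]:
    """Technical-replicate reproducibility.

    Returns (per-locus fraction of concordant replicate calls, per-sample
    fraction of loci concordant with its replicate).  Calls missing in
    either member are excluded from the denominator.
    """
    if not replicate_pairs:
        return (
            pd.Series(dtype=float, name="locus_reproducibility"),
            pd.Series(dtype=float, name="sample_reproducibility"),
        )
    n_loci = geno.n_loci
    conc = np.zeros(n_loci)
    denom = np.zeros(n_loci)
    per_sample = {}
    for a, b in replicate_pairs:
        ia, ib = geno.sample_index(a), geno.sample_index(b)
        ga, gb = geno.calls[ia], geno.calls[ib]
        both = (ga != MISSING) & (gb != MISSING)
        same = both & (ga == gb)
        conc += same
        denom += both
        frac = same.sum() / both.sum() if both.sum() else np.nan
        per_sample[a] = frac
        per_sample[b] = frac
    with np.errstate(invalid="ignore", divide="ignore"):
        per_locus = pd.Series(
            np.where(denom > 0, conc / np.maximum(denom, 1), np.nan),
            index=geno.locus_ids,
            name="locus_reproducibility",
        )
    return per_locus, pd.Series(per_sample, name="sample_reproducibility")


def run_qc(
    geno: GenotypeMatrix,
    loci: LocusSet,
    maf_min: float = 0.05,
    depth_min: float = 25.0,
    thin_mode: str = "random",
    dup_concordance: float = 0.95,
    outlier_policy: OutlierPolicy = OutlierPolicy(),
    seed: int = 0,
) -> tuple[GenotypeMatrix, LocusSet, QCReport]:
    """Full QC pipeline in the fixed order.

    Locus filters use the metadata MAF; after thinning, allele
    frequencies are re-estimated from the retained samples (quartile
    scheme) and drive duplicate and outlier removal.  The returned
    LocusSet carries the estimated frequencies.
    """
    report = QCReport()
    geno, loci, r = filter_loci(geno, loci, maf_min, depth_min)
    report.extend(r)

    thinned = thin_secondary_snps(loci, mode=thin_mode, seed=seed, geno=geno)
    report.add("secondary_snp_thinning", thin_mode, len(loci), len(loci) - len(thinned))
    keep_ids = set(thinned.table["locus_id"])
    idx = [i for i, l in enumerate(geno.locus_ids) if l in keep_ids]
    geno = geno.take_loci(idx)
    loci = thinned.align_to(geno)

    loci = estimate_allele_freqs(geno, loci)
    # frequencies estimated from data may fall below the MAF floor or be
    # undefined; re-apply the informativeness rule on the estimates
    usable = np.isfinite(loci.p) & (loci.table["maf"].to_numpy() >= maf_min)
    report.add("locus_estimated_maf", maf_min, len(loci), int((~usable).sum()))
    geno = geno.take_loci(np.nonzero(usable)[0])
    loci = loci.subset(np.nonzero(usable)[0])

    dups = find_duplicates(geno, concordance_min=dup_concordance)
    to_drop = {d[3] for d in dups}
    report.add("duplicate_samples", dup_concordance, geno.n_samples, len(to_drop))
    keep = [i for i, s in enumerate(geno.sample_ids) if s not in to_drop]
    geno = geno.take_samples(keep)

    geno, r = filter_sample_outliers(geno, loci, outlier_policy)
    report.extend(r)
    return geno, loci, report
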