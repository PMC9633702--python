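"""Pairwise kinship inference from SNP genotypes via the PLOD statistic.

For each pair of samples the pseudo-log-odds (PLOD) is the sum over
co-observed loci of ``log P(g_i, g_j | HSP) / P(g_i, g_j | UP)``, where
the pair-genotype probabilities come from the Cotterman IBD mixture

    P(g_i, g_j) = k0 P(g_i) P(g_j) + k1 P(g_i) T(g_j | g_i)
                  + k2 P(g_i) 1[g_i = g_j]

with HWE genotype probabilities ``P`` and the one-shared-allele
transition ``T``.  Genotyping error enters as a symmetric per-allele
miscall channel convolved independently into each margin.  Expected
class-conditional PLOD means and variances follow by exact 3x3
enumeration per locus, and kin classes (UP / HSP / FSP, plus DUP for
near-identical samples) are assigned by segmenting the PLOD axis with
cutoffs scaled to each pair's number of co-observed loci.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .containers import MISSING, GenotypeMatrix, LocusSet

__all__ = [
    "KinshipModel",
    "UP",
    "HSP",
    "FSP",
    "POP",
    "DUP",
    "PLODReference",
    "pair_genotype_prob",
    "pair_prob_table",
    "plod_pair",
    "plod_all_pairs",
    "expected_plod_moments",
    "build_reference",
    "classify_pairs",
    "find_kin_pairs",
]


@dataclass(frozen=True)
class KinshipModel:
    """Cotterman IBD-sharing coefficients plus a per-allele error rate."""

    kappa: tuple[float, float, float]
    error_rate: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        k0, k1, k2 = self.kappa
        if not all(0 <= k <= 1 for k in self.kappa) or abs(k0 + k1 + k2 - 1) > 1e-9:
            raise ValueError(f"invalid kappa {self.kappa}: must be a probability simplex")

    def with_error(self, error_rate: float) -> "KinshipModel":
        return KinshipModel(self.kappa, error_rate, self.name)


UP = KinshipModel((1.0, 0.0, 0.0), name="UP")
HSP = KinshipModel((0.5, 0.5, 0.0), name="HSP")
FSP = KinshipModel((0.25, 0.5, 0.25), name="FSP")
POP = KinshipModel((0.0, 1.0, 0.0), name="POP")
DUP = KinshipModel((0.0, 0.0, 1.0), name="DUP")  # same individual twice


def _error_channel(e: float) -> np.ndarray:
    """3x3 matrix E[t, o] = P(observed o | true t), per-allele flip rate e."""
    return np.array(
        [
            [(1 - e) ** 2, 2 * e * (1 - e), e**2],
            [e * (1 - e), (1 - e) ** 2 + e**2, e * (1 - e)],
            [e**2, 2 * e * (1 - e), (1 - e) ** 2],
        ]
    )


def pair_prob_table(p: np.ndarray, model: KinshipModel) -> np.ndarray:
    """Joint pair-genotype probability tables, shape ``(L, 3, 3)``.

    ``p`` is the alternate-allele frequency per locus (all in (0, 1)).
    """
    p = np.atleast_1d(np.asarray(p, dtype=float))
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("allele frequencies must lie strictly in (0, 1)")
    q = 1.0 - p
    hwe = np.stack([q**2, 2 * p * q, p**2], axis=1)  # (L, 3)

    # T[l, gi, gj]: child of one shared parent -- a random allele of gi plus
    # one population allele
    share = np.stack([np.zeros_like(p), np.full_like(p, 0.5), np.ones_like(p)], axis=1)
    T = np.empty((len(p), 3, 3))
    for gi in range(3):
        a = share[:, gi]  # P(IBD allele is alt | gi)
        T[:, gi, 0] = (1 - a) * q
        T[:, gi, 1] = (1 - a) * p + a * q
        T[:, gi, 2] = a * p

    k0, k1, k2 = model.kappa
    table = (
        k0 * hwe[:, :, None] * hwe[:, None, :]
        + k1 * hwe[:, :, None] * T
        + k2 * hwe[:, :, None] * np.eye(3)[None, :, :]
    )
    if model.error_rate > 0:
        E = _error_channel(model.error_rate)
        table = np.einsum("ab,lbc,cd->lad", E.T, table, E)
    # the joint is symmetric analytically; enforce it bitwise so that
    # plod(i, j) == plod(j, i) exactly
    return 0.5 * (table + np.swapaxes(table, 1, 2))


def pair_genotype_prob(g_i: int, g_j: int, p: float, model: KinshipModel) -> float:
    """Probability of observing the genotype pair ``(g_i, g_j)`` at one locus."""
    if g_i not in (0, 1, 2) or g_j not in (0, 1, 2):
        raise ValueError("genotypes must be 0, 1 or 2")
    return float(pair_prob_table(np.array([p]), model)[0, g_i, g_j])


def _log_ratio_table(
    p: np.ndarray, model_num: KinshipModel, model_den: KinshipModel
) -> np.ndarray:
    num = pair_prob_table(p, model_num)
    den = pair_prob_table(p, model_den)
    return np.log(num) - np.log(den)


def plod_pair(
    i,
    j,
    geno: GenotypeMatrix,
    loci: LocusSet,
    model_num: KinshipModel = HSP,
    model_den: KinshipModel = UP,
    error_rate: float = 0.0,
) -> tuple[float, int]:
    """PLOD and co-observed locus count for one sample pair."""
    loci = loci.align_to(geno)
    gi = geno.calls[geno.sample_index(i)]
    gj = geno.calls[geno.sample_index(j)]
    both = (gi != MISSING) & (gj != MISSING) & np.isfinite(loci.p)
    n_shared = int(both.sum())
    if n_shared == 0:
        raise ValueError(f"pair ({i}, {j}) has zero co-observed loci")
    R = _log_ratio_table(
        loci.p[both], model_num.with_error(error_rate), model_den.with_error(error_rate)
    )
    return float(R[np.arange(n_shared), gi[both], gj[both]].sum()), n_shared


def plod_all_pairs(
    geno: GenotypeMatrix,
    loci: LocusSet,
    model_num: KinshipModel = HSP,
    model_den: KinshipModel = UP,
    error_rate: float = 0.0,
    block_size: int = 256,
) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs PLOD matrix and co-observed locus counts.

    Computed blockwise with nine indicator matrix products; the result is
    independent of ``block_size`` (pure sums of per-locus terms).
    """
    loci = loci.align_to(geno)
    usable = np.isfinite(loci.p)
    calls = geno.calls[:, usable]
    R = _log_ratio_table(
        loci.p[usable], model_num.with_error(error_rate), model_den.with_error(error_rate)
    )
    n = geno.n_samples
    obs = (calls != MISSING).astype(np.float64)
    ind = [((calls == g) & (calls != MISSING)).astype(np.float64) for g in (0, 1, 2)]

    plod = np.zeros((n, n))
    shared = np.zeros((n, n))
    for start in range(0, n, block_size):
        sl = slice(start, min(start + block_size, n))
        shared[sl] = obs[sl] @ obs.T
        acc = np.zeros((sl.stop - sl.start, n))
        for a in range(3):
            for b in range(3):
                acc += ind[a][sl] @ (ind[b] * R[:, a, b][None, :]).T
        plod[sl] = acc
    return plod, shared.astype(np.int64)


def expected_plod_moments(
    loci: LocusSet,
    true_model: KinshipModel,
    model_num: KinshipModel = HSP,
    model_den: KinshipModel = UP,
    error_rate: float = 0.0,
) -> tuple[float, float]:
    """Analytic mean and variance of the PLOD under a true kinship class.

    Exact 3x3 enumeration per locus, summed across the locus set; no
    sampling involved.  The same error channel is applied to the true
    distribution and to the log-ratio tables.
    """
    p = loci.p
    usable = np.isfinite(p) & (p > 0) & (p < 1)
    p = p[usable]
    R = _log_ratio_table(p, model_num.with_error(error_rate), model_den.with_error(error_rate))
    P = pair_prob_table(p, true_model.with_error(error_rate))
    mean_l = (P * R).sum(axis=(1, 2))
    var_l = (P * R**2).sum(axis=(1, 2)) - mean_l**2
    return float(mean_l.sum()), float(var_l.sum())


@dataclass
class PLODReference:
    """Class-conditional PLOD moments and segmentation cutoffs.

    Means, variances and cutoffs are totals over the full locus set; the
    ``n_loci`` field allows scaling to a pair's co-observed locus count
    (the per-locus expected increment times the co-observed count).
    """

    n_loci: int
    means: dict
    variances: dict
    cutoff_up_hsp: float
    cutoff_hsp_fsp: float
    cutoff_dup: float
    mode: str = "midpoint"

    def scaled_cutoffs(self, n_shared) -> tuple:
        f = np.asarray(n_shared, dtype=float) / self.n_loci
        return (self.cutoff_up_hsp * f, self.cutoff_hsp_fsp * f, self.cutoff_dup * f)


def build_reference(
    loci: LocusSet,
    error_rate: float = 0.01,
    cutoff_mode: str = "midpoint",
    n_pairs: int | None = None,
    max_false_hsp: float = 0.1,
) -> PLODReference:
    """Compute class-conditional PLOD moments and segmentation cutoffs.

    ``midpoint`` places each cutoff halfway between adjacent class means.
    ``fpr`` places the UP/HSP cutoff at ``mean_UP + z * sd_UP`` with z
    chosen so the expected number of false HSPs among ``n_pairs``
    comparisons is below ``max_false_hsp`` (Gaussian tail).
    """
    usable = int((np.isfinite(loci.p) & (loci.p > 0) & (loci.p < 1)).sum())
    means, variances = {}, {}
    for model in (UP, HSP, FSP, DUP):
        m, v = expected_plod_moments(loci, model, error_rate=error_rate)
        means[model.name] = m
        variances[model.name] = v
    if cutoff_mode == "midpoint":
        cut_uh = 0.5 * (means["UP"] + means["HSP"])
    elif cutoff_mode == "fpr":
        if not n_pairs:
            raise ValueError("fpr cutoff mode needs n_pairs")
        z = norm.isf(max_false_hsp / n_pairs)
        cut_uh = means["UP"] + z * np.sqrt(variances["UP"])
    else:
        raise ValueError(f"unknown cutoff mode {cutoff_mode!r}")
    cut_hf = 0.5 * (means["HSP"] + means["FSP"])
    cut_dup = 0.5 * (means["FSP"] + means["DUP"])
    if not means["UP"] < cut_uh < means["HSP"] < cut_hf < means["FSP"]:
        raise ValueError("degenerate PLOD reference: class means not separated")
    return PLODReference(
        n_loci=usable,
        means=means,
        variances=variances,
        cutoff_up_hsp=float(cut_uh),
        cutoff_hsp_fsp=float(cut_hf),
        cutoff_dup=float(cut_dup),
        mode=cutoff_mode,
    )


def classify_pairs(comparisons: pd.DataFrame, reference: PLODReference) -> pd.DataFrame:
    """Assign UP/HSP/FSP/DUP by segmenting the PLOD axis.

    ``comparisons`` needs columns (sample_i, sample_j, plod,
    n_shared_loci); cutoffs are scaled per pair to its co-observed locus
    count.
    """
    out = comparisons.copy()
    cut_uh, cut_hf, cut_dup = reference.scaled_cutoffs(out["n_shared_loci"].to_numpy())
    plod = out["plod"].to_numpy(dtype=float)
    kin = np.full(len(out), "UP", dtype=object)
    kin[plod >= cut_uh] = "HSP"
    kin[plod >= cut_hf] = "FSP"
    kin[plod >= cut_dup] = "DUP"
    out["kin_class"] = kin
    return out


def find_kin_pairs(
    geno: GenotypeMatrix,
    loci: LocusSet,
    error_rate: float = 0.01,
    cutoff_mode: str = "midpoint",
    min_shared_loci: int = 1,
    block_size: int = 256,
) -> tuple[pd.DataFrame, PLODReference]:
    """All-pairs PLOD scan plus classification.

    Pairs with fewer than ``min_shared_loci`` co-observed loci are
    reported with ``kin_class = "NC"`` (not classified).
    """
    n = geno.n_samples
    reference = build_reference(
        loci,
        error_rate=error_rate,
        cutoff_mode=cutoff_mode,
        n_pairs=n * (n - 1) // 2 or 1,
    )
    plod, shared = plod_all_pairs(
        geno, loci, error_rate=error_rate, block_size=block_size
    )
    iu = np.triu_indices(n, k=1)
    comp = pd.DataFrame(
        {
            "sample_i": geno.sample_ids[iu[0]],
            "sample_j": geno.sample_ids[iu[1]],
            "plod": plod[iu],
            "n_shared_loci": shared[iu],
        }
    )
    ok = comp["n_shared_loci"] >= max(min_shared_loci, 1)
    comp = classify_pairs(comp, reference)
    comp.loc[~ok, "kin_class"] = "NC"
    return comp, reference
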