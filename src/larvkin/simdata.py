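"""Synthetic batch-spawning pedigrees, patchy tow surveys and SNP genotypes.

The generator emulates the sampling situation of a larval close-kin study
on a large batch-spawning fish stock: ~1e5 adults spawn in small nightly
groups over a multi-week season, larvae aggregate into a patchy spatial
field, plankton tows sample the patches either on a spatial grid or by
repeatedly re-sampling one rich patch, and sampled larvae are genotyped
at thousands of biallelic SNPs with realistic error, read-depth-driven
missingness and injected QC challenges (duplicates, contaminated,
degraded and off-target-species samples).

Every stage draws from a substream derived from the single master seed,
so identical ``(config, seed)`` reproduce bit-identical output while each
stage remains individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, LocusSet

__all__ = [
    "SimConfig",
    "TruePedigree",
    "TowSample",
    "ConfigurationError",
    "simulate_pedigree",
    "sample_tows",
    "simulate_genotypes",
    "true_kinship",
    "simulate_dataset",
]

#: survey box (lon_min, lon_max, lat_min, lat_max), northern Gulf of Mexico
DEFAULT_BOX = (-96.0, -83.5, 24.0, 30.0)

_STAGE_PEDIGREE = 101
_STAGE_TOWS = 202
_STAGE_GENO = 303


class ConfigurationError(ValueError):
    """Simulation configuration is internally infeasible."""


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stage]))


def _draw(dist: Sequence, rng: np.random.Generator, size: int) -> np.ndarray:
    """Draw from a small parametric distribution spec ``(name, *params)``."""
    name, *params = dist
    if name == "lognormal":
        mu, sigma = params
        return rng.lognormal(mu, sigma, size)
    if name == "uniform":
        lo, hi = params
        return rng.uniform(lo, hi, size)
    if name == "uniform_int":
        lo, hi = params
        return rng.integers(lo, hi + 1, size)
    if name == "constant":
        return np.full(size, params[0], dtype=float)
    raise ConfigurationError(f"unknown distribution spec {name!r}")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic survey cohort.

    Defaults follow the conditions the analysis is designed for: a large
    (1e5) adult population, small-group spawning over a three-week season,
    heavily right-skewed larval patches (so that most larvae sit in a
    small fraction of tows), 15-40% per-individual missingness and ~41%
    of loci sharing a sequenced fragment with another SNP.
    """

    n_adults: int = 100_000
    sex_ratio: float = 0.5
    adult_size_dist: tuple = ("lognormal", 5.0, 0.25)
    fecundity_exponent: float = 1.0
    n_spawning_groups_per_night: int = 50
    group_size_dist: tuple = ("uniform_int", 6, 40)
    n_nights: int = 21
    group_persistence_prob: float = 0.3
    n_patches: int = 40
    patch_intensity_dispersion: float = 0.04
    n_larvae: int = 5000
    n_tows: int = 30
    survey_mode: str = "grid"
    tow_catch_prob: float = 0.01
    max_genotyped: int | None = 500  # lab subsampling cap across all tows
    survey_box: tuple = DEFAULT_BOX
    cohort_year: int = 2016
    n_loci: int = 8000
    maf_dist: tuple = ("uniform", 0.05, 0.5)
    genotyping_error_rate: float = 0.01
    missingness_profile: tuple = (0.15, 0.40)
    mean_depth_dist: tuple = ("lognormal", 3.8, 0.35)
    frac_secondary_snps: float = 0.41
    frac_polyploid: float = 0.02
    n_duplicates: int = 2
    n_contaminated: int = 3
    n_degraded: int = 3
    n_offtarget_species: int = 2
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "sex_ratio": self.sex_ratio,
            "group_persistence_prob": self.group_persistence_prob,
            "tow_catch_prob": self.tow_catch_prob,
            "genotyping_error_rate": self.genotyping_error_rate,
            "frac_secondary_snps": self.frac_secondary_snps,
            "frac_polyploid": self.frac_polyploid,
        }
        for name, v in probs.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        counts = {
            "n_adults": self.n_adults,
            "n_spawning_groups_per_night": self.n_spawning_groups_per_night,
            "n_nights": self.n_nights,
            "n_patches": self.n_patches,
            "n_larvae": self.n_larvae,
            "n_tows": self.n_tows,
            "n_loci": self.n_loci,
            "n_duplicates": self.n_duplicates,
            "n_contaminated": self.n_contaminated,
            "n_degraded": self.n_degraded,
            "n_offtarget_species": self.n_offtarget_species,
        }
        for name, v in counts.items():
            if v < 0:
                raise ConfigurationError(f"{name}={v} must be >= 0")
        if self.survey_mode not in ("grid", "targeted"):
            raise ConfigurationError(f"survey_mode={self.survey_mode!r}")
        lo, hi = self.missingness_profile
        if not (0 <= lo <= hi <= 1):
            raise ConfigurationError("missingness_profile must be an ordered pair in [0,1]")
        if self.maf_dist[0] == "uniform":
            lo, hi = self.maf_dist[1:]
            if not (0 < lo <= hi <= 0.5):
                raise ConfigurationError("maf_dist support must lie in (0, 0.5]")

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass
class TruePedigree:
    """Ground-truth pedigree: who spawned whom, when and where.

    ``adults`` has columns (adult_id, sex, size); ``larvae`` has columns
    (larva_id, mother_id, father_id, birth_night, patch_id); ``patches``
    has (patch_id, lon, lat, weight).  ``spawning_groups`` records the
    (night, member adult_ids) history.
    """

    adults: pd.DataFrame
    larvae: pd.DataFrame
    spawning_groups: list
    patches: pd.DataFrame

    @property
    def n_larvae(self) -> int:
        return len(self.larvae)


@dataclass
class TowSample:
    """One plankton-net deployment and the larvae it captured."""

    tow_id: str
    lon: float
    lat: float
    date: str
    cohort_year: int
    larva_ids: list

    def __len__(self) -> int:
        return len(self.larva_ids)


def simulate_pedigree(config: SimConfig) -> TruePedigree:
    """Simulate adults, nightly spawning groups, and the larval pool.

    Spawning groups form each night; with probability
    ``group_persistence_prob`` a group (with its pairings) persists to the
    next night, which is what generates full-sibling pairs born weeks
    apart.  Group membership is drawn with probability proportional to
    fecundity (size ** ``fecundity_exponent``); within a group each larva
    draws its mother and father uniformly from the group members of each
    sex.  Larvae are allocated to (group, night) spawning events with
    weights given by the heavy-tailed intensities of the patches the
    events occur in, producing the strongly skewed larvae-per-patch field.
    """
    config.validate()
    rng = _stage_rng(config.seed, _STAGE_PEDIGREE)

    n_f = int(round(config.n_adults * config.sex_ratio))
    n_m = config.n_adults - n_f
    if n_f == 0 or n_m == 0:
        raise ConfigurationError("need at least one adult of each sex")
    sizes = _draw(config.adult_size_dist, rng, config.n_adults)
    sex = np.array(["F"] * n_f + ["M"] * n_m)
    adult_ids = np.array([f"A{i:06d}" for i in range(config.n_adults)], dtype=object)
    adults = pd.DataFrame({"adult_id": adult_ids, "sex": sex, "size": sizes})

    fec = sizes**config.fecundity_exponent
    w_f = fec[:n_f]
    w_m = fec[n_f:]

    def weighted_sample(w: np.ndarray, k: int) -> np.ndarray:
        # weighted sampling without replacement via exponential races
        keys = rng.standard_exponential(len(w)) / w
        return np.argpartition(keys, k)[:k] if k < len(w) else np.arange(len(w))

    # spatial patch field with gamma-distributed intensities; a small shape
    # parameter concentrates most larvae into a few patches
    lon0, lon1, lat0, lat1 = config.survey_box
    patch_lon = rng.uniform(lon0, lon1, config.n_patches)
    patch_lat = rng.uniform(lat0, lat1, config.n_patches)
    patch_w = rng.gamma(config.patch_intensity_dispersion, 1.0, config.n_patches)
    patch_w = np.maximum(patch_w, 1e-12)
    patches = pd.DataFrame(
        {
            "patch_id": np.arange(config.n_patches),
            "lon": patch_lon,
            "lat": patch_lat,
            "weight": patch_w,
        }
    )

    # nightly groups with persistence
    max_group = min(n_f, n_m) * 2
    groups: list[tuple[int, np.ndarray, np.ndarray]] = []  # (night, females, males)
    spawning_groups = []
    prev: list[tuple[np.ndarray, np.ndarray]] = []
    for night in range(config.n_nights):
        cur: list[tuple[np.ndarray, np.ndarray]] = []
        for g in range(config.n_spawning_groups_per_night):
            if prev and g < len(prev) and rng.random() < config.group_persistence_prob:
                females, males = prev[g]
            else:
                size = int(_draw(config.group_size_dist, rng, 1)[0])
                size = max(size, 2)
                if size > max_group:
                    raise ConfigurationError(
                        f"group size {size} exceeds available adults per sex"
                    )
                k_f = max(1, size // 2)
                k_m = max(1, size - k_f)
                females = weighted_sample(w_f, k_f)
                males = n_f + weighted_sample(w_m, k_m)
            cur.append((females, males))
            groups.append((night, females, males))
            spawning_groups.append(
                (night, tuple(adult_ids[np.concatenate([females, males])]))
            )
        prev = cur

    # spawning events co-locate in rich patches (that is what makes a patch
    # rich); larvae are spread roughly evenly across events, so large tows
    # contain many moderate families rather than one huge one
    n_events = len(groups)
    event_patch = rng.choice(config.n_patches, size=n_events, p=patch_w / patch_w.sum())
    counts = rng.multinomial(config.n_larvae, np.full(n_events, 1.0 / n_events))

    mothers = np.empty(config.n_larvae, dtype=np.int64)
    fathers = np.empty(config.n_larvae, dtype=np.int64)
    birth_night = np.empty(config.n_larvae, dtype=np.int64)
    patch_id = np.empty(config.n_larvae, dtype=np.int64)
    pos = 0
    for (night, females, males), patch, c in zip(groups, event_patch, counts):
        if c == 0:
            continue
        sl = slice(pos, pos + c)
        mothers[sl] = rng.choice(females, size=c)
        fathers[sl] = rng.choice(males, size=c)
        birth_night[sl] = night
        patch_id[sl] = patch
        pos += c

    larva_ids = np.array([f"L{i:06d}" for i in range(config.n_larvae)], dtype=object)
    larvae = pd.DataFrame(
        {
            "larva_id": larva_ids,
            "mother_id": adult_ids[mothers],
            "father_id": adult_ids[fathers],
            "birth_night": birth_night,
            "patch_id": patch_id,
        }
    )
    return TruePedigree(adults, larvae, spawning_groups, patches)


def sample_tows(pedigree: TruePedigree, config: SimConfig) -> list[TowSample]:
    """Sample the larval field with plankton tows.

    ``grid`` mode assigns tows to patches drawn uniformly over the survey
    box (one patch per tow, without replacement while patches last), as a
    spatially spread-out station grid would; ``targeted`` mode places all
    tows on the single richest patch, repeatedly re-sampling it, as a
    buoy-following design would.  Each larva is sampled at most once.
    """
    config.validate()
    rng = _stage_rng(config.seed, _STAGE_TOWS)
    if config.n_tows == 0:
        return []

    by_patch: dict[int, list] = {
        int(k): list(v)
        for k, v in pedigree.larvae.groupby("patch_id")["larva_id"].apply(list).items()
    }
    n_patches = len(pedigree.patches)

    if config.survey_mode == "grid":
        if config.n_tows <= n_patches:
            tow_patches = rng.choice(n_patches, size=config.n_tows, replace=False)
        else:
            tow_patches = rng.integers(0, n_patches, config.n_tows)
    else:  # targeted: find the richest patch and hammer it
        patch_counts = np.zeros(n_patches, dtype=int)
        for k, ids in by_patch.items():
            patch_counts[k] = len(ids)
        richest = int(np.argmax(patch_counts))
        tow_patches = np.full(config.n_tows, richest)

    plon = pedigree.patches["lon"].to_numpy()
    plat = pedigree.patches["lat"].to_numpy()
    tows = []
    for t, patch in enumerate(tow_patches):
        pool = by_patch.get(int(patch), [])
        if pool:
            take = rng.random(len(pool)) < config.tow_catch_prob
            caught = [lid for lid, c in zip(pool, take) if c]
            by_patch[int(patch)] = [lid for lid, c in zip(pool, take) if not c]
        else:
            caught = []
        jitter = rng.normal(0.0, 0.01, 2)  # ~1 km scatter around the patch
        tows.append(
            TowSample(
                tow_id=f"T{config.cohort_year}-{t:03d}",
                lon=float(plon[patch] + jitter[0]),
                lat=float(plat[patch] + jitter[1]),
                date=f"{config.cohort_year}-05-{(t % 28) + 1:02d}",
                cohort_year=config.cohort_year,
                larva_ids=caught,
            )
        )
    # lab subsampling: only a capped number of caught larvae are genotyped
    cap = config.max_genotyped
    total = sum(len(t) for t in tows)
    if cap is not None and total > cap:
        flat = [(ti, lid) for ti, tow in enumerate(tows) for lid in tow.larva_ids]
        keep_idx = rng.choice(total, size=cap, replace=False)
        keep = [flat[i] for i in sorted(keep_idx)]
        for tow in tows:
            tow.larva_ids = []
        for ti, lid in keep:
            tows[ti].larva_ids.append(lid)
    return tows


# ---------------------------------------------------------------------------
# genotypes


def _apply_error(calls: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Symmetric per-allele miscall channel applied to true genotypes."""
    if rate == 0:
        return calls.copy()
    # each of the two alleles flips independently
    f1 = rng.binomial(1, rate, calls.shape)
    f2 = rng.binomial(1, rate, calls.shape)
    out = calls.copy()
    out = np.where(calls == 0, f1 + f2, out)
    out = np.where(calls == 2, 2 - (f1 + f2), out)
    out = np.where(calls == 1, 1 + f1 - f2, out)
    return out.astype(np.int8)


def _mendelian(g_mother: np.ndarray, g_father: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    a1 = rng.random(g_mother.shape) < g_mother / 2.0
    a2 = rng.random(g_father.shape) < g_father / 2.0
    return (a1.astype(np.int8) + a2.astype(np.int8)).astype(np.int8)


def simulate_genotypes(
    pedigree: TruePedigree, sampled: list[TowSample], config: SimConfig
) -> tuple[GenotypeMatrix, LocusSet, pd.DataFrame]:
    """Genotype the sampled larvae and inject QC challenges.

    Founder (adult) genotypes are Hardy-Weinberg draws at MAFs from
    ``maf_dist``; larvae inherit Mendelian alleles from their true parents;
    a symmetric per-allele miscall channel and read-depth-driven
    missingness are then applied.  Appended QC challenges: near-identical
    duplicates, two-individual mixtures (contaminated), degraded samples
    (allelic dropout plus extra missingness), and off-target-species
    samples drawn from a shifted allele-frequency spectrum.

    Returns the genotype matrix, the per-locus metadata (with the
    *generating* allele frequencies), and the per-sample metadata table
    whose ``anomaly`` column records the injected ground truth.
    """
    config.validate()
    rng = _stage_rng(config.seed, _STAGE_GENO)
    L = config.n_loci

    maf = _draw(config.maf_dist, rng, L)
    flip = rng.random(L) < 0.5
    p = np.where(flip, maf, 1.0 - maf)  # alternate-allele frequency

    # fragments: a frac_secondary_snps share of loci sit on shared fragments
    n_secondary = int(round(config.frac_secondary_snps * L))
    order = rng.permutation(L)
    fragment_id = np.empty(L, dtype=object)
    frag = 0
    i = 0
    # group the first n_secondary loci (in shuffled order) into fragments of 2-3
    while i < n_secondary:
        k = 2 if (n_secondary - i == 2 or rng.random() < 0.8) else 3
        k = min(k, n_secondary - i)
        if k == 1:
            break
        for j in range(k):
            fragment_id[order[i + j]] = f"F{frag:06d}"
        frag += 1
        i += k
    for j in range(i, L):
        fragment_id[order[j]] = f"F{frag:06d}"
        frag += 1

    mean_depth = _draw(config.mean_depth_dist, rng, L)
    polyploid = rng.random(L) < config.frac_polyploid
    locus_ids = np.array([f"S{l:06d}" for l in range(L)], dtype=object)
    loci = LocusSet(
        pd.DataFrame(
            {
                "locus_id": locus_ids,
                "fragment_id": fragment_id,
                "p": p,
                "maf": np.minimum(p, 1 - p),
                "mean_depth": mean_depth,
                "polyploid_flag": polyploid,
            }
        )
    )

    # sampled larvae and their parents
    larva_rows = []
    for tow in sampled:
        for lid in tow.larva_ids:
            larva_rows.append((lid, tow))
    known = set(pedigree.larvae["larva_id"])
    for lid, _ in larva_rows:
        if lid not in known:
            raise ValueError(f"sampled larva {lid!r} not in pedigree")

    ped = pedigree.larvae.set_index("larva_id")
    sampled_ids = [lid for lid, _ in larva_rows]
    moms = ped.loc[sampled_ids, "mother_id"].to_numpy()
    dads = ped.loc[sampled_ids, "father_id"].to_numpy()
    parents = pd.unique(np.concatenate([moms, dads]))
    pidx = {a: i for i, a in enumerate(parents)}

    parent_g = rng.binomial(2, p, size=(len(parents), L)).astype(np.int8)
    gm = parent_g[[pidx[a] for a in moms]]
    gf = parent_g[[pidx[a] for a in dads]]
    true_g = _mendelian(gm, gf, rng)

    n = len(sampled_ids)
    sample_ids = list(sampled_ids)
    meta_rows = [
        {
            "sample_id": lid,
            "tow_id": tow.tow_id,
            "lon": tow.lon,
            "lat": tow.lat,
            "date": tow.date,
            "cohort_year": tow.cohort_year,
            "species": "target",
            "anomaly": "",
        }
        for lid, tow in larva_rows
    ]
    blocks = [true_g]

    def _pick(k: int) -> np.ndarray:
        return rng.choice(n, size=min(k, n), replace=False) if n else np.array([], int)

    # duplicates: extra near-identical copies of existing samples
    for src in _pick(config.n_duplicates):
        blocks.append(true_g[src : src + 1].copy())
        row = dict(meta_rows[src])
        row["sample_id"] = f"{sample_ids[src]}-dup"
        row["anomaly"] = f"duplicate_of:{sample_ids[src]}"
        meta_rows.append(row)
        sample_ids.append(row["sample_id"])

    # contaminated: pooled reads from two individuals -- a het is called
    # wherever the pool carries both alleles, so heterozygosity is inflated
    for src in _pick(config.n_contaminated):
        other = int(rng.integers(n))
        ga, gb = true_g[src], true_g[other]
        has_ref = (ga < 2) | (gb < 2)
        has_alt = (ga > 0) | (gb > 0)
        g = np.where(has_ref & has_alt, 1, np.where(has_alt, 2, 0)).astype(np.int8)
        blocks.append(g[None, :])
        row = dict(meta_rows[src])
        row["sample_id"] = f"X{len(sample_ids):04d}-mix"
        row["anomaly"] = "contaminated"
        meta_rows.append(row)
        sample_ids.append(row["sample_id"])

    # degraded: allelic dropout collapses hets, plus extra missingness later
    degraded_tags = []
    for src in _pick(config.n_degraded):
        g = true_g[src].copy()
        het = g == 1
        drop = het & (rng.random(L) < 0.8)
        g[drop] = np.where(rng.random(drop.sum()) < 0.5, 0, 2)
        blocks.append(g[None, :])
        row = dict(meta_rows[src])
        row["sample_id"] = f"X{len(sample_ids):04d}-deg"
        row["anomaly"] = "degraded"
        meta_rows.append(row)
        sample_ids.append(row["sample_id"])
        degraded_tags.append(len(sample_ids) - 1)

    # off-target species: genotypes from a shifted allele-frequency spectrum
    for k in range(config.n_offtarget_species):
        shift = rng.uniform(0.2, 0.45, L) * np.where(p < 0.5, 1.0, -1.0)
        p_off = np.clip(p + shift, 0.02, 0.98)
        blocks.append(rng.binomial(2, p_off, L).astype(np.int8)[None, :])
        row = {
            "sample_id": f"X{len(sample_ids):04d}-sp",
            "tow_id": meta_rows[0]["tow_id"] if meta_rows else "T-none",
            "lon": meta_rows[0]["lon"] if meta_rows else 0.0,
            "lat": meta_rows[0]["lat"] if meta_rows else 0.0,
            "date": meta_rows[0]["date"] if meta_rows else "",
            "cohort_year": config.cohort_year,
            "species": "offtarget",
            "anomaly": "offtarget",
        }
        meta_rows.append(row)
        sample_ids.append(row["sample_id"])

    calls = np.vstack(blocks) if blocks else np.zeros((0, L), np.int8)
    calls = _apply_error(calls, config.genotyping_error_rate, rng)

    # read-depth-driven missingness: rarely-covered loci go missing first
    lo, hi = config.missingness_profile
    target = rng.uniform(lo, hi, calls.shape[0])
    for idx in degraded_tags:
        target[idx] = min(1.0, target[idx] + 0.2)
    inv_depth = 1.0 / np.maximum(mean_depth, 1e-9)
    locus_w = inv_depth / inv_depth.mean()
    p_miss = np.clip(target[:, None] * locus_w[None, :], 0.0, 0.95)
    miss = rng.random(calls.shape) < p_miss
    calls = np.where(miss, np.int8(-1), calls).astype(np.int8)

    geno = GenotypeMatrix(np.array(sample_ids, dtype=object), locus_ids, calls)
    meta = pd.DataFrame(meta_rows)
    return geno, loci, meta


def true_kinship(pedigree: TruePedigree, i: str, j: str) -> str:
    """True kin class of a larva pair from shared-parent count."""
    ped = pedigree.larvae.set_index("larva_id")
    mi, fi = ped.loc[i, ["mother_id", "father_id"]]
    mj, fj = ped.loc[j, ["mother_id", "father_id"]]
    shared = int(mi == mj) + int(fi == fj)
    return {0: "UP", 1: "HSP", 2: "FSP"}[shared]


def true_kin_classes(pedigree: TruePedigree, sample_ids: Sequence[str]) -> dict:
    """Shared-parent class for every pair among ``sample_ids`` (vectorized)."""
    ped = pedigree.larvae.set_index("larva_id")
    ids = list(sample_ids)
    moms = ped.loc[ids, "mother_id"].to_numpy()
    dads = ped.loc[ids, "father_id"].to_numpy()
    out = {}
    n = len(ids)
    same_m = moms[:, None] == moms[None, :]
    same_f = dads[:, None] == dads[None, :]
    shared = same_m.astype(int) + same_f.astype(int)
    names = {0: "UP", 1: "HSP", 2: "FSP"}
    for a in range(n):
        for b in range(a + 1, n):
            out[(ids[a], ids[b])] = names[shared[a, b]]
    return out


def simulate_dataset(config: SimConfig):
    """Convenience wrapper: pedigree -> tows -> genotypes in one call."""
    ped = simulate_pedigree(config)
    tows = sample_tows(ped, config)
    geno, loci, meta = simulate_genotypes(ped, tows, config)
    return ped, tows, geno, loci, meta
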