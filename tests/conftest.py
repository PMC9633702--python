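from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from larvkin import simdata
from larvkin.containers import LocusSet

settings.register_profile("suite", derandomize=True, max_examples=40)
settings.load_profile("suite")


def make_locus_set(p, depth=40.0, fragment=None) -> LocusSet:
    p = np.asarray(p, dtype=float)
    n = len(p)
    return LocusSet(
        pd.DataFrame(
            {
                "locus_id": [f"S{i:05d}" for i in range(n)],
                "fragment_id": fragment if fragment is not None else [f"F{i:05d}" for i in range(n)],
                "p": p,
                "maf": np.minimum(p, 1 - p),
                "mean_depth": depth,
                "polyploid_flag": False,
            }
        )
    )


@pytest.fixture(scope="session")
def small_config() -> simdata.SimConfig:
    """A compact but fully-featured survey: anomalies included."""
    return simdata.SimConfig(
        n_adults=20_000,
        n_larvae=3_000,
        n_loci=1_500,
        n_tows=18,
        n_patches=30,
        survey_mode="targeted",
        tow_catch_prob=0.12,
        max_genotyped=180,
        genotyping_error_rate=0.005,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simdata.simulate_dataset(small_config)


def sibling_pair_genotypes(
    p: np.ndarray,
    n_pairs: int,
    relationship: str,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Direct pedigree simulation of genotype pairs (no library code).

    Returns two (n_pairs, L) int arrays of true genotypes.
    """
    L = len(p)
    shape = (n_pairs, L)
    if relationship == "UP":
        return rng.binomial(2, p, shape).astype(int), rng.binomial(2, p, shape).astype(int)
    if relationship == "HSP":
        gp = rng.binomial(2, p, shape)
        g1 = (rng.random(shape) < gp / 2).astype(int) + (rng.random(shape) < p).astype(int)
        g2 = (rng.random(shape) < gp / 2).astype(int) + (rng.random(shape) < p).astype(int)
        return g1, g2
    if relationship == "FSP":
        gm = rng.binomial(2, p, shape)
        gf = rng.binomial(2, p, shape)
        g1 = (rng.random(shape) < gm / 2).astype(int) + (rng.random(shape) < gf / 2).astype(int)
        g2 = (rng.random(shape) < gm / 2).astype(int) + (rng.random(shape) < gf / 2).astype(int)
        return g1, g2
    raise ValueError(relationship)


def apply_miscalls(g: np.ndarray, e: float, rng: np.random.Generator) -> np.ndarray:
    if e == 0:
        return g
    f1 = rng.binomial(1, e, g.shape)
    f2 = rng.binomial(1, e, g.shape)
    out = np.where(g == 0, f1 + f2, np.where(g == 2, 2 - f1 - f2, 1 + f1 - f2))
    return out
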