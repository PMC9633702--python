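"""Simulate a batch-spawning population and a targeted larval survey.

Builds a synthetic pedigree (adults, nightly spawning groups, larval
patches), samples it with tows, and genotypes the sampled larvae.
"""

from larvkin import simdata

cfg = simdata.SimConfig(
    n_adults=20_000,
    n_larvae=3_000,
    n_loci=2_000,
    n_tows=15,
    n_patches=30,
    survey_mode="targeted",
    max_genotyped=200,
    tow_catch_prob=0.05,
    seed=1,
)
ped, tows, geno, loci, meta = simdata.simulate_dataset(cfg)

counts = sorted((len(t) for t in tows), reverse=True)
print(f"adults: {len(ped.adults)}, larval pool: {ped.n_larvae}")
print(f"tows: {len(tows)}, larvae per tow (sorted): {counts}")
print(f"genotyped samples: {geno.n_samples} x {geno.n_loci} loci")
print(f"per-sample missingness: {geno.missing_fraction().min():.2f}"
      f"-{geno.missing_fraction().max():.2f}")
print(f"injected QC challenges: {meta['anomaly'].ne('').sum()}")
# The skewed per-tow counts reflect the patchy larval field: most larvae
# sit in a few rich patches, which the targeted survey re-samples.
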