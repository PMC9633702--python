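import numpy as np
import pandas as pd
import pytest
from scipy import stats

from larvkin import simdata
from larvkin.simdata import ConfigurationError, SimConfig


def _kin_counts(ped, ids):
    classes = simdata.true_kin_classes(ped, ids)
    out = {"UP": 0, "HSP": 0, "FSP": 0}
    for v in classes.values():
        out[v] += 1
    return out


class TestConfig:
    def test_rejects_bad_probabilities(self):
        with pytest.raises(ConfigurationError):
            SimConfig(sex_ratio=1.5).validate()
        with pytest.raises(ConfigurationError):
            SimConfig(group_persistence_prob=-0.1).validate()

    def test_rejects_negative_counts_and_bad_mode(self):
        with pytest.raises(ConfigurationError):
            SimConfig(n_larvae=-1).validate()
        with pytest.raises(ConfigurationError):
            SimConfig(survey_mode="spiral").validate()

    def test_rejects_maf_support_outside_half(self):
        with pytest.raises(ConfigurationError):
            SimConfig(maf_dist=("uniform", 0.05, 0.7)).validate()

    def test_infeasible_group_size(self):
        cfg = SimConfig(n_adults=6, group_size_dist=("constant", 40), n_larvae=10)
        with pytest.raises(ConfigurationError):
            simdata.simulate_pedigree(cfg)


class TestPedigree:
    def test_determinism(self, small_config):
        a = simdata.simulate_dataset(small_config)
        b = simdata.simulate_dataset(small_config)
        pd.testing.assert_frame_equal(a[0].larvae, b[0].larvae)
        assert [t.larva_ids for t in a[1]] == [t.larva_ids for t in b[1]]
        np.testing.assert_array_equal(a[2].calls, b[2].calls)
        pd.testing.assert_frame_equal(a[3].table, b[3].table)

    def test_single_mating_pair_gives_all_full_sibs(self):
        cfg = SimConfig(
            n_adults=2,
            n_spawning_groups_per_night=1,
            group_size_dist=("constant", 2),
            n_nights=1,
            n_larvae=10,
            n_patches=2,
            seed=5,
        )
        ped = simdata.simulate_pedigree(cfg)
        counts = _kin_counts(ped, list(ped.larvae["larva_id"]))
        assert counts == {"UP": 0, "HSP": 0, "FSP": 45}

    def test_parent_sexes(self, small_dataset):
        ped = small_dataset[0]
        sex = ped.adults.set_index("adult_id")["sex"]
        assert (sex.loc[ped.larvae["mother_id"]] == "F").all()
        assert (sex.loc[ped.larvae["father_id"]] == "M").all()

    def test_no_persistence_no_cross_night_full_sibs(self):
        # with a fresh draw of spawning groups every night and a large adult
        # population, the same pair re-mating by chance is vanishingly rare
        cfg = SimConfig(
            n_adults=100_000,
            group_persistence_prob=0.0,
            n_larvae=2000,
            n_spawning_groups_per_night=40,
            n_nights=10,
            seed=9,
        )
        ped = simdata.simulate_pedigree(cfg)
        pairs = ped.larvae.groupby(["mother_id", "father_id"])["birth_night"].nunique()
        assert (pairs == 1).all()

    def test_persistence_creates_cross_night_full_sibs(self):
        cfg = SimConfig(
            n_adults=5_000,
            group_persistence_prob=0.8,
            n_larvae=4000,
            n_spawning_groups_per_night=10,
            n_nights=10,
            seed=9,
        )
        ped = simdata.simulate_pedigree(cfg)
        pairs = ped.larvae.groupby(["mother_id", "father_id"])["birth_night"].nunique()
        assert (pairs > 1).any()

    def test_offspring_conservation(self, small_dataset):
        ped = small_dataset[0]
        per_mother = ped.larvae.groupby("mother_id").size().sum()
        assert per_mother == len(ped.larvae)

    def test_kinship_is_symmetric_function_of_shared_parents(self, small_dataset):
        ped = small_dataset[0]
        ids = list(ped.larvae["larva_id"].iloc[:15])
        for (i, j), cls in simdata.true_kin_classes(ped, ids).items():
            assert simdata.true_kinship(ped, j, i) == cls


class TestTows:
    def test_zero_tows(self, small_config):
        ped = simdata.simulate_pedigree(small_config)
        assert simdata.sample_tows(ped, small_config.with_(n_tows=0)) == []

    def test_each_larva_sampled_at_most_once(self, small_dataset):
        tows = small_dataset[1]
        flat = [l for t in tows for l in t.larva_ids]
        assert len(flat) == len(set(flat))

    def test_coordinates_near_survey_box(self, small_dataset, small_config):
        lon0, lon1, lat0, lat1 = small_config.survey_box
        for t in small_dataset[1]:
            assert lon0 - 0.1 <= t.lon <= lon1 + 0.1
            assert lat0 - 0.1 <= t.lat <= lat1 + 0.1

    def test_targeted_mode_elevates_sibship(self):
        wins = 0
        for seed in range(12):
            cfg = SimConfig(
                n_adults=20_000,
                n_larvae=2_500,
                n_tows=15,
                n_patches=30,
                tow_catch_prob=0.02,
                max_genotyped=200,
                n_loci=10,
                seed=seed,
            )
            fracs = {}
            ped = simdata.simulate_pedigree(cfg)
            for mode in ("targeted", "grid"):
                tows = simdata.sample_tows(ped, cfg.with_(survey_mode=mode))
                ids = [l for t in tows for l in t.larva_ids]
                if len(ids) < 2:
                    fracs[mode] = 0.0
                    continue
                classes = simdata.true_kin_classes(ped, ids)
                with_sib = {
                    s for (a, b), c in classes.items() if c != "UP" for s in (a, b)
                }
                fracs[mode] = len(with_sib) / len(ids)
            wins += fracs["targeted"] > fracs["grid"]
        assert wins >= 9

    def test_grid_counts_multinomial_with_uniform_patches(self):
        # a huge gamma shape makes patch intensities essentially equal, and
        # many small spawning events make larvae nearly independent draws
        cfg = SimConfig(
            n_adults=5_000,
            n_larvae=500,
            n_spawning_groups_per_night=100,
            n_nights=50,
            n_tows=20,
            n_patches=20,
            patch_intensity_dispersion=1e6,
            survey_mode="grid",
            tow_catch_prob=0.9,
            max_genotyped=None,
            n_loci=10,
            seed=3,
        )
        ped = simdata.simulate_pedigree(cfg)
        tows = simdata.sample_tows(ped, cfg)
        counts = np.array([len(t) for t in tows])
        expected = np.full(len(counts), counts.sum() / len(counts))
        stat, pval = stats.chisquare(counts, expected)
        assert pval > 0.01

    def test_patch_skew_default_dispersion(self):
        # the default patch-intensity dispersion concentrates ~90% of the
        # larvae into the top decile of tows
        shares = []
        for seed in range(25):
            cfg = SimConfig(
                n_adults=5_000,
                n_larvae=2_000,
                n_tows=30,
                n_patches=40,
                survey_mode="grid",
                tow_catch_prob=0.9,
                max_genotyped=None,
                n_loci=10,
                seed=seed,
            )
            ped = simdata.simulate_pedigree(cfg)
            tows = simdata.sample_tows(ped, cfg)
            counts = np.sort([len(t) for t in tows])[::-1]
            if counts.sum():
                shares.append(counts[:3].sum() / counts.sum())
        assert 0.8 < np.mean(shares) <= 1.0


class TestGenotypes:
    def test_mendelian_certainty_homref_x_homalt(self):
        rng = np.random.default_rng(0)
        gm = np.zeros((200, 50), dtype=np.int8)
        gf = np.full((200, 50), 2, dtype=np.int8)
        g = simdata._mendelian(gm, gf, rng)
        assert (g == 1).all()

    def test_mendelian_transition_table(self):
        # empirical offspring distribution matches gamete enumeration
        rng = np.random.default_rng(1)
        n = 40_000
        for gm in (0, 1, 2):
            for gf in (0, 1, 2):
                g = simdata._mendelian(
                    np.full((n, 1), gm, np.int8), np.full((n, 1), gf, np.int8), rng
                )
                freq = np.bincount(g.ravel(), minlength=3) / n
                pm = [1 - gm / 2, gm / 2]
                pf = [1 - gf / 2, gf / 2]
                expect = np.zeros(3)
                for a in (0, 1):
                    for b in (0, 1):
                        expect[a + b] += pm[a] * pf[b]
                assert np.abs(freq - expect).max() < 0.01

    def test_observed_allele_frequency_tracks_generating_maf(self, small_dataset):
        _, _, geno, loci, meta = small_dataset
        clean = meta["anomaly"] == ""
        calls = geno.calls[clean.to_numpy()]
        obs = calls != -1
        n = obs.sum(axis=0)
        phat = np.where(obs, calls, 0).sum(axis=0) / (2 * np.maximum(n, 1))
        p = loci.p
        se = np.sqrt(p * (1 - p) / (2 * np.maximum(n, 1)))
        ok = np.abs(phat - p) < 4 * se + 0.02  # error channel adds a small bias
        assert ok.mean() > 0.99

    def test_missingness_within_profile(self, small_dataset):
        geno = small_dataset[2]
        miss = geno.missing_fraction()
        assert miss.min() > 0.05 and miss.max() < 0.75

    def test_contaminated_heterozygosity_exceeds_clean_upper_quartile(self):
        hits = 0
        for seed in range(20):
            cfg = SimConfig(
                n_adults=2_000,
                n_larvae=600,
                n_loci=400,
                n_tows=8,
                n_patches=10,
                tow_catch_prob=0.3,
                max_genotyped=60,
                n_contaminated=1,
                n_duplicates=0,
                n_degraded=0,
                n_offtarget_species=0,
                seed=seed,
            )
            _, _, geno, _, meta = simdata.simulate_dataset(cfg)
            obs = geno.calls != -1
            het = ((geno.calls == 1) & obs).sum(axis=1) / obs.sum(axis=1)
            is_mix = (meta["anomaly"] == "contaminated").to_numpy()
            if not is_mix.any():
                continue
            q3 = np.quantile(het[~is_mix], 0.75)
            hits += (het[is_mix] > q3).all()
        assert hits >= 19

    def test_duplicates_are_near_identical(self, small_dataset):
        _, _, geno, _, meta = small_dataset
        dups = meta[meta["anomaly"].str.startswith("duplicate_of:")]
        assert len(dups)
        for _, row in dups.iterrows():
            src = row["anomaly"].split(":", 1)[1]
            a = geno.calls[geno.sample_index(src)]
            b = geno.calls[geno.sample_index(row["sample_id"])]
            both = (a != -1) & (b != -1)
            assert (a[both] == b[both]).mean() > 0.97

    def test_sampled_larvae_must_exist(self, small_config):
        ped = simdata.simulate_pedigree(small_config)
        bad = simdata.TowSample("T0", -90.0, 26.0, "2016-05-01", 2016, ["nope"])
        with pytest.raises(ValueError, match="nope"):
            simdata.simulate_genotypes(ped, [bad], small_config)
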