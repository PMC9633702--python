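import numpy as np
import pandas as pd
import pytest

from conftest import make_locus_set
from larvkin import genoqc
from larvkin.containers import GenotypeMatrix


def _geno(calls, locus_ids=None):
    calls = np.asarray(calls, dtype=np.int8)
    n, L = calls.shape
    return GenotypeMatrix(
        [f"I{i}" for i in range(n)],
        locus_ids if locus_ids is not None else [f"S{l:05d}" for l in range(L)],
        calls,
    )


class TestFilterLoci:
    def test_maf_boundary_is_strict(self):
        loci = make_locus_set([0.04, 0.05, 0.3])
        geno = _geno(np.zeros((4, 3)))
        out, kept, report = genoqc.filter_loci(geno, loci, maf_min=0.05, depth_min=0)
        assert list(kept.table["maf"].round(2)) == [0.05, 0.3]
        assert report.stages[0]["n_removed"] == 1

    def test_depth_boundary_is_strict(self):
        loci = make_locus_set([0.3, 0.3])
        loci.table.loc[0, "mean_depth"] = 24.0
        loci.table.loc[1, "mean_depth"] = 25.0
        geno = _geno(np.zeros((4, 2)))
        _, kept, _ = genoqc.filter_loci(geno, loci, maf_min=0.0, depth_min=25.0)
        assert list(kept.table["mean_depth"]) == [25.0]

    def test_polyploid_removed_and_all_pass_identity(self):
        loci = make_locus_set([0.2, 0.3])
        out, kept, report = genoqc.filter_loci(_geno(np.ones((4, 2))), loci, 0.05, 25)
        assert out.n_loci == 2
        assert all(s["n_removed"] == 0 for s in report.stages)
        loci.table.loc[0, "polyploid_flag"] = True
        _, kept2, _ = genoqc.filter_loci(_geno(np.ones((4, 2))), loci, 0.05, 25)
        assert len(kept2) == 1

    def test_missing_metadata_names_locus(self):
        loci = make_locus_set([0.3])
        geno = _geno(np.zeros((4, 2)))
        with pytest.raises(KeyError, match="S00001"):
            genoqc.filter_loci(geno, loci, 0.05, 25)

    def test_idempotent(self):
        loci = make_locus_set(np.linspace(0.01, 0.5, 9))
        geno = _geno(np.zeros((4, 9)))
        g1, l1, _ = genoqc.filter_loci(geno, loci, 0.05, 25)
        g2, l2, rep = genoqc.filter_loci(g1, l1, 0.05, 25)
        assert g2.n_loci == g1.n_loci
        assert rep.stages[-1]["n_removed"] == 0

    def test_report_conservation(self):
        loci = make_locus_set(np.linspace(0.01, 0.5, 9))
        _, _, rep = genoqc.filter_loci(_geno(np.zeros((4, 9))), loci, 0.05, 25)
        for s in rep.stages:
            assert s["n_removed"] + s["n_retained"] == s["n_input"]


class TestThinning:
    def test_one_per_fragment(self):
        loci = make_locus_set([0.3] * 5, fragment=["FA", "FA", "FA", "FB", "FB"])
        out = genoqc.thin_secondary_snps(loci, seed=0)
        assert len(out) == 2
        assert set(out.table["fragment_id"]) == {"FA", "FB"}

    def test_singleton_fragments_identity(self):
        loci = make_locus_set([0.3] * 4)
        out = genoqc.thin_secondary_snps(loci, seed=0)
        assert list(out.table["locus_id"]) == list(loci.table["locus_id"])

    def test_seed_determinism(self):
        loci = make_locus_set([0.3] * 6, fragment=["FA"] * 3 + ["FB"] * 3)
        a = genoqc.thin_secondary_snps(loci, seed=7)
        b = genoqc.thin_secondary_snps(loci, seed=7)
        assert list(a.table["locus_id"]) == list(b.table["locus_id"])

    def test_best_callrate_mode(self):
        calls = np.array([[0, -1, 0], [0, -1, 0], [0, 0, 0]], dtype=np.int8)
        geno = _geno(calls)
        loci = make_locus_set([0.3] * 3, fragment=["FA"] * 3)
        out = genoqc.thin_secondary_snps(loci, mode="best_callrate", geno=geno)
        assert list(out.table["locus_id"]) in (["S00000"], ["S00002"])
        # S00001 has the worst call rate and can never win
        assert list(out.table["locus_id"]) != ["S00001"]


class TestAlleleFreqs:
    def test_uniform_heterozygosity_uses_everyone(self):
        # every sample identical => no exclusions, full-sample frequency
        calls = np.tile(np.array([[0, 1, 2, 1]], dtype=np.int8), (6, 1))
        out = genoqc.estimate_allele_freqs(_geno(calls))
        np.testing.assert_allclose(out.p, [0.0, 0.5, 1.0, 0.5])

    def test_recovers_generating_frequency(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(0.1, 0.9, 40)
        calls = rng.binomial(2, p, size=(500, 40)).astype(np.int8)
        out = genoqc.estimate_allele_freqs(_geno(calls))
        se = np.sqrt(p * (1 - p) / (2 * 250))  # at least half retained
        assert np.abs(out.p - p).max() < 3 * np.sqrt(p * (1 - p) / (2 * 250)).max() + 0.02

    def test_contaminated_sample_excluded_from_estimation(self):
        rng = np.random.default_rng(3)
        p = np.full(300, 0.3)
        calls = rng.binomial(2, p, size=(40, 300)).astype(np.int8)
        calls[0] = 1  # fully heterozygous, far above Q3
        geno = _geno(calls)
        het = ((geno.calls == 1)).mean(axis=1)
        q3 = np.quantile(het, 0.75)
        assert het[0] > q3
        # frequency estimate should match the clean subset, not the mix
        out = genoqc.estimate_allele_freqs(geno)
        clean_p = calls[1:].mean(axis=0) / 2
        assert np.abs(out.p - clean_p).mean() < np.abs(out.p - calls.mean(axis=0) / 2).mean() + 0.02

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        calls = rng.binomial(2, 0.4, size=(30, 50)).astype(np.int8)
        a = genoqc.estimate_allele_freqs(_geno(calls))
        perm = rng.permutation(30)
        b = genoqc.estimate_allele_freqs(_geno(calls[perm]))
        np.testing.assert_allclose(a.p, b.p)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            genoqc.estimate_allele_freqs(_geno(np.zeros((3, 5))))

    def test_all_missing_locus_flagged_nan(self):
        calls = np.zeros((8, 3), dtype=np.int8)
        calls[:, 1] = -1
        out = genoqc.estimate_allele_freqs(_geno(calls))
        assert np.isnan(out.p[1])


class TestDuplicates:
    def test_exact_copy_detected(self):
        rng = np.random.default_rng(0)
        calls = rng.binomial(2, 0.3, size=(6, 300)).astype(np.int8)
        calls[1] = calls[0]
        hits = genoqc.find_duplicates(_geno(calls), concordance_min=0.95)
        assert len(hits) == 1
        assert hits[0][:2] == ("I0", "I1") and hits[0][2] == 1.0

    def test_unrelated_pairs_not_called(self):
        rng = np.random.default_rng(1)
        p = 0.3
        calls = rng.binomial(2, p, size=(20, 500)).astype(np.int8)
        # expected concordance for independent HWE pairs
        hwe = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
        expected = float((hwe**2).sum())
        assert expected < 0.5
        assert genoqc.find_duplicates(_geno(calls), concordance_min=0.95) == []

    def test_degraded_copy_detected_at_looser_threshold(self):
        rng = np.random.default_rng(2)
        calls = rng.binomial(2, 0.3, size=(6, 400)).astype(np.int8)
        copy = calls[0].copy()
        flip = rng.random(400) < 0.05
        copy[flip] = (copy[flip] + 1) % 3
        calls[1] = copy
        calls[1, :40] = -1  # more missingness => marked member
        hits = genoqc.find_duplicates(_geno(calls), concordance_min=0.9)
        assert len(hits) == 1
        assert hits[0][3] == "I1"

    def test_thin_overlap_pairs_warned_and_skipped(self):
        calls = np.full((3, 120), -1, dtype=np.int8)
        calls[0, :50] = 1
        calls[1, 60:] = 1
        calls[2, :] = 0
        with pytest.warns(UserWarning, match="co-observed"):
            genoqc.find_duplicates(_geno(calls), concordance_min=0.9)


class TestSampleOutliers:
    def _clean(self, rng, n=60, L=400):
        p = rng.uniform(0.2, 0.8, L)
        return rng.binomial(2, p, size=(n, L)).astype(np.int8), p

    def test_clean_data_nearly_no_removals(self):
        rng = np.random.default_rng(4)
        calls, p = self._clean(rng)
        geno = _geno(calls)
        loci = make_locus_set(p)
        out, rep = genoqc.filter_sample_outliers(geno, loci)
        assert rep.stages[-1]["n_removed"] <= 2

    def test_offtarget_species_removed_by_likelihood_rule(self):
        removed = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            calls, p = self._clean(rng)
            shift = np.where(p < 0.5, 0.4, -0.4)
            calls[0] = rng.binomial(2, np.clip(p + shift, 0.02, 0.98), 400)
            out, rep = genoqc.filter_sample_outliers(_geno(calls), make_locus_set(p))
            removed += "I0" not in out.sample_ids
        assert removed >= 18

    def test_degraded_removed_by_low_het_rule(self):
        rng = np.random.default_rng(6)
        calls, p = self._clean(rng)
        het = calls[0] == 1
        calls[0, het] = np.where(rng.random(het.sum()) < 0.5, 0, 2)
        out, rep = genoqc.filter_sample_outliers(_geno(calls), make_locus_set(p))
        assert "I0" not in out.sample_ids
        assert rep.stages[2]["n_removed"] >= 1  # low-het rule fired


class TestReplicates:
    def test_identical_replicates(self):
        rng = np.random.default_rng(0)
        calls = rng.binomial(2, 0.4, size=(4, 100)).astype(np.int8)
        calls[1] = calls[0]
        per_locus, per_sample = genoqc.replicate_concordance(_geno(calls), [("I0", "I1")])
        assert (per_locus == 1).all()
        assert per_sample["I0"] == 1.0

    def test_missing_excluded_from_denominator(self):
        calls = np.array([[1, -1, 0], [1, 2, -1]], dtype=np.int8)
        per_locus, per_sample = genoqc.replicate_concordance(
            _geno(calls), [("I0", "I1")]
        )
        assert per_locus.iloc[0] == 1.0
        assert np.isnan(per_locus.iloc[1]) and np.isnan(per_locus.iloc[2])
        assert per_sample["I0"] == 1.0

    def test_error_rate_concordance_matches_enumeration(self):
        # both replicates pass the per-allele miscall channel independently;
        # concordance = sum_o (sum_t P(t) E[t,o]^2) ... enumerated directly
        from oracles import flip_channel, hwe

        rng = np.random.default_rng(8)
        e, p, L = 0.05, 0.35, 30_000
        true = rng.binomial(2, p, L)
        E = flip_channel(e)
        cum = E.cumsum(axis=1)
        def observe():
            u = rng.random(L)
            return (u[:, None] > cum[true]).sum(axis=1)
        a, b = observe(), observe()
        measured = (a == b).mean()
        expected = sum(
            hwe(p)[t] * sum(E[t, o] ** 2 for o in range(3)) for t in range(3)
        )
        assert abs(measured - expected) < 0.01

    def test_no_replicates_empty(self):
        per_locus, per_sample = genoqc.replicate_concordance(
            _geno(np.zeros((2, 5))), []
        )
        assert per_locus.empty and per_sample.empty


class TestFullQC:
    def test_pipeline_removes_planted_anomalies(self, small_dataset):
        _, _, geno, loci, meta = small_dataset
        out, kept, rep = genoqc.run_qc(geno, loci, seed=1)
        stages = {s["stage"]: s for s in rep.stages}
        assert stages["duplicate_samples"]["n_removed"] >= 1
        assert stages["sample_het_high"]["n_removed"] >= 1
        anomalies = set(meta.loc[meta["anomaly"] == "offtarget", "sample_id"])
        assert not anomalies & set(out.sample_ids)

    def test_qc_is_idempotent_on_its_output(self, small_dataset):
        _, _, geno, loci, _ = small_dataset
        g1, l1, _ = genoqc.run_qc(geno, loci, seed=1)
        g2, l2, rep = genoqc.run_qc(g1, l1, seed=1)
        # no loci or samples should fall to the deterministic filters again
        stages = {s["stage"]: s for s in rep.stages}
        assert stages["locus_maf"]["n_removed"] == 0
        assert stages["locus_depth"]["n_removed"] == 0
        assert stages["secondary_snp_thinning"]["n_removed"] == 0
        assert stages["duplicate_samples"]["n_removed"] == 0
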