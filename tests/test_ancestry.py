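"""Local-ancestry HMM dosage, deviation scanning and the Grubbs test."""

import numpy as np
import pandas as pd
import pytest

import sweepscan as ss

from conftest import make_dataset


def _model(freqs, sources=None, **kw):
    sources = sources or [f"src{k}" for k in range(freqs.shape[1])]
    return ss.AncestryModel(source_freqs=pd.DataFrame(freqs, columns=sources), **kw)


class TestAncestryDosage:
    def test_identical_sources_posterior_equals_prior(self):
        rng = np.random.default_rng(0)
        m = 200
        f = rng.beta(2, 2, m)
        F = np.stack([f, f, f], axis=1)
        calls = rng.binomial(2, f[None, :], (4, m)).astype(np.int8)
        d = make_dataset(calls)
        pi = pd.DataFrame(np.tile([0.5, 0.3, 0.2], (4, 1)),
                          index=d.samples["sample_id"],
                          columns=["src0", "src1", "src2"])
        track = ss.ancestry_dosage(d, _model(F, global_q=pi), keep_individual=True)
        expect = 2 * np.array([0.5, 0.3, 0.2])
        assert np.allclose(track.per_individual, expect[None, None, :], atol=1e-9)

    def test_pure_source_individual_recovered(self):
        cfg = ss.SimConfig(n_snps=5000, n_chromosomes=2, n_admixed=5,
                           dirichlet_alpha=(100, 0.01, 0.01), seed=1)
        cohort, _, truth, _, freq = ss.simulate_cohort(cfg)
        model = ss.AncestryModel(source_freqs=freq[cfg.sources], generations=10)
        track = ss.ancestry_dosage(cohort, model, keep_individual=True)
        # cohort simulated almost entirely from the first source
        assert track.per_individual[:, :, 0].mean() >= 1.9

    def test_dosages_sum_to_two(self, small_cohort):
        cfg = small_cohort["cfg"]
        track = ss.ancestry_dosage(
            small_cohort["cohort"],
            ss.AncestryModel(source_freqs=small_cohort["freq"][cfg.sources]),
            keep_individual=True)
        sums = track.per_individual.sum(axis=2)
        assert np.allclose(sums, 2.0, atol=1e-6)
        cohort_sums = sum(track.dosage(s) for s in track.sources)
        assert np.allclose(cohort_sums, 2.0, atol=1e-6)

    def test_tract_recovery_correlation(self):
        """g=10 standard simulation: posterior dosage tracks the true tracts."""
        cfg = ss.SimConfig(n_snps=4000, n_chromosomes=2, n_admixed=50, seed=2)
        cohort, _, truth, _, freq = ss.simulate_cohort(cfg)
        model = ss.AncestryModel(source_freqs=freq[cfg.sources], generations=10)
        track = ss.ancestry_dosage(cohort, model, keep_individual=True)
        anc = truth.local_ancestry
        corrs = []
        for k in range(3):
            true_d = (anc[0::2] == k).astype(float) + (anc[1::2] == k)
            corrs.append(np.corrcoef(true_d.ravel(),
                                     track.per_individual[:, :, k].ravel())[0, 1])
        assert np.mean(corrs) >= 0.9

    def test_g_near_zero_constant_ancestry(self):
        """With no recombination time the chain cannot switch: posterior
        dosage is (numerically) constant along each chromosome."""
        cfg = ss.SimConfig(n_snps=1000, n_chromosomes=1, n_admixed=10,
                           generations=1, cm_per_mb=1e-6, seed=3)
        cohort, _, truth, _, freq = ss.simulate_cohort(cfg)
        model = ss.AncestryModel(source_freqs=freq[cfg.sources], generations=1,
                                 cm_per_mb=1e-6)
        track = ss.ancestry_dosage(cohort, model, keep_individual=True)
        spread = track.per_individual.max(axis=1) - track.per_individual.min(axis=1)
        assert spread.max() < 0.2

    def test_divergence_improves_recovery(self):
        corrs = []
        for fst in (0.05, 0.3):
            cfg = ss.SimConfig(n_snps=2000, n_chromosomes=1, n_admixed=20,
                               fst=fst, seed=4)
            cohort, _, truth, _, freq = ss.simulate_cohort(cfg)
            model = ss.AncestryModel(source_freqs=freq[cfg.sources])
            track = ss.ancestry_dosage(cohort, model, keep_individual=True)
            anc = truth.local_ancestry
            cs = []
            for k in range(3):
                true_d = (anc[0::2] == k).astype(float) + (anc[1::2] == k)
                cs.append(np.corrcoef(true_d.ravel(),
                                      track.per_individual[:, :, k].ravel())[0, 1])
            corrs.append(np.mean(cs))
        assert corrs[1] > corrs[0]

    def test_genomewide_dosage_matches_cohort_q(self):
        cfg = ss.SimConfig(n_snps=4000, n_chromosomes=2, n_admixed=80, seed=5)
        cohort, _, truth, _, freq = ss.simulate_cohort(cfg)
        track = ss.ancestry_dosage(
            cohort, ss.AncestryModel(source_freqs=freq[cfg.sources]))
        for k, src in enumerate(cfg.sources):
            est = track.dosage(src).mean() / 2.0
            assert abs(est - truth.realized_q.iloc[:, k].mean()) < 0.03


class TestDeviationScan:
    def _track(self, dosages, sources=("a", "b")):
        m = dosages.shape[0]
        table = pd.DataFrame({"snp_id": [f"s{i}" for i in range(m)],
                              "chrom": "1", "pos": np.arange(1, m + 1)})
        for k, s in enumerate(sources):
            table[f"dosage_{s}"] = dosages[:, k]
        return ss.AncestryDosageTrack(table=table, sources=list(sources))

    def test_flat_track_no_flags(self):
        dos = np.tile([1.0, 1.0], (150, 1))
        with pytest.warns(UserWarning, match="constant"):
            out = ss.deviation_scan(self._track(dos))
        assert out.table.empty

    def test_threshold_rule_between_2_and_3_sd(self):
        rng = np.random.default_rng(6)
        base = rng.normal(1.0, 0.1, 200)
        mu, sd = base.mean(), base.std(ddof=0)
        base[50] = mu + 2.5 * sd
        # keep mean/sd from shifting materially: large n, one bump
        dos = np.stack([base, 2 - base], axis=1)
        out = ss.deviation_scan(self._track(dos))
        hit = out.table[(out.table["source"] == "a") & (out.table["pos"] == 51)]
        assert len(hit) == 1
        assert bool(hit["flag_2sd"].iloc[0]) and not bool(hit["flag_3sd"].iloc[0])

    def test_injected_block_matches_bruteforce(self):
        rng = np.random.default_rng(7)
        base = rng.normal(0.5, 0.05, 300)
        base[120:130] += 0.5
        dos = np.stack([base, 2 - base], axis=1)
        out = ss.deviation_scan(self._track(dos))
        mu, sd = base.mean(), base.std(ddof=0)
        expect = set(np.flatnonzero(base > mu + 2 * sd) + 1)
        got = set(out.table.loc[out.table["source"] == "a", "pos"])
        assert got == expect

    def test_short_track_rejected(self):
        dos = np.tile([1.0, 1.0], (50, 1))
        with pytest.raises(ValueError, match="needs >="):
            ss.deviation_scan(self._track(dos))


class TestGrubbs:
    def test_single_outlier_formula(self):
        res = ss.grubbs_one_outlier([1, 1, 1, 1, 10])
        assert res.G == pytest.approx(1.789, abs=5e-4)
        assert res.G == pytest.approx((5 - 1) / np.sqrt(5))  # saturated bound
        assert res.U == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_three_points(self):
        res = ss.grubbs_one_outlier([1, 2, 3])
        assert res.G == pytest.approx(1.0)
        assert res.U == pytest.approx(0.25)

    def test_u_equals_direct_variance_ratio(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=40)
        res = ss.grubbs_one_outlier(x)
        x_wo = np.delete(x, np.argmax(x))
        ss1 = ((x_wo - x_wo.mean()) ** 2).sum()
        ss0 = ((x - x.mean()) ** 2).sum()
        assert res.U == pytest.approx(ss1 / ss0)

    def test_bound_respected_and_p_range(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            x = rng.normal(size=25)
            res = ss.grubbs_one_outlier(x)
            assert res.G <= (25 - 1) / np.sqrt(25) + 1e-12
            assert 0.0 <= res.p <= 1.0

    def test_constant_input_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            ss.grubbs_one_outlier([2.0, 2.0, 2.0])
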