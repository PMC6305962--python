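"""EHH/iHH machinery, iHS and XP-EHH scans."""

import itertools

import numpy as np
import pandas as pd
import pytest

import sweepscan as ss
from sweepscan.haplotype import (FLAG_CHROM_END, FLAG_OK, HaplotypeSet,
                                 _ihh_one_side, ihs_transform,
                                 two_sided_gaussian_p)

from conftest import make_dataset


def make_haps(matrix, pos=None):
    matrix = np.asarray(matrix, dtype=np.int8)
    m = matrix.shape[1]
    markers = pd.DataFrame({
        "snp_id": [f"s{j}" for j in range(m)], "chrom": ["1"] * m,
        "pos": pos if pos is not None else np.arange(1, m + 1) * 1000,
        "ref": ["A"] * m, "alt": ["G"] * m})
    return HaplotypeSet(markers=markers, haplotypes=matrix,
                        sample_ids=[f"i{k}" for k in range(matrix.shape[0] // 2)])


def brute_force_ehh(matrix, core, allele, to):
    """Independent oracle: fraction of carrier pairs identical core..to."""
    carriers = [h for h in range(matrix.shape[0]) if matrix[h, core] == allele]
    lo, hi = min(core, to), max(core, to)
    same = 0
    pairs = list(itertools.combinations(carriers, 2))
    for a, b in pairs:
        if np.array_equal(matrix[a, lo:hi + 1], matrix[b, lo:hi + 1]):
            same += 1
    return same / len(pairs)


class TestAncestralInference:
    def test_majority_rule_and_tie(self):
        # SNP0: alt common -> ancestral alt; SNP1: tie -> ref
        calls = np.array([[2, 1], [2, 1], [1, 0], [2, 2]], dtype=np.int8)
        d = make_dataset(calls)
        anc_alt, usable = ss.infer_ancestral_alleles(d)
        assert anc_alt[0] and usable[0]
        assert not anc_alt[1]  # 4 alt vs 4 ref -> ref by tie-break

    def test_monomorphic_flagged(self):
        d = make_dataset(np.zeros((3, 1), dtype=np.int8))
        anc_alt, usable = ss.infer_ancestral_alleles(d)
        assert not usable[0]

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(0)
        calls = rng.integers(0, 3, (25, 40)).astype(np.int8)
        d = make_dataset(calls)
        anc_alt, _ = ss.infer_ancestral_alleles(d)
        alt = calls.sum(axis=0)
        ref = 2 * 25 - alt
        assert np.array_equal(anc_alt, alt > ref)


class TestEhh:
    def test_core_itself_is_one(self):
        h = make_haps([[0, 1], [0, 0], [1, 1], [0, 1]])
        assert ss.ehh(h, 0, 0, 0) == 1.0

    def test_three_one_split(self):
        """4 carriers extending as {x,x,x,y} -> C(3,2)/C(4,2) = 0.5."""
        mat = [[1, 0, 0],
               [1, 0, 0],
               [1, 0, 0],
               [1, 0, 1],
               [0, 1, 1],
               [0, 1, 0]]
        h = make_haps(mat)
        assert ss.ehh(h, 0, 1, 2) == pytest.approx(0.5)

    def test_shared_haplotype_stays_one(self):
        mat = np.zeros((6, 10), dtype=np.int8)
        mat[:4, 0] = 1  # carriers all share the all-zero extension
        h = make_haps(mat)
        assert ss.ehh(h, 0, 1, 9) == 1.0

    def test_equals_bruteforce_on_random_fixtures(self):
        """Pair-counting enumeration oracle on fixtures <= 30 haps x 20 SNPs."""
        rng = np.random.default_rng(1)
        for trial in range(20):
            n_h = int(rng.integers(6, 31) // 2 * 2)
            m = int(rng.integers(5, 21))
            mat = rng.integers(0, 2, (n_h, m)).astype(np.int8)
            core = int(rng.integers(0, m))
            allele = int(rng.integers(0, 2))
            if (mat[:, core] == allele).sum() < 2:
                continue
            to = int(rng.integers(0, m))
            assert ss.ehh(make_haps(mat), core, allele, to) == pytest.approx(
                brute_force_ehh(mat, core, allele, to))

    def test_non_increasing_with_distance(self):
        rng = np.random.default_rng(2)
        mat = rng.integers(0, 2, (20, 15)).astype(np.int8)
        h = make_haps(mat)
        vals = [ss.ehh(h, 0, mat[0, 0], t) for t in range(15)]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))


class TestIhh:
    def test_constant_ehh_rectangle(self):
        """EHH stays 1 over a 10 kb flank shared by all carriers, then collapses."""
        mat = np.zeros((8, 3), dtype=np.int8)
        mat[:4, 0] = 1
        # SNP2 splits every carrier into its own class -> EHH ~ 0
        mat[:, 2] = [0, 1, 0, 1, 0, 1, 0, 1]
        mat[0, 2], mat[1, 2], mat[2, 2], mat[3, 2] = 0, 0, 1, 1
        h = make_haps(mat, pos=[1000, 11000, 11001])
        total, fl, fr = ss.ihh(h, 0, 1)
        # right side: 1.0 across 10 kb, then EHH drops to C(2,2)-pairs level
        assert total >= 10_000

    def test_piecewise_trapezoid_with_interpolated_tail(self):
        """Hand-checked trapezoid: EHH {1@0, 0.5@1k, 0.04@2k}, cutoff 0.05
        -> 750 + interpolated tail 269.02 (truncate at the 0.05 crossing)."""
        ehh_vals = np.array([1.0, 0.5, 0.04])
        pos = np.array([0, 1000, 2000])
        cutoff = 0.05
        area = 0.5 * (ehh_vals[0] + ehh_vals[1]) * 1000
        frac = (ehh_vals[1] - cutoff) / (ehh_vals[1] - ehh_vals[2])
        area += 0.5 * (ehh_vals[1] + cutoff) * frac * 1000
        assert area == pytest.approx(750 + 269.0217, abs=0.01)
        # and the kernel reproduces it on a fixture engineered to that decay:
        # 4 carriers at core; next SNP splits 2/2 (EHH=(1+1)/6=1/3)... use
        # direct curve check instead via explicit haplotypes below.

    def test_kernel_matches_manual_integration(self):
        rng = np.random.default_rng(3)
        mat = rng.integers(0, 2, (16, 12)).astype(np.int8)
        mat[:, 0] = [1] * 8 + [0] * 8
        pos = np.sort(rng.choice(np.arange(1, 100_000), 12, replace=False))
        h = make_haps(mat, pos=pos)
        carriers = np.flatnonzero(mat[:, 0] == 1).astype(np.int64)
        got, flag = _ihh_one_side(mat, pos.astype(np.int64), 0, carriers,
                                  +1, 0.05, 10 ** 9)
        # manual: EHH curve by brute force, trapezoid with crossing truncation
        curve = [1.0] + [brute_force_ehh(mat, 0, 1, t) for t in range(1, 12)]
        area, prev = 0.0, 1.0
        for t in range(1, 12):
            span = pos[t] - pos[t - 1]
            cur = curve[t]
            if cur < 0.05:
                if prev > 0.05:
                    fracn = (prev - 0.05) / (prev - cur)
                    area += 0.5 * (prev + 0.05) * fracn * span
                break
            area += 0.5 * (prev + cur) * span
            prev = cur
        else:
            assert flag == FLAG_CHROM_END
        assert got == pytest.approx(area)

    def test_mirrored_haplotypes_symmetric_integrals(self):
        rng = np.random.default_rng(4)
        right = rng.integers(0, 2, (10, 6)).astype(np.int8)
        core = np.ones((10, 1), dtype=np.int8)
        mat = np.hstack([right[:, ::-1], core, right])
        pos = np.arange(13) * 1000 + 1
        h = make_haps(mat, pos=pos)
        carriers = np.arange(10, dtype=np.int64)
        left, _ = _ihh_one_side(mat, pos.astype(np.int64), 6, carriers, -1, 0.05, 10 ** 9)
        rgt, _ = _ihh_one_side(mat, pos.astype(np.int64), 6, carriers, +1, 0.05, 10 ** 9)
        assert left == pytest.approx(rgt)


class TestIhsScan:
    def test_transform_and_p_at_zero_and_quantile(self):
        assert ihs_transform(np.array([0.0]))[0] == pytest.approx(0.0)
        assert two_sided_gaussian_p(np.array([0.0]))[0] == pytest.approx(1.0)
        assert two_sided_gaussian_p(np.array([1.959964]))[0] == pytest.approx(0.05, abs=1e-6)

    def test_bin_standardization_zero_mean_unit_sd(self, small_cohort):
        hset = small_cohort["hset"]
        anc_alt, usable = ss.infer_ancestral_alleles(small_cohort["cohort"])
        h = HaplotypeSet(markers=hset.markers, haplotypes=hset.haplotypes,
                         sample_ids=hset.sample_ids,
                         ancestral_is_alt=anc_alt, usable=usable)
        res = ss.ihs_scan(h)
        for b, grp in res.table.groupby("freq_bin"):
            if len(grp) >= 2:
                assert abs(grp["ihs_std"].mean()) < 1e-9
                assert grp["ihs_std"].std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_transform_is_minus_log10_of_two_sided_p(self, small_cohort):
        z = np.linspace(-4, 4, 11)
        assert np.allclose(ihs_transform(z), -np.log10(two_sided_gaussian_p(z)))


class TestXpehhScan:
    def _pair_sets(self, seed=5, m=300):
        rng = np.random.default_rng(seed)
        mat = rng.integers(0, 2, (40, m)).astype(np.int8)
        h1 = make_haps(mat)
        h2 = make_haps(mat.copy())
        return h1, h2

    def test_identical_populations_zero_raw(self):
        h1, h2 = self._pair_sets()
        res = ss.xpehh_scan(h1, h2)
        assert np.allclose(res.table["xpehh_raw"], 0.0)

    def test_fixed_object_population_positive(self):
        rng = np.random.default_rng(6)
        ref = rng.integers(0, 2, (30, 41)).astype(np.int8)
        obj = rng.integers(0, 2, (30, 41)).astype(np.int8)
        obj[:, 15:26] = obj[0, 15:26]  # one fixed extended haplotype
        h_obj, h_ref = make_haps(obj), make_haps(ref)
        res = ss.xpehh_scan(h_obj, h_ref)
        row = res.table[res.table["pos"] == 21 * 1000]
        assert row["xpehh_raw"].iloc[0] > 0

    def test_population_relabel_negates_raw(self):
        rng = np.random.default_rng(7)
        a = make_haps(rng.integers(0, 2, (24, 200)).astype(np.int8))
        b = make_haps(rng.integers(0, 2, (30, 200)).astype(np.int8))
        r1 = ss.xpehh_scan(a, b).table.set_index("snp_id")
        r2 = ss.xpehh_scan(b, a).table.set_index("snp_id")
        common = r1.index.intersection(r2.index)
        assert np.allclose(r1.loc[common, "xpehh_raw"],
                           -r2.loc[common, "xpehh_raw"])

    def test_standardization_exact(self, small_cohort):
        hset = small_cohort["hset"]
        panels = small_cohort["panels"]
        ref = panels.subset_population("indicine")
        h_ref = HaplotypeSet(markers=hset.markers.copy(),
                             haplotypes=ref.haplotypes,
                             sample_ids=ref.samples["sample_id"].tolist())
        res = ss.xpehh_scan(hset, h_ref)
        std = res.table["xpehh_std"].to_numpy()
        assert std.mean() == pytest.approx(0.0, abs=1e-12)
        assert std.std(ddof=0) == pytest.approx(1.0, abs=1e-12)
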