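"""FDR control, sweep-region clustering, annotation and overlaps."""

import numpy as np
import pandas as pd
import pytest

import sweepscan as ss


def bh_bruteforce(p, alpha):
    """Step-up scan over every cutoff: reject all p <= p_(i*) where
    i* = max{i: p_(i) <= i*alpha/m}."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    istar = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * alpha / m:
            istar = rank
    reject = np.zeros(m, bool)
    if istar:
        reject[order[:istar]] = True
    return reject


class TestFdrControl:
    def test_step_up_enumeration_example(self):
        res = ss.fdr_control(np.array([0.01, 0.02, 0.03, 0.5]), alpha=0.05)
        assert res.reject.sum() == 3
        assert res.p_cutoff == 0.03

    def test_all_ones_none_rejected(self):
        assert ss.fdr_control(np.ones(10), alpha=0.05).reject.sum() == 0

    def test_all_zeros_all_rejected(self):
        assert ss.fdr_control(np.zeros(10), alpha=0.01).reject.all()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_on_random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        p = np.concatenate([rng.uniform(0, 1, 5000),
                            rng.uniform(0, 1e-3, 50)])
        for alpha in (0.01, 0.05):
            got = ss.fdr_control(p, alpha=alpha).reject
            assert np.array_equal(got, bh_bruteforce(p, alpha))

    def test_monotone_in_alpha(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0, 0.2, 500)
        r1 = ss.fdr_control(p, alpha=0.01).reject
        r2 = ss.fdr_control(p, alpha=0.05).reject
        assert np.all(r2[r1])  # every 1%-rejection also rejected at 5%

    def test_storey_rejects_superset_structure(self):
        rng = np.random.default_rng(4)
        p = np.concatenate([rng.uniform(0, 1, 1000), rng.uniform(0, 1e-4, 20)])
        res = ss.fdr_control(p, alpha=0.01, method="storey")
        assert res.reject.sum() >= 20
        assert np.all((res.qvalues >= 0) & (res.qvalues <= 1))


def _sig(pos_kb, chrom="1", stat=None):
    n = len(pos_kb)
    return pd.DataFrame({
        "chrom": [chrom] * n,
        "pos": [int(p * 1000) for p in pos_kb],
        "snp_id": [f"m{i}" for i in range(n)],
        "stat": stat if stat is not None else np.ones(n)})


class TestClusterCandidates:
    def test_chain_enumeration_example(self):
        regs, singles = ss.cluster_candidates(
            _sig([100, 450, 700, 1500, 2300, 2350]), statistic="stat")
        spans = sorted((r.start_bp, r.end_bp, r.n_members) for r in regs)
        assert spans == [(100_000, 700_000, 3), (2_300_000, 2_350_000, 2)]
        assert singles["pos"].tolist() == [1_500_000]

    def test_single_snp_no_region(self):
        regs, singles = ss.cluster_candidates(_sig([500]))
        assert regs == [] and len(singles) == 1

    def test_exact_500kb_gap_inclusive(self):
        regs, _ = ss.cluster_candidates(_sig([100, 600]))  # gap exactly 500 kb
        assert len(regs) == 1

    def test_partition_and_idempotence(self):
        rng = np.random.default_rng(5)
        pos = np.sort(rng.choice(np.arange(1, 50_000_000), 200, replace=False))
        sig = pd.DataFrame({"chrom": "1", "pos": pos,
                            "snp_id": [f"m{i}" for i in range(200)]})
        regs, singles = ss.cluster_candidates(sig)
        n_in_regions = sum(r.n_members for r in regs)
        assert n_in_regions + len(singles) == 200
        # regions are disjoint and reproduce themselves when re-clustered
        spans = sorted((r.start_bp, r.end_bp) for r in regs)
        assert all(a[1] < b[0] for a, b in zip(spans, spans[1:]))
        for r in regs:
            sub = sig[sig["snp_id"].isin(r.member_snp_ids)]
            regs2, s2 = ss.cluster_candidates(sub)
            assert len(regs2) == 1 and len(s2) == 0
            assert (regs2[0].start_bp, regs2[0].end_bp) == (r.start_bp, r.end_bp)

    def test_top_snp_most_extreme_tie_smallest_pos(self):
        sig = _sig([100, 200, 300], stat=[-5.0, 5.0, 3.0])
        regs, _ = ss.cluster_candidates(sig, statistic="stat")
        assert regs[0].top_snp_id == "m0"  # |−5| ties |5|; smaller position wins


def _regions(spans, chrom="1"):
    return [ss.SweepRegion(chrom=chrom, start_bp=s, end_bp=e,
                           member_snp_ids=["a", "b"], top_snp_id="a",
                           top_statistic=1.0) for s, e in spans]


class TestAnnotateRegions:
    def test_containment_and_flank_boundary(self):
        genes = pd.DataFrame({
            "gene": ["inside", "at_flank_edge", "beyond"],
            "chrom": ["1"] * 3,
            "start": [1_200_000, 800_000, 600_000],
            "end": [1_300_000, 900_000, 899_999]})
        regs = _regions([(1_000_000, 2_000_000)])
        out = ss.annotate_regions(regs, genes, flank=100_000)
        # flank window starts at 900,000: a gene ending exactly there is in
        assert set(out["gene"]) == {"inside", "at_flank_edge"}

    def test_unknown_chromosome_warns_empty(self):
        genes = pd.DataFrame({"gene": ["g"], "chrom": ["9"],
                              "start": [1], "end": [10]})
        regs = _regions([(100, 200)])
        with pytest.warns(UserWarning, match="absent"):
            out = ss.annotate_regions(regs, genes)
        assert out.empty and regs[0].genes == []

    def test_matches_bruteforce_intersection(self):
        rng = np.random.default_rng(6)
        genes = pd.DataFrame({
            "gene": [f"g{i}" for i in range(50)],
            "chrom": rng.choice(["1", "2"], 50),
            "start": rng.integers(1, 10_000_000, 50)})
        genes["end"] = genes["start"] + rng.integers(1000, 200_000, 50)
        regs = []
        for i in range(5):
            s = int(rng.integers(1, 9_000_000))
            regs.append(ss.SweepRegion(chrom=str(rng.choice(["1", "2"])),
                                       start_bp=s, end_bp=s + 500_000,
                                       member_snp_ids=["x", "y"],
                                       top_snp_id="x", top_statistic=0.0))
        flank = 100_000
        out = ss.annotate_regions(regs, genes, flank=flank)
        expected = set()
        for ri, r in enumerate(regs):
            for _, g in genes.iterrows():
                if g["chrom"] == r.chrom and g["start"] <= r.end_bp + flank \
                        and g["end"] >= max(1, r.start_bp - flank):
                    expected.add((ri, g["gene"]))
        got = set(zip(out["region_index"], out["gene"]))
        assert got == expected

    def test_bed_halfopen_conversion(self, tmp_path):
        (tmp_path / "g.bed").write_text("1\t999\t2000\tgeneA\n")
        genes = ss.read_gene_annotation(tmp_path / "g.bed")
        assert genes.loc[0, "start"] == 1000 and genes.loc[0, "end"] == 2000

    def test_gff3_gene_features_only(self, tmp_path):
        (tmp_path / "g.gff3").write_text(
            "##gff-version 3\n"
            "1\tsrc\tgene\t1000\t2000\t.\t+\t.\tID=g1;Name=MYGENE\n"
            "1\tsrc\texon\t1000\t1500\t.\t+\t.\tID=e1\n")
        genes = ss.read_gene_annotation(tmp_path / "g.gff3")
        assert genes["gene"].tolist() == ["MYGENE"]


class TestOverlapRegions:
    def test_identity(self):
        regs = _regions([(100, 200), (300, 400)])
        pairs = ss.overlap_regions(regs, regs)
        assert set(pairs) >= {(0, 0), (1, 1)}

    def test_disjoint_chromosomes_empty(self):
        assert ss.overlap_regions(_regions([(100, 200)], "1"),
                                  _regions([(100, 200)], "2")) == []

    def test_one_large_vs_two_subregions(self):
        """A broad interval overlaps both nested sub-intervals but not a
        distal one (the two-methods-same-locus comparison pattern)."""
        big = _regions([(23_280_000, 26_990_000)], "14")
        subs = _regions([(23_490_000, 23_860_000), (26_470_000, 26_680_000),
                         (30_000_000, 31_000_000)], "14")
        pairs = ss.overlap_regions(big, subs)
        assert sorted(pairs) == [(0, 0), (0, 1)]
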