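"""End-to-end pipeline orchestration with a checksummed output manifest.

Stages run in the fixed order qc -> stats -> structure -> scans (iHS,
XP-EHH, pcadapt) -> fdr/regions -> ancestry.  Every stage writes TSV outputs
into the run directory; the manifest records parameters, per-stage counts and
a sha256 for each file, so reruns under the same config and seed are
verifiable byte-for-byte.  The quick-start mode generates its own synthetic
admixed cohort, so the whole pipeline is runnable without any input data.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ancestry as anc_mod
from . import haplotype as hap_mod
from . import io_qc, pca_outlier, popgen, regions as reg_mod, structure
from .simulate import SimConfig, SweepSpec, simulate_cohort


@dataclass
class PipelineConfig:
    """Validated knobs for every stage (defaults = the emulated study's)."""

    out_dir: str = "sweepscan_run"
    seed: int = 0
    # inputs; when vcf is None the synthetic quick-start cohort is used
    vcf: str | None = None
    genes: str | None = None
    # synthetic cohort size (quick-start mode)
    sim_n_snps: int = 4000
    sim_n_admixed: int = 120
    sim_sweep: bool = True
    # QC
    min_call_rate: float = 0.90
    min_maf: float = 0.05
    max_sample_missing: float = 0.10
    # LD pruning
    prune_window: int = 50
    prune_step: int = 5
    prune_r2: float = 0.3
    # scans
    n_freq_bins: int = 20
    ehh_cutoff: float = 0.05
    max_gap_bp: int = 200_000
    pca_components: int = 10
    pcadapt_df: int | None = None
    # FDR / regions
    fdr_alpha: float = 0.01
    fdr_method: str = "bh"
    cluster_max_gap: int = 500_000
    cluster_min_snps: int = 2
    flank_bp: int = 100_000
    # ancestry
    generations: float = 10.0
    cm_per_mb: float = 1.0

    def __post_init__(self) -> None:
        for name, lo, hi in [("min_call_rate", 0, 1), ("min_maf", 0, 0.5),
                             ("max_sample_missing", 0, 1), ("fdr_alpha", 0, 1),
                             ("ehh_cutoff", 0, 1), ("prune_r2", 0, 1)]:
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo},{hi}]")
        if self.fdr_method not in ("bh", "storey"):
            raise ValueError(f"unknown fdr_method {self.fdr_method!r}")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(df: pd.DataFrame, out_dir: str, name: str, manifest: dict) -> str:
    path = os.path.join(out_dir, name)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    manifest["outputs"][name] = _sha256(path)
    return path


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages; returns (and writes) the manifest."""
    os.makedirs(cfg.out_dir, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(cfg), "outputs": {}, "counts": {}}

    # ----- data -------------------------------------------------------
    if cfg.vcf is not None:
        cohort = io_qc.read_vcf(cfg.vcf)
        hset = (hap_mod.HaplotypeSet.from_dataset(cohort)
                if cohort.haplotypes is not None else None)
        panels = None
        freq_table = None
    else:
        sweeps = []
        sim = SimConfig(n_snps=cfg.sim_n_snps, n_admixed=cfg.sim_n_admixed,
                        generations=cfg.generations, cm_per_mb=cfg.cm_per_mb,
                        seed=cfg.seed)
        if cfg.sim_sweep:
            core = int(sim.chrom_length_bp * 0.5)
            sweeps = [SweepSpec(chrom="1", core_pos=core,
                                source_bias=sim.sources[1])]
            sim = dataclasses.replace(sim, sweeps=sweeps)
        cohort, hset, truth, panels, freq_table = simulate_cohort(sim)

    # ----- qc ---------------------------------------------------------
    cohort_qc, report = io_qc.qc_filter(
        cohort, cfg.min_call_rate, cfg.min_maf, cfg.max_sample_missing)
    _write(report.to_frame(), cfg.out_dir, "qc_dropped.tsv", manifest)
    per_chrom, totals = io_qc.panel_summary(cohort_qc)
    _write(per_chrom, cfg.out_dir, "panel_summary.tsv", manifest)
    manifest["counts"]["qc"] = {
        "n_snps_in": report.n_snps_in, "n_snps_out": report.n_snps_out,
        "n_samples_in": report.n_samples_in, "n_samples_out": report.n_samples_out,
        **totals}
    kept = cohort_qc.markers["snp_id"]
    if hset is not None:
        keep_idx = hset.markers.set_index("snp_id").index.get_indexer(kept)
        keep_idx = keep_idx[keep_idx >= 0]
        hset = hap_mod.HaplotypeSet(
            markers=hset.markers.iloc[keep_idx],
            haplotypes=hset.haplotypes[:, keep_idx],
            sample_ids=hset.sample_ids)

    # ----- stats ------------------------------------------------------
    freqs = popgen.allele_freq_table(cohort_qc)
    spectrum = popgen.maf_spectrum(freqs, groups=None)
    _write(spectrum, cfg.out_dir, "maf_spectrum.tsv", manifest)
    het = popgen.observed_heterozygosity(cohort_qc)
    _write(het, cfg.out_dir, "heterozygosity.tsv", manifest)
    pruned = popgen.ld_prune(cohort_qc, cfg.prune_window, cfg.prune_step, cfg.prune_r2)
    fvals = popgen.inbreeding_f(cohort_qc, pruned)
    _write(fvals, cfg.out_dir, "inbreeding.tsv", manifest)
    manifest["counts"]["stats"] = {"n_pruned_retained": len(pruned)}

    # ----- structure --------------------------------------------------
    kin = structure.king_kinship(cohort_qc)
    unrelated = structure.select_unrelated(kin)
    pca = structure.pca_genotypes(cohort_qc, n_components=cfg.pca_components,
                                  unrelated_only=True, kinship=kin)
    scree = pd.DataFrame({"component": np.arange(1, len(pca.variance_ratio) + 1),
                          "variance_ratio": pca.variance_ratio})
    _write(scree, cfg.out_dir, "pca_scree.tsv", manifest)
    _write(pca.scores.reset_index(names="sample_id"), cfg.out_dir,
           "pca_scores.tsv", manifest)
    manifest["counts"]["structure"] = {"n_unrelated": len(unrelated)}

    model_q = None
    if freq_table is not None:
        ref = freq_table.set_index("snp_id").loc[kept].reset_index()
        src_cols = [c for c in ref.columns if c not in ("snp_id", "ancestral_freq")]
        admix = structure.supervised_admixture(cohort_qc, ref[src_cols])
        _write(admix.q.reset_index(names="sample_id"), cfg.out_dir,
               "admixture_q.tsv", manifest)
        model_q = admix.q

    # ----- scans ------------------------------------------------------
    sig_tables = {}
    if hset is not None:
        anc_alt, usable = hap_mod.infer_ancestral_alleles(cohort_qc)
        hset.ancestral_is_alt = anc_alt
        hset.usable = usable
        ihs = hap_mod.ihs_scan(hset, maf_min=cfg.min_maf,
                               n_freq_bins=cfg.n_freq_bins,
                               ehh_cutoff=cfg.ehh_cutoff, max_gap_bp=cfg.max_gap_bp)
        _write(ihs.table, cfg.out_dir, "ihs.tsv", manifest)
        sig_tables["ihs"] = (ihs.table, "ihs_std")
        if panels is not None:
            ref_pop = panels.samples["population"].iloc[-1]
            ref_panel = panels.subset_population(ref_pop)
            ref_idx = ref_panel.markers.set_index("snp_id").index.get_indexer(
                hset.markers["snp_id"])
            h_ref = hap_mod.HaplotypeSet(
                markers=hset.markers.copy(),
                haplotypes=ref_panel.haplotypes[:, ref_idx],
                sample_ids=ref_panel.samples["sample_id"].tolist())
            xp = hap_mod.xpehh_scan(hset, h_ref, ehh_cutoff=cfg.ehh_cutoff,
                                    max_gap_bp=cfg.max_gap_bp)
            _write(xp.table, cfg.out_dir, "xpehh.tsv", manifest)
            sig_tables["xpehh"] = (xp.table, "xpehh_std")

    scan = pca_outlier.pcadapt_scan(cohort_qc, pca, df=cfg.pcadapt_df)
    _write(scan.table, cfg.out_dir, "pcadapt.tsv", manifest)
    sig_tables["pcadapt"] = (scan.table.rename(columns={"p": "p_two_sided"}), "D2")
    manifest["counts"]["scans"] = {"pcadapt_K": scan.K, "pcadapt_df": scan.df}

    # ----- fdr / regions ---------------------------------------------
    genes = (reg_mod.read_gene_annotation(cfg.genes) if cfg.genes else None)
    all_regions: dict[str, list] = {}
    region_frames = []
    for method, (table, stat_col) in sig_tables.items():
        fdr = reg_mod.fdr_control(table["p_two_sided"].to_numpy(),
                                  alpha=cfg.fdr_alpha, method=cfg.fdr_method)
        sig = table[fdr.reject]
        regs, singles = reg_mod.cluster_candidates(
            sig, max_gap=cfg.cluster_max_gap, min_snps=cfg.cluster_min_snps,
            statistic=stat_col, method=method)
        if genes is not None:
            reg_mod.annotate_regions(regs, genes, flank=cfg.flank_bp)
        frame = reg_mod.regions_to_frame(regs)
        region_frames.append(frame)
        all_regions[method] = regs
        manifest["counts"][f"regions_{method}"] = {
            "n_significant": int(fdr.reject.sum()), "n_regions": len(regs),
            "n_singletons": len(singles), "p_cutoff": fdr.p_cutoff}
    regions_out = (pd.concat(region_frames, ignore_index=True)
                   if region_frames else pd.DataFrame())
    _write(regions_out, cfg.out_dir, "regions.tsv", manifest)
    methods = list(all_regions)
    overlap_rows = []
    for i in range(len(methods)):
        for j in range(i + 1, len(methods)):
            for (ia, ib) in reg_mod.overlap_regions(all_regions[methods[i]],
                                                    all_regions[methods[j]]):
                ra, rb = all_regions[methods[i]][ia], all_regions[methods[j]][ib]
                overlap_rows.append({
                    "method_a": methods[i], "method_b": methods[j],
                    "chrom": ra.chrom,
                    "a_start": ra.start_bp, "a_end": ra.end_bp,
                    "b_start": rb.start_bp, "b_end": rb.end_bp})
    _write(pd.DataFrame(overlap_rows,
                        columns=["method_a", "method_b", "chrom", "a_start",
                                 "a_end", "b_start", "b_end"]),
           cfg.out_dir, "region_overlaps.tsv", manifest)

    # ----- ancestry ---------------------------------------------------
    if freq_table is not None:
        unrel_idx = [i for i, s in enumerate(cohort_qc.samples["sample_id"])
                     if s in set(unrelated)]
        cohort_unrel = cohort_qc.take_samples(unrel_idx)
        ref = freq_table.set_index("snp_id").loc[kept]
        src_cols = [c for c in ref.columns if c != "ancestral_freq"]
        model = anc_mod.AncestryModel(
            source_freqs=ref[src_cols].reset_index(drop=True),
            generations=cfg.generations, global_q=model_q,
            cm_per_mb=cfg.cm_per_mb)
        track = anc_mod.ancestry_dosage(cohort_unrel, model)
        _write(track.table, cfg.out_dir, "ancestry_dosage.tsv", manifest)
        try:
            dev = anc_mod.deviation_scan(track)
            _write(dev.table, cfg.out_dir, "ancestry_deviation.tsv", manifest)
            _write(dev.stats, cfg.out_dir, "ancestry_stats.tsv", manifest)
            grubbs_rows = []
            for src in track.sources:
                gr = anc_mod.grubbs_one_outlier(track.dosage(src))
                grubbs_rows.append({"source": src, "G": gr.G, "U": gr.U,
                                    "p": gr.p, "n": gr.n})
            _write(pd.DataFrame(grubbs_rows), cfg.out_dir,
                   "ancestry_grubbs.tsv", manifest)
        except ValueError:
            pass  # track too short for a meaningful SD

    path = os.path.join(cfg.out_dir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
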