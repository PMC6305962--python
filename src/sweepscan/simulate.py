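"""Synthetic admixed-cohort generator with full ground truth.

Emulates the study design the scans are built for: a multi-chromosome
SNP-array panel, 2-3 divergent source populations (taurine-like,
African-taurine-like, indicine-like) drawn from the Balding-Nichols model
around a shared ancestral frequency, an admixed cohort whose per-individual
global ancestry Q is Dirichlet-distributed, Markov local-ancestry tracts for
g generations since admixture, phased haplotypes, and optionally injected
sweeps (a fixed donor haplotype copied into a carrier fraction of
haplotypes, with or without a source-ancestry bias).

Defaults mirror the emulated study: three sources, pairwise divergence
F = 0.2, g = 10 generations, ~25 kb marker spacing, Dirichlet alpha chosen so
the dominant (taurine-like) ancestry averages ~70% with wide individual
spread.  SNP frequencies are independent across loci within sources, so the
only extended haplotype structure is what admixture tracts and injected
sweeps create — exactly the signal classes the scans target.

All outputs are bit-reproducible from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .haplotype import HaplotypeSet
from .io_qc import GenotypeDataset


@dataclass
class SweepSpec:
    """An injected sweep: a shared donor haplotype around a core SNP.

    ``taper='eroded'`` (default) draws each carrier's shared tract
    independently per side as Uniform(0, length_bp/2), emulating
    recombination erosion of a swept haplotype: the fraction of carrier
    pairs still sharing decays quadratically away from the core, so the
    homozygosity signal peaks at the core as in a real sweep.
    ``taper='hard'`` copies the full window [core-L/2, core+L/2] into every
    carrier (a rectangular block, appropriate for ancestry-excess sweeps
    where whole local-ancestry tracts rise in frequency).
    """

    chrom: str
    core_pos: int
    carrier_fraction: float = 0.6
    length_bp: int = 1_000_000
    source_bias: str | None = None
    taper: str = "eroded"

    def __post_init__(self) -> None:
        if not 0 < self.carrier_fraction <= 1:
            raise ValueError("carrier_fraction must be in (0,1]")
        if self.taper not in ("eroded", "hard"):
            raise ValueError(f"unknown taper {self.taper!r}")


@dataclass
class SimConfig:
    """Study-condition parameters of the generator."""

    n_snps: int = 5000
    n_chromosomes: int = 2
    chrom_length_bp: int | None = None      # default: ~25 kb mean spacing
    n_sources: int = 3
    fst: float = 0.2                        # Balding-Nichols divergence
    source_panel_size: int = 50             # diploids per source panel
    n_admixed: int = 200
    dirichlet_alpha: tuple = (7.0, 1.9, 1.1)  # ~70/19/11% mean ancestry
    generations: float = 10.0
    cm_per_mb: float = 1.0
    missing_rate: float = 0.0
    sweeps: list[SweepSpec] = field(default_factory=list)
    seed: int = 0
    source_names: tuple = ("taurine", "african_taurine", "indicine")

    def __post_init__(self) -> None:
        if not 0 < self.fst < 1:
            raise ValueError("fst must be in (0,1)")
        if len(self.dirichlet_alpha) != self.n_sources:
            raise ValueError("dirichlet_alpha length must equal n_sources")
        if self.chrom_length_bp is None:
            per_chrom = self.n_snps // self.n_chromosomes
            self.chrom_length_bp = int(per_chrom * 25_000)

    @property
    def sources(self) -> list[str]:
        return list(self.source_names[: self.n_sources])


@dataclass
class TruthTables:
    """Ground truth emitted alongside the synthetic cohort.

    ``q`` holds the sampled (stationary) Dirichlet proportions that drive the
    ancestry chains; ``realized_q`` holds the fraction of each source actually
    present along each individual's genome, which differs from ``q`` by
    tract-sampling noise and is the quantity a genome-based ancestry
    estimator targets.
    """

    q: pd.DataFrame                    # admixed samples x K stationary proportions
    realized_q: pd.DataFrame           # admixed samples x K genome-realized fractions
    local_ancestry: np.ndarray         # (2*n_admixed, m) source index per haplotype
    source_freqs: pd.DataFrame         # SNPs x K alt-allele frequencies
    ancestral_freq: np.ndarray
    sweep_cores: list[tuple[str, int]] = field(default_factory=list)


def _marker_map(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    per_chrom = cfg.n_snps // cfg.n_chromosomes
    counts = [per_chrom] * cfg.n_chromosomes
    counts[-1] += cfg.n_snps - sum(counts)
    rows = []
    for c, n_c in enumerate(counts, start=1):
        # array-like placement: regular grid with uniform jitter, mirroring a
        # designed genotyping panel's even coverage (no pathological holes)
        spacing = cfg.chrom_length_bp / n_c
        grid = (np.arange(n_c) + 0.5) * spacing
        jitter = rng.uniform(-0.45, 0.45, n_c) * spacing
        pos = np.unique(np.clip((grid + jitter).astype(np.int64), 1,
                                cfg.chrom_length_bp))
        while len(pos) < n_c:
            extra = rng.integers(1, cfg.chrom_length_bp + 1, size=n_c - len(pos))
            pos = np.unique(np.concatenate([pos, extra]))
        pos = np.sort(pos[:n_c])
        for p in pos:
            rows.append((f"snp_{c}_{p}", str(c), int(p), "A", "G"))
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "ref", "alt"])


def simulate_sources(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, GenotypeDataset]:
    """Balding-Nichols source frequencies and reference panel genotypes.

    Ancestral frequency ~ U(0.05, 0.95) per SNP; source k frequency
    ~ Beta(p(1-F)/F, (1-p)(1-F)/F); panel genotypes ~ Binomial(2, f_k).
    Returns (marker map, source frequency table, panel GenotypeDataset with
    phased haplotypes).
    """
    rng = np.random.default_rng(cfg.seed)
    markers = _marker_map(cfg, rng)
    m = len(markers)
    p_anc = rng.uniform(0.05, 0.95, size=m)
    ratio = (1.0 - cfg.fst) / cfg.fst
    F = np.empty((m, cfg.n_sources))
    for k in range(cfg.n_sources):
        F[:, k] = rng.beta(p_anc * ratio, (1.0 - p_anc) * ratio)
    F = np.clip(F, 1e-6, 1.0 - 1e-6)
    freq_table = pd.DataFrame(F, columns=cfg.sources)
    freq_table.insert(0, "snp_id", markers["snp_id"])
    freq_table["ancestral_freq"] = p_anc

    hap_rows, sample_rows = [], []
    for k, src in enumerate(cfg.sources):
        haps = (rng.random((2 * cfg.source_panel_size, m)) < F[:, k]).astype(np.int8)
        hap_rows.append(haps)
        sample_rows += [(f"{src}_{i}", src) for i in range(cfg.source_panel_size)]
    haplotypes = np.vstack(hap_rows)
    calls = haplotypes[0::2] + haplotypes[1::2]
    panels = GenotypeDataset(
        markers=markers,
        samples=pd.DataFrame(sample_rows, columns=["sample_id", "population"]),
        calls=calls, haplotypes=haplotypes)
    return markers, freq_table, panels


def simulate_admixed(cfg: SimConfig, markers: pd.DataFrame,
                     freq_table: pd.DataFrame
                     ) -> tuple[GenotypeDataset, HaplotypeSet, TruthTables]:
    """Admixed cohort with Markov local-ancestry tracts.

    Per haplotype, ancestry along each chromosome is a Markov chain with
    stationary distribution equal to the individual's Q and switch
    probability 1 - exp(-g*r) between adjacent SNPs (r in Morgans from the
    constant-rate map); the allele is drawn from the active source's
    frequency.  Phase is retained; truth (Q, tract labels) is recorded.
    """
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 1)))
    m = len(markers)
    K = cfg.n_sources
    F = freq_table[cfg.sources].to_numpy(dtype=float)
    n = cfg.n_admixed
    Q = rng.dirichlet(cfg.dirichlet_alpha, size=n)
    n_hap = 2 * n
    anc = np.empty((n_hap, m), dtype=np.int8)
    Q_hap = np.repeat(Q, 2, axis=0)

    for chrom, grp in markers.groupby("chrom", sort=False):
        cols = grp.index.to_numpy()
        pos = grp["pos"].to_numpy(dtype=float)
        r = np.diff(pos) * cfg.cm_per_mb / 1e8
        switch = 1.0 - np.exp(-cfg.generations * r)
        # initial state from stationary Q
        u = rng.random(n_hap)
        cum = np.cumsum(Q_hap, axis=1)
        state = (u[:, None] > cum).sum(axis=1).astype(np.int8)
        anc[:, cols[0]] = state
        for t in range(1, len(cols)):
            do_switch = rng.random(n_hap) < switch[t - 1]
            if do_switch.any():
                u = rng.random(do_switch.sum())
                new = (u[:, None] > cum[do_switch]).sum(axis=1).astype(np.int8)
                state = state.copy()
                state[do_switch] = new
            anc[:, cols[t]] = state

    hap = (rng.random((n_hap, m)) < F[np.arange(m)[None, :], anc]).astype(np.int8)
    calls = hap[0::2] + hap[1::2]
    if cfg.missing_rate > 0:
        mask = rng.random(calls.shape) < cfg.missing_rate
        calls = np.where(mask, -1, calls).astype(np.int8)
        haplotypes = None
    else:
        haplotypes = hap
    samples = pd.DataFrame({
        "sample_id": [f"adm_{i}" for i in range(n)],
        "population": "admixed"})
    dataset = GenotypeDataset(markers=markers, samples=samples, calls=calls,
                              haplotypes=haplotypes)
    hset = HaplotypeSet(markers=markers.copy(), haplotypes=hap,
                        sample_ids=samples["sample_id"].tolist())
    realized = np.stack([(anc[0::2] == k).mean(axis=1) + (anc[1::2] == k).mean(axis=1)
                         for k in range(K)], axis=1) / 2.0
    truth = TruthTables(
        q=pd.DataFrame(Q, index=samples["sample_id"], columns=cfg.sources),
        realized_q=pd.DataFrame(realized, index=samples["sample_id"],
                                columns=cfg.sources),
        local_ancestry=anc,
        source_freqs=freq_table[["snp_id", *cfg.sources]].copy(),
        ancestral_freq=freq_table["ancestral_freq"].to_numpy())
    return dataset, hset, truth


def inject_sweep(h: HaplotypeSet, truth: TruthTables, spec: SweepSpec,
                 cfg: SimConfig, rng: np.random.Generator | None = None
                 ) -> tuple[HaplotypeSet, TruthTables]:
    """Copy one donor haplotype into a carrier fraction over a window.

    Within the window [core - L/2, core + L/2] (truncated at chromosome ends
    with a warning), a random ``carrier_fraction`` of haplotypes share a
    single fixed donor haplotype over per-carrier tract reaches (see
    :class:`SweepSpec`); the derived (alt) allele at the core is set on
    carriers.  This creates the extended-haplotype-homozygosity signal class.

    With ``source_bias`` the injected signal is local-ancestry excess
    instead: each carrier's tract is drawn independently from that source's
    allele frequencies (diverse haplotypes of one ancestry, as selection on
    standing ancestral variation produces) and the carriers' local-ancestry
    truth in the tract is relabelled to that source.
    """
    import warnings

    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 2)))
    markers = h.markers
    on_chrom = markers["chrom"] == spec.chrom
    if not on_chrom.any():
        raise ValueError(f"chromosome {spec.chrom!r} not in marker map")
    pos = markers["pos"].to_numpy()
    core_candidates = np.flatnonzero(on_chrom.to_numpy())
    core = core_candidates[np.argmin(np.abs(pos[core_candidates] - spec.core_pos))]
    lo_bp = spec.core_pos - spec.length_bp // 2
    hi_bp = spec.core_pos + spec.length_bp // 2
    chrom_pos = pos[core_candidates]
    if lo_bp < chrom_pos.min() or hi_bp > chrom_pos.max():
        warnings.warn("sweep window truncated at chromosome end")
    window = core_candidates[(chrom_pos >= lo_bp) & (chrom_pos <= hi_bp)]

    hap = h.haplotypes.copy()
    anc = truth.local_ancestry.copy()
    n_hap = hap.shape[0]
    n_carriers = max(2, int(round(spec.carrier_fraction * n_hap)))
    carriers = rng.choice(n_hap, size=n_carriers, replace=False)

    if spec.source_bias is not None:
        k = cfg.sources.index(spec.source_bias)
        f_src = truth.source_freqs[spec.source_bias].to_numpy()[window]
        donor = None
    else:
        k = None
        donor = hap[rng.integers(n_hap), window].copy()
        donor[np.searchsorted(window, core)] = 1   # derived allele at the core

    half = spec.length_bp / 2.0
    if spec.taper == "hard":
        reach = np.full((n_carriers, 2), half)
    else:
        reach = rng.uniform(0.0, half, size=(n_carriers, 2))
    win_pos = pos[window].astype(float)
    anchor = float(spec.core_pos)
    core_in_window = np.searchsorted(window, core)
    for t, c in enumerate(carriers):
        share = ((win_pos >= anchor - reach[t, 0])
                 & (win_pos <= anchor + reach[t, 1]))
        cols = window[share]
        if donor is not None:
            hap[c, cols] = donor[share]
        else:
            tract = (rng.random(share.sum()) < f_src[share]).astype(np.int8)
            hap[c, cols] = tract
            hap[c, window[core_in_window]] = 1  # derived allele at the core
            anc[c, cols] = k

    new_h = HaplotypeSet(markers=markers.copy(), haplotypes=hap,
                         sample_ids=list(h.sample_ids))
    new_truth = replace(truth, local_ancestry=anc,
                        sweep_cores=truth.sweep_cores + [(spec.chrom, int(pos[core]))])
    return new_h, new_truth


def simulate_cohort(cfg: SimConfig):
    """One-call convenience: sources + admixed cohort (+ sweeps).

    Returns (admixed GenotypeDataset, HaplotypeSet, TruthTables, source-panel
    GenotypeDataset, source frequency table).
    """
    markers, freq_table, panels = simulate_sources(cfg)
    dataset, hset, truth = simulate_admixed(cfg, markers, freq_table)
    if cfg.sweeps:
        rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 2)))
        for spec in cfg.sweeps:
            hset, truth = inject_sweep(hset, truth, spec, cfg, rng=rng)
        calls = hset.haplotypes[0::2] + hset.haplotypes[1::2]
        dataset = GenotypeDataset(markers=dataset.markers, samples=dataset.samples,
                                  calls=calls, haplotypes=hset.haplotypes)
    return dataset, hset, truth, panels, freq_table
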