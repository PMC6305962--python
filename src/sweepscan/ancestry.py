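"""Local-ancestry dosage from unphased genotypes via a haplotype-pair HMM.

The hidden state at each SNP is the ordered pair of source-population
ancestries of an individual's two haplotypes (K^2 states; emissions and
dosages depend only on the unordered pair).  Each haplotype switches ancestry
between adjacent SNPs with probability 1 - exp(-g*r) toward the individual's
stationary global proportions pi, where g is generations since admixture and
r the inter-SNP distance in Morgans (constant-rate map by default, 1 cM/Mb).
Emissions are binomial mixtures of the state pair's reference allele
frequencies.  Scaled forward-backward posteriors give each individual's
expected ancestry allele dosage (0-2) per source per SNP; the cohort track is
the mean over individuals.

Deviation scanning flags loci whose cohort dosage exceeds the genome-wide
mean by 2 (and 3) SDs — the ancestry-excess analogue of a selection peak —
and a one-outlier Grubbs test quantifies the most extreme locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_qc import MISSING, GenotypeDataset

CM_PER_MB_DEFAULT = 1.0


@dataclass
class AncestryModel:
    """Fixed quantities of the ancestry HMM.

    source_freqs: SNPs x K alt-allele frequencies (columns = source labels),
    aligned to the dataset's marker order; smoothed away from {0,1}.
    generations: admixture age g (default 10).
    global_q: optional per-sample stationary proportions (samples x K,
    indexed by sample_id); uniform when absent.
    cm_per_mb: constant-rate recombination map (ignored where an explicit
    per-SNP genetic map column ``cm`` exists in the markers).
    """

    source_freqs: pd.DataFrame
    generations: float = 10.0
    global_q: pd.DataFrame | None = None
    cm_per_mb: float = CM_PER_MB_DEFAULT
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if len(self.source_freqs.columns) < 2:
            raise ValueError("need >= 2 source populations")

    @property
    def sources(self) -> list[str]:
        return list(self.source_freqs.columns)

    @property
    def K(self) -> int:
        return len(self.source_freqs.columns)


@dataclass
class AncestryDosageTrack:
    """Cohort-mean posterior ancestry allele dosage per SNP per source."""

    table: pd.DataFrame                    # chrom, pos, snp_id, dosage_<src>...
    sources: list[str]
    per_individual: np.ndarray | None = None   # (n, m, K) posterior dosages
    sample_ids: list[str] = field(default_factory=list)

    def dosage(self, source: str) -> np.ndarray:
        return self.table[f"dosage_{source}"].to_numpy()


def _smooth_freqs(F: np.ndarray, n_samples: int, pseudocount: float) -> np.ndarray:
    eps = pseudocount / (2.0 * n_samples + 1.0)
    return np.clip(F, eps, 1.0 - eps)


def ancestry_dosage(d: GenotypeDataset, model: AncestryModel,
                    keep_individual: bool = False) -> AncestryDosageTrack:
    """Posterior expected ancestry dosage per locus, averaged over the cohort.

    Runs scaled forward-backward independently per chromosome for all
    individuals simultaneously.  Individuals with no non-missing genotype are
    excluded.  Per SNP, dosages across sources sum to 2.
    """
    K = model.K
    F = model.source_freqs.to_numpy(dtype=float)
    if F.shape[0] != d.n_snps:
        raise ValueError("source_freqs rows must align with dataset markers")
    F = _smooth_freqs(F, d.n_samples, model.pseudocount)

    keep = (d.calls != MISSING).any(axis=1)
    if not keep.all():
        d = d.take_samples(np.flatnonzero(keep))
    n = d.n_samples
    ids = d.samples["sample_id"].tolist()

    if model.global_q is not None:
        pi = model.global_q.reindex(ids)[model.sources].to_numpy(dtype=float)
        pi = np.clip(pi, 1e-6, None)
        pi /= pi.sum(axis=1, keepdims=True)
    else:
        pi = np.full((n, K), 1.0 / K)

    g = model.generations
    dosage_ind = np.zeros((n, d.n_snps, K))
    for chrom, grp in d.markers.groupby("chrom", sort=False):
        cols = grp.index.to_numpy()
        pos = grp["pos"].to_numpy(dtype=float)
        if "cm" in grp.columns and grp["cm"].notna().all():
            r = np.diff(grp["cm"].to_numpy(dtype=float)) / 100.0
        else:
            r = np.diff(pos) * model.cm_per_mb / 1e8  # bp -> Morgans
        r = np.maximum(r, 0.0)
        stay = np.exp(-g * r)                         # per-haplotype no-switch prob
        post = _forward_backward_pairs(
            d.calls[:, cols], F[cols], pi, stay)      # (n, m_c, K, K)
        # dosage_k = expected count of source k in the ordered pair
        dos = post.sum(axis=3) + post.sum(axis=2)     # (n, m_c, K)
        dosage_ind[:, cols, :] = dos

    cohort = dosage_ind.mean(axis=0)                  # (m, K)
    table = pd.DataFrame({
        "snp_id": d.markers["snp_id"],
        "chrom": d.markers["chrom"],
        "pos": d.markers["pos"],
    })
    for k, src in enumerate(model.sources):
        table[f"dosage_{src}"] = cohort[:, k]
    return AncestryDosageTrack(
        table=table, sources=model.sources,
        per_individual=dosage_ind if keep_individual else None,
        sample_ids=ids)


def _forward_backward_pairs(calls: np.ndarray, F: np.ndarray, pi: np.ndarray,
                            stay: np.ndarray) -> np.ndarray:
    """Scaled forward-backward over ordered ancestry pairs.

    calls: (n, m) with MISSING allowed; F: (m, K); pi: (n, K);
    stay: (m-1,) per-interval no-switch probability.  Returns posteriors
    (n, m, K, K) summing to 1 over the last two axes at every SNP.
    """
    n, m = calls.shape
    K = F.shape[1]
    # emission probs per (snp, a, b, genotype-class)
    # P(g | a, b): 0 -> (1-fa)(1-fb); 1 -> fa(1-fb)+(1-fa)fb; 2 -> fa*fb
    fa = F[:, :, None]      # (m, K, 1)
    fb = F[:, None, :]      # (m, 1, K)
    e0 = (1 - fa) * (1 - fb)
    e1 = fa * (1 - fb) + (1 - fa) * fb
    e2 = fa * fb
    emis = np.stack([e0, e1, e2, np.ones_like(e0)], axis=-1)  # (m, K, K, 4)
    gidx = np.where(calls == MISSING, 3, calls)                # (n, m)

    def trans_apply(mat: np.ndarray, s: float) -> np.ndarray:
        """Apply the pair transition to (n, K, K) mass: each haplotype stays
        with prob s, else redraws from pi (same kernel forwards/backwards
        applied to the appropriate mass)."""
        # one-haplotype kernel: T = s*I + (1-s)*1 pi^T  (rows: from, cols: to)
        # forward: out[c,d] = sum_ab mat[a,b] T[a,c] T[b,d]
        # row-sums over 'from' with redraw weight:
        tot = mat.sum(axis=(1, 2))[:, None]                    # (n,1)
        rowa = mat.sum(axis=2)                                 # (n,K) mass per a
        rowb = mat.sum(axis=1)                                 # (n,K) mass per b
        out = (s * s) * mat
        out += s * (1 - s) * rowa[:, :, None] * pi[:, None, :]
        out += (1 - s) * s * pi[:, :, None] * rowb[:, None, :]
        out += (1 - s) * (1 - s) * tot[:, :, None] * pi[:, :, None] * pi[:, None, :]
        return out

    prior = pi[:, :, None] * pi[:, None, :]                    # (n, K, K)
    alpha = np.empty((n, m, K, K))
    scale = np.empty((n, m))
    a = prior * emis[0][:, :, gidx[:, 0]].transpose(2, 0, 1)
    s0 = np.maximum(a.sum(axis=(1, 2)), 1e-300)
    alpha[:, 0] = a / s0[:, None, None]
    scale[:, 0] = s0
    for j in range(1, m):
        pred = trans_apply(alpha[:, j - 1], stay[j - 1])
        e = emis[j][:, :, gidx[:, j]].transpose(2, 0, 1)       # (n, K, K)
        a = pred * e
        sj = a.sum(axis=(1, 2))
        sj = np.maximum(sj, 1e-300)
        alpha[:, j] = a / sj[:, None, None]
        scale[:, j] = sj

    beta = np.empty((n, m, K, K))
    beta[:, m - 1] = 1.0
    for j in range(m - 2, -1, -1):
        e = emis[j + 1][:, :, gidx[:, j + 1]].transpose(2, 0, 1)
        # backward: b[a,b] = sum_cd T[a,c] T[b,d] e[c,d] beta[c,d]
        mass = e * beta[:, j + 1]
        s = stay[j]
        tot = (mass * pi[:, :, None] * pi[:, None, :]).sum(axis=(1, 2))[:, None]
        colc = (mass * pi[:, None, :]).sum(axis=2)             # (n,K): per c=a fixed
        cold = (mass * pi[:, :, None]).sum(axis=1)             # (n,K)
        b = (s * s) * mass
        b += s * (1 - s) * colc[:, :, None] * np.ones((1, 1, K))
        b += (1 - s) * s * np.ones((1, K, 1)) * cold[:, None, :]
        b += (1 - s) * (1 - s) * tot[:, :, None] * np.ones((1, K, K))
        b /= np.maximum(scale[:, j + 1], 1e-300)[:, None, None]
        beta[:, j] = b

    post = alpha * beta
    post /= post.sum(axis=(2, 3), keepdims=True)
    return post


@dataclass
class DeviationScan:
    """Loci whose cohort dosage exceeds mean + s*SD, per source."""

    table: pd.DataFrame            # chrom, pos, snp_id, source, dosage, flag_2sd, flag_3sd
    stats: pd.DataFrame            # source, mean, sd, max_dosage, max_snp_id, max_pos


def deviation_scan(track: AncestryDosageTrack,
                   sd_thresholds: tuple[float, ...] = (2.0, 3.0),
                   min_snps: int = 100) -> DeviationScan:
    """Flag loci with excess ancestry dosage relative to the genome-wide
    mean.  Requires >= ``min_snps`` scanned loci for the SD to be meaningful;
    a zero-SD (constant) track yields no flags with a warning."""
    import warnings

    t = track.table
    if len(t) < min_snps:
        raise ValueError(f"deviation scan needs >= {min_snps} SNPs, got {len(t)}")
    rows, srows = [], []
    for src in track.sources:
        dos = track.dosage(src)
        mu, sd = dos.mean(), dos.std(ddof=0)
        if sd == 0:
            warnings.warn(f"constant dosage track for source {src!r}; no flags")
        imax = int(np.argmax(dos))
        srows.append({"source": src, "mean": mu, "sd": sd,
                      "max_dosage": dos[imax],
                      "max_snp_id": t["snp_id"].iloc[imax],
                      "max_chrom": t["chrom"].iloc[imax],
                      "max_pos": int(t["pos"].iloc[imax])})
        flags = {s: (sd > 0) & (dos > mu + s * sd) for s in sd_thresholds}
        for i in range(len(t)):
            if any(f[i] for f in flags.values()):
                row = {"snp_id": t["snp_id"].iloc[i], "chrom": t["chrom"].iloc[i],
                       "pos": int(t["pos"].iloc[i]), "source": src,
                       "dosage": dos[i]}
                for s in sd_thresholds:
                    row[f"flag_{s:g}sd"] = bool(flags[s][i])
                rows.append(row)
    flag_cols = [f"flag_{s:g}sd" for s in sd_thresholds]
    table = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "source",
                                        "dosage", *flag_cols])
    return DeviationScan(table=table, stats=pd.DataFrame(srows))


@dataclass
class GrubbsResult:
    G: float
    U: float
    p: float
    n: int


def grubbs_one_outlier(x) -> GrubbsResult:
    """One-sided Grubbs test for a single maximum outlier.

    G = (max - mean)/s with the sample SD; U = SS(excluding max about its own
    mean)/SS(all) = 1 - n G^2/(n-1)^2; p = min(1, n * P(T_{n-2} > t)) with
    t^2 = n (n-2) G^2 / ((n-1)^2 - n G^2).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("Grubbs test needs n >= 3")
    s = x.std(ddof=1)
    if s == 0:
        raise ValueError("zero variance; Grubbs statistic undefined")
    G = (x.max() - x.mean()) / s
    U = 1.0 - n * G * G / (n - 1.0) ** 2
    denom = (n - 1.0) ** 2 - n * G * G
    if denom <= 0:
        p = 0.0
    else:
        t = np.sqrt(n * (n - 2.0) * G * G / denom)
        p = min(1.0, n * stats.t.sf(t, n - 2))
    return GrubbsResult(G=float(G), U=float(U), p=float(p), n=n)
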