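"""Extended-haplotype-homozygosity selection scans: EHH, iHH, iHS, XP-EHH.

EHH at distance x from a core SNP is the probability that two random
haplotypes carrying the core allele are identical over the interval core->x.
iHH integrates the EHH decay curve over physical position (trapezoid rule,
truncated by linear interpolation where EHH crosses the cutoff).  iHS is
ln(iHH_ancestral / iHH_derived) standardized within derived-allele-frequency
bins, so that extreme values mark unusually slow haplotype decay for a
frequency class; strongly negative scores mark sweeps on the derived allele.
XP-EHH contrasts the integrated homozygosity of all haplotypes between an
object and a reference population at each focal SNP, truncated where the
pooled EHH decays below the cutoff, and is standardized genome-wide to zero
mean and unit variance.

The inner decay walks are numba kernels; a pure-Python pair-counting EHH is
exposed for small-scale work and serves as the reference definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats

from .io_qc import MISSING, GenotypeDataset

EHH_CUTOFF = 0.05
MAX_GAP_BP = 200_000
MIN_CARRIERS = 2

# boundary flags from the decay kernels
FLAG_OK = 0
FLAG_CHROM_END = 1
FLAG_MAX_GAP = 2


@dataclass
class HaplotypeSet:
    """Phased binary haplotypes (2 per individual) plus ancestral assignment.

    ``ancestral_is_alt[j]`` is True when the ancestral allele at SNP j is the
    alt allele; ``usable[j]`` is False for monomorphic SNPs where the
    ancestral call is vacuous.
    """

    markers: pd.DataFrame
    haplotypes: np.ndarray          # (n_hap, m) int8 in {0,1}
    sample_ids: list[str]
    ancestral_is_alt: np.ndarray | None = None
    usable: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.haplotypes = np.ascontiguousarray(self.haplotypes, dtype=np.int8)
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("haplotypes must be binary with no missing entries")
        if self.haplotypes.shape[1] != len(self.markers):
            raise ValueError("haplotype columns must align with marker map")
        self.markers = self.markers.reset_index(drop=True)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[1]

    @classmethod
    def from_dataset(cls, d: GenotypeDataset,
                     ancestral_is_alt: np.ndarray | None = None,
                     usable: np.ndarray | None = None) -> "HaplotypeSet":
        if d.haplotypes is None:
            raise ValueError("dataset carries no phased haplotypes")
        return cls(markers=d.markers.copy(), haplotypes=d.haplotypes,
                   sample_ids=d.samples["sample_id"].tolist(),
                   ancestral_is_alt=ancestral_is_alt, usable=usable)

    def derived_frequency(self) -> np.ndarray:
        """Frequency of the derived (non-ancestral) allele per SNP."""
        if self.ancestral_is_alt is None:
            raise ValueError("ancestral assignment not set")
        alt_freq = self.haplotypes.mean(axis=0)
        return np.where(self.ancestral_is_alt, 1.0 - alt_freq, alt_freq)


def infer_ancestral_alleles(d: GenotypeDataset) -> tuple[np.ndarray, np.ndarray]:
    """Ancestral allele per SNP = the majority allele over the whole dataset.

    Ties resolve to the reference allele.  Returns (ancestral_is_alt, usable);
    monomorphic SNPs get their observed allele and ``usable=False``.
    """
    obs = d.calls != MISSING
    n_alleles = 2 * obs.sum(axis=0)
    alt_count = np.where(obs, d.calls, 0).sum(axis=0)
    ref_count = n_alleles - alt_count
    ancestral_is_alt = alt_count > ref_count  # tie -> ref
    usable = (alt_count > 0) & (ref_count > 0)
    return ancestral_is_alt, usable


# ---------------------------------------------------------------------------
# Reference (pure-Python) EHH
# ---------------------------------------------------------------------------

def ehh(h: HaplotypeSet, core_snp: int, core_allele: int, to_snp: int) -> float:
    """EHH from ``core_snp`` to ``to_snp`` (inclusive) among carriers of
    ``core_allele``: sum_h C(n_h,2) / C(n_c,2) over distinct extended
    haplotypes.  Equals 1 at the core itself.
    """
    carriers = np.flatnonzero(h.haplotypes[:, core_snp] == core_allele)
    n_c = len(carriers)
    if n_c < MIN_CARRIERS:
        raise ValueError(f"core allele carried by {n_c} < {MIN_CARRIERS} haplotypes")
    lo, hi = sorted((core_snp, to_snp))
    segment = h.haplotypes[carriers, lo:hi + 1]
    _, counts = np.unique(segment, axis=0, return_counts=True)
    pairs = (counts * (counts - 1)).sum() / 2.0
    return float(pairs / (n_c * (n_c - 1) / 2.0))


# ---------------------------------------------------------------------------
# numba decay kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _ehh_step(keys: np.ndarray, labels: np.ndarray, order: np.ndarray) -> float:
    """Compress keys into labels (0..k-1) and return the pair-sharing EHH."""
    n = keys.shape[0]
    for i in range(n):
        order[i] = i
    # insertion-free: argsort
    idx = np.argsort(keys, kind="mergesort")
    rank = 0
    prev = keys[idx[0]]
    labels[idx[0]] = 0
    run = 1
    pairs = 0.0
    for t in range(1, n):
        k = keys[idx[t]]
        if k != prev:
            pairs += run * (run - 1) / 2.0
            rank += 1
            run = 1
            prev = k
        else:
            run += 1
        labels[idx[t]] = rank
    pairs += run * (run - 1) / 2.0
    return pairs / (n * (n - 1) / 2.0)


@njit(cache=True)
def _ihh_one_side(hap: np.ndarray, pos: np.ndarray, core: int,
                  carriers: np.ndarray, direction: int,
                  cutoff: float, max_gap: int) -> tuple[float, int]:
    """Integrate EHH from the core outward in one direction.

    Trapezoid over physical position; when EHH first drops below ``cutoff``
    the integral ends at the linearly interpolated crossing.  Returns
    (integral in bp*EHH, flag): flag 1 = chromosome end reached with EHH
    still above cutoff, flag 2 = inter-SNP gap above ``max_gap``.
    """
    n = carriers.shape[0]
    m = hap.shape[1]
    labels = np.zeros(n, dtype=np.int64)
    keys = np.zeros(n, dtype=np.int64)
    order = np.zeros(n, dtype=np.int64)
    prev_ehh = 1.0
    prev_pos = pos[core]
    integral = 0.0
    j = core
    while True:
        j_next = j + direction
        if j_next < 0 or j_next >= m:
            return integral, FLAG_CHROM_END
        gap = pos[j_next] - pos[j] if direction > 0 else pos[j] - pos[j_next]
        if gap > max_gap:
            return integral, FLAG_MAX_GAP
        for t in range(n):
            keys[t] = labels[t] * 2 + hap[carriers[t], j_next]
        cur_ehh = _ehh_step(keys, labels, order)
        cur_pos = pos[j_next]
        span = cur_pos - prev_pos if direction > 0 else prev_pos - cur_pos
        if cur_ehh < cutoff:
            if prev_ehh > cutoff:
                frac = (prev_ehh - cutoff) / (prev_ehh - cur_ehh)
                integral += 0.5 * (prev_ehh + cutoff) * frac * span
            return integral, FLAG_OK
        integral += 0.5 * (prev_ehh + cur_ehh) * span
        prev_ehh = cur_ehh
        prev_pos = cur_pos
        j = j_next


@njit(cache=True)
def _xpehh_site(hap: np.ndarray, pos: np.ndarray, core: int, n_obj: int,
                direction: int, cutoff: float, max_gap: int
                ) -> tuple[float, float, int]:
    """One-sided XP-EHH integrals at a focal SNP.

    ``hap`` stacks object haplotypes (rows 0..n_obj-1) above reference
    haplotypes.  All haplotypes in each population are carriers (EHH is
    unconditional on the core allele).  The walk stops where the EHH of the
    pooled haplotypes crosses ``cutoff``; both populations' integrals end at
    the interpolated pooled crossing.  Returns (ihh_obj, ihh_ref, flag).
    """
    n_all = hap.shape[0]
    n_ref = n_all - n_obj
    m = hap.shape[1]
    lab_o = np.zeros(n_obj, dtype=np.int64)
    lab_r = np.zeros(n_ref, dtype=np.int64)
    lab_p = np.zeros(n_all, dtype=np.int64)
    key_o = np.zeros(n_obj, dtype=np.int64)
    key_r = np.zeros(n_ref, dtype=np.int64)
    key_p = np.zeros(n_all, dtype=np.int64)
    ord_o = np.zeros(n_obj, dtype=np.int64)
    ord_r = np.zeros(n_ref, dtype=np.int64)
    ord_p = np.zeros(n_all, dtype=np.int64)
    prev_o = 1.0
    prev_r = 1.0
    prev_p = 1.0
    prev_pos = pos[core]
    int_o = 0.0
    int_r = 0.0
    j = core
    while True:
        j_next = j + direction
        if j_next < 0 or j_next >= m:
            return int_o, int_r, FLAG_CHROM_END
        gap = pos[j_next] - pos[j] if direction > 0 else pos[j] - pos[j_next]
        if gap > max_gap:
            return int_o, int_r, FLAG_MAX_GAP
        for t in range(n_obj):
            key_o[t] = lab_o[t] * 2 + hap[t, j_next]
        for t in range(n_ref):
            key_r[t] = lab_r[t] * 2 + hap[n_obj + t, j_next]
        for t in range(n_all):
            key_p[t] = lab_p[t] * 2 + hap[t, j_next]
        cur_o = _ehh_step(key_o, lab_o, ord_o)
        cur_r = _ehh_step(key_r, lab_r, ord_r)
        cur_p = _ehh_step(key_p, lab_p, ord_p)
        cur_pos = pos[j_next]
        span = cur_pos - prev_pos if direction > 0 else prev_pos - cur_pos
        if cur_p < cutoff:
            if prev_p > cutoff:
                frac = (prev_p - cutoff) / (prev_p - cur_p)
                eo = prev_o + frac * (cur_o - prev_o)
                er = prev_r + frac * (cur_r - prev_r)
                int_o += 0.5 * (prev_o + eo) * frac * span
                int_r += 0.5 * (prev_r + er) * frac * span
            return int_o, int_r, FLAG_OK
        int_o += 0.5 * (prev_o + cur_o) * span
        int_r += 0.5 * (prev_r + cur_r) * span
        prev_o, prev_r, prev_p = cur_o, cur_r, cur_p
        prev_pos = cur_pos
        j = j_next


def ihh(h: HaplotypeSet, core_snp: int, core_allele: int,
        ehh_cutoff: float = EHH_CUTOFF, max_gap_bp: int = MAX_GAP_BP
        ) -> tuple[float, int, int]:
    """Integrated EHH for one core allele: (left + right integral,
    left flag, right flag).  Callers normally exclude SNPs whose flags are
    not FLAG_OK (boundary or oversized gap)."""
    carriers = np.flatnonzero(h.haplotypes[:, core_snp] == core_allele).astype(np.int64)
    if len(carriers) < MIN_CARRIERS:
        raise ValueError("core allele has fewer than MIN_CARRIERS carriers")
    pos = h.markers["pos"].to_numpy(dtype=np.int64)
    left, fl = _ihh_one_side(h.haplotypes, pos, core_snp, carriers, -1,
                             ehh_cutoff, max_gap_bp)
    right, fr = _ihh_one_side(h.haplotypes, pos, core_snp, carriers, +1,
                              ehh_cutoff, max_gap_bp)
    return left + right, fl, fr


# ---------------------------------------------------------------------------
# Scans
# ---------------------------------------------------------------------------

@dataclass
class IhsResult:
    """Per-SNP iHS track; ``table`` has one row per scored SNP."""

    table: pd.DataFrame
    n_excluded: int = 0
    bin_edges: np.ndarray = field(default_factory=lambda: np.array([]))


@dataclass
class XpehhResult:
    table: pd.DataFrame
    n_excluded: int = 0


def ihs_transform(ihs_std: np.ndarray) -> np.ndarray:
    """-log10(1 - 2|Phi(iHS) - 0.5|): the two-sided Gaussian tail on a
    -log10 scale, used for Manhattan-style display."""
    phi = stats.norm.cdf(ihs_std)
    tail = np.clip(1.0 - 2.0 * np.abs(phi - 0.5), 1e-300, 1.0)
    return -np.log10(tail)


def two_sided_gaussian_p(score: np.ndarray) -> np.ndarray:
    """p = 2 (1 - Phi(|score|)) for a standardized scan statistic."""
    return 2.0 * stats.norm.sf(np.abs(score))


def _merge_small_bins(bin_idx: np.ndarray, n_bins: int, min_size: int = 2) -> np.ndarray:
    """Merge frequency bins holding < min_size SNPs into the nearest
    lower-index non-empty neighbour (or upward at the left edge)."""
    bin_idx = bin_idx.copy()
    for b in range(n_bins):
        size = (bin_idx == b).sum()
        if 0 < size < min_size:
            others = np.setdiff1d(np.unique(bin_idx), [b])
            if len(others) == 0:
                continue
            nearest = others[np.argmin(np.abs(others - b))]
            bin_idx[bin_idx == b] = nearest
    return bin_idx


def ihs_scan(h: HaplotypeSet, maf_min: float = 0.05, n_freq_bins: int = 20,
             ehh_cutoff: float = EHH_CUTOFF, max_gap_bp: int = MAX_GAP_BP,
             min_carriers: int = MIN_CARRIERS) -> IhsResult:
    """Genome-wide iHS: raw ln(iHH_A/iHH_D), bin-standardized score, the
    -log10 display transform, and two-sided Gaussian p per SNP.

    SNPs are excluded when the derived-allele MAF is below ``maf_min``,
    either allele has fewer than ``min_carriers`` carriers, or a decay walk
    hits a chromosome end / a gap above ``max_gap_bp`` before reaching the
    EHH cutoff.
    """
    if h.ancestral_is_alt is None:
        raise ValueError("HaplotypeSet needs ancestral assignments for iHS")
    usable = h.usable if h.usable is not None else np.ones(h.n_snps, dtype=bool)
    derived_freq = h.derived_frequency()
    maf = np.minimum(derived_freq, 1.0 - derived_freq)

    hap = h.haplotypes
    rows = []
    n_excluded = 0
    for chrom, grp in h.markers.groupby("chrom", sort=False):
        cols = grp.index.to_numpy()
        sub = np.ascontiguousarray(hap[:, cols])
        pos = grp["pos"].to_numpy(dtype=np.int64)
        anc_alt = np.asarray(h.ancestral_is_alt)[cols]
        for local_j in range(len(cols)):
            g = cols[local_j]
            if not usable[g] or maf[g] < maf_min:
                n_excluded += 1
                continue
            anc_allele = 1 if anc_alt[local_j] else 0
            der_allele = 1 - anc_allele
            car_a = np.flatnonzero(sub[:, local_j] == anc_allele).astype(np.int64)
            car_d = np.flatnonzero(sub[:, local_j] == der_allele).astype(np.int64)
            if len(car_a) < min_carriers or len(car_d) < min_carriers:
                n_excluded += 1
                continue
            la, fla = _ihh_one_side(sub, pos, local_j, car_a, -1, ehh_cutoff, max_gap_bp)
            ra, fra = _ihh_one_side(sub, pos, local_j, car_a, +1, ehh_cutoff, max_gap_bp)
            ld, fld = _ihh_one_side(sub, pos, local_j, car_d, -1, ehh_cutoff, max_gap_bp)
            rd, frd = _ihh_one_side(sub, pos, local_j, car_d, +1, ehh_cutoff, max_gap_bp)
            if any(f != FLAG_OK for f in (fla, fra, fld, frd)):
                n_excluded += 1
                continue
            ihh_a, ihh_d = la + ra, ld + rd
            if ihh_a <= 0 or ihh_d <= 0:
                n_excluded += 1
                continue
            rows.append((h.markers.at[g, "snp_id"], chrom, int(pos[local_j]),
                         derived_freq[g], ihh_a, ihh_d, np.log(ihh_a / ihh_d)))
    table = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "freq_derived",
                                        "ihh_a", "ihh_d", "ihs_raw"])
    if table.empty:
        return IhsResult(table=table, n_excluded=n_excluded)

    # standardize within equal-width derived-frequency bins
    edges = np.linspace(0.0, 1.0, n_freq_bins + 1)
    bin_idx = np.clip(np.digitize(table["freq_derived"], edges[1:-1]), 0, n_freq_bins - 1)
    bin_idx = _merge_small_bins(bin_idx, n_freq_bins)
    std = np.full(len(table), np.nan)
    raw = table["ihs_raw"].to_numpy()
    for b in np.unique(bin_idx):
        sel = bin_idx == b
        mu, sd = raw[sel].mean(), raw[sel].std(ddof=0)
        std[sel] = (raw[sel] - mu) / sd if sd > 0 else 0.0
    table["ihs_std"] = std
    table["p_ihs"] = ihs_transform(std)
    table["p_two_sided"] = two_sided_gaussian_p(std)
    table["freq_bin"] = bin_idx
    return IhsResult(table=table, n_excluded=n_excluded, bin_edges=edges)


def xpehh_scan(h_obj: HaplotypeSet, h_ref: HaplotypeSet,
               ehh_cutoff: float = EHH_CUTOFF, max_gap_bp: int = MAX_GAP_BP
               ) -> XpehhResult:
    """Genome-wide XP-EHH of an object population against a reference.

    Both sets must share the marker map.  Raw score = ln(iHH_obj/iHH_ref)
    with both integrals truncated where the pooled-haplotype EHH crosses
    ``ehh_cutoff``; standardized genome-wide to exactly zero mean and unit
    variance.  SNPs with boundary flags or a zero integral are excluded.
    """
    if not h_obj.markers["snp_id"].equals(h_ref.markers["snp_id"]):
        raise ValueError("object and reference marker maps differ")
    n_obj = h_obj.n_haplotypes
    stacked_all = np.ascontiguousarray(
        np.vstack([h_obj.haplotypes, h_ref.haplotypes]))
    rows = []
    n_excluded = 0
    for chrom, grp in h_obj.markers.groupby("chrom", sort=False):
        cols = grp.index.to_numpy()
        sub = np.ascontiguousarray(stacked_all[:, cols])
        pos = grp["pos"].to_numpy(dtype=np.int64)
        for local_j in range(len(cols)):
            lo, lr, fl = _xpehh_site(sub, pos, local_j, n_obj, -1,
                                     ehh_cutoff, max_gap_bp)
            ro, rr, fr = _xpehh_site(sub, pos, local_j, n_obj, +1,
                                     ehh_cutoff, max_gap_bp)
            if fl != FLAG_OK or fr != FLAG_OK:
                n_excluded += 1
                continue
            ihh_o, ihh_r = lo + ro, lr + rr
            if ihh_o <= 0 or ihh_r <= 0:
                n_excluded += 1
                continue
            g = cols[local_j]
            rows.append((h_obj.markers.at[g, "snp_id"], chrom, int(pos[local_j]),
                         ihh_o, ihh_r, np.log(ihh_o / ihh_r)))
    table = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos",
                                        "ihh_obj", "ihh_ref", "xpehh_raw"])
    if not table.empty:
        raw = table["xpehh_raw"].to_numpy()
        sd = raw.std(ddof=0)
        table["xpehh_std"] = (raw - raw.mean()) / sd if sd > 0 else 0.0
        table["p_two_sided"] = two_sided_gaussian_p(table["xpehh_std"].to_numpy())
    return XpehhResult(table=table, n_excluded=n_excluded)
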