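"""Genotype I/O, dataset merging and SNP-array quality control.

The central container is :class:`GenotypeDataset`: a samples x SNPs matrix of
alt-allele counts (0/1/2, ``-1`` missing) together with a marker map
(chromosome, 1-based physical position, ref/alt alleles) and per-sample
population labels.  Readers accept VCF (via cyvcf2) and PLINK PED/MAP text;
phase, when present in a VCF, is retained separately as a haplotype matrix.

QC follows the conventional array-cleaning recipe: drop unmapped SNPs, drop
SNPs under a call-rate floor, drop samples over a missingness ceiling, then
recompute frequencies on the retained samples and drop low-MAF SNPs — in that
order, because MAF is only meaningful on the cohort that survives.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

MARKER_COLUMNS = ["snp_id", "chrom", "pos", "ref", "alt"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class GenotypeParseError(ValueError):
    """Raised for malformed genotype files; message names the offending line."""


def _validate_markers(markers: pd.DataFrame) -> pd.DataFrame:
    markers = markers.reset_index(drop=True)
    missing_cols = [c for c in MARKER_COLUMNS if c not in markers.columns]
    if missing_cols:
        raise ValueError(f"marker map missing columns: {missing_cols}")
    if markers["snp_id"].duplicated().any():
        dup = markers.loc[markers["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise ValueError(f"duplicate snp_id in marker map: {dup!r}")
    if (markers["pos"] < 1).any():
        raise ValueError("marker positions must be 1-based (>= 1)")
    if (markers["ref"] == markers["alt"]).any():
        bad = markers.loc[markers["ref"] == markers["alt"], "snp_id"].iloc[0]
        raise ValueError(f"ref == alt for SNP {bad!r}")
    return markers


@dataclass
class GenotypeDataset:
    """Diploid genotypes with a marker map and sample/population labels.

    Parameters
    ----------
    markers : DataFrame with columns snp_id, chrom, pos, ref, alt.
    samples : DataFrame with columns sample_id, population.
    calls : int array (n_samples, n_snps); alt-allele counts, ``MISSING`` = -1.
    haplotypes : optional (2*n_samples, n_snps) phased 0/1 matrix, row order
        (sample0_hapA, sample0_hapB, sample1_hapA, ...).
    """

    markers: pd.DataFrame
    samples: pd.DataFrame
    calls: np.ndarray
    haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.markers = _validate_markers(self.markers)
        self.samples = self.samples.reset_index(drop=True)
        if self.samples["sample_id"].duplicated().any():
            dup = self.samples.loc[self.samples["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"calls shape {self.calls.shape} != (n_samples={len(self.samples)}, "
                f"n_snps={len(self.markers)})"
            )
        ok = (self.calls == MISSING) | ((self.calls >= 0) & (self.calls <= 2))
        if not ok.all():
            raise ValueError("calls must be in {0,1,2} or MISSING (-1)")
        if self.haplotypes is not None:
            self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
            if self.haplotypes.shape != (2 * len(self.samples), len(self.markers)):
                raise ValueError("haplotypes must be (2*n_samples, n_snps)")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.markers)

    def sort_by_position(self) -> "GenotypeDataset":
        """Return a copy with SNPs sorted by (chromosome, position)."""
        order = self.markers.sort_values(
            ["chrom", "pos"], kind="mergesort"
        ).index.to_numpy()
        return self.take_snps(order)

    def take_snps(self, idx) -> "GenotypeDataset":
        idx = np.asarray(idx)
        return GenotypeDataset(
            markers=self.markers.iloc[idx],
            samples=self.samples,
            calls=self.calls[:, idx],
            haplotypes=None if self.haplotypes is None else self.haplotypes[:, idx],
        )

    def take_samples(self, idx) -> "GenotypeDataset":
        idx = np.asarray(idx)
        hap = None
        if self.haplotypes is not None:
            hap_idx = np.repeat(idx * 2, 2) + np.tile([0, 1], len(idx))
            hap = self.haplotypes[hap_idx]
        return GenotypeDataset(
            markers=self.markers,
            samples=self.samples.iloc[idx],
            calls=self.calls[idx],
            haplotypes=hap,
        )

    def subset_population(self, *populations: str) -> "GenotypeDataset":
        mask = self.samples["population"].isin(populations).to_numpy()
        return self.take_samples(np.flatnonzero(mask))

    def alt_frequencies(self) -> np.ndarray:
        """Per-SNP alt-allele frequency over non-missing genotypes (NaN if none)."""
        calls = self.calls
        obs = calls != MISSING
        n = obs.sum(axis=0)
        alt = np.where(obs, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, alt / (2.0 * n), np.nan)


@dataclass
class QcReport:
    """Per-item record of what QC removed and why."""

    n_snps_in: int = 0
    n_snps_out: int = 0
    n_samples_in: int = 0
    n_samples_out: int = 0
    dropped_snp_reasons: dict = field(default_factory=dict)  # snp_id -> reason
    dropped_sample_reasons: dict = field(default_factory=dict)  # sample_id -> reason
    thresholds: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [("snp", k, v) for k, v in self.dropped_snp_reasons.items()]
        rows += [("sample", k, v) for k, v in self.dropped_sample_reasons.items()]
        return pd.DataFrame(rows, columns=["item_type", "item_id", "reason"])


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | os.PathLike, populations: dict | None = None) -> GenotypeDataset:
    """Read a VCF (4.x, plain or bgzipped) of biallelic SNPs.

    Phase separators ("|") are honoured: if every genotype in the file is
    phased, a haplotype matrix is attached.  ``populations`` maps sample id to
    population label (default ``"unknown"``).
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(os.fspath(path))
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise GenotypeParseError(f"cannot parse VCF {path}: {exc}") from exc
    sample_ids = list(vcf.samples)
    rows, call_rows, hapa, hapb = [], [], [], []
    all_phased = True
    for i, var in enumerate(vcf):
        if len(var.ALT) != 1:
            raise GenotypeParseError(
                f"{path}: record {i + 1} ({var.CHROM}:{var.POS}) is not biallelic"
            )
        rows.append((var.ID or f"{var.CHROM}:{var.POS}", str(var.CHROM), int(var.POS),
                     var.REF, var.ALT[0]))
        gts = var.genotypes  # [[a0, a1, phased], ...]
        a = np.array([g[0] for g in gts], dtype=np.int8)
        b = np.array([g[1] for g in gts], dtype=np.int8)
        call = np.where((a < 0) | (b < 0), MISSING, a + b).astype(np.int8)
        call_rows.append(call)
        if all_phased and not all(g[2] for g in gts):
            all_phased = False
        hapa.append(a)
        hapb.append(b)
    if not rows:
        raise GenotypeParseError(f"{path}: no variant records")
    markers = pd.DataFrame(rows, columns=MARKER_COLUMNS)
    calls = np.stack(call_rows, axis=1)
    haplotypes = None
    if all_phased and not (calls == MISSING).any():
        haplotypes = np.empty((2 * len(sample_ids), len(rows)), dtype=np.int8)
        haplotypes[0::2] = np.stack(hapa, axis=1)
        haplotypes[1::2] = np.stack(hapb, axis=1)
    populations = populations or {}
    samples = pd.DataFrame(
        {"sample_id": sample_ids,
         "population": [populations.get(s, "unknown") for s in sample_ids]}
    )
    return GenotypeDataset(markers, samples, calls, haplotypes)


def write_vcf(d: GenotypeDataset, path: str | os.PathLike, phased: bool = False) -> None:
    """Write a minimal VCF 4.2; ``phased=True`` emits ``|``-separated haplotypes."""
    if phased and d.haplotypes is None:
        raise ValueError("dataset has no haplotypes to write phased")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(d.markers["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(d.samples["sample_id"]) + "\n")
        markers = d.markers
        for j in range(d.n_snps):
            if phased:
                a = d.haplotypes[0::2, j]
                b = d.haplotypes[1::2, j]
                gts = [f"{x}|{y}" for x, y in zip(a, b)]
            else:
                gts = ["./." if c == MISSING else ("0/0", "0/1", "1/1")[c]
                       for c in d.calls[:, j]]
            row = markers.iloc[j]
            fh.write(f"{row.chrom}\t{row.pos}\t{row.snp_id}\t{row.ref}\t{row.alt}"
                     f"\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n")


# ---------------------------------------------------------------------------
# PLINK PED/MAP text
# ---------------------------------------------------------------------------

def read_plink(prefix: str | os.PathLike, alleles: pd.DataFrame | None = None,
               populations: dict | None = None) -> GenotypeDataset:
    """Read a PLINK text fileset ``prefix.ped`` + ``prefix.map``.

    MAP files carry no ref/alt orientation, so it is taken from ``alleles``
    (columns snp_id, ref, alt — e.g. the sidecar written by
    :func:`write_plink`) when given, and otherwise inferred from the data:
    ref = major allele, ties broken alphabetically.  ``"0 0"`` is missing.
    """
    prefix = os.fspath(prefix)
    map_path, ped_path = prefix + ".map", prefix + ".ped"
    mp = pd.read_csv(map_path, sep=r"\s+", header=None,
                     names=["chrom", "snp_id", "cm", "pos"],
                     dtype={"chrom": str, "snp_id": str})
    m = len(mp)
    sample_rows, geno_rows = [], []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * m:
                raise GenotypeParseError(
                    f"{ped_path}: line {ln} has {len(fields)} fields, "
                    f"expected {6 + 2 * m} for {m} MAP SNPs"
                )
            sample_rows.append((fields[1], fields[0]))
            geno_rows.append(fields[6:])
    if not sample_rows:
        raise GenotypeParseError(f"{ped_path}: no sample rows")
    geno = np.array(geno_rows, dtype="U1").reshape(len(sample_rows), m, 2)

    if alleles is not None:
        atab = alleles.set_index("snp_id")
        ref = atab.loc[mp["snp_id"], "ref"].to_numpy(dtype="U1")
        alt = atab.loc[mp["snp_id"], "alt"].to_numpy(dtype="U1")
    else:
        ref = np.empty(m, dtype="U1")
        alt = np.empty(m, dtype="U1")
        for j in range(m):
            col = geno[:, j, :].ravel()
            col = col[col != "0"]
            uniq, counts = np.unique(col, return_counts=True)
            if len(uniq) == 0:
                ref[j], alt[j] = "A", "G"  # fully missing column; arbitrary
            elif len(uniq) == 1:
                ref[j] = uniq[0]
                alt[j] = _COMPLEMENT.get(uniq[0], "N")
            elif len(uniq) == 2:
                # major allele -> ref; tie -> alphabetical
                order = np.lexsort((uniq, -counts))
                ref[j], alt[j] = uniq[order[0]], uniq[order[1]]
            else:
                raise GenotypeParseError(
                    f"{ped_path}: SNP {mp['snp_id'][j]!r} has >2 alleles: {list(uniq)}"
                )

    missing = (geno == "0").any(axis=2)
    n_alt = (geno == alt[None, :, None]).sum(axis=2).astype(np.int8)
    bad = ~missing & ((geno != ref[None, :, None]) & (geno != alt[None, :, None])).any(axis=2)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise GenotypeParseError(
            f"{ped_path}: sample {sample_rows[i][0]!r} SNP {mp['snp_id'][j]!r} "
            f"carries an allele not in {{{ref[j]},{alt[j]}}}"
        )
    calls = np.where(missing, MISSING, n_alt).astype(np.int8)
    populations = populations or {}
    samples = pd.DataFrame(
        {"sample_id": [s for s, _ in sample_rows],
         "population": [populations.get(s, fid) for s, fid in sample_rows]}
    )
    markers = pd.DataFrame(
        {"snp_id": mp["snp_id"], "chrom": mp["chrom"], "pos": mp["pos"].astype(int),
         "ref": ref, "alt": alt}
    )
    return GenotypeDataset(markers, samples, calls)


def write_plink(d: GenotypeDataset, prefix: str | os.PathLike,
                write_alleles: bool = True) -> None:
    """Write ``prefix.ped`` / ``prefix.map`` (+ ``prefix.alleles`` sidecar)."""
    prefix = os.fspath(prefix)
    mp = d.markers
    with open(prefix + ".map", "w") as fh:
        for row in mp.itertuples():
            fh.write(f"{row.chrom}\t{row.snp_id}\t0\t{row.pos}\n")
    ref = mp["ref"].to_numpy(dtype="U1")
    alt = mp["alt"].to_numpy(dtype="U1")
    with open(prefix + ".ped", "w") as fh:
        for i in range(d.n_samples):
            srow = d.samples.iloc[i]
            buf = io.StringIO()
            buf.write(f"{srow.population}\t{srow.sample_id}\t0\t0\t0\t-9")
            for j, c in enumerate(d.calls[i]):
                if c == MISSING:
                    buf.write("\t0 0")
                else:
                    a1 = alt[j] if c >= 1 else ref[j]
                    a2 = alt[j] if c == 2 else ref[j]
                    buf.write(f"\t{a1} {a2}")
            fh.write(buf.getvalue() + "\n")
    if write_alleles:
        mp[["snp_id", "ref", "alt"]].to_csv(prefix + ".alleles", sep="\t", index=False)


# ---------------------------------------------------------------------------
# Merging and QC
# ---------------------------------------------------------------------------

def _is_ambiguous(ref: str, alt: str) -> bool:
    """A/T and C/G SNPs cannot be strand-resolved without strand metadata."""
    return _COMPLEMENT.get(ref) == alt


def merge_on_shared_snps(a: GenotypeDataset, b: GenotypeDataset,
                         return_excluded: bool = False):
    """Intersect two datasets on snp_id, harmonizing allele orientation.

    SNPs whose ref/alt labels are swapped between inputs have ``b``'s calls
    flipped (c -> 2-c).  Strand-ambiguous (A/T, C/G) SNPs with mismatched
    alleles are excluded, as are SNPs with incompatible allele pairs.
    Samples are concatenated; haplotypes are dropped (phase alignment across
    cohorts is the caller's responsibility).
    """
    shared = a.markers.merge(b.markers, on="snp_id", suffixes=("_a", "_b"))
    if shared.empty:
        raise ValueError("no shared SNPs between datasets")
    collisions = set(a.samples["sample_id"]) & set(b.samples["sample_id"])
    if collisions:
        raise ValueError(f"duplicate sample ids across datasets: {sorted(collisions)[:5]}")

    same = (shared["ref_a"] == shared["ref_b"]) & (shared["alt_a"] == shared["alt_b"])
    swapped = (shared["ref_a"] == shared["alt_b"]) & (shared["alt_a"] == shared["ref_b"])
    ambiguous = shared.apply(lambda r: _is_ambiguous(r["ref_a"], r["alt_a"]), axis=1)
    keep = (same | swapped) & ~(ambiguous & ~same)
    excluded = shared.loc[~keep, "snp_id"].tolist()
    shared = shared[keep]
    if shared.empty:
        raise ValueError("no compatible shared SNPs after allele harmonization")

    a_idx = a.markers.set_index("snp_id").index.get_indexer(shared["snp_id"])
    b_idx = b.markers.set_index("snp_id").index.get_indexer(shared["snp_id"])
    calls_a = a.calls[:, a_idx]
    calls_b = b.calls[:, b_idx].copy()
    flip = swapped[keep].to_numpy()
    flip_cols = calls_b[:, flip]
    flip_cols = np.where(flip_cols == MISSING, MISSING, 2 - flip_cols).astype(np.int8)
    calls_b[:, flip] = flip_cols

    markers = pd.DataFrame({
        "snp_id": shared["snp_id"].to_numpy(),
        "chrom": shared["chrom_a"].to_numpy(),
        "pos": shared["pos_a"].to_numpy(),
        "ref": shared["ref_a"].to_numpy(),
        "alt": shared["alt_a"].to_numpy(),
    })
    samples = pd.concat([a.samples, b.samples], ignore_index=True)
    merged = GenotypeDataset(markers, samples,
                             np.concatenate([calls_a, calls_b], axis=0)).sort_by_position()
    if return_excluded:
        return merged, excluded
    return merged


def qc_filter(d: GenotypeDataset, min_call_rate: float = 0.90, min_maf: float = 0.05,
              max_sample_missing: float = 0.10, drop_unmapped: bool = True
              ) -> tuple[GenotypeDataset, QcReport]:
    """Apply array QC in the fixed order: unmapped -> SNP call rate ->
    sample missingness -> MAF (recomputed on retained samples).

    Boundaries are strict per the thresholds' wording: a SNP is dropped when
    call rate < ``min_call_rate`` or MAF < ``min_maf``; a sample when its
    missing fraction > ``max_sample_missing``.
    """
    for name, v in [("min_call_rate", min_call_rate), ("min_maf", min_maf),
                    ("max_sample_missing", max_sample_missing)]:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0,1], got {v}")
    report = QcReport(n_snps_in=d.n_snps, n_samples_in=d.n_samples,
                      thresholds=dict(min_call_rate=min_call_rate, min_maf=min_maf,
                                      max_sample_missing=max_sample_missing,
                                      drop_unmapped=drop_unmapped))
    snp_ids = d.markers["snp_id"].to_numpy()

    # 1. unmapped SNPs (chromosome "0", "", or NA)
    keep_snp = np.ones(d.n_snps, dtype=bool)
    if drop_unmapped:
        chrom = d.markers["chrom"].astype(str).to_numpy()
        unmapped = (chrom == "0") | (chrom == "") | (chrom == "nan")
        for sid in snp_ids[unmapped]:
            report.dropped_snp_reasons[sid] = "unmapped"
        keep_snp &= ~unmapped

    # 2. SNP call rate on all current samples
    obs = d.calls != MISSING
    call_rate = obs.mean(axis=0)
    low_cr = keep_snp & (call_rate < min_call_rate)
    for sid in snp_ids[low_cr]:
        report.dropped_snp_reasons[sid] = "call_rate"
    keep_snp &= ~low_cr

    # 3. sample missingness over surviving SNPs
    miss_frac = (~obs[:, keep_snp]).mean(axis=1) if keep_snp.any() else np.ones(d.n_samples)
    keep_sample = miss_frac <= max_sample_missing
    for samp in d.samples["sample_id"].to_numpy()[~keep_sample]:
        report.dropped_sample_reasons[samp] = "missingness"
    if not keep_sample.any():
        raise ValueError("QC removed all samples")

    # 4. MAF recomputed on retained samples
    sub = d.take_samples(np.flatnonzero(keep_sample)).take_snps(np.flatnonzero(keep_snp))
    freq = sub.alt_frequencies()
    with np.errstate(invalid="ignore"):
        maf = np.fmin(freq, 1.0 - freq)
    low_maf = ~(maf >= min_maf)  # NaN (all-missing SNP) also drops
    for sid in sub.markers["snp_id"].to_numpy()[low_maf]:
        report.dropped_snp_reasons[sid] = "maf"
    out = sub.take_snps(np.flatnonzero(~low_maf))

    report.n_snps_out = out.n_snps
    report.n_samples_out = out.n_samples
    return out, report


def panel_summary(d: GenotypeDataset) -> tuple[pd.DataFrame, dict]:
    """Marker-panel spacing summary.

    Returns a per-chromosome table (span, SNP count, mean adjacent gap; gap is
    NaN on single-SNP chromosomes) and genome totals where the mean spacing
    pools all adjacent gaps across chromosomes.
    """
    rows = []
    all_gaps = []
    for chrom, grp in d.markers.groupby("chrom", sort=False):
        pos = np.sort(grp["pos"].to_numpy())
        gaps = np.diff(pos)
        rows.append({
            "chrom": chrom, "n_snps": len(pos),
            "span_bp": int(pos[-1] - pos[0]) if len(pos) > 1 else 0,
            "mean_gap_bp": float(gaps.mean()) if len(gaps) else np.nan,
        })
        all_gaps.append(gaps)
    pooled = np.concatenate(all_gaps) if all_gaps else np.array([])
    if pooled.size == 0:
        raise ValueError("panel summary needs >=2 SNPs on at least one chromosome")
    per_chrom = pd.DataFrame(rows)
    totals = {
        "n_snps": int(d.n_snps),
        "n_chromosomes": int(per_chrom.shape[0]),
        "total_span_bp": int(per_chrom["span_bp"].sum()),
        "mean_adjacent_gap_bp": float(pooled.mean()),
    }
    return per_chrom, totals
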