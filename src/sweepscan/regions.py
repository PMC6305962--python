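"""FDR control, candidate-sweep clustering, gene annotation and overlaps.

A candidate selective-sweep region is a maximal chain of FDR-significant SNPs
in which consecutive SNPs are separated by at most 500 kb, with at least two
members; singleton significant SNPs are reported separately.  Regions are
annotated against user-supplied gene intervals (BED or GFF3) with a 100 kb
flank on each side, and regions from different scan methods are compared by
closed-interval intersection on the same chromosome.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from statsmodels.stats.multitest import multipletests

MAX_GAP_BP = 500_000
FLANK_BP = 100_000


@dataclass
class FdrResult:
    reject: np.ndarray            # bool per input p
    qvalues: np.ndarray
    alpha: float
    method: str
    p_cutoff: float               # largest p rejected (0 if none)


def fdr_control(p: np.ndarray, alpha: float = 0.01, method: str = "bh") -> FdrResult:
    """False-discovery-rate control over a vector of per-SNP p-values.

    ``'bh'``: Benjamini-Hochberg step-up (reject all p_(i) with
    i <= max{i : p_(i) <= i*alpha/m}).  ``'storey'``: Storey q-values with
    the lambda=0.5 pi0 estimate; rejects q <= alpha.  NaN p-values are never
    rejected and carry NaN q-values.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0,1]")
    reject = np.zeros(p.shape, dtype=bool)
    qvals = np.full(p.shape, np.nan)
    pf = p[finite]
    if method == "bh":
        rej, q, _, _ = multipletests(pf, alpha=alpha, method="fdr_bh")
    elif method == "storey":
        m = len(pf)
        pi0 = min(1.0, (pf > 0.5).sum() / (0.5 * m)) or 1.0 / m
        order = np.argsort(pf)
        ranked = pf[order]
        q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
        q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
        q = np.empty(m)
        q[order] = np.clip(q_sorted, 0, 1)
        rej = q <= alpha
    else:
        raise ValueError(f"unknown FDR method {method!r}")
    reject[finite] = rej
    qvals[finite] = q
    p_cutoff = float(pf[rej].max()) if rej.any() else 0.0
    return FdrResult(reject=reject, qvalues=qvals, alpha=alpha, method=method,
                     p_cutoff=p_cutoff)


@dataclass
class SweepRegion:
    """A clustered candidate selective-sweep interval (1-based inclusive)."""

    chrom: str
    start_bp: int
    end_bp: int
    member_snp_ids: list[str]
    top_snp_id: str
    top_statistic: float
    method: str = ""
    genes: list[str] = field(default_factory=list)

    @property
    def n_members(self) -> int:
        return len(self.member_snp_ids)


def cluster_candidates(significant: pd.DataFrame, max_gap: int = MAX_GAP_BP,
                       min_snps: int = 2, statistic: str | None = None,
                       method: str = "") -> tuple[list[SweepRegion], pd.DataFrame]:
    """Chain significant SNPs into candidate sweep regions.

    ``significant``: DataFrame with columns chrom, pos, snp_id and optionally
    a ``statistic`` column used to pick each region's top SNP (most extreme
    absolute value; ties -> smallest position).  Consecutive SNPs within a
    chromosome separated by <= ``max_gap`` (inclusive) join a chain; chains
    with >= ``min_snps`` members become regions spanning [min pos, max pos].
    Returns (regions, excluded-singleton table).
    """
    req = {"chrom", "pos", "snp_id"}
    if not req.issubset(significant.columns):
        raise ValueError(f"significant table needs columns {sorted(req)}")
    regions: list[SweepRegion] = []
    singles = []
    df = significant.sort_values(["chrom", "pos"], kind="mergesort")
    for chrom, grp in df.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > max_gap)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(pos) - 1]])
        for s, e in zip(starts, ends):
            chain = grp.iloc[s:e + 1]
            if len(chain) < min_snps:
                singles.append(chain)
                continue
            if statistic is not None:
                stat = chain[statistic].to_numpy(dtype=float)
                best = np.abs(stat).max()
                cand = chain[np.abs(stat) == best].sort_values("pos")
                top = cand.iloc[0]
                top_stat = float(top[statistic])
            else:
                top = chain.iloc[0]
                top_stat = float("nan")
            regions.append(SweepRegion(
                chrom=str(chrom), start_bp=int(chain["pos"].min()),
                end_bp=int(chain["pos"].max()),
                member_snp_ids=chain["snp_id"].tolist(),
                top_snp_id=str(top["snp_id"]), top_statistic=top_stat,
                method=method))
    excluded = (pd.concat(singles, ignore_index=True) if singles
                else df.iloc[0:0].copy())
    return regions, excluded


def read_gene_annotation(path: str | os.PathLike, fmt: str | None = None) -> pd.DataFrame:
    """Read gene intervals from BED (3+ cols, half-open) or GFF3 ('gene'
    features).  Returns 1-based closed intervals: gene, chrom, start, end."""
    path = os.fspath(path)
    if fmt is None:
        fmt = "gff3" if path.endswith((".gff", ".gff3")) else "bed"
    rows = []
    if fmt == "bed":
        bed = pd.read_csv(path, sep="\t", header=None, comment="#")
        for i, r in bed.iterrows():
            name = str(r[3]) if bed.shape[1] > 3 else f"interval_{i}"
            # BED is 0-based half-open -> 1-based closed
            rows.append((name, str(r[0]), int(r[1]) + 1, int(r[2])))
    elif fmt == "gff3":
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9 or f[2] != "gene":
                    continue
                attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
                name = attrs.get("Name") or attrs.get("ID") or f"{f[0]}:{f[3]}"
                rows.append((name, f[0], int(f[3]), int(f[4])))
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])


def annotate_regions(regions: list[SweepRegion], genes: pd.DataFrame,
                     flank: int = FLANK_BP) -> pd.DataFrame:
    """Attach genes whose 1-based closed interval intersects
    [start - flank, end + flank] to each region (also filled into
    ``region.genes``).  Returns a region x gene long table."""
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in genes.groupby("chrom"):
        # IntervalTree is half-open; +1 on end makes the query closed
        trees[str(chrom)] = IntervalTree.from_tuples(
            (int(s), int(e) + 1, g) for g, s, e in
            zip(grp["gene"], grp["start"], grp["end"]))
    rows = []
    known = set(trees)
    for i, reg in enumerate(regions):
        if reg.chrom not in known:
            warnings.warn(f"region chromosome {reg.chrom!r} absent from annotation")
            reg.genes = []
            continue
        lo = max(1, reg.start_bp - flank)
        hi = reg.end_bp + flank
        hits = sorted({iv.data for iv in trees[reg.chrom].overlap(lo, hi + 1)})
        reg.genes = list(hits)
        for g in hits:
            rows.append((i, reg.chrom, reg.start_bp, reg.end_bp, reg.method, g))
    return pd.DataFrame(rows, columns=["region_index", "chrom", "start_bp",
                                       "end_bp", "method", "gene"])


def overlap_regions(a: list[SweepRegion], b: list[SweepRegion]
                    ) -> list[tuple[int, int]]:
    """Index pairs (i, j) where a[i] and b[j] share a chromosome and their
    closed [start, end] intervals intersect."""
    pairs = []
    for i, ra in enumerate(a):
        for j, rb in enumerate(b):
            if ra.chrom == rb.chrom and ra.start_bp <= rb.end_bp and rb.start_bp <= ra.end_bp:
                pairs.append((i, j))
    return pairs


def regions_to_frame(regions: list[SweepRegion]) -> pd.DataFrame:
    return pd.DataFrame([{
        "chrom": r.chrom, "start_bp": r.start_bp, "end_bp": r.end_bp,
        "n_members": r.n_members, "top_snp_id": r.top_snp_id,
        "top_statistic": r.top_statistic, "method": r.method,
        "genes": ",".join(r.genes),
    } for r in regions])
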