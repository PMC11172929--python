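"""Selection scan: Z-scores, empirical tails, region merging, annotation.

The scan turns the per-window statistics table into candidate sweep regions
by three complementary routes:

* ``ZFST`` — windowed Weir-Cockerham F_ST, Z-normalised genome-wide, upper
  0.5% tail;
* ``ZHP`` — pooled heterozygosity of the test population, Z-normalised,
  lower 0.5% tail;
* ``PI_RATIO`` — ln(pi_test / pi_ref) with the reference diversity computed
  on the pooled reference samples; the *lower* tail is selected because a
  sweep depresses diversity in the test population, driving the log ratio
  down (``ratio_tail="upper"`` flips this for the inverted convention).

Tails always flag exactly ceil(q * W) windows out of the W windows carrying
a finite value of the statistic, with ties at the cutoff broken by genomic
order so that reruns are byte-identical.  Flagged windows are merged into
maximal overlapping/book-ended regions, regions are annotated with
overlapping genes (>= 1 bp, half-open arithmetic), and genes recovered by
all three methods form the intersection set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GeneModel, GenotypeMatrix
from .stats import ScanConfig, Window, tajimas_d, window_stats_table, windowed_fst

__all__ = [
    "CandidateRegion", "GeneHit", "METHODS",
    "z_transform", "ln_pi_ratio", "select_tail", "merge_windows",
    "annotate_regions", "intersect_methods", "gene_region_profile",
    "scan_table", "run_scan",
]

METHODS = ("ZFST", "ZHP", "PI_RATIO")


@dataclass
class CandidateRegion:
    """Maximal run of flagged windows for one method (0-based half-open)."""

    chrom: str
    start: int
    end: int
    method: str
    peak: float
    windows: list = field(default_factory=list)


@dataclass
class GeneHit:
    """A gene overlapped by candidate regions of one or more methods."""

    gene: GeneModel
    methods: set
    regions: list = field(default_factory=list)


def z_transform(values) -> np.ndarray:
    """(x - mean) / sd over the finite entries, population-sd convention.

    Non-finite entries stay NaN in the output; order is preserved.  A zero
    standard deviation is an error (the Z-scores would be undefined).
    """
    x = np.asarray(values, dtype=np.float64)
    finite = np.isfinite(x)
    if finite.sum() < 2:
        raise ValueError("need at least 2 finite values to Z-transform")
    mu = x[finite].mean()
    sd = x[finite].std()  # population (ddof=0) convention
    if sd == 0:
        raise ValueError("zero spread: Z-scores undefined")
    out = np.full_like(x, np.nan)
    out[finite] = (x[finite] - mu) / sd
    return out


def ln_pi_ratio(pi_test, pi_ref_pooled):
    """ln(pi_test / pi_ref); NaN (flagged) when either term is 0 or NaN.

    Windows with zero diversity in either population are excluded from the
    empirical tails rather than propagating +/- infinity.
    """
    t = np.asarray(pi_test, dtype=np.float64)
    r = np.asarray(pi_ref_pooled, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where((t > 0) & (r > 0), np.log(t / r), np.nan)
    if np.ndim(pi_test) == 0 and np.ndim(pi_ref_pooled) == 0:
        return float(out)
    return out


def select_tail(records: pd.DataFrame, statistic: str, side: str,
                q: float) -> np.ndarray:
    """Boolean mask flagging exactly ceil(q*W) windows in one tail.

    W counts the windows with a finite value of ``statistic``.  ``side`` is
    "upper" or "lower".  Ties at the cutoff are broken by genomic order
    (chromosome appearance order, then start), so the selection is
    deterministic.
    """
    if not (0.0 < q < 0.5):
        raise ValueError("q must be in (0, 0.5)")
    if side not in ("upper", "lower"):
        raise ValueError("side must be 'upper' or 'lower'")
    x = records[statistic].to_numpy(dtype=np.float64)
    finite = np.isfinite(x)
    W = int(finite.sum())
    if W == 0:
        raise ValueError(f"no finite values of {statistic!r}")
    k = math.ceil(q * W)
    chrom_order = {c: i for i, c in
                   enumerate(pd.unique(records["chrom"]))}
    corder = records["chrom"].map(chrom_order).to_numpy()
    starts = records["start"].to_numpy()
    key = x if side == "upper" else -x
    key = np.where(finite, key, -np.inf)
    # sort: extreme first, genomic order among ties
    order = np.lexsort((starts, corder, -key))
    mask = np.zeros(len(records), dtype=bool)
    mask[order[:k]] = True
    return mask


def merge_windows(flagged: pd.DataFrame, method: str,
                  statistic: str) -> list:
    """Merge overlapping or book-ended flagged windows into regions.

    ``flagged`` must be in genomic order (as produced by the window table).
    The peak keeps the member value of largest magnitude, which is the most
    extreme Z-score / log-ratio regardless of which tail was selected.
    Idempotent: merging the output again is a no-op.
    """
    regions = []
    for _, row in flagged.iterrows():
        v = float(row[statistic])
        if (regions
                and regions[-1].chrom == row["chrom"]
                and row["start"] <= regions[-1].end):
            r = regions[-1]
            r.end = max(r.end, int(row["end"]))
            r.peak = max(r.peak, v, key=abs)
            r.windows.append((int(row["start"]), int(row["end"])))
        else:
            regions.append(CandidateRegion(
                chrom=row["chrom"], start=int(row["start"]),
                end=int(row["end"]), method=method, peak=v,
                windows=[(int(row["start"]), int(row["end"]))],
            ))
    return regions


def annotate_regions(regions: list, genes: list) -> list:
    """Genes overlapping candidate regions by >= 1 bp (half-open).

    Raises when region chromosomes are entirely absent from the gene set
    (a chromosome-naming mismatch between VCF and GFF3).
    """
    gene_chroms = {gm.chrom for gm in genes}
    region_chroms = {r.chrom for r in regions}
    unmatched = sorted(region_chroms - gene_chroms)
    if unmatched:
        raise ValueError(
            "region chromosomes absent from annotation "
            f"(VCF/GFF3 naming mismatch?): {unmatched}"
        )
    hits = {}
    for gm in genes:
        gs, ge = gm.to_zero_based()
        for r in regions:
            if r.chrom != gm.chrom:
                continue
            if r.start < ge and gs < r.end:  # >= 1 bp overlap, half-open
                h = hits.setdefault(gm.gene_id,
                                    GeneHit(gene=gm, methods=set()))
                h.methods.add(r.method)
                h.regions.append(r)
    return list(hits.values())


def intersect_methods(hits_by_method: dict) -> dict:
    """Combine per-method gene lists into Venn counts and the shared set.

    ``hits_by_method`` maps method label -> iterable of gene identifiers
    (or GeneHit objects).  Returns a dict with:

    * ``methods_of``: gene id -> frozenset of methods that recovered it;
    * ``venn``: membership-pattern -> count, keys like "ZFST&ZHP";
    * ``shared``: sorted ids present in every method's list.
    """
    def ids(v):
        return {h.gene.gene_id if isinstance(h, GeneHit) else h for h in v}

    sets = {m: ids(v) for m, v in hits_by_method.items()}
    methods = list(sets)
    union = set().union(*sets.values()) if sets else set()
    methods_of = {
        gid: frozenset(m for m in methods if gid in sets[m])
        for gid in union
    }
    venn = {}
    for gid, ms in methods_of.items():
        key = "&".join(m for m in methods if m in ms)
        venn[key] = venn.get(key, 0) + 1
    shared = sorted(gid for gid, ms in methods_of.items()
                    if len(ms) == len(methods))
    return {"methods_of": methods_of, "venn": venn, "shared": shared}


def gene_region_profile(g: GenotypeMatrix, gene: GeneModel,
                        pop_test, pop_refs, flank_bp: int = 500_000,
                        cfg: ScanConfig = None) -> pd.DataFrame:
    """Windowed F_ST and test-population Tajima's D across gene +/- flank.

    A plot-ready table (chrom, start, end, in_gene, fst, tajd).  Windows
    without SNPs carry NaN.
    """
    if cfg is None:
        cfg = ScanConfig()
    if gene.chrom not in g.chroms():
        raise ValueError(f"gene chromosome {gene.chrom!r} not in matrix")
    gs, ge = gene.to_zero_based()
    lo = max(0, gs - flank_bp)
    hi = ge + flank_bp
    refs = list(pop_refs) if isinstance(pop_refs, (list, tuple)) else pop_refs
    rows = []
    start = lo
    while start < hi:
        w = Window(gene.chrom, start, min(start + cfg.window_size, hi))
        rows.append((
            w.chrom, w.start, w.end,
            (w.start < ge and gs < w.end),
            windowed_fst(g, w, pop_test, refs),
            tajimas_d(g, w, pop_test),
        ))
        start += cfg.step
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "in_gene", "fst", "tajd"])


def scan_table(g: GenotypeMatrix, cfg: ScanConfig, pop_test, pop_refs,
               chrom_lengths: dict = None,
               ratio_tail: str = "lower") -> pd.DataFrame:
    """Window table augmented with zfst, zhp, ln_pi_ratio and tail flags."""
    tbl = window_stats_table(g, cfg, pop_test, pop_refs,
                             chrom_lengths=chrom_lengths)
    tbl["zfst"] = z_transform(tbl["fst"])
    tbl["zhp"] = z_transform(tbl["hp"])
    tbl["ln_pi_ratio"] = ln_pi_ratio(tbl["pi_test"], tbl["pi_ref"])
    q = cfg.tail_fraction
    tbl["hit_zfst"] = select_tail(tbl, "zfst", "upper", q)
    tbl["hit_zhp"] = select_tail(tbl, "zhp", "lower", q)
    tbl["hit_pi_ratio"] = select_tail(tbl, "ln_pi_ratio", ratio_tail, q)
    return tbl


def run_scan(g: GenotypeMatrix, cfg: ScanConfig, pop_test, pop_refs,
             genes: list = None, chrom_lengths: dict = None,
             ratio_tail: str = "lower") -> dict:
    """Full scan: table, per-method regions, gene hits and intersection."""
    tbl = scan_table(g, cfg, pop_test, pop_refs,
                     chrom_lengths=chrom_lengths, ratio_tail=ratio_tail)
    regions = {
        "ZFST": merge_windows(tbl[tbl["hit_zfst"]], "ZFST", "zfst"),
        "ZHP": merge_windows(tbl[tbl["hit_zhp"]], "ZHP", "zhp"),
        "PI_RATIO": merge_windows(tbl[tbl["hit_pi_ratio"]], "PI_RATIO",
                                  "ln_pi_ratio"),
    }
    out = {"table": tbl, "regions": regions}
    if genes is not None:
        hits = {m: annotate_regions(regions[m], genes) for m in regions}
        out["hits"] = hits
        out["intersection"] = intersect_methods(hits)
    return out
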