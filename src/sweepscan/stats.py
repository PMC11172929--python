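"""Windowed population-genetic statistics.

Implements the per-site primitives (site heterozygosity, Weir & Cockerham
1984 variance components) and the sliding-window statistics built on them:

* nucleotide diversity pi, per bp of window span;
* weighted Weir-Cockerham F_ST (ratio of summed variance components);
* pooled heterozygosity Hp = 2*sum(n_maj)*sum(n_min) / (sum(n_maj)+sum(n_min))^2;
* Tajima's D with the standard a1/a2/b1/b2/c1/c2/e1/e2 constants.

All statistics use per-site called allele counts; missing genotypes reduce
the per-site sample size and are never imputed.  Windows are 0-based
half-open.  Windows with fewer than ``min_snps_per_window`` SNPs carry NaN
for the affected statistics and are excluded from downstream Z-score
distributions rather than contributing noise-driven extremes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix

__all__ = [
    "Window", "ScanConfig", "make_windows",
    "site_pi", "window_pi", "wc_fst_site", "windowed_fst",
    "pairwise_fst_matrix", "hp_window", "tajimas_d",
    "window_stats_table",
]


@dataclass(frozen=True)
class Window:
    """A genomic window, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty window [{self.start}, {self.end})")

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ScanConfig:
    """Sliding-window and tail parameters for the genome scan.

    Defaults: 100 kb windows advanced by 50 kb (overlapping), empirical
    0.5% tails, at least 10 SNPs per window.
    """

    window_size: int = 100_000
    step: int = 50_000
    tail_fraction: float = 0.005
    min_snps_per_window: int = 10

    def __post_init__(self):
        if not (0 < self.step <= self.window_size):
            raise ValueError("require 0 < step <= window_size")
        if not (0.0 < self.tail_fraction < 0.5):
            raise ValueError("tail_fraction must be in (0, 0.5)")
        if self.min_snps_per_window < 1:
            raise ValueError("min_snps_per_window must be >= 1")


def make_windows(chrom_lengths: dict, cfg: ScanConfig) -> list:
    """Sliding windows over every contig.

    Starts are 0, step, 2*step, ...; each end is clipped to the contig
    length, so trailing windows may be partial (``span < window_size``).
    """
    windows = []
    for chrom, length in chrom_lengths.items():
        if length < 1:
            raise ValueError(f"contig {chrom!r} has length {length}")
        start = 0
        while start < length:
            windows.append(
                Window(chrom, start, min(start + cfg.window_size, length))
            )
            start += cfg.step
    return windows


# ---------------------------------------------------------------------------
# per-site primitives


def site_pi(alt_count, called_haplotypes):
    """Mean pairwise difference at one site: c_ref*c_alt / C(n, 2).

    Accepts scalars or arrays; returns NaN where fewer than two haplotypes
    were called.
    """
    alt = np.asarray(alt_count, dtype=np.float64)
    n = np.asarray(called_haplotypes, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(n >= 2, alt * (n - alt) / (n * (n - 1) / 2.0), np.nan)
    if np.ndim(alt_count) == 0 and np.ndim(called_haplotypes) == 0:
        return float(out)
    return out


def _pop_counts(geno: np.ndarray) -> tuple:
    """(called diploids, alt allele count, het count) per site for one pop."""
    called = geno != MISSING
    n_called = called.sum(axis=0)
    alt = np.where(called, geno, 0).sum(axis=0)
    het = (geno == 1).sum(axis=0)
    return n_called, alt, het


def wc_fst_site(counts_pop1, counts_pop2):
    """Weir & Cockerham (1984) variance components for two populations.

    Each ``counts_pop*`` is a triple ``(n_called_diploids, alt_count,
    het_count)`` of scalars or aligned arrays.  Returns ``(a, b, c)``: the
    among-population, among-individual-within-population and
    within-individual components.  Sites where either population has no
    called genotype, or where the mean sample size is 1 (the components are
    undefined), yield NaN in all three.

    The single-site estimate is theta = a / (a + b + c); the windowed
    estimator sums components before dividing.
    """
    n1, alt1, het1 = (np.asarray(x, dtype=np.float64) for x in counts_pop1)
    n2, alt2, het2 = (np.asarray(x, dtype=np.float64) for x in counts_pop2)
    r = 2.0
    nbar = (n1 + n2) / r
    valid = (n1 >= 1) & (n2 >= 1) & (nbar > 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = alt1 / (2.0 * n1)
        p2 = alt2 / (2.0 * n2)
        h1 = het1 / n1
        h2 = het2 / n2
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1.0 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0)
            / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar) - (r - 1.0) / r * s2
            - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
    a = np.where(valid, a, np.nan)
    b = np.where(valid, b, np.nan)
    c = np.where(valid, c, np.nan)
    if np.ndim(counts_pop1[0]) == 0 and np.ndim(counts_pop2[0]) == 0:
        return float(a), float(b), float(c)
    return a, b, c


# ---------------------------------------------------------------------------
# windowed statistics


def window_pi(g: GenotypeMatrix, w: Window, population) -> float:
    """Per-bp nucleotide diversity of one population (or pooled list) in w.

    Sum of per-site mean pairwise differences divided by the window span;
    invariant positions contribute zero through the denominator.  NaN when
    no in-window site has two called haplotypes but sites are present;
    0.0 for a window without SNPs.
    """
    sl = g.site_slice(w.chrom, w.start, w.end)
    geno = g.pop_geno(population)[:, sl]
    if geno.shape[1] == 0:
        return 0.0
    n_called, alt, _ = _pop_counts(geno)
    pi = site_pi(alt, 2 * n_called)
    if np.all(np.isnan(pi)):
        return float("nan")
    return float(np.nansum(pi) / w.span)


def windowed_fst(g: GenotypeMatrix, w: Window, pop_test, pop_ref) -> float:
    """Weighted Weir-Cockerham F_ST over a window: sum(a)/sum(a+b+c).

    Negative values are retained.  NaN when the denominator is zero or no
    site is usable.
    """
    sl = g.site_slice(w.chrom, w.start, w.end)
    gt = g.pop_geno(pop_test)[:, sl]
    gr = g.pop_geno(pop_ref)[:, sl]
    if gt.shape[1] == 0:
        return float("nan")
    a, b, c = wc_fst_site(_pop_counts(gt), _pop_counts(gr))
    num = np.nansum(a)
    den = np.nansum(a + b + c)
    if den == 0 or np.all(np.isnan(a)):
        return float("nan")
    return float(num / den)


def mean_of_ratios_fst(g: GenotypeMatrix, w: Window, pop_test, pop_ref) -> float:
    """Unweighted (mean of per-site theta) F_ST variant, for comparison."""
    sl = g.site_slice(w.chrom, w.start, w.end)
    gt = g.pop_geno(pop_test)[:, sl]
    gr = g.pop_geno(pop_ref)[:, sl]
    if gt.shape[1] == 0:
        return float("nan")
    a, b, c = wc_fst_site(_pop_counts(gt), _pop_counts(gr))
    den = a + b + c
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.where(den != 0, a / den, np.nan)
    if np.all(np.isnan(theta)):
        return float("nan")
    return float(np.nanmean(theta))


def hp_window(g: GenotypeMatrix, w: Window, population) -> float:
    """Pooled heterozygosity of a window in one population.

    Hp = 2 * sum(n_MAJ) * sum(n_MIN) / (sum(n_MAJ) + sum(n_MIN))^2 with the
    sums running over in-window SNPs of per-site major/minor allele counts.
    Bounded by 0 (all sites monomorphic) and 0.5 (every site at 50/50).
    NaN when the window has no called site.
    """
    sl = g.site_slice(w.chrom, w.start, w.end)
    geno = g.pop_geno(population)[:, sl]
    if geno.shape[1] == 0:
        return float("nan")
    n_called, alt, _ = _pop_counts(geno)
    total = 2 * n_called
    use = total > 0
    if not np.any(use):
        return float("nan")
    n_maj = np.maximum(alt, total - alt)[use].sum()
    n_min = np.minimum(alt, total - alt)[use].sum()
    if n_maj + n_min == 0:
        return float("nan")
    return float(2.0 * n_maj * n_min / (n_maj + n_min) ** 2)


def tajima_constants(n: int) -> dict:
    """The a1..e2 constants of Tajima's D for sample size n (haplotypes)."""
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i ** 2 for i in range(1, n))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n ** 2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(g: GenotypeMatrix, w: Window, population) -> float:
    """Tajima's D for one population over a window.

    D = (pi_sum - S/a1) / sqrt(e1*S + e2*S*(S-1)) where pi_sum is the
    un-normalised sum of per-site mean pairwise differences and S the number
    of segregating sites in the population sample.  With missing data the
    per-site called haplotype counts vary; the constants use the rounded
    mean called count over segregating sites.  NaN (flagged) when S < 2,
    n < 4, or the variance term is non-positive.
    """
    sl = g.site_slice(w.chrom, w.start, w.end)
    geno = g.pop_geno(population)[:, sl]
    if geno.shape[1] == 0:
        return float("nan")
    n_called, alt, _ = _pop_counts(geno)
    total = 2 * n_called
    seg = (alt > 0) & (alt < total) & (total >= 2)
    S = int(seg.sum())
    if S < 2:
        return float("nan")
    n = int(round(float(np.mean(total[seg]))))
    if n < 4:
        return float("nan")
    k = tajima_constants(n)
    pi_sum = float(np.nansum(site_pi(alt[seg], total[seg])))
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    if var <= 0:
        return float("nan")
    return float((pi_sum - S / k["a1"]) / math.sqrt(var))


def genome_fst(g: GenotypeMatrix, pop_test, pop_ref) -> float:
    """Genome-wide weighted Weir-Cockerham F_ST: sum(a)/sum(a+b+c) over all
    sites (the single-window estimator applied to the whole genome)."""
    a, b, c = wc_fst_site(_pop_counts(g.pop_geno(pop_test)),
                          _pop_counts(g.pop_geno(pop_ref)))
    den = np.nansum(a + b + c)
    if den == 0:
        return float("nan")
    return float(np.nansum(a) / den)


def pairwise_fst_matrix(g: GenotypeMatrix, populations=None,
                        cfg: ScanConfig = None,
                        chrom_lengths: dict = None) -> pd.DataFrame:
    """Genome-wide mean windowed weighted F_ST for every population pair.

    Symmetric with NaN diagonal.  Pairs involving a population with fewer
    than two samples are skipped (NaN) with a warning.
    """
    import logging
    log = logging.getLogger(__name__)
    if populations is None:
        populations = g.populations()
    if cfg is None:
        cfg = ScanConfig()
    if chrom_lengths is None:
        chrom_lengths = {c: int(g.pos[g.chrom == c].max()) + 1
                         for c in g.chroms()}
    windows = make_windows(chrom_lengths, cfg)
    mat = pd.DataFrame(np.nan, index=populations, columns=populations)
    for i, p1 in enumerate(populations):
        for p2 in populations[i + 1:]:
            if (g.sample_indices(p1).size < 2
                    or g.sample_indices(p2).size < 2):
                log.warning("pairwise_fst_matrix: skipping %s/%s "
                            "(population with < 2 samples)", p1, p2)
                continue
            vals = [windowed_fst(g, w, p1, p2) for w in windows]
            vals = [v for v in vals if not math.isnan(v)]
            if vals:
                m = float(np.mean(vals))
                mat.loc[p1, p2] = m
                mat.loc[p2, p1] = m
    return mat


# ---------------------------------------------------------------------------
# bulk per-window table (single pass, prefix sums)


def window_stats_table(g: GenotypeMatrix, cfg: ScanConfig,
                       pop_test, pop_refs,
                       chrom_lengths: dict = None) -> pd.DataFrame:
    """Per-window statistics table for a test-vs-references contrast.

    Computes, per window: SNP count, pi of the test population, pi of the
    pooled references, weighted WC F_ST (test vs pooled references), pooled
    heterozygosity Hp of the test population, and Tajima's D of the test
    population.  Statistics in windows with fewer than
    ``cfg.min_snps_per_window`` SNPs are set to NaN and the window marked
    ``flagged``.

    This is the bulk engine behind the genome scan; it aggregates the same
    per-site primitives as the single-window functions via prefix sums, so
    the two routes agree to float round-off.
    """
    if chrom_lengths is None:
        chrom_lengths = {c: int(g.pos[g.chrom == c].max()) + 1
                         for c in g.chroms()}
    windows = make_windows(chrom_lengths, cfg)

    gt = g.pop_geno(pop_test)
    gr = g.pop_geno(list(pop_refs) if isinstance(pop_refs, (list, tuple))
                    else pop_refs)

    nt, altt, hett = _pop_counts(gt)
    nr, altr, hetr = _pop_counts(gr)
    tot_t, tot_r = 2 * nt, 2 * nr

    pi_t = site_pi(altt, tot_t)
    pi_r = site_pi(altr, tot_r)
    a, b, c = wc_fst_site((nt, altt, hett), (nr, altr, hetr))
    abc = a + b + c
    n_maj = np.where(tot_t > 0, np.maximum(altt, tot_t - altt), 0)
    n_min = np.where(tot_t > 0, np.minimum(altt, tot_t - altt), 0)
    seg_t = (altt > 0) & (altt < tot_t) & (tot_t >= 2)

    def cum(x):
        return np.concatenate([[0.0], np.cumsum(np.nan_to_num(x))])

    cums = {
        "pi_t": cum(pi_t), "pi_r": cum(pi_r),
        "a": cum(a), "abc": cum(abc),
        "maj": cum(n_maj), "min": cum(n_min),
        "seg": cum(seg_t.astype(float)),
        "seg_n": cum(np.where(seg_t, tot_t, 0).astype(float)),
        "pi_seg": cum(np.where(seg_t, np.nan_to_num(pi_t), 0.0)),
        "ones": cum(np.ones(g.n_sites)),
    }

    rows = []
    for w in windows:
        sl = g.site_slice(w.chrom, w.start, w.end)
        lo, hi = sl.start, sl.stop

        def wsum(key):
            return cums[key][hi] - cums[key][lo]

        n_snps = int(wsum("ones"))
        flagged = n_snps < cfg.min_snps_per_window
        if flagged:
            pi_test = pi_ref = fst = hp = tajd = float("nan")
        else:
            pi_test = wsum("pi_t") / w.span
            pi_ref = wsum("pi_r") / w.span
            den = wsum("abc")
            fst = wsum("a") / den if den != 0 else float("nan")
            smaj, smin = wsum("maj"), wsum("min")
            hp = (2.0 * smaj * smin / (smaj + smin) ** 2
                  if smaj + smin > 0 else float("nan"))
            S = int(wsum("seg"))
            if S < 2:
                tajd = float("nan")
            else:
                n = int(round(wsum("seg_n") / S))
                if n < 4:
                    tajd = float("nan")
                else:
                    k = tajima_constants(n)
                    var = k["e1"] * S + k["e2"] * S * (S - 1)
                    tajd = ((wsum("pi_seg") - S / k["a1"]) / math.sqrt(var)
                            if var > 0 else float("nan"))
        rows.append((w.chrom, w.start, w.end, w.span, n_snps, flagged,
                     pi_test, pi_ref, fst, hp, tajd))
    return pd.DataFrame(rows, columns=[
        "chrom", "start", "end", "span", "n_snps", "flagged",
        "pi_test", "pi_ref", "fst", "hp", "tajd",
    ])
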