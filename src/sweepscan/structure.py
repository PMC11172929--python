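"""Diversity and structure layer: ROH, LD decay, LD pruning, PCA, NJ tree.

Runs of homozygosity are detected with a sliding SNP-window scan in the
style of the common whole-genome callers: a 50-SNP window is "homozygous
eligible" when it contains at most one heterozygote and two missing calls;
a SNP joins a run when more than 5% of the windows covering it are
eligible; final segments must contain at least 50 SNPs, span at least
0.5 Mb and keep a density of one SNP per 50 kb.  Segments are classified
into the three size classes 0.5-1 Mb, 1-2 Mb and >2 Mb.

Linkage disequilibrium is the squared Pearson correlation of unphased
genotype dosages (the composite measure); pruning follows the greedy
window-50 / step-10 / r2 > 0.2 scheme and iterates to a fixed point so that
no surviving pair inside any 50-SNP window of the kept set exceeds the
threshold.

PCA standardises dosages by the Patterson convention (centre by 2*p_hat,
scale by sqrt(2*p_hat*(1-p_hat)), mean-imputing missing calls) and reports
percent variance explained per component.  Sample relationships use
1 - IBS distances and Saitou-Nei neighbour joining with negative branch
lengths clamped to zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ROHParams", "ROHSegment", "LDDecayCurve", "PcaResult", "TreeNode",
    "detect_roh", "summarize_roh", "ld_r2", "ld_decay", "ld_prune",
    "pca", "ibs_distance_matrix", "nj_tree",
    "ROH_CLASSES", "classify_roh_length",
]

ROH_CLASSES = ("0.5-1Mb", "1-2Mb", ">2Mb")


@dataclass(frozen=True)
class ROHParams:
    window_snps: int = 50
    max_het_per_window: int = 1
    max_missing_per_window: int = 2
    hit_fraction: float = 0.05
    min_snps: int = 50
    min_length_bp: int = 500_000
    max_bp_per_snp: int = 50_000   # density: >= 1 SNP per 50 kb


@dataclass(frozen=True)
class ROHSegment:
    sample: str
    chrom: str
    start: int       # bp of first SNP in the run (0-based)
    end: int         # bp one past the last SNP in the run
    n_snps: int
    size_class: str


def classify_roh_length(length_bp: int) -> str:
    """Size class of a run; lengths below 0.5 Mb have no class (None)."""
    if length_bp < 500_000:
        return None
    if length_bp < 1_000_000:
        return ROH_CLASSES[0]
    if length_bp < 2_000_000:
        return ROH_CLASSES[1]
    return ROH_CLASSES[2]


@dataclass
class LDDecayCurve:
    """Mean r^2 per physical-distance bin."""

    bin_edges: np.ndarray      # length n_bins + 1, bp
    mean_r2: np.ndarray        # NaN where a bin has no pairs
    pair_counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "dist_lo": self.bin_edges[:-1],
            "dist_hi": self.bin_edges[1:],
            "mean_r2": self.mean_r2,
            "n_pairs": self.pair_counts,
        })


@dataclass
class PcaResult:
    coords: np.ndarray         # samples x components (unit eigenvectors)
    pct_variance: np.ndarray   # percent of total variance per component
    samples: list

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.coords,
            columns=[f"PC{i + 1}" for i in range(self.coords.shape[1])],
        )
        df.insert(0, "sample", self.samples)
        return df


@dataclass
class TreeNode:
    """Tree node; leaves carry a label, internal nodes children with
    branch lengths to each child."""

    label: str = None
    children: list = field(default_factory=list)  # (TreeNode, length)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list:
        if self.is_leaf():
            return [self.label]
        out = []
        for ch, _ in self.children:
            out.extend(ch.leaves())
        return out

    def to_newick(self) -> str:
        return self._newick() + ";"

    def _newick(self) -> str:
        if self.is_leaf():
            return str(self.label)
        inner = ",".join(f"{ch._newick()}:{ln:.6g}"
                         for ch, ln in self.children)
        return f"({inner})"


# ---------------------------------------------------------------------------
# runs of homozygosity


def detect_roh(g: GenotypeMatrix, sample: str,
               params: ROHParams = ROHParams()) -> list:
    """ROH segments for one sample (see module docstring for the scheme)."""
    si = g.samples.index(sample)
    segments = []
    for chrom in g.chroms():
        on = np.flatnonzero(g.chrom == chrom)
        geno = g.geno[si, on]
        pos = g.pos[on]
        m = geno.size
        w = params.window_snps
        if m < w:
            logger.info("detect_roh: contig %s has %d < %d SNPs, skipped",
                        chrom, m, w)
            continue
        het = (geno == 1).astype(np.int32)
        mis = (geno == MISSING).astype(np.int32)
        # window i covers SNPs [i, i+w); eligibility per window
        chet = np.concatenate([[0], np.cumsum(het)])
        cmis = np.concatenate([[0], np.cumsum(mis)])
        nwin = m - w + 1
        whet = chet[w:] - chet[:-w]
        wmis = cmis[w:] - cmis[:-w]
        ok = ((whet <= params.max_het_per_window)
              & (wmis <= params.max_missing_per_window)).astype(np.int32)
        # SNP j is covered by windows max(0, j-w+1) .. min(j, nwin-1)
        cok = np.concatenate([[0], np.cumsum(ok)])
        j = np.arange(m)
        lo = np.maximum(0, j - w + 1)
        hi = np.minimum(j, nwin - 1)
        n_cov = hi - lo + 1
        n_ok = cok[hi + 1] - cok[lo]
        frac = n_ok / n_cov
        eligible = frac > params.hit_fraction
        # maximal runs of eligible SNPs
        idx = np.flatnonzero(eligible)
        if idx.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [idx.size - 1]])
        # window votes locate candidate runs but blur their edges; the final
        # segment boundaries are taken from the het-free stretch itself: a
        # run is extended outward through non-heterozygous calls, split at
        # any heterozygote inside, and trimmed to homozygous calls
        homozygous = (geno == 0) | (geno == 2)
        compatible = geno != 1        # homozygous or missing
        emitted = set()
        for a, b in zip(starts, ends):
            first, last = idx[a], idx[b]
            while first > 0 and compatible[first - 1]:
                first -= 1
            while last + 1 < m and compatible[last + 1]:
                last += 1
            comp = compatible[first:last + 1]
            sidx = np.flatnonzero(comp)
            if sidx.size == 0:
                continue
            sb = np.flatnonzero(np.diff(sidx) > 1)
            s_starts = np.concatenate([[0], sb + 1])
            s_ends = np.concatenate([sb, [sidx.size - 1]])
            for sa, se in zip(s_starts, s_ends):
                lo, hi = first + sidx[sa], first + sidx[se]
                while lo <= hi and not homozygous[lo]:
                    lo += 1
                while hi >= lo and not homozygous[hi]:
                    hi -= 1
                if hi <= lo or (lo, hi) in emitted:
                    continue
                n_snps = hi - lo + 1
                length = int(pos[hi] - pos[lo]) + 1
                if (n_snps < params.min_snps
                        or length < params.min_length_bp
                        or length / n_snps > params.max_bp_per_snp):
                    continue
                emitted.add((lo, hi))
                segments.append(ROHSegment(
                    sample=sample, chrom=chrom,
                    start=int(pos[lo]), end=int(pos[hi]) + 1,
                    n_snps=int(n_snps),
                    size_class=classify_roh_length(length),
                ))
    return segments


def summarize_roh(segments: list, pop_of: dict = None) -> pd.DataFrame:
    """Per-sample (and, with ``pop_of``, per-population mean) ROH summary.

    Returns a table with one row per sample: counts in each size class and
    the total ROH length; when ``pop_of`` is given, per-population means are
    appended as rows with sample = "<pop>(mean)".
    """
    rows = {}
    for seg in segments:
        r = rows.setdefault(seg.sample,
                            {c: 0 for c in ROH_CLASSES} | {"total_bp": 0})
        r[seg.size_class] += 1
        r["total_bp"] += seg.end - seg.start
    num_cols = [*ROH_CLASSES, "total_bp"]
    df = pd.DataFrame(
        [{"sample": s, **r} for s, r in rows.items()],
        columns=["sample", *num_cols],
    )
    df[num_cols] = df[num_cols].astype(float)
    if pop_of is not None:
        # include samples with zero ROH in the population means
        full = (df.set_index("sample")
                  .reindex(list(pop_of), fill_value=0.0)
                  .astype(float))
        full["pop"] = [pop_of[s] for s in full.index]
        means = full.groupby("pop").mean(numeric_only=True).reset_index()
        means["sample"] = means.pop("pop") + "(mean)"
        df = pd.concat([df, means[df.columns]] if len(df) else
                       [means[df.columns]], ignore_index=True)
    return df


# ---------------------------------------------------------------------------
# linkage disequilibrium


def ld_r2(geno_i, geno_j) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Computed over jointly-called samples; NaN when fewer than two samples
    are jointly called or either site has zero variance among them.
    """
    x = np.asarray(geno_i, dtype=np.float64)
    y = np.asarray(geno_j, dtype=np.float64)
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return float("nan")
    x, y = x[ok], y[ok]
    vx = x.var()
    vy = y.var()
    if vx == 0 or vy == 0:
        return float("nan")
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(cov * cov / (vx * vy))


def _pairwise_r2_block(geno: np.ndarray) -> np.ndarray:
    """r^2 between all column pairs of a (samples x sites) dosage block.

    Missing calls are handled pairwise; entries with <2 joint samples or a
    zero-variance member are NaN.
    """
    G = geno.astype(np.float64)
    M = (geno != MISSING).astype(np.float64)
    G0 = np.where(geno == MISSING, 0.0, G)
    n = M.T @ M
    sx = G0.T @ M
    sy = M.T @ G0
    sxy = G0.T @ G0
    sxx = (G0 * G0).T @ M
    syy = M.T @ (G0 * G0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = sxy / n - (sx / n) * (sy / n)
        vx = sxx / n - (sx / n) ** 2
        vy = syy / n - (sy / n) ** 2
        r2 = cov * cov / (vx * vy)
        r2 = np.where((n >= 2) & (vx > 0) & (vy > 0), r2, np.nan)
    return r2


def ld_decay(g: GenotypeMatrix, population, max_dist: int = 500_000,
             bin_width: int = 1_000, maf_min: float = 0.05) -> LDDecayCurve:
    """Mean r^2 by physical distance for one population.

    All intra-chromosomal site pairs closer than ``max_dist`` are binned by
    distance.  Sites below ``maf_min`` within the population are excluded
    first.  Empty bins carry count 0 and NaN mean.
    """
    geno_all = g.pop_geno(population)
    called = geno_all != MISSING
    nc = called.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(nc > 0, np.where(called, geno_all, 0).sum(axis=0)
                     / (2.0 * nc), 0.0)
    keep = np.minimum(p, 1 - p) > maf_min
    n_bins = int(np.ceil(max_dist / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for chrom in g.chroms():
        on = np.flatnonzero((g.chrom == chrom) & keep)
        pos = g.pos[on]
        geno = geno_all[:, on]
        m = pos.size
        hi = np.searchsorted(pos, pos + max_dist, side="left")
        for i in range(m - 1):
            j0, j1 = i + 1, hi[i]
            if j0 >= j1:
                continue
            d = pos[j0:j1] - pos[i]
            r2 = np.array([ld_r2(geno[:, i], geno[:, j])
                           for j in range(j0, j1)])
            ok = np.isfinite(r2)
            if not np.any(ok):
                continue
            b = np.minimum(d[ok] // bin_width, n_bins - 1).astype(np.int64)
            np.add.at(sums, b, r2[ok])
            np.add.at(counts, b, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return LDDecayCurve(bin_edges=edges, mean_r2=mean, pair_counts=counts)


def ld_prune(g: GenotypeMatrix, window_snps: int = 50, step_snps: int = 10,
             r2_max: float = 0.2) -> np.ndarray:
    """Greedy LD pruning; returns the kept site indices (ascending).

    Sliding windows of ``window_snps`` SNPs advanced by ``step_snps`` over
    the current kept set; within each window, for any pair with
    r^2 > ``r2_max`` the later site is dropped.  Passes repeat until stable,
    so on exit no surviving pair inside any window of the kept sequence
    exceeds the threshold.
    """
    kept = list(range(g.n_sites))
    changed = True
    while changed:
        changed = False
        start = 0
        while start < len(kept):
            win = kept[start:start + window_snps]
            if len(win) >= 2:
                r2 = _pairwise_r2_block(g.geno[:, win])
                drop = set()
                for a in range(len(win)):
                    if a in drop:
                        continue
                    for b in range(a + 1, len(win)):
                        if b in drop:
                            continue
                        if np.isfinite(r2[a, b]) and r2[a, b] > r2_max:
                            drop.add(b)
                if drop:
                    changed = True
                    dropped_ids = {win[b] for b in drop}
                    kept = [i for i in kept if i not in dropped_ids]
            if start + window_snps >= len(kept):
                break
            start += step_snps
    return np.array(kept, dtype=np.intp)


# ---------------------------------------------------------------------------
# PCA / distances / NJ


def pca(g: GenotypeMatrix, n_components: int = 10) -> PcaResult:
    """Genotype PCA with Patterson standardisation.

    Missing dosages are mean-imputed per site; sites centred by 2*p_hat and
    scaled by sqrt(2*p_hat*(1-p_hat)); monomorphic sites dropped.  Returns
    unit-norm sample eigenvectors and percent variance per component
    (non-increasing, summing to <= 100 over the reported components).
    """
    if g.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    G = g.geno.astype(np.float64)
    Ms = g.geno != MISSING
    nc = Ms.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(nc > 0, np.where(Ms, G, 0.0).sum(axis=0) / (2.0 * nc),
                     0.0)
    keep = (p > 0) & (p < 1)
    G, Ms, p = G[:, keep], Ms[:, keep], p[keep]
    mean = 2.0 * p
    G = np.where(Ms, G, mean)                      # mean imputation
    Y = (G - mean) / np.sqrt(2.0 * p * (1.0 - p))  # Patterson scaling
    C = Y @ Y.T / Y.shape[1]
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, None)
    k = min(n_components, g.n_samples)
    total = evals.sum()
    pct = (100.0 * evals[:k] / total if total > 0
           else np.zeros(k))
    # sign convention: largest-magnitude loading positive
    for i in range(k):
        j = np.argmax(np.abs(evecs[:, i]))
        if evecs[j, i] < 0:
            evecs[:, i] = -evecs[:, i]
    return PcaResult(coords=evecs[:, :k], pct_variance=pct,
                     samples=list(g.samples))


def ibs_distance_matrix(g: GenotypeMatrix, level: str = "sample") -> pd.DataFrame:
    """1 - IBS distances between samples or populations.

    IBS between two samples is the mean over jointly-called sites of
    (2 - |dosage_i - dosage_j|) / 2.  Population-level distances average
    the distances over cross-population sample pairs.  A sample pair with
    no jointly-called site is an error.
    """
    if level not in ("sample", "population"):
        raise ValueError("level must be 'sample' or 'population'")
    n = g.n_samples
    G = g.geno.astype(np.float64)
    Ms = (g.geno != MISSING).astype(np.float64)
    D = np.zeros((n, n))
    for i in range(n):
        joint = Ms[i] * Ms[i + 1:]
        nj = joint.sum(axis=1)
        if np.any(nj == 0):
            bad = int(np.flatnonzero(nj == 0)[0]) + i + 1
            raise ValueError(
                f"samples {g.samples[i]} and {g.samples[bad]} share no "
                "called site"
            )
        diff = np.abs(G[i] - G[i + 1:]) * joint
        ibs = ((2.0 - diff) / 2.0 * joint).sum(axis=1) / nj
        D[i, i + 1:] = D[i + 1:, i] = 1.0 - ibs
    if level == "sample":
        return pd.DataFrame(D, index=g.samples, columns=g.samples)
    pops = g.populations()
    P = np.zeros((len(pops), len(pops)))
    for a, p1 in enumerate(pops):
        i1 = g.sample_indices(p1)
        for b in range(a + 1, len(pops)):
            i2 = g.sample_indices(pops[b])
            P[a, b] = P[b, a] = D[np.ix_(i1, i2)].mean()
    return pd.DataFrame(P, index=pops, columns=pops)


def nj_tree(d: pd.DataFrame) -> TreeNode:
    """Saitou-Nei neighbour joining on a symmetric distance matrix.

    Standard Q-criterion agglomeration with the usual branch-length
    formulas; the unrooted result is returned as a trifurcating root.
    Negative branch lengths are clamped to zero (logged).  Exact on
    additive matrices.
    """
    D = np.asarray(d, dtype=np.float64)
    labels = list(d.index)
    if D.shape[0] != D.shape[1] or D.shape[0] < 3:
        raise ValueError("need a square matrix with >= 3 taxa")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0):
        raise ValueError("distance matrix must have a zero diagonal")

    clamped = [0]

    def clamp(x):
        if x < 0:
            clamped[0] += 1
            return 0.0
        return float(x)

    nodes = [TreeNode(label=l) for l in labels]
    active = list(range(len(labels)))
    D = D.copy()
    while len(active) > 3:
        n = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (n - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        ai, aj = np.unravel_index(np.argmin(Q), Q.shape)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (n - 2))
        lj = dij - li
        parent = TreeNode(children=[(nodes[i], clamp(li)),
                                    (nodes[j], clamp(lj))])
        # distances from the new node to the remaining taxa
        dnew = 0.5 * (D[i, :] + D[j, :] - dij)
        D = np.vstack([D, dnew])
        D = np.hstack([D, np.append(dnew, 0.0)[:, None]])
        new_idx = D.shape[0] - 1
        nodes.append(parent)
        active = [x for x in active if x not in (i, j)] + [new_idx]
    i, j, k = active
    li = clamp(0.5 * (D[i, j] + D[i, k] - D[j, k]))
    lj = clamp(0.5 * (D[i, j] + D[j, k] - D[i, k]))
    lk = clamp(0.5 * (D[i, k] + D[j, k] - D[i, j]))
    root = TreeNode(children=[(nodes[i], li), (nodes[j], lj),
                              (nodes[k], lk)])
    if clamped[0]:
        logger.warning("nj_tree: clamped %d negative branch lengths",
                       clamped[0])
    return root
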