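"""Independent brute-force reference implementations used as test oracles.

Everything here is written in plain scalar Python (explicit loops over
haplotype pairs, per-site arithmetic, direct summation of constants) so
that it shares no code path with the package's vectorised implementations.
"""

from __future__ import annotations

import math
import random

MISSING = -1


def haplotypes_of_site(dosages):
    """Expand one site's diploid dosages into a haplotype list (0/1)."""
    hap = []
    for g in dosages:
        if g == MISSING:
            continue
        hap.extend([1] * int(g) + [0] * (2 - int(g)))
    return hap


def brute_site_pi(dosages):
    """Mean pairwise difference at one site by enumerating haplotype pairs."""
    hap = haplotypes_of_site(dosages)
    n = len(hap)
    if n < 2:
        return float("nan")
    diff = 0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            pairs += 1
            if hap[i] != hap[j]:
                diff += 1
    return diff / pairs


def brute_window_pi(geno_rows, positions, start, end):
    """Per-bp pi over [start, end): sum of site pi / span."""
    total = 0.0
    any_site = False
    any_valid = False
    for j, p in enumerate(positions):
        if not (start <= p < end):
            continue
        any_site = True
        v = brute_site_pi([row[j] for row in geno_rows])
        if not math.isnan(v):
            any_valid = True
            total += v
    if not any_site:
        return 0.0
    if not any_valid:
        return float("nan")
    return total / (end - start)


def site_counts(dosages):
    """(called diploids, alt alleles, het count) for one site."""
    n = alt = het = 0
    for g in dosages:
        if g == MISSING:
            continue
        n += 1
        alt += int(g)
        if g == 1:
            het += 1
    return n, alt, het


def brute_wc_components(dos1, dos2):
    """Weir-Cockerham (1984) a, b, c for one site, two populations."""
    n1, alt1, het1 = site_counts(dos1)
    n2, alt2, het2 = site_counts(dos2)
    nbar = (n1 + n2) / 2.0
    if n1 < 1 or n2 < 1 or nbar <= 1:
        return float("nan"), float("nan"), float("nan")
    r = 2.0
    p1 = alt1 / (2.0 * n1)
    p2 = alt2 / (2.0 * n2)
    h1 = het1 / n1
    h2 = het2 / n2
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1.0)
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
    return a, b, c


def brute_windowed_fst(geno1_rows, geno2_rows, positions, start, end):
    """Ratio-of-sums WC F_ST over sites of [start, end)."""
    num = den = 0.0
    any_valid = False
    for j, p in enumerate(positions):
        if not (start <= p < end):
            continue
        a, b, c = brute_wc_components([row[j] for row in geno1_rows],
                                      [row[j] for row in geno2_rows])
        if math.isnan(a):
            continue
        any_valid = True
        num += a
        den += a + b + c
    if not any_valid or den == 0:
        return float("nan")
    return num / den


def brute_hp(geno_rows, positions, start, end):
    """Pooled heterozygosity: 2*sum(maj)*sum(min)/(sum(maj)+sum(min))^2."""
    smaj = smin = 0
    any_site = False
    for j, p in enumerate(positions):
        if not (start <= p < end):
            continue
        n, alt, _ = site_counts([row[j] for row in geno_rows])
        if n == 0:
            continue
        any_site = True
        total = 2 * n
        smaj += max(alt, total - alt)
        smin += min(alt, total - alt)
    if not any_site or smaj + smin == 0:
        return float("nan")
    return 2.0 * smaj * smin / (smaj + smin) ** 2


def brute_tajimas_d(geno_rows, positions, start, end):
    """Tajima's D with constants from direct summation."""
    seg = []
    for j, p in enumerate(positions):
        if not (start <= p < end):
            continue
        n, alt, _ = site_counts([row[j] for row in geno_rows])
        total = 2 * n
        if total >= 2 and 0 < alt < total:
            seg.append(j)
    S = len(seg)
    if S < 2:
        return float("nan")
    mean_n = sum(2 * site_counts([row[j] for row in geno_rows])[0]
                 for j in seg) / S
    n = int(round(mean_n))
    if n < 4:
        return float("nan")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / (i * i) for i in range(1, n))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    pi_sum = sum(brute_site_pi([row[j] for row in geno_rows]) for j in seg)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return float("nan")
    return (pi_sum - S / a1) / math.sqrt(var)


# ---------------------------------------------------------------------------
# random additive trees for NJ recovery


def random_additive_tree(n_taxa, rng: random.Random):
    """Random binary tree over taxa t0..t{n-1} with positive branch lengths.

    Returns (edges, leaf names): edges as (node_a, node_b, length) with
    internal nodes named i0, i1, ...  Built by sequential random joining.
    """
    leaves = [f"t{i}" for i in range(n_taxa)]
    nodes = list(leaves)
    edges = []
    next_internal = 0
    while len(nodes) > 1:
        a = nodes.pop(rng.randrange(len(nodes)))
        b = nodes.pop(rng.randrange(len(nodes)))
        parent = f"i{next_internal}"
        next_internal += 1
        edges.append((parent, a, rng.uniform(0.1, 2.0)))
        edges.append((parent, b, rng.uniform(0.1, 2.0)))
        nodes.append(parent)
    return edges, leaves


def tree_distance_matrix(edges, leaves):
    """Pairwise path lengths between leaves of an edge list."""
    adj = {}
    for a, b, ln in edges:
        adj.setdefault(a, []).append((b, ln))
        adj.setdefault(b, []).append((a, ln))
    dist = {}
    for src in leaves:
        seen = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, ln in adj[u]:
                if v not in seen:
                    seen[v] = seen[u] + ln
                    stack.append(v)
        for dst in leaves:
            dist[(src, dst)] = seen[dst]
    return dist


def newick_tree_distances(node, acc=None, depth=0.0, out=None):
    """Leaf-pair path distances of a sweepscan TreeNode."""
    # collect (leaf, depth) per subtree, combine at each internal node
    out = {} if out is None else out

    def collect(nd, d):
        if nd.is_leaf():
            return [(nd.label, d)]
        pairs = []
        below = []
        for ch, ln in nd.children:
            below.append(collect(ch, d + ln))
        for i in range(len(below)):
            for j in range(i + 1, len(below)):
                for la, da in below[i]:
                    for lb, db in below[j]:
                        out[frozenset((la, lb))] = (da - d) + (db - d)
        return [x for sub in below for x in sub]

    collect(node, 0.0)
    return out
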