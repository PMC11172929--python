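"""Synthetic genotype data with known structure and planted sweeps.

Two generators cover the two kinds of signal the downstream statistics need:

* :func:`simulate_balding_nichols` — a fast frequency model in which each
  population's allele frequency is Beta-distributed around an ancestral
  frequency with variance ``F * p * (1 - p)``.  ``F`` is the expected
  Weir-Cockerham F_ST, so the generator provides closed-form divergence for
  estimator-recovery tests.

* :func:`simulate_wright_fisher` — a mechanistic forward model: stationary
  neutral standing variation (population frequency spectrum proportional to
  1/i), per-generation binomial resampling of every site's frequency in each
  population after the split, new mutations entering at 1/(2N), and an
  optional hard sweep in a designated test population.  The sweep trajectory
  follows p' = p (1+s) / (1 + p s) with binomial noise, conditioned on
  fixation by restarting (capped budget); at fixation, linked neutral sites
  hitchhike: a site at distance d escapes the sweep with probability
  1 - exp(-(r d / s) * ln(2N)) and is otherwise dragged to fixation or loss
  of the allele that rode the sweeping haplotype (probability equal to its
  frequency).  This produces the diversity trough, F_ST peak and pooled-
  heterozygosity deficit that the scan is meant to detect.

Every run is fully determined by ``SimParams.seed``.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np

from .io import MISSING, GenotypeMatrix

__all__ = [
    "SweepParams", "SimParams", "SimTruth", "SimulationError",
    "simulate_balding_nichols", "simulate_wright_fisher", "emit_fixture",
]


class SimulationError(RuntimeError):
    """Raised when a simulation cannot satisfy its own contract."""


@dataclass(frozen=True)
class SweepParams:
    """A hard sweep planted in one test population.

    position is in bp on the simulated chromosome; ``s`` is the selection
    coefficient of the beneficial allele; ``test_pop`` indexes the swept
    population; ``max_restarts`` caps the rejection budget used to condition
    the trajectory on fixation.
    """

    position: int
    s: float = 0.1
    test_pop: int = 0
    max_restarts: int = 1000

    def __post_init__(self):
        if self.s < 0:
            raise ValueError("selection coefficient s must be >= 0")


@dataclass(frozen=True)
class SimParams:
    """Parameters shared by both generators.

    The defaults mirror the study design this package targets: three
    populations of 10 diploid individuals each (one test, two reference
    breeds).  ``fst_target`` defaults to 0.12, the order of differentiation
    between a zebu test breed and a Sanga reference; ``pop_size_N`` and
    ``mutation_rate`` are rescaled so that theta = 4*N*mu per bp stays at a
    realistic 1e-4 while generations remain cheap to iterate.
    """

    n_pops: int = 3
    samples_per_pop: int = 10
    chrom_length: int = 5_000_000
    chrom: str = "1"
    n_snps: int = 10_000            # Balding-Nichols mode only
    fst_target: float = 0.12        # Balding-Nichols divergence F
    pop_size_N: int = 100           # Wright-Fisher diploid population size
    mutation_rate: float = 2.5e-7   # per bp per generation (rescaled)
    recomb_rate: float = 1e-8       # per bp per generation
    split_gen: int = 20             # generations since the populations split
    sweep: SweepParams = None
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.fst_target < 1.0):
            raise ValueError("fst_target must be in [0, 1)")
        if self.n_snps > self.chrom_length:
            raise ValueError("n_snps cannot exceed chrom_length")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.sweep is not None and not (
                0 <= self.sweep.position < self.chrom_length):
            raise ValueError("sweep position outside the chromosome")
        if self.pop_size_N < 2:
            raise ValueError("pop_size_N must be >= 2")
        if self.split_gen < 0:
            raise ValueError("split_gen must be >= 0")


@dataclass
class SimTruth:
    """Planted ground truth recorded alongside a simulated dataset."""

    seed: int
    fst_target: float = None
    sweep_interval: tuple = None      # (start, end) bp, 0-based half-open
    sweep_position: int = None
    ancestral_freqs: np.ndarray = None
    mode: str = ""

    def to_json(self) -> str:
        d = {
            "mode": self.mode,
            "seed": self.seed,
            "fst_target": self.fst_target,
            "sweep_interval": (list(self.sweep_interval)
                               if self.sweep_interval else None),
            "sweep_position": self.sweep_position,
        }
        return json.dumps(d, indent=2)


def _pop_labels(params: SimParams) -> tuple:
    pops = [f"pop{i}" for i in range(params.n_pops)]
    samples, pop_of = [], {}
    for p in pops:
        for j in range(params.samples_per_pop):
            s = f"{p}_ind{j}"
            samples.append(s)
            pop_of[s] = p
    return samples, pop_of


def _unique_positions(rng, n, length) -> np.ndarray:
    """n distinct, sorted 0-based positions drawn uniformly on [0, length)."""
    if n > length:
        raise ValueError("more sites than base pairs")
    if n > length // 2:
        pos = rng.choice(length, size=n, replace=False)
    else:
        pos = np.unique(rng.integers(0, length, size=int(n * 1.2) + 16))
        while pos.size < n:
            extra = rng.integers(0, length, size=n)
            pos = np.unique(np.concatenate([pos, extra]))
        pos = rng.choice(pos, size=n, replace=False)
    pos.sort()
    return pos.astype(np.int64)


def _alleles(rng, n) -> tuple:
    bases = np.array(["A", "C", "G", "T"], dtype=object)
    ref = bases[rng.integers(0, 4, size=n)]
    shift = rng.integers(1, 4, size=n)
    lut = {b: i for i, b in enumerate(bases)}
    alt = bases[(np.array([lut[b] for b in ref]) + shift) % 4]
    return ref, alt


def _sample_genotypes(rng, freqs, samples_per_pop) -> np.ndarray:
    """Binomial(2, p) genotypes: (n_pops*samples_per_pop, n_sites) int8."""
    n_pops, n_sites = freqs.shape
    out = np.empty((n_pops * samples_per_pop, n_sites), dtype=np.int8)
    for k in range(n_pops):
        out[k * samples_per_pop:(k + 1) * samples_per_pop] = rng.binomial(
            2, freqs[k], size=(samples_per_pop, n_sites)
        ).astype(np.int8)
    return out


def _apply_missing(rng, geno, rate) -> np.ndarray:
    if rate > 0:
        mask = rng.random(geno.shape) < rate
        geno = geno.copy()
        geno[mask] = MISSING
    return geno


def _drop_monomorphic(pos, ref, alt, geno, extra=None):
    called = geno != MISSING
    n = called.sum(axis=0)
    ac = np.where(called, geno, 0).sum(axis=0)
    keep = (ac > 0) & (ac < 2 * n)
    out_extra = None if extra is None else extra[keep]
    return pos[keep], ref[keep], alt[keep], geno[:, keep], out_extra


def simulate_balding_nichols(params: SimParams) -> tuple:
    """Balding-Nichols genotypes: (GenotypeMatrix, SimTruth).

    Per site: ancestral frequency p ~ Uniform(0.05, 0.95); each population's
    frequency ~ Beta(p(1-F)/F, (1-p)(1-F)/F) for F > 0 (exactly p at F = 0);
    genotypes ~ Binomial(2, p_pop).  Sites monomorphic in the whole sample
    are dropped (they are not variants).
    """
    rng = np.random.default_rng(params.seed)
    F = params.fst_target
    n = params.n_snps
    pos = _unique_positions(rng, n, params.chrom_length)
    ref, alt = _alleles(rng, n)
    p = rng.uniform(0.05, 0.95, size=n)
    if F == 0.0:
        freqs = np.broadcast_to(p, (params.n_pops, n)).copy()
    else:
        shape1 = p * (1.0 - F) / F
        shape2 = (1.0 - p) * (1.0 - F) / F
        freqs = rng.beta(shape1, shape2, size=(params.n_pops, n))
    geno = _sample_genotypes(rng, freqs, params.samples_per_pop)
    geno = _apply_missing(rng, geno, params.missing_rate)
    pos, ref, alt, geno, p = _drop_monomorphic(pos, ref, alt, geno, p)
    samples, pop_of = _pop_labels(params)
    g = GenotypeMatrix(
        chrom=np.full(pos.size, params.chrom, dtype=object),
        pos=pos, ref=ref, alt=alt, geno=geno,
        samples=samples, pop_of=pop_of,
    )
    truth = SimTruth(seed=params.seed, fst_target=F, ancestral_freqs=p,
                     mode="balding_nichols")
    return g, truth


# ---------------------------------------------------------------------------
# Wright-Fisher forward model


def _stationary_standing_variation(rng, params: SimParams) -> tuple:
    """Positions and frequencies of neutral standing variation.

    At mutation-drift equilibrium the expected number of sites with derived
    count i (of 2N) is theta_L / i, theta_L = 4 N mu L.  Site count is
    Poisson with mean theta_L * sum(1/i); frequencies are i/(2N) with
    probability proportional to 1/i.
    """
    two_n = 2 * params.pop_size_N
    theta_l = 4.0 * params.pop_size_N * params.mutation_rate \
        * params.chrom_length
    weights = 1.0 / np.arange(1, two_n)
    n_sites = rng.poisson(theta_l * weights.sum())
    counts = rng.choice(np.arange(1, two_n), size=n_sites,
                        p=weights / weights.sum())
    pos = _unique_positions(rng, min(n_sites, params.chrom_length),
                            params.chrom_length)
    counts = counts[: pos.size]
    return pos, counts / two_n


def _sweep_trajectory(rng, s: float, two_n: int, max_restarts: int) -> int:
    """Generations to fixation of a beneficial allele, conditioned on
    fixation via restart.  Raises SimulationError when the budget runs out.
    """
    for _ in range(max_restarts):
        p = 1.0 / two_n
        gens = 0
        while 0.0 < p < 1.0:
            p_sel = p * (1.0 + s) / (1.0 + p * s)
            p = rng.binomial(two_n, p_sel) / two_n
            gens += 1
            if gens > 100 * two_n:   # pathological drift; treat as loss
                p = 0.0
        if p == 1.0:
            return gens
    raise SimulationError(
        f"sweep failed to fix within {max_restarts} restarts"
    )


def sweep_halfwidth(params: SimParams) -> int:
    """Distance at which the hitchhiking escape probability reaches 1/2.

    Solves 1 - exp(-(r d / s) ln 2N) = 1/2 for d; sites closer than this are
    more likely dragged than not, so [pos - d, pos + d) is recorded as the
    truth sweep interval.
    """
    s = params.sweep.s
    if s == 0:
        return 0
    log2n = math.log(2 * params.pop_size_N)
    return int(s * math.log(2.0) / (params.recomb_rate * log2n))


def simulate_wright_fisher(params: SimParams) -> tuple:
    """Forward Wright-Fisher simulation: (GenotypeMatrix, SimTruth).

    Stationary standing variation is split into ``n_pops`` daughter
    populations which drift independently for ``split_gen`` generations
    (binomial resampling of every site frequency, new mutations entering at
    1/(2N) each generation under the infinite-sites assumption).  An
    optional hard sweep then runs to fixation in the test population and
    drags linked variation (see module docstring).  Diploid samples are
    drawn at present; sites monomorphic across the whole sample are
    dropped.
    """
    rng = np.random.default_rng(params.seed)
    two_n = 2 * params.pop_size_N

    pos, anc = _stationary_standing_variation(rng, params)
    freqs = np.broadcast_to(anc, (params.n_pops, anc.size)).copy()

    # independent drift after the split + new private mutations
    new_pos, new_freq, new_popidx = [], [], []
    mut_mean = two_n * params.mutation_rate * params.chrom_length
    for _ in range(params.split_gen):
        for k in range(params.n_pops):
            freqs[k] = rng.binomial(two_n, freqs[k]) / two_n
            n_new = rng.poisson(mut_mean)
            if n_new:
                new_pos.append(rng.integers(0, params.chrom_length,
                                            size=n_new))
                new_popidx.append(np.full(n_new, k))
    # private mutations drift from their birth generation onwards; each gets
    # a birth time and is drifted for its remaining generations in one pass
    if new_pos:
        np_pos = np.concatenate(new_pos)
        np_pop = np.concatenate(new_popidx)
        birth = rng.integers(0, max(params.split_gen, 1), size=np_pos.size)
        f = np.full(np_pos.size, 1.0 / two_n)
        remaining = params.split_gen - 1 - birth
        max_rem = int(remaining.max(initial=0))
        for t in range(max_rem):
            active = remaining > t
            f[active] = rng.binomial(two_n, f[active]) / two_n
        alive = f > 0
        np_pos, np_pop, f = np_pos[alive], np_pop[alive], f[alive]
        nf = np.zeros((params.n_pops, np_pos.size))
        nf[np_pop, np.arange(np_pos.size)] = f
        pos = np.concatenate([pos, np_pos])
        freqs = np.concatenate([freqs, nf], axis=1)
        order = np.argsort(pos, kind="stable")
        pos, freqs = pos[order], freqs[:, order]
        pos, uniq_idx = np.unique(pos, return_index=True)
        freqs = freqs[:, uniq_idx]

    truth = SimTruth(seed=params.seed, mode="wright_fisher",
                     ancestral_freqs=anc)

    if params.sweep is not None:
        sw = params.sweep
        _sweep_trajectory(rng, sw.s, two_n, sw.max_restarts)
        k = sw.test_pop
        d = np.abs(pos - sw.position)
        if sw.s > 0:
            escape = 1.0 - np.exp(
                -(params.recomb_rate * d / sw.s) * math.log(two_n)
            )
        else:
            escape = np.ones_like(d, dtype=float)
        # star-like hitchhiking: the allele rode the sweeping haplotype with
        # probability equal to its frequency; the escape fraction of lineages
        # recombines back onto the pre-sweep background, leaving a post-sweep
        # frequency b*(1-e) + e*p -- near-fixed or near-lost close to the
        # sweep (U-shaped spectrum, negative Tajima's D), untouched far away
        rode = (rng.random(pos.size) < freqs[k]).astype(float)
        freqs[k] = rode * (1.0 - escape) + escape * freqs[k]
        # the beneficial site itself: fixed in the test population only
        half = sweep_halfwidth(params)
        truth.sweep_position = int(sw.position)
        truth.sweep_interval = (
            max(0, sw.position - half),
            min(params.chrom_length, sw.position + half),
        )
        ins = int(np.searchsorted(pos, sw.position))
        if ins >= pos.size or pos[ins] != sw.position:
            pos = np.insert(pos, ins, sw.position)
            col = np.zeros((params.n_pops, 1))
            freqs = np.concatenate(
                [freqs[:, :ins], col, freqs[:, ins:]], axis=1)
        freqs[:, int(np.searchsorted(pos, sw.position))] = 0.0
        freqs[k, int(np.searchsorted(pos, sw.position))] = 1.0

    ref, alt = _alleles(rng, pos.size)
    geno = _sample_genotypes(rng, freqs, params.samples_per_pop)
    geno = _apply_missing(rng, geno, params.missing_rate)
    pos, ref, alt, geno, _ = _drop_monomorphic(pos, ref, alt, geno)
    samples, pop_of = _pop_labels(params)
    g = GenotypeMatrix(
        chrom=np.full(pos.size, params.chrom, dtype=object),
        pos=pos, ref=ref, alt=alt, geno=geno,
        samples=samples, pop_of=pop_of,
    )
    return g, truth


# ---------------------------------------------------------------------------
# fixture emission


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(g: GenotypeMatrix, path, contig_lengths: dict = None) -> None:
    """Write the matrix as a minimal VCF 4.2 file (GT only, one ALT)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sweepscan\n")
        for c in g.chroms():
            if contig_lengths and c in contig_lengths:
                fh.write(f"##contig=<ID={c},length={contig_lengths[c]}>\n")
            else:
                fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.samples) + "\n")
        for j in range(g.n_sites):
            calls = "\t".join(_GT_STR[int(v)] for v in g.geno[:, j])
            fh.write(f"{g.chrom[j]}\t{g.pos[j] + 1}\t.\t{g.ref[j]}\t"
                     f"{g.alt[j]}\t.\tPASS\t.\tGT\t{calls}\n")


def make_gene_models(chrom: str, chrom_length: int,
                     truth: SimTruth = None,
                     gene_length: int = 100_000,
                     gene_spacing: int = 300_000):
    """Toy gene set tiled over a chromosome (in-memory GeneModel list).

    Genes of ``gene_length`` bp every ``gene_spacing`` bp, protein-coding,
    plus — when the truth carries a sweep — one gene covering the whole
    sweep interval (named SWEEPGENE) and one lncRNA decoy for biotype
    filters.
    """
    from .io import GeneModel

    genes = []
    i = 0
    start0 = 50_000
    while start0 + gene_length <= chrom_length:
        i += 1
        genes.append(GeneModel(
            gene_id=f"GENE{i:04d}", gene_name=f"GENE{i:04d}",
            biotype="protein_coding", chrom=chrom,
            start=start0 + 1, end=start0 + gene_length,
        ))
        start0 += gene_spacing
    if genes:
        g0 = genes[0]
        genes.append(GeneModel(
            gene_id="LNC0001", gene_name="LNC0001", biotype="lncRNA",
            chrom=chrom, start=g0.start, end=g0.end,
        ))
    if truth is not None and truth.sweep_interval is not None:
        s0, e0 = truth.sweep_interval
        genes.append(GeneModel(
            gene_id="SWEEPGENE", gene_name="SWEEPGENE",
            biotype="protein_coding", chrom=chrom,
            start=int(s0) + 1, end=max(int(e0), int(s0) + 1),
        ))
    return genes


def write_gff3(genes, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gm in genes:
            attrs = (f"ID={gm.gene_id};Name={gm.gene_name};"
                     f"biotype={gm.biotype}")
            fh.write(f"{gm.chrom}\tsweepscan\tgene\t{gm.start}\t{gm.end}"
                     f"\t.\t+\t.\t{attrs}\n")


def emit_fixture(g: GenotypeMatrix, truth: SimTruth, out_dir,
                 chrom_length: int = None) -> dict:
    """Write VCF + population map + toy GFF3 + truth JSON into out_dir.

    Returns {"vcf": ..., "pop_map": ..., "gff3": ..., "truth": ...}.
    """
    os.makedirs(out_dir, exist_ok=True)
    if chrom_length is None:
        chrom_length = int(g.pos.max()) + 1 if g.n_sites else 1
    paths = {
        "vcf": os.path.join(out_dir, "sim.vcf"),
        "pop_map": os.path.join(out_dir, "pops.tsv"),
        "gff3": os.path.join(out_dir, "genes.gff3"),
        "truth": os.path.join(out_dir, "truth.json"),
    }
    write_vcf(g, paths["vcf"],
              contig_lengths={c: chrom_length for c in g.chroms()})
    with open(paths["pop_map"], "w") as fh:
        for s in g.samples:
            fh.write(f"{s}\t{g.pop_of[s]}\n")
    chrom = g.chroms()[0] if g.n_sites else "1"
    write_gff3(make_gene_models(chrom, chrom_length, truth), paths["gff3"])
    with open(paths["truth"], "w") as fh:
        fh.write(truth.to_json() + "\n")
    return paths
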