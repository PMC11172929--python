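"""Variant, annotation and population-map input/output.

The central container is :class:`GenotypeMatrix`: a samples x sites matrix of
alt-allele dosages (0/1/2, ``-1`` for missing) restricted to biallelic SNPs,
with a population label attached to every sample.

Coordinate conventions
----------------------
Internally every position and interval is 0-based, half-open.  VCF and GFF3
are 1-based on disk; the conversion happens only here, at the I/O boundary.
BED output is written 0-based half-open, i.e. identical to the internal
representation.  :class:`GeneModel` is the one deliberate exception: it keeps
the GFF3 1-based inclusive ``start``/``end`` of the source file so that gene
records remain directly comparable with annotation browsers; interval
arithmetic against genes converts on the fly (see ``to_zero_based``).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

#: contig names treated as non-autosomal when ``autosomes_only`` is set.
#: Names are matched verbatim against the VCF header (no "chr" normalisation),
#: case-insensitively for the conventional sex/organelle labels.
NON_AUTOSOMES = {"x", "y", "mt", "m", "chrx", "chry", "chrmt", "chrm"}


class VariantIOError(RuntimeError):
    """Raised for malformed or inconsistent variant/annotation inputs."""


@dataclass
class GenotypeMatrix:
    """Biallelic SNP genotypes for a set of samples with population labels.

    Attributes
    ----------
    chrom : np.ndarray of str, shape (n_sites,)
        Contig of each site.
    pos : np.ndarray of int64, shape (n_sites,)
        0-based site positions, strictly increasing within a contig.
    ref, alt : np.ndarray of str
        Reference and alternate allele per site (single bases).
    geno : np.ndarray of int8, shape (n_samples, n_sites)
        Alt-allele dosage; ``-1`` encodes a missing call.
    samples : list of str
        Ordered sample identifiers (rows of ``geno``).
    pop_of : dict
        Sample id -> population label; defined for every sample.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    geno: np.ndarray
    samples: list
    pop_of: dict

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.geno = np.asarray(self.geno, dtype=np.int8)
        missing_labels = [s for s in self.samples if s not in self.pop_of]
        if missing_labels:
            raise VariantIOError(
                f"samples without population label: {missing_labels}"
            )
        for c in self.chroms():
            p = self.pos[self.chrom == c]
            if p.size > 1 and not np.all(np.diff(p) > 0):
                raise VariantIOError(
                    f"positions not strictly increasing on contig {c!r}"
                )

    @property
    def n_sites(self) -> int:
        return self.pos.size

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def chroms(self) -> list:
        """Contig names in order of first appearance."""
        seen, out = set(), []
        for c in self.chrom:
            if c not in seen:
                seen.add(c)
                out.append(c)
        return out

    def populations(self) -> list:
        seen, out = set(), []
        for s in self.samples:
            p = self.pop_of[s]
            if p not in seen:
                seen.add(p)
                out.append(p)
        return out

    def sample_indices(self, population: str) -> np.ndarray:
        idx = np.array(
            [i for i, s in enumerate(self.samples)
             if self.pop_of[s] == population],
            dtype=np.intp,
        )
        if idx.size == 0:
            raise KeyError(f"no samples in population {population!r}")
        return idx

    def pop_geno(self, population) -> np.ndarray:
        """Genotype rows of one population, or of several pooled (list)."""
        if isinstance(population, (list, tuple)):
            idx = np.concatenate(
                [self.sample_indices(p) for p in population]
            )
        else:
            idx = self.sample_indices(population)
        return self.geno[idx]

    def take_sites(self, selector) -> "GenotypeMatrix":
        """New matrix restricted to a boolean mask or index array of sites."""
        return replace(
            self,
            chrom=self.chrom[selector],
            pos=self.pos[selector],
            ref=self.ref[selector],
            alt=self.alt[selector],
            geno=self.geno[:, selector],
        )

    def site_slice(self, chrom: str, start: int, end: int) -> slice:
        """Index slice of sites falling in [start, end) on ``chrom``.

        Relies on per-contig position sortedness; sites of other contigs are
        excluded by restricting the search to the contig block.
        """
        on = np.flatnonzero(self.chrom == chrom)
        if on.size == 0:
            return slice(0, 0)
        block = slice(on[0], on[-1] + 1)
        p = self.pos[block]
        lo = int(np.searchsorted(p, start, side="left")) + on[0]
        hi = int(np.searchsorted(p, end, side="left")) + on[0]
        return slice(lo, hi)


@dataclass(frozen=True)
class FilterConfig:
    """Site-level filters: pooled MAF and per-site missingness.

    ``maf_min`` is inclusive: a site at exactly the threshold is kept.
    """

    maf_min: float = 0.05
    missing_max: float = 0.10
    autosomes_only: bool = False
    maf_inclusive: bool = True

    def __post_init__(self):
        if not (0.0 <= self.maf_min < 0.5):
            raise ValueError("maf_min must be in [0, 0.5)")
        if not (0.0 <= self.missing_max <= 1.0):
            raise ValueError("missing_max must be in [0, 1]")


@dataclass(frozen=True)
class GeneModel:
    """A gene feature as read from GFF3 (1-based inclusive coordinates)."""

    gene_id: str
    gene_name: str
    biotype: str
    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive

    def __post_init__(self):
        if self.start > self.end:
            raise VariantIOError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    def to_zero_based(self) -> tuple:
        """(start, end) as a 0-based half-open interval."""
        return self.start - 1, self.end


def read_pop_map(path) -> dict:
    """Read a two-column TSV (sample, population) into a dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "pop"],
                     dtype=str, comment="#")
    return dict(zip(df["sample"], df["pop"]))


def read_vcf(path, pop_map_path) -> GenotypeMatrix:
    """Load a VCF into a :class:`GenotypeMatrix`.

    Only biallelic SNP records are retained; multiallelic or non-SNP records
    are skipped and counted.  Half-calls and ``./.`` become missing.  VCF
    positions are converted to the internal 0-based convention.
    """
    from cyvcf2 import VCF

    pop_of = read_pop_map(pop_map_path)
    vcf = VCF(os.fspath(path), gts012=True)
    samples = list(vcf.samples)
    unmapped = [s for s in samples if s not in pop_of]
    if unmapped:
        raise VariantIOError(
            f"VCF samples absent from population map: {unmapped}"
        )

    chroms, poss, refs, alts, rows = [], [], [], [], []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or not rec.is_snp:
            n_skipped += 1
            continue
        # gts012: 0/1/2 = alt dosage, 3 = unknown (covers ./., half-calls)
        g = rec.gt_types.astype(np.int8)
        g[g == 3] = MISSING
        chroms.append(rec.CHROM)
        poss.append(rec.POS - 1)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        rows.append(g)
    vcf.close()
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNP records",
                    n_skipped)
    geno = (np.array(rows, dtype=np.int8).T if rows
            else np.zeros((len(samples), 0), dtype=np.int8))
    return GenotypeMatrix(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        geno=geno,
        samples=samples,
        pop_of={s: pop_of[s] for s in samples},
    )


def site_maf_missing(g: GenotypeMatrix) -> tuple:
    """Per-site pooled minor-allele frequency and missing-call fraction.

    MAF is computed over all non-missing calls pooled across samples; a site
    with no calls gets MAF 0 and missingness 1.
    """
    called = g.geno != MISSING
    n_called = called.sum(axis=0)
    alt = np.where(called, g.geno, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_called > 0, alt / (2.0 * n_called), 0.0)
    maf = np.minimum(p, 1.0 - p)
    miss = 1.0 - n_called / g.n_samples
    return maf, miss


def filter_sites(g: GenotypeMatrix, f: FilterConfig) -> GenotypeMatrix:
    """Apply MAF / missingness / autosome filters; site order is preserved.

    Idempotent: filtering a filtered matrix with the same config is a no-op.
    """
    maf, miss = site_maf_missing(g)
    if f.maf_inclusive:
        keep = maf >= f.maf_min
    else:
        keep = maf > f.maf_min
    keep &= miss <= f.missing_max
    if f.autosomes_only:
        auto = np.array(
            [str(c).lower() not in NON_AUTOSOMES for c in g.chrom]
        )
        keep &= auto
    out = g.take_sites(keep)
    logger.info("filter_sites: kept %d of %d sites", out.n_sites, g.n_sites)
    if out.n_sites == 0:
        logger.warning("filter_sites: all sites removed")
    return out


def read_gff3(path, protein_coding_only: bool = True) -> list:
    """Parse gene features from a GFF3 file into :class:`GeneModel` records.

    By default only genes whose ``biotype`` (or ``gene_biotype``) attribute is
    ``protein_coding`` are returned; pass ``protein_coding_only=False`` for
    all biotypes.  A gene without a biotype attribute is treated as
    protein-coding.
    """
    import gffutils

    db = gffutils.create_db(
        os.fspath(path), ":memory:",
        merge_strategy="create_unique", keep_order=True,
    )
    genes = []
    for feat in db.features_of_type("gene"):
        biotype = (feat.attributes.get("biotype")
                   or feat.attributes.get("gene_biotype")
                   or ["protein_coding"])[0]
        if protein_coding_only and biotype != "protein_coding":
            continue
        name = (feat.attributes.get("Name")
                or feat.attributes.get("gene_name")
                or [feat.id])[0]
        if feat.start is None or feat.end is None or feat.start < 1:
            raise VariantIOError(
                f"malformed coordinates for gene {feat.id} in {path}"
            )
        genes.append(GeneModel(
            gene_id=feat.id, gene_name=name, biotype=biotype,
            chrom=feat.seqid, start=int(feat.start), end=int(feat.end),
        ))
    return genes


def write_bed(regions, path) -> None:
    """Write intervals as BED (0-based half-open).

    ``regions`` is an iterable of objects with ``chrom``/``start``/``end``
    attributes (already in the internal convention) or (chrom, start, end)
    tuples.  An empty iterable produces a valid empty file.
    """
    with open(path, "w") as fh:
        for r in regions:
            if isinstance(r, tuple):
                c, s, e = r[:3]
            else:
                c, s, e = r.chrom, r.start, r.end
            fh.write(f"{c}\t{s}\t{e}\n")


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_outputs(tables: dict = None, trees: dict = None,
                  regions: dict = None, out_dir=".") -> dict:
    """Write result tables (TSV), trees (newick) and regions (BED).

    Each argument maps a basename (without extension) to the object to write.
    Returns {name: path} for everything written.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for name, df in (tables or {}).items():
        p = os.path.join(out_dir, f"{name}.tsv")
        try:
            write_tsv(df, p)
        except OSError as exc:
            raise VariantIOError(f"cannot write table to {p}: {exc}") from exc
        paths[name] = p
        logger.info("wrote table %s", p)
    for name, newick in (trees or {}).items():
        p = os.path.join(out_dir, f"{name}.nwk")
        try:
            with open(p, "w") as fh:
                fh.write(newick.rstrip("\n") + "\n")
        except OSError as exc:
            raise VariantIOError(f"cannot write tree to {p}: {exc}") from exc
        paths[name] = p
        logger.info("wrote tree %s", p)
    for name, regs in (regions or {}).items():
        p = os.path.join(out_dir, f"{name}.bed")
        try:
            write_bed(regs, p)
        except OSError as exc:
            raise VariantIOError(f"cannot write BED to {p}: {exc}") from exc
        paths[name] = p
        logger.info("wrote regions %s", p)
    return paths
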