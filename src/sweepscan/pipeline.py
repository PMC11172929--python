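"""Config-driven orchestration of the full analysis.

Stages, in order: read + filter variants, windowed statistics, selection
scan (Z-scores, empirical tails, region merging, gene annotation,
three-method intersection), diversity (ROH, LD decay) and structure
(LD pruning, PCA, IBS distances, NJ tree).  The run is a pure function of
(inputs, config, seed): rerunning the same configuration reproduces
byte-identical output files; the manifest additionally records a timestamp.
"""

from __future__ import annotations

import difflib
import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .io import (FilterConfig, GenotypeMatrix, filter_sites, read_gff3,
                 read_vcf, write_outputs)
from .scan import run_scan
from .stats import ScanConfig, pairwise_fst_matrix
from .structure import (ROHParams, detect_roh, ibs_distance_matrix, ld_decay,
                        ld_prune, nj_tree, pca, summarize_roh)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    vcf: str
    pop_map: str
    test_pop: str
    ref_pops: list
    gff3: str = None
    out_dir: str = "sweepscan_out"
    seed: int = 0
    filter: FilterConfig = field(default_factory=FilterConfig)
    scan: ScanConfig = field(default_factory=ScanConfig)
    roh: ROHParams = field(default_factory=ROHParams)
    ld_max_dist: int = 500_000
    ld_bin_width: int = 1_000
    pca_components: int = 10
    ratio_tail: str = "lower"
    run_diversity: bool = True
    run_structure: bool = True

    def __post_init__(self):
        if self.test_pop in self.ref_pops:
            raise ConfigError(
                f"test population {self.test_pop!r} also listed as reference"
            )
        if not self.ref_pops:
            raise ConfigError("at least one reference population required")


_SECTION_TYPES = {"filter": FilterConfig, "scan": ScanConfig,
                  "roh": ROHParams}
_TOP_KEYS = {
    "vcf", "pop_map", "gff3", "test_pop", "ref_pops", "out_dir", "seed",
    "filter", "scan", "roh", "ld_max_dist", "ld_bin_width",
    "pca_components", "ratio_tail", "run_diversity", "run_structure",
}


def _check_keys(given, allowed, context):
    for k in given:
        if k not in allowed:
            hint = difflib.get_close_matches(k, allowed, n=1)
            msg = f"unknown key {context}{k!r}"
            if hint:
                msg += f" (did you mean {hint[0]!r}?)"
            raise ConfigError(msg)


def validate_config(raw: dict) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a plain dict (e.g. parsed TOML).

    Defaults are injected for every omitted block (100 kb / 50 kb windows,
    0.5% tails, MAF 0.05, missingness 0.10, the standard ROH and LD
    parameters); unknown keys are rejected with a suggestion.
    """
    _check_keys(raw, _TOP_KEYS, "")
    kwargs = {}
    for key, val in raw.items():
        if key in _SECTION_TYPES:
            cls = _SECTION_TYPES[key]
            fields = set(cls.__dataclass_fields__)
            _check_keys(val, fields, f"{key}.")
            try:
                kwargs[key] = cls(**val)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"in section {key!r}: {exc}") from exc
        else:
            kwargs[key] = val
    for req in ("vcf", "pop_map", "test_pop", "ref_pops"):
        if req not in kwargs:
            raise ConfigError(f"missing required key {req!r}")
    try:
        return PipelineConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path) -> PipelineConfig:
    """Read a TOML configuration file."""
    import tomllib

    with open(path, "rb") as fh:
        return validate_config(tomllib.load(fh))


def _config_hash(cfg: PipelineConfig) -> str:
    canon = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and write all outputs; returns the manifest."""
    os.makedirs(cfg.out_dir, exist_ok=True)
    manifest = {
        "version": __version__,
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
        "outputs": [],
        "complete": False,
    }

    def stage(name):
        logger.info("stage: %s", name)
        return time.perf_counter()

    def done(name, t0, **counts):
        manifest["stages"][name] = {
            "seconds": round(time.perf_counter() - t0, 3), **counts}

    try:
        t0 = stage("read")
        g = read_vcf(cfg.vcf, cfg.pop_map)
        done("read", t0, sites=g.n_sites, samples=g.n_samples)

        t0 = stage("filter")
        g = filter_sites(g, cfg.filter)
        done("filter", t0, sites=g.n_sites)

        genes = read_gff3(cfg.gff3) if cfg.gff3 else None

        t0 = stage("scan")
        scan_out = run_scan(g, cfg.scan, cfg.test_pop, cfg.ref_pops,
                            genes=genes, ratio_tail=cfg.ratio_tail)
        tbl = scan_out["table"]
        done("scan", t0, windows=len(tbl),
             flagged=int(tbl[["hit_zfst", "hit_zhp",
                              "hit_pi_ratio"]].to_numpy().sum()))

        tables = {"window_stats": tbl}
        regions = {f"regions_{m.lower()}": scan_out["regions"][m]
                   for m in scan_out["regions"]}
        trees = {}

        if genes is not None:
            inter = scan_out["intersection"]
            rows = []
            for gid, ms in sorted(inter["methods_of"].items()):
                rows.append({
                    "gene_id": gid,
                    "methods": "&".join(m for m in scan_out["hits"]
                                        if m in ms),
                    "shared": gid in inter["shared"],
                })
            tables["gene_hits"] = pd.DataFrame(
                rows, columns=["gene_id", "methods", "shared"])
            manifest["shared_genes"] = inter["shared"]
            manifest["venn"] = inter["venn"]

        if cfg.run_diversity:
            t0 = stage("diversity")
            segs = []
            for s in g.samples:
                segs.extend(detect_roh(g, s, cfg.roh))
            tables["roh_segments"] = pd.DataFrame(
                [{"sample": x.sample, "chrom": x.chrom, "start": x.start,
                  "end": x.end, "n_snps": x.n_snps, "class": x.size_class}
                 for x in segs],
                columns=["sample", "chrom", "start", "end", "n_snps",
                         "class"])
            tables["roh_summary"] = summarize_roh(segs, g.pop_of)
            curves = []
            for p in g.populations():
                c = ld_decay(g, p, max_dist=cfg.ld_max_dist,
                             bin_width=cfg.ld_bin_width).to_frame()
                c.insert(0, "pop", p)
                curves.append(c)
            tables["ld_decay"] = pd.concat(curves, ignore_index=True)
            done("diversity", t0, roh_segments=len(segs))

        if cfg.run_structure:
            t0 = stage("structure")
            kept = ld_prune(g)
            gp = g.take_sites(kept)
            pc = pca(gp, n_components=cfg.pca_components)
            tables["pca_coords"] = pc.to_frame()
            tables["pca_variance"] = pd.DataFrame({
                "component": [f"PC{i + 1}"
                              for i in range(pc.pct_variance.size)],
                "pct_variance": pc.pct_variance,
            })
            dmat = ibs_distance_matrix(gp, level="population")
            tables["ibs_population"] = dmat.reset_index(names="pop")
            # NJ needs >= 3 taxa; fall back to a sample-level tree when the
            # run has only two populations
            if len(dmat) >= 3:
                trees["nj_populations"] = nj_tree(dmat).to_newick()
            elif gp.n_samples >= 3:
                dsam = ibs_distance_matrix(gp, level="sample")
                trees["nj_samples"] = nj_tree(dsam).to_newick()
            done("structure", t0, pruned_sites=gp.n_sites)

        t0 = stage("fst_matrix")
        fmat = pairwise_fst_matrix(g, cfg=cfg.scan)
        tables["fst_matrix"] = fmat.reset_index(names="pop")
        done("fst_matrix", t0, pairs=int(np.isfinite(
            fmat.to_numpy()).sum() // 2))

        paths = write_outputs(tables=tables, trees=trees, regions=regions,
                              out_dir=cfg.out_dir)
        manifest["outputs"] = sorted(paths.values())
        manifest["complete"] = True
    except Exception as exc:
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        _write_manifest(manifest, cfg.out_dir)
        raise RuntimeError(
            f"pipeline failed in stage {list(manifest['stages'])[-1:]}: {exc}"
        ) from exc
    _write_manifest(manifest, cfg.out_dir)
    return manifest


def _write_manifest(manifest: dict, out_dir) -> None:
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
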