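import numpy as np
import pytest

from sweepscan.io import MISSING, GenotypeMatrix


def random_matrix(rng, n_samples_per_pop=5, n_pops=2, n_sites=30,
                  length=10_000, missing_rate=0.1):
    """Small random GenotypeMatrix for oracle-equivalence tests."""
    n_samples = n_samples_per_pop * n_pops
    pos = np.sort(rng.choice(length, size=n_sites, replace=False))
    geno = rng.integers(0, 3, size=(n_samples, n_sites)).astype(np.int8)
    if missing_rate > 0:
        geno[rng.random(geno.shape) < missing_rate] = MISSING
    samples = [f"s{i}" for i in range(n_samples)]
    pop_of = {s: f"pop{i // n_samples_per_pop}"
              for i, s in enumerate(samples)}
    return GenotypeMatrix(
        chrom=np.full(n_sites, "1", dtype=object),
        pos=pos,
        ref=np.full(n_sites, "A", dtype=object),
        alt=np.full(n_sites, "T", dtype=object),
        geno=geno,
        samples=samples,
        pop_of=pop_of,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def bn_fixture_dir(tmp_path_factory):
    """A small Balding-Nichols dataset written to disk once per session."""
    from sweepscan.simulate import SimParams, emit_fixture, simulate_balding_nichols

    params = SimParams(n_pops=2, samples_per_pop=6, n_snps=400,
                       fst_target=0.1, chrom_length=2_000_000,
                       missing_rate=0.05, seed=42)
    g, truth = simulate_balding_nichols(params)
    out = tmp_path_factory.mktemp("bn_fixture")
    paths = emit_fixture(g, truth, out, chrom_length=params.chrom_length)
    return {"matrix": g, "truth": truth, "params": params, **paths}


@pytest.fixture(scope="session")
def sweep_fixture():
    """A Wright-Fisher dataset with one planted strong sweep (in memory)."""
    from sweepscan.simulate import (SimParams, SweepParams,
                                    simulate_wright_fisher)

    L = 20_000_000
    params = SimParams(n_pops=3, samples_per_pop=10, chrom_length=L,
                       pop_size_N=100, mutation_rate=5e-7, split_gen=20,
                       seed=99, sweep=SweepParams(position=L // 2, s=0.1))
    g, truth = simulate_wright_fisher(params)
    return {"matrix": g, "truth": truth, "params": params}
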