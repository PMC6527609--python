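import numpy as np
import pandas as pd
import pytest

from rpeqtl import simgen
from rpeqtl.io import GenotypeTable


@pytest.fixture(scope="session")
def small_cohort():
    cfg = simgen.SimulationConfig(n_samples=60, n_loci=4, variants_per_locus=15,
                                  seed=101, depth_dispersion=0.02)
    return simgen.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def powered_cohort():
    cfg = simgen.SimulationConfig(n_samples=100, n_loci=6, variants_per_locus=20,
                                  seed=7, depth_dispersion=0.02, ase_depth=80.0)
    return simgen.simulate_cohort(cfg)


def make_genotype_table(haplotypes, chroms=None, positions=None, refs=None, alts=None,
                        ar2=None, samples=None):
    """Build a GenotypeTable from a raw haplotype array with simple defaults."""
    haps = np.asarray(haplotypes, dtype=np.int8)
    n_s, n_v, _ = haps.shape
    variants = pd.DataFrame({
        "variant_id": [f"v{j:04d}" for j in range(n_v)],
        "chrom": chroms if chroms is not None else ["chr1"] * n_v,
        "pos": positions if positions is not None else np.arange(1, n_v + 1) * 100,
        "ref": refs if refs is not None else ["A"] * n_v,
        "alt": alts if alts is not None else ["G"] * n_v,
        "ar2": ar2 if ar2 is not None else np.ones(n_v),
    })
    samples = samples if samples is not None else [f"S{i:03d}" for i in range(n_s)]
    return GenotypeTable(haplotypes=haps, variants=variants, samples=samples)


def random_haplotypes(rng, n_samples, n_variants, maf=0.3):
    return (rng.random((n_samples, n_variants, 2)) < maf).astype(np.int8)
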