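import numpy as np
import pytest

from gwaskit.synthetic import simulate_genotypes, simulate_phenotype, write_fixture_set
from gwaskit.types import MISSING, GenotypeMatrix, make_sample_table, make_variant_table


@pytest.fixture(scope="session")
def toy_bundle(tmp_path_factory):
    """Hand-specified 4-sample x 3-variant fixture bundle on disk."""
    d = tmp_path_factory.mktemp("toy")
    return write_fixture_set(d, "toy4x3", seed=0)


@pytest.fixture(scope="session")
def small_sim():
    """Unstructured 120 x 300 simulation with a 40%-heritable trait."""
    g, variants, samples, labels = simulate_genotypes(120, 300, seed=11)
    pheno, truth = simulate_phenotype(g, n_causal=5, h2=0.4, seed=11)
    return {
        "g": g,
        "variants": variants,
        "samples": samples,
        "y": pheno["value"].to_numpy(),
        "truth": truth,
    }


def random_triple(rng, n, m, missing_frac=0.1):
    """Random valid genotype triple for round-trip tests."""
    dosages = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    mask = rng.random((n, m)) < missing_frac
    dosages[mask] = MISSING
    vids = [f"v{j}" for j in range(m)]
    variants = make_variant_table(
        chrom=[str(1 + j % 3) for j in range(m)],
        variant_id=vids,
        pos=rng.integers(1, 10**6, size=m),
        a1=["A"] * m,
        a2=["T"] * m,
    )
    iids = [f"i{i}" for i in range(n)]
    samples = make_sample_table(iids, iids)
    return GenotypeMatrix(dosages, [(i, i) for i in iids], vids), variants, samples
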