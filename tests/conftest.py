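import numpy as np
import pandas as pd
import pytest

from netpres.preprocess import collapse_probes, harmonize_orthologs
from netpres.preservation import align_test_to_ref
from netpres.synthetic_data import SimConfig, generate_paired_study
from netpres.types import ExpressionMatrix


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        n_genes=600,
        n_samples_ref=150,
        n_samples_test=60,
        module_sizes=(100, 80, 60),
        preserved_flags=(True, True, False),
        loading_range=(0.5, 0.9),
        seed=1,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_paired_study(small_config)


@pytest.fixture(scope="session")
def harmonized(small_study):
    """(ref, test) gene-level matrices on the shared reference gene IDs."""
    ref, _ = collapse_probes(small_study.ref_probes)
    test, _ = collapse_probes(small_study.test_probes)
    ref, test, pairs = harmonize_orthologs(ref, test, small_study.ortholog_map)
    return ref, align_test_to_ref(test, pairs)


def random_expression(n_genes, n_samples, seed=0, species=""):
    rng = np.random.default_rng(seed)
    return ExpressionMatrix(
        pd.DataFrame(
            rng.normal(size=(n_genes, n_samples)),
            index=[f"G{i:04d}" for i in range(n_genes)],
            columns=[f"S{i:03d}" for i in range(n_samples)],
        ),
        species=species,
    )
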