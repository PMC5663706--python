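import pytest

from aepks import SyntheticSpec, generate_cluster, generate_hybrid, generate_integrant


@pytest.fixture(scope="session")
def small_spec():
    return SyntheticSpec(
        n_modules=5, module_aa_length=300, identity_target=0.6,
        hotspot_boost=0.2, seed=11, n_genes=2, name="toy",
    )


@pytest.fixture(scope="session")
def small_cluster(small_spec):
    return generate_cluster(small_spec)


@pytest.fixture(scope="session")
def rap_like_cluster():
    """14-extension-module, 3-gene cluster shaped like the rapamycin PKS."""
    return generate_cluster(
        SyntheticSpec(
            n_modules=14, identity_target=0.6, hotspot_boost=0.2,
            seed=7, n_genes=3, name="raplike",
        )
    )


@pytest.fixture(scope="session")
def deletion_hybrid(small_cluster):
    return generate_hybrid(small_cluster, 1, 4, crossover_frac=0.5)


@pytest.fixture(scope="session")
def small_integrant(small_cluster):
    m2 = small_cluster.module_by_index(2)
    s, _ = m2.nt_interval
    return generate_integrant(
        small_cluster, m2.gene_id, (s + 90, s + 690), seed=3
    )


def native_aa(cluster):
    """Concatenated extension-module translation of the native line."""
    return "".join(m.aa_seq for m in cluster.extension_modules)


def module_nt(cluster, module):
    gene = cluster.gene(module.gene_id)
    s, e = module.nt_interval
    return gene.nt_seq[s:e]
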