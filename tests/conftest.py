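import pytest

from lfsmo.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale cohort: enough structure to exercise every stage quickly."""
    return SimConfig(
        seed=11,
        n_probes=300,
        cohort_sizes=(60, 70, 80),
        n_overlap=40,
        n_planted_meqtl=15,
        n_planted_csce=10,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def classified_small(small_cohort):
    from lfsmo.variants import apply_population_filter, apply_qc_filters, classify_variants

    passed, _ = apply_qc_filters(small_cohort.variants)
    rare, _ = apply_population_filter(passed)
    return classify_variants(
        rare,
        small_cohort.families,
        small_cohort.gene_tiers,
        small_cohort.lof_mechanism_genes,
        small_cohort.class4_support,
    )
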