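import numpy as np
import pytest

from dredgecarbon import (
    SynthConfig,
    build_combined_distribution,
    build_substrate_distributions,
    classify_samples_by_substrate,
    filter_coastal_samples,
    gen_event_table,
    gen_substrate_map_and_coastline,
    gen_toc_library,
)


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down study world: full structure, desk-scale sizes."""
    return SynthConfig(
        seed=20250901,
        n_coastal=600,
        n_sand=400,
        n_coarse=120,
        n_mixed=60,
        n_seagrass=30,
        n_saltmarsh=30,
        n_above_mhw=20,
        n_beyond_5km=40,
        dredging_years=(2000, 2004),
        aggregate_years=(2000, 2004),
        events_per_country_year=3,
        n_hist_ports=24,
        n_hist_both=4,
        n_hist_cost_only=10,
        hist_period=(1883, 1902),
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    """(samples, toc_truth, records, event_truth, substrate_map)."""
    rng = np.random.default_rng(small_config.seed)
    samples, toc_truth = gen_toc_library(small_config, rng)
    records, event_truth = gen_event_table(small_config, rng)
    smap = gen_substrate_map_and_coastline(small_config)
    return samples, toc_truth, records, event_truth, smap


@pytest.fixture(scope="session")
def small_dists(small_world):
    samples, _, _, _, smap = small_world
    coastal, _ = filter_coastal_samples(samples, smap.coastline)
    classified = classify_samples_by_substrate(samples, smap)
    dists = build_substrate_distributions(classified)
    dists["coastal"] = coastal
    dists["combined"] = build_combined_distribution(dists)
    return dists
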