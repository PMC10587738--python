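import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import circadyn as cd
from circadyn.io_formats import CATALOG_COLUMNS

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

SEED = 1437


@pytest.fixture(scope="session")
def sim_config():
    return cd.SimConfig()


@pytest.fixture(scope="session")
def toy_genome(sim_config):
    """Toy genome + annotation built once for the whole session."""
    return cd.build_toy_genome(sim_config, seed=SEED)


@pytest.fixture(scope="session")
def calibrated_config(toy_genome, sim_config):
    genome, annot = toy_genome
    beta, f = cd.calibrate_placement(genome, annot, sim_config, seed=SEED)
    return dataclasses.replace(sim_config, gc_beta=beta, exon_force_frac=f)


@pytest.fixture(scope="session")
def catalog_50k(toy_genome, calibrated_config):
    genome, annot = toy_genome
    return cd.simulate_catalog(genome, annot, calibrated_config, seed=SEED,
                               n_records=50_000, timepoint="pre")


@pytest.fixture(scope="session")
def lengths_100k(sim_config):
    rng = np.random.default_rng(SEED)
    return cd.sample_lengths(sim_config, rng, 100_000)


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort for tests that only need group structure."""
    cfg = cd.SimConfig(n_patients=6, records_per_sample=1000,
                       n_followup=4, n_remission=2)
    return cd.simulate_cohort(cfg, seed=SEED)


def make_catalog(chroms, starts, ends, sample_id="S1",
                 total_mapped_reads=1_000_000, **stat_overrides):
    """Small hand-built catalog with passing detection statistics."""
    n = len(starts)
    df = pd.DataFrame({
        "chrom": chroms if not isinstance(chroms, str) else [chroms] * n,
        "start": starts,
        "end": ends,
        "n_discordant": 5, "n_split": 5, "score": 500.0,
        "mean_cov": 20.0, "sd_cov": 5.0, "start_inc": 0.8, "end_inc": 0.8,
        "uncovered_frac": 0.0,
    })
    for k, v in stat_overrides.items():
        df[k] = v
    return cd.Catalog(sample_id=sample_id, df=df[CATALOG_COLUMNS],
                      total_mapped_reads=total_mapped_reads)
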