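"""Shared fixtures: small study configurations and heavyweight fitted
models reused across the model-recovery and acceptance tests."""

from __future__ import annotations

import warnings
from datetime import date

import numpy as np
import pytest

import fdslink as fl


@pytest.fixture(scope="session")
def small_config() -> fl.SimulationConfig:
    """A compact but fully structured study configuration."""
    return fl.SimulationConfig(
        n_pcps_per_group={"non": 60, "low": 20, "high": 20},
        patients_per_pcp=8,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    """Rosters, claims and cohort for the compact configuration."""
    rng = np.random.default_rng(small_config.seed)
    pcps, patients = fl.generate_rosters(small_config, rng)
    claims = fl.generate_claims(small_config, pcps, patients, rng)
    cohort, counts = fl.build_cohort(
        claims, pcps, rng=rng, interruptive_start=small_config.interruptive_start
    )
    return {
        "config": small_config,
        "pcps": pcps,
        "patients": patients,
        "claims": claims,
        "cohort": cohort,
        "counts": counts,
    }


@pytest.fixture(scope="session")
def diff_in_diff_fit():
    """Large odds-ratio-calibrated cohort and its fitted GEE tier model.

    Group sizes are enlarged so the high-user x interruptive-period cell
    carries enough claims for a tight interaction estimate.
    """
    config = fl.SimulationConfig(
        n_pcps_per_group={"non": 600, "low": 200, "high": 600},
        patients_per_pcp=10,
        seed=5,
    )
    rng = np.random.default_rng(config.seed)
    pcps, patients = fl.generate_rosters(config, rng)
    claims = fl.generate_claims(config, pcps, patients, rng)
    cohort, _ = fl.build_cohort(
        claims, pcps, rng=rng, interruptive_start=config.interruptive_start
    )
    estimates = fl.fit_fds_tier(cohort)
    truth = fl.true_parameters(config)
    return {"config": config, "cohort": cohort, "estimates": estimates, "truth": truth}


@pytest.fixture(scope="session")
def adherence_fit():
    """50k record-level adherence draws and the fitted mixed model."""
    config = fl.SimulationConfig(seed=1)
    rng = np.random.default_rng(11)
    records = fl.generate_adherence_records(config, 50_000, 1000, rng)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        estimates = fl.fit_copay_adherence(records, lam=0.25)
    truth = fl.true_parameters(config)
    return {
        "config": config,
        "records": records,
        "estimates": estimates,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def calibrated_cohort():
    """End-to-end cohort from the generator calibrated to the unadjusted
    percent-preferred table, with cell sizes large enough for +-2pp."""
    config = fl.SimulationConfig(
        n_pcps_per_group={"non": 500, "low": 150, "high": 500},
        patients_per_pcp=40,
        tier_probabilities=fl.tier_cells_from_pooled(),
        seed=9,
    )
    rng = np.random.default_rng(config.seed)
    pcps, patients = fl.generate_rosters(config, rng)
    claims = fl.generate_claims(config, pcps, patients, rng)
    cohort, counts = fl.build_cohort(
        claims, pcps, rng=rng, interruptive_start=config.interruptive_start
    )
    return {"config": config, "cohort": cohort, "counts": counts}


def coverage_replicate(seed: int):
    """One reduced-n replicate for the CI-coverage experiment: simulate a
    small cohort plus adherence records and fit all three links."""
    config = fl.SimulationConfig(
        n_pcps_per_group={"non": 60, "low": 30, "high": 30},
        patients_per_pcp=10,
        interruptive_start=date(2006, 2, 1),
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    pcps, patients = fl.generate_rosters(config, rng)
    claims = fl.generate_claims(config, pcps, patients, rng)
    cohort, _ = fl.build_cohort(
        claims, pcps, rng=rng, interruptive_start=config.interruptive_start
    )
    records = fl.generate_adherence_records(config, 1500, 80, rng)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gee = fl.fit_fds_tier(cohort).fds_tier
        tier_copay = fl.fit_tier_copay(cohort).tier_copay
        adherence = fl.fit_copay_adherence(records, lam=0.25).copay_adherence
    return config, gee, tier_copay, adherence
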