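"""Shared fixtures: reference tables, simulated datasets, recovery study."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.special import ndtr, ndtri

from srcmon.hierarchical import (
    MCMCConfig,
    fit_hierarchical,
    gelman_rubin,
    summarize_posterior,
)
from srcmon.io import load_reference_frequencies
from srcmon.mpt import FrequencyTable, _free_to_probs
from srcmon.simulate import ExperimentConfig, simulate_experiment

#: group-level generating means (unit scale) used for latent-trait recovery
RECOVERY_TRUTH = np.array([0.71, 0.73, 0.48, 0.83, 0.33, 0.75])
RECOVERY_SD = 0.4
RECOVERY_PARTICIPANTS = 40
RECOVERY_ITEMS = 32
RECOVERY_REPLICATES = 40


def simulate_latent_tables(
    mu_unit: np.ndarray,
    heterogeneity_sd: float,
    n_participants: int,
    n_items: int,
    rng: np.random.Generator,
) -> list[FrequencyTable]:
    """Individual 3x3 tables from the probit latent-trait generative model."""
    mu_probit = ndtri(mu_unit)
    tables = []
    for _ in range(n_participants):
        eta = mu_probit + heterogeneity_sd * rng.standard_normal(len(mu_unit))
        P = _free_to_probs(ndtr(eta), "D_N=D_U")
        counts = np.stack([rng.multinomial(n_items, P[t]) for t in range(3)])
        tables.append(FrequencyTable(counts))
    return tables


@pytest.fixture(scope="session")
def reference_tables():
    return load_reference_frequencies()


@pytest.fixture(scope="session")
def full_scale_trials():
    """One full-scale simulated experiment (72 participants per group)."""
    return simulate_experiment(ExperimentConfig(), seed=11)


@pytest.fixture(scope="session")
def recovery_study():
    """Null-model recovery study at the reduced study conditions.

    40 replicates: data simulated from known group means (40 participants,
    32 items per trial type), fitted with the default sampler configuration
    (4 chains, 20,000 iterations, 10,000 burn-in, thin 5).  Returns per
    replicate: the posterior means of Phi(mu), the 95% BCIs, whether each
    BCI covers the generating mean, and the convergence diagnostics.
    """
    results = {
        "est": np.empty((RECOVERY_REPLICATES, 6)),
        "bci": np.empty((RECOVERY_REPLICATES, 6, 2)),
        "cover": np.empty((RECOVERY_REPLICATES, 6), dtype=bool),
        "max_rhat": np.empty(RECOVERY_REPLICATES),
        "truth": RECOVERY_TRUTH,
    }
    for rep in range(RECOVERY_REPLICATES):
        rng = np.random.default_rng(20_000 + rep)
        tables = simulate_latent_tables(
            RECOVERY_TRUTH, RECOVERY_SD, RECOVERY_PARTICIPANTS, RECOVERY_ITEMS, rng
        )
        post = fit_hierarchical(tables, MCMCConfig(seed=rep))
        summ = summarize_posterior(post)
        results["est"][rep] = summ["mean"].to_numpy()
        results["bci"][rep] = summ[["bci_low", "bci_high"]].to_numpy()
        results["cover"][rep] = (
            (results["bci"][rep, :, 0] <= RECOVERY_TRUTH)
            & (RECOVERY_TRUTH <= results["bci"][rep, :, 1])
        )
        results["max_rhat"][rep] = gelman_rubin(post).max_rhat
    return results
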