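"""Shared fixtures; the expensive MCMC fits are session-scoped and reused."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import turnpoint as tp
from turnpoint import MCMCConfig, TimeGrid


@pytest.fixture(scope="session")
def grid8() -> TimeGrid:
    return TimeGrid(range(8))


@pytest.fixture(scope="session")
def fast_cfg() -> MCMCConfig:
    return MCMCConfig(seed=5, n_iter=400, n_burn=200, thin=1)


# ---------------------------------------------------------------------------
# core recovery fixture: 200 genes, T=8, 2 reps, noise 0.1, 25% 4-fold steps
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def core_recovery(grid8):
    truth = tp.simulate_rate_profiles(
        200, grid8, 0.25, 4.0, change_time_index=4, seed=1, base_degradation=0.5
    )
    data, truth = tp.simulate_paired_dataset(truth, grid8, seed=1)
    cfg = MCMCConfig(seed=5, n_iter=1500, n_burn=750, thin=1)
    result = tp.fit_core(data, cfg)
    return truth, data, result


@pytest.fixture(scope="session")
def core_null(grid8):
    truth = tp.simulate_rate_profiles(
        200, grid8, 0.0, 1.0, seed=21, base_degradation=0.5
    )
    data, truth = tp.simulate_paired_dataset(truth, grid8, seed=21)
    cfg = MCMCConfig(seed=5, n_iter=1500, n_burn=750, thin=1)
    result = tp.fit_core(data, cfg)
    return truth, data, result


# ---------------------------------------------------------------------------
# pulsed fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def pulsed_noise_free(grid8):
    """Constant rates, constant mRNA, zero noise: closed-form recovery."""
    truth = tp.simulate_rate_profiles(
        25, grid8, 0.0, 1.0, seed=2,
        base_synthesis=0.02, base_degradation=0.1, base_log_sd=0.0,
    )
    data, truth = tp.simulate_pulsed_dataset(
        truth, grid8, mrna="constant", noise_sd=0.0, seed=2
    )
    result = tp.fit_pulsed(data, MCMCConfig(seed=3, n_iter=600, n_burn=300, thin=1))
    return truth, data, result


@pytest.fixture(scope="session")
def pulsed_noisy(grid8):
    truth = tp.simulate_rate_profiles(
        200, grid8, 0.25, 3.0, change_time_index=4, seed=4, degradation_log_sd=0.4
    )
    data, truth = tp.simulate_pulsed_dataset(truth, grid8, seed=4)
    result = tp.fit_pulsed(data, MCMCConfig(seed=5, n_iter=1500, n_burn=750, thin=1))
    return truth, data, result


# ---------------------------------------------------------------------------
# shared-truth pulsed/total fixture (Fig-5-style design)
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def shared_truth_fits(grid8):
    truth = tp.simulate_rate_profiles(
        200, grid8, 0.25, 4.0, change_time_index=4, seed=1,
        base_synthesis=0.015, base_degradation=0.2,
        base_log_sd=0.7, degradation_log_sd=0.5,
    )
    pdata, truth = tp.simulate_pulsed_dataset(
        truth, grid8, seed=1, new_degrades=True, m0=("steady", 3.0)
    )
    total = tp.derive_total_from_pulsed(pdata)
    cfg = MCMCConfig(seed=1001, n_iter=2000, n_burn=1000, thin=2)
    res_ps = tp.fit_pulsed(pdata, cfg)
    res_r = tp.fit_rates(total, cfg)
    return truth, pdata, total, res_ps, res_r


# ---------------------------------------------------------------------------
# network fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def clique_fits(grid8):
    """20-gene clique sharing a weak change; several below the core threshold."""
    truth = tp.simulate_rate_profiles(
        200, grid8, 0.0, 3.0, change_time_index=4, seed=11,
        base_degradation=0.5, changed_genes=range(20),
    )
    data, truth = tp.simulate_paired_dataset(truth, grid8, noise_sd=0.15, seed=11)
    cfg = MCMCConfig(seed=12, n_iter=1500, n_burn=750, thin=1)
    res_core = tp.fit_core(data, cfg)
    clique = tp.Network(
        [
            (f"g{i:04d}", f"g{j:04d}")
            for i, j in itertools.combinations(range(20), 2)
        ]
    )
    res_net = tp.fit_network(
        data, clique, cfg, params=tp.MRFPriorParams(0.0, 1.0)
    )
    res_empty = tp.fit_network(
        data, tp.Network([]), cfg, params=tp.MRFPriorParams(0.0, 1.0)
    )
    return truth, data, res_core, res_net, res_empty


@pytest.fixture(scope="session")
def star_guard_fits(grid8):
    """Changed genes wired only to null neighbors (disjoint stars)."""
    truth = tp.simulate_rate_profiles(
        200, grid8, 0.0, 4.0, change_time_index=4, seed=11,
        base_degradation=0.5, changed_genes=range(20),
    )
    data, truth = tp.simulate_paired_dataset(truth, grid8, seed=11)
    edges = [
        (f"g{i:04d}", f"g{20 + i * 5 + k:04d}")
        for i in range(20)
        for k in range(5)
    ]
    net = tp.Network(edges)
    cfg = MCMCConfig(seed=12, n_iter=1500, n_burn=750, thin=1)
    res0 = tp.fit_network(data, net, cfg, params=tp.MRFPriorParams(0.0, 0.0))
    res1 = tp.fit_network(data, net, cfg, params=tp.MRFPriorParams(0.0, 1.0))
    return truth, res0, res1


@pytest.fixture(scope="session")
def null_dense_net_fit(core_null, grid8):
    truth, data, _res = core_null
    rng = np.random.default_rng(33)
    G = len(truth.gene_ids)
    edges = [
        (f"g{i:04d}", f"g{j:04d}")
        for i in range(G)
        for j in range(i + 1, G)
        if rng.random() < 0.05
    ]
    cfg = MCMCConfig(seed=12, n_iter=1500, n_burn=750, thin=1)
    return tp.fit_network(data, tp.Network(edges), cfg, params="estimate")


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC (Mann-Whitney), independent of sklearn."""
    from scipy.stats import rankdata

    r = rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    return float(
        (r[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    )
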