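"""Synthetic datasets with known ground-truth rates and change points.

Every model module's recovery property is defined against this generator.
Latent product trajectories follow the interval mass-action update; pulsed
channels accumulate (new protein) and decay (pre-existing protein)
monotonically; measurement noise is multiplicative, Gaussian on the log10
scale (sd 0.1 by default); missingness is at random, capped per replicate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import (
    ExpressionSeries,
    PairedDataset,
    TimeGrid,
    ValidationError,
)
from .pulsed import PulsedDataset, filter_monotone

logger = logging.getLogger("turnpoint")

DEFAULT_NOISE_SD = 0.1  # log10-scale Gaussian sd


@dataclass
class GroundTruth:
    """True per-interval rates plus the planted change points."""

    gene_ids: tuple[str, ...]
    true_synthesis: np.ndarray  # (G, T-1)
    true_degradation: np.ndarray  # (G, T-1)
    change_points: tuple  # per gene: tuple of (boundary idx, rate, direction)
    noise_sd: float
    seed: int

    def __post_init__(self) -> None:
        if np.any(self.true_synthesis <= 0) or np.any(self.true_degradation <= 0):
            raise ValidationError("true rates must be positive")
        n_boundaries = self.true_synthesis.shape[1] - 1
        for gene_cps in self.change_points:
            for idx, rate, _direction in gene_cps:
                if not 1 <= idx <= n_boundaries:
                    raise ValidationError(
                        f"change point index {idx} outside interior range"
                    )
                if rate not in ("synthesis", "degradation"):
                    raise ValidationError(f"unknown rate tag {rate!r}")

    @property
    def changed(self) -> np.ndarray:
        return np.array([len(c) > 0 for c in self.change_points])

    @property
    def log_ratio(self) -> np.ndarray:
        return np.log10(self.true_synthesis / self.true_degradation)


def simulate_rate_profiles(
    n_genes: int,
    grid: TimeGrid,
    frac_changed: float,
    fold_change: float,
    change_time_index="random",
    seed: int = 0,
    rate: str = "synthesis",
    base_synthesis: float = 0.05,
    base_degradation: float = 0.15,
    base_log_sd: float = 0.3,
    degradation_log_sd: float = 0.0,
    noise_sd: float = DEFAULT_NOISE_SD,
    changed_genes=None,
) -> GroundTruth:
    """Piecewise-constant log-rate profiles with planted step changes.

    ``frac_changed`` of the genes carry a single ``fold_change`` step in
    ``rate`` at the given interior boundary index (or a random one);
    ``changed_genes`` may name explicit gene indices instead.
    """
    if not 0 <= frac_changed <= 1:
        raise ValidationError("frac_changed must be in [0, 1]")
    if fold_change <= 0:
        raise ValidationError("fold_change must be positive")
    if rate not in ("synthesis", "degradation"):
        raise ValidationError(f"unknown rate tag {rate!r}")
    T = grid.n_times
    K = T - 1
    if change_time_index != "random":
        if not 1 <= int(change_time_index) <= T - 2:
            raise ValidationError(
                f"change_time_index must be in [1, {T - 2}]"
            )
    rng = np.random.default_rng(seed)
    gene_ids = tuple(f"g{i:04d}" for i in range(n_genes))
    ks = np.power(
        10.0,
        np.log10(base_synthesis) + base_log_sd * rng.normal(size=n_genes),
    )
    synthesis = np.repeat(ks[:, None], K, axis=1)
    kd = np.power(
        10.0,
        np.log10(base_degradation)
        + degradation_log_sd * rng.normal(size=n_genes),
    )
    degradation = np.repeat(kd[:, None], K, axis=1)
    if changed_genes is None:
        n_changed = int(round(frac_changed * n_genes))
        changed_genes = rng.choice(n_genes, size=n_changed, replace=False)
    changed_genes = np.asarray(sorted(int(i) for i in changed_genes))
    change_points: list[tuple] = [() for _ in range(n_genes)]
    direction = 1 if fold_change >= 1 else -1
    for g in changed_genes:
        idx = (
            int(rng.integers(1, T - 1))
            if change_time_index == "random"
            else int(change_time_index)
        )
        target = synthesis if rate == "synthesis" else degradation
        target[g, idx:] *= fold_change
        change_points[g] = ((idx, rate, direction),)
    return GroundTruth(
        gene_ids,
        synthesis,
        degradation,
        tuple(change_points),
        float(noise_sd),
        int(seed),
    )


def _gp_log_trajectories(
    rng: np.random.Generator,
    grid: TimeGrid,
    n_genes: int,
    level: float,
    amplitude: float = 0.15,
    length_scale: float | None = None,
) -> np.ndarray:
    """Smooth random log10 trajectories (GP draws) around a constant level."""
    t = np.asarray(grid.times, float)
    ls = length_scale if length_scale is not None else grid.span / 3.0
    d = np.subtract.outer(t, t)
    K = amplitude**2 * np.exp(-0.5 * (d / ls) ** 2)
    K[np.diag_indices_from(K)] += 1e-10
    L = np.linalg.cholesky(K)
    draws = rng.normal(size=(n_genes, len(t))) @ L.T
    return np.log10(level) + draws


def _mrna_latent(mrna, rng, grid, n_genes, level=100.0):
    if isinstance(mrna, str):
        if mrna == "gp":
            return np.power(10.0, _gp_log_trajectories(rng, grid, n_genes, level))
        if mrna == "constant":
            return np.full((n_genes, grid.n_times), float(level))
        raise ValidationError(f"unknown mrna model {mrna!r}")
    X = np.asarray(mrna, float)
    if X.shape != (n_genes, grid.n_times):
        raise ValidationError("user mRNA curve has wrong shape")
    if np.any(X <= 0):
        raise ValidationError("mRNA curves must be positive")
    return X


def _noisy_series(
    rng: np.random.Generator,
    gene_ids,
    latent: np.ndarray,
    replicates: int,
    noise_sd: float,
    missing_rate: float = 0.0,
    missing_cap: int = 2,
) -> ExpressionSeries:
    """Log-normal measurement noise plus capped missing-at-random cells."""
    G, T = latent.shape
    log_lat = np.log10(latent)
    obs = log_lat[:, :, None] + noise_sd * rng.normal(size=(G, T, replicates))
    mask = np.zeros((G, T, replicates), dtype=bool)
    if missing_rate > 0:
        raw = rng.random((G, T, replicates)) < missing_rate
        for g in range(G):
            for r in range(replicates):
                idx = np.nonzero(raw[g, :, r])[0]
                if idx.size > missing_cap:
                    keep = rng.choice(idx, size=missing_cap, replace=False)
                    sel = np.zeros(T, dtype=bool)
                    sel[keep] = True
                else:
                    sel = raw[g, :, r]
                mask[g, :, r] = sel
    values = np.power(10.0, obs)
    values[mask] = np.nan
    return ExpressionSeries(gene_ids, values, mask, "linear")


def protein_latent(truth: GroundTruth, grid: TimeGrid, X: np.ndarray) -> np.ndarray:
    """Cumulative-sum mass-action trajectory from the truth rates."""
    dh = grid.intervals
    ks, kd = truth.true_synthesis, truth.true_degradation
    if np.any(kd * dh[None, :] >= 1.0):
        raise ValidationError(
            "degradation per interval too fast for the cumulative-sum update"
        )
    G, T = X.shape
    y = np.empty((G, T))
    y[:, 0] = ks[:, 0] * X[:, 0] / kd[:, 0]
    for k in range(T - 1):
        y[:, k + 1] = y[:, k] + dh[k] * (ks[:, k] * X[:, k] - kd[:, k] * y[:, k])
    return y


def simulate_paired_dataset(
    truth: GroundTruth,
    grid: TimeGrid,
    mrna="gp",
    replicates: int = 2,
    noise_sd: float | None = None,
    missing_rate: float = 0.0,
    seed: int | None = None,
    mrna_level: float = 100.0,
) -> tuple[PairedDataset, GroundTruth]:
    """Template + product dataset whose product obeys the truth dynamics."""
    if not 0 <= missing_rate < 0.3:
        raise ValidationError("missing_rate must be in [0, 0.3)")
    noise_sd = truth.noise_sd if noise_sd is None else float(noise_sd)
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    G = len(truth.gene_ids)
    X = _mrna_latent(mrna, rng, grid, G, mrna_level)
    y = protein_latent(truth, grid, X)
    template = _noisy_series(
        rng, truth.gene_ids, X, replicates, noise_sd, missing_rate
    )
    product = _noisy_series(
        rng, truth.gene_ids, y, replicates, noise_sd, missing_rate
    )
    return PairedDataset(template, product, grid), truth


def pulsed_latents(
    truth: GroundTruth,
    grid: TimeGrid,
    X: np.ndarray,
    m0="steady",
    h0_scale: float = 1e-3,
    new_degrades: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Latent new (H, rising) and old (M, falling) channel trajectories.

    ``m0='steady'`` starts the pre-existing pool at its pre-pulse steady
    state k_s X_0 / k_d (a scalar fixes it instead).  With
    ``new_degrades=True`` newly made protein is itself subject to
    first-order decay (physically realistic; the total H + M then follows
    the same mass-action law as a generic protein layer) -- the default
    keeps pure accumulation, matching the pulsed fitting model.
    """
    dh = grid.intervals
    ks, kd = truth.true_synthesis, truth.true_degradation
    G, T = X.shape
    steady = ks[:, 0] * X[:, 0] / kd[:, 0]
    H = np.empty((G, T))
    H[:, 0] = h0_scale * steady
    for k in range(T - 1):
        if new_degrades:
            w = np.exp(-kd[:, k] * dh[k])
            H[:, k + 1] = w * H[:, k] + (1.0 - w) * ks[:, k] * X[:, k] / kd[:, k]
        else:
            H[:, k + 1] = H[:, k] + dh[k] * ks[:, k] * X[:, k]
    if isinstance(m0, str) and m0 == "steady":
        m_start = steady
    elif isinstance(m0, tuple) and m0[0] == "steady":
        m_start = float(m0[1]) * steady
    else:
        m_start = float(m0)
    M = np.empty((G, T))
    M[:, 0] = m_start
    M[:, 1:] = (M[:, 0])[:, None] * np.exp(
        -np.cumsum(kd * dh[None, :], axis=1)
    )
    return H, M


def simulate_pulsed_dataset(
    truth: GroundTruth,
    grid: TimeGrid,
    mrna="gp",
    replicates: int = 2,
    noise_sd: float | None = None,
    seed: int | None = None,
    m0="steady",
    mrna_level: float = 100.0,
    new_degrades: bool = False,
) -> tuple[PulsedDataset, GroundTruth]:
    """Pulsed two-channel dataset: monotone latent H up, M down, plus mRNA."""
    noise_sd = truth.noise_sd if noise_sd is None else float(noise_sd)
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    G = len(truth.gene_ids)
    X = _mrna_latent(mrna, rng, grid, G, mrna_level)
    H, M = pulsed_latents(truth, grid, X, m0=m0, new_degrades=new_degrades)
    new = _noisy_series(rng, truth.gene_ids, H, replicates, noise_sd)
    old = _noisy_series(rng, truth.gene_ids, M, replicates, noise_sd)
    mrna_series = _noisy_series(rng, truth.gene_ids, X, replicates, noise_sd)
    return PulsedDataset(new, old, mrna_series, grid), truth


def derive_total_from_pulsed(pulsed: PulsedDataset) -> PairedDataset:
    """Total product layer H + M paired with the mRNA template."""
    for s in (pulsed.new_channel, pulsed.old_channel, pulsed.mrna):
        if s.scale != "linear":
            raise ValidationError("derive_total_from_pulsed needs linear scale")
    mask = pulsed.new_channel.mask | pulsed.old_channel.mask
    values = np.where(
        mask, np.nan, pulsed.new_channel.values + pulsed.old_channel.values
    )
    total = ExpressionSeries(pulsed.gene_ids, values, mask, "linear")
    return PairedDataset(pulsed.mrna, total, pulsed.grid)


def paper_recipe_dataset(
    n_genes: int,
    grid: TimeGrid,
    seed: int,
    tol: float = 0.05,
    noise_sd: float = DEFAULT_NOISE_SD,
    frac_changed: float = 0.25,
    fold_change: float = 3.0,
    replicates: int = 2,
) -> tuple[PulsedDataset, GroundTruth]:
    """Smooth -> monotone-filter -> add Gaussian (sd 0.1) noise, in that order.

    Mirrors the published synthetic-set construction: smooth monotone
    channels are built first, genes violating the pulse-label direction are
    removed, and log-scale Gaussian noise is added last.
    """
    truth = simulate_rate_profiles(
        n_genes, grid, frac_changed, fold_change, seed=seed, noise_sd=noise_sd
    )
    rng = np.random.default_rng(seed)
    G = len(truth.gene_ids)
    X = _mrna_latent("gp", rng, grid, G)
    H, M = pulsed_latents(truth, grid, X)
    clean = PulsedDataset(
        ExpressionSeries(truth.gene_ids, H[:, :, None], None, "linear"),
        ExpressionSeries(truth.gene_ids, M[:, :, None], None, "linear"),
        ExpressionSeries(truth.gene_ids, X[:, :, None], None, "linear"),
        grid,
    )
    retained, _report = filter_monotone(clean, tol)
    keep = [truth.gene_ids.index(g) for g in retained.gene_ids]
    noisy_new = _noisy_series(rng, retained.gene_ids, H[keep], replicates, noise_sd)
    noisy_old = _noisy_series(rng, retained.gene_ids, M[keep], replicates, noise_sd)
    noisy_mrna = _noisy_series(rng, retained.gene_ids, X[keep], replicates, noise_sd)
    kept_truth = GroundTruth(
        retained.gene_ids,
        truth.true_synthesis[keep],
        truth.true_degradation[keep],
        tuple(truth.change_points[i] for i in keep),
        noise_sd,
        seed,
    )
    return PulsedDataset(noisy_new, noisy_old, noisy_mrna, grid), kept_truth
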