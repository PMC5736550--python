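"""Gaussian-process smoothing and imputation of expression time series.

One squared-exponential GP is fit per gene per replicate on log10
intensities; hyperparameters are shared across all genes within a layer
(short series cannot support per-gene fits) and may be tuned by maximizing
the summed log marginal likelihood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

from .io import ExpressionSeries, TimeGrid, ValidationError

logger = logging.getLogger("turnpoint")

JITTER = 1e-8
NOISE_FLOOR = 1e-6


@dataclass(frozen=True)
class GPHyperparams:
    """Squared-exponential kernel parameters plus observation noise.

    length_scale is in hours; the variances are on squared log10-intensity
    scale.  noise_variance is floored for numerical conditioning.
    """

    length_scale: float
    signal_variance: float
    noise_variance: float

    def __post_init__(self) -> None:
        if not (self.length_scale > 0 and np.isfinite(self.length_scale)):
            raise ValidationError("length_scale must be positive")
        if not (self.signal_variance > 0 and np.isfinite(self.signal_variance)):
            raise ValidationError("signal_variance must be positive")
        if not (self.noise_variance >= 0 and np.isfinite(self.noise_variance)):
            raise ValidationError("noise_variance must be non-negative")

    @property
    def floored_noise(self) -> float:
        return max(self.noise_variance, NOISE_FLOOR)


DEFAULT_HYPERPARAMS = GPHyperparams(
    length_scale=4.0, signal_variance=0.25, noise_variance=0.01
)


@dataclass
class SmoothedSeries:
    """GP posterior mean/sd per gene/time/replicate on log10 scale."""

    gene_ids: tuple[str, ...]
    posterior_mean: np.ndarray  # (G, T, R) log10
    posterior_sd: np.ndarray  # (G, T, R)
    imputed_mask: np.ndarray  # (G, T, R) bool; cells that were missing
    hyperparams: GPHyperparams
    unsmoothable: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if np.any(self.posterior_sd[np.isfinite(self.posterior_sd)] < 0):
            raise ValidationError("negative posterior sd")

    def as_series(self, scale: str = "log") -> ExpressionSeries:
        """Smoothed values as a fully observed ExpressionSeries."""
        out = ExpressionSeries(
            self.gene_ids,
            self.posterior_mean,
            np.zeros(self.posterior_mean.shape, dtype=bool),
            "log",
        )
        return out if scale == "log" else out.to_linear()


def se_kernel(t1: np.ndarray, t2: np.ndarray, hp: GPHyperparams) -> np.ndarray:
    d = np.subtract.outer(np.asarray(t1, float), np.asarray(t2, float))
    return hp.signal_variance * np.exp(-0.5 * (d / hp.length_scale) ** 2)


def fit_gp_curve(
    times: TimeGrid | np.ndarray,
    y: np.ndarray,
    hp: GPHyperparams,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """GP-regression posterior mean and sd at every grid time.

    ``y`` holds log-scale observations; masked entries (mask True, or NaN)
    are treated as unobserved and predicted from the rest.
    """
    t_all = np.asarray(times.times if isinstance(times, TimeGrid) else times, float)
    y = np.asarray(y, float)
    if mask is None:
        mask = ~np.isfinite(y)
    obs = ~np.asarray(mask, bool)
    if not np.all(np.isfinite(y[obs])):
        raise ValidationError("non-finite unmasked observation")
    if obs.sum() < 2:
        raise ValidationError("need at least 2 unmasked points for a GP fit")
    t_o = t_all[obs]
    y_o = y[obs]
    mu = y_o.mean()
    K_oo = se_kernel(t_o, t_o, hp)
    K_oo[np.diag_indices_from(K_oo)] += hp.floored_noise + JITTER
    cho = cho_factor(K_oo, lower=True)
    K_ao = se_kernel(t_all, t_o, hp)
    mean = mu + K_ao @ cho_solve(cho, y_o - mu)
    v = cho_solve(cho, K_ao.T)
    var = hp.signal_variance - np.einsum("ij,ji->i", K_ao, v)
    sd = np.sqrt(np.clip(var, 0.0, None))
    return mean, sd


def log_marginal_likelihood(
    t_obs: np.ndarray, y_obs: np.ndarray, hp: GPHyperparams
) -> float:
    """Marginal likelihood of one centered series under the GP."""
    y = y_obs - y_obs.mean()
    K = se_kernel(t_obs, t_obs, hp)
    K[np.diag_indices_from(K)] += hp.floored_noise + JITTER
    cho = cho_factor(K, lower=True)
    alpha = cho_solve(cho, y)
    logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
    n = y.size
    return float(-0.5 * y @ alpha - 0.5 * logdet - 0.5 * n * np.log(2 * np.pi))


def _collect_log_series(series: ExpressionSeries):
    """Yield (gene index, rep index, log10 values, observed bool) per curve."""
    log_series = series.to_log10()
    vals, mask = log_series.values, log_series.mask
    for g in range(series.n_genes):
        for r in range(series.n_reps):
            yield g, r, vals[g, :, r], ~mask[g, :, r]


def hyperparam_bounds(grid: TimeGrid) -> dict:
    dh = grid.intervals
    return {
        "length_scale": (0.5 * float(dh.min()), 2.0 * grid.span),
        "signal_variance": (1e-4, 10.0),
        "noise_variance": (1e-4, 10.0),
    }


def optimize_hyperparams(
    series: ExpressionSeries,
    grid: TimeGrid,
    min_series: int = 20,
) -> GPHyperparams:
    """Maximize the summed GP log marginal likelihood over bounded search.

    Coarse log-spaced grid followed by an L-BFGS-B polish; falls back to
    defaults with a warning when fewer than ``min_series`` smoothable
    gene-replicate curves are available.
    """
    curves = [
        (np.asarray(grid.times)[obs], y[obs])
        for _, _, y, obs in _collect_log_series(series)
        if obs.sum() >= 2
    ]
    if len(curves) < min_series:
        logger.warning(
            "only %d smoothable series (< %d); falling back to default "
            "hyperparameters",
            len(curves),
            min_series,
        )
        return DEFAULT_HYPERPARAMS
    bounds = hyperparam_bounds(grid)

    def neg_total_lml(log10_params) -> float:
        ls, sf2, sn2 = np.power(10.0, log10_params)
        hp = GPHyperparams(ls, sf2, sn2)
        try:
            return -sum(log_marginal_likelihood(t, y, hp) for t, y in curves)
        except np.linalg.LinAlgError:
            return np.inf

    ls_grid = np.geomspace(*bounds["length_scale"], 8)
    sf_grid = np.geomspace(1e-3, 5.0, 5)
    sn_grid = np.geomspace(1e-4, 1.0, 5)
    best, best_val = None, np.inf
    for ls in ls_grid:
        for sf2 in sf_grid:
            for sn2 in sn_grid:
                val = neg_total_lml(np.log10([ls, sf2, sn2]))
                if val < best_val:
                    best, best_val = (ls, sf2, sn2), val
    x0 = np.log10(best)
    log_bounds = [
        np.log10(bounds["length_scale"]),
        np.log10(bounds["signal_variance"]),
        np.log10(bounds["noise_variance"]),
    ]
    res = minimize(
        neg_total_lml, x0, method="L-BFGS-B", bounds=log_bounds
    )
    if res.success and res.fun <= best_val:
        ls, sf2, sn2 = np.power(10.0, res.x)
    else:
        logger.warning("hyperparameter polish did not converge; using grid best")
        ls, sf2, sn2 = best
    hp = GPHyperparams(float(ls), float(sf2), float(sn2))
    logger.info(
        "gp hyperparams length_scale=%.4g signal_variance=%.4g "
        "noise_variance=%.4g lml=%.4g",
        hp.length_scale,
        hp.signal_variance,
        hp.noise_variance,
        -min(best_val, res.fun if res.success else np.inf),
    )
    return hp


def smooth_series(
    series: ExpressionSeries,
    grid: TimeGrid,
    hp: GPHyperparams | str = "optimize",
) -> SmoothedSeries:
    """Smooth every gene/replicate curve and impute missing cells.

    Missing cells are filled with the posterior mean and flagged in
    ``imputed_mask``.  Genes with fewer than two observed points in some
    replicate are flagged unsmoothable and passed through unchanged; a
    single bad gene never aborts the run.
    """
    if series.n_times != grid.n_times:
        raise ValidationError("series length differs from time grid")
    if isinstance(hp, str):
        if hp != "optimize":
            raise ValidationError(f"unknown hyperparameter mode {hp!r}")
        hp = optimize_hyperparams(series, grid)
    log_series = series.to_log10()
    G, T, R = log_series.values.shape
    mean = np.array(log_series.values, copy=True)
    sd = np.zeros((G, T, R))
    bad_genes: set[str] = set()

    # group curves by observation pattern so the Cholesky factor is shared
    t_all = np.asarray(grid.times, float)
    groups: dict[bytes, list[tuple[int, int]]] = {}
    for g, r, y, obs in _collect_log_series(series):
        if obs.sum() < 2:
            bad_genes.add(series.gene_ids[g])
            continue
        groups.setdefault(obs.tobytes(), []).append((g, r))
    for key, members in groups.items():
        obs = np.frombuffer(key, dtype=bool)
        t_o = t_all[obs]
        K_oo = se_kernel(t_o, t_o, hp)
        K_oo[np.diag_indices_from(K_oo)] += hp.floored_noise + JITTER
        cho = cho_factor(K_oo, lower=True)
        K_ao = se_kernel(t_all, t_o, hp)
        v = cho_solve(cho, K_ao.T)
        var = hp.signal_variance - np.einsum("ij,ji->i", K_ao, v)
        sd_common = np.sqrt(np.clip(var, 0.0, None))
        Y = np.stack(
            [log_series.values[g, obs, r] for g, r in members], axis=1
        )  # (n_obs, n_curves)
        mu = Y.mean(axis=0)
        pred = mu[:, None] + (K_ao @ cho_solve(cho, Y - mu)).T  # (n_curves, T)
        for i, (g, r) in enumerate(members):
            mean[g, :, r] = pred[i]
            sd[g, :, r] = sd_common
    if bad_genes:
        logger.warning(
            "unsmoothable genes (fewer than 2 observed points): %s",
            ",".join(sorted(bad_genes)[:10]),
        )
    return SmoothedSeries(
        gene_ids=series.gene_ids,
        posterior_mean=mean,
        posterior_sd=sd,
        imputed_mask=series.mask.copy(),
        hyperparams=hp,
        unsmoothable=tuple(sorted(bad_genes)),
    )


def plot_gene_fit(
    series: ExpressionSeries,
    smoothed: SmoothedSeries,
    gene_id: str,
    grid: TimeGrid,
    path=None,
):
    """Raw vs smoothed curves for one gene, for visual inspection."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    g = series.gene_ids.index(gene_id)
    log_series = series.to_log10()
    t = np.asarray(grid.times)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for r in range(series.n_reps):
        obs = ~series.mask[g, :, r]
        ax.plot(t[obs], log_series.values[g, obs, r], "o", label=f"rep {r + 1} raw")
        ax.plot(t, smoothed.posterior_mean[g, :, r], "-", alpha=0.8)
        ax.fill_between(
            t,
            smoothed.posterior_mean[g, :, r] - 2 * smoothed.posterior_sd[g, :, r],
            smoothed.posterior_mean[g, :, r] + 2 * smoothed.posterior_sd[g, :, r],
            alpha=0.15,
        )
    ax.set_xlabel("time (h)")
    ax.set_ylabel("log10 intensity")
    ax.set_title(gene_id)
    ax.legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
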