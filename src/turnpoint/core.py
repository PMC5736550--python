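"""Change-point inference on synthesis/degradation rate ratios.

For each gene the product layer follows the interval mass-action update

    E[Y_{t+1}] = E[Y_t] + dh_t * (k_s,t * X_t - k_d * E[Y_t])

with the template level X_t held at its smoothed consensus.  Only the rate
ratio r_t = k_s,t / k_d is identifiable from paired data, so the
degradation rate is fixed internally (to 0.5/max(dh), keeping the update
positive on any grid) and r_t carries the signal.  Change indicators on the
log ratio yield a change-point probability score (CPS) per gene per
interior time point; a pooled Bayesian FDR map converts CPS into a
selection threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._mcmc import MCMCConfig, replicate_sigma2, run_spike_slab
from .io import PairedDataset, ValidationError

logger = logging.getLogger("turnpoint")

__all__ = [
    "MCMCConfig",
    "LatentTrajectory",
    "RateRatioProfile",
    "CPSTable",
    "FDRMap",
    "CoreResult",
    "fit_core",
    "cps_fdr_threshold",
    "consensus_trajectory",
]

#: sentinel returned when no threshold attains the FDR target
NO_THRESHOLD = float(np.nextafter(1.0, 2.0))


@dataclass
class LatentTrajectory:
    """Posterior-mean denoised product concentrations, one curve per gene."""

    gene_ids: tuple[str, ...]
    expected_product: np.ndarray  # (G, T) linear scale

    def __post_init__(self) -> None:
        good = np.isfinite(self.expected_product)
        if np.any(self.expected_product[good] <= 0):
            raise ValidationError("latent trajectory must be strictly positive")


@dataclass
class RateRatioProfile:
    """Posterior-mean synthesis/degradation rate ratios per interval."""

    gene_ids: tuple[str, ...]
    ratio: np.ndarray  # (G, T-1) linear, relative units

    def __post_init__(self) -> None:
        good = np.isfinite(self.ratio)
        if np.any(self.ratio[good] <= 0):
            raise ValidationError("rate ratios must be strictly positive")

    def to_frame(self, times=None) -> pd.DataFrame:
        cols = [f"ratio_{k}" for k in range(self.ratio.shape[1])]
        df = pd.DataFrame(self.ratio, columns=cols)
        df.insert(0, "gene", list(self.gene_ids))
        return df


@dataclass
class CPSTable:
    """Change-point probability scores at interior time points."""

    gene_ids: tuple[str, ...]
    cps: np.ndarray  # (G, T-2) in [0, 1]
    direction: np.ndarray  # (G, T-2) in {-1, +1}

    def __post_init__(self) -> None:
        self.cps = np.asarray(self.cps, float)
        self.direction = np.asarray(self.direction, int)
        good = np.isfinite(self.cps)
        if np.any((self.cps[good] < 0) | (self.cps[good] > 1)):
            raise ValidationError("CPS outside [0, 1]")
        if not np.all(np.isin(self.direction, (-1, 1))):
            raise ValidationError("direction must be -1 or +1")

    @property
    def n_boundaries(self) -> int:
        return self.cps.shape[1]

    def to_frame(self) -> pd.DataFrame:
        data = {"gene": list(self.gene_ids)}
        for j in range(self.n_boundaries):
            data[f"cps_{j + 1}"] = self.cps[:, j]
        for j in range(self.n_boundaries):
            data[f"dir_{j + 1}"] = self.direction[:, j]
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CPSTable":
        cps_cols = [c for c in df.columns if c.startswith("cps_")]
        dir_cols = [c for c in df.columns if c.startswith("dir_")]
        return cls(
            tuple(str(g) for g in df["gene"]),
            df[cps_cols].to_numpy(float),
            df[dir_cols].to_numpy(int),
        )


@dataclass
class FDRMap:
    """Estimated Bayesian FDR at each candidate CPS threshold."""

    thresholds: np.ndarray  # ascending
    fdr: np.ndarray

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, float)
        self.fdr = np.asarray(self.fdr, float)
        if np.any(np.diff(self.thresholds) <= 0):
            raise ValidationError("thresholds must be strictly increasing")
        if np.any(np.diff(self.fdr) > 1e-9):
            raise ValidationError("estimated FDR must be non-increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds, "fdr": self.fdr})


def cps_fdr_threshold(cps, target_fdr: float = 0.05) -> tuple[float, FDRMap]:
    """Smallest CPS cutoff whose Bayesian FDR is within the target.

    For a candidate cutoff c the estimated FDR is mean(1 - s) over all
    scores s >= c; the map over all observed score values is returned
    alongside the selected cutoff.  When no cutoff attains the target a
    sentinel just above 1 is returned so that nothing is selected.
    """
    if not 0 < target_fdr < 1:
        raise ValidationError("target FDR must be in (0, 1)")
    scores = np.asarray(cps.cps if isinstance(cps, CPSTable) else cps, float)
    scores = scores[np.isfinite(scores)].ravel()
    if scores.size == 0:
        raise ValidationError("no CPS scores supplied")
    order = np.argsort(scores)
    s = scores[order]
    # suffix means of (1 - s): FDR at cutting exactly at each unique value
    tail_mean = np.cumsum((1.0 - s)[::-1])[::-1] / np.arange(s.size, 0, -1)
    uniq, first_idx = np.unique(s, return_index=True)
    fdr_at = tail_mean[first_idx]
    fdr_map = FDRMap(uniq, fdr_at) if uniq.size > 1 else FDRMap(
        np.array([uniq[0] - 1e-9, uniq[0]]),
        np.array([fdr_at[0], fdr_at[0]]),
    )
    passing = np.nonzero(fdr_at <= target_fdr)[0]
    if passing.size == 0:
        logger.warning(
            "no CPS threshold attains FDR <= %.3g; returning sentinel", target_fdr
        )
        return NO_THRESHOLD, fdr_map
    return float(uniq[passing[0]]), fdr_map


@dataclass
class CoreResult:
    trajectory: LatentTrajectory
    ratios: RateRatioProfile
    cps: CPSTable
    fdr_threshold: float
    fdr_map: FDRMap
    sigma2: float
    change_prior: np.ndarray  # posterior mean pi_t per boundary
    diverged: tuple[str, ...]
    template: np.ndarray | None = None  # posterior-mean denoised template (G, T)
    coverage: dict | None = None


def _prepare(data: PairedDataset):
    if data.template.mask.any() or data.product.mask.any():
        raise ValidationError(
            "dataset has missing cells; smooth/impute first (gp module)"
        )
    X = data.template.consensus_linear()  # (G, T)
    if np.any(X <= 0):
        raise ValidationError("template layer must be strictly positive")
    product = data.product.to_log10()
    obs_l10 = product.values  # (G, T, R)
    return X, obs_l10


def _core_inputs(data: PairedDataset, cfg: MCMCConfig):
    X, obs_l10 = _prepare(data)
    dh = data.grid.intervals
    kd = 0.5 / float(dh.max())
    a = kd * dh  # (K,), all in (0, 0.5]

    # a constant template (RNA-level mode) is treated as exact; otherwise
    # the denoised template trajectory is a latent state so that template
    # measurement noise cannot masquerade as product rate changes
    tvals = data.template.to_linear().values
    constant_template = bool(
        np.allclose(tvals, tvals[:, :1, :1], rtol=1e-12, atol=0)
    )
    template_obs_l10 = None if constant_template else np.log10(tvals)

    # the trajectory starts at the stationary level r_0 * X_0 (system at
    # equilibrium before the perturbation); a free initial level would let
    # (y_0, r_0) overfit the first two observations and fake changes at the
    # first interior time point
    def _recursion(l0, lk, Xcur):
        y = np.empty((Xcur.shape[0], Xcur.shape[1]))
        r = np.power(10.0, lk)
        y[:, 0] = r[:, 0] * Xcur[:, 0]
        for k in range(len(a)):
            y[:, k + 1] = (1.0 - a[k]) * y[:, k] + a[k] * r[:, k] * Xcur[:, k]
        with np.errstate(divide="ignore"):
            return np.log10(y)

    if constant_template:
        def traj_fn(l0: np.ndarray, lk: np.ndarray) -> np.ndarray:
            return _recursion(l0, lk, X)
    else:
        def traj_fn(l0: np.ndarray, lk: np.ndarray, lx: np.ndarray) -> np.ndarray:
            return _recursion(l0, lk, np.power(10.0, lx))

    ybar = np.power(10.0, obs_l10.mean(axis=2))  # (G, T) consensus of obs
    r_stat = ybar[:, :-1] / X[:, :-1]  # stationary guess per interval
    r_mom = (ybar[:, 1:] - (1.0 - a) * ybar[:, :-1]) / (a * X[:, :-1])
    r_mom = np.where(r_mom > 0, r_mom, r_stat)
    lk_init = np.log10(r_mom)
    sigma2_init = replicate_sigma2(obs_l10)
    init = {
        "l0": np.log10(ybar[:, 0]),
        "lk0": lk_init[:, 0],
        "d": np.diff(lk_init, axis=1),
        "sigma2": sigma2_init,
        "lx": np.log10(X),
    }
    # the initial level is anchored at the first consensus observation with
    # its measurement precision: a diffuse y0 lets (y0, r_0) overfit the
    # first two time points and fake first-boundary changes on null genes
    R = obs_l10.shape[2]
    l0_sd = max(0.02, 2.0 * np.sqrt(sigma2_init / R))
    prior = {
        "l0_mean": np.log10(ybar[:, 0]),
        "l0_sd": l0_sd,
        "lk0_mean": np.log10(ybar.mean(axis=1) / X.mean(axis=1)),
        "lk0_sd": 2.0,
    }
    return obs_l10, traj_fn, init, prior, template_obs_l10


def _assemble(data: PairedDataset, out: dict, target_fdr: float) -> CoreResult:
    gene_ids = data.gene_ids
    direction = np.where(out["mean_zd"] >= 0, 1, -1)
    ties = out["mean_zd"] == 0
    if ties.any():
        logger.warning(
            "%d gene/time direction ties assigned +1", int(ties.sum())
        )
    cps = CPSTable(gene_ids, np.clip(out["cps"], 0.0, 1.0), direction)
    threshold, fdr_map = cps_fdr_threshold(cps, target_fdr)
    diverged = tuple(
        g for g, bad in zip(gene_ids, out["diverged"]) if bad
    )
    if diverged:
        logger.warning("aborted genes (divergent chain): %s", ",".join(diverged))
    return CoreResult(
        trajectory=LatentTrajectory(gene_ids, out["mean_traj"]),
        ratios=RateRatioProfile(gene_ids, out["mean_rate"]),
        cps=cps,
        fdr_threshold=threshold,
        fdr_map=fdr_map,
        sigma2=out["sigma2"],
        change_prior=out["pi"],
        diverged=diverged,
        template=out.get("mean_template"),
    )


def fit_core(
    data: PairedDataset,
    cfg: MCMCConfig,
    target_fdr: float = 0.05,
    adjacency=None,
    beta: float = 0.0,
) -> CoreResult:
    """Fit the rate-ratio change-point model to a paired dataset.

    ``adjacency``/``beta`` switch on the network (MRF) change prior and are
    used by the network module; with the defaults the change prior is the
    shared per-time-point probability estimated across all genes.
    """
    if data.grid.n_times < 3:
        raise ValidationError("need at least 3 time points")
    obs_l10, traj_fn, init, prior, template_obs_l10 = _core_inputs(data, cfg)
    rng = np.random.default_rng(cfg.seed)
    out = run_spike_slab(
        obs_l10,
        traj_fn,
        init,
        prior,
        cfg,
        rng,
        adjacency=adjacency,
        beta=beta,
        template_obs_l10=template_obs_l10,
        sample_l0=False,
    )
    # the reported consensus trajectory is the plug-in reconstruction from
    # the posterior-mean rates and template, so it satisfies the interval
    # mass-action equation exactly
    Xbar = (
        out["mean_template"]
        if out.get("mean_template") is not None
        else data.template.consensus_linear()
    )
    dh = data.grid.intervals
    kd = 0.5 / float(dh.max())
    a = kd * dh
    rbar = out["mean_rate"]
    y = np.empty(Xbar.shape)
    y[:, 0] = rbar[:, 0] * Xbar[:, 0]
    for k in range(len(a)):
        y[:, k + 1] = (1.0 - a[k]) * y[:, k] + a[k] * rbar[:, k] * Xbar[:, k]
    out = dict(out, mean_traj=y)
    return _assemble(data, out, target_fdr)


def consensus_trajectory(result: CoreResult) -> LatentTrajectory:
    """Posterior-mean latent product trajectory (one curve per gene)."""
    return result.trajectory
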