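"""Synthesis/degradation deconvolution from generic paired mRNA-protein data.

Total product concentration follows first-order mass action per interval,

    E[Y_{k+1}] = e^{-k_d dh} E[Y_k] + (1 - e^{-k_d dh}) (k_s / k_d) X_k,

with both rates free per gene.  That problem is unidentifiable from totals
alone, so the parameter space is restricted by attributing each
concentration change: increases beyond what the template trajectory
explains at held rates may only move the synthesis rate up; decreases
beyond the template-explained envelope may only move the degradation rate
up; anything inside the envelope (or below the noise floor) holds both
rates.  The restriction is enforced through truncated proposals in the
sampler, and the change scores are correspondingly more diluted than the
pulse-labeled estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._mcmc import (
    MCMCConfig,
    _logit,
    _sigmoid,
    lk_matrix,
    replicate_sigma2,
    sample_invgamma,
    LOG_RATE_BOUND,
    STEP_BOUNDS,
)
from .core import CPSTable, FDRMap, LatentTrajectory, cps_fdr_threshold
from .io import PairedDataset, ValidationError
from .pulsed import RateProfile

logger = logging.getLogger("turnpoint")

TAGS = ("none", "synthesis", "degradation", "template")
TAG_NONE, TAG_SYNTH, TAG_DEG, TAG_TEMPLATE = range(4)

_LKD_BOUNDS = (-6.0, 2.0)  # log10 bisection range for degradation rates


def attribute_change(
    delta_protein,
    template_explained,
    noise_floor: float,
):
    """Attribute an interval's protein change; vectorized over inputs.

    Returns 'none' when |delta| is below the noise floor, 'synthesis' for
    an increase beyond the template-explained change (+ floor),
    'degradation' for a decrease beyond it (- floor), and 'template' when
    the held-rate prediction already explains the change.
    """
    delta = np.asarray(delta_protein, float)
    te = np.asarray(template_explained, float)
    floor = np.broadcast_to(np.asarray(noise_floor, float), delta.shape)
    tag = np.full(delta.shape, TAG_TEMPLATE, dtype=int)
    small = np.abs(delta) <= floor
    up = (delta > floor) & (delta > te + floor)
    down = (delta < -floor) & (delta < te - floor)
    tag[up] = TAG_SYNTH
    tag[down] = TAG_DEG
    tag[small] = TAG_NONE
    if tag.ndim == 0:
        return TAGS[int(tag)]
    return tag


def _forward(y: np.ndarray, ks, kd, X, dh):
    """One mass-action step at given rates."""
    w = np.exp(-kd * dh)
    return w * y + (1.0 - w) * (ks / kd) * X


def _solve_kd(y: np.ndarray, target: np.ndarray, ks: np.ndarray, X, dh):
    """Degradation rate reproducing ``target`` from ``y`` (vector bisection).

    The forward map is monotone decreasing in k_d, so bisection on log10
    k_d converges; out-of-range targets clip to the bounds.
    """
    lo = np.full(y.shape, _LKD_BOUNDS[0])
    hi = np.full(y.shape, _LKD_BOUNDS[1])
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        pred = _forward(y, ks, np.power(10.0, mid), X, dh)
        too_high = pred > target  # prediction above target -> need more decay
        lo = np.where(too_high, mid, lo)
        hi = np.where(too_high, hi, mid)
    return np.power(10.0, 0.5 * (lo + hi))


@dataclass
class RatesResult:
    trajectory: LatentTrajectory
    rates: RateProfile
    synthesis_cps: CPSTable
    degradation_cps: CPSTable
    synthesis_fdr: tuple[float, FDRMap]
    degradation_fdr: tuple[float, FDRMap]
    attribution: pd.DataFrame  # gene x boundary tags
    sigma2: float
    diverged: tuple[str, ...]


def _constant_rate_fit(ybar, X, dh, kd_scale):
    """Least-squares constant (k_s, k_d) per gene on the increments."""
    dy = np.diff(ybar, axis=1)  # (G, K)
    A = dh[None, :] * X[:, :-1]
    B = -dh[None, :] * ybar[:, :-1]
    # normal equations for dy ~ ks*A + kd*B
    aa = (A * A).sum(axis=1)
    ab = (A * B).sum(axis=1)
    bb = (B * B).sum(axis=1)
    ay = (A * dy).sum(axis=1)
    by = (B * dy).sum(axis=1)
    det = aa * bb - ab * ab
    ok = det > 1e-12 * np.maximum(aa * bb, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        ks = (bb * ay - ab * by) / det
        kd = (aa * by - ab * ay) / det
    kd_fallback = np.full(ybar.shape[0], kd_scale)
    ks_fallback = kd_fallback * ybar.mean(axis=1) / X.mean(axis=1)
    kd = np.where(ok & (kd > 1e-6), kd, kd_fallback)
    ks = np.where(ok & (ks > 1e-9), ks, ks_fallback)
    # keep the stationary anchor when the fit ran away
    ks = np.clip(ks, 1e-9, 1e9)
    kd = np.clip(kd, 1e-6, 10.0 / dh.min())
    return ks, kd


def fit_rates(
    data: PairedDataset,
    cfg: MCMCConfig,
    target_fdr: float = 0.05,
    noise_floor: float = 0.05,
    kd_scale: float | None = None,
) -> RatesResult:
    """Restricted-space inference of per-interval synthesis and degradation.

    ``noise_floor`` is the minimum relative concentration change treated as
    signal when attributing changes; the attribution envelope additionally
    widens with the replicate-estimated noise sd.
    """
    if data.grid.n_times < 3:
        raise ValidationError("need at least 3 time points")
    if data.template.mask.any() or data.product.mask.any():
        raise ValidationError(
            "dataset has missing cells; smooth/impute first (gp module)"
        )
    if noise_floor < 0:
        raise ValidationError("noise floor must be >= 0")
    X = data.template.consensus_linear()
    if np.any(X <= 0):
        raise ValidationError("template layer must be strictly positive")
    obs_l10 = data.product.to_log10().values  # (G, T, R)
    ybar = np.power(10.0, obs_l10.mean(axis=2))
    dh = data.grid.intervals
    G, T, R = obs_l10.shape
    K, J = T - 1, T - 2
    if kd_scale is None:
        kd_scale = 0.5 / float(dh.max())

    # relative envelope around the held-rate prediction; the input is
    # expected to be smoothed, so a user-set relative floor is used rather
    # than the (over-wide) raw replicate scatter
    rel_floor = noise_floor

    # ---- attribution pass with running held-rate predictions ----
    # first interval anchored on the stationary ray k_s X_0 = k_d Y_0:
    # the constant-rate fit pins the synthesis flux, the ray pins k_d
    ks_run, _kd_ls = _constant_rate_fit(ybar, X, dh, kd_scale)
    kd_run = np.clip(ks_run * X[:, 0] / ybar[:, 0], 1e-6, 10.0 / dh.min())
    ks_path = np.empty((G, K))
    kd_path = np.empty((G, K))
    ks_path[:, 0] = ks_run
    kd_path[:, 0] = kd_run
    tags = np.empty((G, J), dtype=int)
    for j in range(1, K):
        ks_prev, kd_prev = ks_path[:, j - 1], kd_path[:, j - 1]
        pred = _forward(ybar[:, j], ks_prev, kd_prev, X[:, j], dh[j])
        delta = ybar[:, j + 1] - ybar[:, j]
        te = pred - ybar[:, j]
        floor_abs = rel_floor * ybar[:, j]
        tags[:, j - 1] = attribute_change(delta, te, floor_abs)
        ks_j = ks_prev.copy()
        kd_j = kd_prev.copy()
        synth = tags[:, j - 1] == TAG_SYNTH
        if synth.any():
            w = np.exp(-kd_prev[synth] * dh[j])
            num = ybar[synth, j + 1] - w * ybar[synth, j]
            ks_j[synth] = np.clip(
                kd_prev[synth] * num / ((1.0 - w) * X[synth, j]),
                1e-9,
                1e9,
            )
        deg = tags[:, j - 1] == TAG_DEG
        if deg.any():
            kd_j[deg] = _solve_kd(
                ybar[deg, j],
                ybar[deg, j + 1],
                ks_prev[deg],
                X[deg, j],
                dh[j],
            )
        ks_path[:, j] = ks_j
        kd_path[:, j] = kd_j

    allow_s = tags == TAG_SYNTH
    allow_d = tags == TAG_DEG

    # ---- sampler state ----
    rng = np.random.default_rng(cfg.seed)
    slab2 = cfg.slab_sd**2
    lks_path = np.log10(ks_path)
    lkd_path = np.log10(kd_path)
    ly0 = np.log10(ybar[:, 0])
    lks0 = lks_path[:, 0]
    lkd0 = lkd_path[:, 0]
    ds = np.where(allow_s, np.maximum(np.diff(lks_path, axis=1), cfg.min_jump), 0.0)
    dd = np.where(allow_d, np.maximum(np.diff(lkd_path, axis=1), cfg.min_jump), 0.0)
    zs = np.zeros((G, J), dtype=bool)
    zd = np.zeros((G, J), dtype=bool)
    sigma2 = replicate_sigma2(obs_l10)
    pi_s = np.full(J, cfg.pi_a / (cfg.pi_a + cfg.pi_b))
    pi_d = np.full(J, cfg.pi_a / (cfg.pi_a + cfg.pi_b))

    lks0_mean, lkd0_mean = lks0.copy(), lkd0.copy()
    ly0_mean = ly0.copy()

    def traj_l10(l0, lks_mat, lkd_mat):
        y = np.empty((G, T))
        y[:, 0] = np.power(10.0, l0)
        ks = np.power(10.0, lks_mat)
        kd = np.power(10.0, lkd_mat)
        for k in range(K):
            y[:, k + 1] = _forward(y[:, k], ks[:, k], kd[:, k], X[:, k], dh[k])
        with np.errstate(divide="ignore"):
            return np.log10(y)

    def ss_of(l0, lks_mat, lkd_mat):
        resid = obs_l10 - traj_l10(l0, lks_mat, lkd_mat)[:, :, None]
        return np.einsum("gtr,gtr->g", resid, resid)

    lks_mat = lk_matrix(lks0, zs * ds)
    lkd_mat = lk_matrix(lkd0, zd * dd)
    ss_cur = ss_of(ly0, lks_mat, lkd_mat)

    step_ds = np.full((G, J), cfg.step_init)
    step_dd = np.full((G, J), cfg.step_init)
    step_lks0 = np.full(G, cfg.step_init)
    step_lkd0 = np.full(G, cfg.step_init)
    step_ly0 = np.full(G, cfg.step_init)

    n_keep = 0
    sums = {
        "zs": np.zeros((G, J)),
        "zd": np.zeros((G, J)),
        "zds": np.zeros((G, J)),
        "zdd": np.zeros((G, J)),
        "ks": np.zeros((G, K)),
        "kd": np.zeros((G, K)),
        "traj": np.zeros((G, T)),
        "sigma2": 0.0,
    }

    def boundary_update(j, z, d, allow, other_zd_mat, own_lk0, pi_j, step_d, adapting):
        """Spike-slab update of one rate chain at boundary j (truncated d > 0)."""
        nonlocal ss_cur, sigma2
        a_j = allow[:, j]
        fresh = cfg.min_jump + np.abs(rng.normal(0.0, cfg.slab_sd, size=G))
        d[:, j] = np.where(z[:, j], d[:, j], fresh)
        zd_own = z * d
        zd_on = zd_own.copy()
        zd_on[:, j] = d[:, j]
        zd_off = zd_own.copy()
        zd_off[:, j] = 0.0
        if z is zs:
            ss_on = ss_of(ly0, lk_matrix(own_lk0, zd_on), other_zd_mat)
            ss_off = ss_of(ly0, lk_matrix(own_lk0, zd_off), other_zd_mat)
        else:
            ss_on = ss_of(ly0, other_zd_mat, lk_matrix(own_lk0, zd_on))
            ss_off = ss_of(ly0, other_zd_mat, lk_matrix(own_lk0, zd_off))
        logp = _logit(pi_j) - 0.5 * (ss_on - ss_off) / sigma2
        u = rng.random(G)
        z[:, j] = (u < _sigmoid(logp)) & a_j
        ss_cur = np.where(z[:, j], ss_on, ss_off)
        # reflected random walk keeps the jump above the minimum effect size
        eps = rng.normal(size=G)
        prop = cfg.min_jump + np.abs(d[:, j] - cfg.min_jump + step_d[:, j] * eps)
        zd_prop = z * d
        zd_prop[:, j] = np.where(z[:, j], prop, 0.0)
        if z is zs:
            ss_prop = ss_of(ly0, lk_matrix(own_lk0, zd_prop), other_zd_mat)
        else:
            ss_prop = ss_of(ly0, other_zd_mat, lk_matrix(own_lk0, zd_prop))
        logacc = (
            -0.5 * (ss_prop - ss_cur) / sigma2
            - 0.5
            * ((prop - cfg.min_jump) ** 2 - (d[:, j] - cfg.min_jump) ** 2)
            / slab2
        )
        logacc = np.where(prop > LOG_RATE_BOUND, -np.inf, logacc)
        acc = (np.log(rng.random(G)) < logacc) & z[:, j]
        d[acc, j] = prop[acc]
        ss_cur = np.where(acc, ss_prop, ss_cur)
        if adapting:
            upd = z[:, j]
            step_d[upd, j] *= np.exp(
                cfg.adapt_rate * (acc[upd].astype(float) - cfg.target_accept)
            )
            np.clip(step_d[:, j], *STEP_BOUNDS, out=step_d[:, j])

    def scalar_update(vec, mean, sd, step, which, adapting):
        """Adaptive MH on a per-gene scalar block (baseline or level)."""
        nonlocal ss_cur
        eps = rng.normal(size=G)
        prop = vec + step * eps
        if which == "lks0":
            ss_prop = ss_of(ly0, lk_matrix(prop, zs * ds), lk_matrix(lkd0, zd * dd))
        elif which == "lkd0":
            ss_prop = ss_of(ly0, lk_matrix(lks0, zs * ds), lk_matrix(prop, zd * dd))
        else:
            ss_prop = ss_of(prop, lk_matrix(lks0, zs * ds), lk_matrix(lkd0, zd * dd))
        logacc = (
            -0.5 * (ss_prop - ss_cur) / sigma2
            - 0.5 * ((prop - mean) ** 2 - (vec - mean) ** 2) / sd**2
        )
        logacc = np.where(np.abs(prop) > LOG_RATE_BOUND, -np.inf, logacc)
        acc = np.log(rng.random(G)) < logacc
        out = np.where(acc, prop, vec)
        ss_cur = np.where(acc, ss_prop, ss_cur)
        if adapting:
            step *= np.exp(cfg.adapt_rate * (acc.astype(float) - cfg.target_accept))
            np.clip(step, *STEP_BOUNDS, out=step)
        return out

    n_obs = obs_l10.size
    for it in range(cfg.n_iter):
        adapting = it < cfg.n_burn
        for j in range(J):
            boundary_update(
                j, zs, ds, allow_s, lk_matrix(lkd0, zd * dd), lks0, pi_s[j],
                step_ds, adapting,
            )
            boundary_update(
                j, zd, dd, allow_d, lk_matrix(lks0, zs * ds), lkd0, pi_d[j],
                step_dd, adapting,
            )
        lks0 = scalar_update(lks0, lks0_mean, 1.0, step_lks0, "lks0", adapting)
        lkd0 = scalar_update(lkd0, lkd0_mean, 1.0, step_lkd0, "lkd0", adapting)
        ly0 = scalar_update(ly0, ly0_mean, 2.0, step_ly0, "ly0", adapting)
        finite = np.isfinite(ss_cur)
        sigma2 = max(
            sample_invgamma(
                rng,
                cfg.sigma2_a + 0.5 * n_obs * finite.mean(),
                cfg.sigma2_b + 0.5 * float(ss_cur[finite].sum()),
            ),
            1e-8,
        )
        ns = zs.sum(axis=0)
        nd = zd.sum(axis=0)
        n_as = allow_s.sum(axis=0)
        n_ad = allow_d.sum(axis=0)
        pi_s = rng.beta(cfg.pi_a + ns, cfg.pi_b + np.maximum(n_as - ns, 0))
        pi_d = rng.beta(cfg.pi_a + nd, cfg.pi_b + np.maximum(n_ad - nd, 0))

        if it >= cfg.n_burn and (it - cfg.n_burn) % cfg.thin == 0:
            n_keep += 1
            lks_mat = lk_matrix(lks0, zs * ds)
            lkd_mat = lk_matrix(lkd0, zd * dd)
            sums["zs"] += zs
            sums["zd"] += zd
            sums["zds"] += zs * ds
            sums["zdd"] += zd * dd
            sums["ks"] += np.power(10.0, lks_mat)
            sums["kd"] += np.power(10.0, lkd_mat)
            sums["traj"] += np.power(10.0, traj_l10(ly0, lks_mat, lkd_mat))
            sums["sigma2"] += sigma2

    gene_ids = data.gene_ids
    bad = ~np.isfinite(ss_cur)
    if bad.any():
        logger.warning("divergent chains for %d genes", int(bad.sum()))
    syn_cps = CPSTable(
        gene_ids,
        np.clip(sums["zs"] / n_keep, 0, 1),
        np.where(sums["zds"] >= 0, 1, -1),
    )
    deg_cps = CPSTable(
        gene_ids,
        np.clip(sums["zd"] / n_keep, 0, 1),
        np.where(sums["zdd"] >= 0, 1, -1),
    )
    attribution = pd.DataFrame(
        {"gene": list(gene_ids)}
        | {
            f"tag_{j + 1}": [TAGS[t] for t in tags[:, j]]
            for j in range(J)
        }
    )
    return RatesResult(
        trajectory=LatentTrajectory(gene_ids, sums["traj"] / n_keep),
        rates=RateProfile(gene_ids, sums["ks"] / n_keep, sums["kd"] / n_keep),
        synthesis_cps=syn_cps,
        degradation_cps=deg_cps,
        synthesis_fdr=cps_fdr_threshold(syn_cps, target_fdr),
        degradation_fdr=cps_fdr_threshold(deg_cps, target_fdr),
        attribution=attribution,
        sigma2=sums["sigma2"] / n_keep,
        diverged=tuple(g for g, b in zip(gene_ids, bad) if b),
    )
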