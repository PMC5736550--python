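"""Shared spike-and-slab change-point sampler.

One latent rate series per gene, piecewise-constant on the log10 scale:
``lk[:, k] = lk0 + sum_{j < k} z_j * d_j`` where ``z_j`` is the change
indicator at interior time point j+1 and ``d_j`` the log10 jump size.
Observations are Gaussian on the log10 scale around a deterministic latent
trajectory (model-specific ``traj_fn``), replicates conditionally
independent.  Indicators are updated by exact Gibbs (the jump carries an
independent slab pseudo-prior, so the conditional is available in closed
form); jump sizes, baselines and initial levels move by adaptive
random-walk Metropolis; the noise variance and the shared change prior are
conjugate Gibbs updates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger("turnpoint")

LOG_RATE_BOUND = 15.0  # log10 bound on latent rates / levels
STEP_BOUNDS = (1e-4, 5.0)


@dataclass
class MCMCConfig:
    """Sampler settings; the seed is mandatory for reproducibility."""

    seed: int
    n_iter: int = 4000
    n_burn: int = 2000
    thin: int = 2
    slab_sd: float = 0.8  # log10 jump-size prior sd
    min_jump: float = 0.1  # slab support excludes |jump| below this (log10)
    pi_a: float = 1.0  # Beta prior on the shared change probability
    pi_b: float = 9.0
    sigma2_a: float = 2.0  # inverse-gamma prior on the log10 noise variance
    sigma2_b: float = 0.01
    robust_dof: float = 6.0  # Student-t dof for observation noise (0 = Gaussian)
    evidence_scale: float = 0.5  # power-posterior tempering (1 = full likelihood)
    field_cap: float = 5.0  # MRF concordance field clipped to +- this
    step_init: float = 0.2
    adapt_rate: float = 0.05
    target_accept: float = 0.3

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("MCMC seed is required")
        if not self.n_iter > self.n_burn >= 0:
            raise ValueError("need n_iter > n_burn >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _logit(p: float) -> float:
    p = min(max(p, 1e-12), 1 - 1e-12)
    return float(np.log(p / (1 - p)))


def replicate_sigma2(obs_l10: np.ndarray, floor: float = 1e-6) -> float:
    """Initial noise variance from replicate scatter (log10 scale)."""
    if obs_l10.shape[2] < 2:
        return 0.01
    return float(max(floor, np.mean(np.var(obs_l10, axis=2, ddof=1))))


def sample_invgamma(rng: np.random.Generator, shape: float, rate: float) -> float:
    return float(rate / rng.gamma(shape))


def lk_matrix(lk0: np.ndarray, zd: np.ndarray) -> np.ndarray:
    """Per-interval log10 rates from the baseline and active jumps."""
    G, J = zd.shape
    out = np.empty((G, J + 1))
    out[:, 0] = lk0
    np.cumsum(zd, axis=1, out=out[:, 1:])
    out[:, 1:] += lk0[:, None]
    return out


def color_classes(adjacency, n_genes: int) -> list[np.ndarray]:
    """Independent gene sets for exact vectorized Gibbs under an MRF prior."""
    if adjacency is None or all(len(a) == 0 for a in adjacency):
        return [np.arange(n_genes)]
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(n_genes))
    for i, nbrs in enumerate(adjacency):
        for j in nbrs:
            g.add_edge(i, int(j))
    coloring = nx.coloring.greedy_color(g, strategy="largest_first")
    n_colors = max(coloring.values()) + 1
    return [
        np.array(sorted(i for i, c in coloring.items() if c == k), dtype=int)
        for k in range(n_colors)
    ]


def run_spike_slab(
    obs_l10: np.ndarray,
    traj_fn,
    init: dict,
    prior: dict,
    cfg: MCMCConfig,
    rng: np.random.Generator,
    adjacency=None,
    beta: float = 0.0,
    template_obs_l10: np.ndarray | None = None,
    sample_l0: bool = True,
) -> dict:
    """Run the sampler and return posterior summaries.

    Parameters
    ----------
    obs_l10
        (G, T, R) log10 observations, fully observed.
    traj_fn
        ``traj_fn(l0, lk) -> (G, T) log10 latent trajectory`` where ``l0``
        is the per-gene log10 initial level and ``lk`` the (G, T-1) log10
        rate matrix.  With a noisy template layer the signature is
        ``traj_fn(l0, lk, lx)`` where ``lx`` is the (G, T) log10 latent
        template.
    init
        dict with 'l0' (G,), 'lk0' (G,), 'd' (G, J) starting values (plus
        'lx' (G, T) when a template layer is sampled).
    prior
        dict with 'l0_mean', 'l0_sd', 'lk0_mean', 'lk0_sd'.
    adjacency, beta
        Optional MRF change prior: ``adjacency`` is a list of neighbor
        index arrays, ``beta`` the signed-concordance coupling (>= 0).
    template_obs_l10
        Optional (G, T, R) log10 template observations.  When given, a
        latent denoised template trajectory is sampled jointly so that
        template measurement noise is not mistaken for product-layer rate
        changes.
    """
    G, T, R = obs_l10.shape
    K = T - 1
    J = T - 2
    if beta < 0:
        raise ValueError("MRF coupling beta must be >= 0")
    # power-posterior tempering guards against overconfident change calls
    # under mild model misspecification (fractional/safe Bayes)
    eta = cfg.evidence_scale

    l0 = np.array(init["l0"], dtype=float)
    lk0 = np.array(init["lk0"], dtype=float)
    d = np.array(init["d"], dtype=float)
    z = np.zeros((G, J), dtype=bool)
    sigma2 = float(init.get("sigma2", 0.01))
    pi = np.full(J, cfg.pi_a / (cfg.pi_a + cfg.pi_b))

    has_template = template_obs_l10 is not None
    if has_template:
        lx = np.array(init["lx"], dtype=float)
        lx_anchor = lx.copy()
        sigma2_x = float(init.get("sigma2_x", replicate_sigma2(template_obs_l10)))
        step_lx = np.full((G, T), cfg.step_init)
        n_obs_x = template_obs_l10.size

    l0_mean = np.asarray(prior["l0_mean"], float)
    l0_sd = float(prior["l0_sd"])
    lk0_mean = np.asarray(prior["lk0_mean"], float)
    lk0_sd = float(prior["lk0_sd"])
    slab2 = cfg.slab_sd**2

    classes = color_classes(adjacency, G)
    if adjacency is not None:
        edge_i, edge_j = [], []
        for i, nbrs in enumerate(adjacency):
            for h in nbrs:
                if i < h:
                    edge_i.append(i)
                    edge_j.append(int(h))
        edge_i = np.asarray(edge_i, dtype=int)
        edge_j = np.asarray(edge_j, dtype=int)

    def neighbor_field(zj: np.ndarray, dj: np.ndarray) -> np.ndarray:
        """Signed concordance s_g = sign(d_g) * sum_{h in N(g)} z_h sign(d_h)."""
        if adjacency is None or edge_i.size == 0:
            return np.zeros(G)
        contrib = np.where(zj, np.sign(dj), 0.0)
        sums = np.bincount(
            edge_i, weights=contrib[edge_j], minlength=G
        ) + np.bincount(edge_j, weights=contrib[edge_i], minlength=G)
        return np.clip(np.sign(dj) * sums, -cfg.field_cap, cfg.field_cap)

    # Student-t noise as a normal scale mixture: per-cell variance factors
    # lam absorb lone outliers so that single aberrant observations cannot
    # masquerade as confident rate changes
    inv_lam = np.ones_like(obs_l10)

    def traj_of(l0_v, lk_mat, lx_v=None) -> np.ndarray:
        if has_template:
            return traj_fn(l0_v, lk_mat, lx if lx_v is None else lx_v)
        return traj_fn(l0_v, lk_mat)

    def ss_of(l0_v, lk0_v, zd, lx_v=None) -> np.ndarray:
        traj = traj_of(l0_v, lk_matrix(lk0_v, zd), lx_v)
        resid = obs_l10 - traj[:, :, None]
        return np.einsum("gtr,gtr,gtr->g", resid, resid, inv_lam)

    zd = z * d
    ss_cur = ss_of(l0, lk0, zd)
    n_obs = obs_l10.size

    step_d = np.full((G, J), cfg.step_init)
    step_lk0 = np.full(G, cfg.step_init)
    step_l0 = np.full(G, cfg.step_init)

    n_keep = 0
    sum_z = np.zeros((G, J))
    sum_zd = np.zeros((G, J))
    sum_k = np.zeros((G, K))
    sum_lk = np.zeros((G, K))
    sum_traj = np.zeros((G, T))
    sum_l0 = np.zeros(G)
    sum_sigma2 = 0.0
    sum_pi = np.zeros(J)
    sum_lx = np.zeros((G, T))

    for it in range(cfg.n_iter):
        adapting = it < cfg.n_burn
        # ---- change indicators and jump sizes, one boundary at a time ----
        for j in range(J):
            # slab excludes (-min_jump, min_jump): an active change must be
            # distinguishable from no change, else z=1 states with a
            # likelihood-free zero jump become sticky and inflate CPS
            raw = rng.normal(0.0, cfg.slab_sd, size=G)
            fresh = np.sign(raw) * (cfg.min_jump + np.abs(raw))
            d[:, j] = np.where(z[:, j], d[:, j], fresh)
            zd = z * d
            zd_on = zd.copy()
            zd_on[:, j] = d[:, j]
            zd_off = zd.copy()
            zd_off[:, j] = 0.0
            ss_on = ss_of(l0, lk0, zd_on)
            ss_off = ss_of(l0, lk0, zd_off)
            base_logit = _logit(pi[j])
            for cls in classes:
                if beta != 0.0 and adjacency is not None:
                    s = neighbor_field(z[:, j], d[:, j])
                    logits = base_logit + beta * s[cls]
                else:
                    logits = base_logit
                logp = np.asarray(
                    logits - 0.5 * eta * (ss_on[cls] - ss_off[cls]) / sigma2,
                    dtype=float,
                )
                u = rng.random(len(cls))
                z[cls, j] = u < _sigmoid(logp)
            ss_cur = np.where(z[:, j], ss_on, ss_off)
            # Metropolis on the active jump sizes
            eps = rng.normal(size=G)
            prop = d[:, j] + step_d[:, j] * eps
            zd = z * d
            zd_prop = zd.copy()
            zd_prop[:, j] = np.where(z[:, j], prop, 0.0)
            ss_prop = ss_of(l0, lk0, zd_prop)
            logacc = (
                -0.5 * eta * (ss_prop - ss_cur) / sigma2
                - 0.5
                * (
                    (np.abs(prop) - cfg.min_jump) ** 2
                    - (np.abs(d[:, j]) - cfg.min_jump) ** 2
                )
                / slab2
            )
            bad_prop = (np.abs(prop) > LOG_RATE_BOUND) | (
                np.abs(prop) < cfg.min_jump
            )
            logacc = np.where(bad_prop, -np.inf, logacc)
            acc = (np.log(rng.random(G)) < logacc) & z[:, j]
            d[acc, j] = prop[acc]
            ss_cur = np.where(acc, ss_prop, ss_cur)
            if adapting:
                upd = z[:, j]
                step_d[upd, j] *= np.exp(
                    cfg.adapt_rate * (acc[upd].astype(float) - cfg.target_accept)
                )
                np.clip(step_d[:, j], *STEP_BOUNDS, out=step_d[:, j])
        zd = z * d

        # ---- baseline log rate ----
        eps = rng.normal(size=G)
        prop = lk0 + step_lk0 * eps
        ss_prop = ss_of(l0, prop, zd)
        logacc = (
            -0.5 * eta * (ss_prop - ss_cur) / sigma2
            - 0.5 * ((prop - lk0_mean) ** 2 - (lk0 - lk0_mean) ** 2) / lk0_sd**2
        )
        logacc = np.where(np.abs(prop) > LOG_RATE_BOUND, -np.inf, logacc)
        acc = np.log(rng.random(G)) < logacc
        lk0 = np.where(acc, prop, lk0)
        ss_cur = np.where(acc, ss_prop, ss_cur)
        if adapting:
            step_lk0 *= np.exp(cfg.adapt_rate * (acc.astype(float) - cfg.target_accept))
            np.clip(step_lk0, *STEP_BOUNDS, out=step_lk0)

        # ---- initial level (skipped when the model pins it, e.g. to the
        # stationary start r_0 * X_0) ----
        if sample_l0:
            eps = rng.normal(size=G)
            prop = l0 + step_l0 * eps
            ss_prop = ss_of(prop, lk0, zd)
            logacc = (
                -0.5 * eta * (ss_prop - ss_cur) / sigma2
                - 0.5 * ((prop - l0_mean) ** 2 - (l0 - l0_mean) ** 2) / l0_sd**2
            )
            logacc = np.where(np.abs(prop) > LOG_RATE_BOUND, -np.inf, logacc)
            acc = np.log(rng.random(G)) < logacc
            l0 = np.where(acc, prop, l0)
            ss_cur = np.where(acc, ss_prop, ss_cur)
            if adapting:
                step_l0 *= np.exp(
                    cfg.adapt_rate * (acc.astype(float) - cfg.target_accept)
                )
                np.clip(step_l0, *STEP_BOUNDS, out=step_l0)

        # ---- latent template trajectory (one time column at a time) ----
        if has_template:
            for t in range(T):
                eps = rng.normal(size=G)
                prop_col = lx[:, t] + step_lx[:, t] * eps
                lx_prop = lx.copy()
                lx_prop[:, t] = prop_col
                ss_prop = ss_of(l0, lk0, zd, lx_prop)
                xres_cur = template_obs_l10[:, t, :] - lx[:, t, None]
                xres_prop = template_obs_l10[:, t, :] - prop_col[:, None]
                dst = (xres_prop**2 - xres_cur**2).sum(axis=1)
                logacc = (
                    -0.5 * eta * (ss_prop - ss_cur) / sigma2
                    - 0.5 * eta * dst / sigma2_x
                    - 0.5
                    * ((prop_col - lx_anchor[:, t]) ** 2 - (lx[:, t] - lx_anchor[:, t]) ** 2)
                    / 4.0
                )
                logacc = np.where(np.abs(prop_col) > LOG_RATE_BOUND, -np.inf, logacc)
                acc = np.log(rng.random(G)) < logacc
                lx[acc, t] = prop_col[acc]
                ss_cur = np.where(acc, ss_prop, ss_cur)
                if adapting:
                    step_lx[:, t] *= np.exp(
                        cfg.adapt_rate * (acc.astype(float) - cfg.target_accept)
                    )
                    np.clip(step_lx[:, t], *STEP_BOUNDS, out=step_lx[:, t])
            xres = template_obs_l10 - lx[:, :, None]
            sigma2_x = max(
                sample_invgamma(
                    rng,
                    cfg.sigma2_a + 0.5 * eta * n_obs_x,
                    cfg.sigma2_b + 0.5 * eta * float(np.sum(xres**2)),
                ),
                1e-8,
            )

        # ---- per-cell variance factors (t-noise scale mixture) ----
        if cfg.robust_dof > 0:
            nu = cfg.robust_dof
            traj = traj_of(l0, lk_matrix(lk0, zd))
            resid2 = (obs_l10 - traj[:, :, None]) ** 2
            gam = rng.gamma((nu + eta) / 2.0, size=obs_l10.shape)
            inv_lam = gam / (0.5 * (nu + eta * resid2 / sigma2))
            ss_cur = np.einsum("gtr,gtr->g", resid2, inv_lam)

        # ---- shared noise variance (inverse gamma) ----
        finite = np.isfinite(ss_cur)
        sigma2 = sample_invgamma(
            rng,
            cfg.sigma2_a + 0.5 * eta * n_obs * finite.mean(),
            cfg.sigma2_b + 0.5 * eta * float(ss_cur[finite].sum()),
        )
        sigma2 = max(sigma2, 1e-8)

        # ---- shared change prior per boundary ----
        nz = z.sum(axis=0)
        pi = rng.beta(cfg.pi_a + nz, cfg.pi_b + G - nz)

        if it >= cfg.n_burn and (it - cfg.n_burn) % cfg.thin == 0:
            n_keep += 1
            sum_z += z
            sum_zd += z * d
            lk = lk_matrix(lk0, z * d)
            sum_lk += lk
            sum_k += np.power(10.0, lk)
            sum_traj += np.power(10.0, traj_of(l0, lk))
            sum_l0 += l0
            sum_sigma2 += sigma2
            sum_pi += pi
            if has_template:
                sum_lx += np.power(10.0, lx)

    bad = ~np.isfinite(ss_cur)
    if bad.any():
        logger.warning("divergent chains for %d genes", int(bad.sum()))
    return {
        "cps": sum_z / n_keep,
        "mean_zd": sum_zd / n_keep,
        "mean_rate": sum_k / n_keep,
        "mean_log_rate": sum_lk / n_keep,
        "mean_traj": sum_traj / n_keep,
        "mean_l0": sum_l0 / n_keep,
        "sigma2": sum_sigma2 / n_keep,
        "pi": sum_pi / n_keep,
        "mean_template": sum_lx / n_keep if has_template else None,
        "n_draws": n_keep,
        "diverged": bad,
    }
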