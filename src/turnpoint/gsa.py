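"""Time-resolved gene-set enrichment on CPS-thresholded gene lists.

For each gene set, time point and direction (up, down, any) an exact
upper-tail hypergeometric test is computed against the background of all
genes in the analyzed dataset.  Heatmap cells are signed -log10 p-values
(+ up, - down).  Raw p-values are reported as in the source heatmaps; a
Benjamini-Hochberg column is emitted alongside as a clearly-labeled extra.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .core import CPSTable
from .io import GeneSetCollection, ValidationError

logger = logging.getLogger("turnpoint")

DIRECTIONS = ("up", "down", "any")


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    time_index: int
    direction: str
    background: int  # N
    set_size: int  # K (within background)
    selected: int  # n
    overlap: int  # k
    p_value: float
    signed_score: float

    def __post_init__(self) -> None:
        N, K, n, k = self.background, self.set_size, self.selected, self.overlap
        if not (0 <= k <= min(K, n) and K <= N and n <= N):
            raise ValidationError("inconsistent enrichment counts")
        if not 0 < self.p_value <= 1:
            raise ValidationError("p-value outside (0, 1]")


def _log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeometric_pvalue(N: int, K: int, n: int, k: int) -> float:
    """Exact upper tail P(X >= k), X ~ Hypergeometric(N, K, n).

    Summed in log space (log binomial coefficients + logsumexp) for
    numerical stability; the GSA step is exact, never simulated.
    """
    N, K, n, k = int(N), int(K), int(n), int(k)
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValidationError(
            f"invalid hypergeometric counts N={N} K={K} n={n} k={k}"
        )
    if k == 0:
        return 1.0
    i = np.arange(k, min(K, n) + 1)
    log_terms = (
        _log_binom(K, i) + _log_binom(N - K, n - i) - _log_binom(N, n)
    )
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def select_genes(
    cps: CPSTable,
    threshold: float,
    direction: str,
    time_index: int,
) -> tuple[str, ...]:
    """Genes with CPS >= threshold at one interior time point.

    ``time_index`` is the boundary column (0-based); ``direction`` filters
    by the sign of the rate(-ratio) change.
    """
    if not 0 <= threshold:
        raise ValidationError("threshold must be >= 0")
    if direction not in DIRECTIONS:
        raise ValidationError(f"direction must be one of {DIRECTIONS}")
    if not 0 <= time_index < cps.n_boundaries:
        raise ValidationError(
            f"time_index {time_index} out of range [0, {cps.n_boundaries})"
        )
    passing = cps.cps[:, time_index] >= threshold
    if direction == "up":
        passing &= cps.direction[:, time_index] > 0
    elif direction == "down":
        passing &= cps.direction[:, time_index] < 0
    return tuple(g for g, p in zip(cps.gene_ids, passing) if p)


def run_gsa(
    cps: CPSTable,
    sets: GeneSetCollection,
    threshold: float,
    min_k: int = 3,
    set_size_range: tuple[int, int] = (5, 500),
) -> pd.DataFrame:
    """Enrichment table over (set, time, direction) cells.

    The background is the gene list of the analyzed dataset; every set is
    intersected with it before testing, and sets outside ``set_size_range``
    (after intersection) or cells with overlap below ``min_k`` are skipped.
    """
    background = set(cps.gene_ids)
    N = len(background)
    lo, hi = set_size_range
    rows = []
    restricted = {}
    for name, genes in sets.sets.items():
        inter = frozenset(genes) & background
        if not inter:
            logger.info("gene set %r absent from dataset background; skipped", name)
            continue
        if not lo <= len(inter) <= hi:
            continue
        restricted[name] = inter
    for t in range(cps.n_boundaries):
        selections = {
            direction: frozenset(select_genes(cps, threshold, direction, t))
            for direction in DIRECTIONS
        }
        for name, members in restricted.items():
            K = len(members)
            for direction in DIRECTIONS:
                selected = selections[direction]
                n = len(selected)
                k = len(selected & members)
                if k < min_k:
                    continue
                p = hypergeometric_pvalue(N, K, n, k)
                if direction == "up":
                    sign = 1.0
                elif direction == "down":
                    sign = -1.0
                else:
                    # dominant direction; 0 on a tie (signs defined only
                    # for the up/down cells)
                    k_up = len(selections["up"] & members)
                    k_down = len(selections["down"] & members)
                    sign = float(np.sign(k_up - k_down))
                rows.append(
                    EnrichmentResult(
                        set_name=name,
                        time_index=t,
                        direction=direction,
                        background=N,
                        set_size=K,
                        selected=n,
                        overlap=k,
                        p_value=p,
                        signed_score=-np.log10(p) * sign,
                    )
                )
    df = pd.DataFrame([r.__dict__ for r in rows])
    if df.empty:
        return pd.DataFrame(
            columns=[
                "set_name", "time_index", "direction", "background",
                "set_size", "selected", "overlap", "p_value",
                "signed_score", "bh_fdr_extra",
            ]
        )
    df = df.sort_values(["time_index", "direction", "p_value"]).reset_index(
        drop=True
    )
    df["bh_fdr_extra"] = _benjamini_hochberg(df["p_value"].to_numpy())
    return df


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Step-up BH adjusted p-values (extra column, not used for selection)."""
    m = p.size
    order = np.argsort(p)
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def signed_score_matrix(results: pd.DataFrame, direction: str = "any") -> pd.DataFrame:
    """Sets x time points matrix of signed -log10 p for heatmap export."""
    sub = results[results["direction"] == direction]
    if sub.empty:
        return pd.DataFrame()
    mat = sub.pivot_table(
        index="set_name", columns="time_index", values="signed_score",
        fill_value=0.0,
    )
    mat.columns = [f"t{c + 1}" for c in mat.columns]
    return mat.reset_index()


def plot_heatmap(matrix: pd.DataFrame, path=None):
    """Optional signed-score heatmap plot."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = matrix.set_index("set_name").to_numpy(float)
    fig, ax = plt.subplots(
        figsize=(1.2 * data.shape[1] + 3, 0.3 * data.shape[0] + 2)
    )
    vmax = max(1.0, np.abs(data).max())
    im = ax.imshow(data, cmap="RdBu_r", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_yticks(range(data.shape[0]))
    ax.set_yticklabels(matrix["set_name"], fontsize=7)
    ax.set_xticks(range(data.shape[1]))
    ax.set_xticklabels(matrix.columns[1:], fontsize=7)
    fig.colorbar(im, ax=ax, label="signed -log10 p")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
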