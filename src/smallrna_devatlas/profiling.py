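"""Stage-profile statistics for the miRNA expression matrix.

Z-standardization is per row: Z = (X - Avg) / SD with Avg and SD taken over
that row's developmental stages and SD the *population* standard deviation;
all-constant rows get Z = 0 by convention.  Clustering is agglomerative with
complete linkage, D(A,B) = max pairwise member distance, implemented here
with explicit deterministic tie-breaking (smallest original cluster index
first) so runs are exactly reproducible; scipy's implementation serves as an
independent cross-check in the test suite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "zscore_matrix",
    "complete_linkage_cluster",
    "replicate_correlation",
    "abundance_tiers",
    "categorize_pattern",
    "categorize_matrix",
    "plot_heatmap",
]


def zscore_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-row Z-scores over stages; rows with zero SD become all-zero."""
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 stage columns to standardize")
    values = matrix.to_numpy(dtype=float)
    avg = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    z = np.zeros_like(values)
    nz = sd[:, 0] > 0
    z[nz] = (values[nz] - avg[nz]) / sd[nz]
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)


def _distance_matrix(rows: np.ndarray, metric: str) -> np.ndarray:
    if metric == "euclidean":
        return squareform(pdist(rows, metric="euclidean"))
    if metric == "correlation":
        return squareform(pdist(rows, metric="correlation"))
    raise ValueError(f"unknown metric {metric!r}")


def complete_linkage_cluster(
    rows: np.ndarray | pd.DataFrame, metric: str = "euclidean"
) -> tuple[np.ndarray, list[int]]:
    """Agglomerative complete-linkage clustering.

    Returns ``(linkage, leaf_order)``.  ``linkage`` has one row per merge:
    (cluster_a, cluster_b, height, size) with original rows numbered
    0..n-1 and merged clusters n, n+1, ...  At every step the pair with the
    smallest complete-linkage distance merges; ties break toward the smallest
    (a, b) index pair.  Leaf order comes from a recursive traversal putting
    the lower-index subtree first.
    """
    X = rows.to_numpy(dtype=float) if isinstance(rows, pd.DataFrame) else np.asarray(
        rows, dtype=float
    )
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 rows")
    if not np.isfinite(X).all():
        raise ValueError("matrix contains non-finite values")
    n = X.shape[0]
    D = _distance_matrix(X, metric)
    active: dict[int, list[int]] = {i: [i] for i in range(n)}
    dist: dict[tuple[int, int], float] = {
        (i, j): D[i, j] for i in range(n) for j in range(i + 1, n)
    }
    children: dict[int, tuple[int, int]] = {}
    linkage = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        (a, b), h = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        members = active[a] + active[b]
        del active[a], active[b]
        dist = {k: v for k, v in dist.items() if a not in k and b not in k}
        for c, cm in active.items():
            d = max(D[i, j] for i in members for j in cm)
            dist[(min(c, next_id), max(c, next_id))] = d
        active[next_id] = members
        children[next_id] = (a, b)
        linkage[step] = (a, b, h, len(members))
        next_id += 1

    def leaves(node: int) -> list[int]:
        if node < n:
            return [node]
        a, b = children[node]
        lo, hi = (a, b) if a < b else (b, a)
        return leaves(lo) + leaves(hi)

    return linkage, leaves(next_id - 1)


def replicate_correlation(
    counts1: pd.Series | dict, counts2: pd.Series | dict
) -> float:
    """Pearson r between replicates on log10(count + 1).

    The two count vectors are aligned on the union of detected ids (missing
    = 0) before the log transform.
    """
    s1, s2 = pd.Series(counts1, dtype=float), pd.Series(counts2, dtype=float)
    idx = s1.index.union(s2.index)
    if len(idx) < 3:
        raise ValueError("need >= 3 shared points for a correlation")
    x = np.log10(s1.reindex(idx, fill_value=0.0).to_numpy() + 1.0)
    y = np.log10(s2.reindex(idx, fill_value=0.0).to_numpy() + 1.0)
    return float(stats.pearsonr(x, y)[0])


def abundance_tiers(
    matrix: pd.DataFrame, thresholds: tuple[float, ...] = (300.0, 1000.0)
) -> dict:
    """Per-stage counts above each TPM threshold (strict), plus cross-stage
    summaries: rows > first threshold in more than one stage, and rows below
    it at every stage."""
    t0 = thresholds[0]
    per_stage = {
        thr: (matrix > thr).sum(axis=0) for thr in thresholds
    }
    above_t0 = (matrix > t0).sum(axis=1)
    return {
        "per_stage": per_stage,
        "gt_first_threshold_multi_stage": int((above_t0 >= 2).sum()),
        "lt_first_threshold_all_stages": int((matrix < t0).all(axis=1).sum()),
    }


def categorize_pattern(
    series: np.ndarray | pd.Series,
    rho_threshold: float = 0.7,
    prominence: float = 2.0,
) -> str:
    """Assign a developmental expression archetype to one stage series.

    Monotone trends are called by Spearman correlation with stage index
    (|rho| >= ``rho_threshold``); otherwise a strictly interior extremum
    qualifies as mid_peak when the peak reaches ``prominence`` times the mean
    of the two endpoint values (mid_trough symmetric, trough at most the
    endpoint mean divided by ``prominence``); everything else is flat, the
    explicit residual class.
    """
    y = np.asarray(series, dtype=float)
    if y.size < 4:
        raise ValueError("need >= 4 stages to categorize a pattern")
    rho = stats.spearmanr(np.arange(y.size), y)[0]
    if np.isnan(rho):
        rho = 0.0
    if rho >= rho_threshold:
        return "increasing"
    if rho <= -rho_threshold:
        return "decreasing"
    end_mean = (y[0] + y[-1]) / 2.0
    k = int(np.argmax(y))
    if 0 < k < y.size - 1 and y[k] >= prominence * end_mean and end_mean >= 0:
        return "mid_peak"
    k = int(np.argmin(y))
    if 0 < k < y.size - 1 and end_mean > 0 and y[k] <= end_mean / prominence:
        return "mid_trough"
    return "flat"


def categorize_matrix(matrix: pd.DataFrame, **kwargs) -> pd.Series:
    return pd.Series(
        {rid: categorize_pattern(row.to_numpy(), **kwargs) for rid, row in matrix.iterrows()},
        name="pattern",
    )


def plot_heatmap(
    z: pd.DataFrame, leaf_order: list[int], path: str
) -> None:
    """Clustered Z-score heatmap (red = high, green = low)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ordered = z.iloc[leaf_order]
    fig, ax = plt.subplots(
        figsize=(max(4, 0.5 * z.shape[1] + 2), max(4, 0.12 * z.shape[0]))
    )
    im = ax.imshow(ordered.to_numpy(), aspect="auto", cmap="RdYlGn_r")
    ax.set_xticks(range(z.shape[1]), labels=list(z.columns), rotation=90)
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="Z score")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
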