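"""Cross-study fold-change matrix and hierarchical clustering.

The matrix holds log2 case/control ratios of the overlapping features,
with missing cells where a study did not report a feature. Distances
use pairwise-complete observations (Euclidean, rescaled by the fraction
of shared columns, as R's ``dist`` does under NA handling) and average
linkage by default; the defaults are recorded in every output header.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from fabrymeta.errors import ValidationError

logger = logging.getLogger(__name__)


def build_matrix(
    features: pd.DataFrame,
    overlap_clusters,
    studies: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the log2-ratio matrix of the overlapping features.

    Rows are cluster_ids, columns study_ids, values log2(ratio); cells a
    study did not report are NaN. Rows with fewer than two observed
    values are dropped with a warning. Returns ``(matrix, annotations)``
    where annotations carry fluid and group per study column.
    """
    overlap_clusters = list(overlap_clusters)
    if not overlap_clusters:
        raise ValidationError("overlap subset is empty")
    sub = features[features["cluster_id"].isin(overlap_clusters)].copy()
    sub["log2_ratio"] = np.log2(sub["ratio"].to_numpy(dtype=float))
    matrix = sub.pivot_table(index="cluster_id", columns="study_id",
                             values="log2_ratio", aggfunc="mean")
    matrix = matrix.reindex(index=sorted(set(sub["cluster_id"])),
                            columns=sorted(set(sub["study_id"])))
    thin = matrix.notna().sum(axis=1) < 2
    if thin.any():
        logger.warning("dropping %d matrix row(s) with < 2 observed "
                       "values: %s", int(thin.sum()),
                       sorted(matrix.index[thin]))
        matrix = matrix[~thin]
    meta = studies.set_index("study_id")
    annotations = pd.DataFrame({
        "fluid": [meta.loc[s, "fluid"] for s in matrix.columns],
        "group": [meta.loc[s, "group"] for s in matrix.columns],
    }, index=matrix.columns)
    return matrix, annotations


def filter_pairwise_complete(
    matrix: pd.DataFrame,
    min_overlap: int = 2,
) -> tuple[pd.DataFrame, list[str]]:
    """Drop rows until every pair shares >= min_overlap observed columns.

    Greedy: repeatedly remove the row involved in the most violating
    pairs (ties broken by fewest observed values, then label), so the
    densest rows survive. Returns the filtered matrix and the dropped
    row labels.
    """
    obs = matrix.notna().to_numpy()
    labels = list(matrix.index)
    shared = obs.astype(int) @ obs.astype(int).T
    np.fill_diagonal(shared, min_overlap)
    keep = list(range(len(labels)))
    dropped: list[str] = []
    while True:
        sub = shared[np.ix_(keep, keep)]
        violations = (sub < min_overlap).sum(axis=1)
        if not violations.any():
            break
        n_obs = obs[keep].sum(axis=1)
        worst = max(range(len(keep)),
                    key=lambda i: (violations[i], -n_obs[i], labels[keep[i]]))
        dropped.append(labels[keep[worst]])
        del keep[worst]
    if dropped:
        logger.warning("dropping %d matrix row(s) with insufficient "
                       "pairwise overlap: %s", len(dropped), sorted(dropped))
    return matrix.iloc[keep], dropped


def pairwise_complete_distances(
    X: np.ndarray,
    metric: str = "euclidean",
    min_overlap: int = 2,
    labels=None,
) -> np.ndarray:
    """Square distance matrix over rows using pairwise-complete columns.

    Euclidean sums of squares over the shared columns are rescaled by
    p/m (p total columns, m shared) before the square root, so rows with
    different missingness stay comparable. A pair sharing fewer than
    ``min_overlap`` observed columns is an error naming the rows.
    """
    if metric != "euclidean":
        raise ValidationError(f"unsupported metric {metric!r}")
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    labels = list(labels) if labels is not None else list(range(n))
    D = np.zeros((n, n))
    obs = ~np.isnan(X)
    for i in range(n):
        for j in range(i + 1, n):
            shared = obs[i] & obs[j]
            m = int(shared.sum())
            if m < min_overlap:
                raise ValidationError(
                    f"rows {labels[i]!r} and {labels[j]!r} share only {m} "
                    f"observed column(s); need >= {min_overlap}")
            ss = float(np.sum((X[i, shared] - X[j, shared]) ** 2))
            D[i, j] = D[j, i] = np.sqrt(ss * p / m)
    return D


@dataclass(frozen=True)
class LinkageTree:
    """Agglomeration result: scipy-format merge table plus leaf labels.

    ``merges`` rows are (node_a, node_b, height, size); leaves 0..n-1
    are the input rows in order, internal node i is merge row i - n.
    """

    merges: np.ndarray
    labels: tuple[str, ...]
    leaf_order: tuple[int, ...]

    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


def hcluster(
    matrix: pd.DataFrame,
    axis: str = "rows",
    metric: str = "euclidean",
    method: str = "average",
    min_overlap: int = 2,
) -> LinkageTree:
    """Hierarchically cluster matrix rows or columns.

    Distances are pairwise-complete (see
    :func:`pairwise_complete_distances`); identical rows merge at height
    zero first, and the tree is deterministic for a fixed input (ties
    resolved by input index).
    """
    if axis not in ("rows", "columns"):
        raise ValidationError("axis must be 'rows' or 'columns'")
    data = matrix if axis == "rows" else matrix.T
    labels = tuple(str(x) for x in data.index)
    if len(labels) < 2:
        raise ValidationError("need at least two observations to cluster")
    D = pairwise_complete_distances(data.to_numpy(dtype=float),
                                    metric=metric, min_overlap=min_overlap,
                                    labels=labels)
    Z = linkage(squareform(D, checks=False), method=method)
    order = tuple(int(i) for i in leaves_list(Z))
    return LinkageTree(Z, labels, order)


def linkage_table(tree: LinkageTree) -> pd.DataFrame:
    """Merge list as a table: node ids, height and cluster size."""
    n = len(tree.labels)
    rows = []
    for i, (a, b, h, size) in enumerate(tree.merges):
        def name(idx):
            idx = int(idx)
            return tree.labels[idx] if idx < n else f"node{idx - n}"
        rows.append((f"node{i}", name(a), name(b), float(h), int(size)))
    return pd.DataFrame(rows, columns=["merge", "left", "right",
                                       "height", "size"])


def plot_heatmap(
    matrix: pd.DataFrame,
    annotations: pd.DataFrame,
    path,
    row_tree: LinkageTree | None = None,
) -> None:
    """Heatmap of log2 ratios, diverging around 0 (blue down, red up),
    with fluid/group annotation bars under the columns."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = matrix.copy()
    if row_tree is not None:
        data = data.iloc[list(row_tree.leaf_order)]
    vmax = float(np.nanmax(np.abs(data.to_numpy()))) or 1.0
    fig, axes = plt.subplots(
        2, 1, figsize=(1.2 + 0.5 * data.shape[1], 1.5 + 0.3 * data.shape[0]),
        gridspec_kw={"height_ratios": [data.shape[0], 2]}, sharex=True)
    im = axes[0].imshow(data.to_numpy(), cmap="RdBu_r", vmin=-vmax,
                        vmax=vmax, aspect="auto", interpolation="nearest")
    axes[0].set_yticks(range(data.shape[0]), data.index)
    fig.colorbar(im, ax=axes[0], label="log2 ratio")
    fluid_colors = {"urine": "#b8e0b8", "blood": "#e0b8b8"}
    group_colors = {"naive": "#f2c894", "ERT": "#8a8a8a"}
    bar = np.zeros((2, data.shape[1], 3))
    for j, study in enumerate(data.columns):
        bar[0, j] = matplotlib.colors.to_rgb(
            fluid_colors[annotations.loc[study, "fluid"]])
        bar[1, j] = matplotlib.colors.to_rgb(
            group_colors[annotations.loc[study, "group"]])
    axes[1].imshow(bar, aspect="auto", interpolation="nearest")
    axes[1].set_yticks([0, 1], ["fluid", "group"])
    axes[1].set_xticks(range(data.shape[1]), data.columns, rotation=90)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
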