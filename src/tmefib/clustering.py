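"""PCA and hierarchical clustering on principal components (HCPC).

The thirteen fiber morphology metrics per tumor are standardized (the
metrics mix incommensurate units), decomposed by PCA, and samples are
agglomerated with Ward linkage on Euclidean distances in the retained-PC
space.  Clusters are characterized per metric on the original scale by
one-way ANOVA (eta squared and the F-test p) and by the standardized
difference of the cluster mean from the grand mean.  TIL distributions are
compared between clusters pairwise with the Mann-Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy

from .stats import mann_whitney_u

__all__ = [
    "PCAModel",
    "FibrillaryClusterModel",
    "fit_pca",
    "variable_contributions",
    "hcpc",
    "characterize_clusters",
    "cluster_til_comparison",
    "linkage_to_newick",
]


@dataclass
class PCAModel:
    center: pd.Series
    scale: pd.Series
    loadings: pd.DataFrame  # (n_metrics, n_pcs), columns PC1..
    explained_variance_ratio: np.ndarray
    coordinates: pd.DataFrame  # (n_samples, n_pcs)
    standardized: bool
    dropped_constant: tuple = ()

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def cumulative_variance(self, k: int) -> float:
        return float(self.explained_variance_ratio[:k].sum())


def fit_pca(metrics: pd.DataFrame, standardize: bool = True) -> PCAModel:
    """PCA of a metrics table (rows = samples).

    Columns are centered and, by default, scaled to unit variance; constant
    columns are dropped with a warning note in ``dropped_constant``.  Loading
    signs are fixed so each component's largest-magnitude entry is positive.
    Requires at least 3 complete rows.
    """
    df = metrics.dropna()
    if len(df) < 3:
        raise ValueError("PCA requires at least 3 complete rows")
    sd = df.std(ddof=1)
    dropped = tuple(sd.index[sd == 0])
    df = df.drop(columns=list(dropped))
    if df.shape[1] == 0:
        raise ValueError("all columns constant")
    center = df.mean()
    scale = df.std(ddof=1) if standardize else pd.Series(1.0, index=df.columns)
    Z = (df - center) / scale
    u, s, vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
    # sign convention: largest |loading| positive per component
    for i in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] = -vt[i]
            u[:, i] = -u[:, i]
    var = s**2 / (len(df) - 1)
    evr = var / var.sum()
    pcs = [f"PC{i + 1}" for i in range(len(s))]
    loadings = pd.DataFrame(vt.T, index=df.columns, columns=pcs)
    coords = pd.DataFrame(u * s, index=df.index, columns=pcs)
    return PCAModel(
        center=center,
        scale=scale,
        loadings=loadings,
        explained_variance_ratio=evr,
        coordinates=coords,
        standardized=standardize,
        dropped_constant=dropped,
    )


def variable_contributions(model: PCAModel, pc: int = 1) -> pd.DataFrame:
    """Percent contribution of each metric to one PC (sums to 100).

    ``above_uniform`` flags metrics exceeding the uniform expectation
    100 / n_metrics — the dashed-line convention of contribution barplots.
    """
    col = f"PC{pc}"
    load = model.loadings[col].to_numpy()
    contrib = 100.0 * load**2 / (load**2).sum()
    uniform = 100.0 / len(load)
    return pd.DataFrame(
        {
            "contribution_pct": contrib,
            "above_uniform": contrib > uniform,
        },
        index=model.loadings.index,
    ).sort_values("contribution_pct", ascending=False)


@dataclass
class FibrillaryClusterModel:
    pca: PCAModel
    retained: int
    cumulative_variance: float
    linkage: np.ndarray
    labels: pd.Series  # 1..k, ordered by cluster size (largest = 1)
    k: int
    characterization: pd.DataFrame


def _canonical_labels(raw: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..k by decreasing size; ties by lowest row index."""
    order = sorted(
        np.unique(raw),
        key=lambda c: (-(raw == c).sum(), int(np.argmax(raw == c))),
    )
    remap = {c: i + 1 for i, c in enumerate(order)}
    return np.array([remap[c] for c in raw])


def hcpc(
    model: PCAModel,
    k: int = 3,
    retain: int | float = 7,
    metrics: pd.DataFrame | None = None,
) -> FibrillaryClusterModel:
    """Ward clustering in retained-PC space, cut at ``k`` clusters.

    ``retain`` is either a PC count (int) or a cumulative-variance threshold
    in (0, 1].  Characterization (per-metric ANOVA across clusters) is
    computed on the original metric scale when ``metrics`` is provided.
    """
    if isinstance(retain, float) and 0 < retain <= 1:
        csum = np.cumsum(model.explained_variance_ratio)
        n_retain = int(np.searchsorted(csum, retain) + 1)
    else:
        n_retain = int(retain)
    n_retain = min(n_retain, model.n_components)
    coords = model.coordinates.iloc[:, :n_retain].to_numpy()
    if k > len(coords):
        raise ValueError(f"k={k} exceeds {len(coords)} samples")
    Z = hierarchy.ward(coords)
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    labels = pd.Series(
        _canonical_labels(raw), index=model.coordinates.index, name="cluster"
    )
    if k == 1 or metrics is None:
        charac = pd.DataFrame(
            columns=["metric", "cluster", "cluster_mean", "overall_mean",
                     "direction", "smd", "eta_sq", "f_p"]
        )
    else:
        charac = characterize_clusters(metrics.loc[labels.index], labels)
    return FibrillaryClusterModel(
        pca=model,
        retained=n_retain,
        cumulative_variance=model.cumulative_variance(n_retain),
        linkage=Z,
        labels=labels,
        k=k,
        characterization=charac,
    )


def characterize_clusters(metrics: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Per-metric one-way ANOVA across clusters plus per-cluster directions.

    For each metric: eta^2 = between-SS / total-SS and the F-test p; for each
    (metric, cluster): the cluster mean, grand mean, standardized mean
    difference and its sign.  Rows are sorted by eta^2 descending.
    """
    rows = []
    uniq = sorted(labels.unique())
    for m in metrics.columns:
        v = metrics[m].to_numpy(dtype=float)
        ok = ~np.isnan(v)
        v, lab = v[ok], labels.to_numpy()[ok]
        grand = v.mean()
        groups = [v[lab == c] for c in uniq]
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups if len(g))
        ss_total = ((v - grand) ** 2).sum()
        eta_sq = ss_between / ss_total if ss_total > 0 else 0.0
        if ss_total > 0 and all(len(g) > 1 for g in groups):
            f, p = sps.f_oneway(*groups)
            if np.isnan(p):
                p = 1.0
        else:
            p = 1.0
        sd = v.std(ddof=1) if len(v) > 1 else 0.0
        for c, g in zip(uniq, groups):
            if not len(g):
                continue
            diff = g.mean() - grand
            rows.append(
                {
                    "metric": m,
                    "cluster": int(c),
                    "cluster_mean": float(g.mean()),
                    "overall_mean": float(grand),
                    "direction": "up" if diff > 0 else ("down" if diff < 0 else "flat"),
                    "smd": float(diff / sd) if sd > 0 else 0.0,
                    "eta_sq": float(eta_sq),
                    "f_p": float(p),
                }
            )
    return (
        pd.DataFrame(rows)
        .sort_values(["eta_sq", "metric", "cluster"], ascending=[False, True, True])
        .reset_index(drop=True)
    )


def cluster_til_comparison(til_counts: pd.Series, labels: pd.Series) -> pd.DataFrame:
    """Pairwise Mann-Whitney U of TIL counts between clusters (+ medians)."""
    uniq = sorted(labels.unique())
    rows = []
    for i, a in enumerate(uniq):
        for b in uniq[i + 1 :]:
            xa = til_counts[labels == a].to_numpy()
            xb = til_counts[labels == b].to_numpy()
            u, p = mann_whitney_u(xa, xb)
            rows.append(
                {
                    "cluster_a": int(a),
                    "cluster_b": int(b),
                    "median_a": float(np.median(xa)),
                    "median_b": float(np.median(xb)),
                    "n_a": len(xa),
                    "n_b": len(xb),
                    "U": u,
                    "p": p,
                }
            )
    return pd.DataFrame(
        rows, columns=["cluster_a", "cluster_b", "median_a", "median_b", "n_a", "n_b", "U", "p"]
    )


def linkage_to_newick(Z: np.ndarray, leaf_names) -> str:
    """Scipy linkage matrix -> Newick string with branch lengths."""
    tree = hierarchy.to_tree(Z)
    names = list(leaf_names)

    def rec(node, parent_dist):
        if node.is_leaf():
            return f"{names[node.id]}:{parent_dist - node.dist:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{parent_dist - node.dist:.6g}"

    return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"
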