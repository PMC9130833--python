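"""Correlation, PCA outlier screening, and clustering of tissue expression profiles.

All operations work on log2(FPKM + 1); correlations are Pearson with the exact
t-transform two-sided p-value, outliers are flagged by a median + k*MAD rule on
distances to the tissue centroid in (PC1, PC2), and tissues are clustered by
average linkage on 1 - Pearson correlation.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA

from .data_model import ExpressionMatrix, TissueProfileMatrix


def log2p1(values: pd.DataFrame | TissueProfileMatrix) -> pd.DataFrame:
    """Elementwise log2(x + 1)."""
    df = values.means if isinstance(values, TissueProfileMatrix) else values
    return np.log2(df + 1.0)


def tissue_correlations(
    transformed: pd.DataFrame,
    genes: Iterable[str] | None = None,
    tissues: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Pairwise Pearson correlation between tissue columns over a gene subset.

    Returns a long data frame (tissue_a, tissue_b, r, p, n) for each unordered
    pair; p is the two-sided t-transform p-value with n - 2 degrees of
    freedom.  A zero-variance profile yields r = NaN (reported missing).
    """
    sub = transformed
    if genes is not None:
        sub = sub.loc[sorted(set(genes) & set(sub.index))]
    if tissues is not None:
        sub = sub[list(tissues)]
    if len(sub) < 3:
        raise ValueError("correlation needs >= 3 genes")
    cols = list(sub.columns)
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            x, y = sub[a].to_numpy(), sub[b].to_numpy()
            if x.std() == 0 or y.std() == 0:
                r, p = float("nan"), float("nan")
            else:
                r, p = stats.pearsonr(x, y)
            rows.append({"tissue_a": a, "tissue_b": b, "r": r, "p": p, "n": len(sub)})
    return pd.DataFrame(rows)


def correlation_matrix(pairs: pd.DataFrame) -> pd.DataFrame:
    """Symmetric unit-diagonal r matrix from the long pair table."""
    tissues = sorted(set(pairs["tissue_a"]) | set(pairs["tissue_b"]))
    mat = pd.DataFrame(np.eye(len(tissues)), index=tissues, columns=tissues)
    for _, row in pairs.iterrows():
        mat.loc[row["tissue_a"], row["tissue_b"]] = row["r"]
        mat.loc[row["tissue_b"], row["tissue_a"]] = row["r"]
    return mat


def pca_outlier_screen(em: ExpressionMatrix, k_mads: float = 3.0) -> pd.DataFrame:
    """Flag replicate samples far from their tissue centroid in PCA space.

    PCA is run on log2(FPKM + 1) with genes centred; each sample's Euclidean
    distance to its tissue centroid in (PC1, PC2) is compared against
    median + k_mads * MAD of all within-tissue distances (tissues with a
    single sample contribute distance 0 and are never flagged).  Invariant to
    gene and sample order.
    """
    if len(em.sample_ids) < 3:
        raise ValueError("PCA outlier screening needs >= 3 samples")
    order = sorted(em.sample_ids)
    X = np.log2(em.values[order].to_numpy(dtype=float).T + 1.0)
    X = X - X.mean(axis=0, keepdims=True)
    # deterministic full SVD; PC sign is irrelevant to centroid distances
    coords = PCA(n_components=2, svd_solver="full").fit_transform(X)
    df = pd.DataFrame(
        {
            "sample": order,
            "tissue": [em.sample_tissue[s] for s in order],
            "pc1": coords[:, 0],
            "pc2": coords[:, 1],
        }
    )
    dist = np.zeros(len(df))
    multi = np.zeros(len(df), dtype=bool)
    for _, idx in df.groupby("tissue").groups.items():
        pts = coords[np.asarray(idx)]
        centroid = pts.mean(axis=0)
        dist[np.asarray(idx)] = np.linalg.norm(pts - centroid, axis=1)
        multi[np.asarray(idx)] = len(idx) > 1
    med = np.median(dist[multi]) if multi.any() else 0.0
    mad = stats.median_abs_deviation(dist[multi]) if multi.any() else 0.0
    threshold = med + k_mads * mad
    df["distance"] = dist
    df["flagged"] = multi & (dist > threshold)
    return df


def cluster_tissues(
    transformed: pd.DataFrame,
    genes: Iterable[str] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Average-linkage clustering of tissue columns, distance 1 - Pearson r.

    Returns (scipy linkage matrix, tissue labels in column order).  Tiny
    negative distances from float error are clipped to 0.
    """
    sub = transformed
    if genes is not None:
        sub = sub.loc[sorted(set(genes) & set(sub.index))]
    if sub.shape[1] < 2:
        raise ValueError("clustering needs >= 2 tissues")
    labels = list(sub.columns)
    r = np.corrcoef(sub.to_numpy(dtype=float).T)
    d = np.clip(1.0 - r, 0.0, None)
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="average")
    return z, labels


def dendrogram_newick(z: np.ndarray, labels: Sequence[str]) -> str:
    """Newick string (with branch lengths) for a scipy linkage matrix."""
    tree = to_tree(z)

    def render(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left, right = node.get_left(), node.get_right()
        return (
            f"({render(left)}:{node.dist - left.dist:.6g},"
            f"{render(right)}:{node.dist - right.dist:.6g})"
        )

    return render(tree) + ";"


def forms_clade(z: np.ndarray, labels: Sequence[str], subset: Iterable[str]) -> bool:
    """True iff ``subset`` is exactly the leaf set of some node of the dendrogram."""
    want = set(subset)
    if not want <= set(labels):
        raise ValueError("subset contains unknown tissue labels")

    tree = to_tree(z)
    found = False

    def leaves(node) -> set[str]:
        nonlocal found
        if node.is_leaf():
            return {labels[node.id]}
        s = leaves(node.get_left()) | leaves(node.get_right())
        if s == want:
            found = True
        return s

    all_leaves = leaves(tree)
    return found or want == all_leaves or (len(want) == 1 and want <= all_leaves)
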