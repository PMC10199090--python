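"""Sample-level quality control: PCA, outlier screening, clustering, CV.

The study screens samples on principal components of the log-CPM matrix
(human PCs are dominated by donor; mouse PCs by time in culture and medium)
and excludes samples far from the bulk.  The outlier rule here is an
explicit, parameterised criterion — a robust per-component z-score
(deviation from the component median in MAD units) over the leading
components — since the original screening was visual.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import median_abs_deviation

from .de import ExpressionMatrix

__all__ = [
    "PCAResult",
    "run_pca",
    "flag_outliers",
    "top_loadings",
    "ClusteringResult",
    "hierarchical_cluster",
    "cv_by_condition",
]


@dataclass
class PCAResult:
    """Exact PCA of a gene-centred expression matrix.

    ``scores`` is samples x components, ``loadings`` genes x components,
    ``variance_explained`` the fraction of total variance per kept component.
    Component sign is fixed so the gene with the largest |loading| has a
    positive loading.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_explained: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def run_pca(expr: ExpressionMatrix, n_components: int = 10) -> PCAResult:
    """PCA via SVD of the gene-centred matrix; deterministic sign convention."""
    X = expr.values.to_numpy().T  # samples x genes
    n, p = X.shape
    if n < 2 or p < 2:
        raise ValueError("need at least 2 samples and 2 genes")
    if n_components > min(n, p):
        raise ValueError(
            f"n_components={n_components} exceeds min(samples, genes)={min(n, p)}"
        )
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # fix sign: largest-|loading| gene positive on each component
    for j in range(n_components):
        g = np.argmax(np.abs(Vt[j]))
        if Vt[j, g] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    total = float((S**2).sum())
    frac = (S[:n_components] ** 2) / total if total > 0 else np.zeros(n_components)
    comp_names = [f"PC{j + 1}" for j in range(n_components)]
    scores = pd.DataFrame(
        U[:, :n_components] * S[:n_components], index=expr.sample_ids, columns=comp_names
    )
    loadings = pd.DataFrame(Vt[:n_components].T, index=expr.gene_ids, columns=comp_names)
    return PCAResult(scores=scores, loadings=loadings, variance_explained=frac)


def flag_outliers(
    pca: PCAResult, n_pcs: int = 3, mad_mult: float = 5.0
) -> pd.DataFrame:
    """Robust outlier screen on the leading principal components.

    A sample is flagged iff on any of the top ``n_pcs`` components its score
    deviates from the component median by more than ``mad_mult`` x MAD, with
    the MAD scaled by the usual normal-consistency factor 1.4826 (the
    convention of R's ``mad()``), so the rule reads as a robust z-score
    threshold.  Returns one row per sample: the maximal robust distance (in
    consistent-MAD units), the flag, and the parameters used.  A zero-MAD
    component is skipped with a warning.
    """
    n_pcs = min(n_pcs, pca.n_components)
    S = pca.scores.iloc[:, :n_pcs].to_numpy()
    dist = np.zeros((S.shape[0], 0))
    used = []
    for j in range(n_pcs):
        med = np.median(S[:, j])
        mad = median_abs_deviation(S[:, j], scale="normal")
        if mad == 0:
            warnings.warn(f"MAD of PC{j + 1} is zero; component skipped", stacklevel=2)
            continue
        dist = np.hstack([dist, (np.abs(S[:, j] - med) / mad)[:, None]])
        used.append(f"PC{j + 1}")
    if dist.shape[1] == 0:
        rd = np.zeros(S.shape[0])
    else:
        rd = dist.max(axis=1)
    return pd.DataFrame(
        {
            "sample_id": pca.scores.index,
            "robust_distance": rd,
            "outlier": rd > mad_mult,
            "n_pcs": dist.shape[1],
            "mad_mult": mad_mult,
            "components": ",".join(used),
        }
    ).reset_index(drop=True)


def top_loadings(pca: PCAResult, component: int = 1, k: int = 20) -> pd.DataFrame:
    """Top-k genes by |loading| on one component (1-based); ties by gene id."""
    name = f"PC{component}"
    if name not in pca.loadings.columns:
        raise ValueError(f"component {component} not computed")
    tab = pd.DataFrame(
        {
            "gene_id": pca.loadings.index,
            "loading": pca.loadings[name].to_numpy(),
        }
    )
    tab["abs_loading"] = tab["loading"].abs()
    tab = tab.sort_values(
        ["abs_loading", "gene_id"], ascending=[False, True], kind="mergesort"
    )
    return tab.head(min(k, len(tab))).reset_index(drop=True)


@dataclass
class ClusteringResult:
    """Agglomerative sample clustering (Euclidean, complete linkage)."""

    linkage: np.ndarray
    sample_ids: list[str]

    def leaf_order(self) -> list[str]:
        return [self.sample_ids[i] for i in hierarchy.leaves_list(self.linkage)]

    def cut(self, n_clusters: int) -> pd.Series:
        labels = hierarchy.fcluster(self.linkage, n_clusters, criterion="maxclust")
        return pd.Series(labels, index=self.sample_ids, name="cluster")

    def newick(self) -> str:
        """Nested-parenthesis (Newick) text with merge-height branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.sample_ids[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"


def hierarchical_cluster(expr: ExpressionMatrix) -> ClusteringResult:
    """Complete-linkage clustering of samples on Euclidean log-CPM distance."""
    X = expr.values.to_numpy().T
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples to cluster")
    Z = hierarchy.linkage(X, method="complete", metric="euclidean")
    return ClusteringResult(linkage=Z, sample_ids=list(expr.sample_ids))


def cv_by_condition(
    values: pd.DataFrame, metadata: pd.DataFrame, values_are_log2: bool = True
) -> pd.DataFrame:
    """Coefficient of variation per gene per (medium, timepoint) group.

    CV = sample SD (n-1 denominator) / mean on the linear scale; log2 input
    (the default, matching log-CPM) is exponentiated first, raw counts can be
    passed with ``values_are_log2=False``.  Groups need >= 2 included
    samples; zero-mean cells are emitted as NaN.
    """
    meta = metadata[metadata["status"] == "included"]
    group = meta["medium"].astype(str) + "_" + meta["timepoint_h"].astype(str) + "h"
    out = {}
    for g, sub in meta.groupby(group.to_numpy()):
        cols = [s for s in sub["sample_id"] if s in values.columns]
        if len(cols) < 2:
            continue
        block = values[cols].to_numpy(dtype=float)
        if values_are_log2:
            block = np.exp2(block)
        mean = block.mean(axis=1)
        sd = block.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.where(mean != 0, sd / mean, np.nan)
        out[g] = cv
    return pd.DataFrame(out, index=values.index)
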