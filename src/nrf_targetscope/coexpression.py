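"""Tissue co-expression coherence of a target gene set.

Within each tissue, pairwise correlations between the log2(+1) expression
levels of the gene set across donors are computed and each gene's row of
correlation coefficients is clustered into k groups (k-means with restarts, or
average-linkage hierarchical as an alternative). The "core" cluster — the one
with the highest mean intra-cluster correlation — anchors a per-gene coherence
class: genes whose mean correlation to the core is at least tau_pos are
"correlated", those at or below tau_neg are "anti-correlated", the rest
"unclassified". A reference tissue's cluster-sorted gene order can be imposed
on all tissues for side-by-side matrix display.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans

from .differential_expression import ExpressionMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class CorrelationMatrix:
    gene_ids: list[str]
    values: np.ndarray
    tissue: str
    method: str = "pearson"
    n_samples: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.gene_ids)
        if self.values.shape != (n, n):
            raise ValueError("correlation matrix must be square over gene_ids")
        if not np.array_equal(self.values, self.values.T):
            raise ValueError("correlation matrix must be exactly symmetric")
        if not np.allclose(np.diag(self.values), 1.0, rtol=0, atol=0):
            raise ValueError("correlation matrix must have a unit diagonal")
        if np.abs(self.values).max() > 1.0:
            raise ValueError("correlations must lie in [-1, 1]")


@dataclass
class TissueResult:
    """Per-tissue correlation matrix with cluster labels and coherence classes."""

    matrix: CorrelationMatrix
    labels: np.ndarray
    classes: dict[str, str] = field(default_factory=dict)


@dataclass
class CoexpressionResult:
    tissues: dict[str, TissueResult]
    reference: str
    display_order: list[str]
    assignment: pd.DataFrame
    ordered_matrices: dict[str, pd.DataFrame]


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------


def correlation_matrix(
    panel: ExpressionMatrix,
    gene_set: list[str],
    method: str = "pearson",
    min_samples: int = 10,
) -> CorrelationMatrix:
    """Pairwise gene-gene correlations over donors on log2(abundance + 1).

    Genes absent from the panel or with zero variance across donors are
    dropped (logged). The result is forced exactly symmetric with a unit
    diagonal.
    """
    if panel.n_samples < min_samples:
        raise ValueError(
            f"tissue panel has {panel.n_samples} donors; need >= {min_samples}"
        )
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")

    wanted = {g.upper() for g in gene_set}
    rows = [i for i, g in enumerate(panel.gene_ids) if g.upper() in wanted]
    missing = wanted - {panel.gene_ids[i].upper() for i in rows}
    if missing:
        logger.info("%d gene-set members absent from panel (reason=not_measured)",
                    len(missing))
    if not rows:
        raise ValueError("gene set is disjoint from the panel's genes")

    data = np.log2(panel.values[rows] + 1.0)
    keep = data.std(axis=1) > 0
    if not keep.all():
        logger.info("%d genes dropped (reason=zero_variance)", int((~keep).sum()))
    genes = [panel.gene_ids[i] for i, k in zip(rows, keep) if k]
    data = data[keep]
    if data.shape[0] < 2:
        raise ValueError("fewer than two usable genes after filtering")

    if method == "spearman":
        data = stats.rankdata(data, axis=1)
    corr = np.corrcoef(data)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    tissue = str(panel.design["tissue"].iloc[0]) if "tissue" in panel.design else ""
    return CorrelationMatrix(
        gene_ids=genes, values=corr, tissue=tissue, method=method,
        n_samples=panel.n_samples,
    )


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


def _mean_intra_correlation(values: np.ndarray, labels: np.ndarray, lab: int) -> float:
    """Mean off-diagonal correlation within one cluster; NaN for singletons."""
    idx = np.flatnonzero(labels == lab)
    if idx.size < 2:
        return float("nan")
    sub = values[np.ix_(idx, idx)]
    return float((sub.sum() - idx.size) / (idx.size * (idx.size - 1)))


def _renumber_by_coherence(values: np.ndarray, raw: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..k by descending mean intra-cluster correlation.

    Singletons (NaN coherence) sort last; ties break on the raw label for
    determinism.
    """
    labs = sorted(set(raw.tolist()))
    coh = {l: _mean_intra_correlation(values, raw, l) for l in labs}
    order = sorted(labs, key=lambda l: (np.isnan(coh[l]), -(coh[l] if not np.isnan(coh[l]) else 0.0), l))
    mapping = {l: i + 1 for i, l in enumerate(order)}
    return np.array([mapping[l] for l in raw], dtype=int)


def cluster_correlation_profiles(
    matrix: CorrelationMatrix,
    k: int = 3,
    method: str = "kmeans",
    n_restarts: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Cluster genes by their rows of correlation coefficients into k groups.

    Each gene's feature vector is its full row of the correlation matrix
    (including the constant unit diagonal entry, which does not affect the
    Euclidean geometry between rows). k-means keeps the best of ``n_restarts``
    initializations; the hierarchical alternative is average linkage on
    Euclidean distance cut at k groups. Labels are renumbered 1..k by
    descending mean intra-cluster correlation, so label 1 is the most
    internally coherent ("core") cluster.
    """
    n = len(matrix.gene_ids)
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of genes ({n})")
    if method == "kmeans":
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed,
                    algorithm="lloyd")
        raw = km.fit_predict(matrix.values)
    elif method == "hierarchical":
        raw = fcluster(linkage(matrix.values, method="average", metric="euclidean"),
                       t=k, criterion="maxclust")
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    return _renumber_by_coherence(matrix.values, np.asarray(raw))


# ---------------------------------------------------------------------------
# Coherence classification
# ---------------------------------------------------------------------------


def classify_coherence(
    matrix: CorrelationMatrix,
    labels: np.ndarray,
    tau_pos: float = 0.3,
    tau_neg: float = -0.1,
) -> dict[str, str]:
    """Per-gene coherence class relative to the core cluster.

    The core cluster is the one with the highest mean intra-cluster
    correlation (labels are already renumbered so this is label 1). A gene is
    "correlated" when its mean correlation to core genes (self excluded) is
    >= tau_pos, "anti-correlated" when <= tau_neg, else "unclassified".
    """
    if tau_neg > tau_pos:
        raise ValueError("tau_neg must not exceed tau_pos")
    labels = np.asarray(labels)
    sizes = {l: int((labels == l).sum()) for l in set(labels.tolist())}
    non_singleton = [l for l, s in sizes.items() if s >= 2]
    if not non_singleton:
        logger.warning("all clusters are singletons; every gene unclassified")
        return {g: "unclassified" for g in matrix.gene_ids}
    core = min(non_singleton)  # renumbered: lowest label = most coherent
    core_idx = np.flatnonzero(labels == core)

    classes: dict[str, str] = {}
    for i, g in enumerate(matrix.gene_ids):
        others = core_idx[core_idx != i]
        if others.size == 0:
            classes[g] = "unclassified"
            continue
        mean_r = float(matrix.values[i, others].mean())
        if mean_r >= tau_pos:
            classes[g] = "correlated"
        elif mean_r <= tau_neg:
            classes[g] = "anti-correlated"
        else:
            classes[g] = "unclassified"
    return classes


# ---------------------------------------------------------------------------
# Cross-tissue comparison
# ---------------------------------------------------------------------------


def cross_tissue_order(
    tissues: dict[str, TissueResult], reference: str
) -> CoexpressionResult:
    """Impose the reference tissue's cluster-sorted gene order on every tissue.

    Genes are restricted to the intersection across tissues (logged when
    non-trivial). Within the reference, genes sort by cluster label, then by
    descending mean correlation to their own cluster, then by gene id.
    """
    if reference not in tissues:
        raise ValueError(f"reference tissue {reference!r} not among results")
    common = set(tissues[reference].matrix.gene_ids)
    for tr in tissues.values():
        common &= set(tr.matrix.gene_ids)
    if not common:
        raise ValueError("tissues share no common genes")
    n_ref = len(tissues[reference].matrix.gene_ids)
    if len(common) < n_ref:
        logger.info("cross-tissue comparison restricted to %d/%d common genes",
                    len(common), n_ref)

    ref = tissues[reference]
    ref_pos = {g: i for i, g in enumerate(ref.matrix.gene_ids)}

    def sort_key(g: str):
        i = ref_pos[g]
        lab = int(ref.labels[i])
        own = np.flatnonzero(ref.labels == lab)
        own = own[own != i]
        mean_r = float(ref.matrix.values[i, own].mean()) if own.size else -np.inf
        return (lab, -mean_r, g)

    display = sorted(common, key=sort_key)

    ordered: dict[str, pd.DataFrame] = {}
    records = []
    for tissue, tr in tissues.items():
        pos = {g: i for i, g in enumerate(tr.matrix.gene_ids)}
        idx = [pos[g] for g in display]
        ordered[tissue] = pd.DataFrame(
            tr.matrix.values[np.ix_(idx, idx)], index=display, columns=display
        )
        for g in display:
            records.append(
                {
                    "gene": g,
                    "tissue": tissue,
                    "cluster": int(tr.labels[pos[g]]),
                    "class": tr.classes.get(g, "unclassified"),
                }
            )
    assignment = pd.DataFrame(records, columns=["gene", "tissue", "cluster", "class"])
    return CoexpressionResult(
        tissues=tissues,
        reference=reference,
        display_order=display,
        assignment=assignment,
        ordered_matrices=ordered,
    )


def analyze_tissue(
    panel: ExpressionMatrix,
    gene_set: list[str],
    k: int = 3,
    method: str = "pearson",
    cluster_method: str = "kmeans",
    n_restarts: int = 50,
    tau_pos: float = 0.3,
    tau_neg: float = -0.1,
    min_samples: int = 10,
    seed: int = 0,
) -> TissueResult:
    """Convenience wrapper: correlation -> clustering -> coherence classes."""
    cm = correlation_matrix(panel, gene_set, method=method, min_samples=min_samples)
    labels = cluster_correlation_profiles(
        cm, k=k, method=cluster_method, n_restarts=n_restarts, seed=seed
    )
    classes = classify_coherence(cm, labels, tau_pos=tau_pos, tau_neg=tau_neg)
    return TissueResult(matrix=cm, labels=labels, classes=classes)
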