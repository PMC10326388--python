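"""Region-to-region resting-state functional connectivity and graph analysis.

Node time courses (region means) are correlated across all unordered pairs,
Fisher-Z transformed, combined across subjects with one-group t-tests
expressed on a standard-normal Z scale, thresholded at |Z| >= 2.3 into an
undirected binary network, and summarized by degree centrality

    C_D(j) = sum_i A_ij

with group comparison of regional degrees inside named subregions
(Shapiro-Wilk normality gate choosing paired t versus Wilcoxon signed-rank).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .core import AtlasVolume, BoldScan

__all__ = [
    "EdgeStats",
    "ConnectivityNetwork",
    "region_timeseries",
    "pairwise_correlation",
    "fisher_z",
    "inverse_fisher_z",
    "group_edge_test",
    "threshold_network",
    "knn_cluster",
    "compare_degrees",
    "DEFAULT_Z_CUTOFF",
]

DEFAULT_Z_CUTOFF: float = 2.3


@dataclass
class EdgeStats:
    """Pairwise edge statistics for one subject (or one group level)."""

    node_ids: np.ndarray  # ordered region ids
    r: np.ndarray  # n x n Pearson matrix, NaN diagonal
    z: np.ndarray  # Fisher-transformed, NaN diagonal / degenerate edges

    @property
    def n_pairs(self) -> int:
        n = len(self.node_ids)
        return n * (n - 1) // 2


@dataclass
class ConnectivityNetwork:
    """Thresholded undirected network with per-node degree centrality."""

    node_ids: np.ndarray
    weights: np.ndarray  # symmetric real matrix the threshold was applied to
    threshold: float
    adjacency: np.ndarray = field(init=False)
    degrees: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("weight matrix must be square")
        finite = np.nan_to_num(W, nan=0.0, posinf=np.inf, neginf=-np.inf)
        A = (np.abs(finite) >= self.threshold).astype(np.int8)
        np.fill_diagonal(A, 0)
        A = np.maximum(A, A.T)  # enforce symmetry
        self.adjacency = A
        self.degrees = A.sum(axis=1).astype(int)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)

    def to_networkx(self):
        import networkx as nx

        G = nx.Graph()
        ids = [int(i) for i in self.node_ids]
        G.add_nodes_from(ids)
        ii, jj = np.nonzero(np.triu(self.adjacency, k=1))
        G.add_edges_from(
            (ids[i], ids[j], {"weight": float(self.weights[i, j])})
            for i, j in zip(ii, jj)
        )
        return G


def region_timeseries(
    scan: BoldScan, atlas: AtlasVolume
) -> tuple[np.ndarray, np.ndarray]:
    """Mean in-region voxel time course per node.

    Returns ``(node_ids, series)`` with ``series`` of shape (n_nodes, t).
    Regions without voxel support (inside the scan mask) are dropped with a
    warning, so the node set is the atlas regions that actually have data —
    the node count is recorded in the returned ids, never assumed.
    """
    if atlas.labels.shape != scan.mask.shape:
        raise ValueError("scan must be registered to atlas space")
    labels = np.where(scan.mask, atlas.labels, 0)
    flat = labels.ravel()
    counts = np.bincount(flat, minlength=atlas.n_regions + 1)
    data2d = scan.data.reshape(-1, scan.n_acquisitions)
    sums = np.zeros((atlas.n_regions + 1, scan.n_acquisitions))
    np.add.at(sums, flat, data2d)
    present = np.flatnonzero(counts[1:] > 0) + 1
    if present.size == 0:
        raise ValueError("no atlas region has voxel support in the scan mask")
    dropped = [int(i) for i in atlas.region_ids if counts[i] == 0]
    if dropped:
        warnings.warn(f"dropping {len(dropped)} empty regions: {dropped[:10]}...")
    series = sums[present] / counts[present, None]
    return present.astype(int), series


def pairwise_correlation(node_series: np.ndarray, node_ids: np.ndarray | None = None) -> EdgeStats:
    """Pearson correlation over all unordered node pairs.

    Zero-variance nodes yield NaN edges (excluded downstream).  The diagonal
    is NaN by construction — self-correlation is not an edge.
    """
    X = np.asarray(node_series, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need an (n_nodes >= 2, t) series matrix")
    if X.shape[1] < 4:
        raise ValueError("need at least 4 timepoints")
    if node_ids is None:
        node_ids = np.arange(1, X.shape[0] + 1)
    Xc = X - X.mean(axis=1, keepdims=True)
    sd = np.sqrt((Xc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ Xc.T) / np.outer(sd, sd)
    r[sd == 0, :] = np.nan
    r[:, sd == 0] = np.nan
    r = np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, np.nan)
    z = fisher_z(r)
    return EdgeStats(node_ids=np.asarray(node_ids, dtype=int), r=r, z=z)


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher's variance-stabilizing transform z = atanh(r).

    |r| = 1 maps to +/-inf (flagged downstream, excluded from group tests).
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.arctanh(r)


def inverse_fisher_z(z: np.ndarray | float) -> np.ndarray | float:
    return np.tanh(z)


def group_edge_test(z_matrices: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """Group-level Z-score matrix from per-edge one-sample t-tests.

    ``z_matrices`` is a (subjects, n, n) stack of Fisher-Z matrices.  Per
    edge, the subject values are tested against zero with a one-sample t;
    the t CDF value is mapped through the standard-normal quantile function,
    preserving sign, so under the null the output is standard normal.  Edges
    with any non-finite subject value are NaN.
    """
    Z = np.asarray(z_matrices, dtype=float)
    if Z.ndim != 3 or Z.shape[1] != Z.shape[2]:
        raise ValueError("expected a (subjects, n, n) stack")
    s = Z.shape[0]
    if s < 3:
        raise ValueError("group edge test needs at least 3 subjects")
    mean = Z.mean(axis=0)
    sd = Z.std(axis=0, ddof=1)
    sd = np.maximum(sd, eps)
    t = mean / (sd / np.sqrt(s))
    df = s - 1
    # two equivalent one-sided mappings, chosen for tail accuracy
    with np.errstate(invalid="ignore"):
        pos = t >= 0
        sf = stats.t.sf(np.abs(t), df)
        sf = np.clip(sf, 1e-300, 1.0)
        out = np.where(pos, stats.norm.isf(sf), -stats.norm.isf(sf))
    bad = ~np.isfinite(Z).all(axis=0)
    out[bad] = np.nan
    np.fill_diagonal(out, np.nan)
    return out


def threshold_network(
    z_score_matrix: np.ndarray,
    cutoff: float = DEFAULT_Z_CUTOFF,
    node_ids: np.ndarray | None = None,
) -> ConnectivityNetwork:
    """Binary undirected network on |Z| >= cutoff, with degrees."""
    Z = np.asarray(z_score_matrix, dtype=float)
    if not np.allclose(np.nan_to_num(Z), np.nan_to_num(Z.T), atol=1e-8):
        raise ValueError("Z-score matrix must be symmetric")
    if node_ids is None:
        node_ids = np.arange(1, Z.shape[0] + 1)
    return ConnectivityNetwork(
        node_ids=np.asarray(node_ids, dtype=int), weights=Z, threshold=cutoff
    )


def knn_cluster(
    z_score_matrix: np.ndarray,
    k: int = 5,
    method: str = "knn_graph",
    n_clusters: int | None = None,
) -> np.ndarray:
    """Cluster nodes by their connectivity profiles.

    Default: build the (symmetrized) k-nearest-neighbor graph on the rows of
    the matrix under correlation distance and return its connected
    components — an unsupervised reading of "k-nearest-neighbors
    clustering".  ``method='spectral'`` instead runs spectral clustering on
    the profile-correlation affinity (requires ``n_clusters``).
    Deterministic given the input.
    """
    Z = np.asarray(z_score_matrix, dtype=float).copy()
    n = Z.shape[0]
    if not (1 <= k < n):
        raise ValueError("need 1 <= k < n_nodes")
    np.fill_diagonal(Z, 0.0)
    Z = np.nan_to_num(Z, nan=0.0, posinf=0.0, neginf=0.0)
    prof = Z - Z.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(prof, axis=1)
    norm[norm == 0] = 1.0
    corr = (prof @ prof.T) / np.outer(norm, norm)
    dist = 1.0 - corr

    if method == "spectral":
        if n_clusters is None:
            raise ValueError("spectral clustering requires n_clusters")
        from sklearn.cluster import SpectralClustering

        model = SpectralClustering(
            n_clusters=n_clusters, affinity="precomputed", random_state=0,
            assign_labels="discretize",
        )
        return model.fit_predict(np.clip(corr + 1.0, 0.0, None))
    if method != "knn_graph":
        raise ValueError("method must be 'knn_graph' or 'spectral'")

    np.fill_diagonal(dist, np.inf)
    order = np.argsort(dist, axis=1, kind="stable")[:, :k]
    rows = np.repeat(np.arange(n), k)
    cols = order.ravel()
    A = csr_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n))
    A = ((A + A.T) > 0).astype(int)
    _, labels = connected_components(A, directed=False)
    return labels


def compare_degrees(
    network_a: ConnectivityNetwork,
    network_b: ConnectivityNetwork,
    subregion_map: dict[str, list[int]],
    normality_alpha: float = 0.05,
) -> pd.DataFrame:
    """Compare regional degree centrality between two conditions, per
    named subregion.

    Conditions are paired region-by-region within each subregion; a
    Shapiro-Wilk test on the paired differences (alpha 0.05) gates a paired
    t-test versus a Wilcoxon signed-rank test.  Subregions with fewer than
    3 member regions present in both networks are skipped with a warning.
    Reports per-condition mean and SD of degrees, the test used, p-value,
    and the direction of the difference.
    """
    ids_a = {int(i): idx for idx, i in enumerate(network_a.node_ids)}
    ids_b = {int(i): idx for idx, i in enumerate(network_b.node_ids)}
    rows = []
    for name, members in subregion_map.items():
        shared = [int(m) for m in members if int(m) in ids_a and int(m) in ids_b]
        if len(shared) < 3:
            warnings.warn(f"subregion '{name}' has < 3 usable regions; skipped")
            continue
        da = np.array([network_a.degrees[ids_a[m]] for m in shared], dtype=float)
        db = np.array([network_b.degrees[ids_b[m]] for m in shared], dtype=float)
        diff = da - db
        if np.allclose(diff, 0):
            test, p, normal_p = "none", 1.0, np.nan
        else:
            if np.ptp(diff) == 0:
                normal_p = 0.0  # constant nonzero differences: not plausibly normal
            else:
                normal_p = float(stats.shapiro(diff).pvalue)
            if normal_p > normality_alpha:
                test = "paired_t"
                p = float(stats.ttest_rel(da, db).pvalue)
            else:
                test = "wilcoxon_signed_rank"
                nz = diff[diff != 0]
                p = float(stats.wilcoxon(nz).pvalue) if nz.size else 1.0
        direction = ">" if da.mean() > db.mean() else ("<" if da.mean() < db.mean() else "=")
        rows.append({
            "subregion": name,
            "n_regions": len(shared),
            "mean_a": float(da.mean()), "sd_a": float(da.std(ddof=1)),
            "mean_b": float(db.mean()), "sd_b": float(db.std(ddof=1)),
            "direction": direction,
            "normality_p": normal_p,
            "test": test,
            "p_value": p,
        })
    return pd.DataFrame(rows)
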