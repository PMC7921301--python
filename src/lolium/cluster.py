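"""Genotype x trait clustering with internal validation.

Genotype trait means are z-scored per trait, clustered with Ward's
minimum-variance hierarchical criterion on Euclidean distances (and
optionally k-means), and solutions across a method x k grid are scored
with three internal validation metrics:

* connectivity — for each point, penalties 1/j for its j-th nearest
  neighbour (j = 1..L, default L = 10) that lands in another cluster;
  lower is better;
* mean silhouette width — in [-1, 1], higher is better;
* Dunn index — minimum between-cluster point distance over maximum
  within-cluster diameter; higher is better.

Solutions are ranked by silhouette, ties broken by lower connectivity.

The default trait set for clustering contains only traits measured on
every plant (DW, A_op, WUE_op, C_mass, C:N, LMA, tiller count,
LA_tiller): biochemical-capacity traits measured on a subsample, and
members of collinear pairs (g_sop with WUE_op, N_mass with C:N), are
excluded.

Between the two clusters of a chosen solution, each trait is compared
with a normality/homoscedasticity-driven test choice (Student's t,
Welch's t, or Mann-Whitney U).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

__all__ = [
    "CLUSTERING_TRAITS",
    "ClusterSolution",
    "standardize",
    "connectivity",
    "dunn_index",
    "select_clustering",
    "compare_cluster_traits",
    "dendrogram_newick",
]

#: Traits entering the genotype-mean cluster analysis.
CLUSTERING_TRAITS = (
    "DW", "A_op", "WUE_op", "C_mass", "CN_ratio", "LMA", "tiller_count", "LA_tiller",
)

DEFAULT_NEIGHBOURHOOD = 10


@dataclass
class ClusterSolution:
    """One method x k clustering with its validation metrics."""

    method: str
    k: int
    assignments: pd.Series  # genotype -> cluster label (1-based)
    connectivity: float
    silhouette: float
    dunn: float
    linkage_matrix: np.ndarray | None = None

    def cluster_sizes(self) -> pd.Series:
        return self.assignments.value_counts().sort_index()


def standardize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Z-score each trait column (sample SD) of a genotype x trait matrix."""
    if len(matrix) < 2:
        raise ValueError("need at least two genotypes")
    sd = matrix.std(ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        raise ValueError(f"constant trait column(s): {constant}")
    return (matrix - matrix.mean()) / sd


def connectivity(
    dist: np.ndarray, labels: np.ndarray, L: int = DEFAULT_NEIGHBOURHOOD
) -> float:
    """Neighbourhood-violation score; 0 when all L-neighbourhoods are pure."""
    n = dist.shape[0]
    score = 0.0
    L = min(L, n - 1)
    for i in range(n):
        order = np.argsort(dist[i], kind="stable")
        neighbours = [j for j in order if j != i][:L]
        for rank, j in enumerate(neighbours, start=1):
            if labels[j] != labels[i]:
                score += 1.0 / rank
    return score


def dunn_index(dist: np.ndarray, labels: np.ndarray) -> float:
    """Min between-cluster distance over max within-cluster diameter."""
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ValueError("Dunn index needs at least two clusters")
    min_between = np.inf
    max_diameter = 0.0
    for a_i, a in enumerate(clusters):
        ia = np.where(labels == a)[0]
        if len(ia) > 1:
            max_diameter = max(max_diameter, float(dist[np.ix_(ia, ia)].max()))
        for b in clusters[a_i + 1:]:
            ib = np.where(labels == b)[0]
            min_between = min(min_between, float(dist[np.ix_(ia, ib)].min()))
    if max_diameter == 0.0:
        return np.inf
    return min_between / max_diameter


def select_clustering(
    matrix: pd.DataFrame,
    methods: tuple[str, ...] = ("ward_hierarchical", "kmeans"),
    k_range: range | tuple[int, ...] = range(2, 7),
    neighbourhood: int = DEFAULT_NEIGHBOURHOOD,
    kmeans_restarts: int = 25,
    random_state: int = 0,
    pre_standardized: bool = False,
) -> list[ClusterSolution]:
    """Score every method x k combination; best solution first.

    The matrix is z-scored unless ``pre_standardized``. Hierarchical
    solutions use Ward's criterion on Euclidean distances (the
    squared-distance Lance-Williams dialect, matching the classic
    "Ward.D2" contract) and are fully deterministic; k-means uses
    ``kmeans_restarts`` seeded restarts. Ranking: highest silhouette,
    ties to lower connectivity.
    """
    z = matrix if pre_standardized else standardize(matrix)
    n = len(z)
    ks = list(k_range)
    if any(k < 2 or k >= n for k in ks):
        raise ValueError(f"k_range must lie within [2, {n - 1}]")
    X = z.to_numpy(float)
    dist = squareform(pdist(X))
    solutions: list[ClusterSolution] = []
    link = linkage(X, method="ward") if "ward_hierarchical" in methods else None
    for method in methods:
        for k in ks:
            if method == "ward_hierarchical":
                labels = fcluster(link, t=k, criterion="maxclust")
            elif method == "kmeans":
                km = KMeans(n_clusters=k, n_init=kmeans_restarts, random_state=random_state)
                labels = km.fit_predict(X) + 1
            else:
                raise ValueError(f"unknown clustering method {method!r}")
            solutions.append(
                ClusterSolution(
                    method=method,
                    k=k,
                    assignments=pd.Series(labels, index=z.index, name="cluster"),
                    connectivity=connectivity(dist, labels, neighbourhood),
                    silhouette=float(silhouette_score(X, labels)),
                    dunn=dunn_index(dist, labels),
                    linkage_matrix=link if method == "ward_hierarchical" else None,
                )
            )
    solutions.sort(key=lambda s: (-s.silhouette, s.connectivity))
    return solutions


def compare_cluster_traits(
    data: pd.DataFrame, assignments: pd.Series
) -> pd.DataFrame:
    """Per-trait two-cluster comparisons with an adaptive test choice.

    ``data`` holds per-genotype trait means indexed like
    ``assignments``. Per trait: Shapiro-Wilk within each cluster at
    alpha = 0.05; both normal -> Levene decides Student's vs Welch's t;
    any non-normal -> Mann-Whitney U. Returns mean +/- SD per cluster,
    the test used, p and significance stars.
    """
    clusters = np.sort(assignments.unique())
    if len(clusters) != 2:
        raise ValueError("trait comparison expects exactly 2 clusters")
    groups = {c: data.loc[assignments[assignments == c].index] for c in clusters}
    if any(len(g) < 3 for g in groups.values()):
        raise ValueError("each cluster must contain at least 3 genotypes")
    from .stats import significance_stars

    rows = []
    for trait in data.columns:
        a = groups[clusters[0]][trait].dropna().to_numpy(float)
        b = groups[clusters[1]][trait].dropna().to_numpy(float)
        normal = all(
            sps.shapiro(x).pvalue >= 0.05 if np.ptp(x) > 0 else False for x in (a, b)
        )
        if normal:
            equal_var = sps.levene(a, b).pvalue >= 0.05
            res = sps.ttest_ind(a, b, equal_var=equal_var)
            test = "student_t" if equal_var else "welch_t"
        else:
            if np.ptp(np.concatenate([a, b])) == 0:
                res = None
                test = "degenerate"
            else:
                res = sps.mannwhitneyu(a, b, alternative="two-sided")
                test = "mann_whitney_u"
        p = 1.0 if res is None else float(res.pvalue)
        rows.append(
            {
                "trait": trait,
                "mean_1": float(a.mean()), "sd_1": float(a.std(ddof=1)),
                "mean_2": float(b.mean()), "sd_2": float(b.std(ddof=1)),
                "test": test,
                "p_value": p,
                "significance": significance_stars(p),
            }
        )
    return pd.DataFrame(rows).set_index("trait")


def dendrogram_newick(link: np.ndarray, labels: list[str]) -> str:
    """Render a linkage matrix as a Newick string (heights as branch lengths)."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: labels[i] for i in range(n)}
    for step, (a, b, h, _) in enumerate(link):
        a, b = int(a), int(b)
        la = max(h - heights[a], 0.0)
        lb = max(h - heights[b], 0.0)
        nodes[n + step] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
        heights[n + step] = h
    return nodes[n + len(link) - 1] + ";"
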