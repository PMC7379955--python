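"""Trait profile groups: Gower distances, Ward clustering, ANOSIM and
random-forest trait importance.

Genera with similar multi-trait profiles are grouped by hierarchical
clustering of Gower dissimilarities under Ward's minimum-variance criterion.
The number of groups is chosen by maximizing the ANOSIM R statistic over
dendrogram cuts (capped at 10 groups), and the traits that delineate each
group are ranked by the mean decrease in Gini impurity of a random-forest
classifier of group membership.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier

#: Double-centering diagnostic above which Gower dissimilarities are no
#: longer safely treated as Euclidean for Ward clustering.
EUCLIDEAN_WARN_THRESHOLD = 0.05


@dataclass
class TPGAssignment:
    """Result of cluster-number selection."""

    labels: pd.Series  # genus -> group id (1..k)
    k: int
    anosim_r: float
    r_by_k: dict[int, float]
    euclidean_diagnostic: float


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------


def gower_matrix(traits: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Gower dissimilarity between genus trait profiles.

    All traits are quantitative, so Gower reduces to the mean over traits of
    range-normalized absolute differences. Traits constant across genera
    carry no information and are excluded (with a warning).
    """
    if len(traits) < 2:
        raise ValueError("Gower distance needs at least 2 genera")
    X = traits.to_numpy(dtype=float)
    ranges = X.max(axis=0) - X.min(axis=0)
    keep = ranges > 0
    if not keep.all():
        dropped = [str(c) for c in traits.columns[~keep]]
        warnings.warn(f"constant traits excluded from Gower distance: {dropped}")
    if not keep.any():
        raise ValueError("all traits are constant; Gower distance undefined")
    Z = X[:, keep] / ranges[keep]
    D = np.abs(Z[:, None, :] - Z[None, :, :]).mean(axis=2)
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=traits.index, columns=traits.index)


def check_euclidean(distance: pd.DataFrame) -> float:
    """Fraction of negative eigenvalue mass after double-centering.

    Double-centres -1/2 J D^2 J (classical MDS); a matrix of exactly
    Euclidean distances yields a positive semi-definite form, so the
    returned fraction sum(|negative eigenvalues|) / sum(|eigenvalues|) is 0
    for Euclidean data and grows with non-Euclidean structure.
    """
    D = distance.to_numpy(dtype=float)
    n = len(D)
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D**2) @ J
    eig = np.linalg.eigvalsh((G + G.T) / 2)
    total = np.abs(eig).sum()
    if total == 0:
        return 0.0
    return float(np.abs(eig[eig < -1e-12]).sum() / total)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


def ward_cluster(distance: pd.DataFrame) -> np.ndarray:
    """Ward's minimum-variance dendrogram on a dissimilarity matrix.

    Applied directly to Gower dissimilarities; justified when the
    double-centering diagnostic is near zero (a warning is issued
    otherwise). Returns a scipy linkage matrix.
    """
    diag = check_euclidean(distance)
    if diag > EUCLIDEAN_WARN_THRESHOLD:
        warnings.warn(
            f"Gower dissimilarities deviate from Euclidean (diagnostic {diag:.3f}); "
            "Ward merge heights may be distorted"
        )
    condensed = squareform(distance.to_numpy(dtype=float), checks=False)
    return linkage(condensed, method="ward")


def cut_dendrogram(Z: np.ndarray, k: int, index: pd.Index) -> pd.Series:
    """Cluster labels (1..k) from cutting a dendrogram into k groups."""
    return pd.Series(fcluster(Z, t=k, criterion="maxclust"), index=index, name="tpg")


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------


def anosim_r(
    distance: pd.DataFrame,
    labels,
    n_permutations: int = 0,
    seed: int | None = None,
) -> float | tuple[float, float]:
    """Analysis-of-similarities R statistic (optionally with permutation p).

    R = (mean rank of between-group distances - mean rank of within-group
    distances) / (M / 2), with mid-ranks for ties over all M = n(n-1)/2
    pairs. R is 1 when every between-group distance exceeds every
    within-group distance and near 0 for random labels.
    """
    labels = np.asarray(labels)
    if len(set(labels)) < 2:
        raise ValueError("ANOSIM needs at least two groups")
    D = distance.to_numpy(dtype=float)
    n = len(D)
    iu = np.triu_indices(n, 1)
    d = D[iu]
    ranks = rankdata(d)
    M = len(d)

    def statistic(lab):
        within = lab[iu[0]] == lab[iu[1]]
        if within.all() or not within.any():
            raise ValueError("ANOSIM needs both within- and between-group pairs")
        return float((ranks[~within].mean() - ranks[within].mean()) / (M / 2.0))

    r_obs = statistic(labels)
    if n_permutations <= 0:
        return r_obs
    rng = np.random.default_rng(seed)
    hits = 1  # observed labelling counts toward the null
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        if statistic(perm) >= r_obs - 1e-12:
            hits += 1
    return r_obs, hits / (n_permutations + 1)


def select_k_by_anosim(
    distance: pd.DataFrame,
    k_max: int = 10,
    Z: np.ndarray | None = None,
) -> TPGAssignment:
    """Choose the dendrogram cut with maximal ANOSIM R.

    Cuts the Ward dendrogram at k = 2..k_max, computes R for each labelling
    against the same Gower matrix, and returns the k maximizing R; exact
    ties go to the smaller k (parsimony). A warning is issued when even the
    best R indicates weak structure (< 0.3).
    """
    if len(distance) <= 2:
        raise ValueError("cluster-number selection needs more than 2 genera")
    if k_max < 2:
        raise ValueError("k_max must be at least 2")
    if Z is None:
        Z = ward_cluster(distance)
    diag = check_euclidean(distance)
    best: tuple[float, int, pd.Series] | None = None
    r_by_k: dict[int, float] = {}
    for k in range(2, min(k_max, len(distance) - 1) + 1):
        labels = cut_dendrogram(Z, k, distance.index)
        if labels.nunique() < 2:
            continue
        r = anosim_r(distance, labels.to_numpy())
        r_by_k[k] = r
        if best is None or r > best[0] + 1e-12:
            best = (r, k, labels)
    assert best is not None
    r, k, labels = best
    if r < 0.3:
        warnings.warn(f"weak cluster structure: max ANOSIM R = {r:.2f}")
    return TPGAssignment(
        labels=labels, k=k, anosim_r=r, r_by_k=r_by_k, euclidean_diagnostic=diag
    )


# ---------------------------------------------------------------------------
# Trait importance
# ---------------------------------------------------------------------------


def gini_importance(
    traits: pd.DataFrame,
    labels,
    n_trees: int = 500,
    seed: int = 0,
    multiclass: bool = False,
) -> pd.DataFrame:
    """Mean decrease in Gini impurity of each trait, per trait profile group.

    By default fits one balanced one-vs-rest random forest per group, so
    each group's importances reflect what separates it from the rest of the
    community; ``multiclass=True`` instead fits a single forest whose
    importances are shared by all groups. Importances are the raw
    (unnormalized) impurity decreases averaged over trees; all trees
    consider every trait at every split, which concentrates credit on the
    strongest separators and makes rankings stable.

    Returns a long-format DataFrame (group, feature, trait, gini).
    """
    labels = pd.Series(np.asarray(labels), index=traits.index)
    X = traits.to_numpy(dtype=float)
    groups = sorted(labels.unique())
    rows = []

    def forest_importances(y, rs):
        rf = RandomForestClassifier(
            n_estimators=n_trees,
            class_weight="balanced",
            max_features=None,
            random_state=rs,
        ).fit(X, y)
        imp = np.zeros(X.shape[1])
        for tree in rf.estimators_:
            imp += tree.tree_.compute_feature_importances(normalize=False)
        return imp / len(rf.estimators_)

    if multiclass:
        shared = forest_importances(labels.to_numpy(), seed)
    for gi, group in enumerate(groups):
        size = int((labels == group).sum())
        if size == 1:
            warnings.warn(f"group {group!r} has a single member; importances unstable")
        imp = shared if multiclass else forest_importances(
            (labels == group).astype(int).to_numpy(), seed + gi
        )
        for col, value in zip(traits.columns, imp):
            feature, trait = col if isinstance(col, tuple) else ("", col)
            rows.append((group, feature, trait, float(value)))
    return pd.DataFrame(rows, columns=["group", "feature", "trait", "gini"])


def feature_importance(gini_table: pd.DataFrame) -> pd.DataFrame:
    """Grouping-feature importance: sum of member-trait Gini values."""
    return (
        gini_table.groupby(["group", "feature"], sort=True)["gini"].sum().reset_index()
    )


def linkage_to_newick(Z: np.ndarray, names: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree string."""
    n = len(names)

    def build(node: int) -> str:
        if node < n:
            return names[node]
        left, right, height, _ = Z[node - n]
        lh = height - (Z[int(left) - n][2] if left >= n else 0.0)
        rh = height - (Z[int(right) - n][2] if right >= n else 0.0)
        return f"({build(int(left))}:{lh:.6g},{build(int(right))}:{rh:.6g})"

    return build(2 * n - 2) + ";"
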