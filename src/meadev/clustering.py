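"""Dimensionality reduction and trajectory clustering of dish development.

Two complementary views of the 18-feature profiles:

* PCA of the z-scored per-recording feature table, with per-feature
  contribution percentages to each component and the ``100/p`` reference
  line above which a feature contributes more than under uniformity.
* A 5x5 hexagonal self-organizing map (SOM) trained on per-dish trajectories
  of two representative network features (channels with bursts, mean STTC)
  across the three DIV intervals, followed by k-means on the 25 codebook
  vectors with the number of clusters selected by the Davies-Bouldin index.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

#: trajectory features used as SOM inputs (at each of the three intervals)
SOM_FEATURES: tuple[str, str] = ("ch_bursts", "sttc")


# ---------------------------------------------------------------------------
# PCA


def pca_project(
    features: pd.DataFrame, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame, float]:
    """PCA of a complete numeric feature table after z-scoring.

    Returns ``(scores, explained_pct, contributions_pct, reference_pct)``:
    per-row component scores, the percentage of variance explained per
    component, the percentage contribution of each feature to each component
    (squared-loading share), and the uniform-contribution reference line
    ``100 / n_features``.
    """
    num = features.select_dtypes(include=[np.number])
    sd = num.std(ddof=0)
    dropped = sd.index[sd == 0.0]
    if len(dropped):
        warnings.warn(f"dropping zero-variance columns: {list(dropped)}")
        num = num.drop(columns=list(dropped))
    if num.isna().any().any():
        raise ValueError("pca_project requires a complete table (impute upstream)")
    z = (num - num.mean()) / num.std(ddof=0)
    pca = PCA(n_components=min(n_components, z.shape[1]))
    scores = pca.fit_transform(z.to_numpy())
    explained_pct = pca.explained_variance_ratio_ * 100.0
    loads = pca.components_  # rows are unit-norm eigenvectors
    contrib = 100.0 * loads**2 / (loads**2).sum(axis=1, keepdims=True)
    contrib_df = pd.DataFrame(
        contrib.T,
        index=num.columns,
        columns=[f"PC{i + 1}" for i in range(loads.shape[0])],
    )
    scores_df = pd.DataFrame(
        scores, index=features.index, columns=[f"PC{i + 1}" for i in range(scores.shape[1])]
    )
    return scores_df, explained_pct, contrib_df, 100.0 / num.shape[1]


# ---------------------------------------------------------------------------
# SOM


@dataclasses.dataclass(frozen=True)
class SOMConfig:
    grid: tuple[int, int] = (5, 5)
    n_iterations: int = 50  # full passes over the data
    learning_rate: tuple[float, float] = (0.05, 0.01)  # linear start -> end
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.grid) < 1 or self.n_iterations < 1:
            raise ValueError("grid dims and n_iterations must be >= 1")


def _hex_axial(grid: tuple[int, int]) -> np.ndarray:
    """Axial (q, r) coordinates of an odd-r offset hexagonal grid."""
    rows, cols = grid
    coords = []
    for r in range(rows):
        for c in range(cols):
            q = c - (r - (r & 1)) // 2
            coords.append((q, r))
    return np.asarray(coords, dtype=float)


def _hex_distances(coords: np.ndarray) -> np.ndarray:
    """Pairwise hex (cube) distances between axial coordinates."""
    dq = coords[:, 0][:, None] - coords[:, 0][None, :]
    dr = coords[:, 1][:, None] - coords[:, 1][None, :]
    return (np.abs(dq) + np.abs(dr) + np.abs(dq + dr)) / 2.0


@dataclasses.dataclass
class SOMModel:
    codebook: np.ndarray  # (n_units, n_features)
    coords: np.ndarray  # axial unit coordinates
    grid: tuple[int, int]

    def bmu(self, x: np.ndarray) -> np.ndarray:
        """Best-matching unit index for each row of ``x``."""
        x = np.atleast_2d(x)
        d = np.linalg.norm(x[:, None, :] - self.codebook[None, :, :], axis=2)
        return d.argmin(axis=1)


def fit_som(data: np.ndarray, cfg: SOMConfig | None = None) -> SOMModel:
    """Train a hexagonal SOM by sequential Kohonen updates.

    Each pass presents every data row once in shuffled order; the BMU and its
    lattice neighbors move toward the row with a Gaussian neighborhood weight.
    The learning rate decays linearly over all steps and the neighborhood
    radius shrinks linearly from 2/3 of the lattice diameter to 1.
    Deterministic under a fixed seed.
    """
    cfg = cfg or SOMConfig()
    x = np.asarray(data, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("fit_som needs a 2-D array with at least 2 rows")
    if np.isnan(x).any():
        raise ValueError("fit_som requires complete data")
    rng = np.random.default_rng(cfg.seed)
    coords = _hex_axial(cfg.grid)
    unit_dist = _hex_distances(coords)
    n_units = coords.shape[0]
    codebook = x[rng.integers(0, x.shape[0], size=n_units)].copy()

    diameter = unit_dist.max()
    radius0, radius1 = max(1.0, 2.0 * diameter / 3.0), 1.0
    lr0, lr1 = cfg.learning_rate
    total_steps = cfg.n_iterations * x.shape[0]
    step = 0
    for _ in range(cfg.n_iterations):
        for i in rng.permutation(x.shape[0]):
            frac = step / max(1, total_steps - 1)
            lr = lr0 + frac * (lr1 - lr0)
            radius = radius0 + frac * (radius1 - radius0)
            bmu = int(np.linalg.norm(codebook - x[i], axis=1).argmin())
            w = np.exp(-(unit_dist[bmu] ** 2) / (2.0 * radius**2))
            codebook += lr * w[:, None] * (x[i] - codebook)
            step += 1
    return SOMModel(codebook=codebook, coords=coords, grid=cfg.grid)


# ---------------------------------------------------------------------------
# k-means on the codebook + Davies-Bouldin model selection


def davies_bouldin(points: np.ndarray, labels: np.ndarray) -> float:
    """Davies-Bouldin index: mean over clusters of max (s_i+s_j)/d(c_i,c_j).

    ``s_i`` is the mean Euclidean distance of cluster members to their
    centroid.  Coincident centroids make the pairwise term infinite, so such
    degenerate partitions are never selected.
    """
    uniq = np.unique(labels)
    k = uniq.size
    if k < 2:
        return math.inf
    cents = np.stack([points[labels == u].mean(axis=0) for u in uniq])
    scatter = np.array(
        [np.mean(np.linalg.norm(points[labels == u] - cents[i], axis=1)) for i, u in enumerate(uniq)]
    )
    worst = np.zeros(k)
    for i in range(k):
        ratios = []
        for j in range(k):
            if i == j:
                continue
            d = np.linalg.norm(cents[i] - cents[j])
            ratios.append((scatter[i] + scatter[j]) / d if d > 0 else math.inf)
        worst[i] = max(ratios)
    return float(np.mean(worst))


@dataclasses.dataclass
class ClusterResult:
    k: int
    dish_labels: pd.Series  # cluster label (1..k) per dish
    db_scores: dict[int, float]  # Davies-Bouldin per candidate k
    codebook_labels: np.ndarray


def cluster_som(
    model: SOMModel,
    data: np.ndarray,
    dish_ids: list[str],
    k_range: range = range(2, 7),
    seed: int = 0,
    occupied_only: bool = True,
) -> ClusterResult:
    """k-means on the SOM codebook; k selected by the Davies-Bouldin index.

    By default only *occupied* units (best-matching unit of at least one
    input case) are clustered: a map cell stands for the centroid of the
    cases that activate it, so cells activated by nothing carry no case
    information — they are lattice interpolation artifacts that would
    otherwise form spurious clusters of their own.  Each dish inherits the
    k-means label of its best-matching unit, and the Davies-Bouldin index
    is evaluated on the resulting partition of the *dishes* (the entities
    being clustered); scoring the handful of codebook points instead
    rewards singleton codebook clusters, whose scatter is zero.
    """
    x = np.asarray(data, dtype=float)
    bmus = model.bmu(x)
    if occupied_only:
        units = np.unique(bmus)
    else:
        units = np.arange(model.codebook.shape[0])
    points = model.codebook[units]
    db_scores: dict[int, float] = {}
    labelings: dict[int, np.ndarray] = {}
    dish_labelings: dict[int, np.ndarray] = {}
    for k in k_range:
        if k > points.shape[0]:
            continue
        km = KMeans(n_clusters=k, init="k-means++", n_init=50, random_state=seed)
        labels = km.fit_predict(points)
        if np.unique(labels).size < k:
            warnings.warn(f"k={k}: empty cluster, candidate excluded")
            continue
        unit_label = dict(zip(units.tolist(), labels.tolist()))
        dish_lab = np.array([unit_label[int(u)] for u in bmus])
        if np.unique(dish_lab).size < 2:
            continue
        labelings[k] = labels
        dish_labelings[k] = dish_lab
        db_scores[k] = davies_bouldin(x, dish_lab)
    if not db_scores:
        raise RuntimeError("no valid k-means partition in the candidate range")
    best_k = min(db_scores, key=db_scores.get)
    dish_labels = pd.Series(dish_labelings[best_k] + 1, index=dish_ids, name="cluster")
    codebook_labels = np.full(model.codebook.shape[0], -1)
    codebook_labels[units] = labelings[best_k]
    return ClusterResult(best_k, dish_labels, db_scores, codebook_labels)


def som_input_matrix(
    trajectories: pd.DataFrame,
    features: tuple[str, ...] = SOM_FEATURES,
    n_intervals: int = 3,
) -> tuple[np.ndarray, list[str]]:
    """Z-scored (dish x [feature x interval]) matrix of SOM inputs.

    Dishes with no trajectory value at all are dropped; remaining missing
    cells (e.g. STTC of a dish with < 2 active channels in one interval) are
    imputed with the column mean before z-scoring.
    """
    wide = trajectories.pivot(index="dish", columns="interval", values=list(features))
    needed = [(f, i) for f in features for i in range(n_intervals)]
    wide = wide.reindex(columns=pd.MultiIndex.from_tuples(needed))
    wide = wide.dropna(axis=0, thresh=1)
    x = wide.to_numpy(dtype=float)
    col_mean = np.nanmean(x, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(x))
    x[nan_r, nan_c] = col_mean[nan_c]
    mu, sd = x.mean(axis=0), x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (x - mu) / sd, list(wide.index)


def summarize_clusters(
    dish_labels: pd.Series, trajectories: pd.DataFrame
) -> pd.DataFrame:
    """Mean, median, SEM and IQR of every feature per (cluster, interval).

    SEM uses the n-1 denominator and is NaN for singleton groups; IQR is the
    75th minus the 25th percentile (linear interpolation).
    """
    feat_cols = [c for c in trajectories.columns if c not in ("dish", "interval")]
    df = trajectories.merge(
        dish_labels.rename("cluster"), left_on="dish", right_index=True
    )
    long = df.melt(
        id_vars=["cluster", "interval"],
        value_vars=feat_cols,
        var_name="feature",
    )
    def iqr(s: pd.Series) -> float:
        v = s.dropna()
        return float(np.percentile(v, 75) - np.percentile(v, 25)) if len(v) else math.nan

    out = (
        long.groupby(["cluster", "interval", "feature"])["value"]
        .agg(mean="mean", median="median", sem="sem", iqr=iqr)
        .reset_index()
    )
    return out
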