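"""Step One: grid search, k-means clustering, and local-outlier flagging.

The screening step looks for *locally* outlying providers: hospitals that
sit unusually far from the centroid of their own peer cluster, rather
than global extremes.  The pipeline is

1. grid search over (n, k) — number of features kept by ensemble PFA and
   number of k-means clusters — maximizing the average silhouette width;
2. local distances — Euclidean distance of each hospital to its own
   cluster centroid, in the standardized selected-feature space the
   clustering ran in;
3. flagging — hospitals whose distance lies strictly above the 95th
   percentile (linear interpolation between order statistics) of the
   distance distribution.

With distinct distances the flagged count is exactly
``N - floor(1 + 0.95 (N - 1))`` — 10 providers out of 183.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.spatial.distance import squareform, pdist
from sklearn.cluster import KMeans

from .aggregation import FeatureMatrix
from .pfa_selection import PFAConfig, pfa_ensemble

__all__ = [
    "GridConfig",
    "ScreeningResult",
    "mean_silhouette",
    "grid_search",
    "local_distances",
    "flag_outliers",
    "screen",
    "plot_distance_distribution",
]


class GridConfig(BaseModel):
    """Grid-search settings for Step One."""

    model_config = ConfigDict(frozen=True)

    n_grid: tuple[int, ...] = (20, 30, 40)
    k_grid: tuple[int, ...] = (5, 6, 7, 8)
    pfa: PFAConfig = Field(default_factory=lambda: PFAConfig(n_select=20))
    use_feature_selection: bool = True
    percentile: float = 95.0
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "GridConfig":
        if not self.n_grid or not self.k_grid:
            raise ValueError("grids must be non-empty")
        if any(k < 2 for k in self.k_grid):
            raise ValueError("all k must be >= 2")
        if not 0 < self.percentile < 100:
            raise ValueError("percentile must be in (0, 100)")
        return self


@dataclass
class ScreeningResult:
    best_n: int
    best_k: int
    selected_features: tuple[str, ...]
    unit_ids: tuple[str, ...]
    labels: np.ndarray
    centroids: np.ndarray
    silhouette_mean: float
    grid_table: pd.DataFrame
    appearance_counts: dict[str, int] = field(default_factory=dict)
    distances: np.ndarray | None = None
    threshold: float | None = None
    outlier_ids: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        """Per-hospital label, local distance and outlier flag."""
        flagged = set(self.outlier_ids)
        return pd.DataFrame(
            {
                "hospital_id": list(self.unit_ids),
                "cluster": self.labels.astype(int),
                "distance": self.distances,
                "outlier": [u in flagged for u in self.unit_ids],
            }
        )

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(out / "hospitals.csv", index=False)
        self.grid_table.to_csv(out / "grid_table.csv", index=False)
        summary = {
            "best_n": int(self.best_n),
            "best_k": int(self.best_k),
            "selected_features": list(self.selected_features),
            "silhouette_mean": float(self.silhouette_mean),
            "threshold": None if self.threshold is None else float(self.threshold),
            "outlier_ids": list(self.outlier_ids),
            "appearance_counts": {k: int(v) for k, v in self.appearance_counts.items()},
        }
        (out / "result.json").write_text(json.dumps(summary, indent=2))


def mean_silhouette(X: np.ndarray, labels: Sequence[int]) -> float:
    """Average silhouette width with Euclidean distances.

    ``s(i) = (b - a) / max(a, b)`` where ``a`` is the mean distance to the
    other members of i's cluster and ``b`` the smallest mean distance to
    another cluster.  Points in singleton clusters contribute 0 (so a
    labeling of all singletons scores 0).  A single cluster overall is
    undefined and raises.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("mean_silhouette undefined for a single cluster")
    n = X.shape[0]
    D = squareform(pdist(X))
    sizes = {c: int(np.sum(labels == c)) for c in uniq}
    s = np.zeros(n)
    masks = {c: labels == c for c in uniq}
    for i in range(n):
        c = labels[i]
        if sizes[c] == 1:
            s[i] = 0.0
            continue
        a = D[i, masks[c]].sum() / (sizes[c] - 1)
        b = min(D[i, masks[o]].mean() for o in uniq if o != c)
        m = max(a, b)
        s[i] = 0.0 if m == 0 else (b - a) / m
    return float(s.mean())


def _cell_seed(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence(entropy=seed, spawn_key=key).generate_state(1)[0] % (2**31))


def _fit_kmeans(values: np.ndarray, k: int, seed: int) -> KMeans:
    return KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed).fit(values)


def grid_search(X: FeatureMatrix, config: GridConfig) -> ScreeningResult:
    """Exhaustive silhouette evaluation of every (n, k) grid cell.

    Each cell runs ensemble PFA (once per n) followed by k-means; the cell
    maximizing the average silhouette wins, ties broken by smaller k then
    smaller n.  Cells with k at or above the number of units, or whose fit
    degenerates to fewer than k clusters after one re-seed, are skipped
    with a warning.  Deterministic for a fixed ``config.seed``.
    """
    Xs = X.standardize()
    n_units = len(Xs.unit_ids)
    p = len(Xs.feature_names)

    if config.use_feature_selection:
        n_values = list(dict.fromkeys(min(n, p) for n in config.n_grid))
    else:
        n_values = [p]

    selections: dict[int, tuple[tuple[str, ...], dict[str, int]]] = {}
    for ni, n in enumerate(n_values):
        if config.use_feature_selection and n < p:
            pfa_cfg = config.pfa.model_copy(
                update={"n_select": n, "seed": _cell_seed(config.seed, 1, ni)}
            )
            res = pfa_ensemble(Xs, pfa_cfg)
            selections[n] = (res.selected, res.appearance_counts)
        else:
            selections[n] = (Xs.feature_names, {})

    rows = []
    fits: dict[tuple[int, int], tuple[KMeans, tuple[str, ...]]] = {}
    for ni, n in enumerate(n_values):
        features, _ = selections[n]
        values = Xs.select(features).values
        for ki, k in enumerate(config.k_grid):
            if k >= n_units:
                warnings.warn(f"grid cell (n={n}, k={k}) skipped: k >= units", stacklevel=2)
                continue
            km = _fit_kmeans(values, k, _cell_seed(config.seed, 2, ni, ki))
            if np.unique(km.labels_).size < k:
                km = _fit_kmeans(values, k, _cell_seed(config.seed, 3, ni, ki))
            if np.unique(km.labels_).size < k:
                warnings.warn(
                    f"grid cell (n={n}, k={k}) skipped: degenerate clustering", stacklevel=2
                )
                continue
            sil = mean_silhouette(values, km.labels_)
            rows.append({"n": n, "k": k, "silhouette": sil})
            fits[(n, k)] = (km, features)

    if not rows:
        raise ValueError("every grid cell was skipped; nothing to select")
    grid_table = pd.DataFrame(rows)
    best = min(rows, key=lambda r: (-r["silhouette"], r["k"], r["n"]))
    best_n, best_k = int(best["n"]), int(best["k"])
    km, features = fits[(best_n, best_k)]
    return ScreeningResult(
        best_n=best_n,
        best_k=best_k,
        selected_features=tuple(features),
        unit_ids=Xs.unit_ids,
        labels=km.labels_.copy(),
        centroids=km.cluster_centers_.copy(),
        silhouette_mean=float(best["silhouette"]),
        grid_table=grid_table,
        appearance_counts=dict(selections[best_n][1]),
    )


def local_distances(
    X_selected: np.ndarray, labels: Sequence[int], centroids: np.ndarray
) -> np.ndarray:
    """Euclidean distance of each unit to its own cluster centroid."""
    X_selected = np.asarray(X_selected, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if X_selected.shape[1] != centroids.shape[1]:
        raise ValueError(
            f"dimension mismatch: points have {X_selected.shape[1]} features, "
            f"centroids {centroids.shape[1]}"
        )
    return np.linalg.norm(X_selected - centroids[labels], axis=1)


def flag_outliers(
    distances: Sequence[float], percentile: float = 95.0
) -> tuple[float, np.ndarray]:
    """Threshold at the empirical percentile; flag strictly above it.

    The percentile uses linear interpolation between order statistics, so
    with distinct distances exactly ``N - floor(1 + p/100 (N-1))`` units
    are flagged; with all distances equal nothing is.
    """
    d = np.asarray(distances, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 distances")
    threshold = float(np.percentile(d, percentile, method="linear"))
    return threshold, np.flatnonzero(d > threshold)


def screen(X: FeatureMatrix, config: GridConfig) -> ScreeningResult:
    """Full Step One: grid search, local distances, percentile flagging.

    With ``use_feature_selection=False`` all features are used (the
    robustness variant).  Deterministic under ``config.seed``.
    """
    Xs = X.standardize()
    result = grid_search(Xs, config)
    values = Xs.select(result.selected_features).values
    d = local_distances(values, result.labels, result.centroids)
    threshold, idx = flag_outliers(d, config.percentile)
    result.distances = d
    result.threshold = threshold
    result.outlier_ids = tuple(result.unit_ids[i] for i in idx)
    return result


def plot_distance_distribution(result: ScreeningResult, path: str | Path | None = None):
    """Histogram of local distances with the threshold as a dashed line."""
    import matplotlib.pyplot as plt

    if result.distances is None:
        raise ValueError("result has no distances; run screen() first")
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.hist(result.distances, bins=40, color="steelblue", edgecolor="white")
    if result.threshold is not None:
        ax.axvline(result.threshold, ls="--", color="black", label="95th percentile")
        ax.legend()
    ax.set_xlabel("local distance to own centroid")
    ax.set_ylabel("providers")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
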