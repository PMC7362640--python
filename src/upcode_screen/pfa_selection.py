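"""Principal Feature Analysis (PFA) and its repeated-run ensemble.

PFA is an unsupervised feature-selection method: compute the principal
decomposition of the standardized feature matrix, keep the q leading
components retaining a target fraction of variance, represent each
feature by its q-dimensional loading row, cluster the loading rows into
``n_select`` groups with k-means, and keep one representative feature per
group (the one closest to the group mean).  Redundant features have
nearly identical loading rows, land in the same group, and only one of
them survives.

Because the inner k-means is greedy, single runs are unstable; the
ensemble repeats the selection B times with derived seeds, counts how
often each feature is selected, and keeps the ``n_select`` most frequent
features.  Appearance counts double as an audit trail of selection
stability.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .aggregation import FeatureMatrix

__all__ = ["PFAConfig", "SelectionResult", "pfa_once", "pfa_ensemble"]


class PFAConfig(BaseModel):
    """Knobs of the ensemble: subset size n, repetitions B, variance target."""

    model_config = ConfigDict(frozen=True)

    n_select: int
    n_runs: int = 200
    variance_retained: float = 0.90
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "PFAConfig":
        if self.n_select < 1:
            raise ValueError("n_select must be >= 1")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if not 0 < self.variance_retained <= 1:
            raise ValueError("variance_retained must be in (0, 1]")
        return self


@dataclass(frozen=True)
class SelectionResult:
    selected: tuple[str, ...]
    appearance_counts: dict[str, int]

    def to_dict(self) -> dict:
        return {"selected": list(self.selected), "appearance_counts": dict(self.appearance_counts)}


def _loading_rows(values: np.ndarray, variance_retained: float) -> np.ndarray:
    """Feature-by-q matrix of principal-component loadings."""
    pca = PCA()
    pca.fit(values)
    cum = np.cumsum(pca.explained_variance_ratio_)
    q = int(np.searchsorted(cum, variance_retained - 1e-12) + 1)
    q = min(q, pca.components_.shape[0])
    return pca.components_[:q].T


def pfa_once(
    X: FeatureMatrix,
    n_select: int,
    variance_retained: float = 0.90,
    seed: int = 0,
) -> set[str]:
    """One PFA run: cluster loading rows, keep one feature per cluster.

    With ``n_select`` at or above the feature count all features are
    returned (with a warning).  Deterministic for a fixed seed; run-to-run
    variability comes from the random initialization of the inner k-means.
    """
    if not X.standardized:
        raise ValueError("PFA expects a standardized feature matrix")
    names = X.feature_names
    p = len(names)
    if n_select >= p:
        if n_select > p:
            warnings.warn(
                f"n_select={n_select} exceeds feature count {p}; selecting all",
                stacklevel=2,
            )
        return set(names)
    A = _loading_rows(X.values, variance_retained)
    # cluster loading rows in canonical (sorted-name) order so the result
    # does not depend on the column order of the input matrix
    canon = np.argsort(np.array(names, dtype=object))
    A = A[canon]
    sorted_names = [names[i] for i in canon]
    km = KMeans(
        n_clusters=n_select,
        init="random",
        n_init=10,
        random_state=int(seed) % (2**32),
    ).fit(A)
    selected: set[str] = set()
    for g in range(n_select):
        members = np.flatnonzero(km.labels_ == g)
        if members.size == 0:  # k-means relocates empty clusters; defensive
            continue
        d = np.linalg.norm(A[members] - km.cluster_centers_[g], axis=1)
        # round so numerically tied rows (duplicate features) break by name
        order = np.lexsort((np.array(sorted_names, dtype=object)[members], np.round(d, 10)))
        selected.add(sorted_names[members[order[0]]])
    return selected


def _run_seeds(seed: int, n_runs: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n_runs)


def pfa_ensemble(X: FeatureMatrix, config: PFAConfig) -> SelectionResult:
    """Repeat PFA B times and keep the most frequently selected features.

    Per-run seeds derive deterministically from ``config.seed``.  Ties at
    the selection boundary break by (higher count, then lexicographic
    feature name).
    """
    counts: Counter[str] = Counter()
    for run_seed in _run_seeds(config.seed, config.n_runs):
        counts.update(pfa_once(X, config.n_select, config.variance_retained, int(run_seed)))
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    n_out = min(config.n_select, len(X.feature_names))
    selected = tuple(name for name, _ in ranked[:n_out])
    return SelectionResult(selected=selected, appearance_counts=dict(counts))
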