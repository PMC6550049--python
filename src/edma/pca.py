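"""PCA of ln-transformed inter-landmark distances.

Each specimen contributes one row of ln(distance) values over all unique
landmark pairs; the principal components of the column variance-
covariance matrix summarize form variation (size and shape together).
With ``scale_free=True`` each specimen's distances are first divided by
their geometric mean — equivalently, each log-row is centered by its row
mean — giving "shape" variation with overall scale removed.

The decomposition is computed by SVD of the column-centered table,
which yields the covariance eigenstructure without materializing the
pairs × pairs matrix (relevant when pairs ≫ specimens). Components use
a deterministic sign convention: each is oriented so its largest-
magnitude loading is positive.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import distance_rows, pair_index_for
from .landmarks import LandmarkDataset, ValidationError

__all__ = [
    "DistanceTable",
    "PCAResult",
    "GroupSeparation",
    "ln_distance_table",
    "run_pca",
    "group_separation",
]


@dataclass
class DistanceTable:
    """Specimens × landmark-pairs table of ln inter-landmark distances."""

    values: np.ndarray  # (n_specimens, n_pairs), ln(distance in mm)
    pair_index: tuple[tuple[str, str], ...]
    specimen_ids: tuple[str, ...]
    groups: tuple[str, ...]
    scale_free: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, p = self.values.shape
        if n != len(self.specimen_ids) or p != len(self.pair_index):
            raise ValidationError("distance table dimensions do not match labels")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("distance table contains non-finite entries")

    def to_frame(self) -> pd.DataFrame:
        cols = pd.MultiIndex.from_tuples(self.pair_index,
                                         names=["landmark_i", "landmark_j"])
        df = pd.DataFrame(self.values, index=list(self.specimen_ids), columns=cols)
        df.index.name = "specimen"
        return df


@dataclass
class PCAResult:
    """Scores, loadings, and explained variance of a distance-table PCA."""

    scores: np.ndarray  # (n_specimens, n_components)
    loadings: np.ndarray  # (n_pairs, n_components), orthonormal columns
    explained_variance: np.ndarray  # eigenvalues (ddof=1 scale)
    explained_variance_fraction: np.ndarray
    specimen_ids: tuple[str, ...]
    groups: tuple[str, ...]
    pair_index: tuple[tuple[str, str], ...]

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def scores_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.scores,
            index=list(self.specimen_ids),
            columns=[f"PC{i + 1}" for i in range(self.n_components)],
        )
        df.insert(0, "group", list(self.groups))
        df.index.name = "specimen"
        return df


@dataclass
class GroupSeparation:
    """Between-group separation in a PC score subspace."""

    centroid_distance: float
    pooled_dispersion: float
    ratio: float
    components: tuple[int, ...]
    group_names: tuple[str, ...]


def ln_distance_table(
    dataset: LandmarkDataset, scale_free: bool = False
) -> DistanceTable:
    """Build the ln-distance table of a dataset.

    With ``scale_free=True`` each row is centered by its row mean in log
    space (geometric-mean scaling of the distances), removing overall
    size per specimen.
    """
    rows = distance_rows(dataset)
    logd = np.log(rows)
    if scale_free:
        logd = logd - logd.mean(axis=1, keepdims=True)
    sids = dataset.specimen_ids
    return DistanceTable(
        values=logd,
        pair_index=pair_index_for(dataset.landmark_labels),
        specimen_ids=sids,
        groups=tuple(dataset.group_labels[s] for s in sids),
        scale_free=scale_free,
    )


def run_pca(table: DistanceTable, n_components: int | None = None) -> PCAResult:
    """PCA of the column covariance matrix of a ln-distance table."""
    x = table.values
    n, p = x.shape
    if n < 2:
        raise ValidationError("PCA needs at least 2 specimens")
    max_comp = min(n - 1, p)
    if n_components is None:
        n_components = max_comp
    if not 1 <= n_components <= max_comp:
        raise ValidationError(
            f"n_components must be in [1, {max_comp}], got {n_components}"
        )

    centered = x - x.mean(axis=0, keepdims=True)
    # SVD gives the covariance eigenstructure: eigval_i = s_i^2 / (n-1)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    eigvals = (s ** 2) / (n - 1)
    total_var = centered.var(axis=0, ddof=1).sum()

    loadings = vt[:n_components].T  # (p, n_components)
    # deterministic orientation: largest-|loading| entry positive
    for j in range(n_components):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
    scores = centered @ loadings

    frac = eigvals[:n_components] / total_var if total_var > 0 else \
        np.zeros(n_components)
    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_variance=eigvals[:n_components],
        explained_variance_fraction=frac,
        specimen_ids=table.specimen_ids,
        groups=table.groups,
        pair_index=table.pair_index,
    )


def group_separation(
    result: PCAResult,
    groups: Sequence[str] | None = None,
    components: Iterable[int] = (1, 2),
) -> GroupSeparation:
    """Centroid separation vs within-group dispersion in PC space.

    ``components`` are 1-based PC indices. Returns the Euclidean distance
    between group centroids in the selected score subspace, the pooled
    within-group dispersion sqrt(Σ_g Σ_i ||s_i − c_g||² / (N − G)), and
    their ratio. With more than two groups the mean pairwise centroid
    distance is reported.
    """
    comps = sorted(set(int(c) for c in components))
    if not comps or comps[0] < 1 or comps[-1] > result.n_components:
        raise ValidationError(
            f"components must be within [1, {result.n_components}]"
        )
    cols = [c - 1 for c in comps]
    labels = np.asarray(result.groups, dtype=object)
    names = tuple(groups) if groups is not None else tuple(dict.fromkeys(labels))
    if len(names) < 2:
        raise ValidationError("group separation needs at least 2 groups")
    for g in names:
        if g not in labels:
            raise ValidationError(f"no specimens in group {g!r}")

    sub = result.scores[:, cols]
    centroids = {g: sub[labels == g].mean(axis=0) for g in names}
    ss = 0.0
    n_total = 0
    for g in names:
        pts = sub[labels == g]
        ss += float(((pts - centroids[g]) ** 2).sum())
        n_total += pts.shape[0]
    dof = n_total - len(names)
    pooled = float(np.sqrt(ss / dof)) if dof > 0 else 0.0

    dists = [
        float(np.linalg.norm(centroids[a] - centroids[b]))
        for i, a in enumerate(names)
        for b in names[i + 1:]
    ]
    centroid_distance = float(np.mean(dists))
    if pooled > 0:
        ratio = centroid_distance / pooled
    else:
        ratio = float("inf") if centroid_distance > 0 else 0.0
    return GroupSeparation(
        centroid_distance=centroid_distance,
        pooled_dispersion=pooled,
        ratio=ratio,
        components=tuple(comps),
        group_names=names,
    )
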