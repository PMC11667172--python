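"""Pairwise inter-subject dissimilarity indices and matrix assembly.

Indices follow the correlation- and distance-based conventions of
inter-subject representational analysis:

- time-dynamics: 1 - Pearson r between two subjects' single-region series;
- FC profile: Euclidean distance between vectorized connectivity edges,
  with per-edge absolute differences as its components;
- strength centrality: Euclidean distance between per-region strength
  vectors, with per-region absolute differences as components;
- semantic: 1 - cosine similarity of document-embedding vectors;
- gaze: see :mod:`annak.gaze`.

Matrices are symmetric with a zero diagonal; subjects whose mean
dissimilarity to the rest of the sample is extreme (|z| above threshold)
can be excluded in a single pass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DissimMatrix",
    "td_dissim",
    "fc_profile_dissim",
    "edge_dissim",
    "centrality_dissim",
    "semantic_dissim",
    "build_dissim_matrix",
    "exclude_outliers",
]


@dataclass
class DissimMatrix:
    """Symmetric subject-by-subject dissimilarity matrix for one index."""

    index_name: str
    subject_ids: list[str]
    d: np.ndarray
    failures: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.subject_ids = [str(s) for s in self.subject_ids]
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.subject_ids)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape must match subject_ids")
        if not np.allclose(self.d, self.d.T, equal_nan=True):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("diagonal must be zero")
        off = self.d[~np.eye(n, dtype=bool)]
        if np.any(off[np.isfinite(off)] < 0):
            raise ValueError("dissimilarities must be non-negative")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def condensed(self) -> np.ndarray:
        """Strict upper triangle, row-major (one value per unordered dyad)."""
        iu = np.triu_indices(self.n_subjects, k=1)
        return self.d[iu].copy()

    def subset(self, ids: list[str]) -> "DissimMatrix":
        """Restrict to the given subjects, preserving their given order."""
        pos = {s: i for i, s in enumerate(self.subject_ids)}
        idx = [pos[s] for s in ids]
        return DissimMatrix(self.index_name, list(ids), self.d[np.ix_(idx, idx)])

    def to_square_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.subject_ids, columns=self.subject_ids)

    def plot(self, order_by=None, ax=None, cmap: str = "viridis",
             standardize: bool = True):
        """Heatmap of the dissimilarity matrix.

        Parameters
        ----------
        order_by : mapping or Series, optional
            Per-subject scores (e.g. trait values); rows/columns are
            sorted by increasing score, the conventional display for
            trait-ordered inter-subject dissimilarity matrices.
        standardize : bool
            Show z-scored dissimilarities (color scale comparable across
            indices).
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        ids = list(self.subject_ids)
        if order_by is not None:
            ids = sorted(ids, key=lambda s: order_by[s])
        dm = self.subset(ids)
        d = dm.d.copy()
        if standardize:
            off = ~np.eye(dm.n_subjects, dtype=bool)
            vals = d[off]
            sd = np.nanstd(vals)
            if sd > 0:
                d = (d - np.nanmean(vals)) / sd
                np.fill_diagonal(d, np.nan)
        im = ax.imshow(d, cmap=cmap)
        ax.set_title(self.index_name)
        ax.set_xlabel("subjects" + (" (by score)" if order_by is not None else ""))
        ax.set_ylabel("subjects")
        plt.colorbar(im, ax=ax,
                     label="standardized dissimilarity" if standardize
                     else "dissimilarity")
        return ax

    def to_tidy_frame(self) -> pd.DataFrame:
        """One row per unordered dyad: subject_i, subject_j, index, value."""
        rows = []
        n = self.n_subjects
        for i in range(n):
            for j in range(i + 1, n):
                rows.append(
                    (self.subject_ids[i], self.subject_ids[j], self.index_name,
                     self.d[i, j])
                )
        return pd.DataFrame(rows, columns=["subject_i", "subject_j", "index", "value"])


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("series lengths differ")
    if a.size < 3:
        raise ValueError("need at least 3 samples")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance series: correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def td_dissim(ts_i: np.ndarray, ts_j: np.ndarray) -> float:
    """Time-dynamics dissimilarity of a single region: 1 - Pearson r."""
    return 1.0 - _pearson(ts_i, ts_j)


def fc_profile_dissim(v_i: np.ndarray, v_j: np.ndarray) -> float:
    """Euclidean distance between two vectorized connectivity profiles."""
    v_i = np.asarray(v_i, dtype=float)
    v_j = np.asarray(v_j, dtype=float)
    if v_i.shape != v_j.shape:
        raise ValueError("edge vector lengths differ")
    return float(np.linalg.norm(v_i - v_j))


def edge_dissim(v_i: np.ndarray, v_j: np.ndarray) -> np.ndarray:
    """Per-edge dissimilarity: elementwise |z_i - z_j|.

    The squared global profile distance equals the sum of these squared.
    """
    v_i = np.asarray(v_i, dtype=float)
    v_j = np.asarray(v_j, dtype=float)
    if v_i.shape != v_j.shape:
        raise ValueError("edge vector lengths differ")
    return np.abs(v_i - v_j)


def centrality_dissim(s_i, s_j) -> tuple[float, np.ndarray]:
    """Global and per-region strength-centrality dissimilarity.

    Accepts :class:`~annak.connectome.StrengthVector` instances or plain
    arrays. Returns ``(Euclidean distance, per-region |difference|)``.
    """
    names_i = getattr(s_i, "roi_names", None)
    names_j = getattr(s_j, "roi_names", None)
    if names_i is not None and names_j is not None and list(names_i) != list(names_j):
        raise ValueError("ROI order differs between strength vectors")
    a = np.asarray(getattr(s_i, "s", s_i), dtype=float)
    b = np.asarray(getattr(s_j, "s", s_j), dtype=float)
    if a.shape != b.shape:
        raise ValueError("strength vector lengths differ")
    per_region = np.abs(a - b)
    return float(np.linalg.norm(a - b)), per_region


def semantic_dissim(v_i: np.ndarray, v_j: np.ndarray) -> float:
    """Semantic dissimilarity of two document embeddings: 1 - cosine."""
    v_i = np.asarray(v_i, dtype=float)
    v_j = np.asarray(v_j, dtype=float)
    if v_i.shape != v_j.shape:
        raise ValueError("embedding dimensions differ")
    ni, nj = np.linalg.norm(v_i), np.linalg.norm(v_j)
    if ni == 0 or nj == 0:
        raise ValueError("zero embedding vector: cosine undefined")
    return 1.0 - float(v_i @ v_j) / (ni * nj)


def build_dissim_matrix(
    features: Mapping[str, object],
    metric: Callable[[object, object], float],
    index_name: str,
    *,
    allow_missing: bool = False,
) -> DissimMatrix:
    """Apply a pairwise metric to all unordered subject pairs.

    Parameters
    ----------
    features : mapping of subject_id -> feature
        Per-subject features in a stable order.
    metric : callable
        ``metric(feat_i, feat_j) -> float``. Pairwise failures (ValueError)
        are recorded; unless ``allow_missing`` the first failure aborts.

    Returns
    -------
    DissimMatrix
        n x n symmetric matrix with n(n-1)/2 unique entries; failed dyads
        are NaN when ``allow_missing``.
    """
    ids = list(features.keys())
    if len(ids) < 2:
        raise ValueError("need at least 2 subjects")
    n = len(ids)
    d = np.zeros((n, n))
    failures: list[tuple[str, str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            try:
                val = float(metric(features[ids[i]], features[ids[j]]))
                if val < 0 and val > -1e-12:
                    val = 0.0  # rounding guard for identical features
            except ValueError as exc:
                if not allow_missing:
                    raise ValueError(
                        f"dissimilarity failed for dyad ({ids[i]!r}, {ids[j]!r}): {exc}"
                    ) from exc
                failures.append((ids[i], ids[j], str(exc)))
                val = np.nan
            d[i, j] = d[j, i] = val
    return DissimMatrix(index_name, ids, d, failures)


def retained_ids(dm: DissimMatrix) -> list[str]:
    """Subjects with at least one finite off-diagonal entry.

    Excluded subjects are represented by all-NaN rows/columns (the zero
    diagonal does not count as data).
    """
    n = dm.n_subjects
    off = ~np.eye(n, dtype=bool)
    return [
        s for i, s in enumerate(dm.subject_ids)
        if not np.isnan(dm.d[i][off[i]]).all()
    ]


def exclude_outliers(
    dm: DissimMatrix, z_threshold: float = 3.0
) -> tuple[list[str], pd.DataFrame]:
    """Single-pass exclusion of subjects with extreme mean dissimilarity.

    Each subject's mean off-diagonal dissimilarity is z-scored across
    subjects; subjects with |z| above the threshold are removed. The rule
    is applied once (no re-iteration after removal), per index.

    Returns
    -------
    retained : list of subject ids
    exclusions : DataFrame with columns subject_id, mean_dissim, z
    """
    n = dm.n_subjects
    if n < 4:
        raise ValueError("need at least 4 subjects for outlier screening")
    mask = ~np.eye(n, dtype=bool)
    means = np.array([np.nanmean(dm.d[i][mask[i]]) for i in range(n)])
    sd = means.std(ddof=1)
    if sd == 0:
        warnings.warn("zero spread of mean dissimilarities; no exclusions",
                      RuntimeWarning, stacklevel=2)
        z = np.zeros(n)
    else:
        z = (means - means.mean()) / sd
    out = np.abs(z) > z_threshold
    exclusions = pd.DataFrame(
        {"subject_id": np.array(dm.subject_ids)[out],
         "mean_dissim": means[out], "z": z[out]}
    )
    retained = [s for s, o in zip(dm.subject_ids, out) if not o]
    return retained, exclusions
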