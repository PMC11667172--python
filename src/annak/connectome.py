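"""Per-subject neural features from ROI time series.

Functional connectivity (Fisher-z Pearson correlations between regions),
strength centrality (row sums of the z matrix), temporal inter-subject
correlation, time-window segmentation, and the within- vs outside-network
connectivity contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "RoiTimeSeries",
    "FCMatrix",
    "StrengthVector",
    "NetworkContrastResult",
    "fisher_z",
    "compute_fc",
    "vectorize_upper",
    "unvectorize_upper",
    "strength_centrality",
    "temporal_isc",
    "segment",
    "network_contrast",
]

#: correlations with |r| >= 1 - CLAMP_TOL are clamped to +/-(1 - CLAMP_TOL)
#: before arctanh so that numerically perfect correlations stay finite.
CLAMP_TOL = 1e-7


@dataclass
class RoiTimeSeries:
    """One subject's extracted ROI time series for one scanning condition.

    Parameters
    ----------
    subject_id : str
        Subject identifier.
    condition : str
        Scanning condition, ``"movie"`` or ``"rest"``.
    values : ndarray, shape (n_timepoints, n_regions)
        BOLD signal per timepoint (TR) and region; arbitrary units.
    roi_names : list of str
        Region labels, one per column, unique.
    tr_seconds : float
        Sampling interval (repetition time) in seconds.
    """

    subject_id: str
    condition: str
    values: np.ndarray
    roi_names: list[str]
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2D (timepoints x regions) array")
        if self.values.shape[0] < 3:
            raise ValueError("need at least 3 timepoints")
        if self.values.shape[1] < 2:
            raise ValueError("need at least 2 regions")
        if not np.isfinite(self.values).all():
            raise ValueError(
                f"non-finite values in time series of subject {self.subject_id!r}"
            )
        self.roi_names = list(self.roi_names)
        if len(self.roi_names) != self.values.shape[1]:
            raise ValueError("roi_names length must match number of columns")
        if len(set(self.roi_names)) != len(self.roi_names):
            raise ValueError("roi_names must be unique")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass
class FCMatrix:
    """Region-by-region functional connectivity in Fisher-z space.

    The diagonal is fixed at 0 by convention (self-correlation excluded);
    all downstream sums and vectorizations use off-diagonal entries only.
    ``clamped_edges`` records region pairs whose |r| reached the clamping
    window (numerically perfect correlation).
    """

    subject_id: str
    z: np.ndarray
    roi_names: list[str]
    clamped_edges: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        n = len(self.roi_names)
        if self.z.shape != (n, n):
            raise ValueError("z must be square and match roi_names")
        if not np.allclose(self.z, self.z.T, atol=1e-12):
            raise ValueError("z must be symmetric")
        if not np.allclose(np.diag(self.z), 0.0):
            raise ValueError("diagonal of z must be 0 by convention")
        off = self.z[~np.eye(n, dtype=bool)]
        if not np.isfinite(off).all():
            raise ValueError("off-diagonal z values must be finite")

    @property
    def n_regions(self) -> int:
        return len(self.roi_names)


@dataclass
class StrengthVector:
    """Per-region strength centrality: the sum of a region's Fisher-z
    connectivity with all other regions in the network."""

    subject_id: str
    s: np.ndarray
    roi_names: list[str]

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        if self.s.shape != (len(self.roi_names),):
            raise ValueError("s must have one entry per region")


def fisher_z(r, *, clamp_tol: float = CLAMP_TOL, edge: str | None = None):
    """Fisher z-transform, ``z = arctanh(r)``, with a clamping window.

    Values with ``1 - clamp_tol <= |r| <= 1`` are clamped to
    ``+/-(1 - clamp_tol)`` with a warning; ``|r| > 1`` is rejected.

    Parameters
    ----------
    r : float or ndarray
        Correlation coefficient(s).
    clamp_tol : float
        Width of the clamping window below ±1.
    edge : str, optional
        Label naming the edge, used in diagnostics.
    """
    r = np.asarray(r, dtype=float)
    label = f" for edge {edge}" if edge else ""
    if np.any(np.abs(r) > 1.0):
        raise ValueError(f"|r| > 1{label}: not a correlation coefficient")
    hi = np.abs(r) >= 1.0 - clamp_tol
    if np.any(hi):
        warnings.warn(
            f"correlation(s) with |r| >= {1 - clamp_tol}{label} clamped before arctanh",
            RuntimeWarning,
            stacklevel=2,
        )
        r = np.clip(r, -(1.0 - clamp_tol), 1.0 - clamp_tol)
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def compute_fc(ts: RoiTimeSeries, *, clamp_tol: float = CLAMP_TOL) -> FCMatrix:
    """Pairwise Pearson correlations between all regions, Fisher z-transformed.

    Raises
    ------
    ValueError
        If any region's time series is constant (zero variance), naming it.
    """
    X = ts.values
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = [ts.roi_names[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant time series for ROI(s) {bad}: correlation undefined")
    r = np.corrcoef(X, rowvar=False)
    n = ts.n_regions
    clamped = []
    iu = np.triu_indices(n, k=1)
    for i, j in zip(*iu):
        if abs(r[i, j]) >= 1.0 - clamp_tol:
            clamped.append((ts.roi_names[i], ts.roi_names[j]))
    with warnings.catch_warnings():
        if clamped:
            warnings.simplefilter("ignore", RuntimeWarning)
        z = np.arctanh(np.clip(r, -(1.0 - clamp_tol), 1.0 - clamp_tol))
    if clamped:
        warnings.warn(
            f"clamped numerically perfect correlation(s) for edges {clamped} "
            f"of subject {ts.subject_id!r}",
            RuntimeWarning,
            stacklevel=2,
        )
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0  # enforce exact symmetry against rounding
    return FCMatrix(ts.subject_id, z, list(ts.roi_names), clamped)


def vectorize_upper(fc: FCMatrix) -> np.ndarray:
    """Flatten the strict upper triangle of the z matrix, row-major.

    For R regions the vector has length R(R-1)/2; the ordering follows the
    ROI order of the matrix: (0,1), (0,2), ..., (0,R-1), (1,2), ...
    This ordering is stable and is the one used for per-edge reports.
    """
    iu = np.triu_indices(fc.n_regions, k=1)
    return fc.z[iu].copy()


def unvectorize_upper(vec: np.ndarray, roi_names: list[str],
                      subject_id: str = "") -> FCMatrix:
    """Inverse of :func:`vectorize_upper` (zero diagonal restored)."""
    n = len(roi_names)
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (n * (n - 1) // 2,):
        raise ValueError("vector length does not match n(n-1)/2 for roi_names")
    z = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    z[iu] = vec
    z = z + z.T
    return FCMatrix(subject_id, z, list(roi_names))


def strength_centrality(fc: FCMatrix) -> StrengthVector:
    """Row sums of the off-diagonal Fisher-z connectivity matrix."""
    s = fc.z.sum(axis=1)  # diagonal is 0, so this is the off-diagonal sum
    return StrengthVector(fc.subject_id, s, list(fc.roi_names))


def temporal_isc(ts_i: RoiTimeSeries, ts_j: RoiTimeSeries) -> np.ndarray:
    """Per-region Pearson correlation of two subjects' time series.

    Both series must share shape, ROI order, and condition.
    """
    if ts_i.values.shape != ts_j.values.shape:
        raise ValueError("time series shapes differ")
    if ts_i.roi_names != ts_j.roi_names:
        raise ValueError("ROI order differs between subjects")
    a, b = ts_i.values, ts_j.values
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    denom = np.sqrt((ac**2).sum(axis=0) * (bc**2).sum(axis=0))
    if np.any(denom == 0):
        raise ValueError("zero-variance region in one of the series")
    return (ac * bc).sum(axis=0) / denom


def segment(ts: RoiTimeSeries, window: tuple[int, int]) -> RoiTimeSeries:
    """Restrict a series to a 1-based, both-ends-inclusive TR window.

    ``segment(ts, (1, 50))`` keeps the first 50 TRs; the movie windows
    (1-50), (51-110), (111-151) partition a 151-TR series exactly.
    """
    start, end = window
    if not (1 <= start <= end <= ts.n_timepoints):
        raise ValueError(
            f"window {window} out of range for series with {ts.n_timepoints} TRs"
        )
    return RoiTimeSeries(
        ts.subject_id,
        ts.condition,
        ts.values[start - 1 : end].copy(),
        list(ts.roi_names),
        ts.tr_seconds,
    )


@dataclass
class NetworkContrastResult:
    """Within- minus outside-network seed connectivity, tested across subjects."""

    diffs: np.ndarray  # per-subject mean(within) - mean(outside)
    t: float
    p: float
    df: int
    degenerate: bool = False


def network_contrast(seed_values: np.ndarray, in_network: np.ndarray) -> NetworkContrastResult:
    """Contrast mean seed connectivity within vs. outside a network.

    Parameters
    ----------
    seed_values : ndarray, shape (n_subjects, n_regions)
        Per-subject seed-to-region connectivity values (Fisher z).
    in_network : boolean array, shape (n_regions,)
        True for regions inside the network.

    Returns
    -------
    NetworkContrastResult
        Per-subject differences and a one-sample t-test of the differences
        against zero. A zero-variance set of differences is reported as
        degenerate rather than producing a spurious statistic.
    """
    seed_values = np.atleast_2d(np.asarray(seed_values, dtype=float))
    in_network = np.asarray(in_network, dtype=bool)
    if seed_values.shape[1] != in_network.shape[0]:
        raise ValueError("label length must match number of regions")
    if in_network.all() or (~in_network).all():
        raise ValueError("both network label classes must be non-empty")
    if seed_values.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    diffs = seed_values[:, in_network].mean(axis=1) - seed_values[:, ~in_network].mean(axis=1)
    df = len(diffs) - 1
    if diffs.std(ddof=1) == 0:
        m = diffs.mean()
        if m == 0:
            return NetworkContrastResult(diffs, 0.0, 1.0, df, degenerate=True)
        warnings.warn("zero-variance network contrast; t undefined", RuntimeWarning,
                      stacklevel=2)
        return NetworkContrastResult(diffs, np.inf if m > 0 else -np.inf, 0.0, df,
                                     degenerate=True)
    t, p = stats.ttest_1samp(diffs, 0.0)
    return NetworkContrastResult(diffs, float(t), float(p), df)
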