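"""Mantel permutation test and confound residualization for dyad values.

The Mantel statistic is the Pearson correlation between the condensed
(strict upper triangle) forms of two subject-by-subject dissimilarity
matrices. Its null distribution is built by jointly permuting the rows
and columns of one matrix (a subject-label permutation), which respects
the dependence structure of distance entries sharing a subject. The
permutation count includes the identity (+1 convention), so p is never 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations as _permutations

import numpy as np

from .dissim import DissimMatrix

__all__ = ["MantelResult", "mantel", "residualize"]


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    alternative: str
    df_report: int  #: n_subjects - 2, the df convention used when printing r(df)
    exhaustive: bool = False

    def __str__(self) -> str:
        return (f"Mantel r({self.df_report}) = {self.r:.3f}, "
                f"p = {self.p:.4g} ({self.alternative}, "
                f"{'exhaustive' if self.exhaustive else f'{self.n_perm} permutations'})")


def _condensed(d: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(d.shape[0], k=1)
    return d[iu]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        raise ValueError("zero-variance condensed matrix in Mantel test")
    return float(a @ b / denom)


def mantel(
    dm_a: DissimMatrix | np.ndarray,
    dm_b: DissimMatrix | np.ndarray,
    n_perm: int = 10_000,
    alternative: str = "greater",
    seed: int | np.random.Generator | None = None,
    *,
    exhaustive_max_n: int = 6,
) -> MantelResult:
    """Mantel test between two dissimilarity matrices on the same subjects.

    Parameters
    ----------
    dm_a, dm_b : DissimMatrix or square ndarray
        Must share the subject set and order.
    n_perm : int
        Number of random label permutations. For small samples
        (n <= ``exhaustive_max_n``) the full permutation group is
        enumerated instead, giving an exact p.
    alternative : {"greater", "less", "two-sided"}
        Directional hypotheses default to "greater" (larger dissimilarity
        in one matrix goes with larger dissimilarity in the other).
    seed : int, Generator, or None
        Reproducibility control for the random permutations.
    """
    if isinstance(dm_a, DissimMatrix) and isinstance(dm_b, DissimMatrix):
        if dm_a.subject_ids != dm_b.subject_ids:
            raise ValueError("subject sets/order differ between matrices")
    A = dm_a.d if isinstance(dm_a, DissimMatrix) else np.asarray(dm_a, dtype=float)
    B = dm_b.d if isinstance(dm_b, DissimMatrix) else np.asarray(dm_b, dtype=float)
    if A.shape != B.shape or A.shape[0] != A.shape[1]:
        raise ValueError("matrices must be square and of equal size")
    n = A.shape[0]
    if n < 4:
        raise ValueError("need at least 4 subjects for a Mantel test")
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError("alternative must be greater, less, or two-sided")

    va = _condensed(A)
    r_obs = _pearson(va, _condensed(B))

    def exceed(r_null: float) -> bool:
        if alternative == "greater":
            return r_null >= r_obs
        if alternative == "less":
            return r_null <= r_obs
        return abs(r_null) >= abs(r_obs)

    if n <= exhaustive_max_n:
        perms = list(_permutations(range(n)))
        count = sum(
            exceed(_pearson(va, _condensed(B[np.ix_(p, p)]))) for p in perms
        )
        # identity permutation is part of the enumeration
        return MantelResult(r_obs, count / len(perms), len(perms) - 1,
                            alternative, n - 2, exhaustive=True)

    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    count = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        count += exceed(_pearson(va, _condensed(B[np.ix_(p, p)])))
    return MantelResult(r_obs, (1 + count) / (1 + n_perm), n_perm,
                        alternative, n - 2)


def residualize(values: np.ndarray, confounds: np.ndarray | None) -> np.ndarray:
    """OLS residuals of dyad-level values on confound dyad means.

    With no confounds this reduces to centering. Collinear confound
    columns are dropped (numerically, via a pivoted least-squares fit on
    the full design; residuals are unaffected by which redundant column
    is dropped). Residuals are orthogonal to every confound column and to
    the intercept.
    """
    y = np.asarray(values, dtype=float).ravel()
    if confounds is None or (hasattr(confounds, "__len__") and len(confounds) == 0):
        return y - y.mean()
    X = np.atleast_2d(np.asarray(confounds, dtype=float))
    if X.shape[0] != y.shape[0]:
        X = X.T
    if X.shape[0] != y.shape[0]:
        raise ValueError("confound rows must match number of dyad values")
    if y.shape[0] < X.shape[1] + 2:
        raise ValueError("need at least (n_confounds + 2) dyads")
    design = np.column_stack([np.ones_like(y), X])
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        import warnings

        warnings.warn("collinear confound columns; redundant directions dropped",
                      RuntimeWarning, stacklevel=2)
    return y - design @ beta
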