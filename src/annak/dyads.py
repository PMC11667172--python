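"""Dyad-level data assembly: trait median splits, covariate screening,
and the one-row-per-unordered-dyad table consumed by the mixed models."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dissim import DissimMatrix

__all__ = ["median_split", "screen_covariates", "DyadTable", "build_dyad_table"]


def median_split(scores: pd.Series | Mapping[str, float]) -> pd.Series:
    """Dichotomize scores at the sample median.

    Scores strictly above the median are "high"; scores at or below the
    median are "low" (ties at the median go to the low group, matching
    the questionnaire-cutoff convention "high iff score > median").
    """
    s = pd.Series(scores, dtype=float)
    if len(s) < 2:
        raise ValueError("need at least 2 subjects to split")
    med = s.median()
    if (s == s.iloc[0]).all():
        raise ValueError("all scores equal: no median split possible")
    return pd.Series(np.where(s > med, "high", "low"), index=s.index, name="group")


def screen_covariates(
    subjects: pd.DataFrame,
    trait: str,
    candidates: Sequence[str] | None = None,
    *,
    categorical: Sequence[str] = (),
    alpha: float = 0.05,
) -> tuple[list[str], pd.DataFrame]:
    """Flag covariates confounded with the trait.

    A candidate is a confound if its Pearson correlation with the trait
    is significant, OR it differs between the high/low trait groups
    (two-sample t for continuous candidates, chi-square for categorical
    ones), at level ``alpha``. Constant covariates are skipped with a
    warning.

    Returns
    -------
    confounds : list of flagged covariate names
    detail : DataFrame with per-candidate test statistics and p-values
    """
    if candidates is None:
        candidates = [c for c in subjects.columns if c != trait]
    groups = median_split(subjects[trait])
    records = []
    confounds = []
    for name in candidates:
        x = subjects[name]
        if x.nunique() <= 1:
            warnings.warn(f"covariate {name!r} is constant; skipped", RuntimeWarning,
                          stacklevel=2)
            continue
        is_cat = name in categorical
        xv = pd.to_numeric(x, errors="coerce") if not is_cat else x
        r_p = np.nan
        r = np.nan
        if not is_cat:
            r, r_p = stats.pearsonr(xv.astype(float), subjects[trait].astype(float))
        if is_cat:
            tab = pd.crosstab(x, groups)
            stat, g_p = stats.chi2_contingency(tab)[:2]
        else:
            hi = xv[groups == "high"].astype(float)
            lo = xv[groups == "low"].astype(float)
            stat, g_p = stats.ttest_ind(hi, lo)
        flagged = (not np.isnan(r_p) and r_p < alpha) or g_p < alpha
        if flagged:
            confounds.append(name)
        records.append(
            {"covariate": name, "categorical": is_cat, "r_trait": r, "p_corr": r_p,
             "stat_group": float(stat), "p_group": float(g_p), "confound": flagged}
        )
    return confounds, pd.DataFrame(records)


@dataclass
class DyadTable:
    """One row per unordered dyad of retained subjects.

    ``data`` columns: p1, p2 (member ids), group (HH/HL/LL from the trait
    median split), mean_trait, one column per dissimilarity index, and for
    each confound both a dyad-level group code (``<name>_group``, from
    that covariate's own median split) and the dyad mean of the raw
    values (``<name>_mean``).
    """

    data: pd.DataFrame
    subject_ids: list[str]
    index_names: list[str]
    confounds: list[str] = field(default_factory=list)

    @property
    def n_dyads(self) -> int:
        return len(self.data)

    def __post_init__(self) -> None:
        n = len(self.subject_ids)
        if self.n_dyads != n * (n - 1) // 2:
            raise ValueError("row count must equal n(n-1)/2 over retained subjects")
        if (self.data["p1"] == self.data["p2"]).any():
            raise ValueError("self-dyads are not allowed")


def _dyad_group(g1: str, g2: str) -> str:
    pair = sorted([g1[0].upper(), g2[0].upper()])
    return "".join(pair)  # HH, HL, LL (unordered)


def build_dyad_table(
    subjects: pd.DataFrame,
    trait: str,
    dissim: Mapping[str, DissimMatrix],
    confounds: Sequence[str] = (),
    *,
    subject_ids: Sequence[str] | None = None,
) -> DyadTable:
    """Enumerate all unordered dyads with groups, traits, and index values.

    Parameters
    ----------
    subjects : DataFrame indexed by subject id
        Must contain the trait column and any confound columns.
    trait : str
        Trait column name; the HH/HL/LL dyad group comes from its median
        split, ``mean_trait`` is the members' average.
    dissim : mapping index name -> DissimMatrix
        Matrices may cover subject subsets (after per-index outlier
        exclusion); a dyad with a missing member for some index gets NaN
        in that column.
    confounds : sequence of str
        Covariates to carry along, each binarized by its own median split
        into an HH/HL/LL dyad code plus a dyad-mean column.
    """
    if subject_ids is None:
        subject_ids = list(subjects.index)
    subject_ids = [str(s) for s in subject_ids]
    groups = median_split(subjects.loc[subject_ids, trait])
    cov_groups = {}
    for name in confounds:
        col = pd.to_numeric(subjects.loc[subject_ids, name], errors="coerce")
        try:
            cov_groups[name] = median_split(col)
        except ValueError:
            warnings.warn(f"confound {name!r} has no spread; dyad code skipped",
                          RuntimeWarning, stacklevel=2)
            cov_groups[name] = None

    lookups = {}
    for idx_name, dm in dissim.items():
        pos = {s: i for i, s in enumerate(dm.subject_ids)}
        lookups[idx_name] = (pos, dm.d)

    rows = []
    for i, a in enumerate(subject_ids):
        for b in subject_ids[i + 1 :]:
            row = {
                "p1": a,
                "p2": b,
                "group": _dyad_group(groups[a], groups[b]),
                "mean_trait": (subjects.loc[a, trait] + subjects.loc[b, trait]) / 2.0,
            }
            for idx_name, (pos, d) in lookups.items():
                if a in pos and b in pos:
                    row[idx_name] = d[pos[a], pos[b]]
                else:
                    row[idx_name] = np.nan
            for name in confounds:
                cg = cov_groups[name]
                row[f"{name}_group"] = (
                    _dyad_group(cg[a], cg[b]) if cg is not None else "HH"
                )
                va = pd.to_numeric(subjects.loc[a, name])
                vb = pd.to_numeric(subjects.loc[b, name])
                row[f"{name}_mean"] = (va + vb) / 2.0
            rows.append(row)
    data = pd.DataFrame(rows)
    missing = {
        idx: int(data[idx].isna().sum()) for idx in dissim if data[idx].isna().any()
    }
    if missing:
        warnings.warn(f"dyads with missing index values: {missing}", RuntimeWarning,
                      stacklevel=2)
    return DyadTable(data, subject_ids, list(dissim.keys()), list(confounds))
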