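"""Dyadic linear mixed models for inter-subject dissimilarity.

The estimation strategy follows the double-entry convention for
indistinguishable dyads: every unordered dyad contributes two rows with
the member roles swapped, and the model carries crossed random intercepts
for the two member columns, so each participant's tendency to be globally
(dis)similar to others is absorbed regardless of role. Fixed effects are
either the HH/HL/LL dyad-group factor (with covariate dyad-group factors)
or the continuous dyad mean trait (with covariate dyad means). The
dependent variable and all continuous predictors are standardized over
unique dyads before doubling, so coefficients are on the standardized
scale.

Two inference corrections are applied on top of the REML/ML fit:

1. *Degrees of freedom*: Wald t/F tests use ``df = N - k`` where N is the
   number of unique dyads (not doubled rows) and k counts fixed effects
   (by default the single focal predictor).
2. *Double-entry covariance*: duplicating every row doubles the apparent
   Fisher information, shrinking Wald standard errors by ~sqrt(2); the
   fixed-effects covariance is therefore scaled by 2. Without this the
   dyad-group test is strongly anticonservative (empirical type-I error
   ~0.17 at a nominal 0.05 in null simulations; ~0.04 with it). Set
   ``se_correction=False`` to reproduce the uncorrected covariance.

Pairwise group contrasts are computed emmeans-style as differences of
marginal means averaged over covariate factor levels (equal weights by
default), with Benjamini-Hochberg adjustment across the contrast family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd
import patsy
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .dyads import DyadTable

__all__ = [
    "DyadLMM",
    "DyadLMMResults",
    "InteractionResult",
    "ModelFitError",
    "fit_group_lmm",
    "fit_continuous_lmm",
    "network_interaction",
    "fdr_adjust",
]

GROUP_ORDER = ("HH", "HL", "LL")
CONTRAST_PAIRS = (("HH", "HL"), ("HH", "LL"), ("HL", "LL"))


class ModelFitError(RuntimeError):
    """Raised when the mixed model cannot be brought to convergence."""


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, adjusted >= raw)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _zscore_unique(x: pd.Series) -> pd.Series:
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        return x * 0.0
    return (x - x.mean()) / sd


def _double(df: pd.DataFrame) -> pd.DataFrame:
    swapped = df.rename(columns={"p1": "p2", "p2": "p1"})
    return pd.concat([df, swapped], ignore_index=True)


@dataclass
class DyadLMM:
    """Dyadic mixed model for one dissimilarity index.

    Parameters
    ----------
    table : DyadTable or DataFrame
        One row per unordered dyad (p1, p2, group, mean_trait, index
        columns, covariate codes).
    dv : str
        Column holding the dissimilarity index to model.
    predictor : {"group", "mean_trait"}
        Focal fixed effect: the HH/HL/LL dyad-group factor, or the
        standardized dyad mean trait as a continuous slope.
    covariates : sequence of str
        Confound names; entered as ``<name>_group`` factors under the
        group predictor and as standardized ``<name>_mean`` columns under
        the continuous predictor.
    k : int or {"focal", "all"}
        Fixed-effect count for the df correction ``df = N - k``. "focal"
        (default) counts only the focal predictor (k = 1), matching the
        convention of treating covariates as nuisance terms; "all" counts
        every non-intercept design column.
    se_correction : bool
        Apply the double-entry covariance correction (see module notes).
    """

    table: DyadTable | pd.DataFrame
    dv: str
    predictor: str = "group"
    covariates: Sequence[str] = ()
    k: int | str = "focal"
    se_correction: bool = True

    def __post_init__(self) -> None:
        df = self.table.data if isinstance(self.table, DyadTable) else self.table
        if self.predictor not in ("group", "mean_trait"):
            raise ValueError("predictor must be 'group' or 'mean_trait'")
        if self.dv not in df.columns:
            raise ValueError(f"dependent variable {self.dv!r} not in table")
        df = df.dropna(subset=[self.dv]).copy()
        df["_dv"] = _zscore_unique(df[self.dv].astype(float))
        terms = []
        if self.predictor == "group":
            if df["group"].nunique() < 2:
                raise ValueError("need at least two dyad groups represented")
            terms.append(f"C(group, levels={list(GROUP_ORDER)})")
            for name in self.covariates:
                col = f"{name}_group"
                if col not in df.columns:
                    raise ValueError(f"missing covariate dyad code column {col!r}")
                if df[col].nunique() > 1:
                    terms.append(f"C({col}, levels={list(GROUP_ORDER)})")
        else:
            df["_mt"] = _zscore_unique(df["mean_trait"].astype(float))
            terms.append("_mt")
            for name in self.covariates:
                col = f"{name}_mean"
                if col not in df.columns:
                    raise ValueError(f"missing covariate dyad-mean column {col!r}")
                zcol = f"_{name}_mean_z"
                df[zcol] = _zscore_unique(df[col].astype(float))
                terms.append(zcol)
        self._unique = df
        self._formula = "_dv ~ " + " + ".join(terms)

    @property
    def n_unique(self) -> int:
        return len(self._unique)

    def fit(self, reml: bool = True,
            methods: Sequence[str] = ("lbfgs", "bfgs", "powell")) -> "DyadLMMResults":
        dbl = _double(self._unique)
        dbl["_one"] = 1
        model = smf.mixedlm(
            self._formula, dbl, groups="_one",
            vc_formula={"p1": "0 + C(p1)", "p2": "0 + C(p2)"},
        )
        res = None
        diagnostics: list[str] = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", UserWarning)
            for method in methods:
                try:
                    cand = model.fit(reml=reml, method=method, maxiter=200)
                except (np.linalg.LinAlgError, ValueError) as exc:
                    diagnostics.append(f"{method}: {exc}")
                    continue
                if np.all(np.isfinite(cand.params)):
                    res = cand
                    if not cand.converged:
                        diagnostics.append(f"{method}: optimizer did not report "
                                           "convergence; estimates retained")
                    break
                diagnostics.append(f"{method}: non-finite estimates")
        if res is None:
            raise ModelFitError(
                "mixed model failed to converge; settings: "
                f"formula={self._formula!r}, reml={reml}, methods={list(methods)}, "
                f"n_rows={len(dbl)}, n_unique={self.n_unique}"
            )
        if np.any(res.vcomp < 1e-10):
            diagnostics.append("variance component at boundary (~0); retained at floor")
        k_exog = res.model.exog.shape[1] - 1  # non-intercept fixed-effect columns
        k = 1 if self.k == "focal" else (k_exog if self.k == "all" else int(self.k))
        fe_names = list(res.model.exog_names)
        params = pd.Series(res.params[: len(fe_names)].values, index=fe_names)
        cov = pd.DataFrame(
            np.asarray(res.cov_params())[: len(fe_names), : len(fe_names)],
            index=fe_names, columns=fe_names,
        )
        if self.se_correction:
            cov = cov * 2.0
        return DyadLMMResults(
            model=self,
            params=params,
            cov_params=cov,
            vcomp=pd.Series(res.vcomp, index=["p1", "p2"]),
            scale=float(res.scale),
            n_unique=self.n_unique,
            n_rows=len(dbl),
            k=k,
            reml=reml,
            converged=bool(res.converged),
            diagnostics=diagnostics,
            design_info=res.model.data.design_info,
            data=self._unique,
        )


@dataclass
class DyadLMMResults:
    """Fitted dyadic mixed model: standardized estimates and Wald tests.

    ``params``/``bse`` are on the standardized scale; ``df_resid`` is the
    corrected ``N - k`` with N the number of unique dyads. ``contrasts``
    (group predictor only) holds the emmeans-style pairwise group
    differences with raw and BH-adjusted p-values.
    """

    model: DyadLMM
    params: pd.Series
    cov_params: pd.DataFrame
    vcomp: pd.Series
    scale: float
    n_unique: int
    n_rows: int
    k: int
    reml: bool
    converged: bool
    diagnostics: list[str]
    design_info: object
    data: pd.DataFrame
    _contrasts: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params)), index=self.params.index)

    @property
    def df_resid(self) -> int:
        return self.n_unique - self.k

    @property
    def tvalues(self) -> pd.Series:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        t = self.tvalues.fillna(0.0)
        return pd.Series(
            2 * stats.t.sf(np.abs(t), self.df_resid), index=self.params.index
        )

    # -- emmeans-style machinery -------------------------------------------

    def _marginal_design(self, level: str, weighting: str) -> np.ndarray:
        """Design row for one group level, averaged over covariate levels."""
        factor_cols = [
            f"{name}_group"
            for name in self.model.covariates
            if f"{name}_group" in self.data.columns
            and self.data[f"{name}_group"].nunique() > 1
        ]
        grids = []
        weights = []
        if factor_cols:
            level_sets = [sorted(self.data[c].unique()) for c in factor_cols]
            combos = list(product(*level_sets))
            if weighting == "observed":
                freq = self.data.groupby(factor_cols).size()
                for combo in combos:
                    key = combo if len(combo) > 1 else combo[0]
                    weights.append(freq.get(key, 0))
            else:
                weights = [1.0] * len(combos)
            for combo in combos:
                grids.append(dict(zip(factor_cols, combo)))
        else:
            grids = [{}]
            weights = [1.0]
        rows = pd.DataFrame(
            [{"group": level, **g} for g in grids]
        )
        X = np.asarray(
            patsy.build_design_matrices([self.design_info], rows)[0]
        )
        w = np.asarray(weights, dtype=float)
        if w.sum() == 0:
            w = np.ones_like(w)
        return (X * (w / w.sum())[:, None]).sum(axis=0)

    def marginal_means(self, weighting: str = "equal") -> pd.DataFrame:
        """Estimated marginal mean of the standardized dv per dyad group."""
        if self.model.predictor != "group":
            raise ValueError("marginal means require the group predictor")
        levels = [g for g in GROUP_ORDER if g in set(self.data["group"])]
        rows = []
        for g in levels:
            L = self._marginal_design(g, weighting)
            est = float(L @ self.params.values)
            se = float(np.sqrt(L @ self.cov_params.values @ L))
            rows.append({"group": g, "emmean": est, "se": se})
        return pd.DataFrame(rows).set_index("group")

    def contrasts(self, weighting: str = "equal",
                  fdr_family: Sequence[float] | None = None) -> pd.DataFrame:
        """Pairwise HH/HL/LL differences of marginal means, Wald-t tested.

        ``df = N - k``; BH-FDR across the three contrasts (or across the
        pooled family if extra raw p-values are passed via ``fdr_family``).
        """
        if self.model.predictor != "group":
            raise ValueError("contrasts require the group predictor")
        present = set(self.data["group"])
        rows = []
        for g1, g2 in CONTRAST_PAIRS:
            if g1 not in present or g2 not in present:
                continue
            L = self._marginal_design(g1, weighting) - self._marginal_design(g2, weighting)
            est = float(L @ self.params.values)
            var = float(L @ self.cov_params.values @ L)
            se = float(np.sqrt(var))
            t = est / se if se > 0 else 0.0
            p = float(2 * stats.t.sf(abs(t), self.df_resid))
            rows.append({"contrast": f"{g1}-{g2}", "estimate": est, "se": se,
                         "t": t, "df": self.df_resid, "p": p})
        out = pd.DataFrame(rows)
        if len(out):
            if fdr_family is not None:
                pooled = np.concatenate([out["p"].values, np.asarray(fdr_family)])
                out["p_fdr"] = fdr_adjust(pooled)[: len(out)]
            else:
                out["p_fdr"] = fdr_adjust(out["p"].values)
        return out

    @property
    def slope(self) -> pd.Series | None:
        """Standardized trait slope (continuous predictor only)."""
        if self.model.predictor != "mean_trait":
            return None
        est = self.params["_mt"]
        se = self.bse["_mt"]
        t = est / se if se > 0 else 0.0
        p = 2 * stats.t.sf(abs(t), self.df_resid)
        return pd.Series({"beta": est, "se": se, "t": t, "df": self.df_resid, "p": p})

    def plot_marginal_means(self, ax=None):
        """Point-and-error plot of the dyad-group marginal means."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 3))
        em = self.marginal_means()
        ax.errorbar(em.index, em["emmean"], yerr=em["se"], fmt="o", capsize=4)
        ax.set_ylabel(f"{self.model.dv} (standardized)")
        ax.set_xlabel("dyad group")
        ax.axhline(0.0, color="grey", lw=0.5)
        return ax

    def summary(self) -> str:
        lines = [
            "Dyadic mixed model (double-entry, crossed member intercepts)",
            f"  dv: {self.model.dv}   predictor: {self.model.predictor}"
            f"   covariates: {list(self.model.covariates) or '-'}",
            f"  unique dyads: {self.n_unique}   rows fitted: {self.n_rows}"
            f"   df = N - k = {self.n_unique} - {self.k} = {self.df_resid}",
            f"  REML: {self.reml}   converged: {self.converged}"
            f"   SE correction (x sqrt2): {self.model.se_correction}",
            f"  random-intercept variances: p1={self.vcomp['p1']:.4f} "
            f"p2={self.vcomp['p2']:.4f}   residual={self.scale:.4f}",
            "",
            "  Fixed effects (standardized):",
        ]
        for name in self.params.index:
            lines.append(
                f"    {name:<42s} beta={self.params[name]:+.4f} "
                f"SE={self.bse[name]:.4f} p={self.pvalues[name]:.4g}"
            )
        if self.model.predictor == "group":
            lines.append("")
            lines.append("  Pairwise dyad-group contrasts (marginal means):")
            for _, row in self.contrasts().iterrows():
                lines.append(
                    f"    {row['contrast']:<6s} beta={row['estimate']:+.4f} "
                    f"SE={row['se']:.4f} t({row['df']})={row['t']:+.3f} "
                    f"p={row['p']:.4g} p_fdr={row['p_fdr']:.4g}"
                )
        if self.diagnostics:
            lines.append("")
            lines.append("  Diagnostics: " + "; ".join(self.diagnostics))
        return "\n".join(lines)


def fit_group_lmm(table, dv: str, covariates: Sequence[str] = (),
                  **kwargs) -> DyadLMMResults:
    """Fit the HH/HL/LL dyad-group model for one dissimilarity index."""
    return DyadLMM(table, dv, predictor="group", covariates=covariates, **kwargs).fit()


def fit_continuous_lmm(table, dv: str, covariates: Sequence[str] = (),
                       **kwargs) -> DyadLMMResults:
    """Fit the continuous dyad-mean-trait model for one index."""
    return DyadLMM(table, dv, predictor="mean_trait", covariates=covariates,
                   **kwargs).fit()


@dataclass
class InteractionResult:
    """Wald F-test of the dyad-group x network interaction."""

    F: float
    df1: int
    df2: int
    p: float
    params: pd.Series
    n_unique: int
    converged: bool


def network_interaction(
    table,
    dv_a: str,
    dv_b: str,
    network_names: tuple[str, str] = ("net_a", "net_b"),
    *,
    se_correction: bool = True,
    k: str | int = "all",
) -> InteractionResult:
    """Test whether the dyad-group pattern differs between two networks.

    The two per-network dissimilarities are standardized (within network,
    over unique dyads), stacked long with a network factor, and modelled
    with group, network, and group x network fixed effects plus crossed
    member random intercepts on the doubled rows. The interaction is
    Wald-F tested against ``df2 = N_long - k`` where ``N_long`` counts
    unique (dyad, network) observations.
    """
    df = table.data if isinstance(table, DyadTable) else table
    df = df.dropna(subset=[dv_a, dv_b]).copy()
    long_rows = []
    for dv, net in ((dv_a, network_names[0]), (dv_b, network_names[1])):
        part = df[["p1", "p2", "group"]].copy()
        part["_dv"] = _zscore_unique(df[dv].astype(float)).values
        part["network"] = net
        long_rows.append(part)
    long = pd.concat(long_rows, ignore_index=True)
    n_long_unique = len(long)
    dbl = _double(long)
    dbl["_one"] = 1
    formula = (
        f"_dv ~ C(group, levels={list(GROUP_ORDER)}) * C(network)"
    )
    model = smf.mixedlm(formula, dbl, groups="_one",
                        vc_formula={"p1": "0 + C(p1)", "p2": "0 + C(p2)"})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        res = model.fit(reml=True, method="lbfgs", maxiter=200)
    fe_names = list(res.model.exog_names)
    params = pd.Series(res.params[: len(fe_names)].values, index=fe_names)
    cov = np.asarray(res.cov_params())[: len(fe_names), : len(fe_names)]
    if se_correction:
        cov = cov * 2.0
    inter_idx = [i for i, name in enumerate(fe_names) if ":" in name]
    if not inter_idx:
        raise ValueError("no interaction terms in design (degenerate grouping)")
    L = np.zeros((len(inter_idx), len(fe_names)))
    for r, i in enumerate(inter_idx):
        L[r, i] = 1.0
    est = L @ params.values
    V = L @ cov @ L.T
    try:
        W = float(est @ np.linalg.solve(V, est))
    except np.linalg.LinAlgError:
        W = float(est @ np.linalg.pinv(V) @ est)
    df1 = len(inter_idx)
    k_count = len(fe_names) - 1 if k == "all" else (1 if k == "focal" else int(k))
    df2 = n_long_unique - k_count
    F = W / df1
    p = float(stats.f.sf(F, df1, df2))
    return InteractionResult(F, df1, df2, p, params, n_long_unique,
                             bool(res.converged))
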