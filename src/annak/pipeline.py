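"""End-to-end orchestration: cohort -> features -> dissimilarity ->
dyadic inference -> report.

The pipeline reproduces the full analysis sequence on either a simulated
cohort or an ingested directory of per-subject tables: functional
connectivity and strength centrality per subject, pairwise dissimilarity
matrices per index, per-index outlier exclusion, covariate screening,
dyad-table construction, dyad-group and continuous-trait mixed models
with a pooled FDR family, and Mantel associations between residualized
neural and behavioral indices. Every stochastic step derives its seed
from the single run seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__ as _version
from .connectome import compute_fc, segment, strength_centrality, vectorize_upper
from .dissim import (DissimMatrix, build_dissim_matrix, exclude_outliers,
                     fc_profile_dissim, retained_ids, semantic_dissim, td_dissim)
from .dyads import build_dyad_table, screen_covariates
from .gaze import gaze_dissim, preprocess_gaze
from .io import read_cohort, write_dissim, write_fc_tidy, write_json, write_strength_tidy
from .mantel import mantel, residualize
from .models import fdr_adjust, fit_continuous_lmm, fit_group_lmm
from .simulate import SimConfig, simulate_cohort

__all__ = ["RunConfig", "RunReport", "run"]

log = logging.getLogger("annak")

DEFAULT_SEGMENTS = ((1, 50), (51, 110), (111, 151))


@dataclass
class RunConfig:
    """Configuration for one full analysis run.

    ``mode="simulate"`` draws a synthetic cohort from ``sim``;
    ``mode="ingest"`` reads one from ``input_dir``. ``indices`` selects
    the dissimilarity indices to analyse; "td" expands to one index per
    ROI. Confounds are auto-screened unless an explicit list is given.
    """

    mode: str = "simulate"
    sim: SimConfig = field(default_factory=SimConfig)
    input_dir: str | None = None
    output_dir: str | None = None
    indices: tuple[str, ...] = ("fc_profile", "strength", "gaze", "semantic")
    confounds: tuple[str, ...] | str = "auto"
    categorical_covariates: tuple[str, ...] = ("gender",)
    alpha: float = 0.05
    z_threshold: float = 3.0
    k: int | str = "focal"
    n_perm: int = 10_000
    mantel_alternative: str = "greater"
    mantel_pairs: tuple[tuple[str, str], ...] = (
        ("fc_profile", "semantic"),
        ("strength", "semantic"),
        ("gaze", "semantic"),
    )
    segments: tuple[tuple[int, int], ...] = DEFAULT_SEGMENTS
    run_segments: bool = False
    min_gaze_overlap: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "ingest"):
            raise ValueError("mode must be 'simulate' or 'ingest'")
        if self.mode == "ingest":
            if not self.input_dir:
                raise ValueError("ingest mode requires input_dir")
            if not Path(self.input_dir).exists():
                raise ValueError(f"input_dir {self.input_dir!r} does not exist")
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "sim" in raw and isinstance(raw["sim"], dict):
            raw["sim"] = SimConfig(**raw["sim"])
        for key in ("indices", "confounds", "categorical_covariates"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        if "mantel_pairs" in raw:
            raw["mantel_pairs"] = tuple(tuple(p) for p in raw["mantel_pairs"])
        if "segments" in raw:
            raw["segments"] = tuple(tuple(w) for w in raw["segments"])
        return cls(**raw)


@dataclass
class RunReport:
    """Structured results of one run; serializable to JSON."""

    seed: int
    version: str
    config: dict
    screening: list[dict]
    confounds: list[str]
    exclusions: dict[str, list[dict]]
    group_fits: dict[str, dict]
    continuous_fits: dict[str, dict]
    fdr_family: list[dict]
    mantel: list[dict]
    segments: dict[str, dict]
    n_subjects: int
    n_dyads: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def summary(self) -> str:
        lines = [
            f"annak run (seed={self.seed}, version={self.version})",
            f"  subjects: {self.n_subjects}   dyads: {self.n_dyads}",
            f"  screened confounds: {self.confounds or '-'}",
        ]
        for idx, fit in self.group_fits.items():
            lines.append(f"  [{idx}] dyad-group contrasts:")
            for c in fit["contrasts"]:
                lines.append(
                    f"    {c['contrast']:<6s} beta={c['estimate']:+.3f} "
                    f"SE={c['se']:.3f} p={c['p']:.4g} p_fdr={c['p_fdr']:.4g}"
                )
            slope = self.continuous_fits[idx]["slope"]
            lines.append(
                f"    continuous PT slope beta={slope['beta']:+.3f} p={slope['p']:.4g}"
            )
        for m in self.mantel:
            lines.append(
                f"  Mantel {m['pair'][0]} ~ {m['pair'][1]}: "
                f"r({m['df_report']}) = {m['r']:.3f}, p = {m['p']:.4g}"
            )
        return "\n".join(lines)


def _mask_excluded(dm: DissimMatrix, retained: list[str]) -> DissimMatrix:
    """NaN-out rows/cols of excluded subjects, keeping the full id set."""
    keep = np.isin(dm.subject_ids, retained)
    d = dm.d.copy()
    d[~keep, :] = np.nan
    d[:, ~keep] = np.nan
    np.fill_diagonal(d, 0.0)
    return DissimMatrix(dm.index_name, dm.subject_ids, d)


def _compute_dissim_matrices(cohort, cfg: RunConfig) -> dict[str, DissimMatrix]:
    matrices: dict[str, DissimMatrix] = {}
    movie = cohort.timeseries.get("movie", {})
    if any(i in cfg.indices for i in ("fc_profile", "strength")) or "td" in cfg.indices:
        if not movie:
            raise ValueError("stage 'features': no movie time series available")
        fcs = {sid: compute_fc(ts) for sid, ts in movie.items()}
        if "fc_profile" in cfg.indices:
            edges = {sid: vectorize_upper(fc) for sid, fc in fcs.items()}
            matrices["fc_profile"] = build_dissim_matrix(
                edges, fc_profile_dissim, "fc_profile"
            )
        if "strength" in cfg.indices:
            strengths = {sid: strength_centrality(fc).s for sid, fc in fcs.items()}
            matrices["strength"] = build_dissim_matrix(
                strengths, fc_profile_dissim, "strength"
            )
        if "td" in cfg.indices:
            roi_names = next(iter(movie.values())).roi_names
            for r, roi in enumerate(roi_names):
                series = {sid: ts.values[:, r] for sid, ts in movie.items()}
                matrices[f"td_{roi}"] = build_dissim_matrix(
                    series, td_dissim, f"td_{roi}"
                )
    if "gaze" in cfg.indices and cohort.gaze:
        traces = {sid: preprocess_gaze(tr) for sid, tr in cohort.gaze.items()}
        matrices["gaze"] = build_dissim_matrix(
            traces,
            lambda a, b: gaze_dissim(a, b, min_overlap=cfg.min_gaze_overlap),
            "gaze",
            allow_missing=True,
        )
    if "semantic" in cfg.indices and cohort.embedding:
        matrices["semantic"] = build_dissim_matrix(
            cohort.embedding, semantic_dissim, "semantic"
        )
    return matrices


def run(config: RunConfig) -> RunReport:
    """Execute the full analysis; deterministic given ``config.seed``."""
    cfg = config
    rng_seq = np.random.SeedSequence(cfg.seed)
    mantel_seeds = rng_seq.spawn(max(len(cfg.mantel_pairs), 1))

    # ---- stage: cohort -----------------------------------------------------
    if cfg.mode == "simulate":
        sim = dataclasses.replace(cfg.sim, seed=cfg.seed)
        cohort = simulate_cohort(sim)
    else:
        try:
            cohort = read_cohort(cfg.input_dir)
        except ValueError as exc:
            raise RuntimeError(f"stage 'ingest' failed: {exc}") from exc
    log.info("cohort: %d subjects", cohort.n_subjects)

    subjects = cohort.covariates.copy()
    subjects["pt"] = cohort.trait

    # ---- stage: features + dissimilarity ----------------------------------
    matrices = _compute_dissim_matrices(cohort, cfg)

    # ---- stage: outlier exclusion (per index, single pass) -----------------
    exclusions: dict[str, list[dict]] = {}
    masked: dict[str, DissimMatrix] = {}
    for name, dm in matrices.items():
        retained, excl = exclude_outliers(dm, cfg.z_threshold)
        exclusions[name] = excl.to_dict(orient="records")
        masked[name] = _mask_excluded(dm, retained) if len(excl) else dm
        if len(excl):
            log.info("index %s: excluded %s", name, list(excl["subject_id"]))

    # ---- stage: covariate screening ---------------------------------------
    if cfg.confounds == "auto":
        confounds, detail = screen_covariates(
            subjects, "pt",
            categorical=cfg.categorical_covariates, alpha=cfg.alpha,
        )
        screening = detail.to_dict(orient="records")
    else:
        confounds = list(cfg.confounds)
        screening = []

    # ---- stage: dyad table + models ---------------------------------------
    table = build_dyad_table(subjects, "pt", masked, confounds)
    group_fits: dict[str, dict] = {}
    continuous_fits: dict[str, dict] = {}
    raw_family: list[tuple[str, str, float]] = []
    for name in masked:
        gres = fit_group_lmm(table, name, confounds, k=cfg.k)
        cres = fit_continuous_lmm(table, name, confounds, k=cfg.k)
        contrasts = gres.contrasts()
        group_fits[name] = {
            "params": gres.params.to_dict(),
            "bse": gres.bse.to_dict(),
            "df": gres.df_resid,
            "n_unique": gres.n_unique,
            "vcomp": gres.vcomp.to_dict(),
            "converged": gres.converged,
            "contrasts": contrasts.to_dict(orient="records"),
        }
        continuous_fits[name] = {
            "slope": cres.slope.to_dict(),
            "df": cres.df_resid,
            "converged": cres.converged,
        }
        for _, row in contrasts.iterrows():
            raw_family.append((name, row["contrast"], row["p"]))

    # pooled FDR family: all pairwise contrasts across all indices
    pooled = fdr_adjust([p for _, _, p in raw_family])
    fdr_family = [
        {"index": n, "contrast": c, "p": p, "p_fdr_pooled": q}
        for (n, c, p), q in zip(raw_family, pooled)
    ]

    # ---- stage: Mantel associations (confound-residualized) ----------------
    mantel_results = []
    conf_mean_cols = [f"{c}_mean" for c in confounds]
    for pair, seed_child in zip(cfg.mantel_pairs, mantel_seeds):
        a, b = pair
        if a not in masked or b not in masked:
            continue
        ok = set(retained_ids(masked[a])) & set(retained_ids(masked[b]))
        ids = [s for s in masked[a].subject_ids if s in ok]
        if len(ids) < 4:
            continue
        sub_a, sub_b = masked[a].subset(ids), masked[b].subset(ids)
        pair_table = build_dyad_table(subjects, "pt", {a: sub_a, b: sub_b},
                                      confounds, subject_ids=ids)
        X = (pair_table.data[conf_mean_cols].to_numpy(float)
             if conf_mean_cols else None)
        squares = []
        for dm, col in ((sub_a, a), (sub_b, b)):
            resid = residualize(pair_table.data[col].to_numpy(float), X)
            sq = np.zeros((len(ids), len(ids)))
            iu = np.triu_indices(len(ids), k=1)
            sq[iu] = resid
            squares.append(sq + sq.T)
        res = mantel(squares[0], squares[1], n_perm=cfg.n_perm,
                     alternative=cfg.mantel_alternative,
                     seed=np.random.default_rng(seed_child))
        mantel_results.append(
            {"pair": [a, b], "r": res.r, "p": res.p, "n_perm": res.n_perm,
             "alternative": res.alternative, "df_report": res.df_report,
             "n_subjects": len(ids), "residualized_on": confounds}
        )

    # ---- stage: movie-segment controlling analysis -------------------------
    segment_fits: dict[str, dict] = {}
    if cfg.run_segments and "movie" in cohort.timeseries:
        for window in cfg.segments:
            seg_edges = {}
            for sid, ts in cohort.timeseries["movie"].items():
                fc = compute_fc(segment(ts, window))
                seg_edges[sid] = vectorize_upper(fc)
            dm = build_dissim_matrix(seg_edges, fc_profile_dissim,
                                     f"fc_profile_{window[0]}_{window[1]}")
            seg_table = build_dyad_table(subjects, "pt", {dm.index_name: dm},
                                         confounds)
            sres = fit_group_lmm(seg_table, dm.index_name, confounds, k=cfg.k)
            segment_fits[f"{window[0]}-{window[1]}"] = {
                "contrasts": sres.contrasts().to_dict(orient="records"),
                "n_unique": sres.n_unique,
            }

    report = RunReport(
        seed=cfg.seed,
        version=_version,
        config=_config_echo(cfg),
        screening=screening,
        confounds=confounds,
        exclusions=exclusions,
        group_fits=group_fits,
        continuous_fits=continuous_fits,
        fdr_family=fdr_family,
        mantel=mantel_results,
        segments=segment_fits,
        n_subjects=cohort.n_subjects,
        n_dyads=table.n_dyads,
    )

    # ---- stage: outputs ----------------------------------------------------
    if cfg.output_dir:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        movie = cohort.timeseries.get("movie", {})
        if movie:
            fcs = {sid: compute_fc(ts) for sid, ts in movie.items()}
            write_fc_tidy(fcs, out / "fc_edges.csv")
            write_strength_tidy(
                {sid: strength_centrality(fc) for sid, fc in fcs.items()},
                out / "strength.csv",
            )
        for name, dm in masked.items():
            write_dissim(dm, out / f"dissim_{name}.csv",
                         out / f"dissim_{name}_tidy.csv")
        table.data.to_csv(out / "dyads.csv", index=False)
        write_json(report.to_dict(), out / "report.json")
        (out / "summary.txt").write_text(report.summary() + "\n")
    return report


def _config_echo(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    sim = d.get("sim")
    if sim is not None and sim.get("template_fc") is not None:
        sim["template_fc"] = np.asarray(sim["template_fc"]).tolist()
    return d
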