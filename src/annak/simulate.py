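"""Synthetic cohorts with controllable inter-subject idiosyncrasy.

The generator realizes the "Anna Karenina" (AnnaK) premise: every subject
shares a common template of functional connectivity, gaze trajectory, and
verbal-embedding direction, and deviates from it by an amount whose spread
grows with the subject's trait score (perspective-taking). In ``annak``
mode the deviation SD is linear in the normalized trait; in ``null`` mode
the slope is forced to zero, so inter-subject spread is trait-independent
— the null hypothesis of the downstream dyadic analysis.

Neural deviations are injected additively in Fisher-z space; gaze
deviations are smooth pixel-space offsets from a canonical trajectory;
verbal embeddings are von Mises-Fisher draws around a shared direction
with concentration decreasing in trait.

Every generator is deterministic under a fixed seed. The global seed is
expanded into per-subject child seeds, so subject i's data do not change
when the cohort grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from statsmodels.stats.correlation_tools import corr_clipped

from .connectome import RoiTimeSeries
from .gaze import GazeTrace

__all__ = [
    "GazeSimConfig",
    "CovariateSpec",
    "SimConfig",
    "Cohort",
    "default_template_fc",
    "default_roi_names",
    "canonical_gaze_path",
    "simulate_subject_fc",
    "simulate_timeseries",
    "simulate_gaze",
    "simulate_embedding",
    "simulate_cohort",
]

#: eigenvalue floor below which a perturbed correlation matrix is repaired
PSD_FLOOR = 1e-8


def default_roi_names(n_rois: int) -> list[str]:
    """Mentalizing-network region labels for the canonical 6-ROI setup."""
    mtn = ["DMPFC", "MMPFC", "VMPFC", "PreC", "LTPJ", "RTPJ"]
    if n_rois <= len(mtn):
        return mtn[:n_rois]
    return mtn + [f"ROI{k}" for k in range(len(mtn), n_rois)]


def default_template_fc(n_rois: int = 6) -> np.ndarray:
    """A positive-definite template correlation matrix with block structure.

    Regions are split into two sub-blocks (medial-prefrontal vs.
    posterior) with stronger within-block than between-block coupling,
    mimicking the community structure of a small functional network.
    """
    C = np.full((n_rois, n_rois), 0.30)
    half = n_rois // 2
    C[:half, :half] = 0.55
    C[half:, half:] = 0.50
    np.fill_diagonal(C, 1.0)
    if np.linalg.eigvalsh(C).min() <= 0:  # pragma: no cover - defensive
        C = corr_clipped(C, threshold=1e-6)
    return C


@dataclass(frozen=True)
class GazeSimConfig:
    """Frame geometry and artifact rates for simulated gaze traces."""

    n_frames: int = 7203
    frame_width_px: float = 1280.0
    frame_height_px: float = 790.0
    fps: float = 24.0
    blink_rate: float = 0.002       # per-frame chance of starting a blink (>=2 frames)
    offscreen_rate: float = 0.001   # per-frame chance of an off-screen sample
    dropout_rate: float = 0.002     # per-frame chance of a 1-frame dropout
    sigma0_px: float = 40.0         # baseline SD of the smooth deviation, pixels
    sigma1_px: float = 120.0        # trait slope of the deviation SD, pixels
    smooth_frames: float = 12.0     # Gaussian smoothing SD of the deviation, frames


@dataclass(frozen=True)
class CovariateSpec:
    """A candidate covariate with a target Pearson correlation to the trait."""

    name: str
    rho: float = 0.0
    kind: str = "continuous"  # or "categorical" (binary, median-split of latent)


def _default_covariates() -> tuple[CovariateSpec, ...]:
    return (
        CovariateSpec("fantasy", 0.40),
        CovariateSpec("empathy", 0.40),
        CovariateSpec("age", 0.0),
        CovariateSpec("gender", 0.0, kind="categorical"),
    )


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for a synthetic cohort.

    Defaults mirror the reference study's recording setup: 6 mentalizing
    ROIs sampled for 151 movie TRs (180 at rest), 7203 gaze frames on a
    1280x790 screen at 24 fps, 768-dimensional document embeddings, and
    integer trait scores on the questionnaire subscale range [10, 28].
    ``sigma0``/``sigma1`` (Fisher-z units) set the baseline and
    trait-slope of the connectivity idiosyncrasy; ``kappa0``/``kappa1``
    control embedding concentration. ``mode="null"`` forces all trait
    slopes to zero.
    """

    n_subjects: int = 55
    n_rois: int = 6
    n_timepoints: int = 151
    n_timepoints_rest: int = 180
    trait_range: tuple[int, int] = (10, 28)
    template_fc: np.ndarray | None = None
    sigma0: float = 0.10
    sigma1: float = 0.40
    mode: str = "annak"
    gaze: GazeSimConfig = field(default_factory=GazeSimConfig)
    embed_dim: int = 768
    kappa0: float = 2500.0
    kappa1: float = 1500.0
    covariate_spec: tuple[CovariateSpec, ...] = field(default_factory=_default_covariates)
    conditions: tuple[str, ...] = ("movie", "rest")
    modalities: tuple[str, ...] = ("fmri", "gaze", "embedding")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 4:
            raise ValueError("n_subjects must be at least 4")
        if self.sigma0 < 0:
            raise ValueError("sigma0 must be non-negative")
        if self.mode not in ("annak", "null"):
            raise ValueError("mode must be 'annak' or 'null'")
        if self.mode == "annak":
            if self.sigma0 + self.sigma1 < 0:
                raise ValueError("sigma0 + sigma1 must be non-negative")
            if self.kappa0 - self.kappa1 < 0:
                raise ValueError("kappa0 - kappa1 must be non-negative")
        lo, hi = self.trait_range
        if lo >= hi:
            raise ValueError("trait_range must be a nondegenerate interval")
        if self.template_fc is not None:
            C = np.asarray(self.template_fc, dtype=float)
            if C.shape != (self.n_rois, self.n_rois):
                raise ValueError("template_fc shape must be (n_rois, n_rois)")
            if not np.allclose(C, C.T):
                raise ValueError("template_fc must be symmetric")
            if not np.allclose(np.diag(C), 1.0):
                raise ValueError("template_fc must have a unit diagonal")
            if np.linalg.eigvalsh(C).min() <= 0:
                raise ValueError("template_fc must be positive definite")

    @property
    def effective_sigma1(self) -> float:
        return 0.0 if self.mode == "null" else self.sigma1

    @property
    def effective_kappa1(self) -> float:
        return 0.0 if self.mode == "null" else self.kappa1

    def resolved_template(self) -> np.ndarray:
        if self.template_fc is not None:
            return np.asarray(self.template_fc, dtype=float)
        return default_template_fc(self.n_rois)


@dataclass
class Cohort:
    """A synthetic (or ingested) cohort keyed by subject id."""

    subject_ids: list[str]
    trait: pd.Series
    covariates: pd.DataFrame
    timeseries: dict[str, dict[str, RoiTimeSeries]]  # condition -> id -> series
    gaze: dict[str, GazeTrace]
    embedding: dict[str, np.ndarray]
    roi_names: list[str] = field(default_factory=list)
    config: SimConfig | None = None

    def __post_init__(self) -> None:
        ids = set(self.subject_ids)
        if set(self.trait.index) != ids:
            raise ValueError("trait must be keyed by the subject id set")
        for cond, per_subj in self.timeseries.items():
            if set(per_subj) != ids:
                raise ValueError(f"time series for condition {cond!r} missing subjects")
            shapes = {ts.values.shape for ts in per_subj.values()}
            if len(shapes) > 1:
                raise ValueError(f"inconsistent time-series shapes in {cond!r}")
        for name, container in (("gaze", self.gaze), ("embedding", self.embedding)):
            if container and set(container) != ids:
                raise ValueError(f"{name} container missing subjects")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)


def _symmetric_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Zero-diagonal symmetric matrix with unit-variance Gaussian entries."""
    E = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    E[iu] = rng.standard_normal(len(iu[0]))
    return E + E.T


def simulate_subject_fc(
    template_z: np.ndarray,
    trait_norm: float,
    sigma0: float,
    sigma1: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One subject's FC matrix: tanh of the z-template plus scaled noise.

    ``sigma = sigma0 + sigma1 * trait_norm`` scales a symmetric,
    zero-diagonal Gaussian perturbation added in Fisher-z space. The
    result is repaired to the nearest valid correlation matrix
    (eigenvalue clipping, unit diagonal) when the perturbation breaks
    positive semi-definiteness.
    """
    Z = np.asarray(template_z, dtype=float)
    if not np.allclose(Z, Z.T):
        raise ValueError("template_z must be symmetric")
    if not np.allclose(np.diag(Z), 0.0):
        raise ValueError("template_z must have a zero diagonal")
    if not 0.0 <= trait_norm <= 1.0:
        raise ValueError("trait_norm must lie in [0, 1]")
    sigma = sigma0 + sigma1 * trait_norm
    if sigma < 0:
        raise ValueError(f"negative idiosyncrasy SD ({sigma:.3g}) at trait {trait_norm}")
    n = Z.shape[0]
    C = np.tanh(Z + sigma * _symmetric_noise(n, rng))
    np.fill_diagonal(C, 1.0)
    if np.linalg.eigvalsh(C).min() < PSD_FLOOR:
        C = corr_clipped(C, threshold=1e-6)
        C = (C + C.T) / 2.0
        np.fill_diagonal(C, 1.0)
    return C


def simulate_timeseries(
    corr: np.ndarray, n_timepoints: int, rng: np.random.Generator
) -> np.ndarray:
    """Zero-mean Gaussian series with the given inter-region correlation."""
    C = np.asarray(corr, dtype=float)
    if not np.allclose(C, C.T):
        raise ValueError("corr must be symmetric")
    if not np.allclose(np.diag(C), 1.0):
        raise ValueError("corr must have a unit diagonal")
    w, V = np.linalg.eigh(C)
    if w.min() < -1e-10:
        raise ValueError(
            "corr is not positive semi-definite; repair it first "
            "(e.g. statsmodels corr_clipped)"
        )
    L = V * np.sqrt(np.clip(w, 0.0, None))
    return rng.standard_normal((n_timepoints, C.shape[0])) @ L.T


def canonical_gaze_path(cfg: GazeSimConfig) -> np.ndarray:
    """Deterministic smooth scan path shared by all subjects.

    A Lissajous-style sweep around screen center, emulating a viewer
    tracking moving content; returns an (n_frames, 2) array of pixels.
    """
    t = np.arange(cfg.n_frames) / cfg.fps
    x = cfg.frame_width_px * (0.5 + 0.30 * np.sin(2 * np.pi * 0.11 * t))
    y = cfg.frame_height_px * (0.5 + 0.25 * np.sin(2 * np.pi * 0.07 * t + 1.0))
    return np.column_stack([x, y])


def simulate_gaze(
    canonical: np.ndarray,
    trait_norm: float,
    sigma0_px: float,
    sigma1_px: float,
    cfg: GazeSimConfig,
    rng: np.random.Generator,
    subject_id: str = "sim",
) -> GazeTrace:
    """A subject's gaze trace: canonical path plus smooth trait-scaled drift.

    Blink gaps (NaN runs of >= 2 frames), single-frame dropouts, and
    off-screen samples are inserted at the configured rates so the
    preprocessing stage has realistic artifacts to handle.
    """
    canonical = np.asarray(canonical, dtype=float)
    if canonical.shape != (cfg.n_frames, 2):
        raise ValueError("canonical path must have shape (n_frames, 2)")
    sigma = sigma0_px + sigma1_px * trait_norm
    if sigma < 0:
        raise ValueError("negative gaze deviation SD")
    xy = canonical.copy()
    if sigma > 0:
        dev = rng.standard_normal((cfg.n_frames, 2))
        dev = gaussian_filter1d(dev, cfg.smooth_frames, axis=0, mode="nearest")
        sd = dev.std(axis=0)
        sd[sd == 0] = 1.0
        xy = xy + dev / sd * sigma
    x = np.clip(xy[:, 0], 0.0, cfg.frame_width_px)
    y = np.clip(xy[:, 1], 0.0, cfg.frame_height_px)
    # off-screen samples (recorded coordinates beyond the video frame)
    off = rng.random(cfg.n_frames) < cfg.offscreen_rate
    x[off] = cfg.frame_width_px + 30.0
    # blinks: runs of >= 2 missing frames; dropouts: single missing frames
    missing = np.zeros(cfg.n_frames, dtype=bool)
    starts = np.flatnonzero(rng.random(cfg.n_frames) < cfg.blink_rate)
    for s in starts:
        missing[s : s + int(rng.integers(2, 7))] = True
    missing |= rng.random(cfg.n_frames) < cfg.dropout_rate
    x[missing] = np.nan
    y[missing] = np.nan
    return GazeTrace(
        subject_id, np.arange(cfg.n_frames), x, y,
        cfg.frame_width_px, cfg.frame_height_px, cfg.fps,
    )


def _sample_vmf(mu: np.ndarray, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """von Mises-Fisher draw on the unit sphere (Wood's rejection scheme)."""
    d = mu.shape[0]
    if np.isinf(kappa):
        return mu.copy()
    if kappa == 0:
        v = rng.standard_normal(d)
        return v / np.linalg.norm(v)
    b = (-2 * kappa + np.sqrt(4 * kappa**2 + (d - 1) ** 2)) / (d - 1)
    x0 = (1 - b) / (1 + b)
    c = kappa * x0 + (d - 1) * np.log(1 - x0**2)
    while True:
        zbeta = rng.beta((d - 1) / 2, (d - 1) / 2)
        w = (1 - (1 + b) * zbeta) / (1 - (1 - b) * zbeta)
        if kappa * w + (d - 1) * np.log(1 - x0 * w) - c >= np.log(rng.random()):
            break
    v = rng.standard_normal(d)
    v = v - (v @ mu) * mu
    v /= np.linalg.norm(v)
    return w * mu + np.sqrt(max(1 - w**2, 0.0)) * v


def simulate_embedding(
    mu: np.ndarray,
    trait_norm: float,
    kappa0: float,
    kappa1: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit-norm embedding around ``mu`` with trait-dependent dispersion.

    Concentration ``kappa = kappa0 - kappa1 * trait_norm`` (rejected if
    negative): higher-trait subjects scatter more widely around the shared
    semantic direction. ``kappa0 = inf`` returns ``mu`` exactly.
    """
    mu = np.asarray(mu, dtype=float)
    if not np.isclose(np.linalg.norm(mu), 1.0):
        raise ValueError("mu must be a unit vector")
    kappa = kappa0 - kappa1 * trait_norm
    if kappa < 0:
        raise ValueError(f"negative concentration ({kappa:.3g}) at trait {trait_norm}")
    return _sample_vmf(mu, kappa, rng)


def _subject_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def simulate_cohort(config: SimConfig) -> Cohort:
    """Generate a full cohort under the configured study conditions.

    Traits are uniform integers over ``trait_range``; covariates hit their
    target trait correlations through a Gaussian copula on the trait's
    latent normal score. Movie-condition connectivity carries the
    trait-dependent idiosyncrasy; rest-condition connectivity uses the
    baseline spread only (trait-independent), as intrinsic activity
    should not exhibit the AnnaK structure.
    """
    cfg = config
    n = cfg.n_subjects
    lo, hi = cfg.trait_range
    template = cfg.resolved_template()
    template_z = np.arctanh(np.clip(template, -1 + 1e-12, 1 - 1e-12))
    np.fill_diagonal(template_z, 0.0)
    roi_names = default_roi_names(cfg.n_rois)

    cohort_rng = _subject_rng(cfg.seed, 0)
    mu = cohort_rng.standard_normal(cfg.embed_dim)
    mu /= np.linalg.norm(mu)
    canonical = canonical_gaze_path(cfg.gaze)

    ids = [f"S{k + 1:03d}" for k in range(n)]
    from scipy.stats import norm as _norm

    traits = {}
    cov_rows = {}
    movie_ts: dict[str, RoiTimeSeries] = {}
    rest_ts: dict[str, RoiTimeSeries] = {}
    gaze_traces: dict[str, GazeTrace] = {}
    embeddings: dict[str, np.ndarray] = {}

    for k, sid in enumerate(ids):
        rng = _subject_rng(cfg.seed, k + 1)
        z0 = rng.standard_normal()
        # Gaussian copula: map the latent normal score to a uniform integer
        trait = int(lo + np.floor(_norm.cdf(z0) * (hi - lo + 1)))
        trait = min(trait, hi)
        traits[sid] = trait
        tnorm = (trait - lo) / (hi - lo)

        row = {}
        for spec in cfg.covariate_spec:
            eps = rng.standard_normal()
            latent = spec.rho * z0 + np.sqrt(max(1 - spec.rho**2, 0.0)) * eps
            if spec.kind == "categorical":
                row[spec.name] = int(latent > 0)
            elif spec.name == "age":
                row[spec.name] = float(np.round(21.0 + 1.5 * latent, 1))
            else:
                row[spec.name] = float(latent)
        cov_rows[sid] = row

        if "fmri" in cfg.modalities:
            C_movie = simulate_subject_fc(
                template_z, tnorm, cfg.sigma0, cfg.effective_sigma1, rng
            )
            movie_ts[sid] = RoiTimeSeries(
                sid, "movie",
                simulate_timeseries(C_movie, cfg.n_timepoints, rng), roi_names,
            )
            if "rest" in cfg.conditions:
                C_rest = simulate_subject_fc(template_z, tnorm, cfg.sigma0, 0.0, rng)
                rest_ts[sid] = RoiTimeSeries(
                    sid, "rest",
                    simulate_timeseries(C_rest, cfg.n_timepoints_rest, rng), roi_names,
                )
        if "gaze" in cfg.modalities:
            gaze_traces[sid] = simulate_gaze(
                canonical, tnorm, cfg.gaze.sigma0_px,
                0.0 if cfg.mode == "null" else cfg.gaze.sigma1_px,
                cfg.gaze, rng, subject_id=sid,
            )
        if "embedding" in cfg.modalities:
            embeddings[sid] = simulate_embedding(
                mu, tnorm, cfg.kappa0, cfg.effective_kappa1, rng
            )

    timeseries: dict[str, dict[str, RoiTimeSeries]] = {}
    if movie_ts:
        timeseries["movie"] = movie_ts
    if rest_ts:
        timeseries["rest"] = rest_ts
    return Cohort(
        subject_ids=ids,
        trait=pd.Series(traits, name="pt").loc[ids],
        covariates=pd.DataFrame.from_dict(cov_rows, orient="index").loc[ids],
        timeseries=timeseries,
        gaze=gaze_traces,
        embedding=embeddings,
        roi_names=roi_names,
        config=cfg,
    )


def null_config(config: SimConfig) -> SimConfig:
    """The same study conditions with all trait slopes forced to zero."""
    return replace(config, mode="null")
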