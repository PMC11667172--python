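"""Plain-text input/output: cohort manifests, per-subject tables, results.

Layout written by :func:`write_cohort` (all small delimited text files):

    <root>/manifest.csv             subject_id, pt, covariates, file paths
    <root>/config.yaml              simulation / ingest configuration echo
    <root>/ts/<id>_<condition>.tsv  header = ROI names, one row per TR
    <root>/gaze/<id>.csv            frame, x, y (blank = missing sample)
    <root>/embeddings.csv           subject_id, v1..vD
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .connectome import FCMatrix, RoiTimeSeries, StrengthVector
from .dissim import DissimMatrix
from .gaze import GazeTrace
from .simulate import Cohort, SimConfig

__all__ = [
    "write_cohort",
    "read_cohort",
    "read_timeseries_tsv",
    "write_fc_tidy",
    "write_strength_tidy",
    "write_dissim",
    "read_dissim_square",
]


def _config_to_dict(cfg: SimConfig) -> dict:
    d = dataclasses.asdict(cfg)
    if d.get("template_fc") is not None:
        d["template_fc"] = np.asarray(d["template_fc"]).tolist()
    d["covariate_spec"] = [dataclasses.asdict(s) if dataclasses.is_dataclass(s) else s
                           for s in cfg.covariate_spec]
    return d


def write_cohort(cohort: Cohort, root: str | Path) -> Path:
    """Write a cohort to disk as delimited text; returns the manifest path."""
    root = Path(root)
    (root / "ts").mkdir(parents=True, exist_ok=True)
    if cohort.gaze:
        (root / "gaze").mkdir(exist_ok=True)
    rows = []
    for sid in cohort.subject_ids:
        row = {"subject_id": sid, "pt": int(cohort.trait[sid])}
        row.update(cohort.covariates.loc[sid].to_dict())
        for cond, per_subj in cohort.timeseries.items():
            ts = per_subj[sid]
            rel = f"ts/{sid}_{cond}.tsv"
            pd.DataFrame(ts.values, columns=ts.roi_names).to_csv(
                root / rel, sep="\t", index=False, float_format="%.6f"
            )
            row[f"ts_{cond}"] = rel
        if sid in cohort.gaze:
            tr = cohort.gaze[sid]
            rel = f"gaze/{sid}.csv"
            pd.DataFrame({"frame": tr.frames, "x": tr.x, "y": tr.y}).to_csv(
                root / rel, index=False, float_format="%.2f"
            )
            row["gaze"] = rel
        rows.append(row)
    pd.DataFrame(rows).to_csv(root / "manifest.csv", index=False)
    if cohort.embedding:
        emb = pd.DataFrame(
            {sid: cohort.embedding[sid] for sid in cohort.subject_ids}
        ).T
        emb.columns = [f"v{i + 1}" for i in range(emb.shape[1])]
        emb.index.name = "subject_id"
        emb.to_csv(root / "embeddings.csv", float_format="%.8f")
    if cohort.config is not None:
        with open(root / "config.yaml", "w") as fh:
            yaml.safe_dump(_config_to_dict(cohort.config), fh, sort_keys=False)
    return root / "manifest.csv"


def read_timeseries_tsv(path: str | Path, subject_id: str,
                        condition: str) -> RoiTimeSeries:
    """Read one subject's ROI time series (header = ROI names, rows = TRs)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
        values = df.to_numpy(dtype=float)
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"malformed time-series TSV {path}: {exc}") from exc
    return RoiTimeSeries(subject_id, condition, values, list(df.columns))


def _read_gaze_csv(path: Path, subject_id: str,
                   width: float, height: float, fps: float) -> GazeTrace:
    df = pd.read_csv(path)
    return GazeTrace(subject_id, df["frame"].to_numpy(int),
                     df["x"].to_numpy(float), df["y"].to_numpy(float),
                     width, height, fps)


def read_cohort(root: str | Path) -> Cohort:
    """Read a cohort previously written by :func:`write_cohort` (or laid
    out the same way by hand)."""
    root = Path(root)
    manifest = pd.read_csv(root / "manifest.csv", dtype={"subject_id": str})
    cfg = None
    cfg_path = root / "config.yaml"
    width, height, fps = 1280.0, 790.0, 24.0
    if cfg_path.exists():
        with open(cfg_path) as fh:
            raw = yaml.safe_load(fh)
        g = raw.get("gaze", {})
        width = g.get("frame_width_px", width)
        height = g.get("frame_height_px", height)
        fps = g.get("fps", fps)
    ids = list(manifest["subject_id"])
    trait = pd.Series(manifest["pt"].values, index=ids, name="pt")
    path_cols = [c for c in manifest.columns if c.startswith("ts_") or c == "gaze"]
    cov_cols = [c for c in manifest.columns
                if c not in ("subject_id", "pt") and c not in path_cols]
    covariates = manifest.set_index("subject_id")[cov_cols]
    timeseries: dict[str, dict[str, RoiTimeSeries]] = {}
    gaze: dict[str, GazeTrace] = {}
    for _, row in manifest.iterrows():
        sid = row["subject_id"]
        for col in path_cols:
            if col == "gaze":
                if isinstance(row[col], str):
                    gaze[sid] = _read_gaze_csv(root / row[col], sid, width, height, fps)
                continue
            cond = col[len("ts_"):]
            ts = read_timeseries_tsv(root / row[col], sid, cond)
            timeseries.setdefault(cond, {})[sid] = ts
    embedding: dict[str, np.ndarray] = {}
    emb_path = root / "embeddings.csv"
    if emb_path.exists():
        emb = pd.read_csv(emb_path, index_col="subject_id")
        emb.index = emb.index.astype(str)
        for sid in ids:
            embedding[sid] = emb.loc[sid].to_numpy(float)
    return Cohort(ids, trait, covariates, timeseries, gaze, embedding,
                  roi_names=(list(next(iter(timeseries["movie"].values())).roi_names)
                             if "movie" in timeseries else []),
                  config=cfg)


def write_fc_tidy(fcs: Mapping[str, FCMatrix], path: str | Path) -> None:
    """Tidy edge list: subject_id, roi_i, roi_j, z (strict upper triangle)."""
    rows = []
    for sid, fc in fcs.items():
        n = fc.n_regions
        for i in range(n):
            for j in range(i + 1, n):
                rows.append((sid, fc.roi_names[i], fc.roi_names[j], fc.z[i, j]))
    pd.DataFrame(rows, columns=["subject_id", "roi_i", "roi_j", "z"]).to_csv(
        path, index=False, float_format="%.6f"
    )


def write_strength_tidy(strengths: Mapping[str, StrengthVector],
                        path: str | Path) -> None:
    rows = []
    for sid, sv in strengths.items():
        for roi, val in zip(sv.roi_names, sv.s):
            rows.append((sid, roi, val))
    pd.DataFrame(rows, columns=["subject_id", "roi", "strength"]).to_csv(
        path, index=False, float_format="%.6f"
    )


def write_dissim(dm: DissimMatrix, square_path: str | Path,
                 tidy_path: str | Path | None = None) -> None:
    dm.to_square_frame().to_csv(square_path, float_format="%.6f")
    if tidy_path is not None:
        dm.to_tidy_frame().to_csv(tidy_path, index=False, float_format="%.6f")


def read_dissim_square(path: str | Path, index_name: str) -> DissimMatrix:
    df = pd.read_csv(path, index_col=0)
    return DissimMatrix(index_name, [str(s) for s in df.index], df.to_numpy(float))


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.Series):
            return o.to_dict()
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="records")
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
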