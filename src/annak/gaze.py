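"""Gaze traces: blink/gap preprocessing and trajectory dissimilarity.

A trace is a frame-by-frame series of screen coordinates. Missing samples
are NaN. Preprocessing follows the standard eye-tracking convention:
short dropout gaps are linearly interpolated, longer gaps are treated as
eye blinks and removed, and samples outside the video frame are removed.
Dyad-level dissimilarity is computed on the frames where both traces are
valid, as 1 - (r_x + r_y)/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GazeTrace", "GazeOverlapError", "preprocess_gaze", "gaze_dissim"]


class GazeOverlapError(ValueError):
    """Raised when a dyad's valid-frame intersection is unusable."""


@dataclass
class GazeTrace:
    """Frame-indexed gaze positions for one subject.

    ``x``/``y`` are pixel coordinates with NaN marking missing samples;
    ``valid`` marks samples usable for dissimilarity (set by
    :func:`preprocess_gaze`: present, on-screen, and not part of a blink).
    """

    subject_id: str
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    frame_width_px: float = 1280.0
    frame_height_px: float = 790.0
    fps: float = 24.0
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = len(self.frames)
        if not (len(self.x) == len(self.y) == n):
            raise ValueError("frames, x, y must have equal length")
        if n > 1 and np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.valid is None:
            self.valid = ~(np.isnan(self.x) | np.isnan(self.y))
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if len(self.valid) != n:
                raise ValueError("valid must match trace length")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def _missing(self) -> np.ndarray:
        return np.isnan(self.x) | np.isnan(self.y)


def _runs(mask: np.ndarray):
    """Yield (start, stop) index pairs of consecutive True runs (stop exclusive)."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    stops = np.concatenate([idx[breaks] + 1, [idx[-1] + 1]])
    yield from zip(starts, stops)


def preprocess_gaze(
    trace: GazeTrace,
    *,
    max_interp_frames: int | None = None,
    gap_ms: float = 75.0,
) -> GazeTrace:
    """Interpolate short dropout gaps, remove blinks and off-screen samples.

    Runs of missing samples spanning at most ``max_interp_frames`` frames
    and flanked by present samples are linearly interpolated; longer runs
    are eye blinks and stay missing (invalid). By default the frame
    threshold is derived from ``gap_ms`` (75 ms): gaps strictly shorter
    than 75 ms are interpolated, which at 24 fps (41.7 ms/frame) means
    single-frame gaps; two frames and more count as blinks. Samples
    outside the video frame are marked invalid but keep their coordinates,
    so a second application of this function is a no-op (idempotence).

    Raises
    ------
    GazeOverlapError
        If no valid samples remain.
    """
    if max_interp_frames is None:
        # largest run length whose duration is strictly below gap_ms
        frame_ms = 1000.0 / trace.fps
        max_interp_frames = max(int(np.ceil(gap_ms / frame_ms)) - 1, 0)
    x = trace.x.copy()
    y = trace.y.copy()
    missing = trace._missing()
    for start, stop in _runs(missing):
        length = stop - start
        if length > max_interp_frames:
            continue  # blink: stays missing
        if start == 0 or stop == len(x):
            continue  # no flanking sample on one side; cannot interpolate
        f0, f1 = trace.frames[start - 1], trace.frames[stop]
        for k in range(start, stop):
            w = (trace.frames[k] - f0) / (f1 - f0)
            x[k] = trace.x[start - 1] + w * (trace.x[stop] - trace.x[start - 1])
            y[k] = trace.y[start - 1] + w * (trace.y[stop] - trace.y[start - 1])
    present = ~(np.isnan(x) | np.isnan(y))
    onscreen = (
        (x >= 0) & (x <= trace.frame_width_px) & (y >= 0) & (y <= trace.frame_height_px)
    )
    valid = present & onscreen
    if not valid.any():
        raise GazeOverlapError(
            f"no valid gaze samples remain for subject {trace.subject_id!r}"
        )
    return GazeTrace(
        trace.subject_id,
        trace.frames.copy(),
        x,
        y,
        trace.frame_width_px,
        trace.frame_height_px,
        trace.fps,
        valid=valid,
    )


def gaze_dissim(
    trace_i: GazeTrace,
    trace_j: GazeTrace,
    *,
    min_overlap: float = 0.10,
) -> float:
    """Gaze-trajectory dissimilarity, ``1 - (r_x + r_y) / 2``.

    Pearson correlations of the horizontal and vertical gaze positions are
    computed on the intersection of the two traces' valid frames. The
    intersection must cover at least ``min_overlap`` of the frame count;
    otherwise the dyad is rejected (:class:`GazeOverlapError`).
    """
    if trace_i.n_frames != trace_j.n_frames or np.any(trace_i.frames != trace_j.frames):
        raise ValueError("traces must share the same frame index")
    both = trace_i.valid & trace_j.valid
    n_ok = int(both.sum())
    if n_ok < max(3, int(np.ceil(min_overlap * trace_i.n_frames))):
        raise GazeOverlapError(
            f"valid-frame overlap {n_ok}/{trace_i.n_frames} below minimum for dyad "
            f"({trace_i.subject_id!r}, {trace_j.subject_id!r})"
        )
    rs = []
    for a, b in ((trace_i.x[both], trace_j.x[both]), (trace_i.y[both], trace_j.y[both])):
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            raise GazeOverlapError(
                "zero variance on the valid-frame intersection for dyad "
                f"({trace_i.subject_id!r}, {trace_j.subject_id!r})"
            )
        rs.append(float(np.corrcoef(a, b)[0, 1]))
    return 1.0 - (rs[0] + rs[1]) / 2.0
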