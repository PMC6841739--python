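"""Weighted-centroid nucleus tracking.

Each cell's position in a frame is estimated as the score-weighted average of
pixel positions in a window around its previous position. The per-pixel score
is the product of three terms:

* S¹ = exp(−((x−x₀)² + (y−y₀)²)/σ₁²) — proximity to the previous position
  (σ₁ = 12 px); consecutive frames are 2 min apart, far below the migration
  timescale, so the cell cannot have moved far.
* S² = exp(−f²/σ₂²) — darkness (σ₂ = 10 brightness units); the nucleus
  centre is the darkest part of the cell in phase-contrast imaging.
* S³ = 1 if f(x, y) − f(x₀, y₀) ≤ threshold (10), else 0 — pixels markedly
  brighter than the nucleus centre belong to the cell rim or background and
  are excluded.

All three are evaluated only within a cutoff (50 μm = 10 px) of the previous
position. The normalizing constants of S¹ and S² cancel in the weighted
centroid and are set to 1. Estimated positions are reported at 1/10 pixel
(0.5 μm) resolution. If every score in a cell's window is zero the track ends
there (truncated and flagged, never silently dropped).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .imaging import ImageStack
from .trajectories import TrajectoryTable

__all__ = [
    "TrackerParams",
    "ScoreField",
    "LostTrackError",
    "score_pixels",
    "weighted_centroid",
    "track_stack",
    "TrackingResult",
]


class LostTrackError(RuntimeError):
    """All scores zero in the search window; the track cannot continue."""


@dataclass
class TrackerParams:
    sigma1: float = 12.0  # px, width of the proximity score
    sigma2: float = 10.0  # brightness units, width of the darkness score
    brightness_threshold: float = 10.0  # brightness units, S³ cut
    cutoff: float = 50.0  # μm, search radius around the previous position
    pixel_size: float = 5.0  # μm per pixel

    def __post_init__(self) -> None:
        for name in ("sigma1", "sigma2", "brightness_threshold", "cutoff", "pixel_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def cutoff_px(self) -> float:
        return self.cutoff / self.pixel_size


@dataclass
class ScoreField:
    """Scores over the cutoff window; coordinates are 0-based pixel indices."""

    scores: np.ndarray  # (ny, nx), zero outside the cutoff disc
    x0: int  # window origin (left column) in the full frame
    y0: int  # window origin (top row)

    def pixel_coords(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.scores.shape
        ys, xs = np.mgrid[self.y0 : self.y0 + ny, self.x0 : self.x0 + nx]
        return xs, ys


def score_pixels(
    frame: np.ndarray, prev_pos: tuple[float, float], params: TrackerParams
) -> ScoreField:
    """Score every pixel within the cutoff of ``prev_pos`` = (x, y) in pixels."""
    frame = np.asarray(frame, dtype=float)
    h, w = frame.shape
    px, py = float(prev_pos[0]), float(prev_pos[1])
    if not (0 <= px <= w - 1 and 0 <= py <= h - 1):
        raise ValueError(f"previous position {prev_pos} outside the {w}x{h} frame")
    r = params.cutoff_px
    x_lo, x_hi = max(0, int(np.floor(px - r))), min(w - 1, int(np.ceil(px + r)))
    y_lo, y_hi = max(0, int(np.floor(py - r))), min(h - 1, int(np.ceil(py + r)))
    window = frame[y_lo : y_hi + 1, x_lo : x_hi + 1]
    ys, xs = np.mgrid[y_lo : y_hi + 1, x_lo : x_hi + 1]
    d2 = (xs - px) ** 2 + (ys - py) ** 2
    inside = d2 <= r * r
    f0 = frame[int(round(py)), int(round(px))]
    s1 = np.exp(-d2 / params.sigma1**2)
    s2 = np.exp(-(window**2) / params.sigma2**2)
    s3 = (window - f0) <= params.brightness_threshold
    return ScoreField(np.where(inside, s1 * s2 * s3, 0.0), x_lo, y_lo)


def weighted_centroid(field: ScoreField) -> tuple[float, float]:
    """Score-weighted mean pixel position (x̂, ŷ); raises if all scores are zero."""
    total = field.scores.sum()
    if total <= 0:
        raise LostTrackError("all scores are zero in the search window")
    xs, ys = field.pixel_coords()
    x_hat = float((xs * field.scores).sum() / total)
    y_hat = float((ys * field.scores).sum() / total)
    return x_hat, y_hat


@dataclass
class TrackingResult:
    trajectories: TrajectoryTable  # positions in μm on the output grid
    lost: dict = field(default_factory=dict)  # cell_id -> frame index where lost


def track_stack(
    stack: ImageStack,
    initial_positions,
    params: TrackerParams | None = None,
    output_sampling: float = 34.0,
) -> TrackingResult:
    """Track every cell through the stack from its (manually identified) start.

    ``initial_positions`` is a list of (x, y) in pixels for frame 0. The
    previous estimate seeds each frame's score window. Positions are rounded
    to 1/10 pixel, converted to μm (× pixel size) and subsampled to
    ``output_sampling`` minutes. Lost tracks are truncated at the last good
    frame and recorded in ``lost``.
    """
    params = params or TrackerParams(pixel_size=stack.pixel_size)
    stride_f = output_sampling / stack.frame_interval
    if abs(stride_f - round(stride_f)) > 1e-9 or stride_f < 1:
        raise ValueError(
            f"output sampling {output_sampling} min is not a multiple of the "
            f"frame interval {stack.frame_interval} min"
        )
    stride = int(round(stride_f))
    h, w = stack.shape
    tracks: dict[int, list[tuple[float, float]]] = {}
    lost: dict[int, int] = {}
    for cid, (x, y) in enumerate(initial_positions):
        if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
            raise ValueError(f"cell {cid}: initial position {(x, y)} outside frame")
        tracks[cid] = [(round(float(x), 1), round(float(y), 1))]
    for k in range(1, stack.n_frames):
        frame = stack.frames[k]
        for cid, positions in tracks.items():
            if cid in lost:
                continue
            prev = positions[-1]
            try:
                field = score_pixels(frame, prev, params)
                x_hat, y_hat = weighted_centroid(field)
            except LostTrackError:
                lost[cid] = k
                continue
            positions.append((round(x_hat, 1), round(y_hat, 1)))
    data = {}
    for cid, positions in tracks.items():
        pos_px = np.asarray(positions)[::stride]
        if pos_px.shape[0] < 2:
            lost.setdefault(cid, len(positions))
            continue
        t = np.arange(pos_px.shape[0]) * output_sampling
        data[cid] = (t, pos_px * params.pixel_size)
    return TrackingResult(TrajectoryTable(data), lost)
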