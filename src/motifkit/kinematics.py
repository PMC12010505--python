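"""Egocentric alignment of pose tracks and kinematic summaries.

Alignment expresses every body part relative to a chosen center part with
the body midline (center -> axis part, e.g. tail base) mapped onto the
negative y-axis: caudal = -y, rostral = +y, the subject's left = -x,
matching a ventral camera view. The transform per frame is rigid
(translation + rotation), so pairwise inter-part distances are preserved
exactly and alignment is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import LabelSeries, PoseTrack, ValidationError

__all__ = ["EgoTrack", "egocentric_align", "allocentric_speed",
           "motif_kinematic_profile"]


@dataclass
class EgoTrack:
    """A pose track in egocentric coordinates plus the per-frame rotation.

    ``coords[t, center] == (0, 0)`` and the axis part lies on the negative
    y-axis wherever both reference parts were observed; frames with a
    missing reference are fully missing. ``angle`` is the rotation applied
    (radians), retained so allocentric context can be reconstructed.
    """

    subject_id: str
    fps: float
    parts: list[str]
    coords: np.ndarray       # (n_frames, n_parts, 2)
    likelihood: np.ndarray
    angle: np.ndarray        # (n_frames,)
    center_part: str
    axis_part: str

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def part_index(self, name: str) -> int:
        try:
            return self.parts.index(name)
        except ValueError:
            raise ValidationError(
                f"unknown body part {name!r}; available: {self.parts}"
            ) from None


def egocentric_align(track: PoseTrack | EgoTrack, center_part: str = "center",
                     axis_part: str = "tail_base") -> EgoTrack:
    """Translate/rotate each frame so the midline lies on the negative y-axis.

    Per frame the center part becomes the origin and the vector
    center -> axis part is rotated onto (0, -r). Frames where either
    reference part is missing yield missing coordinates for all parts.
    """
    ci = track.part_index(center_part)
    ai = track.part_index(axis_part)
    if ci == ai:
        raise ValidationError("center_part and axis_part must differ")
    xy = np.asarray(track.coords, float)
    n = xy.shape[0]
    center = xy[:, ci, :]
    rel = xy - center[:, None, :]
    v = rel[:, ai, :]  # midline vector, to be mapped onto (0, -|v|)
    ok = np.isfinite(center).all(axis=1) & np.isfinite(v).all(axis=1)
    # rotation angle: v makes angle phi with +x; we need it at -pi/2
    phi = np.arctan2(v[:, 1], v[:, 0])
    theta = np.where(ok, -np.pi / 2 - phi, np.nan)
    c, s = np.cos(theta), np.sin(theta)
    out = np.empty_like(rel)
    out[:, :, 0] = c[:, None] * rel[:, :, 0] - s[:, None] * rel[:, :, 1]
    out[:, :, 1] = s[:, None] * rel[:, :, 0] + c[:, None] * rel[:, :, 1]
    out[~ok] = np.nan
    like = np.asarray(track.likelihood, float).copy()
    return EgoTrack(track.subject_id, track.fps, list(track.parts), out, like,
                    theta, center_part, axis_part)


def allocentric_speed(track: PoseTrack, part: str = "center",
                      fps: float | None = None,
                      scale: float = 1.0) -> np.ndarray:
    """Per-frame speed of one body part: |displacement| * fps / scale.

    ``scale`` converts px to the desired unit (px per mm for mm/s output;
    1 keeps px/s). The first frame has no predecessor and is NaN, as is any
    frame adjacent to a missing coordinate.
    """
    if scale <= 0:
        raise ValidationError("scale must be positive")
    fps = track.fps if fps is None else fps
    if fps <= 0:
        raise ValidationError("fps must be positive")
    pi = track.part_index(part)
    xy = np.asarray(track.coords, float)[:, pi, :]
    disp = np.hypot(np.diff(xy[:, 0]), np.diff(xy[:, 1]))
    out = np.empty(xy.shape[0])
    out[0] = np.nan
    out[1:] = disp * fps / scale
    return out


def motif_kinematic_profile(ego: EgoTrack, speeds: np.ndarray,
                            labels: LabelSeries,
                            window_frames: int = 10) -> pd.DataFrame:
    """Per-motif mean egocentric posture and speed over post-onset windows.

    A motif onset is any frame whose label differs from the previous frame
    (frame 0 included). From each onset, up to ``window_frames`` frames are
    accumulated while the label persists. Motifs never observed appear with
    n_frames = 0 and missing means. Pass ``window_frames = np.inf`` (any
    value >= series length) for whole-occupancy averaging.

    Returns a tidy table with one row per (motif, part) carrying mean/sd of
    the egocentric x and y plus per-motif speed summaries.
    """
    if window_frames < 1:
        raise ValidationError("window_frames must be >= 1")
    speeds = np.asarray(speeds, float)
    lab = labels.labels
    if not (ego.n_frames == speeds.size == lab.size):
        raise ValidationError("ego track, speeds and labels must share length")
    m = labels.alphabet_size
    # frames inside onset windows, per motif
    onset = np.empty(lab.size, dtype=bool)
    onset[0] = True
    onset[1:] = lab[1:] != lab[:-1]
    run_pos = np.arange(lab.size) - np.maximum.accumulate(
        np.where(onset, np.arange(lab.size), -1))
    in_window = run_pos < window_frames
    rows = []
    for motif in range(m):
        sel = (lab == motif) & in_window
        n_sel = int(sel.sum())
        spd = speeds[sel]
        spd = spd[np.isfinite(spd)]
        spd_mean = float(spd.mean()) if spd.size else np.nan
        spd_sd = float(spd.std(ddof=1)) if spd.size > 1 else np.nan
        for p, part in enumerate(ego.parts):
            xy = ego.coords[sel, p, :]
            for axis, name in ((0, "x"), (1, "y")):
                vals = xy[:, axis]
                vals = vals[np.isfinite(vals)]
                rows.append({
                    "motif": motif, "part": part, "axis": name,
                    "mean": float(vals.mean()) if vals.size else np.nan,
                    "sd": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
                    "n_frames": n_sel,
                    "speed_mean": spd_mean, "speed_sd": spd_sd,
                })
    return pd.DataFrame(rows)
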