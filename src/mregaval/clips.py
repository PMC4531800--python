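"""Peri-event 4D clip extraction and averaging.

For every motion-free activity peak, the (voxelwise-normalized) volume
series is cropped to 50 samples before and 100 after the peak — a
151-frame, 15.1 s clip at 10 Hz. Clips are averaged framewise within a
subject and component, and subject means are averaged with equal weight
per subject into a group mean.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from mregaval.io import VolumeSeries


@dataclass
class Clip:
    """A peri-peak 4D excerpt; frame ``peak_frame`` is the peak sample."""

    data: np.ndarray
    peak_frame: int
    source: tuple = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("clip data must be 4D")
        if not (0 <= self.peak_frame < self.data.shape[3]):
            raise ValueError("peak_frame outside clip")

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]


def normalize_voxelwise(series: VolumeSeries, global_mode: bool = False) -> VolumeSeries:
    """Standardize each voxel's time course to zero mean, unit variance.

    Normalization over the whole (post-trim) record makes values
    comparable across regions. Zero-variance voxels (outside the brain)
    become all-zero rather than NaN. With ``global_mode=True`` a single
    mean/SD over all in-brain voxels and times is used instead.
    """
    if series.n_volumes < 2:
        raise ValueError("need at least 2 volumes to normalize")
    data = series.data
    if global_mode:
        sd = data.std()
        out = (data - data.mean()) / sd if sd > 0 else np.zeros_like(data)
    else:
        mean = data.mean(axis=3, keepdims=True)
        sd = data.std(axis=3, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = (data - mean) / sd
        out[np.broadcast_to(sd == 0, out.shape)] = 0.0
        out = np.nan_to_num(out, nan=0.0, posinf=0.0, neginf=0.0)
    return dataclasses.replace(series, data=out)


def extract_clip(
    series: VolumeSeries,
    peak_index: int,
    pre: int = 50,
    post: int = 100,
    source: tuple = (),
) -> Clip:
    """Crop ``[peak_index - pre, peak_index + post]`` (inclusive) frames.

    The defaults give the standard 151-frame (15.1 s at 10 Hz) clip with
    the peak at frame 50.
    """
    if pre < 0 or post < 0:
        raise ValueError("pre and post must be nonnegative")
    T = series.n_volumes
    if peak_index - pre < 0 or peak_index + post > T - 1:
        raise ValueError(
            f"clip window [{peak_index - pre}, {peak_index + post}] exits "
            f"series of length {T}"
        )
    data = series.data[..., peak_index - pre : peak_index + post + 1]
    return Clip(data=data.copy(), peak_frame=pre, source=source)


def subject_mean_clip(clips: list[Clip]) -> Clip:
    """Framewise arithmetic mean of one subject's clips (same component)."""
    if not clips:
        raise ValueError("need at least one clip")
    shape = clips[0].data.shape
    for c in clips[1:]:
        if c.data.shape != shape:
            raise ValueError("all clips must have identical shapes")
        if c.peak_frame != clips[0].peak_frame:
            raise ValueError("all clips must share the peak frame")
    mean = np.mean([c.data for c in clips], axis=0)
    return Clip(data=mean, peak_frame=clips[0].peak_frame, source=("subject-mean",))


def group_mean_clip(subject_means: list[Clip]) -> Clip:
    """Equal-weight mean over subjects.

    Each subject counts once regardless of how many peaks contributed to
    its mean, so a subject with many events does not dominate the group.
    """
    if not subject_means:
        raise ValueError("need at least one subject mean")
    return Clip(
        data=np.mean([c.data for c in subject_means], axis=0),
        peak_frame=subject_means[0].peak_frame,
        source=("group-mean",),
    )


def focus_voxel(zmap: np.ndarray) -> tuple[int, int, int]:
    """Voxel of maximum z-score in a component map (slice intersection point).

    Ties resolve to the lexicographically smallest index triple.
    """
    zmap = np.asarray(zmap, dtype=float)
    if not np.all(np.isfinite(zmap)):
        raise ValueError("map must be finite")
    if np.all(zmap == 0):
        raise ValueError("all-zero map has no focus voxel")
    flat = int(np.argmax(zmap))  # np.argmax returns the first (C-order) maximum
    return tuple(int(v) for v in np.unravel_index(flat, zmap.shape))
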