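"""Head-motion screening: speed series and peri-event exclusion masks.

Realignment parameters are differentiated along time and the absolute
per-axis velocities summed, giving a translational speed (mm/sample) and
a rotational speed (rad/sample). Samples where either speed exceeds its
threshold (defaults 0.2 mm/sample, 1e-3 rad/sample) are flagged, and an
exclusion mask is grown around them so that every surviving peak's crop
window (5 s before, 10 s after at 10 Hz) is guaranteed motion-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from mregaval.io import MotionTrace


@dataclass
class SpeedSeries:
    """Per-sample summed absolute speeds; sample 0 is defined as 0."""

    trans_speed: np.ndarray
    rot_speed: np.ndarray

    def __post_init__(self) -> None:
        self.trans_speed = np.asarray(self.trans_speed, dtype=float)
        self.rot_speed = np.asarray(self.rot_speed, dtype=float)
        if self.trans_speed.shape != self.rot_speed.shape:
            raise ValueError("speed series must have equal length")

    def __len__(self) -> int:
        return self.trans_speed.size


@dataclass
class ExclusionMask:
    """Boolean exclusion mask plus the raw threshold-crossing samples."""

    excluded: np.ndarray
    flagged_samples: np.ndarray

    def __post_init__(self) -> None:
        self.excluded = np.asarray(self.excluded, dtype=bool)
        self.flagged_samples = np.asarray(self.flagged_samples, dtype=int)
        if self.flagged_samples.size and not np.all(
            self.excluded[self.flagged_samples]
        ):
            raise ValueError("every flagged sample must be excluded")

    def __len__(self) -> int:
        return self.excluded.size


def compute_speeds(trace: MotionTrace) -> SpeedSeries:
    """Convert realignment parameters into per-sample speeds.

    Velocity is the first difference along time per axis; speed is the
    sum of absolute velocities over the three spatial axes. Speeds are
    invariant to constant offsets in the parameters.
    """
    if len(trace) < 2:
        raise ValueError("need at least 2 volumes to compute speeds")
    tv = np.abs(np.diff(trace.translations, axis=0)).sum(axis=1)
    rv = np.abs(np.diff(trace.rotations, axis=0)).sum(axis=1)
    trans = np.concatenate([[0.0], tv])
    rot = np.concatenate([[0.0], rv])
    return SpeedSeries(trans_speed=trans, rot_speed=rot)


def exclusion_mask(
    speeds: SpeedSeries,
    trans_thresh: float = 0.2,
    rot_thresh: float = 1e-3,
    pre: int = 50,
    post: int = 100,
    *,
    symmetric: bool = False,
    exclude_boundaries: bool = True,
) -> ExclusionMask:
    """Exclude samples whose peri-peak crop window would contain motion.

    A sample is flagged when its translational speed strictly exceeds
    ``trans_thresh`` or its rotational speed strictly exceeds
    ``rot_thresh``. A sample ``t`` is then excluded if any flagged sample
    lies in ``[t - post, t + pre]`` - the reflected dilation, which is
    exactly the condition that the crop window ``[t - pre, t + post]``
    contains no flagged sample. With ``symmetric=True`` the literal
    symmetric neighborhood ``[t - w, t + w]``, ``w = max(pre, post)``, is
    excluded instead.

    Boundary samples whose full crop window would exit the series are
    excluded too (they could not be cropped anyway) unless
    ``exclude_boundaries=False``.
    """
    if trans_thresh <= 0 or rot_thresh <= 0:
        raise ValueError("thresholds must be positive")
    if pre < 0 or post < 0:
        raise ValueError("pre and post must be nonnegative")
    T = len(speeds)
    flagged = np.flatnonzero(
        (speeds.trans_speed > trans_thresh) | (speeds.rot_speed > rot_thresh)
    )
    excluded = np.zeros(T, dtype=bool)
    if symmetric:
        back, fwd = max(pre, post), max(pre, post)
    else:
        # crop [t - pre, t + post] contains f  <=>  t in [f - post, f + pre]
        back, fwd = post, pre
    for f in flagged:
        lo = max(0, f - back)
        hi = min(T, f + fwd + 1)
        excluded[lo:hi] = True
    if exclude_boundaries:
        excluded[:pre] = True
        if post > 0:
            excluded[T - post :] = True
    return ExclusionMask(excluded=excluded, flagged_samples=flagged)


def export_mask(mask: ExclusionMask, path) -> None:
    """Write the mask as a two-column table (sample_index, excluded 0/1)."""
    arr = np.column_stack(
        [np.arange(len(mask)), mask.excluded.astype(int)]
    )
    np.savetxt(path, arr, fmt="%d", header="sample_index\texcluded", comments="")
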