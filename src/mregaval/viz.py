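"""Bicolor overlay rendering: frame tiles, videos, and pipeline overviews.

Normalized BOLD values are overlaid on an anatomical grayscale: positive
values map from red (at the cut threshold) to yellow (at saturation),
negative values from blue to cyan; values below the cut show anatomy
only. Slices are smoothed with a small Gaussian kernel (SD 1.2 px) and
out-of-brain voxels are zeroed before thresholding.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v2 as imageio
import numpy as np
from matplotlib.figure import Figure
from scipy import ndimage

from mregaval.clips import Clip, focus_voxel

logger = logging.getLogger(__name__)


@dataclass
class RenderSpec:
    """Display thresholds and slice geometry for overlay rendering.

    ``cut``/``sat``: lower and saturation |value| display thresholds for
    the activity overlay (defaults 1.7 / 3.5 in normalized units);
    ``map_cut``/``map_sat``: the same for the component z-score map
    (defaults 3 / 7); ``gaussian_sd_px``: smoothing SD in pixels;
    ``slice_planes``: the three orthogonal slice indices (filled from
    the component map's focus voxel when None).
    """

    cut: float = 1.7
    sat: float = 3.5
    map_cut: float = 3.0
    map_sat: float = 7.0
    gaussian_sd_px: float = 1.2
    slice_planes: tuple[int, int, int] | None = None
    fps: float = 10.0

    def __post_init__(self) -> None:
        if not (0 <= self.cut < self.sat):
            raise ValueError("need 0 <= cut < sat")
        if not (0 <= self.map_cut < self.map_sat):
            raise ValueError("need 0 <= map_cut < map_sat")


def _to_gray(anatomy: np.ndarray) -> np.ndarray:
    a = np.asarray(anatomy, dtype=float)
    lo, hi = float(a.min()), float(a.max())
    if hi > lo:
        a = (a - lo) / (hi - lo)
    else:
        a = np.zeros_like(a)
    return a


def render_frame(
    values: np.ndarray,
    anatomy: np.ndarray,
    spec: RenderSpec,
    brain_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Render one 2D slice of normalized values over an anatomy slice.

    Returns an (H, W, 3) float RGB image in [0, 1]. Values are zeroed
    outside the brain mask and smoothed with a Gaussian kernel
    (SD ``spec.gaussian_sd_px``). Pixels with |v| <= cut show the
    anatomy; above the cut, red (positive) or blue (negative) is at
    maximum and the green channel rises linearly from 0 at the cut to 1
    at saturation, giving red-to-yellow and blue-to-cyan scales.
    """
    v = np.asarray(values, dtype=float).copy()
    if v.ndim != 2:
        raise ValueError("render_frame expects a 2D slice")
    if brain_mask is not None:
        v[~np.asarray(brain_mask, dtype=bool)] = 0.0
    if spec.gaussian_sd_px > 0:
        v = ndimage.gaussian_filter(v, sigma=spec.gaussian_sd_px)
    gray = _to_gray(anatomy)
    img = np.repeat(gray[..., None], 3, axis=2)
    absv = np.abs(v)
    over = absv > spec.cut
    g = np.clip((absv - spec.cut) / (spec.sat - spec.cut), 0.0, 1.0)
    pos = over & (v > 0)
    neg = over & (v < 0)
    img[pos] = np.stack(
        [np.ones(pos.sum()), g[pos], np.zeros(pos.sum())], axis=1
    )
    img[neg] = np.stack(
        [np.zeros(neg.sum()), g[neg], np.ones(neg.sum())], axis=1
    )
    return img


def _three_planes(volume: np.ndarray, planes: tuple[int, int, int]):
    i, j, k = planes
    return volume[i, :, :], volume[:, j, :], volume[:, :, k]


def _compose_row(slices, pad_to: tuple[int, int]) -> np.ndarray:
    """Place RGB slices side by side on a common canvas height/width."""
    h, w = pad_to
    padded = []
    for s in slices:
        canvas = np.zeros((h, w, 3))
        canvas[: s.shape[0], : s.shape[1]] = s
        padded.append(canvas)
    return np.concatenate(padded, axis=1)


def render_composite_frame(
    frame: np.ndarray,
    anatomy: np.ndarray,
    spec: RenderSpec,
    planes: tuple[int, int, int],
    brain_mask: np.ndarray | None = None,
    cut: float | None = None,
    sat: float | None = None,
) -> np.ndarray:
    """Render the three orthogonal slices of one 3D frame side by side."""
    use_spec = spec
    if cut is not None or sat is not None:
        use_spec = RenderSpec(
            cut=cut if cut is not None else spec.cut,
            sat=sat if sat is not None else spec.sat,
            gaussian_sd_px=spec.gaussian_sd_px,
        )
    vs = _three_planes(frame, planes)
    ans = _three_planes(anatomy, planes)
    ms = (
        _three_planes(brain_mask, planes)
        if brain_mask is not None
        else (None, None, None)
    )
    rendered = [
        render_frame(v, a, use_spec, brain_mask=m) for v, a, m in zip(vs, ans, ms)
    ]
    h = max(r.shape[0] for r in rendered)
    w = max(r.shape[1] for r in rendered)
    return _compose_row(rendered, (h, w))


def render_tiles(
    clip: Clip,
    zmap: np.ndarray,
    anatomy: np.ndarray,
    spec: RenderSpec,
    frame_stride: int = 1,
) -> np.ndarray:
    """Frame-tile sheet: component map on top, then frames top-to-bottom.

    The first row shows the component z-score map's three orthogonal
    slices (cut/saturated at ``map_cut``/``map_sat``); each following row
    is one clip frame (every ``frame_stride``-th), so time flows
    vertically at ``frame_stride`` x 100 ms per row for 10 Hz data.
    Returns an (H, W, 3) float RGB image.
    """
    if frame_stride < 1:
        raise ValueError("frame_stride must be >= 1")
    planes = spec.slice_planes or focus_voxel(zmap)
    rows = [
        render_composite_frame(
            np.asarray(zmap, dtype=float),
            anatomy,
            spec,
            planes,
            cut=spec.map_cut,
            sat=spec.map_sat,
        )
    ]
    for t in range(0, clip.n_frames, frame_stride):
        rows.append(
            render_composite_frame(clip.data[..., t], anatomy, spec, planes)
        )
    w = max(r.shape[1] for r in rows)
    rows = [
        np.pad(r, ((0, 0), (0, w - r.shape[1]), (0, 0))) for r in rows
    ]
    return np.concatenate(rows, axis=0)


def n_tile_rows(n_frames: int, frame_stride: int) -> int:
    """Rows in a tile sheet: one map row plus ceil(n_frames/stride)."""
    return 1 + math.ceil(n_frames / frame_stride)


def export_video(
    clip: Clip,
    spec: RenderSpec,
    path: str | Path,
    anatomy: np.ndarray,
    zmap: np.ndarray | None = None,
    brain_mask: np.ndarray | None = None,
) -> Path:
    """Export a clip as a video, one video frame per clip sample.

    The default display rate (``spec.fps`` = 10) plays 10 Hz data in
    real time. Writes MP4 when the path ends in ``.mp4`` and an H.264
    encoder is available, GIF for ``.gif``; if the encoder is missing,
    falls back to a PNG image-sequence directory named
    ``<path stem>_frames`` and returns that directory.
    """
    path = Path(path)
    planes = spec.slice_planes or (
        focus_voxel(zmap) if zmap is not None else tuple(
            s // 2 for s in clip.data.shape[:3]
        )
    )
    frames = []
    for t in range(clip.n_frames):
        img = render_composite_frame(
            clip.data[..., t], anatomy, spec, planes, brain_mask=brain_mask
        )
        frames.append((np.clip(img, 0, 1) * 255).astype(np.uint8))
    if path.suffix.lower() in (".mp4", ".gif"):
        try:
            if path.suffix.lower() == ".gif":
                imageio.mimwrite(path, frames, duration=1000.0 / spec.fps)
            else:
                imageio.mimwrite(path, frames, fps=spec.fps)
            return path
        except Exception as exc:
            logger.warning(
                "encoder unavailable for %s (%s); falling back to a PNG "
                "image-sequence directory",
                path.suffix,
                exc,
            )
    out_dir = path.parent / (path.stem + "_frames")
    out_dir.mkdir(parents=True, exist_ok=True)
    for t, frame in enumerate(frames):
        imageio.imwrite(out_dir / f"frame_{t:04d}.png", frame)
    return out_dir


def render_overview(
    raw: np.ndarray,
    trend: np.ndarray,
    decomposition,
    clean,
    peaks: list,
    mask,
    speeds=None,
    fs_hz: float = 10.0,
) -> Figure:
    """Single-subject peak-detection overview figure.

    Stacked panels: motion speeds with excluded spans shaded (when
    speeds are given), then raw series with the vasomotor trend, the
    noise-removed activation signal, and the clean series with kept
    peaks (triangles) and motion-rejected peaks (crosses).
    """
    raw = np.asarray(raw, dtype=float)
    t = np.arange(raw.size) / fs_hz
    n_panels = 4 if speeds is not None else 3
    fig = Figure(figsize=(12, 2.2 * n_panels))
    axes = fig.subplots(n_panels, 1, sharex=True)
    row = 0
    if speeds is not None:
        ax = axes[row]
        ax.plot(t, speeds.trans_speed, lw=0.6, label="trans (mm/sample)")
        ax.plot(t, speeds.rot_speed * 100, lw=0.6, label="rot (x100 rad/sample)")
        _shade_excluded(ax, mask, fs_hz)
        ax.set_ylabel("speed")
        ax.legend(loc="upper right", fontsize=7)
        row += 1
    ax = axes[row]
    ax.plot(t, raw, lw=0.5, label="raw")
    ax.plot(t, np.asarray(trend, dtype=float), lw=1.0, label="vasomotor trend")
    ax.set_ylabel("raw")
    ax.legend(loc="upper right", fontsize=7)
    row += 1
    ax = axes[row]
    ax.plot(t, decomposition.cleaned, lw=0.5)
    ax.set_ylabel("noise-removed")
    row += 1
    ax = axes[row]
    cv = clean.values
    ax.plot(t, cv, lw=0.5)
    _shade_excluded(ax, mask, fs_hz)
    kept = [p for p in peaks if not mask.excluded[p.index]]
    rej = [p for p in peaks if mask.excluded[p.index]]
    if kept:
        ax.plot([p.time_s for p in kept], [p.value for p in kept], "v", ms=6,
                color="tab:green", label="kept peaks")
    if rej:
        ax.plot([p.time_s for p in rej], [p.value for p in rej], "x", ms=6,
                color="tab:red", label="motion-rejected")
    if clean.threshold is not None:
        ax.axhline(clean.threshold, color="gray", lw=0.8, ls="--")
    ax.set_ylabel("clean")
    ax.set_xlabel("time (s)")
    if kept or rej:
        ax.legend(loc="upper right", fontsize=7)
    fig.tight_layout()
    return fig


def _shade_excluded(ax, mask, fs_hz: float) -> None:
    excluded = np.asarray(mask.excluded, dtype=bool)
    if not excluded.any():
        return
    edges = np.flatnonzero(np.diff(excluded.astype(int)))
    starts = [0] if excluded[0] else []
    starts += [int(e) + 1 for e in edges if not excluded[e]]
    ends = [int(e) for e in edges if excluded[e]]
    if excluded[-1]:
        ends.append(excluded.size - 1)
    for s, e in zip(starts, ends):
        ax.axvspan(s / fs_hz, e / fs_hz, color="red", alpha=0.12, lw=0)


def save_distribution_plot(estimate, path: str | Path, title: str = "") -> None:
    """Log-log plot of a size/lifetime density with the fitted power laws."""
    fig = Figure(figsize=(5, 4))
    ax = fig.subplots()
    pos = estimate.densities > 0
    ax.loglog(estimate.bin_centers[pos], estimate.densities[pos], "o", ms=4)
    x = estimate.bin_centers[pos]
    if x.size >= 2 and np.isfinite(estimate.exponent_mle):
        ref = x ** (-estimate.exponent_mle)
        ref *= estimate.densities[pos][0] / ref[0]
        ax.loglog(x, ref, "-", lw=1,
                  label=f"MLE slope -{estimate.exponent_mle:.2f}")
        ax.legend(fontsize=8)
    ax.set_xlabel("value")
    ax.set_ylabel("density")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
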