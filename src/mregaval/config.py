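"""Run configuration for the avalanche-detection pipeline.

All defaults are the published operating point of the method: 10 Hz
sampling, 180-sample initial trim, respiratory search grid 8-24 bpm at
0.2 bpm steps, cardiac grid 45-65 bpm at 0.4 bpm steps, Savitzky-Golay
order 2 / window 513, motion thresholds 0.2 mm and 1e-3 rad per sample,
peak threshold 1.5 x SD, 50-sample minimum peak distance, and a
50-before / 100-after peri-peak crop window.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Parameters steering every pipeline stage.

    Attributes
    ----------
    fs_hz:
        Sampling rate of the component series in Hz.
    trim_n:
        Number of initial volumes/samples removed to let T1 relaxation
        settle.
    resp_grid, cardiac_grid:
        ``(fmin_bpm, fmax_bpm, step_bpm)`` frequency search grids for the
        respiratory and cardiac trackers.
    sg_order, sg_window:
        Savitzky-Golay polynomial order and window length (samples) for
        vasomotor trend estimation.
    trans_thresh, rot_thresh:
        Motion-speed exclusion thresholds in mm/sample and rad/sample.
    peak_k:
        Peak threshold as a multiple of the clean-series SD.
    min_dist:
        Minimum distance between detected peaks, samples.
    pre, post:
        Peri-peak crop window: samples before and after the peak.
    dscore_limit:
        Frequency-trajectory SD (bpm) above which physiological-noise
        removal is considered trustworthy.
    resp_harmonics, cardiac_harmonics:
        Number of resonator harmonics in the noise-removal state space.
    imm_stay_prob:
        Self-transition probability of the frequency tracker's sticky
        mode-transition matrix.
    motion_cols:
        Column convention of the realignment-parameter file:
        ``"rot-first"`` (3 rotations then 3 translations) or
        ``"trans-first"``.
    symmetric_exclusion:
        If True, exclude the literal symmetric neighborhood around
        flagged motion samples instead of the reflected crop window.
    threshold_on_included_only:
        If True, the peak-threshold SD is computed over non-excluded
        samples only instead of the full record.
    global_normalization:
        If True, visualization normalization uses one global mean/SD for
        the whole volume series instead of per-voxel standardization.
    selected_components:
        Indices of the mixing-matrix columns to process.
    seed:
        Seed for the synthetic generators.
    """

    fs_hz: float = 10.0
    trim_n: int = 180
    resp_grid: tuple[float, float, float] = (8.0, 24.0, 0.2)
    cardiac_grid: tuple[float, float, float] = (45.0, 65.0, 0.4)
    sg_order: int = 2
    sg_window: int = 513
    trans_thresh: float = 0.2
    rot_thresh: float = 1e-3
    peak_k: float = 1.5
    min_dist: int = 50
    pre: int = 50
    post: int = 100
    dscore_limit: float = 1.0
    resp_harmonics: int = 3
    cardiac_harmonics: int = 2
    imm_stay_prob: float = 0.8
    motion_cols: str = "rot-first"
    symmetric_exclusion: bool = False
    threshold_on_included_only: bool = False
    global_normalization: bool = False
    selected_components: list[int] = field(default_factory=lambda: [0])
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_order:
            raise ValueError("sg_window must be odd and greater than sg_order")
        if self.pre < 0 or self.post < 0:
            raise ValueError("pre and post must be nonnegative")
        nyq_bpm = self.fs_hz / 2.0 * 60.0
        for name, (lo, hi, step) in (
            ("resp_grid", self.resp_grid),
            ("cardiac_grid", self.cardiac_grid),
        ):
            if not (0.0 < lo < hi < nyq_bpm):
                raise ValueError(
                    f"{name} must lie inside (0, {nyq_bpm}) bpm, got ({lo}, {hi})"
                )
            if step <= 0:
                raise ValueError(f"{name} step must be positive")
        if self.motion_cols not in ("rot-first", "trans-first"):
            raise ValueError("motion_cols must be 'rot-first' or 'trans-first'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["resp_grid"] = list(self.resp_grid)
        d["cardiac_grid"] = list(self.cardiac_grid)
        return d


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML file.

    Unknown keys raise; keyword overrides win over file values. With no
    path, returns the shipped defaults (plus overrides).
    """
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        values.update(loaded)
    values.update(overrides)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(values) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("resp_grid", "cardiac_grid"):
        if key in values:
            values[key] = tuple(values[key])
    return PipelineConfig(**values)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    """Write the configuration as YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
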