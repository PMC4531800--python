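"""End-to-end orchestration of the avalanche-detection steps.

Chains the per-component stages — frequency tracking, Dscore QC,
Kalman/RTS noise removal, Savitzky-Golay detrending, cleaning, motion
screening, peak detection, and size/lifetime measurement — behind one
call, for the CLI and for whole-pipeline tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from mregaval.avalanche import (
    AvalancheRecord,
    Peak,
    build_records,
    detect_peaks,
    peak_threshold,
    records_to_table,
)
from mregaval.config import PipelineConfig
from mregaval.io import MixingMatrix, MotionTrace, check_aligned
from mregaval.motion import ExclusionMask, compute_speeds, exclusion_mask
from mregaval.physio import (
    CleanSeries,
    ComponentSeries,
    DscoreReport,
    FrequencyGrid,
    FrequencyTrajectory,
    NoiseDecomposition,
    clean_component,
    dscore,
    estimate_frequency_trajectory,
    estimate_vasomotor,
    remove_periodic_noise,
)


@dataclass
class ComponentResult:
    """Everything the pipeline computed for one component."""

    series: ComponentSeries
    resp_traj: FrequencyTrajectory
    cardiac_traj: FrequencyTrajectory
    dscore_resp: DscoreReport
    dscore_cardiac: DscoreReport
    decomposition: NoiseDecomposition
    trend: np.ndarray
    clean: CleanSeries
    threshold: float
    peaks: list[Peak]
    kept_peaks: list[Peak]
    records: list[AvalancheRecord]

    @property
    def qc_passed(self) -> bool:
        return self.dscore_resp.passed and self.dscore_cardiac.passed


def clean_series(
    series: ComponentSeries, config: PipelineConfig
) -> tuple[CleanSeries, FrequencyTrajectory, FrequencyTrajectory, NoiseDecomposition, np.ndarray]:
    """Steps B-D for one component: track, decompose, detrend, clean."""
    resp_grid = FrequencyGrid(*config.resp_grid)
    cardiac_grid = FrequencyGrid(*config.cardiac_grid)
    resp_traj = estimate_frequency_trajectory(
        series, resp_grid, stay_prob=config.imm_stay_prob
    )
    cardiac_traj = estimate_frequency_trajectory(
        series, cardiac_grid, stay_prob=config.imm_stay_prob
    )
    decomp = remove_periodic_noise(
        series,
        resp_traj,
        cardiac_traj,
        harmonics=(config.resp_harmonics, config.cardiac_harmonics),
    )
    trend = estimate_vasomotor(series, window=config.sg_window, order=config.sg_order)
    clean = clean_component(series, decomp, trend)
    return clean, resp_traj, cardiac_traj, decomp, trend


def screen_motion(trace: MotionTrace, config: PipelineConfig) -> ExclusionMask:
    """Step E: speeds plus the peri-event exclusion mask."""
    speeds = compute_speeds(trace)
    return exclusion_mask(
        speeds,
        trans_thresh=config.trans_thresh,
        rot_thresh=config.rot_thresh,
        pre=config.pre,
        post=config.post,
        symmetric=config.symmetric_exclusion,
    )


def process_component(
    series: ComponentSeries,
    config: PipelineConfig,
    mask: ExclusionMask | None = None,
) -> ComponentResult:
    """Run steps B-F for one component series.

    A component whose respiratory or cardiac Dscore fails the limit is
    flagged (``qc_passed``) but still processed; exclusion is a policy
    decision left to the caller.
    """
    clean, resp_traj, cardiac_traj, decomp, trend = clean_series(series, config)
    ds_r = dscore(resp_traj, config.dscore_limit)
    ds_c = dscore(cardiac_traj, config.dscore_limit)
    if mask is not None and len(mask) != len(series):
        raise ValueError("mask and series lengths differ")
    if config.threshold_on_included_only and mask is not None:
        incl = CleanSeries(values=clean.values[~mask.excluded], fs_hz=clean.fs_hz)
        threshold = peak_threshold(incl, config.peak_k)
    else:
        threshold = peak_threshold(clean, config.peak_k)
    clean.threshold = threshold
    peaks = detect_peaks(clean, threshold, config.min_dist)
    records = build_records(clean, peaks, threshold, mask)
    kept = [r.peak for r in records if not r.motion_excluded]
    return ComponentResult(
        series=series,
        resp_traj=resp_traj,
        cardiac_traj=cardiac_traj,
        dscore_resp=ds_r,
        dscore_cardiac=ds_c,
        decomposition=decomp,
        trend=trend,
        clean=clean,
        threshold=threshold,
        peaks=peaks,
        kept_peaks=kept,
        records=records,
    )


def process_recording(
    mixing: MixingMatrix,
    trace: MotionTrace | None,
    config: PipelineConfig,
) -> tuple[dict[int, ComponentResult], pd.DataFrame]:
    """Process every selected component of one recording.

    Returns per-component results plus the combined avalanche table.
    """
    if trace is not None:
        check_aligned(mixing, trace)
        mask = screen_motion(trace, config)
    else:
        mask = None
    results: dict[int, ComponentResult] = {}
    tables = []
    for ci in config.selected_components:
        if not (0 <= ci < mixing.n_components):
            raise ValueError(f"component index {ci} out of range")
        series = ComponentSeries(values=mixing.values[:, ci], fs_hz=config.fs_hz)
        res = process_component(series, config, mask)
        results[ci] = res
        tables.append(
            records_to_table(
                res.records,
                component=ci,
                dscore_resp=res.dscore_resp.score,
                dscore_cardiac=res.dscore_cardiac.score,
            )
        )
    table = (
        pd.concat(tables, ignore_index=True)
        if tables
        else records_to_table([], component=0)
    )
    return results, table
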