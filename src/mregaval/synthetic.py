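"""Ground-truthed synthetic stand-ins for every scanner-derived input.

Emulates what a 10-minute resting-state MREG acquisition delivers to the
pipeline after standard preprocessing: ICA component time courses at
10 Hz containing slow vasomotor drift, a drifting respiratory oscillation
(8-24 bpm), a drifting cardiac oscillation (45-65 bpm), white measurement
noise and brief (0.2-1 s) avalanche-type activity events; realignment
parameters with sub-threshold baseline wobble plus injected motion
spikes; and a small 4D volume series in which each event spreads from a
Gaussian-blob component map into adjacent voxels.

Every generator is deterministic given its seed, and returns a
:class:`GroundTruth` record of everything injected so recovery can be
scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

from mregaval.config import PipelineConfig
from mregaval.io import MixingMatrix, MotionTrace, SpatialMaps, VolumeSeries
from mregaval.physio import ComponentSeries


@dataclass
class SynthParams:
    """Amplitudes and rates of the synthetic recording.

    Defaults emulate a 10-minute (6000-sample) 10 Hz resting-state
    recording: vasomotor drift and respiration of comparable strength,
    a somewhat weaker cardiac oscillation, white noise at half the
    respiratory amplitude, and a dozen brief events clearly above the
    noise floor. Frequency trajectories wander as reflected Gaussian
    random walks (0.1 bpm/sample step SD) inside their grids.
    """

    n_samples: int = 6000
    trend_sd: float = 1.0
    resp_amp: float = 1.0
    cardiac_amp: float = 0.7
    noise_sd: float = 0.5
    n_events: int = 12
    event_amp: float = 3.0
    event_dur_range: tuple[int, int] = (2, 10)
    freq_step_sd_bpm: float = 0.1
    trend_cutoff_hz: float = 0.005
    motion_n_spikes: int = 4
    motion_baseline_frac: float = 0.4
    motion_spike_frac: float = 2.0
    grid_shape: tuple[int, int, int] = (20, 24, 20)
    blob_sigma_vox: float = 2.5
    volume_noise_sd: float = 0.2


@dataclass
class GroundTruth:
    """Everything the generators injected, for exact recovery scoring."""

    event_times: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    event_durations: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    event_amplitudes: np.ndarray = field(default_factory=lambda: np.zeros(0))
    resp_freq_traj: np.ndarray = field(default_factory=lambda: np.zeros(0))
    cardiac_freq_traj: np.ndarray = field(default_factory=lambda: np.zeros(0))
    trend: np.ndarray = field(default_factory=lambda: np.zeros(0))
    motion_spike_times: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))


def _reflected_walk(
    rng: np.random.Generator, n: int, lo: float, hi: float, step_sd: float
) -> np.ndarray:
    """Gaussian random walk reflected at [lo, hi]; starts in the middle half."""
    x = np.empty(n)
    x[0] = rng.uniform(lo + 0.25 * (hi - lo), hi - 0.25 * (hi - lo))
    steps = rng.normal(0.0, step_sd, size=n - 1)
    for i in range(1, n):
        v = x[i - 1] + steps[i - 1]
        # reflect until inside
        while v < lo or v > hi:
            v = 2 * lo - v if v < lo else 2 * hi - v
        x[i] = v
    return x


def _raised_cosine(duration: int) -> np.ndarray:
    """Smooth unimodal bump of unit peak over ``duration`` samples."""
    t = np.arange(duration)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * (t + 0.5) / duration))


def _slow_trend(
    rng: np.random.Generator, n: int, fs: float, cutoff_hz: float, sd: float
) -> np.ndarray:
    """Integrated low-pass random walk with essentially all power < 0.01 Hz."""
    walk = np.cumsum(rng.normal(0.0, 1.0, size=n))
    b, a = sp_signal.butter(4, cutoff_hz, btype="low", fs=fs)
    trend = sp_signal.filtfilt(b, a, walk)
    trend -= trend.mean()
    cur = trend.std()
    if cur > 0:
        trend *= sd / cur
    return trend


def generate_component_series(
    config: PipelineConfig,
    seed: int,
    params: SynthParams | None = None,
) -> tuple[ComponentSeries, GroundTruth]:
    """Generate one synthetic ICA component time course with ground truth.

    series = slow vasomotor trend + respiratory oscillation (frequency a
    reflected random walk inside the respiratory grid) + cardiac
    oscillation (inside the cardiac grid) + white Gaussian noise + brief
    raised-cosine events (durations drawn from ``event_dur_range``,
    amplitude ``event_amp`` >= 2x noise SD).
    """
    p = params or SynthParams()
    rng = np.random.default_rng(seed)
    n, fs = p.n_samples, config.fs_hz
    nyq_bpm = fs / 2.0 * 60.0
    for lo, hi, _ in (config.resp_grid, config.cardiac_grid):
        if hi >= nyq_bpm:
            raise ValueError(f"grid extends past Nyquist ({nyq_bpm} bpm)")
    if n < config.sg_window:
        raise ValueError("duration must be at least sg_window samples")

    trend = _slow_trend(rng, n, fs, p.trend_cutoff_hz, p.trend_sd)

    resp_f = _reflected_walk(
        rng, n, config.resp_grid[0], config.resp_grid[1], p.freq_step_sd_bpm
    )
    card_f = _reflected_walk(
        rng, n, config.cardiac_grid[0], config.cardiac_grid[1], p.freq_step_sd_bpm
    )
    resp_phase = 2.0 * np.pi * np.cumsum(resp_f / 60.0) / fs
    card_phase = 2.0 * np.pi * np.cumsum(card_f / 60.0) / fs
    resp = p.resp_amp * np.sin(resp_phase + rng.uniform(0, 2 * np.pi))
    cardiac = p.cardiac_amp * np.sin(card_phase + rng.uniform(0, 2 * np.pi))

    noise = rng.normal(0.0, p.noise_sd, size=n)

    events = np.zeros(n)
    ev_times, ev_durs, ev_amps = [], [], []
    if p.n_events > 0:
        lo_d, hi_d = p.event_dur_range
        margin = config.pre + hi_d
        # events separated by at least min_dist + max duration so each is
        # individually detectable
        gap = config.min_dist + hi_d
        candidates = np.arange(margin, n - config.post - hi_d)
        chosen: list[int] = []
        order = rng.permutation(candidates)
        for c in order:
            if len(chosen) >= p.n_events:
                break
            if all(abs(c - t) >= gap for t in chosen):
                chosen.append(int(c))
        chosen.sort()
        for c in chosen:
            dur = int(rng.integers(lo_d, hi_d + 1))
            bump = p.event_amp * _raised_cosine(dur)
            events[c : c + dur] += bump
            peak_off = int(np.argmax(bump))
            ev_times.append(c + peak_off)
            ev_durs.append(dur)
            ev_amps.append(p.event_amp)

    values = trend + resp + cardiac + noise + events
    gt = GroundTruth(
        event_times=np.asarray(ev_times, dtype=int),
        event_durations=np.asarray(ev_durs, dtype=int),
        event_amplitudes=np.asarray(ev_amps),
        resp_freq_traj=resp_f,
        cardiac_freq_traj=card_f,
        trend=trend,
    )
    return ComponentSeries(values=values, fs_hz=fs), gt


def generate_motion_trace(
    config: PipelineConfig,
    seed: int,
    n_samples: int | None = None,
    params: SynthParams | None = None,
) -> tuple[MotionTrace, GroundTruth]:
    """Generate realignment parameters: smooth drift plus motion spikes.

    The baseline is low-pass-filtered noise scaled so its per-sample
    speeds stay below ``motion_baseline_frac`` of each threshold; on top,
    ``motion_n_spikes`` step displacements of ``motion_spike_frac`` times
    the threshold are injected at random samples (alternating between
    translational and rotational), each guaranteed to cross a threshold.
    """
    p = params or SynthParams()
    rng = np.random.default_rng(seed)
    n = n_samples if n_samples is not None else p.n_samples
    fs = config.fs_hz

    b, a = sp_signal.butter(2, 0.05, btype="low", fs=fs)

    def _baseline(thresh: float) -> np.ndarray:
        base = sp_signal.filtfilt(b, a, rng.normal(0, 1, size=(n, 3)), axis=0)
        pos = np.cumsum(np.diff(base, axis=0, prepend=base[:1]), axis=0)
        speeds = np.abs(np.diff(pos, axis=0)).sum(axis=1)
        peak = speeds.max() if speeds.size else 0.0
        if peak > 0:
            pos *= p.motion_baseline_frac * thresh / peak
        return pos

    trans = _baseline(config.trans_thresh)
    rots = _baseline(config.rot_thresh)

    spikes: list[int] = []
    if p.motion_n_spikes > 0:
        cand = rng.permutation(np.arange(1, n))
        for c in cand:
            if len(spikes) >= p.motion_n_spikes:
                break
            if all(abs(c - s) > config.pre + config.post for s in spikes):
                spikes.append(int(c))
        spikes.sort()
        for k, s in enumerate(spikes):
            axis = int(rng.integers(0, 3))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            if k % 2 == 0:
                trans[s:, axis] += sign * p.motion_spike_frac * config.trans_thresh
            else:
                rots[s:, axis] += sign * p.motion_spike_frac * config.rot_thresh

    gt = GroundTruth(motion_spike_times=np.asarray(spikes, dtype=int))
    return MotionTrace(rotations=rots, translations=trans), gt


def _blob(shape: tuple[int, int, int], center: np.ndarray, sigma: float) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return np.exp(-d2 / (2.0 * sigma**2))


def generate_volume_series(
    config: PipelineConfig,
    seed: int,
    params: SynthParams | None = None,
    n_components: int = 1,
) -> tuple[VolumeSeries, SpatialMaps, MixingMatrix, GroundTruth]:
    """Generate a small 4D volume series with event-driven blob activity.

    Each component is a Gaussian blob in a small grid. At every
    ground-truth event, signal rises inside the blob and spreads to
    adjacent voxels over the event duration (the blob's effective width
    grows from 70% to 130% of its nominal sigma). The mixing matrix is
    the blob-weighted spatial mean time course; voxelwise white noise is
    added on top.
    """
    p = params or SynthParams()
    rng = np.random.default_rng(seed)
    shape = p.grid_shape
    n = p.n_samples

    centers = []
    zmaps = np.zeros(shape + (n_components,))
    for c in range(n_components):
        center = np.array(
            [rng.uniform(0.3 * s, 0.7 * s) for s in shape]
        )
        if np.any(center < 0) or np.any(center >= np.asarray(shape)):
            raise ValueError("blob center outside grid")
        centers.append(center)
        zmaps[..., c] = 8.0 * _blob(shape, center, p.blob_sigma_vox)

    affine = np.diag([4.0, 4.0, 4.0, 1.0])

    data = np.zeros(shape + (n,))
    _, gt = generate_component_series(config, seed, params=p)
    for c in range(n_components):
        for t_ev, dur, amp in zip(
            gt.event_times, gt.event_durations, gt.event_amplitudes
        ):
            start = t_ev - dur // 2
            bump = _raised_cosine(dur)
            for j in range(dur):
                tt = start + j
                if not (0 <= tt < n):
                    continue
                # spatial spread grows over the event's lifetime
                sigma = p.blob_sigma_vox * (0.7 + 0.6 * j / max(dur - 1, 1))
                data[..., tt] += amp * bump[j] * _blob(shape, centers[c], sigma)
    if p.volume_noise_sd > 0:
        data += rng.normal(0.0, p.volume_noise_sd, size=data.shape)

    weights = zmaps / zmaps.sum(axis=(0, 1, 2), keepdims=True)
    mixing = np.einsum("xyzc,xyzt->tc", weights, data)

    vol = VolumeSeries(data=data, affine=affine, tr_s=1.0 / config.fs_hz)
    maps = SpatialMaps(zmaps=zmaps, affine=affine)
    return vol, maps, MixingMatrix(values=mixing), gt


def write_ground_truth(gt: GroundTruth, path) -> None:
    """Write injected event bookkeeping as a tab-separated sidecar file."""
    import pandas as pd

    pd.DataFrame(
        {
            "event_time": gt.event_times,
            "event_duration": gt.event_durations,
            "event_amplitude": gt.event_amplitudes,
        }
    ).to_csv(path, sep="\t", index=False)
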