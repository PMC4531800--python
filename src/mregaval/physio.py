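"""Reference-free cardio-respiratory noise removal and vasomotor detrending.

Ultrafast (10 Hz) fMRI critically samples cardiac (~1 Hz) and respiratory
(~0.2-0.4 Hz) oscillations, so both can be estimated from the data itself,
without external reference recordings. The approach here is state-space:

1. An interacting-multiple-models (IMM) filter runs a bank of
   linear-Gaussian oscillator models, one per candidate frequency on a
   grid, and mixes them with a sticky mode-transition matrix; the
   probability-weighted grid mean gives the instantaneous frequency
   trajectory of the physiological oscillation
   (:func:`estimate_frequency_trajectory`).
2. The trajectory's standard deviation (the "Dscore") diagnoses tracking
   quality: a tracker that races to a grid boundary and sticks there
   produces a low-variance trajectory and unreliable noise removal
   (:func:`dscore`).
3. A joint state-space model - slow local-level activation state plus
   stochastic resonators at each band's instantaneous frequency and its
   harmonics - is run forward (Kalman filter) and backward (RTS smoother)
   to split the series into cleaned / respiratory / cardiac / residual
   components (:func:`remove_periodic_noise`).
4. Slow vasomotor drift (< 0.01 Hz) is estimated separately with a
   Savitzky-Golay polynomial smooth (order 2, window 513 samples at
   10 Hz) and subtracted (:func:`estimate_vasomotor`,
   :func:`clean_component`).

All operations are deterministic for fixed inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

logger = logging.getLogger(__name__)


@dataclass
class ComponentSeries:
    """One ICA component's time course.

    ``values`` in arbitrary units, ``fs_hz`` the sampling rate.
    """

    values: np.ndarray
    fs_hz: float = 10.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("component series must be finite")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class FrequencyGrid:
    """Candidate-frequency search grid in beats/breaths per minute."""

    fmin_bpm: float
    fmax_bpm: float
    step_bpm: float

    def __post_init__(self) -> None:
        if not self.fmin_bpm < self.fmax_bpm:
            raise ValueError("fmin_bpm must be below fmax_bpm")
        if self.step_bpm <= 0:
            raise ValueError("step_bpm must be positive")
        span = (self.fmax_bpm - self.fmin_bpm) / self.step_bpm
        if abs(span - round(span)) > 1e-6:
            raise ValueError("grid span must be an integral number of steps")

    @property
    def freqs_bpm(self) -> np.ndarray:
        n = int(round((self.fmax_bpm - self.fmin_bpm) / self.step_bpm)) + 1
        return self.fmin_bpm + self.step_bpm * np.arange(n)

    @property
    def size(self) -> int:
        return self.freqs_bpm.size


@dataclass
class FrequencyTrajectory:
    """Per-sample frequency estimate plus the full mode-probability history."""

    freq_bpm: np.ndarray
    mode_probs: np.ndarray
    grid: FrequencyGrid

    def __post_init__(self) -> None:
        self.freq_bpm = np.asarray(self.freq_bpm, dtype=float)
        self.mode_probs = np.asarray(self.mode_probs, dtype=float)
        if self.mode_probs.shape != (self.freq_bpm.size, self.grid.size):
            raise ValueError("mode_probs must be T x grid-size")

    def __len__(self) -> int:
        return self.freq_bpm.size


@dataclass
class NoiseDecomposition:
    """Additive split of a component series.

    ``cleaned`` is the activation estimate (smoothed local level), ``resp``
    and ``cardiac`` the periodic physiological components, and ``residual``
    the white-measurement-noise remainder. The four always sum to the
    input exactly, because the residual is defined as the remainder.
    """

    cleaned: np.ndarray
    resp: np.ndarray
    cardiac: np.ndarray
    residual: np.ndarray

    def total(self) -> np.ndarray:
        return self.cleaned + self.resp + self.cardiac + self.residual


@dataclass
class DscoreReport:
    """Frequency-tracking quality score: SD of the trajectory, in bpm."""

    score: float
    passed: bool
    limit: float


@dataclass
class CleanSeries:
    """Noise-removed, detrended component series (close to zero mean)."""

    values: np.ndarray
    fs_hz: float = 10.0
    threshold: float | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("clean series must be finite")

    def __len__(self) -> int:
        return self.values.size


def _resonator_blocks(freq_hz: np.ndarray, fs_hz: float, harmonics: int):
    """Yield harmonic multipliers whose frequency stays below Nyquist."""
    nyq = fs_hz / 2.0
    fmax = float(np.max(freq_hz))
    kept = [h for h in range(1, harmonics + 1) if h * fmax < nyq]
    if len(kept) < harmonics:
        logger.info(
            "dropping harmonics above Nyquist: keeping %d of %d", len(kept), harmonics
        )
    return kept


def _rotation(theta: np.ndarray) -> np.ndarray:
    """2x2 rotation blocks for an array of angles; shape (..., 2, 2)."""
    c, s = np.cos(theta), np.sin(theta)
    out = np.empty(theta.shape + (2, 2))
    out[..., 0, 0] = c
    out[..., 0, 1] = s
    out[..., 1, 0] = -s
    out[..., 1, 1] = c
    return out


def estimate_frequency_trajectory(
    series: ComponentSeries,
    grid: FrequencyGrid,
    *,
    harmonics: int = 1,
    stay_prob: float = 0.8,
    level_q_frac: float = 1e-4,
    res_q_frac: float = 1e-3,
    meas_r_frac: float = 0.3,
    estimator: str = "mean",
    smooth_modes: bool = True,
) -> FrequencyTrajectory:
    """Track the instantaneous frequency of a physiological oscillation.

    Runs a bank of linear-Gaussian models, one per grid frequency. Each
    model's state is a slow local level plus ``harmonics`` stochastic
    resonator pairs rotating at the candidate frequency; the measurement
    is level + sum of resonator cosine components + white noise. Mode
    probabilities evolve under a sticky tridiagonal transition matrix
    (``stay_prob`` self-transition, the remaining mass split between the
    two adjacent grid modes) and are updated with each model's one-step
    prediction likelihood.

    Parameters
    ----------
    harmonics:
        Resonator harmonics per candidate model (harmonics above Nyquist
        are dropped).
    level_q_frac, res_q_frac, meas_r_frac:
        Process/measurement noise variances as fractions of the series
        variance.
    estimator:
        ``"mean"`` (default) returns the probability-weighted grid mean;
        ``"argmax"`` the most probable grid frequency.
    smooth_modes:
        When True (default), the filtered mode probabilities are refined
        with a backward pass over the mode Markov chain (fixed-interval
        forward-backward smoothing), which removes the causal tracking
        lag. Set False for the purely filtered trajectory.

    Returns
    -------
    FrequencyTrajectory
        Per-sample frequency (bpm) and the T x G mode-probability matrix.
    """
    y = series.values
    T = y.size
    if T <= 10:
        raise ValueError("series too short for frequency tracking (need T > 10)")
    fs = series.fs_hz
    freqs_bpm = grid.freqs_bpm
    freqs_hz = freqs_bpm / 60.0
    if np.max(freqs_hz) >= fs / 2.0:
        raise ValueError("grid maximum must be below Nyquist")
    G = freqs_bpm.size
    if G == 1:
        logger.warning("frequency grid has a single mode; trajectory is constant")
        probs = np.ones((T, 1))
        return FrequencyTrajectory(
            freq_bpm=np.full(T, freqs_bpm[0]), mode_probs=probs, grid=grid
        )

    kept_h = _resonator_blocks(freqs_hz, fs, harmonics)
    if not kept_h:
        raise ValueError("all harmonics above Nyquist; lower the grid or harmonics")
    n = 1 + 2 * len(kept_h)

    var = float(np.var(y))
    if var == 0.0:
        var = 1.0
    r = meas_r_frac * var + 1e-12 * var
    q_level = level_q_frac * var
    q_res = res_q_frac * var

    # Per-mode transition matrices: block-diag(1, rotations).
    A = np.zeros((G, n, n))
    A[:, 0, 0] = 1.0
    for bi, h in enumerate(kept_h):
        theta = 2.0 * np.pi * freqs_hz * h / fs
        A[:, 1 + 2 * bi : 3 + 2 * bi, 1 + 2 * bi : 3 + 2 * bi] = _rotation(theta)
    Q = np.zeros((n, n))
    Q[0, 0] = q_level
    for bi in range(len(kept_h)):
        Q[1 + 2 * bi, 1 + 2 * bi] = q_res
        Q[2 + 2 * bi, 2 + 2 * bi] = q_res
    Hvec = np.zeros(n)
    Hvec[0] = 1.0
    Hvec[1::2] = 1.0  # cosine component of each resonator pair

    # Sticky tridiagonal mode-transition matrix (rows = from, cols = to).
    Pi = np.zeros((G, G))
    off = (1.0 - stay_prob) / 2.0
    for i in range(G):
        Pi[i, i] = stay_prob
        if i > 0:
            Pi[i, i - 1] = off
        else:
            Pi[i, i] += off
        if i < G - 1:
            Pi[i, i + 1] = off
        else:
            Pi[i, i] += off

    # Initial conditions: uniform mode probabilities, diffuse states.
    mu = np.full(G, 1.0 / G)
    x = np.zeros((G, n))
    x[:, 0] = y[0]
    P = np.tile(np.eye(n) * var, (G, 1, 1))

    freq = np.empty(T)
    mode_probs = np.empty((T, G))
    logliks = np.empty((T, G))

    for t in range(T):
        # --- IMM mixing ---
        c = mu @ Pi  # predicted mode probabilities
        c = np.maximum(c, 1e-300)
        W = Pi * mu[:, None] / c[None, :]  # W[i, j] = P(mode i | next mode j)
        x0 = W.T @ x
        # Spread term via second moments: sum_i W_ij x_i x_i^T - x0_j x0_j^T
        xx = np.einsum("in,im->inm", x, x)
        P0 = (
            np.einsum("ij,inm->jnm", W, P + xx)
            - np.einsum("jn,jm->jnm", x0, x0)
        )
        # --- per-mode predict ---
        x_pred = np.einsum("gij,gj->gi", A, x0)
        P_pred = np.einsum("gij,gjk,glk->gil", A, P0, A) + Q
        # --- per-mode update ---
        yhat = x_pred @ Hvec
        Ph = P_pred @ Hvec
        S = Ph @ Hvec if Ph.ndim == 1 else np.einsum("gn,n->g", Ph, Hvec)
        S = S + r
        nu = y[t] - yhat
        K = Ph / S[:, None]
        x = x_pred + K * nu[:, None]
        P = P_pred - np.einsum("gn,gm->gnm", K, Ph)
        # symmetrize for numerical hygiene
        P = 0.5 * (P + np.transpose(P, (0, 2, 1)))
        # --- mode-probability update (log domain) ---
        loglik = -0.5 * (np.log(2.0 * np.pi * S) + nu * nu / S)
        logliks[t] = loglik
        logmu = np.log(c) + loglik
        logmu -= logmu.max()
        mu = np.exp(logmu)
        mu /= mu.sum()
        mode_probs[t] = mu

    if smooth_modes:
        # Backward pass over the mode chain (treating the per-mode
        # prediction likelihoods as emissions): gamma_t ~ alpha_t * beta_t.
        lik = np.exp(logliks - logliks.max(axis=1, keepdims=True))
        beta = np.ones(G)
        for t in range(T - 2, -1, -1):
            b = Pi @ (lik[t + 1] * beta)
            s = b.sum()
            beta = b / s if s > 0 else np.full(G, 1.0 / G)
            g = mode_probs[t] * beta
            gs = g.sum()
            if gs > 0:
                mode_probs[t] = g / gs

    for t in range(T):
        if estimator == "argmax":
            freq[t] = freqs_bpm[int(np.argmax(mode_probs[t]))]
        else:
            freq[t] = float(mode_probs[t] @ freqs_bpm)

    return FrequencyTrajectory(freq_bpm=freq, mode_probs=mode_probs, grid=grid)


def dscore(traj: FrequencyTrajectory, limit: float = 1.0) -> DscoreReport:
    """Frequency-tracking quality score.

    The score is the sample standard deviation (n-1 denominator) of the
    frequency trajectory, in bpm. A healthy tracker follows the slow
    physiological wander and produces a score above ``limit`` (default
    1 bpm); a tracker stuck at a grid boundary produces a near-constant
    trajectory and fails.
    """
    if len(traj) < 2:
        raise ValueError("need at least 2 samples to compute a Dscore")
    score = float(np.std(traj.freq_bpm, ddof=1))
    return DscoreReport(score=score, passed=score > limit, limit=limit)


def remove_periodic_noise(
    series: ComponentSeries,
    resp_traj: FrequencyTrajectory | None,
    cardiac_traj: FrequencyTrajectory | None,
    harmonics: tuple[int, int] = (3, 2),
    *,
    level_q_frac: float = 0.02,
    res_q_frac: float = 1e-3,
    meas_r_frac: float = 0.05,
) -> NoiseDecomposition:
    """Split a series into activation, periodic noise, and white noise.

    Builds one joint time-varying state-space model: a slow local-level
    activation state plus stochastic resonator pairs at the respiratory
    and cardiac instantaneous frequencies and their harmonics (harmonics
    above Nyquist are dropped). A forward Kalman filter followed by a
    Rauch-Tung-Striebel backward smoother yields fixed-interval state
    estimates; the respiratory/cardiac components are the smoothed
    resonator outputs, the cleaned signal is the smoothed local level,
    and the residual is the exact remainder (the white-noise estimate),
    so the decomposition conserves the input to machine precision.

    Either trajectory may be ``None`` to skip that band.
    """
    y = series.values
    T = y.size
    fs = series.fs_hz
    bands: list[tuple[np.ndarray, list[int]]] = []
    for traj, hmax in zip((resp_traj, cardiac_traj), harmonics):
        if traj is None:
            bands.append((np.zeros(0), []))
            continue
        if len(traj) != T:
            raise ValueError("trajectory length must match series length")
        f_hz = traj.freq_bpm / 60.0
        kept = _resonator_blocks(f_hz, fs, hmax)
        bands.append((f_hz, kept))

    n_res = sum(len(kept) for _, kept in bands)
    n = 1 + 2 * n_res
    var = float(np.var(y))
    if var == 0.0:
        # Zero (or constant) input: every component is trivially zero/constant.
        lvl = np.full(T, y[0] if T else 0.0)
        z = np.zeros(T)
        return NoiseDecomposition(cleaned=lvl, resp=z, cardiac=z.copy(),
                                  residual=y - lvl)
    r = meas_r_frac * var
    Q = np.zeros((n, n))
    Q[0, 0] = level_q_frac * var
    for k in range(n_res):
        Q[1 + 2 * k, 1 + 2 * k] = res_q_frac * var
        Q[2 + 2 * k, 2 + 2 * k] = res_q_frac * var
    Hvec = np.zeros(n)
    Hvec[0] = 1.0
    Hvec[1::2] = 1.0

    # Precompute per-sample rotation angles for every resonator pair.
    thetas = np.zeros((T, n_res))
    col = 0
    band_slices: list[slice] = []
    for f_hz, kept in bands:
        start = col
        for h in kept:
            thetas[:, col] = 2.0 * np.pi * f_hz * h / fs
            col += 1
        band_slices.append(slice(start, col))

    # Forward Kalman filter.
    x_pred = np.zeros((T, n))
    P_pred = np.zeros((T, n, n))
    x_filt = np.zeros((T, n))
    P_filt = np.zeros((T, n, n))
    A_all = np.zeros((T, n, n))

    x = np.zeros(n)
    x[0] = y[0]
    P = np.eye(n) * var
    eye = np.eye(n)
    for t in range(T):
        A = np.zeros((n, n))
        A[0, 0] = 1.0
        rot = _rotation(thetas[t])
        for k in range(n_res):
            A[1 + 2 * k : 3 + 2 * k, 1 + 2 * k : 3 + 2 * k] = rot[k]
        A_all[t] = A
        if t == 0:
            xp, Pp = x, P
        else:
            xp = A @ x
            Pp = A @ P @ A.T + Q
        x_pred[t], P_pred[t] = xp, Pp
        Ph = Pp @ Hvec
        S = float(Ph @ Hvec) + r
        if not np.isfinite(S) or S <= 0:
            raise FloatingPointError(
                f"singular innovation covariance at sample {t}"
            )
        K = Ph / S
        nu = y[t] - float(xp @ Hvec)
        x = xp + K * nu
        P = Pp - np.outer(K, Ph)
        P = 0.5 * (P + P.T)
        x_filt[t], P_filt[t] = x, P

    # RTS backward smoother.
    x_sm = np.zeros_like(x_filt)
    x_sm[-1] = x_filt[-1]
    P_sm = P_filt[-1]
    for t in range(T - 2, -1, -1):
        Pp = P_pred[t + 1]
        Gmat = np.linalg.solve(Pp.T, (P_filt[t] @ A_all[t + 1].T).T).T
        x_sm[t] = x_filt[t] + Gmat @ (x_sm[t + 1] - x_pred[t + 1])
        P_sm = P_filt[t] + Gmat @ (P_sm - Pp) @ Gmat.T

    cleaned = x_sm[:, 0]
    comp = np.zeros((T, 2))
    for bi, sl in enumerate(band_slices):
        for k in range(sl.start, sl.stop):
            comp[:, bi] += x_sm[:, 1 + 2 * k]
    resp_c, cardiac_c = comp[:, 0], comp[:, 1]
    residual = y - cleaned - resp_c - cardiac_c
    return NoiseDecomposition(
        cleaned=cleaned, resp=resp_c, cardiac=cardiac_c, residual=residual
    )


def estimate_vasomotor(
    series: ComponentSeries | np.ndarray,
    window: int = 513,
    order: int = 2,
) -> np.ndarray:
    """Estimate the slow vasomotor trend with a Savitzky-Golay smooth.

    Least-squares local polynomial fit of the given order over a sliding
    window (defaults: order 2, 513 samples = 51.3 s at 10 Hz). Interior
    samples use the standard symmetric window; the first and last
    half-window samples are fitted on the truncated asymmetric window
    (no reflection padding), so no data is fabricated at the edges.
    """
    y = series.values if isinstance(series, ComponentSeries) else np.asarray(
        series, dtype=float
    )
    T = y.size
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if T < window:
        raise ValueError(
            f"series length {T} shorter than window {window}; "
            "shorten the window or provide a longer series"
        )
    out = sp_signal.savgol_filter(y, window, order, mode="interp")
    half = window // 2
    # Asymmetric truncated-window fits at the edges.
    for i in range(half):
        sl = y[: i + half + 1]
        t = np.arange(sl.size) - i
        coef = np.polynomial.polynomial.polyfit(t, sl, order)
        out[i] = coef[0]
        j = T - 1 - i
        sr = y[j - half :]
        t = np.arange(sr.size) - (sr.size - 1 - i)
        coef = np.polynomial.polynomial.polyfit(t, sr, order)
        out[j] = coef[0]
    return out


def clean_component(
    series: ComponentSeries,
    decomposition: NoiseDecomposition,
    trend: np.ndarray,
) -> CleanSeries:
    """Subtract the vasomotor trend from the noise-removed activation signal.

    The result is the "clean" series peak detection operates on; its mean
    is close to (but not forced to) zero.
    """
    trend = np.asarray(trend, dtype=float)
    if decomposition.cleaned.size != trend.size:
        raise ValueError("decomposition and trend lengths differ")
    if len(series) != trend.size:
        raise ValueError("series and trend lengths differ")
    return CleanSeries(values=decomposition.cleaned - trend, fs_hz=series.fs_hz)


@dataclass
class PowerSpectrum:
    """One-sided power spectral density with band-averaging support."""

    freqs_hz: np.ndarray
    power: np.ndarray

    def band_mean(self, f_lo: float, f_hi: float) -> float:
        """Mean power inside [f_lo, f_hi]."""
        sel = (self.freqs_hz >= f_lo) & (self.freqs_hz <= f_hi)
        if not np.any(sel):
            raise ValueError(f"no spectral bins inside [{f_lo}, {f_hi}] Hz")
        return float(np.mean(self.power[sel]))


def estimate_spectrum(
    series: ComponentSeries | np.ndarray,
    fs_hz: float | None = None,
    nperseg: int | None = None,
) -> PowerSpectrum:
    """Welch power spectral density of a standardized series.

    The series is normalized to zero mean and unit variance first, so
    spectra of different components are directly comparable and the PSD
    integrates to approximately 1.
    """
    if isinstance(series, ComponentSeries):
        y, fs = series.values, series.fs_hz
    else:
        y = np.asarray(series, dtype=float)
        fs = fs_hz if fs_hz is not None else 10.0
    T = y.size
    if T < 64:
        raise ValueError("need at least 64 samples for spectrum estimation")
    sd = np.std(y)
    if sd == 0:
        raise ValueError("constant input has no spectrum (zero variance)")
    z = (y - np.mean(y)) / sd
    if nperseg is None:
        nperseg = min(T, 4096)
    freqs, power = sp_signal.welch(z, fs=fs, nperseg=nperseg, detrend="constant")
    return PowerSpectrum(freqs_hz=freqs, power=power)


def band_power_fraction(psd: PowerSpectrum, f_cut_hz: float) -> float:
    """Fraction of total spectral power below ``f_cut_hz``."""
    if not (psd.freqs_hz[0] <= f_cut_hz <= psd.freqs_hz[-1]):
        raise ValueError("f_cut_hz outside the PSD frequency range")
    total = float(np.sum(psd.power))
    if total == 0:
        return 0.0
    below = float(np.sum(psd.power[psd.freqs_hz < f_cut_hz]))
    return below / total
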