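# Methods

This note documents the models, the numerical choices, and what the
synthetic validation does and does not establish.

## Signal model

Each ICA component time course sampled at `fs = 10 Hz` is treated as

    y(t) = a(t) + v(t) + r(t) + c(t) + e(t)

with `a` the activation signal of interest (containing brief,
avalanche-type events), `v` slow vasomotor drift (< 0.01 Hz), `r` and
`c` quasi-periodic respiratory and cardiac oscillations with slowly
drifting fundamental frequencies, and `e` white measurement noise.

## Frequency tracking (IMM)

The respiratory and cardiac fundamentals are tracked on discrete grids
(8–24 bpm in 0.2 bpm steps; 45–65 bpm in 0.4 bpm steps). Each grid
frequency defines a linear-Gaussian model: a random-walk local level
plus stochastic resonator pairs rotating at the candidate frequency
(one harmonic by default for tracking), observed as
`level + Σ cosine-components + noise`. The bank is run as an
interacting-multiple-models filter: standard per-mode mixing under a
sticky tridiagonal transition matrix, mode weights updated with each
model's one-step prediction likelihood. The reported trajectory is the
probability-weighted grid mean (argmax is available).

Numerical choices, with units and defaults:

- **Mode stickiness** `stay_prob = 0.8`. Physiological frequencies that
  wander with ~0.1 bpm/sample step SD cross a 0.2 bpm grid step about
  once every 4 samples; a self-transition probability much closer to 1
  forces the tracker to lag. The remaining mass is split between the
  two adjacent modes (reflected at the grid edges).
- **Noise fractions** (relative to the series variance):
  `level_q_frac = 1e-4`, `res_q_frac = 1e-3`, `meas_r_frac = 0.3`.
  Stiff resonators sharpen frequency discrimination; the relatively
  large measurement variance keeps per-mode likelihoods well scaled for
  signals where the tracked band is a minority of total power.
- **Mode smoothing.** After the forward pass, mode probabilities are
  refined by a backward recursion over the mode Markov chain (standard
  fixed-interval forward–backward smoothing, treating the per-mode
  prediction likelihoods as emissions). This removes the causal
  tracking lag and roughly halves trajectory RMSE; `smooth_modes=False`
  restores the purely filtered estimate. The operation remains
  deterministic.
- Likelihood updates run in the log domain; probability rows are
  renormalized every step and sum to 1 within 1e-9.

The **Dscore** is the sample SD (n−1) of the trajectory in bpm. Grids
and steps are specified in bpm, so the published pass limit of "one"
reads as 1 bpm; in Hz the limit would be unreachable (the whole
respiratory grid spans 0.27 Hz). A tracker pulled quickly to a grid
boundary by an out-of-band or phase-shifting signal produces a
near-constant trajectory and a score far below 1 (measured ≈ 0.01 for
a tone outside the grid), while healthy wander scores well above 1, so
the limit separates the two regimes by orders of magnitude.

## Noise removal (Kalman/RTS)

Given both trajectories, one joint time-varying state-space model is
built — a random-walk activation level plus resonator pairs at the
respiratory instantaneous frequency (3 harmonics) and the cardiac one
(2 harmonics; any harmonic at or above Nyquist is dropped) — and solved
with a forward Kalman filter plus RTS backward smoother. Respiratory
and cardiac estimates are the summed smoothed resonator cosine
components; the cleaned signal is the smoothed level; the residual is
defined as the exact remainder, so
`cleaned + resp + cardiac + residual == y` to machine precision by
construction. Estimating both bands in a single joint pass avoids any
dependence on processing order.

The split of non-periodic energy between `cleaned` and `residual` is
governed by `level_q_frac = 0.02` and `meas_r_frac = 0.05`: this level
bandwidth (~1 Hz) follows 0.2–1 s activity bumps while relegating most
white noise to the residual. Smaller level noise yields a smoother
cleaned signal but swallows the shortest events; the values are
deliberately biased toward retaining events, since the downstream
threshold (1.5 × SD) handles the extra background. Covariances are
symmetrized each step; a non-finite or non-positive innovation variance
raises an error naming the sample.

## Vasomotor trend

Savitzky–Golay least-squares polynomial smoothing, order 2, window 513
samples (51.3 s at 10 Hz). Interior samples use the standard symmetric
window; the first and last 256 samples are fitted on the truncated
asymmetric window (no reflection padding — nothing is fabricated beyond
the series edge). The filter is linear and reproduces polynomials up to
order 2 exactly. On the default synthetic conditions at least ~90% (and
typically > 99%) of the trend estimate's spectral power lies below
0.01 Hz, comfortably above the 80% characteristic expected of a
vasomotor estimate. The clean series is
`cleaned (state-space) − trend`; its mean is close to, but not forced
to, zero.

## Motion screening

Speeds are first differences of the realignment parameters, summed as
absolute values over the three axes (sample 0 defined as 0). A sample
is flagged when translational speed exceeds 0.2 mm/sample or rotational
speed exceeds 1e-3 rad/sample, with strict inequality ("exceeds").
A sample `t` is excluded iff some flagged sample falls inside `t`'s
crop window `[t − pre, t + post]` — equivalently the reflected
dilation `[f − post, f + pre]` around each flag `f`. This is the unique
exclusion rule that exactly guarantees motion-free crops; the literal
symmetric neighborhood is available via `symmetric_exclusion`. Samples
whose full crop window would exit the series are excluded as well
(they could never be cropped).

## Peak detection and avalanche statistics

The threshold is 1.5 × sample SD of the full clean series, including
samples later excluded for motion (Fig-style overviews show peaks
detected everywhere, then motion-filtered; a config switch restricts
the SD to non-excluded samples). Candidates are strict local maxima
(plateaus contribute their leftmost sample; series endpoints are never
candidates). Selection is greedy in descending value order with
candidates closer than 50 samples to an accepted peak discarded; equal
values tie-break toward the earlier index. Lifetime is the maximal
contiguous run of values ≥ threshold around the peak ("no value falls
under" the threshold, read inclusively), clipped at the series
boundaries; size is Σ|clean| over the run, hence always ≥
lifetime × threshold.

Size/lifetime samples are summarized by logarithmically binned
densities (12 bins between min and max) with two exponents: a
least-squares slope on the positive log-log bins, and the continuous
maximum-likelihood estimate with `xmin` fixed at the sample minimum,
`α̂ = 1 + n / Σ ln(xᵢ/xmin)`. The MLE is scale-invariant and preferred;
the LS slope documents the straight line a reader would draw through
the histogram. No formal power-law versus lognormal comparison is
performed.

## Clips and rendering

Volume series are standardized per voxel over the full record
(zero-variance voxels → 0); a global-statistics mode exists for
comparison. Clips span `[peak − 50, peak + 100]` (151 frames). Subject
means are framewise averages over that subject's clips; the group mean
weights each subject equally regardless of peak count. Slices pass
through the component map's maximum-z voxel (ties → lexicographically
smallest index; grid axes stand in for anatomical planes on synthetic
data). Rendering: out-of-brain voxels zeroed, Gaussian smoothing
SD 1.2 px, |v| ≤ cut shows anatomy, above it red (positive) or blue
(negative) at maximum with green rising linearly from cut (1.7) to
saturation (3.5) — red→yellow and blue→cyan ramps; component maps use
cut 3 / saturation 7 in z-units. The color map is odd-symmetric
(negation swaps the red and blue channels exactly). Videos default to
10 fps (real time for 10 Hz data); if no MP4 encoder is present the
export falls back to a PNG image sequence. All rendering is
deterministic.

## Synthetic study conditions

The generator defaults emulate one 10-minute resting-state recording
after the 180-sample trim: 6000 samples at 10 Hz; vasomotor drift built
as a low-pass-filtered (0.005 Hz, 4th-order Butterworth, zero-phase)
random walk scaled to SD 1.0; respiratory oscillation amplitude 1.0 and
cardiac 0.7 with fundamentals wandering as reflected Gaussian random
walks inside their grids; white noise SD 0.5; 12 raised-cosine events
of 2–10 samples and amplitude 3.0, separated by at least the peak
search window; motion with sub-threshold smooth baseline (40% of each
threshold) plus 4 step displacements at 2× threshold. The frequency
walk step is 0.1 bpm/sample: this makes essentially every 6000-sample
trajectory's SD exceed 1 bpm, the regime real recordings are observed
to occupy almost always, so the Dscore limit separates healthy tracking
from boundary-stuck tracking rather than penalizing calm-but-correct
trajectories.

What the generator does **not** model: hemodynamic response shapes,
1/f-structured physiological baselines, spatially correlated noise,
scanner drift nonstationarity, or anatomy-realistic geometry. Passing
tests therefore demonstrate correct mechanics and recoverability under
the stated signal model, not performance on arbitrary real recordings.

Validation fixtures and problem sizes: frequency-recovery runs use a
wandering oscillation plus white noise at SNR 3 (amplitude/noise-SD),
6000 samples, 10 seeds, scored against 2 grid steps RMSE. The
end-to-end event-recovery fixture raises event amplitude to 6.0 over
noise SD 0.2 — events ≥ 3× (in practice ≈ 30×) the clean-series SD —
the regime the recovery contract addresses; with the self-scaling
1.5 × SD threshold, false-positive control requires events to carry a
visible share of the clean-series variance, which weak-event regimes
cannot provide regardless of filtering. The CLI demo uses 1500-sample
recordings and a 20×24×20 voxel grid so a full simulate→render cycle
completes in seconds.

## Known limitations

- The IMM tracker assumes a single dominant oscillation per band; two
  comparable tones inside one grid produce an averaged trajectory.
- The linear state-space split cannot fully separate broadband event
  energy from white noise; very short (≤ 0.3 s) low-amplitude events
  lose most of their amplitude in the cleaned signal.
- Dscore is a variance heuristic: a pathological tracker oscillating
  between boundaries would pass despite being wrong.
- Power-law exponent estimation fixes `xmin` at the sample minimum; no
  tail-onset selection or alternative-model comparison is attempted.
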