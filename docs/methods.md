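# Methods

This note documents the models, parameter choices and numerical conventions
behind cvrkit, and what the synthetic phantoms do and do not establish about
behaviour on real data.

## Signal model

The BOLD response to a CO2 challenge is modelled per voxel as a lagged
linear response to end-tidal CO2:

    Y(t) = β0 + β1 · etCO2(t − s),        CVR = 100 · β1 / (β0 + β1 · b)

with `b` the resting etCO2 baseline in mmHg. The denominator is the
predicted BOLD level at baseline CO2, so CVR is the percent signal change
per mmHg around the resting operating point. The identity is exact for data
generated as `Y = β0'·(1 + (CVR/100)·(etCO2(t−δ) − b))`, which is how the
phantom generator writes its voxels; this generator/model consistency is
asserted numerically in the tests. No hemodynamic response convolution or
dispersion model is applied: over the ~10-s timescales of a CO2 block
design, a pure delay is the standard first-order description.

Assumptions: the response is linear in etCO2 over the stimulated range
(~38–45 mmHg), time-invariant within a run, and adequately captured by a
single per-voxel lag. Negative β1 (pathological "steal" physiology) is
allowed throughout: the optimal shift maximizes |r|, and the sign of β1 is
preserved into the CVR map.

## etCO2 extraction

A capnograph samples mouth CO2 continuously; end-tidal CO2 is the upper
envelope of the breath-by-breath oscillation. The envelope is computed by:

1. expiratory-peak detection — local maxima at least 1.5 s apart
   (`min_breath_period`, i.e. at most 40 breaths/min) with prominence
   ≥ 25% of the trace inter-quartile range, rejecting cardiogenic ripple;
2. linear interpolation through the peaks on the trace's native grid,
   edge-held at the boundaries;
3. smoothing with a quadratic Savitzky–Golay filter of width
   `smoothing_window` (default 10 s).

The kernel choice matters more than it first appears: the envelope *is* the
GLM regressor, and a plain moving average of the same width attenuates the
slow block waveform by 1–2%, which propagates multiplicatively into every
CVR value. The Savitzky–Golay kernel preserves locally quadratic structure,
so the block plateaus and ramps pass essentially undistorted while
breath-to-breath jitter is still averaged out. With the default window the
measured end-to-end noiseless CVR bias is ~0.5%; a boxcar of the same width
measured ~2.3%.

The baseline is the mean of the lowest 10% (`baseline_fraction`) of
envelope samples — robust to designs where hypercapnia occupies most of the
run, and exact when the normocapnic plateau occupies at least 10% of it.
Unit conversion from %CO2 uses a dry barometric pressure of 760 mmHg
(configurable); no water-vapour correction is applied.

## Delay estimation

Shifted regressors are built in continuous time on the envelope's native
grid, `x_s(t_i) = etCO2(t_i − s)`, with the baseline value substituted
wherever `t_i − s` falls outside the recording — so a short recording pads
the regressor instead of forcing the BOLD series to be trimmed. Frame `i`
is taken to occur at `i·TR`; slice-timing alignment is assumed handled
upstream.

The global delay is the grid shift maximizing the Pearson correlation with
the whole-brain mean of the denoised data (ties toward the smallest
absolute shift). The voxelwise search then reuses the same grid centred on
the global delay, and reported delays are referenced so the global signal
maps to 0 s; positive delay means the voxel responds later than the global
signal. For a single regressor plus intercept, maximizing |r| and
minimizing RSS select the same shift (asserted on random fixtures); ties go
to the smallest referenced delay, then the smaller shift — deterministic by
construction. The default grid (±30 s, 0.5-s step) covers sampling-line
lags (~10 s in a typical setup) plus physiological arrival-time spreads at
sub-TR resolution; both numbers are configurable.

Degenerate cases: a constant global signal raises an error; a constant
voxel gets delay 0, β1 = 0 and is counted in the log; a fully padded
(information-free) regressor is skipped in the search.

## Noise-label refinement and non-aggressive denoising

Upstream ICA-AROMA-style classifiers treat physiological fluctuations as
noise, which is wrong for CVR — so each upstream noise component is
correlated with the etCO2 regressor at its best shift over the search grid
(the global delay is unknown at this stage, hence max-|r| over shifts), and
rescued when |r| ≥ 0.6. The threshold is the conventional boundary of a
moderate correlation and is configurable; the absolute value is used so
anti-correlated CO2 components are rescued too. Denoising then fits the
full mixing matrix plus intercept per voxel by OLS and subtracts only the
remaining noise columns' fitted contribution, preserving variance shared
with signal components. A rank-deficient mixing matrix is an error naming
the collinear columns; the intercept is never treated as noise.

## Synthetic phantoms

`cvrkit.synthetic` generates the full input set with known truth. Defaults
describe a realistic CO2-inhalation protocol: 180 frames at TR 2 s, etCO2
blocks of 60 s alternating 38 → 45 mmHg, breathing at 0.25 Hz sampled at
10 Hz with inspiratory dips to 2 mmHg, a 10-s global acquisition lag
matching a typical gas sampling line, voxel tSNR 50, and per-voxel baseline
intensities in [800, 1200]. Block transitions are smoothed with a Gaussian
ramp (σ = 5 s) because alveolar CO2 follows the inhaled step with a lung
washout ramp, not instantaneously.

Timing convention: the BOLD response is generated as
`etCO2_design(t − g − δ_v)` on the recording clock, so the global lag `g`
plus the local delay `δ_v` is exactly the shift the analysis should find —
a positive recovered shift means the BOLD lags the recorded trace.

Two deliberate design points:

* the mixing matrix's first component is the (globally shifted) etCO2
  timecourse *mislabelled as noise*, exercising the rescue logic;
* confound timecourses (drift, spikes, white noise) are orthogonalized
  against the intercept and every CO2 regressor present in the phantom, so
  non-aggressive denoising removes exactly the injected confound and the
  noiseless phantom is an exact fixed point of the analysis. Without this,
  chance correlation between confounds and shifted envelopes leaks up to
  ~1% into noiseless CVR, which would mask genuine regressions in the
  recovery tests.

What the phantoms do **not** emulate: anatomy and partial-volume structure,
EPI distortion and motion, autocorrelated (AR) noise, low-frequency drifts
*inside* signal voxels, and HRF dispersion. Passing recovery tests
therefore demonstrates correctness of the estimator chain under the stated
model, not robustness to every property of real data.

## Measured recovery and known limits

Problem sizes were chosen so the whole suite runs in seconds: recovery
studies use 10×10×10×180 phantoms (1000 voxels), the oracle-equivalence
check 6×6×6×120.

* Noiseless end-to-end (file-based pipeline, random CVR in [0.1, 0.6]
  %/mmHg, delays in [−4, +8] s): max CVR error ~0.5% relative, delays exact
  on the grid.
* tSNR 50, three seeds: median |CVR error| ~9.5% relative — per-voxel CVR
  at this noise level is honest but noisy, which is why the field smooths
  or averages over regions.
* Per-voxel **delay** at tSNR 50 has a median error of ~1.5 s (three grid
  steps). This is an information limit of the block design, not an
  estimator defect: substituting the exact noiseless design regressor for
  the extracted envelope leaves the number unchanged, and a Cramér–Rao
  argument gives ~2 s at the median contrast (timing information lives only
  in the ~6 ramp transitions of a 60-s block paradigm). Sub-second per-voxel
  delay precision at this tSNR requires faster designs (e.g. sinusoidal
  modulation), spatial smoothing, or regional averaging.
* The 10-s sampling-line lag is recovered exactly; the mislabelled CO2
  component (design |r| ≈ 0.9) is rescued at the 0.6 threshold with zero
  false rescues among white-noise components; the two-compartment
  (GM-like/WM-like) contrast is recovered with every matched voxel pair
  ordered correctly and the 3-s arrival difference exact.

These numbers are recomputed, not quoted, by `scripts/acceptance.py` and
asserted in `tests/test_acceptance.py`.

## Other design choices

* **%-scaling**: the raw ratio β1/(β0 + β1·b) is a fractional change per
  mmHg; maps are scaled by 100 and labelled %BOLD/mmHg.
* **Degenerate denominators** (≤ 0, or smaller than 1e-6·|β1·b|) are
  written as NaN and excluded from the validity mask rather than clipped:
  clinical users must see missingness, not fabricated values.
* **Output naming**: BIDS derivatives do not define CVR suffixes, so the
  package uses `_cvr` / `_delay` and documents the vocabulary in
  `dataset_description.json`. Output maps always inherit the input BOLD
  grid and affine; the tool never resamples.
* **IC index convention**: the upstream noise-IC list is read as 1-based
  (fMRIPrep convention) and converted to 0-based internally.
* **Spatial smoothing** (optional, default off) is a mask-renormalized
  Gaussian applied frame-by-frame before delay fitting.
* **Determinism**: the pipeline itself is deterministic given its inputs;
  all phantom randomness flows through one seeded generator, and identical
  seeds give bitwise-identical phantoms.

## Limitations

Participant-level only — group statistics are out of scope by design.
Multi-echo combination, ICA estimation and all spatial preprocessing are
delegated to the upstream pipeline. The baseline estimator assumes the run
contains a normocapnic stretch of at least `baseline_fraction` of its
duration; fully hypercapnic runs would bias the baseline high and CVR
accordingly. Respiration-volume effects, O2 traces and physiological-noise
models (e.g. RETROICOR) are not modelled.
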