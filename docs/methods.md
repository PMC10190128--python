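# Methods

## Signal model

A cell of diameter `d` traveling at constant velocity `v` through an
illuminated detection window of length `L` along the flow axis produces,
per detector channel, a trapezoidal fluorescence pulse:

* rise `T_a = d / v` while the cell enters the window,
* plateau `T_s = (L − d) / v` while it is fully inside,
* fall `T_d = T_a` on exit (an asymmetry factor is exposed for instruments
  with asymmetric optics; default 1, i.e. symmetric, which follows from
  constant velocity).

The plateau amplitude above baseline is `gain_c · N_c`, where `N_c` is the
number of fluorophore-conjugated antibodies bound to the cell's target
protein for channel `c` and `gain_c` the forward intensity map in
mV/molecule.  Spectral spillover is a unit-diagonal 3×3 matrix applied to
the above-baseline amplitude vector (identity by default; a non-trivial
preset `DEMO_SPILLOVER` exercises compensation).  Samples are taken at
500 kHz; i.i.d. Gaussian noise (default SD 1.5 mV) and a constant baseline
(default 2 mV) are added.

The default channel gains (1.67 × 10⁻⁵, 1.44 × 10⁻², 3.13 × 10⁻⁴
mV/molecule for FITC/PE/PerCP) are arbitrary-but-consistent: they are
anchored so the default A549-like copy-number means produce plateau means
of 29.7 / 80.5 / 25.4 mV, i.e. typical few-tens-of-mV PMT pulses.  Nothing
downstream depends on their absolute values, because quantification always
goes through a rendered calibration.

## Populations

Copy numbers, diameters and velocities are drawn from **moment-matched
lognormals**: for configured mean `m` and SD `s`,
`σ² = ln(1 + s²/m²)`, `μ = ln m − σ²/2`, so the configured values are the
exact first two moments of the sampling distribution.  Lognormals were
chosen over truncated normals because several configured SDs approach or
exceed their means (e.g. velocity 16.32 ± 13.12 μm/ms); truncation at zero
would bias the realised mean upward, while the lognormal has positive
support and the exact moments by construction.

Two presets carry the reference population moments used throughout the
tests: `A549_PARAMS` (β-actin 1.78 ± 1.06 × 10⁶, EpCAM 0.56 ± 0.43 × 10⁴,
β-tubulin 8.11 ± 4.89 × 10⁴ copies; 15.2 ± 4.0 μm; 16.32 ± 13.12 μm/ms)
and `CAL27_PARAMS` (2.65 ± 1.19 × 10⁶, 3.47 ± 2.45 × 10⁴,
8.61 ± 5.25 × 10⁴; 16.6 ± 4.0 μm; 17.16 ± 5.35 μm/ms).

Arrivals follow a homogeneous Poisson process (default 40 events/s, a
realistic constriction throughput) with every inter-arrival gap floored at
3× the expected transit duration *and* at 1.5× the actual duration of the
preceding pulse.  The second floor matters: with the heavy-tailed velocity
distribution, a fixed floor alone would let slow-cell pulses overlap their
successors.  Under this rule every injected cell produces exactly one
suprathreshold excursion per channel at the SNRs used in testing.

The window length `L` is not a measurable of the instrument configuration
we emulate; the default of 60 μm is chosen so that `velocity × (plateau +
rise)` reproduces transit durations of a few ms for ~15 μm cells, and it is
configurable everywhere (`GeometryModel`, `ChannelConfig`).

## Detection and ladder fitting

1. **Median filter**, default 50 points (widened to 51 internally so the
   window is centred), replicate padding at the edges.
2. **Background**: first pass uses median and MAD-derived sigma (robust to
   heavy pulse occupancy); second pass recomputes ordinary mean/SD after
   excluding every suprathreshold excursion *in full* — each run above the
   robust cutoff is extended outward to the nearest median crossing, so
   rise/fall ramps do not leak into the baseline statistics.  The detection
   threshold is `mean + k·SD`, `k = 3`.
3. **Events**: maximal suprathreshold runs of at least `min_event_samples`
   (default 100 ≙ 0.2 ms), extended outward to the nearest baseline-mean
   crossing; overlapping extensions are merged (a noise dip can split one
   pulse into two runs).  Coordinates are 0-based, half-open sample
   intervals.  Runs longer than 3× the median event duration are flagged
   as possible doublets but **kept by default**
   (`DetectionSettings.exclude_long_events`): with velocity SD ~80% of the
   mean, ~6% of genuine single-cell transits exceed that limit, and
   excluding them would bias recovered kinematic means upward by ~5%.
4. **Ladder fit**: the plateau level is seeded from the upper quartile of
   the segment, breakpoints from 10%/90% threshold crossings, then all five
   parameters (onset, three widths, amplitude) are refined by bounded
   trust-region least squares on the filtered segment.  Fitting on the
   filtered trace is a deliberate choice: the median filter preserves edge
   positions of ramps longer than the window (median of a monotone window
   is its centre) and only rounds the corners symmetrically, so fitted
   durations are unbiased, while the ~5× noise reduction stabilises the
   breakpoints.  Non-converged fits are logged and excluded.
5. **Matching**: greedy nearest-time matching of per-channel fits into
   triples within a 1 ms tolerance; each fit is used at most once;
   unmatched fits are dropped and counted.

## Quantification

Calibration solutions of stock concentration `C` diluted by factor `f`
contain `N = (C/f) · V · N_A` molecules in the detection volume
`V = L × 20 μm × 20 μm = 2.4 × 10⁻¹¹ L`.  A per-channel ordinary
least-squares line of measured level against `N` gives slope (= gain) and
intercept (= baseline); the fit refuses non-positive slopes and fewer than
two distinct concentrations.  Default stock concentrations
(10 μM / 15 nM / 220 nM for FITC/PE/PerCP) place the six dilution levels
around the default pulse amplitudes.

A cell's copy number is `(I_abs − intercept) / slope` per channel, where
`I_abs` is the fitted above-baseline plateau plus the cell trace's own
background mean (so calibration and cell measurements share one intensity
scale), after optional spillover compensation (`S⁻¹ ·` the plateau vector)
and a multiplicative equivalence factor (default 1) reserved for a
cell-vs-solution geometry correction.  Negative results are clipped to
zero and flagged rather than dropped, keeping event counts stable.

Kinematics invert the forward model exactly: `T_rise = (T_a + T_d)/2`,
`v = L / (T_rise + T_s)`, `d = v · T_rise`.  This inversion is a modelling
choice — it assumes the symmetric-trapezoid transit model — and is exact on
rendered pulses up to discretisation.

## Classification

* **FFNN**: scikit-learn MLP, one hidden ReLU layer (default 50 units),
  softmax output, Adam (lr 0.001, batch 100), features z-scored with
  training-set statistics.
* **LSTM**: a from-scratch numpy implementation (standard gates, forget
  bias 1, dropout 0.2 on the final hidden state, dense softmax head, full
  BPTT, Adam), checked against central finite differences in the test
  suite.  Pulses are resampled to a fixed length (default 256) by linear
  interpolation and z-scored per channel with training-set statistics.
* Both use a stratified 70/15/15 train/validation/test split
  (largest-remainder apportionment per class, seeded permutation), an
  epoch cap of 50 and early stopping with patience 5.  An epoch counts as
  stale only when neither validation accuracy nor validation log-loss
  improves — validation accuracy alone can sit at chance for many epochs
  while the loss still falls, which would otherwise trigger a premature
  stop.  The best checkpoint (by validation accuracy, loss as tie-break)
  is restored.
* The hyperparameter screen trains one model per grid point
  (batch size × learning rate × hidden units, default
  {10, 100, 1000} × {0.01, 0.001, 0.0001} × {64, 128, 256}) with a shared
  seed and reports final accuracies plus per-epoch traces.

Confusion matrices use the fixed class order (class 0, class 1).

## Reference studies and problem sizes

`ladderflow.studies` runs the self-consistency benchmarks that
`scripts/acceptance.py` reports: 2,000 cells per population (processed in
chunks of 250 so no full-length trace materialises at once), which keeps a
complete study under two minutes on one CPU while population means carry
standard errors below 2%.  The pulse-shape study renders single-channel
pulses with transit durations from the A549 transit moments
(3.00 ± 1.43 ms; rise and fall 15% of the total each) and PE plateaus from
the A549 plateau moments (80.5 ± 46.1 mV), then measures the fitted mean
duration and plateau.  Plateau moments are drawn directly (rather than
derived from copy numbers) because plateau-intensity and copy-number
population moments are not connected by a single linear gain across cell
types once calibration intercepts and compensation are involved.

## What the generator does and does not emulate

It reproduces the statistical structure the analysis relies on —
trapezoidal pulses with kinematically consistent timing, linear
intensity-to-copy maps, Gaussian detector noise, Poisson arrivals,
dilution series — so passing tests demonstrate that the analysis chain is
self-consistent and unbiased under its own model.  It does **not** emulate
photobleaching, detector saturation, baseline drift, cell deformation in
the constriction, uneven intracellular fluorophore distribution, doublets
or coincident transits; agreement on synthetic data therefore does not
establish accuracy on real recordings, and the classifier accuracies
obtained on synthetic populations are not comparable to accuracies on real
cell measurements.

## Numerical notes

* Everything is seeded; a single global seed expands into per-stage child
  seeds by hashing `(seed, stage-key)`, so stages are independently
  reproducible and identical config+seed yields byte-identical artifacts.
* Trapezoid knots are kept strictly increasing by a 1 pm-scale jitter so
  degenerate (rectangular) pulses remain fittable.
* A zero-variance trace yields `threshold = mean` and is flagged.
* Traces round-trip exactly through both storage formats (Parquet, or
  17-significant-digit TSV read back with round-trip float parsing).
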