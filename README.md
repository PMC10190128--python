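# ladderflow

Quantitative single-cell protein analysis for **constrictional-microchannel
fluorescent flow cytometry**.

Conventional flow cytometry reports fluorescence intensities, not protein
copy numbers, because bead-based calibration (MESF) does not exist for most
intracellular targets.  When cells are driven single-file through a
constriction whose cross-section (20 × 20 μm) is only marginally larger
than the cell, every cell presents its bound fluorophores inside the same
fixed illuminated detection volume.  Fluorescence of antibody solutions of
known concentration flushed through the same channel then provides an
absolute calibration — the *volume equivalence* principle — and the pulse
of a transiting cell carries its kinematics in its shape.

`ladderflow` implements the complete analysis chain for such instruments,
plus a seeded synthetic-trace generator so the whole pipeline is testable
without recordings:

* **simulate** — draw cells from population distributions (moment-matched
  lognormal copy numbers, diameters, velocities), render three-channel
  (FITC/PE/PerCP) PMT traces at 500 kHz with trapezoidal pulses, baseline
  and Gaussian noise; render gradient dilution series
  (1:10 … 1:5000) for calibration.
* **pulse processing** — 50-point median filter, robust two-pass baseline
  statistics, `mean + 3σ` event detection, least-squares trapezoid
  ("ladder") fitting of the per-pulse features `T_a, T_s, T_d, I_f`, and
  cross-channel coincidence matching.
* **quantification** — per-channel linear calibration curves
  (molecules in the detection volume ↔ plateau mV), optional spillover
  compensation, conversion of plateaus into absolute copy numbers, and
  kinematic inversion: with `T_rise = (T_a + T_d)/2`,
  `v = L / (T_rise + T_s)` and `d = v · T_rise` for a window of length `L`.
* **classification** — a feedforward network (one hidden layer, 50 units)
  on the three copy-number features, and an LSTM sequence classifier on the
  raw resampled pulses, with stratified 70/15/15 splits, early stopping and
  a hyperparameter screen over batch size, learning rate and hidden units.

## Worked example

```python
import ladderflow as lf
from ladderflow.pipeline import simulate_and_quantify

records, truth, stats = simulate_and_quantify(
    lf.A549_PARAMS, 200, lf.ChannelConfig(), lf.DetectionSettings(), seed=7)
print(f"matched {stats['n_matched']} / {stats['n_injected']} cells")
print(records[["copies_fitc", "copies_pe", "copies_percp",
               "diameter_um", "velocity_um_per_ms", "transit_ms"]]
      .mean().round(2))
```

prints

```
matched 200 / 200 cells
copies_fitc           1731965.45
copies_pe                5335.58
copies_percp            83464.60
diameter_um                15.20
velocity_um_per_ms         17.58
transit_ms                  7.01
```

Each of the 200 synthetic A549-like cells was rendered into a noisy
three-channel trace, detected, ladder-fitted and calibrated.  The recovered
population means sit within sampling error of the generator's configured
moments (β-actin 1.78 ± 1.06 × 10⁶ copies, EpCAM 0.56 ± 0.43 × 10⁴,
β-tubulin 8.11 ± 4.89 × 10⁴; diameter 15.2 μm, velocity 16.32 μm/ms), and
every injected cell was recovered as exactly one matched event.

## Command line

```sh
ladderflow run-all --out runs/demo --seed 1            # full pipeline
ladderflow simulate --out runs/demo --seed 1           # ... or stage by stage
ladderflow detect   --out runs/demo --seed 1
ladderflow quantify --out runs/demo --seed 1
ladderflow classify --out runs/demo --seed 1
```

`run-all` chains exactly the four stage commands, so both routes produce
byte-identical artifacts: traces (Parquet + JSON sidecar), events and
cell-record CSVs, calibration-curve JSON and classifier reports, each
stamped with the config hash and seed.  A YAML configuration
(`--config run.yaml`) controls populations, detector, detection and
training settings; unknown keys are rejected.  Cell records can be exported
as FCS 3.1 via `ladderflow.pipeline.export_fcs`.

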