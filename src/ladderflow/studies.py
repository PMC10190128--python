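"""Reference synthetic studies: population-parameter recovery at scale.

These functions run the full analysis chain (render -> median filter ->
threshold detection -> ladder fit -> calibration -> quantification) on
synthetic populations generated from the A549 / CAL 27 population moments,
and report the recovered population means.  They define the package's
standard self-consistency benchmarks: the generator's configured moments
should be recovered by the analysis within sampling error.

Problem size defaults to 2,000 cells per population, processed in chunks,
which keeps a full study under a couple of minutes on one CPU while the
population means carry sub-2% standard errors.
"""

from __future__ import annotations

import numpy as np

from .pulses import DetectionSettings, detect_events, estimate_background, \
    fit_ladder, median_filter
from .simulate import (A549_PARAMS, CAL27_PARAMS, ChannelConfig,
                       GroundTruthCell, PopulationParams, lognormal_params,
                       render_trace, sample_lognormal)
from .pipeline import child_seed, simulate_and_quantify

__all__ = ["population_recovery_study", "pulse_shape_study",
           "a549_study", "cal27_study"]


def population_recovery_study(params: PopulationParams, n_cells: int,
                              seed: int, chunk_size: int = 250) -> dict:
    """Render, detect, fit, calibrate and quantify one population.

    Returns the recovered population means (copy numbers per channel,
    diameter, velocity, transit time) together with the number of matched
    cells.
    """
    cfg = ChannelConfig()
    settings = DetectionSettings()
    records, _, stats = simulate_and_quantify(
        params, n_cells, cfg, settings, seed, chunk_size=chunk_size)
    return {
        "n_matched": int(stats["n_matched"]),
        "mean_copies_fitc": float(records["copies_fitc"].mean()),
        "mean_copies_pe": float(records["copies_pe"].mean()),
        "mean_copies_percp": float(records["copies_percp"].mean()),
        "mean_diameter_um": float(records["diameter_um"].mean()),
        "mean_velocity_um_per_ms": float(records["velocity_um_per_ms"].mean()),
        "mean_transit_ms": float(records["transit_ms"].mean()),
    }


def a549_study(seed: int, n_cells: int = 2000) -> dict:
    return population_recovery_study(A549_PARAMS, n_cells,
                                     child_seed(seed, "a549"))


def cal27_study(seed: int, n_cells: int = 2000) -> dict:
    return population_recovery_study(CAL27_PARAMS, n_cells,
                                     child_seed(seed, "cal27"))


def pulse_shape_study(seed: int, n_pulses: int = 2000,
                      transit_mean_ms: float = 3.00,
                      transit_sd_ms: float = 1.43,
                      plateau_mean_mV: float = 80.5,
                      plateau_sd_mV: float = 46.1,
                      rise_fraction: float = 0.15,
                      chunk_size: int = 250) -> dict:
    """Single-channel pulse-shape recovery: detection + ladder fitting.

    Pulses are rendered on the PE channel with total durations drawn from a
    moment-matched lognormal (``T_a = T_d = rise_fraction * T``, plateau
    ``T_s`` the remainder) and plateau amplitudes drawn from a
    moment-matched lognormal, at the default 1.5 mV noise.  The fitted mean
    total duration ``T_a + T_s + T_d`` and mean plateau are reported.

    With a window of length ``L`` and symmetric rise/fall, a duration ``T``
    maps onto cell kinematics as ``velocity = L / ((1 - rise_fraction) T)``
    and ``diameter = velocity * rise_fraction * T``.
    """
    cfg = ChannelConfig()
    settings = DetectionSettings()
    rng = np.random.default_rng(child_seed(seed, "shape"))
    window = cfg.window_length_um
    gain_pe = cfg.gain[1]

    durations_ms = sample_lognormal(transit_mean_ms, transit_sd_ms,
                                    n_pulses, rng)
    plateaus_mV = sample_lognormal(plateau_mean_mV, plateau_sd_mV,
                                   n_pulses, rng)
    velocities = window / ((1.0 - rise_fraction) * durations_ms)
    diameter = window * rise_fraction / (1.0 - rise_fraction)

    mu_t, sig_t = lognormal_params(transit_mean_ms, transit_sd_ms)
    mean_dur_s = np.exp(mu_t + sig_t ** 2 / 2) * 1e-3

    totals, fitted_plateaus = [], []
    n_chunks = int(np.ceil(n_pulses / chunk_size))
    for k in range(n_chunks):
        sl = slice(k * chunk_size, min((k + 1) * chunk_size, n_pulses))
        m = sl.stop - sl.start
        gaps = np.maximum(rng.exponential(0.025, size=m),
                          np.maximum(3 * mean_dur_s,
                                     1.5e-3 * durations_ms[sl]))
        arrivals = np.cumsum(gaps)
        cells = [
            GroundTruthCell(
                copies=(0, int(round(plateaus_mV[sl][i] / gain_pe)), 0),
                diameter_um=diameter,
                velocity_um_per_ms=float(velocities[sl][i]),
                arrival_time_s=float(arrivals[i]),
            )
            for i in range(m)
        ]
        trace = render_trace(cells, cfg, child_seed(seed, f"shape-trace{k}"))
        filtered = median_filter(trace, settings.effective_median_window)
        background = estimate_background(filtered, settings.threshold_k)
        events = detect_events(filtered, settings, background)[1]
        for ev in events:
            fit = fit_ladder(ev, trace.sample_rate_hz,
                             baseline_mV=background.mean[1])
            if fit.converged:
                totals.append(fit.total_ms)
                fitted_plateaus.append(fit.i_f_mV)

    return {
        "n_fitted": len(totals),
        "mean_total_duration_ms": float(np.mean(totals)),
        "mean_plateau_mV": float(np.mean(fitted_plateaus)),
    }
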