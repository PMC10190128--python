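"""Synthetic three-channel PMT trace generator for constrictional-microchannel
fluorescent flow cytometry.

A cell transiting the illuminated detection window of a constrictional
microchannel produces a trapezoidal ("ladder") fluorescence pulse per detector
channel: a linear rise while the cell enters the window (duration
``T_a = diameter / velocity``), a plateau while it is fully inside
(``T_s = (window_length - diameter) / velocity``), and a symmetric fall on
exit.  The plateau amplitude is proportional to the number of bound
fluorophore-conjugated antibodies, i.e. to the protein copy number.

This module draws ground-truth cells from population distributions, renders
their pulses onto a noisy baseline at the instrument sampling rate
(500 kHz), and renders constant-level calibration-solution traces for the
gradient dilution series used to build calibration curves.  Everything is
seeded and bit-reproducible, so the whole downstream analysis is testable
without instrument recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .quantify import GeometryModel, molecules_in_volume

__all__ = [
    "PopulationParams",
    "ChannelConfig",
    "GroundTruthCell",
    "RawTrace",
    "CHANNEL_NAMES",
    "A549_PARAMS",
    "CAL27_PARAMS",
    "DEMO_SPILLOVER",
    "lognormal_params",
    "sample_lognormal",
    "sample_population",
    "render_trace",
    "render_calibration_series",
]

#: Detector channel order used everywhere: FITC (beta-actin), PE (EpCAM),
#: PerCP (beta-tubulin).
CHANNEL_NAMES = ("FITC", "PE", "PerCP")


class ParameterError(ValueError):
    """Invalid population or channel parameter."""


class GeometryError(ValueError):
    """Cell geometry incompatible with the detection window."""


@dataclass(frozen=True)
class PopulationParams:
    """Generative description of one cell type.

    Copy numbers, diameter and velocity are modelled as moment-matched
    lognormals: the configured mean/SD are the exact first two moments of
    the sampling distribution (positive support, no truncation bias).

    Units: copies are molecules per cell, diameter um, velocity um/ms,
    arrival_rate events per second.
    """

    name: str
    copies_mean: tuple[float, float, float]
    copies_sd: tuple[float, float, float]
    diameter_mean: float
    diameter_sd: float
    velocity_mean: float
    velocity_sd: float
    arrival_rate: float = 40.0

    def __post_init__(self) -> None:
        vals = (
            *self.copies_mean, *self.copies_sd,
            self.diameter_mean, self.diameter_sd,
            self.velocity_mean, self.velocity_sd, self.arrival_rate,
        )
        if any(not np.isfinite(v) or v <= 0 for v in vals):
            raise ParameterError(
                f"all means, SDs and the arrival rate must be strictly "
                f"positive and finite, got {self!r}"
            )


#: Default non-trivial spillover preset (rows: detector, columns: dye) for
#: exercising compensation; unit diagonal as the forward map convention.
DEMO_SPILLOVER = np.array(
    [
        [1.00, 0.08, 0.02],
        [0.05, 1.00, 0.06],
        [0.01, 0.10, 1.00],
    ]
)

# Forward gains anchored so that the default A549-like copy-number means land
# on plateau means near the instrument's typical few-tens-of-mV pulses
# (29.7 / 80.5 / 25.4 mV for the three channels).
DEFAULT_GAINS = (29.7 / 1.78e6, 80.5 / 0.56e4, 25.4 / 8.11e4)


@dataclass
class ChannelConfig:
    """Detector / geometry configuration of the rendered instrument.

    ``gain`` is the forward intensity map in mV per molecule per channel;
    ``spillover`` is the unit-diagonal dye-to-detector mixing matrix applied
    to the above-baseline amplitudes.
    """

    gain: tuple[float, float, float] = DEFAULT_GAINS
    baseline_mV: float = 2.0
    noise_sd_mV: float = 1.5
    sample_rate_hz: float = 500_000.0
    window_length_um: float = 60.0
    cross_section_um2: float = 400.0  # 20 um x 20 um constriction
    asymmetry: float = 1.0  # T_d = asymmetry * T_a
    spillover: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.spillover = np.asarray(self.spillover, dtype=float)
        if any(g <= 0 for g in self.gain):
            raise ParameterError("gains must be strictly positive")
        if self.noise_sd_mV < 0:
            raise ParameterError("noise SD must be non-negative")
        if self.spillover.shape != (3, 3):
            raise ParameterError("spillover must be a 3x3 matrix")
        if not np.allclose(np.diag(self.spillover), 1.0):
            raise ParameterError("spillover diagonal entries must equal 1")
        if abs(np.linalg.det(self.spillover)) < 1e-12:
            raise ParameterError("spillover matrix must be invertible")

    @property
    def geometry(self) -> GeometryModel:
        return GeometryModel(
            window_length_um=self.window_length_um,
            cross_section_um2=self.cross_section_um2,
        )


@dataclass(frozen=True)
class GroundTruthCell:
    """Latent variables behind one rendered pulse triple."""

    copies: tuple[int, int, int]  # molecules per channel
    diameter_um: float
    velocity_um_per_ms: float
    arrival_time_s: float  # time the leading edge enters the window

    def durations_ms(self, window_length_um: float, asymmetry: float = 1.0
                     ) -> tuple[float, float, float]:
        """(T_a, T_s, T_d) in ms for a given detection-window length."""
        if self.diameter_um >= window_length_um:
            raise GeometryError(
                f"cell diameter {self.diameter_um:.2f} um >= window length "
                f"{window_length_um:.2f} um"
            )
        t_a = self.diameter_um / self.velocity_um_per_ms
        t_s = (window_length_um - self.diameter_um) / self.velocity_um_per_ms
        return t_a, t_s, asymmetry * t_a

    def total_duration_ms(self, window_length_um: float,
                          asymmetry: float = 1.0) -> float:
        return sum(self.durations_ms(window_length_um, asymmetry))


@dataclass
class RawTrace:
    """Uniformly sampled multi-channel voltage recording in mV."""

    values: np.ndarray  # shape (3, n), mV
    sample_rate_hz: float
    channel_names: tuple[str, ...] = CHANNEL_NAMES

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("trace contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate_hz


# Population presets: A549 (lung adenocarcinoma) and CAL 27 (tongue squamous
# carcinoma) with per-channel protein copy-number, diameter, velocity moments.
A549_PARAMS = PopulationParams(
    name="A549",
    copies_mean=(1.78e6, 0.56e4, 8.11e4),
    copies_sd=(1.06e6, 0.43e4, 4.89e4),
    diameter_mean=15.2,
    diameter_sd=4.0,
    velocity_mean=16.32,
    velocity_sd=13.12,
)

CAL27_PARAMS = PopulationParams(
    name="CAL27",
    copies_mean=(2.65e6, 3.47e4, 8.61e4),
    copies_sd=(1.19e6, 2.45e4, 5.25e4),
    diameter_mean=16.6,
    diameter_sd=4.0,
    velocity_mean=17.16,
    velocity_sd=5.35,
)


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the lognormal with the given arithmetic mean and SD."""
    if mean <= 0 or sd <= 0:
        raise ParameterError("lognormal moments must be strictly positive")
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def sample_lognormal(mean: float, sd: float, size: int,
                     rng: np.random.Generator) -> np.ndarray:
    mu, sigma = lognormal_params(mean, sd)
    return rng.lognormal(mu, sigma, size=size)


def sample_population(
    params: PopulationParams,
    n_cells: int,
    seed: int,
    *,
    window_length_um: float = 60.0,
    min_spacing_factor: float = 3.0,
) -> list[GroundTruthCell]:
    """Draw ``n_cells`` ground-truth cells with non-overlapping arrivals.

    Copy numbers, diameter and velocity are independent moment-matched
    lognormals.  Arrival times follow a homogeneous Poisson process at
    ``params.arrival_rate``, with each inter-arrival gap floored at
    ``min_spacing_factor`` times the expected transit duration and at
    1.5 times the actual duration of the preceding pulse, which guarantees
    non-overlapping pulses even in the slow tail of the velocity
    distribution.
    """
    if n_cells < 0:
        raise ParameterError("n_cells must be non-negative")
    rng = np.random.default_rng(seed)
    if n_cells == 0:
        return []

    copies = np.column_stack([
        np.rint(sample_lognormal(m, s, n_cells, rng))
        for m, s in zip(params.copies_mean, params.copies_sd)
    ]).astype(np.int64)
    diameters = sample_lognormal(params.diameter_mean, params.diameter_sd,
                                 n_cells, rng)
    velocities = sample_lognormal(params.velocity_mean, params.velocity_sd,
                                  n_cells, rng)

    # expected transit duration (s): E[(L + d) / v] for independent d, v,
    # using the lognormal closed form for E[1/v]
    mu_v, sig_v = lognormal_params(params.velocity_mean, params.velocity_sd)
    e_inv_v = np.exp(-mu_v + sig_v ** 2 / 2.0)  # ms/um
    expected_transit_s = (window_length_um + params.diameter_mean) * e_inv_v * 1e-3

    durations_s = (window_length_um + diameters) / velocities * 1e-3
    gaps = rng.exponential(1.0 / params.arrival_rate, size=n_cells)
    floor = min_spacing_factor * expected_transit_s
    prev_dur = np.concatenate([[0.0], durations_s[:-1]])
    gaps = np.maximum(gaps, np.maximum(floor, 1.5 * prev_dur))
    arrivals = np.cumsum(gaps)

    return [
        GroundTruthCell(
            copies=tuple(int(c) for c in copies[i]),
            diameter_um=float(diameters[i]),
            velocity_um_per_ms=float(velocities[i]),
            arrival_time_s=float(arrivals[i]),
        )
        for i in range(n_cells)
    ]


def _trapezoid_knots(cell: GroundTruthCell, cfg: ChannelConfig
                     ) -> tuple[np.ndarray, float]:
    """Breakpoint times (s) of the cell's trapezoid and its end time."""
    t_a, t_s, t_d = cell.durations_ms(cfg.window_length_um, cfg.asymmetry)
    t0 = cell.arrival_time_s
    knots = t0 + 1e-3 * np.array([0.0, t_a, t_a + t_s, t_a + t_s + t_d])
    return knots, float(knots[-1])


def render_trace(
    cells: Sequence[GroundTruthCell],
    cfg: ChannelConfig,
    seed: int,
    *,
    duration_s: float | None = None,
    pad_s: float = 0.01,
) -> RawTrace:
    """Render the three-channel voltage trace of a list of cells.

    Each cell contributes, per channel ``c``, a trapezoid of above-baseline
    amplitude ``gain[c] * copies[c]`` (then mixed by the spillover matrix),
    with rise/plateau/fall durations fixed by its diameter and velocity.
    I.i.d. Gaussian noise of ``cfg.noise_sd_mV`` is added to every sample.
    Identical (cells, cfg, seed) give bit-identical output.
    """
    rng = np.random.default_rng(seed)
    end = 0.0
    rendered: list[tuple[np.ndarray, np.ndarray]] = []
    for cell in cells:
        knots, cell_end = _trapezoid_knots(cell, cfg)
        amps = cfg.spillover @ (np.asarray(cfg.gain) * np.asarray(cell.copies))
        rendered.append((knots, amps))
        end = max(end, cell_end)

    if duration_s is None:
        duration_s = end + pad_s
    n = max(1, int(round(duration_s * cfg.sample_rate_hz)))

    values = np.full((3, n), cfg.baseline_mV, dtype=float)
    dt = 1.0 / cfg.sample_rate_hz
    for knots, amps in rendered:
        i0 = max(0, int(np.floor(knots[0] / dt)))
        i1 = min(n, int(np.ceil(knots[-1] / dt)) + 1)
        if i1 <= i0:
            continue
        t = np.arange(i0, i1) * dt
        shape = np.interp(t, knots, [0.0, 1.0, 1.0, 0.0], left=0.0, right=0.0)
        values[:, i0:i1] += amps[:, None] * shape[None, :]

    if cfg.noise_sd_mV > 0:
        values += rng.normal(0.0, cfg.noise_sd_mV, size=values.shape)
    return RawTrace(values=values, sample_rate_hz=cfg.sample_rate_hz)


def render_calibration_series(
    dilutions: Sequence[float],
    stock_concentration_molar: float | Sequence[float],
    cfg: ChannelConfig,
    seed: int,
    *,
    duration_s: float = 0.05,
) -> list[tuple[float, RawTrace]]:
    """Render constant-plateau traces of the gradient dilution series.

    Each dilution factor ``f`` (e.g. 10 for a 1:10 dilution) produces one
    trace per call whose per-channel level is ``gain * N + baseline`` plus
    noise, where ``N`` is the expected molecule count of the diluted stock
    occupying the detection volume.  Single-dye solutions are measured in
    their own detector channel, so no spillover is applied here; spectral
    compensation is handled downstream.
    """
    dilutions = list(dilutions)
    stock = np.broadcast_to(np.asarray(stock_concentration_molar, dtype=float),
                            (3,)).copy()
    if any(d <= 0 for d in dilutions):
        raise ParameterError("dilution factors must be strictly positive")
    if np.any(stock <= 0):
        raise ParameterError("stock concentration must be strictly positive")

    rng = np.random.default_rng(seed)
    geometry = cfg.geometry
    n = max(1, int(round(duration_s * cfg.sample_rate_hz)))
    out: list[tuple[float, RawTrace]] = []
    for dil in dilutions:
        levels = np.array([
            cfg.gain[c] * molecules_in_volume(stock[c] / dil, geometry)
            + cfg.baseline_mV
            for c in range(3)
        ])
        values = np.repeat(levels[:, None], n, axis=1)
        if cfg.noise_sd_mV > 0:
            values = values + rng.normal(0.0, cfg.noise_sd_mV, size=values.shape)
        out.append((dil, RawTrace(values=values,
                                  sample_rate_hz=cfg.sample_rate_hz)))
    return out
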