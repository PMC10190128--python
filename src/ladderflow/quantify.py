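"""Volume-equivalence quantification: calibration curves, copy-number
conversion, spillover compensation, and pulse-timing kinematics.

The constrictional microchannel fixes the illuminated detection volume, so a
cell's plateau fluorescence can be compared directly against calibration
solutions of known fluorophore concentration occupying the same volume
("volume equivalence").  A linear fit of plateau intensity against the
expected molecule count in the detection volume, one curve per channel,
converts fitted plateau intensities into absolute protein copy numbers.

Pulse timing inverts to cell kinematics: with rise time ``T_rise`` and
plateau time ``T_s``, the cell crosses the window of length ``L`` in
``T_rise + T_s``, so ``velocity = L / (T_rise + T_s)`` and
``diameter = velocity * T_rise``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

AVOGADRO = 6.02214076e23  # 1/mol

__all__ = [
    "GeometryModel",
    "CalibrationCurve",
    "CellRecord",
    "CalibrationError",
    "CompensationError",
    "molecules_in_volume",
    "fit_calibration_curve",
    "apply_compensation",
    "intensity_to_copies",
    "kinematics_from_pulse",
]


class CalibrationError(ValueError):
    """Degenerate or non-physical calibration input."""


class CompensationError(ValueError):
    """Spillover matrix unusable for compensation."""


@dataclass(frozen=True)
class GeometryModel:
    """Detection-volume geometry of the constrictional microchannel.

    The illuminated window has length ``window_length_um`` along the flow
    axis and the constriction a fixed ``cross_section_um2`` (20 x 20 um by
    default), so the detection volume is their product.
    """

    window_length_um: float = 60.0
    cross_section_um2: float = 400.0

    def __post_init__(self) -> None:
        if self.window_length_um <= 0 or self.cross_section_um2 <= 0:
            raise ValueError("geometry dimensions must be strictly positive")

    @property
    def detection_volume_L(self) -> float:
        # 1 um^3 = 1e-15 L
        return self.window_length_um * self.cross_section_um2 * 1e-15


@dataclass
class CalibrationCurve:
    """Per-channel linear map molecule count -> plateau intensity (mV)."""

    channel: str
    slope_mV_per_molecule: float
    intercept_mV: float
    r_squared: float
    points: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.slope_mV_per_molecule <= 0:
            raise CalibrationError(
                f"channel {self.channel}: calibration slope must be positive, "
                f"got {self.slope_mV_per_molecule}"
            )


@dataclass
class CellRecord:
    """Quantified per-cell outputs."""

    cell_id: int
    copies: tuple[float, float, float]
    diameter_um: float
    velocity_um_per_ms: float
    transit_ms: float
    t_center_s: float
    clipped: tuple[bool, bool, bool] = (False, False, False)


def molecules_in_volume(concentration_molar: float,
                        geometry: GeometryModel) -> float:
    """Expected molecule count of a solution occupying the detection volume.

    ``N = C * V * N_A`` with C in mol/L and V the detection volume in L.
    """
    if concentration_molar < 0:
        raise ValueError("concentration must be non-negative")
    return concentration_molar * geometry.detection_volume_L * AVOGADRO


def fit_calibration_curve(points: list[tuple[float, float]],
                          channel: str = "") -> CalibrationCurve:
    """Ordinary least-squares line through (molecule count, intensity) points.

    Requires at least two distinct molecule counts and a strictly positive
    slope (intensity must grow with concentration for the channel to be
    usable).
    """
    pts = [(float(n), float(i)) for n, i in points]
    n_vals = np.array([p[0] for p in pts])
    i_vals = np.array([p[1] for p in pts])
    if len(pts) < 2 or np.ptp(n_vals) == 0:
        raise CalibrationError(
            f"channel {channel}: need >= 2 distinct molecule counts"
        )
    res = stats.linregress(n_vals, i_vals)
    if res.slope <= 0:
        raise CalibrationError(
            f"channel {channel}: non-positive calibration slope {res.slope:g}"
        )
    return CalibrationCurve(
        channel=channel,
        slope_mV_per_molecule=float(res.slope),
        intercept_mV=float(res.intercept),
        r_squared=float(res.rvalue ** 2),
        points=pts,
    )


def apply_compensation(intensities: np.ndarray,
                       spillover: np.ndarray) -> np.ndarray:
    """Unmix detector intensities: ``spillover^-1 @ intensities``.

    ``intensities`` may be a 3-vector or an (n, 3) array of above-baseline
    plateau amplitudes.
    """
    spill = np.asarray(spillover, dtype=float)
    if spill.shape != (3, 3):
        raise CompensationError("spillover must be a 3x3 matrix")
    if abs(np.linalg.det(spill)) < 1e-12:
        raise CompensationError("spillover matrix is singular")
    inv = np.linalg.inv(spill)
    arr = np.asarray(intensities, dtype=float)
    if arr.ndim == 1:
        return inv @ arr
    return arr @ inv.T


def intensity_to_copies(i_f_mV: float, curve: CalibrationCurve,
                        equivalence_factor: float = 1.0
                        ) -> tuple[float, bool]:
    """Convert a plateau intensity (same scale as the calibration points,
    i.e. baseline included) into a molecule count.

    Negative results are clipped to zero and flagged rather than dropped so
    event counts stay stable.  ``equivalence_factor`` is the multiplicative
    cell-vs-solution geometry correction (default 1).

    Returns ``(copies, clipped)``.
    """
    copies = equivalence_factor * (i_f_mV - curve.intercept_mV) \
        / curve.slope_mV_per_molecule
    if copies < 0:
        return 0.0, True
    return float(copies), False


def kinematics_from_pulse(t_a_ms: float, t_s_ms: float, t_d_ms: float,
                          geometry: GeometryModel
                          ) -> tuple[float, float, float]:
    """Invert ladder timing into (velocity um/ms, diameter um, transit ms).

    With ``T_rise = (T_a + T_d)/2`` (averaging entry and exit edges), the
    cell's leading edge crosses the window in ``T_rise + T_s``, giving
    ``velocity = window_length / (T_rise + T_s)`` and
    ``diameter = velocity * T_rise``.
    """
    t_rise = (t_a_ms + t_d_ms) / 2.0
    crossing = t_rise + t_s_ms
    if crossing <= 0:
        raise ValueError("pulse has zero rise+plateau duration")
    velocity = geometry.window_length_um / crossing
    diameter = velocity * t_rise
    return float(velocity), float(diameter), float(t_a_ms + t_s_ms + t_d_ms)
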