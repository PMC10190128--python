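"""Run configuration: validated YAML/JSON config for the full pipeline.

Unknown keys are rejected on load; the SHA-256 hash of the canonical JSON
form is recorded in every output for provenance.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .classify import TrainConfig
from .pulses import DetectionSettings
from .quantify import GeometryModel
from .simulate import ChannelConfig, DEFAULT_GAINS, PopulationParams

__all__ = ["RunConfig", "load_config", "DEFAULT_STOCK_NM"]

# Default stock antibody concentrations (nM) per channel, chosen so the
# default gains put the 1:10 .. 1:5000 dilution levels comfortably around
# the default cell plateau intensities.
DEFAULT_STOCK_NM = (10_000.0, 15.0, 220.0)

DEFAULT_DILUTIONS = (10.0, 50.0, 100.0, 500.0, 1000.0, 5000.0)


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PopulationModel(_Model):
    name: str
    copies_mean: tuple[float, float, float]
    copies_sd: tuple[float, float, float]
    diameter_mean: float
    diameter_sd: float
    velocity_mean: float
    velocity_sd: float
    arrival_rate: float = 40.0

    def to_params(self) -> PopulationParams:
        return PopulationParams(**self.model_dump())


class ChannelModel(_Model):
    gain: tuple[float, float, float] = DEFAULT_GAINS
    baseline_mV: float = 2.0
    noise_sd_mV: float = 1.5
    sample_rate_hz: float = 500_000.0
    window_length_um: float = 60.0
    cross_section_um2: float = 400.0
    asymmetry: float = 1.0
    spillover: tuple[tuple[float, float, float],
                     tuple[float, float, float],
                     tuple[float, float, float]] = (
        (1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0))

    def to_config(self) -> ChannelConfig:
        d = self.model_dump()
        d["spillover"] = np.array(d["spillover"])
        return ChannelConfig(**d)


class DetectionModel(_Model):
    median_window: int = 50
    threshold_k: float = 3.0
    min_event_samples: int = 100
    coincidence_tolerance_ms: float = 1.0
    long_event_factor: float = 3.0
    exclude_long_events: bool = False

    def to_settings(self) -> DetectionSettings:
        return DetectionSettings(**self.model_dump())


class CalibrationModel(_Model):
    dilutions: tuple[float, ...] = DEFAULT_DILUTIONS
    stock_concentration_nM: tuple[float, float, float] = DEFAULT_STOCK_NM
    noise_sd_mV: float = 0.0
    equivalence_factor: float = 1.0


class TrainModel(_Model):
    split_fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    hidden_units_ffnn: int = 50
    lstm_hidden: int = 128
    batch_size: int = 100
    learning_rate: float = 1e-3
    max_epochs: int = 50
    patience: int = 5
    dropout: float = 0.2

    def to_config(self, seed: int) -> TrainConfig:
        return TrainConfig(seed=seed, **self.model_dump())


def _default_populations() -> list[PopulationModel]:
    from .simulate import A549_PARAMS, CAL27_PARAMS
    return [PopulationModel(**{
        f: getattr(p, f) for f in PopulationModel.model_fields
    }) for p in (A549_PARAMS, CAL27_PARAMS)]


class RunConfig(_Model):
    """Top-level pipeline configuration."""

    populations: list[PopulationModel] = Field(
        default_factory=_default_populations)
    n_cells_per_type: int = 500
    channel: ChannelModel = Field(default_factory=ChannelModel)
    detection: DetectionModel = Field(default_factory=DetectionModel)
    calibration: CalibrationModel = Field(default_factory=CalibrationModel)
    training: TrainModel = Field(default_factory=TrainModel)
    sequence_length: int = 256
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @property
    def geometry(self) -> GeometryModel:
        return GeometryModel(
            window_length_um=self.channel.window_length_um,
            cross_section_um2=self.channel.cross_section_um2,
        )


def load_config(path: Path | str | None = None, **overrides) -> RunConfig:
    """Load a YAML or JSON run configuration (defaults if no path given)."""
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
    data.update(overrides)
    return RunConfig(**data)
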