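"""End-to-end pipeline: simulate -> detect -> quantify -> classify.

Each stage is a standalone function operating on a run directory, so the
CLI subcommands and :func:`run_pipeline` (which simply chains the stages)
produce identical artifacts by construction.  A single global seed is
expanded into per-stage child seeds by hashing ``(seed, stage-key)``, so
every stage is independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._version import __version__
from .classify import (FeatureTable, SequenceDataset, resample_sequence,
                       train_ffnn, train_lstm)
from .config import RunConfig
from .fcs import write_fcs
from .io import read_trace, write_ground_truth, write_trace
from .pulses import (DetectionSettings, LadderFit, MatchResult, PulseEvent,
                     detect_events, estimate_background, fit_ladder,
                     match_channels, median_filter)
from .quantify import (CalibrationCurve, GeometryModel, apply_compensation,
                       fit_calibration_curve, intensity_to_copies,
                       kinematics_from_pulse, molecules_in_volume)
from .simulate import (ChannelConfig, GroundTruthCell, PopulationParams,
                       RawTrace, render_calibration_series, render_trace,
                       sample_population)

log = logging.getLogger("ladderflow")

__all__ = [
    "child_seed", "process_trace", "build_calibration_curves",
    "quantify_matched", "simulate_and_quantify", "run_pipeline",
    "stage_simulate", "stage_detect", "stage_quantify", "stage_classify",
    "export_fcs", "ProcessResult",
]


def child_seed(seed: int, key: str) -> int:
    """Deterministic per-stage child seed derived from the global seed."""
    digest = hashlib.sha256(f"{seed}:{key}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2 ** 31)


@dataclass
class ProcessResult:
    """Everything the detection chain extracted from one trace."""

    matched: MatchResult
    fits_per_channel: list[list[LadderFit]]
    events_per_channel: list[list[PulseEvent]]
    background_mean: np.ndarray
    background_sd: np.ndarray
    matched_events: list[tuple[PulseEvent, PulseEvent, PulseEvent]] = field(
        default_factory=list)


def process_trace(trace: RawTrace, settings: DetectionSettings
                  ) -> ProcessResult:
    """Filter, estimate background, detect, ladder-fit and match a trace."""
    filtered = median_filter(trace, settings.effective_median_window)
    background = estimate_background(filtered, settings.threshold_k)
    events = detect_events(filtered, settings, background)

    fits_per_channel: list[list[LadderFit]] = []
    fit_to_event: dict[int, PulseEvent] = {}
    for c, ch_events in enumerate(events):
        fits: list[LadderFit] = []
        for ev in ch_events:
            fit = fit_ladder(ev, trace.sample_rate_hz,
                             baseline_mV=background.mean[c])
            if not fit.converged:
                log.warning("channel %d: ladder fit did not converge for "
                            "event at sample %d; excluded", c, ev.start)
                continue
            fits.append(fit)
            fit_to_event[id(fit)] = ev
        fits_per_channel.append(fits)

    matched = match_channels(fits_per_channel,
                             settings.coincidence_tolerance_ms)
    matched_events = [tuple(fit_to_event[id(f)] for f in m.fits)
                      for m in matched.matched]
    return ProcessResult(matched=matched, fits_per_channel=fits_per_channel,
                         events_per_channel=events,
                         background_mean=background.mean,
                         background_sd=background.sd,
                         matched_events=matched_events)


def build_calibration_curves(
    cfg: ChannelConfig,
    dilutions,
    stock_concentration_nM,
    seed: int,
    noise_sd_mV: float = 0.0,
) -> list[CalibrationCurve]:
    """Render the gradient dilution series and fit one line per channel."""
    import copy
    cal_cfg = copy.deepcopy(cfg)
    cal_cfg.noise_sd_mV = noise_sd_mV
    stock_molar = np.asarray(stock_concentration_nM, dtype=float) * 1e-9
    series = render_calibration_series(dilutions, stock_molar, cal_cfg, seed)
    geometry = cfg.geometry
    curves = []
    for c in range(3):
        points = []
        for dil, trace in series:
            n_mol = molecules_in_volume(stock_molar[c] / dil, geometry)
            points.append((n_mol, float(trace.values[c].mean())))
        curves.append(fit_calibration_curve(points, channel=str(c)))
    return curves


def quantify_matched(
    matched: MatchResult,
    curves: list[CalibrationCurve],
    geometry: GeometryModel,
    background_mean: np.ndarray,
    spillover: np.ndarray | None = None,
    equivalence_factor: float = 1.0,
) -> pd.DataFrame:
    """Convert matched ladder fits into per-cell records.

    Plateau amplitudes (above baseline) are optionally compensated with the
    spillover matrix, shifted back to the absolute calibration scale with
    the trace background mean, and converted through the per-channel
    calibration curves.  Timing is averaged over the three channels and
    inverted into velocity/diameter.
    """
    rows = []
    for i, m in enumerate(matched.matched):
        plateau = m.plateaus_mV
        if spillover is not None:
            plateau = apply_compensation(plateau, spillover)
        copies, clipped = [], []
        for c in range(3):
            n, was_clipped = intensity_to_copies(
                plateau[c] + background_mean[c], curves[c],
                equivalence_factor)
            copies.append(n)
            clipped.append(was_clipped)
        t_a = float(np.mean([f.t_a_ms for f in m.fits]))
        t_s = float(np.mean([f.t_s_ms for f in m.fits]))
        t_d = float(np.mean([f.t_d_ms for f in m.fits]))
        velocity, diameter, transit = kinematics_from_pulse(
            t_a, t_s, t_d, geometry)
        rows.append({
            "cell_id": i,
            "t_center_s": m.t_center_s,
            "copies_fitc": copies[0],
            "copies_pe": copies[1],
            "copies_percp": copies[2],
            "clipped_any": any(clipped),
            "diameter_um": diameter,
            "velocity_um_per_ms": velocity,
            "transit_ms": transit,
            "i_f1_mV": m.fits[0].i_f_mV,
            "i_f2_mV": m.fits[1].i_f_mV,
            "i_f3_mV": m.fits[2].i_f_mV,
        })
    return pd.DataFrame(rows)


def simulate_and_quantify(
    params: PopulationParams,
    n_cells: int,
    cfg: ChannelConfig,
    settings: DetectionSettings,
    seed: int,
    curves: list[CalibrationCurve] | None = None,
    equivalence_factor: float = 1.0,
    chunk_size: int = 250,
    collect_sequences: int = 0,
) -> tuple[pd.DataFrame, list[GroundTruthCell], dict]:
    """Full in-memory pipeline for one population.

    Cells are rendered and processed in chunks of ``chunk_size`` so traces
    of thousands of cells never materialise at once.  If ``curves`` is None
    a noiseless default calibration is built.  Returns (cell records,
    ground-truth cells, stage statistics); when ``collect_sequences`` > 0,
    resampled matched pulse matrices are included in the statistics dict
    under ``"sequences"``.
    """
    if curves is None:
        from .config import DEFAULT_DILUTIONS, DEFAULT_STOCK_NM
        curves = build_calibration_curves(
            cfg, DEFAULT_DILUTIONS, DEFAULT_STOCK_NM,
            child_seed(seed, "calibration"))

    records, truth, seq_list = [], [], []
    stats = {"n_injected": 0, "n_detected": [0, 0, 0], "n_matched": 0,
             "n_dropped": 0, "n_clipped": 0}
    n_chunks = int(np.ceil(n_cells / chunk_size)) if n_cells else 0
    spill = cfg.spillover if not np.allclose(cfg.spillover, np.eye(3)) else None
    for k in range(n_chunks):
        m = min(chunk_size, n_cells - k * chunk_size)
        cells = sample_population(params, m, child_seed(seed, f"pop{k}"),
                                  window_length_um=cfg.window_length_um)
        trace = render_trace(cells, cfg, child_seed(seed, f"trace{k}"))
        result = process_trace(trace, settings)
        df = quantify_matched(result.matched, curves, cfg.geometry,
                              result.background_mean, spillover=spill,
                              equivalence_factor=equivalence_factor)
        df["cell_id"] += sum(len(r) for r in records)
        records.append(df)
        truth.extend(cells)
        stats["n_injected"] += m
        for c in range(3):
            stats["n_detected"][c] += len(result.fits_per_channel[c])
        stats["n_matched"] += len(result.matched.matched)
        stats["n_dropped"] += result.matched.n_dropped
        stats["n_clipped"] += int(df["clipped_any"].sum()) if len(df) else 0
        if collect_sequences:
            for evs in result.matched_events:
                seq_list.append(_matched_sequence(
                    evs, result.background_mean, collect_sequences))
    out = pd.concat(records, ignore_index=True) if records else pd.DataFrame()
    if collect_sequences:
        stats["sequences"] = (np.stack(seq_list)
                              if seq_list else np.empty((0, 0, 3)))
    log.info("%s: injected=%d detected=%s matched=%d dropped=%d clipped=%d",
             params.name, stats["n_injected"], stats["n_detected"],
             stats["n_matched"], stats["n_dropped"], stats["n_clipped"])
    return out, truth, stats


def _matched_sequence(events: tuple[PulseEvent, ...],
                      background_mean: np.ndarray, length: int) -> np.ndarray:
    """Common-support, baseline-subtracted (length, 3) pulse matrix."""
    start = min(e.start for e in events)
    end = max(e.end for e in events)
    mat = np.zeros((end - start, 3))
    for c, e in enumerate(events):
        mat[e.start - start:e.end - start, c] = e.segment - background_mean[c]
    return resample_sequence(mat, length)


# ---------------------------------------------------------------------------
# run-directory stages

def _provenance(config: RunConfig) -> dict:
    return {"config_hash": config.config_hash(), "seed": config.seed,
            "version": __version__}


def _write_csv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    prov = _provenance(config)
    with open(path, "w") as fh:
        for k, v in prov.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def _read_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def stage_simulate(config: RunConfig, out: Path) -> None:
    """Render per-population cell traces, ground truth and the calibration
    dilution series into ``out``."""
    out = Path(out)
    (out / "traces").mkdir(parents=True, exist_ok=True)
    (out / "calibration").mkdir(exist_ok=True)
    cfg = config.channel.to_config()
    meta = _provenance(config)
    for k, pop in enumerate(config.populations):
        params = pop.to_params()
        cells = sample_population(params, config.n_cells_per_type,
                                  child_seed(config.seed, f"pop{k}"),
                                  window_length_um=cfg.window_length_um)
        trace = render_trace(cells, cfg, child_seed(config.seed, f"trace{k}"))
        write_trace(trace, out / "traces" / f"{params.name}.parquet", meta)
        write_ground_truth(cells, out / "traces" / f"{params.name}_truth.csv")
    import copy
    cal_cfg = copy.deepcopy(cfg)
    cal_cfg.noise_sd_mV = config.calibration.noise_sd_mV
    stock_molar = np.asarray(config.calibration.stock_concentration_nM) * 1e-9
    series = render_calibration_series(
        config.calibration.dilutions, stock_molar, cal_cfg,
        child_seed(config.seed, "calibration"))
    for dil, trace in series:
        write_trace(trace, out / "calibration" / f"dilution_{dil:g}.parquet",
                    {**meta, "dilution": dil})
    (out / "calibration" / "series.json").write_text(json.dumps({
        "dilutions": list(config.calibration.dilutions),
        "stock_concentration_nM":
            list(config.calibration.stock_concentration_nM),
        **meta}, indent=1))


def stage_detect(config: RunConfig, out: Path) -> None:
    """Detect, ladder-fit and match events on every simulated trace."""
    out = Path(out)
    (out / "events").mkdir(parents=True, exist_ok=True)
    settings = config.detection.to_settings()
    background = {}
    for pop in config.populations:
        trace = read_trace(out / "traces" / f"{pop.name}.parquet")
        result = process_trace(trace, settings)
        rows = []
        seqs = []
        for i, m in enumerate(result.matched.matched):
            row = {"cell_id": i, "t_center_s": m.t_center_s}
            for c, tag in enumerate(("1", "2", "3")):
                f = m.fits[c]
                row.update({f"t_a{tag}_ms": f.t_a_ms, f"t_s{tag}_ms": f.t_s_ms,
                            f"t_d{tag}_ms": f.t_d_ms, f"i_f{tag}_mV": f.i_f_mV,
                            f"residual{tag}_mV": f.fit_residual_mV})
            rows.append(row)
        for evs in result.matched_events:
            seqs.append(_matched_sequence(evs, result.background_mean,
                                          config.sequence_length))
        _write_csv(pd.DataFrame(rows), out / "events" / f"{pop.name}.csv",
                   config)
        np.savez(out / "events" / f"{pop.name}_sequences.npz",
                 sequences=np.stack(seqs) if seqs
                 else np.empty((0, config.sequence_length, 3)))
        background[pop.name] = {
            "mean_mV": result.background_mean.tolist(),
            "sd_mV": result.background_sd.tolist(),
            "n_dropped": result.matched.n_dropped,
        }
    (out / "events" / "background.json").write_text(
        json.dumps({**background, **_provenance(config)}, indent=1))


def stage_quantify(config: RunConfig, out: Path) -> None:
    """Fit calibration curves and convert matched events to cell records."""
    out = Path(out)
    cfg = config.channel.to_config()
    geometry = config.geometry
    stock_molar = np.asarray(config.calibration.stock_concentration_nM) * 1e-9
    curves = []
    levels: dict[float, np.ndarray] = {}
    for dil in config.calibration.dilutions:
        trace = read_trace(out / "calibration" / f"dilution_{dil:g}.parquet")
        levels[dil] = trace.values.mean(axis=1)
    for c in range(3):
        points = [(molecules_in_volume(stock_molar[c] / dil, geometry),
                   float(levels[dil][c]))
                  for dil in config.calibration.dilutions]
        curves.append(fit_calibration_curve(points, channel=str(c)))
    (out / "calibration" / "curves.json").write_text(json.dumps({
        "curves": [{
            "channel": cv.channel,
            "slope_mV_per_molecule": cv.slope_mV_per_molecule,
            "intercept_mV": cv.intercept_mV,
            "r_squared": cv.r_squared,
            "points": cv.points,
        } for cv in curves],
        **_provenance(config)}, indent=1))

    background = json.loads((out / "events" / "background.json").read_text())
    spill = np.array(config.channel.spillover)
    spill_arg = None if np.allclose(spill, np.eye(3)) else spill
    frames = []
    for label, pop in enumerate(config.populations):
        df = _read_csv(out / "events" / f"{pop.name}.csv")
        bg = np.array(background[pop.name]["mean_mV"])
        rows = []
        for r in df.itertuples():
            plateau = np.array([r.i_f1_mV, r.i_f2_mV, r.i_f3_mV])
            if spill_arg is not None:
                plateau = apply_compensation(plateau, spill_arg)
            copies, clipped = [], []
            for c in range(3):
                n, was = intensity_to_copies(
                    plateau[c] + bg[c], curves[c],
                    config.calibration.equivalence_factor)
                copies.append(n)
                clipped.append(was)
            t_a = np.mean([r.t_a1_ms, r.t_a2_ms, r.t_a3_ms])
            t_s = np.mean([r.t_s1_ms, r.t_s2_ms, r.t_s3_ms])
            t_d = np.mean([r.t_d1_ms, r.t_d2_ms, r.t_d3_ms])
            velocity, diameter, transit = kinematics_from_pulse(
                t_a, t_s, t_d, geometry)
            rows.append({
                "cell_id": r.cell_id, "label": label, "cell_type": pop.name,
                "t_center_s": r.t_center_s,
                "copies_fitc": copies[0], "copies_pe": copies[1],
                "copies_percp": copies[2], "clipped_any": any(clipped),
                "diameter_um": diameter, "velocity_um_per_ms": velocity,
                "transit_ms": transit,
            })
        frames.append(pd.DataFrame(rows))
    _write_csv(pd.concat(frames, ignore_index=True),
               out / "cell_records.csv", config)


def stage_classify(config: RunConfig, out: Path) -> dict:
    """Train the FFNN on copy-number features and the LSTM on raw pulses."""
    out = Path(out)
    (out / "reports").mkdir(parents=True, exist_ok=True)
    records = _read_csv(out / "cell_records.csv")
    cfg = config.training.to_config(child_seed(config.seed, "train"))

    features = FeatureTable(
        records[["copies_fitc", "copies_pe", "copies_percp"]].to_numpy(),
        records["label"].to_numpy())
    ffnn = train_ffnn(features, cfg)

    seq_arrays, seq_labels = [], []
    for label, pop in enumerate(config.populations):
        arr = np.load(out / "events" / f"{pop.name}_sequences.npz")["sequences"]
        seq_arrays.append(arr)
        seq_labels.append(np.full(len(arr), label))
    sequences = SequenceDataset(np.concatenate(seq_arrays),
                                np.concatenate(seq_labels))
    lstm = train_lstm(sequences, cfg)

    reports = {"ffnn": ffnn.to_dict(), "lstm": lstm.to_dict()}
    for name, rep in reports.items():
        (out / "reports" / f"{name}.json").write_text(json.dumps(
            {**rep, **_provenance(config)}, indent=1))
        np.savetxt(out / "reports" / f"{name}_confusion.csv",
                   np.asarray(rep["confusion_test"]), fmt="%d", delimiter=",")
    return reports


def run_pipeline(config: RunConfig, out: Path | str) -> dict:
    """Execute simulate -> detect -> quantify -> classify into ``out``.

    Identical config+seed produce byte-identical artifacts.  Stage errors
    abort with a stage-labelled diagnostic; artifacts of completed stages
    are retained.
    """
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_meta.json").write_text(json.dumps(_provenance(config),
                                                 indent=1))
    stages = [("simulate", stage_simulate), ("detect", stage_detect),
              ("quantify", stage_quantify), ("classify", stage_classify)]
    reports: dict = {}
    for name, fn in stages:
        log.info("stage %s ...", name)
        try:
            result = fn(config, out)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        if name == "classify":
            reports = result
    return reports


def export_fcs(records: pd.DataFrame, path: Path | str) -> Path:
    """Export cell records as an FCS 3.1 file.

    Parameters: FITC-A / PE-A / PerCP-A copy numbers, Width (transit ms)
    and Diameter (um); $TOT equals the record count.  Cells whose
    calibrated copies were clipped to zero are counted in the
    LADDERFLOW_CLIPPED keyword.
    """
    if len(records) == 0:
        raise ValueError("cannot export zero records")
    data = records[["copies_fitc", "copies_pe", "copies_percp",
                    "transit_ms", "diameter_um"]].to_numpy()
    n_clipped = int(records["clipped_any"].sum()) \
        if "clipped_any" in records else 0
    return write_fcs(path, data,
                     ["FITC-A", "PE-A", "PerCP-A", "Width", "Diameter"],
                     extra_keywords={"LADDERFLOW_CLIPPED": str(n_clipped)})
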