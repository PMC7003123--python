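"""End-to-end orchestration: simulate or load recordings, align, compute
per-event CCFs and accuracy regressions, and write a report bundle."""

from __future__ import annotations

import importlib.resources
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alignment import (
    FramePolicy,
    build_trend,
    filter_frames,
    pair_series,
    restrict_to_event,
)
from .ccf import MODERATE_THRESHOLD, ccf_trend, classify_strength, summarize_events
from .exceptions import (
    ConfigError,
    InsufficientDataError,
    RegressionError,
    UndefinedCorrelationError,
    ValidationError,
)
from .io import (
    read_events,
    read_hr_file,
    read_pulse_file,
    write_events,
    write_hr_file,
    write_pulse_file,
)
from .regression import event_accuracy, fit_accuracy_regression
from .series import AFEvent, Device, EventTable
from .synthetic import (
    DeficitModel,
    DeviceModel,
    RhythmParams,
    apply_pulse_deficit,
    compose_recording,
    derive_telemetry_hr,
    sample_device,
)

logger = logging.getLogger(__name__)

_DEVICE_FACTORIES = {
    Device.FBT: DeviceModel.fbt,
    Device.AWW: DeviceModel.aww,
    Device.AWS: DeviceModel.aws,
}


@dataclass(frozen=True)
class RunConfig:
    """Pipeline run configuration.

    Exactly one of ``scenario`` (a YAML path or an equivalent dict, to be
    simulated) and the input paths (``hr_path`` + ``pulse_paths`` +
    ``events_path``) must be given.
    """

    out_dir: Path
    scenario: object | None = None
    hr_path: Path | None = None
    pulse_paths: tuple[Path, ...] = ()
    events_path: Path | None = None
    window_size: int = 10
    frame_policy: FramePolicy = field(default_factory=FramePolicy)
    seed: int = 0

    def __post_init__(self) -> None:
        has_inputs = bool(self.hr_path or self.pulse_paths or self.events_path)
        if self.scenario is not None and has_inputs:
            raise ConfigError("give either a scenario or input paths, not both")
        if self.scenario is None and not (
            self.hr_path and self.pulse_paths and self.events_path
        ):
            raise ConfigError(
                "need a scenario, or all of hr_path, pulse_paths, events_path"
            )


@dataclass
class ReportBundle:
    events_ccf: pd.DataFrame
    counts: pd.DataFrame
    accuracy_events: pd.DataFrame
    accuracy_fits: pd.DataFrame
    manifest: dict
    out_dir: Path


def _build_device(cfg: dict) -> DeviceModel:
    cfg = dict(cfg)
    mode = Device(cfg.pop("mode"))
    return _DEVICE_FACTORIES[mode](**cfg)


def load_scenario(scenario) -> dict:
    """Load a scenario from a YAML path or pass a dict through."""
    if isinstance(scenario, dict):
        return scenario
    with open(scenario, "r", encoding="utf-8") as fh:
        loaded = yaml.safe_load(fh)
    if not isinstance(loaded, dict):
        raise ConfigError(f"scenario {scenario} is not a mapping")
    return loaded


def simulate_scenario(scenario, out_dir: Path, seed: int | None = None) -> dict:
    """Simulate a scenario and write its CSV inputs under ``out_dir``.

    Returns ``{"hr": path, "events": path, "pulse": [paths]}``.  The
    scenario's own ``seed`` is used unless ``seed`` is given.
    """
    sc = load_scenario(scenario)
    duration = float(sc["duration"])
    use_seed = int(sc.get("seed", 0) if seed is None else seed)
    rhythm = RhythmParams(**sc.get("rhythm", {}))
    schedule = [
        AFEvent(float(e["onset"]), float(e["offset"]), str(e.get("label", "")))
        for e in sc.get("events", [])
    ]
    devices = [_build_device(d) for d in sc.get("devices", [])]
    if not devices:
        raise ConfigError("scenario lists no devices")
    deficit = DeficitModel(**sc["deficit"]) if sc.get("deficit") else None

    rng = np.random.default_rng(use_seed)
    s_beats, s_def = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))
    beats, schedule = compose_recording(schedule, rhythm, duration, s_beats)
    perfused = (
        apply_pulse_deficit(beats, deficit, s_def) if deficit else beats
    )
    hr = derive_telemetry_hr(beats, duration)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    hr_path = out_dir / "hr.csv"
    write_hr_file(hr, hr_path)
    events_path = out_dir / "events.csv"
    write_events(EventTable(tuple(schedule)), events_path)
    pulse_paths = []
    for dev in devices:
        s_dev = int(rng.integers(0, 2**31 - 1))
        pulse = sample_device(perfused, dev, duration, s_dev)
        p = out_dir / f"pulse_{dev.mode.value.lower()}.csv"
        write_pulse_file(pulse, p)
        pulse_paths.append(p)
    return {"hr": hr_path, "events": events_path, "pulse": pulse_paths}


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Run the full analysis and write the report bundle to ``out_dir``.

    Outputs: ``events_ccf.csv`` (per event and device), ``counts.csv``
    (per-device strength counts), ``accuracy_events.csv`` and
    ``accuracy_fits.csv`` (per-event statistics and across-event
    regressions), and ``manifest.json``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.scenario is not None:
        inputs = simulate_scenario(
            config.scenario, out_dir / "inputs", seed=config.seed
        )
        hr_path, events_path = inputs["hr"], inputs["events"]
        pulse_paths = inputs["pulse"]
    else:
        hr_path, events_path = config.hr_path, config.events_path
        pulse_paths = list(config.pulse_paths)

    hr = read_hr_file(hr_path)
    events = read_events(events_path)
    if len(events) == 0:
        raise ValidationError(f"{events_path}: no events to analyze")

    ccf_rows, acc_records, skipped = [], [], []
    for p_path in pulse_paths:
        pulse = read_pulse_file(p_path)
        device = pulse.device.value if pulse.device else "unknown"
        pairs = pair_series(pulse, hr)
        trend = filter_frames(
            build_trend(pairs, config.window_size), config.frame_policy
        )
        for i, ev in enumerate(events, start=1):
            ev_id = ev.label or i
            sub = restrict_to_event(trend, ev)
            try:
                ccf_rows.append((ev_id, device, ccf_trend(sub)))
            except (InsufficientDataError, UndefinedCorrelationError) as exc:
                skipped.append(
                    {"event_id": ev_id, "device": device, "reason": str(exc)}
                )
                logger.warning("event %s / %s skipped: %s", ev_id, device, exc)
            try:
                acc_records.append(event_accuracy(sub, ev_id, device))
            except InsufficientDataError:
                pass

    events_ccf, counts = summarize_events(ccf_rows)
    accuracy_events = pd.DataFrame(
        [vars(a) for a in acc_records],
        columns=["event_id", "device", "mean_P", "mean_H", "sd_P", "sd_H",
                 "n_points"],
    )
    fit_rows = []
    for device in sorted({a.device for a in acc_records}):
        per_dev = [a for a in acc_records if a.device == device]
        for stat in ("mean", "sd"):
            try:
                fit = fit_accuracy_regression(per_dev, stat)
            except RegressionError as exc:
                logger.warning("%s %s regression skipped: %s", device, stat, exc)
                continue
            fit_rows.append(
                {"device": device, "statistic": stat, **vars(fit)}
            )
    accuracy_fits = pd.DataFrame(
        fit_rows,
        columns=["device", "statistic", "intercept", "slope", "r_squared",
                 "p_value", "n_events"],
    )

    manifest = {
        "package": "ppgtrend",
        "version": __version__,
        "seed": config.seed,
        "window_size": config.window_size,
        "frame_policy": vars(config.frame_policy),
        "inputs": {
            "hr": str(hr_path),
            "events": str(events_path),
            "pulse": [str(p) for p in pulse_paths],
        },
        "scenario": (
            str(config.scenario)
            if not isinstance(config.scenario, dict)
            else config.scenario
        ),
        "skipped": skipped,
    }

    events_ccf.to_csv(out_dir / "events_ccf.csv", index=False,
                      float_format="%.6g")
    counts.to_csv(out_dir / "counts.csv", index=False, float_format="%.6g")
    accuracy_events.to_csv(out_dir / "accuracy_events.csv", index=False,
                           float_format="%.6g")
    accuracy_fits.to_csv(out_dir / "accuracy_fits.csv", index=False,
                         float_format="%.6g")
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return ReportBundle(events_ccf, counts, accuracy_events, accuracy_fits,
                        manifest, out_dir)


# ---------------------------------------------------------------------------
# Published reference values

def reference_fixture_path() -> Path:
    """Path of the packaged per-event reference CCF table."""
    return Path(
        importlib.resources.files("ppgtrend") / "data" / "event_ccf_reference.csv"
    )


def load_reference_event_ccf(path=None) -> pd.DataFrame:
    """Load the published per-event CCF values (23 events; missing cells
    are events a device did not record)."""
    path = Path(path) if path is not None else reference_fixture_path()
    df = pd.read_csv(path, comment="#")
    expected = ["event_id", "aww_ccf", "fbt_ccf"]
    if list(df.columns) != expected:
        raise ValidationError(
            f"{path}: expected columns {','.join(expected)}"
        )
    return df


def reference_strength_counts(df: pd.DataFrame | None = None) -> pd.DataFrame:
    """Strength counts per device from the published per-event values.

    For each device: the number of analyzable events, the count with CCF
    above the moderate threshold (> 0.40), and the count classified very
    weak or negative.
    """
    if df is None:
        df = load_reference_event_ccf()
    rows = []
    for device, col in (("AWW", "aww_ccf"), ("FBT", "fbt_ccf")):
        vals = df[col].dropna().to_numpy(dtype=float)
        classes = [classify_strength(v) for v in vals]
        n = vals.size
        n_mod = int((vals > MODERATE_THRESHOLD).sum())
        n_weak = sum(c.name in ("negative", "very_weak") for c in classes)
        rows.append(
            {
                "device": device,
                "n_events": n,
                "n_moderate_or_higher": n_mod,
                "frac_moderate_or_higher": n_mod / n if n else 0.0,
                "n_very_weak_or_negative": n_weak,
            }
        )
    return pd.DataFrame(rows)
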