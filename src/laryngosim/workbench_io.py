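"""Run configuration, result serialization and manifests.

A :class:`RunConfig` collects everything a reproducible run needs (gains,
delays, grid, schedule, seed); results are written as CSV traces plus a
JSON summary, finished by an atomically-written manifest listing every
output file with the config hash and map provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .controller import ControllerGains, DelayConfig
from .forward_map import GridSpec
from .paradigms import ParadigmResult, PerturbationSchedule

__all__ = ["RunConfig", "RunManifest", "ConfigError", "load_config",
           "save_config", "write_results"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


@dataclass(frozen=True)
class RunConfig:
    """Fully serializable description of one run."""

    paradigm: str = "reflexive"          # reflexive|adaptive|equivalence|prosody|fit|fixture
    gains: ControllerGains = field(default_factory=ControllerGains)
    delays: DelayConfig = field(default_factory=DelayConfig)
    grid: GridSpec = field(default_factory=GridSpec.test_grid)
    map_path: str | None = None          # cached forward map (.npz base path)
    pert_magnitude_cents: float = 100.0
    pert_onset_s: float = 0.5
    x0: tuple[float, float] = (0.169, 0.175)
    ps: float = 800.0
    utterance_ms: float = 3050.0
    seed: int = 0
    out_dir: str = "results"

    def schedule(self) -> PerturbationSchedule:
        if self.paradigm == "adaptive":
            return PerturbationSchedule.adaptive(self.pert_magnitude_cents)
        return PerturbationSchedule.reflexive(self.pert_magnitude_cents,
                                              self.pert_onset_s)

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


_NESTED = {"gains": ControllerGains, "delays": DelayConfig, "grid": GridSpec}


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Build a validated RunConfig from a YAML file and/or overrides.

    Missing keys take the defaults (the published best-fit values:
    g_fb_aud = 0.5, lambda_ff = 0.1, P_s = 800 Pa, Case-B activations,
    3050-ms utterance).  Unknown keys raise :class:`ConfigError` listing
    them; nested invariant violations are aggregated.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config root must be a mapping, got {type(data)}")
    if overrides:
        data.update(overrides)

    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")

    errors: list[str] = []
    kwargs: dict = {}
    for key, value in data.items():
        if key in _NESTED and isinstance(value, dict):
            cls = _NESTED[key]
            sub_known = {f.name for f in dataclasses.fields(cls)}
            sub_unknown = set(value) - sub_known
            if sub_unknown:
                errors.append(f"unknown keys under '{key}': {sorted(sub_unknown)}")
                continue
            try:
                kwargs[key] = cls(**value)
            except (TypeError, ValueError) as exc:
                errors.append(f"{key}: {exc}")
        elif key == "x0" and isinstance(value, (list, tuple)):
            kwargs[key] = tuple(float(v) for v in value)
        else:
            kwargs[key] = value
    if errors:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(errors))
    try:
        return RunConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(cfg), sort_keys=True))


@dataclass
class RunManifest:
    """Written last; lists every produced file."""

    config_hash: str
    map_provenance: str
    version: str
    wall_clock_s: float
    created: str
    files: list[str]

    def write(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        tmp = out_dir / ".manifest.json.tmp"
        final = out_dir / "manifest.json"
        tmp.write_text(json.dumps(asdict(self), indent=2))
        tmp.replace(final)
        return final


def write_results(result: ParadigmResult, out_dir: str | Path,
                  config: RunConfig | None = None,
                  map_provenance: str = "",
                  t_start: float | None = None) -> RunManifest:
    """CSV trace + JSON summary + manifest for a paradigm result."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: list[str] = []

    if result.kind == "reflexive":
        utt = result.utterances[0] if result.utterances else None
        frame = pd.DataFrame({
            "t_ms": result.t_ms,
            "response_cents": result.response_cents,
        })
        if utt is not None:
            frame["f_o_hz"] = utt.f_produced
            frame["pert_cents"] = utt.pert_cents
            frame["a_CT"] = utt.x_eff[:, 0]
            frame["a_TA"] = utt.x_eff[:, 1]
        trace = out_dir / "reflexive_trace.csv"
        frame.to_csv(trace, index=False)
        files.append(trace.name)
        summary = {
            "kind": "reflexive",
            "baseline_f0_hz": result.baseline_f0,
            "steady_state_compensation_cents":
                float(-np.nanmean(result.response_cents[-100:])),
        }
    elif result.kind == "adaptive":
        frame = pd.DataFrame({
            "trial": np.arange(1, len(result.trial_adaptation_cents) + 1),
            "phase": list(result.phases),
            "pert_cents": list(result.schedule.magnitudes_cents),
            "adaptation_cents": result.trial_adaptation_cents,
        })
        trace = out_dir / "adaptive_trials.csv"
        frame.to_csv(trace, index=False)
        files.append(trace.name)
        summary = {
            "kind": "adaptive",
            "baseline_f0_hz": result.baseline_f0,
            "hold_mean_cents": result.phase_mean("hold"),
            "aftereffect_mean_cents": result.phase_mean("aftereffect"),
        }
    else:
        raise ValueError(f"cannot serialize paradigm kind {result.kind!r}")

    summary_path = out_dir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2))
    files.append(summary_path.name)

    manifest = RunManifest(
        config_hash=config.content_hash() if config else "",
        map_provenance=map_provenance,
        version=__version__,
        wall_clock_s=(time.time() - t_start) if t_start else 0.0,
        created=time.strftime("%Y-%m-%dT%H:%M:%S"),
        files=files,
    )
    manifest.write(out_dir)
    return manifest
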