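"""Readers/writers for sweep tables, channel/protocol configs and manifests.

Sweep dialect: tab-separated columns ``time_s voltage_mV current_pA
temperature_C`` preceded by ``# key = value`` metadata lines. Channel and
protocol configurations are YAML with an explicit units block; values may
also carry an inline unit tag (e.g. ``dH: "100 kcal/mol"``). No silent
unit coercion: unknown keys and unknown unit tags are errors.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .constants import JOULES_PER_KCAL
from .synth import ChannelSpec, Protocol, Segment, SweepRecord
from .thermo import AllostericParams, ThermoTransition

__version__ = "0.1.0"

SWEEP_COLUMNS = ["time_s", "voltage_mV", "current_pA", "temperature_C"]

_META_TYPES = {"seed": int, "n_channels": int, "leak_nS": float,
               "noise_sd_pA": float, "v_rev_mV": float, "gamma_ref_pS": float,
               "gamma_q10": float, "availability": float, "p2_voltage_mV": float}


class ParseError(ValueError):
    def __init__(self, path, line: int | None, message: str):
        loc = f"{path}:{line}" if line is not None else str(path)
        super().__init__(f"{loc}: {message}")
        self.path, self.line = path, line


def write_sweep_table(record: SweepRecord, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for key, value in record.meta.items():
            fh.write(f"# {key} = {value}\n")
        df = pd.DataFrame({
            "time_s": record.time, "voltage_mV": record.voltage,
            "current_pA": record.current, "temperature_C": record.temperature,
        })
        df.to_csv(fh, sep="\t", index=False, float_format="%.12g")
    return path


def _parse_meta_value(key: str, raw: str):
    caster = _META_TYPES.get(key)
    if caster is not None:
        try:
            return caster(float(raw)) if caster is int else caster(raw)
        except ValueError:
            return raw
    for caster in (int, float):
        try:
            return caster(raw)
        except ValueError:
            continue
    return raw


def read_sweep_table(path) -> SweepRecord:
    path = Path(path)
    meta: dict = {}
    header_line = 0
    with open(path) as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" not in body:
                raise ParseError(path, i + 1, f"malformed metadata line {body!r}")
            key, _, raw = body.partition("=")
            meta[key.strip()] = _parse_meta_value(key.strip(), raw.strip())
        else:
            header_line = i
            break
    else:
        raise ParseError(path, len(lines), "no data table found")
    try:
        df = pd.read_csv(path, sep="\t", skiprows=header_line)
    except Exception as err:
        raise ParseError(path, header_line + 1, f"cannot parse table: {err}") from err
    missing = [c for c in SWEEP_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(path, header_line + 1,
                         f"missing required column(s): {', '.join(missing)}")
    time = df["time_s"].to_numpy(float)
    if time.size > 1 and not np.all(np.diff(time) > 0):
        bad = int(np.nonzero(np.diff(time) <= 0)[0][0])
        raise ParseError(path, header_line + 2 + bad + 1,
                         "time_s not strictly increasing")
    return SweepRecord(time, df["voltage_mV"].to_numpy(float),
                       df["current_pA"].to_numpy(float),
                       df["temperature_C"].to_numpy(float), meta)


# ---------------------------------------------------------------------------
# Channel configuration

_ENERGY_UNITS = {"J/mol": 1.0, "kJ/mol": 1e3, "kcal/mol": JOULES_PER_KCAL}
_ENTROPY_UNITS = {"J/(mol*K)": 1.0, "J/(mol·K)": 1.0, "kJ/(mol*K)": 1e3,
                  "kJ/(mol·K)": 1e3, "cal/(mol*K)": 4.184, "cal/(mol·K)": 4.184}

_TRANSITION_KEYS = {"dH", "dS", "z"}
_CONFIG_KEYS = {"channel_name", "kind", "J", "L", "D", "csi", "units",
                "n_channels", "gamma_ref", "gamma_q10", "ion_in", "ion_out"}


class ConfigError(ValueError):
    pass


def _convert(value, units: dict[str, float], default_scale: float, path, key: str):
    """A value is either a bare number (scaled by the units block) or a
    string like '100 kcal/mol' with an explicit unit tag."""
    if isinstance(value, str):
        parts = value.split(None, 1)
        if len(parts) != 2:
            raise ConfigError(f"{path}: {key}: cannot parse {value!r}")
        num, tag = parts
        if tag not in units:
            raise ConfigError(f"{path}: {key}: unknown unit {tag!r} "
                              f"(expected one of {sorted(units)})")
        return float(num) * units[tag]
    if isinstance(value, (int, float)):
        return float(value) * default_scale
    raise ConfigError(f"{path}: {key}: expected number or 'number unit' string")


def _load_transition(raw: dict, units_block: dict, path, label: str) -> ThermoTransition:
    unknown = set(raw) - _TRANSITION_KEYS
    if unknown:
        raise ConfigError(f"{path}: {label}: unknown key(s) {sorted(unknown)}")
    for k in ("dH", "dS"):
        if k not in raw:
            raise ConfigError(f"{path}: {label}: missing required key {k!r}")
    e_scale = _ENERGY_UNITS[units_block.get("energy", "J/mol")]
    s_scale = _ENTROPY_UNITS[units_block.get("entropy", "J/(mol*K)")]
    return ThermoTransition(
        dH=_convert(raw["dH"], _ENERGY_UNITS, e_scale, path, f"{label}.dH"),
        dS=_convert(raw["dS"], _ENTROPY_UNITS, s_scale, path, f"{label}.dS"),
        z=float(raw.get("z", 0.0)),
    )


@dataclass(frozen=True)
class ChannelConfig:
    """Validated channel description: gating model plus patch parameters."""

    name: str
    model: AllostericParams | ThermoTransition
    csi: tuple[float, float] | None = None
    n_channels: int = 1000
    gamma_ref: float = 10.0
    gamma_q10: float = 1.5
    ion_in: tuple[str, float] = ("K", 130.0)
    ion_out: tuple[str, float] = ("K", 130.0)

    def channel_spec(self) -> ChannelSpec:
        return ChannelSpec(model=self.model, n_channels=self.n_channels,
                           gamma_ref=self.gamma_ref, gamma_q10=self.gamma_q10,
                           ion_in=self.ion_in, ion_out=self.ion_out,
                           csi=self.csi, name=self.name)


def load_config(path) -> ChannelConfig:
    """Load and validate a channel configuration file (YAML).

    Units are normalized to SI internally. Unknown keys are rejected; the
    units block declares defaults (energy J/mol unless stated), and any
    scalar may instead carry an inline tag, e.g. ``dH: "100 kcal/mol"``.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)}")
    for k in ("channel_name", "kind", "L"):
        if k not in raw:
            raise ConfigError(f"{path}: missing required key {k!r}")
    units_block = raw.get("units", {}) or {}
    for tag_key, table in (("energy", _ENERGY_UNITS), ("entropy", _ENTROPY_UNITS)):
        tag = units_block.get(tag_key)
        if tag is not None and tag not in table:
            raise ConfigError(f"{path}: units.{tag_key}: unknown unit {tag!r}")
    L = _load_transition(raw["L"], units_block, path, "L")
    kind = raw["kind"]
    if kind == "two_state":
        if "J" in raw or "D" in raw:
            raise ConfigError(f"{path}: two_state config must not define J or D")
        model: AllostericParams | ThermoTransition = L
    elif kind == "allosteric":
        if "J" not in raw or "D" not in raw:
            raise ConfigError(f"{path}: allosteric config requires J and D")
        D = float(raw["D"])
        if D < 0:
            raise ConfigError(f"{path}: D must be >= 0, got {D}")
        model = AllostericParams(J=_load_transition(raw["J"], units_block, path, "J"),
                                 L=L, D=D, name=str(raw["channel_name"]))
    else:
        raise ConfigError(f"{path}: kind must be 'two_state' or 'allosteric', got {kind!r}")
    csi = None
    if "csi" in raw and raw["csi"] is not None:
        csi_raw = raw["csi"]
        if set(csi_raw) != {"v_half", "q"}:
            raise ConfigError(f"{path}: csi block requires exactly v_half and q")
        csi = (float(csi_raw["v_half"]), float(csi_raw["q"]))
    ion_in = tuple(raw.get("ion_in", ("K", 130.0)))
    ion_out = tuple(raw.get("ion_out", ("K", 130.0)))
    return ChannelConfig(
        name=str(raw["channel_name"]), model=model, csi=csi,
        n_channels=int(raw.get("n_channels", 1000)),
        gamma_ref=float(raw.get("gamma_ref", 10.0)),
        gamma_q10=float(raw.get("gamma_q10", 1.5)),
        ion_in=(str(ion_in[0]), float(ion_in[1])),
        ion_out=(str(ion_out[0]), float(ion_out[1])),
    )


def load_protocol(path) -> Protocol:
    """Load a protocol configuration (YAML): segments, sampling, temperature."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    unknown = set(raw) - {"name", "segments", "sample_interval_ms", "temperature"}
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)}")
    segs = []
    for s in raw.get("segments", []):
        segs.append(Segment(s["kind"], float(s["v_start"]), float(s["v_end"]),
                            float(s["duration_ms"])))
    temp_raw = raw.get("temperature", 24.0)
    temp = (tuple(float(x) for x in temp_raw) if isinstance(temp_raw, (list, tuple))
            else float(temp_raw))
    return Protocol(segments=tuple(segs),
                    sample_interval=float(raw.get("sample_interval_ms", 0.1)),
                    temperature=temp, name=str(raw.get("name", "")))


# ---------------------------------------------------------------------------
# Run manifest

@dataclass
class RunManifest:
    """Machine-readable record of one pipeline run: inputs, seeds, outputs."""

    config_hash: str
    seeds: list[int]
    files: list[str] = field(default_factory=list)
    parameters: dict = field(default_factory=dict)
    software_version: str = __version__
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.timestamp:
            self.timestamp = _time.strftime("%Y-%m-%dT%H:%M:%S")

    @staticmethod
    def hash_config(obj) -> str:
        return hashlib.sha256(
            json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]

    def write(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n")
        return path

    @classmethod
    def read(cls, path) -> "RunManifest":
        data = json.loads(Path(path).read_text())
        return cls(**data)
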