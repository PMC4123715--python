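"""Access to the shipped channel parameterizations.

Six reference channels are shipped as config files: ``trpv1_like`` (heat-
gated two-state pore), ``shaker_like`` (obligatory sensor–gate coupling),
``ilt_like`` (decoupled, heat-activated), ``v2_like`` (decoupled, heat-
deactivated) and ``kv21_like`` / ``kv43_like`` (partial decoupling through
closed-state inactivation). They are calibrated to reproduce the measured
apparent charges and midpoints, not fitted to any recording.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .io import ChannelConfig, load_config

PRESET_NAMES = ("trpv1_like", "shaker_like", "ilt_like", "v2_like",
                "kv21_like", "kv43_like")


def preset_path(name: str) -> Path:
    if name not in PRESET_NAMES:
        raise KeyError(f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}")
    return Path(str(resources.files("kvtherm.presets").joinpath(f"{name}.yaml")))


def load_preset(name: str) -> ChannelConfig:
    return load_config(preset_path(name))
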