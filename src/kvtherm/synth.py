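"""Synthetic inside-out patch-clamp recordings.

Generates voltage-step / voltage-ramp sweeps with the structure of real
macropatch data: equilibrium gating of a thermodynamic channel model,
ohmic open-channel current with a Nernst reversal potential, a
temperature-dependent single-channel conductance (Q10 = 1.5 about a 22 °C
reference), linear leak reversing at 0 mV, Gaussian current noise, slow
temperature ramps (default 0.3 °C/s) recorded simultaneously with current,
and the triple-pulse protocol used to map closed-state inactivation.

Gating is evaluated at instantaneous equilibrium at each sample — the slow
heating rate is chosen precisely so that gating transitions equilibrate
during the temperature change; no kinetics are modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .constants import F, R, celsius_to_kelvin
from .thermo import AllostericParams, ThermoTransition, csi_availability, open_probability

__all__ = [
    "ChannelSpec",
    "Segment",
    "Protocol",
    "SweepRecord",
    "nernst_reversal",
    "synthesize_sweep",
    "synthesize_csi_family",
    "gv_step_protocol",
    "heating_protocol",
    "ramp_protocol",
]

GAMMA_T_REF = 22.0  # °C reference for single-channel conductance


def nernst_reversal(conc_in: float, conc_out: float, valence: int, temp: float) -> float:
    """Nernst reversal potential (R·T/(z·F))·ln([out]/[in]) in mV.

    Invariant under scaling both concentrations; 0 mV for symmetric
    solutions (e.g. 130 mM K+ on both faces of the patch).
    """
    if conc_in <= 0 or conc_out <= 0:
        raise ValueError("ion concentrations must be positive")
    if valence == 0:
        raise ValueError("valence must be non-zero")
    t_k = celsius_to_kelvin(temp)
    return (R * t_k / (valence * F)) * math.log(conc_out / conc_in) * 1e3


@dataclass(frozen=True)
class ChannelSpec:
    """A patch-worth of channels: gating model plus permeation properties.

    ``gamma_ref`` is the single-channel conductance (pS) at 22 °C; it grows
    with temperature as gamma_q10^((T−22)/10). Ion entries are
    (species, concentration mM) for the intracellular and extracellular
    faces; the reversal potential follows the Nernst relation on the
    concentrations (equal permeabilities assumed for substituted species).
    """

    model: AllostericParams | ThermoTransition
    n_channels: int = 1000
    gamma_ref: float = 10.0     # pS at 22 °C
    gamma_q10: float = 1.5
    ion_in: tuple[str, float] = ("K", 130.0)
    ion_out: tuple[str, float] = ("K", 130.0)
    csi: tuple[float, float] | None = None   # (v_half mV, q e0) availability
    name: str = ""

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.gamma_ref <= 0 or self.gamma_q10 <= 0:
            raise ValueError("gamma_ref and gamma_q10 must be positive")

    def gamma(self, temp_c) -> np.ndarray:
        """Single-channel conductance in pS at temperature ``temp_c`` (°C)."""
        return self.gamma_ref * self.gamma_q10 ** ((np.asarray(temp_c, dtype=float)
                                                    - GAMMA_T_REF) / 10.0)

    def reversal(self, temp_c: float) -> float:
        return nernst_reversal(self.ion_in[1], self.ion_out[1], 1, temp_c)


@dataclass(frozen=True)
class Segment:
    kind: Literal["hold", "step", "ramp"]
    v_start: float    # mV
    v_end: float      # mV
    duration: float   # ms

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("segment duration must be positive")
        if self.kind in ("hold", "step") and self.v_start != self.v_end:
            raise ValueError(f"{self.kind} segment must have v_start == v_end")


@dataclass(frozen=True)
class Protocol:
    """Ordered command-voltage segments plus the temperature track.

    ``temperature`` is either a constant (°C) or a (start °C, rate °C/s)
    pair describing a linear heating ramp running over the whole sweep.
    Default sampling is 10 kHz (0.1 ms); slow heating sweeps may use a
    coarser interval since gating is at equilibrium.
    """

    segments: tuple[Segment, ...]
    sample_interval: float = 0.1  # ms
    temperature: float | tuple[float, float] = 24.0
    name: str = ""

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        if self.sample_interval <= 0:
            raise ValueError("sample interval must be positive")

    @property
    def duration(self) -> float:
        """Total duration in ms."""
        return sum(s.duration for s in self.segments)

    def command(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Sampled (time s, voltage mV, temperature °C) series.

        Segment endpoints are reproduced exactly: each segment contributes
        samples on [start, end) of its interval, and the final sample of
        the sweep lands on the protocol end at the last segment's v_end.
        """
        dt = self.sample_interval
        t_parts, v_parts = [], []
        t0 = 0.0
        for seg in self.segments:
            n = max(int(round(seg.duration / dt)), 1)
            tt = t0 + dt * np.arange(n)
            frac = (tt - t0) / seg.duration
            v_parts.append(seg.v_start + (seg.v_end - seg.v_start) * frac)
            t_parts.append(tt)
            t0 += seg.duration
        t_parts.append(np.array([t0]))
        v_parts.append(np.array([self.segments[-1].v_end]))
        time_s = np.concatenate(t_parts) * 1e-3
        volt = np.concatenate(v_parts)
        if isinstance(self.temperature, tuple):
            t_start, rate = self.temperature
            temp = t_start + rate * time_s
        else:
            temp = np.full_like(time_s, float(self.temperature))
        return time_s, volt, temp


@dataclass
class SweepRecord:
    """One voltage-clamp sweep: simultaneous time/voltage/current/temperature."""

    time: np.ndarray         # s
    voltage: np.ndarray      # mV
    current: np.ndarray      # pA
    temperature: np.ndarray  # °C
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arrays = [np.asarray(a, dtype=float)
                  for a in (self.time, self.voltage, self.current, self.temperature)]
        self.time, self.voltage, self.current, self.temperature = arrays
        lengths = {a.size for a in arrays}
        if len(lengths) != 1:
            raise ValueError("sweep series must have equal length")
        if self.time.size > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")

    def with_current(self, current: np.ndarray, **meta) -> "SweepRecord":
        return SweepRecord(self.time, self.voltage, current, self.temperature,
                           {**self.meta, **meta})

    def select(self, mask: np.ndarray) -> "SweepRecord":
        """Sub-record of the samples where ``mask`` is True."""
        return SweepRecord(self.time[mask], self.voltage[mask],
                           self.current[mask], self.temperature[mask],
                           dict(self.meta))


def synthesize_sweep(spec: ChannelSpec, protocol: Protocol, leak_g: float = 0.0,
                     noise_sd: float = 0.5, seed: int = 0,
                     availability: float = 1.0) -> SweepRecord:
    """Simulate one sweep under the given protocol.

    At each sample::

        I = n·Po(V,T)·availability·γ(T)·(V − Vrev) + g_leak·V + ε,

    with γ(T) = gamma_ref·gamma_q10^((T−22)/10), ε ~ N(0, noise_sd²) pA,
    and the leak reversing at 0 mV. Identical seed and configuration give a
    bit-identical record. ``availability`` scales open probability by a
    steady-state CSI factor (used by the triple-pulse generator).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    time_s, volt, temp = protocol.command()
    po = open_probability(spec.model, volt, temp) * availability
    v_rev = spec.reversal(float(np.mean(temp)))
    # pS · mV = 1e-3 pA
    ionic = spec.n_channels * po * spec.gamma(temp) * (volt - v_rev) * 1e-3
    leak = leak_g * volt  # nS · mV = pA
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=volt.size) if noise_sd > 0 else 0.0
    current = ionic + leak + noise
    meta = {
        "channel": spec.name or type(spec.model).__name__,
        "seed": seed,
        "protocol": protocol.name or "custom",
        "leak_nS": leak_g,
        "noise_sd_pA": noise_sd,
        "v_rev_mV": v_rev,
        "n_channels": spec.n_channels,
        "gamma_ref_pS": spec.gamma_ref,
        "gamma_q10": spec.gamma_q10,
    }
    return SweepRecord(time_s, volt, current, temp, meta)


# ---------------------------------------------------------------------------
# Canonical protocols

def gv_step_protocol(step_v: float, hold_v: float = -100.0, hold_ms: float = 20.0,
                     step_ms: float = 50.0, temp: float = 24.0,
                     sample_interval: float = 0.1) -> Protocol:
    """Hold → depolarizing step → return to hold, at constant temperature."""
    return Protocol(
        segments=(
            Segment("hold", hold_v, hold_v, hold_ms),
            Segment("step", step_v, step_v, step_ms),
            Segment("hold", hold_v, hold_v, hold_ms),
        ),
        temperature=temp,
        sample_interval=sample_interval,
        name=f"gv_step_{step_v:+.0f}mV",
    )


def heating_protocol(v: float, t_start: float = 24.0, t_end: float = 48.0,
                     rate: float = 0.3, sample_interval: float = 10.0,
                     leak_hold_ms: float = 500.0,
                     leak_hold_v: float = -100.0) -> Protocol:
    """Constant command voltage while the bath heats linearly at ``rate`` °C/s.

    A brief initial hold at ``leak_hold_v`` (default −100 mV, 500 ms —
    thermally negligible at 0.3 °C/s) provides the closed-channel samples
    needed for leak estimation; pass ``leak_hold_ms=0`` to omit it.
    """
    if not t_end > t_start:
        raise ValueError("t_end must exceed t_start")
    duration_ms = (t_end - t_start) / rate * 1e3
    segments = (Segment("hold", v, v, duration_ms),)
    if leak_hold_ms > 0:
        segments = (Segment("hold", leak_hold_v, leak_hold_v, leak_hold_ms),) + segments
    return Protocol(
        segments=segments,
        temperature=(t_start, rate),
        sample_interval=sample_interval,
        name=f"heat_{v:+.0f}mV_{rate}Cps",
    )


def ramp_protocol(v_start: float = -100.0, v_end: float = 50.0,
                  ramp_ms: float = 200.0, hold_v: float = -100.0,
                  hold_ms: float = 20.0, temp: float = 24.0,
                  sample_interval: float = 0.1) -> Protocol:
    """Hold then linear voltage ramp (default −100→+50 mV in 200 ms)."""
    return Protocol(
        segments=(
            Segment("hold", hold_v, hold_v, hold_ms),
            Segment("ramp", v_start, v_end, ramp_ms),
        ),
        temperature=temp,
        sample_interval=sample_interval,
        name=f"ramp_{v_start:+.0f}to{v_end:+.0f}mV_{ramp_ms:.0f}ms",
    )


def synthesize_csi_family(spec: ChannelSpec, p2_voltages: Sequence[float],
                          p2_duration: float = 10.0, seed: int = 0,
                          p1_v: float = 40.0, pulse_ms: float = 50.0,
                          hold_v: float = -100.0, temp: float = 24.0,
                          leak_g: float = 0.0, noise_sd: float = 0.5,
                          ) -> list[tuple[SweepRecord, SweepRecord, SweepRecord]]:
    """Triple-pulse closed-state-inactivation families.

    For each conditioning voltage: P1 test pulse (``p1_v``), a long P2
    conditioning segment (default 10 s), then P3 identical to P1.
    Occupancy entering P3 is scaled by the steady-state availability at the
    P2 voltage (instantaneous-equilibration shortcut — P2 is long enough
    that CSI reaches steady state). With no CSI configured on the spec,
    availability is 1 and P3 reproduces P1.

    Returns one (P1, P2, P3) sweep triple per conditioning voltage.
    """
    if p2_duration <= 0:
        raise ValueError("p2_duration must be positive")
    triples = []
    for i, v2 in enumerate(p2_voltages):
        if spec.csi is None:
            avail = 1.0
        else:
            avail = float(csi_availability(v2, spec.csi[0], spec.csi[1], temp))
        pulse = gv_step_protocol(p1_v, hold_v=hold_v, step_ms=pulse_ms, temp=temp)
        p2_proto = Protocol(
            segments=(Segment("step", v2, v2, p2_duration * 1e3),),
            temperature=temp, sample_interval=10.0, name=f"csi_p2_{v2:+.0f}mV",
        )
        base = 1000 * seed + 3 * i
        p1 = synthesize_sweep(spec, pulse, leak_g, noise_sd, seed=base)
        p2 = synthesize_sweep(spec, p2_proto, leak_g, noise_sd, seed=base + 1)
        p3 = synthesize_sweep(spec, pulse, leak_g, noise_sd, seed=base + 2,
                              availability=avail)
        for rec, label in ((p1, "P1"), (p2, "P2"), (p3, "P3")):
            rec.meta.update(pulse_role=label, p2_voltage_mV=v2,
                            availability=avail if label == "P3" else 1.0)
        triples.append((p1, p2, p3))
    return triples
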