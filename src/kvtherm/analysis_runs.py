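"""Composed end-to-end runs: generator → measurement pipeline.

These glue functions express the standard experiments as single calls so
the command line, the analysis drivers and the tests all execute exactly
the same code path.
"""

from __future__ import annotations

import numpy as np

from .curves import Q10Profile, VantHoffEstimate
from .io import ChannelConfig
from .pipeline import (correct_conductance, extract_gv, isolate_voltage,
                       q10_voltage_profile, subtract_leak, vant_hoff)
from .presets_api import load_preset
from .synth import ChannelSpec, SweepRecord, gv_step_protocol, heating_protocol, \
    synthesize_sweep
from .thermo import open_probability

GV_WINDOW = (0.045, 0.065)  # s, inside the 20–70 ms step of gv_step_protocol


def _spec(channel: str | ChannelConfig | ChannelSpec) -> ChannelSpec:
    if isinstance(channel, str):
        channel = load_preset(channel)
    if isinstance(channel, ChannelConfig):
        channel = channel.channel_spec()
    return channel


def synth_gv_family(channel, temp: float, seed: int, steps=None,
                    leak_g: float = 0.05,
                    noise_sd: float = 0.5) -> tuple[list[SweepRecord], float]:
    """Voltage-step family for one channel at constant temperature.

    ``channel`` is a preset name, a :class:`ChannelConfig` or a
    :class:`ChannelSpec`. Returns the raw sweeps and the reversal potential.
    """
    spec = _spec(channel)
    if steps is None:
        steps = np.arange(-100.0, 51.0, 5.0)
    sweeps = [
        synthesize_sweep(spec, gv_step_protocol(v, temp=temp, sample_interval=0.5),
                         leak_g=leak_g, noise_sd=noise_sd, seed=seed * 4096 + k)
        for k, v in enumerate(steps)
    ]
    return sweeps, spec.reversal(temp)


def _corrected_gv(sweeps: list[SweepRecord], v_rev: float, do_subtract: bool):
    """(Optionally) leak-subtract, γ-correct to 22 °C, reduce to a G-V curve."""
    corrected = []
    for s in sweeps:
        if do_subtract:
            s = subtract_leak(s)
        corrected.append(s.with_current(
            correct_conductance(s.current, s.temperature), gamma_corrected=True))
    return extract_gv(corrected, v_rev=v_rev, window=GV_WINDOW)


def pipeline_q10_profile(channel, t1: float, t2: float, seed: int = 0,
                         steps=None, leak_g: float = 0.05,
                         noise_sd: float = 0.5,
                         do_subtract_leak: bool = True) -> Q10Profile:
    """Voltage-resolved Q10 measured the way an experiment would do it:
    two step families at t1 and t2, leak-subtracted, conductance-corrected,
    reduced to G-V curves and ratioed per voltage.

    Note the −100 mV leak reference also samples the residual open
    probability of a decoupled pore, so leak subtraction baselines the
    G-V foot against it — exactly as a real measurement would.
    ``do_subtract_leak=False`` (with ``leak_g=0``) bypasses that step when
    the pure profile arithmetic is wanted.
    """
    sweeps1, v_rev = synth_gv_family(channel, t1, seed, steps, leak_g, noise_sd)
    sweeps2, _ = synth_gv_family(channel, t2, seed + 1, steps, leak_g, noise_sd)
    gv1 = _corrected_gv(sweeps1, v_rev, do_subtract_leak)
    gv2 = _corrected_gv(sweeps2, v_rev, do_subtract_leak)
    if noise_sd > 0:
        # conductances below the noise floor of a G-V point carry no Q10
        # information; mark them undefined (3× the SD of the windowed
        # conductance estimate, which shrinks with the driving force)
        n_win = max(int((GV_WINDOW[1] - GV_WINDOW[0]) / 0.5e-3), 1)
        for gv in (gv1, gv2):
            sigma_g = noise_sd / np.sqrt(n_win) / np.abs(gv.voltages - v_rev)
            gv.conductances[np.abs(gv.conductances) < 3 * sigma_g] = np.nan
    return q10_voltage_profile(gv1, gv2)


def pipeline_vant_hoff(channel, voltage: float | None = None,
                       t1: float = 24.0, t2: float = 44.0, seed: int = 0,
                       leak_g: float = 0.05, noise_sd: float = 0.5,
                       n_bins: int = 50, po_band: tuple[float, float] = (1e-3, 0.9),
                       ) -> tuple[VantHoffEstimate, float]:
    """Van't Hoff ΔH/ΔS from a synthetic heating sweep at fixed voltage.

    If no voltage is given, one is chosen so the model open probability is
    ~2% midway through the heating range (currents measurable but far from
    saturation, the regime used for thermodynamic measurements). The sweep
    is leak-subtracted, the heating segment isolated, currents binned on
    temperature (``n_bins`` bins), and bins whose implied open probability
    falls outside ``po_band`` dropped (below: noise-dominated; above:
    saturated).

    Returns the estimate and the voltage used. At a voltage-sensitive
    transition the fitted enthalpy is the apparent value at that voltage,
    ΔH − z·F·V.
    """
    spec = _spec(channel)
    if voltage is None:
        grid = np.arange(-100.0, 601.0, 1.0)
        po_mid = open_probability(spec.model, grid, 0.5 * (t1 + t2))
        voltage = float(grid[np.argmin(np.abs(po_mid - 0.02))])
    proto = heating_protocol(voltage, t_start=t1, t_end=t2, sample_interval=10.0)
    sweep = subtract_leak(
        synthesize_sweep(spec, proto, leak_g=leak_g, noise_sd=noise_sd, seed=seed))
    sweep = isolate_voltage(sweep, voltage)
    edges = np.linspace(t1, t2, n_bins + 1)
    idx = np.clip(np.digitize(sweep.temperature, edges) - 1, 0, n_bins - 1)
    temps, currents = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            temps.append(float(np.mean(sweep.temperature[sel])))
            currents.append(float(np.mean(sweep.current[sel])))
    temps = np.asarray(temps)
    currents = np.asarray(currents)
    g_max_ref = spec.n_channels * spec.gamma_ref * 1e-3  # nS at 22 °C
    v_rev = spec.reversal(0.5 * (t1 + t2))
    po = (correct_conductance(currents, temps) / (voltage - v_rev)) / g_max_ref
    keep = (po > po_band[0]) & (po < po_band[1])
    est = vant_hoff(currents[keep], temps[keep], g_max_ref, voltage, v_rev)
    return est, voltage
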