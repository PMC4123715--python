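"""Headline quantities of the study, recomputed from the shipped presets.

Each function runs the relevant part of the package from scratch — no
cached numbers — and returns (value, problem size). The G-V recovery
experiments push synthetic noisy step families through the full
measurement pipeline (leak subtraction → G-V extraction → Boltzmann fit);
the Q10 quantities are noiseless model evaluations at the temperatures and
voltage grids of the corresponding measurements.
"""

from __future__ import annotations

import numpy as np

from .pipeline import extract_gv, fit_boltzmann, subtract_leak
from .presets_api import load_preset
from .synth import ChannelSpec, gv_step_protocol, synthesize_sweep
from .thermo import ThermoTransition, model_q10_profile, open_probability

__all__ = [
    "recover_boltzmann_fit",
    "trpv1_gv_recovery",
    "shaker_gv_recovery",
    "trp_min_q10",
    "shaker_mean_q10",
    "ilt_peak_q10",
    "v2_q10_heat_deactivation",
    "headline_quantities",
]


def recover_boltzmann_fit(v_half: float, q: float, step_voltages, n_patches: int,
                          seed: int, temp: float = 24.0, leak_g: float = 0.05,
                          noise_sd: float = 0.5):
    """Round-trip recovery of Boltzmann G-V parameters via the full pipeline.

    For each synthetic patch: channels gate as a two-state transition that
    reproduces the target single-Boltzmann curve exactly at ``temp``; a
    voltage-step family is simulated with leak and current noise, leak-
    subtracted, reduced to a G-V curve and refitted. Returns arrays of the
    fitted (v_half, q) across patches.
    """
    trans = ThermoTransition.from_boltzmann(v_half, q, temp)
    v_halfs, qs = [], []
    for patch in range(n_patches):
        spec = ChannelSpec(model=trans, name=f"synthetic_patch_{patch}")
        v_rev = spec.reversal(temp)
        sweeps = []
        for k, v_step in enumerate(step_voltages):
            proto = gv_step_protocol(v_step, temp=temp, sample_interval=0.5)
            sweeps.append(synthesize_sweep(
                spec, proto, leak_g=leak_g, noise_sd=noise_sd,
                seed=seed * 100003 + patch * 1009 + k))
        sweeps = [subtract_leak(s) for s in sweeps]
        gv = extract_gv(sweeps, v_rev=v_rev, window=(0.045, 0.065))
        fit = fit_boltzmann(gv)
        v_halfs.append(fit.v_half)
        qs.append(fit.q)
    return np.asarray(v_halfs), np.asarray(qs)


def trpv1_gv_recovery(seed: int = 1):
    """Mean fitted (v_half mV, q e0) for TRP-like shallow activation
    (generating values 114.9 mV, 0.76 e0; 4 patches as measured)."""
    steps = np.arange(-50.0, 271.0, 20.0)
    v_halfs, qs = recover_boltzmann_fit(114.9, 0.76, steps, n_patches=4, seed=seed)
    return float(np.mean(v_halfs)), float(np.mean(qs)), v_halfs.size


def shaker_gv_recovery(seed: int = 1):
    """Mean fitted (v_half mV, q e0) for steep Kv-type activation
    (generating values −54.2 mV, 5.1 e0; 5 patches as measured)."""
    steps = np.arange(-95.0, 16.0, 10.0)
    v_halfs, qs = recover_boltzmann_fit(-54.2, 5.1, steps, n_patches=5, seed=seed)
    return float(np.mean(v_halfs)), float(np.mean(qs)), v_halfs.size


def trp_min_q10():
    """Minimum Q10 of the two-state heat-gated pore over −100…+150 mV
    between 36.6 and 46.0 °C."""
    model = load_preset("trpv1_like").model
    grid = np.arange(-100.0, 151.0, 1.0)
    profile = model_q10_profile(model, 36.6, 46.0, grid)
    return float(np.nanmin(profile.q10)), grid.size


def shaker_mean_q10():
    """Mean Q10 of the strongly coupled channel over the activated range
    (−40…+50 mV) between 22.4 and 27.7 °C."""
    model = load_preset("shaker_like").model
    grid = np.arange(-40.0, 51.0, 1.0)
    profile = model_q10_profile(model, 22.4, 27.7, grid)
    return float(np.nanmean(profile.q10)), grid.size


def ilt_peak_q10():
    """Peak Q10 of the decoupled channel over −100…+100 mV between 25 and 35 °C."""
    model = load_preset("ilt_like").model
    grid = np.arange(-100.0, 101.0, 1.0)
    profile = model_q10_profile(model, 25.0, 35.0, grid)
    return float(np.nanmax(profile.q10)), grid.size


def v2_q10_heat_deactivation():
    """Q10 of the heat-deactivated channel between 25 and 35 °C, at the
    voltage whose 25 °C open probability is closest to 60% (the heating
    protocol for this channel steps to ~60% of maximal response; with the
    sign-flipped pore the channel is substantially open everywhere, so the
    closest-to-60% voltage is used)."""
    model = load_preset("v2_like").model
    grid = np.arange(-100.0, 151.0, 1.0)
    po25 = open_probability(model, grid, 25.0)
    i = int(np.argmin(np.abs(po25 - 0.6)))
    po35 = float(open_probability(model, grid[i], 35.0))
    return float((po35 / po25[i]) ** 1.0), 1


def headline_quantities(seed: int = 1) -> dict[str, dict]:
    """All headline numbers as {name: {"value": float, "n": int}}."""
    trp_vh, trp_q, trp_n = trpv1_gv_recovery(seed)
    sh_vh, sh_q, sh_n = shaker_gv_recovery(seed)
    out = {
        "trp_gv_vhalf_mV": (trp_vh, trp_n),
        "trp_gv_charge_e0": (trp_q, trp_n),
        "shaker_gv_vhalf_mV": (sh_vh, sh_n),
        "shaker_gv_charge_e0": (sh_q, sh_n),
        "trp_min_q10": trp_min_q10(),
        "shaker_mean_q10": shaker_mean_q10(),
        "ilt_peak_q10": ilt_peak_q10(),
        "v2_q10": v2_q10_heat_deactivation(),
    }
    return {k: {"value": v, "n": n} for k, (v, n) in out.items()}
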