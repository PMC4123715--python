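"""Measurement pipeline for patch-clamp sweeps.

Implements the analysis chain applied to each recording: linear leak
subtraction referenced at −100 mV, G-V extraction from step families,
single-Boltzmann fitting, correction of the single-channel conductance
temperature dependence (Q10 = 1.5 about 22 °C), Q10 measurement on heating
sweeps with automatic threshold detection, voltage-resolved Q10 profiles
from G-V pairs, Van't Hoff estimation of ΔH and ΔS, gating free-energy
shifts z·F·ΔV1/2, and closed-state-inactivation availability curves.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import expit

from .constants import F, R, celsius_to_kelvin
from .curves import (BoltzmannFit, EnergyShift, GVCurve, NoActivation,
                     Q10Measurement, Q10Profile, VantHoffEstimate)
from .synth import SweepRecord

__all__ = [
    "isolate_voltage",
    "subtract_leak",
    "extract_gv",
    "fit_boltzmann",
    "correct_conductance",
    "measure_q10",
    "q10_voltage_profile",
    "vant_hoff",
    "delta_g_shift",
    "csi_curve",
]


class LeakError(ValueError):
    pass


def subtract_leak(sweep: SweepRecord, leak_ref_v: float = -100.0,
                  v_tol: float = 0.25) -> SweepRecord:
    """Subtract linear leak estimated at a hyperpolarized reference voltage.

    Leak conductance is the mean current at ``leak_ref_v`` (where channels
    are closed, i.e. the holding segment) divided by the driving voltage;
    the leak at every sample is then g_leak·V (leak reverses at 0 mV).
    The estimated g_leak (nS) is recorded in the output metadata.
    """
    if leak_ref_v == 0:
        raise LeakError("leak reference voltage must be non-zero")
    mask = np.abs(sweep.voltage - leak_ref_v) < v_tol
    if not mask.any():
        raise LeakError(
            f"no holding samples at {leak_ref_v} mV in sweep "
            f"(protocol {sweep.meta.get('protocol', '?')!r}); "
            "leak subtraction needs a hyperpolarized holding segment"
        )
    g_leak = float(np.mean(sweep.current[mask])) / leak_ref_v  # pA/mV = nS
    corrected = sweep.current - g_leak * sweep.voltage
    return sweep.with_current(corrected, leak_nS_estimated=g_leak,
                              leak_subtracted=True)


def isolate_voltage(sweep: SweepRecord, v: float | None = None,
                    v_tol: float = 0.25) -> SweepRecord:
    """Sub-sweep at one command voltage (default: the voltage held longest).

    Used to strip the leak-reference holding prefix off heating sweeps
    before threshold detection, which requires a constant voltage.
    """
    if v is None:
        values, counts = np.unique(sweep.voltage, return_counts=True)
        v = float(values[np.argmax(counts)])
    mask = np.abs(sweep.voltage - v) < v_tol
    if not mask.any():
        raise ValueError(f"no samples at {v} mV in sweep")
    return sweep.select(mask)


def extract_gv(step_sweeps: list[SweepRecord], v_rev: float,
               window: tuple[float, float], v_rev_tol: float = 1.0) -> GVCurve:
    """Conductance–voltage curve from a family of voltage-step sweeps.

    For each sweep, G = (mean current in the time window) / (V − v_rev),
    where V is the (constant) commanded voltage inside the window, which
    must sit in the equilibrated portion of the step. Steps at the reversal
    potential are excluded with a warning (conductance undefined there).
    """
    t0, t1 = window
    if not t1 > t0:
        raise ValueError("measurement window must have positive length")
    voltages, conductances, temps = [], [], []
    for sweep in step_sweeps:
        in_win = (sweep.time >= t0) & (sweep.time <= t1)
        if not in_win.any():
            raise ValueError(f"empty measurement window ({t0}, {t1}) s for sweep "
                             f"{sweep.meta.get('protocol', '?')!r}")
        v_cmd = sweep.voltage[in_win]
        if np.ptp(v_cmd) > 1e-6:
            raise ValueError("measurement window must lie within a constant-voltage step")
        v_step = float(v_cmd[0])
        if abs(v_step - v_rev) < v_rev_tol:
            warnings.warn(f"step at {v_step} mV excluded: at reversal potential, "
                          "conductance undefined", stacklevel=2)
            continue
        i_mean = float(np.mean(sweep.current[in_win]))
        voltages.append(v_step)
        conductances.append(i_mean / (v_step - v_rev))  # pA/mV = nS
        temps.append(float(np.mean(sweep.temperature[in_win])))
    order = np.argsort(voltages)
    return GVCurve(np.asarray(voltages)[order], np.asarray(conductances)[order],
                   temperature=float(np.mean(temps)))


def _boltzmann_model(v, v_half, q, g_max, t_k):
    return g_max * expit(q * F * (v - v_half) * 1e-3 / (R * t_k))


def _init_boltzmann(v: np.ndarray, g: np.ndarray, t_k: float):
    """Deterministic initialization: v_half by linear interpolation of the
    half-max crossing, q from the maximal slope of the normalized curve
    (q = 4·(RT/F)·max dĜ/dV), g_max from the top-plateau mean."""
    top = np.sort(g)[-max(2, g.size // 4):]
    g_max0 = float(np.mean(top))
    g_hat = g / g_max0
    half = 0.5
    above = np.nonzero(g_hat >= half)[0]
    if above.size == 0 or above[0] == 0:
        v_half0 = float(v[np.argmin(np.abs(g_hat - half))])
    else:
        i = above[0]
        x0, x1, y0, y1 = v[i - 1], v[i], g_hat[i - 1], g_hat[i]
        v_half0 = float(x0 + (half - y0) * (x1 - x0) / (y1 - y0)) if y1 != y0 else float(x1)
    slope = np.max(np.gradient(g_hat, v))
    q0 = float(np.clip(4.0 * (R * t_k / F) * 1e3 * slope, 0.1, 20.0))
    return v_half0, q0, g_max0


def fit_boltzmann(gv: GVCurve) -> BoltzmannFit:
    """Least-squares single-Boltzmann fit of a G-V curve.

    Free parameters (v_half, q, g_max); deterministic for given data (no
    random restarts). Fitting runs on conductance normalized by the fitted
    g_max in a two-pass scheme; negative conductances are clipped to zero
    for fitting only. Degenerate inputs (no transition in the voltage
    range) return a non-converged fit carrying the initialization values
    and a failure message.
    """
    v = gv.voltages
    g = np.clip(gv.conductances, 0.0, None)
    if v.size < 4:
        raise ValueError("Boltzmann fit needs at least 4 points spanning the transition")
    t_k = celsius_to_kelvin(gv.temperature)
    v_half0, q0, g_max0 = _init_boltzmann(v, g, t_k)
    span = g.max() - g.min()
    if g.max() <= 0 or span < 1e-3 * max(g.max(), 1e-30):
        return BoltzmannFit(v_half0, q0, max(g_max0, 1e-30), residual=np.inf,
                            temperature=gv.temperature, converged=False,
                            message="degenerate G-V: no transition in voltage range")
    p = (v_half0, q0, g_max0)
    try:
        for _ in range(2):  # two-pass normalized fit
            scale = p[2]
            popt, _ = curve_fit(
                lambda vv, vh, q, gm: _boltzmann_model(vv, vh, q, gm * scale, t_k) / scale,
                v, g / scale, p0=(p[0], p[1], p[2] / scale), maxfev=10000)
            p = (float(popt[0]), float(popt[1]), float(popt[2] * scale))
    except RuntimeError as err:
        return BoltzmannFit(v_half0, q0, g_max0, residual=np.inf,
                            temperature=gv.temperature, converged=False,
                            message=f"fit did not converge: {err}")
    v_half, q, g_max = p
    resid = g / g_max - _boltzmann_model(v, v_half, q, 1.0, t_k)
    return BoltzmannFit(v_half, q, g_max, residual=float(np.sum(resid ** 2)),
                        temperature=gv.temperature)


def correct_conductance(current, temp, gamma_q10: float = 1.5,
                        t_ref: float = 22.0):
    """Remove the single-channel conductance temperature dependence.

    Divides by gamma_q10^((T − t_ref)/10), referring amplitudes to the
    reference temperature (22 °C) so that remaining temperature dependence
    reflects gating alone.
    """
    factor = gamma_q10 ** ((np.asarray(temp, dtype=float) - t_ref) / 10.0)
    return np.asarray(current, dtype=float) / factor


def measure_q10(sweep: SweepRecord, special_dt: float | None = None,
                smooth_dT: float = 0.5, baseline_dT: float = 1.5,
                threshold_sd: float = 3.0) -> Q10Measurement | NoActivation:
    """Q10 from a heating sweep at constant voltage.

    The current trace is binned on a ``smooth_dT``-wide temperature grid.
    The activation threshold T1 is the first temperature at which the
    smoothed current exceeds the pre-heating baseline mean by
    ``threshold_sd`` baseline standard deviations (baseline = the first
    ``baseline_dT`` °C of the sweep). I1 is the smoothed current at T1 and
    I2 the smoothed current at T1 + ΔT (ΔT = ``special_dt`` or 10 °C; a
    smaller interval is used for channels that inactivate on further
    heating). Q10 = (I2/I1)^(10/(T2−T1)).

    Detection works on the departure of the smoothed current from the
    baseline in either direction, so inward (negative) currents and
    heat-deactivated (falling) currents are handled: I1 and I2 keep their
    sign and their ratio must be positive, giving Q10 < 1 for a current
    that falls on heating.

    Returns :class:`NoActivation` when no threshold is found, and raises
    if I1 is zero or I1 and I2 differ in sign (leak subtraction failed).
    """
    voltage = float(np.median(sweep.voltage))
    if np.ptp(sweep.voltage) > 0.5:
        raise ValueError("measure_q10 requires a constant-voltage heating sweep")
    temp, cur = sweep.temperature, sweep.current
    t_span = temp.max() - temp.min()
    dt_req = special_dt if special_dt is not None else 10.0
    if dt_req <= 0:
        raise ValueError("Q10 temperature interval must be positive")
    if t_span < baseline_dT + 1.0:
        return NoActivation(voltage, "temperature span too small to detect activation")
    # bin current on a temperature grid
    edges = np.arange(temp.min(), temp.max() + smooth_dT, smooth_dT)
    idx = np.clip(np.digitize(temp, edges) - 1, 0, edges.size - 2)
    centers, smoothed = [], []
    for b in range(edges.size - 1):
        sel = idx == b
        if sel.any():
            centers.append(edges[b] + smooth_dT / 2)
            smoothed.append(float(np.mean(cur[sel])))
    centers = np.asarray(centers)
    smoothed = np.asarray(smoothed)
    n_base_bins = int(np.sum(centers <= centers[0] + baseline_dT))
    base = smoothed[:n_base_bins]
    base_mean = float(np.mean(base))
    # noise floor of a bin mean, estimated from the raw baseline samples
    # (more robust than the SD over a handful of bin means)
    raw_base = cur[temp <= centers[0] + baseline_dT]
    sd_floor = float(np.std(raw_base)) / max(np.sqrt(raw_base.size
                                                     / max(n_base_bins, 1)), 1.0)
    base_sd = max(float(np.std(base)), sd_floor, 1e-12)
    # detect in the direction of the sweep's final excursion so that noise
    # blips on a near-zero baseline are not mistaken for thresholds; a
    # heat-deactivated current (falling excursion) is detected the same way.
    # The crossing must be sustained: gating is at equilibrium, so a real
    # threshold is never re-crossed on further heating.
    direction = np.sign(smoothed[-1] - base_mean)
    departure = direction * (smoothed - base_mean)
    above = departure > threshold_sd * base_sd
    below = np.nonzero(~above)[0]
    k1 = (below[-1] + 1) if below.size else n_base_bins
    k1 = max(k1, n_base_bins)
    if k1 >= centers.size:
        return NoActivation(voltage, "no heat-activation threshold detected")
    # an activation-from-closed sweep has a baseline indistinguishable from
    # zero: reference amplitudes to it, cancelling any residual leak offset.
    # A deactivating sweep starts on a real channel current — use absolute
    # amplitudes there, as the baseline is the signal itself.
    offset = base_mean if abs(base_mean) <= 3.0 * max(float(np.std(raw_base)),
                                                      1e-12) else 0.0
    t1, i1 = float(centers[k1]), float(smoothed[k1] - offset)
    t2_target = t1 + dt_req
    if t2_target > centers[-1] + smooth_dT / 2:
        return NoActivation(voltage,
                            f"sweep does not reach T1 + {dt_req:g} °C (T1 = {t1:.1f} °C)")
    k2 = int(np.argmin(np.abs(centers - t2_target)))
    t2, i2 = float(centers[k2]), float(smoothed[k2] - offset)
    if i1 == 0 or i2 / i1 <= 0:
        raise ValueError("currents at T1 and T2 must be non-zero and share a sign; "
                         "check leak subtraction")
    q10 = (i2 / i1) ** (10.0 / (t2 - t1))
    return Q10Measurement(i1=i1, i2=i2, t1=t1, t2=t2, q10=q10, voltage=voltage)


def q10_voltage_profile(gv_t1: GVCurve, gv_t2: GVCurve) -> Q10Profile:
    """Voltage-resolved Q10 from two conductance-corrected G-V curves.

    The second curve is linearly interpolated onto the first curve's
    voltages (no extrapolation: voltages outside the second curve's range
    are undefined). Q10(V) = (G2/G1)^(10/(T2−T1)); entries with
    non-positive conductance at either temperature are NaN.
    """
    if not gv_t2.temperature > gv_t1.temperature:
        raise ValueError("gv_t2 must be the warmer curve")
    v = gv_t1.voltages
    g1 = gv_t1.conductances
    g2 = np.interp(v, gv_t2.voltages, gv_t2.conductances,
                   left=np.nan, right=np.nan)
    dT = gv_t2.temperature - gv_t1.temperature
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where((g1 > 0) & (g2 > 0), g2 / g1, np.nan)
        q10 = ratio ** (10.0 / dT)
    return Q10Profile(v, q10, t1=gv_t1.temperature, t2=gv_t2.temperature)


def vant_hoff(currents, temps, g_max_ref: float, v: float, v_rev: float,
              gamma_q10: float = 1.5, t_ref: float = 22.0) -> VantHoffEstimate:
    """Van't Hoff estimate of ΔH and ΔS from a current–temperature series.

    At fixed voltage ``v``: open probability is the conductance-corrected
    conductance divided by ``g_max_ref`` (the maximal conductance at the
    reference temperature); Keq = Po/(1−Po); a linear fit of ln Keq
    against 1/T then gives ΔH = −slope·R and ΔS = intercept·R.

    The series must be leak-subtracted. Raises if any Po reaches 1
    (normalization reference too small).
    """
    currents = np.asarray(currents, dtype=float)
    temps = np.asarray(temps, dtype=float)
    if currents.size != temps.size:
        raise ValueError("currents and temps must have equal length")
    if currents.size < 3:
        raise ValueError("Van't Hoff fit requires at least 3 temperatures")
    if abs(v - v_rev) < 1e-9:
        raise ValueError("voltage at reversal potential: conductance undefined")
    if g_max_ref <= 0:
        raise ValueError("g_max_ref must be positive")
    g_corr = correct_conductance(currents, temps, gamma_q10, t_ref) / (v - v_rev)
    po = g_corr / g_max_ref
    if np.any(po >= 1):
        raise ValueError("open probability >= 1: normalization reference too small")
    if np.any(po <= 0):
        raise ValueError("non-positive open probability in series; "
                         "check leak subtraction and current sign")
    keq = po / (1.0 - po)
    inv_t = 1.0 / celsius_to_kelvin(temps)
    slope, intercept = np.polyfit(inv_t, np.log(keq), 1)
    pred = slope * inv_t + intercept
    ss_res = float(np.sum((np.log(keq) - pred) ** 2))
    ss_tot = float(np.sum((np.log(keq) - np.mean(np.log(keq))) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return VantHoffEstimate(dH=-slope * R, dS=intercept * R, r_squared=r2,
                            n_points=int(currents.size),
                            slope=float(slope), intercept=float(intercept))


def delta_g_shift(z_total: float, delta_v_half: float) -> EnergyShift:
    """Gating free-energy change of a G-V midpoint shift: ΔG = z·F·ΔV1/2.

    ``z_total`` is the total gating charge (e0) and ``delta_v_half`` the
    temperature-induced shift in half-activation voltage (mV); the result
    is in J/mol (kcal/mol via :attr:`EnergyShift.delta_g_kcal`).
    """
    delta_g = z_total * F * delta_v_half * 1e-3
    return EnergyShift(z_total=z_total, delta_v_half=delta_v_half, delta_g=delta_g)


def csi_curve(triples, window: tuple[float, float] | None = None
              ) -> tuple[np.ndarray, np.ndarray, BoltzmannFit]:
    """Closed-state-inactivation availability curve from triple-pulse families.

    For each (P1, P2, P3) triple, availability = mean P3 current / mean P1
    current over the test-pulse window (default: the depolarized step of
    the pulse protocol), plotted against the P2 conditioning voltage and
    fitted with a decreasing Boltzmann. Triples with vanishing P1 current
    are excluded with a warning.

    Returns (p2_voltages, availabilities, fit).
    """
    v2s, avails, temp = [], [], 24.0
    for p1, p2, p3 in triples:
        if window is None:
            step_mask = p1.voltage > np.min(p1.voltage) + 1.0
        else:
            step_mask = (p1.time >= window[0]) & (p1.time <= window[1])
        if not step_mask.any():
            raise ValueError("empty test-pulse window in CSI triple")
        i1 = float(np.mean(p1.current[step_mask]))
        i3 = float(np.mean(p3.current[step_mask]))
        v2 = float(p2.meta.get("p2_voltage_mV", np.median(p2.voltage)))
        if abs(i1) < 1e-9:
            warnings.warn(f"CSI triple at P2 = {v2} mV excluded: P1 current ≈ 0",
                          stacklevel=2)
            continue
        temp = float(np.mean(p1.temperature))
        v2s.append(v2)
        avails.append(i3 / i1)
    order = np.argsort(v2s)
    v2s = np.asarray(v2s)[order]
    avails = np.asarray(avails)[order]
    # fit a falling Boltzmann by fitting the rising form to (1 - availability)
    if v2s.size < 4:
        fit = BoltzmannFit(float(np.median(v2s)) if v2s.size else 0.0, 1.0, 1.0,
                           np.inf, temp, converged=False,
                           message="too few CSI points")
    elif np.max(1.0 - avails) < 0.05:  # < 5% inactivation anywhere: no CSI
        fit = BoltzmannFit(float(np.median(v2s)), 1.0, 1.0, np.inf, temp,
                           converged=False,
                           message="no closed-state inactivation detected "
                                   "(availability ≈ 1 at all voltages)")
    else:
        fit = fit_boltzmann(GVCurve(v2s, 1.0 - avails, temperature=temp))
    return v2s, avails, fit
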