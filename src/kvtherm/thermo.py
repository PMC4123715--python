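"""Equilibrium statistical mechanics of heat- and voltage-dependent gating.

The core object is a four-state allosteric scheme for a channel whose
voltage sensor is coupled to its pore gate::

        C  --J-->  C'          J : voltage-sensor activation (charge z_J)
        |          |
        L          L·D         L : pore opening (enthalpy-driven)
        |          |
        O  --J·D-> O'          D : allosteric coupling factor

State statistical weights are 1, J, L and J·L·D for C, C', O and O'.
D = 1 decouples sensor from gate entirely; D ≫ 1 makes pore opening
effectively obligatory on sensor activation, the wild-type Kv phenotype.

Each transition carries an enthalpy ΔH, entropy ΔS and gating charge z, so
its equilibrium constant is K(V,T) = exp(−(ΔH − T·ΔS − z·F·V)/(R·T)).
A transition with large ΔH and ΔS is steeply temperature-dependent — this
is the mechanism by which an intrinsically heat-sensitive pore transition,
normally masked by obligatory voltage-sensor control, produces high Q10
once the sensor is decoupled from the gate.

All weights are accumulated in log space so that |exponents| up to ~500
(|ΔH| up to several hundred kJ/mol at extreme voltages) never overflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logsumexp

from .constants import F, R, celsius_to_kelvin
from .curves import BoltzmannFit, GVCurve, Q10Profile

__all__ = [
    "ThermoTransition",
    "AllostericParams",
    "StateDistribution",
    "boltzmann_open_fraction",
    "two_state_open_probability",
    "state_distribution",
    "open_probability",
    "gv_curve",
    "qv_curve",
    "model_q10_profile",
    "csi_availability",
    "combined_probability",
    "PO_UNDERFLOW",
]

PO_UNDERFLOW = 1e-12
"""Open probabilities below this are treated as numerically indistinguishable
from zero when forming Q10 ratios; such voltages are reported as undefined."""


def _require_finite(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.all(np.isfinite(value)):
            raise ValueError(f"{name} must be finite, got {value!r}")


def _require_temp(temp_c) -> None:
    if not np.all(np.asarray(temp_c) > -273.15):
        raise ValueError("temperature must exceed absolute zero (−273.15 °C)")


@dataclass(frozen=True)
class ThermoTransition:
    """Thermodynamics of one two-state gating transition.

    Parameters
    ----------
    dH : float
        Enthalpy change, J/mol. Negative for heat-deactivated transitions.
    dS : float
        Entropy change, J/(mol·K).
    z : float
        Gating charge moved, in e0 (per-mole convention: multiplied by F).
    """

    dH: float
    dS: float
    z: float = 0.0

    def __post_init__(self) -> None:
        _require_finite(dH=self.dH, dS=self.dS, z=self.z)

    def log_k(self, v_mv, temp_c):
        """ln K(V, T) = −(ΔH − T·ΔS − z·F·V) / (R·T).

        K is strictly positive for all finite V and T > 0 since this log is
        always finite.
        """
        _require_temp(temp_c)
        t_k = celsius_to_kelvin(np.asarray(temp_c, dtype=float))
        v = np.asarray(v_mv, dtype=float) * 1e-3
        return -(self.dH - t_k * self.dS - self.z * F * v) / (R * t_k)

    def equilibrium_constant(self, v_mv, temp_c):
        return np.exp(self.log_k(v_mv, temp_c))

    @classmethod
    def from_boltzmann(cls, v_half_mv: float, q: float, temp_c: float,
                       dH: float = 0.0) -> "ThermoTransition":
        """Transition whose open probability reproduces a single-Boltzmann
        G-V (given v_half, q) exactly at temperature ``temp_c``.

        The enthalpy split is free at a single temperature; ``dH`` fixes it
        and ΔS is solved from ΔG(v_half) = 0.
        """
        t_k = celsius_to_kelvin(temp_c)
        dS = (dH - q * F * v_half_mv * 1e-3) / t_k
        return cls(dH=dH, dS=dS, z=q)


@dataclass(frozen=True)
class AllostericParams:
    """Parameters of the four-state allosteric gating scheme.

    ``J`` is the voltage-sensor transition (vertical step), ``L`` the pore
    opening (horizontal step) and ``D`` the dimensionless coupling factor:
    D = 1 means no coupling, D > 1 favors opening once the sensor is up.
    """

    J: ThermoTransition
    L: ThermoTransition
    D: float
    name: str = ""

    def __post_init__(self) -> None:
        _require_finite(D=self.D)
        if self.D < 0:
            raise ValueError(f"coupling factor D must be >= 0, got {self.D}")

    def log_weights(self, v_mv, temp_c) -> np.ndarray:
        """Log statistical weights of (C, C', O, O'), shape (..., 4)."""
        log_j = self.J.log_k(v_mv, temp_c)
        log_l = self.L.log_k(v_mv, temp_c)
        log_d = math.log(self.D) if self.D > 0 else -np.inf
        zero = np.zeros(np.broadcast_shapes(np.shape(log_j), np.shape(log_l)))
        return np.stack(
            [zero, log_j + zero, log_l + zero, log_j + log_l + log_d], axis=-1
        )

    def state_probs(self, v_mv, temp_c) -> np.ndarray:
        """Occupancies of (C, C', O, O') via log-sum-exp, shape (..., 4)."""
        lw = self.log_weights(v_mv, temp_c)
        return np.exp(lw - logsumexp(lw, axis=-1, keepdims=True))


@dataclass(frozen=True)
class StateDistribution:
    """Equilibrium occupancies of the four gating states."""

    pC: float
    pCp: float
    pO: float
    pOp: float

    def __post_init__(self) -> None:
        probs = (self.pC, self.pCp, self.pO, self.pOp)
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("state probabilities must lie in [0, 1]")
        if abs(sum(probs) - 1.0) > 1e-12:
            raise ValueError("state probabilities must sum to 1 within 1e-12")

    @property
    def open_probability(self) -> float:
        return self.pO + self.pOp


def boltzmann_open_fraction(v, v_half, q, temp):
    """Open fraction of a single-Boltzmann G-V curve.

    G/Gmax = 1 / (1 + exp(−q·F·(V − V1/2)/(R·T))), the standard form fitted
    to macroscopic conductance–voltage data. Strictly increasing in ``v``
    for q > 0.

    Parameters are in mV (``v``, ``v_half``), e0 (``q``) and °C (``temp``).
    """
    _require_finite(v=v, v_half=v_half, q=q, temp=temp)
    _require_temp(temp)
    t_k = celsius_to_kelvin(np.asarray(temp, dtype=float))
    x = np.asarray(q, dtype=float) * F * (np.asarray(v, dtype=float) - v_half) * 1e-3
    return expit(x / (R * t_k))


def two_state_open_probability(trans: ThermoTransition, v, temp):
    """Open probability K/(1+K) of an isolated two-state transition.

    At z = 0 this is the pure thermal form 1/(1 + exp(ΔH/RT − ΔS/R)): the
    probability is increasing in temperature iff ΔH > 0 (heat activation)
    and decreasing iff ΔH < 0 (heat deactivation).
    """
    return expit(trans.log_k(v, temp))


def state_distribution(params: AllostericParams, v: float, temp: float) -> StateDistribution:
    """Equilibrium occupancies of C, C', O, O' at one voltage and temperature."""
    p = params.state_probs(float(v), float(temp))
    # renormalize exactly: logsumexp softmax is accurate but the dataclass
    # enforces a 1e-12 budget on the sum
    p = p / p.sum()
    return StateDistribution(*p.tolist())


def open_probability(params, v, temp):
    """Open probability of the gating model (pO + pO' for the four-state scheme).

    ``params`` may be an :class:`AllostericParams` or a bare
    :class:`ThermoTransition` (two-state channel, e.g. a TRP-like pore).
    Accepts scalar or array ``v`` / ``temp``.
    """
    if isinstance(params, ThermoTransition):
        return two_state_open_probability(params, v, temp)
    p = params.state_probs(v, temp)
    return p[..., 2] + p[..., 3]


def _check_grid(v_grid) -> np.ndarray:
    v_grid = np.asarray(v_grid, dtype=float)
    if v_grid.size == 0:
        raise ValueError("voltage grid must be non-empty")
    if v_grid.ndim != 1 or (v_grid.size > 1 and not np.all(np.diff(v_grid) > 0)):
        raise ValueError("voltage grid must be 1-D and strictly increasing")
    return v_grid


def gv_curve(params, v_grid, temp, g_max: float = 1.0) -> GVCurve:
    """Model conductance–voltage curve: G(V) = Po(V, T) · g_max."""
    v_grid = _check_grid(v_grid)
    po = open_probability(params, v_grid, temp)
    return GVCurve(v_grid, po * g_max, temperature=float(temp))


def qv_curve(params: AllostericParams, v_grid, temp) -> np.ndarray:
    """Normalized gating-charge displacement ⟨q⟩(V) over the grid.

    The mean charge moved is z_J·(pC' + pO') + z_L·(pO + pO'), min–max
    normalized over the grid so the endpoints map to 0 and 1. The Q-V
    reports voltage-sensor movement independently of pore opening; its
    separation from the G-V is the signature of sensor–gate decoupling.
    """
    v_grid = _check_grid(v_grid)
    p = params.state_probs(v_grid, temp)
    q_mean = params.J.z * (p[..., 1] + p[..., 3]) + params.L.z * (p[..., 2] + p[..., 3])
    lo, hi = q_mean.min(), q_mean.max()
    if hi == lo:
        return np.zeros_like(q_mean)
    return (q_mean - lo) / (hi - lo)


def model_q10_profile(params, t1: float, t2: float, v_grid) -> Q10Profile:
    """Voltage-resolved temperature coefficient of the model open probability.

    Q10(V) = (Po(V, t2) / Po(V, t1))^(10/(t2 − t1)). Voltages where
    Po(V, t1) has underflowed below :data:`PO_UNDERFLOW` are reported as
    NaN (undefined) rather than infinity. The single-channel conductance
    temperature factor is a property of the measurement, not the gating
    model, and is deliberately excluded here.
    """
    if not t2 > t1:
        raise ValueError("t2 must exceed t1")
    v_grid = _check_grid(v_grid)
    po1 = np.asarray(open_probability(params, v_grid, t1), dtype=float)
    po2 = np.asarray(open_probability(params, v_grid, t2), dtype=float)
    q10 = np.full_like(po1, np.nan)
    ok = po1 > PO_UNDERFLOW
    q10[ok] = (po2[ok] / po1[ok]) ** (10.0 / (t2 - t1))
    return Q10Profile(v_grid, q10, t1=t1, t2=t2)


def csi_availability(v, v_half_csi, q_csi, temp):
    """Steady-state availability after closed-state inactivation (CSI).

    A decreasing Boltzmann of voltage: depolarized conditioning drives the
    channel into an inactivated (unavailable) state reached from closed
    states, so availability falls from 1 to 0 through ``v_half_csi`` with
    steepness ``q_csi`` (e0, applied with negative sense).
    """
    _require_finite(v=v, v_half_csi=v_half_csi, q_csi=q_csi)
    _require_temp(temp)
    t_k = celsius_to_kelvin(np.asarray(temp, dtype=float))
    x = -np.abs(q_csi) * F * (np.asarray(v, dtype=float) - v_half_csi) * 1e-3
    return expit(x / (R * t_k))


def combined_probability(act_fit: BoltzmannFit, csi_fit: BoltzmannFit, v_grid,
                         temp: float, use_inactivation: bool = False) -> np.ndarray:
    """Pointwise product of normalized activation and CSI curves.

    The product peaks in the window where channels are slightly activated
    while CSI is substantial — the voltage range where sensor–gate coupling
    is relaxed and heat sensitivity is unmasked. Unimodal on any interval
    spanning both midpoints.

    With ``use_inactivation`` the availability factor is replaced by
    1 − availability (probability of being inactivated) — an alternative
    reading of the same construction.
    """
    v_grid = _check_grid(v_grid)
    activation = boltzmann_open_fraction(v_grid, act_fit.v_half, abs(act_fit.q), temp)
    avail = csi_availability(v_grid, csi_fit.v_half, csi_fit.q, temp)
    if use_inactivation:
        avail = 1.0 - avail
    return activation * avail
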