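"""Shared result containers for conductance–voltage and temperature analyses."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import F, R, celsius_to_kelvin


@dataclass
class GVCurve:
    """Macroscopic conductance versus command voltage at one temperature.

    Conductances are leak-subtracted; negative values (noise at the foot of
    the curve) are retained here and only clipped inside the Boltzmann fit.
    """

    voltages: np.ndarray      # mV
    conductances: np.ndarray  # nS
    temperature: float        # °C
    normalized: bool = False

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.conductances = np.asarray(self.conductances, dtype=float)
        if self.voltages.shape != self.conductances.shape:
            raise ValueError("voltages and conductances must have equal length")

    def normalize(self, g_max: float) -> "GVCurve":
        if g_max <= 0:
            raise ValueError("g_max must be positive")
        return GVCurve(self.voltages, self.conductances / g_max,
                       self.temperature, normalized=True)


@dataclass
class BoltzmannFit:
    """Single-Boltzmann fit G/Gmax = 1/(1+exp(−qF(V−V1/2)/RT)).

    ``converged`` is False for degenerate inputs (e.g. no transition in the
    voltage range); the carried parameters are then the deterministic
    initialization values, and ``message`` names the failure.
    """

    v_half: float        # mV
    q: float             # e0 (apparent gating charge)
    g_max: float         # nS
    residual: float      # sum of squared residuals on normalized conductance
    temperature: float   # °C
    converged: bool = True
    message: str = ""

    def predict_fraction(self, v) -> np.ndarray:
        """Open fraction G/Gmax at voltage(s) v (mV); exactly 0.5 at v_half."""
        t_k = celsius_to_kelvin(self.temperature)
        x = self.q * F * (np.asarray(v, dtype=float) - self.v_half) * 1e-3 / (R * t_k)
        return 1.0 / (1.0 + np.exp(-x))

    def predict(self, v) -> np.ndarray:
        """Absolute conductance g_max·G/Gmax in nS."""
        return self.g_max * self.predict_fraction(v)


@dataclass
class Q10Measurement:
    """One temperature-coefficient measurement at a fixed voltage.

    Q10 = (I2/I1)^(10/(T2−T1)): the fold-increase in current per 10 °C.
    """

    i1: float       # pA at t1
    i2: float       # pA at t2
    t1: float       # °C, activation threshold temperature
    t2: float       # °C
    q10: float
    voltage: float  # mV

    def __post_init__(self) -> None:
        if not self.t2 > self.t1:
            raise ValueError("t2 must exceed t1")
        if not self.q10 > 0:
            raise ValueError("q10 must be positive")


@dataclass
class NoActivation:
    """Explicit result for a sweep in which no heat-activation threshold was found."""

    voltage: float
    reason: str


@dataclass
class Q10Profile:
    """Voltage-resolved Q10 between two temperatures; NaN marks undefined entries."""

    voltages: np.ndarray
    q10: np.ndarray
    t1: float
    t2: float

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.q10 = np.asarray(self.q10, dtype=float)
        defined = self.q10[np.isfinite(self.q10)]
        if np.any(defined <= 0):
            raise ValueError("defined Q10 entries must be positive")

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.q10)


@dataclass
class VantHoffEstimate:
    """Van't Hoff estimate: ln Keq = −ΔH/(R·T) + ΔS/R fitted against 1/T."""

    dH: float          # J/mol
    dS: float          # J/(mol·K)
    r_squared: float
    n_points: int
    slope: float = field(default=float("nan"))      # of ln Keq vs 1/T, K
    intercept: float = field(default=float("nan"))  # dimensionless

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError("Van't Hoff fit requires at least 3 temperatures")


@dataclass
class EnergyShift:
    """Free-energy change z·F·ΔV1/2 of a temperature-induced G-V midpoint shift."""

    z_total: float       # e0
    delta_v_half: float  # mV
    delta_g: float       # J/mol

    @property
    def delta_g_kcal(self) -> float:
        return self.delta_g / 4184.0
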