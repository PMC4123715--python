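import numpy as np
import pytest

from kvtherm.presets_api import load_preset
from kvtherm.thermo import AllostericParams, ThermoTransition


@pytest.fixture(scope="session")
def trp_transition() -> ThermoTransition:
    """Heat-gated two-state pore: large ΔH/ΔS, weak voltage dependence."""
    return load_preset("trpv1_like").model


@pytest.fixture(scope="session")
def shaker_params() -> AllostericParams:
    """Strongly coupled voltage-gated channel (D = 1e4)."""
    return load_preset("shaker_like").model


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)


def brute_force_state_probs(params: AllostericParams, v_mv: float,
                            temp_c: float) -> np.ndarray:
    """Independent oracle: enumerate the four unnormalized statistical
    weights in extended (long double) precision and normalize directly,
    without any log-space bookkeeping."""
    R, F = 8.314, 96485.0
    t_k = np.longdouble(temp_c) + np.longdouble(273.15)
    v = np.longdouble(v_mv) * np.longdouble(1e-3)

    def K(tr):
        return np.exp(-(np.longdouble(tr.dH) - t_k * np.longdouble(tr.dS)
                        - np.longdouble(tr.z) * np.longdouble(F) * v)
                      / (np.longdouble(R) * t_k))

    J, L = K(params.J), K(params.L)
    w = np.array([np.longdouble(1.0), J, L, J * L * np.longdouble(params.D)])
    return (w / w.sum()).astype(float)
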