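import numpy as np
import pytest

from osmovol import OsmoticCellParams, SimulationParams


@pytest.fixture
def params_0c() -> OsmoticCellParams:
    """Reference cell state at 0 °C (isotonic volume 3853, V_b 1116 µm³)."""
    return OsmoticCellParams.from_isotonic(3853.0, 1116.0)


@pytest.fixture
def params_10c() -> OsmoticCellParams:
    return OsmoticCellParams.from_isotonic(3920.0, 1135.0)


@pytest.fixture
def shrink_sim_10c(params_10c) -> SimulationParams:
    """Hypertonic (602 mOsm/kg) shrink at 10 °C with Lp 0.21 µm/(min·atm)."""
    return SimulationParams(
        Lp=0.21,
        A=params_10c.A,
        N=params_10c.N,
        T=283.15,
        M_ext=0.602,
        V_b=params_10c.V_b,
        V0_water=params_10c.V_iso,
    )


@pytest.fixture
def swell_sim_10c(params_10c) -> SimulationParams:
    """Hypotonic (157 mOsm/kg) swell at 10 °C with Lp 1.73 µm/(min·atm)."""
    return SimulationParams(
        Lp=1.73,
        A=params_10c.A,
        N=params_10c.N,
        T=283.15,
        M_ext=0.157,
        V_b=params_10c.V_b,
        V0_water=params_10c.V_iso,
    )


def random_sim_params(rng: np.random.Generator) -> SimulationParams:
    """A physically plausible random shrink or swell parameter set."""
    V_c_iso = rng.uniform(1500.0, 8000.0)
    vb = rng.uniform(0.15, 0.45)
    p = OsmoticCellParams.from_isotonic(V_c_iso, vb * V_c_iso)
    M_ext = rng.choice([rng.uniform(0.10, 0.28), rng.uniform(0.35, 1.0)])
    return SimulationParams(
        Lp=rng.uniform(0.05, 3.0),
        A=p.A,
        N=p.N,
        T=rng.uniform(270.0, 300.0),
        M_ext=float(M_ext),
        V_b=p.V_b,
        V0_water=p.V_iso,
    )
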