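import numpy as np
import pytest

from bathrc import CircuitParams, LungParams, VentSettings


@pytest.fixture
def settings25():
    """Pressure-control settings of the high-pressure bench runs."""
    return VentSettings(pinsp=25.0, peep=5.0, rr=15.0, ie_e=2.0)


@pytest.fixture
def settings15():
    return VentSettings(pinsp=15.0, peep=5.0, rr=15.0, ie_e=2.0)


@pytest.fixture
def lung1():
    """Bench test lung 1: R = 12 cmH2O/(L/s), C = 0.040 L/cmH2O."""
    return LungParams(r=12.0, c=0.040)


@pytest.fixture
def lung2():
    return LungParams(r=10.0, c=0.030)


@pytest.fixture
def tubing():
    """Characterised circle-system tubing: Rv = 22, Cv = 0.004."""
    return CircuitParams(r_v=22.0, c_v=0.004)


def random_parameter_sets(n: int, seed: int):
    """Valid parameter draws spanning clinically plausible ranges.

    Tubing compliance is either exactly zero (one-state limit) or large
    enough that the fast time constant is resolvable by the RK4 oracle.
    """
    rng = np.random.default_rng(seed)
    draws = []
    for _ in range(n):
        c_v = 0.0 if rng.random() < 0.25 else rng.uniform(0.002, 0.008)
        draws.append(
            (
                VentSettings(
                    pinsp=rng.uniform(5, 30),
                    peep=rng.uniform(0, 10),
                    rr=rng.uniform(10, 25),
                    ie_e=rng.uniform(1.0, 3.0),
                ),
                LungParams(r=rng.uniform(5, 30), c=rng.uniform(0.01, 0.06)),
                CircuitParams(
                    r_v=rng.uniform(10, 40),
                    c_v=c_v,
                    r_restrictor_insp=rng.uniform(0, 40),
                ),
            )
        )
    return draws
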