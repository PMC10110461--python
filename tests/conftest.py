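import numpy as np
import pytest

from starss.photophysics import FluorophoreModel, Illumination, RotorModel
from starss.sphere import SphereGrid


@pytest.fixture(scope="session")
def fluor() -> FluorophoreModel:
    return FluorophoreModel.from_preset("rsEGFP2")


@pytest.fixture(scope="session")
def grid() -> SphereGrid:
    # reduced resolution for speed; band limit l=31 is ample for cos^2 kernels
    return SphereGrid(32, 64)


@pytest.fixture(scope="session")
def circular_probe() -> Illumination:
    return Illumination(
        role="probe_488", polarization="circular", power_density=100.0, duration=400e-6
    )


@pytest.fixture
def slow_rotor() -> RotorModel:
    return RotorModel(rotational_correlation_time=50e-6)


def poissonify(curve, cycles: int, seed: int, stream: str = "test"):
    """Scale a noiseless curve to `cycles` repeats and Poisson-sample it."""
    from starss.schemes import DecayCurve, substream

    rng = substream(seed, stream)
    return DecayCurve(
        curve.bin_centers,
        rng.poisson(curve.counts_parallel * cycles),
        rng.poisson(curve.counts_perpendicular * cycles),
        curve.bin_widths,
        curve.segment_labels,
        {**curve.metadata, "mode": "poisson", "cycles": cycles, "seed": seed},
    )


@pytest.fixture(scope="session")
def method1_slow_curve(fluor, grid, circular_probe):
    """Noiseless scheme-1 expectation for a tau = 50 us rotor (shared)."""
    from starss.schemes import simulate_method1

    rotor = RotorModel(rotational_correlation_time=50e-6)
    return simulate_method1(
        fluor, rotor, probe_488=circular_probe, grid=grid,
        mode="expectation", bin_width=2e-6,
    )
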