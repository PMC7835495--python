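import numpy as np
import pytest

from beekin import FlightConfig, generate_flight
from beekin.series import PoseSeries, VelocitySeries, time_grid


@pytest.fixture(scope="session")
def small_flights():
    """Three short default-condition flights, shared across tests."""
    return [generate_flight(FlightConfig(duration=6.0), seed=900 + i)
            for i in range(3)]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_velocity(omega, fps=500.0, part="head"):
    omega = np.asarray(omega, float)
    return VelocitySeries(times=time_grid(omega.size, fps), fps=fps,
                          part=part, omega_z=omega)


def make_pose(yaw, pitch=None, roll=None, fps=500.0, part="head"):
    yaw = np.asarray(yaw, float)
    z = np.zeros_like(yaw)
    return PoseSeries(times=time_grid(yaw.size, fps), fps=fps, part=part,
                      yaw=yaw, pitch=z if pitch is None else np.asarray(pitch),
                      roll=z if roll is None else np.asarray(roll))
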