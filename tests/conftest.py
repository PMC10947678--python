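"""Shared fixtures: expensive simulations and the standard map, built once."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_fast():
    from epimap.models import FastParams

    return FastParams()


@pytest.fixture(scope="session")
def default_curves(default_fast):
    from epimap.bifurcations import bifurcation_set

    return bifurcation_set(default_fast)


@pytest.fixture(scope="session")
def standard_map(default_fast):
    """The reference amplitude/frequency map over the standard rectangle.

    Grid values avoid landing exactly on the analytic curves (the axes have
    an even number of intervals over ranges whose curve values fall between
    nodes).
    """
    from epimap.mapgrid import build_map

    mu_values = np.linspace(-2.0, 1.0, 17)
    mbar_values = np.linspace(-3.0, 2.0, 20)
    return build_map(default_fast, mu_values, mbar_values)


def _preset_traj(name, **kw):
    from epimap.simulate import run_preset

    traj, report = run_preset(name, **kw)
    return traj, report


@pytest.fixture(scope="session")
def original_run():
    return _preset_traj("original")


@pytest.fixture(scope="session")
def sn_sh_run():
    return _preset_traj("sn_sh")


@pytest.fixture(scope="session")
def depol_block_run():
    return _preset_traj("depol_block")


@pytest.fixture(scope="session")
def suph_sh_run():
    return _preset_traj("suph_sh")


@pytest.fixture(scope="session")
def suph_suph_run():
    return _preset_traj("suph_suph")


@pytest.fixture(scope="session")
def dtb_run():
    return _preset_traj("dtb_sn_sh")
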