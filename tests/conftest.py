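"""Shared fixtures: expensive optimizations and dictionaries are built once
per session and reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from mcdpmrf import (
    ConstraintSpec,
    HardwareLimits,
    build_dictionary,
    build_timing,
    compress,
    default_schedule,
    in_vivo_grids,
    optimize_prep,
)


@pytest.fixture(scope="session")
def schedule():
    return default_schedule()


@pytest.fixture(scope="session")
def opt_results():
    """Diffusion-prep optimizations for the standard constraint sets."""
    timing = build_timing()
    limits = HardwareLimits()
    specs = {
        "mc0": ConstraintSpec(null_m1=False, maxwell=False),
        "mc0_mc1": ConstraintSpec(maxwell=False),
        "mc0_mc1_mx": ConstraintSpec(),
        "mc0_mc1_mc2_mx": ConstraintSpec(null_m2=True),
    }
    return {name: optimize_prep(timing, limits, spec) for name, spec in specs.items()}


@pytest.fixture(scope="session")
def invivo_dictionary(schedule):
    """Full in-vivo-grid dictionary, compressed at the default 96% energy."""
    t1, t2, adc = in_vivo_grids()
    return compress(build_dictionary(schedule, t1, t2, adc))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
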