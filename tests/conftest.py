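"""Shared fixtures: small knot sets, injections, schedules and ROI builders."""

from __future__ import annotations

import numpy as np
import pytest

from aifx import (
    FrameSchedule,
    ImpulseResponse,
    InjectionProfile,
    KnotVector,
    ROITimeCourse,
    make_knots,
)
from aifx.synthetic_data import builtin_archetypes


@pytest.fixture(scope="session")
def h2o_arch():
    return next(a for a in builtin_archetypes() if a.name == "h2o")


@pytest.fixture(scope="session")
def fdg_arch():
    return next(a for a in builtin_archetypes() if a.name == "fdg")


@pytest.fixture
def knots_small() -> KnotVector:
    """Hand-set knots for closed-form checks (K = 3)."""
    return KnotVector(np.array([0.0, 10.0, 30.0, 80.0]))


@pytest.fixture
def knots_h2o(h2o_arch) -> KnotVector:
    return make_knots(h2o_arch.schedule.end_time, K=12, first_knot=5.0)


@pytest.fixture
def square60() -> InjectionProfile:
    """Unit-height 60 s infusion (not unit mass)."""
    return InjectionProfile("square", duration=60.0, height=1.0)


@pytest.fixture
def square5() -> InjectionProfile:
    """5 s bolus-style injection with unit total mass."""
    return InjectionProfile("square", duration=5.0)


@pytest.fixture
def bolus() -> InjectionProfile:
    return InjectionProfile("bolus")


@pytest.fixture
def simple_schedule() -> FrameSchedule:
    """Ten equal 30 s frames, no decay."""
    edges = np.arange(11) * 30.0
    return FrameSchedule(edges[:-1], edges[1:], 0.0)


def make_decaying_theta(K: int, rate: float = 0.6, cut: int | None = None) -> np.ndarray:
    theta = np.exp(-np.arange(K) * rate)
    if cut is not None:
        theta[cut:] = 0.0
    return theta


@pytest.fixture
def decaying_ir(knots_h2o) -> ImpulseResponse:
    return ImpulseResponse(knots_h2o, make_decaying_theta(knots_h2o.K, cut=7))
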