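"""Shared fixtures: the coarse desk-scale case runs are expensive, so they
are computed once per session and shared between the behavioural and
acceptance tests."""

from __future__ import annotations

import logging

import pytest

from etflow.cases import builtin_case, run_case

logging.getLogger("etflow").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def case1_result():
    """Reference case (saline, fast injection) with catheter withdrawal."""
    return run_case(builtin_case(1))


@pytest.fixture(scope="session")
def case7_result():
    """Equal-viscosity case with catheter withdrawal."""
    return run_case(builtin_case(7))


@pytest.fixture(scope="session")
def case4_result():
    """Intermediate-viscosity case, injection only."""
    return run_case(builtin_case(4, withdrawal=False))
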