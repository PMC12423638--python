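"""Shared phantom fixtures.

Heavy artifacts (96^3 phantom cases and full pipeline runs) are session-
scoped so the acceptance tests and the invariant tests share one
computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from ramps.cavity import run_cavity_pipeline
from ramps.core import BinaryMask, ResectionSpec
from ramps.phantom import generate_case, preset_config


@pytest.fixture(scope="session")
def case_a():
    """Aligned, noiseless phantom pair (easiest conditions)."""
    return generate_case(preset_config("a", seed=1))


@pytest.fixture(scope="session")
def case_d():
    """Rigid-misalignment-only phantom pair (4 mm / 3 deg)."""
    return generate_case(preset_config("d", seed=1))


@pytest.fixture(scope="session")
def case_e():
    """Full-difficulty pair: sagging + misalignment + bias + noise."""
    return generate_case(preset_config("e", seed=1))


@pytest.fixture(scope="session")
def case_f():
    """Small-lesionectomy pair."""
    return generate_case(preset_config("f", seed=1))


@pytest.fixture(scope="session")
def small_case():
    """64^3 aligned noiseless pair for fast operator-level tests."""
    return generate_case(preset_config("a", seed=2, grid_shape=(64, 64, 64)))


def _run(case):
    pre, post, truth = case
    return run_cavity_pipeline(pre, post, truth.region_labels,
                               truth.region_labels_post,
                               ResectionSpec("L", "T"))


@pytest.fixture(scope="session")
def pipeline_a(case_a):
    return _run(case_a)


@pytest.fixture(scope="session")
def pipeline_e(case_e):
    return _run(case_e)


@pytest.fixture(scope="session")
def pipeline_f(case_f):
    return _run(case_f)


@pytest.fixture()
def brain_of():
    def _brain(truth, affine):
        return BinaryMask(truth.region_labels.data > 0, affine)
    return _brain
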