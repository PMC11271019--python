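"""Shared fixtures: synthetic studies at several sizes, reused per session."""

from __future__ import annotations

import pytest

from clinreview.pipeline import load_config
from clinreview.synth import StudyRecipe, generate_study, load_fixture_study


@pytest.fixture(scope="session")
def small_study():
    """12-subject study with every domain populated (seed 3)."""
    return generate_study(StudyRecipe(n_subjects=12, seed=3))


@pytest.fixture(scope="session")
def mid_study():
    """50-subject study used for oracle comparisons (seed 11)."""
    return generate_study(StudyRecipe(n_subjects=50, seed=11))


@pytest.fixture(scope="session")
def large_study():
    """200-subject study for brute-force tabulation checks (seed 7)."""
    return generate_study(StudyRecipe(n_subjects=200, seed=7))


@pytest.fixture(scope="session")
def fixture_batch():
    """The frozen six-subject study shipped with the package."""
    return load_fixture_study()


@pytest.fixture(scope="session")
def default_config():
    return load_config()
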