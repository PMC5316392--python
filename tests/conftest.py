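"""Shared fixtures: small designs and pre-rendered synthetic fields."""

import numpy as np
import pytest

from glutmorph import CohortDesign, EffectProfile, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_design():
    """A scaled-down sampling design (fast to generate and render)."""
    return CohortDesign(
        group_sizes={"GDMG1": 3, "GDMG2": 2, "PGDM": 2, "control": 4},
        sections_per_specimen_per_marker=1,
        fields_per_section=2,
        vessel_fields_per_specimen=2,
        image_size_px=256,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_design):
    return generate_cohort(small_design, EffectProfile())


@pytest.fixture(scope="session")
def default_cohort():
    """Full-scale default cohort (tables only; nothing rendered)."""
    return generate_cohort(CohortDesign(seed=11))
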