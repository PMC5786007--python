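"""Shared fixtures: synthetic golden sets and toy references."""

from __future__ import annotations

import numpy as np
import pytest

from ntcana.reference import GoldenSetMember, build_golden_set
from ntcana.structure_io import StepTorsions
from ntcana.synthetic import default_fixture_spec, make_reference_fixture

#: Canonical BI-like nine-torsion template used across tests.
B_TEMPLATE = np.array([135.0, 187.0, 262.0, 303.0, 179.0, 45.0, 135.0,
                       250.0, 250.0])
#: A-form-like template (C3'-endo sugars, low delta).
A_TEMPLATE = np.array([83.0, 205.0, 287.0, 295.0, 174.0, 52.0, 83.0,
                       203.0, 203.0])


def make_symmetric_members(ntc_class: str, template, p_mean: float,
                           offsets=(-6.0, -4.0, -2.0, 2.0, 4.0, 6.0),
                           n_repeat: int = 2):
    """Members displaced by the same offset on every torsion.

    The offsets are symmetric about zero, so the circular means are
    exactly the template and the esds are the rms offset; handy when a
    test needs a class whose means are known in closed form.
    """
    members = []
    k = 0
    for _ in range(n_repeat):
        for off in offsets:
            members.append(GoldenSetMember(
                member_id=f"{ntc_class}_{k:03d}", ntc_class=ntc_class,
                torsions=StepTorsions.from_values(
                    (np.asarray(template) + off) % 360.0,
                    (p_mean + off) % 360.0, (p_mean + off) % 360.0)))
            k += 1
    return members


@pytest.fixture(scope="session")
def fixture_golden():
    """10 well-separated classes x 30 members, seed 1."""
    return make_reference_fixture(default_fixture_spec(seed=1))


@pytest.fixture(scope="session")
def toy_golden():
    """Two symmetric classes (12 members each) with known means."""
    members = (make_symmetric_members("BB00", B_TEMPLATE, 155.0)
               + make_symmetric_members("AA00", A_TEMPLATE, 18.0))
    return build_golden_set(members, metadata={"source": "toy"})


@pytest.fixture(scope="session")
def single_class_golden():
    """One symmetric class of 12 members around the BI template."""
    return build_golden_set(
        make_symmetric_members("BB00", B_TEMPLATE, 155.0),
        metadata={"source": "toy-single"})
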