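"""Shared fixtures: one synthetic study subject and pre-computed maps.

The study subject uses explicit, generous strength limits (2.2 / 0.8 N m
per kg plantar-/dorsiflexion) so that the balance boundaries are limited
by foot geometry (center of pressure) rather than strength, which is the
regime the feasibility maps describe.
"""

from dataclasses import replace

import pytest

from stsbalance import (
    InertiaProfile,
    SubjectModel,
    SyntheticSpec,
    compute_balance_map,
    make_inertia_profile,
    make_subject,
)

VARIATION = 0.25


@pytest.fixture(scope="session")
def spec():
    return SyntheticSpec(seed=1)


@pytest.fixture(scope="session")
def subject(spec):
    sub = make_subject(spec, 0)
    return replace(sub, tau_pf_max=2.2 * sub.mass, tau_df_max=0.8 * sub.mass)


@pytest.fixture(scope="session")
def const_profile(subject):
    return InertiaProfile.constant(0.55 * subject.height, subject.mass)


@pytest.fixture(scope="session")
def var_profile(subject):
    return make_inertia_profile(subject, VARIATION)


@pytest.fixture(scope="session")
def unconstrained_subject():
    """Huge foot, friction and strength: constraints never bind."""
    return SubjectModel(mass=70.0, height=1.75, d_toe=5.0, d_heel=5.0,
                        ankle_height=0.0, foot_length=10.0, mu=100.0,
                        tau_pf_max=1e6, tau_df_max=1e6)


@pytest.fixture(scope="session")
def map_simple(subject, const_profile):
    return compute_balance_map(subject, const_profile, model="simple")


@pytest.fixture(scope="session")
def map_var(subject, var_profile):
    return compute_balance_map(subject, var_profile, model="variable")


@pytest.fixture(scope="session")
def map_var_as_simple(subject, var_profile):
    return compute_balance_map(subject, var_profile, model="simple")
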