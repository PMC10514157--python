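"""Shared fixtures: the worked parameter sets of the four response scenarios."""

import pytest

from twopatch import PatchParams


@pytest.fixture
def mono_beneficial_discrete() -> PatchParams:
    return PatchParams(r_A=3.0, r_B=1.5, K_A=2.0, K_B=1.5)


@pytest.fixture
def unimodal_discrete() -> PatchParams:
    return PatchParams(r_A=3.2, r_B=1.5, K_A=3.85, K_B=1.37)


@pytest.fixture
def turning_discrete() -> PatchParams:
    return PatchParams(r_A=3.4, r_B=1.5, K_A=8.4, K_B=1.37)


@pytest.fixture
def mono_detrimental_discrete() -> PatchParams:
    return PatchParams(r_A=2.0, r_B=1.25, K_A=1.0, K_B=1.25)


@pytest.fixture
def beyond_mixing_discrete() -> PatchParams:
    """Discrete set whose optimal dispersal rate exceeds perfect mixing."""
    return PatchParams(r_A=2.35, r_B=1.7, K_A=2.35, K_B=1.75)


@pytest.fixture
def mono_beneficial_continuous() -> PatchParams:
    return PatchParams(r_A=0.5, r_B=2.0, K_A=0.5, K_B=1.0, mode="continuous")


@pytest.fixture
def turning_continuous() -> PatchParams:
    return PatchParams(r_A=1.0, r_B=2.0, K_A=0.5, K_B=1.5, mode="continuous")


@pytest.fixture
def mono_detrimental_continuous() -> PatchParams:
    return PatchParams(r_A=1.1, r_B=2.0, K_A=2.0, K_B=1.0, mode="continuous")
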