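"""Shared fixtures.

The two reference-scale drying runs (monomodal and bimodal 5x5x15
networks) take a few minutes each, so they are session scoped and shared
between the engine-level and acceptance-level tests.
"""

import pytest

from lyopnm.engine import run_primary_drying
from lyopnm.fixtures import make_fixture


@pytest.fixture(scope="session")
def small_mono_record():
    """Completed drying run of the fast 3x3x5 monomodal lattice."""
    net, _ = make_fixture("mono_small")
    return run_primary_drying(net)


@pytest.fixture(scope="session")
def ref_mono():
    """Reference 5x5x15 monomodal network and its completed drying run."""
    net, _ = make_fixture("mono_ref")
    return net, run_primary_drying(net)


@pytest.fixture(scope="session")
def ref_bi():
    """Reference 5x5x15 bimodal network and its completed drying run."""
    net, _ = make_fixture("bi_ref")
    return net, run_primary_drying(net)
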