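"""Shared fixtures: protocols and signal models are expensive to build, so
they are session-scoped and reused across test modules."""

import numpy as np
import pytest

from dwspectra import inversion, protocols


@pytest.fixture(scope="session")
def reduced_protocol():
    """Wide-frequency protocol (~130 acquisitions) with encoding spectra."""
    return protocols.make_reduced_preclinical_protocol()


@pytest.fixture(scope="session")
def reduced_model(reduced_protocol):
    return inversion.SignalModel(reduced_protocol)


@pytest.fixture(scope="session")
def clinical_protocol():
    """Narrow-frequency 134-volume protocol (record-only)."""
    return protocols.make_clinical_protocol()


@pytest.fixture(scope="session")
def clinical_model(clinical_protocol):
    return inversion.SignalModel(clinical_protocol)


@pytest.fixture(scope="session")
def full_preclinical_protocol():
    """Full 1491-acquisition wide-frequency protocol (scalars only)."""
    return protocols.make_preclinical_protocol()


@pytest.fixture()
def rng():
    return np.random.default_rng(20250929)
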