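import sys
from pathlib import Path

import numpy as np
import pytest

import introcap as ic

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def tiny_ref():
    """5 kb single-chromosome reference for mapper/probe oracles."""
    return ic.make_reference([5_000], [0.5], seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact reference + donors + one mosaic carrier, reused across tests."""
    ref = ic.make_reference([300_000, 200_000], [0.4, 0.5], seed=21)
    donors = {
        "primary": ic.make_donor(ref, ic.DonorSpec("primary", "primary", 0.015, 0.0, 31)),
        "tertiary": ic.make_donor(ref, ic.DonorSpec("tertiary", "tertiary", 0.12, 0.0, 32)),
    }
    segments = [
        ic.IntrogressionSegment("chr1", 0, 100_000, "tertiary"),
        ic.IntrogressionSegment("chr2", 50_000, 100_000, "primary"),
    ]
    mosaic = ic.make_accession(ref, donors, segments, "ACC1")
    return ref, donors, mosaic
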