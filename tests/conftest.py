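import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from orthodesign.efm import enumerate_efms, partition_modes
from orthodesign.fixtures import build_fixture


@pytest.fixture(scope="session")
def branched_toy():
    return build_fixture("branched_toy")


@pytest.fixture(scope="session")
def branched_toy_redundant():
    return build_fixture("branched_toy_redundant")


@pytest.fixture(scope="session")
def toy_efms(branched_toy):
    efms = enumerate_efms(branched_toy)
    return partition_modes(efms, "v_bio", "v8")


@pytest.fixture(scope="session")
def redundant_efms(branched_toy_redundant):
    efms = enumerate_efms(branched_toy_redundant)
    return partition_modes(efms, "v_bio", "v8")
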