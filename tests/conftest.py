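from pathlib import Path

import pytest

from crlm_cea.lifetable import bundled_lifetable
from crlm_cea.parameters import apply_overrides, builtin_basecase, load_overrides

REPO_ROOT = Path(__file__).resolve().parents[1]
CALIBRATION_CONFIG = REPO_ROOT / "config" / "calibration.yaml"


@pytest.fixture(scope="session")
def basecase():
    table, strategies = builtin_basecase()
    return table, strategies


@pytest.fixture(scope="session")
def lifetable():
    return bundled_lifetable()


@pytest.fixture(scope="session")
def calibrated():
    """Base-case table with the committed calibration configuration applied."""
    table, _ = builtin_basecase()
    return apply_overrides(table, load_overrides(CALIBRATION_CONFIG))
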