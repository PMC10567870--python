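import dataclasses

import pytest

from methylfluid.cohort import default_distributions
from methylfluid.panel import PreTestPanel, default_rules


@pytest.fixture(scope="session")
def rules():
    return default_rules()


@pytest.fixture(scope="session")
def noiseless_distributions():
    """Every cell pinned to its reference mean (SD 0, no outliers)."""
    return {
        key: dataclasses.replace(dist, sd=0.0, outlier_spec=None)
        for key, dist in default_distributions(include_outliers=False).items()
    }


def pretests(blood="not_done", saliva="not_done", sperm="not_done") -> PreTestPanel:
    return PreTestPanel.from_strings(blood, saliva, sperm)
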