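import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for property_lookup

from stabpath import curation, synthetic_data as sd


@pytest.fixture(scope="session")
def small_cohort():
    """1,000 records per class under the default study conditions."""
    config = sd.paper_shaped_config(n_benign=1000, n_pathogenic=1000)
    records, sidecar = sd.generate_variant_table(config, seed=11)
    return config, records, sidecar


@pytest.fixture(scope="session")
def curated_small_cohort(small_cohort):
    _, records, _ = small_cohort
    kept, report = curation.curate(records)
    return kept, report
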