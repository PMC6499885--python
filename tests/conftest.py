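import numpy as np
import pandas as pd
import pytest

from nephrosig.pharmacovigilance import FrequencyTable


@pytest.fixture
def small_freq_table() -> FrequencyTable:
    """Four drugs, two special ADR groups, hand-countable totals."""
    rows = []
    for d, (g1, g2, other) in {
        "d1": (5, 10, 85),
        "d2": (10, 20, 170),
        "d3": (20, 40, 340),
        "d4": (40, 80, 680),
    }.items():
        rows += [
            (d, "t_glom", g1),
            (d, "t_hyp", g2),
            (d, "t_other", other),
        ]
    records = pd.DataFrame(rows, columns=["drug", "adr_term", "count"])
    return FrequencyTable(
        records=records,
        term_groups={"t_glom": "glomerular", "t_hyp": "hypertension"},
        drug_class={"d1", "d2", "d3", "d4"},
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
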