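import pandas as pd
import pytest

from pbfaudit.labeling import label_panel
from pbfaudit.simulate import SimConfig, generate_panel


@pytest.fixture(scope="session")
def default_panel():
    """One default-sized panel (140 facilities × 4 quarters)."""
    return generate_panel(SimConfig(seed=11))


@pytest.fixture(scope="session")
def default_labels(default_panel):
    return label_panel(default_panel)


def labels_from_flags(flags: dict[str, list[int]]) -> pd.DataFrame:
    """Hand-built label table from {facility_id: [q1..q4 flags]}."""
    rows = [
        {"facility_id": fid, "quarter": q + 1, "reported_bonus": 0.0,
         "verified_bonus": 0.0, "over_report": flag}
        for fid, qflags in flags.items()
        for q, flag in enumerate(qflags)
    ]
    return pd.DataFrame(rows)
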