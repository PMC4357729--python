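import io

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_counts() -> "pd.DataFrame":
    """Unmerged long-format toy table: 3 proteins, 3 samples, 2 NSC fractions."""
    rows = [
        ("P1", "differentiating", "cytoplasmic", 3),
        ("P1", "differentiating", "nuclear", 2),
        ("P1", "proliferating", "cytoplasmic", 4),
        ("P2", "proliferating", "nuclear", 7),
        ("P2", "differentiating", "cytoplasmic", 1),
        ("P3", "control", "whole", 5),
    ]
    return pd.DataFrame(rows, columns=["protein_id", "sample", "fraction", "count"])


@pytest.fixture
def toy_counts_file(toy_counts) -> io.StringIO:
    buf = io.StringIO()
    toy_counts.to_csv(buf, sep="\t", index=False)
    buf.seek(0)
    return buf
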