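import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=30,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def write_tsv(tmp_path):
    """Write a small tab-delimited fixture file and return its path."""

    def _write(name: str, text: str):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write


@pytest.fixture
def small_universe():
    """A hand-sized marker/gene universe with known marker lists."""
    import mergenet as mg

    pairs = [
        ("G1", "m1"), ("G1", "m2"),
        ("G2", "m3"),
        ("G3", "m4"), ("G3", "m5"), ("G3", "m6"),
        ("G4", "m7"),
        ("G5", "m8"), ("G5", "m9"),
        ("G6", "m2"), ("G6", "m10"),
    ]
    mgmap = mg.MarkerGeneMap.from_pairs(pairs)
    rng = np.random.default_rng(7)
    values = rng.random(10) * 4
    assoc = mg.MarkerAssociationTable(
        pd.Series(values, index=[f"m{i}" for i in range(1, 11)])
    )
    return mgmap, assoc
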