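import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import soilrisk as sr

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def refs() -> sr.ReferenceSet:
    return sr.default_reference_set()


@pytest.fixture
def background_table(refs) -> sr.SampleTable:
    """A single site sitting exactly at the background value for all nine
    elements — the identity point of every index."""
    row = {"x": 100.0, "y": 200.0, **{el: refs.background[el] for el in sr.STUDY_ELEMENTS}}
    df = pd.DataFrame([row], index=pd.Index(["B001"], name="site_id"))
    return sr.SampleTable(df, source_tag="SOIL", crs_tag="EPSG:32629")


def random_sample_table(rng: np.random.Generator, n_sites: int, elements) -> sr.SampleTable:
    """Log-normally distributed concentrations around the default backgrounds."""
    data = {
        "x": rng.uniform(0, 5000, n_sites),
        "y": rng.uniform(0, 5000, n_sites),
    }
    for el in elements:
        data[el] = sr.DEFAULT_BACKGROUND[el] * rng.lognormal(0.0, 0.8, n_sites)
    df = pd.DataFrame(data, index=pd.Index([f"P{i:03d}" for i in range(n_sites)], name="site_id"))
    return sr.SampleTable(df, source_tag="SOIL", crs_tag="EPSG:32629")


def classified_from_labels(index: str, labels: dict[str, str]) -> pd.DataFrame:
    """Build a minimal classified table from site_id → label."""
    return pd.DataFrame(
        {
            "site_id": list(labels),
            "index": index,
            "value": np.nan,
            "label": list(labels.values()),
            "scheme_version": index.split("_", 1)[0],
        }
    )
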