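import numpy as np
import pandas as pd
import pytest

from hamkit.core_data import ExpressionMatrix, GeneSet, SampleTable


@pytest.fixture
def small_counts():
    """3 genes x 4 samples integer count matrix."""
    df = pd.DataFrame(
        [[10, 20, 30, 40], [5, 5, 5, 5], [0, 1, 2, 3]],
        index=["gA", "gB", "gC"],
        columns=["s1", "s2", "s3", "s4"],
        dtype=float,
    )
    return ExpressionMatrix(values=df, layer="counts")


@pytest.fixture
def centered_matrix():
    """Pre-centered 3 genes x 3 samples matrix (layer=centered)."""
    df = pd.DataFrame(
        [[1.0, -1.0, 2.0], [2.0, 0.0, -4.0], [6.0, 1.0, 1.0]],
        index=["gA", "gB", "gC"],
        columns=["s1", "s2", "s3"],
    )
    return ExpressionMatrix(values=df, layer="centered")


@pytest.fixture
def diagnosis_meta():
    idx = [f"s{i}" for i in range(1, 9)]
    return SampleTable(
        pd.DataFrame(
            {
                "diagnosis": ["control"] * 4 + ["AD"] * 4,
                "age": [70, 75, 80, 85, 72, 77, 82, 87],
                "sex": ["M", "F", "M", "F", "M", "F", "M", "F"],
                "pmi": [3.0, 2.5, 3.2, 2.8, 3.1, 2.9, 3.0, 2.7],
                "apoe4": [False, False, False, True, True, True, False, True],
            },
            index=pd.Index(idx, name="sample_id"),
        )
    )


@pytest.fixture
def plain_set():
    return GeneSet(name="plain", members=["gA", "gB", "gC"])


@pytest.fixture
def signed_set():
    return GeneSet(
        name="signed",
        members=["gA", "gB"],
        direction={"gA": 1, "gB": -1},
    )
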