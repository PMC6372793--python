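"""Shared fixtures for the test suite."""

import numpy as np
import pandas as pd
import pytest


def make_catalog(lengths, categories=None, gene_ids=None):
    """Hand-built minimal catalog (gene_id, length_nt, category)."""
    n = len(lengths)
    if gene_ids is None:
        gene_ids = [f"g{i + 1}" for i in range(n)]
    if categories is None:
        categories = ["other"] * n
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "scaffold_id": ["s1"] * n,
            "start": np.arange(1, n + 1),
            "end": np.arange(1, n + 1) + np.asarray(lengths) - 1,
            "strand": ["+"] * n,
            "length_nt": list(lengths),
            "category": list(categories),
            "pathway_tag": ["hyp"] * n,
        }
    )


@pytest.fixture
def toy_catalog():
    return make_catalog([1000, 2000, 500])
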