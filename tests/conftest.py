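"""Shared fixtures: small hand-checkable inputs built programmatically."""

import math

import pandas as pd
import pytest

from pathkit.io import DEGTable, GeneSet, GeneSetDatabase, InteractionTable

FC_15 = math.log2(1.5)


@pytest.fixture
def six_gene_table() -> DEGTable:
    """Six genes spanning every significance/direction combination.

    With cutoffs (p < 0.05, |log2 fc| >= log2 1.5): g1 and g6 are up,
    g2 and g5 are down, g3 fails the fold-change cutoff and g4 the p
    cutoff.
    """
    df = pd.DataFrame({
        "gene_id": ["g1", "g2", "g3", "g4", "g5", "g6"],
        "log2_fc": [1.0, -2.0, 0.2, 3.0, -0.8, 0.59],
        "p_value": [0.005, 0.0005, 0.001, 0.1, 0.02, 0.02],
        "p_adjusted": [0.01, 0.001, 0.003, 0.2, 0.04, 0.049],
    })
    return DEGTable(comparison_name="toy", data=df)


@pytest.fixture
def toy_pair_db() -> GeneSetDatabase:
    """Two 3-gene sets sharing exactly one gene (c): all pairs unique."""
    return GeneSetDatabase([
        GeneSet("P1", "Pathway one", frozenset("abc")),
        GeneSet("P2", "Pathway two", frozenset("cde")),
    ])


@pytest.fixture
def toy_interactions() -> InteractionTable:
    """The worked network toy: a path plus a shortcut through x."""
    return InteractionTable(edges=[
        ("a", "b"), ("b", "c"), ("c", "d"), ("a", "x"), ("c", "x"), ("d", "e"),
    ])
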