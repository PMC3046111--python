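import networkx as nx
import pandas as pd
import pytest

from keymir.expression import ExpressionTable
from keymir.synthetic import SyntheticConfig, generate


@pytest.fixture
def star_net():
    """K1,4 star: hub H, leaves L1..L4, unit confidences.

    Network means: degree (4+1+1+1+1)/5 = 1.6, neighborhood connectivity
    (1 + 4+4+4+4)/5 = 3.4.
    """
    net = nx.Graph()
    for leaf in ("L1", "L2", "L3", "L4"):
        net.add_edge("H", leaf, confidence=1.0)
    return net


@pytest.fixture
def toy_table():
    """Five miRNAs with disease deviations +0.6, -0.7, +0.4, 0.0, -0.5."""
    deltas = {"m1": 0.6, "m2": -0.7, "m3": 0.4, "m4": 0.0, "m5": -0.5}
    frame = pd.DataFrame({
        "control": {m: 8.0 for m in deltas},
        "disease": {m: 8.0 + d for m, d in deltas.items()},
        "disease_drug": {m: 8.0 for m in deltas},
        "drug_only": {m: 8.0 for m in deltas},
    })
    frame.index.name = "mirna_id"
    return ExpressionTable(frame)


def make_table(rows):
    """Build an ExpressionTable from {mirna: (control, disease,
    disease_drug, drug_only)}."""
    frame = pd.DataFrame.from_dict(
        {m: dict(zip(("control", "disease", "disease_drug", "drug_only"), v))
         for m, v in rows.items()}, orient="index")
    frame.index.name = "mirna_id"
    return ExpressionTable(frame)


@pytest.fixture(scope="session")
def bundle():
    """One default synthetic bundle shared across read-only tests."""
    return generate(SyntheticConfig(), seed=7)
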