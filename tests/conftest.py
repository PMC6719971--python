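import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from clustermod.io_core import ExpressionMatrix, GeneModel, GeneTable, SampleMeta

settings.register_profile(
    "suite", derandomize=True, max_examples=40, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture
def toy_genes():
    """12-gene toy genome: one 3-enzyme cluster, one isolated enzyme gene
    200 kb away, and 8 non-enzyme genes."""
    enz = lambda i: frozenset([["CYP450", "UDP-glucosyltransferase",
                                "2OG-FeII-oxygenase"][i % 3]])
    genes = [
        GeneModel("e1", "chr1", 10_000, 11_000, "+", enz(0), frozenset(["F1"])),
        GeneModel("e2", "chr1", 13_000, 14_000, "-", enz(1), frozenset(["F2"])),
        GeneModel("e3", "chr1", 16_000, 17_000, "+", enz(2), frozenset(["F3"])),
        GeneModel("e4", "chr1", 216_000, 217_000, "+", enz(0), frozenset(["F4"])),
    ]
    pos = 300_000
    for i in range(8):
        genes.append(GeneModel(f"n{i}", "chr1", pos, pos + 1_000, "+"))
        pos += 40_000
    return GeneTable(genes)


@pytest.fixture
def small_expr():
    """Deterministic 6-gene x 8-sample matrix: two perfectly correlated
    triplets plus independent jitter-free profiles."""
    rng = np.random.default_rng(42)
    f1 = rng.standard_normal(8)
    f2 = rng.standard_normal(8)
    rows = {
        "a1": 10 + 2 * f1, "a2": 5 + 1 * f1, "a3": 8 + 3 * f1,
        "b1": 10 + 2 * f2, "b2": 5 + 1 * f2, "b3": 8 + 3 * f2,
    }
    df = pd.DataFrame(rows, index=[f"s{i}" for i in range(8)]).T
    df.index.name = "gene_id"
    return ExpressionMatrix(df)
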