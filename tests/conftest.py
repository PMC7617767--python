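import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from vmsig.io_formats import DEResultTable, ExpressionMatrix, GeneSet, RankedList

settings.register_profile(
    "vmsig",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("vmsig")


@pytest.fixture
def four_gene_list() -> RankedList:
    """The canonical 4-gene ranked list used by the hand-computed walks."""
    return RankedList([("A", 3.0), ("B", 2.0), ("C", 1.0), ("D", -1.0)])


@pytest.fixture
def small_de_table() -> DEResultTable:
    rng = np.random.default_rng(11)
    n = 200
    genes = [f"G{i:03d}" for i in range(n)]
    sig = rng.random(n) < 0.75
    fdr = np.where(sig, rng.uniform(0, 0.049, n), rng.uniform(0.05, 1, n))
    lfc = np.where(sig, rng.uniform(0.1, 4, n), rng.uniform(-4, 4, n))
    p = fdr * rng.uniform(0.5, 1.0, n)
    return DEResultTable(
        "toy", pd.DataFrame({"gene": genes, "log2fc": lfc, "pvalue": p, "fdr": fdr})
    )


def make_matrix(values, genes=None, samples=None, scale="linear") -> ExpressionMatrix:
    arr = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples), scale)


@pytest.fixture
def gene_set_factory():
    def make(name: str, *members: str) -> GeneSet:
        return GeneSet(name, frozenset(members))

    return make
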