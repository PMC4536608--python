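import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from rer_scan.core_io import ExpressionMatrix, GeneTable

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_gene_table(n_genes: int, chroms: int = 1, spacing: int = 1000) -> GeneTable:
    rows = []
    per = n_genes // chroms
    for c in range(chroms):
        for i in range(per):
            rows.append((f"g{c}_{i}", f"chr{c + 1}", i * spacing, i * spacing + spacing // 2))
    return GeneTable.from_frame(
        pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])
    )


def make_expression(gene_table: GeneTable, values: np.ndarray, prefix: str = "s") -> ExpressionMatrix:
    return ExpressionMatrix(
        pd.DataFrame(
            values,
            index=pd.Index(gene_table.data["gene_id"], name="gene_id"),
            columns=[f"{prefix}{j}" for j in range(values.shape[1])],
        )
    )


@pytest.fixture
def gene_table_10():
    return make_gene_table(10)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
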