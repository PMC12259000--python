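import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from irdatlas.io import ExpressionMatrix, GeneRecord
from irdatlas.schemes import CellGroupScheme, TissueGroupScheme


@pytest.fixture(scope="session")
def tissue_scheme() -> TissueGroupScheme:
    return TissueGroupScheme.builtin()


@pytest.fixture(scope="session")
def cell_scheme() -> CellGroupScheme:
    return CellGroupScheme.builtin()


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    frame = pd.DataFrame(
        [[1.0, 2.0], [3.0, 4.0], [0.0, 5.0]],
        index=["GA", "GB", "GC"],
        columns=["s1", "s2"],
    )
    return ExpressionMatrix(frame)


def make_gene(symbol="GENE1", status="disease", subsets=("RP",), modes=("AR",),
              year=2010, go=(), cats=(), is_locus=False) -> GeneRecord:
    return GeneRecord(
        symbol=symbol,
        status=status,
        phenotype_subsets=frozenset(subsets),
        inheritance_modes=frozenset(modes),
        discovery_year=year,
        go_terms=frozenset(go),
        functional_categories=frozenset(cats),
        is_locus=is_locus,
    )
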