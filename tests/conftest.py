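import pandas as pd
import pytest

from methexp.expression import process_expression_matrix
from methexp.integration import integrate_profiles
from methexp.methylation import betas_from_arrayset, process_beta_matrix
from methexp.simulate import fixture_from_table1


@pytest.fixture(scope="session")
def table1_fixture():
    """Deterministic 19-gene fixture with a small decoy load."""
    return fixture_from_table1(decoys=20, seed=1)


@pytest.fixture(scope="session")
def table1_selection(table1_fixture):
    """Full in-memory selection run on the fixture: (records, report, logs)."""
    meth, expr, design = table1_fixture
    betas, _ = process_beta_matrix(betas_from_arrayset(meth))
    normalized, _ = process_expression_matrix(expr)
    return integrate_profiles(betas, meth.annotation, normalized, design)
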