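import numpy as np
import pandas as pd
import pytest

from regmod import ExpressionMatrix, RegulatoryNetwork


@pytest.fixture
def tiny_expression(tmp_path):
    """2-gene x 3-sample TSV with one NA."""
    path = tmp_path / "expr.tsv"
    path.write_text("gene\ts1\ts2\ts3\nG1\t1.0\t2.0\tNA\nG2\t0.5\t-0.5\t1.5\n")
    return path


@pytest.fixture
def simple_network():
    edges = pd.DataFrame(
        [
            ("A", "B", "src1", 0.5),
            ("A", "B", "src2", 0.3),
            ("A", "C", "src1", 1.0),
            ("B", "C", "src1", 1.0),
        ],
        columns=["regulator", "target", "source", "weight"],
    )
    return RegulatoryNetwork(edges)


def make_expression(values: np.ndarray, genes=None, samples=None, condition=None):
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), condition or {}
    )


@pytest.fixture
def make_expr():
    return make_expression
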