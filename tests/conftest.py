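import numpy as np
import pandas as pd
import pytest

from stromasig.containers import LOG2, ZSCORE, ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_expression_tsv(tmp_path):
    path = tmp_path / "expr.tsv"
    path.write_text(
        "gene\ts1\ts2\n"
        "A\t1.0\t2.0\n"
        "B\t3.0\t4.0\n"
        "C\t5.0\t6.0\n"
    )
    return path


@pytest.fixture
def clinical_tsv(tmp_path):
    path = tmp_path / "clinical.tsv"
    path.write_text(
        "sample\ttime\tevent\tstage\n"
        "s1\t100\t1\tI\n"
        "s2\t250\t0\tII\n"
        "s3\t400\t1\tI\n"
    )
    return path


def make_matrix(values, genes=None, samples=None, scale=LOG2):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), scale=scale)


def make_zmatrix(values, genes=None, samples=None):
    return make_matrix(values, genes=genes, samples=samples, scale=ZSCORE)
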