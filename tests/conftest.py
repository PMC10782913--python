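import numpy as np
import pytest

import mrgps


@pytest.fixture(scope="session")
def demo_cohort():
    """One small synthetic cohort shared across read-only tests."""
    return mrgps.generate_cohort(mrgps.default_demo_config(17))


@pytest.fixture()
def tiny_expression(tmp_path):
    path = tmp_path / "expr.tsv"
    path.write_text(
        "gene\tS1\tS2\n"
        "A\t1.0\t2.0\n"
        "B\t3.5\t0.25\n"
        "C\t2.0\t2.0\n"
    )
    return path


@pytest.fixture()
def tiny_clinical(tmp_path):
    path = tmp_path / "clin.tsv"
    path.write_text(
        "sample_id\ttime_months\tevent\tgrade\n"
        "S1\t12.0\t1\tLGG\n"
        "S2\t30.0\t0\tLGG\n"
        "S3\t6.0\t1\tGBM\n"
        "S4\t9.5\t0\tGBM\n"
    )
    return path


def make_expression(gene_ids, values, sample_ids=None):
    values = np.asarray(values, dtype=float)
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(values.shape[1])]
    return mrgps.ExpressionMatrix(list(gene_ids), list(sample_ids), values)
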