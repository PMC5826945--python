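import numpy as np
import pandas as pd
import pytest

from sczprio.types import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_expression(values: np.ndarray, genes, ages, regions=None,
                    diagnosis=None, donors=None) -> ExpressionMatrix:
    """Assemble an ExpressionMatrix from raw pieces for small test panels."""
    n_samples = values.shape[1]
    samples = [f"s{i}" for i in range(n_samples)]
    meta = pd.DataFrame(
        {
            "donor": donors if donors is not None else samples,
            "region": regions if regions is not None else ["PFC"] * n_samples,
            "age_days": list(ages),
            "stage": ["NA"] * n_samples,
            "diagnosis": diagnosis if diagnosis is not None else ["NA"] * n_samples,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    vals = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                        columns=samples)
    return ExpressionMatrix(values=vals, meta=meta)


@pytest.fixture
def tiny_panel():
    """3 genes x 6 samples: one declining, one rising, one flat."""
    ages = [56, 100, 266, 3200, 5000, 8000]
    values = np.array(
        [
            [10.0, 9.0, 8.0, 2.0, 1.5, 1.0],   # early-high
            [1.0, 1.5, 2.0, 8.0, 9.0, 10.0],   # late-high
            [5.0, 5.0, 5.0, 5.0, 5.0, 5.0],    # flat
        ]
    )
    return make_expression(values, ["gA", "gB", "gC"], ages)
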