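import numpy as np
import pandas as pd
import pytest

import chemosig as cs


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_counts():
    """3-gene x 2-sample raw-count matrix."""
    return cs.ExpressionMatrix(
        pd.DataFrame(
            [[10.0, 20.0], [5.0, 2.0], [100.0, 80.0]],
            index=["TP53", "KRAS", "GAPDH"],
            columns=["S1", "S2"],
        )
    )


@pytest.fixture(scope="session")
def small_study():
    """One default synthetic study (irinotecan response only), shared."""
    return cs.simulate_study(seed=1, drugs=("irinotecan",))


@pytest.fixture(scope="session")
def small_study_aucs(small_study):
    from chemosig.workflows import fitted_aucs

    return (
        fitted_aucs(small_study, "pool", "irinotecan"),
        fitted_aucs(small_study, "validation", "irinotecan"),
    )
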