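import numpy as np
import pandas as pd
import pytest

from wrfenboost.association import MatchedDataset


def make_dataset(X: np.ndarray, y: np.ndarray, gene_prefix: str = "g") -> MatchedDataset:
    """Wrap raw arrays as a matched dataset (unit-test shortcut past the
    association stage)."""
    n, m = X.shape
    cols = [f"{gene_prefix}{i:04d}" for i in range(1, m + 1)]
    meta = pd.DataFrame(
        {
            "instance_id": [f"inst{i:05d}" for i in range(n)],
            "cell_line": "CL00",
            "pert_id": "drug000",
            "pert_type": "compound",
            "dose_um": 1.0,
            "time_h": 24.0,
            "batch": "b1",
        }
    )
    return MatchedDataset(X=pd.DataFrame(X, columns=cols), y=pd.Series(y, name="viability"), meta=meta)


@pytest.fixture
def planted_linear_dataset():
    """300 x 40 dataset whose target is a noisy linear function of 3 genes."""
    rng = np.random.default_rng(42)
    X = rng.standard_normal((300, 40))
    y = 3.0 * X[:, 0] - 2.0 * X[:, 4] + 1.5 * X[:, 9] + 0.05 * rng.standard_normal(300)
    return make_dataset(X, y)
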