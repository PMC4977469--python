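import numpy as np
import pandas as pd
import pytest

from mesopotency.containers import DesignTable, ExpressionMatrix
from mesopotency.synthetic_data import SimulationTruth


@pytest.fixture
def toy_design() -> DesignTable:
    rows = [
        {"sample": f"{cond}_{r}", "condition": cond, "replicate": r}
        for cond in ("baseline", "mid", "high")
        for r in (1, 2, 3)
    ]
    return DesignTable(pd.DataFrame(rows))


@pytest.fixture
def toy_matrix(toy_design) -> ExpressionMatrix:
    rng = np.random.default_rng(0)
    genes = [f"G{i}" for i in range(20)]
    values = pd.DataFrame(
        rng.normal(8.0, 1.0, size=(20, 9)), index=genes, columns=toy_design.samples
    )
    return ExpressionMatrix(values, toy_design)


@pytest.fixture
def small_truth() -> SimulationTruth:
    return SimulationTruth(seed=11, n_genes=300)
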