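import numpy as np
import pandas as pd
import pytest

from strisk.expression_io import ExpressionTensor


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_tensor(values: np.ndarray, regions=None, stages=None, unit=None,
                stage_order=None) -> ExpressionTensor:
    """Small annotated tensor straight from an array (test helper)."""
    if unit is None:
        unit = "LOG2CPM" if (np.asarray(values) < 0).any() else "RPKM"
    n_genes, n_samples = values.shape
    genes = [f"G{i}" for i in range(n_genes)]
    sids = [f"S{j}" for j in range(n_samples)]
    samples = pd.DataFrame(index=pd.Index(sids, name="sample_id"))
    if regions is not None:
        samples["region"] = regions
    if stages is not None:
        samples["stage"] = stages
    return ExpressionTensor(
        values=pd.DataFrame(values, index=genes, columns=sids),
        samples=samples,
        unit=unit,
        stage_order=list(stage_order or []),
    )


def pair_count_rank_biserial(values: np.ndarray, risk: np.ndarray) -> tuple[float, float]:
    """Exhaustive pair-counting oracle: (U, r) with ties counted 1/2.

    Enumerates every (risk, non-risk) gene pair; U is wins + half-ties of
    the risk group, r is (wins - losses) / (n1 * n2).
    """
    a = values[risk]
    b = values[~risk]
    wins = ties = 0
    for x in a:
        for y in b:
            if x > y:
                wins += 1
            elif x == y:
                ties += 1
    n_pairs = len(a) * len(b)
    losses = n_pairs - wins - ties
    U = wins + 0.5 * ties
    return U, (wins - losses) / n_pairs
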