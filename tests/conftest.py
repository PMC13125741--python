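import numpy as np
import pytest

from fscore import ConfusionTable, PairedObservation, PerfParams


@pytest.fixture
def cfdna_table() -> ConfusionTable:
    """cfDNA test on the prenatal screening cohort: 38/38 TPs, 9 FPs."""
    return ConfusionTable(N=15841, S=38, d=38, b=9)


@pytest.fixture
def screening_table() -> ConfusionTable:
    """Standard first-trimester screening: 30/38 TPs, 854 FPs."""
    return ConfusionTable(N=15841, S=38, d=30, b=854)


@pytest.fixture
def trisomy_pair(cfdna_table, screening_table) -> PairedObservation:
    return PairedObservation(cfdna_table, screening_table)


@pytest.fixture
def toy_table() -> ConfusionTable:
    return ConfusionTable(N=10, S=4, d=4, b=1)


@pytest.fixture
def null_55() -> PerfParams:
    return PerfParams(ps=0.8, pp=0.5)


@pytest.fixture
def alt_69() -> PerfParams:
    return PerfParams(ps=0.9, pp=0.6)


def brute_force_min_tail_pvalue(support, probs, f_obs, tol=1e-12):
    """O(n^2) reference implementation of the minimum-tail p-value."""
    support = np.asarray(support)
    probs = np.asarray(probs)

    def C(x):
        return min(probs[support <= x + tol].sum(), probs[support >= x - tol].sum())

    c_obs = C(f_obs)
    return float(sum(p for f, p in zip(support, probs) if C(f) <= c_obs + tol))
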