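import numpy as np
import pytest

from cistrans import ChromosomeSet, MixtureParams, TransModel, WeibullParams


@pytest.fixture(scope="session")
def human_model() -> TransModel:
    """Trans model on the default 23-chromosome human set."""
    return TransModel()


@pytest.fixture(scope="session")
def toy_model() -> TransModel:
    """Two tiny chromosomes: small enough for exhaustive pair enumeration."""
    return TransModel(ChromosomeSet(("a", "b"), (10, 20)))


@pytest.fixture(scope="session")
def pietzner_params() -> MixtureParams:
    """Final-fit mixture parameters of the primary proteomic dataset."""
    return MixtureParams(
        WeibullParams(6.777, 4.478, shape_se=0.211, scale_se=0.024),
        weibull_fraction=0.799,
        fraction_se=0.013,
        source_total=2051,
    )


def enumerate_pair_pmf(lengths: tuple[int, ...]) -> np.ndarray:
    """Brute-force pmf of |p1 - p2| over all ordered same-chromosome pairs.

    Enumerates every ordered position pair on every chromosome, conditions
    on same-chromosome and distance > 0, and tabulates distances.  Index d
    of the returned array holds P(distance = d).
    """
    max_len = max(lengths)
    counts = np.zeros(max_len, dtype=np.int64)
    for n in lengths:
        for p1 in range(1, n + 1):
            for p2 in range(1, n + 1):
                d = abs(p1 - p2)
                if d > 0:
                    counts[d] += 1
    return counts / counts.sum()
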