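import numpy as np
import pandas as pd
import pytest

from rohscape import GenotypeMatrix, MarkerMap


@pytest.fixture
def tiny_panel():
    """2 individuals x 3 markers on one chromosome."""
    M = MarkerMap(pd.DataFrame({"chrom": ["1", "1", "1"],
                                "marker_id": ["m1", "m2", "m3"],
                                "pos": [1000, 5000, 9000]}))
    G = GenotypeMatrix(["a", "b"], np.array([[0, 1, 2], [2, 2, -1]], np.int8))
    return G, M


@pytest.fixture
def brute_maximal_runs():
    """Exhaustive enumeration of maximal valid homozygous runs: the
    independent oracle for the scanning detector."""

    def oracle(g, pos, L, mL, nH, nM):
        g = list(g)
        n = len(g)
        hom = [(x == 0 or x == 2) for x in g]
        valid = []
        for i in range(n):
            for j in range(i, n):
                if not (hom[i] and hom[j]):
                    continue
                w = g[i:j + 1]
                if sum(1 for x in w if x == 1) > nH:
                    continue
                if sum(1 for x in w if x == -1) > nM:
                    continue
                if j - i + 1 < L or pos[j] - pos[i] + 1 < mL:
                    continue
                valid.append((i, j))
        return sorted((i, j) for (i, j) in valid
                      if not any(a <= i and j <= b and (a, b) != (i, j)
                                 for (a, b) in valid))

    return oracle


@pytest.fixture
def random_panel_factory():
    """Random small genotype panels for oracle-equivalence testing."""

    def factory(rng, max_snps=60):
        n = int(rng.integers(5, max_snps + 1))
        g = rng.choice([-1, 0, 1, 2], size=n,
                       p=[0.05, 0.45, 0.15, 0.35]).astype(np.int8)
        pos = np.sort(rng.choice(np.arange(1, 10_000_000), size=n,
                                 replace=False))
        params = dict(L=int(rng.integers(2, 7)),
                      mL=float(rng.integers(1, 5_000_000)),
                      nH=int(rng.integers(0, 4)),
                      nM=int(rng.integers(0, 4)))
        return g, pos, params

    return factory
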