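import numpy as np
import pandas as pd
import pytest

from duoscan import MarkerCatalog, RecombinationMap


@pytest.fixture
def toy_catalog() -> MarkerCatalog:
    """Six markers on 2L/2R/X with fixed alleles (fly naming)."""
    frame = pd.DataFrame(
        {
            "chromosome": ["2", "2", "2", "2", "X", "X"],
            "arm": ["2L", "2L", "2R", "2R", "X", "X"],
            "position": [100, 250, 40, 90, 10, 55],
            "focal_allele": ["A", "C", "G", "T", "A", "G"],
            "other_allele": ["C", "T", "A", "G", "G", "A"],
        }
    )
    return MarkerCatalog(frame)


@pytest.fixture
def toy_map() -> RecombinationMap:
    return RecombinationMap.uniform(
        {"2L": 2.0, "2R": 2.0, "X": 2.5}, {"2L": 1000, "2R": 1000, "X": 1000}
    )


def random_counts(catalog: MarkerCatalog, n_samples: int, rng: np.random.Generator):
    """Random sync-style counts concentrated on the two parental alleles."""
    from duoscan.syncio import NUC_INDEX, CountTable

    n = len(catalog)
    counts = np.zeros((n, n_samples, 6), dtype=np.int64)
    focal_idx = catalog.frame["focal_allele"].map(NUC_INDEX).to_numpy()
    other_idx = catalog.frame["other_allele"].map(NUC_INDEX).to_numpy()
    cov = rng.poisson(20, size=(n, n_samples))
    focal = rng.binomial(cov, 0.3)
    rows = np.arange(n)
    for j in range(n_samples):
        counts[rows, j, focal_idx] = focal[:, j]
        counts[rows, j, other_idx] += cov[:, j] - focal[:, j]
    return CountTable(catalog, counts, [f"s{j + 1}" for j in range(n_samples)])
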