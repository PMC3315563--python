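"""Shared fixtures: one small genome/cohort reused across the suite.

The session-scoped cohort keeps the expensive pieces (genome layout, truth
sampling, coupling profile) to a single computation; tests that need
different parameters build their own small instances.
"""

import numpy as np
import pandas as pd
import pytest

from medipseq.annotate import FeatureMatrix
from medipseq.coupling import compute_coupling
from medipseq.genome import generate_genome
from medipseq.simulate import CohortDesign, generate_truth


@pytest.fixture(scope="session")
def genome():
    return generate_genome(seed=1, n_chroms=2, chrom_length=500_000, n_genes=50,
                           n_repeats_per_class=40)


@pytest.fixture(scope="session")
def truth(genome):
    return generate_truth(genome, CohortDesign(), seed=2)


@pytest.fixture(scope="session")
def coupling(genome):
    return compute_coupling(genome, 450.0)


@pytest.fixture(scope="session")
def small_genome():
    """A fast, single-chromosome genome for quantifier-level tests."""
    return generate_genome(seed=7, n_chroms=1, chrom_length=200_000, n_genes=10,
                           n_repeats_per_class=8)


def truth_feature_matrix(truth, genome, classes=None) -> FeatureMatrix:
    """Feature matrix built from ground-truth scores (no quantifier noise):
    the input the DMR/cluster stages see under ideal quantification."""
    from medipseq.annotate import aggregate_features
    from medipseq.track import MethylomeTrack

    tracks = []
    for i, s in enumerate(truth.samples):
        scores = truth.scores[i].astype(float)
        tracks.append(
            MethylomeTrack(s, genome.grid, scores, np.zeros_like(scores),
                           np.zeros(genome.grid.total_windows, dtype=np.int64))
        )
    return aggregate_features(tracks, genome, min_windows=1, feature_classes=classes)


@pytest.fixture(scope="session")
def truth_matrix(truth, genome):
    return truth_feature_matrix(truth, genome)


def make_feature_matrix(values: np.ndarray, samples=None, feature_class="cgi") -> FeatureMatrix:
    """Wrap a plain array as a FeatureMatrix with dummy metadata."""
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    samples = samples or [f"s{i}" for i in range(k)]
    idx = pd.Index([f"f{i}" for i in range(n)], name="feature_id")
    vals = pd.DataFrame(values, index=idx, columns=samples)
    meta = pd.DataFrame(
        {
            "feature_class": feature_class,
            "chrom": "chr1",
            "start": np.arange(n) * 1000,
            "end": np.arange(n) * 1000 + 500,
            "cpg_count": 5,
            "context": "",
            "n_windows": 5,
        },
        index=idx,
    )
    return FeatureMatrix(vals, meta)
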