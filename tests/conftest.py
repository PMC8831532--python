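"""Shared fixtures: small hand-built experiments and a fast simulated run."""

import numpy as np
import pandas as pd
import pytest

from rnasense import AnalysisParams, TimeCourseExperiment
from rnasense.synthetic import SyntheticSpec, simulate


def build_experiment(counts: dict, meta_rows: list[tuple], normalized: bool = False):
    """Construct a TimeCourseExperiment from a {sample: values} dict and
    (sample, condition, time, replicate) tuples."""
    genes = [f"g{i}" for i in range(len(next(iter(counts.values()))))]
    frame = pd.DataFrame(counts, index=genes, dtype=float)
    meta = pd.DataFrame(
        meta_rows, columns=["sample", "condition", "time_hpf", "replicate"]
    ).set_index("sample")
    return TimeCourseExperiment(counts=frame, samples=meta, normalized=normalized)


@pytest.fixture
def default_params():
    return AnalysisParams()


@pytest.fixture
def two_condition_exp():
    """2 conditions × 4 time points × 2 replicates, deterministic values."""
    times = [2.5, 3.0, 3.5, 4.0]
    counts = {}
    meta = []
    rng = np.random.default_rng(42)
    for cond in ("WT", "MUT"):
        for rep in (1, 2):
            for t in times:
                sid = f"{cond}_r{rep}_t{t:g}"
                counts[sid] = rng.integers(80, 120, size=5).astype(float)
                meta.append((sid, cond, t, rep))
    return build_experiment(counts, meta, normalized=True)


@pytest.fixture(scope="session")
def small_spec():
    """Fast generator spec for end-to-end tests (same design, fewer genes)."""
    return SyntheticSpec(n_flat=60, n_zygotic=24, n_maternal=16, seed=11)


@pytest.fixture(scope="session")
def small_sim(small_spec):
    return simulate(small_spec)
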