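"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import thermoagree as ta


@pytest.fixture(scope="session")
def model():
    return ta.HeatFluxModel(0.5)


@pytest.fixture(scope="session")
def cohort20(model):
    """One 20-patient default cohort, paired and artifact-filtered once.

    Shared across tests that probe cohort-level statistical structure
    (difference-SD calibration, bias recovery, filter sensitivity, report
    invariants) so the 48 h x 1 Hz simulation runs a single time.
    """
    cohort = ta.CohortConfig(n_patients=20, seed=1)
    bundles = ta.simulate_cohort(cohort)
    per_patient = [ta.pair_streams(b.ds, b.ref, model) for b in bundles]
    pooled = ta.concat_datasets(per_patient)
    filtered = ta.remove_artifacts(pooled)
    return bundles, pooled, filtered


def dataset_from_diffs(diffs, filtered: bool = False) -> ta.PairedDataset:
    """Wrap a plain difference vector as a PairedDataset (ref held at 34)."""
    d = np.asarray(diffs, dtype=float)
    frame = pd.DataFrame(
        {
            "t": np.arange(d.size, dtype=float) * 1800.0,
            "ds_core": 34.0 + d,
            "ref": 34.0,
            "diff": d,
            "artifact": False,
        }
    )
    return ta.PairedDataset(frame=frame, filtered=filtered)


def icc_anova_oracle(x, y):
    """Consistency ICC by explicit elementwise two-way ANOVA sums of squares.

    Deliberately loop-based and definition-first, independent of the
    package's vectorized implementation.
    """
    x = list(map(float, x))
    y = list(map(float, y))
    n, k = len(x), 2
    grand = sum(x + y) / (n * k)
    ssb = sum(k * ((xi + yi) / 2 - grand) ** 2 for xi, yi in zip(x, y))
    col_x = sum(x) / n
    col_y = sum(y) / n
    ssc = n * ((col_x - grand) ** 2 + (col_y - grand) ** 2)
    sst = sum((v - grand) ** 2 for v in x + y)
    sse = sst - ssb - ssc
    msb = ssb / (n - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msb - mse) / (msb + (k - 1) * mse)


def mc_icc_power(n, p0, p1, alpha=0.05, n_sim=5000, seed=0):
    """Monte-Carlo power of the one-sided F-method ICC test.

    Simulates studies from the bivariate model x = s + e1, y = s + e2 with
    Var(s) = p1 and Var(e) = 1 - p1 (true consistency ICC = p1), and rejects
    H0: ICC = p0 when the one-sided lower F confidence bound exceeds p0.
    """
    rng = np.random.default_rng(seed)
    s = rng.normal(0.0, np.sqrt(p1), (n_sim, n, 1))
    e = rng.normal(0.0, np.sqrt(1.0 - p1), (n_sim, n, 2))
    data = s + e
    grand = data.mean(axis=(1, 2), keepdims=True)
    row = data.mean(axis=2, keepdims=True)
    col = data.mean(axis=1, keepdims=True)
    ssb = 2.0 * ((row - grand) ** 2).sum(axis=(1, 2))
    ssc = n * ((col - grand) ** 2).sum(axis=(1, 2))
    sse = ((data - grand) ** 2).sum(axis=(1, 2)) - ssb - ssc
    f = (ssb / (n - 1)) / (sse / (n - 1))
    fq = stats.f.ppf(1.0 - alpha, n - 1, n - 1)
    lower = (f / fq - 1.0) / (f / fq + 1.0)
    return float(np.mean(lower > p0))
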