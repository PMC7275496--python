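"""Shared fixtures: small record builders used across the suite."""

import numpy as np
import pytest

from cprobit import ObservationRecord


def make_records(y1, y2, covs1=None, covs2=None):
    """Build long-format records for n subjects from per-time arrays.

    covs1/covs2: (n, p) covariate arrays for time 1 / time 2 (default: the
    period-indicator design (t, t*x) with x = 0, i.e. a single constant-1
    difference column is NOT created — pass covariates explicitly).
    """
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    n = y1.size
    if covs1 is None:
        covs1 = np.zeros((n, 1))
    if covs2 is None:
        covs2 = np.ones((n, 1))
    covs1 = np.atleast_2d(np.asarray(covs1, dtype=float))
    covs2 = np.atleast_2d(np.asarray(covs2, dtype=float))
    recs = []
    for i in range(n):
        recs.append(ObservationRecord(i + 1, 1, float(y1[i]), tuple(covs1[i])))
        recs.append(ObservationRecord(i + 1, 2, float(y2[i]), tuple(covs2[i])))
    return recs


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def single_covariate_dataset(rng):
    """n = 50 subjects, one covariate difference, positive outcomes."""
    from cprobit import build_paired_dataset

    n = 50
    x = rng.standard_normal(n)
    y1 = 5.0 + rng.standard_normal(n)
    y2 = y1 + 0.8 * x + rng.standard_normal(n)
    recs = make_records(y1, y2, covs1=np.zeros((n, 1)), covs2=x[:, None])
    return build_paired_dataset(recs)
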