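"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately use explicit loops and closed-form
arithmetic, independent of the package's vectorized implementations.
"""

from __future__ import annotations

from math import comb

import numpy as np
import pandas as pd
import pytest

from mmsig import synthetic as sd


def base_deviation_oracle(e, w):
    """Explicit-loop BASE preliminary score over all prefixes.

    Returns (score, rank) with smallest rank winning ties in |f - b|.
    """
    n = len(e)
    f_tot = sum(abs(e[j] * w[j]) for j in range(n))
    b_tot = sum(abs(e[j] * (1.0 - w[j])) for j in range(n))
    assert f_tot > 0 and b_tot > 0, "degenerate weights in oracle"
    best, best_abs, best_rank = 0.0, -1.0, -1
    fa = ba = 0.0
    for i in range(n):
        fa += abs(e[i] * w[i])
        ba += abs(e[i] * (1.0 - w[i]))
        d = fa / f_tot - ba / b_tot
        if abs(d) > best_abs + 1e-15:
            best, best_abs, best_rank = d, abs(d), i
    return best, best_rank


def logrank_oracle(groups, time, event):
    """Two-group log-rank chi-square by explicit risk-set enumeration."""
    groups = np.asarray(groups)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    labels = sorted(set(groups.tolist()))
    g1 = groups == labels[0]
    O1 = E1 = V = 0.0
    for t in sorted(set(time[event == 1].tolist())):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & g1).sum()
        O1 += d1
        E1 += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    assert V > 0
    return (O1 - E1) ** 2 / V


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher P by exhaustive enumeration over fixed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = a + b + c + d

    def prob(x):
        if x < 0 or x > r1 or c1 - x < 0 or c1 - x > r2:
            return 0.0
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    return sum(p for p in (prob(x) for x in range(r1 + 1)) if p <= p_obs * (1 + 1e-9))


@pytest.fixture(scope="session")
def base_oracle():
    return base_deviation_oracle


@pytest.fixture(scope="session")
def logrank_ref():
    return logrank_oracle


@pytest.fixture(scope="session")
def fisher_ref():
    return fisher_oracle


@pytest.fixture(scope="session")
def small_cohort():
    """Compact seeded cohort shared by fast tests."""
    cfg = sd.CohortConfig(
        n_samples=200,
        n_genes=300,
        drivers=(sd.DriverSpec("TP53", frequency=0.15, n_targets=30, effect=2.0),),
        seed=42,
    )
    return sd.generate_cohort(cfg)


@pytest.fixture(scope="session")
def paired_cohort():
    cfg = sd.CohortConfig(
        n_samples=120,
        n_genes=150,
        drivers=(sd.DriverSpec("TP53", frequency=0.2, n_targets=20, effect=2.0),),
        seed=7,
    )
    return sd.generate_paired_bone_marrow(sd.generate_cohort(cfg))


def random_survival_fixtures(n_datasets=200, max_n=8, seed=0):
    """Small random survival datasets (with ties) for oracle comparisons."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_datasets):
        n = int(rng.integers(4, max_n + 1))
        time = rng.integers(1, 5, size=n).astype(float)  # heavy ties on purpose
        event = rng.integers(0, 2, size=n)
        groups = np.array(["a"] * (n // 2) + ["b"] * (n - n // 2))
        rng.shuffle(groups)
        # need >= 1 event and both groups represented among risk sets
        if event.sum() == 0:
            event[int(rng.integers(0, n))] = 1
        out.append((groups, time, event))
    return out
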