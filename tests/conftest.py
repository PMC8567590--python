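"""Shared fixtures: small catalogs, complete/incomplete datasets, and a
session-scoped sparse-VAR recovery simulation reused by several tests."""

from __future__ import annotations

import numpy as np
import pytest

import idionet as idn


@pytest.fixture()
def catalog5() -> idn.SymptomCatalog:
    return idn.SymptomCatalog.from_entries(
        [
            (1, "bodydiss", "Body dissatisfaction"),
            (2, "drivethin", "Drive for thinness"),
            (3, "shame", "Shame"),
            (4, "worry", "Worry"),
            (5, "guilt", "Guilt"),
        ]
    )


@pytest.fixture()
def schedule() -> idn.Schedule:
    return idn.Schedule(days=15, beeps_per_day=5)


@pytest.fixture()
def complete_ds(catalog5, schedule) -> idn.EMADataset:
    """Fully observed 75-beep dataset on 5 items with nontrivial variation."""
    rng = np.random.default_rng(42)
    values = np.clip(50 + 12 * rng.standard_normal((schedule.total_beeps, 5)), 0, 100)
    return idn.EMADataset("p1", schedule, catalog5, values)


def simulate_var_pairs(k, n_pairs, B, K, seed, burn=50):
    """Draw standardized lag-1 pairs from a stationary VAR(1) with known truth."""
    rng = np.random.default_rng(seed)
    chol_Q = np.linalg.cholesky(np.linalg.inv(K))
    x = np.zeros(k)
    rows = []
    for _ in range(n_pairs + burn + 1):
        x = B @ x + chol_Q @ rng.standard_normal(k)
        rows.append(x.copy())
    arr = np.asarray(rows[burn:])
    pairs = idn.LaggedPairs(
        "sim", tuple(f"item{j}" for j in range(k)), arr[:-1], arr[1:]
    )
    std, _ = idn.standardize(pairs)
    return std


RECOVERY_K = 6
RECOVERY_N_PAIRS = 500
RECOVERY_N_SEEDS = 50


def recovery_truth():
    """Sparse (B*, K*): a two-edge temporal hub (item 0, the unique top
    out-strength item), one further temporal edge, and three
    contemporaneous edges."""
    k = RECOVERY_K
    B = np.zeros((k, k))
    np.fill_diagonal(B, 0.3)
    B[1, 0] = 0.35
    B[2, 0] = 0.35
    B[4, 3] = -0.35
    K = np.eye(k)
    K[0, 1] = K[1, 0] = -0.3
    K[2, 3] = K[3, 2] = 0.3
    K[4, 5] = K[5, 4] = -0.3
    return B, K


@pytest.fixture(scope="session")
def recovery_fits():
    """EBIC-selected fits on 50 independent draws from the recovery truth.

    Session-scoped: this is the expensive simulation shared by the support
    -recovery acceptance check and the estimation-bias property test.
    """
    B_true, K_true = recovery_truth()
    fits = []
    for seed in range(RECOVERY_N_SEEDS):
        pairs = simulate_var_pairs(
            RECOVERY_K, RECOVERY_N_PAIRS, B_true, K_true, seed=1000 + seed
        )
        # dense grid: at n=500 the EBIC optimum is sensitive to penalty
        # resolution, and the default 10-point grid steps over it
        fits.append((pairs, idn.fit_gvar_path(pairs, n_lambda=20)))
    return {"B_true": B_true, "K_true": K_true, "fits": fits}
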