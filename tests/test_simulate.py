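"""Synthetic cohort generator: reproducibility, moment checks against VAR
theory, missingness, and recovery metrics."""

from __future__ import annotations

import numpy as np
import pytest

import idionet as idn
from idionet.simulate import ParticipantTruth

from test_gvar import make_fit


def small_spec(B, K, items=("bodydiss", "drivethin", "shame"), days=15, beeps=5,
               missing=0.0, seed=0):
    catalog = idn.default_catalog()
    return idn.TruthSpec(
        catalog=catalog,
        schedule=idn.Schedule(days=days, beeps_per_day=beeps),
        participants=[ParticipantTruth("P1", tuple(items), B, K)],
        missing_prob=missing,
        seed=seed,
    )


def lag1_autocorr(x):
    x = x - x.mean()
    return float(np.sum(x[1:] * x[:-1]) / np.sum(x * x))


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def test_nonstationary_truth_rejected():
    B = np.eye(3) * 1.05
    with pytest.raises(idn.ValidationError, match="non-stationary"):
        small_spec(B, np.eye(3))


def test_non_pd_precision_rejected():
    K = np.eye(3)
    K[0, 1] = K[1, 0] = 1.5
    with pytest.raises(idn.ValidationError, match="positive definite"):
        small_spec(np.zeros((3, 3)), K)


# ---------------------------------------------------------------------------
# Reproducibility and missingness
# ---------------------------------------------------------------------------


def test_same_seed_identical_cohort_and_files(tmp_path):
    spec1 = idn.make_default_cohort(seed=5)
    spec2 = idn.make_default_cohort(seed=5)
    ds1, rec1 = idn.simulate_cohort(spec1)
    ds2, rec2 = idn.simulate_cohort(spec2)
    assert rec1 == rec2
    for a, b in zip(ds1, ds2):
        np.testing.assert_array_equal(a.values, b.values)
    p1 = idn.write_ema(ds1, tmp_path / "a.csv", format="wide")
    p2 = idn.write_ema(ds2, tmp_path / "b.csv", format="wide")
    assert p1.read_bytes() == p2.read_bytes()


def test_default_cohort_dimensions():
    spec = idn.make_default_cohort(seed=0)
    datasets, record = idn.simulate_cohort(spec)
    assert len(datasets) == 34
    assert all(ds.schedule.total_beeps == 75 for ds in datasets)
    assert all(len(ds.catalog) == 55 for ds in datasets)
    assert len(record["participants"]) == 34
    n_null = sum(
        not np.any(np.asarray(p["B"]))
        for p in record["participants"].values()
    )
    assert n_null >= 2  # no-temporal-process participants are present


def test_missing_beep_count_near_expectation():
    """With 20% beep nonresponse the observed beep count averages ~60 of 75."""
    counts = []
    for seed in range(40):
        spec = small_spec(np.zeros((3, 3)), np.eye(3), missing=0.2, seed=seed)
        ds, _ = idn.simulate_cohort(spec)
        observed = (~np.isnan(ds[0].values[:, 0])).sum()
        counts.append(observed)
    assert abs(np.mean(counts) - 60) < 3  # se of the mean ~ 0.6


# ---------------------------------------------------------------------------
# Moments vs VAR(1) theory
# ---------------------------------------------------------------------------


def test_white_noise_truth_has_near_zero_autocorrelation():
    """With no temporal process the lag-1 sample autocorrelation at n=75 has
    sd ~ 1/sqrt(75) ~ 0.115, so a 2-sigma band of 0.25 holds ~95% of the
    time and the autocorrelations average out to ~0."""
    hits = 0
    rs = []
    n_rep = 60
    for seed in range(n_rep):
        spec = small_spec(np.zeros((3, 3)), np.eye(3), seed=seed)
        ds, _ = idn.simulate_cohort(spec)
        r = lag1_autocorr(ds[0].item_values("bodydiss"))
        rs.append(r)
        hits += abs(r) < 0.25
    assert hits / n_rep >= 0.9
    assert abs(np.mean(rs)) < 0.06


def test_diagonal_truth_long_run_autocorrelation():
    """x_t = 0.5 x_{t-1} + e_t has lag-1 autocorrelation 0.5; with one long
    day there are no restarts to dilute it."""
    B = np.eye(3) * 0.5
    spec = small_spec(B, np.eye(3), days=1, beeps=2000, seed=1)
    ds, _ = idn.simulate_cohort(spec)
    r = lag1_autocorr(ds[0].item_values("bodydiss"))
    assert r == pytest.approx(0.5, abs=0.06)


def test_stationary_covariance_solves_lyapunov_and_matches_simulation():
    B = np.array([[0.4, 0.2, 0.0], [0.0, 0.3, 0.0], [0.1, 0.0, 0.2]])
    Q = np.linalg.inv(np.eye(3) + 0.2 * np.ones((3, 3)))
    S = idn.stationary_covariance(B, Q)
    np.testing.assert_allclose(S, B @ S @ B.T + Q, atol=1e-10)
    # the observed series is the latent process scaled per item, so its
    # long-run correlation matrix approaches the stationary correlations
    truth = ParticipantTruth("P1", ("bodydiss", "drivethin", "shame"),
                             B, np.linalg.inv(Q), active_scale=5.0, active_loc=50.0)
    spec = idn.TruthSpec(idn.default_catalog(), idn.Schedule(1, 20000), [truth],
                         missing_prob=0.0, seed=3)
    ds, _ = idn.simulate_cohort(spec)
    cols = ds[0].catalog.indices(truth.active_items)
    emp_corr = np.corrcoef(ds[0].values[:, cols].T)
    d = np.sqrt(np.diag(S))
    np.testing.assert_allclose(emp_corr, S / np.outer(d, d), atol=0.05)
    # per-item marginal sd on the response scale equals active_scale
    np.testing.assert_allclose(
        ds[0].values[:, cols].std(axis=0), 5.0, rtol=0.05
    )


def test_day_restart_breaks_the_process_across_nights():
    """Within a day consecutive beeps correlate at the autoregressive level;
    across the overnight gap the restart makes them independent."""
    B = np.eye(2) * 0.7
    K = np.eye(2)
    truth = ParticipantTruth("P1", ("bodydiss", "drivethin"), B, K,
                             active_scale=1.0, active_loc=50.0)
    spec = idn.TruthSpec(idn.default_catalog(), idn.Schedule(3000, 2), [truth],
                         missing_prob=0.0, seed=4)
    ds, _ = idn.simulate_cohort(spec)
    x = ds[0].values[:, 0]
    within = np.corrcoef(x[ds[0].beep_index == 1], x[ds[0].beep_index == 2])[0, 1]
    overnight = np.corrcoef(
        x[ds[0].beep_index == 2][:-1], x[ds[0].beep_index == 1][1:]
    )[0, 1]
    assert within == pytest.approx(0.7, abs=0.05)
    assert abs(overnight) < 0.05


# ---------------------------------------------------------------------------
# Recovery metrics
# ---------------------------------------------------------------------------


def toy_truth_record():
    B = np.zeros((3, 3))
    B[1, 0] = 0.4
    K = np.eye(3)
    K[0, 2] = K[2, 0] = -0.3
    return B, K, {
        "participants": {
            "P1": {"active_items": ["a", "b", "c"], "B": B.tolist(), "K": K.tolist()}
        }
    }


def test_perfect_fit_scores_ones():
    B, K, record = toy_truth_record()
    fit = make_fit(B, K, items=("a", "b", "c"))
    metrics = idn.evaluate_recovery({"P1": fit}, record).iloc[0]
    assert metrics["sens_B"] == 1.0 and metrics["spec_B"] == 1.0
    assert metrics["sens_K"] == 1.0 and metrics["spec_K"] == 1.0
    assert metrics["target_hit"] == 1.0


def test_empty_fit_on_nonempty_truth():
    B, K, record = toy_truth_record()
    fit = make_fit(np.zeros((3, 3)), np.eye(3), items=("a", "b", "c"))
    metrics = idn.evaluate_recovery({"P1": fit}, record).iloc[0]
    assert metrics["sens_B"] == 0.0 and metrics["spec_B"] == 1.0
    assert metrics["sens_K"] == 0.0 and metrics["spec_K"] == 1.0
    assert metrics["target_hit"] == 0.0


def test_mismatched_participants_error():
    _, _, record = toy_truth_record()
    fit = make_fit(np.zeros((3, 3)), np.eye(3), items=("a", "b", "c"))
    with pytest.raises(ValueError, match="different participants"):
        idn.evaluate_recovery({"P2": fit}, record)


def test_null_truth_participants_propagate_to_temporal_na():
    """End to end: participants generated with B* = 0 come out of the whole
    pipeline with no identifiable temporal target."""
    spec = idn.make_default_cohort(seed=11, n_participants=6)
    null_ids = [
        p.participant_id for p in spec.participants if not np.any(p.B)
    ]
    assert len(null_ids) >= 2
    datasets, _ = idn.simulate_cohort(spec)
    for ds in datasets:
        if ds.participant_id not in null_ids[:2]:
            continue
        sel_items = idn.select_items(ds, idn.SelectionRule("highest_mean", k=8))
        pairs, _ = idn.standardize(idn.build_lagged_pairs(ds, sel_items.items))
        best = idn.fit_gvar_path(pairs, n_lambda=8)
        cent = idn.compute_centrality(idn.to_networks(best))
        sel = idn.select_targets(cent, "out_strength", ds.participant_id)
        assert sel.is_na
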