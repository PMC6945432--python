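"""Evaluation metrics against brute-force oracles and hand computations."""

import itertools

import numpy as np
import pytest

from redsnn import (
    AT_RISK,
    CENSORED_OUT,
    DEAD,
    EvaluationReport,
    calibration_bins,
    concordance_index,
    evaluate_report,
    km_estimate,
    log_rank_test,
    mann_whitney,
    stratify_by_probability,
    window_roc_auc,
)

# --- independent oracles ------------------------------------------------


def cindex_oracle(risk, time, event):
    """Exhaustive pair enumeration (distinct times assumed)."""
    conc = comp = 0.0
    n = len(risk)
    for i, j in itertools.combinations(range(n), 2):
        first, second = (i, j) if time[i] < time[j] else (j, i)
        if not event[first]:
            continue  # earlier time censored: incomparable
        comp += 1
        if risk[first] > risk[second]:
            conc += 1
        elif risk[first] == risk[second]:
            conc += 0.5
    return conc / comp


def auc_oracle(score, label):
    """Concordant case-control pair count with mid-rank ties."""
    pos = score[label == 1]
    neg = score[label == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def km_oracle(time, event):
    """Hand product-limit table: deaths processed before censorings at ties."""
    out_t, out_s = [], []
    s = 1.0
    for tau in sorted(set(time[event == 1])):
        at_risk = int((time >= tau).sum())
        d = int(((time == tau) & (event == 1)).sum())
        s *= 1.0 - d / at_risk
        out_t.append(tau)
        out_s.append(s)
    return np.array(out_t), np.array(out_s)


# --- concordance index --------------------------------------------------


def test_reversed_risk_ordering_is_perfect():
    time = np.array([1.0, 2.0, 3.0, 4.0])
    risk = np.array([4.0, 3.0, 2.0, 1.0])
    assert concordance_index(risk, time, np.ones(4, int)) == 1.0


def test_constant_risk_is_chance():
    time = np.array([1.0, 2.0, 3.0, 4.0])
    assert concordance_index(np.ones(4), time, np.ones(4, int)) == 0.5


def test_five_patient_censored_example_matches_oracle():
    time = np.array([2.0, 4.0, 5.0, 7.0, 9.0])
    event = np.array([1, 0, 1, 1, 0])
    risk = np.array([0.9, 0.1, 0.6, 0.4, 0.2])
    assert concordance_index(risk, time, event) == pytest.approx(
        cindex_oracle(risk, time, event)
    )


def test_no_comparable_pairs_is_an_error():
    with pytest.raises(ValueError):
        concordance_index(np.array([1.0, 2.0]), np.array([3.0, 4.0]), np.array([0, 0]))


@pytest.mark.parametrize("seed", range(20))
def test_cindex_matches_exhaustive_enumeration(seed):
    rng = np.random.default_rng(seed)
    n = rng.integers(8, 25)
    time = rng.uniform(1, 100, size=n)
    event = rng.integers(0, 2, size=n)
    event[rng.integers(0, n)] = 1  # ensure a comparable pair exists
    risk = rng.normal(size=n)
    assert concordance_index(risk, time, event) == pytest.approx(
        cindex_oracle(risk, time, event), abs=1e-12
    )


# --- per-window AUC -----------------------------------------------------


def test_perfect_separation_gives_auc_one():
    S = np.array([[0.9], [0.8], [0.2], [0.1]])
    status = np.array([[AT_RISK], [AT_RISK], [DEAD], [DEAD]])
    aucs, mean, sd = window_roc_auc(S, status)
    assert aucs[0] == 1.0 and mean == 1.0


def test_uninformative_predictions_are_near_half(rng):
    n = 4000
    S = rng.uniform(size=(n, 1))
    status = rng.choice([AT_RISK, DEAD], size=(n, 1))
    _, mean, _ = window_roc_auc(S, status)
    assert abs(mean - 0.5) < 0.05


def test_censored_out_are_excluded_from_auc():
    S = np.array([[0.9], [0.8], [0.01], [0.2], [0.1]])
    status = np.array([[AT_RISK], [AT_RISK], [CENSORED_OUT], [DEAD], [DEAD]])
    aucs, _, _ = window_roc_auc(S, status)
    assert aucs[0] == 1.0  # the censored low-S patient must not spoil it


def test_degenerate_windows_are_excluded_and_all_degenerate_raises():
    S = np.array([[0.5, 0.4], [0.6, 0.3]])
    status = np.array([[AT_RISK, DEAD], [AT_RISK, DEAD]])
    with pytest.raises(ValueError):
        window_roc_auc(S, status)


@pytest.mark.parametrize("seed", range(20))
def test_window_auc_matches_pair_counting(seed):
    rng = np.random.default_rng(100 + seed)
    n = rng.integers(6, 30)
    S = rng.uniform(size=(n, 1))
    status = rng.choice([AT_RISK, DEAD, CENSORED_OUT], size=(n, 1))
    include = status[:, 0] != CENSORED_OUT
    label = (status[include, 0] == DEAD).astype(int)
    if label.sum() == 0 or label.sum() == len(label):
        status[0, 0] = DEAD
        status[1, 0] = AT_RISK
        include = status[:, 0] != CENSORED_OUT
        label = (status[include, 0] == DEAD).astype(int)
    aucs, _, _ = window_roc_auc(S, status)
    assert aucs[0] == pytest.approx(
        auc_oracle(1.0 - S[include, 0], label), abs=1e-12
    )


# --- Kaplan-Meier -------------------------------------------------------


def test_km_three_deaths_no_censoring():
    km = km_estimate(np.array([1.0, 2.0, 3.0]), np.array([1, 1, 1]))
    np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0])


def test_km_all_censored_stays_at_one():
    km = km_estimate(np.array([1.0, 2.0, 3.0]), np.array([0, 0, 0]))
    assert km.survival_at(10.0) == 1.0


def test_km_six_patient_hand_table():
    time = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0])
    event = np.array([1, 1, 0, 1, 0, 1])
    km = km_estimate(time, event)
    # hand product-limit: S(1)=5/6, S(2)=5/6*4/5=2/3, S(3)=2/3*2/3=4/9, S(5)=0
    t, s = km_oracle(time, event)
    for ti, si in zip(t, s):
        assert km.survival_at(ti) == pytest.approx(si)


@pytest.mark.parametrize("seed", range(20))
def test_km_matches_hand_product_limit(seed):
    rng = np.random.default_rng(200 + seed)
    n = rng.integers(5, 40)
    time = rng.integers(1, 15, size=n).astype(float)  # ties on purpose
    event = rng.integers(0, 2, size=n)
    km = km_estimate(time, event)
    t, s = km_oracle(time, event)
    for ti, si in zip(t, s):
        assert km.survival_at(ti) == pytest.approx(si, abs=1e-12)
    # survival curve is non-increasing and starts at 1
    assert km.survival_at(0.0) == 1.0
    assert (np.diff(km.survival) <= 1e-12).all()


# --- log-rank -----------------------------------------------------------


def test_identical_groups_give_zero_statistic():
    time = np.array([2.0, 4.0, 6.0, 8.0])
    event = np.array([1, 0, 1, 1])
    stat, p = log_rank_test(time, event, time, event)
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_log_rank_invariant_under_group_relabeling(rng):
    ta, tb = rng.uniform(1, 50, 12), rng.uniform(1, 80, 15)
    ea, eb = rng.integers(0, 2, 12), rng.integers(0, 2, 15)
    ea[0] = 1
    s1, p1 = log_rank_test(ta, ea, tb, eb)
    s2, p2 = log_rank_test(tb, eb, ta, ea)
    assert s1 == pytest.approx(s2) and p1 == pytest.approx(p2)


def test_log_rank_requires_events():
    with pytest.raises(ValueError):
        log_rank_test(np.ones(3), np.zeros(3, int), np.ones(3), np.zeros(3, int))


# --- Mann-Whitney -------------------------------------------------------


def test_identical_samples_give_p_one():
    x = np.array([1.0, 2.0, 3.0])
    _, p = mann_whitney(x, x)
    assert p == pytest.approx(1.0)


def test_fully_separated_samples_hit_extreme_u():
    u, _ = mann_whitney(np.array([10.0, 11.0, 12.0]), np.array([1.0, 2.0, 3.0]))
    assert u == 9.0


@pytest.mark.parametrize("seed", range(20))
def test_mann_whitney_matches_full_enumeration(seed):
    rng = np.random.default_rng(300 + seed)
    combined = rng.normal(size=10)
    while len(np.unique(combined)) < 10:
        combined = rng.normal(size=10)
    x, y = combined[:5], combined[5:]
    u_obs, p = mann_whitney(x, y)
    # full 10-choose-5 enumeration of the U distribution
    mu = 25 / 2
    dist = []
    for idx in itertools.combinations(range(10), 5):
        xs = combined[list(idx)]
        ys = np.delete(combined, list(idx))
        u = sum(1.0 for a in xs for b in ys if a > b)
        dist.append(u)
    dist = np.array(dist)
    p_exact = np.mean(np.abs(dist - mu) >= abs(u_obs - mu) - 1e-12)
    assert p == pytest.approx(p_exact, abs=1e-9)


# --- calibration & stratification --------------------------------------


def test_fourteen_patients_give_seven_bins_of_two(rng):
    S = rng.uniform(size=14)
    time = rng.uniform(1, 100, size=14)
    event = rng.integers(0, 2, size=14)
    bins = calibration_bins(S, time, event, n_bins=7, horizon=60.0)
    assert [b.size for b in bins] == [2] * 7
    assert [b.bin_id for b in bins] == list(range(1, 8))


def test_too_few_patients_rejected(rng):
    with pytest.raises(ValueError):
        calibration_bins(rng.uniform(size=5), np.ones(5), np.ones(5, int), n_bins=7)


def test_self_consistent_predictions_calibrate(rng):
    # predictions equal to the true survival function on an uncensored cohort
    n = 10000
    horizon = 40.0
    rates = rng.uniform(0.005, 0.05, size=n)
    time = rng.exponential(1.0 / rates)
    event = np.ones(n, int)
    S_true = np.exp(-rates * horizon)
    bins = calibration_bins(S_true, time, event, n_bins=7, horizon=horizon)
    gaps = [abs(b.mean_predicted - b.km_actual) for b in bins]
    assert max(gaps) < 0.05


def test_stratification_reference_points():
    S = np.array([0.99, 0.96, 0.90, 0.60, 0.40, 0.10, 0.0, 1.0])
    groups = stratify_by_probability(S)
    assert groups.tolist() == [1, 1, 2, 3, 4, 5, 5, 1]


def test_stratification_is_an_exhaustive_partition(rng):
    S = rng.uniform(size=1000)
    groups = stratify_by_probability(S)
    assert set(np.unique(groups)) <= {1, 2, 3, 4, 5}
    assert len(groups) == 1000


def test_non_monotone_cutpoints_rejected():
    with pytest.raises(ValueError):
        stratify_by_probability(np.array([0.5]), cutpoints=(0.3, 0.8))


# --- duality and report -------------------------------------------------


@pytest.mark.parametrize("seed", range(10))
def test_auc_equals_scaled_mann_whitney_u(seed):
    rng = np.random.default_rng(400 + seed)
    n1, n0 = rng.integers(4, 12), rng.integers(4, 12)
    cases = rng.normal(size=n1)
    controls = rng.normal(size=n0)
    S = np.concatenate([cases, controls])[:, None]
    status = np.array([[DEAD]] * n1 + [[AT_RISK]] * n0)
    aucs, _, _ = window_roc_auc(S, status)
    u, _ = mann_whitney(1.0 - cases, 1.0 - controls)
    assert aucs[0] == pytest.approx(u / (n1 * n0), abs=1e-12)


def _toy_report(rng):
    n = 60
    S = np.column_stack([rng.uniform(size=n), rng.uniform(size=n)])
    S = np.sort(S, axis=1)[:, ::-1]
    status = rng.choice([AT_RISK, DEAD], size=(n, 2))
    time = rng.uniform(1, 100, size=n)
    event = rng.integers(0, 2, size=n)
    event[:5] = 1
    risk = 1 - S[:, -1]
    return evaluate_report(
        S, status, risk, time, event, boundaries=np.array([30.0, 60.0]),
        n_calibration_bins=7, calibration_horizon=60.0, seed=5,
    )


def test_report_has_one_auc_entry_per_window(rng):
    rep = _toy_report(rng)
    assert len(rep.aucs) == 2
    assert rep.seed == 5


def test_report_serialization_round_trip(rng):
    rep = _toy_report(rng)
    clone = EvaluationReport.from_json(rep.to_json())
    assert clone.to_json() == rep.to_json()


def test_report_cindex_matches_standalone(rng):
    n = 60
    rng2 = np.random.default_rng(7)
    S = np.sort(rng2.uniform(size=(n, 2)), axis=1)[:, ::-1]
    status = rng2.choice([AT_RISK, DEAD], size=(n, 2))
    time = rng2.uniform(1, 100, size=n)
    event = rng2.integers(0, 2, size=n)
    event[:5] = 1
    risk = 1 - S[:, -1]
    rep = evaluate_report(S, status, risk, time, event, np.array([30.0, 60.0]))
    assert rep.c_index == pytest.approx(concordance_index(risk, time, event))
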