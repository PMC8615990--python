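from itertools import combinations

import numpy as np
import pytest

import erpdecode as ed

from conftest import make_epochs


def _toy_six_trial_epochs(seed=0):
    rng = np.random.default_rng(seed)
    data = rng.standard_normal((6, 2, 4))
    labels = np.array([1, 1, 1, -1, -1, -1])
    return make_epochs(data, tmin_ms=0.0, labels=labels)


def _oracle_lda_correct(Xtr, ytr, xte, yte, lam):
    """Closed-form shrinkage discriminant, written out directly."""
    mp = Xtr[ytr == 1].mean(0)
    mm = Xtr[ytr == -1].mean(0)
    Z = Xtr - np.where(ytr[:, None] == 1, mp, mm)
    S = Z.T @ Z / len(Xtr)
    d = Xtr.shape[1]
    sigma = (1 - lam) * S + lam * (np.trace(S) / d) * np.eye(d)
    w = np.linalg.solve(sigma, mp - mm)
    dval = w @ xte - w @ (mp + mm) / 2
    return (1 if dval >= 0 else -1) == yte


def _exhaustive_null_oracle(ep, window_ms, shrinkage):
    """Enumerate every distinct assignment of the label multiset and run
    leave-one-trial-out CV with a directly coded closed-form discriminant
    (no shared code with the package's sufficient-statistics engine)."""
    tmask = ep.time_mask(window_ms)
    X = ep.data[:, :, tmask]
    n = ep.n_trials
    n_p = int((ep.labels == 1).sum())
    rows = []
    for pos in combinations(range(n), n_p):
        y = -np.ones(n, dtype=int)
        y[list(pos)] = 1
        accs = np.empty((n, X.shape[2]))
        for i in range(n):
            tr = np.arange(n) != i
            for t in range(X.shape[2]):
                accs[i, t] = _oracle_lda_correct(
                    X[tr][:, :, t], y[tr], X[i, :, t], y[i], shrinkage)
        rows.append(accs.mean(axis=0))
    return np.array(rows)


def test_exhaustive_null_matches_enumeration_oracle():
    """The empirical null under exhaustive label exchange equals an
    independently coded enumeration, including every percentile."""
    ep = _toy_six_trial_epochs()
    window = (0.0, 8.0)  # 2 samples
    null = ed.permutation_null(ep, cv_scheme="trial", window_ms=window,
                               shrinkage=0.3, exhaustive=True)
    oracle = _exhaustive_null_oracle(ep, window, shrinkage=0.3)
    assert null.n_perm == 20  # C(6, 3)
    assert null.accuracies.shape == oracle.shape
    a = np.sort(null.accuracies, axis=0)
    b = np.sort(oracle, axis=0)
    assert np.abs(a - b).max() < 1e-12
    for q in (50, 95, 99):
        assert np.allclose(np.percentile(null.accuracies, q, axis=0),
                           np.percentile(oracle, q, axis=0), atol=1e-12)


def test_sampled_null_reproducible_and_bounded(null_epochs):
    kw = dict(n_perm=8, window_ms=(-600, -550), seed=4)
    with pytest.warns(UserWarning, match="unstable"):
        a = ed.permutation_null(null_epochs, **kw)
    with pytest.warns(UserWarning, match="unstable"):
        b = ed.permutation_null(null_epochs, **kw)
    assert np.array_equal(a.accuracies, b.accuracies)
    assert a.accuracies.min() >= 0 and a.accuracies.max() <= 1


def test_invalid_arguments():
    ep = _toy_six_trial_epochs()
    with pytest.raises(ValueError):
        ed.permutation_null(ep, n_perm=0, cv_scheme="trial")
    ep_single = make_epochs(np.zeros((4, 2, 4)), tmin_ms=0.0,
                            labels=[1, 1, 1, 1])
    with pytest.raises(ValueError):
        ed.permutation_null(ep_single, n_perm=10, cv_scheme="trial")


def _results(times, acc):
    return ed.DecodingResults(times_ms=times, accuracy=acc,
                              se=np.zeros_like(acc),
                              fold_accuracies=acc[None, :], n_folds=1,
                              cv_scheme="trial")


def _null(times, values):
    return ed.NullDistribution(accuracies=values, times_ms=times,
                               n_perm=len(values), seed=0, cv_scheme="trial")


class TestSignificantMask:
    def test_chance_observation_never_flagged(self):
        times = np.arange(10.0)
        obs = _results(times, np.full(10, 0.5))
        null = _null(times, np.random.default_rng(0).uniform(0, 0.4, (200, 10)))
        assert not ed.significant_mask(obs, null).any()  # 0.5 < 60% threshold

    def test_single_point_above_both_criteria(self):
        times = np.arange(5.0)
        acc = np.full(5, 0.5)
        acc[2] = 0.9
        obs = _results(times, acc)
        null = _null(times, np.full((300, 5), 0.55)
                     + np.random.default_rng(1).uniform(0, 0.07, (300, 5)))
        mask = ed.significant_mask(obs, null, percentile=99,
                                   chance_threshold=0.60)
        assert list(mask) == [False, False, True, False, False]

    def test_percentile_matches_order_statistic_oracle(self):
        rng = np.random.default_rng(2)
        times = np.arange(20.0)
        null = _null(times, rng.uniform(0.3, 0.7, (157, 20)))
        obs = _results(times, rng.uniform(0.3, 0.7, 20))
        mask = ed.significant_mask(obs, null, chance_threshold=None)
        # independent order-statistic computation with linear interpolation
        srt = np.sort(null.accuracies, axis=0)
        h = 0.99 * (157 - 1)
        lo = int(np.floor(h))
        thr = srt[lo] + (h - lo) * (srt[lo + 1] - srt[lo])
        assert np.array_equal(mask, obs.accuracy > thr)

    def test_axis_mismatch_raises(self):
        obs = _results(np.arange(5.0), np.full(5, 0.5))
        null = _null(np.arange(6.0), np.zeros((10, 6)))
        with pytest.raises(ValueError):
            ed.significant_mask(obs, null)

    def test_raising_percentile_shrinks_mask(self):
        rng = np.random.default_rng(3)
        times = np.arange(50.0)
        null = _null(times, rng.uniform(0.4, 0.6, (200, 50)))
        obs = _results(times, rng.uniform(0.4, 0.7, 50))
        m90 = ed.significant_mask(obs, null, percentile=90,
                                  chance_threshold=None)
        m99 = ed.significant_mask(obs, null, percentile=99,
                                  chance_threshold=None)
        assert not np.any(m99 & ~m90)


class TestExtractIntervals:
    def test_empty_mask(self):
        assert ed.extract_intervals(np.zeros(10, bool), np.arange(10.0)) == []

    def test_covering_run_maps_to_printed_interval(self):
        # 4 ms sampling grid placed so -550 and -450 are on-grid
        times = np.arange(-702.0, -302.0, 4.0)
        mask = (times >= -550) & (times < -450)
        ivs = ed.extract_intervals(mask, times)
        assert len(ivs) == 1
        assert (ivs[0].start_ms, ivs[0].end_ms) == (-550.0, -450.0)
        assert ivs[0].duration_ms == 100.0

    def test_short_runs_discarded(self):
        times = np.arange(0.0, 100.0, 4.0)  # 250 Hz: one sample = 4 ms
        mask = np.zeros(len(times), bool)
        mask[3] = mask[10] = True
        assert ed.extract_intervals(mask, times, min_duration_ms=20) == []
        ivs = ed.extract_intervals(mask, times, min_duration_ms=0)
        assert len(ivs) == 2

    def test_accuracy_summary_fields_and_sorting(self):
        times = np.arange(0.0, 40.0, 4.0)
        acc = np.linspace(0.5, 0.95, len(times))
        mask = np.zeros(len(times), bool)
        mask[7:9] = True
        mask[1:3] = True
        ivs = ed.extract_intervals(mask, times, accuracy=acc)
        assert [iv.start_ms for iv in ivs] == [4.0, 28.0]
        assert ivs[1].peak_accuracy == pytest.approx(acc[8])
        assert ivs[1].mean_accuracy == pytest.approx(acc[7:9].mean())
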