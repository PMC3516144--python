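import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from mindist import (
    MinDistClassifier,
    evaluate_samples,
    fit_cutoff_model,
    make_samples,
    min_distance,
    roc_and_youden,
    select_candidates,
)


def brute_force_roc(pos, neg):
    """Exhaustive enumeration over all observed cutoffs."""
    best_j, best_c = -np.inf, None
    for c in sorted(set(pos) | set(neg)):
        tpr = np.mean(np.asarray(pos) <= c)
        fpr = np.mean(np.asarray(neg) <= c)
        if tpr - fpr > best_j:
            best_j, best_c = tpr - fpr, c
    return best_j, best_c


class TestMinDistance:
    def test_basic_geometry(self):
        refs = np.array([[0.0, 0.0], [10.0, 0.0]])
        assert min_distance([[0.0, 0.0]], refs)[0] == 0.0
        assert min_distance([[3.0, 4.0]], [[0.0, 0.0]])[0] == pytest.approx(5.0)

    def test_matches_all_pairs_oracle(self, rng):
        cands, refs = rng.normal(size=(50, 4)), rng.normal(size=(10, 4))
        expected = [min(np.linalg.norm(c - r) for r in refs) for c in cands]
        assert np.allclose(min_distance(cands, refs), expected)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            min_distance(np.zeros((2, 2)), np.zeros((0, 2)))


class TestRocAndYouden:
    def test_perfect_separation(self):
        ev = roc_and_youden([1.0, 2.0], [5.0, 6.0])
        assert ev.youden_j == 1.0 and ev.optimal_cutoff == 2.0
        assert ev.sensitivity == 1.0 and ev.specificity == 1.0 and ev.f1 == 1.0

    def test_identical_score_lists_give_zero_j(self):
        ev = roc_and_youden([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert ev.youden_j == 0.0

    def test_matches_brute_force_on_random_scores(self, rng):
        for _ in range(100):
            pos = rng.exponential(size=rng.integers(2, 30))
            neg = rng.exponential(size=rng.integers(2, 30)) * rng.uniform(0.5, 2)
            ev = roc_and_youden(pos, neg)
            j, c = brute_force_roc(pos, neg)
            assert ev.youden_j == pytest.approx(j)
            assert ev.optimal_cutoff == pytest.approx(c)

    def test_rates_monotone_in_cutoff(self, rng):
        ev = roc_and_youden(rng.exponential(size=40), rng.exponential(size=40))
        assert np.all(np.diff(ev.tpr) >= 0) and np.all(np.diff(ev.fpr) >= 0)

    def test_j_invariant_under_monotone_transform(self, rng):
        pos, neg = rng.exponential(size=25), 2 * rng.exponential(size=25)
        base = roc_and_youden(pos, neg)
        for f in (np.sqrt, np.log1p, lambda x: 3 * x + 1):
            assert roc_and_youden(f(pos), f(neg)).youden_j == pytest.approx(base.youden_j)

    def test_smallest_cutoff_wins_ties(self):
        # cutoffs 1.0 and 3.0 both attain J = 1/2; the smallest is returned
        ev = roc_and_youden([1.0, 3.0], [2.0, 4.0])
        assert ev.youden_j == pytest.approx(0.5)
        assert ev.optimal_cutoff == 1.0


class TestMakeSamples:
    def test_sizes_forced_by_design(self):
        knowns = [f"k{i}" for i in range(20)]
        cands = [f"c{i}" for i in range(40)]
        for s in make_samples(knowns, cands, 0.5, 25, seed=0):
            assert len(s.train_pos) == len(s.train_neg) == 10
            assert len(s.test_pos) == len(s.test_neg) == 10
            assert set(s.train_pos) | set(s.test_pos) == set(knowns)

    def test_single_representative_per_family(self):
        knowns = ["k1a", "k1b", "k2a", "k2b", "k3", "k4"]
        fam = {"k1a": "f1", "k1b": "f1", "k2a": "f2", "k2b": "f2", "k3": "f3", "k4": "f4"}
        for s in make_samples(knowns, [f"c{i}" for i in range(12)], 0.5, 200, seed=1,
                              families=fam):
            train_fams = [fam[k] for k in s.train_pos]
            assert len(train_fams) == len(set(train_fams))

    def test_negative_sets_disjoint(self):
        knowns = [f"k{i}" for i in range(10)]
        cands = [f"c{i}" for i in range(30)]
        for s in make_samples(knowns, cands, 0.2, 500, seed=2):
            assert not set(s.train_neg) & set(s.test_neg)

    def test_too_few_families_rejected(self):
        knowns = ["a", "b", "c", "d"]
        fam = dict.fromkeys(knowns, "onefam")
        with pytest.raises(ValueError, match="families"):
            make_samples(knowns, [f"c{i}" for i in range(10)], 0.5, 1, seed=0, families=fam)

    def test_reproducible_under_seed(self):
        knowns = [f"k{i}" for i in range(10)]
        cands = [f"c{i}" for i in range(20)]
        assert make_samples(knowns, cands, 0.2, 5, seed=9) == make_samples(
            knowns, cands, 0.2, 5, seed=9
        )


def two_population_coords(rng, n_known=20, n_cand=60, separation=8.0):
    known = rng.normal(scale=1.0, size=(n_known, 3))
    cand = rng.normal(scale=1.0, size=(n_cand, 3)) + separation
    ids = [f"k{i}" for i in range(n_known)] + [f"c{i}" for i in range(n_cand)]
    return (
        pd.DataFrame(np.vstack([known, cand]), index=ids),
        [f"k{i}" for i in range(n_known)],
        [f"c{i}" for i in range(n_cand)],
    )


class TestEvaluateSamples:
    def test_wide_separation_gives_j_near_one(self, rng):
        coords, knowns, cands = two_population_coords(rng, separation=20.0)
        samples = make_samples(knowns, cands, 0.5, 50, seed=0)
        evals, avg = evaluate_samples(samples, coords, train_fraction=0.5)
        assert avg.mean_youden_j > 0.95

    def test_null_distribution_gives_j_near_zero(self, rng):
        coords, knowns, cands = two_population_coords(rng, separation=0.0)
        samples = make_samples(knowns, cands, 0.5, 100, seed=0)
        _, avg = evaluate_samples(samples, coords, train_fraction=0.5)
        assert avg.mean_youden_j < 0.35

    def test_operating_point_is_mean_of_per_sample_optima(self, rng):
        coords, knowns, cands = two_population_coords(rng)
        samples = make_samples(knowns, cands, 0.2, 20, seed=3)
        evals, avg = evaluate_samples(samples, coords)
        assert avg.operating_tpr == pytest.approx(np.mean([e.sensitivity for e in evals]))
        assert avg.operating_fpr == pytest.approx(
            np.mean([1 - e.specificity for e in evals])
        )


class TestCutoffModel:
    def test_exact_log_linear_recovery(self):
        a, b = -1.0, 2.0
        fractions = [0.05, 0.1, 0.2, 0.5]
        cutoffs = np.exp(a + b * np.asarray(fractions))
        model = fit_cutoff_model(fractions, cutoffs)
        assert model.slope == pytest.approx(b)
        assert model.intercept == pytest.approx(a)
        assert model.r_squared == pytest.approx(1.0)
        assert model.extrapolated_cutoff == pytest.approx(np.exp(a + b))

    def test_noisy_recovery_within_three_standard_errors(self, rng):
        a, b, sigma = 0.5, -1.5, 0.05
        fractions = np.array([0.05, 0.1, 0.2, 0.5])
        hits = 0
        for _ in range(50):
            y = a + b * fractions + rng.normal(scale=sigma, size=4)
            model = fit_cutoff_model(fractions, np.exp(y))
            x = fractions
            sxx = ((x - x.mean()) ** 2).sum()
            se_b = sigma / np.sqrt(sxx)
            se_a = sigma * np.sqrt(1 / len(x) + x.mean() ** 2 / sxx)
            hits += abs(model.slope - b) < 3 * se_b and abs(model.intercept - a) < 3 * se_a
        assert hits >= 45  # ~99.7% nominal per coefficient

    def test_log_fraction_form(self):
        fractions = [0.1, 0.2, 0.5, 1.0]
        cutoffs = 2.0 + 0.5 * np.log(fractions)
        model = fit_cutoff_model(fractions, cutoffs, form="log-fraction")
        assert model.extrapolated_cutoff == pytest.approx(2.0)

    def test_insufficient_or_invalid_input_rejected(self):
        with pytest.raises(ValueError, match="3 distinct"):
            fit_cutoff_model([0.1, 0.5], [1.0, 2.0])
        with pytest.raises(ValueError, match="positive"):
            fit_cutoff_model([0.1, 0.2, 0.5], [1.0, 0.0, 2.0])


class TestSelectCandidates:
    def test_boundary_behaviour(self):
        scores = {"a": 0.0, "b": 1.0, "c": 2.0}
        assert select_candidates(scores, 0.0).accepted_ids == ["a"]
        res = select_candidates(scores, 2.0)
        assert set(res.accepted_ids) == {"a", "b", "c"} and res.acceptance_fraction == 1.0

    def test_order_statistic_count(self, rng):
        values = np.sort(rng.random(10))
        scores = {f"c{i}": v for i, v in enumerate(values)}
        cutoff = (values[3] + values[4]) / 2
        assert len(select_candidates(scores, cutoff).accepted_ids) == 4

    def test_negative_cutoff_rejected(self):
        with pytest.raises(ValueError):
            select_candidates({"a": 1.0}, -0.1)


class TestMinDistClassifier:
    def test_sklearn_protocol(self):
        est = MinDistClassifier(cutoff=1.5)
        assert clone(est).get_params() == {"cutoff": 1.5}
        est.set_params(cutoff=2.0)
        assert est.cutoff == 2.0

    def test_fit_predict_with_label_mask(self, rng):
        X = np.vstack([np.zeros((5, 2)), np.full((5, 2), 10.0)])
        y = np.array([1] * 5 + [0] * 5)
        est = MinDistClassifier(cutoff=3.0).fit(X, y)
        assert est.reference_coords_.shape == (5, 2)
        assert est.predict([[0.1, 0.1], [9.0, 9.0]]).tolist() == [True, False]
        assert est.decision_function([[0.0, 0.0]])[0] == pytest.approx(3.0)

    def test_predict_without_cutoff_raises(self):
        est = MinDistClassifier().fit(np.zeros((2, 2)))
        with pytest.raises(ValueError, match="cutoff"):
            est.predict(np.zeros((1, 2)))
        assert est.score_samples([[3.0, 4.0]])[0] == pytest.approx(5.0)
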