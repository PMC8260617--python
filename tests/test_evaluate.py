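import itertools

import numpy as np
import pytest

from pursuitdecode import evaluate
from pursuitdecode.evaluate import TaskData
from pursuitdecode.protocol import TASKS
from pursuitdecode.slir import ARDSettings, SLiRConfig


class TestSplits:
    def test_balanced_disjoint_exhaustive(self):
        folds = evaluate.tenfold_split(40, seed=0)
        sizes = [len(f) for f in folds]
        assert sizes == [4] * 10
        union = np.sort(np.concatenate(folds))
        assert np.array_equal(union, np.arange(40))
        for a, b in itertools.combinations(folds, 2):
            assert not set(a) & set(b)

    def test_deterministic(self):
        a = evaluate.tenfold_split(23, seed=9)
        b = evaluate.tenfold_split(23, seed=9)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_too_few_trials(self):
        with pytest.raises(ValueError):
            evaluate.tenfold_split(9, seed=0)


class TestCoefficients:
    def test_correlation_identities(self):
        x = np.random.default_rng(0).standard_normal(50)
        assert evaluate.correlation_coefficient(x, x) == pytest.approx(1.0)
        assert evaluate.correlation_coefficient(x, -x) == pytest.approx(-1.0)
        assert evaluate.correlation_coefficient(x, 2 * x + 5) == pytest.approx(1.0)

    def test_correlation_zero_variance(self):
        with pytest.raises(ValueError):
            evaluate.correlation_coefficient(np.ones(10), np.arange(10.0))

    def test_determination_hand_example(self):
        assert evaluate.determination_coefficient([1, 2, 3], [3, 2, 1]) == pytest.approx(-3.0)

    def test_determination_identities(self):
        x = np.random.default_rng(1).standard_normal(40)
        assert evaluate.determination_coefficient(x, x) == pytest.approx(1.0)
        const = np.full_like(x, x.mean())
        assert evaluate.determination_coefficient(x, const) == pytest.approx(0.0)

    def test_affine_sensitivity_split(self):
        """Correlation ignores the affine map that R2 penalises."""
        x = np.random.default_rng(2).standard_normal(60)
        pred = 2 * x + 5
        assert evaluate.correlation_coefficient(x, pred) == pytest.approx(1.0)
        assert evaluate.determination_coefficient(x, pred) < 0.0


class TestNormalization:
    def test_diagonal_is_one_with_zero_sd(self):
        mats = [np.random.default_rng(s).uniform(0.3, 1.0, (5, 5, 2)) for s in range(4)]
        out = evaluate.normalize_scores(mats)
        diag = np.einsum("iik->ik", out.mean)
        assert np.allclose(diag, 1.0)
        assert np.allclose(np.einsum("iik->ik", out.sd), 0.0)

    def test_half_diagonal_cell(self):
        m = np.eye(5)
        m[0, 1] = 0.5  # half of the test-task diagonal (which is 1)
        out = evaluate.normalize_scores([m, m])
        assert out.mean[0, 1] == pytest.approx(0.5)
        assert out.sd[0, 1] == pytest.approx(0.0)

    def test_mode_switch_preserves_diagonal(self):
        m = np.random.default_rng(3).uniform(0.2, 1.0, (5, 5))
        by_test = evaluate.normalize_scores([m], mode="by-test")
        by_train = evaluate.normalize_scores([m], mode="by-train")
        assert np.allclose(np.diag(by_test.mean), np.diag(by_train.mean))
        assert not np.allclose(by_test.mean, by_train.mean)

    def test_zero_diagonal_replicate_excluded(self):
        good = np.eye(5) + 0.1
        bad = good.copy()
        bad[2, 2] = 0.0
        with pytest.warns(RuntimeWarning, match="excluded"):
            out = evaluate.normalize_scores([good, bad])
        assert out.n_replicates == 1

    @pytest.mark.parametrize(
        "value, label",
        [(0.66, "high"), (0.6, "high"), (0.2, "middle"), (0.59, "middle"), (0.19, "low"),
         (-0.06, "low")],
    )
    def test_classification_thresholds(self, value, label):
        assert evaluate.classify_generalization(value) == label

    def test_classification_rejects_nan(self):
        with pytest.raises(ValueError):
            evaluate.classify_generalization(float("nan"))


class TestPermutation:
    def test_perfect_prediction_minimum_p(self):
        rng = np.random.default_rng(0)
        trues = [rng.standard_normal(50) for _ in range(10)]
        p = evaluate.permutation_test(trues, [t.copy() for t in trues], n_perm=999, seed=1)
        assert p == pytest.approx(1 / 1000)

    def test_constant_statistic_gives_p_one(self):
        rng = np.random.default_rng(0)
        trues = [rng.standard_normal(30) for _ in range(6)]
        preds = [rng.standard_normal(30) for _ in range(6)]
        p = evaluate.permutation_test(trues, preds, statistic=lambda t, q: 0.0,
                                      n_perm=199, seed=0)
        assert p == 1.0

    def test_exact_enumeration_for_few_trials(self):
        rng = np.random.default_rng(0)
        trues = [rng.standard_normal(30) for _ in range(3)]
        with pytest.warns(RuntimeWarning, match="enumerating"):
            p = evaluate.permutation_test(trues, [t.copy() for t in trues],
                                          n_perm=999, seed=0)
        assert p == pytest.approx(1 / 6)

    def test_argument_validation(self):
        with pytest.raises(ValueError):
            evaluate.permutation_test([np.ones(5)], [np.ones(5)], n_perm=999)
        with pytest.raises(ValueError):
            evaluate.permutation_test([np.ones(5)] * 4, [np.ones(5)] * 4, n_perm=50)


class TestBH:
    def test_stepup_hand_example(self):
        reject, adj = evaluate.bh_correct(np.array([0.01, 0.02, 0.03, 0.5]), alpha=0.05)
        assert reject.tolist() == [True, True, True, False]

    def test_degenerate_extremes(self):
        r1, _ = evaluate.bh_correct(np.ones(6))
        assert not r1.any()
        r0, _ = evaluate.bh_correct(np.zeros(6))
        assert r0.all()

    def test_against_brute_force_stepup(self):
        """BH output matches a direct step-up implementation on random vectors."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            p = rng.uniform(size=rng.integers(3, 20))
            reject, _ = evaluate.bh_correct(p, alpha=0.05)
            order = np.argsort(p)
            m = p.size
            k_max = 0
            for rank, idx in enumerate(order, start=1):
                if p[idx] <= rank * 0.05 / m:
                    k_max = rank
            expected = np.zeros(m, dtype=bool)
            expected[order[:k_max]] = True
            assert np.array_equal(reject, expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            evaluate.bh_correct(np.array([0.2, 1.4]))


class TestSharedDipoles:
    def test_disjoint_sets_share_nothing(self):
        sel = {t: {10 * k + j for j in range(3)} for k, t in enumerate(TASKS)}
        table = evaluate.categorize_shared_dipoles(sel)
        assert evaluate.shared_fraction(table) == 0.0
        assert table["fraction"].sum() == pytest.approx(1.0)

    def test_identical_sets_all_deeply_shared(self):
        sel = {t: {1, 2, 3} for t in TASKS}
        table = evaluate.categorize_shared_dipoles(sel)
        row = table.set_index("category").loc[">=3-tasks-shared"]
        assert row["fraction"] == pytest.approx(1.0)

    def test_against_membership_pattern_enumeration(self):
        """Brute force over all 2^5 membership patterns, one dipole each."""
        sel = {t: set() for t in TASKS}
        expected = {}
        for dip, pattern in enumerate(itertools.product([0, 1], repeat=5)):
            if sum(pattern) == 0:
                continue
            members = frozenset(t for t, m in zip(TASKS, pattern) if m)
            for t in members:
                sel[t].add(dip)
            if len(members) == 1:
                cat = f"exclusive-{next(iter(members))}"
            elif len(members) >= 3:
                cat = ">=3-tasks-shared"
            elif members == {"covert_0.5", "covert_0.8"}:
                cat = "covert-shared"
            elif members == {"overt_0.5", "overt_0.8"}:
                cat = "overt-shared"
            elif members == {"covert_0.5", "overt_0.5"}:
                cat = "0.5Hz-shared"
            elif members == {"covert_0.8", "overt_0.8"}:
                cat = "0.8Hz-shared"
            else:
                cat = "other-2-task"
            expected[cat] = expected.get(cat, 0) + 1
        table = evaluate.categorize_shared_dipoles(sel).set_index("category")
        for cat, count in expected.items():
            assert table.loc[cat, "count"] == count
        assert table["count"].sum() == 31


class TestGeneralizationMatrix:
    def test_identical_noiseless_tasks_score_unity(self):
        """If every task shares one generative signal, all cells reach r = 1."""
        rng = np.random.default_rng(0)
        cfg = SLiRConfig(tau=2, dtau=2, tpred=1)
        t = np.linspace(0, 4, 300)
        pos = np.sin(2 * np.pi * 0.7 * t)
        vel = np.cos(2 * np.pi * 0.7 * t)
        task_data = {}
        currents = []
        for k in range(10):
            J = np.vstack([pos + 0.9 * vel, pos - 0.8 * vel, 0.5 * pos + vel])
            currents.append(J)
        shared = TaskData(
            currents=currents,
            targets={"position": [pos] * 10, "velocity": [vel] * 10},
        )
        task_data = {t_: shared for t_ in TASKS}
        m = evaluate.build_generalization_matrix(task_data, cfg=cfg, seed=0)
        assert np.all(m.r > 0.999)
        assert np.all(m.R2 > 0.99)

    def test_missing_task_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            evaluate.build_generalization_matrix({"control": None})


class TestLagSweep:
    def test_grid_exceeding_epoch_rejected(self):
        J = [np.random.default_rng(0).standard_normal((3, 100))]
        with pytest.raises(ValueError, match="epoch"):
            evaluate.lag_sweep(J, [np.ones(100)], np.array([-3000.0]), fs=200.0)

    def test_white_noise_profile_is_flat(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 4, 400)
        tgt = np.sin(2 * np.pi * t)
        trials = [rng.standard_normal((10, 400)) for _ in range(4)]
        _, curve, _ = evaluate.lag_sweep(trials, [tgt] * 4, np.arange(-200, 201, 50),
                                         fs=200.0, seed=1)
        assert np.abs(curve).max() < 0.2
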