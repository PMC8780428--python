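import numpy as np
import pytest

from smirnet.evaluation import (
    EvaluationConfig,
    PerfectScorer,
    RandomScorer,
    RecallCurve,
    case_study,
    five_fold_cv,
    locate_pairs,
    partition_folds,
    recall_curve,
)
from smirnet.io import AssociationList
from smirnet.predictor import rank_predictions


def grid_assoc(n_sm=10, n_mi=10, pairs=None):
    sm_ids = [f"s{i}" for i in range(n_sm)]
    mi_ids = [f"m{i}" for i in range(n_mi)]
    if pairs is None:
        pairs = {(f"s{i}", f"m{i}") for i in range(min(n_sm, n_mi))}
    return AssociationList(pairs=set(pairs), sm_ids=sm_ids, mirna_ids=mi_ids)


class TestLocatePairs:
    @pytest.fixture
    def ranking(self):
        rng = np.random.default_rng(3)
        scores = rng.random((10, 20))
        return rank_predictions(scores, [f"s{i}" for i in range(10)],
                                [f"m{j}" for j in range(20)])

    def test_boundary_inclusion(self, ranking):
        top2 = {(s, m) for _, s, m, _, _ in ranking.rows[:2]}
        p = 2 / len(ranking)
        assert locate_pairs(ranking, top2, p) == (2, 2)

    def test_full_coverage_at_p_one(self, ranking):
        targets = {(s, m) for _, s, m, _, _ in ranking.rows[::7]}
        assert locate_pairs(ranking, targets, 1.0) == (len(targets), len(targets))

    def test_ceiling_rule(self):
        scores = np.arange(200, dtype=float).reshape(10, 20)
        ranking = rank_predictions(scores, [f"s{i}" for i in range(10)],
                                   [f"m{j}" for j in range(20)])
        rank2_pair = ranking.rows[1][1:3]
        # ceil(0.01 * 200) = 2, so the rank-2 pair is inside the cutoff
        assert locate_pairs(ranking, {rank2_pair}, 0.01) == (1, 1)

    def test_absent_target_raises(self, ranking):
        with pytest.raises(KeyError):
            locate_pairs(ranking, {("sX", "mX")}, 0.5)


class TestRecallCurve:
    def test_monotone_with_unit_endpoint(self):
        rng = np.random.default_rng(0)
        ranking = rank_predictions(rng.random((8, 8)),
                                   [f"s{i}" for i in range(8)],
                                   [f"m{j}" for j in range(8)])
        targets = {(s, m) for _, s, m, _, _ in ranking.rows[::5]}
        curve = recall_curve(ranking, targets, (0.1, 0.25, 0.5, 1.0))
        assert all(a <= b for a, b in zip(curve.recalls, curve.recalls[1:]))
        assert curve.at(1.0) == 1.0
        assert all(0.0 <= r <= 1.0 for r in curve.recalls)

    def test_average_is_unweighted_pointwise_mean(self):
        pts = (0.1, 0.5)
        curves = [RecallCurve(pts, (0.2, 0.6)), RecallCurve(pts, (0.4, 1.0))]
        avg = RecallCurve.average(curves)
        assert avg.recalls == (pytest.approx(0.3), pytest.approx(0.8))


class TestPartition:
    def test_true_partition_with_near_equal_sizes(self):
        pairs = [(f"s{i}", f"m{i}") for i in range(23)]
        folds = partition_folds(pairs, 5, seed=1)
        sizes = [len(f) for f in folds]
        assert sum(sizes) == 23
        assert max(sizes) - min(sizes) <= 1
        flat = [p for f in folds for p in f]
        assert sorted(flat) == sorted(pairs)

    def test_seeded_determinism_and_order_insensitivity(self):
        pairs = [(f"s{i}", f"m{i}") for i in range(17)]
        a = partition_folds(pairs, 5, seed=9)
        b = partition_folds(pairs[::-1], 5, seed=9)
        assert a == b


class TestFiveFoldCV:
    def test_perfect_scorer_recalls_everything(self):
        known = grid_assoc(20, 20)
        scorer = PerfectScorer(truth=frozenset(known.pairs))
        curve, _ = five_fold_cv(known, scorer, EvaluationConfig(seed=0))
        assert all(r == 1.0 for r in curve.recalls)

    def test_random_scorer_recall_matches_percent_point(self):
        """Under a random ranking, E[recall@p] = p; the mean over 50
        seeded runs must sit within 3 standard errors."""
        known = grid_assoc(12, 12)
        pts = (0.1, 0.25, 0.5)
        cfg_pts = []
        for seed in range(50):
            scorer = RandomScorer(seed=seed)
            curve, _ = five_fold_cv(
                known, scorer,
                EvaluationConfig(percent_points=pts, seed=seed),
            )
            cfg_pts.append(curve.recalls)
        arr = np.array(cfg_pts)
        for j, p in enumerate(pts):
            mean = arr[:, j].mean()
            se = arr[:, j].std(ddof=1) / np.sqrt(len(arr))
            assert abs(mean - p) <= 3 * max(se, 1e-9), (p, mean, se)

    def test_same_seed_gives_identical_curves(self):
        known = grid_assoc()
        a, _ = five_fold_cv(known, RandomScorer(seed=4), EvaluationConfig(seed=4))
        b, _ = five_fold_cv(known, RandomScorer(seed=4), EvaluationConfig(seed=4))
        assert a == b

    def test_fewer_associations_than_folds_rejected(self):
        known = grid_assoc(pairs={("s0", "m0"), ("s1", "m1")})
        with pytest.raises(ValueError):
            five_fold_cv(known, RandomScorer(), EvaluationConfig(n_folds=5))


class TestCaseStudy:
    def test_perfect_scorer_gives_unit_curve(self):
        known = grid_assoc()
        curve = case_study("s0", known, PerfectScorer(truth=frozenset(known.pairs)),
                           EvaluationConfig(seed=0), entity_type="sm")
        assert curve.recalls[-1] == 1.0

    def test_ratio_definition_at_point(self):
        """An entity with 10 withheld pairs, 9 inside the cutoff, scores 0.9."""
        sm_ids = [f"s{i}" for i in range(2)]
        mi_ids = [f"m{j}" for j in range(40)]
        pairs = {("s0", f"m{j}") for j in range(10)}
        known = AssociationList(pairs=pairs, sm_ids=sm_ids, mirna_ids=mi_ids)
        # rank 9 of the withheld pairs at the top, 1 at the bottom
        truth = {("s0", f"m{j}") for j in range(9)}
        curve = case_study(
            "s0", known, PerfectScorer(truth=frozenset(truth)),
            EvaluationConfig(percent_points=(0.25,), seed=0), entity_type="sm",
        )
        assert curve.at(0.25) == pytest.approx(0.9)

    def test_mirna_entity_type(self):
        known = grid_assoc()
        curve = case_study("m3", known, PerfectScorer(truth=frozenset(known.pairs)),
                           EvaluationConfig(seed=0), entity_type="mirna")
        assert curve.recalls[-1] == 1.0

    def test_entity_without_associations_rejected(self):
        known = grid_assoc(pairs={("s0", "m0")})
        with pytest.raises(ValueError):
            case_study("s5", known, RandomScorer(), EvaluationConfig())


class TestConfigValidation:
    def test_points_must_increase(self):
        with pytest.raises(ValueError):
            EvaluationConfig(percent_points=(0.5, 0.1))

    def test_points_must_be_in_unit_interval(self):
        with pytest.raises(ValueError):
            EvaluationConfig(percent_points=(0.0, 0.5))
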