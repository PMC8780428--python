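"""Ranking-based evaluation: 5-fold cross-validation and case studies.

The accuracy measure throughout is recall@top-p%: the fraction of held-out
known associations whose rank falls within the top ceil(p * N) of the
candidate ranking, where N is the ranking length.  Curves over a grid of
percentage points are averaged unweighted over folds or case-study
entities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from typing import Callable, Sequence

import numpy as np
from sklearn.base import clone

from .io import AssociationList
from .predictor import GraphletLinkPredictor, RankedPredictions

#: Default percentage points, matching the usual reporting grid.
DEFAULT_PERCENT_POINTS = (
    0.01, 0.02, 0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.40, 0.50,
)


@dataclass(frozen=True)
class EvaluationConfig:
    percent_points: tuple[float, ...] = DEFAULT_PERCENT_POINTS
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        pts = self.percent_points
        if any(not 0 < p <= 1 for p in pts):
            raise ValueError("percentage points must lie in (0, 1]")
        if any(b <= a for a, b in zip(pts, pts[1:])):
            raise ValueError("percentage points must be strictly increasing")
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")


@dataclass(frozen=True)
class RecallCurve:
    """Recall of held-out associations at each percentage point."""

    percent_points: tuple[float, ...]
    recalls: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.percent_points) != len(self.recalls):
            raise ValueError("points and recalls must align")

    def at(self, p: float) -> float:
        return self.recalls[self.percent_points.index(p)]

    @staticmethod
    def average(curves: Sequence["RecallCurve"]) -> "RecallCurve":
        """Unweighted pointwise mean over folds or case studies."""
        pts = curves[0].percent_points
        for c in curves:
            if c.percent_points != pts:
                raise ValueError("curves use different percentage grids")
        mean = tuple(float(np.mean([c.recalls[i] for c in curves]))
                     for i in range(len(pts)))
        return RecallCurve(percent_points=pts, recalls=mean)


def locate_pairs(
    ranking: RankedPredictions, targets: set[tuple[str, str]], p: float
) -> tuple[int, int]:
    """Count targets ranked within the top ceil(p * N) predictions."""
    rank_map = ranking.rank_map()
    cutoff = ceil(p * len(ranking))
    found = 0
    for pair in targets:
        if pair not in rank_map:
            raise KeyError(f"pair {pair} absent from the ranking")
        if rank_map[pair] <= cutoff:
            found += 1
    return found, len(targets)


def recall_curve(
    ranking: RankedPredictions,
    targets: set[tuple[str, str]],
    percent_points: Sequence[float],
) -> RecallCurve:
    rank_map = ranking.rank_map()
    n = len(ranking)
    ranks = []
    for pair in targets:
        if pair not in rank_map:
            raise KeyError(f"pair {pair} absent from the ranking")
        ranks.append(rank_map[pair])
    ranks_arr = np.asarray(ranks)
    recalls = tuple(
        float(np.mean(ranks_arr <= ceil(p * n))) if len(ranks_arr) else 0.0
        for p in percent_points
    )
    return RecallCurve(percent_points=tuple(percent_points), recalls=recalls)


def partition_folds(
    pairs: Sequence[tuple[str, str]], n_folds: int, seed: int
) -> list[list[tuple[str, str]]]:
    """Seeded random partition into near-equal folds (sizes differ by <=1).

    The remainder is spread over the first folds.  Input ordering does not
    affect the partition: pairs are sorted before shuffling.
    """
    pairs = sorted(pairs)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    shuffled = [pairs[i] for i in order]
    base, rem = divmod(len(pairs), n_folds)
    folds = []
    start = 0
    for k in range(n_folds):
        size = base + (1 if k < rem else 0)
        folds.append(shuffled[start : start + size])
        start += size
    return folds


def _subset_assoc(full: AssociationList, pairs: set[tuple[str, str]]) -> AssociationList:
    return AssociationList(
        pairs=set(pairs), sm_ids=list(full.sm_ids), mirna_ids=list(full.mirna_ids)
    )


Scorer = GraphletLinkPredictor  # any estimator with fit(assoc) + rank_predictions


class RandomScorer:
    """Null model: i.i.d. uniform scores.  E[recall@p] = p.

    Used to calibrate the evaluation machinery and as the baseline that
    planted-structure recovery must beat.
    """

    def __init__(self, seed: int = 0) -> None:
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {"seed": self.seed}

    def set_params(self, **params) -> "RandomScorer":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, known: AssociationList, y=None) -> "RandomScorer":
        self.known_ = known
        rng = np.random.default_rng(self.seed)
        self.score_matrix_ = rng.random(
            (len(known.sm_ids), len(known.mirna_ids))
        )
        return self

    def rank_predictions(
        self, exclude: set[tuple[str, str]] | None = None
    ) -> RankedPredictions:
        from .predictor import rank_predictions as _rank

        return _rank(
            self.score_matrix_,
            list(self.known_.sm_ids),
            list(self.known_.mirna_ids),
            exclude=exclude,
        )


class PerfectScorer:
    """Oracle model: scores 1 for pairs in a supplied truth set, else 0.

    With the truth set containing all known associations, every held-out
    positive outranks every true negative, so recall is 1 at any
    percentage point wide enough to hold the positives.
    """

    def __init__(self, truth: set | frozenset = frozenset()) -> None:
        self.truth = truth

    def get_params(self, deep: bool = True) -> dict:
        return {"truth": self.truth}

    def set_params(self, **params) -> "PerfectScorer":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, known: AssociationList, y=None) -> "PerfectScorer":
        self.known_ = known
        truth = set(self.truth)
        self.score_matrix_ = np.array(
            [
                [1.0 if (s, m) in truth else 0.0 for m in known.mirna_ids]
                for s in known.sm_ids
            ]
        )
        return self

    def rank_predictions(
        self, exclude: set[tuple[str, str]] | None = None
    ) -> RankedPredictions:
        from .predictor import rank_predictions as _rank

        return _rank(
            self.score_matrix_,
            list(self.known_.sm_ids),
            list(self.known_.mirna_ids),
            exclude=exclude,
        )


def five_fold_cv(
    known: AssociationList,
    scorer: Scorer,
    config: EvaluationConfig | None = None,
) -> tuple[RecallCurve, list[RecallCurve]]:
    """Cross-validated recall curve, averaged unweighted over folds.

    Per fold the scorer is refitted on the training associations; the
    candidate universe is every pair except the training positives, so the
    held-out positives compete against all unknown pairs.
    """
    config = config or EvaluationConfig()
    if len(known) < config.n_folds:
        raise ValueError("fewer associations than folds")
    folds = partition_folds(sorted(known.pairs), config.n_folds, config.seed)
    curves = []
    for k in range(config.n_folds):
        held_out = set(folds[k])
        train = known.pairs - held_out
        model = clone(scorer)
        model.fit(_subset_assoc(known, train))
        ranking = model.rank_predictions(exclude=train)
        curves.append(recall_curve(ranking, held_out, config.percent_points))
    return RecallCurve.average(curves), curves


def case_study(
    entity_id: str,
    known: AssociationList,
    scorer: Scorer,
    config: EvaluationConfig | None = None,
    entity_type: str = "sm",
) -> RecallCurve:
    """Withhold every association of one entity and rank them back.

    ``entity_type`` selects whether the id names a small molecule or a
    miRNA.  The ranking universe is all candidate pairs minus the training
    positives, consistent with cross-validation.
    """
    config = config or EvaluationConfig()
    if entity_type == "sm":
        held_out = {(s, m) for s, m in known.pairs if s == entity_id}
    elif entity_type == "mirna":
        held_out = {(s, m) for s, m in known.pairs if m == entity_id}
    else:
        raise ValueError("entity_type must be 'sm' or 'mirna'")
    if not held_out:
        raise ValueError(f"entity {entity_id!r} has no known associations")
    train = known.pairs - held_out
    model = clone(scorer)
    model.fit(_subset_assoc(known, train))
    ranking = model.rank_predictions(exclude=train)
    return recall_curve(ranking, held_out, config.percent_points)
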