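"""Graphlet-interaction link prediction over the two similarity networks.

The score of a candidate pair (s, m) combines evidence from both
homogeneous networks through the known-association bipartite graph:

    score(s, m) = sum over known partners m_t of s (m_t != m) of
                      w . counts(m, m_t; miRNA network)
                + sum over known partners s_u of m (s_u != s) of
                      w . counts(s, s_u; SM network)

where counts(a, b; net) is the 28-class graphlet interaction vector with a
in the source position, and w the per-class weights (uniform by default).
A pair never contributes evidence to itself.  High scores mean that the
candidate sits close, in graphlet-interaction terms, to entities with
confirmed associations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .graphlets import (
    InteractionCounter,
    IsomerCatalogue,
    SimilarityNetwork,
    enumerate_isomers,
)
from .io import AssociationList


@dataclass(frozen=True)
class RankedPredictions:
    """All candidate pairs ordered by score.

    ``rows`` is a list of (rank, sm_id, mirna_id, score, is_known) with
    ranks 1..N, scores non-increasing, ties broken by (sm_id, mirna_id)
    lexicographic order so rankings are deterministic.
    """

    rows: tuple[tuple[int, str, str, float, bool], ...]

    def __len__(self) -> int:
        return len(self.rows)

    def rank_of(self, sm_id: str, mirna_id: str) -> int:
        for rank, s, m, _, _ in self.rows:
            if s == sm_id and m == mirna_id:
                return rank
        raise KeyError(f"pair ({sm_id}, {mirna_id}) not in ranking")

    def rank_map(self) -> dict[tuple[str, str], int]:
        return {(s, m): rank for rank, s, m, _, _ in self.rows}


def _weighted_matrix_cached(
    network: SimilarityNetwork, cat: IsomerCatalogue, weights: np.ndarray
) -> np.ndarray:
    """Weighted interaction matrix, memoised on the network object.

    The matrix depends only on (network, catalogue, weights), never on the
    association split, so cross-validation folds reuse a single count.
    """
    cache = network.__dict__.setdefault("_weighted_cache", {})
    key = (tuple(cat.classes), tuple(np.asarray(weights, dtype=float)))
    if key not in cache:
        cache[key] = InteractionCounter(network, cat).weighted_matrix(
            np.asarray(weights, dtype=float)
        )
    return cache[key]


class GraphletLinkPredictor(BaseEstimator):
    """Rank candidate SM-miRNA associations by graphlet-interaction score.

    Parameters
    ----------
    sm_network, mirna_network : SimilarityNetwork
        Binary similarity networks over the small molecules and the
        miRNAs.  They are data-independent of the association split, so a
        predictor can be cloned and refitted across cross-validation folds
        without recounting graphlets (counts are cached lazily per
        network).
    weights : array of 28 reals or None
        Per-isomer-class weights; None means uniform weights of 1.

    Attributes
    ----------
    known_ : AssociationList the predictor was fitted on.
    score_matrix_ : |SM| x |miRNA| array of association scores.
    """

    def __init__(
        self,
        sm_network: SimilarityNetwork,
        mirna_network: SimilarityNetwork,
        weights: np.ndarray | None = None,
        catalogue: IsomerCatalogue | None = None,
    ) -> None:
        self.sm_network = sm_network
        self.mirna_network = mirna_network
        self.weights = weights
        self.catalogue = catalogue

    def _weighted_matrices(self) -> tuple[np.ndarray, np.ndarray]:
        cat = self.catalogue if self.catalogue is not None else enumerate_isomers()
        w = (
            np.ones(len(cat))
            if self.weights is None
            else np.asarray(self.weights, dtype=float)
        )
        Ws = _weighted_matrix_cached(self.sm_network, cat, w)
        Wm = _weighted_matrix_cached(self.mirna_network, cat, w)
        return Ws, Wm

    def fit(self, known: AssociationList, y=None) -> "GraphletLinkPredictor":
        if list(known.sm_ids) != list(self.sm_network.ids):
            raise ValueError("association SM ids do not match the SM network")
        if list(known.mirna_ids) != list(self.mirna_network.ids):
            raise ValueError("association miRNA ids do not match the miRNA network")
        self.known_ = known
        Ws, Wm = self._weighted_matrices()
        A = known.matrix()
        # term 1: evidence from known partners of s in the miRNA network;
        # term 2: evidence from known partners of m in the SM network.
        # W diagonals are zero, which implements self-evidence exclusion.
        self.score_matrix_ = A @ Wm.T + Ws @ A
        return self

    def decision_function(self) -> np.ndarray:
        self._check_fitted()
        return self.score_matrix_

    def score_pair(self, sm_id: str, mirna_id: str) -> float:
        self._check_fitted()
        i = list(self.known_.sm_ids).index(sm_id)
        j = list(self.known_.mirna_ids).index(mirna_id)
        return float(self.score_matrix_[i, j])

    def rank_predictions(
        self, exclude: set[tuple[str, str]] | None = None
    ) -> RankedPredictions:
        """Order the candidate universe by score (descending).

        ``exclude`` removes pairs (typically the training positives) from
        the ranking entirely.
        """
        self._check_fitted()
        exclude = exclude or set()
        known_pairs = self.known_.pairs
        entries = []
        for i, s in enumerate(self.known_.sm_ids):
            for j, m in enumerate(self.known_.mirna_ids):
                if (s, m) in exclude:
                    continue
                entries.append((-self.score_matrix_[i, j], s, m))
        entries.sort()
        rows = tuple(
            (rank, s, m, -neg, (s, m) in known_pairs)
            for rank, (neg, s, m) in enumerate(entries, start=1)
        )
        return RankedPredictions(rows=rows)

    def _check_fitted(self) -> None:
        if not hasattr(self, "score_matrix_"):
            raise RuntimeError("predictor is not fitted; call fit first")


def score_pair(
    sm_id: str,
    mirna_id: str,
    sm_net: SimilarityNetwork,
    mirna_net: SimilarityNetwork,
    known: AssociationList,
    weights: np.ndarray | None = None,
) -> float:
    """Functional wrapper: score one pair with a freshly fitted predictor."""
    model = GraphletLinkPredictor(sm_net, mirna_net, weights=weights).fit(known)
    return model.score_pair(sm_id, mirna_id)


def score_all(
    sm_net: SimilarityNetwork,
    mirna_net: SimilarityNetwork,
    known: AssociationList,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Functional wrapper: the full |SM| x |miRNA| score matrix."""
    model = GraphletLinkPredictor(sm_net, mirna_net, weights=weights).fit(known)
    return model.score_matrix_


def rank_predictions(
    scores: np.ndarray,
    sm_ids: list[str],
    mirna_ids: list[str],
    exclude: set[tuple[str, str]] | None = None,
) -> RankedPredictions:
    """Rank a raw score matrix without a fitted predictor."""
    exclude = exclude or set()
    entries = []
    for i, s in enumerate(sm_ids):
        for j, m in enumerate(mirna_ids):
            if (s, m) in exclude:
                continue
            entries.append((-float(scores[i, j]), s, m))
    entries.sort()
    rows = tuple(
        (rank, s, m, -neg, False)
        for rank, (neg, s, m) in enumerate(entries, start=1)
    )
    return RankedPredictions(rows=rows)
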