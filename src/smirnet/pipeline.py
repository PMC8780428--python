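"""End-to-end orchestration: corpora -> encoders -> similarities -> ranking.

The full workflow is: train one character-level autoencoder per entity
type, encode every entity to a latent vector, convert latent distances to
per-type similarity matrices, binarize those into similarity networks, and
hand the networks plus known associations to the graphlet-interaction
predictor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .autoencoder import SequenceAutoencoder
from .encoding import mirna_vocabulary
from .evaluation import EvaluationConfig, RecallCurve, five_fold_cv
from .graphlets import SimilarityNetwork, binarize_similarity
from .io import AssociationList, SequenceRecord
from .predictor import GraphletLinkPredictor
from .similarity import SimilarityMatrix, similarity_matrix

#: Maximum string lengths for the two entity types.
MIRNA_MAX_LEN = 30
SMILES_MAX_LEN = 50


@dataclass(frozen=True)
class PipelineConfig:
    """Settings for one end-to-end run.

    ``latent_dim`` selects the encoding version (64 or 128);
    ``retain_fraction`` controls similarity-network sparsity; the
    autoencoder settings are shared by both entity types.
    """

    latent_dim: int = 64
    hidden_units: int = 64
    epochs: int = 150
    batch_size: int = 128
    learning_rate: float = 1e-2
    retain_fraction: float = 0.05
    weights: tuple[float, ...] | None = None
    seed: int = 0


@dataclass
class PipelineResult:
    mirna_encoder: SequenceAutoencoder
    sm_encoder: SequenceAutoencoder
    mirna_latents: np.ndarray
    sm_latents: np.ndarray
    mirna_similarity: SimilarityMatrix
    sm_similarity: SimilarityMatrix
    mirna_network: SimilarityNetwork
    sm_network: SimilarityNetwork
    predictor: GraphletLinkPredictor


def build_predictor(
    mirna_records: Sequence[SequenceRecord],
    sm_records: Sequence[SequenceRecord],
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Train encoders and assemble an (unfitted) graphlet link predictor."""
    cfg = config or PipelineConfig()

    mirna_encoder = SequenceAutoencoder(
        latent_dim=cfg.latent_dim,
        hidden_units=cfg.hidden_units,
        epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        learning_rate=cfg.learning_rate,
        vocab=mirna_vocabulary(MIRNA_MAX_LEN),
        random_state=cfg.seed,
    ).fit(mirna_records)
    sm_encoder = SequenceAutoencoder(
        latent_dim=cfg.latent_dim,
        hidden_units=cfg.hidden_units,
        epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        learning_rate=cfg.learning_rate,
        max_len=SMILES_MAX_LEN,
        random_state=cfg.seed + 1,
    ).fit(sm_records)

    mirna_latents = mirna_encoder.transform(mirna_records)
    sm_latents = sm_encoder.transform(sm_records)
    mirna_sim = similarity_matrix(mirna_latents, [r.id for r in mirna_records])
    sm_sim = similarity_matrix(sm_latents, [r.id for r in sm_records])
    mirna_net = binarize_similarity(mirna_sim, cfg.retain_fraction)
    sm_net = binarize_similarity(sm_sim, cfg.retain_fraction)

    weights = None if cfg.weights is None else np.asarray(cfg.weights, dtype=float)
    predictor = GraphletLinkPredictor(sm_net, mirna_net, weights=weights)
    return PipelineResult(
        mirna_encoder=mirna_encoder,
        sm_encoder=sm_encoder,
        mirna_latents=mirna_latents,
        sm_latents=sm_latents,
        mirna_similarity=mirna_sim,
        sm_similarity=sm_sim,
        mirna_network=mirna_net,
        sm_network=sm_net,
        predictor=predictor,
    )


def cross_validate(
    mirna_records: Sequence[SequenceRecord],
    sm_records: Sequence[SequenceRecord],
    known: AssociationList,
    config: PipelineConfig | None = None,
    eval_config: EvaluationConfig | None = None,
) -> RecallCurve:
    """Full-pipeline 5-fold cross-validated recall curve."""
    cfg = config or PipelineConfig()
    result = build_predictor(mirna_records, sm_records, cfg)
    eval_cfg = eval_config or EvaluationConfig(seed=cfg.seed)
    mean_curve, _ = five_fold_cv(known, result.predictor, eval_cfg)
    return mean_curve
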