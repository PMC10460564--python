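"""Integrated similarity construction.

Component similarity matrices (chemical structure, disease phenotype,
side effect, target-gene functional consistency for small molecules;
disease phenotype and functional consistency for miRNAs) are merged into
a single integrated similarity by entrywise weighted averaging,

    S = sum_k w_k S_k / sum_k w_k,

with all weights defaulting to 1.  A Jaccard utility derives
profile-based component similarities from binary entity x feature
annotation matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_model import EntityIndex, SimilarityMatrix
from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IntegrationWeights:
    """Non-negative weights, one per component matrix."""

    weights: tuple[float, ...]

    def __post_init__(self):
        w = tuple(float(x) for x in self.weights)
        if any(x < 0 for x in w):
            raise ValidationError("integration weights must be non-negative")
        if not any(x > 0 for x in w):
            raise ValidationError("at least one weight must be positive")
        object.__setattr__(self, "weights", w)


def integrate_similarities(
    components: Sequence[SimilarityMatrix | None],
    weights: IntegrationWeights | Sequence[float] | None = None,
) -> SimilarityMatrix:
    """Entrywise weighted mean of component similarities.

    ``None`` entries mark component matrices a dataset does not provide;
    they are dropped and the remaining weights renormalized, with a
    logged notice.  The output diagonal is forced to 1.
    """
    if weights is None:
        weights = IntegrationWeights(tuple(1.0 for _ in components))
    elif not isinstance(weights, IntegrationWeights):
        weights = IntegrationWeights(tuple(weights))
    if len(weights.weights) != len(components):
        raise ValidationError(
            f"{len(components)} components but {len(weights.weights)} weights"
        )

    present = [
        (c, w) for c, w in zip(components, weights.weights) if c is not None
    ]
    if len(present) < len(components):
        logger.info(
            "dropping %d missing component matrices; weights renormalized",
            len(components) - len(present),
        )
    if not present:
        raise ValidationError("no component similarity matrices supplied")

    entities = present[0][0].entities
    for c, _ in present[1:]:
        if c.entities.ids != entities.ids:
            raise ValidationError("component matrices cover different entities")
    wsum = sum(w for _, w in present)
    if wsum <= 0:
        raise ValidationError("all weights for present components are zero")

    S = sum(w * c.S for c, w in present) / wsum
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(entities=entities, S=S)


def jaccard_profile_similarity(
    profiles: np.ndarray, ids: Sequence[str] | EntityIndex | None = None
) -> SimilarityMatrix:
    """Jaccard similarity between rows of a binary entity x feature matrix.

    S(a, b) = |P_a & P_b| / |P_a | P_b| over the entities' feature sets.
    A pair of empty profiles scores 0 (absence of evidence carries no
    neighbor signal), except the diagonal which is 1 by convention.
    """
    P = np.asarray(profiles)
    if P.ndim != 2 or P.shape[1] < 1:
        raise ValidationError("profiles must be a 2-D matrix with >= 1 feature")
    if not np.isin(P, (0, 1)).all():
        raise ValidationError("profiles must be binary")
    P = P.astype(float)
    inter = P @ P.T
    sizes = P.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    np.fill_diagonal(S, 1.0)
    if ids is None:
        ids = [f"e{i}" for i in range(P.shape[0])]
    entities = ids if isinstance(ids, EntityIndex) else EntityIndex.from_ids(ids)
    return SimilarityMatrix(entities=entities, S=S)
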