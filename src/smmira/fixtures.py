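"""Synthetic bipartite datasets with planted block structure.

The generator emulates the statistical assumption behind neighborhood
scoring — similar entities share association partners — by assigning
SMs and miRNAs to blocks and planting associations densely within
co-blocks and sparsely across.  Similarities are block-structured
(``sim_within`` vs ``sim_between``) with optional symmetric Gaussian
noise, so the NI threshold grid has a meaningful operating range
between the two similarity levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import AssociationMatrix, EntityIndex, SimilarityMatrix
from .errors import ValidationError


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a planted-block synthetic dataset."""

    ns: int = 20
    nm: int = 30
    n_blocks: int = 2
    within_density: float = 0.4
    between_density: float = 0.02
    sim_within: float = 0.8
    sim_between: float = 0.2
    sim_noise_sd: float = 0.05
    seed: int = 7

    def __post_init__(self):
        if self.ns < 1 or self.nm < 1 or self.n_blocks < 1:
            raise ValidationError("ns, nm and n_blocks must be positive")
        if not (0 < self.within_density <= 1):
            raise ValidationError("within_density must lie in (0, 1]")
        if not (0 <= self.between_density < 1):
            raise ValidationError("between_density must lie in [0, 1)")
        if self.within_density <= self.between_density:
            raise ValidationError("within_density must exceed between_density")
        if not (0 < self.sim_within <= 1):
            raise ValidationError("sim_within must lie in (0, 1]")
        if not (0 <= self.sim_between < self.sim_within):
            raise ValidationError("sim_between must lie in [0, sim_within)")
        if self.sim_noise_sd < 0:
            raise ValidationError("sim_noise_sd must be non-negative")


def _block_similarity(
    labels: np.ndarray, spec: FixtureSpec, rng: np.random.Generator
) -> np.ndarray:
    same = labels[:, None] == labels[None, :]
    S = np.where(same, spec.sim_within, spec.sim_between).astype(float)
    if spec.sim_noise_sd > 0:
        noise = rng.normal(0.0, spec.sim_noise_sd, size=S.shape)
        S = S + (noise + noise.T) / 2.0  # symmetric noise
    S = np.clip(S, 0.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return S


def generate_fixture(
    spec: FixtureSpec,
) -> tuple[AssociationMatrix, SimilarityMatrix, SimilarityMatrix, dict]:
    """Generate (associations, SM similarity, miRNA similarity, block labels).

    Entities are assigned to blocks round-robin; ``A[i, j]`` is Bernoulli
    with probability ``within_density`` when SM i and miRNA j share a
    block and ``between_density`` otherwise.  Deterministic given the
    spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    sm_labels = np.arange(spec.ns) % spec.n_blocks
    mirna_labels = np.arange(spec.nm) % spec.n_blocks

    same_block = sm_labels[:, None] == mirna_labels[None, :]
    p = np.where(same_block, spec.within_density, spec.between_density)
    A = (rng.random((spec.ns, spec.nm)) < p).astype(np.int8)

    sms = EntityIndex.from_ids([f"SM{i:03d}" for i in range(spec.ns)])
    mirnas = EntityIndex.from_ids([f"miR{j:03d}" for j in range(spec.nm)])
    assoc = AssociationMatrix(sms=sms, mirnas=mirnas, A=A)
    sm_sim = SimilarityMatrix(
        entities=sms, S=_block_similarity(sm_labels, spec, rng)
    )
    mirna_sim = SimilarityMatrix(
        entities=mirnas, S=_block_similarity(mirna_labels, spec, rng)
    )
    labels = {"sm": sm_labels, "mirna": mirna_labels}
    return assoc, sm_sim, mirna_sim, labels
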