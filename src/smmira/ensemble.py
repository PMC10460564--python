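"""Score normalization and fusion of the NI and RBM base predictors.

Each raw score matrix is z-scored over all ns x nm cells and squashed
through a scaled tanh,

    S' = (tanh(0.1 * (S - mu) / sigma) + 1) / 2,

which maps scores into (0, 1) while preserving their ranking, then the
two normalized matrices are averaged with equal weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import AssociationMatrix, ScoreMatrix, SimilarityMatrix
from .errors import ConfigError, ValidationError
from .ni import NIConfig, ni_predict
from .rbm import RBMConfig, rbm_predict, train_cd


@dataclass(frozen=True)
class EnsembleConfig:
    tanh_scale: float = 0.1
    weight_ni: float = 0.5

    def __post_init__(self):
        if self.tanh_scale <= 0:
            raise ConfigError("tanh_scale must be positive")
        if not (0 <= self.weight_ni <= 1):
            raise ConfigError("weight_ni must lie in [0, 1]")


def normalize_scores(raw: ScoreMatrix, scale: float = 0.1) -> ScoreMatrix:
    """tanh z-score normalization over the whole matrix.

    The mean and population standard deviation are taken over all cells.
    A constant matrix (sigma = 0) maps uniformly to 0.5, which keeps
    cross-validation loops robust on degenerate folds.
    """
    X = raw.values
    mu = X.mean()
    sd = X.std()  # population form; affine invariance makes n vs n-1 moot
    if sd == 0:
        out = np.full_like(X, 0.5)
    else:
        out = (np.tanh(scale * (X - mu) / sd) + 1.0) / 2.0
    return ScoreMatrix(sms=raw.sms, mirnas=raw.mirnas, values=out)


def combine(s1: ScoreMatrix, s2: ScoreMatrix, w: float = 0.5) -> ScoreMatrix:
    """Convex combination w*S1 + (1-w)*S2, elementwise."""
    if s1.values.shape != s2.values.shape:
        raise ValidationError("score matrices have different shapes")
    if not (0 <= w <= 1):
        raise ValidationError("weight must lie in [0, 1]")
    return ScoreMatrix(
        sms=s1.sms, mirnas=s1.mirnas, values=w * s1.values + (1 - w) * s2.values
    )


def nirbm_predict(
    assoc: AssociationMatrix,
    isms: SimilarityMatrix,
    ims: SimilarityMatrix,
    ni_cfg: NIConfig | None = None,
    rbm_cfg: RBMConfig | None = None,
    ens_cfg: EnsembleConfig | None = None,
) -> ScoreMatrix:
    """Full pipeline: NI and RBM predictions, normalized and averaged."""
    ens_cfg = ens_cfg or EnsembleConfig()
    s_ni = ni_predict(assoc, isms, ims, ni_cfg)
    params = train_cd(assoc, rbm_cfg)
    s_rbm = rbm_predict(params, assoc)
    s1 = normalize_scores(s_ni, ens_cfg.tanh_scale)
    s2 = normalize_scores(s_rbm, ens_cfg.tanh_scale)
    return combine(s1, s2, ens_cfg.weight_ni)
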