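"""Neighborhood-based inference (NI) scoring.

An unknown (SM, miRNA) pair is scored by the similarity-weighted average
of the known associations held by the SM's (or miRNA's) above-threshold
neighbors:

    score^S(i, j) = sum_{d != i, S(d,i) >= sigma} A(d, j) S(d, i)
                    ---------------------------------------------
                    sum_{d != i, S(d,i) >= sigma} S(d, i)

and symmetrically on the miRNA side.  To reduce the bias of any single
neighborhood cutoff, basic models over a fixed grid of thresholds
(0.05, 0.10, ..., 0.50) up to an upper bound ``sigma_upper`` are
averaged, and the SM-side and miRNA-side averages are themselves
averaged into the final NI score.

Conventions: the self entity is never its own neighbor; ties at the
threshold are included (>=); an empty neighborhood scores 0, reading
"no evidence" conservatively rather than propagating 0/0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import AssociationMatrix, ScoreMatrix, SimilarityMatrix
from .errors import ConfigError, ValidationError

DEFAULT_GRID: tuple[float, ...] = tuple(round(0.05 * k, 2) for k in range(1, 11))


@dataclass(frozen=True)
class NIConfig:
    """Threshold grid and upper bound selecting the participating cutoffs."""

    grid: tuple[float, ...] = DEFAULT_GRID
    sigma_upper: float = 0.5

    def __post_init__(self):
        g = tuple(float(x) for x in self.grid)
        if not g:
            raise ConfigError("threshold grid is empty")
        if any(not (0 < x < 1) for x in g):
            raise ConfigError("grid thresholds must lie in (0, 1)")
        if any(b <= a for a, b in zip(g, g[1:])):
            raise ConfigError("grid must be strictly increasing")
        if not (0 < self.sigma_upper <= 0.5):
            raise ConfigError("sigma_upper must lie in (0, 0.5]")
        if self.sigma_upper < g[0]:
            raise ConfigError("sigma_upper below the smallest grid threshold")
        object.__setattr__(self, "grid", g)

    @property
    def active_thresholds(self) -> tuple[float, ...]:
        return tuple(s for s in self.grid if s <= self.sigma_upper)


def _check_sm_index(assoc: AssociationMatrix, sim: SimilarityMatrix) -> None:
    if sim.entities.ids != assoc.sms.ids:
        raise ValidationError("similarity matrix is not indexed by the SMs")


def _check_mirna_index(assoc: AssociationMatrix, sim: SimilarityMatrix) -> None:
    if sim.entities.ids != assoc.mirnas.ids:
        raise ValidationError("similarity matrix is not indexed by the miRNAs")


def _neighbor_scores(A: np.ndarray, S: np.ndarray, sigma: float) -> np.ndarray:
    """Columns of S index the focal entity; rows its potential neighbors."""
    W = np.where(S >= sigma, S, 0.0)
    np.fill_diagonal(W, 0.0)  # self never a neighbor
    num = W.T @ A
    den = W.sum(axis=0)[:, None]
    return np.divide(num, den, out=np.zeros_like(num, dtype=float), where=den > 0)


def sm_side_scores(
    assoc: AssociationMatrix, isms: SimilarityMatrix, sigma: float
) -> ScoreMatrix:
    """Single-threshold NI score using SM-SM similarity neighborhoods."""
    _check_sm_index(assoc, isms)
    vals = _neighbor_scores(assoc.A.astype(float), isms.S, sigma)
    return ScoreMatrix(sms=assoc.sms, mirnas=assoc.mirnas, values=vals)


def mirna_side_scores(
    assoc: AssociationMatrix, ims: SimilarityMatrix, sigma: float
) -> ScoreMatrix:
    """Single-threshold NI score using miRNA-miRNA similarity neighborhoods."""
    _check_mirna_index(assoc, ims)
    vals = _neighbor_scores(assoc.A.T.astype(float), ims.S, sigma).T
    return ScoreMatrix(sms=assoc.sms, mirnas=assoc.mirnas, values=vals)


def multi_threshold_average(
    assoc: AssociationMatrix,
    sim: SimilarityMatrix,
    side: str,
    cfg: NIConfig,
) -> ScoreMatrix:
    """Average of the basic single-threshold models over the active grid."""
    if side not in ("sm", "mirna"):
        raise ValidationError(f"side must be 'sm' or 'mirna', got {side!r}")
    thresholds = cfg.active_thresholds
    if not thresholds:
        raise ConfigError("no grid threshold lies at or below sigma_upper")
    score_fn = sm_side_scores if side == "sm" else mirna_side_scores
    acc = np.zeros((assoc.n_sms, assoc.n_mirnas))
    for s in thresholds:
        acc += score_fn(assoc, sim, s).values
    return ScoreMatrix(
        sms=assoc.sms, mirnas=assoc.mirnas, values=acc / len(thresholds)
    )


def ni_predict(
    assoc: AssociationMatrix,
    isms: SimilarityMatrix,
    ims: SimilarityMatrix,
    cfg: NIConfig | None = None,
) -> ScoreMatrix:
    """Full NI prediction: mean of SM-side and miRNA-side grid averages."""
    cfg = cfg or NIConfig()
    m_isms = multi_threshold_average(assoc, isms, "sm", cfg)
    m_ims = multi_threshold_average(assoc, ims, "mirna", cfg)
    return ScoreMatrix(
        sms=assoc.sms,
        mirnas=assoc.mirnas,
        values=(m_isms.values + m_ims.values) / 2.0,
    )
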