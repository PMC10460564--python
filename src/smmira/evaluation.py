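"""Cross-validation protocols and ranking metrics.

Four protocols are provided, all of which rank a held-out known pair
against *candidate samples* — cells that are 0 in the full association
matrix (held-in positives are never candidates):

* global LOOCV: each known pair is masked in turn, the pipeline is
  retrained, and the pair's score is ranked against every candidate;
* miRNA-fixed / SM-fixed local LOOCV: same loop, but candidates are
  restricted to pairs sharing the test pair's miRNA (resp. SM);
* repeated k-fold CV: the positives are partitioned into near-equal
  folds, each fold masked in turn, and the per-repetition AUC pooled
  into a mean and standard deviation.

Because candidate sets differ between iterations (local LOOCV), each
test score is converted to a normalized mid-rank within its own
iteration's candidate set; the pooled AUC compares those normalized
ranks against the candidates' own uniform quantiles, which reduces to
the usual Mann-Whitney statistic when candidate sets coincide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score

from .data_model import AssociationMatrix, SimilarityMatrix
from .ensemble import EnsembleConfig, combine, normalize_scores
from .errors import ValidationError
from .ni import NIConfig, ni_predict
from .rbm import RBMConfig, rbm_predict, train_cd

logger = logging.getLogger(__name__)

# A scorer maps a (possibly masked) association matrix to an ns x nm
# score array.  The evaluation loops are agnostic to what model backs it.
Scorer = Callable[[AssociationMatrix], np.ndarray]


@dataclass
class EvalResult:
    protocol: str
    auc: float
    aupr: float | None = None
    auc_sd: float | None = None
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    per_test_ranks: list[tuple[str, str, float, int]] = field(default_factory=list)
    repetition_aucs: list[float] = field(default_factory=list)


def rank_auc(pos_scores: Sequence[float], neg_scores: Sequence[float]) -> float:
    """AUC as the Mann-Whitney statistic P(pos > neg) + 0.5 P(pos = neg).

    Ties are handled by mid-ranks, matching trapezoidal integration of
    the tie-grouped ROC curve.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("both score lists must be nonempty")
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    return float((r_pos - pos.size * (pos.size + 1) / 2) / (pos.size * neg.size))


def roc_points(
    pos_scores: Sequence[float], neg_scores: Sequence[float]
) -> list[tuple[float, float]]:
    """Tie-grouped ROC curve from (0,0) to (1,1), FPR on the x axis."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("both score lists must be nonempty")
    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    pts = [(0.0, 0.0)]
    for t in thresholds:
        tpr = float((pos >= t).mean())
        fpr = float((neg >= t).mean())
        pts.append((fpr, tpr))
    if pts[-1] != (1.0, 1.0):
        pts.append((1.0, 1.0))
    return pts


def aupr(pos_scores: Sequence[float], neg_scores: Sequence[float]) -> float:
    """Area under the precision-recall curve (step-wise interpolation)."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("both score lists must be nonempty")
    labels = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    return float(average_precision_score(labels, np.concatenate([pos, neg])))


def normalized_rank(test_score: float, candidate_scores: np.ndarray) -> float:
    """Fraction of candidates ranked below the test score (ties count half)."""
    below = float((candidate_scores < test_score).sum())
    ties = float((candidate_scores == test_score).sum())
    return (below + 0.5 * ties) / candidate_scores.size


def _candidate_quantiles(n: int) -> np.ndarray:
    """Normalized mid-ranks a candidate set of size n occupies among itself."""
    return (np.arange(n) + 0.5) / n


def _masked(assoc: AssociationMatrix, pairs: Sequence[tuple[int, int]]) -> AssociationMatrix:
    A = assoc.A.copy()
    for i, j in pairs:
        A[i, j] = 0
    return AssociationMatrix(sms=assoc.sms, mirnas=assoc.mirnas, A=A)


def _pooled_result(
    protocol: str,
    pos_ranks: list[float],
    neg_quantiles: list[np.ndarray],
    per_test: list[tuple[str, str, float, int]],
) -> EvalResult:
    pos = np.asarray(pos_ranks)
    neg = np.concatenate(neg_quantiles)
    return EvalResult(
        protocol=protocol,
        auc=rank_auc(pos, neg),
        aupr=aupr(pos, neg),
        roc_points=roc_points(pos, neg),
        per_test_ranks=per_test,
    )


def global_loocv(assoc: AssociationMatrix, scorer: Scorer) -> EvalResult:
    """Leave-one-out over known pairs, ranked against all unknown pairs."""
    positives = assoc.positive_pairs()
    if len(positives) < 2:
        raise ValidationError("global LOOCV needs at least 2 known associations")
    cand_mask = assoc.A == 0
    pos_ranks, negs, per_test = [], [], []
    n_cand = int(cand_mask.sum())
    for i, j in positives:
        scores = scorer(_masked(assoc, [(i, j)]))
        r = normalized_rank(scores[i, j], scores[cand_mask])
        pos_ranks.append(r)
        negs.append(_candidate_quantiles(n_cand))
        per_test.append((assoc.sms.ids[i], assoc.mirnas.ids[j], r, n_cand))
    return _pooled_result("global_loocv", pos_ranks, negs, per_test)


def local_loocv(assoc: AssociationMatrix, scorer: Scorer, axis: str) -> EvalResult:
    """LOOCV with candidates restricted to the test pair's miRNA or SM.

    ``axis`` is ``"mirna_fixed"`` (candidates share the miRNA column) or
    ``"sm_fixed"`` (candidates share the SM row).  Test pairs with an
    empty restricted candidate set are skipped with a logged notice.
    """
    if axis not in ("mirna_fixed", "sm_fixed"):
        raise ValidationError(f"axis must be 'mirna_fixed' or 'sm_fixed', got {axis!r}")
    positives = assoc.positive_pairs()
    if len(positives) < 2:
        raise ValidationError("LOOCV needs at least 2 known associations")
    cand_mask = assoc.A == 0
    pos_ranks, negs, per_test = [], [], []
    for i, j in positives:
        local = cand_mask[:, j] if axis == "mirna_fixed" else cand_mask[i, :]
        n_cand = int(local.sum())
        if n_cand == 0:
            logger.info(
                "skipping (%s, %s): empty %s candidate set",
                assoc.sms.ids[i], assoc.mirnas.ids[j], axis,
            )
            continue
        scores = scorer(_masked(assoc, [(i, j)]))
        cand_scores = scores[:, j][local] if axis == "mirna_fixed" else scores[i, :][local]
        r = normalized_rank(scores[i, j], cand_scores)
        pos_ranks.append(r)
        negs.append(_candidate_quantiles(n_cand))
        per_test.append((assoc.sms.ids[i], assoc.mirnas.ids[j], r, n_cand))
    if not pos_ranks:
        raise ValidationError("every test pair had an empty candidate set")
    return _pooled_result(axis[:-6] + "_loocv", pos_ranks, negs, per_test)


def make_folds(
    n: int, k: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Random partition of range(n) into k folds with sizes differing by <= 1."""
    if k < 2 or k > n:
        raise ValidationError(f"k={k} must satisfy 2 <= k <= number of positives ({n})")
    return [np.sort(f) for f in np.array_split(rng.permutation(n), k)]


def kfold_cv(
    assoc: AssociationMatrix,
    scorer: Scorer,
    k: int = 5,
    repetitions: int = 1,
    seed: int = 0,
) -> EvalResult:
    """Repeated k-fold CV over the positives; mean and sd of per-rep AUC."""
    if repetitions < 1:
        raise ValidationError("repetitions must be >= 1")
    positives = assoc.positive_pairs()
    cand_mask = assoc.A == 0
    n_cand = int(cand_mask.sum())
    rep_aucs = []
    all_per_test: list[tuple[str, str, float, int]] = []
    last_pos, last_negs = [], []
    for rep in range(repetitions):
        rng = np.random.default_rng(seed + rep)
        folds = make_folds(len(positives), k, rng)
        pos_ranks, negs = [], []
        for fold in folds:
            held = [positives[t] for t in fold]
            scores = scorer(_masked(assoc, held))
            cand_scores = scores[cand_mask]
            for i, j in held:
                r = normalized_rank(scores[i, j], cand_scores)
                pos_ranks.append(r)
                negs.append(_candidate_quantiles(n_cand))
                all_per_test.append(
                    (assoc.sms.ids[i], assoc.mirnas.ids[j], r, n_cand)
                )
        rep_aucs.append(rank_auc(pos_ranks, np.concatenate(negs)))
        last_pos, last_negs = pos_ranks, negs
    res = _pooled_result("kfold", last_pos, last_negs, all_per_test)
    res.auc = float(np.mean(rep_aucs))
    res.auc_sd = float(np.std(rep_aucs, ddof=1)) if repetitions > 1 else 0.0
    res.repetition_aucs = [float(a) for a in rep_aucs]
    return res


def permutation_null(
    n_tests: int,
    candidate_sizes: Sequence[int],
    n_permutations: int = 100,
    seed: int = 0,
) -> tuple[float, float]:
    """Null distribution of the pooled AUC under random score permutation.

    Each permutation places every test sample uniformly among its
    candidates (the exchangeable-scores null) and recomputes the pooled
    AUC; returns the (mean, sd) over permutations.
    """
    rng = np.random.default_rng(seed)
    sizes = np.asarray(candidate_sizes, dtype=int)
    if sizes.shape != (n_tests,):
        sizes = np.full(n_tests, int(sizes.flat[0]))
    negs = np.concatenate([_candidate_quantiles(int(n)) for n in sizes])
    aucs = []
    for _ in range(n_permutations):
        # position k among n candidates is uniform on {0, ..., n}
        ranks = [rng.integers(0, n + 1) / n for n in sizes]
        aucs.append(rank_auc(np.asarray(ranks), negs))
    return float(np.mean(aucs)), float(np.std(aucs))


# ---------------------------------------------------------------------------
# Scorer factories

def make_ni_scorer(
    isms: SimilarityMatrix, ims: SimilarityMatrix, cfg: NIConfig | None = None
) -> Scorer:
    def scorer(assoc: AssociationMatrix) -> np.ndarray:
        return ni_predict(assoc, isms, ims, cfg).values

    return scorer


def make_rbm_scorer(cfg: RBMConfig | None = None) -> Scorer:
    def scorer(assoc: AssociationMatrix) -> np.ndarray:
        params = train_cd(assoc, cfg)
        return rbm_predict(params, assoc).values

    return scorer


def make_nirbm_scorer(
    isms: SimilarityMatrix,
    ims: SimilarityMatrix,
    ni_cfg: NIConfig | None = None,
    rbm_cfg: RBMConfig | None = None,
    ens_cfg: EnsembleConfig | None = None,
) -> Scorer:
    ens_cfg = ens_cfg or EnsembleConfig()

    def scorer(assoc: AssociationMatrix) -> np.ndarray:
        s_ni = ni_predict(assoc, isms, ims, ni_cfg)
        s_rbm = rbm_predict(train_cd(assoc, rbm_cfg), assoc)
        return combine(
            normalize_scores(s_ni, ens_cfg.tanh_scale),
            normalize_scores(s_rbm, ens_cfg.tanh_scale),
            ens_cfg.weight_ni,
        ).values

    return scorer


def tune_hyperparameters(
    train_assoc: AssociationMatrix,
    isms: SimilarityMatrix,
    ims: SimilarityMatrix,
    sigma_upper_grid: Sequence[float],
    s_grid: Sequence[int],
    inner_k: int = 5,
    seed: int = 0,
    ni_grid: Sequence[float] | None = None,
    rbm_base_cfg: RBMConfig | None = None,
) -> tuple[float, int]:
    """Select sigma_upper (NI) and hidden-unit count s (RBM) by inner-CV AUPR.

    Each knob is tuned against its own base predictor on the training
    positives only: candidates are evaluated by mean AUPR over an inner
    k-fold split (shared across candidates), and the argmax wins with
    ties broken toward the smaller value.  One-element grids are
    returned unchanged without running the inner CV.
    """
    if not sigma_upper_grid or not s_grid:
        raise ValidationError("candidate grids must be nonempty")
    ni_grid = tuple(ni_grid) if ni_grid is not None else NIConfig().grid
    rbm_base_cfg = rbm_base_cfg or RBMConfig()

    positives = train_assoc.positive_pairs()
    cand_mask = train_assoc.A == 0
    rng = np.random.default_rng(seed)
    folds = (
        make_folds(len(positives), inner_k, rng)
        if (len(sigma_upper_grid) > 1 or len(s_grid) > 1)
        else []
    )

    def mean_aupr(scorer: Scorer) -> float:
        vals = []
        for fold in folds:
            held = [positives[t] for t in fold]
            scores = scorer(_masked(train_assoc, held))
            pos_scores = [scores[i, j] for i, j in held]
            vals.append(aupr(pos_scores, scores[cand_mask]))
        return float(np.mean(vals))

    if len(sigma_upper_grid) == 1:
        best_sigma = float(sigma_upper_grid[0])
    else:
        results = []
        for su in sigma_upper_grid:
            cfg = NIConfig(grid=ni_grid, sigma_upper=float(su))
            results.append((mean_aupr(make_ni_scorer(isms, ims, cfg)), -float(su)))
        best_sigma = -max(results)[1]

    if len(s_grid) == 1:
        best_s = int(s_grid[0])
    else:
        results = []
        for s in s_grid:
            cfg = RBMConfig(
                hidden_units=int(s),
                learning_rate=rbm_base_cfg.learning_rate,
                epochs=rbm_base_cfg.epochs,
                batch_size=rbm_base_cfg.batch_size,
                cd_steps=rbm_base_cfg.cd_steps,
                seed=rbm_base_cfg.seed,
            )
            results.append((mean_aupr(make_rbm_scorer(cfg)), -int(s)))
        best_s = -max(results)[1]
    return best_sigma, int(best_s)
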