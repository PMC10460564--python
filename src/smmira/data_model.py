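"""Typed containers for association and similarity data, with TSV I/O.

The central object is a binary small-molecule x miRNA association matrix
``A`` in {0,1}^(ns x nm) built from a curated edge list, together with
square symmetric similarity matrices over each entity set.  All matrices
carry :class:`EntityIndex` objects so that identifiers, never integer
positions, appear in files and reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

_SYMMETRY_TOL = 1e-9


@dataclass(frozen=True)
class EntityIndex:
    """Ordered set of unique entity identifiers with O(1) lookup."""

    ids: tuple[str, ...]
    position: dict[str, int] = field(repr=False, compare=False, default=None)

    def __post_init__(self):
        if len(self.ids) == 0:
            raise ValidationError("entity index must contain at least one id")
        pos = {s: i for i, s in enumerate(self.ids)}
        if len(pos) != len(self.ids):
            dupes = [s for s in pos if self.ids.count(s) > 1]
            raise ValidationError(f"duplicate identifiers: {dupes[:5]}")
        object.__setattr__(self, "position", pos)

    @classmethod
    def from_ids(cls, ids: Iterable[str]) -> "EntityIndex":
        return cls(ids=tuple(str(s) for s in ids))

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, item: str) -> bool:
        return item in self.position


@dataclass(frozen=True)
class AssociationMatrix:
    """Binary ns x nm matrix of known SM-miRNA associations.

    ``A[i, j] == 1`` iff small molecule ``sms.ids[i]`` is known to be
    associated with miRNA ``mirnas.ids[j]``.
    """

    sms: EntityIndex
    mirnas: EntityIndex
    A: np.ndarray

    def __post_init__(self):
        A = np.asarray(self.A, dtype=np.int8)
        if A.shape != (len(self.sms), len(self.mirnas)):
            raise ValidationError(
                f"matrix shape {A.shape} does not match index sizes "
                f"({len(self.sms)}, {len(self.mirnas)})"
            )
        if not np.isin(A, (0, 1)).all():
            raise ValidationError("association matrix entries must be 0 or 1")
        object.__setattr__(self, "A", A)

    @property
    def n_sms(self) -> int:
        return len(self.sms)

    @property
    def n_mirnas(self) -> int:
        return len(self.mirnas)

    @property
    def n_associations(self) -> int:
        return int(self.A.sum())

    def positive_pairs(self) -> list[tuple[int, int]]:
        """Row/column index pairs of the known associations, row-major order."""
        return [(int(i), int(j)) for i, j in zip(*np.nonzero(self.A))]


@dataclass(frozen=True)
class SimilarityMatrix:
    """Square symmetric similarity matrix in [0, 1] over one entity set."""

    entities: EntityIndex
    S: np.ndarray

    def __post_init__(self):
        S = np.asarray(self.S, dtype=float)
        n = len(self.entities)
        if S.shape != (n, n):
            raise ValidationError(f"similarity shape {S.shape} != ({n}, {n})")
        if not np.isfinite(S).all():
            raise ValidationError("similarity matrix contains non-finite entries")
        if np.abs(S - S.T).max() > _SYMMETRY_TOL:
            raise ValidationError("similarity matrix is not symmetric")
        if S.min() < -_SYMMETRY_TOL or S.max() > 1 + _SYMMETRY_TOL:
            raise ValidationError("similarity entries must lie in [0, 1]")
        object.__setattr__(self, "S", np.clip(S, 0.0, 1.0))


@dataclass(frozen=True)
class ScoreMatrix:
    """Real-valued ns x nm prediction matrix."""

    sms: EntityIndex
    mirnas: EntityIndex
    values: np.ndarray

    def __post_init__(self):
        V = np.asarray(self.values, dtype=float)
        if V.shape != (len(self.sms), len(self.mirnas)):
            raise ValidationError(
                f"score shape {V.shape} does not match index sizes"
            )
        if not np.isfinite(V).all():
            raise ValidationError("score matrix contains non-finite entries")
        object.__setattr__(self, "values", V)


def read_universe(path: str | Path) -> EntityIndex:
    """Read a one-id-per-line universe file, order preserved."""
    ids = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line:
            ids.append(line)
    if not ids:
        raise FormatError(f"universe file {path} is empty")
    return EntityIndex.from_ids(ids)


def read_association_edges(
    path: str | Path,
    sm_universe: Sequence[str] | EntityIndex | None = None,
    mirna_universe: Sequence[str] | EntityIndex | None = None,
) -> AssociationMatrix:
    """Build the binary association matrix from a two-column TSV edge list.

    Each line names one known (SM id, miRNA id) pair.  When universes are
    supplied the matrix covers every universe entity in universe order,
    including zero-degree rows/columns; otherwise row and column order
    follow first appearance in the file.  Duplicate edges collapse to a
    single 1 (counted in the log).
    """
    edges: list[tuple[str, str]] = []
    for lineno, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
            raise FormatError(
                f"{path}:{lineno}: expected two tab-separated ids, got {line!r}"
            )
        edges.append((parts[0].strip(), parts[1].strip()))
    if not edges:
        raise FormatError(f"edge file {path} contains no edges")

    if sm_universe is not None:
        sms = (
            sm_universe
            if isinstance(sm_universe, EntityIndex)
            else EntityIndex.from_ids(sm_universe)
        )
    else:
        sms = EntityIndex.from_ids(dict.fromkeys(s for s, _ in edges))
    if mirna_universe is not None:
        mirnas = (
            mirna_universe
            if isinstance(mirna_universe, EntityIndex)
            else EntityIndex.from_ids(mirna_universe)
        )
    else:
        mirnas = EntityIndex.from_ids(dict.fromkeys(m for _, m in edges))

    A = np.zeros((len(sms), len(mirnas)), dtype=np.int8)
    n_dup = 0
    for s, m in edges:
        if s not in sms:
            raise ValidationError(f"SM id {s!r} not in supplied universe")
        if m not in mirnas:
            raise ValidationError(f"miRNA id {m!r} not in supplied universe")
        i, j = sms.position[s], mirnas.position[m]
        if A[i, j]:
            n_dup += 1
        A[i, j] = 1
    if n_dup:
        logger.info("collapsed %d duplicate edges in %s", n_dup, path)
    return AssociationMatrix(sms=sms, mirnas=mirnas, A=A)


def write_association_edges(assoc: AssociationMatrix, path: str | Path) -> None:
    """Write the known pairs back out as a two-column TSV, row-major order."""
    with open(path, "w", encoding="utf-8") as fh:
        for i, j in assoc.positive_pairs():
            fh.write(f"{assoc.sms.ids[i]}\t{assoc.mirnas.ids[j]}\n")


def read_similarity_matrix(
    path: str | Path, force_unit_diagonal: bool = True
) -> SimilarityMatrix:
    """Read a similarity TSV whose first row and first column are entity ids.

    Small asymmetries are symmetrized as (S + S^T)/2 and out-of-range
    entries are clipped to [0, 1], both with a logged warning.  The
    diagonal is forced to 1 by default: an entity is maximally similar to
    itself, and downstream neighborhood scoring excludes self-neighbors so
    this cannot leak label information.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise FormatError(f"{path}: similarity body is not square {df.shape}")
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise FormatError(f"{path}: row ids and column ids differ")
    S = df.to_numpy(dtype=float)
    if np.isnan(S).any():
        raise FormatError(f"{path}: similarity matrix contains NaN entries")
    if np.abs(S - S.T).max() > _SYMMETRY_TOL:
        logger.warning("%s: asymmetric similarity symmetrized as (S+S^T)/2", path)
        S = (S + S.T) / 2.0
    if S.min() < 0.0 or S.max() > 1.0:
        logger.warning("%s: similarity entries clipped to [0, 1]", path)
        S = np.clip(S, 0.0, 1.0)
    if force_unit_diagonal:
        np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(
        entities=EntityIndex.from_ids(df.index.astype(str)), S=S
    )


def write_similarity_matrix(sim: SimilarityMatrix, path: str | Path) -> None:
    ids = list(sim.entities.ids)
    pd.DataFrame(sim.S, index=ids, columns=ids).to_csv(
        path, sep="\t", float_format="%.10g"
    )


def restrict_to_connected(assoc: AssociationMatrix) -> AssociationMatrix:
    """Drop SMs and miRNAs with no known association.

    This is the dataset-reduction step that turns the full sparse matrix
    into its connected core; the number of 1 entries is conserved.
    """
    row_keep = assoc.A.sum(axis=1) > 0
    col_keep = assoc.A.sum(axis=0) > 0
    if not row_keep.any() or not col_keep.any():
        raise ValidationError("association matrix has no known pairs")
    return AssociationMatrix(
        sms=EntityIndex.from_ids(
            [s for s, k in zip(assoc.sms.ids, row_keep) if k]
        ),
        mirnas=EntityIndex.from_ids(
            [m for m, k in zip(assoc.mirnas.ids, col_keep) if k]
        ),
        A=assoc.A[np.ix_(row_keep, col_keep)],
    )


def count_isolated_rows(assoc: AssociationMatrix) -> int:
    """Number of SMs without any known associated miRNA."""
    return int((assoc.A.sum(axis=1) == 0).sum())


def write_ranked_scores(
    scores: ScoreMatrix,
    assoc: AssociationMatrix,
    path: str | Path,
    known_only: bool = False,
) -> None:
    """Write scores as a ranked TSV: sm, mirna, score, known flag.

    Rows are sorted by descending score; ties break lexicographically on
    (sm id, miRNA id).  With ``known_only=False`` every cell is written;
    callers filter to unknown pairs beforehand if desired.
    """
    rows = []
    for i, s in enumerate(scores.sms.ids):
        for j, m in enumerate(scores.mirnas.ids):
            rows.append((s, m, scores.values[i, j], int(assoc.A[i, j])))
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sm\tmirna\tscore\tknown\n")
        for s, m, v, k in rows:
            if known_only and not k:
                continue
            fh.write(f"{s}\t{m}\t{v:.10g}\t{k}\n")
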