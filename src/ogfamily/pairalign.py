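"""Exact pairwise protein alignment (global and local, affine gaps).

This is the similarity engine behind orthogroup inference: instead of a
heuristic database search, every comparison is an optimal Needleman-Wunsch
or Smith-Waterman alignment under an affine gap model, computed by
numba-compiled dynamic programming. A gap of length L costs
``gap_open + (L-1) * gap_extend``.

Percent identity and percent similarity use the alignment length (gap
columns included) as denominator, the convention of the EMBOSS suite.
Hit lists are ranked by raw local alignment score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from numba import njit

from .datamodel import AMINO_ACIDS, DataError, ProteinRecord

#: residue order used by the integer encoding; X is the final symbol
ALPHABET_ORDER = AMINO_ACIDS + "X"
_INDEX = {c: i for i, c in enumerate(ALPHABET_ORDER)}

GLOBAL, LOCAL = "global", "local"

NEG_INF = -1e30


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix (21x21 over :data:`ALPHABET_ORDER`) + gap penalties."""

    name: str
    matrix: np.ndarray  # float64, symmetric
    gap_open: float
    gap_extend: float

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise DataError("gap penalties must be >= 0")
        if self.gap_extend > self.gap_open:
            raise DataError("gap_extend must be <= gap_open")
        if self.matrix.shape != (21, 21) or not np.allclose(self.matrix, self.matrix.T):
            raise DataError("substitution matrix must be symmetric 21x21")

    @classmethod
    def blosum62(cls, gap_open: float = 10.0, gap_extend: float = 0.5) -> "ScoringScheme":
        """BLOSUM62 with EMBOSS-style default penalties; X scores 0 vs all."""
        return cls.from_biopython(
            substitution_matrices.load("BLOSUM62"), "BLOSUM62", gap_open, gap_extend
        )

    @classmethod
    def from_ncbi_file(cls, path, gap_open: float = 10.0, gap_extend: float = 0.5,
                       name: str = "custom") -> "ScoringScheme":
        """Read a matrix in NCBI matrix text format."""
        with open(path) as fh:
            return cls.from_biopython(substitution_matrices.read(fh), name, gap_open, gap_extend)

    @classmethod
    def from_biopython(cls, bm, name: str, gap_open: float, gap_extend: float) -> "ScoringScheme":
        mat = np.zeros((21, 21))
        for i, a in enumerate(AMINO_ACIDS):
            for j, b in enumerate(AMINO_ACIDS):
                mat[i, j] = bm[a, b]
        # X is "unknown": neutral against everything, including itself
        mat[20, :] = 0.0
        mat[:, 20] = 0.0
        return cls(name=name, matrix=mat, gap_open=gap_open, gap_extend=gap_extend)


def encode(seq: str) -> np.ndarray:
    try:
        return np.array([_INDEX[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise DataError(f"residue {exc.args[0]!r} outside alphabet") from exc


@dataclass
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    mode: str
    identity_pct: float
    similarity_pct: float
    alignment_length: int


# ---------------------------------------------------------------------------
# numba DP kernels
# ---------------------------------------------------------------------------
# States: 0 = M (diagonal), 1 = gap in b (consumes a), 2 = gap in a (consumes b).

@njit(cache=True)
def _gotoh_score(a, b, sub, gap_open, gap_extend, local):  # pragma: no cover - jit
    n, m = a.shape[0], b.shape[0]
    M = np.full(m + 1, NEG_INF)
    Ix = np.full(m + 1, NEG_INF)
    Iy = np.full(m + 1, NEG_INF)
    M[0] = 0.0
    if local:
        for j in range(1, m + 1):
            M[j] = 0.0
    else:
        for j in range(1, m + 1):
            Iy[j] = -(gap_open + (j - 1) * gap_extend)
    best = 0.0
    for i in range(1, n + 1):
        prevM, prevIx, prevIy = M[0], Ix[0], Iy[0]
        if local:
            M[0] = 0.0
            Ix[0] = NEG_INF
        else:
            M[0] = NEG_INF
            Ix[0] = -(gap_open + (i - 1) * gap_extend)
        Iy[0] = NEG_INF
        for j in range(1, m + 1):
            curM, curIx, curIy = M[j], Ix[j], Iy[j]
            # diagonal
            d = prevM
            if prevIx > d:
                d = prevIx
            if prevIy > d:
                d = prevIy
            s = d + sub[a[i - 1], b[j - 1]]
            if local and s < 0.0:
                s = 0.0
            # gap in b (vertical, consumes a[i-1]) from row above, same column
            gx = curM - gap_open
            if curIx - gap_extend > gx:
                gx = curIx - gap_extend
            if curIy - gap_open > gx:
                gx = curIy - gap_open
            # gap in a (horizontal, consumes b[j-1]) from same row, previous column
            gy = M[j - 1] - gap_open
            if Iy[j - 1] - gap_extend > gy:
                gy = Iy[j - 1] - gap_extend
            if Ix[j - 1] - gap_open > gy:
                gy = Ix[j - 1] - gap_open
            prevM, prevIx, prevIy = curM, curIx, curIy
            M[j] = s
            Ix[j] = gx
            Iy[j] = gy
            if local and s > best:
                best = s
    if local:
        return best
    f = M[m]
    if Ix[m] > f:
        f = Ix[m]
    if Iy[m] > f:
        f = Iy[m]
    return f


@njit(cache=True)
def _gotoh_full(a, b, sub, gap_open, gap_extend, local):  # pragma: no cover - jit
    """Full DP with traceback pointers. Returns (M, Ix, Iy, ptr)."""
    n, m = a.shape[0], b.shape[0]
    M = np.full((n + 1, m + 1), NEG_INF)
    Ix = np.full((n + 1, m + 1), NEG_INF)
    Iy = np.full((n + 1, m + 1), NEG_INF)
    # ptr[state, i, j]: predecessor state (0,1,2), 3 = alignment start
    ptr = np.full((3, n + 1, m + 1), -1, dtype=np.int8)
    M[0, 0] = 0.0
    ptr[0, 0, 0] = 3
    for i in range(1, n + 1):
        if local:
            M[i, 0] = 0.0
            ptr[0, i, 0] = 3
        else:
            Ix[i, 0] = -(gap_open + (i - 1) * gap_extend)
            ptr[1, i, 0] = 1 if i > 1 else 0
    for j in range(1, m + 1):
        if local:
            M[0, j] = 0.0
            ptr[0, 0, j] = 3
        else:
            Iy[0, j] = -(gap_open + (j - 1) * gap_extend)
            ptr[2, 0, j] = 2 if j > 1 else 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # M: tie-break prefers diagonal predecessor M, then Ix, then Iy
            bestv = M[i - 1, j - 1]
            bests = 0
            if Ix[i - 1, j - 1] > bestv:
                bestv = Ix[i - 1, j - 1]
                bests = 1
            if Iy[i - 1, j - 1] > bestv:
                bestv = Iy[i - 1, j - 1]
                bests = 2
            s = bestv + sub[a[i - 1], b[j - 1]]
            if local and s < 0.0:
                M[i, j] = 0.0
                ptr[0, i, j] = 3
            else:
                M[i, j] = s
                ptr[0, i, j] = bests
            # Ix (gap in b, consumes a)
            bestv = M[i - 1, j] - gap_open
            bests = 0
            if Ix[i - 1, j] - gap_extend > bestv:
                bestv = Ix[i - 1, j] - gap_extend
                bests = 1
            if Iy[i - 1, j] - gap_open > bestv:
                bestv = Iy[i - 1, j] - gap_open
                bests = 2
            Ix[i, j] = bestv
            ptr[1, i, j] = bests
            # Iy (gap in a, consumes b)
            bestv = M[i, j - 1] - gap_open
            bests = 0
            if Iy[i, j - 1] - gap_extend > bestv:
                bestv = Iy[i, j - 1] - gap_extend
                bests = 2
            if Ix[i, j - 1] - gap_open > bestv:
                bestv = Ix[i, j - 1] - gap_open
                bests = 1
            Iy[i, j] = bestv
            ptr[2, i, j] = bests
    return M, Ix, Iy, ptr


def _traceback(a: str, b: str, M, Ix, Iy, ptr, local: bool):
    n, m = len(a), len(b)
    if local:
        # deterministic end cell: best M score, smallest (i, j) on ties
        best, end_i, end_j = 0.0, 0, 0
        for i in range(n + 1):
            for j in range(m + 1):
                if M[i, j] > best + 1e-9:
                    best, end_i, end_j = M[i, j], i, j
        if best <= 0.0:
            return "", "", 0.0
        i, j, state, score = end_i, end_j, 0, float(best)
    else:
        # final state preference mirrors the cell tie-break: M, then Ix, then Iy
        state, score = 0, M[n, m]
        if Ix[n, m] > score:
            score, state = Ix[n, m], 1
        if Iy[n, m] > score:
            score, state = Iy[n, m], 2
        i, j = n, m
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        if state == 0 and ptr[0, i, j] == 3:
            break  # local alignment start marker
        prev = ptr[state, i, j]
        if state == 0:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
        elif state == 1:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
        state = prev
    return "".join(reversed(out_a)), "".join(reversed(out_b)), float(score)


def _stats(aligned_a: str, aligned_b: str, scheme: ScoringScheme) -> tuple[float, float, int]:
    length = len(aligned_a)
    if length == 0:
        return 0.0, 0.0, 0
    ident = sim = 0
    for x, y in zip(aligned_a, aligned_b):
        if x == "-" or y == "-":
            continue
        if x == y:
            ident += 1
            sim += 1
        elif scheme.matrix[_INDEX[x], _INDEX[y]] > 0:
            sim += 1
    return 100.0 * ident / length, 100.0 * sim / length, length


def _align(a: str, b: str, scheme: ScoringScheme, mode: str) -> AlignmentResult:
    if not a or not b:
        raise DataError("cannot align empty sequence")
    ea, eb = encode(a), encode(b)
    local = mode == LOCAL
    M, Ix, Iy, ptr = _gotoh_full(ea, eb, scheme.matrix, scheme.gap_open,
                                 scheme.gap_extend, local)
    aligned_a, aligned_b, score = _traceback(a, b, M, Ix, Iy, ptr, local)
    ident, sim, length = _stats(aligned_a, aligned_b, scheme)
    return AlignmentResult(aligned_a, aligned_b, float(score), mode, ident, sim, length)


def align_global(a: str, b: str, scheme: ScoringScheme) -> AlignmentResult:
    """Optimal global (Needleman-Wunsch) alignment under affine gaps."""
    return _align(a, b, scheme, GLOBAL)


def align_local(a: str, b: str, scheme: ScoringScheme) -> AlignmentResult:
    """Optimal local (Smith-Waterman) alignment; empty alignment scores 0."""
    return _align(a, b, scheme, LOCAL)


def score_global(a: str, b: str, scheme: ScoringScheme) -> float:
    if not a or not b:
        raise DataError("cannot align empty sequence")
    return float(_gotoh_score(encode(a), encode(b), scheme.matrix,
                              scheme.gap_open, scheme.gap_extend, False))


def score_local(a: str, b: str, scheme: ScoringScheme) -> float:
    if not a or not b:
        raise DataError("cannot align empty sequence")
    return float(_gotoh_score(encode(a), encode(b), scheme.matrix,
                              scheme.gap_open, scheme.gap_extend, True))


# ---------------------------------------------------------------------------
# hit lists
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Hit:
    target: str
    species: str
    score: float


def rank_hits(
    query: ProteinRecord,
    database: Sequence[ProteinRecord],
    scheme: ScoringScheme,
    precomputed: Optional[dict[str, float]] = None,
) -> list[Hit]:
    """Local-score hit list: descending score, ties by ascending target id.

    ``precomputed`` may supply scores keyed by target id (e.g. from
    :func:`all_pairs_scores`) to avoid recomputation.
    """
    if not database:
        raise DataError("empty database")
    eq = encode(query.sequence)
    hits = []
    for rec in database:
        if precomputed is not None and rec.id in precomputed:
            s = precomputed[rec.id]
        else:
            s = float(_gotoh_score(eq, encode(rec.sequence), scheme.matrix,
                                   scheme.gap_open, scheme.gap_extend, True))
        hits.append(Hit(rec.id, rec.species, s))
    hits.sort(key=lambda h: (-h.score, h.target))
    return hits


def all_pairs_scores(records: Sequence[ProteinRecord], scheme: ScoringScheme) -> pd.DataFrame:
    """Symmetric local-score matrix over all records (ids as index/columns)."""
    enc = [encode(r.sequence) for r in records]
    ids = [r.id for r in records]
    n = len(records)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            s = _gotoh_score(enc[i], enc[j], scheme.matrix,
                             scheme.gap_open, scheme.gap_extend, True)
            out[i, j] = out[j, i] = s
    return pd.DataFrame(out, index=ids, columns=ids)


def read_blast_tab(path) -> pd.DataFrame:
    """Import BLAST tabular hits (12-column outfmt 6).

    Only qseqid, sseqid and bitscore are used; the returned frame is sorted
    by the hit-list contract (descending score, ascending target id).
    """
    cols = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
            "qstart", "qend", "sstart", "send", "evalue", "bitscore"]
    df = pd.read_csv(path, sep="\t", names=cols, comment="#")
    df = df[["qseqid", "sseqid", "bitscore"]].rename(
        columns={"sseqid": "target", "bitscore": "score"})
    return df.sort_values(["qseqid", "score", "target"],
                          ascending=[True, False, True]).reset_index(drop=True)
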