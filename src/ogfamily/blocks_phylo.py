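"""Conserved-block selection, distance trees, bootstrap and monophyly checks.

Alignments come from outside (an external aligner, or the simulator's true
alignment, where positional homology is known by construction); this module
selects conserved blocks with relaxed Gblocks-style criteria, computes
corrected protein distances, builds neighbour-joining (NJ) trees with
bootstrap supports, verifies that orthogroups form clades, and runs a
leave-one-out probe for long-branch attraction (LBA).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
from Bio import SeqIO
from skbio import TreeNode

from .datamodel import DataError, ProteinRecord

GAP = "-"


def _leafset(node: TreeNode) -> frozenset:
    """Leaf names under a node (the node itself when it is a tip)."""
    if node.is_tip():
        return frozenset({node.name})
    return frozenset(t.name for t in node.tips())


# ---------------------------------------------------------------------------
# multiple sequence alignments
# ---------------------------------------------------------------------------

@dataclass
class MSA:
    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise DataError("ids and rows differ in number")
        if len(set(self.ids)) != len(self.ids):
            raise DataError("duplicate ids in MSA")
        if self.rows and len({len(r) for r in self.rows}) != 1:
            raise DataError("MSA rows differ in length")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @classmethod
    def from_fasta(cls, path) -> "MSA":
        recs = list(SeqIO.parse(str(path), "fasta"))
        return cls([r.id for r in recs], [str(r.seq).upper() for r in recs])

    @classmethod
    def from_records(cls, records: Sequence[ProteinRecord]) -> "MSA":
        """Stack equal-length sequences that are positionally homologous
        (the simulator's true alignment for one orthogroup)."""
        return cls([r.id for r in records], [r.sequence for r in records])

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for i, row in zip(self.ids, self.rows):
                fh.write(f">{i}\n{row}\n")

    def drop(self, leaf_id: str) -> "MSA":
        if leaf_id not in self.ids:
            raise DataError(f"{leaf_id!r} not in MSA")
        keep = [k for k, i in enumerate(self.ids) if i != leaf_id]
        return MSA([self.ids[k] for k in keep], [self.rows[k] for k in keep])


# ---------------------------------------------------------------------------
# conserved-block selection (relaxed Gblocks-style)
# ---------------------------------------------------------------------------

NONE, HALF, ALL = "none", "half", "all"


@dataclass
class BlockParams:
    """Relaxed defaults: small final blocks, gaps tolerated in half of the
    rows, flanks held to the same conservation level as interior columns."""

    min_conserved_frac: float = 0.5
    min_flank_frac: Optional[float] = None  # default: same as min_conserved_frac
    max_nonconserved_run: int = 8
    min_block_length: int = 5
    gap_policy: str = HALF

    def __post_init__(self) -> None:
        if self.min_block_length < 1:
            raise DataError("min_block_length must be >= 1")
        if self.gap_policy not in (NONE, HALF, ALL):
            raise DataError(f"unknown gap policy {self.gap_policy!r}")
        if self.min_flank_frac is None:
            self.min_flank_frac = self.min_conserved_frac


@dataclass
class BlockSelection:
    kept_columns: list[int]  # 0-based, strictly increasing
    blocks: list[tuple[int, int]]  # 1-based inclusive ranges
    parameters: BlockParams

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("block_start\tblock_end\n")
            for s, e in self.blocks:
                fh.write(f"{s}\t{e}\n")


def _column_stats(msa: MSA) -> tuple[np.ndarray, np.ndarray]:
    """Per column: modal non-gap residue frequency (over all rows) and gap
    fraction."""
    arr = np.array([list(r) for r in msa.rows])
    n, m = arr.shape
    modal = np.zeros(m)
    gapfrac = np.zeros(m)
    for j in range(m):
        col = arr[:, j]
        gaps = int((col == GAP).sum())
        gapfrac[j] = gaps / n
        residues = col[col != GAP]
        if residues.size:
            _, counts = np.unique(residues, return_counts=True)
            modal[j] = counts.max() / n
    return modal, gapfrac


def select_blocks(msa: MSA, params: Optional[BlockParams] = None) -> BlockSelection:
    """Classify columns, assemble blocks, trim flanks, drop short blocks."""
    if not msa.rows:
        raise DataError("empty MSA")
    params = params or BlockParams()
    modal, gapfrac = _column_stats(msa)
    if params.gap_policy == NONE:
        gap_ok = gapfrac == 0.0
    elif params.gap_policy == HALF:
        gap_ok = gapfrac <= 0.5
    else:
        gap_ok = np.ones_like(gapfrac, dtype=bool)
    conserved = (modal >= params.min_conserved_frac) & gap_ok
    flank_ok = (modal >= params.min_flank_frac) & gap_ok

    m = msa.n_cols
    # split at runs of > max_nonconserved_run consecutive non-conserved columns
    segments: list[tuple[int, int]] = []
    start = 0
    j = 0
    while j < m:
        if not conserved[j]:
            run_start = j
            while j < m and not conserved[j]:
                j += 1
            if j - run_start > params.max_nonconserved_run:
                if run_start > start:
                    segments.append((start, run_start))
                start = j
        else:
            j += 1
    if start < m:
        segments.append((start, m))

    blocks: list[tuple[int, int]] = []
    kept: list[int] = []
    for s, e in segments:
        while s < e and not flank_ok[s]:
            s += 1
        while e > s and not flank_ok[e - 1]:
            e -= 1
        # gap-policy-violating columns are dropped even inside a block;
        # the remaining runs must still satisfy the length threshold
        run: list[int] = []
        for j in list(range(s, e)) + [None]:
            if j is not None and gap_ok[j]:
                run.append(j)
                continue
            if len(run) >= params.min_block_length:
                blocks.append((run[0] + 1, run[-1] + 1))  # 1-based inclusive
                kept.extend(run)
            run = []
    return BlockSelection(kept_columns=kept, blocks=blocks, parameters=params)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

P_DIST, POISSON = "p", "poisson"


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray  # symmetric, zero diagonal, non-negative

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise DataError("distance matrix shape mismatch")
        if not np.allclose(v, v.T) or (np.diag(v) != 0).any() or (v < 0).any():
            raise DataError("distances must be symmetric, non-negative, zero diagonal")

    def submatrix(self, keep: Sequence[str]) -> "DistanceMatrix":
        idx = [self.ids.index(k) for k in keep]
        return DistanceMatrix(list(keep), self.values[np.ix_(idx, idx)])


def distance_matrix(
    msa: MSA, selection: Optional[BlockSelection] = None, correction: str = POISSON
) -> DistanceMatrix:
    """Pairwise p-distance over kept, mutually ungapped columns, optionally
    Poisson-corrected (d = -ln(1-p)). Saturated pairs (p -> 1) are clamped
    to p = 1 - 1/(2 * comparable columns) before correction."""
    if len(msa.ids) < 2:
        raise DataError("need at least 2 sequences")
    if correction not in (P_DIST, POISSON):
        raise DataError(f"unknown correction {correction!r}")
    cols = selection.kept_columns if selection is not None else list(range(msa.n_cols))
    if not cols:
        raise DataError("no kept columns")
    arr = np.array([list(r) for r in msa.rows])[:, cols]
    n = len(msa.ids)
    d = np.zeros((n, n))
    nongap = arr != GAP
    for i in range(n):
        for j in range(i + 1, n):
            both = nongap[i] & nongap[j]
            total = int(both.sum())
            if total == 0:
                raise DataError(
                    f"no comparable columns between {msa.ids[i]!r} and {msa.ids[j]!r}"
                )
            p = float((arr[i, both] != arr[j, both]).sum()) / total
            if correction == POISSON:
                p = min(p, 1.0 - 1.0 / (2 * total))
                dist = -np.log(1.0 - p)
            else:
                dist = p
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(list(msa.ids), d)


# ---------------------------------------------------------------------------
# neighbour joining
# ---------------------------------------------------------------------------

@dataclass
class SupportTree:
    """Leaf-labelled tree with branch lengths and optional split supports.

    Stored rooted at a trifurcation; semantics are unrooted. Supports are
    bootstrap proportions in [0, 1], keyed by the canonical split (the side
    not containing the alphabetically first leaf).
    """

    tree: TreeNode
    supports: dict[frozenset, float] = field(default_factory=dict)

    @property
    def leaves(self) -> frozenset:
        return frozenset(t.name for t in self.tree.tips())

    def splits(self) -> set[frozenset]:
        """Non-trivial splits, canonical side excluding the reference leaf."""
        ref = min(self.leaves)
        out: set[frozenset] = set()
        nleaves = len(self.leaves)
        for node in self.tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if ref in side:
                side = self.leaves - side
            if 2 <= len(side) <= nleaves - 2:
                out.add(side)
        return out

    def to_newick(self, path=None) -> str:
        t = self.tree.copy()
        ref = min(self.leaves)
        for node in t.non_tips(include_self=False):
            side = frozenset(x.name for x in node.tips())
            if ref in side:
                side = self.leaves - side
            if side in self.supports:
                node.name = f"{self.supports[side]:.3f}"
        s = str(t)
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_newick(cls, source) -> "SupportTree":
        """Adapter for externally computed trees; numeric internal labels are
        read as supports."""
        text = str(source)
        handle = StringIO(text if ("(" in text and ";" in text) else Path(source).read_text())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tree = TreeNode.read(handle, format="newick")
        st = cls(tree=tree)
        for node in tree.non_tips(include_self=False):
            if node.name:
                try:
                    val = float(node.name)
                except ValueError:
                    continue
                side = frozenset(t.name for t in node.tips())
                ref = min(st.leaves)
                if ref in side:
                    side = st.leaves - side
                if 0.0 <= val <= 1.0:
                    st.supports[side] = val
        return st


def nj_tree(d: DistanceMatrix) -> SupportTree:
    """Deterministic neighbour joining.

    Ties in the Q criterion are broken by the smallest (label_i, label_j)
    pair, labels being the alphabetically first leaf of each cluster.
    Negative limb lengths are clamped to zero with the deficit moved to the
    sibling limb.
    """
    n0 = len(d.ids)
    if n0 < 3:
        raise DataError("neighbour joining needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=i) for i in d.ids]
    labels: list[str] = list(d.ids)  # canonical smallest-leaf label per cluster
    D = d.values.astype(float).copy()
    active = list(range(n0))

    while len(active) > 3:
        n = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (n - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = np.argwhere(Q <= qmin + 1e-10)
        best = min(
            (tuple(sorted((labels[active[i]], labels[active[j]]))), i, j)
            for i, j in cand
            if i < j
        )
        _, i, j = best
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (n - 2))
        lj = dij - li
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        child_i, child_j = nodes[ai], nodes[aj]
        child_i.length = float(li)
        child_j.length = float(lj)
        parent = TreeNode(children=[child_i, child_j])
        # distances from the new cluster to the rest
        new_d = 0.5 * (D[ai, active] + D[aj, active] - dij)
        D[ai, active] = new_d
        D[active, ai] = new_d
        D[ai, ai] = 0.0
        nodes[ai] = parent
        labels[ai] = min(labels[ai], labels[aj])
        active.pop(j)

    # final three clusters joined at a trifurcating root (three-point formulas)
    a, b, c = active
    dab, dac, dbc = D[a, b], D[a, c], D[b, c]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    limbs = [la, lb, lc]
    for k in range(3):
        if limbs[k] < 0:
            # move the deficit onto the other two limbs equally
            for other in range(3):
                if other != k:
                    limbs[other] += -limbs[k] / 2
            limbs[k] = 0.0
    for idx, limb in zip((a, b, c), limbs):
        nodes[idx].length = float(max(limb, 0.0))
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    return SupportTree(tree=root)


def bootstrap_support(
    msa: MSA,
    selection: Optional[BlockSelection] = None,
    n_replicates: int = 100,
    seed: int = 0,
    correction: str = POISSON,
) -> SupportTree:
    """NJ tree with bootstrap supports from resampling kept columns."""
    if n_replicates < 1:
        raise DataError("n_replicates must be >= 1")
    cols = selection.kept_columns if selection is not None else list(range(msa.n_cols))
    full = nj_tree(distance_matrix(msa, selection, correction))
    target_splits = full.splits()
    counts = {s: 0 for s in target_splits}
    rng = np.random.default_rng(seed)
    done = 0
    for _ in range(n_replicates):
        resampled = rng.choice(cols, size=len(cols), replace=True)
        sub = MSA(list(msa.ids), ["".join(row[k] for k in resampled) for row in msa.rows])
        try:
            rep = nj_tree(distance_matrix(sub, None, correction))
        except DataError:
            continue  # replicate with an incomparable pair carries no signal
        rep_splits = rep.splits()
        for s in target_splits:
            if s in rep_splits:
                counts[s] += 1
        done += 1
    denom = max(done, 1)
    full.supports = {s: counts[s] / denom for s in target_splits}
    return full


# ---------------------------------------------------------------------------
# orthogroup monophyly
# ---------------------------------------------------------------------------

def check_og_monophyly(tree: SupportTree, labels: dict[str, str]) -> dict[str, dict]:
    """Per-OG report: leaves of an OG must form a clade on the unrooted tree.

    Returns ``{og: {"status": "consistent"|"split", "offending": [...]}}``;
    offending leaves are the minimal symmetric difference against the best
    matching split side.
    """
    leaves = tree.leaves
    unlabeled = leaves - set(labels)
    if unlabeled:
        raise DataError(f"unlabeled leaves: {sorted(unlabeled)[:5]}")
    by_og: dict[str, set] = {}
    for leaf in leaves:
        by_og.setdefault(labels[leaf], set()).add(leaf)

    # candidate clade sides: every edge of the unrooted tree, both orientations
    sides: list[frozenset] = []
    for node in tree.tree.traverse(include_self=False):
        s = _leafset(node)
        sides.append(s)
        sides.append(frozenset(leaves - s))
    report: dict[str, dict] = {}
    for og, members in sorted(by_og.items()):
        fm = frozenset(members)
        if len(fm) <= 1 or len(fm) == len(leaves) or fm in sides:
            report[og] = {"status": "consistent", "offending": []}
            continue
        best = min(sides, key=lambda s: (len(s ^ fm), tuple(sorted(s ^ fm))))
        report[og] = {"status": "split", "offending": sorted(best ^ fm)}
    return report


# ---------------------------------------------------------------------------
# long-branch probe
# ---------------------------------------------------------------------------

def _placement(tree: SupportTree, focal: str) -> frozenset:
    """Unrooted placement of a leaf: the set of leaf sets of the subtrees
    adjacent to its attachment node."""
    leaves = tree.leaves
    tip = next(t for t in tree.tree.tips() if t.name == focal)
    parent = tip.parent
    sets: list[frozenset] = []
    below = frozenset()
    for child in parent.children:
        if child is tip:
            continue
        s = _leafset(child)
        sets.append(s)
        below = below | s
    up = leaves - below - {focal}
    if up:
        sets.append(frozenset(up))
    return frozenset(sets)


def _sister_group(tree: SupportTree, focal: str) -> frozenset:
    """Leaf set of the focal leaf's smallest adjacent subtree (unrooted)."""
    return min(_placement(tree, focal), key=lambda s: (len(s), tuple(sorted(s))))


@dataclass
class LbaReport:
    focal_id: str
    removed_id: str
    placement_full: frozenset
    placement_without_partner: frozenset
    lba_flag: bool


def lba_probe(
    msa: MSA,
    focal_id: str,
    params: Optional[BlockParams] = None,
    correction: str = POISSON,
) -> LbaReport:
    """Leave-one-out probe: rebuild the tree without the longest-branch
    partner of the focal sequence and flag the focal placement as a likely
    LBA artifact when its sister group changes."""
    if focal_id not in msa.ids:
        raise DataError(f"focal {focal_id!r} not in alignment")
    if len(msa.ids) < 4:
        raise DataError("need at least 4 taxa")
    sel = select_blocks(msa, params)
    full = nj_tree(distance_matrix(msa, sel, correction))
    # longest terminal branch among the other leaves
    partner, length = None, -1.0
    for t in sorted(full.tree.tips(), key=lambda t: t.name):
        if t.name == focal_id:
            continue
        tl = t.length or 0.0
        if tl > length:
            partner, length = t.name, tl
    if len(msa.ids) - 1 < 4:
        raise DataError("removal would leave fewer than 4 taxa")
    reduced_msa = msa.drop(partner)
    sel2 = select_blocks(reduced_msa, params)
    reduced = nj_tree(distance_matrix(reduced_msa, sel2, correction))
    place_full = frozenset(
        s - {partner} for s in _placement(full, focal_id) if s - {partner}
    )
    place_reduced = _placement(reduced, focal_id)
    return LbaReport(
        focal_id=focal_id,
        removed_id=partner,
        placement_full=place_full,
        placement_without_partner=place_reduced,
        lba_flag=place_full != place_reduced,
    )
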