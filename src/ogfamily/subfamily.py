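"""Grouping orthogroups into subfamilies and applying the naming scheme.

A subfamily is a higher classification rank: one or more orthogroups whose
representatives cluster together on a representative tree under a support
and depth criterion. Naming follows the convention of curated gene-family
studies: each subfamily takes the name of its first-described member gene;
orthogroups inside a multi-OG subfamily are distinguished by a hyphen and a
number (``OG-SCR-1``), while a subfamily with a single orthogroup keeps the
bare name (``OG-DLT``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .datamodel import DataError, ProteinRecord
from .blocks_phylo import DistanceMatrix, SupportTree, nj_tree
from .matrix_losses import subfamily_prefix
from .orthogroup import Orthogroup
from .pairalign import ScoringScheme, align_global


@dataclass
class SubfamilyMap:
    subfamily_of: dict[str, str]  # og_id -> subfamily label
    members: dict[str, list[str]]  # label -> ordered og ids
    provenance: dict[str, str] = field(default_factory=dict)

    def n_subfamilies(self) -> int:
        return len(self.members)

    def n_multi(self) -> int:
        return sum(1 for m in self.members.values() if len(m) > 1)


# ---------------------------------------------------------------------------
# representatives and the representative tree
# ---------------------------------------------------------------------------

def _poisson_from_alignment(a: str, b: str, scheme: ScoringScheme) -> float:
    res = align_global(a, b, scheme)
    compared = ident = 0
    for x, y in zip(res.aligned_a, res.aligned_b):
        if x == "-" or y == "-":
            continue
        compared += 1
        if x == y:
            ident += 1
    if compared == 0:
        return 5.0
    p = 1.0 - ident / compared
    p = min(p, 1.0 - 1.0 / (2 * compared))
    return -float(np.log(1.0 - p))


def choose_representatives(
    ogs: Sequence[Orthogroup],
    records: Sequence[ProteinRecord],
    scheme: Optional[ScoringScheme] = None,
) -> dict[str, str]:
    """One representative gene per OG: smallest mean distance to the other
    members (ties by gene id)."""
    scheme = scheme or ScoringScheme.blosum62()
    by_id = {r.id: r for r in records}
    reps: dict[str, str] = {}
    for og in ogs:
        members = sorted(og.all_members)
        missing = [m for m in members if m not in by_id]
        if missing:
            raise DataError(f"{og.og_id}: no record for members {missing[:3]}")
        if len(members) == 1:
            reps[og.og_id] = members[0]
            continue
        seqs = {m: by_id[m].sequence for m in members}
        d = np.zeros((len(members), len(members)))
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                d[i, j] = d[j, i] = _poisson_from_alignment(
                    seqs[members[i]], seqs[members[j]], scheme)
        reps[og.og_id] = members[int(np.argmin(d.mean(axis=1)))]
    return reps


def representative_tree(
    ogs: Sequence[Orthogroup],
    records: Sequence[ProteinRecord],
    scheme: Optional[ScoringScheme] = None,
) -> SupportTree:
    """NJ tree over OG representatives (leaves named by og_id), from
    Poisson-corrected global-alignment distances."""
    scheme = scheme or ScoringScheme.blosum62()
    reps = choose_representatives(ogs, records, scheme)
    by_id = {r.id: r for r in records}
    og_ids = sorted(reps)
    if len(og_ids) < 3:
        raise DataError("need at least 3 orthogroups for a representative tree")
    n = len(og_ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _poisson_from_alignment(
                by_id[reps[og_ids[i]]].sequence,
                by_id[reps[og_ids[j]]].sequence, scheme)
    return nj_tree(DistanceMatrix(og_ids, d))


# ---------------------------------------------------------------------------
# grouping
# ---------------------------------------------------------------------------

def group_subfamilies(
    og_tree: SupportTree,
    support_min: float = 0.9,
    depth_max: Optional[float] = None,
) -> SubfamilyMap:
    """Maximal supported, shallow clades of the representative tree become
    multi-OG subfamilies; remaining OGs are singleton subfamilies.

    A clade qualifies when its split support is at least ``support_min``
    (splits without a support value count as supported) and its diameter
    (largest within-clade path length) is at most ``depth_max``. The default
    ``depth_max`` is 0.7x the median pairwise representative distance: the
    distance distribution is bimodal (shallow within-subfamily pairs versus
    the deep between-subfamily background, which dominates the median), and
    0.7 of the background median falls in the gap between the two modes.
    """
    leaves = og_tree.leaves
    tipdist = og_tree.tree.tip_tip_distances()
    ids = list(tipdist.ids)
    dm = np.asarray(tipdist.data)
    pos = {name: k for k, name in enumerate(ids)}
    if depth_max is None:
        tri = dm[np.triu_indices(len(ids), k=1)]
        depth_max = 0.7 * float(np.median(tri))
    ref = min(leaves)

    def diameter(names: frozenset) -> float:
        idx = [pos[n] for n in names]
        return float(dm[np.ix_(idx, idx)].max())

    def supported(names: frozenset) -> bool:
        side = names if ref not in names else leaves - names
        if side not in og_tree.supports:
            return True
        return og_tree.supports[side] >= support_min

    groups: list[list[str]] = []
    grouped: set[str] = set()

    def walk(node) -> None:
        if node.is_tip():
            return
        names = frozenset(t.name for t in node.tips())
        if (
            2 <= len(names) < len(leaves)
            and supported(names)
            and diameter(names) <= depth_max
        ):
            groups.append(sorted(names))
            grouped.update(names)
            return
        for child in node.children:
            walk(child)

    walk(og_tree.tree)
    subfamily_of: dict[str, str] = {}
    members: dict[str, list[str]] = {}
    for k, group in enumerate(sorted(groups), start=1):
        label = f"SF{k:02d}"
        members[label] = group
        for og in group:
            subfamily_of[og] = label
    for og in sorted(leaves - grouped):
        label = f"SF{len(members) + 1:02d}"
        members[label] = [og]
        subfamily_of[og] = label
    return SubfamilyMap(subfamily_of=subfamily_of, members=members)


def assign_names(
    smap: SubfamilyMap,
    seed_names: dict[str, str],
    og_sizes: Optional[dict[str, int]] = None,
    pinned: Optional[dict[str, str]] = None,
) -> dict[str, str]:
    """Final OG labels from subfamily base names.

    Singleton subfamilies: ``OG-<base>``. Multi-OG subfamilies:
    ``OG-<base>-1``, ``-2``, ... ordered by descending gene count then by
    smallest member gene id (og id as fallback). ``pinned`` may fix labels
    for specific og ids outright (reproducing published numbering).
    """
    bases = list(seed_names.values())
    if len(set(bases)) != len(bases):
        raise DataError("duplicate base labels in seed names")
    out: dict[str, str] = {}
    for label, group in smap.members.items():
        if label not in seed_names:
            raise DataError(f"no seed name for subfamily {label!r}")
        base = seed_names[label]
        if len(group) == 1:
            out[group[0]] = f"OG-{base}"
            continue
        sizes = og_sizes or {}
        ordered = sorted(group, key=lambda og: (-sizes.get(og, 0), og))
        for k, og in enumerate(ordered, start=1):
            out[og] = f"OG-{base}-{k}"
    if pinned:
        for og, label in pinned.items():
            if og not in out:
                raise DataError(f"pinned label for unknown og {og!r}")
            out[og] = label
    return out


def subfamilies_from_labels(og_ids: Sequence[str]) -> SubfamilyMap:
    """Regroup published-style OG labels by stripping numbering suffixes."""
    members: dict[str, list[str]] = {}
    for og in og_ids:
        members.setdefault(subfamily_prefix(og), []).append(og)
    subfamily_of = {og: sf for sf, ogs in members.items() for og in ogs}
    return SubfamilyMap(subfamily_of=subfamily_of, members=members)


def write_subfamilies(smap: SubfamilyMap, names: Optional[dict[str, str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("og_id\tsubfamily\trank\n")
        for label in sorted(smap.members):
            for k, og in enumerate(smap.members[label], start=1):
                final = names.get(og, og) if names else og
                fh.write(f"{final}\t{label}\t{k}\n")
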