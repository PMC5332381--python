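"""Orthogroup inference anchored at the monocot/dicot split.

An orthogroup (OG) is the set of genes descended from one ancestral gene
present at the reference speciation event, here the split between monocots
and dicots. The procedure approximates a curated reciprocal-best-hit
workflow:

1. cross-species reciprocal best hits (RBH) among non-basal species are
   collected and their connected components form OG cores;
2. unplaced genes are absorbed as in-paralogs when they score close enough
   to an OG core (``in_paralog_ratio`` of the core's median cross-species
   score);
3. genes of the basal outgroup species attach to the OG of their top
   non-basal hit when reciprocity holds against at least one member, and
   otherwise stay unassigned (outgroup-specific genes);
4. a manual-overrides table is honoured last, so a published curated
   assignment can be reproduced exactly.

Pseudogene and remnant records never seed cores but may be attached.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import BASAL, DataError, ProteinRecord, SpeciesRegistry, VALID
from .pairalign import Hit, ScoringScheme, all_pairs_scores, rank_hits

UNASSIGNED = "unassigned"


@dataclass
class OrthogroupParams:
    """Tunable thresholds of the inference and the diagnostic classifier."""

    in_paralog_ratio: float = 0.8
    #: minimum winning margin for classify_query, as a fraction of the top score
    min_margin_frac: float = 0.05
    #: reciprocity window k: query must rank within the top k hits of its best
    #: reference partner (self-hit included)
    reciprocity_window: int = 3
    #: RBH edges are screened per species pair: since all orthologs of a given
    #: species pair diverged at the same speciation, their self-normalised
    #: scores cluster tightly; an edge below this fraction of the species-pair
    #: median is a likely pre-split (cross-OG) link and is dropped, unless it
    #: is an endpoint's only edge
    rbh_relative_min: float = 0.85
    #: a core whose genes' best external hits point consistently at another
    #: core is a post-split duplication clique and merges into it when the
    #: median normalised score of those hits reaches this fraction of the
    #: species-pair median
    core_merge_relative_min: float = 0.80
    #: fraction of a core's genes that must point at the same target core
    core_merge_majority: float = 0.5


class HitTable:
    """Per-gene ranked hit lists plus a pairwise score lookup."""

    def __init__(self, hits: dict[str, list[Hit]], species: dict[str, str]):
        self.hits = hits
        self.species = species
        for q, lst in hits.items():
            for h in lst:
                if h.target not in species:
                    raise DataError(f"hit target {h.target!r} is not a known record")
        self._score = {
            (q, h.target): h.score for q, lst in hits.items() for h in lst
        }

    @classmethod
    def from_records(
        cls,
        records: Sequence[ProteinRecord],
        scheme: ScoringScheme,
        scores: Optional[pd.DataFrame] = None,
    ) -> "HitTable":
        """Build the all-vs-all hit table with the internal aligner.

        ``scores`` may carry a precomputed symmetric score matrix
        (:func:`ogfamily.pairalign.all_pairs_scores`).
        """
        if scores is None:
            scores = all_pairs_scores(records, scheme)
        species = {r.id: r.species for r in records}
        hits: dict[str, list[Hit]] = {}
        for r in records:
            row = scores.loc[r.id]
            lst = [Hit(t, species[t], float(row[t])) for t in scores.columns]
            lst.sort(key=lambda h: (-h.score, h.target))
            hits[r.id] = lst
        return cls(hits, species)

    @classmethod
    def from_blast_tab(cls, table: pd.DataFrame, records: Sequence[ProteinRecord]) -> "HitTable":
        """Adapt imported BLAST tabular hits to the hit-list contract."""
        species = {r.id: r.species for r in records}
        hits: dict[str, list[Hit]] = {r.id: [] for r in records}
        for row in table.itertuples(index=False):
            if row.qseqid not in species:
                raise DataError(f"unknown query {row.qseqid!r} in BLAST table")
            hits[row.qseqid].append(Hit(row.target, species[row.target], float(row.score)))
        for lst in hits.values():
            lst.sort(key=lambda h: (-h.score, h.target))
        return cls(hits, species)

    def score(self, a: str, b: str) -> float:
        return self._score[(a, b)]

    def best_in_species(self, query: str, target_species: str) -> Optional[Hit]:
        """Top hit of ``query`` among genes of ``target_species`` (no self-hit)."""
        for h in self.hits[query]:
            if h.species == target_species and h.target != query:
                return h
        return None

    def top_cross_species(self, query: str, exclude_species: Iterable[str] = ()) -> Optional[Hit]:
        excl = set(exclude_species) | {self.species[query]}
        for h in self.hits[query]:
            if h.species not in excl:
                return h
        return None


@dataclass
class Orthogroup:
    og_id: str
    members: set[str] = field(default_factory=set)
    anchor: str = "monocot-dicot"
    outgroup_members: set[str] = field(default_factory=set)
    provenance: dict[str, str] = field(default_factory=dict)  # member -> join reason

    @property
    def all_members(self) -> set[str]:
        return self.members | self.outgroup_members


@dataclass
class ClassificationResult:
    query_id: str
    og_id: str  # OG label or "unassigned"
    best_score: float
    margin: float
    reciprocal_ok: bool


# ---------------------------------------------------------------------------

def reciprocal_best_pairs(hits: HitTable) -> set[frozenset]:
    """Cross-species pairs that are mutually each other's top hit."""
    pairs: set[frozenset] = set()
    for a in hits.hits:
        sa = hits.species[a]
        for sb in {h.species for h in hits.hits[a]} - {sa}:
            best = hits.best_in_species(a, sb)
            if best is None:
                continue
            back = hits.best_in_species(best.target, sa)
            if back is not None and back.target == a:
                pairs.add(frozenset((a, best.target)))
    return pairs


class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic root: lexicographically smallest id
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


def build_orthogroups(
    records: Sequence[ProteinRecord],
    hits: HitTable,
    registry: SpeciesRegistry,
    params: Optional[OrthogroupParams] = None,
    manual_overrides: Optional[dict[str, str]] = None,
) -> tuple[list[Orthogroup], list[str]]:
    """Infer orthogroups; returns (orthogroups, unassigned gene ids)."""
    if not records:
        raise DataError("empty record set")
    params = params or OrthogroupParams()
    lineages = {registry.lineage(r.species) for r in records}
    if not ({"monocot", "dicot"} <= lineages):
        raise DataError("records must cover both sides of the monocot/dicot split")

    by_id = {r.id: r for r in records}
    seed_ok = {
        r.id
        for r in records
        if r.status == VALID and registry.lineage(r.species) != BASAL
    }
    basal_ids = sorted(r.id for r in records if registry.lineage(r.species) == BASAL)

    # 1. RBH edges among non-basal, valid-status genes, screened per species
    # pair: orthologous pairs of one species pair share one divergence time,
    # so their self-normalised scores cluster; clear low outliers are
    # pre-split links between different OGs of one subfamily.
    pairs = reciprocal_best_pairs(hits)
    edges = sorted(tuple(sorted(p)) for p in pairs if all(x in seed_ok for x in p))
    selfscore = {g: hits.score(g, g) for g in hits.hits}

    def norm_score(a: str, b: str) -> float:
        return hits.score(a, b) / min(selfscore[a], selfscore[b])

    pair_median: dict[tuple, float] = {}
    by_species_pair: dict[tuple, list[tuple]] = {}
    for e in edges:
        key = tuple(sorted((hits.species[e[0]], hits.species[e[1]])))
        by_species_pair.setdefault(key, []).append(e)
    for key, lst in by_species_pair.items():
        pair_median[key] = float(np.median([norm_score(*e) for e in lst]))

    def rel_score(a: str, b: str) -> float:
        key = tuple(sorted((hits.species[a], hits.species[b])))
        med = pair_median.get(key, 0.0)
        return norm_score(a, b) / med if med > 0 else 0.0

    degree: dict[str, int] = {}
    for a, b in edges:
        degree[a] = degree.get(a, 0) + 1
        degree[b] = degree.get(b, 0) + 1
    kept_edges = [
        e for e in edges
        if rel_score(*e) >= params.rbh_relative_min
        or degree[e[0]] == 1 or degree[e[1]] == 1
    ]

    uf = _UnionFind(seed_ok)
    core_ids = set()
    for a, b in kept_edges:
        uf.union(a, b)
        core_ids.update((a, b))
    assignment: dict[str, str] = {g: uf.find(g) for g in core_ids}
    provenance: dict[str, str] = {g: "rbh" for g in core_ids}

    def members_of(root: str) -> list[str]:
        return sorted(g for g, r in assignment.items() if r == root)

    # 1b. merge post-split duplication cliques: a duplication after the
    # monocot/dicot split (e.g. on the monocot stem) yields a separate RBH
    # clique that belongs, by the OG definition, to its parent core.
    changed = True
    while changed:
        changed = False
        cores = {}
        for g, root in assignment.items():
            cores.setdefault(root, []).append(g)
        order = sorted(cores, key=lambda r: (len(cores[r]), r))
        for root in order:
            members = sorted(cores[root])
            covered = {hits.species[g] for g in members}
            votes: dict[str, list[float]] = {}
            for g in members:
                # the informative hits are in species the core does not
                # reach: a post-split duplication clique points at its
                # parent core there with ortholog-level scores, while a
                # genuine neighbouring OG scores at pre-split level
                for h in hits.hits[g]:
                    if h.target == g or h.species in covered:
                        continue
                    tgt_root = assignment.get(h.target)
                    if tgt_root is None or tgt_root == root:
                        continue
                    votes.setdefault(tgt_root, []).append(rel_score(g, h.target))
                    break
            if not votes:
                continue
            target = max(votes, key=lambda r: (len(votes[r]), len(cores[r]), r))
            if (
                len(votes[target]) >= params.core_merge_majority * len(members)
                and float(np.median(votes[target])) >= params.core_merge_relative_min
                and len(cores[target]) >= len(members)
            ):
                for g in members:
                    assignment[g] = target
                changed = True
                break

    # median cross-species score within each core (absorption yardstick)
    core_members: dict[str, list[str]] = {}
    for g, root in assignment.items():
        core_members.setdefault(root, []).append(g)
    core_median: dict[str, float] = {}
    for root, members in core_members.items():
        scores = [
            hits.score(a, b)
            for i, a in enumerate(sorted(members))
            for b in sorted(members)[i + 1:]
            if hits.species[a] != hits.species[b]
        ]
        core_median[root] = float(pd.Series(scores).median()) if scores else 0.0

    # 2. in-paralog absorption (iterate to fixed point, deterministic order)
    non_basal = sorted(
        r.id for r in records if registry.lineage(r.species) != BASAL
    )
    changed = True
    while changed:
        changed = False
        for g in non_basal:
            if g in assignment:
                continue
            candidate = None
            for h in hits.hits[g]:
                if h.species != hits.species[g] and h.target in assignment:
                    candidate = h
                    break
            if candidate is None:
                continue
            root = assignment[candidate.target]
            if candidate.score >= params.in_paralog_ratio * core_median.get(root, 0.0):
                assignment[g] = root
                provenance[g] = "in-paralog"
                changed = True

    # 3. basal outgroup attachment by reciprocity against >= 1 member
    rbh_lookup = {frozenset(p) for p in pairs}
    for g in basal_ids:
        top = hits.top_cross_species(g)
        if top is None or top.target not in assignment:
            continue
        root = assignment[top.target]
        if any(frozenset((g, m)) in rbh_lookup for m in members_of(root)):
            assignment[g] = root
            provenance[g] = "outgroup-attach"

    # 3b. basal in-paralog absorption: an unplaced basal gene whose closest
    # same-species anchor is attached joins that anchor's OG when it sits
    # closer to the anchor than the anchor sits to the core (tandem copies
    # of an attached outgroup gene; isolated basal pairs stay unassigned)
    for g in basal_ids:
        if g in assignment:
            continue
        anchor = None
        for h in hits.hits[g]:
            if h.target != g and h.species == hits.species[g] and h.target in assignment:
                anchor = h
                break
        if anchor is None:
            continue
        root = assignment[anchor.target]
        core_scores = [
            hits.score(anchor.target, c)
            for c in members_of(root)
            if hits.species[c] != hits.species[g]
        ]
        if core_scores and anchor.score >= params.in_paralog_ratio * max(core_scores):
            assignment[g] = root
            provenance[g] = "in-paralog"

    # 4. manual overrides, honoured last
    manual_roots: dict[str, str] = {}
    if manual_overrides:
        for g, label in sorted(manual_overrides.items()):
            if g not in by_id:
                raise DataError(f"manual override for unknown gene {g!r}")
            assignment[g] = f"manual:{label}"
            provenance[g] = "manual"

    # deterministic labels: OGs ordered by smallest member id
    groups: dict[str, list[str]] = {}
    for g, root in assignment.items():
        groups.setdefault(root, []).append(g)
    ordered = sorted(groups.values(), key=lambda ms: min(ms))
    ogs: list[Orthogroup] = []
    for k, members in enumerate(ordered, start=1):
        og = Orthogroup(og_id=f"OG{k:03d}")
        for g in sorted(members):
            if registry.lineage(by_id[g].species) == BASAL:
                og.outgroup_members.add(g)
            else:
                og.members.add(g)
            og.provenance[g] = provenance[g]
        ogs.append(og)
        for g in members:
            by_id[g].og_id = og.og_id

    unassigned = sorted(
        r.id for r in records if r.id not in assignment and r.status == VALID
    )
    return ogs, unassigned


def classify_query(
    query: ProteinRecord,
    reference: Sequence[ProteinRecord],
    scheme: ScoringScheme,
    params: Optional[OrthogroupParams] = None,
    ref_scores: Optional[pd.DataFrame] = None,
) -> ClassificationResult:
    """Diagnostic classification of a novel sequence against a curated set.

    The query is assigned to the OG of its top-scoring reference hit when the
    margin over the best other-OG score is at least ``min_margin_frac`` of
    the top score and the query ranks within the top ``reciprocity_window``
    hits of that reference member (computed against reference + query).
    ``ref_scores`` may carry a precomputed reference all-vs-all matrix to
    speed up batch classification.
    """
    if not reference:
        raise DataError("empty reference set")
    if any(r.og_id is None for r in reference):
        raise DataError("every reference record must carry an og_id")
    params = params or OrthogroupParams()

    qhits = rank_hits(query, reference, scheme)
    best = qhits[0]
    og_of = {r.id: r.og_id for r in reference}
    best_og = og_of[best.target]
    other = [h for h in qhits if og_of[h.target] != best_og]
    best_other = other[0].score if other else 0.0
    margin = best.score - best_other

    # reciprocity: rank the best partner's hits over reference + query
    partner = next(r for r in reference if r.id == best.target)
    if ref_scores is not None:
        pre = {t: float(ref_scores.at[partner.id, t]) for t in ref_scores.columns}
    else:
        pre = None
    phits = rank_hits(partner, list(reference) + [query], scheme, precomputed=pre)
    topk = [h.target for h in phits[: params.reciprocity_window]]
    # a novel-species query in a large OG is legitimately outranked by the
    # partner's own orthologs, so ortholog-level similarity (relative to the
    # partner's best cross-species score) also satisfies reciprocity
    best_cross = max(
        (h.score for h in phits
         if h.target != query.id and h.species != partner.species),
        default=0.0,
    )
    qscore = next(h.score for h in phits if h.target == query.id)
    reciprocal_ok = (
        query.id in topk or qscore >= params.in_paralog_ratio * best_cross
    )

    assigned = reciprocal_ok and margin >= params.min_margin_frac * best.score and best.score > 0
    return ClassificationResult(
        query_id=query.id,
        og_id=best_og if assigned else UNASSIGNED,
        best_score=best.score,
        margin=max(margin, 0.0),
        reciprocal_ok=reciprocal_ok,
    )


def write_assignments(ogs: Sequence[Orthogroup], records: Sequence[ProteinRecord], path) -> None:
    """OG assignments as TSV (gene, species, og_id, provenance)."""
    species = {r.id: r.species for r in records}
    with open(path, "w") as fh:
        fh.write("gene\tspecies\tog_id\tprovenance\n")
        for og in ogs:
            for g in sorted(og.all_members):
                fh.write(f"{g}\t{species[g]}\t{og.og_id}\t{og.provenance[g]}\n")


def read_manual_overrides(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    return dict(zip(df[0], df[1]))
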