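"""Orthogroup x species count matrix, summaries and lineage-loss calls.

The matrix mirrors the printed layout of the curated GRAS study: one row
per orthogroup, one column per species, remnant gene copies flagged with an
asterisk, and outgroup-specific rows (basal-species genes outside every
orthogroup) kept in the table but excluded from orthogroup-level counting.

Loss calls are made against the taxonomy: for every orthogroup, each
maximal clade whose sampled species all lack the gene (no count, no
remnant) is reported. A declarative wider-taxon evidence table (from
database searches beyond the sampled panel) can lift a call to a wider
clade or restrict it to a narrower one when presence is attested in a
sister lineage.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .datamodel import (
    CountMatrix,
    DataError,
    ProteinRecord,
    REMNANT,
    SpeciesRegistry,
    TaxonomyTree,
    VALID,
)
from .orthogroup import Orthogroup

#: trailing OG-number suffix: hyphen + integer or hyphen + Roman numeral
_SUFFIX_RE = re.compile(r"-(\d+|[IVXLC]+)$")


def subfamily_prefix(og_id: str) -> str:
    """Strip a trailing ``-<number>`` / ``-<roman>`` suffix from an OG label."""
    return _SUFFIX_RE.sub("", og_id)


@dataclass
class MatrixSummary:
    per_species_totals: dict[str, int]
    per_og_totals: dict[str, int]
    grand_total: int
    mean_genes_per_species: float
    mean_genes_per_species_rounded: int
    largest_og: tuple[str, int]
    n_og_rows: int
    n_subfamilies: int
    n_multi_og_subfamilies: int


@dataclass
class LossCall:
    og_id: str
    clade: str  # taxonomy clade label or single species code
    evidence_level: str  # "sampled-only" | "wider-taxon"
    note: str = ""


# ---------------------------------------------------------------------------

def build_matrix(
    ogs: Sequence[Orthogroup],
    registry: SpeciesRegistry,
    records: Optional[Sequence[ProteinRecord]] = None,
    outgroup_specific: Iterable[str] = (),
) -> CountMatrix:
    """Count valid-status members per (og, species); propagate remnant flags.

    ``records`` supplies per-gene status; without it all members count as
    valid. ``outgroup_specific`` declares extra rows (label -> handled by
    the caller via a pre-built matrix) kept outside OG-level statistics.
    """
    status = {r.id: r.status for r in records} if records else {}
    species_of = {r.id: r.species for r in records} if records else {}
    rows = []
    remnant_rows = []
    labels = []
    for og in ogs:
        counts = {sp: 0 for sp in registry.codes}
        remnant = {sp: False for sp in registry.codes}
        for g in sorted(og.all_members):
            sp = species_of.get(g)
            if sp is None:
                raise DataError(f"no record supplied for member {g!r}")
            st = status.get(g, VALID)
            if st == VALID:
                counts[sp] += 1
            elif st == REMNANT:
                remnant[sp] = True
            # pseudogenes neither count nor flag
        labels.append(og.og_id)
        rows.append(counts)
        remnant_rows.append(remnant)
    counts_df = pd.DataFrame(rows, index=labels, columns=registry.codes).fillna(0)
    remnant_df = pd.DataFrame(remnant_rows, index=labels, columns=registry.codes).fillna(False)
    return CountMatrix(counts_df, remnant_df, outgroup_specific_rows=outgroup_specific)


def summarize(matrix: CountMatrix) -> MatrixSummary:
    """Summary statistics; OG-row statistics exclude outgroup-specific rows,
    species totals include their genes."""
    counts = matrix.counts
    per_species = counts.sum(axis=0).to_dict()
    per_og = counts.sum(axis=1).to_dict()
    grand = int(counts.to_numpy().sum())
    og_rows = matrix.og_ids
    n_species = len(matrix.species)
    mean = grand / n_species if n_species else 0.0
    if og_rows:
        og_totals = {og: int(per_og[og]) for og in og_rows}
        largest = max(og_totals.items(), key=lambda kv: (kv[1], kv[0]))
    else:
        largest = ("", 0)
    prefixes = [subfamily_prefix(og) for og in og_rows]
    from collections import Counter

    pref_counts = Counter(prefixes)
    return MatrixSummary(
        per_species_totals={k: int(v) for k, v in per_species.items()},
        per_og_totals={k: int(v) for k, v in per_og.items()},
        grand_total=grand,
        mean_genes_per_species=mean,
        mean_genes_per_species_rounded=round(mean),
        largest_og=largest,
        n_og_rows=len(og_rows),
        n_subfamilies=len(pref_counts),
        n_multi_og_subfamilies=sum(1 for v in pref_counts.values() if v > 1),
    )


def missing_og_count(
    matrix: CountMatrix, species: str, taxonomy: Optional[TaxonomyTree] = None
) -> int:
    """Number of OG rows with neither a gene model nor a remnant in species.

    Without a taxonomy this is the plain per-column count of empty,
    unflagged OG rows. With a taxonomy, losses are attributed to their
    maximal absent clade first and only losses proper to this species are
    counted: an absence that extends across a deeper clade (e.g. a
    monocot-wide loss also emptying the rice column) is attributed to that
    deeper clade, not to the species. The latter is how per-species loss
    counts are usually reported alongside clade-level loss calls.
    """
    if species not in matrix.counts.columns:
        raise DataError(f"unknown species {species!r}")
    n = 0
    for og in matrix.og_ids:
        if matrix.counts.at[og, species] == 0 and not matrix.remnant.at[og, species]:
            if taxonomy is None:
                n += 1
                continue
            sampled = set(matrix.species)
            for clade in _maximal_absent_clades(matrix, taxonomy, og):
                leaves = taxonomy.leafset(clade) if clade in taxonomy else frozenset({clade})
                if species in leaves and leaves & sampled == {species}:
                    n += 1
                    break
    return n


# ---------------------------------------------------------------------------
# lineage-loss calling
# ---------------------------------------------------------------------------

def _maximal_absent_clades(
    matrix: CountMatrix, taxonomy: TaxonomyTree, og: str
) -> list[str]:
    """Maximal taxonomy clades whose sampled species all lack ``og``."""
    sampled = set(matrix.species)

    def absent(leafset: frozenset[str]) -> Optional[bool]:
        inside = leafset & sampled
        if not inside:
            return None  # no information
        return all(not matrix.present(og, sp) for sp in inside)

    calls: list[str] = []

    def walk(node) -> None:
        if node.is_tip():
            if node.name in sampled and not matrix.present(og, node.name):
                calls.append(node.name)
            return
        leafset = frozenset(t.name for t in node.tips())
        state = absent(leafset)
        if state is None:
            return
        if state is True:
            # maximal absent clade: emit at the nearest named node, walking
            # down unary chains; an unnamed multifurcation splits the call
            n = node
            while not n.is_tip() and not n.name and len(n.children) == 1:
                n = n.children[0]
            if n.name:
                calls.append(n.name)
            else:
                for child in n.children:
                    walk(child)
            return
        for child in node.children:
            walk(child)

    walk(taxonomy.tree)
    return calls


def call_losses(
    matrix: CountMatrix,
    taxonomy: TaxonomyTree,
    evidence: Optional[pd.DataFrame] = None,
) -> list[LossCall]:
    """Call lineage-level losses for every orthogroup row.

    ``evidence`` is a frame with columns (og, clade, status in
    {present, absent}). An ``absent`` row at a clade containing a call lifts
    the call to that clade with evidence_level=wider-taxon. A ``present``
    row at a clade containing a call restricts it to the largest named
    descendant clade that still contains all absent sampled species.
    """
    if not set(matrix.species) <= set(taxonomy.leaves):
        raise DataError("taxonomy must cover all matrix species")
    ev_rows: dict[str, list[tuple[str, str]]] = {}
    if evidence is not None:
        for row in evidence.itertuples(index=False):
            if row.clade not in taxonomy:
                raise DataError(f"evidence clade {row.clade!r} not in taxonomy")
            if row.status not in ("present", "absent"):
                raise DataError(f"bad evidence status {row.status!r}")
            ev_rows.setdefault(row.og, []).append((row.clade, row.status))

    calls: list[LossCall] = []
    for og in matrix.og_ids:
        for clade in _maximal_absent_clades(matrix, taxonomy, og):
            call = LossCall(og_id=og, clade=clade, evidence_level="sampled-only")
            leafset = taxonomy.leafset(clade) if clade in taxonomy else frozenset(clade.split(","))
            for ev_clade, status in ev_rows.get(og, []):
                ev_leaves = taxonomy.leafset(ev_clade)
                if status == "absent" and leafset <= ev_leaves:
                    call = LossCall(og, ev_clade, "wider-taxon",
                                    note=f"absent across {ev_clade}")
                elif status == "present" and leafset <= ev_leaves:
                    narrowed = _largest_named_descendant(taxonomy, ev_clade, leafset, matrix, og)
                    if narrowed is not None:
                        call = LossCall(og, narrowed, "wider-taxon",
                                        note=f"present elsewhere in {ev_clade}")
            calls.append(call)
    return calls


def _largest_named_descendant(
    taxonomy: TaxonomyTree, clade: str, absent_leaves: frozenset[str],
    matrix: CountMatrix, og: str,
) -> Optional[str]:
    """Largest named proper descendant of ``clade`` containing the absent
    sampled species (the restriction step for sister-lineage presence)."""
    sampled_absent = absent_leaves & set(matrix.species)
    node = taxonomy.clade_node(clade)
    best: Optional[str] = None
    for sub in node.traverse(include_self=False):
        if sub.is_tip():
            continue
        name = sub.name
        if not name:
            continue
        leaves = taxonomy.leafset(name)
        if sampled_absent <= leaves and all(
            not matrix.present(og, sp) for sp in leaves & set(matrix.species)
        ):
            if best is None or len(leaves) > len(taxonomy.leafset(best)):
                best = name
    if best is None and len(sampled_absent) == 1:
        return next(iter(sampled_absent))
    return best


def losses_to_frame(calls: Sequence[LossCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.og_id, c.clade, c.evidence_level, c.note) for c in calls],
        columns=["og", "clade", "evidence_level", "note"],
    )


def write_losses(calls: Sequence[LossCall], path) -> None:
    losses_to_frame(calls).to_csv(path, sep="\t", index=False)


def write_summary(summary: MatrixSummary, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"grand_total\t{summary.grand_total}\n")
        fh.write(f"n_og_rows\t{summary.n_og_rows}\n")
        fh.write(f"n_subfamilies\t{summary.n_subfamilies}\n")
        fh.write(f"n_multi_og_subfamilies\t{summary.n_multi_og_subfamilies}\n")
        fh.write(f"mean_genes_per_species\t{summary.mean_genes_per_species:.3f}\n")
        fh.write(f"largest_og\t{summary.largest_og[0]}\t{summary.largest_og[1]}\n")
        for sp, tot in summary.per_species_totals.items():
            fh.write(f"species_total\t{sp}\t{tot}\n")
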