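"""Shared record types and input parsing.

The pipeline consumes three kinds of input: multi-species protein sets as
FASTA with species-coded headers (``SPECIES|geneid``), a species taxonomy as
Newick whose internal nodes may carry clade names (orders, families,
monocots/dicots), and an orthogroup x species count matrix in a small TSV
dialect where a cell is an integer, an integer followed by ``*`` (a remnant
gene copy is detectable in the genome), or ``-``/U+2212 (no member found).

All residue coordinates exposed here are 1-based inclusive.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from io import StringIO
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq
from skbio import TreeNode

log = logging.getLogger("ogfamily")

#: the 20 standard amino acids plus X for unknown/ambiguous residues
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = frozenset(AMINO_ACIDS + "X")

#: accepted "missing" marks in count-matrix cells (ASCII hyphen and U+2212)
_MISSING_MARKS = {"-", "−"}

VALID, PSEUDOGENE, REMNANT = "valid", "pseudogene", "remnant"
_STATUSES = {VALID, PSEUDOGENE, REMNANT}


class DataError(ValueError):
    """Raised on malformed or inconsistent input data."""


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------

@dataclass
class ProteinRecord:
    """One curated protein: id, species code, sequence and annotation.

    ``domain_start`` is the 1-based position of the first residue of the
    conserved C-terminal (GRAS-like) domain; everything before it is the
    hypervariable N-terminal region.
    """

    id: str
    species: str
    sequence: str
    status: str = VALID
    domain_start: Optional[int] = None
    og_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.status not in _STATUSES:
            raise DataError(f"{self.id}: unknown status {self.status!r}")
        if self.status == VALID and not self.sequence:
            raise DataError(f"{self.id}: empty sequence for valid-status record")
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise DataError(
                f"{self.id}: residues outside alphabet: {''.join(sorted(bad))}"
            )
        if self.domain_start is not None and not (
            1 <= self.domain_start <= max(len(self.sequence), 1)
        ):
            raise DataError(f"{self.id}: domain_start {self.domain_start} out of range")

    @property
    def nterm(self) -> str:
        """Residues strictly before the domain start (may be empty)."""
        if self.domain_start is None:
            raise DataError(f"{self.id}: no domain_start set")
        return self.sequence[: self.domain_start - 1]


BASAL, MONOCOT, DICOT = "basal", "monocot", "dicot"


@dataclass(frozen=True)
class SpeciesEntry:
    code: str
    name: str
    lineage: str  # basal | monocot | dicot
    order: str
    family: str


class SpeciesRegistry:
    """The sampled species panel with lineage class, order and family."""

    def __init__(self, entries: Iterable[SpeciesEntry]):
        self.entries = list(entries)
        codes = [e.code for e in self.entries]
        if len(set(codes)) != len(codes):
            raise DataError("duplicate species codes in registry")
        basal = [e for e in self.entries if e.lineage == BASAL]
        if len(basal) > 1:
            raise DataError("more than one basal (outgroup) species")
        for e in self.entries:
            if e.lineage not in (BASAL, MONOCOT, DICOT):
                raise DataError(f"{e.code}: unknown lineage class {e.lineage!r}")
        self._by_code = {e.code: e for e in self.entries}

    @property
    def codes(self) -> list[str]:
        return [e.code for e in self.entries]

    @property
    def basal(self) -> Optional[str]:
        for e in self.entries:
            if e.lineage == BASAL:
                return e.code
        return None

    def lineage(self, code: str) -> str:
        return self._by_code[code].lineage

    def __contains__(self, code: str) -> bool:
        return code in self._by_code

    def __len__(self) -> int:
        return len(self.entries)


class TaxonomyTree:
    """Rooted species taxonomy; internal nodes may carry unique clade names."""

    def __init__(self, tree: TreeNode):
        self.tree = tree
        self.clades: dict[str, frozenset[str]] = {}
        self._clade_nodes: dict[str, TreeNode] = {}
        for node in tree.traverse(include_self=True):
            if node.is_tip() or not node.name:
                continue
            if node.name in self.clades:
                raise DataError(f"duplicate clade name {node.name!r} in taxonomy")
            self.clades[node.name] = frozenset(t.name for t in node.tips())
            self._clade_nodes[node.name] = node
        tips = [tree] if tree.is_tip() else list(tree.tips())
        self.leaves = frozenset(t.name for t in tips)
        if len(self.leaves) != len(tips):
            raise DataError("duplicate leaf labels in taxonomy")

    def leafset(self, clade_or_species: str) -> frozenset[str]:
        """Resolve a clade name or single species code to its leaf set."""
        if clade_or_species in self.clades:
            return self.clades[clade_or_species]
        if clade_or_species in self.leaves:
            return frozenset({clade_or_species})
        raise DataError(f"unknown clade or species {clade_or_species!r}")

    def __contains__(self, name: str) -> bool:
        return name in self.clades or name in self.leaves

    def clade_node(self, name: str) -> TreeNode:
        return self._clade_nodes[name]


class CountMatrix:
    """Orthogroup x species gene counts with remnant flags.

    ``outgroup_specific_rows`` are rows kept in the table (their genes count
    in species totals) but excluded from orthogroup-level statistics: they
    hold genes confined to the basal outgroup that belong to no orthogroup
    anchored at the monocot/dicot split.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        remnant: Optional[pd.DataFrame] = None,
        outgroup_specific_rows: Iterable[str] = (),
    ):
        if counts.index.has_duplicates or counts.columns.has_duplicates:
            raise DataError("duplicate row or column labels in count matrix")
        if (counts.to_numpy() < 0).any():
            raise DataError("negative counts")
        self.counts = counts.astype(int)
        if remnant is None:
            remnant = pd.DataFrame(False, index=counts.index, columns=counts.columns)
        self.remnant = remnant.astype(bool)
        if not self.remnant.index.equals(self.counts.index) or not self.remnant.columns.equals(
            self.counts.columns
        ):
            raise DataError("remnant flags not aligned with counts")
        self.outgroup_specific_rows = frozenset(outgroup_specific_rows)
        unknown = self.outgroup_specific_rows - set(counts.index)
        if unknown:
            raise DataError(f"unknown outgroup-specific rows: {sorted(unknown)}")

    @property
    def og_ids(self) -> list[str]:
        """Orthogroup row labels (outgroup-specific rows excluded)."""
        return [r for r in self.counts.index if r not in self.outgroup_specific_rows]

    @property
    def species(self) -> list[str]:
        return list(self.counts.columns)

    def present(self, og_id: str, species: str) -> bool:
        """Presence = at least one gene model, or a remnant mark."""
        return bool(
            self.counts.at[og_id, species] > 0 or self.remnant.at[og_id, species]
        )


# ---------------------------------------------------------------------------
# FASTA input / output
# ---------------------------------------------------------------------------

def read_fasta(
    path,
    registry: Optional[SpeciesRegistry] = None,
    delimiter: str = "|",
    species_map: Optional[dict[str, str]] = None,
) -> list[ProteinRecord]:
    """Read species-coded protein FASTA into :class:`ProteinRecord` objects.

    Headers follow ``SPECIESCODE<delimiter>geneid``; ``species_map`` may
    override parsed species codes per gene id (for source genomes whose
    headers deviate from the convention). Sequences are uppercased and a
    trailing ``*`` stop symbol is stripped.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.id
        if delimiter not in header:
            raise DataError(f"header {header!r} lacks delimiter {delimiter!r}")
        species, gene_id = header.split(delimiter, 1)
        if species_map and gene_id in species_map:
            species = species_map[gene_id]
        if registry is not None and species not in registry:
            raise DataError(f"{gene_id}: unknown species code {species!r}")
        if gene_id in seen:
            raise DataError(f"duplicate gene id {gene_id!r}")
        seen.add(gene_id)
        seq = str(rec.seq).upper().rstrip("*")
        records.append(ProteinRecord(id=gene_id, species=species, sequence=seq))
    if not records:
        log.warning("read_fasta: %s contained no sequences", path)
    return records


def write_fasta(records: Sequence[ProteinRecord], path, delimiter: str = "|") -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=f"{r.species}{delimiter}{r.id}", description="")
        for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_species_map(path) -> dict[str, str]:
    """TSV of (gene id, species code) overriding header-parsed codes."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    return dict(zip(df[0], df[1]))


# ---------------------------------------------------------------------------
# count-matrix dialect
# ---------------------------------------------------------------------------

_CELL_RE = re.compile(r"^(\d*)(\*?)$")


def _parse_cell(token: str, row: str, col: str) -> tuple[int, bool]:
    token = token.strip()
    if token in _MISSING_MARKS:
        return 0, False
    m = _CELL_RE.match(token)
    if not m or (not m.group(1) and not m.group(2)):
        raise DataError(f"bad cell {token!r} at row {row!r}, column {col!r}")
    count = int(m.group(1)) if m.group(1) else 0
    return count, bool(m.group(2))


def load_count_matrix(path, outgroup_specific: Iterable[str] = ()) -> CountMatrix:
    """Parse the printed count-matrix dialect.

    A leading comment line ``#outgroup_specific<TAB>row1,row2`` may declare
    outgroup-specific rows inside the file; the ``outgroup_specific``
    argument adds to it.
    """
    og_specific = set(outgroup_specific)
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    body: list[str] = []
    for line in lines:
        if line.startswith("#outgroup_specific"):
            og_specific.update(
                x.strip() for x in line.split("\t", 1)[1].split(",") if x.strip()
            )
        elif line.strip() and not line.startswith("#"):
            body.append(line)
    if not body:
        raise DataError(f"{path}: empty count matrix")
    header = body[0].split("\t")
    species = header[1:]
    counts: dict[str, list[int]] = {}
    remnant: dict[str, list[bool]] = {}
    order: list[str] = []
    for line in body[1:]:
        cells = line.split("\t")
        if len(cells) != len(header):
            raise DataError(
                f"ragged row {cells[0]!r}: {len(cells)} fields, expected {len(header)}"
            )
        og = cells[0]
        if og in counts:
            raise DataError(f"duplicate row label {og!r}")
        order.append(og)
        row_counts, row_flags = [], []
        for col, tok in zip(species, cells[1:]):
            c, f = _parse_cell(tok, og, col)
            row_counts.append(c)
            row_flags.append(f)
        counts[og] = row_counts
        remnant[og] = row_flags
    cdf = pd.DataFrame.from_dict(counts, orient="index", columns=species).loc[order]
    rdf = pd.DataFrame.from_dict(remnant, orient="index", columns=species).loc[order]
    return CountMatrix(cdf, rdf, outgroup_specific_rows=og_specific)


def write_count_matrix(matrix: CountMatrix, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if matrix.outgroup_specific_rows:
            fh.write(
                "#outgroup_specific\t%s\n" % ",".join(sorted(matrix.outgroup_specific_rows))
            )
        fh.write("og\t" + "\t".join(matrix.species) + "\n")
        for og in matrix.counts.index:
            cells = []
            for sp in matrix.species:
                c = matrix.counts.at[og, sp]
                star = "*" if matrix.remnant.at[og, sp] else ""
                cells.append(f"{c}{star}" if (c or star) else "-")
            fh.write(og + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------

def load_taxonomy(path_or_newick, registry: Optional[SpeciesRegistry] = None) -> TaxonomyTree:
    """Parse a Newick taxonomy whose internal node labels name clades."""
    text = str(path_or_newick)
    if "(" in text or ";" in text:
        handle = StringIO(text)
    else:
        handle = StringIO(Path(path_or_newick).read_text())
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tree = TreeNode.read(handle, format="newick")
    except Exception as exc:  # scikit-bio raises its own parse errors
        raise DataError(f"malformed Newick: {exc}") from exc
    tax = TaxonomyTree(tree)
    if registry is not None and tax.leaves != frozenset(registry.codes):
        raise DataError(
            f"taxonomy leaves {sorted(tax.leaves)} != registry codes {sorted(registry.codes)}"
        )
    return tax


# ---------------------------------------------------------------------------
# packaged fixtures: the curated GRAS panel of eight angiosperms
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("ogfamily").joinpath("data", name)


def load_gras_registry() -> SpeciesRegistry:
    """Species panel of the curated angiosperm GRAS dataset."""
    df = pd.read_csv(_data_path("species_registry.tsv"), sep="\t", comment="#")
    return SpeciesRegistry(
        SpeciesEntry(r.code, r.name, r.lineage, r.order, r.family)
        for r in df.itertuples(index=False)
    )


def load_gras_taxonomy() -> TaxonomyTree:
    return load_taxonomy(_data_path("taxonomy.nwk"), registry=load_gras_registry())


def load_gras_counts() -> CountMatrix:
    """The published GRAS orthogroup x species count matrix (8 species)."""
    return load_count_matrix(_data_path("gras_og_counts.tsv"))


def load_gras_loss_evidence() -> pd.DataFrame:
    """Wider-taxon presence/absence evidence (og, clade, status)."""
    return pd.read_csv(_data_path("loss_evidence.tsv"), sep="\t", comment="#")
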