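"""Synthetic gene-family generator with full ground truth.

The generator inverts the evolutionary history the analysis pipeline tries
to reconstruct: a panel of species with one basal outgroup and a
monocot/dicot split, a configurable number of ancestral genes at the root
(29 by default, structured into 17 founder lineages so that some ancestral
genes are pre-split duplicates of each other, mirroring multi-orthogroup
subfamilies), branchwise birth-death gene duplication and loss, optional
forced clade-wide losses, domain-structured sequence evolution (slow
conserved C-terminal domain, fast hypervariable N-terminus) and plantable
orthogroup-specific N-terminal motifs.

Sequence evolution uses a time-reversible substitution model built from an
exchangeability matrix and equilibrium amino-acid frequencies; the default
has uniform exchangeabilities over empirical protein composition (an
F81-style model), and any exchangeability matrix can be supplied. Rates are
in expected substitutions per site per unit branch length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm
from skbio import TreeNode

from .datamodel import (
    AMINO_ACIDS,
    DataError,
    ProteinRecord,
    SpeciesEntry,
    SpeciesRegistry,
    TaxonomyTree,
    load_taxonomy,
)

_N_AA = 20
_IDX = {c: i for i, c in enumerate(AMINO_ACIDS)}

#: empirical average amino-acid composition of globular proteins
EMPIRICAL_FREQS = np.array([
    0.074, 0.025, 0.054, 0.054, 0.047, 0.074, 0.026, 0.068, 0.058, 0.099,
    0.025, 0.045, 0.039, 0.034, 0.052, 0.057, 0.051, 0.073, 0.013, 0.032,
])
EMPIRICAL_FREQS = EMPIRICAL_FREQS / EMPIRICAL_FREQS.sum()

#: default species panel: unit-length branches, basal outgroup, named splits
DEFAULT_SPECIES_TREE = (
    "(((Os:1.0,(Pd:1.0,Ma:1.0):1.0)monocots:1.0,"
    "(((At:1.0,Tc:1.0):1.0,Vv:1.0):1.0,Cc:1.0)dicots:1.0)mesangiosperms:1.0,"
    "Amb:1.0)root;"
)

TANDEM, SEGMENTAL = "tandem", "segmental"


@dataclass
class DomainSpec:
    """Architecture and per-region substitution rates.

    Rates are expected substitutions per site per unit branch length; the
    N-terminal rate must exceed the domain rate (hypervariable N-terminus
    by construction).
    """

    nterm_length_range: tuple[int, int] = (30, 60)
    domain_length_range: tuple[int, int] = (100, 160)
    nterm_rate_multiplier: float = 0.60
    domain_rate_multiplier: float = 0.05

    def __post_init__(self) -> None:
        if self.nterm_rate_multiplier <= self.domain_rate_multiplier:
            raise DataError("N-terminal rate must exceed domain rate")
        if min(self.nterm_rate_multiplier, self.domain_rate_multiplier) <= 0:
            raise DataError("rate multipliers must be > 0")


@dataclass
class MotifSpec:
    """One plantable N-terminal motif for one root gene."""

    motif: str
    window: tuple[int, int] = (1, 30)  # 1-based window of allowed start positions
    mutation_prob: float = 0.1
    carrier_fraction: float = 1.0


@dataclass
class SimConfig:
    species_tree: str = DEFAULT_SPECIES_TREE
    n_root_genes: int = 29
    duplication_rate: float = 0.1  # events per gene per unit branch length
    loss_rate: float = 0.15
    #: forced losses applied after stochastic events: (root gene index, clade)
    clade_loss_table: list = field(default_factory=list)
    domain_spec: DomainSpec = field(default_factory=DomainSpec)
    #: root gene index -> MotifSpec
    motif_spec: dict = field(default_factory=dict)
    #: founder group sizes; root genes within a group are pre-split duplicates
    #: (17 founders, 8 of them multi-gene, mirroring the subfamily structure)
    subfamily_sizes: tuple = (3, 2, 2, 3, 2, 2, 4, 2, 1, 1, 1, 1, 1, 1, 1, 1, 1)
    #: divergence (unit branch lengths) between founder and each root gene;
    #: pre-split duplications are ancient, so same-founder orthogroups are
    #: markedly further apart than orthologs within any orthogroup
    pre_split_divergence: float = 3.0
    #: per-root-gene duplication-rate multipliers (one amplified, LISCL-like
    #: group by default: strongly duplicating and strongly retained)
    duplication_multipliers: dict = field(default_factory=lambda: {28: 8.0})
    #: per-root-gene loss-rate multipliers
    loss_multipliers: dict = field(default_factory=lambda: {28: 0.3})
    tandem_prob: float = 0.5
    #: N-terminal indel rate (events per unit branch length); off by default
    indel_rate: float = 0.0
    #: optional (20, 20) symmetric exchangeability matrix; None = uniform (F81)
    exchangeability: Optional[np.ndarray] = None
    equilibrium_freqs: np.ndarray = field(default_factory=lambda: EMPIRICAL_FREQS.copy())
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duplication_rate < 0 or self.loss_rate < 0:
            raise DataError("rates must be >= 0")
        if sum(self.subfamily_sizes) != self.n_root_genes:
            # keep the founder structure consistent with n_root_genes: pad
            # with singleton founders or truncate deterministically
            sizes = []
            total = 0
            for s in self.subfamily_sizes:
                if total + s > self.n_root_genes:
                    break
                sizes.append(s)
                total += s
            sizes.extend([1] * (self.n_root_genes - total))
            self.subfamily_sizes = tuple(sizes)


@dataclass
class SimEvent:
    root_gene: int
    branch: str  # species-tree node name or species code of the child end
    kind: str  # "duplication" | "loss" | "forced-loss"
    dup_type: Optional[str] = None  # tandem | segmental
    time: float = 0.0  # position along the branch


@dataclass
class GroundTruth:
    og_of: dict[str, int]  # gene id -> root gene (true orthogroup)
    subfamily_of_root: dict[int, int]  # root gene -> founder index
    matrix: pd.DataFrame  # root gene x species counts
    gene_trees: dict[int, str]  # root gene -> newick over surviving genes
    domain_start: dict[str, int]
    motif_sites: dict[str, tuple[int, str]]  # gene id -> (1-based start, motif)
    motif_exceptions: dict[int, list[str]]  # root gene -> non-carrier ids
    events: list[SimEvent] = field(default_factory=list)


# ---------------------------------------------------------------------------
# substitution machinery
# ---------------------------------------------------------------------------

class SubstitutionModel:
    """Time-reversible 20-state model, normalised to 1 sub/site/unit time."""

    def __init__(self, exchangeability: Optional[np.ndarray], freqs: np.ndarray):
        freqs = np.asarray(freqs, dtype=float)
        freqs = freqs / freqs.sum()
        self.freqs = freqs
        S = np.ones((_N_AA, _N_AA)) if exchangeability is None else np.asarray(exchangeability, float)
        if S.shape != (_N_AA, _N_AA) or not np.allclose(S, S.T):
            raise DataError("exchangeability matrix must be symmetric 20x20")
        Q = S * freqs[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        rate = -(freqs * np.diag(Q)).sum()
        self.Q = Q / rate
        self._cache: dict[float, np.ndarray] = {}

    def transition(self, t: float) -> np.ndarray:
        key = round(t, 9)
        if key not in self._cache:
            self._cache[key] = expm(self.Q * t)
        return self._cache[key]

    def sample_root(self, length: int, rng: np.random.Generator) -> np.ndarray:
        return rng.choice(_N_AA, size=length, p=self.freqs)

    def evolve(self, seq: np.ndarray, t: float, rng: np.random.Generator) -> np.ndarray:
        if t <= 0:
            return seq.copy()
        P = self.transition(t)
        out = seq.copy()
        for residue in range(_N_AA):
            sites = np.flatnonzero(seq == residue)
            if sites.size:
                out[sites] = rng.choice(_N_AA, size=sites.size, p=P[residue])
        return out


def evolve_sequence(
    seq: str,
    branch_length: float,
    domain_start: int,
    config: SimConfig,
    rng: np.random.Generator,
    model: Optional[SubstitutionModel] = None,
) -> tuple[str, int]:
    """Evolve one protein along a branch; returns (sequence, domain_start).

    Sites before ``domain_start`` evolve at the N-terminal rate and may
    drift in length under the geometric indel model (default off); domain
    sites evolve at the slow domain rate with no indels.
    """
    if branch_length < 0:
        raise DataError("branch_length must be >= 0")
    model = model or SubstitutionModel(config.exchangeability, config.equilibrium_freqs)
    ds = config.domain_spec
    enc = np.array([_IDX[c] for c in seq], dtype=np.int64)
    nterm = enc[: domain_start - 1]
    domain = enc[domain_start - 1:]
    nterm = model.evolve(nterm, branch_length * ds.nterm_rate_multiplier, rng)
    domain = model.evolve(domain, branch_length * ds.domain_rate_multiplier, rng)
    if config.indel_rate > 0 and nterm.size:
        n_events = rng.poisson(config.indel_rate * branch_length)
        for _ in range(n_events):
            length = int(rng.geometric(0.5))
            pos = int(rng.integers(0, max(len(nterm), 1)))
            if rng.random() < 0.5 and len(nterm) > length:
                nterm = np.delete(nterm, slice(pos, pos + length))
            else:
                ins = model.sample_root(length, rng)
                nterm = np.concatenate([nterm[:pos], ins, nterm[pos:]])
    out = np.concatenate([nterm, domain])
    return "".join(AMINO_ACIDS[i] for i in out), len(nterm) + 1


# ---------------------------------------------------------------------------
# birth-death gene evolution down the species tree
# ---------------------------------------------------------------------------

class _Lineage:
    __slots__ = ("seq", "domain_start", "node")

    def __init__(self, seq: np.ndarray, domain_start: int, node: TreeNode):
        self.seq = seq
        self.domain_start = domain_start
        self.node = node


def _species_lineage_classes(tree: TreeNode) -> dict[str, str]:
    """basal / monocot / dicot per leaf, from the named monocots/dicots
    clades; everything outside both (and outside their shared stem) is
    basal."""
    classes: dict[str, str] = {}
    mono = dico = frozenset()
    for node in tree.traverse(include_self=True):
        if node.name == "monocots":
            mono = frozenset(t.name for t in node.tips())
        elif node.name == "dicots":
            dico = frozenset(t.name for t in node.tips())
    for t in tree.tips():
        if t.name in mono:
            classes[t.name] = "monocot"
        elif t.name in dico:
            classes[t.name] = "dicot"
        else:
            classes[t.name] = "basal"
    return classes


def registry_from_tree(taxonomy: TaxonomyTree) -> SpeciesRegistry:
    """Derive a minimal registry (codes + lineage classes) from a species
    tree with named monocots/dicots clades."""
    classes = _species_lineage_classes(taxonomy.tree)
    basal = [c for c, l in classes.items() if l == "basal"]
    if len(basal) > 1:  # keep a single outgroup: the rest become dicots
        for extra in sorted(basal)[1:]:
            classes[extra] = "dicot"
    return SpeciesRegistry(
        SpeciesEntry(code, code, classes[code], "", "") for code in sorted(classes)
    )


def simulate_dataset(config: SimConfig) -> tuple[list[ProteinRecord], GroundTruth]:
    """Generate one dataset plus complete ground truth (bit-reproducible)."""
    taxonomy = load_taxonomy(config.species_tree)
    stree = taxonomy.tree
    for node in stree.non_tips(include_self=True):
        if len(node.children) != 2:
            raise DataError("species tree must be binary")
        for child in node.children:
            if child.length is None:
                raise DataError("species tree branches must have lengths")
    rng = np.random.default_rng(config.seed)
    model = SubstitutionModel(config.exchangeability, config.equilibrium_freqs)
    ds = config.domain_spec

    # founders and root genes (pre-split duplications within founder groups)
    subfamily_of_root: dict[int, int] = {}
    root_genes: list[tuple[np.ndarray, int]] = []  # (sequence, domain_start)
    g = 0
    for founder_idx, size in enumerate(config.subfamily_sizes):
        nlen = int(rng.integers(ds.nterm_length_range[0], ds.nterm_length_range[1] + 1))
        dlen = int(rng.integers(ds.domain_length_range[0], ds.domain_length_range[1] + 1))
        founder = model.sample_root(nlen + dlen, rng)
        for _ in range(size):
            seq_str, dstart = evolve_sequence(
                "".join(AMINO_ACIDS[i] for i in founder),
                config.pre_split_divergence, nlen + 1, config, rng, model)
            root_genes.append((np.array([_IDX[c] for c in seq_str]), dstart))
            subfamily_of_root[g] = founder_idx
            g += 1

    records: list[ProteinRecord] = []
    og_of: dict[str, int] = {}
    domain_start_truth: dict[str, int] = {}
    events: list[SimEvent] = []
    gene_trees: dict[int, str] = {}
    counters: dict[str, int] = {}

    forced: dict[int, set[str]] = {}
    for root_idx, clade in config.clade_loss_table:
        forced.setdefault(root_idx, set()).update(taxonomy.leafset(clade))

    # the branch between the basal-outgroup split and the monocot/dicot split
    # carries no birth-death events: ancestral genes at the root are, by
    # construction, the gene lineages present at the anchor split (a
    # duplication on that stem would predate the split and found a new
    # orthogroup, contradicting the root-gene ground truth)
    stem_node = None
    mono_dico = frozenset()
    for node in stree.traverse(include_self=False):
        if node.name in ("monocots", "dicots"):
            mono_dico = mono_dico | frozenset(t.name for t in node.tips())
    for child in stree.children:
        if not child.is_tip() and mono_dico <= frozenset(t.name for t in child.tips()):
            stem_node = child

    for og_idx, (root_seq, root_ds) in enumerate(root_genes):
        dup_rate = config.duplication_rate * config.duplication_multipliers.get(og_idx, 1.0)
        loss_rate = config.loss_rate * config.loss_multipliers.get(og_idx, 1.0)
        leaf_nodes: list[TreeNode] = []

        def descend(snode: TreeNode, lin: _Lineage) -> None:
            """Recurse into a species-tree node with one incoming lineage."""
            if snode.is_tip():
                sp = snode.name
                if sp in forced.get(og_idx, set()):
                    events.append(SimEvent(og_idx, sp, "forced-loss"))
                    _kill(lin.node)
                    return
                counters[sp] = counters.get(sp, 0) + 1
                gid = f"{sp}_og{og_idx:02d}_{counters[sp]}"
                lin.node.name = gid
                leaf_nodes.append(lin.node)
                seq_str = "".join(AMINO_ACIDS[i] for i in lin.seq)
                records.append(ProteinRecord(
                    id=gid, species=sp, sequence=seq_str,
                    domain_start=lin.domain_start))
                og_of[gid] = og_idx
                domain_start_truth[gid] = lin.domain_start
                return
            for child in snode.children:
                survivors = _branch(child, lin.seq, lin.domain_start, lin.node)
                for sv in survivors:
                    descend(child, sv)

        def _branch(child: TreeNode, seq: np.ndarray, dstart: int,
                    parent_gnode: TreeNode) -> list[_Lineage]:
            """Evolve one lineage along a species-tree branch with
            birth-death events; returns surviving lineages at branch end."""
            out: list[_Lineage] = []

            def run(seq, dstart, t_left, gnode, t_used):
                total = 0.0 if child is stem_node else dup_rate + loss_rate
                tau = rng.exponential(1.0 / total) if total > 0 else math.inf
                if tau >= t_left:
                    s, d = _evolve(seq, dstart, t_left)
                    gnode.length = (gnode.length or 0.0) + t_left
                    out.append(_Lineage(s, d, gnode))
                    return
                s, d = _evolve(seq, dstart, tau)
                gnode.length = (gnode.length or 0.0) + tau
                if rng.random() < dup_rate / total:
                    dup_type = TANDEM if rng.random() < config.tandem_prob else SEGMENTAL
                    events.append(SimEvent(og_idx, child.name or "internal",
                                           "duplication", dup_type, t_used + tau))
                    left = TreeNode(length=0.0)
                    right = TreeNode(length=0.0)
                    gnode.extend([left, right])
                    run(s.copy(), d, t_left - tau, left, t_used + tau)
                    run(s.copy(), d, t_left - tau, right, t_used + tau)
                else:
                    events.append(SimEvent(og_idx, child.name or "internal",
                                           "loss", None, t_used + tau))
                    _kill(gnode)

            start = TreeNode(length=0.0)
            parent_gnode.append(start)
            run(seq.copy(), dstart, float(child.length), start, 0.0)
            return out

        def _evolve(seq: np.ndarray, dstart: int, t: float) -> tuple[np.ndarray, int]:
            s, d = evolve_sequence("".join(AMINO_ACIDS[i] for i in seq),
                                   t, dstart, config, rng, model)
            return np.array([_IDX[c] for c in s], dtype=np.int64), d

        groot = TreeNode(length=0.0)
        descend(stree, _Lineage(root_seq.copy(), root_ds, groot))
        gene_trees[og_idx] = _prune_gene_tree(groot, leaf_nodes)

    # ground-truth matrix
    species_codes = sorted(t.name for t in stree.tips())
    mat = pd.DataFrame(0, index=range(len(root_genes)), columns=species_codes)
    for gid, og_idx in og_of.items():
        sp = gid.split("_og")[0]
        mat.at[og_idx, sp] += 1

    truth = GroundTruth(
        og_of=og_of,
        subfamily_of_root=subfamily_of_root,
        matrix=mat,
        gene_trees=gene_trees,
        domain_start=domain_start_truth,
        motif_sites={},
        motif_exceptions={},
        events=events,
    )
    if config.motif_spec:
        records, truth = plant_motif(records, truth, config.motif_spec, rng)
    return records, truth


def _kill(gnode: TreeNode) -> None:
    gnode.name = "__dead__"


def _prune_gene_tree(groot: TreeNode, leaves: Sequence[TreeNode]) -> str:
    """Drop dead lineages, suppress unary nodes, return newick ('' if no
    survivors, 'name:len;' for a single survivor)."""
    keep = {id(l) for l in leaves}

    def prune(node: TreeNode) -> Optional[TreeNode]:
        if node.is_tip():
            return node if id(node) in keep else None
        kids = [prune(c) for c in node.children]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            kids[0].length = (kids[0].length or 0.0) + (node.length or 0.0)
            return kids[0]
        new = TreeNode(length=node.length)
        new.extend(kids)
        return new

    pruned = prune(groot)
    if pruned is None:
        return ""
    pruned.length = None
    return str(pruned).strip()


# ---------------------------------------------------------------------------
# motif planting
# ---------------------------------------------------------------------------

def plant_motif(
    records: list[ProteinRecord],
    truth: GroundTruth,
    motif_spec: dict,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> tuple[list[ProteinRecord], GroundTruth]:
    """Write orthogroup-specific motifs into carriers' N-terminal regions.

    The motif overwrites residues at a uniform-random start inside the
    allowed window, then mutates per site with the stated probability.
    Non-carriers are recorded as ground-truth exceptions.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    out: list[ProteinRecord] = []
    by_og: dict[int, list[int]] = {}
    for k, r in enumerate(records):
        by_og.setdefault(truth.og_of[r.id], []).append(k)
    new_records = list(records)
    for og_idx, spec in sorted(motif_spec.items()):
        members = by_og.get(og_idx, [])
        if not members:
            continue
        w = len(spec.motif)
        min_nterm = min(new_records[k].domain_start - 1 for k in members)
        if w > min_nterm:
            raise DataError(
                f"motif of width {w} does not fit the shortest N-terminus "
                f"({min_nterm}) of root gene {og_idx}")
        n_carriers = int(round(spec.carrier_fraction * len(members)))
        order = rng.permutation(len(members))
        carrier_set = {members[i] for i in order[:n_carriers]}
        exceptions = []
        for k in sorted(members):
            rec = new_records[k]
            if k not in carrier_set:
                exceptions.append(rec.id)
                continue
            nterm_len = rec.domain_start - 1
            lo = max(spec.window[0], 1)
            hi = min(spec.window[1], nterm_len - w + 1)
            if hi < lo:
                lo, hi = 1, nterm_len - w + 1
            start = int(rng.integers(lo, hi + 1))  # 1-based
            motif = list(spec.motif)
            for i in range(w):
                if rng.random() < spec.mutation_prob:
                    motif[i] = AMINO_ACIDS[int(rng.integers(0, _N_AA))]
            s = rec.sequence
            s = s[: start - 1] + "".join(motif) + s[start - 1 + w:]
            new_records[k] = replace(rec, sequence=s)
            truth.motif_sites[rec.id] = (start, spec.motif)
        truth.motif_exceptions[og_idx] = exceptions
    return new_records, truth


# ---------------------------------------------------------------------------
# provenance
# ---------------------------------------------------------------------------

def write_config(config: SimConfig, path) -> None:
    """Flat key-value snapshot of the generator settings."""
    with open(path, "w") as fh:
        fh.write(f"species_tree\t{config.species_tree}\n")
        fh.write(f"n_root_genes\t{config.n_root_genes}\n")
        fh.write(f"duplication_rate\t{config.duplication_rate}\n")
        fh.write(f"loss_rate\t{config.loss_rate}\n")
        fh.write(f"subfamily_sizes\t{','.join(map(str, config.subfamily_sizes))}\n")
        fh.write(f"pre_split_divergence\t{config.pre_split_divergence}\n")
        ds = config.domain_spec
        fh.write(f"nterm_length_range\t{ds.nterm_length_range[0]}-{ds.nterm_length_range[1]}\n")
        fh.write(f"domain_length_range\t{ds.domain_length_range[0]}-{ds.domain_length_range[1]}\n")
        fh.write(f"nterm_rate\t{ds.nterm_rate_multiplier}\n")
        fh.write(f"domain_rate\t{ds.domain_rate_multiplier}\n")
        fh.write(f"tandem_prob\t{config.tandem_prob}\n")
        fh.write(f"indel_rate\t{config.indel_rate}\n")
        fh.write(f"seed\t{config.seed}\n")
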