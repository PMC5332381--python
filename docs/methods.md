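# Methods

`ogfamily` reconstructs the classification workflow used in curated studies
of plant transcription-factor families — here modelled on the GRAS family in
eight angiosperms — and packages it as a tested, reproducible pipeline. This
note documents the models, the algorithms, the tunable parameters, and the
design decisions taken where the procedure was genuinely open.

## The classification model

An **orthogroup (OG)** is the set of genes descended from a single ancestral
gene present at a chosen reference speciation event. The reference here is
the **monocot/dicot split**: it post-dates the divergence of the basal
outgroup (*Amborella trichopoda*), so outgroup genes polarise OG ancestry
but never define OGs. A **subfamily** is a higher rank: one or more OGs
whose members cluster by sequence similarity, named after the
first-characterised member gene; OGs inside a multi-OG subfamily carry a
hyphen-number suffix (`OG-SCR-1`), singleton subfamilies stay bare
(`OG-DLT`).

GRAS-like proteins have a conserved C-terminal domain and a hypervariable,
intrinsically disordered N-terminal region. The pipeline exploits both:
similarity ranking and tree building lean on the domain, motif discovery
targets the N-terminus.

## Pairwise similarity engine

All similarity computations are optimal pairwise alignments (Gotoh dynamic
programming, numba-compiled): Needleman–Wunsch global and Smith–Waterman
local modes under an affine gap model in which a gap of length L costs
`gap_open + (L-1) * gap_extend`. Defaults are BLOSUM62 with open 10 /
extend 0.5; `X` scores 0 against everything. Percent identity and percent
similarity (substitution score > 0) use the alignment length including gap
columns as denominator — the EMBOSS convention. Hit lists rank by raw local
score with ties broken by target id; raw scores are adequate and exactly
reproducible at family scale (hundreds of sequences), which is why no
E-value machinery is included. Externally computed BLAST tabular hits
(outfmt 6) can be imported under the same hit-list contract.

Traceback tie-breaks prefer diagonal moves, then gaps consuming the first
sequence, so alignments are bit-reproducible. The local-mode end cell is the
best-scoring cell with the smallest (row, column) index.

## Orthogroup inference

Cores are built from cross-species **reciprocal best hits (RBH)** among
non-basal, valid-status genes, then refined:

1. **RBH edge screening.** For a fixed species pair, every true ortholog
   pair diverged at the same speciation, so self-normalised scores
   (`score(a,b) / min(selfscore)`) cluster tightly. An edge below
   `rbh_relative_min` (default 0.85) of its species-pair median is a likely
   pre-split link between sibling OGs of one subfamily — the signature of
   complementary loss patterns — and is dropped, unless it is an endpoint's
   only edge (protecting two-species OGs).
2. **Cores.** Connected components of the screened RBH graph.
3. **Post-split duplication clique merging.** A duplication after the
   anchor split (e.g. on the monocot stem) produces a separate RBH clique
   that belongs, by the OG definition, to its parent OG. For each core, the
   informative hits are in species the core does not reach: if a majority
   (`core_merge_majority`, 0.5) of its genes' best such hits point at one
   other core with median species-pair-relative score at least
   `core_merge_relative_min` (0.80), the core merges into it. Ortholog-level
   hits score near 1.0 on this scale; pre-split (cross-OG) hits near 0.65,
   so the threshold separates a post-split duplication from a sibling OG.
   Duplications arbitrarily close to the split are irreducibly ambiguous.
4. **In-paralog absorption.** An unplaced gene joins the OG of its top
   assigned cross-species hit when that score is at least
   `in_paralog_ratio` (0.8) of the OG core's median cross-species score;
   iterated to a fixed point in deterministic order.
5. **Outgroup attachment.** Basal-species genes attach to the OG of their
   top non-basal hit when an RBH holds against at least one member; tandem
   copies of an attached outgroup gene are absorbed through their
   same-species anchor; everything else stays unassigned (the model for
   outgroup-specific tandem pairs such as the unassignable basal NSP2-like
   genes).
6. **Manual overrides** (a gene → OG table) are honoured last with
   provenance `manual`, so a published curated assignment can be reproduced
   exactly. OG labels are deterministic (ordered by smallest member id).

Strict monotonicity under species deletion is *not* guaranteed: removing a
species can create exactly the complementary presence pattern that forms a
cross-OG bridge. Empirically fewer than 2% of previously-separated gene
pairs merge per deleted species; the property suite asserts that
statistical form.

### Diagnostic classification

A novel sequence is assigned to the OG of its top-scoring reference hit
when (i) the margin over the best other-OG score is at least
`min_margin_frac` (5%) of the top score, and (ii) reciprocity holds: the
query ranks within the top `reciprocity_window` (3) hits of its best
partner over reference ∪ {query}, **or** scores at least
`in_paralog_ratio` of the partner's best cross-species score. The second
arm matters in large OGs, where the partner's own orthologs legitimately
outrank a novel-species query; composition-matched shuffled sequences are
still always rejected (they fail both arms and the margin).

## Count matrix, summaries and loss calling

The OG × species matrix counts valid-status members; remnant records
(degraded copies detectable in a genome but not annotated as gene models)
set a per-cell flag instead of counting. *Presence* therefore means
`count > 0 or remnant` — a remnant proves the gene existed, so remnants
block loss calls but do not add to totals. Outgroup-specific rows stay in
the table (their genes count in species totals) but are excluded from
OG-level statistics; this is the only reading under which the curated
matrix's species totals, grand total and OG count are simultaneously
consistent.

Loss calls walk the taxonomy from the root: each maximal clade whose
sampled species all lack an OG is emitted at its nearest named node
(unnamed multifurcations split the call). A declarative wider-taxon
evidence table can lift a call to a wider clade (`absent` rows) or restrict
it to the largest named descendant still containing the absent species
(`present` rows — the model for "absent in the family but present
elsewhere in the order"). Presence in an unsampled sister lineage is
recorded at the nearest named ancestor clade in the taxonomy.

`missing_og_count` has two forms. The plain rule counts empty, unflagged
rows per species. With a taxonomy it counts only losses *proper to the
species* — absences whose maximal absent clade samples exactly that
species — attributing deeper (e.g. monocot-wide) losses to their clade;
this is how per-species loss counts are conventionally reported next to
clade-level calls.

Subfamily labels are recovered from OG ids by stripping a trailing hyphen
suffix that is either an integer or a Roman numeral (`OG-HAM-II` and
`OG-SCR-2` both strip), since historical naming uses both styles.

## Blocks, distances, trees

**Block selection** is a relaxed Gblocks-style procedure: a column is
conserved when its modal residue frequency (over all rows) reaches
`min_conserved_frac` (0.5) and its gap content satisfies the gap policy
(`none`/`half`/`all`, default `half` = at most 50% gaps). Runs of more than
`max_nonconserved_run` (8) non-conserved columns split the alignment;
flanks are trimmed to `min_flank_frac` quality; gap-violating columns are
excluded even inside blocks; final runs shorter than `min_block_length` (5)
are dropped. The defaults mirror the "relaxed" options of desk Gblocks use
(smaller final blocks, in-block gaps, less strict flanks). For locating the
conserved-domain start (`ANCHOR_BLOCK_PARAMS`: 0.7 / 0.85 / 4 / 10) a
stricter profile is needed, because sporadically conserved N-terminal
columns chain into relaxed blocks and drag the anchor into the disordered
region.

**Distances** are p-distances over kept, mutually ungapped columns,
optionally Poisson-corrected (`d = -ln(1-p)`); saturated pairs are clamped
at `p = 1 - 1/(2·columns)` before correction, and a pair with zero
comparable columns is an error.

**Neighbour joining** is the classical agglomeration with two deterministic
refinements: Q-criterion ties break by the lexicographically smallest pair
of cluster labels (a cluster's label is its smallest leaf name), and
negative limb lengths are clamped to zero with the deficit moved to the
sibling limb. On exactly additive matrices NJ returns the generating
topology and branch lengths (property-tested to 10 taxa). NJ plus bootstrap
stands in for maximum-likelihood inference with aLRT supports: the
pipeline's checks are consistency and recovery properties, not likelihoods,
and externally computed Newick trees can be supplied wherever a tree is
consumed. **Bootstrap supports** are the fraction of column-resampled NJ
replicates containing each split of the full-data tree.

**Monophyly checking** asks, per OG, whether an edge of the unrooted tree
separates exactly that leaf set; offending leaves are the minimal symmetric
difference against the best-matching split side. **The long-branch probe**
removes the longest-branch partner of a focal sequence and flags the
placement as a likely long-branch-attraction artifact when the focal
attachment (the set of adjacent-subtree leaf sets) changes. Comparing
attachment sets rather than a single "sister clade" avoids false flags from
tie-break flips when a removal changes subtree sizes.

## Motif discovery

Motifs are sought in N-terminal regions (explicit domain start first, MSA
anchor estimate second) under a **ZOOPS** model: with prior γ (initialised
0.8, re-estimated) a sequence carries one site at a uniform position,
otherwise pure background. EM restarts from the top 10 data words;
pseudocount 0.01 per residue makes the M-step a Dirichlet-MAP update, so
the monotone quantity asserted at every iteration is the penalised
objective (LLR + Dirichlet log-prior). Background frequencies are estimated
from the input.

Because the raw LLR objective is monotone-increasing in width, widths
compete on a null-standardised score — (LLR − null mean) / null sd over
`n_select_shuffles` shuffled refits at the same width — the shuffle-null
analogue of an E-value-based width choice. The winning candidate is kept
only if its LLR exceeds mean + 5 sd of a 100-shuffle null fitted with the
identical protocol at that width; accepted sites are masked with `X` and
the search repeats up to `n_motifs`. Everything is deterministic under a
fixed seed. Reported significance is this empirical shuffle null, not an
analytic E-value; published MEME p-values are therefore not comparable
quantities.

Member sequences whose best site log-odds falls below a caller-chosen
threshold are reported as exceptions ("motif missing in …").

## Subfamily grouping and naming

One representative per OG (smallest mean distance to its OG mates, from
Poisson-corrected global-alignment distances) is placed on an NJ tree.
Maximal clades with split support ≥ `support_min` (0.9; splits without a
support value count as supported) and diameter ≤ `depth_max` become
multi-OG subfamilies. The default `depth_max` is 0.7× the median pairwise
representative distance: the distance distribution is bimodal (shallow
within-subfamily pairs against a deep between-subfamily background that
dominates the median), and 0.7 of the background median falls in the gap.
Within multi-OG subfamilies, numbering is by descending gene count, then
smallest member id; a pinned-label table reproduces published numbering
(including Roman-numeral styles) exactly. These thresholds are declared
configuration, recorded in output provenance — subfamily boundaries are
acknowledged to be convention, not inference.

## The synthetic-data generator

The generator inverts the reconstructed history the pipeline assumes, and
is the ground-truth oracle for every stochastic test.

- **Species tree**: 8 taxa, unit branch lengths, one basal outgroup, named
  monocot (3 species) and dicot (4 species) clades — the shape of the
  curated panel; any binary, branch-lengthed Newick with named
  monocots/dicots clades can be substituted.
- **Ancestral structure**: 29 root genes drawn from 17 founder groups
  (sizes 3,2,2,3,2,2,4,2 and nine singletons — the published subfamily
  shape); root genes within a founder group are pre-split duplicates
  separated by `pre_split_divergence` = 3.0 unit branches each. This value
  keeps outgroup genes strictly closer to their own orthologs than to
  same-founder cousins (at 1.5 the two expected distances coincide and
  single-tree placements of outgroup sequences become ambiguous — the
  artifact class curated studies report for their full-panel trees).
- **Birth–death**: per-gene duplication 0.1 and loss 0.15 events per unit
  branch, simulated by exponential waiting times; duplications are labelled
  tandem or segmental (probability 0.5, event log only). One LISCL-like
  root gene is amplified and retained (duplication ×8, loss ×0.3), giving a
  median family share close to the published largest OG and making it the
  largest OG in ~95% of replicates. The stem branch between the outgroup
  split and the monocot/dicot split carries **no** birth–death events:
  events there would predate the anchor and found new OGs, contradicting
  the root-gene ground truth (and the reconstructed history, in which no
  duplication falls in that window). Forced clade-wide losses are applied
  after stochastic events.
- **Sequences**: per root gene, an N-terminal region (30–60 aa) evolving at
  0.6 substitutions/site per unit branch and a domain (100–160 aa) at 0.05
  — the 12× contrast renders the N-terminus effectively unalignable across
  the panel, as in the real family. Substitution follows a time-reversible
  model normalised to 1 sub/site/unit: uniform exchangeabilities over
  empirical amino-acid composition by default (an F81-style model; any
  symmetric exchangeability matrix can be supplied), with transition
  matrices by matrix exponential, cached per branch length. A geometric
  indel model for the N-terminus exists but is off by default so that
  within-OG records are positionally homologous (the "true alignment").
- **Motifs**: per-root-gene motif strings are written into carriers'
  N-termini at uniform positions in a window, mutated per site, after
  sequence evolution; non-carriers are recorded as ground-truth exceptions.
- Everything is bit-reproducible from the seed; ground truth carries the
  gene→OG map, count matrix, pruned gene trees, domain boundaries, motif
  sites and the event log.

**What the generator does not emulate** — and hence what green tests do not
show about real data: alignment uncertainty (true positional homology is
given), gene-model annotation errors and fragmentary proteins,
whole-genome-duplication events (the γ-hexaploidy analysis is out of
scope), rate heterogeneity across sites and lineages beyond the two-region
architecture, and codon-level or selective effects.

## Problem sizes used in benchmarks

Recovery benchmarks run at the study shape (29 root genes, 8 species,
~230 sequences of 130–220 aa): 25 replicates for orthogroup ARI and the
long-branch probe, 10–25 for subfamily recovery, two novel-species
datasets (~60 queries) for classification, 40 random additive matrices to
10 taxa for NJ, 12 trees × 6 label sets for monophyly, and 20 shuffled
controls for motif significance. At these sizes the full suite and the
acceptance script each run in minutes on a single core.

## Known limitations

- OG boundaries for duplications arbitrarily close to the anchor split are
  ambiguous in principle; the core-merge threshold decides them.
- Similarity-graph inference cannot strictly guarantee stability under
  species deletion (see above).
- The empirical motif null is exchangeable-shuffle based; compositional
  structure such as low-complexity runs can inflate apparent significance
  on real disordered regions.
- Published kept-position counts from specific alignment/filtering tool
  versions, exact motif strings and analytic p-values, and any
  synteny/WGD-based conclusions are outside what this package recomputes.
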