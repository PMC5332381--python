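import numpy as np
import pytest
from skbio import TreeNode

from ogfamily.blocks_phylo import (
    MSA,
    BlockParams,
    DistanceMatrix,
    SupportTree,
    bootstrap_support,
    check_og_monophyly,
    distance_matrix,
    lba_probe,
    nj_tree,
    select_blocks,
)
from ogfamily.datamodel import DataError
from ogfamily.simulate import DomainSpec, SimConfig, simulate_dataset


def random_tree_and_distances(n, seed):
    """Random binary unrooted tree with branch lengths and its exact
    path-distance matrix (the additive oracle)."""
    import random as _random
    rng = _random.Random(seed)
    nodes = [TreeNode(name=f"t{i}") for i in range(n)]
    while len(nodes) > 3:
        i, j = sorted(rng.sample(range(len(nodes)), 2), reverse=True)
        a, b = nodes.pop(i), nodes.pop(j)
        a.length = rng.uniform(0.5, 3.0)
        b.length = rng.uniform(0.5, 3.0)
        nodes.append(TreeNode(children=[a, b]))
    for x in nodes:
        x.length = rng.uniform(0.5, 3.0)
    root = TreeNode(children=nodes)
    ids = sorted(t.name for t in root.tips())
    dm = root.tip_tip_distances(endpoints=ids)
    return root, ids, np.asarray(dm.data)


# ---------------------------------------------------------------------------
# block selection
# ---------------------------------------------------------------------------

class TestSelectBlocks:
    def test_fully_conserved_msa_is_one_block(self):
        msa = MSA(["a", "b", "c"], ["MKTAYIAKQR"] * 3)
        sel = select_blocks(msa)
        assert sel.blocks == [(1, 10)]
        assert sel.kept_columns == list(range(10))

    def test_gap_policy_semantics(self):
        rows = ["MKTAY", "MKTAY", "MK-AY", "MK-AY", "MK-AY"]  # col 3: 60% gaps
        msa = MSA(list("abcde"), rows)
        kept_none = select_blocks(
            msa, BlockParams(gap_policy="none", min_block_length=1)).kept_columns
        kept_all = select_blocks(
            msa, BlockParams(gap_policy="all", min_block_length=1)).kept_columns
        assert 2 not in kept_none
        assert 2 in kept_all

    def test_planted_conserved_segment_recovered(self):
        rng = np.random.default_rng(42)
        aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        n, left, w, right = 12, 40, 20, 40
        planted = "".join(rng.choice(aa, w))
        rows = []
        for _ in range(n):
            rows.append("".join(rng.choice(aa, left)) + planted
                        + "".join(rng.choice(aa, right)))
        msa = MSA([f"s{i}" for i in range(n)], rows)
        sel = select_blocks(msa, BlockParams(min_conserved_frac=0.5,
                                             max_nonconserved_run=3))
        assert sel.kept_columns == list(range(left, left + w))

    def test_monotone_in_conservation_threshold(self):
        rng = np.random.default_rng(3)
        aa = np.array(list("ACDEFG"))
        msa = MSA([f"s{i}" for i in range(8)],
                  ["".join(rng.choice(aa, 80)) for _ in range(8)])
        prev = None
        for frac in (0.3, 0.5, 0.7, 0.9):
            kept = set(select_blocks(msa, BlockParams(min_conserved_frac=frac,
                                                      min_block_length=1,
                                                      max_nonconserved_run=2)).kept_columns)
            if prev is not None:
                assert kept <= prev
            prev = kept

    def test_min_block_length_validated(self):
        with pytest.raises(DataError):
            BlockParams(min_block_length=0)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

class TestDistances:
    def test_identical_rows_zero(self):
        msa = MSA(["a", "b"], ["MKTAY", "MKTAY"])
        d = distance_matrix(msa, None, "p")
        assert d.values[0, 1] == 0.0

    def test_half_different_closed_form(self):
        msa = MSA(["a", "b"], ["AAAA", "AACC"])
        dp = distance_matrix(msa, None, "p")
        assert dp.values[0, 1] == pytest.approx(0.5)
        dpo = distance_matrix(msa, None, "poisson")
        assert dpo.values[0, 1] == pytest.approx(-np.log(0.5))

    def test_symmetric_zero_diagonal_on_random_input(self):
        rng = np.random.default_rng(7)
        aa = np.array(list("ACDEFGHIKL"))
        msa = MSA([f"s{i}" for i in range(6)],
                  ["".join(rng.choice(aa, 50)) for _ in range(6)])
        d = distance_matrix(msa, None, "poisson")
        assert np.allclose(d.values, d.values.T)
        assert (np.diag(d.values) == 0).all()
        assert (d.values >= 0).all()

    def test_disjoint_gap_patterns_rejected(self):
        msa = MSA(["a", "b"], ["AA--", "--AA"])
        with pytest.raises(DataError, match="comparable"):
            distance_matrix(msa, None, "p")


# ---------------------------------------------------------------------------
# neighbour joining
# ---------------------------------------------------------------------------

class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = DistanceMatrix(["a", "b", "c"],
                           np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0]], float))
        t = nj_tree(d)
        lengths = {tip.name: tip.length for tip in t.tree.tips()}
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 4.0})

    def test_four_taxon_additive_recovery(self):
        # ((A:1,B:2):5,C:3,D:4) path distances
        D = np.array([[0, 3, 9, 10], [3, 0, 10, 11],
                      [9, 10, 0, 7], [10, 11, 7, 0]], float)
        t = nj_tree(DistanceMatrix(list("ABCD"), D))
        assert t.splits() == {frozenset({"C", "D"})}
        dm = t.tree.tip_tip_distances(endpoints=list("ABCD"))
        assert np.allclose(np.asarray(dm.data), D)

    @pytest.mark.parametrize("seed", range(15))
    def test_random_additive_matrices_inverted(self, seed):
        n = 4 + seed % 7  # up to 10 taxa
        true, ids, D = random_tree_and_distances(n, seed)
        got = nj_tree(DistanceMatrix(ids, D))
        assert got.splits() == SupportTree(tree=true).splits()
        dm = got.tree.tip_tip_distances(endpoints=ids)
        assert np.allclose(np.asarray(dm.data), D, atol=1e-9)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(DataError):
            nj_tree(DistanceMatrix(["a", "b"], np.zeros((2, 2))))

    def test_negative_branches_clamped(self):
        # a non-additive matrix that induces a negative limb estimate
        D = np.array([[0.0, 1.0, 1.0, 2.0],
                      [1.0, 0.0, 2.0, 1.0],
                      [1.0, 2.0, 0.0, 1.0],
                      [2.0, 1.0, 1.0, 0.0]])
        t = nj_tree(DistanceMatrix(list("abcd"), D))
        for node in t.tree.traverse(include_self=False):
            assert (node.length or 0.0) >= 0.0


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def clean_msa():
    cfg = SimConfig(n_root_genes=1, subfamily_sizes=(1,),
                    duplication_rate=0, loss_rate=0,
                    duplication_multipliers={}, loss_multipliers={}, seed=3,
                    domain_spec=DomainSpec(nterm_rate_multiplier=0.4,
                                           domain_rate_multiplier=0.1))
    records, _ = simulate_dataset(cfg)
    return MSA.from_records(records), cfg


class TestBootstrap:
    def test_clean_data_high_support_for_true_splits(self, clean_msa):
        msa, cfg = clean_msa
        st = bootstrap_support(msa, select_blocks(msa), n_replicates=100, seed=3)
        from ogfamily.datamodel import load_taxonomy
        tax = load_taxonomy(cfg.species_tree)
        id_of_sp = {r.split("_")[0]: r for r in msa.ids}
        leaves = frozenset(msa.ids)
        ref = min(leaves)
        for name in ("monocots", "dicots"):
            side = frozenset(id_of_sp[s] for s in tax.leafset(name))
            if ref in side:
                side = leaves - side
            if 2 <= len(side) <= len(leaves) - 2:
                assert st.supports[side] >= 0.9, name

    def test_same_seed_identical_supports(self, clean_msa):
        msa, _ = clean_msa
        sel = select_blocks(msa)
        a = bootstrap_support(msa, sel, n_replicates=25, seed=11)
        b = bootstrap_support(msa, sel, n_replicates=25, seed=11)
        assert a.supports == b.supports

    def test_supports_invariant_to_leaf_order(self, clean_msa):
        msa, _ = clean_msa
        rev = MSA(list(reversed(msa.ids)), list(reversed(msa.rows)))
        a = bootstrap_support(msa, select_blocks(msa), n_replicates=25, seed=5)
        b = bootstrap_support(rev, select_blocks(rev), n_replicates=25, seed=5)
        assert a.supports == b.supports


# ---------------------------------------------------------------------------
# orthogroup monophyly
# ---------------------------------------------------------------------------

def brute_force_monophyletic(tree: SupportTree, members: frozenset) -> bool:
    """Edge-removal oracle: members form a clade iff cutting some edge
    separates exactly that leaf set."""
    import networkx as nx

    g = nx.Graph()
    counter = [0]
    names = {}

    def build(node):
        counter[0] += 1
        me = counter[0]
        names[me] = node.name if node.is_tip() else None
        for child in node.children:
            cid = build(child)
            g.add_edge(me, cid)
        return me

    build(tree.tree)
    leaves = tree.leaves
    for edge in list(g.edges):
        g.remove_edge(*edge)
        comps = list(nx.connected_components(g))
        g.add_edge(*edge)
        for comp in comps:
            side = frozenset(names[n] for n in comp if names[n])
            if side == members or leaves - side == members:
                return True
    return False


class TestMonophyly:
    def test_caterpillar_contiguous_labels_consistent(self):
        st = SupportTree.from_newick(
            "(((((A:1,B:1):1,C:1):1,D:1):1,E:1):1,F:1);")
        rep = check_og_monophyly(st, {"A": "x", "B": "x", "C": "y", "D": "y",
                                      "E": "z", "F": "z"})
        assert rep["x"]["status"] == "consistent"

    def test_swapped_leaf_reported_with_offender(self):
        st = SupportTree.from_newick("((A:1,D:1):1,(C:1,B:1):1,(E:1,F:1):1);")
        rep = check_og_monophyly(st, {"A": "x", "B": "x", "C": "y", "D": "y",
                                      "E": "z", "F": "z"})
        assert rep["x"]["status"] == "split" and rep["y"]["status"] == "split"
        assert rep["z"]["status"] == "consistent"
        assert set(rep["x"]["offending"]) <= {"A", "B", "C", "D"}

    def test_unlabeled_leaf_rejected(self):
        st = SupportTree.from_newick("((A:1,B:1):1,C:1,D:1);")
        with pytest.raises(DataError):
            check_og_monophyly(st, {"A": "x", "B": "x", "C": "y"})

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_edge_removal_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        tree, ids, _ = random_tree_and_distances(n, seed)
        st = SupportTree(tree=tree)
        for _ in range(8):
            k = int(rng.integers(1, n))
            members = frozenset(rng.choice(ids, size=k, replace=False))
            labels = {i: ("in" if i in members else f"out_{i}") for i in ids}
            rep = check_og_monophyly(st, labels)
            expected = (len(members) <= 1 or len(members) == n
                        or brute_force_monophyletic(st, members))
            assert (rep["in"]["status"] == "consistent") == expected


# ---------------------------------------------------------------------------
# long-branch probe
# ---------------------------------------------------------------------------

def _lba_scenario(seed, accel, base=0.3):
    # Felsenstein-zone geometry: short internal branches, two independently
    # accelerated terminal lineages (the basal outgroup and one dicot)
    i = 0.3
    tree = ("(((Os:1.0,(Pd:1.0,Ma:1.0):%s)monocots:%s,"
            "(((At:%s,Tc:1.0):%s,Vv:1.0):%s,Cc:1.0)dicots:%s)mesangiosperms:%s,"
            "Amb:%s)root;" % (i, i, accel, i, i, i, i, accel))
    cfg = SimConfig(species_tree=tree, n_root_genes=1, subfamily_sizes=(1,),
                    duplication_rate=0.0, loss_rate=0.0,
                    duplication_multipliers={}, loss_multipliers={},
                    domain_spec=DomainSpec(nterm_rate_multiplier=2 * base,
                                           domain_rate_multiplier=base),
                    seed=seed)
    records, _ = simulate_dataset(cfg)
    msa = MSA.from_records(records)
    focal = next(r.id for r in records if r.species == "Amb")
    return msa, focal


class TestLbaProbe:
    def test_homogeneous_rates_not_flagged(self):
        flags = []
        for seed in range(400, 410):
            msa, focal = _lba_scenario(seed, accel=1.0)
            rep = lba_probe(msa, focal,
                            params=BlockParams(min_conserved_frac=0.25),
                            correction="p")
            flags.append(rep.lba_flag)
        assert sum(flags) <= 1

    def test_two_accelerated_lineages_usually_flagged(self):
        flags = []
        for seed in range(400, 425):
            msa, focal = _lba_scenario(seed, accel=5.0)
            rep = lba_probe(msa, focal,
                            params=BlockParams(min_conserved_frac=0.25),
                            correction="p")
            flags.append(rep.lba_flag)
        assert np.mean(flags) >= 0.8

    def test_too_few_taxa_rejected(self):
        msa = MSA(list("abcd"), ["MKTAY"] * 4)
        with pytest.raises(DataError):
            lba_probe(MSA(list("abc"), ["MKTAY"] * 3), "a")
        # removal of the partner would leave 3 taxa
        with pytest.raises(DataError):
            lba_probe(msa, "a")
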