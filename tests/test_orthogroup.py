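import itertools
import random

import pytest
from sklearn.metrics import adjusted_rand_score

from ogfamily.datamodel import DataError, ProteinRecord, load_taxonomy
from ogfamily.orthogroup import (
    HitTable,
    OrthogroupParams,
    build_orthogroups,
    classify_query,
    reciprocal_best_pairs,
)
from ogfamily.pairalign import Hit, ScoringScheme, all_pairs_scores
from ogfamily.simulate import SimConfig, simulate_dataset, registry_from_tree


def _table(rows):
    """rows: {gene: (species, [(target, score), ...])}"""
    species = {g: sp for g, (sp, _) in rows.items()}
    hits = {
        g: sorted((Hit(t, species[t], s) for t, s in lst),
                  key=lambda h: (-h.score, h.target))
        for g, (_, lst) in rows.items()
    }
    return HitTable(hits, species)


class TestReciprocalBestPairs:
    def test_mutual_top_hits_pair(self):
        ht = _table({
            "a": ("S", [("a", 100), ("b", 50)]),
            "b": ("T", [("b", 100), ("a", 50)]),
        })
        assert reciprocal_best_pairs(ht) == {frozenset({"a", "b"})}

    def test_non_reciprocal_excluded(self):
        # a's best in T is b, but b's best in S is c
        ht = _table({
            "a": ("S", [("b", 50), ("c", 10)]),
            "c": ("S", [("b", 60)]),
            "b": ("T", [("c", 60), ("a", 50)]),
        })
        assert frozenset({"a", "b"}) not in reciprocal_best_pairs(ht)
        assert frozenset({"b", "c"}) in reciprocal_best_pairs(ht)

    def test_single_copy_families_fully_recovered(self, scheme):
        cfg = SimConfig(seed=11, n_root_genes=6, subfamily_sizes=(1,) * 6,
                        duplication_rate=0.0, loss_rate=0.0,
                        duplication_multipliers={}, loss_multipliers={})
        records, truth = simulate_dataset(cfg)
        hits = HitTable.from_records(records, scheme)
        pairs = reciprocal_best_pairs(hits)
        expected = {
            frozenset({a.id, b.id})
            for a, b in itertools.combinations(records, 2)
            if a.species != b.species and truth.og_of[a.id] == truth.og_of[b.id]
        }
        assert pairs == expected


class TestBuildOrthogroups:
    def test_zero_rates_exact_recovery(self, scheme):
        cfg = SimConfig(seed=1, duplication_rate=0.0, loss_rate=0.0,
                        duplication_multipliers={}, loss_multipliers={})
        records, truth = simulate_dataset(cfg)
        reg = registry_from_tree(load_taxonomy(cfg.species_tree))
        hits = HitTable.from_records(records, scheme)
        ogs, unassigned = build_orthogroups(records, hits, reg)
        assert len(ogs) == 29 and not unassigned
        pred = {g: og.og_id for og in ogs for g in og.all_members}
        ari = adjusted_rand_score(
            [truth.og_of[r.id] for r in records],
            [pred[r.id] for r in records])
        assert ari == 1.0

    def test_partition_property(self, sim_default, sim_inference):
        _, records, _ = sim_default
        _, ogs, unassigned = sim_inference
        seen = set()
        for og in ogs:
            assert not (og.all_members & seen)
            seen |= og.all_members
        valid = {r.id for r in records if r.status == "valid"}
        assert seen | set(unassigned) == valid

    def test_determinism(self, sim_default, sim_registry, scheme, sim_inference):
        _, records, _ = sim_default
        hits = HitTable.from_records(records, scheme)
        ogs2, un2 = build_orthogroups(records, hits, sim_registry)
        _, ogs1, un1 = sim_inference
        assert un1 == un2
        assert [(o.og_id, sorted(o.all_members)) for o in ogs1] == \
               [(o.og_id, sorted(o.all_members)) for o in ogs2]

    def test_species_deletion_rarely_merges(self, sim_default, sim_registry,
                                            scheme, sim_inference):
        """Deleting a species can create complementary-absence artifacts, but
        previously-separated genes must almost never fuse."""
        _, records, _ = sim_default
        _, ogs_full, _ = sim_inference
        pred_full = {g: og.og_id for og in ogs_full for g in og.all_members}
        sub = [r for r in records if r.species != "Vv"]
        hits = HitTable.from_records(sub, scheme)
        ogs2, _ = build_orthogroups(sub, hits, sim_registry)
        pred2 = {g: og.og_id for og in ogs2 for g in og.all_members}
        ids = [r.id for r in sub if r.id in pred_full and r.id in pred2]
        merged = sum(
            1 for a, b in itertools.combinations(ids, 2)
            if pred_full[a] != pred_full[b] and pred2[a] == pred2[b]
        )
        n_pairs = len(ids) * (len(ids) - 1) // 2
        assert merged / n_pairs < 0.02

    def test_species_specific_tandem_pair_absorbed(self, scheme):
        cfg = SimConfig(seed=5, n_root_genes=4, subfamily_sizes=(1,) * 4,
                        duplication_rate=0.0, loss_rate=0.0,
                        duplication_multipliers={}, loss_multipliers={})
        records, truth = simulate_dataset(cfg)
        # duplicate one non-basal gene in place (post-speciation tandem copy)
        donor = next(r for r in records if r.species == "Vv")
        copy = ProteinRecord(id=donor.id + "_tandem", species="Vv",
                             sequence=donor.sequence,
                             domain_start=donor.domain_start)
        records = records + [copy]
        reg = registry_from_tree(load_taxonomy(cfg.species_tree))
        hits = HitTable.from_records(records, scheme)
        ogs, unassigned = build_orthogroups(records, hits, reg)
        pred = {g: og.og_id for og in ogs for g in og.all_members}
        assert pred[copy.id] == pred[donor.id]
        assert ogs[[o.og_id for o in ogs].index(pred[copy.id])].provenance[copy.id] == "in-paralog"

    def test_manual_override_wins(self, scheme):
        cfg = SimConfig(seed=5, n_root_genes=3, subfamily_sizes=(1,) * 3,
                        duplication_rate=0.0, loss_rate=0.0,
                        duplication_multipliers={}, loss_multipliers={})
        records, _ = simulate_dataset(cfg)
        reg = registry_from_tree(load_taxonomy(cfg.species_tree))
        hits = HitTable.from_records(records, scheme)
        target = records[0].id
        ogs, _ = build_orthogroups(records, hits, reg,
                                   manual_overrides={target: "CURATED"})
        og_of = {g: og for og in ogs for g in og.all_members}
        assert og_of[target].provenance[target] == "manual"
        assert og_of[target].all_members == {target}

    def test_missing_split_side_rejected(self, scheme):
        records = [ProteinRecord("g1", "Os", "MKTAYIAKQR"),
                   ProteinRecord("g2", "Ma", "MKTAYIAKQR")]
        reg = registry_from_tree(load_taxonomy(
            "(((Os:1,(Pd:1,Ma:1):1)monocots:1,(Vv:1,Cc:1)dicots:1)mesangiosperms:1,Amb:1)r;"))
        hits = HitTable.from_records(records, scheme)
        with pytest.raises(DataError, match="split"):
            build_orthogroups(records, hits, reg)

    def test_empty_records_rejected(self, scheme, sim_registry):
        with pytest.raises(DataError):
            build_orthogroups([], HitTable({}, {}), sim_registry)


@pytest.fixture(scope="module")
def reference(sim_default):
    _, records, truth = sim_default
    return [ProteinRecord(r.id, r.species, r.sequence,
                          og_id=f"T{truth.og_of[r.id]:02d}")
            for r in records]


@pytest.fixture(scope="module")
def ref_scores(reference, scheme):
    return all_pairs_scores(reference, scheme)


class TestClassifyQuery:
    def test_identical_query_returns_own_og(self, reference, scheme, ref_scores):
        member = reference[10]
        q = ProteinRecord("query", "Xx", member.sequence)
        res = classify_query(q, reference, scheme, ref_scores=ref_scores)
        assert res.og_id == member.og_id and res.reciprocal_ok
        assert res.margin >= 0

    def test_shuffled_query_unassigned(self, reference, scheme, ref_scores):
        rnd = random.Random(0)
        for k in (0, 50, 150):
            base = list(reference[k].sequence)
            rnd.shuffle(base)
            q = ProteinRecord(f"shuf{k}", "Xx", "".join(base))
            res = classify_query(q, reference, scheme, ref_scores=ref_scores)
            assert res.og_id == "unassigned"

    def test_novel_species_queries_recover_true_og(self, scheme):
        tree9 = ("(((Os:1.0,(Pd:1.0,Ma:1.0):1.0)monocots:1.0,"
                 "(((At:1.0,Tc:1.0):1.0,Vv:1.0):1.0,(Cc:0.5,Sl:0.5):0.5)dicots:1.0)"
                 "mesangiosperms:1.0,Amb:1.0)root;")
        cfg = SimConfig(species_tree=tree9, seed=2)
        records, truth = simulate_dataset(cfg)
        ref = [r for r in records if r.species != "Sl"]
        queries = [r for r in records if r.species == "Sl"]
        for r in ref:
            r.og_id = f"T{truth.og_of[r.id]:02d}"
        scores = all_pairs_scores(ref, scheme)
        ok = sum(
            classify_query(q, ref, scheme, ref_scores=scores).og_id
            == f"T{truth.og_of[q.id]:02d}"
            for q in queries
        )
        assert ok / len(queries) >= 0.95

    def test_empty_reference_rejected(self, scheme):
        with pytest.raises(DataError):
            classify_query(ProteinRecord("q", "Xx", "MKT"), [], scheme)

    def test_reference_without_og_rejected(self, scheme):
        ref = [ProteinRecord("r1", "Vv", "MKTAYIAK")]
        with pytest.raises(DataError):
            classify_query(ProteinRecord("q", "Xx", "MKT"), ref, scheme)

    def test_self_classification_complete(self, reference, scheme, ref_scores):
        """Every reference member classified against the reference returns
        its own OG (spot-checked on a deterministic subset)."""
        for k in range(0, len(reference), 23):
            member = reference[k]
            others = [r for r in reference]
            res = classify_query(
                ProteinRecord("probe_" + member.id, member.species, member.sequence),
                others, scheme, ref_scores=ref_scores)
            assert res.og_id == member.og_id
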