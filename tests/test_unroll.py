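"""Unrolling detection, scoring, ranking, and brute-force oracle equivalence."""

import itertools
import math
from pathlib import Path

import numpy as np
import pytest

from dynomics.errors import DynomicsError
from dynomics.network import EntityRef, TwoSliceNetwork, entity_adjacency, read_network_tsv, subset_types
from dynomics.unroll import (
    UnrollingRecord,
    find_full_chain_unrollings,
    find_unrollings,
    rank_unrollings,
    score_unrolling,
)

from conftest import build_network, entity, make_edge

DATA = Path(__file__).parent / "data"


def brute_force_unrollings(coarse, fine, include_self_loops=True):
    """Independent oracle: enumerate all (pair, mediator path) combinations."""
    added = subset_types(fine.subset_label) - subset_types(coarse.subset_label)
    cadj = entity_adjacency(coarse)
    fadj = entity_adjacency(fine)
    fine_entities = sorted({e for p in fadj for e in p})
    found = set()
    for (a, b) in cadj:
        if a == b and not include_self_loops:
            continue
        if (a, b) in fadj:
            continue
        for x in fine_entities:
            if x.omic_type not in added:
                continue
            if (a, x) in fadj and (x, b) in fadj:
                found.add((a, b, (x,)))
            if len(added) >= 2:
                for y in fine_entities:
                    if y.omic_type not in added or y.omic_type == x.omic_type:
                        continue
                    if (a, x) in fadj and (x, y) in fadj and (y, b) in fadj:
                        found.add((a, b, (x, y)))
    return found


def random_network(label, rng, n_per_type=4, p_edge=0.25):
    """Random entity-level network over the subset's types (+lag mix)."""
    types = sorted(subset_types(label))
    entities = [entity(f"{t[:1].upper()}{i}", t) for t in types for i in range(n_per_type)]
    net = TwoSliceNetwork(label)
    for src, dst in itertools.product(entities, repeat=2):
        if rng.random() < p_edge:
            lag = int(rng.integers(0, 2))
            if src == dst:
                lag = 1
            net.add_edge(
                make_edge(src, dst, lag=lag, weight=float(rng.normal()), score=float(rng.uniform(0.1, 1)))
            )
    return net


class TestConditions:
    def test_mediation_chain_worked_example(self):
        coarse = read_network_tsv(DATA / "net_T_mediation.tsv")
        fine = read_network_tsv(DATA / "net_TGM_mediation.tsv")
        records = find_unrollings(coarse, fine)
        two_step = [r for r in records if len(r.mediators) == 2]
        assert len(two_step) == 1
        rec = two_step[0]
        assert rec.coarse_src.name == "Eubacterium siraeum"
        assert rec.coarse_dst.name == "Bacteroides thetaiotaomicron"
        assert [m.name for m in rec.mediators] == ["uridine kinase", "cytidine"]
        assert rec.overall_score == pytest.approx(0.8 * 0.7 * 0.9)

    def test_self_loop_unrolls_through_mediators(self):
        coarse = read_network_tsv(DATA / "net_T_selfloop.tsv")
        fine = read_network_tsv(DATA / "net_TGM_selfloop.tsv")
        records = find_unrollings(coarse, fine)
        assert any(
            r.coarse_src == r.coarse_dst
            and r.coarse_src.name == "Bacteroides stercoris"
            and [m.name for m in r.mediators] == ["uridine kinase", "cytidine"]
            for r in records
        )

    def test_edge_retained_in_fine_blocks_unrolling(self):
        a, b = entity("A", "taxon"), entity("B", "taxon")
        m = entity("M", "metabolite")
        coarse = build_network("T", [(a, b, 1, 0.9)])
        fine = build_network("TM", [(a, b, 1, 0.9), (a, m, 0, 0.8), (m, b, 1, 0.8)])
        assert find_unrollings(coarse, fine) == []

    def test_reverse_fine_edge_does_not_block(self):
        a, b = entity("A", "taxon"), entity("B", "taxon")
        m = entity("M", "metabolite")
        coarse = build_network("T", [(a, b, 1, 0.9)])
        fine = build_network("TM", [(b, a, 1, 0.9), (a, m, 0, 0.8), (m, b, 1, 0.8)])
        assert len(find_unrollings(coarse, fine)) == 1

    def test_non_nested_subsets_rejected(self):
        coarse = build_network("T", [])
        fine = build_network("GM", [])
        with pytest.raises(DynomicsError):
            find_unrollings(coarse, fine)

    def test_emitted_records_satisfy_all_three_conditions(self, rng):
        for trial in range(20):
            coarse = random_network("T", rng)
            fine = random_network("TGM", rng)
            cadj = entity_adjacency(coarse)
            fadj = entity_adjacency(fine)
            for r in find_unrollings(coarse, fine):
                pair = (r.coarse_src, r.coarse_dst)
                assert pair in cadj  # condition 1
                assert pair not in fadj  # condition 2
                hops = [r.coarse_src, *r.mediators, r.coarse_dst]
                for s, d in zip(hops, hops[1:]):  # condition 3
                    assert (s, d) in fadj
                for m in r.mediators:
                    assert m.omic_type not in subset_types(coarse.subset_label)


class TestOracleEquivalence:
    @pytest.mark.parametrize("coarse_label,fine_label", [("T", "TM"), ("T", "TG"), ("T", "TGM"), ("G", "TG")])
    def test_matches_brute_force_on_random_networks(self, coarse_label, fine_label, rng):
        for trial in range(25):
            coarse = random_network(coarse_label, rng)
            fine = random_network(fine_label, rng)
            got = {
                (r.coarse_src, r.coarse_dst, r.mediators)
                for r in find_unrollings(coarse, fine)
            }
            assert got == brute_force_unrollings(coarse, fine)


class TestScoring:
    @pytest.mark.parametrize(
        "scores,expected",
        [((0.8, 0.5), 0.40), ((1.0, 1.0), 1.0), ((0.9, 0.8, 0.5), 0.36)],
    )
    def test_overall_is_product_of_replacement_scores(self, scores, expected):
        rec = _record(scores)
        assert score_unrolling(rec) == pytest.approx(expected)

    def test_overall_bounded_by_min_edge_score(self, rng):
        for _ in range(50):
            scores = tuple(rng.uniform(0, 1, size=int(rng.integers(2, 4))))
            assert score_unrolling(_record(scores)) <= min(scores) + 1e-12

    def test_ranking_order(self):
        recs = [
            _record((0.2,), support=1, names=("A", "B")),
            _record((0.9,), support=1, names=("A", "C")),
            _record((0.5,), support=1, names=("A", "D")),
        ]
        assert [r.overall_score for r in rank_unrollings(recs)] == [0.9, 0.5, 0.2]
        tied = [
            _record((0.5,), support=1, names=("A", "B")),
            _record((0.5,), support=3, names=("A", "C")),
        ]
        assert rank_unrollings(tied)[0].support_count == 3
        assert rank_unrollings([]) == []


def _record(scores, support=1, names=("A", "B")):
    a = entity(names[0], "taxon")
    b = entity(names[1], "taxon")
    m = entity("M", "metabolite")
    chain = (make_edge(a, m, 0, score=scores[0]), make_edge(m, b, 1, score=scores[-1]))
    return UnrollingRecord(
        coarse_src=a,
        coarse_dst=b,
        coarse_score=1.0,
        chain=chain,
        mediators=(m,),
        coarse_label="T",
        fine_label="TM",
        per_edge_scores=tuple(scores),
        overall_score=float(math.prod(scores)),
        support_count=support,
    )


class TestFullChains:
    def _nets(self, with_tm=True, with_tg=True):
        a, b = entity("A", "taxon"), entity("B", "taxon")
        g, m = entity("G", "gene"), entity("M", "metabolite")
        nets = {
            "T": build_network("T", [(a, b, 1, 0.9)]),
            "TGM": build_network("TGM", [(a, g, 0, 0.8), (g, m, 0, 0.7), (m, b, 1, 0.6)]),
        }
        if with_tm:
            nets["TM"] = build_network("TM", [(a, m, 0, 0.8), (m, b, 1, 0.9)])
        if with_tg:
            nets["TG"] = build_network("TG", [(a, g, 0, 0.8), (g, b, 1, 0.9)])
        return nets

    def test_support_counts_consistent_networks(self):
        records = find_full_chain_unrollings(self._nets())
        assert len(records) == 1
        rec = records[0]
        assert rec.support_count == 3  # TGM + TM + TG
        assert [m.omic_type for m in rec.mediators] == ["gene", "metabolite"]
        assert rec.overall_score == pytest.approx(0.8 * 0.7 * 0.6)

    def test_support_drops_without_consistent_coarser_networks(self):
        assert find_full_chain_unrollings(self._nets(with_tm=False))[0].support_count == 2
        assert find_full_chain_unrollings(self._nets(with_tm=False, with_tg=False))[0].support_count == 1

    def test_no_taxon_gene_edges_means_no_chains(self):
        a, b = entity("A", "taxon"), entity("B", "taxon")
        nets = {
            "T": build_network("T", [(a, b, 1, 0.9)]),
            "TGM": build_network("TGM", []),
        }
        assert find_full_chain_unrollings(nets) == []

    def test_missing_required_networks_named(self):
        with pytest.raises(DynomicsError, match="TGM"):
            find_full_chain_unrollings({"T": build_network("T", [])})
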