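"""Family scoring, per-child search, and bootstrap consensus semantics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from dynomics.errors import DynomicsError
from dynomics.learn import (
    LearnConfig,
    bootstrap_consensus,
    build_transition_rows,
    candidate_parent_sets,
    combine_bootstrap_networks,
    learn_dbn,
    score_family,
)
from dynomics.network import (
    Edge,
    EntityRef,
    NodeRef,
    TwoSliceNetwork,
    derive_subset_skeleton,
    validate_network,
)
from dynomics.preprocess import OmicsDataset

from conftest import entity, make_dataset


class TestCandidateParentSets:
    def test_binomial_count_for_five_parents_bound_three(self):
        taxa = [entity(f"T{i}", "taxon") for i in range(5)]
        child = NodeRef(taxa[0], 1)
        con = derive_subset_skeleton("skeleton", "T")
        sets = list(candidate_parent_sets(child, con, taxa, 3))
        assert len(sets) == 26  # 1 + 5 + 10 + 10

    def test_no_allowed_parents_yields_only_empty_set(self):
        taxa = [entity(f"T{i}", "taxon") for i in range(3)]
        child = NodeRef(entity("other", "taxon"), 1)
        con = derive_subset_skeleton("skeleton", "TGM")  # no taxon->taxon edges
        sets = list(candidate_parent_sets(child, con, taxa, 3))
        assert sets == [()]

    def test_bound_six_enumerates_sizes_up_to_six(self):
        taxa = [entity(f"T{i}", "taxon") for i in range(7)]
        child = NodeRef(taxa[0], 1)
        con = derive_subset_skeleton("skeleton", "T")
        sizes = {len(s) for s in candidate_parent_sets(child, con, taxa, 6)}
        assert sizes == set(range(7))

    def test_self_loop_parent_always_in_pool(self):
        g = entity("G1", "gene")
        con = derive_subset_skeleton("skeleton", "TGM")
        singles = [s[0] for s in candidate_parent_sets(NodeRef(g, 1), con, [g], 1) if s]
        assert NodeRef(g, 0) in singles


class TestScoreFamily:
    def test_true_parent_beats_empty_family_noiseless(self, rng):
        x = rng.normal(size=200)
        y = 0.7 * x
        assert score_family(y, x[:, None]) > score_family(y, None)

    def test_bic_rejects_spurious_parent_in_most_replicates(self):
        wins = 0
        n_rep = 40
        for r in range(n_rep):
            rng = np.random.default_rng(1000 + r)
            y = rng.normal(size=500)
            x = rng.normal(size=500)
            if score_family(y, None) > score_family(y, x[:, None]):
                wins += 1
        assert wins / n_rep >= 0.95

    def test_empty_family_matches_closed_form(self, rng):
        y = rng.normal(size=64)
        n = len(y)
        sigma2 = y.var()
        expected = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1) - 0.5 * 2 * np.log(n)
        assert score_family(y, None) == pytest.approx(expected)

    def test_too_few_rows_raises(self):
        with pytest.raises(DynomicsError):
            score_family(np.zeros(3), np.zeros((3, 2)))


def _grid_dataset(values: dict[EntityRef, np.ndarray], n_subjects=1) -> OmicsDataset:
    """Wrap per-entity value arrays (shared across subjects) as a 7-day grid dataset."""
    rows = []
    for s in range(n_subjects):
        for ent, vals in values.items():
            for t, v in enumerate(np.asarray(vals)):
                rows.append(
                    dict(
                        subject=f"s{s}",
                        time=7.0 * t,
                        entity=ent.name,
                        omic_type=ent.omic_type,
                        value=float(v),
                        has_compound_id=True,
                    )
                )
    return OmicsDataset(pd.DataFrame(rows))


class TestLearnDbn:
    def _random_dataset(self, rng, n_time=40):
        ents = (
            [entity(f"T{i}", "taxon") for i in range(2)]
            + [entity(f"G{i}", "gene") for i in range(2)]
            + [entity(f"M{i}", "metabolite") for i in range(2)]
        )
        return _grid_dataset({e: rng.uniform(0.1, 1.0, size=n_time) for e in ents})

    def test_per_child_choice_equals_exhaustive_enumeration(self, rng):
        """Oracle equivalence on 6-entity problems with max_parents 2."""
        for trial in range(5):
            ds = self._random_dataset(rng)
            config = LearnConfig(subset_label="TGM", max_parents=2, transform="none", seed=0)
            net = learn_dbn(ds, config)
            data = build_transition_rows(ds, transform="none")
            con = config.constraint()
            entities = ds.entities()
            for ent in entities:
                child = NodeRef(ent, 1)
                y = data.columns[child]
                best, best_score = (), score_family(y, None)
                for combo in candidate_parent_sets(child, con, entities, 2):
                    if not combo:
                        continue
                    X = np.column_stack([data.columns[p] for p in combo])
                    s = score_family(y, X)
                    if s > best_score:
                        best, best_score = combo, s
                chosen = tuple(
                    sorted(e.src for e in net.edges if e.dst == child)
                )
                assert chosen == tuple(sorted(best)), f"child {ent}"

    def test_all_constant_data_learns_no_edges(self):
        ents = [entity("T0", "taxon"), entity("T1", "taxon")]
        ds = _grid_dataset({e: np.full(20, 0.5) for e in ents})
        net = learn_dbn(ds, LearnConfig(subset_label="T", seed=0))
        assert len(net) == 0

    def test_learned_network_is_skeleton_compliant(self, rng):
        ds = self._random_dataset(rng)
        config = LearnConfig(subset_label="TGM", max_parents=2, seed=0)
        net = learn_dbn(ds, config)
        assert validate_network(net, config.constraint()) == []

    def test_subset_mismatch_rejected(self, rng):
        ds = self._random_dataset(rng)
        with pytest.raises(DynomicsError, match="outside subset"):
            learn_dbn(ds, LearnConfig(subset_label="T"))

    def test_empty_dataset_rejected(self):
        ds = make_dataset([("s1", 0.0, "A", "taxon", 1.0)])
        ds = OmicsDataset(ds.frame.iloc[0:0])
        with pytest.raises(DynomicsError):
            learn_dbn(ds, LearnConfig(subset_label="T"))


def _edge(name_a, name_b, weight):
    a, b = entity(name_a, "taxon"), entity(name_b, "taxon")
    return Edge(NodeRef(a, 0), NodeRef(b, 1), weight, 1.0)


class TestConsensusSemantics:
    def _reps(self):
        """100 repetition networks: edge A->B in all, C->D in 9, E->F in 10."""
        reps = []
        for r in range(100):
            net = TwoSliceNetwork("T")
            net.add_edge(_edge("A", "B", 0.3 + (0.1 if r % 2 else -0.1)))
            if r < 9:
                net.add_edge(_edge("C", "D", 1.0))
            if r < 10:
                net.add_edge(_edge("E", "F", 0.5))
            reps.append(net)
        return reps

    def test_support_threshold_and_weight_averaging(self):
        consensus = combine_bootstrap_networks(self._reps(), min_support=0.10)
        edges = {(e.src.entity.name, e.dst.entity.name): e for e in consensus.edges}
        assert edges[("A", "B")].bootstrap_score == 1.0
        assert edges[("A", "B")].weight == pytest.approx(0.3)  # mean over occurrences
        assert ("C", "D") not in edges  # 9/100 < 10%
        assert edges[("E", "F")].bootstrap_score == pytest.approx(0.10)  # boundary kept
        assert edges[("E", "F")].weight == pytest.approx(0.5)

    def test_every_consensus_edge_respects_support_bounds(self):
        consensus = combine_bootstrap_networks(self._reps(), min_support=0.10)
        for e in consensus.edges:
            assert 0.10 <= e.bootstrap_score <= 1.0

    def test_bootstrap_is_deterministic_and_needs_two_subjects(self, rng):
        ents = [entity("T0", "taxon"), entity("T1", "taxon")]
        ds = _grid_dataset({e: rng.uniform(0.1, 1, 12) for e in ents}, n_subjects=3)
        config = LearnConfig(subset_label="T", n_bootstrap=8, seed=5)
        assert bootstrap_consensus(ds, config) == bootstrap_consensus(ds, config)
        single = OmicsDataset(ds.frame[ds.frame.subject == "s0"])
        with pytest.raises(DynomicsError):
            bootstrap_consensus(single, config)
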