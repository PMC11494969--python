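"""Typed network representation, skeleton constraints, and edge-list I/O."""

import pytest

from dynomics.errors import InvalidLagError, NetworkFormatError
from dynomics.network import (
    Edge,
    EntityRef,
    NodeRef,
    TwoSliceNetwork,
    derive_subset_skeleton,
    entity_adjacency,
    is_allowed_edge,
    load_constraint_yaml,
    read_network_tsv,
    save_constraint_yaml,
    to_networkx,
    validate_network,
    write_graphml,
    write_network_tsv,
)

from conftest import build_network, entity, make_edge


class TestTypes:
    def test_entity_identity_is_name_and_type(self):
        assert entity("A", "taxon") == entity("A", "taxon")
        assert entity("A", "taxon") != entity("A", "gene")
        assert entity("a", "taxon") != entity("A", "taxon")  # case-sensitive

    @pytest.mark.parametrize("bad", [("", "taxon"), ("A", "protein")])
    def test_invalid_entities_rejected(self, bad):
        with pytest.raises(ValueError):
            EntityRef(*bad)

    def test_node_slice_restricted(self):
        with pytest.raises(ValueError):
            NodeRef(entity("A", "taxon"), 2)

    def test_edge_lag_and_score_validated(self):
        a, b = entity("A", "taxon"), entity("B", "taxon")
        with pytest.raises(InvalidLagError):
            Edge(NodeRef(a, 1), NodeRef(b, 0), 0.5)  # lag -1
        with pytest.raises(ValueError):
            Edge(NodeRef(a, 0), NodeRef(b, 1), 0.5, bootstrap_score=1.5)

    def test_network_rejects_duplicates_and_label_mismatch(self):
        a, b = entity("A", "taxon"), entity("B", "taxon")
        net = TwoSliceNetwork("T", [make_edge(a, b, 1)])
        with pytest.raises(ValueError, match="duplicate"):
            net.add_edge(make_edge(a, b, 1))
        with pytest.raises(ValueError, match="not.*consistent|consistent"):
            net.add_edge(make_edge(entity("G", "gene"), b, 1))


@pytest.fixture(scope="module")
def tgm():
    return derive_subset_skeleton("skeleton", "TGM")


class TestSkeleton:
    @pytest.mark.parametrize(
        "src,dst,lag,expect",
        [
            ("taxon", "gene", 0, True),        # taxa express their genes
            ("gene", "metabolite", 0, True),   # genes synthesize metabolites
            ("gene", "taxon", 0, False),       # direct gene -> taxa disallowed
            ("metabolite", "taxon", 1, True),  # metabolites feed back next step
            ("taxon", "metabolite", 0, False), # skeleton variant: not allowed
            ("taxon", "taxon", 1, False),      # no direct taxon shortcut in TGM
            ("gene", "taxon", 1, False),
            ("metabolite", "gene", 0, False),
        ],
    )
    def test_tgm_skeleton_table(self, tgm, src, dst, lag, expect):
        assert is_allowed_edge(tgm, src, dst, lag) is expect

    def test_self_loops_always_allowed(self, tgm):
        for t in ("taxon", "gene", "metabolite", "clinical"):
            assert is_allowed_edge(tgm, t, t, 1, is_self=True)

    def test_invalid_lag_raises(self, tgm):
        with pytest.raises(InvalidLagError):
            is_allowed_edge(tgm, "taxon", "gene", 2)

    def test_augmented_adds_exactly_taxon_to_metabolite_intra(self):
        sk = derive_subset_skeleton("skeleton", "TGM").allowed
        aug = derive_subset_skeleton("augmented", "TGM").allowed
        diff = {k for k in aug if aug[k] != sk[k]}
        assert diff == {("taxon", "metabolite", 0)}

    @pytest.mark.parametrize(
        "label,allowed_triples",
        [
            ("T", [("taxon", "taxon", 1)]),
            ("TM", [("taxon", "metabolite", 0), ("metabolite", "taxon", 1)]),
            ("TG", [("taxon", "gene", 0), ("gene", "taxon", 1)]),
            ("G", [("gene", "gene", 1)]),
            ("M", [("metabolite", "metabolite", 1)]),
            ("GM", [("gene", "metabolite", 0), ("metabolite", "gene", 1)]),
        ],
    )
    def test_reduced_subsets_bridge_absent_layers(self, label, allowed_triples):
        con = derive_subset_skeleton("skeleton", label)
        for triple in allowed_triples:
            assert con.allowed[triple], triple
        # no same-type intra shortcuts appear from bridging
        for t in ("taxon", "gene", "metabolite"):
            assert not con.allowed[(t, t, 0)]

    def test_tm_forbids_taxon_taxon_shortcut(self):
        con = derive_subset_skeleton("skeleton", "TM")
        assert not con.allowed[("taxon", "taxon", 1)]

    def test_unknown_subset_rejected(self):
        with pytest.raises(ValueError):
            derive_subset_skeleton("skeleton", "TX")

    def test_clinical_is_lag1_source_never_intra_destination(self):
        con = derive_subset_skeleton("skeleton", "TGM")
        assert con.allowed[("clinical", "taxon", 1)]
        assert con.allowed[("clinical", "gene", 1)]
        assert not con.allowed[("taxon", "clinical", 0)]
        assert not con.allowed[("clinical", "taxon", 0)]


class TestValidateAndCollapse:
    def test_compliant_and_empty_networks_pass(self):
        con = derive_subset_skeleton("skeleton", "TGM")
        t, g = entity("A", "taxon"), entity("B", "gene")
        net = build_network("TGM", [(t, g, 0, 1.0)])
        assert validate_network(net, con) == []
        assert validate_network(TwoSliceNetwork("TGM"), con) == []

    def test_gene_to_taxon_intra_flagged(self):
        con = derive_subset_skeleton("skeleton", "TGM")
        t, g = entity("A", "taxon"), entity("B", "gene")
        net = build_network("TGM", [(g, t, 0, 1.0)])
        violations = validate_network(net, con)
        assert len(violations) == 1
        assert violations[0].edge.src.entity == g

    def test_entity_adjacency_keeps_max_score_on_lag_ties(self):
        a, b = entity("A", "taxon"), entity("B", "metabolite")
        aug = build_network(
            "TM",
            [make_edge(a, b, lag=0, score=0.3), make_edge(a, b, lag=1, score=0.8)],
        )
        adj = entity_adjacency(aug)
        assert adj[(a, b)].bootstrap_score == 0.8

    def test_entity_adjacency_self_loop_and_empty(self):
        a = entity("A", "taxon")
        net = build_network("T", [make_edge(a, a, 1)])
        assert set(entity_adjacency(net)) == {(a, a)}
        assert entity_adjacency(TwoSliceNetwork("T")) == {}


class TestNetworkIO:
    def _sample(self):
        t, g, m = entity("A b", "taxon"), entity("g1", "gene"), entity("m-1", "metabolite")
        return build_network(
            "TGM",
            [
                make_edge(t, g, 0, score=0.25),
                make_edge(g, m, 0, score=1.0),
                make_edge(m, t, 1, score=0.5),
                make_edge(t, t, 1, score=0.9),
            ],
        )

    def test_round_trip_identity(self, tmp_path):
        for net in (self._sample(), TwoSliceNetwork("T")):
            p = tmp_path / f"{net.subset_label}.tsv"
            write_network_tsv(net, p)
            assert read_network_tsv(p) == net

    def test_header_only_file_is_empty_network(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text(
            "src_name\tsrc_type\tsrc_slice\tdst_name\tdst_type\tdst_slice\tweight\tbootstrap_score\n"
        )
        net = read_network_tsv(p, subset_label="T")
        assert len(net) == 0

    @pytest.mark.parametrize(
        "row",
        [
            "A\ttaxon\t0\tB\ttaxon\t1\t0.5",  # wrong column count
            "A\ttaxon\t0\tB\ttaxon\t1\tx\t0.5",  # non-numeric weight
            "A\ttaxon\t0\tB\ttaxon\t1\t0.5\t1.5",  # score outside [0,1]
            "A\ttaxon\t1\tB\ttaxon\t0\t0.5\t0.5",  # negative lag
        ],
    )
    def test_malformed_rows_name_line_number(self, tmp_path, row):
        p = tmp_path / "bad.tsv"
        p.write_text(
            "src_name\tsrc_type\tsrc_slice\tdst_name\tdst_type\tdst_slice\tweight\tbootstrap_score\n"
            + row
            + "\n"
        )
        with pytest.raises(NetworkFormatError, match="line 2"):
            read_network_tsv(p, subset_label="T")

    def test_graphml_export(self, tmp_path):
        net = self._sample()
        g = to_networkx(net)
        assert g.number_of_edges() == len(net)
        write_graphml(net, tmp_path / "net.graphml")
        assert (tmp_path / "net.graphml").stat().st_size > 0

    def test_constraint_yaml_round_trip(self, tmp_path):
        con = derive_subset_skeleton("augmented", "TM")
        p = tmp_path / "con.yaml"
        save_constraint_yaml(con, p)
        back = load_constraint_yaml(p)
        assert back.variant == con.variant
        assert back.subset_label == con.subset_label
        assert dict(back.allowed) == dict(con.allowed)
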