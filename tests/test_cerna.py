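"""Correlation filtering, negative pairs and ceRNA network assembly."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cernet.cerna import (
    build_network,
    correlate,
    export_network,
    import_network,
    load_reference_negative_pairs,
    negative_pair_marginals,
    negative_pairs,
    negative_pairs_table,
)
from cernet.degradome import CleavageEvent
from cernet.expression import DEResult, ExpressionMatrix
from cernet.targeting import DuplexAlignment, TargetSite


def matrix(rows, tissue="leaf"):
    values = pd.DataFrame(
        list(rows.values()),
        index=list(rows),
        columns=[f"{tissue}_{c}_{r}" for c in ("ck", "st") for r in (1, 2, 3)],
    )
    samples = pd.DataFrame(
        [(tissue, c, r) for c in ("ck", "st") for r in (1, 2, 3)],
        index=values.columns,
        columns=["tissue", "condition", "replicate"],
    )
    return ExpressionMatrix(values, samples, "raw_count")


def site(mid, tid, mode="cleavage"):
    d = DuplexAlignment(mid, tid, (1, 21), ["WC"] * 21, [], mode, 0.0 if mode == "cleavage" else None)
    return TargetSite(d, 12 if mode == "cleavage" else None)


def de(fid, direction, tissue="leaf", cls="gene_like"):
    lfc = {"up": 2.0, "down": -2.0, "ns": 0.0}[direction]
    p = 0.001 if direction != "ns" else 0.9
    return DEResult(fid, tissue, lfc, p, direction, cls)


class TestCorrelate:
    def test_identical_series_r_one(self):
        m = matrix({"a": [1, 2, 3, 10, 11, 12], "b": [1, 2, 3, 10, 11, 12]})
        assert correlate(m, "a", m, "b", "leaf") == pytest.approx(1.0)

    def test_reciprocal_series_r_minus_one(self):
        a = np.array([1.0, 2, 4, 8, 16, 32])
        m = matrix({"a": a, "b": 64 / a})  # log-space negation
        assert correlate(m, "a", m, "b", "leaf") == pytest.approx(-1.0)

    def test_constant_series_flagged_nan(self):
        m = matrix({"a": [5] * 6, "b": [1, 2, 3, 4, 5, 6]})
        assert math.isnan(correlate(m, "a", m, "b", "leaf"))


class TestNegativePairs:
    events = [CleavageEvent("m1", "t1", 12, 50.0, 0, 0.001)]

    def test_opposite_directions_with_event_flagged_y(self):
        recs = negative_pairs(
            [de("m1", "up", cls="mirna")], [de("t1", "down")], [site("m1", "t1")], self.events, "leaf"
        )
        (r,) = recs
        assert (r.mirna_direction, r.transcript_direction, r.degradome_flag) == ("up", "down", "Y")

    def test_same_direction_is_not_a_pair(self):
        recs = negative_pairs(
            [de("m1", "up", cls="mirna")], [de("t1", "up")], [site("m1", "t1")], self.events, "leaf"
        )
        assert recs == []

    def test_pair_without_event_flagged_n(self):
        recs = negative_pairs(
            [de("m2", "up", cls="mirna")], [de("t2", "down")], [site("m2", "t2")], self.events, "leaf"
        )
        assert recs[0].degradome_flag == "N"

    def test_table_has_published_column_layout(self):
        recs = negative_pairs(
            [de("m1", "up", cls="mirna")], [de("t1", "down")], [site("m1", "t1")], self.events, "leaf"
        )
        table = negative_pairs_table(recs)
        assert list(table.columns) == [
            "miR_name", "up/down", "Transcript", "up/down", "Tissue", "Degradome Detection",
        ]


def triplet_fixture():
    """miRNA anti-correlated with two positively correlated ceRNAs."""
    ce = [100, 110, 90, 800, 810, 790]
    anti = [800, 810, 790, 100, 110, 90]
    gene = matrix({"t1": ce, "t2": [x + 5 for x in ce], "t3": [200] * 6, "weak": [100, 200, 50, 120, 80, 160]})
    mirna = matrix({"m1": anti})
    des = [
        de("m1", "up", cls="mirna"),
        de("t1", "down"),
        de("t2", "down"),
        de("weak", "down"),
    ]
    sites = [site("m1", "t1"), site("m1", "t2", "mimic"), site("m1", "weak")]
    classes = {"t1": "mRNA", "t2": "lncRNA", "t3": "mRNA", "weak": "mRNA"}
    return des, classes, sites, gene, mirna


class TestBuildNetwork:
    def test_planted_triplet_connected_via_mirna(self):
        des, classes, sites, gene, mirna = triplet_fixture()
        net = build_network(des, classes, sites, gene, mirna, "leaf")
        assert net.has_edge("m1", "t1") and net.has_edge("m1", "t2")
        assert net.nodes["t2"]["kind"] == "lncRNA"
        assert net.edges["m1", "t2"]["mode"] == "mimic"

    def test_weak_correlation_edge_dropped(self):
        des, classes, sites, gene, mirna = triplet_fixture()
        net = build_network(des, classes, sites, gene, mirna, "leaf")
        assert not net.has_edge("m1", "weak")  # r well above -0.7

    def test_non_de_features_never_appear(self):
        des, classes, sites, gene, mirna = triplet_fixture()
        sites = sites + [site("m1", "t3")]
        net = build_network(des, classes, sites, gene, mirna, "leaf")
        assert "t3" not in net  # t3 has no DE call

    def test_edge_count_monotone_in_threshold(self):
        des, classes, sites, gene, mirna = triplet_fixture()
        counts = [
            build_network(des, classes, sites, gene, mirna, "leaf", r_threshold=t).number_of_edges()
            for t in (0.5, 0.7, 0.9, 0.99)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_pair_positivity_prunes_lone_cerna(self):
        des, classes, sites, gene, mirna = triplet_fixture()
        lone = build_network(des, classes, [site("m1", "t1")], gene, mirna, "leaf")
        assert lone.number_of_edges() == 0  # no competing partner
        off = build_network(
            des, classes, [site("m1", "t1")], gene, mirna, "leaf", require_pair_positivity=False
        )
        assert off.has_edge("m1", "t1")

    def test_degradome_verified_flag_propagates(self):
        des, classes, sites, gene, mirna = triplet_fixture()
        events = [CleavageEvent("m1", "t1", 12, 50.0, 0, 0.001)]
        net = build_network(des, classes, sites, gene, mirna, "leaf", events)
        assert net.edges["m1", "t1"]["degradome_verified"]
        assert not net.edges["m1", "t2"]["degradome_verified"]

    def test_empty_de_sets_give_empty_network(self):
        _, classes, sites, gene, mirna = triplet_fixture()
        net = build_network([], classes, sites, gene, mirna, "leaf")
        assert net.number_of_nodes() == 0


class TestExportNetwork:
    def test_graphml_round_trip_preserves_attributes(self, tmp_path):
        des, classes, sites, gene, mirna = triplet_fixture()
        net = build_network(des, classes, sites, gene, mirna, "leaf")
        path = tmp_path / "net.graphml"
        export_network(net, path)
        again = import_network(path)
        assert set(again.nodes) == set(net.nodes)
        for u, v, data in net.edges(data=True):
            assert again.edges[u, v]["r"] == pytest.approx(data["r"])
            assert again.edges[u, v]["mode"] == data["mode"]
            assert again.edges[u, v]["degradome_verified"] == data["degradome_verified"]

    def test_empty_network_is_valid_graphml(self, tmp_path):
        path = tmp_path / "empty.graphml"
        export_network(nx.Graph(tissue="leaf", r_threshold=0.7, relaxed=False), path)
        assert import_network(path).number_of_nodes() == 0

    def test_tsv_export_and_unknown_format(self, tmp_path):
        des, classes, sites, gene, mirna = triplet_fixture()
        net = build_network(des, classes, sites, gene, mirna, "leaf")
        export_network(net, tmp_path / "net.tsv", format="tsv")
        df = pd.read_csv(tmp_path / "net.tsv", sep="\t")
        assert len(df) == net.number_of_edges()
        with pytest.raises(ValueError):
            export_network(net, tmp_path / "x", format="xml")


class TestReferenceTable:
    def test_marginals_match_published_counts(self):
        table = load_reference_negative_pairs()
        m = negative_pair_marginals(table)
        assert m == {"n_leaf": 16, "n_root": 17, "n_degradome_verified": 11, "n_total": 33}

    def test_every_row_is_a_negative_pair(self):
        table = load_reference_negative_pairs()
        assert (table["miR_direction"] != table["transcript_direction"]).all()
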