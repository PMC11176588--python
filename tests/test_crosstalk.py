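"""Pathway cross-talk detection, including a literal brute-force oracle.

The oracle below evaluates the two bridging criteria by exhaustive
quantifier enumeration over gene-pair combinations, independently of the
adjacency-based implementation.
"""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from xtalk.coexpression import CoexpressionNetwork, canonical_pair
from xtalk.crosstalk import (
    BRIDGE_PAIR,
    EXCLUSIVE_A,
    EXCLUSIVE_B,
    GMTError,
    NEITHER,
    SHARED,
    SHARED_GENE,
    PathwayCollection,
    build_crosstalk_network,
    classify_gene,
    detect_crosstalk,
    filter_pathways,
    read_gmt,
)

# ---------------------------------------------------------------------------
# brute-force oracle


def oracle_crit_i(a, b, pairs):
    plist = sorted(pairs)
    for p1, p2 in itertools.combinations(plist, 2):
        for gi, gj in (p1, p1[::-1]):
            for gp, gq in (p2, p2[::-1]):
                if (
                    gi in a and gi not in b and gp in a and gp not in b
                    and gj in b and gj not in a and gq in b and gq not in a
                ):
                    return True
    return False


def oracle_crit_ii(a, b, pairs):
    genes = {g for p in pairs for g in p}
    for gk, gl, gm in itertools.product(genes, repeat=3):
        if len({gk, gl, gm}) < 3:
            continue
        if canonical_pair(gk, gl) in pairs and canonical_pair(gl, gm) in pairs:
            if (
                gk in a and gk not in b
                and gl in a and gl in b
                and gm in b and gm not in a
            ):
                return True
    return False


def oracle_has_crosstalk(a, b, pairs):
    return oracle_crit_i(a, b, pairs) or oracle_crit_ii(a, b, pairs)


# ---------------------------------------------------------------------------


class TestReadGmt:
    def test_basic_line(self, tmp_path):
        p = tmp_path / "x.gmt"
        p.write_text("P1\tdesc\ta\tB\nP2\td2\tC\tC\tD\n")
        pc = read_gmt(p)
        assert pc.pathways["P1"] == {"A", "B"}
        assert pc.pathways["P2"] == {"C", "D"}

    def test_short_line_errors_with_line_number(self, tmp_path):
        p = tmp_path / "x.gmt"
        p.write_text("P1\tdesc\tA\nP2\tdesc\n")
        with pytest.raises(GMTError, match=":2"):
            read_gmt(p)

    def test_empty_file_gives_empty_collection(self, tmp_path):
        p = tmp_path / "x.gmt"
        p.write_text("")
        assert len(read_gmt(p)) == 0


class TestFilterPathways:
    def _pc(self, sets, categories=None):
        return PathwayCollection(
            {k: frozenset(v) for k, v in sets.items()}, categories=categories or {}
        )

    def test_min_gene_rule(self):
        pc = self._pc(
            {
                "SMALL": "ABCD",
                "BIG1": "ABCDEF",
                "BIG2": "CDEFGH",
            }
        )
        out = filter_pathways(pc, set("ABCDEFGH"), min_genes=5)
        assert "SMALL" not in out
        assert {"BIG1", "BIG2"} <= set(out.pathways)

    def test_excluded_category(self):
        pc = self._pc(
            {"DIS": "ABCDE", "OK1": "ABCDE", "OK2": "DEFGH"},
            categories={"DIS": "human disease"},
        )
        out = filter_pathways(pc, set("ABCDEFGH"), excluded_categories=["human disease"])
        assert "DIS" not in out

    def test_overlap_retention_drops_isolated_pathways(self):
        # P1/P2 share one gene only; P3 overlaps nothing by >=2 genes
        pc = self._pc({"P1": "ABCDE", "P2": "EFGHI", "P3": "JKLMN"})
        out = filter_pathways(pc, set("ABCDEFGHIJKLMN"))
        assert len(out) == 0
        pc2 = self._pc({"P1": "ABCDE", "P2": "DEFGH", "P3": "JKLMN"})
        out2 = filter_pathways(pc2, set("ABCDEFGHIJKLMN"))
        assert set(out2.pathways) == {"P1", "P2"}

    def test_universe_intersection_applies_before_min_genes(self):
        pc = self._pc({"P1": "ABCDEFXY", "P2": "CDEFGH"})
        out = filter_pathways(pc, set("ABCDEFGH"), min_genes=5)
        assert out.pathways["P1"] == set("ABCDEF")


class TestClassifyGene:
    A = frozenset({"X", "S"})
    B = frozenset({"Y", "S"})

    @pytest.mark.parametrize(
        "gene,expected",
        [("S", SHARED), ("X", EXCLUSIVE_A), ("Y", EXCLUSIVE_B), ("Z", NEITHER)],
    )
    def test_roles(self, gene, expected):
        assert classify_gene(gene, self.A, self.B) == expected


class TestDetectCrosstalk:
    A = frozenset({"A1", "A2", "S"})
    B = frozenset({"B1", "B2", "S"})

    def test_two_bridge_pairs(self):
        ev = detect_crosstalk(self.A, self.B, [("A1", "B1"), ("A2", "B2")])
        assert ev is not None and ev.criterion == BRIDGE_PAIR
        assert ev.gene_pairs == {("A1", "B1"), ("A2", "B2")}

    def test_single_pair_is_rejected(self):
        assert detect_crosstalk(self.A, self.B, [("A1", "B1")]) is None

    def test_two_pairs_may_share_a_gene(self):
        ev = detect_crosstalk(self.A, self.B, [("A1", "B1"), ("A1", "B2")])
        assert ev is not None and ev.criterion == BRIDGE_PAIR

    def test_shared_gene_route(self):
        ev = detect_crosstalk(self.A, self.B, [("A1", "S"), ("S", "B1")])
        assert ev is not None and ev.criterion == SHARED_GENE
        assert ev.roles["S"] == SHARED

    def test_shared_gene_needs_both_sides(self):
        assert detect_crosstalk(self.A, self.B, [("A1", "S"), ("S", "A2")]) is None

    def test_symmetry(self):
        pairs = [("A1", "B1"), ("A1", "S"), ("S", "B2")]
        ev_ab = detect_crosstalk(self.A, self.B, pairs)
        ev_ba = detect_crosstalk(self.B, self.A, pairs)
        assert (ev_ab is None) == (ev_ba is None)
        assert ev_ab.gene_pairs == ev_ba.gene_pairs

    def test_removing_shared_genes_keeps_criterion_i(self):
        pairs = [("A1", "B1"), ("A2", "B2"), ("A1", "S"), ("S", "B1")]
        with_shared = detect_crosstalk(self.A, self.B, pairs)
        without = detect_crosstalk(self.A - {"S"}, self.B - {"S"}, pairs)
        assert with_shared is not None and without is not None
        assert without.criterion == BRIDGE_PAIR


class TestBuildCrosstalkNetwork:
    def _net(self, pairs):
        import pandas as pd

        rows = [(a, b, 0.9, 0.001) for a, b in (canonical_pair(*p) for p in pairs)]
        return CoexpressionNetwork(
            "tumor", pd.DataFrame(rows, columns=["gene_a", "gene_b", "r", "p"])
        )

    def test_empty_network_no_crosstalk(self):
        pc = PathwayCollection({"P1": frozenset("ABC"), "P2": frozenset("DEF")})
        ctn, pgn = build_crosstalk_network(pc, self._net([]))
        assert len(ctn.edges) == 0
        assert len(pgn.edges) == 0

    def test_planted_bridge_recovered_exactly(self):
        pc = PathwayCollection(
            {"P1": frozenset("AB"), "P2": frozenset("CD"), "P3": frozenset("EF")}
        )
        ctn, pgn = build_crosstalk_network(pc, self._net([("A", "C"), ("B", "D")]))
        assert ctn.pair_set() == {("P1", "P2")}
        assert pgn.edges == {("A", "C"), ("B", "D")}

    def test_duplicated_pathway_has_no_exclusive_genes(self):
        pc = PathwayCollection({"P1": frozenset("AB"), "COPY": frozenset("AB")})
        ctn, _ = build_crosstalk_network(pc, self._net([("A", "B")]))
        assert ("COPY", "P1") not in ctn.pair_set()

    def test_pathgenet_subset_of_consensus(self, default_study):
        from xtalk.coexpression import consensus_network, state_network

        study = default_study
        cons = consensus_network(
            [state_network(d, "tumor") for d in study.datasets]
        )
        filt = filter_pathways(study.pathways, set(study.datasets[0].genes))
        _, pgn = build_crosstalk_network(filt, cons)
        assert pgn.edges <= cons.pair_set()


@given(data=st.data())
def test_matches_literal_oracle_on_random_toys(data):
    """Adjacency implementation equals quantifier enumeration on small toys."""
    genes = [f"g{i}" for i in range(data.draw(st.integers(6, 10)))]
    n_pw = data.draw(st.integers(2, 4))
    pathways = {}
    for p in range(n_pw):
        members = data.draw(
            st.sets(st.sampled_from(genes), min_size=2, max_size=5)
        )
        pathways[f"P{p}"] = frozenset(members)
    pool = list(itertools.combinations(genes, 2))
    edge_pool = data.draw(st.sets(st.sampled_from(pool), max_size=7))
    for (pa, ga), (pb, gb) in itertools.combinations(sorted(pathways.items()), 2):
        ev = detect_crosstalk(ga, gb, edge_pool)
        assert (ev is not None) == oracle_has_crosstalk(ga, gb, set(edge_pool))


def test_monotone_in_coexpression_edges():
    """Adding co-expression edges never removes a cross-talk call."""
    a = frozenset({"A1", "A2", "S"})
    b = frozenset({"B1", "B2", "S"})
    base = [("A1", "B1"), ("A2", "B2")]
    extra = base + [("A1", "S"), ("S", "B2"), ("A1", "A2")]
    assert detect_crosstalk(a, b, base) is not None
    assert detect_crosstalk(a, b, extra) is not None
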