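import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netflex import (
    BipartiteNetwork,
    EmptyInputError,
    NetworkSeries,
    SchemaError,
    align_edges,
    build_meta_network,
    read_interaction_table,
    write_incidence_matrix,
    write_interaction_table,
)
from netflex.network import SHARED, UNIQUE_RW, UNIQUE_ST

from .conftest import random_series


def write(tmp_path, text, name="edges.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


TOY = "realization\tconsumer\tresource\tcount\nApr\tA\tx\t2\nApr\tA\ty\t1\nMay\tA\tx\t1\n"


class TestReadInteractionTable:
    def test_basic_aggregation(self, tmp_path):
        series = read_interaction_table(write(tmp_path, TOY))
        assert series.realization_ids == ("Apr", "May")
        assert series["Apr"].edges == {("A", "x"): 2.0, ("A", "y"): 1.0}
        assert series.meta.edges == {("A", "x"): 3.0, ("A", "y"): 1.0}

    def test_duplicate_rows_summed(self, tmp_path):
        text = "realization\tconsumer\tresource\tcount\nApr\tA\tx\t2\nApr\tA\tx\t3\n"
        series = read_interaction_table(write(tmp_path, text))
        assert series["Apr"].edges == {("A", "x"): 5.0}

    def test_zero_rows_dropped(self, tmp_path):
        text = TOY + "May\tA\ty\t0\n"
        series = read_interaction_table(write(tmp_path, text))
        assert ("A", "y") not in series["May"]

    def test_custom_columns_and_delimiter(self, tmp_path):
        text = "month,spider,prey,n\nApr,A,x,2\n"
        series = read_interaction_table(
            write(tmp_path, text),
            delimiter=",",
            columns={"realization": "month", "consumer": "spider",
                     "resource": "prey", "count": "n"},
        )
        assert series["Apr"].edges == {("A", "x"): 2.0}

    def test_explicit_realization_order(self, tmp_path):
        series = read_interaction_table(
            write(tmp_path, TOY), realization_order=["May", "Apr"]
        )
        assert series.realization_ids == ("May", "Apr")

    def test_order_missing_realization_rejected(self, tmp_path):
        with pytest.raises(SchemaError, match="May"):
            read_interaction_table(write(tmp_path, TOY), realization_order=["Apr"])

    def test_missing_column_names_the_column(self, tmp_path):
        text = "realization\tconsumer\tresource\nApr\tA\tx\n"
        with pytest.raises(SchemaError, match="count"):
            read_interaction_table(write(tmp_path, text))

    @pytest.mark.parametrize("bad", ["-1", "2.5", "frog"])
    def test_invalid_weight_reports_row(self, tmp_path, bad):
        text = TOY + f"May\tB\ty\t{bad}\n"
        with pytest.raises(ValueError, match="line 5"):
            read_interaction_table(write(tmp_path, text))

    def test_empty_after_filtering(self, tmp_path):
        text = "realization\tconsumer\tresource\tcount\nApr\tA\tx\t0\n"
        with pytest.raises(EmptyInputError):
            read_interaction_table(write(tmp_path, text))

    def test_round_trip(self, tmp_path, rng):
        series = random_series(rng)
        out = tmp_path / "rt.tsv"
        write_interaction_table(series, out, header_comments=["settings: defaults"])
        again = read_interaction_table(out)
        assert again == series


class TestBipartiteNetwork:
    def test_vertex_sets_are_edge_implied(self):
        net = BipartiteNetwork({("A", "x"): 1, ("B", "y"): 2})
        assert net.consumers == {"A", "B"}
        assert net.resources == {"x", "y"}
        assert net.species == {"A", "B", "x", "y"}

    def test_rejects_nonpositive_weight(self):
        with pytest.raises(ValueError):
            BipartiteNetwork({("A", "x"): 0})

    def test_rejects_overlapping_namespaces(self):
        with pytest.raises(SchemaError):
            BipartiteNetwork({("A", "x"): 1, ("x", "y"): 1})

    def test_to_proportions(self):
        net = BipartiteNetwork({("A", "x"): 3, ("A", "y"): 1})
        assert net.to_proportions().edges == {("A", "x"): 0.75, ("A", "y"): 0.25}

    def test_to_proportions_derived(self):
        net = BipartiteNetwork({("A", "x"): 2, ("B", "x"): 2, ("B", "y"): 1})
        assert net.to_proportions().edges == {
            ("A", "x"): 0.4, ("B", "x"): 0.4, ("B", "y"): 0.2,
        }

    def test_to_proportions_idempotent(self):
        net = BipartiteNetwork({("A", "x"): 0.75, ("A", "y"): 0.25}).to_proportions()
        assert net.to_proportions() == net

    def test_to_proportions_empty_raises(self):
        with pytest.raises(ValueError):
            BipartiteNetwork().to_proportions()

    def test_remove_species(self):
        net = BipartiteNetwork({("A", "x"): 1, ("B", "x"): 1, ("B", "y"): 1})
        assert net.remove_species("B").edges == {("A", "x"): 1.0}
        assert net.remove_species("absent") == net
        assert net.edges == {("A", "x"): 1, ("B", "x"): 1, ("B", "y"): 1}  # unchanged


class TestMetaNetwork:
    def test_union_and_sums(self):
        nets = [
            BipartiteNetwork({("A", "x"): 1}),
            BipartiteNetwork({("A", "x"): 1, ("B", "y"): 2}),
        ]
        assert build_meta_network(nets).edges == {("A", "x"): 2.0, ("B", "y"): 2.0}

    def test_single_realization_identity(self):
        net = BipartiteNetwork({("A", "x"): 3})
        assert build_meta_network([net]) == net

    def test_empty_list_rejected(self):
        with pytest.raises(EmptyInputError):
            build_meta_network([])

    def test_weight_conservation(self, rng):
        series = random_series(rng)
        for edge, w in series.meta.edges.items():
            assert w == sum(net.weight(edge) for net in series.networks)

    def test_remove_commutes_with_meta(self, rng):
        series = random_series(rng)
        sp = sorted(series.meta.species)[0]
        removed_then_meta = series.remove_species(sp).meta
        meta_then_removed = series.meta.remove_species(sp)
        assert removed_then_meta == meta_then_removed


class TestSeriesRemoveSpecies:
    def test_emptied_realization_retained(self):
        series = NetworkSeries(
            [
                ("r1", BipartiteNetwork({("A", "x"): 1, ("B", "y"): 1})),
                ("r2", BipartiteNetwork({("A", "y"): 1})),
            ]
        )
        reduced = series.remove_species("A")
        assert len(reduced) == 2
        assert reduced["r1"].edges == {("B", "y"): 1.0}
        assert reduced["r2"].is_empty


class TestAlignEdges:
    def test_all_species_shared(self):
        m = BipartiteNetwork({("A", "x"): 1, ("A", "y"): 1, ("B", "x"): 1})
        n = BipartiteNetwork({("A", "x"): 1, ("B", "y"): 1})
        aln = align_edges(m, n)
        assert (aln.a, aln.b, aln.c) == (1, 2, 1)
        assert (aln.b_rw, aln.c_rw, aln.b_st, aln.c_st) == (2, 1, 0, 0)

    def test_turnover_classification(self):
        m = BipartiteNetwork({("A", "x"): 1, ("B", "y"): 1})
        n = BipartiteNetwork({("A", "x"): 1, ("C", "x"): 1})
        aln = align_edges(m, n)
        assert (aln.a, aln.b, aln.c) == (1, 1, 1)
        assert (aln.b_rw, aln.c_rw) == (0, 0)
        assert aln.class_of[("B", "y")] == UNIQUE_ST
        assert aln.class_of[("C", "x")] == UNIQUE_ST

    def test_identical_networks(self):
        m = BipartiteNetwork({("A", "x"): 1, ("B", "y"): 2})
        aln = align_edges(m, m)
        assert aln.b == aln.c == 0
        assert all(cls == SHARED for cls in aln.class_of.values())

    def test_cross_network_namespace_clash(self):
        m = BipartiteNetwork({("A", "x"): 1})
        n = BipartiteNetwork({("x", "z"): 1})
        with pytest.raises(SchemaError):
            align_edges(m, n)

    def test_class_partition_property(self, rng):
        from .oracles import random_network_edges

        for _ in range(200):
            m = BipartiteNetwork(random_network_edges(rng))
            n = BipartiteNetwork(random_network_edges(rng))
            aln = align_edges(m, n)
            assert aln.a + aln.b_rw + aln.b_st + aln.c_rw + aln.c_st == len(aln.edge_ids)
            assert aln.b == aln.b_rw + aln.b_st
            assert aln.c == aln.c_rw + aln.c_st


@st.composite
def small_edge_dicts(draw):
    consumers = [f"C{i}" for i in range(4)]
    resources = [f"r{i}" for i in range(4)]
    pairs = [(c, r) for c in consumers for r in resources]
    chosen = draw(st.lists(st.sampled_from(pairs), min_size=1, max_size=8,
                           unique=True))
    return {e: float(draw(st.integers(1, 9))) for e in chosen}


@settings(max_examples=200, derandomize=True)
@given(me=small_edge_dicts(), ne=small_edge_dicts())
def test_alignment_classes_partition_edge_union(me, ne):
    """The shared/rewired/turnover classes always partition the edge union,
    and one-sided edges split consistently (b = b' + b_ST, c = c' + c_ST)."""
    aln = align_edges(BipartiteNetwork(me), BipartiteNetwork(ne))
    assert aln.a + aln.b + aln.c == len(set(me) | set(ne))
    assert aln.b == aln.b_rw + aln.b_st
    assert aln.c == aln.c_rw + aln.c_st
    shared = BipartiteNetwork(me).species & BipartiteNetwork(ne).species
    for e, cls in aln.class_of.items():
        if cls == "shared":
            assert e in me and e in ne
        else:
            one_sided_rw = e[0] in shared and e[1] in shared
            assert cls == ("unique_rw" if one_sided_rw else "unique_st")


def test_incidence_matrix_writer(tmp_path):
    import pandas as pd

    net = BipartiteNetwork({("A", "x"): 2, ("B", "y"): 1})
    out = tmp_path / "mat.tsv"
    write_incidence_matrix(net, out)
    mat = pd.read_csv(out, sep="\t", index_col=0)
    assert mat.loc["A", "x"] == 2
    assert mat.loc["A", "y"] == 0
    assert mat.loc["B", "y"] == 1
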