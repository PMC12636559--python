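import logging

import pytest

from foxcircuit import (
    ConnectomeGraph,
    EdgeRecord,
    NeuronRecord,
    Side,
    by_cell_type,
    by_ids,
    by_population,
    classify_fda,
    input_fraction,
    load_connectome,
    output_fraction,
    pair_count,
    write_tables,
)
from foxcircuit.connectome import (
    ConnectomeFormatError,
    ConnectomeIntegrityError,
    SelectorError,
    UndefinedFractionError,
)


def _write(path, text):
    path.write_text(text)
    return path


NEURONS_3 = (
    "neuron_id,cell_type,populations,side,region\n"
    "A,typeA,GRN;sweet,L,labellum\n"
    "B,typeB,GIN,R,SEZ\n"
    "C,typeC,,U,SEZ\n"
)


class TestLoadConnectome:
    def test_three_neuron_read_back(self, tmp_path):
        npath = _write(tmp_path / "n.csv", NEURONS_3)
        epath = _write(tmp_path / "e.csv",
                       "pre_id,post_id,synapse_count,sign\n"
                       "A,B,5,+1\nB,C,3,-1\n")
        g = load_connectome(npath, epath)
        assert g.n_neurons == 3 and g.n_edges == 2
        assert g.neuron("A").populations == {"GRN", "sweet"}
        assert g.neuron("A").side is Side.LEFT
        edges = {(e.pre_id, e.post_id): e for e in g.edges()}
        assert edges[("A", "B")].synapse_count == 5
        assert edges[("B", "C")].sign == -1

    def test_duplicate_rows_are_summed(self, tmp_path):
        npath = _write(tmp_path / "n.csv", NEURONS_3)
        epath = _write(tmp_path / "e.csv",
                       "pre_id,post_id,synapse_count,sign\n"
                       "A,B,5,+1\nA,B,3,+1\n")
        g = load_connectome(npath, epath)
        assert g.n_edges == 1
        (edge,) = g.edges()
        assert edge.synapse_count == 8

    def test_dangling_endpoint_is_integrity_error(self, tmp_path):
        npath = _write(tmp_path / "n.csv", NEURONS_3)
        epath = _write(tmp_path / "e.csv",
                       "pre_id,post_id,synapse_count,sign\nA,X,5,+1\n")
        with pytest.raises(ConnectomeIntegrityError, match="X"):
            load_connectome(npath, epath)

    def test_missing_column_named_in_error(self, tmp_path):
        npath = _write(tmp_path / "n.csv",
                       "neuron_id,cell_type,populations,side\nA,t,,L\n")
        epath = _write(tmp_path / "e.csv", "pre_id,post_id,synapse_count\n")
        with pytest.raises(ConnectomeFormatError, match="region"):
            load_connectome(npath, epath)

    def test_missing_sign_defaults_to_excitatory_with_warning(
            self, tmp_path, caplog):
        npath = _write(tmp_path / "n.csv", NEURONS_3)
        epath = _write(tmp_path / "e.csv",
                       "pre_id,post_id,synapse_count\nA,B,5\n")
        with caplog.at_level(logging.WARNING, "foxcircuit.connectome"):
            g = load_connectome(npath, epath)
        (edge,) = g.edges()
        assert edge.sign == 1
        assert any("excitatory" in r.message for r in caplog.records)

    def test_round_trip_is_identity(self, tmp_path, reference_graph):
        npath, epath = write_tables(reference_graph, tmp_path)
        assert load_connectome(npath, epath) == reference_graph
        # and re-export is byte-identical
        first = (npath.read_bytes(), epath.read_bytes())
        npath2, epath2 = write_tables(reference_graph, tmp_path / "again")
        assert (npath2.read_bytes(), epath2.read_bytes()) == first


def _tiny_fanin():
    return ConnectomeGraph(
        [NeuronRecord("A", "a"), NeuronRecord("B", "b"),
         NeuronRecord("fox", "fox")],
        [EdgeRecord("A", "fox", 10), EdgeRecord("B", "fox", 90)],
    )


class TestFractions:
    def test_input_fraction_by_definition(self):
        g = _tiny_fanin()
        assert input_fraction(g, ["fox"], ["A"]) == pytest.approx(10.0)
        assert input_fraction(g, ["fox"], ["B"]) == pytest.approx(90.0)

    def test_all_sources_normalize_to_100(self):
        g = _tiny_fanin()
        assert input_fraction(g, ["fox"], ["A", "B"]) == pytest.approx(100.0)

    def test_zero_denominator_raises(self):
        g = _tiny_fanin()
        with pytest.raises(UndefinedFractionError):
            input_fraction(g, ["A"], ["B"])

    def test_output_fraction_by_definition(self):
        g = ConnectomeGraph(
            [NeuronRecord("fox", "fox"), NeuronRecord("P", "p"),
             NeuronRecord("Q", "q")],
            [EdgeRecord("fox", "P", 44), EdgeRecord("fox", "Q", 956)],
        )
        assert output_fraction(g, ["fox"], ["P"]) == pytest.approx(4.4)
        assert output_fraction(g, ["fox"], ["P"],
                               within=["P"]) == pytest.approx(100.0)

    def test_partition_of_sources_sums_to_100(self, reference_graph,
                                              ground_truth):
        pops = ground_truth.populations
        fox = pops["fox"]
        shares = [
            input_fraction(reference_graph, fox, pops[name])
            for name in ("fdg", "grn", "gin", "sez_local")
        ]
        assert sum(shares) == pytest.approx(100.0, abs=1e-9)
        assert all(0 <= s <= 100 for s in shares)

    def test_region_filter_restricts_denominator(self, reference_graph):
        dsk = by_cell_type("DSKMP1B")
        fox = by_cell_type("fox")
        filtered = input_fraction(reference_graph, dsk, fox,
                                  region_filter="SEZ")
        unfiltered = input_fraction(reference_graph, dsk, fox)
        assert filtered > unfiltered  # central relay input dilutes the share


class TestClassifyFda:
    @staticmethod
    def _graph(extra_edges=()):
        neurons = [
            NeuronRecord("fox", "fox"),
            NeuronRecord("X", "x", {"ascending"}),
            NeuronRecord("Y", "y", {"ascending"}),
            NeuronRecord("mid", "m"),
            NeuronRecord("pam", "PAM", {"PAM"}),
        ]
        edges = [EdgeRecord("fox", "X", 5), EdgeRecord("X", "mid", 5),
                 EdgeRecord("mid", "pam", 5)]
        edges += [EdgeRecord(*e) for e in extra_edges]
        return ConnectomeGraph(neurons, edges)

    def test_two_hop_path_is_fda2(self):
        g = self._graph()
        fda1, fda2 = classify_fda(g, ["fox"], ["pam"])
        assert fda1 == frozenset() and fda2 == {"X"}

    def test_direct_edge_dominates(self):
        g = self._graph([("fox", "Y", 5), ("Y", "mid", 5), ("Y", "pam", 5)])
        fda1, fda2 = classify_fda(g, ["fox"], ["pam"])
        assert fda1 == {"Y"} and fda2 == {"X"}
        assert not (fda1 & fda2)

    def test_non_ascending_downstream_is_ignored(self):
        g = self._graph([("fox", "mid", 5)])
        fda1, fda2 = classify_fda(g, ["fox"], ["pam"])
        assert "mid" not in fda1 | fda2

    def test_sets_contained_in_direct_downstream(self, reference_graph):
        fox = by_cell_type("fox").resolve(reference_graph)
        pam = by_population("PAM").resolve(reference_graph)
        fda1, fda2 = classify_fda(reference_graph, fox, pam)
        down = set().union(*(reference_graph.successors(f) for f in fox))
        assert (fda1 | fda2) <= down
        assert not (fda1 & fda2)


class TestPairCount:
    def test_left_right_pair_counts_once(self):
        g = ConnectomeGraph([
            NeuronRecord("xl", "X", side=Side.LEFT),
            NeuronRecord("xr", "X", side=Side.RIGHT),
        ])
        assert pair_count(g, ["xl", "xr"]) == 1

    def test_unilateral_type_counts_zero(self):
        g = ConnectomeGraph([NeuronRecord("xl", "X", side=Side.LEFT)])
        assert pair_count(g, ["xl"]) == 0


class TestSelectors:
    def test_by_cell_type_with_side(self, reference_graph):
        left_fox = by_cell_type("fox", side=Side.LEFT).resolve(reference_graph)
        assert left_fox == {"fox_L"}

    def test_empty_resolution_raises(self, reference_graph):
        with pytest.raises(SelectorError):
            by_cell_type("no-such-type").resolve(reference_graph)
        with pytest.raises(SelectorError):
            by_ids(["fox_L", "nope"]).resolve(reference_graph)
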