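"""Pathway signal flow: KGML parsing, propagation, profile matching."""

from __future__ import annotations

import numpy as np
import networkx as nx
import pandas as pd
import pytest

from somportrait.psf import (
    PathwayGraph,
    compute_psf,
    match_profiles,
    node_fold_change,
    parse_kgml,
    psf_time_profiles,
    read_edge_list,
)

KGML_CHAIN = """<?xml version="1.0"?>
<pathway name="path:toy01" title="toy chain">
  <entry id="1" name="hsa:10" type="gene"/>
  <entry id="2" name="hsa:20 hsa:21" type="gene"/>
  <entry id="3" name="hsa:30" type="gene"/>
  <relation entry1="1" entry2="2" type="PPrel"><subtype name="activation" value="--&gt;"/></relation>
  <relation entry1="2" entry2="3" type="PPrel"><subtype name="inhibition" value="--|"/></relation>
</pathway>
"""


def _chain(types, fcs):
    """Linear pathway n0 -> n1 -> ... with given edge types and node FCs."""
    g = nx.DiGraph()
    for i in range(len(types) + 1):
        g.add_node(f"n{i}", members=[f"n{i}"])
    for i, t in enumerate(types):
        g.add_edge(f"n{i}", f"n{i+1}", type=t)
    pw = PathwayGraph(name="chain", graph=g)
    return pw, {f"n{i}": fc for i, fc in enumerate(fcs)}


class TestKgmlParsing:
    def test_three_entry_chain(self, tmp_path):
        p = tmp_path / "toy.xml"
        p.write_text(KGML_CHAIN)
        pw = parse_kgml(p)
        assert len(pw.graph) == 3
        assert pw.graph.number_of_edges() == 2
        assert pw.graph.edges["1", "2"]["type"] == "activation"
        assert pw.graph.edges["2", "3"]["type"] == "inhibition"
        assert pw.sources == ["1"] and pw.sinks == ["3"]
        assert pw.graph.nodes["2"]["members"] == ["hsa:20", "hsa:21"]

    def test_two_cycle_broken_and_logged(self, tmp_path):
        xml = """<?xml version="1.0"?><pathway name="c">
        <entry id="1" name="a"/><entry id="2" name="b"/><entry id="3" name="c"/>
        <relation entry1="1" entry2="2"><subtype name="activation"/></relation>
        <relation entry1="2" entry2="1"><subtype name="activation"/></relation>
        <relation entry1="2" entry2="3"><subtype name="activation"/></relation>
        </pathway>"""
        p = tmp_path / "cycle.xml"
        p.write_text(xml)
        pw = parse_kgml(p)
        assert len(pw.removed_back_edges) == 1
        assert nx.is_directed_acyclic_graph(pw.graph)

    def test_unsupported_subtype_dropped_and_counted(self, tmp_path):
        xml = """<?xml version="1.0"?><pathway name="b">
        <entry id="1" name="a"/><entry id="2" name="b"/>
        <relation entry1="1" entry2="2"><subtype name="binding/association"/></relation>
        <relation entry1="1" entry2="2"><subtype name="activation"/></relation>
        </pathway>"""
        p = tmp_path / "bind.xml"
        p.write_text(xml)
        pw = parse_kgml(p)
        assert pw.dropped_relations == 1
        assert pw.graph.number_of_edges() == 1

    def test_malformed_xml_rejected(self, tmp_path):
        p = tmp_path / "bad.xml"
        p.write_text("<pathway><entry")
        with pytest.raises(ValueError, match="malformed"):
            parse_kgml(p)

    def test_edge_list_round(self, tmp_path):
        p = tmp_path / "toy.tsv"
        p.write_text("A\tB\tactivation\nB\tC\tinhibition\n")
        pw = read_edge_list(p)
        assert pw.sources == ["A"] and pw.sinks == ["C"]

    def test_edge_list_bad_type_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("A\tB\tbinds\n")
        with pytest.raises(ValueError, match="line 1"):
            read_edge_list(p)


class TestNodeFoldChange:
    def test_mean_of_members(self):
        pw, _ = _chain(["activation"], [1, 1])
        pw.graph.nodes["n0"]["members"] = ["a", "b"]
        fc = node_fold_change(pw, {"a": 2.0, "b": 4.0})
        assert fc["n0"] == pytest.approx(3.0)

    def test_unmeasured_node_neutral(self):
        pw, _ = _chain(["activation"], [1, 1])
        fc = node_fold_change(pw, {"x": 2.0})
        assert fc == {"n0": 1.0, "n1": 1.0}

    def test_nonpositive_fc_rejected(self):
        pw, _ = _chain(["activation"], [1, 1])
        with pytest.raises(ValueError):
            node_fold_change(pw, {"n0": 0.0})


class TestPropagation:
    def test_neutral_chain(self):
        pw, fc = _chain(["activation"], [1.0, 1.0])
        assert compute_psf(pw, fc).sink_signals["n1"] == pytest.approx(1.0)

    def test_activation_chain_multiplies(self):
        pw, fc = _chain(["activation"], [2.0, 3.0])
        assert compute_psf(pw, fc).sink_signals["n1"] == pytest.approx(6.0)

    def test_inhibition_chain_divides(self):
        pw, fc = _chain(["inhibition"], [2.0, 4.0])
        assert compute_psf(pw, fc).sink_signals["n1"] == pytest.approx(0.5)

    def test_random_chain_closed_form(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 10))
            types = [("activation", "inhibition")[rng.integers(2)] for _ in range(n)]
            fcs = rng.uniform(0.2, 5.0, size=n + 1)
            pw, fc = _chain(types, fcs)
            signal = fcs[0]
            for i, t in enumerate(types):
                signal = signal * fcs[i + 1] if t == "activation" else signal / fcs[i + 1]
            assert compute_psf(pw, fc).sink_signals[f"n{n}"] == pytest.approx(signal)

    def test_neutrality_on_random_dags(self, rng):
        for _ in range(30):
            n = int(rng.integers(3, 12))
            g = nx.DiGraph()
            g.add_nodes_from((f"n{i}", {"members": [f"n{i}"]}) for i in range(n))
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.35:
                        t = "activation" if rng.random() < 0.7 else "inhibition"
                        g.add_edge(f"n{i}", f"n{j}", type=t)
            if not g.number_of_edges():
                continue
            pw = PathwayGraph(name="dag", graph=g)
            res = compute_psf(pw, {f"n{i}": 1.0 for i in range(n)})
            assert all(v == pytest.approx(1.0) for v in res.sink_signals.values())

    def test_topological_order_invariance(self, rng):
        # relabelling shuffles the iteration order of any topological sort;
        # signals per original node must not change
        n = 10
        g = nx.DiGraph()
        g.add_nodes_from((f"n{i}", {"members": [f"n{i}"]}) for i in range(n))
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.4:
                    g.add_edge(f"n{i}", f"n{j}", type="activation" if rng.random() < 0.5 else "inhibition")
        fc = {f"n{i}": float(rng.uniform(0.5, 2)) for i in range(n)}
        pw = PathwayGraph(name="a", graph=g)
        base = compute_psf(pw, fc).node_signals
        perm = {f"n{i}": f"m{rng.integers(1000)}_{i}" for i in range(n)}
        g2 = nx.relabel_nodes(g, perm)
        pw2 = PathwayGraph(name="b", graph=g2)
        other = compute_psf(pw2, {perm[k]: v for k, v in fc.items()}).node_signals
        for k in base:
            assert other[perm[k]] == pytest.approx(base[k])

    def test_no_sink_rejected(self):
        g = nx.DiGraph()
        g.add_edge("a", "b", type="activation")
        g.add_edge("b", "a", type="activation")
        with pytest.raises(ValueError):
            PathwayGraph(name="x", graph=g)


class TestTimeProfiles:
    def test_constant_series_constant_profile(self):
        pw, _ = _chain(["activation", "inhibition"], [1, 1, 1])
        ab = pd.DataFrame(
            {t: [0.4, 0.6, 0.2] for t in range(5)}, index=["n0", "n1", "n2"]
        )
        prof = psf_time_profiles(pw, ab)
        assert prof.shape == (1, 5)
        assert np.allclose(prof.values, prof.values[:, :1])

    def test_fold_change_pseudocount(self):
        pw, _ = _chain([], [1])  # single node: source = sink
        ab = pd.DataFrame({0: [0.0], 1: [1.0]}, index=["n0"])
        prof = psf_time_profiles(pw, ab, epsilon=0.01)
        # fc(t) = (x + eps) / (mean + eps) with mean = 0.5
        assert prof.values[0, 0] == pytest.approx(0.01 / 0.51)
        assert prof.values[0, 1] == pytest.approx(1.01 / 0.51)


class TestMatching:
    def test_identical_profile_perfect_match(self):
        t = np.arange(8.0)
        spot = pd.DataFrame([np.sin(t), np.cos(t)], index=["A", "B"], columns=t)
        psf = pd.DataFrame([np.sin(t)], index=["s1"], columns=t)
        m = match_profiles(psf, spot)
        best = m[m["best"]]
        assert best.iloc[0]["spot"] == "A"
        assert best.iloc[0]["r"] == pytest.approx(1.0)

    def test_antiphase_profile_anticorrelates(self):
        t = np.arange(8.0)
        spot = pd.DataFrame([np.sin(t)], index=["A"], columns=t)
        psf = pd.DataFrame([-np.sin(t)], index=["s1"], columns=t)
        m = match_profiles(psf, spot)
        assert m.iloc[0]["r"] == pytest.approx(-1.0)

    def test_permuted_time_destroys_match(self, rng):
        t = np.arange(24.0)
        base = np.sin(t / 3)
        spot = pd.DataFrame([base], index=["A"], columns=t)
        perm = rng.permutation(24)
        psf = pd.DataFrame([base[perm]], index=["s1"], columns=t)
        r_perm = match_profiles(psf, spot).iloc[0]["r"]
        assert abs(r_perm) < 0.5

    def test_zero_variance_flagged(self):
        t = np.arange(5.0)
        spot = pd.DataFrame([np.ones(5)], index=["A"], columns=t)
        psf = pd.DataFrame([np.sin(t)], index=["s1"], columns=t)
        m = match_profiles(psf, spot)
        assert np.isnan(m.iloc[0]["r"])

    def test_mismatched_grids_rejected(self):
        a = pd.DataFrame([[1.0, 2.0]], columns=[0, 1])
        b = pd.DataFrame([[1.0, 2.0]], columns=[1, 2])
        with pytest.raises(ValueError):
            match_profiles(a, b)
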