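"""Structure parsing, distance/contact construction, and normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peppinet.embeddings import SyntheticEmbedder
from peppinet.fixtures import corrupt_pdb, make_toy_pdb
from peppinet.structures_io import (
    ResidueChain,
    build_contact_map,
    check_consistency,
    distance_matrix,
    normalize_adjacency,
    parse_chain,
    write_contact_tsv,
    write_edge_list,
)


class TestParseChain:
    def test_round_trip_against_fixture_writer(self):
        text = make_toy_pdb("ACD", "random_walk", seed=1)
        chain = parse_chain(text, "A")
        assert chain.sequence == "ACD"
        assert len(chain) == 3
        # PDB coordinates are printed at 1e-3 precision
        d = np.linalg.norm(np.diff(chain.coords, axis=0), axis=1)
        np.testing.assert_allclose(d, 3.8, atol=0.011)

    def test_single_residue_glycine(self):
        chain = parse_chain(make_toy_pdb("G"), "A")
        assert chain.sequence == "G" and len(chain) == 1

    def test_two_chain_file_selects_requested_chain(self):
        text_a = make_toy_pdb("ACDE", chain_id="A")
        text_b = make_toy_pdb("KLM", chain_id="B")
        combined = text_a.replace("TER\nEND\n", "TER\n") + text_b
        assert parse_chain(combined, "B").sequence == "KLM"
        assert parse_chain(combined, "A").sequence == "ACDE"

    def test_missing_chain_raises(self):
        with pytest.raises(KeyError, match="'Z'"):
            parse_chain(make_toy_pdb("ACD"), "Z")

    def test_residue_without_representative_atom_is_skipped(self):
        text = corrupt_pdb(make_toy_pdb("ACDE"), drop_residue=2)
        chain = parse_chain(text, "A")
        assert chain.sequence == "ADE"

    def test_chain_invariant_rejects_length_mismatch(self):
        with pytest.raises(ValueError):
            ResidueChain("A", "AC", np.zeros((3, 3)))


class TestDistanceMatrix:
    def test_hand_computed_345_triangle(self):
        chain = ResidueChain("A", "AG", np.array([[0, 0, 0], [3, 4, 0]]))
        np.testing.assert_allclose(
            distance_matrix(chain), [[0, 5], [5, 0]], atol=1e-12
        )

    def test_single_residue_zero_matrix(self):
        chain = ResidueChain("A", "G", np.zeros((1, 3)))
        assert distance_matrix(chain).shape == (1, 1)
        assert distance_matrix(chain)[0, 0] == 0.0

    def test_matches_double_loop_oracle(self, rng):
        coords = rng.normal(size=(6, 3)) * 10
        chain = ResidueChain("A", "ACDEFG", coords)
        dist = distance_matrix(chain)
        for i in range(6):
            for j in range(6):
                assert dist[i, j] == pytest.approx(
                    np.linalg.norm(coords[i] - coords[j]), abs=1e-9
                )

    @given(st.integers(0, 100))
    @settings(deadline=None, max_examples=20)
    def test_triangle_inequality(self, seed):
        coords = np.random.default_rng(seed).normal(size=(5, 3)) * 8
        d = distance_matrix(ResidueChain("A", "ACDEF", coords))
        for i in range(5):
            for j in range(5):
                for k in range(5):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


class TestContactMap:
    def test_threshold_rules(self):
        dist = np.array([[0.0, 5.0], [5.0, 0.0]])
        assert build_contact_map(dist, 10)[0, 1] == 1
        dist[0, 1] = dist[1, 0] = 12.0
        assert build_contact_map(dist, 10)[0, 1] == 0

    def test_matches_elementwise_oracle(self, rng):
        coords = rng.normal(size=(6, 3)) * 6
        dist = distance_matrix(ResidueChain("A", "ACDEFG", coords))
        adj = build_contact_map(dist, 10.0)
        for i in range(6):
            for j in range(6):
                expected = int(i != j and dist[i, j] <= 10.0)
                assert adj[i, j] == expected
        assert np.all(np.diag(adj) == 0)

    @given(st.integers(0, 50), st.floats(1.0, 15.0), st.floats(0.0, 10.0))
    @settings(deadline=None, max_examples=30)
    def test_monotone_in_threshold(self, seed, thr, bump):
        coords = np.random.default_rng(seed).normal(size=(7, 3)) * 5
        dist = distance_matrix(ResidueChain("A", "ACDEFGH", coords))
        lo = build_contact_map(dist, thr)
        hi = build_contact_map(dist, thr + bump)
        assert np.all(hi >= lo)  # raising threshold never removes an edge

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            build_contact_map(np.zeros((2, 2)), 0.0)


class TestNormalizeAdjacency:
    def test_edgeless_graph_gives_identity(self):
        np.testing.assert_allclose(normalize_adjacency(np.zeros((2, 2))),
                                   np.eye(2), atol=1e-12)

    def test_single_edge_gives_half_everywhere(self):
        adj = np.array([[0, 1], [1, 0]])
        np.testing.assert_allclose(normalize_adjacency(adj),
                                   np.full((2, 2), 0.5), atol=1e-12)

    @given(st.integers(0, 200))
    @settings(deadline=None, max_examples=50)
    def test_matches_dense_closed_form(self, seed):
        g = np.random.default_rng(seed)
        n = int(g.integers(1, 13))
        adj = (g.random((n, n)) < 0.4).astype(int)
        adj = np.triu(adj, 1)
        adj = adj + adj.T
        out = normalize_adjacency(adj)
        a_hat = adj + np.eye(n)
        d_half = np.diag(1 / np.sqrt(a_hat.sum(axis=1)))
        np.testing.assert_allclose(out, d_half @ a_hat @ d_half, atol=1e-9)
        assert np.abs(out - out.T).max() < 1e-9


class TestConsistencyFilter:
    def test_equal_lengths_pass(self):
        chain = parse_chain(make_toy_pdb("ACDEF"), "A")
        emb = SyntheticEmbedder(8, 0).embed("ACDEF")
        assert check_consistency(chain, emb)

    def test_row_count_mismatch_fails(self):
        chain = parse_chain(make_toy_pdb("ACDEF"), "A")
        emb = SyntheticEmbedder(8, 0).embed("ACDEFKK")
        assert not check_consistency(chain, emb)

    def test_missing_atom_breaks_consistency(self):
        text = corrupt_pdb(make_toy_pdb("ACDEF"), drop_residue=3)
        chain = parse_chain(text, "A")  # parses to length 4
        emb = SyntheticEmbedder(8, 0).embed("ACDEF")  # full sequence
        assert not check_consistency(chain, emb)


def test_contact_writers_round_trip(tmp_path, rng):
    coords = rng.normal(size=(5, 3)) * 5
    chain = ResidueChain("A", "ACDEF", coords)
    dist = distance_matrix(chain)
    adj = build_contact_map(dist, 10.0)
    dense = tmp_path / "map.tsv"
    write_contact_tsv(dense, adj, 10.0)
    rows = [line.split("\t") for line in dense.read_text().splitlines()[1:]]
    np.testing.assert_array_equal(np.array(rows, dtype=int), adj)
    edges = tmp_path / "edges.tsv"
    write_edge_list(edges, dist, 10.0)
    lines = edges.read_text().splitlines()
    assert lines[0].startswith("# edges threshold=10.0 atom=CA")
    n_edges = int(np.triu(adj, 1).sum())
    assert len(lines) == 2 + n_edges
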