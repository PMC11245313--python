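import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gep import io as gio
from gep import representations as rep
from gep.types import Atom, ProteinStructure

from conftest import random_rigid_transform


def brute_force_edges(points, k=15, radius=10.0):
    """Independent O(R^2) oracle for the kNN-within-radius graph."""
    n = len(points)
    pairs = set()
    for i in range(n):
        cand = []
        for j in range(n):
            if j == i:
                continue
            d = float(np.linalg.norm(points[i] - points[j]))
            if d <= radius:
                cand.append((d, j))
        cand.sort()
        for _, j in cand[:k]:
            pairs.add((i, j))
            pairs.add((j, i))
    return np.array(sorted(pairs), dtype=int).reshape(-1, 2)


def single_residue(atoms):
    return ProteinStructure(
        chains=["A"],
        residues=[(("A", 1, ""), "ALA", (0, len(atoms)))],
        atoms=atoms,
    )


class TestReferencePoints:
    def test_ca_preferred(self):
        s = single_residue(
            [
                Atom("N", "N", np.array([9.0, 9, 9]), ("A", 1, "")),
                Atom("CA", "C", np.array([1.0, 2, 3]), ("A", 1, "")),
            ]
        )
        np.testing.assert_allclose(rep.residue_reference_points(s)[0], [1, 2, 3])

    def test_centroid_fallback(self):
        s = single_residue(
            [
                Atom("N", "N", np.array([0.0, 0, 0]), ("A", 1, "")),
                Atom("C", "C", np.array([2.0, 0, 0]), ("A", 1, "")),
            ]
        )
        np.testing.assert_allclose(rep.residue_reference_points(s)[0], [1, 0, 0])

    def test_empty_residue_is_error(self):
        s = ProteinStructure(
            chains=["A"],
            residues=[(("A", 1, ""), "ALA", (0, 0))],
            atoms=[],
        )
        with pytest.raises(ValueError):
            rep.residue_reference_points(s)


class TestResidueGraph:
    def test_collinear_chain(self):
        # 5 points 4 A apart on a line: ends cannot reach past 10 A
        pts = np.array([[4.0 * i, 0, 0] for i in range(5)])
        edges = rep.build_residue_graph(pts)
        neigh = {i: set() for i in range(5)}
        for a, b in edges:
            neigh[a].add(b)
        assert neigh[2] == {0, 1, 3, 4}
        assert neigh[0] == {1, 2}  # 12 A to node 3 exceeds the radius

    def test_single_point(self):
        assert rep.build_residue_graph(np.zeros((1, 3))).size == 0

    def test_degree_cap_at_15(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 1.0, (20, 3))  # all within 1 A: radius never binds
        edges = rep.build_residue_graph(pts)
        out_deg = np.bincount(edges[:, 0], minlength=20)
        # out-edges before symmetrization are capped at 15; the union may
        # raise some degrees, but every node keeps at least 15 neighbors
        assert out_deg.min() >= 15
        assert len(set(map(tuple, edges))) == len(edges)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 60))
        pts = rng.uniform(0, 25, (n, 3))
        got = rep.build_residue_graph(pts)
        want = brute_force_edges(pts)
        np.testing.assert_array_equal(got, want)

    def test_rigid_motion_preserves_edges(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 20, (40, 3))
        base = rep.build_residue_graph(pts)
        for _ in range(10):
            rot, shift = random_rigid_transform(rng)
            moved = pts @ rot.T + shift
            np.testing.assert_array_equal(rep.build_residue_graph(moved), base)


class TestFeatures:
    def test_every_standard_code_has_one_hot(self):
        for i, aa in enumerate(gio.STANDARD_AA3):
            v = rep.encode_residue_features(aa)
            assert v.shape == (28,)
            assert v[:21].sum() == 1.0 and v[i] == 1.0
            assert np.any(v[21:] != 0.0)

    def test_unknown_code_maps_to_unclassified(self):
        v = rep.encode_residue_features("XYZ")
        assert v[20] == 1.0 and v[:20].sum() == 0.0
        np.testing.assert_array_equal(v[21:], 0.0)

    def test_physchem_scalars_standardized(self):
        mat = np.stack([rep.encode_residue_features(aa) for aa in gio.STANDARD_AA3])
        np.testing.assert_allclose(mat[:, 21:].mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(mat[:, 21:].std(axis=0), 1.0, atol=1e-12)


class TestSurface:
    def test_single_atom_sphere(self):
        s = single_residue([Atom("CA", "C", np.zeros(3), ("A", 1, ""))])
        pts = rep.generate_surface(s, target_points=200)
        r = np.linalg.norm(pts, axis=1)
        np.testing.assert_allclose(r, rep.vdw_radius("C"), atol=1e-9)

    def test_disjoint_atoms_give_two_patches(self):
        s = ProteinStructure(
            chains=["A"],
            residues=[
                (("A", 1, ""), "ALA", (0, 1)),
                (("A", 2, ""), "GLY", (1, 2)),
            ],
            atoms=[
                Atom("CA", "C", np.zeros(3), ("A", 1, "")),
                Atom("CA", "C", np.array([100.0, 0, 0]), ("A", 2, "")),
            ],
        )
        pts = rep.generate_surface(s, target_points=300)
        d0 = np.linalg.norm(pts, axis=1)
        d1 = np.linalg.norm(pts - [100, 0, 0], axis=1)
        on0 = np.isclose(d0, 1.7, atol=1e-6)
        on1 = np.isclose(d1, 1.7, atol=1e-6)
        assert np.all(on0 | on1) and on0.any() and on1.any()

    def test_point_budget_contract(self):
        s = single_residue([Atom("CA", "C", np.zeros(3), ("A", 1, ""))])
        pts = rep.generate_surface(s, target_points=256)
        assert 0.9 * 256 <= len(pts) <= 1.1 * 256


class TestAssociatePoints:
    def test_nearest_atom_wins(self):
        s = ProteinStructure(
            chains=["A"],
            residues=[
                (("A", 1, ""), "ALA", (0, 1)),
                (("A", 2, ""), "GLY", (1, 2)),
            ],
            atoms=[
                Atom("CA", "C", np.zeros(3), ("A", 1, "")),
                Atom("CA", "C", np.array([0.0, 0, 10]), ("A", 2, "")),
            ],
        )
        idx = rep.associate_points(np.array([[0.0, 0, 2]]), s)
        assert idx[0] == 0

    def test_tie_goes_to_earlier_atom(self):
        s = ProteinStructure(
            chains=["A"],
            residues=[
                (("A", 1, ""), "ALA", (0, 1)),
                (("A", 2, ""), "GLY", (1, 2)),
            ],
            atoms=[
                Atom("CA", "C", np.zeros(3), ("A", 1, "")),
                Atom("CA", "C", np.array([0.0, 0, 4]), ("A", 2, "")),
            ],
        )
        idx = rep.associate_points(np.array([[0.0, 0, 2]]), s)
        assert idx[0] == 0

    def test_matches_brute_force_scan(self, synth_sample):
        s = synth_sample.ab_structure
        rng = np.random.default_rng(5)
        pts = rng.uniform(-10, 30, (50, 3))
        got = rep.associate_points(pts, s)
        coords = s.atom_coords()
        res_of_atom = s.atom_residue_index()
        for p, g in zip(pts, got):
            d = np.linalg.norm(coords - p, axis=1)
            assert g == res_of_atom[np.argmin(d)]


class TestTransferFeatures:
    def test_gather_semantics(self):
        feats = np.arange(6.0).reshape(2, 3)
        out = rep.transfer_features_to_surface(np.array([0, 0]), feats)
        np.testing.assert_array_equal(out, feats[[0, 0]])

    def test_permutation_equivariance_and_loop_oracle(self):
        rng = np.random.default_rng(1)
        feats = rng.standard_normal((7, 28))
        p2r = rng.integers(0, 7, 40)
        out = rep.transfer_features_to_surface(p2r, feats)
        for p in range(40):
            np.testing.assert_array_equal(out[p], feats[p2r[p]])
        perm = rng.permutation(40)
        np.testing.assert_array_equal(
            rep.transfer_features_to_surface(p2r[perm], feats), out[perm]
        )

    def test_out_of_range_index_rejected(self):
        with pytest.raises(IndexError):
            rep.transfer_features_to_surface(np.array([5]), np.zeros((2, 28)))


class TestBindingLabels:
    @staticmethod
    def two_atom_pair(dist):
        a = single_residue([Atom("CA", "C", np.zeros(3), ("A", 1, ""))])
        b = ProteinStructure(
            chains=["B"],
            residues=[(("B", 1, ""), "GLY", (0, 1))],
            atoms=[Atom("CA", "C", np.array([dist, 0, 0]), ("B", 1, ""))],
        )
        return a, b

    def test_close_pair_positive(self):
        la, lb = rep.compute_binding_labels(*self.two_atom_pair(3.0))
        assert la.per_residue[0] and lb.per_residue[0]
        assert la.positive_count == 1

    def test_distant_pair_negative(self):
        la, lb = rep.compute_binding_labels(*self.two_atom_pair(20.0))
        assert not la.per_residue.any() and not lb.per_residue.any()

    def test_matches_all_pairs_scan(self, synth_sample):
        ab, ag = synth_sample.ab_structure, synth_sample.ag_structure
        la, lb = rep.compute_binding_labels(ab, ag, cutoff=4.5)
        ca, cb = ab.atom_coords(), ag.atom_coords()
        d = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=2)
        ra, rb_idx = ab.atom_residue_index(), ag.atom_residue_index()
        want_a = np.zeros(ab.n_residues, bool)
        want_b = np.zeros(ag.n_residues, bool)
        ii, jj = np.where(d <= 4.5)
        want_a[ra[ii]] = True
        want_b[rb_idx[jj]] = True
        np.testing.assert_array_equal(la.per_residue, want_a)
        np.testing.assert_array_equal(lb.per_residue, want_b)

    def test_monotone_in_cutoff(self, synth_sample):
        ab, ag = synth_sample.ab_structure, synth_sample.ag_structure
        prev_a = prev_b = None
        for cutoff in (3.0, 4.5, 6.0, 8.0):
            la, lb = rep.compute_binding_labels(ab, ag, cutoff=cutoff)
            if prev_a is not None:
                assert np.all(la.per_residue >= prev_a)
                assert np.all(lb.per_residue >= prev_b)
            prev_a, prev_b = la.per_residue, lb.per_residue


class TestCdrRegion:
    def test_ranges_select_union(self, synth_sample):
        ab = synth_sample.ab_structure
        mask = rep.select_cdr_region(ab, [("H", 5, 10), ("H", 8, 12)])
        for r, (key, _, _) in enumerate(ab.residues):
            assert mask[r] == (5 <= key[1] <= 12)

    def test_empty_spec_selects_everything(self, synth_sample):
        assert rep.select_cdr_region(synth_sample.ab_structure, None).all()

    def test_absent_chain_rejected(self, synth_sample):
        with pytest.raises(ValueError):
            rep.select_cdr_region(synth_sample.ab_structure, [("Q", 1, 5)])
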