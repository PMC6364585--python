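"""Cortex allocation, surface triangulation, labelling and tension."""

import numpy as np
import pytest

from scemsort import (Aggregate, CortexParams, TriangulationError,
                      allocate_cortex, make_model_params, morse_force,
                      triangulate_cortex)
from scemsort import cortex
from scemsort.core import CORTEX, advance, total_forces
from scemsort.cortex import sector_index
from scemsort.fixtures import _fibonacci_sphere
from scemsort.lifecycle import seed_cell

CP = CortexParams()


def brute_force_allocation(positions, com, frac=0.8):
    rel = positions - com
    r = np.linalg.norm(rel, axis=1)
    sec = sector_index(rel)
    labels = np.zeros(len(positions), dtype=np.uint8)
    for s in np.unique(sec):
        mask = sec == s
        labels[mask] = (r[mask] >= frac * r[mask].max()).astype(np.uint8)
    return labels


class TestSectorPartition:
    def test_covers_sphere_with_equal_solid_angles(self, rng):
        """Uniform directions land in each of the 32 sectors with equal
        probability (equal steradians)."""
        n = 400_000
        v = rng.normal(size=(n, 3))
        counts = np.bincount(sector_index(v), minlength=32)
        assert counts.min() > 0
        expected = n / 32
        assert np.abs(counts - expected).max() < 5 * np.sqrt(expected)

    def test_all_indices_in_range(self, rng):
        idx = sector_index(rng.normal(size=(1000, 3)))
        assert idx.min() >= 0 and idx.max() <= 31


class TestAllocateCortex:
    def test_single_element_is_cortex(self):
        out = allocate_cortex(np.array([[0.0, 0.0, 0.0]]),
                              np.zeros(3), CP)
        assert out[0] == CORTEX

    def test_uniform_shell_is_all_cortex(self):
        pts = _fibonacci_sphere(64) * 2.0
        assert np.all(allocate_cortex(pts, np.zeros(3), CP) == CORTEX)

    def test_matches_brute_force_oracle(self, rng):
        pts = rng.normal(size=(200, 3))
        pts *= (rng.uniform(0, 1, 200) ** (1 / 3) /
                np.linalg.norm(pts, axis=1))[:, None] * 2.0
        com = pts.mean(axis=0)
        assert np.array_equal(allocate_cortex(pts, com, CP),
                              brute_force_allocation(pts, com))

    def test_idempotent_for_fixed_positions(self, rng):
        pts = rng.normal(size=(80, 3))
        com = pts.mean(axis=0)
        first = allocate_cortex(pts, com, CP)
        assert np.array_equal(first, allocate_cortex(pts, com, CP))


class TestTriangulation:
    def test_tetrahedron(self):
        pts = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                       dtype=float)
        mesh = triangulate_cortex(0, np.arange(4), pts)
        assert len(mesh.facets) == 4
        assert len(mesh.edges) == 6
        assert mesh.euler_characteristic == 2

    def test_icosahedron(self):
        phi = (1 + 5 ** 0.5) / 2
        pts = np.array([[0, 1, phi], [0, -1, phi], [0, 1, -phi],
                        [0, -1, -phi], [1, phi, 0], [-1, phi, 0],
                        [1, -phi, 0], [-1, -phi, 0], [phi, 0, 1],
                        [-phi, 0, 1], [phi, 0, -1], [-phi, 0, -1]],
                       dtype=float)
        mesh = triangulate_cortex(0, np.arange(12), pts)
        assert len(mesh.facets) == 20
        assert len(mesh.edges) == 30
        assert mesh.euler_characteristic == 2

    def test_sphere_area_converges(self):
        R = 3.0
        pts = _fibonacci_sphere(500) * R
        mesh = triangulate_cortex(0, np.arange(500), pts)
        assert mesh.total_area == pytest.approx(4 * np.pi * R * R,
                                                rel=0.02)

    def test_closed_surface_invariants(self, rng):
        pts = _fibonacci_sphere(100) * (2.0 + 0.2 * rng.normal(size=(100, 1)))
        mesh = triangulate_cortex(0, np.arange(100), pts)
        assert mesh.euler_characteristic == 2
        assert np.all(mesh.edge_facet_incidence() == 2)
        # every cortex element is a vertex of >= 3 facets
        counts = np.bincount(mesh.facets.ravel(), minlength=100)
        assert counts.min() >= 3

    def test_too_few_points_raises(self):
        with pytest.raises(TriangulationError):
            triangulate_cortex(0, np.arange(3), np.eye(3))

    def test_outward_normals(self):
        pts = _fibonacci_sphere(64) * 2.0
        mesh = triangulate_cortex(0, np.arange(64), pts)
        unit = pts / np.linalg.norm(pts, axis=1)[:, None]
        dots = np.einsum("ij,ij->i", mesh.vertex_normals[mesh.vertices],
                         unit[mesh.vertices])
        assert dots.min() > 0.9


def _three_cell_row(params):
    """Types 1, 1, 2 in a row of touching shell cells."""
    shell = _fibonacci_sphere(40) * 1.5
    sep = 3.6
    pos = np.vstack([shell + [-sep, 0, 0], shell, shell + [sep, 0, 0]])
    agg = Aggregate(pos, np.repeat([0, 1, 2], 40), [1, 1, 2])
    cortex.refresh(agg, params.table, params.cortex)
    return agg


class TestInterfaceLabels:
    def test_isolated_cell_has_no_labels(self, base_params, rng):
        agg = seed_cell(32, base_params, rng, relax_steps=50)
        assert not agg.label_same.any()
        assert not agg.label_other.any()

    def test_like_doublet_labels_same_type(self, base_params):
        shell = _fibonacci_sphere(40) * 1.5
        pos = np.vstack([shell + [-1.8, 0, 0], shell + [1.8, 0, 0]])
        agg = Aggregate(pos, np.repeat([0, 1], 40), [1, 1])
        cortex.refresh(agg, base_params.table, base_params.cortex)
        assert agg.label_same.any()
        assert not agg.label_other.any()

    def test_middle_cell_carries_both_labels_in_disjoint_zones(
            self, base_params):
        agg = _three_cell_row(base_params)
        mid = agg.cell_ids == 1
        assert (agg.label_same & mid).any()
        assert (agg.label_other & mid).any()
        # the two zones are disjoint element sets on opposite sides
        same_x = agg.positions[agg.label_same & mid, 0]
        other_x = agg.positions[agg.label_other & mid, 0]
        assert same_x.max() < 0 < other_x.min()

    def test_zero_adhesion_means_no_adhesive_labels(self):
        params = make_model_params(beta=1.0, A_M=0.0, gamma_m=1.0)
        agg = _three_cell_row(params)
        assert not agg.label_same.any()
        assert not agg.label_other.any()


class TestCorticalTension:
    def test_beta_one_leaves_tensions_uniform(self, base_params):
        agg = _three_cell_row(base_params)  # beta == 1 everywhere
        for mesh in agg.network.meshes.values():
            assert np.allclose(mesh.edge_tensions,
                               base_params.cortex.gamma_m)

    def test_beta_zero_zeroes_interface_edges(self):
        params = make_model_params(beta=0.0, A_M=0.2, gamma_m=1.0)
        agg = _three_cell_row(params)
        mesh = agg.network.meshes[1]  # middle cell, type 1
        both_same = (agg.label_same[mesh.edges[:, 0]]
                     & agg.label_same[mesh.edges[:, 1]])
        assert both_same.any()
        assert np.allclose(mesh.edge_tensions[both_same], 0.0)
        assert np.allclose(mesh.edge_tensions[~both_same],
                           params.cortex.gamma_m)

    def test_unlike_interface_uses_cross_beta(self):
        B = np.array([[0.4, 0.7], [0.7, 1.0]])
        params = make_model_params(beta=B, A_M=0.2, gamma_m=1.0)
        agg = _three_cell_row(params)
        mesh = agg.network.meshes[1]
        both_other = (agg.label_other[mesh.edges[:, 0]]
                      & agg.label_other[mesh.edges[:, 1]])
        only_same = (agg.label_same[mesh.edges[:, 0]]
                     & agg.label_same[mesh.edges[:, 1]]) & ~both_other
        assert np.allclose(mesh.edge_tensions[both_other & ~only_same],
                           0.7)
        assert np.allclose(mesh.edge_tensions[only_same], 0.4)

    def test_tension_forces_are_edge_aligned_and_balanced(self,
                                                          base_params):
        agg = _three_cell_row(base_params)
        f = agg.network.tension_forces(agg.positions, agg.n_elements)
        assert np.linalg.norm(f.sum(axis=0)) < 1e-10


class TestDensityNormalisedAdhesion:
    def test_uniform_shell_gives_unit_factors(self, base_params):
        shell = _fibonacci_sphere(100) * 2.0
        agg = Aggregate(shell, np.zeros(100, int), [1])
        cortex.refresh(agg, base_params.table, base_params.cortex)
        f = agg.adhesion_factors
        assert f.mean() == pytest.approx(1.0, abs=0.02)
        assert f.std() < 0.25

    def test_denser_patch_gets_smaller_factors(self, base_params):
        """Doubling the local element density roughly halves the local
        adhesion factors (area share per element halves)."""
        base = _fibonacci_sphere(100) * 2.0
        cap = base[base[:, 2] > 1.7]
        dense = np.vstack([base, cap + [0.12, 0.07, -0.02]])
        n = len(dense)
        agg = Aggregate(dense, np.zeros(n, int), [1])
        cortex.refresh(agg, base_params.table, base_params.cortex)
        in_cap = dense[:, 2] > 1.75
        lo = agg.adhesion_factors[in_cap].mean()
        hi = agg.adhesion_factors[~in_cap & (dense[:, 2] < 1.0)].mean()
        assert lo < 0.75 * hi
        assert lo == pytest.approx(0.5 * hi, rel=0.45)


class TestContainment:
    def test_no_element_escapes_over_long_run(self, rng):
        """Escaping cytoplasm is re-allocated cortex and pulled back, so
        the max radius stays bounded over thousands of steps."""
        params = make_model_params(beta=1.0, A_M=0.0, gamma_m=0.8,
                                   noise_amplitude=1.0)
        agg = seed_cell(32, params, rng, relax_steps=200)
        rmax = []
        for _ in range(20):
            advance(agg, params, rng, 100)
            com = agg.positions.mean(axis=0)
            rmax.append(np.linalg.norm(agg.positions - com,
                                       axis=1).max())
        assert max(rmax) < 4.0

    def test_relaxed_cell_com_drift_without_noise(self, rng):
        params = make_model_params(beta=1.0, A_M=0.0, gamma_m=0.8,
                                   noise_amplitude=0.0)
        agg = seed_cell(32, params, rng, relax_steps=2000)
        com0 = agg.positions.mean(axis=0)
        for _ in range(100):
            advance(agg, params, rng, 1)
        drift = np.linalg.norm(agg.positions.mean(axis=0) - com0) / 100
        assert drift < 1e-9
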