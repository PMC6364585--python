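"""Element-level mechanics: Morse pair law, neighbour search, stepping."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scemsort import (Aggregate, ConsistencyError, DynamicsParams,
                      MorseParams, StepSizeError, advance, find_neighbours,
                      langevin_step, make_model_params, morse_force,
                      morse_potential, total_forces)
from scemsort import cortex

UNTRUNCATED = MorseParams(De=1.0, a=1.0, re=1.0, cutoff=np.inf)


class TestMorsePair:
    def test_zero_at_minimum_and_plateau_at_infinity(self):
        assert morse_potential(1.0, UNTRUNCATED) == pytest.approx(0.0)
        assert morse_potential(60.0, UNTRUNCATED) == pytest.approx(1.0,
                                                                   abs=1e-9)

    def test_quarter_depth_point(self):
        # r = re + ln2/a makes the exponentials 1/4 and 1/2: V = De/4
        r = 1.0 + math.log(2.0)
        assert morse_potential(r, UNTRUNCATED) == pytest.approx(0.25)

    def test_shift_truncation_is_continuous_and_zero_beyond(self):
        p = MorseParams(De=1.0, a=4.0, re=1.0, cutoff=2.5)
        eps = 1e-6
        assert morse_potential(2.5 - eps, p) == pytest.approx(0.0, abs=1e-4)
        assert morse_potential(2.5 + eps, p) == 0.0
        assert morse_force(2.6, p) == 0.0

    def test_force_sign_convention(self):
        assert morse_force(1.0, UNTRUNCATED) == pytest.approx(0.0)
        assert morse_force(0.8, UNTRUNCATED) > 0  # repulsive inside
        assert morse_force(1.5, UNTRUNCATED) < 0  # attractive outside

    def test_max_attractive_force_location_and_value(self):
        # analytic minimum of dV/dr: r* = re + ln2/a, |F| = a De / 2
        for a, De in [(1.0, 1.0), (4.0, 0.05), (8.0, 0.1)]:
            p = MorseParams(De=De, a=a, re=1.0, cutoff=np.inf)
            rstar = 1.0 + math.log(2.0) / a
            assert morse_force(rstar, p) == pytest.approx(-a * De / 2.0)
            rr = np.linspace(1.0, 1.0 + 6.0 / a, 4001)
            assert morse_force(rr, p).min() == pytest.approx(
                -a * De / 2.0, rel=1e-5)

    def test_nonpositive_separation_rejected(self):
        with pytest.raises(ValueError):
            morse_potential(0.0, UNTRUNCATED)
        with pytest.raises(ValueError):
            morse_force(-1.0, UNTRUNCATED)

    @given(st.floats(min_value=0.05, max_value=3.0))
    @settings(max_examples=50, deadline=None)
    def test_force_is_negative_gradient(self, r):
        h = 1e-6
        fd = -(morse_potential(r + h, UNTRUNCATED)
               - morse_potential(r - h, UNTRUNCATED)) / (2 * h)
        assert morse_force(r, UNTRUNCATED) == pytest.approx(fd, abs=1e-4,
                                                            rel=1e-4)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            MorseParams(De=-1.0, a=1.0)
        with pytest.raises(ValueError):
            MorseParams(De=1.0, a=0.0)
        with pytest.raises(ValueError):
            MorseParams(De=1.0, a=1.0, re=1.0, cutoff=0.5)


class TestNeighbourSearch:
    def test_boundary_inclusion(self):
        pts = np.array([[0.0, 0, 0], [0.99, 0, 0]])
        assert len(find_neighbours(pts, 1.0)) == 1
        pts[1, 0] = 1.01
        assert len(find_neighbours(pts, 1.0)) == 0

    def test_matches_all_pairs_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 200))
            cutoff = float(rng.uniform(0.5, 2.0))
            pts = rng.uniform(-3, 3, size=(n, 3))
            got = {tuple(p) for p in find_neighbours(pts, cutoff)}
            d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
            iu = np.triu_indices(n, 1)
            want = {(int(i), int(j))
                    for i, j in zip(*iu) if d[i, j] <= cutoff}
            assert got == want

    def test_invalid_cutoff(self):
        with pytest.raises(ValueError):
            find_neighbours(np.zeros((2, 3)), 0.0)


def _relaxed_cell(params, rng, n=32, steps=400):
    from scemsort.lifecycle import seed_cell

    return seed_cell(n, params, rng, relax_steps=steps)


class TestTotalForces:
    def test_net_internal_force_is_zero(self, base_params, rng):
        agg = _relaxed_cell(base_params, rng)
        f = total_forces(agg, base_params.table)
        assert np.linalg.norm(f.sum(axis=0)) < 1e-9

    def test_net_force_zero_for_multicell(self, base_params, rng):
        from scemsort.lifecycle import LifecycleParams, divide_cell

        agg = _relaxed_cell(base_params, rng, n=64)
        divide_cell(agg, 0, LifecycleParams(division_mode="symmetric"), rng)
        cortex.refresh(agg, base_params.table, base_params.cortex)
        f = total_forces(agg, base_params.table)
        assert np.linalg.norm(f.sum(axis=0)) < 1e-9

    def test_stale_network_raises(self, base_params, rng):
        agg = _relaxed_cell(base_params, rng)
        agg.invalidate()
        with pytest.raises(ConsistencyError):
            total_forces(agg, base_params.table)

    def test_mirror_symmetric_doublet_forces(self, base_params):
        """A doublet mirrored through its interface plane has a mirror-
        symmetric force field."""
        from scemsort.fixtures import synthetic_truncated_doublet

        half = synthetic_truncated_doublet(0.5)
        lower = half.positions[half.cell_ids == 0]
        upper = lower * [1.0, 1.0, -1.0]  # exact mirror through z = 0
        n0 = len(lower)
        agg = Aggregate(np.vstack([lower, upper]),
                        np.r_[np.zeros(n0, int), np.ones(n0, int)], [1, 1])
        cortex.refresh(agg, base_params.table, base_params.cortex)
        f = total_forces(agg, base_params.table)
        f0, f1 = f[:n0], f[n0:]
        assert np.allclose(f0[:, :2], f1[:, :2], atol=1e-8)
        assert np.allclose(f0[:, 2], -f1[:, 2], atol=1e-8)


class TestLangevinStep:
    def test_no_force_no_noise_is_identity(self, rng):
        agg = Aggregate(rng.normal(size=(5, 3)), np.zeros(5, int), [1])
        before = agg.positions.copy()
        dp = DynamicsParams(noise_amplitude=0.0, dt=0.01)
        langevin_step(agg, np.zeros((5, 3)), dp, rng)
        assert np.array_equal(agg.positions, before)
        assert agg.time == pytest.approx(0.01)

    def test_constant_force_displacement(self, rng):
        agg = Aggregate(np.zeros((1, 3)), [0], [1])
        dp = DynamicsParams(gamma_drag=2.0, noise_amplitude=0.0, dt=0.05)
        langevin_step(agg, np.array([[4.0, 0.0, 0.0]]), dp, rng)
        assert agg.positions[0, 0] == pytest.approx(0.05 * 4.0 / 2.0)

    def test_displacement_guard(self, rng):
        agg = Aggregate(np.zeros((1, 3)), [0], [1])
        dp = DynamicsParams(noise_amplitude=0.0, dt=0.01)
        with pytest.raises(StepSizeError):
            langevin_step(agg, np.array([[100.0, 0.0, 0.0]]), dp, rng)

    def test_free_diffusion_msd_matches_closed_form(self, rng):
        """With zero force the mean-squared displacement grows linearly:
        MSD(n steps) = 3 n (dt sigma / gamma)^2 per element."""
        n_el, n_steps = 200, 2000
        agg = Aggregate(np.zeros((n_el, 3)), np.zeros(n_el, int), [1])
        dp = DynamicsParams(noise_amplitude=0.5, dt=0.01)
        zero = np.zeros((n_el, 3))
        for _ in range(n_steps):
            langevin_step(agg, zero, dp, rng)
        msd = (agg.positions ** 2).sum(axis=1).mean()
        expected = 3 * n_steps * (dp.dt * dp.noise_amplitude
                                  / dp.gamma_drag) ** 2
        assert msd == pytest.approx(expected, rel=0.15)


class TestTableAndViews:
    def test_interaction_table_lookup(self, base_params):
        table = base_params.table
        p, adhesive = table.lookup(1, 1, same_cell=True)
        assert p is table.intra and not adhesive
        p, adhesive = table.lookup(1, 1, same_cell=False)
        assert p is table.repulsion and adhesive
        _, adhesive = table.lookup(0, 1, same_cell=False)
        assert not adhesive
        adh = table.adhesive_params(1, 2)
        # well depth realises the target maximum attractive force A_M
        assert adh.a * adh.De / 2.0 == pytest.approx(table.A_M[0, 1])

    def test_element_view(self, base_params, rng):
        agg = _relaxed_cell(base_params, rng, n=24, steps=50)
        el = agg.element(0)
        assert el.cell_id == 0
        assert el.etype in ("cytoplasm", "cortex")
        assert el.interface_label == frozenset()
        # labels only ever appear on cortex elements
        labelled = agg.label_same | agg.label_other
        assert not np.any(labelled & (agg.etypes == 0))

    def test_invalid_aggregate_inputs(self):
        with pytest.raises(ValueError):
            Aggregate(np.zeros((2, 3)), [0, 5], [1])  # missing cell
        with pytest.raises(ValueError):
            Aggregate(np.zeros((2, 3)), [0, 0], [3])  # bad type


class TestDeterminism:
    def test_same_seed_same_trajectory(self):
        params = make_model_params(beta=0.8, A_M=0.1, gamma_m=0.5,
                                   noise_amplitude=0.5)
        out = []
        for _ in range(2):
            rng = np.random.default_rng(42)
            agg = _relaxed_cell(params, rng, n=24, steps=50)
            advance(agg, params, rng, 100)
            out.append(agg.positions.copy())
        assert np.array_equal(out[0], out[1])
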