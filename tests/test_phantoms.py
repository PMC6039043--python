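"""Refractive-index models and phantom geometry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octfdtd import (
    BrixModel,
    GlassRodSpec,
    GridSpec,
    NerveSpec,
    brix_index,
    build_glass_rod,
    build_nerve,
    build_slab,
    build_two_layer,
    epineurium_index,
    mixture_index,
    myelin_index,
    perturb_axons,
)
from octfdtd.phantoms import ACTIVE_DELTA_N, TISSUE_INDICES


class TestBrix:
    def test_pure_water_intercept(self):
        assert brix_index(0.0) == pytest.approx(1.3290, abs=1e-12)

    def test_ten_degrees(self):
        assert brix_index(10.0) == pytest.approx(1.3435, abs=1e-12)

    def test_slope_per_degree(self):
        assert brix_index(1.0) - brix_index(0.0) == pytest.approx(0.00145, abs=1e-12)

    def test_active_nerve_equivalence(self):
        """0.01 degree Brix shifts the index by the active-nerve delta."""
        assert brix_index(0.01) - brix_index(0.0) == pytest.approx(
            ACTIVE_DELTA_N, rel=1e-9
        )

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            brix_index(-0.1)

    def test_bad_model_rejected(self):
        with pytest.raises(ValueError):
            BrixModel(slope=-1e-3)


class TestMixture:
    def test_epineurium_recipe(self):
        # 40% ground substance, dry mass 70% fibres / 30% lipids
        n = epineurium_index()
        assert n == pytest.approx(0.40 * 1.345 + 0.60 * (0.70 * 1.43 + 0.30 * 1.45),
                                  abs=1e-12)
        assert round(n, 1) == 1.4

    def test_myelin_recipe(self):
        n = myelin_index()
        assert n == pytest.approx(0.40 * 1.3290 + 0.60 * (0.70 * 1.45 + 0.30 * 1.5),
                                  abs=1e-12)
        assert round(n, 1) == 1.4

    def test_identity_mixture(self):
        assert mixture_index([(1.42, 1.0)]) == pytest.approx(1.42)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            mixture_index([(1.4, 0.5), (1.3, 0.4)])

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.tuples(
                st.floats(1.0, 2.0, allow_nan=False),
                st.floats(0.01, 1.0, allow_nan=False),
            ),
            min_size=1, max_size=6,
        ),
        st.randoms(use_true_random=False),
    )
    def test_permutation_invariant_and_bounded(self, comps, rnd):
        total = sum(f for _, f in comps)
        comps = [(n, f / total) for n, f in comps]
        n0 = mixture_index(comps)
        shuffled = list(comps)
        rnd.shuffle(shuffled)
        assert mixture_index(shuffled) == pytest.approx(n0, rel=1e-12)
        lo = min(n for n, _ in comps)
        hi = max(n for n, _ in comps)
        assert lo - 1e-12 <= n0 <= hi + 1e-12


@pytest.fixture(scope="module")
def grid():
    return GridSpec.create(850e-9 / 25, 20e-6, 4e-6)


class TestGlassRod:
    def spec(self, brix=0.1):
        return GlassRodSpec(water_glass_x=10e-6, glass_solution_x=14e-6, brix=brix)

    def test_layer_indices_sampled(self, grid):
        m = build_glass_rod(self.spec(), grid)
        j = grid.n_cells_y // 2
        assert m.n_grid[grid.x_index(5e-6), j] == pytest.approx(1.3272)
        assert m.n_grid[grid.x_index(12e-6), j] == pytest.approx(1.5098)
        assert m.n_grid[grid.x_index(17e-6), j] == pytest.approx(brix_index(0.1))

    def test_zero_brix_is_pure_water_solution(self, grid):
        m = build_glass_rod(self.spec(brix=0.0), grid)
        assert m.provenance["solution"] == pytest.approx(1.3290)

    def test_layer_cell_counts(self, grid):
        m = build_glass_rod(self.spec(), grid)
        glass_cols = np.sum(m.labels[:, 0] == 1)
        assert glass_cols == pytest.approx(4e-6 / grid.dx, abs=1)

    def test_overlapping_layers_rejected(self):
        with pytest.raises(ValueError):
            GlassRodSpec(water_glass_x=10e-6, glass_solution_x=10e-6)

    def test_layers_outside_domain_rejected(self, grid):
        with pytest.raises(ValueError):
            build_glass_rod(
                GlassRodSpec(water_glass_x=10e-6, glass_solution_x=30e-6), grid
            )


class TestNerve:
    def spec(self):
        return NerveSpec(epineurium_thickness=2.5e-6, fibre_radius=0.35e-6,
                         edge_margin=0.6e-6)

    def test_index_support_matches_tissue_registry(self, grid):
        m = build_nerve(self.spec(), grid, seed=0)
        support = set(np.round(np.unique(m.n_grid), 6))
        assert support == set(np.round(list(TISSUE_INDICES.values()), 6))

    def test_three_elastic_fibres_present(self, grid):
        from scipy.ndimage import label as cc_label

        m = build_nerve(self.spec(), grid, seed=0)
        _, n_components = cc_label(m.mask("elastic_fibre"))
        assert n_components == 3

    def test_first_half_is_ringer(self, grid):
        m = build_nerve(self.spec(), grid, seed=0)
        half = grid.x_index(10e-6)
        assert np.all(m.labels[:half] == 0)
        assert np.allclose(m.n_grid[:half], 1.3290)

    def test_deterministic_given_seed(self, grid):
        a = build_nerve(self.spec(), grid, seed=7)
        b = build_nerve(self.spec(), grid, seed=7)
        assert np.array_equal(a.n_grid, b.n_grid)
        assert np.array_equal(a.labels, b.labels)

    def test_axons_present_with_myelin_sheaths(self, grid):
        m = build_nerve(self.spec(), grid, seed=0)
        assert np.sum(m.mask("axon")) > 0
        assert np.sum(m.mask("myelin")) > 0

    def test_fibre_outside_band_rejected(self, grid):
        spec = NerveSpec(
            epineurium_thickness=2.5e-6,
            fibre_centres=((10.1e-6, 2e-6),),  # touches the Ringer boundary
            fibre_radius=0.35e-6,
        )
        with pytest.raises(ValueError):
            build_nerve(spec, grid, seed=0)


class TestPerturbAxons:
    def test_zero_delta_is_identity(self, grid):
        m = build_nerve(NerveSpec(epineurium_thickness=2.5e-6,
                                  fibre_radius=0.35e-6, edge_margin=0.6e-6), grid, 0)
        p = perturb_axons(m, 0.0)
        assert np.array_equal(p.n_grid, m.n_grid)

    def test_only_axon_cells_modified(self, grid):
        m = build_nerve(NerveSpec(epineurium_thickness=2.5e-6,
                                  fibre_radius=0.35e-6, edge_margin=0.6e-6), grid, 0)
        p = perturb_axons(m, ACTIVE_DELTA_N)
        mask = m.mask("axon")
        assert np.all(p.n_grid[mask] == pytest.approx(1.338 + ACTIVE_DELTA_N))
        changed = p.n_grid != m.n_grid
        assert np.array_equal(changed, mask)
        assert np.sum(changed) == np.sum(mask)

    def test_missing_label_rejected(self, grid):
        m = build_two_layer(10e-6, 1.3272, 1.5098, grid)
        with pytest.raises(KeyError):
            perturb_axons(m, 1e-5)

    def test_index_below_one_rejected(self, grid):
        m = build_nerve(NerveSpec(epineurium_thickness=2.5e-6,
                                  fibre_radius=0.35e-6, edge_margin=0.6e-6), grid, 0)
        with pytest.raises(ValueError):
            perturb_axons(m, -0.5)


class TestGenericBuilders:
    def test_two_layer_interface_position(self, grid):
        m = build_two_layer(12e-6, 1.3272, 1.5098, grid)
        prof = m.axial_profile(grid)
        assert prof.interface_x("layer1/layer2") == pytest.approx(12e-6, abs=grid.dx)

    def test_slab_round_trip_profile(self, grid):
        m = build_slab(10e-6, 4e-6, 1.5098, 1.3272, grid)
        prof = m.axial_profile(grid)
        width = prof.interface_x("slab/background") - prof.interface_x("background/slab")
        assert width == pytest.approx(4e-6, abs=2 * grid.dx)

    def test_maps_accepted_by_solver_contract(self, grid):
        """Every builder output passes the solver's material validation."""
        from octfdtd import Solver

        for m in (
            build_two_layer(12e-6, 1.3272, 1.5098, grid),
            build_slab(10e-6, 4e-6, 1.5098, 1.3272, grid),
            build_glass_rod(GlassRodSpec(water_glass_x=10e-6, glass_solution_x=14e-6),
                            grid),
            build_nerve(NerveSpec(epineurium_thickness=2.5e-6, fibre_radius=0.35e-6,
                                  edge_margin=0.6e-6), grid, 0),
        ):
            Solver(grid, m)  # raises on any shape/value violation
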