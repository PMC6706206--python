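import math

import numpy as np
import pytest

from debipm import (
    SizeMesh,
    assemble_kernel,
    build_mesh,
    dominant_eigenpair,
    growth_mean,
    growth_sd,
    growth_transition,
    mean_body_size,
    offspring_distribution,
    reproduction_rate,
    survival_probability,
)
from debipm.kernel import export_kernel, reproduction_cell_average, survival_cell_average
from debipm.life_history import DEBParams


class TestMesh:
    def test_upper_bound_covers_starvation_cutoff(self, orchestia, manta):
        assert build_mesh(orchestia, 0.1, 100).upper == pytest.approx(15.61 / 0.8)
        assert build_mesh(manta, 0.1, 100).upper == pytest.approx(550 / 0.8)

    def test_midpoints_structure(self, orchestia):
        mesh = build_mesh(orchestia, 0.1, 50)
        mids = mesh.midpoints
        assert len(mids) == 50
        assert np.all(np.diff(mids) > 0)
        np.testing.assert_allclose(
            mids, mesh.lower + (np.arange(50) + 0.5) * mesh.cell_width
        )

    def test_tiny_mesh_rejected(self, orchestia):
        with pytest.raises(ValueError):
            build_mesh(orchestia, 0.1, 1)

    def test_lower_bound_padded_below_birth_length(self, orchestia):
        mesh = build_mesh(orchestia, 0.1, 100)
        sd = growth_sd(orchestia, 0.1)
        assert mesh.lower == pytest.approx(orchestia.L_b - 5 * sd)


class TestSurvival:
    def test_below_cutoff(self, orchestia):
        assert survival_probability(10.0, orchestia, 1.0) == pytest.approx(
            math.exp(-0.27), abs=1e-12
        )

    def test_starved(self, orchestia):
        # cutoff at E(Y)=0.4 is 15.61*0.4/0.8 = 7.805 mm
        assert survival_probability(10.0, orchestia, 0.4) == 0.0

    def test_maximum_length_starves_below_kappa(self, orchestia):
        assert survival_probability(orchestia.L_m, orchestia, 0.79) == 0.0
        assert survival_probability(orchestia.L_m, orchestia, 0.81) > 0.0

    def test_feeding_level_domain(self, orchestia):
        with pytest.raises(ValueError):
            survival_probability(5.0, orchestia, 1.2)

    def test_cell_average_interpolates_the_step(self, orchestia):
        mesh = build_mesh(orchestia, 0.1, 200)
        S = survival_cell_average(mesh, orchestia, 0.4)
        cutoff = orchestia.starvation_cutoff(0.4)
        full = mesh.midpoints + mesh.cell_width / 2 <= cutoff
        none = mesh.midpoints - mesh.cell_width / 2 >= cutoff
        np.testing.assert_allclose(S[full], math.exp(-0.27))
        np.testing.assert_allclose(S[none], 0.0)
        partial = ~(full | none)
        assert np.all((S[partial] > 0) & (S[partial] < math.exp(-0.27)))


class TestGrowth:
    def test_fixed_point_at_full_feeding(self, orchestia):
        assert growth_mean(orchestia.L_m, orchestia, 1.0) == pytest.approx(orchestia.L_m)

    def test_manta_first_year(self, manta):
        expected = 130 * math.exp(-0.18) + (1 - math.exp(-0.18)) * 550
        assert growth_mean(130.0, manta, 1.0) == pytest.approx(expected)
        assert expected == pytest.approx(199.2, abs=0.05)

    def test_shrinks_toward_ultimate_length(self, orchestia):
        L = 12.0  # above L_inf = 15.61 * 0.5 = 7.805
        assert growth_mean(L, orchestia, 0.5) < L

    def test_sd_value_and_linearity(self, orchestia):
        sd = growth_sd(orchestia, 0.1)
        assert sd == pytest.approx((1 - math.exp(-0.13)) * 15.61 * 0.1)
        assert sd == pytest.approx(0.1903, abs=5e-4)
        assert growth_sd(orchestia, 0.5) == pytest.approx(5 * sd)
        assert growth_sd(orchestia, 0.0) == 0.0

    def test_interior_columns_are_probabilities(self, orchestia):
        mesh = build_mesh(orchestia, 0.1, 200)
        G = growth_transition(mesh, orchestia, 1.0, 0.1)
        sums = G.sum(axis=0)
        sd = growth_sd(orchestia, 0.1)
        means = growth_mean(mesh.midpoints, orchestia, 1.0)
        interior = (means - 5 * sd >= mesh.lower) & (means + 5 * sd <= mesh.upper)
        assert np.all(sums[interior] >= 0.999)
        assert np.all(sums <= 1.0 + 1e-12)

    def test_no_shrink_truncates_below_source(self, manta):
        mesh = build_mesh(manta, 0.1, 150)
        G = growth_transition(mesh, manta, 0.9, 0.1)
        below = np.tril_indices(150, k=-1)
        assert np.all(G[below[1], below[0]] == 0)  # destinations i < source j

    def test_no_shrink_preserves_column_totals(self, manta):
        mesh = build_mesh(manta, 0.1, 150)
        free = growth_transition(mesh, manta, 0.9, 0.1, shrink_allowed=True)
        trunc = growth_transition(mesh, manta, 0.9, 0.1, shrink_allowed=False)
        np.testing.assert_allclose(trunc.sum(axis=0), free.sum(axis=0), atol=1e-12)

    def test_degenerate_noise_gives_point_mass(self, orchestia):
        mesh = build_mesh(orchestia, 0.0, 100)
        G = growth_transition(mesh, orchestia, 1.0, 0.0)
        sums = G.sum(axis=0)
        np.testing.assert_allclose(sums, 1.0)
        assert np.all(G.max(axis=0) == 1.0)  # one cell per column
        j = 10
        k = np.argmax(G[:, j])
        target = growth_mean(mesh.midpoints[j], orchestia, 1.0)
        assert abs(mesh.midpoints[k] - target) <= mesh.cell_width / 2 + 1e-12

    def test_eviction_warning_on_narrow_mesh(self, orchestia):
        mesh = SizeMesh(lower=10.0, upper=16.0, n_cells=60)
        with pytest.warns(RuntimeWarning, match="eviction"):
            growth_transition(mesh, orchestia, 0.2, 0.1, shrink_allowed=True)


class TestReproduction:
    def test_formula_inside_fertile_window(self, orchestia):
        assert reproduction_rate(7.30, orchestia, 1.0) == pytest.approx(
            32 * 7.30**2 / 15.61**2
        )

    def test_maximum_at_maximum_length(self, orchestia):
        assert reproduction_rate(orchestia.L_m, orchestia, 1.0) == pytest.approx(32.0)

    def test_juveniles_and_starved_do_not_reproduce(self, orchestia):
        assert reproduction_rate(5.0, orchestia, 1.0) == 0.0
        assert reproduction_rate(10.0, orchestia, 0.4) == 0.0  # above cutoff 7.805

    def test_feeding_level_scales_fecundity(self, orchestia):
        full = reproduction_rate(8.0, orchestia, 1.0)
        assert reproduction_rate(8.0, orchestia, 0.8) == pytest.approx(0.8 * full)

    def test_cell_average_matches_pointwise_away_from_edges(self, orchestia):
        mesh = build_mesh(orchestia, 0.1, 400)
        R_cells = reproduction_cell_average(mesh, orchestia, 1.0)
        mids = mesh.midpoints
        inside = (mids > orchestia.L_p + mesh.cell_width) & (
            mids < orchestia.starvation_cutoff(1.0) - mesh.cell_width
        )
        pointwise = reproduction_rate(mids[inside], orchestia, 1.0)
        np.testing.assert_allclose(R_cells[inside], pointwise, rtol=1e-4)


class TestOffspring:
    def test_point_mass_mean_is_exact(self, manta):
        mesh = build_mesh(manta, 0.1, 200)
        D = offspring_distribution(mesh, manta)
        assert D.sum() == pytest.approx(1.0)
        assert np.count_nonzero(D) <= 2
        assert float(mesh.midpoints @ D) == pytest.approx(130.0, abs=1e-9)

    def test_narrow_gaussian_concentrates_near_birth_length(self, orchestia):
        mesh = build_mesh(orchestia, 0.1, 200)
        D = offspring_distribution(mesh, orchestia)
        assert D.sum() == pytest.approx(1.0)
        sd = math.sqrt(orchestia.offspring_variance)
        near = np.abs(mesh.midpoints - orchestia.offspring_mean) <= 3 * sd + mesh.cell_width
        assert D[near].sum() >= 0.99


class TestKernelAssembly:
    def test_nonnegative_and_starved_columns_zero(self, orchestia):
        mesh = build_mesh(orchestia, 0.1, 200)
        A = assemble_kernel(mesh, orchestia, 0.4, 0.1).matrix
        assert np.all(A >= 0)
        starved = mesh.midpoints - mesh.cell_width / 2 >= orchestia.starvation_cutoff(0.4)
        assert np.all(A[:, starved] == 0)

    def test_juvenile_columns_sum_to_survival(self, orchestia):
        mesh = build_mesh(orchestia, 0.1, 200)
        A = assemble_kernel(mesh, orchestia, 1.0, 0.1).matrix
        sd = growth_sd(orchestia, 0.1)
        means = growth_mean(mesh.midpoints, orchestia, 1.0)
        juvenile = mesh.midpoints + mesh.cell_width / 2 < orchestia.L_p
        interior = (means - 5 * sd >= mesh.lower) & (means + 5 * sd <= mesh.upper)
        cols = A[:, juvenile & interior].sum(axis=0)
        np.testing.assert_allclose(cols, math.exp(-0.27), atol=1e-3)


class TestEigenAnalysis:
    def test_matches_dense_eigendecomposition_on_small_mesh(self, orchestia):
        mesh = build_mesh(orchestia, 0.1, 10)
        A = assemble_kernel(mesh, orchestia, 1.0, 0.1).matrix
        lam, w = dominant_eigenpair(A)
        eigvals, eigvecs = np.linalg.eig(A)
        k = np.argmax(eigvals.real)
        assert lam == pytest.approx(eigvals[k].real, abs=1e-8)
        dense = np.abs(eigvecs[:, k].real)
        np.testing.assert_allclose(w, dense / dense.sum(), atol=1e-8)

    def test_eigenvalue_homogeneity(self, orchestia):
        mesh = build_mesh(orchestia, 0.1, 60)
        A = assemble_kernel(mesh, orchestia, 0.8, 0.1).matrix
        lam, _ = dominant_eigenpair(A)
        lam3, _ = dominant_eigenpair(3.0 * A)
        assert lam3 == pytest.approx(3 * lam, rel=1e-9)

    @pytest.mark.parametrize("feeding", [0.7, 1.0])
    def test_without_reproduction_growth_rate_is_survival(self, orchestia, feeding):
        """With R_m = 0 (and shrinking allowed) only mortality acts."""
        sterile = DEBParams(**{**orchestia.to_dict(), "R_m": 0.0})
        mesh = build_mesh(sterile, 0.1, 200)
        lam, _ = dominant_eigenpair(assemble_kernel(mesh, sterile, feeding, 0.1))
        assert lam == pytest.approx(math.exp(-sterile.mu), abs=1e-6)

    def test_growth_rate_nondecreasing_in_feeding_level(self, orchestia, manta):
        for params in (orchestia, manta):
            mesh = build_mesh(params, 0.1, 150)
            lams = [
                dominant_eigenpair(assemble_kernel(mesh, params, y, 0.1))[0]
                for y in np.linspace(0.4, 1.0, 13)
            ]
            assert np.all(np.diff(lams) >= -1e-9)

    def test_annihilating_kernel_raises(self, orchestia):
        mesh = build_mesh(orchestia, 0.1, 50)
        with pytest.raises(ValueError, match="annihilated"):
            dominant_eigenpair(np.zeros((50, 50)))


class TestMeanBodySize:
    def test_point_mass(self, orchestia):
        mesh = build_mesh(orchestia, 0.1, 100)
        w = np.zeros(100)
        w[7] = 1.0
        assert mean_body_size(w, mesh) == pytest.approx(mesh.midpoints[7])

    def test_two_cell_uniform(self, orchestia):
        mesh = build_mesh(orchestia, 0.1, 100)
        w = np.zeros(100)
        w[[3, 9]] = 0.5
        assert mean_body_size(w, mesh) == pytest.approx(
            (mesh.midpoints[3] + mesh.midpoints[9]) / 2
        )

    def test_stable_structure_mean_is_in_domain(self, orchestia):
        mesh = build_mesh(orchestia, 0.1, 200)
        _, w = dominant_eigenpair(assemble_kernel(mesh, orchestia, 1.0, 0.1))
        size = mean_body_size(w, mesh)
        assert orchestia.L_b < size < orchestia.L_m / orchestia.kappa

    def test_all_zero_rejected(self, orchestia):
        mesh = build_mesh(orchestia, 0.1, 100)
        with pytest.raises(ValueError):
            mean_body_size(np.zeros(100), mesh)


def test_kernel_export_round_trip(tmp_path, orchestia):
    mesh = build_mesh(orchestia, 0.1, 40)
    kern = assemble_kernel(mesh, orchestia, 0.9, 0.1)
    path = tmp_path / "kernel.tsv"
    export_kernel(kern, path)
    matrix = np.loadtxt(path, delimiter="\t")
    np.testing.assert_allclose(matrix, kern.matrix)
    assert (tmp_path / "kernel.tsv.meta.yaml").exists()
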