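import numpy as np
import pytest

from membind import fel
from membind.core import AnalysisConfig, MembindError
from membind.synthetic import (
    SyntheticSpec,
    generate_binding_ensemble,
    sample_two_state_cv,
    two_state_delta_g,
)


class TestComputeFel2d:
    def test_single_bin(self, config):
        grid = fel.compute_fel_2d([1.0] * 50, [5.0] * 50, config)
        assert grid.occupied.sum() == 1
        assert np.nanmin(grid.G) == 0.0

    def test_two_equal_bins_both_zero(self, config):
        x = [1.0] * 50 + [2.0] * 50
        y = [5.0] * 100
        grid = fel.compute_fel_2d(x, y, config)
        occupied_g = grid.G[grid.occupied]
        assert np.allclose(occupied_g, 0.0)

    def test_probability_normalised(self, config):
        rng = np.random.default_rng(0)
        grid = fel.compute_fel_2d(
            rng.normal(3, 0.3, 1000), rng.integers(0, 50, 1000), config
        )
        assert grid.P.sum() == pytest.approx(1.0)

    def test_log_ratio_closed_form(self, config):
        # counts 300 vs 100 -> dG = ln 3 exactly
        x = [1.0] * 300 + [2.0] * 100
        grid = fel.compute_fel_2d(x, [0.0] * 400, config)
        occ = np.sort(grid.G[grid.occupied])
        assert occ[0] == 0.0
        assert occ[1] == pytest.approx(np.log(3.0), abs=1e-12)

    def test_kcal_conversion(self, config):
        x = [1.0] * 300 + [2.0] * 100
        grid = fel.compute_fel_2d(x, [0.0] * 400, config)
        g_kcal = grid.free_energy("kcal/mol", config)
        occ = np.sort(g_kcal[grid.occupied])
        assert occ[1] == pytest.approx(np.log(3.0) * 0.0019872 * 343, abs=1e-9)

    def test_duplication_invariance(self, config):
        rng = np.random.default_rng(1)
        x = rng.normal(3, 0.2, 500)
        y = rng.integers(0, 30, 500).astype(float)
        g1 = fel.compute_fel_2d(x, y, config)
        g2 = fel.compute_fel_2d(np.tile(x, 2), np.tile(y, 2), config)
        assert np.allclose(g1.P, g2.P)

    def test_length_mismatch(self, config):
        with pytest.raises(MembindError):
            fel.compute_fel_2d([1.0], [1.0, 2.0], config)


class TestProject1d:
    def test_two_population_minima(self, config):
        x = sample_two_state_cv(
            (2.65, 3.45), (0.08, 0.08), (0.5, 0.5), 100_000, seed=11
        )
        prof = fel.project_fel_1d(x, config=config)
        minima = prof.minima()
        assert len(minima) >= 2
        # the two deepest minima sit within one bin of the planted means
        g_at = {m: prof.G[np.argmin(np.abs(prof.centers - m))] for m in minima}
        deepest = sorted(minima, key=lambda m: g_at[m])[:2]
        deepest.sort()
        assert abs(deepest[0] - 2.65) <= config.fel_bins_distance
        assert abs(deepest[1] - 3.45) <= config.fel_bins_distance

    def test_single_gaussian_single_minimum(self, config):
        rng = np.random.default_rng(2)
        prof = fel.project_fel_1d(rng.normal(3.0, 0.1, 50_000), config=config)
        minima = prof.minima()
        assert len(minima) == 1
        assert abs(minima[0] - 3.0) <= config.fel_bins_distance

    def test_uniform_flat(self, config):
        rng = np.random.default_rng(3)
        x = rng.uniform(2.0, 3.0, 1_000_000)
        prof = fel.project_fel_1d(x, config=config)
        interior = prof.G[2:-2]
        assert np.nanmax(interior) - np.nanmin(interior) < 0.2

    def test_marginalises_grid(self, config):
        rng = np.random.default_rng(4)
        x = rng.normal(3, 0.2, 2000)
        y = rng.integers(0, 30, 2000).astype(float)
        grid = fel.compute_fel_2d(x, y, config)
        prof = fel.project_fel_1d(grid, axis=0)
        assert prof.P.sum() == pytest.approx(1.0)


class TestFindBasins:
    def _two_gaussian_grid(self, config, weights=(0.5, 0.5), n=100_000,
                           seed=5):
        x = sample_two_state_cv(
            (2.65, 3.45), (0.08, 0.08), weights, n, seed=seed
        )
        y = np.zeros_like(x)
        return fel.compute_fel_2d(x, y, config)

    def test_two_basins_at_planted_centers(self, config):
        grid = self._two_gaussian_grid(config)
        basins = fel.find_basins(grid, config, min_depth_kT=3.0)
        assert len(basins) == 2
        centers = sorted(b.min_coords[0] for b in basins.basins)
        assert abs(centers[0] - 2.65) <= config.fel_bins_distance
        assert abs(centers[1] - 3.45) <= config.fel_bins_distance

    def test_single_gaussian_one_basin(self, config):
        rng = np.random.default_rng(6)
        grid = fel.compute_fel_2d(
            rng.normal(3.0, 0.1, 20_000), np.zeros(20_000), config
        )
        assert len(fel.find_basins(grid, config)) == 1

    def test_members_partition_frames(self, config):
        grid = self._two_gaussian_grid(config, n=5000)
        basins = fel.find_basins(grid, config, min_depth_kT=3.0)
        all_members = np.concatenate(
            [b.member_frames for b in basins.basins]
        )
        assert len(all_members) == 5000
        assert len(np.unique(all_members)) == 5000

    def test_labels_ordered_by_descending_distance(self, config):
        grid = self._two_gaussian_grid(config)
        basins = fel.find_basins(grid, config, min_depth_kT=3.0)
        coords = [b.min_coords[0] for b in basins.basins]
        assert basins.basins[0].label == "a"
        assert coords == sorted(coords, reverse=True)

    def test_coarser_bins_never_more_basins(self, config):
        x = sample_two_state_cv(
            (2.65, 3.45), (0.08, 0.08), (0.5, 0.5), 50_000, seed=7
        )
        y = np.zeros_like(x)
        counts = []
        for width in (0.05, 0.1, 0.2, 0.5, 1.0):
            grid = fel.compute_fel_2d(
                x, y, config, bin_width_x=width
            )
            counts.append(
                len(fel.find_basins(grid, config, min_depth_kT=3.0))
            )
        assert counts == sorted(counts, reverse=True)

    def test_population_ratio_matches_weights(self, config):
        w = (np.e / (1 + np.e), 1 / (1 + np.e))
        grid = self._two_gaussian_grid(config, weights=w)
        basins = fel.find_basins(grid, config, min_depth_kT=3.0)
        pops = {b.min_coords[0]: len(b.member_frames) for b in basins.basins}
        lo = pops[min(pops)]
        hi = pops[max(pops)]
        dg = -np.log(hi / lo)
        assert dg == pytest.approx(two_state_delta_g(w), abs=0.05)


class TestPerBasinFel:
    def test_two_conformer_groups(self, config):
        rng = np.random.default_rng(8)
        n = 400
        rmsd = np.concatenate(
            [rng.normal(0.2, 0.01, n // 2), rng.normal(0.6, 0.01, n // 2)]
        )
        beta = np.concatenate(
            [np.full(n // 2, 0.4) + rng.normal(0, 0.005, n // 2),
             np.abs(rng.normal(0, 0.005, n // 2))]
        )
        basin = fel.Basin(
            label="a", min_index=(0, 0), min_coords=(0.0, 0.0),
            G_min=0.0, member_frames=np.arange(n),
        )
        grid, microstates = fel.per_basin_fel(rmsd, beta, basin, config)
        assert len(microstates) == 2
        groups = sorted(ms.group for ms in microstates)
        assert groups == [1, 2]
        labels = sorted(ms.label for ms in microstates)
        assert labels == ["a1", "a2"]

    def test_homogeneous_single_microstate(self, config):
        rng = np.random.default_rng(9)
        n = 200
        rmsd = rng.normal(0.3, 0.005, n)
        beta = np.full(n, 0.35)
        basin = fel.Basin(
            label="b", min_index=(0, 0), min_coords=(0.0, 0.0),
            G_min=0.0, member_frames=np.arange(n),
        )
        _, microstates = fel.per_basin_fel(rmsd, beta, basin, config)
        assert len(microstates) == 1
        assert microstates[0].group == 1  # beta 0.35 >= 0.2 threshold

    def test_few_members_warns(self, config):
        basin = fel.Basin(
            label="c", min_index=(0, 0), min_coords=(0.0, 0.0),
            G_min=0.0, member_frames=np.arange(5),
        )
        with pytest.warns(UserWarning):
            fel.per_basin_fel(
                np.full(5, 0.2), np.full(5, 0.1), basin, config
            )


class TestPartitionBound:
    def test_rule(self):
        flags = fel.partition_bound(np.array([0, 1, 5, 0]))
        assert list(flags) == [False, True, True, False]

    def test_mixture_fraction_exact(self, config):
        spec = SyntheticSpec(
            seed=9, n_frames=40, model_template="mixture",
            mixture_weights={"model3": 0.5, "unbound": 0.5},
        )
        traj, truth = generate_binding_ensemble(spec)
        flags = fel.partition_bound(traj, config)
        assert flags.mean() == pytest.approx(0.5, abs=0)
        assert list(flags) == truth.bound


def _features(**kw):
    base = dict(
        distance=3.5,
        n_contacts=10,
        n_contact_residues=5,
        beta_fraction=0.0,
        helix_fraction_total=0.0,
        helix_fraction_by_region={"NT": 0.0, "CHC": 0.0, "CL": 0.0, "CT": 0.0},
        buried_fraction_by_region={"NT": 0.0, "CHC": 0.0, "CL": 0.0, "CT": 0.0},
        min_depth=0.5,
    )
    base.update(kw)
    return fel.FrameFeatures(**base)


class TestClassifier:
    def test_unbound(self, config):
        f = _features(n_contacts=0, distance=5.0)
        assert fel.classify_binding_model(f, config) == "unbound"

    def test_model4(self, config):
        f = _features(
            buried_fraction_by_region={"NT": 0.0, "CHC": 0.6, "CL": 0.0,
                                       "CT": 0.8},
            min_depth=-0.8,
        )
        assert fel.classify_binding_model(f, config) == "model4"

    def test_model3(self, config):
        f = _features(
            buried_fraction_by_region={"NT": 0.0, "CHC": 0.0, "CL": 0.0,
                                       "CT": 0.8},
            beta_fraction=0.2,
            min_depth=-0.8,
        )
        assert fel.classify_binding_model(f, config) == "model3"

    def test_model1(self, config):
        f = _features(
            buried_fraction_by_region={"NT": 0.0, "CHC": 0.0, "CL": 0.0,
                                       "CT": 0.3},
            beta_fraction=0.4,
            min_depth=-0.3,
        )
        assert fel.classify_binding_model(f, config) == "model1"

    def test_model2(self, config):
        f = _features(
            helix_fraction_by_region={"NT": 0.4, "CHC": 0.0, "CL": 0.0,
                                      "CT": 0.0},
            helix_fraction_total=0.15,
            min_depth=-0.05,
        )
        assert fel.classify_binding_model(f, config) == "model2"

    def test_unclassified_fallthrough(self, config):
        f = _features(beta_fraction=0.7)
        assert fel.classify_binding_model(f, config) == "unclassified"

    def test_total_and_deterministic(self, config):
        rng = np.random.default_rng(10)
        for _ in range(200):
            f = _features(
                n_contacts=int(rng.integers(0, 50)),
                n_contact_residues=int(rng.integers(0, 30)),
                beta_fraction=float(rng.uniform(0, 0.8)),
                helix_fraction_total=float(rng.uniform(0, 0.5)),
                helix_fraction_by_region={
                    k: float(rng.uniform(0, 0.6))
                    for k in ("NT", "CHC", "CL", "CT")
                },
                buried_fraction_by_region={
                    k: float(rng.uniform(0, 1))
                    for k in ("NT", "CHC", "CL", "CT")
                },
                min_depth=float(rng.uniform(-1.5, 1.0)),
            )
            first = fel.classify_binding_model(f, config)
            assert first in fel.MODEL_LABELS
            assert fel.classify_binding_model(f, config) == first


class TestBasinRelativeFreeEnergy:
    def test_equal_populations(self):
        dg = fel.basin_relative_free_energy([100, 100])
        assert np.allclose(dg, 0.0)

    def test_ratio_e_is_one_kT(self):
        dg = fel.basin_relative_free_energy([np.e * 500, 500])
        assert dg[0] == 0.0
        assert dg[1] == pytest.approx(1.0, abs=1e-12)

    def test_most_populated_always_zero(self):
        rng = np.random.default_rng(11)
        pops = rng.integers(1, 1000, size=7)
        dg = fel.basin_relative_free_energy(pops)
        assert dg[np.argmax(pops)] == 0.0
        assert np.all(dg >= 0)

    def test_zero_population_masked(self):
        dg = fel.basin_relative_free_energy([10, 0])
        assert np.isinf(dg[1])

    def test_all_zero_rejected(self):
        with pytest.raises(MembindError):
            fel.basin_relative_free_energy([0, 0])
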