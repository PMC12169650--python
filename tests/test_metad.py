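"""Hill parsing, FES reconstruction, windowed averaging, pruning, and
minimum/width diagnostics."""

import math

import numpy as np
import pytest

from dnaadapt.metad import (FESProfile, HillsRecord, default_grid,
                            fes_minimum_and_width, free_diffusion_check,
                            prune_opened, read_hills, reconstruct_fes,
                            windowed_profiles, write_hills, KT_298)
from dnaadapt.synthetic import FlatPotential, generate_hills


class TestHillsIO:
    def test_roundtrip(self, tmp_path, doublewell_hills):
        path = write_hills(doublewell_hills[:200], tmp_path / "HILLS")
        back = read_hills(path)
        assert len(back) == 200
        assert np.allclose([h.center for h in back],
                           [h.center for h in doublewell_hills[:200]])
        assert all(h.sigma == 0.04 and h.height == 0.1 for h in back)

    def test_empty_file_empty_list(self, tmp_path):
        p = tmp_path / "HILLS"
        p.write_text("")
        assert read_hills(p) == []

    def test_biasfactor_flagged_unsupported(self, tmp_path):
        p = tmp_path / "HILLS"
        p.write_text("#! FIELDS time twist sigma_twist height biasf\n"
                     "4.0 0.6 0.04 0.1 10.0\n")
        with pytest.warns(UserWarning, match="well-tempered"):
            hills = read_hills(p)
        assert len(hills) == 1

    def test_non_monotone_time_line_number(self, tmp_path):
        p = tmp_path / "HILLS"
        p.write_text("#! FIELDS time twist sigma_twist height biasf\n"
                     "4.0 0.6 0.04 0.1 1.0\n"
                     "2.0 0.5 0.04 0.1 1.0\n")
        with pytest.raises(ValueError, match="line 3"):
            read_hills(p)

    def test_missing_columns(self, tmp_path):
        p = tmp_path / "HILLS"
        p.write_text("#! FIELDS time twist sigma_twist height\n"
                     "4.0 0.6 0.04\n")
        with pytest.raises(ValueError, match="4 columns"):
            read_hills(p)


class TestReconstruction:
    def test_single_hill_preshift_depth(self):
        """One hill of height 0.1 kJ/mol gives F(s0) = -0.1 before the
        min-shift."""
        h = HillsRecord(4.0, np.radians(35.0), 0.04, 0.1)
        grid, F = reconstruct_fes([h], align=False)
        i = np.argmin(np.abs(grid - 35.0))
        assert F[i] == pytest.approx(-0.1, abs=1e-12)

    def test_two_colocated_hills(self):
        h = HillsRecord(4.0, np.radians(35.0), 0.04, 0.1)
        grid, F = reconstruct_fes([h, h], align=False)
        assert F.min() == pytest.approx(-0.2, abs=1e-12)

    def test_matches_exact_summation_oracle(self):
        """Vectorised reconstruction equals exact per-hill summation
        (math.fsum) to 1e-12 over 10^4 random hills."""
        rng = np.random.default_rng(17)
        hills = [HillsRecord(4.0 * (i + 1),
                             rng.uniform(np.radians(10), np.radians(60)),
                             rng.uniform(0.02, 0.08),
                             rng.uniform(0.05, 0.2))
                 for i in range(10_000)]
        grid, F = reconstruct_fes(hills, align=False)
        centers = np.array([h.center_deg for h in hills])
        sigmas = np.array([h.sigma_deg for h in hills])
        heights = np.array([h.height for h in hills])
        for i in range(0, len(grid), 20):
            s = grid[i]
            exact = -math.fsum(
                hk * math.exp(-0.5 * ((s - ck) / sk) ** 2)
                for hk, ck, sk in zip(heights, centers, sigmas))
            assert abs(F[i] - exact) < 1e-12

    def test_grid_outside_boundaries_rejected(self):
        with pytest.raises(ValueError, match="boundaries"):
            reconstruct_fes([], grid=np.array([5.0, 10.0]))


class TestWindowedProfiles:
    def test_single_subprofile_zero_sd(self, doublewell_hills):
        prof = windowed_profiles(doublewell_hills, every_ns=2.0,
                                 window_ns=(50.0, 50.0))
        assert prof.n_subprofiles == 1
        assert np.all(prof.F_sd == 0.0)
        assert prof.F.min() == 0.0

    def test_mean_of_identical_profiles_is_profile(self):
        """A single early hill makes every sub-profile identical."""
        hills = [HillsRecord(4.0, np.radians(30.0), 0.04, 0.1)]
        hills.append(HillsRecord(52_000.0, np.radians(30.0), 0.04, 0.0))
        prof = windowed_profiles(hills)
        single = reconstruct_fes(hills, align=True)[1]
        assert np.allclose(prof.F, single, atol=1e-12)
        assert np.all(prof.F_sd < 1e-12)

    def test_insufficient_span_rejected(self, doublewell_hills):
        with pytest.raises(ValueError, match="requires"):
            windowed_profiles(doublewell_hills[:100])

    def test_flat_potential_converges(self):
        """On a flat landscape the windowed-average profile is flat in the
        interior relative to kT (boundary zones within ~3 sigma of the
        walls carry the known edge artifact of bounded deposition)."""
        hills = generate_hills(FlatPotential(), duration_ns=52.0, seed=5)
        prof = windowed_profiles(hills)
        interior = (prof.grid >= 17.0) & (prof.grid <= 53.0)
        assert prof.F[interior].max() - prof.F[interior].min() < KT_298


class TestFreeDiffusion:
    def test_monotone_sweep_single_traversal(self):
        t = np.linspace(0, 5000.0, 200)
        cv = np.linspace(10.0, 60.0, 200)
        diag = free_diffusion_check(t, cv)
        assert diag["n_traversals"] == 1
        assert diag["passed"]

    def test_confined_series_fails(self):
        t = np.linspace(0, 5000.0, 200)
        cv = 10.0 + 25.0 * (np.arange(200) % 2)   # bounces in lower half
        diag = free_diffusion_check(t, cv)
        assert diag["coverage"] <= 0.55
        assert diag["n_traversals"] == 0
        assert not diag["passed"]

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_generator_flat_run_passes_early(self, seed):
        """The default walker reaches free diffusion well before 10 ns."""
        _, (t, cv) = generate_hills(FlatPotential(), duration_ns=12.0,
                                    seed=seed, return_trajectory=True)
        diag = free_diffusion_check(t, cv)
        assert diag["passed"]
        assert diag["first_traversal_ns"] < 10.0

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            free_diffusion_check(np.array([]), np.array([]))


class TestPruning:
    def test_all_intact_included(self):
        series = np.ones((100, 3), dtype=bool)
        assert prune_opened(series)

    def test_two_unrecovered_pairs_excluded(self):
        series = np.ones((100, 3), dtype=bool)
        series[20:, 0] = False   # opens at frame 20, never recovers
        series[40:, 2] = False   # second pair opens, never recovers
        assert not prune_opened(series)

    def test_open_then_recovered_included(self):
        series = np.ones((100, 3), dtype=bool)
        series[20:60, 0] = False   # opens then re-pairs
        series[30:, 1] = False     # one pair lost for good: still included
        assert prune_opened(series)

    def test_pure_function_of_series(self):
        rng = np.random.default_rng(3)
        series = rng.random((50, 4)) > 0.2
        assert prune_opened(series) == prune_opened(series.copy())


class TestMinimumAndWidth:
    def test_quadratic_closed_form(self):
        """F = k/2 (s - s0)^2: s_min = s0 and width = 2 sqrt(2 level / k)."""
        grid = default_grid()
        k, s0, level = 0.5, 34.0, KT_298
        prof = FESProfile(grid, 0.5 * k * (grid - s0) ** 2,
                          np.zeros_like(grid), (10.0, 50.0), 1)
        res = fes_minimum_and_width(prof, level=level)
        assert res["s_min"] == pytest.approx(s0, abs=0.25)
        assert res["width"] == pytest.approx(2.0 * np.sqrt(2.0 * level / k),
                                             abs=0.05)
        assert not res["at_boundary"]

    def test_flat_profile_full_width_flagged(self):
        grid = default_grid()
        prof = FESProfile(grid, np.zeros_like(grid), np.zeros_like(grid),
                          (10.0, 50.0), 1)
        res = fes_minimum_and_width(prof)
        assert res["width"] == pytest.approx(grid[-1] - grid[0])
        assert res["at_boundary"]

    def test_double_well_minima_recovered(self, doublewell_hills):
        """The windowed average over the production protocol locates both
        generator wells (25 and 45 deg) within 1 deg."""
        prof = windowed_profiles(doublewell_hills, every_ns=2.0,
                                 window_ns=(10.0, 50.0))
        res = fes_minimum_and_width(prof)
        assert min(abs(res["s_min"] - 25.0), abs(res["s_min"] - 45.0)) <= 1.0
        for target in (25.0, 45.0):
            zone = (prof.grid > target - 5.0) & (prof.grid < target + 5.0)
            local = prof.grid[zone][np.argmin(prof.F[zone])]
            assert abs(local - target) <= 1.0
        assert not res["at_boundary"]
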