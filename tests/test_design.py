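import numpy as np
import pytest
from scipy import stats
from scipy.spatial.distance import cdist

from tsetse_sdm import (
    SpeciesObservation,
    generate_pseudo_absences,
    remove_absences_near_presence,
    sampling_effort_kernel,
    significant_absences,
    thin_per_pixel,
)
from tsetse_sdm.design import build_design, min_significant_trap_days
from tsetse_sdm.errors import ConfigError, DataError
from tsetse_sdm.grid import GridSpec


def obs(x, y, presence=True, trap_days=10, species="sp1"):
    return SpeciesObservation(x=x, y=y, species=species, presence=presence, trap_days=trap_days)


@pytest.fixture
def grid():
    return GridSpec(x0=0.0, y0=10_000.0, cell=500.0, nrows=20, ncols=20)


class TestThinPerPixel:
    def test_longest_deployment_wins(self, grid):
        records = [obs(100, 9900, trap_days=3), obs(200, 9800, trap_days=14), obs(300, 9700, trap_days=7)]
        kept = thin_per_pixel(records, grid)
        assert len(kept) == 1
        assert kept[0].trap_days == 14

    def test_tie_keeps_first(self, grid):
        a, b = obs(100, 9900, trap_days=5), obs(200, 9800, trap_days=5)
        assert thin_per_pixel([a, b], grid) == [a]

    def test_distinct_cells_untouched(self, grid):
        records = [obs(250 + 500 * i, 9750, trap_days=i + 1) for i in range(5)]
        assert thin_per_pixel(records, grid) == records

    def test_count_equals_occupied_cells(self, grid, rng):
        records = [obs(rng.uniform(0, 9999), rng.uniform(1, 10_000), trap_days=int(d))
                   for d in rng.integers(1, 20, size=200)]
        kept = thin_per_pixel(records, grid)
        cells = {grid.cell_of(o.x, o.y) for o in records}
        assert len(kept) == len(cells)

    def test_point_outside_grid_rejected(self, grid):
        with pytest.raises(DataError):
            thin_per_pixel([obs(-5.0, 100.0)], grid)


class TestBufferRemoval:
    def test_closed_buffer_boundary(self):
        presence = obs(0, 0, presence=True)
        near = obs(1999.0, 0, presence=False)
        far = obs(2001.0, 0, presence=False)
        out = remove_absences_near_presence([presence, near, far], radius=2000.0)
        assert near not in out and far in out and presence in out

    def test_no_presences_passthrough(self):
        absences = [obs(i * 100.0, 0, presence=False) for i in range(5)]
        assert remove_absences_near_presence(absences) == absences

    def test_matches_pairwise_oracle(self, rng):
        pts = [obs(x, y, presence=bool(p), trap_days=5)
               for x, y, p in zip(rng.uniform(0, 10_000, 100), rng.uniform(0, 10_000, 100),
                                  rng.uniform(size=100) < 0.3)]
        out = remove_absences_near_presence(pts, radius=2000.0)
        pcoords = np.array([[o.x, o.y] for o in pts if o.presence])
        expected = [
            o for o in pts
            if o.presence or cdist([[o.x, o.y]], pcoords).min() > 2000.0
        ]
        assert out == expected


class TestSignificanceFilter:
    def test_closed_form_boundary(self):
        # exp(-0.1*14) ~ 0.247 > 0.05 -> removed; exp(-0.1*30) ~ 0.0498 <= 0.05 -> kept
        short = obs(0, 0, presence=False, trap_days=14)
        long = obs(100, 0, presence=False, trap_days=30)
        out = significant_absences([short, long], mu0=0.1, alpha=0.05)
        assert out == [long]

    def test_alpha_one_keeps_all(self):
        absences = [obs(i * 10.0, 0, presence=False, trap_days=1) for i in range(4)]
        assert significant_absences(absences, mu0=0.1, alpha=1.0) == absences

    def test_presences_untouched(self):
        pres = obs(0, 0, presence=True, trap_days=1)
        assert significant_absences([pres], mu0=0.1) == [pres]

    def test_threshold_formula(self):
        assert min_significant_trap_days(0.1, 0.05) == pytest.approx(-np.log(0.05) / 0.1)

    def test_invalid_parameters(self):
        with pytest.raises(ConfigError):
            significant_absences([], mu0=0.0)
        with pytest.raises(ConfigError):
            significant_absences([], mu0=0.1, alpha=1.5)


class TestEffortKernel:
    def test_single_trap_peaks_at_its_cell(self, grid):
        kernel = sampling_effort_kernel(np.array([[5250.0, 5250.0]]), grid, bandwidth=500.0)
        peak = np.unravel_index(np.argmax(kernel.density), kernel.density.shape)
        assert peak == grid.cell_of(5250.0, 5250.0)

    def test_density_normalized(self, grid, rng):
        traps = rng.uniform(500, 9500, size=(30, 2))
        kernel = sampling_effort_kernel(traps, grid, bandwidth=800.0)
        assert kernel.density.sum() == pytest.approx(1.0, abs=1e-9)

    def test_two_separated_traps_split_mass(self, grid):
        kernel = sampling_effort_kernel(
            np.array([[2000.0, 5000.0], [8000.0, 5000.0]]), grid, bandwidth=400.0
        )
        left = kernel.density[:, :10].sum()
        assert left == pytest.approx(0.5, abs=0.01)

    def test_zero_traps_rejected(self, grid):
        with pytest.raises(DataError):
            sampling_effort_kernel(np.empty((0, 2)), grid)


class TestPseudoAbsences:
    def test_uniform_kernel_exhausts_grid(self, grid):
        density = np.full(grid.shape, 1.0 / grid.n_cells)
        from tsetse_sdm.design import EffortKernel

        kernel = EffortKernel(grid=grid, density=density, bandwidth=1.0)
        pts = generate_pseudo_absences(kernel, [], n=grid.n_cells, seed=0)
        assert len(pts) == grid.n_cells
        assert len({(p.x, p.y) for p in pts}) == grid.n_cells

    def test_no_eligible_cells_errors(self):
        small = GridSpec(x0=0, y0=1000.0, cell=500.0, nrows=2, ncols=2)
        density = np.full((2, 2), 0.25)
        from tsetse_sdm.design import EffortKernel

        kernel = EffortKernel(grid=small, density=density, bandwidth=1.0)
        presence = obs(500.0, 500.0, presence=True)
        with pytest.raises(DataError):
            generate_pseudo_absences(kernel, [presence], n=1, buffer_radius=2000.0, seed=0)

    def test_sampling_frequencies_follow_kernel_mass(self, rng):
        # 3:1 mass ratio between halves -> selection frequencies follow suit
        grid = GridSpec(x0=0, y0=5000.0, cell=500.0, nrows=10, ncols=10)
        density = np.ones(grid.shape)
        density[:, :5] = 3.0
        density /= density.sum()
        from tsetse_sdm.design import EffortKernel

        kernel = EffortKernel(grid=grid, density=density, bandwidth=1.0)
        left = 0
        total = 0
        for seed in range(500):
            pts = generate_pseudo_absences(kernel, [], n=4, seed=seed)
            left += sum(p.x < 2500.0 for p in pts)
            total += len(pts)
        expected_left = 0.75 * total
        chi2 = (left - expected_left) ** 2 / expected_left + (
            (total - left) - 0.25 * total
        ) ** 2 / (0.25 * total)
        assert stats.chi2.sf(chi2, df=1) > 0.01

    def test_buffer_and_uniqueness_invariants_over_seeds(self, grid, rng):
        presences = [obs(rng.uniform(0, 9999), rng.uniform(1, 9999)) for _ in range(15)]
        traps = np.array([[o.x, o.y] for o in presences])
        kernel = sampling_effort_kernel(traps, grid, bandwidth=2000.0)
        pcoords = np.array([[o.x, o.y] for o in presences])
        for seed in range(50):
            pts = generate_pseudo_absences(kernel, presences, n=40, seed=seed)
            coords = np.array([[p.x, p.y] for p in pts])
            assert cdist(coords, pcoords).min() > 2000.0
            cells = {grid.cell_of(p.x, p.y) for p in pts}
            assert len(cells) == len(pts)


class TestFullDesign:
    def test_pipeline_idempotent(self, grid, rng):
        pts = [obs(x, y, presence=bool(p), trap_days=int(d))
               for x, y, p, d in zip(rng.uniform(0, 9999, 80), rng.uniform(1, 9999, 80),
                                     rng.uniform(size=80) < 0.5, rng.integers(1, 60, 80))]
        from tsetse_sdm.design import remove_absences_near_presence as buf
        from tsetse_sdm.design import significant_absences as sig
        from tsetse_sdm.design import thin_per_pixel as thin

        once = sig(buf(thin(pts, grid)))
        twice = sig(buf(thin(once, grid)))
        assert once == twice

    def test_training_and_validation_sets_disjoint(self, grid, rng):
        # sparse presences so the 2 km buffer leaves eligible background cells
        pts = [obs(x, y, presence=bool(p), trap_days=int(d))
               for x, y, p, d in zip(rng.uniform(0, 9999, 120), rng.uniform(1, 9999, 120),
                                     rng.uniform(size=120) < 0.08, rng.integers(1, 60, 120))]
        traps = np.array([[o.x, o.y] for o in pts])
        design = build_design(pts, grid, traps, seed=3)
        pa = {(p.x, p.y) for p in design.pseudo_absences}
        ra = {(a.x, a.y) for a in design.retained_absences}
        assert not pa & ra
        assert all(p.source == "pseudo_absence" for p in design.pseudo_absences)

    def test_design_csv(self, grid, rng, tmp_path):
        pts = [obs(x, y, presence=bool(p), trap_days=40)
               for x, y, p in zip(rng.uniform(0, 9999, 60), rng.uniform(1, 9999, 60),
                                  rng.uniform(size=60) < 0.5)]
        traps = np.array([[o.x, o.y] for o in pts])
        design = build_design(pts, grid, traps, seed=1)
        design.to_csv(tmp_path / "design.csv")
        import pandas as pd

        df = pd.read_csv(tmp_path / "design.csv")
        assert set(df["role"]) <= {"presence", "retained_absence", "pseudo_absence"}
        assert len(df[df["role"] == "presence"]) == len(design.presences)
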