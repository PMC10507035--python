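"""RSS scoring, ranking, std-matched ensemble selection, orientation scan."""

import numpy as np
import pytest

from viscaselect import (
    ExcitonParameters,
    ExperimentalDataset,
    FrequencyGrid,
    HelixSpec,
    build_ideal_helix,
    calc_frame_spectra,
    fit_scale,
    orient_structure,
    orientation_scan,
    rank_frames,
    rss_score,
    select_ensemble,
)
from viscaselect.errors import ConfigurationError, GridMismatchError
from viscaselect.frame_selection import (
    compute_library_spectra,
    experimental_std,
    pooled_std_from_dataset,
    read_experimental_table,
    write_scores_table,
)
from viscaselect.structure_io import TrajectoryEnsemble
from viscaselect.synthetic_fixtures import _build_backbone, scenario_experiment


def dataset_from(spec, scale=1.0, add=None):
    """Experimental dataset whose means are a scaled copy of a calculated
    spectrum set (plus an optional per-PC addition), stds zero."""
    means = {pc: scale * I.copy() for pc, I in spec.intensities.items()}
    if add:
        for pc, v in add.items():
            means[pc] = means[pc] + v
    stds = {pc: np.zeros_like(I) for pc, I in means.items()}
    return ExperimentalDataset(grid=spec.grid, means=means, stds=stds, n_replicates=2)


@pytest.fixture
def helix_spec(helix20, params, grid):
    return calc_frame_spectra(helix20, params, grid)


class TestFitScaleAndRss:
    def test_exact_double_recovers_scale_two_and_zero_rss(self, helix_spec):
        exp = dataset_from(helix_spec, scale=2.0)
        assert np.isclose(fit_scale(helix_spec, exp), 2.0, rtol=1e-12)
        assert rss_score(helix_spec, exp).rss < 1e-20

    def test_zero_experiment_gives_zero_scale(self, helix_spec):
        exp = dataset_from(helix_spec, scale=0.0)
        assert fit_scale(helix_spec, exp) == 0.0

    def test_scale_matches_closed_form_on_disjoint_peaks(self, grid, params):
        """Calc and exp peaking at different frequencies: s equals the
        clamped normal-equation solution computed independently."""
        a = calc_frame_spectra(build_ideal_helix(HelixSpec(6)), params, grid)
        shifted = calc_frame_spectra(
            build_ideal_helix(HelixSpec(6)), ExcitonParameters(omega0=1685.0), grid
        )
        exp = dataset_from(shifted)
        num = sum(float(exp.means[pc] @ a.intensities[pc]) for pc in exp.pcs)
        den = sum(float(a.intensities[pc] @ a.intensities[pc]) for pc in exp.pcs)
        assert np.isclose(fit_scale(a, exp), max(0.0, num / den), rtol=1e-12)
        assert fit_scale(a, exp) >= 0.0

    def test_rss_equals_orthogonal_residual_norm(self, helix_spec):
        """exp = 3*calc + r with r orthogonal to calc over the scored
        points: fitted scale is exactly 3 and RSS = |r|^2."""
        rng = np.random.default_rng(0)
        calc_flat = np.concatenate([helix_spec.intensities[pc] for pc in ("ssp", "ppp", "sps", "psp")])
        v = rng.normal(size=calc_flat.shape)
        r = v - (v @ calc_flat) / (calc_flat @ calc_flat) * calc_flat
        n = len(helix_spec.grid)
        add = {pc: r[i * n : (i + 1) * n] for i, pc in enumerate(("ssp", "ppp", "sps", "psp"))}
        exp = dataset_from(helix_spec, scale=3.0, add=add)
        score = rss_score(helix_spec, exp)
        assert np.isclose(score.scale, 3.0, rtol=1e-10)
        assert np.isclose(score.rss, float(r @ r), rtol=1e-8)

    def test_stronger_pc_dominates_sensitivity(self, helix_spec):
        """A relative perturbation of a strong PC moves the RSS more than
        the same relative perturbation of a weak PC."""
        exp = dataset_from(helix_spec)
        strong = max(exp.pcs, key=lambda pc: exp.means[pc].max())
        weak = min(exp.pcs, key=lambda pc: exp.means[pc].max())
        eps = 0.05
        rss_strong = rss_score(helix_spec, dataset_from(helix_spec, add={strong: eps * exp.means[strong]})).rss
        rss_weak = rss_score(helix_spec, dataset_from(helix_spec, add={weak: eps * exp.means[weak]})).rss
        assert rss_strong > rss_weak

    def test_empty_pc_subset_rejected(self, helix_spec):
        with pytest.raises(ConfigurationError):
            rss_score(helix_spec, dataset_from(helix_spec), pcs=[])

    def test_grid_mismatch_rejected(self, helix_spec, helix20, params):
        other = calc_frame_spectra(helix20, params, FrequencyGrid(np.arange(1610.0, 1691.0)))
        with pytest.raises(GridMismatchError):
            fit_scale(other, dataset_from(helix_spec))


class TestRanking:
    @pytest.fixture(scope="class")
    @staticmethod
    def small_library():
        frames = [
            orient_structure(build_ideal_helix(HelixSpec(10)), tilt, twist)
            for tilt in (0, 30, 60, 90)
            for twist in (0, 45, 120)
        ]
        for i, f in enumerate(frames):
            f.time_ps = 50.0 * i
            f.traj_id = "lib"
        return TrajectoryEnsemble(frames)

    def test_generating_frame_ranks_first_with_zero_rss(self, small_library, params, grid):
        spectra = compute_library_spectra(small_library, params, grid)
        exp = dataset_from(spectra[5])
        ranking = rank_frames(small_library, exp, params, grid, spectra=spectra)
        assert ranking[0].frame_index == 5
        assert ranking[0].rss < 1e-18
        assert ranking[0].rss <= ranking[1].rss

    def test_ties_broken_by_frame_index(self, small_library, params, grid):
        frames = [small_library[0], small_library[0], small_library[3]]
        lib = TrajectoryEnsemble(
            [f.__class__(**{**f.__dict__, "time_ps": 50.0 * i}) for i, f in enumerate(frames)]
        )
        spectra = compute_library_spectra(lib, params, grid)
        exp = dataset_from(spectra[0])
        ranking = rank_frames(lib, exp, params, grid, spectra=spectra)
        assert [s.frame_index for s in ranking[:2]] == [0, 1]

    def test_ranking_equals_independent_rescoring(self, small_library, params, grid):
        """Full ranking equals a brute-force per-frame recomputation of
        scale and RSS straight from the intensity arrays."""
        spectra = compute_library_spectra(small_library, params, grid)
        exp = dataset_from(spectra[7], scale=1.3)
        ranking = rank_frames(small_library, exp, params, grid, spectra=spectra)
        mask = (grid.points >= 1600) & (grid.points <= 1700)
        brute = []
        for i, spec in enumerate(spectra):
            num = den = 0.0
            for pc in exp.pcs:
                num += float(exp.means[pc][mask] @ spec.intensities[pc][mask])
                den += float(spec.intensities[pc][mask] @ spec.intensities[pc][mask])
            s = max(0.0, num / den)
            rss = sum(
                float(np.sum((exp.means[pc][mask] - s * spec.intensities[pc][mask]) ** 2))
                for pc in exp.pcs
            )
            brute.append((rss, i, s))
        brute.sort()
        assert [sc.frame_index for sc in ranking] == [i for _, i, _ in brute]
        np.testing.assert_allclose([sc.rss for sc in ranking], [r for r, _, _ in brute], rtol=1e-10)

    def test_scores_table_roundtrip(self, small_library, params, grid, tmp_path):
        import pandas as pd

        spectra = compute_library_spectra(small_library, params, grid)
        ranking = rank_frames(small_library, dataset_from(spectra[2]), params, grid, spectra=spectra)
        path = tmp_path / "scores.tsv"
        write_scores_table(ranking, path)
        df = pd.read_csv(path, sep="\t")
        assert list(df.columns) == ["frame_index", "trajectory_id", "time_ps", "scale", "rss"]
        assert len(df) == len(small_library)


class TestExperimentalStd:
    def test_identical_replicates_zero(self, grid):
        rep = {"ssp": np.ones(len(grid))}
        assert experimental_std([rep, rep, rep], grid) == 0.0

    def test_two_replicates_closed_form(self, grid):
        """Per-point sample std of two values a, b is |a-b|/sqrt(2)."""
        a = {"ssp": np.full(len(grid), 1.0)}
        b = {"ssp": np.full(len(grid), 2.0)}
        assert np.isclose(experimental_std([a, b], grid), 1.0 / np.sqrt(2.0), rtol=1e-12)

    def test_gaussian_noise_recovered(self, grid):
        rng = np.random.default_rng(123)
        sigma = 0.05
        reps = [{"ssp": rng.normal(1.0, sigma, len(grid))} for _ in range(50)]
        assert abs(experimental_std(reps, grid) - sigma) < 0.25 * sigma

    def test_single_replicate_rejected(self, grid):
        with pytest.raises(ConfigurationError):
            experimental_std([{"ssp": np.ones(len(grid))}], grid)


class TestSelectEnsemble:
    def test_zero_sigma_selects_unique_best(self, scenario, scenario_spectra, params):
        exp = scenario_experiment(scenario, "upright", params, seed=3, spectra=scenario_spectra)
        ranking = rank_frames(
            scenario.ensemble, exp.dataset, params, spectra=scenario_spectra
        )
        ens = select_ensemble(ranking, scenario_spectra, 0.0)
        assert ens.size == 1
        assert ens.threshold == ranking[0].rss
        assert ens.member_indices == [ranking[0].frame_index]

    def test_first_crossing_and_envelopes(self, scenario, scenario_spectra, params):
        from viscaselect.frame_selection import _pooled_calc_std, _window_mask

        exp = scenario_experiment(scenario, "upright", params, seed=3, spectra=scenario_spectra)
        sigma = pooled_std_from_dataset(exp.dataset)
        ranking = rank_frames(scenario.ensemble, exp.dataset, params, spectra=scenario_spectra)
        ens = select_ensemble(ranking, scenario_spectra, sigma)
        assert ens.pooled_calc_std >= sigma
        # removing the last member drops the spread below sigma (first crossing)
        mask = _window_mask(ens.grid, (1600.0, 1700.0))
        shrunk = _pooled_calc_std(
            [scenario_spectra[m.frame_index] for m in ens.member_scores[:-1]],
            [m.scale for m in ens.member_scores[:-1]],
            mask,
            list(exp.dataset.pcs),
        )
        assert shrunk < sigma
        # members are exactly the ranking head, threshold = last member RSS
        assert ens.member_indices == [sc.frame_index for sc in ranking[: ens.size]]
        assert ens.threshold == ens.member_scores[-1].rss
        for pc in exp.dataset.pcs:
            assert np.all(ens.min_spectra[pc] <= ens.mean_spectra[pc] + 1e-15)
            assert np.all(ens.mean_spectra[pc] <= ens.max_spectra[pc] + 1e-15)

    def test_ensembles_nested_in_sigma(self, scenario, scenario_spectra, params):
        exp = scenario_experiment(scenario, "flat", params, seed=5, spectra=scenario_spectra)
        sigma = pooled_std_from_dataset(exp.dataset)
        ranking = rank_frames(scenario.ensemble, exp.dataset, params, spectra=scenario_spectra)
        small = select_ensemble(ranking, scenario_spectra, sigma)
        large = select_ensemble(ranking, scenario_spectra, 2.0 * sigma)
        assert set(small.member_indices) <= set(large.member_indices)
        assert small.threshold <= large.threshold

    def test_selection_deterministic(self, scenario, scenario_spectra, params):
        exp = scenario_experiment(scenario, "upright", params, seed=3, spectra=scenario_spectra)
        sigma = pooled_std_from_dataset(exp.dataset)
        ranking = rank_frames(scenario.ensemble, exp.dataset, params, spectra=scenario_spectra)
        a = select_ensemble(ranking, scenario_spectra, sigma)
        b = select_ensemble(ranking, scenario_spectra, sigma)
        assert a.member_indices == b.member_indices and a.threshold == b.threshold


class TestExperimentalTableIO:
    def test_roundtrip(self, tmp_path, scenario, scenario_spectra, params):
        exp = scenario_experiment(scenario, "upright", params, seed=3, spectra=scenario_spectra)
        path = tmp_path / "exp.tsv"
        exp.dataset.to_table(path)
        back = read_experimental_table(path)
        assert back.n_replicates == exp.dataset.n_replicates
        for pc in exp.dataset.pcs:
            np.testing.assert_allclose(back.means[pc], exp.dataset.means[pc], rtol=1e-12)
            np.testing.assert_allclose(back.stds[pc], exp.dataset.stds[pc], rtol=1e-12)


class TestOrientationScan:
    @pytest.fixture(scope="class")
    @staticmethod
    def kinked_helix():
        """Two helical segments joined by a bend: twist is non-degenerate."""
        phi = np.full(24, -57.0)
        psi = np.full(24, -47.0)
        phi[10:13], psi[10:13] = -90.0, 60.0
        return _build_backbone(phi, psi)

    def test_recovery_of_generating_orientation(self, kinked_helix, params):
        grid = FrequencyGrid(np.arange(1620.0, 1681.0, 2.0))
        truth_tilt, truth_twist = 40.0, 80.0
        centroid = kinked_helix.xyz.mean(axis=0)
        from viscaselect.geometry import tilt_twist_matrix

        target = (
            kinked_helix.transformed(translation=-centroid)
            .transformed(rotation=tilt_twist_matrix(truth_tilt, truth_twist), translation=centroid)
        )
        exp = dataset_from(calc_frame_spectra(target, params, grid))
        res = orientation_scan(
            kinked_helix, exp, np.arange(0.0, 181.0, 20.0), np.arange(0.0, 360.0, 40.0),
            params, grid,
        )
        assert abs(res.best_tilt - truth_tilt) <= 20.0
        dpsi = min(abs(res.best_twist - truth_twist), 360.0 - abs(res.best_twist - truth_twist))
        assert dpsi <= 40.0
        assert np.isfinite(res.rss).all()

    def test_zero_tilt_row_constant_over_twist(self, helix20, params):
        grid = FrequencyGrid(np.arange(1630.0, 1671.0, 5.0))
        exp = dataset_from(calc_frame_spectra(helix20, params, grid))
        res = orientation_scan(helix20, exp, [0.0], np.arange(0.0, 360.0, 60.0), params, grid)
        row = res.rss[0]
        assert np.abs(row - row[0]).max() <= 1e-8 * max(row[0], 1.0)

    def test_twist_periodicity(self, helix20, params):
        grid = FrequencyGrid(np.arange(1640.0, 1661.0, 5.0))
        exp = dataset_from(calc_frame_spectra(orient_structure(helix20, 30.0, 0.0), params, grid))
        res = orientation_scan(helix20, exp, [30.0], [45.0, 405.0], params, grid)
        assert np.isclose(res.rss[0, 0], res.rss[0, 1], rtol=1e-10)

    def test_empty_grid_rejected(self, helix20, params):
        exp = dataset_from(calc_frame_spectra(helix20, params))
        with pytest.raises(ConfigurationError):
            orientation_scan(helix20, exp, [], [0.0], params)
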