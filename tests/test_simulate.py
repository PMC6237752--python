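"""The synthetic-microscopy generator: determinism, statistics, optics."""

import math
import warnings

import numpy as np
import pytest
from scipy.optimize import curve_fit

from halofoci import (
    FocusTruth,
    SyntheticCell,
    find_maxima,
    render_hoechst,
    render_zstack,
    sample_cell_field,
    sim_config,
    widefield_config,
)
from halofoci.config import FWHM_PER_SIGMA
from halofoci.simulate import (
    FrapSimParams,
    GeometryPriors,
    default_focus_flux,
    simulate_frap_trace,
)
from halofoci.stats import poisson_gof


def _single_focus_cell(config, diameter_nm=150.0, flux=1000.0):
    mid_z = (config.n_slices - 1) / 2.0 * config.z_step_nm
    center = (
        config.image_shape_px[0] / 2 * config.pixel_size_nm,
        config.image_shape_px[1] / 2 * config.pixel_size_nm,
    )
    cell = SyntheticCell(
        center_nm=center, semi_axes_nm=(2000.0, 1500.0), orientation_rad=0.0,
        cytoplasm_intensity=0.0, dna_total_intensity=1.0,
    )
    cell.foci.append(FocusTruth((center[0], center[1], mid_z), flux, diameter_nm))
    return cell


class TestSampleCellField:
    def test_lambda_zero_gives_no_foci(self):
        config = widefield_config(image_shape_px=(512, 512), seed=0)
        cells, truth = sample_cell_field(config, 10, 0.0, seed=0)
        assert truth.focus_counts.sum() == 0
        assert all(len(c.foci) == 0 for c in cells)

    def test_same_seed_identical_field(self):
        config = widefield_config(image_shape_px=(512, 512), seed=0)
        _, t1 = sample_cell_field(config, 12, 2.5, seed=99)
        _, t2 = sample_cell_field(config, 12, 2.5, seed=99)
        assert np.array_equal(t1.label_image, t2.label_image)
        assert np.array_equal(t1.focus_counts, t2.focus_counts)
        for c1, c2 in zip(t1.cells, t2.cells):
            assert c1.center_nm == c2.center_nm
            for f1, f2 in zip(c1.foci, c2.foci):
                assert f1 == f2

    def test_sample_mean_close_to_lambda(self):
        """CLT bound: mean of 391 Poisson(2.76) counts within 3*sqrt(2.76/391)."""
        config = widefield_config(image_shape_px=(2048, 2048), seed=0)
        misses = 0
        n_rep = 30
        for s in range(n_rep):
            _, truth = sample_cell_field(config, 391, 2.76, seed=1000 + s)
            if abs(truth.focus_counts.mean() - 2.76) > 3 * math.sqrt(2.76 / 391):
                misses += 1
        assert misses <= 1  # ~0.3% per replicate under the CLT

    def test_counts_pass_poisson_gof(self):
        config = widefield_config(image_shape_px=(4096, 4096), seed=0)
        _, truth = sample_cell_field(config, 2000, 2.0, seed=31)
        _, _, p = poisson_gof(truth.focus_counts, lambda_hat=2.0)
        assert p > 0.01

    def test_overcrowded_field_raises_with_explanation(self):
        config = widefield_config(image_shape_px=(64, 64), seed=0)
        with pytest.raises(RuntimeError, match="crowded"):
            sample_cell_field(config, 50, 1.0, seed=0, max_tries_per_cell=50)

    def test_foci_respect_minimum_separation(self):
        config = widefield_config(image_shape_px=(1024, 1024), seed=0)
        priors = GeometryPriors()
        cells, _ = sample_cell_field(config, 20, 4.0, geometry_priors=priors, seed=3)
        for cell in cells:
            pos = np.array([f.position_nm for f in cell.foci])
            for i in range(len(pos)):
                for j in range(i + 1, len(pos)):
                    assert np.linalg.norm(pos[i] - pos[j]) >= 0.5 * priors.min_focus_separation_nm

    def test_foci_inside_cell_boundary(self):
        config = sim_config(image_shape_px=(1024, 1024), seed=0)
        cells, _ = sample_cell_field(config, 10, 3.0, seed=5)
        for cell in cells:
            for f in cell.foci:
                assert cell.contains_nm(f.position_nm[0], f.position_nm[1])


class TestRenderZstack:
    @pytest.mark.parametrize("maker", [widefield_config, sim_config])
    def test_rendered_fwhm_matches_object_psf_convolution(self, maker):
        config = maker(image_shape_px=(96, 96))
        cell = _single_focus_cell(config, diameter_nm=150.0)
        stack, _ = render_zstack([cell], config, add_noise=False)
        proj = stack.max(axis=0)
        r, c = np.unravel_index(proj.argmax(), proj.shape)
        xs = np.arange(proj.shape[1], dtype=float)

        def g(x, a, mu, s):
            return a * np.exp(-0.5 * ((x - mu) / s) ** 2)

        popt, _ = curve_fit(g, xs, proj[r, :], p0=[proj[r, c], c, 2.0])
        fwhm_nm = abs(popt[2]) * FWHM_PER_SIGMA * config.pixel_size_nm
        expected = math.hypot(config.psf_fwhm_nm, 150.0)
        assert fwhm_nm == pytest.approx(expected, rel=0.05)

    def test_integrated_flux_independent_of_modality(self):
        flux = 2000.0
        totals = []
        for maker in (widefield_config, sim_config):
            config = maker(image_shape_px=(160, 160))
            cell = _single_focus_cell(config, diameter_nm=100.0, flux=flux)
            stack, _ = render_zstack([cell], config, add_noise=False)
            totals.append(stack.sum())
        assert totals[0] == pytest.approx(flux, rel=0.01)
        assert totals[1] == pytest.approx(flux, rel=0.01)

    def test_empty_cell_list_gives_pure_noise_stack(self):
        config = widefield_config(image_shape_px=(64, 64), seed=1)
        stack, _ = render_zstack([], config, add_noise=True)
        # background is zero photons: read noise only, clipped at zero
        assert stack.mean() < 3 * config.read_noise_sd
        noiseless, _ = render_zstack([], config, add_noise=False)
        assert noiseless.sum() == 0.0

    def test_noiseless_render_deterministic(self):
        config = sim_config(image_shape_px=(64, 64))
        cell = _single_focus_cell(config)
        s1, _ = render_zstack([cell], config, add_noise=False)
        s2, _ = render_zstack([cell], config, add_noise=False)
        assert np.array_equal(s1, s2)

    def test_noise_reproducible_given_rng_seed(self):
        config = sim_config(image_shape_px=(64, 64), seed=5)
        cell = _single_focus_cell(config)
        s1, _ = render_zstack([cell], config, rng=np.random.default_rng(5))
        s2, _ = render_zstack([cell], config, rng=np.random.default_rng(5))
        assert np.array_equal(s1, s2)

    def test_out_of_bounds_focus_warns(self):
        config = widefield_config(image_shape_px=(32, 32))
        cell = _single_focus_cell(config)
        cell.foci.append(FocusTruth((-5000.0, -5000.0, 0.0), 100.0, 100.0))
        with pytest.warns(UserWarning, match="clipped"):
            render_zstack([cell], config, add_noise=False)

    def test_resolvability_of_150nm_pair_by_modality(self):
        """A 150 nm pair yields one maximum in wide-field, two in SIM."""
        for maker, expected in ((widefield_config, 1), (sim_config, 2)):
            config = maker(image_shape_px=(int(6000 / maker().pixel_size_nm),) * 2)
            mid_z = (config.n_slices - 1) / 2.0 * config.z_step_nm
            flux = default_focus_flux(config) / config.photon_scale
            cell = SyntheticCell(
                center_nm=(3000.0, 3000.0), semi_axes_nm=(2000.0, 1500.0),
                orientation_rad=0.0, cytoplasm_intensity=0.0, dna_total_intensity=1.0,
            )
            cell.foci = [
                FocusTruth((3000.0, 3000.0 - 75.0, mid_z), flux, 50.0),
                FocusTruth((3000.0, 3000.0 + 75.0, mid_z), flux, 50.0),
            ]
            stack, _ = render_zstack([cell], config, add_noise=False)
            peaks = find_maxima(stack.max(axis=0), config.default_noise_tolerance)
            assert len(peaks) == expected


class TestRenderHoechst:
    def _field(self, compacted):
        config = widefield_config(image_shape_px=(512, 512), seed=2)
        cells, truth = sample_cell_field(
            config, 12, 1.0, seed=2,
            compacted_fraction_of_cells=1.0 if compacted else 0.0,
        )
        return config, cells, truth

    def test_fraction_one_identical_to_diffuse(self):
        config, cells, truth = self._field(compacted=True)
        a = render_hoechst(cells, config, compaction_fraction=1.0, add_noise=False)
        for cell in cells:
            cell.compacted_dna = False
        b = render_hoechst(cells, config, compaction_fraction=1.0, add_noise=False)
        assert np.array_equal(a, b)

    def test_integrated_intensity_conserved_and_max_raised(self):
        config, cells, truth = self._field(compacted=True)
        comp = render_hoechst(cells, config, compaction_fraction=0.2, add_noise=False)
        for cell in cells:
            cell.compacted_dna = False
        diff = render_hoechst(cells, config, compaction_fraction=0.2, add_noise=False)
        for lab in range(1, len(cells) + 1):
            m = truth.label_image == lab
            assert comp[0][m].sum() == pytest.approx(diff[0][m].sum(), rel=1e-3)
            assert comp[0][m].max() > diff[0][m].max()

    def test_zero_fraction_rejected(self):
        config, cells, _ = self._field(compacted=True)
        with pytest.raises(ValueError):
            render_hoechst(cells, config, compaction_fraction=0.0)

    def test_compaction_flags_round_trip(self):
        config = widefield_config(image_shape_px=(512, 512), seed=6)
        cells, truth = sample_cell_field(
            config, 2, 0.0, seed=6, compacted_fraction_of_cells=0.5
        )
        assert np.array_equal(
            truth.compaction_flags, [c.compacted_dna for c in cells]
        )
        payload = truth.to_json_dict()
        assert payload["compaction_flags"] == [c.compacted_dna for c in cells]


class TestFrapSimulation:
    def test_half_recovery_at_ln2_over_k(self):
        p = FrapSimParams(A=1.0, B=0.8, k=0.1, noise_sd=0.0)
        trace = simulate_frap_trace(p)
        from halofoci import normalize_trace

        norm = normalize_trace(trace)
        t_post = trace.time_s - trace.time_s[trace.bleach_index]
        target = np.log(2) / 0.1
        idx = int(np.argmin(np.abs(t_post - target)))
        expected = 1.0 - 0.8 * np.exp(-0.1 * t_post[idx])
        assert norm[idx] == pytest.approx(expected, abs=1e-9)
        assert abs(expected - 0.6) < 0.02  # half recovery ~ A - B/2

    def test_bleach_frame_drops(self):
        p = FrapSimParams(noise_sd=0.0)
        trace = simulate_frap_trace(p)
        assert trace.i_bleach[trace.bleach_index] < trace.i_bleach[trace.bleach_index - 1]

    def test_default_geometry_is_50s_101_frames(self):
        p = FrapSimParams()
        trace = simulate_frap_trace(p)
        assert trace.time_s.size == 101
        assert trace.bleach_index == 10
        assert trace.time_s[-1] == pytest.approx(50.0)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            FrapSimParams(k=-1.0)
        with pytest.raises(ValueError):
            FrapSimParams(A=0.5, B=0.8)
        with pytest.raises(ValueError):
            FrapSimParams(n_prebleach=101, n_frames=101)
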