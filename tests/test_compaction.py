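"""Focal-plane selection and DNA-compaction intensity metrics."""

import numpy as np
import pytest

from halofoci import (
    compare_compaction,
    measure_compaction,
    render_hoechst,
    sample_cell_field,
    select_focal_plane,
    widefield_config,
)
from halofoci.compaction import nearest_dna_peak_distance
from halofoci.segment import CellROI


def _square_roi(label, r0, c0, size):
    rr, cc = np.meshgrid(range(r0, r0 + size), range(c0, c0 + size), indexing="ij")
    px = np.stack([rr.ravel(), cc.ravel()], axis=1)
    return CellROI(
        label=label, pixels=px, area_px=size * size, area_um2=0.0,
        mean_intensity=0.0, min_intensity=0.0, max_intensity=0.0,
    )


def _rois_from_truth(truth):
    rois = []
    for k in range(1, len(truth.cells) + 1):
        rr, cc = np.nonzero(truth.label_image == k)
        rois.append(
            CellROI(
                label=k, pixels=np.stack([rr, cc], axis=1), area_px=rr.size,
                area_um2=0.0, mean_intensity=0.0, min_intensity=0.0,
                max_intensity=0.0,
            )
        )
    return rois


class TestSelectFocalPlane:
    def _stack_with_peak(self, n_z, z_peaks):
        stack = np.zeros((n_z, 12, 12))
        for z, n in z_peaks.items():
            for i in range(n):
                stack[z, 3 + 2 * i, 5] = 100.0
        return stack

    def test_single_slice_with_foci_selected(self):
        stack = self._stack_with_peak(30, {12: 2})
        roi = _square_roi(1, 2, 2, 8)
        assert select_focal_plane(stack, roi, 35.0) == 12

    def test_tie_broken_toward_mid_stack(self):
        stack = self._stack_with_peak(30, {10: 2, 20: 2})
        roi = _square_roi(1, 2, 2, 8)
        # mid = 14.5: slice 10 is 4.5 away, slice 20 is 5.5 away
        assert select_focal_plane(stack, roi, 35.0) == 10

    def test_no_foci_returns_mid_stack(self, caplog):
        stack = np.zeros((30, 12, 12))
        roi = _square_roi(1, 2, 2, 8)
        with caplog.at_level("WARNING", logger="halofoci.compaction"):
            plane = select_focal_plane(stack, roi, 35.0)
        assert plane == 14
        assert "mid-stack" in caplog.text

    def test_recovers_ground_truth_plane_within_one_step(self):
        from halofoci import render_zstack

        config = widefield_config(image_shape_px=(512, 512), seed=19)
        cells, truth = sample_cell_field(config, 8, 2.0, seed=19)
        stack, _ = render_zstack(cells, config, rng=np.random.default_rng(20))
        rois = _rois_from_truth(truth)
        for roi, cell in zip(rois, truth.cells):
            if not cell.foci:
                continue
            plane = select_focal_plane(stack, roi, config.default_noise_tolerance)
            z_true = np.mean([f.position_nm[2] for f in cell.foci]) / config.z_step_nm
            assert abs(plane - z_true) <= 2.0

    def test_non_stack_rejected(self):
        with pytest.raises(ValueError):
            select_focal_plane(np.zeros((5, 5)), _square_roi(1, 0, 0, 3), 35.0)


class TestMeasureCompaction:
    def test_uniform_signal_mean_equals_max(self):
        plane = np.full((20, 20), 42.0)
        rois = [_square_roi(1, 2, 2, 6)]
        res = measure_compaction(plane, rois, [2])
        row = res.per_cell.iloc[0]
        assert row.dna_mean == 42.0
        assert row.dna_max == 42.0

    def test_strata_bookkeeping(self):
        plane = np.full((20, 20), 10.0)
        rois = [_square_roi(k, 2 * k, 2, 2) for k in range(1, 8)]
        counts = [0, 1, 1, 2, 4, 5, 9]
        res = measure_compaction(plane, rois, counts)
        in_strata = res.per_cell["gfp_focus_count"].isin([1, 2, 3, 4]).sum()
        assert in_strata == 4
        assert res.group_stats["n"].sum() == 4

    def test_max_geq_mean_per_cell(self):
        rng = np.random.default_rng(23)
        plane = rng.uniform(0, 100, (30, 30))
        rois = [_square_roi(1, 5, 5, 10)]
        res = measure_compaction(plane, rois, [1])
        assert res.per_cell.dna_max.iloc[0] >= res.per_cell.dna_mean.iloc[0]


class TestCompactionComparison:
    def _arm(self, fraction, seed, n_cells=60):
        config = widefield_config(image_shape_px=(1024, 1024), seed=seed)
        cells, truth = sample_cell_field(
            config, n_cells, 2.0, seed=seed,
            compacted_fraction_of_cells=1.0 if fraction < 1.0 else 0.0,
        )
        stack = render_hoechst(
            cells, config, compaction_fraction=fraction,
            rng=np.random.default_rng(seed + 1),
        )
        counts = np.clip(truth.focus_counts, 1, 4)
        return measure_compaction(stack[0], _rois_from_truth(truth), counts)

    def test_max_differs_mean_does_not(self):
        """Conserved DNA but compacted: max intensity separates the arms,
        mean intensity does not."""
        control = self._arm(1.0, seed=301)
        treated = self._arm(0.2, seed=302)
        table = compare_compaction(control, treated)
        pooled = table[table.stratum == "pooled_1_4"].set_index("metric")
        assert pooled.loc["dna_max", "p"] < 0.01
        assert pooled.loc["dna_mean", "p"] > 0.05

    def test_effect_grows_as_fraction_shrinks(self):
        maxima = []
        for frac, seed in ((1.0, 311), (0.5, 312), (0.2, 313)):
            arm = self._arm(frac, seed=seed, n_cells=40)
            maxima.append(arm.per_cell.dna_max.mean())
        assert maxima[0] < maxima[1] < maxima[2]

    def test_small_stratum_skipped(self, caplog):
        plane = np.full((20, 20), 10.0)
        rois = [_square_roi(1, 2, 2, 4)]
        a = measure_compaction(plane, rois, [1])
        with caplog.at_level("INFO", logger="halofoci.compaction"):
            table = compare_compaction(a, a)
        assert table.empty

    def test_integrated_intensity_conserved_across_arms_noiseless(self):
        config = widefield_config(image_shape_px=(1024, 1024), seed=42)
        cells, truth = sample_cell_field(
            config, 30, 1.0, seed=42, compacted_fraction_of_cells=1.0
        )
        compacted = render_hoechst(cells, config, 0.2, add_noise=False)
        for c in cells:
            c.compacted_dna = False
        diffuse = render_hoechst(cells, config, 0.2, add_noise=False)
        rois = _rois_from_truth(truth)
        a = measure_compaction(compacted[0], rois, np.ones(30))
        b = measure_compaction(diffuse[0], rois, np.ones(30))
        ratio = a.per_cell.dna_integrated / b.per_cell.dna_integrated
        assert np.allclose(ratio, 1.0, atol=0.01)


class TestColocalizationProxy:
    def test_gfp_peaks_on_compacted_dna_are_near_dna_maxima(self):
        plane = np.zeros((30, 30))
        plane[10:14, 10:14] = 200.0  # compacted DNA blob
        roi = _square_roi(1, 2, 2, 25)
        d = nearest_dna_peak_distance([(11, 11), (20, 20)], plane, roi, 50.0, 160.0)
        assert d[0] < d[1]

    def test_no_dna_peaks_gives_nan(self):
        plane = np.zeros((10, 10))
        roi = _square_roi(1, 0, 0, 8)
        d = nearest_dna_peak_distance([(2, 2)], plane, roi, 50.0, 160.0)
        assert np.isnan(d).all()
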