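"""Canned in-silico experiments that exercise the whole pipeline.

Each function simulates a study-scale dataset with the generator's default
conditions, runs the relevant analysis stages, and returns the summary
quantities a validation run would report: count-recovery accuracy and
Poisson goodness of fit, estimator bias and coverage, two-point
resolvability by modality, FRAP rate recovery, DNA-compaction contrasts,
and Welch-test calibration.  All randomness is controlled by the ``seed``
argument.
"""

from __future__ import annotations

import math

import numpy as np

from halofoci.config import ImagingConfig, sim_config, widefield_config
from halofoci.foci import analyze_foci, find_maxima
from halofoci.frap import fit_recovery, normalize_trace
from halofoci.pipeline import stage_seed
from halofoci.segment import max_project, otsu_threshold, segment_cells
from halofoci.simulate import (
    FocusTruth,
    FrapSimParams,
    SyntheticCell,
    default_focus_flux,
    render_hoechst,
    render_zstack,
    sample_cell_field,
    simulate_frap_trace,
)
from halofoci.stats import fit_poisson, poisson_gof, welch_ttest

__all__ = [
    "count_recovery_experiment",
    "poisson_recovery_experiment",
    "pair_resolution_experiment",
    "frap_recovery_experiment",
    "compaction_experiment",
    "welch_type1_experiment",
]


def count_recovery_experiment(
    n_cells: int = 400,
    lambda_foci: float = 2.76,
    modality: str = "sim",
    n_fields: int = 4,
    field_px: int = 1700,
    seed: int = 0,
) -> dict:
    """Simulate fields, run segment -> detect, compare counts with truth.

    Returns the detected mean, the realized true mean (matched per
    segmented cell), their relative difference, and the chi-square Poisson
    goodness-of-fit p-value of the detected counts.
    """
    maker = sim_config if modality == "sim" else widefield_config
    per_field = n_cells // n_fields
    detected, true = [], []
    for f in range(n_fields):
        fseed = stage_seed(seed, f"count_field_{f}")
        config = maker(image_shape_px=(field_px, field_px), seed=fseed)
        cells, truth = sample_cell_field(config, per_field, lambda_foci, seed=fseed)
        stack, _ = render_zstack(
            cells, config, rng=np.random.default_rng(stage_seed(fseed, "render"))
        )
        proj = max_project(stack)
        rois = segment_cells(
            proj,
            otsu_threshold(proj, clip_percentile=99.0),
            pixel_size_nm=config.pixel_size_nm,
        )
        result = analyze_foci(
            proj, rois, config.default_noise_tolerance, config.pixel_size_nm
        )
        detected.append(result.counts)
        for roi in rois:
            votes = truth.label_image[roi.pixels[:, 0], roi.pixels[:, 1]]
            true.append(truth.focus_counts[np.bincount(votes).argmax() - 1])
    counts = np.concatenate(detected)
    true = np.array(true)
    _, _, gof_p = poisson_gof(counts)
    return {
        "n_cells": int(counts.size),
        "mean_detected": float(counts.mean()),
        "mean_true": float(true.mean()),
        "rel_err_vs_true": float(abs(counts.mean() - true.mean()) / true.mean()),
        "gof_p": float(gof_p),
    }


def poisson_recovery_experiment(
    lambdas: tuple[float, ...] = (1.0, 2.76, 5.0),
    n_cells: int = 391,
    n_replicates: int = 200,
    seed: int = 0,
) -> dict:
    """Sampling behaviour of the Poisson estimators at study-scale n.

    For each lambda: relative bias of the sample-mean MLE over replicates,
    coverage of the 3*sqrt(lambda/n) interval, and the relative difference
    between the zero-truncated and full MLEs (reported for lambda >= 2,
    where the truncated estimator is well conditioned).
    """
    out = {}
    for lam in lambdas:
        rng = np.random.default_rng(stage_seed(seed, f"poisson_{lam}"))
        estimates, covered, trunc_rel = [], 0, []
        bound = 3.0 * math.sqrt(lam / n_cells)
        for _ in range(n_replicates):
            counts = rng.poisson(lam, size=n_cells)
            fit = fit_poisson(counts, method="mle_full", n_bootstrap=0)
            estimates.append(fit.lambda_hat)
            covered += abs(fit.lambda_hat - lam) <= bound
            if lam >= 2.0 and (counts > 0).any():
                trunc = fit_poisson(counts, method="mle_truncated", n_bootstrap=0)
                trunc_rel.append(
                    abs(trunc.lambda_hat - fit.lambda_hat) / fit.lambda_hat
                )
        out[lam] = {
            "bias_rel": float(abs(np.mean(estimates) - lam) / lam),
            "coverage": covered / n_replicates,
            "trunc_vs_full_max_rel": float(np.max(trunc_rel)) if trunc_rel else None,
        }
    return out


def pair_resolution_experiment(
    config: ImagingConfig,
    separation_nm: float = 150.0,
    n_pairs: int = 25,
    true_diameter_nm: float = 50.0,
    seed: int = 0,
) -> float:
    """Fraction of noiseless two-focus renders counted as two maxima.

    Pairs are placed at random sub-pixel phases and orientations and
    rendered without noise; detection uses the modality's default noise
    tolerance and the generator's default focus flux.
    """
    rng = np.random.default_rng(seed)
    mid_z = (config.n_slices - 1) / 2.0 * config.z_step_nm
    flux = default_focus_flux(config) / config.photon_scale
    side_px = int(6000 / config.pixel_size_nm)
    local = type(config)(**{**config.to_dict(), "image_shape_px": (side_px, side_px)})
    counted_two = 0
    for _ in range(n_pairs):
        cx = 3000.0 + rng.uniform(0, config.pixel_size_nm)
        cy = 3000.0 + rng.uniform(0, config.pixel_size_nm)
        ang = rng.uniform(0, math.pi)
        dx = separation_nm / 2.0 * math.cos(ang)
        dy = separation_nm / 2.0 * math.sin(ang)
        cell = SyntheticCell(
            center_nm=(cx, cy), semi_axes_nm=(2500.0, 2500.0), orientation_rad=0.0,
            cytoplasm_intensity=0.0, dna_total_intensity=1.0,
        )
        cell.foci = [
            FocusTruth((cx - dx, cy - dy, mid_z), flux, true_diameter_nm),
            FocusTruth((cx + dx, cy + dy, mid_z), flux, true_diameter_nm),
        ]
        stack, _ = render_zstack([cell], local, add_noise=False)
        peaks = find_maxima(stack.max(axis=0), local.default_noise_tolerance)
        counted_two += len(peaks) == 2
    return counted_two / n_pairs


def frap_recovery_experiment(
    n_traces: int = 100,
    noise_sd: float = 0.02,
    A: float = 0.95,
    B: float = 0.75,
    tau_half_s: float = 8.4,
    seed: int = 0,
) -> dict:
    """Rate and amplitude recovery from simulated noisy FRAP traces."""
    k_true = math.log(2.0) / tau_half_s
    k_errs, b_errs, taus = [], [], []
    for i in range(n_traces):
        tseed = stage_seed(seed, f"frap_{i}")
        params = FrapSimParams(A=A, B=B, k=k_true, noise_sd=noise_sd, seed=tseed)
        trace = simulate_frap_trace(params)
        fit = fit_recovery(
            trace.time_s, normalize_trace(trace), trace.bleach_index, seed=tseed
        )
        k_errs.append(abs(fit.k - k_true) / k_true)
        b_errs.append(abs(fit.B - B))
        taus.append(fit.tau_half_s)
    return {
        "median_k_rel_err": float(np.median(k_errs)),
        "median_B_abs_err": float(np.median(b_errs)),
        "mean_tau_half_s": float(np.mean(taus)),
    }


def compaction_experiment(
    n_cells_per_arm: int = 100,
    compaction_fraction: float = 0.2,
    lambda_foci: float = 2.0,
    field_px: int = 1024,
    seed: int = 0,
) -> dict:
    """Hoechst metrics for a compacted arm vs a diffuse arm.

    Per-cell integrated DNA intensity is drawn from the same prior in both
    arms; the compacted arm concentrates it into ``compaction_fraction`` of
    the cell area.  Returns pooled Welch p-values for mean and maximum
    per-cell DNA intensity (cells with 1-4 foci).
    """
    from halofoci.compaction import compare_compaction, measure_compaction
    from halofoci.segment import CellROI

    def one_arm(fraction: float, arm_seed: int):
        config = widefield_config(
            image_shape_px=(field_px, field_px), n_slices=1, seed=arm_seed
        )
        cells, truth = sample_cell_field(
            config, n_cells_per_arm, lambda_foci, seed=arm_seed,
            compacted_fraction_of_cells=1.0 if fraction < 1.0 else 0.0,
        )
        stack = render_hoechst(
            cells, config, compaction_fraction=fraction,
            rng=np.random.default_rng(stage_seed(arm_seed, "hoechst")),
        )
        rois = []
        for k in range(1, len(cells) + 1):
            rr, cc = np.nonzero(truth.label_image == k)
            rois.append(
                CellROI(
                    label=k, pixels=np.stack([rr, cc], axis=1), area_px=rr.size,
                    area_um2=0.0, mean_intensity=0.0, min_intensity=0.0,
                    max_intensity=0.0,
                )
            )
        counts = np.clip(truth.focus_counts, 1, 4)
        return measure_compaction(stack[0], rois, counts, condition=str(fraction))

    control = one_arm(1.0, stage_seed(seed, "arm_control"))
    treated = one_arm(compaction_fraction, stage_seed(seed, "arm_treated"))
    table = compare_compaction(control, treated)
    pooled = table[table.stratum == "pooled_1_4"].set_index("metric")
    return {
        "p_mean": float(pooled.loc["dna_mean", "p"]),
        "p_max": float(pooled.loc["dna_max", "p"]),
        "max_ratio": float(
            pooled.loc["dna_max", "mean_treated"] / pooled.loc["dna_max", "mean_control"]
        ),
        "n_per_arm": int(n_cells_per_arm),
    }


def welch_type1_experiment(
    n_replicates: int = 5000,
    n_per_group: int = 30,
    sd_ratio: float = 2.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Type-I error rate of the Welch test under unequal variances."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        x = rng.normal(0.0, 1.0, n_per_group)
        y = rng.normal(0.0, sd_ratio, n_per_group)
        _, _, p = welch_ttest(x, y)
        rejections += p < alpha
    return rejections / n_replicates
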