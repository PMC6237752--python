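"""End-to-end, reproducible runs: configuration, seeding, I/O, manifest.

A run is fully described by a :class:`RunConfig`; every parameter that
affects results is serialized verbatim into the output directory together
with a config hash, the seed, and package versions, so a rerun from the
manifest is bit-identical.  Per-stage randomness (e.g. the bootstrap) is
derived from the single global seed with a stable per-stage hash so stages
can be rerun independently yet reproducibly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from halofoci._version import __version__ as _pkg_version
from halofoci.config import DEFAULT_NOISE_TOLERANCE, ImagingConfig, sim_config, widefield_config
from halofoci.foci import analyze_foci, count_foci
from halofoci.segment import max_project, otsu_threshold, segment_cells
from halofoci.stats import fit_poisson, summarize_diameters, zero_class_deficit

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]


def stage_seed(base_seed: int, stage: str) -> int:
    """Stable per-stage seed (< 2**31) derived from the global seed."""
    digest = hashlib.sha256(f"{base_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Everything needed to reproduce one analysis run."""

    gfp_path: str
    output_dir: str
    modality: str = "widefield"
    hoechst_path: str | None = None
    frap_paths: list[str] = field(default_factory=list)
    adjust_factor: float = 1.0
    threshold_clip_percentile: float | None = 99.0
    min_area_px: int = 40
    exclude_border: bool = True
    noise_tolerance: float | None = None  # None -> modality default (35 / 400)
    pixel_size_nm: float | None = None  # None -> modality default (160 / 80)
    poisson_support: tuple[int, int] = (1, 9)
    measure_areas: bool | None = None  # None -> True for sim only
    frap_subtract_background_from_reference: bool = True
    seed: int = 0

    def resolved(self) -> "RunConfig":
        cfg = RunConfig(**{**asdict(self)})
        base = sim_config() if self.modality == "sim" else widefield_config()
        if cfg.noise_tolerance is None:
            cfg.noise_tolerance = DEFAULT_NOISE_TOLERANCE[self.modality]
        if cfg.pixel_size_nm is None:
            cfg.pixel_size_nm = base.pixel_size_nm
        if cfg.measure_areas is None:
            cfg.measure_areas = self.modality == "sim"
        cfg.poisson_support = tuple(cfg.poisson_support)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text())
        if "poisson_support" in data:
            data["poisson_support"] = tuple(data["poisson_support"])
        return cls(**data)

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_stack(path: str | Path) -> np.ndarray:
    import tifffile

    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    return arr


def run_pipeline(config: RunConfig) -> dict:
    """Run project -> segment -> detect -> fit on one field (plus options).

    Writes per-cell and per-focus CSVs, fit JSONs, and a run manifest into
    ``config.output_dir``, and returns the in-memory results.  Fails before
    any computation if a requested stage lacks its input channel.
    """
    cfg = config.resolved()
    if cfg.hoechst_path is not None and not Path(cfg.hoechst_path).exists():
        raise FileNotFoundError(f"hoechst channel not found: {cfg.hoechst_path}")
    for p in cfg.frap_paths:
        if not Path(p).exists():
            raise FileNotFoundError(f"FRAP trace not found: {p}")
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    stack = _load_stack(cfg.gfp_path)
    projection = max_project(stack)
    threshold = otsu_threshold(
        projection,
        adjust_factor=cfg.adjust_factor,
        clip_percentile=cfg.threshold_clip_percentile,
    )
    rois = segment_cells(
        projection,
        threshold,
        min_area_px=cfg.min_area_px,
        exclude_border=cfg.exclude_border,
        pixel_size_nm=cfg.pixel_size_nm,
    )
    result = analyze_foci(
        projection,
        rois,
        noise_tolerance=cfg.noise_tolerance,
        pixel_size_nm=cfg.pixel_size_nm,
        measure_areas=bool(cfg.measure_areas),
        modality=cfg.modality,
    )

    import pandas as pd

    cells_df = pd.DataFrame(
        [
            dict(
                label=r.label, area_px=r.area_px, area_um2=r.area_um2,
                mean=r.mean_intensity, min=r.min_intensity, max=r.max_intensity,
                focus_count=int(n),
            )
            for r, n in zip(rois, result.counts)
        ]
    )
    cells_df.to_csv(outdir / "cells.csv", index=False)
    result.to_frame().to_csv(outdir / "foci.csv", index=False)

    bundle: dict = {
        "threshold": threshold,
        "rois": rois,
        "foci": result,
        "counts": result.counts,
    }

    if len(result.counts) > 0:
        boot_seed = stage_seed(cfg.seed, "poisson_bootstrap")
        fit_full = fit_poisson(result.counts, method="mle_full", seed=boot_seed)
        fit_report: dict = {"mle_full": _fit_to_dict(fit_full)}
        if (result.counts > 0).any():
            fit_trunc = fit_poisson(
                result.counts, support=cfg.poisson_support,
                method="mle_truncated", seed=boot_seed,
            )
            obs0, exp0, p0 = zero_class_deficit(result.counts, fit_trunc)
            fit_report["mle_truncated"] = _fit_to_dict(fit_trunc)
            fit_report["zero_class_deficit"] = {
                "observed_zero_fraction": obs0,
                "expected_zero_fraction": exp0,
                "one_sided_p": p0,
            }
            bundle["poisson_fit"] = fit_trunc
        bundle.setdefault("poisson_fit", fit_full)
        bundle["poisson_report"] = fit_report
        (outdir / "poisson_fit.json").write_text(json.dumps(fit_report, indent=2))
        _write_histogram(outdir / "count_histogram.csv", result.counts, bundle["poisson_fit"])

    diameters = result.all_diameters_nm()
    if diameters.size:
        summary = summarize_diameters(diameters)
        morpho = {
            "n_foci": summary.n,
            "mean_diameter_nm": summary.mean,
            "sd_diameter_nm": summary.sd,
            "ci95_nm": list(summary.ci95),
            "mean_area_um2": float(np.mean([
                f.area_um2 for recs in result.foci for f in recs if f.area_um2 is not None
            ])),
            "diameter_of_mean_area_nm": None,
        }
        from halofoci.foci import focus_diameter

        morpho["diameter_of_mean_area_nm"] = focus_diameter(morpho["mean_area_um2"])
        (outdir / "morphometry.json").write_text(json.dumps(morpho, indent=2))
        bundle["morphometry"] = morpho

    if cfg.hoechst_path is not None:
        from halofoci.compaction import measure_compaction, select_focal_plane

        hoechst = _load_stack(cfg.hoechst_path)
        planes = [
            select_focal_plane(stack, roi, cfg.noise_tolerance) for roi in rois
        ]
        comp = measure_compaction(
            hoechst, rois, result.counts, plane_indices=planes, condition="run"
        )
        comp.per_cell.to_csv(outdir / "compaction_cells.csv", index=False)
        comp.group_stats.to_csv(outdir / "compaction_groups.csv", index=False)
        bundle["compaction"] = comp

    if cfg.frap_paths:
        from halofoci.frap import fit_recovery, normalize_trace, read_frap_csv

        frap_fits = []
        for p in cfg.frap_paths:
            trace = read_frap_csv(p)
            norm = normalize_trace(
                trace,
                subtract_background_from_reference=cfg.frap_subtract_background_from_reference,
            )
            fit = fit_recovery(
                trace.time_s, norm, trace.bleach_index,
                seed=stage_seed(cfg.seed, f"frap:{Path(p).name}"),
            )
            frap_fits.append({"path": str(p), **_frap_fit_to_dict(fit)})
        (outdir / "frap_fits.json").write_text(json.dumps(frap_fits, indent=2))
        bundle["frap_fits"] = frap_fits

    manifest = {
        "config": asdict(cfg),
        "config_hash": cfg.content_hash(),
        "seed": cfg.seed,
        "versions": _versions(),
        "n_cells": len(rois),
        "threshold": threshold,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    bundle["manifest"] = manifest
    return bundle


def _fit_to_dict(fit) -> dict:
    return {
        "lambda_hat": fit.lambda_hat,
        "stderr": fit.stderr,
        "method": fit.method,
        "support": list(fit.support),
        "n_cells": fit.n_cells,
        "observed_zero_fraction": fit.observed_zero_fraction,
        "expected_zero_fraction": fit.expected_zero_fraction,
    }


def _frap_fit_to_dict(fit) -> dict:
    return {
        "A": fit.A, "B": fit.B, "k": fit.k,
        "tau_half_s": fit.tau_half_s,
        "mobile_fraction": fit.mobile_fraction,
        "immobile_fraction": fit.immobile_fraction,
        "mobile_fraction_normalized": fit.mobile_fraction_normalized,
        "rss": fit.rss, "converged": fit.converged,
        "n_postbleach": fit.n_postbleach,
    }


def _write_histogram(path: Path, counts: np.ndarray, fit) -> None:
    import pandas as pd
    from scipy import stats as sps

    ks = np.arange(0, counts.max() + 1)
    obs = np.array([(counts == k).mean() for k in ks])
    expected = sps.poisson.pmf(ks, fit.lambda_hat)
    pd.DataFrame(
        {"count": ks, "observed_frequency": obs, "fitted_poisson_frequency": expected}
    ).to_csv(path, index=False)


def _versions() -> dict:
    import scipy
    import skimage

    return {
        "halofoci": _pkg_version,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "scikit-image": skimage.__version__,
    }
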