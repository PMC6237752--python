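"""DNA-compaction metrics from a Hoechst channel.

DNA-damaging treatments can leave the per-cell DNA *amount* unchanged while
condensing the nucleoid: the per-cell mean Hoechst intensity stays similar
across conditions but the maximum localized intensity rises sharply.  This
module extracts those two per-cell statistics on the optical plane that
carries the most GFP foci for each cell, stratifies cells by their GFP
focus count (1-4), and compares conditions with Welch t-tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from halofoci.foci import find_maxima
from halofoci.segment import CellROI
from halofoci.stats import p_to_stars, welch_ttest

logger = logging.getLogger(__name__)

__all__ = [
    "CompactionResult",
    "select_focal_plane",
    "measure_compaction",
    "compare_compaction",
    "nearest_dna_peak_distance",
]

STRATA = (1, 2, 3, 4)


def select_focal_plane(
    gfp_stack: np.ndarray, roi: CellROI, noise_tolerance: float
) -> int:
    """The z index whose slice has the most GFP foci within the ROI.

    Ties are broken by proximity to the stack center, then by the lower
    index.  If no slice has any focus the mid-stack slice is returned and a
    warning logged.
    """
    gfp_stack = np.asarray(gfp_stack)
    if gfp_stack.ndim != 3:
        raise ValueError("gfp_stack must be (z, rows, cols)")
    n_z = gfp_stack.shape[0]
    mid = (n_z - 1) / 2.0
    r0 = int(roi.pixels[:, 0].min())
    r1 = int(roi.pixels[:, 0].max()) + 1
    c0 = int(roi.pixels[:, 1].min())
    c1 = int(roi.pixels[:, 1].max()) + 1
    submask = np.zeros((r1 - r0, c1 - c0), dtype=bool)
    submask[roi.pixels[:, 0] - r0, roi.pixels[:, 1] - c0] = True
    counts = [
        len(find_maxima(gfp_stack[z, r0:r1, c0:c1], noise_tolerance, mask=submask))
        for z in range(n_z)
    ]
    best = max(counts)
    if best == 0:
        logger.warning(
            "select_focal_plane: no foci in any slice for ROI %d; "
            "returning mid-stack", roi.label,
        )
        return int(mid)
    candidates = [z for z, c in enumerate(counts) if c == best]
    candidates.sort(key=lambda z: (abs(z - mid), z))
    return candidates[0]


@dataclass
class CompactionResult:
    """Per-cell DNA intensity metrics for one condition."""

    condition: str
    per_cell: pd.DataFrame  # label, gfp_focus_count, dna_mean, dna_max, plane_index
    group_stats: pd.DataFrame  # per focus-count stratum: n, mean/sd of each metric

    def metric_values(self, metric: str, stratum: int | None = None) -> np.ndarray:
        df = self.per_cell
        if stratum is not None:
            df = df[df["gfp_focus_count"] == stratum]
        else:
            df = df[df["gfp_focus_count"].isin(STRATA)]
        return df[metric].to_numpy()


def measure_compaction(
    hoechst_plane: np.ndarray,
    rois: list[CellROI],
    gfp_counts,
    plane_indices=None,
    condition: str = "",
) -> CompactionResult:
    """Per-cell mean and maximum DNA intensity over the GFP-derived masks.

    ``hoechst_plane`` may be a single 2D plane used for every cell, or a
    z-stack combined with ``plane_indices`` (per-cell output of
    :func:`select_focal_plane`).  Group summaries are restricted to cells
    with 1-4 GFP foci.
    """
    hoechst_plane = np.asarray(hoechst_plane, dtype=float)
    gfp_counts = np.asarray(gfp_counts, dtype=int)
    if len(rois) != gfp_counts.size:
        raise ValueError("rois and gfp_counts must align")
    rows = []
    for idx, roi in enumerate(rois):
        if hoechst_plane.ndim == 3:
            z = int(plane_indices[idx]) if plane_indices is not None else hoechst_plane.shape[0] // 2
            plane = hoechst_plane[z]
        else:
            z = -1
            plane = hoechst_plane
        vals = plane[roi.pixels[:, 0], roi.pixels[:, 1]]
        rows.append(
            dict(
                label=roi.label,
                gfp_focus_count=int(gfp_counts[idx]),
                dna_mean=float(vals.mean()),
                dna_max=float(vals.max()),
                dna_integrated=float(vals.sum()),
                plane_index=z,
            )
        )
    per_cell = pd.DataFrame(rows)
    groups = []
    for stratum in STRATA:
        sel = per_cell[per_cell["gfp_focus_count"] == stratum]
        groups.append(
            dict(
                gfp_focus_count=stratum,
                n=len(sel),
                dna_mean_mean=float(sel["dna_mean"].mean()) if len(sel) else float("nan"),
                dna_mean_sd=float(sel["dna_mean"].std(ddof=1)) if len(sel) > 1 else float("nan"),
                dna_max_mean=float(sel["dna_max"].mean()) if len(sel) else float("nan"),
                dna_max_sd=float(sel["dna_max"].std(ddof=1)) if len(sel) > 1 else float("nan"),
            )
        )
    return CompactionResult(
        condition=condition, per_cell=per_cell, group_stats=pd.DataFrame(groups)
    )


def compare_compaction(
    control: CompactionResult,
    treated: CompactionResult,
    metrics: tuple[str, ...] = ("dna_mean", "dna_max"),
) -> pd.DataFrame:
    """Welch t-tests of treated vs control, pooled over strata 1-4 and per
    stratum.  Strata with fewer than 2 cells in either arm are skipped and
    logged."""
    rows = []
    for metric in metrics:
        for stratum in (None, *STRATA):
            x = control.metric_values(metric, stratum)
            y = treated.metric_values(metric, stratum)
            name = "pooled_1_4" if stratum is None else str(stratum)
            if x.size < 2 or y.size < 2:
                logger.info(
                    "compare_compaction: stratum %s of %s skipped "
                    "(n_control=%d, n_treated=%d)", name, metric, x.size, y.size,
                )
                continue
            t, df, p = welch_ttest(x, y)
            rows.append(
                dict(
                    metric=metric, stratum=name,
                    n_control=x.size, n_treated=y.size,
                    mean_control=float(x.mean()), mean_treated=float(y.mean()),
                    t=t, df=df, p=p, stars=p_to_stars(p),
                )
            )
    return pd.DataFrame(rows)


def nearest_dna_peak_distance(
    gfp_peaks: list[tuple[int, int]],
    hoechst_plane: np.ndarray,
    roi: CellROI,
    noise_tolerance: float,
    pixel_size_nm: float,
) -> np.ndarray:
    """Distance (nm) from each GFP peak to the nearest Hoechst local maximum.

    A defined, testable proxy for visual co-localization of foci with
    compacted DNA: compacted nucleoids concentrate the DNA maxima, pulling
    these distances down for foci that sit on them.
    """
    dna_peaks = find_maxima(
        np.asarray(hoechst_plane, dtype=float), noise_tolerance,
        mask=roi.mask(np.asarray(hoechst_plane).shape),
    )
    if not dna_peaks or not gfp_peaks:
        return np.full(len(gfp_peaks), np.nan)
    dna = np.asarray(dna_peaks, dtype=float)
    gfp = np.asarray(gfp_peaks, dtype=float)
    d2 = ((gfp[:, None, :] - dna[None, :, :]) ** 2).sum(axis=2)
    return np.sqrt(d2.min(axis=1)) * pixel_size_nm
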