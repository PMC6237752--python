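"""Ground-truthed synthetic microscopy of focus-bearing archaeal cells.

The generator emulates the statistical structure of live-cell data from a
pleomorphic haloarchaeon imaged in wide-field or 3D-SIM mode:

* ellipse-shaped cells a few micrometres across, placed without overlap;
* per-cell focus counts drawn i.i.d. from a Poisson distribution;
* sub-diffraction foci (true diameters 50-300 nm) rendered through a
  Gaussian PSF, so the rendered lateral FWHM is
  ``sqrt(psf_fwhm**2 + true_diameter**2)`` (object-PSF convolution in the
  Gaussian approximation);
* z-stacks with the acquisition geometry of each modality;
* Poisson shot noise plus Gaussian read noise;
* a "compacted DNA" Hoechst mode that concentrates each cell's total DNA
  signal into a smaller area while conserving the integrated intensity;
* three-ROI FRAP time series following a mono-exponential recovery.

Every draw is recorded in a :class:`GroundTruth` object so that detection,
counting, morphometry and fitting can be verified against the truth.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from halofoci.config import FWHM_PER_SIGMA, ImagingConfig

logger = logging.getLogger(__name__)

__all__ = [
    "FocusTruth",
    "SyntheticCell",
    "GroundTruth",
    "GeometryPriors",
    "FrapSimParams",
    "sample_cell_field",
    "render_zstack",
    "render_hoechst",
    "apply_camera_noise",
    "simulate_frap_trace",
    "write_field",
    "label_image_from_cells",
]


@dataclass(frozen=True)
class FocusTruth:
    """A single true focus: 3D position (nm), total flux and physical size."""

    position_nm: tuple[float, float, float]  # (row, col, z), nm
    amplitude: float  # total integrated flux, intensity units
    true_diameter_nm: float


@dataclass
class SyntheticCell:
    """Ground-truth geometry and contents of one cell.

    The cell body is an ellipse with half-axes ``semi_axes_nm = (a, b)``
    rotated by ``orientation_rad`` about ``center_nm`` (row, col in nm).
    """

    center_nm: tuple[float, float]
    semi_axes_nm: tuple[float, float]
    orientation_rad: float
    cytoplasm_intensity: float
    foci: list[FocusTruth] = field(default_factory=list)
    compacted_dna: bool = False
    dna_total_intensity: float = 0.0

    @property
    def area_nm2(self) -> float:
        return math.pi * self.semi_axes_nm[0] * self.semi_axes_nm[1]

    def contains_nm(self, row_nm: float, col_nm: float, inset: float = 1.0) -> bool:
        """True if (row, col) in nm lies inside the (inset-scaled) ellipse."""
        dr = row_nm - self.center_nm[0]
        dc = col_nm - self.center_nm[1]
        ct, st = math.cos(self.orientation_rad), math.sin(self.orientation_rad)
        u = ct * dr + st * dc
        v = -st * dr + ct * dc
        a, b = self.semi_axes_nm
        return (u / (inset * a)) ** 2 + (v / (inset * b)) ** 2 <= 1.0


@dataclass
class GroundTruth:
    """Everything the generator drew, for recovery tests.

    ``label_image`` assigns pixels to cells (0 = background) with labels
    1..n_cells matching the order of ``cells``.
    """

    label_image: np.ndarray
    focus_counts: np.ndarray  # per-cell true focus count
    lambda_foci: float
    compaction_flags: np.ndarray
    seed: int
    cells: list[SyntheticCell] = field(default_factory=list)

    def __post_init__(self) -> None:
        for k, cell in enumerate(self.cells):
            if len(cell.foci) != int(self.focus_counts[k]):
                raise ValueError("focus_counts inconsistent with cells[].foci")

    def to_json_dict(self) -> dict:
        return {
            "lambda_foci": self.lambda_foci,
            "seed": self.seed,
            "focus_counts": [int(c) for c in self.focus_counts],
            "compaction_flags": [bool(f) for f in self.compaction_flags],
            "cells": [
                {
                    "center_nm": list(c.center_nm),
                    "semi_axes_nm": list(c.semi_axes_nm),
                    "orientation_rad": c.orientation_rad,
                    "cytoplasm_intensity": c.cytoplasm_intensity,
                    "compacted_dna": c.compacted_dna,
                    "dna_total_intensity": c.dna_total_intensity,
                    "foci": [
                        {
                            "position_nm": list(f.position_nm),
                            "amplitude": f.amplitude,
                            "true_diameter_nm": f.true_diameter_nm,
                        }
                        for f in c.foci
                    ],
                }
                for c in self.cells
            ],
        }


@dataclass(frozen=True)
class GeometryPriors:
    """Priors for cell geometry and intensity statistics.

    The source study states no cell dimensions or intensity statistics, so
    these are explicit, configurable modelling choices.  Photon-count
    parameters are converted to camera units through
    ``ImagingConfig.photon_scale`` so that the noise-tolerance operating
    point tracks the camera gain of each modality.
    """

    semi_major_nm: tuple[float, float] = (1250.0, 2250.0)
    aspect_ratio: tuple[float, float] = (1.2, 2.5)
    cytoplasm_photons: float = 60.0
    cytoplasm_cv: float = 0.1  # cell-to-cell coefficient of variation
    focus_flux_photons: float | None = None  # None -> default_focus_flux rule
    focus_flux_cv: float = 0.2
    focus_diameter_nm: tuple[float, float] = (50.0, 300.0)
    dna_photons_per_cell: float = 4.0e4
    dna_cv: float = 0.1
    placement_margin_nm: float = 500.0
    focus_inset: float = 0.8  # foci placed within this fraction of the ellipse
    focus_z_span_steps: float = 1.0  # foci within +- this many z-steps of mid-stack
    min_focus_separation_nm: float = 500.0  # hard-core distance between foci


def peak_intensity_factor(config: ImagingConfig, true_diameter_nm: float) -> float:
    """Peak pixel intensity per unit of integrated flux for a centred focus.

    The rendered spot is a Gaussian with lateral sigma
    ``hypot(psf_sigma, object_sigma)``; the best slice carries an axial
    weight ``z_step / (sigma_z * sqrt(2*pi))``, and the in-plane peak is
    that weight over ``2*pi*sigma_px**2``.
    """
    sigma_obj = true_diameter_nm / FWHM_PER_SIGMA
    sigma_xy_px = math.hypot(config.psf_sigma_nm, sigma_obj) / config.pixel_size_nm
    sigma_z = math.hypot(config.psf_sigma_z_nm, sigma_obj)
    w0 = config.z_step_nm / (sigma_z * math.sqrt(2.0 * math.pi))
    return w0 / (2.0 * math.pi * sigma_xy_px**2)


def flux_for_peak_snr(
    config: ImagingConfig,
    peak_snr: float = 10.0,
    true_diameter_nm: float = 300.0,
    background_photons: float = 60.0,
) -> float:
    """Focus flux (photons) giving the requested peak SNR over background.

    The default sizing rule for simulated fields: the *largest* (hence
    dimmest, most spread-out) foci of the prior — 300 nm — are placed at
    peak SNR ~ 10 over the cytoplasmic background, so every focus in the
    50-300 nm range is comfortably detectable at the modality's default
    noise tolerance, with the same safety margin in both modalities.  Noise
    at the peak combines shot noise on background plus signal with read
    noise: ``sigma^2 = (bg + P)/photon_scale + read_noise_sd^2`` (A.U.).
    """
    ps = config.photon_scale
    bg = background_photons / ps
    a = peak_snr**2 / ps
    b = peak_snr**2 * (bg / ps + config.read_noise_sd**2)
    peak = (a + math.sqrt(a * a + 4.0 * b)) / 2.0
    flux_au = peak / peak_intensity_factor(config, true_diameter_nm)
    return flux_au * ps


def default_focus_flux(config: ImagingConfig, tolerance_multiple: float = 2.5) -> float:
    """Default focus flux (photons): dimmest foci stand clear of the tolerance.

    Sized so a 300 nm focus (the largest, hence dimmest-peaked, of the
    default prior) peaks at ``tolerance_multiple`` times the modality's
    default noise tolerance above the cytoplasm — about peak SNR 10 in both
    modalities, and small enough that the diffuse cytoplasm, not the foci,
    dominates the image histogram (as in real data, where Otsu's threshold
    separates cells from background rather than foci from cells).
    """
    from halofoci.config import DEFAULT_NOISE_TOLERANCE

    peak = tolerance_multiple * DEFAULT_NOISE_TOLERANCE[config.modality]
    flux_au = peak / peak_intensity_factor(config, true_diameter_nm=300.0)
    return flux_au * config.photon_scale


def _px_center_to_nm(idx: float, pixel_size_nm: float) -> float:
    return (idx + 0.5) * pixel_size_nm


def _nm_to_px(x_nm: float, pixel_size_nm: float) -> float:
    return x_nm / pixel_size_nm - 0.5


def _ellipse_pixel_mask(
    cell: SyntheticCell, shape: tuple[int, int], pixel_size_nm: float, inset: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """(rows, cols) of pixels whose centers lie inside the (inset) ellipse."""
    a, b = cell.semi_axes_nm
    r_c = _nm_to_px(cell.center_nm[0], pixel_size_nm)
    c_c = _nm_to_px(cell.center_nm[1], pixel_size_nm)
    rad_px = inset * max(a, b) / pixel_size_nm + 1.0
    r0 = max(0, int(math.floor(r_c - rad_px)))
    r1 = min(shape[0] - 1, int(math.ceil(r_c + rad_px)))
    c0 = max(0, int(math.floor(c_c - rad_px)))
    c1 = min(shape[1] - 1, int(math.ceil(c_c + rad_px)))
    if r1 < r0 or c1 < c0:
        return np.empty(0, int), np.empty(0, int)
    rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij")
    dr = _px_center_to_nm(rr.astype(float), pixel_size_nm) - cell.center_nm[0]
    dc = _px_center_to_nm(cc.astype(float), pixel_size_nm) - cell.center_nm[1]
    ct, st = math.cos(cell.orientation_rad), math.sin(cell.orientation_rad)
    u = ct * dr + st * dc
    v = -st * dr + ct * dc
    inside = (u / (inset * a)) ** 2 + (v / (inset * b)) ** 2 <= 1.0
    return rr[inside], cc[inside]


def label_image_from_cells(
    cells: list[SyntheticCell], config: ImagingConfig
) -> np.ndarray:
    """Rasterize cells into an integer label image (1-based, 0 = background)."""
    lab = np.zeros(config.image_shape_px, dtype=np.int32)
    for k, cell in enumerate(cells, start=1):
        rr, cc = _ellipse_pixel_mask(cell, config.image_shape_px, config.pixel_size_nm)
        lab[rr, cc] = k
    return lab


def sample_cell_field(
    config: ImagingConfig,
    n_cells: int,
    lambda_foci: float,
    geometry_priors: GeometryPriors | None = None,
    seed: int | None = None,
    compacted_fraction_of_cells: float = 0.0,
    max_tries_per_cell: int = 2000,
) -> tuple[list[SyntheticCell], GroundTruth]:
    """Place non-overlapping cells and draw per-cell Poisson focus counts.

    Cells are placed by rejection sampling: a candidate is rejected when its
    bounding circle (semi-major axis plus ``placement_margin_nm``) intersects
    an already-placed cell's, or falls outside the field.  Per-cell focus
    counts are i.i.d. Poisson(``lambda_foci``); focus positions are uniform
    in the inset ellipse with z within ``focus_z_span_steps`` z-steps of the
    stack center.  Identical seeds give identical fields.

    Raises
    ------
    RuntimeError
        If ``n_cells`` cannot be placed — the message names the limiting
        parameters (field size, cell size, margin).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if lambda_foci < 0:
        raise ValueError("lambda_foci must be >= 0")
    priors = geometry_priors or GeometryPriors()
    flux_photons = priors.focus_flux_photons
    if flux_photons is None:
        flux_photons = default_focus_flux(config)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    px = config.pixel_size_nm
    field_rows_nm = config.image_shape_px[0] * px
    field_cols_nm = config.image_shape_px[1] * px
    mid_z_nm = (config.n_slices - 1) / 2.0 * config.z_step_nm

    cells: list[SyntheticCell] = []
    placed: list[tuple[float, float, float]] = []  # (row, col, bounding radius)
    for _ in range(n_cells):
        for attempt in range(max_tries_per_cell):
            a = rng.uniform(*priors.semi_major_nm)
            aspect = rng.uniform(*priors.aspect_ratio)
            b = a / aspect
            radius = a + priors.placement_margin_nm
            r = rng.uniform(radius, field_rows_nm - radius)
            c = rng.uniform(radius, field_cols_nm - radius)
            if all(
                (r - r0) ** 2 + (c - c0) ** 2 >= (radius + rad0) ** 2
                for r0, c0, rad0 in placed
            ):
                break
        else:
            raise RuntimeError(
                f"could not place {n_cells} cells in a "
                f"{config.image_shape_px} px field at pixel size {px} nm "
                f"(semi-major {priors.semi_major_nm} nm, margin "
                f"{priors.placement_margin_nm} nm): field too crowded"
            )
        theta = rng.uniform(0.0, math.pi)
        cyto = priors.cytoplasm_photons * (
            1.0 + priors.cytoplasm_cv * rng.standard_normal()
        )
        cyto = max(cyto, 0.1 * priors.cytoplasm_photons) / config.photon_scale
        dna = priors.dna_photons_per_cell * (1.0 + priors.dna_cv * rng.standard_normal())
        dna = max(dna, 0.1 * priors.dna_photons_per_cell) / config.photon_scale
        cell = SyntheticCell(
            center_nm=(r, c),
            semi_axes_nm=(a, b),
            orientation_rad=theta,
            cytoplasm_intensity=cyto,
            compacted_dna=bool(rng.random() < compacted_fraction_of_cells),
            dna_total_intensity=dna,
        )
        # Counts are drawn first and never altered by placement: foci model
        # distinct replication factories with a hard-core minimum separation
        # (individually resolvable structures, as the counting analysis
        # assumes); if a crowded cell cannot host them the separation is
        # relaxed for that cell rather than dropping a focus.
        n_foci = int(rng.poisson(lambda_foci))
        min_sep = priors.min_focus_separation_nm
        positions: list[tuple[float, float, float]] = []
        ct, st = math.cos(theta), math.sin(theta)
        while len(positions) < n_foci:
            for _ in range(200):
                while True:
                    u, v = rng.uniform(-1.0, 1.0, size=2)
                    if u * u + v * v <= 1.0:
                        break
                du = u * priors.focus_inset * a
                dv = v * priors.focus_inset * b
                fr = r + ct * du - st * dv
                fc = c + st * du + ct * dv
                fz = mid_z_nm + rng.uniform(-1.0, 1.0) * priors.focus_z_span_steps * config.z_step_nm
                if all(
                    (fr - p[0]) ** 2 + (fc - p[1]) ** 2 + (fz - p[2]) ** 2
                    >= min_sep**2
                    for p in positions
                ):
                    positions.append((fr, fc, fz))
                    break
            else:
                min_sep *= 0.8
                logger.info(
                    "sample_cell_field: relaxing focus separation to %.0f nm "
                    "for a crowded cell (%d foci)", min_sep, n_foci,
                )
        for pos in positions:
            flux = flux_photons * (1.0 + priors.focus_flux_cv * rng.standard_normal())
            flux = max(flux, 0.2 * flux_photons) / config.photon_scale
            diam = rng.uniform(*priors.focus_diameter_nm)
            cell.foci.append(
                FocusTruth(position_nm=pos, amplitude=flux, true_diameter_nm=diam)
            )
        cells.append(cell)
        placed.append((r, c, radius))

    truth = GroundTruth(
        label_image=label_image_from_cells(cells, config),
        focus_counts=np.array([len(c.foci) for c in cells], dtype=int),
        lambda_foci=float(lambda_foci),
        compaction_flags=np.array([c.compacted_dna for c in cells], dtype=bool),
        seed=int(config.seed if seed is None else seed),
        cells=cells,
    )
    return cells, truth


def _add_gaussian_spot(
    stack: np.ndarray, focus: FocusTruth, config: ImagingConfig
) -> None:
    """Add one PSF-broadened focus to the stack (local-window evaluation).

    The object is approximated as a Gaussian of FWHM equal to its true
    diameter; convolution with the Gaussian PSF adds widths in quadrature.
    Peak amplitude is normalized so the flux integrated over the whole stack
    equals ``focus.amplitude`` regardless of modality.
    """
    px = config.pixel_size_nm
    sigma_obj = focus.true_diameter_nm / FWHM_PER_SIGMA
    sigma_xy = math.hypot(config.psf_sigma_nm, sigma_obj)
    sigma_z = math.hypot(config.psf_sigma_z_nm, sigma_obj)
    r_nm, c_nm, z_nm = focus.position_nm
    r_px = _nm_to_px(r_nm, px)
    c_px = _nm_to_px(c_nm, px)
    sig_px = sigma_xy / px
    half = max(2, int(math.ceil(4.0 * sig_px)))
    n_z, n_r, n_c = stack.shape
    if not (0 <= r_px < n_r and 0 <= c_px < n_c):
        warnings.warn("focus outside image bounds; contribution clipped", stacklevel=2)
    r0 = max(0, int(math.floor(r_px)) - half)
    r1 = min(n_r - 1, int(math.ceil(r_px)) + half)
    c0 = max(0, int(math.floor(c_px)) - half)
    c1 = min(n_c - 1, int(math.ceil(c_px)) + half)
    if r1 < r0 or c1 < c0:
        return
    rr = np.arange(r0, r1 + 1, dtype=float)
    cc = np.arange(c0, c1 + 1, dtype=float)
    g_r = np.exp(-0.5 * ((rr - r_px) / sig_px) ** 2)
    g_c = np.exp(-0.5 * ((cc - c_px) / sig_px) ** 2)
    plane = np.outer(g_r, g_c) / (2.0 * math.pi * sig_px**2)
    z_nm_axis = np.arange(n_z, dtype=float) * config.z_step_nm
    w_z = (
        config.z_step_nm
        / (sigma_z * math.sqrt(2.0 * math.pi))
        * np.exp(-0.5 * ((z_nm_axis - z_nm) / sigma_z) ** 2)
    )
    stack[:, r0 : r1 + 1, c0 : c1 + 1] += (
        focus.amplitude * w_z[:, None, None] * plane[None, :, :]
    )


def _cytoplasm_plane(cells: list[SyntheticCell], config: ImagingConfig) -> np.ndarray:
    from scipy.ndimage import gaussian_filter

    plane = np.zeros(config.image_shape_px, dtype=float)
    for cell in cells:
        rr, cc = _ellipse_pixel_mask(cell, config.image_shape_px, config.pixel_size_nm)
        plane[rr, cc] += cell.cytoplasm_intensity
    # smooth the cell edge at the PSF scale: in-cell background is smooth
    sig_px = config.psf_sigma_nm / config.pixel_size_nm
    return gaussian_filter(plane, sigma=sig_px, mode="constant")


def apply_camera_noise(
    stack: np.ndarray, config: ImagingConfig, rng: np.random.Generator
) -> np.ndarray:
    """Poisson shot noise on the photon-scaled signal plus Gaussian read noise.

    Output is quantized to integer camera units and clipped to the camera
    range ``[0, 2**bit_depth - 1]``.
    """
    photons = rng.poisson(np.clip(stack, 0.0, None) * config.photon_scale)
    noisy = photons / config.photon_scale + rng.normal(
        0.0, config.read_noise_sd, size=stack.shape
    )
    return np.clip(np.rint(noisy), 0.0, config.max_intensity)


def render_zstack(
    cells: list[SyntheticCell],
    config: ImagingConfig,
    channel: str = "gfp",
    add_noise: bool = True,
    rng: np.random.Generator | None = None,
    compaction_fraction: float = 0.2,
) -> tuple[np.ndarray, GroundTruth]:
    """Render a z-stack for one channel and return it with its ground truth.

    For the GFP channel every focus contributes a PSF-broadened Gaussian
    spot on top of a smooth cytoplasmic background; the Hoechst channel is
    delegated to :func:`render_hoechst` (compacted cells use
    ``compaction_fraction``).  Noise follows :func:`apply_camera_noise` and
    is reproducible through ``rng`` (defaults to ``config.seed``).
    """
    if channel not in ("gfp", "hoechst"):
        raise ValueError(f"unknown channel {channel!r}")
    truth = GroundTruth(
        label_image=label_image_from_cells(cells, config),
        focus_counts=np.array([len(c.foci) for c in cells], dtype=int),
        lambda_foci=float("nan"),
        compaction_flags=np.array([c.compacted_dna for c in cells], dtype=bool),
        seed=config.seed,
        cells=cells,
    )
    if channel == "hoechst":
        stack = render_hoechst(
            cells, config, compaction_fraction=compaction_fraction,
            add_noise=add_noise, rng=rng,
        )
        return stack, truth
    shape = (config.n_slices, *config.image_shape_px)
    stack = np.zeros(shape, dtype=float)
    stack += _cytoplasm_plane(cells, config)[None, :, :]
    for cell in cells:
        for focus in cell.foci:
            _add_gaussian_spot(stack, focus, config)
    if add_noise:
        rng = rng if rng is not None else np.random.default_rng(config.seed)
        stack = apply_camera_noise(stack, config, rng)
    return stack, truth


def render_hoechst(
    cells: list[SyntheticCell],
    config: ImagingConfig,
    compaction_fraction: float = 0.2,
    add_noise: bool = True,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render the DNA (Hoechst) channel.

    Non-compacted cells spread ``dna_total_intensity`` uniformly over the
    cell; compacted cells concentrate the *same* total intensity into a
    concentric co-oriented ellipse of area ``compaction_fraction`` times the
    cell area (axes scaled by sqrt of the fraction).  Per-cell integrated
    intensity per plane is therefore conserved exactly on noiseless renders;
    ``compaction_fraction = 1`` reproduces the diffuse render identically.
    """
    if not 0.0 < compaction_fraction <= 1.0:
        raise ValueError("compaction_fraction must be in (0, 1]")
    shape = (config.n_slices, *config.image_shape_px)
    plane = np.zeros(config.image_shape_px, dtype=float)
    for cell in cells:
        if cell.dna_total_intensity <= 0:
            raise ValueError("cell.dna_total_intensity must be set (> 0)")
        inset = math.sqrt(compaction_fraction) if cell.compacted_dna else 1.0
        rr, cc = _ellipse_pixel_mask(
            cell, config.image_shape_px, config.pixel_size_nm, inset=inset
        )
        if rr.size == 0:
            warnings.warn("cell outside image bounds; skipped", stacklevel=2)
            continue
        plane[rr, cc] += cell.dna_total_intensity / rr.size
    stack = np.broadcast_to(plane, shape).copy()
    if add_noise:
        rng = rng if rng is not None else np.random.default_rng(config.seed)
        stack = apply_camera_noise(stack, config, rng)
    return stack


# ---------------------------------------------------------------------------
# FRAP trace simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FrapSimParams:
    """Parameters of a simulated FRAP experiment.

    ``A`` is the normalized recovery plateau, ``B`` the recovery amplitude
    and ``k`` the recovery rate (1/s) of the target curve
    ``A - B*exp(-k*t)`` with t = 0 at the first post-bleach frame.  Defaults
    follow the acquisition geometry of the modelled experiments: 101 frames
    at 500 ms including 10 pre-bleach frames (50 s total), a plateau around
    0.95 with ~80% recovery and a half-time near 8.4 s.  The bleach itself
    is an instantaneous drop; no reaction-diffusion physics is modelled —
    the trace exists to exercise the fitting procedure.
    """

    A: float = 0.95
    B: float = 0.75
    k: float = 0.0825
    n_prebleach: int = 10
    n_frames: int = 101
    frame_interval_s: float = 0.5
    noise_sd: float = 0.02
    background_level: float = 50.0
    cell_intensity: float = 1000.0
    sample_bleach_rate: float = 0.002  # 1/s, acquisition photobleaching of I_sb
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be > 0")
        if not 0.0 <= self.B <= self.A:
            raise ValueError("need 0 <= B <= A")
        if not 0 < self.n_prebleach < self.n_frames:
            raise ValueError("need 0 < n_prebleach < n_frames")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")


def simulate_frap_trace(params: FrapSimParams) -> "FrapTrace":
    """Simulate a three-ROI FRAP trace (bleached spot, background, whole cell).

    The whole-cell reference decays as ``exp(-sample_bleach_rate * t)``
    (acquisition photobleaching) on top of a constant camera background; the
    bleached-ROI trace follows the target normalized curve scaled back to
    raw units, so that three-ROI normalization recovers the target exactly
    in the noiseless case.
    """
    from halofoci.frap import FrapTrace

    p = params
    rng = np.random.default_rng(p.seed)
    t = np.arange(p.n_frames) * p.frame_interval_s
    bleach_index = p.n_prebleach
    t_post = t - t[bleach_index]
    target = np.where(
        np.arange(p.n_frames) < bleach_index,
        1.0,
        p.A - p.B * np.exp(-p.k * np.clip(t_post, 0.0, None)),
    )
    sb_signal = p.cell_intensity * np.exp(-p.sample_bleach_rate * t)

    def _noise(scale: float) -> np.ndarray:
        if p.noise_sd > 0:
            return rng.normal(0.0, scale, size=p.n_frames)
        return np.zeros(p.n_frames)

    i_cell = sb_signal * (1.0 + _noise(p.noise_sd)) + p.background_level
    # background ROI fluctuates at a fraction of the in-cell noise scale
    i_background = p.background_level + p.cell_intensity * _noise(0.2 * p.noise_sd)
    i_bleach = (target + _noise(p.noise_sd)) * sb_signal + p.background_level
    return FrapTrace(
        time_s=t,
        i_bleach=i_bleach,
        i_background=i_background,
        i_cell=i_cell,
        bleach_index=bleach_index,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_field(
    outdir: str | Path,
    gfp_stack: np.ndarray,
    truth: GroundTruth,
    config: ImagingConfig,
    hoechst_stack: np.ndarray | None = None,
) -> dict[str, Path]:
    """Write 16-bit TIFF stacks plus a JSON ground-truth sidecar."""
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    gfp_path = outdir / "gfp.tif"
    tifffile.imwrite(gfp_path, np.clip(gfp_stack, 0, 65535).astype(np.uint16))
    paths["gfp"] = gfp_path
    if hoechst_stack is not None:
        hoechst_path = outdir / "hoechst.tif"
        tifffile.imwrite(hoechst_path, np.clip(hoechst_stack, 0, 65535).astype(np.uint16))
        paths["hoechst"] = hoechst_path
    sidecar = outdir / "ground_truth.json"
    payload = truth.to_json_dict()
    payload["config"] = config.to_dict()
    sidecar.write_text(json.dumps(payload, indent=2))
    paths["ground_truth"] = sidecar
    return paths


def write_frap_csv(path: str | Path, trace: "FrapTrace") -> Path:
    """Write a FRAP trace as CSV (time_s, I_bleach, I_background, I_cell)."""
    path = Path(path)
    pd.DataFrame(
        {
            "time_s": trace.time_s,
            "I_bleach": trace.i_bleach,
            "I_background": trace.i_background,
            "I_cell": trace.i_cell,
        }
    ).to_csv(path, index=False)
    return path
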