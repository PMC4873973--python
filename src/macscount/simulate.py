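"""Synthetic EMCCD microscopy of virtual cells.

Two channels are rendered: a *spot* channel in which each immobilized
molecule appears as a diffraction-limited Gaussian spot on top of a
height-scaled cellular autofluorescence background, and a *segmentation*
channel in which a cytoplasmic marker fills each cell uniformly.

The camera model is the standard EMCCD chain: Poisson photoelectrons,
stochastic electron multiplication approximated by a Gamma distribution
(shape = photoelectron count, scale = EM gain) which reproduces the
excess-noise factor of 2, Gaussian read noise, and quantization to ADU
with an offset and bit-depth clamp.

Flattening a cell halves its height, so the per-pixel autofluorescence
drops by the height factor while the footprint grows - exactly the
signal-to-background gain that makes single molecules countable in
pressed cells.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import special

from .geometry import CellGeometry, MoleculeSet, PopulationSpec, sample_population

__all__ = [
    "OpticsModel",
    "CameraModel",
    "ImageFrame",
    "render_expected_photons",
    "apply_camera",
    "render_segmentation_channel",
    "generate_dataset",
]

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...


@dataclass(frozen=True)
class OpticsModel:
    """Microscope point-spread function and photon budget.

    psf_fwhm : nm
        Full width at half maximum of the (Gaussian) PSF; ~250 nm for a
        high-NA objective at green wavelengths.
    photons_per_molecule : expected photons per molecule per exposure.
    autofluorescence_density : photons per um^2 per unit height factor,
        added inside each cell footprint.
    extracellular_background : photons per pixel, everywhere.
    segmentation_density : photons per um^2 per unit height factor for the
        cytoplasmic segmentation marker channel.
    exposure_ms : metadata only (the photon numbers are per exposure).
    """

    psf_fwhm: float = 250.0
    photons_per_molecule: float = 250.0
    autofluorescence_density: float = 400.0
    extracellular_background: float = 1.0
    segmentation_density: float = 4000.0
    exposure_ms: float = 30.0

    def __post_init__(self) -> None:
        if self.psf_fwhm <= 0:
            raise ValueError("psf_fwhm must be > 0")
        for name in (
            "photons_per_molecule",
            "autofluorescence_density",
            "extracellular_background",
            "segmentation_density",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def psf_sigma_um(self) -> float:
        return self.psf_fwhm / FWHM_TO_SIGMA / 1000.0


@dataclass(frozen=True)
class CameraModel:
    """EMCCD readout chain parameters."""

    pixel_size: float = 64.0  # nm
    em_gain: float = 300.0
    read_noise: float = 50.0  # electrons rms at the output register
    offset: float = 100.0  # ADU
    adu_per_electron: float = 0.02
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.em_gain < 1:
            raise ValueError("em_gain must be >= 1")

    @property
    def pixel_size_um(self) -> float:
        return self.pixel_size / 1000.0

    @property
    def max_adu(self) -> int:
        return 2**self.bit_depth - 1


@dataclass
class ImageFrame:
    """A single camera frame in ADU with pixel-size metadata."""

    pixels: np.ndarray
    pixel_size: float  # nm
    channel: str = "spot"
    frame_id: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


def _gaussian_pixel_profile(coord: float, sigma: float, n: int, window: int) -> tuple[int, np.ndarray]:
    """Integral of a 1-D Gaussian centred at ``coord`` over each pixel.

    Pixel i spans [i - 0.5, i + 0.5) in pixel units ((0,0) is the centre
    of the first pixel).  Returns the starting index and the per-pixel
    integrals over a +/- window around the centre.
    """
    c = int(np.round(coord))
    lo = max(c - window, 0)
    hi = min(c + window, n - 1)
    edges = np.arange(lo, hi + 2) - 0.5
    cdf = 0.5 * (1.0 + special.erf((edges - coord) / (np.sqrt(2.0) * sigma)))
    return lo, np.diff(cdf)


def _footprint_pixel_mask(cell: CellGeometry, shape: tuple[int, int], px_um: float) -> np.ndarray:
    """Boolean in-footprint mask evaluated at pixel centres."""
    h, w = shape
    half_reach = cell.length / 2.0 + cell.width * cell.lateral_scale  # generous
    cx, cy = cell.center
    x0 = max(int((cx - half_reach) / px_um) - 1, 0)
    x1 = min(int((cx + half_reach) / px_um) + 2, w)
    y0 = max(int((cy - half_reach) / px_um) - 1, 0)
    y1 = min(int((cy + half_reach) / px_um) + 2, h)
    mask = np.zeros(shape, dtype=bool)
    if x0 >= x1 or y0 >= y1:
        return mask
    yy, xx = np.mgrid[y0:y1, x0:x1]
    pts = np.column_stack([(xx.ravel() + 0.5) * px_um, (yy.ravel() + 0.5) * px_um])
    mask[y0:y1, x0:x1] = cell.contains(pts).reshape(yy.shape)
    return mask


def render_expected_photons(
    cells: list[CellGeometry],
    molecules: list[MoleculeSet],
    optics: OpticsModel,
    grid_shape: tuple[int, int],
    pixel_size_um: float,
) -> np.ndarray:
    """Noise-free expected-photon image (float, photons per pixel).

    Each molecule contributes an integrated 2-D Gaussian of total
    ``photons_per_molecule`` (error-function differences per pixel, exact
    at any pixel size).  Cell autofluorescence adds
    ``density * pixel_area * height_factor`` inside each footprint;
    ``extracellular_background`` photons are added to every pixel.
    """
    h, w = grid_shape
    img = np.full(grid_shape, float(optics.extracellular_background))
    sigma_px = optics.psf_sigma_um / pixel_size_um
    window = max(int(np.ceil(6.0 * sigma_px)), 3)
    px_area = pixel_size_um**2
    for cell in cells:
        if optics.autofluorescence_density > 0:
            mask = _footprint_pixel_mask(cell, grid_shape, pixel_size_um)
            img[mask] += optics.autofluorescence_density * px_area * cell.height_factor
    for mset in molecules:
        for x_um, y_um in mset.positions:
            xc = x_um / pixel_size_um - 0.5
            yc = y_um / pixel_size_um - 0.5
            if not (-0.5 <= xc <= w - 0.5 and -0.5 <= yc <= h - 0.5):
                raise ValueError(f"molecule at ({x_um:.3f}, {y_um:.3f}) um is outside the grid")
            x0, px = _gaussian_pixel_profile(xc, sigma_px, w, window)
            y0, py = _gaussian_pixel_profile(yc, sigma_px, h, window)
            img[y0 : y0 + len(py), x0 : x0 + len(px)] += (
                optics.photons_per_molecule * np.outer(py, px)
            )
    return img


def apply_camera(
    photon_image: np.ndarray,
    camera: CameraModel,
    rng: np.random.Generator,
    channel: str = "spot",
    frame_id: int = 0,
) -> ImageFrame:
    """Push an expected-photon image through the EMCCD noise chain."""
    mean = np.asarray(photon_image, dtype=float)
    if np.any(mean < 0):
        raise ValueError("photon image must be non-negative")
    n_pe = rng.poisson(mean)
    electrons = np.zeros_like(mean)
    if camera.em_gain == 1.0:
        electrons = n_pe.astype(float)
    else:
        nz = n_pe > 0
        electrons[nz] = rng.gamma(shape=n_pe[nz], scale=camera.em_gain)
    if camera.read_noise > 0:
        electrons = electrons + rng.normal(0.0, camera.read_noise, size=mean.shape)
    adu = np.rint(electrons * camera.adu_per_electron + camera.offset)
    adu = np.clip(adu, 0, camera.max_adu)
    return ImageFrame(adu.astype(np.uint16), camera.pixel_size, channel=channel, frame_id=frame_id)


def render_segmentation_channel(
    cells: list[CellGeometry],
    optics: OpticsModel,
    camera: CameraModel,
    rng: np.random.Generator,
    grid_shape: tuple[int, int],
    frame_id: int = 0,
) -> ImageFrame:
    """Cytoplasmic-marker frame: uniform height-scaled signal per cell, no spots."""
    px_um = camera.pixel_size_um
    img = np.full(grid_shape, float(optics.extracellular_background))
    px_area = px_um**2
    for cell in cells:
        mask = _footprint_pixel_mask(cell, grid_shape, px_um)
        img[mask] += optics.segmentation_density * px_area * cell.height_factor
    return apply_camera(img, camera, rng, channel="segmentation", frame_id=frame_id)


def grid_shape_for(spec: PopulationSpec, pixel_size_um: float) -> tuple[int, int]:
    """Smallest square pixel grid that holds the population layout."""
    side = int(np.ceil(np.sqrt(spec.n_cells)))
    pitch = spec.length_max + 2.0
    npx = int(np.ceil(side * pitch / pixel_size_um)) + 4
    return npx, npx


def generate_dataset(
    spec: PopulationSpec,
    optics: OpticsModel,
    camera: CameraModel,
    out_dir: str | Path,
    n_frames: int = 1,
    seed: int | None = None,
) -> pd.DataFrame:
    """Write paired spot/segmentation TIFF frames plus ground-truth CSVs.

    Each frame holds an independently drawn population.  Files written per
    frame ``k``: ``frame_<k>_spot.tif`` and ``frame_<k>_seg.tif`` (16-bit
    grayscale), plus ``truth.csv`` (per-cell) and ``molecules.csv``
    (per-molecule) spanning all frames, and ``meta.json`` with the pixel
    size.  Fully reproducible from the seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    truth_parts: list[pd.DataFrame] = []
    mol_rows: list[dict] = []
    px_um = camera.pixel_size_um
    for k in range(n_frames):
        cells, molecules, truth = sample_population(spec, rng)
        shape = grid_shape_for(spec, px_um)
        photons = render_expected_photons(cells, molecules, optics, shape, px_um)
        spot = apply_camera(photons, camera, rng, channel="spot", frame_id=k)
        seg = render_segmentation_channel(cells, optics, camera, rng, shape, frame_id=k)
        tifffile.imwrite(out / f"frame_{k}_spot.tif", spot.pixels)
        tifffile.imwrite(out / f"frame_{k}_seg.tif", seg.pixels)
        truth.insert(0, "frame_id", k)
        truth_parts.append(truth)
        for mset in molecules:
            for x, y in mset.positions:
                mol_rows.append({"frame_id": k, "cell_id": mset.cell_id, "x_um": x, "y_um": y})
    columns = ["frame_id", "cell_id", "length_um", "width_um", "area_um2", "pressed", "true_count"]
    truth_all = (
        pd.concat(truth_parts, ignore_index=True) if truth_parts else pd.DataFrame(columns=columns)
    )
    truth_all.to_csv(out / "truth.csv", index=False)
    pd.DataFrame(mol_rows, columns=["frame_id", "cell_id", "x_um", "y_um"]).to_csv(
        out / "molecules.csv", index=False
    )
    meta = {"pixel_size_nm": camera.pixel_size, "n_frames": n_frames, "seed": seed,
            "optics": asdict(optics), "camera": asdict(camera)}
    (out / "meta.json").write_text(json.dumps(meta, indent=2))
    return truth_all
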