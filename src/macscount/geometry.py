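"""Virtual cell geometries and molecule placement.

The footprint of a rod-shaped bacterium lying flat is modelled as a 2-D
spherocylinder: a ``(length - width) x width`` rectangle capped by two
half-discs of diameter ``width``.  Mechanically pressing a cell between a
coverslip and an elastomer membrane flattens it: the footprint grows (by a
factor ``area_factor``, ~1.72 at typical valve pressures) while the cell
height drops (``height_factor``, ~0.5).  The pressed footprint is the
unpressed spherocylinder stretched laterally (across the short axis) by
``area_factor``, which multiplies the area exactly while keeping the
pole-to-pole length fixed.

Molecules are treated as points placed uniformly over the 2-D footprint:
pressed cells are thinner than the depth of focus, so the axial dimension
carries no information and the projected position is what the camera sees.

Coordinates are physical micrometres with the origin at the image corner,
x to the right and y down.  Conversion to pixels happens in the imaging
module only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CellGeometry",
    "MoleculeSet",
    "PopulationSpec",
    "footprint_area",
    "sample_positions",
    "sample_population",
]


@dataclass(frozen=True)
class CellGeometry:
    """A single virtual cell footprint.

    Parameters
    ----------
    length, width:
        Pole-to-pole length and short-axis width of the *unpressed*
        spherocylinder, in micrometres.  ``length >= width > 0``.
    center:
        Footprint centre in lab coordinates (um).
    orientation:
        Rotation of the long axis, radians, counter-clockwise from +x.
    pressed:
        Whether the cell is mechanically flattened.
    height_factor:
        Cell height relative to the unpressed cell; in (0, 1], must be 1
        for unpressed cells.  Scales the in-cell autofluorescence density.
    area_factor:
        Footprint area multiplier applied when pressed (lateral stretch).
    """

    length: float
    width: float
    center: tuple[float, float] = (0.0, 0.0)
    orientation: float = 0.0
    pressed: bool = False
    height_factor: float = 1.0
    area_factor: float = 1.0
    cell_id: int = 0

    def __post_init__(self) -> None:
        if not (self.length >= self.width > 0):
            raise ValueError(
                f"need length >= width > 0, got length={self.length}, width={self.width}"
            )
        if not (0 < self.height_factor <= 1):
            raise ValueError(f"height_factor must be in (0, 1], got {self.height_factor}")
        if not self.pressed and self.height_factor != 1.0:
            raise ValueError("unpressed cells must have height_factor == 1")
        if self.area_factor < 1.0:
            raise ValueError(f"area_factor must be >= 1, got {self.area_factor}")

    @property
    def lateral_scale(self) -> float:
        """Lateral stretch applied to the footprint (1 when unpressed)."""
        return self.area_factor if self.pressed else 1.0

    def pressed_twin(self, area_factor: float = 1.72, height_factor: float = 0.5) -> "CellGeometry":
        """The same cell flattened with the given press parameters."""
        return replace(
            self,
            pressed=True,
            area_factor=area_factor,
            height_factor=height_factor,
        )

    def to_local(self, points: np.ndarray) -> np.ndarray:
        """Map lab-frame (N, 2) points into the unpressed cell frame."""
        pts = np.asarray(points, dtype=float).reshape(-1, 2) - np.asarray(self.center)
        c, s = np.cos(-self.orientation), np.sin(-self.orientation)
        rot = pts @ np.array([[c, -s], [s, c]]).T
        rot[:, 1] /= self.lateral_scale
        return rot

    def to_lab(self, local: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`to_local`."""
        pts = np.asarray(local, dtype=float).reshape(-1, 2).copy()
        pts[:, 1] *= self.lateral_scale
        c, s = np.cos(self.orientation), np.sin(self.orientation)
        return pts @ np.array([[c, -s], [s, c]]).T + np.asarray(self.center)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean inside-footprint predicate for lab-frame (N, 2) points."""
        local = self.to_local(points)
        half_body = max(self.length - self.width, 0.0) / 2.0
        # distance to the central segment of the spherocylinder axis
        dx = np.maximum(np.abs(local[:, 0]) - half_body, 0.0)
        return dx**2 + local[:, 1] ** 2 <= (self.width / 2.0) ** 2 + 1e-15

    @property
    def area(self) -> float:
        return footprint_area(self)


def footprint_area(geometry: CellGeometry) -> float:
    """Analytic footprint area in um^2.

    Spherocylinder area ``W*(L - W) + pi*(W/2)^2`` times the pressed area
    multiplier.  The lateral-stretch pressing model multiplies area exactly.
    """
    L, W = geometry.length, geometry.width
    base = W * (L - W) + np.pi * (W / 2.0) ** 2
    return base * (geometry.area_factor if geometry.pressed else 1.0)


@dataclass
class MoleculeSet:
    """Ground-truth molecule positions belonging to one cell."""

    cell_id: int
    positions: np.ndarray  # (N, 2) um, lab frame

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.positions)


def sample_positions(geometry: CellGeometry, n: int, rng: np.random.Generator) -> MoleculeSet:
    """Place ``n`` molecules uniformly over the footprint (rejection sampling).

    Sampling happens in the cell frame over the bounding box of the
    (possibly stretched) spherocylinder; acceptance uses the exact
    indicator, so the result is uniform over the footprint.
    """
    n = int(n)
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    if n == 0:
        return MoleculeSet(geometry.cell_id, np.empty((0, 2)))
    half_l = geometry.length / 2.0
    half_w = geometry.width * geometry.lateral_scale / 2.0
    half_body = max(geometry.length - geometry.width, 0.0) / 2.0
    r2 = (geometry.width / 2.0) ** 2
    out = np.empty((0, 2))
    while len(out) < n:
        m = max(2 * (n - len(out)), 64)
        cand = rng.uniform([-half_l, -half_w], [half_l, half_w], size=(m, 2))
        local = cand.copy()
        local[:, 1] /= geometry.lateral_scale
        dx = np.maximum(np.abs(local[:, 0]) - half_body, 0.0)
        keep = dx**2 + local[:, 1] ** 2 <= r2
        out = np.vstack([out, local[keep]])
    return MoleculeSet(geometry.cell_id, geometry.to_lab(out[:n]))


@dataclass
class PopulationSpec:
    """Parameters of a simulated cell population.

    Cell lengths follow a truncated normal (extreme sizes excluded by the
    truncation bounds); per-cell true copy numbers are Poisson with mean
    ``copy_number_mean``.  Defaults give flattened cells with footprints in
    the 2-6 um^2 range typical of exponentially growing E. coli and a
    balanced-growth mean of 7.5 molecules per cell.
    """

    n_cells: int = 200
    length_mean: float = 3.0
    length_sd: float = 0.6
    length_min: float = 2.0
    length_max: float = 4.5
    width: float = 0.9
    copy_number_mean: float = 7.5
    pressed: bool = True
    area_factor: float = 1.72
    height_factor: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.copy_number_mean < 0:
            raise ValueError("copy_number_mean must be >= 0")
        if not (self.length_min >= self.width):
            raise ValueError("length_min must be >= width (spherocylinder)")
        if not (self.length_min < self.length_max):
            raise ValueError("impossible truncation bounds")


def _grid_centers(n_cells: int, pitch: float) -> tuple[np.ndarray, int]:
    """Lay cells on a square grid with the given pitch (um)."""
    side = int(np.ceil(np.sqrt(n_cells)))
    ii, jj = np.divmod(np.arange(n_cells), side)
    xy = np.column_stack([(jj + 0.5) * pitch, (ii + 0.5) * pitch])
    return xy, side


def sample_population(
    spec: PopulationSpec,
    rng: np.random.Generator | None = None,
) -> tuple[list[CellGeometry], list[MoleculeSet], pd.DataFrame]:
    """Draw a cell population with ground-truth molecule placements.

    Returns the cell geometries (laid out on a non-overlapping grid so the
    population can be rendered into one field of view), the per-cell
    molecule sets, and a truth table with columns
    ``cell_id, length_um, width_um, area_um2, pressed, true_count``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    a, b = (
        (spec.length_min - spec.length_mean) / spec.length_sd,
        (spec.length_max - spec.length_mean) / spec.length_sd,
    )
    lengths = stats.truncnorm.rvs(
        a, b, loc=spec.length_mean, scale=spec.length_sd, size=spec.n_cells, random_state=rng
    )
    counts = rng.poisson(spec.copy_number_mean, size=spec.n_cells)
    lateral = spec.area_factor if spec.pressed else 1.0
    pitch = spec.length_max + 2.0  # clearance so PSF tails do not mix between cells
    centers, _ = _grid_centers(spec.n_cells, pitch)
    # Alternate orientations slightly so the layout is not perfectly regular.
    angles = rng.uniform(-0.35, 0.35, size=spec.n_cells)
    del lateral

    cells: list[CellGeometry] = []
    molecules: list[MoleculeSet] = []
    rows = []
    for i in range(spec.n_cells):
        geom = CellGeometry(
            length=float(lengths[i]),
            width=spec.width,
            center=(float(centers[i, 0]), float(centers[i, 1])),
            orientation=float(angles[i]),
            pressed=spec.pressed,
            height_factor=spec.height_factor if spec.pressed else 1.0,
            area_factor=spec.area_factor if spec.pressed else 1.0,
            cell_id=i,
        )
        cells.append(geom)
        molecules.append(sample_positions(geom, int(counts[i]), rng))
        rows.append(
            {
                "cell_id": i,
                "length_um": geom.length,
                "width_um": geom.width,
                "area_um2": footprint_area(geom),
                "pressed": geom.pressed,
                "true_count": int(counts[i]),
            }
        )
    truth = pd.DataFrame(rows)
    return cells, molecules, truth
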