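"""Half-ring array geometry and imaging grids.

Coordinate conventions (used by every other module):

* The array is a circular arc of radius ``radius_mm`` centred on the origin,
  opening upward: element angles are measured from the downward vertical
  (``-y``) axis, so the arc spans ``[-arc_deg/2, +arc_deg/2]`` symmetric about
  the vertical axis, with element 0 and element ``n-1`` the two topmost
  elements.  The breast sits above the arc, around the origin.
* Element normals are inward unit vectors (pointing at the arc centre).
* Imaging grids use pixel-centre sampling with index ``(0, 0)`` at the
  ``(-x, top)`` corner; row index grows downward (deeper), column index grows
  with ``+x``.  Depth below the skin line is measured along ``-y``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidGeometryError, InvalidGridError, RoleAssignmentError

__all__ = [
    "ArrayGeometry",
    "ImagingGrid",
    "build_half_ring_geometry",
    "assign_element_roles",
    "build_grid",
]


@dataclass(frozen=True)
class ArrayGeometry:
    """Half-ring transducer array: positions, normals and element roles."""

    n_elements: int
    radius_mm: float
    arc_deg: float
    element_xy: np.ndarray        # (n, 2) mm, array-centred Cartesian
    element_normal: np.ndarray    # (n, 2) inward unit vectors
    f_center_MHz: float = 3.0
    bandwidth_frac: float = 0.7
    emitter_idx: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    reserved_idx: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    tx_half_angle_deg: tuple[float, float] = (38.0, 48.0)
    # recorded metadata only; the well-resolved FOV ellipse is not derived here
    fov_ellipse_mm: tuple[float, float] = (82.0, 63.0)

    @property
    def receiver_idx(self) -> np.ndarray:
        """All elements that neither emit nor are reserved."""
        excluded = set(self.emitter_idx.tolist()) | set(self.reserved_idx.tolist())
        return np.array(
            [i for i in range(self.n_elements) if i not in excluded], dtype=int
        )

    @property
    def element_angles_deg(self) -> np.ndarray:
        """Angles from the downward vertical, degrees, ascending with index."""
        x, y = self.element_xy[:, 0], self.element_xy[:, 1]
        return np.degrees(np.arctan2(x, -y))

    def to_dict(self) -> dict:
        roles = np.full(self.n_elements, "receiver", dtype=object)
        roles[self.reserved_idx] = "reserved"
        roles[self.emitter_idx] = "emitter"
        return {
            "n_elements": self.n_elements,
            "radius_mm": self.radius_mm,
            "arc_deg": self.arc_deg,
            "f_center_MHz": self.f_center_MHz,
            "bandwidth_frac": self.bandwidth_frac,
            "tx_half_angle_deg": list(self.tx_half_angle_deg),
            "elements": [
                {
                    "index": i,
                    "x_mm": float(self.element_xy[i, 0]),
                    "y_mm": float(self.element_xy[i, 1]),
                    "role": str(roles[i]),
                }
                for i in range(self.n_elements)
            ],
        }


def build_half_ring_geometry(
    n_elements: int = 512,
    radius_mm: float = 130.0,
    arc_deg: float = 176.0,
    spacing: str = "uniform",
    angles_deg: np.ndarray | None = None,
    f_center_MHz: float = 3.0,
    bandwidth_frac: float = 0.7,
) -> ArrayGeometry:
    """Place ``n_elements`` on a circular arc symmetric about the vertical axis.

    ``spacing='uniform'`` spreads elements at equal angular pitch over
    ``arc_deg``; ``spacing='custom-table'`` takes a per-element angle table
    (degrees from the downward vertical) for arrays with nonuniform layouts.
    """
    if radius_mm <= 0:
        raise InvalidGeometryError(f"radius must be positive, got {radius_mm}")
    if n_elements < 3:
        raise InvalidGeometryError(f"need at least 3 elements, got {n_elements}")
    if not (0 < arc_deg <= 360):
        raise InvalidGeometryError(f"arc must be in (0, 360] deg, got {arc_deg}")

    if spacing == "uniform":
        ang = np.linspace(-arc_deg / 2.0, arc_deg / 2.0, n_elements)
    elif spacing == "custom-table":
        if angles_deg is None:
            raise InvalidGeometryError("custom-table spacing requires angles_deg")
        ang = np.asarray(angles_deg, dtype=float)
        if ang.shape != (n_elements,):
            raise InvalidGeometryError("angles_deg must have one angle per element")
    else:
        raise InvalidGeometryError(f"unknown spacing '{spacing}'")

    rad = np.radians(ang)
    element_xy = radius_mm * np.column_stack([np.sin(rad), -np.cos(rad)])
    element_normal = -element_xy / radius_mm
    return ArrayGeometry(
        n_elements=n_elements,
        radius_mm=radius_mm,
        arc_deg=arc_deg,
        element_xy=element_xy,
        element_normal=element_normal,
        f_center_MHz=f_center_MHz,
        bandwidth_frac=bandwidth_frac,
    )


def assign_element_roles(geom: ArrayGeometry, n_emitters: int = 30) -> ArrayGeometry:
    """Reserve the two topmost elements and pick emitters evenly among the rest.

    Within a frame an element is exclusively an emitter or a receiver; the
    ``receiver_idx`` property exposes the complement of emitters + reserved.
    """
    reserved = np.array([0, geom.n_elements - 1], dtype=int)
    n_avail = geom.n_elements - reserved.size
    if n_emitters > n_avail:
        raise RoleAssignmentError(
            f"{n_emitters} emitters requested but only {n_avail} eligible elements"
        )
    candidates = np.arange(1, geom.n_elements - 1)
    if n_emitters == 0:
        emitters = np.empty(0, dtype=int)
    else:
        pick = np.round(np.linspace(0, candidates.size - 1, n_emitters)).astype(int)
        emitters = candidates[pick]
    return replace(geom, emitter_idx=emitters, reserved_idx=reserved)


@dataclass(frozen=True)
class ImagingGrid:
    """Regular pixel grid in array coordinates (mm)."""

    width_mm: float
    depth_mm: float
    pitch_mm: float
    center_xy: tuple[float, float]
    n_x: int
    n_y: int

    @property
    def x_mm(self) -> np.ndarray:
        """Pixel-centre x coordinates, ascending with column index."""
        x0 = self.center_xy[0] - self.width_mm / 2.0
        return x0 + (np.arange(self.n_x) + 0.5) * self.pitch_mm

    @property
    def y_mm(self) -> np.ndarray:
        """Pixel-centre y coordinates; row 0 is the top of the image."""
        y0 = self.center_xy[1] + self.depth_mm / 2.0
        return y0 - (np.arange(self.n_y) + 0.5) * self.pitch_mm

    @property
    def depth_of_row_mm(self) -> np.ndarray:
        """Depth of each row below the image top, mm."""
        return (np.arange(self.n_y) + 0.5) * self.pitch_mm

    def index_to_xy(self, row: np.ndarray, col: np.ndarray):
        return self.x_mm[np.asarray(col)], self.y_mm[np.asarray(row)]

    def xy_to_index(self, x: np.ndarray, y: np.ndarray):
        x0 = self.center_xy[0] - self.width_mm / 2.0
        ytop = self.center_xy[1] + self.depth_mm / 2.0
        col = np.floor((np.asarray(x) - x0) / self.pitch_mm).astype(int)
        row = np.floor((ytop - np.asarray(y)) / self.pitch_mm).astype(int)
        return row, col


def build_grid(
    width_mm: float = 120.0,
    depth_mm: float = 50.0,
    pitch_mm: float = 0.25,
    center_xy: tuple[float, float] = (0.0, -5.0),
) -> ImagingGrid:
    """Build an imaging grid; pitch must tile both extents to within half a pixel."""
    if pitch_mm <= 0:
        raise InvalidGridError(f"pitch must be positive, got {pitch_mm}")
    n_x = round(width_mm / pitch_mm)
    n_y = round(depth_mm / pitch_mm)
    if n_x < 1 or n_y < 1:
        raise InvalidGridError("grid has no pixels")
    if abs(n_x * pitch_mm - width_mm) > 0.5 * pitch_mm + 1e-12:
        raise InvalidGridError("pitch does not divide width to within 0.5 px")
    if abs(n_y * pitch_mm - depth_mm) > 0.5 * pitch_mm + 1e-12:
        raise InvalidGridError("pitch does not divide depth to within 0.5 px")
    return ImagingGrid(
        width_mm=float(width_mm),
        depth_mm=float(depth_mm),
        pitch_mm=float(pitch_mm),
        center_xy=(float(center_xy[0]), float(center_xy[1])),
        n_x=n_x,
        n_y=n_y,
    )
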