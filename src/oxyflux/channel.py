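"""Reduced channel geometry, structured grid and prescribed velocity fields.

The desk-scale stand-in for a staggered fiber bundle is a 2D slit channel:
a membrane wall at y = 0, the symmetry plane (or a second membrane wall) at
y = half_gap, and axial flow in +x with a prescribed profile.  The grid is
structured and optionally graded geometrically toward the membrane wall,
where the O2 boundary layer is thin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import ParameterError

__all__ = [
    "ChannelGeometry",
    "StructuredGrid",
    "VelocityField",
    "build_grid",
    "plug_profile",
    "poiseuille_profile",
    "velocity_from_csv",
    "velocity_to_csv",
]


@dataclass(frozen=True)
class ChannelGeometry:
    """Slit-channel extents (m). ``symmetry=True`` solves the half-channel
    with a zero-flux centerline at y = half_gap."""

    length: float = 0.016
    half_gap: float = 90e-6
    symmetry: bool = True

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ParameterError("length must be non-negative")
        if self.half_gap <= 0:
            raise ParameterError("half_gap must be positive")


@dataclass(frozen=True)
class StructuredGrid:
    """Structured finite-volume grid: x_faces (Nx+1,), y_faces (Ny+1,)."""

    x_faces: np.ndarray
    y_faces: np.ndarray
    grading: float = 1.0

    def __post_init__(self) -> None:
        for f in (self.x_faces, self.y_faces):
            if len(f) < 2 or np.any(np.diff(f) <= 0):
                raise ParameterError("face coordinates must be strictly increasing")

    @property
    def Nx(self) -> int:
        return len(self.x_faces) - 1

    @property
    def Ny(self) -> int:
        return len(self.y_faces) - 1

    @property
    def dx(self) -> np.ndarray:
        return np.diff(self.x_faces)

    @property
    def dy(self) -> np.ndarray:
        return np.diff(self.y_faces)

    @property
    def xc(self) -> np.ndarray:
        return 0.5 * (self.x_faces[:-1] + self.x_faces[1:])

    @property
    def yc(self) -> np.ndarray:
        return 0.5 * (self.y_faces[:-1] + self.y_faces[1:])


def build_grid(geometry: ChannelGeometry, Nx: int, Ny: int,
               grading: float = 1.0) -> StructuredGrid:
    """Build a structured grid; ``grading`` > 1 refines toward the wall.

    Transverse cell widths follow a geometric series: the cell adjacent to
    the membrane wall (y = 0) is the finest and successive widths grow by
    the factor ``grading``.
    """
    if Nx < 1 or Ny < 1:
        raise ParameterError("Nx and Ny must be at least 1")
    if grading <= 0:
        raise ParameterError("grading must be positive")
    x_faces = np.linspace(0.0, geometry.length, Nx + 1)
    if abs(grading - 1.0) < 1e-14:
        y_faces = np.linspace(0.0, geometry.half_gap, Ny + 1)
    else:
        widths = grading ** np.arange(Ny)
        widths *= geometry.half_gap / widths.sum()
        y_faces = np.concatenate([[0.0], np.cumsum(widths)])
        y_faces[-1] = geometry.half_gap
    return StructuredGrid(x_faces=x_faces, y_faces=y_faces, grading=grading)


@dataclass(frozen=True)
class VelocityField:
    """Axial velocity per cell, shape (Nx, Ny), m/s; non-negative."""

    u: np.ndarray
    mean: float
    profile: str = "plug"

    def __post_init__(self) -> None:
        if np.any(self.u < 0):
            raise ParameterError("axial velocity must be non-negative")

    def check_mean(self, grid: StructuredGrid, rtol: float = 1e-12) -> None:
        m = area_weighted_mean(self.u, grid)
        if self.mean > 0 and abs(m - self.mean) > rtol * max(abs(self.mean), 1e-300):
            raise ParameterError(
                f"declared mean velocity {self.mean} inconsistent with field mean {m}")


def area_weighted_mean(u: np.ndarray, grid: StructuredGrid) -> float:
    w = np.outer(grid.dx, grid.dy)
    return float((u * w).sum() / w.sum())


def plug_profile(grid: StructuredGrid, mean_velocity: float) -> VelocityField:
    """Uniform axial velocity equal to the mean."""
    if mean_velocity < 0:
        raise ParameterError("mean velocity must be non-negative")
    u = np.full((grid.Nx, grid.Ny), float(mean_velocity))
    return VelocityField(u=u, mean=float(mean_velocity), profile="plug")


def poiseuille_profile(grid: StructuredGrid, mean_velocity: float) -> VelocityField:
    """Laminar parabolic profile for the half-channel,
    u(y) = 1.5 * u_mean * (1 - (s/H)^2) with s the distance from the
    centerline (y = half_gap).

    Cells carry the exact cell-averaged parabola, so the discrete
    area-weighted mean reproduces ``mean_velocity`` to round-off.
    """
    if mean_velocity < 0:
        raise ParameterError("mean velocity must be non-negative")
    H = grid.y_faces[-1]
    s1 = H - grid.y_faces[1:]    # distance from centerline, near edge
    s2 = H - grid.y_faces[:-1]   # far edge
    # cell average of s^2 over [s1, s2]: (s1^2 + s1*s2 + s2^2)/3
    s2_avg = (s1 * s1 + s1 * s2 + s2 * s2) / 3.0
    uy = 1.5 * mean_velocity * (1.0 - s2_avg / H ** 2)
    u = np.tile(uy, (grid.Nx, 1))
    return VelocityField(u=u, mean=float(mean_velocity), profile="poiseuille")


def velocity_to_csv(field: VelocityField, path) -> None:
    """Write a velocity field as CSV (x_index, y_index, u_axial_m_per_s);
    0-based indices, x varying fastest."""
    nx, ny = field.u.shape
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx))
    # x fastest: iterate y outer, x inner
    df = pd.DataFrame({
        "x_index": xx.T.ravel(),
        "y_index": yy.T.ravel(),
        "u_axial_m_per_s": field.u.T.ravel(),
    })
    df.to_csv(path, index=False)


def velocity_from_csv(path, grid: StructuredGrid,
                      profile: str = "file") -> VelocityField:
    """Load a per-cell axial velocity field written by :func:`velocity_to_csv`."""
    df = pd.read_csv(path)
    required = {"x_index", "y_index", "u_axial_m_per_s"}
    if not required.issubset(df.columns):
        raise ParameterError(f"velocity CSV must have columns {sorted(required)}")
    u = np.full((grid.Nx, grid.Ny), np.nan)
    u[df["x_index"].to_numpy(int), df["y_index"].to_numpy(int)] = \
        df["u_axial_m_per_s"].to_numpy(float)
    if np.isnan(u).any():
        raise ParameterError("velocity CSV does not cover every grid cell")
    return VelocityField(u=u, mean=area_weighted_mean(u, grid), profile=profile)
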