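"""Viewpoint enumeration and deterministic ball-and-stick rasterization.

Viewpoints are the Cartesian product over x, y, z of the per-axis rotation
angles {k*theta : k >= 0, k*theta < 360}, so an increment of 195 degrees
yields 2 angles per axis and 8 images, 176 degrees yields 3 and 27, etc.

Rendering is a pure-NumPy orthographic rasterizer: atoms are Lambert-shaded
spheres colored by element, bonds are sticks split at the midpoint and
colored per half; occlusion is handled by painter's-algorithm depth sorting.
Identical inputs always produce identical pixel arrays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from snapqsar.conformer3d import Conformer3D

__all__ = [
    "SnapshotSpec",
    "Viewpoint",
    "BACKGROUND_PALETTE",
    "ELEMENT_PALETTE",
    "enumerate_viewpoints",
    "rotation_matrix",
    "rotate_conformer",
    "resolve_background_color",
    "render_snapshot",
    "save_png",
    "generate_snapshots",
]

# Background colors: PyMOL-style named values (0-1 RGB).
BACKGROUND_PALETTE: dict[str, tuple[float, float, float]] = {
    # primaries
    "blue": (0.0, 0.0, 1.0),
    "cyan": (0.0, 1.0, 1.0),
    "green": (0.0, 1.0, 0.0),
    "magenta": (1.0, 0.0, 1.0),
    "orange": (1.0, 0.5, 0.0),
    "red": (1.0, 0.0, 0.0),
    "wheat": (0.99, 0.82, 0.65),
    "white": (1.0, 1.0, 1.0),
    "yellow": (1.0, 1.0, 0.0),
    # extended set
    "aquamarine": (0.5, 1.0, 1.0),
    "blue_white": (0.85, 0.85, 1.00),
    "grey70": (0.7, 0.7, 0.7),
    "grey80": (0.8, 0.8, 0.8),
    "grey90": (0.9, 0.9, 0.9),
    "light_blue": (0.75, 0.75, 1.00),
    "light_pink": (1.00, 0.75, 0.87),
    "pale_cyan": (0.8, 1.0, 1.0),
    "pale_green": (0.65, 0.90, 0.65),
    "pale_yellow": (1.0, 1.0, 0.5),
    "violet": (1.0, 0.5, 1.0),
    "bright_orange": (1.0, 0.7, 0.2),
    "deep_salmon": (1.0, 0.5, 0.5),
    "gold": (1.00, 0.82, 0.14),
    "light_orange": (1.0, 0.8, 0.5),
    "salmon": (1.0, 0.6, 0.6),
    "tv_orange": (1.00, 0.55, 0.15),
    "yellow_orange": (1.00, 0.87, 0.37),
    "black": (0.0, 0.0, 0.0),
}

# CPK-like element colors.
ELEMENT_PALETTE: dict[str, tuple[float, float, float]] = {
    "H": (0.95, 0.95, 0.95),
    "C": (0.35, 0.35, 0.35),
    "N": (0.19, 0.31, 0.97),
    "O": (1.0, 0.05, 0.05),
    "S": (1.0, 0.9, 0.23),
    "P": (1.0, 0.5, 0.0),
    "F": (0.56, 0.88, 0.31),
    "Cl": (0.12, 0.94, 0.12),
    "Br": (0.65, 0.16, 0.16),
    "I": (0.58, 0.0, 0.58),
    "B": (1.0, 0.71, 0.71),
    "Si": (0.94, 0.78, 0.63),
}
_DEFAULT_ELEMENT_COLOR = (0.8, 0.4, 0.8)

# display radii in Angstrom before atom_scale
ELEMENT_RADII: dict[str, float] = {
    "H": 1.10, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "Cl": 1.75, "Br": 1.85, "I": 1.98, "B": 1.65, "Si": 2.10,
}
_DEFAULT_RADIUS = 1.75


def _normalize_color_name(name: str) -> str:
    return name.strip().lower().replace("-", "_").replace(" ", "_")


def resolve_background_color(name_or_rgb) -> tuple[float, float, float]:
    """Resolve a named color or pass through an explicit RGB triple in
    [0,1]^3. Unknown names raise a lookup error listing the valid names."""
    if isinstance(name_or_rgb, str):
        key = _normalize_color_name(name_or_rgb)
        if key not in BACKGROUND_PALETTE:
            raise KeyError(
                f"unknown background color {name_or_rgb!r}; valid names: "
                + ", ".join(sorted(BACKGROUND_PALETTE)))
        return BACKGROUND_PALETTE[key]
    rgb = tuple(float(v) for v in name_or_rgb)
    if len(rgb) != 3 or any(not (0.0 <= v <= 1.0) for v in rgb):
        raise ValueError(f"RGB triple must lie in [0,1]^3, got {name_or_rgb}")
    return rgb


@dataclass(frozen=True)
class Viewpoint:
    """Rotation angles (degrees) about x, y, z; each in [0, 360)."""

    rx: float
    ry: float
    rz: float

    def tag(self) -> str:
        return f"rx{self.rx:g}_ry{self.ry:g}_rz{self.rz:g}"


@dataclass
class SnapshotSpec:
    """Rendering recipe: per-axis angle increments, image geometry, colors."""

    theta: tuple[float, float, float] = (195.0, 195.0, 195.0)
    image_size: int = 256
    background: object = "white"  # name or RGB triple
    atom_scale: float = 0.30
    bond_radius: float = 0.14  # Angstrom
    margin_fraction: float = 0.12
    element_palette: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.theta) != 3 or any(
                not (0.0 < t <= 360.0) for t in self.theta):
            raise ValueError("theta must have three components in (0, 360]")
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        resolve_background_color(self.background)  # fail fast

    def palette(self, element: str) -> tuple[float, float, float]:
        return (self.element_palette.get(element)
                or ELEMENT_PALETTE.get(element, _DEFAULT_ELEMENT_COLOR))


def _axis_angles(theta: float) -> list[float]:
    if theta <= 0:
        raise ValueError("angle increment must be positive")
    out, k = [], 0
    while k * theta < 360.0:
        out.append(k * theta)
        k += 1
    return out


def enumerate_viewpoints(theta: Sequence[float]) -> list[Viewpoint]:
    """All (kx*tx, ky*ty, kz*tz) triples with each component below 360,
    in lexicographic (x-major) order; len == prod(ceil(360/theta_axis))."""
    if len(theta) != 3:
        raise ValueError("theta must have three components")
    ax, ay, az = (_axis_angles(float(t)) for t in theta)
    return [Viewpoint(x, y, z) for x in ax for y in ay for z in az]


def rotation_matrix(viewpoint: Viewpoint) -> np.ndarray:
    """Rz(rz) @ Ry(ry) @ Rx(rx), angles in degrees."""
    rx, ry, rz = (math.radians(a) for a in
                  (viewpoint.rx, viewpoint.ry, viewpoint.rz))
    cx, sx = math.cos(rx), math.sin(rx)
    cy, sy = math.cos(ry), math.sin(ry)
    cz, sz = math.cos(rz), math.sin(rz)
    mx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    my = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    mz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return mz @ my @ mx


def rotate_conformer(conformer: Conformer3D,
                     viewpoint: Viewpoint) -> Conformer3D:
    """Rotate coordinates about the molecule centroid; distances and the
    centroid itself are preserved."""
    coords = conformer.coords
    centroid = coords.mean(axis=0)
    rotated = (coords - centroid) @ rotation_matrix(viewpoint).T + centroid
    return conformer.with_coords(rotated)


def _draw_sphere(img, zbuf, cx, cy, r, z, color):
    size = img.shape[0]
    x0, x1 = max(int(cx - r), 0), min(int(cx + r) + 2, size)
    y0, y1 = max(int(cy - r), 0), min(int(cy + r) + 2, size)
    if x0 >= x1 or y0 >= y1:
        return
    ys, xs = np.mgrid[y0:y1, x0:x1]
    dx = xs + 0.5 - cx
    dy = ys + 0.5 - cy
    d2 = dx * dx + dy * dy
    mask = d2 <= r * r
    if not mask.any():
        return
    nz = np.sqrt(np.clip(1.0 - d2 / (r * r), 0.0, 1.0))
    nxl = -dx / r
    nyl = -dy / r
    # light from upper-left-front (screen y grows downward)
    lx, ly, lz = -0.45, -0.45, 0.77
    diff = np.clip(nxl * lx + nyl * ly + nz * lz, 0.0, 1.0)
    shade = 0.30 + 0.70 * diff
    zhere = z + nz * r  # sphere surface depth
    visible = mask & (zhere > zbuf[y0:y1, x0:x1])
    for ch in range(3):
        img[y0:y1, x0:x1, ch][visible] = np.clip(
            color[ch] * shade[visible], 0.0, 1.0)
    zbuf[y0:y1, x0:x1][visible] = zhere[visible]


def _draw_stick(img, zbuf, p0, p1, z0, z1, width, color):
    size = img.shape[0]
    x0 = max(int(min(p0[0], p1[0]) - width), 0)
    x1 = min(int(max(p0[0], p1[0]) + width) + 2, size)
    y0 = max(int(min(p0[1], p1[1]) - width), 0)
    y1 = min(int(max(p0[1], p1[1]) + width) + 2, size)
    if x0 >= x1 or y0 >= y1:
        return
    ys, xs = np.mgrid[y0:y1, x0:x1]
    px = xs + 0.5
    py = ys + 0.5
    vx, vy = p1[0] - p0[0], p1[1] - p0[1]
    vv = vx * vx + vy * vy
    if vv < 1e-12:
        return
    t = np.clip(((px - p0[0]) * vx + (py - p0[1]) * vy) / vv, 0.0, 1.0)
    dx = px - (p0[0] + t * vx)
    dy = py - (p0[1] + t * vy)
    d2 = dx * dx + dy * dy
    mask = d2 <= width * width
    if not mask.any():
        return
    nz = np.sqrt(np.clip(1.0 - d2 / (width * width), 0.0, 1.0))
    shade = 0.35 + 0.65 * nz
    zhere = z0 + t * (z1 - z0) + nz * width * 0.5
    visible = mask & (zhere > zbuf[y0:y1, x0:x1])
    for ch in range(3):
        img[y0:y1, x0:x1, ch][visible] = np.clip(
            color[ch] * shade[visible], 0.0, 1.0)
    zbuf[y0:y1, x0:x1][visible] = zhere[visible]


def render_snapshot(conformer: Conformer3D, viewpoint: Viewpoint,
                    spec: SnapshotSpec) -> np.ndarray:
    """Rasterize one snapshot; returns a uint8 array of shape
    (image_size, image_size, 3). Deterministic for identical inputs."""
    if not conformer.atoms:
        raise ValueError("cannot render a zero-atom conformer")
    rotated = rotate_conformer(conformer, viewpoint)
    coords = rotated.coords
    coords = coords - coords.mean(axis=0)
    elements = rotated.elements
    radii = np.array([spec.atom_scale * ELEMENT_RADII.get(el, _DEFAULT_RADIUS)
                      for el in elements])

    size = spec.image_size
    extent = float(np.max(np.linalg.norm(coords, axis=1) + radii))
    extent = max(extent, 1e-6)
    scale = (size / 2.0) * (1.0 - spec.margin_fraction) / extent
    cx = cy = size / 2.0
    # screen coords: x right, y up (flip), z toward the viewer
    u = cx + coords[:, 0] * scale
    v = cy - coords[:, 1] * scale
    z = coords[:, 2] * scale

    bg = resolve_background_color(spec.background)
    img = np.empty((size, size, 3), dtype=float)
    img[:, :] = bg
    zbuf = np.full((size, size), -np.inf)

    stick_w = max(spec.bond_radius * scale, 0.75)
    for i, j, _order in rotated.bonds:
        mid = ((u[i] + u[j]) / 2.0, (v[i] + v[j]) / 2.0)
        zmid = (z[i] + z[j]) / 2.0
        _draw_stick(img, zbuf, (u[i], v[i]), mid, z[i], zmid, stick_w,
                    spec.palette(elements[i]))
        _draw_stick(img, zbuf, mid, (u[j], v[j]), zmid, z[j], stick_w,
                    spec.palette(elements[j]))
    for i in np.argsort(z, kind="mergesort"):
        _draw_sphere(img, zbuf, u[i], v[i], radii[i] * scale, z[i],
                     spec.palette(elements[i]))

    return (np.clip(img, 0.0, 1.0) * 255.0 + 0.5).astype(np.uint8)


def save_png(pixels: np.ndarray, path: str | Path) -> None:
    from PIL import Image

    Image.fromarray(pixels, mode="RGB").save(path, format="PNG")


def generate_snapshots(conformers: Sequence[Conformer3D], spec: SnapshotSpec,
                       out_dir: str | Path,
                       molecule_info: dict[str, dict] | None = None,
                       overwrite: bool = True) -> pd.DataFrame:
    """Render every (molecule, viewpoint) pair to PNG and return the manifest.

    ``molecule_info`` optionally maps compound_id -> {"split": ..,
    "label": ..} to stamp those columns into the manifest. With
    ``overwrite=False`` existing files are kept (idempotent re-run).
    """
    conformers = list(conformers)
    if not conformers:
        raise ValueError("conformer list must be non-empty")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not out_dir.is_dir():
        raise IOError(f"cannot write to {out_dir}")
    viewpoints = enumerate_viewpoints(spec.theta)
    rows = []
    for conf in conformers:
        cid = conf.compound_id or "mol"
        info = (molecule_info or {}).get(cid, {})
        for vp in viewpoints:
            fname = f"{cid}_{vp.tag()}.png"
            fpath = out_dir / fname
            if overwrite or not fpath.exists():
                save_png(render_snapshot(conf, vp, spec), fpath)
            rows.append({
                "image_path": str(fpath), "compound_id": cid,
                "rx": vp.rx, "ry": vp.ry, "rz": vp.rz,
                "split": info.get("split", "unassigned"),
                "label": info.get("label", -1),
            })
    return pd.DataFrame(rows)
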