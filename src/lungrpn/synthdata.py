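"""Synthetic CT phantoms with known ground truth.

Real lung-screening data comes as MetaImage volumes of 512x512 slices in
Hounsfield units (HU), with nodule annotations as world-coordinate centres
and diameters in a CSV.  This module fabricates that exact dialect from
scratch: a body ellipse of soft tissue on an air background, two lung
ellipses of near-air density inside it, optional bone arcs, and inserted
nodule disks of diameter >= 3 mm.  Because every structure is placed
analytically, each phantom carries exact ground truth (compartment maps and
tight pixel bounding boxes), which is what makes the rest of the pipeline
testable without any download.

World coordinates: origin at the volume corner, axes aligned with array
indices, so ``world_mm = pixel_index * spacing`` (x = column, y = row,
z = slice).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import SimpleITK as sitk

from .rpn import Box

__all__ = [
    "Ellipse",
    "BoneArc",
    "HULevels",
    "PhantomSpec",
    "NoduleSpec",
    "BoxPopulationSpec",
    "HUImage",
    "make_phantom_slice",
    "compartment_map",
    "sample_nodule_boxes",
    "sample_nodule_specs",
    "write_dataset",
    "read_dataset",
    "default_phantom_spec",
]


@dataclass(frozen=True)
class HUImage:
    """A 2-D CT slice calibrated in Hounsfield units, with pixel spacing in mm."""

    values: np.ndarray
    spacing: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("HUImage must be 2-D")
        if not np.all(np.isfinite(v)):
            raise ValueError("HU values must be finite")
        if not self.spacing > 0:
            raise ValueError("spacing must be > 0")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class Ellipse:
    """Axis-aligned ellipse in pixel coordinates: centre (cx, cy), semi-axes (ax, ay)."""

    cx: float
    cy: float
    ax: float
    ay: float

    def contains(self, x: np.ndarray, y: np.ndarray, margin: float = 0.0) -> np.ndarray:
        return ((x - self.cx) / (self.ax - margin)) ** 2 + (
            (y - self.cy) / (self.ay - margin)
        ) ** 2 <= 1.0

    @property
    def area(self) -> float:
        return np.pi * self.ax * self.ay


@dataclass(frozen=True)
class BoneArc:
    """A rib-like arc: annulus sector around (cx, cy) between radii r0 < r1,
    spanning [theta0, theta1] radians."""

    cx: float
    cy: float
    r0: float
    r1: float
    theta0: float
    theta1: float


@dataclass(frozen=True)
class HULevels:
    """Compartment radiodensities in HU; air < lung air < soft tissue < bone."""

    background_air: float = -1000.0
    lung_air: float = -850.0
    soft_tissue: float = 40.0
    bone: float = 700.0

    def __post_init__(self) -> None:
        if not (
            self.background_air <= self.lung_air < self.soft_tissue < self.bone
        ):
            raise ValueError("HU levels must be ordered background <= lung < tissue < bone")


DEFAULT_NODULE_HU = -50.0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and radiodensity of one synthetic thorax slice."""

    image_size: int = 512
    spacing: float = 0.7  # mm per pixel
    body_ellipse: Ellipse | None = None
    left_lung_ellipse: Ellipse | None = None
    right_lung_ellipse: Ellipse | None = None
    hu_levels: HULevels = field(default_factory=HULevels)
    bone_arcs: tuple[BoneArc, ...] = ()
    noise_sd: float = 0.0  # additive Gaussian noise in HU; 0 keeps tests exact
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 16:
            raise ValueError("image_size too small")
        if not self.spacing > 0:
            raise ValueError("spacing must be > 0")
        s = self.image_size
        if self.body_ellipse is None:
            object.__setattr__(self, "body_ellipse", Ellipse(s / 2, s / 2, 0.45 * s, 0.38 * s))
        if self.left_lung_ellipse is None:
            object.__setattr__(
                self, "left_lung_ellipse", Ellipse(0.34 * s, 0.5 * s, 0.14 * s, 0.24 * s)
            )
        if self.right_lung_ellipse is None:
            object.__setattr__(
                self, "right_lung_ellipse", Ellipse(0.66 * s, 0.5 * s, 0.14 * s, 0.24 * s)
            )
        for lung in (self.left_lung_ellipse, self.right_lung_ellipse):
            for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                px = lung.cx + dx * lung.ax
                py = lung.cy + dy * lung.ay
                b = self.body_ellipse
                if ((px - b.cx) / b.ax) ** 2 + ((py - b.cy) / b.ay) ** 2 >= 1.0:
                    raise ValueError("lung ellipse must lie strictly inside the body ellipse")
        object.__setattr__(self, "bone_arcs", tuple(self.bone_arcs))


@dataclass(frozen=True)
class NoduleSpec:
    """A spherical nodule: world-mm centre, diameter (>= 3 mm) and density."""

    center: tuple[float, float]  # (x_mm, y_mm) within the slice
    diameter: float  # mm
    intensity: float = DEFAULT_NODULE_HU  # HU

    def __post_init__(self) -> None:
        if self.diameter < 3.0:
            raise ValueError(f"nodule diameter {self.diameter} mm < 3 mm minimum")


@dataclass(frozen=True)
class BoxPopulationSpec:
    """Log-normal mixture over box (width, height); feeds clustering tests.

    components: list of (mean_log_w, mean_log_h, log_sd, weight).
    """

    n: int
    components: tuple[tuple[float, float, float, float], ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        comps = tuple(tuple(float(v) for v in c) for c in self.components)
        if len(comps) == 0:
            raise ValueError("need at least one component")
        w = sum(c[3] for c in comps)
        if abs(w - 1.0) > 1e-9:
            raise ValueError("component weights must sum to 1")
        if any(c[2] < 0 for c in comps):
            raise ValueError("log-sd must be >= 0")
        object.__setattr__(self, "components", comps)


def default_phantom_spec(image_size: int = 512, spacing: float = 0.7, **kw) -> PhantomSpec:
    """A standard thorax phantom at the given raster size."""
    return PhantomSpec(image_size=image_size, spacing=spacing, **kw)


def _grids(n: int) -> tuple[np.ndarray, np.ndarray]:
    y, x = np.mgrid[0:n, 0:n]
    return x.astype(float) + 0.5, y.astype(float) + 0.5  # pixel centres


def compartment_map(spec: PhantomSpec) -> np.ndarray:
    """Integer map of the phantom's anatomy: 0 background air, 1 soft tissue,
    2 lung air, 3 bone (no nodules)."""
    x, y = _grids(spec.image_size)
    comp = np.zeros((spec.image_size, spec.image_size), dtype=np.uint8)
    comp[spec.body_ellipse.contains(x, y)] = 1
    comp[spec.left_lung_ellipse.contains(x, y)] = 2
    comp[spec.right_lung_ellipse.contains(x, y)] = 2
    for arc in spec.bone_arcs:
        r = np.hypot(x - arc.cx, y - arc.cy)
        theta = np.arctan2(y - arc.cy, x - arc.cx)
        in_arc = (r >= arc.r0) & (r <= arc.r1) & (theta >= arc.theta0) & (theta <= arc.theta1)
        comp[in_arc & (comp == 1)] = 3
    return comp


def _nodule_in_lung(spec: PhantomSpec, nodule: NoduleSpec) -> bool:
    cx_px = nodule.center[0] / spec.spacing
    cy_px = nodule.center[1] / spec.spacing
    r_px = nodule.diameter / 2.0 / spec.spacing
    for lung in (spec.left_lung_ellipse, spec.right_lung_ellipse):
        # conservative containment: nodule circle inside the ellipse shrunk by r
        if lung.ax - r_px > 0 and lung.ay - r_px > 0:
            if ((cx_px - lung.cx) / (lung.ax - r_px)) ** 2 + (
                (cy_px - lung.cy) / (lung.ay - r_px)
            ) ** 2 <= 1.0:
                return True
    return False


def make_phantom_slice(
    spec: PhantomSpec, nodules: Sequence[NoduleSpec] = ()
) -> tuple[HUImage, list[Box]]:
    """Rasterise a thorax phantom and insert nodules.

    Returns the HU slice and the tight pixel bounding box of each nodule
    (half-open, in raster order matching ``nodules``).  A nodule whose disk is
    not contained in a lung ellipse is rejected with a ValueError naming it.
    """
    for i, nod in enumerate(nodules):
        if not _nodule_in_lung(spec, nod):
            raise ValueError(
                f"nodule {i} at {nod.center} mm (d={nod.diameter} mm) is not inside a lung"
            )
    comp = compartment_map(spec)
    levels = spec.hu_levels
    lut = np.array(
        [levels.background_air, levels.soft_tissue, levels.lung_air, levels.bone]
    )
    img = lut[comp]
    x, y = _grids(spec.image_size)
    boxes: list[Box] = []
    for nod in nodules:
        cx = nod.center[0] / spec.spacing
        cy = nod.center[1] / spec.spacing
        r = nod.diameter / 2.0 / spec.spacing
        disk = (x - cx) ** 2 + (y - cy) ** 2 <= r ** 2
        img[disk] = nod.intensity
        cols = np.where(disk.any(axis=0))[0]
        rows = np.where(disk.any(axis=1))[0]
        boxes.append(Box(float(cols[0]), float(rows[0]), float(cols[-1] + 1), float(rows[-1] + 1)))
    if spec.noise_sd > 0:
        rng = np.random.RandomState(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    return HUImage(img, spec.spacing), boxes


def sample_nodule_boxes(spec: BoxPopulationSpec) -> np.ndarray:
    """Draw n (width, height) pairs from the log-normal mixture; shape (n, 2)."""
    rng = np.random.RandomState(spec.seed)
    weights = np.array([c[3] for c in spec.components])
    comp_idx = rng.choice(len(spec.components), size=spec.n, p=weights)
    out = np.empty((spec.n, 2))
    for i, ci in enumerate(comp_idx):
        mu_w, mu_h, sd, _ = spec.components[ci]
        out[i, 0] = np.exp(rng.normal(mu_w, sd))
        out[i, 1] = np.exp(rng.normal(mu_h, sd))
    return out


def sample_nodule_specs(
    spec: PhantomSpec,
    n: int,
    rng: np.random.RandomState,
    diameter_range: tuple[float, float] = (4.0, 16.0),
    intensity: float = DEFAULT_NODULE_HU,
) -> list[NoduleSpec]:
    """Place n random nodules safely inside the lung ellipses (rejection sampling)."""
    out: list[NoduleSpec] = []
    lungs = (spec.left_lung_ellipse, spec.right_lung_ellipse)
    while len(out) < n:
        lung = lungs[rng.randint(2)]
        d = rng.uniform(*diameter_range)
        r_px = d / 2.0 / spec.spacing
        if lung.ax - r_px <= 1 or lung.ay - r_px <= 1:
            continue
        # uniform in the shrunk ellipse
        t = rng.uniform(0, 2 * np.pi)
        rho = np.sqrt(rng.uniform())
        cx = lung.cx + rho * np.cos(t) * (lung.ax - r_px - 1)
        cy = lung.cy + rho * np.sin(t) * (lung.ay - r_px - 1)
        out.append(
            NoduleSpec(
                center=(cx * spec.spacing, cy * spec.spacing),
                diameter=d,
                intensity=intensity,
            )
        )
    return out


ANNOTATION_COLUMNS = ("seriesuid", "coordX", "coordY", "coordZ", "diameter_mm")


def write_dataset(
    slices: Sequence[HUImage],
    boxes: Sequence[Sequence[Box]],
    path: str | Path,
    nodules: Sequence[Sequence[NoduleSpec]] | None = None,
    seriesuid: str = "synthetic.phantom",
) -> Path:
    """Write slices as one MetaImage volume plus the annotation CSV.

    The CSV lists one row per nodule with world-mm centre and diameter
    (columns ``seriesuid, coordX, coordY, coordZ, diameter_mm``).  When the
    originating :class:`NoduleSpec` objects are not supplied, centres and
    diameters are reconstructed from the pixel boxes.  Returns the dataset
    directory.
    """
    if len(slices) != len(boxes):
        raise ValueError("slices and boxes must be aligned")
    if nodules is not None and len(nodules) != len(slices):
        raise ValueError("nodules and slices must be aligned")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if slices:
        spacing = slices[0].spacing
        vol = np.stack([s.values for s in slices]).astype(np.float32)
        img = sitk.GetImageFromArray(vol)  # (z, y, x)
        img.SetSpacing((spacing, spacing, spacing))
        img.SetOrigin((0.0, 0.0, 0.0))
        sitk.WriteImage(img, str(path / f"{seriesuid}.mhd"))
    rows = []
    for z, slice_boxes in enumerate(boxes):
        spacing = slices[z].spacing if slices else 1.0
        for j, b in enumerate(slice_boxes):
            if nodules is not None:
                nod = nodules[z][j]
                cx_mm, cy_mm = nod.center
                d_mm = nod.diameter
            else:
                cx_mm = 0.5 * (b.x_min + b.x_max) * spacing
                cy_mm = 0.5 * (b.y_min + b.y_max) * spacing
                d_mm = max(b.width, b.height) * spacing
            rows.append((seriesuid, cx_mm, cy_mm, z * spacing, d_mm))
    with open(path / "annotations.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(ANNOTATION_COLUMNS)
        w.writerows(rows)
    return path


def read_dataset(
    path: str | Path, seriesuid: str = "synthetic.phantom"
) -> tuple[list[HUImage], list[list[Box]]]:
    """Read a dataset written by :func:`write_dataset`; inverse round-trip.

    Annotation rows are converted back to tight pixel boxes via the spacing
    (mm / spacing = px); nodules are assumed circular in-plane.
    """
    path = Path(path)
    mhd = path / f"{seriesuid}.mhd"
    slices: list[HUImage] = []
    if mhd.exists():
        img = sitk.ReadImage(str(mhd))
        spacing = img.GetSpacing()[0]
        vol = sitk.GetArrayFromImage(img)
        slices = [HUImage(vol[z].astype(float), spacing) for z in range(vol.shape[0])]
    boxes: list[list[Box]] = [[] for _ in slices]
    ann = path / "annotations.csv"
    if ann.exists():
        with open(ann) as fh:
            for row in csv.DictReader(fh):
                spacing = slices[0].spacing if slices else 1.0
                z = int(round(float(row["coordZ"]) / spacing))
                cx = float(row["coordX"]) / spacing
                cy = float(row["coordY"]) / spacing
                r = float(row["diameter_mm"]) / 2.0 / spacing
                box = _tight_disk_box(cx, cy, r, slices[z].shape if slices else None)
                while z >= len(boxes):
                    boxes.append([])
                boxes[z].append(box)
    return slices, boxes


def _tight_disk_box(cx: float, cy: float, r: float, shape: tuple[int, int] | None) -> Box:
    """Tight half-open pixel box of the disk rasterised at pixel centres.

    Matches the rasteriser in :func:`make_phantom_slice`: a pixel (row, col)
    is inside iff (col+0.5-cx)^2 + (row+0.5-cy)^2 <= r^2.
    """
    c0 = int(np.floor(cx - r - 1))
    c1 = int(np.ceil(cx + r + 1))
    r0 = int(np.floor(cy - r - 1))
    r1 = int(np.ceil(cy + r + 1))
    if shape is not None:
        c0, c1 = max(c0, 0), min(c1, shape[1])
        r0, r1 = max(r0, 0), min(r1, shape[0])
    rows, cols = np.mgrid[r0:r1, c0:c1]
    disk = (cols + 0.5 - cx) ** 2 + (rows + 0.5 - cy) ** 2 <= r ** 2
    if not disk.any():
        raise ValueError("annotation disk rasterises to no pixels")
    set_cols = np.where(disk.any(axis=0))[0] + c0
    set_rows = np.where(disk.any(axis=1))[0] + r0
    return Box(
        float(set_cols[0]), float(set_rows[0]), float(set_cols[-1] + 1), float(set_rows[-1] + 1)
    )
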