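"""ROI polygon annotations, slide tiling, and patch preprocessing.

Slides are tiled into non-overlapping 512x512 patches on a grid anchored at
the slide origin; a patch is retained only if strictly more than 80% of its
area lies inside the union of the annotated carcinoma ROI polygons.  Retained
patches are center-cropped to 224x224 and z-scored per RGB channel with
training-set statistics; training-time augmentation applies a random
horizontal flip and a mild random affine transform that keeps the patch
center fixed, before the crop.

Annotations use the Aperio ImageScope XML dialect
(Annotations/Annotation/Regions/Region/Vertices/Vertex with X,Y attributes),
level-0 pixel coordinates, y increasing downward.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from lxml import etree
from scipy import ndimage
from shapely.geometry import Polygon, box
from shapely.ops import unary_union

PATCH_SIZE = 512
CROP_SIZE = 224
MIN_OVERLAP = 0.8


@dataclass
class ROIAnnotation:
    """Carcinoma region-of-interest polygons for one slide."""

    slide_id: str
    polygons: list[np.ndarray]  # each (n,2) float array of (x, y) vertices
    mpp: float = 0.5

    def union(self):
        polys = []
        for ring in self.polygons:
            p = Polygon(ring)
            if not p.is_valid:
                p = p.buffer(0)  # clean self-touching rings
            polys.append(p)
        return unary_union(polys)


@dataclass
class PatchRef:
    """One candidate patch on the tiling grid."""

    slide_id: str
    grid_x: int
    grid_y: int
    origin: tuple[int, int]
    size: int = PATCH_SIZE
    overlap: float = 0.0


@dataclass
class PreprocessConfig:
    """Crop/normalization/augmentation settings shared by training and inference."""

    crop_size: int = CROP_SIZE
    channel_mean: np.ndarray = field(default_factory=lambda: np.zeros(3))
    channel_std: np.ndarray = field(default_factory=lambda: np.ones(3))
    augment: bool = False
    flip_prob: float = 0.5
    affine: bool = True  # random affine applied only when augment is on
    magnification_factor: int = 1  # 1/2/4 downsample for the 20x/10x/5x ablation

    def __post_init__(self):
        self.channel_mean = np.asarray(self.channel_mean, dtype=float)
        self.channel_std = np.asarray(self.channel_std, dtype=float)
        if np.any(self.channel_std <= 0):
            raise ValueError("channel_std must be strictly positive")
        if self.magnification_factor not in (1, 2, 4):
            raise ValueError("magnification_factor must be 1, 2 or 4")


def parse_annotation_xml(path: str | Path) -> ROIAnnotation:
    """Parse an ImageScope-dialect annotation XML into polygon rings.

    One ring per Region, vertices in document order; regions with fewer than
    3 vertices are skipped with a warning.  An annotation with no usable
    region is an error.
    """
    path = Path(path)
    tree = etree.parse(str(path))
    root = tree.getroot()
    slide_id = root.get("SlideId") or path.stem
    mpp = float(root.get("MicronsPerPixel") or 0.5)
    polygons = []
    for region in root.iter("Region"):
        verts = [
            (float(v.get("X")), float(v.get("Y"))) for v in region.iter("Vertex")
        ]
        if len(verts) < 3:
            warnings.warn(
                f"{path.name}: region with {len(verts)} vertices skipped",
                stacklevel=2,
            )
            continue
        polygons.append(np.asarray(verts, dtype=float))
    if not polygons:
        raise ValueError(f"{path}: no region with >= 3 vertices")
    return ROIAnnotation(slide_id=slide_id, polygons=polygons, mpp=mpp)


def write_annotation_xml(roi: ROIAnnotation, path: str | Path) -> None:
    """Serialize an annotation back to the ImageScope XML dialect."""
    root = etree.Element(
        "Annotations", MicronsPerPixel=str(roi.mpp), SlideId=roi.slide_id
    )
    ann = etree.SubElement(root, "Annotation", Id="1")
    regions = etree.SubElement(ann, "Regions")
    for i, ring in enumerate(roi.polygons, start=1):
        region = etree.SubElement(regions, "Region", Id=str(i))
        verts = etree.SubElement(region, "Vertices")
        for x, y in ring:
            etree.SubElement(verts, "Vertex", X=repr(float(x)), Y=repr(float(y)))
    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )


def compute_overlap_fraction(patch: PatchRef, roi: ROIAnnotation) -> float:
    """Fraction of the patch square covered by the ROI polygon union."""
    x0, y0 = patch.origin
    square = box(x0, y0, x0 + patch.size, y0 + patch.size)
    inter = roi.union().intersection(square)
    return float(inter.area / square.area)


def tile_slide(
    roi: ROIAnnotation,
    slide_extent: tuple[int, int],
    patch_size: int = PATCH_SIZE,
    min_overlap: float = MIN_OVERLAP,
) -> list[PatchRef]:
    """Grid-tile the slide and keep patches with overlap strictly above threshold.

    The grid is anchored at (0,0) with stride = patch_size (patches do not
    overlap each other).  Only grid cells intersecting the ROI bounding box
    are evaluated.
    """
    width, height = slide_extent
    if width <= 0 or height <= 0:
        raise ValueError("slide extent must be positive")
    if not 0 < min_overlap <= 1:
        raise ValueError("min_overlap must be in (0,1]")
    union = roi.union()
    minx, miny, maxx, maxy = union.bounds
    if minx < 0 or miny < 0 or maxx > width or maxy > height:
        raise ValueError("ROI extends outside the slide extent")
    gx0, gy0 = int(minx // patch_size), int(miny // patch_size)
    gx1 = int(np.ceil(maxx / patch_size))
    gy1 = int(np.ceil(maxy / patch_size))
    out = []
    for gy in range(gy0, gy1):
        for gx in range(gx0, gx1):
            ref = PatchRef(
                slide_id=roi.slide_id,
                grid_x=gx,
                grid_y=gy,
                origin=(gx * patch_size, gy * patch_size),
                size=patch_size,
            )
            frac = compute_overlap_fraction(ref, roi)
            if frac > min_overlap:
                ref.overlap = frac
                out.append(ref)
    return out


def _random_affine(rng: np.random.Generator, size: int) -> np.ndarray:
    """Mild center-invariant affine: rotation +-10 deg, shear +-5 deg, scale 0.9-1.1."""
    theta = np.deg2rad(rng.uniform(-10, 10))
    shear = np.deg2rad(rng.uniform(-5, 5))
    scale = rng.uniform(0.9, 1.1)
    rot = np.array(
        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    )
    shr = np.array([[1.0, np.tan(shear)], [0.0, 1.0]])
    return scale * rot @ shr


def preprocess_patch(
    pixels: np.ndarray,
    cfg: PreprocessConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Augment (optional), center-crop, and z-score one patch.

    Input is an 8-bit HxWx3 tile (512x512 at full scale; any square size is
    accepted so reduced-scale synthetic tiles flow through the same path).
    Output pixel (0,0) of an unaugmented crop maps to input pixel
    ((H-crop)/2, (W-crop)/2) — (144,144) for 512 -> 224.
    """
    pixels = np.asarray(pixels)
    if pixels.ndim != 3 or pixels.shape[2] != 3 or pixels.shape[0] != pixels.shape[1]:
        raise ValueError(f"expected square HxWx3 patch, got {pixels.shape}")
    img = pixels.astype(float)

    if cfg.magnification_factor > 1:
        f = cfg.magnification_factor
        h = (img.shape[0] // f) * f
        img = img[:h, :h].reshape(h // f, f, h // f, f, 3).mean(axis=(1, 3))

    if cfg.augment:
        if rng is None:
            rng = np.random.default_rng()
        if rng.random() < cfg.flip_prob:
            img = img[:, ::-1, :]
        if cfg.affine:
            mat = _random_affine(rng, img.shape[0])
            center = (np.array(img.shape[:2]) - 1) / 2
            inv = np.linalg.inv(mat)
            offset = center - inv @ center
            img = np.stack(
                [
                    ndimage.affine_transform(
                        img[..., c], inv, offset=offset, order=1, mode="reflect"
                    )
                    for c in range(3)
                ],
                axis=-1,
            )

    crop = min(cfg.crop_size, img.shape[0])
    start = (img.shape[0] - crop) // 2
    img = img[start : start + crop, start : start + crop]
    return (img - cfg.channel_mean) / cfg.channel_std


def channel_statistics(patches) -> tuple[np.ndarray, np.ndarray]:
    """Dataset-level per-channel mean and std over an iterable of HxWx3 tiles."""
    s = np.zeros(3)
    ss = np.zeros(3)
    n = 0
    for p in patches:
        p = np.asarray(p, dtype=float)
        s += p.sum(axis=(0, 1))
        ss += (p**2).sum(axis=(0, 1))
        n += p.shape[0] * p.shape[1]
    mean = s / n
    std = np.sqrt(np.maximum(ss / n - mean**2, 1e-12))
    return mean, std


def patch_index_frame(refs: list[PatchRef]):
    """Patch-index table (slide_id, grid_x, grid_y, origin_x, origin_y, overlap)."""
    import pandas as pd

    return pd.DataFrame(
        [
            (r.slide_id, r.grid_x, r.grid_y, r.origin[0], r.origin[1], r.overlap)
            for r in refs
        ],
        columns=["slide_id", "grid_x", "grid_y", "origin_x", "origin_y", "overlap"],
    )
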