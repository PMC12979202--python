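"""Z-stack single-cell extraction: detection grouping, focus selection, crops.

Optical sections of a thick cytology slide are scanned at several focal
depths; a 2D nucleus detector run per layer therefore reports the same
nucleus on multiple neighbouring layers.  This module

* merges per-layer detections into 3D nucleus instances by single-linkage
  connectivity (lateral distance within a tolerance, layer difference within
  a gap), giving each instance a score-weighted representative centre and a
  Z range;
* scores per-layer sharpness (variance of Laplacian by default, Tenengrad
  optionally) on a window around the instance centre and selects the
  best-focus layer;
* crops a nucleus-centred patch (default 224 x 224) from the chosen layer
  with reflection padding at image borders.

Coordinates are 0-based with x = column, y = row, half-open pixel intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "DetectionBox",
    "NucleusInstance",
    "ImageStack",
    "group_detections",
    "focus_score",
    "select_focus_layer",
    "crop_patch",
    "make_blurred_stack",
    "extract_cells",
    "read_detections",
    "write_detections",
]

PATCH_SIZE = 224

#: Detection-resolution to full-resolution scale (1,024 px maps onto 4,480).
DETECTION_SCALE = 4480 / 1024


@dataclass(frozen=True)
class DetectionBox:
    """One per-layer nucleus detection at detection resolution."""

    x: float
    y: float
    width: float
    height: float
    z: int
    score: float = 1.0

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ValueError("detection box width and height must be positive")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"detection score must lie in [0, 1], got {self.score}")

    @property
    def diagonal(self) -> float:
        return float(np.hypot(self.width, self.height))


@dataclass
class NucleusInstance:
    """A grouped 3D nucleus: member detections plus derived geometry."""

    members: list[DetectionBox]
    centre: tuple[float, float]
    z_min: int
    z_max: int
    best_layer: int | None = None
    focus_scores: dict[int, float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.members:
            raise ValueError("an instance needs at least one member detection")
        if self.z_min > self.z_max:
            raise ValueError("z_min must not exceed z_max")
        for det in self.members:
            if not self.z_min <= det.z <= self.z_max:
                raise ValueError("member layer outside the instance z range")


@dataclass
class ImageStack:
    """A small image volume: layers x rows x cols intensities."""

    data: np.ndarray
    pixel_size_um: float = 0.22
    layer_spacing_um: float = 1.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[0] < 1:
            raise ValueError("stack must be a 3D array with at least one layer")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("stack intensities must be finite")

    @property
    def n_layers(self) -> int:
        return self.data.shape[0]


def group_detections(
    detections: list[DetectionBox],
    lateral_tolerance: float | None = None,
    max_layer_gap: int = 0,
) -> list[NucleusInstance]:
    """Merge per-layer detections into nucleus instances by single linkage.

    Two detections are directly linked when their centre distance is at most
    ``lateral_tolerance`` and their layer indices differ by at most
    ``max_layer_gap + 1``; instances are the connected components of that
    relation, so every detection belongs to exactly one instance.  The
    tolerance defaults to half the mean box diagonal.  The representative
    centre is the detection-score-weighted mean of member centres.
    """
    if max_layer_gap < 0:
        raise ValueError("max_layer_gap must be >= 0")
    if not detections:
        return []
    if lateral_tolerance is None:
        lateral_tolerance = 0.5 * float(np.mean([d.diagonal for d in detections]))
    if lateral_tolerance <= 0:
        raise ValueError("lateral_tolerance must be positive")

    xy = np.array([(d.x, d.y) for d in detections])
    z = np.array([d.z for d in detections])
    parent = np.arange(len(detections))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    tree = cKDTree(xy)
    for i, j in tree.query_pairs(lateral_tolerance):
        if abs(int(z[i]) - int(z[j])) <= max_layer_gap + 1:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj

    groups: dict[int, list[int]] = {}
    for i in range(len(detections)):
        groups.setdefault(find(i), []).append(i)

    instances = []
    for idx in groups.values():
        members = [detections[i] for i in idx]
        w = np.array([d.score for d in members])
        if w.sum() == 0:
            w = np.ones_like(w)
        cx = float(np.average([d.x for d in members], weights=w))
        cy = float(np.average([d.y for d in members], weights=w))
        zs = [d.z for d in members]
        instances.append(
            NucleusInstance(members=members, centre=(cx, cy), z_min=min(zs), z_max=max(zs))
        )
    # deterministic output order: by first-member appearance in the input
    order = {id(d): i for i, d in enumerate(detections)}
    instances.sort(key=lambda inst: min(order[id(m)] for m in inst.members))
    return instances


def focus_score(tile: np.ndarray, metric: str = "laplacian") -> float:
    """Sharpness of an image tile; 0 for a constant tile.

    ``laplacian`` is the variance of the discrete Laplacian (default);
    ``tenengrad`` is the mean squared Sobel gradient magnitude.  Both are
    invariant to an additive intensity offset and strictly decrease when a
    textured tile is Gaussian-blurred.
    """
    tile = np.asarray(tile, dtype=float)
    if tile.size == 0:
        raise ValueError("tile is empty")
    if metric == "laplacian":
        lap = ndimage.laplace(tile)
        return float(lap.var())
    if metric == "tenengrad":
        gx = ndimage.sobel(tile, axis=1)
        gy = ndimage.sobel(tile, axis=0)
        return float(np.mean(gx**2 + gy**2))
    raise ValueError(f"unknown focus metric {metric!r}")


def crop_patch(
    stack: ImageStack | np.ndarray,
    centre: tuple[float, float],
    layer: int = 0,
    size: int = PATCH_SIZE,
) -> np.ndarray:
    """Crop a ``size x size`` patch centred on ``centre`` from one layer.

    ``centre`` is (x, y) in 0-based pixel coordinates; the centre pixel maps
    to output index ``(size // 2, size // 2)``.  Regions beyond the image
    border are filled by reflection padding.
    """
    if size <= 0:
        raise ValueError("patch size must be positive")
    if isinstance(stack, ImageStack):
        if not 0 <= layer < stack.n_layers:
            raise IndexError(f"layer {layer} outside stack depth {stack.n_layers}")
        image = stack.data[layer]
    else:
        image = np.asarray(stack, dtype=float)
    cx, cy = int(round(centre[0])), int(round(centre[1]))
    half = size // 2
    pad = size  # generous; reflection handles any in-bounds centre
    padded = np.pad(image, pad, mode="reflect")
    r0 = cy - half + pad
    c0 = cx - half + pad
    return padded[r0 : r0 + size, c0 : c0 + size].copy()


def select_focus_layer(
    stack: ImageStack,
    instance: NucleusInstance,
    window: int = PATCH_SIZE,
    metric: str = "laplacian",
) -> int:
    """Best-focus layer inside the instance's Z range.

    Scores a ``window``-sized tile around the representative centre on every
    layer of the range; returns the argmax.  Ties go to the layer nearest
    the Z-range midpoint, then to the lower index.  The focus scores are
    recorded on the instance.
    """
    if not (0 <= instance.z_min and instance.z_max < stack.n_layers):
        raise IndexError("instance z range outside stack depth")
    rows, cols = stack.data.shape[1:]
    cx, cy = instance.centre
    if not (-window / 2 < cx < cols + window / 2 and -window / 2 < cy < rows + window / 2):
        raise ValueError("focus window lies fully outside image bounds")
    scores = {
        z: focus_score(crop_patch(stack, instance.centre, z, window), metric)
        for z in range(instance.z_min, instance.z_max + 1)
    }
    best = max(scores.values())
    mid = (instance.z_min + instance.z_max) / 2.0
    candidates = [z for z, s in scores.items() if s == best]
    candidates.sort(key=lambda z: (abs(z - mid), z))
    instance.focus_scores = scores
    instance.best_layer = candidates[0]
    return instance.best_layer


def make_blurred_stack(
    n_layers: int,
    focus_layer: int,
    seed: int = 0,
    shape: tuple[int, int] = (96, 96),
    blur_per_layer: float = 0.8,
    base_sigma: float = 1.0,
) -> ImageStack:
    """Synthetic textured stack whose blur grows away from ``focus_layer``.

    Layer ``z`` is the same random texture smoothed with a Gaussian of
    ``sigma = base_sigma * blur_per_layer * |z - focus_layer|`` (the focus
    layer itself is left sharp).  Deterministic given the seed.
    """
    if not 0 <= focus_layer < n_layers:
        raise ValueError("focus_layer must lie within [0, n_layers)")
    rng = np.random.default_rng(seed)
    texture = rng.uniform(0.0, 1.0, shape)
    layers = []
    for z in range(n_layers):
        sigma = base_sigma * blur_per_layer * abs(z - focus_layer)
        layers.append(texture if sigma == 0 else ndimage.gaussian_filter(texture, sigma))
    return ImageStack(np.stack(layers))


def extract_cells(
    stack: ImageStack,
    detections: list[DetectionBox],
    lateral_tolerance: float | None = None,
    max_layer_gap: int = 0,
    size: int = PATCH_SIZE,
    metric: str = "laplacian",
) -> list[tuple[NucleusInstance, np.ndarray]]:
    """Full extraction: group, pick best focus, crop a nucleus-centred patch."""
    out = []
    for inst in group_detections(detections, lateral_tolerance, max_layer_gap):
        layer = select_focus_layer(stack, inst, window=size, metric=metric)
        out.append((inst, crop_patch(stack, inst.centre, layer, size)))
    return out


DETECTION_COLUMNS = ["slide_id", "x", "y", "w", "h", "z", "score"]


def write_detections(path, detections: list[DetectionBox], slide_id: str = "slide") -> None:
    """Write detections as delimited text (slide id, x, y, w, h, z, score)."""
    pd.DataFrame(
        [
            {"slide_id": slide_id, "x": d.x, "y": d.y, "w": d.width, "h": d.height,
             "z": d.z, "score": d.score}
            for d in detections
        ],
        columns=DETECTION_COLUMNS,
    ).to_csv(path, index=False)


def read_detections(path) -> list[DetectionBox]:
    """Read a detection table written by :func:`write_detections`."""
    df = pd.read_csv(path)
    missing = set(DETECTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"detection table missing columns: {sorted(missing)}")
    return [
        DetectionBox(x=r.x, y=r.y, width=r.w, height=r.h, z=int(r.z), score=r.score)
        for r in df.itertuples()
    ]
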