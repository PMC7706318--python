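"""Learning-target codec: dots -> density -> patch counts -> count-interval classes,
and the decode path classes -> counts -> pixel count map -> total.

The encode direction turns a dot annotation (one point per plant root) into a
grid of count-interval class indices over overlapping image patches; the decode
direction maps predicted classes back to representative counts and averages the
overlapping patch predictions into a pixel-resolution count map whose sum is
the estimated number of plants.

Count intervals are log-spaced: a patch count ``n > 0`` falls in class
``max(floor((ln n - q) / s) + 2, 1)``, so class 0 is reserved for exactly-empty
patches and class 1 for counts in ``(0, e^q)``. Decoding uses the interval
midpoint as the representative count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DotAnnotation",
    "DensityConfig",
    "PatchGrid",
    "CountMap",
    "QuantizerSpec",
    "ClassMap",
    "PixelCountMap",
    "rasterize_dots",
    "density_from_dots",
    "count_map_from_density",
    "quantize_count",
    "class_map_from_count_map",
    "class_count_value",
    "dequantize_class_map",
    "deredundancy",
    "total_count",
]


@dataclass
class DotAnnotation:
    """Per-image list of plant-root points.

    Points are ``(x, y)`` pixel coordinates, 0-based, origin at the top-left
    corner, ``x`` indexing columns and ``y`` rows. Floats are allowed; the
    list may be empty.
    """

    image_id: str
    points: list[tuple[float, float]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.points)

    def scaled(self, ratio: float) -> "DotAnnotation":
        """Annotation with every coordinate multiplied by ``ratio``."""
        return DotAnnotation(self.image_id, [(x * ratio, y * ratio) for x, y in self.points])


@dataclass(frozen=True)
class DensityConfig:
    """Gaussian smoothing parameters for density-map generation.

    ``sigma`` is the kernel standard deviation in pixels; ``truncation_radius``
    is the kernel support half-width (defaults to ``3 * sigma``). Each dot's
    kernel is renormalized after truncation and border clipping so that every
    dot contributes exactly unit mass.
    """

    sigma: float = 4.0
    truncation_radius: float | None = None

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if self.truncation_radius is not None and self.truncation_radius < 2 * self.sigma:
            raise ValueError("truncation_radius must be >= 2*sigma")

    @property
    def radius(self) -> int:
        r = self.truncation_radius if self.truncation_radius is not None else 3.0 * self.sigma
        return int(np.ceil(r))


@dataclass(frozen=True)
class PatchGrid:
    """Layout of (possibly overlapping) square patches over an image.

    Patches of side ``block`` are placed at offsets 0, stride, 2*stride, ...
    along each axis; only patches fully contained in the image are kept.
    """

    block: int
    stride: int
    image_shape: tuple[int, int]

    def __post_init__(self):
        if not (self.block >= self.stride >= 1):
            raise ValueError(f"need block >= stride >= 1, got block={self.block}, stride={self.stride}")
        h, w = self.image_shape
        if h < self.block or w < self.block:
            raise ValueError(
                f"image {self.image_shape} smaller than block; needs at least "
                f"({self.block}, {self.block})"
            )

    @property
    def n_patches(self) -> tuple[int, int]:
        h, w = self.image_shape
        return ((h - self.block) // self.stride + 1, (w - self.block) // self.stride + 1)

    @property
    def pixels_per_patch(self) -> int:
        return self.block * self.block

    def coverage(self) -> np.ndarray:
        """Integer grid T(x, y): number of patches covering each pixel."""
        cov = np.zeros(self.image_shape, dtype=np.int64)
        nr, nc = self.n_patches
        # 1-D coverage profiles are enough: coverage is separable.
        row = np.zeros(self.image_shape[0], dtype=np.int64)
        for i in range(nr):
            row[i * self.stride : i * self.stride + self.block] += 1
        col = np.zeros(self.image_shape[1], dtype=np.int64)
        for j in range(nc):
            col[j * self.stride : j * self.stride + self.block] += 1
        cov[:] = np.outer(row, col)
        return cov


@dataclass(frozen=True)
class QuantizerSpec:
    """Log-space count quantizer: step ``s``, start ``q``, top class ``c_max``.

    Class 0 holds exactly-zero patches and class 1 counts in ``(0, e^q)``;
    class ``c >= 2`` holds counts in ``[e^{q+(c-2)s}, e^{q+(c-1)s})``, with the
    top interval capped at ``c_max``.
    """

    s: float = 0.1
    q: float = -2.0
    c_max: int = 64

    def __post_init__(self):
        if self.s <= 0:
            raise ValueError(f"quantization step s must be > 0, got {self.s}")
        if self.c_max < 2:
            raise ValueError(f"c_max must be >= 2, got {self.c_max}")

    @property
    def n_classes(self) -> int:
        return self.c_max + 1

    @classmethod
    def for_max_count(cls, max_count: float, s: float = 0.1, q: float = -2.0) -> "QuantizerSpec":
        """Spec whose top class exceeds the largest training patch count.

        ``c_max`` is set to the class of ``max_count`` plus one, so the capped
        interval is never hit by in-distribution targets.
        """
        probe = cls(s=s, q=q, c_max=2**31 - 1)
        c = int(quantize_count(float(max_count), probe)) if max_count > 0 else 1
        return cls(s=s, q=q, c_max=max(c + 1, 2))

    def boundary(self, c: int | np.ndarray) -> float | np.ndarray:
        """Lower interval boundary Nt(c): 0 for c <= 1, else e^{q+(c-2)s}."""
        c = np.asarray(c)
        out = np.where(c <= 1, 0.0, np.exp(self.q + (c - 2) * self.s))
        return float(out) if out.ndim == 0 else out


@dataclass
class CountMap:
    """Per-patch object counts N(b_j) on a PatchGrid (row-major patch order)."""

    values: np.ndarray
    grid: PatchGrid

    def __post_init__(self):
        expect = self.grid.n_patches
        if self.values.shape != expect:
            raise ValueError(f"count map shape {self.values.shape} != grid {expect}")


@dataclass
class ClassMap:
    """Per-patch count-interval class indices C(b_j) in [0, c_max]."""

    values: np.ndarray
    grid: PatchGrid
    spec: QuantizerSpec

    def __post_init__(self):
        if self.values.min(initial=0) < 0 or self.values.max(initial=0) > self.spec.c_max:
            raise ValueError("class indices outside [0, c_max]")


@dataclass
class PixelCountMap:
    """Decoded pixel-resolution count map D^o; sums to the estimated total."""

    values: np.ndarray

    def total(self) -> float:
        return float(self.values.sum())


def rasterize_dots(
    annotation: DotAnnotation, shape: tuple[int, int], scale: float = 1.0
) -> np.ndarray:
    """Rasterize dot annotations into an integer-valued grid.

    Each point is scaled by ``scale``, rounded to the nearest pixel and
    accumulated, so several points falling on one pixel keep their
    multiplicity and the grid sum always equals the number of dots. Points
    that round outside the grid are clamped to the nearest border pixel (a
    warning is logged).
    """
    rows, cols = shape
    if rows <= 0 or cols <= 0:
        raise ValueError(f"shape must be positive, got {shape}")
    if scale <= 0:
        raise ValueError(f"scale must be > 0, got {scale}")
    grid = np.zeros(shape, dtype=np.float64)
    for x, y in annotation.points:
        if x < 0 or y < 0:
            raise ValueError(f"negative coordinate ({x}, {y}) in '{annotation.image_id}'")
        r = int(round(y * scale))
        c = int(round(x * scale))
        if not (0 <= r < rows and 0 <= c < cols):
            logger.warning(
                "dot (%.2f, %.2f) of '%s' rounds outside %s; clamped", x, y, annotation.image_id, shape
            )
            r = min(max(r, 0), rows - 1)
            c = min(max(c, 0), cols - 1)
        grid[r, c] += 1.0
    return grid


def _gaussian_kernel(sigma: float, radius: int) -> np.ndarray:
    ax = np.arange(-radius, radius + 1, dtype=np.float64)
    g = np.exp(-(ax**2) / (2.0 * sigma**2))
    return np.outer(g, g)


def density_from_dots(dot_grid: np.ndarray, cfg: DensityConfig = DensityConfig()) -> np.ndarray:
    """Gaussian-smoothed density map whose sum equals the number of dots.

    Each dot is replaced by a truncated 2-D Gaussian of std-dev ``cfg.sigma``.
    The kernel is renormalized per dot over its truncated, border-clipped
    support, so mass is conserved exactly even for dots at image corners.
    """
    dot_grid = np.asarray(dot_grid, dtype=np.float64)
    if np.any(dot_grid < 0):
        raise ValueError("dot grid must be nonnegative")
    rows, cols = dot_grid.shape
    r = cfg.radius
    kernel = _gaussian_kernel(cfg.sigma, r)
    density = np.zeros_like(dot_grid)
    for i, j in zip(*np.nonzero(dot_grid)):
        top, bot = max(0, i - r), min(rows, i + r + 1)
        left, right = max(0, j - r), min(cols, j + r + 1)
        kwin = kernel[top - (i - r) : bot - (i - r), left - (j - r) : right - (j - r)]
        density[top:bot, left:right] += dot_grid[i, j] * kwin / kwin.sum()
    return density


def count_map_from_density(density: np.ndarray, block: int, stride: int) -> CountMap:
    """Blockwise summation of the density map over a (block, stride) grid.

    Patches are placed at offsets 0, stride, 2*stride, ... and only fully
    contained patches are emitted (no padding). Implemented with a summed-area
    table, so overlapping grids cost the same as disjoint ones.
    """
    density = np.asarray(density, dtype=np.float64)
    grid = PatchGrid(block=block, stride=stride, image_shape=density.shape)
    # summed-area table with a zero border row/col
    sat = np.zeros((density.shape[0] + 1, density.shape[1] + 1), dtype=np.float64)
    np.cumsum(np.cumsum(density, axis=0), axis=1, out=sat[1:, 1:])
    nr, nc = grid.n_patches
    r0 = np.arange(nr) * stride
    c0 = np.arange(nc) * stride
    vals = (
        sat[np.ix_(r0 + block, c0 + block)]
        - sat[np.ix_(r0, c0 + block)]
        - sat[np.ix_(r0 + block, c0)]
        + sat[np.ix_(r0, c0)]
    )
    # cumulative sums can leave tiny negative residue on empty patches
    np.clip(vals, 0.0, None, out=vals)
    return CountMap(values=vals, grid=grid)


def quantize_count(n, spec: QuantizerSpec):
    """Map a patch count to its count-interval class index.

    Zero counts map to class 0; positive counts to
    ``max(floor((ln n - q)/s) + 2, 1)`` capped at ``c_max``. Accepts scalars
    or arrays.
    """
    arr = np.asarray(n, dtype=np.float64)
    if np.any(arr < 0):
        raise ValueError("counts must be nonnegative")
    pos = arr > 0
    cls = np.zeros(arr.shape, dtype=np.int64)
    with np.errstate(divide="ignore"):
        c = np.floor((np.log(arr, where=pos, out=np.full(arr.shape, -np.inf)) - spec.q) / spec.s) + 2
    cls[pos] = np.clip(c[pos], 1, spec.c_max).astype(np.int64)
    return int(cls) if np.isscalar(n) or np.ndim(n) == 0 else cls


def class_map_from_count_map(counts: CountMap, spec: QuantizerSpec) -> ClassMap:
    """Elementwise quantization of a CountMap into a ClassMap."""
    return ClassMap(values=quantize_count(counts.values, spec), grid=counts.grid, spec=spec)


def class_count_value(c, spec: QuantizerSpec):
    """Representative count for a class: the midpoint of its interval.

    Class 0 decodes to 0; class ``c >= 1`` decodes to
    ``(Nt(c) + Nt(c+1)) / 2`` where Nt is the lower interval boundary.
    Accepts scalars or arrays.
    """
    arr = np.asarray(c)
    if np.any(arr < 0) or np.any(arr > spec.c_max):
        raise ValueError(f"class index outside [0, {spec.c_max}]")
    val = np.where(arr == 0, 0.0, (spec.boundary(arr) + spec.boundary(arr + 1)) / 2.0)
    return float(val) if val.ndim == 0 else val


def dequantize_class_map(classes: ClassMap) -> CountMap:
    """Elementwise inverse quantization of a ClassMap into a CountMap."""
    return CountMap(values=class_count_value(classes.values, classes.spec), grid=classes.grid)


def deredundancy(counts: CountMap) -> PixelCountMap:
    """Average overlapping patch counts down to a pixel-resolution count map.

    Each patch spreads its count evenly over its pixels (``N(b_j) / n_b``);
    every pixel then averages the contributions of the patches covering it,
    dividing by the coverage count T(x, y). Pixels covered by no patch (the
    right/bottom margin when dimensions do not align with the grid) are 0.
    """
    if counts.values.size == 0:
        raise ValueError("empty count map")
    g = counts.grid
    acc = np.zeros(g.image_shape, dtype=np.float64)
    per_pixel = counts.values / g.pixels_per_patch
    nr, nc = g.n_patches
    for i in range(nr):
        r0 = i * g.stride
        for j in range(nc):
            c0 = j * g.stride
            acc[r0 : r0 + g.block, c0 : c0 + g.block] += per_pixel[i, j]
    cov = g.coverage()
    out = np.divide(acc, cov, out=np.zeros_like(acc), where=cov > 0)
    return PixelCountMap(values=out)


def total_count(m: PixelCountMap | CountMap) -> float:
    """Total object count of a decoded map.

    For a CountMap this is only meaningful when patches do not overlap
    (stride == block); overlapping maps must go through ``deredundancy``
    first, and asking for their raw sum is an error.
    """
    if isinstance(m, PixelCountMap):
        return m.total()
    if isinstance(m, CountMap):
        if m.grid.stride != m.grid.block:
            raise ValueError(
                "count map has overlapping patches (stride < block); "
                "decode with deredundancy() before totaling"
            )
        return float(m.values.sum())
    raise TypeError(f"expected CountMap or PixelCountMap, got {type(m).__name__}")
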