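"""Seeded generator of rice-paddy-like dotted scenes.

Every scene is a flooded-field background (greenish-brown base, water-glint
speckle, a linear illumination gradient) with plants rendered as radial
clusters of curved leaf strokes. The cluster center is the annotated root
dot, matching the one-point-per-plant annotation convention, so ground truth
is unambiguous by construction. Plants are placed on a jittered row grid with
a minimum-separation constraint; the ``overlap_fraction`` knob relaxes that
constraint and widens the jitter, producing progressively more entangled
canopies. Rendering is fully determined by the spec's seed.

The generator emulates the statistics of early-season (transplantation to
tillering) paddy imagery at working resolution — plant footprints of roughly
20-75 px and per-image counts in the hundreds for field-sized frames — not
its photometric realism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .codec import DotAnnotation

__all__ = ["SceneSpec", "SyntheticScene", "render_scene", "generate_dataset"]


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic paddy scene.

    ``n_plants`` may be an int or an inclusive ``(lo, hi)`` range sampled per
    scene. ``plant_radius`` is the per-plant footprint radius range in pixels
    (default 10-38 px, i.e. 20-75 px diameters at working resolution).
    ``overlap_fraction`` in [0, 1] shrinks the enforced minimum plant
    separation and widens placement jitter; ``illumination_gradient`` and
    ``reflection_noise`` are amplitudes in [0, 1]. ``border_margin`` keeps
    root dots away from the frame edge so every plant's density mass lies in
    the uniformly-covered interior of the redundant patch grid, where the
    spread-then-average decode is exactly mass-conserving (it is clipped to a
    quarter of the scene side for small scenes).
    """

    size: tuple[int, int] = (512, 512)
    n_plants: int | tuple[int, int] = (100, 400)
    plant_radius: tuple[float, float] = (10.0, 38.0)
    row_spacing: float = 32.0
    illumination_gradient: float = 0.25
    reflection_noise: float = 0.15
    overlap_fraction: float = 0.3
    border_margin: float = 48.0
    seed: int = 0

    def __post_init__(self):
        if min(self.size) < 64:
            raise ValueError(f"scene size must be >= 64 px per side, got {self.size}")
        if self.plant_radius[0] <= 0:
            raise ValueError("plant radii must be positive")
        n = self.n_plants
        if (n if isinstance(n, int) else min(n)) < 0:
            raise ValueError("n_plants must be >= 0")


@dataclass
class SyntheticScene:
    image: np.ndarray  # (rows, cols, 3) float32 in [0, 1]
    annotation: DotAnnotation
    spec: SceneSpec


def _place_plants(spec: SceneSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Jittered row-grid placement with a minimum-separation constraint.

    Returns an (n, 2) array of (x, y) centers. Raises if ``n`` plants cannot
    be seated at the implied separation.
    """
    if n == 0:
        return np.zeros((0, 2))
    rows_px, cols_px = spec.size
    margin = min(spec.border_margin, min(rows_px, cols_px) / 4)
    usable_h, usable_w = rows_px - 2 * margin, cols_px - 2 * margin
    # row grid at the requested spacing, densified until it can seat n plants
    n_cols = max(1, int(usable_w // spec.row_spacing))
    n_rows = max(1, int(usable_h // spec.row_spacing))
    while n_rows * n_cols < n:
        if usable_h / (n_rows + 1) >= usable_w / (n_cols + 1):
            n_rows += 1
        else:
            n_cols += 1
    pitch_y, pitch_x = usable_h / n_rows, usable_w / n_cols
    pitch = min(pitch_x, pitch_y)
    if pitch < 3.0:
        raise ValueError(
            f"cannot place {n} plants in {spec.size} at a workable separation; "
            f"reduce n_plants or enlarge the scene"
        )
    d_min = (1.0 - spec.overlap_fraction) * pitch * 0.7
    jitter = pitch * (0.3 + 0.5 * spec.overlap_fraction)
    cells = rng.choice(n_rows * n_cols, size=n, replace=False)
    cy = margin + (cells // n_cols + 0.5) * pitch_y
    cx = margin + (cells % n_cols + 0.5) * pitch_x
    pts = np.stack([cx, cy], axis=1)
    for _ in range(20):
        pts_j = pts + rng.uniform(-jitter, jitter, size=pts.shape)
        np.clip(pts_j[:, 0], margin, cols_px - 1 - margin, out=pts_j[:, 0])
        np.clip(pts_j[:, 1], margin, rows_px - 1 - margin, out=pts_j[:, 1])
        d2 = np.sum((pts_j[:, None, :] - pts_j[None, :, :]) ** 2, axis=-1)
        np.fill_diagonal(d2, np.inf)
        if d2.min() >= d_min**2:
            return pts_j
    # fall back to the un-jittered grid cells, which always satisfy d_min
    return pts


def _draw_plant(img: np.ndarray, cx: float, cy: float, radius: float, rng: np.random.Generator):
    """Radial cluster of 4-9 curved strokes centered at the root dot."""
    rows_px, cols_px = img.shape[:2]
    n_strokes = rng.integers(4, 10)
    base = np.array([0.16, 0.45, 0.18]) + rng.uniform(-0.04, 0.04, 3)
    for _ in range(n_strokes):
        theta = rng.uniform(0, 2 * np.pi)
        length = radius * rng.uniform(0.6, 1.0)
        curve = rng.uniform(-0.8, 0.8)
        shade = rng.uniform(0.75, 1.2)
        t = np.linspace(0.0, 1.0, max(4, int(2 * length)))
        ang = theta + curve * t**2
        xs = cx + length * t * np.cos(ang)
        ys = cy + length * t * np.sin(ang)
        # leaf tapers from ~2 px at the base to 1 px at the tip
        for dx, dy in ((0, 0), (1, 0), (0, 1)):
            keep = t < (0.35 if (dx or dy) else 1.0)
            c = np.clip(np.round(xs[keep] + dx), 0, cols_px - 1).astype(int)
            r = np.clip(np.round(ys[keep] + dy), 0, rows_px - 1).astype(int)
            img[r, c] = shade * base * (1.0 - 0.35 * t[keep, None])


def render_scene(spec: SceneSpec) -> SyntheticScene:
    """Render one seeded scene with its dot annotation."""
    rng = np.random.default_rng(spec.seed)
    rows_px, cols_px = spec.size
    n = (
        spec.n_plants
        if isinstance(spec.n_plants, int)
        else int(rng.integers(spec.n_plants[0], spec.n_plants[1] + 1))
    )
    # background: muddy water base + illumination ramp + glint speckle
    img = np.empty((rows_px, cols_px, 3), dtype=np.float64)
    img[..., 0] = 0.32
    img[..., 1] = 0.34
    img[..., 2] = 0.26
    phi = rng.uniform(0, 2 * np.pi)
    yy, xx = np.mgrid[0:rows_px, 0:cols_px]
    ramp = (np.cos(phi) * xx / cols_px + np.sin(phi) * yy / rows_px)
    img += spec.illumination_gradient * 0.5 * ramp[..., None]
    img += 0.35 * spec.reflection_noise * rng.standard_normal((rows_px, cols_px, 1))
    n_glints = int(spec.reflection_noise * rows_px * cols_px / 400)
    if n_glints:
        gr = rng.integers(1, rows_px - 1, n_glints)
        gc = rng.integers(1, cols_px - 1, n_glints)
        img[gr, gc] += rng.uniform(0.2, 0.6, n_glints)[:, None]

    centers = _place_plants(spec, n, rng)
    radii = rng.uniform(spec.plant_radius[0], spec.plant_radius[1], size=len(centers))
    for (cx, cy), r in zip(centers, radii):
        _draw_plant(img, cx, cy, r, rng)

    np.clip(img, 0.0, 1.0, out=img)
    ann = DotAnnotation(
        image_id=f"scene_{spec.seed:08d}",
        points=[(float(x), float(y)) for x, y in centers],
    )
    return SyntheticScene(image=img.astype(np.float32), annotation=ann, spec=spec)


def generate_dataset(
    n_scenes: int, template: SceneSpec, seed: int, out_dir: str | Path
) -> list[Path]:
    """Write ``n_scenes`` PNG images plus ``ann.csv`` and ``manifest.json``.

    Per-scene seeds are derived from ``seed`` through a SeedSequence, so the
    dataset is reproducible from (template, seed) alone. The annotation CSV
    uses the ``image,x,y`` dialect read by :func:`paddycount.dataio.load_annotations`.
    """
    from PIL import Image
    import pandas as pd

    if n_scenes < 1:
        raise ValueError("n_scenes must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    child_seeds = np.random.SeedSequence(seed).generate_state(n_scenes) % (2**31)
    rows = []
    manifest = {"seed": int(seed), "n_scenes": int(n_scenes), "scenes": []}
    paths = []
    for i, s in enumerate(child_seeds):
        spec = SceneSpec(**{**asdict(template), "seed": int(s)})
        scene = render_scene(spec)
        name = f"scene_{i:04d}.png"
        Image.fromarray((scene.image * 255).round().astype(np.uint8)).save(out_dir / name)
        for x, y in scene.annotation.points:
            rows.append({"image": name, "x": x, "y": y})
        manifest["scenes"].append({"image": name, **asdict(spec), "n_dots": len(scene.annotation)})
        paths.append(out_dir / name)
    pd.DataFrame(rows, columns=["image", "x", "y"]).to_csv(out_dir / "ann.csv", index=False)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return paths
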