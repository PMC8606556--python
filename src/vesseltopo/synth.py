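"""Synthetic fundus-like images with labeled artery/vein trees.

Vessel trees are grown as biased random walks with stochastic branching and
rasterized with disk brushes, giving connected, branching, occasionally
crossing curvilinear structures on a dark background.  Everything is a
deterministic function of a single integer seed.

Label encoding (integer class ids, shared across the package):

====================  ===
background            0
artery                1
crossing / unknown    2
vein                  3
====================  ===
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

BACKGROUND, ARTERY, CROSSING, VEIN = 0, 1, 2, 3
NUM_CLASSES = 4
CLASS_NAMES = ("background", "artery", "crossing_unknown", "vein")

# Color-coded label rasters: artery=red, vein=blue, crossing=green;
# white is accepted on read as an alias for the crossing/unknown class.
_LABEL_TO_RGB = {
    BACKGROUND: (0, 0, 0),
    ARTERY: (255, 0, 0),
    CROSSING: (0, 255, 0),
    VEIN: (0, 0, 255),
}
_RGB_TO_LABEL = {v: k for k, v in _LABEL_TO_RGB.items()}
_RGB_TO_LABEL[(255, 255, 255)] = CROSSING


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic vascular image generator."""

    canvas_height: int = 128
    canvas_width: int = 128
    trees_per_class: int = 2
    branch_probability: float = 0.04
    vessel_radius_range: tuple[int, int] = (1, 2)
    color_means: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "background": (0.12, 0.05, 0.04),
            "artery": (0.85, 0.30, 0.25),
            "vein": (0.30, 0.30, 0.80),
        }
    )
    noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.canvas_height < 32 or self.canvas_width < 32:
            raise ValueError(
                f"canvas must be at least 32x32, got "
                f"{self.canvas_height}x{self.canvas_width}"
            )
        if self.trees_per_class < 1:
            raise ValueError("trees_per_class must be >= 1")
        if not 0.0 <= self.branch_probability <= 1.0:
            raise ValueError("branch_probability must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        rmin, rmax = self.vessel_radius_range
        if rmin < 1 or rmax < rmin:
            raise ValueError("vessel_radius_range must satisfy 1 <= min <= max")
        for key in ("background", "artery", "vein"):
            if key not in self.color_means:
                raise ValueError(f"color_means missing entry for {key!r}")


@dataclass
class LabeledImage:
    """RGB raster in [0, 1] plus a per-pixel 4-class label map."""

    image: np.ndarray  # (P, Q, 3) float in [0, 1]
    labels: np.ndarray  # (P, Q) int in {0, 1, 2, 3}

    def __post_init__(self) -> None:
        if self.image.shape[:2] != self.labels.shape:
            raise ValueError("image and labels must share height and width")


def _disk_offsets(radius: int) -> tuple[np.ndarray, np.ndarray]:
    """Lattice offsets (di, dj) with di^2 + dj^2 <= radius^2."""
    rng = np.arange(-radius, radius + 1)
    di, dj = np.meshgrid(rng, rng, indexing="ij")
    keep = di * di + dj * dj <= radius * radius
    return di[keep], dj[keep]


def _stamp_disk(mask: np.ndarray, r: int, c: int, radius: int) -> None:
    P, Q = mask.shape
    di, dj = _disk_offsets(radius)
    ii = di + r
    jj = dj + c
    keep = (ii >= 0) & (ii < P) & (jj >= 0) & (jj < Q)
    mask[ii[keep], jj[keep]] = True


def grow_tree(rng: np.random.Generator, config: SynthConfig) -> np.ndarray:
    """Grow one vessel tree; returns its boolean pixel mask.

    A walker starts at a margin-adjacent root heading inward and advances
    one pixel at a time with small random turns, stamping a disk brush at
    every step; with ``branch_probability`` a visited position is pushed as
    a new branch root.  Unit steps and overlapping brushes keep the union
    8-connected by construction.
    """
    P, Q = config.canvas_height, config.canvas_width
    mask = np.zeros((P, Q), dtype=bool)
    rmin, rmax = config.vessel_radius_range

    side = rng.integers(0, 4)
    if side == 0:  # top
        pos = np.array([1.0, rng.uniform(2, Q - 3)])
        angle = rng.uniform(np.pi * 0.25, np.pi * 0.75)
    elif side == 1:  # bottom
        pos = np.array([P - 2.0, rng.uniform(2, Q - 3)])
        angle = rng.uniform(-np.pi * 0.75, -np.pi * 0.25)
    elif side == 2:  # left
        pos = np.array([rng.uniform(2, P - 3), 1.0])
        angle = rng.uniform(-np.pi * 0.25, np.pi * 0.25)
    else:  # right
        pos = np.array([rng.uniform(2, P - 3), Q - 2.0])
        angle = rng.uniform(np.pi * 0.75, np.pi * 1.25)

    max_steps = 2 * (P + Q)
    radius = int(rng.integers(rmin, rmax + 1))
    stack = [(pos.copy(), angle, radius, max_steps)]
    total_budget = 6 * (P + Q)
    spent = 0
    while stack and spent < total_budget:
        pos, angle, radius, steps = stack.pop()
        for _ in range(steps):
            r, c = int(round(pos[0])), int(round(pos[1]))
            if not (0 <= r < P and 0 <= c < Q):
                break
            _stamp_disk(mask, r, c, radius)
            spent += 1
            if spent >= total_budget:
                break
            if rng.random() < config.branch_probability and len(stack) < 8:
                child_angle = angle + rng.choice([-1.0, 1.0]) * rng.uniform(0.4, 1.0)
                child_radius = max(rmin, radius - 1)
                stack.append((pos.copy(), child_angle, child_radius, steps // 2))
            angle += rng.normal(0.0, 0.18)
            # step direction: angle measured as (dr, dc) = (sin, cos)
            pos = pos + np.array([np.sin(angle), np.cos(angle)])
    return mask


def generate_tree_masks(
    config: SynthConfig,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Per-tree boolean masks for arteries and veins (in generation order)."""
    min_side = 2 * max(config.vessel_radius_range) + 5
    if config.canvas_height < min_side or config.canvas_width < min_side:
        raise ValueError(
            f"canvas {config.canvas_height}x{config.canvas_width} too small for "
            f"vessel radius up to {max(config.vessel_radius_range)}; "
            f"need at least {min_side} pixels per side"
        )
    rng = np.random.default_rng(config.seed)
    arteries = [grow_tree(rng, config) for _ in range(config.trees_per_class)]
    veins = [grow_tree(rng, config) for _ in range(config.trees_per_class)]
    return arteries, veins


def generate_labeled_image(config: SynthConfig) -> LabeledImage:
    """Render a synthetic labeled fundus-like image.

    Overlap between artery and vein trees is labeled crossing/unknown and
    rendered as the mean of the two class colors.  Deterministic in
    ``config.seed``.
    """
    arteries, veins = generate_tree_masks(config)
    artery_mask = np.logical_or.reduce(arteries)
    vein_mask = np.logical_or.reduce(veins)
    cross_mask = artery_mask & vein_mask

    labels = np.full((config.canvas_height, config.canvas_width), BACKGROUND, dtype=np.int64)
    labels[artery_mask] = ARTERY
    labels[vein_mask] = VEIN
    labels[cross_mask] = CROSSING

    colors = config.color_means
    image = np.empty(labels.shape + (3,), dtype=np.float64)
    image[:] = np.asarray(colors["background"])
    image[artery_mask] = np.asarray(colors["artery"])
    image[vein_mask] = np.asarray(colors["vein"])
    image[cross_mask] = 0.5 * (
        np.asarray(colors["artery"]) + np.asarray(colors["vein"])
    )

    if config.noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0FFEE]))
        image = image + rng.normal(0.0, config.noise_sd, size=image.shape)
    image = np.clip(image, 0.0, 1.0)
    return LabeledImage(image=image, labels=labels)


def corrupt_mask(
    mask: np.ndarray, break_count: int, gap_length: int, seed: int
) -> np.ndarray:
    """Erase up to ``break_count`` short gaps from a binary vessel mask.

    Each gap clears foreground pixels within Euclidean distance
    ``gap_length / 2`` of a randomly chosen foreground site, simulating the
    broken-vessel errors of a pixel classifier.  Never adds foreground;
    deterministic in ``seed``.
    """
    if break_count < 0:
        raise ValueError("break_count must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    out = mask.copy()
    if break_count == 0:
        return out
    rng = np.random.default_rng(seed)
    radius = max(gap_length / 2.0, 0.5)
    ir = int(np.ceil(radius))
    rr = np.arange(-ir, ir + 1)
    di, dj = np.meshgrid(rr, rr, indexing="ij")
    keep = di * di + dj * dj <= radius * radius
    di, dj = di[keep], dj[keep]
    P, Q = out.shape
    for _ in range(break_count):
        fg = np.flatnonzero(out)
        if fg.size == 0:
            break
        site = fg[rng.integers(0, fg.size)]
        r, c = divmod(site, Q)
        ii, jj = di + r, dj + c
        ok = (ii >= 0) & (ii < P) & (jj >= 0) & (jj < Q)
        out[ii[ok], jj[ok]] = False
    return out


# ---------------------------------------------------------------------------
# label-map raster I/O (color-coded PNG dialect)
# ---------------------------------------------------------------------------

def labels_to_rgb(labels: np.ndarray) -> np.ndarray:
    """4-class label map -> 8-bit color-coded RGB raster."""
    lut = np.zeros((NUM_CLASSES, 3), dtype=np.uint8)
    for cls, rgb in _LABEL_TO_RGB.items():
        lut[cls] = rgb
    return lut[labels]


def rgb_to_labels(rgb: np.ndarray) -> np.ndarray:
    """Color-coded RGB raster -> 4-class label map.

    Accepts both green and white for the crossing/unknown class; any other
    color maps to its nearest dialect color.
    """
    rgb = np.asarray(rgb)
    palette = np.array(
        [_LABEL_TO_RGB[c] for c in range(NUM_CLASSES)] + [(255, 255, 255)],
        dtype=np.float64,
    )
    classes = np.array([BACKGROUND, ARTERY, CROSSING, VEIN, CROSSING])
    d = ((rgb[..., None, :].astype(np.float64) - palette) ** 2).sum(axis=-1)
    return classes[np.argmin(d, axis=-1)]


def save_labeled_image(sample: LabeledImage, image_path, labels_path, config: SynthConfig | None = None) -> None:
    """Write the RGB raster and color-coded labels as PNGs.

    When ``config`` is given, a sidecar JSON (``<image>.json``) records it.
    """
    img8 = np.clip(np.round(sample.image * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(img8, mode="RGB").save(image_path)
    Image.fromarray(labels_to_rgb(sample.labels), mode="RGB").save(labels_path)
    if config is not None:
        sidecar = Path(str(image_path)).with_suffix(".json")
        sidecar.write_text(json.dumps(dataclasses.asdict(config), indent=2))


def load_labeled_image(image_path, labels_path) -> LabeledImage:
    image = np.asarray(Image.open(image_path).convert("RGB"), dtype=np.float64) / 255.0
    labels = rgb_to_labels(np.asarray(Image.open(labels_path).convert("RGB")))
    return LabeledImage(image=image, labels=labels)
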