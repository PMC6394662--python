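"""Synthetic scanned-dish images with exact ground truth.

The generator renders what a flatbed scan of a Giemsa-stained dish looks
like to the counting pipeline: a light dish on a darker surround, a dark
rim annulus, purple-blue soft-edged colony disks, a smooth illumination
gradient across the plate, and per-pixel Gaussian sensor noise. Because
every colony's centre, radius and true area are known, every pipeline
stage — and the end-to-end count — can be scored against ground truth.

Four quality presets emulate the qualitative plate categories seen in
practice, ordered from easy to hard:

=======  ==========  ===============  ======  =========
preset   contrast    overlap pairs    noise   gradient
=======  ==========  ===============  ======  =========
``#1``   high (120)  none             low     mild
``#2``   high (120)  30 %             low     mild
``#3``   low (35)    30 %             medium  moderate
``#4``   low (25)    50 %             high    strong
=======  ==========  ===============  ======  =========

The numeric values are this package's operationalization of those
qualitative categories, chosen so detection difficulty increases
monotonically from #1 to #4; all of them can be overridden on the spec.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import GenerationError, ValidationError
from .plate_io import PlateImage, save_plate_image

__all__ = [
    "RadiusLaw",
    "SyntheticPlateSpec",
    "GroundTruth",
    "generate_plate",
    "category_preset",
    "sample_sizes",
    "write_ground_truth",
    "CATEGORY_NAMES",
]

CATEGORY_NAMES = ("#1", "#2", "#3", "#4")

#: fraction of the (r1 + r2) centre distance used for touching pairs;
#: < 1 so paired colonies genuinely merge in the mask
_PAIR_DISTANCE_FACTOR = 0.8

#: soft-edge width of rendered colonies, px (emulates scan blur of stain edges)
_EDGE_WIDTH = 1.5


@dataclass
class RadiusLaw:
    """Distribution of colony radii in pixels.

    family ``"weibull"`` (params shape, scale), ``"lognormal"`` (params
    mean_log, sigma_log) or ``"fixed"`` (param radius).
    """

    family: str = "weibull"
    params: dict = field(default_factory=lambda: {"shape": 3.0, "scale": 10.0})

    def __post_init__(self):
        if self.family not in ("weibull", "lognormal", "fixed"):
            raise ValidationError(f"unknown radius law family {self.family!r}")
        required = {"weibull": ("shape", "scale"),
                    "lognormal": ("mean_log", "sigma_log"),
                    "fixed": ("radius",)}[self.family]
        for key in required:
            if key not in self.params:
                raise ValidationError(f"radius law {self.family!r} needs parameter {key!r}")
            if self.params[key] <= 0 and key != "mean_log":
                raise ValidationError(f"radius law parameter {key!r} must be > 0")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "fixed":
            return np.full(n, float(self.params["radius"]))
        if self.family == "weibull":
            a, b = self.params["shape"], self.params["scale"]
            return b * rng.weibull(a, size=n)
        m, s = self.params["mean_log"], self.params["sigma_log"]
        return rng.lognormal(m, s, size=n)


@dataclass
class SyntheticPlateSpec:
    """Everything needed to render one synthetic plate deterministically.

    ``contrast`` is the mean intensity gap (gray levels) between the dish
    background and a colony centre in the most-stained channel;
    ``overlap_fraction`` is the fraction of colonies placed as touching
    pairs; ``gradient_amplitude`` is the peak-to-trough illumination tilt
    across the dish. Identical spec + seed gives bit-identical output.
    """

    image_size: tuple[int, int] = (768, 768)
    dpi: float = 300.0
    n_colonies: int = 50
    radius_law: RadiusLaw = field(default_factory=RadiusLaw)
    overlap_fraction: float = 0.0
    contrast: float = 120.0
    gradient_amplitude: float = 8.0
    noise_sd: float = 3.0
    stain_color: tuple[float, float, float] = (0.60, 1.00, 0.45)
    rim: bool = True
    seed: int = 0
    category: str | None = None

    def __post_init__(self):
        if self.n_colonies < 0:
            raise ValidationError("n_colonies must be ≥ 0")
        if self.contrast < 0 or self.noise_sd < 0:
            raise ValidationError("contrast and noise_sd must be ≥ 0")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValidationError("overlap_fraction must be in [0, 1]")
        if self.dpi <= 0:
            raise ValidationError("dpi must be > 0")
        if min(self.image_size) < 32:
            raise ValidationError("image must be at least 32×32")
        if isinstance(self.radius_law, dict):
            self.radius_law = RadiusLaw(**self.radius_law)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """True colony geometry behind a rendered plate."""

    colonies: list   # of (center=(row, col), radius, true_area)
    n_true: int
    category_preset: str | None = None

    def to_dict(self) -> dict:
        return {
            "n_true": self.n_true,
            "category_preset": self.category_preset,
            "colonies": [
                {"center": [float(c[0]), float(c[1])],
                 "radius": float(r), "true_area": float(a)}
                for (c, r, a) in self.colonies
            ],
        }


# dish geometry relative to min(H, W); the rim sits just inside the dish
# edge so the default ROI margin of 0.05 excludes it
_DISH_RADIUS_FRACTION = 0.49
_PLACEMENT_RADIUS_FRACTION = 0.86   # colonies stay well inside the ROI
_RIM_WIDTH = 4.0
_BACKGROUND_RGB = (234.0, 234.0, 234.0)   # near-white dish
# light scanner bed, as in scan protocols that back the dish with a white
# filler for contrast; keeps channel variance driven by the colonies
_SURROUND = 205.0
_RIM_LEVEL = 90.0


def _place_colonies(spec: SyntheticPlateSpec, rng: np.random.Generator):
    """Rejection-sample colony centres; returns list of (center, radius)."""
    h, w = spec.image_size
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    dish_r = _DISH_RADIUS_FRACTION * min(h, w)

    n = spec.n_colonies
    n_pairs = int(round(spec.overlap_fraction * n / 2.0))
    n_singles = n - 2 * n_pairs

    radii = np.clip(spec.radius_law.sample(n, rng), 2.0, 0.12 * min(h, w))
    placed: list[tuple[tuple[float, float], float]] = []

    def far_enough(y, x, r):
        return all(math.hypot(y - py, x - px) > r + pr + 3.0
                   for (py, px), pr in placed)

    def sample_center(r):
        max_r = _PLACEMENT_RADIUS_FRACTION * dish_r - r
        if max_r <= 0:
            raise GenerationError("colony radius exceeds the dish interior")
        for _ in range(400):
            rho = max_r * math.sqrt(rng.uniform())
            theta = rng.uniform(0.0, 2.0 * math.pi)
            y, x = cy + rho * math.sin(theta), cx + rho * math.cos(theta)
            if far_enough(y, x, r):
                return y, x
        raise GenerationError(
            f"could not place {spec.n_colonies} colonies; the dish is too "
            "crowded — reduce n_colonies or the colony radii"
        )

    k = 0
    for _ in range(n_singles):
        r = float(radii[k]); k += 1
        placed.append((sample_center(r), r))
    for _ in range(n_pairs):
        r1, r2 = float(radii[k]), float(radii[k + 1]); k += 2
        # the pair needs clearance for both members
        y1, x1 = sample_center(r1 + r2 + 2.0)
        placed.append(((y1, x1), r1))
        d = _PAIR_DISTANCE_FACTOR * (r1 + r2)
        theta = rng.uniform(0.0, 2.0 * math.pi)
        placed.append(((y1 + d * math.sin(theta), x1 + d * math.cos(theta)), r2))
    return placed, (cy, cx), dish_r


def generate_plate(spec: SyntheticPlateSpec) -> tuple[PlateImage, GroundTruth]:
    """Render one synthetic dish scan and its exact ground truth.

    The render is float until the final clip-and-quantize to uint8, and is
    bit-identical for identical spec + seed.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    placed, (cy, cx), dish_r = _place_colonies(spec, rng)

    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    dish_dist = np.hypot(yy - cy, xx - cx)

    # illumination tilt: a plane across the dish in a seeded direction
    theta = rng.uniform(0.0, 2.0 * math.pi)
    tilt = ((yy - cy) * math.sin(theta) + (xx - cx) * math.cos(theta)) / max(h, w)
    illum = spec.gradient_amplitude * tilt

    # colony absorption map: soft-edged disks, overlapping absorption
    # saturates (max) rather than adds, like stacked stain
    absorption = np.zeros((h, w))
    for (y, x), r in placed:
        y0, y1 = max(0, int(y - r - 4)), min(h, int(y + r + 5))
        x0, x1 = max(0, int(x - r - 4)), min(w, int(x + r + 5))
        d = np.hypot(yy[y0:y1, x0:x1] - y, xx[y0:y1, x0:x1] - x)
        weight = np.clip((r - d) / _EDGE_WIDTH + 0.5, 0.0, 1.0)
        np.maximum(absorption[y0:y1, x0:x1], weight,
                   out=absorption[y0:y1, x0:x1])

    channels = []
    for ch in range(3):
        base = np.full((h, w), _SURROUND)
        inside = dish_dist <= dish_r
        base[inside] = _BACKGROUND_RGB[ch] + illum[inside]
        if spec.rim:
            rim_band = inside & (dish_dist >= dish_r - _RIM_WIDTH)
            base[rim_band] = _RIM_LEVEL
        base -= spec.contrast * spec.stain_color[ch] * absorption
        channels.append(base)
    img = np.stack(channels, axis=-1)

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)

    truth = GroundTruth(
        colonies=[((y, x), r, math.pi * r**2) for (y, x), r in placed],
        n_true=len(placed),
        category_preset=spec.category,
    )
    plate = PlateImage(pixels=pixels, resolution_dpi=spec.dpi,
                       source_id=f"synthetic_seed{spec.seed}")
    return plate, truth


_PRESETS = {
    "#1": dict(contrast=120.0, overlap_fraction=0.0, noise_sd=3.0,
               gradient_amplitude=8.0),
    "#2": dict(contrast=120.0, overlap_fraction=0.30, noise_sd=3.0,
               gradient_amplitude=8.0),
    "#3": dict(contrast=35.0, overlap_fraction=0.36, noise_sd=4.0,
               gradient_amplitude=15.0),
    "#4": dict(contrast=25.0, overlap_fraction=0.50, noise_sd=4.0,
               gradient_amplitude=25.0),
}


def category_preset(name: str, n_colonies: int = 50, seed: int = 0,
                    **overrides) -> SyntheticPlateSpec:
    """Spec for one of the four quality categories ``"#1"``..``"#4"``.

    #1: high contrast, well separated. #2: high contrast, 30% of colonies
    in touching pairs. #3: low contrast (≤ 40 gray levels), moderate
    overlaps. #4: low contrast, 50% overlapping pairs, strong gradient.
    """
    key = name if name.startswith("#") else f"#{name}"
    if key not in _PRESETS:
        raise ValidationError(
            f"unknown category {name!r}; expected one of {CATEGORY_NAMES}")
    kwargs = dict(_PRESETS[key])
    kwargs.update(overrides)
    return SyntheticPlateSpec(n_colonies=n_colonies, seed=seed,
                              category=key, **kwargs)


def sample_sizes(law: RadiusLaw, n: int, seed: int = 0) -> np.ndarray:
    """Draw n colony radii from the law and return areas π·r²."""
    if n < 1:
        raise ValidationError("n must be ≥ 1")
    rng = np.random.default_rng(seed)
    r = law.sample(n, rng)
    return math.pi * r**2


def write_ground_truth(truth: GroundTruth, path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=2) + "\n",
                          encoding="utf-8")


def save_synthetic_plate(spec: SyntheticPlateSpec, out_dir,
                         stem: str | None = None) -> tuple[Path, Path]:
    """Render and write PNG (with DPI tag) + ground-truth JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    plate, truth = generate_plate(spec)
    if stem is None:
        stem = plate.source_id
    img_path = out_dir / f"{stem}.png"
    json_path = out_dir / f"{stem}.truth.json"
    save_plate_image(plate, img_path, dpi=spec.dpi)
    write_ground_truth(truth, json_path)
    return img_path, json_path
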