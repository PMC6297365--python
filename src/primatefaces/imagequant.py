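"""Color and pattern quantification of face stimuli.

Stimulus images are RGBA rasters in which fully transparent pixels
(alpha = 0) mark the cut-away background and are excluded from every
statistic.  Opaque pixels are converted to the HSL color space and
assigned to one of eight mutually exclusive color classes:

* hue bins — ``red`` [350°, 360°) ∪ [0°, 18°) (reddish brown in primate
  coats), ``orange`` [18°, 45°), ``yellow`` [45°, 75°) (yellowish brown),
  ``bluish`` [170°, 270°);
* achromatic gates applied first — ``black`` (L < 0.20), ``white``
  (L > 0.71), ``gray`` (S < 0.15);
* everything else is ``unclassified`` so the classes always partition
  the opaque pixels.

The achromatic gates take precedence over the hue bins (a very dark red
pixel is black, not red), and black precedes white precedes gray.

A ``pattern`` score captures fine-grained luminance texture (agouti-like
fur speckling): the fraction of interior opaque pixels whose Sobel
gradient magnitude exceeds a threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.filters import sobel, prewitt, scharr
from scipy.ndimage import binary_erosion

__all__ = [
    "COLOR_CLASSES",
    "ColorProfile",
    "StimulusImage",
    "EmptyImageError",
    "rgb_to_hsl",
    "classify_pixel",
    "classify_pixels",
    "color_profile",
    "transform_fraction",
    "pattern_score",
    "profiles_to_frame",
]

#: Color classes in canonical order; together they partition the opaque pixels.
COLOR_CLASSES = (
    "red",
    "orange",
    "yellow",
    "bluish",
    "black",
    "white",
    "gray",
    "unclassified",
)

#: Hue bins in degrees, half-open [lo, hi).  Red wraps around 360°.
HUE_BINS = {
    "red": ((350.0, 360.0), (0.0, 18.0)),
    "orange": ((18.0, 45.0),),
    "yellow": ((45.0, 75.0),),
    "bluish": ((170.0, 270.0),),
}

BLACK_LIGHTNESS = 0.20
WHITE_LIGHTNESS = 0.71
GRAY_SATURATION = 0.15

#: Alpha at or above this value counts as opaque (binary stimuli use {0, 1}).
OPACITY_THRESHOLD = 0.5

_EDGE_OPERATORS = {"sobel": sobel, "prewitt": prewitt, "scharr": scharr}


class EmptyImageError(ValueError):
    """Raised when an image has no opaque pixels to quantify."""


@dataclass
class StimulusImage:
    """RGBA raster with channels in [0, 1]; alpha = 0 marks background."""

    pixels: np.ndarray  # (height, width, 4) float array

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 3 or px.shape[2] != 4:
            raise ValueError("pixels must have shape (height, width, 4)")
        if px.min() < 0 or px.max() > 1:
            raise ValueError("channel values must lie in [0, 1]")
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def opaque_mask(self) -> np.ndarray:
        return self.pixels[..., 3] >= OPACITY_THRESHOLD

    @classmethod
    def from_file(cls, path: str | Path) -> "StimulusImage":
        with Image.open(path) as im:
            arr = np.asarray(im.convert("RGBA"), dtype=float) / 255.0
        return cls(arr)

    def to_file(self, path: str | Path) -> None:
        arr = np.clip(np.rint(self.pixels * 255.0), 0, 255).astype(np.uint8)
        Image.fromarray(arr, mode="RGBA").save(path)


@dataclass
class ColorProfile:
    """Per-image color composition and texture summary."""

    fractions: dict[str, float]
    transformed_fractions: dict[str, float] = field(init=False)
    mean_lightness: float = 0.0
    mean_saturation: float = 0.0
    pattern: float = 0.0
    n_opaque: int = 0

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {total!r}")
        self.transformed_fractions = {
            k: transform_fraction(v) for k, v in self.fractions.items()
        }

    def as_dict(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for k in COLOR_CLASSES:
            out[k] = self.fractions[k]
        for k in COLOR_CLASSES:
            out[f"{k}_t"] = self.transformed_fractions[k]
        out["mean_lightness"] = self.mean_lightness
        out["mean_saturation"] = self.mean_saturation
        out["pattern"] = self.pattern
        out["n_opaque"] = self.n_opaque
        return out


def rgb_to_hsl(rgb: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Convert RGB in [0, 1] to (H degrees in [0, 360), S, L).

    Accepts a single pixel ``(3,)`` or an array ``(..., 3)``.  Hue is 0 by
    convention for achromatic pixels (S = 0).
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.shape[-1] != 3:
        raise ValueError("last axis must hold (R, G, B)")
    if rgb.min() < 0 or rgb.max() > 1:
        raise ValueError("RGB channels must lie in [0, 1]")
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    cmax = np.maximum.reduce([r, g, b])
    cmin = np.minimum.reduce([r, g, b])
    c = cmax - cmin
    light = (cmax + cmin) / 2.0

    with np.errstate(divide="ignore", invalid="ignore"):
        sat = np.where(c == 0, 0.0, c / (1.0 - np.abs(2.0 * light - 1.0)))
        hue = np.zeros_like(light)
        safe_c = np.where(c == 0, 1.0, c)
        hr = ((g - b) / safe_c) % 6.0
        hg = (b - r) / safe_c + 2.0
        hb = (r - g) / safe_c + 4.0
        hue = np.where(cmax == r, hr, np.where(cmax == g, hg, hb))
        hue = np.where(c == 0, 0.0, hue * 60.0) % 360.0
    sat = np.clip(sat, 0.0, 1.0)
    return hue, sat, light


def _hue_class(h: np.ndarray) -> np.ndarray:
    """Map hue in degrees to a class index into COLOR_CLASSES (7 = unclassified)."""
    out = np.full(np.shape(h), COLOR_CLASSES.index("unclassified"), dtype=int)
    for name, intervals in HUE_BINS.items():
        idx = COLOR_CLASSES.index(name)
        for lo, hi in intervals:
            out = np.where((h >= lo) & (h < hi), idx, out)
    return out


def classify_pixels(
    h: np.ndarray, s: np.ndarray, light: np.ndarray, alpha: np.ndarray
) -> np.ndarray:
    """Vectorized classification; returns class indices, -1 for excluded pixels.

    Precedence: excluded -> black -> white -> gray -> hue bin -> unclassified.
    """
    h = np.asarray(h, dtype=float)
    cls = _hue_class(h)
    cls = np.where(np.asarray(s) < GRAY_SATURATION, COLOR_CLASSES.index("gray"), cls)
    cls = np.where(np.asarray(light) > WHITE_LIGHTNESS, COLOR_CLASSES.index("white"), cls)
    cls = np.where(np.asarray(light) < BLACK_LIGHTNESS, COLOR_CLASSES.index("black"), cls)
    cls = np.where(np.asarray(alpha) < OPACITY_THRESHOLD, -1, cls)
    return cls


def classify_pixel(h: float, s: float, light: float, alpha: float = 1.0) -> str:
    """Classify one pixel; returns a class name or ``"excluded"``."""
    if not (0.0 <= h < 360.0):
        raise ValueError("hue must lie in [0, 360)")
    if not (0.0 <= s <= 1.0 and 0.0 <= light <= 1.0):
        raise ValueError("S and L must lie in [0, 1]")
    idx = int(classify_pixels(np.array(h), np.array(s), np.array(light), np.array(alpha)))
    return "excluded" if idx == -1 else COLOR_CLASSES[idx]


def transform_fraction(p: float) -> float:
    """Arcsine-square-root transform of a proportion (radians, [0, π/2])."""
    p = float(p)
    if not (0.0 <= p <= 1.0):
        raise ValueError("proportion must lie in [0, 1]")
    return float(np.arcsin(np.sqrt(p)))


def _luminance(rgb: np.ndarray) -> np.ndarray:
    # Rec. 601 luma; adequate for an ordinal texture score.
    return 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]


def pattern_score(
    image: StimulusImage,
    threshold: float = 0.1,
    operator: str = "sobel",
) -> float:
    """Fraction of interior opaque pixels with gradient magnitude > threshold.

    The opaque mask is eroded by one pixel before counting so the face
    outline against the transparent background never contributes; the
    score is the exceedance fraction among those interior pixels.
    """
    mask = image.opaque_mask
    if not mask.any():
        raise EmptyImageError("image has no opaque pixels")
    try:
        op = _EDGE_OPERATORS[operator]
    except KeyError:
        raise ValueError(f"unknown edge operator {operator!r}") from None
    grad = op(_luminance(image.pixels))
    interior = binary_erosion(mask, structure=np.ones((3, 3)), border_value=0)
    if not interior.any():
        return 0.0
    return float(np.mean(grad[interior] > threshold))


def color_profile(
    image: StimulusImage,
    exclusion_mask: np.ndarray | None = None,
    edge_threshold: float = 0.1,
    edge_operator: str = "sobel",
) -> ColorProfile:
    """Quantify the color composition of a stimulus.

    Parameters
    ----------
    image
        RGBA stimulus; alpha = 0 pixels are excluded.
    exclusion_mask
        Optional boolean array (height, width); True pixels are excluded
        on top of transparency (e.g. masking genuinely blue facial parts
        before measuring the residual bluish tint).  Fractions are
        renormalized over the remaining pixels.
    edge_threshold, edge_operator
        Forwarded to :func:`pattern_score` (computed on the unmasked image).
    """
    keep = image.opaque_mask
    if exclusion_mask is not None:
        exclusion_mask = np.asarray(exclusion_mask, dtype=bool)
        if exclusion_mask.shape != keep.shape:
            raise ValueError("exclusion_mask shape must match the image")
        keep = keep & ~exclusion_mask
    n = int(keep.sum())
    if n == 0:
        raise EmptyImageError("no opaque pixels outside the exclusion mask")

    rgb = image.pixels[keep][:, :3]
    alpha = image.pixels[keep][:, 3]
    h, s, light = rgb_to_hsl(rgb)
    cls = classify_pixels(h, s, light, alpha)
    counts = np.bincount(cls, minlength=len(COLOR_CLASSES))
    fractions = {name: counts[i] / n for i, name in enumerate(COLOR_CLASSES)}
    return ColorProfile(
        fractions=fractions,
        mean_lightness=float(light.mean()),
        mean_saturation=float(s.mean()),
        pattern=pattern_score(image, threshold=edge_threshold, operator=edge_operator),
        n_opaque=n,
    )


def profiles_to_frame(profiles: dict[str, ColorProfile]) -> pd.DataFrame:
    """Stack per-image profiles into a tidy table (one row per image)."""
    rows = {image_id: prof.as_dict() for image_id, prof in profiles.items()}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "image_id"
    return df


def profiles_to_json(profiles: dict[str, ColorProfile], path: str | Path) -> None:
    payload = {k: v.as_dict() for k, v in profiles.items()}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
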