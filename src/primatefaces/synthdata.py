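"""Synthetic study generator: species panels, stimuli, landmarks, ratings.

The generator emulates the statistical structure of a primate
face-rating study so the full analysis chain runs without any image
downloads:

* a species panel spread over three morphologically distinct groups
  (prosimians, Platyrrhini, Catarrhini) with per-species truth values
  for sexual size dimorphism (LG ratio), human-likeness, color
  composition, fur-pattern level, and two latent morphological factors
  ("outer" and "inner" facial features) that displace a group-specific
  landmark template;
* elliptical face stimuli whose opaque pixels are partitioned into
  color classes in *exact* integer counts (largest-remainder
  apportionment), so color quantification recovers the generating
  composition exactly; the pattern level controls the density of
  fine-scale luminance alternation inside the face;
* landmark digitization with isotropic pixel noise;
* complete Likert rating matrices from a linear latent-score model
  (species signal + rater intercept + residual noise) discretized
  through fixed cutpoints into 1..7, with rater gender/age metadata and
  optional male-preference offsets for a subset of species.

All stage seeds derive from one global integer seed by fixed offsets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .imagequant import COLOR_CLASSES, StimulusImage, transform_fraction
from .morphometry import (
    LANDMARK_NAMES,
    LandmarkSet,
    save_landmarks_csv,
    save_landmarks_tps,
)
from .raterstats import RatingMatrix

__all__ = [
    "GROUPS",
    "SpeciesSpec",
    "SyntheticStudy",
    "RaterModel",
    "generate_species_panel",
    "generate_panel",
    "render_stimulus",
    "sample_landmarks",
    "simulate_ratings",
    "panel_covariates",
    "default_cutpoints",
    "simulate_icc_matrix",
    "categorization_attenuation",
    "make_study",
    "write_study",
    "DEFAULT_SIGNAL",
]

GROUPS = ("prosimian", "platyrrhine", "catarrhine")

# fixed seed offsets per stage (kept below 2**31 after adding the user seed)
_SEED_OFFSETS = {
    "panel": 11,
    "landmarks": 101,
    "images": 211,
    "beauty": 307,
    "humanlikeness": 401,
}


def _stage_seed(seed: int, stage: str) -> int:
    return (int(seed) + _SEED_OFFSETS[stage]) % (2**31 - 1)


# ---------------------------------------------------------------------------
# Color-class paint
# ---------------------------------------------------------------------------

def _hsl_to_rgb_u8(h: float, s: float, light: float) -> tuple[int, int, int]:
    c = (1.0 - abs(2.0 * light - 1.0)) * s
    hp = (h % 360.0) / 60.0
    x = c * (1.0 - abs(hp % 2.0 - 1.0))
    sector = int(hp) % 6
    r, g, b = [
        (c, x, 0.0), (x, c, 0.0), (0.0, c, x),
        (0.0, x, c), (x, 0.0, c), (c, 0.0, x),
    ][sector]
    m = light - c / 2.0
    return tuple(int(round((v + m) * 255.0)) for v in (r, g, b))


# representative hue per chromatic class; achromatic classes keyed by (s, l)
_CLASS_HSL = {
    "red": (0.0, 0.6),
    "orange": (30.0, 0.6),
    "yellow": (60.0, 0.6),
    "bluish": (220.0, 0.6),
    "unclassified": (120.0, 0.6),
}

#: (base, dark-variant, light-variant) uint8 paint per class.  The two
#: variants stay inside the class's own HSL bin, so checker-texturing a
#: region never changes its class membership.
CLASS_PAINT: dict[str, tuple[tuple[int, int, int], ...]] = {}
for _name, (_h, _s) in _CLASS_HSL.items():
    CLASS_PAINT[_name] = (
        _hsl_to_rgb_u8(_h, _s, 0.50),
        _hsl_to_rgb_u8(_h, _s, 0.35),
        _hsl_to_rgb_u8(_h, _s, 0.65),
    )
CLASS_PAINT["black"] = (
    _hsl_to_rgb_u8(0, 0, 0.10), _hsl_to_rgb_u8(0, 0, 0.02), _hsl_to_rgb_u8(0, 0, 0.19)
)
CLASS_PAINT["white"] = (
    _hsl_to_rgb_u8(0, 0, 0.90), _hsl_to_rgb_u8(0, 0, 0.73), _hsl_to_rgb_u8(0, 0, 0.97)
)
CLASS_PAINT["gray"] = (
    _hsl_to_rgb_u8(0, 0.05, 0.50), _hsl_to_rgb_u8(0, 0.05, 0.32),
    _hsl_to_rgb_u8(0, 0.05, 0.64),
)


# ---------------------------------------------------------------------------
# Landmark templates
# ---------------------------------------------------------------------------

# Base face in a 360 x 540 frame (x right, y down); eyes share one y line.
_BASE_TEMPLATE = {
    "A": (180.0, 120.0), "N": (180.0, 90.0),
    "B": (100.0, 280.0), "C": (260.0, 280.0),
    "O1": (70.0, 280.0), "O2": (290.0, 280.0),
    "E1": (120.0, 240.0), "E2": (155.0, 240.0),
    "G2": (205.0, 240.0), "G1": (240.0, 240.0),
    "F": (180.0, 250.0),
    "H": (160.0, 330.0), "I": (200.0, 330.0), "J": (180.0, 345.0),
    "K": (220.0, 390.0), "L": (180.0, 390.0), "M": (140.0, 390.0),
    "D": (180.0, 450.0), "P": (180.0, 470.0),
}

# Additive (dx, dy) per landmark for each group; chosen so the groups
# separate cleanly in trait space (face width and nose length carry most
# of the between-group signal).
_GROUP_DELTAS: dict[str, dict[str, tuple[float, float]]] = {
    "prosimian": {
        "B": (-12, 0), "C": (12, 0), "O1": (-12, 0), "O2": (12, 0),
        "A": (0, 12), "N": (0, 12),
        "H": (0, -18), "I": (0, -18), "J": (0, -18),
        "E1": (-4, 0), "G1": (4, 0),
    },
    "platyrrhine": {
        "B": (-7, 0), "C": (7, 0), "O1": (-7, 0), "O2": (7, 0),
        "A": (0, 5), "N": (0, 5),
        "H": (0, -9), "I": (0, -9), "J": (0, -9),
        "K": (4, 0), "M": (-4, 0),
    },
    "catarrhine": {
        "H": (0, 9), "I": (0, 9), "J": (0, 12),
        "E1": (2, 0), "G1": (-2, 0),
    },
}

# Displacement fields (per unit latent factor score) generating the two
# morphological factors recovered downstream by factor analysis.
_OUTER_DIRECTION = {
    "A": (0, -8), "N": (0, -16), "P": (0, 10), "O1": (-8, 0), "O2": (8, 0),
}
_INNER_DIRECTION = {
    "E1": (-10, 0), "G1": (10, 0), "E2": (-5, 0), "G2": (5, 0),
    "K": (8, 0), "M": (-8, 0), "L": (0, 8), "I": (0, 2),
}

# Group parameter regimes (means/SDs of the per-species truth draws)
_GROUP_PARAMS = {
    "prosimian": {
        "hl": (5.4, 0.6), "lg": (0.02, 0.08), "pattern_beta": (4.0, 4.0),
        "colors": {"black": 0.25, "white": 0.20, "gray": 0.28, "red": 0.05,
                   "orange": 0.05, "yellow": 0.05, "bluish": 0.03,
                   "unclassified": 0.09},
    },
    "platyrrhine": {
        "hl": (4.2, 0.6), "lg": (-0.15, 0.20), "pattern_beta": (3.0, 4.0),
        "colors": {"black": 0.10, "white": 0.10, "gray": 0.15, "red": 0.05,
                   "orange": 0.20, "yellow": 0.29, "bluish": 0.03,
                   "unclassified": 0.08},
    },
    "catarrhine": {
        "hl": (2.6, 0.8), "lg": (-0.55, 0.30), "pattern_beta": (2.0, 6.0),
        "colors": {"red": 0.29, "orange": 0.20, "gray": 0.15, "black": 0.10,
                   "white": 0.05, "yellow": 0.10, "bluish": 0.04,
                   "unclassified": 0.07},
    },
}

#: Default species-level signal on the raw Likert latent scale
#: (1 = most beautiful, so negative weights make a trait "prettier").
#: Signs mirror an attractiveness regime in which prosimians score best,
#: male-larger dimorphism and bluish tint help, and less human-like
#: faces score worse within the human-like range.
DEFAULT_SIGNAL = {
    "morph_inner": 0.35,
    "lg": -0.5,
    "human_likeness": 0.21,
    "bluish_t": -1.6,
    "group_platyrrhine": 0.29,
    # the direct prosimian offset outweighs the human-likeness penalty the
    # group carries, so prosimians end up the most attractive group overall
    "group_prosimian": -0.8,
}


@dataclass
class SpeciesSpec:
    """Generating truth for one synthetic species."""

    species_id: str
    genus_id: str
    group: str
    latent_beauty: float          # standardized across the panel
    human_likeness_true: float    # 1..7, 1 = most human-like
    lg_true: float                # Lovich-Gibbons ratio
    color_weights: dict[str, float]
    pattern_level: float          # in [0, 1]
    landmark_template: LandmarkSet
    morph_outer: float = 0.0      # latent "outer facial features" score
    morph_inner: float = 0.0      # latent "inner facial features" score

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        w = self.color_weights
        if any(v < 0 for v in w.values()):
            raise ValueError("color weights must be nonnegative")
        if abs(sum(w.values()) - 1.0) > 1e-12:
            raise ValueError("color weights must sum to 1")
        if not (-2.0 <= self.lg_true <= 2.0):
            raise ValueError("lg_true must lie in [-2, 2]")
        if not (1.0 <= self.human_likeness_true <= 7.0):
            raise ValueError("human_likeness_true must lie in [1, 7]")
        if not (0.0 <= self.pattern_level <= 1.0):
            raise ValueError("pattern_level must lie in [0, 1]")


def _make_template(group: str, s_outer: float, s_inner: float,
                   rng: np.random.Generator, jitter_sd: float = 2.0) -> LandmarkSet:
    pts = {}
    delta = _GROUP_DELTAS[group]
    for name in LANDMARK_NAMES:
        x, y = _BASE_TEMPLATE[name]
        dx, dy = delta.get(name, (0.0, 0.0))
        ox, oy = _OUTER_DIRECTION.get(name, (0.0, 0.0))
        ix, iy = _INNER_DIRECTION.get(name, (0.0, 0.0))
        pts[name] = (
            x + dx + s_outer * ox + s_inner * ix + rng.normal(0, jitter_sd),
            y + dy + s_outer * oy + s_inner * iy + rng.normal(0, jitter_sd),
        )
    # keep the four eye landmarks on one notional horizontal line
    eye_y = float(np.mean([pts[n][1] for n in ("E1", "E2", "G1", "G2")]))
    for n in ("E1", "E2", "G1", "G2"):
        pts[n] = (pts[n][0], eye_y)
    return LandmarkSet(pts)


def generate_panel(group_sizes: dict[str, int], seed: int) -> list[SpeciesSpec]:
    """Generate a species panel with the given per-group sizes."""
    for g, n in group_sizes.items():
        if g not in GROUPS:
            raise ValueError(f"unknown group {g!r}")
        if n < 2:
            raise ValueError("each group needs at least 2 species")
    rng = np.random.default_rng(_stage_seed(seed, "panel"))
    panel: list[SpeciesSpec] = []
    for group in GROUPS:
        n = group_sizes.get(group, 0)
        params = _GROUP_PARAMS[group]
        for i in range(n):
            sp_id = f"{group[:4]}_{i + 1:03d}"
            genus = f"{group[:4]}_gen{i // 3 + 1:02d}"
            s_outer = float(rng.normal())
            s_inner = float(rng.normal())
            hl = float(np.clip(rng.normal(*params["hl"]), 1.0, 7.0))
            lg = float(np.clip(rng.normal(*params["lg"]), -1.4, 0.32))
            pattern = float(np.clip(rng.beta(*params["pattern_beta"]), 0.0, 1.0))
            mean_w = np.array([params["colors"][c] for c in COLOR_CLASSES])
            w = rng.dirichlet(mean_w * 60.0)
            w = w / w.sum()
            template = _make_template(group, s_outer, s_inner, rng)
            panel.append(
                SpeciesSpec(
                    species_id=sp_id,
                    genus_id=genus,
                    group=group,
                    latent_beauty=0.0,  # filled below
                    human_likeness_true=hl,
                    lg_true=lg,
                    color_weights=dict(zip(COLOR_CLASSES, w)),
                    pattern_level=pattern,
                    landmark_template=template,
                    morph_outer=s_outer,
                    morph_inner=s_inner,
                )
            )
    # latent beauty = standardized default-signal combination
    cov = panel_covariates(panel)
    raw = np.zeros(len(panel))
    for k, wgt in DEFAULT_SIGNAL.items():
        raw += wgt * cov[k].values
    z = (raw - raw.mean()) / (raw.std(ddof=0) or 1.0)
    panel = [replace(sp, latent_beauty=float(v)) for sp, v in zip(panel, z)]
    return panel


def generate_species_panel(n_per_group: int, seed: int) -> list[SpeciesSpec]:
    """Balanced panel with ``n_per_group`` species in each of the 3 groups."""
    if n_per_group < 1:
        raise ValueError("n_per_group must be a positive integer")
    if n_per_group < 2:
        raise ValueError("need at least 2 species per group")
    return generate_panel({g: n_per_group for g in GROUPS}, seed)


def panel_covariates(panel: list[SpeciesSpec]) -> pd.DataFrame:
    """Generating covariates per species (the truth the analyses estimate)."""
    rows = []
    for sp in panel:
        rows.append(
            {
                "species_id": sp.species_id,
                "group": sp.group,
                "morph_outer": sp.morph_outer,
                "morph_inner": sp.morph_inner,
                "human_likeness": sp.human_likeness_true,
                "lg": sp.lg_true,
                "bluish_t": transform_fraction(sp.color_weights["bluish"]),
                "pattern": sp.pattern_level,
                "group_prosimian": float(sp.group == "prosimian"),
                "group_platyrrhine": float(sp.group == "platyrrhine"),
                "latent_beauty": sp.latent_beauty,
            }
        )
    return pd.DataFrame(rows).set_index("species_id")


# ---------------------------------------------------------------------------
# Stimulus rendering
# ---------------------------------------------------------------------------

def _largest_remainder(weights: np.ndarray, n: int) -> np.ndarray:
    """Apportion n pixels to classes in exact integer counts."""
    quotas = weights * n
    counts = np.floor(quotas).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(quotas - counts), kind="stable")
    counts[order[:short]] += 1
    return counts


def render_stimulus(
    spec: SpeciesSpec,
    width: int = 96,
    height: int = 128,
    seed: int = 0,
) -> tuple[StimulusImage, dict[str, float]]:
    """Render an elliptical face stimulus with exact color-class counts.

    Opaque pixels are partitioned among the classes in
    ``spec.color_weights`` by largest-remainder apportionment and
    painted as contiguous angular sectors; the returned truth map holds
    the exact pixel fractions.  ``spec.pattern_level`` sets the area
    fraction of a central region textured as a 2x2-pixel checkerboard of
    darker/lighter variants of each class's own color (class membership
    is unchanged, only luminance texture is added).  Background pixels
    are white with alpha 0.
    """
    if width < 32 or height < 32:
        raise ValueError("width and height must be >= 32 pixels")
    weights = np.array([spec.color_weights.get(c, 0.0) for c in COLOR_CLASSES])
    if abs(weights.sum() - 1.0) > 1e-9 or (weights < 0).any():
        raise ValueError("color_weights must be nonnegative and sum to 1")

    yy, xx = np.mgrid[0:height, 0:width]
    cx, cy = (width - 1) / 2.0, (height - 1) / 2.0
    a, b = 0.45 * width, 0.45 * height
    rho2 = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2
    face = rho2 <= 1.0
    n = int(face.sum())
    if n == 0:
        raise ValueError("face ellipse contains no pixels")

    counts = _largest_remainder(weights, n)
    truth = {c: counts[i] / n for i, c in enumerate(COLOR_CLASSES)}

    # contiguous sectors: order face pixels by angle around the center
    fy, fx = np.nonzero(face)
    ang = np.arctan2(fy - cy, fx - cx)
    order = np.lexsort((fy, fx, ang))
    class_of = np.empty(n, dtype=int)
    start = 0
    for i, cnt in enumerate(counts):
        class_of[order[start:start + cnt]] = i
        start += cnt

    patterned = rho2[fy, fx] <= spec.pattern_level
    parity = ((fx // 2) + (fy // 2)) % 2

    img = np.zeros((height, width, 4), dtype=float)
    img[..., :3] = 1.0  # white background
    rgb = np.empty((n, 3), dtype=float)
    for i, cname in enumerate(COLOR_CLASSES):
        base, dark, lightv = CLASS_PAINT[cname]
        sel = class_of == i
        rgb[sel] = np.array(base) / 255.0
        sel_dark = sel & patterned & (parity == 0)
        sel_light = sel & patterned & (parity == 1)
        rgb[sel_dark] = np.array(dark) / 255.0
        rgb[sel_light] = np.array(lightv) / 255.0
    img[fy, fx, :3] = rgb
    img[fy, fx, 3] = 1.0
    return StimulusImage(img), truth


def sample_landmarks(spec: SpeciesSpec, noise_sd: float = 1.5,
                     seed: int = 0) -> LandmarkSet:
    """Digitize the template with isotropic Gaussian pixel noise.

    Eye-landmark vertical noise is clipped to 1.5 noise_sd so the four
    eye points stay within 3 noise_sd of a common horizontal line.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    coords = spec.landmark_template.as_array()
    if noise_sd == 0:
        return LandmarkSet.from_array(coords)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=coords.shape)
    eye_rows = [LANDMARK_NAMES.index(nm) for nm in ("E1", "E2", "G1", "G2")]
    noise[eye_rows, 1] = np.clip(noise[eye_rows, 1], -1.5 * noise_sd, 1.5 * noise_sd)
    return LandmarkSet.from_array(coords + noise)


# ---------------------------------------------------------------------------
# Rating simulation
# ---------------------------------------------------------------------------

@dataclass
class RaterModel:
    """Rater-population configuration for the Likert simulation."""

    p_male: float = 91.0 / 286.0
    age_mean: float = 22.7
    age_sd: float = 8.0
    age_range: tuple[int, int] = (15, 69)
    n_male_preferred: int = 0          # species given a male-preference offset
    male_preference_offset: float = -1.0  # latent shift for male raters (lower = prettier)
    preferred_species: list[str] | None = None  # explicit ids override the count


def default_cutpoints(signal: np.ndarray, rater_sd: float,
                      residual_sd: float) -> np.ndarray:
    """Equal-probability Likert cutpoints for the implied latent normal.

    The six cutpoints are standard-normal septile boundaries scaled by
    the model-implied latent SD and centered on the mean species signal,
    so the seven categories are used roughly uniformly.
    """
    scale = float(np.sqrt(np.var(signal) + rater_sd**2 + residual_sd**2))
    center = float(np.mean(signal))
    return center + scale * norm.ppf(np.arange(1, 7) / 7.0)


def simulate_ratings(
    panel: list[SpeciesSpec],
    n_raters: int,
    rater_sd: float,
    species_signal: dict[str, float],
    likert_cutpoints: np.ndarray | None = None,
    rater_metadata_model: RaterModel | None = None,
    residual_sd: float = 1.0,
    seed: int = 0,
) -> RatingMatrix:
    """Simulate a complete raters x species Likert rating matrix.

    The latent score of rater i for species j is
    ``sum_k w_k c_jk + b_i + e_ij`` with covariates ``c`` from
    :func:`panel_covariates`, rater intercepts ``b_i ~ N(0, rater_sd^2)``
    and residuals ``e_ij ~ N(0, residual_sd^2)``, plus an optional
    male-rater offset for a configurable subset of species.  Latents are
    discretized through six strictly increasing cutpoints into 1..7.
    """
    if n_raters < 1:
        raise ValueError("n_raters must be positive")
    if rater_sd < 0 or residual_sd < 0:
        raise ValueError("standard deviations must be >= 0")
    cov = panel_covariates(panel)
    unknown = set(species_signal) - set(cov.columns)
    if unknown:
        raise ValueError(f"unknown covariate(s) in species_signal: {sorted(unknown)}")
    signal = np.zeros(len(panel))
    for key, w in species_signal.items():
        signal += w * cov[key].values

    if likert_cutpoints is None:
        cut = default_cutpoints(signal, rater_sd, residual_sd)
    else:
        cut = np.asarray(likert_cutpoints, dtype=float)
        if cut.shape != (6,):
            raise ValueError("need exactly 6 cutpoints")
        if not np.all(np.diff(cut) > 0):
            raise ValueError("cutpoints must be strictly increasing")

    model = rater_metadata_model or RaterModel()
    rng = np.random.default_rng(seed)
    genders = np.where(rng.random(n_raters) < model.p_male, "male", "female")
    ages = np.clip(
        np.rint(rng.normal(model.age_mean, model.age_sd, n_raters)),
        *model.age_range,
    ).astype(int)

    species_ids = [sp.species_id for sp in panel]
    offset = np.zeros(len(panel))
    preferred = model.preferred_species
    if preferred is None and model.n_male_preferred > 0:
        pick = rng.choice(len(panel), size=model.n_male_preferred, replace=False)
        preferred = [species_ids[i] for i in sorted(pick)]
    if preferred:
        idx = [species_ids.index(s) for s in preferred]
        offset[idx] = model.male_preference_offset

    b = rng.normal(0.0, rater_sd, size=n_raters)
    eps = rng.normal(0.0, residual_sd, size=(n_raters, len(panel)))
    latent = signal[None, :] + b[:, None] + eps
    latent = latent + (genders == "male")[:, None] * offset[None, :]
    scores = 1 + np.searchsorted(cut, latent.ravel()).reshape(latent.shape)

    rater_ids = [f"r{i + 1:04d}" for i in range(n_raters)]
    meta = pd.DataFrame({"gender": genders, "age": ages}, index=rater_ids)
    frame = pd.DataFrame(scores, index=rater_ids, columns=species_ids)
    mat = RatingMatrix(frame, meta)
    mat.scores.attrs["male_preferred_species"] = list(preferred or [])
    return mat


def categorization_attenuation() -> float:
    """Correlation attenuation factor of equal-probability 7-point scoring.

    lambda = Cov(Z, s(Z)) / (sd(Z) sd(s(Z))) for standard-normal Z and
    septile cutpoints; the ICC of categorized scores is approximately
    lambda^2 times the latent ICC.
    """
    cut = norm.ppf(np.arange(1, 7) / 7.0)
    cov = norm.pdf(cut).sum()  # sum_k E[Z 1(Z > c_k)]
    var_s = np.var(np.arange(1, 8))  # uniform categories
    return float(cov / np.sqrt(var_s))


def simulate_icc_matrix(
    n_stimuli: int,
    n_raters: int,
    icc_single: float,
    seed: int = 0,
    rater_sd: float = 0.3,
    residual_sd: float = 1.0,
) -> RatingMatrix:
    """Rating matrix targeting an observed single-measure consistency ICC.

    The latent between-species variance is chosen so that, after the
    analytic attenuation of 7-point categorization, the observed ICC is
    approximately ``icc_single``.
    """
    if not (0.0 <= icc_single < 0.95):
        raise ValueError("target ICC must lie in [0, 0.95)")
    lam2 = categorization_attenuation() ** 2
    tau_latent = min(icc_single / lam2, 0.99)
    if tau_latent >= 1.0:
        raise ValueError("target ICC too large to reach through categorization")
    sigma_s2 = tau_latent / (1.0 - tau_latent) * residual_sd**2
    rng = np.random.default_rng(seed)
    signal = rng.normal(0.0, np.sqrt(sigma_s2), size=n_stimuli)
    cut = default_cutpoints(signal, rater_sd, residual_sd)
    b = rng.normal(0.0, rater_sd, size=n_raters)
    eps = rng.normal(0.0, residual_sd, size=(n_raters, n_stimuli))
    latent = signal[None, :] + b[:, None] + eps
    scores = 1 + np.searchsorted(cut, latent.ravel()).reshape(latent.shape)
    rater_ids = [f"r{i + 1:04d}" for i in range(n_raters)]
    meta = pd.DataFrame(
        {"gender": ["female"] * n_raters, "age": [25] * n_raters}, index=rater_ids
    )
    cols = [f"s{j + 1:04d}" for j in range(n_stimuli)]
    return RatingMatrix(pd.DataFrame(scores, index=rater_ids, columns=cols), meta)


# ---------------------------------------------------------------------------
# Whole-study assembly
# ---------------------------------------------------------------------------

@dataclass
class SyntheticStudy:
    """A complete synthetic study: panel, stimuli, landmarks, ratings, truth."""

    panel: list[SpeciesSpec]
    images: dict[str, StimulusImage]
    landmarks: dict[str, LandmarkSet]
    beauty_ratings: RatingMatrix
    humanlikeness_ratings: RatingMatrix
    seed: int
    truth: dict = field(default_factory=dict)


def make_study(
    group_sizes: dict[str, int] | None = None,
    n_beauty_raters: int = 286,
    n_humanlikeness_raters: int = 60,
    image_size: tuple[int, int] = (96, 128),
    landmark_noise_sd: float = 1.5,
    beauty_rater_sd: float = 0.5,
    beauty_residual_sd: float = 1.1,
    humanlikeness_rater_sd: float = 0.3,
    humanlikeness_residual_sd: float = 1.36,
    species_signal: dict[str, float] | None = None,
    n_male_preferred: int = 5,
    male_preference_offset: float = -1.0,
    seed: int = 0,
    render: bool = True,
) -> SyntheticStudy:
    """Assemble a full synthetic study under the default study conditions.

    Defaults emulate the study regime this package targets: 107 species
    (33 prosimians, 24 Platyrrhini, 50 Catarrhini), 286 beauty raters
    and 60 human-likeness raters, rater/residual noise tuned so the
    single-measure beauty ICC lands near 0.18 (hence average-measure
    near 0.985 with 286 raters) and the human-likeness single-measure
    ICC near 0.55, and five species with a male-preference offset of
    about one Likert point.
    """
    if group_sizes is None:
        group_sizes = {"prosimian": 33, "platyrrhine": 24, "catarrhine": 50}
    panel = generate_panel(group_sizes, seed)
    species_ids = [sp.species_id for sp in panel]

    landmarks = {
        sp.species_id: sample_landmarks(
            sp, noise_sd=landmark_noise_sd,
            seed=(_stage_seed(seed, "landmarks") + i) % (2**31 - 1),
        )
        for i, sp in enumerate(panel)
    }
    images = {}
    truth_colors = {}
    if render:
        for i, sp in enumerate(panel):
            img, truth = render_stimulus(
                sp, *image_size, seed=(_stage_seed(seed, "images") + i) % (2**31 - 1)
            )
            images[sp.species_id] = img
            truth_colors[sp.species_id] = truth

    signal = dict(DEFAULT_SIGNAL if species_signal is None else species_signal)
    beauty = simulate_ratings(
        panel,
        n_raters=n_beauty_raters,
        rater_sd=beauty_rater_sd,
        residual_sd=beauty_residual_sd,
        species_signal=signal,
        rater_metadata_model=RaterModel(
            n_male_preferred=n_male_preferred,
            male_preference_offset=male_preference_offset,
        ),
        seed=_stage_seed(seed, "beauty"),
    )
    humanlike = simulate_ratings(
        panel,
        n_raters=n_humanlikeness_raters,
        rater_sd=humanlikeness_rater_sd,
        residual_sd=humanlikeness_residual_sd,
        species_signal={"human_likeness": 1.0},
        rater_metadata_model=RaterModel(n_male_preferred=0),
        seed=_stage_seed(seed, "humanlikeness"),
    )
    truth = {
        "signal_weights": signal,
        "color_fractions": truth_colors,
        "male_preferred_species": beauty.scores.attrs["male_preferred_species"],
        "group_sizes": dict(group_sizes),
        "covariates": panel_covariates(panel).to_dict(orient="index"),
    }
    return SyntheticStudy(
        panel=panel,
        images=images,
        landmarks=landmarks,
        beauty_ratings=beauty,
        humanlikeness_ratings=humanlike,
        seed=seed,
        truth=truth,
    )


def write_study(study: SyntheticStudy, outdir: str | Path) -> None:
    """Write a study to disk: PNG stimuli, TPS+CSV landmarks, rating CSVs,
    species table CSV, and the generating truth as JSON."""
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    for sp_id, img in study.images.items():
        img.to_file(outdir / "images" / f"{sp_id}.png")
    save_landmarks_tps(study.landmarks, outdir / "landmarks.tps")
    save_landmarks_csv(study.landmarks, outdir / "landmarks.csv")
    study.beauty_ratings.to_csv(outdir / "beauty_ratings.csv")
    study.humanlikeness_ratings.to_csv(outdir / "humanlikeness_ratings.csv")
    species = pd.DataFrame(
        [
            {
                "species_id": sp.species_id,
                "genus_id": sp.genus_id,
                "group": sp.group,
                "lg": sp.lg_true,
                "human_likeness_true": sp.human_likeness_true,
                "pattern_level": sp.pattern_level,
            }
            for sp in study.panel
        ]
    )
    species.to_csv(outdir / "species.csv", index=False)

    def _clean(obj):
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    (outdir / "truth.json").write_text(json.dumps(_clean(study.truth), indent=2))
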