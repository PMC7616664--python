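"""Synthetic stained-tissue fields and datasets with known ground truth.

Real whole-slide images from nanomedicine biodistribution studies are not
publicly distributable, so every input to this pipeline is generated
in-silico with the generating truth recorded alongside:

* multichannel immunofluorescence/DAB-like fields with a controllable number
  of disjoint CD31+ vessel objects, co-stain fractions (lectin, aSMA, VEGFR2,
  collagen I/IV), an F4/80+ macrophage area fraction hit exactly at the pixel
  level, LYVE-1+ lymphatics and a nuclear channel;
* per-animal feature tables (23 microenvironment features + a tumour
  accumulation outcome in %ID per 250 mm3) in which accumulation is a stated
  noisy affine function of vessel count and macrophage area fraction;
* ordinal 1-4 observer x section x marker score matrices for a ten-model
  xenograft panel whose consensus scores reproduce the published
  classification pattern (three low-accumulating true negatives, one
  high-accumulating low-scoring outlier, six high-scoring true positives).

Everything is seeded: identical ``(arguments, seed)`` give bit-identical
output.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw

from .histoquant import (
    CHANNEL_NAMES,
    DEFAULT_MIN_SIZE_PX,
    DEFAULT_THRESHOLD,
    FEATURE_NAMES,
    StainedTissueImage,
)
from .scoring import ObserverScoreMatrix, ValidationError

COSTAIN_CHANNELS = ("lectin", "aSMA", "VEGFR2", "colI", "colIV")

#: Intensity rendered for stained pixels; safely above the default
#: segmentation threshold even before noise.
FOREGROUND_INTENSITY = 0.9

_MAX_PLACEMENT_RETRIES = 10_000
_STRUCT8 = np.ones((3, 3), dtype=int)  # 8-connectivity for component labelling


class PlacementError(RuntimeError):
    """Non-overlapping object placement failed within the retry budget."""


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TissueProfile:
    """Generator setpoints for one tumour model's microscopy field."""

    name: str
    n_vessels: int
    costain_fractions: dict
    tam_area_fraction: float
    lymph_vessel_count: int
    nuclear_density: int
    field_size_px: tuple[int, int] = (512, 512)
    vessel_radius_px: tuple[float, float] = (3.0, 7.0)
    noise_amplitude: float = 0.2

    def __post_init__(self) -> None:
        if self.n_vessels < 0 or self.lymph_vessel_count < 0 or self.nuclear_density < 0:
            raise ValidationError("object counts must be non-negative")
        lo, hi = self.vessel_radius_px
        if not 0 < lo <= hi:
            raise ValidationError("vessel_radius_px must be a positive range")
        for ch, f in self.costain_fractions.items():
            if ch not in COSTAIN_CHANNELS:
                raise ValidationError(f"unknown co-stain channel {ch!r}")
            if not 0 <= f <= 1:
                raise ValidationError(f"co-stain fraction for {ch!r} outside [0,1]")
        if not 0 <= self.tam_area_fraction <= 1:
            raise ValidationError("tam_area_fraction outside [0,1]")
        if not 0 <= self.noise_amplitude < 0.5:
            raise ValidationError("noise_amplitude must lie in [0, 0.5)")
        if self.noise_amplitude >= DEFAULT_THRESHOLD:
            raise ValidationError("noise must stay below the segmentation threshold")
        h, w = self.field_size_px
        max_area = math.pi * hi * hi
        if self.n_vessels * max_area > 0.4 * h * w:
            raise ValidationError("vessels would cover >40% of the field; "
                                  "non-overlapping placement not guaranteed")


def _builtin(name, n_vessels, lectin, asma, vegfr2, coli, coliv, tam, lymph,
             nuclei) -> TissueProfile:
    return TissueProfile(
        name=name, n_vessels=n_vessels,
        costain_fractions={"lectin": lectin, "aSMA": asma, "VEGFR2": vegfr2,
                           "colI": coli, "colIV": coliv},
        tam_area_fraction=tam, lymph_vessel_count=lymph, nuclear_density=nuclei,
    )


#: Packaged per-model profiles for the three-model training panel.  Vessel
#: counts, perfused (lectin+) fractions and TAM area fractions follow the
#: published per-model means; co-stain fractions without a printed value are
#: plausible defaults (see docs/methods.md).
BUILTIN_PROFILES: dict[str, TissueProfile] = {
    "CT26": _builtin("CT26", 89, 0.549, 0.40, 0.35, 0.45, 0.55,
                     0.077, 22, 450),
    "A431": _builtin("A431", 28, 0.913, 0.55, 0.30, 0.50, 0.60,
                     0.022, 11, 500),
    "MLS": _builtin("MLS", 55, 0.627, 0.50, 0.32, 0.48, 0.58,
                    0.051, 12, 480),
}


@dataclass(frozen=True)
class ImageGroundTruth:
    """Exact rendered counts and fractions for one generated field."""

    object_count: dict
    area_fraction: dict
    double_positive_count: dict  # (channelA, channelB) -> int

    def to_json_dict(self) -> dict:
        return {
            "object_count": dict(self.object_count),
            "area_fraction": dict(self.area_fraction),
            "double_positive_count": {
                f"{a}|{b}": v for (a, b), v in self.double_positive_count.items()
            },
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "ImageGroundTruth":
        return cls(
            object_count=dict(d["object_count"]),
            area_fraction=dict(d["area_fraction"]),
            double_positive_count={
                tuple(k.split("|")): v
                for k, v in d["double_positive_count"].items()
            },
        )


# ---------------------------------------------------------------------------
# rendering helpers
# ---------------------------------------------------------------------------

def _place_ellipses(rng: np.random.Generator, n: int, shape: tuple[int, int],
                    radius_range: tuple[float, float]) -> list[tuple]:
    """Sample n mutually disjoint in-bounds ellipses by rejection sampling.

    Returns (row, col, r_radius, c_radius, rotation) tuples.  Disjointness
    (with a 3 px diagonal-safe gap) is enforced through bounding-circle
    separation, so segmentation under 8-connectivity can never merge two
    objects.
    """
    lo, hi = radius_range
    h, w = shape
    placed: list[tuple] = []
    retries = 0
    while len(placed) < n:
        if retries > _MAX_PLACEMENT_RETRIES:
            raise PlacementError(
                f"could not place {n} disjoint vessels in a {h}x{w} field"
            )
        a = rng.uniform(lo, hi)
        b = rng.uniform(lo, hi)
        theta = rng.uniform(0, math.pi)
        rmax = max(a, b)
        margin = rmax + 2
        r = rng.uniform(margin, h - margin)
        c = rng.uniform(margin, w - margin)
        ok = all(
            math.hypot(r - pr, c - pc) >= rmax + max(pa, pb) + 3
            for (pr, pc, pa, pb, _) in placed
        )
        if ok:
            placed.append((r, c, a, b, theta))
        else:
            retries += 1
    return placed


def _ellipse_mask(shape, ellipses) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for (r, c, a, b, theta) in ellipses:
        rr, cc = draw.ellipse(r, c, a, b, shape=shape, rotation=theta)
        mask[rr, cc] = True
    return mask


def _fill_blobs(rng: np.random.Generator, zone: np.ndarray,
                target_px: int) -> np.ndarray:
    """Pixel-exact blob fill: random disks clipped to ``zone`` until exactly
    ``target_px`` pixels are set (the last disk is trimmed)."""
    h, w = zone.shape
    mask = np.zeros_like(zone)
    placed = 0
    while placed < target_px:
        radius = rng.uniform(4, 12)
        r = rng.uniform(0, h)
        c = rng.uniform(0, w)
        rr, cc = draw.disk((r, c), radius, shape=zone.shape)
        keep = zone[rr, cc] & ~mask[rr, cc]
        rr, cc = rr[keep], cc[keep]
        need = target_px - placed
        if len(rr) > need:
            rr, cc = rr[:need], cc[:need]
        mask[rr, cc] = True
        placed += len(rr)
    return mask


def _count_components(mask: np.ndarray, min_size: int = DEFAULT_MIN_SIZE_PX) -> int:
    """8-connected component count, ignoring components below min_size."""
    labels, n = ndimage.label(mask, structure=_STRUCT8)
    if n == 0:
        return 0
    sizes = np.bincount(labels.ravel())[1:]
    return int(np.sum(sizes >= min_size))


# ---------------------------------------------------------------------------
# image generation
# ---------------------------------------------------------------------------

def make_tissue_image(profile: TissueProfile,
                      seed: int) -> tuple[StainedTissueImage, ImageGroundTruth]:
    """Render one multichannel field and its exact ground truth.

    The CD31 channel holds exactly ``profile.n_vessels`` disjoint filled
    ellipses; each co-stain channel re-renders ``round(fraction*n)`` of those
    same ellipses (chosen by seeded sampling without replacement).  The F4/80
    channel covers the requested area fraction exactly at the pixel level,
    both over the full field and over the central-quarter (emulated 20x)
    crop.  Uniform background noise (amplitude < segmentation threshold) is
    added to every channel last, so default-threshold segmentation recovers
    the noiseless masks exactly.
    """
    rng = np.random.default_rng(seed)
    shape = tuple(profile.field_size_px)
    h, w = shape

    vessels = _place_ellipses(rng, profile.n_vessels, shape,
                              profile.vessel_radius_px)
    masks: dict[str, np.ndarray] = {"CD31": _ellipse_mask(shape, vessels)}

    object_count = {"CD31": profile.n_vessels}
    double_positive_count = {}
    for ch in COSTAIN_CHANNELS:
        frac = profile.costain_fractions.get(ch, 0.0)
        k = round_half_up(frac * profile.n_vessels)
        idx = (rng.choice(profile.n_vessels, size=k, replace=False)
               if k > 0 else np.array([], dtype=int))
        masks[ch] = _ellipse_mask(shape, [vessels[i] for i in idx])
        object_count[ch] = k
        double_positive_count[("CD31", ch)] = k

    lymph = _place_ellipses(rng, profile.lymph_vessel_count, shape,
                            profile.vessel_radius_px)
    masks["LYVE1"] = _ellipse_mask(shape, lymph)
    object_count["LYVE1"] = profile.lymph_vessel_count

    # F4/80: exact pixel budgets inside and outside the central quarter so
    # both the 10x field and the emulated 20x crop see the target fraction.
    centre = np.zeros(shape, dtype=bool)
    centre[h // 4:h // 4 + h // 2, w // 4:w // 4 + w // 2] = True
    target_total = round_half_up(profile.tam_area_fraction * h * w)
    target_centre = round_half_up(profile.tam_area_fraction * int(centre.sum()))
    target_centre = min(target_centre, target_total)
    f480 = (_fill_blobs(rng, centre, target_centre)
            | _fill_blobs(rng, ~centre, target_total - target_centre))
    masks["F480"] = f480
    object_count["F480"] = _count_components(f480)

    nuclei = np.zeros(shape, dtype=bool)
    for _ in range(profile.nuclear_density):
        radius = rng.uniform(2.0, 3.0)
        r = rng.uniform(radius + 1, h - radius - 1)
        c = rng.uniform(radius + 1, w - radius - 1)
        rr, cc = draw.disk((r, c), radius, shape=shape)
        nuclei[rr, cc] = True
    masks["nuclei"] = nuclei
    object_count["nuclei"] = _count_components(nuclei)

    area_fraction = {ch: float(m.sum() / m.size) for ch, m in masks.items()}

    channels = {}
    for ch in CHANNEL_NAMES:
        img = np.where(masks[ch], FOREGROUND_INTENSITY, 0.0)
        if profile.noise_amplitude > 0:
            img = img + rng.uniform(0, profile.noise_amplitude, size=shape)
        channels[ch] = np.clip(img, 0.0, 1.0)

    image = StainedTissueImage(channels=channels)
    truth = ImageGroundTruth(object_count=object_count,
                             area_fraction=area_fraction,
                             double_positive_count=double_positive_count)
    return image, truth


# ---------------------------------------------------------------------------
# feature-table generation
# ---------------------------------------------------------------------------

OUTCOME_COLUMN = "accumulation_pct_id"

#: Causal features of the synthetic accumulation model.
CAUSAL_FEATURES = ("CD31 number", "F4/80 AF")


@dataclass(frozen=True)
class EffectConfig:
    """Statistical structure of the synthetic animal-panel feature table.

    Accumulation (%ID per 250 mm3) is an affine function of the CD31 vessel
    count and the F4/80 area fraction plus Gaussian noise; the remaining 21
    features are nuisance variables correlated with the causal ones at most
    at ``nuisance_correlation``.  Animals are cycled over the three-model
    training panel, so the causal features cluster around per-model means
    (per-animal vessel counts ~28/55/89, TAM AF ~2.2/5.1/7.7%) with
    between-animal spread inside each model; defaults give outcomes of
    roughly 4-11 %ID across 14 animals.
    """

    n_samples: int = 14
    beta_vessel: float = 0.05    # %ID per CD31+ vessel per field
    beta_tam: float = 50.0       # %ID per unit F4/80 area fraction
    intercept: float = 2.0       # %ID
    noise_sd: float = 0.3        # %ID
    missing_rate: float = 0.05
    nuisance_correlation: float = 0.5

    def __post_init__(self) -> None:
        if self.n_samples < 3:
            raise ValidationError("n_samples must be >= 3")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        if not 0 <= self.missing_rate < 1:
            raise ValidationError("missing_rate must lie in [0,1)")
        if not 0 <= self.nuisance_correlation < 1:
            raise ValidationError("nuisance_correlation must lie in [0,1)")


#: Per-animal causal-feature setpoints of the three-model training panel:
#: (vessel count mean, vessel count sd, TAM AF mean, TAM AF sd).  Vessel
#: means follow the per-model quantification; per-animal sds take the
#: image-level spread averaged over the twelve images analysed per tumour.
#: TAM sds reflect the large between-animal heterogeneity of macrophage
#: infiltration (CV roughly 25-55%).
_ANIMAL_PANEL = (
    (28.5, 4.4, 0.022, 0.012),   # A431-like: low vessels, low TAM
    (55.0, 8.0, 0.051, 0.015),   # MLS-like: intermediate
    (89.0, 10.4, 0.077, 0.018),  # CT26-like: high vessels, high TAM
)

# plausible (parent, mean, sd, low-clip, high-clip) per nuisance feature;
# parent picks which causal feature the nuisance correlates with
_NUISANCE_SCALES: dict[str, tuple[str, float, float, float, float]] = {
    "lectin number": ("vessel", 40.0, 15.0, 0.0, np.inf),
    "aSMA number": ("vessel", 30.0, 12.0, 0.0, np.inf),
    "VEGFR2 number": ("vessel", 20.0, 8.0, 0.0, np.inf),
    "LYVE-1 number": ("vessel", 14.0, 6.0, 0.0, np.inf),
    "Col I vessels number": ("vessel", 28.0, 10.0, 0.0, np.inf),
    "Col IV vessels number": ("vessel", 33.0, 11.0, 0.0, np.inf),
    "lectin vessels percentage": ("vessel", 0.65, 0.15, 0.0, 1.0),
    "aSMA vessels percentage": ("vessel", 0.50, 0.12, 0.0, 1.0),
    "VEGFR2 vessels percentage": ("vessel", 0.32, 0.08, 0.0, 1.0),
    "Col I vessels percentage": ("vessel", 0.48, 0.10, 0.0, 1.0),
    "Col IV vessels percentage": ("vessel", 0.57, 0.10, 0.0, 1.0),
    "CD31 AF": ("vessel", 0.035, 0.012, 0.0, 1.0),
    "lectin AF": ("vessel", 0.022, 0.008, 0.0, 1.0),
    "aSMA AF": ("vessel", 0.018, 0.007, 0.0, 1.0),
    "VEGFR2 AF": ("vessel", 0.012, 0.005, 0.0, 1.0),
    "LYVE-1 AF": ("vessel", 0.008, 0.004, 0.0, 1.0),
    "Col I AF": ("vessel", 0.020, 0.008, 0.0, 1.0),
    "Col IV AF": ("vessel", 0.024, 0.008, 0.0, 1.0),
    "F4/80 number": ("tam", 120.0, 40.0, 0.0, np.inf),
    "nuclei number": ("tam", 470.0, 60.0, 0.0, np.inf),
    "nuclei AF": ("tam", 0.12, 0.03, 0.0, 1.0),
}


def make_feature_dataset(cfg: EffectConfig, seed: int) -> pd.DataFrame:
    """Synthetic animals x (23 features + outcome) table with known effects."""
    rng = np.random.default_rng(seed)
    n = cfg.n_samples

    assign = [i % len(_ANIMAL_PANEL) for i in range(n)]
    vm, vs, tm, ts = (np.array([_ANIMAL_PANEL[a][k] for a in assign])
                      for k in range(4))
    vessel = np.clip(rng.normal(vm, vs), 0.0, None)
    tam = np.clip(rng.normal(tm, ts), 0.0, 1.0)

    def zscore(x):
        sd = x.std()
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    z = {"vessel": zscore(vessel), "tam": zscore(tam)}

    rho = cfg.nuisance_correlation
    data = {}
    for name in FEATURE_NAMES:
        if name == "CD31 number":
            data[name] = vessel
        elif name == "F4/80 AF":
            data[name] = tam
        else:
            parent, mean, sd, lo, hi = _NUISANCE_SCALES[name]
            eps = rng.standard_normal(n)
            vals = mean + sd * (rho * z[parent] + math.sqrt(1 - rho * rho) * eps)
            data[name] = np.clip(vals, lo, hi)

    outcome = (cfg.intercept + cfg.beta_vessel * vessel + cfg.beta_tam * tam)
    if cfg.noise_sd > 0:
        outcome = outcome + rng.normal(0, cfg.noise_sd, size=n)
    data[OUTCOME_COLUMN] = outcome

    table = pd.DataFrame(data, columns=list(FEATURE_NAMES) + [OUTCOME_COLUMN])
    if cfg.missing_rate > 0:
        mask = rng.uniform(size=(n, len(FEATURE_NAMES))) < cfg.missing_rate
        feat = table[list(FEATURE_NAMES)].to_numpy()
        feat[mask] = np.nan
        table[list(FEATURE_NAMES)] = feat
    return table


# ---------------------------------------------------------------------------
# observer-score generation and the ten-model fixture panel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelFixture:
    """One xenograft model with its accumulation class and consensus grades."""

    model_id: str
    truth_class: str             # "high" | "low"
    consensus_vessel_score: int
    consensus_tam_score: int

    def __post_init__(self) -> None:
        if self.truth_class not in ("high", "low"):
            raise ValidationError("truth_class must be 'high' or 'low'")
        for s in (self.consensus_vessel_score, self.consensus_tam_score):
            if not 1 <= s <= 4:
                raise ValidationError("consensus scores must lie in 1..4")

    @property
    def product(self) -> int:
        return self.consensus_vessel_score * self.consensus_tam_score


def default_fixtures() -> list[ModelFixture]:
    """The packaged ten-model panel (six PDX + four CDX), ordered by
    decreasing liposomal drug accumulation.

    SW620, A549 and Calu-6 are the low-accumulating models with product
    scores below the cutoff (true negatives); E35CR accumulates strongly but
    scores (vessel 3, TAM 1) -> product 3, the designated false negative; the
    remaining six high accumulators score at or above the cutoff.
    """
    return [
        ModelFixture("E35CR", "high", 3, 1),
        ModelFixture("Calu-3", "high", 4, 4),
        ModelFixture("OVFX899", "high", 4, 3),
        ModelFixture("LXFE2257", "high", 3, 3),
        ModelFixture("CFX1297", "high", 4, 2),
        ModelFixture("RXF423", "high", 3, 3),
        ModelFixture("E77", "high", 4, 2),
        ModelFixture("SW620", "low", 2, 2),
        ModelFixture("A549", "low", 1, 2),
        ModelFixture("Calu-6", "low", 2, 1),
    ]


def make_observer_scores(fixtures: list[ModelFixture], n_observers: int,
                         n_sections: int, observer_sd: float,
                         seed: int) -> ObserverScoreMatrix:
    """Ordinal scores from blinded observers grading sections of each model.

    Each score perturbs the model's consensus grade with Gaussian noise of
    sd ``observer_sd`` on the latent scale, rounds to the nearest integer and
    clamps to [1, 4]; ``observer_sd = 0`` reproduces the consensus exactly.
    """
    if not fixtures:
        raise ValidationError("fixture list is empty")
    if n_observers < 1 or n_sections < 1:
        raise ValidationError("need >= 1 observer and >= 1 section")
    if observer_sd < 0:
        raise ValidationError("observer_sd must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    for fx in fixtures:
        for marker, base in (("vessel", fx.consensus_vessel_score),
                             ("TAM", fx.consensus_tam_score)):
            latent = base + (rng.normal(0, observer_sd,
                                        size=(n_observers, n_sections))
                             if observer_sd > 0
                             else np.zeros((n_observers, n_sections)))
            scores = np.clip(np.rint(latent), 1, 4).astype(int)
            for o in range(n_observers):
                for s in range(n_sections):
                    rows.append((fx.model_id, o + 1, s + 1, marker,
                                 scores[o, s]))
    return ObserverScoreMatrix(pd.DataFrame(
        rows, columns=["model", "observer", "section", "marker", "score"]
    ))


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def write_image(image: StainedTissueImage, truth: ImageGroundTruth,
                profile: TissueProfile, directory, sample: str) -> list[Path]:
    """Write one 16-bit TIFF per channel plus a JSON ground-truth sidecar."""
    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for ch, arr in image.channels.items():
        path = directory / f"{sample}_{ch}.tif"
        tifffile.imwrite(path, np.round(arr * 65535).astype(np.uint16))
        paths.append(path)
    sidecar = directory / f"{sample}_truth.json"
    payload = {"profile": asdict(profile), "ground_truth": truth.to_json_dict()}
    sidecar.write_text(json.dumps(payload, indent=1, sort_keys=True))
    paths.append(sidecar)
    return paths


def read_ground_truth(directory, sample: str) -> ImageGroundTruth:
    path = Path(directory) / f"{sample}_truth.json"
    payload = json.loads(path.read_text())
    return ImageGroundTruth.from_json_dict(payload["ground_truth"])


def profile_from_dict(d: dict) -> TissueProfile:
    d = dict(d)
    for key in ("field_size_px", "vessel_radius_px"):
        if key in d:
            d[key] = tuple(d[key])
    return TissueProfile(**d)


def load_profiles_yaml(path) -> dict[str, TissueProfile]:
    """Read a YAML mapping of profile name -> TissueProfile fields."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    profiles = {}
    for name, fields in raw.items():
        fields.setdefault("name", name)
        profiles[name] = profile_from_dict(fields)
    return profiles
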