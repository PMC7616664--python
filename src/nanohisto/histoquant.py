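"""Quantification of tumour-microenvironment biomarkers from stained tissue.

Implements the image operations a histopathology quantification workflow
needs to turn multichannel stained-tissue rasters into a feature table:
threshold segmentation with connected-component labelling, object counting,
marker area fractions, double-positive (co-stain) fractions, and the
assembly of a 23-feature tumour-microenvironment panel per field.  Also
provides the accumulation-side helpers: normalization of %ID readouts to a
250 mm3 reference tumour volume, trapezoidal area under a drug
concentration-time curve, and ordinary-least-squares trendlines with R2.

Feature panel
-------------
The panel covers four biology categories: vasculature (CD31 total vessels,
lectin-perfused vessels, aSMA pericyte-supported vessels, VEGFR2 angiogenic
vessels, LYVE-1 lymphatics), stroma (collagen I / collagen IV vessels),
macrophages (F4/80) and cellularity (nuclear staining).  Each feature is an
absolute object count per field, a marker area fraction, or a relative
fraction of CD31+ vessels co-labelled by a second marker.  Vessel counts for
CD31/lectin/aSMA and the collagen channels use the full 10x field; VEGFR2,
LYVE-1, F4/80 and nuclear features use a 20x basis, emulated as the central
quarter crop of the 10x field.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skimage import measure

from .scoring import ValidationError

DEFAULT_THRESHOLD = 0.5
DEFAULT_MIN_SIZE_PX = 8

#: %ID readouts are normalized to this reference tumour volume.
REFERENCE_VOLUME_MM3 = 250.0


# ---------------------------------------------------------------------------
# image container (produced by nanohisto.synthgen, consumed here)
# ---------------------------------------------------------------------------

CHANNEL_NAMES = (
    "CD31", "lectin", "aSMA", "VEGFR2", "LYVE1", "colI", "colIV", "F480",
    "nuclei",
)


@dataclass
class StainedTissueImage:
    """One multichannel microscopy field with intensities in [0, 1]."""

    channels: dict[str, np.ndarray]
    pixel_size_um: float = 0.65
    magnification_tag: str = "10x"

    def __post_init__(self) -> None:
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise ValidationError("all channels must share one shape")
        for name, ch in self.channels.items():
            if ch.min() < 0 or ch.max() > 1:
                raise ValidationError(f"channel {name!r} outside [0,1]")
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def central_quarter(self) -> "StainedTissueImage":
        """Central half-height x half-width crop, the emulated 20x view."""
        h, w = self.shape
        sl = (slice(h // 4, h // 4 + h // 2), slice(w // 4, w // 4 + w // 2))
        return StainedTissueImage(
            channels={k: v[sl] for k, v in self.channels.items()},
            pixel_size_um=self.pixel_size_um / 2,
            magnification_tag="20x",
        )


# ---------------------------------------------------------------------------
# feature registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureSpec:
    """One panel member: what is measured, from which channels, at which basis."""

    name: str
    category: str                 # vascular | stroma | macrophage | cellularity
    mode: str                     # absolute_count | area_fraction | relative_fraction
    magnification_basis: str      # 10x | 20x
    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.mode == "relative_fraction" and len(self.channels) != 2:
            raise ValidationError(
                f"{self.name}: relative_fraction needs exactly two channels"
            )
        if self.mode in ("absolute_count", "area_fraction") and len(self.channels) != 1:
            raise ValidationError(f"{self.name}: needs exactly one channel")


def _spec(name, category, mode, mag, *channels) -> FeatureSpec:
    return FeatureSpec(name, category, mode, mag, tuple(channels))


#: The default 23-feature tumour-microenvironment panel.  Features named in
#: the biology (counts, relative co-stain fractions, area fractions); users
#: may pass their own panel definition to :func:`compute_feature_panel`.
FEATURE_PANEL: tuple[FeatureSpec, ...] = (
    _spec("CD31 number", "vascular", "absolute_count", "10x", "CD31"),
    _spec("lectin number", "vascular", "absolute_count", "10x", "lectin"),
    _spec("aSMA number", "vascular", "absolute_count", "10x", "aSMA"),
    _spec("VEGFR2 number", "vascular", "absolute_count", "20x", "VEGFR2"),
    _spec("LYVE-1 number", "vascular", "absolute_count", "20x", "LYVE1"),
    _spec("Col I vessels number", "stroma", "absolute_count", "10x", "colI"),
    _spec("Col IV vessels number", "stroma", "absolute_count", "10x", "colIV"),
    _spec("lectin vessels percentage", "vascular", "relative_fraction", "10x",
          "CD31", "lectin"),
    _spec("aSMA vessels percentage", "vascular", "relative_fraction", "10x",
          "CD31", "aSMA"),
    _spec("VEGFR2 vessels percentage", "vascular", "relative_fraction", "20x",
          "CD31", "VEGFR2"),
    _spec("Col I vessels percentage", "stroma", "relative_fraction", "10x",
          "CD31", "colI"),
    _spec("Col IV vessels percentage", "stroma", "relative_fraction", "10x",
          "CD31", "colIV"),
    _spec("CD31 AF", "vascular", "area_fraction", "10x", "CD31"),
    _spec("lectin AF", "vascular", "area_fraction", "10x", "lectin"),
    _spec("aSMA AF", "vascular", "area_fraction", "10x", "aSMA"),
    _spec("VEGFR2 AF", "vascular", "area_fraction", "20x", "VEGFR2"),
    _spec("LYVE-1 AF", "vascular", "area_fraction", "20x", "LYVE1"),
    _spec("Col I AF", "stroma", "area_fraction", "10x", "colI"),
    _spec("Col IV AF", "stroma", "area_fraction", "10x", "colIV"),
    _spec("F4/80 AF", "macrophage", "area_fraction", "20x", "F480"),
    _spec("F4/80 number", "macrophage", "absolute_count", "20x", "F480"),
    _spec("nuclei number", "cellularity", "absolute_count", "20x", "nuclei"),
    _spec("nuclei AF", "cellularity", "area_fraction", "20x", "nuclei"),
)

FEATURE_NAMES: tuple[str, ...] = tuple(s.name for s in FEATURE_PANEL)

assert len(FEATURE_PANEL) == 23
assert len(set(FEATURE_NAMES)) == 23


# ---------------------------------------------------------------------------
# segmentation and per-channel quantities
# ---------------------------------------------------------------------------

def segment_channel(image: StainedTissueImage, channel: str,
                    threshold: float = DEFAULT_THRESHOLD,
                    min_size_px: int = DEFAULT_MIN_SIZE_PX) -> np.ndarray:
    """Label supra-threshold connected components (8-connectivity).

    Components smaller than ``min_size_px`` pixels are discarded; surviving
    components get labels 1..n, background 0.
    """
    if not 0 < threshold < 1:
        raise ValidationError("threshold must lie strictly in (0,1)")
    mask = image.channels[channel] >= threshold
    labels = measure.label(mask, connectivity=2)
    if min_size_px > 1 and labels.max() > 0:
        sizes = np.bincount(labels.ravel())
        keep = sizes >= min_size_px
        keep[0] = False
        remap = np.zeros(len(sizes), dtype=labels.dtype)
        remap[keep] = np.arange(1, int(keep.sum()) + 1)
        labels = remap[labels]
    return labels


def count_objects(labels: np.ndarray) -> int:
    """Number of distinct positive labels in a label map."""
    return int(labels.max()) and len(np.unique(labels[labels > 0]))


def area_fraction(image: StainedTissueImage, channel: str,
                  threshold: float = DEFAULT_THRESHOLD) -> float:
    """Fraction of pixels at or above ``threshold`` in one channel."""
    ch = image.channels[channel]
    return float(np.count_nonzero(ch >= threshold) / ch.size)


def double_positive(labelsA: np.ndarray, image: StainedTissueImage,
                    channelB: str, threshold: float = DEFAULT_THRESHOLD,
                    overlap_frac: float = 0.3) -> tuple[int, float]:
    """Count A-objects co-labelled by channel B.

    An object from ``labelsA`` is B-positive when at least ``overlap_frac``
    of its pixels are supra-threshold in B (default 30%, robust to rim
    effects on ring-shaped vessels).  Returns ``(count, count / n_objects)``;
    the fraction is 0 when there are no A-objects.
    """
    if not 0 < overlap_frac <= 1:
        raise ValidationError("overlap_frac must lie in (0,1]")
    n = int(labelsA.max())
    if n == 0:
        return 0, 0.0
    maskB = image.channels[channelB] >= threshold
    sizes = np.bincount(labelsA.ravel(), minlength=n + 1)[1:]
    overlaps = np.bincount(labelsA.ravel(), weights=maskB.ravel().astype(float),
                           minlength=n + 1)[1:]
    count = int(np.sum(overlaps >= overlap_frac * sizes))
    return count, count / n


def compute_feature_panel(image: StainedTissueImage,
                          spec: Sequence[FeatureSpec] = FEATURE_PANEL,
                          params: Mapping | None = None) -> pd.Series:
    """One feature-table row for a field, in canonical panel order.

    ``params`` may override ``threshold``, ``min_size_px`` and
    ``overlap_frac``.  A feature whose channel is absent from the image is
    recorded as missing (NaN) rather than raising, so downstream learners
    exercise their missing-data handling.
    """
    p = dict(params or {})
    threshold = p.get("threshold", DEFAULT_THRESHOLD)
    min_size = p.get("min_size_px", DEFAULT_MIN_SIZE_PX)
    overlap = p.get("overlap_frac", 0.3)

    views = {"10x": image, "20x": image.central_quarter()}
    label_cache: dict[tuple[str, str], np.ndarray] = {}

    def labels_for(basis: str, channel: str) -> np.ndarray:
        key = (basis, channel)
        if key not in label_cache:
            label_cache[key] = segment_channel(views[basis], channel,
                                               threshold, min_size)
        return label_cache[key]

    values: dict[str, float] = {}
    for fs in spec:
        view = views[fs.magnification_basis]
        if any(ch not in view.channels for ch in fs.channels):
            values[fs.name] = np.nan
            continue
        if fs.mode == "absolute_count":
            values[fs.name] = float(count_objects(
                labels_for(fs.magnification_basis, fs.channels[0])))
        elif fs.mode == "area_fraction":
            values[fs.name] = area_fraction(view, fs.channels[0], threshold)
        else:  # relative_fraction
            labA = labels_for(fs.magnification_basis, fs.channels[0])
            _, frac = double_positive(labA, view, fs.channels[1],
                                      threshold, overlap)
            values[fs.name] = frac
    return pd.Series(values, index=[fs.name for fs in spec])


# ---------------------------------------------------------------------------
# accumulation-side helpers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AccumulationRecord:
    """Tumour accumulation of a nanocarrier for one animal."""

    raw_pct_id: float
    tumour_volume_mm3: float
    normalized_pct_id: float
    auc_drug: float = 0.0

    def __post_init__(self) -> None:
        if self.tumour_volume_mm3 <= 0:
            raise ValidationError("tumour volume must be positive")
        if self.auc_drug < 0:
            raise ValidationError("auc_drug must be non-negative")


def normalize_accumulation(raw_pct_id: float, tumour_volume_mm3: float) -> float:
    """Rescale a %ID readout linearly to the 250 mm3 reference volume."""
    if tumour_volume_mm3 <= 0:
        raise ValidationError("tumour volume must be positive")
    return raw_pct_id * (REFERENCE_VOLUME_MM3 / tumour_volume_mm3)


def auc_time(timepoints, concentrations) -> float:
    """Trapezoidal area under a concentration-time curve (e.g. AUC 0-120 h)."""
    t = np.asarray(timepoints, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if t.ndim != 1 or t.shape != c.shape or len(t) < 2:
        raise ValidationError("need >= 2 aligned timepoints")
    if not np.all(np.diff(t) > 0):
        raise ValidationError("timepoints must be strictly increasing")
    if np.any(c < 0):
        raise ValidationError("concentrations must be non-negative")
    return float(np.trapezoid(c, t))


def linear_fit(x, y) -> tuple[float, float, float]:
    """Ordinary-least-squares trendline: (slope, intercept, r_squared)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or x.shape != y.shape:
        raise ValidationError("need >= 3 aligned points")
    if np.ptp(x) == 0:
        raise ValidationError("x is constant; degenerate fit")
    if np.ptp(y) == 0:
        return 0.0, float(y.mean()), 0.0
    res = stats.linregress(x, y)
    # for OLS, 1 - SS_res/SS_tot equals the squared correlation
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)


# ---------------------------------------------------------------------------
# file I/O (synthgen TIFF + JSON sidecar layout)
# ---------------------------------------------------------------------------

def read_image_dir(directory, sample: str) -> StainedTissueImage:
    """Load ``<sample>_<channel>.tif`` rasters back into a field image."""
    import tifffile

    directory = Path(directory)
    channels = {}
    for ch in CHANNEL_NAMES:
        path = directory / f"{sample}_{ch}.tif"
        if path.exists():
            raw = tifffile.imread(path)
            scale = float(np.iinfo(raw.dtype).max) if raw.dtype.kind == "u" else 1.0
            channels[ch] = raw.astype(float) / scale
    if not channels:
        raise FileNotFoundError(f"no channel TIFFs for sample {sample!r} in {directory}")
    return StainedTissueImage(channels=channels)
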