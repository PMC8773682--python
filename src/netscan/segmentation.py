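"""Primary object identification on the all-nuclei (Hoechst) channel.

The intent of the assay is to capture *every* Hoechst-positive object,
including dim spent nuclei of NET-forming cells: the automatic Otsu
threshold is therefore multiplied by a scale < 1 (default 0.6) so that the
dimmest nuclei stay above threshold.  Touching nuclei are split by a
watershed on the negated Euclidean distance transform, with seeds taken as
distance-transform maxima separated by at least the expected nuclear radius
(the "segmentation" dial).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from skimage import feature, filters, measure, morphology, segmentation as sks

from .imaging_io import ChannelImage


class DegenerateImageError(ValueError):
    """Image has no foreground/background separation (e.g. constant)."""


class ThresholdMethod(str, enum.Enum):
    OTSU_SCALED = "OTSU_SCALED"
    FIXED = "FIXED"


@dataclass
class SegmentationParams:
    threshold_method: ThresholdMethod = ThresholdMethod.OTSU_SCALED
    threshold_scale: float = 0.6
    fixed_threshold: Optional[float] = None
    segmentation_radius_um: float = 4.0   # expected nuclear radius; seed spacing
    min_object_area_um2: float = 12.0
    exclude_border: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.threshold_scale <= 2:
            raise ValueError("threshold_scale must be in (0, 2]")
        if self.segmentation_radius_um <= 0:
            raise ValueError("segmentation_radius_um must be positive")
        if self.min_object_area_um2 <= 0:
            raise ValueError("min_object_area_um2 must be positive")


@dataclass
class LabeledMask:
    """Densely labeled nuclei: 0 = background, labels 1..n_objects.

    ``border_labels`` holds labels of objects touching the image edge; they
    remain in the mask (and the object table, flagged) but are excluded from
    quantification when ``exclude_border`` is set.
    """

    labels: np.ndarray
    n_objects: int
    border_labels: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        present = np.unique(self.labels)
        present = present[present > 0]
        if len(present) != self.n_objects or (
            len(present) and present[-1] != self.n_objects
        ):
            raise ValueError("labels must be exactly {1..n_objects}")

    @property
    def interior_labels(self) -> list[int]:
        return [k for k in range(1, self.n_objects + 1)
                if k not in self.border_labels]


def compute_threshold(img: ChannelImage, params: SegmentationParams) -> float:
    """Intensity threshold for the foreground of a channel.

    OTSU_SCALED: Otsu's between-class-variance split times
    ``threshold_scale``.  FIXED: the configured value, unscaled.
    """
    if params.threshold_method is ThresholdMethod.FIXED:
        if params.fixed_threshold is None:
            raise ValueError("FIXED threshold method requires fixed_threshold")
        return float(params.fixed_threshold)
    pixels = np.asarray(img.pixels, dtype=np.float64)
    if pixels.size == 0:
        raise ValueError("empty image")
    if np.ptp(pixels) == 0:
        raise DegenerateImageError(
            "constant image: no foreground/background separation"
        )
    return float(filters.threshold_otsu(pixels)) * params.threshold_scale


def _watershed_split(
    fg: np.ndarray, radius_px: float, h: float = 0.5
) -> np.ndarray:
    """Split touching objects in a binary mask by distance-transform
    watershed.  Every 8-connected component is guaranteed at least one seed
    (its distance-transform argmax), so components are never lost."""
    cc = measure.label(fg, connectivity=2)
    edt = ndi.distance_transform_edt(fg)
    # h-maxima suppression removes shallow maxima (noise on the ridge)
    suppressed = morphology.reconstruction(
        np.clip(edt - h, 0, None), edt, method="dilation"
    )
    coords = feature.peak_local_max(
        suppressed,
        min_distance=max(1, int(round(radius_px))),
        labels=cc,
        exclude_border=False,
    )
    # deterministic seed order: scan order of the coordinates
    coords = coords[np.lexsort((coords[:, 1], coords[:, 0]))]
    seeded = set(cc[tuple(coords.T)].tolist()) if len(coords) else set()
    extra = []
    for comp in range(1, cc.max() + 1):
        if comp not in seeded:
            flat = np.where(cc.ravel() == comp, edt.ravel(), -1.0)
            extra.append(np.unravel_index(int(np.argmax(flat)), cc.shape))
    if extra:
        coords = np.vstack([coords, np.array(extra)]) if len(coords) else np.array(extra)
        coords = coords[np.lexsort((coords[:, 1], coords[:, 0]))]
    markers = np.zeros(fg.shape, dtype=np.int32)
    for i, (r, c) in enumerate(coords, start=1):
        markers[r, c] = i
    return sks.watershed(-edt, markers=markers, mask=fg, connectivity=2)


def identify_primary_objects(
    img: ChannelImage, params: SegmentationParams
) -> LabeledMask:
    """Threshold the preprocessed nucleus channel and label individual
    nuclei.

    Foreground pixels are those at or above the computed threshold; touching
    nuclei are split by the watershed; objects smaller than
    ``min_object_area_um2`` are dropped; objects touching the image edge are
    flagged as border objects.  Labels are relabeled densely in scan order,
    making the output deterministic.
    """
    thr = compute_threshold(img, params)
    fg = np.asarray(img.pixels) >= thr
    radius_px = params.segmentation_radius_um / img.pixel_size_um
    labels = _watershed_split(fg, radius_px)

    min_px = params.min_object_area_um2 / img.pixel_area_um2
    counts = np.bincount(labels.ravel(), minlength=labels.max() + 1)
    keep = counts >= min_px
    keep[0] = False
    labels = np.where(keep[labels], labels, 0)

    # dense relabel; ascending seed order keeps the result deterministic
    survivors = np.unique(labels)
    survivors = survivors[survivors > 0]
    lut = np.zeros(labels.max() + 1, dtype=np.int32)
    lut[survivors] = np.arange(1, len(survivors) + 1)
    labels = lut[labels]
    n = len(survivors)

    border = set(np.unique(labels[0, :])) | set(np.unique(labels[-1, :])) \
        | set(np.unique(labels[:, 0])) | set(np.unique(labels[:, -1]))
    border.discard(0)
    return LabeledMask(
        labels=labels, n_objects=n,
        border_labels=frozenset(int(b) for b in border),
    )


def identify_ch2_foreground(img: ChannelImage, threshold: float) -> np.ndarray:
    """Binary mask of impermeable-dye-positive pixels.

    No size filtering: NET clouds can be diffuse and must keep their full
    footprint.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return np.asarray(img.pixels) >= threshold


def robust_foreground_threshold(
    img: ChannelImage, n_sigma: float = 8.0
) -> float:
    """Noise-floor threshold: median + n_sigma robust-SD (1.4826 * MAD).

    Suited to the impermeable-DNA channel, where most pixels are background
    regardless of treatment, so a bimodal split is not guaranteed.
    """
    pixels = np.asarray(img.pixels, dtype=np.float64).ravel()
    med = float(np.median(pixels))
    mad = float(np.median(np.abs(pixels - med)))
    return med + n_sigma * 1.4826 * max(mad, 1.0)
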