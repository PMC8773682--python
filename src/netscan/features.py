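"""Per-object measurement of the gating features.

Each nucleus gets a *modified target region*: its nuclear mask dilated by a
fixed radius, large enough that the decondensed DNA cloud of a NET-forming
cell stays inside its own region.  Where dilations of neighbouring objects
overlap, contested pixels go to the nearer object centroid, so target
regions always partition their union and measurements remain single-cell.

The two features that drive classification are measured inside this region
on the impermeable-DNA channel (Ch2):

* ``target_area_ch2_um2`` — area of Ch2-foreground pixels in the region
  (the decondensed-chromatin footprint);
* ``avg_intensity_ch2`` — mean background-corrected Ch2 intensity over the
  whole region, sensitive to both brightness and spatial extent.

Four-channel mode adds two Annexin V descriptors: a ring ratio (boundary
shell over eroded interior) that is high for surface-localized apoptotic
staining, and a coefficient of variation that is high for the punctate
staining of lysed NET-forming cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage as ndi

from .imaging_io import ChannelImage, ChannelRole, ConfigurationError, FieldImage
from .segmentation import LabeledMask

#: Column order of the exported per-object table.
CELL_TABLE_COLUMNS = [
    "object_id", "well_id", "field_index", "time_point_min",
    "centroid_row", "centroid_col", "area_ch1_um2", "target_area_ch2_um2",
    "avg_intensity_ch2", "avg_intensity_ch1", "annexin_ring_ratio",
    "annexin_cv", "border",
]


@dataclass
class TargetMaskParams:
    """Geometry of the per-object measurement regions, in micrometres.

    ``dilation_um`` controls the Ch2 target region (default 8 um: several-
    fold nuclear expansion of a NET still fits).  ``annexin_dilation_um`` is
    a smaller dilation used only for the Annexin descriptors, so the
    boundary shell of that region sits near the plasma membrane where
    surface Annexin V accumulates.  ``shell_width_um`` is the width of that
    boundary shell.
    """

    dilation_um: float = 8.0
    shell_width_um: float = 1.5
    annexin_dilation_um: float = 2.0

    def __post_init__(self) -> None:
        if self.dilation_um < 0 or self.annexin_dilation_um < 0:
            raise ValueError("dilation radii must be >= 0")
        if self.shell_width_um <= 0:
            raise ValueError("shell_width_um must be positive")


@dataclass
class CellRecord:
    object_id: int
    well_id: str
    field_index: int
    time_point_min: float
    centroid_row: float
    centroid_col: float
    area_ch1_um2: float
    target_area_ch2_um2: float
    avg_intensity_ch2: float
    avg_intensity_ch1: float
    annexin_ring_ratio: Optional[float] = None
    annexin_cv: Optional[float] = None
    border: bool = False


def build_target_mask(
    mask: LabeledMask, params: TargetMaskParams,
    pixel_size_um: float, dilation_um: Optional[float] = None,
) -> LabeledMask:
    """Dilate every object by ``dilation_um`` (default: params.dilation_um).

    The union of the target regions is the union of the Euclidean dilations;
    a pixel covered by more than one dilation is assigned to the object with
    the nearer centroid (ties to the lower label), so the regions partition
    the union.
    """
    radius_um = params.dilation_um if dilation_um is None else dilation_um
    r_px = radius_um / pixel_size_um
    labels = mask.labels
    if r_px == 0 or mask.n_objects == 0:
        return LabeledMask(labels.copy(), mask.n_objects, mask.border_labels)

    centroids = ndi.center_of_mass(
        labels > 0, labels, index=range(1, mask.n_objects + 1)
    )
    out = np.zeros_like(labels, dtype=np.int32)
    coverage = np.zeros_like(labels, dtype=np.int16)
    pad = int(np.ceil(r_px)) + 1
    slices = ndi.find_objects(labels)
    dilated_boxes = []
    for k, sl in enumerate(slices, start=1):
        if sl is None:
            dilated_boxes.append(None)
            continue
        rs = slice(max(0, sl[0].start - pad), min(labels.shape[0], sl[0].stop + pad))
        cs = slice(max(0, sl[1].start - pad), min(labels.shape[1], sl[1].stop + pad))
        box = labels[rs, cs] == k
        # Euclidean dilation: distance-to-object <= r
        dist = ndi.distance_transform_edt(~box)
        dil = dist <= r_px
        dilated_boxes.append((rs, cs, dil))
        coverage[rs, cs] += dil
        out[rs, cs] = np.where(dil, k, out[rs, cs])

    contested = coverage > 1
    if contested.any():
        rows, cols = np.nonzero(contested)
        best_label = np.zeros(len(rows), dtype=np.int32)
        best_dist = np.full(len(rows), np.inf)
        for k, entry in enumerate(dilated_boxes, start=1):
            if entry is None:
                continue
            rs, cs, dil = entry
            inbox = (
                (rows >= rs.start) & (rows < rs.stop)
                & (cols >= cs.start) & (cols < cs.stop)
            )
            idx = np.nonzero(inbox)[0]
            covered = dil[rows[idx] - rs.start, cols[idx] - cs.start]
            idx = idx[covered]
            cy, cx = centroids[k - 1]
            d = (rows[idx] - cy) ** 2 + (cols[idx] - cx) ** 2
            better = d < best_dist[idx]  # strict: ties keep the lower label
            upd = idx[better]
            best_label[upd] = k
            best_dist[upd] = d[better]
        out[rows, cols] = best_label
    return LabeledMask(out, mask.n_objects, mask.border_labels)


def measure_objects(
    field: FieldImage,
    nuclei: LabeledMask,
    targets: LabeledMask,
    ch2_foreground: np.ndarray,
    params: TargetMaskParams,
    ch2_corrected: Optional[ChannelImage] = None,
    ch1_corrected: Optional[ChannelImage] = None,
    annexin_targets: Optional[LabeledMask] = None,
    annexin_corrected: Optional[ChannelImage] = None,
) -> list[CellRecord]:
    """One CellRecord per nucleus label, sorted by object id.

    Intensities are taken from the background-corrected (unsmoothed) channel
    images when given, else from the raw field channels.
    """
    if nuclei.labels.shape != field.shape or targets.labels.shape != field.shape:
        raise ValueError("mask dimensions do not match the field")
    if np.asarray(ch2_foreground).shape != field.shape:
        raise ValueError("ch2_foreground dimensions do not match the field")

    px_area = field.channels[ChannelRole.NUCLEUS_ALL].pixel_area_um2
    ch1 = (ch1_corrected or field.channels[ChannelRole.NUCLEUS_ALL]).pixels
    ch2_img = ch2_corrected or field.channels.get(ChannelRole.IMPERMEABLE_DNA)
    ch2 = None if ch2_img is None else np.asarray(ch2_img.pixels, dtype=np.float64)

    n = nuclei.n_objects
    index = range(1, n + 1)
    if n == 0:
        return []

    nuc_areas = ndi.sum_labels(np.ones_like(nuclei.labels), nuclei.labels, index)
    centroids = ndi.center_of_mass(nuclei.labels > 0, nuclei.labels, index)
    mean_ch1 = ndi.mean(np.asarray(ch1, dtype=np.float64), nuclei.labels, index)

    tlab = targets.labels
    tgt_sizes = ndi.sum_labels(np.ones_like(tlab), tlab, index)
    if ch2 is not None:
        fg = np.asarray(ch2_foreground, dtype=bool)
        tgt_fg = ndi.sum_labels(fg.astype(np.float64), tlab, index)
        mean_ch2 = np.where(
            tgt_sizes > 0, ndi.mean(ch2, tlab, index), 0.0
        )
    else:
        tgt_fg = np.zeros(n)
        mean_ch2 = np.zeros(n)

    ann: Optional[tuple[np.ndarray, np.ndarray]] = None
    if annexin_corrected is not None:
        ann = annexin_descriptors(
            field, nuclei, annexin_targets or targets, params,
            annexin_corrected=annexin_corrected,
        )

    records = []
    for i, k in enumerate(index):
        records.append(
            CellRecord(
                object_id=k,
                well_id=field.well_id,
                field_index=field.field_index,
                time_point_min=field.time_point_min,
                centroid_row=float(centroids[i][0]),
                centroid_col=float(centroids[i][1]),
                area_ch1_um2=float(nuc_areas[i]) * px_area,
                target_area_ch2_um2=float(tgt_fg[i]) * px_area,
                avg_intensity_ch2=float(mean_ch2[i]),
                avg_intensity_ch1=float(mean_ch1[i]),
                annexin_ring_ratio=None if ann is None else float(ann[0][i]),
                annexin_cv=None if ann is None else float(ann[1][i]),
                border=k in nuclei.border_labels,
            )
        )
    return records


RING_EPSILON = 1.0  # intensity units; stabilizes the ratio on dark interiors


def annexin_descriptors(
    field: FieldImage,
    nuclei: LabeledMask,
    targets: LabeledMask,
    params: TargetMaskParams,
    annexin_corrected: Optional[ChannelImage] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-object (ring_ratio, cv) of the Annexin V channel.

    ring_ratio = mean Annexin in the boundary shell of the target region
    (outermost ``shell_width_um`` band) over mean Annexin in the eroded
    interior, with a small additive stabilizer on the denominator.  Surface-
    localized staining gives ratios well above 1.  cv = std/mean over the
    whole target region; punctate staining gives high cv.
    """
    src = annexin_corrected or field.channels.get(ChannelRole.ANNEXIN)
    if src is None:
        raise ConfigurationError("ANNEXIN channel required for annexin_descriptors")
    ann = np.asarray(src.pixels, dtype=np.float64)

    shell_px = max(1, int(round(params.shell_width_um / field.pixel_size_um)))
    tlab = targets.labels
    # erode each target region: pixels farther than shell_px from its border
    interior = np.zeros_like(tlab)
    struct = ndi.generate_binary_structure(2, 2)
    eroded = ndi.binary_erosion(
        tlab > 0, structure=struct, iterations=shell_px, border_value=1
    )
    # per-label erosion must not leak across touching regions: a pixel is
    # interior only if its whole neighbourhood (within shell) has its label
    same = ndi.minimum_filter(
        np.where(tlab > 0, tlab, np.iinfo(np.int32).max),
        size=2 * shell_px + 1,
    ) == np.where(tlab > 0, tlab, -1)
    interior = np.where(eroded & same, tlab, 0)
    shell = np.where((tlab > 0) & (interior == 0), tlab, 0)

    n = targets.n_objects
    index = range(1, n + 1)
    ring = np.zeros(n)
    cv = np.zeros(n)
    if n == 0:
        return ring, cv
    shell_mean = _safe_mean(ann, shell, index)
    int_mean = _safe_mean(ann, interior, index)
    ring = shell_mean / (int_mean + RING_EPSILON)
    tgt_mean = _safe_mean(ann, tlab, index)
    tgt_std = np.sqrt(np.maximum(_safe_var(ann, tlab, index), 0.0))
    cv = np.where(tgt_mean > 0, tgt_std / np.maximum(tgt_mean, RING_EPSILON), 0.0)
    return ring, cv


def _safe_mean(img: np.ndarray, labels: np.ndarray, index) -> np.ndarray:
    counts = ndi.sum_labels(np.ones_like(labels), labels, index)
    sums = ndi.sum_labels(img, labels, index)
    return np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)


def _safe_var(img: np.ndarray, labels: np.ndarray, index) -> np.ndarray:
    counts = ndi.sum_labels(np.ones_like(labels), labels, index)
    out = np.zeros(len(counts))
    ok = counts > 0
    if ok.any():
        var = ndi.variance(img, labels, np.asarray(list(index))[ok])
        out[ok] = var
    return out
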