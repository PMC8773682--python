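"""Event classification: NET-forming, other death, live.

The assay distinguishes three populations on two per-object features of the
membrane-impermeable DNA channel (Ch2):

* **Type 1 (NET)** — Ch2-positive *and* enlarged decondensed chromatin:
  ``avg_intensity_ch2 >= I*`` AND ``target_area_ch2 >= A*``;
* **Type 2 (other death)** — Ch2-positive but condensed:
  ``avg_intensity_ch2 >= I*`` AND ``target_area_ch2 < A*``;
* **Type 3 (live)** — Ch2-negative: ``avg_intensity_ch2 < I*`` (area is
  irrelevant for live cells).

Cells exactly at a reference level are responders (the gates use ``>=``).

Four-channel mode (PI + Annexin V) refines "other death": surface-localized
Annexin V (high ring ratio) with a condensed nucleus marks apoptosis —
whether or not PI has entered yet (early vs late apoptosis) — while bare PI
positivity with a condensed nucleus marks necrosis.  The gates are
evaluated in a fixed precedence NET > APOPTOTIC > NECROTIC because Annexin V
also decorates NET remnants (decondensation must dominate Annexin
positivity) and late apoptotic cells are PI-positive (surface Annexin must
dominate bare PI positivity).

Reference levels can be estimated automatically: the intensity gate I* is a
between-class-variance split of the pooled per-object Ch2 intensities (all
wells — stimulated wells supply the positive mode), falling back to
median + 5*MAD of the control wells when the pooled distribution is not
convincingly bimodal; the area gate A* is a multiple (default 2x) of the
median nuclear area of Ch2-negative control cells.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .features import CellRecord

#: Sarle's bimodality coefficient of a uniform distribution; values above
#: this cutoff indicate meaningful bimodality.
BIMODALITY_CUTOFF = 5.0 / 9.0


class EstimationError(ValueError):
    """Automatic reference-level estimation is not possible; set MANUAL gates."""


class CellClass(str, enum.Enum):
    # two-channel classes
    TYPE1_NET = "TYPE1_NET"
    TYPE2_OTHER_DEATH = "TYPE2_OTHER_DEATH"
    TYPE3_LIVE = "TYPE3_LIVE"
    # four-channel classes
    NET = "NET"
    NECROTIC = "NECROTIC"
    APOPTOTIC = "APOPTOTIC"
    LIVE = "LIVE"


@dataclass
class ReferenceLevels:
    """The gating thresholds that drive classification."""

    intensity_ref: float                 # I*: minimum Ch2 mean intensity
    area_ref_um2: float                  # A*: decondensed-vs-condensed area gate
    annexin_ring_ref: float = 2.0        # R*: surface-localized staining gate
    annexin_cv_ref: float = 0.8          # C*: punctate staining gate
    provenance: str = "MANUAL"           # AUTO | MANUAL

    def __post_init__(self) -> None:
        if not (self.intensity_ref > 0 and np.isfinite(self.intensity_ref)):
            raise ValueError("intensity_ref must be positive and finite")
        if not (self.area_ref_um2 > 0 and np.isfinite(self.area_ref_um2)):
            raise ValueError("area_ref_um2 must be positive and finite")
        if not (np.isfinite(self.annexin_ring_ref) and np.isfinite(self.annexin_cv_ref)):
            raise ValueError("annexin gates must be finite")


def between_class_split(values: np.ndarray) -> float:
    """Exact 1-D Otsu on a sample: the cut maximizing between-class variance
    over all midpoints between consecutive sorted values."""
    x = np.sort(np.asarray(values, dtype=np.float64))
    n = len(x)
    if n < 2 or x[0] == x[-1]:
        raise EstimationError("cannot split a constant sample")
    csum = np.cumsum(x)
    total = csum[-1]
    k = np.arange(1, n)                      # left class sizes
    mu_l = csum[:-1] / k
    mu_r = (total - csum[:-1]) / (n - k)
    bcv = k * (n - k) * (mu_l - mu_r) ** 2   #/n^2 omitted: same argmax
    valid = x[1:] > x[:-1]                   # cut only between distinct values
    bcv = np.where(valid, bcv, -np.inf)
    i = int(np.argmax(bcv))
    return float(0.5 * (x[i] + x[i + 1]))


def bimodality_coefficient(values: np.ndarray) -> float:
    """Sarle's bimodality coefficient (skew^2 + 1) / adjusted kurtosis."""
    x = np.asarray(values, dtype=np.float64)
    n = len(x)
    if n < 4:
        return 0.0
    m = x.mean()
    s = x.std(ddof=0)
    if s == 0:
        return 0.0
    skew = np.mean(((x - m) / s) ** 3)
    kurt = np.mean(((x - m) / s) ** 4) - 3.0
    denom = kurt + 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3))
    return float((skew ** 2 + 1.0) / denom)


def estimate_reference_levels(
    control_records: Sequence[CellRecord],
    all_records: Sequence[CellRecord],
    min_control_objects: int = 50,
    area_multiplier: float = 2.0,
    annexin_ring_ref: float = 2.0,
    annexin_cv_ref: float = 0.8,
) -> ReferenceLevels:
    """Estimate I* and A* from the plate itself.

    ``control_records`` come from CONTROL wells (or the pre-stimulation
    frame of a time-lapse); ``all_records`` pool every well so that
    stimulated wells contribute the Ch2-positive mode.
    """
    control = [r for r in control_records if not r.border]
    everything = [r for r in all_records if not r.border]
    if len(control) < min_control_objects:
        raise EstimationError(
            f"only {len(control)} control objects (< {min_control_objects}); "
            "provide MANUAL reference levels"
        )
    pooled = np.array([r.avg_intensity_ch2 for r in everything])
    ctrl_int = np.array([r.avg_intensity_ch2 for r in control])

    if bimodality_coefficient(pooled) > BIMODALITY_CUTOFF:
        intensity_ref = between_class_split(pooled)
    else:
        med = float(np.median(ctrl_int))
        mad = float(np.median(np.abs(ctrl_int - med)))
        intensity_ref = med + 5.0 * mad
    intensity_ref = max(intensity_ref, np.finfo(float).tiny)

    ch2_negative = [r for r in control if r.avg_intensity_ch2 < intensity_ref]
    if not ch2_negative:
        raise EstimationError(
            "no Ch2-negative control objects; control wells appear stimulated"
        )
    median_live_area = float(np.median([r.area_ch1_um2 for r in ch2_negative]))
    return ReferenceLevels(
        intensity_ref=float(intensity_ref),
        area_ref_um2=area_multiplier * median_live_area,
        annexin_ring_ref=annexin_ring_ref,
        annexin_cv_ref=annexin_cv_ref,
        provenance="AUTO",
    )


def classify_two_channel(record: CellRecord, refs: ReferenceLevels) -> CellClass:
    """Type 1/2/3 event logic on the intensity and area gates."""
    ch2_positive = record.avg_intensity_ch2 >= refs.intensity_ref
    decondensed = record.target_area_ch2_um2 >= refs.area_ref_um2
    if ch2_positive and decondensed:
        return CellClass.TYPE1_NET
    if ch2_positive:
        return CellClass.TYPE2_OTHER_DEATH
    return CellClass.TYPE3_LIVE


def classify_four_channel(record: CellRecord, refs: ReferenceLevels) -> CellClass:
    """NET / apoptotic / necrotic / live logic with Annexin V refinement."""
    if record.annexin_ring_ratio is None or record.annexin_cv is None:
        raise ValueError(
            "four-channel classification requires Annexin features; "
            "was the field analyzed in FOUR_CHANNEL mode?"
        )
    pi_positive = record.avg_intensity_ch2 >= refs.intensity_ref
    decondensed = record.target_area_ch2_um2 >= refs.area_ref_um2
    surface_annexin = record.annexin_ring_ratio >= refs.annexin_ring_ref
    if pi_positive and decondensed:
        return CellClass.NET
    if surface_annexin and not decondensed:
        return CellClass.APOPTOTIC          # early (PI-) or late (PI+)
    if pi_positive and not decondensed:
        return CellClass.NECROTIC
    return CellClass.LIVE


def classify_records(
    records: Iterable[CellRecord],
    refs: ReferenceLevels,
    four_channel: bool = False,
) -> list[CellClass]:
    fn = classify_four_channel if four_channel else classify_two_channel
    return [fn(r, refs) for r in records]
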