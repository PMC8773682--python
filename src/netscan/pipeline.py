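"""End-to-end orchestration: preprocess -> segment -> target mask ->
features -> reference levels -> classification -> quantification.

The plate is the unit of analysis: reference levels are estimated once from
the pooled plate (so every treatment is gated identically) and recorded in
the run manifest together with all effective parameters.  Field-level
failures are isolated by default — a bad field is logged and skipped, the
rest of the plate completes — unless strict mode is requested.
"""

from __future__ import annotations

import logging
import traceback
from dataclasses import dataclass, field as dfield
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from . import classification as cls
from . import features as feat
from . import quantification as quant
from . import segmentation as seg
from . import timelapse as tl
from .imaging_io import (
    ChannelRole,
    ConfigurationError,
    FieldImage,
    PlateLayout,
    PlateMode,
    load_plate_layout,
    read_field,
    write_results,
)
from .preprocess import PreprocessParams, correct_background, smooth

logger = logging.getLogger("netscan")


@dataclass
class GateConfig:
    mode: str = "auto"                       # auto | manual
    intensity_ref: Optional[float] = None    # required when manual
    area_ref_um2: Optional[float] = None
    area_multiplier: float = 2.0
    annexin_ring_ref: float = 2.0
    annexin_cv_ref: float = 0.8
    min_control_objects: int = 50
    ch2_threshold_nsigma: float = 8.0        # Ch2 foreground noise floor


@dataclass
class TrackingConfig:
    max_displacement_um: float = 10.0
    max_gap: int = 1
    min_follow_min: float = 45.0


@dataclass
class PipelineParams:
    preprocess: PreprocessParams = dfield(default_factory=PreprocessParams)
    segmentation: seg.SegmentationParams = dfield(
        default_factory=seg.SegmentationParams)
    target_mask: feat.TargetMaskParams = dfield(
        default_factory=feat.TargetMaskParams)
    gates: GateConfig = dfield(default_factory=GateConfig)
    tracking: TrackingConfig = dfield(default_factory=TrackingConfig)


@dataclass
class RunConfig:
    layout_path: Path
    image_dir: Path
    out_dir: Path
    params: PipelineParams = dfield(default_factory=PipelineParams)
    strict: bool = False
    seed: int = 0
    log_level: str = "INFO"


@dataclass
class FieldResult:
    records: list[feat.CellRecord]
    nuclei: seg.LabeledMask


@dataclass
class PlateResult:
    records: list[feat.CellRecord]
    classes: list[cls.CellClass]
    summaries: list[quant.WellSummary]
    refs: cls.ReferenceLevels
    comparisons: dict
    masks: dict[str, np.ndarray]
    failed_fields: list[str]


@dataclass
class TimelapseResult:
    tracks_per_well: dict[str, list[tl.Track]]
    fate_fractions: dict[str, dict[str, float]]
    per_frame_summaries: dict[str, list[quant.WellSummary]]
    refs: cls.ReferenceLevels


def analyze_field(
    fimg: FieldImage, params: PipelineParams, four_channel: bool = False
) -> FieldResult:
    """Static single-field analysis producing per-object measurements."""
    ch1 = fimg.channels[ChannelRole.NUCLEUS_ALL]
    ch1_corr = correct_background(ch1, params.preprocess)
    ch1_seg = smooth(ch1_corr, params.preprocess)
    nuclei = seg.identify_primary_objects(ch1_seg, params.segmentation)

    ch2 = fimg.channels.get(ChannelRole.IMPERMEABLE_DNA)
    ch2_corr = None
    ch2_fg = np.zeros(fimg.shape, dtype=bool)
    if ch2 is not None:
        ch2_corr = correct_background(ch2, params.preprocess)
        thr = seg.robust_foreground_threshold(
            ch2_corr, params.gates.ch2_threshold_nsigma
        )
        ch2_fg = seg.identify_ch2_foreground(ch2_corr, thr)

    targets = feat.build_target_mask(
        nuclei, params.target_mask, fimg.pixel_size_um
    )
    ann_corr = None
    ann_targets = None
    if four_channel:
        ann = fimg.channels.get(ChannelRole.ANNEXIN)
        if ann is None:
            raise ConfigurationError(
                "FOUR_CHANNEL mode requires an ANNEXIN channel"
            )
        ann_corr = correct_background(ann, params.preprocess)
        ann_targets = feat.build_target_mask(
            nuclei, params.target_mask, fimg.pixel_size_um,
            dilation_um=params.target_mask.annexin_dilation_um,
        )
    records = feat.measure_objects(
        fimg, nuclei, targets, ch2_fg, params.target_mask,
        ch2_corrected=ch2_corr, ch1_corrected=ch1_corr,
        annexin_targets=ann_targets, annexin_corrected=ann_corr,
    )
    return FieldResult(records=records, nuclei=nuclei)


def resolve_reference_levels(
    records: Sequence[feat.CellRecord],
    layout: PlateLayout,
    gates: GateConfig,
    extra_control_records: Sequence[feat.CellRecord] = (),
) -> cls.ReferenceLevels:
    """Manual gates from config, or automatic estimation from the plate."""
    if gates.mode.lower() == "manual":
        if gates.intensity_ref is None or gates.area_ref_um2 is None:
            raise ConfigurationError(
                "manual gates require intensity_ref and area_ref_um2"
            )
        return cls.ReferenceLevels(
            intensity_ref=gates.intensity_ref,
            area_ref_um2=gates.area_ref_um2,
            annexin_ring_ref=gates.annexin_ring_ref,
            annexin_cv_ref=gates.annexin_cv_ref,
            provenance="MANUAL",
        )
    control_ids = set(layout.control_wells)
    if not control_ids and not extra_control_records:
        raise ConfigurationError(
            "automatic reference levels need at least one CONTROL well"
        )
    control = [r for r in records if r.well_id in control_ids]
    control += list(extra_control_records)
    return cls.estimate_reference_levels(
        control, list(records),
        min_control_objects=gates.min_control_objects,
        area_multiplier=gates.area_multiplier,
        annexin_ring_ref=gates.annexin_ring_ref,
        annexin_cv_ref=gates.annexin_cv_ref,
    )


def compare_by_treatment(
    summaries: Sequence[quant.WellSummary], layout: PlateLayout
) -> dict:
    """Group statistics on per-well percent NETosis.

    Pairwise unpaired t tests of every treatment against the control
    treatment, plus a one-way ANOVA across all treatments, wherever the
    replicate requirement (n >= 2 wells) is met.
    """
    groups: dict[str, list[float]] = {}
    roles: dict[str, str] = {}
    for s in summaries:
        if s.pct_net is None:
            continue
        spec = layout.well(s.well_id)
        groups.setdefault(spec.treatment_label, []).append(s.pct_net)
        roles[spec.treatment_label] = spec.role.value
    control_labels = [t for t, r in roles.items() if r == "CONTROL"]
    out: dict = {"vs_control": {}, "anova": None, "groups": groups}
    eligible = {t: v for t, v in groups.items() if len(v) >= 2}
    if control_labels:
        ctrl = control_labels[0]
        if ctrl in eligible:
            for t, v in eligible.items():
                if t != ctrl:
                    out["vs_control"][t] = quant.compare_groups(eligible[ctrl], v)
    if len(eligible) > 2:
        out["anova"] = quant.compare_groups(*eligible.values())
    return out


def analyze_fields(
    fields: Sequence[FieldImage],
    layout: PlateLayout,
    params: Optional[PipelineParams] = None,
    strict: bool = False,
) -> PlateResult:
    """Run the full static analysis on in-memory fields."""
    params = params or PipelineParams()
    four_channel = layout.mode is PlateMode.FOUR_CHANNEL
    all_records: list[feat.CellRecord] = []
    masks: dict[str, np.ndarray] = {}
    failed: list[str] = []
    for fimg in fields:
        key = f"{fimg.well_id}_f{fimg.field_index:02d}"
        try:
            res = analyze_field(fimg, params, four_channel=four_channel)
        except Exception as exc:
            if strict:
                raise
            logger.error("field %s failed: %s", key, exc)
            logger.debug("%s", traceback.format_exc())
            failed.append(key)
            continue
        all_records.extend(res.records)
        masks[key] = res.nuclei.labels
        logger.info("field %s: %d objects", key, res.nuclei.n_objects)

    refs = resolve_reference_levels(all_records, layout, params.gates)
    classes = cls.classify_records(all_records, refs, four_channel=four_channel)
    summaries = [
        quant.summarize_well(
            all_records, classes, w.well_id, treatment=w.treatment_label
        )
        for w in layout.wells
        if any(r.well_id == w.well_id for r in all_records)
    ]
    comparisons = compare_by_treatment(summaries, layout)
    return PlateResult(
        records=all_records, classes=classes, summaries=summaries,
        refs=refs, comparisons=comparisons, masks=masks, failed_fields=failed,
    )


def _load_fields(
    layout: PlateLayout, image_dir: Path, time_point: float = 0.0
) -> list[FieldImage]:
    fields = []
    for w in layout.wells:
        for f in range(1, layout.fields_per_well + 1):
            paths = {
                role: image_dir / layout.filename(w.well_id, f, role, time_point)
                for role in layout.channel_names
            }
            fields.append(
                read_field(
                    paths, w.well_id, f, time_point, layout.pixel_size_um
                )
            )
    return fields


def analyze_plate(config: RunConfig) -> PlateResult:
    """Disk-to-disk plate analysis: read TIFFs per the layout, analyze,
    write the object table, summaries, masks and manifest."""
    layout = load_plate_layout(config.layout_path, check_files=False)
    fields = _load_fields(layout, Path(config.image_dir))
    result = analyze_fields(fields, layout, config.params, strict=config.strict)

    class_col = [c.value for c in result.classes]
    rows = []
    for r, c in zip(result.records, class_col):
        d = r.__dict__.copy()
        d["cell_class"] = c
        rows.append(d)
    manifest_extra = {
        "reference_levels": {
            "intensity_ref": result.refs.intensity_ref,
            "area_ref_um2": result.refs.area_ref_um2,
            "annexin_ring_ref": result.refs.annexin_ring_ref,
            "annexin_cv_ref": result.refs.annexin_cv_ref,
            "provenance": result.refs.provenance,
        },
        "parameters": _params_dict(config.params),
        "failed_fields": result.failed_fields,
        "seed": config.seed,
    }
    write_results(
        rows, result.summaries, result.masks, config.out_dir,
        manifest_extra=manifest_extra,
    )
    return result


def analyze_timelapse_fields(
    frames: Sequence[Sequence[FieldImage]],
    layout: PlateLayout,
    params: Optional[PipelineParams] = None,
) -> TimelapseResult:
    """Time-lapse analysis of in-memory frames.

    ``frames`` is one list of FieldImages per time point (all wells/fields
    of that frame).  Static per-frame analysis is followed by track linking
    and trajectory classification.  When no CONTROL well exists, the
    pre-stimulation frame (t = 0) serves as the control population for
    automatic reference levels.
    """
    params = params or PipelineParams()
    if len(frames) < 2:
        raise ValueError(
            "time-lapse needs >= 2 frames; use analyze_fields for single scans"
        )
    per_frame_records: list[list[feat.CellRecord]] = []
    times: list[float] = []
    for frame_fields in frames:
        recs: list[feat.CellRecord] = []
        for fimg in frame_fields:
            recs.extend(analyze_field(fimg, params).records)
        per_frame_records.append(recs)
        times.append(frame_fields[0].time_point_min)
    if times != sorted(times):
        raise ValueError("frames must be in increasing time order")

    all_records = [r for recs in per_frame_records for r in recs]
    t0_records = per_frame_records[0]
    try:
        refs = resolve_reference_levels(all_records, layout, params.gates)
    except ConfigurationError:
        refs = resolve_reference_levels(
            all_records, layout, params.gates,
            extra_control_records=t0_records,
        )

    px = layout.pixel_size_um
    tracks_per_well: dict[str, list[tl.Track]] = {}
    fate_fractions: dict[str, dict[str, float]] = {}
    per_frame_summaries: dict[str, list[quant.WellSummary]] = {}
    well_field_keys = sorted(
        {(r.well_id, r.field_index) for r in all_records}
    )
    wells = sorted({w for w, _ in well_field_keys})
    for well in wells:
        tracks: list[tl.Track] = []
        for w, f in well_field_keys:
            if w != well:
                continue
            seq = [
                (t, [r for r in recs
                     if r.well_id == w and r.field_index == f])
                for t, recs in zip(times, per_frame_records)
            ]
            tracks.extend(
                tl.link_frames(
                    seq, px,
                    max_displacement_um=params.tracking.max_displacement_um,
                    max_gap=params.tracking.max_gap,
                )
            )
        tl.classify_tracks(
            tracks, refs, min_follow_min=params.tracking.min_follow_min
        )
        tracks_per_well[well] = tracks
        fated = [t for t in tracks if t.fate is not None]
        n = max(len(fated), 1)
        fate_fractions[well] = {
            f.value: sum(1 for t in fated if t.fate is f) / n
            for f in tl.Fate
        }
        spec = layout.well(well)
        per_frame_summaries[well] = [
            quant.summarize_well(
                recs, cls.classify_records(recs, refs), well,
                treatment=spec.treatment_label,
            )
            for recs in per_frame_records
        ]
    return TimelapseResult(
        tracks_per_well=tracks_per_well,
        fate_fractions=fate_fractions,
        per_frame_summaries=per_frame_summaries,
        refs=refs,
    )


def analyze_timelapse(config: RunConfig) -> TimelapseResult:
    """Disk-based time-lapse analysis driven by the layout's time series."""
    layout = load_plate_layout(config.layout_path, check_files=False)
    if not layout.time_series or len(layout.time_series) < 2:
        raise ConfigurationError(
            "layout has no multi-point time_series; use analyze_plate"
        )
    frames = [
        _load_fields(layout, Path(config.image_dir), time_point=t)
        for t in layout.time_series
    ]
    return analyze_timelapse_fields(frames, layout, config.params)


def _params_dict(params: PipelineParams) -> dict:
    import dataclasses

    def conv(obj):
        if dataclasses.is_dataclass(obj):
            return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, Path):
            return str(obj)
        return obj

    return {
        "preprocess": conv(params.preprocess),
        "segmentation": conv(params.segmentation),
        "target_mask": conv(params.target_mask),
        "gates": conv(params.gates),
        "tracking": conv(params.tracking),
    }


def load_run_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file with optional parameter blocks."""
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    root = path.parent
    params = PipelineParams()
    if "preprocess" in cfg:
        params.preprocess = PreprocessParams(**cfg["preprocess"])
    if "segmentation" in cfg:
        s = dict(cfg["segmentation"])
        if "threshold_method" in s:
            s["threshold_method"] = seg.ThresholdMethod(
                s["threshold_method"].upper())
        params.segmentation = seg.SegmentationParams(**s)
    if "target_mask" in cfg:
        params.target_mask = feat.TargetMaskParams(**cfg["target_mask"])
    if "gates" in cfg:
        params.gates = GateConfig(**cfg["gates"])
    if "tracking" in cfg:
        params.tracking = TrackingConfig(**cfg["tracking"])
    layout_path = root / cfg.get("layout", "layout.yaml")
    return RunConfig(
        layout_path=layout_path,
        image_dir=root / cfg.get("image_dir", "."),
        out_dir=root / cfg.get("out_dir", "results"),
        params=params,
        strict=bool(cfg.get("strict", False)),
        seed=int(cfg.get("seed", 0)),
        log_level=str(cfg.get("log_level", "INFO")),
    )
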