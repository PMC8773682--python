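"""Image and plate-layout I/O for the NET screening pipeline.

The analysis is anchored on a per-field, per-channel image model: each field
of view is stored as one single-plane grayscale TIFF per fluorescence
channel, tied together by a plate-layout config that maps wells to
treatments, fields and files.  Channels are identified by *role* rather than
wavelength so the same pipeline runs on Hoechst + Sytox Green (two-channel
mode) or Hoechst + PI + Annexin V (four-channel mode).
"""

from __future__ import annotations

import dataclasses
import enum
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger("netscan")

#: Default filename template for one TIFF per channel per field.
FILENAME_TEMPLATE = "{well}_f{field:02d}_t{minutes:04d}_{channel}.tif"

#: Default pixel pitch for a 20x objective, in micrometres per pixel edge.
DEFAULT_PIXEL_SIZE_UM = 0.65


class ConfigurationError(ValueError):
    """Invalid plate layout or run configuration."""


class DimensionMismatchError(ValueError):
    """Channel images of one field do not share dimensions."""


class ChannelRole(str, enum.Enum):
    """What a fluorescence channel reports, independent of its wavelength."""

    NUCLEUS_ALL = "NUCLEUS_ALL"          # Hoechst 33342: all nuclei
    IMPERMEABLE_DNA = "IMPERMEABLE_DNA"  # Sytox Green or PI: compromised membranes
    ANNEXIN = "ANNEXIN"                  # Annexin V: externalized phosphatidylserine
    OTHER = "OTHER"                      # carried along, ignored by the analysis


class WellRole(str, enum.Enum):
    CONTROL = "CONTROL"
    STIMULATED = "STIMULATED"
    STIMULATED_PLUS_INHIBITOR = "STIMULATED_PLUS_INHIBITOR"
    OTHER = "OTHER"


class PlateMode(str, enum.Enum):
    TWO_CHANNEL = "TWO_CHANNEL"
    FOUR_CHANNEL = "FOUR_CHANNEL"


@dataclass
class ChannelImage:
    """One channel of one field: a non-negative 2-D intensity grid."""

    pixels: np.ndarray
    bit_depth: int = 16
    channel_role: ChannelRole = ChannelRole.OTHER
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError("pixels must be a 2-D grid with both dims >= 1")
        if self.bit_depth not in (8, 12, 16):
            raise ValueError(f"unsupported bit depth {self.bit_depth}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if np.any(self.pixels < 0):
            raise ValueError("pixel values must be non-negative")
        if np.any(self.pixels > 2 ** self.bit_depth - 1):
            raise ValueError(
                f"pixel values exceed {self.bit_depth}-bit range"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um ** 2


@dataclass
class FieldImage:
    """All registered channel images of one field of view."""

    well_id: str
    field_index: int
    channels: dict[ChannelRole, ChannelImage]
    time_point_min: float = 0.0

    def __post_init__(self) -> None:
        if self.field_index < 1:
            raise ValueError("field_index must be >= 1")
        if self.time_point_min < 0:
            raise ValueError("time_point_min must be non-negative")
        if ChannelRole.NUCLEUS_ALL not in self.channels:
            raise ConfigurationError(
                "FieldImage requires a NUCLEUS_ALL (Hoechst) channel"
            )
        ref = self.channels[ChannelRole.NUCLEUS_ALL]
        for role, ch in self.channels.items():
            if ch.shape != ref.shape:
                raise DimensionMismatchError(
                    f"channel {role.value} is {ch.shape}, "
                    f"NUCLEUS_ALL is {ref.shape}"
                )
            if not np.isclose(ch.pixel_size_um, ref.pixel_size_um):
                raise DimensionMismatchError(
                    f"channel {role.value} pixel size differs from NUCLEUS_ALL"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels[ChannelRole.NUCLEUS_ALL].shape

    @property
    def pixel_size_um(self) -> float:
        return self.channels[ChannelRole.NUCLEUS_ALL].pixel_size_um


@dataclass
class WellSpec:
    well_id: str
    treatment_label: str = "untreated"
    concentration: float = 0.0
    concentration_units: str = ""
    role: WellRole = WellRole.OTHER


@dataclass
class PlateLayout:
    """Plate map: wells, treatments, acquisition mode and file naming."""

    wells: list[WellSpec]
    fields_per_well: int = 6
    mode: PlateMode = PlateMode.TWO_CHANNEL
    time_series: Optional[list[float]] = None
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    filename_template: str = FILENAME_TEMPLATE
    channel_names: dict[ChannelRole, str] = field(
        default_factory=lambda: {
            ChannelRole.NUCLEUS_ALL: "hoechst",
            ChannelRole.IMPERMEABLE_DNA: "sytox",
        }
    )

    def __post_init__(self) -> None:
        ids = [w.well_id for w in self.wells]
        dupes = {w for w in ids if ids.count(w) > 1}
        if dupes:
            raise ConfigurationError(f"duplicate well_id(s): {sorted(dupes)}")
        if self.fields_per_well < 1:
            raise ConfigurationError("fields_per_well must be >= 1")
        if self.time_series is not None:
            ts = list(self.time_series)
            if sorted(ts) != ts or len(set(ts)) != len(ts):
                raise ConfigurationError("time_series must be strictly increasing")

    @property
    def well_ids(self) -> list[str]:
        return [w.well_id for w in self.wells]

    def well(self, well_id: str) -> WellSpec:
        for w in self.wells:
            if w.well_id == well_id:
                return w
        raise KeyError(well_id)

    @property
    def control_wells(self) -> list[str]:
        return [w.well_id for w in self.wells if w.role is WellRole.CONTROL]

    def filename(
        self, well_id: str, field_index: int, role: ChannelRole, minutes: float = 0.0
    ) -> str:
        return self.filename_template.format(
            well=well_id,
            field=field_index,
            minutes=int(round(minutes)),
            channel=self.channel_names[role],
        )


def _infer_bit_depth(arr: np.ndarray) -> int:
    if arr.dtype == np.uint8:
        return 8
    if arr.dtype == np.uint16:
        return 16
    raise ValueError(f"unsupported TIFF sample format {arr.dtype}")


def read_field(
    paths: Mapping[ChannelRole, str | Path],
    well_id: str,
    field_index: int,
    time_point_min: float = 0.0,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    bit_depth: Optional[int] = None,
) -> FieldImage:
    """Read one field from single-plane grayscale TIFFs, one per channel.

    Bit depth is inferred from the TIFF sample format (uint8 -> 8, uint16 ->
    16) unless given explicitly, e.g. ``bit_depth=12`` for 12-bit data stored
    in 16-bit containers.
    """
    if ChannelRole.NUCLEUS_ALL not in paths:
        raise ConfigurationError("read_field requires a NUCLEUS_ALL channel path")
    channels: dict[ChannelRole, ChannelImage] = {}
    for role, path in paths.items():
        arr = tifffile.imread(str(path))
        if arr.ndim != 2:
            raise ValueError(f"{path}: expected a single-plane grayscale TIFF")
        depth = bit_depth if bit_depth is not None else _infer_bit_depth(arr)
        channels[role] = ChannelImage(
            pixels=arr, bit_depth=depth, channel_role=role,
            pixel_size_um=pixel_size_um,
        )
    return FieldImage(
        well_id=well_id, field_index=field_index,
        time_point_min=time_point_min, channels=channels,
    )


_ROLE_KEYS = {r.value.lower(): r for r in ChannelRole}


def load_plate_layout(
    config_path: str | Path, check_files: bool = False
) -> PlateLayout:
    """Load and validate a YAML plate-layout config.

    With ``check_files=True`` every file implied by the filename template is
    required to exist next to the config; missing ones are listed in the
    error.
    """
    config_path = Path(config_path)
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "wells" not in cfg:
        raise ConfigurationError(f"{config_path}: missing 'wells' section")

    wells = []
    for w in cfg["wells"]:
        wells.append(
            WellSpec(
                well_id=str(w["well_id"]),
                treatment_label=str(w.get("treatment", "untreated")),
                concentration=float(w.get("concentration", 0.0)),
                concentration_units=str(w.get("units", "")),
                role=WellRole(str(w.get("role", "OTHER")).upper()),
            )
        )
    channel_names = {
        _ROLE_KEYS[str(k).lower()]: str(v)
        for k, v in cfg.get(
            "channels", {"nucleus_all": "hoechst", "impermeable_dna": "sytox"}
        ).items()
    }
    layout = PlateLayout(
        wells=wells,
        fields_per_well=int(cfg.get("fields_per_well", 6)),
        mode=PlateMode(str(cfg.get("mode", "TWO_CHANNEL")).upper()),
        time_series=(
            [float(t) for t in cfg["time_series"]]
            if cfg.get("time_series") else None
        ),
        pixel_size_um=float(cfg.get("pixel_size_um", DEFAULT_PIXEL_SIZE_UM)),
        filename_template=str(cfg.get("filename_template", FILENAME_TEMPLATE)),
        channel_names=channel_names,
    )
    if check_files:
        root = config_path.parent
        times = layout.time_series or [0.0]
        missing = []
        for w in layout.wells:
            for f in range(1, layout.fields_per_well + 1):
                for role in layout.channel_names:
                    for t in times:
                        p = root / layout.filename(w.well_id, f, role, t)
                        if not p.exists():
                            missing.append(p.name)
        if missing:
            raise ConfigurationError(
                f"{len(missing)} image file(s) missing, e.g. {missing[:5]}"
            )
    return layout


def write_results(
    records: Sequence,
    summaries: Sequence,
    masks: Mapping[str, np.ndarray],
    out_dir: str | Path,
    manifest_extra: Optional[dict] = None,
) -> dict:
    """Write the object table, well summaries, label masks and a manifest.

    ``records`` and ``summaries`` may be dataclass instances or plain dicts;
    masks are written as 16-bit label TIFFs keyed by a field identifier.
    Returns the manifest (also written as ``manifest.json``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def _rows(items: Sequence) -> pd.DataFrame:
        dicts = [
            dataclasses.asdict(it) if dataclasses.is_dataclass(it) else dict(it)
            for it in items
        ]
        return pd.DataFrame(dicts)

    from .features import CELL_TABLE_COLUMNS  # deferred: avoids import cycle

    obj = _rows(records)
    if obj.empty:
        obj = pd.DataFrame(columns=CELL_TABLE_COLUMNS)
    obj_path = out_dir / "objects.csv"
    obj.to_csv(obj_path, index=False)

    summ = _rows(summaries)
    summ_path = out_dir / "well_summary.csv"
    summ.to_csv(summ_path, index=False)

    mask_files = {}
    for key, labels in masks.items():
        labels = np.asarray(labels)
        if labels.max(initial=0) > np.iinfo(np.uint16).max:
            raise ValueError(f"mask {key}: labels exceed 16-bit range")
        p = out_dir / f"mask_{key}.tif"
        tifffile.imwrite(str(p), labels.astype(np.uint16))
        mask_files[key] = {"file": p.name, "n_objects": int(labels.max(initial=0))}

    manifest = {
        "software": "netscan",
        "files": {
            "objects": {"file": obj_path.name, "rows": int(len(obj))},
            "well_summary": {"file": summ_path.name, "rows": int(len(summ))},
            "masks": mask_files,
        },
    }
    if manifest_extra:
        manifest.update(manifest_extra)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    logger.info("wrote %d objects, %d wells to %s", len(obj), len(summ), out_dir)
    return manifest
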