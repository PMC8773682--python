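"""Synthetic ground-truth plates with the four neutrophil phenotypes.

The generator renders multi-channel fluorescence fields that exercise the
whole pipeline without any real data:

* **LIVE** — multilobed Hoechst-bright nucleus (union of 2-4 offset disks),
  no impermeable-dye signal;
* **NET** — enlarged decondensed chromatin cloud (footprint 2.5-6x the live
  nuclear area, sampled per cell), bright in the impermeable-DNA channel
  with a soft radial profile, dim Hoechst; punctate Annexin V in
  four-channel mode;
* **NECROTIC** — condensed nucleus, bright in both DNA channels;
* **APOPTOTIC** — condensed Hoechst-bright nucleus with a surface Annexin V
  ring at the cell membrane; the impermeable dye is off in the early
  sub-state and on in the late sub-state.

Cells are placed by rejection sampling with a hard minimum centre spacing
(no overlapping footprints, so ground-truth masks partition trivially) and
a margin keeping every footprint clear of the field border.  Rendering
applies a Gaussian PSF, a constant-plus-gradient background, and
signal-dependent shot noise plus Gaussian read noise.  Every output is a
pure function of (parameters, seed).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy import ndimage as ndi

from .imaging_io import (
    DEFAULT_PIXEL_SIZE_UM,
    ChannelImage,
    ChannelRole,
    FieldImage,
    PlateLayout,
    PlateMode,
    WellRole,
    WellSpec,
)


class TrueState(str, enum.Enum):
    LIVE = "LIVE"
    NET = "NET"
    NECROTIC = "NECROTIC"
    APOPTOTIC = "APOPTOTIC"


@dataclass
class PhenotypeModel:
    """Appearance model of the four phenotypes.  Lengths in micrometres,
    intensities in camera counts (16-bit range)."""

    nuclear_radius_um: float = 3.5          # live-cell base nuclear radius
    radius_jitter: float = 0.05             # uniform fractional radius spread
    net_area_factor_range: tuple[float, float] = (2.5, 6.0)
    condensed_factor: float = 0.8           # necrotic/apoptotic radius shrink
    psf_sigma_um: float = 0.8
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    field_shape: tuple[int, int] = (1024, 1024)
    min_spacing_um: float = 20.0
    bit_depth: int = 16
    # channel intensity means per state
    ch1_live: float = 3000.0
    ch1_net: float = 1200.0
    ch1_condensed: float = 3500.0
    ch2_net_peak: float = 1500.0
    ch2_necrotic: float = 2500.0
    ch2_apoptotic_late: float = 2000.0
    annexin_ring: float = 2000.0
    annexin_puncta: float = 2500.0
    apoptotic_late_fraction: float = 0.5
    # acquisition noise model
    background_level: float = 100.0
    background_gradient: float = 30.0
    read_noise_sd: float = 10.0
    shot_noise_gain: float = 0.5            # noise variance = gain * signal

    def __post_init__(self) -> None:
        lo, hi = self.net_area_factor_range
        if not 0 < lo <= hi:
            raise ValueError("net_area_factor_range must be positive and ordered")
        if self.nuclear_radius_um <= 0 or self.psf_sigma_um < 0:
            raise ValueError("invalid geometry parameters")

    @property
    def max_footprint_radius_um(self) -> float:
        hi = self.net_area_factor_range[1]
        return self.nuclear_radius_um * (1 + self.radius_jitter) * np.sqrt(hi)


@dataclass
class TrueCell:
    cell_id: int
    state: TrueState
    center_row: float                      # px
    center_col: float
    base_nuclear_area_um2: float
    footprint_area_um2: float              # rendered ground-truth mask area
    net_area_factor: float = 1.0
    apoptotic_late: bool = False


@dataclass
class GroundTruth:
    cells: list[TrueCell]
    label_mask: np.ndarray                 # noiseless footprint labels
    class_fractions: dict[str, float]
    frames_min: Optional[list[float]] = None
    # per-frame scripts, aligned with cells: fate, onset time, and per-frame
    # (permeable, area_factor) pairs
    fates: Optional[list[str]] = None
    onsets_min: Optional[list[Optional[float]]] = None
    per_frame: Optional[list[list[tuple[bool, float]]]] = None


# ---------------------------------------------------------------------------
# geometry helpers

def _place_centers(
    n: int,
    shape: tuple[int, int],
    min_spacing_px: float,
    margin_px: float,
    rng: np.random.Generator,
    max_attempts_per_cell: int = 400,
) -> np.ndarray:
    """Hard-core rejection sampling of cell centres."""
    if n == 0:
        return np.empty((0, 2))
    lo_r, hi_r = margin_px, shape[0] - margin_px
    lo_c, hi_c = margin_px, shape[1] - margin_px
    if hi_r <= lo_r or hi_c <= lo_c:
        raise ValueError("field too small for the requested margin")
    cell = min_spacing_px / np.sqrt(2)
    grid: dict[tuple[int, int], list[int]] = {}
    pts: list[tuple[float, float]] = []

    def ok(r: float, c: float) -> bool:
        gr, gc = int(r // cell), int(c // cell)
        for dr in (-2, -1, 0, 1, 2):
            for dc in (-2, -1, 0, 1, 2):
                for idx in grid.get((gr + dr, gc + dc), ()):
                    pr, pc = pts[idx]
                    if (pr - r) ** 2 + (pc - c) ** 2 < min_spacing_px ** 2:
                        return False
        return True

    attempts = 0
    budget = max_attempts_per_cell * n
    while len(pts) < n:
        attempts += 1
        if attempts > budget:
            raise RuntimeError(
                f"could not place {n} cells with spacing "
                f"{min_spacing_px:.1f}px after {budget} attempts"
            )
        r = rng.uniform(lo_r, hi_r)
        c = rng.uniform(lo_c, hi_c)
        if ok(r, c):
            idx = len(pts)
            pts.append((r, c))
            grid.setdefault((int(r // cell), int(c // cell)), []).append(idx)
    return np.array(pts)


def _disk_profile(bbox_shape, center, radius_px):
    rr, cc = np.ogrid[: bbox_shape[0], : bbox_shape[1]]
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    return d2 <= radius_px ** 2, np.sqrt(d2)


def _state_counts(n: int, fractions: dict[TrueState, float]) -> dict[TrueState, int]:
    tot = sum(fractions.values())
    if abs(tot - 1.0) > 1e-9:
        raise ValueError(f"class fractions must sum to 1 (got {tot})")
    states = sorted(fractions, key=lambda s: s.value)
    counts = {}
    acc = 0.0
    assigned = 0
    for s in states:
        acc += fractions[s]
        k = int(round(acc * n)) - assigned
        counts[s] = k
        assigned += k
    return counts


# ---------------------------------------------------------------------------
# single-cell rendering

def _render_cell(
    canvases: dict[str, np.ndarray],
    label_mask: np.ndarray,
    cell_id: int,
    state: TrueState,
    center: tuple[float, float],
    model: PhenotypeModel,
    rng: np.random.Generator,
    area_factor: float = 1.0,
    permeable: Optional[bool] = None,
    annexin: bool = False,
    apoptotic_late: bool = False,
    base_radius_um: Optional[float] = None,
    lobe_geometry: Optional[list[tuple[float, float, float]]] = None,
) -> dict:
    """Draw one cell into the channel canvases; returns its geometry."""
    px = model.pixel_size_um
    R_um = (
        base_radius_um
        if base_radius_um is not None
        else model.nuclear_radius_um
        * rng.uniform(1 - model.radius_jitter, 1 + model.radius_jitter)
    )
    R = R_um / px
    cr, cc = center
    shape = label_mask.shape

    def paint(mask_bbox, values_bbox, channel, rs, cs):
        canvases[channel][rs, cs][mask_bbox] = np.maximum(
            canvases[channel][rs, cs][mask_bbox], values_bbox[mask_bbox]
        )

    if state is TrueState.LIVE or (state is TrueState.NET and area_factor <= 1.0):
        # multilobed nucleus: 2-4 disks of 0.62R offset by 0.55R
        if lobe_geometry is None:
            k = int(rng.integers(2, 5))
            angles = rng.uniform(0, 2 * np.pi, size=k)
            lobe_geometry = [
                (0.62 * R, cr + 0.55 * R * np.sin(a), cc + 0.55 * R * np.cos(a))
                for a in angles
            ]
        ext = int(np.ceil(1.3 * R)) + 2
        rs = slice(max(0, int(cr) - ext), min(shape[0], int(cr) + ext))
        cs = slice(max(0, int(cc) - ext), min(shape[1], int(cc) + ext))
        bbox = np.zeros((rs.stop - rs.start, cs.stop - cs.start), dtype=bool)
        for lr, lcr, lcc in lobe_geometry:
            m, _ = _disk_profile(bbox.shape, (lcr - rs.start, lcc - cs.start), lr)
            bbox |= m
        vals = np.full(bbox.shape, model.ch1_live)
        paint(bbox, vals, "ch1", rs, cs)
        if permeable:                       # pre-decondensation NET onset
            paint(bbox, np.full(bbox.shape, model.ch2_necrotic), "ch2", rs, cs)
        label_mask[rs, cs][bbox & (label_mask[rs, cs] == 0)] = cell_id
        area = float(bbox.sum())
        return {
            "base_radius_um": R_um,
            "base_area_um2": area * px ** 2,
            "footprint_area_um2": area * px ** 2,
            "lobe_geometry": lobe_geometry,
        }

    if state is TrueState.NET:
        Rf = R * np.sqrt(area_factor)
        ext = int(np.ceil(Rf)) + 2
        rs = slice(max(0, int(cr) - ext), min(shape[0], int(cr) + ext))
        cs = slice(max(0, int(cc) - ext), min(shape[1], int(cc) + ext))
        m, dist = _disk_profile(
            (rs.stop - rs.start, cs.stop - cs.start),
            (cr - rs.start, cc - cs.start), Rf,
        )
        profile = 0.55 + 0.45 * np.exp(-2.0 * (dist / max(Rf, 1e-9)) ** 2)
        paint(m, model.ch2_net_peak * profile, "ch2", rs, cs)
        paint(m, model.ch1_net * profile, "ch1", rs, cs)
        if annexin:
            k = int(rng.integers(4, 9))
            for _ in range(k):
                ang = rng.uniform(0, 2 * np.pi)
                rad = rng.uniform(0, 0.8 * Rf)
                pm, _ = _disk_profile(
                    m.shape,
                    (cr - rs.start + rad * np.sin(ang),
                     cc - cs.start + rad * np.cos(ang)),
                    1.0 / px,
                )
                paint(pm & m, np.full(m.shape, model.annexin_puncta),
                      "annexin", rs, cs)
        label_mask[rs, cs][m & (label_mask[rs, cs] == 0)] = cell_id
        area = float(m.sum())
        return {
            "base_radius_um": R_um,
            "base_area_um2": np.pi * R_um ** 2,
            "footprint_area_um2": area * px ** 2,
            "lobe_geometry": None,
        }

    # condensed states: NECROTIC / APOPTOTIC
    Rc = R * model.condensed_factor
    ring_outer_um = R_um * model.condensed_factor + 1.7  # membrane radius
    ext = int(np.ceil(max(Rc, ring_outer_um / px))) + 2
    rs = slice(max(0, int(cr) - ext), min(shape[0], int(cr) + ext))
    cs = slice(max(0, int(cc) - ext), min(shape[1], int(cc) + ext))
    m, dist = _disk_profile(
        (rs.stop - rs.start, cs.stop - cs.start), (cr - rs.start, cc - cs.start), Rc
    )
    paint(m, np.full(m.shape, model.ch1_condensed), "ch1", rs, cs)
    if state is TrueState.NECROTIC or (state is TrueState.APOPTOTIC and apoptotic_late):
        lvl = model.ch2_necrotic if state is TrueState.NECROTIC \
            else model.ch2_apoptotic_late
        paint(m, np.full(m.shape, lvl), "ch2", rs, cs)
    if state is TrueState.APOPTOTIC and annexin:
        band = (dist * model.pixel_size_um >= ring_outer_um - 0.9) & (
            dist * model.pixel_size_um <= ring_outer_um
        )
        paint(band, np.full(m.shape, model.annexin_ring), "annexin", rs, cs)
    label_mask[rs, cs][m & (label_mask[rs, cs] == 0)] = cell_id
    area = float(m.sum())
    return {
        "base_radius_um": R_um,
        "base_area_um2": area * px ** 2,
        "footprint_area_um2": area * px ** 2,
        "lobe_geometry": None,
    }


def _finish_channels(
    canvases: dict[str, np.ndarray],
    model: PhenotypeModel,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Apply PSF, background, noise and quantization, in that order."""
    px = model.pixel_size_um
    out = {}
    H, W = model.field_shape
    rows = np.linspace(-0.5, 0.5, H)[:, None]
    cols = np.linspace(-0.5, 0.5, W)[None, :]
    background = model.background_level + model.background_gradient * (rows + cols)
    background = np.clip(background, 0, None)
    for name, img in canvases.items():
        if model.psf_sigma_um > 0:
            img = ndi.gaussian_filter(img, sigma=model.psf_sigma_um / px,
                                      mode="reflect")
        img = img + background
        sd = np.sqrt(model.read_noise_sd ** 2 + model.shot_noise_gain * img)
        img = img + rng.normal(0.0, 1.0, size=img.shape) * sd
        maxval = 2 ** model.bit_depth - 1
        out[name] = np.clip(np.round(img), 0, maxval).astype(np.uint16)
    return out


def generate_field(
    n_cells: int,
    class_fractions: dict[TrueState, float],
    model: PhenotypeModel,
    seed: int,
    well_id: str = "A01",
    field_index: int = 1,
    annexin: bool = False,
    time_point_min: float = 0.0,
) -> tuple[FieldImage, GroundTruth]:
    """Render one field with the requested phenotype mix.

    Class counts are the deterministic rounding of ``n_cells *
    class_fractions``; identical arguments (including seed) give
    bit-identical output.
    """
    rng = np.random.default_rng(seed)
    px = model.pixel_size_um
    shape = model.field_shape
    counts = _state_counts(n_cells, class_fractions)
    states: list[TrueState] = []
    for s in sorted(counts, key=lambda s: s.value):
        states.extend([s] * counts[s])
    rng.shuffle(states)  # type: ignore[arg-type]

    margin = model.max_footprint_radius_um / px + 4
    centers = _place_centers(
        n_cells, shape, model.min_spacing_um / px, margin, rng
    )
    canvases = {"ch1": np.zeros(shape), "ch2": np.zeros(shape)}
    if annexin:
        canvases["annexin"] = np.zeros(shape)
    label_mask = np.zeros(shape, dtype=np.int32)

    cells = []
    for i, (state, (cr, cc)) in enumerate(zip(states, centers), start=1):
        factor = 1.0
        late = False
        if state is TrueState.NET:
            factor = float(rng.uniform(*model.net_area_factor_range))
        if state is TrueState.APOPTOTIC:
            late = bool(rng.uniform() < model.apoptotic_late_fraction)
        geom = _render_cell(
            canvases, label_mask, i, state, (cr, cc), model, rng,
            area_factor=factor, annexin=annexin, apoptotic_late=late,
        )
        cells.append(
            TrueCell(
                cell_id=i, state=state, center_row=cr, center_col=cc,
                base_nuclear_area_um2=geom["base_area_um2"],
                footprint_area_um2=geom["footprint_area_um2"],
                net_area_factor=factor, apoptotic_late=late,
            )
        )

    rendered = _finish_channels(canvases, model, rng)
    channels = {
        ChannelRole.NUCLEUS_ALL: ChannelImage(
            rendered["ch1"], model.bit_depth, ChannelRole.NUCLEUS_ALL, px
        ),
        ChannelRole.IMPERMEABLE_DNA: ChannelImage(
            rendered["ch2"], model.bit_depth, ChannelRole.IMPERMEABLE_DNA, px
        ),
    }
    if annexin:
        channels[ChannelRole.ANNEXIN] = ChannelImage(
            rendered["annexin"], model.bit_depth, ChannelRole.ANNEXIN, px
        )
    fimg = FieldImage(
        well_id=well_id, field_index=field_index,
        time_point_min=time_point_min, channels=channels,
    )
    fractions = {
        s.value: (counts.get(s, 0) / n_cells if n_cells else 0.0)
        for s in TrueState
    }
    return fimg, GroundTruth(
        cells=cells, label_mask=label_mask, class_fractions=fractions
    )


# ---------------------------------------------------------------------------
# time-lapse

#: scripted trajectory fates
class TrueFate(str, enum.Enum):
    NETOSIS = "NETOSIS"
    NECROSIS = "NECROSIS"
    LIVE = "LIVE"


def generate_timelapse(
    n_cells: int,
    fate_fractions: dict[TrueFate, float],
    frames_min: Sequence[float],
    model: PhenotypeModel,
    seed: int,
    well_id: str = "A01",
    field_index: int = 1,
) -> tuple[list[FieldImage], GroundTruth]:
    """Render a scripted time series of one field.

    NECROSIS cells permeabilize at an onset sampled in 30-60 min and stay
    condensed; NETOSIS cells permeabilize at 60-120 min and their
    impermeable-dye area then grows monotonically to the sampled
    decondensation factor over 3-5 frames; LIVE cells never permeabilize.
    Cells jitter by < 2 um per frame and are otherwise immobile.
    """
    frames = [float(t) for t in frames_min]
    if frames != sorted(frames) or len(set(frames)) != len(frames):
        raise ValueError("frames must be strictly increasing")
    rng = np.random.default_rng(seed)
    px = model.pixel_size_um
    shape = model.field_shape

    tot = sum(fate_fractions.values())
    if abs(tot - 1.0) > 1e-9:
        raise ValueError("fate fractions must sum to 1")
    fates: list[TrueFate] = []
    acc, assigned = 0.0, 0
    for f in sorted(fate_fractions, key=lambda f: f.value):
        acc += fate_fractions[f]
        k = int(round(acc * n_cells)) - assigned
        fates.extend([f] * k)
        assigned += k
    rng.shuffle(fates)  # type: ignore[arg-type]

    margin = model.max_footprint_radius_um / px + 4
    centers = _place_centers(n_cells, shape, model.min_spacing_um / px, margin, rng)

    # per-cell scripts
    onsets: list[Optional[float]] = []
    factors = []
    growth_frames = []
    base_radii = []
    lobes: list = [None] * n_cells
    for i, fate in enumerate(fates):
        base_radii.append(
            model.nuclear_radius_um
            * rng.uniform(1 - model.radius_jitter, 1 + model.radius_jitter)
        )
        if fate is TrueFate.NECROSIS:
            onsets.append(float(rng.uniform(30.0, 60.0)))
            factors.append(1.0)
            growth_frames.append(0)
        elif fate is TrueFate.NETOSIS:
            onsets.append(float(rng.uniform(60.0, 120.0)))
            factors.append(float(rng.uniform(*model.net_area_factor_range)))
            growth_frames.append(int(rng.integers(3, 6)))
        else:
            onsets.append(None)
            factors.append(1.0)
            growth_frames.append(0)
    jitter = rng.uniform(-1.5 / px, 1.5 / px, size=(len(frames), n_cells, 2))

    dt = frames[1] - frames[0] if len(frames) > 1 else 15.0
    per_frame: list[list[tuple[bool, float]]] = [[] for _ in range(n_cells)]
    fields = []
    for fi, t in enumerate(frames):
        canvases = {"ch1": np.zeros(shape), "ch2": np.zeros(shape)}
        label_mask = np.zeros(shape, dtype=np.int32)
        for i, fate in enumerate(fates):
            cr = centers[i, 0] + jitter[fi, i, 0]
            cc = centers[i, 1] + jitter[fi, i, 1]
            onset = onsets[i]
            permeable = onset is not None and t >= onset
            if fate is TrueFate.NETOSIS and permeable:
                progress = min(1.0, (t - onset) / (growth_frames[i] * dt))
                factor = 1.0 + progress * (factors[i] - 1.0)
                state = TrueState.NET
            elif fate is TrueFate.NECROSIS and permeable:
                factor = 1.0
                state = TrueState.NECROTIC
            else:
                factor = 1.0
                state = TrueState.LIVE
            geom = _render_cell(
                canvases, label_mask, i + 1, state, (cr, cc), model, rng,
                area_factor=factor,
                permeable=permeable if state in (TrueState.LIVE, TrueState.NET)
                else None,
                base_radius_um=base_radii[i],
                lobe_geometry=lobes[i],
            )
            if lobes[i] is None and geom["lobe_geometry"] is not None:
                lobes[i] = geom["lobe_geometry"]
            per_frame[i].append((bool(permeable), float(factor)))
        rendered = _finish_channels(canvases, model, rng)
        fields.append(
            FieldImage(
                well_id=well_id, field_index=field_index, time_point_min=t,
                channels={
                    ChannelRole.NUCLEUS_ALL: ChannelImage(
                        rendered["ch1"], model.bit_depth,
                        ChannelRole.NUCLEUS_ALL, px),
                    ChannelRole.IMPERMEABLE_DNA: ChannelImage(
                        rendered["ch2"], model.bit_depth,
                        ChannelRole.IMPERMEABLE_DNA, px),
                },
            )
        )

    cells = [
        TrueCell(
            cell_id=i + 1,
            state=TrueState.NET if fates[i] is TrueFate.NETOSIS
            else TrueState.NECROTIC if fates[i] is TrueFate.NECROSIS
            else TrueState.LIVE,
            center_row=centers[i, 0], center_col=centers[i, 1],
            base_nuclear_area_um2=np.pi * base_radii[i] ** 2,
            footprint_area_um2=np.pi * base_radii[i] ** 2 * factors[i],
            net_area_factor=factors[i],
        )
        for i in range(n_cells)
    ]
    n = max(n_cells, 1)
    fractions = {
        f.value: sum(1 for x in fates if x is f) / n for f in TrueFate
    }
    return fields, GroundTruth(
        cells=cells,
        label_mask=np.zeros(shape, dtype=np.int32),
        class_fractions=fractions,
        frames_min=frames,
        fates=[f.value for f in fates],
        onsets_min=onsets,
        per_frame=per_frame,
    )


# ---------------------------------------------------------------------------
# ground-truth matching and on-disk plates

#: expected two-channel class per generator state
EXPECTED_TWO_CHANNEL = {
    TrueState.LIVE: "TYPE3_LIVE",
    TrueState.NET: "TYPE1_NET",
    TrueState.NECROTIC: "TYPE2_OTHER_DEATH",
    TrueState.APOPTOTIC: "TYPE2_OTHER_DEATH",  # late sub-state; early is live
}

def match_ground_truth(
    records: Sequence,
    truth: GroundTruth,
    pixel_size_um: float,
    max_dist_um: float = 8.0,
) -> list[tuple[int, Optional[int]]]:
    """Match measured objects to ground-truth cells by nearest centre.

    Returns (record index, truth cell index or None) for every record;
    greedy on ascending distance, one-to-one.
    """
    if not truth.cells or not records:
        return [(i, None) for i in range(len(records))]
    tcent = np.array([[c.center_row, c.center_col] for c in truth.cells])
    rcent = np.array([[r.centroid_row, r.centroid_col] for r in records])
    d = np.sqrt(
        ((rcent[:, None, :] - tcent[None, :, :]) ** 2).sum(-1)
    ) * pixel_size_um
    pairs = []
    ri, ti = np.nonzero(d <= max_dist_um)
    order = np.argsort(d[ri, ti], kind="stable")
    used_r: set[int] = set()
    used_t: set[int] = set()
    out: dict[int, int] = {}
    for k in order:
        r, t = int(ri[k]), int(ti[k])
        if r in used_r or t in used_t:
            continue
        used_r.add(r)
        used_t.add(t)
        out[r] = t
    return [(i, out.get(i)) for i in range(len(records))]


@dataclass
class SyntheticWell:
    well_id: str
    role: WellRole
    treatment: str
    concentration: float
    fractions: dict[TrueState, float]
    units: str = "nM"


def simulate_plate(
    wells: Sequence[SyntheticWell],
    out_dir: str | Path,
    seed: int,
    model: Optional[PhenotypeModel] = None,
    n_cells_per_field: int = 200,
    fields_per_well: int = 2,
    annexin: bool = False,
) -> tuple[PlateLayout, pd.DataFrame]:
    """Write a complete synthetic plate directory: one TIFF per channel per
    field, a plate-layout YAML, and a ground-truth table."""
    model = model or PhenotypeModel()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    channel_names = {
        ChannelRole.NUCLEUS_ALL: "hoechst",
        ChannelRole.IMPERMEABLE_DNA: "sytox" if not annexin else "pi",
    }
    if annexin:
        channel_names[ChannelRole.ANNEXIN] = "annexin"
    layout = PlateLayout(
        wells=[
            WellSpec(w.well_id, w.treatment, w.concentration, w.units, w.role)
            for w in wells
        ],
        fields_per_well=fields_per_well,
        mode=PlateMode.FOUR_CHANNEL if annexin else PlateMode.TWO_CHANNEL,
        pixel_size_um=model.pixel_size_um,
        channel_names=channel_names,
    )
    truth_rows = []
    root_rng = np.random.default_rng(seed)
    for w in wells:
        for f in range(1, fields_per_well + 1):
            sub_seed = int(root_rng.integers(0, 2 ** 31 - 1))
            fimg, gt = generate_field(
                n_cells_per_field, w.fractions, model, sub_seed,
                well_id=w.well_id, field_index=f, annexin=annexin,
            )
            for role, ch in fimg.channels.items():
                name = layout.filename(w.well_id, f, role, 0.0)
                tifffile.imwrite(str(out_dir / name), ch.pixels)
            for c in gt.cells:
                truth_rows.append(
                    {"well_id": w.well_id, "field_index": f,
                     "cell_id": c.cell_id, "state": c.state.value,
                     "center_row": c.center_row, "center_col": c.center_col,
                     "footprint_area_um2": c.footprint_area_um2}
                )
    cfg = {
        "mode": layout.mode.value,
        "pixel_size_um": model.pixel_size_um,
        "fields_per_well": fields_per_well,
        "filename_template": layout.filename_template,
        "channels": {r.value.lower(): n for r, n in channel_names.items()},
        "wells": [
            {"well_id": w.well_id, "treatment": w.treatment,
             "concentration": w.concentration, "units": w.units,
             "role": w.role.value}
            for w in wells
        ],
    }
    with open(out_dir / "layout.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    truth = pd.DataFrame(truth_rows)
    truth.to_csv(out_dir / "ground_truth.csv", index=False)
    return layout, truth
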