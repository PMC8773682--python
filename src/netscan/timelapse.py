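"""Time-lapse tracking and death-trajectory classification.

Neutrophils are imaged every few minutes without stage movement, so objects
barely move between frames; a greedy globally-nearest-pair linker (sorted
by distance, assignments beyond ``max_displacement_um`` forbidden) is
sufficient and deterministic.  Tracks tolerate short detection gaps.

A track's fate follows the temporal signatures of the two lytic deaths:
necrosis permeabilizes early and the nucleus stays condensed for the rest
of the observation, whereas NETosis shows late loss of membrane integrity
followed by progressive chromatin decondensation (growing impermeable-dye
area).  Because the necrosis call rests on the chromatin *never*
decondensing, it additionally requires a minimum follow-up time after
permeabilization; a permeable cell observed too briefly is AMBIGUOUS.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .classification import ReferenceLevels
from .features import CellRecord


class Fate(str, enum.Enum):
    NETOSIS = "NETOSIS"
    NECROSIS = "NECROSIS"
    LIVE = "LIVE"
    AMBIGUOUS = "AMBIGUOUS"


@dataclass
class TrackEntry:
    time_point_min: float
    object_id: Optional[int]        # None = MISSING (bridged gap)
    target_area_ch2_um2: float
    avg_intensity_ch2: float
    centroid_row: float
    centroid_col: float


@dataclass
class Track:
    track_id: int
    entries: list[TrackEntry] = field(default_factory=list)
    fate: Optional[Fate] = None

    def __post_init__(self) -> None:
        times = [e.time_point_min for e in self.entries]
        if times != sorted(set(times)):
            raise ValueError("track entries must be strictly increasing in time")

    @property
    def detections(self) -> list[TrackEntry]:
        return [e for e in self.entries if e.object_id is not None]

    def first_permeable_min(self, refs: ReferenceLevels) -> Optional[float]:
        for e in self.detections:
            if e.avg_intensity_ch2 >= refs.intensity_ref:
                return e.time_point_min
        return None

    @property
    def max_area_um2(self) -> float:
        d = self.detections
        return max((e.target_area_ch2_um2 for e in d), default=0.0)


class TrackingError(ValueError):
    pass


def _entry(rec: CellRecord, t: float) -> TrackEntry:
    return TrackEntry(
        time_point_min=t,
        object_id=rec.object_id,
        target_area_ch2_um2=rec.target_area_ch2_um2,
        avg_intensity_ch2=rec.avg_intensity_ch2,
        centroid_row=rec.centroid_row,
        centroid_col=rec.centroid_col,
    )


def link_frames(
    frames: Sequence[tuple[float, Sequence[CellRecord]]],
    pixel_size_um: float,
    max_displacement_um: float = 10.0,
    max_gap: int = 1,
) -> list[Track]:
    """Link per-frame detections into tracks.

    For each frame transition, candidate pairs (active track end, new
    detection) closer than ``max_displacement_um`` are sorted by distance
    (ties by lower object id) and greedily matched.  Unmatched detections
    start new tracks; a track not matched for more than ``max_gap``
    consecutive frames is terminated.
    """
    if len(frames) < 2:
        raise TrackingError("need at least 2 frames to link")
    times = [t for t, _ in frames]
    if times != sorted(times) or len(set(times)) != len(times):
        raise TrackingError("frames must be in strictly increasing time order")

    max_disp_px = max_displacement_um / pixel_size_um
    tracks: list[Track] = []
    active: list[dict] = []     # {"track": Track, "pos": (r, c), "misses": int}
    next_id = 1

    t0, recs0 = frames[0]
    for rec in recs0:
        tr = Track(track_id=next_id, entries=[_entry(rec, t0)])
        next_id += 1
        tracks.append(tr)
        active.append({"track": tr, "pos": (rec.centroid_row, rec.centroid_col),
                       "misses": 0})

    for t, recs in frames[1:]:
        pairs = []
        for ai, a in enumerate(active):
            ar, ac = a["pos"]
            for ri, rec in enumerate(recs):
                d = np.hypot(rec.centroid_row - ar, rec.centroid_col - ac)
                if d <= max_disp_px:
                    pairs.append((d, a["track"].track_id, rec.object_id, ai, ri))
        pairs.sort()
        used_tracks: set[int] = set()
        used_recs: set[int] = set()
        for d, _tid, _oid, ai, ri in pairs:
            if ai in used_tracks or ri in used_recs:
                continue
            used_tracks.add(ai)
            used_recs.add(ri)
            rec = recs[ri]
            a = active[ai]
            a["track"].entries.append(_entry(rec, t))
            a["pos"] = (rec.centroid_row, rec.centroid_col)
            a["misses"] = 0
        survivors = []
        for ai, a in enumerate(active):
            if ai in used_tracks:
                survivors.append(a)
                continue
            a["misses"] += 1
            if a["misses"] <= max_gap:
                a["track"].entries.append(
                    TrackEntry(t, None, np.nan, np.nan, *a["pos"])
                )
                survivors.append(a)
            else:
                # drop trailing MISSING placeholders of the dead track
                while a["track"].entries and a["track"].entries[-1].object_id is None:
                    a["track"].entries.pop()
        active = survivors
        for ri, rec in enumerate(recs):
            if ri not in used_recs:
                tr = Track(track_id=next_id, entries=[_entry(rec, t)])
                next_id += 1
                tracks.append(tr)
                active.append(
                    {"track": tr,
                     "pos": (rec.centroid_row, rec.centroid_col), "misses": 0}
                )
    for a in active:     # trim unterminated gap placeholders
        while a["track"].entries and a["track"].entries[-1].object_id is None:
            a["track"].entries.pop()
    return tracks


def classify_trajectory(
    track: Track,
    refs: ReferenceLevels,
    min_follow_min: float = 45.0,
) -> Fate:
    """Assign a death fate to one track.

    LIVE: the intensity gate never passes.  NETOSIS: permeable and the Ch2
    area reaches the decondensation gate A* at or after permeabilization.
    NECROSIS: permeable, the area stays below A*, and the track persists at
    least ``min_follow_min`` beyond permeabilization (prolonged incubation
    without DNA extrusion).  Anything else — typically permeabilization too
    close to the end of the observation — is AMBIGUOUS.
    """
    det = track.detections
    if len(det) < 3:
        raise TrackingError(
            f"track {track.track_id} too short to classify ({len(det)} entries)"
        )
    t_perm = track.first_permeable_min(refs)
    if t_perm is None:
        return Fate.LIVE
    max_area_after = max(
        (e.target_area_ch2_um2 for e in det if e.time_point_min >= t_perm),
        default=0.0,
    )
    if max_area_after >= refs.area_ref_um2:
        return Fate.NETOSIS
    followed = det[-1].time_point_min - t_perm
    if followed >= min_follow_min:
        return Fate.NECROSIS
    return Fate.AMBIGUOUS


def classify_tracks(
    tracks: Sequence[Track],
    refs: ReferenceLevels,
    min_follow_min: float = 45.0,
    min_entries: int = 3,
) -> list[Track]:
    """Classify every track long enough; shorter tracks get fate None."""
    for tr in tracks:
        if len(tr.detections) >= min_entries:
            tr.fate = classify_trajectory(tr, refs, min_follow_min)
        else:
            tr.fate = None
    return tracks
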