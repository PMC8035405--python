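"""2-D coculture contact-duration analysis.

Each frame of a two-channel time-lapse (EGFP osteoblasts, here carried on
the "cyan"/green channel; tdTomato osteoclasts on "red") is Otsu-binarized
per channel, labeled with 8-connectivity, and filtered by physical area:
green objects ≥ 100 µm² and red objects ≥ 1000 µm² are retained (boundary
retained), excluding extracellular vesicles and mononuclear tdTomato+
cells. Objects are tracked across frames by greedy maximal pixel overlap;
green–red overlap components define contacts attributed to an object pair,
and a contact track spans the frames in which its pair keeps nonzero
overlap, tolerating up to ``max_gap`` missing frames. Durations are
reported in minutes, ``(end - start + 1) * frame_interval``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .containers import DataError, TimeLapse, TwoChannelImage
from .preprocess import otsu_threshold

__all__ = [
    "ContactTrack",
    "segment_frame",
    "track_objects",
    "link_contacts",
    "duration_summary",
    "analyze_timelapse",
    "MIN_GREEN_UM2",
    "MIN_RED_UM2",
    "LONG_THRESHOLD_MIN",
]

#: retention cutoffs (objects with area >= cutoff are analyzed)
MIN_GREEN_UM2 = 100.0
MIN_RED_UM2 = 1000.0
#: default boundary for a "long" contact, motivated by typical contacts
#: lasting under an hour in control cocultures
LONG_THRESHOLD_MIN = 60.0

_STRUCTURE_8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class ContactTrack:
    """One tracked contact between a green and a red object."""

    track_id: int
    green_id: int
    red_id: int
    start_frame: int
    end_frame: int
    duration_min: float
    n_frames_observed: int
    max_gap_used: int

    def __post_init__(self) -> None:
        if self.start_frame > self.end_frame:
            raise DataError("track start after end")


def segment_frame(
    frame: TwoChannelImage,
    min_green_um2: float = MIN_GREEN_UM2,
    min_red_um2: float = MIN_RED_UM2,
) -> dict[str, np.ndarray]:
    """Per-channel retained label images of one frame.

    Otsu binarization, 8-connected labeling, then retention of objects with
    area ≥ the channel cutoff (``>=`` — boundary objects are kept). A
    degenerate (constant) channel yields an empty labeling with a warning
    rather than an error.
    """
    px_area = frame.pixel_size_um**2
    cutoffs = {"cyan": min_green_um2, "red": min_red_um2}
    out: dict[str, np.ndarray] = {}
    for ch in ("cyan", "red"):
        try:
            _, mask = otsu_threshold(frame.channel(ch))
        except DataError:
            warnings.warn(f"degenerate {ch} channel: no objects retained")
            out[ch] = np.zeros(frame.shape, dtype=np.int32)
            continue
        lab, n_obj = ndi.label(mask, structure=_STRUCTURE_8)
        if n_obj:
            counts = np.bincount(lab.ravel())
            keep = counts * px_area >= cutoffs[ch]
            keep[0] = False
            lab = np.where(keep[lab], lab, 0)
        out[ch] = lab.astype(np.int32)
    return out


def _greedy_overlap_matching(prev: np.ndarray, curr: np.ndarray) -> dict[int, int]:
    """Map current-frame labels to previous-frame labels by maximal overlap."""
    both = (prev > 0) & (curr > 0)
    if not both.any():
        return {}
    pairs, counts = np.unique(
        np.stack([prev[both], curr[both]]), axis=1, return_counts=True
    )
    order = np.argsort(-counts, kind="stable")
    used_prev: set[int] = set()
    mapping: dict[int, int] = {}
    for idx in order:
        p, c = int(pairs[0, idx]), int(pairs[1, idx])
        if c in mapping or p in used_prev:
            continue
        mapping[c] = p
        used_prev.add(p)
    return mapping


def track_objects(label_frames: list[np.ndarray]) -> list[dict[int, int]]:
    """Assign persistent track ids to per-frame labels.

    Returns, per frame, a dict mapping frame-local label -> persistent id.
    Identity is propagated by greedy maximal overlap between consecutive
    frames; unmatched objects open new ids.
    """
    next_id = 0
    result: list[dict[int, int]] = []
    prev_ids: dict[int, int] = {}
    for t, lab in enumerate(label_frames):
        ids: dict[int, int] = {}
        mapping = _greedy_overlap_matching(label_frames[t - 1], lab) if t > 0 else {}
        for local in np.unique(lab):
            if local == 0:
                continue
            local = int(local)
            if local in mapping and mapping[local] in prev_ids:
                ids[local] = prev_ids[mapping[local]]
            else:
                ids[local] = next_id
                next_id += 1
        result.append(ids)
        prev_ids = ids
    return result


def link_contacts(
    frames: list[dict[str, np.ndarray]],
    frame_interval_min: float,
    max_gap: int = 0,
) -> list[ContactTrack]:
    """Contact tracks from per-frame retained label images.

    A contact exists in a frame wherever retained green and red objects
    overlap; each 8-connected overlap component is attributed to the
    (green, red) pair covering most of it. Tracks follow pair identity (not
    component identity), so a sliding pair that stays in touch remains one
    contact; runs separated by more than ``max_gap`` frames split.
    """
    if len(frames) < 2:
        raise DataError("need at least 2 frames to link contacts")
    shapes = {f["cyan"].shape for f in frames} | {f["red"].shape for f in frames}
    if len(shapes) != 1:
        raise DataError(f"inconsistent frame shapes: {sorted(shapes)}")
    if max_gap < 0:
        raise DataError("max_gap must be >= 0")

    green_ids = track_objects([f["cyan"] for f in frames])
    red_ids = track_objects([f["red"] for f in frames])

    pair_frames: dict[tuple[int, int], list[int]] = {}
    for t, f in enumerate(frames):
        overlap = (f["cyan"] > 0) & (f["red"] > 0)
        comp, n_comp = ndi.label(overlap, structure=_STRUCTURE_8)
        for i in range(1, n_comp + 1):
            voxels = comp == i
            g_local = int(np.bincount(f["cyan"][voxels]).argmax())
            r_local = int(np.bincount(f["red"][voxels]).argmax())
            pair = (green_ids[t][g_local], red_ids[t][r_local])
            pair_frames.setdefault(pair, [])
            if not pair_frames[pair] or pair_frames[pair][-1] != t:
                pair_frames[pair].append(t)

    tracks: list[ContactTrack] = []
    tid = 0
    for (g, r) in sorted(pair_frames):
        run_start = prev = pair_frames[(g, r)][0]
        observed = 1
        for t in pair_frames[(g, r)][1:] + [None]:
            if t is not None and t - prev <= max_gap + 1:
                prev = t
                observed += 1
                continue
            tracks.append(
                ContactTrack(
                    track_id=tid,
                    green_id=g,
                    red_id=r,
                    start_frame=run_start,
                    end_frame=prev,
                    duration_min=(prev - run_start + 1) * frame_interval_min,
                    n_frames_observed=observed,
                    max_gap_used=max_gap,
                )
            )
            tid += 1
            if t is not None:
                run_start = prev = t
                observed = 1
    return tracks


def duration_summary(
    tracks: list[ContactTrack], long_threshold_min: float = LONG_THRESHOLD_MIN
) -> dict:
    """Mean/median contact duration and the fraction of long contacts.

    ``long_fraction`` is the share of tracks lasting at least
    ``long_threshold_min`` minutes. An empty track list yields a null
    summary (count 0), not an error.
    """
    durations = np.array([t.duration_min for t in tracks], dtype=float)
    if durations.size == 0:
        return {
            "n_tracks": 0,
            "mean_min": None,
            "median_min": None,
            "long_fraction": None,
            "long_threshold_min": long_threshold_min,
        }
    return {
        "n_tracks": int(durations.size),
        "mean_min": float(durations.mean()),
        "median_min": float(np.median(durations)),
        "long_fraction": float(np.mean(durations >= long_threshold_min)),
        "long_threshold_min": long_threshold_min,
    }


def analyze_timelapse(
    timelapse: TimeLapse,
    min_green_um2: float = MIN_GREEN_UM2,
    min_red_um2: float = MIN_RED_UM2,
    max_gap: int = 0,
    long_threshold_min: float = LONG_THRESHOLD_MIN,
) -> tuple[pd.DataFrame, dict]:
    """Segment every frame, link contacts, and summarize durations."""
    frames = [
        segment_frame(f, min_green_um2, min_red_um2) for f in timelapse.frames
    ]
    tracks = link_contacts(frames, timelapse.frame_interval_min, max_gap)
    table = pd.DataFrame(
        [
            {
                "track_id": t.track_id,
                "green_id": t.green_id,
                "red_id": t.red_id,
                "start_frame": t.start_frame,
                "end_frame": t.end_frame,
                "start_min": t.start_frame * timelapse.frame_interval_min,
                "end_min": (t.end_frame + 1) * timelapse.frame_interval_min,
                "duration_min": t.duration_min,
            }
            for t in tracks
        ],
        columns=[
            "track_id",
            "green_id",
            "red_id",
            "start_frame",
            "end_frame",
            "start_min",
            "end_min",
            "duration_min",
        ],
    )
    return table, duration_summary(tracks, long_threshold_min)
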