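"""Pixel-level membrane dynamics from segmented cell-mask movies.

A cell's footprint at time *t* is compared with its footprints at *t−1* and
*t+1* (at their actual positions — frames are never re-aligned to the cell
center, so translocation itself generates protrusion/retraction signal).
Every foreground pixel of the focal frame falls into exactly one of four
categories determined by its membership in the neighbouring frames:

==========  ==========  ==============
in prev?    in next?    category
==========  ==========  ==============
yes         yes         stable
no          yes         protrusion
yes         no          retraction
no          no          short-lived
==========  ==========  ==============

Dynamic Cell Area is the total non-stable area (protrusion + retraction +
short-lived); ΔCell Area is protrusion minus retraction area (net growth).
Cell Speed is the distance between the centers of area of consecutive
frames divided by the frame interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BACKGROUND",
    "STABLE",
    "PROTRUSION",
    "RETRACTION",
    "SHORT_LIVED",
    "MaskSequence",
    "RegionMap",
    "classify_regions",
    "compute_speed",
    "sequence_dynamics",
]

# label codes used in RegionMap.labels and exported label images
BACKGROUND, STABLE, PROTRUSION, RETRACTION, SHORT_LIVED = 0, 1, 2, 3, 4

#: default spatial calibration, μm per pixel
DEFAULT_PIXEL_SIZE_UM = 0.21
#: default temporal calibration, minutes per frame
DEFAULT_FRAME_INTERVAL_MIN = 5.0


def _as_bool_mask(mask: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be a 2-D mask, got shape {arr.shape}")
    return arr.astype(bool, copy=False)


@dataclass
class MaskSequence:
    """Ordered binary cell masks with calibration and gap flags.

    ``frames`` is a (T, H, W) boolean array; ``gap_flags[t]`` marks frames
    where the cell could not be segmented (the mask is ignored there).
    """

    frames: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    frame_interval_min: float = DEFAULT_FRAME_INTERVAL_MIN
    gap_flags: np.ndarray | None = None
    cell_id: str = "cell"
    experiment_id: str = "exp"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames).astype(bool)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) stack")
        if self.gap_flags is None:
            self.gap_flags = np.zeros(len(self.frames), dtype=bool)
        self.gap_flags = np.asarray(self.gap_flags, dtype=bool)
        if self.gap_flags.shape != (len(self.frames),):
            raise ValueError("gap_flags must have one entry per frame")
        for t in range(len(self.frames)):
            if not self.gap_flags[t] and not self.frames[t].any():
                raise ValueError(f"non-gap frame {t} has no foreground pixels")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class RegionMap:
    """Per-pixel partition of one frame plus derived areas (μm²)."""

    frame_index: int
    labels: np.ndarray
    pixel_size_um: float
    # exact integer pixel counts (kept alongside calibrated areas)
    n_stable: int = 0
    n_protrusion: int = 0
    n_retraction: int = 0
    n_short_lived: int = 0
    area_stable: float = field(init=False)
    area_protrusion: float = field(init=False)
    area_retraction: float = field(init=False)
    area_short_lived: float = field(init=False)

    def __post_init__(self) -> None:
        px_area = self.pixel_size_um**2
        self.area_stable = self.n_stable * px_area
        self.area_protrusion = self.n_protrusion * px_area
        self.area_retraction = self.n_retraction * px_area
        self.area_short_lived = self.n_short_lived * px_area

    @property
    def cell_area(self) -> float:
        return (
            self.area_stable
            + self.area_protrusion
            + self.area_retraction
            + self.area_short_lived
        )

    @property
    def dynamic_cell_area(self) -> float:
        """Total non-stable area: protrusion + retraction + short-lived."""
        return self.area_protrusion + self.area_retraction + self.area_short_lived

    @property
    def delta_cell_area(self) -> float:
        """Net area change: protrusion minus retraction."""
        return self.area_protrusion - self.area_retraction


def classify_regions(
    mask_prev: np.ndarray,
    mask_curr: np.ndarray,
    mask_next: np.ndarray,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    frame_index: int = 0,
) -> RegionMap:
    """Partition the focal frame's pixels by membership in its neighbours.

    Regions are plain pixel sets: no connected-component labelling or
    minimum-size filtering is applied, and masks are compared at their
    actual positions (no centering).
    """
    prev = _as_bool_mask(mask_prev, "mask_prev")
    curr = _as_bool_mask(mask_curr, "mask_curr")
    nxt = _as_bool_mask(mask_next, "mask_next")
    if not (prev.shape == curr.shape == nxt.shape):
        raise ValueError(
            f"mask shapes differ: {prev.shape}, {curr.shape}, {nxt.shape}"
        )
    if not curr.any():
        raise ValueError("focal mask is empty")

    labels = np.zeros(curr.shape, dtype=np.uint8)
    labels[curr & prev & nxt] = STABLE
    labels[curr & ~prev & nxt] = PROTRUSION
    labels[curr & prev & ~nxt] = RETRACTION
    labels[curr & ~prev & ~nxt] = SHORT_LIVED

    return RegionMap(
        frame_index=frame_index,
        labels=labels,
        pixel_size_um=pixel_size_um,
        n_stable=int((labels == STABLE).sum()),
        n_protrusion=int((labels == PROTRUSION).sum()),
        n_retraction=int((labels == RETRACTION).sum()),
        n_short_lived=int((labels == SHORT_LIVED).sum()),
    )


def center_of_area(mask: np.ndarray) -> tuple[float, float]:
    """(row, col) centroid of the foreground, uniform pixel weights."""
    mask = _as_bool_mask(mask, "mask")
    if not mask.any():
        raise ValueError("cannot compute centroid of an empty mask")
    rows, cols = np.nonzero(mask)
    return float(rows.mean()), float(cols.mean())


def compute_speed(
    mask_curr: np.ndarray,
    mask_next: np.ndarray,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    frame_interval_min: float = DEFAULT_FRAME_INTERVAL_MIN,
) -> float:
    """Cell speed in μm/min: centroid displacement over one frame interval."""
    r0, c0 = center_of_area(mask_curr)
    r1, c1 = center_of_area(mask_next)
    dist_px = float(np.hypot(r1 - r0, c1 - c0))
    return dist_px * pixel_size_um / frame_interval_min


def sequence_dynamics(seq: MaskSequence) -> pd.DataFrame:
    """Per-frame dynamics table for a whole mask sequence.

    A frame is *valid* for the dynamic measures only when both temporal
    neighbours exist and are segmentable: the first and last frames of the
    sequence and frames adjacent to gaps are flagged invalid (protrusions
    are undefined without a previous frame, retractions without a next).
    Speed is reported wherever the forward pair (t, t+1) exists, attached
    to frame t.
    """
    n = len(seq)
    if n < 3:
        raise ValueError("need at least 3 frames to measure dynamics")
    ok = ~seq.gap_flags
    if ok.sum() < 3:
        warnings.warn("fewer than 3 segmentable frames: no valid dynamics")

    px = seq.pixel_size_um
    rows = []
    for t in range(n):
        rec: dict[str, object] = {
            "frame": t,
            "gap": bool(seq.gap_flags[t]),
            "valid": False,
            "speed": np.nan,
            "cell_area": np.nan,
            "protrusion_pixels": np.nan,
            "retraction_pixels": np.nan,
            "short_lived_pixels": np.nan,
            "area_stable": np.nan,
            "area_protrusion": np.nan,
            "area_retraction": np.nan,
            "area_short_lived": np.nan,
            "dynamic_cell_area": np.nan,
            "delta_cell_area": np.nan,
        }
        if ok[t]:
            rec["cell_area"] = float(seq.frames[t].sum()) * px**2
            if t + 1 < n and ok[t + 1]:
                rec["speed"] = compute_speed(
                    seq.frames[t], seq.frames[t + 1], px, seq.frame_interval_min
                )
            if 0 < t < n - 1 and ok[t - 1] and ok[t + 1]:
                rm = classify_regions(
                    seq.frames[t - 1], seq.frames[t], seq.frames[t + 1], px, t
                )
                rec.update(
                    valid=True,
                    protrusion_pixels=rm.n_protrusion,
                    retraction_pixels=rm.n_retraction,
                    short_lived_pixels=rm.n_short_lived,
                    area_stable=rm.area_stable,
                    area_protrusion=rm.area_protrusion,
                    area_retraction=rm.area_retraction,
                    area_short_lived=rm.area_short_lived,
                    dynamic_cell_area=rm.dynamic_cell_area,
                    delta_cell_area=rm.delta_cell_area,
                )
        rows.append(rec)
    df = pd.DataFrame(rows)
    df["cell_id"] = seq.cell_id
    df["experiment_id"] = seq.experiment_id
    return df
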