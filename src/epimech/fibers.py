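"""Stress-fiber quantification by line-profile peak detection.

A profile is sampled along the longest interior chord perpendicular to
the cell's dominant fiber orientation (estimated from the image
structure tensor), excluding the cortical rim.  Peaks are local maxima
whose height reaches the wild-type reference threshold: one standard
deviation below the mean height of raw peaks pooled across control
cells.  Fiber density is the number of accepted peaks per μm of
profile.  Whole-cell intensity ratios between mutant and control cells
are background-subtracted using cell-free (label 0) regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.feature import structure_tensor

from .synth.scene import (FIBER_HALFWIDTH_PX, ImageScene, SceneTruth)

MIN_PROFILE_UM = 2.0
MIN_PEAK_SEPARATION_UM = 0.5
DEFAULT_CORTICAL_MARGIN_UM = 1.0


@dataclass
class LineProfile:
    """Intensity along a chord across one cell's basal surface."""

    positions_um: np.ndarray
    intensity: np.ndarray
    cell_id: int

    def __post_init__(self) -> None:
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.positions_um.shape != self.intensity.shape:
            raise ValueError("positions and intensities must align")
        if np.any(np.diff(self.positions_um) <= 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def length_um(self) -> float:
        return float(self.positions_um[-1] - self.positions_um[0])


@dataclass
class ControlReference:
    """Pooled wild-type peak statistics defining the detection threshold."""

    mean_peak_intensity: float
    sd_peak_intensity: float
    n_peaks: int

    @property
    def threshold(self) -> float:
        return self.mean_peak_intensity - self.sd_peak_intensity


@dataclass
class PeakSet:
    peak_positions_um: np.ndarray
    peak_heights: np.ndarray
    threshold_used: float

    def __len__(self) -> int:
        return int(self.peak_positions_um.size)


def local_maxima(values: np.ndarray) -> np.ndarray:
    """Indices of raw local maxima: strict rise on the left, non-strict
    fall on the right, so a plateau yields its leftmost sample."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        return np.array([], dtype=int)
    interior = np.arange(1, x.size - 1)
    keep = (x[interior] > x[interior - 1]) & (x[interior] >= x[interior + 1])
    return interior[keep]


def extract_profile(scene: ImageScene, cell_id: int,
                    cortical_margin_um: float = DEFAULT_CORTICAL_MARGIN_UM
                    ) -> LineProfile:
    """Sample an intensity profile across a cell, perpendicular to its fibers.

    The chord runs through the centroid of the margin-eroded cell
    interior, along the dominant gradient direction of the structure
    tensor (which is normal to the fiber axis), and is sampled at pixel
    pitch with linear interpolation.
    """
    cal = scene.calibration
    mask = scene.labels == cell_id
    if not mask.any():
        raise ValueError(f"cell {cell_id} not present in labels")
    margin_px = max(int(round(cortical_margin_um / cal)), 0)
    interior = mask
    if margin_px:
        interior = ndimage.binary_erosion(
            mask, ndimage.generate_binary_structure(2, 1), iterations=margin_px)
    if not interior.any():
        raise ValueError(f"cell {cell_id} degenerate after cortical erosion")

    # dominant variation direction from the structure tensor
    rows, cols = np.nonzero(interior)
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    window = scene.image[r0:r1, c0:c1]
    sub = interior[r0:r1, c0:c1]
    Arr, Arc, Acc = structure_tensor(window, sigma=1.5, order="rc")
    M = np.array([[Arr[sub].mean(), Arc[sub].mean()],
                  [Arc[sub].mean(), Acc[sub].mean()]])
    evals, evecs = np.linalg.eigh(M)
    direction = evecs[:, int(np.argmax(evals))]     # (dr, dc), unit norm
    if not np.isfinite(direction).all() or np.allclose(direction, 0):
        direction = np.array([0.0, 1.0])
    # snap near-axis chords onto the pixel grid: keeps sampling exact on
    # axis-aligned fibers instead of drifting sub-pixel over the chord
    dom = int(np.argmax(np.abs(direction)))
    if abs(direction[1 - dom]) < 0.1:
        direction = np.zeros(2)
        direction[dom] = 1.0

    centroid = np.array([rows.mean(), cols.mean()])
    # longest contiguous run of the chord inside the interior, through the centroid
    diag = float(np.hypot(*interior.shape))
    s_fine = np.arange(-diag, diag, 0.25)
    pts = centroid[None, :] + s_fine[:, None] * direction[None, :]
    rr = np.round(pts[:, 0]).astype(int)
    cc = np.round(pts[:, 1]).astype(int)
    valid = ((rr >= 0) & (rr < interior.shape[0])
             & (cc >= 0) & (cc < interior.shape[1]))
    inside = np.zeros(s_fine.size, dtype=bool)
    inside[valid] = interior[rr[valid], cc[valid]]
    zero_idx = int(np.searchsorted(s_fine, 0.0))
    if not inside[zero_idx]:
        raise ValueError(f"cell {cell_id}: centroid outside the eroded interior")
    lo = zero_idx
    while lo > 0 and inside[lo - 1]:
        lo -= 1
    hi = zero_idx
    while hi < inside.size - 1 and inside[hi + 1]:
        hi += 1
    s_min, s_max = s_fine[lo], s_fine[hi]
    if (s_max - s_min) * cal < MIN_PROFILE_UM:
        raise ValueError(
            f"cell {cell_id}: interior chord shorter than {MIN_PROFILE_UM} um")

    # sample at pixel pitch, snapped to the pixel grid along the dominant
    # chord axis so peak samples land on rendered fiber centres exactly
    if direction[dom] < 0:
        direction = -direction
    p0 = centroid + s_min * direction
    shift = (np.ceil(p0[dom] - 1e-9) - p0[dom]) / direction[dom]
    s = np.arange(s_min + shift, s_max + 0.5, 1.0)  # pixel-pitch sampling
    coords = centroid[None, :] + s[:, None] * direction[None, :]
    values = ndimage.map_coordinates(scene.image, coords.T, order=1)
    return LineProfile(positions_um=(s - s[0]) * cal, intensity=values,
                       cell_id=cell_id)


def build_control_reference(profiles: Sequence[LineProfile]) -> ControlReference:
    """Pool raw local-maximum heights across wild-type profiles."""
    if len(profiles) < 2:
        raise ValueError("need at least two control profiles")
    heights: List[float] = []
    for prof in profiles:
        idx = local_maxima(prof.intensity)
        heights.extend(prof.intensity[idx].tolist())
    if len(heights) < 2:
        raise ValueError("too few raw maxima in control profiles")
    arr = np.asarray(heights)
    return ControlReference(mean_peak_intensity=float(arr.mean()),
                            sd_peak_intensity=float(arr.std(ddof=1)),
                            n_peaks=arr.size)


def detect_peaks(profile: LineProfile, ref: ControlReference,
                 min_separation_um: float = MIN_PEAK_SEPARATION_UM) -> PeakSet:
    """Local maxima at or above the wild-type threshold (mean − 1 SD).

    Candidates closer than ``min_separation_um`` are merged greedily,
    keeping the higher peak (ties resolved toward the leftmost).
    """
    threshold = ref.threshold
    idx = local_maxima(profile.intensity)
    heights = profile.intensity[idx]
    keep = heights >= threshold
    idx, heights = idx[keep], heights[keep]
    pos = profile.positions_um[idx]

    order = np.lexsort((pos, -heights))             # by height desc, then position
    accepted: List[int] = []
    for k in order:
        if all(abs(pos[k] - pos[j]) >= min_separation_um for j in accepted):
            accepted.append(int(k))
    accepted.sort(key=lambda k: pos[k])
    return PeakSet(peak_positions_um=pos[accepted],
                   peak_heights=heights[accepted],
                   threshold_used=threshold)


def peak_density(peaks: PeakSet, profile: LineProfile) -> float:
    """Fiber peaks per μm of profile length."""
    if profile.length_um <= 0:
        raise ValueError("profile has zero length")
    return len(peaks) / profile.length_um


def _fiber_region_mask(scene: ImageScene, truth: SceneTruth,
                       cell_ids: Iterable[int]) -> np.ndarray:
    mask = np.zeros_like(scene.labels, dtype=bool)
    wanted = set(cell_ids)
    for f in truth.fibers:
        if f.cell_id in wanted:
            c0 = max(f.col - FIBER_HALFWIDTH_PX, 0)
            c1 = min(f.col + FIBER_HALFWIDTH_PX + 1, mask.shape[1])
            mask[f.row_start:f.row_stop + 1, c0:c1] = True
    return mask


def relative_intensity(scene: ImageScene, cell_ids_mutant: Sequence[int],
                       cell_ids_control: Sequence[int],
                       mask_source: str = "whole-cell",
                       truth: Optional[SceneTruth] = None) -> float:
    """Mutant / control mean per-area intensity ratio.

    The mean of cell-free (label 0) pixels is subtracted from both
    groups first.  ``mask_source`` selects whole-cell masks or the
    fiber-region masks reconstructed from the scene truth (required for
    that mode, since fibers are not re-segmented here).
    """
    if not cell_ids_mutant or not cell_ids_control:
        raise ValueError("both cell groups must be non-empty")
    if mask_source not in ("whole-cell", "fiber-region"):
        raise ValueError(f"unknown mask_source {mask_source!r}")
    bg_pixels = scene.image[scene.labels == 0]
    background = float(bg_pixels.mean()) if bg_pixels.size else 0.0

    def group_mean(ids: Sequence[int]) -> float:
        if mask_source == "whole-cell":
            mask = np.isin(scene.labels, list(ids))
        else:
            if truth is None:
                raise ValueError("fiber-region mode requires the scene truth")
            mask = _fiber_region_mask(scene, truth, ids)
        if not mask.any():
            raise ValueError("empty group mask")
        return float(scene.image[mask].mean()) - background

    return group_mean(cell_ids_mutant) / group_mean(cell_ids_control)
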