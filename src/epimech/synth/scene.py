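"""Synthetic basal-surface scenes: cell mosaics with stress fibers,
cortical rings, and whip-like protrusions.

A scene emulates one confocal frame of the follicular epithelium basal
surface.  Cells are Voronoi regions of a jittered hexagonal lattice
(yielding realistic tricellular junctions); an outer ring of virtual
seeds becomes label-0 background so that cell-free regions exist for
background estimation.  Each cell is rendered with

* parallel vertical stress fibers (Gaussian cross-section, truncated at
  3σ so that fiber peak heights are exact),
* a cortical ring on every boundary whose intensity depends on the
  genotypes of the two flanking cells (two mutant cells share a
  brighter junction), and
* whip-like protrusions: short polylines hugging the cell edge,
  anchored at leading-edge tricellular junctions, rendered only in the
  F-actin channel (whips contain no myosin).

Poisson shot noise plus Gaussian read noise is added last; ground truth
is recorded before noise.  ``noise_sd = 0`` disables both noise terms so
noiseless renders are exactly reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .config import Preset, SynthConfig

FIBER_SIGMA_PX = 1.0          # Gaussian cross-section of a rendered fiber
FIBER_HALFWIDTH_PX = 3        # truncation radius (3 sigma)
FIBER_SPACING_PX = 7          # > 2*halfwidth: cross-sections never overlap
CORTICAL_MARGIN_PX = 4        # rim excluded from the fiber interior
CORTEX_MYOSIN_AU = 30.0       # flat cortical level in the myosin channel


@dataclass(frozen=True)
class FiberSegment:
    """One rendered stress fiber: a vertical segment at pixel column ``col``."""

    cell_id: int
    col: int
    row_start: int
    row_stop: int          # inclusive
    peak_intensity: float


@dataclass(frozen=True)
class Whip:
    cell_id: int
    anchor: Tuple[float, float]        # (row, col) of the anchoring junction
    polyline: np.ndarray               # (N, 2) pixel coordinates
    length_um: float


@dataclass
class SceneTruth:
    """Ground truth recorded by the generator before noise."""

    fibers: List[FiberSegment]
    cortical_intensity: Dict[FrozenSet[int], float]
    whips: List[Whip]
    protrusion_masks: Dict[int, np.ndarray]
    fiber_orientation_deg: float = 90.0    # fibers run along image rows axis

    def fiber_count(self, cell_id: int) -> int:
        return sum(1 for f in self.fibers if f.cell_id == cell_id)

    def whip_count(self, cell_id: int) -> int:
        return sum(1 for w in self.whips if w.cell_id == cell_id)


@dataclass
class ImageScene:
    """One basal-surface frame: image, cell labels, genotypes, calibration."""

    image: np.ndarray                       # 2-D nonnegative, a.u.
    labels: np.ndarray                      # 2-D int, 0 = background
    genotype: Dict[int, str]                # cell id -> {"control", "mutant"}
    tricellular_points: List[Tuple[float, float]]
    calibration: float                      # um / pixel
    channel: str = "factin"
    leading_edge: str = "west"              # side facing the migration direction

    def __post_init__(self) -> None:
        if self.image.shape != self.labels.shape:
            raise ValueError("image and labels must share a shape")

    @property
    def cell_ids(self) -> List[int]:
        return sorted(self.genotype)

    def cells_of(self, genotype: str) -> List[int]:
        return sorted(c for c, g in self.genotype.items() if g == genotype)

    def interior_cells(self) -> List[int]:
        """Cells not touching background; these carry full junction sets."""
        bg_adjacent = set()
        lab = self.labels
        for ax, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
            rolled = np.roll(lab, shift, axis=ax)
            edge = (lab > 0) & (rolled == 0)
            bg_adjacent.update(np.unique(lab[edge]).tolist())
        border = set(np.unique(np.concatenate([
            lab[0], lab[-1], lab[:, 0], lab[:, -1]])).tolist())
        return sorted(set(self.genotype) - bg_adjacent - border)


def junction_cells(labels: np.ndarray, point: Tuple[float, float]) -> FrozenSet[int]:
    """Distinct nonzero labels within a 1-pixel neighbourhood of ``point``."""
    r, c = point
    r0, c0 = int(math.floor(r)), int(math.floor(c))
    h, w = labels.shape
    block = labels[max(r0 - 1, 0):min(r0 + 2, h), max(c0 - 1, 0):min(c0 + 2, w)]
    return frozenset(int(v) for v in np.unique(block) if v != 0)


# ---------------------------------------------------------------------------
# mosaic construction

def _hex_lattice(n_cells: int, pitch: float, jitter_frac: float,
                 rng: np.random.Generator):
    """Jittered hex lattice with one virtual (background) ring around it."""
    ncols = math.ceil(math.sqrt(n_cells))
    nrows = math.ceil(n_cells / ncols)
    pitch_v = pitch * 0.87
    margin = pitch * 0.75
    points, ids = [], []
    next_id = 1
    for r in range(-1, nrows + 1):
        for c in range(-1, ncols + 1):
            y = margin + (r + 0.5) * pitch_v
            x = margin + (c + 0.5) * pitch + (r % 2) * pitch / 2.0
            jy, jx = rng.uniform(-jitter_frac, jitter_frac, size=2) * pitch
            points.append((y + jy, x + jx))
            inner = 0 <= r < nrows and 0 <= c < ncols
            if inner and next_id <= n_cells:
                ids.append(next_id)
                next_id += 1
            else:
                ids.append(0)
    height = int(round(2 * margin + nrows * pitch_v))
    width = int(round(2 * margin + ncols * pitch + pitch / 2.0))
    return np.asarray(points), np.asarray(ids), (height, width)


def _voronoi_labels(points, ids, shape):
    rows, cols = np.mgrid[0:shape[0], 0:shape[1]]
    pix = np.column_stack([rows.ravel(), cols.ravel()]).astype(float)
    _, nearest = cKDTree(points).query(pix)
    return ids[nearest].reshape(shape).astype(np.int32)


def _tricellular_points(labels: np.ndarray) -> List[Tuple[float, float]]:
    h, w = labels.shape
    pts: List[Tuple[float, float]] = []
    blocks = np.stack([labels[:-1, :-1], labels[:-1, 1:],
                       labels[1:, :-1], labels[1:, 1:]], axis=-1)
    nz = np.sort(blocks, axis=-1)
    # count distinct nonzero labels per 2x2 block
    distinct = (np.diff(nz, axis=-1) != 0).sum(axis=-1) + 1
    distinct -= (nz[..., 0] == 0).astype(int) * 0  # zeros collapse below
    has_zero = (blocks == 0).any(axis=-1)
    distinct_nonzero = distinct - has_zero.astype(int)
    cand = np.argwhere(distinct_nonzero >= 3)
    for r, c in cand:
        p = (r + 0.5, c + 0.5)
        if all((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 > 6.25 for q in pts):
            pts.append(p)
    return pts


def _boundary_pairs(labels: np.ndarray):
    """4-adjacent pixel pairs with distinct nonzero labels.

    Returns dict mapping frozenset({a, b}) -> list of (pixel_a, pixel_b).
    """
    pairs: Dict[FrozenSet[int], list] = {}
    h, w = labels.shape
    for dr, dc in ((0, 1), (1, 0)):
        a = labels[: h - dr, : w - dc]
        b = labels[dr:, dc:]
        mask = (a != b) & (a > 0) & (b > 0)
        rs, cs = np.nonzero(mask)
        for r, c in zip(rs.tolist(), cs.tolist()):
            key = frozenset((int(a[r, c]), int(b[r, c])))
            pairs.setdefault(key, []).append(((r, c), (r + dr, c + dc)))
    return pairs


# ---------------------------------------------------------------------------
# rendering

def _render_fibers(image, interior_buffered, cell_id, preset_intensity,
                   fiber_count, truth_fibers):
    """Place ``fiber_count`` vertical fibers in the buffered interior.

    Fibers sit at integer columns with fixed spacing FIBER_SPACING_PX,
    centred in the interior span.  The spacing exceeds twice the
    truncation half-width, so cross-sections never overlap and every
    fiber contributes an identical intensity footprint with its peak
    sample equal to ``preset_intensity`` exactly.
    """
    rows, cols = np.nonzero(interior_buffered)
    if rows.size == 0:
        return
    crow = int(round(rows.mean()))
    row_cols = np.nonzero(interior_buffered[crow])[0]
    if row_cols.size == 0:
        return
    cmin, cmax = int(row_cols.min()), int(row_cols.max())
    span = cmax - cmin
    n = fiber_count
    if n <= 0:
        return
    while n > 1 and (n - 1) * FIBER_SPACING_PX > span:
        n -= 1
    start = int(round((cmin + cmax) / 2 - (n - 1) * FIBER_SPACING_PX / 2))
    xs = [start + i * FIBER_SPACING_PX for i in range(n)]
    dxs = np.arange(-FIBER_HALFWIDTH_PX, FIBER_HALFWIDTH_PX + 1)
    profile = preset_intensity * np.exp(-(dxs.astype(float) ** 2)
                                        / (2.0 * FIBER_SIGMA_PX ** 2))
    h = image.shape[0]
    for x0 in xs:
        col_rows = np.nonzero(interior_buffered[:, x0])[0]
        if col_rows.size == 0:
            continue
        # contiguous run containing the centroid row (or the nearest run)
        runs = np.split(col_rows, np.nonzero(np.diff(col_rows) > 1)[0] + 1)
        run = min(runs, key=lambda rr: abs(int(rr.mean()) - crow))
        r0, r1 = int(run.min()), int(run.max())
        for dx, val in zip(dxs.tolist(), profile.tolist()):
            x = x0 + dx
            if 0 <= x < image.shape[1]:
                seg = image[r0:r1 + 1, x]
                np.maximum(seg, val, out=seg)
        truth_fibers.append(FiberSegment(cell_id, x0, r0, r1, preset_intensity))


def _whip_polyline(boundary_tree, boundary_pts, anchor, length_px, rng):
    """Polyline hugging the cell edge, starting at the anchor junction."""
    start = np.asarray(anchor, float)
    _, i0 = boundary_tree.query(start)
    p = boundary_pts[i0].astype(float)
    pts = [p]
    # walk along boundary pixels away from the anchor
    direction = None
    travelled = 0.0
    while travelled < length_px:
        d = np.linalg.norm(boundary_pts - pts[-1], axis=1)
        near = np.nonzero((d > 0.5) & (d < 2.5))[0]
        if near.size == 0:
            break
        if direction is None:
            j = near[rng.integers(near.size)]
        else:
            vecs = boundary_pts[near] - pts[-1]
            scores = vecs @ direction
            j = near[int(np.argmax(scores))]
            if (boundary_pts[j] - pts[-1]) @ direction <= 0:
                break
        step = boundary_pts[j].astype(float)
        direction = step - pts[-1]
        direction = direction / (np.linalg.norm(direction) + 1e-12)
        travelled += float(np.linalg.norm(step - pts[-1]))
        pts.append(step)
    return np.asarray(pts)


def _render_polyline(image, polyline, value):
    from skimage.draw import line
    for p, q in zip(polyline[:-1], polyline[1:]):
        rr, cc = line(int(round(p[0])), int(round(p[1])),
                      int(round(q[0])), int(round(q[1])))
        keep = (rr >= 0) & (rr < image.shape[0]) & (cc >= 0) & (cc < image.shape[1])
        seg = image[rr[keep], cc[keep]]
        image[rr[keep], cc[keep]] = np.maximum(seg, value)


# ---------------------------------------------------------------------------
# public API

def generate_scene(config: SynthConfig, preset_name: str, n_cells: int,
                   seed: int, channel: str = "factin",
                   pitch_px: int = 64) -> Tuple[ImageScene, SceneTruth]:
    """Render one synthetic basal-surface scene plus its ground truth.

    ``preset_name`` selects the condition of the *clone* cells: with
    ``"control"`` every cell is wild type; any other preset produces a
    mosaic whose right half is a clone of that condition next to control
    neighbours (mirroring mosaic egg chambers with mys clones).

    Parameters
    ----------
    channel:
        ``"factin"`` renders fibers at ``fiber_intensity``, cortical rings
        and whips; ``"myosin"`` renders fibers at ``myosin_intensity`` and a
        flat dim cortex, and never renders whips.
    """
    preset = config.preset(preset_name)
    control = config.preset("control")
    if n_cells < 4:
        raise ValueError("n_cells must be >= 4 to form tricellular junctions")
    if channel not in ("factin", "myosin"):
        raise ValueError(f"unknown channel {channel!r}")
    rng = np.random.default_rng(seed)

    points, ids, shape = _hex_lattice(n_cells, float(pitch_px), 0.06, rng)
    labels = _voronoi_labels(points, ids, shape)
    cell_ids = sorted(int(i) for i in np.unique(labels) if i != 0)

    # genotype assignment: right-half clone for non-control presets
    if preset_name == "control":
        genotype = {c: "control" for c in cell_ids}
    else:
        seed_cols = {int(i): points[k][1] for k, i in enumerate(ids) if i != 0}
        med = float(np.median([seed_cols[c] for c in cell_ids]))
        genotype = {c: ("mutant" if seed_cols[c] >= med else "control")
                    for c in cell_ids}

    def cell_preset(cid: int) -> Preset:
        return preset if genotype[cid] == "mutant" else control

    image = np.zeros(shape, dtype=float)
    truth = SceneTruth(fibers=[], cortical_intensity={}, whips=[],
                       protrusion_masks={})

    # --- stress fibers ---
    struct = ndimage.generate_binary_structure(2, 1)
    for cid in cell_ids:
        mask = labels == cid
        interior = ndimage.binary_erosion(mask, struct,
                                          iterations=CORTICAL_MARGIN_PX)
        buffered = ndimage.binary_erosion(interior, struct,
                                          iterations=FIBER_HALFWIDTH_PX)
        p = cell_preset(cid)
        intensity = p.fiber_intensity if channel == "factin" else p.myosin_intensity
        _render_fibers(image, buffered, cid, intensity,
                       p.fiber_count_per_cell, truth.fibers)

    # --- cortical rings ---
    pairs = _boundary_pairs(labels)
    for key, pixel_pairs in pairs.items():
        a, b = sorted(key)
        both_mut = genotype[a] == "mutant" and genotype[b] == "mutant"
        if channel == "factin":
            value = preset.cortical_intensity if both_mut else control.cortical_intensity
        else:
            value = CORTEX_MYOSIN_AU
        truth.cortical_intensity[key] = value
        for (pa, pb) in pixel_pairs:
            for (r, c) in (pa, pb):
                image[r, c] = max(image[r, c], value)

    junctions = _tricellular_points(labels)

    # --- whip-like protrusions (F-actin only; whips contain no myosin) ---
    if channel == "factin":
        jarr = np.asarray(junctions) if junctions else np.empty((0, 2))
        centroids = {cid: ndimage.center_of_mass(labels == cid)
                     for cid in cell_ids}
        for cid in cell_ids:
            p = cell_preset(cid)
            mean = p.whip_count_leading_edge
            if mean <= 0:
                continue
            # leading-edge junctions: on the west side of the cell centroid
            touching = [tuple(j) for j in jarr
                        if cid in junction_cells(labels, tuple(j))]
            leading = [j for j in touching if j[1] < centroids[cid][1]]
            if not leading:
                continue
            k = int(mean) + int(rng.random() < (mean - int(mean)))
            if k == 0:
                continue
            mask = labels == cid
            boundary = mask & ~ndimage.binary_erosion(mask, struct)
            bpts = np.argwhere(boundary)
            btree = cKDTree(bpts)
            pm = truth.protrusion_masks.setdefault(
                cid, np.zeros(shape, dtype=bool))
            for w in range(k):
                anchor = leading[w % len(leading)]
                length_um = rng.uniform(2.0, 4.0)
                poly = _whip_polyline(btree, bpts, anchor,
                                      length_um / config.pixel_size_um, rng)
                if len(poly) < 2:
                    continue
                value = p.fiber_intensity
                _render_polyline(image, poly, value)
                rr = np.clip(np.round(poly[:, 0]).astype(int), 0, shape[0] - 1)
                cc = np.clip(np.round(poly[:, 1]).astype(int), 0, shape[1] - 1)
                pm[rr, cc] = True
                truth.whips.append(Whip(cid, anchor, poly, length_um))

    # --- noise, added last ---
    noise_sd = preset.noise_sd
    if noise_sd > 0:
        image = rng.poisson(np.clip(image, 0, None)).astype(float)
        image += rng.normal(0.0, noise_sd, size=image.shape)
        image = np.clip(image, 0.0, None)

    scene = ImageScene(image=image, labels=labels, genotype=genotype,
                       tricellular_points=junctions,
                       calibration=config.pixel_size_um, channel=channel)
    return scene, truth
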