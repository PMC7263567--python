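"""Per-cell geometry, protrusion and whip quantification, and the
consolidated statistical report.

Basal areas come from label-image pixel counts times the squared
calibration.  Stage-to-stage growth ratios compare mean basal areas of
consecutive stages per genotype with a bootstrap confidence interval.
Whip-like protrusions are counted per cell at leading-edge tricellular
junctions.  Contraction anisotropy is the ratio of mean per-cycle
fractional D-V length change to the A-P one.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.ndimage import gaussian_filter1d

from .oscillation import detect_cycles, IntensityTrace
from .synth.config import ALL_STAGES
from .synth.scene import ImageScene, junction_cells

DEFAULT_ANCHOR_RADIUS_UM = 1.0


def measure_areas(scene: ImageScene) -> pd.DataFrame:
    """Basal area per cell: pixel count x (μm/pixel)²."""
    labels = scene.labels
    counts = np.bincount(labels.ravel())
    rows = []
    for cid in scene.cell_ids:
        if cid >= counts.size or counts[cid] == 0:
            continue
        rows.append({
            "cell_id": cid,
            "genotype": scene.genotype[cid],
            "n_pixels": int(counts[cid]),
            "basal_area_um2": float(counts[cid]) * scene.calibration ** 2,
        })
    return pd.DataFrame(rows)


def growth_ratios(table: pd.DataFrame, n_boot: int = 200,
                  seed: int = 0) -> pd.DataFrame:
    """Stage-to-stage fold change of mean basal area per genotype.

    Consecutive stage pairs follow the S6..S10B ordering; pairs with a
    missing stage are omitted.  Bootstrap resampling of cells gives a
    95% percentile confidence interval.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for genotype, sub in table.groupby("genotype"):
        stages = [s for s in ALL_STAGES if s in set(sub["stage"])]
        for s_from, s_to in zip(stages[:-1], stages[1:]):
            a = sub.loc[sub["stage"] == s_from, "basal_area_um2"].to_numpy()
            b = sub.loc[sub["stage"] == s_to, "basal_area_um2"].to_numpy()
            if a.size == 0 or b.size == 0:
                continue
            fold = float(b.mean() / a.mean())
            boots = [
                b[rng.integers(b.size, size=b.size)].mean()
                / a[rng.integers(a.size, size=a.size)].mean()
                for _ in range(n_boot)
            ]
            lo, hi = np.percentile(boots, [2.5, 97.5])
            rows.append({"genotype": genotype, "stage_from": s_from,
                         "stage_to": s_to, "fold_change": fold,
                         "ci_low": float(lo), "ci_high": float(hi)})
    return pd.DataFrame(rows)


def protrusion_fraction(cell_mask: np.ndarray,
                        protrusion_masks: Iterable[np.ndarray]) -> float:
    """Union protrusion area as a percentage of the basal (cell) area."""
    cell_mask = np.asarray(cell_mask, dtype=bool)
    basal = int(cell_mask.sum())
    if basal == 0:
        raise ValueError("cell mask is empty")
    union = np.zeros_like(cell_mask)
    for m in protrusion_masks:
        union |= np.asarray(m, dtype=bool)
    return 100.0 * float((union & cell_mask).sum()) / basal


def leading_edge_junctions(scene: ImageScene) -> Dict[int, list]:
    """Per cell, the tricellular junctions on its leading-edge side."""
    side = scene.leading_edge
    # leading-edge junctions sit on the leading side of the cell centroid:
    # e.g. "west" keeps junctions whose column is below the centroid column
    axis, sign = {"west": (1, 1), "east": (1, -1),
                  "north": (0, 1), "south": (0, -1)}[side]
    centroids = {cid: ndimage.center_of_mass(scene.labels == cid)
                 for cid in scene.cell_ids}
    out: Dict[int, list] = {}
    for j in scene.tricellular_points:
        for cid in junction_cells(scene.labels, j):
            if cid not in centroids:
                continue
            if sign * (j[axis] - centroids[cid][axis]) < 0:
                out.setdefault(cid, []).append(tuple(j))
    return out


def count_whips(whips: Sequence, scene: ImageScene,
                anchor_radius_um: float = DEFAULT_ANCHOR_RADIUS_UM
                ) -> Dict[int, int]:
    """Whips anchored at leading-edge tricellular junctions, per cell.

    ``whips`` are objects with an ``anchor`` (row, col) attribute and an
    optional ``cell_id`` (scene-truth whips or detected objects).  A whip
    counts for the cell owning the leading-edge junction nearest to its
    anchor, within ``anchor_radius_um``; an explicit ``cell_id``
    restricts the assignment to that cell.  Cells owning at least one
    leading-edge junction appear in the result, with zero if unclaimed.
    """
    if not scene.tricellular_points:
        raise ValueError("scene has no tricellular junctions")
    per_cell = leading_edge_junctions(scene)
    radius_px = anchor_radius_um / scene.calibration
    counts = {cid: 0 for cid in per_cell}
    for whip in whips:
        anchor = np.asarray(whip.anchor, dtype=float)
        owner_ids = ([whip.cell_id] if getattr(whip, "cell_id", None) is not None
                     else list(per_cell))
        best = None
        for cid in owner_ids:
            for j in per_cell.get(cid, ()):
                d = float(np.hypot(anchor[0] - j[0], anchor[1] - j[1]))
                if d <= radius_px and (best is None or d < best[0]):
                    best = (d, cid)
        if best is not None:
            counts[best[1]] = counts.get(best[1], 0) + 1
    return counts


def _cycle_windows(values: np.ndarray, dt_s: float):
    """Trough-to-trough cycle windows found on a σ=3-smoothed copy."""
    smoothed = gaussian_filter1d(values, 3.0, mode="reflect")
    cycles = detect_cycles(IntensityTrace(values=smoothed, dt_s=dt_s))
    troughs = cycles.trough_indices
    return [(int(t0), int(t1)) for t0, t1 in zip(troughs[:-1], troughs[1:])]


def dv_ap_anisotropy(bundle) -> float:
    """D-V / A-P contraction anisotropy of one trace bundle.

    Per detected cycle (windows from the D-V trace), the fractional
    length change is (max − min)/mean; the anisotropy is the ratio of
    the mean D-V fractional change to the mean A-P one.  Returns
    ``inf`` when the A-P length does not change.
    """
    dv = bundle.dv_length
    ap = bundle.ap_length
    if dv.values.size != ap.values.size:
        raise ValueError("dv/ap traces are not aligned")
    windows = _cycle_windows(dv.values, dv.dt_s)
    if not windows:
        raise ValueError("no contraction cycle detected on the D-V trace")

    def frac_changes(x: np.ndarray) -> float:
        out = []
        for t0, t1 in windows:
            w = x[t0:t1 + 1]
            m = w.mean()
            out.append((w.max() - w.min()) / m if m else np.nan)
        return float(np.nanmean(out))

    dv_change = frac_changes(dv.values)
    ap_change = frac_changes(ap.values)
    if ap_change == 0:
        return math.inf
    return dv_change / ap_change


@dataclass
class ReportBundle:
    group_stats: pd.DataFrame
    comparisons: pd.DataFrame
    provenance: dict


def _config_hash(config) -> str:
    try:
        import dataclasses
        import yaml
        payload = yaml.safe_dump(dataclasses.asdict(config), sort_keys=True)
    except Exception:
        payload = repr(config)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


def summarize(tables: Mapping[str, pd.DataFrame], seed: Optional[int] = None,
              config=None, out_dir=None) -> ReportBundle:
    """Consolidated report: per-group means, SE and pairwise Welch t-tests.

    Each input table is grouped by its ``genotype`` (or ``group``) column;
    every numeric column contributes group means ± SE and Welch p-values
    for all group pairs.  Empty input yields an empty report.
    """
    stat_rows, cmp_rows = [], []
    for name, table in sorted(tables.items()):
        if table is None or len(table) == 0:
            continue
        group_col = next((c for c in ("genotype", "group")
                          if c in table.columns), None)
        if group_col is None:
            continue
        numeric = [c for c in table.columns
                   if c != group_col and pd.api.types.is_numeric_dtype(table[c])]
        groups = sorted(table[group_col].dropna().unique())
        for col in numeric:
            vals = {g: table.loc[table[group_col] == g, col].dropna().to_numpy()
                    for g in groups}
            for g, v in vals.items():
                if v.size == 0:
                    continue
                se = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
                stat_rows.append({"table": name, "measure": col, "group": g,
                                  "n": int(v.size), "mean": float(v.mean()),
                                  "se": se})
            for i, ga in enumerate(groups):
                for gb in groups[i + 1:]:
                    va, vb = vals[ga], vals[gb]
                    if va.size < 2 or vb.size < 2:
                        continue
                    if va.std(ddof=1) == 0 and vb.std(ddof=1) == 0:
                        t_stat, p = ((0.0, 1.0)
                                     if np.isclose(va.mean(), vb.mean())
                                     else (float("inf"), 0.0))
                    else:
                        t_stat, p = stats.ttest_ind(va, vb, equal_var=False)
                    cmp_rows.append({"table": name, "measure": col,
                                     "group_a": ga, "group_b": gb,
                                     "t": float(t_stat), "p": float(p)})
    provenance = {"seed": seed}
    if config is not None:
        provenance["config_hash"] = _config_hash(config)
    report = ReportBundle(group_stats=pd.DataFrame(stat_rows),
                          comparisons=pd.DataFrame(cmp_rows),
                          provenance=provenance)
    if out_dir is not None:
        from pathlib import Path
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.group_stats.to_csv(out / "group_stats.csv", index=False)
        report.comparisons.to_csv(out / "comparisons.csv", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump({
                "provenance": provenance,
                "group_stats": report.group_stats.to_dict(orient="records"),
                "comparisons": report.comparisons.to_dict(orient="records"),
            }, fh, indent=2)
    return report
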