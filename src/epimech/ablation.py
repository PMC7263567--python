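"""Laser-ablation recoil analysis: tension proxies from vertex-distance traces.

After a cell-cell junction is severed, cortical tension relaxes and the
two flanking vertices separate.  Under the equal-viscosity assumption
the initial recoil velocity is proportional to the junctional tension
before the cut, so group comparisons of v0 compare tensions.  The
estimators follow the standard protocol: the baseline L0 is the mean
vertex distance over the 10 s immediately before the cut, and v0 is the
displacement at the first post-cut frame (t1 = 0.8 s) divided by 0.8 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from scipy import stats

BASELINE_WINDOW_S = 10.0


@dataclass
class AblationTrace:
    """Vertex-to-vertex distance versus time around one laser cut.

    ``cut_index`` is the frame at which the cut occurs; frames after it
    record the recoil.  Sampling must be uniform (0.8 s in the source
    protocol, but any constant step is accepted).
    """

    times_s: np.ndarray
    distance_um: np.ndarray
    cut_index: int
    truth_v0_um_per_s: float = float("nan")

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.distance_um = np.asarray(self.distance_um, dtype=float)
        if self.times_s.shape != self.distance_um.shape:
            raise ValueError("times and distances must have equal length")
        steps = np.diff(self.times_s)
        if steps.size and not np.allclose(steps, steps[0]):
            raise ValueError("sampling must be uniform")
        if not 0 <= self.cut_index < len(self.times_s):
            raise ValueError("cut_index out of range")

    @property
    def dt_s(self) -> float:
        return float(self.times_s[1] - self.times_s[0])

    @property
    def cut_time_s(self) -> float:
        return float(self.times_s[self.cut_index])


@dataclass
class RecoilCurve:
    """Averaged displacement curve ΔL(t) across ablation experiments."""

    post_cut_times_s: np.ndarray
    delta_L_um: np.ndarray
    se_um: np.ndarray
    n_traces: int


@dataclass
class RecoilSummary:
    """Per-group initial-velocity summary."""

    group: str
    v0_um_per_s: np.ndarray
    mean: float = field(init=False)
    se: float = field(init=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.v0_um_per_s, dtype=float)
        if v.size < 1:
            raise ValueError("group must contain at least one trace")
        self.v0_um_per_s = v
        self.mean = float(v.mean())
        self.se = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0


def baseline_L0(trace: AblationTrace,
                window_s: float = BASELINE_WINDOW_S) -> float:
    """Mean vertex distance over the ``window_s`` before the cut.

    The window covers pre-cut frames with cut_time − window_s <= t <
    cut_time (the frame at the cut itself is excluded: the membranes
    have already been severed there).
    """
    t = trace.times_s
    cut_t = trace.cut_time_s
    if cut_t - t[0] < window_s:
        raise ValueError(
            f"need >= {window_s} s of pre-cut baseline, have {cut_t - t[0]:.1f} s")
    sel = (t >= cut_t - window_s) & (t < cut_t)
    return float(trace.distance_um[sel].mean())


def initial_velocity(trace: AblationTrace,
                     window_s: float = BASELINE_WINDOW_S) -> float:
    """Recoil velocity at the first post-cut frame: (L(t1) − L0) / t1."""
    i = trace.cut_index + 1
    if i >= len(trace.times_s):
        raise ValueError("trace has no post-cut frame")
    L0 = baseline_L0(trace, window_s)
    dt = trace.times_s[i] - trace.cut_time_s
    return float((trace.distance_um[i] - L0) / dt)


def displacement_curve(traces: Sequence[AblationTrace]) -> RecoilCurve:
    """Average ΔL(t) = L(t) − L0 over experiments, with standard errors."""
    if not traces:
        raise ValueError("no traces given")
    ref = traces[0]
    rel_ref = ref.times_s[ref.cut_index + 1:] - ref.cut_time_s
    deltas = []
    for tr in traces:
        rel = tr.times_s[tr.cut_index + 1:] - tr.cut_time_s
        if rel.shape != rel_ref.shape or not np.allclose(rel, rel_ref):
            raise ValueError("traces do not share a post-cut sampling grid")
        deltas.append(tr.distance_um[tr.cut_index + 1:] - baseline_L0(tr))
    arr = np.asarray(deltas)
    mean = arr.mean(axis=0)
    if arr.shape[0] > 1:
        se = arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0])
    else:
        se = np.zeros_like(mean)
    return RecoilCurve(post_cut_times_s=rel_ref, delta_L_um=mean,
                       se_um=se, n_traces=arr.shape[0])


def summarize_group(traces: Sequence[AblationTrace], group: str) -> RecoilSummary:
    v0 = np.array([initial_velocity(tr) for tr in traces])
    return RecoilSummary(group=group, v0_um_per_s=v0)


def compare_groups(summaries: Sequence[RecoilSummary]) -> pd.DataFrame:
    """Pairwise Welch t-tests between group initial velocities.

    Degenerate zero-variance pairs are flagged instead of propagating an
    infinite statistic: equal means give t = 0, p = 1; unequal means are
    reported with t = inf, p = 0 and ``zero_variance = True``.
    """
    if len(summaries) < 2:
        raise ValueError("need at least two groups")
    for s in summaries:
        if s.v0_um_per_s.size < 2:
            raise ValueError(f"group {s.group!r} needs n >= 2 for a t-test")
    rows = []
    for i, a in enumerate(summaries):
        for b in summaries[i + 1:]:
            va, vb = a.v0_um_per_s, b.v0_um_per_s
            degenerate = va.std(ddof=1) == 0 and vb.std(ddof=1) == 0
            if degenerate:
                same = np.isclose(va.mean(), vb.mean())
                t_stat, p = (0.0, 1.0) if same else (float("inf"), 0.0)
            else:
                t_stat, p = stats.ttest_ind(va, vb, equal_var=False)
            rows.append({
                "group_a": a.group, "group_b": b.group,
                "mean_a": a.mean, "se_a": a.se,
                "mean_b": b.mean, "se_b": b.se,
                "t": float(t_stat), "p": float(p),
                "zero_variance": degenerate,
            })
    return pd.DataFrame(rows)
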