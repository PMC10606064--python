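"""Cell-migration track metrics and population comparison.

Random 2-D motility assays record each cell's position over a fixed
observation window (61 frames over 600 min by default).  Three metrics
summarise a track:

* total distance   - sum of Euclidean step lengths (µm)
* distance to origin - net translocation first -> last position (µm)
* velocity         - total distance / nominal experiment time (µm/min)
* directional persistence - distance to origin / total distance (0-1)

The nominal time divisor is the full experiment span even for cells
tracked the whole window; a track that ends early (lost cell) falls
back to its own elapsed time and is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "Track",
    "MigrationMetrics",
    "PopulationSummary",
    "track_metrics",
    "population_summary",
    "METRIC_NAMES",
]

METRIC_NAMES = ("total_distance", "distance_to_origin", "velocity", "persistence")

DEFAULT_TOTAL_TIME = 600.0  # min


@dataclass(frozen=True)
class Track:
    """Time-stamped 2-D trajectory of one cell."""

    track_id: str
    times: np.ndarray  # min
    x: np.ndarray  # µm
    y: np.ndarray  # µm

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        for name, v in (("times", t), ("x", x), ("y", y)):
            object.__setattr__(self, name, v)
        if t.ndim != 1 or t.size < 2:
            raise ValidationError("track needs >= 2 points")
        if x.shape != t.shape or y.shape != t.shape:
            raise ValidationError("times, x, y lengths differ")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("track times must be strictly increasing")


@dataclass(frozen=True)
class MigrationMetrics:
    track_id: str
    total_distance: float  # µm
    distance_to_origin: float  # µm
    velocity: float  # µm/min
    persistence: float  # 0-1
    flags: tuple[str, ...] = field(default_factory=tuple)


def track_metrics(track: Track, total_time: float = DEFAULT_TOTAL_TIME) -> MigrationMetrics:
    """Compute the three motility metrics for one track.

    A track with zero total distance has persistence defined as 0 and
    is flagged degenerate (keeping population means finite).
    """
    steps = np.hypot(np.diff(track.x), np.diff(track.y))
    total = float(np.sum(steps))
    origin = float(np.hypot(track.x[-1] - track.x[0], track.y[-1] - track.y[0]))
    span = float(track.times[-1] - track.times[0])
    flags = []
    denom = total_time
    if span < total_time:
        denom = span
        flags.append("short_track")
    if total > 0:
        persistence = origin / total
    else:
        persistence = 0.0
        flags.append("degenerate")
    return MigrationMetrics(
        track_id=track.track_id,
        total_distance=total,
        distance_to_origin=origin,
        velocity=total / denom,
        persistence=persistence,
        flags=tuple(flags),
    )


@dataclass(frozen=True)
class PopulationSummary:
    """Group means +/- SEM and pairwise percent changes vs a reference.

    ``per_group``: rows = group, columns = <metric>_mean/_sem plus n.
    ``comparisons``: one row per (group, metric) with the percent change
    relative to the reference group and a two-sided rank-sum p-value.
    """

    per_group: pd.DataFrame
    comparisons: pd.DataFrame
    reference: str


def population_summary(
    groups: Mapping[str, Sequence[Track]],
    reference: str,
    total_time: float = DEFAULT_TOTAL_TIME,
) -> PopulationSummary:
    if len(groups) < 2:
        raise ValidationError("at least two groups are required")
    if reference not in groups:
        raise ValidationError(f"reference group {reference!r} not present")
    for name, tracks in groups.items():
        if len(tracks) < 5:
            raise ValidationError(f"group {name!r} has fewer than 5 tracks")

    values: dict[str, dict[str, np.ndarray]] = {}
    rows = []
    for name, tracks in groups.items():
        metrics = [track_metrics(t, total_time) for t in tracks]
        values[name] = {
            m: np.array([getattr(mm, m) for mm in metrics]) for m in METRIC_NAMES
        }
        row: dict[str, float] = {"group": name, "n": len(metrics)}
        for m in METRIC_NAMES:
            v = values[name][m]
            row[f"{m}_mean"] = float(v.mean())
            row[f"{m}_sem"] = float(stats.sem(v)) if v.size > 1 else float("nan")
        rows.append(row)
    per_group = pd.DataFrame(rows).set_index("group")

    comp_rows = []
    for name in groups:
        if name == reference:
            continue
        for m in METRIC_NAMES:
            ref_v = values[reference][m]
            v = values[name][m]
            pct = 100.0 * (v.mean() - ref_v.mean()) / ref_v.mean() if ref_v.mean() != 0 else float("nan")
            p = float(stats.mannwhitneyu(v, ref_v, alternative="two-sided").pvalue)
            comp_rows.append({"group": name, "metric": m, "pct_change": pct, "p_value": p})
    comparisons = pd.DataFrame(comp_rows)
    return PopulationSummary(per_group=per_group, comparisons=comparisons, reference=reference)
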