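"""Hypotensive-episode detection on 20-s MAP series.

An episode is a maximal run of consecutive grid points with MAP strictly
below 65 mmHg lasting at least 1 min (three 20-s points).  Each episode may
carry a contiguous *preceding* run of points with 65 ≤ MAP < 72 mmHg that
immediately abuts it — the pressures from which a patient typically slides
into overt hypotension.  Missing grid points break runs; nothing is
interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .core import HaemoSeries


@dataclass(frozen=True)
class EpisodeConfig:
    hypo_threshold_mmhg: float = 65.0
    preceding_threshold_mmhg: float = 72.0
    min_duration_s: float = 60.0
    grid_s: float = 20.0

    def __post_init__(self) -> None:
        if self.preceding_threshold_mmhg <= self.hypo_threshold_mmhg:
            raise ConfigError("preceding threshold must exceed hypotension threshold")
        n = self.min_duration_s / self.grid_s
        if self.grid_s <= 0 or self.min_duration_s <= 0 or abs(round(n) - n) > 1e-9:
            raise ConfigError("min_duration_s must be a positive multiple of grid_s")

    @property
    def min_points(self) -> int:
        return int(round(self.min_duration_s / self.grid_s))


@dataclass(frozen=True)
class HypotensionEpisode:
    """Half-open index span [start, end) of sub-65 points on the patient grid,
    plus the start of the abutting preceding run ([preceding_start, start),
    empty when preceding_start == start)."""

    patient_id: str
    start: int
    end: int
    preceding_start: int

    @property
    def n_points(self) -> int:
        return self.end - self.start

    @property
    def n_preceding(self) -> int:
        return self.start - self.preceding_start

    def episode_indices(self) -> np.ndarray:
        return np.arange(self.start, self.end)

    def preceding_indices(self) -> np.ndarray:
        return np.arange(self.preceding_start, self.start)


def _segments(time_s: np.ndarray, grid_s: float) -> np.ndarray:
    """Segment ids: a new segment starts wherever the grid has a gap."""
    if time_s.size == 0:
        return np.array([], dtype=int)
    dt = np.diff(time_s)
    if np.any(dt <= 0):
        raise DataError("timestamps must be strictly increasing (no duplicates)")
    breaks = np.abs(dt - grid_s) > 1e-9
    return np.concatenate([[0], np.cumsum(breaks)])


def detect_episodes(series, cfg: EpisodeConfig = EpisodeConfig()) -> list[HypotensionEpisode]:
    """Find all hypotensive episodes of one patient's series.

    ``series`` is a :class:`HaemoSeries` or a single-patient DataFrame with
    ``patient_id``, ``time_s`` and ``map`` columns, assumed quality-filtered.
    Indices in the returned episodes refer to row positions of the series.
    """
    if isinstance(series, HaemoSeries):
        pid, frame = series.patient_id, series.frame
    else:
        frame = series
        ids = frame["patient_id"].unique()
        if len(ids) != 1:
            raise DataError("detect_episodes expects a single patient; use detect_cohort")
        pid = str(ids[0])
    t = frame["time_s"].to_numpy(dtype=float)
    m = frame["map"].to_numpy(dtype=float)
    seg = _segments(t, cfg.grid_s)

    episodes: list[HypotensionEpisode] = []
    n = len(m)
    i = 0
    while i < n:
        if m[i] < cfg.hypo_threshold_mmhg:
            j = i
            while j < n and seg[j] == seg[i] and m[j] < cfg.hypo_threshold_mmhg:
                j += 1
            if j - i >= cfg.min_points:
                p = i
                while (
                    p > 0
                    and seg[p - 1] == seg[i]
                    and cfg.hypo_threshold_mmhg <= m[p - 1] < cfg.preceding_threshold_mmhg
                ):
                    p -= 1
                episodes.append(HypotensionEpisode(pid, start=i, end=j, preceding_start=p))
            i = j
        else:
            i += 1
    return episodes


def detect_cohort(frame: pd.DataFrame, cfg: EpisodeConfig = EpisodeConfig()) -> dict[str, list[HypotensionEpisode]]:
    """Run :func:`detect_episodes` per patient of a cohort frame."""
    return {
        str(pid): detect_episodes(HaemoSeries(str(pid), g.reset_index(drop=True)), cfg)
        for pid, g in frame.groupby("patient_id", sort=False)
    }


def extract_analysis_points(
    series,
    episodes: list[HypotensionEpisode],
    include_preceding: bool = True,
) -> pd.DataFrame:
    """Collect the endotyping point set of one patient.

    Returns the episode points (class ``hypotensive``) and, when
    ``include_preceding`` is set, the abutting sub-72 points (class
    ``preceding``), each tagged with its source ``episode_id`` (index into
    ``episodes``).
    """
    frame = series.frame if isinstance(series, HaemoSeries) else series
    n = len(frame)
    rows: list[np.ndarray] = []
    classes: list[np.ndarray] = []
    eids: list[np.ndarray] = []
    for eid, ep in enumerate(episodes):
        if not (0 <= ep.preceding_start <= ep.start < ep.end <= n):
            raise DataError(f"episode {eid} references out-of-range indices")
        idx = ep.episode_indices()
        rows.append(idx)
        classes.append(np.full(idx.size, "hypotensive", dtype=object))
        eids.append(np.full(idx.size, eid))
        if include_preceding and ep.n_preceding:
            pidx = ep.preceding_indices()
            rows.append(pidx)
            classes.append(np.full(pidx.size, "preceding", dtype=object))
            eids.append(np.full(pidx.size, eid))
    if not rows:
        out = frame.iloc[:0].copy()
        out["class"] = pd.Series(dtype=object)
        out["episode_id"] = pd.Series(dtype=int)
        return out
    idx = np.concatenate(rows)
    out = frame.iloc[idx].copy()
    out["class"] = np.concatenate(classes)
    out["episode_id"] = np.concatenate(eids).astype(int)
    return out.sort_index(kind="stable").reset_index(drop=True)


def extract_cohort_points(
    frame: pd.DataFrame,
    cfg: EpisodeConfig = EpisodeConfig(),
    include_preceding: bool = True,
) -> pd.DataFrame:
    """Detect episodes and extract analysis points for a whole cohort frame.

    ``episode_id`` is made globally unique across patients.
    """
    parts = []
    offset = 0
    for pid, g in frame.groupby("patient_id", sort=False):
        series = HaemoSeries(str(pid), g.reset_index(drop=True))
        eps = detect_episodes(series, cfg)
        pts = extract_analysis_points(series, eps, include_preceding)
        if len(pts):
            pts["episode_id"] = pts["episode_id"] + offset
        offset += len(eps)
        parts.append(pts)
    if not parts:
        return frame.iloc[:0].copy()
    return pd.concat(parts, ignore_index=True)
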