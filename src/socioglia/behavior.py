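"""Dyad social-behavior metrics and optomotor response curves.

The social assay places two sibling fish in adjacent 50 x 50 mm arenas
separated by a transparent divider and films them from below at 10
frames/s. From each fish's trajectory we score:

* relative proximity to the divider: mean over frames of ``1 - d/L``
  where ``d`` is the perpendicular distance to the divider wall and
  ``L`` the arena extent perpendicular to it (1 = pressed against the
  divider, 0 = at the far wall);
* percent of time orienting at 45-90 degrees: the fraction of frames in
  which the heading, folded against the divider line into [0, 90]
  degrees, lies in [45, 90] (both toward- and away-facing headings
  count, since only the angular band is specified);
* percent of time in motion: a frame counts as "in motion" when the fish
  moved at least one-third of its body length since the previous frame;
  fish in motion for less than 10% of the assay are excluded;
* mean swim speed in mm/s.

The optomotor assay presents 20-s episodes of concentric rings moving
toward the dish centre followed by a 20-s refractory period, at 30
frames/s; we average distance-to-centre traces over trials and report
the net centerward displacement during the stimulus window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Arena",
    "Trajectory",
    "SocialMetrics",
    "OptomotorTrial",
    "motion_mask",
    "social_metrics",
    "exclude_inactive",
    "optomotor_curve",
    "read_trajectory_csv",
    "write_trajectory_csv",
]

_DIVIDER_SIDES = ("x+", "x-", "y+", "y-")


@dataclass(frozen=True)
class Arena:
    """Rectangular arena in mm with the divider on one wall.

    ``divider_side`` names the wall carrying the transparent divider:
    'x+' is the wall at x = width, 'x-' at x = 0, 'y+' at y = length,
    'y-' at y = 0.
    """

    width: float = 50.0
    length: float = 50.0
    divider_side: str = "x+"

    def __post_init__(self) -> None:
        if self.width <= 0 or self.length <= 0:
            raise ValueError("arena dimensions must be positive")
        if self.divider_side not in _DIVIDER_SIDES:
            raise ValueError(f"divider_side must be one of {_DIVIDER_SIDES}")

    @property
    def perpendicular_extent(self) -> float:
        return self.width if self.divider_side[0] == "x" else self.length

    def divider_distance(self, xy: np.ndarray) -> np.ndarray:
        """Perpendicular distance (mm) of each position to the divider wall."""
        xy = np.atleast_2d(xy)
        axis = 0 if self.divider_side[0] == "x" else 1
        wall = {"x+": self.width, "x-": 0.0,
                "y+": self.length, "y-": 0.0}[self.divider_side]
        return np.abs(xy[:, axis] - wall)

    def folded_divider_angle(self, heading_deg: np.ndarray) -> np.ndarray:
        """Angle between heading and the divider *line*, folded into [0, 90]."""
        # the divider line runs along y for x-walls, along x for y-walls
        line_angle = 90.0 if self.divider_side[0] == "x" else 0.0
        a = np.mod(np.asarray(heading_deg, float) - line_angle, 180.0)
        return np.minimum(a, 180.0 - a)


@dataclass
class Trajectory:
    """Per-frame 2D positions (mm) of one fish, with optional heading (deg)."""

    positions: np.ndarray
    fps: float
    body_length: float
    arena: Arena = field(default_factory=Arena)
    heading: np.ndarray | None = None
    fish_id: str = "fish"
    condition: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be (n_frames, 2)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite positions")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.body_length <= 0:
            raise ValueError("body_length must be positive")
        if self.heading is not None:
            self.heading = np.asarray(self.heading, dtype=float)
            if self.heading.shape != (len(self.positions),):
                raise ValueError("heading must have one value per frame")

    @property
    def n_frames(self) -> int:
        return len(self.positions)

    def displacements(self) -> np.ndarray:
        """Frame-to-frame displacement magnitudes (n_frames - 1 values)."""
        return np.linalg.norm(np.diff(self.positions, axis=0), axis=1)


@dataclass
class SocialMetrics:
    fish_id: str
    condition: str
    relative_proximity: float
    mean_divider_distance_mm: float
    pct_orienting_45_90: float
    pct_in_motion: float
    swim_speed_mm_s: float
    included: bool = True
    orienting_defined: bool = True


@dataclass
class OptomotorTrial:
    """Distance-to-centre trace (mm) at fixed fps with a stimulus window (s)."""

    distance_to_center: np.ndarray
    stimulus_window: tuple[float, float] = (0.0, 20.0)
    fps: float = 30.0

    def __post_init__(self) -> None:
        self.distance_to_center = np.asarray(self.distance_to_center, float)
        t_on, t_off = self.stimulus_window
        if not t_on < t_off:
            raise ValueError("stimulus window must satisfy t_on < t_off")
        if np.any(self.distance_to_center < 0):
            raise ValueError("distances must be non-negative")


# ---------------------------------------------------------------------------
# Motion filter
# ---------------------------------------------------------------------------

def motion_mask(traj: Trajectory) -> tuple[np.ndarray, float]:
    """Per-frame "in motion" flags and the percentage of moving frames.

    A frame is in motion when the fish displaced at least one-third of its
    body length since the previous frame; frame 0 inherits frame 1's state.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least two frames for the motion filter")
    thresh = traj.body_length / 3.0
    disp = traj.displacements()
    moving = np.empty(traj.n_frames, dtype=bool)
    moving[1:] = disp >= thresh
    moving[0] = moving[1]
    pct = 100.0 * moving.mean()
    return moving, float(pct)


def exclude_inactive(metrics: Iterable[SocialMetrics],
                     min_pct: float = 10.0) -> list[SocialMetrics]:
    """Flag fish in motion for less than ``min_pct`` percent of the assay.

    The comparison is strict: a fish at exactly ``min_pct`` is retained.
    Returns the full list with ``included`` updated.
    """
    out = []
    for m in metrics:
        out.append(replace(m, included=m.pct_in_motion >= min_pct))
    return out


# ---------------------------------------------------------------------------
# Social metrics
# ---------------------------------------------------------------------------

def _derive_heading(traj: Trajectory) -> np.ndarray:
    """Heading (deg) from displacement vectors; NaN before the first move.

    Frames with zero displacement carry the last defined heading forward.
    """
    head = np.full(traj.n_frames, np.nan)
    deltas = np.diff(traj.positions, axis=0)
    mags = np.linalg.norm(deltas, axis=1)
    last = np.nan
    for f in range(1, traj.n_frames):
        if mags[f - 1] > 1e-12:
            last = np.degrees(np.arctan2(deltas[f - 1, 1], deltas[f - 1, 0]))
        head[f] = last
    # frame 0: inherit the first defined heading is NOT done — frames before
    # the first movement stay undefined and drop out of the denominator
    return head


def social_metrics(traj: Trajectory) -> SocialMetrics:
    """Score one fish: proximity, orienting, motion and swim speed."""
    arena = traj.arena
    d = arena.divider_distance(traj.positions)
    L = arena.perpendicular_extent
    rel_prox = float(np.mean(1.0 - d / L))

    heading = traj.heading if traj.heading is not None else _derive_heading(traj)
    defined = np.isfinite(heading)
    if defined.any():
        theta = arena.folded_divider_angle(heading[defined])
        pct_orient = float(100.0 * np.mean((theta >= 45.0) & (theta <= 90.0)))
        orient_ok = True
    else:
        warnings.warn("no frame with a defined heading; orienting undefined")
        pct_orient = float("nan")
        orient_ok = False

    _, pct_motion = motion_mask(traj)
    speed = float(traj.displacements().mean() * traj.fps)

    return SocialMetrics(
        fish_id=traj.fish_id,
        condition=traj.condition,
        relative_proximity=rel_prox,
        mean_divider_distance_mm=float(d.mean()),
        pct_orienting_45_90=pct_orient,
        pct_in_motion=pct_motion,
        swim_speed_mm_s=speed,
        orienting_defined=orient_ok,
    )


def metrics_table(metrics: Iterable[SocialMetrics]) -> pd.DataFrame:
    """Per-fish metrics as a tidy DataFrame (one row per fish)."""
    rows = [
        {
            "fish_id": m.fish_id,
            "condition": m.condition,
            "relative_proximity": m.relative_proximity,
            "pct_orienting_45_90": m.pct_orienting_45_90,
            "pct_in_motion": m.pct_in_motion,
            "swim_speed_mm_s": m.swim_speed_mm_s,
            "included": m.included,
        }
        for m in metrics
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Optomotor response
# ---------------------------------------------------------------------------

def optomotor_curve(trials: Sequence[OptomotorTrial]) -> dict:
    """Trial-averaged distance-to-centre curve and response magnitude.

    Response magnitude is the mean distance at stimulus onset minus the
    mean distance at stimulus offset: positive values mean net centerward
    displacement during the stimulus.
    """
    if not trials:
        raise ValueError("no trials supplied")
    fps = trials[0].fps
    n = min(len(t.distance_to_center) for t in trials)
    stack = np.vstack([t.distance_to_center[:n] for t in trials])
    mean_curve = stack.mean(axis=0)
    t_on, t_off = trials[0].stimulus_window
    i_on = int(round(t_on * fps))
    i_off = min(int(round(t_off * fps)), n - 1)
    response = float(mean_curve[i_on] - mean_curve[i_off])
    return {
        "time_s": np.arange(n) / fps,
        "mean_curve": mean_curve,
        "sem_curve": stack.std(axis=0, ddof=1) / np.sqrt(len(trials))
        if len(trials) > 1 else np.zeros(n),
        "response_mm": response,
        "n_trials": len(trials),
    }


# ---------------------------------------------------------------------------
# Trajectory CSV I/O
# ---------------------------------------------------------------------------

def write_trajectory_csv(traj: Trajectory, path) -> None:
    n = traj.n_frames
    df = pd.DataFrame(
        {
            "frame": np.arange(n),
            "t_s": np.arange(n) / traj.fps,
            "x_mm": traj.positions[:, 0],
            "y_mm": traj.positions[:, 1],
            "heading_deg": traj.heading if traj.heading is not None
            else np.full(n, np.nan),
        }
    )
    df.to_csv(path, index=False)


def read_trajectory_csv(path, fps: float, body_length: float,
                        arena: Arena | None = None, fish_id: str = "fish",
                        condition: str = "") -> Trajectory:
    df = pd.read_csv(path)
    heading = None
    if "heading_deg" in df.columns and np.isfinite(df["heading_deg"]).any():
        heading = df["heading_deg"].to_numpy(float)
    return Trajectory(
        positions=df[["x_mm", "y_mm"]].to_numpy(float),
        fps=fps,
        body_length=body_length,
        arena=arena or Arena(),
        heading=heading,
        fish_id=fish_id,
        condition=condition,
    )
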