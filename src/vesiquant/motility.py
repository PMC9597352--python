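"""Single-particle track motility analysis.

Implements the MSD-based classification of 2D vesicle trajectories into
processive / diffusive / non-processive classes, active/passive phase
segmentation, and run-length statistics.

The pipeline for one track is::

    filter (>= min_frames)  ->  MSD(k*dt)  ->  OLS fit of
    log MSD = alpha * log(dt) + C  ->  class from alpha  ->
    phase segmentation  ->  run length per active phase

Classification thresholds: tracks with fitted exponent alpha > 1.45 are
processive (directed, motor-driven), 1 <= alpha <= 1.45 diffusive, and
alpha < 1 non-processive (confined/stalled).  Both boundary values land in
the diffusive class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .exceptions import DegenerateFitError, InvalidArgumentError

__all__ = [
    "Trajectory",
    "MSDCurve",
    "PowerLawFit",
    "ClassifierConfig",
    "MotilityClass",
    "PhaseState",
    "Phase",
    "TrackSummary",
    "PopulationSummary",
    "filter_tracks",
    "compute_msd",
    "fit_power_law",
    "classify_track",
    "segment_phases",
    "compute_run_lengths",
    "summarize_track",
    "summarize_population",
]


@dataclass(frozen=True)
class Trajectory:
    """One particle's ordered 2D positions over frames.

    Parameters
    ----------
    track_id : hashable
        Identifier of the track.
    dt : float
        Seconds per frame interval.
    frames : array of int
        Strictly increasing, consecutive frame indices (gaps are rejected,
        not interpolated).
    xy : (n, 2) array of float
        Positions in micrometres.
    """

    track_id: object
    dt: float
    frames: np.ndarray
    xy: np.ndarray

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=np.int64)
        xy = np.asarray(self.xy, dtype=np.float64)
        if not (self.dt > 0) or not math.isfinite(self.dt):
            raise InvalidArgumentError(f"dt must be positive, got {self.dt}")
        if frames.ndim != 1 or xy.shape != (frames.size, 2):
            raise InvalidArgumentError(
                f"frames {frames.shape} and xy {xy.shape} are inconsistent"
            )
        if frames.size < 2:
            raise InvalidArgumentError("a trajectory needs at least 2 points")
        d = np.diff(frames)
        if np.any(d <= 0):
            raise InvalidArgumentError("frame indices must strictly increase")
        if np.any(d != 1):
            raise InvalidArgumentError(
                f"track {self.track_id!r} has frame gaps; gaps are rejected, "
                "not interpolated"
            )
        if not np.all(np.isfinite(xy)):
            raise InvalidArgumentError("coordinates must be finite")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "xy", xy)

    @property
    def n_frames(self) -> int:
        return int(self.frames.size)

    @property
    def duration_s(self) -> float:
        return float((self.frames[-1] - self.frames[0]) * self.dt)


@dataclass(frozen=True)
class MSDCurve:
    """Lag-indexed mean squared displacement.

    ``lags`` are in seconds (k*dt for integer k), ``values`` in um^2, and
    ``n_pairs[i]`` counts the displacement pairs averaged at lag i.
    """

    lags: np.ndarray
    values: np.ndarray
    n_pairs: np.ndarray

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=np.float64)
        values = np.asarray(self.values, dtype=np.float64)
        n_pairs = np.asarray(self.n_pairs, dtype=np.int64)
        if not (lags.size == values.size == n_pairs.size):
            raise InvalidArgumentError("lags/values/n_pairs length mismatch")
        if np.any(lags <= 0) or np.any(np.diff(lags) <= 0):
            raise InvalidArgumentError("lags must be positive and increasing")
        if np.any(values < 0) or np.any(n_pairs < 1):
            raise InvalidArgumentError("MSD values must be >= 0 with n_pairs >= 1")
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "n_pairs", n_pairs)


@dataclass(frozen=True)
class PowerLawFit:
    """Result of fitting log MSD = alpha * log(dt) + C (natural log)."""

    alpha: float
    intercept: float
    r_squared: float
    n_lags_used: int


class MotilityClass(str, Enum):
    PROCESSIVE = "processive"
    DIFFUSIVE = "diffusive"
    NON_PROCESSIVE = "non_processive"


class PhaseState(str, Enum):
    ACTIVE = "active"
    PASSIVE = "passive"


@dataclass(frozen=True)
class Phase:
    """A maximal run of frames in one motion state (inclusive bounds)."""

    state: PhaseState
    start_frame: int
    end_frame: int

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds and windows for track classification.

    ``alpha_processive_gt``: exponent above which a track is processive
    (strict inequality).  ``alpha_diffusive_min``: lower bound of the closed
    diffusive interval.  ``min_frames``: minimum track length retained for
    analysis.  ``max_lag_fraction``: fraction of (n-1) used as the longest
    MSD lag in the fit.  ``phase_window``: rolling-window length (frames)
    for active/passive segmentation; ``phase_alpha_active``: local-exponent
    threshold for an active window; ``min_phase_frames``: phase runs shorter
    than this are absorbed into their neighbours.
    """

    alpha_processive_gt: float = 1.45
    alpha_diffusive_min: float = 1.0
    min_frames: int = 25
    max_lag_fraction: float = 0.25
    phase_window: int = 10
    phase_alpha_active: float = 1.45
    min_phase_frames: int = 3

    def __post_init__(self) -> None:
        if not self.alpha_processive_gt > self.alpha_diffusive_min:
            raise InvalidArgumentError(
                "alpha_processive_gt must exceed alpha_diffusive_min"
            )
        if self.min_frames < 2:
            raise InvalidArgumentError("min_frames must be >= 2")
        if not (0 < self.max_lag_fraction <= 1):
            raise InvalidArgumentError("max_lag_fraction must be in (0, 1]")
        if self.phase_window < 4:
            raise InvalidArgumentError(
                "phase_window must be >= 4 (local fits need >= 2 lags)"
            )
        if self.min_phase_frames < 1:
            raise InvalidArgumentError("min_phase_frames must be >= 1")


DEFAULT_CONFIG = ClassifierConfig()


@dataclass(frozen=True)
class TrackSummary:
    track_id: object
    n_frames: int
    alpha: float  # NaN when the fit is degenerate
    r_squared: float
    motility_class: MotilityClass
    run_lengths_um: tuple
    duration_s: float


@dataclass(frozen=True)
class PopulationSummary:
    """Population-level class fractions and run-length histogram.

    ``fractions`` is None when no track survives filtering (undefined, not
    silently zero).  The histogram uses half-open 1-um bins [0,1), [1,2), ...
    """

    n_tracks_input: int
    n_tracks_retained: int
    fractions: dict | None
    run_lengths_um: np.ndarray
    hist_edges_um: np.ndarray
    hist_counts: np.ndarray
    tracks: tuple


# ---------------------------------------------------------------------------


def filter_tracks(
    tracks: Iterable[Trajectory], config: ClassifierConfig = DEFAULT_CONFIG
) -> list[Trajectory]:
    """Keep tracks observed for at least ``config.min_frames`` frames.

    The boundary is inclusive: a track of exactly ``min_frames`` points is
    retained.  Order is preserved.
    """
    return [t for t in tracks if t.n_frames >= config.min_frames]


def compute_msd(traj: Trajectory, max_lag_fraction: float = 0.25) -> MSDCurve:
    """Time-averaged MSD over all overlapping pairs.

    For lag k in 1..floor(max_lag_fraction*(n-1)) the value is the mean of
    |r(i+k) - r(i)|^2 over every ordered pair, and the lag time is k*dt.

    Raises
    ------
    InvalidArgumentError
        If ``max_lag_fraction`` yields zero usable lags.
    """
    n = traj.n_frames
    max_k = int(math.floor(max_lag_fraction * (n - 1)))
    if max_k < 1:
        raise InvalidArgumentError(
            f"max_lag_fraction={max_lag_fraction} yields no lags for a "
            f"{n}-frame track"
        )
    xy = traj.xy
    lags = np.empty(max_k)
    values = np.empty(max_k)
    n_pairs = np.empty(max_k, dtype=np.int64)
    for k in range(1, max_k + 1):
        d = xy[k:] - xy[:-k]
        sq = d[:, 0] ** 2 + d[:, 1] ** 2
        lags[k - 1] = k * traj.dt
        values[k - 1] = float(np.mean(sq))
        n_pairs[k - 1] = sq.size
    return MSDCurve(lags=lags, values=values, n_pairs=n_pairs)


def fit_power_law(msd: MSDCurve) -> PowerLawFit:
    """Fit log MSD(dt) = alpha*log(dt) + C by unweighted OLS (natural log).

    Lags with MSD == 0 are dropped before fitting; ``n_lags_used`` reports
    the retained count.

    Raises
    ------
    DegenerateFitError
        If fewer than 2 lags have strictly positive MSD (e.g. a stationary
        track); callers map this to the non-processive class.
    """
    keep = msd.values > 0
    n_used = int(np.count_nonzero(keep))
    if n_used < 2:
        raise DegenerateFitError(
            f"only {n_used} lag(s) with positive MSD; cannot fit exponent"
        )
    x = np.log(msd.lags[keep])
    y = np.log(msd.values[keep])
    xm = x - x.mean()
    sxx = float(np.dot(xm, xm))
    if sxx == 0.0:
        raise DegenerateFitError("all retained lags coincide")
    alpha = float(np.dot(xm, y) / sxx)
    intercept = float(y.mean() - alpha * x.mean())
    resid = y - (alpha * x + intercept)
    ss_res = float(np.dot(resid, resid))
    ss_tot = float(np.dot(y - y.mean(), y - y.mean()))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    r2 = min(1.0, max(0.0, r2))
    return PowerLawFit(alpha=alpha, intercept=intercept, r_squared=r2, n_lags_used=n_used)


def classify_track(
    fit: PowerLawFit | None, config: ClassifierConfig = DEFAULT_CONFIG
) -> MotilityClass:
    """Map a fitted exponent to a motility class.

    alpha > 1.45 -> processive; 1 <= alpha <= 1.45 -> diffusive;
    alpha < 1 -> non-processive.  A degenerate fit (None) is
    non-processive: a motionless particle is the limiting case.
    """
    if fit is None:
        return MotilityClass.NON_PROCESSIVE
    a = fit.alpha
    if a > config.alpha_processive_gt:
        return MotilityClass.PROCESSIVE
    if a >= config.alpha_diffusive_min:
        return MotilityClass.DIFFUSIVE
    return MotilityClass.NON_PROCESSIVE


def _fit_track(traj: Trajectory, config: ClassifierConfig) -> PowerLawFit | None:
    """MSD + power-law fit for one track; None when degenerate.

    ``max_lag_fraction`` is widened just enough to give the fit its minimum
    of 2 lags on very short tracks (a 25-frame track at the default 0.25
    already has 6 lags; this only matters below 9 frames).
    """
    n = traj.n_frames
    frac = config.max_lag_fraction
    if math.floor(frac * (n - 1)) < 2:
        frac = min(1.0, 2.0 / (n - 1))
    try:
        return fit_power_law(compute_msd(traj, frac))
    except (DegenerateFitError, InvalidArgumentError):
        return None


# --------------------------- phase segmentation ----------------------------


def _local_alpha(xy: np.ndarray, dt: float, start: int, w: int) -> float | None:
    """Log-log MSD slope within the window xy[start:start+w]; None if
    degenerate (e.g. motionless segment)."""
    seg = xy[start : start + w]
    max_k = w // 2
    lags = []
    vals = []
    for k in range(1, max_k + 1):
        d = seg[k:] - seg[:-k]
        v = float(np.mean(d[:, 0] ** 2 + d[:, 1] ** 2))
        if v > 0:
            lags.append(k * dt)
            vals.append(v)
    if len(vals) < 2:
        return None
    x = np.log(lags)
    y = np.log(vals)
    xm = x - x.mean()
    sxx = float(np.dot(xm, xm))
    if sxx == 0.0:
        return None
    return float(np.dot(xm, y) / sxx)


def _runs(states: np.ndarray) -> list[list]:
    """[state, start_idx, end_idx] runs (inclusive) of a boolean array."""
    runs = []
    start = 0
    for i in range(1, states.size + 1):
        if i == states.size or states[i] != states[start]:
            runs.append([bool(states[start]), start, i - 1])
            start = i
    return runs


def _absorb_short_runs(states: np.ndarray, min_len: int) -> np.ndarray:
    """Flip the shortest run (< min_len) into its neighbours' state until
    every run is long enough or a single run remains.  Ties: first run."""
    states = states.copy()
    while True:
        runs = _runs(states)
        if len(runs) <= 1:
            return states
        lengths = [r[2] - r[1] + 1 for r in runs]
        j = int(np.argmin(lengths))
        if lengths[j] >= min_len:
            return states
        s, a, b = runs[j]
        states[a : b + 1] = not s
    # unreachable


def segment_phases(
    traj: Trajectory, config: ClassifierConfig = DEFAULT_CONFIG
) -> list[Phase]:
    """Partition a track into alternating active/passive phases.

    A rolling window of ``phase_window`` frames votes "active" when its
    local log-log MSD slope exceeds ``phase_alpha_active``.  Each frame takes
    the majority vote of the windows covering it (ties -> passive), and runs
    shorter than ``min_phase_frames`` are absorbed into their neighbours.
    Tracks shorter than the window collapse to a single phase whose state is
    the whole-track classification (processive -> active, else passive).
    """
    n = traj.n_frames
    w = config.phase_window
    frames = traj.frames
    if n < w:
        cls = classify_track(_fit_track(traj, config), config)
        state = PhaseState.ACTIVE if cls is MotilityClass.PROCESSIVE else PhaseState.PASSIVE
        return [Phase(state, int(frames[0]), int(frames[-1]))]

    n_windows = n - w + 1
    window_active = np.zeros(n_windows, dtype=bool)
    for i in range(n_windows):
        a = _local_alpha(traj.xy, traj.dt, i, w)
        window_active[i] = a is not None and a > config.phase_alpha_active

    frame_active = np.zeros(n, dtype=bool)
    for j in range(n):
        lo = max(0, j - w + 1)
        hi = min(j, n_windows - 1)
        votes = window_active[lo : hi + 1]
        frame_active[j] = float(np.mean(votes)) > 0.5

    frame_active = _absorb_short_runs(frame_active, config.min_phase_frames)
    phases = []
    for s, a, b in _runs(frame_active):
        state = PhaseState.ACTIVE if s else PhaseState.PASSIVE
        phases.append(Phase(state, int(frames[a]), int(frames[b])))
    return phases


def compute_run_lengths(traj: Trajectory, phases: Sequence[Phase]) -> list[float]:
    """Net Euclidean displacement (um) of each active phase.

    The run length is the straight-line distance between the phase's first
    and last positions — transport distance rather than path length, which
    localization noise would inflate.
    """
    lengths = []
    frame_to_idx = {int(f): i for i, f in enumerate(traj.frames)}
    for ph in phases:
        if ph.state is not PhaseState.ACTIVE:
            continue
        i0 = frame_to_idx[ph.start_frame]
        i1 = frame_to_idx[ph.end_frame]
        d = traj.xy[i1] - traj.xy[i0]
        lengths.append(float(np.hypot(d[0], d[1])))
    return lengths


# ----------------------------- population level ----------------------------


def summarize_track(
    traj: Trajectory, config: ClassifierConfig = DEFAULT_CONFIG
) -> TrackSummary:
    """Run the full per-track pipeline: MSD, exponent fit, classification,
    phase segmentation and run lengths."""
    fit = _fit_track(traj, config)
    cls = classify_track(fit, config)
    phases = segment_phases(traj, config)
    runs = compute_run_lengths(traj, phases)
    return TrackSummary(
        track_id=traj.track_id,
        n_frames=traj.n_frames,
        alpha=fit.alpha if fit is not None else float("nan"),
        r_squared=fit.r_squared if fit is not None else float("nan"),
        motility_class=cls,
        run_lengths_um=tuple(runs),
        duration_s=traj.duration_s,
    )


def summarize_population(
    tracks: Iterable[Trajectory], config: ClassifierConfig = DEFAULT_CONFIG
) -> PopulationSummary:
    """Filter, classify and summarize a track population.

    Class fractions are computed over retained tracks; run lengths from all
    active phases are pooled into half-open 1-um bins ([0,1), [1,2), ...).
    With zero retained tracks ``fractions`` is None.
    """
    tracks = list(tracks)
    retained = filter_tracks(tracks, config)
    summaries = tuple(summarize_track(t, config) for t in retained)

    if summaries:
        counts = {c: 0 for c in MotilityClass}
        for s in summaries:
            counts[s.motility_class] += 1
        n_ret = len(summaries)
        fractions = {c.value: counts[c] / n_ret for c in MotilityClass}
    else:
        fractions = None

    run_lengths = np.array(
        [r for s in summaries for r in s.run_lengths_um], dtype=np.float64
    )
    if run_lengths.size:
        top = int(math.floor(run_lengths.max())) + 2
    else:
        top = 1
    edges = np.arange(0, top + 1, dtype=np.float64)
    counts_hist, _ = np.histogram(run_lengths, bins=edges)

    return PopulationSummary(
        n_tracks_input=len(tracks),
        n_tracks_retained=len(summaries),
        fractions=fractions,
        run_lengths_um=run_lengths,
        hist_edges_um=edges,
        hist_counts=counts_hist,
        tracks=summaries,
    )
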