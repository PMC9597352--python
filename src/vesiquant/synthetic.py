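"""Synthetic data with known ground truth.

Every downstream stage of the package is testable without microscopy data:
this module generates 2D particle trajectories (stationary, ballistic,
Brownian, confined, and two-state switching motion), two-channel punctate
images with a controlled colocalized fraction, radially structured cell
images, linear pH-calibration readings, and exponential-decay time courses.
Each generator returns the object together with the ground truth that fully
determines it given the seed.

Motion models
-------------
Brownian steps are independent Gaussian displacements per axis with
variance 2*D*dt (so MSD(t) = 4*D*t in 2D).  Ballistic motion advances at
constant speed along a fixed heading (MSD(t) = (v*t)^2).  Confined motion
is Brownian reflected at a circle around the start point.  Switching
motion is a per-frame two-state Markov chain: the active state is ballistic
with a persistent heading (redrawn at each passive-to-active transition),
the passive state Brownian.  Localization noise is additive i.i.d. Gaussian
per coordinate per frame, applied on top of the true path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assays import TimeCourse
from .exceptions import GenerationError, InvalidArgumentError
from .image_quant import IntensityImage
from .motility import Trajectory

__all__ = [
    "MotionModel",
    "TrackGroundTruth",
    "PopulationGroundTruth",
    "PunctaGroundTruth",
    "RadialGroundTruth",
    "simulate_trajectory",
    "simulate_population",
    "synth_two_channel_puncta",
    "synth_radial_cell",
    "synth_calibration_readings",
    "synth_decay_timecourse",
]

_KINDS = ("stationary", "ballistic", "brownian", "confined", "switching")


@dataclass(frozen=True)
class MotionModel:
    """Parameters of one motion regime.

    Defaults emulate retrograde vesicle transport in cultured cells:
    motor-driven runs at ~0.5 um/s, cytoplasmic vesicle diffusion around
    0.01 um^2/s, rare per-frame state switches (mean dwell ~200 frames, so
    phases are long relative to the segmentation window), and ~20 nm
    localization noise.

    Fields irrelevant to ``kind`` are ignored (e.g. ``speed`` for a
    Brownian model).
    """

    kind: str
    speed: float = 0.5  # um/s, ballistic / active state
    heading: float | None = None  # radians; None -> drawn from the seed
    diffusion_coeff: float = 0.01  # um^2/s, brownian / passive state
    confinement_radius: float = 0.3  # um, confined only
    switch_active_to_passive: float = 0.005  # per-frame probability
    switch_passive_to_active: float = 0.005
    localization_noise_sd: float = 0.02  # um, per coordinate per frame

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise InvalidArgumentError(
                f"kind must be one of {_KINDS}, got {self.kind!r}"
            )
        if self.speed < 0:
            raise InvalidArgumentError("speed must be >= 0")
        if self.diffusion_coeff < 0:
            raise InvalidArgumentError("diffusion_coeff must be >= 0")
        if self.kind == "confined" and not (self.confinement_radius > 0):
            raise InvalidArgumentError("confinement_radius must be > 0")
        for p in (self.switch_active_to_passive, self.switch_passive_to_active):
            if not (0 <= p <= 1):
                raise InvalidArgumentError("switch probabilities must be in [0,1]")
        if self.localization_noise_sd < 0:
            raise InvalidArgumentError("localization_noise_sd must be >= 0")


@dataclass(frozen=True)
class TrackGroundTruth:
    """What was actually simulated for one track.

    ``true_xy`` is the noise-free path; ``states`` is the per-frame
    active/passive indicator (True = active) for switching tracks, None
    otherwise.
    """

    model: MotionModel
    true_xy: np.ndarray
    states: np.ndarray | None = None

    def active_phases(self) -> list[tuple]:
        """Maximal (start_idx, end_idx) runs of the active state, inclusive."""
        if self.states is None:
            if self.model.kind == "ballistic":
                return [(0, self.true_xy.shape[0] - 1)]
            return []
        s = self.states
        phases = []
        start = None
        for i, a in enumerate(s):
            if a and start is None:
                start = i
            elif not a and start is not None:
                phases.append((start, i - 1))
                start = None
        if start is not None:
            phases.append((start, len(s) - 1))
        return phases

    def run_lengths(self) -> list[float]:
        """Net noise-free displacement (um) of each active phase."""
        out = []
        for a, b in self.active_phases():
            d = self.true_xy[b] - self.true_xy[a]
            out.append(float(np.hypot(d[0], d[1])))
        return out


@dataclass(frozen=True)
class PopulationGroundTruth:
    """Mixture assignment and per-track ground truth for a population."""

    models: tuple
    assignments: np.ndarray  # index into ``models`` per track
    tracks: tuple  # TrackGroundTruth per track


def _simulate_path(
    model: MotionModel, n_frames: int, dt: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray | None]:
    """Noise-free path and per-frame states (switching only)."""
    xy = np.zeros((n_frames, 2))
    states = None
    if model.kind == "stationary":
        pass
    elif model.kind == "ballistic":
        heading = (
            model.heading
            if model.heading is not None
            else float(rng.uniform(0, 2 * math.pi))
        )
        step = model.speed * dt * np.array([math.cos(heading), math.sin(heading)])
        xy = np.arange(n_frames)[:, None] * step[None, :]
    elif model.kind == "brownian":
        sd = math.sqrt(2 * model.diffusion_coeff * dt)
        steps = rng.normal(0.0, sd, size=(n_frames - 1, 2))
        xy[1:] = np.cumsum(steps, axis=0)
    elif model.kind == "confined":
        sd = math.sqrt(2 * model.diffusion_coeff * dt)
        R = model.confinement_radius
        pos = np.zeros(2)
        for i in range(1, n_frames):
            pos = pos + rng.normal(0.0, sd, size=2)
            r = float(np.hypot(pos[0], pos[1]))
            if r > R:
                # radial reflection at the confinement circle, iterated so
                # steps larger than the circle fold back inside
                r_new = r
                while r_new > R:
                    r_new = abs(2 * R - r_new)
                pos = pos * (r_new / r) if r > 0 else pos
            xy[i] = pos
    elif model.kind == "switching":
        p_ap = model.switch_active_to_passive
        p_pa = model.switch_passive_to_active
        denom = p_ap + p_pa
        p_active0 = p_pa / denom if denom > 0 else 0.5
        states = np.zeros(n_frames, dtype=bool)
        states[0] = rng.random() < p_active0
        heading = (
            model.heading
            if model.heading is not None
            else float(rng.uniform(0, 2 * math.pi))
        )
        sd = math.sqrt(2 * model.diffusion_coeff * dt)
        pos = np.zeros(2)
        for i in range(1, n_frames):
            prev = states[i - 1]
            if prev:
                switch = rng.random() < p_ap
                states[i] = not switch
            else:
                switch = rng.random() < p_pa
                states[i] = switch
                if switch:
                    heading = float(rng.uniform(0, 2 * math.pi))
            if states[i]:
                pos = pos + model.speed * dt * np.array(
                    [math.cos(heading), math.sin(heading)]
                )
            else:
                pos = pos + rng.normal(0.0, sd, size=2)
            xy[i] = pos
    return xy, states


def _make_track(
    model: MotionModel,
    n_frames: int,
    dt: float,
    rng: np.random.Generator,
    track_id,
) -> tuple[Trajectory, TrackGroundTruth]:
    true_xy, states = _simulate_path(model, n_frames, dt, rng)
    xy = true_xy
    if model.localization_noise_sd > 0:
        xy = true_xy + rng.normal(0.0, model.localization_noise_sd, size=true_xy.shape)
    traj = Trajectory(
        track_id=track_id, dt=dt, frames=np.arange(n_frames), xy=xy
    )
    return traj, TrackGroundTruth(model=model, true_xy=true_xy, states=states)


def simulate_trajectory(
    model: MotionModel, n_frames: int, dt: float, seed: int
) -> tuple[Trajectory, TrackGroundTruth]:
    """Simulate one track of ``n_frames`` points at interval ``dt`` seconds.

    Identical (model, n_frames, dt, seed) reproduce identical output.

    Raises
    ------
    InvalidArgumentError
        If n_frames < 2 or dt <= 0.
    """
    if n_frames < 2:
        raise InvalidArgumentError("n_frames must be >= 2")
    if not (dt > 0):
        raise InvalidArgumentError("dt must be positive")
    rng = np.random.default_rng(seed)
    return _make_track(model, n_frames, dt, rng, track_id=0)


def simulate_population(
    mixture: list,
    n_tracks: int,
    n_frames: int,
    dt: float,
    seed: int,
) -> tuple[list, PopulationGroundTruth]:
    """Simulate a track population from a weighted mixture of motion models.

    ``mixture`` is a list of (MotionModel, weight); each track's model is a
    multinomial draw in the normalized weights.  All randomness flows from
    one generator seeded with ``seed``, so identical inputs reproduce
    identical track tables bytewise.

    Raises
    ------
    InvalidArgumentError
        Empty mixture, negative weights, or weights summing to zero.
    """
    if not mixture:
        raise InvalidArgumentError("mixture must not be empty")
    models = tuple(m for m, _ in mixture)
    weights = np.array([w for _, w in mixture], dtype=np.float64)
    if np.any(weights < 0) or weights.sum() <= 0:
        raise InvalidArgumentError("weights must be nonnegative with positive sum")
    if n_frames < 2:
        raise InvalidArgumentError("n_frames must be >= 2")
    if not (dt > 0):
        raise InvalidArgumentError("dt must be positive")
    probs = weights / weights.sum()
    rng = np.random.default_rng(seed)
    assignments = rng.choice(len(models), size=n_tracks, p=probs)
    tracks = []
    truths = []
    for i, mi in enumerate(assignments):
        traj, gt = _make_track(models[mi], n_frames, dt, rng, track_id=i)
        tracks.append(traj)
        truths.append(gt)
    return tracks, PopulationGroundTruth(
        models=models, assignments=assignments, tracks=tuple(truths)
    )


# ------------------------------- images ------------------------------------


@dataclass(frozen=True)
class PunctaGroundTruth:
    """Planted punctum centres for a two-channel image pair.

    ``centers_b[i]`` for i < ``n_coloc`` coincide with ``centers_a[i]``;
    the remaining B puncta are disjoint from every A punctum.
    """

    centers_a: np.ndarray  # (n, 2) row/col pixel coordinates
    centers_b: np.ndarray
    n_coloc: int
    radius_px: float
    intensity: float
    background: float

    def mask_a(self, shape) -> np.ndarray:
        return _disk_mask(shape, self.centers_a, self.radius_px)

    def mask_b(self, shape) -> np.ndarray:
        return _disk_mask(shape, self.centers_b, self.radius_px)


def _disk_mask(shape, centers, radius) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    rows, cols = np.indices(shape)
    for r, c in centers:
        mask |= (rows - r) ** 2 + (cols - c) ** 2 <= radius**2
    return mask


def _render_puncta(shape, centers, radius, intensity, background) -> np.ndarray:
    img = np.full(shape, float(background))
    img[_disk_mask(shape, centers, radius)] = float(background) + float(intensity)
    return img


def synth_two_channel_puncta(
    n_puncta: int,
    coloc_fraction: float,
    image_shape: tuple = (256, 256),
    puncta_radius_px: float = 3.0,
    intensity: float = 1000.0,
    background: float = 20.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    pixel_size: float = 0.1,
    max_tries: int = 20000,
) -> tuple[IntensityImage, IntensityImage, PunctaGroundTruth]:
    """Two punctate channels with a known colocalized fraction.

    ``n_puncta`` disks per channel; round(coloc_fraction * n_puncta) B
    puncta share centres with A puncta, the remainder are placed so that no
    B disk touches any A disk.  All independently placed disks keep a
    mutual clearance of one pixel so the planted count equals the
    connected-component count.  Disks add ``intensity`` onto a uniform
    ``background``; optional Gaussian noise on top.

    Raises
    ------
    GenerationError
        If a non-overlapping placement cannot be found within
        ``max_tries`` draws (image too crowded).
    """
    if not (0 <= coloc_fraction <= 1):
        raise InvalidArgumentError("coloc_fraction must be in [0,1]")
    if n_puncta < 0:
        raise InvalidArgumentError("n_puncta must be >= 0")
    margin = int(math.ceil(puncta_radius_px)) + 1
    if 2 * margin >= min(image_shape):
        raise InvalidArgumentError("puncta do not fit inside the image")
    rng = np.random.default_rng(seed)
    n_coloc = int(round(coloc_fraction * n_puncta))
    min_sep = 2 * puncta_radius_px + 2  # no touching disks

    placed: list = []  # all centres that must stay mutually clear

    def _place() -> tuple:
        for _ in range(max_tries):
            r = rng.integers(margin, image_shape[0] - margin)
            c = rng.integers(margin, image_shape[1] - margin)
            if all((r - pr) ** 2 + (c - pc) ** 2 >= min_sep**2 for pr, pc in placed):
                placed.append((int(r), int(c)))
                return int(r), int(c)
        raise GenerationError(
            f"could not place punctum after {max_tries} tries; "
            "reduce n_puncta or enlarge the image"
        )

    centers_a = np.array([_place() for _ in range(n_puncta)], dtype=int).reshape(-1, 2)
    centers_b_coloc = centers_a[:n_coloc]
    centers_b_free = np.array(
        [_place() for _ in range(n_puncta - n_coloc)], dtype=int
    ).reshape(-1, 2)
    centers_b = np.vstack([centers_b_coloc, centers_b_free])

    img_a = _render_puncta(image_shape, centers_a, puncta_radius_px, intensity, background)
    img_b = _render_puncta(image_shape, centers_b, puncta_radius_px, intensity, background)
    if noise_sd > 0:
        img_a = np.clip(img_a + rng.normal(0, noise_sd, image_shape), 0, None)
        img_b = np.clip(img_b + rng.normal(0, noise_sd, image_shape), 0, None)

    gt = PunctaGroundTruth(
        centers_a=centers_a,
        centers_b=centers_b,
        n_coloc=n_coloc,
        radius_px=puncta_radius_px,
        intensity=intensity,
        background=background,
    )
    return (
        IntensityImage(img_a, pixel_size=pixel_size, channel="A"),
        IntensityImage(img_b, pixel_size=pixel_size, channel="B"),
        gt,
    )


@dataclass(frozen=True)
class RadialGroundTruth:
    """Requested ring geometry and normalized intensity weights."""

    center_um: tuple
    edges_um: np.ndarray
    ring_weights: np.ndarray


def synth_radial_cell(
    center: tuple,
    ring_weights,
    image_shape: tuple = (256, 256),
    seed: int = 0,
    outer_radius_px: float | None = None,
    total_intensity: float = 10000.0,
    noise_sd: float = 0.0,
    pixel_size: float = 0.1,
) -> tuple[IntensityImage, RadialGroundTruth]:
    """Image whose intensity is distributed over concentric rings in the
    given proportions.

    ``center`` is (row, col) in pixels; the rings equally divide
    [0, outer_radius_px) (default: the largest circle fitting in the
    image).  Each ring's share of ``total_intensity`` is spread uniformly
    over its pixels, so a downstream radial profile with the same centre
    and edges recovers the normalized weights up to discretization.
    """
    w = np.asarray(ring_weights, dtype=np.float64)
    if w.size < 1 or np.any(w < 0) or w.sum() <= 0:
        raise InvalidArgumentError("ring_weights must be nonnegative, sum > 0")
    w = w / w.sum()
    r0, c0 = float(center[0]), float(center[1])
    nr, nc = image_shape
    if not (0 <= r0 <= nr - 1 and 0 <= c0 <= nc - 1):
        raise InvalidArgumentError("center must lie inside the image")
    if outer_radius_px is None:
        outer_radius_px = min(r0, c0, nr - 1 - r0, nc - 1 - c0)
    if not (outer_radius_px > 0):
        raise InvalidArgumentError("outer radius must be positive")

    rows, cols = np.indices(image_shape)
    dist = np.hypot(rows - r0, cols - c0)
    edges = np.linspace(0.0, float(outer_radius_px), w.size + 1)
    img = np.zeros(image_shape)
    for i in range(w.size):
        ring = (dist >= edges[i]) & (dist < edges[i + 1])
        n_px = int(ring.sum())
        if n_px == 0:
            if w[i] > 0:
                raise GenerationError(
                    f"ring {i} contains no pixels but carries weight {w[i]}"
                )
            continue
        img[ring] = w[i] * total_intensity / n_px
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = np.clip(img + rng.normal(0, noise_sd, image_shape), 0, None)
    gt = RadialGroundTruth(
        center_um=(c0 * pixel_size, r0 * pixel_size),
        edges_um=edges * pixel_size,
        ring_weights=w,
    )
    return IntensityImage(img, pixel_size=pixel_size), gt


# --------------------------- tabular fixtures ------------------------------


def synth_calibration_readings(
    slope: float,
    intercept: float,
    ph_values,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Ratiometric calibration readings: ratio = slope*pH + intercept + noise.

    Returns a DataFrame with columns ``ph`` and ``ratio_340_380``.
    """
    ph = np.asarray(ph_values, dtype=np.float64)
    ratio = slope * ph + intercept
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ratio = ratio + rng.normal(0, noise_sd, ph.shape)
    return pd.DataFrame({"ph": ph, "ratio_340_380": ratio})


def synth_decay_timecourse(
    initial: float,
    half_life_min: float,
    times_min,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> TimeCourse:
    """Exponential-decay intensity time course: I(t) = I0 * 2^(−t/half-life)."""
    if not (initial > 0) or not (half_life_min > 0):
        raise InvalidArgumentError("initial and half_life_min must be positive")
    t = np.asarray(times_min, dtype=np.float64)
    y = initial * np.power(2.0, -t / half_life_min)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = np.clip(y + rng.normal(0, noise_sd, t.shape), 0, None)
    return TimeCourse(times_min=t, intensities=y)
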