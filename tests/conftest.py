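import numpy as np
import pytest

from vesiquant import IntensityImage, MotionModel, Trajectory


@pytest.fixture
def ballistic_track() -> Trajectory:
    """Noiseless 1 um/s track along x, 50 frames at 1 s."""
    n = 50
    xy = np.column_stack([np.arange(n, dtype=float), np.zeros(n)])
    return Trajectory(track_id="ball", dt=1.0, frames=np.arange(n), xy=xy)


@pytest.fixture
def stationary_track() -> Trajectory:
    n = 30
    return Trajectory(
        track_id="still", dt=1.0, frames=np.arange(n), xy=np.ones((n, 2))
    )


@pytest.fixture
def disk_image() -> IntensityImage:
    """One filled disk of radius 10 px (1 um at 0.1 um/px) on black."""
    rows, cols = np.indices((64, 64))
    data = (((rows - 32) ** 2 + (cols - 32) ** 2) <= 100).astype(float) * 200.0
    return IntensityImage(data, pixel_size=0.1)


def brute_force_msd(track: Trajectory, max_lag_fraction: float = 1.0):
    """Independent all-pairs MSD oracle: explicit double loop per lag."""
    n = track.n_frames
    max_k = int(np.floor(max_lag_fraction * (n - 1)))
    lags, values, n_pairs = [], [], []
    for k in range(1, max_k + 1):
        sq = []
        for i in range(n - k):
            dx = track.xy[i + k, 0] - track.xy[i, 0]
            dy = track.xy[i + k, 1] - track.xy[i, 1]
            # square by multiplication: scalar pow() can be off by one ulp
            sq.append(dx * dx + dy * dy)
        lags.append(k * track.dt)
        values.append(np.mean(np.asarray(sq)))
        n_pairs.append(len(sq))
    return np.asarray(lags), np.asarray(values), np.asarray(n_pairs)


def brute_force_kapur(counts: np.ndarray):
    """Independent exhaustive evaluation of the Kapur entropy objective.

    Computes each candidate threshold's foreground/background entropies
    from scratch (no shared cumulative sums).  Returns (argmax bin index
    of the last background bin, objective array with -inf at invalid
    splits).  Distinct algebra can order exact mathematical ties
    differently in floating point, so equivalence checks should compare
    attained objectives, not only indices.
    """
    p = counts / counts.sum()
    n = p.size
    obj = np.full(n - 1, -np.inf)
    for t in range(n - 1):
        p0 = p[: t + 1].sum()
        p1 = p[t + 1 :].sum()
        if p0 <= 0 or p1 <= 0:
            continue
        h0 = 0.0
        for q in p[: t + 1]:
            if q > 0:
                h0 -= (q / p0) * np.log(q / p0)
        h1 = 0.0
        for q in p[t + 1 :]:
            if q > 0:
                h1 -= (q / p1) * np.log(q / p1)
        obj[t] = h0 + h1
    return int(np.argmax(obj)), obj
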