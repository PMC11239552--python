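"""Post-processing of voltage recordings.

All activation/recovery quantities derive from threshold crossings of the
recorded voltage at -70 mV, linearly interpolated between frames:

* LAT (local activation time): first upward crossing inside a beat window.
* APD (action potential duration): matching downward crossing minus LAT.
* Activation delay: LAT difference against a uniform-diffusion baseline run.
* Active wavefronts at time t: connected regions (4-connectivity) that rose
  through the threshold during the preceding 20 ms — the area traversed by a
  propagating action potential over that window.

Re-entry is classified from wavefront counts long after the last stimulus:
sustained if any active wavefront remains at 3.0 s, transient if wavefronts
are present at 2.6 s but none at 3.0 s, otherwise none.

Nodes that never cross threshold in a window (scar, unexcited tissue) carry
NaN sentinels and are excluded from order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import ndimage

from .solver import VoltageRecording

__all__ = [
    "ACTIVATION_THRESHOLD_MV",
    "WAVEFRONT_WINDOW_MS",
    "ActivationMap",
    "APDMap",
    "WavefrontSet",
    "ReentryOutcome",
    "find_threshold_crossings",
    "compute_lat_apd",
    "beat_windows_from_events",
    "activation_delay",
    "dispersion_stats",
    "detect_active_wavefronts",
    "classify_reentry",
    "infarct_region_mask",
]

ACTIVATION_THRESHOLD_MV = -70.0
WAVEFRONT_WINDOW_MS = 20.0
REENTRY_EARLY_MS = 2600.0
REENTRY_LATE_MS = 3000.0


@dataclass(frozen=True)
class ActivationMap:
    """Per-node local activation time (ms) for one beat; NaN where undefined."""

    values: np.ndarray
    threshold: float = ACTIVATION_THRESHOLD_MV
    window: tuple[float, float] | None = None


@dataclass(frozen=True)
class APDMap:
    """Per-node action potential duration (ms) for one beat; NaN undefined."""

    values: np.ndarray
    threshold: float = ACTIVATION_THRESHOLD_MV
    window: tuple[float, float] | None = None


@dataclass(frozen=True)
class WavefrontSet:
    """Connected components of recently activated tissue at one instant."""

    t_eval: float
    labels: np.ndarray  # int array, 0 = background, 1..n_fronts = components
    n_fronts: int

    def component_masks(self) -> list[np.ndarray]:
        return [self.labels == k for k in range(1, self.n_fronts + 1)]


class ReentryOutcome(Enum):
    NONE = "none"
    TRANSIENT = "transient"
    SUSTAINED = "sustained"


def find_threshold_crossings(
    times: np.ndarray, v: np.ndarray, threshold: float = ACTIVATION_THRESHOLD_MV
) -> tuple[np.ndarray, np.ndarray]:
    """Linearly interpolated upward and downward crossing times of a trace."""
    times = np.asarray(times, dtype=float)
    v = np.asarray(v, dtype=float)
    above = v >= threshold
    change = np.diff(above.astype(np.int8))
    up_idx = np.flatnonzero(change == 1)
    down_idx = np.flatnonzero(change == -1)

    def interp(idx):
        t0, t1 = times[idx], times[idx + 1]
        v0, v1 = v[idx], v[idx + 1]
        frac = np.where(v1 != v0, (threshold - v0) / (v1 - v0), 0.0)
        return t0 + frac * (t1 - t0)

    return interp(up_idx), interp(down_idx)


def beat_windows_from_events(
    stim_events: list[tuple[float, str]], end_time: float
) -> list[tuple[float, float]]:
    """One window per stimulus, from its onset to the next (last ends at end)."""
    times = sorted(t for t, _ in stim_events)
    if not times:
        return []
    edges = times + [end_time]
    return [(a, b) for a, b in zip(edges[:-1], edges[1:]) if b > a]


def compute_lat_apd(
    recording: VoltageRecording,
    beat_windows: list[tuple[float, float]],
    threshold: float = ACTIVATION_THRESHOLD_MV,
) -> list[tuple[ActivationMap, APDMap]]:
    """LAT and APD maps for each beat window.

    LAT is the first upward crossing in the window; APD pairs it with the
    first later downward crossing (which may fall past the window end, so a
    beat whose repolarisation outlasts its window still gets a defined APD).
    """
    for (a0, a1), (b0, b1) in zip(beat_windows, beat_windows[1:]):
        if b0 < a1 - 1e-9:
            raise ValueError("beat windows must be disjoint and ordered")
    t = recording.times
    frames = recording.frames.astype(float)
    ny, nx = frames.shape[1:]
    flat = frames.reshape(frames.shape[0], -1)

    out = []
    for t0, t1 in beat_windows:
        lat = np.full(ny * nx, np.nan)
        apd = np.full(ny * nx, np.nan)
        for n in range(ny * nx):
            ups, downs = find_threshold_crossings(t, flat[:, n], threshold)
            ups = ups[(ups >= t0) & (ups < t1)]
            if ups.size == 0:
                continue
            lat[n] = ups[0]
            later = downs[downs > ups[0]]
            if later.size:
                apd[n] = later[0] - ups[0]
        out.append(
            (
                ActivationMap(lat.reshape(ny, nx), threshold, (t0, t1)),
                APDMap(apd.reshape(ny, nx), threshold, (t0, t1)),
            )
        )
    return out


def activation_delay(map_: ActivationMap, baseline: ActivationMap) -> np.ndarray:
    """Element-wise LAT difference vs the uniform-diffusion baseline (ms).

    NaN where either input is undefined.  Delays are measured within matching
    beat windows, so both LATs are referenced to the same stimulus onset.
    """
    if map_.values.shape != baseline.values.shape:
        raise ValueError("activation maps are on different grids")
    ref = map_.window[0] if map_.window else 0.0
    ref_b = baseline.window[0] if baseline.window else 0.0
    return (map_.values - ref) - (baseline.values - ref_b)


def dispersion_stats(
    values: np.ndarray | APDMap, region_mask: np.ndarray | None = None
) -> dict[str, float]:
    """Median, inter-quartile and inter-decile range over defined nodes.

    Quantiles use linear interpolation of order statistics.  ``region_mask``
    restricts the statistics, e.g. to the infarct region.
    """
    v = values.values if isinstance(values, APDMap) else np.asarray(values, float)
    if region_mask is not None:
        if region_mask.shape != v.shape:
            raise ValueError("region mask shape mismatch")
        v = v[region_mask]
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no defined nodes in region")
    q10, q25, q50, q75, q90 = np.percentile(v, [10, 25, 50, 75, 90])
    return {
        "median": float(q50),
        "iqr": float(q75 - q25),
        "interdecile": float(q90 - q10),
        "n": int(v.size),
    }


def infarct_region_mask(
    grid, centers: tuple[tuple[float, float], tuple[float, float]], radius: float = 25.0
) -> np.ndarray:
    """Union of discs of ``radius`` mm about the two scar lobe centres."""
    return (grid.distance_to(centers[0]) <= radius) | (
        grid.distance_to(centers[1]) <= radius
    )


def detect_active_wavefronts(
    recording: VoltageRecording,
    t_eval: float,
    window: float = WAVEFRONT_WINDOW_MS,
    threshold: float = ACTIVATION_THRESHOLD_MV,
) -> WavefrontSet:
    """Regions that rose through threshold during the ``window`` before t_eval.

    A node is active when it was below threshold at ``t_eval - window`` and
    crossed upward at some point within the window.  Active nodes are grouped
    with 4-connectivity.
    """
    t = recording.times
    if t_eval - window < t[0] - 1e-9 or t_eval > t[-1] + 1e-9:
        raise ValueError(
            f"recording [{t[0]}, {t[-1]}] ms does not cover "
            f"[{t_eval - window}, {t_eval}] ms"
        )
    sel = (t >= t_eval - window - 1e-9) & (t <= t_eval + 1e-9)
    win = recording.frames[sel].astype(float)
    below_at_start = win[0] < threshold
    crossed_up = np.zeros_like(below_at_start)
    above = win >= threshold
    # upward crossing anywhere in the window: below at some frame, above later
    crossed_up = (
        (~above[:-1] & above[1:]).any(axis=0)
    )
    active = below_at_start & crossed_up
    labels, n = ndimage.label(active, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    return WavefrontSet(t_eval=t_eval, labels=labels, n_fronts=int(n))


def classify_reentry(
    recording: VoltageRecording,
    t_early: float = REENTRY_EARLY_MS,
    t_late: float = REENTRY_LATE_MS,
) -> tuple[ReentryOutcome, int, int]:
    """Apply the transient/sustained re-entry rule.

    Returns (outcome, wavefront count at ``t_early``, count at ``t_late``).
    Sustained: one or more active wavefronts at the late time.  Transient:
    wavefronts at the early time but none at the late time.
    """
    n_early = detect_active_wavefronts(recording, t_early).n_fronts
    n_late = detect_active_wavefronts(recording, t_late).n_fronts
    if n_late >= 1:
        outcome = ReentryOutcome.SUSTAINED
    elif n_early >= 1:
        outcome = ReentryOutcome.TRANSIENT
    else:
        outcome = ReentryOutcome.NONE
    return outcome, n_early, n_late
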