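"""S1 pacing train and dynamically triggered premature (S2) stimuli.

The tissue is paced through a small disc near the scar isthmus with a
-52 pA/pF, 2 ms stimulus.  Three S1 beats at a 400 ms cycle length condition
the tissue; then up to five S2 stimuli are delivered as aggressively as
possible: each fires at the first instant the whole pacing region has
recovered below -84.5 mV (checked every diffusion step), probing the
vulnerable window right at the edge of refractoriness.  A ``fixed_s2`` mode
delivers instead a single premature beat at a prescribed S1-S2 coupling
interval, which is what the activation-delay and APD-dispersion maps use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import GridSpec

__all__ = [
    "PacingProtocol",
    "PacingController",
    "stimulus_mask",
    "stimulus_current",
    "dynamic_trigger",
]


@dataclass(frozen=True)
class PacingProtocol:
    """Pacing site geometry, stimulus waveform, and S1/S2 schedule."""

    site_center: tuple[float, float] = (18.5, 18.5)  # mm
    site_radius: float = 1.25  # mm
    amplitude: float = -52.0  # pA/pF (negative = depolarising)
    pulse_duration: float = 2.0  # ms
    n_s1: int = 3
    s1_cycle_length: float = 400.0  # ms
    n_s2: int = 5
    trigger_threshold: float = -84.5  # mV, recovery level that releases an S2
    mode: str = "dynamic_s2"  # or "fixed_s2"
    fixed_s2_coupling: float = 300.0  # ms, S1-S2 interval in fixed_s2 mode

    def __post_init__(self) -> None:
        if self.amplitude >= 0:
            raise ValueError("stimulus amplitude must be negative (depolarising)")
        if self.pulse_duration <= 0:
            raise ValueError("pulse_duration must be positive")
        if self.mode not in ("dynamic_s2", "fixed_s2"):
            raise ValueError(f"unknown pacing mode {self.mode!r}")
        if self.n_s1 < 1:
            raise ValueError("need at least one S1 stimulus")

    def s1_times(self) -> list[float]:
        """S1 onsets: t = 0, CL, 2 CL, ..."""
        return [k * self.s1_cycle_length for k in range(self.n_s1)]


def stimulus_mask(protocol: PacingProtocol, grid: GridSpec) -> np.ndarray:
    """Boolean mask of nodes whose centres lie within the pacing disc."""
    cx, cy = protocol.site_center
    if not (0 <= cx <= grid.width and 0 <= cy <= grid.height):
        raise ValueError("pacing site centre lies outside the sheet")
    mask = grid.distance_to(protocol.site_center) <= protocol.site_radius
    if not mask.any():
        raise ValueError(
            "pacing disc contains no nodes; increase site_radius or move the site"
        )
    return mask


def stimulus_current(
    t: float, events: list[tuple[float, str]], protocol: PacingProtocol, grid: GridSpec
) -> np.ndarray:
    """Per-node stimulus current (pA/pF) at time ``t`` for delivered events."""
    amp = _active_amplitude(t, events, protocol)
    field = np.zeros(grid.shape)
    if amp != 0.0:
        field[stimulus_mask(protocol, grid)] = amp
    return field


def _active_amplitude(
    t: float, events: list[tuple[float, str]], protocol: PacingProtocol
) -> float:
    times = [e[0] for e in events]
    if any(
        t2 - t1 < protocol.pulse_duration
        for t1, t2 in zip(times, times[1:])
    ):
        raise ValueError("overlapping stimulus events in schedule")
    for t0, _ in events:
        if t0 <= t < t0 + protocol.pulse_duration:
            return protocol.amplitude
    return 0.0


def dynamic_trigger(
    v_mask: np.ndarray, t: float, controller: "PacingController"
) -> tuple[float, str] | None:
    """Fire an S2 if the whole pacing region has recovered below threshold.

    The region statistic is the maximum voltage over the disc: a stimulus is
    released only once every node in the pacing region has fallen below the
    trigger threshold.  Preconditions: the S1 train is complete, fewer than
    ``n_s2`` premature stimuli have been delivered, and the previous pulse
    has ended.
    """
    p = controller.protocol
    if controller.n_s2_delivered >= p.n_s2:
        return None
    last_end = controller.events[-1][0] + p.pulse_duration
    if t < last_end or controller.n_s1_delivered < p.n_s1:
        return None
    if np.max(v_mask) < p.trigger_threshold:
        return (t, "S2")
    return None


class PacingController:
    """Stateful pacing engine driven once per diffusion step.

    ``update(t, v_field)`` registers any stimulus due at time ``t`` (S1 by
    schedule; S2 by the dynamic recovery trigger or the fixed coupling
    interval) and returns the stimulus amplitude active at ``t``.
    """

    def __init__(self, protocol: PacingProtocol, grid: GridSpec):
        self.protocol = protocol
        self.grid = grid
        self.mask = stimulus_mask(protocol, grid)
        self.events: list[tuple[float, str]] = []
        self._pending_s1 = protocol.s1_times()
        if protocol.mode == "fixed_s2":
            last_s1 = self._pending_s1[-1]
            self._pending_fixed = [last_s1 + protocol.fixed_s2_coupling]
        else:
            self._pending_fixed = []

    @property
    def n_s1_delivered(self) -> int:
        return sum(1 for _, label in self.events if label == "S1")

    @property
    def n_s2_delivered(self) -> int:
        return sum(1 for _, label in self.events if label == "S2")

    def update(self, t: float, v_field: np.ndarray) -> float:
        if self._pending_s1 and t >= self._pending_s1[0] - 1e-9:
            self.events.append((t, "S1"))
            self._pending_s1.pop(0)
        elif self._pending_fixed and t >= self._pending_fixed[0] - 1e-9:
            self.events.append((t, "S2"))
            self._pending_fixed.pop(0)
        elif self.protocol.mode == "dynamic_s2" and self.events:
            fired = dynamic_trigger(v_field[self.mask], t, self)
            if fired is not None:
                self.events.append(fired)
        return _active_amplitude(t, self.events, self.protocol)

    def coupling_intervals(self) -> list[float]:
        """Intervals (ms) between consecutive stimuli from the last S1 on."""
        times = [t for t, _ in self.events]
        k = self.protocol.n_s1 - 1
        return [t2 - t1 for t1, t2 in zip(times[k:], times[k + 1:])]
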