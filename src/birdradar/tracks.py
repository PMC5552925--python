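"""Track containers shared across the pipeline.

A GPS track is the ground-truth UAV trajectory of one flight test; a radar
track is a sequence of per-scan plots the track-while-scan system associated
into one target. Both are thin wrappers around time-sorted numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GpsTrack", "RadarTrack", "RadarParameters"]


def _as_sorted(t, *cols):
    t = np.asarray(t, dtype=float)
    cols = [np.asarray(c, dtype=float) for c in cols]
    order = np.argsort(t, kind="stable")
    return (t[order], *[c[order] for c in cols])


@dataclass
class GpsTrack:
    """Ground-truth trajectory of one flight test, sampled at the GPS rate."""

    test_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    alt: np.ndarray = None
    test_type: str = ""  # e.g. "DR" (detection over range) / "DC" (over clutter)

    def __post_init__(self):
        if self.alt is None:
            self.alt = np.full(len(np.asarray(self.t)), np.nan)
        self.t, self.x, self.y, self.alt = _as_sorted(self.t, self.x, self.y, self.alt)
        if len(self.t) >= 2 and np.any(np.diff(self.t) == 0):
            raise ValueError(f"duplicate timestamps in GPS track {self.test_id}")

    def __len__(self):
        return len(self.t)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.t[0]), float(self.t[-1])

    def interp(self, times):
        """Linear interpolation of position and altitude at the given times.

        Times outside the track span return nan (no extrapolation).
        """
        times = np.asarray(times, dtype=float)
        inside = (times >= self.t[0]) & (times <= self.t[-1])
        out = []
        for col in (self.x, self.y, self.alt):
            v = np.interp(times, self.t, col)
            out.append(np.where(inside, v, np.nan))
        return out


@dataclass
class RadarTrack:
    """One automated radar track: per-scan plots in the radar's clock frame."""

    track_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    test_id: str = ""

    def __post_init__(self):
        self.t, self.x, self.y = _as_sorted(self.t, self.x, self.y)

    def __len__(self):
        return len(self.t)


@dataclass(frozen=True)
class RadarParameters:
    """Operating parameters of the surveillance (S-band, horizontal) radar.

    Defaults describe a marine fan-beam S-band radar as configured for avian
    surveillance: 22.5 antenna revolutions per minute (one detection
    opportunity every 60/22.5 ≈ 2.67 s), 1,900 Hz pulse repetition
    frequency, 70 ns pulse (range resolution c·τ/2 ≈ 10.5 m), 1.9°
    horizontal 3-dB beam width, 3.05 GHz carrier, two-nautical-mile
    instrumented range.
    """

    scan_rate: float = 22.5          # scans per minute
    prf: float = 1900.0              # Hz
    pulse_width: float = 70e-9       # s
    h_beamwidth: float = 1.9         # degrees
    frequency: float = 3.05e9        # Hz
    instrumented_range: float = 3704.0  # m

    def __post_init__(self):
        for name in ("scan_rate", "prf", "pulse_width", "h_beamwidth",
                     "frequency", "instrumented_range"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def scan_interval(self) -> float:
        """Seconds between successive detection opportunities (60/scan_rate)."""
        return 60.0 / self.scan_rate

    @property
    def range_resolution(self) -> float:
        """Best-case range resolution c·τ/2 in metres."""
        return 299792458.0 * self.pulse_width / 2.0
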