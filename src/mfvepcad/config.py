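"""Pipeline configuration: analysis windows, thresholds and classifier defaults.

All downstream feature definitions hang off a handful of acquisition-protocol
constants: the signal window (45-150 ms, where the cortical response lives),
the noise window (325-430 ms, essentially noise), the 1.7 signal-to-noise
threshold below which a sector is non-analysable, the 1-35 Hz pass band, and
the division of the 60 visual-field sectors into 6 concentric eccentricity
rings (1 degree central to 22.2 degrees peripheral).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError

#: Sectors per ring, central (R1) to peripheral (R6).  The dartboard layout
#: has few large-eccentricity-scaled sectors in the centre and more towards
#: the periphery; sector numbering runs centre-out.
DEFAULT_RING_SIZES = (4, 8, 12, 12, 12, 12)


def ring_map_from_sizes(sizes: tuple[int, ...]) -> np.ndarray:
    """Expand per-ring sector counts into a length-60 array of ring ids (1-6)."""
    if sum(sizes) != 60 or len(sizes) != 6:
        raise ConfigError(f"ring sizes must be 6 values summing to 60, got {sizes}")
    return np.repeat(np.arange(1, 7), sizes)


@dataclass
class PipelineConfig:
    """All tunable parameters of the CAD pipeline with protocol defaults."""

    signal_window_ms: tuple[float, float] = (45.0, 150.0)
    noise_window_ms: tuple[float, float] = (325.0, 430.0)
    snr_threshold: float = 1.7
    band_hz: tuple[float, float] = (1.0, 35.0)
    #: SSA embedding window length L; applied to the signal-window segment.
    ssa_window: int = 7
    #: Number of singular values extracted per sector.
    n_singular_values: int = 7
    ring_sizes: tuple[int, ...] = DEFAULT_RING_SIZES
    #: Cross-correlation lag search bound for latency estimation.
    max_lag_ms: float = 50.0
    n_folds: int = 5
    seed: int = 0
    #: Keep both eyes of a subject in the same cross-validation fold.
    group_eyes_by_subject: bool = True
    #: Subject fusion: compare eye predictions after merging ON/non-ON
    #: (4-class agreement) rather than on the raw 6-class labels.
    agreement_on_subject_class: bool = True
    #: Eye-level SNR scalar used by subject fusion: mean best-channel SNR over
    #: all 60 sectors (False) or over analysable sectors only (True).
    eye_snr_over_analysable: bool = False

    def __post_init__(self) -> None:
        self.signal_window_ms = tuple(self.signal_window_ms)
        self.noise_window_ms = tuple(self.noise_window_ms)
        self.ring_sizes = tuple(int(s) for s in self.ring_sizes)
        self.validate()

    def validate(self) -> None:
        s0, s1 = self.signal_window_ms
        n0, n1 = self.noise_window_ms
        if not (0 <= s0 < s1 and 0 <= n0 < n1):
            raise ConfigError("analysis windows must be non-empty and non-negative")
        if max(s0, n0) < min(s1, n1):
            raise ConfigError("signal and noise windows must be disjoint")
        if not (1 <= self.ssa_window <= 300):
            raise ConfigError(f"ssa_window must lie in [1, 300], got {self.ssa_window}")
        if not (0 <= self.n_singular_values <= self.ssa_window):
            raise ConfigError("n_singular_values must be <= ssa_window")
        lo, hi = self.band_hz
        if not (0 < lo < hi):
            raise ConfigError(f"invalid pass band {self.band_hz}")
        ring_map_from_sizes(self.ring_sizes)  # raises on bad layout
        if self.n_folds < 2:
            raise ConfigError("n_folds must be >= 2")

    @property
    def ring_map(self) -> np.ndarray:
        """Ring id (1..6) for each sector index 0..59."""
        return ring_map_from_sizes(self.ring_sizes)

    def window_samples(self, window_ms: tuple[float, float], fs: float) -> tuple[int, int]:
        """Convert a (start, stop) ms window to sample indices.

        Sample ``i`` covers time ``i/fs`` seconds from stimulus onset; the
        start is inclusive and the stop exclusive, both rounded down
        (45 ms -> sample 54, 150 ms -> sample 180 at 1200 Hz).
        """
        a = int(np.floor(window_ms[0] * fs / 1000.0))
        b = int(np.floor(window_ms[1] * fs / 1000.0))
        return a, b

    def signal_slice(self, fs: float) -> slice:
        a, b = self.window_samples(self.signal_window_ms, fs)
        return slice(a, b)

    def noise_slice(self, fs: float) -> slice:
        a, b = self.window_samples(self.noise_window_ms, fs)
        return slice(a, b)

    def max_lag_samples(self, fs: float) -> int:
        return int(round(self.max_lag_ms * fs / 1000.0))

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["signal_window_ms"] = list(self.signal_window_ms)
        d["noise_window_ms"] = list(self.noise_window_ms)
        d["band_hz"] = list(self.band_hz)
        d["ring_sizes"] = list(self.ring_sizes)
        d["config_version"] = 1
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d.pop("config_version", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
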