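"""Band-pass filtering of mfVEP epochs.

The acquisition protocol band-limits the evoked responses to 1-35 Hz with an
FFT-domain filter.  We implement this as an ideal (brick-wall) mask on the
discrete spectrum: bins whose frequency falls strictly outside
``[low_hz, high_hz]`` are zeroed and the signal is inverse-transformed.  The
operation is linear, idempotent and zero-phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError
from .records import MfVEPRecord


@dataclass(frozen=True)
class FilterSpec:
    low_hz: float = 1.0
    high_hz: float = 35.0
    method: str = "fft_brickwall"

    def validate(self, fs: float) -> None:
        if not (0 < self.low_hz < self.high_hz < fs / 2):
            raise ValueError(
                f"require 0 < low ({self.low_hz}) < high ({self.high_hz}) < fs/2 ({fs / 2})"
            )
        if self.method != "fft_brickwall":
            raise ValueError(f"unknown filter method {self.method!r}")


def bandpass_fft(signal: np.ndarray, spec: FilterSpec = FilterSpec(),
                 fs: float = 1200.0, axis: int = -1) -> np.ndarray:
    """Brick-wall FFT band-pass along ``axis``; length and phase preserved.

    Bins at exactly the edge frequencies are retained.  The DC bin is always
    outside a band with ``low_hz > 0`` and is removed.
    """
    spec.validate(fs)
    x = np.asarray(signal, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise DegenerateInputError("non-finite values in filter input")
    n = x.shape[axis]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (freqs >= spec.low_hz) & (freqs <= spec.high_hz)
    spectrum = np.fft.rfft(x, axis=axis)
    shape = [1] * x.ndim
    shape[axis] = mask.size
    spectrum = spectrum * mask.reshape(shape)
    return np.fft.irfft(spectrum, n=n, axis=axis)


def filter_record(record: MfVEPRecord, spec: FilterSpec = FilterSpec()) -> MfVEPRecord:
    """Filter every sector/channel trace of a record independently."""
    return record.copy_with_signal(bandpass_fft(record.signal, spec, fs=record.fs, axis=-1))
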