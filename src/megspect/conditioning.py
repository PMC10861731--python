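"""FIR conditioning and epoching of region-level signals.

The pipeline consumes continuous region-by-time matrices that have already
been source-reconstructed and artifact-cleaned upstream; here they are
band-limited with Hamming-window FIR filters (bandpass 1-70 Hz to bound the
noise bandwidth, bandstop 48-52 Hz against power-line interference) and cut
into non-overlapping 5-s segments for spectral estimation.

Filters are linear-phase and applied forward-backward (zero-phase), so the
effective magnitude response is the square of the single-pass design.
Spectral analysis downstream is phase-insensitive, but zero-phase
application keeps transients from biasing early epochs; reflect padding of
one filter length absorbs the edges and ``edge_samples`` on the result
records how many boundary samples remain edge-affected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import firwin, oaconvolve

from ._exceptions import EpochError, NyquistError, SchemaError

__all__ = ["RegionTimeSeries", "EpochSet", "fir_bandpass", "fir_bandstop", "segment_epochs"]

#: Hamming-window design rule: numtaps ~ 3.3 * fs / transition_width.
_HAMMING_DESIGN_FACTOR = 3.3


@dataclass
class RegionTimeSeries:
    """Regions x samples signal matrix for one subject.

    ``data`` has shape ``(R, T)`` with one row per region label; amplitude
    units are arbitrary (every downstream parameter is scale-invariant).
    """

    subject_id: str
    fs: float
    region_labels: list[str]
    data: np.ndarray
    edge_samples: int = 0

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise SchemaError("sampling rate must be positive")
        if len(self.region_labels) != self.data.shape[0]:
            raise SchemaError(
                f"{len(self.region_labels)} region labels for "
                f"{self.data.shape[0]} signal rows"
            )
        if len(set(self.region_labels)) != len(self.region_labels):
            raise SchemaError("region labels must be unique")
        if not np.all(np.isfinite(self.data)):
            raise SchemaError("signal contains non-finite values")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class EpochSet:
    """Non-overlapping equal-length epochs, in temporal order."""

    subject_id: str
    fs: float
    region_labels: list[str]
    epochs: list[np.ndarray] = field(default_factory=list)
    epoch_indices: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.epochs)

    def as_array(self) -> np.ndarray:
        """Stack to ``(n_epochs, R, L)``."""
        return np.stack(self.epochs, axis=0)


def _default_numtaps(fs: float, transition_hz: float) -> int:
    n = int(np.ceil(_HAMMING_DESIGN_FACTOR * fs / transition_hz))
    return n + 1 - n % 2  # force odd (type-I FIR: valid for any band layout)


def _zero_phase(data: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Forward-backward FIR via overlap-add convolution with reflect padding."""
    pad = min(h.size, data.shape[-1] - 1)
    padded = np.pad(data, [(0, 0)] * (data.ndim - 1) + [(pad, pad)], mode="reflect")
    for _ in range(2):  # h is symmetric: two same-mode passes == filtfilt
        padded = oaconvolve(padded, h[None, :], mode="same", axes=-1)
    return padded[..., pad : padded.shape[-1] - pad]


def _apply_fir(ts: RegionTimeSeries, h: np.ndarray) -> RegionTimeSeries:
    return RegionTimeSeries(
        subject_id=ts.subject_id,
        fs=ts.fs,
        region_labels=list(ts.region_labels),
        data=_zero_phase(ts.data, h),
        edge_samples=max(ts.edge_samples, min(h.size, ts.n_samples - 1)),
    )


def fir_bandpass(
    ts: RegionTimeSeries,
    low: float = 1.0,
    high: float = 70.0,
    transition_hz: float = 1.0,
    numtaps: int | None = None,
) -> RegionTimeSeries:
    """Hamming-window FIR bandpass, zero-phase, output length preserved."""
    if high >= ts.fs / 2:
        raise NyquistError(
            f"bandpass upper edge {high} Hz is not below Nyquist ({ts.fs / 2} Hz)"
        )
    if not 0 < low < high:
        raise NyquistError("band edges must satisfy 0 < low < high")
    if numtaps is None:
        numtaps = _default_numtaps(ts.fs, transition_hz)
    h = firwin(numtaps, [low, high], pass_zero=False, window="hamming", fs=ts.fs)
    return _apply_fir(ts, h)


def fir_bandstop(
    ts: RegionTimeSeries,
    low: float = 48.0,
    high: float = 52.0,
    transition_hz: float = 1.0,
    numtaps: int | None = None,
) -> RegionTimeSeries:
    """Hamming-window FIR bandstop (line-noise notch), zero-phase."""
    if high >= ts.fs / 2:
        raise NyquistError(
            f"bandstop upper edge {high} Hz is not below Nyquist ({ts.fs / 2} Hz)"
        )
    if not 0 < low < high:
        raise NyquistError("band edges must satisfy 0 < low < high")
    if numtaps is None:
        numtaps = _default_numtaps(ts.fs, transition_hz)
    h = firwin(numtaps, [low, high], pass_zero="bandstop", window="hamming", fs=ts.fs)
    return _apply_fir(ts, h)


def segment_epochs(ts: RegionTimeSeries, epoch_seconds: float = 5.0) -> EpochSet:
    """Cut into non-overlapping epochs of ``epoch_seconds``; remainder dropped."""
    length = int(round(epoch_seconds * ts.fs))
    if length < 1:
        raise EpochError("epoch length must cover at least one sample")
    n_epochs = ts.n_samples // length
    if n_epochs == 0:
        raise EpochError(
            f"recording of {ts.duration:.2f} s is shorter than one "
            f"{epoch_seconds}-s epoch"
        )
    epochs = [
        ts.data[:, i * length : (i + 1) * length].copy() for i in range(n_epochs)
    ]
    return EpochSet(
        subject_id=ts.subject_id,
        fs=ts.fs,
        region_labels=list(ts.region_labels),
        epochs=epochs,
        epoch_indices=list(range(n_epochs)),
    )
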