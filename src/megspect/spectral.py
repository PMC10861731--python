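"""Oscillatory parameters of resting-state neural power spectra.

This module turns an epoched region-level signal into the eleven spectral
summary parameters used throughout the package:

* eight band relative powers (RPd, RPt, RPa1, RPa2, RPa3, RPb, RPlg, RPhg)
  computed on the normalized power spectral density (PSDn) over 1-70 Hz,
* MF, the median frequency splitting PSDn mass into equal halves,
* IAF, the same median construction restricted to the extended alpha
  range 4-15 Hz (a robust stand-in for the alpha peak frequency),
* SSE, the normalized Shannon entropy of PSDn
  (``SSE = -1/log(N) * sum_f PSDn(f) log PSDn(f)``).

The PSD estimator is Blackman-Tukey: the discrete Fourier transform of a
lag-windowed autocorrelation sequence.  With the default Bartlett lag
window the estimate is nonnegative by construction (Fejer kernel), which
matters because PSDn is treated as a probability distribution.

All computational kernels accept stacked spectra (``(..., N)`` arrays) so
cohort-scale work stays vectorized; the public operations are thin,
validated entry points over those kernels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import irfft, next_fast_len, rfft, rfftfreq

from ._exceptions import (
    DegenerateBandError,
    DegenerateSpectrumError,
    LagError,
)

__all__ = [
    "BandDefinition",
    "CANONICAL_BANDS",
    "PRINTED_BANDS",
    "NormalizedSpectrum",
    "blackman_tukey_psd",
    "normalize_psd",
    "relative_power",
    "mean_frequency",
    "individual_alpha_frequency",
    "spectral_entropy",
    "compute_parameters",
    "aggregate_parameters",
    "global_average",
    "PARAMETER_NAMES",
]

_TOL = 1e-9

FREQ_RANGE = (1.0, 70.0)

PARAMETER_NAMES = (
    "RPd",
    "RPt",
    "RPa1",
    "RPa2",
    "RPa3",
    "RPb",
    "RPlg",
    "RPhg",
    "MF",
    "IAF",
    "SSE",
)

IAF_RANGE = (4.0, 15.0)


@dataclass(frozen=True)
class BandDefinition:
    """A canonical frequency band ``[lo, hi)`` in Hz.

    ``closed_upper`` closes the interval at ``hi`` — used for the last
    band so the eight bands exactly partition the 1-70 Hz range and the
    relative powers sum to one.
    """

    name: str
    lo: float
    hi: float
    closed_upper: bool = False

    def mask(self, freqs: np.ndarray) -> np.ndarray:
        m = freqs >= self.lo - _TOL
        if self.closed_upper:
            return m & (freqs <= self.hi + _TOL)
        return m & (freqs < self.hi - _TOL)


#: Contiguous half-open bands. The conventional printed edges (delta 1-3,
#: theta 4-7, alpha1 7-9 ... high gamma 41-70) leave gaps at 3-4, 25-26 and
#: 40-41 Hz and share endpoints at 7/9/11/13 Hz; the half-open contiguous
#: convention below preserves the partition-of-unity property of the
#: relative powers and avoids double counting at shared edges.
CANONICAL_BANDS = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 7.0),
    BandDefinition("alpha1", 7.0, 9.0),
    BandDefinition("alpha2", 9.0, 11.0),
    BandDefinition("alpha3", 11.0, 13.0),
    BandDefinition("beta", 13.0, 26.0),
    BandDefinition("lowgamma", 26.0, 41.0),
    BandDefinition("highgamma", 41.0, 70.0, closed_upper=True),
)

#: Literal printed band edges (closed intervals); RPs computed on these do
#: not sum to one because of the inter-band gaps. Provided for comparison.
PRINTED_BANDS = (
    BandDefinition("delta", 1.0, 3.0, closed_upper=True),
    BandDefinition("theta", 4.0, 7.0, closed_upper=True),
    BandDefinition("alpha1", 7.0, 9.0, closed_upper=True),
    BandDefinition("alpha2", 9.0, 11.0, closed_upper=True),
    BandDefinition("alpha3", 11.0, 13.0, closed_upper=True),
    BandDefinition("beta", 13.0, 25.0, closed_upper=True),
    BandDefinition("lowgamma", 26.0, 40.0, closed_upper=True),
    BandDefinition("highgamma", 41.0, 70.0, closed_upper=True),
)

_BAND_TO_RP = {
    "delta": "RPd",
    "theta": "RPt",
    "alpha1": "RPa1",
    "alpha2": "RPa2",
    "alpha3": "RPa3",
    "beta": "RPb",
    "lowgamma": "RPlg",
    "highgamma": "RPhg",
}


@dataclass
class NormalizedSpectrum:
    """PSDn over the 1-70 Hz grid; sums to one along the last axis.

    ``psdn`` may carry leading axes (epochs, regions) — all parameter
    kernels broadcast over them.
    """

    freqs: np.ndarray
    psdn: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.psdn = np.asarray(self.psdn, dtype=float)
        if self.freqs.ndim != 1 or self.freqs.size < 2:
            raise DegenerateSpectrumError("frequency grid must be 1-D with >= 2 bins")
        if np.any(np.diff(self.freqs) <= 0):
            raise DegenerateSpectrumError("frequency grid must be strictly increasing")
        if self.psdn.shape[-1] != self.freqs.size:
            raise DegenerateSpectrumError("psdn last axis must match frequency grid")
        if np.any(self.psdn < -1e-12):
            raise DegenerateSpectrumError("psdn must be nonnegative")
        totals = self.psdn.sum(axis=-1)
        if not np.allclose(totals, 1.0, atol=1e-10):
            raise DegenerateSpectrumError("psdn must sum to 1 per spectrum")

    @property
    def n_bins(self) -> int:
        return self.freqs.size


def _lag_window(kind: str, n_lags: int) -> np.ndarray:
    if kind == "bartlett":
        return 1.0 - np.arange(n_lags) / n_lags
    if kind == "hamming":
        # one-sided half of a symmetric Hamming of length 2*n_lags - 1
        return np.hamming(2 * n_lags - 1)[n_lags - 1 :]
    raise ValueError(f"unknown lag window {kind!r}")


def blackman_tukey_psd(
    x: np.ndarray,
    fs: float,
    max_lag_seconds: float = 1.0,
    lag_window: str = "bartlett",
    nfft: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Blackman-Tukey PSD estimate of ``x`` (last axis = time).

    The biased sample autocorrelation is computed via FFT, truncated at
    ``max_lag_seconds``, tapered by the lag window, and Fourier transformed.
    Frequency spacing is ``fs / nfft`` with ``nfft = 2 * max_lag_samples``
    by default; pass a larger ``nfft`` for interpolated (zero-padded) bins.

    Returns ``(freqs, psd)`` with ``psd`` in power per Hz. Scaling is such
    that the one-sided integral approximates the signal variance; all
    downstream quantities use PSDn and are scale-free.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    m = int(round(max_lag_seconds * fs))
    if m < 1:
        raise LagError("max_lag_seconds must cover at least one sample")
    if n < 2 * m:
        raise LagError(
            f"epoch of {n} samples is shorter than twice the "
            f"maximum lag ({m} samples)"
        )
    nfa = next_fast_len(2 * n)
    spec = np.abs(rfft(x, nfa, axis=-1)) ** 2
    acf = irfft(spec, nfa, axis=-1)[..., :m] / n

    w = _lag_window(lag_window, m)
    acf = acf * w

    if nfft is None:
        nfft = 2 * m
    if nfft < 2 * m - 1:
        raise LagError("nfft must be at least 2*max_lag_samples - 1")
    # symmetric (circular) arrangement of the two-sided windowed ACF
    sym = np.zeros(x.shape[:-1] + (nfft,), dtype=float)
    sym[..., :m] = acf
    sym[..., nfft - m + 1 :] = acf[..., 1:][..., ::-1]
    psd = rfft(sym, nfft, axis=-1).real / fs
    psd[..., 1:-1] *= 2.0  # fold negative frequencies (one-sided)
    # Bartlett guarantees nonnegativity analytically; clip numerical dust.
    # With a Hamming lag window genuinely negative values may occur and are
    # clipped to zero before any normalization, as PSDn must be a density.
    np.clip(psd, 0.0, None, out=psd)
    freqs = rfftfreq(nfft, 1.0 / fs)
    return freqs, psd


def normalize_psd(
    freqs: np.ndarray,
    psd: np.ndarray,
    fmin: float = FREQ_RANGE[0],
    fmax: float = FREQ_RANGE[1],
) -> NormalizedSpectrum:
    """Restrict to ``[fmin, fmax]`` and divide by the total in-range power."""
    freqs = np.asarray(freqs, dtype=float)
    psd = np.asarray(psd, dtype=float)
    mask = (freqs >= fmin - _TOL) & (freqs <= fmax + _TOL)
    if mask.sum() < 2:
        raise DegenerateSpectrumError("fewer than two bins inside the frequency range")
    sub = psd[..., mask]
    total = sub.sum(axis=-1)
    if np.any(total <= 0):
        raise DegenerateSpectrumError("zero total power in the frequency range of interest")
    return NormalizedSpectrum(freqs=freqs[mask], psdn=sub / total[..., None])


def relative_power(ns: NormalizedSpectrum, band: BandDefinition) -> np.ndarray | float:
    """Cumulative PSDn inside ``band`` (a fraction in [0, 1])."""
    rp = ns.psdn[..., band.mask(ns.freqs)].sum(axis=-1)
    return float(rp) if rp.ndim == 0 else rp


def _median_frequency(freqs: np.ndarray, psdn: np.ndarray) -> np.ndarray:
    """Frequency splitting the mass of ``psdn`` into equal halves.

    Each bin's mass is treated as uniformly spread over its own width, so a
    point-mass spectrum returns exactly the bin's center frequency, and the
    split point is interpolated sub-bin elsewhere.
    """
    df = freqs[1] - freqs[0]
    c = np.cumsum(psdn, axis=-1)
    k = np.argmax(c >= 0.5 - 1e-12, axis=-1)
    k_exp = k[..., None]
    ck = np.take_along_axis(c, k_exp, axis=-1)[..., 0]
    pk = np.take_along_axis(psdn, k_exp, axis=-1)[..., 0]
    cprev = ck - pk
    mf = freqs[k] - 0.5 * df + df * (0.5 - cprev) / pk
    return np.clip(mf, freqs[0], freqs[-1])


def mean_frequency(ns: NormalizedSpectrum) -> np.ndarray | float:
    """MF: the median frequency of PSDn over the full 1-70 Hz range."""
    mf = _median_frequency(ns.freqs, ns.psdn)
    return float(mf) if mf.ndim == 0 else mf


def individual_alpha_frequency(
    ns: NormalizedSpectrum,
    lo: float = IAF_RANGE[0],
    hi: float = IAF_RANGE[1],
) -> np.ndarray | float:
    """IAF: median frequency of PSDn restricted to the extended alpha band.

    The restricted spectrum is renormalized before taking the median; this
    does not move the split point but keeps the intermediate object a
    proper density.
    """
    mask = (ns.freqs >= lo - _TOL) & (ns.freqs <= hi + _TOL)
    if mask.sum() < 1:
        raise DegenerateBandError("no frequency bins inside the alpha range")
    sub = ns.psdn[..., mask]
    total = sub.sum(axis=-1)
    if np.any(total <= 0):
        raise DegenerateBandError("zero spectral mass inside the 4-15 Hz range")
    iaf = _median_frequency(ns.freqs[mask], sub / total[..., None])
    return float(iaf) if iaf.ndim == 0 else iaf


def spectral_entropy(ns: NormalizedSpectrum) -> np.ndarray | float:
    """SSE = -1/log(N) * sum_f PSDn(f) log PSDn(f), with 0*log(0) := 0.

    1 for a flat spectrum, 0 for a single spectral line. The 1/log(N)
    normalization makes the logarithm base immaterial; natural log is used.
    """
    p = ns.psdn
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    sse = -plogp.sum(axis=-1) / np.log(ns.n_bins)
    sse = np.clip(sse, 0.0, 1.0) + 0.0  # normalize the sign of a -0.0
    return float(sse) if sse.ndim == 0 else sse


def compute_parameters(
    ns: NormalizedSpectrum,
    bands: tuple[BandDefinition, ...] = CANONICAL_BANDS,
) -> dict[str, np.ndarray]:
    """All eleven oscillatory parameters for each spectrum in ``ns``.

    Returns a dict mapping parameter name to an array shaped like the
    leading axes of ``ns.psdn``.
    """
    out: dict[str, np.ndarray] = {}
    for band in bands:
        out[_BAND_TO_RP[band.name]] = np.atleast_1d(relative_power(ns, band))
    out["MF"] = np.atleast_1d(mean_frequency(ns))
    out["IAF"] = np.atleast_1d(individual_alpha_frequency(ns))
    out["SSE"] = np.atleast_1d(spectral_entropy(ns))
    return out


def aggregate_parameters(
    epoch_params: dict[str, np.ndarray],
) -> dict[str, np.ndarray]:
    """Average epoch-level parameters across epochs (axis 0).

    Parameters are computed per epoch and then averaged — not computed on
    an epoch-averaged spectrum — so nonlinear parameters (MF, IAF, SSE)
    are means of per-epoch values.
    """
    first = next(iter(epoch_params.values()))
    if first.shape[0] < 1:
        raise ValueError("empty epoch set")
    return {k: np.asarray(v, dtype=float).mean(axis=0) for k, v in epoch_params.items()}


def global_average(region_params: dict[str, np.ndarray]) -> dict[str, float]:
    """Unweighted mean of region-level parameters across regions."""
    return {k: float(np.mean(v)) for k, v in region_params.items()}
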