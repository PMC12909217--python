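"""Weighted phase lag index (wPLI) connectivity between region signals.

The wPLI of two signals is

    wPLI = |< Im(X) >| / < |Im(X)| >

where ``X`` is the cross-spectrum between the two signals and ``< . >``
averages over observations. Only the imaginary part of the cross-spectrum
enters, which makes the index insensitive to zero-lag (volume-conduction)
coupling: instantaneous mixtures of one source have a purely real
cross-spectrum and score 0 under the 0/0 convention. Values lie in [0, 1],
with 1 for a perfectly consistent non-zero phase lag.

Here ``X`` is formed per band from the analytic signals of the two region
traces (Hilbert transform per epoch after zero-phase band extraction), and
the expectation pools epochs and retained time samples.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pywt
from scipy import signal

from .preprocess import EpochedRecording
from .spectral import BANDS

__all__ = [
    "CrossSpectrum",
    "ConnectivityMatrix",
    "band_decompose",
    "analytic_cross_spectrum",
    "wpli",
    "wpli_matrix",
]

# Denominator below this fraction of the mean cross-spectral magnitude is
# treated as the degenerate 0/0 case (zero-lag coupling) and scores 0.
_ZERO_TOL = 1e-9


@dataclass
class CrossSpectrum:
    """Complex cross-spectral samples for one signal pair (epoch x time)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("cross-spectrum must be finite")

    def conj(self) -> "CrossSpectrum":
        return CrossSpectrum(np.conj(self.values))


@dataclass
class ConnectivityMatrix:
    """Symmetric wPLI matrix over the 10 regions for one band."""

    band: str
    w: np.ndarray
    regions: list[str]

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        n = len(self.regions)
        if self.w.shape != (n, n):
            raise ValueError("matrix shape must match region list")
        if not np.allclose(self.w, self.w.T):
            raise ValueError("connectivity matrix must be symmetric")
        if np.any(self.w < -1e-12) or np.any(self.w > 1 + 1e-12):
            raise ValueError("wPLI entries must lie in [0, 1]")
        if np.any(np.abs(np.diag(self.w)) > 1e-12):
            raise ValueError("diagonal must be zero")


def _morlet_band(data: np.ndarray, fs: float, lo: float, hi: float) -> np.ndarray:
    """Band reconstruction from a complex Morlet transform (cmor1.5-1.0):
    sum of the real parts of the coefficients at 0.5 Hz-spaced centre
    frequencies inside the band, rescaled to unit passband gain."""
    freqs = np.arange(lo + 0.25, hi, 0.5)
    wavelet = "cmor1.5-1.0"
    scales = pywt.central_frequency(wavelet) * fs / freqs
    flat = data.reshape(-1, data.shape[-1])
    out = np.empty_like(flat)
    for i, row in enumerate(flat):
        coefs, _ = pywt.cwt(row, scales, wavelet, sampling_period=1.0 / fs)
        out[i] = coefs.real.sum(axis=0)
    # normalise overall gain with a probe sinusoid at band centre
    t = np.arange(data.shape[-1]) / fs
    probe = np.cos(2 * np.pi * (lo + hi) / 2 * t)
    pc, _ = pywt.cwt(probe, scales, wavelet, sampling_period=1.0 / fs)
    rec = pc.real.sum(axis=0)
    gain = np.sqrt(np.mean(rec**2) / np.mean(probe**2))
    return (out / gain).reshape(data.shape)


def band_decompose(
    ep: EpochedRecording, band: str, method: str = "filter", order: int = 4
) -> EpochedRecording:
    """Extract one frequency band from every channel of every epoch.

    ``method='filter'`` (default) uses a zero-phase Butterworth band-pass of
    the stated order; ``method='morlet'`` reconstructs the band from a
    complex Morlet wavelet transform behind the same contract.
    """
    if band not in BANDS:
        raise KeyError(f"unknown band '{band}'")
    lo, hi = BANDS[band]
    if method == "filter":
        sos = signal.butter(order, [lo, hi], btype="bandpass", fs=ep.fs, output="sos")
        out = signal.sosfiltfilt(sos, ep.epochs, axis=-1)
    elif method == "morlet":
        out = _morlet_band(ep.epochs, ep.fs, lo, hi)
    else:
        raise ValueError(f"unknown method '{method}'")
    return replace(ep, epochs=out, provenance=ep.provenance + [f"band:{band}:{method}"])


def analytic_cross_spectrum(
    x_band: np.ndarray, y_band: np.ndarray, edge_frac: float = 0.05
) -> CrossSpectrum:
    """Cross-spectrum from per-epoch analytic signals.

    ``X(t) = a_x(t) * conj(a_y(t))`` with ``a`` the Hilbert analytic signal
    of each epoch; a fraction of samples at each epoch edge is discarded to
    limit transform end effects. Inputs are ``(n_epochs, n_times)`` arrays
    (a single epoch may be passed as 1-D).
    """
    x = np.atleast_2d(np.asarray(x_band, dtype=float))
    y = np.atleast_2d(np.asarray(y_band, dtype=float))
    if x.shape != y.shape:
        raise ValueError("signals must have equal shapes")
    ax = signal.hilbert(x, axis=-1)
    ay = signal.hilbert(y, axis=-1)
    n = x.shape[-1]
    cut = int(round(edge_frac * n))
    sl = slice(cut, n - cut) if n - 2 * cut >= 1 else slice(None)
    return CrossSpectrum(ax[..., sl] * np.conj(ay[..., sl]))


def wpli(cross: CrossSpectrum | np.ndarray) -> float:
    """Weighted phase lag index of a cross-spectral sample set.

    ``|mean(Im X)| / mean(|Im X|)`` pooled over all samples; when the
    denominator vanishes relative to the cross-spectral magnitude (the
    zero-lag case) the value is defined as 0.
    """
    values = cross.values if isinstance(cross, CrossSpectrum) else np.asarray(cross, dtype=complex)
    im = values.imag
    denom = np.abs(im).mean()
    scale = np.abs(values).mean()
    if denom <= _ZERO_TOL * max(scale, 1e-300):
        return 0.0
    return float(abs(im.mean()) / denom)


def _wpli_per_epoch(values: np.ndarray) -> float:
    """Variant: wPLI per epoch, then averaged across epochs."""
    out = [wpli(values[e]) for e in range(values.shape[0])]
    return float(np.mean(out))


def wpli_matrix(
    region_ep: EpochedRecording,
    band: str,
    method: str = "filter",
    pool: str = "all",
    edge_frac: float = 0.05,
) -> ConnectivityMatrix:
    """Band-wise wPLI between every pair of region signals.

    ``pool='all'`` (default) averages the expectation over pooled epochs and
    time samples; ``pool='epoch'`` computes wPLI per epoch and averages the
    per-epoch values. The diagonal is 0 by convention.
    """
    band_ep = band_decompose(region_ep, band, method=method)
    data = band_ep.kept_epochs()
    if data.shape[0] == 0:
        raise ValueError("no kept epochs")
    n = data.shape[1]
    analytic = signal.hilbert(data, axis=-1)
    nt = data.shape[-1]
    cut = int(round(edge_frac * nt))
    sl = slice(cut, nt - cut) if nt - 2 * cut >= 1 else slice(None)
    analytic = analytic[..., sl]
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            x = CrossSpectrum(analytic[:, i, :] * np.conj(analytic[:, j, :]))
            w[i, j] = w[j, i] = (
                wpli(x) if pool == "all" else _wpli_per_epoch(x.values)
            )
    return ConnectivityMatrix(band=band, w=w, regions=list(region_ep.ch_names))
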