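"""Power spectral density, relative band power and quantitative-EEG ratios.

The five resting-state bands are delta 1-4, theta 4-8, alpha 8-15,
beta 15-30 and gamma 30-45 Hz. Band edges are half-open ``[lo, hi)`` so
adjacent bands never double-count a frequency bin, and relative power is
normalised by the sum over the five bands (the 1-45 Hz pass-band).

The PSD estimator is Welch's method with one 2-s Hamming window per kept
epoch, averaged across epochs — the natural estimator given the 2-s epoch
structure, with 0.5 Hz resolution at fs = 500 Hz.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal

from .preprocess import EpochedRecording

__all__ = [
    "BANDS",
    "welch_psd",
    "band_power",
    "relative_power",
    "qeeg_ratios",
    "to_db",
    "band_power_table",
]

#: Resting-state band scheme (Hz), ordered low to high; half-open [lo, hi).
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 15.0),
    "beta": (15.0, 30.0),
    "gamma": (30.0, 45.0),
}


def welch_psd(ep: EpochedRecording) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD averaged over kept epochs.

    Returns ``(freqs, psd)`` with ``psd`` of shape ``(n_channels, n_freqs)``
    in uV^2/Hz. Each kept epoch contributes one Hamming-windowed segment.
    """
    data = ep.kept_epochs()
    if data.shape[0] == 0:
        raise ValueError("no kept epochs; cannot estimate PSD")
    nper = data.shape[2]
    freqs, psd = signal.welch(
        data, fs=ep.fs, window="hamming", nperseg=nper, noverlap=0, axis=-1
    )
    return freqs, psd.mean(axis=0)


def band_power(
    freqs: np.ndarray, psd: np.ndarray, band: tuple[float, float]
) -> np.ndarray:
    """Integrated power over ``[lo, hi)`` in uV^2 (rectangle rule, so that
    the five band powers partition the 1-45 Hz total exactly)."""
    lo, hi = band
    freqs = np.asarray(freqs)
    if lo < freqs[0] - 1e-9 or hi > freqs[-1] + 1e-9:
        raise ValueError(f"band [{lo}, {hi}] outside PSD support "
                         f"[{freqs[0]}, {freqs[-1]}]")
    df = freqs[1] - freqs[0]
    mask = (freqs >= lo) & (freqs < hi)
    return np.asarray(psd)[..., mask].sum(axis=-1) * df


def relative_power(
    freqs: np.ndarray, psd: np.ndarray, band: str, bands: dict | None = None
) -> np.ndarray:
    """One band's share of the total power over the five defined bands."""
    bands = bands or BANDS
    if band not in bands:
        raise KeyError(f"unknown band '{band}'")
    powers = {name: band_power(freqs, psd, rng) for name, rng in bands.items()}
    total = sum(powers.values())
    if np.any(total <= 0):
        raise ValueError("total band power is zero; relative power undefined")
    return powers[band] / total


def qeeg_ratios(
    freqs: np.ndarray, psd: np.ndarray, bands: dict | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Theta/alpha (TAR) and theta/beta (TBR) power ratios.

    A zero denominator yields NaN (flagged undefined, never infinity); zero
    theta power with a positive denominator gives 0.
    """
    bands = bands or BANDS
    p_theta = band_power(freqs, psd, bands["theta"])
    p_alpha = band_power(freqs, psd, bands["alpha"])
    p_beta = band_power(freqs, psd, bands["beta"])
    with np.errstate(divide="ignore", invalid="ignore"):
        tar = np.where(p_alpha > 0, p_theta / np.where(p_alpha > 0, p_alpha, 1.0), np.nan)
        tbr = np.where(p_beta > 0, p_theta / np.where(p_beta > 0, p_beta, 1.0), np.nan)
    return tar, tbr


def to_db(power) -> np.ndarray:
    """10*log10 of a power quantity; rejects non-positive input."""
    power = np.asarray(power, dtype=float)
    if np.any(power <= 0):
        raise ValueError("dB undefined for non-positive power")
    return 10.0 * np.log10(power)


def band_power_table(
    region_ep: EpochedRecording,
    subject: str = "",
    session: str = "",
    condition: str = "",
    bands: dict | None = None,
) -> pd.DataFrame:
    """Tidy long-format band-power table for one preprocessed recording.

    One row per (region, band) with absolute power (uV^2), relative power,
    its dB value, and the region's TAR/TBR repeated on each row. Relative
    powers within a region sum to 1.
    """
    bands = bands or BANDS
    freqs, psd = welch_psd(region_ep)
    abs_p = {name: band_power(freqs, psd, rng) for name, rng in bands.items()}
    total = sum(abs_p.values())
    if np.any(total <= 0):
        raise ValueError("zero total power in at least one region")
    tar, tbr = qeeg_ratios(freqs, psd, bands)
    rows = []
    for r, region in enumerate(region_ep.ch_names):
        for name in bands:
            rel = abs_p[name][r] / total[r]
            rows.append(
                {
                    "subject": subject,
                    "session": session,
                    "condition": condition,
                    "region": region,
                    "band": name,
                    "abs_power_uv2": abs_p[name][r],
                    "relative_power": rel,
                    "relative_power_db": 10.0 * np.log10(rel) if rel > 0 else -np.inf,
                    "tar": tar[r],
                    "tbr": tbr[r],
                }
            )
    return pd.DataFrame(rows)
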