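"""Task-state engagement index and Cz time-frequency analysis.

The engagement ("brain involvement") index scores attention from the
alpha/beta energy ratio of the central midline channels:

    E = 100 * P_beta / (P_alpha + P_beta)

with the attention bands alpha 7-13 Hz and beta 14-30 Hz — a scheme distinct
from the resting five-band scheme and kept separate from it. Beta dominance
(focused engagement) drives the index toward 100; alpha dominance (idling)
toward 0. The index is a power ratio, hence invariant to overall amplitude
scaling.

Time-frequency maps use a complex Morlet transform at 1-45 Hz, with power in
dB relative to each frequency's mean over the whole recording.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt

from .preprocess import EpochedRecording, RawRecording
from .spectral import band_power, welch_psd

__all__ = [
    "ATTENTION_BANDS",
    "CENTRAL_CHANNELS",
    "TimeFrequencyMap",
    "engagement_index",
    "session_trajectory",
    "cz_time_frequency",
]

#: Attention band scheme (Hz) used for the engagement index.
ATTENTION_BANDS: dict[str, tuple[float, float]] = {
    "alpha": (7.0, 13.0),
    "beta": (14.0, 30.0),
}

#: Central midline channels over the (lower-limb) motor area.
CENTRAL_CHANNELS: tuple[str, ...] = ("Cz", "FCz", "CPz")


def engagement_index(
    task_ep: EpochedRecording,
    channels: tuple[str, ...] = CENTRAL_CHANNELS,
    bands: dict | None = None,
    ratio: bool = False,
) -> float:
    """Engagement index of one task recording, in [0, 100].

    Band powers are Welch-estimated over kept epochs and averaged across the
    requested channels. With ``ratio=True`` the raw beta/alpha power ratio is
    returned instead of the bounded 0-100 index.
    """
    bands = bands or ATTENTION_BANDS
    rows = [i for i, ch in enumerate(task_ep.ch_names) if ch in channels]
    if not rows:
        raise KeyError(f"none of {channels} present in recording")
    freqs, psd = welch_psd(task_ep)
    p_alpha = float(band_power(freqs, psd[rows], bands["alpha"]).mean())
    p_beta = float(band_power(freqs, psd[rows], bands["beta"]).mean())
    if p_alpha + p_beta <= 0:
        raise ValueError("zero alpha+beta power; engagement undefined")
    if ratio:
        if p_alpha <= 0:
            raise ValueError("zero alpha power; raw ratio undefined")
        return p_beta / p_alpha
    return 100.0 * p_beta / (p_alpha + p_beta)


def session_trajectory(
    sessions: list[EpochedRecording | None],
    subject: str = "",
    **kwargs,
) -> pd.DataFrame:
    """Engagement per training session, in order.

    ``sessions`` is the ordered list of preprocessed task recordings
    (``None`` marks a missing session, flagged with NaN). The first and last
    present sessions are flagged for the endpoint comparison.
    """
    rows = []
    for k, ep in enumerate(sessions, start=1):
        value = np.nan if ep is None else engagement_index(ep, **kwargs)
        rows.append({"subject": subject, "session": k, "engagement": value,
                     "missing": ep is None})
    df = pd.DataFrame(rows)
    present = df.index[~df["missing"]]
    df["endpoint"] = ""
    if len(present):
        df.loc[present[0], "endpoint"] = "first"
        df.loc[present[-1], "endpoint"] = "last"
    return df


@dataclass
class TimeFrequencyMap:
    """Morlet power map for one channel.

    ``power`` is absolute (uV^2); ``power_db`` is dB relative to the
    per-frequency mean over the whole recording, so a stationary rhythm sits
    at 0 dB throughout.
    """

    channel: str
    times: np.ndarray
    freqs: np.ndarray
    power: np.ndarray  # (n_times, n_freqs), absolute
    power_db: np.ndarray  # (n_times, n_freqs), re. per-frequency mean

    def __post_init__(self) -> None:
        if self.power_db.shape != (len(self.times), len(self.freqs)):
            raise ValueError("power map shape must be (n_times, n_freqs)")
        if self.power.shape != self.power_db.shape:
            raise ValueError("power and power_db shapes must agree")
        if not np.all(np.isfinite(self.power_db)):
            raise ValueError("power map must be finite")

    def ridge(self) -> np.ndarray:
        """Per-time-point frequency of maximal absolute power."""
        return self.freqs[np.argmax(self.power, axis=1)]


def cz_time_frequency(
    rec: RawRecording,
    channel: str = "Cz",
    f_lo: float = 1.0,
    f_hi: float = 45.0,
    f_step: float = 1.0,
    wavelet: str = "cmor1.5-1.0",
) -> TimeFrequencyMap:
    """Complex Morlet time-frequency decomposition of one channel.

    Centre frequencies run from ``f_lo`` to ``f_hi`` in ``f_step`` steps;
    power is expressed in dB relative to each frequency's mean over the
    recording, so a stationary rhythm sits at 0 dB.
    """
    if channel not in rec.ch_names:
        raise KeyError(f"channel {channel!r} not in recording")
    x = rec.data[rec.ch_names.index(channel)]
    if np.allclose(x, 0.0):
        raise ValueError("zero signal; dB power undefined")
    freqs = np.arange(f_lo, f_hi + 1e-9, f_step)
    scales = pywt.central_frequency(wavelet) * rec.fs / freqs
    coefs, _ = pywt.cwt(x, scales, wavelet, sampling_period=1.0 / rec.fs)
    power = np.abs(coefs) ** 2  # (n_freqs, n_times)
    mean_per_freq = power.mean(axis=1, keepdims=True)
    if np.any(mean_per_freq <= 0):
        raise ValueError("degenerate spectrum; dB power undefined")
    power_db = 10.0 * np.log10(power / mean_per_freq)
    times = np.arange(len(x)) / rec.fs
    return TimeFrequencyMap(
        channel=channel, times=times, freqs=freqs,
        power=power.T, power_db=power_db.T,
    )
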