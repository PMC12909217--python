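"""Synthetic EEG recordings and cohorts with known ground truth.

Every downstream stage of the pipeline is exercised against signals whose
spectral content, inter-region phase lags, artifact epochs and treatment
effects are planted by construction:

* band oscillations are narrow-band Gaussian processes (frequency-domain
  synthesis inside the band), one independent process per region, shared by
  the region's channels;
* the 1/f^a background is synthesised in the frequency domain with random
  phases and exactly controlled log-log slope;
* cross-region coupling copies a region's band process into another region
  at a fixed phase lag, mixed with the target's own process at a stated
  strength — the analytic wPLI of such a pair is known;
* artifact epochs receive a square pulse far above the 75 uV rejection
  bound, so the rejection rule fires deterministically;
* pre/post treatment effects multiply band powers (theta up / beta down),
  add coupling strength in the delta and theta bands, and tilt the
  session-wise engagement trajectory.

Every generator is a pure function of its spec and seed: identical inputs
give identical samples. Amplitudes default to the conventional resting-EEG
scale (~10-50 uV peak-to-peak per rhythm).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .preprocess import (
    CHANNELS_30,
    OCULAR_CHANNELS,
    REGIONS_10,
    EpochedRecording,
    Montage,
    RawRecording,
    default_montage,
)

__all__ = [
    "RecordingSpec",
    "CouplingSpec",
    "EffectSpec",
    "Cohort",
    "DEFAULT_BAND_AMPLITUDES",
    "DEFAULT_RESTING_COUPLING",
    "CONTROL_EFFECTS",
    "EXPERIMENTAL_EFFECTS",
    "NULL_EFFECTS",
    "TABLE1_DEMOGRAPHICS",
    "make_band_oscillation",
    "make_background",
    "generate_coupled_pair",
    "generate_resting_recording",
    "generate_task_recording",
    "generate_cohort",
]

#: Default per-rhythm amplitudes (uV, sinusoid-equivalent peak) for a
#: resting recording: alpha-dominant, gamma weakest.
DEFAULT_BAND_AMPLITUDES: dict[str, float] = {
    "delta": 8.0,
    "theta": 6.0,
    "alpha": 10.0,
    "beta": 4.0,
    "gamma": 2.0,
}

_BAND_EDGES: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 15.0),
    "beta": (15.0, 30.0),
    "gamma": (30.0, 45.0),
}

# Attention-band edges for task-state engagement (distinct from the resting
# scheme: alpha 7-13, beta 14-30).
_ATTENTION_ALPHA = (7.0, 13.0)
_ATTENTION_BETA = (14.0, 30.0)
_CENTRAL_CHANNELS = ("Cz", "FCz", "CPz")


def _rng(seed: int, *labels) -> np.random.Generator:
    """Deterministic per-stage generator: the stream depends on the base
    seed plus a label path (stage name, subject id, ...), so adding subjects
    or stages never perturbs existing streams."""
    keys = [zlib.crc32(str(lbl).encode()) for lbl in labels]
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *keys]))


@dataclass
class RecordingSpec:
    """Parameters of one synthetic continuous recording."""

    n_channels: int = 30
    fs: float = 500.0
    duration: float = 120.0
    band_amplitudes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_AMPLITUDES)
    )
    noise_exponent: float = 1.0
    background_amp: float = 5.0
    line_noise_amp: float = 2.0
    artifact_epoch_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")
        if not 0 <= self.artifact_epoch_rate <= 1:
            raise ValueError("artifact_epoch_rate must lie in [0, 1]")
        if not 0 <= self.noise_exponent <= 2:
            raise ValueError("noise exponent must lie in [0, 2]")


@dataclass
class CouplingSpec:
    """Planted phase coupling for one band: the second region of each pair
    receives the first region's band process at phase lag ``lag``, mixed at
    ``strength`` with its own independent process."""

    region_pairs: list[tuple[str, str]]
    band: str
    lag: float
    strength: float

    def __post_init__(self) -> None:
        if not -np.pi < self.lag <= np.pi:
            raise ValueError("lag must lie in (-pi, pi]")
        if not 0 <= self.strength <= 1:
            raise ValueError("strength must lie in [0, 1]")
        if self.band not in _BAND_EDGES:
            raise KeyError(f"unknown band '{self.band}'")


@dataclass
class EffectSpec:
    """Injectable pre-to-post treatment effect for one study arm."""

    theta_power_shift: float = 1.0
    beta_power_shift: float = 1.0
    delta_theta_coupling_shift: float = 0.0
    engagement_baseline: float = 44.0
    engagement_slope: float = 0.0
    group: str = "control"

    def __post_init__(self) -> None:
        if self.theta_power_shift <= 0 or self.beta_power_shift <= 0:
            raise ValueError("power shift factors must be positive")
        if self.group not in ("control", "experimental"):
            raise ValueError("group must be 'control' or 'experimental'")


#: Baseline resting-state coupling structure: a handful of plausible
#: links per band (parietal/occipital posterior hub, frontal midline),
#: each at a moderate strength and a non-zero lag.
DEFAULT_RESTING_COUPLING: list[CouplingSpec] = [
    CouplingSpec([("left_parietal", "right_parietal"),
                  ("central_parietal", "occipital")], "delta", np.pi / 4, 0.35),
    CouplingSpec([("prefrontal", "central_frontal")], "delta", np.pi / 3, 0.30),
    CouplingSpec([("left_frontal", "central_frontal"),
                  ("central_parietal", "left_parietal")], "theta", np.pi / 4, 0.35),
    CouplingSpec([("right_frontal", "central_frontal")], "theta", np.pi / 3, 0.30),
    CouplingSpec([("occipital", "central_parietal"),
                  ("occipital", "left_parietal")], "alpha", np.pi / 4, 0.40),
    CouplingSpec([("left_frontal", "left_parietal"),
                  ("central_frontal", "central_parietal")], "beta", np.pi / 4, 0.30),
    CouplingSpec([("left_temporal", "left_frontal")], "gamma", np.pi / 4, 0.25),
]

# Study-arm effect defaults. The engagement baselines and per-session slopes
# emulate the reported session-1 / session-20 trajectory of each arm
# (control 44.36 -> 74.80, experimental 43.15 -> 78.17 over 20 sessions);
# power shifts and the connectivity shift follow the reported directions
# (theta up, beta down, delta/theta coupling up), larger in the
# experimental arm.
CONTROL_EFFECTS = EffectSpec(1.2, 0.8, 0.15, 44.36, 1.60, "control")
EXPERIMENTAL_EFFECTS = EffectSpec(1.3, 0.7, 0.25, 43.15, 1.84, "experimental")
NULL_EFFECTS = EffectSpec(1.0, 1.0, 0.0, 44.0, 0.0, "control")

#: Printed demographic rows usable as a manifest fixture
#: (sex, age, injury level, KVIQ, ASIA grade).
TABLE1_DEMOGRAPHICS: dict[str, list[tuple[str, int, str, int, str]]] = {
    "control": [
        ("M", 37, "T10", 85, "B"),
        ("M", 62, "L3", 84, "C"),
        ("M", 66, "T12", 86, "C"),
        ("F", 52, "T10", 82, "B"),
        ("M", 55, "C5", 87, "B"),
    ],
    "experimental": [
        ("M", 37, "T10", 84, "B"),
        ("M", 70, "C4", 86, "C"),
        ("M", 52, "T10", 89, "B"),
        ("M", 57, "C4", 83, "B"),
        ("M", 24, "T11", 85, "B"),
        ("M", 66, "T12", 83, "C"),
    ],
}

# Clinical instrument ranges and pre-treatment sampling defaults
# (mean, sd) per arm, with group-specific post-treatment gains.
_CLINICAL = {
    "asia_motor": dict(rng=(0, 100), pre=(52.5, 23.0), gain={"control": 5.2, "experimental": 12.5}),
    "asia_sensory": dict(rng=(0, 224), pre=(160.0, 48.0), gain={"control": 5.0, "experimental": 29.2}),
    "bbs": dict(rng=(0, 56), pre=(5.4, 3.6), gain={"control": 2.4, "experimental": 5.2}),
    "fac": dict(rng=(0, 5), pre=(0.2, 0.45), gain={"control": 0.6, "experimental": 0.9}),
}


# ---------------------------------------------------------------------------
# elementary signal builders
# ---------------------------------------------------------------------------

def make_band_oscillation(
    freq: float, amp: float, phase: float, duration: float, fs: float
) -> np.ndarray:
    """A sinusoid ``amp * sin(2*pi*freq*t + phase)`` of ``round(duration*fs)``
    samples. Frequencies at or above Nyquist are rejected."""
    if freq < 0 or freq >= fs / 2:
        raise ValueError(f"frequency {freq} Hz must lie in [0, fs/2) = [0, {fs / 2})")
    n = round(duration * fs)
    t = np.arange(n) / fs
    return amp * np.sin(2 * np.pi * freq * t + phase)


def make_background(
    noise_exponent: float,
    fs: float,
    duration: float,
    seed: int | np.random.Generator = 0,
    f_floor: float = 1.0,
) -> np.ndarray:
    """Unit-RMS 1/f^a background noise.

    Synthesised in the frequency domain: spectral magnitudes proportional to
    ``f**(-a/2)`` (flattened below ``f_floor`` to avoid a DC blow-up) with
    i.i.d. random phases, so the fitted log-log PSD slope over 1-45 Hz is
    ``-a`` by construction.
    """
    if not 0 <= noise_exponent <= 2:
        raise ValueError("noise exponent must lie in [0, 2]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = round(duration * fs)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mag = np.zeros_like(freqs)
    nz = freqs > 0
    mag[nz] = np.maximum(freqs[nz], f_floor) ** (-noise_exponent / 2.0)
    spec = mag * np.exp(2j * np.pi * rng.random(len(freqs)))
    spec[0] = 0.0
    x = np.fft.irfft(spec, n=n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _narrowband_noise(
    lo: float, hi: float, n: int, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to [lo, hi] (frequency-domain
    synthesis). Models one region's ongoing rhythm within a band."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (freqs >= lo) & (freqs <= hi)
    spec = np.zeros(len(freqs), dtype=complex)
    k = int(mask.sum())
    if k == 0:
        raise ValueError(f"band [{lo}, {hi}] contains no frequency bin")
    spec[mask] = rng.standard_normal(k) + 1j * rng.standard_normal(k)
    x = np.fft.irfft(spec, n=n)
    return x / np.sqrt(np.mean(x**2))


def _phase_lagged(x: np.ndarray, lag: float) -> np.ndarray:
    """Copy of a narrow-band signal with its instantaneous phase delayed by
    ``lag`` radians (rotation of the analytic signal)."""
    from scipy.signal import hilbert

    return np.real(hilbert(x) * np.exp(-1j * lag))


# ---------------------------------------------------------------------------
# coupled pairs (ground truth for wPLI)
# ---------------------------------------------------------------------------

def generate_coupled_pair(
    freq: float = 10.0,
    lag: float = np.pi / 2,
    coupling_strength: float = 1.0,
    noise_sd: float = 0.0,
    n_epochs: int = 20,
    fs: float = 500.0,
    epoch_len: float = 2.0,
    seed: int = 0,
) -> EpochedRecording:
    """Two-channel epochs with a known phase relationship.

    Channel 1 is a sinusoid at ``freq`` with a random phase per epoch;
    channel 2 is channel 1 delayed by ``lag`` radians at the stated coupling
    strength, mixed with an independent same-frequency process and white
    noise. With strength 1 and no noise the analytic wPLI is 1 for any
    ``lag`` with ``sin(lag) != 0`` and 0 (by the 0/0 convention) at zero lag.
    """
    if n_epochs < 2:
        raise ValueError("need at least 2 epochs")
    if not 0 <= coupling_strength <= 1:
        raise ValueError("coupling strength must lie in [0, 1]")
    rng = _rng(seed, "coupled_pair")
    n_t = round(epoch_len * fs)
    t = np.arange(n_t) / fs
    x = np.empty((n_epochs, n_t))
    y = np.empty((n_epochs, n_t))
    mix = np.sqrt(max(0.0, 1.0 - coupling_strength**2))
    for e in range(n_epochs):
        phi = rng.uniform(0, 2 * np.pi)
        psi = rng.uniform(0, 2 * np.pi)
        x[e] = np.sin(2 * np.pi * freq * t + phi)
        lagged = np.sin(2 * np.pi * freq * t + phi - lag)
        indep = np.sin(2 * np.pi * freq * t + psi)
        y[e] = coupling_strength * lagged + mix * indep
        if noise_sd > 0:
            y[e] += noise_sd * rng.standard_normal(n_t)
    epochs = np.stack([x, y], axis=1)
    return EpochedRecording(
        epochs=epochs,
        ch_names=["ch1", "ch2"],
        fs=fs,
        epoch_length=epoch_len,
        kept=np.ones(n_epochs, dtype=bool),
        meta={"freq": freq, "lag": lag, "strength": coupling_strength,
              "noise_sd": noise_sd, "seed": seed},
        provenance=["synth:coupled_pair"],
    )


# ---------------------------------------------------------------------------
# full 30-channel recordings
# ---------------------------------------------------------------------------

def _region_band_components(
    spec: RecordingSpec,
    coupling: list[CouplingSpec],
    montage: Montage,
    rng: np.random.Generator,
    n: int,
) -> dict[str, np.ndarray]:
    """Per-region summed rhythm signal (n samples), couplings applied."""
    regions = montage.region_names
    per_region = {r: np.zeros(n) for r in regions}
    for band, (lo, hi) in _BAND_EDGES.items():
        amp = spec.band_amplitudes.get(band, 0.0)
        comp = {r: _narrowband_noise(lo, hi, n, spec.fs, rng) for r in regions}
        for cs in coupling:
            if cs.band != band:
                continue
            for ri, rj in cs.region_pairs:
                if ri not in comp or rj not in comp:
                    raise KeyError(f"coupling names unknown region: {ri!r}/{rj!r}")
                mix = np.sqrt(max(0.0, 1.0 - cs.strength**2))
                comp[rj] = cs.strength * _phase_lagged(comp[ri], cs.lag) + mix * comp[rj]
        scale = amp / np.sqrt(2.0)  # sinusoid-equivalent RMS
        for r in regions:
            per_region[r] += scale * comp[r]
    return per_region


def generate_resting_recording(
    spec: RecordingSpec,
    coupling: list[CouplingSpec] | None = None,
    montage: Montage | None = None,
    seed: int | None = None,
    meta: dict | None = None,
) -> RawRecording:
    """One continuous 30-channel resting recording.

    Channels receive the mean of the rhythm signals of the regions they
    belong to (FT7/FT8 sit in two regions), plus a per-channel 1/f
    background, 50 Hz line noise, and — in ``artifact_epoch_rate`` of the
    2-s epochs — a square pulse far above the 75 uV rejection bound on a few
    channels. Ocular channels carry low-frequency high-amplitude activity.
    The planted ground truth is recorded in ``meta``.
    """
    montage = montage or default_montage()
    coupling = list(coupling) if coupling is not None else []
    base_seed = spec.seed if seed is None else seed
    rng = _rng(base_seed, "resting")
    n = round(spec.duration * spec.fs)
    ch_names = list(CHANNELS_30)

    per_region = _region_band_components(spec, coupling, montage, rng, n)
    membership: dict[str, list[str]] = {}
    for region, chans in montage.regions.items():
        for ch in chans:
            membership.setdefault(ch, []).append(region)

    data = np.zeros((len(ch_names), n))
    t = np.arange(n) / spec.fs
    for i, ch in enumerate(ch_names):
        if ch in OCULAR_CHANNELS:
            data[i] = 40.0 * _narrowband_noise(0.3, 5.0, n, spec.fs, rng)
        else:
            regions = membership.get(ch, [])
            if regions:
                data[i] = np.mean([per_region[r] for r in regions], axis=0)
        data[i] += spec.background_amp * make_background(
            spec.noise_exponent, spec.fs, spec.duration, rng
        )
        if spec.line_noise_amp > 0:
            data[i] += spec.line_noise_amp * np.sin(
                2 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi)
            )

    # plant artifact epochs: a 0.3 s square pulse at +/-150 uV on three
    # scalp channels, centred in the epoch so filter ringing stays inside it
    n_per_epoch = round(2.0 * spec.fs)
    n_epochs = n // n_per_epoch
    n_art = round(spec.artifact_epoch_rate * n_epochs)
    art_epochs = sorted(rng.choice(n_epochs, size=n_art, replace=False)) if n_art else []
    scalp_idx = [i for i, ch in enumerate(ch_names) if ch not in OCULAR_CHANNELS]
    half_pulse = round(0.15 * spec.fs)
    for e in art_epochs:
        centre = e * n_per_epoch + n_per_epoch // 2
        chans = rng.choice(scalp_idx, size=3, replace=False)
        sign = rng.choice([-1.0, 1.0])
        data[chans, centre - half_pulse : centre + half_pulse] += sign * 150.0

    return RawRecording(
        data=data,
        ch_names=ch_names,
        fs=spec.fs,
        meta={
            **(meta or {}),
            "kind": "resting",
            "seed": base_seed,
            "band_amplitudes": dict(spec.band_amplitudes),
            "coupling": coupling,
            "artifact_epochs": list(map(int, art_epochs)),
            "n_epochs_planted": int(n_epochs),
        },
        provenance=["synth:resting"],
    )


def generate_task_recording(
    engagement: float,
    fs: float = 250.0,
    duration: float = 60.0,
    seed: int = 0,
    background_amp: float = 5.0,
    line_noise_amp: float = 2.0,
    attention_power: float = 100.0,
    noise_exponent: float = 1.0,
    meta: dict | None = None,
) -> RawRecording:
    """One 30-channel task-state recording with a planted engagement level.

    The central midline channels (Cz, FCz, CPz) carry attention-band alpha
    (7-13 Hz) and beta (14-30 Hz) processes whose power split realises the
    target engagement ``E = 100 * Pb / (Pa + Pb)``; other scalp channels
    carry a generic alpha rhythm. Background and line noise as in resting
    recordings.
    """
    if not 0 < engagement < 100:
        raise ValueError("target engagement must lie strictly inside (0, 100)")
    rng = _rng(seed, "task")
    n = round(duration * fs)
    t = np.arange(n) / fs
    ch_names = list(CHANNELS_30)
    beta_power = attention_power * engagement / 100.0
    alpha_power = attention_power - beta_power
    alpha_sig = _narrowband_noise(*_ATTENTION_ALPHA, n, fs, rng) * np.sqrt(alpha_power)
    beta_sig = _narrowband_noise(*_ATTENTION_BETA, n, fs, rng) * np.sqrt(beta_power)

    data = np.zeros((len(ch_names), n))
    for i, ch in enumerate(ch_names):
        if ch in OCULAR_CHANNELS:
            data[i] = 40.0 * _narrowband_noise(0.3, 5.0, n, fs, rng)
        elif ch in _CENTRAL_CHANNELS:
            data[i] = alpha_sig + beta_sig
        else:
            # independent per channel so the average reference leaks little
            # alpha into the central channels
            data[i] = 6.0 * _narrowband_noise(8.0, 13.0, n, fs, rng)
        data[i] += background_amp * make_background(noise_exponent, fs, duration, rng)
        if line_noise_amp > 0:
            data[i] += line_noise_amp * np.sin(2 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi))
    return RawRecording(
        data=data,
        ch_names=ch_names,
        fs=fs,
        meta={**(meta or {}), "kind": "task", "seed": seed,
              "engagement_target": engagement},
        provenance=["synth:task"],
    )


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def _post_coupling(coupling: list[CouplingSpec], shift: float) -> list[CouplingSpec]:
    """Post-treatment coupling: strengths in the delta and theta bands are
    raised by ``shift`` (capped at 0.9)."""
    out = []
    for cs in coupling:
        if cs.band in ("delta", "theta") and shift != 0.0:
            out.append(replace(cs, strength=min(0.9, cs.strength + shift)))
        else:
            out.append(cs)
    return out


def _truncnorm(rng, mean, sd, lo, hi):
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return v
    return float(np.clip(mean, lo, hi))


@dataclass
class Cohort:
    """A synthetic two-arm study.

    Recordings are generated on demand (deterministically from the cohort
    seed and the subject/condition labels) to keep memory flat; the manifest
    and the planted effects are materialised up front.
    """

    manifest: pd.DataFrame
    effects: dict[str, EffectSpec]
    seed: int
    n_sessions: int = 20
    resting_duration: float = 120.0
    task_duration: float = 60.0
    fs_resting: float = 500.0
    fs_task: float = 250.0
    artifact_epoch_rate: float = 0.05
    coupling: list[CouplingSpec] = field(
        default_factory=lambda: list(DEFAULT_RESTING_COUPLING)
    )

    @property
    def subjects(self) -> list[str]:
        return list(self.manifest["subject_id"])

    def _subject_amplitudes(self, subject: str) -> dict[str, float]:
        rng = _rng(self.seed, "amps", subject)
        return {b: a * float(np.exp(rng.normal(0.0, 0.08)))
                for b, a in DEFAULT_BAND_AMPLITUDES.items()}

    def resting_recording(self, subject: str, condition: str) -> RawRecording:
        """Resting recording for one subject, ``condition`` 'pre' or 'post'."""
        if condition not in ("pre", "post"):
            raise ValueError("condition must be 'pre' or 'post'")
        row = self.manifest.loc[self.manifest["subject_id"] == subject]
        if row.empty:
            raise KeyError(f"unknown subject {subject!r}")
        group = row["group"].iloc[0]
        eff = self.effects[group]
        amps = self._subject_amplitudes(subject)
        # independent session-to-session wobble on each band's power
        srng = _rng(self.seed, "session", subject, condition)
        amps = {b: a * float(np.exp(srng.normal(0.0, 0.05))) for b, a in amps.items()}
        coupling = self.coupling
        if condition == "post":
            amps["theta"] *= float(np.sqrt(eff.theta_power_shift))
            amps["beta"] *= float(np.sqrt(eff.beta_power_shift))
            coupling = _post_coupling(coupling, eff.delta_theta_coupling_shift)
        spec = RecordingSpec(
            fs=self.fs_resting,
            duration=self.resting_duration,
            band_amplitudes=amps,
            artifact_epoch_rate=self.artifact_epoch_rate,
        )
        seed = int(_rng(self.seed, "rest-seed", subject, condition).integers(2**31 - 1))
        return generate_resting_recording(
            spec, coupling=coupling, seed=seed,
            meta={"subject": subject, "group": group, "condition": condition},
        )

    def engagement_target(self, subject: str, session: int) -> float:
        """Planted engagement index for one training session (1-based)."""
        if not 1 <= session <= self.n_sessions:
            raise ValueError(f"session must lie in 1..{self.n_sessions}")
        row = self.manifest.loc[self.manifest["subject_id"] == subject]
        if row.empty:
            raise KeyError(f"unknown subject {subject!r}")
        eff = self.effects[row["group"].iloc[0]]
        base = eff.engagement_baseline + float(_rng(self.seed, "eng-base", subject).normal(0, 10.0))
        noise = float(_rng(self.seed, "eng", subject, session).normal(0, 4.0))
        return float(np.clip(base + eff.engagement_slope * (session - 1) + noise, 5.0, 95.0))

    def task_recording(self, subject: str, session: int) -> RawRecording:
        """Task recording for one training session (1-based)."""
        target = self.engagement_target(subject, session)
        seed = int(_rng(self.seed, "task-seed", subject, session).integers(2**31 - 1))
        row = self.manifest.loc[self.manifest["subject_id"] == subject]
        return generate_task_recording(
            target, fs=self.fs_task, duration=self.task_duration, seed=seed,
            meta={"subject": subject, "group": row["group"].iloc[0],
                  "session": int(session)},
        )


def _make_manifest(
    n_per_group: int,
    effects: dict[str, EffectSpec],
    seed: int,
    use_printed_demographics: bool,
) -> pd.DataFrame:
    rows = []
    for group in ("control", "experimental"):
        printed = TABLE1_DEMOGRAPHICS[group]
        for k in range(n_per_group):
            sid = f"{group[:4]}{k + 1:02d}"
            rng = _rng(seed, "manifest", sid)
            if use_printed_demographics and k < len(printed):
                sex, age, level, kviq, grade = printed[k]
            else:
                sex = "M" if rng.random() < 0.85 else "F"
                age = int(rng.integers(24, 71))
                level = str(rng.choice(["C4", "C5", "T10", "T11", "T12", "L3"]))
                kviq = int(round(_truncnorm(rng, 85.0, 2.2, 55, 100)))
                grade = str(rng.choice(["B", "C"]))
            row = {
                "subject_id": sid, "group": group, "sex": sex, "age": age,
                "injury_level": level, "kviq": kviq, "asia_grade": grade,
            }
            for score, cfg in _CLINICAL.items():
                lo, hi = cfg["rng"]
                pre = _truncnorm(rng, *cfg["pre"], lo, hi)
                gain = cfg["gain"][group]
                post = float(np.clip(pre + rng.normal(gain, gain / 2 + 0.5), lo, hi))
                if score == "fac":
                    pre, post = round(pre), round(post)
                row[f"{score}_pre"] = round(float(pre), 1)
                row[f"{score}_post"] = round(float(post), 1)
            rows.append(row)
    return pd.DataFrame(rows)


def generate_cohort(
    n_per_group: int = 6,
    effects: dict[str, EffectSpec] | None = None,
    seed: int = 0,
    use_printed_demographics: bool = False,
    **cohort_kwargs,
) -> Cohort:
    """Build a two-arm synthetic cohort.

    ``effects`` maps arm name to its :class:`EffectSpec`; by default the
    experimental arm receives the larger injected effects
    (:data:`EXPERIMENTAL_EFFECTS` vs :data:`CONTROL_EFFECTS`). Keyword
    arguments are forwarded to :class:`Cohort` (durations, sampling rates,
    artifact rate, coupling).
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 subjects per group")
    effects = effects or {"control": CONTROL_EFFECTS, "experimental": EXPERIMENTAL_EFFECTS}
    for grp in ("control", "experimental"):
        if grp not in effects:
            raise KeyError(f"effects must define arm '{grp}'")
    manifest = _make_manifest(n_per_group, effects, seed, use_printed_demographics)
    return Cohort(manifest=manifest, effects=dict(effects), seed=int(seed), **cohort_kwargs)
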