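"""Synthetic stage-labelled polysomnograms.

Real overnight sleep cohorts are access restricted, so the pipeline is
exercised on simulated recordings that reproduce the montage it expects:
two EEG channels (C3-A2, C4-A1) and one chin EMG at 125 Hz, and two EOG
channels at 50 Hz, all cut into 30-s epochs labelled W / N1 / N2 / N3 / REM.

A first-order Markov chain generates the hypnogram; each epoch's signals
are 1/f (pink) background noise plus stage-dependent signatures encoding
textbook stage phenomenology:

* W   — 8-12 Hz posterior alpha rhythm on EEG, frequent high-amplitude
        EMG bursts, eye blinks (same-polarity in both EOGs);
* N1  — 4-7 Hz theta on EEG, slow rolling eye movements, sparser EMG bursts;
* N2  — 11-16 Hz spindle bursts (~1 s, Gaussian envelope) over mild theta;
* N3  — high-amplitude 0.5-2 Hz slow waves on EEG (bleeding into EOG);
* REM — low-amplitude mixed-frequency EEG, EMG atonia (tonic noise only,
        rare twitches), and conjugate rapid eye movements mirrored between
        EOG-L and EOG-R (negative inter-EOG correlation).

Signature amplitudes scale with ``snr`` (signature RMS over the unit noise
floor); at ``snr = 0`` every stage reduces to identically distributed noise.
All frequencies/amplitudes live in one config block (`STAGE_SIGNATURES`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .psg_io import ChannelEpochs, EpochedRecording, write_annotations, write_edf

__all__ = [
    "SynthSpec",
    "STAGES",
    "CHANNEL_RATES",
    "STAGE_SIGNATURES",
    "default_transition_matrix",
    "sample_hypnogram",
    "render_psg",
    "simulate_recording",
]

STAGES = ("W", "N1", "N2", "N3", "REM")

CHANNEL_RATES: dict[str, float] = {
    "C3-A2": 125.0,
    "C4-A1": 125.0,
    "EMG": 125.0,
    "EOG-L": 50.0,
    "EOG-R": 50.0,
}

EPOCH_SECONDS = 30

# One config block for all stage phenomenology.  Amplitudes are RMS relative
# to the unit pink-noise floor and are multiplied by SynthSpec.snr.
STAGE_SIGNATURES = {
    # EEG rhythm band (Hz) and relative amplitude per stage
    "eeg_rhythm": {
        "W": ((8.0, 12.0), 1.0),
        "N1": ((4.0, 7.0), 0.8),
        "N2": ((4.0, 7.0), 0.3),  # mild background theta
        "N3": ((0.5, 2.0), 2.0),  # high-amplitude slow waves
        "REM": ((4.0, 7.0), 0.35),  # low-amplitude mixed frequency
    },
    # N2 spindles: band, bursts per epoch (mean), duration s, rel amplitude
    "spindles": {"band": (11.0, 16.0), "rate": 3.0, "duration": 1.0, "amp": 2.0},
    # EMG bursts: band, mean bursts/epoch per stage, rel amplitude
    "emg_burst_band": (20.0, 45.0),
    "emg_burst_rate": {"W": 6.0, "N1": 3.0, "N2": 1.5, "N3": 0.8, "REM": 0.15},
    "emg_burst_amp": 2.0,
    # tonic EMG level above floor, per stage (scaled by snr; REM atonia)
    "emg_tone": {"W": 1.5, "N1": 0.7, "N2": 0.5, "N3": 0.4, "REM": 0.0},
    # EOG events: (events per epoch, lowpass corner Hz, rel amplitude, mirrored?)
    "eog": {
        "W": (4.0, 2.0, 1.5, False),  # blinks, same polarity
        "N1": (2.0, 0.5, 1.0, True),  # slow rolling movements
        "N2": (0.0, 1.0, 0.0, True),
        "N3": (0.0, 1.0, 0.0, True),
        "REM": (5.0, 1.5, 2.0, True),  # conjugate rapid eye movements
    },
    # slow-wave bleed of N3 EEG activity into the EOG leads (same polarity)
    "eog_n3_bleed": 0.8,
}


def default_transition_matrix(self_prob: float = 0.85) -> np.ndarray:
    """Chain-adjacent hypnogram dynamics over (W, N1, N2, N3, REM).

    Each stage keeps ``self_prob`` and spreads the rest over its neighbours
    in the listed order.
    """
    n = len(STAGES)
    T = np.zeros((n, n))
    for i in range(n):
        neigh = [j for j in (i - 1, i + 1) if 0 <= j < n]
        T[i, i] = self_prob
        for j in neigh:
            T[i, j] = (1.0 - self_prob) / len(neigh)
    return T


@dataclass
class SynthSpec:
    """Parameters of one synthetic recording."""

    n_epochs: int = 100
    seed: int = 0
    snr: float = 3.0
    transition_matrix: np.ndarray = field(
        default_factory=default_transition_matrix
    )

    def __post_init__(self) -> None:
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")
        if self.snr < 0:
            raise ValueError("snr must be nonnegative")
        T = np.asarray(self.transition_matrix, dtype=float)
        if T.shape != (5, 5) or (T < 0).any() or np.abs(T.sum(axis=1) - 1).max() > 1e-9:
            raise ValueError("transition_matrix must be 5x5 row-stochastic")
        self.transition_matrix = T


def sample_hypnogram(spec: SynthSpec) -> np.ndarray:
    """First-order Markov stage sequence, started at W."""
    rng = np.random.default_rng(spec.seed)
    T = spec.transition_matrix
    out = np.empty(spec.n_epochs, dtype=object)
    state = 0
    for i in range(spec.n_epochs):
        out[i] = STAGES[state]
        state = int(rng.choice(5, p=T[state]))
    return out


# ---------------------------------------------------------------------------
# signal rendering
# ---------------------------------------------------------------------------

def _pink_noise(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Unit-variance 1/f-amplitude-shaped noise, rowwise."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz] / freqs[nz][0])
    shaped = np.fft.irfft(spec * scale, n=n, axis=-1)
    sd = shaped.std(axis=-1, keepdims=True)
    return shaped / np.where(sd > 0, sd, 1.0)


def _rhythm(rng, n_rows, n, rate, band, jitter=True):
    """Rowwise sinusoids with per-row random frequency and phase, unit RMS."""
    t = np.arange(n) / rate
    f = rng.uniform(band[0], band[1], size=(n_rows, 1))
    phase = rng.uniform(0, 2 * np.pi, size=(n_rows, 1))
    return np.sqrt(2.0) * np.sin(2 * np.pi * f * t[None, :] + phase)


def _bursts(rng, n_rows, n, rate, band, mean_rate, duration, kind="noise"):
    """Gaussian-windowed oscillatory or noise bursts, unit peak RMS."""
    out = np.zeros((n_rows, n))
    t = np.arange(n) / rate
    counts = rng.poisson(mean_rate, size=n_rows)
    for i in range(n_rows):
        for _ in range(counts[i]):
            c = rng.uniform(0, EPOCH_SECONDS)
            d = max(0.3, rng.normal(duration, 0.2 * duration))
            env = np.exp(-0.5 * ((t - c) / (d / 2.0)) ** 2)
            if kind == "osc":
                f = rng.uniform(band[0], band[1])
                ph = rng.uniform(0, 2 * np.pi)
                out[i] += env * np.sqrt(2.0) * np.sin(2 * np.pi * f * t + ph)
            else:
                x = rng.standard_normal(n)
                out[i] += env * _bandpass(x, rate, band)
    return out


def _bandpass(x: np.ndarray, rate: float, band: tuple[float, float]) -> np.ndarray:
    """FFT brick-wall band-pass, output rescaled to unit variance."""
    n = x.shape[-1]
    spec = np.fft.rfft(x, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    y = np.fft.irfft(spec * mask, n=n, axis=-1)
    sd = y.std(axis=-1, keepdims=True) if y.ndim > 1 else y.std()
    return y / np.where(sd > 0, sd, 1.0) if y.ndim > 1 else (y / sd if sd > 0 else y)


def _eog_events(rng, n_rows, n, rate, n_events, corner, duration=0.6):
    """Slow deflections (sigmoid-ish monophasic waves), unit RMS-ish."""
    out = np.zeros((n_rows, n))
    t = np.arange(n) / rate
    counts = rng.poisson(n_events, size=n_rows)
    width = max(0.15, 0.35 / corner)
    for i in range(n_rows):
        for _ in range(counts[i]):
            c = rng.uniform(0, EPOCH_SECONDS)
            sgn = rng.choice((-1.0, 1.0))
            out[i] += sgn * np.exp(-0.5 * ((t - c) / width) ** 2)
    sd = out.std(axis=-1, keepdims=True)
    return out / np.where(sd > 0, sd, 1.0)


def render_psg(stages: np.ndarray, spec: SynthSpec) -> EpochedRecording:
    """Render stage-dependent multichannel epochs for a hypnogram."""
    rng = np.random.default_rng(spec.seed + 1)  # independent of hypnogram draw
    sig = STAGE_SIGNATURES
    snr = spec.snr
    n_ep = len(stages)
    stages = np.asarray(stages, dtype=object)
    groups = {s: np.flatnonzero(stages == s) for s in STAGES}

    channels: dict[str, ChannelEpochs] = {}
    # EEG channels: independent noise, same class of stage rhythm
    for ch in ("C3-A2", "C4-A1"):
        rate = CHANNEL_RATES[ch]
        n = int(EPOCH_SECONDS * rate)
        data = _pink_noise(rng, (n_ep, n))
        for s, idx in groups.items():
            if len(idx) == 0:
                continue
            band, amp = sig["eeg_rhythm"][s]
            if amp > 0 and snr > 0:
                data[idx] += snr * amp * _rhythm(rng, len(idx), n, rate, band)
            if s == "N2" and snr > 0:
                sp = sig["spindles"]
                data[idx] += snr * sp["amp"] * _bursts(
                    rng, len(idx), n, rate, sp["band"], sp["rate"],
                    sp["duration"], kind="osc",
                )
        channels[ch] = ChannelEpochs(rate=rate, data=data)

    # EMG: constant tonic noise floor; stage effects are bursts and tone
    rate = CHANNEL_RATES["EMG"]
    n = int(EPOCH_SECONDS * rate)
    emg = _pink_noise(rng, (n_ep, n))
    for s, idx in groups.items():
        if len(idx) == 0 or snr == 0:
            continue
        tone = sig["emg_tone"][s]
        if tone > 0:
            white = rng.standard_normal((len(idx), n))
            emg[idx] += snr * tone * _bandpass(white, rate, sig["emg_burst_band"])
        burst_rate = sig["emg_burst_rate"][s]
        if burst_rate > 0:
            emg[idx] += snr * sig["emg_burst_amp"] * _bursts(
                rng, len(idx), n, rate, sig["emg_burst_band"], burst_rate, 0.5
            )
    channels["EMG"] = ChannelEpochs(rate=rate, data=emg)

    # EOG pair: shared event waveform per epoch, mirrored or same-polarity
    rate = CHANNEL_RATES["EOG-L"]
    n = int(EPOCH_SECONDS * rate)
    eog_l = _pink_noise(rng, (n_ep, n))
    eog_r = _pink_noise(rng, (n_ep, n))
    for s, idx in groups.items():
        if len(idx) == 0 or snr == 0:
            continue
        n_events, corner, amp, mirrored = sig["eog"][s]
        if amp > 0 and n_events > 0:
            ev = snr * amp * _eog_events(rng, len(idx), n, rate, n_events, corner)
            eog_l[idx] += ev
            eog_r[idx] += -ev if mirrored else ev
        if s == "N3":
            band, eeg_amp = sig["eeg_rhythm"]["N3"]
            bleed = snr * sig["eog_n3_bleed"]
            sw = bleed * _rhythm(rng, len(idx), n, rate, band)
            eog_l[idx] += sw
            eog_r[idx] += sw
    channels["EOG-L"] = ChannelEpochs(rate=rate, data=eog_l)
    channels["EOG-R"] = ChannelEpochs(rate=rate, data=eog_r)

    return EpochedRecording(channels=channels, stages=stages)


def simulate_recording(
    spec: SynthSpec,
    edf_path=None,
    labels_path=None,
    dialect: str = "csv",
) -> EpochedRecording:
    """Sample a hypnogram, render the PSG, and optionally write EDF + labels."""
    stages = sample_hypnogram(spec)
    rec = render_psg(stages, spec)
    if edf_path is not None:
        signals = {
            name: (ch.rate, ch.data.reshape(-1))
            for name, ch in rec.channels.items()
        }
        write_edf(edf_path, signals)
    if labels_path is not None:
        write_annotations(labels_path, list(stages), dialect=dialect)
    return rec
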