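"""Seeded generator of EEG-like multichannel signals.

Produces signals with controlled spectral structure — band-limited
oscillations, 1/f background, power-line interference, artifact bursts and
a 3 Hz spike-wave "seizure-like" class — so that every downstream stage
(filtering, patching, masking, pretraining, classification) can be
exercised without external recordings.  This is a spectral surrogate, not
forward-modeled EEG: there is no head model or electrode geometry.

All randomness comes from explicit per-call `numpy` generators; identical
seeds give bitwise-identical output.  Component waveforms scale linearly
with their amplitudes, so the noiseless part of a recording is exactly
homogeneous of degree one in the amplitude vector.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .containers import RawRecording, EpochTensor, LabeledEpochSet

__all__ = ["ComponentSpec", "generate_recording", "inject_artifacts",
           "generate_labeled_dataset", "separable_preset", "write_edf",
           "write_raw_binary", "read_raw_binary"]

_KINDS = ("sinusoid", "band-limited-noise", "spike-wave-burst")


@dataclass
class ComponentSpec:
    """One spectral component of a synthetic recording.

    center_freq, bandwidth : Hz; amplitude : microvolts (peak for sinusoid
    and spike-wave, RMS for band-limited noise); channels : indices the
    component is added to (None = all); kind : one of
    'sinusoid', 'band-limited-noise', 'spike-wave-burst'.
    """

    center_freq: float
    amplitude: float
    kind: str = "sinusoid"
    bandwidth: float = 0.0
    channels: tuple[int, ...] | None = None

    def __post_init__(self):
        if self.center_freq <= 0:
            raise ValueError("center_freq must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}")
        if self.channels is not None and len(self.channels) == 0:
            raise ValueError("channels must be non-empty when given")


def _pink_noise(rng: np.random.Generator, n_channels: int, n: int,
                exponent: float, fs: float) -> np.ndarray:
    """1/f^exponent noise via frequency-domain shaping, unit variance."""
    white = rng.standard_normal((n_channels, n))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shaping = np.ones_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    shaping[0] = 0.0                      # no DC drift
    shaped = np.fft.irfft(spec * shaping, n=n, axis=-1)
    std = shaped.std(axis=-1, keepdims=True)
    std[std == 0] = 1.0
    return shaped / std


def _spike_wave_cycle(f: float, fs: float) -> np.ndarray:
    """One spike-and-slow-wave cycle, unit peak amplitude."""
    n_cycle = max(int(round(fs / f)), 4)
    t = np.arange(n_cycle) / n_cycle      # phase within the cycle
    spike = np.exp(-0.5 * ((t - 0.1) / 0.03) ** 2)
    slow = 0.6 * np.sin(np.pi * np.clip((t - 0.2) / 0.75, 0.0, 1.0))
    return spike - slow


def _component_waveform(spec: ComponentSpec, n_channels: int, n: int,
                        fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-amplitude waveform per channel; caller scales by spec.amplitude."""
    chans = (np.arange(n_channels) if spec.channels is None
             else np.asarray(spec.channels))
    if np.any(chans >= n_channels):
        raise ValueError("component references a channel beyond the recording")
    t = np.arange(n) / fs
    out = np.zeros((n_channels, n))
    if spec.kind == "sinusoid":
        # one phase per component, shared across channels: scalp oscillations
        # are spatially coherent, which also makes masked channels inferable
        phase = rng.uniform(0, 2 * np.pi)
        wave = np.sin(2 * np.pi * spec.center_freq * t + phase)
        out[chans] = wave
    elif spec.kind == "band-limited-noise":
        lo = max(spec.center_freq - spec.bandwidth / 2.0, 0.0)
        hi = spec.center_freq + spec.bandwidth / 2.0
        white = rng.standard_normal((len(chans), n))
        F = np.fft.rfft(white, axis=-1)
        freqs = np.fft.rfftfreq(n, 1.0 / fs)
        F[:, (freqs < lo) | (freqs > hi)] = 0.0
        band = np.fft.irfft(F, n=n, axis=-1)
        rms = band.std(axis=-1, keepdims=True)
        rms[rms == 0] = 1.0
        out[chans] = band / rms           # unit RMS
    else:                                 # spike-wave-burst
        cycle = _spike_wave_cycle(spec.center_freq, fs)
        n_cycle = len(cycle)
        reps = int(np.ceil(n / n_cycle)) + 1
        train = np.tile(cycle, reps)
        # generalized spike-wave discharges are synchronous across channels
        off = int(rng.integers(0, n_cycle))
        out[chans] = train[off:off + n]
    return out


def generate_recording(specs: list[ComponentSpec], n_channels: int,
                       duration_s: float, fs: float,
                       noise_exponent: float = 1.0, noise_amp: float = 5.0,
                       seed: int | np.random.Generator = 0) -> RawRecording:
    """Synthesize a recording: 1/f background plus the listed components.

    `noise_amp` is the standard deviation of the background in microvolts.
    Output shape is (n_channels, duration_s * fs); `duration_s * fs` must be
    a whole number of samples.
    """
    if fs <= 0 or duration_s <= 0:
        raise ValueError(
            f"fs and duration must be positive, got fs={fs}, duration={duration_s}")
    n_float = duration_s * fs
    n = int(round(n_float))
    if abs(n_float - n) > 1e-9 or n < 1:
        raise ValueError(f"duration_s*fs must be an integer >= 1, got {n_float}")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    data = noise_amp * _pink_noise(rng, n_channels, n, noise_exponent, fs)
    for spec in specs:
        data = data + spec.amplitude * _component_waveform(
            spec, n_channels, n, fs, rng)
    return RawRecording(data=data, fs=fs,
                        channel_names=[f"CH{i}" for i in range(n_channels)])


def inject_artifacts(rec: RawRecording, line_freq: float = 50.0,
                     line_amp: float = 0.0,
                     burst_band: tuple[float, float] = (20.0, 60.0),
                     burst_rate: float = 0.0, burst_amp: float = 20.0,
                     burst_duration_s: float = 0.5,
                     seed: int = 0) -> RawRecording:
    """Add power-line interference and short broadband artifact bursts.

    `burst_rate` is in events per minute; each event is a Hann-windowed
    band-limited noise burst across all channels.
    """
    nyq = rec.fs / 2.0
    if line_freq >= nyq:
        raise ValueError(f"line frequency {line_freq} at or above Nyquist {nyq}")
    if burst_band[0] >= burst_band[1] or burst_band[1] >= nyq:
        raise ValueError(f"burst band {burst_band} outside (0, Nyquist)")
    rng = np.random.default_rng(seed)
    n = rec.n_samples
    t = np.arange(n) / rec.fs
    data = rec.data.copy()
    phase = rng.uniform(0, 2 * np.pi)
    data += line_amp * np.sin(2 * np.pi * line_freq * t + phase)[None, :]
    n_events = rng.poisson(burst_rate * rec.duration_s / 60.0)
    burst_len = int(round(burst_duration_s * rec.fs))
    for _ in range(n_events):
        start = int(rng.integers(0, max(n - burst_len, 1)))
        spec = ComponentSpec(center_freq=(burst_band[0] + burst_band[1]) / 2.0,
                             bandwidth=burst_band[1] - burst_band[0],
                             amplitude=1.0, kind="band-limited-noise")
        noise = _component_waveform(spec, rec.n_channels, burst_len, rec.fs, rng)
        window = np.hanning(burst_len)
        data[:, start:start + burst_len] += burst_amp * noise * window
    return RawRecording(data=data, fs=rec.fs,
                        channel_names=list(rec.channel_names))


def _class_seed(seed: int, name: str) -> np.random.Generator:
    # stable per-class stream: signals depend on (seed, class name), not on
    # the position of the class in the mapping
    digest = hashlib.sha256(name.encode()).digest()
    sub = int.from_bytes(digest[:4], "little")
    return np.random.default_rng([int(seed), sub])


def generate_labeled_dataset(n_per_class: int,
                             class_specs: dict[str, list[ComponentSpec]],
                             fs: float = 200.0, win_s: float = 4.0,
                             n_channels: int = 4, noise_amp: float = 5.0,
                             noise_exponent: float = 1.0,
                             seed: int = 0) -> LabeledEpochSet:
    """A labeled epoch set with `n_per_class` windows per class.

    Each epoch is an independent recording of length `win_s` synthesized
    from its class's component list on top of 1/f background noise.  The
    per-class signal stream depends on (seed, class name) only, so
    reordering the class mapping permutes labels without changing signals.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be at least 1")
    if len(class_specs) < 2:
        raise ValueError("need at least two classes")
    epochs: list[EpochTensor] = []
    labels: list[int] = []
    names = list(class_specs)
    for label, name in enumerate(names):
        rng = _class_seed(seed, name)
        for _ in range(n_per_class):
            rec = generate_recording(class_specs[name], n_channels, win_s, fs,
                                     noise_exponent, noise_amp, seed=rng)
            epochs.append(EpochTensor(rec.data, fs, rec.channel_names))
            labels.append(label)
    return LabeledEpochSet(epochs, np.asarray(labels), names)


def separable_preset() -> dict[str, list[ComponentSpec]]:
    """Two classes with disjoint dominant bands.

    'spike_wave': a 3 Hz spike-and-wave discharge (absence-seizure
    surrogate); 'alpha': a 10 Hz oscillation.  A bandpower threshold on the
    two bands separates them near-perfectly, which anchors the end-to-end
    classification checks.
    """
    return {
        "spike_wave": [ComponentSpec(center_freq=3.0, amplitude=50.0,
                                     kind="spike-wave-burst")],
        "alpha": [ComponentSpec(center_freq=10.0, amplitude=30.0,
                                kind="sinusoid")],
    }


# -- writers -----------------------------------------------------------------

def write_edf(rec: RawRecording, path: str | Path) -> None:
    """Write a recording as 16-bit EDF with physical dimension uV.

    Minimal single-record EDF (one data record spanning the recording);
    readable by standard EDF readers.
    """
    path = Path(path)
    data = rec.data
    n_sig = rec.n_channels
    n_samp = rec.n_samples
    phys_max = max(np.abs(data).max(), 1e-6)
    dig_max = 32767
    scaled = np.clip(np.round(data / phys_max * dig_max), -dig_max, dig_max
                     ).astype("<i2")

    def f(text: str, width: int) -> bytes:
        return text[:width].ljust(width).encode("ascii")

    record_dur = n_samp / rec.fs
    header = b"".join([
        f("0", 8), f("X X X X", 80), f("X X X X", 80),
        f("01.01.00", 8), f("00.00.00", 8),
        f(str(256 * (n_sig + 1)), 8), f("", 44), f("1", 8),
        f(f"{record_dur:g}", 8), f(str(n_sig), 4),
    ])
    sig_header = b"".join([
        b"".join(f(name, 16) for name in rec.channel_names),
        b"".join(f("synthetic", 80) for _ in range(n_sig)),
        b"".join(f("uV", 8) for _ in range(n_sig)),
        b"".join(f(f"{-phys_max:.6g}"[:8], 8) for _ in range(n_sig)),
        b"".join(f(f"{phys_max:.6g}"[:8], 8) for _ in range(n_sig)),
        b"".join(f(str(-dig_max), 8) for _ in range(n_sig)),
        b"".join(f(str(dig_max), 8) for _ in range(n_sig)),
        b"".join(f("", 80) for _ in range(n_sig)),
        b"".join(f(str(n_samp), 8) for _ in range(n_sig)),
        b"".join(f("", 32) for _ in range(n_sig)),
    ])
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        fh.write(scaled.tobytes())


def write_raw_binary(rec: RawRecording, path: str | Path) -> None:
    """Flat float32 binary plus a JSON header sidecar."""
    path = Path(path)
    rec.data.astype("<f4").tofile(path)
    sidecar = {"fs": rec.fs, "channel_names": rec.channel_names,
               "shape": list(rec.data.shape), "dtype": "<f4", "unit": "uV"}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_raw_binary(path: str | Path) -> RawRecording:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    data = np.fromfile(path, dtype=meta["dtype"]).reshape(meta["shape"])
    return RawRecording(data=np.asarray(data, dtype=np.float64),
                        fs=meta["fs"], channel_names=meta["channel_names"])
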