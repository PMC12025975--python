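"""EEG preprocessing: channel selection, filtering, resampling, epoching.

The default recipe mirrors common clinical-EEG practice: 0.1-75 Hz
band-pass, 50 Hz notch, resampling to 200 Hz, non-overlapping 4 s windows,
amplitudes in microvolts.  Filtering is zero-phase (forward-backward
4th-order Butterworth band-pass plus a Q=30 IIR notch) so that phase
structure — which the masked-reconstruction objective must recover — is
preserved.  Resampling is polyphase with anti-aliasing and honors the
exact sample-count contract n_out = round(n_in * target_fs / fs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import yaml
from scipy import signal as sps

from .containers import RawRecording, EpochTensor, LabeledEpochSet

__all__ = ["PreprocessConfig", "select_channels", "bandpass_notch", "resample",
           "epoch", "augment", "balance_classes", "run_pipeline",
           "read_edf", "save_epochs", "load_epochs"]


@dataclass
class PreprocessConfig:
    """Preprocessing recipe; defaults follow the pretraining pipeline."""

    band: tuple[float, float] = (0.1, 75.0)
    notch: float | None = 50.0
    target_fs: float = 200.0
    win_s: float = 4.0
    channel_order: list[str] | None = None
    p_reflect: float = 0.0
    scale_range: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self):
        low, high = self.band
        if not (0 <= low < high < self.target_fs / 2):
            raise ValueError(
                f"band {self.band} must satisfy 0 <= low < high < target_fs/2")
        if self.notch is not None and self.notch >= self.target_fs / 2:
            raise ValueError("notch frequency at or above Nyquist")
        if self.win_s <= 0:
            raise ValueError("window length must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PreprocessConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "band" in raw:
            raw["band"] = tuple(raw["band"])
        if "scale_range" in raw:
            raw["scale_range"] = tuple(raw["scale_range"])
        return cls(**raw)


def select_channels(rec: RawRecording, channel_order: list[str]) -> RawRecording:
    """Keep and reorder channels according to `channel_order`."""
    index = {name: i for i, name in enumerate(rec.channel_names)}
    missing = [c for c in channel_order if c not in index]
    if missing:
        raise KeyError(f"channels not present in recording: {missing}")
    rows = [index[c] for c in channel_order]
    return RawRecording(rec.data[rows].copy(), rec.fs, list(channel_order))


def bandpass_notch(rec: RawRecording, band: tuple[float, float],
                   notch: float | None = 50.0, notch_q: float = 30.0
                   ) -> RawRecording:
    """Zero-phase band-pass (4th-order Butterworth) plus optional notch."""
    low, high = band
    nyq = rec.fs / 2.0
    if not (0 <= low < high):
        raise ValueError(f"band must satisfy low < high, got {band}")
    if high >= nyq:
        raise ValueError(f"band edge {high} at or above Nyquist {nyq}")
    data = rec.data
    if low > 0:
        sos = sps.butter(4, [low, high], btype="bandpass", fs=rec.fs,
                         output="sos")
    else:
        sos = sps.butter(4, high, btype="lowpass", fs=rec.fs, output="sos")
    data = sps.sosfiltfilt(sos, data, axis=-1)
    if notch is not None:
        if notch >= nyq:
            raise ValueError(f"notch {notch} at or above Nyquist {nyq}")
        b, a = sps.iirnotch(notch, notch_q, fs=rec.fs)
        data = sps.filtfilt(b, a, data, axis=-1)
    return RawRecording(np.ascontiguousarray(data), rec.fs,
                        list(rec.channel_names))


def resample(rec: RawRecording, target_fs: float) -> RawRecording:
    """Polyphase resampling; output length is round(n * target_fs / fs)."""
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    if math.isclose(target_fs, rec.fs):
        return RawRecording(rec.data.copy(), rec.fs, list(rec.channel_names))
    frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
    out = sps.resample_poly(rec.data, frac.numerator, frac.denominator, axis=-1)
    n_out = int(round(rec.n_samples * target_fs / rec.fs))
    if out.shape[-1] > n_out:
        out = out[..., :n_out]
    elif out.shape[-1] < n_out:
        pad = n_out - out.shape[-1]
        out = np.pad(out, [(0, 0)] * (out.ndim - 1) + [(0, pad)], mode="edge")
    return RawRecording(out, target_fs, list(rec.channel_names))


def epoch(rec: RawRecording, win_s: float) -> list[EpochTensor]:
    """Consecutive non-overlapping windows; a short trailing remainder is
    dropped; a recording shorter than one window yields an empty list."""
    samples = win_s * rec.fs
    n_win = int(round(samples))
    if abs(samples - n_win) > 1e-9:
        raise ValueError(f"win_s*fs must be integral, got {samples}")
    n_epochs = rec.n_samples // n_win
    return [EpochTensor(rec.data[:, k * n_win:(k + 1) * n_win].copy(),
                        rec.fs, list(rec.channel_names))
            for k in range(n_epochs)]


def augment(ep: EpochTensor, p_reflect: float = 0.5,
            scale_range: tuple[float, float] = (0.8, 1.2),
            seed: int = 0) -> EpochTensor:
    """Random time reflection and amplitude scaling."""
    if not 0.0 <= p_reflect <= 1.0:
        raise ValueError("p_reflect must lie in [0, 1]")
    lo, hi = scale_range
    if not 0 < lo <= hi:
        raise ValueError("scale_range must satisfy 0 < lo <= hi")
    rng = np.random.default_rng(seed)
    s = rng.uniform(lo, hi)
    reflect = rng.random() < p_reflect
    data = ep.data[:, ::-1] if reflect else ep.data
    return EpochTensor(s * data.copy(), ep.fs, list(ep.channel_names))


def balance_classes(dataset: LabeledEpochSet, ratio: float = 1.0,
                    seed: int = 0) -> LabeledEpochSet:
    """Subsample majority classes toward `ratio` times the minority count.

    ratio 1.0 gives a 1:1 class balance.  Membership is unchanged when the
    set already satisfies the ratio.
    """
    counts = np.bincount(dataset.labels, minlength=len(dataset.class_names))
    if np.any(counts == 0):
        empty = [dataset.class_names[i] for i in np.flatnonzero(counts == 0)]
        raise ValueError(f"cannot balance: empty classes {empty}")
    rng = np.random.default_rng(seed)
    target = int(round(counts.min() * ratio))
    keep: list[np.ndarray] = []
    for cls in range(len(counts)):
        idx = np.flatnonzero(dataset.labels == cls)
        if len(idx) > target:
            idx = np.sort(rng.choice(idx, size=target, replace=False))
        keep.append(idx)
    order = np.sort(np.concatenate(keep))
    return dataset.subset(order)


def run_pipeline(rec: RawRecording, cfg: PreprocessConfig) -> list[EpochTensor]:
    """Apply the full recipe: select, filter, resample, epoch."""
    if cfg.channel_order:
        rec = select_channels(rec, cfg.channel_order)
    rec = bandpass_notch(rec, cfg.band, cfg.notch)
    rec = resample(rec, cfg.target_fs)
    return epoch(rec, cfg.win_s)


# -- I/O ---------------------------------------------------------------------

def read_edf(path: str | Path) -> RawRecording:
    """Read an EDF file into a recording in microvolts (via mne)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6           # mne returns volts
    return RawRecording(data=data, fs=float(raw.info["sfreq"]),
                        channel_names=list(raw.ch_names))


def save_epochs(path: str | Path, epochs: np.ndarray, labels: np.ndarray,
                fs: float, channel_names: list[str]) -> None:
    """Write an (n, C, T) epoch stack to an HDF5 container."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("epochs", data=np.asarray(epochs, dtype=np.float32))
        f.create_dataset("labels", data=np.asarray(labels, dtype=np.int64))
        f.attrs["fs"] = float(fs)
        f.create_dataset("channel_names",
                         data=np.array(channel_names, dtype="S"))


def load_epochs(path: str | Path):
    import h5py

    with h5py.File(path, "r") as f:
        epochs = np.asarray(f["epochs"], dtype=np.float64)
        labels = np.asarray(f["labels"])
        fs = float(f.attrs["fs"])
        names = [s.decode() for s in f["channel_names"][()]]
    return epochs, labels, fs, names
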