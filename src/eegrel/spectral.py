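"""Short-time Fourier spectrogram with the pipeline's windowing conventions.

The spectrogram S(l, k) is the squared magnitude of the windowed DFT of
frame l at frequency bin k.  Default configuration: a 2.9 s Gaussian
window (503 samples at 173.61 Hz) with 40 % overlap between consecutive
frames, i.e. hop = round(W * 0.6).  The Gaussian sigma is W/6 so the
window is effectively supported within +/- 3 sigma; the DFT length is
the next power of two >= W (zero-padded).  Power is stored one-sided;
the log nonlinearity belongs to the downstream filterbank stage, not
here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sig
from scipy.fft import rfft, rfftfreq

from .exceptions import InsufficientLengthError, WindowTooShortError
from .io import EegSegment


@dataclass(frozen=True)
class StftConfig:
    """Windowing configuration of the short-time transform.

    ``overlap_fraction`` is the fraction of the window shared by
    consecutive frames (0.40 by default), so the hop is
    ``round(W * (1 - overlap_fraction))``.
    """

    window_seconds: float = 2.9
    overlap_fraction: float = 0.40
    window_kind: str = "gaussian"
    gaussian_sigma_fraction: float = 1.0 / 6.0
    n_fft: int | None = None  # next power of two >= window when None
    detrend: bool = False  # per-frame mean removal, off by default

    def __post_init__(self) -> None:
        if not self.window_seconds > 0:
            raise ValueError("window_seconds must be positive")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1)")


@dataclass
class Spectrogram:
    """Time x frequency power matrix with its axes.

    ``power[l, k]`` is the squared DFT magnitude of frame ``l`` at bin
    ``k``; ``times`` are frame centers in seconds; ``freqs`` are one-sided
    bin centers in Hz.
    """

    power: np.ndarray  # (n_frames, n_bins), >= 0
    times: np.ndarray  # (n_frames,)
    freqs: np.ndarray  # (n_bins,)
    fs: float
    config: StftConfig = field(default_factory=StftConfig)

    @property
    def n_frames(self) -> int:
        return self.power.shape[0]

    @property
    def n_bins(self) -> int:
        return self.power.shape[1]


def window_samples(config: StftConfig, fs: float) -> int:
    """Window length in samples: ``round(window_seconds * fs)``.

    2.9 s at 173.61 Hz resolves to 503 samples.
    """
    if not fs > 0:
        raise ValueError("fs must be positive")
    w = int(round(config.window_seconds * fs))
    if w < 8:
        raise WindowTooShortError(
            f"window of {config.window_seconds} s at {fs} Hz is only {w} samples"
        )
    return w


def hop_samples(config: StftConfig, fs: float) -> int:
    """Frame advance in samples: ``round(W * (1 - overlap_fraction))``."""
    w = window_samples(config, fs)
    return max(1, int(round(w * (1.0 - config.overlap_fraction))))


def _make_window(config: StftConfig, w: int) -> np.ndarray:
    kind = config.window_kind.lower()
    if kind == "gaussian":
        return sig.windows.gaussian(w, std=config.gaussian_sigma_fraction * w)
    return sig.get_window(kind, w, fftbins=True)


def compute_spectrogram(segment: EegSegment, config: StftConfig | None = None) -> Spectrogram:
    """Short-time power spectrogram of a segment.

    The number of frames is ``1 + floor((N - W) / hop)``; trailing samples
    that do not fill a window are dropped.  Raises when the segment is
    shorter than one window.
    """
    config = config or StftConfig()
    fs = segment.fs
    w = window_samples(config, fs)
    hop = hop_samples(config, fs)
    x = segment.samples
    if x.size < w:
        raise InsufficientLengthError(
            f"segment of {x.size} samples is shorter than one {w}-sample window"
        )
    n_fft = config.n_fft or int(2 ** np.ceil(np.log2(w)))
    if n_fft < w:
        raise ValueError(f"n_fft={n_fft} shorter than window ({w} samples)")
    win = _make_window(config, w)
    n_frames = 1 + (x.size - w) // hop
    starts = hop * np.arange(n_frames)
    frames = np.stack([x[s : s + w] for s in starts])
    if config.detrend:
        frames = frames - frames.mean(axis=1, keepdims=True)
    spec = np.abs(rfft(frames * win, n=n_fft, axis=1)) ** 2
    times = (starts + (w - 1) / 2.0) / fs
    freqs = rfftfreq(n_fft, d=1.0 / fs)
    return Spectrogram(power=spec, times=times, freqs=freqs, fs=fs, config=config)


def spectrogram_to_csv(spec: Spectrogram, path) -> None:
    """Export as CSV with a frequency header row and a time header column."""
    import pandas as pd

    df = pd.DataFrame(spec.power, index=spec.times, columns=spec.freqs)
    df.index.name = "time_s"
    df.columns.name = "freq_hz"
    df.to_csv(path)
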