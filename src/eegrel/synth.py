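"""Surrogate EEG generator with controllable per-rhythm band power.

Each segment is a sum of band-limited Gaussian noise components, one per
rhythm band (delta, theta, alpha, beta), plus broadband white noise and an
optional power-line sinusoid.  Two features of real scalp/depth EEG that
matter to downstream relevance analysis are emulated explicitly:

* **Class-dependent spectral profiles.**  Relative band powers are set per
  class; presets ship for ``normal`` (dominant alpha with appreciable
  wakeful beta), ``ictal`` (elevated delta/theta power and roughly
  three-fold larger amplitude, as in rhythmic seizure discharges) and
  ``interictal`` (intermediate).
* **Waxing and waning of dominant rhythms.**  Each band component is
  amplitude-modulated by a slow lognormal envelope whose log-depth scales
  with the band's share of total power: prominent rhythms (posterior alpha
  in relaxed wakefulness, delta–theta bursting during seizures) fluctuate
  strongly within a recording while background bands stay near the
  broadband floor.  This within-segment non-stationarity is precisely what
  a short-time relevance analysis is built to pick up; without it the
  generated rhythms would be indistinguishable stationary noises.

Generation is fully deterministic given a seed.  Within each segment,
every band's target power is realized exactly (components are rescaled to
their nominal share), so the configured relative band-power profile is
recoverable from a Welch periodogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as sig

from .exceptions import AliasingError, ConfigError
from .io import DEFAULT_FS, DatasetManifest, EegSegment, ManifestEntry, write_manifest, write_segment

#: Canonical rhythm bands (Hz).  The delta lower edge is 0 by convention.
RHYTHM_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (14.0, 30.0),
}

BAND_ORDER = tuple(RHYTHM_BANDS)


@dataclass(frozen=True)
class ClassProfile:
    """Relative band powers and overall amplitude for one class preset."""

    band_power: Mapping[str, float]
    amplitude_scale: float  # microvolts (RMS of the rhythm mixture)


#: Named class presets.  The seizure state concentrates power below 8 Hz at
#: about three-fold amplitude; the normal state is alpha-dominant with
#: appreciable wakeful beta; interictal sits between the two.  Magnitudes
#: are this package's own calibration of those qualitative profiles.
CLASS_PRESETS: dict[str, ClassProfile] = {
    "normal": ClassProfile({"delta": 0.8, "theta": 1.0, "alpha": 4.0, "beta": 3.0}, 50.0),
    "interictal": ClassProfile({"delta": 2.5, "theta": 2.0, "alpha": 1.5, "beta": 0.8}, 80.0),
    "ictal": ClassProfile({"delta": 5.0, "theta": 4.0, "alpha": 1.0, "beta": 0.4}, 150.0),
}
# Bonn-style subset tags map onto the state presets.
CLASS_PRESETS.update(
    {
        "A": CLASS_PRESETS["normal"],
        "B": CLASS_PRESETS["normal"],
        "C": CLASS_PRESETS["interictal"],
        "D": CLASS_PRESETS["interictal"],
        "E": CLASS_PRESETS["ictal"],
    }
)


@dataclass
class SynthSpec:
    """Configuration of a surrogate dataset.

    Parameters
    ----------
    fs, duration:
        Sampling rate (Hz) and segment duration (s).  Defaults mirror the
        public single-channel epilepsy collection: 23.6 s at 173.61 Hz,
        which resolves to ``floor(duration * fs)`` = 4097 samples.
    n_segments:
        Segments generated per class (default 100).
    profiles:
        Map class tag -> :class:`ClassProfile`; defaults to
        :data:`CLASS_PRESETS`.
    noise_sd:
        White-noise standard deviation relative to the class amplitude scale.
    line_amp, line_freq:
        Amplitude (same relative units) and frequency of an additive
        power-line sinusoid; 60 Hz by default, off (0 amplitude) by default.
    mod_depth:
        Log-envelope depth multiplier; a band holding share ``s`` of total
        power gets a slow lognormal power envelope with log-sd
        ``mod_depth * s``.
    mod_cutoff:
        Low-pass cutoff (Hz) of the envelope noise, i.e. how fast rhythms
        wax and wane.
    seed:
        Base seed for the whole dataset.
    """

    fs: float = DEFAULT_FS
    duration: float = 23.6
    n_segments: int = 100
    profiles: Mapping[str, ClassProfile] = field(default_factory=lambda: dict(CLASS_PRESETS))
    noise_sd: float = 0.15
    line_amp: float = 0.0
    line_freq: float = 60.0
    mod_depth: float = 2.5
    mod_cutoff: float = 0.3
    filter_order: int = 8  # sharp band edges keep skirt leakage small
    seed: int = 0

    @property
    def n_samples(self) -> int:
        """Samples per segment: ``floor(duration * fs)`` (4097 at the defaults)."""
        return int(np.floor(self.duration * self.fs))


def _band_component(n: int, fs: float, lo: float, hi: float, order: int,
                    sigma_log: float, cutoff: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise with slow power modulation.

    White noise is amplitude-modulated by the slow lognormal envelope
    *before* the zero-phase Butterworth band filter, so the component
    stays strictly band-confined while its short-time power still waxes
    and wanes on the envelope timescale.
    """
    white = rng.standard_normal(n)
    env = _slow_envelope(n, fs, sigma_log, cutoff, rng)
    nyq = fs / 2.0
    if lo <= 0.0:
        sos = sig.butter(order, hi / nyq, btype="lowpass", output="sos")
    else:
        sos = sig.butter(order, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    comp = sig.sosfiltfilt(sos, white * np.sqrt(env))
    rms = np.sqrt(np.mean(comp**2))
    return comp / rms if rms > 0 else comp


def _slow_envelope(n: int, fs: float, sigma_log: float, cutoff: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Lognormal power envelope from low-passed white noise, unit log-sd scale."""
    white = rng.standard_normal(n)
    sos = sig.butter(2, cutoff / (fs / 2.0), btype="lowpass", output="sos")
    slow = sig.sosfiltfilt(sos, white)
    sd = slow.std()
    if sd > 0:
        slow = slow / sd
    # bound the modulator: physiological waxing/waning is strong but finite,
    # and an unbounded lognormal tail would collapse a segment into one burst
    slow = np.clip(slow, -1.5, 1.5)
    return np.exp(sigma_log * slow)


def generate_segment(
    spec: SynthSpec,
    class_tag: str,
    seed: int | np.random.SeedSequence,
) -> EegSegment:
    """Generate one surrogate segment for ``class_tag``.

    The segment is the sum over bands of envelope-modulated band-limited
    noise with exact per-band power shares, plus white noise and the
    optional line sinusoid, all scaled by the class amplitude.
    """
    if class_tag not in spec.profiles:
        raise ConfigError(f"no band-power profile for class {class_tag!r}")
    profile = spec.profiles[class_tag]
    for band, power in profile.band_power.items():
        if power < 0:
            raise ConfigError(f"negative band power for {band}")
        if power > 0 and RHYTHM_BANDS[band][1] >= spec.fs / 2.0:
            raise AliasingError(
                f"band {band} upper edge {RHYTHM_BANDS[band][1]} Hz needs "
                f"fs > {2 * RHYTHM_BANDS[band][1]} Hz, got {spec.fs}"
            )

    rng = np.random.default_rng(seed)
    n = spec.n_samples
    total = float(sum(profile.band_power.values()))
    x = np.zeros(n)
    for band in BAND_ORDER:
        power = float(profile.band_power.get(band, 0.0))
        if power <= 0 or total <= 0:
            continue
        share = power / total
        lo, hi = RHYTHM_BANDS[band]
        comp = _band_component(
            n, spec.fs, lo, hi, spec.filter_order,
            spec.mod_depth * share, spec.mod_cutoff, rng,
        )
        x += np.sqrt(share) * comp
    x *= profile.amplitude_scale
    if spec.noise_sd > 0:
        x = x + spec.noise_sd * profile.amplitude_scale * rng.standard_normal(n)
    if spec.line_amp > 0:
        if spec.line_freq >= spec.fs / 2.0:
            raise AliasingError(
                f"line frequency {spec.line_freq} Hz at or above Nyquist ({spec.fs / 2} Hz)"
            )
        t = np.arange(n) / spec.fs
        x = x + spec.line_amp * profile.amplitude_scale * np.sin(
            2 * np.pi * spec.line_freq * t
        )
    seed_repr = seed.entropy if isinstance(seed, np.random.SeedSequence) else seed
    return EegSegment(x, fs=spec.fs, label=class_tag,
                      segment_id=f"{class_tag}-{seed_repr}")


def generate_dataset(
    spec: SynthSpec,
    classes: Sequence[str],
    out_dir: str | Path | None = None,
) -> tuple[DatasetManifest, list[EegSegment]]:
    """Generate ``spec.n_segments`` segments per class.

    Per-segment seeds are spawned deterministically from ``spec.seed``.
    When ``out_dir`` is given, segments are written as one-sample-per-line
    text files next to a ``manifest.yaml``.
    """
    if len(set(classes)) != len(classes):
        raise ConfigError(f"duplicate class labels in {list(classes)}")
    if spec.n_segments < 1:
        raise ConfigError("n_segments must be >= 1")

    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(len(classes) * spec.n_segments)
    segments: list[EegSegment] = []
    entries: list[ManifestEntry] = []
    idx = 0
    for tag in classes:
        for j in range(spec.n_segments):
            seg = generate_segment(spec, tag, children[idx])
            seg.segment_id = f"{tag}{j:03d}"
            idx += 1
            segments.append(seg)
            entries.append(
                ManifestEntry(
                    path=f"{seg.segment_id}.txt",
                    label=tag,
                    fs=spec.fs,
                    segment_id=seg.segment_id,
                )
            )
    manifest = DatasetManifest(
        entries=entries,
        note=f"synthetic dataset, seed={spec.seed}, {spec.n_segments} segments/class",
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for seg, entry in zip(segments, entries):
            write_segment(seg, out / entry.path)
        write_manifest(manifest, out / "manifest.yaml")
    return manifest, segments


def band_power_fractions(
    samples: np.ndarray, fs: float, f_total: tuple[float, float] = (0.0, 40.0)
) -> dict[str, float]:
    """Welch-periodogram power fraction of each rhythm band within ``f_total``.

    Diagnostic used to verify that generated segments realize their
    configured spectral profile.
    """
    nper = min(len(samples), int(4 * fs))
    freqs, psd = sig.welch(samples, fs=fs, nperseg=nper)
    in_total = (freqs >= f_total[0]) & (freqs <= f_total[1])
    total = np.trapezoid(psd[in_total], freqs[in_total])
    out = {}
    for band, (lo, hi) in RHYTHM_BANDS.items():
        m = (freqs >= lo) & (freqs <= hi)
        out[band] = float(np.trapezoid(psd[m], freqs[m]) / total) if total > 0 else 0.0
    return out
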