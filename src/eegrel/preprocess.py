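"""Band-limiting and amplitude normalization of EEG segments.

The experimental protocol filters every recording to the 0–40 Hz range
and then rescales it by its own greatest absolute value, so that each
segment's amplitude lies in [-1, 1] with max |x| = 1 exactly.  Filtering
uses a zero-phase Butterworth (applied forward and backward), the
standard choice in EEG work because it preserves waveform morphology.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sig

from .exceptions import DegenerateSignalError, InvalidBandError
from .io import EegSegment


def bandlimit(
    segment: EegSegment,
    f_lo: float = 0.0,
    f_hi: float = 40.0,
    order: int = 4,
) -> EegSegment:
    """Zero-phase Butterworth band limit to [f_lo, f_hi] Hz.

    ``f_lo = 0`` (the default) degenerates to a pure low-pass, matching a
    literal 0 Hz lower band edge; set ``f_lo`` to e.g. 0.5 Hz to also
    remove drift.  Output has identical length and no group delay; the
    forward-backward pass doubles the effective order, giving >= 40 dB
    attenuation one octave above the cutoff at the default order.
    """
    nyq = segment.fs / 2.0
    if not (0.0 <= f_lo < f_hi):
        raise InvalidBandError(f"need 0 <= f_lo < f_hi, got [{f_lo}, {f_hi}]")
    if f_hi >= nyq:
        raise InvalidBandError(
            f"upper edge {f_hi} Hz must lie below Nyquist ({nyq} Hz)"
        )
    if f_lo <= 0.0:
        sos = sig.butter(order, f_hi / nyq, btype="lowpass", output="sos")
    else:
        sos = sig.butter(order, [f_lo / nyq, f_hi / nyq], btype="bandpass", output="sos")
    return segment.with_samples(sig.sosfiltfilt(sos, segment.samples))


def normalize_amplitude(segment: EegSegment) -> EegSegment:
    """Divide by the greatest absolute sample value.

    Idempotent and scale-invariant; the result satisfies
    ``max |samples| == 1`` to machine precision.  Undefined (and raising)
    on an all-zero segment.
    """
    peak = float(np.max(np.abs(segment.samples)))
    if peak == 0.0:
        raise DegenerateSignalError(
            "cannot amplitude-normalize an all-zero segment"
        )
    return segment.with_samples(segment.samples / peak)


def preprocess_segment(
    segment: EegSegment,
    f_lo: float = 0.0,
    f_hi: float = 40.0,
    order: int = 4,
) -> EegSegment:
    """Standard preprocessing chain: band limit, then amplitude-normalize."""
    return normalize_amplitude(bandlimit(segment, f_lo=f_lo, f_hi=f_hi, order=order))
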