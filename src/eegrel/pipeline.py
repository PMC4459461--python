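"""Glue between stages: segments -> preprocessed -> spectrogram -> features."""

from __future__ import annotations

from typing import Sequence

from .features import (
    ObservationMatrix,
    RhythmBand,
    assemble_observations,
    build_filterbank,
    default_bands,
    extract_rhythm_series,
)
from .io import EegSegment
from .preprocess import preprocess_segment
from .spectral import StftConfig, compute_spectrogram


def extract_observation_matrix(
    segments: Sequence[EegSegment],
    stft: StftConfig | None = None,
    bands: Sequence[RhythmBand] | None = None,
    n_filt: int = 5,
    n_M: int = 5,
    f_lo: float = 0.0,
    f_hi: float = 40.0,
    preprocess: bool = True,
) -> ObservationMatrix:
    """Run the feature chain on a list of segments and stack the results.

    Every segment is band-limited to [f_lo, f_hi], amplitude-normalized,
    transformed to its short-time spectrogram and reduced to per-rhythm
    cepstral trajectories; the filterbank is built once on the first
    spectrogram's frequency grid (all segments must share fs and length).
    """
    stft = stft or StftConfig()
    bands = list(bands) if bands is not None else default_bands(
        delta_lo=0.5 if f_lo > 0 else 0.0
    )
    bank = None
    series = []
    for seg in segments:
        proc = preprocess_segment(seg, f_lo=f_lo, f_hi=f_hi) if preprocess else seg
        spec = compute_spectrogram(proc, stft)
        if bank is None:
            bank = build_filterbank(bands, spec.freqs, n_filt=n_filt)
        series.append(
            extract_rhythm_series(
                spec, bank, n_M=n_M, segment_id=seg.segment_id, label=seg.label
            )
        )
    return assemble_observations(series)
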