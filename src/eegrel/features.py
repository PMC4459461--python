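"""Short-time rhythm features: triangular log-filterbanks and DCT cepstra.

Per rhythm band (delta, theta, alpha, beta) a bank of triangular filters
with linearly spaced centers is laid on the spectrogram's frequency grid
(linear-frequency cepstral coefficients, LFCC — on a linear rather than
mel scale, so each group of filters can be matched exactly to one
rhythm's bandwidth).  Per frame l and filter m the weighted spectral sum

    s_m(l) = sum_k F_m(k) * S(l, k)

is passed through a log (with a small floor) and an orthonormal DCT-II
across the filters of each band, keeping the first ``n_M`` coefficients
(5 by default).  The coefficient trajectories grouped per rhythm form
the short-time rhythm series x_i(t); stacking each object's series into
a column yields the observation matrix analysed by the relevance stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.fft import dct

from .exceptions import (
    FilterbankConfigError,
    FilterResolutionError,
    ShapeError,
)
from .spectral import Spectrogram
from .synth import RHYTHM_BANDS

logger = logging.getLogger(__name__)

#: Floor added before the log to guard empty bands.
LOG_FLOOR = 1e-10


@dataclass(frozen=True)
class RhythmBand:
    """A named frequency band [f_lo, f_hi] in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not 0 <= self.f_lo < self.f_hi:
            raise FilterbankConfigError(
                f"band {self.name}: need 0 <= f_lo < f_hi, got [{self.f_lo}, {self.f_hi}]"
            )


def default_bands(delta_lo: float = 0.0) -> list[RhythmBand]:
    """Canonical delta/theta/alpha/beta bands.

    ``delta_lo`` lets the delta lower edge move to 0.5 Hz when a drift
    high-pass is in use.
    """
    bands = []
    for name, (lo, hi) in RHYTHM_BANDS.items():
        if name == "delta":
            lo = delta_lo
        bands.append(RhythmBand(name, lo, hi))
    return bands


@dataclass
class RhythmFilterBank:
    """Triangular filters on a fixed frequency grid, grouped per band.

    ``filters[b]`` is an (n_filt, n_bins) matrix of unit-peak triangular
    responses whose supports lie inside band ``b`` (adjacent triangles
    within a band share edges, as in standard filterbank construction).
    """

    bands: list[RhythmBand]
    freqs: np.ndarray
    filters: dict[str, np.ndarray]
    n_filt: int

    @property
    def band_names(self) -> list[str]:
        return [b.name for b in self.bands]


def build_filterbank(
    bands: Sequence[RhythmBand] | None,
    freqs: np.ndarray,
    n_filt: int = 5,
) -> RhythmFilterBank:
    """Lay ``n_filt`` triangular filters per band on the grid ``freqs``.

    Filter centers are linearly spaced strictly inside each band: the
    band is divided by ``n_filt + 2`` equidistant points; triangle m
    rises from point m to point m+1 and falls to point m+2.  Each
    response is rescaled to unit peak on the grid.
    """
    bands = list(bands) if bands is not None else default_bands()
    freqs = np.asarray(freqs, dtype=float)
    if n_filt < 1:
        raise FilterbankConfigError("n_filt must be >= 1")
    filters: dict[str, np.ndarray] = {}
    for band in bands:
        if band.f_hi > freqs[-1] or band.f_lo < freqs[0]:
            raise FilterbankConfigError(
                f"band {band.name} [{band.f_lo}, {band.f_hi}] Hz exceeds grid "
                f"coverage [{freqs[0]}, {freqs[-1]}] Hz"
            )
        pts = np.linspace(band.f_lo, band.f_hi, n_filt + 2)
        F = np.zeros((n_filt, freqs.size))
        for m in range(n_filt):
            left, center, right = pts[m], pts[m + 1], pts[m + 2]
            rise = (freqs - left) / (center - left)
            fall = (right - freqs) / (right - center)
            resp = np.clip(np.minimum(rise, fall), 0.0, None)
            n_support = int(np.count_nonzero(resp))
            if n_support < 2:
                raise FilterResolutionError(
                    f"band {band.name}, filter {m}: only {n_support} grid point(s) "
                    f"under the triangle [{left:.2f}, {right:.2f}] Hz"
                )
            F[m] = resp / resp.max()
        filters[band.name] = F
    return RhythmFilterBank(bands=bands, freqs=freqs, filters=filters, n_filt=n_filt)


def filterbank_energies(
    spec: Spectrogram, bank: RhythmFilterBank
) -> dict[str, np.ndarray]:
    """Linear (pre-log) filterbank energies s_m(l) per band, shape (T, n_filt).

    Exposed separately from the cepstral path for band-selectivity
    diagnostics: a pure tone at the center of band b concentrates its
    energy in band b's filters.
    """
    if bank.freqs.shape != spec.freqs.shape or not np.allclose(bank.freqs, spec.freqs):
        raise ShapeError("filterbank frequency grid does not match the spectrogram")
    return {band: spec.power @ bank.filters[band].T for band in bank.band_names}


@dataclass
class RhythmSeries:
    """Cepstral rhythm trajectories of one segment.

    ``values[i, n, l]`` is cepstral coefficient ``n`` of rhythm ``i`` at
    frame ``l``; rhythms follow ``band_names`` order (delta, theta,
    alpha, beta by default).
    """

    values: np.ndarray  # (p, n_M, T)
    times: np.ndarray  # (T,)
    band_names: list[str]
    segment_id: str | None = None
    label: str | None = None

    @property
    def p(self) -> int:
        return self.values.shape[0]

    @property
    def n_M(self) -> int:
        return self.values.shape[1]

    @property
    def n_frames(self) -> int:
        return self.values.shape[2]


def extract_rhythm_series(
    spec: Spectrogram,
    bank: RhythmFilterBank,
    n_M: int = 5,
    eps: float = LOG_FLOOR,
    segment_id: str | None = None,
    label: str | None = None,
) -> RhythmSeries:
    """Filterbank log energies and per-band DCT-II cepstra of a spectrogram."""
    if bank.freqs.shape != spec.freqs.shape or not np.allclose(bank.freqs, spec.freqs):
        raise ShapeError("filterbank frequency grid does not match the spectrogram")
    if n_M < 1 or n_M > bank.n_filt:
        raise ShapeError(f"n_M must lie in [1, n_filt={bank.n_filt}], got {n_M}")
    energies = filterbank_energies(spec, bank)
    blocks = []
    for band in bank.band_names:
        s = energies[band]  # (T, n_filt) weighted spectral sums
        if np.any(s <= 0):
            logger.warning(
                "band %s has %d empty filter energies; log floor %.0e applied",
                band, int(np.count_nonzero(s <= 0)), eps,
            )
        z = dct(np.log(s + eps), type=2, norm="ortho", axis=1)[:, :n_M]
        blocks.append(z.T)  # (n_M, T)
    return RhythmSeries(
        values=np.stack(blocks),
        times=spec.times.copy(),
        band_names=list(bank.band_names),
        segment_id=segment_id,
        label=label,
    )


@dataclass
class ObservationMatrix:
    """Stacked rhythm trajectories of M objects, one object per column.

    Column m is object m's ``values`` flattened in rhythm-major order:
    the delta block first, then theta, alpha, beta; within a block,
    coefficients in order, each coefficient's frames time-ordered.  The
    layout round-trips losslessly via :meth:`unstack`.
    """

    X: np.ndarray  # (p * n_M * T, M)
    labels: list[str]
    band_names: list[str]
    n_M: int
    n_frames: int
    segment_ids: list[str | None] = field(default_factory=list)

    @property
    def p(self) -> int:
        return len(self.band_names)

    @property
    def n_objects(self) -> int:
        return self.X.shape[1]

    @property
    def dims(self) -> tuple[int, int, int]:
        return (self.p, self.n_M, self.n_frames)

    def unstack(self, m: int) -> np.ndarray:
        """Object m's trajectories as a (p, n_M, T) array."""
        return self.X[:, m].reshape(self.p, self.n_M, self.n_frames)

    def select(
        self,
        bands: Sequence[str] | None = None,
        coefficients: Sequence[int] | None = None,
    ) -> "ObservationMatrix":
        """Restrict to a subset of rhythm bands and/or cepstral coefficients.

        Used for the classification scenarios (delta; delta+theta; ...)
        and for the reduced one-value-per-rhythm-per-frame mode
        (``coefficients=[0]``).
        """
        bands = list(bands) if bands is not None else list(self.band_names)
        coeffs = list(coefficients) if coefficients is not None else list(range(self.n_M))
        missing = set(bands) - set(self.band_names)
        if missing:
            raise ShapeError(f"unknown bands {sorted(missing)}")
        band_idx = [self.band_names.index(b) for b in bands]
        cube = self.X.reshape(self.p, self.n_M, self.n_frames, self.n_objects)
        sub = cube[np.ix_(band_idx, coeffs)].reshape(
            len(band_idx) * len(coeffs) * self.n_frames, self.n_objects
        )
        return ObservationMatrix(
            X=sub,
            labels=list(self.labels),
            band_names=bands,
            n_M=len(coeffs),
            n_frames=self.n_frames,
            segment_ids=list(self.segment_ids),
        )


def assemble_observations(
    series: Sequence[RhythmSeries],
    labels: Sequence[str] | None = None,
) -> ObservationMatrix:
    """Stack per-object rhythm series into the observation matrix.

    All series must share (p, n_M, T); column order follows input order.
    """
    if not series:
        raise ShapeError("no series to assemble")
    if labels is None:
        labels = [s.label if s.label is not None else "" for s in series]
    if len(labels) != len(series):
        raise ShapeError("labels and series length mismatch")
    ref = series[0]
    for s in series[1:]:
        if s.values.shape != ref.values.shape:
            raise ShapeError(
                f"series shapes differ: {s.values.shape} vs {ref.values.shape} "
                "(no silent truncation)"
            )
        if s.band_names != ref.band_names:
            raise ShapeError("series band orders differ")
    X = np.stack([s.values.ravel() for s in series], axis=1)
    return ObservationMatrix(
        X=X,
        labels=list(labels),
        band_names=list(ref.band_names),
        n_M=ref.n_M,
        n_frames=ref.n_frames,
        segment_ids=[s.segment_id for s in series],
    )


def features_to_frame(om: ObservationMatrix):
    """Long-format table (segment_id, label, rhythm, coefficient, frame, value)."""
    import pandas as pd

    rows = []
    for m in range(om.n_objects):
        cube = om.unstack(m)
        sid = om.segment_ids[m] if om.segment_ids else str(m)
        for i, band in enumerate(om.band_names):
            for n in range(om.n_M):
                for l in range(om.n_frames):
                    rows.append((sid, om.labels[m], band, n, l, cube[i, n, l]))
    return pd.DataFrame(
        rows, columns=["segment_id", "label", "rhythm", "coefficient", "frame", "value"]
    )
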