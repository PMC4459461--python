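"""Stochastic relevance analysis of short-time rhythm trajectories.

The observation matrix X (one stacked rhythm-trajectory column per
object) is analysed in a principal subspace: eigenpairs of the empirical
covariance of the columns are computed — via the small M x M Gram matrix
when the stacked dimension exceeds the number of objects (the classic
snapshot/rank trick: X Xᵀ and Xᵀ X share their nonzero spectrum) — and
the leading q components are retained by an explained-variance
criterion.  The relevance of each position of the stacked vector is the
eigenvalue-weighted magnitude of its loadings,

    g = sum_{k <= q} lambda_k |v_k|,

sliced into per-rhythm blocks g_i(t) (piecewise constant per time frame)
and time-averaged into a single relevance weight gamma_i per rhythm.
Larger gamma_i means the rhythm's short-time trajectory carries more of
the ensemble's variability.  An unweighted ``sum |v_k|`` variant is kept
switchable; the eigenvalue-weighted form is the default because
components are ranked by eigenvalue in the first place.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import (
    DegenerateCovarianceError,
    InsufficientDataError,
    ShapeError,
)
from .features import ObservationMatrix

logger = logging.getLogger(__name__)

_EIG_TOL = 1e-12  # relative cutoff below which eigenvalues count as null


@dataclass
class EigenBasis:
    """Retained eigenstructure of the observation covariance.

    ``eigenvalues`` are the nonzero covariance eigenvalues in decreasing
    order; ``eigenvectors`` the matching orthonormal directions in the
    stacked d = p * n_M * T space (columns).  ``q`` is the count whose
    cumulative eigenvalue fraction first reaches the explained-variance
    threshold.
    """

    eigenvalues: np.ndarray  # (r,), decreasing, >= 0
    eigenvectors: np.ndarray  # (d, r), orthonormal columns
    q: int
    explained_variance: np.ndarray  # (r,), cumulative fractions
    centered: bool
    var_threshold: float
    dims: tuple[int, int, int] | None = None  # (p, n_M, T) when known

    @property
    def rank(self) -> int:
        return int(self.eigenvalues.size)


def fit_subspace(
    X: ObservationMatrix | np.ndarray,
    var_threshold: float = 0.95,
    center: bool = True,
) -> EigenBasis:
    """Eigendecompose the empirical covariance of the columns of X.

    The covariance is ``C = Xc Xcᵀ / M`` with columns mean-centered
    across objects by default (the model assumes zero-mean stacked
    vectors; centering realizes that empirically).  When d > M the
    eigenpairs are obtained from the M x M Gram matrix ``Xcᵀ Xc / M``
    and mapped back with ``v_k = Xc u_k / sqrt(M lambda_k)``, which is
    exact for the nonzero spectrum.
    """
    dims = None
    if isinstance(X, ObservationMatrix):
        dims = X.dims
        X = X.X
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ShapeError("X must be a 2-D (d, M) matrix")
    d, M = X.shape
    if M < 2:
        raise InsufficientDataError(f"need at least 2 objects, got {M}")
    if not 0.0 < var_threshold <= 1.0:
        raise ValueError("var_threshold must lie in (0, 1]")

    Xc = X - X.mean(axis=1, keepdims=True) if center else X.copy()
    if d > M:
        gram = (Xc.T @ Xc) / M
        lam, U = np.linalg.eigh(gram)
        order = np.argsort(lam)[::-1]
        lam, U = lam[order], U[:, order]
        lam = np.clip(lam, 0.0, None)
        if lam[0] <= 0:
            raise DegenerateCovarianceError(
                "centered observation matrix has zero covariance "
                "(all columns identical?)"
            )
        keep = lam > _EIG_TOL * lam[0]
        lam, U = lam[keep], U[:, keep]
        V = (Xc @ U) / np.sqrt(M * lam)
    else:
        cov = (Xc @ Xc.T) / M
        lam, V = np.linalg.eigh(cov)
        order = np.argsort(lam)[::-1]
        lam, V = lam[order], V[:, order]
        lam = np.clip(lam, 0.0, None)
        if lam[0] <= 0:
            raise DegenerateCovarianceError(
                "centered observation matrix has zero covariance"
            )
        keep = lam > _EIG_TOL * lam[0]
        lam, V = lam[keep], V[:, keep]

    cum = np.cumsum(lam) / lam.sum()
    q = int(np.searchsorted(cum, var_threshold - 1e-12) + 1)
    q = min(q, lam.size)
    logger.info(
        "subspace fit: d=%d M=%d rank=%d q=%d explained=%.4f",
        d, M, lam.size, q, cum[q - 1],
    )
    return EigenBasis(
        eigenvalues=lam,
        eigenvectors=V,
        q=q,
        explained_variance=cum,
        centered=center,
        var_threshold=var_threshold,
        dims=dims,
    )


@dataclass
class RelevanceProfile:
    """Per-rhythm, per-frame relevance g_i(t), piecewise constant per frame."""

    g: np.ndarray  # (p, T), >= 0
    band_names: list[str] | None = None

    @property
    def p(self) -> int:
        return self.g.shape[0]

    @property
    def n_frames(self) -> int:
        return self.g.shape[1]


def relevance_profile(
    basis: EigenBasis,
    dims: tuple[int, int] | tuple[int, int, int] | None = None,
    band_names: list[str] | None = None,
    weighting: str = "eigenvalue",
) -> RelevanceProfile:
    """Slice the loading-magnitude relevance vector into rhythm blocks.

    ``dims`` is (p, T) or (p, n_M, T); when omitted it is taken from the
    basis.  With several cepstral coefficients per rhythm, coefficient
    positions sharing a (rhythm, frame) cell are averaged, which also
    enforces the within-frame constancy of g_i(t).
    """
    if dims is None:
        if basis.dims is None:
            raise ShapeError("dims not stored in basis; pass them explicitly")
        dims = basis.dims
    if len(dims) == 2:
        p, n_m, T = dims[0], 1, dims[1]
    else:
        p, n_m, T = dims
    d = basis.eigenvectors.shape[0]
    if p * n_m * T != d:
        raise ShapeError(f"dims {dims} do not match eigenvector dimension {d}")

    V = np.abs(basis.eigenvectors[:, : basis.q])
    if weighting == "eigenvalue":
        g_raw = V @ basis.eigenvalues[: basis.q]
    elif weighting == "unit":
        g_raw = V.sum(axis=1)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    g = g_raw.reshape(p, n_m, T).mean(axis=1)
    return RelevanceProfile(g=g, band_names=band_names)


@dataclass
class RelevanceWeights:
    """Scalar relevance per rhythm with its descending ranking."""

    gamma: np.ndarray  # (p,), >= 0
    band_names: list[str]
    ranking: list[str]  # band names by decreasing gamma
    class_tag: str | None = None
    normalized: bool = False

    def normalized_copy(self) -> "RelevanceWeights":
        """Weights divided by their maximum, so max gamma == 1 exactly."""
        peak = float(self.gamma.max())
        if peak <= 0:
            raise DegenerateCovarianceError("all relevance weights are zero")
        return RelevanceWeights(
            gamma=self.gamma / peak,
            band_names=list(self.band_names),
            ranking=list(self.ranking),
            class_tag=self.class_tag,
            normalized=True,
        )

    def as_dict(self) -> dict[str, float]:
        return {b: float(v) for b, v in zip(self.band_names, self.gamma)}


def relevance_weights(
    profile: RelevanceProfile,
    band_names: list[str] | None = None,
    class_tag: str | None = None,
) -> RelevanceWeights:
    """Time-average g_i(t) into one weight per rhythm and rank descending.

    Ties break deterministically in canonical band order.
    """
    if profile.g.size == 0:
        raise ShapeError("empty relevance profile")
    names = band_names or profile.band_names
    if names is None:
        names = [f"rhythm{i}" for i in range(profile.p)]
    gamma = profile.g.mean(axis=1)
    order = sorted(range(len(names)), key=lambda i: (-gamma[i], i))
    return RelevanceWeights(
        gamma=gamma,
        band_names=list(names),
        ranking=[names[i] for i in order],
        class_tag=class_tag,
    )


def weights_from_observations(
    om: ObservationMatrix,
    var_threshold: float = 0.95,
    center: bool = True,
    weighting: str = "eigenvalue",
    class_tag: str | None = None,
    reduce_coefficients: bool = True,
) -> RelevanceWeights:
    """Convenience chain: fit_subspace -> relevance_profile -> relevance_weights.

    By default the relevance stage operates on the p-dimensional
    short-time rhythm vector — one value per rhythm per frame, realized
    as cepstral coefficient 0 (the overall log band energy) — matching
    the model in which each rhythm is a scalar stochastic waveform.
    Higher cepstral coefficients describe within-band spectral shape and
    mostly carry estimation noise at these window lengths; set
    ``reduce_coefficients=False`` to analyse the full coefficient block.
    """
    if reduce_coefficients and om.n_M > 1:
        om = om.select(coefficients=[0])
    basis = fit_subspace(om, var_threshold=var_threshold, center=center)
    profile = relevance_profile(basis, band_names=om.band_names, weighting=weighting)
    return relevance_weights(profile, class_tag=class_tag)


def per_class_weights(
    om: ObservationMatrix,
    var_threshold: float = 0.95,
    center: bool = True,
    weighting: str = "eigenvalue",
    reduce_coefficients: bool = True,
) -> dict[str, RelevanceWeights]:
    """Separate subspace fit and relevance weights per class, max-normalized.

    Each class's columns are centered on the class mean; each class's
    weights are divided by their own maximum so max gamma^(k) == 1,
    making profiles comparable across classes.
    """
    out: dict[str, RelevanceWeights] = {}
    labels = np.asarray(om.labels)
    for tag in dict.fromkeys(om.labels):  # preserve first-appearance order
        cols = np.flatnonzero(labels == tag)
        if cols.size < 2:
            raise InsufficientDataError(
                f"class {tag!r} has {cols.size} object(s); need >= 2"
            )
        sub = ObservationMatrix(
            X=om.X[:, cols],
            labels=[om.labels[c] for c in cols],
            band_names=list(om.band_names),
            n_M=om.n_M,
            n_frames=om.n_frames,
            segment_ids=[om.segment_ids[c] for c in cols] if om.segment_ids else [],
        )
        w = weights_from_observations(
            sub, var_threshold=var_threshold, center=center,
            weighting=weighting, class_tag=tag,
            reduce_coefficients=reduce_coefficients,
        )
        out[tag] = w.normalized_copy()
    return out
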