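"""Relevance rhythm diagrams (RRD) for qualitative monitoring.

An RRD compares a class's max-normalized rhythm relevance weights
against a reference class on a four-axis diamond (delta up, theta
right, alpha down, beta left).  The reference is drawn with a shaded
band of half-width 3 sigma per rhythm, where sigma is the sample
standard deviation of the reference weights over segment-level fits;
a compared class whose vertex leaves the band marks a genuine change of
that rhythm's contribution.  The per-rhythm ``Diff`` sign summarizes the
direction of that change (+ increase, - decrease, 0 within tolerance).

Segment-level reference weights are obtained by refitting the per-class
relevance on leave-one-out (or random) subsets of the reference
segments, since a single class fit yields only one weight vector.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .exceptions import ConfigError, InsufficientDataError, ShapeError
from .features import ObservationMatrix
from .relevance import RelevanceWeights, weights_from_observations

#: Axis order and unit directions of the diamond: delta up, theta right,
#: alpha down, beta left.
AXIS_ORDER = ("delta", "theta", "alpha", "beta")
_DIRECTIONS = {
    "delta": (0.0, 1.0),
    "theta": (1.0, 0.0),
    "alpha": (0.0, -1.0),
    "beta": (-1.0, 0.0),
}

SIGN_TOL = 1e-6


@dataclass
class RrdModel:
    """Reference band and compared weights of one diagram."""

    band_names: list[str]
    reference_mean: np.ndarray  # (p,)
    reference_sigma: np.ndarray  # (p,), sample std over reference fits
    compared_mean: np.ndarray  # (p,)
    diff_signs: list[str]  # per rhythm, in {"+", "-", "0"}
    reference_label: str | None = None
    compared_label: str | None = None

    @property
    def band_halfwidth(self) -> np.ndarray:
        """3 sigma per rhythm."""
        return 3.0 * self.reference_sigma

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "band_names": self.band_names,
            "reference_label": self.reference_label,
            "compared_label": self.compared_label,
            "reference_mean": [float(v) for v in self.reference_mean],
            "reference_sigma": [float(v) for v in self.reference_sigma],
            "band_halfwidth": [float(v) for v in self.band_halfwidth],
            "compared_mean": [float(v) for v in self.compared_mean],
            "diff_signs": self.diff_signs,
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _stack_weights(
    weights: Sequence[RelevanceWeights] | RelevanceWeights,
) -> tuple[np.ndarray, list[str], str | None]:
    if isinstance(weights, RelevanceWeights):
        weights = [weights]
    if not weights:
        raise ShapeError("no weight vectors given")
    names = list(weights[0].band_names)
    for w in weights:
        if list(w.band_names) != names:
            raise ShapeError("weight vectors have differing band orders")
        if not w.normalized:
            raise ConfigError("RRD expects max-normalized relevance weights")
    tags = {w.class_tag for w in weights if w.class_tag is not None}
    tag = tags.pop() if len(tags) == 1 else None
    return np.stack([w.gamma for w in weights]), names, tag


def build_rrd(
    reference_weights: Sequence[RelevanceWeights],
    compared_weights: Sequence[RelevanceWeights] | RelevanceWeights,
    tol: float = SIGN_TOL,
) -> RrdModel:
    """Reference mean +/- 3 sigma band versus compared means, with Diff signs.

    Needs at least two reference weight vectors so sigma is estimable.
    Diff is antisymmetric: swapping reference and compared flips + and -.
    """
    ref, names, ref_tag = _stack_weights(list(reference_weights))
    if ref.shape[0] < 2:
        raise InsufficientDataError(
            "sigma undefined: need >= 2 reference weight vectors"
        )
    cmp_, cmp_names, cmp_tag = _stack_weights(compared_weights)
    if cmp_names != names:
        raise ShapeError("reference and compared band orders differ")
    ref_mean = ref.mean(axis=0)
    ref_sigma = ref.std(axis=0, ddof=1)
    cmp_mean = cmp_.mean(axis=0)
    signs = []
    for rm, cm in zip(ref_mean, cmp_mean):
        if cm > rm + tol:
            signs.append("+")
        elif cm < rm - tol:
            signs.append("-")
        else:
            signs.append("0")
    return RrdModel(
        band_names=names,
        reference_mean=ref_mean,
        reference_sigma=ref_sigma,
        compared_mean=cmp_mean,
        diff_signs=signs,
        reference_label=ref_tag,
        compared_label=cmp_tag,
    )


def reference_weight_samples(
    om: ObservationMatrix,
    label: str,
    var_threshold: float = 0.95,
    method: str = "loo",
    n_subsets: int = 20,
    subset_fraction: float = 0.8,
    seed: int = 0,
    weighting: str = "eigenvalue",
) -> list[RelevanceWeights]:
    """Segment-level weight vectors of one class by subset refits.

    ``method="loo"`` refits the class relevance leaving one segment out
    at a time; ``method="subsample"`` uses ``n_subsets`` random subsets
    of ``subset_fraction`` of the segments.  Each refit is
    max-normalized, giving the dispersion that the 3 sigma band of an
    RRD summarizes.
    """
    labels = np.asarray(om.labels)
    cols = np.flatnonzero(labels == label)
    if cols.size < 3:
        raise InsufficientDataError(
            f"class {label!r} has {cols.size} segment(s); need >= 3 for subset fits"
        )
    if method == "loo":
        subsets = [np.delete(cols, i) for i in range(cols.size)]
    elif method == "subsample":
        rng = np.random.default_rng(seed)
        size = max(2, int(round(subset_fraction * cols.size)))
        subsets = [rng.choice(cols, size=size, replace=False) for _ in range(n_subsets)]
    else:
        raise ConfigError(f"unknown method {method!r}")
    out = []
    for sub in subsets:
        som = ObservationMatrix(
            X=om.X[:, sub],
            labels=[om.labels[c] for c in sub],
            band_names=list(om.band_names),
            n_M=om.n_M,
            n_frames=om.n_frames,
        )
        w = weights_from_observations(
            som, var_threshold=var_threshold, weighting=weighting, class_tag=label
        )
        out.append(w.normalized_copy())
    return out


def diamond_vertices(band_names: Sequence[str], values: np.ndarray) -> np.ndarray:
    """(p, 2) xy vertices of a weight polygon on the diamond axes."""
    verts = []
    for name, v in zip(band_names, values):
        dx, dy = _DIRECTIONS.get(name, (np.nan, np.nan))
        verts.append((v * dx, v * dy))
    return np.asarray(verts)


def render_rrd(model: RrdModel, path: str | Path) -> Path:
    """Draw the diamond diagram to PNG or SVG (by extension).

    Reference polygon in red with its shaded 3 sigma band; compared
    polygon in blue; the referenced class is marked with an asterisk in
    the legend.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.patches import PathPatch
    from matplotlib.path import Path as MplPath

    names = list(model.band_names)
    ref_v = diamond_vertices(names, model.reference_mean)
    cmp_v = diamond_vertices(names, model.compared_mean)
    outer = diamond_vertices(names, model.reference_mean + model.band_halfwidth)
    inner = diamond_vertices(
        names, np.clip(model.reference_mean - model.band_halfwidth, 0.0, None)
    )

    fig, ax = plt.subplots(figsize=(5, 5))
    # Band as an outer ring with an inner hole (even-odd fill rule).
    ring = np.vstack([outer, outer[:1], inner[::-1], inner[-1:][::-1]])
    codes = (
        [MplPath.MOVETO] + [MplPath.LINETO] * len(outer)
        + [MplPath.MOVETO] + [MplPath.LINETO] * len(inner)
    )
    ax.add_patch(PathPatch(MplPath(ring, codes), facecolor="red", alpha=0.15,
                           edgecolor="none"))
    ref_label = f"{model.reference_label or 'reference'}*"
    cmp_label = model.compared_label or "compared"
    ax.plot(*_closed(ref_v), color="red", marker="o", label=ref_label)
    ax.plot(*_closed(cmp_v), color="blue", marker="o", label=cmp_label)
    lim = 1.15 * max(1.0, float((model.reference_mean + model.band_halfwidth).max()),
                     float(model.compared_mean.max()))
    for name in names:
        dx, dy = _DIRECTIONS[name]
        ax.plot([0, lim * dx], [0, lim * dy], color="0.8", lw=0.8, zorder=0)
        ax.annotate(name, (1.05 * lim * dx, 1.05 * lim * dy),
                    ha="center", va="center")
    ax.set_xlim(-1.2 * lim, 1.2 * lim)
    ax.set_ylim(-1.2 * lim, 1.2 * lim)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.legend(loc="upper left", frameon=False)
    path = Path(path)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
    return path


def _closed(verts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    loop = np.vstack([verts, verts[:1]])
    return loop[:, 0], loop[:, 1]
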