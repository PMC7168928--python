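"""Visual summaries: band-filter images, 1-sigma ellipses, score histograms.

These are the computational counterparts of the standard figures of a Raman
mapping study — pseudo-color band images, per-sample biomarker ellipses and
the two-class score histogram — returned as plain arrays/records so they can
be tested numerically; rendering to image files is a thin matplotlib layer
on top.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .classify import ScoredSpectrum
from .preprocess import BandWindow, band_area
from .synth import CLASS_NORMAL, CLASS_ROD, SpectralMap

__all__ = [
    "EllipseSummary",
    "band_filter_image",
    "one_sigma_ellipse",
    "score_histogram",
    "save_band_filter_image",
    "save_error_curves_plot",
    "save_score_histogram_plot",
]


@dataclass(frozen=True)
class EllipseSummary:
    """1-sigma ellipse of a bivariate point cloud.

    Semi-axis lengths are the square roots of the covariance eigenvalues;
    the angle is the orientation of the leading eigenvector in degrees. For
    bivariate normal data the ellipse contains 1 - exp(-1/2) ~ 39.3% of the
    points.
    """

    mean: np.ndarray          # (2,)
    covariance: np.ndarray    # (2, 2)
    axes: tuple[float, float]  # semi-axes, descending
    angle_deg: float

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the 1-sigma contour (Mahalanobis
        distance <= 1)."""
        pts = np.column_stack([np.asarray(x) - self.mean[0],
                               np.asarray(y) - self.mean[1]])
        cov = self.covariance
        inv = np.linalg.pinv(cov)
        d2 = np.einsum("ij,jk,ik->i", pts, inv, pts)
        return d2 <= 1.0


def band_filter_image(
    smap: SpectralMap,
    window: BandWindow,
    normalize: bool = True,
    **band_kwargs,
) -> np.ndarray:
    """Per-pixel integrated band area over one window — a pseudo-color
    filter image of the map.

    Each pixel's spectrum is integrated with the usual local linear baseline
    removal. With ``normalize=True`` the image is min-max scaled to [0, 1]
    per image (constant images map to 0). Input spectra are never mutated.
    """
    h, w = smap.shape
    img = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            img[i, j] = band_area(smap.spectrum(i, j), window, **band_kwargs)
    if normalize:
        lo, hi = img.min(), img.max()
        img = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
    return img


def one_sigma_ellipse(x: Sequence[float], y: Sequence[float]) -> EllipseSummary:
    """Sample mean and covariance of (x, y) as a 1-sigma ellipse."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired points")
    mean = np.array([x.mean(), y.mean()])
    cov = np.cov(np.vstack([x, y]))
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals, 0.0, None)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[-1] == 0.0:
        import warnings

        warnings.warn("degenerate covariance: zero-width ellipse axis",
                      stacklevel=2)
    axes = (float(math.sqrt(evals[0])), float(math.sqrt(evals[1])))
    lead = evecs[:, 0]
    angle = math.degrees(math.atan2(lead[1], lead[0])) % 180.0
    return EllipseSummary(mean=mean, covariance=cov, axes=axes, angle_deg=angle)


def score_histogram(
    scored: Sequence[ScoredSpectrum],
    bins: int = 100,
) -> dict:
    """Per-class normalized histograms of log-score (threshold 1 maps to 0).

    Returns bin edges, the two density histograms, and their overlap
    coefficient (integral of the pointwise minimum; 0 for perfectly separated
    classes, ~1 for identical distributions).
    """
    if not scored:
        raise ValueError("no scored spectra")
    log_scores = np.array([math.log(s.score) for s in scored])
    classes = np.array([s.true_class for s in scored])
    edges = np.histogram_bin_edges(log_scores, bins=bins)
    h_norm, _ = np.histogram(log_scores[classes == CLASS_NORMAL], bins=edges,
                             density=True)
    h_rod, _ = np.histogram(log_scores[classes == CLASS_ROD], bins=edges,
                            density=True)
    widths = np.diff(edges)
    overlap = float(np.sum(np.minimum(h_norm, h_rod) * widths))
    return {
        "bin_edges": edges,
        "normal_density": h_norm,
        "rod_density": h_rod,
        "overlap_coefficient": overlap,
        "threshold_log_score": 0.0,
    }


# ---------------------------------------------------------------------------
# rendering layer


def _agg_pyplot():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def save_band_filter_image(img: np.ndarray, path, title: str = "") -> None:
    plt = _agg_pyplot()
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(img, cmap="viridis", origin="lower")
    fig.colorbar(im, ax=ax, shrink=0.8)
    if title:
        ax.set_title(title)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def save_error_curves_plot(curves, path) -> None:
    """Plot the (N, q1, q2) table from ``aggregate.error_curves``."""
    plt = _agg_pyplot()
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.semilogy(curves["N"], curves["q1"], "o-", label="Type I (normal called ROD)")
    ax.semilogy(curves["N"], curves["q2"], "s-", label="Type II (ROD called normal)")
    ax.axhline(0.05, color="k", lw=0.8, ls="--", label="alpha = 0.05")
    ax.set_xlabel("number of independent spectra N")
    ax.set_ylabel("majority-vote error probability")
    ax.legend()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def save_score_histogram_plot(hist: dict, path) -> None:
    plt = _agg_pyplot()
    fig, ax = plt.subplots(figsize=(5, 4))
    centers = 0.5 * (hist["bin_edges"][:-1] + hist["bin_edges"][1:])
    ax.step(centers, hist["normal_density"], where="mid", label="normal")
    ax.step(centers, hist["rod_density"], where="mid", label="ROD")
    ax.axvline(0.0, color="k", lw=0.8, label="score = 1")
    ax.set_xlabel("log score")
    ax.set_ylabel("density")
    ax.legend()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
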