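"""Grooming-duration analytics: histograms, KDE PDFs, condition comparisons,
the 16 s / 40 s dual-duration response metric, and clustering.

Durations are analysed per cell — a (dataset, side, condition) triple, where
condition is ``pre_drug`` or ``post_drug``.  Episodes longer than 100 s are
excluded up front; pre-drug cells pool two recording days, so their
histogram counts carry a per-observation weight of 0.5 to match the single
post-drug day (a normalised PDF is invariant to a uniform weight, so the
KDE itself is unweighted).

The PDF is a Gaussian kernel density estimate with a fixed bandwidth of
3 s, normalised over the whole real line and evaluated on the 1..100 s grid
without boundary correction.  The dual-duration response metric reads the
PDF ordinates at 16 s (short, ordinary grooming) and 40 s (long grooming,
e.g. sustained licking of a painful limb); pain shifts probability mass
from the short mode to the long one, which K-means clustering of the
(y16, y40) points makes visible as separate groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from sklearn.neighbors import KernelDensity

from .clips import Clip

__all__ = [
    "DurationDistribution",
    "ResponseMetricPoint",
    "ClusterResult",
    "build_distribution",
    "ks_compare",
    "compare_totals",
    "response_metric",
    "cluster_points",
    "ks_table",
]

MAX_DURATION_S = 100
GRID = np.arange(1, MAX_DURATION_S + 1, dtype=float)
DEFAULT_BANDWIDTH = 3.0
PRE_DRUG_WEIGHT = 0.5


@dataclass(frozen=True)
class DurationDistribution:
    """Durations, weighted histogram, and KDE PDF for one analysis cell."""

    cell: tuple[str, str, str]          # (dataset, side, condition)
    durations: np.ndarray               # kept durations (<= 100 s)
    weight: float                       # per-observation histogram weight
    bandwidth: float
    histogram: np.ndarray               # weighted counts, 1-s bins over (0, 100]
    pdf: np.ndarray | None              # KDE on GRID; None for an empty cell
    grid: np.ndarray = field(default_factory=lambda: GRID.copy())

    @property
    def is_empty(self) -> bool:
        return self.pdf is None

    @property
    def effective_count(self) -> float:
        """Weighted episode count (pre-drug cells count each episode as 0.5)."""
        return float(len(self.durations) * self.weight)

    def pdf_at(self, x: float) -> float:
        idx = np.flatnonzero(np.isclose(self.grid, x))
        if len(idx) == 0:
            raise ValueError(f"grid does not cover duration {x} s")
        return float(self.pdf[idx[0]])


def _kde_pdf(durations: np.ndarray, bandwidth: float,
             grid: np.ndarray) -> np.ndarray:
    kde = KernelDensity(kernel="gaussian", bandwidth=bandwidth)
    kde.fit(durations[:, None])
    return np.exp(kde.score_samples(grid[:, None]))


def build_distribution(durations, cell: tuple[str, str, str],
                       bandwidth: float = DEFAULT_BANDWIDTH,
                       weight: float | None = None) -> DurationDistribution:
    """Build the duration distribution for one (dataset, side, condition) cell.

    ``durations`` may be a sequence of seconds or of :class:`Clip` objects.
    Durations above 100 s are excluded before any statistic is computed.
    ``weight`` defaults to 0.5 for pre-drug cells (two pooled days) and 1.0
    otherwise.  An empty cell yields an explicit marker distribution with
    ``pdf=None`` rather than an error.
    """
    if len(durations) and isinstance(durations[0], Clip):
        durations = [c.duration_s for c in durations]
    durations = np.asarray(durations, dtype=float)
    if np.any(durations <= 0):
        raise ValueError("durations must be positive")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    condition = cell[2]
    if weight is None:
        weight = PRE_DRUG_WEIGHT if condition == "pre_drug" else 1.0
    kept = durations[durations <= MAX_DURATION_S]
    hist, _ = np.histogram(kept, bins=np.arange(0.0, MAX_DURATION_S + 1.0) + 0.5)
    hist = hist * weight
    pdf = _kde_pdf(kept, bandwidth, GRID) if len(kept) else None
    return DurationDistribution(
        cell=tuple(cell), durations=kept, weight=float(weight),
        bandwidth=float(bandwidth), histogram=hist, pdf=pdf)


def kde_on_grid(durations, bandwidth: float, grid: np.ndarray) -> np.ndarray:
    """Gaussian KDE evaluated on an arbitrary grid (full-line normalisation)."""
    durations = np.asarray(durations, dtype=float)
    if len(durations) == 0:
        raise ValueError("empty duration list")
    return _kde_pdf(durations, bandwidth, np.asarray(grid, dtype=float))


def ks_compare(durations_a, durations_b, exact: bool = False):
    """Two-sided two-sample Kolmogorov-Smirnov test on duration samples.

    Returns ``(statistic, p_value)``; the statistic is the maximum absolute
    gap between the two empirical CDFs.  The asymptotic p-value is used by
    default; ``exact=True`` requests the exact small-sample computation.
    """
    a = np.asarray(durations_a, dtype=float)
    b = np.asarray(durations_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.ks_2samp(a, b, alternative="two-sided",
                       method="exact" if exact else "asymp")
    return float(res.statistic), float(res.pvalue)


def compare_totals(totals_a, totals_b, paired: bool = True) -> float:
    """Two-sided rank test on per-animal totals (duration or episode count).

    Paired (the default): Wilcoxon signed-rank with zero-difference pairs
    dropped; all-zero differences return p = 1 by convention.  Unpaired:
    Wilcoxon rank-sum.
    """
    a = np.asarray(totals_a, dtype=float)
    b = np.asarray(totals_b, dtype=float)
    if paired:
        if a.shape != b.shape:
            raise ValueError(f"paired samples differ in length: {len(a)} vs {len(b)}")
        d = a - b
        if np.all(d == 0):
            return 1.0
        res = sps.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided")
        return float(res.pvalue)
    res = sps.ranksums(a, b, alternative="two-sided")
    return float(res.pvalue)


@dataclass(frozen=True)
class ResponseMetricPoint:
    """PDF ordinates at the two diagnostic durations for one cell."""

    cell: tuple[str, str, str]
    y16: float
    y40: float

    def as_xy(self) -> tuple[float, float]:
        return (self.y16, self.y40)


def response_metric(dist: DurationDistribution,
                    short_s: float = 16.0, long_s: float = 40.0) -> ResponseMetricPoint:
    """Read the dual-duration response metric (y16, y40) off a cell's PDF."""
    if dist.is_empty:
        raise ValueError(f"cell {dist.cell} is empty; no PDF to read")
    return ResponseMetricPoint(cell=dist.cell, y16=dist.pdf_at(short_s),
                               y40=dist.pdf_at(long_s))


@dataclass(frozen=True)
class ClusterResult:
    """K-means labels, centroids, silhouette, and per-cluster 2-SD ellipses."""

    labels: np.ndarray
    centroids: np.ndarray
    silhouette: float
    ellipses: list[dict]      # center, semi_axes (2 SD), angle_rad per cluster
    inertia: float


def _sd_ellipse(points: np.ndarray, n_sd: float = 2.0) -> dict:
    center = points.mean(axis=0)
    if len(points) < 2:
        return {"center": center, "semi_axes": np.zeros(2), "angle_rad": 0.0}
    cov = np.cov(points.T)
    evals, evecs = np.linalg.eigh(np.atleast_2d(cov))
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    angle = float(np.arctan2(evecs[1, 0], evecs[0, 0]))
    return {"center": center, "semi_axes": n_sd * np.sqrt(np.maximum(evals, 0.0)),
            "angle_rad": angle}


def cluster_points(points, k: int, seed: int = 0, n_restarts: int = 10) -> ClusterResult:
    """Seeded multi-start K-means on response-metric points.

    Returns labels, centroids, the mean silhouette coefficient (NaN when it
    is undefined, i.e. k = 1 or k = n), and a 2-SD ellipse per cluster.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2:
        raise ValueError("points must be a 2-D array of (y16, y40) pairs")
    if k > len(pts):
        raise ValueError(f"cannot form k={k} clusters from {len(pts)} points")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed % (2**32))
    labels = km.fit_predict(pts)
    sil = float("nan")
    if 1 < k < len(pts):
        sil = float(silhouette_score(pts, labels))
    ellipses = [_sd_ellipse(pts[labels == c]) for c in range(k)]
    return ClusterResult(labels=labels, centroids=km.cluster_centers_,
                         silhouette=sil, ellipses=ellipses,
                         inertia=float(km.inertia_))


def ks_table(cells: dict[tuple[str, str, str], np.ndarray],
             exact: bool = False) -> pd.DataFrame:
    """KS-test p-value table across the standard four comparisons per dataset.

    ``cells`` maps (dataset, role, condition) -> duration array, with role in
    {"experimental", "control"} and condition in {"pre_drug", "post_drug"}.
    Columns: across-rats pre-drug, across-rats post-drug, same-rat
    experimental (pre vs post), same-rat control.  The final ``Mean`` row is
    the mean of the per-dataset p-values.
    """
    datasets = sorted({key[0] for key in cells})
    rows = []
    for ds in datasets:
        def get(role, cond):
            return cells.get((ds, role, cond))

        def p(sa, sb):
            if sa is None or sb is None or len(sa) == 0 or len(sb) == 0:
                return float("nan")
            return ks_compare(sa, sb, exact=exact)[1]

        rows.append({
            "dataset": ds,
            "across_pre": p(get("experimental", "pre_drug"), get("control", "pre_drug")),
            "across_post": p(get("experimental", "post_drug"), get("control", "post_drug")),
            "same_experimental": p(get("experimental", "pre_drug"),
                                   get("experimental", "post_drug")),
            "same_control": p(get("control", "pre_drug"), get("control", "post_drug")),
        })
    df = pd.DataFrame(rows)
    mean_row = {"dataset": "Mean"}
    for col in ("across_pre", "across_post", "same_experimental", "same_control"):
        mean_row[col] = float(np.nanmean(df[col])) if len(df) else float("nan")
    return pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)
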