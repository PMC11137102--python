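"""CIN cluster classification of copy-number profiles.

Plasma and tissue profiles are summarized into a 102-dimensional feature
vector (mean segment log2 ratio over 43 amplification and 59 deletion peak
regions), optionally rescaled to tumor-equivalent copy numbers using the
sample's tumor fraction, and assigned to one of three chromosomal
instability clusters by nearest centroid under Pearson correlation, with a
genome-altered-burden rule forcing near-diploid profiles into cluster 1
(CIN-low). Clusters 2 and 3 together form the CIN-high group.

Low plasma tumor content dilutes copy-number signal toward neutrality; the
scaling step inverts the two-component mixture in linear copy-number space:

    CN_obs = 2 * 2^L;   CN_tumor = 2 + (CN_obs - 2) / tf

so that profiles from samples with very different tumor fractions become
comparable to tissue-derived centroids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .cna import SegmentedCNAProfile
from .stats import spearman

__all__ = [
    "PeakRegionSet",
    "PeakFeatureVector",
    "ClusterCentroids",
    "ClusterAssignment",
    "ConcordanceResult",
    "extract_peak_features",
    "scale_log2_ratios",
    "dilute_log2_ratios",
    "scale_segmented_profile",
    "derive_cohort_scaling_factor",
    "NearestCentroidCIN",
    "assign_cluster",
    "concordance",
    "peak_correlation_matrix",
]


@dataclass
class PeakRegionSet:
    """43 amplification + 59 deletion peak regions (BED-like, half-open)."""

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    label: np.ndarray
    direction: np.ndarray  # "amp" or "del"

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom)
        self.start = np.asarray(self.start, dtype=int)
        self.end = np.asarray(self.end, dtype=int)
        self.label = np.asarray(self.label)
        self.direction = np.asarray(self.direction)
        if not set(np.unique(self.direction)) <= {"amp", "del"}:
            raise ValueError("directions must be 'amp' or 'del'")

    @property
    def n(self) -> int:
        return len(self.chrom)

    @property
    def n_amp(self) -> int:
        return int((self.direction == "amp").sum())

    @property
    def n_del(self) -> int:
        return int((self.direction == "del").sum())


@dataclass
class PeakFeatureVector:
    sample_id: str
    values: np.ndarray  # one mean log2 ratio per peak region
    tumor_fraction: float | None = None
    scaled: bool = False
    no_overlap: np.ndarray = field(default_factory=lambda: np.array([], bool))


@dataclass
class ClusterCentroids:
    """Per-cluster peak-feature centroids plus the CIN-low burden rule."""

    centroids: np.ndarray  # (3, n_peaks), rows = clusters 1, 2, 3
    burden_threshold: float = 0.05

    def __post_init__(self):
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.centroids.shape[0] != 3:
            raise ValueError("expected 3 centroid rows (clusters 1..3)")
        if not 0.0 <= self.burden_threshold <= 1.0:
            raise ValueError("burden_threshold must be in [0, 1]")
        if not np.all(np.isfinite(self.centroids)):
            raise ValueError("non-finite centroid values")


@dataclass
class ClusterAssignment:
    sample_id: str
    cluster: int  # 1, 2 or 3
    similarity: np.ndarray  # Pearson correlation to each centroid
    cin_high: bool = field(init=False)
    forced_by_burden: bool = False
    degenerate: bool = False

    def __post_init__(self):
        self.cin_high = self.cluster != 1


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------

def extract_peak_features(seg: SegmentedCNAProfile,
                          peaks: PeakRegionSet) -> PeakFeatureVector:
    """Bin-length-weighted mean segment log2 ratio over each peak region.

    Peaks with no unmasked overlapping bin get value 0 and are flagged.
    """
    if peaks.n == 0:
        raise ValueError("empty peak region set")
    binvals = seg.bin_values()
    values = np.zeros(peaks.n)
    no_overlap = np.zeros(peaks.n, dtype=bool)
    for i in range(peaks.n):
        sel = ((seg.chrom == peaks.chrom[i])
               & (seg.start < peaks.end[i]) & (seg.end > peaks.start[i])
               & ~seg.mask)
        vals = binvals[sel]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            no_overlap[i] = True
        else:
            values[i] = vals.mean()
    return PeakFeatureVector(seg.sample_id, values, no_overlap=no_overlap)


# ---------------------------------------------------------------------------
# tumor-fraction scaling
# ---------------------------------------------------------------------------

def scale_log2_ratios(log2, tf: float, floor_tf: float = 0.03,
                      min_cn: float = 0.1):
    """Rescale observed log2 ratios to tumor-equivalent values.

    The mixture is inverted in linear copy-number space; tf below
    ``floor_tf`` is clipped to the floor to cap noise amplification, and the
    tumor copy number is floored at ``min_cn`` to keep the log finite.
    """
    if tf is None or not np.isfinite(tf):
        raise ValueError("tumor fraction required for scaling")
    tf = max(float(tf), floor_tf)
    if tf <= 0:
        raise ValueError("tumor fraction must be positive after clipping")
    log2 = np.asarray(log2, dtype=float)
    cn_obs = 2.0 * np.power(2.0, log2)
    cn_tumor = 2.0 + (cn_obs - 2.0) / tf
    return np.log2(np.maximum(cn_tumor, min_cn) / 2.0)


def dilute_log2_ratios(log2, tf: float):
    """Inverse of :func:`scale_log2_ratios` (noiseless round-trip helper)."""
    log2 = np.asarray(log2, dtype=float)
    cn_tumor = 2.0 * np.power(2.0, log2)
    cn_obs = 2.0 + tf * (cn_tumor - 2.0)
    return np.log2(cn_obs / 2.0)


def scale_segmented_profile(seg: SegmentedCNAProfile, tf: float,
                            floor_tf: float = 0.03) -> SegmentedCNAProfile:
    """Apply tumor-fraction scaling to every segment mean."""
    means = np.array([s.mean for s in seg.segments])
    return seg.with_means(scale_log2_ratios(means, tf, floor_tf=floor_tf))


def derive_cohort_scaling_factor(tissue_tfs, plasma_tfs) -> float:
    """Mean plasma/tissue tumor-fraction ratio over matched pairs.

    Used in place of a per-sample tumor fraction when a cohort has no
    matched tissue (validation-cohort mode).
    """
    t = np.asarray(tissue_tfs, dtype=float)
    p = np.asarray(plasma_tfs, dtype=float)
    if t.size == 0 or t.size != p.size:
        raise ValueError("need non-empty paired tumor-fraction lists")
    if np.any(t <= 0):
        raise ValueError("tissue tumor fractions must be positive")
    return float(np.mean(p / t))


# ---------------------------------------------------------------------------
# cluster assignment
# ---------------------------------------------------------------------------

def _pearson_to_centroids(v: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    vc = v - v.mean()
    nv = np.linalg.norm(vc)
    sims = np.full(centroids.shape[0], -np.inf)
    if nv == 0:
        return sims
    for k in range(centroids.shape[0]):
        c = centroids[k] - centroids[k].mean()
        nc = np.linalg.norm(c)
        if nc > 0:
            sims[k] = float(np.dot(vc, c) / (nv * nc))
    return sims


class NearestCentroidCIN(ClassifierMixin, BaseEstimator):
    """Nearest-centroid CIN cluster classifier with a burden override.

    ``fit(X, y)`` learns per-cluster mean centroids from labelled peak
    features (labels in {1, 2, 3}); alternatively build the classifier from
    externally supplied centroids with :meth:`from_centroids` — real-data
    use requires centroids from a tissue-trained classifier, which are not
    re-derived here. ``predict(X, genome_altered_fraction=...)`` forces any
    sample whose genome-altered burden is below ``burden_threshold`` into
    cluster 1 regardless of centroid geometry; otherwise the cluster with
    the highest Pearson correlation wins, ties toward the lower index.
    """

    def __init__(self, burden_threshold: float = 0.05):
        self.burden_threshold = burden_threshold

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if not set(np.unique(y)) <= {1, 2, 3}:
            raise ValueError("labels must be clusters 1, 2, 3")
        cents = np.zeros((3, X.shape[1]))
        for k in (1, 2, 3):
            if np.any(y == k):
                cents[k - 1] = X[y == k].mean(axis=0)
        self.centroids_ = cents
        self.classes_ = np.array([1, 2, 3])
        self.n_features_in_ = X.shape[1]
        return self

    @classmethod
    def from_centroids(cls, centroids: ClusterCentroids) -> "NearestCentroidCIN":
        est = cls(burden_threshold=centroids.burden_threshold)
        est.centroids_ = centroids.centroids
        est.classes_ = np.array([1, 2, 3])
        est.n_features_in_ = centroids.centroids.shape[1]
        return est

    def assign(self, fv: np.ndarray, burden: float,
               sample_id: str = "") -> ClusterAssignment:
        check_is_fitted(self, "centroids_")
        fv = np.asarray(fv, dtype=float)
        if fv.size != self.n_features_in_:
            raise ValueError("feature length does not match centroids")
        sims = _pearson_to_centroids(fv, self.centroids_)
        if burden < self.burden_threshold:
            return ClusterAssignment(sample_id, 1, sims, forced_by_burden=True)
        if not np.any(np.isfinite(sims)):
            warnings.warn(f"zero-variance feature vector for {sample_id!r}; "
                          "falling back to cluster 1")
            return ClusterAssignment(sample_id, 1, sims, degenerate=True)
        best = int(np.argmax(sims)) + 1  # argmax ties -> lower index
        return ClusterAssignment(sample_id, best, sims)

    def predict(self, X, genome_altered_fraction=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if genome_altered_fraction is None:
            burden = np.full(X.shape[0], np.inf)
        else:
            burden = np.broadcast_to(
                np.asarray(genome_altered_fraction, dtype=float), (X.shape[0],))
        return np.array([self.assign(X[i], burden[i]).cluster
                         for i in range(X.shape[0])])


def assign_cluster(fv: PeakFeatureVector, centroids: ClusterCentroids,
                   burden: float) -> ClusterAssignment:
    """Functional wrapper around :class:`NearestCentroidCIN`."""
    est = NearestCentroidCIN.from_centroids(centroids)
    return est.assign(fv.values, burden, sample_id=fv.sample_id)


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

@dataclass
class ConcordanceResult:
    """3x3 plasma-vs-tissue confusion counts plus the two headline rates."""

    matrix: np.ndarray  # counts[plasma cluster - 1][tissue cluster - 1]
    n_total: int
    match_rate: float = field(init=False)
    binary_accuracy: float = field(init=False)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=int)
        if self.matrix.shape != (3, 3) or self.matrix.sum() != self.n_total:
            raise ValueError("confusion counts inconsistent with n_total")
        self.match_rate = float(np.trace(self.matrix)) / self.n_total
        # binary: CIN-high (clusters 2/3) vs CIN-low (cluster 1); both
        # high->low and low->high crossings count as errors
        errors = (self.matrix[0, 1] + self.matrix[0, 2]
                  + self.matrix[1, 0] + self.matrix[2, 0])
        self.binary_accuracy = 1.0 - errors / self.n_total

    def as_frame(self) -> pd.DataFrame:
        idx = [f"P{k}" for k in (1, 2, 3)]
        cols = [f"T{k}" for k in (1, 2, 3)]
        return pd.DataFrame(self.matrix, index=idx, columns=cols)


def concordance(plasma: dict, tissue: dict) -> ConcordanceResult:
    """Confusion matrix between paired plasma and tissue cluster calls.

    Both arguments map sample/patient id -> cluster in {1, 2, 3}; ids must
    pair up exactly, otherwise the offenders are listed in the error.
    """
    p_ids, t_ids = set(plasma), set(tissue)
    if p_ids != t_ids:
        offenders = sorted(p_ids ^ t_ids)
        raise ValueError(f"unpaired sample ids: {offenders}")
    if not plasma:
        raise ValueError("no pairs")
    mat = np.zeros((3, 3), dtype=int)
    for sid in plasma:
        pc, tc = int(plasma[sid]), int(tissue[sid])
        if pc not in (1, 2, 3) or tc not in (1, 2, 3):
            raise ValueError(f"cluster out of range for {sid!r}")
        mat[pc - 1, tc - 1] += 1
    return ConcordanceResult(mat, len(plasma))


def peak_correlation_matrix(features, sample_ids=None) -> pd.DataFrame:
    """Sample-by-sample Spearman matrix of peak feature vectors.

    Rows/columns follow the order given; for a paired cohort pass samples
    alternating tissue and matching plasma so matched pairs sit next to the
    diagonal. Constant feature vectors yield NaN correlations.
    """
    X = np.stack([f.values if isinstance(f, PeakFeatureVector) else np.asarray(f)
                  for f in features])
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    if sample_ids is None:
        sample_ids = [getattr(f, "sample_id", str(i))
                      for i, f in enumerate(features)]
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                rho, _ = spearman(X[i], X[j])
            except ValueError:
                rho = np.nan
            mat[i, j] = mat[j, i] = rho
    for i in range(n):
        if np.all(X[i] == X[i][0]):
            mat[i, i] = np.nan
    return pd.DataFrame(mat, index=sample_ids, columns=sample_ids)
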