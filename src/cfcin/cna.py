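"""Binned copy-number profiling of low-coverage WGS read counts.

The stages here are deliberately simple, documented analogues of the
panel-of-normals pipelines used for plasma copy-number calling: a healthy
reference panel (per-bin median/MAD of depth-normalized counts), log2-ratio
normalization against that panel, recursive binary segmentation, and a
grid-search tumor-fraction fit under the two-component mixture model

    expected ratio = (2 * (1 - tf) + tf * CN) / 2

where CN is the integer tumor copy number of a segment and tf the fraction
of cell-free DNA contributed by tumor cells. No allele-specific or HMM
modelling is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "BinnedCoverageProfile",
    "ReferencePanel",
    "LogRatioProfile",
    "Segment",
    "SegmentedCNAProfile",
    "TumorFractionEstimate",
    "PanelNormalizer",
    "build_reference_panel",
    "normalize_profile",
    "segment_profile",
    "estimate_tumor_fraction",
]

_MIN_RATIO = 0.01  # floor on the modelled mixture ratio, keeps log2 finite


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class BinnedCoverageProfile:
    """Raw read counts on a fixed genomic bin grid (0-based half-open)."""

    sample_id: str
    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    counts: np.ndarray
    gc: np.ndarray | None = None

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom)
        self.start = np.asarray(self.start, dtype=int)
        self.end = np.asarray(self.end, dtype=int)
        self.counts = np.asarray(self.counts)
        n = len(self.chrom)
        if not (len(self.start) == len(self.end) == len(self.counts) == n):
            raise ValueError("bin arrays must have equal length")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        if np.any(self.end <= self.start):
            raise ValueError("empty or inverted bins")
        # sorted, non-overlapping within each chromosome
        for c in np.unique(self.chrom):
            idx = np.nonzero(self.chrom == c)[0]
            s, e = self.start[idx], self.end[idx]
            if np.any(np.diff(s) <= 0) or np.any(s[1:] < e[:-1]):
                raise ValueError(f"bins on {c} not sorted/non-overlapping")

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def total_reads(self) -> int:
        return int(self.counts.sum())

    def same_grid(self, other: "BinnedCoverageProfile") -> bool:
        return (self.n_bins == other.n_bins
                and bool(np.all(self.chrom == other.chrom))
                and bool(np.all(self.start == other.start))
                and bool(np.all(self.end == other.end)))


@dataclass
class ReferencePanel:
    """Healthy-control panel: per-bin location/scale of normalized depth."""

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    location: np.ndarray  # median of depth-normalized counts
    scale: np.ndarray     # MAD
    blacklist: np.ndarray  # True = excluded from downstream statistics
    sample_ids: list

    @property
    def n_bins(self) -> int:
        return len(self.location)


@dataclass
class LogRatioProfile:
    """Per-bin log2 ratio vs the panel; masked bins carry NaN."""

    sample_id: str
    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    log2: np.ndarray
    z: np.ndarray
    mask: np.ndarray  # True = masked/blacklisted


@dataclass
class Segment:
    chrom: str
    start_bin: int  # global bin index, half-open
    end_bin: int
    mean: float
    n_bins: int  # unmasked bins contributing


@dataclass
class SegmentedCNAProfile:
    """Piecewise-constant summary of a log-ratio profile.

    Segments partition the unmasked bins; the bin grid is retained so peak
    features can be extracted in genomic coordinates later.
    """

    sample_id: str
    segments: list
    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    mask: np.ndarray
    calling_threshold: float = 0.1

    @property
    def n_unmasked(self) -> int:
        return int((~self.mask).sum())

    def bin_values(self) -> np.ndarray:
        """Per-bin segment means (NaN on masked bins)."""
        v = np.full(len(self.chrom), np.nan)
        for seg in self.segments:
            idx = np.arange(seg.start_bin, seg.end_bin)
            idx = idx[~self.mask[idx]]
            v[idx] = seg.mean
        return v

    def genome_altered_fraction(self, threshold: float | None = None) -> float:
        """Fraction of unmasked bins in segments with |mean| > threshold."""
        thr = self.calling_threshold if threshold is None else threshold
        altered = sum(s.n_bins for s in self.segments if abs(s.mean) > thr)
        total = sum(s.n_bins for s in self.segments)
        return altered / total if total else 0.0

    def with_means(self, new_means) -> "SegmentedCNAProfile":
        segs = [Segment(s.chrom, s.start_bin, s.end_bin, float(m), s.n_bins)
                for s, m in zip(self.segments, new_means)]
        return SegmentedCNAProfile(self.sample_id, segs, self.chrom,
                                   self.start, self.end, self.mask,
                                   self.calling_threshold)


@dataclass
class TumorFractionEstimate:
    sample_id: str
    tf: float
    fit_error: float
    segment_cn: np.ndarray = field(default_factory=lambda: np.array([]))


# ---------------------------------------------------------------------------
# panel normalization
# ---------------------------------------------------------------------------

class PanelNormalizer(TransformerMixin, BaseEstimator):
    """Reference-panel normalizer for binned read counts.

    ``fit`` takes a (n_samples, n_bins) matrix of healthy-control counts,
    depth-normalizes each row and stores the per-bin median (location) and
    MAD (scale). Bins with zero median, or MAD above ``mad_outlier_factor``
    times the median MAD, are blacklisted. ``transform`` maps count rows to
    log2 ratios against the panel location (NaN on blacklisted bins).
    """

    def __init__(self, mad_outlier_factor: float = 5.0):
        self.mad_outlier_factor = mad_outlier_factor

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 3:
            raise ValueError("need a (n_samples >= 3, n_bins) count matrix")
        depth = X.sum(axis=1, keepdims=True)
        if np.any(depth == 0):
            raise ValueError("panel sample with zero total count")
        N = X / depth
        self.location_ = np.median(N, axis=0)
        self.scale_ = np.median(np.abs(N - self.location_), axis=0)
        positive = self.scale_[self.scale_ > 0]
        mad_cut = (self.mad_outlier_factor * np.median(positive)
                   if positive.size else np.inf)
        self.blacklist_ = (self.location_ == 0) | (self.scale_ > mad_cut)
        self.n_features_in_ = X.shape[1]
        return self

    def _ratios(self, X):
        check_is_fitted(self, "location_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError("bin grid mismatch with panel")
        keep = ~self.blacklist_
        depth = X[:, keep].sum(axis=1, keepdims=True)
        if np.any(depth == 0):
            raise ValueError("sample with zero counts on unmasked bins")
        norm = X / depth  # normalized over unmasked bins
        ref = self.location_ / self.location_[keep].sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = norm / ref
        # within-sample recentering: total-count normalization is inflated
        # by net copy-number gain, so pin the median (assumed-diploid) bin
        # ratio at 1 and rescale the sample accordingly
        med = np.nanmedian(ratio[:, keep], axis=1, keepdims=True)
        med[~np.isfinite(med) | (med == 0)] = 1.0
        ratio = ratio / med
        norm = norm / med
        ratio[:, self.blacklist_] = np.nan
        return ratio, norm, ref

    def transform(self, X):
        ratio, _, _ = self._ratios(X)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.log2(ratio)

    def zscores(self, X):
        _, norm, ref = self._ratios(X)
        scale = self.scale_ / self.location_[~self.blacklist_].sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (norm - ref) / scale
        z[:, self.blacklist_ | (self.scale_ == 0)] = np.nan
        return z


def build_reference_panel(healthy_profiles, mad_outlier_factor: float = 5.0
                          ) -> ReferencePanel:
    """Build a ReferencePanel from >= 3 healthy profiles on one bin grid."""
    if len(healthy_profiles) < 3:
        raise ValueError("need at least 3 healthy profiles")
    first = healthy_profiles[0]
    for p in healthy_profiles[1:]:
        if not first.same_grid(p):
            raise ValueError(f"bin grid mismatch for sample {p.sample_id}")
    X = np.stack([p.counts for p in healthy_profiles]).astype(float)
    norm = PanelNormalizer(mad_outlier_factor=mad_outlier_factor).fit(X)
    return ReferencePanel(first.chrom, first.start, first.end,
                          norm.location_, norm.scale_, norm.blacklist_,
                          [p.sample_id for p in healthy_profiles])


def normalize_profile(sample: BinnedCoverageProfile,
                      panel: ReferencePanel) -> LogRatioProfile:
    """Depth-normalize a sample and express it as log2 ratio vs the panel."""
    if sample.n_bins != panel.n_bins or not np.all(sample.chrom == panel.chrom) \
            or not np.all(sample.start == panel.start):
        raise ValueError("sample not on the panel's bin grid")
    if sample.counts.sum() == 0:
        raise ValueError("all-zero sample")
    norm = PanelNormalizer()
    norm.location_ = panel.location
    norm.scale_ = panel.scale
    norm.blacklist_ = panel.blacklist
    norm.n_features_in_ = panel.n_bins
    log2 = norm.transform(sample.counts[None, :])[0]
    z = norm.zscores(sample.counts[None, :])[0]
    return LogRatioProfile(sample.sample_id, panel.chrom, panel.start,
                           panel.end, log2, z, panel.blacklist.copy())


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def _best_split(v: np.ndarray, min_bins: int):
    """Best interior interval of ``v`` by the two-sample t-like statistic.

    Scans every interval [i, j) (interior vs the rest of the segment, so
    plain prefix/suffix splits are the i=0 / j=m special cases) and returns
    ((i, j), statistic). Fully vectorized via prefix sums; intervals whose
    non-empty parts would fall below ``min_bins`` are excluded.
    """
    m = v.size
    if m < 2 * min_bins:
        return None, 0.0
    cs = np.r_[0.0, np.cumsum(v)]
    cs2 = np.r_[0.0, np.cumsum(v * v)]
    i = np.arange(m + 1)
    sum_in = cs[None, :] - cs[:, None]        # [i, j] -> sum of v[i:j]
    sq_in = cs2[None, :] - cs2[:, None]
    n_in = (i[None, :] - i[:, None]).astype(float)
    n_out = m - n_in
    valid = (n_in >= min_bins) & (n_out >= min_bins)
    # each resulting flank must be empty or at least min_bins long
    left = i[:, None] * np.ones((1, m + 1), dtype=int)
    right = m - i[None, :] * np.ones((m + 1, 1), dtype=int)
    valid &= (left == 0) | (left >= min_bins)
    valid &= (right == 0) | (right >= min_bins)
    with np.errstate(divide="ignore", invalid="ignore"):
        m_in = sum_in / n_in
        m_out = (cs[-1] - sum_in) / n_out
        ss_in = sq_in - n_in * m_in * m_in
        ss_out = (cs2[-1] - sq_in) - n_out * m_out * m_out
        sp2 = (ss_in + ss_out) / (m - 2)
        t = np.abs(m_in - m_out) / np.sqrt(sp2 * (1.0 / n_in + 1.0 / n_out))
        t = np.where(sp2 <= 0,
                     np.where(np.abs(m_in - m_out) > 0, np.inf, 0.0), t)
    t[~valid] = -np.inf
    if not np.any(valid):
        return None, 0.0
    flat = int(np.nanargmax(t))
    bi, bj = divmod(flat, m + 1)
    return (int(bi), int(bj)), float(t[bi, bj])


def _segment_array(v: np.ndarray, min_bins: int, threshold: float):
    """Recursive segmentation; yields (start, end) pairs in array index.

    Each accepted interval splits the segment into up to three parts
    (left flank, interior, right flank), all recursed on.
    """
    out = []
    stack = [(0, v.size)]
    while stack:
        a, b = stack.pop()
        res, t = _best_split(v[a:b], min_bins)
        if res is not None and t > threshold:
            i, j = res
            for lo, hi in ((a, a + i), (a + i, a + j), (a + j, b)):
                if hi > lo:
                    stack.append((lo, hi))
        else:
            out.append((a, b))
    return sorted(out)


def segment_profile(lrp: LogRatioProfile, min_segment_bins: int = 5,
                    split_threshold: float = 5.0,
                    calling_threshold: float = 0.1) -> SegmentedCNAProfile:
    """Segment a log-ratio profile chromosome by chromosome.

    Recursive binary splitting: within a segment the split maximizing a
    two-sample t statistic is accepted when it exceeds ``split_threshold``
    and both halves keep at least ``min_segment_bins`` unmasked bins.
    """
    segments = []
    for c in _ordered_unique(lrp.chrom):
        cidx = np.nonzero(lrp.chrom == c)[0]
        unmasked = cidx[~lrp.mask[cidx]]
        if unmasked.size == 0:
            continue
        if unmasked.size < min_segment_bins:
            raise ValueError(f"fewer than {min_segment_bins} usable bins on {c}")
        v = lrp.log2[unmasked]
        for a, b in _segment_array(v, min_segment_bins, split_threshold):
            gbins = unmasked[a:b]
            segments.append(Segment(str(c), int(gbins[0]), int(gbins[-1]) + 1,
                                    float(v[a:b].mean()), int(b - a)))
    if not segments:
        raise ValueError("no usable bins to segment")
    return SegmentedCNAProfile(lrp.sample_id, segments, lrp.chrom, lrp.start,
                               lrp.end, lrp.mask, calling_threshold)


def _ordered_unique(arr):
    seen, out = set(), []
    for x in arr:
        if x not in seen:
            seen.add(x)
            out.append(x)
    return out


# ---------------------------------------------------------------------------
# tumor fraction
# ---------------------------------------------------------------------------

def mixture_log2_ratio(tf: float, cn, min_ratio: float = _MIN_RATIO):
    """Expected log2 ratio of a segment with tumor copy number ``cn``."""
    ratio = (2.0 * (1.0 - tf) + tf * np.asarray(cn, dtype=float)) / 2.0
    return np.log2(np.maximum(ratio, min_ratio))


def estimate_tumor_fraction(seg: SegmentedCNAProfile, tf_grid=None,
                            cn_states=(0, 1, 2, 3, 4),
                            neutral_margin: float = 0.02
                            ) -> TumorFractionEstimate:
    """Grid-search mixture fit of the tumor fraction.

    For each candidate tf every segment is assigned the integer copy number
    minimizing the squared deviation from the mixture prediction; the tf
    minimizing the bin-weighted error wins, with near-ties (relative 1e-9)
    resolved toward the smallest tf to avoid purity/ploidy aliasing.
    Profiles with no segment beyond ``neutral_margin`` return tf = 0.
    """
    if not seg.segments:
        raise ValueError("no segments")
    if tf_grid is None:
        tf_grid = np.round(np.arange(0.01, 1.0001, 0.01), 10)
    tf_grid = np.asarray(tf_grid, dtype=float)
    if tf_grid.size == 0:
        raise ValueError("empty tf grid")
    if np.any(tf_grid <= 0) or np.any(tf_grid > 1):
        raise ValueError("tf grid must lie in (0, 1]")
    cn_states = np.asarray(cn_states, dtype=float)
    if np.any(cn_states < 0):
        raise ValueError("negative copy-number state")

    means = np.array([s.mean for s in seg.segments])
    weights = np.array([s.n_bins for s in seg.segments], dtype=float)

    if np.all(np.abs(means) <= neutral_margin):
        return TumorFractionEstimate(seg.sample_id, 0.0, 0.0,
                                     np.full(means.size, 2, dtype=int))

    # model[t, c] = predicted log2 ratio at tf_grid[t] for cn_states[c]
    model = mixture_log2_ratio(tf_grid[:, None], cn_states[None, :])
    # residuals: (tf, segment, cn)
    resid = (means[None, :, None] - model[:, None, :]) ** 2
    best_cn_idx = np.argmin(resid, axis=2)
    seg_err = np.take_along_axis(resid, best_cn_idx[:, :, None], axis=2)[:, :, 0]
    total = seg_err @ weights

    emin = total.min()
    candidates = np.nonzero(total <= emin * (1.0 + 1e-9) + 1e-300)[0]
    pick = int(candidates.min())  # smallest tf among near-ties
    cn = cn_states[best_cn_idx[pick]].astype(int)
    return TumorFractionEstimate(seg.sample_id, float(tf_grid[pick]),
                                 float(total[pick]), cn)
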