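"""Nucleosome footprint profiles and the 0-1 deviation score.

cfDNA fragmentation preferentially starts in linker regions, so the
distribution of signed distances from fragment starts to the nearest
nucleosome center is M-shaped in healthy plasma (modes near +/-73 bp, a dip
at the dyad). Tumor-derived cfDNA is relatively enriched at nucleosome
centers, flattening the M. A sample's profile is summarized by projecting
it onto the healthy->tumor axis:

    score = <s - h, m - h> / <m - h, m - h>

which is exactly 0 at the healthy reference profile h and exactly 1 at the
tumor reference m. Scores outside [0, 1] are permitted (and flagged by
callers if needed) rather than truncated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .stats import spearman

__all__ = [
    "NucleosomeTrack",
    "DistanceProfile",
    "NucleosomeScore",
    "distance_profile",
    "reference_profiles",
    "NucleosomeScorer",
    "nucleosome_score",
    "score_tf_correlation",
]


@dataclass
class NucleosomeTrack:
    """Sorted, unique nucleosome center coordinates per chromosome."""

    centers: dict  # chrom -> np.ndarray of 0-based positions

    def __post_init__(self):
        clean = {}
        for c, pos in self.centers.items():
            arr = np.unique(np.asarray(pos, dtype=np.int64))
            if arr.size:
                clean[c] = arr
        self.centers = clean
        if not self.centers:
            raise ValueError("empty nucleosome track")

    @property
    def n_centers(self) -> int:
        return sum(v.size for v in self.centers.values())


@dataclass
class DistanceProfile:
    """Histogram of signed read-start-to-nearest-center distances."""

    edges: np.ndarray     # bin edges, length n_bins + 1
    fractions: np.ndarray  # sums to 1 over in-window reads
    n_reads: int
    n_excluded: int = 0

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.n_reads <= 0:
            raise ValueError("profile with no in-window reads")

    def same_binning(self, other: "DistanceProfile") -> bool:
        return (self.edges.size == other.edges.size
                and bool(np.allclose(self.edges, other.edges)))


@dataclass
class NucleosomeScore:
    sample_id: str
    score: float
    out_of_range: bool = False


def signed_distances(read_starts: dict, track: NucleosomeTrack) -> np.ndarray:
    """Signed distance (read - center) to the nearest nucleosome center.

    Equidistant ties break toward the upstream (smaller-coordinate) center,
    giving a positive distance.
    """
    out = []
    for c, pos in read_starts.items():
        pos = np.asarray(pos, dtype=np.int64)
        if pos.size == 0:
            continue
        if c not in track.centers:
            continue
        centers = track.centers[c]
        idx = np.searchsorted(centers, pos)
        left = centers[np.clip(idx - 1, 0, centers.size - 1)]
        right = centers[np.clip(idx, 0, centers.size - 1)]
        dl = np.abs(pos - left)
        dr = np.abs(pos - right)
        # tie (dl == dr) -> upstream center wins
        nearest = np.where(dl <= dr, left, right)
        out.append(pos - nearest)
    if not out:
        raise ValueError("no reads on chromosomes covered by the track")
    return np.concatenate(out)


def distance_profile(read_starts: dict, track: NucleosomeTrack,
                     window: int = 300, bin_width: int = 10) -> DistanceProfile:
    """Histogram the signed distances into fixed-width bins over +/-window.

    Reads farther than ``window`` from any center are excluded and counted.
    """
    d = signed_distances(read_starts, track)
    keep = np.abs(d) <= window
    n_in = int(keep.sum())
    if n_in == 0:
        raise ValueError("no reads within the window")
    edges = np.arange(-window, window + bin_width, bin_width, dtype=float)
    counts, _ = np.histogram(d[keep], bins=edges)
    return DistanceProfile(edges, counts / n_in, n_in,
                           n_excluded=int((~keep).sum()))


def reference_profiles(healthy_profiles, tumor_profiles):
    """Mean healthy and mean tumor reference profiles (renormalized)."""
    if not healthy_profiles or not tumor_profiles:
        raise ValueError("need at least one profile per group")

    def mean_profile(profiles):
        first = profiles[0]
        for p in profiles[1:]:
            if not first.same_binning(p):
                raise ValueError("distance-profile binning mismatch")
        f = np.mean([p.fractions for p in profiles], axis=0)
        f = f / f.sum()
        return DistanceProfile(first.edges, f,
                               int(sum(p.n_reads for p in profiles)))

    return mean_profile(healthy_profiles), mean_profile(tumor_profiles)


class NucleosomeScorer(TransformerMixin, BaseEstimator):
    """Projection scorer onto the healthy -> tumor profile axis.

    ``fit(profiles, labels)`` takes distance profiles with binary labels
    (0 = healthy reference sample, 1 = tumor reference sample) and stores
    the two mean reference profiles. ``transform`` maps profiles to scalar
    scores anchored at 0 (healthy mean) and 1 (tumor mean). The projection
    is invariant to adding a constant to all bins of every profile.
    """

    def fit(self, profiles, labels):
        labels = np.asarray(labels, dtype=int)
        healthy = [p for p, y in zip(profiles, labels) if y == 0]
        tumor = [p for p, y in zip(profiles, labels) if y == 1]
        if not healthy or not tumor:
            raise ValueError("need at least one profile per class")
        first = healthy[0]
        for p in healthy[1:] + tumor:
            if not first.same_binning(p):
                raise ValueError("distance-profile binning mismatch")
        # plain (un-renormalized) means keep the projection exactly
        # invariant to a constant shift of all bins
        h = DistanceProfile(first.edges,
                            np.mean([p.fractions for p in healthy], axis=0),
                            int(sum(p.n_reads for p in healthy)))
        m = DistanceProfile(first.edges,
                            np.mean([p.fractions for p in tumor], axis=0),
                            int(sum(p.n_reads for p in tumor)))
        self.healthy_ref_ = h
        self.tumor_ref_ = m
        axis = m.fractions - h.fractions
        norm2 = float(np.dot(axis, axis))
        if norm2 == 0:
            raise ValueError("healthy and tumor references coincide "
                             "(zero-norm axis)")
        self.axis_ = axis
        self.axis_norm2_ = norm2
        return self

    def score_profile(self, profile: DistanceProfile,
                      sample_id: str = "") -> NucleosomeScore:
        check_is_fitted(self, "axis_")
        if not profile.same_binning(self.healthy_ref_):
            raise ValueError("binning mismatch with reference profiles")
        s = float(np.dot(profile.fractions - self.healthy_ref_.fractions,
                         self.axis_) / self.axis_norm2_)
        return NucleosomeScore(sample_id, s, out_of_range=not 0.0 <= s <= 1.0)

    def transform(self, profiles):
        return np.array([self.score_profile(p).score for p in profiles])


def nucleosome_score(sample: DistanceProfile, healthy_ref: DistanceProfile,
                     tumor_ref: DistanceProfile,
                     sample_id: str = "") -> NucleosomeScore:
    """Functional wrapper: score one profile against explicit references."""
    scorer = NucleosomeScorer().fit([healthy_ref, tumor_ref], [0, 1])
    return scorer.score_profile(sample, sample_id=sample_id)


def score_tf_correlation(scores, tumor_fractions):
    """Spearman correlation between nucleosome scores and tumor fractions."""
    scores = np.asarray(scores, dtype=float)
    tf = np.asarray(tumor_fractions, dtype=float)
    if scores.size != tf.size or scores.size < 3:
        raise ValueError("need >= 3 paired observations")
    return spearman(scores, tf)
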