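"""Per-sample analysis chain and cohort-level orchestration.

One binned-count profile flows through: panel normalization -> recursive
segmentation -> grid tumor-fraction fit -> tumor-content scaling -> peak
feature extraction -> CIN cluster assignment. The unscaled assignment is
kept alongside the scaled one so the effect of the scaling step on
plasma/tissue concordance can be measured directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cin import (ClusterCentroids, NearestCentroidCIN, PeakRegionSet,
                  concordance, extract_peak_features, scale_segmented_profile)
from .cna import (BinnedCoverageProfile, ReferencePanel, build_reference_panel,
                  estimate_tumor_fraction, normalize_profile, segment_profile)

__all__ = ["SampleResult", "analyze_profile", "classify_cohort",
           "cohort_concordance"]


@dataclass
class SampleResult:
    sample_id: str
    tf: float
    fit_error: float
    burden_raw: float
    burden_scaled: float
    cluster_raw: int
    cluster_scaled: int
    cin_high_raw: bool
    cin_high_scaled: bool


def analyze_profile(profile: BinnedCoverageProfile, panel: ReferencePanel,
                    peaks: PeakRegionSet, centroids: ClusterCentroids,
                    min_segment_bins: int = 5, split_threshold: float = 5.0,
                    calling_threshold: float = 0.1,
                    floor_tf: float = 0.03,
                    tf_override: float | None = None) -> SampleResult:
    """Run the full per-sample chain; ``tf_override`` replaces the fitted
    tumor fraction (cohort-scaling-factor mode for unmatched cohorts)."""
    lrp = normalize_profile(profile, panel)
    seg = segment_profile(lrp, min_segment_bins=min_segment_bins,
                          split_threshold=split_threshold,
                          calling_threshold=calling_threshold)
    est = estimate_tumor_fraction(seg)
    tf = est.tf if tf_override is None else float(tf_override)

    clf = NearestCentroidCIN.from_centroids(centroids)
    feats_raw = extract_peak_features(seg, peaks)
    burden_raw = seg.genome_altered_fraction()
    a_raw = clf.assign(feats_raw.values, burden_raw, profile.sample_id)

    seg_scaled = scale_segmented_profile(seg, tf, floor_tf=floor_tf)
    feats_scaled = extract_peak_features(seg_scaled, peaks)
    burden_scaled = seg_scaled.genome_altered_fraction()
    a_scaled = clf.assign(feats_scaled.values, burden_scaled,
                          profile.sample_id)

    return SampleResult(profile.sample_id, tf, est.fit_error, burden_raw,
                        burden_scaled, a_raw.cluster, a_scaled.cluster,
                        a_raw.cin_high, a_scaled.cin_high)


def classify_cohort(cohort, panel: ReferencePanel | None = None
                    ) -> pd.DataFrame:
    """Classify every tissue and plasma sample of a synthetic cohort.

    Returns one row per patient with tumor-fraction estimates and the
    scaled/unscaled cluster calls for both specimen types.
    """
    if panel is None:
        panel = build_reference_panel(cohort.healthy_profiles())
    rows = []
    for i, pid in enumerate(cohort.truth.patient_id):
        res = {}
        for kind in ("tissue", "plasma"):
            res[kind] = analyze_profile(cohort.profile(i, kind), panel,
                                        cohort.peaks, cohort.centroids)
        rows.append({
            "patient_id": pid,
            "true_cluster": int(cohort.truth.cluster.iloc[i]),
            "tissue_tf_true": float(cohort.truth.tissue_tf.iloc[i]),
            "plasma_tf_true": float(cohort.truth.plasma_tf.iloc[i]),
            "tissue_tf_est": res["tissue"].tf,
            "plasma_tf_est": res["plasma"].tf,
            "tissue_cluster": res["tissue"].cluster_scaled,
            "plasma_cluster": res["plasma"].cluster_scaled,
            "tissue_cluster_unscaled": res["tissue"].cluster_raw,
            "plasma_cluster_unscaled": res["plasma"].cluster_raw,
        })
    return pd.DataFrame(rows)


def cohort_concordance(calls: pd.DataFrame, scaled: bool = True):
    """Plasma-vs-tissue concordance from a ``classify_cohort`` table."""
    suffix = "" if scaled else "_unscaled"
    plasma = dict(zip(calls.patient_id, calls["plasma_cluster" + suffix]))
    tissue = dict(zip(calls.patient_id, calls["tissue_cluster" + suffix]))
    return concordance(plasma, tissue)
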