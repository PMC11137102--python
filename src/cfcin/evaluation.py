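"""End-to-end benchmark experiments on synthetic cohorts.

Each function here sets up a study condition, runs the package's own
machinery on it and returns the headline numbers: worked examples with
closed-form answers (cohort sizing, published confusion tables, QC
counting) and simulation experiments (tumor-fraction recovery, the benefit
of tumor-content scaling, nucleosome score anchors, methylation mixture
inversion, survival-model parameter recovery). ``scripts/acceptance.py``
re-runs all of them from a single seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import methylation as meth
from . import stats
from .cin import concordance
from .cna import build_reference_panel
from .nucleosome import (DistanceProfile, NucleosomeScorer, distance_profile,
                         reference_profiles)
from .pipeline import analyze_profile, classify_cohort
from .simulate import (BimodalOffsets, CenterOffsets, CohortConfig,
                       generate_nucleosome_track, simulate_binned_reads,
                       simulate_cohort, simulate_fragment_starts,
                       simulate_survival)

__all__ = [
    "CALLER_CONFUSION_TABLES",
    "binomial_sample_size_summary",
    "concordance_benchmarks",
    "qc_worked_example",
    "tf_recovery_experiment",
    "scaling_benefit_experiment",
    "nucleosome_experiment",
    "methylation_experiment",
    "survival_recovery_experiment",
]


# 3x3 plasma-vs-tissue confusion counts for 52 matched pairs, as reported
# for three copy-number callers in the trial cohort this package models.
# counts[plasma cluster - 1][tissue cluster - 1].
CALLER_CONFUSION_TABLES = {
    "ascat": np.array([[9, 8, 9],
                       [4, 3, 8],
                       [5, 2, 4]]),
    "ichorcna": np.array([[2, 6, 9],
                          [3, 10, 4],
                          [0, 4, 14]]),
    "wisecondorx": np.array([[3, 4, 0],
                             [0, 15, 6],
                             [0, 5, 19]]),
}


def _pairs_from_confusion(mat: np.ndarray):
    """Expand a confusion table into paired per-sample cluster calls."""
    plasma, tissue = {}, {}
    k = 0
    for p in range(3):
        for t in range(3):
            for _ in range(int(mat[p, t])):
                sid = f"S{k:03d}"
                plasma[sid] = p + 1
                tissue[sid] = t + 1
                k += 1
    return plasma, tissue


def binomial_sample_size_summary() -> dict:
    """Cohort sizing for detecting at least one CIN-low (p=0.1) patient."""
    n95 = stats.min_samples_binomial(0.1, 0.95)
    conf24 = stats.confidence_at_n(0.1, 24)
    return {
        "min_n_for_95pct_cluster1": n95,
        "confidence_pct_at_n24": round(conf24 * 100.0),
        "confidence_at_min_n": stats.confidence_at_n(0.1, n95),
    }


def concordance_benchmarks() -> dict:
    """Headline rates recomputed from the published confusion tables."""
    out = {}
    for caller, mat in CALLER_CONFUSION_TABLES.items():
        res = concordance(*_pairs_from_confusion(mat))
        out[caller] = res
    wx = out["wisecondorx"]
    n = wx.n_total
    return {
        "ascat_match_rate_pct": out["ascat"].match_rate * 100.0,
        "ichorcna_match_rate_pct": out["ichorcna"].match_rate * 100.0,
        "wisecondorx_match_rate_pct": wx.match_rate * 100.0,
        "wisecondorx_binary_accuracy_pct": wx.binary_accuracy * 100.0,
        "p1_t2_error_pct": wx.matrix[0, 1] / n * 100.0,
        "p2_t3_error_pct": wx.matrix[1, 2] / n * 100.0,
        "n_pairs": n,
    }


def qc_worked_example() -> dict:
    """122-sample methylation cohort: 1 conversion + 22 coverage failures."""
    records = []
    for i in range(122):
        conv, cov = 0.985, 40.0
        if i == 0:
            conv = 0.93          # the single conversion failure
        elif 1 <= i <= 22:
            cov = 6.0            # the 22 coverage failures
        records.append(meth.SampleQCRecord(f"M{i:03d}", conv, cov))
    retained, report = meth.qc_filter(records)
    return {"n_input": 122, "n_retained": len(retained), "report": report}


# ---------------------------------------------------------------------------
# simulation experiments
# ---------------------------------------------------------------------------

def tf_recovery_experiment(seed: int, n_samples: int = 100) -> dict:
    """Recover known tumor fractions (0.1-0.5) across cluster archetypes.

    Samples are drawn from the default archetypes with the default cluster
    mix and uniform tumor fractions, run through the panel/segmentation/
    grid-fit chain, and compared with the generating truth.
    """
    config = CohortConfig(n_patients=n_samples,
                          tissue_tf_range=(0.1, 0.5),
                          cluster1_tf_factor=1.0,   # keep all tf >= 0.1
                          plasma_to_tissue_tf_ratio=1.0,
                          seed=seed)
    cohort = simulate_cohort(config)
    panel = build_reference_panel(cohort.healthy_profiles())
    est = np.array([
        analyze_profile(cohort.profile(i, "tissue"), panel, cohort.peaks,
                        cohort.centroids).tf
        for i in range(n_samples)])
    true = cohort.truth.tissue_tf.to_numpy()
    rmse = float(np.sqrt(np.mean((est - true) ** 2)))
    rho, _ = stats.spearman(est, true)
    return {"tf_rmse": rmse, "tf_spearman_rho": rho, "n": n_samples}


def scaling_benefit_experiment(seed: int, n_pairs: int = 60) -> dict:
    """Tumor-content scaling on a low-plasma-burden paired cohort.

    Tissue tumor fractions are 0.3-0.5 while plasma fractions are diluted
    to 0.03-0.1, the regime where unscaled plasma profiles collapse toward
    cluster 1. Reports binary CIN-high accuracy of the plasma calls before
    and after scaling, and the tissue cluster recovery rate.
    """
    rng = np.random.default_rng(seed)
    config = CohortConfig(n_patients=n_pairs,
                          tissue_tf_range=(0.3, 0.5),
                          cluster1_tf_factor=1.0,
                          plasma_to_tissue_tf_ratio=0.2,
                          seed=seed + 1)
    cohort = simulate_cohort(config)
    # re-draw plasma at per-patient dilutions in [0.03, 0.1]
    plasma_tf = rng.uniform(0.03, 0.1, size=n_pairs)
    plasma_counts = np.stack([
        simulate_binned_reads(cohort.field_notes["patient_templates"][i],
                              plasma_tf[i], config.reads_per_sample, rng,
                              gc_factor=cohort.grid["gc_factor"],
                              dispersion=config.dispersion)
        for i in range(n_pairs)])
    cohort.plasma_counts = plasma_counts
    cohort.truth["plasma_tf"] = plasma_tf

    calls = classify_cohort(cohort)
    truth_high = cohort.truth.cin_high.to_numpy()
    plasma_high_scaled = calls.plasma_cluster.to_numpy() != 1
    plasma_high_raw = calls.plasma_cluster_unscaled.to_numpy() != 1
    tissue_ok = (calls.tissue_cluster.to_numpy()
                 == calls.true_cluster.to_numpy())
    return {
        "binary_accuracy_before_scaling_pct":
            float(np.mean(plasma_high_raw == truth_high)) * 100.0,
        "binary_accuracy_after_scaling_pct":
            float(np.mean(plasma_high_scaled == truth_high)) * 100.0,
        "tissue_cluster_recovery_pct": float(np.mean(tissue_ok)) * 100.0,
        "n": n_pairs,
    }


def nucleosome_experiment(seed: int, n_samples: int = 74) -> dict:
    """Score anchors and the score-vs-mixture-weight rank correlation.

    The anchors (healthy reference -> 0, tumor reference -> 1, arithmetic
    50/50 mixture -> 0.5) are exact properties of the projection score; the
    cohort part draws the default 74 noisy plasma samples and correlates
    their scores with the generating mixture weights.
    """
    rng = np.random.default_rng(seed)
    config = CohortConfig(n_patients=n_samples, seed=seed)
    track = generate_nucleosome_track(config, rng)
    healthy_dist, tumor_dist = BimodalOffsets(), CenterOffsets()

    def profile_at(weight, n_frag=200_000):
        frags = simulate_fragment_starts(weight, n_frag, track, healthy_dist,
                                         tumor_dist, rng)
        return distance_profile(frags, track)

    h_ref, m_ref = reference_profiles(
        [profile_at(0.0) for _ in range(5)],
        [profile_at(1.0) for _ in range(5)])
    scorer = NucleosomeScorer().fit([h_ref, m_ref], [0, 1])
    s_h = scorer.score_profile(h_ref).score
    s_m = scorer.score_profile(m_ref).score
    halfmix = DistanceProfile(h_ref.edges,
                              0.5 * h_ref.fractions + 0.5 * m_ref.fractions,
                              h_ref.n_reads)
    s_half = scorer.score_profile(halfmix).score

    cohort = simulate_cohort(config)
    scorer_c = NucleosomeScorer().fit(
        [distance_profile(f, cohort.track)
         for f in cohort.healthy_ref_fragments + cohort.tumor_ref_fragments],
        [0] * len(cohort.healthy_ref_fragments)
        + [1] * len(cohort.tumor_ref_fragments))
    scores = scorer_c.transform(
        [distance_profile(f, cohort.track) for f in cohort.plasma_fragments])
    rho, p = stats.spearman(scores, cohort.truth.nuc_weight.to_numpy())
    return {
        "score_healthy_ref": s_h,
        "score_tumor_ref": s_m,
        "score_half_mixture": s_half,
        "score_weight_spearman_rho": rho,
        "score_weight_spearman_p": p,
        "n": n_samples,
    }


def methylation_experiment(seed: int, n_patients: int = 500) -> dict:
    """Mixture inversion exactness and post-normalization independence.

    A noiseless cohort checks that tumor-content normalization exactly
    recovers the tumor-component betas. A noisy cohort then trains the
    random-forest score on normalized pre-treatment vs healthy betas,
    scores the normalized on-treatment samples, and verifies that the score
    delta carries no residual rank correlation with the tumor-fraction
    change. The baseline (unnormalized) score's ability to separate
    CIN-low from CIN-high archetypes is reported as an AUC.
    """
    noiseless = simulate_cohort(CohortConfig(
        n_patients=40, beta_noise_sd=0.0, seed=seed))
    reg = noiseless.meth_regions
    max_err = 0.0
    for i, pid in enumerate(noiseless.truth.patient_id):
        cl = int(noiseless.truth.cluster.iloc[i])
        bt_true = reg.tumor_mean_low if cl == 1 else reg.tumor_mean_high
        tf = float(noiseless.truth.plasma_tf.iloc[i])
        if tf < 0.03:
            continue  # below the normalization floor, inversion not exact
        rec = meth.normalize_for_tumor_content(
            noiseless.meth_beta_pre.loc[pid].to_numpy(), reg.healthy_mean, tf)
        max_err = max(max_err, float(np.max(np.abs(rec - bt_true))))

    cohort = simulate_cohort(CohortConfig(n_patients=n_patients,
                                          seed=seed + 1))
    truth = cohort.truth
    href = cohort.meth_beta_healthy.mean(axis=0).to_numpy()
    pre_norm = np.stack([
        meth.normalize_for_tumor_content(
            cohort.meth_beta_pre.iloc[i].to_numpy(), href,
            float(truth.plasma_tf.iloc[i]))
        for i in range(n_patients)])
    post_norm = np.stack([
        meth.normalize_for_tumor_content(
            cohort.meth_beta_post.iloc[i].to_numpy(), href,
            float(truth.post_tf.iloc[i]))
        for i in range(n_patients)])
    model = meth.train_score_model(
        pd.DataFrame(pre_norm, columns=cohort.meth_beta_pre.columns),
        cohort.meth_beta_healthy, seed=seed)
    pre_scores = model.oob_scores_[:n_patients]  # out-of-bag, not refit
    post_scores = model.score_samples(post_norm)
    delta = post_scores - pre_scores
    tf_change = truth.post_tf.to_numpy() - truth.plasma_tf.to_numpy()
    rho_delta, _ = stats.spearman(delta, tf_change)

    # baseline (unnormalized) score vs CIN archetype
    base_model = meth.train_score_model(cohort.meth_beta_pre,
                                        cohort.meth_beta_healthy, seed=seed)
    base_scores = base_model.oob_scores_[:n_patients]
    auc = stats.roc_auc(base_scores, truth.cin_high.to_numpy().astype(int))
    return {
        "inversion_max_abs_error": max_err,
        "delta_tfchange_abs_rho": abs(rho_delta),
        "baseline_auc_cin_high_vs_low": auc,
        "n": n_patients,
    }


def survival_recovery_experiment(seed: int, n: int = 2000) -> dict:
    """Cox hazard-ratio recovery on simulated two-group cohorts.

    Null cohort: identical hazards in both groups (HR estimate should be
    near 1). Effect cohort: true HR 0.5 for the CIN-high group with 20%
    censoring. Both are fit with the package's Breslow/Newton Cox routine.
    """
    rng = np.random.default_rng(seed)
    clusters_null = np.where(rng.random(n) < 0.5, 1, 2)
    df0 = simulate_survival(clusters_null, None, 1.0 / 300.0, 1.0, 1.0,
                            0.0, rng)
    x0 = np.isin(clusters_null, (2, 3)).astype(float)
    fit0 = stats.cox_ph(x0[:, None], df0["time"], df0["event"],
                        terms=["cin_high"])

    clusters_eff = np.where(rng.random(n) < 0.5, 1, 2)
    df1 = simulate_survival(clusters_eff, None, 1.0 / 300.0, 0.5, 1.0,
                            0.2, rng)
    x1 = np.isin(clusters_eff, (2, 3)).astype(float)
    fit1 = stats.cox_ph(x1[:, None], df1["time"], df1["event"],
                        terms=["cin_high"])
    return {
        "null_hr": float(fit0.hr[0]),
        "recovered_hr_true_0p5": float(fit1.hr[0]),
        "n": n,
    }
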