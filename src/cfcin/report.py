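"""End-to-end cohort report: CIN calls, scores, survival, one JSON summary.

``run_report`` chains every stage on a cohort — either freshly simulated or
loaded from a directory previously written by ``write_cohort`` — and writes
a machine-readable summary plus per-sample TSV tables. No quantity is
computed in this layer; every number comes from a module operation. Each
applied threshold and each excluded sample is logged with its reason.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cfio
from . import methylation as meth
from . import stats
from .cna import build_reference_panel
from .nucleosome import NucleosomeScorer, distance_profile
from .pipeline import classify_cohort, cohort_concordance
from .simulate import CohortConfig, SyntheticCohort, simulate_cohort

log = logging.getLogger("cfcin.report")

__all__ = ["write_cohort", "load_cohort_dir", "run_report"]


def write_cohort(cohort: SyntheticCohort, out_dir) -> Path:
    """Serialize a synthetic cohort to plain-text interchange files."""
    out = Path(out_dir)
    for sub in ("bins_healthy", "bins_tissue", "bins_plasma",
                "fragments_plasma", "fragments_healthy_ref",
                "fragments_tumor_ref"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    for i in range(cohort.healthy_counts.shape[0]):
        p = cohort.profile(i, "healthy")
        cfio.write_binned_profile(out / "bins_healthy" / f"{p.sample_id}.bed", p)
    for i, pid in enumerate(cohort.truth.patient_id):
        for kind in ("tissue", "plasma"):
            p = cohort.profile(i, kind)
            cfio.write_binned_profile(out / f"bins_{kind}" / f"{pid}.bed", p)
        cfio.write_fragments(out / "fragments_plasma" / f"{pid}.bed",
                             cohort.plasma_fragments[i])
    for i, f in enumerate(cohort.healthy_ref_fragments):
        cfio.write_fragments(out / "fragments_healthy_ref" / f"R{i:02d}.bed", f)
    for i, f in enumerate(cohort.tumor_ref_fragments):
        cfio.write_fragments(out / "fragments_tumor_ref" / f"T{i:02d}.bed", f)
    cfio.write_peaks(out / "peaks.bed", cohort.peaks)
    cfio.write_centroids(out / "centroids.tsv", cohort.centroids)
    cfio.write_nucleosome_track(out / "track.bed", cohort.track)

    def betas_long(df, timepoint):
        long = df.reset_index(names="sample").melt(
            id_vars="sample", var_name="region_id", value_name="beta")
        long["timepoint"] = timepoint
        return long

    betas = pd.concat([betas_long(cohort.meth_beta_pre, "baseline"),
                       betas_long(cohort.meth_beta_post, "week6"),
                       betas_long(cohort.meth_beta_healthy, "healthy")])
    cfio.write_table(out / "methylation_betas.tsv", betas, "methylation betas")
    cfio.write_table(out / "methylation_qc.tsv", cohort.meth_qc, "QC metrics")
    clinical = cohort.truth[["patient_id", "os_time", "os_event", "pfs_time",
                             "pfs_event", "age", "gender", "tnm_stage",
                             "plasma_tf", "post_tf"]]
    cfio.write_table(out / "clinical.tsv", clinical, "clinical table")
    cfio.write_table(out / "ground_truth.tsv", cohort.truth, "ground truth")
    return out


def load_cohort_dir(in_dir) -> SyntheticCohort:
    """Reload a cohort directory written by :func:`write_cohort`.

    The ground-truth table is reloaded too (reports on simulated data show
    recovery against it); real-data directories would omit it.
    """
    src = Path(in_dir)
    for required in ("peaks.bed", "centroids.tsv", "track.bed",
                     "ground_truth.tsv"):
        if not (src / required).exists():
            raise FileNotFoundError(f"missing input file: {src / required}")
    truth = cfio.read_table(src / "ground_truth.tsv")
    healthy = sorted((src / "bins_healthy").glob("*.bed"))
    first = cfio.read_binned_profile(healthy[0])
    grid = {"chrom": first.chrom, "start": first.start, "end": first.end,
            "gc": None, "gc_factor": None}
    healthy_counts = np.stack(
        [cfio.read_binned_profile(p).counts for p in healthy])
    tissue_counts, plasma_counts, plasma_fragments = [], [], []
    for pid in truth.patient_id:
        tissue_counts.append(
            cfio.read_binned_profile(src / "bins_tissue" / f"{pid}.bed").counts)
        plasma_counts.append(
            cfio.read_binned_profile(src / "bins_plasma" / f"{pid}.bed").counts)
        plasma_fragments.append(
            cfio.read_fragments(src / "fragments_plasma" / f"{pid}.bed"))
    betas = cfio.read_table(src / "methylation_betas.tsv")

    def beta_frame(tp):
        sub = betas[betas.timepoint == tp]
        return sub.pivot(index="sample", columns="region_id", values="beta")

    from .simulate import MethylationRegions
    pre = beta_frame("baseline").loc[truth.patient_id]
    regions = MethylationRegions(list(pre.columns),
                                 np.full(pre.shape[1], np.nan),
                                 np.full(pre.shape[1], np.nan),
                                 np.full(pre.shape[1], np.nan))
    return SyntheticCohort(
        config=CohortConfig(n_patients=len(truth)),
        grid=grid, archetypes=_archetypes_from_files(src), truth=truth,
        tissue_counts=np.stack(tissue_counts),
        plasma_counts=np.stack(plasma_counts),
        healthy_counts=healthy_counts,
        track=cfio.read_nucleosome_track(src / "track.bed"),
        plasma_fragments=plasma_fragments,
        healthy_ref_fragments=[cfio.read_fragments(p) for p in
                               sorted((src / "fragments_healthy_ref").glob("*.bed"))],
        tumor_ref_fragments=[cfio.read_fragments(p) for p in
                             sorted((src / "fragments_tumor_ref").glob("*.bed"))],
        meth_regions=regions, meth_beta_pre=pre,
        meth_beta_post=beta_frame("week6").loc[truth.patient_id],
        meth_beta_healthy=beta_frame("healthy"),
        meth_qc=cfio.read_table(src / "methylation_qc.tsv"),
    )


def _archetypes_from_files(src: Path):
    from .simulate import ClusterArchetypes
    peaks = cfio.read_peaks(src / "peaks.bed")
    centroids = cfio.read_centroids(src / "centroids.tsv")
    return ClusterArchetypes(peaks, centroids, {}, [], [])


def run_report(out_dir, seed: int = 0, simulate: bool = True,
               in_dir=None, cohort_config: CohortConfig | None = None) -> dict:
    """Run every pipeline stage on a cohort and write the report.

    Stage failures are caught into a failure manifest; the partial report
    is still written and the manifest is returned under "failures".
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    failures = {}

    if simulate:
        config = cohort_config or CohortConfig(seed=seed)
        log.info("stage=simulate seed=%d n_patients=%d", seed,
                 config.n_patients)
        cohort = simulate_cohort(config)
    else:
        if in_dir is None:
            raise ValueError("in_dir required when simulate=False")
        cohort = load_cohort_dir(in_dir)

    report = {"seed": seed, "version": cfio.FORMAT_VERSION,
              "n_patients": int(len(cohort.truth))}

    # --- CIN classification -------------------------------------------------
    panel = build_reference_panel(cohort.healthy_profiles())
    log.info("stage=panel n_healthy=%d n_blacklisted=%d",
             len(panel.sample_ids), int(panel.blacklist.sum()))
    calls = classify_cohort(cohort, panel)
    for _, row in calls.iterrows():
        log.info("stage=classify sample=%s tf_plasma=%.3f cluster_plasma=%d "
                 "cluster_tissue=%d", row.patient_id, row.plasma_tf_est,
                 row.plasma_cluster, row.tissue_cluster)
    cfio.write_table(out / "cin_calls.tsv", calls, "CIN cluster calls")
    conc = cohort_concordance(calls, scaled=True)
    conc_raw = cohort_concordance(calls, scaled=False)
    report["concordance"] = {
        "matrix": conc.matrix.tolist(),
        "match_rate": conc.match_rate,
        "binary_accuracy": conc.binary_accuracy,
        "binary_accuracy_unscaled": conc_raw.binary_accuracy,
        "n": conc.n_total,
    }

    # --- nucleosome scores --------------------------------------------------
    try:
        scorer = NucleosomeScorer().fit(
            [distance_profile(f, cohort.track)
             for f in cohort.healthy_ref_fragments + cohort.tumor_ref_fragments],
            [0] * len(cohort.healthy_ref_fragments)
            + [1] * len(cohort.tumor_ref_fragments))
        nuc_scores = scorer.transform(
            [distance_profile(f, cohort.track)
             for f in cohort.plasma_fragments])
        rho, p = stats.spearman(nuc_scores, calls.plasma_tf_est.to_numpy())
        nuc_df = pd.DataFrame({"patient_id": cohort.truth.patient_id,
                               "nucleosome_score": nuc_scores})
        cfio.write_table(out / "nucleosome_scores.tsv", nuc_df,
                         "nucleosome deviation scores")
        report["nucleosome"] = {"score_tf_spearman_rho": rho,
                                "score_tf_spearman_p": p,
                                "mean_score": float(np.mean(nuc_scores))}
    except (ValueError, stats.ConvergenceError) as exc:
        failures["nucleosome"] = str(exc)

    # --- methylation --------------------------------------------------------
    try:
        qc_records = [
            meth.SampleQCRecord(r.sample_id, r.bisulfite_conversion_rate,
                                r.mean_region_coverage)
            for r in cohort.meth_qc.itertuples()]
        retained, qc_report = meth.qc_filter(qc_records)
        retained = set(retained)
        for rec in qc_records:
            if rec.sample_id not in retained:
                log.info("stage=meth_qc sample=%s decision=excluded "
                         "reason=%s", rec.sample_id, rec.fail_reason)
        qc_pass = {pid: (f"{pid}_pre" in retained and f"{pid}_post" in retained)
                   for pid in cohort.truth.patient_id}
        keep = [pid for pid, ok in qc_pass.items() if ok]
        truth_idx = cohort.truth.set_index("patient_id")
        href = cohort.meth_beta_healthy.mean(axis=0).to_numpy()
        pre_norm = np.stack([
            meth.normalize_for_tumor_content(
                cohort.meth_beta_pre.loc[pid].to_numpy(), href,
                float(truth_idx.loc[pid, "plasma_tf"])) for pid in keep])
        post_norm = np.stack([
            meth.normalize_for_tumor_content(
                cohort.meth_beta_post.loc[pid].to_numpy(), href,
                float(truth_idx.loc[pid, "post_tf"])) for pid in keep])
        model = meth.train_score_model(
            pd.DataFrame(pre_norm, index=keep,
                         columns=cohort.meth_beta_pre.columns),
            cohort.meth_beta_healthy, seed=seed)
        pre_scores = pd.Series(model.oob_scores_[:len(keep)], index=keep)
        post_scores = pd.Series(model.score_samples(post_norm), index=keep)
        strat = meth.delta_stratify(pre_scores, post_scores)
        meth_df = pd.DataFrame({
            "patient_id": keep,
            "score_pre": pre_scores.to_numpy(),
            "score_post": post_scores.to_numpy(),
            "delta": strat["delta"].to_numpy(),
            "decrease_group": strat["group"].to_numpy(),
        })
        cfio.write_table(out / "methylation_scores.tsv", meth_df,
                         "methylation scores")
        report["methylation"] = {
            "qc_retained": len(retained),
            "qc_report": qc_report,
            "n_paired_patients": len(keep),
            "delta_median": strat["median"],
        }
    except (ValueError,) as exc:
        failures["methylation"] = str(exc)
        meth_df = None

    # --- survival -----------------------------------------------------------
    surv = cohort.truth.copy()
    surv["plasma_cin_high"] = np.where(
        calls.set_index("patient_id").loc[surv.patient_id,
                                          "plasma_cluster"].to_numpy() != 1,
        "CIN-high", "CIN-low")
    report["survival"] = {}
    for endpoint, (tcol, ecol) in (("OS", ("os_time", "os_event")),
                                   ("PFS", ("pfs_time", "pfs_event"))):
        try:
            fit = stats.cox_multivariate(
                surv, tcol, ecol, "plasma_cin_high",
                covariates=("age", "gender", "tnm"), reference="CIN-low")
            km = stats.kaplan_meier_by_group(surv, tcol, ecol,
                                             "plasma_cin_high")
            medians = {g: (None if c is None or np.isnan(c.median)
                           else c.median) for g, c in km.items()}
            report["survival"][endpoint] = {
                "cox": fit.summary().reset_index(names="term")
                       .to_dict(orient="records"),
                "km_median": medians,
                "n_events": fit.n_events,
            }
            for g, c in km.items():
                if c is not None:
                    km_df = pd.DataFrame({"time": c.times,
                                          "survival": c.survival})
                    cfio.write_table(out / f"km_{endpoint}_{g}.tsv", km_df,
                                     f"KM {endpoint} {g}")
        except (ValueError, stats.ConvergenceError) as exc:
            failures[f"survival_{endpoint}"] = str(exc)
    if meth_df is not None and meth_df.decrease_group.nunique() == 2:
        try:
            msurv = surv.merge(meth_df[["patient_id", "decrease_group"]],
                               on="patient_id")
            fit = stats.cox_multivariate(
                msurv, "os_time", "os_event", "decrease_group",
                covariates=("age", "gender", "tnm"),
                reference=meth.LARGE_DECREASE)
            report["survival"]["OS_by_methylation_delta"] = {
                "cox": fit.summary().reset_index(names="term")
                       .to_dict(orient="records"),
                "n_events": fit.n_events,
            }
        except (ValueError, stats.ConvergenceError) as exc:
            failures["survival_methylation"] = str(exc)

    report["failures"] = failures
    payload = json.dumps(cfio.to_jsonable(report), indent=2, sort_keys=True)
    (out / "report.json").write_text(payload + "\n")
    return report
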