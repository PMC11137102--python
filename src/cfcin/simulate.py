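"""Synthetic paired tissue/plasma mCRC cohort with known ground truth.

Everything downstream (panel normalization, segmentation, tumor-fraction
fitting, CIN clustering, nucleosome scoring, methylation scoring, survival)
is exercised on cohorts produced here, so each generator encodes the
qualitative structure the assay rests on:

* three CIN archetypes — cluster 1 near-diploid (prevalence ~0.1), clusters
  2 and 3 with many partially overlapping amplification/deletion events;
* plasma tumor fractions systematically lower than matched tissue;
* binned read counts as a negative-binomial sample of the GC-biased
  two-component copy-number mixture;
* fragment starts around nucleosome centers mixing an M-shaped healthy
  offset distribution with a center-enriched tumor one, weighted by tumor
  fraction;
* methylation target regions hypomethylated in healthy plasma (mean beta
  < 0.03) and hypermethylated in tumor, observed as a tumor-fraction
  mixture, with tumor-component hypomethylation on effective treatment;
* proportional-hazards survival driven by CIN-high membership and by the
  methylation-score decrease.

All draws flow from a single seed, bit-for-bit reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cin import ClusterCentroids, PeakRegionSet
from .cna import BinnedCoverageProfile
from .nucleosome import NucleosomeTrack

__all__ = [
    "CohortConfig",
    "MethylationRegions",
    "SyntheticCohort",
    "BimodalOffsets",
    "CenterOffsets",
    "generate_bin_grid",
    "generate_cluster_archetypes",
    "simulate_binned_reads",
    "generate_nucleosome_track",
    "simulate_fragment_starts",
    "generate_methylation_regions",
    "simulate_methylation",
    "simulate_survival",
    "simulate_cohort",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the profiled trial cohort: 74 patients, cluster-1
    prevalence 0.1, plasma tumor content at 0.6 of matched tissue, 43
    amplification and 59 deletion peaks, and survival reported in days.
    The genome is scaled down to 3000 bins of 500 kb across 4 chromosomes
    with ~1000 reads per bin, which preserves the segment-level statistics
    of 500 kb LC-WGS binning at a desk-scale problem size.
    """

    n_patients: int = 74
    cluster_probs: tuple = (0.1, 0.45, 0.45)
    tissue_tf_range: tuple = (0.1, 0.5)
    cluster1_tf_factor: float = 0.4   # cluster-1 tumors shed less ctDNA
    plasma_to_tissue_tf_ratio: float = 0.6
    bin_size: int = 500_000
    n_bins: int = 3000
    n_chromosomes: int = 4
    reads_per_sample: int = 3_000_000
    dispersion: float = 2000.0        # NB size parameter; inf -> Poisson
    gc_bias_slope: float = 2.0
    n_healthy: int = 20               # reference-panel samples
    n_amp_peaks: int = 43
    n_del_peaks: int = 59
    peak_width_bins: int = 4
    event_width_bins: int = 12
    peak_dropout: float = 0.1         # per-patient chance an event reverts
    # nucleosome footprint
    n_nucleosomes: int = 5000
    nucleosome_spacing: int = 200
    n_fragments: int = 20_000
    weight_noise_sd: float = 0.05
    cluster3_shrink: float = 0.35     # heterogeneous cluster-3 mixture mode
    # methylation
    n_meth_regions: int = 60
    n_meth_healthy: int = 41
    healthy_beta_range: tuple = (0.005, 0.03)
    tumor_beta_low: tuple = (0.15, 0.45)   # cluster-1 tumor component
    tumor_beta_high: tuple = (0.5, 0.9)    # clusters 2/3 tumor component
    beta_noise_sd: float = 0.02
    meth_coverage_mean: float = 60.0
    treatment_effect: float = 0.15    # responder tumor-beta drop
    responder_prob: float = 0.5
    post_tf_ratio_range: tuple = (0.4, 0.9)  # on-treatment tf decline
    # survival (days)
    baseline_hazard: float = 1.0 / 320.0
    hr_cluster_high: float = 0.35
    hr_large_decrease: float = 0.5
    censoring_rate: float = 0.2
    seed: int = 0

    def validate(self) -> "CohortConfig":
        probs = np.asarray(self.cluster_probs, dtype=float)
        if probs.size != 3 or np.any(probs < 0) or np.any(probs > 1):
            raise ValueError("cluster_probs must be three probabilities")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError("cluster_probs must sum to 1")
        lo, hi = self.tissue_tf_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("tissue_tf_range must lie within [0, 1]")
        if self.plasma_to_tissue_tf_ratio <= 0:
            raise ValueError("plasma_to_tissue_tf_ratio must be positive")
        if not 0.0 <= self.censoring_rate <= 1.0:
            raise ValueError("censoring_rate must be in [0, 1]")
        if self.n_bins < (self.n_amp_peaks + self.n_del_peaks):
            raise ValueError("n_bins too small to host the peak regions")
        return self


# ---------------------------------------------------------------------------
# genome grid and CIN archetypes
# ---------------------------------------------------------------------------

def generate_bin_grid(config: CohortConfig, rng) -> dict:
    """Fixed bin grid (chrom, start, end) plus per-bin GC and GC bias."""
    per_chrom = config.n_bins // config.n_chromosomes
    counts = [per_chrom] * config.n_chromosomes
    counts[-1] += config.n_bins - per_chrom * config.n_chromosomes
    chrom, start = [], []
    for c, nb in enumerate(counts, start=1):
        chrom.extend([f"chr{c}"] * nb)
        start.extend(np.arange(nb) * config.bin_size)
    chrom = np.array(chrom)
    start = np.array(start, dtype=int)
    end = start + config.bin_size
    gc = rng.uniform(0.35, 0.55, size=config.n_bins)
    gc_factor = 1.0 + config.gc_bias_slope * (gc - 0.45)
    return {"chrom": chrom, "start": start, "end": end,
            "gc": gc, "gc_factor": gc_factor}


@dataclass
class ClusterArchetypes:
    peaks: PeakRegionSet
    centroids: ClusterCentroids
    templates: dict            # cluster -> per-bin integer CN
    event_bins: list           # per peak: (bin_lo, bin_hi) of the CNA event
    peak_bins: list            # per peak: (bin_lo, bin_hi) of the peak core


def generate_cluster_archetypes(config: CohortConfig, grid: dict,
                                rng) -> ClusterArchetypes:
    """Place 43 amp + 59 del events and derive the three CIN templates.

    Each peak region sits at the core of a wider copy-number event (broad
    CNAs carry focal peaks). Cluster 1 is near-diploid: one CN4 and one CN3
    amplification plus one CN1 deletion. Clusters 2 and 3 alter large,
    partially overlapping subsets of the peaks; each is guaranteed at least
    one CN4 amplification and one homozygous (CN0) deletion so that the
    grid tumor-fraction fit is not aliased by a half-purity solution.
    """
    n_peaks = config.n_amp_peaks + config.n_del_peaks
    n_bins = config.n_bins
    ew, pw = config.event_width_bins, config.peak_width_bins
    if n_peaks == 0:
        peaks = PeakRegionSet(np.array([], dtype=object), np.array([], int),
                              np.array([], int), np.array([], object),
                              np.array([], object))
        centroids = ClusterCentroids(np.zeros((3, 0)))
        templates = {k: np.full(n_bins, 2, dtype=int) for k in (1, 2, 3)}
        return ClusterArchetypes(peaks, centroids, templates, [], [])
    step = n_bins // n_peaks
    if step < ew + 1:
        raise ValueError(
            f"{n_bins} bins cannot host {n_peaks} events of {ew} bins")

    chrom, start = grid["chrom"], grid["start"]
    # chromosome block boundaries in bin index space
    bounds = np.nonzero(np.r_[True, chrom[1:] != chrom[:-1]])[0]
    bounds = np.r_[bounds, n_bins]

    directions = np.array(["amp"] * config.n_amp_peaks
                          + ["del"] * config.n_del_peaks, dtype=object)
    rng.shuffle(directions)

    event_bins, peak_bins = [], []
    for s in range(n_peaks):
        lo = s * step + int(rng.integers(0, step - ew))
        hi = lo + ew
        # keep the event inside one chromosome
        blk = np.searchsorted(bounds, lo, side="right") - 1
        if hi > bounds[blk + 1]:
            shift = hi - bounds[blk + 1]
            lo, hi = lo - shift, hi - shift
        event_bins.append((lo, hi))
        core = lo + (ew - pw) // 2
        peak_bins.append((core, core + pw))

    p_lo = np.array([p[0] for p in peak_bins])
    p_hi = np.array([p[1] for p in peak_bins])
    peaks = PeakRegionSet(
        chrom=chrom[p_lo],
        start=start[p_lo],
        end=start[p_hi - 1] + config.bin_size,
        label=np.array([f"peak_{s:03d}" for s in range(n_peaks)], dtype=object),
        direction=directions,
    )

    amp_idx = np.nonzero(directions == "amp")[0]
    del_idx = np.nonzero(directions == "del")[0]

    def high_cin_template(alter_prob, amp_cn_probs, del_cn_probs):
        cn_by_peak = np.full(n_peaks, 2, dtype=int)
        for i in amp_idx:
            if rng.random() < alter_prob:
                cn_by_peak[i] = rng.choice([3, 4], p=amp_cn_probs)
        for i in del_idx:
            if rng.random() < alter_prob:
                cn_by_peak[i] = rng.choice([1, 0], p=del_cn_probs)
        # guarantee alias-breaking extreme states
        if amp_idx.size and not np.any(cn_by_peak[amp_idx] == 4):
            cn_by_peak[rng.choice(amp_idx)] = 4
        if del_idx.size and not np.any(cn_by_peak[del_idx] == 0):
            cn_by_peak[rng.choice(del_idx)] = 0
        return cn_by_peak

    peak_cn = {1: np.full(n_peaks, 2, dtype=int)}
    if amp_idx.size >= 2 and del_idx.size >= 1:
        c1_amp = rng.choice(amp_idx, size=2, replace=False)
        c1_del = rng.choice(del_idx)
        peak_cn[1][c1_amp[0]] = 4
        peak_cn[1][c1_amp[1]] = 3
        peak_cn[1][c1_del] = 1
    peak_cn[2] = high_cin_template(0.60, [0.6, 0.4], [0.8, 0.2])
    peak_cn[3] = high_cin_template(0.85, [0.5, 0.5], [0.7, 0.3])

    templates = {}
    for k in (1, 2, 3):
        t = np.full(n_bins, 2, dtype=int)
        for s, (lo, hi) in enumerate(event_bins):
            if peak_cn[k][s] != 2:
                t[lo:hi] = peak_cn[k][s]
        templates[k] = t

    with np.errstate(divide="ignore"):
        cents = np.stack([np.log2(peak_cn[k] / 2.0) for k in (1, 2, 3)])
    cents[np.isneginf(cents)] = np.log2(0.05)  # CN0 peaks, kept finite
    centroids = ClusterCentroids(cents)
    return ClusterArchetypes(peaks, centroids, templates, event_bins, peak_bins)


# ---------------------------------------------------------------------------
# read counts
# ---------------------------------------------------------------------------

def simulate_binned_reads(template, tumor_fraction: float, reads: int, rng,
                          gc_factor=None, dispersion: float = 2000.0
                          ) -> np.ndarray:
    """Negative-binomial bin counts under the copy-number mixture.

    Per-bin mean is proportional to gc_factor * (2(1-tf) + tf*CN)/2 and the
    means sum to ``reads``. Dispersion is the NB size parameter; infinite
    dispersion degrades to Poisson.
    """
    cn = np.asarray(template, dtype=float)
    if np.any(cn < 0):
        raise ValueError("negative copy number in template")
    if not 0.0 <= tumor_fraction <= 1.0:
        raise ValueError("tumor_fraction must be in [0, 1]")
    if reads <= 0:
        raise ValueError("reads must be positive")
    gc = np.ones_like(cn) if gc_factor is None else np.asarray(gc_factor, float)
    rel = gc * (2.0 * (1.0 - tumor_fraction) + tumor_fraction * cn) / 2.0
    mean = reads * rel / rel.sum()
    if not np.isfinite(dispersion):
        return rng.poisson(mean)
    r = float(dispersion)
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def expected_bin_ratio(cn, tumor_fraction: float):
    """Closed-form diploid-relative mean: (2(1-tf) + tf*CN)/2."""
    return (2.0 * (1.0 - tumor_fraction)
            + tumor_fraction * np.asarray(cn, float)) / 2.0


# ---------------------------------------------------------------------------
# nucleosome fragments
# ---------------------------------------------------------------------------

@dataclass
class BimodalOffsets:
    """Healthy linker-biased offsets: symmetric modes at +/-mode bp."""

    mode: float = 73.0
    sd: float = 25.0

    def sample(self, rng, n: int) -> np.ndarray:
        signs = rng.choice(np.array([-1.0, 1.0]), size=n)
        return signs * self.mode + rng.normal(0.0, self.sd, size=n)


@dataclass
class CenterOffsets:
    """Tumor offsets concentrated at the nucleosome center."""

    sd: float = 45.0

    def sample(self, rng, n: int) -> np.ndarray:
        return rng.normal(0.0, self.sd, size=n)


def generate_nucleosome_track(config: CohortConfig, rng) -> NucleosomeTrack:
    """Irregularly spaced centers on one synthetic chromosome."""
    spacing = rng.integers(config.nucleosome_spacing - 40,
                           config.nucleosome_spacing + 41,
                           size=config.n_nucleosomes)
    centers = 1000 + np.cumsum(spacing)
    return NucleosomeTrack({"chrN": centers})


def simulate_fragment_starts(tumor_fraction: float, n_fragments: int,
                             track: NucleosomeTrack, healthy_dist,
                             tumor_dist, rng) -> dict:
    """Fragment starts = nucleosome center + mixture-drawn offset.

    Each fragment picks a center uniformly, then a healthy offset with
    probability (1 - tf) and a tumor offset with probability tf.
    """
    if not 0.0 <= tumor_fraction <= 1.0:
        raise ValueError("tumor_fraction must be in [0, 1]")
    if track.n_centers == 0:
        raise ValueError("empty nucleosome track")
    chroms = list(track.centers)
    sizes = np.array([track.centers[c].size for c in chroms])
    flat = rng.integers(0, sizes.sum(), size=n_fragments)
    offsets = np.empty(n_fragments)
    is_tumor = rng.random(n_fragments) < tumor_fraction
    n_t = int(is_tumor.sum())
    offsets[is_tumor] = tumor_dist.sample(rng, n_t)
    offsets[~is_tumor] = healthy_dist.sample(rng, n_fragments - n_t)

    cum = np.cumsum(sizes)
    out = {}
    lo = 0
    for c, hi in zip(chroms, cum):
        sel = (flat >= lo) & (flat < hi)
        centers = track.centers[c][flat[sel] - lo]
        out[c] = np.sort(centers + np.rint(offsets[sel]).astype(np.int64))
        lo = hi
    return out


# ---------------------------------------------------------------------------
# methylation
# ---------------------------------------------------------------------------

@dataclass
class MethylationRegions:
    """Region-level methylation parameters of the capture design."""

    region_ids: list
    healthy_mean: np.ndarray       # < 0.03 by design
    tumor_mean_low: np.ndarray     # CIN-low tumor component
    tumor_mean_high: np.ndarray    # CIN-high tumor component


def generate_methylation_regions(config: CohortConfig, rng
                                 ) -> MethylationRegions:
    n = config.n_meth_regions
    return MethylationRegions(
        region_ids=[f"region_{i:03d}" for i in range(n)],
        healthy_mean=rng.uniform(*config.healthy_beta_range, size=n),
        tumor_mean_low=rng.uniform(*config.tumor_beta_low, size=n),
        tumor_mean_high=rng.uniform(*config.tumor_beta_high, size=n),
    )


def simulate_methylation(tf_pre: float, tf_post: float, responder: bool,
                         regions: MethylationRegions, cluster: int, rng,
                         treatment_effect: float = 0.15,
                         noise_sd: float = 0.02) -> dict:
    """Observed pre/post betas for one patient under the mixture model.

    The tumor component is cluster-dependent (CIN-low tumors carry weaker
    hypermethylation); responders shift the tumor component down by
    ``treatment_effect`` at the on-treatment draw. Returns the observed
    mixtures and the underlying tumor-component betas.
    """
    for tf in (tf_pre, tf_post):
        if not 0.0 <= tf <= 1.0:
            raise ValueError("tumor fractions must be in [0, 1]")
    h = regions.healthy_mean
    bt_pre = regions.tumor_mean_low if cluster == 1 else regions.tumor_mean_high
    bt_post = np.clip(bt_pre - (treatment_effect if responder else 0.0),
                      0.0, 1.0)

    def observe(tf, bt):
        mix = (1.0 - tf) * h + tf * bt
        if noise_sd > 0:
            mix = mix + rng.normal(0.0, noise_sd, size=mix.size)
        return np.clip(mix, 0.0, 1.0)

    return {
        "beta_pre": observe(tf_pre, bt_pre),
        "beta_post": observe(tf_post, bt_post),
        "tumor_beta_pre": bt_pre.copy(),
        "tumor_beta_post": bt_post,
    }


def betas_to_counts(betas: np.ndarray, coverage_mean: float, rng):
    """Binomial read counts whose ratio re-estimates the beta."""
    cov = np.maximum(rng.poisson(coverage_mean, size=betas.shape), 1)
    meth = rng.binomial(cov, betas)
    return meth, cov - meth


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def simulate_survival(cluster_labels, methylation_deltas, baseline_hazard:
                      float, hr_cluster_high: float, hr_large_decrease: float,
                      censoring_rate: float, rng) -> pd.DataFrame:
    """Exponential event times under a proportional-hazards structure.

    The hazard is multiplied by ``hr_cluster_high`` for CIN-high patients
    (clusters 2/3) and by ``hr_large_decrease`` for patients whose
    methylation delta falls below the cohort median. Censoring is a
    Bernoulli(censoring_rate) uniform truncation of the event time, so
    rates 0 and 1 are exact.
    """
    if hr_cluster_high <= 0 or hr_large_decrease <= 0:
        raise ValueError("hazard ratios must be positive")
    clusters = np.asarray(cluster_labels, dtype=int)
    n = clusters.size
    hazard = np.full(n, baseline_hazard)
    hazard[np.isin(clusters, (2, 3))] *= hr_cluster_high
    if methylation_deltas is not None:
        deltas = np.asarray(methylation_deltas, dtype=float)
        hazard[deltas < np.median(deltas)] *= hr_large_decrease
    t_event = rng.exponential(1.0 / hazard)
    censored = rng.random(n) < censoring_rate
    time = np.where(censored, rng.uniform(0.0, 1.0, size=n) * t_event, t_event)
    time = np.maximum(time, 1e-6)
    return pd.DataFrame({"time": time, "event": (~censored).astype(int)})


# ---------------------------------------------------------------------------
# full cohort
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    """Everything a pipeline run needs, plus the generating ground truth."""

    config: CohortConfig
    grid: dict
    archetypes: ClusterArchetypes
    truth: pd.DataFrame
    tissue_counts: np.ndarray
    plasma_counts: np.ndarray
    healthy_counts: np.ndarray
    track: NucleosomeTrack
    plasma_fragments: list
    healthy_ref_fragments: list
    tumor_ref_fragments: list
    meth_regions: MethylationRegions
    meth_beta_pre: pd.DataFrame
    meth_beta_post: pd.DataFrame
    meth_beta_healthy: pd.DataFrame
    meth_qc: pd.DataFrame
    field_notes: dict = field(default_factory=dict)

    @property
    def peaks(self) -> PeakRegionSet:
        return self.archetypes.peaks

    @property
    def centroids(self) -> ClusterCentroids:
        return self.archetypes.centroids

    def profile(self, index: int, kind: str) -> BinnedCoverageProfile:
        counts = {"tissue": self.tissue_counts, "plasma": self.plasma_counts,
                  "healthy": self.healthy_counts}[kind][index]
        if kind == "healthy":
            sid = f"H{index + 1:03d}"
        else:
            sid = f"{self.truth.patient_id.iloc[index]}_{kind}"
        return BinnedCoverageProfile(sid, self.grid["chrom"],
                                     self.grid["start"], self.grid["end"],
                                     counts, gc=self.grid["gc"])

    def healthy_profiles(self) -> list:
        return [self.profile(i, "healthy")
                for i in range(self.healthy_counts.shape[0])]


def simulate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Generate the full paired tissue/plasma cohort from one seed."""
    config = (config or CohortConfig()).validate()
    rng = np.random.default_rng(config.seed)

    grid = generate_bin_grid(config, rng)
    arch = generate_cluster_archetypes(config, grid, rng)

    n = config.n_patients
    clusters = rng.choice([1, 2, 3], size=n, p=np.asarray(config.cluster_probs))
    lo, hi = config.tissue_tf_range
    tissue_tf = rng.uniform(lo, hi, size=n)
    tissue_tf[clusters == 1] *= config.cluster1_tf_factor
    plasma_tf = tissue_tf * config.plasma_to_tissue_tf_ratio

    # per-patient copy-number templates: cluster template with event dropout
    patient_templates = []
    for i in range(n):
        t = arch.templates[clusters[i]].copy()
        if config.peak_dropout > 0:
            for lo_b, hi_b in arch.event_bins:
                if t[lo_b] != 2 and rng.random() < config.peak_dropout:
                    t[lo_b:hi_b] = 2
        patient_templates.append(t)

    gcf = grid["gc_factor"]
    kw = dict(reads=config.reads_per_sample, gc_factor=gcf,
              dispersion=config.dispersion)
    tissue_counts = np.stack([
        simulate_binned_reads(patient_templates[i], tissue_tf[i], rng=rng, **kw)
        for i in range(n)])
    plasma_counts = np.stack([
        simulate_binned_reads(patient_templates[i], plasma_tf[i], rng=rng, **kw)
        for i in range(n)])
    diploid = np.full(config.n_bins, 2, dtype=int)
    healthy_counts = np.stack([
        simulate_binned_reads(diploid, 0.0, rng=rng, **kw)
        for _ in range(config.n_healthy)])

    # nucleosome footprints
    track = generate_nucleosome_track(config, rng)
    healthy_dist, tumor_dist = BimodalOffsets(), CenterOffsets()
    weight = np.clip(plasma_tf + rng.normal(0, config.weight_noise_sd, n),
                     0.0, 1.0)
    shrunk = (clusters == 3) & (rng.random(n) < 0.5)
    weight[shrunk] = np.clip(
        config.cluster3_shrink * plasma_tf[shrunk]
        + rng.normal(0, config.weight_noise_sd, int(shrunk.sum())), 0.0, 1.0)
    plasma_fragments = [
        simulate_fragment_starts(weight[i], config.n_fragments, track,
                                 healthy_dist, tumor_dist, rng)
        for i in range(n)]
    healthy_ref_fragments = [
        simulate_fragment_starts(0.0, config.n_fragments, track,
                                 healthy_dist, tumor_dist, rng)
        for _ in range(10)]
    tumor_ref_fragments = [
        simulate_fragment_starts(1.0, config.n_fragments, track,
                                 healthy_dist, tumor_dist, rng)
        for _ in range(5)]

    # methylation
    regions = generate_methylation_regions(config, rng)
    responder = rng.random(n) < config.responder_prob
    post_tf = plasma_tf * rng.uniform(*config.post_tf_ratio_range, size=n)
    beta_pre, beta_post, delta_true = [], [], []
    for i in range(n):
        m = simulate_methylation(plasma_tf[i], post_tf[i], bool(responder[i]),
                                 regions, int(clusters[i]), rng,
                                 treatment_effect=config.treatment_effect,
                                 noise_sd=config.beta_noise_sd)
        beta_pre.append(m["beta_pre"])
        beta_post.append(m["beta_post"])
        delta_true.append(float(np.mean(m["tumor_beta_post"]
                                        - m["tumor_beta_pre"])))
    pids = [f"P{i + 1:03d}" for i in range(n)]
    meth_beta_pre = pd.DataFrame(beta_pre, index=pids,
                                 columns=regions.region_ids)
    meth_beta_post = pd.DataFrame(beta_post, index=pids,
                                  columns=regions.region_ids)
    healthy_rows = [
        np.clip(regions.healthy_mean
                + rng.normal(0, config.beta_noise_sd, regions.healthy_mean.size),
                0.0, 1.0)
        for _ in range(config.n_meth_healthy)]
    meth_beta_healthy = pd.DataFrame(
        healthy_rows, index=[f"HM{i + 1:03d}" for i in range(config.n_meth_healthy)],
        columns=regions.region_ids)

    # QC metrics: occasional conversion failures, log-normal coverage
    qc_rows = []
    for tp, suffix in (("baseline", "pre"), ("week6", "post")):
        conv = np.where(rng.random(n) < 0.02,
                        rng.uniform(0.90, 0.95, n), rng.uniform(0.96, 0.999, n))
        cov = rng.lognormal(np.log(50.0), 0.9, n)
        for i in range(n):
            qc_rows.append({"sample_id": f"{pids[i]}_{suffix}",
                            "patient_id": pids[i], "timepoint": tp,
                            "bisulfite_conversion_rate": float(conv[i]),
                            "mean_region_coverage": float(cov[i])})
    meth_qc = pd.DataFrame(qc_rows)

    # survival: OS and PFS, both driven by CIN-high and methylation response
    os_df = simulate_survival(clusters, delta_true, config.baseline_hazard,
                              config.hr_cluster_high,
                              config.hr_large_decrease,
                              config.censoring_rate, rng)
    pfs_df = simulate_survival(clusters, delta_true,
                               config.baseline_hazard * 2.0,
                               config.hr_cluster_high,
                               config.hr_large_decrease,
                               config.censoring_rate, rng)

    age = np.clip(rng.normal(63, 10, n), 35, 88).round(0)
    gender = np.where(rng.random(n) < 0.62, "male", "female")
    tnm = rng.choice([2.0, 3.0, 4.0], size=n, p=[0.1, 0.4, 0.5])
    tnm[rng.random(n) < 0.1] = np.nan

    truth = pd.DataFrame({
        "patient_id": pids,
        "cluster": clusters,
        "cin_high": np.isin(clusters, (2, 3)),
        "tissue_tf": tissue_tf,
        "plasma_tf": plasma_tf,
        "post_tf": post_tf,
        "nuc_weight": weight,
        "responder": responder,
        "meth_delta_true": delta_true,
        "os_time": os_df["time"].to_numpy(),
        "os_event": os_df["event"].to_numpy(),
        "pfs_time": pfs_df["time"].to_numpy(),
        "pfs_event": pfs_df["event"].to_numpy(),
        "age": age,
        "gender": gender,
        "tnm_stage": tnm,
    })

    return SyntheticCohort(
        config=config, grid=grid, archetypes=arch, truth=truth,
        tissue_counts=tissue_counts, plasma_counts=plasma_counts,
        healthy_counts=healthy_counts, track=track,
        plasma_fragments=plasma_fragments,
        healthy_ref_fragments=healthy_ref_fragments,
        tumor_ref_fragments=tumor_ref_fragments,
        meth_regions=regions, meth_beta_pre=meth_beta_pre,
        meth_beta_post=meth_beta_post, meth_beta_healthy=meth_beta_healthy,
        meth_qc=meth_qc,
        field_notes={"patient_templates": patient_templates},
    )
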