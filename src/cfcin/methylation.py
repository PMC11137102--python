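"""Region-level cfDNA methylation: betas, QC, deconvolution, scoring.

Target regions are designed to be unmethylated in healthy plasma (mean beta
below 0.03) and hypermethylated in colorectal tumors, so the observed beta
of a plasma sample is a two-component mixture

    beta_obs = (1 - tf) * beta_healthy + tf * beta_tumor

weighted by the sample's tumor fraction tf. ``normalize_for_tumor_content``
inverts that mixture so on-treatment samples with shrinking tumor burden
remain comparable to baseline. A random-forest classifier on region betas
(tumor vs healthy) supplies the 0 (healthy) to 1 (tumorigenic) methylation
score; its pre-to-on-treatment change stratifies patients into large vs
small decrease groups at the cohort median.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "QC_MIN_CONVERSION",
    "QC_MIN_COVERAGE",
    "SampleQCRecord",
    "region_betas",
    "qc_filter",
    "normalize_for_tumor_content",
    "MethylationScoreModel",
    "train_score_model",
    "methylation_score",
    "delta_stratify",
]

QC_MIN_CONVERSION = 0.95
QC_MIN_COVERAGE = 10.0

LARGE_DECREASE = "Large decrease"
SMALL_DECREASE = "Small decrease"


@dataclass
class SampleQCRecord:
    sample_id: str
    bisulfite_conversion_rate: float
    mean_region_coverage: float

    @property
    def fail_reason(self) -> str | None:
        if self.bisulfite_conversion_rate < QC_MIN_CONVERSION:
            return "conversion"
        if self.mean_region_coverage < QC_MIN_COVERAGE:
            return "coverage"
        return None

    @property
    def passes(self) -> bool:
        return self.fail_reason is None


def region_betas(counts: pd.DataFrame) -> tuple:
    """Pivot long-format methylation counts into beta and coverage matrices.

    ``counts`` needs columns sample, region_id, meth, unmeth; CpG-level rows
    within a region are pooled by summing counts before the ratio is taken.
    Returns (betas, coverage) as samples x regions DataFrames; cells with
    zero coverage are NaN in the beta matrix.
    """
    required = {"sample", "region_id", "meth", "unmeth"}
    if not required <= set(counts.columns):
        raise ValueError(f"counts table needs columns {sorted(required)}")
    if (counts["meth"] < 0).any() or (counts["unmeth"] < 0).any():
        raise ValueError("negative methylation counts")
    pooled = (counts.groupby(["sample", "region_id"])[["meth", "unmeth"]]
              .sum().reset_index())
    meth = pooled.pivot(index="sample", columns="region_id", values="meth")
    unmeth = pooled.pivot(index="sample", columns="region_id", values="unmeth")
    coverage = (meth + unmeth).fillna(0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        betas = meth / (meth + unmeth)
    betas = betas.where(coverage > 0)
    return betas, coverage


def qc_filter(records) -> tuple:
    """Apply the conversion >= 95% and mean coverage >= 10x sample filters.

    Returns (retained sample ids, report) where the report counts
    exclusions per fail reason; a sample failing both thresholds is counted
    under conversion.
    """
    retained, report = [], {"conversion": 0, "coverage": 0}
    seen = set()
    for rec in records:
        if rec.sample_id in seen:
            raise ValueError(f"duplicate QC record for {rec.sample_id!r}")
        seen.add(rec.sample_id)
        reason = rec.fail_reason
        if reason is None:
            retained.append(rec.sample_id)
        else:
            report[reason] += 1
    return retained, report


def normalize_for_tumor_content(beta_obs, beta_healthy_ref, tf: float,
                                floor_tf: float = 0.03):
    """Deconvolve the tumor-component beta from an observed mixture.

        beta_tumor = clip((beta_obs - (1 - tf) * beta_healthy) / tf, 0, 1)

    tf below ``floor_tf`` is clipped to the floor (noise amplification cap).
    """
    if tf is None or not np.isfinite(tf):
        raise ValueError("tumor fraction required")
    tf = max(float(tf), floor_tf)
    if tf <= 0:
        raise ValueError("tumor fraction must be positive after clipping")
    obs = np.asarray(beta_obs, dtype=float)
    href = np.asarray(beta_healthy_ref, dtype=float)
    return np.clip((obs - (1.0 - tf) * href) / tf, 0.0, 1.0)


class MethylationScoreModel(ClassifierMixin, BaseEstimator):
    """Random-forest tumor-vs-healthy classifier on region betas.

    The methylation score of a sample is the forest's tumor-class
    probability. Training-set samples are scored out-of-bag so no sample is
    scored by trees that saw it. Missing regions in a query are imputed
    with the healthy-panel mean beta (flagged); queries missing more than
    half the regions are refused.
    """

    def __init__(self, n_estimators: int = 500, max_features="sqrt",
                 random_state: int = 0):
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("need both tumor and healthy samples")
        if min((y == c).sum() for c in classes) < 5:
            raise ValueError("need at least 5 samples per class")
        self.rf_ = RandomForestClassifier(
            n_estimators=self.n_estimators, max_features=self.max_features,
            oob_score=True, bootstrap=True, random_state=self.random_state)
        self.rf_.fit(X, y)
        self.classes_ = self.rf_.classes_
        self.n_features_in_ = X.shape[1]
        tumor_col = int(np.nonzero(self.rf_.classes_ == 1)[0][0])
        # out-of-bag tumor probability for every training sample
        self.oob_scores_ = self.rf_.oob_decision_function_[:, tumor_col]
        self.healthy_mean_ = X[y == 0].mean(axis=0)
        return self

    def score_samples(self, X) -> np.ndarray:
        """Tumor-class probability per sample, with NaN-region imputation."""
        check_is_fitted(self, "rf_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError("region set mismatch with the trained model")
        missing = ~np.isfinite(X)
        frac_missing = missing.mean(axis=1)
        if np.any(frac_missing > 0.5):
            bad = np.nonzero(frac_missing > 0.5)[0].tolist()
            raise ValueError(f"samples {bad} missing more than half of the "
                             "regions; refusing to score")
        if missing.any():
            X = X.copy()
            X[missing] = np.broadcast_to(self.healthy_mean_, X.shape)[missing]
        tumor_col = int(np.nonzero(self.rf_.classes_ == 1)[0][0])
        return self.rf_.predict_proba(X)[:, tumor_col]

    def predict_proba(self, X):
        check_is_fitted(self, "rf_")
        s = self.score_samples(X)
        return np.column_stack([1.0 - s, s])

    def predict(self, X):
        return (self.score_samples(X) >= 0.5).astype(int)


def train_score_model(pretreatment: pd.DataFrame, healthy: pd.DataFrame,
                      n_estimators: int = 500, seed: int = 0
                      ) -> MethylationScoreModel:
    """Train the score model on pre-treatment (tumor) vs healthy betas.

    Both inputs are samples x regions beta DataFrames on one region set.
    """
    if list(pretreatment.columns) != list(healthy.columns):
        raise ValueError("pre-treatment and healthy region sets differ")
    X = np.vstack([pretreatment.to_numpy(float), healthy.to_numpy(float)])
    y = np.concatenate([np.ones(len(pretreatment), dtype=int),
                        np.zeros(len(healthy), dtype=int)])
    model = MethylationScoreModel(n_estimators=n_estimators, random_state=seed)
    return model.fit(X, y)


def methylation_score(model: MethylationScoreModel, betas) -> np.ndarray:
    """Score samples (rows of a beta DataFrame or array) with the model."""
    if isinstance(betas, pd.DataFrame):
        betas = betas.to_numpy(float)
    return model.score_samples(betas)


def delta_stratify(pre_scores: pd.Series, post_scores: pd.Series) -> dict:
    """Per-patient score delta and large/small decrease grouping.

    delta = post - pre; the cohort median m of the deltas is recomputed for
    every cohort (even n: mean of the two central order statistics); deltas
    strictly below m form the "Large decrease" group, the rest "Small
    decrease". Patients present in only one series are excluded and
    reported.
    """
    pre = pd.Series(pre_scores, dtype=float)
    post = pd.Series(post_scores, dtype=float)
    paired = sorted(set(pre.index) & set(post.index))
    excluded = sorted(set(pre.index) ^ set(post.index))
    if not paired:
        raise ValueError("no paired patients")
    delta = (post[paired] - pre[paired]).astype(float)
    median = float(np.median(delta.to_numpy()))
    group = pd.Series(np.where(delta < median, LARGE_DECREASE, SMALL_DECREASE),
                      index=delta.index, name="decrease_group")
    degenerate = bool(np.all(delta.to_numpy() == delta.iloc[0]))
    return {
        "delta": delta,
        "median": median,
        "group": group,
        "excluded": excluded,
        "degenerate": degenerate,
    }
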