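"""Screening evaluation and reconstruction-quality metrics.

Screening side: AUROC with a stratified-bootstrap 95% CI, a
fixed-sensitivity operating point (screening convention: sensitivity is
pinned, e.g. at 0.9, and specificity/PPV/NPV are read off there), and the
full confusion-table report. The decision rule at a threshold t is
``score >= t`` (inclusive), which matters when scores tie at the threshold.

Reconstruction side: PSNR/RMSE on the 8-bit (0-255) scale, SSIM with the
standard constants, plus Welch and paired t-tests for group comparisons.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
from scipy import stats
from skimage.metrics import structural_similarity
from sklearn.metrics import roc_auc_score, roc_curve

PSNR_INF = float("inf")  # sentinel for identical images (rmse == 0)


def _check_binary(labels: np.ndarray):
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if not np.isin(classes, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    if classes.size < 2:
        raise ValueError("both classes must be present")
    return labels.astype(int)


def auroc(scores, labels) -> float:
    """Area under the ROC curve (equals the Mann-Whitney statistic)."""
    labels = _check_binary(labels)
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def auroc_ci(scores, labels, n_boot: int = 2000, seed: int = 0,
             method: str = "bootstrap"):
    """95% CI for the AUROC.

    ``method="bootstrap"`` (default): stratified percentile bootstrap —
    positives and negatives are resampled separately so every replicate has
    both classes; NaNs from any pathological resample are skipped and
    counted. ``method="delong"``: the asymptotic normal interval from the
    DeLong covariance estimate, clipped to [0, 1].
    """
    if method == "delong":
        return _delong_ci(scores, labels)
    if method != "bootstrap":
        raise ValueError("method must be 'bootstrap' or 'delong'")
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    rng = np.random.default_rng(seed)
    vals = []
    skipped = 0
    for _ in range(n_boot):
        ps = rng.choice(pos, size=pos.size, replace=True)
        ns = rng.choice(neg, size=neg.size, replace=True)
        s = np.concatenate([ps, ns])
        y = np.concatenate([np.ones(ps.size, int), np.zeros(ns.size, int)])
        a = roc_auc_score(y, s)
        if math.isnan(a):
            skipped += 1
            continue
        vals.append(a)
    vals = np.sort(vals)
    low, high = np.percentile(vals, [2.5, 97.5])
    return float(low), float(high)


def _delong_ci(scores, labels):
    """DeLong 95% CI: AUROC +/- 1.96 * SE from placement-value variances."""
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    r_all = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = stats.rankdata(pos)
    r_neg = stats.rankdata(neg)
    point = (r_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (r_all[:m] - r_pos) / n          # placement values of positives
    v10 = 1.0 - (r_all[m:] - r_neg) / m    # placement values of negatives
    se = math.sqrt(v01.var(ddof=1) / m + v10.var(ddof=1) / n)
    half = 1.959963984540054 * se
    return max(point - half, 0.0), min(point + half, 1.0)


def fixed_sensitivity_threshold(scores, labels, target: float = 0.9) -> float:
    """Largest threshold t with sensitivity(score >= t) >= target.

    With P positives, at least ceil(target * P) of them must score at or
    above t, so t is the ceil(target*P)-th largest positive score. Raising
    t to the next observed score above it necessarily drops below target
    (tightness).
    """
    if not (0.0 < target <= 1.0):
        raise ValueError("target sensitivity must lie in (0, 1]")
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=float)
    pos = np.sort(scores[labels == 1])[::-1]
    k = math.ceil(target * pos.size)
    return float(pos[k - 1])


@dataclass
class ScreeningReport:
    auroc: float
    ci_low: float
    ci_high: float
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float

    def to_json(self, path: Optional[str] = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def summary(self) -> str:
        return (
            f"AUROC {self.auroc:.3f} (95% CI {self.ci_low:.3f}-{self.ci_high:.3f})\n"
            f"threshold {self.threshold:.4f}  "
            f"TP {self.tp}  FP {self.fp}  TN {self.tn}  FN {self.fn}\n"
            f"ACC {self.accuracy:.3f}  SEN {self.sensitivity:.3f}  "
            f"SPE {self.specificity:.3f}  PPV {self.ppv:.3f}  NPV {self.npv:.3f}"
        )


def confusion_metrics(
    scores, labels, threshold: float,
    auroc_value: Optional[float] = None, ci: Optional[tuple] = None,
) -> ScreeningReport:
    """Confusion table and derived rates at ``score >= threshold``."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=float)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    n = tp + fp + tn + fn

    def ratio(a, b):
        return a / b if b > 0 else float("nan")

    if auroc_value is None:
        auroc_value = auroc(scores, labels)
    if ci is None:
        ci = (float("nan"), float("nan"))
    return ScreeningReport(
        auroc=float(auroc_value),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        threshold=float(threshold),
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=ratio(tp + tn, n),
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        ppv=ratio(tp, tp + fp),
        npv=ratio(tn, tn + fn),
    )


def screening_report(
    scores, labels, target_sensitivity: float = 0.9,
    n_boot: int = 2000, seed: int = 0,
) -> ScreeningReport:
    """AUROC + CI + confusion metrics at the fixed-sensitivity threshold."""
    t = fixed_sensitivity_threshold(scores, labels, target_sensitivity)
    ci = auroc_ci(scores, labels, n_boot=n_boot, seed=seed)
    return confusion_metrics(scores, labels, t, ci=ci)


def roc_points(scores, labels) -> np.ndarray:
    """(fpr, tpr, threshold) rows for plotting/export."""
    labels = _check_binary(labels)
    fpr, tpr, thr = roc_curve(labels, np.asarray(scores, dtype=float))
    return np.column_stack([fpr, tpr, thr])


@dataclass
class ReconQuality:
    psnr: float   # dB on the 0-255 scale; inf when rmse == 0
    ssim: float
    rmse: float   # 0-255 scale
    group: Optional[str] = None


def recon_quality(original, reconstruction, group: Optional[str] = None) -> ReconQuality:
    """PSNR/SSIM/RMSE between a query image and its reconstruction.

    Inputs are [0,1] grids of identical shape; RMSE and PSNR use the 8-bit
    convention (data range 255) common for radiograph exports.
    """
    a = np.asarray(original, dtype=np.float64)
    b = np.asarray(reconstruction, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("original and reconstruction must share a shape")
    if min(a.min(), b.min()) < 0 or max(a.max(), b.max()) > 1:
        raise ValueError("intensities must lie in [0, 1]")
    a8, b8 = a * 255.0, b * 255.0
    rmse = float(np.sqrt(np.mean((a8 - b8) ** 2)))
    psnr = PSNR_INF if rmse == 0 else float(20.0 * np.log10(255.0 / rmse))
    ssim = float(
        structural_similarity(a8, b8, data_range=255.0, win_size=7)
    )
    return ReconQuality(psnr=psnr, ssim=ssim, rmse=rmse, group=group)


@dataclass
class GroupComparison:
    t: float
    p: float
    mode: str
    degenerate: bool = False


def compare_groups(values_a, values_b, mode: str = "independent") -> GroupComparison:
    """Welch (independent) or paired two-sided t-test between metric groups."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    if mode == "independent":
        res = stats.ttest_ind(a, b, equal_var=False)
    elif mode == "paired":
        if a.size != b.size:
            raise ValueError("paired mode requires equal lengths")
        diffs = a - b
        if np.allclose(diffs.std(ddof=1), 0.0):
            t = 0.0 if np.allclose(diffs.mean(), 0.0) else float("inf")
            return GroupComparison(t=t, p=1.0 if t == 0.0 else 0.0,
                                   mode=mode, degenerate=True)
        res = stats.ttest_rel(a, b)
    else:
        raise ValueError("mode must be 'independent' or 'paired'")
    t, p = float(res.statistic), float(res.pvalue)
    if math.isnan(t):  # zero variance in both groups with equal means
        return GroupComparison(t=0.0, p=1.0, mode=mode, degenerate=True)
    return GroupComparison(t=t, p=p, mode=mode)
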