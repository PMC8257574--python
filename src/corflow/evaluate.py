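"""Diagnostic performance and agreement of simulated vs. reference FFR.

A vessel is *positive* (functionally significant stenosis) when its FFR is
less than or equal to the 0.80 cutoff — the comparison is inclusive.
Simulated FFR acts as the prediction and measured FFR as the truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .geometry import ValidationError

__all__ = [
    "FFR_CUTOFF",
    "ConfusionCounts",
    "AgreementStats",
    "classify",
    "metrics",
    "roc_auc",
    "bland_altman",
    "evaluation_report",
    "load_pairs",
    "plot_report",
]

FFR_CUTOFF = 0.80


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class AgreementStats:
    """Bland–Altman summary of paired FFR values (differences = sim - ref)."""

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    pearson_r: float
    paired_test_p: float


def _check_pairs(ffr_s, ffr_m) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(ffr_s, dtype=float)
    m = np.asarray(ffr_m, dtype=float)
    if s.shape != m.shape or s.ndim != 1:
        raise ValidationError("ffr_s and ffr_m must be 1-D and the same length")
    return s, m


def classify(ffr_s, ffr_m, cutoff: float = FFR_CUTOFF) -> ConfusionCounts:
    """Tally the confusion matrix at an FFR cutoff (positive iff value <= cutoff)."""
    s, m = _check_pairs(ffr_s, ffr_m)
    pred = s <= cutoff
    truth = m <= cutoff
    return ConfusionCounts(
        tp=int(np.sum(pred & truth)),
        tn=int(np.sum(~pred & ~truth)),
        fp=int(np.sum(pred & ~truth)),
        fn=int(np.sum(~pred & truth)),
    )


def metrics(counts: ConfusionCounts) -> dict[str, float | None]:
    """Accuracy, sensitivity, specificity and precision from a confusion matrix.

    A metric with a zero denominator is reported as ``None`` (undefined),
    never as zero.
    """
    if counts.total == 0:
        raise ValidationError("cannot compute metrics of an empty confusion matrix")

    def _ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    return {
        "accuracy": (counts.tp + counts.tn) / counts.total,
        "sensitivity": _ratio(counts.tp, counts.tp + counts.fn),
        "specificity": _ratio(counts.tn, counts.tn + counts.fp),
        "precision": _ratio(counts.tp, counts.tp + counts.fp),
    }


def roc_auc(scores, truth_labels) -> float:
    """Area under the ROC curve; higher score = more likely positive.

    When ranking vessels by simulated FFR, pass ``scores = -ffr_s`` so that
    low FFR (severe stenosis) ranks as more positive. Ties contribute 1/2,
    the pairwise-concordance convention.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth_labels, dtype=bool)
    if scores.shape != truth.shape or scores.ndim != 1:
        raise ValidationError("scores and truth_labels must be 1-D and the same length")
    if truth.all() or not truth.any():
        raise ValidationError("ROC AUC requires at least one positive and one negative")
    return float(roc_auc_score(truth.astype(int), scores))


def bland_altman(ffr_s, ffr_m) -> AgreementStats:
    """Bland–Altman agreement of paired FFR values.

    Differences are ``ffr_s - ffr_m``; limits of agreement are
    mean ± 1.96 x sample SD (ddof = 1). Also reports the Pearson correlation
    of the pairs and a two-sided paired t-test p-value on the differences.
    """
    s, m = _check_pairs(ffr_s, ffr_m)
    if len(s) < 2:
        raise ValidationError("Bland–Altman analysis requires at least 2 pairs")
    d = s - m
    mean_diff = float(np.mean(d))
    sd_diff = float(np.std(d, ddof=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        if np.ptp(s) == 0 or np.ptp(m) == 0:
            r = float("nan")
        else:
            r = float(stats.pearsonr(s, m).statistic)
        if sd_diff == 0:
            p = float("nan") if mean_diff != 0 else 1.0
        else:
            p = float(stats.ttest_rel(s, m).pvalue)
    return AgreementStats(
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=mean_diff - 1.96 * sd_diff,
        loa_high=mean_diff + 1.96 * sd_diff,
        pearson_r=r,
        paired_test_p=p,
    )


def evaluation_report(ffr_s, ffr_m, cutoff: float = FFR_CUTOFF) -> dict:
    """Full per-vessel evaluation: confusion matrix, metrics, AUC, agreement."""
    s, m = _check_pairs(ffr_s, ffr_m)
    counts = classify(s, m, cutoff)
    report: dict = {
        "n_vessels": int(len(s)),
        "cutoff": cutoff,
        "confusion": {"tp": counts.tp, "tn": counts.tn, "fp": counts.fp, "fn": counts.fn},
        "metrics": metrics(counts),
    }
    truth = m <= cutoff
    if truth.any() and not truth.all():
        report["auc"] = roc_auc(-s, truth)
    else:
        report["auc"] = None
    agree = bland_altman(s, m)
    report["agreement"] = {
        "mean_diff": agree.mean_diff,
        "sd_diff": agree.sd_diff,
        "loa_low": agree.loa_low,
        "loa_high": agree.loa_high,
        "pearson_r": agree.pearson_r,
        "paired_test_p": agree.paired_test_p,
    }
    return report


def load_pairs(path) -> pd.DataFrame:
    """Read a vessel_id/ffr_s/ffr_m CSV of paired FFR values."""
    df = pd.read_csv(path)
    missing = {"vessel_id", "ffr_s", "ffr_m"} - set(df.columns)
    if missing:
        raise ValidationError(f"pairs CSV missing columns: {sorted(missing)}")
    return df


def plot_report(ffr_s, ffr_m, out_dir, cutoff: float = FFR_CUTOFF) -> list[str]:
    """Write scatter, Bland–Altman and ROC plots; returns the file paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from sklearn.metrics import roc_curve

    s, m = _check_pairs(ffr_s, ffr_m)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []

    fig, ax = plt.subplots()
    ax.scatter(m, s, color="tab:blue")
    ax.axhline(cutoff, color="red", ls="--", lw=1)
    ax.axvline(cutoff, color="red", ls="--", lw=1)
    ax.plot([0, 1], [0, 1], color="gray", lw=0.8)
    ax.set_xlabel("measured FFR")
    ax.set_ylabel("simulated FFR")
    p = out / "scatter.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(str(p))

    agree = bland_altman(s, m)
    fig, ax = plt.subplots()
    ax.scatter((s + m) / 2, s - m, color="tab:blue")
    ax.axhline(agree.mean_diff, color="blue")
    ax.axhline(agree.loa_low, color="red", ls="--")
    ax.axhline(agree.loa_high, color="red", ls="--")
    ax.set_xlabel("mean of simulated and measured FFR")
    ax.set_ylabel("difference (sim - meas)")
    p = out / "bland_altman.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(str(p))

    truth = m <= cutoff
    if truth.any() and not truth.all():
        fpr, tpr, _ = roc_curve(truth.astype(int), -s)
        fig, ax = plt.subplots()
        ax.plot(fpr, tpr, color="tab:blue")
        ax.plot([0, 1], [0, 1], color="gray", ls="--")
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        p = out / "roc.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(str(p))
    return paths
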