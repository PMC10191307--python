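"""Classifier performance metrics and clinical sleep metrics.

Confusion matrices are stored as raw K x K counts with rows = predicted
and columns = true stage; the display normalization divides each column
by its true-class total (columns sum to 100%). Classifier metrics are
computed one-vs-rest per class and aggregated both unweighted (macro) and
weighted by true-class support. Clinical metrics summarize a hypnogram
per night: total sleep time, efficiency, onset latency (first run of
three consecutive sleep epochs), fragmentation, the sleep transition
index, and per-stage times/fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stages import Hypnogram

#: sentinel for metrics that are undefined for a night (e.g. no sleep onset)
UNDEFINED = None


@dataclass
class ConfusionMatrix:
    counts: np.ndarray            # (K, K): rows predicted, columns true
    labels: tuple[str, ...] = ()

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        K = self.counts.shape[0]
        if self.counts.shape != (K, K):
            raise ValueError("confusion matrix must be square")
        if np.any(self.counts < 0):
            raise ValueError("confusion matrix counts must be nonnegative")
        if not self.labels:
            self.labels = tuple(str(i) for i in range(K))

    @property
    def K(self) -> int:
        return self.counts.shape[0]

    def column_normalized(self) -> np.ndarray:
        """Percentage matrix whose columns sum to 100."""
        col = self.counts.sum(axis=0, keepdims=True).astype(np.float64)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(col > 0, 100.0 * self.counts / col, np.nan)

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts + other.counts, self.labels)


def confusion(pred: Hypnogram, true: Hypnogram) -> ConfusionMatrix:
    if pred.scheme.name != true.scheme.name:
        raise ValueError("hypnograms use different stage schemes")
    if len(pred) != len(true):
        raise ValueError("hypnograms differ in length")
    K = true.scheme.K
    counts = np.zeros((K, K), dtype=np.int64)
    np.add.at(counts, (pred.codes, true.codes), 1)
    return ConfusionMatrix(counts, true.scheme.labels)


def _binary_mcc(tp: float, fp: float, fn: float, tn: float) -> float:
    denom = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return (tp * tn - fp * fn) / denom if denom > 0 else 0.0


def classifier_metrics(cm: ConfusionMatrix) -> dict:
    """Accuracy, per-class one-vs-rest metrics and their aggregates.

    Per-class values for zero-support classes are NaN and are excluded
    from macro averages (weighted averages give them zero weight).
    """
    c = cm.counts.astype(np.float64)
    total = c.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    support = c.sum(axis=0)            # true counts per class
    predicted = c.sum(axis=1)
    tp = np.diag(c)
    fp = predicted - tp                # predicted k, true other
    fn = support - tp
    tn = total - tp - fp - fn
    with np.errstate(invalid="ignore", divide="ignore"):
        sens = np.where(support > 0, tp / (tp + fn), np.nan)
        spec = np.where(tn + fp > 0, tn / (tn + fp), np.nan)
        prec = np.where(tp + fp > 0, tp / (tp + fp), np.where(support > 0, 0.0, np.nan))
        f1 = np.where(np.isnan(sens) | np.isnan(prec), np.nan,
                      np.where(sens + prec > 0, 2 * sens * prec / (sens + prec), 0.0))
    mcc = np.array([_binary_mcc(tp[k], fp[k], fn[k], tn[k]) if support[k] > 0 else np.nan
                    for k in range(cm.K)])
    w = support / support.sum()

    def wavg(x):
        valid = ~np.isnan(x)
        return float(np.sum(x[valid] * w[valid]) / np.sum(w[valid]))

    return {
        "accuracy": float(tp.sum() / total),
        "per_class": {
            "sensitivity": sens, "specificity": spec, "precision": prec,
            "f1": f1, "mcc": mcc, "support": support.astype(np.int64),
        },
        "sensitivity": float(np.nanmean(sens)),
        "specificity": float(np.nanmean(spec)),
        "precision": float(np.nanmean(prec)),
        "weighted_f1": wavg(f1),
        "macro_mcc": float(np.nanmean(mcc)),
        "weighted_mcc": wavg(mcc),
    }


def subject_wise(metric_values: list[float]) -> tuple[float, float]:
    """Mean and sample SD over per-subject metric values (SD 0 for n=1)."""
    v = np.asarray(metric_values, dtype=np.float64)
    return float(v.mean()), float(v.std(ddof=1)) if v.size > 1 else 0.0


# ---------------------------------------------------------------------------
# Clinical sleep metrics
# ---------------------------------------------------------------------------

def sleep_onset_index(hyp: Hypnogram) -> int | None:
    """Index of the first epoch of the first run of 3 consecutive sleep epochs."""
    sleep = hyp.is_sleep()
    for i in range(len(hyp) - 2):
        if sleep[i] and sleep[i + 1] and sleep[i + 2]:
            return i
    return UNDEFINED


def sleep_onset_latency(hyp: Hypnogram) -> float | None:
    """Minutes from recording start to sleep onset; None if never asleep."""
    i = sleep_onset_index(hyp)
    return UNDEFINED if i is None else i * hyp.epoch_s / 60.0


def sleep_transition_index(hyp: Hypnogram) -> float | None:
    """Post-onset stage-change time over post-onset sleep time.

    A transition is any epoch whose stage differs from its predecessor's
    (within the post-onset segment, any stage pair including wake). The
    denominator is the number of post-onset sleep epochs.
    """
    i0 = sleep_onset_index(hyp)
    if i0 is None:
        return UNDEFINED
    seg = hyp.codes[i0:]
    transitions = int(np.sum(seg[1:] != seg[:-1]))
    sleep_epochs = int(np.sum(hyp.is_sleep()[i0:]))
    if sleep_epochs == 0:
        return UNDEFINED
    return transitions / sleep_epochs


@dataclass
class ClinicalMetrics:
    total_sleep_time_h: float
    recording_time_h: float
    sleep_efficiency: float
    sleep_onset_latency_min: float | None
    sleep_fragmentation: float | None     # sleep->wake transitions per hour TST
    sleep_transition_index: float | None
    stage_time_h: dict[str, float] = field(default_factory=dict)
    stage_fraction: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "total_sleep_time_h": self.total_sleep_time_h,
            "recording_time_h": self.recording_time_h,
            "sleep_efficiency": self.sleep_efficiency,
            "sleep_onset_latency_min": self.sleep_onset_latency_min,
            "sleep_fragmentation": self.sleep_fragmentation,
            "sleep_transition_index": self.sleep_transition_index,
        }
        for k, v in self.stage_time_h.items():
            d[f"time_{k}_h"] = v
        for k, v in self.stage_fraction.items():
            d[f"fraction_{k}"] = v
        return d


def clinical_metrics(hyp: Hypnogram) -> ClinicalMetrics:
    """Night-level clinical summary of a hypnogram.

    Sleep efficiency uses the full concurrent recording duration as its
    denominator (an in-bed proxy). Fragmentation counts post-onset
    sleep-to-wake transitions per hour of total sleep time. Stage
    fractions are over sleep epochs for the sleep stages.
    """
    n = len(hyp)
    ep_h = hyp.epoch_s / 3600.0
    sleep = hyp.is_sleep()
    n_sleep = int(sleep.sum())
    tst_h = n_sleep * ep_h
    rec_h = n * ep_h
    i0 = sleep_onset_index(hyp)
    if i0 is None or tst_h == 0:
        frag = UNDEFINED
    else:
        s = sleep[i0:]
        frag = int(np.sum(s[:-1] & ~s[1:])) / tst_h
    stage_time = {}
    stage_frac = {}
    counts = np.bincount(hyp.codes, minlength=hyp.scheme.K)
    for k, lab in enumerate(hyp.scheme.labels):
        stage_time[lab] = counts[k] * ep_h
        if k != hyp.scheme.wake_index:
            stage_frac[lab] = counts[k] / n_sleep if n_sleep else np.nan
    return ClinicalMetrics(
        total_sleep_time_h=tst_h,
        recording_time_h=rec_h,
        sleep_efficiency=tst_h / rec_h if rec_h else np.nan,
        sleep_onset_latency_min=sleep_onset_latency(hyp),
        sleep_fragmentation=frag,
        sleep_transition_index=sleep_transition_index(hyp),
        stage_time_h=stage_time,
        stage_fraction=stage_frac,
    )


def mae_of_metrics(pred: list[ClinicalMetrics],
                   ref: list[ClinicalMetrics]) -> dict[str, dict]:
    """Per-metric mean absolute error over paired subjects.

    Undefined (None/NaN) values are excluded pairwise; the number of
    contributing subjects is reported per metric. SD is the sample SD of
    the absolute errors (0 for a single subject).
    """
    if len(pred) != len(ref):
        raise ValueError("prediction and reference lists must be paired")
    keys = pred[0].to_dict().keys() if pred else ()
    out: dict[str, dict] = {}
    for key in keys:
        errs = []
        for p, r in zip(pred, ref):
            pv, rv = p.to_dict().get(key), r.to_dict().get(key)
            if pv is None or rv is None or not (np.isfinite(pv) and np.isfinite(rv)):
                continue
            errs.append(abs(pv - rv))
        if errs:
            mean, sd = subject_wise(errs)
            out[key] = {"mae": mean, "sd": sd, "n": len(errs)}
        else:
            out[key] = {"mae": None, "sd": None, "n": 0}
    return out
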