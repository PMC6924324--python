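"""Quantitative comparison of segmenters against reference masks.

Per image: Dice overlap, region-level sensitivity (a reference region
counts as detected when at least 80% of its area is covered), false-positive
region count (predicted regions with zero overlap with any reference
region), and the slide-area fraction covered by false positives.  Method
comparison uses paired t-tests with Bonferroni correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import ndimage, stats

from .core import BinaryMask

_EIGHT = np.ones((3, 3), dtype=bool)

#: detection ratio above which a reference region is a true positive
DETECTION_RATIO = 0.80

#: paired differences with zero variance cannot produce a finite t statistic;
#: such comparisons are flagged degenerate and reported at this bound
DEGENERATE_P_BOUND = float(np.finfo(np.float64).eps)


def _check_compatible(pred: BinaryMask, ref: BinaryMask):
    if pred.data.shape != ref.data.shape:
        raise ValueError("prediction and reference shapes differ")
    if not math.isclose(pred.spacing, ref.spacing, rel_tol=1e-6):
        raise ValueError("prediction and reference spacings differ")


def dice(pred: BinaryMask, ref: BinaryMask) -> float:
    """Dice overlap 2|P∩R| / (|P| + |R|).

    Convention for empty masks: both empty -> 1.0 (perfect agreement on
    'no tissue'); exactly one empty -> 0.0.
    """
    _check_compatible(pred, ref)
    p = pred.data.astype(bool)
    r = ref.data.astype(bool)
    denom = int(p.sum()) + int(r.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((p & r).sum()) / denom


def region_metrics(pred: BinaryMask, ref: BinaryMask):
    """Region-level detection statistics.

    Returns ``(tp, fn, fp, sensitivity, fp_area_fraction)``.  A reference
    region (8-connected) is a true positive iff >= 80% of its area is
    predicted tissue; a predicted region is a false positive iff it overlaps
    no reference region at all.  With no reference regions the sensitivity
    is undefined and reported as NaN.
    """
    _check_compatible(pred, ref)
    p = pred.data.astype(bool)
    r = ref.data.astype(bool)

    ref_lab, n_ref = ndimage.label(r, structure=_EIGHT)
    tp = fn = 0
    for comp in range(1, n_ref + 1):
        region = ref_lab == comp
        covered = int((region & p).sum()) / int(region.sum())
        if covered >= DETECTION_RATIO:
            tp += 1
        else:
            fn += 1

    pred_lab, n_pred = ndimage.label(p, structure=_EIGHT)
    fp = 0
    fp_area = 0
    for comp in range(1, n_pred + 1):
        region = pred_lab == comp
        if not (region & r).any():
            fp += 1
            fp_area += int(region.sum())

    sensitivity = tp / (tp + fn) if (tp + fn) else float("nan")
    fp_area_fraction = fp_area / p.size
    return tp, fn, fp, sensitivity, fp_area_fraction


@dataclass
class ImageResult:
    image: str
    method: str
    dice: float
    sensitivity: float
    fp_count: int
    fp_area_fraction: float


@dataclass
class EvalReport:
    """Per-image rows plus per-method aggregates (mean/stdev/min/max)."""

    rows: list = field(default_factory=list)

    def add(self, image, method, pred: BinaryMask, ref: BinaryMask):
        d = dice(pred, ref)
        _, _, fp, sens, fp_frac = region_metrics(pred, ref)
        self.rows.append(ImageResult(image, method, d, sens, fp, fp_frac))

    def methods(self):
        return sorted({r.method for r in self.rows})

    def scores(self, method, metric="dice"):
        return [getattr(r, metric) for r in self.rows if r.method == method]

    def aggregate(self, method, metric="dice"):
        vals = np.asarray(self.scores(method, metric), dtype=float)
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            return {"mean": float("nan"), "stdev": float("nan"),
                    "min": float("nan"), "max": float("nan")}
        return {
            "mean": float(vals.mean()),
            "stdev": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
            "min": float(vals.min()),
            "max": float(vals.max()),
        }

    def to_csv(self, path):
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["image", "method", "dice", "sensitivity",
                        "fp_count", "fp_area_fraction"])
            for r in self.rows:
                w.writerow([r.image, r.method, f"{r.dice:.6f}",
                            f"{r.sensitivity:.6f}", r.fp_count,
                            f"{r.fp_area_fraction:.8f}"])
            w.writerow([])
            w.writerow(["method", "metric", "mean", "stdev", "min", "max"])
            for m in self.methods():
                for metric in ("dice", "sensitivity", "fp_count", "fp_area_fraction"):
                    agg = self.aggregate(m, metric)
                    w.writerow([m, metric, agg["mean"], agg["stdev"],
                                agg["min"], agg["max"]])

    def to_dict(self):
        return {
            "rows": [vars(r) for r in self.rows],
            "aggregates": {
                m: {metric: self.aggregate(m, metric)
                    for metric in ("dice", "sensitivity", "fp_count", "fp_area_fraction")}
                for m in self.methods()
            },
        }


def paired_t(a, b):
    """Paired t-test returning (t, raw two-sided p, degenerate flag).

    Identical vectors give t = 0, p = 1.  Non-zero constant differences have
    zero variance: the t statistic diverges, so the p-value is reported as
    the machine-epsilon bound with the degenerate flag set.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length vectors with >= 2 observations")
    d = a - b
    sd = d.std(ddof=1)
    # constant differences: sd is zero up to float representation noise
    if sd <= 1e-12 * max(1.0, abs(d.mean())):
        if d.mean() == 0.0:
            return 0.0, 1.0, False
        return math.copysign(math.inf, d.mean()), DEGENERATE_P_BOUND, True
    t = d.mean() / (sd / math.sqrt(d.size))
    p = 2.0 * stats.t.sf(abs(t), df=d.size - 1)
    return float(t), float(p), False


def compare_methods(scores_by_method: dict, alpha: float = 0.05):
    """Pairwise paired t-tests over per-image Dice scores, Bonferroni-corrected.

    ``scores_by_method`` maps method name -> score vector over the same
    images in the same order.  Raw p-values are multiplied by the number of
    method pairs (capped at 1).  Returns a dict keyed by (method_a,
    method_b) with t, p_raw, p_corrected, significant, degenerate.
    """
    methods = sorted(scores_by_method)
    if len(methods) < 2:
        raise ValueError("need at least two methods to compare")
    n = {m: len(scores_by_method[m]) for m in methods}
    if len(set(n.values())) != 1:
        raise ValueError("methods must be scored on identical images")
    pairs = list(combinations(methods, 2))
    out = {}
    for a, b in pairs:
        t, p_raw, degen = paired_t(scores_by_method[a], scores_by_method[b])
        p_corr = min(1.0, p_raw * len(pairs))
        out[(a, b)] = {
            "t": t,
            "p_raw": p_raw,
            "p_corrected": p_corr,
            "significant": p_corr < alpha,
            "degenerate": degen,
        }
    return out
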