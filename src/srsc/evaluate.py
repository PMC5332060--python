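"""Tissue naming, fractional populations, correlation and class-wise statistics.

Cluster indices coming out of an unsupervised fit are arbitrary; this module
maps them to tissue names by their mean apparent diffusion coefficient
(necrotic > peri-necrotic > viable), computes per-class volume fractions,
matches predicted to reference labelings, correlates fractions across
subjects, and summarizes per-class parameter distributions with the
Kruskal-Wallis / Bonferroni-corrected rank-sum testing scheme.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score

__all__ = [
    "SegmentationResult",
    "TissueFractions",
    "segmentation_from_responsibilities",
    "assign_tissue_names",
    "compute_fractions",
    "match_labels",
    "correlate_fractions",
    "classwise_parameter_stats",
    "TISSUE_ORDER",
]

logger = logging.getLogger(__name__)

#: Tissue names in decreasing order of mean ADC.
TISSUE_ORDER = ("necrotic", "peri-necrotic", "viable")

#: Bonferroni-corrected significance threshold for the 3 pairwise comparisons.
BONFERRONI_ALPHA = 0.05 / 3


@dataclass
class SegmentationResult:
    """Hard label volume plus per-class probability volumes and metadata.

    ``labels`` is 0 outside the mask and 1..K inside; ``probabilities`` has
    shape ``grid + (K,)`` and sums to 1 inside the mask.
    """

    labels: np.ndarray
    probabilities: np.ndarray
    mask: np.ndarray
    class_info: list[dict] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.labels.shape != self.mask.shape:
            raise ValueError("labels and mask shapes differ")
        if self.probabilities.shape[:-1] != self.mask.shape:
            raise ValueError("probability grid does not match mask")
        if np.any(self.labels[~self.mask] != 0):
            raise ValueError("labels outside mask must be 0")
        inside = self.labels[self.mask]
        if inside.min() < 1 or inside.max() > self.n_classes:
            raise ValueError("labels inside mask must lie in 1..K")
        psum = self.probabilities[self.mask].sum(axis=1)
        if np.abs(psum - 1.0).max() > 1e-6:
            raise ValueError("probabilities must sum to 1 inside mask")
        if not self.class_info:
            self.class_info = [
                {"name": f"class_{k + 1}"} for k in range(self.n_classes)
            ]

    @property
    def n_classes(self) -> int:
        return self.probabilities.shape[-1]

    def class_index(self, name: str) -> int:
        for k, info in enumerate(self.class_info):
            if info["name"] == name:
                return k
        raise KeyError(name)


@dataclass
class TissueFractions:
    """Per-class volume fractions over the mask (hard counts or mean
    probabilities)."""

    fractions: dict[str, float]
    basis: str
    total_voxels: int

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {total}, expected 1")


def segmentation_from_responsibilities(
    R: np.ndarray, coords: np.ndarray, mask: np.ndarray, metadata: dict | None = None
) -> SegmentationResult:
    """Assemble a SegmentationResult from an N x K responsibility matrix."""
    R = np.asarray(R, dtype=float)
    K = R.shape[1]
    probs = np.zeros(mask.shape + (K,))
    probs[tuple(coords.T)] = R
    labels = np.zeros(mask.shape, dtype=int)
    labels[tuple(coords.T)] = np.argmax(R, axis=1) + 1
    return SegmentationResult(
        labels=labels,
        probabilities=probs,
        mask=mask,
        metadata=metadata or {},
    )


def assign_tissue_names(
    seg: SegmentationResult,
    stack,
    adc_name: str = "ADC",
    t2_post_name: str = "T2_post",
) -> SegmentationResult:
    """Name classes by mean raw ADC: highest = necrotic, middle =
    peri-necrotic, lowest = viable; extra classes become other_1, other_2, ...

    Ties on mean ADC (< 1e-9 apart) are broken by larger mean post-contrast
    T2 -> necrotic, and logged.  Also records per-class mean/SD of every raw
    parameter and the voxel count in ``class_info``.
    """
    K = seg.n_classes
    if K < 3:
        raise ValueError("need >=3 classes for tissue naming")
    if adc_name not in stack.maps:
        raise ValueError(f"parameter {adc_name!r} not present in stack")

    stats = []
    for k in range(K):
        sel = seg.labels == (k + 1)
        entry = {"count": int(sel.sum())}
        for pname, vol in stack.maps.items():
            vals = vol[sel]
            entry[pname] = (
                (float(vals.mean()), float(vals.std(ddof=0)))
                if len(vals)
                else (np.nan, np.nan)
            )
        stats.append(entry)

    adc_means = np.array([s[adc_name][0] for s in stats])
    order = sorted(range(K), key=lambda k: -adc_means[k])
    # tie-break: nearly equal ADC -> larger mean T2 post goes first (necrotic)
    for a, b in itertools.pairwise(range(len(order))):
        ka, kb = order[a], order[b]
        if abs(adc_means[ka] - adc_means[kb]) < 1e-9 and t2_post_name in stack.maps:
            if stats[kb][t2_post_name][0] > stats[ka][t2_post_name][0]:
                order[a], order[b] = kb, ka
                logger.info("ADC tie between classes %d and %d broken by T2 post",
                            ka, kb)

    names = {}
    for rank, k in enumerate(order):
        if rank < 3:
            names[k] = TISSUE_ORDER[rank]
        else:
            names[k] = f"other_{rank - 2}"

    class_info = []
    for k in range(K):
        info = {"name": names[k], "count": stats[k]["count"]}
        for pname in stack.maps:
            info[f"{pname}_mean"], info[f"{pname}_sd"] = stats[k][pname]
        class_info.append(info)

    return SegmentationResult(
        labels=seg.labels,
        probabilities=seg.probabilities,
        mask=seg.mask,
        class_info=class_info,
        metadata=seg.metadata,
    )


def compute_fractions(seg: SegmentationResult, basis: str = "hard") -> TissueFractions:
    """Fraction of mask voxels per class (hard counts or mean probability)."""
    if basis not in ("hard", "soft"):
        raise ValueError(f"basis must be 'hard' or 'soft', got {basis!r}")
    n = int(seg.mask.sum())
    fractions = {}
    for k in range(seg.n_classes):
        name = seg.class_info[k]["name"]
        if basis == "hard":
            fractions[name] = float((seg.labels == (k + 1)).sum()) / n
        else:
            fractions[name] = float(seg.probabilities[seg.mask, k].mean())
    total = sum(fractions.values())
    fractions = {k: v / total for k, v in fractions.items()}  # guard rounding
    return TissueFractions(fractions=fractions, basis=basis, total_voxels=n)


def match_labels(pred: np.ndarray, truth: np.ndarray, mask: np.ndarray | None = None):
    """Optimally match predicted to reference classes and score the agreement.

    Solves the assignment problem maximizing total overlap (Hungarian
    algorithm — exact; verified against exhaustive permutation search in the
    test suite for K <= 10).  Returns a dict with the permutation (predicted
    class -> truth class), matched accuracy, per-class Dice and the adjusted
    Rand index.
    """
    if mask is None:
        mask = (np.asarray(pred) > 0) | (np.asarray(truth) > 0)
    p = np.asarray(pred)[mask].ravel()
    t = np.asarray(truth)[mask].ravel()
    p_classes = np.unique(p)
    t_classes = np.unique(t)
    cont = np.zeros((len(p_classes), len(t_classes)))
    for i, pc in enumerate(p_classes):
        for j, tc in enumerate(t_classes):
            cont[i, j] = np.sum((p == pc) & (t == tc))

    ri, ci = linear_sum_assignment(-cont)
    perm = {int(p_classes[i]): int(t_classes[j]) for i, j in zip(ri, ci)}
    matched = sum(cont[i, j] for i, j in zip(ri, ci))
    accuracy = float(matched / len(p))

    dice = {}
    for i, j in zip(ri, ci):
        pc, tc = p_classes[i], t_classes[j]
        inter = cont[i, j]
        denom = (p == pc).sum() + (t == tc).sum()
        dice[int(tc)] = float(2 * inter / denom) if denom else float("nan")

    leftovers = [int(c) for c in p_classes if int(c) not in perm]
    return {
        "permutation": perm,
        "accuracy": accuracy,
        "dice": dice,
        "ari": float(adjusted_rand_score(t, p)),
        "unmatched_pred_classes": leftovers,
    }


def correlate_fractions(
    pred: list[TissueFractions] | list[dict],
    ref: list[TissueFractions] | list[dict],
    tissues: tuple[str, ...] = TISSUE_ORDER,
) -> pd.DataFrame:
    """Pearson correlation between predicted and reference tissue fractions.

    One row per tissue plus a pooled ``All`` row concatenating every
    (subject, tissue) pair.  Two-sided p-values come from the t-transform.
    Zero variance in either vector makes r undefined; it is reported as None
    with a reason rather than propagating NaN.
    """
    if len(pred) != len(ref):
        raise ValueError("pred and ref must have equal length")

    def frac(obj, tissue):
        d = obj.fractions if isinstance(obj, TissueFractions) else obj
        return float(d.get(tissue, 0.0))

    rows = []
    pooled_x, pooled_y = [], []
    for tissue in tissues:
        x = np.array([frac(p, tissue) for p in pred])
        y = np.array([frac(r, tissue) for r in ref])
        pooled_x.append(x)
        pooled_y.append(y)
        rows.append(_pearson_row(tissue, x, y))
    rows.append(_pearson_row("All", np.concatenate(pooled_x), np.concatenate(pooled_y)))
    table = pd.DataFrame(rows).set_index("tissue")
    # keep undefined correlations as None instead of coercing to NaN
    for col in ("r", "p"):
        table[col] = pd.Series(
            [row[col] for row in rows], index=table.index, dtype=object
        )
    return table


def _pearson_row(name: str, x: np.ndarray, y: np.ndarray) -> dict:
    if len(x) < 3:
        return {"tissue": name, "r": None, "p": None, "n": len(x),
                "note": "fewer than 3 pairs"}
    if np.all(x == x[0]) or np.all(y == y[0]):
        return {"tissue": name, "r": None, "p": None, "n": len(x),
                "note": "zero variance"}
    r, p = scipy.stats.pearsonr(x, y)
    return {"tissue": name, "r": float(r), "p": float(p), "n": len(x), "note": ""}


def classwise_parameter_stats(
    seg: SegmentationResult, stack, alpha: float = BONFERRONI_ALPHA
) -> dict:
    """Per-class, per-parameter summaries with the omnibus + pairwise testing
    scheme.

    For each class and parameter: mean, SD, median and the 5th/95th
    percentiles (box-plot convention with whiskers at those percentiles).
    Per distribution a one-sample Kolmogorov-Smirnov normality test; per
    parameter a Kruskal-Wallis omnibus test across classes and, when
    significant at 0.05, pairwise two-sided rank-sum tests flagged
    significant iff p < ``alpha`` (Bonferroni 0.05/3 = 0.0167 by default).
    Classes with < 2 voxels are skipped and flagged.
    """
    names = [info["name"] for info in seg.class_info]
    summaries = []
    tests = {}
    skipped = []
    for pname, vol in stack.maps.items():
        samples = {}
        for k, name in enumerate(names):
            vals = vol[seg.labels == (k + 1)]
            if len(vals) < 2:
                skipped.append((name, pname))
                continue
            samples[name] = vals
            z = (vals - vals.mean()) / max(vals.std(ddof=1), 1e-300)
            ks_stat, ks_p = scipy.stats.kstest(z, "norm")
            summaries.append(
                {
                    "parameter": pname,
                    "class": name,
                    "n": len(vals),
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)),
                    "median": float(np.median(vals)),
                    "p5": float(np.percentile(vals, 5)),
                    "p95": float(np.percentile(vals, 95)),
                    "ks_stat": float(ks_stat),
                    "ks_p": float(ks_p),
                    "normal": bool(ks_p >= 0.05),
                }
            )
        entry = {"kruskal_p": None, "pairwise": {}}
        if len(samples) >= 2:
            _, kw_p = scipy.stats.kruskal(*samples.values())
            entry["kruskal_p"] = float(kw_p)
            if kw_p < 0.05:
                for a, b in itertools.combinations(samples, 2):
                    _, rs_p = scipy.stats.ranksums(samples[a], samples[b])
                    entry["pairwise"][(a, b)] = {
                        "p": float(rs_p),
                        "significant": bool(rs_p < alpha),
                    }
        tests[pname] = entry
    return {
        "summary": pd.DataFrame(summaries),
        "tests": tests,
        "alpha": alpha,
        "skipped": skipped,
    }
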