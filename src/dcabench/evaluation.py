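"""Quality metrics for scored pairs: ROC discriminability, threshold-based
classification, rms coupling error, and false-positive topology histograms.

AUC is computed on the tie-collapsed ROC curve by the trapezoid rule, which
equals the Mann-Whitney statistic with ties counted one half.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .graph_ensemble import CouplingMatrix, PairTopology
from .inference import InferredCouplings, ScoredPairs

__all__ = [
    "RocCurve",
    "ClassificationReport",
    "RmseReport",
    "FalsePositiveTopologyReport",
    "roc_curve",
    "auc",
    "threshold_by_positive_count",
    "threshold_by_closest_to_ideal",
    "rmse_report",
    "false_positive_topology",
    "contact_map_codes",
]


def _require_both_classes(labels: np.ndarray, what: str) -> None:
    if labels is None:
        raise ValueError(f"{what} requires ground-truth labels")
    if labels.all() or not labels.any():
        raise ValueError(f"{what} needs at least one positive and one negative pair")


@dataclass
class RocCurve:
    """ROC points over all distinct thresholds, highest threshold first."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def roc_curve(scored: ScoredPairs) -> RocCurve:
    """Trace (fpr, tpr) as the threshold sweeps the distinct scores.

    A point is produced per distinct score value, with the convention that a
    pair is predicted positive when ``score >= threshold``; ties therefore
    traverse a single diagonal segment. Starts at (0, 0) (threshold +inf) and
    ends at (1, 1).
    """
    _require_both_classes(scored.labels, "ROC analysis")
    scores = scored.scores
    labels = scored.labels
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    l_sorted = labels[order]
    P = int(labels.sum())
    N = labels.size - P
    tp = np.cumsum(l_sorted)
    fp = np.cumsum(~l_sorted)
    # keep the last index of each run of tied scores
    last_of_tie = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tpr = np.r_[0.0, tp[last_of_tie] / P]
    fpr = np.r_[0.0, fp[last_of_tie] / N]
    thresholds = np.r_[np.inf, s_sorted[last_of_tie]]
    area = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=area)


def auc(scored: ScoredPairs) -> float:
    return roc_curve(scored).auc


@dataclass
class ClassificationReport:
    """Hard classification at one threshold."""

    threshold: float
    tpr: float
    fpr: float
    positive_rate: float
    overprediction: float
    predictions: np.ndarray = field(repr=False)  # bool per pair
    pairs: np.ndarray = field(repr=False)
    labels: np.ndarray = field(repr=False)
    metadata: dict = field(default_factory=dict)

    @property
    def num_false_positives(self) -> int:
        return int(np.sum(self.predictions & ~self.labels))

    @property
    def num_false_negatives(self) -> int:
        return int(np.sum(~self.predictions & self.labels))


def _report(pairs, labels, predictions, threshold, metadata) -> ClassificationReport:
    P = max(int(labels.sum()), 1)
    N = max(int((~labels).sum()), 1)
    tp = int(np.sum(predictions & labels))
    fp = int(np.sum(predictions & ~labels))
    n_pos_true = int(labels.sum())
    return ClassificationReport(
        threshold=float(threshold),
        tpr=tp / P,
        fpr=fp / N,
        positive_rate=float(predictions.mean()),
        overprediction=float(
            (int(predictions.sum()) - n_pos_true) / n_pos_true
        )
        if n_pos_true
        else math.nan,
        predictions=predictions,
        pairs=pairs,
        labels=labels,
        metadata=metadata,
    )


def threshold_by_positive_count(
    scored: ScoredPairs, n_true: int, seed: int = 0
) -> ClassificationReport:
    """Predict exactly ``n_true`` positives (matched-count thresholding).

    The threshold is placed so that all pairs scoring strictly above it are
    positive; if tied scores straddle the boundary, the remaining slots are
    filled by a seeded uniform draw among the tied pairs. When ``n_true``
    equals the number of true interactions, false positives and false
    negatives are equal by construction.
    """
    if scored.labels is None:
        raise ValueError("labels required")
    if n_true > scored.num_pairs:
        raise ValueError("cannot predict more positives than there are pairs")
    scores = scored.scores
    predictions = np.zeros(scored.num_pairs, dtype=bool)
    if n_true > 0:
        order = np.argsort(-scores, kind="stable")
        cutoff = scores[order[n_true - 1]]
        above = scores > cutoff
        n_above = int(above.sum())
        predictions[above] = True
        n_fill = n_true - n_above
        tied = np.flatnonzero(scores == cutoff)
        if n_fill > 0:
            rng = np.random.default_rng(seed)
            predictions[rng.choice(tied, size=n_fill, replace=False)] = True
        threshold = float(cutoff)
    else:
        threshold = math.inf
    return _report(
        scored.pairs,
        scored.labels,
        predictions,
        threshold,
        {"mode": "matched_count", "n_true": n_true, "tie_seed": seed},
    )


def threshold_by_closest_to_ideal(
    validation: ScoredPairs, test: ScoredPairs, p: float = 2.0
) -> ClassificationReport:
    """Pick the validation-ROC threshold nearest the ideal corner (0, 1).

    Distance is the l_p norm of (fpr, 1 - tpr) (Euclidean by default);
    among equal-distance candidates the lowest threshold (most positives)
    wins. The report is computed on the test set with the convention
    ``score >= threshold`` => positive.
    """
    _require_both_classes(validation.labels, "threshold selection")
    if test.labels is None:
        raise ValueError("test labels required")
    curve = roc_curve(validation)
    if math.isinf(p):
        dist = np.maximum(curve.fpr, 1.0 - curve.tpr)
    else:
        dist = (curve.fpr**p + (1.0 - curve.tpr) ** p) ** (1.0 / p)
    # thresholds are descending; argmin of reversed array finds the last
    # (lowest-threshold) minimizer
    best = len(dist) - 1 - int(np.argmin(dist[::-1]))
    threshold = curve.thresholds[best]
    predictions = test.scores >= threshold
    return _report(
        test.pairs,
        test.labels,
        predictions,
        threshold,
        {
            "mode": "closest_to_ideal",
            "p": p,
            "validation_fpr": float(curve.fpr[best]),
            "validation_tpr": float(curve.tpr[best]),
            "validation_distance": float(dist[best]),
        },
    )


@dataclass
class RmseReport:
    """Error decomposition of inferred couplings against the 0/1 truth."""

    rmse: float
    bias_by_class: dict  # true value -> mean inferred coupling
    variance_by_class: dict
    count_by_class: dict

    def check_identity(self) -> float:
        """| rmse^2 - sum_c w_c ((bias_c - c)^2 + var_c) |, ~0 by algebra."""
        total = sum(self.count_by_class.values())
        acc = 0.0
        for cls, cnt in self.count_by_class.items():
            acc += (
                cnt
                / total
                * ((self.bias_by_class[cls] - cls) ** 2 + self.variance_by_class[cls])
            )
        return abs(self.rmse**2 - acc)


def rmse_report(inferred: InferredCouplings, truth: CouplingMatrix) -> RmseReport:
    """Root-mean-square error of J_hat = T*beta*J_hat over unordered pairs."""
    if inferred.n != truth.n:
        raise ValueError("dimension mismatch between inferred and true couplings")
    iu, ju = np.triu_indices(truth.n, k=1)
    est = inferred.couplings[iu, ju]
    true = truth.entries[iu, ju].astype(np.float64)
    rmse = float(np.sqrt(np.mean((est - true) ** 2)))
    bias, var, cnt = {}, {}, {}
    for cls in (0.0, 1.0):
        sel = true == cls
        cnt[cls] = int(sel.sum())
        if cnt[cls]:
            bias[cls] = float(est[sel].mean())
            var[cls] = float(est[sel].var())
        else:
            bias[cls] = math.nan
            var[cls] = math.nan
    return RmseReport(rmse=rmse, bias_by_class=bias, variance_by_class=var, count_by_class=cnt)


@dataclass
class FalsePositiveTopologyReport:
    """Shortest-path-count histograms for distance-2 pairs.

    ``fp_histogram`` covers false-positive noninteracting pairs at graph
    distance two; ``baseline_histogram`` covers all noninteracting
    distance-2 pairs in the evaluated set. Both normalized and raw counts
    are provided; an empty false-positive histogram is flagged, not an error.
    """

    fp_histogram: dict  # path count -> fraction
    baseline_histogram: dict
    fp_counts: dict
    baseline_counts: dict
    empty: bool


def false_positive_topology(
    report: ClassificationReport, topology: list[PairTopology]
) -> FalsePositiveTopologyReport:
    """Histogram shortest-path multiplicities of distance-2 false positives."""
    topo_map = {tuple(t.pair): t for t in topology}
    fp_counter: Counter = Counter()
    base_counter: Counter = Counter()
    for k, (i, j) in enumerate(report.pairs):
        t = topo_map.get((int(i), int(j)))
        if t is None:
            raise ValueError(f"pair ({i}, {j}) missing from topology")
        if t.label or t.graph_distance != 2:
            continue
        base_counter[t.num_shortest_paths] += 1
        if report.predictions[k]:
            fp_counter[t.num_shortest_paths] += 1

    def normalize(counter: Counter) -> dict:
        total = sum(counter.values())
        return {k: v / total for k, v in sorted(counter.items())} if total else {}

    return FalsePositiveTopologyReport(
        fp_histogram=normalize(fp_counter),
        baseline_histogram=normalize(base_counter),
        fp_counts=dict(sorted(fp_counter.items())),
        baseline_counts=dict(sorted(base_counter.items())),
        empty=not fp_counter,
    )


def contact_map_codes(report: ClassificationReport, n: int) -> np.ndarray:
    """n x n matrix coding 1 = true positive, 2 = false positive, 3 = false
    negative, 0 otherwise (symmetric), for contact-map style rendering."""
    codes = np.zeros((n, n), dtype=np.int8)
    for k, (i, j) in enumerate(report.pairs):
        pred = report.predictions[k]
        lab = report.labels[k]
        if pred and lab:
            code = 1
        elif pred and not lab:
            code = 2
        elif lab and not pred:
            code = 3
        else:
            continue
        codes[i, j] = codes[j, i] = code
    return codes
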