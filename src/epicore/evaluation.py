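"""Metrics, ROC/AROC, threshold calibration, cross-validation, cross-evaluation.

All classification throughout uses the strict rule ``score > threshold``.
Thresholds are anchored on specificity: a tier cutoff is the smallest
observed score whose false-positive fraction is at most 1 - Sp_target,
so raising the target specificity can only raise the cutoff.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .matrices import CORE_LENGTH, encode_peptides
from .scoring import score_against_cores

logger = logging.getLogger(__name__)

#: Tier -> target specificity used for cutoff calibration; medium is default.
TIER_SPECIFICITY = {"high": 0.97, "medium": 0.95, "low": 0.90}
DEFAULT_TIER = "medium"


@dataclass
class ScoreTable:
    """Scores for labeled nonamers: one list per class, plus a context label."""

    positive_scores: np.ndarray
    negative_scores: np.ndarray
    context: str = ""
    positive_seqs: list[str] | None = None
    negative_seqs: list[str] | None = None

    def __post_init__(self):
        self.positive_scores = np.asarray(self.positive_scores, dtype=np.float64)
        self.negative_scores = np.asarray(self.negative_scores, dtype=np.float64)

    def require_nonempty(self):
        if self.positive_scores.size == 0:
            raise ValueError("score table has no positive scores")
        if self.negative_scores.size == 0:
            raise ValueError("score table has no negative scores")


def confusion_metrics(tp: int, fp: int, tn: int, fn: int):
    """Sensitivity, specificity, accuracy and Matthews correlation coefficient.

    Sn = TP/(TP+FN), Sp = TN/(TN+FP), Ac = (TP+TN)/total,
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),
    with MCC defined as 0 when any denominator factor vanishes.
    """
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    if tp + fn == 0:
        raise ValueError("no positive examples (TP + FN = 0)")
    if tn + fp == 0:
        raise ValueError("no negative examples (TN + FP = 0)")
    sn = tp / (tp + fn)
    sp = tn / (tn + fp)
    ac = (tp + tn) / (tp + fp + tn + fn)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    return sn, sp, ac, mcc


def metrics_at_threshold(table: ScoreTable, threshold: float):
    """Confusion metrics at a cutoff under the strict ``score > threshold`` rule."""
    table.require_nonempty()
    tp = int((table.positive_scores > threshold).sum())
    fn = table.positive_scores.size - tp
    fp = int((table.negative_scores > threshold).sum())
    tn = table.negative_scores.size - fp
    return confusion_metrics(tp, fp, tn, fn)


@dataclass
class RocCurve:
    """ROC points ((1-Sp, Sn) per threshold, descending) and the trapezoidal area."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    aroc: float


def roc_and_aroc(table: ScoreTable) -> RocCurve:
    """ROC over the observed-score threshold grid and its trapezoidal area.

    Thresholds sweep the sorted union of observed scores plus sentinels,
    descending, with strict ``>`` classification; the area equals the
    Mann-Whitney statistic U / (n_pos * n_neg) with the usual half-credit
    for ties.
    """
    table.require_nonempty()
    pos = np.sort(table.positive_scores)
    neg = np.sort(table.negative_scores)
    grid = np.unique(np.concatenate([pos, neg]))
    # descending thresholds: +inf sentinel (0,0) down to below the minimum (1,1)
    thresholds = np.concatenate([[np.inf], grid[::-1], [-np.inf]])
    n_pos, n_neg = pos.size, neg.size
    tpr = np.empty(thresholds.size)
    fpr = np.empty(thresholds.size)
    for i, t in enumerate(thresholds):
        tpr[i] = (n_pos - np.searchsorted(pos, t, side="right")) / n_pos
        fpr[i] = (n_neg - np.searchsorted(neg, t, side="right")) / n_neg
    aroc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, aroc=aroc)


@dataclass
class PerformanceReport:
    """Evaluation summary: ROC/AROC plus per-tier threshold metrics."""

    context: str
    aroc: float
    roc: RocCurve | None
    tier_metrics: dict  # tier -> dict(threshold, sn, sp, ac, mcc)
    n_positive: int
    n_negative: int

    def to_rows(self):
        rows = []
        for tier, m in self.tier_metrics.items():
            rows.append(
                {
                    "context": self.context,
                    "tier": tier,
                    "threshold": m["threshold"],
                    "sn": m["sn"],
                    "sp": m["sp"],
                    "ac": m["ac"],
                    "mcc": m["mcc"],
                    "aroc": self.aroc,
                }
            )
        return rows


def calibrate_thresholds(table: ScoreTable, tier_specificity=None) -> dict[str, float]:
    """Specificity-anchored tier cutoffs (high/medium/low at Sp 97/95/90%).

    Calibrated on the leave-one-out score table of the final trained
    model; the medium tier is the default at prediction time.  Ordering
    high >= medium >= low always holds.
    """
    from .training import sn_at_fixed_sp  # local import: avoids module cycle

    tiers = tier_specificity or TIER_SPECIFICITY
    out = {}
    for tier, sp in tiers.items():
        _, threshold = sn_at_fixed_sp(table, sp)
        out[tier] = threshold
    return out


def evaluate_table(table: ScoreTable, thresholds: dict[str, float]) -> PerformanceReport:
    """Full report for a score table at the given tier cutoffs."""
    roc = roc_and_aroc(table)
    tier_metrics = {}
    for tier, t in thresholds.items():
        sn, sp, ac, mcc = metrics_at_threshold(table, t)
        tier_metrics[tier] = {"threshold": t, "sn": sn, "sp": sp, "ac": ac, "mcc": mcc}
    return PerformanceReport(
        context=table.context,
        aroc=roc.aroc,
        roc=roc,
        tier_metrics=tier_metrics,
        n_positive=table.positive_scores.size,
        n_negative=table.negative_scores.size,
    )


@dataclass
class CVReport:
    """Averaged n-fold cross-validation results."""

    n_folds: int
    repeats: int
    mean_aroc: float
    mean_sn: float
    mean_sp: float
    mean_ac: float
    mean_mcc: float
    sp_anchor: float
    fold_arocs: np.ndarray = field(default_factory=lambda: np.empty(0))


def n_fold_cv(
    data,
    n_folds: int,
    repeats: int,
    model,
    seed: int = 0,
    sp_anchor: float = 0.90,
    retrain: bool = False,
    train_config=None,
) -> CVReport:
    """Repeated stratified n-fold cross-validation.

    Positives and negatives are mixed and split into ``n_folds``
    stratified parts per repeat; each part is held out once and scored
    against a model whose core set is the training-part positives.  By
    default only the core-set membership changes per fold (the trained
    matrix and weights of ``model`` are frozen); ``retrain=True`` reruns
    the full weight/matrix training inside every fold.

    Per-fold sensitivity and companions are measured at the threshold
    achieving ``sp_anchor`` specificity on that fold's own table; AROC is
    threshold-free.  Averages run over folds and repeats; per-repeat seeds
    derive from the master ``seed``.
    """
    from sklearn.model_selection import StratifiedKFold

    from .training import sn_at_fixed_sp, train_model

    pos = list(data.positives)
    neg = list(data.negatives)
    if len(pos) < n_folds or len(neg) < n_folds:
        raise ValueError(
            f"cannot form {n_folds} folds with {len(pos)} positives and "
            f"{len(neg)} negatives; use fewer folds"
        )
    sequences = np.array(pos + neg)
    labels = np.array([1] * len(pos) + [0] * len(neg))
    codes = encode_peptides(sequences, CORE_LENGTH)

    seeds = np.random.SeedSequence(seed).generate_state(repeats) % (2**31)
    arocs, sns, sps, acs, mccs = [], [], [], [], []
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=int(seeds[r]))
        for train_idx, test_idx in skf.split(sequences, labels):
            train_pos_idx = train_idx[labels[train_idx] == 1]
            test_pos_idx = test_idx[labels[test_idx] == 1]
            test_neg_idx = test_idx[labels[test_idx] == 0]
            if len(test_pos_idx) == 0 or len(test_neg_idx) == 0:
                raise ValueError("a fold has an empty class; use fewer folds")
            if retrain:
                from .dataset import LabeledNonamerSet

                train_neg_idx = train_idx[labels[train_idx] == 0]
                fold_model = train_model(
                    list(sequences[train_pos_idx]),
                    list(sequences[train_neg_idx]),
                    train_config,
                )
                matrix, weights = fold_model.matrix, fold_model.weights
                core_codes = fold_model.encoded_cores
            else:
                matrix, weights = model.matrix, model.weights
                core_codes = codes[train_pos_idx]
            p_scores = score_against_cores(codes[test_pos_idx], core_codes, matrix, weights)
            n_scores = score_against_cores(codes[test_neg_idx], core_codes, matrix, weights)
            table = ScoreTable(p_scores, n_scores, context=f"fold r{r}")
            arocs.append(roc_and_aroc(table).aroc)
            sn, t = sn_at_fixed_sp(table, sp_anchor)
            sn_, sp_, ac_, mcc_ = metrics_at_threshold(table, t)
            sns.append(sn_)
            sps.append(sp_)
            acs.append(ac_)
            mccs.append(mcc_)
    return CVReport(
        n_folds=n_folds,
        repeats=repeats,
        mean_aroc=float(np.mean(arocs)),
        mean_sn=float(np.mean(sns)),
        mean_sp=float(np.mean(sps)),
        mean_ac=float(np.mean(acs)),
        mean_mcc=float(np.mean(mccs)),
        sp_anchor=sp_anchor,
        fold_arocs=np.array(arocs),
    )


def score_labeled_set(model, data, context: str = "") -> ScoreTable:
    """Score a labeled nonamer set against a model's cores (no LOO exclusion)."""
    pos_codes = encode_peptides(data.positives, CORE_LENGTH)
    neg_codes = encode_peptides(data.negatives, CORE_LENGTH)
    p = score_against_cores(pos_codes, model.encoded_cores, model.matrix, model.weights)
    n = score_against_cores(neg_codes, model.encoded_cores, model.matrix, model.weights)
    return ScoreTable(p, n, context=context,
                      positive_seqs=list(data.positives), negative_seqs=list(data.negatives))


def cross_evaluate(model, foreign, context: str = "cross-eval") -> PerformanceReport:
    """Evaluate a model trained on one haplotype against the other's data.

    The foreign positives and negatives are scored against the model's own
    cores, matrix and weights; the report uses the model's calibrated tier
    cutoffs.
    """
    table = score_labeled_set(model, foreign, context=context)
    return evaluate_table(table, model.thresholds)


@dataclass
class EpitopeHitReport:
    """Epitope-level prediction outcome: per-epitope hit flags and the fraction."""

    hits: list[bool]
    hit_fraction: float
    tier: str | None
    threshold: float


def epitope_level_report(
    proteins: dict[str, str],
    epitopes,
    model,
    tier: str | None = None,
    threshold: float | None = None,
) -> EpitopeHitReport:
    """Scan each epitope's source protein and apply the containment hit rule.

    An epitope counts as predicted when at least one predicted nonamer lies
    fully inside its span.
    """
    from .dataset import epitope_hit
    from .scoring import scan_protein

    if threshold is None:
        threshold = model.threshold_for_tier(tier or model.default_tier)
    hits_by_protein: dict[str, list] = {}
    flags = []
    for e in epitopes:
        if e.protein_id not in hits_by_protein:
            seq = proteins[e.protein_id]
            hits_by_protein[e.protein_id] = scan_protein(seq, model, threshold=threshold)
        flags.append(epitope_hit(e, hits_by_protein[e.protein_id]))
    frac = float(np.mean(flags)) if flags else 0.0
    return EpitopeHitReport(hits=flags, hit_fraction=frac, tier=tier, threshold=threshold)
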