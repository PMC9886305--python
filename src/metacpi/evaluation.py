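"""Out-of-distribution splits, metrics, model selection and significance.

The central evaluation idea is *family-disjoint* splitting: whole
protein families are assigned to OOD-train, OOD-dev or OOD-test, so the
dev and test sets contain no family seen in training and the dev set is
itself disjoint from test. The *deployment gap* (OOD-test minus OOD-dev
performance) measures whether dev-set model selection ("stress model
selection") transfers: a gap near zero means the dev set is an honest
rehearsal of deployment.

Prediction scores of known non-binders follow an extreme-value law; the
significance model fits p = exp(-exp(a*x - b)) to the empirical tail of
negative-pair scores and converts a raw score to a p-value and, scaled
by the size of the chemical-genomics search space, an E-value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .msa import InputError

#: calibration printed for the production-scale model: slope, intercept
DEFAULT_SIGNIFICANCE_SLOPE = 21.7678
DEFAULT_SIGNIFICANCE_INTERCEPT = 11.0939
#: ~1e6 chemicals x ~2e4 human proteins
DEFAULT_SEARCH_SPACE = 2.0e10

ACTIVITY_THRESHOLDS = {"pIC50": 5.3, "pKd": 7.3, "pKi": 7.3}
_RAW_TO_P = {"IC50": "pIC50", "Kd": "pKd", "Ki": "pKi"}


class MetricError(ValueError):
    """Metric undefined for the given labels."""


class SplitError(ValueError):
    """Not enough families to build the OOD split."""


@dataclass(frozen=True)
class MetricReport:
    roc_auc: float
    pr_auc: float
    per_class: dict = field(default_factory=dict)

    def __post_init__(self):
        for v in (self.roc_auc, self.pr_auc):
            if not 0.0 <= v <= 1.0:
                raise InputError("metrics must lie in [0, 1]")


@dataclass(frozen=True)
class DeploymentGap:
    gap_roc: float
    gap_pr: float


@dataclass(frozen=True)
class FamilySplitPlan:
    ood_train_families: frozenset
    iid_dev_families: frozenset
    ood_dev_families: frozenset
    ood_test_families: frozenset
    train_pairs: list = field(default_factory=list)
    iid_dev_pairs: list = field(default_factory=list)
    ood_dev_pairs: list = field(default_factory=list)
    ood_test_pairs: list = field(default_factory=list)

    def __post_init__(self):
        tr, dv, te = (self.ood_train_families, self.ood_dev_families,
                      self.ood_test_families)
        if tr & dv or tr & te or dv & te:
            raise SplitError("OOD splits must be family-disjoint")
        if not self.iid_dev_families <= tr:
            raise SplitError("IID-dev families must come from OOD-train")


def make_ood_split(family_ids: Sequence[str],
                   rng: np.random.Generator,
                   fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
                   pairs_by_family: dict[str, list] | None = None,
                   iid_dev_fraction: float = 0.1) -> FamilySplitPlan:
    """Family-level partition into OOD-train / OOD-dev / OOD-test.

    When ``pairs_by_family`` is given, each split receives its families'
    pairs; IID-dev pairs are held out from the train-family pairs (same
    distribution as training, unlike OOD-dev).
    """
    family_ids = list(family_ids)
    if len(family_ids) < 3:
        raise SplitError("need at least 3 families for an OOD split")
    if not math.isclose(sum(fractions), 1.0, abs_tol=1e-9):
        raise SplitError("split fractions must sum to 1")
    perm = [family_ids[i] for i in rng.permutation(len(family_ids))]
    n = len(perm)
    n_dev = max(1, int(round(fractions[1] * n)))
    n_test = max(1, int(round(fractions[2] * n)))
    n_train = n - n_dev - n_test
    if n_train < 1:
        raise SplitError("fractions leave no training family")
    train = perm[:n_train]
    dev = perm[n_train:n_train + n_dev]
    test = perm[n_train + n_dev:]
    train_pairs, iid_dev_pairs, ood_dev_pairs, ood_test_pairs = [], [], [], []
    if pairs_by_family is not None:
        for fid in train:
            pairs = list(pairs_by_family.get(fid, []))
            k = int(round(iid_dev_fraction * len(pairs)))
            idx = set(rng.permutation(len(pairs))[:k].tolist())
            iid_dev_pairs.extend(p for i, p in enumerate(pairs) if i in idx)
            train_pairs.extend(p for i, p in enumerate(pairs) if i not in idx)
        for fid in dev:
            ood_dev_pairs.extend(pairs_by_family.get(fid, []))
        for fid in test:
            ood_test_pairs.extend(pairs_by_family.get(fid, []))
    return FamilySplitPlan(
        ood_train_families=frozenset(train), iid_dev_families=frozenset(train),
        ood_dev_families=frozenset(dev), ood_test_families=frozenset(test),
        train_pairs=train_pairs, iid_dev_pairs=iid_dev_pairs,
        ood_dev_pairs=ood_dev_pairs, ood_test_pairs=ood_test_pairs)


# ---- activity binarization ------------------------------------------------

@dataclass(frozen=True)
class ActivityMeasurement:
    chemical_id: str
    protein_id: str
    measurement_type: str   # pIC50 / pKd / pKi, or raw IC50 / Kd / Ki in nM
    value: float


def binarize_activity(record: ActivityMeasurement) -> int:
    """Active iff pIC50 > 5.3, pKd > 7.3 or pKi > 7.3 (strict); raw nM
    values are converted via p = -log10(value * 1e-9) first."""
    mtype, value = record.measurement_type, record.value
    if mtype in _RAW_TO_P:
        if value <= 0:
            raise InputError(f"raw {mtype} must be positive (got {value})")
        mtype = _RAW_TO_P[mtype]
        value = -math.log10(value * 1e-9)
    if mtype not in ACTIVITY_THRESHOLDS:
        raise InputError(f"unknown measurement type {record.measurement_type!r}")
    return int(value > ACTIVITY_THRESHOLDS[mtype])


# ---- metrics --------------------------------------------------------------

def _check_two_class(labels: np.ndarray):
    if len(np.unique(labels)) < 2:
        raise MetricError("metric undefined: only one class present")


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    labels = np.asarray(labels)
    _check_two_class(labels)
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def pr_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    labels = np.asarray(labels)
    _check_two_class(labels)
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def metric_report(scores: Sequence[float], labels: Sequence[int]) -> MetricReport:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    preds = (scores >= 0.5).astype(int)
    per_class = {}
    for cls in (0, 1):
        tp = int(((preds == cls) & (labels == cls)).sum())
        fp = int(((preds == cls) & (labels != cls)).sum())
        fn = int(((preds != cls) & (labels == cls)).sum())
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        per_class[cls] = {"precision": prec, "recall": rec, "f1": f1}
    return MetricReport(roc_auc=roc_auc(scores, labels),
                        pr_auc=pr_auc(scores, labels), per_class=per_class)


def deployment_gap(test: MetricReport, dev: MetricReport) -> DeploymentGap:
    """Signed test-minus-dev difference (negative = worse at deployment)."""
    return DeploymentGap(gap_roc=test.roc_auc - dev.roc_auc,
                         gap_pr=test.pr_auc - dev.pr_auc)


def stress_select(checkpoints: Sequence, metric: str = "pr_auc"):
    """Checkpoint with the best OOD-dev metric; ties go to the earliest
    step (the less-trained, less-overfit instance)."""
    if not checkpoints:
        raise InputError("no checkpoints to select from")
    scored = [c for c in checkpoints if c.dev_report is not None]
    if not scored:
        return checkpoints[-1]
    return max(sorted(scored, key=lambda c: c.step),
               key=lambda c: getattr(c.dev_report, metric))


# ---- extreme-value significance -------------------------------------------

@dataclass(frozen=True)
class SignificanceModel:
    """p(x) = exp(-exp(a*x - b)); E(p) = p * search_space."""

    slope: float = DEFAULT_SIGNIFICANCE_SLOPE
    intercept: float = DEFAULT_SIGNIFICANCE_INTERCEPT
    search_space: float = DEFAULT_SEARCH_SPACE
    r_squared: float | None = None


def fit_significance(negative_scores: Sequence[float],
                     search_space: float = DEFAULT_SEARCH_SPACE) -> SignificanceModel:
    """Fit the extreme-value tail of non-binder scores.

    Empirical tail probabilities use the plotting position p_k = k/(n+1)
    over descending score ranks (avoids p = 0); least squares on
    log(-log p) against score recovers (a, b), with R^2 reported.
    """
    x = np.sort(np.asarray(negative_scores, dtype=float))[::-1]
    n = len(x)
    if n < 10:
        raise InputError("need at least 10 scores to fit the tail")
    if np.allclose(x, x[0]):
        raise InputError("degenerate fit: all scores identical")
    p_hat = np.arange(1, n + 1) / (n + 1)
    y = np.log(-np.log(p_hat))
    a, neg_b = np.polyfit(x, y, 1)
    resid = y - (a * x + neg_b)
    r2 = 1.0 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
    return SignificanceModel(slope=float(a), intercept=float(-neg_b),
                             search_space=search_space, r_squared=float(r2))


def pvalue(score: float, model: SignificanceModel) -> float:
    return float(np.exp(-np.exp(model.slope * score - model.intercept)))


def evalue(p: float, model: SignificanceModel) -> float:
    """Expected number of false positives at this p-value across the
    search space."""
    return float(p * model.search_space)


def simulate_model_scores(model: SignificanceModel, n: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Draw scores whose survival function is exactly the model's p(x)
    (inverse-transform sampling); used for calibration checks."""
    u = rng.uniform(size=n)
    return (model.intercept + np.log(-np.log(u))) / model.slope


# ---- screening ------------------------------------------------------------

def enrichment_factor(scores: Sequence[float], labels: Sequence[int],
                      fraction: float) -> float:
    """EF = (actives in the top ceil(fraction*n) by score / all actives)
    / fraction; 1.0 is the chance level."""
    if not 0.0 < fraction <= 1.0:
        raise InputError("fraction must lie in (0, 1]")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_act = int(labels.sum())
    if n_act == 0:
        raise MetricError("enrichment factor undefined without actives")
    n_top = int(math.ceil(fraction * len(scores)))
    order = np.argsort(-scores, kind="stable")
    cutoff_score = scores[order[n_top - 1]]
    if n_top < len(scores) and scores[order[n_top]] == cutoff_score:
        warnings.warn("score ties at the enrichment cutoff; "
                      "broken by stable input order")
    top_act = int(labels[order[:n_top]].sum())
    return (top_act / n_act) / fraction


@dataclass(frozen=True)
class KiRecord:
    compound_id: str
    ki_drd1_nM: float
    ki_drd2_nM: float
    ki_drd3_nM: float

    def __post_init__(self):
        if min(self.ki_drd1_nM, self.ki_drd2_nM, self.ki_drd3_nM) <= 0:
            raise InputError("Ki values must be positive")


def dual_antagonist_filter(records: Sequence[KiRecord],
                           threshold_nM: float = 100.0,
                           ) -> tuple[list[KiRecord], float]:
    """Selective dual-D1/D3 antagonist criterion: Ki below the threshold
    at DRD1 and DRD3 but above it at DRD2 (strict inequalities; a
    boundary Ki of exactly 100 nM fails). Returns (passing, rate)."""
    passing = [r for r in records
               if r.ki_drd1_nM < threshold_nM and r.ki_drd3_nM < threshold_nM
               and r.ki_drd2_nM > threshold_nM]
    rate = len(passing) / len(records) if records else float("nan")
    return passing, rate


def read_ki_csv(path) -> list[KiRecord]:
    import csv
    out = []
    with open(path) as fh:
        for row in csv.DictReader(fh):
            out.append(KiRecord(compound_id=row["compound_id"],
                                ki_drd1_nM=float(row["ki_drd1_nM"]),
                                ki_drd2_nM=float(row["ki_drd2_nM"]),
                                ki_drd3_nM=float(row["ki_drd3_nM"])))
    return out
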