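"""Order-k accuracy evaluation under leave-one-out and k-fold protocols.

The evaluation statistic is the order-k accuracy

    ACC_k = (1/n) * sum_i [ k-th-ranked category of protein i is truly
                            annotated on protein i ]

computed for every rank k of the scheme.  Because each prediction is a full
permutation of the categories, the accuracies obey the conservation law
``sum_k ACC_k = mean number of true categories per protein`` for *any*
predictor — a useful cross-check on the harness itself.

Both protocols exclude held-out proteins from the reference universe of
every evidence branch: a held-out protein contributes neither annotations,
similarity hits nor interaction edges to its own prediction, and in k-fold
evaluation test-fold proteins cannot vouch for each other either (they are
unannotated by construction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import clone
from sklearn.model_selection import KFold

from .annotation import RankedPrediction
from .io import Dataset
from .scoring import FunctionCascade


@dataclass
class PredictionRow:
    """One evaluated protein: its ranked prediction against its true labels."""

    protein_id: str
    prediction: RankedPrediction
    truth: frozenset[int]
    branch: str


@dataclass
class BranchStat:
    """Cascade branch accounting: how many queries a branch served and how
    accurate its 1st-order predictions were."""

    count: int
    proportion: float
    acc1: float


@dataclass
class EvaluationReport:
    """Aggregated evaluation output.

    ``order_accuracies[k-1]`` is ACC_k over all evaluated rows.  For k-fold
    runs, ``repeat_accuracies`` holds one ACC vector per repeat and
    ``mean_accuracies`` / ``std_accuracies`` their per-rank mean and sample
    standard deviation (ddof=1) across repeats.
    """

    per_protein: list[PredictionRow]
    order_accuracies: np.ndarray
    branch_stats: dict[str, BranchStat]
    repeat_accuracies: list[np.ndarray] | None = None
    mean_accuracies: np.ndarray | None = None
    std_accuracies: np.ndarray | None = None
    seed: int | None = None
    protocol: str = "loo"


def _as_pairs(rows):
    pairs = []
    for row in rows:
        if isinstance(row, PredictionRow):
            pairs.append((row.prediction, row.truth))
        else:
            pairs.append(tuple(row))
    return pairs


def order_accuracy(rows, j: int) -> float:
    """Fraction of rows whose j-th-ranked category is truly annotated."""
    pairs = _as_pairs(rows)
    if not pairs:
        raise ValueError("order accuracy is undefined for an empty row list")
    k = pairs[0][0].order.size
    if not 1 <= j <= k:
        raise ValueError(f"order index {j} outside 1..{k}")
    hits = sum(1 for pred, truth in pairs if pred.order_k(j) in truth)
    return hits / len(pairs)


def _accuracy_vector(rows) -> np.ndarray:
    pairs = _as_pairs(rows)
    k = pairs[0][0].order.size
    acc = np.zeros(k)
    for pred, truth in pairs:
        truth = set(truth)
        for j in range(k):
            if int(pred.order[j]) in truth:
                acc[j] += 1
    return acc / len(pairs)


def _branch_stats(rows: list[PredictionRow]) -> dict[str, BranchStat]:
    total = len(rows)
    stats: dict[str, BranchStat] = {}
    for branch in sorted({r.branch for r in rows}):
        sub = [r for r in rows if r.branch == branch]
        stats[branch] = BranchStat(
            count=len(sub),
            proportion=len(sub) / total,
            acc1=order_accuracy(sub, 1),
        )
    return stats


def _predict_rows(predictor: FunctionCascade, dataset: Dataset, query_ids, exclude):
    rows = []
    for pid in query_ids:
        pred = predictor.predict_one(pid, exclude=exclude)
        rows.append(
            PredictionRow(
                protein_id=pid,
                prediction=pred,
                truth=frozenset(dataset.annotations[pid]),
                branch=pred.branch,
            )
        )
    return rows


def leave_one_out(dataset: Dataset, predictor: FunctionCascade | None = None) -> EvaluationReport:
    """Predict every annotated protein from all the others.

    All evidence touching the held-out protein as a reference — its
    annotation column, self-hits, and edges to it — is removed before its
    prediction is made.
    """
    ids = list(dataset.annotations)
    if len(ids) < 2:
        raise ValueError("leave-one-out needs at least 2 annotated proteins")
    predictor = clone(predictor) if predictor is not None else FunctionCascade()
    predictor.fit(dataset)
    rows = []
    for pid in ids:
        rows.extend(_predict_rows(predictor, dataset, [pid], exclude={pid}))
    return EvaluationReport(
        per_protein=rows,
        order_accuracies=_accuracy_vector(rows),
        branch_stats=_branch_stats(rows),
        protocol="loo",
    )


def ten_fold_cv(
    dataset: Dataset,
    predictor: FunctionCascade | None = None,
    repeats: int = 5,
    seed: int = 0,
    n_folds: int = 10,
) -> EvaluationReport:
    """Repeated k-fold cross-validation (default ten folds, five repeats).

    Each repeat partitions the annotated proteins uniformly at random into
    ``n_folds`` near-equal folds (sizes differ by at most one); each fold is
    predicted with the entire fold excluded from the reference universe.
    Fully reproducible from ``seed``.
    """
    ids = sorted(dataset.annotations)
    if len(ids) < n_folds:
        raise ValueError(f"k-fold needs at least {n_folds} annotated proteins")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    predictor = clone(predictor) if predictor is not None else FunctionCascade()
    predictor.fit(dataset)
    all_rows: list[PredictionRow] = []
    repeat_acc: list[np.ndarray] = []
    for rep in range(repeats):
        fold_seed = int(np.random.default_rng([seed, rep]).integers(2**31))
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=fold_seed)
        rep_rows: list[PredictionRow] = []
        for _, test_idx in splitter.split(ids):
            fold = [ids[i] for i in test_idx]
            rep_rows.extend(_predict_rows(predictor, dataset, fold, exclude=set(fold)))
        repeat_acc.append(_accuracy_vector(rep_rows))
        all_rows.extend(rep_rows)
    stacked = np.vstack(repeat_acc)
    return EvaluationReport(
        per_protein=all_rows,
        order_accuracies=_accuracy_vector(all_rows),
        branch_stats=_branch_stats(all_rows),
        repeat_accuracies=repeat_acc,
        mean_accuracies=stacked.mean(axis=0),
        std_accuracies=stacked.std(axis=0, ddof=1) if repeats > 1 else np.zeros(stacked.shape[1]),
        seed=seed,
        protocol=f"{n_folds}-fold x {repeats}",
    )


def false_wrong_candidates(report: EvaluationReport) -> list[tuple[str, str]]:
    """Proteins whose 1st-order prediction is wrong but 2nd-order is right.

    These are candidate novel annotations: the top-ranked category is not
    currently annotated on the protein, yet the runner-up is, so the top
    call may simply be missing knowledge rather than a model error.
    Returns ``(protein_id, branch)`` pairs.
    """
    out = []
    for row in report.per_protein:
        first = row.prediction.order_k(1)
        second = row.prediction.order_k(2)
        if first not in row.truth and second in row.truth:
            out.append((row.protein_id, row.branch))
    return out
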