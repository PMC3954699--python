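"""Model selection and performance estimation at a target precision.

The workflow: stratified 5-fold cross-validation produces one held-out
posterior probability per training example; all folds are pooled and treated
as a single continuous experiment; a precision-recall curve over the pooled
probabilities yields the operating point closest to the target precision
(99% by default); the grid value (NB prior or SVM cost) maximizing recall at
that operating point wins. Recall confidence intervals use the Wilson score
method, which behaves well near 0 and 1 where these recalls live.

Also here: the confusion-matrix protocol for scoring a sequence-level domain
annotator against site-level truth through a site -> domain mapping table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.proportion import proportion_confint

from .classifiers import nb_fit, svm_fit

logger = logging.getLogger(__name__)

#: Default cost grid for the SVM (powers of two, per standard grid-search
#: guidelines for soft-margin SVMs).
DEFAULT_C_GRID = tuple(float(2.0 ** k) for k in range(-5, 16, 2))
#: Default prior grid for Naïve Bayes.
DEFAULT_P_GRID = (0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 0.99)

DEFAULT_TARGET_PRECISION = 0.99


@dataclass(frozen=True)
class FoldAssignment:
    """A stratified partition: per-class fold sizes differ by at most one."""

    fold_of: np.ndarray
    F: int
    seed: int


def stratified_folds(labels: np.ndarray, F: int = 5, seed: int = 0
                     ) -> FoldAssignment:
    labels = np.asarray(labels, dtype=int)
    for c in np.unique(labels):
        count = int(np.sum(labels == c))
        if count < F:
            raise ValueError(
                f"class {c} has only {count} examples; need at least {F} "
                f"for {F}-fold stratified cross-validation")
    skf = StratifiedKFold(n_splits=F, shuffle=True, random_state=seed)
    fold_of = np.empty(len(labels), dtype=int)
    for i, (_, test_idx) in enumerate(skf.split(np.zeros((len(labels), 1)),
                                                labels)):
        fold_of[test_idx] = i
    return FoldAssignment(fold_of=fold_of, F=F, seed=seed)


@dataclass
class PooledPredictions:
    """Held-out probabilities for every training example, pooled over folds."""

    y_true: np.ndarray
    p_positive: np.ndarray
    fold_id: np.ndarray
    param: float | None = None

    def __post_init__(self):
        if not (len(self.y_true) == len(self.p_positive) == len(self.fold_id)):
            raise ValueError("prediction arrays must align")


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    fit_fn: Callable[[np.ndarray, np.ndarray], object],
    F: int = 5,
    seed: int = 0,
    param: float | None = None,
) -> PooledPredictions:
    """Train on F-1 folds, predict the held-out fold, pool all predictions.

    Every example receives exactly one prediction, from the model whose
    learning set excluded it.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    folds = stratified_folds(y, F=F, seed=seed)
    p_positive = np.empty(len(y))
    for i in range(F):
        test = folds.fold_of == i
        try:
            model = fit_fn(X[~test], y[~test])
            p_positive[test] = model.predict_proba(X[test])[:, 1]
        except Exception as exc:
            raise RuntimeError(f"classifier failed on fold {i}: {exc}") from exc
    return PooledPredictions(y_true=y, p_positive=p_positive,
                             fold_id=folds.fold_of, param=param)


def nb_fitter(prior_positive: float) -> Callable:
    return lambda X, y: nb_fit(X, y, prior_positive=prior_positive)


def svm_fitter(C: float, seed: int | None = 0) -> Callable:
    return lambda X, y: svm_fit(X, y, C=C, seed=seed)


# ---------------------------------------------------------------------------
# Precision-recall machinery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OperatingPoint:
    threshold: float
    precision: float
    recall: float
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def misclassifications(self) -> int:
        return self.fp + self.fn


def pr_curve(pred: PooledPredictions) -> list[OperatingPoint]:
    """One operating point per distinct predicted probability.

    At each threshold t an example is called positive when p >= t. The list
    ends with the trivial all-negative point (threshold above every score),
    whose precision is undefined (NaN).
    """
    y = np.asarray(pred.y_true, dtype=int)
    p = np.asarray(pred.p_positive, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("pr_curve needs both labels present")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    points = []
    for t in np.unique(p)[::-1]:
        called = p >= t
        tp = int(np.sum(called & (y == 1)))
        fp = int(np.sum(called & (y == 0)))
        points.append(OperatingPoint(
            threshold=float(t),
            precision=tp / (tp + fp),
            recall=tp / n_pos,
            tp=tp, fp=fp, fn=n_pos - tp, tn=n_neg - fp,
        ))
    above = float(np.nextafter(p.max(), np.inf)) if len(p) else 1.0
    points.append(OperatingPoint(
        threshold=above, precision=float("nan"), recall=0.0,
        tp=0, fp=0, fn=n_pos, tn=n_neg))
    return points


def select_threshold(pred: PooledPredictions,
                     target: float = DEFAULT_TARGET_PRECISION
                     ) -> OperatingPoint:
    """The operating point whose precision is closest to the target.

    On a finite sample the target precision is generally not exactly
    achievable, so the closest achievable value is used. Ties break toward
    precision >= target, then higher recall, then higher threshold.
    """
    candidates = [op for op in pr_curve(pred) if op.tp + op.fp > 0]
    if not candidates:
        raise ValueError("no threshold yields any positive call")

    def key(op: OperatingPoint):
        return (abs(op.precision - target),
                0 if op.precision >= target else 1,
                -op.recall,
                -op.threshold)

    return min(candidates, key=key)


def grid_search(
    X: np.ndarray,
    y: np.ndarray,
    fitter_factory: Callable[[float], Callable],
    grid=DEFAULT_C_GRID,
    target_precision: float = DEFAULT_TARGET_PRECISION,
    F: int = 5,
    seed: int = 0,
) -> tuple[float, PooledPredictions]:
    """Cross-validate each grid value; keep the one with the highest recall
    at the closest-achievable target precision (ties -> smaller value)."""
    grid = list(grid)
    if not grid:
        raise ValueError("parameter grid is empty")
    best = None
    for value in grid:
        pred = cross_validate(X, y, fitter_factory(value), F=F, seed=seed,
                              param=value)
        op = select_threshold(pred, target=target_precision)
        logger.info(
            "grid value %g: precision %.4f recall %.4f misclassifications %d",
            value, op.precision, op.recall, op.misclassifications)
        entry = (op.recall, -value, pred)
        if best is None or entry[:2] > best[:2]:
            best = entry
    return -best[1], best[2]


def recall_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score confidence interval for a recall of k successes in n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must be in [0, n]")
    lo, hi = proportion_confint(k, n, alpha=1.0 - level, method="wilson")
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Scoring a sequence-level domain annotator against site-level truth
# ---------------------------------------------------------------------------

class UnscorableSiteError(KeyError):
    """The site has no domain mapping, so annotator agreement is undefined."""


def parse_domain_mapping(text: str) -> dict[str, frozenset[str]]:
    """Read a site -> domains TSV (domains comma-separated; a row with no
    domains marks the site unscorable)."""
    mapping: dict[str, frozenset[str]] = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if parts[0] == "site":
            continue
        domains = frozenset(
            d.strip() for d in parts[1].split(",") if d.strip()
        ) if len(parts) > 1 else frozenset()
        mapping[parts[0]] = domains
    return mapping


def load_domain_mapping() -> dict[str, frozenset[str]]:
    from importlib import resources
    text = resources.files("sitescan.data").joinpath(
        "domain_mapping.tsv").read_text()
    return parse_domain_mapping(text)


def mapped_confusion(
    examples: list[tuple[int, set[str]]],
    mapping: dict[str, frozenset[str]],
    site: str,
) -> OperatingPoint:
    """Confusion matrix for a domain annotator on site-labeled examples.

    A positive example is a TP when any predicted domain intersects the
    site's mapped set, else an FN; a negative example is an FP on
    intersection, else a TN. Sites without a mapping are unscorable.
    """
    if site not in mapping or not mapping[site]:
        raise UnscorableSiteError(
            f"site {site!r} has no domain mapping; cannot score")
    accepted = mapping[site]
    tp = fp = fn = tn = 0
    for label, predicted in examples:
        hit = bool(accepted & set(predicted))
        if label == 1:
            tp += hit
            fn += not hit
        else:
            fp += hit
            tn += not hit
    return OperatingPoint(
        threshold=float("nan"),
        precision=tp / (tp + fp) if tp + fp else float("nan"),
        recall=tp / (tp + fn) if tp + fn else float("nan"),
        tp=tp, fp=fp, fn=fn, tn=tn,
    )
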