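"""Validation harness: confusion/ROC metrics, LOSO cross-validation,
min-max cutoff optimization, and the one-tailed max-t permutation correction.

Throughout, the positive class is the *non-responder* (the clinically
actionable identification), and a subject is flagged when a predicted ΔGCS
falls below the classification cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import constants
from .model import (
    VotingClassifier,
    fit_biomarker_model,
    predict_subject,
    predictors_at_thresholds,
    voting_score,
)


class ValidationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Confusion metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_metrics(counts: ConfusionCounts) -> dict[str, float | None]:
    """Accuracy, sensitivity, specificity, PPV, NPV as percentages.

    Ratios with zero denominator are reported as None (not available), never 0.
    """
    if counts.n == 0:
        raise ValidationError("empty confusion table")

    def ratio(num: int, den: int) -> float | None:
        return None if den == 0 else 100.0 * num / den

    return {
        "accuracy": ratio(counts.tp + counts.tn, counts.n),
        "sensitivity": ratio(counts.tp, counts.tp + counts.fn),
        "specificity": ratio(counts.tn, counts.tn + counts.fp),
        "ppv": ratio(counts.tp, counts.tp + counts.fp),
        "npv": ratio(counts.tn, counts.tn + counts.fn),
    }


# ---------------------------------------------------------------------------
# Cutoff optimization and ROC
# ---------------------------------------------------------------------------

def minmax_cutoff(
    scores: np.ndarray,
    is_non_responder: np.ndarray,
    anchor: float = constants.PREDICTED_DGCS_CUTOFF,
) -> float:
    """Cutoff maximizing min(sensitivity, specificity).

    Candidates are the midpoints of consecutive sorted scores plus the anchor
    value; a subject is flagged when score < cutoff.  Ties are broken toward
    the candidate closest to the anchor, then the smallest.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(is_non_responder, dtype=bool)
    if y.all() or not y.any():
        raise ValidationError("both classes required to optimize the cutoff")
    uniq = np.unique(s)
    mids = (uniq[:-1] + uniq[1:]) / 2 if uniq.size > 1 else np.array([])
    cands = np.unique(np.r_[mids, anchor, uniq.min() - 1e-9, uniq.max() + 1e-9])
    best = None
    for c in cands:
        flag = s < c
        sens = (flag & y).sum() / max(y.sum(), 1)
        spec = (~flag & ~y).sum() / max((~y).sum(), 1)
        crit = min(sens, spec)
        key = (-crit, abs(c - anchor), c)
        if best is None or key < best[0]:
            best = (key, c, crit)
    if best[2] == 0:
        warnings.warn("no cutoff achieves positive min(sens, spec)", RuntimeWarning)
    return float(best[1])


def roc_auc(
    scores: np.ndarray, is_non_responder: np.ndarray
) -> tuple[np.ndarray, float]:
    """ROC points and AUC when subjects are flagged at score < cutoff.

    Equivalent to ranking by −score; tied scores receive half credit (the
    Mann–Whitney convention).  Returns (points, auc) with points as an array
    of (fpr, tpr) rows over the cutoff sweep.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(is_non_responder, dtype=bool)
    if not (y.any() and (~y).any()):
        raise ValidationError("both classes required for ROC analysis")
    pos, neg = s[y], s[~y]
    # P(pos < neg) + 0.5 P(tie): lower predicted ΔGCS should mean non-responder
    diff = pos[:, None] - neg[None, :]
    auc = float(((diff < 0).sum() + 0.5 * (diff == 0).sum()) / diff.size)
    cuts = np.r_[-np.inf, np.unique(s), np.inf]
    pts = []
    for c in cuts:
        flag = s < c
        tpr = (flag & y).sum() / y.sum()
        fpr = (flag & ~y).sum() / (~y).sum()
        pts.append((fpr, tpr))
    return np.asarray(pts), auc


def pessimistic_scores(predicted: list[dict[str, float]]) -> np.ndarray:
    """Continuous per-subject score for whole-dataset ROC sweeps: the minimum
    predicted ΔGCS across the subject's selected biomarkers (the most
    pessimistic prediction); subjects with no prediction score +inf."""
    return np.array(
        [min(p.values()) if p else np.inf for p in predicted], dtype=float
    )


# ---------------------------------------------------------------------------
# LOSO cross-validation
# ---------------------------------------------------------------------------

@dataclass
class FoldResult:
    held_out: int
    classifier: VotingClassifier
    predicted_label: str
    true_label: str
    predicted_dgcs: dict[str, float]
    optimized_cutoff: float | None = None


@dataclass
class LosoResult:
    folds: list[FoldResult]
    counts: ConfusionCounts
    scores: np.ndarray = field(default=None, repr=False)

    @property
    def metrics(self) -> dict[str, float | None]:
        return confusion_metrics(self.counts)


def loso_cv(
    period_table: np.ndarray,
    delta_gcs: np.ndarray,
    alpha: float = 0.1,
    cutoff: float | str = constants.PREDICTED_DGCS_CUTOFF,
    responder_cutoff: float = constants.DELTA_GCS_CUTOFF,
    optimize_cutoffs: bool = False,
) -> LosoResult:
    """Leave-one-subject-out validation of the full decision pipeline.

    For every fold the binarization thresholds, regressions and biomarker
    selection (slope p < ``alpha``, the relaxed training criterion) are
    re-derived from the training subjects only; the held-out subject is then
    predicted by the fold's voting classifier.  ``cutoff`` is either a fixed
    predicted-ΔGCS value or ``"optimize"``, in which case each fold applies
    the cutoff maximizing min(sensitivity, specificity) of the voting
    decisions over its own training subjects.  With ``optimize_cutoffs``
    the fold-optimal cutoff is logged even when a fixed one is applied.
    Responder labels follow ΔGCS ≥ ``responder_cutoff``.
    """
    x = np.asarray(period_table, dtype=float)
    y = np.asarray(delta_gcs, dtype=float)
    n = x.shape[0]
    apply_optimized = cutoff == "optimize"
    fixed_cutoff = constants.PREDICTED_DGCS_CUTOFF if apply_optimized else float(cutoff)
    labels = np.where(y < responder_cutoff, "non-responder", "responder")
    if (labels == "non-responder").sum() < 3 or (labels == "responder").sum() < 3:
        raise ValidationError("need at least three subjects per group for LOSO")
    folds: list[FoldResult] = []
    tp = fp = tn = fn = 0
    scores = np.empty(n)
    for i in range(n):
        train = np.arange(n) != i
        groups = labels[train] == "responder"
        clf, train_predictors = fit_biomarker_model(
            x[train], y[train], groups, alpha=alpha, cutoff=fixed_cutoff
        )
        test_pred = predictors_at_thresholds(x[i:i + 1], clf.threshold_idx)[0]
        pred = predict_subject(test_pred, clf)
        score_i = voting_score(test_pred, clf)
        opt_cut = None
        if (apply_optimized or optimize_cutoffs) and clf.selected:
            train_scores = np.array(
                [voting_score(tp_, clf) for tp_ in train_predictors]
            )
            finite = np.isfinite(train_scores)
            if finite.any() and len(set(labels[train][finite])) == 2:
                opt_cut = minmax_cutoff(
                    train_scores[finite],
                    labels[train][finite] == "non-responder",
                )
        use_cut = opt_cut if (apply_optimized and opt_cut is not None) else fixed_cutoff
        flagged = score_i < use_cut
        folds.append(
            FoldResult(
                held_out=i,
                classifier=clf,
                predicted_label="non-responder" if flagged else "responder",
                true_label=str(labels[i]),
                predicted_dgcs=pred.predicted_dgcs,
                optimized_cutoff=opt_cut,
            )
        )
        scores[i] = score_i
        actual = labels[i] == "non-responder"
        tp += flagged and actual
        fp += flagged and not actual
        tn += (not flagged) and (not actual)
        fn += (not flagged) and actual
    return LosoResult(
        folds=folds,
        counts=ConfusionCounts(tp=int(tp), fp=int(fp), tn=int(tn), fn=int(fn)),
        scores=scores,
    )


# ---------------------------------------------------------------------------
# Max-t permutation correction
# ---------------------------------------------------------------------------

@dataclass
class PermutationReport:
    observed_t: np.ndarray
    corrected_p: np.ndarray
    raw_p: np.ndarray
    n_permutations: int


def _corr_t(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """t statistics of the Pearson correlations of each column of X with y."""
    n = y.shape[-1]
    Xc = X - X.mean(axis=0, keepdims=True)
    yc = y - y.mean(axis=-1, keepdims=True)
    xs = np.sqrt((Xc**2).sum(axis=0))
    ys = np.sqrt((yc**2).sum(axis=-1))
    r = (yc @ Xc) / (xs[None, :] * ys[..., None])
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    return r * np.sqrt((n - 2) / (1 - r**2))


def maxt_permutation(
    predictors: np.ndarray,
    delta_gcs: np.ndarray,
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> PermutationReport:
    """One-tailed (negative direction) max-t permutation test over a family.

    ``predictors``: (subject, family_size) — e.g. the five period-level
    values of one chromophore x metric.  Observed t comes from the Pearson
    correlation of each member with ΔGCS; the null permutes ΔGCS across
    subjects and records the most extreme negative t across the family per
    permutation.  Corrected p for member m = (1 + #{min_t ≤ t_m})/(n_perm+1),
    so p is never exactly zero and corrected p ≥ raw p.
    """
    X = np.asarray(predictors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(delta_gcs, dtype=float)
    if np.ptp(y) == 0:
        raise ValidationError("constant ΔGCS; correlations undefined")
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations; p-values will be coarse",
                      RuntimeWarning)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t_obs = np.atleast_1d(np.squeeze(_corr_t(X, y[None, :])))
    perms = np.stack([rng.permutation(y) for _ in range(n_perm)])
    t_null = _corr_t(X, perms)  # (n_perm, family)
    min_null = t_null.min(axis=1)  # most extreme negative per permutation
    corrected = (1 + (min_null[:, None] <= t_obs[None, :]).sum(axis=0)) / (n_perm + 1)
    raw = (1 + (t_null <= t_obs[None, :]).sum(axis=0)) / (n_perm + 1)
    return PermutationReport(
        observed_t=t_obs,
        corrected_p=corrected,
        raw_p=raw,
        n_permutations=n_perm,
    )
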