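"""The predictive core: binarization-threshold optimization by mixed
(split-plot) ANOVA, single-predictor regressions of ΔGCS on graph-index
changes, biomarker selection, and the voting classifier at the predicted-ΔGCS
cutoff.

Index tables are dense numpy arrays with axes

    (subject, chromophore[HbO,HbR,HbT], metric[DC,GE,CC], threshold[51],
     period[5])

so a whole threshold scan is one vectorized ANOVA over 459 cells.  The mixed
ANOVA is written out in sums-of-squares form (group between-subjects, period
within-subjects, one observation per cell); ``pingouin.mixed_anova`` is the
independent cross-check in the test suite.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from . import constants


class ModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Mixed (split-plot) ANOVA, vectorized over leading axes
# ---------------------------------------------------------------------------

def mixed_anova_interaction(
    values: np.ndarray, group_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray, tuple[int, int]]:
    """Group x period interaction of a two-way mixed design.

    ``values`` has shape (..., n_subjects, n_periods); ``group_mask`` is a
    boolean vector over subjects (True = first group).  Returns
    ``(F, p, (df1, df2))`` with F and p broadcast over the leading axes.
    Degenerate cells (zero within-cell error) yield p = 1 with a warning.
    """
    x = np.asarray(values, dtype=float)
    g = np.asarray(group_mask, dtype=bool)
    S, P = x.shape[-2], x.shape[-1]
    n1, n2 = int(g.sum()), int((~g).sum())
    if n1 < 2 or n2 < 2:
        raise ModelError("each group needs at least two subjects")
    if P < 2:
        raise ModelError("need at least two periods")

    gm = x.mean(axis=(-2, -1), keepdims=True)
    subj_mean = x.mean(axis=-1)  # (..., S)
    m1 = x[..., g, :].mean(axis=-2)   # (..., P) cell means group 1
    m2 = x[..., ~g, :].mean(axis=-2)
    g1 = m1.mean(axis=-1)  # (...,) group means
    g2 = m2.mean(axis=-1)
    per = (n1 * m1 + n2 * m2) / (n1 + n2)  # weighted period means

    gm_ = gm[..., 0, 0]
    ss_total = ((x - gm) ** 2).sum(axis=(-2, -1))
    ss_between_subj = P * ((subj_mean - gm[..., 0]) ** 2).sum(axis=-1)
    ss_group = P * (n1 * (g1 - gm_) ** 2 + n2 * (g2 - gm_) ** 2)
    ss_cells = n1 * ((m1 - gm_[..., None]) ** 2).sum(axis=-1) \
        + n2 * ((m2 - gm_[..., None]) ** 2).sum(axis=-1)
    ss_period = (n1 + n2) * ((per - gm_[..., None]) ** 2).sum(axis=-1)
    ss_inter = ss_cells - ss_group - ss_period
    ss_within = ss_total - ss_between_subj
    ss_err_within = ss_within - ss_period - ss_inter

    df1 = P - 1  # (a-1)(b-1) with a = 2 groups
    df2 = (n1 + n2 - 2) * (P - 1)
    ms_inter = ss_inter / df1
    ms_err = ss_err_within / df2

    with np.errstate(divide="ignore", invalid="ignore"):
        F = ms_inter / ms_err
    degenerate = ~np.isfinite(F) | (ms_err <= 0)
    if np.any(degenerate):
        warnings.warn(
            "degenerate ANOVA cell(s) (no within-cell variance); p set to 1",
            RuntimeWarning,
            stacklevel=2,
        )
    F = np.where(degenerate, 0.0, F)
    p = np.where(degenerate, 1.0, stats.f.sf(np.where(degenerate, 1.0, F), df1, df2))
    if np.ndim(values) == 2:
        return float(F), float(p), (df1, df2)
    return F, p, (df1, df2)


def rmanova_group_by_period(
    values: np.ndarray, groups: np.ndarray
) -> tuple[float, float, tuple[int, int]]:
    """Interaction test for one (subject x period) table; see
    :func:`mixed_anova_interaction`.  ``groups`` may be boolean or labels."""
    g = np.asarray(groups)
    if g.dtype != bool:
        labels = np.unique(g)
        if labels.size != 2:
            raise ModelError("exactly two group labels required")
        g = g == labels[0]
    return mixed_anova_interaction(np.asarray(values), g)


# ---------------------------------------------------------------------------
# Threshold optimization
# ---------------------------------------------------------------------------

@dataclass
class ThresholdScan:
    """Full rmANOVA scan over the binarization grid and the chosen thresholds.

    ``p``/``F`` have shape (3 chromophores, 3 metrics, 51 thresholds);
    ``chosen_idx`` and ``chosen`` give, per chromophore x metric, the grid
    index/value minimizing the interaction p (ties -> smallest threshold).
    """

    F: np.ndarray
    p: np.ndarray
    df: tuple[int, int]
    chosen_idx: np.ndarray
    chosen: np.ndarray


def optimize_threshold(period_table: np.ndarray, groups: np.ndarray) -> ThresholdScan:
    """Pick, per chromophore x metric, the binarization threshold whose
    period-level indices best separate the groups (minimum interaction p).

    ``period_table``: (subject, 3, 3, n_thresholds, 5 periods).
    """
    x = np.asarray(period_table, dtype=float)
    if x.ndim != 5 or x.shape[-1] != constants.N_PERIODS:
        raise ModelError("period_table must be (subject, 3, 3, n_thresholds, 5)")
    g = np.asarray(groups)
    if g.dtype != bool:
        labels = np.unique(g)
        g = g == labels[0]
    # reorder to (3, 3, thr, subject, period) for the vectorized ANOVA
    arr = np.moveaxis(x, 0, 3)
    F, p, df = mixed_anova_interaction(arr, g)
    if not np.all(np.isfinite(p)):
        raise ModelError("rmANOVA p undefined over the whole grid")
    chosen_idx = p.argmin(axis=-1)  # argmin returns first (= smallest) on ties
    chosen = constants.THRESHOLD_GRID[chosen_idx]
    return ThresholdScan(F=F, p=p, df=df, chosen_idx=chosen_idx, chosen=chosen)


# ---------------------------------------------------------------------------
# Regressions, selection, voting
# ---------------------------------------------------------------------------

#: predictor periods: period-1 baseline plus Δperiods 2..5
PREDICTOR_PERIODS: tuple[str, ...] = ("baseline", "delta2", "delta3", "delta4", "delta5")


@dataclass
class BiomarkerRegression:
    chromophore: str
    metric: str
    period: str  # one of PREDICTOR_PERIODS
    slope: float
    intercept: float
    r_squared: float
    p_value: float

    @property
    def key(self) -> str:
        return f"{self.chromophore}:{self.metric}:{self.period}"


def predictor_matrix(period_table_at_chosen: np.ndarray) -> np.ndarray:
    """(subject, 3, 3, 5 periods) -> (subject, 3, 3, 5 predictors):
    baseline value followed by Δperiod 2..5."""
    x = np.asarray(period_table_at_chosen, dtype=float)
    base = x[..., :1]
    deltas = x[..., 1:] - base
    return np.concatenate([base, deltas], axis=-1)


def fit_biomarker_regressions(
    predictors: np.ndarray, delta_gcs: np.ndarray
) -> list[BiomarkerRegression]:
    """OLS of ΔGCS on each single predictor (45 candidate regressions).

    ``predictors``: (subject, 3, 3, 5) as from :func:`predictor_matrix`.
    Constant predictors are skipped with a warning.
    """
    x = np.asarray(predictors, dtype=float)
    y = np.asarray(delta_gcs, dtype=float)
    out: list[BiomarkerRegression] = []
    for c, chrom in enumerate(constants.CHROMOPHORES):
        for m, metric in enumerate(constants.GRAPH_METRICS):
            for k, period in enumerate(PREDICTOR_PERIODS):
                v = x[:, c, m, k]
                if np.ptp(v) == 0:
                    warnings.warn(
                        f"constant predictor {chrom}:{metric}:{period}; skipped",
                        RuntimeWarning,
                    )
                    continue
                res = stats.linregress(v, y)
                out.append(
                    BiomarkerRegression(
                        chromophore=chrom,
                        metric=metric,
                        period=period,
                        slope=float(res.slope),
                        intercept=float(res.intercept),
                        r_squared=float(res.rvalue**2),
                        p_value=float(res.pvalue),
                    )
                )
    return out


def select_biomarkers(
    regressions: list[BiomarkerRegression], alpha: float = 0.05
) -> dict[str, list[BiomarkerRegression]]:
    """Predictors with slope p < alpha, grouped by period (insertion order)."""
    by_period: dict[str, list[BiomarkerRegression]] = {}
    for reg in regressions:
        if reg.p_value < alpha:
            by_period.setdefault(reg.period, []).append(reg)
    return by_period


def _votes_needed(n_biomarkers: int) -> int:
    """Voting rule: 1 -> its flag decides; 2 -> unanimity; 3 -> majority;
    >3 -> at least two flags."""
    if n_biomarkers <= 1:
        return 1
    if n_biomarkers == 2:
        return 2
    return 2


@dataclass
class VotingClassifier:
    """Fitted model: chosen thresholds, per-period biomarker regressions,
    classification cutoff on predicted ΔGCS, and the voting rule."""

    thresholds: np.ndarray  # (3, 3) chosen binarization thresholds
    threshold_idx: np.ndarray  # (3, 3) grid indices
    selected: dict[str, list[BiomarkerRegression]]
    cutoff: float = constants.PREDICTED_DGCS_CUTOFF
    alpha: float = 0.05
    scan_p: np.ndarray | None = field(default=None, repr=False)

    def to_json(self) -> str:
        from . import __version__

        payload = {
            "software_version": __version__,
            "thresholds": np.asarray(self.thresholds).tolist(),
            "threshold_idx": np.asarray(self.threshold_idx).tolist(),
            "selected": {
                per: [asdict(r) for r in regs] for per, regs in sorted(self.selected.items())
            },
            "cutoff": self.cutoff,
            "alpha": self.alpha,
            "voting": "1:flag, 2:unanimity, 3:majority, >3:>=2 flags; union over periods",
        }
        return json.dumps(payload, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "VotingClassifier":
        d = json.loads(text)
        selected = {
            per: [BiomarkerRegression(**r) for r in regs]
            for per, regs in d["selected"].items()
        }
        return cls(
            thresholds=np.asarray(d["thresholds"]),
            threshold_idx=np.asarray(d["threshold_idx"], dtype=int),
            selected=selected,
            cutoff=d["cutoff"],
            alpha=d["alpha"],
        )


@dataclass
class SubjectPrediction:
    per_period: dict[str, bool]  # period -> flagged non-responder
    union_non_responder: bool
    predicted_dgcs: dict[str, float]  # biomarker key -> predicted ΔGCS

    @property
    def label(self) -> str:
        return "non-responder" if self.union_non_responder else "responder"


def predict_subject(
    subject_predictors: np.ndarray, classifier: VotingClassifier
) -> SubjectPrediction:
    """Apply the fitted voting classifier to one subject.

    ``subject_predictors``: (3, 3, 5) array of the subject's baseline/Δperiod
    values at the classifier's chosen thresholds.  Each selected biomarker
    predicts ΔGCS = intercept + slope x predictor and flags the subject when
    the prediction falls below the cutoff; periods vote; the final label is
    the union of period-level flags.  Biomarkers with missing (NaN) predictor
    values abstain; if every biomarker abstains the subject defaults to
    responder with a warning.
    """
    x = np.asarray(subject_predictors, dtype=float)
    c_idx = {c: i for i, c in enumerate(constants.CHROMOPHORES)}
    m_idx = {m: i for i, m in enumerate(constants.GRAPH_METRICS)}
    k_idx = {p: i for i, p in enumerate(PREDICTOR_PERIODS)}
    per_period: dict[str, bool] = {}
    preds: dict[str, float] = {}
    any_vote = False
    for period, regs in classifier.selected.items():
        flags = []
        for reg in regs:
            v = x[c_idx[reg.chromophore], m_idx[reg.metric], k_idx[reg.period]]
            if not np.isfinite(v):
                continue
            yhat = reg.intercept + reg.slope * v
            preds[reg.key] = float(yhat)
            flags.append(yhat < classifier.cutoff)
        if not flags:
            continue
        any_vote = True
        per_period[period] = sum(flags) >= _votes_needed(len(flags))
    if classifier.selected and not any_vote:
        warnings.warn("all biomarkers abstained; defaulting to responder", RuntimeWarning)
    union = any(per_period.values())
    return SubjectPrediction(per_period=per_period, union_non_responder=union,
                             predicted_dgcs=preds)


def voting_score(subject_predictors: np.ndarray, classifier: VotingClassifier) -> float:
    """The decision score of the voting protocol: the cutoff value at which
    the subject's label flips.

    A period with k biomarkers and vote requirement m flags the subject iff
    the m-th smallest predicted ΔGCS in that period is below the cutoff; the
    union over periods therefore flags iff min over periods of that order
    statistic is below the cutoff.  Classifying by ``voting_score < cutoff``
    is exactly the voting protocol, which makes cutoff sweeps (min-max
    optimization, ROC over the voting rule) cheap.  Subjects with no usable
    biomarker score +inf (never flagged).
    """
    x = np.asarray(subject_predictors, dtype=float)
    c_idx = {c: i for i, c in enumerate(constants.CHROMOPHORES)}
    m_idx = {m: i for i, m in enumerate(constants.GRAPH_METRICS)}
    k_idx = {p: i for i, p in enumerate(PREDICTOR_PERIODS)}
    best = np.inf
    for regs in classifier.selected.values():
        preds = []
        for reg in regs:
            v = x[c_idx[reg.chromophore], m_idx[reg.metric], k_idx[reg.period]]
            if np.isfinite(v):
                preds.append(reg.intercept + reg.slope * v)
        if not preds:
            continue
        m = _votes_needed(len(preds))
        best = min(best, float(np.sort(preds)[m - 1]))
    return best


def fit_biomarker_model(
    period_table: np.ndarray,
    delta_gcs: np.ndarray,
    groups: np.ndarray,
    alpha: float = 0.05,
    cutoff: float = constants.PREDICTED_DGCS_CUTOFF,
) -> tuple[VotingClassifier, np.ndarray]:
    """Full fit on a (training) cohort.

    ``period_table``: (subject, 3, 3, 51, 5) period-level index values over
    the whole binarization grid; ``groups``: responder/non-responder labels
    used by the threshold-optimizing ANOVA.  Returns the classifier and the
    (subject, 3, 3, 5) predictor matrix at the chosen thresholds.
    """
    scan = optimize_threshold(period_table, groups)
    s = np.arange(period_table.shape[0])[:, None, None]
    c = np.arange(3)[None, :, None]
    m = np.arange(3)[None, None, :]
    at_chosen = period_table[s, c, m, scan.chosen_idx[None, :, :], :]
    predictors = predictor_matrix(at_chosen)
    regs = fit_biomarker_regressions(predictors, delta_gcs)
    selected = select_biomarkers(regs, alpha)
    clf = VotingClassifier(
        thresholds=scan.chosen,
        threshold_idx=scan.chosen_idx,
        selected=selected,
        cutoff=cutoff,
        alpha=alpha,
        scan_p=scan.p,
    )
    return clf, predictors


def predictors_at_thresholds(
    period_table: np.ndarray, threshold_idx: np.ndarray
) -> np.ndarray:
    """Extract (subject, 3, 3, 5) predictors at given per-cell grid indices."""
    s = np.arange(period_table.shape[0])[:, None, None]
    c = np.arange(3)[None, :, None]
    m = np.arange(3)[None, None, :]
    at = period_table[s, c, m, np.asarray(threshold_idx)[None, :, :], :]
    return predictor_matrix(at)
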