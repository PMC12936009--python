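"""Global cognitive score (GCS), ΔGCS, responder labels and demographic tests.

The battery holds nine metrics, each measured before and after the 12-week
intervention.  Metrics that improved significantly at the cohort level are
z-scored (orientation-aligned so higher always means better) and averaged
into the GCS; ΔGCS = GCS_post − GCS_pre, and a subject is a responder iff
ΔGCS ≥ 0.5 (inclusive).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import constants


class ScoringError(ValueError):
    pass


def _orientation(metric: str) -> float:
    return 1.0 if constants.COGNITIVE_METRICS[metric]["higher_is_better"] else -1.0


def select_improved_metrics(
    batteries: pd.DataFrame,
    alpha: float = 0.05,
    metrics: tuple[str, ...] = constants.METRIC_NAMES,
) -> list[str]:
    """Metrics with a significant cohort-level improvement (paired t-test).

    A metric is retained when the orientation-aligned post−pre change is
    significant at two-sided ``alpha`` AND in the improving direction.
    Zero-variance changes are excluded with a warning.
    """
    if len(batteries) < 2:
        raise ScoringError("need at least two subjects for the paired t-test")
    selected = []
    for m in metrics:
        d = _orientation(m) * (batteries[f"{m}_post"] - batteries[f"{m}_pre"]).to_numpy()
        if d.std() == 0:
            # constant change: the paired t is undefined; a uniform improvement
            # is kept, a uniform zero (or decline) is not
            if d.mean() > 0:
                warnings.warn(
                    f"metric {m} changed identically in every subject; kept",
                    RuntimeWarning,
                )
                selected.append(m)
            continue
        t, p = stats.ttest_rel(
            batteries[f"{m}_post"].to_numpy(), batteries[f"{m}_pre"].to_numpy()
        )
        if p < alpha and d.mean() > 0:
            selected.append(m)
    return selected


def normalization_stats(
    batteries: pd.DataFrame,
    metrics: list[str],
    basis: str = "pooled",
) -> dict[str, tuple[float, float]]:
    """Per-metric (mean, SD) used for z-scoring.

    ``basis='pooled'`` pools the pre and post values of the cohort (one common
    scale for both time points, the default); ``'pre'`` uses pre values only.
    """
    out = {}
    for m in metrics:
        if basis == "pooled":
            vals = np.concatenate(
                [batteries[f"{m}_pre"].to_numpy(), batteries[f"{m}_post"].to_numpy()]
            )
        elif basis == "pre":
            vals = batteries[f"{m}_pre"].to_numpy()
        else:
            raise ScoringError(f"unknown normalization basis {basis!r}")
        out[m] = (float(vals.mean()), float(vals.std(ddof=1)))
    return out


def compute_gcs(
    batteries: pd.DataFrame,
    metrics: list[str] | None = None,
    norm_stats: dict[str, tuple[float, float]] | None = None,
    responder_cutoff: float = constants.DELTA_GCS_CUTOFF,
) -> pd.DataFrame:
    """Score a cohort: GCS pre/post, ΔGCS and responder labels.

    Per metric, z = orientation x (value − mean)/SD; GCS = mean of z over the
    selected metrics.  Metrics with SD = 0 are dropped from the mean with a
    warning.  Returns a frame indexed like ``batteries`` with columns
    ``gcs_pre, gcs_post, delta_gcs, label`` (label ``"responder"`` iff
    ΔGCS ≥ ``responder_cutoff``).
    """
    if metrics is None:
        metrics = list(constants.METRIC_NAMES)
    if not metrics:
        raise ScoringError("empty metric subset")
    if norm_stats is None:
        norm_stats = normalization_stats(batteries, metrics)
    z_pre, z_post = [], []
    for m in metrics:
        mean, sd = norm_stats[m]
        if sd == 0:
            warnings.warn(f"metric {m} has zero SD; dropped from the GCS mean", RuntimeWarning)
            continue
        o = _orientation(m)
        z_pre.append(o * (batteries[f"{m}_pre"].to_numpy() - mean) / sd)
        z_post.append(o * (batteries[f"{m}_post"].to_numpy() - mean) / sd)
    if not z_pre:
        raise ScoringError("no metric with positive SD to score")
    gcs_pre = np.mean(z_pre, axis=0)
    gcs_post = np.mean(z_post, axis=0)
    delta = gcs_post - gcs_pre
    return pd.DataFrame(
        {
            "gcs_pre": gcs_pre,
            "gcs_post": gcs_post,
            "delta_gcs": delta,
            "label": np.where(delta >= responder_cutoff, "responder", "non-responder"),
            "metrics_used": [",".join(metrics)] * len(batteries),
        },
        index=batteries.index,
    )


def demographic_tests(table: pd.DataFrame, group_col: str = "group") -> dict:
    """Demographic comparisons across groups.

    Sex composition: Pearson chi-square without continuity correction.
    Continuous columns: Kruskal–Wallis for 3+ groups, Wilcoxon rank-sum for 2;
    with 3+ groups, Bonferroni-corrected pairwise rank-sum post hocs are added.
    """
    groups = [g for g, _ in table.groupby(group_col, sort=True)]
    if any((table[group_col] == g).sum() == 0 for g in groups) or len(groups) < 2:
        raise ScoringError("need at least two non-empty groups")
    report: dict = {"groups": groups}
    if "sex" in table.columns:
        cont = pd.crosstab(table[group_col], table["sex"])
        chi2, p, dof, _ = stats.chi2_contingency(cont.to_numpy(), correction=False)
        report["sex"] = {"chi2": float(chi2), "p": float(p), "dof": int(dof)}
    numeric = [c for c in table.columns if c not in (group_col, "sex")
               and pd.api.types.is_numeric_dtype(table[c])]
    for col in numeric:
        samples = [table.loc[table[group_col] == g, col].to_numpy() for g in groups]
        if len(groups) == 2:
            s, p = stats.ranksums(samples[0], samples[1])
            report[col] = {"test": "wilcoxon_ranksum", "stat": float(s), "p": float(p)}
        else:
            h, p = stats.kruskal(*samples)
            entry = {"test": "kruskal_wallis", "stat": float(h), "p": float(p), "posthoc": {}}
            pairs = list(itertools.combinations(range(len(groups)), 2))
            for i, j in pairs:
                s, pr = stats.ranksums(samples[i], samples[j])
                entry["posthoc"][f"{groups[i]}|{groups[j]}"] = {
                    "stat": float(s),
                    "p_bonferroni": float(min(1.0, pr * len(pairs))),
                }
            report[col] = entry
    return report


@dataclass
class GCSRecord:
    """Convenience view of one subject's scoring result."""

    subject_id: str
    gcs_pre: float
    gcs_post: float
    delta_gcs: float
    label: str
    metrics_used: list[str]
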