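"""End-to-end orchestration: configuration, stimulation dosimetry, and the
simulate -> preprocess -> network -> scoring -> fit -> predict -> validate run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import constants, graphs, io, model, preprocess, scoring, synthetic, validation

log = logging.getLogger("pbmnet")


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Stimulation dosimetry
# ---------------------------------------------------------------------------

@dataclass
class StimulationSpec:
    """Photobiomodulation stimulation parameters of the wearable device."""

    power_density_mw_cm2: float = 80.0
    duty_cycle: float = 0.5
    session_duration_s: float = constants.SESSION_DURATION_S
    pulse_frequency_range_hz: tuple[float, float] = (32.0, 64.0)

    def validate(self) -> None:
        if not 0.0 <= self.duty_cycle <= 1.0:
            raise ConfigError("duty cycle must lie in [0, 1]")
        if self.power_density_mw_cm2 < 0 or self.session_duration_s < 0:
            raise ConfigError("stimulation parameters must be non-negative")


def energy_density(spec: StimulationSpec) -> float:
    """Delivered energy density in J/cm²: power (W/cm²) x duty cycle x time (s).

    The study condition — 80 mW/cm², 50% duty cycle, 15 min — delivers
    36 J/cm² per session.
    """
    spec.validate()
    return spec.power_density_mw_cm2 * 1e-3 * spec.duty_cycle * spec.session_duration_s


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "simulate": {
        "n_responders": 14,
        "n_nonresponders": 15,
        "n_sessions_per_subject": 20,
        "session_duration": constants.SESSION_DURATION_S,
        "sampling_rate": constants.SAMPLING_RATE_HZ,
        "effect_slope": 0.45,
        "artifact_rate": 2.0,
    },
    "preprocess": {
        "band": [0.01, 0.09],
        "filter_order": 6,
        "iqr_factor": 1.5,
        "dpf": list(constants.DPF_DEFAULT),
        "distance_cm": constants.SOURCE_DETECTOR_DISTANCE_CM,
    },
    "network": {
        "trials": constants.N_TRIALS,
        "trial_pool": constants.TRIAL_POOL,
    },
    "scoring": {
        "alpha": 0.05,
        "normalization": "pooled",
    },
    "fit": {
        "alpha": 0.05,
        "cutoff": constants.PREDICTED_DGCS_CUTOFF,
    },
    "validate": {
        "alpha": 0.1,
        # per-fold min-max-optimized cutoff; set a float for a fixed one
        "cutoff": "optimize",
        "optimize_cutoffs": True,
    },
    "permtest": {
        "n_perm": 10000,
    },
}

REQUIRED_BLOCKS = tuple(DEFAULT_CONFIG)


@dataclass
class RunConfig:
    """Serializable configuration for a full reproducible run."""

    blocks: dict
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path, seed: int = 0) -> "RunConfig":
        blocks = json.loads(Path(path).read_text())
        return cls.validate_blocks(blocks, seed)

    @classmethod
    def default(cls, seed: int = 0, **overrides) -> "RunConfig":
        blocks = json.loads(json.dumps(DEFAULT_CONFIG))
        for block, vals in overrides.items():
            blocks.setdefault(block, {}).update(vals)
        return cls.validate_blocks(blocks, seed)

    @classmethod
    def validate_blocks(cls, blocks: dict, seed: int = 0) -> "RunConfig":
        missing = [b for b in REQUIRED_BLOCKS if b not in blocks]
        if missing:
            raise ConfigError(f"config missing required block(s): {', '.join(missing)}")
        return cls(blocks=blocks, seed=seed)

    def hash(self) -> str:
        payload = json.dumps({"blocks": self.blocks, "seed": self.seed}, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Stage functions
# ---------------------------------------------------------------------------

def simulate_stage(cfg: RunConfig) -> tuple[dict, pd.DataFrame, synthetic.GroundTruth,
                                            synthetic.CohortSpec]:
    sim = cfg.blocks["simulate"]
    spec = synthetic.CohortSpec(seed=cfg.seed, **sim)
    sessions, battery, truth = synthetic.generate_cohort(spec)
    return sessions, battery, truth, spec


def network_stage(cfg: RunConfig, sessions: dict) -> tuple[np.ndarray, list[str]]:
    """Quality-screen, standardize to 15 trials, preprocess and sweep the grid.

    Returns the (subject, 3, 3, 51, 5) period-level index table and the kept
    subject ids (subjects failing quality or trial-count rules are dropped
    with a log entry).
    """
    pp = cfg.blocks["preprocess"]
    net = cfg.blocks["network"]
    tables = []
    kept: list[str] = []
    for i, (sid, trials) in enumerate(sessions.items()):
        report = preprocess.screen_quality(trials)
        if report.excluded:
            log.warning("subject %s excluded: %d low-quality trials", sid,
                        report.n_flagged)
            continue
        usable = [t for t, bad in zip(trials, report.flagged) if not bad]
        try:
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=cfg.seed, spawn_key=(77, i)))
            pick = preprocess.sample_trials(
                len(usable), k=net["trials"], pool=net["trial_pool"], seed=rng)
        except preprocess.InsufficientTrialsError as exc:
            log.warning("subject %s dropped: %s", sid, exc)
            continue
        segments = preprocess.preprocess_trials(
            [usable[j] for j in pick],
            dpf=tuple(pp["dpf"]),
            distance_cm=pp["distance_cm"],
            iqr_factor=pp["iqr_factor"],
            band=tuple(pp["band"]),
            filter_order=pp["filter_order"],
        )
        trial_values = graphs.trial_index_sweep(segments)
        periods, _ = graphs.aggregate_periods(trial_values)
        tables.append(periods)
        kept.append(sid)
    if not tables:
        raise ConfigError("no subject survived preprocessing")
    return np.stack(tables), kept


def scoring_stage(cfg: RunConfig, battery: pd.DataFrame) -> pd.DataFrame:
    sc = cfg.blocks["scoring"]
    metrics = scoring.select_improved_metrics(battery, alpha=sc["alpha"])
    if not metrics:
        metrics = list(constants.METRIC_NAMES)
        log.warning("no metric improved significantly; scoring over all nine")
    stats_ = scoring.normalization_stats(battery, metrics, basis=sc["normalization"])
    return scoring.compute_gcs(battery, metrics, stats_)


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Execute every stage and write models, predictions and reports.

    Every artifact carries the config hash; the run is a pure function of
    (config, seed).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = cfg.hash()
    log.info("run %s starting", h)

    sessions, battery, truth, spec = simulate_stage(cfg)
    log.info("simulated %d subjects x %d sessions", len(sessions),
             spec.n_sessions_per_subject)

    period_table, kept = network_stage(cfg, sessions)
    log.info("network stage kept %d/%d subjects", len(kept), len(sessions))

    gcs = scoring_stage(cfg, battery)
    gcs_kept = gcs.loc[kept]
    dgcs = gcs_kept["delta_gcs"].to_numpy()
    groups = gcs_kept["label"].to_numpy() == "responder"

    fit_cfg = cfg.blocks["fit"]
    clf, predictors = model.fit_biomarker_model(
        period_table, dgcs, groups, alpha=fit_cfg["alpha"], cutoff=fit_cfg["cutoff"])
    preds = [model.predict_subject(p, clf) for p in predictors]

    flagged = np.array([p.union_non_responder for p in preds])
    actual = ~groups
    counts = validation.ConfusionCounts(
        tp=int((flagged & actual).sum()),
        fp=int((flagged & ~actual).sum()),
        tn=int((~flagged & ~actual).sum()),
        fn=int((~flagged & actual).sum()),
    )
    whole = validation.confusion_metrics(counts)
    scores = validation.pessimistic_scores([p.predicted_dgcs for p in preds])
    finite = np.isfinite(scores)
    auc = None
    roc_points = None
    if finite.sum() >= 2 and len(set(actual[finite])) == 2:
        roc_points, auc = validation.roc_auc(scores[finite], actual[finite])

    val_cfg = cfg.blocks["validate"]
    loso = validation.loso_cv(
        period_table, dgcs, alpha=val_cfg["alpha"], cutoff=val_cfg["cutoff"],
        optimize_cutoffs=val_cfg.get("optimize_cutoffs", False))

    # artifacts
    (out / "model.json").write_text(clf.to_json())
    if roc_points is not None:
        pd.DataFrame(roc_points, columns=["fpr", "tpr"]).to_csv(
            out / "roc_points.csv", index=False)
    gcs.assign(config_hash=h).to_csv(out / "gcs.csv")
    io.write_manifest(
        [
            {
                "subject_id": sid,
                "group_truth": "responder" if truth.responder[truth.subject_ids.index(sid)]
                else "non-responder",
                "n_sessions": spec.n_sessions_per_subject,
                "battery_file": "battery.csv",
            }
            for sid in kept
        ],
        out / "manifest.csv",
    )
    battery.to_csv(out / "battery.csv")
    pd.DataFrame(
        {
            "subject_id": kept,
            "delta_gcs": dgcs,
            "predicted_label": [p.label for p in preds],
            "true_label": np.where(actual, "non-responder", "responder"),
            "score": scores,
            "config_hash": h,
        }
    ).to_csv(out / "predictions.csv", index=False)
    pd.DataFrame(
        [
            {
                "fold": f.held_out,
                "held_out_subject": kept[f.held_out],
                "chosen_thresholds": ";".join(map(str, f.classifier.thresholds.ravel())),
                "selected_biomarkers": ";".join(
                    r.key for regs in f.classifier.selected.values() for r in regs),
                "cutoff": f.optimized_cutoff if f.optimized_cutoff is not None
                else val_cfg["cutoff"],
                "predicted_label": f.predicted_label,
                "true_label": f.true_label,
                "config_hash": h,
            }
            for f in loso.folds
        ]
    ).to_csv(out / "loso_folds.csv", index=False)

    report = {
        "config_hash": h,
        "n_subjects": len(kept),
        "whole_dataset": {**whole, "auc": auc,
                          "counts": counts.__dict__},
        "loso": {**loso.metrics, "counts": loso.counts.__dict__},
        "chosen_thresholds": clf.thresholds.tolist(),
        "selected_biomarkers": {
            per: [r.key for r in regs] for per, regs in clf.selected.items()},
    }
    (out / "report.json").write_text(json.dumps(report, indent=1, default=float))
    log.info("run %s finished: whole-dataset accuracy %s, LOSO accuracy %s",
             h, whole["accuracy"], loso.metrics["accuracy"])
    return report
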