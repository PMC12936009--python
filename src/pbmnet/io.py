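"""Plain-text interchange formats: session CSV + sidecar JSON, cohort
manifest, cognitive battery CSV, hemodynamic segment CSV, tidy index tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import constants
from .preprocess import HemodynamicSeries, OpticalSession


def write_session(session: OpticalSession, csv_path: str | Path) -> None:
    """`time_s, chNN_w810, chNN_w850, ...` plus a metadata sidecar JSON."""
    csv_path = Path(csv_path)
    n = session.n_times
    cols = {"time_s": np.arange(n) / session.sampling_rate}
    for ch in range(session.n_channels):
        for wi, w in enumerate(session.wavelengths):
            cols[f"ch{ch + 1:02d}_w{int(w)}"] = session.intensities[ch, wi]
    pd.DataFrame(cols).to_csv(csv_path, index=False, float_format="%.8g")
    sidecar = dict(session.metadata)
    sidecar.update(
        sampling_rate_hz=session.sampling_rate,
        wavelengths_nm=list(session.wavelengths),
        n_channels=session.n_channels,
    )
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, default=str))


def read_session(csv_path: str | Path) -> OpticalSession:
    csv_path = Path(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    df = pd.read_csv(csv_path)
    wavelengths = tuple(float(w) for w in meta["wavelengths_nm"])
    nch = int(meta["n_channels"])
    inten = np.stack(
        [
            np.stack([df[f"ch{ch + 1:02d}_w{int(w)}"].to_numpy() for w in wavelengths])
            for ch in range(nch)
        ]
    )
    keep = {k: v for k, v in meta.items()
            if k not in ("sampling_rate_hz", "wavelengths_nm", "n_channels")}
    return OpticalSession(
        intensities=inten,
        sampling_rate=float(meta["sampling_rate_hz"]),
        wavelengths=wavelengths,
        metadata=keep,
    )


def write_hemodynamics(series: HemodynamicSeries, csv_path: str | Path,
                       provenance: dict | None = None) -> None:
    """`time_s, chNN_hbo, chNN_hbr, chNN_hbt` plus a provenance JSON."""
    csv_path = Path(csv_path)
    n = series.dHbO.shape[1]
    t0 = series.segment_window[0]
    cols = {"time_s": t0 + np.arange(n) / series.sampling_rate}
    for ch in range(series.dHbO.shape[0]):
        cols[f"ch{ch + 1:02d}_hbo"] = series.dHbO[ch]
        cols[f"ch{ch + 1:02d}_hbr"] = series.dHbR[ch]
        cols[f"ch{ch + 1:02d}_hbt"] = series.dHbT[ch]
    pd.DataFrame(cols).to_csv(csv_path, index=False, float_format="%.8g")
    info = {
        "segment_window_s": list(series.segment_window),
        "baseline_window_s": list(series.baseline_window),
        "sampling_rate_hz": series.sampling_rate,
    }
    info.update(provenance or {})
    csv_path.with_suffix(".json").write_text(json.dumps(info, indent=1, default=str))


def write_manifest(truth_rows: list[dict], path: str | Path) -> None:
    pd.DataFrame(truth_rows).to_csv(path, index=False)


def index_table_to_tidy(period_table: np.ndarray,
                        subject_ids: list[str]) -> pd.DataFrame:
    """(subject, 3, 3, 51, 5) -> tidy frame with Δ-vs-period-1 column."""
    rows = []
    grid = constants.THRESHOLD_GRID
    for si, sid in enumerate(subject_ids):
        for c, chrom in enumerate(constants.CHROMOPHORES):
            for m, metric in enumerate(constants.GRAPH_METRICS):
                for ti, thr in enumerate(grid):
                    vals = period_table[si, c, m, ti]
                    for p in range(constants.N_PERIODS):
                        rows.append(
                            {
                                "subject_id": sid,
                                "chromophore": chrom,
                                "metric": metric,
                                "threshold": float(thr),
                                "period": p + 1,
                                "value": float(vals[p]),
                                "delta_vs_period1": float(vals[p] - vals[0]) if p else 0.0,
                            }
                        )
    return pd.DataFrame(rows)


def tidy_to_index_table(df: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Inverse of :func:`index_table_to_tidy`."""
    subjects = sorted(df["subject_id"].unique())
    grid = constants.THRESHOLD_GRID
    out = np.full((len(subjects), 3, 3, grid.size, constants.N_PERIODS), np.nan)
    c_idx = {c: i for i, c in enumerate(constants.CHROMOPHORES)}
    m_idx = {m: i for i, m in enumerate(constants.GRAPH_METRICS)}
    s_idx = {s: i for i, s in enumerate(subjects)}
    t_idx = {round(float(t), 2): i for i, t in enumerate(grid)}
    for row in df.itertuples(index=False):
        out[
            s_idx[row.subject_id],
            c_idx[row.chromophore],
            m_idx[row.metric],
            t_idx[round(float(row.threshold), 2)],
            int(row.period) - 1,
        ] = row.value
    return out, subjects
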