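"""Device geometry, optical constants, and cognitive-battery definitions.

All values here are configuration defaults: the optical constants follow
standard adult-forehead practice and are overridable through the relevant
function arguments, because no downstream statistic depends on the absolute
concentration scale (everything is correlation-based).
"""

from __future__ import annotations

import numpy as np

#: Wavelengths of the dual-wavelength source, nm.
WAVELENGTHS_NM: tuple[float, float] = (810.0, 850.0)

#: Base-10 molar extinction coefficients, cm^-1 mM^-1, {wavelength: (HbO, HbR)}.
#: Compendium-style values for adult haemoglobin.
EXTINCTION_CM1_MM1: dict[float, tuple[float, float]] = {
    810.0: (0.8830, 0.7470),
    850.0: (1.0580, 0.6913),
}

#: Differential pathlength factor, dimensionless, per wavelength.
DPF_DEFAULT: tuple[float, float] = (6.0, 6.0)

#: Source-detector separation, cm.
SOURCE_DETECTOR_DISTANCE_CM: float = 3.0

#: Sampling rate of the wearable device, Hz.
SAMPLING_RATE_HZ: float = 8.138

#: Session length, s.
SESSION_DURATION_S: float = 900.0

N_CHANNELS: int = 15

#: Prefrontal montage: 5 sources x 7 detectors, 15 channels at 3 cm.
#: Each source pairs with three adjacent detectors.
SOURCE_DETECTOR_PAIRS: list[tuple[int, int]] = [
    (s, d) for s in range(1, 6) for d in (s, s + 1, s + 2)
]

#: Binarization threshold grid for the connectivity matrices.
THRESHOLD_GRID: np.ndarray = np.round(np.arange(0.40, 0.901, 0.01), 2)

CHROMOPHORES: tuple[str, ...] = ("HbO", "HbR", "HbT")
GRAPH_METRICS: tuple[str, ...] = ("DC", "GE", "CC")

N_TRIALS: int = 15
TRIALS_PER_PERIOD: int = 3
N_PERIODS: int = 5
TRIAL_POOL: int = 20

#: Responder cutoff on the change in global cognitive score.
DELTA_GCS_CUTOFF: float = 0.5

#: Default classification cutoff on predicted ΔGCS.
PREDICTED_DGCS_CUTOFF: float = 0.35

# ---------------------------------------------------------------------------
# Cognitive battery: nine metrics, administered before and after the 12-week
# intervention.  ``higher_is_better`` drives the orientation alignment before
# z-scoring (time-based scores improve downward).  ``pre_mean``/``pre_sd`` are
# the synthetic generator's population parameters, in native units.
# ``improves`` marks the metrics the generator treats as responsive at the
# cohort level (seven of nine).
# ---------------------------------------------------------------------------
COGNITIVE_METRICS: dict[str, dict] = {
    "DST_F": {"pre_mean": 8.0, "pre_sd": 2.0, "higher_is_better": True, "improves": True},
    "DST_B": {"pre_mean": 6.0, "pre_sd": 2.0, "higher_is_better": True, "improves": True},
    "VFT": {"pre_mean": 30.0, "pre_sd": 8.0, "higher_is_better": True, "improves": False},
    "KAVLT_immediate": {"pre_mean": 40.0, "pre_sd": 10.0, "higher_is_better": True, "improves": True},
    "KAVLT_delayed": {"pre_mean": 8.0, "pre_sd": 3.0, "higher_is_better": True, "improves": True},
    "KAVLT_recognition": {"pre_mean": 12.0, "pre_sd": 2.5, "higher_is_better": True, "improves": True},
    "Stroop_time": {"pre_mean": 60.0, "pre_sd": 15.0, "higher_is_better": False, "improves": True},
    "DSC": {"pre_mean": 45.0, "pre_sd": 12.0, "higher_is_better": True, "improves": True},
    "RMT": {"pre_mean": 20.0, "pre_sd": 4.0, "higher_is_better": True, "improves": False},
}

METRIC_NAMES: tuple[str, ...] = tuple(COGNITIVE_METRICS)
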