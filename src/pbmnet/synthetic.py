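"""Synthetic cohorts with planted treatment-response structure.

The generator emulates the study design the analysis pipeline assumes: two
groups of older adults (responders / non-responders to a 12-week home
photobiomodulation course), each contributing ~20 resting prefrontal optical
sessions recorded at 8.138 Hz from 15 channels at 810/850 nm, plus a
nine-metric cognitive battery administered before and after the course.

Planted structure
-----------------
* True ΔGCS: responders ~ Normal(0.9, 0.3) truncated at ≥ 0.5,
  non-responders ~ Normal(0.1, 0.25) truncated at < 0.5.
* Each subject carries a latent inter-channel correlation matrix per session;
  for responders its mean off-diagonal level declines linearly across
  sessions with slope effect_slope x true ΔGCS, for non-responders it is
  flat.  This is what makes Δperiod graph indices correlate negatively with
  ΔGCS downstream.
* Sessions are built in the hemodynamic domain — band-limited (0.01–0.09 Hz)
  correlated slow oscillations plus cardiac / respiratory / Mayer sinusoids,
  1/f noise, and Poisson motion artifacts (spikes and baseline steps) — and
  then pushed through the forward modified Beer–Lambert model to dual-
  wavelength intensities, so preprocessing must genuinely invert the optics.

Seeding is hierarchical (master seed -> per-subject -> per-session streams),
so adding a subject never perturbs the others' data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import fft as sp_fft
from scipy import signal, stats

from . import constants
from .preprocess import OpticalSession


class SyntheticError(ValueError):
    pass


@dataclass
class NoiseSpec:
    """Amplitudes of the physiological/noise components, µM equivalents."""

    structured: float = 0.5      # band-limited correlated component
    cardiac: float = 0.25        # ~1 Hz (alias-prone at 8.138 Hz, as in reality)
    respiratory: float = 0.15    # ~0.3 Hz
    mayer: float = 0.20          # ~0.1 Hz
    one_over_f: float = 0.25
    battery_noise_sd: float = 0.25  # per-metric noise on cognitive changes, z-units


@dataclass
class CohortSpec:
    n_responders: int = 14
    n_nonresponders: int = 15
    n_sessions_per_subject: int = 20
    sampling_rate: float = constants.SAMPLING_RATE_HZ
    session_duration: float = constants.SESSION_DURATION_S
    n_channels: int = constants.N_CHANNELS
    wavelengths: tuple[float, float] = constants.WAVELENGTHS_NM
    effect_slope: float = 0.45
    base_correlation: float = 0.60
    correlation_jitter: float = 0.08
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    artifact_rate: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_responders, self.n_nonresponders) < 0:
            raise SyntheticError("group sizes must be non-negative")
        if self.n_sessions_per_subject < constants.TRIAL_POOL:
            raise SyntheticError(
                f"need at least {constants.TRIAL_POOL} sessions per subject"
            )
        if self.session_duration <= 25:
            raise SyntheticError("session too short for the segmentation windows")


@dataclass
class SubjectState:
    """Latent per-subject ground truth carried into session generation."""

    subject_id: str
    responder: bool
    true_delta_gcs: float
    pair_jitter: np.ndarray          # symmetric per-pair offsets, zero diag
    decline_per_session: float       # drop in off-diagonal correlation per session


@dataclass
class GroundTruth:
    subject_ids: list[str]
    responder: np.ndarray            # bool per subject
    true_delta_gcs: np.ndarray
    latent_correlations: dict[str, np.ndarray]  # subject -> (n_sessions, ch, ch)


def _nearest_psd_correlation(R: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues and renormalize to unit diagonal."""
    w, V = np.linalg.eigh((R + R.T) / 2)
    if w.min() < 1e-9:
        w = np.clip(w, 1e-9, None)
        R = (V * w) @ V.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return R


def latent_correlation(state: SubjectState, session_index: int,
                       spec: CohortSpec) -> np.ndarray:
    """Planted inter-channel correlation matrix for one session."""
    level = spec.base_correlation - state.decline_per_session * session_index
    R = np.clip(level + state.pair_jitter, 0.02, 0.97)
    np.fill_diagonal(R, 1.0)
    return _nearest_psd_correlation(R)


@lru_cache(maxsize=8)
def _band_sos(fs: float, band: tuple[float, float]) -> np.ndarray:
    return signal.butter(2, band, btype="bandpass", fs=fs, output="sos")


def _band_limited_correlated(rng: np.random.Generator, R: np.ndarray, n: int,
                             fs: float, band: tuple[float, float]) -> np.ndarray:
    """Unit-SD signals with correlation ~R inside the 0.01–0.09 Hz band."""
    nch = R.shape[0]
    pad = int(round(60 * fs))  # settle the filter transient outside the session
    white = rng.standard_normal((nch, n + 2 * pad), dtype=np.float32)
    sos = _band_sos(fs, band)
    slow = signal.sosfilt(sos, white, axis=-1)[:, pad:pad + n]
    slow /= slow.std(axis=-1, keepdims=True) + 1e-30
    w, V = np.linalg.eigh(R)
    sqrtR = ((V * np.sqrt(np.clip(w, 0, None))) @ V.T).astype(np.float32)
    mixed = sqrtR @ slow
    return mixed / (mixed.std(axis=-1, keepdims=True) + 1e-30)


def _one_over_f(rng: np.random.Generator, nch: int, n: int) -> np.ndarray:
    nf = sp_fft.next_fast_len(n)  # pad: arbitrary n can hit worst-case FFT sizes
    white = rng.standard_normal((nch, nf), dtype=np.float32)
    spec_f = sp_fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(nf)
    with np.errstate(divide="ignore"):
        scale = np.where(f > 0, 1.0 / np.sqrt(f), 0.0).astype(np.float32)
    pink = sp_fft.irfft(spec_f * scale, n=nf, axis=-1)[:, :n]
    sd = pink.std(axis=-1, keepdims=True)
    return pink / (sd + 1e-30)


def _oscillations(rng: np.random.Generator, nch: int, t: np.ndarray,
                  noise: NoiseSpec) -> np.ndarray:
    out = np.zeros((nch, t.size), dtype=np.float32)
    for amp, f0, jit in ((noise.cardiac, 1.0, 0.1), (noise.respiratory, 0.3, 0.03),
                         (noise.mayer, 0.1, 0.01)):
        if amp == 0:
            continue
        freq = f0 + jit * rng.standard_normal()
        phase = rng.uniform(0, 2 * np.pi, size=(nch, 1))
        # sin(wt + φ) expanded so the n-length sin/cos are computed once,
        # not per channel
        wt_sin = np.sin(2 * np.pi * freq * t, dtype=np.float32)
        wt_cos = np.cos(2 * np.pi * freq * t, dtype=np.float32)
        out += amp * (np.cos(phase).astype(np.float32) * wt_sin[None, :]
                      + np.sin(phase).astype(np.float32) * wt_cos[None, :])
    return out


def _motion_artifacts(rng: np.random.Generator, sig: np.ndarray,
                      rate: float) -> np.ndarray:
    """Poisson motion events: sharp spikes (5–20 x SD, 1–3 samples) and step
    baseline shifts persisting to session end, common across channels with
    channel-specific gains."""
    nch, n = sig.shape
    k = rng.poisson(rate)
    art = np.zeros_like(sig)
    sd = sig.std(axis=-1, keepdims=True) + 1e-30
    for _ in range(k):
        pos = rng.integers(0, n)
        gain = rng.uniform(0.5, 1.5, size=(nch, 1))
        sign = rng.choice([-1.0, 1.0])
        if rng.random() < 0.6:
            width = rng.integers(1, 4)
            amp = rng.uniform(5, 20)
            art[:, pos:pos + width] += (sign * amp * gain * sd)
        else:
            amp = rng.uniform(2, 8)
            art[:, pos:] += (sign * amp * gain * sd)
    return art


def forward_intensities(dHbO: np.ndarray, dHbR: np.ndarray, rng: np.random.Generator,
                        wavelengths: tuple[float, float] = constants.WAVELENGTHS_NM,
                        dpf: tuple[float, float] = constants.DPF_DEFAULT,
                        distance_cm: float = constants.SOURCE_DETECTOR_DISTANCE_CM,
                        base_intensity: np.ndarray | None = None,
                        dtype=np.float64) -> np.ndarray:
    """Forward modified Beer–Lambert model: µM concentration changes to
    dual-wavelength intensities, I = I0 · 10^(−ΔOD).

    ``dtype=float64`` (default) keeps the forward/inverse round trip exact to
    numerical precision; the session generator uses float32 internally, where
    noise dwarfs the representation error.
    """
    E = np.asarray([constants.EXTINCTION_CM1_MM1[w] for w in wavelengths])
    conc_mM = np.stack([dHbO, dHbR], axis=1).astype(dtype) * 1e-3  # (ch, 2, t)
    scale = (E * distance_cm * np.asarray(dpf)[:, None]).astype(dtype)
    dod = np.einsum("lk,ckt->clt", scale, conc_mM)
    nch = dHbO.shape[0]
    if base_intensity is None:
        base_intensity = rng.uniform(0.5, 2.0, size=(nch, 2, 1))
    return base_intensity.astype(dtype) * np.exp(dtype(-np.log(10.0)) * dod)


def generate_session(state: SubjectState, session_index: int, spec: CohortSpec,
                     seed: np.random.SeedSequence | int | None = None,
                     latent: np.ndarray | None = None) -> OpticalSession:
    """One 15-channel dual-wavelength session for a given subject state."""
    if seed is None:
        seed = np.random.SeedSequence(spec.seed)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    n = int(round(spec.session_duration * spec.sampling_rate))
    t = np.arange(n) / spec.sampling_rate
    R = latent_correlation(state, session_index, spec) if latent is None else latent
    noise = spec.noise

    slow = noise.structured * _band_limited_correlated(
        rng, R, n, spec.sampling_rate, (0.01, 0.09))
    osc_o = _oscillations(rng, spec.n_channels, t, noise)
    pink_o = noise.one_over_f * _one_over_f(rng, spec.n_channels, n)
    dHbO = slow + osc_o + pink_o

    osc_r = _oscillations(rng, spec.n_channels, t, noise)
    pink_r = noise.one_over_f * _one_over_f(rng, spec.n_channels, n)
    dHbR = -0.35 * slow + 0.3 * (osc_r + pink_r)

    if spec.artifact_rate > 0:
        art = _motion_artifacts(rng, dHbO, spec.artifact_rate)
        dHbO = dHbO + art
        dHbR = dHbR - 0.35 * art

    intensities = forward_intensities(dHbO, dHbR, rng, spec.wavelengths,
                                      dtype=np.float32)
    return OpticalSession(
        intensities=intensities,
        sampling_rate=spec.sampling_rate,
        wavelengths=spec.wavelengths,
        metadata={
            "subject_id": state.subject_id,
            "session_index": session_index,
            "source_detector_pairs": constants.SOURCE_DETECTOR_PAIRS[: spec.n_channels],
            "seed_entropy": int(ss.entropy) if ss.entropy is not None else None,
        },
    )


def generate_cognitive_battery(true_delta_gcs: np.ndarray,
                               rng: np.random.Generator,
                               noise_sd: float = 0.25) -> pd.DataFrame:
    """Nine-metric pre/post battery consistent with the true ΔGCS values.

    For the seven cohort-responsive metrics the orientation-aligned change is
    true ΔGCS (in units of the metric's population SD) plus independent
    Gaussian noise; the two flat metrics carry noise only.  With noise_sd = 0
    and the generator's normalization stats, scoring recovers ΔGCS exactly.
    """
    d = np.asarray(true_delta_gcs, dtype=float)
    n = d.size
    cols = {}
    for m, info in constants.COGNITIVE_METRICS.items():
        o = 1.0 if info["higher_is_better"] else -1.0
        pre = info["pre_mean"] + info["pre_sd"] * rng.standard_normal(n)
        effect = d if info["improves"] else 0.0
        change_z = effect + noise_sd * rng.standard_normal(n)
        cols[f"{m}_pre"] = pre
        cols[f"{m}_post"] = pre + o * info["pre_sd"] * change_z
    return pd.DataFrame(cols, index=[f"S{i:02d}" for i in range(n)])


def generator_norm_stats() -> dict[str, tuple[float, float]]:
    """The population (mean, SD) per metric the generator draws from; handing
    these to ``scoring.compute_gcs`` gives exact ΔGCS recovery at zero noise."""
    return {
        m: (info["pre_mean"], info["pre_sd"])
        for m, info in constants.COGNITIVE_METRICS.items()
    }


def _draw_delta_gcs(rng: np.random.Generator, responder: bool) -> float:
    """Truncated-normal ΔGCS either side of the 0.5 responder cutoff."""
    if responder:
        a = (0.5 - 0.9) / 0.3
        return float(stats.truncnorm.rvs(a, np.inf, loc=0.9, scale=0.3, random_state=rng))
    b = (0.5 - 0.1) / 0.25
    return float(stats.truncnorm.rvs(-np.inf, b, loc=0.1, scale=0.25, random_state=rng))


def _subject_state(spec: CohortSpec, idx: int, responder: bool,
                   rng: np.random.Generator) -> SubjectState:
    sid = f"S{idx:02d}"
    dgcs = _draw_delta_gcs(rng, responder)
    J = rng.normal(0.0, spec.correlation_jitter,
                   size=(spec.n_channels, spec.n_channels))
    J = (J + J.T) / 2
    np.fill_diagonal(J, 0.0)
    # responders' connectivity declines in proportion to effect_slope x ΔGCS
    total_decline = spec.effect_slope * dgcs if responder else 0.0
    per_session = total_decline / max(spec.n_sessions_per_subject - 1, 1)
    return SubjectState(subject_id=sid, responder=responder, true_delta_gcs=dgcs,
                        pair_jitter=J, decline_per_session=per_session)


def generate_cohort(spec: CohortSpec) -> tuple[
        dict[str, list[OpticalSession]], pd.DataFrame, GroundTruth]:
    """Generate a full cohort: per-subject session lists, the cognitive
    battery table, and the ground truth.

    Determinism: the output is a pure function of ``spec`` (bit-exact under a
    fixed seed); per-subject and per-session streams are keyed sub-seeds of
    ``spec.seed``.
    """
    spec.validate()
    n_tot = spec.n_responders + spec.n_nonresponders
    sessions: dict[str, list[OpticalSession]] = {}
    states: list[SubjectState] = []
    latents: dict[str, np.ndarray] = {}
    for idx in range(n_tot):
        responder = idx < spec.n_responders
        subj_ss = np.random.SeedSequence(entropy=spec.seed, spawn_key=(idx,))
        subj_rng = np.random.default_rng(subj_ss)
        state = _subject_state(spec, idx, responder, subj_rng)
        states.append(state)
        subj_sessions = []
        lat = np.empty((spec.n_sessions_per_subject, spec.n_channels, spec.n_channels))
        for s in range(spec.n_sessions_per_subject):
            sess_ss = np.random.SeedSequence(entropy=spec.seed, spawn_key=(idx, s))
            R = latent_correlation(state, s, spec)
            lat[s] = R
            subj_sessions.append(
                generate_session(state, s, spec, seed=sess_ss, latent=R))
        sessions[state.subject_id] = subj_sessions
        latents[state.subject_id] = lat

    batt_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(n_tot, 9999)))
    dgcs = np.array([st.true_delta_gcs for st in states])
    battery = generate_cognitive_battery(dgcs, batt_rng,
                                         noise_sd=spec.noise.battery_noise_sd)
    battery.index = [st.subject_id for st in states]
    truth = GroundTruth(
        subject_ids=[st.subject_id for st in states],
        responder=np.array([st.responder for st in states]),
        true_delta_gcs=dgcs,
        latent_correlations=latents,
    )
    return sessions, battery, truth
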