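"""Synthetic epoched-fNIRS corpora with hierarchical domain shift.

The generator emulates block-design workload experiments: every epoch carries
a class-dependent hemodynamic response on a subset of informative channels,
plus nuisance structure at three hierarchy levels —

* subject: multiplicative response gain + additive baseline offset
  (anatomy / optode coupling differences between people),
* session: per-feature additive offset (sensor re-placement between sittings),
* block: slow additive offset + linear drift + small gain jitter
  (instrument drift and posture changes within a sitting),

with AR(1)-correlated measurement noise and a sinusoidal systemic
(physiological) oscillation on top.  Oxygenated-hemoglobin (HbO) features
carry the positive task response; deoxygenated (HbR) features carry the
negated, scaled response, as in real hemodynamics.

All randomness flows from one integer seed through per-subject spawned
streams, so corpora are reproducible and independent of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from .core_data import DomainKey, Epoch, EpochSet, ExperimentDesign, ValidationError

__all__ = [
    "HRFModel",
    "GeneratorConfig",
    "hrf_response",
    "generate_dataset",
    "sample_domain_effects",
    "default_class_amplitudes",
]


# ---------------------------------------------------------------------------
# hemodynamic response
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HRFModel:
    """Canonical hemodynamic response: gamma rise plus delayed undershoot.

    The rise is a gamma-shaped curve with its mode at ``peak_seconds``; the
    undershoot is a second gamma curve starting *at* the main peak (so the
    unit normalization at the peak is exact), scaled by ``undershoot_ratio``.
    """

    peak_seconds: float = 6.0
    width_seconds: float = 3.0
    undershoot_ratio: float = 1.0 / 6.0
    undershoot_delay_seconds: float = 10.0
    undershoot_width_seconds: float = 6.0

    def __post_init__(self):
        if self.peak_seconds <= 0 or self.width_seconds <= 0:
            raise ValueError("HRF peak and width must be positive")
        if self.undershoot_ratio < 0:
            raise ValueError("undershoot_ratio must be >= 0")


def _gamma_shape_scale(mode: float, width: float) -> tuple[float, float]:
    # gamma pdf with mode at `mode`: scale = width^2/mode, shape = mode/scale + 1
    scale = width**2 / mode
    shape = mode / scale + 1.0
    return shape, scale


def hrf_response(t: np.ndarray, model: HRFModel = HRFModel()) -> np.ndarray:
    """Unit-peak hemodynamic response sampled at times ``t`` (seconds, >= 0).

    ``response(0) == 0`` and ``response(peak_seconds) == 1`` exactly; the
    undershoot pulls the tail below zero after the peak.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("hrf_response requires t >= 0")
    a1, s1 = _gamma_shape_scale(model.peak_seconds, model.width_seconds)
    rise = sp_stats.gamma.pdf(t, a1, scale=s1)
    rise = rise / sp_stats.gamma.pdf(model.peak_seconds, a1, scale=s1)
    out = rise
    if model.undershoot_ratio > 0:
        a2, s2 = _gamma_shape_scale(model.undershoot_delay_seconds, model.undershoot_width_seconds)
        tu = np.clip(t - model.peak_seconds, 0.0, None)
        under = sp_stats.gamma.pdf(tu, a2, scale=s2)
        under = under / sp_stats.gamma.pdf(model.undershoot_delay_seconds, a2, scale=s2)
        out = rise - model.undershoot_ratio * under
    return out


# ---------------------------------------------------------------------------
# generator configuration
# ---------------------------------------------------------------------------

def default_class_amplitudes(design: ExperimentDesign) -> dict[int, float]:
    """Monotone per-class response gains: harder conditions activate more."""
    labels = sorted(design.class_set)
    lo, hi = 0.5, 1.5
    if len(labels) == 1:
        return {labels[0]: hi}
    return {
        lab: lo + (hi - lo) * i / (len(labels) - 1) for i, lab in enumerate(labels)
    }


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic corpus.

    Effect magnitudes are in the same arbitrary concentration units as the
    class response (whose strongest class has gain ~1.5 by default).
    ``informative_channel_fraction`` controls how many of the lowest-index
    spatial channels carry any class signal; the rest are pure nuisance.
    """

    design: ExperimentDesign
    class_amplitudes: Mapping[int, float] | None = None
    hrf: HRFModel = field(default_factory=HRFModel)
    subject_gain_sd: float = 0.25
    subject_offset_sd: float = 0.4
    session_offset_sd: float = 0.5
    block_drift_sd: float = 0.6
    ar1_coefficient: float = 0.6
    physio_oscillation_amplitude: float = 0.3
    physio_oscillation_frequency: float = 0.1
    measurement_noise_sd: float = 0.35
    informative_channel_fraction: float = 0.25
    hbr_ratio: float = 1.0 / 3.0
    seed: int = 0

    def __post_init__(self):
        for name in (
            "subject_gain_sd",
            "subject_offset_sd",
            "session_offset_sd",
            "block_drift_sd",
            "measurement_noise_sd",
            "physio_oscillation_amplitude",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.informative_channel_fraction <= 1:
            raise ValueError("informative_channel_fraction must be in (0, 1]")
        if not abs(self.ar1_coefficient) < 1:
            raise ValueError("|ar1_coefficient| must be < 1")
        if self.hbr_ratio <= 0:
            raise ValueError("hbr_ratio must be > 0")

    def resolved_amplitudes(self) -> dict[int, float]:
        if self.class_amplitudes is None:
            return default_class_amplitudes(self.design)
        amps = dict(self.class_amplitudes)
        missing = set(self.design.class_set) - set(amps)
        if missing:
            raise ValueError(f"class_amplitudes missing labels {sorted(missing)}")
        return amps

    def informative_channels(self) -> np.ndarray:
        n = max(1, int(round(self.informative_channel_fraction * self.design.n_spatial_channels)))
        return np.arange(n)


# ---------------------------------------------------------------------------
# domain effects
# ---------------------------------------------------------------------------

def _subject_streams(seed: int, n_subjects: int):
    """Two independent child streams per subject: (effects, data)."""
    children = np.random.SeedSequence(seed).spawn(n_subjects)
    return [tuple(np.random.default_rng(s) for s in child.spawn(2)) for child in children]


def _draw_subject_effects(cfg: GeneratorConfig, rng: np.random.Generator, subject_id: str):
    design = cfg.design
    F = design.n_features
    subject = {
        "gain": rng.normal(0.0, cfg.subject_gain_sd),
        "offset": rng.normal(0.0, cfg.subject_offset_sd),
    }
    sessions = {}
    blocks = {}
    for sess in range(design.sessions_per_subject):
        sessions[DomainKey(subject_id, sess, 0, "session")] = {
            "channel_offsets": rng.normal(0.0, cfg.session_offset_sd, size=F)
        }
        for blk in range(design.blocks_per_session):
            # per-feature offsets: regional baseline and coupling drift differ
            # across channels within a sitting, not uniformly
            blocks[DomainKey(subject_id, sess, blk, "block")] = {
                "offset": rng.normal(0.0, cfg.block_drift_sd, size=F),
                "ramp": rng.normal(0.0, cfg.block_drift_sd),
                "gain_jitter": rng.normal(0.0, cfg.block_drift_sd / 4.0),
            }
    return subject, sessions, blocks


def sample_domain_effects(
    config: GeneratorConfig, n_subjects: int | None = None, seed: int | None = None
) -> dict[str, dict]:
    """Draw the per-subject/session/block effect tables.

    Returns a dict with keys ``subject`` / ``session`` / ``block``, each a
    table keyed by :class:`DomainKey` in the corresponding mode.  These are
    exactly the effects :func:`generate_dataset` applies for the same seed.
    """
    if n_subjects is None:
        n_subjects = config.design.n_subjects
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if seed is None:
        seed = config.seed
    out = {"subject": {}, "session": {}, "block": {}}
    for i, (eff_rng, _) in enumerate(_subject_streams(seed, n_subjects)):
        sid = f"S{i:03d}"
        subj, sess, blk = _draw_subject_effects(config, eff_rng, sid)
        out["subject"][DomainKey(sid, 0, 0, "subject")] = subj
        out["session"].update(sess)
        out["block"].update(blk)
    return out


# ---------------------------------------------------------------------------
# corpus generation
# ---------------------------------------------------------------------------

def _trial_activation(design: ExperimentDesign, hrf: HRFModel) -> np.ndarray:
    """Within-window activation curve, peak-normalized over the window.

    The task response is a boxcar of the task period convolved with the HRF,
    truncated to the epoch window and scaled to peak 1 so class amplitudes
    set the within-epoch signal size directly regardless of window length.
    """
    T = design.n_timesteps
    fs = design.sampling_rate
    kernel_t = np.arange(0, 32.0, 1.0 / fs)
    kernel = hrf_response(kernel_t, hrf)
    kernel = kernel / np.abs(kernel).sum()
    boxcar = np.ones(T)
    act = np.convolve(boxcar, kernel)[:T]
    peak = np.abs(act).max()
    if peak > 0:
        act = act / peak
    return act


def _session_labels(design: ExperimentDesign, rng: np.random.Generator) -> np.ndarray:
    """Per-trial labels for one session of a label-heterogeneous design."""
    n_trials = design.blocks_per_session * design.trials_per_block
    n_cls = design.n_classes
    if n_trials % n_cls != 0:
        raise ValidationError(
            "heterogeneous design needs trials per session divisible by class count"
        )
    labels = np.repeat(np.asarray(design.class_set), n_trials // n_cls)
    rng.shuffle(labels)
    return labels


def generate_dataset(config: GeneratorConfig) -> EpochSet:
    """Generate a full corpus following ``config.design``.

    Epoch data = subject gain x (class amplitude x HRF activation on the
    informative channels) + subject offset + session channel offsets + block
    offset/ramp + AR(1) noise + sinusoidal physiological oscillation, with
    HbR features receiving the negated, ``hbr_ratio``-scaled class response.
    """
    design = config.design
    if design.n_subjects < 1:
        raise ValidationError("design must include at least one subject")
    amps = config.resolved_amplitudes()
    act = _trial_activation(design, config.hrf)
    T, F = design.n_timesteps, design.n_features
    fs = design.sampling_rate
    rho = config.ar1_coefficient
    innov_sd = config.measurement_noise_sd * np.sqrt(1.0 - rho**2)

    info_ch = config.informative_channels()
    hbo_cols = np.intersect1d(design.hbo_columns(), np.concatenate([
        design.feature_columns(ch) for ch in info_ch
    ]))
    hbr_all = design.hbr_columns()
    hbr_cols = (
        np.intersect1d(hbr_all, np.concatenate([design.feature_columns(ch) for ch in info_ch]))
        if hbr_all.size
        else hbr_all
    )

    window_time = np.arange(T) / fs
    epochs: list[Epoch] = []
    streams = _subject_streams(config.seed, design.n_subjects)
    for i, (eff_rng, data_rng) in enumerate(streams):
        sid = f"S{i:03d}"
        subj_eff, sess_eff, blk_eff = _draw_subject_effects(config, eff_rng, sid)
        gain = 1.0 + subj_eff["gain"]
        for sess in range(design.sessions_per_subject):
            sess_offsets = sess_eff[DomainKey(sid, sess, 0, "session")]["channel_offsets"]
            if design.block_condition_order is None:
                labels = _session_labels(design, data_rng)
            for blk in range(design.blocks_per_session):
                be = blk_eff[DomainKey(sid, sess, blk, "block")]
                phase = data_rng.uniform(0.0, 2.0 * np.pi)
                block_len = design.trials_per_block * T
                for trial in range(design.trials_per_block):
                    if design.block_condition_order is None:
                        label = int(labels[blk * design.trials_per_block + trial])
                    else:
                        label = design.block_condition(sess, blk)
                    # nuisance noise: AR(1) + systemic oscillation
                    innov = data_rng.normal(0.0, innov_sd, size=(T, F))
                    noise = sp_signal.lfilter([1.0], [1.0, -rho], innov, axis=0)
                    t_in_block = (trial * T + np.arange(T)) / fs
                    physio = config.physio_oscillation_amplitude * np.sin(
                        2.0 * np.pi * config.physio_oscillation_frequency * t_in_block + phase
                    )
                    frac = (trial * T + np.arange(T)) / max(block_len - 1, 1)
                    drift = be["offset"][None, :] + be["ramp"] * (frac - 0.5)[:, None]

                    data = noise + physio[:, None] + drift
                    data += subj_eff["offset"] + sess_offsets[None, :]
                    response = gain * (1.0 + be["gain_jitter"]) * amps[label] * act
                    data[:, hbo_cols] += response[:, None]
                    if hbr_cols.size:
                        data[:, hbr_cols] -= config.hbr_ratio * response[:, None]
                    epochs.append(
                        Epoch(
                            data=data.astype(np.float32),
                            sampling_rate=fs,
                            subject_id=sid,
                            session_idx=sess,
                            block_idx=blk,
                            trial_idx=trial,
                            label=label,
                        )
                    )
    return EpochSet(epochs, design)
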