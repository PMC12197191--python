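"""Domain types and on-disk container for epoched fNIRS data.

An *epoch* is one windowed trial: a ``[T timesteps x F features]`` array of
hemoglobin-concentration changes plus its position in the experiment hierarchy
(subject / session / block / trial) and its class label.  The experiment
designs bundled as presets mirror three published block-design workload
studies: a 26-subject n-back study with 36 optode channels ("tuberlin"), a
30-subject finger/foot-tapping study with 20 channels ("fft"), and a
68-subject single-session n-back study with 2 dual-slope probes ("tufts").

On disk an epoch corpus is an HDF5 array (``epochs.h5``, dataset ``epochs``),
a CSV metadata table (``meta.csv``) and a JSON design record (``design.json``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "Epoch",
    "ExperimentDesign",
    "EpochSet",
    "DomainKey",
    "TaskPeriod",
    "ValidationError",
    "tuberlin_design",
    "fft_design",
    "tufts_design",
    "save_epochs",
    "load_epochs",
    "slide_windows",
]


class ValidationError(ValueError):
    """Raised when epoch data or metadata violates the container schema."""


# ---------------------------------------------------------------------------
# experiment designs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentDesign:
    """Structure of a block-design fNIRS experiment.

    ``block_condition_order`` is the within-session condition sequence, one
    label per block (length = ``blocks_per_session``), applied identically to
    every session.  ``None`` means blocks are label-heterogeneous and trial
    labels are assigned by a balanced random order within each session (the
    finger-tapping convention, where a "block" is simply a run of consecutive
    trials).
    """

    name: str
    n_subjects: int
    sessions_per_subject: int
    blocks_per_session: int
    trials_per_block: int
    block_condition_order: tuple[int, ...] | None
    window_seconds: float
    sampling_rate: float
    n_spatial_channels: int
    n_hemoglobin_types: int
    n_optical_types: int
    class_set: tuple[int, ...]
    n_timesteps_override: int | None = None

    def __post_init__(self):
        if self.block_condition_order is not None:
            if len(self.block_condition_order) != self.blocks_per_session:
                raise ValidationError(
                    f"block_condition_order has {len(self.block_condition_order)} entries; "
                    f"expected blocks_per_session = {self.blocks_per_session}"
                )
            bad = set(self.block_condition_order) - set(self.class_set)
            if bad:
                raise ValidationError(f"block conditions {sorted(bad)} not in class_set")
        if self.trials_per_block < 1 or self.blocks_per_session < 1:
            raise ValidationError("design must have at least one trial per block")

    # -- derived shape -----------------------------------------------------
    @property
    def n_timesteps(self) -> int:
        """Samples per epoch, T."""
        if self.n_timesteps_override is not None:
            return self.n_timesteps_override
        return int(round(self.window_seconds * self.sampling_rate))

    @property
    def n_features(self) -> int:
        """Feature columns per timestep, F = channels x hemoglobin x optical."""
        return self.n_spatial_channels * self.n_hemoglobin_types * self.n_optical_types

    @property
    def n_classes(self) -> int:
        return len(self.class_set)

    # -- feature layout ------------------------------------------------------
    # channel-major: channel s owns a contiguous run of (hb x optical) columns,
    # HbO rows first, then HbR, each with its optical types in order.
    @property
    def features_per_channel(self) -> int:
        return self.n_hemoglobin_types * self.n_optical_types

    def feature_columns(self, channel: int) -> np.ndarray:
        q = self.features_per_channel
        return np.arange(channel * q, (channel + 1) * q)

    def hbo_columns(self) -> np.ndarray:
        """Columns holding oxygenated-hemoglobin features."""
        q = self.features_per_channel
        cols = []
        for ch in range(self.n_spatial_channels):
            cols.extend(range(ch * q, ch * q + self.n_optical_types))
        return np.asarray(cols)

    def hbr_columns(self) -> np.ndarray:
        """Columns holding deoxygenated-hemoglobin features."""
        if self.n_hemoglobin_types < 2:
            return np.asarray([], dtype=int)
        q = self.features_per_channel
        cols = []
        for ch in range(self.n_spatial_channels):
            cols.extend(range(ch * q + self.n_optical_types, ch * q + 2 * self.n_optical_types))
        return np.asarray(cols)

    def block_condition(self, session_idx: int, block_idx: int) -> int | None:
        if self.block_condition_order is None:
            return None
        return self.block_condition_order[block_idx]

    def to_json(self) -> str:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["block_condition_order"] = (
            list(self.block_condition_order) if self.block_condition_order is not None else None
        )
        d["class_set"] = list(self.class_set)
        return json.dumps(d, indent=1)

    @staticmethod
    def from_json(text: str) -> "ExperimentDesign":
        d = json.loads(text)
        if d.get("block_condition_order") is not None:
            d["block_condition_order"] = tuple(d["block_condition_order"])
        d["class_set"] = tuple(d["class_set"])
        return ExperimentDesign(**d)


def tuberlin_design(n_subjects: int = 26) -> ExperimentDesign:
    """Three-session n-back design: 9 blocks/session of 20 trials (three of
    each condition, counterbalanced 0-2-3-2-3-0-3-0-2, so each condition
    accrues 180 trials = 20 x 3 blocks x 3 sessions); 36 channels x HbO/HbR
    intensity -> 72 features; 2 s windows at 10 Hz -> T=20."""
    return ExperimentDesign(
        name="tuberlin",
        n_subjects=n_subjects,
        sessions_per_subject=3,
        blocks_per_session=9,
        trials_per_block=20,
        block_condition_order=(0, 2, 3, 2, 3, 0, 3, 0, 2),
        window_seconds=2.0,
        sampling_rate=10.0,
        n_spatial_channels=36,
        n_hemoglobin_types=2,
        n_optical_types=1,
        class_set=(0, 2, 3),
    )


def fft_design(n_subjects: int = 30) -> ExperimentDesign:
    """Finger/foot-tapping design: 3 sessions x 25 trials per task type in a
    randomized order, grouped as 25 "blocks" of 3 consecutive trials;
    20 channels x HbO/HbR -> 40 features; 10 s at 13.33 Hz, stored as T=134."""
    return ExperimentDesign(
        name="fft",
        n_subjects=n_subjects,
        sessions_per_subject=3,
        blocks_per_session=25,
        trials_per_block=3,
        block_condition_order=None,
        window_seconds=10.0,
        sampling_rate=13.33,
        n_spatial_channels=20,
        n_hemoglobin_types=2,
        n_optical_types=1,
        class_set=(0, 1, 2),
        n_timesteps_override=134,
    )


def tufts_design(n_subjects: int = 68) -> ExperimentDesign:
    """Single-session n-back design: 16 blocks of 40 trials, conditions
    counterbalanced 0-1-2-3-1-2-3-0-2-3-0-1-3-0-1-2; 2 probes x HbO/HbR x
    intensity/phase -> 8 features; 15 s windows at 10 Hz -> T=150."""
    return ExperimentDesign(
        name="tufts",
        n_subjects=n_subjects,
        sessions_per_subject=1,
        blocks_per_session=16,
        trials_per_block=40,
        block_condition_order=(0, 1, 2, 3, 1, 2, 3, 0, 2, 3, 0, 1, 3, 0, 1, 2),
        window_seconds=15.0,
        sampling_rate=10.0,
        n_spatial_channels=2,
        n_hemoglobin_types=2,
        n_optical_types=2,
        class_set=(0, 1, 2, 3),
    )


DESIGN_PRESETS = {
    "tuberlin": tuberlin_design,
    "fft": fft_design,
    "tufts": tufts_design,
}


# ---------------------------------------------------------------------------
# epochs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DomainKey:
    """Hierarchical domain identity of an epoch under a DA mode.

    ``mode`` controls projection: ``subject`` keys on the subject only,
    ``session`` on (subject, session), ``block`` on (subject, session, block).
    """

    subject_id: str
    session_idx: int
    block_idx: int
    mode: str = "block"

    _MODES = ("subject", "session", "block")

    def __post_init__(self):
        if self.mode not in self._MODES:
            raise ValueError(f"mode must be one of {self._MODES}, got {self.mode!r}")

    def project(self) -> tuple:
        if self.mode == "subject":
            return (self.subject_id,)
        if self.mode == "session":
            return (self.subject_id, self.session_idx)
        return (self.subject_id, self.session_idx, self.block_idx)


@dataclass
class Epoch:
    """One windowed fNIRS trial with its hierarchy metadata."""

    data: np.ndarray  # [T x F], float32
    sampling_rate: float
    subject_id: str
    session_idx: int
    block_idx: int
    trial_idx: int
    label: int

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 2:
            raise ValidationError(
                f"epoch data must be [T x F], got shape {self.data.shape} "
                f"(subject={self.subject_id}, trial={self.trial_idx})"
            )
        if not np.isfinite(self.data).all():
            raise ValidationError(
                f"non-finite values in epoch (subject={self.subject_id}, "
                f"session={self.session_idx}, block={self.block_idx}, trial={self.trial_idx})"
            )

    def key(self, mode: str = "block") -> DomainKey:
        return DomainKey(self.subject_id, self.session_idx, self.block_idx, mode)


class EpochSet:
    """An ordered corpus of epochs plus its experiment design."""

    def __init__(self, epochs: Sequence[Epoch], design: ExperimentDesign):
        self.epochs = list(epochs)
        self.design = design
        self._validate()

    def _validate(self) -> None:
        seen = set()
        class_set = set(self.design.class_set)
        T, F = self.design.n_timesteps, self.design.n_features
        for i, ep in enumerate(self.epochs):
            if ep.data.shape != (T, F):
                raise ValidationError(
                    f"epoch {i} has shape {ep.data.shape}, design requires ({T}, {F})"
                )
            if ep.label not in class_set:
                raise ValidationError(
                    f"epoch {i} label {ep.label} not in class set {sorted(class_set)}"
                )
            key = (ep.subject_id, ep.session_idx, ep.block_idx, ep.trial_idx)
            if key in seen:
                raise ValidationError(f"duplicate epoch identity {key}")
            seen.add(key)

    # -- container protocol --------------------------------------------------
    def __len__(self) -> int:
        return len(self.epochs)

    def __iter__(self):
        return iter(self.epochs)

    def __getitem__(self, idx):
        if isinstance(idx, (int, np.integer)):
            return self.epochs[idx]
        if isinstance(idx, slice):
            return EpochSet(self.epochs[idx], self.design)
        return EpochSet([self.epochs[i] for i in np.asarray(idx)], self.design)

    def subset(self, indices: Iterable[int]) -> "EpochSet":
        return self[list(indices)]

    # -- array views ---------------------------------------------------------
    @property
    def X(self) -> np.ndarray:
        """Stacked epoch data, [n x T x F]."""
        if not self.epochs:
            return np.zeros((0, self.design.n_timesteps, self.design.n_features), np.float32)
        return np.stack([ep.data for ep in self.epochs])

    @property
    def labels(self) -> np.ndarray:
        return np.asarray([ep.label for ep in self.epochs], dtype=int)

    @property
    def meta(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch_idx": np.arange(len(self.epochs)),
                "subject_id": [ep.subject_id for ep in self.epochs],
                "session_idx": [ep.session_idx for ep in self.epochs],
                "block_idx": [ep.block_idx for ep in self.epochs],
                "trial_idx": [ep.trial_idx for ep in self.epochs],
                "label": self.labels,
            }
        )

    def domain_keys(self, mode: str = "block") -> list[DomainKey]:
        return [ep.key(mode) for ep in self.epochs]

    @property
    def n_classes(self) -> int:
        return self.design.n_classes


# ---------------------------------------------------------------------------
# on-disk container
# ---------------------------------------------------------------------------

_META_COLUMNS = ["epoch_idx", "subject_id", "session_idx", "block_idx", "trial_idx", "label"]


def save_epochs(epoch_set: EpochSet, path: str | Path) -> None:
    """Write ``epochs.h5`` + ``meta.csv`` + ``design.json`` under ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    X = epoch_set.X.astype(np.float32)
    with h5py.File(path / "epochs.h5", "w") as f:
        f.create_dataset("epochs", data=X)
    epoch_set.meta.to_csv(path / "meta.csv", index=False)
    (path / "design.json").write_text(epoch_set.design.to_json())


def load_epochs(path: str | Path) -> EpochSet:
    """Load a container written by :func:`save_epochs`, validating the schema."""
    path = Path(path)
    for fname in ("epochs.h5", "meta.csv", "design.json"):
        if not (path / fname).exists():
            raise ValidationError(f"missing container file: {path / fname}")
    design = ExperimentDesign.from_json((path / "design.json").read_text())
    with h5py.File(path / "epochs.h5", "r") as f:
        X = np.asarray(f["epochs"], dtype=np.float32)
    meta = pd.read_csv(path / "meta.csv", dtype={"subject_id": str})
    missing = [c for c in _META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValidationError(f"meta.csv missing columns: {missing}")
    if len(meta) != X.shape[0]:
        raise ValidationError(
            f"meta.csv has {len(meta)} rows but epochs.h5 holds {X.shape[0]} epochs"
        )
    epochs = []
    for row in meta.itertuples(index=False):
        idx = int(row.epoch_idx)
        if not 0 <= idx < X.shape[0]:
            raise ValidationError(f"meta row references out-of-range epoch_idx {idx}")
        epochs.append(
            Epoch(
                data=X[idx],
                sampling_rate=design.sampling_rate,
                subject_id=str(row.subject_id),
                session_idx=int(row.session_idx),
                block_idx=int(row.block_idx),
                trial_idx=int(row.trial_idx),
                label=int(row.label),
            )
        )
    return EpochSet(epochs, design)


# ---------------------------------------------------------------------------
# sliding-window epoching
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaskPeriod:
    """An annotated task period inside a continuous recording.

    Windows are cut from ``[onset, onset + duration)`` only, so no epoch can
    cross a block boundary.
    """

    onset_seconds: float
    duration_seconds: float
    label: int
    block_idx: int
    session_idx: int = 0


def slide_windows(
    recording: np.ndarray,
    sampling_rate: float,
    window_seconds: float,
    stride_seconds: float | None,
    trial_annotations: Sequence[TaskPeriod],
    subject_id: str = "S0",
) -> list[Epoch]:
    """Cut sliding windows out of annotated task periods of a recording.

    The default stride equals the window length (non-overlapping windows, the
    convention when the window matches the trial task period).  Windows are
    half-open sample ranges ``[start, start + T)``; a window that would extend
    past its task period is not emitted.
    """
    recording = np.asarray(recording)
    if recording.ndim != 2:
        raise ValidationError("recording must be [T_total x F]")
    T = int(round(window_seconds * sampling_rate))
    if T < 1:
        raise ValidationError("window must span at least one sample")
    if stride_seconds is None:
        stride_seconds = window_seconds
    stride = int(round(stride_seconds * sampling_rate))
    if stride < 1:
        raise ValidationError("stride must span at least one sample")

    epochs: list[Epoch] = []
    for ann in trial_annotations:
        start0 = int(round(ann.onset_seconds * sampling_rate))
        n_samples = int(round(ann.duration_seconds * sampling_rate))
        if n_samples < T:
            raise ValidationError(
                f"window ({window_seconds}s) longer than task period "
                f"({ann.duration_seconds}s) at block {ann.block_idx}"
            )
        if start0 + n_samples > recording.shape[0]:
            raise ValidationError("annotation extends past end of recording")
        trial = 0
        for start in range(start0, start0 + n_samples - T + 1, stride):
            epochs.append(
                Epoch(
                    data=recording[start : start + T],
                    sampling_rate=sampling_rate,
                    subject_id=subject_id,
                    session_idx=ann.session_idx,
                    block_idx=ann.block_idx,
                    trial_idx=trial,
                    label=ann.label,
                )
            )
            trial += 1
    return epochs
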