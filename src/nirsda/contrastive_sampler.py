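"""Paired mini-batch construction for domain-adaptive training.

Training with a discrepancy penalty needs mini-batches whose two halves come
from *different domains* under the chosen adaptation mode: different blocks
of the same subject's session (block mode), different sessions of the same
subject (session mode), or different subjects (subject mode).  Halves are
matched by class where the class-conditional losses require it.

Partitions are built either from an :class:`~nirsda.core_data.EpochSet` or
from any metadata table with ``subject_id`` / ``session_idx`` / ``block_idx``
/ ``label`` columns, so the sampler also serves estimators that receive raw
arrays plus metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import EpochSet

__all__ = [
    "BatchSpec",
    "DomainPartition",
    "PairedBatch",
    "PairingError",
    "partition_domains",
    "build_paired_batch",
]

_MODES = ("subject", "session", "block")


class PairingError(ValueError):
    """No valid domain pair can be formed under the requested mode."""


@dataclass(frozen=True)
class BatchSpec:
    """Composition of one paired mini-batch."""

    n_domain_pairs: int = 4
    samples_per_class_per_side: int = 4

    def __post_init__(self):
        if self.n_domain_pairs < 1 or self.samples_per_class_per_side < 1:
            raise ValueError("batch spec counts must be >= 1")


def _as_meta(train_set) -> pd.DataFrame:
    if isinstance(train_set, EpochSet):
        return train_set.meta
    meta = pd.DataFrame(train_set)
    required = {"subject_id", "session_idx", "block_idx", "label"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata table missing columns: {sorted(missing)}")
    return meta.reset_index(drop=True)


def _project(meta: pd.DataFrame, mode: str) -> list[tuple]:
    subj = meta["subject_id"].astype(str)
    if mode == "subject":
        return [(s,) for s in subj]
    if mode == "session":
        return list(zip(subj, meta["session_idx"].astype(int)))
    return list(zip(subj, meta["session_idx"].astype(int), meta["block_idx"].astype(int)))


@dataclass
class DomainPartition:
    """Deterministic grouping of epoch indices by projected domain key."""

    mode: str
    meta: pd.DataFrame
    groups: dict[tuple, np.ndarray] = field(default_factory=dict)
    class_indices: dict[tuple, dict[int, np.ndarray]] = field(default_factory=dict)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def valid_pairs(self) -> list[tuple[tuple, tuple]]:
        """All unordered group pairs satisfying the mode's key constraints
        and sharing at least one class."""
        keys = sorted(self.groups)
        pairs = []
        for i, ka in enumerate(keys):
            for kb in keys[i + 1 :]:
                if self.mode == "block":
                    ok = ka[:2] == kb[:2] and ka[2] != kb[2]
                elif self.mode == "session":
                    ok = ka[0] == kb[0] and ka[1] != kb[1]
                else:  # subject
                    ok = ka[0] != kb[0]
                if not ok:
                    continue
                shared = set(self.class_indices[ka]) & set(self.class_indices[kb])
                if shared:
                    pairs.append((ka, kb))
        return pairs


def partition_domains(train_set, mode: str) -> DomainPartition:
    """Group training indices by the mode's domain-key projection.

    ``train_set`` is an :class:`EpochSet` or a metadata table.  Every index
    lands in exactly one group.
    """
    if mode not in _MODES:
        raise ValueError(f"unknown DA mode {mode!r}; choose from {_MODES}")
    meta = _as_meta(train_set)
    if len(meta) == 0:
        raise ValueError("cannot partition an empty epoch set")
    if mode == "block":
        per_session_blocks = meta.groupby(["subject_id", "session_idx"])["block_idx"].nunique()
        if (per_session_blocks < 2).all():
            raise PairingError(
                "no session holds more than one block; block-mode pairing is "
                "impossible — use session mode instead"
            )
    keys = _project(meta, mode)
    groups: dict[tuple, list[int]] = {}
    for i, key in enumerate(keys):
        groups.setdefault(key, []).append(i)
    part = DomainPartition(mode=mode, meta=meta)
    labels = meta["label"].to_numpy()
    for key, idx in groups.items():
        idx = np.asarray(idx)
        part.groups[key] = idx
        part.class_indices[key] = {
            int(c): idx[labels[idx] == c] for c in np.unique(labels[idx])
        }
    return part


@dataclass
class PairedBatch:
    """One training mini-batch of domain pairs.

    ``pairs`` lists, per domain pair, the source/target epoch indices (into
    the partitioned set) selected class-by-class.
    """

    mode: str
    meta: pd.DataFrame
    pairs: list[dict] = field(default_factory=list)

    @property
    def source_indices(self) -> np.ndarray:
        return (
            np.concatenate([p["source"] for p in self.pairs]) if self.pairs else np.array([], int)
        )

    @property
    def target_indices(self) -> np.ndarray:
        return (
            np.concatenate([p["target"] for p in self.pairs]) if self.pairs else np.array([], int)
        )

    @property
    def all_indices(self) -> np.ndarray:
        return np.concatenate([self.source_indices, self.target_indices])

    def satisfies_constraints(self) -> bool:
        """Audit every pair against the mode's key rules."""
        keys = _project(self.meta, self.mode)
        for p in self.pairs:
            ka, kb = p["source_key"], p["target_key"]
            if any(keys[int(i)] != ka for i in p["source"]):
                return False
            if any(keys[int(i)] != kb for i in p["target"]):
                return False
            if self.mode == "block" and not (ka[:2] == kb[:2] and ka[2] != kb[2]):
                return False
            if self.mode == "session" and not (ka[0] == kb[0] and ka[1] != kb[1]):
                return False
            if self.mode == "subject" and not ka[0] != kb[0]:
                return False
        return True


def build_paired_batch(
    partition: DomainPartition,
    batch_spec: BatchSpec = BatchSpec(),
    rng: np.random.Generator | int | None = None,
) -> PairedBatch:
    """Sample a paired mini-batch.

    Domain pairs are drawn uniformly from all valid pairs; within a pair,
    up to ``samples_per_class_per_side`` epochs per shared class are drawn
    per side, without replacement within the batch (classes are balanced up
    to availability).  Fully reproducible from the rng state.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    valid = partition.valid_pairs()
    if not valid:
        subjects = sorted({k[0] for k in partition.groups})
        raise PairingError(
            f"no valid {partition.mode}-mode domain pair with a shared class "
            f"among subjects {subjects}"
        )
    batch = PairedBatch(mode=partition.mode, meta=partition.meta)
    used: set[int] = set()
    pick_ids = rng.integers(0, len(valid), size=batch_spec.n_domain_pairs)
    for pid in pick_ids:
        ka, kb = valid[int(pid)]
        if rng.random() < 0.5:  # randomize which side acts as source
            ka, kb = kb, ka
        shared = sorted(set(partition.class_indices[ka]) & set(partition.class_indices[kb]))
        src: list[int] = []
        tgt: list[int] = []
        for c in shared:
            for pool, out in (
                (partition.class_indices[ka][c], src),
                (partition.class_indices[kb][c], tgt),
            ):
                avail = np.asarray([i for i in pool if i not in used])
                if avail.size == 0:
                    continue
                take = min(batch_spec.samples_per_class_per_side, avail.size)
                chosen = rng.choice(avail, size=take, replace=False)
                out.extend(int(i) for i in chosen)
                used.update(int(i) for i in chosen)
        if src and tgt:
            batch.pairs.append(
                {
                    "source_key": ka,
                    "target_key": kb,
                    "source": np.asarray(src),
                    "target": np.asarray(tgt),
                    "shared_classes": shared,
                }
            )
    if not batch.pairs:
        raise PairingError("sampled domain pairs yielded no usable epochs")
    return batch
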