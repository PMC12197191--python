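"""Evaluation: split scenarios, metrics, shift diagnostics, mask importance.

The split scenarios probe how a classifier degrades as train and test sets
are separated along successively coarser experiment axes:

* **trial** — train/test split over individual epochs (every subject,
  session and block is seen during training);
* **block** — whole blocks held out;
* **session** — one session of every subject held out, the others trained on;
* **subject** — whole subjects held out (the deployment-relevant setting).

The Wasserstein diagnostic quantifies the train/test feature-distribution
shift each scenario induces: the mean exact optimal-transport cost between
seeded mini-batches of encoder features.  The channel-masking scan measures
spatial importance by zeroing groups of optode channels and flagging the
groups whose loss of accuracy falls below the 95% confidence band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from sklearn.metrics import f1_score, precision_recall_fscore_support

from .core_data import EpochSet

__all__ = [
    "SplitSpec",
    "MetricsReport",
    "MaskSpec",
    "MaskScanResult",
    "ZeroVarianceError",
    "make_split",
    "evaluate_metrics",
    "wasserstein_diagnostic",
    "paired_ttest",
    "make_channel_masks",
    "channel_mask_scan",
    "cross_validate",
]

_SCENARIOS = ("trial", "block", "session", "subject")


class ZeroVarianceError(ValueError):
    """Paired differences have zero variance; the t statistic is undefined."""


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    """How to carve train/validation/test folds.

    Unit counts default to roughly 70/20/10 of the scenario's atomic units
    (subjects, sessions, blocks or trials), each at least one; e.g. 26
    subjects over 10 folds gives 18 train / 5 validation / 3 test subjects.
    """

    scenario: str
    k_folds: int = 10
    n_train_units: int | None = None
    n_val_units: int | None = None
    n_test_units: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in _SCENARIOS:
            raise ValueError(f"scenario must be one of {_SCENARIOS}")
        if self.k_folds < 1:
            raise ValueError("k_folds must be >= 1")

    def resolve_counts(self, n_units: int) -> tuple[int, int, int]:
        n_test = self.n_test_units if self.n_test_units is not None else max(
            1, int(round(0.1 * n_units))
        )
        n_val = self.n_val_units if self.n_val_units is not None else max(
            1, int(round(0.2 * n_units))
        )
        n_train = (
            self.n_train_units if self.n_train_units is not None else n_units - n_val - n_test
        )
        if n_train < 1 or n_train + n_val + n_test > n_units:
            raise ValueError(
                f"fold counts ({n_train}/{n_val}/{n_test}) incompatible with {n_units} units"
            )
        return n_train, n_val, n_test


def _unit_keys(epoch_set: EpochSet, scenario: str) -> list[tuple]:
    out = []
    for ep in epoch_set:
        if scenario == "trial":
            out.append((ep.subject_id, ep.session_idx, ep.block_idx, ep.trial_idx))
        elif scenario == "block":
            out.append((ep.subject_id, ep.session_idx, ep.block_idx))
        elif scenario == "session":
            out.append((ep.subject_id, ep.session_idx))
        else:
            out.append((ep.subject_id,))
    return out


def make_split(
    epoch_set: EpochSet, spec: SplitSpec, fold: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic (train, val, test) epoch indices for one fold.

    The splitting unit is atomic — no epoch of a test unit appears in train
    — and the test units rotate through a seeded unit permutation as ``fold``
    advances.  The session scenario follows the hold-one-session-out
    protocol: the held-out session index rotates per fold, training keeps
    the remaining sessions, and validation takes one kept session from a
    20% subset of subjects.
    """
    if not 0 <= fold < spec.k_folds:
        raise ValueError(f"fold must be in [0, {spec.k_folds})")
    keys = _unit_keys(epoch_set, spec.scenario)

    if spec.scenario == "session":
        return _session_split(epoch_set, spec, fold, keys)

    units = sorted(set(keys))
    n_units = len(units)
    n_train, n_val, n_test = spec.resolve_counts(n_units)
    rng = np.random.default_rng(spec.seed)
    perm = [units[i] for i in rng.permutation(n_units)]
    shift = int(round(fold * n_units / spec.k_folds))
    rotated = perm[shift:] + perm[:shift]
    test_u = set(rotated[:n_test])
    val_u = set(rotated[n_test : n_test + n_val])
    train_u = set(rotated[n_test + n_val : n_test + n_val + n_train])
    tr = np.asarray([i for i, k in enumerate(keys) if k in train_u], dtype=int)
    va = np.asarray([i for i, k in enumerate(keys) if k in val_u], dtype=int)
    te = np.asarray([i for i, k in enumerate(keys) if k in test_u], dtype=int)
    if min(len(tr), len(va), len(te)) == 0:
        raise ValueError("a split side received no epochs; too few units")
    return tr, va, te


def _session_split(epoch_set, spec, fold, keys):
    sessions = sorted({k[1] for k in keys})
    if len(sessions) < 2:
        raise ValueError("session scenario needs at least two sessions per subject")
    held = sessions[fold % len(sessions)]
    subjects = sorted({k[0] for k in keys})
    rng = np.random.default_rng(spec.seed + fold)
    n_val_subj = max(1, int(round(0.2 * len(subjects))))
    n_val_subj = min(n_val_subj, len(subjects) - 1) if len(subjects) > 1 else 1
    val_subjects = set(str(s) for s in rng.permutation(subjects)[:n_val_subj])
    kept = [s for s in sessions if s != held]
    val_session = kept[fold % len(kept)]
    tr, va, te = [], [], []
    for i, (subj, sess) in enumerate(keys):
        if sess == held:
            te.append(i)
        elif subj in val_subjects and sess == val_session:
            va.append(i)
        else:
            tr.append(i)
    return np.asarray(tr, int), np.asarray(va, int), np.asarray(te, int)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """Accuracy, macro F1, and per-class precision/recall on a test split."""

    accuracy: float
    macro_f1: float
    per_class: dict[int, dict[str, float]]
    n_test: int
    absent_classes: tuple[int, ...] = ()


def evaluate_metrics(predictions, labels) -> MetricsReport:
    """Standard accuracy + macro F1 (unweighted mean of per-class F1)."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape != labels.shape or len(labels) == 0:
        raise ValueError("predictions and labels must be aligned and nonempty")
    classes = np.unique(np.concatenate([labels, predictions]))
    prec, rec, f1, support = precision_recall_fscore_support(
        labels, predictions, labels=classes, zero_division=0
    )
    per_class = {
        int(c): {"precision": float(p), "recall": float(r), "f1": float(f), "support": int(s)}
        for c, p, r, f, s in zip(classes, prec, rec, f1, support)
    }
    absent = tuple(int(c) for c, s in zip(classes, support) if s == 0)
    return MetricsReport(
        accuracy=float((predictions == labels).mean()),
        macro_f1=float(f1_score(labels, predictions, labels=classes, average="macro",
                                zero_division=0)),
        per_class=per_class,
        n_test=len(labels),
        absent_classes=absent,
    )


# ---------------------------------------------------------------------------
# distribution-shift diagnostic
# ---------------------------------------------------------------------------

def wasserstein_diagnostic(
    train_feats,
    test_feats,
    n_pairs: int = 50,
    batch_size: int = 64,
    seed: int = 0,
    standardize: bool = True,
) -> float:
    """Mean exact optimal-transport cost between seeded mini-batch pairs.

    Each pair draws ``batch_size`` feature rows without replacement from each
    side; with uniform weights and equal sizes the exact Euclidean OT cost is
    an assignment problem.  Larger values mean larger train/test feature
    shift.

    ``standardize`` scales both sides by the per-dimension standard deviation
    of the training features, so diagnostics from differently-scaled encoders
    are comparable; near-constant dimensions keep unit scale.
    """
    A = np.asarray(getattr(train_feats, "features", train_feats), dtype=float)
    B = np.asarray(getattr(test_feats, "features", test_feats), dtype=float)
    if A.shape[0] < batch_size or B.shape[0] < batch_size:
        raise ValueError(
            f"batch_size {batch_size} exceeds available samples ({A.shape[0]}, {B.shape[0]})"
        )
    if standardize:
        sd = A.std(axis=0)
        sd = np.where(sd > 1e-12, sd, 1.0)
        A = A / sd
        B = B / sd
    rng = np.random.default_rng(seed)
    costs = []
    for _ in range(n_pairs):
        ia = rng.choice(A.shape[0], size=batch_size, replace=False)
        ib = rng.choice(B.shape[0], size=batch_size, replace=False)
        C = cdist(A[ia], B[ib])
        row, col = linear_sum_assignment(C)
        costs.append(C[row, col].mean())
    return float(np.mean(costs))


def paired_ttest(scores_a, scores_b) -> tuple[float, float]:
    """Classical paired t on fold-wise score differences ``a - b`` (df = k-1).

    Raises :class:`ZeroVarianceError` when all differences are identical.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two aligned score vectors of length >= 2")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise ZeroVarianceError("all paired differences are identical; t undefined")
    t = d.mean() / (sd / np.sqrt(len(d)))
    p = 2.0 * sp_stats.t.sf(abs(t), df=len(d) - 1)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# channel-mask importance scan
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MaskSpec:
    """A group of spatial channels blanked together during the scan."""

    mask_id: int
    channels: tuple[int, ...]


@dataclass
class MaskScanResult:
    """Per-mask accuracies with the confidence band and critical masks."""

    unmasked_accuracy: float
    mask_accuracies: dict[int, float]
    mean_masked_accuracy: float
    ci_lower: float
    ci_upper: float
    critical_masks: tuple[int, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mask_id": list(self.mask_accuracies),
                "accuracy": list(self.mask_accuracies.values()),
                "critical": [m in self.critical_masks for m in self.mask_accuracies],
            }
        )


def make_channel_masks(n_spatial_channels: int, channels_per_mask: int = 4) -> list[MaskSpec]:
    """Disjoint contiguous channel groups (the last may be smaller)."""
    masks = []
    for mid, start in enumerate(range(0, n_spatial_channels, channels_per_mask)):
        chans = tuple(range(start, min(start + channels_per_mask, n_spatial_channels)))
        masks.append(MaskSpec(mask_id=mid, channels=chans))
    return masks


def channel_mask_scan(
    model,
    test_set: EpochSet,
    masks: Sequence[MaskSpec],
    confidence: float = 0.95,
) -> MaskScanResult:
    """Blank one channel group at a time and measure the accuracy drop.

    All feature columns of a masked spatial channel are set to zero.  The
    confidence band is the t-interval on the mean of the per-mask accuracies;
    masks whose accuracy falls below its lower bound are flagged critical.
    """
    design = test_set.design
    seen: set[int] = set()
    for m in masks:
        bad = [c for c in m.channels if not 0 <= c < design.n_spatial_channels]
        if bad:
            raise ValueError(f"mask {m.mask_id} has invalid channels {bad}")
        overlap = seen & set(m.channels)
        if overlap:
            raise ValueError(f"mask {m.mask_id} overlaps earlier masks on channels {sorted(overlap)}")
        seen |= set(m.channels)

    X = test_set.X.astype(np.float64)
    y = test_set.labels
    unmasked = float((model.predict(X) == y).mean())
    accs: dict[int, float] = {}
    for m in masks:
        Xm = X.copy()
        for ch in m.channels:
            Xm[:, :, design.feature_columns(ch)] = 0.0
        accs[m.mask_id] = float((model.predict(Xm) == y).mean())

    vals = np.asarray(list(accs.values()))
    mean = float(vals.mean())
    if len(vals) > 1 and vals.std(ddof=1) > 0:
        half = sp_stats.t.ppf(0.5 + confidence / 2, df=len(vals) - 1) * vals.std(ddof=1) / np.sqrt(
            len(vals)
        )
    else:
        half = 0.0
    lo, hi = mean - half, mean + half
    critical = tuple(mid for mid, a in accs.items() if a < lo)
    return MaskScanResult(
        unmasked_accuracy=unmasked,
        mask_accuracies=accs,
        mean_masked_accuracy=mean,
        ci_lower=float(lo),
        ci_upper=float(hi),
        critical_masks=critical,
    )


# ---------------------------------------------------------------------------
# cross-validation orchestration
# ---------------------------------------------------------------------------

def cross_validate(
    epoch_set: EpochSet,
    spec: SplitSpec,
    estimator_factory,
    folds: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Train/evaluate one estimator per fold; returns per-fold metrics.

    ``estimator_factory()`` must return an unfitted classifier with the
    ``fit(X, y, meta, X_val, y_val, meta_val)`` / ``predict`` interface.
    Leakage is asserted per fold: train/val/test unit sets are disjoint.
    """
    rows = []
    fold_ids = list(folds) if folds is not None else list(range(spec.k_folds))
    keys = _unit_keys(epoch_set, spec.scenario)
    for fold in fold_ids:
        tr, va, te = make_split(epoch_set, spec, fold)
        units = lambda idx: {keys[i] for i in idx}  # noqa: E731
        assert not units(tr) & units(te) and not units(va) & units(te), "unit leakage"
        train, val, test = epoch_set[tr], epoch_set[va], epoch_set[te]
        clf = estimator_factory()
        clf.fit(
            train.X, train.labels, meta=train.meta,
            X_val=val.X, y_val=val.labels, meta_val=val.meta,
        )
        report = evaluate_metrics(clf.predict(test.X), test.labels)
        rows.append(
            {
                "fold": fold,
                "accuracy": report.accuracy,
                "macro_f1": report.macro_f1,
                "n_test": report.n_test,
                "_model": clf,
                "_test_idx": te,
            }
        )
    return pd.DataFrame(rows)
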