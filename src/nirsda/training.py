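"""Training: the MixerClassifier estimator, Adam loop, and grid search.

:class:`MixerClassifier` is a scikit-learn style classifier.  ``fit`` takes
epochs ``X [n x T x F]``, labels ``y`` and (for domain adaptation) a metadata
table with ``subject_id`` / ``session_idx`` / ``block_idx`` columns.  The
objective is ``l_ce + alpha * (D_cdd + D_bwise)``: plain cross-entropy when
``da_mode="none"`` or ``alpha=0``, otherwise cross-entropy over paired
mini-batches plus the contrastive domain discrepancy between the two batch
halves and the mean same-class discrepancy within each domain pair.  Under
``da_mode="subject"`` there are no within-subject pairs, so the block-wise
term is identically zero and only CDD aligns features.

Optimization is Adam with default moments; training stops when the
validation objective has not improved for ``patience`` consecutive epochs,
and the best-validation parameters are restored.  Everything is seeded, so a
fit is bit-reproducible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import f1_score

from . import autodiff as ad
from .contrastive_sampler import (
    BatchSpec,
    PairingError,
    build_paired_batch,
    partition_domains,
)
from .core_data import EpochSet
from .da_losses import (
    KernelSpec,
    ObjectiveConfig,
    cdd,
    class_aware_discrepancy,
    mmd,
    total_objective,
)
from .models import (
    FeatureBatch,
    MixerConfig,
    init_params,
    mixer_forward,
)

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "MixerClassifier",
    "train_model",
    "grid_search",
]


def _mean_terms(terms):
    if not terms:
        return None
    acc = terms[0]
    for t in terms[1:]:
        acc = ad.add(acc, t)
    return ad.div(acc, float(len(terms)))


# ---------------------------------------------------------------------------
# configuration / history records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol for one training run."""

    learning_rate: float = 1e-3
    dropout_ratio: float = 0.0
    alpha: float = 1.0
    da_mode: str = "none"
    batch_spec: BatchSpec = field(default_factory=BatchSpec)
    batch_size: int = 32
    patience_epochs: int = 50
    max_epochs: int = 500
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.patience_epochs < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class TrainHistory:
    """Per-epoch loss components and validation metrics."""

    records: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    stop_reason: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class MixerClassifier(ClassifierMixin, BaseEstimator):
    """MLP-Mixer workload classifier with optional block-wise domain adaptation.

    Parameters
    ----------
    hidden_dim, n_layers, temporal_hidden, channel_hidden, n_probe_groups:
        Architecture widths (token width C, mixer layers N, temporal / channel
        MLP hidden widths, probe groups whose features are concatenated per
        timestep).
    dropout_ratio:
        Dropout applied to each MLP-block output during training.
    learning_rate, batch_size, steps_per_epoch, max_epochs, patience:
        Adam step size and loop protocol; ``steps_per_epoch=None`` derives
        the step count from the training-set size.
    alpha, da_mode, n_domain_pairs, samples_per_class:
        Discrepancy-penalty weight, the domain granularity (``none`` /
        ``subject`` / ``session`` / ``block``) and the paired mini-batch
        composition.
    kernel_bandwidths:
        Explicit Gaussian kernel sigmas, or ``None`` for the per-batch median
        heuristic with multipliers (0.5, 1, 2).
    validation_fraction:
        Fraction of training units (subjects when metadata is given) carved
        out for early stopping when no validation split is supplied.
    random_state:
        Seeds initialization, batch order, dropout and validation pairing.

    Attributes
    ----------
    classes_ : ndarray of distinct labels.
    params_ : dict of fitted parameter arrays.
    config_ : the resolved :class:`MixerConfig`.
    history_ : :class:`TrainHistory` of the fit.
    """

    def __init__(
        self,
        hidden_dim: int = 16,
        n_layers: int = 4,
        temporal_hidden: int = 64,
        channel_hidden: int = 32,
        n_probe_groups: int = 1,
        dropout_ratio: float = 0.0,
        learning_rate: float = 1e-3,
        alpha: float = 0.0,
        da_mode: str = "none",
        n_domain_pairs: int = 4,
        samples_per_class: int = 4,
        batch_size: int = 32,
        steps_per_epoch: int | None = None,
        max_epochs: int = 500,
        patience: int = 50,
        validation_fraction: float = 0.15,
        kernel_bandwidths: Sequence[float] | None = None,
        cross_term: str = "standard",
        cdd_scope: str = "within_pair",
        selection: str = "loss",
        random_state: int | None = None,
        verbose: int = 0,
    ):
        self.hidden_dim = hidden_dim
        self.n_layers = n_layers
        self.temporal_hidden = temporal_hidden
        self.channel_hidden = channel_hidden
        self.n_probe_groups = n_probe_groups
        self.dropout_ratio = dropout_ratio
        self.learning_rate = learning_rate
        self.alpha = alpha
        self.da_mode = da_mode
        self.n_domain_pairs = n_domain_pairs
        self.samples_per_class = samples_per_class
        self.batch_size = batch_size
        self.steps_per_epoch = steps_per_epoch
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.kernel_bandwidths = kernel_bandwidths
        self.cross_term = cross_term
        self.cdd_scope = cdd_scope
        self.selection = selection
        self.random_state = random_state
        self.verbose = verbose

    # -- helpers -----------------------------------------------------------
    def _kernel_spec(self) -> KernelSpec:
        if self.kernel_bandwidths is None:
            return KernelSpec()
        return KernelSpec(bandwidths=tuple(self.kernel_bandwidths))

    def _check_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3:
            raise ValueError(f"X must be [n x T x F] epochs, got ndim={X.ndim}")
        if not np.isfinite(X).all():
            raise ValueError("X contains non-finite values")
        return X

    def _encode(self, y) -> np.ndarray:
        y = np.asarray(y)
        return np.searchsorted(self.classes_, y)

    def _split_validation(self, X, y, meta, rng):
        """Carve a held-out validation split: by subject when metadata is
        available (no subject leaks across the split), else by sample."""
        n = X.shape[0]
        frac = self.validation_fraction
        if meta is not None:
            subjects = np.asarray(sorted(meta["subject_id"].astype(str).unique()))
            if len(subjects) >= 2 and frac > 0:
                n_val = max(1, int(round(frac * len(subjects))))
                n_val = min(n_val, len(subjects) - 1)
                val_subj = set(rng.permutation(subjects)[:n_val])
                is_val = meta["subject_id"].astype(str).isin(val_subj).to_numpy()
                tr, va = np.flatnonzero(~is_val), np.flatnonzero(is_val)
                return tr, va
        if frac > 0 and n >= 4:
            perm = rng.permutation(n)
            n_val = max(1, int(round(frac * n)))
            return perm[n_val:], perm[:n_val]
        idx = np.arange(n)
        return idx, idx  # degenerate: validate on train

    # -- forward -------------------------------------------------------------
    def _features(self, X, params, dropout_rng=None):
        return mixer_forward(X, self.config_, params, mode="features", dropout_rng=dropout_rng)

    @staticmethod
    def _head(feats, params):
        return ad.add(ad.matmul(feats, params["head.w"]), params["head.b"])

    # -- loss ---------------------------------------------------------------
    def _da_terms(self, feats, labels_enc, batch, kernel):
        """Discrepancy penalties over one paired mini-batch.

        The contrastive term is evaluated within each domain pair (the two
        halves share a subject in block/session mode) and averaged across
        pairs; when a pair carries a single shared class its contribution
        degenerates to the intra-class alignment term.  With
        ``cdd_scope="pooled"`` the halves of all pairs are pooled into one
        source/target pair instead (cross-subject variant).  The block-wise
        term is the mean same-class MMD within each pair.
        """
        n_src = len(batch.source_indices)
        # one batch-level median-heuristic resolution per step: every term in
        # this batch shares the same kernel bandwidths (stable, and avoids a
        # shrinking-bandwidth feedback on aligned class subsets)
        fv = ad.value_of(feats)
        kernel = KernelSpec(bandwidths=kernel.resolve(fv, fv))
        cdd_terms = []
        bwise_terms = []
        offset_s = 0
        offset_t = n_src
        for pair in batch.pairs:
            ns, nt = len(pair["source"]), len(pair["target"])
            ys = labels_enc[offset_s : offset_s + ns]
            yt = labels_enc[offset_t : offset_t + nt]
            rows_s = offset_s + np.arange(ns)
            rows_t = offset_t + np.arange(nt)
            if self.cdd_scope == "within_pair":
                fb_s = FeatureBatch(ad.take(feats, rows_s), ys)
                fb_t = FeatureBatch(ad.take(feats, rows_t), yt)
                shared = np.intersect1d(np.unique(ys), np.unique(yt))
                if len(shared) >= 2:
                    term, _ = cdd(fb_s, fb_t, spec=kernel)
                    cdd_terms.append(term)
                elif len(shared) == 1:
                    c = int(shared[0])
                    term, _ = class_aware_discrepancy(fb_s, fb_t, c, c, spec=kernel)
                    cdd_terms.append(term)
            if self.da_mode in ("block", "session"):
                for c in np.intersect1d(np.unique(ys), np.unique(yt)):
                    src_rows = offset_s + np.flatnonzero(ys == c)
                    tgt_rows = offset_t + np.flatnonzero(yt == c)
                    bwise_terms.append(
                        mmd(
                            ad.take(feats, src_rows),
                            ad.take(feats, tgt_rows),
                            kernel,
                            cross_term=self.cross_term,
                        )
                    )
            offset_s += ns
            offset_t += nt
        if self.cdd_scope == "pooled":
            fb_s = FeatureBatch(ad.take(feats, slice(0, n_src)), labels_enc[:n_src])
            fb_t = FeatureBatch(ad.take(feats, slice(n_src, None)), labels_enc[n_src:])
            try:
                term, _ = cdd(fb_s, fb_t, spec=kernel)
                cdd_terms = [term]
            except ValueError:
                cdd_terms = []
        d_cdd = _mean_terms(cdd_terms)
        d_bwise = _mean_terms(bwise_terms)
        return d_cdd, d_bwise

    # -- fit ------------------------------------------------------------------
    def fit(self, X, y, meta: pd.DataFrame | None = None, X_val=None, y_val=None,
            meta_val: pd.DataFrame | None = None):
        X = self._check_X(X)
        y = np.asarray(y)
        if len(y) != X.shape[0]:
            raise ValueError("X and y length mismatch")
        if self.da_mode not in ("none", "subject", "session", "block"):
            raise ValueError(f"unknown da_mode {self.da_mode!r}")
        if self.cdd_scope not in ("within_pair", "pooled"):
            raise ValueError("cdd_scope must be 'within_pair' or 'pooled'")
        if self.da_mode != "none" and meta is None:
            raise ValueError("domain adaptation requires a metadata table")

        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        y_enc = self._encode(y)
        n, T, F = X.shape
        if F % self.n_probe_groups:
            raise ValueError("feature count not divisible by n_probe_groups")
        self.config_ = MixerConfig(
            T=T,
            D=F // self.n_probe_groups,
            n_probe_groups=self.n_probe_groups,
            C=self.hidden_dim,
            N=self.n_layers,
            T_h=self.temporal_hidden,
            C_h=self.channel_hidden,
            n_classes=len(self.classes_),
            dropout_ratio=self.dropout_ratio,
        )
        self.n_features_in_ = F

        master = np.random.default_rng(self.random_state)
        init_rng, split_rng, batch_rng, drop_rng, valpair_rng = master.spawn(5)

        # validation split
        if X_val is not None:
            X_val = self._check_X(X_val)
            yv_enc = self._encode(np.asarray(y_val))
            Xtr, ytr, meta_tr = X, y_enc, meta
            mv = meta_val
        else:
            tr, va = self._split_validation(X, y, meta, split_rng)
            Xtr, ytr = X[tr], y_enc[tr]
            X_val, yv_enc = X[va], y_enc[va]
            meta_tr = meta.iloc[tr].reset_index(drop=True) if meta is not None else None
            mv = meta.iloc[va].reset_index(drop=True) if meta is not None else None

        kernel = self._kernel_spec()
        objective = ObjectiveConfig(alpha=self.alpha, kernel=kernel, da_mode=self.da_mode)
        spec = BatchSpec(self.n_domain_pairs, self.samples_per_class)

        partition = None
        if self.da_mode != "none":
            table = meta_tr.copy()
            table["label"] = ytr
            partition = partition_domains(table, self.da_mode)

        # fixed validation pairing for the evaluation objective
        val_batch = None
        if self.da_mode != "none" and self.alpha > 0 and mv is not None:
            try:
                vt = mv.copy()
                vt["label"] = yv_enc
                val_batch = build_paired_batch(
                    partition_domains(vt, self.da_mode), spec, valpair_rng
                )
            except (PairingError, ValueError):
                val_batch = None  # fall back to plain CE on validation

        params = init_params(self.config_, init_rng)
        adam_m = {k: np.zeros_like(v) for k, v in params.items()}
        adam_v = {k: np.zeros_like(v) for k, v in params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t_step = 0

        n_train = Xtr.shape[0]
        if self.steps_per_epoch is not None:
            steps = self.steps_per_epoch
        elif self.da_mode != "none":
            nominal = 2 * self.n_domain_pairs * self.samples_per_class
            steps = max(1, n_train // max(nominal, 1))
        else:
            steps = max(1, int(np.ceil(n_train / self.batch_size)))

        if self.selection not in ("loss", "accuracy"):
            raise ValueError("selection must be 'loss' or 'accuracy'")
        history = TrainHistory()
        best_metric = np.inf if self.selection == "loss" else -np.inf
        best_params = {k: v.copy() for k, v in params.items()}
        best_epoch = 0
        use_da = self.da_mode != "none"

        for epoch in range(1, self.max_epochs + 1):
            ep_losses = []
            plain_order = batch_rng.permutation(n_train) if not use_da else None
            for step in range(steps):
                if use_da:
                    batch = build_paired_batch(partition, spec, batch_rng)
                    idx = batch.all_indices
                else:
                    lo = step * self.batch_size
                    idx = plain_order[lo : lo + self.batch_size]
                    if idx.size == 0:
                        continue
                xb, yb = Xtr[idx], ytr[idx]
                tparams = {k: ad.Tensor(v, requires_grad=True) for k, v in params.items()}
                feats = self._features(
                    xb, tparams, dropout_rng=drop_rng if self.dropout_ratio > 0 else None
                )
                logits = self._head(feats, tparams)
                d_cdd = d_bwise = None
                if use_da and self.alpha > 0:
                    d_cdd, d_bwise = self._da_terms(feats, yb, batch, kernel)
                loss = total_objective(logits, yb, d_cdd, d_bwise, objective)
                total = loss.total
                if not np.isfinite(ad.value_of(total)):
                    raise RuntimeError(
                        f"training diverged at epoch {epoch}: {loss.as_floats()}"
                    )
                total.backward()
                t_step += 1
                for k in params:
                    g = tparams[k].grad
                    if g is None:
                        continue
                    adam_m[k] = beta1 * adam_m[k] + (1 - beta1) * g
                    adam_v[k] = beta2 * adam_v[k] + (1 - beta2) * g * g
                    mhat = adam_m[k] / (1 - beta1**t_step)
                    vhat = adam_v[k] / (1 - beta2**t_step)
                    params[k] = params[k] - self.learning_rate * mhat / (np.sqrt(vhat) + eps)
                ep_losses.append(loss.as_floats())

            val_rec = self._validation_pass(
                X_val, yv_enc, params, objective, kernel, val_batch
            )
            rec = {
                "epoch": epoch,
                **{f"train_{k}": np.mean([d[k] for d in ep_losses]) for k in ep_losses[0]},
                **val_rec,
            }
            history.records.append(rec)
            if self.verbose:
                print(
                    f"epoch {epoch}: train {rec['train_total']:.4f} "
                    f"val {rec['val_total']:.4f} acc {rec['val_accuracy']:.3f}"
                )
            if self.selection == "loss":
                improved = rec["val_total"] < best_metric - 1e-12
                metric = rec["val_total"]
            else:
                improved = rec["val_accuracy"] > best_metric + 1e-12
                metric = rec["val_accuracy"]
            if improved:
                best_metric = metric
                best_epoch = epoch
                best_params = {k: v.copy() for k, v in params.items()}
            if epoch - best_epoch >= self.patience:
                history.stop_reason = f"no improvement for {self.patience} epochs"
                break
        else:
            history.stop_reason = "max_epochs reached"

        history.best_epoch = best_epoch
        self.params_ = best_params
        self.history_ = history
        return self

    def _validation_pass(self, X_val, yv_enc, params, objective, kernel, val_batch):
        feats = self._features(X_val, params)
        logits = ad.value_of(self._head(feats, params))
        d_cdd = d_bwise = None
        if val_batch is not None and self.alpha > 0:
            fv = ad.value_of(feats)
            n_src = len(val_batch.source_indices)
            reorder = val_batch.all_indices
            d_cdd, d_bwise = self._da_terms(
                fv[reorder], yv_enc[reorder], val_batch, kernel
            )
        loss = total_objective(logits, yv_enc, d_cdd, d_bwise, objective)
        pred = logits.argmax(axis=1)
        return {
            "val_total": float(ad.value_of(loss.total)),
            "val_cross_entropy": float(ad.value_of(loss.cross_entropy)),
            "val_d_cdd": float(ad.value_of(loss.d_cdd)),
            "val_d_bwise": float(ad.value_of(loss.d_bwise)),
            "val_accuracy": float((pred == yv_enc).mean()),
            "val_f1": float(f1_score(yv_enc, pred, average="macro", zero_division=0)),
        }

    # -- inference -------------------------------------------------------------
    def decision_function(self, X) -> np.ndarray:
        X = self._check_X(X)
        feats = self._features(X, self.params_)
        return ad.value_of(self._head(feats, self.params_))

    def predict_proba(self, X) -> np.ndarray:
        logits = self.decision_function(X)
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.decision_function(X).argmax(axis=1)]

    def transform(self, X) -> np.ndarray:
        """Pooled pre-head features (the representation the DA losses align)."""
        X = self._check_X(X)
        return ad.value_of(self._features(X, self.params_))


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def _estimator_from(mixer_config: MixerConfig, config: TrainConfig, **overrides) -> MixerClassifier:
    kwargs = dict(
        hidden_dim=mixer_config.C,
        n_layers=mixer_config.N,
        temporal_hidden=mixer_config.T_h,
        channel_hidden=mixer_config.C_h,
        n_probe_groups=mixer_config.n_probe_groups,
        dropout_ratio=config.dropout_ratio,
        learning_rate=config.learning_rate,
        alpha=config.alpha,
        da_mode=config.da_mode,
        n_domain_pairs=config.batch_spec.n_domain_pairs,
        samples_per_class=config.batch_spec.samples_per_class_per_side,
        batch_size=config.batch_size,
        max_epochs=config.max_epochs,
        patience=config.patience_epochs,
        random_state=config.seed,
    )
    kwargs.update(overrides)
    return MixerClassifier(**kwargs)


def train_model(
    mixer_config: MixerConfig,
    train_set: EpochSet,
    val_set: EpochSet,
    config: TrainConfig,
) -> tuple[dict, TrainHistory]:
    """Fit a mixer on epoch sets; returns (fitted params, history).

    Thin wrapper over :class:`MixerClassifier` for callers holding
    :class:`EpochSet` objects.
    """
    if len(val_set) == 0:
        raise ValueError("validation set must be nonempty")
    clf = _estimator_from(mixer_config, config)
    clf.fit(
        train_set.X,
        train_set.labels,
        meta=train_set.meta,
        X_val=val_set.X,
        y_val=val_set.labels,
        meta_val=val_set.meta,
    )
    return clf.params_, clf.history_


def grid_search(
    base: MixerClassifier | Mapping,
    folds: Sequence[tuple[EpochSet, EpochSet]],
    grids: Mapping[str, Sequence],
) -> tuple[dict, pd.DataFrame]:
    """Exhaustive hyper-parameter search over ``grids``.

    ``grids`` maps estimator parameter names (``learning_rate``,
    ``dropout_ratio``, ``alpha``) to candidate values; every combination is
    trained on each (train, validation) fold and scored by validation
    accuracy.  Returns the winning parameter dict and the full results table.
    Ties break toward lower learning rate, then lower dropout, then lower
    alpha.
    """
    if not grids or any(len(v) == 0 for v in grids.values()):
        raise ValueError("grids must be nonempty")
    base_params = dict(base.get_params()) if isinstance(base, MixerClassifier) else dict(base)
    names = list(grids)
    rows = []
    for combo in itertools.product(*(grids[k] for k in names)):
        setting = dict(zip(names, combo))
        accs = []
        for train_set, val_set in folds:
            clf = MixerClassifier(**{**base_params, **setting})
            clf.fit(
                train_set.X,
                train_set.labels,
                meta=train_set.meta,
                X_val=val_set.X,
                y_val=val_set.labels,
                meta_val=val_set.meta,
            )
            accs.append(clf.score(val_set.X, val_set.labels))
        rows.append({**setting, "mean_accuracy": float(np.mean(accs))})
    table = pd.DataFrame(rows)
    order = ["mean_accuracy"] + [k for k in ("learning_rate", "dropout_ratio", "alpha") if k in names]
    ranked = table.sort_values(
        order, ascending=[False] + [True] * (len(order) - 1), kind="mergesort"
    )
    best = {k: ranked.iloc[0][k] for k in names}
    return best, table
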