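"""Reproducible study recipes built from the library pieces.

These are the package's standard experiments on synthetic corpora:

* :func:`da_benchmark` — held-out-subject accuracy of cross-entropy-only
  training versus domain-adaptive training, over several seeds;
* :func:`split_scenario_benchmark` — accuracy and Wasserstein shift
  diagnostic under the trial / block / session / subject split scenarios;
* :func:`mask_recovery_benchmark` — whether the channel-masking scan
  recovers a planted set of informative channels;
* :func:`da_ablation_study` — the four-way CE / subject / session / block
  comparison table with per-fold deltas.

Problem sizes default to a scaled-down benchmark (a 12-subject three-session
block-design corpus, ~25k-parameter mixers, a few dozen training epochs)
chosen so a full study runs in minutes on one CPU while preserving the
qualitative phenomena; see docs/methods.md.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_data import EpochSet, ExperimentDesign, tuberlin_design
from .evaluation import (
    SplitSpec,
    cross_validate,
    channel_mask_scan,
    evaluate_metrics,
    make_channel_masks,
    make_split,
    wasserstein_diagnostic,
)
from .synthetic_fnirs import GeneratorConfig, generate_dataset
from .training import MixerClassifier

__all__ = [
    "benchmark_corpus",
    "benchmark_estimator",
    "da_benchmark",
    "split_scenario_benchmark",
    "mask_recovery_benchmark",
    "da_ablation_study",
]


def benchmark_corpus(seed: int = 1, n_subjects: int = 12) -> EpochSet:
    """The standard synthetic benchmark: a three-session block-design n-back
    corpus with the generator's default subject/session/block shift."""
    return generate_dataset(GeneratorConfig(design=tuberlin_design(n_subjects), seed=seed))


def benchmark_estimator(
    da_mode: str = "none",
    alpha: float = 0.0,
    seed: int = 0,
    **overrides,
) -> MixerClassifier:
    """The benchmark training protocol (a ~25k-parameter mixer, short runs)."""
    kwargs = dict(
        hidden_dim=16,
        n_layers=4,
        da_mode=da_mode,
        alpha=alpha,
        n_domain_pairs=8,
        samples_per_class=4,
        batch_size=64,
        steps_per_epoch=20,
        max_epochs=60,
        patience=20,
        selection="accuracy",
        random_state=seed,
    )
    kwargs.update(overrides)
    return MixerClassifier(**kwargs)


def _subject_fold_spec(epoch_set: EpochSet, k_folds: int, seed: int = 0) -> SplitSpec:
    n_subj = len({ep.subject_id for ep in epoch_set})
    n_test = max(1, int(round(0.25 * n_subj)))
    n_val = max(1, int(round(0.1 * n_subj)))
    return SplitSpec(
        scenario="subject",
        k_folds=k_folds,
        n_train_units=n_subj - n_test - n_val,
        n_val_units=n_val,
        n_test_units=n_test,
        seed=seed,
    )


def da_benchmark(
    epoch_set: EpochSet,
    seeds: Sequence[int] = (0, 1, 2, 3, 4),
    modes: Sequence[tuple[str, float]] = (("none", 0.0), ("block", 1.0)),
    estimator_overrides: Mapping | None = None,
) -> pd.DataFrame:
    """Held-out-subject comparison of training objectives.

    For each seed, one subject-level fold (rotating with the seed) is used:
    every mode trains on the identical fold and is scored on the held-out
    subjects.  Returns one row per (mode, seed) with accuracy and macro F1.
    """
    spec = _subject_fold_spec(epoch_set, k_folds=len(seeds))
    rows = []
    for i, seed in enumerate(seeds):
        tr, va, te = make_split(epoch_set, spec, i % spec.k_folds)
        train, val, test = epoch_set[tr], epoch_set[va], epoch_set[te]
        for mode, alpha in modes:
            clf = benchmark_estimator(mode, alpha, seed, **(estimator_overrides or {}))
            clf.fit(
                train.X, train.labels, meta=train.meta,
                X_val=val.X, y_val=val.labels, meta_val=val.meta,
            )
            report = evaluate_metrics(clf.predict(test.X), test.labels)
            rows.append(
                {
                    "da_mode": mode,
                    "alpha": alpha,
                    "seed": seed,
                    "fold": i % spec.k_folds,
                    "accuracy": report.accuracy,
                    "macro_f1": report.macro_f1,
                    "n_test": report.n_test,
                }
            )
    return pd.DataFrame(rows)


def split_scenario_benchmark(
    epoch_set: EpochSet,
    seeds: Sequence[int] = (0, 1, 2, 3, 4),
    scenarios: Sequence[str] = ("trial", "block", "session", "subject"),
    estimator_overrides: Mapping | None = None,
    wd_batch_size: int = 64,
    wd_pairs: int = 20,
) -> pd.DataFrame:
    """Accuracy + train/test Wasserstein diagnostic per split scenario.

    A fresh cross-entropy model is trained per (scenario, seed); the
    diagnostic compares encoder features of the training and test sides.
    """
    overrides = dict(max_epochs=30, patience=12)
    overrides.update(estimator_overrides or {})
    rows = []
    for scen in scenarios:
        for seed in seeds:
            spec = SplitSpec(scenario=scen, k_folds=5, seed=seed)
            tr, va, te = make_split(epoch_set, spec, 0)
            train, val, test = epoch_set[tr], epoch_set[va], epoch_set[te]
            clf = benchmark_estimator("none", 0.0, seed, **overrides)
            clf.fit(
                train.X, train.labels, meta=train.meta,
                X_val=val.X, y_val=val.labels, meta_val=val.meta,
            )
            acc = clf.score(test.X, test.labels)
            f_tr = clf.transform(train.X)
            f_te = clf.transform(test.X)
            bs = min(wd_batch_size, f_tr.shape[0], f_te.shape[0])
            wd = wasserstein_diagnostic(f_tr, f_te, n_pairs=wd_pairs, batch_size=bs, seed=seed)
            rows.append({"scenario": scen, "seed": seed, "accuracy": acc, "wasserstein": wd})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# planted-signal mask recovery
# ---------------------------------------------------------------------------

def _planted_design(n_subjects: int = 8) -> ExperimentDesign:
    # binary task, 32 channels (8 masks of 4), only the first 4 informative
    return ExperimentDesign(
        name="custom",
        n_subjects=n_subjects,
        sessions_per_subject=1,
        blocks_per_session=6,
        trials_per_block=10,
        block_condition_order=(0, 1, 0, 1, 0, 1),
        window_seconds=2.0,
        sampling_rate=10.0,
        n_spatial_channels=32,
        n_hemoglobin_types=2,
        n_optical_types=1,
        class_set=(0, 1),
    )


def mask_recovery_benchmark(
    seeds: Sequence[int] = (0, 1, 2, 3, 4),
    n_subjects: int = 8,
    channels_per_mask: int = 4,
    estimator_overrides: Mapping | None = None,
) -> pd.DataFrame:
    """Train on corpora where only spatial channels 0..3 carry class signal,
    then check the masking scan flags exactly that channel group as critical.

    The corpora use a strong, well-separated class signal with mild domain
    shift: this study validates the importance scan itself, so the model
    must first be able to learn the task.  Returns one row per seed with
    the flagged masks and a hit indicator (the informative mask is flagged
    and is the only flagged mask).
    """
    design = _planted_design(n_subjects)
    overrides = dict(max_epochs=40, patience=15, steps_per_epoch=15)
    overrides.update(estimator_overrides or {})
    rows = []
    for seed in seeds:
        cfg = GeneratorConfig(
            design=design,
            seed=seed,
            class_amplitudes={0: 0.4, 1: 1.8},
            subject_gain_sd=0.1,
            subject_offset_sd=0.2,
            session_offset_sd=0.2,
            block_drift_sd=0.3,
            measurement_noise_sd=0.3,
            informative_channel_fraction=channels_per_mask / design.n_spatial_channels,
        )
        corpus = generate_dataset(cfg)
        subjects = sorted({ep.subject_id for ep in corpus})
        test_subjects = set(subjects[-2:])
        is_test = np.asarray([ep.subject_id in test_subjects for ep in corpus])
        train = corpus[np.flatnonzero(~is_test)]
        test = corpus[np.flatnonzero(is_test)]
        clf = benchmark_estimator("none", 0.0, seed, **overrides)
        clf.fit(train.X, train.labels, meta=train.meta)
        masks = make_channel_masks(design.n_spatial_channels, channels_per_mask)
        result = channel_mask_scan(clf, test, masks)
        rows.append(
            {
                "seed": seed,
                "unmasked_accuracy": result.unmasked_accuracy,
                "critical_masks": result.critical_masks,
                "informative_mask_accuracy": result.mask_accuracies[0],
                "hit": result.critical_masks == (0,),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# four-way DA ablation
# ---------------------------------------------------------------------------

def da_ablation_study(
    epoch_set: EpochSet,
    modes: Sequence[str] = ("none", "subject", "session", "block"),
    k_folds: int = 3,
    alpha: float = 1.0,
    seed: int = 0,
    estimator_overrides: Mapping | None = None,
) -> pd.DataFrame:
    """CE vs subject/session/block DA with subject-level cross-validation.

    One row per (model, da_mode, fold) with accuracy, macro F1 and the
    per-fold deltas against the cross-entropy baseline.  Modes impossible
    for the corpus design (block pairing without multi-block sessions,
    session pairing without multi-session subjects) are skipped.
    """
    design = epoch_set.design
    spec = _subject_fold_spec(epoch_set, k_folds=k_folds, seed=seed)
    frames = []
    for mode in modes:
        if mode == "session" and design.sessions_per_subject < 2:
            continue
        if mode == "block" and design.blocks_per_session < 2:
            continue
        a = 0.0 if mode == "none" else alpha

        def factory(mode=mode, a=a):
            return benchmark_estimator(mode, a, seed, **(estimator_overrides or {}))

        table = cross_validate(epoch_set, spec, factory)
        table = table.drop(columns=["_model", "_test_idx"])
        table.insert(0, "da_mode", mode)
        table.insert(0, "model", "mlpmixer")
        frames.append(table)
    out = pd.concat(frames, ignore_index=True)
    base = out[out.da_mode == "none"].set_index("fold")
    out["delta_accuracy_vs_ce"] = out.apply(
        lambda r: r.accuracy - base.loc[r.fold, "accuracy"], axis=1
    )
    out["delta_f1_vs_ce"] = out.apply(
        lambda r: r.macro_f1 - base.loc[r.fold, "macro_f1"], axis=1
    )
    return out
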