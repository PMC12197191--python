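import numpy as np
import pytest

from nirsda.core_data import Epoch, EpochSet, ExperimentDesign


@pytest.fixture(scope="session")
def tiny_design() -> ExperimentDesign:
    """2 subjects x 2 sessions x 4 blocks x 5 trials, binary, 6 channels."""
    return ExperimentDesign(
        name="custom",
        n_subjects=2,
        sessions_per_subject=2,
        blocks_per_session=4,
        trials_per_block=5,
        block_condition_order=(0, 1, 1, 0),
        window_seconds=2.0,
        sampling_rate=5.0,
        n_spatial_channels=6,
        n_hemoglobin_types=2,
        n_optical_types=1,
        class_set=(0, 1),
    )


def make_epochs(design: ExperimentDesign, seed: int = 0) -> EpochSet:
    """A small random corpus following ``design`` exactly."""
    rng = np.random.default_rng(seed)
    T, F = design.n_timesteps, design.n_features
    epochs = []
    for s in range(design.n_subjects):
        for sess in range(design.sessions_per_subject):
            for blk in range(design.blocks_per_session):
                label = design.block_condition(sess, blk)
                for trial in range(design.trials_per_block):
                    epochs.append(
                        Epoch(
                            data=rng.normal(size=(T, F)).astype(np.float32),
                            sampling_rate=design.sampling_rate,
                            subject_id=f"S{s:03d}",
                            session_idx=sess,
                            block_idx=blk,
                            trial_idx=trial,
                            label=label,
                        )
                    )
    return EpochSet(epochs, design)


@pytest.fixture(scope="session")
def tiny_corpus(tiny_design) -> EpochSet:
    return make_epochs(tiny_design, seed=0)
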