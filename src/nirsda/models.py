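"""The fNIRS-adapted MLP-Mixer classifier.

The network maps an epoch ``[T timesteps x F features]`` to class logits:

1. a per-timestep fully-connected encoder projects the spatial feature vector
   (all probe groups concatenated, width ``n_probe_groups * D = F``) to a
   C-dimensional token, so the token sequence runs along time;
2. N mixer layers alternate a temporal-mixing MLP (acting along the T axis)
   and a channel-mixing MLP (acting along the C axis), each pre-norm with a
   residual skip-connection; an MLP block is ``w2 @ gelu(w1 x + b1) + b2``;
3. global average pooling over time yields the pooled feature vector
   (the tap used by all discrepancy losses), followed by a linear head.

Parameters are plain named numpy arrays; the same forward code runs on
autodiff tensors during training.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import autodiff as ad
from .core_data import DomainKey

__all__ = [
    "MixerConfig",
    "MixerParams",
    "FeatureBatch",
    "init_params",
    "mlp_block",
    "mixer_forward",
    "count_parameters_and_macs",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class MixerConfig:
    """Architecture hyper-parameters.

    Defaults follow the published configuration for the two-probe n-back
    dataset: T=150 timesteps, D=4 features per probe group, token width C=16,
    N=4 mixer layers, temporal-mixing hidden width 64, channel-mixing hidden
    width 32.  For single-probe-group montages set ``n_probe_groups=1`` and
    ``D`` to the full per-timestep feature count.
    """

    T: int = 150
    D: int = 4
    n_probe_groups: int = 2
    C: int = 16
    N: int = 4
    T_h: int = 64
    C_h: int = 32
    n_classes: int = 2
    dropout_ratio: float = 0.0

    def __post_init__(self):
        if min(self.T, self.D, self.n_probe_groups, self.C, self.n_classes) < 1 or self.N < 0:
            raise ValueError("invalid mixer dimensions")
        if not 0 <= self.dropout_ratio < 1:
            raise ValueError("dropout_ratio must be in [0, 1)")

    @property
    def input_width(self) -> int:
        """Per-timestep encoder input width: all probe groups concatenated."""
        return self.n_probe_groups * self.D


@dataclass
class FeatureBatch:
    """Encoder outputs (pooled pre-head features) with labels and domain keys."""

    features: object  # [n x C] array or Tensor
    labels: np.ndarray
    domain_keys: Sequence[DomainKey] = field(default_factory=list)

    def __post_init__(self):
        n = ad.value_of(self.features).shape[0]
        if n < 1:
            raise ValueError("FeatureBatch must hold at least one sample")
        self.labels = np.asarray(self.labels)
        if len(self.labels) != n:
            raise ValueError("labels length does not match features")
        if self.domain_keys and len(self.domain_keys) != n:
            raise ValueError("domain_keys length does not match features")

    def __len__(self) -> int:
        return ad.value_of(self.features).shape[0]


MixerParams = dict  # named parameter arrays; see init_params for the layout


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_params(config: MixerConfig, rng: np.random.Generator | int | None = None) -> MixerParams:
    """Glorot-uniform weights, zero biases, unit layer-norm gains."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    p: MixerParams = {
        "encoder.w": _glorot(rng, config.input_width, config.C),
        "encoder.b": np.zeros(config.C),
    }
    for layer in range(config.N):
        pre = f"layer{layer}"
        p[f"{pre}.ln1.gain"] = np.ones(config.C)
        p[f"{pre}.ln1.bias"] = np.zeros(config.C)
        p[f"{pre}.temporal.w1"] = _glorot(rng, config.T, config.T_h)
        p[f"{pre}.temporal.b1"] = np.zeros(config.T_h)
        p[f"{pre}.temporal.w2"] = _glorot(rng, config.T_h, config.T)
        p[f"{pre}.temporal.b2"] = np.zeros(config.T)
        p[f"{pre}.ln2.gain"] = np.ones(config.C)
        p[f"{pre}.ln2.bias"] = np.zeros(config.C)
        p[f"{pre}.channel.w1"] = _glorot(rng, config.C, config.C_h)
        p[f"{pre}.channel.b1"] = np.zeros(config.C_h)
        p[f"{pre}.channel.w2"] = _glorot(rng, config.C_h, config.C)
        p[f"{pre}.channel.b2"] = np.zeros(config.C)
    p["head.w"] = _glorot(rng, config.C, config.n_classes)
    p["head.b"] = np.zeros(config.n_classes)
    return p


def mlp_block(x, params: Mapping[str, object] | Sequence, hidden_dim: int | None = None):
    """Two-layer MLP ``w2 @ gelu(w1 x + b1) + b2`` on the last axis.

    Output width equals input width (to fit the residual skip-connection).
    ``params`` is either the mapping {w1, b1, w2, b2} or a 4-sequence.
    """
    if isinstance(params, Mapping):
        w1, b1, w2, b2 = params["w1"], params["b1"], params["w2"], params["b2"]
    else:
        w1, b1, w2, b2 = params
    din = ad.value_of(x).shape[-1]
    w1v, w2v = ad.value_of(w1), ad.value_of(w2)
    if w1v.shape[0] != din or w2v.shape[1] != din:
        raise ValueError(
            f"mlp_block shape mismatch: input width {din}, w1 {w1v.shape}, w2 {w2v.shape}"
        )
    if hidden_dim is not None and w1v.shape[1] != hidden_dim:
        raise ValueError(f"hidden width {w1v.shape[1]} != requested {hidden_dim}")
    h = ad.gelu(ad.add(ad.matmul(x, w1), b1))
    return ad.add(ad.matmul(h, w2), b2)


def _layer_params(params: Mapping, layer: int, which: str) -> dict:
    pre = f"layer{layer}.{which}"
    return {k: params[f"{pre}.{k}"] for k in ("w1", "b1", "w2", "b2")}


def mixer_forward(
    x,
    config: MixerConfig,
    params: Mapping[str, object],
    mode: str = "logits",
    dropout_rng: np.random.Generator | None = None,
):
    """Run the mixer on a batch.

    ``x`` is ``[n x T x F]`` (or ``[n x groups x T x D]``, which is reshaped).
    ``mode="logits"`` returns ``[n x n_classes]``; ``mode="features"`` returns
    the pooled pre-head ``[n x C]`` vector.  Dropout is active only when a
    ``dropout_rng`` is supplied and ``config.dropout_ratio > 0``.
    """
    if mode not in ("logits", "features"):
        raise ValueError("mode must be 'logits' or 'features'")
    xv = ad.value_of(x)
    if not np.isfinite(xv).all():
        raise ValueError("non-finite values in mixer input")
    if xv.ndim == 4:
        # [n, groups, T, D] -> [n, T, groups*D]
        x = ad.reshape(ad.swapaxes(x, 1, 2), (xv.shape[0], config.T, config.input_width))
        xv = ad.value_of(x)
    if xv.ndim != 3 or xv.shape[1] != config.T or xv.shape[2] != config.input_width:
        raise ValueError(
            f"expected input [n x {config.T} x {config.input_width}], got {xv.shape}"
        )

    drop = config.dropout_ratio if dropout_rng is not None else 0.0

    def _dropout(h):
        if drop <= 0:
            return h
        mask = (dropout_rng.random(ad.value_of(h).shape) >= drop) / (1.0 - drop)
        return ad.mul(h, mask)

    h = ad.add(ad.matmul(x, params["encoder.w"]), params["encoder.b"])  # [n, T, C]
    for layer in range(config.N):
        pre = f"layer{layer}"
        u = ad.layer_norm(h, params[f"{pre}.ln1.gain"], params[f"{pre}.ln1.bias"])
        u = ad.swapaxes(u, 1, 2)  # [n, C, T]
        u = mlp_block(u, _layer_params(params, layer, "temporal"), config.T_h)
        u = ad.swapaxes(u, 1, 2)
        h = ad.add(h, _dropout(u))
        v = ad.layer_norm(h, params[f"{pre}.ln2.gain"], params[f"{pre}.ln2.bias"])
        v = mlp_block(v, _layer_params(params, layer, "channel"), config.C_h)
        h = ad.add(h, _dropout(v))
    pooled = ad.mean(h, axis=1)  # [n, C]
    if mode == "features":
        return pooled
    return ad.add(ad.matmul(pooled, params["head.w"]), params["head.b"])


def count_parameters_and_macs(config: MixerConfig) -> tuple[int, int]:
    """Closed-form parameter and multiply-accumulate counts per forward pass.

    MACs count linear-map multiplies only (no layer-norm, GELU or bias adds):
    encoder ``T * (G*D) * C``; each mixer layer ``C * (T*T_h + T_h*T) +
    T * (C*C_h + C_h*C)``; head ``C * M``.
    """
    gd, T, C, M = config.input_width, config.T, config.C, config.n_classes
    params = gd * C + C  # encoder
    macs = T * gd * C
    per_layer_params = (
        T * config.T_h + config.T_h + config.T_h * T + T
        + C * config.C_h + config.C_h + config.C_h * C + C
        + 4 * C  # two layer norms, gain+bias each
    )
    per_layer_macs = C * (T * config.T_h + config.T_h * T) + T * (C * config.C_h + config.C_h * C)
    params += config.N * per_layer_params
    macs += config.N * per_layer_macs
    params += C * M + M  # head
    macs += C * M
    return params, macs


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path: str | Path, config: MixerConfig, params: MixerParams) -> None:
    """Single-file archive of named parameter arrays plus a JSON config block."""
    path = Path(path)
    cfg = {k: getattr(config, k) for k in config.__dataclass_fields__}
    np.savez(path, __config__=json.dumps(cfg), **{k: ad.value_of(v) for k, v in params.items()})


def load_checkpoint(path: str | Path) -> tuple[MixerConfig, MixerParams]:
    with np.load(Path(path), allow_pickle=False) as archive:
        cfg = MixerConfig(**json.loads(str(archive["__config__"])))
        params = {k: archive[k] for k in archive.files if k != "__config__"}
    return cfg, params
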