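"""Kernel two-sample discrepancies and the training objective.

Implements the full discrepancy family used for feature alignment:

* the biased (V-statistic) maximum mean discrepancy between two feature
  batches under a multi-bandwidth Gaussian kernel,
* the class-aware discrepancy ``e1 + e2 - 2*e3`` built from indicator-masked
  kernel means (intra-class when the two class arguments agree, inter-class
  otherwise),
* the contrastive domain discrepancy: mean intra-class term minus mean
  inter-class term,
* the block-wise discrepancy: the same-class MMD between two blocks of the
  same subject and session,
* the overall objective ``l = l_ce + alpha * (D_cdd + D_bwise)``.

Every function accepts plain numpy arrays (returning numpy scalars) or
:class:`nirsda.autodiff.Tensor` features (returning a differentiable node),
so the identical code path is used for analysis and for training gradients.
Kernel bandwidths resolved by the median heuristic are always computed from
detached values and enter the graph as constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist

from . import autodiff as ad
from .core_data import DomainKey

__all__ = [
    "KernelSpec",
    "DiscrepancyReport",
    "ObjectiveConfig",
    "LossBreakdown",
    "UndefinedClassTermError",
    "DomainMismatchError",
    "gaussian_kernel",
    "mmd",
    "class_aware_discrepancy",
    "cdd",
    "bwise_discrepancy",
    "total_objective",
    "cross_entropy",
]


class UndefinedClassTermError(ValueError):
    """A class-conditional kernel mean has an empty membership mask."""


class DomainMismatchError(ValueError):
    """Feature batches violate the subject/session/block key constraints."""


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KernelSpec:
    """Multi-bandwidth Gaussian RBF kernel.

    ``bandwidths=None`` resolves sigma by the median heuristic on the pooled
    pairwise distances of the two batches at call time, scaled by
    ``multipliers``; explicit bandwidths are used as given.  The kernel value
    is the arithmetic mean over bandwidths of ``exp(-||x-y||^2 / (2 sigma^2))``.
    """

    bandwidths: tuple[float, ...] | None = None
    multipliers: tuple[float, ...] = (0.5, 1.0, 2.0)

    def __post_init__(self):
        if self.bandwidths is not None:
            if len(self.bandwidths) == 0:
                raise ValueError("at least one bandwidth required")
            if any(b <= 0 for b in self.bandwidths):
                raise ValueError("kernel bandwidths must be > 0")
        elif len(self.multipliers) == 0:
            raise ValueError("at least one multiplier required")

    def resolve(self, X, Y) -> tuple[float, ...]:
        """Concrete sigmas for a pair of batches (median heuristic if needed)."""
        if self.bandwidths is not None:
            return tuple(float(b) for b in self.bandwidths)
        pooled = np.concatenate([ad.value_of(X), ad.value_of(Y)], axis=0)
        if pooled.shape[0] < 2:
            med = 1.0
        else:
            d = pdist(pooled)
            med = float(np.median(d))
        if med <= 0:
            med = 1.0
        return tuple(float(m) * med for m in self.multipliers)


def _features(batch):
    """Feature array/tensor of a FeatureBatch or a raw operand."""
    return getattr(batch, "features", batch)


def _labels(batch) -> np.ndarray:
    labels = getattr(batch, "labels", None)
    if labels is None:
        raise ValueError("this discrepancy needs a FeatureBatch with labels")
    return np.asarray(labels)


def _squared_distances(X, Y):
    """Pairwise squared Euclidean distances, autodiff-compatible."""
    xx = ad.sum(ad.mul(X, X), axis=1, keepdims=True)  # [n,1]
    yy = ad.reshape(ad.sum(ad.mul(Y, Y), axis=1), (1, -1))  # [1,m]
    cross = ad.matmul(X, ad.swapaxes(Y, 0, 1))
    d2 = ad.add(ad.sub(xx, ad.mul(2.0, cross)), yy)
    return ad.clip_min(d2, 0.0)  # kill negative float residue


def gaussian_kernel(X, Y, spec: KernelSpec = KernelSpec()):
    """Kernel matrix [n x m]: mean over sigmas of exp(-||x-y||^2 / (2 sigma^2))."""
    Xf, Yf = _features(X), _features(Y)
    if ad.value_of(Xf).shape[1] != ad.value_of(Yf).shape[1]:
        raise ValueError("feature dimensions differ")
    sigmas = spec.resolve(Xf, Yf)
    d2 = _squared_distances(Xf, Yf)
    acc = None
    for s in sigmas:
        term = ad.exp(ad.mul(d2, -1.0 / (2.0 * s**2)))
        acc = term if acc is None else ad.add(acc, term)
    return ad.div(acc, float(len(sigmas)))


# ---------------------------------------------------------------------------
# discrepancies
# ---------------------------------------------------------------------------

@dataclass
class DiscrepancyReport:
    """Breakdown of a class-aware / contrastive discrepancy computation."""

    e1: float | None = None
    e2: float | None = None
    e3: float | None = None
    class_pair_masks: dict = field(default_factory=dict)
    D_class_pair: float | None = None
    D_cdd: float | None = None
    D_bwise: float | None = None
    counts: dict = field(default_factory=dict)
    intra_terms: dict = field(default_factory=dict)
    inter_terms: dict = field(default_factory=dict)


def mmd(source, target, spec: KernelSpec = KernelSpec(), cross_term: str = "standard"):
    """Biased V-statistic MMD estimate between two feature batches.

    ``cross_term="standard"`` uses the scale-consistent ``2/(n_s n_t)``
    normalization; ``"printed"`` keeps the ``2/(n_s^2 n_t^2)`` variant for
    comparison (it is not zero for identical batches).
    """
    Xs, Xt = _features(source), _features(target)
    ns, nt = ad.value_of(Xs).shape[0], ad.value_of(Xt).shape[0]
    if ns == 0 or nt == 0:
        raise ValueError("mmd requires nonempty batches")
    sigmas = spec.resolve(Xs, Xt)
    fixed = KernelSpec(bandwidths=sigmas)
    k_ss = ad.mean(gaussian_kernel(Xs, Xs, fixed))
    k_tt = ad.mean(gaussian_kernel(Xt, Xt, fixed))
    k_st = ad.sum(gaussian_kernel(Xs, Xt, fixed))
    if cross_term == "standard":
        cross = ad.mul(k_st, 2.0 / (ns * nt))
    elif cross_term == "printed":
        cross = ad.mul(k_st, 2.0 / (ns**2 * nt**2))
    else:
        raise ValueError("cross_term must be 'standard' or 'printed'")
    return ad.sub(ad.add(k_ss, k_tt), cross)


def _masked_kernel_mean(K, mask: np.ndarray):
    """Sum of kernel entries under a boolean mask, divided by the mask count."""
    count = int(mask.sum())
    if count == 0:
        raise UndefinedClassTermError("empty class mask: the term's denominator vanishes")
    return ad.div(ad.sum(ad.mul(K, mask.astype(float))), float(count))


def class_aware_discrepancy(
    source,
    target,
    c1: int,
    c2: int,
    spec: KernelSpec = KernelSpec(),
):
    """Class-conditional discrepancy ``D_{c1 c2} = e1 + e2 - 2 e3``.

    ``e1`` is the within-source kernel mean over class-``c1`` pairs, ``e2``
    the within-target mean over class-``c2`` pairs, ``e3`` the cross-domain
    mean over (``c1``, ``c2``) pairs.  Raises
    :class:`UndefinedClassTermError` when either class is absent.
    """
    Xs, Xt = _features(source), _features(target)
    ys, yt = _labels(source), _labels(target)
    ms = ys == c1
    mt = yt == c2
    if not ms.any() or not mt.any():
        raise UndefinedClassTermError(
            f"class {c1} in source: {int(ms.sum())} samples; "
            f"class {c2} in target: {int(mt.sum())} samples"
        )
    sigmas = spec.resolve(Xs, Xt)
    fixed = KernelSpec(bandwidths=sigmas)
    e1 = _masked_kernel_mean(gaussian_kernel(Xs, Xs, fixed), np.outer(ms, ms))
    e2 = _masked_kernel_mean(gaussian_kernel(Xt, Xt, fixed), np.outer(mt, mt))
    e3 = _masked_kernel_mean(gaussian_kernel(Xs, Xt, fixed), np.outer(ms, mt))
    value = ad.sub(ad.add(e1, e2), ad.mul(2.0, e3))
    report = DiscrepancyReport(
        e1=float(ad.value_of(e1)),
        e2=float(ad.value_of(e2)),
        e3=float(ad.value_of(e3)),
        class_pair_masks={(c1, c2): (ms, mt)},
        D_class_pair=float(ad.value_of(value)),
        counts={"source": {c1: int(ms.sum())}, "target": {c2: int(mt.sum())}},
    )
    return value, report


def cdd(
    source,
    target,
    M: int | None = None,
    spec: KernelSpec = KernelSpec(),
    classes: Sequence[int] | None = None,
):
    """Contrastive domain discrepancy: mean intra-class minus mean inter-class.

    Class terms whose mask is empty in either domain are skipped and the two
    normalizing counts are reduced to the number of terms actually computed
    (small mini-batches routinely miss classes).  Requires at least two
    classes overall.
    """
    ys, yt = _labels(source), _labels(target)
    if classes is None:
        classes = sorted(set(ys) | set(yt))
    classes = list(classes)
    if M is None:
        M = len(classes)
    if M < 2 or len(classes) < 2:
        raise ValueError("cdd needs at least two classes (inter term undefined)")

    Xs, Xt = _features(source), _features(target)
    sigmas = spec.resolve(Xs, Xt)
    fixed = KernelSpec(bandwidths=sigmas)
    K_ss = gaussian_kernel(Xs, Xs, fixed)
    K_tt = gaussian_kernel(Xt, Xt, fixed)
    K_st = gaussian_kernel(Xs, Xt, fixed)

    report = DiscrepancyReport(class_pair_masks={}, counts={"skipped": []})
    intra, inter = [], []
    for c1 in classes:
        ms = ys == c1
        for c2 in classes:
            mt = yt == c2
            if not ms.any() or not mt.any():
                report.counts["skipped"].append((c1, c2))
                continue
            e1 = _masked_kernel_mean(K_ss, np.outer(ms, ms))
            e2 = _masked_kernel_mean(K_tt, np.outer(mt, mt))
            e3 = _masked_kernel_mean(K_st, np.outer(ms, mt))
            term = ad.sub(ad.add(e1, e2), ad.mul(2.0, e3))
            report.class_pair_masks[(c1, c2)] = (ms, mt)
            if c1 == c2:
                intra.append(term)
                report.intra_terms[c1] = float(ad.value_of(term))
            else:
                inter.append(term)
                report.inter_terms[(c1, c2)] = float(ad.value_of(term))
    if not intra:
        raise UndefinedClassTermError("no class is present in both domains")
    value = ad.div(_sum_terms(intra), float(len(intra)))
    if inter:
        value = ad.sub(value, ad.div(_sum_terms(inter), float(len(inter))))
    report.D_cdd = float(ad.value_of(value))
    return value, report


def _sum_terms(terms):
    acc = terms[0]
    for t in terms[1:]:
        acc = ad.add(acc, t)
    return acc


def bwise_discrepancy(
    block_a,
    block_b,
    c: int,
    spec: KernelSpec = KernelSpec(),
    cross_term: str = "standard",
):
    """Same-class MMD between two blocks of the same subject and session.

    Returns ``None`` (a skip signal, distinct from an error) when class ``c``
    is absent from either block; raises :class:`DomainMismatchError` when the
    batches do not come from two different blocks of one subject's session.
    """
    keys_a = getattr(block_a, "domain_keys", None)
    keys_b = getattr(block_b, "domain_keys", None)
    if keys_a is not None and keys_b is not None and len(keys_a) and len(keys_b):
        subj_a = {k.subject_id for k in keys_a}
        subj_b = {k.subject_id for k in keys_b}
        sess_a = {k.session_idx for k in keys_a}
        sess_b = {k.session_idx for k in keys_b}
        blk_a = {k.block_idx for k in keys_a}
        blk_b = {k.block_idx for k in keys_b}
        if len(subj_a | subj_b) != 1 or len(sess_a | sess_b) != 1:
            raise DomainMismatchError(
                "block-wise discrepancy requires both batches from the same "
                f"subject and session (got subjects {subj_a | subj_b}, sessions {sess_a | sess_b})"
            )
        if len(blk_a) != 1 or len(blk_b) != 1 or blk_a == blk_b:
            raise DomainMismatchError(
                f"batches must each come from a single, distinct block (got {blk_a} vs {blk_b})"
            )
    ya, yb = _labels(block_a), _labels(block_b)
    ma, mb = ya == c, yb == c
    if not ma.any() or not mb.any():
        return None
    Xa, Xb = _features(block_a), _features(block_b)
    Xa_c = ad.take(Xa, np.flatnonzero(ma)) if ad.is_tensor(Xa) else np.asarray(Xa)[ma]
    Xb_c = ad.take(Xb, np.flatnonzero(mb)) if ad.is_tensor(Xb) else np.asarray(Xb)[mb]
    return mmd(Xa_c, Xb_c, spec, cross_term=cross_term)


# ---------------------------------------------------------------------------
# overall objective
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ObjectiveConfig:
    """Weights and mode of the training objective."""

    alpha: float = 1.0
    kernel: KernelSpec = field(default_factory=KernelSpec)
    da_mode: str = "none"  # none | subject | session | block

    def __post_init__(self):
        if not np.isfinite(self.alpha) or self.alpha < 0:
            raise ValueError("alpha must be finite and >= 0")
        if self.da_mode not in ("none", "subject", "session", "block"):
            raise ValueError(f"unknown da_mode {self.da_mode!r}")


@dataclass
class LossBreakdown:
    """Components of the objective ``total = ce + alpha * (D_cdd + D_bwise)``."""

    total: object
    cross_entropy: object
    d_cdd: object
    d_bwise: object

    def as_floats(self) -> dict[str, float]:
        return {
            "total": float(ad.value_of(self.total)),
            "cross_entropy": float(ad.value_of(self.cross_entropy)),
            "d_cdd": float(ad.value_of(self.d_cdd)),
            "d_bwise": float(ad.value_of(self.d_bwise)),
        }


def cross_entropy(logits, labels):
    """Mean softmax cross-entropy of integer class indices."""
    return ad.softmax_cross_entropy(logits, labels)


def total_objective(logits, labels, d_cdd, d_bwise, config: ObjectiveConfig) -> LossBreakdown:
    """Assemble the overall loss.

    Under subject-mode adaptation there are no within-subject block pairs, so
    the block-wise term contributes zero regardless of what was passed.
    """
    lce = cross_entropy(logits, labels)
    if config.da_mode == "subject" or d_bwise is None:
        d_bwise = 0.0
    if d_cdd is None:
        d_cdd = 0.0
    penalty = ad.add(d_cdd, d_bwise)
    total = ad.add(lce, ad.mul(float(config.alpha), penalty))
    return LossBreakdown(total=total, cross_entropy=lce, d_cdd=d_cdd, d_bwise=d_bwise)
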