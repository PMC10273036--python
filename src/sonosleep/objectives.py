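"""Training objectives.

Four components drive training, combined as a nonnegative weighted sum:

* ``L_c``  — supervised cross-entropy on labeled source windows;
* ``L_d``  — binary cross-entropy of the domain discriminator (made
  adversarial by gradient reversal in the trainer);
* ``L_a``  — auxiliary loss on target windows: conditional entropy of the
  posterior plus a virtual adversarial training (VAT) term;
* ``L_js`` — Jensen–Shannon divergence among the posteriors of a clean
  source window and its two noise-augmented variants.

All entropies and divergences use natural logarithms; probabilities are
clamped at 1e-7 before any log. Every function accepts either autograd
Tensors (returning a Tensor for backprop) or plain numpy arrays (returning
a float).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .autograd import Tensor, no_grad
from .hypnogram import STAGE_TO_INDEX

PROB_CLAMP = 1e-7


def _as3d(post) -> Tensor:
    t = post if isinstance(post, Tensor) else Tensor(post)
    if t.ndim == 2:
        t = t.reshape(1, *t.shape)
    return t


def _maybe_float(result: Tensor, *inputs):
    if any(isinstance(x, Tensor) for x in inputs):
        return result
    return result.item()


def stage_indices(labels: Sequence) -> np.ndarray:
    """Stage names (or already-integer indices) -> canonical indices."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "iu":
        return arr.astype(np.int64)
    return np.vectorize(STAGE_TO_INDEX.__getitem__)(arr).astype(np.int64)


# ---------------------------------------------------------------------------
# component losses


def cross_entropy(post, labels) -> float | Tensor:
    """Mean negative log-probability of the true stage over labeled epochs."""
    p = _as3d(post)
    b, t, _ = p.shape
    idx = stage_indices(labels).reshape(b, t)
    bi = np.broadcast_to(np.arange(b)[:, None], (b, t))
    ti = np.broadcast_to(np.arange(t)[None, :], (b, t))
    chosen = p.clip_min(PROB_CLAMP)[bi, ti, idx]
    return _maybe_float(-(chosen.log().mean()), post)


def domain_bce(pred, label) -> float | Tensor:
    """-log of the probability assigned to the true domain.

    `pred` is P(source); `label` is "source"/"target", 0/1, or an array of
    those (1 = source).
    """
    p = pred if isinstance(pred, Tensor) else Tensor(np.atleast_1d(pred))
    if isinstance(label, str):
        y = np.full(p.shape, 1.0 if label == "source" else 0.0)
    else:
        arr = np.atleast_1d(np.asarray(label, dtype=object))
        y = np.array(
            [1.0 if (v == "source" or v == 1) else 0.0 for v in arr.ravel()]
        ).reshape(p.shape)
    p_true = p * y + (1.0 - p) * (1.0 - y)
    return _maybe_float(-(p_true.clip_min(PROB_CLAMP).log().mean()), pred)


def conditional_entropy(post) -> float | Tensor:
    """Mean Shannon entropy of posterior rows, in [0, ln 5]."""
    p = _as3d(post)
    ent = -(p * p.clip_min(PROB_CLAMP).log()).sum(axis=-1)
    return _maybe_float(ent.mean(), post)


def _kl_rows(p: Tensor, q: Tensor) -> Tensor:
    """Row-wise KL(p || q), probabilities clamped inside the logs."""
    logp = p.clip_min(PROB_CLAMP).log()
    logq = q.clip_min(PROB_CLAMP).log()
    return (p * (logp - logq)).sum(axis=-1)


def js_consistency(p1, p2, p3) -> float | Tensor:
    """Mean Jensen–Shannon divergence of three posteriors, in [0, ln 3].

    JSD(p1,p2,p3) = (1/3) sum_i KL(p_i || m) with m the equal-weight mixture;
    symmetric in its arguments and zero iff the three posteriors coincide.
    """
    t1, t2, t3 = _as3d(p1), _as3d(p2), _as3d(p3)
    if not (t1.shape == t2.shape == t3.shape):
        raise ValueError("posterior shape mismatch")
    m = (t1 + t2 + t3) * (1.0 / 3.0)
    jsd = (_kl_rows(t1, m) + _kl_rows(t2, m) + _kl_rows(t3, m)) * (1.0 / 3.0)
    return _maybe_float(jsd.mean(), p1, p2, p3)


# ---------------------------------------------------------------------------
# virtual adversarial training


@dataclass
class VATConfig:
    epsilon: float = 1.0   # perturbation radius, z-score input units
    xi: float = 1e-6       # finite-difference scale for power iteration
    power_iters: int = 1


def _unit_per_sample(d: np.ndarray) -> np.ndarray:
    flat = d.reshape(d.shape[0], -1)
    norms = np.linalg.norm(flat, axis=1, keepdims=True)
    return (flat / np.maximum(norms, 1e-12)).reshape(d.shape)


def _kl_to_const(p_const: np.ndarray, q: Tensor) -> Tensor:
    p = np.clip(p_const, PROB_CLAMP, None)
    logp = Tensor(np.log(p))
    logq = q.clip_min(PROB_CLAMP).log()
    return (Tensor(p) * (logp - logq)).sum(axis=-1).mean()


def vat_loss(
    forward_fn: Callable[[Tensor], Tensor],
    x: np.ndarray,
    config: VATConfig,
    rng: np.random.Generator,
    return_perturbation: bool = False,
    freeze: Sequence[Tensor] = (),
):
    """KL divergence between the posterior at x and at x + r_adv.

    The adversarial direction r_adv (||r_adv|| = epsilon per sample) is found
    by xi-scaled power iteration on the KL divergence, following the standard
    VAT recipe. `forward_fn` maps an input Tensor to a posterior Tensor; the
    clean posterior is treated as a constant. Tensors in `freeze` (typically
    model parameters) get no gradients during the power iteration, which
    only needs the gradient with respect to the input.
    """
    if config.epsilon <= 0 or config.power_iters < 1:
        raise ValueError("epsilon must be > 0 and power_iters >= 1")
    x = np.asarray(x)
    if x.dtype != np.float32:
        x = x.astype(np.float64)
    with no_grad():
        p0 = forward_fn(Tensor(x)).data
    d = _unit_per_sample(rng.standard_normal(x.shape)).astype(x.dtype)
    try:
        for t in freeze:
            t.requires_grad = False
        for _ in range(config.power_iters):
            xt = Tensor(x + config.xi * d, requires_grad=True)
            dist = _kl_to_const(p0, forward_fn(xt))
            dist.backward()
            if xt.grad is None or not np.any(xt.grad):
                break  # posterior locally flat; keep current direction
            d = _unit_per_sample(xt.grad).astype(x.dtype)
    finally:
        for t in freeze:
            t.requires_grad = True
    r_adv = config.epsilon * d
    loss = _kl_to_const(p0, forward_fn(Tensor(x + r_adv)))
    if return_perturbation:
        return loss, r_adv
    return loss


# ---------------------------------------------------------------------------
# aggregation


@dataclass
class LossWeights:
    l_c: float = 1.0
    l_d: float = 1.0
    l_a: float = 0.1
    l_js: float = 1.0

    def __post_init__(self):
        for name, w in self.as_dict().items():
            if w < 0:
                raise ValueError(f"negative loss weight {name}={w}")

    def as_dict(self) -> dict[str, float]:
        return {"l_c": self.l_c, "l_d": self.l_d, "l_a": self.l_a,
                "l_js": self.l_js}


@dataclass
class LossComponents:
    """The four component values, their weights, and the weighted total."""

    l_c: float
    l_d: float
    l_a: float
    l_js: float
    weights: LossWeights = field(default_factory=LossWeights)
    total: float = field(init=False)

    def __post_init__(self):
        self.total = total_loss(
            (self.l_c, self.l_d, self.l_a, self.l_js), self.weights
        )


def total_loss(components: Sequence[float], weights: LossWeights) -> float:
    """Weighted sum of (L_c, L_d, L_a, L_js)."""
    w = weights.as_dict()
    vals = list(components)
    if len(vals) != 4:
        raise ValueError("expected the four components (L_c, L_d, L_a, L_js)")
    return float(sum(wi * vi for wi, vi in zip(w.values(), vals)))
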