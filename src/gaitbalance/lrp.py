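"""Layer-wise relevance propagation for the residual balance classifier.

The class score to be explained is redistributed backwards through the
network with the epsilon-stabilized z-rule: a neuron j with forward
contributions ``z_ij = a_i * w_ij`` from the layer below passes its
relevance down as ``R_i <- (z_ij / z_j) * R_j`` with ``z_j = sum_i z_ij``
(the bias term is not part of the denominator).  This redistribution
conserves relevance exactly: the input relevances of every sample sum to
the explained pre-softmax score.

The default stabilizer is ``eps = 0`` with an exact-zero guard: denominators
that are exactly zero drop their relevance (and surface in the conservation
gap), every other division is well-defined in float64.  This keeps the
conservation property intact to floating-point precision.  A positive
``eps`` is available and applies a *relative* stabilizer — the denominator
becomes ``z_j * (1 + eps)`` — which caps no denominator but shrinks each
neuron's outgoing relevance by exactly ``1/(1 + eps)`` per step.  Note that
any nonzero stabilizer (relative or the textbook absolute offset) breaks
conservation through a residual network: the merge split can hand the two
paths totals that are orders of magnitude larger than the explained score
and of opposite sign, and because branch and skip traverse different
numbers of redistribution steps, the per-step shrinkage no longer cancels
between them.  With eps = 0 the signed path totals recombine exactly.

The full-network propagation additionally rescales the relevance after
every redistribution step to the total the rule prescribes in exact
arithmetic (a floating-point drift correction; the identity map in exact
arithmetic).  The standalone ``zrule_*`` functions are uncompensated so the
redistribution arithmetic can be verified against closed-form oracles.

Layer handling:

* convolutions and the dense head: z-rule on their affine weights;
* batch normalization: folded into the preceding convolution's effective
  weights and bias (inference statistics), which is exact at inference;
* ReLU and dropout: relevance passes through unchanged;
* global average pooling: an affine layer with equal weights 1/T;
* residual addition: incoming relevance is split between branch and skip in
  proportion to each path's contribution to the sum (epsilon-stabilized);
  the skip projection, when present, is a 1-wide convolution under the
  z-rule.

All relevance arithmetic runs in float64 regardless of the network's
parameter dtype.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classifier import BalanceClassifier
from .nn.layers import ResidualBlock, conv1d_raw, conv1d_input_grad
from .preprocessing import PreprocessedSample
from .skeleton import Joint, JointGroup, joint_group

DEFAULT_EPSILON = 0.0

AXIS_NAMES = ("X", "Y", "Z")


@dataclass
class RelevanceMap:
    """Signed relevance of every input scalar for one classified sample."""

    relevance: np.ndarray        # (window, J, 3), same layout as the input
    target_class: int
    target_score: float          # pre-softmax score being explained
    predicted_class: int
    epsilon: float
    group: str

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.relevance)):
            raise ValueError("relevance contains non-finite values")

    @property
    def total(self) -> float:
        return float(self.relevance.sum())


@dataclass
class ContributionMatrix:
    """Aggregated relevance as axis blocks (X, Y, Z) x joints x frames."""

    matrix: np.ndarray           # (3 * J, window)
    row_labels: list[str]
    aggregation: str
    level: int | None


def _safe_ratio(r: np.ndarray, z: np.ndarray, eps: float) -> np.ndarray:
    denom = z * (1.0 + eps)
    out = np.zeros_like(r)
    np.divide(r, denom, out=out, where=denom != 0)
    return out


def _compensate(r_in: np.ndarray, total_out: float, eps: float) -> float:
    """Rescale ``r_in`` in place so its sum equals ``total_out / (1 + eps)``,
    the value the z-rule guarantees in exact arithmetic; returns the new
    total.  Corrects floating-point drift only."""
    target = total_out / (1.0 + eps)
    current = float(r_in.sum())
    if current != 0.0:
        r_in *= target / current
        return target
    return current


def zrule_dense(a: np.ndarray, weight: np.ndarray, r_out: np.ndarray,
                eps: float = 0.0) -> np.ndarray:
    """z-rule through ``y = a @ W.T``: ``a`` (N, D_in), ``r_out`` (N, D_out)."""
    z = a @ weight.T
    s = _safe_ratio(r_out, z, eps)
    return a * (s @ weight)


def zrule_conv(a: np.ndarray, weight: np.ndarray, r_out: np.ndarray,
               eps: float = 0.0) -> np.ndarray:
    """z-rule through a same-padded bias-free 1D convolution."""
    z = conv1d_raw(a, weight)
    s = _safe_ratio(r_out, z, eps)
    return a * conv1d_input_grad(s, weight, a.shape[2])


def zrule_pool(a: np.ndarray, r_out: np.ndarray, eps: float = 0.0) -> np.ndarray:
    """z-rule through global average pooling: ``a`` (N, C, T), ``r_out`` (N, C)."""
    t = a.shape[2]
    z = a.mean(axis=2)
    s = _safe_ratio(r_out, z, eps)
    return (a / t) * s[:, :, None]


def _fold_conv_bn(conv, bn) -> tuple[np.ndarray, np.ndarray]:
    """Effective float64 (weight, bias) of conv followed by inference BN."""
    scale, shift = bn.effective_affine()
    w = conv.weight.astype(np.float64) * scale.astype(np.float64)[:, None, None]
    b = shift.astype(np.float64)
    if conv.bias is not None:
        b = b + conv.bias.astype(np.float64) * scale.astype(np.float64)
    return w, b


class _FoldedBlock:
    """Float64 inference-mode view of a residual block with BN folded in."""

    def __init__(self, block: ResidualBlock, relu: bool) -> None:
        self.w1, self.b1 = _fold_conv_bn(block.conv1, block.bn1)
        self.w2, self.b2 = _fold_conv_bn(block.conv2, block.bn2)
        self.w3, self.b3 = _fold_conv_bn(block.conv3, block.bn3)
        self.wp = (block.proj.weight.astype(np.float64)
                   if block.proj is not None else None)
        self.relu = relu

    def _act(self, x: np.ndarray) -> np.ndarray:
        return np.maximum(x, 0.0) if self.relu else x

    def forward(self, a: np.ndarray) -> dict:
        x1 = self._act(conv1d_raw(a, self.w1) + self.b1[None, :, None])
        x2 = self._act(conv1d_raw(x1, self.w2) + self.b2[None, :, None])
        x3 = self._act(conv1d_raw(x2, self.w3) + self.b3[None, :, None])
        skip = conv1d_raw(a, self.wp) if self.wp is not None else a
        return {"a": a, "x1": x1, "x2": x2, "x3": x3, "skip": skip,
                "out": x3 + skip}

    def backward_relevance(self, rec: dict, r_out: np.ndarray,
                           eps: float, compensate: bool = True) -> np.ndarray:
        # split at the merge, proportional to each path's contribution
        total = float(r_out.sum())
        ratio = _safe_ratio(r_out, rec["out"], eps)
        r_branch = rec["x3"] * ratio
        r_skip = rec["skip"] * ratio
        if compensate:
            target = total / (1.0 + eps)
            current = float(r_branch.sum() + r_skip.sum())
            if current != 0.0:
                r_branch *= target / current
                r_skip *= target / current
        tb = float(r_branch.sum())
        r = zrule_conv(rec["x2"], self.w3, r_branch, eps)
        if compensate:
            tb = _compensate(r, tb, eps)
        r = zrule_conv(rec["x1"], self.w2, r, eps)
        if compensate:
            tb = _compensate(r, tb, eps)
        r_a = zrule_conv(rec["a"], self.w1, r, eps)
        if compensate:
            _compensate(r_a, tb, eps)
        if self.wp is not None:
            ts = float(r_skip.sum())
            r_proj = zrule_conv(rec["a"], self.wp, r_skip, eps)
            if compensate:
                _compensate(r_proj, ts, eps)
            r_a = r_a + r_proj
        else:
            r_a = r_a + r_skip
        return r_a


def _folded_forward(model: BalanceClassifier, a: np.ndarray):
    """Inference forward pass in float64 with BN folded; returns
    (block views, per-block records, pooled activations, logits)."""
    relu = model.config.activation == "relu"
    blocks = [_FoldedBlock(b, relu) for b in model.blocks]
    records = []
    h = a
    for blk in blocks:
        rec = blk.forward(h)
        records.append(rec)
        h = rec["out"]
    pooled = h.mean(axis=2)
    wd = model.dense.weight.astype(np.float64)
    bd = (model.dense.bias.astype(np.float64)
          if model.dense.bias is not None else 0.0)
    logits = pooled @ wd.T + bd
    return blocks, records, pooled, logits


def relevance(
    model: BalanceClassifier,
    sample: PreprocessedSample,
    target_class: int | None = None,
    epsilon: float = DEFAULT_EPSILON,
    compensate: bool = True,
) -> RelevanceMap:
    """Input relevance of one sample for a (by default, the predicted) class.

    The output-layer relevance is initialized to the target class's
    pre-softmax score and propagated to the input with the epsilon-stabilized
    z-rule.  ``compensate=False`` disables the per-step floating-point drift
    correction (useful when comparing against closed-form oracles).
    """
    a = model.to_channels(sample.tensor[None]).astype(np.float64)
    blocks, records, pooled, logits = _folded_forward(model, a)
    predicted = int(logits[0].argmax())
    target = predicted if target_class is None else int(target_class)
    if not 0 <= target < model.config.n_classes:
        raise ValueError(f"target_class {target} outside 0..{model.config.n_classes - 1}")
    score = float(logits[0, target])

    wd = model.dense.weight.astype(np.float64)
    r_logits = np.zeros_like(logits)
    r_logits[0, target] = score
    r = zrule_dense(pooled, wd, r_logits, epsilon)
    total = _compensate(r, score, epsilon) if compensate else 0.0

    h_last = records[-1]["out"]
    r = zrule_pool(h_last, r, epsilon)
    if compensate:
        _compensate(r, total, epsilon)
    for blk, rec in zip(reversed(blocks), reversed(records)):
        r = blk.backward_relevance(rec, r, epsilon, compensate=compensate)

    rel = model.from_channels(r)[0]
    return RelevanceMap(
        relevance=rel,
        target_class=target,
        target_score=score,
        predicted_class=predicted,
        epsilon=epsilon,
        group=sample.group,
    )


def conservation_check(
    rmap: RelevanceMap,
    model: BalanceClassifier,
    sample: PreprocessedSample,
    tiny: float = 1e-9,
) -> float:
    """Relative conservation gap: |sum(input relevance) - target score|
    normalized by max(|score|, tiny).

    Exact (up to floating point) at the default epsilon = 0; the documented
    tolerance for the full trained network is 1e-2, with observed gaps around
    1e-6.
    """
    a = model.to_channels(sample.tensor[None]).astype(np.float64)
    _, _, _, logits = _folded_forward(model, a)
    score = float(logits[0, rmap.target_class])
    return abs(rmap.relevance.sum() - score) / max(abs(score), tiny)


def contribution_matrix(
    maps: list[RelevanceMap],
    level: int | None = None,
    aggregation: str = "mean_abs",
) -> ContributionMatrix:
    """Aggregate relevance maps into an axis-block x joint x frame matrix.

    Rows are ordered as axis blocks X (walking direction), Y (left-right),
    Z (up-down); within each block joints appear in ascending skeleton index.
    Columns are the 20 frames.  ``mean_abs`` (default) averages absolute
    relevance over the supplied maps and is non-negative; ``mean`` keeps the
    sign.
    """
    if not maps:
        raise ValueError("need at least one relevance map")
    shapes = {m.relevance.shape for m in maps}
    if len(shapes) > 1:
        raise ValueError(f"mixed relevance geometries: {shapes}")
    groups = {m.group for m in maps}
    if len(groups) > 1:
        raise ValueError(f"mixed joint groups: {groups}")
    if aggregation == "mean_abs":
        agg = np.mean([np.abs(m.relevance) for m in maps], axis=0)
    elif aggregation == "mean":
        agg = np.mean([m.relevance for m in maps], axis=0)
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")

    window, j, _ = agg.shape
    group_name = groups.pop()
    try:
        indices = joint_group(group_name).indices
        names = [Joint(i).name for i in indices]
    except KeyError:
        names = [f"J{k:02d}" for k in range(j)]
    # (window, J, 3) -> rows: axis-major, joint-minor; columns: frames
    matrix = agg.transpose(2, 1, 0).reshape(3 * j, window)
    labels = [f"{ax}_{name}" for ax in AXIS_NAMES for name in names]
    return ContributionMatrix(
        matrix=matrix, row_labels=labels, aggregation=aggregation, level=level,
    )
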