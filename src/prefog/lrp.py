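"""Epsilon layer-wise relevance propagation (eps-LRP) over the trained CNN.

The relevance of the explained class starts at its pre-softmax score (logit)
and is redistributed layer by layer down to the 101x3 input, following the
proportional rule

    R_i = sum_j z_ij / (sum_i' z_i'j + eps * sign(sum_i' z_i'j)) * R_j,
    z_ij = x_i * w_ij,

applied to dense layers, to convolutions via weight sharing, and to global
average pooling as a linear layer with uniform weights. Max-pooling routes
relevance winner-take-all to the recorded argmax (ties split equally); ReLU
passes relevance through unchanged. Each layer's bias enters the denominator;
the relevance share it absorbs is dropped and accumulated as the reported
bias-absorbed total, so conservation can be audited explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Conv1D, Dense, Dropout, GlobalAvgPool, MaxPool1D, Network, ReLU, Softmax
from .preprocessing import CLASS_ORDER, GaitCycle, N_SAMPLES

DEFAULT_EPSILON = 1e-4


class ZeroDenominatorError(ZeroDivisionError):
    """Raised when eps = 0 meets an exactly zero pre-activation sum."""

    def __init__(self):
        super().__init__(
            "relevance denominator is exactly zero at eps=0; use eps > 0"
        )


def _relevance_ratio(R_up, denom, eps: float):
    """R_up / stabilized denominator.

    A zero denominator carrying zero upstream relevance (a dead unit) has
    nothing to redistribute and contributes an exact 0 even at eps = 0; a
    zero denominator with nonzero relevance is rejected at eps = 0 because
    the rule is undefined there.
    """
    if eps < 0:
        raise ValueError("eps must be >= 0")
    R_up = np.asarray(R_up, dtype=float)
    denom = np.asarray(denom, dtype=float)
    if eps == 0.0:
        dead = denom == 0.0
        if np.any(dead & (R_up != 0.0)):
            raise ZeroDenominatorError()
        out = np.zeros_like(R_up)
        np.divide(R_up, denom, out=out, where=~dead)
        return out
    sign = np.where(denom >= 0.0, 1.0, -1.0)
    return R_up / (denom + eps * sign)


def layer_relevance_linear(x, W, b, R_up, eps: float):
    """Eps-rule through a dense map y_j = sum_i x_i W_ij + b_j.

    Returns ``(R, bias_absorbed)``: relevance attributed to the inputs and
    the total share absorbed by the bias terms (dropped from propagation).
    """
    x = np.asarray(x, dtype=float)
    W = np.asarray(W, dtype=float)
    b = np.zeros(W.shape[1]) if b is None else np.asarray(b, dtype=float)
    R_up = np.asarray(R_up, dtype=float)
    if x.shape[0] != W.shape[0] or R_up.shape[0] != W.shape[1]:
        raise ValueError("shapes of x, W and upstream relevance do not conform")
    z = x[:, None] * W  # (in, out)
    s = _relevance_ratio(R_up, z.sum(axis=0) + b, eps)
    R = z @ s
    bias_absorbed = float(b @ s)
    return R, bias_absorbed


def layer_relevance_pool(kind: str, x, R_up, eps: float):
    """Relevance through pooling.

    ``kind='max'``: x is (T, C) of pool inputs reshaped per window upstream;
    here x is one pooling window per output, i.e. (out_t, width, C), and R_up
    is (out_t, C). Winner-take-all with equal tie splitting.
    ``kind='gap'``: x is (T, C), R_up is (C,); treated as a linear layer with
    uniform weights 1/T under the eps-rule.
    """
    x = np.asarray(x, dtype=float)
    R_up = np.asarray(R_up, dtype=float)
    if kind == "max":
        maxval = x.max(axis=1, keepdims=True)
        mask = x == maxval
        if not np.all(mask.any(axis=1)):
            raise ValueError("pool assignment inconsistent with inputs")
        counts = mask.sum(axis=1, keepdims=True)
        return mask * (R_up[:, None, :] / counts)
    if kind == "gap":
        t = x.shape[0]
        return (x / t) * _relevance_ratio(R_up, x.mean(axis=0), eps)[None, :]
    raise ValueError(f"unknown pool kind {kind!r}")


@dataclass
class RelevanceMap:
    """Signed 101x3 input attribution for one cycle and one target class."""

    relevance: np.ndarray  # (101, 3), channels hip, knee, ankle
    target_class: str
    start_value: float  # pre-softmax score of the explained class
    bias_absorbed: float
    cycle_id: str | None = None

    @property
    def leakage_fraction(self) -> float:
        """(start - input relevance - bias-absorbed) / start; nan if start = 0."""
        if self.start_value == 0.0:
            return float("nan")
        return (
            self.start_value - float(self.relevance.sum()) - self.bias_absorbed
        ) / self.start_value


def lrp_epsilon(net: Network, cycle, target_class: str = "pre-FOG",
                eps: float = DEFAULT_EPSILON) -> RelevanceMap:
    """Propagate the target class's logit down to the input samples."""
    if target_class not in CLASS_ORDER:
        raise ValueError(f"unknown target class {target_class!r}; expected {CLASS_ORDER}")
    cycle_id = None
    if isinstance(cycle, GaitCycle):
        cycle_id = cycle.cycle_id
        values = cycle.values
    else:
        values = np.asarray(cycle, dtype=float)
    if values.ndim != 2:
        raise ValueError(f"expected a (T, C) cycle matrix, got shape {values.shape}")
    x = values[None]  # batch of one
    net.forward(x, train=False, record=True)
    target_idx = CLASS_ORDER.index(target_class)

    # locate the softmax head; relevance starts at the logit below it
    layers = net.recorded
    if not isinstance(layers[-1][0], Softmax):
        raise ValueError("expected the network to end in a softmax layer")
    logits = np.asarray(layers[-1][1][0]).ravel()
    start = float(logits[target_idx])
    R = np.zeros_like(logits)
    R[target_idx] = start
    bias_total = 0.0

    for layer, inp in reversed(layers[:-1]):
        xin = inp[0]
        if isinstance(layer, Dense):
            R, absorbed = layer_relevance_linear(
                np.asarray(xin).ravel(), layer.W, layer.b, np.asarray(R).ravel(), eps
            )
            bias_total += absorbed
        elif isinstance(layer, GlobalAvgPool):
            R = layer_relevance_pool("gap", xin, R, eps)
        elif isinstance(layer, MaxPool1D):
            w = layer.width
            out_t = xin.shape[0] // w
            windows = xin[: out_t * w].reshape(out_t, w, xin.shape[1])
            Rwin = layer_relevance_pool("max", windows, R, eps)
            Rfull = np.zeros_like(xin)
            Rfull[: out_t * w] = Rwin.reshape(out_t * w, xin.shape[1])
            R = Rfull
        elif isinstance(layer, Conv1D):
            R, absorbed = _conv_relevance(layer, xin, R, eps)
            bias_total += absorbed
        elif isinstance(layer, (ReLU, Dropout)):
            pass  # relevance passes through unchanged
        else:
            raise ValueError(f"no relevance rule for layer {type(layer).__name__}")
    return RelevanceMap(
        relevance=np.asarray(R).reshape(values.shape),
        target_class=target_class,
        start_value=start,
        bias_absorbed=bias_total,
        cycle_id=cycle_id,
    )


def _conv_relevance(layer: Conv1D, x, R_up, eps: float):
    """Eps-rule through a same-padded convolution via weight sharing.

    x: (T, C); R_up: (T, F). The denominator of each output unit is its
    pre-activation (patch sum plus bias).
    """
    t, c = x.shape
    k, pad = layer.kernel, layer.pad
    xp = np.pad(x, ((pad, pad), (0, 0)))
    pre = layer.forward(x[None], train=False)[0]  # (T, F), includes bias
    s = _relevance_ratio(R_up, pre, eps)  # (T, F)
    bias_absorbed = float((layer.b[None, :] * s).sum())
    # R_in[t] = x[t] * sum_{tau, f} W[f, t - tau + pad] * s[tau, f]
    c_acc = np.zeros_like(xp)
    sW = np.einsum("tf,fkc->tkc", s, layer.W)  # (T, k, C)
    for j in range(k):
        c_acc[j : j + t] += sW[:, j, :]
    R_in = xp * c_acc
    return R_in[pad : pad + t], bias_absorbed


def conservation_report(rmap: RelevanceMap, tol: float = 1e-4) -> dict:
    """Audit relevance conservation of one map.

    ``leakage`` isolates what neither the input relevance nor the bias terms
    account for (the eps stabilizer's share); ``conserved`` checks the strict
    input-level balance used for bias-free eps=0 runs. A zero start value is
    reported as undefined rather than an error.
    """
    total = float(rmap.relevance.sum())
    if rmap.start_value == 0.0:
        return {"undefined": True, "leakage": float("nan"), "conserved": False,
                "total_relevance": total}
    leakage = (rmap.start_value - total - rmap.bias_absorbed) / rmap.start_value
    rel_gap = abs(rmap.start_value - total) / abs(rmap.start_value)
    return {
        "undefined": False,
        "leakage": leakage,
        "conserved": bool(rel_gap < tol),
        "relative_gap": rel_gap,
        "total_relevance": total,
    }


@dataclass
class GroupAttribution:
    """Group-mean joint trajectories with the mean relevance overlay.

    Sign convention: positive relevance marks contribution toward the pre-FOG
    (freezing) class, negative toward functional gait.
    """

    name: str
    target_class: str
    mean_trajectory: np.ndarray  # (101, 3)
    sd_trajectory: np.ndarray  # (101, 3)
    mean_relevance: np.ndarray  # (101, 3)
    n_cycles: int


def aggregate_group_relevance(maps, cycles, name: str = "group",
                              per_subject: int | None = None,
                              seed: int = 0) -> GroupAttribution:
    """Average trajectories and relevance over a named group of cycles.

    ``maps`` and ``cycles`` are aligned sequences (one map per preprocessed
    cycle; all maps must explain the same class, and cycles excluded from
    attribution — unmatched FGCs — must not be passed in). When
    ``per_subject`` is given, each subject contributes at most that many
    cycles (seeded subsampling), the equal-contribution rule used for
    group-mean plots.
    """
    maps, cycles = list(maps), list(cycles)
    if not maps or len(maps) != len(cycles):
        raise ValueError("need equal, non-zero numbers of maps and cycles")
    targets = {m.target_class for m in maps}
    if len(targets) != 1:
        raise ValueError(f"maps explain different classes: {sorted(targets)}")
    if any(isinstance(c, GaitCycle) and not c.matched for c in cycles):
        raise ValueError("unmatched cycles are excluded from attribution analysis")

    idx = np.arange(len(maps))
    if per_subject is not None:
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([int(seed), 83])))
        keep = []
        subjects = np.array([
            c.subject_id if isinstance(c, GaitCycle) else "?" for c in cycles
        ], dtype=object)
        for s in sorted(set(subjects)):
            mine = idx[subjects == s]
            if len(mine) > per_subject:
                mine = rng.choice(mine, size=per_subject, replace=False)
            keep.extend(sorted(int(i) for i in mine))
        idx = np.array(keep, dtype=int)

    traj = np.stack([
        cycles[i].values if isinstance(cycles[i], GaitCycle) else np.asarray(cycles[i])
        for i in idx
    ])
    rel = np.stack([maps[i].relevance for i in idx])
    return GroupAttribution(
        name=name,
        target_class=maps[0].target_class,
        mean_trajectory=traj.mean(axis=0),
        sd_trajectory=traj.std(axis=0),
        mean_relevance=rel.mean(axis=0),
        n_cycles=len(idx),
    )


def relevance_to_frame(maps, cycles=None):
    """Long-format export: cycle_id, joint, cycle_percent, angle, relevance."""
    import pandas as pd

    joints = ("hip", "knee", "ankle")
    rows = []
    for i, m in enumerate(maps):
        values = None
        if cycles is not None:
            c = cycles[i]
            values = c.values if isinstance(c, GaitCycle) else np.asarray(c)
        for j, joint in enumerate(joints):
            rows.append(pd.DataFrame({
                "cycle_id": m.cycle_id or f"cycle{i}",
                "joint": joint,
                "cycle_percent": np.arange(N_SAMPLES),
                "angle": np.nan if values is None else values[:, j],
                "relevance": m.relevance[:, j],
            }))
    return pd.concat(rows, ignore_index=True)


def write_relevance(path, maps, cycles=None) -> None:
    """Write relevance maps as long-format CSV (one row per sample per joint)."""
    relevance_to_frame(maps, cycles).to_csv(path, index=False)


def plot_group_attribution(groups, path=None, title=None):
    """Render group-mean trajectories colorized by relevance (bipolar map).

    One row per group, one column per joint; the mean trajectory is drawn as
    a scatter colored red (toward pre-FOG) to blue (toward FGC) with a gray
    SD cloud, mirroring standard attribution-plot layouts.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = list(groups)
    joints = ("hip", "knee", "ankle")
    fig, axes = plt.subplots(len(groups), 3, figsize=(12, 3 * len(groups)),
                             squeeze=False)
    vmax = max(np.abs(g.mean_relevance).max() for g in groups) or 1.0
    t = np.arange(N_SAMPLES)
    for r, g in enumerate(groups):
        for c, joint in enumerate(joints):
            ax = axes[r][c]
            mu = g.mean_trajectory[:, c]
            sd = g.sd_trajectory[:, c]
            ax.fill_between(t, mu - sd, mu + sd, color="0.85")
            sc = ax.scatter(t, mu, c=g.mean_relevance[:, c], cmap="bwr",
                            vmin=-vmax, vmax=vmax, s=8)
            ax.set_title(f"{g.name}: {joint}")
            ax.set_xlabel("% gait cycle")
            if c == 0:
                ax.set_ylabel("rescaled angle")
    fig.colorbar(sc, ax=[a for row in axes for a in row], shrink=0.6,
                 label="relevance (red: pre-FOG, blue: FGC)")
    if title:
        fig.suptitle(title)
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
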