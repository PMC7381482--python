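"""Recurrent hub-and-spoke auto-associator and its feed-forward variant.

The network has 216 visible units -- a 40-unit name block, a 64-unit visual
block and a 112-unit verbal block -- bidirectionally connected to a hidden
"hub" layer, whose units are also recurrently connected to each other.
Every unit receives a fixed, untrainable bias input of -2.0.  Activation is
the logistic sigmoid and updates are synchronous: on each cycle every unit
recomputes its activation from the previous cycle's activations.

Processing an item clamps one visible block to the item's pattern for a
number of cycles (default 2), then lets the whole network settle freely
(default 5 further cycles).  Picture naming clamps the visual block and
reads the most active name unit above 0.5 after the 2 + 5 cycle protocol.

Training is backpropagation through time over the same 7-cycle unroll, with
cross-entropy targets applied to the visible units on every free cycle and
weights updated after every single pattern presentation (each epoch
presents every item three times: name, verbal and visual clamped).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.special import expit as sigmoid

from .patterns import N_NAME, N_UNITS, N_VISUAL, PatternSet

NO_RESPONSE = -1

NAME_SLICE = slice(0, N_NAME)
VISUAL_SLICE = slice(N_NAME, N_NAME + N_VISUAL)
VERBAL_SLICE = slice(N_NAME + N_VISUAL, N_UNITS)
BLOCK_SLICES = {"name": NAME_SLICE, "visual": VISUAL_SLICE,
                "verbal": VERBAL_SLICE}


@dataclass(frozen=True)
class HubConfig:
    n_name: int = N_NAME
    n_visual: int = N_VISUAL
    n_verbal: int = 112
    n_hidden: int = 64
    learning_rate: float = 0.001
    weight_decay: float = 0.001
    epochs: int = 1000
    bias_value: float = -2.0  # fixed, untrainable
    settle_cycles_clamped: int = 2
    settle_cycles_free: int = 5
    target_cycles: int = 5  # targets applied on the last N unrolled cycles
    init_weight_scale: float = 0.5

    @property
    def n_visible(self) -> int:
        return self.n_name + self.n_visual + self.n_verbal

    @property
    def unroll_cycles(self) -> int:
        return self.settle_cycles_clamped + self.settle_cycles_free

    def validate(self) -> None:
        for f in ("n_name", "n_visual", "n_verbal", "n_hidden"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")
        if self.settle_cycles_clamped < 0 or self.settle_cycles_free < 0:
            raise ValueError("cycle counts must be non-negative")


@dataclass(frozen=True)
class ClampSpec:
    """Which visible blocks are clamped, and to what binary values.

    ``values`` maps block name -> array of the block's width (or a batch
    thereof).  Clamped blocks retain their values on every clamped cycle.
    """

    values: dict  # block name -> (width,) or (batch, width) array

    def __post_init__(self):
        for block in self.values:
            if block not in BLOCK_SLICES:
                raise ValueError(f"unknown visible block {block!r}")

    @staticmethod
    def visual(v: np.ndarray) -> "ClampSpec":
        return ClampSpec({"visual": np.asarray(v, dtype=float)})

    @staticmethod
    def name(v: np.ndarray) -> "ClampSpec":
        return ClampSpec({"name": np.asarray(v, dtype=float)})

    @staticmethod
    def verbal(v: np.ndarray) -> "ClampSpec":
        return ClampSpec({"verbal": np.asarray(v, dtype=float)})


@dataclass
class SettleTrace:
    visible: np.ndarray  # (cycles + 1, ..., n_visible)
    hidden: np.ndarray   # (cycles + 1, ..., n_hidden)

    @property
    def final_visible(self) -> np.ndarray:
        return self.visible[-1]

    @property
    def final_hidden(self) -> np.ndarray:
        return self.hidden[-1]


class HubNet:
    """Weights + processing for the recurrent (or feed-forward) hub model."""

    def __init__(self, config: HubConfig, weights: dict[str, np.ndarray],
                 feedforward: bool = False):
        config.validate()
        self.config = config
        self.weights = weights
        self.feedforward = feedforward
        expected = {"W_vh", "W_hv"} | (set() if feedforward else {"W_hh"})
        if set(weights) != expected:
            raise ValueError(f"expected weight matrices {sorted(expected)}")

    # ablation removes a hub unit's *outgoing* connections (axis-0 rows)
    @property
    def ablatable(self) -> dict:
        if self.feedforward:
            return {"hidden": [("W_hv", 0)]}
        return {"hidden": [("W_hh", 0), ("W_hv", 0)]}

    @property
    def bias(self) -> float:
        return self.config.bias_value

    def copy(self) -> "HubNet":
        return HubNet(self.config, {k: v.copy() for k, v in self.weights.items()},
                      self.feedforward)

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        import json
        path = Path(path)
        np.savez(path, **self.weights)
        meta = {"schema": "lesionlab-hubnet-v1",
                "feedforward": self.feedforward,
                "config": self.config.__dict__}
        path.with_suffix(".json").write_text(json.dumps(meta))

    @staticmethod
    def load(path: str | Path) -> "HubNet":
        import json
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        with np.load(path if path.suffix else path.with_suffix(".npz")) as z:
            weights = {k: z[k] for k in z.files}
        return HubNet(HubConfig(**meta["config"]), weights,
                      meta["feedforward"])


def init_network(config: HubConfig = HubConfig(), seed: int = 0,
                 feedforward: bool = False) -> HubNet:
    """Initialise with uniform weights in +/- init_weight_scale."""
    config.validate()
    rng = np.random.default_rng(seed)
    s = config.init_weight_scale
    nv, nh = config.n_visible, config.n_hidden
    weights = {"W_vh": rng.uniform(-s, s, (nv, nh))}
    if not feedforward:
        weights["W_hh"] = rng.uniform(-s, s, (nh, nh))
    weights["W_hv"] = rng.uniform(-s, s, (nh, nv))
    return HubNet(config, weights, feedforward)


def make_feedforward_variant(config: HubConfig = HubConfig(),
                             seed: int = 0) -> HubNet:
    """The feed-forward auto-associator comparison network (216-64-216).

    A single input->hidden->output pass with no recurrence; compatible with
    all lesion operators except per-cycle activation noise.
    """
    return init_network(config, seed, feedforward=True)


def _apply_clamp(v: np.ndarray, clamp: ClampSpec | None) -> None:
    if clamp is None:
        return
    for block, vals in clamp.values.items():
        v[..., BLOCK_SLICES[block]] = vals


def settle(net: HubNet, clamp: ClampSpec | None,
           cycles_clamped: int | None = None,
           cycles_free: int | None = None) -> SettleTrace:
    """Synchronously circulate activation, clamped then free.

    Accepts batched clamp values (leading batch axis).  Activations start
    at zero (clamped blocks at their clamped values), and every unit
    receives the fixed -2.0 bias on each cycle.
    """
    cfg = net.config
    if cycles_clamped is None:
        cycles_clamped = cfg.settle_cycles_clamped
    if cycles_free is None:
        cycles_free = cfg.settle_cycles_free
    if cycles_clamped < 0 or cycles_free < 0:
        raise ValueError("cycle counts must be non-negative")

    if net.feedforward:
        raise ValueError("feed-forward variant does not settle; use process()")

    batch_shape = ()
    if clamp is not None:
        for vals in clamp.values.values():
            vals = np.asarray(vals)
            if vals.ndim > 1:
                batch_shape = vals.shape[:-1]
    v = np.zeros(batch_shape + (cfg.n_visible,))
    h = np.zeros(batch_shape + (cfg.n_hidden,))
    _apply_clamp(v, clamp)

    W_vh, W_hh, W_hv = (net.weights[k] for k in ("W_vh", "W_hh", "W_hv"))
    b = net.bias
    total = cycles_clamped + cycles_free
    vs, hs = [v.copy()], [h.copy()]
    for t in range(1, total + 1):
        h_new = sigmoid(v @ W_vh + h @ W_hh + b)
        v_new = sigmoid(h @ W_hv + b)
        if t <= cycles_clamped:
            _apply_clamp(v_new, clamp)
        v, h = v_new, h_new
        vs.append(v.copy())
        hs.append(h.copy())
    return SettleTrace(np.stack(vs), np.stack(hs))


def process_feedforward(net: HubNet, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Single forward pass of the feed-forward variant: returns (hidden, output)."""
    h = sigmoid(x @ net.weights["W_vh"] + net.bias)
    out = sigmoid(h @ net.weights["W_hv"] + net.bias)
    return h, out


def name_response(net: HubNet, visual_vector: np.ndarray):
    """Picture naming: clamp the visual block, settle 2 + 5, read name units.

    Returns the index of the most active name unit if it exceeds 0.5
    (lowest index on ties), else :data:`NO_RESPONSE`.  A batch of visual
    vectors yields an array of responses.
    """
    visual_vector = np.asarray(visual_vector, dtype=float)
    if visual_vector.shape[-1] != net.config.n_visual:
        raise ValueError(
            f"visual vector must have length {net.config.n_visual}")
    trace = settle(net, ClampSpec.visual(visual_vector))
    names = trace.final_visible[..., NAME_SLICE]
    best = np.argmax(names, axis=-1)
    peak = np.max(names, axis=-1)
    resp = np.where(peak > 0.5, best, NO_RESPONSE)
    return resp if resp.ndim else int(resp)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _present(net: HubNet, x: np.ndarray, clamp_block: str) -> float:
    """One pattern presentation: unrolled settle, BPTT, online update.

    Returns the summed cross-entropy over the target cycles (for loss
    monitoring).  Bias weights are constants and receive no update.
    """
    cfg = net.config
    W_vh, W_hh, W_hv = (net.weights[k] for k in ("W_vh", "W_hh", "W_hv"))
    b = cfg.bias_value
    T = cfg.unroll_cycles
    n_clamped = cfg.settle_cycles_clamped
    target_from = T - cfg.target_cycles + 1
    sl = BLOCK_SLICES[clamp_block]

    v = np.zeros(cfg.n_visible)
    v[sl] = x[sl]
    h = np.zeros(cfg.n_hidden)
    vs, hs = [v], [h]
    clamp_masks = []
    for t in range(1, T + 1):
        h_new = sigmoid(vs[-1] @ W_vh + hs[-1] @ W_hh + b)
        v_new = sigmoid(hs[-1] @ W_hv + b)
        clamped = t <= n_clamped
        if clamped:
            v_new = v_new.copy()
            v_new[sl] = x[sl]
        clamp_masks.append(clamped)
        vs.append(v_new)
        hs.append(h_new)

    V = np.stack(vs)  # (T+1, n_visible)
    H = np.stack(hs)

    # backward pass through the unrolled cycles
    GV = np.zeros_like(V)  # dL/d netv_t
    GH = np.zeros_like(H)  # dL/d neth_t
    loss = 0.0
    eps = 1e-12
    for t in range(T, 0, -1):
        gv = np.zeros(cfg.n_visible)
        if t >= target_from:
            gv += V[t] - x  # cross-entropy: delta on net input directly
            loss -= float(np.sum(x * np.log(V[t] + eps)
                                 + (1 - x) * np.log(1 - V[t] + eps)))
        if t < T:
            # v_t feeds neth_{t+1}; clamped components were overwritten
            dv = GH[t + 1] @ W_vh.T
            if clamp_masks[t - 1]:
                dv = dv.copy()
                dv[sl] = 0.0
            gv += dv * V[t] * (1 - V[t])
            gh = (GH[t + 1] @ W_hh.T + GV[t + 1] @ W_hv.T) * H[t] * (1 - H[t])
            GH[t] = gh
        GV[t] = gv

    lr, decay = cfg.learning_rate, cfg.weight_decay
    dW_vh = V[:-1].T @ GH[1:]
    dW_hh = H[:-1].T @ GH[1:]
    dW_hv = H[:-1].T @ GV[1:]
    W_vh -= lr * (dW_vh + decay * W_vh)
    W_hh -= lr * (dW_hh + decay * W_hh)
    W_hv -= lr * (dW_hv + decay * W_hv)
    return loss


def train(net: HubNet, ps: PatternSet, epochs: int | None = None,
          seed: int = 0, loss_trace: list | None = None) -> HubNet:
    """Train in place (and return) the network on a pattern set.

    Each epoch presents every item three times -- name, verbal and visual
    clamped -- in an order shuffled with ``seed``; weights update after
    every presentation.  ``epochs=0`` leaves the network unchanged.
    """
    if net.feedforward:
        return train_feedforward(net, ps, epochs, seed, loss_trace)
    cfg = net.config
    if ps.vectors.shape[1] != cfg.n_visible:
        raise ValueError("pattern width does not match network visible size")
    if epochs is None:
        epochs = cfg.epochs
    rng = np.random.default_rng(seed)
    x = ps.vectors.astype(float)
    schedule = [(i, block) for i in range(len(x))
                for block in ("name", "verbal", "visual")]
    for _ in range(epochs):
        order = rng.permutation(len(schedule))
        total = 0.0
        for k in order:
            i, block = schedule[k]
            total += _present(net, x[i], block)
        if loss_trace is not None:
            loss_trace.append(total)
    return net


def train_feedforward(net: HubNet, ps: PatternSet, epochs: int | None = None,
                      seed: int = 0, loss_trace: list | None = None) -> HubNet:
    """Plain backprop auto-association training for the feed-forward variant."""
    cfg = net.config
    if epochs is None:
        epochs = cfg.epochs
    rng = np.random.default_rng(seed)
    x = ps.vectors.astype(float)
    W_vh, W_hv = net.weights["W_vh"], net.weights["W_hv"]
    lr, decay, b = cfg.learning_rate, cfg.weight_decay, cfg.bias_value
    eps = 1e-12
    for _ in range(epochs):
        total = 0.0
        for i in rng.permutation(len(x)):
            xi = x[i]
            h = sigmoid(xi @ W_vh + b)
            out = sigmoid(h @ W_hv + b)
            total -= float(np.sum(xi * np.log(out + eps)
                                  + (1 - xi) * np.log(1 - out + eps)))
            gout = out - xi
            gh = (gout @ W_hv.T) * h * (1 - h)
            W_hv -= lr * (np.outer(h, gout) + decay * W_hv)
            W_vh -= lr * (np.outer(xi, gh) + decay * W_vh)
        if loss_trace is not None:
            loss_trace.append(total)
    return net


def max_unit_error(net: HubNet, ps: PatternSet) -> float:
    """Max |activation - target| over all visible units and items.

    Each item is settled under the 2 + 5 naming protocol (visual clamp);
    errors are measured at the final cycle against the full 216-unit target.
    """
    trace = settle(net, ClampSpec.visual(ps.visual_block.astype(float)))
    return float(np.abs(trace.final_visible - ps.vectors).max())


def naming_accuracy(net: HubNet, ps: PatternSet,
                    by_domain: bool = False):
    """Proportion of the 48 items whose visual input evokes the right name."""
    resp = name_response(net, ps.visual_block.astype(float))
    correct = resp == ps.name_units
    if not by_domain:
        return float(np.mean(correct))
    doms = np.array(ps.domains)
    return {d: float(np.mean(correct[doms == d]))
            for d in ("animal", "artefact")}
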