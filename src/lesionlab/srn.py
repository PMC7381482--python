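"""Simple recurrent network for routine sequential action selection.

An Elman-style network maps a featural description of the fixated and held
objects (plus a transient instruction cue on the first step) to a discrete
action, with a context layer holding the previous step's hidden state.  It
is trained with backpropagation through time on the six beverage
sequences, teacher-forced through the environment, together with the
single-step background pairs; at test time the selected action (argmax of
the output layer) is executed in the environment, whose new state becomes
the next input.

Damage is applied either to the weight matrices (severing, noise, unit
removal, scaling -- see :mod:`lesionlab.lesions`) or by injecting Gaussian
noise into the context activations on every processing step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
from scipy.special import expit as sigmoid

from . import beverage as bev
from .lesions import ActivationNoise
from .seeds import derive_seed


@dataclass(frozen=True)
class SRNConfig:
    n_input: int = bev.INPUT_WIDTH
    n_hidden: int = 50  # context width equals hidden width
    n_output: int = bev.OUTPUT_WIDTH
    epochs: int = 20000  # training stops early once all six sequences are exact
    learning_rate: float = 0.5
    momentum: float = 0.9
    init_weight_scale: float = 0.5
    context_init: float = 0.5
    max_run_steps: int = 60
    check_every: int = 100  # reproduction check interval during training
    stop_loss: float = 1.0  # stop only once total loss is also below this

    def validate(self) -> None:
        if min(self.n_input, self.n_hidden, self.n_output) <= 0:
            raise ValueError("layer sizes must be positive")


class SRNNet:
    """Weight matrices, biases and processing for the action-selection SRN."""

    def __init__(self, config: SRNConfig, weights: dict[str, np.ndarray],
                 biases: dict[str, np.ndarray]):
        config.validate()
        self.config = config
        self.weights = weights  # W_ih, W_ch, W_ho (lesionable)
        self.biases = biases    # b_h, b_o (exempt from damage)

    @property
    def ablatable(self) -> dict:
        # removing a context unit severs all its outgoing connections
        return {"context": [("W_ch", 0)]}

    def copy(self) -> "SRNNet":
        return SRNNet(self.config,
                      {k: v.copy() for k, v in self.weights.items()},
                      {k: v.copy() for k, v in self.biases.items()})

    def step_forward(self, x: np.ndarray, context: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
        """One processing step: returns (hidden, output activations)."""
        h = sigmoid(x @ self.weights["W_ih"] + context @ self.weights["W_ch"]
                    + self.biases["b_h"])
        z = h @ self.weights["W_ho"] + self.biases["b_o"]
        return h, _softmax(z)

    def save(self, path) -> None:
        import json
        from pathlib import Path
        path = Path(path)
        np.savez(path, **self.weights, **self.biases)
        meta = {"schema": "lesionlab-srn-v1", "config": self.config.__dict__}
        path.with_suffix(".json").write_text(json.dumps(meta))

    @staticmethod
    def load(path) -> "SRNNet":
        import json
        from pathlib import Path
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        with np.load(path if path.suffix else path.with_suffix(".npz")) as z:
            weights = {k: z[k] for k in ("W_ih", "W_ch", "W_ho")}
            biases = {k: z[k] for k in ("b_h", "b_o")}
        return SRNNet(SRNConfig(**meta["config"]), weights, biases)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def init_srn(config: SRNConfig = SRNConfig(), seed: int = 0) -> SRNNet:
    config.validate()
    rng = np.random.default_rng(seed)
    s = config.init_weight_scale
    ni, nh, no = config.n_input, config.n_hidden, config.n_output
    weights = {"W_ih": rng.uniform(-s, s, (ni, nh)),
               "W_ch": rng.uniform(-s, s, (nh, nh)),
               "W_ho": rng.uniform(-s, s, (nh, no))}
    biases = {"b_h": np.zeros(nh), "b_o": np.zeros(no)}
    return SRNNet(config, weights, biases)


# ---------------------------------------------------------------------------
# Training data: teacher-forced input/target tensors per sequence
# ---------------------------------------------------------------------------

def _sequence_tensors(seq: bev.TaskSequence) -> tuple[np.ndarray, np.ndarray]:
    states, anomalies = bev.replay(seq)
    assert anomalies == 0
    T = len(seq.actions)
    X = np.zeros((T, bev.INPUT_WIDTH))
    Y = np.zeros((T, bev.OUTPUT_WIDTH))
    for t, a in enumerate(seq.actions):
        instr = seq.instruction if t == 0 else None
        X[t], Y[t] = bev.encode_io(states[t], a, instr)
    return X, Y


def _background_tensors(corpus: bev.TaskCorpus) -> tuple[np.ndarray, np.ndarray]:
    n = len(corpus.background)
    X = np.zeros((n, bev.INPUT_WIDTH))
    Y = np.zeros((n, bev.OUTPUT_WIDTH))
    for i, (state, action) in enumerate(corpus.background):
        X[i], Y[i] = bev.encode_io(state, action)
    return X, Y


class TrainingDivergence(RuntimeError):
    """Raised when the training loss becomes non-finite."""


def train_srn(config: SRNConfig | None = None,
              corpus: bev.TaskCorpus | None = None,
              seed: int = 0,
              loss_trace: list | None = None) -> SRNNet:
    """Train an SRN on the six sequences plus the background set.

    Full-batch backpropagation through time with momentum; sequences of
    equal length are processed as a batch and the background pairs as a
    single-step batch.  Training runs for at most ``config.epochs`` epochs
    but stops as soon as the network reproduces all six sequences exactly
    in free-running mode (checked every ``check_every`` epochs).
    """
    if config is None:
        config = SRNConfig()
    if corpus is None:
        corpus, _ = bev.build_corpus()
    net = init_srn(config, seed)

    groups = []  # (X (B,T,ni), Y (B,T,no)) per equal-length group
    for seqs in (corpus.coffee, corpus.tea):
        Xs, Ys = zip(*(_sequence_tensors(s) for s in seqs))
        groups.append((np.stack(Xs), np.stack(Ys)))
    Xb, Yb = _background_tensors(corpus)
    groups.append((Xb[:, None, :], Yb[:, None, :]))
    total_steps = sum(X.shape[0] * X.shape[1] for X, _ in groups)

    lr, mom = config.learning_rate, config.momentum
    W = net.weights
    vel = {k: np.zeros_like(w) for k, w in W.items()}
    vel["b_h"] = np.zeros_like(net.biases["b_h"])
    vel["b_o"] = np.zeros_like(net.biases["b_o"])

    for epoch in range(config.epochs):
        grads = {k: np.zeros_like(v) for k, v in vel.items()}
        loss = 0.0
        for X, Y in groups:
            loss += _bptt_group(net, X, Y, grads)
        if not np.isfinite(loss):
            raise TrainingDivergence(f"non-finite loss at epoch {epoch}")
        if loss_trace is not None:
            loss_trace.append(loss)
        for k in grads:
            g = grads[k] / total_steps
            vel[k] = mom * vel[k] - lr * g
            if k in W:
                W[k] += vel[k]
            else:
                net.biases[k] += vel[k]
        if (epoch + 1) % config.check_every == 0:
            if loss < config.stop_loss and reproduces_all_sequences(net, corpus):
                break
    return net


def _bptt_group(net: SRNNet, X: np.ndarray, Y: np.ndarray,
                grads: dict) -> float:
    """Accumulate BPTT gradients for one batch of equal-length sequences."""
    cfg = net.config
    W_ih, W_ch, W_ho = (net.weights[k] for k in ("W_ih", "W_ch", "W_ho"))
    b_h, b_o = net.biases["b_h"], net.biases["b_o"]
    B, T, _ = X.shape
    H = np.zeros((B, T, cfg.n_hidden))
    C = np.zeros((B, T, cfg.n_hidden))
    P = np.zeros((B, T, cfg.n_output))
    context = np.full((B, cfg.n_hidden), cfg.context_init)
    for t in range(T):
        C[:, t] = context
        h = sigmoid(X[:, t] @ W_ih + context @ W_ch + b_h)
        P[:, t] = _softmax(h @ W_ho + b_o)
        H[:, t] = h
        context = h
    eps = 1e-12
    loss = -float(np.sum(Y * np.log(P + eps)))

    GZ = P - Y  # dL/d output net input (softmax + cross-entropy)
    gh_next = np.zeros((B, cfg.n_hidden))
    GH = np.zeros((B, T, cfg.n_hidden))
    for t in range(T - 1, -1, -1):
        gh = (GZ[:, t] @ W_ho.T + gh_next @ W_ch.T) * H[:, t] * (1 - H[:, t])
        GH[:, t] = gh
        gh_next = gh
    flatX = X.reshape(B * T, -1)
    flatH = H.reshape(B * T, -1)
    flatC = C.reshape(B * T, -1)
    flatGH = GH.reshape(B * T, -1)
    flatGZ = GZ.reshape(B * T, -1)
    grads["W_ih"] += flatX.T @ flatGH
    grads["W_ch"] += flatC.T @ flatGH
    grads["W_ho"] += flatH.T @ flatGZ
    grads["b_h"] += flatGH.sum(axis=0)
    grads["b_o"] += flatGZ.sum(axis=0)
    return loss


def train_cohort(n_networks: int = 12, config: SRNConfig | None = None,
                 corpus: bev.TaskCorpus | None = None,
                 master_seed: int = 0) -> list[SRNNet]:
    """Train a sample of networks differing only in initial random weights."""
    if corpus is None:
        corpus, _ = bev.build_corpus()
    return [train_srn(config, corpus, derive_seed(master_seed, "srn-init", i))
            for i in range(n_networks)]


# ---------------------------------------------------------------------------
# Episode generation
# ---------------------------------------------------------------------------

@dataclass
class EpisodeTrace:
    """One free-running episode of a (possibly damaged) network."""

    task: str
    cream_first: bool
    sugar_source: str
    actions: list[str]
    anomalies: list[bool]
    hidden: np.ndarray  # (steps, n_hidden)
    contexts: np.ndarray  # (steps, n_hidden) context actually used per step
    noise_sigma: float = 0.0
    seed: int | None = None

    @property
    def n_steps(self) -> int:
        return len(self.actions)

    def to_json(self) -> str:
        """One JSON line per episode (actions + metadata, no activations)."""
        import json
        return json.dumps({
            "task": self.task, "cream_first": self.cream_first,
            "sugar_source": self.sugar_source, "actions": self.actions,
            "anomalies": self.anomalies, "noise_sigma": self.noise_sigma,
            "seed": self.seed})


def write_traces(path, traces: list["EpisodeTrace"]) -> None:
    """Write episodes as JSON lines, one per episode."""
    from pathlib import Path
    Path(path).write_text("".join(t.to_json() + "\n" for t in traces))


def run_episode(net: SRNNet, task: str, sugar_source: str = "packet",
                cream_first: bool = False,
                injector: ActivationNoise | None = None,
                seed: int | None = None,
                max_steps: int | None = None) -> EpisodeTrace:
    """Free-run the network in the environment until say_done or the cap.

    The context starts at ``context_init`` and is the previous hidden state
    plus, when an injector is supplied, zero-mean Gaussian noise on every
    processing step.  Without an injector the run is fully deterministic.
    """
    cfg = net.config
    if max_steps is None:
        max_steps = cfg.max_run_steps
    if injector is not None and seed is not None:
        injector.reset(seed)
    bowl_open = task == "tea" and sugar_source == "bowl"
    state = bev.initial_state(sugar_source, bowl_open)
    instr = bev.instruction_vector(task, cream_first)
    context = np.full(cfg.n_hidden, cfg.context_init)
    actions, anomalies, hs, cs = [], [], [], []
    for t in range(max_steps):
        if injector is not None:
            context = injector(context)
        x = bev.encode_input(state, instr if t == 0 else None)
        h, p = net.step_forward(x, context)
        action = bev.ACTIONS[int(np.argmax(p))]
        state, bad = bev.step(state, action)
        actions.append(action)
        anomalies.append(bool(bad))
        hs.append(h)
        cs.append(context)
        context = h
        if state.done:
            break
    return EpisodeTrace(task, cream_first, sugar_source, actions, anomalies,
                        np.array(hs), np.array(cs),
                        injector.sigma if injector else 0.0, seed)


def valid_realizations(corpus: bev.TaskCorpus, task: str,
                       sugar_source: str | None = None) -> list[tuple[str, ...]]:
    """All target action strings for a task, optionally per scenario."""
    return [s.actions for s in corpus.sequences
            if s.task == task and (sugar_source is None
                                   or s.sugar_source == sugar_source)]


def episode_correct(trace: EpisodeTrace, corpus: bev.TaskCorpus) -> bool:
    """An episode is correct if it exactly matches any valid realization
    of its task compatible with the scenario's sugar source (legitimate
    sugar/cream order variation is not an error)."""
    return tuple(trace.actions) in set(
        valid_realizations(corpus, trace.task, trace.sugar_source))


def reproduces_all_sequences(net: SRNNet, corpus: bev.TaskCorpus) -> bool:
    """True when free runs reproduce every one of the six target sequences."""
    for seq in corpus.sequences:
        trace = run_episode(net, seq.task, seq.sugar_source, seq.cream_first)
        if tuple(trace.actions) != seq.actions:
            return False
    return True
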