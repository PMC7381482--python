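"""The five damage operators applied to trained networks.

Each operator takes an intact network, a single severity parameter and (for
the stochastic kinds) a seed, and returns a damaged copy together with a
:class:`LesionRecord` that replays the identical lesion.  Bias weights are
never touched by any operator.

Networks are duck-typed: they must expose ``weights`` (an ordered dict of
named non-bias weight matrices), ``copy()``, and -- for unit ablation -- an
``ablatable`` mapping from layer name to a list of ``(matrix_name, axis)``
pairs identifying each unit's outgoing connections.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

KINDS = ("sever", "perturb_weights", "ablate_units", "scale_weights",
         "activation_noise")


@dataclass(frozen=True)
class LesionRecord:
    """Metadata sufficient to reproduce a lesion from the intact network."""

    kind: str
    severity: float
    seed: int | None = None
    target: tuple[str, ...] | None = None  # matrix names, or (layer,) for ablation
    distribution: str = "uniform"  # perturb_weights only

    def apply(self, net):
        """Re-apply this lesion to an intact network; returns the damaged copy."""
        if self.kind == "sever":
            return sever(net, self.severity, self.seed, target=self.target)[0]
        if self.kind == "perturb_weights":
            return perturb_weights(net, self.severity, self.seed,
                                   target=self.target,
                                   distribution=self.distribution)[0]
        if self.kind == "ablate_units":
            layer = self.target[0] if self.target else None
            return ablate_units(net, self.severity, self.seed, layer=layer)[0]
        if self.kind == "scale_weights":
            return scale_weights(net, self.severity)[0]
        raise ValueError(f"cannot replay lesion kind {self.kind!r}")

    def to_json(self) -> str:
        return json.dumps({
            "kind": self.kind, "severity": self.severity, "seed": self.seed,
            "target": list(self.target) if self.target else None,
            "distribution": self.distribution,
        })

    @staticmethod
    def from_json(s: str) -> "LesionRecord":
        d = json.loads(s)
        return LesionRecord(d["kind"], d["severity"], d["seed"],
                            tuple(d["target"]) if d["target"] else None,
                            d.get("distribution", "uniform"))


def _target_names(net, target: Sequence[str] | None) -> list[str]:
    names = list(net.weights) if target is None else list(target)
    for n in names:
        if n not in net.weights:
            raise KeyError(f"network has no weight matrix {n!r}")
    return names


def sever(net, q: float, seed: int | None = None, *,
          target: Sequence[str] | None = None):
    """Zero each targeted weight independently with probability ``q``.

    Equivalent to multiplying each weight by a Bernoulli(1 - q) variable.
    A single pooled random stream covers all targeted matrices in their
    declared order, so severing is exchangeable across matrices.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"severing probability q={q} outside [0, 1]")
    damaged = net.copy()
    rng = np.random.default_rng(seed)
    names = _target_names(net, target)
    for n in names:
        w = damaged.weights[n]
        w *= rng.random(w.shape) >= q
    return damaged, LesionRecord("sever", q, seed, tuple(names))


def perturb_weights(net, r: float, seed: int | None = None, *,
                    target: Sequence[str] | None = None,
                    distribution: str = "uniform"):
    """Add independent zero-mean noise to every targeted weight.

    ``distribution="uniform"`` adds U(-r, +r) noise (the semantic case
    study's grid); ``"gaussian"`` adds N(0, r^2) noise (used for the
    recurrent weights of the action-selection network).
    """
    if r <= 0:
        raise ValueError(f"noise parameter r={r} must be positive")
    if distribution not in ("uniform", "gaussian"):
        raise ValueError(f"unknown noise distribution {distribution!r}")
    damaged = net.copy()
    rng = np.random.default_rng(seed)
    names = _target_names(net, target)
    for n in names:
        w = damaged.weights[n]
        if distribution == "uniform":
            w += rng.uniform(-r, r, w.shape)
        else:
            w += rng.normal(0.0, r, w.shape)
    return damaged, LesionRecord("perturb_weights", r, seed, tuple(names),
                                 distribution)


def ablate_units(net, p: float, seed: int | None = None, *,
                 layer: str | None = None):
    """Remove each unit of a hidden/context layer with probability ``p``.

    Removal zeroes all of the unit's outgoing connections (incoming weights
    are retained), which is exactly equivalent to severing that unit's
    output connections.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"ablation probability p={p} outside [0, 1]")
    if layer is None:
        layer = next(iter(net.ablatable))
    if layer not in net.ablatable:
        raise KeyError(f"network has no ablatable layer {layer!r}")
    damaged = net.copy()
    rng = np.random.default_rng(seed)
    outgoing = net.ablatable[layer]
    n_units = damaged.weights[outgoing[0][0]].shape[outgoing[0][1]]
    removed = rng.random(n_units) < p
    for name, axis in outgoing:
        w = damaged.weights[name]
        if axis == 0:
            w[removed, :] = 0.0
        else:
            w[:, removed] = 0.0
    return damaged, LesionRecord("ablate_units", p, seed, (layer,))


def scale_weights(net, s: float):
    """Multiply every non-bias weight by a fixed factor ``s`` in (0, 1].

    Deterministic: no seed and no replicates needed.  Factors above 1 are
    rejected as outside the damage regime.
    """
    if not 0.0 < s <= 1.0:
        raise ValueError(f"scaling factor s={s} outside (0, 1]")
    damaged = net.copy()
    for w in damaged.weights.values():
        w *= s
    return damaged, LesionRecord("scale_weights", s)


@dataclass
class ActivationNoise:
    """Per-step injector adding N(0, sigma^2) noise to context activations.

    The injector carries its own RNG; reseed (or recreate) it to reproduce a
    run.  With sigma = 0 it is an exact no-op, so damaged and intact runs
    are bit-identical.
    """

    sigma: float
    seed: int | None = None
    rng: np.random.Generator = field(init=False, repr=False)

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError(f"activation-noise SD sigma={self.sigma} negative")
        self.reset()

    def reset(self, seed: int | None = None) -> None:
        if seed is not None:
            self.seed = seed
        self.rng = np.random.default_rng(self.seed)

    def __call__(self, activations: np.ndarray) -> np.ndarray:
        if self.sigma == 0:
            return activations
        return activations + self.rng.normal(0.0, self.sigma, activations.shape)


def activation_noise(sigma: float, seed: int | None = None) -> ActivationNoise:
    """Build a context activation-noise injector (the fifth damage kind)."""
    return ActivationNoise(sigma, seed)
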