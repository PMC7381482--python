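"""Case-study analyses for the lesioned hub-and-spoke model.

Implements the full damage-grid experiment: each trained network is damaged
repeatedly at every severity level of each damage kind, picture naming is
scored separately for the animal and artefact domains, and the domain
difference is summarised as the signed area between the two
naming-accuracy curves (positive = artefact advantage).  Also provides the
attractor-density, weight-distribution and output-error analyses used to
interpret the dissociations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist

from . import lesions
from .hub import HubNet, ClampSpec, settle, naming_accuracy
from .patterns import PatternSet, TemplateProfile, generate_patterns
from .seeds import derive_seed

DOMAINS = ("animal", "artefact")
STOCHASTIC_KINDS = ("sever", "perturb_weights", "ablate_units")


@dataclass(frozen=True)
class DamageGrid:
    """One damage kind with its ordered severity ladder.

    The default grids reproduce the published severity ladders exactly:
    severing 2.5%..50% in 2.5% steps, uniform weight noise with half-range
    0.05..1.00 in 0.05 steps, unit ablation probability 0.00..1.00 in 0.05
    steps, and weight scaling 0.75 down to 0.55 in 0.01 steps.
    """

    kind: str
    levels: tuple
    lesions_per_level: int = 10

    def __post_init__(self):
        if self.kind not in lesions.KINDS:
            raise ValueError(f"unknown damage kind {self.kind!r}")
        diffs = np.diff(self.levels)
        if len(self.levels) > 1 and not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError("severity levels must be strictly ordered")


def default_grid(kind: str, lesions_per_level: int = 10) -> DamageGrid:
    if kind == "sever":
        levels = np.arange(1, 21) * 0.025  # 2.5% .. 50%
    elif kind == "perturb_weights":
        levels = np.arange(1, 21) * 0.05  # 0.05 .. 1.00
    elif kind == "ablate_units":
        levels = np.arange(0, 21) * 0.05  # 0.00 .. 1.00
    elif kind == "scale_weights":
        levels = np.round(np.arange(75, 54, -1) * 0.01, 2)  # 0.75 .. 0.55
    else:
        raise ValueError(f"no default grid for damage kind {kind!r}")
    return DamageGrid(kind, tuple(np.round(levels, 6)), lesions_per_level)


def default_grids(lesions_per_level: int = 10) -> list[DamageGrid]:
    return [default_grid(k, lesions_per_level)
            for k in ("sever", "perturb_weights", "ablate_units",
                      "scale_weights")]


def _lesion(net: HubNet, kind: str, severity: float, seed: int) -> HubNet:
    if kind == "sever":
        return lesions.sever(net, severity, seed)[0]
    if kind == "perturb_weights":
        return lesions.perturb_weights(net, severity, seed)[0]
    if kind == "ablate_units":
        return lesions.ablate_units(net, severity, seed)[0]
    if kind == "scale_weights":
        return lesions.scale_weights(net, severity)[0]
    raise ValueError(f"damage kind {kind!r} not applicable to the hub model")


def run_damage_grid(nets: list[HubNet], grid: DamageGrid,
                    pattern_sets: list[PatternSet] | PatternSet,
                    master_seed: int = 0) -> pd.DataFrame:
    """Damage every network at every level and score naming per domain.

    ``pattern_sets`` is either one set (all networks trained on it) or one
    per network.  Weight scaling is deterministic, so a single lesion per
    level is generated regardless of ``lesions_per_level``.

    Returns a tidy frame: network_id, damage_kind, severity, replicate,
    domain, accuracy.
    """
    if isinstance(pattern_sets, PatternSet):
        pattern_sets = [pattern_sets] * len(nets)
    if len(pattern_sets) != len(nets):
        raise ValueError("need one pattern set, or one per network")
    n_reps = 1 if grid.kind == "scale_weights" else grid.lesions_per_level
    rows = []
    counter = 0
    for net_id, (net, ps) in enumerate(zip(nets, pattern_sets)):
        for severity in grid.levels:
            for rep in range(n_reps):
                seed = derive_seed(master_seed, f"lesion-{grid.kind}", counter)
                counter += 1
                damaged = _lesion(net, grid.kind, severity, seed)
                acc = naming_accuracy(damaged, ps, by_domain=True)
                for d in DOMAINS:
                    rows.append((net_id, grid.kind, severity, rep, d, acc[d]))
    return pd.DataFrame(rows, columns=["network_id", "damage_kind",
                                       "severity", "replicate", "domain",
                                       "accuracy"])


@dataclass
class AreaResult:
    """Signed area (artefact - animal) between domain accuracy curves."""

    per_network: np.ndarray
    mean: float
    sd: float
    ci95: tuple | None  # None when only one network

    @property
    def significant(self) -> bool:
        return self.ci95 is not None and (self.ci95[0] > 0 or self.ci95[1] < 0)


def area_between_curves(curve: pd.DataFrame) -> AreaResult:
    """Mean per-level accuracy difference (artefact - animal), per network.

    The area is the average over severity levels of the domain accuracy
    difference (equivalent to the trapezoid area normalised by the severity
    span, but comparable across damage kinds with different severity
    units).  The 95% CI is a Student-t interval over per-network areas.
    """
    by = (curve.groupby(["network_id", "severity", "domain"])["accuracy"]
          .mean().unstack("domain"))
    diff = (by["artefact"] - by["animal"]).groupby(level="network_id").mean()
    areas = diff.to_numpy()
    mean = float(areas.mean())
    if len(areas) < 2:
        return AreaResult(areas, mean, float("nan"), None)
    sd = float(areas.std(ddof=1))
    sem = sd / np.sqrt(len(areas))
    tcrit = stats.t.ppf(0.975, len(areas) - 1)
    ci = (mean - tcrit * sem, mean + tcrit * sem)
    return AreaResult(areas, mean, sd, ci)


def template_variants_study(profile: TemplateProfile,
                            n_variants: int = 20,
                            grids: list[DamageGrid] | None = None,
                            epochs: int | None = None,
                            master_seed: int = 0,
                            net_factory=None) -> pd.DataFrame:
    """Train one network per template-generated pattern-set variant.

    Generates ``n_variants`` sets with distinct seeds, trains a fresh
    network on each, then runs every damage grid and reports mean (SD)
    signed areas per damage kind, as in the published variants table.
    """
    from .hub import init_network, train
    if n_variants < 2:
        raise ValueError("need at least 2 variants")
    if grids is None:
        grids = default_grids()
    if net_factory is None:
        net_factory = init_network
    sets, nets = [], []
    for i in range(n_variants):
        ps = generate_patterns(profile, derive_seed(master_seed, "variant", i))
        net = net_factory(seed=derive_seed(master_seed, "netinit", i))
        train(net, ps, epochs=epochs, seed=derive_seed(master_seed, "train", i))
        sets.append(ps)
        nets.append(net)
    rows = []
    for grid in grids:
        curve = run_damage_grid(nets, grid, sets, master_seed)
        res = area_between_curves(curve)
        rows.append((grid.kind, res.mean, res.sd, res.ci95[0], res.ci95[1]))
    return pd.DataFrame(rows, columns=["damage_kind", "mean_area", "sd_area",
                                       "ci_lo", "ci_hi"])


# ---------------------------------------------------------------------------
# Attractor, weight and output-error analyses
# ---------------------------------------------------------------------------

@dataclass
class AttractorSummary:
    hidden_states: np.ndarray  # (48, n_hidden) settled hub states
    mean_distance: dict  # domain -> mean pairwise Euclidean distance


def attractor_summary(net: HubNet, ps: PatternSet) -> AttractorSummary:
    """Within-domain mean pairwise distance between settled hub states.

    The attractor estimate for an item is the hidden state after the same
    2 + 5 visual-clamp protocol used for naming.  Smaller means denote more
    densely packed attractors.
    """
    trace = settle(net, ClampSpec.visual(ps.visual_block.astype(float)))
    hidden = trace.final_hidden
    out = {}
    for d in DOMAINS:
        mask = ps.domain_mask(d)
        if mask.sum() < 2:
            raise ValueError(f"need >= 2 items in domain {d}")
        out[d] = float(pdist(hidden[mask]).mean())
    return AttractorSummary(hidden, out)


def attractor_anova(summaries: dict[str, list[AttractorSummary]]) -> pd.DataFrame:
    """Two-way ANOVA (domain x pattern set) on per-network attractor density.

    ``summaries`` maps a profile label to that profile's per-network
    summaries.  Returns the standard ANOVA table with F and p values.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols
    rows = []
    for profile, ss in summaries.items():
        if len(ss) < 2:
            raise ValueError("need >= 2 networks per profile")
        for net_id, s in enumerate(ss):
            for d in DOMAINS:
                rows.append((profile, d, net_id, s.mean_distance[d]))
    df = pd.DataFrame(rows, columns=["profile", "domain", "network_id",
                                     "distance"])
    counts = df.groupby(["profile", "domain"]).size()
    if counts.nunique() != 1:
        raise ValueError("unbalanced design")
    model = ols("distance ~ C(domain) * C(profile)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    return table


def weight_summary(nets: list[HubNet]) -> pd.DataFrame:
    """Min/max/mean/proportion-positive per weight matrix, with 95% t CIs.

    Statistics are computed per network and the CI is over networks (a
    single network yields NaN CIs).
    """
    recs = {}
    for net in nets:
        for name, w in net.weights.items():
            recs.setdefault(name, []).append(
                (w.min(), w.max(), w.mean(), (w > 0).mean()))
    rows = []
    for name, vals in recs.items():
        vals = np.array(vals)
        for j, stat in enumerate(("min", "max", "mean",
                                  "proportion_positive")):
            col = vals[:, j]
            m = float(col.mean())
            if len(col) > 1:
                sem = col.std(ddof=1) / np.sqrt(len(col))
                tcrit = stats.t.ppf(0.975, len(col) - 1)
                lo, hi = m - tcrit * sem, m + tcrit * sem
            else:
                lo = hi = float("nan")
            rows.append((name, stat, m, lo, hi))
    return pd.DataFrame(rows, columns=["matrix", "statistic", "mean",
                                       "ci_lo", "ci_hi"])


def pattern_and_name_error(net: HubNet, ps: PatternSet,
                           outputs: np.ndarray | None = None) -> pd.DataFrame:
    """Euclidean output error per domain, over all units and over name units.

    Pattern error is the distance between the settled visible output and
    the 216-unit target; name error restricts to the 40 name units.  Both
    are averaged within domain.  ``outputs`` overrides the settled visible
    states (mainly for definitional checks).
    """
    if outputs is None:
        trace = settle(net, ClampSpec.visual(ps.visual_block.astype(float)))
        out = trace.final_visible
    else:
        out = np.asarray(outputs, dtype=float)
    target = ps.vectors.astype(float)
    diff = out - target
    pattern_err = np.linalg.norm(diff, axis=1)
    name_err = np.linalg.norm(diff[:, :net.config.n_name], axis=1)
    rows = []
    for d in DOMAINS:
        mask = ps.domain_mask(d)
        rows.append((d, float(pattern_err[mask].mean()),
                     float(name_err[mask].mean())))
    return pd.DataFrame(rows, columns=["domain", "pattern_error",
                                       "name_error"])
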