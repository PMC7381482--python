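"""Error taxonomy and damage-sweep analyses for sequential action.

A damaged network's episode is classified in three deterministic passes:

1. *Parse*: the produced action string is segmented into non-overlapping
   complete subtask tokens (from the joint inventory of both tasks),
   maximising the number of covered actions with earliest-start
   tie-breaking.
2. *Fragments*: each residual run is scanned left-to-right for maximal
   fragments -- contiguous substrings (length >= 3) of some subtask token.
   A fragment containing its token's crux action fulfils that subtask's
   goal (the goal was achieved even though the routine was truncated);
   a crux-less fragment whose goal is already fulfilled elsewhere is a
   subtask perseveration; any other crux-less fragment is a broken subtask
   attempt, a within-subtask error.  Residual actions belonging to no
   fragment are disorganised ("independent") actions, each a
   within-subtask error.
3. *Goal comparison*: the temporally ordered fulfilled goals are compared
   with the task's valid goal orders, yielding subtask omissions (expected
   goal never fulfilled), intrusions (fulfilled goal foreign to the task),
   perseverations (goal re-fulfilled) and displacements (expected goals in
   an order matching no valid realisation).

Action-level errors (omission vs sequence vs other) come from an edit
alignment against the nearest valid realisation.  All rules are simple
enough to check exhaustively against a brute-force enumeration of all
segmentations on short episodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from . import beverage as bev
from . import lesions
from .beverage import SUBTASKS, SUBTASK_GOAL, GOAL_ORDERS, SUBTASK_CRUX
from .seeds import derive_seed
from .srn import (EpisodeTrace, SRNNet, run_episode, valid_realizations)

SUBTASK_LABELS = ("intrusion", "omission", "perseveration", "displacement",
                  "within_subtask")
ACTION_LABELS = ("omission", "sequence", "other")


# ---------------------------------------------------------------------------
# Parsing produced action strings into subtask segments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Parse:
    segments: tuple  # ((subtask_id, start), ...) with start action index
    covered: int     # total actions inside complete segments

    def residual_indices(self, n: int) -> list[int]:
        inside = set()
        for st, start in self.segments:
            inside.update(range(start, start + len(SUBTASKS[st])))
        return [i for i in range(n) if i not in inside]


def parse_episode_actions(actions: tuple[str, ...]) -> Parse:
    """Segment an action string into non-overlapping complete subtasks.

    Dynamic programme over positions; at each position either skip one
    action or consume a matching subtask token.  Among maximal-coverage
    segmentations the one with lexicographically smallest segment starts
    (i.e. earliest matches) is returned.
    """
    n = len(actions)
    tokens = sorted(SUBTASKS.items())  # deterministic order
    # best[i] = (coverage, segments) achievable for suffix starting at i
    best: list[tuple[int, tuple]] = [(0, ())] * (n + 1)
    for i in range(n - 1, -1, -1):
        cov, segs = best[i + 1]  # skip actions[i]
        cand = (cov, segs)
        for st, tok in tokens:
            L = len(tok)
            if i + L <= n and tuple(actions[i:i + L]) == tok:
                cov2, segs2 = best[i + L]
                c = (cov2 + L, ((st, i),) + segs2)
                # maximise coverage; ties resolved toward the earliest
                # starts, then lexicographically by token name
                if c[0] > cand[0] or (c[0] == cand[0]
                                      and _tie_key(c[1]) < _tie_key(cand[1])):
                    cand = c
        best[i] = cand
    cov, segs = best[0]
    return Parse(segs, cov)


def _tie_key(segments: tuple) -> tuple:
    return (tuple(s for _, s in segments), tuple(st for st, _ in segments))


# ---------------------------------------------------------------------------
# Fragment extraction within residual runs
# ---------------------------------------------------------------------------

MIN_FRAGMENT = 3  # shortest action run still recognisable as subtask-coherent


@lru_cache(maxsize=1)
def _fragment_index() -> dict:
    """substring -> (token_id, offset) for every token substring >= MIN_FRAGMENT.

    Ambiguous substrings resolve to the smallest (token_id, offset) pair in
    the sorted token order, making fragment attribution deterministic.
    """
    index: dict = {}
    for st in sorted(SUBTASKS):
        tok = SUBTASKS[st]
        for i in range(len(tok)):
            for j in range(i + MIN_FRAGMENT, len(tok) + 1):
                key = tok[i:j]
                if key not in index:
                    index[key] = (st, i)
    return index


@dataclass(frozen=True)
class Fragment:
    subtask: str
    start: int        # index into the episode's action string
    length: int
    offset: int       # position of the fragment within the full token

    @property
    def has_crux(self) -> bool:
        crux_pos = SUBTASKS[self.subtask].index(SUBTASK_CRUX[self.subtask])
        return self.offset <= crux_pos < self.offset + self.length

    @property
    def goal(self) -> str:
        return SUBTASK_GOAL[self.subtask]


def extract_fragments(actions: tuple[str, ...], run: list[int]
                      ) -> tuple[list[Fragment], list[int]]:
    """Leftmost-longest fragment decomposition of one residual run.

    Returns the fragments and the leftover (disorganised) action indices.
    """
    index = _fragment_index()
    max_len = max(len(t) for t in SUBTASKS.values())
    fragments, leftover = [], []
    i = 0
    while i < len(run):
        # runs are contiguous; limit match length to the remaining run
        found = None
        for L in range(min(max_len, len(run) - i), MIN_FRAGMENT - 1, -1):
            key = tuple(actions[run[i] + k] for k in range(L))
            if key in index:
                st, off = index[key]
                found = Fragment(st, run[i], L, off)
                break
        if found is not None:
            fragments.append(found)
            i += found.length
        else:
            leftover.append(run[i])
            i += 1
    return fragments, leftover


# ---------------------------------------------------------------------------
# Episode-level classification
# ---------------------------------------------------------------------------

@dataclass
class EpisodeLabels:
    """Error labels for one episode."""

    correct: bool
    subtask_counts: dict  # label -> count, keys = SUBTASK_LABELS
    action_counts: dict   # label -> count, keys = ACTION_LABELS
    independent_actions: int
    crux_errors: int
    non_crux_errors: int
    n_actions: int
    parsed_goals: list = field(default_factory=list)

    @property
    def total_subtask_errors(self) -> int:
        return sum(self.subtask_counts[k] for k in
                   ("intrusion", "omission", "perseveration", "displacement"))

    @property
    def any_error(self) -> bool:
        return not self.correct


def classify_episode(trace: EpisodeTrace | tuple, corpus: bev.TaskCorpus,
                     task: str | None = None,
                     sugar_source: str | None = None) -> EpisodeLabels:
    """Label one episode's errors at the subtask and action level."""
    if isinstance(trace, EpisodeTrace):
        actions = tuple(trace.actions)
        task = trace.task
        sugar_source = trace.sugar_source
    else:
        actions = tuple(trace)
        if task is None:
            raise ValueError("task required when passing a raw action string")
    if task not in GOAL_ORDERS:
        raise ValueError(f"unknown task {task!r}")

    valids = set(valid_realizations(corpus, task, sugar_source))
    if actions in valids:
        return EpisodeLabels(True, dict.fromkeys(SUBTASK_LABELS, 0),
                             dict.fromkeys(ACTION_LABELS, 0), 0, 0, 0,
                             len(actions))

    parse = parse_episode_actions(actions)
    residual = parse.residual_indices(len(actions))
    fragments: list[Fragment] = []
    disorganized: list[int] = []
    for run in _runs(residual):
        frs, left = extract_fragments(actions, run)
        fragments.extend(frs)
        disorganized.extend(left)

    # temporally ordered fulfilled goals: complete tokens plus
    # crux-containing fragments (the goal was achieved mid-fragment)
    events = [(start, SUBTASK_GOAL[st]) for st, start in parse.segments]
    events += [(f.start, f.goal) for f in fragments if f.has_crux]
    events.sort()
    goals = [g for _, g in events]
    fulfilled = set(goals)

    expected_orders = GOAL_ORDERS[task]
    expected = set(expected_orders[0])
    counts = dict.fromkeys(SUBTASK_LABELS, 0)
    counts["omission"] = sum(1 for g in expected if g not in fulfilled)
    seen: set = set()
    for g in goals:
        if g in seen:
            counts["perseveration"] += 1
        elif g not in expected:
            counts["intrusion"] += 1
        seen.add(g)
    # a crux-less fragment re-enacting a fulfilled goal is a perseveration;
    # one attempting an unfulfilled goal is a broken subtask attempt
    broken = 0
    for f in fragments:
        if not f.has_crux:
            if f.goal in fulfilled:
                counts["perseveration"] += 1
            else:
                broken += 1
    # displacement: first occurrences of expected goals, in produced order,
    # must follow some valid order's relative order
    reduced = []
    for g in goals:
        if g in expected and g not in reduced:
            reduced.append(g)
    counts["displacement"] = min(
        len(reduced) - _lcs(tuple(reduced), order)
        for order in expected_orders)
    counts["within_subtask"] = broken + len(disorganized)

    crux = sum(1 for i in residual if actions[i] in bev.CRUX_ACTIONS)
    action_counts = _action_level(actions, valids)
    return EpisodeLabels(False, counts, action_counts, len(disorganized),
                         crux, len(residual) - crux, len(actions), goals)


def _runs(indices: list[int]) -> list[list[int]]:
    runs: list[list[int]] = []
    for i in indices:
        if runs and i == runs[-1][-1] + 1:
            runs[-1].append(i)
        else:
            runs.append([i])
    return runs


def _count_runs(indices: list[int]) -> int:
    runs = 0
    prev = None
    for i in indices:
        if prev is None or i != prev + 1:
            runs += 1
        prev = i
    return runs


def _lcs(a: tuple, b: tuple) -> int:
    dp = [[0] * (len(b) + 1) for _ in range(len(a) + 1)]
    for i in range(len(a)):
        for j in range(len(b)):
            dp[i + 1][j + 1] = dp[i][j] + 1 if a[i] == b[j] \
                else max(dp[i][j + 1], dp[i + 1][j])
    return dp[len(a)][len(b)]


def _action_level(actions: tuple, valids: set) -> dict:
    """Edit-align against the nearest valid realisation and bin the edits.

    Deletions are action omissions.  Insertions/substitutions whose action
    occurs elsewhere in the target are sequence errors (anticipations and
    perseverations); edits introducing actions absent from the target are
    "other" errors (e.g. object substitutions).
    """
    best = None
    for v in sorted(valids):
        ops = _edit_ops(actions, v)
        if best is None or len(ops) < len(best[0]):
            best = (ops, v)
    ops, target = best
    counts = dict.fromkeys(ACTION_LABELS, 0)
    tset = set(target)
    for op, act in ops:
        if op == "delete":
            counts["omission"] += 1
        elif act in tset:
            counts["sequence"] += 1
        else:
            counts["other"] += 1
    return counts


def _edit_ops(a: tuple, b: tuple) -> list[tuple[str, str]]:
    """Minimal edit script from produced ``a`` to target ``b``.

    Returns (op, action) pairs: ``("delete", target_action)`` for an action
    of the target missing from the production, ``("insert", produced)`` or
    ``("substitute", produced)`` for extraneous/substituted productions.
    Ties in the DP are broken deterministically (substitute < delete <
    insert).
    """
    la, lb = len(a), len(b)
    dp = np.zeros((la + 1, lb + 1), dtype=int)
    dp[:, 0] = np.arange(la + 1)
    dp[0, :] = np.arange(lb + 1)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            sub = dp[i - 1][j - 1] + (a[i - 1] != b[j - 1])
            dp[i][j] = min(sub, dp[i - 1][j] + 1, dp[i][j - 1] + 1)
    ops = []
    i, j = la, lb
    while i > 0 or j > 0:
        if i > 0 and j > 0 and dp[i][j] == dp[i - 1][j - 1] + (a[i - 1] != b[j - 1]):
            if a[i - 1] != b[j - 1]:
                ops.append(("substitute", a[i - 1]))
            i, j = i - 1, j - 1
        elif j > 0 and dp[i][j] == dp[i][j - 1] + 1:
            ops.append(("delete", b[j - 1]))
            j -= 1
        else:
            ops.append(("insert", a[i - 1]))
            i -= 1
    return [op for op in reversed(ops) if op[0] != "match"]


# ---------------------------------------------------------------------------
# Survival curves
# ---------------------------------------------------------------------------

def first_divergence(actions: tuple[str, ...],
                     valids: list[tuple[str, ...]]) -> int:
    """1-based step of the first deviation from the nearest realisation.

    Returns ``len(target) + 1`` when the episode matches a full
    realisation exactly (no divergence).
    """
    best = 0
    for v in valids:
        i = 0
        while i < min(len(actions), len(v)) and actions[i] == v[i]:
            i += 1
        if i == len(v) and len(actions) == len(v):
            return len(v) + 1
        best = max(best, i)
    return best + 1


@dataclass
class SurvivalCurve:
    task: str
    steps: np.ndarray       # 1..task length
    proportion: np.ndarray  # fraction error-free through each step
    per_network: np.ndarray | None = None  # (nets, steps)

    def drops(self) -> np.ndarray:
        """Per-step decreases of the survival curve (index 0 = step 1)."""
        prev = np.concatenate([[1.0], self.proportion[:-1]])
        return prev - self.proportion


def survival_analysis(episodes: list[EpisodeTrace], corpus: bev.TaskCorpus,
                      task: str | None = None) -> SurvivalCurve:
    """Proportion of episodes still error-free through each task step.

    Divergence is measured against the nearest valid realisation for each
    episode's scenario, so legitimate order variation never counts as an
    error.  The curve is monotone non-increasing and equals 1.0 throughout
    for intact cohorts.
    """
    if task is None:
        tasks = {e.task for e in episodes}
        if len(tasks) != 1:
            raise ValueError("episodes span multiple tasks; pass task=")
        task = tasks.pop()
    eps = [e for e in episodes if e.task == task]
    if not eps:
        raise ValueError(f"no episodes for task {task!r}")
    n_steps = bev.SEQUENCE_LENGTH[task]
    div = np.array([
        first_divergence(tuple(e.actions),
                         valid_realizations(corpus, task, e.sugar_source))
        for e in eps])
    steps = np.arange(1, n_steps + 1)
    prop = np.array([(div > k).mean() for k in steps])
    return SurvivalCurve(task, steps, prop)


def boundary_windows(task: str, width: int = 2) -> set[int]:
    """Steps at which boundary captures surface in the survival curve.

    A capture at the boundary after step b manifests within the first
    ``width`` steps of the next subtask, because subtasks open with
    actions shared across continuations (putting the held object down).
    """
    return {b + k for b in bev.SUBTASK_BOUNDARIES[task]
            for k in range(1, width + 1)}


# ---------------------------------------------------------------------------
# Damage sweeps
# ---------------------------------------------------------------------------

#: the published mild severities per damage kind
DEFAULT_SEVERITIES = {
    "activation_noise": 0.10,
    "perturb_weights": 0.05,  # gaussian SD on the recurrent weights
    "sever": 0.05,
    "ablate_units": 0.05,
}

STOCHASTIC_KINDS = tuple(DEFAULT_SEVERITIES)


def severity_ladder(kind: str, n_levels: int = 4,
                    factor: float = 2.0) -> list[float]:
    """Geometric severity ladder around the published mild setting."""
    base = DEFAULT_SEVERITIES[kind]
    return [round(base * factor ** k, 6) for k in range(n_levels)]


def _lesioned_net(net: SRNNet, kind: str, severity: float, seed: int):
    """(damaged_net, injector) for one episode of one damage kind."""
    if kind == "activation_noise":
        return net, lesions.activation_noise(severity, seed)
    if kind == "perturb_weights":
        d, _ = lesions.perturb_weights(net, severity, seed,
                                       target=("W_ch",),
                                       distribution="gaussian")
        return d, None
    if kind == "sever":
        d, _ = lesions.sever(net, severity, seed, target=("W_ch",))
        return d, None
    if kind == "ablate_units":
        d, _ = lesions.ablate_units(net, severity, seed, layer="context")
        return d, None
    if kind == "scale_weights":
        return lesions.scale_weights(net, severity)[0], None
    raise ValueError(f"unknown damage kind {kind!r}")


def run_damaged_episodes(net: SRNNet, corpus: bev.TaskCorpus, kind: str,
                         severity: float, task: str, n_episodes: int,
                         master_seed: int = 0) -> list[EpisodeTrace]:
    """Run episodes under one damage condition.

    Stochastic lesions are redrawn for every episode (each trial is an
    independent instance of the damaged network); the sugar source
    alternates between the packet and bowl scenarios.
    """
    episodes = []
    for k in range(n_episodes):
        seed = derive_seed(master_seed, f"{kind}-{severity}-{task}", k)
        damaged, injector = _lesioned_net(net, kind, severity, seed)
        source = "packet" if k % 2 == 0 else "bowl"
        episodes.append(run_episode(damaged, task, source,
                                    injector=injector, seed=seed))
    return episodes


def damage_sweep(nets: list[SRNNet], corpus: bev.TaskCorpus,
                 kinds_severities: dict[str, list[float]] | None = None,
                 tasks: tuple[str, ...] = ("coffee", "tea"),
                 episodes_per_cell: int = 500,
                 master_seed: int = 0) -> pd.DataFrame:
    """Full damage sweep: classify every episode of every cell.

    Returns a tidy frame with one row per (network, kind, severity, task)
    cell and aggregate error counts.
    """
    if not nets:
        raise ValueError("empty network cohort")
    if kinds_severities is None:
        kinds_severities = {k: severity_ladder(k) for k in STOCHASTIC_KINDS}
    rows = []
    for net_id, net in enumerate(nets):
        for kind, severities in kinds_severities.items():
            for sev in severities:
                for task in tasks:
                    eps = run_damaged_episodes(
                        net, corpus, kind, sev, task, episodes_per_cell,
                        derive_seed(master_seed, f"net{net_id}", 0))
                    labels = [classify_episode(e, corpus) for e in eps]
                    row = {"network_id": net_id, "damage_kind": kind,
                           "severity": sev, "task": task,
                           "n_episodes": len(eps),
                           "n_errorful": sum(l.any_error for l in labels),
                           "independent_actions":
                               sum(l.independent_actions for l in labels),
                           "crux_errors": sum(l.crux_errors for l in labels),
                           "non_crux_errors":
                               sum(l.non_crux_errors for l in labels),
                           "total_actions": sum(l.n_actions for l in labels)}
                    for lab in SUBTASK_LABELS:
                        row[lab] = sum(l.subtask_counts[lab] for l in labels)
                    for lab in ACTION_LABELS:
                        row[f"action_{lab}"] = sum(l.action_counts[lab]
                                                   for l in labels)
                    rows.append(row)
    return pd.DataFrame(rows)


def crux_analysis(report: pd.DataFrame) -> pd.DataFrame:
    """Independent-action and crux/non-crux error proportions by severity."""
    g = report.groupby(["damage_kind", "severity"]).sum(numeric_only=True)
    out = pd.DataFrame({
        "independent_proportion":
            g["independent_actions"] / g["total_actions"],
        "crux_error_proportion": g["crux_errors"] / g["total_actions"],
        "non_crux_error_proportion":
            g["non_crux_errors"] / g["total_actions"],
    })
    with np.errstate(divide="ignore", invalid="ignore"):
        out["non_crux_to_crux_ratio"] = np.where(
            g["crux_errors"] > 0, g["non_crux_errors"] / g["crux_errors"],
            np.inf)
        out.loc[(g["crux_errors"] == 0) & (g["non_crux_errors"] == 0),
                "non_crux_to_crux_ratio"] = 0.0
    return out.reset_index()


def scaling_threshold_search(nets: list[SRNNet], corpus: bev.TaskCorpus,
                             task: str,
                             s_grid: np.ndarray | None = None) -> float:
    """Largest scaling factor at which any episode of a task fails.

    Weight scaling is deterministic, so one episode per (network, scenario,
    order cue, factor) suffices.  Returns 0.0 if no factor in the grid
    produces a failure.
    """
    if s_grid is None:
        s_grid = np.round(np.arange(0.99, 0.29, -0.01), 2)
    s_grid = np.asarray(s_grid)
    if len(s_grid) > 1 and not np.all(np.diff(s_grid) < 0):
        raise ValueError("s_grid must be strictly descending")
    cues = [False, True] if task == "coffee" else [False]
    for s in s_grid:
        for net in nets:
            damaged = lesions.scale_weights(net, float(s))[0]
            for source in ("packet", "bowl"):
                for cue in cues:
                    tr = run_episode(damaged, task, source, cue)
                    from .srn import episode_correct
                    if not episode_correct(tr, corpus):
                        return float(s)
    return 0.0
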