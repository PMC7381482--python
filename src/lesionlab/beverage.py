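"""Simulated beverage-preparation environment and task corpus.

A simplified kitchen world with a cup, spoon, coffee packet, sugar packet,
sugar bowl (with removable lid), cream carton and teabag, manipulated by a
simulated eye (one fixated object) and hand (at most one held object).  The
agent perceives featural descriptions of the fixated and held objects and
emits discrete actions ("pick up", "fixate spoon", ...).  Actions have
deterministic effects; inapplicable actions leave the world unchanged and
are flagged as anomalous.

The task corpus holds six target sequences -- four ways of preparing
coffee (37 steps each: add grounds, add sugar and cream in either order,
drink) and two ways of preparing tea (20 steps each: steep the teabag, add
sugar, drink) -- plus a large set (250+) of single-step background
state/action pairs.  Sugar comes from a packet or from the bowl depending
on which sugar source the environment scenario provides; the choice of
coffee sub-task order is part of the agent's instruction cue.  Subtask
boundaries fall after steps 10, 21 and 32 of coffee and after steps 10 and
15 of tea.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

OBJECTS = ("cup", "spoon", "coffee_packet", "sugar_packet", "sugar_bowl",
           "cream_carton", "teabag", "lid")

GRASPABLE = ("cup", "spoon", "coffee_packet", "sugar_packet",
             "cream_carton", "teabag", "lid")

ACTIONS = (
    "fixate_cup", "fixate_spoon", "fixate_coffee_packet", "fixate_sugar",
    "fixate_cream_carton", "fixate_teabag", "fixate_lid",
    "pick_up", "put_down", "tear_open", "pull_open", "pull_off",
    "pour", "scoop", "dip", "stir", "sip", "say_done",
)
ACTION_INDEX = {a: i for i, a in enumerate(ACTIONS)}

N_OBJECT_FEATURES = len(OBJECTS) + 4  # identity + open/content/liquid/stirred
N_INSTRUCTION = 3  # coffee, tea, cream-first
INPUT_WIDTH = 2 * N_OBJECT_FEATURES + N_INSTRUCTION
OUTPUT_WIDTH = len(ACTIONS)

CRUX_ACTIONS = ("pour", "dip", "sip")


class UnknownActionError(KeyError):
    pass


class CorpusError(RuntimeError):
    pass


@dataclass(frozen=True)
class WorldState:
    """Deterministic state of the beverage world."""

    fixated: str = "cup"
    held: str | None = None
    # container states
    coffee_packet_open: bool = False
    coffee_packet_full: bool = True
    sugar_packet_open: bool = False
    sugar_packet_full: bool = True
    carton_open: bool = False
    carton_full: bool = True
    bowl_open: bool = False  # lid removed
    bowl_full: bool = True
    teabag_unwrapped: bool = False
    teabag_in_cup: bool = False
    spoon_sugar: bool = False
    cup_contents: frozenset = frozenset()
    cup_stirred: bool = False
    sips: int = 0
    done: bool = False
    # scenario (immutable environment configuration)
    sugar_source: str = "packet"  # which sugar source the scene provides
    lid_present: bool = True

    def object_features(self, obj: str | None) -> np.ndarray:
        """Featural description of one object (all zeros for an empty hand)."""
        v = np.zeros(N_OBJECT_FEATURES)
        if obj is None:
            return v
        v[OBJECTS.index(obj)] = 1.0
        is_open = {
            "cup": True,
            "coffee_packet": self.coffee_packet_open,
            "sugar_packet": self.sugar_packet_open,
            "cream_carton": self.carton_open,
            "sugar_bowl": self.bowl_open,
            "teabag": self.teabag_unwrapped,
        }.get(obj, False)
        has_content = {
            "cup": bool(self.cup_contents),
            "coffee_packet": self.coffee_packet_full,
            "sugar_packet": self.sugar_packet_full,
            "cream_carton": self.carton_full,
            "sugar_bowl": self.bowl_full,
            "spoon": self.spoon_sugar,
            "teabag": not self.teabag_in_cup,
        }.get(obj, False)
        v[len(OBJECTS)] = float(is_open)
        v[len(OBJECTS) + 1] = float(has_content)
        if obj == "cup":
            v[len(OBJECTS) + 2] = float(
                bool(self.cup_contents & {"grounds", "tea"}))
            v[len(OBJECTS) + 3] = float(self.cup_stirred)
        return v


def initial_state(sugar_source: str = "packet",
                  bowl_open: bool = False) -> WorldState:
    if sugar_source not in ("packet", "bowl"):
        raise ValueError(f"unknown sugar source {sugar_source!r}")
    return WorldState(sugar_source=sugar_source, bowl_open=bowl_open,
                      lid_present=not bowl_open)


def _pourable(state: WorldState) -> str | None:
    """Which ingredient the held object would release into the cup."""
    h = state.held
    if h == "coffee_packet" and state.coffee_packet_open and state.coffee_packet_full:
        return "grounds"
    if h == "sugar_packet" and state.sugar_packet_open and state.sugar_packet_full:
        return "sugar"
    if h == "cream_carton" and state.carton_open and state.carton_full:
        return "cream"
    if h == "spoon" and state.spoon_sugar:
        return "sugar"
    return None


def step(state: WorldState, action: str) -> tuple[WorldState, bool]:
    """Apply an action; returns (new_state, anomaly_flag).

    Inapplicable actions return the state unchanged with the anomaly flag
    set; unknown action ids raise :class:`UnknownActionError`.
    """
    if action not in ACTION_INDEX:
        raise UnknownActionError(action)

    if action.startswith("fixate_"):
        target = action[len("fixate_"):]
        if target == "sugar":
            target = "sugar_packet" if state.sugar_source == "packet" \
                else "sugar_bowl"
        if target == "lid" and not state.lid_present:
            return state, True
        if target == "sugar_packet" and state.sugar_source != "packet":
            return state, True
        return replace(state, fixated=target), False

    if action == "pick_up":
        if state.held is None and state.fixated in GRASPABLE:
            if state.fixated == "teabag" and state.teabag_in_cup:
                return state, True
            return replace(state, held=state.fixated), False
        return state, True

    if action == "put_down":
        if state.held is not None:
            return replace(state, held=None), False
        return state, True

    if action == "tear_open":
        if state.held == "coffee_packet" and not state.coffee_packet_open:
            return replace(state, coffee_packet_open=True), False
        if state.held == "sugar_packet" and not state.sugar_packet_open:
            return replace(state, sugar_packet_open=True), False
        if state.held == "teabag" and not state.teabag_unwrapped:
            return replace(state, teabag_unwrapped=True), False
        return state, True

    if action == "pull_open":
        if state.held == "cream_carton" and not state.carton_open:
            return replace(state, carton_open=True), False
        return state, True

    if action == "pull_off":
        if (state.held is None and state.fixated == "sugar_bowl"
                and state.lid_present and not state.bowl_open):
            return replace(state, bowl_open=True, held="lid"), False
        return state, True

    if action == "pour":
        ingredient = _pourable(state)
        if ingredient is None:
            return state, True
        new = {"cup_contents": state.cup_contents | {ingredient},
               "cup_stirred": False}
        if state.held == "coffee_packet":
            new["coffee_packet_full"] = False
        elif state.held == "sugar_packet":
            new["sugar_packet_full"] = False
        elif state.held == "cream_carton":
            new["carton_full"] = False
        elif state.held == "spoon":
            new["spoon_sugar"] = False
        return replace(state, **new), False

    if action == "scoop":
        # scooping works on the (single) open sugar bowl with the held spoon
        if (state.held == "spoon" and state.bowl_open and state.bowl_full
                and not state.spoon_sugar):
            return replace(state, spoon_sugar=True), False
        return state, True

    if action == "dip":
        if (state.held == "teabag" and state.teabag_unwrapped
                and state.fixated == "cup" and not state.teabag_in_cup):
            return replace(state, teabag_in_cup=True, held=None,
                           cup_contents=state.cup_contents | {"tea"},
                           cup_stirred=False), False
        return state, True

    if action == "stir":
        if state.held == "spoon" and state.fixated == "cup":
            return replace(state, cup_stirred=True), False
        return state, True

    if action == "sip":
        if state.held == "cup" and state.cup_contents:
            return replace(state, sips=state.sips + 1), False
        return state, True

    if action == "say_done":
        return replace(state, done=True), False

    raise UnknownActionError(action)  # pragma: no cover


def encode_io(state: WorldState, action: str,
              instruction: np.ndarray | None = None
              ) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-width binary input/output encodings for the SRN.

    Input: fixated-object features ++ held-object features ++ instruction
    units (zeros unless supplied).  Output: one-hot action.
    """
    x = encode_input(state, instruction)
    y = np.zeros(OUTPUT_WIDTH)
    y[ACTION_INDEX[action]] = 1.0
    return x, y


def encode_input(state: WorldState,
                 instruction: np.ndarray | None = None) -> np.ndarray:
    x = np.zeros(INPUT_WIDTH)
    x[:N_OBJECT_FEATURES] = state.object_features(state.fixated)
    x[N_OBJECT_FEATURES:2 * N_OBJECT_FEATURES] = state.object_features(state.held)
    if instruction is not None:
        x[2 * N_OBJECT_FEATURES:] = instruction
    return x


def decode_action(y: np.ndarray) -> str:
    return ACTIONS[int(np.argmax(y))]


def instruction_vector(task: str, cream_first: bool = False) -> np.ndarray:
    """Transient goal cue presented on the first step of an episode."""
    v = np.zeros(N_INSTRUCTION)
    if task == "coffee":
        v[0] = 1.0
        v[2] = float(cream_first)
    elif task == "tea":
        v[1] = 1.0
    else:
        raise ValueError(f"unknown task {task!r}")
    return v


# ---------------------------------------------------------------------------
# Subtask inventory and the six target sequences
# ---------------------------------------------------------------------------

# Coffee "addition" subtasks start by putting down the spoon held from the
# previous stir; every addition ends with a stir, so subtask boundaries fall
# at the completion of each ingredient (steps 10/11, 21/22, 32/33 of coffee;
# 10/11 and 15/16 of tea).
SUBTASKS: dict[str, tuple[str, ...]] = {
    "grounds": ("fixate_coffee_packet", "pick_up", "tear_open", "fixate_cup",
                "pour", "put_down", "fixate_spoon", "pick_up", "fixate_cup",
                "stir"),
    "sugar_packet_c": ("put_down", "fixate_sugar", "pick_up", "tear_open",
                       "fixate_cup", "pour", "put_down", "fixate_spoon",
                       "pick_up", "fixate_cup", "stir"),
    "sugar_bowl_c": ("put_down", "fixate_sugar", "pull_off", "put_down",
                     "fixate_spoon", "pick_up", "fixate_sugar", "scoop",
                     "fixate_cup", "pour", "stir"),
    "cream": ("put_down", "fixate_cream_carton", "pick_up", "pull_open",
              "fixate_cup", "pour", "put_down", "fixate_spoon", "pick_up",
              "fixate_cup", "stir"),
    "steep": ("fixate_teabag", "pick_up", "tear_open", "fixate_cup", "dip",
              "fixate_spoon", "pick_up", "fixate_cup", "stir", "put_down"),
    "sugar_packet_t": ("fixate_sugar", "pick_up", "tear_open", "fixate_cup",
                       "pour"),
    "sugar_bowl_t": ("fixate_sugar", "fixate_spoon", "pick_up", "scoop",
                     "pour"),
    "drink": ("put_down", "fixate_cup", "pick_up", "sip", "say_done"),
}

# which subtask fulfils which notional goal (used for omission/intrusion
# labelling: sugar-from-packet and sugar-from-bowl fulfil the same goal)
SUBTASK_GOAL = {
    "grounds": "add_grounds",
    "sugar_packet_c": "add_sugar",
    "sugar_bowl_c": "add_sugar",
    "sugar_packet_t": "add_sugar",
    "sugar_bowl_t": "add_sugar",
    "cream": "add_cream",
    "steep": "steep_tea",
    "drink": "drink",
}

# goal-level realisations per task (subtask order patterns)
GOAL_ORDERS = {
    "coffee": (("add_grounds", "add_sugar", "add_cream", "drink"),
               ("add_grounds", "add_cream", "add_sugar", "drink")),
    "tea": (("steep_tea", "add_sugar", "drink"),),
}

SUBTASK_BOUNDARIES = {"coffee": (10, 21, 32), "tea": (10, 15)}
SEQUENCE_LENGTH = {"coffee": 37, "tea": 20}

# the single goal-fulfilling ("crux") action of each subtask
SUBTASK_CRUX = {
    "grounds": "pour", "sugar_packet_c": "pour", "sugar_bowl_c": "pour",
    "cream": "pour", "steep": "dip", "sugar_packet_t": "pour",
    "sugar_bowl_t": "pour", "drink": "sip",
}


@dataclass(frozen=True)
class TaskSequence:
    """One target realisation: task, cue, scenario, actions, segmentation."""

    name: str
    task: str  # "coffee" | "tea"
    cream_first: bool
    sugar_source: str  # "packet" | "bowl"
    subtasks: tuple[str, ...]  # subtask ids in order
    actions: tuple[str, ...]

    @property
    def instruction(self) -> np.ndarray:
        return instruction_vector(self.task, self.cream_first)

    def initial_state(self) -> WorldState:
        # in the tea-from-bowl scenario the bowl on the counter is already open
        bowl_open = self.task == "tea" and self.sugar_source == "bowl"
        return initial_state(self.sugar_source, bowl_open)

    @property
    def segments(self) -> list[tuple[str, int, int]]:
        """(subtask_id, start, end) with end exclusive, over action indices."""
        out, pos = [], 0
        for st in self.subtasks:
            n = len(SUBTASKS[st])
            out.append((st, pos, pos + n))
            pos += n
        return out

    def crux_flags(self) -> np.ndarray:
        flags = np.zeros(len(self.actions), dtype=bool)
        for st, a, b in self.segments:
            crux = SUBTASK_CRUX[st]
            idx = a + list(SUBTASKS[st]).index(crux)
            flags[idx] = True
        return flags


def _make_sequences() -> list[TaskSequence]:
    seqs = []
    for cream_first in (False, True):
        for source in ("packet", "bowl"):
            sugar = "sugar_packet_c" if source == "packet" else "sugar_bowl_c"
            middle = ("cream", sugar) if cream_first else (sugar, "cream")
            subtasks = ("grounds",) + middle + ("drink",)
            actions = tuple(a for st in subtasks for a in SUBTASKS[st])
            order = "cream-first" if cream_first else "sugar-first"
            seqs.append(TaskSequence(f"coffee-{order}-{source}", "coffee",
                                     cream_first, source, subtasks, actions))
    for source in ("packet", "bowl"):
        sugar = "sugar_packet_t" if source == "packet" else "sugar_bowl_t"
        subtasks = ("steep", sugar, "drink")
        actions = tuple(a for st in subtasks for a in SUBTASKS[st])
        seqs.append(TaskSequence(f"tea-{source}", "tea", False, source,
                                 subtasks, actions))
    return seqs


@dataclass
class SubtaskGrammar:
    """Subtask segmentation, crux flags and boundary steps for each task."""

    subtasks: dict = field(default_factory=lambda: dict(SUBTASKS))
    goal_of: dict = field(default_factory=lambda: dict(SUBTASK_GOAL))
    goal_orders: dict = field(default_factory=lambda: dict(GOAL_ORDERS))
    crux_of: dict = field(default_factory=lambda: dict(SUBTASK_CRUX))
    boundaries: dict = field(default_factory=lambda: dict(SUBTASK_BOUNDARIES))

    def expected_goals(self, task: str) -> tuple[str, ...]:
        return self.goal_orders[task][0]

    def to_json(self) -> str:
        return json.dumps({
            "subtasks": {k: list(v) for k, v in self.subtasks.items()},
            "goal_of": self.goal_of,
            "goal_orders": {k: [list(o) for o in v]
                            for k, v in self.goal_orders.items()},
            "crux_of": self.crux_of,
            "boundaries": {k: list(v) for k, v in self.boundaries.items()},
        })


@dataclass
class TaskCorpus:
    """Six validated target sequences plus 250+ background pairs."""

    sequences: list[TaskSequence]
    background: list[tuple[WorldState, str]]  # (state, action) pairs

    @property
    def coffee(self) -> list[TaskSequence]:
        return [s for s in self.sequences if s.task == "coffee"]

    @property
    def tea(self) -> list[TaskSequence]:
        return [s for s in self.sequences if s.task == "tea"]

    def realizations(self, task: str) -> list[tuple[str, ...]]:
        """All valid action strings for a task (across cues and scenarios)."""
        return [s.actions for s in self.sequences if s.task == task]

    def export_json(self, path: str | Path) -> None:
        data = {
            "sequences": [{
                "name": s.name, "task": s.task, "cream_first": s.cream_first,
                "sugar_source": s.sugar_source, "subtasks": list(s.subtasks),
                "actions": list(s.actions),
            } for s in self.sequences],
            "n_background": len(self.background),
        }
        Path(path).write_text(json.dumps(data, indent=1))


def replay(seq: TaskSequence) -> tuple[list[WorldState], int]:
    """Execute a sequence from its initial state; returns (states, anomalies)."""
    state = seq.initial_state()
    states = [state]
    anomalies = 0
    for a in seq.actions:
        state, bad = step(state, a)
        anomalies += bad
        states.append(state)
    return states, anomalies


def _canonical_action(state: WorldState) -> str | None:
    """The single sensible next action for a world state, if any.

    Used to generate background training pairs: each distinct state maps to
    one affordance-driven action, so the background set never gives the
    network conflicting targets for the same input.
    """
    h, f = state.held, state.fixated
    if h is None:
        if f == "sugar_bowl" and state.lid_present and not state.bowl_open:
            return "pull_off"
        if f in GRASPABLE and not (f == "teabag" and state.teabag_in_cup):
            return "pick_up"
        return None
    if h == "coffee_packet" and not state.coffee_packet_open:
        return "tear_open"
    if h == "sugar_packet" and not state.sugar_packet_open:
        return "tear_open"
    if h == "teabag" and not state.teabag_unwrapped:
        return "tear_open"
    if h == "cream_carton" and not state.carton_open:
        return "pull_open"
    if _pourable(state) is not None and f == "cup":
        return "pour"
    if h == "spoon" and f == "sugar_bowl" and state.bowl_open \
            and state.bowl_full and not state.spoon_sugar:
        return "scoop"
    if h == "teabag" and state.teabag_unwrapped and f == "cup" \
            and not state.teabag_in_cup:
        return "dip"
    if h == "spoon" and f == "cup" and state.cup_contents \
            and not state.cup_stirred:
        return "stir"
    if h == "cup" and state.cup_contents:
        return "sip"
    return "put_down"


# per-object state variants used to enumerate background pairs
_OBJECT_VARIANTS: dict[str, list[dict]] = {
    "cup": [dict(cup_contents=frozenset()),
            dict(cup_contents=frozenset({"sugar"})),
            dict(cup_contents=frozenset({"sugar"}), cup_stirred=True),
            dict(cup_contents=frozenset({"grounds"})),
            dict(cup_contents=frozenset({"grounds"}), cup_stirred=True)],
    "spoon": [dict(spoon_sugar=False), dict(spoon_sugar=True)],
    "coffee_packet": [dict(), dict(coffee_packet_open=True),
                      dict(coffee_packet_open=True,
                           coffee_packet_full=False)],
    "sugar_packet": [dict(), dict(sugar_packet_open=True),
                     dict(sugar_packet_open=True, sugar_packet_full=False)],
    "sugar_bowl": [dict(), dict(bowl_open=True),
                   dict(bowl_open=True, bowl_full=False)],
    "cream_carton": [dict(), dict(carton_open=True),
                     dict(carton_open=True, carton_full=False)],
    "teabag": [dict(), dict(teabag_unwrapped=True),
               dict(teabag_unwrapped=True, teabag_in_cup=True)],
    "lid": [dict(bowl_open=True)],
}


def _background_pairs() -> list[tuple[WorldState, str]]:
    """Enumerate 250+ single-step state/action training pairs.

    The cross product of fixated-object and held-object state variants
    covers the world's local affordances; each distinct input encoding
    appears once, mapped to its canonical action.
    """
    pairs = []
    seen = set()
    held_options = [None, "spoon", "cup", "coffee_packet", "sugar_packet",
                    "cream_carton", "teabag", "lid"]
    for fixated in OBJECTS:
        for fix_over in _OBJECT_VARIANTS[fixated]:
            for held in held_options:
                if held == fixated and held is not None:
                    continue
                held_variants = [dict()] if held is None \
                    else _OBJECT_VARIANTS[held]
                for held_over in held_variants:
                    if held == "teabag" and held_over.get("teabag_in_cup"):
                        continue  # a steeping bag cannot be in the hand
                    over = {**fix_over, **held_over}
                    source = "packet" if fixated != "sugar_bowl" else "bowl"
                    state = WorldState(fixated=fixated, held=held,
                                       sugar_source=source,
                                       lid_present=not over.get("bowl_open",
                                                                False),
                                       **over)
                    action = _canonical_action(state)
                    if action is None:
                        continue
                    key = (tuple(encode_input(state)), action)
                    if key in seen:
                        continue
                    seen.add(key)
                    pairs.append((state, action))
    return pairs


def build_corpus() -> tuple[TaskCorpus, SubtaskGrammar]:
    """Construct and validate the task corpus and its subtask grammar.

    Every sequence is replayed through the environment; an anomalous step,
    a wrong length or a missing terminal action raises :class:`CorpusError`
    naming the offending sequence.
    """
    sequences = _make_sequences()
    for seq in sequences:
        expected = SEQUENCE_LENGTH[seq.task]
        if len(seq.actions) != expected:
            raise CorpusError(
                f"{seq.name}: {len(seq.actions)} steps, expected {expected}")
        states, anomalies = replay(seq)
        if anomalies:
            bad = _first_anomaly(seq)
            raise CorpusError(f"{seq.name}: anomalous step {bad}")
        if not states[-1].done:
            raise CorpusError(f"{seq.name}: does not terminate with say_done")
        bounds = SUBTASK_BOUNDARIES[seq.task]
        ends = [end for _, _, end in seq.segments[:-1]]
        if tuple(ends) != bounds:
            raise CorpusError(
                f"{seq.name}: subtask boundaries {ends}, expected {bounds}")
    background = _background_pairs()
    if len(background) < 250:
        raise CorpusError(
            f"only {len(background)} background pairs (need 250+)")
    return TaskCorpus(sequences, background), SubtaskGrammar()


def _first_anomaly(seq: TaskSequence) -> int:
    state = seq.initial_state()
    for i, a in enumerate(seq.actions):
        state, bad = step(state, a)
        if bad:
            return i + 1
    return -1
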