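"""Error taxonomy: parser vs brute-force oracle, survival curves, crux."""

import itertools

import numpy as np
import pandas as pd
import pytest

from lesionlab import action_analysis as aa
from lesionlab import beverage as bev
from lesionlab.beverage import SUBTASKS, SUBTASK_CRUX, SUBTASK_GOAL


# ---------------------------------------------------------------------------
# Brute-force oracle: exhaustive segmentation instead of dynamic programming
# ---------------------------------------------------------------------------

def oracle_parse(actions):
    """Enumerate every set of non-overlapping complete-token placements and
    pick the maximal-coverage one, earliest starts (then token names) first."""
    actions = tuple(actions)
    placements = []
    for st in sorted(SUBTASKS):
        tok = SUBTASKS[st]
        for i in range(len(actions) - len(tok) + 1):
            if actions[i:i + len(tok)] == tok:
                placements.append((i, st, len(tok)))
    best = None
    for r in range(len(placements) + 1):
        for combo in itertools.combinations(placements, r):
            spans = [(i, i + L) for i, _, L in combo]
            if any(a2 > b1 and a1 < b2
                   for (a1, a2), (b1, b2) in itertools.combinations(spans, 2)):
                continue
            ordered = sorted(combo)
            cov = sum(L for _, _, L in ordered)
            key = (-cov, tuple(i for i, _, _ in ordered),
                   tuple(st for _, st, _ in ordered))
            if best is None or key < best[0]:
                best = (key, ordered)
    ordered = best[1]
    segments = tuple((st, i) for i, st, _ in ordered)
    return segments, sum(L for _, _, L in ordered)


def oracle_fragments(actions, residual):
    """Straightforward leftmost-longest scan for token substrings >= 3."""
    frags, loose = [], []
    runs = []
    for i in residual:
        if runs and i == runs[-1][-1] + 1:
            runs[-1].append(i)
        else:
            runs.append([i])
    for run in runs:
        pos = 0
        while pos < len(run):
            match = None
            for L in range(len(run) - pos, 2, -1):
                window = tuple(actions[j] for j in run[pos:pos + L])
                cands = []
                for st in sorted(SUBTASKS):
                    tok = SUBTASKS[st]
                    for off in range(len(tok) - L + 1):
                        if tok[off:off + L] == window:
                            cands.append((st, off))
                if cands:
                    match = (min(cands), L)
                    break
            if match:
                (st, off), L = match
                crux_pos = SUBTASKS[st].index(SUBTASK_CRUX[st])
                frags.append((st, run[pos], L, off,
                              off <= crux_pos < off + L))
                pos += L
            else:
                loose.append(run[pos])
                pos += 1
    return frags, loose


def oracle_labels(actions, task, corpus, sugar_source=None):
    """Independent re-derivation of the subtask-level error labels."""
    from lesionlab.srn import valid_realizations
    actions = tuple(actions)
    if actions in set(valid_realizations(corpus, task, sugar_source)):
        return None  # correct episode
    segments, covered = oracle_parse(actions)
    inside = set()
    for st, start in segments:
        inside.update(range(start, start + len(SUBTASKS[st])))
    residual = [i for i in range(len(actions)) if i not in inside]
    frags, loose = oracle_fragments(actions, residual)

    events = [(start, SUBTASK_GOAL[st]) for st, start in segments]
    events += [(start, SUBTASK_GOAL[st])
               for st, start, L, off, has_crux in frags if has_crux]
    goals = [g for _, g in sorted(events)]
    expected_orders = bev.GOAL_ORDERS[task]
    expected = set(expected_orders[0])
    fulfilled = set(goals)

    omission = sum(1 for g in expected if g not in fulfilled)
    intrusion = 0
    perseveration = 0
    seen = set()
    for g in goals:
        if g in seen:
            perseveration += 1
        elif g not in expected:
            intrusion += 1
        seen.add(g)
    broken = 0
    for st, start, L, off, has_crux in frags:
        if not has_crux:
            if SUBTASK_GOAL[st] in fulfilled:
                perseveration += 1
            else:
                broken += 1
    reduced = []
    for g in goals:
        if g in expected and g not in reduced:
            reduced.append(g)

    def lcs(a, b):
        m = [[0] * (len(b) + 1) for _ in range(len(a) + 1)]
        for i in range(len(a)):
            for j in range(len(b)):
                m[i + 1][j + 1] = m[i][j] + 1 if a[i] == b[j] else \
                    max(m[i][j + 1], m[i + 1][j])
        return m[-1][-1]

    displacement = min(len(reduced) - lcs(reduced, list(o))
                       for o in expected_orders)
    return {"intrusion": intrusion, "omission": omission,
            "perseveration": perseveration, "displacement": displacement,
            "within_subtask": broken + len(loose)}


def _corrupted_episodes(corpus):
    """Hand-corrupted action strings (all <= 25 steps) with their task."""
    rng = np.random.default_rng(20)
    tea = list(corpus.tea[0].actions)      # packet variant, 20 steps
    tea_b = list(corpus.tea[1].actions)    # bowl variant, 20 steps
    cream = list(SUBTASKS["cream"])
    episodes = []
    # deletions of single actions and whole spans
    for k in (0, 4, 9, 14, 19):
        episodes.append(("tea", tea[:k] + tea[k + 1:]))
    episodes.append(("tea", tea[:10] + tea[15:]))        # sugar removed
    episodes.append(("tea", tea[:5] + tea[10:]))         # steep broken
    # insertions of foreign fragments (kept under 25 steps)
    episodes.append(("tea", tea[:15] + cream[:5] + tea[15:]))
    episodes.append(("tea", tea[:10] + cream[-4:] + tea[10:]))
    episodes.append(("tea", tea_b[:16] + tea_b[11:16] + tea_b[16:]))
    # substitutions and swaps
    swapped = tea.copy()
    swapped[3], swapped[8] = swapped[8], swapped[3]
    episodes.append(("tea", swapped))
    subbed = tea.copy()
    subbed[6] = "stir"
    episodes.append(("tea", subbed))
    # random garbage and truncations
    for n in (8, 15, 22):
        episodes.append(("tea", list(rng.choice(bev.ACTIONS, size=n))))
    episodes.append(("coffee", list(corpus.coffee[0].actions[:24])))
    episodes.append(("coffee", list(SUBTASKS["grounds"])
                     + list(SUBTASKS["drink"])))
    # perseverated and displaced token arrangements
    episodes.append(("tea", list(SUBTASKS["steep"]) + list(SUBTASKS["drink"])
                     + list(SUBTASKS["sugar_bowl_t"])))
    episodes.append(("tea", list(SUBTASKS["sugar_packet_t"])
                     + list(SUBTASKS["sugar_packet_t"])
                     + list(SUBTASKS["drink"])))
    episodes.append(("coffee", list(SUBTASKS["steep"])
                     + list(SUBTASKS["drink"])))
    assert all(len(a) <= 25 for _, a in episodes)
    return episodes


class TestParserAgainstOracle:
    def test_classifier_equals_bruteforce_on_corrupted_episodes(
            self, corpus_grammar):
        """The DP parser and rule set must agree with exhaustive-alignment
        brute force on every hand-corrupted episode of <= 25 steps."""
        corpus, _ = corpus_grammar
        for task, actions in _corrupted_episodes(corpus):
            parse = aa.parse_episode_actions(tuple(actions))
            oracle_segments, oracle_cov = oracle_parse(actions)
            assert parse.segments == oracle_segments, actions
            assert parse.covered == oracle_cov
            expected = oracle_labels(actions, task, corpus)
            got = aa.classify_episode(tuple(actions), corpus, task=task)
            if expected is None:
                assert got.correct
            else:
                assert got.subtask_counts == expected, actions


class TestClassifierExamples:
    def test_intact_episode_has_no_labels(self, corpus_grammar):
        corpus, _ = corpus_grammar
        got = aa.classify_episode(corpus.sequences[0].actions, corpus,
                                  task="coffee")
        assert got.correct
        assert got.total_subtask_errors == 0
        assert got.independent_actions == 0

    def test_coffee_without_cream_is_one_omission(self, corpus_grammar):
        corpus, _ = corpus_grammar
        seq = corpus.coffee[0]  # sugar-first: cream occupies steps 22..32
        actions = seq.actions[:21] + seq.actions[32:]
        got = aa.classify_episode(actions, corpus, task="coffee")
        assert got.subtask_counts["omission"] == 1
        assert got.subtask_counts["intrusion"] == 0
        assert got.subtask_counts["within_subtask"] == 0

    def test_tea_with_cream_inserted_is_one_intrusion(self, corpus_grammar):
        corpus, _ = corpus_grammar
        tea = corpus.tea[0].actions
        actions = tea[:15] + SUBTASKS["cream"] + tea[15:]
        got = aa.classify_episode(actions, corpus, task="tea")
        assert got.subtask_counts["intrusion"] == 1
        assert got.subtask_counts["omission"] == 0

    def test_unknown_task_rejected(self, corpus_grammar):
        corpus, _ = corpus_grammar
        with pytest.raises(ValueError):
            aa.classify_episode(("stir",), corpus, task="soup")


class TestSurvival:
    def test_first_divergence_cases(self, corpus_grammar):
        corpus, _ = corpus_grammar
        tea = corpus.tea[0].actions
        valids = [tea]
        assert aa.first_divergence(tea, valids) == 21  # no divergence
        assert aa.first_divergence(tea[:5] + ("stir",) + tea[6:], valids) == 6
        assert aa.first_divergence(tea[:7], valids) == 8  # truncation

    def test_all_correct_episodes_curve_at_one(self, srn_cohort,
                                               corpus_grammar):
        corpus, _ = corpus_grammar
        from lesionlab.srn import run_episode
        eps = [run_episode(srn_cohort[0], "tea", src)
               for src in ("packet", "bowl")]
        curve = aa.survival_analysis(eps, corpus)
        assert np.allclose(curve.proportion, 1.0)

    def test_constructed_failures_drop_at_step_five(self, corpus_grammar):
        corpus, _ = corpus_grammar
        from lesionlab.srn import EpisodeTrace
        tea = corpus.tea[0].actions
        bad = list(tea[:4]) + ["say_done"]
        eps = [EpisodeTrace("tea", False, "packet", bad, [False] * 5,
                            np.zeros((5, 1)), np.zeros((5, 1)))
               for _ in range(4)]
        curve = aa.survival_analysis(eps, corpus)
        assert np.allclose(curve.proportion[:4], 1.0)
        assert np.allclose(curve.proportion[4:], 0.0)

    def test_curve_monotone_non_increasing(self, srn_cohort, corpus_grammar):
        corpus, _ = corpus_grammar
        eps = aa.run_damaged_episodes(srn_cohort[0], corpus,
                                      "activation_noise", 0.10, "coffee",
                                      60, master_seed=3)
        curve = aa.survival_analysis(eps, corpus)
        assert (np.diff(curve.proportion) <= 1e-12).all()


class TestCruxAnalysis:
    def test_zero_error_cohort_all_proportions_zero(self):
        report = pd.DataFrame([{
            "damage_kind": "sever", "severity": 0.05,
            "independent_actions": 0, "crux_errors": 0,
            "non_crux_errors": 0, "total_actions": 400}])
        out = aa.crux_analysis(report)
        assert out["independent_proportion"].iloc[0] == 0
        assert out["non_crux_to_crux_ratio"].iloc[0] == 0

    def test_hand_labelled_ratio(self):
        report = pd.DataFrame([{
            "damage_kind": "sever", "severity": 0.05,
            "independent_actions": 12, "crux_errors": 3,
            "non_crux_errors": 9, "total_actions": 100}])
        out = aa.crux_analysis(report)
        assert out["non_crux_to_crux_ratio"].iloc[0] == pytest.approx(3.0)
        assert out["independent_proportion"].iloc[0] == pytest.approx(0.12)


class TestScaling:
    def test_no_failure_at_unit_scaling(self, srn_cohort, corpus_grammar):
        corpus, _ = corpus_grammar
        onset = aa.scaling_threshold_search(srn_cohort[:1], corpus, "coffee",
                                            s_grid=np.array([1.0]))
        assert onset == 0.0

    def test_descending_grid_required(self, srn_cohort, corpus_grammar):
        corpus, _ = corpus_grammar
        with pytest.raises(ValueError):
            aa.scaling_threshold_search(srn_cohort[:1], corpus, "coffee",
                                        s_grid=np.array([0.5, 0.9]))
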