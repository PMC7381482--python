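"""Semantic-pipeline analyses: areas, grids, attractors, weights, ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from lesionlab import semantic as sem
from lesionlab.hub import HubConfig, init_network


def curve_frame(rows):
    return pd.DataFrame(rows, columns=["network_id", "damage_kind",
                                       "severity", "replicate", "domain",
                                       "accuracy"])


class TestGrids:
    def test_default_grids_reproduce_printed_ladders(self):
        sever = sem.default_grid("sever")
        assert len(sever.levels) == 20
        assert sever.levels[0] == pytest.approx(0.025)
        assert sever.levels[-1] == pytest.approx(0.5)
        perturb = sem.default_grid("perturb_weights")
        assert len(perturb.levels) == 20
        assert perturb.levels[0] == pytest.approx(0.05)
        assert perturb.levels[-1] == pytest.approx(1.0)
        ablate = sem.default_grid("ablate_units")
        assert len(ablate.levels) == 21
        assert ablate.levels[0] == 0.0
        scale = sem.default_grid("scale_weights")
        assert len(scale.levels) == 21
        assert scale.levels[0] == pytest.approx(0.75)
        assert scale.levels[-1] == pytest.approx(0.55)

    def test_unordered_levels_rejected(self):
        with pytest.raises(ValueError):
            sem.DamageGrid("sever", (0.1, 0.3, 0.2))


class TestAreaBetweenCurves:
    def test_hand_built_two_level_area(self):
        rows = []
        for level, art, ani in ((0.1, 1.0, 1.0), (0.2, 0.8, 0.6)):
            rows.append((0, "sever", level, 0, "artefact", art))
            rows.append((0, "sever", level, 0, "animal", ani))
        rows += [(1, "sever", 0.1, 0, "artefact", 1.0),
                 (1, "sever", 0.1, 0, "animal", 1.0),
                 (1, "sever", 0.2, 0, "artefact", 0.8),
                 (1, "sever", 0.2, 0, "animal", 0.6)]
        res = sem.area_between_curves(curve_frame(rows))
        assert res.mean == pytest.approx(+0.10)

    def test_identical_curves_give_zero_area_ci_spanning_zero(self):
        rows = []
        for net in range(3):
            for level in (0.1, 0.2):
                acc = 0.9 - 0.1 * level + 0.01 * net
                rows.append((net, "sever", level, 0, "artefact", acc))
                rows.append((net, "sever", level, 0, "animal", acc))
        res = sem.area_between_curves(curve_frame(rows))
        assert res.mean == pytest.approx(0.0)
        assert res.ci95[0] <= 0 <= res.ci95[1]

    def test_antisymmetric_under_domain_swap(self):
        rng = np.random.default_rng(1)
        rows = []
        for net in range(4):
            for level in (0.1, 0.2, 0.3):
                a, b = rng.random(2)
                rows.append((net, "sever", level, 0, "artefact", a))
                rows.append((net, "sever", level, 0, "animal", b))
        df = curve_frame(rows)
        swapped = df.assign(domain=df["domain"].map(
            {"artefact": "animal", "animal": "artefact"}))
        res, res_sw = sem.area_between_curves(df), sem.area_between_curves(swapped)
        assert res.mean == pytest.approx(-res_sw.mean)

    def test_single_network_has_no_ci(self):
        rows = [(0, "sever", 0.1, 0, "artefact", 1.0),
                (0, "sever", 0.1, 0, "animal", 0.8)]
        res = sem.area_between_curves(curve_frame(rows))
        assert res.ci95 is None
        assert res.mean == pytest.approx(0.2)


class TestAttractors:
    def test_degenerate_identical_states_give_zero_distances(
            self, small_pattern_set):
        net = init_network(seed=0)
        for w in net.weights.values():
            w[:] = 0.0  # every item settles to the same hidden state
        summary = sem.attractor_summary(net, small_pattern_set)
        assert summary.mean_distance["animal"] == pytest.approx(0.0)
        assert summary.mean_distance["artefact"] == pytest.approx(0.0)

    def test_anova_identical_groups_near_zero_F(self):
        rng = np.random.default_rng(0)
        base = rng.random(8)

        def mk(vals):
            return [sem.AttractorSummary(np.zeros((2, 2)),
                                         {"animal": v, "artefact": v})
                    for v in vals]

        table = sem.attractor_anova({"P1": mk(base), "P2": mk(base)})
        assert table.loc["C(domain)", "F"] == pytest.approx(0.0, abs=1e-20)

    def test_anova_recovers_injected_domain_effect(self):
        rng = np.random.default_rng(7)
        summaries = {}
        for profile in ("P1", "P2"):
            ss = []
            for _ in range(10):
                animal = 4.0 + rng.normal(0, 0.05)
                artefact = animal + 0.3  # additive domain effect
                ss.append(sem.AttractorSummary(
                    np.zeros((2, 2)), {"animal": animal,
                                       "artefact": artefact}))
            summaries[profile] = ss
        table = sem.attractor_anova(summaries)
        assert table.loc["C(domain)", "PR(>F)"] < 0.001
        assert table.loc["C(domain):C(profile)", "F"] < 1.0

    def test_anova_matches_hand_computed_sums_of_squares(self):
        # balanced 2x2 with 3 observations per cell
        data = {("P1", "animal"): [4.0, 4.1, 3.9],
                ("P1", "artefact"): [4.3, 4.5, 4.4],
                ("P2", "animal"): [4.2, 4.4, 4.3],
                ("P2", "artefact"): [4.6, 4.8, 4.7]}
        summaries = {p: [sem.AttractorSummary(np.zeros((2, 2)),
                                              {"animal": data[(p, "animal")][i],
                                               "artefact": data[(p, "artefact")][i]})
                         for i in range(3)]
                     for p in ("P1", "P2")}
        table = sem.attractor_anova(summaries)
        # classic two-way ANOVA arithmetic
        y = np.array([data[k] for k in sorted(data)])  # 4 cells x 3
        grand = y.mean()
        dom_means = {d: np.mean([data[(p, d)] for p in ("P1", "P2")])
                     for d in ("animal", "artefact")}
        prof_means = {p: np.mean([data[(p, d)]
                                  for d in ("animal", "artefact")])
                      for p in ("P1", "P2")}
        ss_dom = 6 * sum((m - grand) ** 2 for m in dom_means.values())
        ss_prof = 6 * sum((m - grand) ** 2 for m in prof_means.values())
        cell_means = {k: np.mean(v) for k, v in data.items()}
        ss_cells = 3 * sum((m - grand) ** 2 for m in cell_means.values())
        ss_int = ss_cells - ss_dom - ss_prof
        ss_err = sum((x - cell_means[k]) ** 2
                     for k, v in data.items() for x in v)
        ms_err = ss_err / 8
        assert table.loc["C(domain)", "F"] == pytest.approx(
            (ss_dom / 1) / ms_err)
        assert table.loc["C(profile)", "F"] == pytest.approx(
            (ss_prof / 1) / ms_err)
        assert table.loc["C(domain):C(profile)", "F"] == pytest.approx(
            (ss_int / 1) / ms_err)

    def test_unbalanced_design_rejected(self):
        s = sem.AttractorSummary(np.zeros((2, 2)),
                                 {"animal": 1.0, "artefact": 2.0})
        with pytest.raises(ValueError):
            sem.attractor_anova({"P1": [s, s], "P2": [s]})


class TestWeightAndErrorSummaries:
    def test_toy_matrix_statistics(self):
        class Fake:
            weights = {"W": np.array([[-1.0, 0.0], [2.0, 3.0]])}

        df = sem.weight_summary([Fake()])
        by = df.set_index("statistic")["mean"]
        assert by["min"] == -1.0
        assert by["max"] == 3.0
        assert by["mean"] == 1.0
        assert by["proportion_positive"] == 0.5

    def test_all_positive_matrix(self):
        class Fake:
            weights = {"W": np.ones((3, 3))}

        df = sem.weight_summary([Fake()])
        prop = df.set_index("statistic")["mean"]["proportion_positive"]
        assert prop == 1.0

    def test_perfect_output_gives_zero_errors(self, small_pattern_set):
        net = init_network(seed=0)
        out = small_pattern_set.vectors.astype(float)
        df = sem.pattern_and_name_error(net, small_pattern_set, outputs=out)
        assert (df["pattern_error"] == 0).all()
        assert (df["name_error"] == 0).all()

    def test_single_unit_deviation_contributes_one(self, small_pattern_set):
        net = init_network(seed=0)
        out = small_pattern_set.vectors.astype(float)
        out[0, 100] += 1.0  # one unit off by exactly 1.0 (item 0 is a bird)
        df = sem.pattern_and_name_error(net, small_pattern_set, outputs=out)
        animal = df.set_index("domain").loc["animal"]
        assert animal["pattern_error"] == pytest.approx(1.0 / 24)
        assert animal["name_error"] == 0.0


class TestRunDamageGrid:
    def test_aggregation_matches_hand_computation(self, p2_cohort):
        nets, sets = p2_cohort
        grid = sem.DamageGrid("sever", (0.05, 0.25), lesions_per_level=2)
        curve = sem.run_damage_grid(nets[:2], grid, sets[:2], master_seed=3)
        assert set(curve["domain"]) == {"animal", "artefact"}
        assert len(curve) == 2 * 2 * 2 * 2  # nets x levels x reps x domains
        res = sem.area_between_curves(curve)
        by_hand = (curve.pivot_table(index=["network_id", "severity"],
                                     columns="domain", values="accuracy")
                   .assign(d=lambda t: t["artefact"] - t["animal"])
                   .groupby(level="network_id")["d"].mean())
        assert res.mean == pytest.approx(by_hand.mean())

    def test_scaling_is_deterministic_single_replicate(self, p2_cohort):
        nets, sets = p2_cohort
        grid = sem.DamageGrid("scale_weights", (0.7,), lesions_per_level=5)
        curve = sem.run_damage_grid(nets[:1], grid, sets[:1])
        assert curve["replicate"].max() == 0  # one replicate suffices


class TestTemplateVariantsStudy:
    def test_schema_and_aggregation(self):
        """With tiny untrained variants the study still reports one row per
        damage kind, and its means equal a hand recomputation from the same
        derived seeds."""
        from lesionlab.hub import init_network, train
        from lesionlab.patterns import build_profile, generate_patterns
        from lesionlab.seeds import derive_seed
        profile = build_profile("P2-like")
        grids = [sem.DamageGrid("sever", (0.1, 0.3), lesions_per_level=2)]
        out = sem.template_variants_study(profile, n_variants=2, grids=grids,
                                          epochs=0, master_seed=5)
        assert list(out["damage_kind"]) == ["sever"]
        # replicate the study's generation/seeding by hand
        sets, nets = [], []
        for i in range(2):
            sets.append(generate_patterns(profile, derive_seed(5, "variant", i)))
            net = init_network(seed=derive_seed(5, "netinit", i))
            train(net, sets[-1], epochs=0, seed=derive_seed(5, "train", i))
            nets.append(net)
        curve = sem.run_damage_grid(nets, grids[0], sets, 5)
        res = sem.area_between_curves(curve)
        assert out["mean_area"].iloc[0] == pytest.approx(res.mean)
        assert out["sd_area"].iloc[0] == pytest.approx(res.sd)

    def test_too_few_variants_rejected(self):
        from lesionlab.patterns import build_profile
        with pytest.raises(ValueError):
            sem.template_variants_study(build_profile("P2-like"),
                                        n_variants=1)
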