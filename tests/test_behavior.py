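import numpy as np
import pandas as pd
import pingouin as pg
import pytest

from emolearn import behavior, cohort, task
from emolearn.anova import mixed_anova

from .conftest import true_param_flagged
from .oracles import split_plot_anova_oracle


def _props_frame(cells: dict, n_per_group: int) -> pd.DataFrame:
    """Long proportions table from {(group, visit, condition): array} cells."""
    rows = []
    for (group, visit, condition), values in cells.items():
        for i, v in enumerate(values):
            rows.append(
                {
                    "participant_id": f"{group}{i:02d}",
                    "group": group,
                    "visit": visit,
                    "condition": condition,
                    "prop_ideal": v,
                }
            )
    return pd.DataFrame(rows)


def _exact_moments(n, mean, sd, rng):
    """Sample with exactly the requested mean and SD (for closed-form checks)."""
    z = rng.standard_normal(n)
    z = (z - z.mean()) / z.std(ddof=1)
    return mean + sd * z


class TestChanceTests:
    def test_null_cell_gives_zero_t(self):
        props = _props_frame(
            {("g1", "A", "emotional"): np.full(10, 0.5)}, 10
        )
        out = behavior.chance_tests(props)
        assert out["t"].iloc[0] == pytest.approx(0.0)
        assert not out["above_chance"].iloc[0]

    def test_summary_stats_reproduce_closed_form_t(self, rng):
        """A cell with M=0.54, SD=0.094, n=15 gives t ~ 1.65: not above
        chance at the Bonferroni-adjusted threshold."""
        x = _exact_moments(15, 0.54, 0.094, rng)
        props = _props_frame({("res", "C", "emotional"): x}, 15)
        out = behavior.chance_tests(props)
        t_expected = (0.54 - 0.5) / (0.094 / np.sqrt(15))
        assert out["t"].iloc[0] == pytest.approx(t_expected, abs=1e-9)
        assert out["t"].iloc[0] == pytest.approx(1.648, abs=0.01)
        assert out["p"].iloc[0] > behavior.BONFERRONI_ALPHA
        assert not out["above_chance"].iloc[0]

    def test_tiny_cell_skipped_with_reason(self):
        props = _props_frame({("g", "A", "neutral"): [0.7]}, 1)
        out = behavior.chance_tests(props)
        assert out["skipped"].iloc[0]
        assert np.isnan(out["t"].iloc[0])

    def test_responsive_cells_clear_adjusted_threshold(self, small_cohort):
        """Calibration: under the default generator all four responsive cells
        are significantly above chance in nearly every simulation."""
        _, labels = small_cohort
        analysed = labels.loc[labels["label"] != "unclassified"]
        from .conftest import true_param_proportions

        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            trials = task.simulate_visits(analysed, seed=3000 + seed)
            props = true_param_proportions(analysed, trials, task.DEFAULT_PARAM_MAP)
            out = behavior.chance_tests(props)
            resp = out.loc[out["group"] == "responsive"]
            hits += int(resp["above_chance"].all())
        assert hits >= 0.9 * n_seeds


class TestMixedAnova2x2x2:
    def test_no_variation_gives_zero_f(self):
        cells = {
            (g, v, c): np.full(10, 0.7)
            for g in ("a", "b") for v in ("A", "C") for c in ("emotional", "neutral")
        }
        out = behavior.mixed_anova_2x2x2(_props_frame(cells, 10))
        assert (out["F"] <= 1e-10).all()

    def test_balanced_fixture_matches_sums_of_squares_oracle(self, rng):
        n = 4
        Y = rng.normal(0.7, 0.1, size=(2 * n, 2, 2))
        groups = np.repeat(["res", "resp"], n)
        cells = {}
        for gi, g in enumerate(["res", "resp"]):
            for vi, v in enumerate(["A", "C"]):
                for ci, c in enumerate(["emotional", "neutral"]):
                    cells[(g, v, c)] = Y[groups == g, vi, ci]
        out = behavior.mixed_anova_2x2x2(_props_frame(cells, n)).set_index("Source")
        oracle = split_plot_anova_oracle(Y, groups)
        mapping = {
            "group": "group",
            "visit": "B",
            "group * visit": "group * B",
            "condition": "C",
            "group * condition": "group * C",
            "visit * condition": "B * C",
            "group * visit * condition": "group * B * C",
        }
        for source, key in mapping.items():
            assert out.loc[source, "F"] == pytest.approx(oracle[key], abs=1e-8), source

    def test_selective_recovery_of_injected_interaction(self):
        """A pure visit x condition effect shows up in that term only."""
        rng = np.random.default_rng(99)
        sig_vc = other_sig = 0
        n_sims = 100
        for _ in range(n_sims):
            cells = {}
            for g in ("res", "resp"):
                for v in ("A", "C"):
                    for c in ("emotional", "neutral"):
                        shift = 0.08 if (v == "C") == (c == "neutral") else 0.0
                        base = rng.normal(0.7 + shift, 0.08, size=12)
                        cells[(g, v, c)] = base
            # within-subject correlation: add a participant offset
            props = _props_frame(cells, 12)
            out = behavior.mixed_anova_2x2x2(props).set_index("Source")
            sig_vc += int(out.loc["visit * condition", "p"] < 0.05)
            other_sig += int(out.loc["group * visit", "p"] < 0.05)
        assert sig_vc >= 0.9 * n_sims
        assert other_sig <= 0.15 * n_sims

    def test_two_way_reduction_matches_pingouin(self, rng):
        """Independent library cross-check for the group x visit design."""
        n = 12
        rows = []
        for g in ("res", "resp"):
            for i in range(n):
                base = rng.normal(0.1 if g == "res" else 0.0, 0.2)
                for v in ("A", "C"):
                    rows.append(
                        {
                            "participant_id": f"{g}{i}",
                            "group": g,
                            "visit": v,
                            "score": base + rng.normal(0.05 if v == "C" else 0, 0.15),
                        }
                    )
        data = pd.DataFrame(rows)
        mine = mixed_anova(
            data, dv="score", subject="participant_id", between="group", within=["visit"]
        ).set_index("Source")
        ref = pg.mixed_anova(
            data, dv="score", subject="participant_id", between="group", within="visit"
        ).set_index("Source")
        assert mine.loc["group", "F"] == pytest.approx(ref.loc["group", "F"], rel=1e-6)
        assert mine.loc["visit", "F"] == pytest.approx(ref.loc["visit", "F"], rel=1e-6)
        assert mine.loc["group * visit", "F"] == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-6
        )

    def test_incomplete_participants_are_dropped(self):
        cells = {
            (g, v, c): np.full(6, 0.7)
            for g in ("a", "b") for v in ("A", "C") for c in ("emotional", "neutral")
        }
        props = _props_frame(cells, 6)
        props = props.drop(props[(props.participant_id == "a00") & (props.visit == "C")].index)
        out = behavior.mixed_anova_2x2x2(props)
        assert out.attrs["n_dropped"] == 1
        assert out.attrs["n_used"] == 11


class TestEmotionalBias:
    def _flagged(self, choices, ideal_options, missing=None):
        n = len(choices)
        return pd.DataFrame(
            {
                "participant_id": "p1",
                "visit": "A",
                "condition": "emotional",
                "block": 1,
                "trial": np.arange(1, n + 1),
                "choice": choices,
                "reward": 1,
                "missing": missing if missing is not None else [False] * n,
                "ideal_option": ideal_options,
            }
        )

    def test_pure_happy_chooser_scores_one(self):
        fl = self._flagged([1, 1, 1, 1], [2, 2, 1, 1])
        out = behavior.emotional_bias(fl)
        assert out["score"].iloc[0] == pytest.approx(1.0)  # 1 - 0

    def test_ideal_tracking_agent_scores_zero(self):
        fl = self._flagged([2, 2, 1, 1], [2, 2, 1, 1])
        out = behavior.emotional_bias(fl)
        assert out["score"].iloc[0] == pytest.approx(0.0)

    def test_count_fixture(self):
        """4 angry-ideal trials with 3 happy choices, 4 happy-ideal with one
        angry choice: score = 0.75 - 0.25 = 0.5."""
        choices = [1, 1, 1, 2, 2, 1, 1, 1]
        ideal = [2, 2, 2, 2, 1, 1, 1, 1]
        out = behavior.emotional_bias(self._flagged(choices, ideal))
        assert out["score"].iloc[0] == pytest.approx(0.5)
        assert out["n_angry_ideal"].iloc[0] == 4
        assert out["n_happy_ideal"].iloc[0] == 4

    def test_empty_conditioning_set_is_undefined(self):
        fl = self._flagged([1, 1], [1, 1])  # never angry-ideal
        out = behavior.emotional_bias(fl)
        assert np.isnan(out["score"].iloc[0])

    def test_ties_and_missing_trials_never_condition(self):
        fl = self._flagged([1, 1, 2, 1], [0, 2, 1, 2], missing=[False, False, False, True])
        out = behavior.emotional_bias(fl)
        # only trials 2 (angry-ideal, chose happy) and 3 (happy-ideal, chose angry)
        assert out["n_angry_ideal"].iloc[0] == 1
        assert out["n_happy_ideal"].iloc[0] == 1
        assert out["score"].iloc[0] == pytest.approx(1.0 - 1.0)

    def test_scores_bounded_on_simulated_cohort(self, small_cohort, simulated_trials):
        _, labels = small_cohort
        analysed = labels.loc[labels["label"] != "unclassified"]
        flagged = true_param_flagged(analysed, simulated_trials, task.DEFAULT_PARAM_MAP)
        scores = behavior.emotional_bias(flagged)
        defined = scores["score"].dropna()
        assert len(defined) > 0
        assert defined.between(-1, 1).all()


class TestBiasAnova:
    def test_identical_scores_give_zero_f(self):
        rows = [
            {"participant_id": f"{g}{i}", "group": g, "visit": v, "score": 0.1}
            for g in ("res", "resp") for i in range(5) for v in ("A", "C")
        ]
        out = behavior.bias_anova(pd.DataFrame(rows))
        assert (out["F"] <= 1e-12).all()

    def test_two_per_cell_fixture_matches_oracle(self, rng):
        n = 2
        Y = rng.normal(0.05, 0.1, size=(2 * n, 2))
        groups = np.repeat(["res", "resp"], n)
        rows = []
        for i in range(2 * n):
            for vi, v in enumerate(["A", "C"]):
                rows.append(
                    {
                        "participant_id": f"s{i}",
                        "group": groups[i],
                        "visit": v,
                        "score": Y[i, vi],
                    }
                )
        out = behavior.bias_anova(pd.DataFrame(rows)).set_index("Source")
        oracle = split_plot_anova_oracle(Y[:, :, None].repeat(2, axis=2), groups)
        assert out.loc["group", "F"] == pytest.approx(oracle["group"], abs=1e-8)
        assert out.loc["visit", "F"] == pytest.approx(oracle["B"], abs=1e-8)
        assert out.loc["group * visit", "F"] == pytest.approx(oracle["group * B"], abs=1e-8)

    def test_uniform_generator_reproduces_positive_grand_mean(self):
        """With identical agents everywhere (happy bias 0.32) the grand-mean
        emotional bias lands near the 0.069 level the scoring targets."""
        pm = {
            (g, v): task.AgentParams(0.35, 5.5, 0.32, 0.03)
            for g in ("resistant", "responsive") for v in ("A", "C")
        }
        _, labels = cohort.generate_cohort(seed=17)
        analysed = labels.loc[labels["label"] != "unclassified"]
        means = []
        for seed in range(20):
            trials = task.simulate_visits(analysed, param_map=pm, seed=6000 + seed)
            flagged = true_param_flagged(analysed, trials, pm)
            scores = behavior.emotional_bias(flagged)
            means.append(behavior.overall_bias_mean(scores)[0])
        assert np.mean(means) == pytest.approx(0.069, abs=0.02)
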