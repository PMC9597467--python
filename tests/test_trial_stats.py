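"""Treatment contrasts, Tukey letters, correlation, split-plot ANOVA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from yamnue import calibration, trial_stats
from yamnue.trial_stats import (
    compact_letter_display,
    pearson_r,
    split_plot_anova,
    treatment_contrast,
    tukey_letters,
)


def _frame(values_by_group, treatment="non-F", trait="y"):
    rows = []
    for g, vals in values_by_group.items():
        for i, v in enumerate(vals):
            rows.append({"genotype": g, "treatment": treatment, "block": 1 + i % 4,
                         "plant_id": f"p{i}", trait: v})
    return pd.DataFrame(rows)


class TestTreatmentContrast:
    def test_identical_arms_null_identity(self):
        frame = _frame({"A": [10, 12, 14]}, "non-F")
        frame = pd.concat([frame, _frame({"A": [10, 12, 14]}, "+F")], ignore_index=True)
        res = treatment_contrast(frame, "A", "y")
        assert res.t_statistic == 0.0 and res.p_value == 1.0 and not res.significant

    def test_well_separated_arms(self):
        frame = pd.concat([
            _frame({"A": [10.0, 10.1, 10.2, 9.9]}, "non-F"),
            _frame({"A": [20.0, 20.1, 19.9, 20.2]}, "+F"),
        ], ignore_index=True)
        res = treatment_contrast(frame, "A", "y")
        assert res.p_value < 1e-6 and res.significant

    def test_tiny_arm_rejected(self):
        frame = pd.concat([
            _frame({"A": [10.0]}, "non-F"),
            _frame({"A": [20.0, 21.0]}, "+F"),
        ], ignore_index=True)
        with pytest.raises(ValueError, match=">= 2 plants"):
            treatment_contrast(frame, "A", "y")

    def test_power_at_reference_effect_size(self):
        """A ~54 g shift against 20 g plant SD with 12 plants per arm is
        detected at alpha=0.05 in at least 95% of replicates."""
        rng = np.random.default_rng(7)
        hits = 0
        n_rep = 500
        for _ in range(n_rep):
            a = rng.normal(76.9, 20.0, 12)
            b = rng.normal(130.5, 20.0, 12)
            frame = pd.concat([
                _frame({"A": a}, "non-F"), _frame({"A": b}, "+F")
            ], ignore_index=True)
            hits += treatment_contrast(frame, "A", "y").significant
        assert hits / n_rep >= 0.95


class TestPearson:
    def test_reference_tuber_vs_nitrogen_uptake(self, reference_means):
        """+F dry tuber means vs +F N uptake means correlate at r = 0.98."""
        sel = reference_means[reference_means.treatment == "+F"]
        tuber = sel[sel.trait == "dry_tuber_weight_g"].set_index("genotype")["mean"]
        upn = sel[sel.trait == "uptake_N_g"].set_index("genotype")["mean"]
        r, p = pearson_r(tuber.sort_index(), upn.sort_index())
        assert round(r, 2) == 0.98
        assert p < 0.01

    def test_perfect_linearity(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r, p = pearson_r(x, 2 * x + 3)
        assert r == pytest.approx(1.0)

    def test_matches_brute_force_covariance(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            x, y = rng.normal(size=8), rng.normal(size=8)
            r, _ = pearson_r(x, y)
            brute = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
                np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
            )
            assert r == pytest.approx(brute, abs=1e-12)

    def test_t_based_p_consistent_with_permutation_null(self):
        """Two-sided p from the t transform agrees with a permutation p
        (10^4 shuffles) within Monte-Carlo/small-n error at n=6."""
        x = np.array([489.9, 433.3, 239.0, 313.8, 262.5, 370.3])
        y = np.array([2.2, 2.0, 1.4, 1.9, 1.7, 2.1])
        r_obs, p_t = pearson_r(x, y)
        rng = np.random.default_rng(5)
        count = 0
        n_perm = 10_000
        for _ in range(n_perm):
            r_perm = np.corrcoef(x, rng.permutation(y))[0, 1]
            count += abs(r_perm) >= abs(r_obs) - 1e-12
        p_perm = count / n_perm
        assert abs(p_perm - p_t) < 0.1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestTukeyLetters:
    def test_two_separated_groups(self):
        frame = _frame({"A": [10.0, 10.2, 9.8, 10.1], "B": [20.0, 20.2, 19.8, 20.1]})
        disp = tukey_letters(frame, "y", "non-F")
        assert disp.letters == {"B": "a", "A": "b"}

    def test_identical_groups_share_one_letter(self):
        frame = _frame({g: [10.0, 12.0, 14.0] for g in "ABCD"})
        disp = tukey_letters(frame, "y", "non-F")
        assert set(disp.letters.values()) == {"a"}

    def test_letters_consistent_with_p_matrix(self):
        """Sharing a letter <=> pairwise p >= alpha, on random instances."""
        rng = np.random.default_rng(21)
        for _ in range(25):
            k = rng.integers(3, 6)
            frame = _frame({
                f"G{i}": rng.normal(10 + 3 * rng.random() * i, 2.0, 5) for i in range(k)
            })
            disp = tukey_letters(frame, "y", "non-F")
            for a, b in itertools.combinations(sorted(disp.letters), 2):
                share = bool(set(disp.letters[a]) & set(disp.letters[b]))
                assert share == (disp.p_matrix.loc[a, b] >= disp.alpha)

    def test_matches_studentized_range_oracle(self):
        """Letter partition agrees with one built from a hand-computed
        Tukey-Kramer p-matrix (studentized range distribution)."""
        rng = np.random.default_rng(33)
        for _ in range(10):
            groups = {f"G{i}": rng.normal(5 * i * rng.random(), 3.0, 6) for i in range(3)}
            frame = _frame(groups)
            disp = tukey_letters(frame, "y", "non-F")

            names = sorted(groups)
            n = {g: len(groups[g]) for g in names}
            means = {g: float(np.mean(groups[g])) for g in names}
            df_err = sum(n.values()) - len(names)
            mse = sum(np.sum((np.asarray(groups[g]) - means[g]) ** 2) for g in names) / df_err
            pmat = pd.DataFrame(np.ones((3, 3)), index=names, columns=names)
            for a, b in itertools.combinations(names, 2):
                q = abs(means[a] - means[b]) / np.sqrt(mse / 2 * (1 / n[a] + 1 / n[b]))
                p = stats.studentized_range.sf(q, len(names), df_err)
                pmat.loc[a, b] = pmat.loc[b, a] = p
            oracle = compact_letter_display(means, pmat, alpha=0.05)
            assert oracle == disp.letters


def _simulate_plants(rng, means_by_gt, cv_main=0.10, cv_sub=0.10, cv_plant=0.20,
                     n_blocks=4, n_plants=3):
    """Minimal multiplicative-noise split-plot draw for ANOVA tests."""

    def factor(cv, size=None):
        if cv == 0:
            return 1.0 if size is None else np.ones(size)
        s2 = np.log1p(cv * cv)
        return rng.lognormal(-s2 / 2, np.sqrt(s2), size)

    rows = []
    for t in ("non-F", "+F"):
        for b in range(1, n_blocks + 1):
            fm = factor(cv_main)
            for g, mu in means_by_gt.items():
                fs = factor(cv_sub)
                for p in range(n_plants):
                    rows.append({"block": b, "treatment": t, "genotype": g, "plant_id": f"p{p}",
                                 "y": mu[t] * fm * fs * factor(cv_plant)})
    return pd.DataFrame(rows)


class TestSplitPlotAnova:
    def test_sums_of_squares_additive(self, plant_frame):
        table = split_plot_anova(plant_frame, "dry_tuber_weight_g").set_index("effect")
        parts = table.loc[["block", "treatment", "main_plot_error", "genotype",
                           "genotype_x_treatment", "subplot_error"], "ss"].sum()
        assert parts == pytest.approx(table.loc["total", "ss"], rel=1e-10)

    def test_missing_cell_rejected(self, plant_frame):
        broken = plant_frame[~((plant_frame.genotype == "TDr1499")
                               & (plant_frame.treatment == "+F"))]
        with pytest.raises(ValueError, match="incomplete"):
            split_plot_anova(broken, "dry_tuber_weight_g")

    def test_treatment_only_effect_detected_in_majority(self):
        """With a pure treatment effect, T is significant and G is not in
        the majority of runs."""
        rng = np.random.default_rng(13)
        t_sig = g_sig = 0
        n_runs = 50
        for _ in range(n_runs):
            means = {f"G{i}": {"non-F": 200.0, "+F": 320.0} for i in range(6)}
            frame = _simulate_plants(rng, means)
            table = split_plot_anova(frame, "y").set_index("effect")
            t_sig += table.loc["treatment", "p"] < 0.05
            g_sig += table.loc["genotype", "p"] < 0.05
        assert t_sig / n_runs > 0.5
        assert g_sig / n_runs < 0.5

    def test_interaction_power_with_responsiveness_gradient(self):
        """The calibrated genotype responsiveness gradient yields a
        detectable genotype x treatment interaction in >= 90% of runs."""
        means = {}
        ref = calibration.reference_means()
        for g in calibration.GENOTYPES:
            sel = ref[(ref.genotype == g) & (ref.trait == "dry_tuber_weight_g")]
            means[g] = {t: float(sel[sel.treatment == t]["mean"].iloc[0])
                        for t in ("non-F", "+F")}
        rng = np.random.default_rng(17)
        hits = 0
        n_runs = 100
        for _ in range(n_runs):
            table = split_plot_anova(_simulate_plants(rng, means), "y").set_index("effect")
            hits += table.loc["genotype_x_treatment", "p"] < 0.05
        assert hits / n_runs >= 0.9
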