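"""Group statistics: complete-case enforcement, the mixed-design ANOVA
decomposition (against independent oracles), Tukey post-hocs, regressions,
and group summaries."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats as sps

from whiskvib import synth
from whiskvib.stats import (
    InsufficientDataError,
    UnbalancedDataError,
    enforce_complete_cases,
    length_regression,
    mixed_anova,
    summarize_groups,
    tukey_within_species,
)

ANGLES = (0, 45, 90)


def make_table(values, species_of, angles=ANGLES):
    """Long table from a subjects x angles matrix and species labels."""
    rows = []
    for s, (vals, sp) in enumerate(zip(values, species_of)):
        for a, v in zip(angles, vals):
            rows.append(dict(subject_id=f"s{s:03d}", species=sp, angle_deg=a,
                             peak_freq_hz=v, peak_vel_m_s=v / 1000.0,
                             length_cm=7.0 + 0.1 * s))
    return pd.DataFrame(rows)


def random_table(rng, n_per_species=(4, 3, 5)):
    species = []
    for sp, n in zip(("A", "B", "C"), n_per_species):
        species += [sp] * n
    values = rng.normal(100, 15, size=(len(species), 3))
    return make_table(values, species)


class TestEnforceCompleteCases:
    def test_incomplete_subject_removed(self, default_table):
        broken = default_table[
            ~(
                (default_table.subject_id == "harbor_seal_001")
                & (default_table.angle_deg == 90)
            )
        ]
        out, removed = enforce_complete_cases(broken)
        assert removed == ["harbor_seal_001"]
        assert "harbor_seal_001" not in set(out.subject_id)

    def test_complete_table_identity(self, default_table):
        out, removed = enforce_complete_cases(default_table)
        assert removed == []
        pd.testing.assert_frame_equal(out, default_table)

    def test_study_attrition_pattern(self):
        """9/8/9 subjects with 1/0/3 incomplete leaves 8/8/6 — the sample the
        group statistics ran on."""
        design = synth.StudyDesign(
            n_subjects={"california_sea_lion": 9, "elephant_seal": 8,
                        "harbor_seal": 9},
            seed=5,
        )
        tab = synth.generate_study_table(design)
        drop = ["california_sea_lion_002", "harbor_seal_001", "harbor_seal_004",
                "harbor_seal_007"]
        broken = tab[~(tab.subject_id.isin(drop) & (tab.angle_deg == 90))]
        out, removed = enforce_complete_cases(broken)
        counts = out.groupby("species")["subject_id"].nunique()
        assert counts.to_dict() == {"california_sea_lion": 8, "elephant_seal": 8,
                                    "harbor_seal": 6}
        assert sorted(removed) == sorted(drop)

    def test_too_few_subjects_rejected(self):
        tab = make_table(np.ones((2, 3)), ["A", "A"])
        broken = tab[~((tab.subject_id == "s000") & (tab.angle_deg == 90))]
        with pytest.raises(InsufficientDataError):
            enforce_complete_cases(broken)


class TestMixedAnova:
    def test_df_layout(self, default_table):
        a = mixed_anova(default_table, "peak_freq_hz").table
        assert a["DF"].tolist() == [2, 2, 4, 19, 38]
        assert a["DF"].sum() == len(default_table) - 1

    def test_constant_data_gives_zero_ss(self):
        tab = make_table(np.full((6, 3), 42.0), ["A"] * 3 + ["B"] * 3)
        a = mixed_anova(tab, "peak_freq_hz").table
        assert np.allclose(a["SS"], 0.0, atol=1e-9)

    def test_ss_additivity(self, default_table):
        a = mixed_anova(default_table, "peak_freq_hz").table
        y = default_table["peak_freq_hz"].to_numpy()
        total = ((y - y.mean()) ** 2).sum()
        assert a["SS"].sum() == pytest.approx(total, rel=1e-9)

    def test_matches_pingouin(self, default_table):
        """Independent oracle: pingouin's mixed ANOVA on the same table."""
        mine = mixed_anova(default_table, "peak_freq_hz").table
        ref = pg.mixed_anova(
            data=default_table, dv="peak_freq_hz", within="angle_deg",
            subject="subject_id", between="species",
        ).set_index("Source")
        assert mine.loc["species", "F"] == pytest.approx(ref.loc["species", "F"])
        assert mine.loc["angle", "F"] == pytest.approx(ref.loc["angle_deg", "F"])
        assert mine.loc["interaction", "F"] == pytest.approx(
            ref.loc["Interaction", "F"]
        )
        assert mine.loc["angle", "p"] == pytest.approx(ref.loc["angle_deg", "p_unc"])

    def test_matches_projection_oracle(self):
        """Brute-force oracle: sequential least-squares model comparison
        (intercept -> +angle -> +species -> +interaction -> +subjects)
        reproduces every SS term to 1e-8 on 10 random unbalanced datasets."""
        rng = np.random.default_rng(123)
        for _ in range(10):
            tab = random_table(rng)
            mine = mixed_anova(tab, "peak_freq_hz").table
            y = tab["peak_freq_hz"].to_numpy()
            cols = [np.ones(len(tab))]
            rss = []
            for factors in (
                ["angle_deg"],
                ["species"],
                ["interaction"],
                ["subject_id"],
            ):
                if factors == ["interaction"]:
                    d = pd.get_dummies(
                        tab["species"].astype(str) + "@" + tab["angle_deg"].astype(str)
                    ).to_numpy(float)
                else:
                    d = pd.get_dummies(tab[factors[0]]).to_numpy(float)
                cols.append(d)
                X = np.column_stack(sum([[c] if c.ndim == 1 else list(c.T)
                                         for c in cols], []))
                res = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
                rss.append(float(res @ res))
            tss = float(((y - y.mean()) ** 2).sum())
            ss_angle = tss - rss[0]
            ss_species = rss[0] - rss[1]
            ss_inter = rss[1] - rss[2]
            ss_subj = rss[2] - rss[3]
            ss_resid = rss[3]
            assert mine.loc["angle", "SS"] == pytest.approx(ss_angle, abs=1e-8)
            assert mine.loc["species", "SS"] == pytest.approx(ss_species, abs=1e-8)
            assert mine.loc["interaction", "SS"] == pytest.approx(ss_inter, abs=1e-8)
            assert mine.loc["subjects", "SS"] == pytest.approx(ss_subj, abs=1e-8)
            assert mine.loc["residual", "SS"] == pytest.approx(ss_resid, abs=1e-8)

    def test_single_species_reduces_to_one_way_rm(self, default_table):
        sub = default_table[default_table.species == "elephant_seal"]
        mine = mixed_anova(sub, "peak_freq_hz").table
        ref = pg.rm_anova(data=sub, dv="peak_freq_hz", within="angle_deg",
                          subject="subject_id")
        assert mine.loc["angle", "F"] == pytest.approx(ref["F"].iloc[0])
        assert "species" not in mine.index

    def test_unbalanced_rejected(self, default_table):
        broken = default_table.iloc[:-1]
        with pytest.raises(UnbalancedDataError):
            mixed_anova(broken, "peak_freq_hz")

    def test_type_one_error_calibrated(self):
        """Under the null the angle test rejects at ~5% (600 seeded reps)."""
        rng = np.random.default_rng(77)
        tab = synth.generate_study_table(synth.default_study_design(seed=0))
        crit = sps.f.isf(0.05, 2, 38)
        rej = 0
        reps = 600
        for _ in range(reps):
            tab["peak_freq_hz"] = rng.standard_normal(len(tab))
            rej += mixed_anova(tab, "peak_freq_hz").table.loc["angle", "F"] > crit
        assert rej / reps == pytest.approx(0.05, abs=0.025)


class TestTukey:
    def test_three_comparisons_per_species(self, default_table):
        a = mixed_anova(default_table, "peak_freq_hz")
        tk = tukey_within_species(default_table, "peak_freq_hz", a).table
        assert len(tk) == 9
        assert (tk.groupby("species").size() == 3).all()
        pairs = set(map(tuple, tk[["angle_1", "angle_2"]].to_numpy()))
        assert pairs == {(0, 45), (0, 90), (45, 90)}

    def test_zero_differences_give_p_near_one(self):
        vals = np.tile([[100.0, 100.0, 100.0]], (8, 1))
        vals = vals + np.random.default_rng(0).normal(0, 1e-9, vals.shape)
        tab = make_table(vals, ["A"] * 4 + ["B"] * 4)
        a = mixed_anova(tab, "peak_freq_hz")
        tk = tukey_within_species(tab, "peak_freq_hz", a).table
        assert np.allclose(tk["mean_diff"], 0.0, atol=1e-6)
        assert (tk["p_adj"] > 0.9).all()

    def test_sign_convention_first_minus_second(self, default_table):
        """Frequency decreases with angle, so 0 vs 90 differences are
        positive; velocity increases, so they are negative."""
        a_f = mixed_anova(default_table, "peak_freq_hz")
        tk_f = tukey_within_species(default_table, "peak_freq_hz", a_f).table
        d = tk_f[(tk_f.angle_1 == 0) & (tk_f.angle_2 == 90)]["mean_diff"]
        assert (d > 0).all()
        a_v = mixed_anova(default_table, "peak_vel_m_s")
        tk_v = tukey_within_species(default_table, "peak_vel_m_s", a_v).table
        d = tk_v[(tk_v.angle_1 == 0) & (tk_v.angle_2 == 90)]["mean_diff"]
        assert (d < 0).all()

    def test_power_for_large_angle_effect(self):
        """Means 200/150/100 with sigma ~ 15 and n = 8: the 0 vs 90 contrast
        is detected at p < 0.001 in >= 95% of seeded replicates."""
        rng = np.random.default_rng(55)
        hits = 0
        reps = 40
        for _ in range(reps):
            vals = np.array([200.0, 150.0, 100.0]) + rng.normal(0, 15, (16, 3))
            tab = make_table(vals, ["A"] * 8 + ["B"] * 8)
            a = mixed_anova(tab, "peak_freq_hz")
            tk = tukey_within_species(tab, "peak_freq_hz", a).table
            sub = tk[(tk.angle_1 == 0) & (tk.angle_2 == 90)]
            hits += (sub["p_adj"] < 0.001).all()
        assert hits / reps >= 0.95

    def test_familywise_error_near_nominal(self):
        """Under the null the chance of any of the 3 within-species
        comparisons at p < 0.05 is ~5% (seeded)."""
        rng = np.random.default_rng(99)
        fw = 0
        reps = 400
        for _ in range(reps):
            vals = rng.normal(0, 1, (8, 3))
            tab = make_table(vals, ["A"] * 8)
            a = mixed_anova(tab, "peak_freq_hz")
            tk = tukey_within_species(tab, "peak_freq_hz", a).table
            fw += (tk["p_adj"] < 0.05).any()
        assert fw / reps == pytest.approx(0.05, abs=0.02)


class TestLengthRegression:
    def test_exact_line(self):
        rows = []
        for s, x in enumerate(np.linspace(6.0, 9.0, 10)):
            for a in ANGLES:
                rows.append(dict(subject_id=f"s{s}", species="A", angle_deg=a,
                                 peak_freq_hz=2 * x + 1, peak_vel_m_s=0.0,
                                 length_cm=x))
        res = length_regression(pd.DataFrame(rows), "peak_freq_hz")
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)
        assert res.n == 10

    def test_independent_variable_r2_near_zero(self):
        rng = np.random.default_rng(8)
        rows = []
        for s in range(200):
            rows.append(dict(subject_id=f"s{s}", species="A", angle_deg=0,
                             peak_freq_hz=rng.normal(150, 30),
                             peak_vel_m_s=0.0, length_cm=rng.normal(7.7, 0.55)))
        res = length_regression(pd.DataFrame(rows), "peak_freq_hz")
        assert res.r_squared < 0.05

    def test_slope_recovery_with_weak_signal(self):
        """A -20 Hz/cm effect buried in noise tuned to r^2 ~ 0.07 is
        recovered on average (200 seeded replicates of n = 26)."""
        rng = np.random.default_rng(14)
        slopes, r2s = [], []
        for _ in range(200):
            x = rng.normal(7.7, 0.55, 26)
            y = 300.0 - 20.0 * x + rng.normal(0, 39.0, 26)
            rows = [
                dict(subject_id=f"s{i}", species="A", angle_deg=0,
                     peak_freq_hz=yi, peak_vel_m_s=0.0, length_cm=xi)
                for i, (xi, yi) in enumerate(zip(x, y))
            ]
            res = length_regression(pd.DataFrame(rows), "peak_freq_hz")
            slopes.append(res.slope)
            r2s.append(res.r_squared)
        assert np.mean(slopes) == pytest.approx(-20.0, abs=5.0)
        assert 0.03 < np.mean(r2s) < 0.15

    def test_zero_length_variance_rejected(self):
        rows = [dict(subject_id=f"s{i}", species="A", angle_deg=0,
                     peak_freq_hz=float(i), peak_vel_m_s=0.0, length_cm=7.0)
                for i in range(5)]
        with pytest.raises(InsufficientDataError):
            length_regression(pd.DataFrame(rows), "peak_freq_hz")


class TestSummaries:
    def test_hand_computed_cell(self):
        tab = make_table(np.array([[100.0, 0, 0], [110.0, 0, 0], [120.0, 0, 0]]),
                         ["A"] * 3)
        s = summarize_groups(tab, "peak_freq_hz")
        cell = s[(s.species == "A") & (s.angle_deg == 0)].iloc[0]
        assert cell["mean"] == pytest.approx(110.0)
        assert cell["se"] == pytest.approx(5.7735, abs=1e-3)
        assert (cell["min"], cell["max"]) == (100.0, 120.0)
        assert cell["n"] == 3

    def test_single_value_cell_flagged(self):
        tab = make_table(np.array([[100.0, 0, 0]]), ["A"])
        s = summarize_groups(tab, "peak_freq_hz")
        cell = s[(s.species == "A") & (s.angle_deg == 0)].iloc[0]
        assert cell["se"] == 0.0
        assert bool(cell["se_flagged"])
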