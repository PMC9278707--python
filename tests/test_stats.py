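import numpy as np
import pandas as pd
import pytest

from lvatlas import (
    CohortDesign,
    align_meshes,
    compute_atlas,
    compare_mode_scores,
    rm_anova_growth,
    sample_shape_params,
    two_way_anova_bonferroni,
)
from lvatlas.meshfit import mesh_from_shape
from lvatlas.stats import default_posthoc_pairs


def balanced_layout(n_cell=6):
    ox = np.repeat(["room_air", "high_O2"], 3 * n_cell)
    tr = np.tile(np.repeat(["CD", "CD_Ang17", "CD_Ala"], n_cell), 2)
    return ox, tr


def anova_oracle(y, ox, tr):
    """Hand sums-of-squares for a balanced two-factor layout."""
    y = np.asarray(y, float)
    ox_levels, tr_levels = list(dict.fromkeys(ox)), list(dict.fromkeys(tr))
    a, b = len(ox_levels), len(tr_levels)
    n = len(y) // (a * b)
    grand = y.mean()
    cell = np.array([[y[(ox == o) & (tr == t)].mean() for t in tr_levels]
                     for o in ox_levels])
    am, bm = cell.mean(1), cell.mean(0)
    ss_a = b * n * ((am - grand) ** 2).sum()
    ss_b = a * n * ((bm - grand) ** 2).sum()
    ss_ab = n * ((cell - am[:, None] - bm[None, :] + grand) ** 2).sum()
    ss_e = sum(((y[(ox == o) & (tr == t)] - cell[i, j]) ** 2).sum()
               for i, o in enumerate(ox_levels) for j, t in enumerate(tr_levels))
    df_e = a * b * (n - 1)
    return {
        "oxygen": (ss_a / (a - 1)) / (ss_e / df_e),
        "treatment": (ss_b / (b - 1)) / (ss_e / df_e),
        "interaction": (ss_ab / ((a - 1) * (b - 1))) / (ss_e / df_e),
    }


class TestCompareModeScores:
    @staticmethod
    def small_atlas(master_seed=2):
        design = CohortDesign(master_seed=master_seed)
        meshes, labels = [], {}
        for ox, tr in design.cells():
            for i in range(design.n_per_cell):
                m = mesh_from_shape(sample_shape_params(design, ox, tr, i), 8, 8)
                cid = f"{ox}-{tr}-{i}"
                m.provenance["case_id"] = cid
                meshes.append(m)
                labels[cid] = ox
        aligned, _ = align_meshes(meshes)
        return compute_atlas(aligned), labels

    def test_identical_groups_give_t0_p1(self):
        atlas, labels = self.small_atlas()
        # mirror group A's scores onto group B by relabelling symmetric halves
        sym = {cid: ("A" if i % 2 == 0 else "B") for i, cid in enumerate(atlas.case_ids)}
        atlas.scores = np.vstack([atlas.scores[::2], atlas.scores[::2]])
        atlas.case_ids = [c for c in atlas.case_ids[::2]] + [c + "_dup" for c in atlas.case_ids[::2]]
        labels = {c: ("A" if not c.endswith("_dup") else "B") for c in atlas.case_ids}
        res = compare_mode_scores(atlas, labels, modes=[1])
        assert res.ttests[0].t_statistic == 0.0
        assert res.ttests[0].p_value == 1.0

    def test_separated_groups_significant(self):
        atlas, _ = self.small_atlas()
        labels = {}
        rng = np.random.default_rng(0)
        atlas.scores = atlas.scores.copy()
        for i, cid in enumerate(atlas.case_ids):
            group = "lo" if i < 12 else "hi"
            atlas.scores[i, 0] = (0.0 if group == "lo" else 1.0) + rng.normal(0, 1e-3)
            labels[cid] = group
        res = compare_mode_scores(atlas, labels, modes=[1])
        assert res.ttests[0].p_value < 0.01

    def test_oxygen_separation_on_generated_cohort(self):
        atlas, labels = self.small_atlas()
        res = compare_mode_scores(atlas, labels, modes=[1, 2])
        assert res.ttests[0].p_value < 0.05  # hyperoxia shifts mode 1

    def test_errors(self):
        atlas, labels = self.small_atlas()
        with pytest.raises(IndexError):
            compare_mode_scores(atlas, labels, modes=[atlas.n_modes + 1])
        one_case = {c: ("A" if i == 0 else "B") for i, c in enumerate(atlas.case_ids)}
        with pytest.raises(ValueError):
            compare_mode_scores(atlas, one_case)


class TestTwoWayAnova:
    def test_all_equal_values(self):
        ox, tr = balanced_layout(3)
        res = two_way_anova_bonferroni(np.ones(18), ox, tr)
        assert all(e.f_statistic == 0.0 and e.p_value == 1.0 for e in res.effects)
        assert all(p.p_raw == 1.0 and p.p_adjusted == 1.0 for p in res.posthoc)

    def test_matches_hand_sums_of_squares_oracle(self, rng):
        """Large injected oxygen effect: F statistics agree with the
        brute-force sums-of-squares oracle to 1e-10 and oxygen p < 0.001."""
        ox, tr = balanced_layout(6)
        y = rng.normal(size=36) + 3.0 * (ox == "high_O2")
        res = two_way_anova_bonferroni(y, ox, tr)
        oracle = anova_oracle(y, ox, tr)
        for name, f_expected in oracle.items():
            assert res.effect(name).f_statistic == pytest.approx(f_expected, abs=1e-10)
        assert res.effect("oxygen").p_value < 1e-3

    def test_unbalanced_type3_path(self, rng):
        ox, tr = balanced_layout(4)
        y = rng.normal(size=len(ox))
        keep = np.ones(len(ox), bool)
        keep[[0, 1, 7]] = False  # unbalance two cells
        res = two_way_anova_bonferroni(y[keep], ox[keep], tr[keep])
        assert len(res.effects) == 3
        assert all(0 <= e.p_value <= 1 for e in res.effects)

    def test_bonferroni_adjustment_properties(self, rng):
        ox, tr = balanced_layout(4)
        y = rng.normal(size=len(ox))
        res = two_way_anova_bonferroni(y, ox, tr, posthoc_pairs="all")
        assert len(res.posthoc) == 15
        for p in res.posthoc:
            assert p.p_adjusted >= p.p_raw
            assert p.p_adjusted <= 1.0
            assert p.p_adjusted == pytest.approx(min(1.0, p.p_raw * 15))

    def test_default_pairs_are_the_six_figure_comparisons(self):
        pairs = default_posthoc_pairs()
        assert len(pairs) == 6
        assert (("room_air", "CD"), ("high_O2", "CD")) in pairs

    def test_errors(self, rng):
        ox, tr = balanced_layout(2)
        y = rng.normal(size=len(ox))
        with pytest.raises(ValueError):  # empty cell
            keep = ~((ox == "room_air") & (tr == "CD"))
            two_way_anova_bonferroni(y[keep], ox[keep], tr[keep])
        with pytest.raises(ValueError):  # constant within cells, different means
            means = pd.factorize(pd.Series(list(zip(ox, tr))))[0].astype(float)
            two_way_anova_bonferroni(means, ox, tr)

    def test_null_calibration_smoke(self):
        """Type-I error of the oxygen effect near nominal (small replicate
        count here; the full 2000-replicate check runs in the acceptance
        suite)."""
        rng = np.random.default_rng(99)
        ox, tr = balanced_layout(6)
        rej = sum(
            two_way_anova_bonferroni(rng.normal(size=36), ox, tr,
                                     posthoc_pairs=None).effect("oxygen").p_value < 0.05
            for _ in range(400)
        )
        assert 0.02 <= rej / 400 <= 0.08


class TestRMAnovaGrowth:
    @staticmethod
    def panel(slopes=(0.0, 1.0), n=6, noise=0.3, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for g, slope in zip("AB", slopes):
            for a in range(n):
                intercept = rng.normal(0, 0.5)
                for tp in range(4):
                    rows.append({
                        "animal_id": f"{g}{a}", "group": g, "timepoint": tp,
                        "value": intercept + slope * tp + rng.normal(0, noise),
                    })
        return pd.DataFrame(rows)

    def test_flat_identical_trajectories_give_p1(self):
        df = self.panel(slopes=(0, 0), noise=0)
        df["value"] = 5.0
        res = rm_anova_growth(df)
        assert all(e.p_value == 1.0 for e in res.effects)

    def test_different_slopes_detected_as_interaction(self):
        res = rm_anova_growth(self.panel())
        assert res.effect("interaction").p_value < 0.05
        assert res.effect("time").p_value < 0.05

    def test_animal_order_invariance(self):
        df = self.panel()
        r1 = rm_anova_growth(df)
        r2 = rm_anova_growth(df.sample(frac=1.0, random_state=3))
        for e1, e2 in zip(r1.effects, r2.effects):
            assert e1.f_statistic == pytest.approx(e2.f_statistic, abs=1e-10)

    def test_missing_cell_rejected(self):
        df = self.panel().iloc[:-1]
        with pytest.raises(ValueError):
            rm_anova_growth(df)
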