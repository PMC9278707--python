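"""Group-comparison statistics for shape modes and echo endpoints.

Three tests cover the study's comparisons: unpaired t-tests on PCA mode
scores (Welch by default), 2×3 factorial ANOVA with Bonferroni-adjusted
pairwise post-hoc tests for the endpoint tables, and a mixed
repeated-measures ANOVA for growth curves (between-group factor × time
with animal as the repeated unit).

Balanced factorial layouts use an exact closed-form sums-of-squares
computation (identical to type-III there); unbalanced layouts fall back
to a type-III linear-model fit via statsmodels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "EffectResult",
    "PosthocResult",
    "TTestResult",
    "StatResult",
    "compare_mode_scores",
    "two_way_anova_bonferroni",
    "rm_anova_growth",
    "default_posthoc_pairs",
]


@dataclass(frozen=True)
class EffectResult:
    name: str
    f_statistic: float
    df_num: float
    df_den: float
    p_value: float


@dataclass(frozen=True)
class PosthocResult:
    pair: tuple[tuple[str, str], tuple[str, str]]
    mean_a: float
    mean_b: float
    t_statistic: float
    p_raw: float
    p_adjusted: float


@dataclass(frozen=True)
class TTestResult:
    label: str
    t_statistic: float
    df: float
    p_value: float
    mean_a: float
    mean_b: float
    mean_difference: float
    n_a: int
    n_b: int


@dataclass
class StatResult:
    """Container for one statistical comparison."""

    test_name: str
    effects: list[EffectResult] = field(default_factory=list)
    posthoc: list[PosthocResult] = field(default_factory=list)
    ttests: list[TTestResult] = field(default_factory=list)
    alpha: float = 0.05

    def effect(self, name: str) -> EffectResult:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"kind": "effect", "name": e.name, "statistic": e.f_statistic,
             "df1": e.df_num, "df2": e.df_den, "p": e.p_value}
            for e in self.effects
        ]
        rows += [
            {"kind": "posthoc", "name": f"{p.pair[0]} vs {p.pair[1]}",
             "statistic": p.t_statistic, "p": p.p_raw, "p_adj": p.p_adjusted}
            for p in self.posthoc
        ]
        rows += [
            {"kind": "ttest", "name": t.label, "statistic": t.t_statistic,
             "df1": t.df, "p": t.p_value, "mean_diff": t.mean_difference}
            for t in self.ttests
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# t-tests on mode scores
# ---------------------------------------------------------------------------


def compare_mode_scores(
    atlas,
    labels: dict[str, str] | pd.Series,
    modes: list[int] | None = None,
    welch: bool = True,
    alpha: float = 0.05,
) -> StatResult:
    """Two-sided unpaired t-tests on PCA mode coefficients by group.

    Parameters
    ----------
    atlas:
        :class:`~lvatlas.atlas.ShapeAtlas` with per-case scores.
    labels:
        Mapping case id → group label; exactly two groups required,
        each with at least 2 cases.
    modes:
        1-based mode indices (default ``[1, 2]``).
    welch:
        Welch's unequal-variance t-test (default); ``False`` for
        Student's pooled-variance variant.
    """
    modes = modes or [1, 2]
    lab = pd.Series(labels)
    lab = lab.reindex(atlas.case_ids)
    if lab.isna().any():
        missing = list(lab.index[lab.isna()])
        raise KeyError(f"labels missing for cases {missing}")
    groups = sorted(lab.unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    ia = np.asarray(lab == groups[0])
    ib = np.asarray(lab == groups[1])
    if ia.sum() < 2 or ib.sum() < 2:
        raise ValueError("each group needs at least 2 cases")

    result = StatResult(test_name="unpaired t-test on PCA mode scores", alpha=alpha)
    for m in modes:
        if not 1 <= m <= atlas.n_modes:
            raise IndexError(f"mode {m} outside the {atlas.n_modes} retained modes")
        a = atlas.scores[ia, m - 1]
        b = atlas.scores[ib, m - 1]
        if np.allclose(a.var(ddof=1) + b.var(ddof=1), 0) and np.isclose(a.mean(), b.mean()):
            t_stat, p, df = 0.0, 1.0, float(len(a) + len(b) - 2)
        else:
            res = sps.ttest_ind(a, b, equal_var=not welch)
            t_stat, p, df = float(res.statistic), float(res.pvalue), float(res.df)
        result.ttests.append(TTestResult(
            label=f"mode_{m}: {groups[0]} vs {groups[1]}",
            t_statistic=t_stat, df=df, p_value=p,
            mean_a=float(a.mean()), mean_b=float(b.mean()),
            mean_difference=float(a.mean() - b.mean()),
            n_a=int(ia.sum()), n_b=int(ib.sum()),
        ))
    return result


# ---------------------------------------------------------------------------
# two-way factorial ANOVA + Bonferroni post-hoc
# ---------------------------------------------------------------------------


def default_posthoc_pairs(
    oxygen_levels=("room_air", "high_O2"),
    treatment_levels=("CD", "CD_Ang17", "CD_Ala"),
) -> list[tuple[tuple[str, str], tuple[str, str]]]:
    """The six cell-wise comparisons displayed in the endpoint figures.

    Each active treatment against its same-exposure vehicle (4 pairs)
    plus room-air vs high-O₂ within the vehicle and within the first
    active treatment (2 pairs).
    """
    ra, ho = oxygen_levels
    veh = treatment_levels[0]
    pairs = []
    for ox in (ra, ho):
        for tr in treatment_levels[1:]:
            pairs.append(((ox, veh), (ox, tr)))
    pairs.append(((ra, veh), (ho, veh)))
    pairs.append(((ra, treatment_levels[1]), (ho, treatment_levels[1])))
    return pairs


def _balanced_two_way(y, a_codes, b_codes, na, nb):
    """Closed-form factorial sums of squares for a balanced layout."""
    n_cell = len(y) // (na * nb)
    grand = y.mean()
    cell_means = np.zeros((na, nb))
    sse = 0.0
    for i in range(na):
        for j in range(nb):
            cell = y[(a_codes == i) & (b_codes == j)]
            cell_means[i, j] = cell.mean()
            sse += ((cell - cell.mean()) ** 2).sum()
    a_means = cell_means.mean(axis=1)
    b_means = cell_means.mean(axis=0)
    ss_a = nb * n_cell * ((a_means - grand) ** 2).sum()
    ss_b = na * n_cell * ((b_means - grand) ** 2).sum()
    inter = cell_means - a_means[:, None] - b_means[None, :] + grand
    ss_ab = n_cell * (inter**2).sum()
    df_a, df_b, df_ab = na - 1, nb - 1, (na - 1) * (nb - 1)
    df_e = na * nb * (n_cell - 1)
    mse = sse / df_e
    out = []
    for name, ss, df in (("oxygen", ss_a, df_a), ("treatment", ss_b, df_b),
                         ("interaction", ss_ab, df_ab)):
        if mse == 0:
            f = 0.0 if ss <= 1e-300 else np.inf
        else:
            f = (ss / df) / mse
        p = 1.0 if f == 0 else float(sps.f.sf(f, df, df_e))
        out.append(EffectResult(name, float(f), float(df), float(df_e), p))
    return out


def _type3_two_way(df: pd.DataFrame):
    """Type-III factorial ANOVA via an effect-coded linear model."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    model = smf.ols(
        "value ~ C(oxygen, Sum) * C(treatment, Sum)", data=df
    ).fit()
    table = sm.stats.anova_lm(model, typ=3)
    name_map = {
        "C(oxygen, Sum)": "oxygen",
        "C(treatment, Sum)": "treatment",
        "C(oxygen, Sum):C(treatment, Sum)": "interaction",
    }
    out = []
    for row_name, name in name_map.items():
        row = table.loc[row_name]
        out.append(EffectResult(
            name, float(row["F"]), float(row["df"]),
            float(table.loc["Residual", "df"]), float(row["PR(>F)"]),
        ))
    return out


def two_way_anova_bonferroni(
    values,
    oxygen,
    treatment,
    posthoc_pairs: list | str | None = "default",
    welch: bool = True,
    alpha: float = 0.05,
) -> StatResult:
    """2×3-style factorial ANOVA followed by Bonferroni post-hoc t-tests.

    Main effects and interaction use type-III sums of squares (closed
    form on balanced layouts).  Post-hoc comparisons are pairwise
    two-sample t-tests on the requested cell pairs, with raw p-values
    multiplied by the number of comparisons (capped at 1).
    """
    df = pd.DataFrame({
        "value": np.asarray(values, dtype=float),
        "oxygen": np.asarray(oxygen),
        "treatment": np.asarray(treatment),
    })
    ox_levels = list(pd.unique(df["oxygen"]))
    tr_levels = list(pd.unique(df["treatment"]))
    counts = df.groupby(["oxygen", "treatment"], sort=False).size()
    if len(counts) < len(ox_levels) * len(tr_levels):
        raise ValueError("empty cell in the factorial layout")
    if counts.min() < 2:
        raise ValueError("every cell needs at least 2 observations")
    within_var = df.groupby(["oxygen", "treatment"])["value"].var(ddof=1)
    if np.allclose(within_var, 0):
        if df.groupby(["oxygen", "treatment"])["value"].mean().nunique() == 1:
            # completely constant data: all F = 0, p = 1
            pass
        else:
            raise ValueError("zero within-cell variance everywhere; F undefined")

    a_codes = df["oxygen"].map({l: i for i, l in enumerate(ox_levels)}).to_numpy()
    b_codes = df["treatment"].map({l: i for i, l in enumerate(tr_levels)}).to_numpy()
    balanced = counts.nunique() == 1
    if balanced:
        effects = _balanced_two_way(df["value"].to_numpy(), a_codes, b_codes,
                                    len(ox_levels), len(tr_levels))
    else:
        effects = _type3_two_way(df)

    result = StatResult(
        test_name="two-way factorial ANOVA + Bonferroni post-hoc",
        effects=effects, alpha=alpha,
    )

    if posthoc_pairs is not None:
        if posthoc_pairs == "default":
            pairs = default_posthoc_pairs(tuple(ox_levels), tuple(tr_levels))
        elif posthoc_pairs == "all":
            cells = [(o, t) for o in ox_levels for t in tr_levels]
            pairs = list(itertools.combinations(cells, 2))
        else:
            pairs = list(posthoc_pairs)
        m = len(pairs)
        for (cell_a, cell_b) in pairs:
            ya = df.loc[(df["oxygen"] == cell_a[0]) & (df["treatment"] == cell_a[1]), "value"]
            yb = df.loc[(df["oxygen"] == cell_b[0]) & (df["treatment"] == cell_b[1]), "value"]
            if len(ya) == 0 or len(yb) == 0:
                raise ValueError(f"post-hoc pair {cell_a} vs {cell_b} has an empty cell")
            if np.allclose(ya.var(ddof=1) + yb.var(ddof=1), 0) and np.isclose(ya.mean(), yb.mean()):
                t_stat, p = 0.0, 1.0
            else:
                res = sps.ttest_ind(ya, yb, equal_var=not welch)
                t_stat, p = float(res.statistic), float(res.pvalue)
            result.posthoc.append(PosthocResult(
                pair=(cell_a, cell_b),
                mean_a=float(ya.mean()), mean_b=float(yb.mean()),
                t_statistic=t_stat, p_raw=p,
                p_adjusted=min(1.0, p * m),
            ))
    return result


# ---------------------------------------------------------------------------
# repeated-measures ANOVA for growth curves
# ---------------------------------------------------------------------------


def rm_anova_growth(
    weights: pd.DataFrame,
    alpha: float = 0.05,
) -> StatResult:
    """Mixed repeated-measures ANOVA on a growth-curve panel.

    ``weights`` is long-format with columns ``animal_id``, ``group``,
    ``timepoint``, ``value``.  Every animal must appear at every
    timepoint (no imputation).  The univariate F uses animal-within-group
    as the error term for the between factor (via pingouin's mixed
    ANOVA: group, time, and group × time effects).
    """
    required = {"animal_id", "group", "timepoint", "value"}
    if not required.issubset(weights.columns):
        raise ValueError(f"weights table must have columns {sorted(required)}")
    panel = weights.pivot_table(index="animal_id", columns="timepoint",
                                values="value", aggfunc="count")
    if panel.isna().any().any() or (panel != 1).any().any():
        raise ValueError("incomplete panel: every animal needs exactly one "
                         "value per timepoint")

    data = weights.sort_values(["animal_id", "timepoint"]).reset_index(drop=True)
    if data.groupby("animal_id")["value"].var(ddof=0).sum() == 0 and \
            data.groupby("timepoint")["value"].nunique().max() == 1:
        # flat identical trajectories: nothing to test
        effects = [EffectResult(n, 0.0, np.nan, np.nan, 1.0)
                   for n in ("group", "time", "interaction")]
        return StatResult("repeated-measures ANOVA (growth curve)",
                          effects=effects, alpha=alpha)

    import pingouin as pg
    aov = pg.mixed_anova(data=data, dv="value", within="timepoint",
                         subject="animal_id", between="group")
    aov = aov.set_index("Source")
    name_map = {"group": "group", "timepoint": "time", "Interaction": "interaction"}
    effects = []
    for src, name in name_map.items():
        row = aov.loc[src]
        p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
        effects.append(EffectResult(
            name, float(row["F"]), float(row["DF1"]), float(row["DF2"]),
            float(row[p_col]),
        ))
    return StatResult("repeated-measures ANOVA (growth curve)",
                      effects=effects, alpha=alpha)
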