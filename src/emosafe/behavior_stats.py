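"""Factorial ANOVA, simple effects, summary-statistics ANOVA and OLS with VIF.

The classical balanced sums-of-squares decomposition is authored here (it
is the quantity under test throughout); unbalanced two-way layouts fall
back to a Type II decomposition via statsmodels, and regression goes
through statsmodels OLS.  Effect sizes are reported both as classical
eta-squared (SS_effect / SS_total, additive across effects) and partial
eta-squared (SS_effect / (SS_effect + SS_error)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PairwiseComparison:
    factor: str
    level_a: str
    level_b: str
    mean_a: float
    mean_b: float
    t: float
    p_adjusted: float
    direction: str  # e.g. "fear > anger"


@dataclass
class AnovaEffect:
    name: str
    ss: float
    df: int
    F: float
    p: float
    eta_sq: float
    partial_eta_sq: float

    @property
    def ms(self) -> float:
        return self.ss / self.df if self.df else float("nan")


@dataclass
class AnovaResult:
    effects: dict[str, AnovaEffect]
    ss_error: float
    df_error: int
    ss_total: float
    posthoc: list[PairwiseComparison] = field(default_factory=list)

    @property
    def ms_error(self) -> float:
        return self.ss_error / self.df_error

    def effect(self, name: str) -> AnovaEffect:
        return self.effects[name]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "effect": e.name,
                "ss": e.ss,
                "df": e.df,
                "ms": e.ms,
                "F": e.F,
                "p": e.p,
                "eta_sq": e.eta_sq,
                "partial_eta_sq": e.partial_eta_sq,
            }
            for e in self.effects.values()
        ]
        rows.append(
            {
                "effect": "error",
                "ss": self.ss_error,
                "df": self.df_error,
                "ms": self.ms_error,
                "F": np.nan,
                "p": np.nan,
                "eta_sq": self.ss_error / self.ss_total if self.ss_total else np.nan,
                "partial_eta_sq": np.nan,
            }
        )
        return pd.DataFrame(rows)


@dataclass
class RegressionResult:
    table: pd.DataFrame  # index: predictors (+ const); columns B, se, t, p, vif
    r_squared: float
    residuals: np.ndarray

    @property
    def intercept(self) -> float:
        return float(self.table.loc["const", "B"])


def _effect(name, ss, df, ss_error, df_error, ss_total) -> AnovaEffect:
    if df == 0:  # degenerate (e.g. single-level factor): no test possible
        return AnovaEffect(
            name=name, ss=ss, df=0, F=float("nan"), p=float("nan"),
            eta_sq=ss / ss_total if ss_total > 0 else 0.0,
            partial_eta_sq=0.0,
        )
    ms = ss / df
    mse = ss_error / df_error
    f = ms / mse if mse > 0 else (0.0 if ss == 0 else np.inf)
    p = float(stats.f.sf(f, df, df_error)) if np.isfinite(f) else 0.0
    return AnovaEffect(
        name=name,
        ss=ss,
        df=df,
        F=float(f),
        p=p,
        eta_sq=ss / ss_total if ss_total > 0 else 0.0,
        partial_eta_sq=ss / (ss + ss_error) if (ss + ss_error) > 0 else 0.0,
    )


def _bonferroni_pairs(
    factor: str, groups: dict[str, np.ndarray]
) -> list[PairwiseComparison]:
    """Pairwise Welch t-tests with Bonferroni correction across all pairs."""
    pairs = list(combinations(groups, 2))
    out = []
    for a, b in pairs:
        t, p = stats.ttest_ind(groups[a], groups[b], equal_var=False)
        ma, mb = float(np.mean(groups[a])), float(np.mean(groups[b]))
        hi, lo = (a, b) if ma >= mb else (b, a)
        out.append(
            PairwiseComparison(
                factor=factor,
                level_a=a,
                level_b=b,
                mean_a=ma,
                mean_b=mb,
                t=float(t),
                p_adjusted=min(1.0, float(p) * len(pairs)),
                direction=f"{hi} > {lo}",
            )
        )
    return out


def one_way_anova(values, group_labels, posthoc: bool = False) -> AnovaResult:
    """Classical one-way between-groups ANOVA."""
    y = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    levels = list(dict.fromkeys(labels))
    if len(levels) < 2:
        raise ValueError("one-way ANOVA needs at least 2 groups")
    groups = {lev: y[labels == lev] for lev in levels}
    small = [lev for lev, g in groups.items() if len(g) < 2]
    if small:
        raise ValueError(f"groups with < 2 observations: {small}")

    gm = y.mean()
    ss_total = float(((y - gm) ** 2).sum())
    ss_between = float(
        sum(len(g) * (g.mean() - gm) ** 2 for g in groups.values())
    )
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in groups.values()))
    df_b, df_w = len(levels) - 1, len(y) - len(levels)
    eff = _effect("group", ss_between, df_b, ss_within, df_w, ss_total)
    result = AnovaResult(
        effects={"group": eff}, ss_error=ss_within, df_error=df_w, ss_total=ss_total
    )
    if posthoc:
        result.posthoc = _bonferroni_pairs("group", groups)
    return result


def _check_layout(fa: np.ndarray, fb: np.ndarray):
    a_levels = list(dict.fromkeys(fa))
    b_levels = list(dict.fromkeys(fb))
    counts = {}
    for al in a_levels:
        for bl in b_levels:
            n = int(np.sum((fa == al) & (fb == bl)))
            if n == 0:
                raise ValueError(f"empty cell ({al!r}, {bl!r}) in the factorial layout")
            counts[(al, bl)] = n
    balanced = len(set(counts.values())) == 1
    return a_levels, b_levels, counts, balanced


def two_way_anova(
    dv,
    factor_a,
    factor_b,
    a_name: str = "emotion",
    b_name: str = "psycap",
    unbalanced: str = "error",
) -> AnovaResult:
    """Two-way between-subjects factorial ANOVA with interaction.

    Balanced complete layouts use the classical decomposition; an unbalanced
    layout raises unless ``unbalanced='type2'``, which delegates to a
    statsmodels Type II fit (classical eta-squared then uses Type II SS).
    """
    y = np.asarray(dv, dtype=float)
    fa = np.asarray(factor_a)
    fb = np.asarray(factor_b)
    if not (len(y) == len(fa) == len(fb)):
        raise ValueError("dv and factors must have equal length")
    a_levels, b_levels, counts, balanced = _check_layout(fa, fb)

    if not balanced:
        if unbalanced != "type2":
            raise ValueError(
                "unbalanced layout; pass unbalanced='type2' for a Type II "
                f"decomposition (cell counts: {counts})"
            )
        return _two_way_type2(y, fa, fb, a_name, b_name)

    gm = y.mean()
    ss_total = float(((y - gm) ** 2).sum())
    ss_a = float(
        sum(np.sum(fa == al) * (y[fa == al].mean() - gm) ** 2 for al in a_levels)
    )
    ss_b = float(
        sum(np.sum(fb == bl) * (y[fb == bl].mean() - gm) ** 2 for bl in b_levels)
    )
    ss_cells = 0.0
    ss_error = 0.0
    for (al, bl), n in counts.items():
        cell = y[(fa == al) & (fb == bl)]
        ss_cells += n * (cell.mean() - gm) ** 2
        ss_error += float(((cell - cell.mean()) ** 2).sum())
    ss_ab = ss_cells - ss_a - ss_b

    df_a, df_b_ = len(a_levels) - 1, len(b_levels) - 1
    df_ab = df_a * df_b_
    df_err = len(y) - len(a_levels) * len(b_levels)
    inter = f"{a_name}:{b_name}"
    effects = {
        a_name: _effect(a_name, ss_a, df_a, ss_error, df_err, ss_total),
        b_name: _effect(b_name, ss_b, df_b_, ss_error, df_err, ss_total),
        inter: _effect(inter, ss_ab, df_ab, ss_error, df_err, ss_total),
    }
    return AnovaResult(
        effects=effects, ss_error=ss_error, df_error=df_err, ss_total=ss_total
    )


def _two_way_type2(y, fa, fb, a_name, b_name) -> AnovaResult:
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({"y": y, "a": fa, "b": fb})
    fit = smf.ols("y ~ C(a) * C(b)", data=df).fit()
    tab = sm.stats.anova_lm(fit, typ=2)
    ss_total = float(((y - y.mean()) ** 2).sum())
    ss_error = float(tab.loc["Residual", "sum_sq"])
    df_err = int(tab.loc["Residual", "df"])
    mapping = {"C(a)": a_name, "C(b)": b_name, "C(a):C(b)": f"{a_name}:{b_name}"}
    effects = {}
    for key, name in mapping.items():
        effects[name] = _effect(
            name, float(tab.loc[key, "sum_sq"]), int(tab.loc[key, "df"]),
            ss_error, df_err, ss_total,
        )
    return AnovaResult(
        effects=effects, ss_error=ss_error, df_error=df_err, ss_total=ss_total
    )


def simple_effects(
    dv,
    focal_factor,
    moderator,
    level: str | None = None,
    error: str = "pooled",
    focal_name: str = "emotion",
    alpha: float = 0.05,
) -> dict[str, AnovaResult]:
    """Effect of the focal factor within each level of the moderator.

    ``error='pooled'`` (default) tests each simple effect against the full
    factorial model's error term; ``error='within'`` uses only the data of
    that moderator level (equivalent to a one-way ANOVA there).  Simple
    effects significant at ``alpha`` get Bonferroni-corrected pairwise
    comparisons with direction.
    """
    y = np.asarray(dv, dtype=float)
    ff = np.asarray(focal_factor)
    mod = np.asarray(moderator)
    if error not in ("pooled", "within"):
        raise ValueError(f"unknown error term {error!r}")
    mod_levels = list(dict.fromkeys(mod))
    if level is not None:
        if level not in mod_levels:
            raise ValueError(
                f"unknown moderator level {level!r}; available: {mod_levels}"
            )
        mod_levels = [level]

    full = two_way_anova(y, ff, mod, a_name="focal", b_name="moderator")
    out: dict[str, AnovaResult] = {}
    for ml in mod_levels:
        mask = mod == ml
        sub_y, sub_f = y[mask], ff[mask]
        if error == "within":
            res = one_way_anova(sub_y, sub_f)
            eff = res.effects.pop("group")
            eff.name = focal_name
            res.effects[focal_name] = eff
        else:
            levels = list(dict.fromkeys(sub_f))
            lm = sub_y.mean()
            ss_focal = float(
                sum(
                    np.sum(sub_f == fl) * (sub_y[sub_f == fl].mean() - lm) ** 2
                    for fl in levels
                )
            )
            df_focal = len(levels) - 1
            eff = _effect(
                focal_name, ss_focal, df_focal, full.ss_error, full.df_error,
                full.ss_total,
            )
            res = AnovaResult(
                effects={focal_name: eff},
                ss_error=full.ss_error,
                df_error=full.df_error,
                ss_total=full.ss_total,
            )
        if eff.p < alpha:
            groups = {fl: sub_y[sub_f == fl] for fl in dict.fromkeys(sub_f)}
            res.posthoc = _bonferroni_pairs(focal_name, groups)
        out[ml] = res
    return out


def repeated_measures_anova(
    dv, subject, within_factor, factor_name: str = "emotion"
) -> AnovaResult:
    """One-way repeated-measures ANOVA (each subject under every level).

    Removes the between-subject SS from the error term, so the factor is
    tested against the subject-by-condition residual.  This is the
    within-subject alternative to treating repeated observations as
    independent groups; the factorial functions above deliberately follow
    the between-subjects convention instead, and this one is provided for
    sensitivity analysis.
    """
    y = np.asarray(dv, dtype=float)
    subj = np.asarray(subject)
    fac = np.asarray(within_factor)
    levels = list(dict.fromkeys(fac))
    subjects = list(dict.fromkeys(subj))
    if len(levels) < 2:
        raise ValueError("need at least 2 within-subject levels")
    for s in subjects:
        seen = list(fac[subj == s])
        if sorted(seen) != sorted(levels):
            raise ValueError(
                f"subject {s!r} must appear exactly once per level, got {seen}"
            )

    n, a = len(subjects), len(levels)
    gm = y.mean()
    ss_total = float(((y - gm) ** 2).sum())
    ss_subj = float(sum(a * (y[subj == s].mean() - gm) ** 2 for s in subjects))
    ss_fac = float(sum(n * (y[fac == lev].mean() - gm) ** 2 for lev in levels))
    ss_err = ss_total - ss_subj - ss_fac
    df_fac, df_err = a - 1, (a - 1) * (n - 1)
    eff = _effect(factor_name, ss_fac, df_fac, ss_err, df_err, ss_total)
    return AnovaResult(
        effects={factor_name: eff}, ss_error=ss_err, df_error=df_err,
        ss_total=ss_total,
    )


def anova_from_summary(cells: dict, design: str = "two-way") -> AnovaResult:
    """Reconstruct an ANOVA from per-cell (mean, sd, n) summaries.

    ``cells`` maps a level (one-way) or an ``(a_level, b_level)`` pair
    (two-way) to a ``(mean, sd, n)`` triple; sd is the sample standard
    deviation (ddof=1).  Between-group SS come from the cell means and
    sizes, within-group SS from pooling ``(n - 1) * sd**2``, so the result
    matches a raw-data ANOVA whose summaries these are.
    """
    for key, (mean, sd, n) in cells.items():
        if n < 2:
            raise ValueError(f"cell {key!r} needs n >= 2, got {n}")
        if sd < 0:
            raise ValueError(f"cell {key!r} has negative sd")

    total_n = sum(n for _, _, n in cells.values())
    gm = sum(m * n for m, _, n in cells.values()) / total_n
    ss_within = float(sum((n - 1) * sd**2 for _, sd, n in cells.values()))

    if design == "one-way":
        ss_between = float(sum(n * (m - gm) ** 2 for m, _, n in cells.values()))
        df_b = len(cells) - 1
        df_w = total_n - len(cells)
        ss_total = ss_between + ss_within
        eff = _effect("group", ss_between, df_b, ss_within, df_w, ss_total)
        return AnovaResult(
            effects={"group": eff}, ss_error=ss_within, df_error=df_w,
            ss_total=ss_total,
        )
    if design != "two-way":
        raise ValueError(f"unknown design {design!r}")

    a_levels = list(dict.fromkeys(a for a, _ in cells))
    b_levels = list(dict.fromkeys(b for _, b in cells))
    missing = [
        (a, b) for a in a_levels for b in b_levels if (a, b) not in cells
    ]
    if missing:
        raise ValueError(f"missing cells in the factorial grid: {missing}")

    def marginal(levels, axis):
        ss = 0.0
        for lev in levels:
            sel = [
                (m, n) for (a, b), (m, _, n) in cells.items()
                if (a if axis == 0 else b) == lev
            ]
            n_lev = sum(n for _, n in sel)
            m_lev = sum(m * n for m, n in sel) / n_lev
            ss += n_lev * (m_lev - gm) ** 2
        return float(ss)

    ss_a = marginal(a_levels, 0)
    ss_b = marginal(b_levels, 1)
    ss_cells = float(sum(n * (m - gm) ** 2 for m, _, n in cells.values()))
    ss_ab = ss_cells - ss_a - ss_b
    ss_total = ss_cells + ss_within
    df_a, df_b_ = len(a_levels) - 1, len(b_levels) - 1
    df_err = total_n - len(a_levels) * len(b_levels)
    effects = {
        "emotion": _effect("emotion", ss_a, df_a, ss_within, df_err, ss_total),
        "psycap": _effect("psycap", ss_b, df_b_, ss_within, df_err, ss_total),
        "emotion:psycap": _effect(
            "emotion:psycap", ss_ab, df_a * df_b_, ss_within, df_err, ss_total
        ),
    }
    return AnovaResult(
        effects=effects, ss_error=ss_within, df_error=df_err, ss_total=ss_total
    )


def summarize_cells(dv, factor_a, factor_b=None) -> dict:
    """Per-cell (mean, sd, n) summaries in the format anova_from_summary reads."""
    y = np.asarray(dv, dtype=float)
    fa = np.asarray(factor_a)
    if factor_b is None:
        return {
            lev: (
                float(y[fa == lev].mean()),
                float(y[fa == lev].std(ddof=1)),
                int(np.sum(fa == lev)),
            )
            for lev in dict.fromkeys(fa)
        }
    fb = np.asarray(factor_b)
    out = {}
    for al in dict.fromkeys(fa):
        for bl in dict.fromkeys(fb):
            cell = y[(fa == al) & (fb == bl)]
            out[(al, bl)] = (
                float(cell.mean()), float(cell.std(ddof=1)), int(len(cell))
            )
    return out


def multiple_regression(response, predictor_table: pd.DataFrame) -> RegressionResult:
    """OLS of ``response`` on the predictors, with per-predictor VIF.

    VIF_j = 1 / (1 - R^2_j) where R^2_j comes from regressing predictor j
    (with intercept) on the remaining predictors.
    """
    import statsmodels.api as sm

    y = np.asarray(response, dtype=float)
    x = predictor_table.astype(float)
    n, p = x.shape
    if n <= p + 1:
        raise ValueError(f"need more than {p + 1} rows for {p} predictors, got {n}")
    design = sm.add_constant(x, has_constant="add", prepend=True)
    if np.linalg.matrix_rank(design.values) < design.shape[1]:
        dependent = [
            col for col in x.columns
            if np.linalg.matrix_rank(design.drop(columns=[col]).values)
            == np.linalg.matrix_rank(design.values)
        ]
        raise ValueError(
            f"rank-deficient predictor matrix; dependent columns: {dependent}"
        )
    fit = sm.OLS(y, design).fit()

    vif = {}
    for col in x.columns:
        others = sm.add_constant(x.drop(columns=[col]), has_constant="add", prepend=True)
        r2_j = sm.OLS(x[col].values, others).fit().rsquared if p > 1 else 0.0
        vif[col] = 1.0 / (1.0 - r2_j) if r2_j < 1.0 else np.inf

    table = pd.DataFrame(
        {
            "B": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
            "vif": pd.Series(vif),
        }
    )
    return RegressionResult(
        table=table, r_squared=float(fit.rsquared), residuals=np.asarray(fit.resid)
    )
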