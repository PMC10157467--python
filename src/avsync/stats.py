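"""Group-level inferential statistics for SJ/TOJ cohorts.

Covers the study battery: a mixed group x ISI ANOVA on synchrony proportions
per stimulus order, per-ISI simple effects with LSD post hocs, one-way ANOVAs
on window measures, a paired VA-vs-AV contrast within group, an ANCOVA on
temporal-order-judgment error percentages controlling for SJ synchrony, child
demographic matching tests, and a three-block hierarchical regression of
reading scores on demographics, literacy skills and the binding window.

ANOVA tables are tidy DataFrames with columns
``effect, F, df1, df2, p, np2`` (np2 = partial eta squared). LSD post hocs
are unadjusted pairwise t-tests on the pooled within-cell error term.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pingouin as pg
import statsmodels.api as sm
from scipy import stats as sps

from avsync.io import profiles_to_frame

ANOVA_COLUMNS = ["effect", "F", "df1", "df2", "p", "np2"]


def _p_column(aov: pd.DataFrame) -> pd.Series:
    # pingouin renamed 'p-unc' to 'p_unc' across versions
    for name in ("p_unc", "p-unc"):
        if name in aov.columns:
            return aov[name]
    raise KeyError("no uncorrected p-value column in ANOVA table")


def _as_profile_frame(profiles) -> pd.DataFrame:
    if isinstance(profiles, pd.DataFrame):
        return profiles
    return profiles_to_frame(profiles)


def _complete_order_table(profiles, order: str) -> pd.DataFrame:
    """Wide participant x ISI table of synchrony proportions for one order,
    restricted to participants with all ISI cells present."""
    df = _as_profile_frame(profiles)
    df = df[df["order"] == order].copy()
    df["isi_ms"] = df["soa_ms"].abs()
    wide = df.pivot_table(
        index=["participant_id", "group"], columns="isi_ms", values="proportion"
    )
    return wide.dropna(axis=0)


def mixed_anova_synchrony(
    profiles, order: str, correction: bool = False
) -> pd.DataFrame:
    """Mixed ANOVA: between = group, within = ISI, dv = synchrony proportion.

    Participants missing any ISI cell for the order are dropped listwise.
    No sphericity correction by default (``correction=True`` applies
    Greenhouse-Geisser to the within effects' p-values).
    """
    wide = _complete_order_table(profiles, order)
    if wide.index.get_level_values("group").nunique() < 2:
        raise ValueError("mixed ANOVA needs at least 2 groups")
    long = wide.stack().rename("proportion").reset_index()
    aov = pg.mixed_anova(
        data=long,
        dv="proportion",
        within="isi_ms",
        subject="participant_id",
        between="group",
        correction=correction,
    )
    p = _p_column(aov)
    gg = [c for c in aov.columns if "GG" in c]
    if correction and gg:
        p = aov[gg[0]].fillna(p)
    out = pd.DataFrame(
        {
            "effect": aov["Source"].replace({"isi_ms": "isi", "Interaction": "group x isi"}),
            "F": aov["F"],
            "df1": aov["DF1"].astype(int),
            "df2": aov["DF2"].astype(int),
            "p": p,
            "np2": aov["np2"],
        }
    )
    return out[ANOVA_COLUMNS].reset_index(drop=True)


def lsd_pairwise(values: Sequence[float], groups: Sequence[str]) -> pd.DataFrame:
    """Least-significant-difference post hoc: unadjusted pairwise t-tests on
    the pooled within-group error term (df = N - g)."""
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    labels = sorted(set(g))
    ns = {lbl: int((g == lbl).sum()) for lbl in labels}
    means = {lbl: float(y[g == lbl].mean()) for lbl in labels}
    ss_within = sum(float(((y[g == lbl] - means[lbl]) ** 2).sum()) for lbl in labels)
    df_err = len(y) - len(labels)
    mse = ss_within / df_err
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            diff = means[a] - means[b]
            se = np.sqrt(mse * (1.0 / ns[a] + 1.0 / ns[b]))
            t = diff / se if se > 0 else np.nan
            p = 2.0 * sps.t.sf(abs(t), df_err) if np.isfinite(t) else np.nan
            rows.append({"A": a, "B": b, "mean_diff": diff, "t": t, "df": df_err, "p": p})
    return pd.DataFrame(rows, columns=["A", "B", "mean_diff", "t", "df", "p"])


def one_way_anova(values: Sequence[float], groups: Sequence[str], effect: str = "group") -> pd.DataFrame:
    df = pd.DataFrame({"y": np.asarray(values, dtype=float), "g": np.asarray(groups)})
    aov = pg.anova(data=df, dv="y", between="g", detailed=True)
    row = aov.loc[aov["Source"] == "g"].iloc[0]
    resid = aov.loc[aov["Source"] == "Within"].iloc[0]
    return pd.DataFrame(
        [
            {
                "effect": effect,
                "F": float(row["F"]),
                "df1": int(row["DF"]),
                "df2": int(resid["DF"]),
                "p": float(_p_column(aov).loc[row.name]),
                "np2": float(row["np2"]),
            }
        ],
        columns=ANOVA_COLUMNS,
    )


def simple_effects_by_isi(profiles, order: str) -> dict[float, dict[str, pd.DataFrame]]:
    """Follow-up of the group x ISI interaction: a one-way group ANOVA plus
    LSD pairwise comparisons at each ISI of the given order."""
    wide = _complete_order_table(profiles, order)
    groups = wide.index.get_level_values("group")
    if groups.nunique() < 2:
        raise ValueError("simple effects need at least 2 groups")
    out: dict[float, dict[str, pd.DataFrame]] = {}
    for isi in wide.columns:
        y = wide[isi].to_numpy()
        out[float(isi)] = {
            "anova": one_way_anova(y, groups, effect=f"group @ ISI {isi:g}"),
            "lsd": lsd_pairwise(y, groups),
        }
    return out


def window_anova(windows: pd.DataFrame, measure: str) -> dict[str, pd.DataFrame]:
    """One-way group ANOVA + LSD on a window measure (tbw, av_tbw, va_tbw, pss).

    Only participants with status 'ok' and a non-missing measure enter.
    """
    ok = windows[(windows["status"] == "ok") & windows[measure].notna()]
    if ok.empty:
        raise ValueError(f"no usable values for measure {measure!r}")
    return {
        "anova": one_way_anova(ok[measure], ok["group"], effect=f"group ({measure})"),
        "lsd": lsd_pairwise(ok[measure], ok["group"]),
    }


def within_va_av_contrast(windows: pd.DataFrame, group: str) -> pd.DataFrame:
    """Paired (repeated-measures) F-test of va_tbw vs av_tbw within one group."""
    sub = windows[
        (windows["group"] == group)
        & (windows["status"] == "ok")
        & windows["va_tbw"].notna()
        & windows["av_tbw"].notna()
    ]
    if len(sub) < 2:
        raise ValueError("paired contrast needs at least 2 participants")
    long = pd.melt(
        sub,
        id_vars=["participant_id"],
        value_vars=["va_tbw", "av_tbw"],
        var_name="side",
        value_name="half_window",
    )
    aov = pg.rm_anova(
        data=long, dv="half_window", within="side", subject="participant_id", detailed=True
    )
    row = aov.loc[aov["Source"] == "side"].iloc[0]
    err = aov.loc[aov["Source"] == "Error"].iloc[0]
    np2 = float(row["SS"] / (row["SS"] + err["SS"]))
    return pd.DataFrame(
        [
            {
                "effect": f"va_tbw vs av_tbw ({group})",
                "F": float(row["F"]),
                "df1": int(row["DF"]),
                "df2": len(sub) - 1,
                "p": float(_p_column(aov).loc[row.name]),
                "np2": np2,
            }
        ],
        columns=ANOVA_COLUMNS,
    )


@dataclass
class AncovaResult:
    table: pd.DataFrame  # group effect row, ANOVA_COLUMNS
    adjusted_means: pd.DataFrame  # group, adjusted_mean
    covariate_coef: float
    lsd: pd.DataFrame  # LSD on covariate-adjusted means
    slope_homogeneity_p: float  # diagnostic: group x covariate interaction


def ancova(data: pd.DataFrame, dv: str, covar: str, between: str = "group") -> AncovaResult:
    """One-way ANCOVA with a single covariate and homogeneous-slope assumption.

    The group F-test comes from the classical ANCOVA decomposition
    (df = g-1, N-g-1); adjusted means are model predictions at the grand
    covariate mean; the LSD table holds unadjusted pairwise t-tests on
    adjusted mean differences using the ANCOVA error term. A group x
    covariate interaction p-value is returned as a slope-homogeneity
    diagnostic.
    """
    df = data[[dv, covar, between]].dropna().reset_index(drop=True)
    if df[covar].nunique() <= 1:
        raise ValueError("degenerate ANCOVA: covariate is constant")
    aov = pg.ancova(data=df, dv=dv, covar=covar, between=between)
    row = aov.loc[aov["Source"] == between].iloc[0]
    resid_df = int(aov.loc[aov["Source"] == "Residual", "DF"].iloc[0])
    table = pd.DataFrame(
        [
            {
                "effect": between,
                "F": float(row["F"]),
                "df1": int(row["DF"]),
                "df2": resid_df,
                "p": float(_p_column(aov).loc[row.name]),
                "np2": float(row["np2"]),
            }
        ],
        columns=ANOVA_COLUMNS,
    )

    labels = sorted(df[between].unique())
    X = pd.DataFrame({"const": 1.0, "cov": df[covar] - df[covar].mean()})
    for lbl in labels[1:]:
        X[f"g_{lbl}"] = (df[between] == lbl).astype(float)
    fit = sm.OLS(df[dv], X).fit()
    base = fit.params["const"]
    adj = {labels[0]: base}
    for lbl in labels[1:]:
        adj[lbl] = base + fit.params[f"g_{lbl}"]
    adjusted = pd.DataFrame(
        {"group": labels, "adjusted_mean": [adj[lbl] for lbl in labels]}
    )

    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            contrast = np.zeros(len(fit.params))
            names = list(fit.params.index)
            if a != labels[0]:
                contrast[names.index(f"g_{a}")] = 1.0
            if b != labels[0]:
                contrast[names.index(f"g_{b}")] = -1.0
            tt = fit.t_test(contrast)
            rows.append(
                {
                    "A": a,
                    "B": b,
                    "mean_diff": float(np.atleast_1d(tt.effect)[0]),
                    "t": float(np.atleast_1d(tt.tvalue).ravel()[0]),
                    "df": resid_df,
                    "p": float(np.atleast_1d(tt.pvalue).ravel()[0]),
                }
            )
    lsd = pd.DataFrame(rows, columns=["A", "B", "mean_diff", "t", "df", "p"])

    Xi = X.copy()
    for lbl in labels[1:]:
        Xi[f"cov_x_{lbl}"] = Xi["cov"] * Xi[f"g_{lbl}"]
    inter = sm.OLS(df[dv], Xi).fit()
    ftest = inter.compare_f_test(fit)
    return AncovaResult(
        table=table,
        adjusted_means=adjusted,
        covariate_coef=float(fit.params["cov"]),
        lsd=lsd,
        slope_homogeneity_p=float(ftest[1]),
    )


def toj_ancova_table(
    order_errors: Iterable, profiles, order: str, covariate: str = "order_specific"
) -> pd.DataFrame:
    """Assemble the ANCOVA input: TOJ error % per participant with the SJ
    synchrony % covariate (order-specific by default, or 'overall')."""
    err_rows = []
    for p in order_errors:
        err_rows.append(
            {
                "participant_id": p.participant_id,
                "group": p.group,
                "toj_error_pct": 100.0 * p.errors.get(order, np.nan),
            }
        )
    err = pd.DataFrame(err_rows)
    prof = _as_profile_frame(profiles)
    if covariate == "order_specific":
        prof = prof[prof["order"] == order]
    sj = (
        prof.groupby("participant_id", as_index=False)["proportion"]
        .mean()
        .rename(columns={"proportion": "sj_sync_pct"})
    )
    sj["sj_sync_pct"] *= 100.0
    return err.merge(sj, on="participant_id", how="inner")


def ancova_toj_errors(
    order_errors: Iterable, profiles, order: str, covariate: str = "order_specific"
) -> AncovaResult:
    """ANCOVA of TOJ error % on group, controlling for SJ synchrony %."""
    data = toj_ancova_table(order_errors, profiles, order, covariate)
    return ancova(data, dv="toj_error_pct", covar="sj_sync_pct", between="group")


@dataclass
class RegressionBlock:
    predictors: list[str]
    coefficients: pd.DataFrame  # predictor, beta, t
    r2: float
    delta_r2: float
    p_change: float


@dataclass
class HierarchicalRegressionResult:
    blocks: list[RegressionBlock] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, blk in enumerate(self.blocks, start=1):
            for i, row in blk.coefficients.iterrows():
                rows.append(
                    {
                        "block": k,
                        "predictor": row["predictor"],
                        "beta": row["beta"],
                        "t": row["t"],
                        "r2": blk.r2 if i == blk.coefficients.index[-1] else np.nan,
                        "delta_r2": blk.delta_r2 if i == blk.coefficients.index[-1] else np.nan,
                        "p_change": blk.p_change if i == blk.coefficients.index[-1] else np.nan,
                    }
                )
        return pd.DataFrame(rows)


DEFAULT_BLOCKS = (
    ("gender", "age_years", "raven"),
    ("phonological_awareness", "rapid_naming"),
)


def hierarchical_regression(
    scores: pd.DataFrame,
    window_measure: str,
    dv: str = "reading_fluency",
    blocks: Sequence[Sequence[str]] | None = None,
) -> HierarchicalRegressionResult:
    """Three-block hierarchical regression on children (CD + TD), complete cases.

    Block 1: gender, age, nonverbal IQ (Raven); block 2 adds phonological
    awareness and rapid naming; block 3 adds the window measure. All
    variables (gender coded 0/1 first) are z-scored, so coefficients are
    standardized betas; each block reports cumulative R^2, the R^2 increment
    and the F-change p-value.
    """
    if blocks is None:
        blocks = [list(b) for b in DEFAULT_BLOCKS] + [[window_measure]]
    df = scores[scores["group"].isin(["CD", "TD"])].copy()
    if "gender" in df and df["gender"].dtype == object:
        df["gender"] = (df["gender"] == "M").astype(float)
    cols = [c for blk in blocks for c in blk] + [dv]
    df = df[cols].dropna().reset_index(drop=True)
    n = len(df)
    z = (df - df.mean()) / df.std(ddof=1)

    result = HierarchicalRegressionResult()
    entered: list[str] = []
    prev_r2 = 0.0
    for blk in blocks:
        entered = entered + list(blk)
        X = z[entered].to_numpy()
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(f"rank-deficient (collinear) predictor block: {list(blk)}")
        fit = sm.OLS(z[dv], sm.add_constant(z[entered])).fit()
        r2 = float(fit.rsquared)
        m = len(blk)
        df_den = n - len(entered) - 1
        delta = r2 - prev_r2
        if 1.0 - r2 <= 0:
            p_change = 0.0 if delta > 0 else 1.0
        else:
            f_change = (delta / m) / ((1.0 - r2) / df_den)
            p_change = float(sps.f.sf(f_change, m, df_den))
        coef = pd.DataFrame(
            {
                "predictor": list(blk),
                "beta": [float(fit.params[c]) for c in blk],
                "t": [float(fit.tvalues[c]) for c in blk],
            }
        )
        result.blocks.append(
            RegressionBlock(
                predictors=list(blk),
                coefficients=coef,
                r2=r2,
                delta_r2=delta,
                p_change=p_change,
            )
        )
        prev_r2 = r2
    return result


def demographic_tests(scores: pd.DataFrame) -> pd.DataFrame:
    """Child-group matching tests: independent t for continuous measures
    (df = n1 + n2 - 2), Pearson chi-square (no continuity correction) for
    gender and grade."""
    kids = scores[scores["group"].isin(["CD", "TD"])]
    if kids["group"].nunique() < 2:
        raise ValueError("demographic tests need both child groups")
    rows = []
    for var in ("gender", "grade"):
        tab = pd.crosstab(kids["group"], kids[var])
        chi2, p, dof, _ = sps.chi2_contingency(tab, correction=False)
        rows.append({"variable": var, "test": "chi2", "stat": chi2, "df": dof, "p": p})
    continuous = (
        "age_years",
        "raven",
        "character_recognition",
        "reading_fluency",
        "phonological_awareness",
        "orthographic_knowledge",
        "rapid_naming",
    )
    a = kids[kids["group"] == "CD"]
    b = kids[kids["group"] == "TD"]
    for var in continuous:
        x, y = a[var].dropna(), b[var].dropna()
        t, p = sps.ttest_ind(x, y, equal_var=True)
        rows.append(
            {"variable": var, "test": "t", "stat": float(t), "df": len(x) + len(y) - 2, "p": float(p)}
        )
    return pd.DataFrame(rows, columns=["variable", "test", "stat", "df", "p"])
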