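"""Derivation of analysis phenotypes from longitudinal clinical records.

Implements the clinical definitions used throughout the pipeline: Friedewald
LDL, per-sample mean lipids over repeated draws, baseline statin exclusion
for lipid analyses, the three-criterion type-2-diabetes adjudication rule,
BMI, and the baseline descriptive table (per-stratum counts/percentages,
Welch t-tests for continuous variables, chi-squared for categorical ones).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

#: Friedewald equation validity bound (mg/dL of triglycerides).
FRIEDEWALD_TG_MAX = 400.0


@dataclass
class BaselineStat:
    """One row of a baseline comparison table."""

    variable: str
    groups: tuple
    n: tuple
    mean: tuple  # mean for continuous, count for categorical
    sd: tuple  # SD for continuous, percent for categorical
    test: str  # "welch_t" | "chi2" | "proportion"
    statistic: float
    p_value: float


def friedewald_ldl(tc: float, hdl: float, tg: float) -> float:
    """LDL = TC - HDL - TG/5 (mg/dL); NaN when TG exceeds the validity bound."""
    if tc < 0 or hdl < 0 or tg < 0:
        raise ValueError("lipid inputs must be non-negative")
    if tg > FRIEDEWALD_TG_MAX:
        return float("nan")
    return tc - hdl - tg / 5.0


def resolve_ldl(record: pd.Series) -> float:
    """Per-draw LDL: directly measured value preferred, Friedewald otherwise."""
    direct = record.get("ldl_direct", np.nan)
    if pd.notna(direct):
        return float(direct)
    parts = [record.get(k, np.nan) for k in
             ("total_cholesterol", "hdl", "triglycerides")]
    if any(pd.isna(x) for x in parts):
        return float("nan")
    return friedewald_ldl(*map(float, parts))


def mean_lipids(labs: pd.DataFrame) -> pd.DataFrame:
    """Per-sample mean HDL / LDL / triglycerides over all available draws.

    ``labs`` has one row per draw with columns ``sample_id``,
    ``total_cholesterol``, ``hdl``, ``triglycerides`` and optional
    ``ldl_direct``. Draws whose LDL cannot be resolved contribute to the
    other lipids but not to LDL. Samples with no usable draws get NaN.
    """
    work = labs.copy()
    work["ldl"] = labs.apply(resolve_ldl, axis=1)
    out = work.groupby("sample_id").agg(
        hdl=("hdl", "mean"),
        ldl=("ldl", "mean"),
        tg=("triglycerides", "mean"),
        n_draws=("sample_id", "size"),
    )
    return out.reset_index()


def statin_exclusion(
    cohort: pd.DataFrame, meds: pd.DataFrame, baseline_only: bool = True
) -> pd.DataFrame:
    """Drop samples on lipid-lowering medication from the lipid cohort.

    "Baseline" is the earliest medication record day per sample; with
    ``baseline_only`` the exclusion applies only to flags recorded at that
    earliest day. The returned table is for lipid analyses only — disease
    analyses keep the full cohort.
    """
    if len(meds) == 0:
        return cohort.copy()
    lip = meds[meds["med_class"] == "lipid_lowering"]
    if baseline_only and "day" in meds.columns and len(lip):
        first_day = meds.groupby("sample_id")["day"].min()
        lip = lip[lip["day"].to_numpy() ==
                  first_day.reindex(lip["sample_id"]).to_numpy()]
    flagged = set(lip["sample_id"])
    kept = cohort[~cohort["sample_id"].isin(flagged)].copy()
    if len(kept) == 0:
        log.warning("statin exclusion removed every sample from the lipid cohort")
    return kept


def t2d_adjudicate(
    hba1c: pd.DataFrame,
    meds: pd.DataFrame,
    diagnoses: pd.DataFrame,
) -> pd.Series:
    """Adjudicated T2D status per sample.

    Positive iff any of: (1) HbA1c >= 6.5 at any draw; (2) any
    diabetes-specific medication (e.g. insulin); (3) a diabetes-related
    medication (e.g. a biguanide) together with a diabetes diagnosis flag.
    Absent data sources count as negative evidence.
    """
    pos: set = set()
    if len(hba1c):
        pos |= set(hba1c.loc[hba1c["hba1c"] >= 6.5, "sample_id"])
    related: set = set()
    if len(meds):
        pos |= set(meds.loc[meds["med_class"] == "diabetes_specific", "sample_id"])
        related = set(meds.loc[meds["med_class"] == "diabetes_related", "sample_id"])
    if len(diagnoses):
        dx = set(diagnoses.loc[diagnoses["t2d_dx"].astype(bool), "sample_id"])
        pos |= related & dx
    ids = sorted(
        set(hba1c.get("sample_id", pd.Series(dtype=object)))
        | set(meds.get("sample_id", pd.Series(dtype=object)))
        | set(diagnoses.get("sample_id", pd.Series(dtype=object)))
    )
    return pd.Series([s in pos for s in ids], index=pd.Index(ids, name="sample_id"),
                     name="t2d")


def bmi(height_m: float, weight_kg: float) -> float:
    """Body-mass index, kg/m^2."""
    if height_m <= 0:
        raise ValueError("height must be positive")
    return weight_kg / (height_m * height_m)


def welch_t_from_summary(
    n1: int, mean1: float, sd1: float, n2: int, mean2: float, sd2: float,
    variable: str = "", groups: tuple = ("group1", "group2"),
) -> BaselineStat:
    """Two-sided unequal-variance t-test from group summaries
    (Welch-Satterthwaite degrees of freedom)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    v1, v2 = sd1 * sd1 / n1, sd2 * sd2 / n2
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1 * v1 / (n1 - 1) + v2 * v2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return BaselineStat(variable, groups, (n1, n2), (mean1, mean2), (sd1, sd2),
                        "welch_t", float(t), float(p))


def baseline_table(
    cohort: pd.DataFrame,
    continuous: tuple = ("age",),
    categorical: tuple = ("sex", "site", "art"),
    binary_events: tuple = (),
    by: str = "stratum",
) -> pd.DataFrame:
    """Baseline characteristics by stratum, in the style of a cohort Table 1.

    Continuous variables get per-group mean (SD) and a Welch t-test (two
    groups); categorical variables get counts with percentages of the group
    size (one decimal) and a chi-squared test; ``binary_events`` (0/1
    columns) are summarised as count (percent) with a chi-squared test.
    Empty strata are omitted with a warning.
    """
    groups = [g for g, sub in cohort.groupby(by) if len(sub) > 0]
    if len(groups) < len(cohort[by].unique()):
        log.warning("empty strata omitted from the baseline table")
    subs = {g: cohort[cohort[by] == g] for g in groups}
    rows = []
    for var in continuous:
        stats_g = {g: (len(subs[g]), subs[g][var].mean(), subs[g][var].std(ddof=1))
                   for g in groups}
        if len(groups) == 2:
            g1, g2 = groups
            bs = welch_t_from_summary(*stats_g[g1], *stats_g[g2],
                                      variable=var, groups=(g1, g2))
            p, statistic = bs.p_value, bs.statistic
        else:
            p = statistic = np.nan
        for g in groups:
            n, m, s = stats_g[g]
            rows.append({"variable": var, "level": "", "group": g, "n": n,
                         "value": f"{m:.2f} ± {s:.2f}", "test": "welch_t",
                         "statistic": statistic, "p_value": p})
    for var in tuple(categorical) + tuple(binary_events):
        is_event = var in binary_events
        table = pd.crosstab(cohort[var], cohort[by]).reindex(columns=groups)
        if is_event:
            # report the positive row only, test on the full 2xk table
            table_full = table
            levels = [lv for lv in table.index if lv in (1, True)]
        else:
            table_full = table
            levels = list(table.index)
        if table_full.shape[0] > 1:
            chi2, p, _, _ = stats.chi2_contingency(table_full.to_numpy())
        else:
            chi2, p = np.nan, np.nan
        for lv in levels:
            for g in groups:
                count = int(table.loc[lv, g])
                pct = round(100.0 * count / len(subs[g]), 1)
                rows.append({"variable": var, "level": str(lv), "group": g,
                             "n": len(subs[g]), "value": f"{count} ({pct})",
                             "test": "chi2", "statistic": chi2, "p_value": p})
    return pd.DataFrame(rows)
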