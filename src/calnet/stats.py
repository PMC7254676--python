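"""Group-level statistics for culture observables.

Outliers are excluded per group with the Tukey quartile criterion
(1.5 x IQR fences, linear-interpolation quantiles).  Genotype contrasts in
basal conditions use unpaired two-sample Student's t tests; treatment
designs (basal vs. treated within culture, WT vs. HD between cultures) use
classical two-way mixed-design (split-plot) ANOVA with Bonferroni-corrected
pairwise post hoc comparisons.  p < 0.05 is the significance convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "remove_outliers_quartile",
    "compare_groups_ttest",
    "mixed_anova_posthoc",
    "group_summary",
]


@dataclass
class ComparisonResult:
    test: str
    statistic: float
    df: tuple
    p_value: float
    group_stats: dict = field(default_factory=dict)
    posthoc: pd.DataFrame | None = None
    anova_table: pd.DataFrame | None = None
    excluded: list = field(default_factory=list)


def remove_outliers_quartile(
    values: np.ndarray, multiplier: float = 1.5
) -> tuple[np.ndarray, np.ndarray]:
    """Tukey-fence outlier exclusion within one group.

    Returns ``(kept, excluded)``.  Groups with fewer than 4 values are
    returned unchanged (no reliable quartiles).
    """
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size < 4:
        return values, np.empty(0)
    q1, q3 = np.quantile(values, [0.25, 0.75])
    iqr = q3 - q1
    lo, hi = q1 - multiplier * iqr, q3 + multiplier * iqr
    keep = (values >= lo) & (values <= hi)
    return values[keep], values[~keep]


def _describe(x: np.ndarray) -> dict:
    x = np.asarray(x, dtype=float)
    n = x.size
    sd = float(np.std(x, ddof=1)) if n > 1 else math.nan
    return {
        "n": n,
        "mean": float(np.mean(x)) if n else math.nan,
        "sd": sd,
        "sem": sd / math.sqrt(n) if n > 1 else math.nan,
    }


def compare_groups_ttest(
    a: np.ndarray,
    b: np.ndarray,
    exclude_outliers: bool = True,
    multiplier: float = 1.5,
) -> ComparisonResult:
    """Unpaired two-sample Student's t test (equal variances assumed)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    excluded: list = []
    if exclude_outliers:
        a, ex_a = remove_outliers_quartile(a, multiplier)
        b, ex_b = remove_outliers_quartile(b, multiplier)
        excluded = list(ex_a) + list(ex_b)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 samples per group")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    if not math.isfinite(t):  # zero pooled variance
        t, p = 0.0, 1.0
    return ComparisonResult(
        test="student_t_unpaired",
        statistic=float(t),
        df=(a.size + b.size - 2,),
        p_value=float(p),
        group_stats={"a": _describe(a), "b": _describe(b)},
        excluded=excluded,
    )


def mixed_anova_posthoc(
    table: pd.DataFrame,
    dv: str,
    between: str = "genotype",
    within: str = "phase",
    subject: str = "culture",
) -> ComparisonResult:
    """Two-way mixed-design ANOVA with Bonferroni post hoc tests.

    ``table`` is long-format with one row per culture per phase.  Cultures
    missing a phase are excluded listwise.  The post hoc table contains the
    within-factor contrast inside each between group and the between-factor
    contrast inside each phase, each Bonferroni-corrected within its family.
    """
    import pingouin as pg

    df = table[[subject, between, within, dv]].dropna().copy()
    counts = df.groupby(subject)[within].nunique()
    n_phases = df[within].nunique()
    complete = counts[counts == n_phases].index
    dropped = sorted(set(df[subject]) - set(complete))
    df = df[df[subject].isin(complete)]
    if df.empty or df[between].nunique() < 2 or df[within].nunique() < 2:
        raise ValueError("mixed ANOVA needs >= 2 levels of both factors")

    aov = pg.mixed_anova(
        data=df, dv=dv, within=within, subject=subject, between=between
    )
    inter = aov.loc[aov["Source"] == "Interaction"].iloc[0]

    posthoc = pg.pairwise_tests(
        data=df, dv=dv, within=within, between=between, subject=subject,
        padjust="bonf", interaction=True,
    )
    return ComparisonResult(
        test="mixed_anova",
        statistic=float(inter["F"]),
        df=(float(inter["DF1"]), float(inter["DF2"])),
        p_value=float(inter["p_unc"]),
        anova_table=aov,
        posthoc=posthoc,
        excluded=dropped,
        group_stats={
            name: _describe(g[dv].to_numpy())
            for name, g in df.groupby([between, within])
        },
    )


def group_summary(
    table: pd.DataFrame, observables: list[str], by: list[str]
) -> pd.DataFrame:
    """Mean / SEM / SD per group for each observable (one row per group)."""
    rows = []
    for keys, g in table.groupby(by):
        row = dict(zip(by, keys if isinstance(keys, tuple) else (keys,)))
        for obs in observables:
            d = _describe(g[obs].dropna().to_numpy())
            row[f"{obs}_mean"] = d["mean"]
            row[f"{obs}_sem"] = d["sem"]
            row[f"{obs}_sd"] = d["sd"]
            row[f"{obs}_n"] = d["n"]
        rows.append(row)
    return pd.DataFrame(rows)
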