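"""The statistical battery applied to profiles and indices.

Covers the comparisons used in cross-species rest-activity studies:
one-way ANOVA across species, a mixed (split-plot) two-way ANOVA with
time-of-day as the within-subject factor and species as the
between-subject factor, Šidák-corrected per-species day-vs-night post hoc
contrasts, paired day/night t tests, and ordinary least-squares
correlation of species means across life stages. All tests are two-sided
at alpha = 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatResult",
    "species_anova",
    "day_night_rm_anova",
    "paired_day_night_test",
    "stage_correlation",
    "sidak_adjust",
    "results_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StatResult:
    """One test (or one term of a factorial test) in tidy form."""

    test_name: str
    term: str
    statistic: float  # F, t, or r^2 depending on the test
    df: tuple  # (df1, df2) for F; (df,) for t and r
    p: float
    adjusted_p: Optional[float] = None  # post hoc only
    extra: Optional[dict] = None  # e.g. slope for regressions

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p must lie in [0, 1]")
        if self.adjusted_p is not None and self.adjusted_p < self.p - 1e-12:
            raise ValueError("adjusted_p cannot be smaller than p")


def sidak_adjust(p: float, m: int) -> float:
    """Šidák multiple-comparison correction: 1 - (1 - p)^m for m contrasts."""
    if m < 1:
        raise ValueError("family size m must be >= 1")
    return float(1.0 - (1.0 - p) ** m)


def species_anova(values: Sequence[float], labels: Sequence) -> StatResult:
    """One-way fixed-effects ANOVA of a per-subject scalar across species."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = [values[labels == g] for g in pd.unique(labels)]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 species")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every species needs at least 2 subjects")
    n = len(values)
    f, p = sps.f_oneway(*groups)
    return StatResult(
        test_name="one-way ANOVA", term="species",
        statistic=float(f), df=(k - 1, n - k), p=float(p),
    )


def day_night_rm_anova(
    day_vals: Sequence[float],
    night_vals: Sequence[float],
    labels: Sequence,
) -> list[StatResult]:
    """Mixed two-way ANOVA: time of day (within) x species (between).

    Subjects are nested in species; with a two-level within factor
    sphericity holds trivially. Returns the two main effects and the
    interaction, followed by Šidák-adjusted per-species paired day-vs-
    night contrasts (family size = number of species).

    Subjects with a missing day or night value are dropped with a logged
    count before fitting.
    """
    import pingouin as pg

    day_vals = np.asarray(day_vals, dtype=float)
    night_vals = np.asarray(night_vals, dtype=float)
    labels = np.asarray(labels)
    if not (len(day_vals) == len(night_vals) == len(labels)):
        raise ValueError("day, night and label vectors must have equal length")
    complete = np.isfinite(day_vals) & np.isfinite(night_vals)
    if not complete.all():
        logger.warning("dropping %d subject(s) with incomplete day/night pairs",
                       int((~complete).sum()))
    day_vals, night_vals, labels = day_vals[complete], night_vals[complete], labels[complete]
    n = len(day_vals)
    subjects = np.arange(n)
    long = pd.DataFrame(
        {
            "value": np.concatenate([day_vals, night_vals]),
            "phase": ["day"] * n + ["night"] * n,
            "species": np.concatenate([labels, labels]),
            "subject": np.concatenate([subjects, subjects]),
        }
    )
    aov = pg.mixed_anova(
        data=long, dv="value", within="phase", subject="subject", between="species"
    )
    term_map = {"species": "species", "phase": "time", "Interaction": "species x time"}
    p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
    results = []
    for _, row in aov.iterrows():
        results.append(
            StatResult(
                test_name="mixed two-way RM ANOVA",
                term=term_map.get(row["Source"], str(row["Source"])),
                statistic=float(row["F"]),
                df=(int(row["DF1"]), int(row["DF2"])),
                p=float(row[p_col]),
            )
        )
    # per-species paired day-vs-night contrasts, Šidák-corrected
    species = list(pd.unique(labels))
    m = len(species)
    for sp in species:
        sel = labels == sp
        res = paired_day_night_test(day_vals[sel], night_vals[sel])
        results.append(
            StatResult(
                test_name="paired t (post hoc)",
                term=f"day vs night: {sp}",
                statistic=res.statistic,
                df=res.df,
                p=res.p,
                adjusted_p=sidak_adjust(res.p, m),
            )
        )
    return results


def paired_day_night_test(
    day_vals: Sequence[float], night_vals: Sequence[float]
) -> StatResult:
    """Two-sided paired t test of day vs night values, df = n - 1.

    Identical day and night vectors give t = 0, p = 1; non-zero constant
    differences have no within-pair variance and raise instead of
    reporting an infinite statistic.
    """
    day_vals = np.asarray(day_vals, dtype=float)
    night_vals = np.asarray(night_vals, dtype=float)
    if len(day_vals) != len(night_vals):
        raise ValueError("day and night vectors must be paired")
    n = len(day_vals)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    diff = day_vals - night_vals
    if np.std(diff, ddof=1) == 0:
        if np.all(diff == 0):
            return StatResult(
                test_name="paired t", term="day vs night",
                statistic=0.0, df=(n - 1,), p=1.0,
            )
        raise ValueError("differences have zero variance; t is undefined")
    t, p = sps.ttest_rel(day_vals, night_vals)
    return StatResult(
        test_name="paired t", term="day vs night",
        statistic=float(t), df=(n - 1,), p=float(p),
    )


def stage_correlation(
    juvenile_means: Sequence[float], adult_means: Sequence[float]
) -> StatResult:
    """OLS regression of adult on juvenile per-species means.

    Reports r^2 as the statistic, the slope (in ``extra``), and the
    two-sided p for slope != 0, df = n - 2.
    """
    x = np.asarray(juvenile_means, dtype=float)
    y = np.asarray(adult_means, dtype=float)
    if len(x) != len(y):
        raise ValueError("species mean vectors must be paired")
    if len(x) < 3:
        raise ValueError("need at least 3 species")
    if np.std(x) == 0:
        raise ValueError("juvenile means have zero variance; slope is undefined")
    fit = sps.linregress(x, y)
    return StatResult(
        test_name="OLS stage correlation", term="juvenile vs adult",
        statistic=float(fit.rvalue**2), df=(len(x) - 2,), p=float(fit.pvalue),
        extra={"slope": float(fit.slope), "intercept": float(fit.intercept),
               "r": float(fit.rvalue)},
    )


def results_table(results: Sequence[StatResult]) -> pd.DataFrame:
    """Tidy export: one row per term (term, statistic, df, p, adjusted_p)."""
    rows = [
        (
            r.test_name, r.term, r.statistic,
            "x".join(str(d) for d in r.df), r.p,
            np.nan if r.adjusted_p is None else r.adjusted_p,
        )
        for r in results
    ]
    return pd.DataFrame(
        rows, columns=["test", "term", "statistic", "df", "p", "adjusted_p"]
    )
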