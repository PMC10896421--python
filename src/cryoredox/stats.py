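"""Cohort statistics: genotype x sex ANOVA, sex pooling, t-tests, percent change.

The decision procedure applied per tissue (and per serum analyte):

1. fixed-effects 2x2 factorial ANOVA of the per-animal response on
   genotype, sex and their interaction, with Type II sums of squares
   (each main effect adjusted for the other — appropriate for the
   unbalanced kidney design);
2. if neither the sex effect nor the interaction is significant at
   alpha, the sexes are pooled and a two-sample Student's t-test
   (pooled variance) compares WT vs KO; otherwise pooling is refused
   and per-sex comparisons are reported instead;
3. the genotype effect size is reported as a percent change
   100*(mean_WT - mean_KO)/mean_KO.  This KO-denominator convention is
   the arithmetic consistent with the reference group means this
   pipeline is benchmarked against; the WT-denominator variant is
   available via ``baseline='wt'``.

The ANOVA is computed directly via nested least-squares model
comparisons (it is called tens of thousands of times in calibration
simulations); unit tests cross-check it against statsmodels'
``anova_lm(typ=2)`` on both balanced and unbalanced designs.
No multiple-testing correction is applied across tissues or analytes;
output metadata records this.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "TTestResult",
    "CohortResult",
    "StatsError",
    "two_way_anova",
    "pool_and_test",
    "percent_change",
    "compare_serum",
]

ALPHA_DEFAULT = 0.05


class StatsError(ValueError):
    """Raised for degenerate designs or invalid statistical requests."""


@dataclass
class EffectTest:
    F: float
    df: tuple[int, int]
    p: float


@dataclass
class AnovaResult:
    """Type II two-way factorial ANOVA: one F test per effect."""

    genotype: EffectTest
    sex: EffectTest
    interaction: EffectTest
    alpha: float = ALPHA_DEFAULT
    ss_type: int = 2

    @property
    def pooling_allowed(self) -> bool:
        """Sexes may be pooled iff neither sex nor interaction is significant."""
        return self.sex.p >= self.alpha and self.interaction.p >= self.alpha


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    sidedness: str                     # 'one' or 'two'
    direction: str | None              # for one-sided: 'wt_greater' or 'ko_greater'
    mean_wt: float
    mean_ko: float
    sem_wt: float
    sem_ko: float
    n_wt: int
    n_ko: int


@dataclass
class CohortResult:
    """Full decision-procedure outcome for one tissue or analyte."""

    anova: AnovaResult
    pooled: bool
    ttest: TTestResult | None
    percent_change: float | None
    tissue: str = ""
    per_sex: dict[str, TTestResult] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)


def _validate_table(table: pd.DataFrame, response: str) -> pd.DataFrame:
    for col in ("genotype", "sex", response):
        if col not in table.columns:
            raise StatsError(f"table lacks required column {col!r}")
    bad_g = set(table["genotype"]) - {"WT", "KO"}
    if bad_g:
        raise StatsError(f"unknown genotype labels {bad_g}")
    bad_s = set(table["sex"]) - {"M", "F"}
    if bad_s:
        raise StatsError(f"unknown sex labels {bad_s}")
    counts = table.groupby("genotype")[response].count()
    if set(counts.index) != {"WT", "KO"}:
        raise StatsError("both genotypes must be present")
    if (counts < 2).any():
        raise StatsError("each genotype needs at least 2 animals")
    return table


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    """Residual sum of squares of the least-squares fit y ~ X."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def two_way_anova(
    table: pd.DataFrame,
    response: str = "mean_rr",
    alpha: float = ALPHA_DEFAULT,
    ss_type: int = 2,
) -> AnovaResult:
    """Fixed-effects 2x2 genotype x sex ANOVA.

    Type II (default) tests each main effect adjusted for the other main
    effect (no interaction in the conditioning set) and the interaction
    against the additive model; the error term is always the full
    model's residual.  Type I is sequential (genotype, then sex, then
    interaction); Type III adjusts each effect for everything else
    including the interaction.  All three coincide on balanced designs.
    """
    table = _validate_table(table, response)
    if len(table) < 4:
        raise StatsError("need at least 4 animals for a two-way ANOVA")
    for factor in ("genotype", "sex"):
        if table[factor].nunique() < 2:
            raise StatsError(f"factor {factor!r} has a single level")

    y = table[response].to_numpy(dtype=np.float64)
    # sum-to-zero (effect) coding: Type I/II F tests only depend on column
    # spans, and Type III becomes the standard contrast-coded decomposition
    g = np.where(table["genotype"] == "KO", 1.0, -1.0)
    s = np.where(table["sex"] == "F", 1.0, -1.0)
    one = np.ones_like(y)

    X_full = np.column_stack([one, g, s, g * s])
    X_add = X_full[:, :3]
    X_g = np.column_stack([one, g])
    X_s = np.column_stack([one, s])

    n = y.size
    df_err = n - 4
    if df_err < 1:
        raise StatsError("no residual degrees of freedom (need > 4 animals)")
    rss_full = _rss(y, X_full)
    rss_add = _rss(y, X_add)
    mse = rss_full / df_err

    def effect(ss: float, df_num: int) -> EffectTest:
        ss = max(ss, 0.0)
        if mse == 0:
            F = np.inf if ss > 0 else 0.0
            p = 0.0 if ss > 0 else 1.0
        else:
            F = (ss / df_num) / mse
            p = float(sps.f.sf(F, df_num, df_err))
        return EffectTest(F=float(F), df=(df_num, df_err), p=p)

    if ss_type == 2:
        ss_g = _rss(y, X_s) - rss_add
        ss_s = _rss(y, X_g) - rss_add
    elif ss_type == 1:
        rss_0 = _rss(y, one[:, None])
        rss_g = _rss(y, X_g)
        ss_g = rss_0 - rss_g
        ss_s = rss_g - rss_add
    elif ss_type == 3:
        ss_g = _rss(y, np.column_stack([one, s, g * s])) - rss_full
        ss_s = _rss(y, np.column_stack([one, g, g * s])) - rss_full
    else:
        raise StatsError(f"ss_type must be 1, 2 or 3, got {ss_type}")

    return AnovaResult(
        genotype=effect(ss_g, 1),
        sex=effect(ss_s, 1),
        interaction=effect(rss_add - rss_full, 1),
        alpha=alpha,
        ss_type=ss_type,
    )


def _ttest(
    wt: np.ndarray,
    ko: np.ndarray,
    sidedness: str,
    direction: str | None,
    t_variant: str = "student",
) -> TTestResult:
    if len(wt) < 2 or len(ko) < 2:
        raise StatsError("each group needs at least 2 animals for a t-test")
    if sidedness == "two":
        alternative = "two-sided"
    elif sidedness == "one":
        if direction not in ("wt_greater", "ko_greater"):
            raise StatsError("one-sided test requires direction "
                             "'wt_greater' or 'ko_greater'")
        alternative = "greater" if direction == "wt_greater" else "less"
    else:
        raise StatsError("sidedness must be 'one' or 'two'")
    if t_variant not in ("student", "welch"):
        raise StatsError("t_variant must be 'student' (pooled variance) or 'welch'")
    res = sps.ttest_ind(wt, ko, equal_var=(t_variant == "student"),
                        alternative=alternative)
    return TTestResult(
        t=float(res.statistic), df=float(res.df), p=float(res.pvalue),
        sidedness=sidedness, direction=direction,
        mean_wt=float(np.mean(wt)), mean_ko=float(np.mean(ko)),
        sem_wt=float(sps.sem(wt)), sem_ko=float(sps.sem(ko)),
        n_wt=len(wt), n_ko=len(ko),
    )


def percent_change(mean_wt: float, mean_ko: float, baseline: str = "ko") -> float:
    """Percent change of the KO group relative to WT, in percent.

    Default KO-denominator convention: ``100*(mean_wt - mean_ko)/mean_ko``.
    ``baseline='wt'`` gives the conventional ``100*(mean_wt - mean_ko)/mean_wt``.
    """
    denom = mean_ko if baseline == "ko" else mean_wt
    if baseline not in ("ko", "wt"):
        raise StatsError("baseline must be 'ko' or 'wt'")
    if denom == 0:
        raise StatsError("zero denominator in percent change")
    return 100.0 * (mean_wt - mean_ko) / denom


def pool_and_test(
    table: pd.DataFrame,
    anova: AnovaResult,
    response: str = "mean_rr",
    sidedness: str = "two",
    direction: str | None = None,
    tissue: str = "",
    baseline: str = "ko",
    force_pool: bool = False,
    t_variant: str = "student",
) -> CohortResult:
    """Pool sexes when the ANOVA permits it and run the WT-vs-KO t-test.

    If the sex effect or the interaction is significant, pooling is
    refused (no silent override; ``force_pool`` raises rather than
    obliging) and per-sex t-tests are returned instead.
    """
    table = _validate_table(table, response)
    notes = ["alpha=%g; no multiple-testing correction applied" % anova.alpha]

    if not anova.pooling_allowed:
        if force_pool:
            raise StatsError(
                "pooling requested but the ANOVA found a sex effect or "
                f"interaction (sex p={anova.sex.p:.4g}, "
                f"interaction p={anova.interaction.p:.4g})"
            )
        per_sex = {}
        for sex in ("M", "F"):
            sub = table[table["sex"] == sex]
            wt = sub.loc[sub["genotype"] == "WT", response].to_numpy()
            ko = sub.loc[sub["genotype"] == "KO", response].to_numpy()
            if len(wt) >= 2 and len(ko) >= 2:
                per_sex[sex] = _ttest(wt, ko, sidedness, direction, t_variant)
        notes.append("sex effect or interaction significant: sexes not pooled")
        return CohortResult(anova=anova, pooled=False, ttest=None,
                            percent_change=None, tissue=tissue,
                            per_sex=per_sex, notes=notes)

    wt = table.loc[table["genotype"] == "WT", response].to_numpy(dtype=np.float64)
    ko = table.loc[table["genotype"] == "KO", response].to_numpy(dtype=np.float64)
    tt = _ttest(wt, ko, sidedness, direction, t_variant)
    try:
        pc = percent_change(tt.mean_wt, tt.mean_ko, baseline=baseline)
    except StatsError:
        pc = None
        notes.append("percent change undefined: zero baseline mean")
    return CohortResult(anova=anova, pooled=True, ttest=tt, percent_change=pc,
                        tissue=tissue, notes=notes)


def compare_serum(
    table: pd.DataFrame,
    analyte: str,
    sidedness: str = "two",
    direction: str | None = None,
    alpha: float = ALPHA_DEFAULT,
    baseline: str = "ko",
) -> CohortResult:
    """Apply the ANOVA -> pool -> t-test machinery to one serum analyte.

    Expects the long-format serum table (animal_id, genotype, sex,
    analyte, value); percent change uses the same convention as the
    imaging comparison.
    """
    if "analyte" not in table.columns:
        raise StatsError("serum table lacks an 'analyte' column")
    sub = table[table["analyte"] == analyte]
    if sub.empty:
        raise StatsError(f"analyte {analyte!r} not present")
    sub = sub.rename(columns={"value": "response"})
    anova = two_way_anova(sub, response="response", alpha=alpha)
    return pool_and_test(sub, anova, response="response", sidedness=sidedness,
                         direction=direction, tissue=analyte, baseline=baseline)
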