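"""Cohort-level statistics over ΔFRET tables.

Mirrors a standard preclinical analysis stack: two-way repeated-measures
ANOVA (time x treatment, both within-subject) with a REML mixed-model
fallback when cells are missing, one-way ANOVA with Tukey HSD post hoc
tests for dose comparisons, paired/unpaired t-tests for two-group
contrasts, Pearson correlation for histology covariates, and the
animal-inclusion rules (histology threshold, matched-data subsetting).

Implementations delegate to pingouin, statsmodels and scipy; the test
suite cross-checks them against brute-force sums-of-squares oracles.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

from .errors import DegenerateDataError
from .io import AnimalHistology

__all__ = [
    "TermResult",
    "StatResult",
    "CorrelationResult",
    "exclusion_filter",
    "matched_subset",
    "rm_two_way_anova",
    "one_way_anova_tukey",
    "t_tests",
    "pearson_correlation",
]

ALPHA = 0.05  #: two-sided significance level used throughout


@dataclass(frozen=True)
class TermResult:
    """One model term: test statistic, its degrees of freedom and p-value."""

    statistic: float
    df_num: float
    df_den: float
    p: float
    label: str = "F"


@dataclass
class StatResult:
    """Outcome of one statistical procedure."""

    test: str
    terms: dict[str, TermResult]
    posthoc: pd.DataFrame | None = None
    n: dict = field(default_factory=dict)

    def p(self, term: str) -> float:
        return self.terms[term].p


class CorrelationResult(NamedTuple):
    r: float
    r_squared: float
    p: float


# ---------------------------------------------------------------------------
# inclusion rules
# ---------------------------------------------------------------------------

def exclusion_filter(
    histology: Sequence[AnimalHistology], neuron_threshold: int = 100
) -> tuple[list[AnimalHistology], list[tuple[AnimalHistology, str]]]:
    """Apply the histology inclusion rule.

    Animals with strictly fewer than ``neuron_threshold`` sensor-expressing
    neurons, or with off-target fibre placement, are excluded (a count of
    exactly ``neuron_threshold`` is kept).  Returns (kept, excluded-with-reason).
    """
    kept: list[AnimalHistology] = []
    excluded: list[tuple[AnimalHistology, str]] = []
    for h in histology:
        if h.eyfp_neuron_count < neuron_threshold:
            excluded.append(
                (h, f"{h.eyfp_neuron_count} sensor-expressing neurons < {neuron_threshold}")
            )
        elif not h.fibre_on_target:
            excluded.append((h, "off-target fibre placement"))
        else:
            kept.append(h)
    return kept, excluded


def matched_subset(table: pd.DataFrame, treatments: Sequence[str]) -> pd.DataFrame:
    """Restrict a long-format cohort table to animals with complete data across
    every treatment in ``treatments`` (matched-data inclusion).

    Raises :class:`DegenerateDataError` if no animal is complete; the message
    names which animals miss which treatments.
    """
    treatments = list(treatments)
    sub = table[table["treatment"].isin(treatments)]
    have = sub.groupby("animal_id")["treatment"].agg(lambda s: set(s))
    complete = [a for a, s in have.items() if s >= set(treatments)]
    if not complete:
        gaps = {a: sorted(set(treatments) - s) for a, s in have.items()}
        raise DegenerateDataError(
            "no animal has complete data across the requested treatments; "
            f"missing per animal: {gaps}"
        )
    return sub[sub["animal_id"].isin(complete)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# repeated-measures ANOVA (+ mixed-model fallback)
# ---------------------------------------------------------------------------

def _is_complete(table: pd.DataFrame, subject: str, within: str, factor: str) -> bool:
    counts = table.groupby([subject, within, factor], observed=True).size()
    subjects = table[subject].nunique()
    levels = table[within].nunique() * table[factor].nunique()
    return len(counts) == subjects * levels and (counts == 1).all()


def rm_two_way_anova(
    table: pd.DataFrame,
    dv: str = "delta_fret",
    within: str = "hour",
    treatment: str = "treatment",
    subject: str = "animal_id",
    allow_missing: bool = False,
    gg_correction: bool = False,
) -> StatResult:
    """Two-way repeated-measures ANOVA of ``dv`` on time and treatment.

    Both factors are within-subject (each animal is its own control across
    treatment days).  With complete, balanced data this is the classical
    repeated-measures decomposition (subject x factor interactions as error
    strata).  With missing cells and ``allow_missing=True`` it falls back to
    a REML linear mixed model with a random intercept per animal and Wald
    F-tests with between-within denominator df — the minimal faithful
    analogue of a "mixed-effects two-way ANOVA".

    ``gg_correction`` swaps in Greenhouse-Geisser sphericity-corrected
    p-values (off by default).
    """
    for col, what in ((within, "time"), (treatment, "treatment")):
        if table[col].nunique() < 2:
            raise DegenerateDataError(f"{what} factor {col!r} needs >= 2 levels")
    complete = _is_complete(table, subject, within, treatment)
    if not complete and not allow_missing:
        raise DegenerateDataError(
            "table has missing or duplicated animal x hour x treatment cells; "
            "re-run with allow_missing=True to use the mixed-effects fallback"
        )

    if complete:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant hour-0 cells trip epsilon estimation
            aov = pg.rm_anova(
                data=table, dv=dv, within=[within, treatment], subject=subject,
                detailed=True, effsize="ng2",
            )
        pcol = "p_GG_corr" if gg_correction and "p_GG_corr" in aov.columns else "p_unc"
        name_map = {
            within: "time",
            treatment: "treatment",
            f"{within} * {treatment}": "time x treatment",
        }
        terms = {}
        for _, row in aov.iterrows():
            key = name_map.get(row["Source"], row["Source"])
            f_val, p_val = float(row["F"]), float(row[pcol])
            if not np.isfinite(f_val) and abs(float(row["SS"])) < 1e-12:
                f_val, p_val = 0.0, 1.0  # no effect variance at all (flat dv): F := 0
            terms[key] = TermResult(
                statistic=f_val,
                df_num=float(row["ddof1"]),
                df_den=float(row["ddof2"]),
                p=p_val,
            )
        return StatResult(
            test="two-way repeated-measures ANOVA",
            terms=terms,
            n={"subjects": table[subject].nunique(), "cells": len(table)},
        )
    return _mixed_model_anova(table, dv, within, treatment, subject)


def _mixed_model_anova(
    table: pd.DataFrame, dv: str, within: str, treatment: str, subject: str
) -> StatResult:
    """REML random-intercept mixed model with Wald F-tests per term.

    Denominator df follow a containment/between-within rule:
    n_obs - rank(fixed design) - (n_subjects - 1), floored at 1.
    """
    import statsmodels.formula.api as smf

    data = table[[dv, within, treatment, subject]].dropna().copy()
    data[within] = data[within].astype("category")
    data[treatment] = data[treatment].astype("category")
    # sum-to-zero coding so each main-effect Wald test is the orthogonal
    # (type-III) main effect, matching the classical balanced decomposition
    formula = f"{dv} ~ C({within}, Sum) * C({treatment}, Sum)"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data=data, groups=data[subject])
        fit = model.fit(reml=True)

    exog_names = fit.model.exog_names
    n_obs = len(data)
    n_subj = data[subject].nunique()
    rank = np.linalg.matrix_rank(fit.model.exog)
    df_den = max(1.0, n_obs - rank - (n_subj - 1))

    def wald_for(prefix_time: bool, prefix_treat: bool) -> list[int]:
        idx = []
        for i, name in enumerate(exog_names):
            is_inter = ":" in name
            has_time = f"C({within}," in name
            has_treat = f"C({treatment}," in name
            if prefix_time and prefix_treat:
                if is_inter:
                    idx.append(i)
            elif prefix_time:
                if has_time and not is_inter:
                    idx.append(i)
            elif prefix_treat:
                if has_treat and not is_inter:
                    idx.append(i)
        return idx

    terms: dict[str, TermResult] = {}
    for key, (ptime, ptreat) in (
        ("time", (True, False)),
        ("treatment", (False, True)),
        ("time x treatment", (True, True)),
    ):
        idx = wald_for(ptime, ptreat)
        if not idx:
            continue
        contrast = np.zeros((len(idx), len(fit.params)))
        for row, i in enumerate(idx):
            contrast[row, i] = 1.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            wt = fit.wald_test(contrast, scalar=False)
        chi2 = float(np.squeeze(wt.statistic))
        q = len(idx)
        f_stat = chi2 / q
        p = float(sps.f.sf(f_stat, q, df_den))
        terms[key] = TermResult(statistic=f_stat, df_num=float(q), df_den=df_den, p=p)

    return StatResult(
        test="mixed-effects two-way ANOVA (REML, random intercept per animal)",
        terms=terms,
        n={"subjects": n_subj, "observations": n_obs},
    )


# ---------------------------------------------------------------------------
# one-way ANOVA + Tukey, t-tests, correlation
# ---------------------------------------------------------------------------

def one_way_anova_tukey(groups: Mapping[str, Sequence[float]]) -> StatResult:
    """One-way ANOVA across labelled groups with Tukey HSD post hoc pairs.

    Post hoc adjusted p-values are reported only when there are more than
    two groups (with two, the omnibus test already is the pairwise test).
    """
    labels = list(groups)
    if len(labels) < 2:
        raise DegenerateDataError("one-way ANOVA needs >= 2 groups")
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    for k, arr in zip(labels, arrays):
        if len(arr) < 2:
            raise DegenerateDataError(f"group {k!r} has < 2 values")

    f_stat, p = sps.f_oneway(*arrays)
    k = len(arrays)
    n_tot = sum(len(a) for a in arrays)
    terms = {
        "group": TermResult(float(f_stat), float(k - 1), float(n_tot - k), float(p))
    }

    posthoc = None
    if k > 2:
        hsd = sps.tukey_hsd(*arrays)
        rows = []
        for i, j in itertools.combinations(range(k), 2):
            raw = sps.ttest_ind(arrays[i], arrays[j]).pvalue
            rows.append(
                {
                    "A": labels[i],
                    "B": labels[j],
                    "mean_diff": float(arrays[i].mean() - arrays[j].mean()),
                    "p_adj": float(hsd.pvalue[i, j]),
                    "p_raw": float(raw),
                }
            )
        posthoc = pd.DataFrame(rows)

    return StatResult(
        test="one-way ANOVA with Tukey HSD",
        terms=terms,
        posthoc=posthoc,
        n={k_: len(a) for k_, a in zip(labels, arrays)},
    )


def t_tests(
    x: Sequence[float], y: Sequence[float], paired: bool = False
) -> StatResult:
    """Two-sided paired or unpaired t-test.

    Zero variance in the relevant quantity (the paired differences, or the
    pooled samples) is an error rather than a silent t=0: a flat vector
    almost always means a broken fixture or a degenerate pipeline output.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired and len(x) != len(y):
        raise DegenerateDataError("paired test needs equally long samples")
    if len(x) < 2 or len(y) < 2:
        raise DegenerateDataError("t-test needs n >= 2 per sample")
    if paired:
        d = x - y
        if np.ptp(d) == 0:
            raise DegenerateDataError("paired differences have zero variance; t is undefined")
        res = sps.ttest_rel(x, y)
        df = float(len(x) - 1)
        name = "paired t-test"
    else:
        if np.ptp(x) == 0 and np.ptp(y) == 0:
            raise DegenerateDataError("both samples have zero variance; t is undefined")
        res = sps.ttest_ind(x, y)
        df = float(len(x) + len(y) - 2)
        name = "unpaired t-test"
    term = TermResult(
        statistic=float(res.statistic), df_num=df, df_den=df, p=float(res.pvalue), label="t"
    )
    return StatResult(test=name, terms={"difference": term}, n={"x": len(x), "y": len(y)})


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson's r, r² and two-sided p for paired observations (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise DegenerateDataError("x and y must be equally long")
    if len(x) < 3:
        raise DegenerateDataError("Pearson correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("correlation is undefined for a constant input")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(r=float(r), r_squared=float(r * r), p=float(p))
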