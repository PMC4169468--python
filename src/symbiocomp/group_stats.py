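"""Univariate companions: ANOVA, Dunnett, Tukey and time-course regression.

Relative quantities (symbiont density, viral titer) are compared across
strains by linear models on ln-transformed values (to meet normality and
homoscedasticity), with Dunnett's many-to-one test against the
symbiont-free control and Tukey's honest significant difference for
all-pairs comparisons (summarized as a compact letter display).  Viral
growth time-courses are modelled by polynomial regression in day with
strain interactions, simplified by backward elimination of non-significant
highest-order terms while respecting marginality.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "anova_oneway",
    "dunnett_many_to_one",
    "tukey_hsd",
    "compact_letter_display",
    "polynomial_backward_regression",
]


def _check_samples(samples: dict) -> dict:
    if len(samples) < 2:
        raise ValueError("need >= 2 groups")
    out = {}
    for g, v in samples.items():
        arr = np.asarray(v, dtype=float)
        if arr.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
        if not np.isfinite(arr).all():
            raise ValueError(f"group {g!r} contains non-finite values")
        out[g] = arr
    return out


def anova_oneway(samples: dict) -> tuple[float, int, int, float]:
    """One-way fixed-effects ANOVA: returns (F, df_between, df_within, p).

    Inputs are expected on the ln scale already (quantities are
    ln-transformed upstream); groups with zero pooled within-variance are
    rejected rather than reporting an infinite F.
    """
    samples = _check_samples(samples)
    groups = list(samples.values())
    n = sum(g.size for g in groups)
    k = len(groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ss_within == 0:
        raise ValueError("zero within-group variance; F is undefined")
    F, p = stats.f_oneway(*groups)
    return float(F), k - 1, n - k, float(p)


def dunnett_many_to_one(
    samples: dict, control_label: str, alternative: str = "two-sided",
    seed: int = 0,
) -> pd.DataFrame:
    """Dunnett's many-to-one comparisons against a control group.

    Family-wise adjustment uses the max-|t| distribution of the correlated
    multivariate t across the k comparisons (evaluated by seeded Monte
    Carlo integration); two-sided by default.
    """
    samples = _check_samples(samples)
    if control_label not in samples:
        raise KeyError(f"control group {control_label!r} not found")
    others = [g for g in samples if g != control_label]
    res = stats.dunnett(
        *[samples[g] for g in others],
        control=samples[control_label],
        alternative=alternative,
        rng=np.random.default_rng(seed),
    )
    # unadjusted two-sided t for the monotonicity guarantee p_adj >= p_raw
    ctl = samples[control_label]
    dfw = sum(samples[g].size for g in samples) - len(samples)
    s2 = sum(((samples[g] - samples[g].mean()) ** 2).sum() for g in samples) / dfw
    rows = []
    for g, stat, padj in zip(others, res.statistic, res.pvalue):
        se = np.sqrt(s2 * (1 / samples[g].size + 1 / ctl.size))
        t = (samples[g].mean() - ctl.mean()) / se
        praw = float(2 * stats.t.sf(abs(t), dfw))
        rows.append({"group": g, "diff": samples[g].mean() - ctl.mean(),
                     "t": float(stat), "p_raw": praw,
                     "p_adjusted": float(max(padj, praw))})
    return pd.DataFrame(rows)


def tukey_hsd(samples: dict) -> tuple[pd.DataFrame, dict]:
    """Tukey's honest significant difference over all group pairs.

    Returns the pairwise table (studentized-range adjusted p-values) and a
    compact letter display: groups sharing no letter differ at alpha=0.05.
    """
    samples = _check_samples(samples)
    groups = list(samples)
    res = stats.tukey_hsd(*[samples[g] for g in groups])
    rows = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        rows.append({
            "group1": groups[i],
            "group2": groups[j],
            "diff": samples[groups[i]].mean() - samples[groups[j]].mean(),
            "p_adjusted": float(res.pvalue[i, j]),
        })
    table = pd.DataFrame(rows)
    letters = compact_letter_display(table, groups)
    return table, letters


def compact_letter_display(pairwise: pd.DataFrame, groups: list, alpha: float = 0.05) -> dict:
    """Assign letters so that groups sharing a letter are not distinguishable.

    Insert-and-absorb algorithm over the significant pairs; groups are
    processed in the given order and letters assigned alphabetically.
    """
    distinct = {
        frozenset((r["group1"], r["group2"]))
        for _, r in pairwise.iterrows() if r["p_adjusted"] < alpha
    }
    # start with one set of all groups; split on each significant pair
    sets: list[set] = [set(groups)]
    for pair in distinct:
        a, b = tuple(pair)
        new_sets = []
        for s in sets:
            if a in s and b in s:
                new_sets.extend([s - {a}, s - {b}])
            else:
                new_sets.append(s)
        # absorb subsets
        sets = []
        for s in sorted(new_sets, key=len, reverse=True):
            if not any(s <= t for t in sets):
                sets.append(s)
    # stable letter order by first group appearance
    sets.sort(key=lambda s: min(groups.index(g) for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for letter, s in zip(alphabet, sets):
        for g in groups:
            if g in s:
                out[g] += letter
    return out


def polynomial_backward_regression(
    day: np.ndarray,
    response: np.ndarray,
    strain: np.ndarray,
    max_degree: int = 3,
    alpha: float = 0.05,
) -> dict:
    """Polynomial time-course regression with backward term elimination.

    Starts from ``response ~ strain + day + ... + day^d + strain:day + ...
    + strain:day^d`` and iteratively removes the least significant
    removable term (highest order first, marginality respected: a term is
    removable only while no higher-order term containing it remains) whose
    partial F-test p-value exceeds ``alpha``.

    Returns the selected term list, per-term p-values and the OLS results.
    """
    import statsmodels.api as sm

    day = np.asarray(day, dtype=float)
    y = np.asarray(response, dtype=float)
    strain = np.asarray(strain)
    if y.std() == 0:
        raise ValueError("zero-variance response")
    levels = [l for l in pd.unique(strain)]
    ref = levels[0]
    dummies = {l: (strain == l).astype(float) for l in levels[1:]}

    def columns_for(term: str) -> np.ndarray:
        if term == "strain":
            return np.column_stack([dummies[l] for l in levels[1:]])
        if term.startswith("strain:day^"):
            d = int(term.split("^")[1])
            return np.column_stack([dummies[l] * day**d for l in levels[1:]])
        d = int(term.split("^")[1])
        return day[:, None] ** d

    terms = []
    if len(levels) > 1:
        terms.append("strain")
    terms += [f"day^{d}" for d in range(1, max_degree + 1)]
    if len(levels) > 1:
        terms += [f"strain:day^{d}" for d in range(1, max_degree + 1)]

    def removable(term: str, current: list) -> bool:
        if term == "strain":
            return not any(t.startswith("strain:") for t in current)
        if term.startswith("strain:day^"):
            d = int(term.split("^")[1])
            return not any(
                t.startswith("strain:day^") and int(t.split("^")[1]) > d for t in current
            )
        d = int(term.split("^")[1])
        if any(f"day^{k}" in current for k in range(d + 1, max_degree + 1)):
            return False
        if any(f"strain:day^{k}" in current for k in range(d, max_degree + 1)):
            return False
        return True

    def fit(term_list: list):
        X = np.column_stack([np.ones_like(day)] + [columns_for(t) for t in term_list]) \
            if term_list else np.ones((day.size, 1))
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("rank-deficient (collinear) design")
        return sm.OLS(y, X).fit(), X

    def term_pvalues(term_list: list) -> dict:
        full, _ = fit(term_list)
        pvals = {}
        for t in term_list:
            red, _ = fit([u for u in term_list if u != t])
            ftest = full.compare_f_test(red)
            pvals[t] = float(ftest[1])
        return pvals

    current = list(terms)
    while True:
        pvals = term_pvalues(current)
        candidates = {t: p for t, p in pvals.items()
                      if removable(t, [u for u in current if u != t]) and p >= alpha}
        if not candidates:
            break
        drop = max(candidates, key=candidates.get)
        logger.info("backward selection drops %s (p = %.3f)", drop, candidates[drop])
        current.remove(drop)
        if not current:
            break
    result, X = fit(current)
    return {
        "terms": current,
        "term_pvalues": term_pvalues(current) if current else {},
        "model": result,
        "formula": "response ~ 1" + "".join(f" + {t}" for t in current),
    }
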