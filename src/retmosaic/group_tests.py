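"""Group-comparison statistics shared across the pipeline's figures.

Two-sided throughout, α = 0.05 by convention: Mann-Whitney U (rank test for
skewed enclosure counts), Student's t, one-way ANOVA with Tukey HSD-corrected
pairwise contrasts, chi-squared contingency, and Levene's variance test
(mean-centred, see :func:`retmosaic.enclosure.variance_equality_test`).
Degenerate inputs (identical groups, zero variance) are flagged rather than
propagated as NaN surprises.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import InputError

__all__ = ["run_group_tests"]

_KNOWN_TESTS = ("mann_whitney", "t", "anova_tukey", "levene", "chi2")


def _row(test, comparison, statistic, p, note=""):
    return {
        "test": test,
        "comparison": comparison,
        "statistic": statistic,
        "p_value": p,
        "note": note,
    }


def _degenerate(groups: dict) -> bool:
    pooled = np.concatenate([np.asarray(v, dtype=float) for v in groups.values()])
    return bool(len(pooled) and np.all(pooled == pooled[0]))


def run_group_tests(groups: dict, tests=("mann_whitney",)) -> pd.DataFrame:
    """Run the selected two-sided tests on labelled samples.

    ``groups`` maps group label → sample values. Two-sample tests run on all
    pairs; ANOVA runs on all groups with Tukey-corrected pairwise contrasts
    appended. Returns a tidy results table (one test per row).
    """
    if len(groups) < 2:
        raise InputError("need at least 2 groups")
    for name in tests:
        if name not in _KNOWN_TESTS:
            raise InputError(f"unknown test {name!r}; choose from {_KNOWN_TESTS}")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    rows = []
    pairs = list(itertools.combinations(arrays, 2))

    for name in tests:
        if name == "mann_whitney":
            for a, b in pairs:
                if min(len(arrays[a]), len(arrays[b])) < 2:
                    rows.append(_row(name, f"{a} vs {b}", math.nan, math.nan, "degenerate: n < 2"))
                    continue
                res = stats.mannwhitneyu(arrays[a], arrays[b], alternative="two-sided")
                rows.append(_row(name, f"{a} vs {b}", float(res.statistic), float(res.pvalue)))
        elif name == "t":
            for a, b in pairs:
                x, y = arrays[a], arrays[b]
                if min(len(x), len(y)) < 2:
                    rows.append(_row(name, f"{a} vs {b}", math.nan, math.nan, "degenerate: n < 2"))
                elif np.all(x == x[0]) and np.all(y == y[0]):
                    p = 1.0 if x[0] == y[0] else 0.0
                    rows.append(_row(name, f"{a} vs {b}", 0.0, p, "degenerate: zero variance"))
                else:
                    res = stats.ttest_ind(x, y)
                    rows.append(_row(name, f"{a} vs {b}", float(res.statistic), float(res.pvalue)))
        elif name == "anova_tukey":
            samples = list(arrays.values())
            if any(len(s) < 2 for s in samples):
                rows.append(_row(name, "all groups", math.nan, math.nan, "degenerate: n < 2"))
            elif _degenerate(arrays):
                rows.append(_row(name, "all groups", 0.0, 1.0, "degenerate: identical values"))
            else:
                f, p = stats.f_oneway(*samples)
                rows.append(_row(name, "all groups", float(f), float(p)))
                values = np.concatenate(samples)
                labels = np.concatenate(
                    [np.full(len(v), k) for k, v in arrays.items()]
                )
                tukey = pairwise_tukeyhsd(values, labels, alpha=0.05)
                for (g1, g2), p_adj in zip(
                    itertools.combinations(tukey.groupsunique, 2), tukey.pvalues
                ):
                    rows.append(
                        _row("tukey_hsd", f"{g1} vs {g2}", math.nan, float(p_adj),
                             "Tukey-adjusted")
                    )
        elif name == "levene":
            for a, b in pairs:
                x, y = arrays[a], arrays[b]
                if np.all(x == x[0]) and np.all(y == y[0]):
                    rows.append(_row(name, f"{a} vs {b}", math.nan, math.nan,
                                     "degenerate: zero deviations"))
                else:
                    f, p = stats.levene(x, y, center="mean")
                    rows.append(_row(name, f"{a} vs {b}", float(f), float(p)))
        elif name == "chi2":
            # groups hold categorical observations; build a contingency table
            categories = sorted({v for arr in arrays.values() for v in arr.tolist()})
            table = np.array(
                [[np.sum(arr == c) for c in categories] for arr in arrays.values()]
            )
            if table.shape[1] < 2:
                rows.append(_row(name, "all groups", 0.0, 1.0, "degenerate: one category"))
            else:
                chi2, p, _, _ = stats.chi2_contingency(table)
                rows.append(_row(name, "all groups", float(chi2), float(p)))
    return pd.DataFrame(rows)
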