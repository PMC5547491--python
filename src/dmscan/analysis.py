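"""Standard-error-based filtering and z-test hypothesis testing.

Per-variant standard errors let the experimenter keep the most reliably
scored variants directly, instead of applying read-count cutoffs that
ignore non-sampling noise and bias against depleted variants.  They also
power z-tests of each variant against wild-type and of the same variant
between two experimental conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy import stats

#: criteria ranked ascending (smaller is better)
_ASCENDING = {"random_effects_SE", "fixed_effect_SE"}
#: criteria ranked descending (larger is better)
_DESCENDING = {"input_count", "total_count"}


@dataclass(frozen=True)
class FilterSpec:
    """How to rank variants and what fraction to retain.

    criterion: ``random_effects_SE`` | ``fixed_effect_SE`` | ``input_count``
    | ``total_count``.  SE criteria retain the lowest values, count criteria
    the highest.  ``retention`` is the top fraction kept (0.25 = quartile).
    """

    criterion: str
    retention: float = 0.25

    def __post_init__(self) -> None:
        if self.criterion not in _ASCENDING | _DESCENDING:
            raise ValueError(f"unknown filter criterion {self.criterion!r}")
        if not 0 < self.retention <= 1:
            raise ValueError("retention fraction must be in (0, 1]")


def filter_variants(values: pd.Series, spec: FilterSpec) -> pd.Index:
    """Retain the top ``retention`` fraction of variants by the criterion.

    ``values`` holds the criterion for each candidate variant (e.g. the
    combined SE, or the input-round count).  Ties are broken by stable
    variant-label order.  Returns ceil(retention * n) variant labels.
    """
    if values.isna().any():
        raise ValueError("criterion unavailable (NaN) for some variants")
    ascending = spec.criterion in _ASCENDING
    ordered = values.sort_index().sort_values(ascending=ascending, kind="stable")
    k = math.ceil(spec.retention * len(ordered))
    return ordered.index[:k]


def replicate_concordance(scores_a: pd.Series, scores_b: pd.Series) -> float:
    """Squared Pearson correlation over variants scored in both replicates."""
    joined = pd.concat([scores_a, scores_b], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError("need >= 3 shared scored variants")
    r = stats.pearsonr(joined.iloc[:, 0], joined.iloc[:, 1]).statistic
    return float(r**2)


def z_test_vs_wildtype(score, se):
    """z-test of a score against the wild-type null (score = 0).

    Returns (z, raw two-sided p).  SE = 0 is degenerate: p = 0 for a nonzero
    score (flagged by z = +/-inf), p = 1 for a zero score.
    """
    score = np.asarray(score, dtype=float)
    se = np.asarray(se, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, score / np.where(se > 0, se, 1.0), np.sign(score) * np.inf)
    z = np.where((se == 0) & (score == 0), 0.0, z)
    p = np.where(np.isinf(z), 0.0, 2.0 * stats.norm.sf(np.abs(z)))
    p = np.where((se == 0) & (score == 0), 1.0, p)
    if score.ndim == 0:
        return float(z), float(p)
    return z, p


def z_test_between_conditions(score_a, se_a, score_b, se_b):
    """z-test for a different effect in condition A vs condition B.

    z = (score_a - score_b) / sqrt(se_a^2 + se_b^2).  Assumes the score
    distributions of the two conditions are roughly comparable; no
    cross-condition normalization is applied.
    """
    diff = np.asarray(score_a, dtype=float) - np.asarray(score_b, dtype=float)
    se = np.sqrt(np.asarray(se_a, dtype=float) ** 2 + np.asarray(se_b, dtype=float) ** 2)
    return z_test_vs_wildtype(diff, se)


def adjust_pvalues(p, method: str = "bh"):
    """Benjamini-Hochberg step-up adjusted p-values."""
    if method.lower() not in {"bh", "benjamini-hochberg"}:
        raise ValueError(f"unsupported adjustment method {method!r}")
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return stats.false_discovery_control(arr, method="bh")


def compare_conditions(
    combined_a: pd.DataFrame,
    combined_b: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-variant condition comparison report.

    Joins two combined-score tables (columns ``score``/``SE``) on shared
    variants, computes the between-condition z-test, and BH-adjusts the raw
    p-values.  ``significant`` marks variants with adjusted p < alpha.

    Note: comparisons assume the two conditions' score distributions are
    roughly similar; interpret with caution otherwise.
    """
    joined = combined_a[["score", "SE"]].join(
        combined_b[["score", "SE"]], how="inner", lsuffix="_A", rsuffix="_B"
    )
    joined = joined.dropna()
    z, p = z_test_between_conditions(
        joined["score_A"], joined["SE_A"], joined["score_B"], joined["SE_B"]
    )
    out = joined.copy()
    out["z"] = z
    out["p_raw"] = p
    out["p_adj"] = adjust_pvalues(p) if len(out) else p
    out["significant"] = out["p_adj"] < alpha
    return out
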