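"""Enrichment scores for a single selection.

The score of a variant is the slope of its wild-type-normalized log count
ratio regressed on normalized time.  For each timepoint t (including the
input) the response is

    M_{v,t} = ln( (c_{v,t} + 1/2) / (c_{ref,t} + 1/2) )

where c_ref is the wild-type count (wild-type normalization) or the filtered
library size (library-size normalization).  The 1/2 pseudocount keeps very
small counts finite.  Under Poisson sampling the variance of M_{v,t} is
approximately

    V_{v,t} = 1/(c_{v,t} + 1/2) + 1/(c_{ref,t} + 1/2)

and regression weights are w = 1/V, so low-coverage timepoints are
downweighted.  With three or more timepoints the score is the weighted
least-squares slope over x = t/max(T); with exactly two it is the log ratio
difference (ratio method) with a closed-form Poisson standard error.  The
intercept is fitted but never reported as a score.

p-values test the null that a variant behaves like wild-type (slope 0) with
a two-sided z-test.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy import stats

from .counting import TimepointSchedule, VariantCountTable

PSEUDOCOUNT = 0.5


def log_ratio(c_v, c_ref):
    """ln((c_v + 1/2) / (c_ref + 1/2)); valid for any nonnegative counts."""
    c_v = _check_counts(c_v)
    c_ref = _check_counts(c_ref)
    return np.log((c_v + PSEUDOCOUNT) / (c_ref + PSEUDOCOUNT))


def poisson_variance(c_v, c_ref):
    """Approximate variance of the log ratio under Poisson sampling."""
    c_v = _check_counts(c_v)
    c_ref = _check_counts(c_ref)
    return 1.0 / (c_v + PSEUDOCOUNT) + 1.0 / (c_ref + PSEUDOCOUNT)


def _check_counts(c):
    arr = np.asarray(c)
    if np.any(arr < 0):
        raise ValueError("counts must be nonnegative")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(arr == np.floor(arr)):
            raise ValueError("counts must be integers")
    return arr


@dataclass
class LogRatioSeries:
    """Per-timepoint log ratios and Poisson variances for scored variants."""

    M: pd.DataFrame  # variants x timepoints
    V: pd.DataFrame  # variants x timepoints, strictly positive
    normalization: str  # "wild-type" | "library-size"

    @property
    def weights(self) -> pd.DataFrame:
        return 1.0 / self.V


def build_log_ratios(
    table: VariantCountTable, normalization: str = "wild-type"
) -> LogRatioSeries:
    """Compute M and V for every variant against the chosen denominator."""
    if normalization == "wild-type":
        if table.wild_type is None:
            raise ValueError(
                "no wild-type row in the table; wild-type normalization is "
                "precluded — use library-size normalization"
            )
        c_ref = table.counts.loc[table.wild_type].to_numpy()
    elif normalization == "library-size":
        c_ref = table.filtered_library_size().to_numpy()
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    c = table.counts.to_numpy()
    M = np.log((c + PSEUDOCOUNT) / (c_ref + PSEUDOCOUNT))
    V = 1.0 / (c + PSEUDOCOUNT) + 1.0 / (c_ref + PSEUDOCOUNT)
    return LogRatioSeries(
        pd.DataFrame(M, index=table.variants, columns=table.counts.columns),
        pd.DataFrame(V, index=table.variants, columns=table.counts.columns),
        normalization,
    )


def wls_fit(x: np.ndarray, M: np.ndarray, w: np.ndarray):
    """Weighted least-squares line fit, vectorized over rows of M and w.

    Returns (slope, slope SE, intercept).  The slope variance is the nominal
    WLS variance scaled by the weighted residual mean square
    s^2 = sum(w e^2)/(n-2), so a perfect fit has SE exactly 0.
    """
    x = np.asarray(x, dtype=float)
    M = np.atleast_2d(np.asarray(M, dtype=float))
    w = np.atleast_2d(np.asarray(w, dtype=float))
    n = x.size
    if n < 3:
        raise ValueError("weighted regression requires at least 3 timepoints")
    if np.ptp(x) == 0:
        raise ValueError("all regression x values are equal")
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be positive and finite")
    sw = w.sum(axis=1)
    swx = (w * x).sum(axis=1)
    swy = (w * M).sum(axis=1)
    swxx = (w * x * x).sum(axis=1)
    swxy = (w * x * M).sum(axis=1)
    denom = sw * swxx - swx**2
    slope = (sw * swxy - swx * swy) / denom
    intercept = (swy - slope * swx) / sw
    resid = M - (intercept[:, None] + slope[:, None] * x)
    s2 = (w * resid**2).sum(axis=1) / (n - 2)
    # tiny negative round-off under the sqrt is clipped
    se = np.sqrt(np.clip(s2 * sw / denom, 0.0, None))
    return slope, se, intercept


def wls_score(series: LogRatioSeries, schedule: TimepointSchedule) -> pd.DataFrame:
    """Score variants by weighted regression of M_{v,t} on t/max(T).

    Requires >= 3 timepoints (use `ratio_score` for two).  Returns a
    DataFrame with columns score, SE, p_raw, intercept.
    """
    x = schedule.normalized
    slope, se, intercept = wls_fit(x, series.M.to_numpy(), series.weights.to_numpy())
    p = z_pvalue(slope, se)
    return pd.DataFrame(
        {"score": slope, "SE": se, "p_raw": p, "intercept": intercept},
        index=series.M.index,
    )


def ratio_score(c_v_inp, c_v_sel, c_ref_inp, c_ref_sel) -> pd.DataFrame:
    """Two-timepoint ratio score: slope of the line through the two log ratios.

    L_v  = ln((c_v,sel+1/2)/(c_ref,sel+1/2)) - ln((c_v,inp+1/2)/(c_ref,inp+1/2))
    SE_v = sqrt(1/(c_v,inp+1/2) + 1/(c_ref,inp+1/2)
                + 1/(c_v,sel+1/2) + 1/(c_ref,sel+1/2))
    """
    L = log_ratio(c_v_sel, c_ref_sel) - log_ratio(c_v_inp, c_ref_inp)
    se = np.sqrt(poisson_variance(c_v_inp, c_ref_inp) + poisson_variance(c_v_sel, c_ref_sel))
    p = z_pvalue(L, se)
    return pd.DataFrame(
        {
            "score": np.atleast_1d(L),
            "SE": np.atleast_1d(se),
            "p_raw": np.atleast_1d(p),
        }
    )


def z_pvalue(score, se):
    """Two-sided z-test p-value of score/SE against 0.

    SE == 0 is degenerate: p = 1 when the score is also 0 (the wild-type
    normalization identity) and p = 0 otherwise.
    """
    score = np.asarray(score, dtype=float)
    se = np.asarray(se, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, score / np.where(se > 0, se, 1.0), np.inf)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where((se == 0) & (score == 0), 1.0, p)
    return p


def score_selection(
    table: VariantCountTable, normalization: str = "wild-type"
) -> pd.DataFrame:
    """Score every input-present variant in a selection.

    Dispatches to weighted regression (>= 3 timepoints) or the ratio method
    (exactly 2).  Variants with a zero input count are reported with null
    scores (log-ratio scoring is anchored at the input library).

    Returns a DataFrame indexed by variant with columns score, SE, p_raw,
    method, n_timepoints.
    """
    series = build_log_ratios(table, normalization)
    n_t = table.n_timepoints
    if n_t >= 3:
        scores = wls_score(series, table.schedule).drop(columns="intercept")
        method = "WLS"
    else:
        c = table.counts.to_numpy()
        if normalization == "wild-type":
            ref = table.counts.loc[table.wild_type].to_numpy()
        else:
            ref = table.filtered_library_size().to_numpy()
        scores = ratio_score(c[:, 0], c[:, 1], ref[0], ref[1])
        scores.index = table.variants
        method = "ratio"
    scores["method"] = method
    scores["n_timepoints"] = n_t
    scores["normalization"] = series.normalization
    eligible = table.input_present()
    unscored = ~scores.index.isin(eligible)
    scores.loc[unscored, ["score", "SE", "p_raw"]] = np.nan
    scores.loc[unscored, "method"] = "unscored"
    return scores


def write_scores(scores: pd.DataFrame, path) -> None:
    scores.to_csv(path, sep="\t", index_label="variant")


def read_scores(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="variant")
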