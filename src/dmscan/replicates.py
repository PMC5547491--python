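"""Combining replicate selection scores per variant.

Replicate scores beta_i with standard errors sigma_i are combined with a
one-random-effect meta-analysis model.  The between-replicate variance
sigma_s^2 is estimated by restricted maximum likelihood via a fixed number
of Fisher-scoring (fixed-point) iterations, run for all variants in
parallel; each variant is combined independently of all others.

At every iteration, with weights w_i = (sigma_s^2 + sigma_i^2)^-1:

    beta_hat      = sum(w_i beta_i) / sum(w_i)
    sigma_s^2_new = sigma_s^2 * sum(w_i^2 (beta_i - beta_hat)^2)
                    / ( sum(w_i) - sum(w_i^2)/sum(w_i) )

initialized at the unweighted sample variance of the replicate scores.  The
combined standard error sqrt(1/sum(w_i)) captures both selection-specific
sampling error and the spread of scores across replicates.  The last
iteration's change eps_s = sigma_s^2 - sigma_s-1^2 is recorded; variants
whose |eps_s| exceeds a tolerance are flagged as non-converged.

The fixed-effect model (inverse-variance weighting with sigma_s^2 = 0) is
provided for comparison only: it ignores replicate heterogeneity and can
dramatically underestimate the combined standard error.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .scoring import z_pvalue

N_ITERATIONS = 50
CONVERGENCE_TOL = 1e-6


def random_effects(
    betas,
    sigmas,
    iterations: int = N_ITERATIONS,
    tol: float = CONVERGENCE_TOL,
) -> pd.DataFrame:
    """Combine replicate scores with the random-effects model.

    Parameters
    ----------
    betas, sigmas
        Arrays of shape (n_variants, n_replicates): per-replicate scores and
        standard errors.  NaN marks a replicate in which the variant was not
        scored; a variant needs >= 2 scored replicates to be combined.
    iterations
        Number of Fisher-scoring iterations, run unconditionally for all
        variants (cheaper than per-variant convergence checks).
    tol
        Threshold on |eps_s| above which a variant is flagged non-converged.

    Returns
    -------
    DataFrame with columns score, SE, sigma_s2, eps_s, converged, p_raw,
    n_reps (and the index of ``betas`` if it is a DataFrame).
    """
    index = betas.index if isinstance(betas, pd.DataFrame) else None
    b = np.atleast_2d(np.asarray(betas, dtype=float))
    s = np.atleast_2d(np.asarray(sigmas, dtype=float))
    if b.shape != s.shape:
        raise ValueError("betas and sigmas must have the same shape")
    if b.shape[1] < 2:
        raise ValueError(
            "random-effects combination needs >= 2 replicates; "
            "pass the single replicate's scores through unchanged instead"
        )
    valid = np.isfinite(b) & np.isfinite(s)
    if np.any(s[valid] < 0):
        raise ValueError("standard errors must be nonnegative")
    n = valid.sum(axis=1)
    combinable = n >= 2

    # Work in masked form: invalid cells get variance inf => weight 0.
    var_i = np.where(valid, s**2, np.inf)
    b0 = np.where(valid, b, 0.0)

    mean_b = np.where(n > 0, b0.sum(axis=1) / np.maximum(n, 1), np.nan)
    sigma_s2 = np.where(
        combinable,
        (np.where(valid, (b0 - mean_b[:, None]) ** 2, 0.0)).sum(axis=1)
        / np.maximum(n - 1, 1),
        np.nan,
    )

    # Rows where every scored replicate has SE 0 (e.g. the wild-type under
    # wild-type normalization, scores identically 0): the weights are
    # infinite and the update is degenerate.  Combine them exactly.
    all_zero_var = combinable & (np.where(valid, var_i, 0.0) == 0).all(axis=1)

    eps = np.zeros_like(sigma_s2)
    beta_hat = np.full(b.shape[0], np.nan)
    sw = np.full(b.shape[0], np.nan)
    work = combinable & ~all_zero_var
    if work.any():
        ss = sigma_s2[work]
        vw = var_i[work]
        bw = b0[work]
        eps_w = np.zeros_like(ss)
        for _ in range(iterations):
            w = 1.0 / (ss[:, None] + vw)  # invalid cells: 1/inf = 0
            sw_w = w.sum(axis=1)
            bh = (w * bw).sum(axis=1) / sw_w
            resid2 = np.where(np.isfinite(vw), (bw - bh[:, None]) ** 2, 0.0)
            num = (w**2 * resid2).sum(axis=1)
            den = sw_w - (w**2).sum(axis=1) / sw_w
            with np.errstate(divide="ignore", invalid="ignore"):
                step = np.where(den > 0, num / den, 0.0)
            new = ss * step
            new = np.clip(new, 0.0, None)  # guard: undershoot clamps at 0
            eps_w = new - ss
            ss = new
        w = 1.0 / (ss[:, None] + vw)
        sw_w = w.sum(axis=1)
        beta_hat[work] = (w * bw).sum(axis=1) / sw_w
        sw[work] = sw_w
        sigma_s2[work] = ss
        eps[work] = eps_w

    if all_zero_var.any():
        rows = all_zero_var
        spread = np.where(valid[rows], (b0[rows] - mean_b[rows, None]) ** 2, 0.0)
        sigma_s2[rows] = spread.sum(axis=1) / np.maximum(n[rows] - 1, 1)
        beta_hat[rows] = mean_b[rows]
        with np.errstate(divide="ignore"):
            sw[rows] = np.where(
                sigma_s2[rows] > 0, n[rows] / sigma_s2[rows], np.inf
            )
        eps[rows] = 0.0

    with np.errstate(divide="ignore"):
        se = np.sqrt(1.0 / sw)
    p = np.where(
        np.isfinite(beta_hat), z_pvalue(np.nan_to_num(beta_hat), np.nan_to_num(se)), np.nan
    )
    out = pd.DataFrame(
        {
            "score": beta_hat,
            "SE": se,
            "sigma_s2": sigma_s2,
            "eps_s": eps,
            "converged": np.abs(eps) <= tol,
            "p_raw": p,
            "n_reps": n,
        }
    )
    out.loc[~combinable, ["score", "SE", "sigma_s2", "eps_s", "p_raw"]] = np.nan
    out.loc[~combinable, "converged"] = False
    if index is not None:
        out.index = index
    return out


def fixed_effect(betas, sigmas) -> pd.DataFrame:
    """Inverse-variance-weighted fixed-effect combination (comparison only).

    beta' = sum(beta_i / sigma_i^2) / sum(1 / sigma_i^2)
    SE'   = sqrt(1 / sum(1 / sigma_i^2))

    Any sigma_i == 0 is an error (infinite weight).
    """
    index = betas.index if isinstance(betas, pd.DataFrame) else None
    b = np.atleast_2d(np.asarray(betas, dtype=float))
    s = np.atleast_2d(np.asarray(sigmas, dtype=float))
    if b.shape != s.shape:
        raise ValueError("betas and sigmas must have the same shape")
    if b.shape[1] < 2:
        raise ValueError("fixed-effect combination needs >= 2 replicates")
    valid = np.isfinite(b) & np.isfinite(s)
    if np.any(s[valid] == 0):
        raise ValueError("fixed-effect weights are infinite when any SE is 0")
    w = np.where(valid, 1.0 / s**2, 0.0)
    n = valid.sum(axis=1)
    sw = w.sum(axis=1)
    with np.errstate(invalid="ignore"):
        beta = (w * np.where(valid, b, 0.0)).sum(axis=1) / sw
        se = np.sqrt(1.0 / sw)
    beta = np.where(n >= 2, beta, np.nan)
    se = np.where(n >= 2, se, np.nan)
    out = pd.DataFrame(
        {"score": beta, "SE": se, "p_raw": z_pvalue(np.nan_to_num(beta), np.nan_to_num(se)), "n_reps": n}
    )
    out.loc[n < 2, "p_raw"] = np.nan
    if index is not None:
        out.index = index
    return out


def combine_replicates(
    score_frames: Sequence[pd.DataFrame], model: str = "random"
) -> pd.DataFrame:
    """Combine per-selection score tables (from `score_selection`).

    Aligns the replicate frames on the union of variants; a variant missing
    or unscored in a replicate simply contributes nothing to that replicate's
    weight.
    """
    if len(score_frames) < 2:
        raise ValueError("need >= 2 replicate score tables")
    union = score_frames[0].index
    for f in score_frames[1:]:
        union = union.union(f.index)
    union = pd.Index(sorted(union))
    betas = pd.DataFrame(
        {i: f["score"].reindex(union) for i, f in enumerate(score_frames)}
    )
    sigmas = pd.DataFrame(
        {i: f["SE"].reindex(union) for i, f in enumerate(score_frames)}
    )
    if model == "random":
        return random_effects(betas, sigmas)
    if model == "fixed":
        return fixed_effect(betas, sigmas)
    raise ValueError(f"unknown model {model!r}")
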