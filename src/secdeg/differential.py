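"""Moderated two-group differential abundance with BH correction.

Implements the empirical-Bayes moderated t-statistic for a two-group
comparison: per-feature pooled residual variances s2 with df residual degrees
of freedom are shrunk toward a common prior by fitting a scaled
inverse-chi-square prior (s2_prior, df_prior) via the method of moments on the
log variances (Smyth-style, including the trigamma-inverse Newton iteration).
The posterior variance is

    s2_post = (df_prior * s2_prior + df * s2) / (df_prior + df)

and the moderated t is  t = log2FC / sqrt(s2_post * (1/n_a + 1/n_b))  on
df + df_prior degrees of freedom.  With df_prior = 0 this reduces exactly to
the ordinary equal-variance two-sample t; with df_prior -> inf every feature
is tested against the common prior variance (normal reference distribution).

Multiple testing uses the Benjamini–Hochberg step-up, applied here within
each SEC fraction x contrast family (per-fraction enrichment is the unit of
reporting); a global family is available behind a flag.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .design import REPLICATES, sample_id
from .errors import HyperparameterError
from .terminomics import SEMI_CLASSES

CONTRASTS: tuple[tuple[str, str], ...] = (("L+N", "L"), ("L+V", "L"))


def contrast_label(treatment: str, control: str) -> str:
    return f"{treatment} vs {control}"


def trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration on a stable scale)."""
    if x <= 0:
        raise ValueError("trigamma_inverse requires a positive argument")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def fit_variance_prior(
    s2: np.ndarray, df: np.ndarray | float
) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse-chi-square variance prior.

    Matches the moments of log(s2) against the log-F expectation: with
    z = log(s2), E[z] = digamma(df/2) - log(df/2) + log(s2_prior) + ... and
    Var[z] = trigamma(df/2) + trigamma(df_prior/2).  Features with zero or
    missing variance are excluded from the fit.  Returns (s2_prior, df_prior);
    df_prior is ``inf`` when the observed variances are homogeneous.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        raise HyperparameterError(
            f"need at least 2 features with estimable variance, got {int(ok.sum())}"
        )
    z = np.log(s2[ok])
    dfo = df[ok]
    e = z - special.digamma(dfo / 2.0) + np.log(dfo / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(np.mean(special.polygamma(1, dfo / 2.0)))
    if evar > 0:
        df_prior = 2.0 * trigamma_inverse(evar)
        s2_prior = float(
            np.exp(emean + special.digamma(df_prior / 2.0) - np.log(df_prior / 2.0))
        )
    else:
        # homogeneous variances: infinite prior df, prior = mean variance
        df_prior = np.inf
        s2_prior = float(np.mean(s2[ok]))
    return s2_prior, df_prior


def moderated_t_test(
    matrix: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    *,
    df_prior: float | None = None,
) -> pd.DataFrame:
    """Moderated two-group comparison of every feature (row) in ``matrix``.

    ``group_a`` / ``group_b`` name sample columns (a = treatment, so
    log2FC = mean_a - mean_b).  Features with fewer than two non-missing
    values in either group are reported with ``tested = False``.  Pass
    ``df_prior=0`` to disable shrinkage (ordinary pooled t) or a finite value
    to force it; by default the prior is fitted from the data.  The fitted
    hyperparameters are exposed on ``result.attrs``.
    """
    a = matrix[list(group_a)].to_numpy(dtype=float)
    b = matrix[list(group_b)].to_numpy(dtype=float)
    na = np.sum(~np.isnan(a), axis=1)
    nb = np.sum(~np.isnan(b), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_a = np.nanmean(a, axis=1)
        mean_b = np.nanmean(b, axis=1)
        ss_a = np.nansum((a - mean_a[:, None]) ** 2, axis=1)
        ss_b = np.nansum((b - mean_b[:, None]) ** 2, axis=1)
    df_resid = na + nb - 2.0
    tested = (na >= 2) & (nb >= 2) & (df_resid >= 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        s2 = np.where(tested, (ss_a + ss_b) / np.maximum(df_resid, 1.0), np.nan)
    log2fc = mean_a - mean_b

    fallback = False
    if df_prior is None:
        try:
            s2_prior, d0 = fit_variance_prior(s2[tested], df_resid[tested])
        except HyperparameterError:
            s2_prior, d0, fallback = np.nan, 0.0, True
    else:
        d0 = float(df_prior)
        s2_prior = (
            float(np.nanmean(s2[tested])) if np.any(tested) and d0 > 0 else np.nan
        )

    if np.isinf(d0):
        s2_post = np.full_like(s2, s2_prior)
    elif d0 > 0:
        s2_post = (d0 * s2_prior + df_resid * s2) / (d0 + df_resid)
        s2_post = np.where(s2 > 0, s2_post, s2_prior)  # zero-variance features
    else:
        s2_post = s2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
        t_mod = log2fc / se
        t_mod = np.where((log2fc == 0) & (se == 0), 0.0, t_mod)
    df_total = df_resid + d0
    p = np.full(len(matrix), np.nan)
    finite_df = np.isfinite(df_total)
    with np.errstate(invalid="ignore"):
        p[finite_df] = 2.0 * stats.t.sf(np.abs(t_mod[finite_df]), df_total[finite_df])
        p[~finite_df] = 2.0 * stats.norm.sf(np.abs(t_mod[~finite_df]))
    p = np.where(tested, p, np.nan)
    t_mod = np.where(tested, t_mod, np.nan)

    out = pd.DataFrame(
        {
            "log2fc": np.where((na >= 1) & (nb >= 1), log2fc, np.nan),
            "s2": s2,
            "s2_post": s2_post,
            "t_mod": t_mod,
            "df_resid": df_resid,
            "df_total": df_total,
            "p": p,
            "n_a": na,
            "n_b": nb,
            "tested": tested,
        },
        index=matrix.index,
    )
    out.attrs["s2_prior"] = s2_prior
    out.attrs["df_prior"] = d0
    out.attrs["fallback_ordinary_t"] = fallback
    return out


def adjust_bh(p: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    adj_i = min_{j >= i(rank)} (p_(j) * m / j), capped at 1.  Monotone in the
    input p-values; re-adjusting adjusted values never decreases them.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("adjust_bh expects a 1-d vector")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty(m, dtype=float)
    out[order] = adj_sorted
    return out


def per_fraction_contrasts(
    peptide_matrix: pd.DataFrame,
    annotations: pd.DataFrame,
    *,
    alpha: float = 0.05,
    contrasts: Sequence[tuple[str, str]] = CONTRASTS,
    df_prior: float | None = None,
    global_adjust: bool = False,
) -> pd.DataFrame:
    """Per-fraction moderated differential abundance of semi-tryptic peptides.

    For each SEC fraction and each contrast (treatment vs. LPS control) the
    moderated t-test is run on the semi-specific peptides quantified in that
    fraction; BH adjustment is applied within each fraction x contrast family
    (or globally per contrast with ``global_adjust=True``).  A peptide is
    flagged significant when adj_p < alpha AND log2FC > 0 (more abundant upon
    treatment).  Fractions with fewer than two replicate columns per arm are
    skipped with a warning.
    """
    semi = annotations.loc[annotations["specificity"].isin(SEMI_CLASSES)]
    key = peptide_matrix.index.droplevel("fraction_id")
    sub = peptide_matrix.loc[key.isin(semi.index)]
    records: list[pd.DataFrame] = []
    if not sub.empty:
        for fraction, block in sub.groupby(level="fraction_id", sort=True):
            mat = block.droplevel("fraction_id")
            for treatment, control in contrasts:
                cols_a = [
                    sample_id(treatment, r)
                    for r in REPLICATES
                    if sample_id(treatment, r) in mat.columns
                ]
                cols_b = [
                    sample_id(control, r)
                    for r in REPLICATES
                    if sample_id(control, r) in mat.columns
                ]
                if len(cols_a) < 2 or len(cols_b) < 2:
                    warnings.warn(
                        f"fraction {fraction}: fewer than 2 replicates per arm "
                        f"for {contrast_label(treatment, control)}; skipped"
                    )
                    continue
                res = moderated_t_test(mat, cols_a, cols_b, df_prior=df_prior)
                res = res.reset_index()
                res["fraction_id"] = int(fraction)
                res["contrast"] = contrast_label(treatment, control)
                records.append(res)
    columns = [
        "peptide", "accession", "fraction_id", "contrast", "log2fc", "t_mod",
        "p", "adj_p", "significant", "tested",
    ]
    if not records:
        return pd.DataFrame(columns=columns)
    out = pd.concat(records, ignore_index=True)
    out["adj_p"] = np.nan
    family_keys = ["contrast"] if global_adjust else ["fraction_id", "contrast"]
    for _, fam in out.groupby(family_keys, sort=False):
        idx = fam.index[fam["tested"]]
        if len(idx):
            out.loc[idx, "adj_p"] = adjust_bh(out.loc[idx, "p"].to_numpy())
    out["significant"] = (out["adj_p"] < alpha) & (out["log2fc"] > 0)
    return out[columns]
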