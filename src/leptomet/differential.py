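"""Paired post-vs-pre differential analysis with empirical-Bayes moderation.

With one pre and one post sample per individual the paired design collapses
to a one-sample problem on the within-individual log10 differences
``d_i = x_i,post - x_i,pre``.  Per metabolite g the residual variance
``s_g^2`` (df_g = n - 1) is shrunk toward a prior ``s_0^2`` with prior
degrees of freedom ``d_0``, both estimated across the metabolome by moment
matching on ``log s_g^2`` (digamma/trigamma inversion of the scaled-F law).
The moderated statistic

    t_g = mean(d) / (s~_g / sqrt(n)),   s~_g^2 = (d0 s0^2 + df_g s_g^2) / (d0 + df_g)

is referred to a t distribution with ``d0 + df_g`` degrees of freedom
(standard normal when d0 is infinite), two-sided.  Multiple testing is
controlled by Benjamini-Hochberg; significance is reported on two tiers,
nominal p < 0.05 and FDR < 0.2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .dataio import AbundanceMatrix, FDR_THRESHOLD, NOMINAL_P


@dataclass(frozen=True)
class EBayesPrior:
    """Scaled inverse-chi-square variance prior: d0 degrees of freedom, scale s0^2."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValueError("prior degrees of freedom must be >= 0")
        if self.d0 > 0 and not self.s0_sq > 0:
            raise ValueError("prior variance must be positive when d0 > 0")


def paired_effects(matrix: AbundanceMatrix, metadata: pd.DataFrame) -> pd.DataFrame:
    """Within-individual (post - pre) difference vectors.

    Returns an individuals x metabolites frame.  Individuals lacking either
    condition are excluded with a warning; fewer than 3 complete pairs is an
    error because the variance moderation downstream needs a variance.
    """
    if not matrix.log_scale:
        raise ValueError("paired_effects expects log-scale data")
    meta = metadata.loc[metadata.index.intersection(matrix.sample_ids)]
    pivot = meta.pivot_table(
        index="individual_id", columns="condition", values="sample_id", aggfunc="first"
    )
    for cond in ("pre", "post"):
        if cond not in pivot.columns:
            pivot[cond] = np.nan
    complete = pivot.dropna(subset=["pre", "post"])
    dropped = pivot.index.difference(complete.index)
    if len(dropped):
        warnings.warn(
            f"excluding {len(dropped)} individual(s) without both conditions: "
            f"{', '.join(map(str, dropped))}",
            stacklevel=2,
        )
    if len(complete) < 3:
        raise ValueError(f"need >= 3 complete pre/post pairs, have {len(complete)}")
    post = matrix.data.loc[complete["post"]].to_numpy(dtype=float)
    pre = matrix.data.loc[complete["pre"]].to_numpy(dtype=float)
    return pd.DataFrame(post - pre, index=complete.index, columns=matrix.metabolite_ids)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(s_sq: np.ndarray, df: float) -> EBayesPrior:
    """Moment-matching estimate of (d0, s0^2) from per-metabolite variances.

    Works on ``e_g = log s_g^2 - digamma(df/2) + log(df/2)`` whose mean is
    ``log s0^2 + digamma(d0/2) - log(d0/2)`` and whose excess variance over
    the sampling term ``trigamma(df/2)`` equals ``trigamma(d0/2)``.  When the
    empirical spread does not exceed the sampling spread the prior is a point
    mass (d0 infinite).
    """
    s_sq = np.asarray(s_sq, dtype=float)
    s_sq = s_sq[np.isfinite(s_sq)]
    if (s_sq < 0).any():
        raise ValueError("variances must be non-negative")
    if np.all(s_sq == 0):
        raise ValueError("all residual variances are zero; no variance prior exists")
    if len(s_sq) < 2:
        raise ValueError("need >= 2 metabolites to estimate a variance prior")
    if np.ptp(s_sq) == 0:
        # No spread at all: the observed value is the prior.
        return EBayesPrior(d0=np.inf, s0_sq=float(s_sq[0]))

    # Guard exact zeros before taking logs (limma offsets by a tiny constant).
    s_sq = np.maximum(s_sq, 1e-300)
    e = np.log(s_sq) - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar <= 0:
        return EBayesPrior(d0=np.inf, s0_sq=float(np.exp(emean)))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return EBayesPrior(d0=float(d0), s0_sq=float(s0_sq))


def moderated_t(differences: pd.DataFrame, prior: EBayesPrior | None = None) -> pd.DataFrame:
    """Moderated one-sample t-test on paired differences, per metabolite.

    ``prior=None`` estimates the variance prior from the data; ``d0=0``
    recovers the ordinary paired t-test.  Returns a frame indexed by
    metabolite_id with effect (mean log10 difference), fold_change
    (10^effect), s_g, df_g, t_mod, p_raw, p_adj, n_pairs and the two
    significance tiers.
    """
    n = len(differences)
    if n < 2:
        raise ValueError("need >= 2 pairs for a variance")
    d = differences.to_numpy(dtype=float)
    effect = d.mean(axis=0)
    s_sq = d.var(axis=0, ddof=1)
    df_g = float(n - 1)

    if prior is None:
        prior = estimate_prior(s_sq, df_g)

    if np.isinf(prior.d0):
        s_tilde_sq = np.full_like(s_sq, prior.s0_sq)
        t_mod = effect / np.sqrt(s_tilde_sq / n)
        p_raw = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        s_tilde_sq = (prior.d0 * prior.s0_sq + df_g * s_sq) / (prior.d0 + df_g)
        t_mod = effect / np.sqrt(s_tilde_sq / n)
        p_raw = 2.0 * stats.t.sf(np.abs(t_mod), df=prior.d0 + df_g)

    out = pd.DataFrame(
        {
            "metabolite_id": differences.columns,
            "effect": effect,
            "fold_change": np.power(10.0, effect),
            "s_g": np.sqrt(s_sq),
            "df_g": df_g,
            "t_mod": t_mod,
            "p_raw": p_raw,
            "n_pairs": n,
        }
    ).set_index("metabolite_id", drop=False)
    out.index.name = None
    out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
    out["significant_nominal"] = out["p_raw"] < NOMINAL_P
    out["significant_fdr"] = out["p_adj"] < FDR_THRESHOLD
    return out.sort_values(["p_raw", "metabolite_id"], kind="stable")


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _difference_design(
    metadata: pd.DataFrame, individuals, covariates
) -> np.ndarray | None:
    """Within-individual (post - pre) contrasts of sample-level covariates.

    Individual-constant covariates (sex, age, ethnicity) difference to zero
    and are dropped; what survives — typically the run-day contrast — enters
    the difference regression so batch structure cannot masquerade as a
    treatment effect.
    """
    cols = []
    for cov in covariates:
        if cov not in metadata.columns:
            continue
        series = metadata[cov]
        if pd.api.types.is_numeric_dtype(series):
            enc = series.astype(float).to_frame(cov)
        else:
            enc = pd.get_dummies(series.astype(str), prefix=cov, drop_first=True, dtype=float)
        enc = enc.assign(
            individual_id=metadata["individual_id"], condition=metadata["condition"]
        )
        for col in enc.columns.drop(["individual_id", "condition"]):
            pivot = enc.pivot_table(index="individual_id", columns="condition", values=col)
            cols.append((pivot["post"] - pivot["pre"]).loc[individuals].to_numpy())
    if not cols:
        return None
    W = np.column_stack(cols)
    W = W[:, np.abs(W).sum(axis=0) > 0]
    return W if W.shape[1] else None


def run_differential(
    matrix: AbundanceMatrix,
    metadata: pd.DataFrame,
    d0: float | str = "auto",
    difference_covariates: tuple[str, ...] = ("run_day",),
) -> pd.DataFrame:
    """Full paired differential stage: differences, prior, moderated tests.

    ``difference_covariates`` names sample-level covariates whose
    within-individual contrasts are regressed out of the paired differences
    (individual-constant covariates vanish in the differencing and need no
    correction).  With no surviving contrast columns this reduces to the
    one-sample moderated t on the raw differences.
    """
    diffs = paired_effects(matrix, metadata)
    meta = metadata.loc[metadata.index.intersection(matrix.sample_ids)]
    W = _difference_design(meta, list(diffs.index), difference_covariates)

    n = len(diffs)
    D = diffs.to_numpy(dtype=float)
    if W is None:
        effect = D.mean(axis=0)
        s_sq = D.var(axis=0, ddof=1)
        df_g = float(n - 1)
        var_factor = 1.0 / n
    else:
        X = np.column_stack([np.ones(n), W])
        rank = np.linalg.matrix_rank(X)
        df_g = float(n - rank)
        if df_g < 1:
            raise ValueError("difference covariates leave no residual degrees of freedom")
        beta, *_ = np.linalg.lstsq(X, D, rcond=None)
        resid = D - X @ beta
        effect = beta[0]
        s_sq = (resid**2).sum(axis=0) / df_g
        var_factor = float(np.linalg.pinv(X.T @ X)[0, 0])

    if d0 == "auto":
        prior = estimate_prior(s_sq, df_g)
    else:
        d0 = float(d0)
        base_s0 = 1.0 if d0 == 0 else estimate_prior(s_sq, df_g).s0_sq
        prior = EBayesPrior(d0=d0, s0_sq=base_s0)

    if np.isinf(prior.d0):
        s_tilde_sq = np.full_like(s_sq, prior.s0_sq)
        t_mod = effect / np.sqrt(s_tilde_sq * var_factor)
        p_raw = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        s_tilde_sq = (prior.d0 * prior.s0_sq + df_g * s_sq) / (prior.d0 + df_g)
        t_mod = effect / np.sqrt(s_tilde_sq * var_factor)
        p_raw = 2.0 * stats.t.sf(np.abs(t_mod), df=prior.d0 + df_g)

    out = pd.DataFrame(
        {
            "metabolite_id": diffs.columns,
            "effect": effect,
            "fold_change": np.power(10.0, effect),
            "s_g": np.sqrt(s_sq),
            "df_g": df_g,
            "t_mod": t_mod,
            "p_raw": p_raw,
            "n_pairs": n,
        }
    ).set_index("metabolite_id", drop=False)
    out.index.name = None
    out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
    out["significant_nominal"] = out["p_raw"] < NOMINAL_P
    out["significant_fdr"] = out["p_adj"] < FDR_THRESHOLD
    return out.sort_values(["p_raw", "metabolite_id"], kind="stable")
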