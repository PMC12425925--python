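"""Inverse-variance pooling, heterogeneity, subgroup analysis, meta-regression.

The pooling pipeline mirrors the standard candidate-gene synopsis recipe:
fixed-effects (inverse-variance) pooling, Cochran's Q and I² for
heterogeneity, a DerSimonian–Laird random-effects re-pool whenever
I² >= 50%, between-subgroup Q for ethnicity strata, and weighted
meta-regression with a method-of-moments residual τ² for exploring
heterogeneity sources.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .effects import Z_95, wald_p
from .records import (
    EffectEstimate,
    EligibilityError,
    InsufficientDataError,
    MetaRegressionResult,
    MetaResult,
    SubgroupResult,
)

__all__ = [
    "pool_fixed",
    "cochran_q",
    "i_squared",
    "pool_random_dl",
    "select_model",
    "meta_analyze",
    "subgroup_analysis",
    "meta_regression",
    "I2_RANDOM_THRESHOLD",
]

# Model switch: random effects once heterogeneity reaches this I² (percent).
I2_RANDOM_THRESHOLD = 50.0


def _arrays(effects: Sequence[EffectEstimate]) -> tuple[np.ndarray, np.ndarray]:
    theta = np.array([e.log_or for e in effects], dtype=float)
    se = np.array([e.se for e in effects], dtype=float)
    return theta, se


def _build_result(
    theta_hat: float,
    se_hat: float,
    model: str,
    k: int,
    q: float,
    q_df: int,
    q_p: float,
    i2: float,
    tau2: float,
    variant_id: str = "",
    stratum: str = "",
) -> MetaResult:
    return MetaResult(
        variant_id=variant_id,
        stratum=stratum,
        model=model,
        k=k,
        pooled_log_or=theta_hat,
        pooled_se=se_hat,
        ci_low=math.exp(theta_hat - Z_95 * se_hat),
        ci_high=math.exp(theta_hat + Z_95 * se_hat),
        p_value=wald_p(theta_hat, se_hat),
        q_stat=q,
        q_df=q_df,
        q_p=q_p,
        i_squared=i2,
        tau_squared=tau2,
    )


def pool_fixed(
    effects: Sequence[EffectEstimate], variant_id: str = "", stratum: str = ""
) -> MetaResult:
    """Fixed-effects inverse-variance pool (k >= 1)."""
    if len(effects) == 0:
        raise ValueError("cannot pool an empty set of effects")
    theta, se = _arrays(effects)
    w = 1.0 / se**2
    theta_hat = float(np.sum(w * theta) / np.sum(w))
    se_hat = float(np.sum(w) ** -0.5)
    if len(effects) >= 2:
        q, q_df, q_p = cochran_q(effects)
        i2 = i_squared(q, q_df)
    else:
        q, q_df, q_p, i2 = 0.0, 0, 1.0, 0.0
    return _build_result(
        theta_hat, se_hat, "fixed", len(effects), q, q_df, q_p, i2, 0.0,
        variant_id, stratum,
    )


def cochran_q(effects: Sequence[EffectEstimate]) -> tuple[float, int, float]:
    """Cochran's heterogeneity Q, its df = k-1, and the upper chi-square P."""
    k = len(effects)
    if k < 2:
        raise ValueError("Cochran's Q requires at least two studies")
    theta, se = _arrays(effects)
    w = 1.0 / se**2
    theta_fe = np.sum(w * theta) / np.sum(w)
    q = float(np.sum(w * (theta - theta_fe) ** 2))
    df = k - 1
    p = float(stats.chi2.sf(q, df))
    return q, df, p


def i_squared(q_stat: float, q_df: int) -> float:
    """Higgins' I² in percent: max(0, (Q - df)/Q) * 100; 0 when Q = 0."""
    if q_df < 1:
        raise ValueError("I² requires q_df >= 1")
    if q_stat <= 0.0:
        return 0.0
    return max(0.0, (q_stat - q_df) / q_stat) * 100.0


def pool_random_dl(
    effects: Sequence[EffectEstimate], variant_id: str = "", stratum: str = ""
) -> MetaResult:
    """DerSimonian–Laird random-effects pool (k >= 2).

    τ² is the moment estimator max(0, (Q - df) / (Σw - Σw²/Σw)) with
    fixed-effects weights w; study weights then become 1/(se² + τ²).
    """
    if len(effects) < 2:
        raise ValueError("random-effects pooling requires at least two studies")
    theta, se = _arrays(effects)
    w = 1.0 / se**2
    q, q_df, q_p = cochran_q(effects)
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - q_df) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (se**2 + tau2)
    theta_hat = float(np.sum(w_star * theta) / np.sum(w_star))
    se_hat = float(np.sum(w_star) ** -0.5)
    return _build_result(
        theta_hat, se_hat, "random", len(effects), q, q_df, q_p,
        i_squared(q, q_df), tau2, variant_id, stratum,
    )


def select_model(i_squared_percent: float) -> str:
    """Random effects iff I² >= 50% (boundary inclusive), else fixed."""
    if not (0.0 <= i_squared_percent <= 100.0):
        raise ValueError(f"I² must be in [0, 100], got {i_squared_percent}")
    return "random" if i_squared_percent >= I2_RANDOM_THRESHOLD else "fixed"


def meta_analyze(
    effects: Sequence[EffectEstimate],
    variant_id: str = "",
    stratum: str = "",
    min_k: int = 3,
    model: str = "auto",
) -> MetaResult:
    """Q → I² → model switch → pool.

    ``min_k`` defaults to the synopsis eligibility floor of three
    independent datasets; sensitivity re-pools pass ``min_k=2``.
    ``model`` may force "fixed" or "random" (e.g. for decomposition
    checks); "auto" applies the I² switch.
    """
    if len(effects) < min_k:
        raise EligibilityError(
            f"{variant_id or 'variant'}: {len(effects)} datasets < required {min_k}"
        )
    if model not in ("auto", "fixed", "random"):
        raise ValueError(f"unknown model {model!r}")
    if len(effects) == 1:
        return pool_fixed(effects, variant_id, stratum)
    if model == "auto":
        q, q_df, _ = cochran_q(effects)
        model = select_model(i_squared(q, q_df))
    if model == "random":
        return pool_random_dl(effects, variant_id, stratum)
    return pool_fixed(effects, variant_id, stratum)


def subgroup_analysis(
    effects: Sequence[EffectEstimate],
    labels: Sequence[str],
    min_per_group: int = 2,
    variant_id: str = "",
    model: str = "auto",
) -> SubgroupResult:
    """Stratified pools plus between-subgroup Cochran's Q.

    Groups with fewer than ``min_per_group`` datasets are dropped.  The
    between-group statistic is Q_between = Σ_g w_g (θ̂_g − θ̄)² with
    w_g the inverse squared pooled SE of group g and θ̄ their weighted
    mean, referred to chi-square on (#groups − 1) df.
    """
    if len(effects) != len(labels):
        raise ValueError("labels must align one-to-one with effects")
    grouped: dict[str, list[EffectEstimate]] = {}
    for eff, lab in zip(effects, labels):
        grouped.setdefault(lab, []).append(eff)
    eligible = {
        lab: effs for lab, effs in grouped.items() if len(effs) >= min_per_group
    }
    if len(eligible) < 2:
        raise EligibilityError(
            f"subgroup analysis needs >= 2 strata with >= {min_per_group} datasets; "
            f"got {sorted(len(v) for v in grouped.values())}"
        )
    per_subgroup = {
        lab: meta_analyze(effs, variant_id, lab, min_k=min_per_group, model=model)
        for lab, effs in sorted(eligible.items())
    }
    est = np.array([r.pooled_log_or for r in per_subgroup.values()])
    w_g = np.array([r.pooled_se**-2 for r in per_subgroup.values()])
    grand = np.sum(w_g * est) / np.sum(w_g)
    q_between = float(np.sum(w_g * (est - grand) ** 2))
    df_between = len(per_subgroup) - 1
    p_interaction = float(stats.chi2.sf(q_between, df_between))
    return SubgroupResult(
        per_subgroup=per_subgroup,
        q_between=q_between,
        df_between=df_between,
        p_interaction=p_interaction,
    )


def meta_regression(
    effects: Sequence[EffectEstimate],
    covariate: Sequence[float],
    covariate_name: str = "covariate",
) -> MetaRegressionResult:
    """Weighted least squares of study log ORs on one covariate.

    Residual between-study variance is estimated by the method of
    moments from the fixed-effects-weighted residual Q, then studies are
    re-weighted by 1/(se² + τ̂²); the slope is tested with a Wald z.
    """
    k = len(effects)
    if k < 4:
        raise InsufficientDataError("meta-regression requires at least four studies")
    x = np.asarray(covariate, dtype=float)
    if x.shape != (k,):
        raise ValueError("covariate must align one-to-one with effects")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant; regression design is rank-deficient")
    theta, se = _arrays(effects)
    X = np.column_stack([np.ones(k), x])
    v = se**2
    w = 1.0 / v

    # Method-of-moments residual tau^2 from the FE-weighted fit.
    Wx = X * w[:, None]
    beta_fe = np.linalg.solve(X.T @ Wx, Wx.T @ theta)
    resid = theta - X @ beta_fe
    q_e = float(np.sum(w * resid**2))
    p = X.shape[1]
    xtwx_inv = np.linalg.inv(X.T @ Wx)
    trace_term = float(np.trace(xtwx_inv @ (X.T @ (X * (w**2)[:, None]))))
    denom = float(np.sum(w)) - trace_term
    tau2 = max(0.0, (q_e - (k - p)) / denom) if denom > 0 else 0.0

    w_star = 1.0 / (v + tau2)
    Wsx = X * w_star[:, None]
    cov = np.linalg.inv(X.T @ Wsx)
    beta = cov @ (Wsx.T @ theta)
    slope = float(beta[1])
    slope_se = float(math.sqrt(cov[1, 1]))
    p_value = float(2.0 * stats.norm.sf(abs(slope) / slope_se))
    return MetaRegressionResult(
        covariate=covariate_name,
        coefficient=slope,
        se=slope_se,
        p_value=p_value,
        tau_squared_residual=tau2,
    )
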