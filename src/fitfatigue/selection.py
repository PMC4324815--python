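"""Degrees-of-freedom accounting, goodness-of-fit and nested model tests.

The df convention counts, per model variant, the subject-specific gain
factors (one per rat per component) plus the shared time constants;
per-rat intercepts are excluded by default. For an 11-rat cohort this
gives 12, 24 and 36 model df for the one-, two- and three-component
models, with residual df N - df - 1 = 196, 184, 172 at N = 209
observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .impulse import Variant, as_variant


def model_df(variant, n_rats: int, count_intercepts: bool = False) -> int:
    """Model degrees of freedom: gains-per-rat * n_rats + shared taus.

    ``count_intercepts=True`` adds the per-rat intercepts p0 to the count
    (an alternative convention; off by default).
    """
    v = as_variant(variant)
    if n_rats < 1:
        raise ValueError("n_rats must be >= 1")
    df = v.n_gains * n_rats + v.n_taus
    if count_intercepts:
        df += n_rats
    return df


@dataclass(frozen=True)
class FitDiagnostics:
    """Pooled goodness-of-fit statistics for one fitted variant."""

    r2: float
    adj_r2: float
    f_ratio: float
    df_model: int
    df_resid: int
    p_value: float
    mse: float
    rmse: float


def fit_statistics(
    r2: float, df_model: int, n_obs: int, rss: float | None = None
) -> FitDiagnostics:
    """Diagnostics from a coefficient of determination and df counts.

    adj R^2 = 1 - (1 - R^2)(N - 1)/(N - df - 1);
    F = (R^2/df) / ((1 - R^2)/(N - df - 1)), referred to F(df, N - df - 1).
    ``mse`` (RSS/(N - df - 1)) and ``rmse`` require ``rss``; they are NaN
    when only R^2 is available.
    """
    df_resid = n_obs - df_model - 1
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom (N <= df + 1)")
    adj_r2 = 1.0 - (1.0 - r2) * (n_obs - 1) / df_resid
    if r2 >= 1.0:
        f_ratio, p = np.inf, 0.0
    else:
        f_ratio = (r2 / df_model) / ((1.0 - r2) / df_resid)
        p = float(stats.f.sf(f_ratio, df_model, df_resid))
    mse = rss / df_resid if rss is not None else float("nan")
    return FitDiagnostics(
        r2=float(r2),
        adj_r2=float(adj_r2),
        f_ratio=float(f_ratio),
        df_model=int(df_model),
        df_resid=int(df_resid),
        p_value=p,
        mse=float(mse),
        rmse=float(np.sqrt(mse)),
    )


def goodness_of_fit(fit, cohort, centering: str = "pooled") -> FitDiagnostics:
    """Diagnostics for a fit on its cohort.

    R^2 is computed as 1 - RSS/SStot with SStot about the pooled grand
    mean of all observed performances (``centering='pooled'``) or about
    each rat's own mean (``centering='per_rat'``).
    """
    p_all = np.concatenate([s.p_obs for s in cohort.rats])
    if centering == "pooled":
        sstot = float(np.sum((p_all - p_all.mean()) ** 2))
    elif centering == "per_rat":
        sstot = float(
            sum(np.sum((s.p_obs - s.p_obs.mean()) ** 2) for s in cohort.rats)
        )
    else:
        raise ValueError("centering must be 'pooled' or 'per_rat'")
    if sstot <= 0:
        raise ValueError("zero total variance: R^2 undefined")
    r2 = 1.0 - fit.rss / sstot
    return fit_statistics(r2, fit.df, cohort.N, rss=fit.rss)


@dataclass(frozen=True)
class NestedComparison:
    """F test of a richer model against a nested simpler one."""

    f_ratio: float
    df_num: int
    df_den: int
    p_value: float
    rss_small: float
    rss_large: float


_NESTING_ORDER = {
    Variant.ONE_COMP: 0,
    Variant.TWO_COMP: 1,
    Variant.THREE_COMP: 2,
}


def compare_nested(fit_small, fit_large, cohort) -> NestedComparison:
    """F = ((RSS_s - RSS_l)/(df_l - df_s)) / (RSS_l/(N - df_l - 1)).

    Raises if the richer model has a larger RSS — the models being
    nested, that signals a fitting failure rather than evidence.
    """
    if _NESTING_ORDER[fit_small.variant] >= _NESTING_ORDER[fit_large.variant]:
        raise ValueError("fit_small must be the lower-complexity variant")
    if fit_large.df <= fit_small.df:
        raise ValueError("richer model must have more degrees of freedom")
    if fit_large.rss > fit_small.rss * (1 + 1e-12):
        raise ValueError(
            "richer model has larger RSS than the nested one: "
            "fitting failure (warm-start the richer fit)"
        )
    df_num = fit_large.df - fit_small.df
    df_den = cohort.N - fit_large.df - 1
    if df_den <= 0:
        raise ValueError("no residual degrees of freedom for the richer model")
    if fit_large.rss == 0:
        f = np.inf if fit_small.rss > 0 else 0.0
    else:
        f = ((fit_small.rss - fit_large.rss) / df_num) / (
            fit_large.rss / df_den
        )
    f = max(f, 0.0)
    p = float(stats.f.sf(f, df_num, df_den)) if np.isfinite(f) else 0.0
    return NestedComparison(
        f_ratio=float(f),
        df_num=df_num,
        df_den=df_den,
        p_value=p if np.isfinite(f) else 0.0,
        rss_small=fit_small.rss,
        rss_large=fit_large.rss,
    )


def normality_check(values) -> tuple[float, float]:
    """Shapiro-Wilk W statistic and p-value for a sample.

    Requires 3..5000 values with non-zero variance.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3 or x.size > 5000:
        raise ValueError("Shapiro-Wilk requires between 3 and 5000 values")
    if np.ptp(x) == 0:
        raise ValueError("constant sequence: normality test undefined")
    w, p = stats.shapiro(x)
    return float(w), float(p)
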