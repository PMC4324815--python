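"""Pooled mixed-effects fitting of fitness-fatigue models.

All rats in a cohort share the model's time constants while each rat
gets its own intercept p0 and gain factors; the parameter set is chosen
to minimise the pooled residual sum of squares

    RSS = sum_r sum_n (p_r(n) - phat_r(n))^2

over all measured days of all rats.

The optimiser exploits that, for fixed time constants, every variant is
linear in (p0, gains): the inner problem is solved exactly per rat by
(bounded) linear least squares, and a multistart bounded quasi-Newton
search runs over the log time constants only (variable projection).
A joint bounded least-squares refit over the full parameter vector is
provided as a cross-check.
"""

from __future__ import annotations

import json
import warnings as _warnings
from dataclasses import dataclass, field, replace, asdict

import numpy as np
import pandas as pd
from scipy import optimize

from .impulse import (
    ModelParams,
    Variant,
    as_variant,
    exclusive_decay_sum,
    inclusive_decay_sum,
    predict,
)
from .quantification import TrainingSeries, sessions_by_rat, build_training_series
from .selection import (
    FitDiagnostics,
    NestedComparison,
    compare_nested,
    goodness_of_fit,
    model_df,
)


class UnderdeterminedError(ValueError):
    """Fewer observations per rat than free per-rat parameters."""


class FitError(RuntimeError):
    """No optimisation start converged; carries per-start diagnostics."""

    def __init__(self, message: str, start_log=None):
        super().__init__(message)
        self.start_log = start_log or []


@dataclass
class CohortData:
    """Training series of every rat in a cohort."""

    rats: list[TrainingSeries]

    def __post_init__(self) -> None:
        if not self.rats:
            raise ValueError("cohort must contain at least one rat")

    @property
    def R(self) -> int:
        return len(self.rats)

    @property
    def N(self) -> int:
        return int(sum(s.measured_days.size for s in self.rats))

    @property
    def n_per_rat(self) -> list[int]:
        return [s.measured_days.size for s in self.rats]

    @classmethod
    def from_sessions(cls, sessions, n_days: int | None = None) -> "CohortData":
        groups = sessions_by_rat(list(sessions))
        rats = [
            build_training_series(g, n_days=n_days) for g in groups.values()
        ]
        return cls(rats=rats)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, n_days: int | None = None) -> "CohortData":
        from .quantification import frame_to_sessions

        return cls.from_sessions(frame_to_sessions(df), n_days=n_days)


@dataclass(frozen=True)
class FitConfig:
    """Tunable knobs of the pooled fit.

    tau_bounds : (low, high) days for every shared time constant.
    gain_bounds : (low, high) s^-1 for every per-rat gain.
    p0_upper_factor : upper bound on p0 as a multiple of the largest
        observed performance (lower bound 0).
    n_starts : multistart count; starts are drawn log-uniformly in the
        tau box from ``seed``.
    """

    tau_bounds: tuple[float, float] = (0.5, 60.0)
    gain_bounds: tuple[float, float] = (0.0, 1.0)
    p0_upper_factor: float = 10.0
    n_starts: int = 25
    seed: int = 0
    ftol: float = 1e-10
    xtol: float = 1e-8
    max_iter: int = 200
    count_intercepts_in_df: bool = False
    third_component_sign: str = "plus"
    centering: str = "pooled"

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FitResult:
    """Outcome of one pooled fit (one variant, one cohort)."""

    variant: Variant
    shared: dict[str, float]
    per_rat: list[ModelParams]
    rss: float
    predictions: dict[str, np.ndarray]
    df: int
    n_obs: int
    converged: bool
    n_starts: int
    best_start_seed: int
    warnings: list[str] = field(default_factory=list)
    start_log: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "variant": self.variant.value,
            "shared": self.shared,
            "per_rat": [p.to_dict() for p in self.per_rat],
            "rss": self.rss,
            "df": self.df,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "n_starts": self.n_starts,
            "best_start_seed": self.best_start_seed,
            "warnings": self.warnings,
            "start_log": self.start_log,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def params_frame(self) -> pd.DataFrame:
        """Tidy per-rat parameter table (shared taus repeated per row)."""
        rows = []
        for rid, p in zip(self.rat_ids, self.per_rat):
            d = p.to_dict()
            d["rat_id"] = rid
            rows.append(d)
        return pd.DataFrame(rows)

    rat_ids: list[str] = field(default_factory=list)


_TAU_NAMES = {
    Variant.ONE_COMP: ("tau1",),
    Variant.TWO_COMP: ("tau1", "tau2"),
    Variant.THREE_COMP: ("tau1", "tau2", "tau3"),
}
_GAIN_NAMES = {
    Variant.ONE_COMP: ("k1",),
    Variant.TWO_COMP: ("k1", "k2"),
    Variant.THREE_COMP: ("k1", "k2_0", "k3"),
}


def _design_matrix(
    variant: Variant, taus: np.ndarray, w: np.ndarray, sign: str
) -> np.ndarray:
    """Columns [1, +fitness, -fatigue, (-/+)gain-filter] on every day.

    The coefficient vector is (p0, k1[, k2 | k2_0[, k3]]); column signs
    are arranged so all gains enter with their natural non-negative
    bounds.
    """
    n = len(w)
    cols = [np.ones(n), exclusive_decay_sum(w, taus[0])]
    if variant is not Variant.ONE_COMP:
        cols.append(-exclusive_decay_sum(w, taus[1]))
    if variant is Variant.THREE_COMP:
        c = inclusive_decay_sum(w, taus[2])
        d = exclusive_decay_sum(c * w, taus[1])
        cols.append(-d if sign == "plus" else d)
    return np.column_stack(cols)


def _params_from_coefs(
    variant: Variant, taus: np.ndarray, coefs: np.ndarray, sign: str
) -> ModelParams:
    kw = {"variant": variant, "p0": float(coefs[0]), "k1": float(coefs[1]),
          "tau1": float(taus[0]), "third_sign": sign}
    if variant is Variant.TWO_COMP:
        kw.update(k2=float(coefs[2]), tau2=float(taus[1]))
    elif variant is Variant.THREE_COMP:
        kw.update(
            tau2=float(taus[1]),
            k2_0=float(coefs[2]),
            k3=float(coefs[3]),
            tau3=float(taus[2]),
        )
    return ModelParams(**kw)


def _solve_rat(
    X: np.ndarray, y: np.ndarray, lb: np.ndarray, ub: np.ndarray
) -> np.ndarray:
    """Bounded linear least squares; fast unconstrained path first."""
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    eps = 1e-12
    if np.all(coef >= lb - eps) and np.all(coef <= ub + eps):
        return np.clip(coef, lb, ub)
    if np.all(lb == 0.0):
        coef, _ = optimize.nnls(X, y)
        if np.all(coef <= ub + eps):
            return np.minimum(coef, ub)
    res = optimize.lsq_linear(X, y, bounds=(lb, ub), method="bvls")
    return res.x


def _exclusive_decay_sum_batch(W: np.ndarray, tau: float) -> np.ndarray:
    """Row-wise exclusive decay sums for a stacked (R, n_days) w matrix."""
    a = np.exp(-1.0 / tau)
    out = np.empty_like(W)
    acc = np.zeros(W.shape[0])
    for n in range(W.shape[1]):
        out[:, n] = acc
        acc = a * (acc + W[:, n])
    return out


def _inclusive_decay_sum_batch(W: np.ndarray, tau: float) -> np.ndarray:
    a = np.exp(-1.0 / tau)
    out = np.empty_like(W)
    acc = np.zeros(W.shape[0])
    for n in range(W.shape[1]):
        acc = a * acc + W[:, n]
        out[:, n] = acc
    return out


class _Workspace:
    """Precomputed cohort layout for fast profiled-RSS evaluation.

    When every rat shares the same day grid and measured days (the usual
    cohort design), the inner linear solves are batched across rats;
    otherwise a per-rat loop is used.
    """

    def __init__(self, variant: Variant, cohort: CohortData,
                 lb: np.ndarray, ub: np.ndarray, sign: str):
        self.variant = variant
        self.cohort = cohort
        self.lb, self.ub = lb, ub
        self.sign = sign
        first = cohort.rats[0]
        self.uniform = all(
            s.n_days == first.n_days
            and np.array_equal(s.measured_days, first.measured_days)
            for s in cohort.rats
        )
        if self.uniform:
            self.W = np.vstack([s.w for s in cohort.rats])
            self.idx = first.measured_days - 1
            self.Y = np.vstack([s.p_obs for s in cohort.rats])

    def _design_batch(self, taus: np.ndarray) -> np.ndarray:
        """(R, n_measured, n_coef) stacked design tensor."""
        R, _ = self.W.shape
        cols = [
            np.ones((R, self.idx.size)),
            _exclusive_decay_sum_batch(self.W, taus[0])[:, self.idx],
        ]
        if self.variant is not Variant.ONE_COMP:
            cols.append(
                -_exclusive_decay_sum_batch(self.W, taus[1])[:, self.idx]
            )
        if self.variant is Variant.THREE_COMP:
            c = _inclusive_decay_sum_batch(self.W, taus[2])
            d = _exclusive_decay_sum_batch(c * self.W, taus[1])[:, self.idx]
            cols.append(-d if self.sign == "plus" else d)
        return np.stack(cols, axis=-1)

    def rss(self, taus: np.ndarray, return_coefs: bool = False):
        if not self.uniform:
            return _profiled_rss(
                self.variant, taus, self.cohort, self.lb, self.ub,
                self.sign, return_coefs=return_coefs,
            )
        X = self._design_batch(taus)
        G = np.einsum("rmc,rmd->rcd", X, X)
        b = np.einsum("rmc,rm->rc", X, self.Y)
        eps = 1e-12
        try:
            coefs = np.linalg.solve(G, b[..., None])[..., 0]
            bad = ~(
                np.all(coefs >= self.lb - eps, axis=1)
                & np.all(coefs <= self.ub + eps, axis=1)
            )
        except np.linalg.LinAlgError:
            coefs = np.zeros((X.shape[0], X.shape[2]))
            bad = np.ones(X.shape[0], dtype=bool)
        if bad.any():
            for r in np.flatnonzero(bad):
                coefs[r] = _solve_rat(X[r], self.Y[r], self.lb, self.ub)
        else:
            coefs = np.clip(coefs, self.lb, self.ub)
        resid = self.Y - np.einsum("rmc,rc->rm", X, coefs)
        total = float(np.sum(resid**2))
        if return_coefs:
            return total, list(coefs)
        return total


def pooled_rss(cohort: CohortData, params_per_rat: list[ModelParams]) -> float:
    """Pooled residual sum of squares (W^2) over measured days.

    Validates that all rats use the same variant and identical shared
    time constants.
    """
    if len(params_per_rat) != cohort.R:
        raise ValueError("need exactly one parameter set per rat")
    variants = {p.variant for p in params_per_rat}
    if len(variants) != 1:
        raise ValueError("mixed variants across rats")
    shared = {
        (p.tau1, p.tau2, p.tau3, p.third_sign) for p in params_per_rat
    }
    if len(shared) != 1:
        raise ValueError("shared time constants differ across rats")
    total = 0.0
    for series, p in zip(cohort.rats, params_per_rat):
        phat = predict(p, series)[series.measured_days - 1]
        total += float(np.sum((series.p_obs - phat) ** 2))
    return total


def _profiled_rss(
    variant: Variant,
    taus: np.ndarray,
    cohort: CohortData,
    bounds_lo: np.ndarray,
    bounds_hi: np.ndarray,
    sign: str,
    return_coefs: bool = False,
):
    total = 0.0
    coefs_all = []
    for series in cohort.rats:
        X_full = _design_matrix(variant, taus, series.w, sign)
        idx = series.measured_days - 1
        X = X_full[idx]
        coef = _solve_rat(X, series.p_obs, bounds_lo, bounds_hi)
        total += float(np.sum((series.p_obs - X @ coef) ** 2))
        if return_coefs:
            coefs_all.append(coef)
    if return_coefs:
        return total, coefs_all
    return total


def _draw_starts(
    variant: Variant, config: FitConfig, rng: np.random.Generator
) -> np.ndarray:
    lo, hi = np.log(config.tau_bounds[0]), np.log(config.tau_bounds[1])
    return np.exp(
        rng.uniform(lo, hi, size=(config.n_starts, variant.n_taus))
    )


def _warm_start_taus(
    variant: Variant, warm: "FitResult", config: FitConfig
) -> np.ndarray:
    """Time-constant start embedding a poorer fit into a richer variant.

    Any value for the extra time constants works: the inner linear solve
    may set the extra gains to zero, so the profiled RSS at this start is
    never worse than the poorer fit's RSS.
    """
    lo, hi = config.tau_bounds
    taus = [warm.shared[name] for name in _TAU_NAMES[warm.variant]]
    while len(taus) < variant.n_taus:
        taus.append(float(np.clip(np.sqrt(lo * hi), lo, hi)))
    return np.clip(np.array(taus[: variant.n_taus]), lo, hi)


def fit_model(
    cohort: CohortData,
    variant,
    config: FitConfig | None = None,
    warm_start: "FitResult | None" = None,
) -> FitResult:
    """Fit one model variant to a whole cohort by pooled least squares.

    ``warm_start`` injects a nested poorer fit's solution as an extra
    multistart point, which guarantees the richer fit's RSS does not
    exceed the poorer one's.
    """
    variant = as_variant(variant)
    config = config or FitConfig()
    n_coef = 1 + variant.n_gains
    min_obs = min(cohort.n_per_rat)
    if min_obs < n_coef:
        raise UnderdeterminedError(
            f"{variant.value} needs >= {n_coef} observations per rat, "
            f"got a rat with {min_obs}"
        )

    p_max = max(float(s.p_obs.max()) for s in cohort.rats)
    lb = np.array([0.0] + [config.gain_bounds[0]] * variant.n_gains)
    ub = np.array(
        [config.p0_upper_factor * p_max]
        + [config.gain_bounds[1]] * variant.n_gains
    )
    sign = config.third_component_sign

    rng = np.random.default_rng(config.seed)
    starts = list(_draw_starts(variant, config, rng))
    if warm_start is not None:
        if _TAU_NAMES[warm_start.variant] == _TAU_NAMES[variant] or len(
            _TAU_NAMES[warm_start.variant]
        ) < len(_TAU_NAMES[variant]):
            starts.append(_warm_start_taus(variant, warm_start, config))
        else:
            raise ValueError("warm_start must be the same or a nested variant")

    log_bounds = [np.log(config.tau_bounds)] * variant.n_taus
    workspace = _Workspace(variant, cohort, lb, ub, sign)

    def objective(log_taus: np.ndarray) -> float:
        return workspace.rss(np.exp(log_taus))

    best = None
    start_log: list[dict] = []
    for i, taus0 in enumerate(starts):
        x0 = np.log(taus0)
        f0 = objective(x0)
        try:
            res = optimize.minimize(
                objective,
                x0,
                method="L-BFGS-B",
                bounds=log_bounds,
                options={
                    "ftol": config.ftol,
                    "gtol": 1e-12,
                    "maxiter": config.max_iter,
                },
            )
            fval, x, ok = min(res.fun, f0), res.x, bool(res.success)
            if f0 < res.fun:
                x = x0
        except Exception as exc:  # pragma: no cover - optimizer blowup
            start_log.append(
                {"start": i, "taus0": list(map(float, taus0)),
                 "rss": None, "converged": False, "error": str(exc)}
            )
            continue
        start_log.append(
            {"start": i, "taus0": list(map(float, taus0)),
             "rss": float(fval), "converged": ok}
        )
        if best is None or fval < best[0] - 0.0:
            best = (fval, x, i, ok)

    if best is None:
        raise FitError("no optimisation start succeeded", start_log)

    _, x_best, i_best, converged = best
    taus = np.exp(x_best)
    _, coefs = workspace.rss(taus, return_coefs=True)

    per_rat = [
        _params_from_coefs(variant, taus, c, sign) for c in coefs
    ]
    rat_ids = [s.rat_id for s in cohort.rats]
    predictions = {}
    fit_warnings: list[str] = []
    for series, p in zip(cohort.rats, per_rat):
        phat = predict(p, series)
        predictions[series.rat_id] = phat[series.measured_days - 1]
        X = _design_matrix(variant, taus, series.w, sign)[
            series.measured_days - 1
        ]
        dead = np.where(np.linalg.norm(X[:, 1:], axis=0) < 1e-12)[0]
        for j in dead:
            fit_warnings.append(
                f"rat {series.rat_id}: gain "
                f"{_GAIN_NAMES[variant][j]} unidentifiable (zero regressor)"
            )

    # RSS recomputed from the returned parameters so the reported value is
    # self-consistent with `pooled_rss` (identical to the profiled value for
    # the plus sign convention; under 'minus' the k2 floor may bind).
    rss = pooled_rss(cohort, per_rat)

    shared = {
        name: float(t) for name, t in zip(_TAU_NAMES[variant], taus)
    }
    return FitResult(
        variant=variant,
        shared=shared,
        per_rat=per_rat,
        rss=rss,
        predictions=predictions,
        df=model_df(variant, cohort.R, config.count_intercepts_in_df),
        n_obs=cohort.N,
        converged=converged,
        n_starts=len(starts),
        best_start_seed=i_best,
        warnings=fit_warnings,
        start_log=start_log,
        rat_ids=rat_ids,
    )


def joint_refit(
    cohort: CohortData, fit: FitResult, config: FitConfig | None = None
) -> tuple[float, np.ndarray]:
    """Cross-check: joint bounded least squares over the full vector.

    Starts from a variable-projection solution and returns (rss, x) of
    the joint optimum; used to confirm the profiled search did not stop
    short of a joint local minimum.
    """
    config = config or FitConfig()
    variant = fit.variant
    sign = config.third_component_sign
    n_taus, n_coef = variant.n_taus, 1 + variant.n_gains
    p_max = max(float(s.p_obs.max()) for s in cohort.rats)

    taus0 = np.array([fit.shared[n] for n in _TAU_NAMES[variant]])
    coefs0 = []
    for p in fit.per_rat:
        c = [p.p0, p.k1]
        if variant is Variant.TWO_COMP:
            c.append(p.k2)
        elif variant is Variant.THREE_COMP:
            c.extend([p.k2_0, p.k3])
        coefs0.append(c)
    x0 = np.concatenate([np.log(taus0), np.ravel(coefs0)])

    lo = np.concatenate(
        [np.full(n_taus, np.log(config.tau_bounds[0])),
         np.tile([0.0] + [config.gain_bounds[0]] * variant.n_gains, cohort.R)]
    )
    hi = np.concatenate(
        [np.full(n_taus, np.log(config.tau_bounds[1])),
         np.tile(
             [config.p0_upper_factor * p_max]
             + [config.gain_bounds[1]] * variant.n_gains,
             cohort.R,
         )]
    )

    def residuals(x):
        taus = np.exp(x[:n_taus])
        out = []
        for r, series in enumerate(cohort.rats):
            coef = x[n_taus + r * n_coef: n_taus + (r + 1) * n_coef]
            X = _design_matrix(variant, taus, series.w, sign)[
                series.measured_days - 1
            ]
            out.append(series.p_obs - X @ coef)
        return np.concatenate(out)

    res = optimize.least_squares(
        residuals, np.clip(x0, lo, hi), bounds=(lo, hi), method="trf",
        xtol=config.xtol, ftol=config.ftol,
    )
    return float(np.sum(res.fun**2)), res.x


# ---------------------------------------------------------------------------
# statsmodels-style front end


class FitnessFatigueModel:
    """Fitness-fatigue systems model for a cohort of trained animals.

    Parameters
    ----------
    cohort : CohortData
        One daily training series per animal.
    variant : str or Variant
        ``"1comp"``, ``"2comp"`` (default) or ``"3comp"``.
    config : FitConfig, optional
        Optimiser and convention settings.

    Examples
    --------
    >>> model = FitnessFatigueModel(cohort, variant="2comp")
    >>> results = model.fit()
    >>> print(results.summary())
    """

    def __init__(self, cohort: CohortData, variant="2comp",
                 config: FitConfig | None = None):
        self.cohort = cohort
        self.variant = as_variant(variant)
        self.config = config or FitConfig()

    @classmethod
    def from_sessions(cls, sessions, variant="2comp",
                      config: FitConfig | None = None,
                      n_days: int | None = None) -> "FitnessFatigueModel":
        return cls(CohortData.from_sessions(sessions, n_days=n_days),
                   variant=variant, config=config)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, variant="2comp",
                       config: FitConfig | None = None,
                       n_days: int | None = None) -> "FitnessFatigueModel":
        """Build from a tidy session-log frame (see quantification)."""
        return cls(CohortData.from_dataframe(df, n_days=n_days),
                   variant=variant, config=config)

    def fit(self, warm_start: "FitnessFatigueResults | None" = None,
            **overrides) -> "FitnessFatigueResults":
        """Run the pooled multistart fit and wrap it in a Results object."""
        config = replace(self.config, **overrides) if overrides else self.config
        warm = warm_start._fit if warm_start is not None else None
        fit = fit_model(self.cohort, self.variant, config, warm_start=warm)
        return FitnessFatigueResults(self, fit, config)


class FitnessFatigueResults:
    """Estimates, diagnostics and derived analyses of one pooled fit."""

    def __init__(self, model: FitnessFatigueModel, fit: FitResult,
                 config: FitConfig):
        self.model = model
        self._fit = fit
        self.config = config

    # -- plain accessors -------------------------------------------------
    @property
    def variant(self) -> Variant:
        return self._fit.variant

    @property
    def rss(self) -> float:
        return self._fit.rss

    @property
    def taus(self) -> dict[str, float]:
        return dict(self._fit.shared)

    @property
    def params_per_rat(self) -> list[ModelParams]:
        return list(self._fit.per_rat)

    @property
    def df_model(self) -> int:
        return self._fit.df

    @property
    def df_resid(self) -> int:
        return self._fit.n_obs - self._fit.df - 1

    @property
    def converged(self) -> bool:
        return self._fit.converged

    @property
    def fit_result(self) -> FitResult:
        return self._fit

    # -- diagnostics -----------------------------------------------------
    def diagnostics(self, centering: str | None = None) -> FitDiagnostics:
        return goodness_of_fit(
            self._fit, self.model.cohort,
            centering=centering or self.config.centering,
        )

    def compare(self, other: "FitnessFatigueResults") -> NestedComparison:
        """Nested F test against another variant fitted on the same cohort."""
        pair = sorted([self, other], key=lambda r: r.df_model)
        return compare_nested(
            pair[0]._fit, pair[1]._fit, self.model.cohort
        )

    def predict(self, series: TrainingSeries | None = None) -> dict:
        """Daily predicted performance per rat (or for one new series)."""
        if series is not None:
            # use the cohort-mean gains for an out-of-sample series
            raise NotImplementedError(
                "per-rat parameters are subject-specific; predict per rat "
                "via fitfatigue.impulse.predict(params, series)"
            )
        return {
            s.rat_id: predict(p, s)
            for s, p in zip(self.model.cohort.rats, self._fit.per_rat)
        }

    # -- derived analyses (two-component only) ----------------------------
    def response_characteristics(self) -> pd.DataFrame:
        from .response import cohort_response_summary

        return cohort_response_summary(self._fit)

    def influence_summary(self) -> pd.DataFrame:
        from .response import cohort_influence_summary

        return cohort_influence_summary(self._fit, self.model.cohort)

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        d = self.diagnostics()
        lines = [
            "Fitness-fatigue model fit (pooled least squares)",
            "=" * 52,
            f"variant:       {self.variant.value}",
            f"rats:          {self.model.cohort.R}",
            f"observations:  {self._fit.n_obs}",
            f"model df:      {d.df_model}   residual df: {d.df_resid}",
            f"RSS:           {self.rss:.6g} W^2",
            f"R^2:           {d.r2:.4f}   adj R^2: {d.adj_r2:.4f}",
            f"F({d.df_model}, {d.df_resid}) = {d.f_ratio:.3f}, "
            f"p = {d.p_value:.3g}",
            f"MSE: {d.mse:.4g} W^2   RMSE: {d.rmse:.4g} W",
            "-" * 52,
            "shared time constants (days):",
        ]
        for name, val in self._fit.shared.items():
            lines.append(f"  {name} = {val:.4g}")
        lines.append("per-rat parameters:")
        frame = self._fit.params_frame()
        gain_cols = ["rat_id", "p0"] + [
            c for c in ("k1", "k2", "k2_0", "k3") if frame[c].notna().any()
        ]
        lines.append(frame[gain_cols].to_string(index=False,
                                                float_format="%.5g"))
        if self._fit.warnings:
            lines.append("warnings:")
            lines.extend(f"  {w}" for w in self._fit.warnings)
        return "\n".join(lines)

    def save(self, path) -> None:
        self._fit.to_json(path)
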