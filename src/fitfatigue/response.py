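"""Response characteristics and influence decomposition (two-component model).

After a single training bout the two-component response first dips below
baseline (when k2 > k1), recovers at

    tn = tau1*tau2/(tau1 - tau2) * ln(k2/k1),

peaks at

    tg = tau1*tau2/(tau1 - tau2) * ln(tau1*k2/(tau2*k1)),

and the maximal gain for one unit of training is

    pg = k1*exp(-tg/tau1) - k2*exp(-tg/tau2).

For a full training series, the contribution of day i's dose to day n's
performance,

    E(i, n) = k1*w_i*exp(-(n-i)/tau1) - k2*w_i*exp(-(n-i)/tau2),

is summed per day over its negative terms (in, the fatigue index) and
positive terms (ip, the adaptation index); ip + in recovers the
predicted performance change from baseline exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .impulse import ModelParams, Variant, predict_2comp
from .quantification import TrainingSeries


@dataclass(frozen=True)
class ResponseCharacteristics:
    """Single-bout response summary; NaN where undefined.

    ``tn_defined``/``tg_defined`` flag whether the formulas yield a
    physically meaningful (non-negative time) value for the given
    parameters; e.g. with tau1 > tau2 and k2 < k1 the response never
    dips below baseline, so tn does not exist.
    """

    tn: float
    tg: float
    pg: float
    tn_defined: bool
    tg_defined: bool


def response_characteristics(
    k1: float, tau1: float, k2: float, tau2: float
) -> ResponseCharacteristics:
    """tn, tg, pg of the unit-impulse two-component response."""
    for name, v in (("k1", k1), ("tau1", tau1), ("k2", k2), ("tau2", tau2)):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    if tau1 == tau2:
        raise ValueError("tau1 == tau2: response formulas are singular")
    factor = tau1 * tau2 / (tau1 - tau2)
    tn = factor * np.log(k2 / k1)
    tg = factor * np.log(tau1 * k2 / (tau2 * k1))
    tn_ok = np.isfinite(tn) and tn >= 0
    tg_ok = np.isfinite(tg) and tg >= 0
    if tg_ok:
        pg = k1 * np.exp(-tg / tau1) - k2 * np.exp(-tg / tau2)
    else:
        pg = np.nan
    return ResponseCharacteristics(
        tn=float(tn) if tn_ok else float("nan"),
        tg=float(tg) if tg_ok else float("nan"),
        pg=float(pg),
        tn_defined=bool(tn_ok),
        tg_defined=bool(tg_ok),
    )


@dataclass
class InfluenceSeries:
    """Daily summed negative (in <= 0) and positive (ip >= 0) influences."""

    rat_id: str
    day: np.ndarray
    in_n: np.ndarray
    ip_n: np.ndarray


def influence_decomposition(
    params: ModelParams, series: TrainingSeries
) -> InfluenceSeries:
    """Per-day positive/negative influence sums, term-by-term.

    Each (i, n) contribution is classified by its own sign, as opposed
    to classifying whole days.
    """
    if params.variant is not Variant.TWO_COMP:
        raise ValueError("influence decomposition is defined for 2comp")
    w = np.asarray(series.w, dtype=float)
    n_days = len(w)
    days = np.arange(1, n_days + 1)
    # E[i-1, n-1] = contribution of day i's training to day n (i < n)
    lag = days[None, :] - days[:, None]  # n - i
    with np.errstate(over="ignore"):
        e = (
            params.k1 * w[:, None] * np.exp(-lag / params.tau1)
            - params.k2 * w[:, None] * np.exp(-lag / params.tau2)
        )
    e = np.where(lag >= 1, e, 0.0)
    in_n = np.where(e < 0, e, 0.0).sum(axis=0)
    ip_n = np.where(e > 0, e, 0.0).sum(axis=0)
    return InfluenceSeries(rat_id=series.rat_id, day=days, in_n=in_n, ip_n=ip_n)


def cohort_response_summary(fit) -> pd.DataFrame:
    """Per-rat tn/tg/pg plus a cohort mean +/- SD row.

    Rats whose parameters leave tn or tg undefined contribute NaN to
    those columns and are skipped by the mean/SD (which use the rats
    with defined values).
    """
    if fit.variant is not Variant.TWO_COMP:
        raise ValueError("response characteristics require a 2comp fit")
    rows = []
    for rid, p in zip(fit.rat_ids, fit.per_rat):
        try:
            rc = response_characteristics(p.k1, p.tau1, p.k2, p.tau2)
            rows.append(
                {"rat_id": rid, "tn_days": rc.tn, "tg_days": rc.tg,
                 "pg_watts": rc.pg}
            )
        except ValueError:
            rows.append(
                {"rat_id": rid, "tn_days": np.nan, "tg_days": np.nan,
                 "pg_watts": np.nan}
            )
    df = pd.DataFrame(rows)
    stats = pd.DataFrame(
        [
            {"rat_id": "mean", **df[["tn_days", "tg_days", "pg_watts"]]
             .mean(skipna=True).to_dict()},
            {"rat_id": "sd", **df[["tn_days", "tg_days", "pg_watts"]]
             .std(ddof=1, skipna=True).to_dict()},
        ]
    )
    return pd.concat([df, stats], ignore_index=True)


def cohort_influence_summary(fit, cohort) -> pd.DataFrame:
    """Per-day mean +/- SEM of ip and in across the cohort's rats."""
    if fit.variant is not Variant.TWO_COMP:
        raise ValueError("influence summary requires a 2comp fit")
    per_rat = [
        influence_decomposition(p, s)
        for p, s in zip(fit.per_rat, cohort.rats)
    ]
    n_days = max(len(x.day) for x in per_rat)
    ip = np.full((len(per_rat), n_days), np.nan)
    in_ = np.full((len(per_rat), n_days), np.nan)
    for r, x in enumerate(per_rat):
        ip[r, : len(x.day)] = x.ip_n
        in_[r, : len(x.day)] = x.in_n
    R = len(per_rat)
    sem = (
        lambda a: np.nanstd(a, axis=0, ddof=1) / np.sqrt(R)
        if R > 1
        else np.full(n_days, np.nan)
    )
    return pd.DataFrame(
        {
            "day": np.arange(1, n_days + 1),
            "ip_mean": np.nanmean(ip, axis=0),
            "ip_sem": sem(ip),
            "in_mean": np.nanmean(in_, axis=0),
            "in_sem": sem(in_),
        }
    )


def influence_frame(fit, cohort) -> pd.DataFrame:
    """Tidy per-rat per-day influence table."""
    frames = []
    for p, s in zip(fit.per_rat, cohort.rats):
        x = influence_decomposition(p, s)
        frames.append(
            pd.DataFrame(
                {"rat_id": x.rat_id, "day": x.day,
                 "ip_watts": x.ip_n, "in_watts": x.in_n}
            )
        )
    return pd.concat(frames, ignore_index=True)


def plot_influence(summary: pd.DataFrame, path) -> None:
    """Cohort influence curves (mean +/- SEM) saved to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for col, label, color in (
        ("ip_mean", "positive influence (ip)", "tab:blue"),
        ("in_mean", "negative influence (in)", "tab:red"),
    ):
        sem_col = col.replace("mean", "sem")
        ax.plot(summary["day"], summary[col], label=label, color=color)
        if summary[sem_col].notna().any():
            ax.fill_between(
                summary["day"],
                summary[col] - summary[sem_col],
                summary[col] + summary[sem_col],
                alpha=0.25,
                color=color,
                linewidth=0,
            )
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("day")
    ax.set_ylabel("influence on performance (W)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
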