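"""Forward simulation of fitness-fatigue impulse-response models.

Three nested variants map a daily training-impulse series ``w`` to
predicted performance on day ``n`` (all sums run over days strictly
before ``n``; w(0) = 0 by convention):

* one component (adaptation only)::

      p(n) = p0 + k1 * sum_i w_i exp(-(n-i)/tau1)

* two components (the classic Banister model: adaptation minus fatigue)::

      p(n) = p0 + k1 * sum_i w_i exp(-(n-i)/tau1)
                - k2 * sum_i w_i exp(-(n-i)/tau2)

* three components, where the fatigue gain k2 itself responds to
  accumulated training through a first-order filter with gain k3 and
  time constant tau3::

      dk2(i) = k3 * sum_{j<=i} w_j exp(-(i-j)/tau3)
      k2(i)  = k2_0 + dk2(i)        (default sign convention)
      p(n)   = p0 + k1 * sum_i w_i exp(-(n-i)/tau1)
                  - sum_i k2(i) w_i exp(-(n-i)/tau2)

The ``minus`` sign convention, k2(i) = k2_0 - dk2(i) floored at zero, is
available via ``ModelParams.third_sign`` (the flooring prevents the
fatigue gain from turning into an adaptation gain).

Two evaluators ship for every variant: an O(n) recursive one (default)
and a direct O(n^2) summation used as an independent oracle in tests.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, asdict
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .quantification import TrainingSeries


class Variant(str, enum.Enum):
    """Model variant: number of impulse-response components."""

    ONE_COMP = "1comp"
    TWO_COMP = "2comp"
    THREE_COMP = "3comp"

    @property
    def n_gains(self) -> int:
        """Per-rat gain factors (excludes the intercept p0)."""
        return {"1comp": 1, "2comp": 2, "3comp": 3}[self.value]

    @property
    def n_taus(self) -> int:
        """Shared time constants."""
        return {"1comp": 1, "2comp": 2, "3comp": 3}[self.value]


def as_variant(v) -> Variant:
    if isinstance(v, Variant):
        return v
    try:
        return Variant(str(v).lower())
    except ValueError:
        raise ValueError(f"unknown model variant {v!r}") from None


@dataclass(frozen=True)
class ModelParams:
    """Parameter set of one rat for one model variant.

    Gains ``k*`` are in W/J (s^-1); time constants ``tau*`` in days;
    ``p0`` in W. Fields irrelevant to the variant must be left None.
    """

    variant: Variant
    p0: float
    k1: float
    tau1: float
    k2: float | None = None
    tau2: float | None = None
    k2_0: float | None = None
    k3: float | None = None
    tau3: float | None = None
    third_sign: str = "plus"

    def __post_init__(self) -> None:
        object.__setattr__(self, "variant", as_variant(self.variant))
        v = self.variant
        needed = {"p0", "k1", "tau1"}
        if v is Variant.TWO_COMP:
            needed |= {"k2", "tau2"}
        elif v is Variant.THREE_COMP:
            needed |= {"tau2", "k2_0", "k3", "tau3"}
        missing = sorted(n for n in needed if getattr(self, n) is None)
        if missing:
            raise ValueError(
                f"{v.value} requires parameter(s): {', '.join(missing)}"
            )
        for name in ("tau1", "tau2", "tau3"):
            val = getattr(self, name)
            if val is not None and name in needed and val <= 0:
                raise ValueError(f"time constant {name} must be positive")
        if self.third_sign not in ("plus", "minus"):
            raise ValueError("third_sign must be 'plus' or 'minus'")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["variant"] = self.variant.value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


def _require(params: ModelParams, variant: Variant) -> None:
    if params.variant is not variant:
        raise ValueError(
            f"params are for {params.variant.value}, expected {variant.value}"
        )


# ---------------------------------------------------------------------------
# Recursive building blocks

def exclusive_decay_sum(w: np.ndarray, tau: float) -> np.ndarray:
    """s(n) = sum_{i=1}^{n-1} w_i exp(-(n-i)/tau) for n = 1..len(w).

    Computed by the first-order recursion s(n) = a*(s(n-1) + w_{n-1}),
    a = exp(-1/tau); s(1) = 0. Day n maps to index n-1.
    """
    w = np.asarray(w, dtype=float)
    a = np.exp(-1.0 / tau)
    out = np.empty_like(w)
    acc = 0.0
    for n in range(len(w)):
        out[n] = acc
        acc = a * (acc + w[n])
    return out


def inclusive_decay_sum(w: np.ndarray, tau: float) -> np.ndarray:
    """c(i) = sum_{j=1}^{i} w_j exp(-(i-j)/tau) for i = 1..len(w)."""
    w = np.asarray(w, dtype=float)
    a = np.exp(-1.0 / tau)
    out = np.empty_like(w)
    acc = 0.0
    for i in range(len(w)):
        acc = a * acc + w[i]
        out[i] = acc
    return out


# ---------------------------------------------------------------------------
# Direct O(n^2) oracles (kept deliberately naive)

def exclusive_decay_sum_direct(w, tau: float) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    n_days = len(w)
    out = np.zeros(n_days)
    for n in range(1, n_days + 1):  # day n
        total = 0.0
        for i in range(1, n):  # strictly earlier days
            total += w[i - 1] * np.exp(-(n - i) / tau)
        out[n - 1] = total
    return out


def inclusive_decay_sum_direct(w, tau: float) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    n_days = len(w)
    out = np.zeros(n_days)
    for i in range(1, n_days + 1):
        total = 0.0
        for j in range(1, i + 1):
            total += w[j - 1] * np.exp(-(i - j) / tau)
        out[i - 1] = total
    return out


# ---------------------------------------------------------------------------
# Predictors

def predict_1comp(
    params: ModelParams, series: "TrainingSeries", direct: bool = False
) -> np.ndarray:
    """Predicted performance on every day for the one-component model."""
    _require(params, Variant.ONE_COMP)
    f = exclusive_decay_sum_direct if direct else exclusive_decay_sum
    return params.p0 + params.k1 * f(series.w, params.tau1)


def predict_2comp(
    params: ModelParams, series: "TrainingSeries", direct: bool = False
) -> np.ndarray:
    """Predicted performance for the two-component (Banister) model."""
    _require(params, Variant.TWO_COMP)
    f = exclusive_decay_sum_direct if direct else exclusive_decay_sum
    return (
        params.p0
        + params.k1 * f(series.w, params.tau1)
        - params.k2 * f(series.w, params.tau2)
    )


def k2_series(
    params: ModelParams, series: "TrainingSeries", direct: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Per-day fatigue-gain filter output (dk2(i), k2(i)).

    The combination of k2_0 with dk2 follows ``params.third_sign``;
    under the minus convention k2 is floored at zero.
    """
    _require(params, Variant.THREE_COMP)
    f = inclusive_decay_sum_direct if direct else inclusive_decay_sum
    dk2 = params.k3 * f(series.w, params.tau3)
    if params.third_sign == "plus":
        k2 = params.k2_0 + dk2
    else:
        k2 = np.maximum(params.k2_0 - dk2, 0.0)
    return dk2, k2


def predict_3comp(
    params: ModelParams, series: "TrainingSeries", direct: bool = False
) -> np.ndarray:
    """Predicted performance for the time-varying-fatigue-gain model."""
    _require(params, Variant.THREE_COMP)
    _, k2 = k2_series(params, series, direct=direct)
    w = np.asarray(series.w, dtype=float)
    if direct:
        n_days = len(w)
        fatigue = np.zeros(n_days)
        for n in range(1, n_days + 1):
            total = 0.0
            for i in range(1, n):
                total += k2[i - 1] * w[i - 1] * np.exp(-(n - i) / params.tau2)
            fatigue[n - 1] = total
        fitness = exclusive_decay_sum_direct(w, params.tau1)
    else:
        fatigue = exclusive_decay_sum(k2 * w, params.tau2)
        fitness = exclusive_decay_sum(w, params.tau1)
    return params.p0 + params.k1 * fitness - fatigue


_PREDICTORS = {
    Variant.ONE_COMP: predict_1comp,
    Variant.TWO_COMP: predict_2comp,
    Variant.THREE_COMP: predict_3comp,
}


def predict(
    params: ModelParams, series: "TrainingSeries", direct: bool = False
) -> np.ndarray:
    """Dispatch to the variant's predictor; returns one value per day."""
    return _PREDICTORS[params.variant](params, series, direct=direct)
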