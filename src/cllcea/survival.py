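"""Parametric survival extrapolation for digitized Kaplan-Meier curves.

Decision-analytic models of treatment sequencing need survival functions
over the full model horizon, but published trial follow-up is short.  The
standard workflow fits a parametric family to coordinates read off a
published Kaplan-Meier plot and extrapolates.  This module implements that
workflow for the Weibull family (and its exponential special case):

* :class:`KMCurvePoints` — validated (time, survival) coordinates,
* :func:`fit_parametric` — ordinary least squares on the complementary
  log-log linearization ``ln(-ln S) = k ln t - k ln lambda``,
* :func:`per_cycle_event_prob` — conversion of a fitted curve into
  time-dependent per-cycle transition probabilities
  ``p_i = 1 - S((i+1) dt) / S(i dt)``,
* :func:`pfs_os_decompose` — splitting a PFS event probability into
  progression and death using a companion overall-survival model.

Times are in months throughout.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

FAMILIES = ("weibull", "exponential")


class InsufficientDataError(ValueError):
    """Raised when too few usable points remain for a parametric fit."""


@dataclass(frozen=True)
class KMCurvePoints:
    """Digitized Kaplan-Meier coordinates.

    Parameters
    ----------
    time : array-like
        Time in months, non-negative and strictly increasing.
    survival : array-like
        Survival fractions in ``[0, 1]``, non-increasing.
    n_at_risk : array-like, optional
        Number at risk at each time, when known.
    """

    time: np.ndarray
    survival: np.ndarray
    n_at_risk: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        s = np.asarray(self.survival, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "survival", s)
        if t.ndim != 1 or s.shape != t.shape:
            raise ValueError("time and survival must be 1-d arrays of equal length")
        if t.size == 0:
            raise ValueError("curve must contain at least one point")
        if np.any(t < 0):
            raise ValueError("times must be non-negative")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any((s < 0) | (s > 1)):
            raise ValueError("survival values must lie in [0, 1]")
        if np.any(np.diff(s) > 0):
            raise ValueError("survival values must be non-increasing")
        if self.n_at_risk is not None:
            n = np.asarray(self.n_at_risk, dtype=float)
            if n.shape != t.shape:
                raise ValueError("n_at_risk must match time in length")
            object.__setattr__(self, "n_at_risk", n)

    def __len__(self) -> int:
        return self.time.size

    @classmethod
    def from_csv(cls, path: str | Path) -> "KMCurvePoints":
        """Read a curve from CSV with columns ``time_months,survival[,n_at_risk]``."""
        df = pd.read_csv(path)
        missing = {"time_months", "survival"} - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing required columns {sorted(missing)}")
        n = df["n_at_risk"].to_numpy() if "n_at_risk" in df.columns else None
        return cls(df["time_months"].to_numpy(), df["survival"].to_numpy(), n)

    def to_csv(self, path: str | Path) -> None:
        data = {"time_months": self.time, "survival": self.survival}
        if self.n_at_risk is not None:
            data["n_at_risk"] = self.n_at_risk
        pd.DataFrame(data).to_csv(path, index=False)


@dataclass(frozen=True)
class ParametricSurvivalModel:
    """A fitted Weibull or exponential survival function.

    ``S(t) = exp(-(t / scale) ** shape)`` with shape ``k`` and scale
    ``lambda`` in months; the exponential family fixes ``shape = 1`` so the
    scale is the reciprocal of the constant hazard.  ``coef_covariance`` is
    the 2x2 covariance of ``(ln shape, ln scale)`` from the fit and feeds
    probabilistic sensitivity analysis.
    """

    family: str
    shape: float
    scale: float
    coef_covariance: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if not self.shape > 0:
            raise ValueError("shape must be positive")
        if not self.scale > 0:
            raise ValueError("scale must be positive")
        if self.family == "exponential" and not np.isclose(self.shape, 1.0):
            raise ValueError("exponential family requires shape == 1")
        if self.coef_covariance is not None:
            cov = np.asarray(self.coef_covariance, dtype=float)
            if cov.shape != (2, 2):
                raise ValueError("coef_covariance must be 2x2")
            if not np.allclose(cov, cov.T, atol=1e-10):
                raise ValueError("coef_covariance must be symmetric")
            if np.any(np.linalg.eigvalsh(0.5 * (cov + cov.T)) < -1e-10):
                raise ValueError("coef_covariance must be positive semi-definite")
            object.__setattr__(self, "coef_covariance", cov)

    def survival(self, t) -> np.ndarray | float:
        """Evaluate ``S(t)``; ``t`` in months, scalar or array, must be >= 0."""
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise ValueError("t must be non-negative")
        out = np.exp(-((t_arr / self.scale) ** self.shape))
        return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out

    def median(self) -> float:
        """Median survival time ``scale * ln(2)**(1/shape)`` in months."""
        return self.scale * np.log(2.0) ** (1.0 / self.shape)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "shape": float(self.shape),
            "scale": float(self.scale),
            "coef_covariance": None
            if self.coef_covariance is None
            else np.asarray(self.coef_covariance).tolist(),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ParametricSurvivalModel":
        cov = data.get("coef_covariance")
        return cls(
            family=data["family"],
            shape=float(data["shape"]),
            scale=float(data["scale"]),
            coef_covariance=None if cov is None else np.asarray(cov, dtype=float),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "ParametricSurvivalModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_parametric(points: KMCurvePoints, family: str = "weibull") -> ParametricSurvivalModel:
    """Fit a parametric survival model to digitized KM coordinates.

    Uses OLS on the complementary log-log linearization: for a Weibull,
    ``ln(-ln S(t)) = k ln t - k ln lambda`` is linear in ``ln t`` with slope
    ``k``.  For the exponential family the slope is constrained to 1 and only
    the intercept (``-ln lambda``) is estimated.  Points with survival at 0
    or 1 (log undefined) or time 0 are dropped with a logged warning; at
    least three usable points are required.

    Returns a model whose ``coef_covariance`` holds the delta-method
    covariance of ``(ln shape, ln scale)``.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")
    t = points.time
    s = points.survival
    usable = (s > 0.0) & (s < 1.0) & (t > 0.0)
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.warning(
            "dropping %d point(s) with survival at 0 or 1 (or time 0) from the linearized fit",
            n_dropped,
        )
    if int(usable.sum()) < 3:
        raise InsufficientDataError(
            f"insufficient data: need >= 3 points with 0 < survival < 1, got {int(usable.sum())}"
        )
    x = np.log(t[usable])
    y = np.log(-np.log(s[usable]))

    if family == "weibull":
        res = sm.OLS(y, sm.add_constant(x)).fit()
        b0, b1 = res.params
        if b1 <= 0:
            raise ValueError("fitted shape is non-positive; curve is not Weibull-like")
        shape = float(b1)
        scale = float(np.exp(-b0 / b1))
        # Delta method: ln k = ln b1, ln lambda = -b0 / b1.
        jac = np.array([[0.0, 1.0 / b1], [-1.0 / b1, b0 / b1**2]])
        cov = jac @ np.asarray(res.cov_params()) @ jac.T
    else:
        # Slope fixed at 1: y = ln t - ln lambda, so ln lambda = mean(x - y).
        r = x - y
        ln_scale = float(np.mean(r))
        shape = 1.0
        scale = float(np.exp(ln_scale))
        var = float(np.var(r, ddof=1) / r.size) if r.size > 1 else 0.0
        cov = np.array([[0.0, 0.0], [0.0, var]])
    cov = 0.5 * (cov + cov.T)
    return ParametricSurvivalModel(family=family, shape=shape, scale=scale, coef_covariance=cov)


def survival_at(model: ParametricSurvivalModel, t) -> float | np.ndarray:
    """Evaluate the extrapolated survival fraction at time ``t`` months."""
    return model.survival(t)


def per_cycle_event_prob(
    model: ParametricSurvivalModel, cycle_index: int, cycle_length: float = 1.0
) -> float:
    """Per-cycle event probability ``1 - S((i+1) dt) / S(i dt)``.

    Converts the continuous fitted curve into the discrete time-dependent
    transition probability for model cycle ``cycle_index`` of length
    ``cycle_length`` months.  If the curve has already reached zero the
    event is certain and 1 is returned.
    """
    if cycle_index < 0:
        raise ValueError("cycle_index must be non-negative")
    if not cycle_length > 0:
        raise ValueError("cycle_length must be positive")
    s0 = model.survival(cycle_index * cycle_length)
    if s0 <= 0.0:
        logger.info("survival already zero at cycle %d; event probability set to 1", cycle_index)
        return 1.0
    s1 = model.survival((cycle_index + 1) * cycle_length)
    return float(min(1.0, max(0.0, 1.0 - s1 / s0)))


def event_prob_schedule(
    model: ParametricSurvivalModel, n_cycles: int, cycle_length: float = 1.0
) -> np.ndarray:
    """Vectorized ``per_cycle_event_prob`` for cycles ``0 .. n_cycles - 1``."""
    if n_cycles < 0:
        raise ValueError("n_cycles must be non-negative")
    if not cycle_length > 0:
        raise ValueError("cycle_length must be positive")
    grid = np.arange(n_cycles + 1, dtype=float) * cycle_length
    surv = model.survival(grid)
    surv = np.atleast_1d(surv)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = 1.0 - surv[1:] / surv[:-1]
    p[~np.isfinite(p)] = 1.0
    p[surv[:-1] <= 0.0] = 1.0
    return np.clip(p, 0.0, 1.0)


def linearized_r_squared(points: KMCurvePoints, model: ParametricSurvivalModel) -> float:
    """R-squared of the complementary log-log fit, as a fit diagnostic."""
    t = points.time
    s = points.survival
    usable = (s > 0.0) & (s < 1.0) & (t > 0.0)
    x = np.log(t[usable])
    y = np.log(-np.log(s[usable]))
    yhat = model.shape * (x - np.log(model.scale))
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0


def pfs_os_decompose(
    pfs: ParametricSurvivalModel,
    os: ParametricSurvivalModel,
    cycle_index: int,
    cycle_length: float = 1.0,
) -> tuple[float, float]:
    """Split the per-cycle PFS event probability into (progression, death).

    Death is the per-cycle overall-survival event probability; progression
    is the PFS event probability minus death, floored at zero so that the
    pair is a valid competing-risk split with ``p_prog + p_death <= 1``.
    """
    p_pfs = per_cycle_event_prob(pfs, cycle_index, cycle_length)
    p_death = per_cycle_event_prob(os, cycle_index, cycle_length)
    p_prog = max(0.0, p_pfs - p_death)
    return p_prog, p_death
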