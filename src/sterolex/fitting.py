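"""Nonlinear least-squares fitting of the initial-velocity equations.

Given (protein concentration, v₀) pairs at fixed liposome-site
concentration L0, recover the liposome dissociation constant K1 and the
transfer rate k+2 by fitting either the hyperbolic or the tight-binding
quadratic velocity form, then compare basal vs. phosphoinositide-stimulated
conditions through the fold changes of K1, k+2 and the second-order
constant k+2/K1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .kinetics import VelocityModelParams, v0_hyperbolic, v0_quadratic
from .signals import FluorescenceTrace, default_window, initial_velocity

__all__ = [
    "VelocityDataset",
    "FitResult",
    "ConditionComparison",
    "PlateauReport",
    "fit_velocity_model",
    "compare_conditions",
    "plateau_check",
]

MODELS = ("hyperbolic", "quadratic")


@dataclass(frozen=True)
class VelocityDataset:
    """(protein concentration, v₀) measurements for one condition.

    ``L0`` is the known cargo-site concentration (accessible sterol, μM);
    it is an assay input, not a fitted parameter.
    """

    o_total: np.ndarray  # μM
    v0: np.ndarray  # μM s⁻¹
    replicate: np.ndarray  # replicate id per point
    L0: float  # μM
    condition: str = "basal"
    temperature: float = 15.0  # °C

    def __post_init__(self) -> None:
        o = np.asarray(self.o_total, dtype=float)
        v = np.asarray(self.v0, dtype=float)
        r = np.asarray(self.replicate)
        object.__setattr__(self, "o_total", o)
        object.__setattr__(self, "v0", v)
        object.__setattr__(self, "replicate", r)
        if not (o.shape == v.shape == r.shape) or o.ndim != 1:
            raise ValueError("o_total, v0 and replicate must be 1-D and equal length")
        if np.any(o < 0):
            raise ValueError("protein concentrations must be >= 0")
        if self.L0 <= 0:
            raise ValueError("L0 must be > 0")
        if np.unique(o).size < 4:
            raise ValueError("need >= 4 distinct protein concentrations to fit")

    def __len__(self) -> int:
        return self.o_total.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein_uM": self.o_total,
                "v0_uM_per_s": self.v0,
                "replicate": self.replicate,
                "condition": self.condition,
            }
        )

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, L0: float, condition: Optional[str] = None,
        temperature: float = 15.0,
    ) -> "VelocityDataset":
        cond = condition
        if cond is None:
            cond = str(df["condition"].iloc[0]) if "condition" in df else "basal"
        return cls(
            o_total=df["protein_uM"].to_numpy(float),
            v0=df["v0_uM_per_s"].to_numpy(float),
            replicate=(
                df["replicate"].to_numpy()
                if "replicate" in df
                else np.zeros(len(df), dtype=int)
            ),
            L0=L0,
            condition=cond,
            temperature=temperature,
        )


@dataclass(frozen=True)
class FitResult:
    """Estimates of K1 and k+2 with asymptotic uncertainties."""

    K1_hat: float  # μM
    k_plus2_hat: float  # s⁻¹
    K1_se: float
    k_plus2_se: float
    covariance: np.ndarray  # 2×2, order (K1, k+2)
    residuals: np.ndarray  # v0_obs − v0_model
    objective: float  # sum of squared residuals
    converged: bool
    degenerate: bool
    model: str
    L0: float
    condition: str
    n_points: int

    @property
    def second_order_rate(self) -> float:
        """k+2/K1 (μM⁻¹ s⁻¹) at the point estimate."""
        if self.K1_hat <= 0:
            raise ValueError("second-order rate undefined at K1 = 0")
        return self.k_plus2_hat / self.K1_hat

    @property
    def second_order_se(self) -> float:
        """First-order propagated SE of k+2/K1 (includes the covariance)."""
        r = self.second_order_rate
        gK = -self.k_plus2_hat / self.K1_hat**2
        gk = 1.0 / self.K1_hat
        g = np.array([gK, gk])
        var = float(g @ self.covariance @ g)
        return math.sqrt(max(var, 0.0))

    def params(self) -> VelocityModelParams:
        return VelocityModelParams(self.K1_hat, self.k_plus2_hat, self.L0, self.condition)

    def summary(self) -> dict:
        return {
            "model": self.model,
            "condition": self.condition,
            "K1_uM": self.K1_hat,
            "K1_se": self.K1_se,
            "k_plus2_per_s": self.k_plus2_hat,
            "k_plus2_se": self.k_plus2_se,
            "L0_uM": self.L0,
            "sse": self.objective,
            "n": self.n_points,
            "converged": self.converged,
            "degenerate": self.degenerate,
        }


def _model_fn(model: str):
    if model == "hyperbolic":
        return v0_hyperbolic
    if model == "quadratic":
        return v0_quadratic
    raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")


def _default_init(data: VelocityDataset) -> tuple[float, float]:
    # k+2 from the saturating velocity; K1 from the half-max concentration.
    vmax = float(np.max(data.v0))
    k2_0 = max(vmax / data.L0, 1e-9)
    half = vmax / 2.0
    order = np.argsort(data.o_total)
    o_s, v_s = data.o_total[order], data.v0[order]
    above = np.nonzero(v_s >= half)[0]
    K1_0 = float(o_s[above[0]]) if above.size else float(np.median(o_s))
    return max(K1_0, 1e-6), k2_0


def fit_velocity_model(
    data: VelocityDataset,
    model: str = "quadratic",
    init: Optional[tuple[float, float]] = None,
    bounds: tuple = ((0.0, 0.0), (np.inf, np.inf)),
    weights: Optional[np.ndarray] = None,
) -> FitResult:
    """Least-squares fit of (K1, k+2) to an initial-velocity dataset.

    Unweighted least squares on v₀ by default (pass ``weights`` — e.g.
    1/v₀ — to weight residuals for multiplicative noise).  Estimates are
    bounded to [0, ∞).  Standard errors are asymptotic, from the Jacobian
    at the optimum with variance SSR/(n − 2).  Non-convergence is reported
    through ``converged=False``, never silently; an all-zero dataset yields
    k+2 → 0 flagged ``degenerate``.
    """
    fn = _model_fn(model)
    n = len(data)
    if n < 2:
        raise ValueError("fewer data points than parameters")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)

    degenerate = bool(np.max(np.abs(data.v0)) == 0.0)
    if init is None:
        init = _default_init(data)
    x0 = np.clip(np.asarray(init, dtype=float), bounds[0], bounds[1])
    # Interior start: least_squares with x exactly on a zero bound stalls.
    x0 = np.maximum(x0, 1e-9)

    def resid(x):
        p = VelocityModelParams(x[0], x[1], data.L0, data.condition)
        return w * (data.v0 - fn(p, data.o_total))

    sol = least_squares(resid, x0, bounds=bounds, method="trf",
                        xtol=1e-12, ftol=1e-12, gtol=1e-12)
    K1_hat, k2_hat = float(sol.x[0]), float(sol.x[1])
    residuals = data.v0 - fn(
        VelocityModelParams(K1_hat, k2_hat, data.L0, data.condition), data.o_total
    )
    sse = float(np.sum((w * residuals) ** 2))
    dof = max(n - 2, 1)
    s2 = sse / dof
    JTJ = sol.jac.T @ sol.jac
    try:
        cov = s2 * np.linalg.inv(JTJ)
    except np.linalg.LinAlgError:
        cov = s2 * np.linalg.pinv(JTJ)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))

    return FitResult(
        K1_hat=K1_hat,
        k_plus2_hat=k2_hat,
        K1_se=float(se[0]),
        k_plus2_se=float(se[1]),
        covariance=cov,
        residuals=residuals,
        objective=sse,
        converged=bool(sol.status > 0),
        degenerate=degenerate,
        model=model,
        L0=data.L0,
        condition=data.condition,
        n_points=n,
    )


@dataclass(frozen=True)
class ConditionComparison:
    """Fold changes between basal and stimulated fits, with propagated SEs.

    ``K1_fold`` is basal/stimulated (> 1 means tighter membrane binding
    under stimulation); ``k_plus2_fold`` and ``second_order_fold`` are
    stimulated/basal (> 1 means faster extraction).
    """

    K1_fold: float
    K1_fold_se: float
    k_plus2_fold: float
    k_plus2_fold_se: float
    second_order_fold: float
    second_order_fold_se: float
    basal: FitResult
    stimulated: FitResult

    def summary(self) -> dict:
        return {
            "K1_fold_basal_over_stim": self.K1_fold,
            "K1_fold_se": self.K1_fold_se,
            "k_plus2_fold_stim_over_basal": self.k_plus2_fold,
            "k_plus2_fold_se": self.k_plus2_fold_se,
            "second_order_fold_stim_over_basal": self.second_order_fold,
            "second_order_fold_se": self.second_order_fold_se,
        }


def _ratio_se(a: float, sa: float, b: float, sb: float) -> float:
    # first-order propagation for a/b with independent a, b
    r = a / b
    return abs(r) * math.sqrt((sa / a) ** 2 + (sb / b) ** 2)


def compare_conditions(basal: FitResult, stim: FitResult) -> ConditionComparison:
    """Fold changes of K1, k+2 and k+2/K1 between two fitted conditions.

    Both fits must have converged.  Uncertainties are first-order
    propagated; the within-fit K1–k+2 covariance enters through the
    second-order-rate SE of each fit, and the two conditions are treated as
    independent.
    """
    for r in (basal, stim):
        if not r.converged:
            raise ValueError(f"fit for condition {r.condition!r} did not converge")
        if r.K1_hat <= 0 or r.k_plus2_hat <= 0:
            raise ValueError(f"non-positive estimates in condition {r.condition!r}")
    r2_b, r2_s = basal.second_order_rate, stim.second_order_rate
    return ConditionComparison(
        K1_fold=basal.K1_hat / stim.K1_hat,
        K1_fold_se=_ratio_se(basal.K1_hat, basal.K1_se, stim.K1_hat, stim.K1_se),
        k_plus2_fold=stim.k_plus2_hat / basal.k_plus2_hat,
        k_plus2_fold_se=_ratio_se(
            stim.k_plus2_hat, stim.k_plus2_se, basal.k_plus2_hat, basal.k_plus2_se
        ),
        second_order_fold=r2_s / r2_b,
        second_order_fold_se=_ratio_se(
            r2_s, stim.second_order_se, r2_b, basal.second_order_se
        ),
        basal=basal,
        stimulated=stim,
    )


@dataclass(frozen=True)
class PlateauReport:
    """Final extraction amounts of two progress curves and their ratio."""

    final_basal: float  # μM
    final_stim: float  # μM
    ratio: Optional[float]  # stim/basal, None when either curve lacks a plateau
    basal_plateaued: bool
    stim_plateaued: bool


def _plateau(trace: FluorescenceTrace, slope_ratio: float) -> tuple[bool, float]:
    v_init = initial_velocity(trace, r2_warn=0.0).slope
    n_tail = max(3, int(round(0.10 * trace.times.size)))
    tail = np.arange(trace.times.size - n_tail, trace.times.size)
    v_tail = initial_velocity(trace, window=tail, r2_warn=0.0).slope
    final = float(np.mean(trace.signal[tail]))
    if v_init == 0:
        return bool(v_tail == 0), final
    return bool(abs(v_tail) < slope_ratio * abs(v_init)), final


def plateau_check(
    trace_basal: FluorescenceTrace,
    trace_stim: FluorescenceTrace,
    slope_ratio: float = 0.01,
) -> PlateauReport:
    """Compare final extraction amounts of two converted progress curves.

    A trace is considered plateaued when the slope over its last 10% of
    samples is below ``slope_ratio`` (default 1%) of its initial slope.
    The ratio is only reported when both traces plateau — allosteric
    stimulation is expected to change rates, not the final amount.
    """
    b_ok, b_final = _plateau(trace_basal, slope_ratio)
    s_ok, s_final = _plateau(trace_stim, slope_ratio)
    ratio = (s_final / b_final) if (b_ok and s_ok and b_final != 0) else None
    return PlateauReport(b_final, s_final, ratio, b_ok, s_ok)
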