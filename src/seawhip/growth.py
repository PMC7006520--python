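"""Von Bertalanffy growth modelling with bootstrap confidence intervals.

The von Bertalanffy growth function (VBGF)

    E[L | t] = L_inf * (1 - exp(-K * (t - t0)))

describes mean length at age for organisms whose growth decelerates
toward an asymptote: L_inf is the asymptotic average length (cm), K the
Brody growth-rate coefficient (1/y, the exponential rate of approach to
L_inf) and t0 the nominal age at mean length zero (a model artifact).

The model is fitted by nonlinear least squares.  Wald standard errors
come from the linearised curvature (Gauss–Newton J'J) at the optimum
with n - 3 degrees of freedom; because Wald intervals are unreliable for
nonlinear growth models, 95% intervals are also available by
case-resampling bootstrap (resample (age, length) pairs, refit, take the
2.5/97.5 percentiles).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "VBGFParams",
    "VonBertalanffyModel",
    "VBGFResults",
    "predict_length",
    "fit_vbgf",
    "bootstrap_vbgf",
    "walford_to_k",
]

_PARAM_NAMES = ("l_inf", "k", "t0")


@dataclass
class VBGFParams:
    """VBGF parameter triple: L_inf (cm), K (1/y), t0 (y)."""

    l_inf: float
    k: float
    t0: float

    def as_array(self) -> np.ndarray:
        return np.array([self.l_inf, self.k, self.t0], dtype=float)


def predict_length(params: VBGFParams | Sequence[float], t) -> np.ndarray | float:
    """Expected length at age t: L_inf * (1 - exp(-K (t - t0)))."""
    if isinstance(params, VBGFParams):
        l_inf, k, t0 = params.l_inf, params.k, params.t0
    else:
        l_inf, k, t0 = params
    t = np.asarray(t, dtype=float)
    out = l_inf * (1.0 - np.exp(-k * (t - t0)))
    return float(out) if out.ndim == 0 else out


def _residuals(theta: np.ndarray, t: np.ndarray, length: np.ndarray) -> np.ndarray:
    return length - theta[0] * (1.0 - np.exp(-theta[1] * (t - theta[2])))


def _jacobian(theta: np.ndarray, t: np.ndarray, length: np.ndarray) -> np.ndarray:
    l_inf, k, t0 = theta
    e = np.exp(-k * (t - t0))
    # residual = L - f; d(residual)/d(theta) = -df/dtheta
    return -np.column_stack([1.0 - e, l_inf * (t - t0) * e, -l_inf * k * e])


def walford_to_k(slope: float, dt: float = 1.0) -> float:
    """Brody K implied by a Walford-plot slope.

    A Walford plot regresses length at age t + dt on length at age t;
    under the VBGF its slope is exp(-K dt), so K = -ln(slope) / dt.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not 0 < slope < 1:
        raise ValueError("Walford slope must lie in (0, 1): no asymptotic growth implied")
    return -math.log(slope) / dt


class VonBertalanffyModel:
    """Nonlinear least-squares VBGF model for (age, length) data.

    Parameters
    ----------
    age : array-like
        Ages in years (consensus ring counts; half-year values allowed).
    length : array-like
        Total lengths in cm.

    Examples
    --------
    >>> model = VonBertalanffyModel(ages, lengths)
    >>> res = model.fit()
    >>> res.params["k"], res.conf_int_bootstrap(seed=1).loc["k"]
    """

    def __init__(self, age, length):
        self.age = np.asarray(age, dtype=float)
        self.length = np.asarray(length, dtype=float)
        if self.age.shape != self.length.shape or self.age.ndim != 1:
            raise ValueError("age and length must be 1-d arrays of equal size")
        if self.age.size < 4:
            raise ValueError("VBGF fit requires n >= 4")
        if np.unique(self.age).size < 3:
            raise ValueError("VBGF fit requires >= 3 distinct ages")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, age_col: str = "age",
                       length_col: str = "total_length_cm") -> "VonBertalanffyModel":
        return cls(df[age_col].to_numpy(), df[length_col].to_numpy())

    def default_start(self) -> VBGFParams:
        """L_inf from the largest length; K from a log-linearised fit; t0 = 0."""
        l_inf0 = 1.05 * float(self.length.max())
        frac = 1.0 - self.length / l_inf0
        mask = frac > 1e-6
        if mask.sum() >= 2:
            slope = np.polyfit(self.age[mask], np.log(frac[mask]), 1)[0]
            k0 = max(-slope, 1e-3)
        else:
            k0 = 0.2
        return VBGFParams(l_inf0, k0, 0.0)

    def fit(self, start: Optional[VBGFParams] = None) -> "VBGFResults":
        start = start or self.default_start()
        theta0 = start.as_array()
        sol = optimize.least_squares(
            _residuals,
            theta0,
            jac=_jacobian,
            args=(self.age, self.length),
            method="lm",
            xtol=1e-12,
            ftol=1e-10,
            gtol=1e-12,
            max_nfev=10_000,
        )
        converged = bool(sol.success)
        theta = sol.x
        n = self.age.size
        dof = n - 3
        resid = _residuals(theta, self.age, self.length)
        sse = float(resid @ resid)
        sigma2 = sse / dof if dof > 0 else np.nan
        J = _jacobian(theta, self.age, self.length)
        try:
            cov = sigma2 * np.linalg.inv(J.T @ J)
            bse = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:
            cov = np.full((3, 3), np.nan)
            bse = np.full(3, np.nan)
        return VBGFResults(
            model=self,
            params=pd.Series(theta, index=_PARAM_NAMES),
            bse=pd.Series(bse, index=_PARAM_NAMES),
            cov_params=pd.DataFrame(cov, index=_PARAM_NAMES, columns=_PARAM_NAMES),
            resid=resid,
            sse=sse,
            converged=converged,
            nobs=n,
        )


@dataclass
class VBGFResults:
    """Fitted VBGF: estimates, Wald uncertainty, residuals, bootstrap CIs."""

    model: VonBertalanffyModel
    params: pd.Series
    bse: pd.Series
    cov_params: pd.DataFrame
    resid: np.ndarray
    sse: float
    converged: bool
    nobs: int

    def __post_init__(self) -> None:
        self._boot_samples: Optional[np.ndarray] = None
        self._boot_dropped: int = 0

    @property
    def df_resid(self) -> int:
        return self.nobs - 3

    @property
    def residual_sd(self) -> float:
        return math.sqrt(self.sse / self.df_resid)

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        """Wald t-test p-values (two-sided, n - 3 df)."""
        return pd.Series(
            2.0 * stats.t.sf(np.abs(self.tvalues), self.df_resid), index=self.params.index
        )

    def predict(self, t) -> np.ndarray | float:
        return predict_length(tuple(self.params), t)

    def vbgf_params(self) -> VBGFParams:
        return VBGFParams(*self.params)

    def bootstrap(self, n_boot: int = 1000,
                  seed: Optional[int | np.random.Generator] = None) -> pd.DataFrame:
        """Case-resampling bootstrap percentile 95% CIs.

        Resamples (age, length) pairs with replacement, refits from this
        fit's estimates, and takes the 2.5/97.5 percentiles of the
        converged replicates.  Non-converged or degenerate replicates
        (fewer than three distinct ages) are dropped and counted; a
        warning is attached when more than 20% are lost.
        """
        if n_boot < 100:
            raise ValueError("bootstrap requires >= 100 replicates")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        n = self.nobs
        age, length = self.model.age, self.model.length
        start = VBGFParams(*self.params)
        draws = []
        dropped = 0
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            a, l = age[idx], length[idx]
            if np.unique(a).size < 3:
                dropped += 1
                continue
            try:
                res = VonBertalanffyModel(a, l).fit(start=start)
            except (ValueError, RuntimeError):
                dropped += 1
                continue
            if not res.converged:
                dropped += 1
                continue
            draws.append(res.params.to_numpy())
        if dropped > 0.2 * n_boot:
            warnings.warn(
                f"{dropped}/{n_boot} bootstrap replicates failed to converge; "
                "intervals may be unreliable"
            )
        if not draws:
            raise RuntimeError("all bootstrap replicates failed")
        samples = np.vstack(draws)
        self._boot_samples = samples
        self._boot_dropped = dropped
        lo, hi = np.percentile(samples, [2.5, 97.5], axis=0)
        return pd.DataFrame(
            {"lo95": lo, "hi95": hi}, index=list(self.params.index)
        )

    def conf_int_bootstrap(self, n_boot: int = 1000,
                           seed: Optional[int | np.random.Generator] = None) -> pd.DataFrame:
        return self.bootstrap(n_boot=n_boot, seed=seed)

    def bootstrap_se(self) -> Optional[pd.Series]:
        """Parameter SDs over the last bootstrap sample, if one was run."""
        if self._boot_samples is None:
            return None
        return pd.Series(self._boot_samples.std(axis=0, ddof=1), index=list(self.params.index))

    def summary(self, ci: Optional[pd.DataFrame] = None) -> pd.DataFrame:
        """Parameter table: estimate, Wald SE, t, p, and CIs if provided."""
        tab = pd.DataFrame(
            {
                "estimate": self.params,
                "se": self.bse,
                "t": self.tvalues,
                "p": self.pvalues,
            }
        )
        if ci is not None:
            tab = tab.join(ci)
        return tab

    def __str__(self) -> str:
        lines = [
            "Von Bertalanffy growth fit",
            f"  n = {self.nobs}, residual SD = {self.residual_sd:.3f} cm, "
            f"converged = {self.converged}",
            self.summary().to_string(float_format=lambda x: f"{x:.4g}"),
        ]
        return "\n".join(lines)


def fit_vbgf(age, length, start: Optional[VBGFParams] = None) -> VBGFResults:
    """Functional wrapper: fit the VBGF to (age, length) data."""
    return VonBertalanffyModel(age, length).fit(start=start)


def bootstrap_vbgf(results: VBGFResults, n_boot: int = 1000,
                   seed: Optional[int | np.random.Generator] = None) -> pd.DataFrame:
    """Functional wrapper for :meth:`VBGFResults.bootstrap`."""
    return results.bootstrap(n_boot=n_boot, seed=seed)
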