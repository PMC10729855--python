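"""Causal-effect estimators for two-sample MR on harmonized summary statistics.

Per-SNP Wald ratios are combined by inverse-variance weighting with a
multiplicative random-effects scale, by MR-Egger regression (free
intercept, directional-pleiotropy test), and by the weighted median
(consistent while valid instruments carry a majority of the weight).
An analytic power calculation for binary outcomes is included.

All estimators operate on the log-odds scale; odds ratios and their 95%
confidence limits are exponentiated from the linear scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateInstrumentError, InsufficientInstrumentsError
from .sumstats import HarmonizedSet

__all__ = [
    "MREstimate",
    "RatioEstimates",
    "EggerIntercept",
    "wald_ratios",
    "ivw",
    "egger",
    "weighted_median",
    "mr_power",
]


@dataclass
class MREstimate:
    """A causal log-odds estimate tagged by method, with OR-scale CI."""

    method: str  # IVW | Egger | WeightedMedian | WaldSingle
    beta: float
    se: float
    pvalue: float
    n_snps: int
    scale_phi: float = 1.0
    ci_z: float = 1.959963984540054  # critical value used for the CI

    @property
    def or_(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.beta - self.ci_z * self.se))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.beta + self.ci_z * self.se))

    def as_row(self) -> dict:
        return {
            "method": self.method,
            "nsnp": self.n_snps,
            "beta": self.beta,
            "se": self.se,
            "pvalue": self.pvalue,
            "or": self.or_,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "scale_phi": self.scale_phi,
        }


@dataclass
class EggerIntercept:
    intercept: float
    se: float
    pvalue: float


@dataclass
class RatioEstimates:
    """Per-SNP Wald ratios theta_j = b_out/b_exp with delta-method SEs."""

    df: pd.DataFrame  # snp_id, theta, se, weight

    @property
    def theta(self) -> np.ndarray:
        return self.df["theta"].to_numpy()

    @property
    def weight(self) -> np.ndarray:
        return self.df["weight"].to_numpy()


def wald_ratios(h: HarmonizedSet, second_order: bool = False) -> RatioEstimates:
    """Per-SNP ratio estimates.

    First-order delta method: se_j = se_out / |b_exp|.  With
    ``second_order`` the exposure-side noise term
    (b_out^2 se_exp^2 / b_exp^4) is added.
    """
    df = h.df
    bx = df["b_exp"].to_numpy(dtype=float)
    if np.any(bx == 0):
        bad = df.loc[df["b_exp"] == 0, "snp_id"].tolist()
        raise DegenerateInstrumentError(f"zero exposure effect for {bad}")
    theta = df["b_out"].to_numpy() / bx
    var = (df["se_out"].to_numpy() / np.abs(bx)) ** 2
    if second_order:
        var = var + df["b_out"].to_numpy() ** 2 * df["se_exp"].to_numpy() ** 2 / bx**4
    se = np.sqrt(var)
    out = pd.DataFrame(
        {"snp_id": df["snp_id"], "theta": theta, "se": se, "weight": 1.0 / se**2}
    )
    return RatioEstimates(out)


def _ivw_core(bx, by, se_out):
    """Weighted regression of b_out on b_exp through the origin, w = 1/se_out^2."""
    w = 1.0 / se_out**2
    sxx = np.sum(w * bx * bx)
    beta = np.sum(w * bx * by) / sxx
    resid = by - beta * bx
    q = float(np.sum(w * resid**2))
    return beta, sxx, q


def ivw(h: HarmonizedSet) -> MREstimate:
    """Inverse-variance-weighted estimate with multiplicative random effects.

    Equivalent to the precision-weighted mean of the Wald ratios with
    weights b_exp^2/se_out^2.  The SE is scaled by
    max(1, Q/(J-1)) so between-instrument heterogeneity widens, and never
    narrows, the interval.  P-value from the normal reference.
    """
    df = h.df
    if len(df) < 2:
        raise InsufficientInstrumentsError("IVW requires >= 2 instruments")
    bx = df["b_exp"].to_numpy(dtype=float)
    by = df["b_out"].to_numpy(dtype=float)
    beta, sxx, q = _ivw_core(bx, by, df["se_out"].to_numpy(dtype=float))
    j = len(df)
    phi = max(1.0, q / (j - 1))
    se = float(np.sqrt(phi / sxx))
    p = 2.0 * sps.norm.sf(abs(beta) / se)
    return MREstimate("IVW", float(beta), se, float(p), j, scale_phi=phi)


def egger(h: HarmonizedSet) -> tuple[MREstimate, EggerIntercept]:
    """MR-Egger: weighted regression b_out = a + theta*b_exp, w = 1/se_out^2.

    Rows are oriented so every exposure effect is non-negative (the usual
    Egger convention; the fit is otherwise not orientation-invariant).  The
    intercept estimates the average directional pleiotropy; slope and
    intercept inference uses the t reference with J-2 df and a
    multiplicative dispersion floored at 1.
    """
    df = h.df
    j = len(df)
    if j < 3:
        raise InsufficientInstrumentsError("Egger requires >= 3 instruments")
    sign = np.where(df["b_exp"].to_numpy() < 0, -1.0, 1.0)
    bx = df["b_exp"].to_numpy() * sign
    by = df["b_out"].to_numpy() * sign
    w = 1.0 / df["se_out"].to_numpy() ** 2
    sw, swx = np.sum(w), np.sum(w * bx)
    swxx, swy, swxy = np.sum(w * bx * bx), np.sum(w * by), np.sum(w * bx * by)
    det = sw * swxx - swx**2
    slope = (sw * swxy - swx * swy) / det
    intercept = (swxx * swy - swx * swxy) / det
    resid = by - intercept - slope * bx
    q_e = float(np.sum(w * resid**2))
    phi = max(1.0, q_e / (j - 2))
    var_slope = phi * sw / det
    var_int = phi * swxx / det
    tdist = sps.t(j - 2)
    se_slope, se_int = float(np.sqrt(var_slope)), float(np.sqrt(var_int))
    p_slope = 2.0 * tdist.sf(abs(slope) / se_slope)
    p_int = 2.0 * tdist.sf(abs(intercept) / se_int)
    est = MREstimate(
        "Egger", float(slope), se_slope, float(p_slope), j,
        scale_phi=phi, ci_z=float(tdist.ppf(0.975)),
    )
    return est, EggerIntercept(float(intercept), se_int, float(p_int))


def _weighted_median_point(theta: np.ndarray, weight: np.ndarray) -> float:
    """Interpolated weighted median of theta under normalized weights."""
    order = np.argsort(theta, kind="stable")
    t = theta[order]
    w = weight[order] / np.sum(weight)
    cum = np.cumsum(w) - w / 2.0  # midpoint of each weight step
    if 0.5 <= cum[0]:
        return float(t[0])
    if 0.5 >= cum[-1]:
        return float(t[-1])
    return float(np.interp(0.5, cum, t))


def weighted_median(
    h: HarmonizedSet, n_boot: int = 1000, seed: int | None = None
) -> MREstimate:
    """Weighted-median estimator with parametric-bootstrap SE.

    Consistent as long as instruments carrying at least half the weight are
    valid.  The SE resamples (b_exp, b_out) from their normal sampling
    distributions ``n_boot`` times (seed mandatory) and takes the standard
    deviation of the re-estimated medians.  P-value from the normal
    reference.
    """
    df = h.df
    j = len(df)
    if j < 3:
        raise InsufficientInstrumentsError("weighted median requires >= 3 instruments")
    if seed is None:
        raise ValueError("weighted_median requires an explicit seed")
    ratios = wald_ratios(h)
    point = _weighted_median_point(ratios.theta, ratios.weight)

    rng = np.random.default_rng(seed)
    bx = df["b_exp"].to_numpy()
    by = df["b_out"].to_numpy()
    sx = df["se_exp"].to_numpy()
    sy = df["se_out"].to_numpy()
    bx_s = rng.normal(bx, sx, size=(n_boot, j))
    by_s = rng.normal(by, sy, size=(n_boot, j))
    bx_s = np.where(bx_s == 0, np.finfo(float).tiny, bx_s)
    theta_s = by_s / bx_s
    w_s = (bx_s / sy) ** 2
    order = np.argsort(theta_s, axis=1, kind="stable")
    t_sorted = np.take_along_axis(theta_s, order, axis=1)
    w_sorted = np.take_along_axis(w_s, order, axis=1)
    w_sorted = w_sorted / w_sorted.sum(axis=1, keepdims=True)
    cum = np.cumsum(w_sorted, axis=1) - w_sorted / 2.0
    boots = np.empty(n_boot)
    for i in range(n_boot):  # np.interp has no axis support
        boots[i] = np.interp(0.5, cum[i], t_sorted[i])
    se = float(np.std(boots, ddof=1))
    p = 2.0 * sps.norm.sf(abs(point) / se) if se > 0 else (1.0 if point == 0 else 0.0)
    return MREstimate("WeightedMedian", point, se, float(p), j)


def mr_power(
    n_outcome: float,
    case_fraction: float,
    total_r2: float,
    or_true: float,
    alpha: float = 0.05,
) -> float:
    """Analytic power to detect a causal odds ratio in two-sample MR.

    Uses the asymptotic SE of the IVW estimate for a binary outcome,
    se = 1/sqrt(n * R^2 * K * (1-K)), where R^2 is the variance of the
    (standardized) exposure explained by the instruments and K the case
    fraction; two-sided test at level alpha.
    """
    if not (0 < case_fraction < 1):
        raise ValueError("case_fraction must be in (0,1)")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0,1)")
    if total_r2 <= 0:
        import warnings

        warnings.warn("total_r2 <= 0: power equals the test size", stacklevel=2)
        return float(alpha)
    se = 1.0 / np.sqrt(n_outcome * total_r2 * case_fraction * (1.0 - case_fraction))
    ncp = abs(np.log(or_true)) / se
    z = sps.norm.ppf(1.0 - alpha / 2.0)
    return float(sps.norm.cdf(ncp - z) + sps.norm.cdf(-ncp - z))
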