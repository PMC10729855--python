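"""Sensitivity diagnostics for two-sample MR estimates.

Covers heterogeneity (Cochran's Q), directional pleiotropy (Egger
intercept), simulation-based outlier detection and correction (MR-PRESSO),
radial reformulation with per-SNP Q contributions, leave-one-out
stability, and the Steiger directionality test, plus the composite
verdict combining them: a causal claim is supported only when the primary
IVW estimate is significant, no heterogeneity or pleiotropy is detected,
no single SNP drives the estimate, and the instruments explain more
variance in the exposure than in the outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError, InsufficientInstrumentsError
from .estimators import MREstimate, RatioEstimates, egger, ivw, wald_ratios
from .sumstats import HarmonizedSet

__all__ = [
    "SensitivityReport",
    "PressoResult",
    "RadialResult",
    "LooResult",
    "SteigerResult",
    "cochran_q",
    "mr_presso",
    "radial_mr",
    "leave_one_out",
    "steiger",
    "classify_causal",
    "run_sensitivity",
]

VERDICTS = (
    "supported",
    "not_significant",
    "heterogeneous_or_pleiotropic",
    "unstable",
    "wrong_direction",
)


def cochran_q(ratios: RatioEstimates, theta_ivw: float) -> tuple[float, int, float]:
    """Cochran's Q over per-SNP ratio estimates around the IVW estimate.

    Q = sum w_j (theta_j - theta_ivw)^2, referred to chi-square with J-1 df.
    """
    if len(ratios.df) < 2:
        raise InsufficientInstrumentsError("Cochran's Q requires >= 2 ratios")
    q = float(np.sum(ratios.weight * (ratios.theta - theta_ivw) ** 2))
    df = len(ratios.df) - 1
    return q, df, float(sps.chi2.sf(q, df))


def _loo_thetas(bx, by, w):
    """Leave-one-out IVW point estimates, vectorized over the left-out SNP."""
    sxy = np.sum(w * bx * by)
    sxx = np.sum(w * bx * bx)
    return (sxy - w * bx * by) / (sxx - w * bx * bx)


@dataclass
class PressoResult:
    global_p: float
    outliers: list[str]
    outlier_p: pd.DataFrame  # snp_id, p_bonferroni
    distortion_p: float | None
    corrected: MREstimate | None
    observed_rss: float


def mr_presso(
    h: HarmonizedSet,
    n_sim: int = 1000,
    seed: int | None = None,
    outlier_alpha: float = 0.05,
) -> PressoResult:
    """MR-PRESSO: global pleiotropy test, per-SNP outliers, distortion test.

    The observed residual sum of squares uses leave-one-out IVW predictions;
    its null distribution comes from ``n_sim`` parametric replicates drawn
    from the no-pleiotropy model (exposure effects resampled at their SEs,
    outcome effects at the LOO predictions).  Per-SNP outlier p-values are
    Bonferroni-adjusted over J; the distortion test compares the shift of the
    outlier-free IVW estimate against shifts from removing random subsets of
    the same size.  All empirical p-values carry the +1/(n_sim+1) continuity
    correction.
    """
    df = h.df
    j = len(df)
    if j < 4:
        raise InsufficientInstrumentsError("MR-PRESSO requires >= 4 instruments")
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    if seed is None:
        raise ValueError("mr_presso requires an explicit seed")
    rng = np.random.default_rng(seed)

    bx = df["b_exp"].to_numpy(dtype=float)
    by = df["b_out"].to_numpy(dtype=float)
    sx = df["se_exp"].to_numpy(dtype=float)
    sy = df["se_out"].to_numpy(dtype=float)
    w = 1.0 / sy**2

    theta_loo = _loo_thetas(bx, by, w)
    resid_obs = w * (by - theta_loo * bx) ** 2
    rss_obs = float(np.sum(resid_obs))

    bx_s = rng.normal(bx, sx, size=(n_sim, j))
    by_s = rng.normal(theta_loo * bx, sy, size=(n_sim, j))
    sxy_s = (w * bx_s * by_s).sum(axis=1, keepdims=True)
    sxx_s = (w * bx_s * bx_s).sum(axis=1, keepdims=True)
    theta_loo_s = (sxy_s - w * bx_s * by_s) / (sxx_s - w * bx_s * bx_s)
    resid_s = w * (by_s - theta_loo_s * bx_s) ** 2
    rss_s = resid_s.sum(axis=1)

    global_p = (1.0 + np.sum(rss_s >= rss_obs)) / (n_sim + 1.0)
    p_snp = (1.0 + (resid_s >= resid_obs).sum(axis=0)) / (n_sim + 1.0)
    p_bonf = np.minimum(1.0, p_snp * j)
    outlier_mask = p_bonf < outlier_alpha
    outliers = df.loc[outlier_mask, "snp_id"].tolist()
    outlier_p = pd.DataFrame({"snp_id": df["snp_id"], "p_bonferroni": p_bonf})

    distortion_p = None
    corrected = None
    if outliers:
        if outlier_mask.all():
            raise DataError("all instruments flagged as outliers; no corrected estimate")
        keep = ~outlier_mask
        sub = HarmonizedSet(h.exposure_id, h.outcome_id, df.loc[keep].reset_index(drop=True))
        if keep.sum() >= 2:
            corrected = ivw(sub)
            theta_full = float(np.sum(w * bx * by) / np.sum(w * bx * bx))
            delta_obs = corrected.beta - theta_full
            n_out = int(outlier_mask.sum())
            deltas = np.empty(n_sim)
            idx = np.arange(j)
            for b in range(n_sim):
                drop = rng.choice(idx, size=n_out, replace=False)
                m = np.ones(j, dtype=bool)
                m[drop] = False
                deltas[b] = (
                    np.sum(w[m] * bx[m] * by[m]) / np.sum(w[m] * bx[m] ** 2) - theta_full
                )
            distortion_p = float(
                (1.0 + np.sum(np.abs(deltas) >= abs(delta_obs))) / (n_sim + 1.0)
            )
    return PressoResult(float(global_p), outliers, outlier_p, distortion_p, corrected, rss_obs)


@dataclass
class RadialResult:
    slope: float
    q_total: float
    q_p: float
    per_snp_q: pd.DataFrame  # snp_id, q_j
    outliers: list[str]


def radial_mr(
    h: HarmonizedSet,
    weight_order: str = "first",
    alpha: float = 0.05,
) -> RadialResult:
    """Radial (Galbraith-space) IVW with per-SNP heterogeneity contributions.

    With first-order weights w_j = b_exp^2/se_out^2 the radial slope is
    algebraically the IVW estimate.  Modified second-order weights add the
    exposure-side noise term, using the first-order slope.  SNPs whose
    contribution q_j exceeds the chi-square(1) upper quantile at alpha/J are
    flagged as outliers.
    """
    df = h.df
    if len(df) < 2:
        raise InsufficientInstrumentsError("radial MR requires >= 2 instruments")
    ratios = wald_ratios(h)
    theta = ratios.theta
    w = ratios.weight
    slope = float(np.sum(w * theta) / np.sum(w))
    if weight_order == "second":
        bx = df["b_exp"].to_numpy()
        var2 = df["se_out"].to_numpy() ** 2 / bx**2 + (
            slope**2 * df["se_exp"].to_numpy() ** 2 / bx**2
        )
        w = 1.0 / var2
        slope = float(np.sum(w * theta) / np.sum(w))
    elif weight_order != "first":
        raise ValueError("weight_order must be 'first' or 'second'")
    q_j = w * (theta - slope) ** 2
    q_total = float(np.sum(q_j))
    j = len(df)
    q_p = float(sps.chi2.sf(q_total, j - 1))
    cut = sps.chi2.isf(alpha / j, 1)
    outliers = df.loc[q_j > cut, "snp_id"].tolist()
    per_snp = pd.DataFrame({"snp_id": df["snp_id"], "q_j": q_j})
    return RadialResult(slope, q_total, q_p, per_snp, outliers)


@dataclass
class LooResult:
    estimates: pd.DataFrame  # snp_left_out, beta, se, ci_low, ci_high
    stable: bool
    full_beta: float


def leave_one_out(h: HarmonizedSet, stability_rule=None) -> LooResult:
    """IVW re-estimates with each instrument left out in turn.

    Default stability rule: every re-estimate keeps the sign of the full
    estimate AND the full estimate lies inside every leave-one-out 95% CI.
    A custom ``stability_rule(full_beta, loo_df) -> bool`` may be supplied.
    """
    df = h.df
    j = len(df)
    if j < 3:
        raise InsufficientInstrumentsError("leave-one-out requires >= 3 instruments")
    full = ivw(h)
    rows = []
    for i in range(j):
        sub = HarmonizedSet(
            h.exposure_id, h.outcome_id, df.drop(index=df.index[i]).reset_index(drop=True)
        )
        est = ivw(sub)
        rows.append(
            {
                "snp_left_out": df["snp_id"].iloc[i],
                "beta": est.beta,
                "se": est.se,
                "ci_low": est.beta - est.ci_z * est.se,
                "ci_high": est.beta + est.ci_z * est.se,
            }
        )
    loo = pd.DataFrame(rows)
    if stability_rule is not None:
        stable = bool(stability_rule(full.beta, loo))
    else:
        same_sign = np.all(np.sign(loo["beta"]) == np.sign(full.beta)) or full.beta == 0
        inside = np.all((loo["ci_low"] <= full.beta) & (full.beta <= loo["ci_high"]))
        stable = bool(same_sign and inside)
    return LooResult(loo, stable, full.beta)


@dataclass
class SteigerResult:
    direction_ok: bool
    pvalue: float
    r2_exposure: float
    r2_outcome: float


def _aggregate_r2(beta, se, n):
    z2 = (np.asarray(beta) / np.asarray(se)) ** 2
    return float(np.sum(z2 / (z2 + np.asarray(n) - 2)))


def steiger(
    h: HarmonizedSet,
    n_exp: float | None = None,
    n_out: float | None = None,
) -> SteigerResult:
    """Steiger directionality test on aggregate instrument R^2.

    Variance explained is summed over instruments per trait via
    r^2 = z^2/(z^2 + n - 2); the correlations r = sqrt(R^2) are compared by
    the two-sample Fisher-z statistic.  ``direction_ok`` is true when the
    instruments explain more of the exposure than of the outcome — the
    orientation required for a forward causal reading.
    """
    df = h.df
    n_x = float(n_exp if n_exp is not None else df["n_exp"].mean())
    n_y = float(n_out if n_out is not None else df["n_out"].mean())
    if n_x <= 3 or n_y <= 3:
        raise DataError("Steiger test requires sample sizes > 3")
    r2_x = _aggregate_r2(df["b_exp"], df["se_exp"], df["n_exp"])
    r2_y = _aggregate_r2(df["b_out"], df["se_out"], df["n_out"])
    r_x = np.sqrt(min(r2_x, 1.0 - 1e-12))
    r_y = np.sqrt(min(r2_y, 1.0 - 1e-12))
    z = (np.arctanh(r_x) - np.arctanh(r_y)) / np.sqrt(
        1.0 / (n_x - 3.0) + 1.0 / (n_y - 3.0)
    )
    p = float(2.0 * sps.norm.sf(abs(z)))
    return SteigerResult(bool(r2_x > r2_y), p, r2_x, r2_y)


@dataclass
class SensitivityReport:
    """All sensitivity diagnostics for one exposure-outcome pair."""

    q_stat: float
    q_df: int
    q_p: float
    egger_intercept: float
    egger_intercept_p: float
    presso_global_p: float
    presso_outliers: list[str]
    presso_distortion_p: float | None
    radial_q: float
    radial_outliers: list[str]
    loo_estimates: pd.DataFrame
    loo_stable: bool
    steiger_direction: bool
    steiger_p: float
    verdict: str = ""
    extras: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        return {
            "q_stat": self.q_stat,
            "q_df": self.q_df,
            "q_p": self.q_p,
            "egger_intercept": self.egger_intercept,
            "egger_intercept_p": self.egger_intercept_p,
            "presso_global_p": self.presso_global_p,
            "presso_outliers": ",".join(self.presso_outliers),
            "presso_distortion_p": self.presso_distortion_p,
            "radial_q": self.radial_q,
            "radial_outliers": ",".join(self.radial_outliers),
            "loo_stable": self.loo_stable,
            "steiger_direction": self.steiger_direction,
            "steiger_p": self.steiger_p,
            "verdict": self.verdict,
        }


def classify_causal(
    ivw_est: MREstimate, report: SensitivityReport, alpha: float = 0.05
) -> str:
    """Composite causal verdict.

    Supported requires, in order: a significant primary IVW p-value; no
    detected heterogeneity or horizontal pleiotropy (Cochran's Q, Egger
    intercept and PRESSO global p all above alpha); leave-one-out stability;
    and a confirmed exposure-to-outcome direction.  The first failing
    criterion names the verdict.
    """
    if not ivw_est.pvalue < alpha:
        return "not_significant"
    if report.q_p <= alpha or report.egger_intercept_p <= alpha or (
        report.presso_global_p is not None and report.presso_global_p <= alpha
    ):
        return "heterogeneous_or_pleiotropic"
    if not report.loo_stable:
        return "unstable"
    if not report.steiger_direction:
        return "wrong_direction"
    return "supported"


def run_sensitivity(
    h: HarmonizedSet,
    seed: int,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    alpha: float = 0.05,
    ivw_est: MREstimate | None = None,
) -> tuple[SensitivityReport, str]:
    """Run the full diagnostic suite and classify the pair."""
    est = ivw_est if ivw_est is not None else ivw(h)
    ratios = wald_ratios(h)
    q, q_df, q_p = cochran_q(ratios, est.beta)
    _, intercept = egger(h)
    presso = mr_presso(h, n_sim=n_sim, seed=seed, outlier_alpha=outlier_alpha)
    radial = radial_mr(h, alpha=outlier_alpha)
    loo = leave_one_out(h)
    st = steiger(h)
    report = SensitivityReport(
        q_stat=q,
        q_df=q_df,
        q_p=q_p,
        egger_intercept=intercept.intercept,
        egger_intercept_p=intercept.pvalue,
        presso_global_p=presso.global_p,
        presso_outliers=presso.outliers,
        presso_distortion_p=presso.distortion_p,
        radial_q=radial.q_total,
        radial_outliers=radial.outliers,
        loo_estimates=loo.estimates,
        loo_stable=loo.stable,
        steiger_direction=st.direction_ok,
        steiger_p=st.pvalue,
    )
    report.verdict = classify_causal(est, report, alpha=alpha)
    return report, report.verdict
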