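"""LD score regression: SNP heritability and cross-trait genetic correlation.

Association chi-square statistics regressed on LD scores estimate the
variance a polygenic architecture explains (the slope, scaled by N/M) and
confounding/stratification (the intercept).  Cross-trait, the regression
of z-score products estimates genetic covariance with a free intercept
absorbing sample overlap.  Uncertainty comes from a delete-one block
jackknife over contiguous SNP blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError

__all__ = [
    "LdScoreTable",
    "HeritabilityEstimate",
    "RgEstimate",
    "estimate_h2",
    "genetic_correlation",
    "read_ldscore_tsv",
    "read_ldsc_sumstats_tsv",
]


@dataclass
class LdScoreTable:
    """Per-SNP LD scores and the total number of SNPs setting the h^2 scale."""

    df: pd.DataFrame  # snp_id, l2[, maf]
    m_total: float

    def __post_init__(self) -> None:
        if not {"snp_id", "l2"}.issubset(self.df.columns):
            raise DataError("LD score table needs columns snp_id, l2")
        if not np.isfinite(self.df["l2"]).all():
            raise DataError("non-finite LD scores")
        if self.m_total < len(self.df):
            raise DataError("m_total must be >= number of scored SNPs")


@dataclass
class HeritabilityEstimate:
    h2: float
    h2_se: float
    h2_p: float
    intercept: float
    intercept_se: float
    n_blocks: int
    n_snps: int


@dataclass
class RgEstimate:
    rg: float
    rg_se: float
    rg_p: float
    gencov: float
    gencov_intercept: float
    h2_1: float
    h2_2: float
    na_reason: str | None = None


def read_ldscore_tsv(path) -> LdScoreTable:
    """Headered TSV with columns SNP, L2[, MAF]; m_total from an M column or row count."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    out = pd.DataFrame({"snp_id": df[cols["snp"]], "l2": df[cols["l2"]].astype(float)})
    if "maf" in cols:
        out["maf"] = df[cols["maf"]].astype(float)
    m_total = float(df[cols["m"]].iloc[0]) if "m" in cols else float(len(out))
    return LdScoreTable(out, m_total)


def read_ldsc_sumstats_tsv(path) -> pd.DataFrame:
    """LDSC-style sumstats: TSV with columns SNP, Z, N[, A1, A2]."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    return pd.DataFrame(
        {
            "snp_id": df[cols["snp"]],
            "z": df[cols["z"]].astype(float),
            "n": df[cols["n"]].astype(float),
        }
    )


def _block_bounds(n: int, n_blocks: int) -> list[tuple[int, int]]:
    n_blocks = min(n_blocks, n)
    edges = np.linspace(0, n, n_blocks + 1).astype(int)
    return [(edges[i], edges[i + 1]) for i in range(n_blocks)]


def _wls_sufficient(x, y, w, bounds):
    """Per-block X'WX / X'Wy for design [1, x]; returns (A_blocks, c_blocks)."""
    a = np.empty((len(bounds), 2, 2))
    c = np.empty((len(bounds), 2))
    for i, (lo, hi) in enumerate(bounds):
        wi, xi, yi = w[lo:hi], x[lo:hi], y[lo:hi]
        sw, swx, swxx = wi.sum(), (wi * xi).sum(), (wi * xi * xi).sum()
        a[i] = [[sw, swx], [swx, swxx]]
        c[i] = [(wi * yi).sum(), (wi * xi * yi).sum()]
    return a, c


def _solve(a, c):
    det = a[0, 0] * a[1, 1] - a[0, 1] ** 2
    intercept = (a[1, 1] * c[0] - a[0, 1] * c[1]) / det
    slope = (a[0, 0] * c[1] - a[0, 1] * c[0]) / det
    return intercept, slope


def _jackknife(a_blocks, c_blocks):
    """Full fit plus delete-one-block SEs for (intercept, slope)."""
    a_tot = a_blocks.sum(axis=0)
    c_tot = c_blocks.sum(axis=0)
    full = _solve(a_tot, c_tot)
    b = len(a_blocks)
    dels = np.array([_solve(a_tot - a_blocks[i], c_tot - c_blocks[i]) for i in range(b)])
    mean = dels.mean(axis=0)
    se = np.sqrt((b - 1) / b * np.sum((dels - mean) ** 2, axis=0))
    return full, se, dels


def estimate_h2(
    sumstats: pd.DataFrame,
    scores: LdScoreTable,
    chisq_max: float | None = None,
    n_blocks: int = 200,
    min_snps: int = 200,
) -> HeritabilityEstimate:
    """Univariate LD score regression.

    ``sumstats`` needs columns (snp_id, z, n).  The regression is
    chi^2_j = intercept + h2 * (N_j * l_j / M) + noise, fitted by weighted
    least squares with weights iterated twice from an unweighted fit.
    Extreme statistics (chi^2 > chisq_max, default max(80, 0.001*N)) are
    excluded.  SEs by delete-one block jackknife over ``n_blocks``
    contiguous blocks in the table's SNP order.
    """
    merged = sumstats.merge(scores.df, on="snp_id", how="inner")
    if len(merged) < min_snps:
        raise DataError(f"only {len(merged)} SNPs merged with LD scores (< {min_snps})")
    n_bar = merged["n"].mean()
    if chisq_max is None:
        chisq_max = max(80.0, 0.001 * n_bar)
    chisq = merged["z"].to_numpy() ** 2
    keep = chisq <= chisq_max
    merged, chisq = merged.loc[keep], chisq[keep]
    l2 = merged["l2"].to_numpy(dtype=float)
    if np.ptp(l2) < 1e-12:
        raise DataError("LD scores have zero variance; h2 unidentifiable")
    x = merged["n"].to_numpy() * l2 / scores.m_total

    w = np.ones_like(x)
    intercept, h2 = 0.0, 0.0
    for _ in range(3):  # unweighted fit, then two weight updates
        bounds = _block_bounds(len(x), n_blocks)
        a, c = _wls_sufficient(x, chisq, w, bounds)
        (intercept, h2), _, _ = _jackknife(a, c)
        h2_w = float(np.clip(h2, 0.0, 1.0))
        w = 1.0 / (2.0 * (1.0 + h2_w * x + (intercept - 1.0)) ** 2) / np.maximum(l2, 1.0)

    bounds = _block_bounds(len(x), n_blocks)
    a, c = _wls_sufficient(x, chisq, w, bounds)
    (intercept, h2), (int_se, h2_se), _ = _jackknife(a, c)
    p = float(2.0 * sps.norm.sf(abs(h2) / h2_se)) if h2_se > 0 else float("nan")
    return HeritabilityEstimate(
        float(h2), float(h2_se), p, float(intercept), float(int_se),
        n_blocks=len(bounds), n_snps=len(x),
    )


def genetic_correlation(
    sumstats1: pd.DataFrame,
    sumstats2: pd.DataFrame,
    scores: LdScoreTable,
    n_blocks: int = 200,
    min_snps: int = 200,
) -> RgEstimate:
    """Cross-trait LD score regression.

    Regresses z1*z2 on sqrt(N1*N2)*l/M with a free intercept (absorbing
    sample overlap); rg = gencov / sqrt(h2_1 * h2_2).  The jackknife
    re-derives all three regressions per deleted block so the SE propagates
    through the ratio.  Non-positive heritability in either trait yields a
    flagged non-estimate rather than a number.
    """
    m = sumstats1.merge(sumstats2, on="snp_id", suffixes=("_1", "_2")).merge(
        scores.df, on="snp_id"
    )
    if len(m) < min_snps:
        raise DataError(f"only {len(m)} shared SNPs (< {min_snps})")
    uni1 = estimate_h2(
        m[["snp_id", "z_1", "n_1"]].rename(columns={"z_1": "z", "n_1": "n"}),
        scores, n_blocks=n_blocks, min_snps=min_snps,
    )
    uni2 = estimate_h2(
        m[["snp_id", "z_2", "n_2"]].rename(columns={"z_2": "z", "n_2": "n"}),
        scores, n_blocks=n_blocks, min_snps=min_snps,
    )
    if uni1.h2 <= 0 or uni2.h2 <= 0:
        return RgEstimate(
            float("nan"), float("nan"), float("nan"), float("nan"), float("nan"),
            uni1.h2, uni2.h2, na_reason="non-positive heritability",
        )

    l2 = m["l2"].to_numpy(dtype=float)
    y = (m["z_1"] * m["z_2"]).to_numpy(dtype=float)
    n1 = m["n_1"].to_numpy(dtype=float)
    n2 = m["n_2"].to_numpy(dtype=float)
    x_co = np.sqrt(n1 * n2) * l2 / scores.m_total
    x1 = n1 * l2 / scores.m_total
    x2 = n2 * l2 / scores.m_total
    chisq1 = m["z_1"].to_numpy() ** 2
    chisq2 = m["z_2"].to_numpy() ** 2

    h1w = float(np.clip(uni1.h2, 0.0, 1.0))
    h2w = float(np.clip(uni2.h2, 0.0, 1.0))
    v1 = 1.0 + h1w * x1 + (uni1.intercept - 1.0)
    v2 = 1.0 + h2w * x2 + (uni2.intercept - 1.0)
    w1 = 1.0 / (2.0 * v1**2) / np.maximum(l2, 1.0)
    w2 = 1.0 / (2.0 * v2**2) / np.maximum(l2, 1.0)

    # one pilot fit of the covariance line to set its weights
    bounds = _block_bounds(len(y), n_blocks)
    a_co, c_co = _wls_sufficient(x_co, y, 1.0 / np.maximum(l2, 1.0) / (v1 * v2), bounds)
    (int_co, gencov0), _, _ = _jackknife(a_co, c_co)
    expected_co = gencov0 * x_co + int_co
    w_co = 1.0 / (v1 * v2 + expected_co**2) / np.maximum(l2, 1.0)

    a_co, c_co = _wls_sufficient(x_co, y, w_co, bounds)
    a_1, c_1 = _wls_sufficient(x1, chisq1, w1, bounds)
    a_2, c_2 = _wls_sufficient(x2, chisq2, w2, bounds)
    (int_co, gencov), _, dels_co = _jackknife(a_co, c_co)
    (_, h2_1), _, dels_1 = _jackknife(a_1, c_1)
    (_, h2_2), _, dels_2 = _jackknife(a_2, c_2)

    rg_full = gencov / np.sqrt(h2_1 * h2_2)
    prod = dels_1[:, 1] * dels_2[:, 1]
    ok = prod > 0
    if ok.sum() < 2:
        return RgEstimate(
            float(rg_full), float("nan"), float("nan"), float(gencov), float(int_co),
            float(h2_1), float(h2_2), na_reason="jackknife degenerate",
        )
    rg_dels = dels_co[ok, 1] / np.sqrt(prod[ok])
    b = int(ok.sum())
    rg_se = float(np.sqrt((b - 1) / b * np.sum((rg_dels - rg_dels.mean()) ** 2)))
    rg_p = float(2.0 * sps.norm.sf(abs(rg_full) / rg_se)) if rg_se > 0 else float("nan")
    return RgEstimate(
        float(rg_full), rg_se, rg_p, float(gencov), float(int_co),
        float(h2_1), float(h2_2),
    )
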