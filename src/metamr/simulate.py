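"""Synthetic GWAS summary statistics with known ground truth.

Emulates the data structures of a metabolite-on-disease MR study — an
exposure GWAS of a standardized continuous trait (a serum metabolite in a
cohort of a few thousand) paired with a large case-control outcome GWAS —
entirely at the summary level.  Per-SNP true exposure effects gamma_j are
set to hit a target variance-explained range; outcome effects follow
Gamma_j = theta * gamma_j + alpha_j where alpha_j is a direct (pleiotropic)
effect on the outcome carried by an "invalid" subset of instruments.
Observed betas add sampling noise with the analytic SEs
se_X = 1/sqrt(2 N_X p(1-p)) and se_Y = 1/sqrt(2 N_Y p(1-p) K(1-K)).

A companion generator draws LDSC-consistent z-scores for two traits with
chosen heritabilities and genetic correlation.

Everything is a pure function of (config, seed): identical inputs give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigError
from .instruments import LdMatrix
from .ldsc import LdScoreTable
from .sumstats import SummaryStats

__all__ = [
    "SimConfig",
    "SimTruth",
    "LdscTruth",
    "simulate_pair",
    "simulate_screen",
    "simulate_ldsc_traits",
    "preset",
    "ldsc_preset",
    "PRESETS",
    "LDSC_PRESETS",
]

#: outcome case fraction of a large biobank-style thyroid-autoimmunity GWAS
DEFAULT_CASE_FRACTION = 2836.0 / 377277.0


@dataclass
class SimConfig:
    """Generating parameters for one exposure/outcome summary-statistic pair.

    Defaults are the "clean" validation conditions: 50 valid instruments,
    causal effect 0.3 on the log-odds scale, exposure cohort of 7824, and a
    377 277-sample outcome with ~0.75% cases.  Instrument strengths are
    deliberately heterogeneous (per-SNP R^2 uniform on 0.01%-3%) so that
    regression-based estimators operate in their intended strong-instrument
    regime.
    """

    n_snps: int = 50
    n_exposure: float = 7824.0
    n_outcome: float = 377277.0
    case_fraction: float = DEFAULT_CASE_FRACTION
    theta_true: float = 0.3
    pleiotropy_mode: str = "none"  # none | balanced | directional | outlier
    pleiotropy_sd: float = 0.0
    pleiotropy_mean: float = 0.0
    invalid_fraction: float = 0.0
    outlier_scale: float = 10.0  # offset in units of the SNP's outcome SE
    maf_range: tuple[float, float] = (0.1, 0.9)
    instrument_r2_range: tuple[float, float] = (0.0001, 0.03)
    n_null_snps: int = 0
    ld_block_sizes: tuple[int, ...] | None = None
    ld_within_block_r2: float = 0.0
    seed: int = 0
    exposure_id: str = "sim_exposure"
    outcome_id: str = "sim_outcome"

    def __post_init__(self) -> None:
        if not (0 <= self.invalid_fraction <= 1):
            raise ConfigError("invalid_fraction must be in [0,1]")
        if not (0 < self.case_fraction < 1):
            raise ConfigError("case_fraction must be in (0,1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi < 1):
            raise ConfigError("maf_range must be an ordered pair inside (0,1)")
        lo, hi = self.instrument_r2_range
        if not (0 < lo <= hi < 1):
            raise ConfigError("instrument_r2_range targets must be ordered in (0,1)")
        if self.pleiotropy_mode not in ("none", "balanced", "directional", "outlier"):
            raise ConfigError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if not (0 <= self.ld_within_block_r2 <= 1):
            raise ConfigError("ld_within_block_r2 must be in [0,1]")


@dataclass
class SimTruth:
    """Ground truth of one simulated pair, for recovery tests."""

    theta_true: float
    gamma: np.ndarray  # true per-allele exposure effects (instruments + nulls)
    alpha: np.ndarray  # direct pleiotropic effects on the outcome
    eaf: np.ndarray
    total_r2: float
    invalid_snps: list[str] = field(default_factory=list)
    snp_ids: list[str] = field(default_factory=list)


@dataclass
class LdscTruth:
    h2_1: float
    h2_2: float
    rg: float


def _positions(n: int, block_sizes) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Block-contiguous positions: 10 kb spacing in-block, 10 Mb between blocks."""
    if block_sizes is None:
        blocks = [1] * n
    else:
        blocks = list(block_sizes)
        if sum(blocks) != n:
            raise ConfigError("ld_block_sizes must sum to the total SNP count")
    pos = np.empty(n, dtype=int)
    bounds = []
    i = 0
    for k, size in enumerate(blocks):
        start = 1 + k * 10_000_000
        pos[i : i + size] = start + 10_000 * np.arange(size)
        bounds.append((i, i + size))
        i += size
    return pos, bounds


def simulate_pair(cfg: SimConfig):
    """Draw one exposure/outcome pair plus its LD matrix and ground truth.

    Returns ``(exposure, outcome, ld, truth)``.  Instruments come first
    (ids ``rs000000`` ...), then ``n_null_snps`` null SNPs with zero effect
    on either trait.  The LD matrix is block-diagonal with
    ``ld_within_block_r2`` off the diagonal inside each block; it is
    consumed by clumping and does not correlate the sampling noise.
    """
    rng = np.random.default_rng(cfg.seed)
    j = cfg.n_snps
    total = j + cfg.n_null_snps
    snp_ids = [f"rs{i:06d}" for i in range(total)]

    eaf = rng.uniform(*cfg.maf_range, size=total)
    het = 2.0 * eaf * (1.0 - eaf)

    r2_target = rng.uniform(*cfg.instrument_r2_range, size=j)
    gamma = np.zeros(total)
    # effect allele taken as the exposure-increasing allele, so gamma >= 0
    gamma[:j] = np.sqrt(r2_target / het[:j])

    alpha = np.zeros(total)
    invalid_idx = np.array([], dtype=int)
    k = cfg.case_fraction
    se_x = 1.0 / np.sqrt(2.0 * cfg.n_exposure * eaf * (1.0 - eaf))
    se_y = 1.0 / np.sqrt(2.0 * cfg.n_outcome * eaf * (1.0 - eaf) * k * (1.0 - k))
    if cfg.pleiotropy_mode == "outlier":
        invalid_idx = rng.choice(j, size=1, replace=False)
        alpha[invalid_idx] = cfg.outlier_scale * se_y[invalid_idx]
    elif cfg.pleiotropy_mode in ("balanced", "directional"):
        n_invalid = int(round(cfg.invalid_fraction * j))
        invalid_idx = rng.choice(j, size=n_invalid, replace=False)
        mean = cfg.pleiotropy_mean if cfg.pleiotropy_mode == "directional" else 0.0
        alpha[invalid_idx] = rng.normal(mean, cfg.pleiotropy_sd, size=n_invalid)

    gamma_out = cfg.theta_true * gamma + alpha
    b_x = rng.normal(gamma, se_x)
    b_y = rng.normal(gamma_out, se_y)
    p_x = np.clip(2.0 * sps.norm.sf(np.abs(b_x / se_x)), 1e-300, 1.0)
    p_y = np.clip(2.0 * sps.norm.sf(np.abs(b_y / se_y)), 1e-300, 1.0)

    pos, bounds = _positions(total, cfg.ld_block_sizes)
    base = {
        "snp_id": snp_ids,
        "chrom": "1",
        "pos": pos,
        "effect_allele": "A",
        "other_allele": "G",
        "eaf": eaf,
    }
    exposure = SummaryStats(
        cfg.exposure_id,
        pd.DataFrame({**base, "beta": b_x, "se": se_x, "pvalue": p_x,
                      "n": float(cfg.n_exposure)}),
    )
    outcome = SummaryStats(
        cfg.outcome_id,
        pd.DataFrame({**base, "beta": b_y, "se": se_y, "pvalue": p_y,
                      "n": float(cfg.n_outcome)}),
    )

    r2 = np.eye(total)
    for lo, hi in bounds:
        r2[lo:hi, lo:hi] = cfg.ld_within_block_r2
    np.fill_diagonal(r2, 1.0)
    ld = LdMatrix(snp_ids, r2)

    truth = SimTruth(
        theta_true=cfg.theta_true,
        gamma=gamma,
        alpha=alpha,
        eaf=eaf,
        total_r2=float(np.sum(het[:j] * gamma[:j] ** 2)),
        invalid_snps=[snp_ids[i] for i in np.sort(invalid_idx)],
        snp_ids=snp_ids,
    )
    return exposure, outcome, ld, truth


def simulate_screen(thetas: dict[str, float], base: SimConfig):
    """A metabolome-screen scenario: many exposures, one shared outcome.

    ``thetas`` maps exposure id to its true causal effect on the common
    outcome.  Each exposure gets its own SNP panel (distinct ids, its own
    chromosome) drawn from ``base`` with a per-exposure derived seed; the
    outcome table stacks the per-panel outcome rows and the LD matrix is
    block-diagonal across panels.

    Returns ``(exposures, outcome, ld, truths)`` with ``truths`` keyed by
    exposure id.
    """
    exposures, out_frames, truths = [], [], {}
    ld_ids: list[str] = []
    ld_blocks: list[np.ndarray] = []
    for i, (exp_id, theta) in enumerate(thetas.items()):
        cfg = replace(
            base,
            theta_true=theta,
            seed=int((base.seed * 1_000_003 + i) % 2_147_483_647),
            exposure_id=exp_id,
        )
        exp, out, ld, truth = simulate_pair(cfg)
        rename = {s: f"{exp_id}_{s}" for s in truth.snp_ids}
        for stats in (exp, out):
            stats.df["snp_id"] = stats.df["snp_id"].map(rename)
            stats.df["chrom"] = str(i + 1)
        truth.snp_ids = [rename[s] for s in truth.snp_ids]
        truth.invalid_snps = [rename[s] for s in truth.invalid_snps]
        exposures.append(exp)
        out_frames.append(out.df)
        truths[exp_id] = truth
        ld_ids.extend(truth.snp_ids)
        ld_blocks.append(ld.r2)
    n = len(ld_ids)
    r2 = np.eye(n)
    ofs = 0
    for block in ld_blocks:
        k = block.shape[0]
        r2[ofs : ofs + k, ofs : ofs + k] = block
        ofs += k
    outcome = SummaryStats(base.outcome_id, pd.concat(out_frames, ignore_index=True))
    return exposures, outcome, LdMatrix(ld_ids, r2), truths


def simulate_ldsc_traits(
    n_snps: int,
    h2_1: float,
    h2_2: float,
    rg: float,
    n1: float,
    n2: float,
    seed: int,
    ld_scores_spec: dict | None = None,
):
    """Draw LDSC-consistent z-scores for two traits over one SNP panel.

    Per SNP, (z1, z2) is bivariate normal with variances
    1 + N_i h2_i l_j / M and covariance rg sqrt(h2_1 h2_2 N1 N2) l_j / M.
    LD scores are Gamma-distributed (shape/scale in ``ld_scores_spec``,
    defaults 4.0/25.0), clipped below at 1; ``m_total`` (default 1e6)
    represents the full polygenic SNP count of which the panel is a sample.

    Returns ``(z1_df, z2_df, LdScoreTable, LdscTruth)`` where the z frames
    have columns (snp_id, z, n).
    """
    if abs(rg) > 1:
        raise ConfigError("|rg| must be <= 1")
    for h2 in (h2_1, h2_2):
        if not (0 <= h2 <= 1):
            raise ConfigError("h2 must be in [0,1]")
    spec = {"shape": 4.0, "scale": 25.0, "m_total": 1_000_000.0}
    spec.update(ld_scores_spec or {})
    rng = np.random.default_rng(seed)
    l2 = np.maximum(rng.gamma(spec["shape"], spec["scale"], size=n_snps), 1.0)
    m = float(spec["m_total"])

    v1 = 1.0 + n1 * h2_1 * l2 / m
    v2 = 1.0 + n2 * h2_2 * l2 / m
    cov = rg * np.sqrt(h2_1 * h2_2 * n1 * n2) * l2 / m
    resid = v2 - cov**2 / v1
    if np.any(resid < 0):
        raise ConfigError("per-SNP covariance matrix not positive semidefinite")
    a = rng.standard_normal(n_snps)
    b = rng.standard_normal(n_snps)
    z1 = np.sqrt(v1) * a
    z2 = cov / np.sqrt(v1) * a + np.sqrt(resid) * b

    snp_ids = [f"rs{i:06d}" for i in range(n_snps)]
    z1_df = pd.DataFrame({"snp_id": snp_ids, "z": z1, "n": float(n1)})
    z2_df = pd.DataFrame({"snp_id": snp_ids, "z": z2, "n": float(n2)})
    scores = LdScoreTable(pd.DataFrame({"snp_id": snp_ids, "l2": l2}), m)
    return z1_df, z2_df, scores, LdscTruth(h2_1, h2_2, rg)


# ---------------------------------------------------------------------------
# Named presets: the study conditions exercised by the validation suite.

PRESETS: dict[str, dict] = {
    # no pleiotropy; estimator recovery and type-I-error conditions
    "clean": {},
    # 30% invalid instruments, zero-mean direct effects: heterogeneity
    # without directional bias
    "balanced_pleiotropy": {
        "pleiotropy_mode": "balanced",
        "invalid_fraction": 0.3,
        "pleiotropy_sd": 0.05,
    },
    # 40% invalid instruments with a systematic positive direct effect, on a
    # well-powered balanced case-control outcome so the contamination — not
    # sampling noise — dominates the estimator contrast
    "directional_pleiotropy": {
        "pleiotropy_mode": "directional",
        "invalid_fraction": 0.4,
        "pleiotropy_mean": 0.1,
        "pleiotropy_sd": 0.05,
        "case_fraction": 0.3,
    },
    # a single planted pleiotropic SNP offset by 10x its outcome SE
    "one_outlier": {
        "n_snps": 20,
        "pleiotropy_mode": "outlier",
        "outlier_scale": 10.0,
    },
    # the weighted-median breakdown boundary: half the instruments invalid
    "half_invalid": {
        "pleiotropy_mode": "directional",
        "invalid_fraction": 0.5,
        "pleiotropy_mean": 0.1,
        "pleiotropy_sd": 0.05,
        "case_fraction": 0.3,
    },
}

LDSC_PRESETS: dict[str, dict] = {
    # heritable traits, no genetic correlation
    "ldsc_null": {"h2_1": 0.3, "h2_2": 0.2, "rg": 0.0, "n1": 50000.0,
                  "n2": 50000.0, "n_snps": 10000},
    # moderate genetic correlation
    "ldsc_rg05": {"h2_1": 0.3, "h2_2": 0.2, "rg": 0.5, "n1": 50000.0,
                  "n2": 50000.0, "n_snps": 10000},
}


def preset(name: str, seed: int, **overrides) -> SimConfig:
    """A named SimConfig with its seed set; ``overrides`` adjust fields."""
    if name not in PRESETS:
        raise ConfigError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return replace(SimConfig(seed=seed), **{**PRESETS[name], **overrides})


def ldsc_preset(name: str, seed: int, **overrides):
    """Simulate one of the named LDSC scenarios."""
    if name not in LDSC_PRESETS:
        raise ConfigError(f"unknown preset {name!r}; choose from {sorted(LDSC_PRESETS)}")
    kw = {**LDSC_PRESETS[name], **overrides}
    return simulate_ldsc_traits(seed=seed, **kw)
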