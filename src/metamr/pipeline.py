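"""Metabolome-wide screen orchestration.

Runs many exposures against one outcome through the full funnel —
significance filter, LD clumping, strength filter, outcome pruning,
confounder screen, harmonization, minimum-instrument rule — then the
estimator trio, the sensitivity suite and the composite verdict, and
finally reverse-direction MR and LDSC follow-up for supported hits.

The screen reports both raw IVW p-values and Benjamini-Hochberg adjusted
q-values; the verdict is computed on the raw p by default (the historical
convention for hypothesis-generating metabolome screens), switchable to
the adjusted q.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import instruments as ins
from .errors import ConfigError, MetamrError
from .estimators import egger, ivw, mr_power, weighted_median
from .ldsc import LdScoreTable, estimate_h2, genetic_correlation
from .sensitivity import classify_causal, run_sensitivity
from .sumstats import HarmonizedSet, SummaryStats, harmonize

__all__ = [
    "PipelineConfig",
    "ScreenReport",
    "PairResult",
    "analyze_pair",
    "run_screen",
    "run_reverse",
    "ldsc_followup",
]


@dataclass
class PipelineConfig:
    """Selection thresholds plus screen-level settings and seeds."""

    selection: ins.SelectionConfig = field(default_factory=ins.SelectionConfig)
    alpha: float = 0.05
    palindrome_band: float = 0.08
    presso_n_sim: int = 1000
    wm_n_boot: int = 1000
    seed: int = 0
    confounder_traits: list[str] = field(default_factory=list)
    verdict_on_adjusted_p: bool = False
    #: case fraction of the outcome GWAS, used by the power calculation
    #: (summary tables rarely carry the case split)
    case_fraction_hint: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must be in (0,1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sel_keys = ins.SelectionConfig.__dataclass_fields__
        sel = ins.SelectionConfig(**{k: raw.pop(k) for k in list(raw) if k in sel_keys})
        known = {k: raw[k] for k in raw if k in cls.__dataclass_fields__ and k != "selection"}
        return cls(selection=sel, **known)


def _pair_seed(base: int, idx: int) -> int:
    # distinct reproducible substream per exposure, kept below 2**31
    return int((base * 1_000_003 + idx) % 2_147_483_647)


@dataclass
class PairResult:
    exposure_id: str
    verdict: str
    stage_counts: dict
    harmonized: HarmonizedSet | None = None
    instrument_set: ins.InstrumentSet | None = None
    estimates: dict = field(default_factory=dict)  # method -> MREstimate
    egger_intercept: object | None = None
    sensitivity: object | None = None
    power: float | None = None
    error: str | None = None

    def summary_row(self) -> dict:
        row = {"exposure_id": self.exposure_id, "verdict": self.verdict}
        row.update({f"n_{k}": v for k, v in self.stage_counts.items()})
        for method, est in self.estimates.items():
            for key, val in est.as_row().items():
                if key != "method":
                    row[f"{method.lower()}_{key}"] = val
        if self.sensitivity is not None:
            row.update({f"sens_{k}": v for k, v in self.sensitivity.as_row().items()
                        if k != "verdict"})
        row["power"] = self.power
        row["error"] = self.error
        return row


def analyze_pair(
    exposure: SummaryStats,
    outcome: SummaryStats,
    ld: ins.LdMatrix,
    cfg: PipelineConfig,
    annotations: pd.DataFrame | None = None,
    seed: int | None = None,
) -> PairResult:
    """Run one exposure-outcome pair through selection, estimation, diagnostics."""
    sel = cfg.selection
    seed = cfg.seed if seed is None else seed
    log: list = []
    counts: dict = {"input": exposure.n_snps}

    subset = ins.select_by_pvalue(exposure, sel)
    counts["significant"] = subset.n_snps
    subset = ins.clump(subset, ld, sel, log=log)
    counts["clumped"] = subset.n_snps
    if subset.n_snps:
        subset, per_snp, total_r2 = ins.instrument_strength(subset, sel, log=log)
    else:
        per_snp, total_r2 = pd.DataFrame(columns=["snp_id", "r2_explained", "f_stat"]), 0.0
    counts["strong"] = subset.n_snps
    subset = ins.prune_outcome_associated(subset, outcome, sel, log=log)
    counts["outcome_pruned"] = subset.n_snps
    if annotations is not None and cfg.confounder_traits:
        subset, _rep = ins.screen_confounders(subset, annotations, cfg.confounder_traits, log=log)
    counts["confounder_screened"] = subset.n_snps

    if subset.n_snps == 0:
        return PairResult(exposure.trait_id, "excluded_too_few_ivs", counts)
    h = harmonize(subset, outcome, palindrome_band=cfg.palindrome_band)
    counts["harmonized"] = h.n_snps

    kept = h.df["snp_id"]
    final_subset = subset.subset(subset.df["snp_id"].isin(set(kept)))
    per_snp = per_snp[per_snp["snp_id"].isin(set(kept))].reset_index(drop=True)
    total_r2 = float(per_snp["r2_explained"].sum())
    iset = ins.enforce_min_snps(final_subset, per_snp, total_r2, sel, log=log)
    if isinstance(iset, ins.ExclusionVerdict):
        return PairResult(exposure.trait_id, "excluded_too_few_ivs", counts, harmonized=h)

    result = PairResult(exposure.trait_id, "", counts, harmonized=h, instrument_set=iset)
    est_ivw = ivw(h)
    est_egger, intercept = egger(h)
    est_wm = weighted_median(h, n_boot=cfg.wm_n_boot, seed=seed)
    result.estimates = {"IVW": est_ivw, "Egger": est_egger, "WeightedMedian": est_wm}
    result.egger_intercept = intercept
    n_out = float(h.df["n_out"].mean())
    # power at the OR implied by the IVW point estimate
    result.power = mr_power(
        n_out, cfg.case_fraction_hint, total_r2, float(np.exp(est_ivw.beta)), cfg.alpha
    )
    report, verdict = run_sensitivity(
        h, seed=seed, n_sim=cfg.presso_n_sim, alpha=cfg.alpha, ivw_est=est_ivw
    )
    result.sensitivity = report
    result.verdict = verdict
    return result


@dataclass
class ScreenReport:
    table: pd.DataFrame
    header: dict
    loo_tables: dict = field(default_factory=dict)  # exposure_id -> long LOO table

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def forest_table(self) -> pd.DataFrame:
        """Tidy per-method rows (the forest-plot layout)."""
        rows = []
        for _, r in self.table.iterrows():
            for method in ("ivw", "egger", "weightedmedian"):
                if f"{method}_beta" not in r or pd.isna(r.get(f"{method}_beta", np.nan)):
                    continue
                rows.append(
                    {
                        "exposure": r["exposure_id"],
                        "method": method,
                        "nsnp": r.get(f"{method}_nsnp"),
                        "beta": r[f"{method}_beta"],
                        "se": r[f"{method}_se"],
                        "pvalue": r[f"{method}_pvalue"],
                        "or": r[f"{method}_or"],
                        "ci_low": r[f"{method}_ci_low"],
                        "ci_high": r[f"{method}_ci_high"],
                    }
                )
        return pd.DataFrame(rows)


def run_screen(
    exposures: list[SummaryStats],
    outcome: SummaryStats,
    ld: ins.LdMatrix,
    cfg: PipelineConfig,
    annotations: pd.DataFrame | None = None,
) -> ScreenReport:
    """Screen many exposures against one outcome.

    Per-exposure failures are isolated: a malformed exposure yields a row
    with verdict "failed" and the error message instead of aborting the
    screen.  IVW p-values are BH-adjusted across analyzed exposures; the
    verdict uses the raw p unless ``cfg.verdict_on_adjusted_p``.
    """
    if not exposures:
        raise ConfigError("empty exposure list")
    rows, loo_tables = [], {}
    for idx, exp in enumerate(exposures):
        seed = _pair_seed(cfg.seed, idx)
        try:
            res = analyze_pair(exp, outcome, ld, cfg, annotations=annotations, seed=seed)
        except MetamrError as exc:
            res = PairResult(exp.trait_id, "failed", {}, error=str(exc))
        rows.append(res.summary_row())
        if res.sensitivity is not None:
            loo_tables[exp.trait_id] = res.sensitivity.loo_estimates
    table = pd.DataFrame(rows)

    if "ivw_pvalue" in table.columns:
        mask = table["ivw_pvalue"].notna()
        q = pd.Series(np.nan, index=table.index)
        if mask.any():
            q[mask] = sps.false_discovery_control(table.loc[mask, "ivw_pvalue"], method="bh")
        table["ivw_q_bh"] = q
        if cfg.verdict_on_adjusted_p:
            flip = mask & (table["verdict"] == "supported") & (table["ivw_q_bh"] >= cfg.alpha)
            table.loc[flip, "verdict"] = "not_significant"

    header = {
        "n_exposures": len(exposures),
        "alpha": cfg.alpha,
        "seed": cfg.seed,
        "p_exposure": cfg.selection.p_exposure,
        "clump_r2": cfg.selection.clump_r2,
        "clump_window_kb": cfg.selection.clump_window_kb,
        "f_min": cfg.selection.f_min,
        "min_snps": cfg.selection.min_snps,
        "n_supported": int((table["verdict"] == "supported").sum()),
        "n_excluded_too_few_ivs": int((table["verdict"] == "excluded_too_few_ivs").sum()),
    }
    return ScreenReport(table, header, loo_tables)


def run_reverse(
    outcome_as_exposure: SummaryStats,
    exposure_as_outcome: SummaryStats,
    ld: ins.LdMatrix,
    cfg: PipelineConfig,
) -> PairResult:
    """Reverse-direction MR: identical machinery with the roles swapped.

    Instruments are re-selected from the (former) outcome GWAS at the same
    thresholds.  The verdict is "no_reverse_effect" when the reverse IVW p
    exceeds alpha, "reverse_effect_detected" when it does not, and
    "too_few_reverse_instruments" when the swapped exposure yields too few
    instruments.
    """
    res = analyze_pair(outcome_as_exposure, exposure_as_outcome, ld, cfg, seed=cfg.seed)
    if res.verdict == "excluded_too_few_ivs":
        res.verdict = "too_few_reverse_instruments"
        return res
    p = res.estimates["IVW"].pvalue
    res.verdict = "no_reverse_effect" if p > cfg.alpha else "reverse_effect_detected"
    return res


def ldsc_followup(
    hits: dict[str, pd.DataFrame],
    outcome_sumstats: pd.DataFrame,
    scores: LdScoreTable,
    alpha: float = 0.05,
    n_blocks: int = 200,
    min_snps: int = 200,
) -> pd.DataFrame:
    """Heritability and genetic correlation with the outcome for each hit.

    ``hits`` maps exposure id to an LDSC sumstats frame (snp_id, z, n).
    Hits with significant heritability proceed to the rg stage; a
    "shared_genetics_unlikely" flag is set when the rg p-value is above
    alpha (so co-heritability is an implausible confounder of the MR
    estimate).  Non-positive or unestimable heritability propagates as a
    flagged NA row, never a silent omission.
    """
    rows = []
    for exp_id, z_df in hits.items():
        row = {"exposure_id": exp_id, "h2": np.nan, "h2_se": np.nan, "h2_p": np.nan,
               "rg": np.nan, "rg_se": np.nan, "rg_p": np.nan,
               "shared_genetics_unlikely": False, "na_reason": ""}
        try:
            h2 = estimate_h2(z_df, scores, n_blocks=n_blocks, min_snps=min_snps)
            row.update(h2=h2.h2, h2_se=h2.h2_se, h2_p=h2.h2_p)
        except MetamrError as exc:
            row["na_reason"] = f"h2: {exc}"
            rows.append(row)
            continue
        if h2.h2 <= 0:
            row["na_reason"] = "non-positive heritability"
        elif h2.h2_p < alpha:
            rg = genetic_correlation(z_df, outcome_sumstats, scores,
                                     n_blocks=n_blocks, min_snps=min_snps)
            if rg.na_reason:
                row["na_reason"] = f"rg: {rg.na_reason}"
            else:
                row.update(rg=rg.rg, rg_se=rg.rg_se, rg_p=rg.rg_p)
                row["shared_genetics_unlikely"] = bool(rg.rg_p > alpha)
        else:
            row["na_reason"] = "heritability not significant"
        rows.append(row)
    return pd.DataFrame(rows)
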