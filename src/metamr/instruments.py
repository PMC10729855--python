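"""Instrument selection for two-sample MR.

The funnel applied to each exposure: genome-wide significance filter,
greedy LD clumping, instrument-strength (R^2, F) filtering, pruning of
SNPs directly associated with the outcome, confounder screening against a
local annotation table, and the minimum-instrument-count rule.  Every SNP
removed at any stage is accounted for exactly once in a selection log.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DataError
from .sumstats import SummaryStats

__all__ = [
    "SelectionConfig",
    "LdMatrix",
    "InstrumentSet",
    "ExclusionVerdict",
    "select_by_pvalue",
    "clump",
    "instrument_strength",
    "prune_outcome_associated",
    "screen_confounders",
    "enforce_min_snps",
]


@dataclass
class SelectionConfig:
    """Thresholds of the instrument-selection funnel.

    Defaults follow common practice for metabolite GWAS with modest sample
    sizes: exposure significance 1e-5, clumping at r^2 < 0.01 within
    +/-500 kb, outcome pruning at 1e-5, per-SNP F > 10, and at least 4
    instruments per exposure.
    """

    p_exposure: float = 1e-5
    clump_r2: float = 0.01
    clump_window_kb: float = 500.0
    p_outcome_prune: float = 1e-5
    f_min: float = 10.0
    min_snps: int = 4

    def __post_init__(self) -> None:
        for name in ("p_exposure", "clump_r2", "clump_window_kb", "p_outcome_prune", "f_min"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.min_snps < 2:
            raise ConfigError("min_snps must be >= 2")

    @classmethod
    def from_yaml(cls, path) -> "SelectionConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: raw[k] for k in raw if k in cls.__dataclass_fields__}
        return cls(**known)


class LdMatrix:
    """Squared-correlation matrix over an ordered SNP panel.

    Symmetric, unit diagonal, entries in [0, 1].  Pairs absent from the
    panel are treated as unlinked (r^2 = 0) by :meth:`r2_between`.
    """

    def __init__(self, snp_ids: list[str], r2: np.ndarray):
        r2 = np.asarray(r2, dtype=float)
        if r2.shape != (len(snp_ids), len(snp_ids)):
            raise DataError("LD matrix shape does not match snp_ids")
        if not np.allclose(r2, r2.T, atol=1e-8):
            raise DataError("LD matrix must be symmetric")
        if not np.allclose(np.diag(r2), 1.0, atol=1e-8):
            raise DataError("LD matrix diagonal must be 1")
        if r2.min() < -1e-12 or r2.max() > 1 + 1e-12:
            raise DataError("LD r^2 values must lie in [0, 1]")
        self.snp_ids = list(snp_ids)
        self.r2 = np.clip(r2, 0.0, 1.0)
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def r2_between(self, a: str, b: str) -> float:
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            return 0.0
        return float(self.r2[ia, ib])

    @classmethod
    def from_square_tsv(cls, path) -> "LdMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.columns), df.to_numpy(dtype=float))

    @classmethod
    def from_long_tsv(cls, path) -> "LdMatrix":
        """Triplet format: columns snp_a, snp_b, r2 (unlisted pairs are 0)."""
        df = pd.read_csv(path, sep="\t")
        ids = sorted(set(df["snp_a"]) | set(df["snp_b"]))
        idx = {s: i for i, s in enumerate(ids)}
        mat = np.eye(len(ids))
        for a, b, r2 in df[["snp_a", "snp_b", "r2"]].itertuples(index=False):
            mat[idx[a], idx[b]] = r2
            mat[idx[b], idx[a]] = r2
        return cls(ids, mat)

    def to_square_tsv(self, path) -> None:
        pd.DataFrame(self.r2, index=self.snp_ids, columns=self.snp_ids).to_csv(path, sep="\t")


@dataclass
class InstrumentSet:
    """A validated instrument panel for one exposure."""

    exposure_id: str
    snp_ids: list[str]
    per_snp: pd.DataFrame  # snp_id, r2_explained, f_stat, r2_formula
    total_r2: float
    selection_log: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["snp_id", "stage", "reason"])
    )


@dataclass
class ExclusionVerdict:
    exposure_id: str
    n_snps: int
    reason: str = "too_few_instruments"


def _log(entries: list, snp_ids, stage: str, reason: str) -> None:
    for s in snp_ids:
        entries.append({"snp_id": s, "stage": stage, "reason": reason})


def select_by_pvalue(stats: SummaryStats, cfg: SelectionConfig) -> SummaryStats:
    """Keep rows with p strictly below the exposure threshold, order preserved."""
    return stats.subset(stats.df["pvalue"] < cfg.p_exposure)


def clump(
    candidates: SummaryStats,
    ld: LdMatrix,
    cfg: SelectionConfig,
    log: list | None = None,
) -> SummaryStats:
    """Greedy LD clumping.

    Repeatedly promote the smallest-p remaining SNP (ties broken by
    lexicographic snp_id) to index status and discard remaining SNPs on the
    same chromosome within the window whose r^2 with the index reaches the
    threshold.  Candidates absent from the LD panel are treated as
    independent and noted in the log.  The result is ordered by p-value.
    """
    df = candidates.df
    order = df.sort_values(["pvalue", "snp_id"], kind="mergesort")
    remaining = list(order.itertuples(index=False))
    if log is not None:
        _log(log, [r.snp_id for r in remaining if r.snp_id not in ld],
             "clump", "absent_from_ld_panel_treated_independent")
    kept: list[str] = []
    window_bp = cfg.clump_window_kb * 1000.0
    while remaining:
        index_snp = remaining.pop(0)
        kept.append(index_snp.snp_id)
        survivors = []
        for row in remaining:
            linked = (
                row.chrom == index_snp.chrom
                and abs(row.pos - index_snp.pos) <= window_bp
                and ld.r2_between(index_snp.snp_id, row.snp_id) >= cfg.clump_r2
            )
            if linked:
                if log is not None:
                    _log(log, [row.snp_id], "clump", f"r2_with_{index_snp.snp_id}")
            else:
                survivors.append(row)
        remaining = survivors
    keep_order = {s: i for i, s in enumerate(kept)}
    out = df[df["snp_id"].isin(keep_order)].copy()
    out["_rank"] = out["snp_id"].map(keep_order)
    out = out.sort_values("_rank").drop(columns="_rank")
    return SummaryStats(candidates.trait_id, out.reset_index(drop=True))


def snp_r2(beta, se, eaf, n) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP variance explained, with the formula used per SNP.

    For a standardized continuous trait, r^2 = 2*eaf*(1-eaf)*beta^2 when the
    frequency is available; otherwise the z-score form
    r^2 = z^2/(z^2 + n - 2) with z = beta/se.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    eaf = np.asarray(eaf, dtype=float)
    n = np.asarray(n, dtype=float)
    z2 = (beta / se) ** 2
    r2_z = z2 / (z2 + n - 2)
    r2_eaf = 2.0 * eaf * (1.0 - eaf) * beta**2
    have_eaf = ~np.isnan(eaf)
    r2 = np.where(have_eaf, r2_eaf, r2_z)
    formula = np.where(have_eaf, "eaf", "zscore")
    return r2, formula


def instrument_strength(
    subset: SummaryStats,
    cfg: SelectionConfig,
    log: list | None = None,
) -> tuple[SummaryStats, pd.DataFrame, float]:
    """Per-SNP R^2 and F statistics; drops weak instruments (F <= f_min).

    F = r^2 (n - 2) / (1 - r^2) with the per-row sample size.  Returns the
    surviving subset, a per-SNP table (snp_id, r2_explained, f_stat,
    r2_formula) for survivors, and their summed R^2.
    """
    df = subset.df
    if (df["n"] <= 2).any():
        raise DataError("sample size must exceed 2 for instrument strength")
    r2, formula = snp_r2(df["beta"], df["se"], df["eaf"], df["n"])
    if (r2 >= 1).any():
        bad = df.loc[r2 >= 1, "snp_id"].tolist()
        raise DataError(f"per-SNP r^2 >= 1 for {bad}")
    f_stat = r2 * (df["n"].to_numpy() - 2) / (1.0 - r2)
    keep = f_stat > cfg.f_min
    if log is not None:
        _log(log, df.loc[~keep, "snp_id"], "strength", f"F<={cfg.f_min}")
    per_snp = pd.DataFrame(
        {
            "snp_id": df["snp_id"],
            "r2_explained": r2,
            "f_stat": f_stat,
            "r2_formula": formula,
        }
    ).loc[keep].reset_index(drop=True)
    return subset.subset(keep), per_snp, float(per_snp["r2_explained"].sum())


def prune_outcome_associated(
    subset: SummaryStats,
    outcome: SummaryStats,
    cfg: SelectionConfig,
    log: list | None = None,
) -> SummaryStats:
    """Remove instruments directly associated with the outcome (p < threshold).

    Instruments absent from the outcome table are retained here; the
    harmonization stage is responsible for dropping them with a reason.
    """
    out_p = outcome.df.set_index("snp_id")["pvalue"]
    p = subset.df["snp_id"].map(out_p)
    drop = p.notna() & (p < cfg.p_outcome_prune)
    if log is not None:
        _log(log, subset.df.loc[drop, "snp_id"], "outcome_prune",
             f"outcome_p<{cfg.p_outcome_prune}")
    return subset.subset(~drop)


def screen_confounders(
    subset: SummaryStats,
    annotations: pd.DataFrame,
    confounder_traits: list[str],
    log: list | None = None,
) -> tuple[SummaryStats, pd.DataFrame]:
    """Drop instruments annotated to designated confounder traits.

    ``annotations`` is a local lookup table with columns (snp_id, trait) —
    the offline replacement for a web-based phenotype scan.  Matching is
    case-insensitive substring against ``confounder_traits``.  Returns the
    pruned subset and a report of (snp_id, trait, action).
    """
    if annotations.empty or not confounder_traits:
        report = pd.DataFrame(columns=["snp_id", "trait", "action"])
        return subset, report
    ann = annotations.copy()
    lowered = [t.lower() for t in confounder_traits]
    trait_l = ann["trait"].astype(str).str.lower()
    hit = trait_l.apply(lambda t: any(c in t for c in lowered))
    hits = ann.loc[hit & ann["snp_id"].isin(subset.df["snp_id"])]
    flagged = set(hits["snp_id"])
    if log is not None:
        _log(log, sorted(flagged), "confounder", "annotated_confounder_trait")
    report = pd.DataFrame(
        {"snp_id": hits["snp_id"], "trait": hits["trait"], "action": "removed"}
    ).reset_index(drop=True)
    return subset.subset(~subset.df["snp_id"].isin(flagged)), report


def enforce_min_snps(
    subset: SummaryStats,
    per_snp: pd.DataFrame,
    total_r2: float,
    cfg: SelectionConfig,
    log: list | None = None,
):
    """Apply the minimum-instrument-count rule.

    Exposures retaining fewer than ``cfg.min_snps`` instruments are excluded
    with a verdict record (the rule is inclusive: exactly ``min_snps``
    instruments pass).  Otherwise an :class:`InstrumentSet` is produced.
    """
    n = subset.n_snps
    if n < cfg.min_snps:
        return ExclusionVerdict(subset.trait_id, n)
    log_df = pd.DataFrame(log or [], columns=["snp_id", "stage", "reason"])
    return InstrumentSet(
        exposure_id=subset.trait_id,
        snp_ids=subset.df["snp_id"].tolist(),
        per_snp=per_snp,
        total_r2=total_r2,
        selection_log=log_df,
    )
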