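"""GWAS summary-statistic tables: reading, validation, writing, and allele harmonization.

A :class:`SummaryStats` holds one trait's per-SNP association summaries
(identifier, coordinates, alleles, effect-allele frequency, beta, SE,
p-value, sample size).  For binary traits the beta is a per-allele
log-odds.  :func:`harmonize` aligns an exposure and an outcome table onto
a common effect allele, dropping palindromic SNPs with ambiguous strand
and allele-incompatible SNPs, which is the prerequisite for every
two-sample Mendelian randomization estimator downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyHarmonizationError, EmptyInputError, SumstatsFormatError

__all__ = [
    "SummaryStats",
    "HarmonizedSet",
    "read_sumstats",
    "write_sumstats",
    "harmonize",
    "DIALECTS",
]

CANONICAL_COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
]

#: columns that must be present after dialect mapping; ``eaf`` may be missing
MANDATORY = [c for c in CANONICAL_COLUMNS if c != "eaf"]

#: built-in column-name dialects.  "finngen" mirrors the release-format headers
#: of the FinnGen summary files; "generic" is the identity mapping.
DIALECTS: dict[str, dict[str, str]] = {
    "generic": {c: c for c in CANONICAL_COLUMNS},
    "finngen": {
        "rsids": "snp_id",
        "#chrom": "chrom",
        "pos": "pos",
        "alt": "effect_allele",
        "ref": "other_allele",
        "af_alt": "eaf",
        "beta": "beta",
        "sebeta": "se",
        "pval": "pvalue",
        "n": "n",
    },
}

_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class SummaryStats:
    """Validated per-SNP association table for a single trait."""

    trait_id: str
    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise SumstatsFormatError(
                f"{self.trait_id}: missing canonical columns {missing}"
            )
        self.df = self.df[CANONICAL_COLUMNS].reset_index(drop=True)

    @property
    def n_snps(self) -> int:
        return len(self.df)

    def subset(self, mask) -> "SummaryStats":
        return SummaryStats(self.trait_id, self.df.loc[mask].reset_index(drop=True))

    def indexed(self) -> pd.DataFrame:
        return self.df.set_index("snp_id", drop=False)


@dataclass
class HarmonizedSet:
    """Exposure/outcome effect pairs expressed on a shared effect allele.

    ``df`` columns: snp_id, b_exp, se_exp, b_out, se_out, eaf, n_exp, n_out.
    ``dropped`` columns: snp_id, reason in {palindromic, allele_mismatch,
    missing_in_outcome}.
    """

    exposure_id: str
    outcome_id: str
    df: pd.DataFrame
    dropped: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["snp_id", "reason"])
    )

    @property
    def n_snps(self) -> int:
        return len(self.df)

    def write_drop_report(self, path) -> None:
        self.dropped.to_csv(path, sep="\t", index=False)


def validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a raw canonical-column frame into (valid, rejected-with-reason)."""
    reasons = pd.Series("", index=df.index, dtype=object)

    def flag(mask, why):
        nonlocal reasons
        mask = mask & (reasons == "")
        reasons[mask] = why

    num = {}
    for col in ["pos", "eaf", "beta", "se", "pvalue", "n"]:
        num[col] = pd.to_numeric(df[col], errors="coerce")

    ea = df["effect_allele"].astype(str).str.upper()
    oa = df["other_allele"].astype(str).str.upper()

    flag(df["snp_id"].isna() | (df["snp_id"].astype(str) == ""), "missing snp_id")
    flag(~ea.isin(list(_VALID_ALLELES)), "invalid effect_allele")
    flag(~oa.isin(list(_VALID_ALLELES)), "invalid other_allele")
    flag(ea == oa, "effect_allele == other_allele")
    flag(num["pos"].isna() | (num["pos"] < 1), "invalid pos")
    flag(num["beta"].isna(), "missing beta")
    flag(num["se"].isna() | (num["se"] <= 0), "se not > 0")
    flag(num["pvalue"].isna() | (num["pvalue"] <= 0) | (num["pvalue"] > 1), "pvalue outside (0,1]")
    flag(num["n"].isna() | (num["n"] <= 1), "n not > 1")
    # eaf is optional but, when present, must be an open-interval fraction
    flag(num["eaf"].notna() & ((num["eaf"] <= 0) | (num["eaf"] >= 1)), "eaf outside (0,1)")
    flag(df["snp_id"].duplicated(keep="first"), "duplicate snp_id")

    ok = reasons == ""
    valid = df.loc[ok].copy()
    valid["effect_allele"] = ea[ok]
    valid["other_allele"] = oa[ok]
    for col in ["pos", "eaf", "beta", "se", "pvalue", "n"]:
        valid[col] = num[col][ok]
    valid["pos"] = valid["pos"].astype(int)
    valid["n"] = valid["n"].astype(float)
    rejected = pd.DataFrame(
        {"snp_id": df.loc[~ok, "snp_id"].astype(str), "reason": reasons[~ok]}
    ).reset_index(drop=True)
    return valid.reset_index(drop=True), rejected


def read_sumstats(
    path,
    dialect: str | dict[str, str] = "generic",
    trait_id: str | None = None,
    return_rejects: bool = False,
):
    """Read a headered (optionally gzipped) TSV of GWAS summary statistics.

    ``dialect`` maps file column names to the canonical schema; it is either
    a key of :data:`DIALECTS` or an explicit ``{file_col: canonical_col}``
    mapping.  Rows failing type or range checks are rejected with a per-row
    reason; zero valid rows is an error.
    """
    mapping = DIALECTS[dialect] if isinstance(dialect, str) else dict(dialect)
    raw = pd.read_csv(path, sep="\t", dtype=str, compression="infer")
    present = [c for c in mapping if c in raw.columns]
    mapped = {mapping[c] for c in present}
    missing = [c for c in MANDATORY if c not in mapped]
    if missing:
        raise SumstatsFormatError(f"{path}: missing mandatory column(s) {missing}")
    df = raw[present].rename(columns=mapping)
    if "eaf" not in df.columns:
        df["eaf"] = np.nan
    valid, rejected = validate_rows(df)
    if valid.empty:
        raise EmptyInputError(f"{path}: no valid rows after validation")
    stats = SummaryStats(trait_id or str(path), valid)
    if return_rejects:
        return stats, rejected
    return stats


def write_sumstats(stats: SummaryStats, path) -> None:
    """Write the canonical TSV dialect (gzip inferred from suffix)."""
    stats.df.to_csv(path, sep="\t", index=False, compression="infer")


def harmonize(
    exposure: SummaryStats,
    outcome: SummaryStats,
    palindrome_band: float = 0.08,
) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect allele per SNP.

    Swapped allele labels flip the outcome beta sign and complement its
    frequency; strand flips (A/G vs T/C) are resolved by complementing the
    outcome alleles before comparison.  Palindromic (A/T, C/G) SNPs whose
    exposure effect-allele frequency lies within ``palindrome_band`` of 0.5
    — or that lack a frequency on either side — are dropped as
    strand-ambiguous; outside the band the frequencies disambiguate the
    strand.  Remaining incompatibilities are dropped as allele mismatches.
    """
    if not 0 <= palindrome_band < 0.5:
        raise ValueError("palindrome_band must be in [0, 0.5)")
    if not set(exposure.df["snp_id"]) & set(outcome.df["snp_id"]):
        raise EmptyHarmonizationError(
            f"no shared SNPs between {exposure.trait_id} and {outcome.trait_id}"
        )
    mg = exposure.df.merge(
        outcome.df, on="snp_id", how="left", suffixes=("", "_o"), validate="1:1"
    )
    e_ea, e_oa = mg["effect_allele"], mg["other_allele"]
    o_ea, o_oa = mg["effect_allele_o"], mg["other_allele_o"]
    shared = o_ea.notna()
    comp_o_ea = o_ea.map(_COMPLEMENT)
    comp_o_oa = o_oa.map(_COMPLEMENT)

    palin = e_ea.map(_COMPLEMENT) == e_oa
    direct = (o_ea == e_ea) & (o_oa == e_oa)
    swapped = (o_ea == e_oa) & (o_oa == e_ea)
    flip_direct = (comp_o_ea == e_ea) & (comp_o_oa == e_oa)
    flip_swapped = (comp_o_ea == e_oa) & (comp_o_oa == e_ea)

    b_out = mg["beta_o"].copy()
    eaf_out = mg["eaf_o"].copy()
    swap = np.zeros(len(mg), dtype=bool)

    # non-palindromic: complement-then-compare; a label swap flips the sign
    swap |= ~palin & (swapped | flip_swapped)
    ok = shared & (direct | swapped | flip_direct | flip_swapped)

    # palindromic: labels always match both ways; frequencies must
    # disambiguate the strand and stay clear of 0.5
    palin_labels_ok = direct | swapped  # set equality for a palindrome
    palin_informative = (
        mg["eaf"].notna()
        & eaf_out.notna()
        & ((mg["eaf"] - 0.5).abs() > palindrome_band)
    )
    palin_ok = shared & palin & palin_labels_ok & palin_informative
    swap = np.where(palin, palin_ok & (o_ea != e_ea), swap)
    ok = np.where(palin, palin_ok, ok)

    b_out = np.where(swap, -b_out, b_out)
    eaf_out = np.where(swap, 1.0 - eaf_out, eaf_out)
    # palindrome frequencies on opposite sides of 0.5 signal a strand flip
    freq_flip = palin.to_numpy() & ok & ((mg["eaf"] - 0.5) * (eaf_out - 0.5) < 0)
    b_out = np.where(freq_flip, -b_out, b_out)

    reason = np.where(
        ~shared, "missing_in_outcome",
        np.where(palin & ~palin_informative.to_numpy(), "palindromic", "allele_mismatch"),
    )
    df = pd.DataFrame(
        {
            "snp_id": mg["snp_id"],
            "b_exp": mg["beta"],
            "se_exp": mg["se"],
            "b_out": b_out,
            "se_out": mg["se_o"],
            "eaf": mg["eaf"],
            "n_exp": mg["n"],
            "n_out": mg["n_o"],
        }
    )
    ok = np.asarray(ok, dtype=bool)
    drop_df = pd.DataFrame(
        {"snp_id": mg.loc[~ok, "snp_id"], "reason": reason[~ok]}
    ).reset_index(drop=True)
    return HarmonizedSet(
        exposure.trait_id, outcome.trait_id, df.loc[ok].reset_index(drop=True), drop_df
    )
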