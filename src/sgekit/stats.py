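"""Synonymous-null significance testing and function classes.

Per SGE region, a normal null is fit to synonymous variants (excluding
synonymous SNVs whose day-6 RNA score is below -1.0, which likely disrupt
splicing; for an intron-only region, all SNVs form the null).  One-sided
lower-tail p-values are Benjamini-Hochberg adjusted within each region and
an FDR of 0.01 defines "depleted" SNVs.  Four function classes (neutral /
LOF1 / LOF2 / intermediate) follow fixed score and q-value thresholds
anchored to gold-standard variant distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

FDR_DEFAULT = 0.01
RNA_NULL_EXCLUSION = -1.0
MIN_NULL = 10

# class thresholds (log2 function-score units / BH q-values)
NEUTRAL_SCORE = -0.2188   # 5th percentile of gold-standard neutral variants
LOF1_SCORE = -1.26        # 95th percentile of gold-standard ccRCC variants
LOF2_SCORE = -0.3875      # lowest-scoring gold-standard neutral variant
NEUTRAL_Q = 0.10
LOF2_Q = 0.01


@dataclass
class NullModel:
    region_id: str
    mean: float
    sd: float
    n_null: int
    eligibility: str

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError("null sd must be positive")


def fit_null(
    scores: pd.DataFrame,
    score_col: str = "function_score",
    is_intron_region: bool = False,
    min_null: int = MIN_NULL,
    region_id: str = "",
) -> NullModel:
    """Fit the per-region normal null.

    Eligible variants: synonymous SNVs passing quality filters whose day-6
    RNA score (when present) is at least -1.0; for intron regions, all
    passing SNVs.  Normality is assumed, not tested.
    """
    passing = scores[scores["filter_pass"]] if "filter_pass" in scores else scores
    if is_intron_region:
        elig = passing
        rule = "all_snvs"
    else:
        elig = passing[passing["consequence"] == "synonymous"]
        if "rna_score_d6" in elig.columns:
            rna = elig["rna_score_d6"]
            elig = elig[rna.isna() | (rna >= RNA_NULL_EXCLUSION)]
        rule = "synonymous_rna_ok"
    vals = elig[score_col].dropna().to_numpy(dtype=float)
    if vals.size < min_null:
        raise ValueError(
            f"region {region_id!r}: only {vals.size} null-eligible variants "
            f"(minimum {min_null})"
        )
    return NullModel(
        region_id=region_id,
        mean=float(np.mean(vals)),
        sd=float(np.std(vals, ddof=1)),
        n_null=int(vals.size),
        eligibility=rule,
    )


def p_lower_tail(score, null: NullModel):
    """Lower-tail normal probability of a score under the region null."""
    return norm.cdf((np.asarray(score, dtype=float) - null.mean) / null.sd)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def flag_depleted(q, fdr: float = FDR_DEFAULT):
    """Depleted iff q strictly below the FDR threshold."""
    return np.asarray(q, dtype=float) < fdr


def assign_class(score: float, q: float | None) -> str:
    """Four-way function class with the fixed precedence.

    1. neutral: q > 0.10 and score > -0.2188
    2. LOF1: score < -1.26
    3. LOF2: q < 0.01 and score < -0.3875
    4. intermediate: everything else (including missing q).
    """
    if q is None or (isinstance(q, float) and np.isnan(q)):
        return "intermediate"
    if q > NEUTRAL_Q and score > NEUTRAL_SCORE:
        return "neutral"
    if score < LOF1_SCORE:
        return "LOF1"
    if q < LOF2_Q and score < LOF2_SCORE:
        return "LOF2"
    return "intermediate"


def add_significance(
    scores: pd.DataFrame,
    score_col: str = "function_score",
    fdr: float = FDR_DEFAULT,
    intron_regions: set[str] | None = None,
    min_null: int = MIN_NULL,
) -> tuple[pd.DataFrame, dict[str, NullModel]]:
    """Per-region nulls, p/q values, depletion flags and function classes.

    Only variants passing quality filters receive p/q; filtered variants get
    NA and class ``intermediate`` is never assigned to them (class NA).
    BH adjustment is applied within each region.
    """
    intron_regions = intron_regions or set()
    df = scores.copy()
    df["p"] = np.nan
    df["q"] = np.nan
    nulls: dict[str, NullModel] = {}
    for rid, grp in df.groupby("region"):
        null = fit_null(
            grp,
            score_col=score_col,
            is_intron_region=rid in intron_regions,
            min_null=min_null,
            region_id=str(rid),
        )
        nulls[str(rid)] = null
        mask = df["region"].eq(rid) & df["filter_pass"] & df[score_col].notna()
        p = p_lower_tail(df.loc[mask, score_col], null)
        df.loc[mask, "p"] = p
        df.loc[mask, "q"] = bh_adjust(p)
    df["depleted"] = flag_depleted(df["q"].fillna(1.0), fdr) & df["filter_pass"]
    df["function_class"] = [
        assign_class(s, q) if ok and not pd.isna(s) else None
        for s, q, ok in zip(df[score_col], df["q"], df["filter_pass"])
    ]
    return df, nulls
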