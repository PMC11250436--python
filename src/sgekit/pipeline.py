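"""End-to-end scoring: count tables -> final function scores with significance.

Stages, in the order the analysis defines them:

1. per-region ratios + quality filters (``scoring.compute_ratios``)
2. RNA scores for passing coding SNVs (``scoring.rna_scores``)
3. synonymous-median centering per region
4. linear cross-region scaling on nonsense anchors
5. per-region null fit, p/q, depletion flags (``stats.add_significance``)
6. overlap merging into a single score set (``scoring.merge_overlaps``)
7. four-way function classes
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import scoring, stats
from .design import RegionDesign
from .scoring import MergeRule


def score_experiment(
    counts: pd.DataFrame,
    designs: list[RegionDesign],
    pseudocount: float = scoring.DEFAULT_PSEUDOCOUNT,
    merge_policy: list[MergeRule] | None = None,
    min_anchor: int = 3,
    fdr: float = stats.FDR_DEFAULT,
    min_null: int = stats.MIN_NULL,
) -> pd.DataFrame:
    """Run the full scoring pipeline on an amplicon-caller count table."""
    by_region: dict[str, pd.DataFrame] = {}
    intron_regions = {d.region_id for d in designs if d.is_intron_region}
    for design in designs:
        sub = counts[counts["region"] == design.region_id]
        if sub.empty:
            continue
        ratios = scoring.compute_ratios(
            sub, pseudocount=pseudocount, pam_conflicts=design.pam_codon_conflicts()
        )
        rna = scoring.rna_scores(sub, ratios, pseudocount=pseudocount)
        ratios = ratios.merge(
            rna[["hgvs_c", "rna_score_d6", "rna_score_d20"]], on="hgvs_c", how="left"
        )
        centered = scoring.center_on_synonymous(
            ratios, is_intron_region=design.is_intron_region
        )
        centered.attrs["scaling_window"] = design.scaling_window
        centered.attrs["is_intron_region"] = design.is_intron_region
        by_region[design.region_id] = centered
    scaled = scoring.scale_across_regions(by_region, min_anchor=min_anchor)
    per_region = pd.concat(scaled.values(), ignore_index=True)
    scored, _nulls = stats.add_significance(
        per_region, fdr=fdr, intron_regions=intron_regions, min_null=min_null
    )
    merged = scoring.merge_overlaps(
        scored,
        policy=merge_policy,
        value_cols=("function_score", "centered_score", "raw_score",
                    "rna_score_d6", "rna_score_d20"),
    )
    merged = _merge_significance(merged, scored, merge_policy)
    merged["function_class"] = [
        stats.assign_class(s, q) if ok and not pd.isna(s) else None
        for s, q, ok in zip(
            merged["function_score"], merged["q"], merged["filter_pass"]
        )
    ]
    return merged


def _merge_significance(merged, scored, merge_policy):
    """For mean-merged variants, carry the more conservative (larger) q.

    Variants merged under ``take_second`` already carry the second region's
    p/q; only ``mean``-rule pairs are revisited.
    """
    policy = scoring.DEFAULT_MERGE_POLICY if merge_policy is None else merge_policy
    mean_pairs = {
        "+".join(sorted((r.first, r.second))) for r in policy if r.how == "mean"
    }
    dup = scored["hgvs_c"].value_counts()
    dups = set(dup[dup > 1].index)
    if dups and mean_pairs:
        qmap = scored[scored["hgvs_c"].isin(dups)].groupby("hgvs_c")[["p", "q"]].max()
        sel = merged["hgvs_c"].isin(dups) & merged["merged_from"].isin(mean_pairs)
        for idx in merged.index[sel]:
            hgvs = merged.at[idx, "hgvs_c"]
            merged.loc[idx, ["p", "q"]] = qmap.loc[hgvs, ["p", "q"]].to_numpy()
    merged["depleted"] = stats.flag_depleted(merged["q"].fillna(1.0)) & merged["filter_pass"]
    return merged


SCORE_COLUMNS = [
    "region", "merged_from", "hgvs_c", "consequence", "codon_index",
    "lib_freq", "log2_d20_d6_r1", "log2_d20_d6_r2", "raw_score",
    "filter_pass", "filter_reasons", "centered_score", "function_score",
    "rna_score_d6", "rna_score_d20", "p", "q", "depleted", "function_class",
]


def tidy_scores(scored: pd.DataFrame) -> pd.DataFrame:
    cols = [c for c in SCORE_COLUMNS if c in scored.columns]
    return scored[cols]
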