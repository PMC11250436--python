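"""Benchmarking function scores against clinical and population annotations.

Builds gold-standard variant sets from ClinVar-style labels, tumor
observation counts (cBioPortal-style) and population allele counts
(gnomAD/TOPMed/UKB-style); computes sensitivity/specificity/ROC of the
scores against those sets; groups pathogenic variants by clinical phenotype
(VHLdb-style type 1 vs pheochromocytoma-predominant disease); and annotates
the stop-codon readthrough context of nonsense variants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import STOP_CODONS

PATHOGENIC = {"pathogenic", "likely_pathogenic"}
BENIGN = {"benign", "likely_benign"}


def combined_population_count(gnomad_v2: int, gnomad_v3: int, topmed_het: int, ukb: int) -> int:
    """Combined allele count: sum of gnomAD v2 + v3, TOPMed het and UKB counts."""
    vals = (gnomad_v2, gnomad_v3, topmed_het, ukb)
    if any(v < 0 for v in vals):
        raise ValueError("allele counts must be nonnegative")
    return int(sum(vals))


def collapse_clinvar(labels: set[str] | str) -> str:
    """Collapse dual assertions: pathogenic+likely_pathogenic -> likely_pathogenic,
    benign+likely_benign -> likely_benign."""
    if isinstance(labels, str):
        return labels
    if labels >= {"pathogenic", "likely_pathogenic"}:
        return "likely_pathogenic"
    if labels >= {"benign", "likely_benign"}:
        return "likely_benign"
    if len(labels) == 1:
        return next(iter(labels))
    return "conflicting"


def build_gold_standard(annotations: pd.DataFrame) -> pd.DataFrame:
    """Label variants for benchmarking.

    - ``ccrcc_associated``: >= 2 ccRCC tumor observations, or 1 observation
      plus a pathogenic/likely-pathogenic ClinVar assertion.
    - ``neutral``: benign/likely-benign in ClinVar and seen at least once in
      combined population sequencing.
    - ``missense_neutral``: missense, seen in >= 2 population controls, and
      not asserted pathogenic (the missense-specific neutral set — ClinVar
      has essentially no benign missense assertions in this gene).
    - ``unlabeled`` otherwise.

    ``annotations`` columns: hgvs_c, consequence, clinvar, ccrcc_obs,
    gnomad_v2, gnomad_v3, topmed_het, ukb.
    """
    df = annotations.copy()
    df["combined_pop"] = [
        combined_population_count(a, b, c, d)
        for a, b, c, d in zip(df["gnomad_v2"], df["gnomad_v3"], df["topmed_het"], df["ukb"])
    ]
    labels = []
    for _, r in df.iterrows():
        path = r["clinvar"] in PATHOGENIC
        if r["ccrcc_obs"] >= 2 or (r["ccrcc_obs"] >= 1 and path):
            labels.append("ccrcc_associated")
        elif r["clinvar"] in BENIGN and r["combined_pop"] >= 1:
            labels.append("neutral")
        elif (
            r.get("consequence") == "missense"
            and r["combined_pop"] >= 2
            and not path
        ):
            labels.append("missense_neutral")
        else:
            labels.append("unlabeled")
    df["gold_label"] = labels
    return df


@dataclass
class PerformanceReport:
    threshold: float
    sensitivity: float
    specificity: float
    roc: pd.DataFrame  # columns fpr, tpr, threshold
    auc: float


def classify_performance(
    scores: np.ndarray,
    labels: np.ndarray,
    threshold: float,
) -> PerformanceReport:
    """Sensitivity/specificity at ``threshold`` plus full ROC and AUC.

    Orientation: lower score = more deleterious; a variant is "flagged"
    (called positive) iff its score is strictly below the threshold.  The
    ROC sweeps thresholds over all observed scores plus sentinels; AUC by
    trapezoid over (fpr, tpr).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    npos, nneg = int(labels.sum()), int((~labels).sum())
    if npos == 0 or nneg == 0:
        raise ValueError("need at least one positive and one negative label")

    def sens_spec(t):
        flag = scores < t
        return (flag & labels).sum() / npos, ((~flag) & ~labels).sum() / nneg

    sens, spec = sens_spec(threshold)
    cuts = np.concatenate(([-np.inf], np.sort(np.unique(scores)), [np.inf]))
    pts = []
    for t in cuts:
        s, sp = sens_spec(t)
        pts.append((1 - sp, s, t))
    # ensure the sweep reaches (1,1): threshold just above max score
    pts.append((1.0, 1.0, np.inf))
    roc = pd.DataFrame(sorted(set(pts)), columns=["fpr", "tpr", "threshold"])
    roc = roc.sort_values(["fpr", "tpr"]).reset_index(drop=True)
    auc = float(np.trapezoid(roc["tpr"], roc["fpr"]))
    return PerformanceReport(threshold, float(sens), float(spec), roc, auc)


def vhldb_group(
    entries: list[tuple[str, str]],
    clinvar_label: str,
    combined_pop_count: int,
    recessive: bool = False,
) -> str:
    """Group a pathogenic variant by clinical phenotype entries.

    ``entries`` are (disease type, tumor) pairs, e.g. ("type 1", "ccRCC"),
    ("type 2A", "pheochromocytoma"), or ("", "ccRCC") when only a tumor is
    recorded.  Applicable only to pathogenic/likely-pathogenic variants that
    are not recessive and are seen fewer than twice in population controls.

    - all entries type 1 or ccRCC-only -> ``type1``
    - entries only type 2, or more pheochromocytoma than ccRCC entries ->
      ``pheo_predominant``
    - an explicit type 2B entry, mixed or absent phenotypes -> ``type_unclear``
    """
    if clinvar_label not in PATHOGENIC or recessive or combined_pop_count >= 2:
        return "not_applicable"
    if not entries:
        return "type_unclear"
    types = [t.strip().lower() for t, _ in entries if t and t.strip()]
    tumors = [u.strip().lower() for _, u in entries if u and u.strip()]
    if any(t == "type 2b" for t in types):
        return "type_unclear"
    n_pheo = sum("pheo" in u for u in tumors)
    n_ccrcc = sum("ccrcc" in u for u in tumors)
    type1_only = bool(types) and all(t == "type 1" for t in types)
    type2_only = bool(types) and all(t.startswith("type 2") for t in types)
    ccrcc_only = bool(tumors) and all("ccrcc" in u for u in tumors)
    if (type1_only and not n_pheo) or (not types and ccrcc_only):
        return "type1"
    if (type2_only and not n_ccrcc) or n_pheo > n_ccrcc:
        return "pheo_predominant"
    return "type_unclear"


def mean_obs_by_class(classes: pd.Series, ccrcc_obs: pd.Series) -> pd.Series:
    """Mean tumor observation count per function class; empty class -> NaN."""
    df = pd.DataFrame({"cls": classes, "obs": ccrcc_obs}).dropna(subset=["cls"])
    return df.groupby("cls")["obs"].mean()


def stop_context(cds: str, cds_pos: int, alt: str) -> tuple[str, str, bool]:
    """Stop-codon type, 4-mer RNA context and readthrough permissiveness.

    The SNV at 1-based coding position ``cds_pos`` must create an in-frame
    stop codon.  Returns (type in {amber, ochre, opal}, stop codon + next
    base in RNA letters, permissive).  Opal (UGA) stops followed by a
    pyrimidine are the most permissive to stop-codon readthrough.
    """
    cds = cds.upper()
    mutant = cds[: cds_pos - 1] + alt.upper() + cds[cds_pos:]
    codon_start = (cds_pos - 1) // 3 * 3
    codon = mutant[codon_start : codon_start + 3]
    if codon not in STOP_CODONS:
        raise ValueError(f"SNV does not create a stop codon (codon {codon})")
    if codon_start + 3 >= len(mutant):
        raise ValueError("no downstream base available for context")
    kind = {"TAG": "amber", "TAA": "ochre", "TGA": "opal"}[codon]
    nxt = mutant[codon_start + 3]
    fourmer = (codon + nxt).replace("T", "U")
    permissive = kind == "opal" and nxt in {"C", "T"}
    return kind, fourmer, permissive
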