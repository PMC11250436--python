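"""Function, RNA and InDel scores from HDR-gated variant count tables.

The function score of an SNV is the mean (over two transfection replicates)
log2 ratio of its day-20 to day-6 frequency, centered so the median
synonymous variant in each region scores 0, then scaled linearly across
regions so every region's median nonsense variant (restricted to a scaling
window of residues where nonsense is uniformly deleterious) equals the
global median nonsense variant.  RNA scores are log2 ratios of a coding
SNV's frequency in spliced mRNA to its frequency in gDNA on the same day.
InDel scores are log2 day-13/day-6 frequency ratios of CRISPR editing
outcomes, keyed by CIGAR string.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import STOP_CODONS, translate_codon

# quality-filter thresholds
LIBRARY_FREQ_MIN = 1.0e-4
DAY6_FREQ_MIN = 1.0e-5
REPLICATE_DIFF_MAX = 1.5
REPLICATE_BOTH_BELOW = -1.0
TRAJECTORY_DIFF_MAX = 2.0
TRAJECTORY_BOTH_BELOW = -0.5
ERROR_RATIO_MAX = 0.5

DEFAULT_PSEUDOCOUNT = 0.5

CODING_CONSEQUENCES = {"synonymous", "missense", "nonsense"}

FILTER_REASONS = (
    "low_library",
    "low_day6",
    "replicate_discordant",
    "trajectory_discordant",
    "error_dominated",
    "pam_codon_conflict",
)


def frequencies(read_count, sample_total, pseudocount: float = DEFAULT_PSEUDOCOUNT):
    """Pseudocounted frequency (count + pc) / (total + pc)."""
    read_count = np.asarray(read_count, dtype=float)
    sample_total = np.asarray(sample_total, dtype=float)
    if np.any(read_count < 0):
        raise ValueError("negative read count")
    if np.any(sample_total <= 0):
        raise ValueError("sample_total must be positive")
    return (read_count + pseudocount) / (sample_total + pseudocount)


def log2_ratio(f_num, f_den):
    """log2(f_num / f_den); both must be strictly positive (pseudocounted)."""
    f_num = np.asarray(f_num, dtype=float)
    f_den = np.asarray(f_den, dtype=float)
    if np.any(f_num <= 0) or np.any(f_den <= 0):
        raise ValueError("frequencies must be positive; apply a pseudocount upstream")
    return np.log2(f_num / f_den)


# ----------------------------------------------------------------------
# quality filtering
# ----------------------------------------------------------------------

def quality_filter(
    lib_freq: float,
    d6_freqs: tuple[float, float],
    d20_freqs: tuple[float, float],
    rep_log2_d20_d6: tuple[float, float],
    log2_d13_d6: float,
    log2_d20_d13: float,
    error_freq: float | tuple[float, float] = 0.0,
    pam_codon_conflict: bool = False,
) -> list[str]:
    """Evaluate the six SNV quality-filter rules; return the tripped reasons.

    Rules (all evaluated independently):
    - ``low_library``: HDR library frequency < 1e-4.
    - ``low_day6``: day-6 frequency < 1e-5 in either replicate.
    - ``replicate_discordant``: |log2(d20/d6) difference| across replicates
      > 1.5, unless both ratios are below -1.0 (both strongly depleted).
    - ``trajectory_discordant``: |log2(d13/d6) - log2(d20/d13)| > 2.0,
      unless both are below -0.5.
    - ``error_dominated``: sequencing-error frequency (negative-control
      day-6 sample) exceeds half the variant's observed frequency,
      max(d6, d20), in either replicate.
    - ``pam_codon_conflict``: the SNV shares a codon with a synonymous PAM
      marker edit and the joint codon encodes a different amino acid than
      the SNV alone.
    """
    reasons = []
    if lib_freq < LIBRARY_FREQ_MIN:
        reasons.append("low_library")
    if any(f < DAY6_FREQ_MIN for f in d6_freqs):
        reasons.append("low_day6")
    r1, r2 = rep_log2_d20_d6
    if abs(r1 - r2) > REPLICATE_DIFF_MAX and not (
        r1 < REPLICATE_BOTH_BELOW and r2 < REPLICATE_BOTH_BELOW
    ):
        reasons.append("replicate_discordant")
    if abs(log2_d13_d6 - log2_d20_d13) > TRAJECTORY_DIFF_MAX and not (
        log2_d13_d6 < TRAJECTORY_BOTH_BELOW and log2_d20_d13 < TRAJECTORY_BOTH_BELOW
    ):
        reasons.append("trajectory_discordant")
    err = error_freq if isinstance(error_freq, tuple) else (error_freq, error_freq)
    for e, f6, f20 in zip(err, d6_freqs, d20_freqs):
        denom = max(f6, f20)
        if denom > 0 and e / denom > ERROR_RATIO_MAX:
            reasons.append("error_dominated")
            break
    if pam_codon_conflict:
        reasons.append("pam_codon_conflict")
    return reasons


# ----------------------------------------------------------------------
# ratio computation on count tables
# ----------------------------------------------------------------------

def compute_ratios(
    counts: pd.DataFrame,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    pam_conflicts: set[str] | None = None,
) -> pd.DataFrame:
    """Per-SNV frequencies, replicate log2 ratios and quality-filter report.

    ``counts`` holds one region's gDNA samples with columns region,
    replicate, timepoint, analyte, hgvs_c, consequence, codon_index,
    read_count, sample_total.  Timepoints ``library``, ``negctrl_d6``,
    ``d6``, ``d13``, ``d20`` are used where present; missing library /
    negative-control samples disable the corresponding filters.
    """
    g = counts[counts["analyte"] == "gDNA"].copy()
    if g.empty:
        raise ValueError("no gDNA counts")
    g["freq"] = frequencies(g["read_count"], g["sample_total"], pseudocount)
    piv = g.pivot_table(
        index="hgvs_c", columns=["timepoint", "replicate"], values="freq"
    )
    meta = (
        g.drop_duplicates("hgvs_c")
        .set_index("hgvs_c")[["region", "consequence", "codon_index"]]
    )
    reps = sorted(g.loc[g["timepoint"] == "d6", "replicate"].unique())
    if len(reps) < 2:
        raise ValueError("two replicates required")
    r1, r2 = reps[:2]

    def col(tp, rep):
        return piv[(tp, rep)] if (tp, rep) in piv.columns else None

    out = meta.copy()
    have_lib = "library" in {c[0] for c in piv.columns}
    if have_lib:
        lib_cols = [piv[c] for c in piv.columns if c[0] == "library"]
        out["lib_freq"] = pd.concat(lib_cols, axis=1).mean(axis=1)
    else:
        out["lib_freq"] = np.nan
    for rep, tag in ((r1, "r1"), (r2, "r2")):
        out[f"d6_{tag}"] = col("d6", rep)
        out[f"d13_{tag}"] = col("d13", rep)
        out[f"d20_{tag}"] = col("d20", rep)
        e = col("negctrl_d6", rep)
        out[f"err_{tag}"] = e if e is not None else np.nan
        out[f"log2_d20_d6_{tag}"] = np.log2(out[f"d20_{tag}"] / out[f"d6_{tag}"])
        if out[f"d13_{tag}"].notna().any():
            out[f"log2_d13_d6_{tag}"] = np.log2(out[f"d13_{tag}"] / out[f"d6_{tag}"])
            out[f"log2_d20_d13_{tag}"] = np.log2(out[f"d20_{tag}"] / out[f"d13_{tag}"])
        else:
            out[f"log2_d13_d6_{tag}"] = np.nan
            out[f"log2_d20_d13_{tag}"] = np.nan
    out["raw_score"] = out[["log2_d20_d6_r1", "log2_d20_d6_r2"]].mean(axis=1)
    out["log2_d13_d6"] = out[["log2_d13_d6_r1", "log2_d13_d6_r2"]].mean(axis=1)
    out["log2_d20_d13"] = out[["log2_d20_d13_r1", "log2_d20_d13_r2"]].mean(axis=1)

    pam_conflicts = pam_conflicts or set()
    reasons_col, pass_col = [], []
    for hgvs, row in out.iterrows():
        reasons = quality_filter(
            lib_freq=row["lib_freq"] if have_lib else math.inf,
            d6_freqs=(row["d6_r1"], row["d6_r2"]),
            d20_freqs=(row["d20_r1"], row["d20_r2"]),
            rep_log2_d20_d6=(row["log2_d20_d6_r1"], row["log2_d20_d6_r2"]),
            log2_d13_d6=row["log2_d13_d6"] if not pd.isna(row["log2_d13_d6"]) else 0.0,
            log2_d20_d13=row["log2_d20_d13"] if not pd.isna(row["log2_d20_d13"]) else 0.0,
            error_freq=(
                (row["err_r1"], row["err_r2"])
                if not pd.isna(row["err_r1"])
                else 0.0
            ),
            pam_codon_conflict=hgvs in pam_conflicts,
        )
        reasons_col.append(",".join(reasons))
        pass_col.append(len(reasons) == 0)
    out["filter_reasons"] = reasons_col
    out["filter_pass"] = pass_col
    return out.reset_index()


# ----------------------------------------------------------------------
# normalization and scaling
# ----------------------------------------------------------------------

def _median(values) -> float:
    """Median with even-count = mean of the two middle values."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("median of empty set")
    return float(np.median(v))


def center_on_synonymous(region_scores: pd.DataFrame, is_intron_region: bool = False) -> pd.DataFrame:
    """Subtract the region's median passing synonymous raw score from all scores.

    Regions without synonymous variants (e.g. a deep-intronic region) are
    centered on the median of all passing SNVs instead.
    """
    df = region_scores.copy()
    passing = df[df["filter_pass"]]
    if not is_intron_region:
        syn = passing[passing["consequence"] == "synonymous"]["raw_score"].dropna()
    else:
        syn = pd.Series(dtype=float)
    if len(syn) == 0:
        syn = passing["raw_score"].dropna()
        if len(syn) == 0:
            raise ValueError("no eligible variants to center on")
    df["centered_score"] = df["raw_score"] - _median(syn)
    return df


def scale_across_regions(
    centered_by_region: dict[str, pd.DataFrame],
    min_anchor: int = 3,
) -> dict[str, pd.DataFrame]:
    """Linearly scale each region so its anchor-nonsense median matches the global one.

    Anchors are passing nonsense SNVs whose codon index lies inside the
    region's scaling window.  The multiplicative factor preserves the
    synonymous median at 0.  Regions with fewer than ``min_anchor`` anchors
    or a non-negative anchor median keep factor 1 (with a warning).
    """
    anchors = {}
    pooled = []
    for rid, df in centered_by_region.items():
        lo, hi = df.attrs.get("scaling_window", (54, 198))
        a = df[
            df["filter_pass"]
            & (df["consequence"] == "nonsense")
            & df["codon_index"].between(lo, hi)
        ]["centered_score"].dropna()
        anchors[rid] = a
        pooled.extend(a.tolist())
    out = {}
    if pooled:
        global_median = _median(pooled)
    else:
        global_median = None
    for rid, df in centered_by_region.items():
        a = anchors[rid]
        if (
            global_median is None
            or len(a) < min_anchor
            or _median(a) >= 0
        ):
            k = 1.0
            if global_median is not None and not df.attrs.get("is_intron_region", False):
                warnings.warn(
                    f"region {rid}: insufficient or non-negative nonsense anchors; "
                    "scaling factor fixed at 1"
                )
        else:
            k = global_median / _median(a)
        df = df.copy()
        df["scale_factor"] = k
        df["function_score"] = df["centered_score"] * k
        out[rid] = df
    return out


@dataclass
class MergeRule:
    first: str
    second: str
    how: str  # "take_second" | "mean"


# the study's rules for its three overlapping region pairs
DEFAULT_MERGE_POLICY = [
    MergeRule("exon1_5p", "exon1_mid", "take_second"),
    MergeRule("exon1_mid", "exon1_3p", "mean"),
    MergeRule("exon3_5p", "exon3_3p", "mean"),
]


def merge_overlaps(
    scores: pd.DataFrame,
    policy: list[MergeRule] | None = None,
    value_cols: tuple[str, ...] = ("function_score",),
) -> pd.DataFrame:
    """Collapse variants scored in two overlapping regions into one row.

    ``take_second`` keeps the second region's values; ``mean`` averages the
    two.  A duplicate variant whose region pair has no rule is a
    configuration error.  Provenance is recorded in ``merged_from``.
    """
    policy = DEFAULT_MERGE_POLICY if policy is None else policy
    rules = {frozenset((r.first, r.second)): r for r in policy}
    rows = []
    for hgvs, grp in scores.groupby("hgvs_c", sort=False):
        if len(grp) == 1:
            row = grp.iloc[0].to_dict()
            row["merged_from"] = row["region"]
            rows.append(row)
            continue
        if len(grp) != 2:
            raise ValueError(f"variant {hgvs} scored in {len(grp)} regions")
        regions = frozenset(grp["region"])
        rule = rules.get(regions)
        if rule is None:
            raise ValueError(f"no merge rule for regions {sorted(regions)} ({hgvs})")
        a = grp[grp["region"] == rule.first].iloc[0]
        b = grp[grp["region"] == rule.second].iloc[0]
        if rule.how == "take_second":
            row = b.to_dict()
        else:  # mean; keep non-score metadata from the second region
            row = b.to_dict()
            for c in value_cols:
                va, vb = a[c], b[c]
                if pd.isna(va):
                    row[c] = vb
                elif pd.isna(vb):
                    row[c] = va
                else:
                    row[c] = (va + vb) / 2.0
            row["filter_pass"] = bool(a["filter_pass"] or b["filter_pass"])
        row["merged_from"] = "+".join(sorted(regions))
        rows.append(row)
    return pd.DataFrame(rows).reset_index(drop=True)


# ----------------------------------------------------------------------
# RNA scores
# ----------------------------------------------------------------------

def rna_scores(
    counts: pd.DataFrame,
    ratios: pd.DataFrame,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Day-6 / day-20 RNA scores: log2(RNA freq / gDNA freq), replicate-averaged.

    Assigned only to coding SNVs that passed function-score quality
    filtering; non-coding variants get NA (they are undetectable in spliced
    transcripts).  Regions without RNA samples yield no scores.
    """
    rna = counts[counts["analyte"] == "RNA"].copy()
    out = ratios[["hgvs_c", "consequence"]].copy()
    out["rna_score_d6"] = np.nan
    out["rna_score_d20"] = np.nan
    if rna.empty:
        return out
    rna["freq"] = frequencies(rna["read_count"], rna["sample_total"], pseudocount)
    piv = rna.pivot_table(index="hgvs_c", columns=["timepoint", "replicate"], values="freq")
    gmap = ratios.set_index("hgvs_c")
    eligible = ratios["filter_pass"] & ratios["consequence"].isin(CODING_CONSEQUENCES)
    for day, colname in (("d6", "rna_score_d6"), ("d20", "rna_score_d20")):
        vals = []
        for i, row in out.iterrows():
            if not eligible.iloc[i]:
                vals.append(np.nan)
                continue
            hgvs = row["hgvs_c"]
            per_rep = []
            for rep, tag in ((1, "r1"), (2, "r2")):
                if (day, rep) in piv.columns and hgvs in piv.index:
                    rfreq = piv.loc[hgvs, (day, rep)]
                    gfreq = gmap.loc[hgvs, f"{day}_{tag}"]
                    if not (pd.isna(rfreq) or pd.isna(gfreq)):
                        per_rep.append(math.log2(rfreq / gfreq))
            vals.append(float(np.mean(per_rep)) if per_rep else np.nan)
        out[colname] = vals
    return out


# ----------------------------------------------------------------------
# InDel scores
# ----------------------------------------------------------------------

FRAME_CLASSES = {0: "in_frame", 1: "plus1", 2: "minus1"}


def frame_class(net_length: int) -> str:
    return FRAME_CLASSES[net_length % 3]


def indel_scores(
    outcomes_by_replicate: dict[int, pd.DataFrame],
    freq_floor: float = 1e-6,
) -> pd.DataFrame:
    """Mean log2(d13/d6) per retained CIGAR outcome, with reading-frame class.

    ``freq_floor`` guards the log when an outcome retained on day 6 has zero
    day-13 frequency in one replicate.
    """
    per_rep = []
    for rep, df in outcomes_by_replicate.items():
        d = df.copy()
        d["log2_d13_d6"] = np.log2(
            np.maximum(d["d13_freq"], freq_floor) / np.maximum(d["d6_freq"], freq_floor)
        )
        d["replicate"] = rep
        per_rep.append(d[["cigar", "net_length", "log2_d13_d6"]])
    allr = pd.concat(per_rep)
    agg = (
        allr.groupby(["cigar", "net_length"], as_index=False)["log2_d13_d6"]
        .mean()
        .rename(columns={"log2_d13_d6": "indel_score"})
    )
    agg["frame_class"] = [frame_class(int(n)) for n in agg["net_length"]]
    return agg


# ----------------------------------------------------------------------
# frameshift C-terminal extension
# ----------------------------------------------------------------------

def predict_frameshift_extension(
    cds_plus_utr: str,
    cds_len: int,
    indel_cds_pos: int,
    net_length: int,
) -> tuple[int | None, int | str]:
    """Stop position and C-terminal extension caused by an InDel in the CDS.

    ``cds_plus_utr`` is the coding sequence (including the natural stop)
    concatenated with downstream 3'-UTR sequence.  ``indel_cds_pos`` is the
    1-based coding position after which the insertion occurs (or at which
    the deletion starts); insertions are modeled as duplications of the
    preceding ``net_length`` bases, so only the reading frame downstream is
    altered — the convention of HGVS ``dup`` alleles.

    Returns ``(stop_codon_index, extension_aa)`` where the stop codon index
    is in mutant-protein coordinates and extension is the number of residues
    gained beyond the natural stop; an in-frame InDel returns the net codon
    change (extension ``net_length // 3`` for duplications, negative for
    deletions, reported as 0 extension past the stop).  If no stop codon is
    reached, returns ``(None, "nonstop")``.
    """
    if cds_len % 3 != 0:
        raise ValueError("cds_len must be a multiple of 3")
    seq = cds_plus_utr.upper()
    if net_length == 0:
        raise ValueError("net_length must be nonzero")
    if net_length > 0:
        ins = seq[indel_cds_pos - net_length : indel_cds_pos]
        mutant = seq[:indel_cds_pos] + ins + seq[indel_cds_pos:]
    else:
        mutant = seq[: indel_cds_pos - 1] + seq[indel_cds_pos - 1 - net_length :]
    natural_len = cds_len // 3 - 1  # residues before the natural stop
    stop_at = None
    for i in range(0, len(mutant) - 2, 3):
        if mutant[i : i + 3] in STOP_CODONS:
            stop_at = i // 3 + 1  # 1-based codon index of the stop
            break
    if stop_at is None:
        return None, "nonstop"
    extension = (stop_at - 1) - natural_len
    if net_length % 3 == 0:
        # in-frame InDels change length but translation still ends at the
        # natural stop: no C-terminal extension beyond it
        extension -= net_length // 3
    return stop_at, extension
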