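"""Synthetic SGE experiments with exported ground truth.

Generates a complete experiment in the study's layout: one or more region
designs with all possible SNVs and two synonymous PAM-marker edits; an HDR
library with lognormal representation dispersion; exponential growth
selection over the day 6 -> 20 window for two transfection replicates;
multinomial sequencing counts for gDNA (days 6/13/20), a day-6 negative
control, the library, and RNA (days 6/20); and matching annotation tables
(tumor observations, population allele counts, ClinVar-style labels).

Class-dependent selection mirrors the assayed gene: nonsense and canonical
splice SNVs are depleted, most synonymous SNVs are neutral, a configurable
minority of missense SNVs are loss-of-function, and a few synonymous SNVs
disrupt splicing (low RNA score, depleted).  Every random draw flows from a
single seed through named substreams so modules can be tested in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import RegionDesign, VariantSpec, translate_codon

BASES = "ACGT"

# stop-free codon pool used to draw random coding sequence
_CODONS = [
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if translate_codon(a + b + c) != "*"
]


@dataclass
class SimConfig:
    """Parameters of a synthetic SGE experiment.

    Defaults are the study-like conditions: selection effect of -2.5 log2
    units over the 14-day day-6 -> day-20 window for loss-of-function
    variants (matching the magnitude of observed nonsense depletion),
    splice-disruption RNA effect of -4 log2 units attenuated to half by day
    20 in surviving cells, ~10^6 HDR-gated reads per gDNA sample, and a
    per-base sequencing error rate of 1e-4.
    """

    seed: int = 0
    n_regions: int = 2
    coding_len: int = 102            # coding bases per region (multiple of 3)
    flank_len: int = 30              # intronic flank on each side
    codon_start0: int = 55           # residue number of region 1's first codon
    include_splice_sites: bool = True
    missense_lof_fraction: float = 0.224
    syn_splice_lof_fraction: float = 0.02
    lof_effect: float = -2.5         # log2 abundance change, day 6 -> 20
    splice_rna_effect: float = -4.0  # log2 RNA/gDNA for splice-LoF variants
    rna_day20_attenuation: float = 0.5
    library_sigma: float = 0.5
    replicate_sigma: float = 0.15
    depth: int = 1_000_000
    negctrl_depth: int = 1_000_000
    library_depth: int = 1_000_000
    rna_depth: int = 300_000
    error_rate: float = 1e-4
    days: tuple = (6, 13, 20)
    wt_fraction: float = 0.5         # HDR reads carrying no designed SNV


@dataclass
class SimResult:
    designs: list[RegionDesign]
    truth: pd.DataFrame        # per variant: s, rna_effect, true_class
    counts: pd.DataFrame       # amplicon_caller count-table schema
    annotations: pd.DataFrame
    config: SimConfig
    true_freqs: dict = field(default_factory=dict)


def _rng(seed: int, stream: str) -> np.random.Generator:
    # deterministic named substreams (zlib.crc32 is stable across processes)
    import zlib

    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(stream.encode()) % (2**31)])
    )


def build_design(config: SimConfig, region_index: int = 0) -> RegionDesign:
    """Random region design: flanked coding exon, all SNVs, two PAM edits."""
    if config.coding_len % 3 != 0 or config.coding_len < 60:
        raise ValueError("coding_len must be a multiple of 3 and >= 60")
    rng = _rng(config.seed, f"design{region_index}")
    n_codons = config.coding_len // 3
    codons = [str(_CODONS[i]) for i in rng.integers(0, len(_CODONS), n_codons)]
    exon = "".join(codons)
    left = "".join(BASES[i] for i in rng.integers(0, 4, config.flank_len))
    right = "".join(BASES[i] for i in rng.integers(0, 4, config.flank_len))
    amplicon = left + exon + right
    cds_start = config.flank_len + 1
    cds_end = config.flank_len + config.coding_len
    codon_start = config.codon_start0 + region_index * n_codons
    c_start = (codon_start - 1) * 3 + 1  # c. position of the exon's first base
    design = RegionDesign(
        region_id=f"region{region_index + 1}",
        ref_amplicon=amplicon,
        cds_start=cds_start,
        cds_end=cds_end,
        cds_offset=cds_start - c_start,
        codon_start=codon_start,
        phase=0,
        transcript_flanks=(left[-15:], right[:15]),
    )
    # two synonymous PAM-marker edits: third-base wobble at the 2nd and
    # second-to-last codon of the exon
    pam_edits = []
    for ci in (1, n_codons - 2):
        pos = cds_start + ci * 3 + 2  # third base of codon ci (0-based)
        ref = amplicon[pos - 1]
        codon = amplicon[pos - 3 : pos]
        for alt in BASES:
            if alt != ref and translate_codon(codon[:2] + alt) == translate_codon(codon):
                pam_edits.append((pos, alt))
                break
    design.pam_edits = pam_edits
    pam_set = set(pam_edits)
    snvs: list[VariantSpec] = []
    positions = list(range(cds_start, cds_end + 1))
    if config.include_splice_sites:
        positions = [cds_start - 2, cds_start - 1] + positions + [cds_end + 1, cds_end + 2]
    for pos in positions:
        ref = amplicon[pos - 1]
        for alt in BASES:
            if alt == ref or (pos, alt) in pam_set:
                continue
            snvs.append(design.make_variant(pos, alt))
    design.designed_snvs = snvs
    return design


def assign_truth(designs: list[RegionDesign], config: SimConfig) -> pd.DataFrame:
    """Draw each variant's true fitness / RNA effect from its consequence class."""
    rng = _rng(config.seed, "truth")
    rows = []
    for d in designs:
        for v in d.designed_snvs:
            s, rna, cls = 0.0, 0.0, "neutral"
            if v.consequence == "nonsense":
                s, cls = config.lof_effect, "lof_protein"
            elif v.consequence == "canonical_splice":
                s, rna, cls = config.lof_effect, config.splice_rna_effect, "lof_splice"
            elif v.consequence == "missense":
                if rng.random() < config.missense_lof_fraction:
                    s, cls = config.lof_effect, "lof_protein"
            elif v.consequence == "synonymous":
                if rng.random() < config.syn_splice_lof_fraction:
                    s, rna, cls = (
                        config.lof_effect,
                        config.splice_rna_effect,
                        "lof_splice",
                    )
            rows.append(
                {
                    "region": d.region_id,
                    "hgvs_c": v.hgvs_c,
                    "consequence": v.consequence,
                    "codon_index": v.codon_index,
                    "s": s,
                    "rna_effect": rna,
                    "true_class": cls,
                }
            )
    return pd.DataFrame(rows)


def simulate_timecourse(
    day6_freqs: np.ndarray, s: np.ndarray, days: tuple = (6, 13, 20)
) -> dict[int, np.ndarray]:
    """Exponential selection: f_v(t) proportional to f_v(6) * 2^(s_v (t-6)/14)."""
    day6_freqs = np.asarray(day6_freqs, dtype=float)
    if not np.isclose(day6_freqs.sum(), 1.0):
        raise ValueError("day-6 frequencies must sum to 1")
    out = {}
    for t in days:
        w = day6_freqs * np.power(2.0, np.asarray(s) * (t - 6) / 14.0)
        out[t] = w / w.sum()
    return out


def simulate_counts(
    true_freqs: np.ndarray,
    depth: int,
    error_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Multinomial counts with symmetric single-base sequencing error.

    The last element of ``true_freqs`` is the no-SNV (wild-type HDR) class.
    Each variant count loses a Binomial(count, eps) portion to neighbors
    (returned to the wild-type class) and gains Binomial(wt_count, eps/3)
    error-derived reads from wild-type reads mutating at its position.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    counts = rng.multinomial(depth, true_freqs)
    if error_rate <= 0:
        return counts
    wt = counts[-1]
    losses = rng.binomial(counts[:-1], error_rate)
    gains = rng.binomial(wt, error_rate / 3.0, size=counts.size - 1)
    out = counts.copy()
    out[:-1] = counts[:-1] - losses + gains
    out[-1] = wt - gains.sum() + losses.sum()
    return out


def _sample_rows(
    design: RegionDesign,
    counts_vec: np.ndarray,
    replicate: int,
    timepoint: str,
    analyte: str,
    total: int | None = None,
) -> list[dict]:
    # denominator = all gated reads in the sample, incl. no-SNV HDR reads
    total = int(counts_vec.sum()) if total is None else int(total)
    return [
        {
            "region": design.region_id,
            "replicate": replicate,
            "timepoint": timepoint,
            "analyte": analyte,
            "hgvs_c": v.hgvs_c,
            "consequence": v.consequence,
            "codon_index": v.codon_index,
            "read_count": int(counts_vec[i]),
            "sample_total": total,
        }
        for i, v in enumerate(design.designed_snvs)
    ]


def simulate_region_counts(
    design: RegionDesign, truth: pd.DataFrame, config: SimConfig
) -> tuple[list[dict], dict]:
    """All gDNA + RNA samples for one region; returns rows and true frequencies."""
    rid = design.region_id
    t = truth[truth["region"] == rid].set_index("hgvs_c")
    variants = [v.hgvs_c for v in design.designed_snvs]
    s = t.loc[variants, "s"].to_numpy(dtype=float)
    rna_eff = t.loc[variants, "rna_effect"].to_numpy(dtype=float)
    coding = t.loc[variants, "codon_index"].notna().to_numpy()
    n = len(variants)

    rng_lib = _rng(config.seed, f"library:{rid}")
    w = np.exp(rng_lib.normal(0.0, config.library_sigma, n))
    lib = w / w.sum() * (1.0 - config.wt_fraction)
    lib_full = np.append(lib, config.wt_fraction)

    rows: list[dict] = []
    true_freqs: dict = {"library": lib_full}
    rng_seq = _rng(config.seed, f"seq:{rid}")

    for rep in (1, 2):
        lib_counts = simulate_counts(
            lib_full, config.library_depth, config.error_rate, rng_seq
        )
        rows += _sample_rows(design, lib_counts[:-1], rep, "library", "gDNA", total=lib_counts.sum())

        # negative control: unedited genome, variant reads arise from error only
        nc = np.full(n + 1, 0.0)
        nc[-1] = 1.0
        nc_counts = simulate_counts(nc, config.negctrl_depth, config.error_rate, rng_seq)
        rows += _sample_rows(design, nc_counts[:-1], rep, "negctrl_d6", "gDNA", total=nc_counts.sum())

        rng_rep = _rng(config.seed, f"growth:{rid}:{rep}")
        jitter = np.exp(rng_rep.normal(0.0, config.replicate_sigma, n + 1))
        d6 = lib_full * jitter
        d6 /= d6.sum()
        traj = simulate_timecourse(d6, np.append(s, 0.0), config.days)
        true_freqs[f"rep{rep}"] = traj
        for day, tp in zip(config.days, ("d6", "d13", "d20")):
            cnt = simulate_counts(traj[day], config.depth, config.error_rate, rng_seq)
            rows += _sample_rows(design, cnt[:-1], rep, tp, "gDNA", total=cnt.sum())

        # RNA: spliced transcripts only -> non-coding variants absent
        for day, tp in ((6, "d6"), (20, "d20")):
            eff = rna_eff.copy()
            if day == 20:
                eff = eff * config.rna_day20_attenuation
            rna_w = traj[day][:-1] * np.power(2.0, eff) * coding
            rna_full = np.append(rna_w, traj[day][-1])
            rna_full /= rna_full.sum()
            cnt = simulate_counts(rna_full, config.rna_depth, config.error_rate, rng_seq)
            cnt[:-1][~coding] = 0
            rows += _sample_rows(design, cnt[:-1], rep, tp, "RNA", total=cnt.sum())
    return rows, true_freqs


def simulate_annotations(
    truth: pd.DataFrame,
    config: SimConfig,
    lambda_lof: float = 2.0,
    lambda_neutral: float = 0.01,
    mu_neutral: float = 2.0,
    clinvar_label_rate: float = 0.4,
    miscall_rate: float = 0.0,
) -> pd.DataFrame:
    """Synthetic annotation table: tumor counts, population counts, labels.

    True-LoF variants accumulate tumor observations (Poisson ``lambda_lof``)
    and are essentially absent from population controls; neutral variants
    show the reverse.  A random subset receives ClinVar-style labels, with a
    configurable miscall rate.
    """
    rng = _rng(config.seed, "annotations")
    df = truth.copy()
    is_lof = df["true_class"].isin(["lof_protein", "lof_splice"]).to_numpy()
    n = len(df)
    df["ccrcc_obs"] = np.where(
        is_lof, rng.poisson(lambda_lof, n), rng.poisson(lambda_neutral, n)
    )
    pop = np.where(is_lof, 0.0, mu_neutral / 4.0)
    for colname in ("gnomad_v2", "gnomad_v3", "topmed_het", "ukb"):
        df[colname] = rng.poisson(pop)
    labels = []
    for lof in is_lof:
        if rng.random() >= clinvar_label_rate:
            labels.append("absent")
            continue
        truthful = rng.random() >= miscall_rate
        pathogenic = lof if truthful else not lof
        labels.append("likely_pathogenic" if pathogenic else "likely_benign")
    df["clinvar"] = labels
    return df


def simulate_experiment(config: SimConfig) -> SimResult:
    """Full synthetic experiment: designs, truth, counts, annotations."""
    designs = [build_design(config, i) for i in range(config.n_regions)]
    truth = assign_truth(designs, config)
    rows: list[dict] = []
    true_freqs = {}
    for d in designs:
        r, tf = simulate_region_counts(d, truth, config)
        rows += r
        true_freqs[d.region_id] = tf
    counts = pd.DataFrame(rows)
    annotations = simulate_annotations(truth, config)
    return SimResult(designs, truth, counts, annotations, config, true_freqs)


# ----------------------------------------------------------------------
# synthetic reads (FASTQ-level), for exercising the amplicon caller
# ----------------------------------------------------------------------

def simulate_reads(
    design: RegionDesign,
    n_reads: int,
    config: SimConfig,
    variant_freqs: np.ndarray | None = None,
    read_len: int = 120,
    stream: str = "reads",
) -> tuple[list[tuple[str, str, str]], dict[str, int]]:
    """Paired-end reads for one sample; returns reads and emitted true counts.

    Each HDR molecule carries both PAM edits plus at most one designed SNV
    (or none, for the wild-type fraction).  Per-base errors are applied at
    ``config.error_rate``.  Returns ``(read_id, r1, r2)`` tuples (r2 is the
    reverse complement of the amplicon 3' end) and a dict of the true number
    of reads emitted per variant.
    """
    from Bio.Seq import reverse_complement

    rng = _rng(config.seed, f"{stream}:{design.region_id}")
    snvs = design.designed_snvs
    n = len(snvs)
    if variant_freqs is None:
        variant_freqs = np.full(n, (1.0 - config.wt_fraction) / n)
    probs = np.append(variant_freqs, 1.0 - variant_freqs.sum())
    hdr = list(design.ref_amplicon)
    for pos, alt in design.pam_edits:
        hdr[pos - 1] = alt
    emitted: dict[str, int] = {}
    reads = []
    choices = rng.choice(n + 1, size=n_reads, p=probs / probs.sum())
    for k, ci in enumerate(choices):
        mol = hdr.copy()
        if ci < n:
            v = snvs[ci]
            mol[v.position - 1] = v.alt
            emitted[v.hgvs_c] = emitted.get(v.hgvs_c, 0) + 1
        seq = "".join(mol)
        if config.error_rate > 0:
            errs = rng.random(len(seq)) < config.error_rate
            if errs.any():
                seq = list(seq)
                for i in np.flatnonzero(errs):
                    seq[i] = BASES[(BASES.index(seq[i]) + rng.integers(1, 4)) % 4]
                seq = "".join(seq)
        r1 = seq[:read_len]
        r2 = reverse_complement(seq[-read_len:])
        reads.append((f"read{k}", r1, r2))
    return reads, emitted


def write_fastq_pair(reads, r1_path: str, r2_path: str) -> None:
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for rid, r1, r2 in reads:
            f1.write(f"@{rid}\n{r1}\n+\n{'I' * len(r1)}\n")
            f2.write(f"@{rid}\n{r2}\n+\n{'I' * len(r2)}\n")
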