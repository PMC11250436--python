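"""HDR-gated variant counting from paired-end amplicon reads.

The read-processing stage of an SGE experiment: merge read pairs that overlap
perfectly, align merged reads globally against the region's reference
amplicon, extract substitutions and InDels, gate on the synonymous PAM-edit
HDR markers (and, for RNA, on exact splice-junction flanks), and tally
per-variant read counts.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import reverse_complement

from .design import RegionDesign

# EMBOSS-needleall-like scoring: EDNAFULL match/mismatch with affine gaps.
MATCH = 5
MISMATCH = -4
GAP_OPEN = 10.0
GAP_EXTEND = 0.5

TIMEPOINTS = ("library", "negctrl_d6", "d6", "d13", "d20")
ANALYTES = ("gDNA", "RNA")


class MergeRejection(Exception):
    """Read pair could not be merged under the exact-overlap rule."""


def merge_read_pair(r1: str, r2: str, min_overlap: int = 20) -> str:
    """Merge a read pair into one amplicon-spanning sequence.

    ``r2`` is the raw reverse-strand read; it is reverse-complemented and the
    longest suffix of ``r1`` equal to a prefix of revcomp(``r2``) of length at
    least ``min_overlap`` defines the merge.  Any mismatch in the overlap, an
    overlap shorter than ``min_overlap``, or an N base in the merged sequence
    rejects the pair.
    """
    if not r1 or not r2:
        raise ValueError("empty read")
    r2rc = reverse_complement(r2)
    best = None
    for olen in range(min(len(r1), len(r2rc)), min_overlap - 1, -1):
        if r1[-olen:] == r2rc[:olen]:
            best = olen
            break
    if best is None:
        raise MergeRejection("no perfect overlap of sufficient length")
    merged = r1 + r2rc[best:]
    if "N" in merged:
        raise MergeRejection("merged read contains N")
    return merged


def _aligner() -> PairwiseAligner:
    aln = PairwiseAligner()
    aln.mode = "global"
    aln.match_score = MATCH
    aln.mismatch_score = MISMATCH
    aln.open_gap_score = -GAP_OPEN
    aln.extend_gap_score = -GAP_EXTEND
    return aln


_ALIGNER = _aligner()


@dataclass
class Alignment:
    """Global alignment of a read against the reference amplicon."""

    read: str
    ref: str
    aligned_read: str
    aligned_ref: str
    score: float

    @property
    def cigar(self) -> str:
        ops = []
        for qr, rf in zip(self.aligned_read, self.aligned_ref):
            if qr == "-":
                op = "D"
            elif rf == "-":
                op = "I"
            else:
                op = "M"
            if ops and ops[-1][0] == op:
                ops[-1][1] += 1
            else:
                ops.append([op, 1])
        return "".join(f"{n}{op}" for op, n in ops)


def global_align(read: str, ref_amplicon: str) -> Alignment:
    """End-to-end optimal alignment of ``read`` to ``ref_amplicon``.

    Identical-length reads with substitutions only take a fast gap-free path
    when the gap-free score provably dominates any gapped alternative.
    """
    if not read or not ref_amplicon:
        raise ValueError("empty sequence")
    if len(read) == len(ref_amplicon):
        nmm = sum(a != b for a, b in zip(read, ref_amplicon))
        # one substitution costs MATCH-MISMATCH=9 < 2 gap opens; gap-free is
        # optimal whenever the mismatch penalty is below the cheapest
        # two-gap detour for every arrangement -> safe for small nmm
        if nmm * (MATCH - MISMATCH) < 2 * GAP_OPEN:
            score = (len(read) - nmm) * MATCH + nmm * MISMATCH
            return Alignment(read, ref_amplicon, read, ref_amplicon, float(score))
    res = _ALIGNER.align(read, ref_amplicon)
    best = res[0]
    aligned_read, aligned_ref = _gapped_strings(best, read, ref_amplicon)
    return Alignment(read, ref_amplicon, aligned_read, aligned_ref, float(best.score))


def _gapped_strings(aln, read: str, ref: str) -> tuple[str, str]:
    """Reconstruct gapped read/ref strings from a Biopython alignment."""
    blocks_q, blocks_t = aln.aligned  # target=read (first seq), query=ref
    # Bio.Align: aln.aligned gives (target_blocks, query_blocks) where target
    # is the first sequence passed to align()
    tq, tr = [], []
    q_prev = r_prev = 0
    for (qs, qe), (rs, re) in zip(blocks_q, blocks_t):
        if qs > q_prev:  # insertion relative to ref
            tq.append(read[q_prev:qs])
            tr.append("-" * (qs - q_prev))
        if rs > r_prev:  # deletion relative to ref
            tq.append("-" * (rs - r_prev))
            tr.append(ref[r_prev:rs])
        tq.append(read[qs:qe])
        tr.append(ref[rs:re])
        q_prev, r_prev = qe, re
    if q_prev < len(read):
        tq.append(read[q_prev:])
        tr.append("-" * (len(read) - q_prev))
    if r_prev < len(ref):
        tq.append("-" * (len(ref) - r_prev))
        tr.append(ref[r_prev:])
    return "".join(tq), "".join(tr)


@dataclass
class EditCall:
    """Edits observed in one read relative to the reference amplicon."""

    read_id: str
    substitutions: frozenset[tuple[int, str]]  # (1-based ref position, alt)
    insertions: tuple[tuple[int, str], ...]    # (ref position after which inserted, seq)
    deletions: tuple[tuple[int, str], ...]     # (1-based start, deleted seq)
    n_pam_edits_observed: int = 0
    hdr_gated: bool = False
    rna_splice_ok: bool | None = None

    @property
    def indels(self) -> tuple:
        return self.insertions + self.deletions

    @property
    def has_indel(self) -> bool:
        return bool(self.insertions or self.deletions)


def extract_edits(
    alignment: Alignment, design: RegionDesign, read_id: str = "", ref_offset: int = 0
) -> EditCall:
    """List substitutions/InDels with 1-based amplicon coordinates and gate on PAM edits.

    ``ref_offset`` shifts reported positions when the alignment reference is a
    sub-sequence of the amplicon (RNA reads are aligned exon-only).
    """
    subs: set[tuple[int, str]] = set()
    insertions: list[tuple[int, str]] = []
    deletions: list[tuple[int, str]] = []
    rpos = ref_offset  # 1-based position of the last consumed reference base
    i = 0
    ar, aq = alignment.aligned_ref, alignment.aligned_read
    n = len(ar)
    while i < n:
        if ar[i] == "-":  # insertion in read
            j = i
            while j < n and ar[j] == "-":
                j += 1
            insertions.append((rpos, aq[i:j]))
            i = j
        elif aq[i] == "-":  # deletion from reference
            j = i
            while j < n and aq[j] == "-":
                j += 1
            deletions.append((rpos + 1, ar[i:j]))
            rpos += j - i
            i = j
        else:
            rpos += 1
            if aq[i] != ar[i]:
                subs.add((rpos, aq[i]))
            i += 1
    n_pam = sum((pos, alt) in subs for pos, alt in design.pam_edits)
    return EditCall(
        read_id=read_id,
        substitutions=frozenset(subs),
        insertions=tuple(insertions),
        deletions=tuple(deletions),
        n_pam_edits_observed=n_pam,
        hdr_gated=n_pam >= 1,
    )


def gate_rna_read(call: EditCall, read: str, design: RegionDesign) -> bool:
    """RNA gate: HDR marker present AND exact transcript flanks on both sides.

    Spliced-transcript reads must show the expected sequence on either side
    of the target exon; exon skipping or intron retention breaks the flank
    match and the read is dropped.
    """
    if design.transcript_flanks is None:
        raise ValueError(f"region {design.region_id} has no transcript_flanks; cannot gate RNA")
    if not call.hdr_gated:
        return False
    up, down = design.transcript_flanks
    return up in read and down in read and read.index(up) < read.rindex(down)


def tally_variant_counts(
    calls: Iterable[EditCall],
    design: RegionDesign,
    region: str,
    replicate: int,
    timepoint: str,
    analyte: str = "gDNA",
) -> pd.DataFrame:
    """Count HDR-gated reads per designed SNV for one sample.

    Reads carrying two or more designed SNVs are discarded entirely (the
    assay engineers a single variant per haploid cell, so multi-SNV reads are
    artifacts).  ``sample_total`` is the number of gated reads retained.
    Every designed SNV gets a row, including zero counts.
    """
    designed = {(v.position, v.alt): v for v in design.designed_snvs}
    counts = {v.hgvs_c: 0 for v in design.designed_snvs}
    total = 0
    for call in calls:
        gated = call.hdr_gated if analyte == "gDNA" else bool(call.rna_splice_ok)
        if not gated or call.has_indel:
            continue
        hits = [designed[s] for s in call.substitutions if s in designed]
        if len(hits) >= 2:
            continue  # multi-SNV read: excluded from numerator and denominator
        total += 1
        if len(hits) == 1:
            counts[hits[0].hgvs_c] += 1
    rows = [
        {
            "region": region,
            "replicate": replicate,
            "timepoint": timepoint,
            "analyte": analyte,
            "hgvs_c": v.hgvs_c,
            "consequence": v.consequence,
            "codon_index": v.codon_index,
            "read_count": counts[v.hgvs_c],
            "sample_total": total,
        }
        for v in design.designed_snvs
    ]
    return pd.DataFrame(rows)


def tally_indel_outcomes(
    alignments_by_day: dict[str, list[Alignment]],
    min_freq: float = 0.001,
    min_lead_match: int = 100,
) -> pd.DataFrame:
    """Tally editing outcomes by CIGAR string across day-6 and day-13 samples.

    Inclusion rules: outcome day-6 frequency above ``min_freq``; at most one
    InDel operation in the CIGAR; and a leading exact match of at least
    ``min_lead_match`` bases on the 5' end.
    """
    freqs = {}
    for day, alns in alignments_by_day.items():
        n = len(alns)
        tab: dict[str, int] = {}
        for a in alns:
            tab[a.cigar] = tab.get(a.cigar, 0) + 1
        freqs[day] = {c: k / n for c, k in tab.items()} if n else {}
    rows = []
    all_cigars = set().union(*[set(f) for f in freqs.values()]) if freqs else set()
    for cig in sorted(all_cigars):
        f6 = freqs.get("d6", {}).get(cig, 0.0)
        f13 = freqs.get("d13", {}).get(cig, 0.0)
        if f6 <= min_freq:
            continue
        ops = _parse_cigar(cig)
        n_indel = sum(1 for op, _ in ops if op in "ID")
        if n_indel > 1:
            continue
        if not ops or ops[0][0] != "M" or ops[0][1] < min_lead_match:
            continue
        net = sum(n if op == "I" else -n for op, n in ops if op in "ID")
        rows.append(
            {"cigar": cig, "net_length": net, "d6_freq": f6, "d13_freq": f13}
        )
    return pd.DataFrame(rows, columns=["cigar", "net_length", "d6_freq", "d13_freq"])


def _parse_cigar(cigar: str) -> list[tuple[str, int]]:
    ops = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            ops.append((ch, int(num)))
            num = ""
    return ops


def read_fastq(path: str) -> Iterator[tuple[str, str]]:
    """Yield (read id, sequence) from a FASTQ file, gzipped or plain."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield rec.id, str(rec.seq)


def count_sample(
    r1_path: str,
    r2_path: str,
    design: RegionDesign,
    replicate: int,
    timepoint: str,
    analyte: str = "gDNA",
    min_overlap: int = 20,
) -> pd.DataFrame:
    """FASTQ pair -> HDR-gated count table for one sample."""
    calls = []
    for (rid, s1), (_, s2) in zip(read_fastq(r1_path), read_fastq(r2_path)):
        try:
            merged = merge_read_pair(s1, s2, min_overlap=min_overlap)
        except MergeRejection:
            continue
        calls.append(call_read(merged, design, read_id=rid, analyte=analyte))
    return tally_variant_counts(
        calls, design, design.region_id, replicate, timepoint, analyte
    )


def call_read(
    merged: str, design: RegionDesign, read_id: str = "", analyte: str = "gDNA"
) -> EditCall:
    """Align one merged read and extract its edit call.

    gDNA reads align against the full reference amplicon.  RNA reads are
    spliced: the exact transcript flanks are located, the exonic portion is
    excised and aligned against the exonic reference, and the RNA splice gate
    records whether both flanks matched perfectly.
    """
    if analyte == "gDNA":
        aln = global_align(merged, design.ref_amplicon)
        return extract_edits(aln, design, read_id=read_id)
    if design.transcript_flanks is None:
        raise ValueError(f"region {design.region_id} has no transcript_flanks")
    up, down = design.transcript_flanks
    i = merged.find(up)
    j = merged.rfind(down)
    if i == -1 or j == -1 or i + len(up) > j:
        call = EditCall(read_id, frozenset(), (), (), 0, False)
        call.rna_splice_ok = False
        return call
    exon_read = merged[i + len(up) : j]
    ref_exon = design.ref_amplicon[design.cds_start - 1 : design.cds_end]
    aln = global_align(exon_read, ref_exon) if exon_read else None
    if aln is None:
        call = EditCall(read_id, frozenset(), (), (), 0, False)
        call.rna_splice_ok = False
        return call
    call = extract_edits(aln, design, read_id=read_id, ref_offset=design.cds_start - 1)
    call.rna_splice_ok = call.hdr_gated
    return call
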