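"""Synthetic VHL-like reference mRNA (CDS + 3'UTR).

This module constructs a SYNTHETIC stand-in for the VHL coding sequence plus
downstream 3'UTR — it is not the RefSeq transcript.  It reproduces the
landmarks that the package's C-terminal-extension and stop-codon-context
analyses depend on:

- a 213-residue CDS (642 nt including the natural stop at codon 214);
- tryptophan (TGG) codons at residues 88 and 117, each followed by a C, so
  that c.264G>A and c.351G>A create opal stops in the permissive 5'-UGA-C
  readthrough context (and c.263G>A / c.350G>A create amber stops);
- an arginine codon at residue 200 and a CDS tail (codons 200-213) free of
  A bases, so no stop codon can arise in any frame before the natural stop;
- a 3'UTR whose first +1-frame stop is placed so that any single-base
  (net +1) frameshift between p.R200 and the natural stop extends the
  protein by exactly 41 amino acids, with stops in the other frames further
  downstream so every frameshift terminates.

Use :func:`synthetic_vhl_like_mrna` wherever the analyses need "the" VHL
transcript; tests verify the landmark properties against a codon-by-codon
translation oracle.
"""

from __future__ import annotations

from .design import STOP_CODONS

CDS_LEN = 642          # 213 residues + stop codon
NATURAL_PROTEIN_LEN = 213

_FILL = ["GCT", "GAA", "GTG", "CTG", "CCA", "TCT"]  # stop-free filler codons


def synthetic_vhl_like_mrna() -> tuple[str, int]:
    """Return (CDS + 3'UTR sequence, CDS length) of the synthetic transcript."""
    codons: list[str] = []
    for i in range(1, 214):  # residues 1..213
        if i == 1:
            codons.append("ATG")
        elif i == 88 or i == 117:
            codons.append("TGG")       # Trp; third-base G>A creates opal UGA
        elif i == 89:
            codons.append("CCG")       # starts with C -> UGA-C context at 88
        elif i == 118:
            codons.append("CAC")       # starts with C -> UGA-C context at 117
        elif i >= 200:
            codons.append("CGT")       # Arg tail, A-free: no stop in any frame
        else:
            codons.append(_FILL[i % len(_FILL)])
    codons.append("TAA")               # natural stop, codon 214
    cds = "".join(codons)
    assert len(cds) == CDS_LEN

    # 3'UTR: an early -1-frame stop (UTR bases 8-10) so -1 frameshifts gain
    # only a short tail; an A/T-free body so no other frame can terminate
    # early; the +1-frame stop planted at UTR bases 120-122 (reference
    # 762-764) so +1 frameshifts extend the protein by 41 residues; then
    # stops in the remaining frames.
    utr = "CGGCGGC" + "TAA" + "CGG" * 36 + "C" + "TAA" + "GTTAGCTGACTAAGTGACTAAGCTAGCTAA"
    seq = cds + utr

    # sanity: the planted stop sits where a +1 frameshift reads it
    assert seq[761:764] == "TAA"
    return seq, CDS_LEN


def landmark_checks() -> dict[str, bool]:
    """Self-checks of the landmark properties (used by tests and docs)."""
    seq, cds_len = synthetic_vhl_like_mrna()
    cds = seq[:cds_len]
    checks = {
        "codon88_TGG": cds[261:264] == "TGG",
        "c265_is_C": cds[264] == "C",
        "codon117_TGG": cds[348:351] == "TGG",
        "c352_is_C": cds[351] == "C",
        "natural_stop": cds[639:642] in STOP_CODONS,
        "no_stop_in_frame_before_end": all(
            cds[i : i + 3] not in STOP_CODONS for i in range(0, 639, 3)
        ),
    }
    return checks
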