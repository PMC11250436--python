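"""Region designs and variant specifications for saturation genome editing (SGE).

An SGE *region* is one amplicon targeted for homology-directed repair (HDR)
with a library of single-nucleotide variants (SNVs).  Each library molecule
also carries one or two synonymous "PAM edit" marker substitutions that
destroy the CRISPR protospacer-adjacent motif; in sequencing they prove a
read derives from HDR rather than from the unedited locus.

Coordinates
-----------
Amplicon positions are 1-based.  Coding positions use HGVS ``c.`` numbering;
``cds_offset`` maps amplicon position ``a`` to ``c. = a - cds_offset`` for
positions inside the exon, so the first coding base of the region satisfies
``c. = cds_start``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable

import yaml
from Bio.Seq import Seq

VALID_CONSEQUENCES = (
    "synonymous",
    "missense",
    "nonsense",
    "canonical_splice",
    "splice_region",
    "intronic",
    "utr",
)

STOP_CODONS = {"TAA", "TAG", "TGA"}


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a DNA codon; '*' for stop."""
    if len(codon) != 3:
        raise ValueError(f"codon must be 3 bases, got {codon!r}")
    return str(Seq(codon).translate())


@dataclass(frozen=True)
class VariantSpec:
    """One designed SNV.

    ``hgvs_c`` is the coding-level name (e.g. ``c.264G>A``); ``codon_index``
    is the 1-based residue number for coding variants, ``None`` otherwise.
    """

    region_id: str
    position: int          # 1-based amplicon position
    ref: str
    alt: str
    hgvs_c: str
    consequence: str
    protein_change: str | None = None
    codon_index: int | None = None

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError(f"{self.hgvs_c}: ref equals alt")
        if self.consequence not in VALID_CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")


@dataclass
class RegionDesign:
    """Design of one SGE region.

    Parameters
    ----------
    ref_amplicon
        Reference amplicon sequence (the unedited locus).
    cds_start, cds_end
        1-based amplicon positions of the first/last coding base covered.
        ``None`` for fully non-coding regions (e.g. a deep-intronic region).
    cds_offset
        ``c. position = amplicon position - cds_offset`` inside the exon.
    codon_start
        1-based residue number of the codon containing ``cds_start``; together
        with ``phase`` (0/1/2 bases of that codon lying upstream of the
        region) it anchors codon translation.
    pam_edits
        Synonymous HDR-marker substitutions as ``(position, alt)`` pairs.
    transcript_flanks
        ``(upstream, downstream)`` spliced-transcript sequence expected on
        either side of the target exon in RNA reads; required to gate RNA.
    scaling_window
        Closed codon interval used to pick nonsense anchors for cross-region
        scaling (default residues 54-198).
    """

    region_id: str
    ref_amplicon: str
    cds_start: int | None = None
    cds_end: int | None = None
    cds_offset: int = 0
    codon_start: int = 1
    phase: int = 0
    pam_edits: list[tuple[int, str]] = field(default_factory=list)
    transcript_flanks: tuple[str, str] | None = None
    designed_snvs: list[VariantSpec] = field(default_factory=list)
    scaling_window: tuple[int, int] = (54, 198)
    is_intron_region: bool = False

    def __post_init__(self):
        n = len(self.ref_amplicon)
        for pos, alt in self.pam_edits:
            if not (1 <= pos <= n):
                raise ValueError(f"PAM edit position {pos} outside amplicon")
            if self.ref_amplicon[pos - 1] == alt:
                raise ValueError(f"PAM edit at {pos} equals reference base")
        for v in self.designed_snvs:
            if not (1 <= v.position <= n):
                raise ValueError(f"designed SNV {v.hgvs_c} outside amplicon")

    # ------------------------------------------------------------------
    def is_coding(self, pos: int) -> bool:
        return (
            self.cds_start is not None
            and self.cds_end is not None
            and self.cds_start <= pos <= self.cds_end
        )

    def c_position(self, pos: int) -> int:
        return pos - self.cds_offset

    def codon_at(self, pos: int) -> tuple[int, int, str]:
        """(codon_index, offset within codon 0-2, codon sequence) at amplicon ``pos``."""
        if not self.is_coding(pos):
            raise ValueError(f"position {pos} is not coding in {self.region_id}")
        # bases since the start of the first (possibly partial) codon
        rel = (pos - self.cds_start) + self.phase
        codon_index = self.codon_start + rel // 3
        offset = rel % 3
        codon_first = pos - offset
        codon = self.ref_amplicon[codon_first - 1 : codon_first + 2]
        if len(codon) < 3:
            raise ValueError(f"codon at {pos} extends past amplicon end")
        return codon_index, offset, codon

    def snv_consequence(self, pos: int, alt: str) -> tuple[str, str | None, int | None]:
        """Classify an SNV: (consequence, protein change, codon index).

        Canonical splice sites are the two intronic bases flanking the exon;
        other non-coding positions are ``intronic`` (or ``utr`` for regions
        flagged as UTR-only, which callers handle via design metadata).
        """
        if self.cds_start is None or not self.is_coding(pos):
            if self.cds_start is not None and (
                self.cds_start - 2 <= pos < self.cds_start
                or self.cds_end < pos <= self.cds_end + 2
            ):
                return "canonical_splice", None, None
            return "intronic", None, None
        codon_index, offset, codon = self.codon_at(pos)
        alt_codon = codon[:offset] + alt + codon[offset + 1 :]
        aa_ref = translate_codon(codon)
        aa_alt = translate_codon(alt_codon)
        pchange = f"p.{aa_ref}{codon_index}{aa_alt if aa_alt != '*' else '*'}"
        if aa_alt == aa_ref:
            cons = "synonymous"
        elif aa_alt == "*":
            cons = "nonsense"
        else:
            cons = "missense"
        return cons, pchange, codon_index

    def make_variant(self, pos: int, alt: str) -> VariantSpec:
        ref = self.ref_amplicon[pos - 1]
        cons, pchange, codon_index = self.snv_consequence(pos, alt)
        if self.is_coding(pos):
            hgvs = f"c.{self.c_position(pos)}{ref}>{alt}"
        else:
            # region-qualified name: non-coding positions have no shared c. axis
            hgvs = f"{self.region_id}:n.{pos}{ref}>{alt}"
        return VariantSpec(
            region_id=self.region_id,
            position=pos,
            ref=ref,
            alt=alt,
            hgvs_c=hgvs,
            consequence=cons,
            protein_change=pchange,
            codon_index=codon_index,
        )

    # ------------------------------------------------------------------
    def pam_codon_conflicts(self) -> set[str]:
        """Designed SNVs whose amino acid differs with vs without a same-codon PAM edit.

        These are excluded during quality filtering: the engineered molecule
        carries both edits in one codon, so its protein change is not the
        SNV's nominal one.
        """
        bad: set[str] = set()
        for v in self.designed_snvs:
            if v.codon_index is None:
                continue
            try:
                _, offset, codon = self.codon_at(v.position)
            except ValueError:
                continue
            codon_first = v.position - offset
            for ppos, palt in self.pam_edits:
                if codon_first <= ppos <= codon_first + 2 and ppos != v.position:
                    poff = ppos - codon_first
                    with_snv = codon[:offset] + v.alt + codon[offset + 1 :]
                    both = (
                        with_snv[:poff] + palt + with_snv[poff + 1 :]
                    )
                    if translate_codon(both) != translate_codon(with_snv):
                        bad.add(v.hgvs_c)
        return bad

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["pam_edits"] = [list(p) for p in self.pam_edits]
        if self.transcript_flanks is not None:
            d["transcript_flanks"] = list(self.transcript_flanks)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RegionDesign":
        d = dict(d)
        d["pam_edits"] = [tuple(p) for p in d.get("pam_edits", [])]
        if d.get("transcript_flanks") is not None:
            d["transcript_flanks"] = tuple(d["transcript_flanks"])
        snvs = [
            v if isinstance(v, VariantSpec) else VariantSpec(**v)
            for v in d.get("designed_snvs", [])
        ]
        d["designed_snvs"] = snvs
        if d.get("scaling_window") is not None:
            d["scaling_window"] = tuple(d["scaling_window"])
        return cls(**d)


def save_designs(designs: Iterable[RegionDesign], path: str) -> None:
    payload = [d.to_dict() for d in designs]
    with open(path, "w") as fh:
        if str(path).endswith((".yaml", ".yml")):
            yaml.safe_dump(payload, fh)
        else:
            json.dump(payload, fh, indent=1)


def load_designs(path: str) -> list[RegionDesign]:
    with open(path) as fh:
        if str(path).endswith((".yaml", ".yml")):
            payload = yaml.safe_load(fh)
        else:
            payload = json.load(fh)
    return [RegionDesign.from_dict(d) for d in payload]
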