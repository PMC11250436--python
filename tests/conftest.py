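import numpy as np
import pandas as pd
import pytest

from sgekit.design import RegionDesign
from sgekit.simulate import SimConfig, simulate_experiment


@pytest.fixture(scope="session")
def toy_design():
    """Small hand-built region: 10-bp flanks, 24-bp coding exon (8 codons)."""
    #               flank(10)     exon: ATG GCT TGG CAT CGT GAA TCT TAA? no stop: use CTT
    exon = "ATGGCTTGGCATCGTGAATCTCTT"
    amplicon = "GATCGATCGA" + exon + "TTGACCGGTA"
    d = RegionDesign(
        region_id="toy",
        ref_amplicon=amplicon,
        cds_start=11,
        cds_end=34,
        cds_offset=10,      # c.1 at amplicon position 11
        codon_start=1,
        phase=0,
        pam_edits=[(16, "A"), (31, "C")],  # GCT->GCA (Ala), TCT->TCC (Ser)
        transcript_flanks=("TCGATCGA", "TTGACCGG"),
    )
    pam_set = set(d.pam_edits)
    d.designed_snvs = [
        d.make_variant(pos, alt)
        for pos in range(11, 35)
        for alt in "ACGT"
        if alt != amplicon[pos - 1] and (pos, alt) not in pam_set
    ]
    return d


@pytest.fixture(scope="session")
def default_sim():
    """Default-condition synthetic experiment (seed 11), scored end to end."""
    cfg = SimConfig(seed=11)
    res = simulate_experiment(cfg)
    from sgekit.pipeline import score_experiment

    scored = score_experiment(res.counts, res.designs)
    merged = scored.merge(
        res.truth[["hgvs_c", "region", "s", "rna_effect", "true_class"]],
        on=["hgvs_c", "region"],
        how="left",
    )
    return res, merged


def make_filter_fixture():
    """12-SNV count table tripping each quality-filter rule exactly once.

    Manual derivation (totals 1e6, pseudocount 0.5; freq ~ count/1e6):
      v1  library count 50 both reps -> lib freq 5.05e-5 < 1e-4    [low_library]
      v2  day-6 rep2 count 8 -> 8.5e-6 < 1e-5; d13/d20 rep2 kept
          at 8 so ratios stay 0                                    [low_day6]
      v3  rep1 log2(d20/d6)=+0.4, rep2=-1.2; diff 1.6 > 1.5 and
          not both < -1.0                                          [replicate_discordant]
      v4  both reps d13/d6=+0.3, d20/d13=-1.8; diff 2.1 > 2.0 and
          d13/d6 >= -0.5                                           [trajectory_discordant]
      v5  negctrl count 1500 vs d6=d20=2000: 0.75 > 0.5            [error_dominated]
      v6  flagged as sharing a codon with a PAM edit               [pam_codon_conflict]
      v7-v12  clean counts (~2000 everywhere) -> pass
    Survivors: 6.
    """
    rows = []
    specs = {
        "v1": {"lib": 50},
        "v2": {"d6_r2": 8, "d13_r2": 8, "d20_r2": 8},
        "v3": {"d20_r1": 2639, "d13_r1": 2297, "d20_r2": 871, "d13_r2": 1320},
        "v4": {"d13_r1": 2462, "d20_r1": 707, "d13_r2": 2462, "d20_r2": 707},
        "v5": {"nc": 1500},
        "v6": {},
        "v7": {}, "v8": {}, "v9": {}, "v10": {}, "v11": {}, "v12": {},
    }
    base = {"lib": 2000, "nc": 0, "d6": 2000, "d13": 2000, "d20": 2000}
    for name, over in specs.items():
        for rep in (1, 2):
            for tp, key in (
                ("library", "lib"),
                ("negctrl_d6", "nc"),
                ("d6", "d6"),
                ("d13", "d13"),
                ("d20", "d20"),
            ):
                count = over.get(f"{key}_r{rep}", over.get(key, base[key]))
                rows.append(
                    {
                        "region": "fix",
                        "replicate": rep,
                        "timepoint": tp,
                        "analyte": "gDNA",
                        "hgvs_c": name,
                        "consequence": "missense",
                        "codon_index": 100,
                        "read_count": count,
                        "sample_total": 1_000_000,
                    }
                )
    return pd.DataFrame(rows), {"v6"}, 6  # counts, pam conflicts, survivors


@pytest.fixture(scope="session")
def filter_fixture():
    return make_filter_fixture()
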