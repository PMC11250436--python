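import itertools
import math

import numpy as np
import pandas as pd
import pytest

from oracles import translate
from sgekit import scoring
from sgekit.scoring import (
    MergeRule,
    center_on_synonymous,
    compute_ratios,
    frame_class,
    frequencies,
    indel_scores,
    log2_ratio,
    merge_overlaps,
    predict_frameshift_extension,
    quality_filter,
    rna_scores,
    scale_across_regions,
)


class TestFrequencies:
    def test_plain_ratio(self):
        assert frequencies(30, 3000, pseudocount=0) == pytest.approx(0.01)

    def test_pseudocount_on_zero(self):
        assert frequencies(0, 1000, pseudocount=0.5) == pytest.approx(0.5 / 1000.5)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            frequencies(-1, 100)

    def test_log2_ratio_examples(self):
        assert log2_ratio(0.01, 0.01) == pytest.approx(0.0)
        assert log2_ratio(0.0025, 0.01) == pytest.approx(-2.0)
        rng = np.random.default_rng(0)
        f1, f2 = rng.uniform(1e-6, 1e-2, 50), rng.uniform(1e-6, 1e-2, 50)
        assert log2_ratio(f1, f2) == pytest.approx(np.log(f1 / f2) / np.log(2))

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            log2_ratio(0.01, 0.0)


class TestQualityFilter:
    BASE = dict(
        lib_freq=2e-3,
        d6_freqs=(2e-3, 2e-3),
        d20_freqs=(2e-3, 2e-3),
        rep_log2_d20_d6=(0.0, 0.0),
        log2_d13_d6=0.0,
        log2_d20_d13=0.0,
        error_freq=0.0,
        pam_codon_conflict=False,
    )

    def check(self, **over):
        return quality_filter(**{**self.BASE, **over})

    def test_low_library(self):
        assert self.check(lib_freq=5e-5) == ["low_library"]
        assert self.check(lib_freq=1.0e-4) == []  # strict inequality

    def test_low_day6_either_replicate(self):
        assert self.check(d6_freqs=(2e-3, 8e-6)) == ["low_day6"]
        assert self.check(d6_freqs=(1.0e-5, 1.0e-5)) == []

    def test_replicate_discordance_with_escape(self):
        # both strongly depleted: large difference excused
        assert self.check(rep_log2_d20_d6=(-2.6, -1.05)) == []
        assert "replicate_discordant" in self.check(rep_log2_d20_d6=(0.4, -1.2))
        assert self.check(rep_log2_d20_d6=(0.0, 1.5)) == []  # diff == 1.5 passes

    def test_trajectory_discordance_with_escape(self):
        assert "trajectory_discordant" in self.check(log2_d13_d6=0.3, log2_d20_d13=-1.8)
        assert self.check(log2_d13_d6=-1.5, log2_d20_d13=-4.0) == []  # both < -0.5

    def test_error_dominance(self):
        assert self.check(error_freq=1.2e-3) == ["error_dominated"]  # 0.6 ratio
        assert self.check(error_freq=1.0e-3) == []  # exactly 0.5 passes
        # max(d6, d20) is the denominator: high d20 rescues
        assert self.check(d6_freqs=(1e-4, 1e-4), d20_freqs=(4e-3, 4e-3),
                          error_freq=1.2e-3) == []

    def test_pam_codon_conflict(self):
        assert self.check(pam_codon_conflict=True) == ["pam_codon_conflict"]

    def test_reasons_accumulate_order_independent(self):
        reasons = self.check(
            lib_freq=5e-5, d6_freqs=(8e-6, 2e-3), pam_codon_conflict=True
        )
        assert set(reasons) == {"low_library", "low_day6", "pam_codon_conflict"}


class TestFilterFixture:
    def test_each_rule_trips_exactly_once(self, filter_fixture):
        counts, pam_conflicts, expected_survivors = filter_fixture
        ratios = compute_ratios(counts, pam_conflicts=pam_conflicts)
        tripped = list(
            itertools.chain.from_iterable(
                r.split(",") for r in ratios["filter_reasons"] if r
            )
        )
        assert sorted(tripped) == sorted(scoring.FILTER_REASONS)

    def test_survivor_count_matches_manual_derivation(self, filter_fixture):
        counts, pam_conflicts, expected_survivors = filter_fixture
        ratios = compute_ratios(counts, pam_conflicts=pam_conflicts)
        assert int(ratios["filter_pass"].sum()) == expected_survivors


def _region_df(raw, consequences, region="r1", codon=None, passing=None):
    n = len(raw)
    return pd.DataFrame(
        {
            "region": region,
            "hgvs_c": [f"{region}v{i}" for i in range(n)],
            "consequence": consequences,
            "codon_index": codon if codon is not None else [100] * n,
            "raw_score": raw,
            "filter_pass": passing if passing is not None else [True] * n,
        }
    )


class TestCentering:
    def test_synonymous_median_subtracted(self):
        df = _region_df([-0.2, 0.1, 0.4, -2.0], ["synonymous"] * 3 + ["nonsense"])
        out = center_on_synonymous(df)
        assert out["centered_score"].tolist() == pytest.approx([-0.3, 0.0, 0.3, -2.1])

    def test_median_of_synonymous_centered_is_zero(self):
        rng = np.random.default_rng(5)
        for n_syn in (3, 4, 7, 10):
            raw = list(rng.normal(0, 1, n_syn + 5))
            cons = ["synonymous"] * n_syn + ["missense"] * 5
            out = center_on_synonymous(_region_df(raw, cons))
            syn = out[out["consequence"] == "synonymous"]["centered_score"]
            assert np.median(syn) == pytest.approx(0.0, abs=1e-15)

    def test_even_count_uses_mean_of_middle_two(self):
        df = _region_df([0.0, 1.0, 2.0, 3.0], ["synonymous"] * 4)
        out = center_on_synonymous(df)
        assert out["centered_score"].tolist() == pytest.approx([-1.5, -0.5, 0.5, 1.5])

    def test_only_passing_synonymous_used(self):
        df = _region_df(
            [0.0, 5.0, -1.0],
            ["synonymous", "synonymous", "nonsense"],
            passing=[True, False, True],
        )
        out = center_on_synonymous(df)
        assert out["centered_score"].tolist() == pytest.approx([0.0, 5.0, -1.0])

    def test_intron_region_centers_on_all_passing(self):
        df = _region_df([0.1, 0.3, 0.5], ["intronic"] * 3)
        out = center_on_synonymous(df, is_intron_region=True)
        assert out["centered_score"].tolist() == pytest.approx([-0.2, 0.0, 0.2])

    def test_no_eligible_variants_is_error(self):
        df = _region_df([0.1], ["missense"], passing=[False])
        with pytest.raises(ValueError):
            center_on_synonymous(df)


class TestScaling:
    def _with_attrs(self, df, window=(54, 198), intron=False):
        df.attrs["scaling_window"] = window
        df.attrs["is_intron_region"] = intron
        return df

    def test_hand_computed_factor(self):
        # region A anchors at -1.5 (x3), region B at -2.4 (x7):
        # pooled median -2.4 -> k_A = 1.6, so centered -1.0 -> -1.6
        a = _region_df([-1.5] * 3 + [-1.0], ["nonsense"] * 3 + ["missense"], region="A")
        a["centered_score"] = a["raw_score"]
        b = _region_df([-2.4] * 7, ["nonsense"] * 7, region="B")
        b["centered_score"] = b["raw_score"]
        out = scale_across_regions(
            {"A": self._with_attrs(a), "B": self._with_attrs(b)}
        )
        assert out["A"]["scale_factor"].iloc[0] == pytest.approx(1.6)
        assert out["A"]["function_score"].iloc[3] == pytest.approx(-1.6)
        assert out["B"]["function_score"].tolist() == pytest.approx([-2.4] * 7)

    def test_anchor_median_equalized_across_regions(self):
        rng = np.random.default_rng(9)
        regions = {}
        for rid, shift in (("A", -1.0), ("B", -2.0), ("C", -3.0)):
            raw = list(shift + rng.normal(0, 0.3, 8)) + list(rng.normal(0, 0.1, 4))
            df = _region_df(raw, ["nonsense"] * 8 + ["synonymous"] * 4, region=rid)
            df["centered_score"] = df["raw_score"]
            regions[rid] = self._with_attrs(df)
        out = scale_across_regions(regions)
        medians = [
            np.median(
                d[d["consequence"] == "nonsense"]["function_score"]
            )
            for d in out.values()
        ]
        assert max(medians) - min(medians) < 1e-12

    def test_out_of_window_nonsense_not_used(self):
        a = _region_df(
            [-1.5] * 3 + [-9.0],
            ["nonsense"] * 4,
            region="A",
            codon=[100, 110, 120, 300],  # last one outside p.54-198
        )
        a["centered_score"] = a["raw_score"]
        b = _region_df([-3.0] * 5, ["nonsense"] * 5, region="B")
        b["centered_score"] = b["raw_score"]
        out = scale_across_regions({"A": self._with_attrs(a), "B": self._with_attrs(b)})
        assert out["A"]["scale_factor"].iloc[0] == pytest.approx(2.0)  # -3 / -1.5

    def test_insufficient_anchors_fall_back_to_unit_factor(self):
        a = _region_df([-1.5, -0.2], ["nonsense", "synonymous"], region="A")
        a["centered_score"] = a["raw_score"]
        b = _region_df([-2.0] * 5, ["nonsense"] * 5, region="B")
        b["centered_score"] = b["raw_score"]
        with pytest.warns(UserWarning):
            out = scale_across_regions(
                {"A": self._with_attrs(a), "B": self._with_attrs(b)}
            )
        assert out["A"]["scale_factor"].iloc[0] == 1.0


class TestMergeOverlaps:
    def _scores(self, rows):
        return pd.DataFrame(
            rows, columns=["region", "hgvs_c", "consequence", "function_score", "filter_pass"]
        )

    def test_take_second(self):
        df = self._scores(
            [("exon1_5p", "c.10A>G", "missense", 0.5, True),
             ("exon1_mid", "c.10A>G", "missense", -0.1, True)]
        )
        out = merge_overlaps(df)
        assert len(out) == 1
        assert out["function_score"].iloc[0] == pytest.approx(-0.1)

    def test_mean(self):
        df = self._scores(
            [("exon1_mid", "c.50A>G", "missense", -0.2, True),
             ("exon1_3p", "c.50A>G", "missense", 0.0, True)]
        )
        out = merge_overlaps(df)
        assert out["function_score"].iloc[0] == pytest.approx(-0.1)
        assert out["merged_from"].iloc[0] == "exon1_3p+exon1_mid"

    def test_single_region_unchanged(self):
        df = self._scores([("exon2", "c.200G>T", "missense", -1.4, True)])
        out = merge_overlaps(df)
        assert out["function_score"].iloc[0] == pytest.approx(-1.4)

    def test_unruled_duplicate_is_config_error(self):
        df = self._scores(
            [("exon2", "c.9A>T", "missense", 0.1, True),
             ("exon3_5p", "c.9A>T", "missense", 0.2, True)]
        )
        with pytest.raises(ValueError):
            merge_overlaps(df)


class TestRnaScores:
    def _tables(self):
        rows = []
        # gDNA d6/d20 and RNA d6/d20 for two variants; coding one has RNA
        # freq 1/16 of gDNA on day 6 -> rna score -4
        for rep in (1, 2):
            for tp, analyte, counts in [
                ("d6", "gDNA", {"c.3G>A": 1600, "intr": 1600}),
                ("d20", "gDNA", {"c.3G>A": 1600, "intr": 1600}),
                ("d6", "RNA", {"c.3G>A": 100, "intr": 0}),
                ("d20", "RNA", {"c.3G>A": 1600, "intr": 0}),
            ]:
                for hgvs, c in counts.items():
                    rows.append(
                        {
                            "region": "r",
                            "replicate": rep,
                            "timepoint": tp,
                            "analyte": analyte,
                            "hgvs_c": hgvs,
                            "consequence": "missense" if hgvs.startswith("c.") else "intronic",
                            "codon_index": 1 if hgvs.startswith("c.") else None,
                            "read_count": c,
                            "sample_total": 100_000,
                        }
                    )
        counts = pd.DataFrame(rows)
        ratios = pd.DataFrame(
            {
                "hgvs_c": ["c.3G>A", "intr"],
                "consequence": ["missense", "intronic"],
                "filter_pass": [True, True],
                "d6_r1": [16.005e-3, 16.005e-3],
                "d6_r2": [16.005e-3, 16.005e-3],
                "d20_r1": [16.005e-3, 16.005e-3],
                "d20_r2": [16.005e-3, 16.005e-3],
            }
        )
        return counts, ratios

    def test_log2_rna_over_gdna(self):
        counts, ratios = self._tables()
        out = rna_scores(counts, ratios, pseudocount=0.5)
        coding = out[out["hgvs_c"] == "c.3G>A"].iloc[0]
        assert coding["rna_score_d6"] == pytest.approx(-4.0, abs=0.01)
        assert coding["rna_score_d20"] == pytest.approx(0.0, abs=0.01)

    def test_noncoding_gets_no_rna_score(self):
        counts, ratios = self._tables()
        out = rna_scores(counts, ratios)
        assert np.isnan(out[out["hgvs_c"] == "intr"]["rna_score_d6"].iloc[0])

    def test_filtered_variant_gets_no_rna_score(self):
        counts, ratios = self._tables()
        ratios.loc[0, "filter_pass"] = False
        out = rna_scores(counts, ratios)
        assert np.isnan(out[out["hgvs_c"] == "c.3G>A"]["rna_score_d6"].iloc[0])


class TestIndelScores:
    def test_frame_classes(self):
        assert frame_class(1) == "plus1"
        assert frame_class(-3) == "in_frame"
        assert frame_class(-1) == "minus1"
        assert frame_class(4) == "plus1"
        assert frame_class(-2) == "plus1"  # -2 and +1 share a reading frame

    def test_zero_change_scores_zero(self):
        df = pd.DataFrame(
            {"cigar": ["100M1D100M"], "net_length": [-1],
             "d6_freq": [0.01], "d13_freq": [0.01]}
        )
        out = indel_scores({1: df, 2: df})
        assert out["indel_score"].iloc[0] == pytest.approx(0.0)
        assert out["frame_class"].iloc[0] == "minus1"

    def test_replicate_mean(self):
        d1 = pd.DataFrame({"cigar": ["100M1I100M"], "net_length": [1],
                           "d6_freq": [0.01], "d13_freq": [0.0025]})
        d2 = pd.DataFrame({"cigar": ["100M1I100M"], "net_length": [1],
                           "d6_freq": [0.01], "d13_freq": [0.01]})
        out = indel_scores({1: d1, 2: d2})
        assert out["indel_score"].iloc[0] == pytest.approx(-1.0)


class TestFrameshiftExtension:
    def test_in_frame_deletion_no_extension(self):
        cds = "ATG" + "GCT" * 50 + "TAA"
        seq = cds + "CGGCGG" + "TAATAA" * 10
        stop, ext = predict_frameshift_extension(seq, len(cds), 30, -3)
        assert ext == 0

    def test_matches_translation_oracle_on_random_sequences(self):
        """Frameshift stop positions agree with codon-by-codon translation."""
        rng = np.random.default_rng(12)
        bases = np.array(list("ACGT"))
        n_checked = 0
        for trial in range(40):
            ncod = int(rng.integers(20, 60))
            cds = "ATG" + "".join(
                c for c in ("".join(bases[rng.integers(0, 4, 3)]) for _ in range(ncod))
                if True
            )
            # remove in-frame stops from the body, then add one
            body = [cds[i:i + 3] for i in range(0, len(cds), 3)]
            body = [c if translate(c) or c == "ATG" else "GCT" for c in body]
            cds = "".join(body) + "TAA"
            utr = "".join(bases[rng.integers(0, 4, 90)])
            seq = cds + utr + "TAATAATAATAA"
            pos = int(rng.integers(4, len(cds) - 4))
            net = int(rng.choice([1, 2, -1, -2]))
            stop, ext = predict_frameshift_extension(seq, len(cds), pos, net)
            if ext == "nonstop":
                continue
            # oracle: apply the same dup/del, translate from ATG
            if net > 0:
                mut = seq[:pos] + seq[pos - net:pos] + seq[pos:]
            else:
                mut = seq[:pos - 1] + seq[pos - 1 - net:]
            prot = translate(mut)
            assert len(prot) == (stop - 1)
            assert ext == len(prot) - (len(cds) // 3 - 1)
            n_checked += 1
        assert n_checked >= 20

    def test_nonstop_reported(self):
        cds = "ATG" + "GCT" * 20 + "TAA"
        seq = cds + "CGGCGG"  # no stop reachable in shifted frame
        stop, ext = predict_frameshift_extension(seq, len(cds), 10, 1)
        assert (stop, ext) == (None, "nonstop")
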