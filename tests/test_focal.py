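import numpy as np
import pandas as pd
import pytest

from lncfocal import (
    PeakRegion,
    RegionSpec,
    call_focal_amplification,
    classify_lncrnas,
    differential_expression_focal,
    neighbor_induction,
    region_spec_from_annotation,
    screen_peaks,
    subtype_enrichment,
)
from lncfocal.cn import GeneCNMatrix, SegmentSet
from lncfocal.focal import FocalCallSet, FocalError

from conftest import make_annotation, make_gene


def annotated(*genes, **kw):
    ann = make_annotation(*genes, **kw)
    classify_lncrnas(ann)
    return ann


class TestScreenPeaks:
    def setup_method(self):
        self.ann = annotated(
            make_gene("C1", exons=((1000, 3000),)),
            make_gene("L1", exons=((10_000, 11_000),), biotype="lincRNA"),
            *[make_gene(f"C{i}", exons=((20_000 + i * 3000, 22_000 + i * 3000),))
              for i in range(2, 9)],
        )

    def test_lncrna_only_peak_flagged(self):
        report = screen_peaks([PeakRegion("chr1", 9_000, 12_000, "p1")], self.ann)
        row = report.iloc[0]
        assert row["n_coding"] == 0 and row["n_lncrna"] == 1
        assert row["lncrna_only"] and row["narrow"]

    def test_peak_with_six_coding_genes_not_narrow(self):
        report = screen_peaks([PeakRegion("chr1", 25_000, 44_000, "p2")], self.ann)
        assert report.iloc[0]["n_coding"] == 6
        assert not report.iloc[0]["narrow"]

    def test_gene_desert_peak_has_no_flags(self):
        report = screen_peaks([PeakRegion("chr1", 500_000, 600_000, "p3")], self.ann)
        row = report.iloc[0]
        assert row["n_coding"] == row["n_lncrna"] == 0
        assert not row["lncrna_only"]


def calls_fixture(per_sample):
    """Build cn matrix + segments realizing (center, up_min, down_min) triples."""
    ann = annotated(
        make_gene("UP", exons=((0, 10_000),)),
        make_gene("TGT", exons=((60_000, 68_000),), biotype="lincRNA"),
        make_gene("DN", exons=((130_000, 140_000),)),
    )
    spec = RegionSpec(
        center_gene="TGT", chrom="chr1", upstream_flank=(0, 10_000),
        downstream_flank=(130_000, 140_000), upstream_gene="UP", downstream_gene="DN",
    )
    rows = []
    for sample, (center, up, down) in per_sample.items():
        rows += [
            (sample, "chr1", 0, 10_000, up),
            (sample, "chr1", 10_000, 130_000, center),
            (sample, "chr1", 130_000, 140_000, down),
        ]
    segs = SegmentSet(
        pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "seg_mean"])
    )
    from lncfocal import assign_gene_cna

    return assign_gene_cna(segs, ann), segs, spec


class TestCallFocalAmplification:
    @pytest.mark.parametrize(
        "center,up,down,expected",
        [
            (1.0, 0.1, 0.0, "marked_focal"),   # diffs 0.9 / 1.0 exceed 0.4
            (0.5, 0.1, 0.25, "focal"),         # diffs 0.4 / 0.25: both > 0.2,
                                               # but 0.4 is not > 0.4, so not marked
            (0.5, 0.5, 0.5, "broad"),          # no focal contrast, center > 0.4
            (0.3, 0.25, 0.25, "none"),
        ],
    )
    def test_worked_rule_boundaries(self, center, up, down, expected):
        cn, segs, spec = calls_fixture({"S1": (center, up, down)})
        calls = call_focal_amplification(cn, spec, segments=segs)
        assert calls.table.iloc[0]["call"] == expected

    def test_marked_implies_focal_margins(self):
        cn, segs, spec = calls_fixture({"S1": (0.9, 0.2, 0.1)})
        calls = call_focal_amplification(cn, spec, segments=segs)
        row = calls.table.iloc[0]
        assert row["call"] == "marked_focal"
        assert row["center"] - row["up_min"] > 0.2
        assert row["center"] - row["down_min"] > 0.2

    def test_sample_shift_invariance_of_focal_but_not_broad(self):
        base = {"S1": (0.6, 0.1, 0.1)}
        shifted = {"S1": (0.6 - 0.3, 0.1 - 0.3, 0.1 - 0.3)}
        c1 = call_focal_amplification(*_cn_and_spec(base))
        c2 = call_focal_amplification(*_cn_and_spec(shifted))
        assert c1.table.iloc[0]["call"] == "marked_focal"
        assert c2.table.iloc[0]["call"] == "marked_focal"
        broad_base = {"S1": (0.5, 0.5, 0.5)}
        broad_shift = {"S1": (0.2, 0.2, 0.2)}
        assert call_focal_amplification(*_cn_and_spec(broad_base)).table.iloc[0]["call"] == "broad"
        assert call_focal_amplification(*_cn_and_spec(broad_shift)).table.iloc[0]["call"] == "none"

    def test_amplitude_sweep_switches_calls_monotonically(self):
        previous_focal = False
        for delta in np.arange(0.0, 0.81, 0.05):
            cn, segs, spec = calls_fixture({"S1": (round(delta, 2), 0.0, 0.0)})
            calls = call_focal_amplification(cn, spec, segments=segs)
            is_focal = calls.table.iloc[0]["call"] in ("focal", "marked_focal")
            if previous_focal:
                assert is_focal  # once focal, higher amplitude stays focal
            previous_focal = is_focal
        assert previous_focal

    def test_undetermined_center_skipped(self):
        ann = annotated(
            make_gene("UP", exons=((0, 10_000),)),
            make_gene("TGT", exons=((60_000, 68_000),), biotype="lincRNA"),
            make_gene("DN", exons=((130_000, 140_000),)),
        )
        rows = [("S1", "chr1", 0, 10_000, 0.1), ("S1", "chr1", 130_000, 140_000, 0.1),
                ("S2", "chr1", 0, 140_000, 0.2)]
        segs = SegmentSet(pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "seg_mean"]))
        from lncfocal import assign_gene_cna

        cn = assign_gene_cna(segs, ann, max_missing=1.0)
        spec = RegionSpec("TGT", "chr1", (0, 10_000), (130_000, 140_000), "UP", "DN")
        calls = call_focal_amplification(cn, spec, segments=segs)
        assert calls.skipped == ["S1"]
        assert list(calls.table["sample"]) == ["S2"]


def _cn_and_spec(per_sample):
    cn, segs, spec = calls_fixture(per_sample)
    return cn, spec, segs


def make_calls(call_map):
    table = pd.DataFrame(
        [{"sample": s, "call": c, "center": 0.0, "up_min": 0.0, "down_min": 0.0}
         for s, c in call_map.items()]
    )
    return FocalCallSet(table=table, skipped=[])


class TestDifferentialExpression:
    def test_worked_fold_and_exact_p(self):
        rpkm = pd.DataFrame(
            [[10, 20, 0.1, 0.2, 0.3]], index=["TGT"],
            columns=["f1", "f2", "r1", "r2", "r3"], dtype=float,
        )
        calls = make_calls({"f1": "focal", "f2": "marked_focal",
                            "r1": "none", "r2": "broad", "r3": "none"})
        out = differential_expression_focal(rpkm, calls, "TGT")
        assert out["fold_change"] == pytest.approx(75.0)  # 15 / 0.2
        assert out["p_value"] == pytest.approx(0.2)

    def test_identical_groups_fold_one_p_one(self):
        rpkm = pd.DataFrame([[2.0, 2.0, 2.0, 2.0]], index=["TGT"],
                            columns=["a", "b", "c", "d"])
        calls = make_calls({"a": "focal", "b": "focal", "c": "none", "d": "none"})
        out = differential_expression_focal(rpkm, calls, "TGT")
        assert out["fold_change"] == pytest.approx(1.0)
        assert out["p_value"] == 1.0

    def test_zero_rest_mean_uses_pseudo(self):
        rpkm = pd.DataFrame([[1.0, 0.0, 0.0]], index=["TGT"], columns=["a", "b", "c"])
        calls = make_calls({"a": "focal", "b": "none", "c": "none"})
        out = differential_expression_focal(rpkm, calls, "TGT")
        assert out["fold_change"] == pytest.approx(1.01 / 0.01)

    def test_empty_focal_group_rejected(self):
        rpkm = pd.DataFrame([[1.0, 2.0]], index=["TGT"], columns=["a", "b"])
        calls = make_calls({"a": "none", "b": "none"})
        with pytest.raises(FocalError):
            differential_expression_focal(rpkm, calls, "TGT")


class TestSubtypeEnrichment:
    def test_printed_endometrial_counts(self):
        call_map = {}
        flags = {}
        i = 0
        for flag, call, n in [(True, "focal", 5), (True, "none", 86),
                              (False, "focal", 4), (False, "none", 327)]:
            for _ in range(n):
                call_map[f"s{i}"] = call
                flags[f"s{i}"] = flag
                i += 1
        out = subtype_enrichment(make_calls(call_map), pd.Series(flags))
        assert out["table"] == [[5, 86], [4, 327]]
        assert out["frequency_ratio"] == pytest.approx(4.547, abs=1e-3)
        assert out["p_value"] == pytest.approx(0.025, abs=5e-4)

    def test_no_amplified_samples_give_p_one(self):
        call_map = {f"s{i}": "none" for i in range(20)}
        flags = pd.Series({f"s{i}": i < 10 for i in range(20)})
        out = subtype_enrichment(make_calls(call_map), flags)
        assert out["p_value"] == 1.0

    def test_ratio_above_one_iff_flagged_group_enriched(self):
        call_map = {"a": "focal", "b": "none", "c": "none", "d": "none"}
        flags = pd.Series({"a": True, "b": True, "c": False, "d": False})
        out = subtype_enrichment(make_calls(call_map), flags)
        assert out["frequency_ratio"] > 1 or np.isinf(out["frequency_ratio"])

    def test_missing_flag_rejected(self):
        with pytest.raises(FocalError):
            subtype_enrichment(make_calls({"a": "focal"}), pd.Series({"b": True}))


class TestOnSyntheticCohort:
    def test_neighbor_null_holds_across_repeated_simulations(self):
        """Without a planted neighbor effect the flank genes' focal-vs-rest
        p-values exceed 0.05 in at least 90% of simulation seeds."""
        from lncfocal import assign_gene_cna, simulate
        from lncfocal.simulate import SimConfig

        ok = 0
        seeds = range(10)
        for seed in seeds:
            cfg = SimConfig(
                n_samples=60, n_coding_genes=120, n_lncrna_genes=60,
                chrom_lengths={"chr1": 12_000_000, "chr2": 8_000_000},
                n_signature_genes_per_subtype=4, focal_frequency=0.1,
                focal_partial_neighbor_prob=0.0, seed=seed,
            )
            cohort = simulate(cfg)
            cn = assign_gene_cna(cohort.segments, cohort.annotation)
            spec = region_spec_from_annotation(
                cohort.annotation, cfg.focal_target_gene
            )
            calls = call_focal_amplification(cn, spec, segments=cohort.segments)
            out = neighbor_induction(cohort.counts.rpkm, calls, spec)
            if all(out[s]["p_value"] > 0.05 for s in ("upstream", "downstream")):
                ok += 1
        assert ok / len(seeds) >= 0.9

    def test_neighbors_not_induced(self, cohort400, cn400):
        cohort = cohort400
        spec = region_spec_from_annotation(
            cohort.annotation, cohort.config.focal_target_gene
        )
        calls = call_focal_amplification(cn400, spec, segments=cohort.segments)
        out = neighbor_induction(cohort.counts.rpkm, calls, spec)
        for side in ("upstream", "downstream"):
            assert 0.5 < out[side]["fold_change"] < 2.0
            assert out[side]["p_value"] > 0.05
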