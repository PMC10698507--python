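"""Peak consensus, containment intersection, annotation and the gene funnel."""

import numpy as np
import pandas as pd
import pytest

from ednet.regions import (
    GeneModel,
    PeakSet,
    annotate_peaks,
    center_on_atac,
    common_regions,
    consensus_peaks,
    filter_by_regulon,
    filter_degs,
    genes_under_peaks,
)


def peaks(*tuples, label=""):
    return PeakSet.from_tuples([("chr1", s, e) for s, e in tuples], label=label)


def brute_force_consensus(replicates, min_support, length=2000):
    """Independent oracle: per-base coverage counting."""
    cov = np.zeros(length, dtype=int)
    for rep in replicates:
        mask = np.zeros(length, dtype=bool)
        for _, s, e in rep.intervals[["chrom", "start", "end"]].itertuples(index=False):
            mask[s:e] = True
        cov += mask
    covered = cov >= min_support
    out, start = [], None
    for i, c in enumerate(covered):
        if c and start is None:
            start = i
        elif not c and start is not None:
            out.append(("chr1", start, i))
            start = None
    if start is not None:
        out.append(("chr1", start, length))
    return out


class TestConsensusPeaks:
    def test_majority_vote_keeps_shared_stretch(self):
        reps = [peaks((100, 200)), peaks((150, 250))]
        result = consensus_peaks(reps, min_support=2)
        assert result.intervals[["start", "end"]].values.tolist() == [[150, 200]]

    def test_support_one_is_union(self):
        reps = [peaks((100, 200)), peaks((150, 250))]
        result = consensus_peaks(reps, min_support=1)
        assert result.intervals[["start", "end"]].values.tolist() == [[100, 250]]

    def test_identical_replicates_idempotent(self):
        reps = [peaks((10, 50), (80, 120))] * 3
        for support in (1, 2, 3):
            result = consensus_peaks(reps, min_support=support)
            assert result.intervals[["start", "end"]].values.tolist() == [[10, 50], [80, 120]]

    def test_replicate_internal_overlap_counts_once(self):
        # two overlapping peaks in one replicate still contribute support 1
        reps = [peaks((100, 200), (150, 250)), peaks((300, 400))]
        result = consensus_peaks(reps, min_support=2)
        assert len(result) == 0

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("min_support", [1, 2, 3])
    def test_matches_per_base_oracle(self, seed, min_support):
        rng = np.random.default_rng(seed)
        reps = []
        for _ in range(3):
            starts = rng.integers(0, 1800, size=6)
            reps.append(
                peaks(*[(int(s), int(s) + int(rng.integers(10, 150))) for s in starts])
            )
        expected = brute_force_consensus(reps, min_support)
        got = [
            ("chr1", int(s), int(e))
            for _, s, e in consensus_peaks(reps, min_support).intervals.itertuples(index=False)
        ]
        assert got == expected

    def test_monotone_in_support(self):
        rng = np.random.default_rng(7)
        reps = [
            peaks(*[(int(s), int(s) + 100) for s in rng.integers(0, 1500, 5)])
            for _ in range(4)
        ]
        def covered_bp(ps):
            return int((ps.intervals["end"] - ps.intervals["start"]).sum())
        sizes = [covered_bp(consensus_peaks(reps, k)) for k in range(1, 5)]
        assert sizes == sorted(sizes, reverse=True)

    def test_errors(self):
        with pytest.raises(ValueError):
            consensus_peaks([], 1)
        with pytest.raises(ValueError):
            consensus_peaks([peaks((0, 10))], 2)


class TestCommonRegions:
    def test_containment_retains_inner_interval(self):
        result = common_regions([peaks((100, 200)), peaks((90, 250))])
        assert result.intervals[["start", "end"]].values.tolist() == [[100, 200]]

    def test_partial_overlap_dropped(self):
        result = common_regions([peaks((100, 200)), peaks((150, 300))])
        assert len(result) == 0

    def test_three_conditions_single_chain(self):
        conds = [peaks((100, 200)), peaks((90, 250)), peaks((95, 220))]
        result = common_regions(conds)
        assert result.intervals[["start", "end"]].values.tolist() == [[100, 200]]

    def test_symmetric_in_condition_order(self):
        conds = [
            peaks((100, 200), (500, 600)),
            peaks((90, 250), (520, 580)),
            peaks((95, 220), (400, 700)),
        ]
        base = common_regions(conds).intervals.values.tolist()
        for perm in ([1, 0, 2], [2, 1, 0], [1, 2, 0]):
            assert common_regions([conds[i] for i in perm]).intervals.values.tolist() == base

    def test_needs_two_conditions(self):
        with pytest.raises(ValueError):
            common_regions([peaks((0, 10))])


class TestCenterOnAtac:
    def test_atac_inside_chip(self):
        out = center_on_atac(peaks((0, 1000)), peaks((400, 600)))
        assert out.intervals[["start", "end"]].values.tolist() == [[400, 600]]
        assert out.intervals[["support_start", "support_end"]].values.tolist() == [[0, 1000]]

    def test_reverse_containment_accepted(self):
        out = center_on_atac(peaks((400, 600)), peaks((0, 1000)))
        assert out.intervals[["start", "end"]].values.tolist() == [[0, 1000]]

    def test_strict_mode_rejects_reverse(self):
        out = center_on_atac(peaks((400, 600)), peaks((0, 1000)), either_direction=False)
        assert len(out) == 0

    def test_disjoint_empty(self):
        out = center_on_atac(peaks((0, 100)), peaks((500, 600)))
        assert len(out) == 0

    def test_empty_input_error(self):
        with pytest.raises(ValueError):
            center_on_atac(PeakSet.from_tuples([]), peaks((0, 10)))


class TestAnnotatePeaks:
    @pytest.fixture
    def gene(self):
        return GeneModel(
            gene="GENE1", chrom="chr1", strand="+", tss=5000,
            gene_span=(4800, 20000), exons=[(5000, 5200), (12000, 12400)],
            utr5=[(5000, 5050)],
        )

    def test_midpoint_at_tss_is_promoter(self, gene):
        out = annotate_peaks(peaks((4500, 5500)), [gene])
        assert out.loc[0, "feature"] == "promoter/TSS"
        assert out.loc[0, "distance_to_tss"] == 0
        assert out.loc[0, "gene"] == "GENE1"

    def test_exon_beyond_promoter_window(self, gene):
        out = annotate_peaks(peaks((12100, 12300)), [gene])
        assert out.loc[0, "feature"] == "exon"

    def test_intron(self, gene):
        out = annotate_peaks(peaks((9000, 9100)), [gene])
        assert out.loc[0, "feature"] == "intron"

    def test_unknown_chromosome_is_intergenic_with_warning(self, gene):
        ps = PeakSet.from_tuples([("chrX", 100, 200)])
        with pytest.warns(UserWarning):
            out = annotate_peaks(ps, [gene])
        assert out.loc[0, "feature"] == "intergenic"

    def test_every_peak_gets_exactly_one_feature(self, gene):
        rng = np.random.default_rng(0)
        ps = peaks(*[(int(s), int(s) + 100) for s in rng.integers(0, 30000, 50)])
        out = annotate_peaks(ps, [gene])
        assert len(out) == 50
        assert out["feature"].notna().all()

    def test_nearest_tss_breaks_promoter_tie(self):
        g1 = GeneModel(gene="NEAR", chrom="chr1", strand="+", tss=5000,
                       gene_span=(4500, 9000))
        g2 = GeneModel(gene="FAR", chrom="chr1", strand="+", tss=7000,
                       gene_span=(6500, 11000))
        out = annotate_peaks(peaks((5300, 5500)), [g2, g1])
        assert out.loc[0, "gene"] == "NEAR"


class TestDegFunnel:
    def make_de(self, rows):
        return pd.DataFrame(rows, columns=["gene", "log2fc", "padj"])

    @pytest.mark.parametrize(
        "lfc,padj,kept,direction",
        [(1.6, 0.04, True, "up"), (1.2, 0.04, False, None), (-2.0, 0.06, False, None),
         (-1.8, 0.01, True, "down")],
    )
    def test_threshold_combinations(self, lfc, padj, kept, direction):
        out = filter_degs(self.make_de([("G", lfc, padj)]))
        if kept:
            assert out["gene"].tolist() == ["G"] and out["direction"].iloc[0] == direction
        else:
            assert out.empty

    def test_missing_column_schema_error(self):
        with pytest.raises(ValueError, match="padj"):
            filter_degs(pd.DataFrame({"gene": ["G"], "log2fc": [2.0]}))

    def test_genes_under_peaks_intersection(self):
        annotated = pd.DataFrame({"gene": ["B", "C", ""]})
        assert genes_under_peaks({"c1": {"A", "B"}}, annotated) == {"B"}
        assert genes_under_peaks({"c1": {"A"}}, annotated) == set()

    def test_regulon_filter_panel_and_counts(self):
        regulon = pd.DataFrame({"tf": ["T", "T", "X"], "target": ["G", "G", "G"],
                                "evidence": ["e1", "e1", "e2"]})
        kept, panel, counts = filter_by_regulon({"G"}, ["T"], regulon)
        assert panel == {"T", "G"}
        assert counts == {"tf": 1, "non_tf": 1}
        assert len(kept) == 1  # duplicated rows counted once

    def test_regulon_filter_empty_when_unsupported(self):
        regulon = pd.DataFrame({"tf": ["X"], "target": ["G"], "evidence": ["e"]})
        _, panel, _ = filter_by_regulon({"G"}, ["T"], regulon)
        assert panel == set()
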