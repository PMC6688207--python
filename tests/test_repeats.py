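"""Peak categorization, TE ranking, printed-percentage summaries, gene features."""

import numpy as np
import pytest

import kzfpchip as k
from kzfpchip.consensus import ConsensusPeak
from kzfpchip.intervals import GenomicInterval, IntervalSet, overlap_length
from kzfpchip.repeats import (
    GeneModel,
    RepeatElement,
    classify_peak,
    classify_peaks,
    gene_feature_assign,
    rank_te_names,
    read_bed12_genes,
    summarize_calls,
    summarize_distribution,
    write_bed12_genes,
)

from conftest import random_intervals


def peak(chrom, start, end, name="p"):
    return ConsensusPeak(GenomicInterval(chrom, start, end, name=name), 2, 2)


def rep(chrom, start, end, name="IAPLTR2a2_Mm", cls="LTR"):
    return RepeatElement(GenomicInterval(chrom, start, end), name, cls, cls)


class TestClassify:
    def test_te_inside_ltr(self):
        call = classify_peak(peak("chr1", 100, 200), [rep("chr1", 50, 400)], None)
        assert call.category == "TE"
        assert call.assigned_element.rep_name == "IAPLTR2a2_Mm"

    def test_no_annotation_is_unique(self):
        assert classify_peak(peak("chr1", 0, 100), [], None).category == "UNIQUE"

    def test_max_overlap_wins(self):
        call = classify_peak(
            peak("chr1", 100, 210),
            [rep("chr1", 100, 130, "(CA)n", "Simple_repeat"), rep("chr1", 130, 400)],
            None,
        )
        assert call.category == "TE"
        assert call.overlap_bp == 80

    def test_icr_precedence(self, toy_genome):
        icrs = IntervalSet(toy_genome, [GenomicInterval("chr1", 150, 160)])
        call = classify_peak(peak("chr1", 100, 200), [rep("chr1", 0, 1000)], icrs)
        assert call.category == "ICR"

    def test_matches_pairwise_overlap_oracle(self, toy_genome):
        rng = np.random.default_rng(23)
        elements = []
        for i, iv in enumerate(random_intervals(rng, toy_genome, 120)):
            cls = ("LTR", "LINE", "Simple_repeat")[i % 3]
            elements.append(RepeatElement(iv, f"el{i}", cls, cls))
        peaks = [peak(iv.chrom, iv.start, iv.end, f"p{j}")
                 for j, iv in enumerate(random_intervals(rng, toy_genome, 60))]
        fast = classify_peaks(peaks, elements, None)
        for pk, call in zip(peaks, fast):
            best, best_ov = None, 0
            for el in sorted(
                elements, key=lambda e: (e.interval.chrom, e.interval.start, e.interval.end)
            ):  # exhaustive scan; ties go to the leftmost element
                ov = overlap_length(pk.interval, el.interval)
                if ov > best_ov:
                    best, best_ov = el, ov
            if best is None:
                assert call.category == "UNIQUE"
            else:
                assert call.overlap_bp == best_ov
                assert call.assigned_element.rep_name == best.rep_name

    def test_every_peak_gets_exactly_one_category(self, bundle, consensus_peaks):
        calls = classify_peaks(consensus_peaks, bundle.repeats, bundle.icrs)
        assert len(calls) == len(consensus_peaks)
        summary = summarize_calls(calls)
        assert sum(summary.counts.values()) == summary.total == len(calls)

    def test_no_repeats_makes_everything_unique(self, bundle, consensus_peaks):
        calls = classify_peaks(consensus_peaks, [], bundle.icrs)
        assert all(c.category in ("ICR", "UNIQUE") for c in calls)

    def test_planted_categories_recovered_exactly(self):
        # peaks generated strictly within their annotation elements classify
        # perfectly against the planted category labels
        cfg = k.paper_mimic_config(seed=5)
        cfg.sensitivity = 1.0
        cfg.fp_rate = 0.0
        b = k.simulate(cfg)
        truth = b.truth.sites
        peaks = [
            ConsensusPeak(GenomicInterval(r.chrom, r.start, r.end, name=r.site_id), 3, 3)
            for r in truth.itertuples(index=False)
        ]
        calls = classify_peaks(peaks, b.repeats, b.icrs)
        mapped = {"ICR": "ICR", "UNIQUE_LOSE": "UNIQUE", "UNIQUE_RETAIN": "UNIQUE",
                  "NONTE": "NONTE_REPEAT", "TE_LOSE": "TE", "TE_RETAIN": "TE"}
        acc = np.mean([c.category == mapped[t] for c, t in zip(calls, truth.category)])
        assert acc == 1.0


class TestRanking:
    def test_counts_and_order(self):
        calls = [
            classify_peak(peak("chr1", 0, 100), [rep("chr1", 0, 100, "repA")], None),
            classify_peak(peak("chr1", 200, 300), [rep("chr1", 200, 300, "repA")], None),
            classify_peak(peak("chr1", 400, 500), [rep("chr1", 400, 500, "repA")], None),
            classify_peak(peak("chr1", 600, 700), [rep("chr1", 600, 700, "repB")], None),
        ]
        df = rank_te_names(calls)
        assert list(df.itertuples(index=False, name=None)) == [("repA", 3), ("repB", 1)]

    def test_empty_when_no_te(self):
        assert rank_te_names([classify_peak(peak("chr1", 0, 10), [], None)]).empty

    def test_dominant_planted_name_ranks_first(self, bundle, consensus_peaks):
        calls = classify_peaks(consensus_peaks, bundle.repeats, bundle.icrs)
        df = rank_te_names(calls, top_k=32)
        assert df.iloc[0]["rep_name"] == "IAPLTR2a2_Mm"
        assert df.iloc[0]["peak_count"] > df.iloc[1]["peak_count"]


class TestSummary:
    def test_published_count_table_percentages(self):
        s = summarize_distribution(
            {"UNIQUE": 189, "NONTE_REPEAT": 19, "TE": 1194}, total=1423
        )
        assert s.percentages["TE"] == 83.9
        assert s.percentages["UNIQUE"] == 13.3
        assert s.percentages["NONTE_REPEAT"] == 1.3
        # counts that do not exhaust the total surface as an explicit residual
        assert s.counts["other"] == 21

    def test_rounding_half_up(self):
        s = summarize_distribution({"UNIQUE": 1, "TE": 2})
        assert s.percentages == {"UNIQUE": 33.3, "TE": 66.7}
        assert summarize_distribution({"TE": 1}).percentages == {"TE": 100.0}

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            summarize_distribution({}, total=0)


class TestGeneFeatures:
    def _gene(self, chrom="chr1", start=10_000, end=20_000, strand="+", exons=None):
        exons = exons or ((10_000, 11_000), (19_000, 20_000))
        return GeneModel("g", GenomicInterval(chrom, start, end, strand, "g"), exons)

    def test_promoter_and_intron(self):
        g = self._gene()
        assert gene_feature_assign(peak("chr1", 9_500, 9_800), [g]) == "promoter"
        assert gene_feature_assign(peak("chr1", 14_000, 14_100), [g]) == "intron"
        # exon hit outside the promoter window (promoter has precedence near TSS)
        assert gene_feature_assign(peak("chr1", 19_500, 19_600), [g]) == "exon"
        assert gene_feature_assign(peak("chr1", 50_000, 50_100), [g]) == "intergenic"

    def test_minus_strand_promoter_at_gene_end(self):
        g = self._gene(strand="-")
        assert gene_feature_assign(peak("chr1", 20_200, 20_400), [g]) == "promoter"

    def test_malformed_gene_model_errors(self):
        with pytest.raises(ValueError):
            self._gene(exons=((5_000, 6_000),))

    def test_matches_rasterized_mask_oracle(self, toy_genome):
        rng = np.random.default_rng(31)
        genes = []
        for i in range(10):
            s = int(rng.integers(2_000, 80_000))
            e = s + int(rng.integers(2_000, 8_000))
            strand = "+" if rng.random() < 0.5 else "-"
            ex = np.sort(rng.choice(np.arange(s, e), 4, replace=False))
            exons = ((int(ex[0]), int(ex[1]) + 1), (int(ex[2]), int(ex[3]) + 1))
            genes.append(GeneModel(f"g{i}", GenomicInterval("chr1", s, e, strand), exons))
        window = 1000
        L = 100_000
        # precedence mask: 0 intergenic, 1 intron, 2 exon, 3 promoter
        mask = np.zeros(L, dtype=np.int8)
        for g in genes:
            mask[g.span.start : g.span.end] = np.maximum(mask[g.span.start : g.span.end], 1)
        for g in genes:
            for s, e in g.exons:
                mask[s:e] = np.maximum(mask[s:e], 2)
        for g in genes:
            mask[max(0, g.tss - window) : min(L, g.tss + window)] = 3
        names = {0: "intergenic", 1: "intron", 2: "exon", 3: "promoter"}
        for _ in range(50):
            s = int(rng.integers(0, L - 400))
            pk = peak("chr1", s, s + 400)
            assert gene_feature_assign(pk, genes, window) == names[mask[s : s + 400].max()]


def test_bed12_roundtrip(tmp_path):
    g = GeneModel(
        "gX",
        GenomicInterval("chr1", 1000, 9000, "-", "gX"),
        ((1000, 2000), (5000, 9000)),
    )
    p = tmp_path / "genes.bed12"
    write_bed12_genes([g], p)
    back = read_bed12_genes(p)
    assert back[0].gene_id == "gX"
    assert back[0].span.strand == "-"
    assert back[0].exons == g.exons
    assert back[0].tss == 9000
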