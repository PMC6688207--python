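"""Peak-gene proximity, DE crossing, direction concordance, co-binding Venn."""

import numpy as np
import pytest

import kzfpchip as k
from kzfpchip.intervals import GenomicInterval, IntervalSet
from kzfpchip.targets import (
    DEGene,
    NominationRule,
    TargetCall,
    cross_de,
    de_flag,
    direction_concordance,
    genes_near_peaks,
    multi_kzfp_overlap,
    nominate_direct_targets,
    read_de_table,
    write_de_table,
)

from conftest import random_intervals


def gene(gid, chrom, start, end, log2fc=0.0, adj_p=1.0, strand="+", imprinted=False):
    span = GenomicInterval(chrom, start, end, strand, gid)
    return DEGene(
        gid, span, span.start if strand != "-" else span.end,
        10.0, 10.0 * 2.0**log2fc, log2fc, adj_p, de_flag(log2fc, adj_p), imprinted,
    )


class TestProximity:
    def test_distance_recorded(self, toy_genome):
        peaks = IntervalSet(toy_genome, [GenomicInterval("chr1", 500, 600, name="pk1")])
        calls = genes_near_peaks([gene("g", "chr1", 10_000, 12_000)], peaks, 20_000)
        assert len(calls) == 1
        assert calls[0].distance_bp == 9_400
        assert calls[0].nearest_peak_id == "pk1"

    def test_strict_boundary_excluded(self, toy_genome):
        peaks = IntervalSet(toy_genome, [GenomicInterval("chr1", 0, 100, name="pk1")])
        calls = genes_near_peaks([gene("g", "chr1", 20_100, 22_000)], peaks, 20_000)
        assert calls == []  # gap is exactly 20,000 and the rule is strict "<"
        calls = genes_near_peaks([gene("g", "chr1", 20_099, 22_000)], peaks, 20_000)
        assert len(calls) == 1

    def test_matches_all_pairs_oracle_and_monotone(self, toy_genome):
        rng = np.random.default_rng(14)
        peaks = IntervalSet(toy_genome, random_intervals(rng, toy_genome, 10))
        genes = [
            gene(f"g{i}", iv.chrom, iv.start, iv.end)
            for i, iv in enumerate(random_intervals(rng, toy_genome, 30, max_len=3_000))
        ]
        for max_dist in (1_000, 5_000, 20_000):
            got = {c.gene_id: c.distance_bp for c in genes_near_peaks(genes, peaks, max_dist)}
            for g in genes:
                gaps = []
                for pk in peaks:
                    if pk.chrom != g.span.chrom:
                        continue
                    if pk.end <= g.span.start:
                        gaps.append(g.span.start - pk.end)
                    elif g.span.end <= pk.start:
                        gaps.append(pk.start - g.span.end)
                    else:
                        gaps.append(0)
                expect = min(gaps) if gaps else None
                if expect is not None and expect < max_dist:
                    assert got[g.gene_id] == expect
                else:
                    assert g.gene_id not in got
        small = {c.gene_id for c in genes_near_peaks(genes, peaks, 2_000)}
        large = {c.gene_id for c in genes_near_peaks(genes, peaks, 10_000)}
        assert small <= large


def test_cross_de_partition():
    calls = [
        TargetCall(f"g{i}", "pk", 100, is_de=(i < 2)) for i in range(5)
    ]
    out = cross_de(calls, n_de_total=10)
    assert (out["near_and_de"], out["near_not_de"]) == (2, 3)
    assert out["de_without_nearby_peak"] == 8
    out2 = cross_de([TargetCall(f"g{i}", "pk", 0, is_de=False) for i in range(4)])
    assert (out2["near_and_de"], out2["near_not_de"]) == (0, 4)


class TestDirectionConcordance:
    def test_equal_and_negated(self):
        ids = [f"g{i}" for i in range(6)]
        fc = {g: v for g, v in zip(ids, [2, 1, 3, -1, -2, -0.5])}
        out = direction_concordance(ids, fc, dict(fc))
        assert out["up_agreement"] == 1.0 and out["down_agreement"] == 1.0
        neg = {g: -v for g, v in fc.items()}
        out2 = direction_concordance(ids, fc, neg)
        assert out2["up_agreement"] == 0.0 and out2["down_agreement"] == 0.0

    def test_empty_subset_errors(self):
        with pytest.raises(ValueError):
            direction_concordance([], {}, {})

    def test_planted_up_concordance_beats_down(self, bundle):
        ko = {g.gene_id: g.log2fc for g in bundle.de_ko}
        tko = {g.gene_id: g.log2fc for g in bundle.de_tko}
        truth = bundle.truth.genes
        de_prox = truth[truth.role.isin(["direct", "imprinted", "proximal_down"])]
        out = direction_concordance(list(de_prox.gene_id), ko, tko)
        assert out["up_agreement"] == 1.0
        assert out["up_agreement"] > out["down_agreement"]


class TestNomination:
    def _call(self, state="LOST", de=True, up_ko=1, up_tko=1):
        return TargetCall("g", "pk", 100, de, False, state, up_ko, up_tko, 2.0, 1.5)

    def test_all_conditions_met(self):
        assert nominate_direct_targets([self._call()]) == ["g"]

    def test_retained_peak_blocks_nomination(self):
        assert nominate_direct_targets([self._call(state="RETAINED")]) == []

    def test_rule_components_toggle(self):
        rule = NominationRule(require_lost_state=False)
        assert nominate_direct_targets([self._call(state="RETAINED")], rule) == ["g"]

    def test_precision_recall_on_planted_cohort(self, bundle, consensus_peaks):
        genome = bundle.genome
        peaks = IntervalSet(genome, [p.interval for p in consensus_peaks])
        wt = bundle.tracks[("H3K9me3", "WT")]
        ko_calls = k.call_states(wt, bundle.tracks[("H3K9me3", "KO")], list(peaks), "H3K9me3", "KO")
        state_map = {c.peak_id: c.state for c in ko_calls}
        tko_fc = {g.gene_id: g.log2fc for g in bundle.de_tko}
        calls = genes_near_peaks(bundle.de_ko, peaks, 20_000)
        for c in calls:
            c.h3k9me3_state_at_peak = state_map.get(c.nearest_peak_id)
            c.log2fc_tko = tko_fc[c.gene_id]
            c.direction_tko = int(np.sign(c.log2fc_tko))
        nominated = set(nominate_direct_targets(calls))
        truth = set(bundle.truth.genes.query("direct_target").gene_id)
        tp = len(nominated & truth)
        assert tp / max(len(nominated), 1) >= 0.9   # precision
        assert tp / len(truth) >= 0.9               # recall


class TestVenn:
    def test_disjoint_and_identical(self, toy_genome):
        prim = IntervalSet(toy_genome, [GenomicInterval("chr1", i * 1_000, i * 1_000 + 100) for i in range(5)])
        far = IntervalSet(toy_genome, [GenomicInterval("chr2", 0, 100)])
        out = multi_kzfp_overlap(prim, {"a": far, "b": far})
        assert out["none"] == 5 and out["all_cobound"] == 0
        out2 = multi_kzfp_overlap(prim, {"a": prim, "b": prim})
        assert out2["a+b"] == 5 and out2["all_cobound"] == 5

    def test_pattern_counts_sum_to_primary(self, toy_genome):
        rng = np.random.default_rng(77)
        prim = IntervalSet(toy_genome, random_intervals(rng, toy_genome, 40))
        a = IntervalSet(toy_genome, random_intervals(rng, toy_genome, 20))
        b = IntervalSet(toy_genome, random_intervals(rng, toy_genome, 20))
        out = multi_kzfp_overlap(prim, {"a": a, "b": b})
        patterns = [v for kq, v in out.items() if kq != "all_cobound"]
        assert sum(patterns) == 40
        # exhaustive membership oracle
        from kzfpchip.intervals import overlap_length

        for iv in prim:
            in_a = any(overlap_length(iv, x) > 0 for x in a)
            in_b = any(overlap_length(iv, x) > 0 for x in b)
            key = "+".join(n for n, f in (("a", in_a), ("b", in_b)) if f) or "none"
            assert out[key] >= 1

    def test_planted_triple_cobinding(self, bundle, consensus_peaks):
        peaks = IntervalSet(bundle.genome, [p.interval for p in consensus_peaks])
        out = multi_kzfp_overlap(peaks, bundle.kzfp_sets)
        # planted triple-bound TE sites, allowing for replicate-sensitivity misses
        assert out["all_cobound"] >= int(0.85 * bundle.truth.n_triple_cobound)
        assert out["all_cobound"] <= bundle.truth.n_triple_cobound

    def test_requires_other_sets(self, toy_genome):
        prim = IntervalSet(toy_genome, [GenomicInterval("chr1", 0, 100)])
        with pytest.raises(ValueError):
            multi_kzfp_overlap(prim, {})


def test_de_table_roundtrip(tmp_path, toy_genome):
    genes = [
        gene("g1", "chr1", 1_000, 5_000, 2.5, 1e-8, "+", imprinted=True),
        gene("g2", "chr2", 10_000, 15_000, -0.2, 0.8, "-"),
    ]
    p = tmp_path / "de.tsv"
    write_de_table(genes, p)
    back = read_de_table(p, toy_genome)
    assert [g.gene_id for g in back] == ["g1", "g2"]
    assert back[0].is_de and back[0].is_imprinted
    assert not back[1].is_de
    assert back[1].tss == 15_000
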