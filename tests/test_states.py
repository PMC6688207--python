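"""Signal quantification, loss/retention calling, matrices and concordance."""

import numpy as np
import pytest

import kzfpchip as k
from kzfpchip.intervals import GenomeDef, GenomicInterval, IntervalSet
from kzfpchip.signal import SignalTrack, read_bedgraph, write_bedgraph
from kzfpchip.states import (
    NOT_ENRICHED,
    StateCall,
    StateThresholds,
    aggregate_profile,
    build_matrix,
    call_state,
    call_states,
    concordance,
    partition_by_cobinding,
    partition_counts,
    quantify,
)


def uniform_track(genome, value, chrom="c"):
    L = genome.length_of(chrom)
    return SignalTrack(genome, {chrom: (np.array([0]), np.array([L]), np.array([float(value)]))})


@pytest.fixture
def g1():
    return GenomeDef(["c"], [10_000])


class TestQuantify:
    def test_uniform(self, g1):
        tr = uniform_track(g1, 4.0)
        assert quantify(tr, GenomicInterval("c", 1_000, 1_100), background=2.0) == pytest.approx(2.0)

    def test_zero_track(self, g1):
        tr = SignalTrack(g1, {})
        assert quantify(tr, GenomicInterval("c", 0, 100), background=1.0) == 0.0

    def test_piecewise_mean_matches_per_base_oracle(self, g1):
        tr = SignalTrack(
            g1, {"c": (np.array([0, 50]), np.array([50, 100]), np.array([1.0, 3.0]))}
        )
        got = quantify(tr, GenomicInterval("c", 0, 100), background=1.0, flank=0)
        base = np.zeros(100)
        base[:50] = 1.0
        base[50:] = 3.0
        assert got == pytest.approx(base.mean())
        # random piecewise track against per-base summation
        rng = np.random.default_rng(12)
        starts = np.arange(0, 10_000, 100)
        vals = rng.uniform(0, 5, len(starts))
        tr2 = SignalTrack(g1, {"c": (starts, starts + 100, vals)})
        per_base = np.repeat(vals, 100)
        for _ in range(10):
            a = int(rng.integers(0, 9_000))
            b = a + int(rng.integers(10, 900))
            got = tr2.mean_coverage("c", a, b)
            assert got == pytest.approx(per_base[a:b].mean(), rel=1e-9)

    def test_genome_mean_counts_gaps_as_zero(self, g1):
        tr = SignalTrack(g1, {"c": (np.array([0]), np.array([5_000]), np.array([2.0]))})
        assert tr.genome_mean() == pytest.approx(1.0)


class TestCallState:
    CFG = StateThresholds(background_floor=1.5, ratio_lost=0.25, ratio_retained=0.75)

    def test_examples(self):
        assert call_state(10.0, 0.1, self.CFG) == "LOST"
        assert call_state(10.0, 10.0, self.CFG) == "RETAINED"
        assert call_state(10.0, 5.0, self.CFG) == "PARTIAL"
        assert call_state(1.0, 0.0, self.CFG) == NOT_ENRICHED

    def test_negative_inputs_error(self):
        with pytest.raises(ValueError):
            call_state(-1.0, 1.0, self.CFG)

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            StateThresholds(ratio_lost=0.8, ratio_retained=0.2)

    def test_scale_invariance(self, g1):
        # multiplying both tracks by a common factor leaves every call unchanged
        rng = np.random.default_rng(3)
        starts = np.arange(0, 10_000, 50)
        vals_wt = rng.uniform(0.5, 8, len(starts))
        vals_mut = rng.uniform(0.0, 8, len(starts))
        wt = SignalTrack(g1, {"c": (starts, starts + 50, vals_wt)})
        mut = SignalTrack(g1, {"c": (starts, starts + 50, vals_mut)})
        peaks = [GenomicInterval("c", 500 * i + 100, 500 * i + 300, name=f"p{i}") for i in range(15)]
        base = [c.state for c in call_states(wt, mut, peaks, "H3K9me3", "KO")]
        scaled = [
            c.state
            for c in call_states(wt.scaled(3.7), mut.scaled(3.7), peaks, "H3K9me3", "KO")
        ]
        assert base == scaled

    def test_planted_state_recovery_benchmark(self):
        peaks, wt, mut, truth = k.simulate_state_benchmark(n_peaks=300, seed=11)
        calls = call_states(wt, mut, list(peaks), "H3K9me3", "KO")
        got = np.array([c.state for c in calls])
        truth = np.array(truth)
        for state in ("LOST", "PARTIAL", "RETAINED"):
            sel = truth == state
            assert (got[sel] == state).mean() >= 0.95


class TestPartitionCounts:
    def _call(self, pid, state):
        return StateCall(pid, "H3K9me3", "KO", 5.0, 5.0, 1.0, state)

    def test_published_unique_partition(self):
        calls = [self._call(f"p{i}", "LOST") for i in range(98)] + [
            self._call(f"q{i}", "RETAINED") for i in range(91)
        ]
        groups = {c.peak_id: "UNIQUE" for c in calls}
        df = partition_counts(calls, groups).set_index("category")
        assert df.loc["UNIQUE", "LOST"] == 98
        assert df.loc["UNIQUE", "LOST_pct"] == 51.9  # prints as 52% at integer precision
        assert df.loc["UNIQUE", "RETAINED_pct"] == 48.1

    def test_published_te_partition(self):
        calls = [self._call(f"p{i}", "RETAINED") for i in range(1168)] + [
            self._call(f"q{i}", "LOST") for i in range(26)
        ]
        df = partition_counts(calls, {c.peak_id: "TE" for c in calls}).set_index("category")
        assert df.loc["TE", "RETAINED_pct"] == 97.8  # prints as 98%
        assert df.loc["TE", "LOST_pct"] == 2.2

    def test_empty_category_gives_zero_row(self):
        calls = [self._call("p1", "LOST")]
        df = partition_counts(calls, {"p1": "A", "missing": "B"}).set_index("category")
        assert df.loc["B", "total"] == 0
        assert df.loc["B", "LOST_pct"] == 0.0


class TestMatrix:
    def test_uniform_track_gives_ones(self, g1):
        tr = uniform_track(g1, 1.0)
        peaks = IntervalSet(g1, [GenomicInterval("c", 4_000, 4_300)])
        m = build_matrix(tr, peaks, flank=1_000, n_bins=20)
        assert np.allclose(m.values, 1.0)

    def test_step_function_splits_halves(self, g1):
        tr = SignalTrack(g1, {"c": (np.array([5_000]), np.array([10_000]), np.array([2.0]))})
        peaks = IntervalSet(g1, [GenomicInterval("c", 4_900, 5_100)])  # center 5000
        m = build_matrix(tr, peaks, flank=1_000, n_bins=10)
        assert np.allclose(m.values[0, :5], 0.0)
        assert np.allclose(m.values[0, 5:], 2.0)

    def test_matches_per_base_binning_oracle(self, g1):
        rng = np.random.default_rng(21)
        starts = np.arange(0, 10_000, 25)
        vals = rng.uniform(0, 4, len(starts))
        tr = SignalTrack(g1, {"c": (starts, starts + 25, vals)})
        per_base = np.repeat(vals, 25)
        peaks = IntervalSet(
            g1, [GenomicInterval("c", int(p), int(p) + 200) for p in rng.integers(1_500, 8_000, 10)]
        )
        m = build_matrix(tr, peaks, flank=1_000, n_bins=20)
        for i, iv in enumerate(peaks):
            c = (iv.start + iv.end) // 2
            for j in range(20):
                a, b = c - 1_000 + j * 100, c - 1_000 + (j + 1) * 100
                assert m.values[i, j] == pytest.approx(per_base[a:b].mean(), rel=1e-9)

    def test_edge_clipping_flagged(self, g1):
        tr = uniform_track(g1, 1.0)
        peaks = IntervalSet(g1, [GenomicInterval("c", 0, 100)])
        m = build_matrix(tr, peaks, flank=1_000, n_bins=10)
        assert m.clipped[0]
        assert m.values[0, :4].sum() < m.values[0, 6:].sum()  # zero-filled left side


class TestConcordanceAndProfiles:
    def _calls(self, states, genotype="KO"):
        return [
            StateCall(f"p{i}", "H3K9me3", genotype, 5.0, 5.0, 1.0, s)
            for i, s in enumerate(states)
        ]

    def test_identical_and_complementary(self):
        a = self._calls(["LOST", "RETAINED", "LOST"])
        b = self._calls(["LOST", "RETAINED", "LOST"], "TKO")
        agree, kappa = concordance(a, b)
        assert agree == 1.0 and kappa == 1.0
        c = self._calls(["RETAINED", "LOST", "RETAINED"], "TKO")
        agree, kappa = concordance(a, c)
        assert agree == 0.0 and kappa <= 0.0

    def test_mismatched_ids_error(self):
        a = self._calls(["LOST"])
        b = [StateCall("other", "H3K9me3", "TKO", 5, 5, 1.0, "LOST")]
        with pytest.raises(ValueError):
            concordance(a, b)

    def test_aggregate_profile_means_and_difference(self):
        from kzfpchip.signal import SignalMatrix

        ones = SignalMatrix(np.ones((4, 6)), [f"p{i}" for i in range(4)], 300)
        prof = aggregate_profile(ones)
        assert np.allclose(prof["mean"], 1.0) and np.allclose(prof["stderr"], 0.0)
        rng = np.random.default_rng(2)
        vals = rng.uniform(0, 3, (5, 6))
        m = SignalMatrix(vals, [f"p{i}" for i in range(5)], 300)
        half = SignalMatrix(vals * 0.5, [f"p{i}" for i in range(5)], 300)
        prof2 = aggregate_profile(m, half)
        assert np.allclose(prof2["diff_mean"], vals.mean(axis=0) * 0.5)
        assert np.allclose(prof2["mean"], vals.mean(axis=0))
        with pytest.raises(ValueError):
            aggregate_profile(SignalMatrix(np.zeros((0, 6)), [], 300))


class TestCobinding:
    def test_counts_and_oracle(self, toy_genome):
        rng = np.random.default_rng(15)
        from conftest import random_intervals

        lost = IntervalSet(toy_genome, random_intervals(rng, toy_genome, 40))
        z = IntervalSet(toy_genome, random_intervals(rng, toy_genome, 30))
        kk = IntervalSet(toy_genome, random_intervals(rng, toy_genome, 30))
        res = partition_by_cobinding(lost, z, kk)
        assert res["n_cobound"] + res["n_remainder"] == res["n_total"] == 40
        from kzfpchip.intervals import overlap_length

        for iv in lost:
            co = any(overlap_length(iv, a) > 0 for a in z) and any(
                overlap_length(iv, b) > 0 for b in kk
            )
            in_co = any(
                (iv.chrom, iv.start, iv.end) == (o.chrom, o.start, o.end)
                for o in res["cobound"]
            )
            assert co == in_co

    def test_no_overlap_gives_zero_pct(self, toy_genome):
        lost = IntervalSet(toy_genome, [GenomicInterval("chr1", 0, 100)])
        z = IntervalSet(toy_genome, [GenomicInterval("chr1", 10_000, 10_100)])
        res = partition_by_cobinding(lost, z, z)
        assert res["pct_cobound"] == 0.0


def test_ko_tko_concordance_on_shared_truth(bundle, consensus_peaks):
    """Mutant tracks generated from the same planted truth call near-identically."""
    peaks = [p.interval for p in consensus_peaks]
    wt = bundle.tracks[("H3K9me3", "WT")]
    ko = k.call_states(wt, bundle.tracks[("H3K9me3", "KO")], peaks, "H3K9me3", "KO")
    tko = k.call_states(wt, bundle.tracks[("H3K9me3", "TKO")], peaks, "H3K9me3", "TKO")
    agree, kappa = concordance(ko, tko)
    assert agree >= 0.95
    assert kappa >= 0.9


def test_bedgraph_roundtrip(tmp_path, g1):
    rng = np.random.default_rng(33)
    starts = np.arange(0, 10_000, 100)
    vals = np.round(rng.uniform(0, 5, len(starts)), 4)
    tr = SignalTrack(g1, {"c": (starts, starts + 100, vals)})
    p = tmp_path / "x.bedgraph"
    write_bedgraph(tr, p)
    back = read_bedgraph(p, g1)
    for a, b in [(0, 10_000), (123, 456), (9_000, 9_999)]:
        assert back.mean_coverage("c", a, b) == pytest.approx(tr.mean_coverage("c", a, b), rel=1e-6)
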