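"""Loss/retention state calling for chromatin marks across genotypes.

Each peak is quantified in a wild-type and a mutant track as mean coverage
over the peak +- a fixed flank, normalized to the genome-wide mean
("enrichment", so 1.0 is background).  The mutant/wild-type enrichment ratio
drives a three-state call:

* LOST      - mutant signal at background (< floor) and ratio <= ratio_lost
* RETAINED  - ratio >= ratio_retained
* PARTIAL   - anything in between

Peaks not enriched in wild type (wt < floor) are flagged and excluded from
loss/retention tallies.  Because the call depends on the ratio, it is
invariant to rescaling both tracks by a common factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._util import round_half_up
from .intervals import GenomicInterval, IntervalSet
from .signal import SignalMatrix, SignalTrack

__all__ = [
    "StateThresholds",
    "StateCall",
    "quantify",
    "call_state",
    "call_states",
    "partition_counts",
    "build_matrix",
    "concordance",
    "partition_by_cobinding",
    "aggregate_profile",
]

NOT_ENRICHED = "NOT_ENRICHED_IN_WT"


@dataclass(frozen=True)
class StateThresholds:
    """Tunable state-calling thresholds (enrichment units; 1.0 = background)."""

    background_floor: float = 1.5
    ratio_lost: float = 0.25
    ratio_retained: float = 0.75
    epsilon: float = 0.01
    quant_flank: int = 250

    def __post_init__(self):
        if not self.ratio_lost < self.ratio_retained:
            raise ValueError("ratio_lost must be < ratio_retained")
        if self.background_floor <= 0:
            raise ValueError("background_floor must be > 0")


@dataclass
class StateCall:
    peak_id: str
    mark: str
    genotype: str
    wt_enrichment: float
    mut_enrichment: float
    ratio: float
    state: str  # LOST | PARTIAL | RETAINED | NOT_ENRICHED_IN_WT


def quantify(track: SignalTrack, peak: GenomicInterval, background: float, flank: int = 250) -> float:
    """Mean coverage over peak +- *flank* divided by *background*."""
    if background <= 0:
        raise ValueError("background must be > 0")
    L = track.genome.length_of(peak.chrom)
    if peak.start >= L:
        raise ValueError("peak outside genome")
    a = max(0, peak.start - flank)
    b = min(L, peak.end + flank)
    return track.mean_coverage(peak.chrom, a, b) / background


def call_state(wt: float, mut: float, cfg: StateThresholds = StateThresholds()) -> str:
    """Three-state call from WT and mutant enrichment values."""
    if wt < 0 or mut < 0:
        raise ValueError("enrichments must be non-negative")
    if wt < cfg.background_floor:
        return NOT_ENRICHED
    ratio = (mut + cfg.epsilon) / (wt + cfg.epsilon)
    if mut < cfg.background_floor and ratio <= cfg.ratio_lost:
        return "LOST"
    if ratio >= cfg.ratio_retained:
        return "RETAINED"
    return "PARTIAL"


def call_states(
    wt_track: SignalTrack,
    mut_track: SignalTrack,
    peaks: Sequence[GenomicInterval],
    mark: str,
    genotype: str,
    cfg: StateThresholds = StateThresholds(),
    wt_background: Optional[float] = None,
    mut_background: Optional[float] = None,
) -> List[StateCall]:
    """Quantify and call every peak; backgrounds default to genome-wide means."""
    bg_wt = wt_background if wt_background is not None else wt_track.genome_mean()
    bg_mut = mut_background if mut_background is not None else mut_track.genome_mean()
    out = []
    for i, pk in enumerate(peaks):
        wt = quantify(wt_track, pk, bg_wt, cfg.quant_flank)
        mut = quantify(mut_track, pk, bg_mut, cfg.quant_flank)
        ratio = (mut + cfg.epsilon) / (wt + cfg.epsilon)
        pid = pk.name if pk.name is not None else f"peak_{i + 1}"
        out.append(StateCall(pid, mark, genotype, wt, mut, ratio, call_state(wt, mut, cfg)))
    return out


def partition_counts(
    calls: Sequence[StateCall], groups: Dict[str, str], states: Sequence[str] = ("LOST", "PARTIAL", "RETAINED")
) -> pd.DataFrame:
    """Contingency table of state counts (and row percentages) per peak category.

    *groups* maps peak_id -> category label.  Not-enriched calls are excluded.
    Percentages use half-up one-decimal rounding; empty categories give zero
    rows with percentages of 0.
    """
    cats = sorted(set(groups.values()))
    rows = []
    for cat in cats:
        sub = [c for c in calls if groups.get(c.peak_id) == cat and c.state != NOT_ENRICHED]
        total = len(sub)
        row = {"category": cat, "total": total}
        for st in states:
            n = sum(1 for c in sub if c.state == st)
            row[st] = n
            row[f"{st}_pct"] = round_half_up(100.0 * n / total, 1) if total else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def build_matrix(
    track: SignalTrack, peaks: IntervalSet, flank: int = 2000, n_bins: int = 40
) -> SignalMatrix:
    """Mean coverage in *n_bins* bins across each peak's center +- *flank*.

    Windows running off a chromosome end are clipped (missing bases contribute
    0 signal over the nominal bin width) and flagged.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    n = len(peaks)
    vals = np.zeros((n, n_bins), dtype=float)
    clipped = np.zeros(n, dtype=bool)
    ids = []
    w = 2 * flank / n_bins
    for i, pk in enumerate(peaks):
        ids.append(pk.name if pk.name is not None else f"peak_{i + 1}")
        c = (pk.start + pk.end) // 2
        L = track.genome.length_of(pk.chrom)
        edges = c - flank + np.round(np.arange(n_bins + 1) * w).astype(np.int64)
        if edges[0] < 0 or edges[-1] > L:
            clipped[i] = True
        ce = np.clip(edges, 0, L)
        F = track._F(pk.chrom, ce)
        widths = np.maximum(np.diff(edges), 1)
        vals[i] = np.diff(F) / widths
    return SignalMatrix(vals, ids, flank, clipped)


def concordance(
    states_a: Sequence[StateCall],
    states_b: Sequence[StateCall],
    partial_as: str = "RETAINED",
) -> Tuple[float, float]:
    """Two-genotype agreement on collapsed LOST/RETAINED states.

    PARTIAL collapses to *partial_as* (RETAINED by default, conservative
    toward retained tallies); not-enriched peaks are dropped pairwise.
    Returns (agreement fraction, Cohen's kappa).
    """
    a_map = {c.peak_id: c.state for c in states_a}
    b_map = {c.peak_id: c.state for c in states_b}
    if set(a_map) != set(b_map):
        raise ValueError("state call lists cover different peak ids")

    def collapse(s):
        return partial_as if s == "PARTIAL" else s

    ya, yb = [], []
    for pid in a_map:
        sa, sb = collapse(a_map[pid]), collapse(b_map[pid])
        if NOT_ENRICHED in (sa, sb):
            continue
        ya.append(sa)
        yb.append(sb)
    if not ya:
        raise ValueError("no jointly enriched peaks to compare")
    agree = float(np.mean([x == y for x, y in zip(ya, yb)]))
    if len(set(ya) | set(yb)) < 2:
        kappa = 1.0 if agree == 1.0 else 0.0
    else:
        from sklearn.metrics import cohen_kappa_score

        kappa = float(cohen_kappa_score(ya, yb))
    return agree, kappa


def partition_by_cobinding(
    lost_regions: IntervalSet, zfp57_peaks: IntervalSet, kap1_peaks: IntervalSet
) -> Dict[str, object]:
    """Split regions by joint ZFP57+KAP1 co-binding (>=1 bp overlap with each)."""
    hit_z = lost_regions.overlaps_any(zfp57_peaks)
    hit_k = lost_regions.overlaps_any(kap1_peaks)
    co = hit_z & hit_k
    n = len(lost_regions)
    idx_co = np.flatnonzero(co)
    idx_rest = np.flatnonzero(~co)
    return {
        "n_total": n,
        "n_cobound": int(co.sum()),
        "n_remainder": int((~co).sum()),
        "pct_cobound": round_half_up(100.0 * co.sum() / n, 1) if n else 0.0,
        "cobound": [lost_regions[int(i)] for i in idx_co],
        "remainder": [lost_regions[int(i)] for i in idx_rest],
    }


def aggregate_profile(matrix: SignalMatrix, other: Optional[SignalMatrix] = None) -> Dict[str, np.ndarray]:
    """Per-bin mean +- stderr; with *other*, also the paired difference profile."""
    if matrix.values.shape[0] == 0:
        raise ValueError("matrix has no rows")
    out = {
        "mean": matrix.values.mean(axis=0),
        "stderr": matrix.values.std(axis=0, ddof=1) / np.sqrt(matrix.values.shape[0])
        if matrix.values.shape[0] > 1
        else np.zeros(matrix.n_bins),
    }
    if other is not None:
        if other.values.shape != matrix.values.shape:
            raise ValueError("matrices must share shape for a paired difference")
        diff = matrix.values - other.values
        out["diff_mean"] = diff.mean(axis=0)
        out["other_mean"] = other.values.mean(axis=0)
    return out


def states_to_dataframe(calls: Sequence[StateCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "peak_id": [c.peak_id for c in calls],
            "mark": [c.mark for c in calls],
            "genotype": [c.genotype for c in calls],
            "wt_enrichment": [c.wt_enrichment for c in calls],
            "mut_enrichment": [c.mut_enrichment for c in calls],
            "ratio": [c.ratio for c in calls],
            "state": [c.state for c in calls],
        }
    )
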