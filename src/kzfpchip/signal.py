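"""Piecewise-constant coverage tracks (bedGraph semantics) and peak matrices.

A :class:`SignalTrack` stores, per chromosome, sorted non-overlapping segments
with a coverage value; positions outside any segment read as 0.  Queries go
through a precomputed running integral, so the mean over any window is two
binary searches, which keeps heatmap-matrix construction fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import GenomeDef, GenomicInterval, IntervalSet

__all__ = ["SignalTrack", "SignalMatrix", "read_bedgraph", "write_bedgraph"]


class SignalTrack:
    """Non-negative per-base coverage as sorted, non-overlapping segments."""

    def __init__(self, genome: GenomeDef, segments: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]]):
        """*segments* maps chrom -> (starts, ends, values); validated and indexed."""
        self.genome = genome
        self._seg: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (s, e, v) in segments.items():
            if chrom not in genome:
                raise ValueError(f"track chromosome {chrom!r} not in genome")
            s = np.asarray(s, dtype=np.int64)
            e = np.asarray(e, dtype=np.int64)
            v = np.asarray(v, dtype=float)
            order = np.argsort(s, kind="stable")
            s, e, v = s[order], e[order], v[order]
            if len(s) and (np.any(e[:-1] > s[1:]) or np.any(s >= e) or np.any(v < 0)):
                raise ValueError(f"segments on {chrom} overlap, are empty, or carry negative values")
            if len(s) and e[-1] > genome.length_of(chrom):
                raise ValueError(f"segment beyond end of {chrom}")
            cum = np.concatenate([[0.0], np.cumsum(v * (e - s))])
            self._seg[chrom] = (s, e, v, cum)

    def _F(self, chrom: str, x: np.ndarray) -> np.ndarray:
        """Integral of coverage over [0, x) for an array of positions."""
        if chrom not in self._seg:
            return np.zeros(len(x), dtype=float)
        s, e, v, cum = self._seg[chrom]
        x = np.asarray(x, dtype=np.int64)
        i = np.searchsorted(s, x, side="right") - 1
        j = np.clip(i, 0, len(s) - 1)
        partial = v[j] * np.clip(x - s[j], 0, e[j] - s[j])
        return np.where(i >= 0, cum[j] + partial, 0.0)

    def integral(self, chrom: str, start, end) -> np.ndarray:
        return self._F(chrom, np.atleast_1d(end)) - self._F(chrom, np.atleast_1d(start))

    def mean_coverage(self, chrom: str, start: int, end: int) -> float:
        """Mean per-base value over [start, end), clipped to the chromosome."""
        L = self.genome.length_of(chrom)
        if start >= L or end <= 0 or start >= end:
            raise ValueError(f"window {chrom}:{start}-{end} outside genome")
        a, b = max(0, start), min(L, end)
        return float(self.integral(chrom, a, b)[0]) / (end - start)

    def genome_mean(self) -> float:
        """Genome-wide mean per-base coverage (uncovered positions count as 0)."""
        tot = sum(float(cum[-1]) for (_, _, _, cum) in self._seg.values())
        return tot / self.genome.total_length

    def scaled(self, factor: float) -> "SignalTrack":
        return SignalTrack(
            self.genome,
            {c: (s.copy(), e.copy(), v * factor) for c, (s, e, v, _) in self._seg.items()},
        )

    def segments(self, chrom: str):
        if chrom not in self._seg:
            return (np.array([], dtype=np.int64),) * 2 + (np.array([], dtype=float),)
        s, e, v, _ = self._seg[chrom]
        return s, e, v


@dataclass
class SignalMatrix:
    """Peaks x bins matrix of mean coverage around peak centers."""

    values: np.ndarray  # (n_peaks, n_bins)
    peak_ids: Sequence[str]
    flank: int
    clipped: np.ndarray = field(default=None)  # bool per peak: window hit a chrom edge

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def bin_width(self) -> float:
        return 2 * self.flank / self.n_bins

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"bin_{j}" for j in range(self.n_bins)]
        df = pd.DataFrame(self.values, columns=cols)
        df.insert(0, "peak_id", list(self.peak_ids))
        return df


def read_bedgraph(path, genome: GenomeDef) -> SignalTrack:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"], comment="#",
        dtype={"chrom": str},
    )
    df = df[~df["chrom"].str.startswith(("track", "browser"))]
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["value"] = df["value"].astype(float)
    segs = {
        str(c): (g["start"].to_numpy(), g["end"].to_numpy(), g["value"].to_numpy())
        for c, g in df.groupby("chrom", sort=False)
    }
    return SignalTrack(genome, segs)


def write_bedgraph(track: SignalTrack, path, merge_equal: bool = True) -> None:
    frames = []
    for chrom in track.genome.chrom_names:
        s, e, v = track.segments(chrom)
        if len(s) == 0:
            continue
        if merge_equal and len(s) > 1:
            # collapse runs of book-ended segments sharing one value
            new = np.ones(len(s), dtype=bool)
            new[1:] = (s[1:] != e[:-1]) | (v[1:] != v[:-1])
            gid = np.cumsum(new) - 1
            cs = s[new]
            ce = np.zeros(gid[-1] + 1, dtype=np.int64)
            np.maximum.at(ce, gid, e)
            cv = v[new]
        else:
            cs, ce, cv = s, e, v
        frames.append(pd.DataFrame({"chrom": chrom, "start": cs, "end": ce, "value": cv}))
    if frames:
        df = pd.concat(frames, ignore_index=True)
        df["value"] = [f"{x:g}" for x in df["value"]]
        df.to_csv(path, sep="\t", header=False, index=False)
    else:
        open(path, "w").close()
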