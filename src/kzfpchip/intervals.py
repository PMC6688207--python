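"""Genome-aware interval algebra shared by every pipeline stage.

Coordinates are 0-based, half-open (BED convention) throughout; all readers
convert on the way in.  Intervals live on a declared :class:`GenomeDef` so that
random placement (:func:`shuffle`) and validity checks know the chromosome
lengths.  Strand is carried but ignored by overlap/distance computations, which
is how the peak/repeat analyses in this package use intervals.

The container is columnar (numpy arrays sorted by (chrom, start, end)) because
the permutation-enrichment null repeats shuffle + overlap-count tens of
thousands of times.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeDef",
    "GenomicInterval",
    "IntervalSet",
    "overlap_length",
    "nearest_distance",
    "merge",
    "shuffle",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "write_chrom_sizes",
]


@dataclass(frozen=True)
class GenomeDef:
    """Chromosome name/length table defining the coordinate system."""

    chrom_names: tuple
    chrom_lengths: tuple

    def __init__(self, chrom_names: Sequence[str], chrom_lengths: Sequence[int]):
        names = tuple(str(c) for c in chrom_names)
        lengths = tuple(int(x) for x in chrom_lengths)
        if len(names) != len(lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        if any(x <= 0 for x in lengths):
            raise ValueError("chromosome lengths must be positive")
        object.__setattr__(self, "chrom_names", names)
        object.__setattr__(self, "chrom_lengths", lengths)

    @property
    def sizes(self) -> dict:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sizes

    def length_of(self, chrom: str) -> int:
        try:
            return self.sizes[chrom]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} not in genome") from None

    @property
    def total_length(self) -> int:
        return int(sum(self.chrom_lengths))


@dataclass(frozen=True)
class GenomicInterval:
    """A single 0-based half-open interval with optional strand/name/score."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: Optional[str] = None
    score: Optional[float] = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Length in bp of the overlap between two intervals (0 if disjoint)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


class IntervalSet:
    """Sorted collection of intervals on one genome.

    Iteration order is (chrom, start, end)-sorted, with chromosomes in the
    genome's declared order.  Internally columnar: ``chrom_idx``, ``starts``,
    ``ends`` numpy arrays plus object arrays for strand/name/score.
    """

    def __init__(self, genome: GenomeDef, intervals: Iterable[GenomicInterval] = ()):
        ivs = list(intervals)
        self.genome = genome
        order = {c: i for i, c in enumerate(genome.chrom_names)}
        for iv in ivs:
            if iv.chrom not in order:
                raise ValueError(f"interval on unknown chromosome {iv.chrom!r}")
            if iv.end > genome.length_of(iv.chrom):
                raise ValueError(
                    f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome length"
                )
        self.chrom_idx = np.array([order[iv.chrom] for iv in ivs], dtype=np.int64)
        self.starts = np.array([iv.start for iv in ivs], dtype=np.int64)
        self.ends = np.array([iv.end for iv in ivs], dtype=np.int64)
        self.strands = np.array([iv.strand for iv in ivs], dtype=object)
        self.names = np.array([iv.name for iv in ivs], dtype=object)
        self.scores = np.array([iv.score for iv in ivs], dtype=object)
        self._sort()
        self._index = None

    @classmethod
    def _from_arrays(cls, genome, chrom_idx, starts, ends, strands=None, names=None, scores=None):
        obj = cls.__new__(cls)
        n = len(starts)
        obj.genome = genome
        obj.chrom_idx = np.asarray(chrom_idx, dtype=np.int64)
        obj.starts = np.asarray(starts, dtype=np.int64)
        obj.ends = np.asarray(ends, dtype=np.int64)
        obj.strands = np.full(n, ".", dtype=object) if strands is None else np.asarray(strands, dtype=object)
        obj.names = np.full(n, None, dtype=object) if names is None else np.asarray(names, dtype=object)
        obj.scores = np.full(n, None, dtype=object) if scores is None else np.asarray(scores, dtype=object)
        obj._sort()
        obj._index = None
        return obj

    def _sort(self):
        order = np.lexsort((self.ends, self.starts, self.chrom_idx))
        for attr in ("chrom_idx", "starts", "ends", "strands", "names", "scores"):
            setattr(self, attr, getattr(self, attr)[order])

    def __len__(self) -> int:
        return len(self.starts)

    def __iter__(self) -> Iterator[GenomicInterval]:
        names = self.genome.chrom_names
        for ci, s, e, st, nm, sc in zip(
            self.chrom_idx, self.starts, self.ends, self.strands, self.names, self.scores
        ):
            yield GenomicInterval(names[ci], int(s), int(e), st, nm, sc)

    def __getitem__(self, i: int) -> GenomicInterval:
        return GenomicInterval(
            self.genome.chrom_names[self.chrom_idx[i]],
            int(self.starts[i]),
            int(self.ends[i]),
            self.strands[i],
            self.names[i],
            self.scores[i],
        )

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    def total_coverage(self) -> int:
        """Covered bp after unioning overlaps."""
        m = merge(self)
        return int(np.sum(m.ends - m.starts))

    def to_dataframe(self) -> pd.DataFrame:
        names = np.asarray(self.genome.chrom_names, dtype=object)
        return pd.DataFrame(
            {
                "chrom": names[self.chrom_idx] if len(self) else np.array([], dtype=object),
                "start": self.starts,
                "end": self.ends,
                "name": self.names,
                "score": self.scores,
                "strand": self.strands,
            }
        )

    # -- overlap machinery -------------------------------------------------

    def _merged_index(self):
        """Per-chromosome merged (starts, ends) arrays, cached."""
        if self._index is None:
            m = merge(self)
            idx = {}
            for ci in np.unique(m.chrom_idx):
                sel = m.chrom_idx == ci
                idx[int(ci)] = (m.starts[sel], m.ends[sel])
            self._index = idx
        return self._index

    def overlaps_any(self, other: "IntervalSet") -> np.ndarray:
        """Boolean array: does interval i of *self* overlap any interval of *other*."""
        idx = other._merged_index()
        out = np.zeros(len(self), dtype=bool)
        for ci, (ms, me) in idx.items():
            sel = np.flatnonzero(self.chrom_idx == ci)
            if sel.size == 0:
                continue
            j = np.searchsorted(ms, self.ends[sel], side="left") - 1
            ok = (j >= 0) & (me[np.clip(j, 0, len(me) - 1)] > self.starts[sel])
            out[sel] = ok
        return out

    def count_overlapping(self, other: "IntervalSet") -> int:
        """Number of intervals in *self* overlapping >=1 bp of *other*."""
        return int(self.overlaps_any(other).sum())


def merge(iset: IntervalSet) -> IntervalSet:
    """Union overlapping or book-ended intervals; coverage-conserving.

    Book-ended intervals (gap = 0) are joined, matching the bedtools-merge
    default.  Names/scores/strands are dropped in the result.
    """
    if len(iset) == 0:
        return IntervalSet(iset.genome, [])
    ci, s, e = iset.chrom_idx, iset.starts, iset.ends
    # offset coordinates per chromosome (+1 spacer) so the running max never
    # bleeds across a chromosome boundary
    off = np.concatenate(
        [[0], np.cumsum(np.asarray(iset.genome.chrom_lengths, dtype=np.int64) + 1)]
    )[:-1]
    sg, eg = s + off[ci], e + off[ci]
    cummax = np.maximum.accumulate(eg)
    new_group = np.ones(len(s), dtype=bool)
    new_group[1:] = sg[1:] > cummax[:-1]
    gid = np.cumsum(new_group) - 1
    n_groups = gid[-1] + 1
    out_ci = ci[new_group]
    out_s = s[new_group]
    out_e = np.zeros(n_groups, dtype=np.int64)
    np.maximum.at(out_e, gid, e)
    return IntervalSet._from_arrays(iset.genome, out_ci, out_s, out_e)


def nearest_distance(query: GenomicInterval, subject: IntervalSet):
    """Gap in bp from *query* to the closest subject interval (0 if overlapping).

    Returns ``None`` when the subject has no interval on the query's
    chromosome.  Raises on an empty subject set.
    """
    if len(subject) == 0:
        raise ValueError("subject set is empty")
    try:
        ci = subject.genome.chrom_names.index(query.chrom)
    except ValueError:
        raise ValueError(f"query chromosome {query.chrom!r} not on subject genome") from None
    sel = subject.chrom_idx == ci
    if not sel.any():
        return None
    s, e = subject.starts[sel], subject.ends[sel]
    # any overlap?
    j = np.searchsorted(s, query.end, side="left") - 1
    if j >= 0 and e[: j + 1].max() > query.start:
        return 0
    best = None
    # nearest to the right: smallest start >= query.end
    k = np.searchsorted(s, query.end, side="left")
    if k < len(s):
        best = int(s[k] - query.end)
    # nearest to the left: largest end <= query.start
    left_gaps = query.start - e[e <= query.start]
    if left_gaps.size:
        d = int(left_gaps.min())
        best = d if best is None else min(best, d)
    return best


def nearest_distances(queries: IntervalSet, subject: IntervalSet) -> list:
    """Vector form of :func:`nearest_distance`; entries are int or None."""
    return [nearest_distance(q, subject) for q in queries]


def shuffle(
    iset: IntervalSet,
    genome: Optional[GenomeDef] = None,
    rng_seed=0,
    mode: str = "chromosome",
    exclude: Optional[IntervalSet] = None,
    max_tries: int = 1000,
) -> IntervalSet:
    """Length-preserving uniform random re-placement of every interval.

    mode="chromosome" keeps each interval on its own chromosome with a uniform
    start on [0, L - len]; mode="genome" first picks a chromosome with
    probability proportional to the number of valid start positions.  With an
    *exclude* set, placements overlapping it are rejection-sampled.
    Deterministic given ``rng_seed`` (an int seed or a Generator).
    """
    genome = genome or iset.genome
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    lengths = iset.lengths
    chrom_lens = np.asarray(genome.chrom_lengths, dtype=np.int64)
    if len(iset) and lengths.max() > chrom_lens.max():
        raise ValueError("an interval is longer than every chromosome")

    if mode == "chromosome":
        out_ci = iset.chrom_idx.copy()
        high = chrom_lens[out_ci] - lengths
        if (high < 0).any():
            raise ValueError("interval longer than its chromosome under same-chromosome policy")
    elif mode == "genome":
        out_ci = np.empty(len(iset), dtype=np.int64)
        for i, L in enumerate(lengths):
            w = np.maximum(chrom_lens - L + 1, 0).astype(float)
            out_ci[i] = rng.choice(len(chrom_lens), p=w / w.sum())
        high = chrom_lens[out_ci] - lengths
    else:
        raise ValueError(f"unknown placement policy {mode!r}")

    out_s = rng.integers(0, high + 1) if len(iset) else np.array([], dtype=np.int64)
    if exclude is not None and len(exclude) and len(iset):
        for _ in range(max_tries):
            bad = _overlaps_mask(genome, out_ci, out_s, out_s + lengths, exclude)
            if not bad.any():
                break
            out_s[bad] = rng.integers(0, high[bad] + 1)
        else:
            raise RuntimeError("could not place intervals outside the exclusion set")
    return IntervalSet._from_arrays(
        genome, out_ci, out_s, out_s + lengths, iset.strands.copy(), iset.names.copy(), iset.scores.copy()
    )


def _overlaps_mask(genome, chrom_idx, starts, ends, subject: IntervalSet) -> np.ndarray:
    idx = subject._merged_index()
    out = np.zeros(len(starts), dtype=bool)
    for ci, (ms, me) in idx.items():
        sel = np.flatnonzero(chrom_idx == ci)
        if sel.size == 0:
            continue
        j = np.searchsorted(ms, ends[sel], side="left") - 1
        out[sel] = (j >= 0) & (me[np.clip(j, 0, len(me) - 1)] > starts[sel])
    return out


# -- I/O -------------------------------------------------------------------


def read_chrom_sizes(path) -> GenomeDef:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"], comment="#")
    return GenomeDef(df["chrom"].astype(str).tolist(), df["length"].astype(int).tolist())


def write_chrom_sizes(genome: GenomeDef, path) -> None:
    with open(path, "w") as fh:
        for c, l in zip(genome.chrom_names, genome.chrom_lengths):
            fh.write(f"{c}\t{l}\n")


def read_bed(path, genome: GenomeDef, extra_cols: Sequence[str] = ()) -> IntervalSet:
    """BED3/BED6 reader; track/browser/comment lines are skipped.

    Only columns 1-6 become interval fields; for BED6+N use
    :func:`read_bed_dataframe`, which names columns 7.. via ``extra_cols``.
    """
    df = read_bed_dataframe(path, extra_cols)
    ivs = []
    for row in df.itertuples(index=False):
        ivs.append(
            GenomicInterval(
                str(row.chrom),
                int(row.start),
                int(row.end),
                getattr(row, "strand", ".") if getattr(row, "strand", ".") in ("+", "-") else ".",
                getattr(row, "name", None),
                float(row.score) if getattr(row, "score", None) is not None and str(row.score) not in (".", "nan") else None,
            )
        )
    return IntervalSet(genome, ivs)


def read_bed_dataframe(path, extra_cols: Sequence[str] = ()) -> pd.DataFrame:
    base = ["chrom", "start", "end", "name", "score", "strand"]
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            rows.append(line.split("\t"))
    if not rows:
        return pd.DataFrame(columns=base + list(extra_cols))
    ncol = len(rows[0])
    cols = (base + list(extra_cols))[:ncol]
    df = pd.DataFrame(rows, columns=cols + [f"col{i}" for i in range(len(cols), ncol)])
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_bed(iset: IntervalSet, path) -> None:
    with open(path, "w") as fh:
        for iv in iset:
            name = iv.name if iv.name is not None else "."
            score = iv.score if iv.score is not None else 0
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")
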