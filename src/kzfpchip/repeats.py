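"""Peak categorization against repeat annotation, ICRs and gene models.

Every consensus peak gets exactly one category with precedence
ICR > repeat > UNIQUE; a repeat-overlapping peak is assigned to the single
element with the largest bp overlap (ties broken toward the leftmost element),
and is a TE when that element's class is LTR/LINE/SINE/DNA.  The ICR override
keeps the known imprinting-control internal controls out of the TE tallies.

Gene-feature assignment uses promoter > exon > intron > intergenic precedence
with a strand-aware promoter window around the TSS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._util import round_half_up
from .consensus import ConsensusPeak
from .intervals import GenomeDef, GenomicInterval, IntervalSet, overlap_length

__all__ = [
    "TE_CLASSES",
    "RepeatElement",
    "PeakCategoryCall",
    "CategorySummary",
    "GeneModel",
    "classify_peak",
    "classify_peaks",
    "rank_te_names",
    "summarize_distribution",
    "gene_feature_assign",
    "read_repeat_bed",
    "read_bed12_genes",
]

TE_CLASSES = frozenset({"LTR", "LINE", "SINE", "DNA"})


@dataclass(frozen=True)
class RepeatElement:
    interval: GenomicInterval
    rep_name: str
    rep_class: str
    rep_family: str = ""

    @property
    def is_te(self) -> bool:
        return self.rep_class in TE_CLASSES


@dataclass
class PeakCategoryCall:
    peak: ConsensusPeak
    category: str  # ICR | TE | NONTE_REPEAT | UNIQUE
    assigned_element: Optional[RepeatElement] = None
    overlap_bp: int = 0


@dataclass
class CategorySummary:
    """Counts and half-up one-decimal percentages per category.

    When the per-category counts do not exhaust *total* (e.g. published count
    tables that omit a residual class), the remainder is reported explicitly
    as ``other`` rather than forcing the counts to the total.
    """

    counts: Dict[str, int]
    total: int
    percentages: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.total < 1:
            raise ValueError("total must be >= 1")
        ssum = sum(self.counts.values())
        if ssum > self.total:
            raise ValueError("counts exceed total")
        counts = dict(self.counts)
        if ssum < self.total:
            counts["other"] = self.total - ssum
        self.counts = counts
        self.percentages = {
            k: round_half_up(100.0 * v / self.total, 1) for k, v in counts.items()
        }


def summarize_distribution(counts: Dict[str, int], total: Optional[int] = None) -> CategorySummary:
    total = sum(counts.values()) if total is None else total
    return CategorySummary(dict(counts), total)


def classify_peak(
    peak: ConsensusPeak,
    repeats: Sequence[RepeatElement],
    icrs: Optional[IntervalSet] = None,
) -> PeakCategoryCall:
    """Categorize one peak; see module docstring for the precedence rules."""
    iv = peak.interval
    if icrs is not None and len(icrs):
        for icr in icrs:
            if overlap_length(iv, icr) >= 1:
                return PeakCategoryCall(peak, "ICR")
    best, best_ov = None, 0
    for el in repeats:
        ov = overlap_length(iv, el.interval)
        if ov > best_ov or (
            ov == best_ov
            and ov > 0
            and (el.interval.chrom, el.interval.start, el.interval.end)
            < (best.interval.chrom, best.interval.start, best.interval.end)
        ):  # ties resolve to the leftmost element, independent of input order
            best, best_ov = el, ov
    if best is None:
        return PeakCategoryCall(peak, "UNIQUE")
    cat = "TE" if best.is_te else "NONTE_REPEAT"
    return PeakCategoryCall(peak, cat, best, best_ov)


def classify_peaks(
    peaks: Sequence[ConsensusPeak],
    repeats: Sequence[RepeatElement],
    icrs: Optional[IntervalSet] = None,
) -> List[PeakCategoryCall]:
    """Vector form of :func:`classify_peak` with a per-chromosome prefilter."""
    by_chrom: Dict[str, List[RepeatElement]] = {}
    for el in sorted(repeats, key=lambda e: (e.interval.chrom, e.interval.start, e.interval.end)):
        by_chrom.setdefault(el.interval.chrom, []).append(el)
    # sorted start arrays for a window prefilter
    arr = {
        c: (np.array([e.interval.start for e in els]), np.array([e.interval.end for e in els]))
        for c, els in by_chrom.items()
    }
    out = []
    for pk in peaks:
        iv = pk.interval
        cands: Sequence[RepeatElement] = ()
        if iv.chrom in by_chrom:
            s, e = arr[iv.chrom]
            hi = np.searchsorted(s, iv.end, side="left")
            idx = np.flatnonzero(e[:hi] > iv.start)
            cands = [by_chrom[iv.chrom][i] for i in idx]
        out.append(classify_peak(pk, cands, icrs))
    return out


def rank_te_names(calls: Sequence[PeakCategoryCall], top_k: Optional[int] = None) -> pd.DataFrame:
    """Repeat names ranked by number of TE-category peaks (stable name tie-break)."""
    names = [c.assigned_element.rep_name for c in calls if c.category == "TE"]
    if not names:
        return pd.DataFrame(columns=["rep_name", "peak_count"])
    vc = pd.Series(names).value_counts()
    df = vc.rename_axis("rep_name").reset_index(name="peak_count")
    df = df.sort_values(["peak_count", "rep_name"], ascending=[False, True], kind="stable")
    df = df.reset_index(drop=True)
    return df.head(top_k) if top_k else df


def summarize_calls(calls: Sequence[PeakCategoryCall]) -> CategorySummary:
    counts: Dict[str, int] = {}
    for c in calls:
        counts[c.category] = counts.get(c.category, 0) + 1
    return CategorySummary(counts, len(calls))


# -- gene features ---------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """Gene span with exon blocks; TSS is strand-aware (end for minus strand)."""

    gene_id: str
    span: GenomicInterval
    exons: Tuple[Tuple[int, int], ...]

    def __post_init__(self):
        for s, e in self.exons:
            if s < self.span.start or e > self.span.end or s >= e:
                raise ValueError(f"exon [{s},{e}) outside gene span for {self.gene_id}")

    @property
    def tss(self) -> int:
        return self.span.start if self.span.strand != "-" else self.span.end


def gene_feature_assign(
    peak: ConsensusPeak, genes: Sequence[GeneModel], promoter_window: int = 1000
) -> str:
    """Assign a peak to promoter/exon/intron/intergenic by >=1 bp overlap.

    The promoter is [TSS - window, TSS + window) with the TSS placed by strand;
    precedence promoter > exon > intron > intergenic across all gene models.
    """
    iv = peak.interval
    hit_exon = hit_intron = False
    for g in genes:
        if g.span.chrom != iv.chrom:
            continue
        p0 = max(0, g.tss - promoter_window)
        p1 = g.tss + promoter_window
        if min(iv.end, p1) - max(iv.start, p0) >= 1:
            return "promoter"
        if overlap_length(iv, g.span) >= 1:
            in_exon = any(min(iv.end, e) - max(iv.start, s) >= 1 for s, e in g.exons)
            if in_exon:
                hit_exon = True
            else:
                hit_intron = True
    if hit_exon:
        return "exon"
    if hit_intron:
        return "intron"
    return "intergenic"


# -- I/O -------------------------------------------------------------------


def read_repeat_bed(path, genome: GenomeDef) -> List[RepeatElement]:
    """BED6+3 repeat annotation: cols 7-9 are rep_name, rep_class, rep_family."""
    from .intervals import read_bed_dataframe

    df = read_bed_dataframe(path, extra_cols=["rep_name", "rep_class", "rep_family"])
    out = []
    for row in df.itertuples(index=False):
        iv = GenomicInterval(str(row.chrom), int(row.start), int(row.end),
                             row.strand if row.strand in ("+", "-") else ".")
        out.append(RepeatElement(iv, str(row.rep_name), str(row.rep_class), str(row.rep_family)))
    return out


def write_repeat_bed(repeats: Sequence[RepeatElement], path) -> None:
    with open(path, "w") as fh:
        for el in repeats:
            iv = el.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{el.rep_name}\t0\t{iv.strand}"
                f"\t{el.rep_name}\t{el.rep_class}\t{el.rep_family}\n"
            )


def read_bed12_genes(path) -> List[GeneModel]:
    """BED12 gene models -> :class:`GeneModel` (blocks become exons)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            f = line.split("\t")
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5] if len(f) > 5 and f[5] in ("+", "-") else "."
            if len(f) >= 12:
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offs = [int(x) for x in f[11].rstrip(",").split(",")]
                exons = tuple((start + o, start + o + s) for o, s in zip(offs, sizes))
            else:
                exons = ((start, end),)
            out.append(GeneModel(name, GenomicInterval(chrom, start, end, strand, name), exons))
    return out


def write_bed12_genes(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            iv = g.span
            sizes = ",".join(str(e - s) for s, e in g.exons)
            offs = ",".join(str(s - iv.start) for s, e in g.exons)
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{g.gene_id}\t0\t{iv.strand}"
                f"\t{iv.start}\t{iv.end}\t0\t{len(g.exons)}\t{sizes}\t{offs}\n"
            )
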