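"""Peak-gene integration: proximity, differential expression and co-binding.

Links genes to the nearest consensus peak within a distance cutoff (strict
"< max_dist", gene-span anchoring by default with a TSS mode), partitions
proximal genes by differential-expression status, measures cross-mutant
fold-change direction concordance, nominates direct targets, and counts
multi-KZFP co-binding membership patterns.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, IntervalSet

__all__ = [
    "DEGene",
    "TargetCall",
    "genes_near_peaks",
    "cross_de",
    "direction_concordance",
    "nominate_direct_targets",
    "multi_kzfp_overlap",
    "read_de_table",
    "write_de_table",
]


@dataclass
class DEGene:
    gene_id: str
    span: GenomicInterval
    tss: int
    expr_wt: float
    expr_mut: float
    log2fc: float
    adj_p: float
    is_de: bool
    is_imprinted: bool = False


def de_flag(log2fc: float, adj_p: float, min_abs_lfc: float = 1.0, max_adj_p: float = 0.05) -> bool:
    """Default differential-expression rule: adj_p < 0.05 and |log2FC| >= 1."""
    return (adj_p < max_adj_p) and (abs(log2fc) >= min_abs_lfc)


@dataclass
class TargetCall:
    gene_id: str
    nearest_peak_id: str
    distance_bp: int
    is_de: bool
    is_imprinted: bool = False
    h3k9me3_state_at_peak: Optional[str] = None
    direction_ko: int = 0
    direction_tko: int = 0
    log2fc_ko: float = 0.0
    log2fc_tko: float = 0.0


def _gap(iv: GenomicInterval, s: int, e: int) -> int:
    if iv.end <= s:
        return s - iv.end
    if e <= iv.start:
        return iv.start - e
    return 0


def genes_near_peaks(
    genes: Sequence[DEGene],
    peaks: IntervalSet,
    max_dist: int = 20_000,
    anchor: str = "span",
) -> List[TargetCall]:
    """Genes whose span (or TSS) lies strictly closer than *max_dist* to a peak.

    Each qualifying gene appears once, with its nearest peak and gap recorded.
    """
    if max_dist < 0:
        raise ValueError("max_dist must be >= 0")
    out = []
    for g in genes:
        best_d, best_id = None, None
        for j in range(len(peaks)):
            if peaks.genome.chrom_names[peaks.chrom_idx[j]] != g.span.chrom:
                continue
            s, e = int(peaks.starts[j]), int(peaks.ends[j])
            if anchor == "span":
                d = _gap(g.span, s, e)
            elif anchor == "tss":
                # TSS treated as the 1 bp interval [tss, tss+1)
                d = _gap(GenomicInterval(g.span.chrom, g.tss, g.tss + 1), s, e)
            else:
                raise ValueError(f"unknown anchor {anchor!r}")
            if best_d is None or d < best_d:
                best_d = d
                best_id = peaks.names[j] if peaks.names[j] is not None else f"peak_{j + 1}"
        if best_d is not None and best_d < max_dist:
            out.append(
                TargetCall(
                    g.gene_id,
                    best_id,
                    int(best_d),
                    g.is_de,
                    g.is_imprinted,
                    direction_ko=int(np.sign(g.log2fc)),
                    log2fc_ko=g.log2fc,
                )
            )
    return out


def cross_de(calls: Sequence[TargetCall], n_de_total: Optional[int] = None) -> Dict[str, int]:
    """Partition proximal genes by DE status; optionally report DE genes lacking peaks."""
    n_de = sum(1 for c in calls if c.is_de)
    out = {"near_and_de": n_de, "near_not_de": len(calls) - n_de, "n_near": len(calls)}
    if n_de_total is not None:
        out["de_without_nearby_peak"] = n_de_total - n_de
    return out


def direction_concordance(
    gene_ids: Sequence[str], fc_ko: Dict[str, float], fc_tko: Dict[str, float]
) -> Dict[str, float]:
    """Cross-mutant direction agreement split by KO direction, plus rank correlation.

    Among KO-upregulated genes, the fraction whose second-mutant fold change is
    also positive; likewise for downregulated.  Genes with KO fold change of
    exactly 0 are counted in neither direction group.
    """
    if len(gene_ids) == 0:
        raise ValueError("empty gene subset")
    missing = [g for g in gene_ids if g not in fc_ko or g not in fc_tko]
    if missing:
        raise ValueError(f"fold changes missing for {missing[:3]}...")
    a = np.array([fc_ko[g] for g in gene_ids])
    b = np.array([fc_tko[g] for g in gene_ids])
    up = a > 0
    dn = a < 0
    out = {
        "n_up_ko": int(up.sum()),
        "n_down_ko": int(dn.sum()),
        "up_agreement": float(np.mean(b[up] > 0)) if up.any() else float("nan"),
        "down_agreement": float(np.mean(b[dn] < 0)) if dn.any() else float("nan"),
    }
    if len(a) >= 2 and np.std(a) > 0 and np.std(b) > 0:
        rho, _ = stats.spearmanr(a, b)
        out["spearman_rho"] = float(rho)
    else:
        out["spearman_rho"] = float("nan")
    return out


@dataclass(frozen=True)
class NominationRule:
    """Which conditions a gene must meet to be called a direct target."""

    require_proximal: bool = True
    require_de: bool = True
    require_up_ko: bool = True
    require_up_tko: bool = True
    require_lost_state: bool = True


def nominate_direct_targets(
    calls: Sequence[TargetCall], rule: NominationRule = NominationRule()
) -> List[str]:
    """Direct-target nomination: proximal, DE, up in both mutants, peak H3K9me3 LOST."""
    out = []
    for c in calls:  # calls are proximal by construction
        if rule.require_de and not c.is_de:
            continue
        if rule.require_up_ko and c.direction_ko <= 0:
            continue
        if rule.require_up_tko and c.direction_tko <= 0:
            continue
        if rule.require_lost_state and c.h3k9me3_state_at_peak != "LOST":
            continue
        out.append(c.gene_id)
    return out


def multi_kzfp_overlap(
    primary_peaks: IntervalSet, other_sets: Dict[str, IntervalSet]
) -> Dict[str, int]:
    """Venn-style membership-pattern counts for primary peaks vs other KZFP sets.

    Key "zfp932+gm15446" counts primary peaks overlapping exactly that
    combination; "none" counts primary-exclusive peaks.  Counts sum to the
    primary set size, and the full intersection is also reported under
    "all_cobound".
    """
    if not other_sets:
        raise ValueError("at least one other peak set is required")
    names = list(other_sets)
    hits = {nm: primary_peaks.overlaps_any(other_sets[nm]) for nm in names}
    counts: Dict[str, int] = {}
    for combo in product([False, True], repeat=len(names)):
        mask = np.ones(len(primary_peaks), dtype=bool)
        for nm, present in zip(names, combo):
            mask &= hits[nm] if present else ~hits[nm]
        key = "+".join(nm for nm, p in zip(names, combo) if p) or "none"
        counts[key] = int(mask.sum())
    full = np.ones(len(primary_peaks), dtype=bool)
    for nm in names:
        full &= hits[nm]
    counts["all_cobound"] = int(full.sum())
    return counts


# -- I/O -------------------------------------------------------------------

DE_COLUMNS = [
    "gene_id", "chrom", "start", "end", "strand",
    "expr_wt", "expr_mut", "log2fc", "adj_p", "is_de", "is_imprinted",
]


def read_de_table(path, genome) -> List[DEGene]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        strand = row.strand if row.strand in ("+", "-") else "."
        span = GenomicInterval(str(row.chrom), int(row.start), int(row.end), strand, str(row.gene_id))
        tss = span.start if strand != "-" else span.end
        out.append(
            DEGene(
                str(row.gene_id), span, tss,
                float(row.expr_wt), float(row.expr_mut), float(row.log2fc), float(row.adj_p),
                bool(row.is_de), bool(getattr(row, "is_imprinted", False)),
            )
        )
    return out


def write_de_table(genes: Sequence[DEGene], path) -> None:
    rows = [
        {
            "gene_id": g.gene_id, "chrom": g.span.chrom, "start": g.span.start,
            "end": g.span.end, "strand": g.span.strand, "expr_wt": g.expr_wt,
            "expr_mut": g.expr_mut, "log2fc": g.log2fc, "adj_p": g.adj_p,
            "is_de": g.is_de, "is_imprinted": g.is_imprinted,
        }
        for g in genes
    ]
    pd.DataFrame(rows, columns=DE_COLUMNS).to_csv(path, sep="\t", index=False)


def calls_to_dataframe(calls: Sequence[TargetCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in calls],
            "nearest_peak_id": [c.nearest_peak_id for c in calls],
            "distance_bp": [c.distance_bp for c in calls],
            "is_de": [c.is_de for c in calls],
            "is_imprinted": [c.is_imprinted for c in calls],
            "h3k9me3_state_at_peak": [c.h3k9me3_state_at_peak for c in calls],
            "direction_ko": [c.direction_ko for c in calls],
            "direction_tko": [c.direction_tko for c in calls],
            "log2fc_ko": [c.log2fc_ko for c in calls],
            "log2fc_tko": [c.log2fc_tko for c in calls],
        }
    )
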