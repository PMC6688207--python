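"""Synthetic-data generator with planted ground truth for every pipeline input.

The generator emulates the statistical structure of a ZFP57-style KZFP ChIP
study: ~300 binding sites split across imprinting-control regions, unique
sequence and transposable elements (TE-dominated, with one IAP-like LTR name
carrying the majority of TE sites); three replicate peak calls with
configurable sensitivity/jitter/false positives; piecewise-constant signal
tracks for ZFP57/KAP1/H3K9me3 across WT and mutant genotypes whose bump
amplitudes encode planted LOST/PARTIAL/RETAINED states; gene models and
differential-expression tables with direct targets upregulated in both
mutants; and stage-resolved methylation (and H3K9me3-level) matrices with
planted germline-DMR classes, maternal-allele protection and transient DMRs.

Everything is deterministic given the master seed; each output draws from its
own sub-stream so adding an output never perturbs the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._util import sub_rng
from .intervals import (
    GenomeDef,
    GenomicInterval,
    IntervalSet,
    write_bed,
    write_chrom_sizes,
)
from .repeats import GeneModel, RepeatElement, write_bed12_genes, write_repeat_bed
from .signal import SignalTrack, write_bedgraph
from .targets import DEGene, de_flag, write_de_table
from .methylation import STAGES, MethMatrix

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SimBundle",
    "simulate",
    "paper_mimic_config",
    "simulate_state_benchmark",
    "simulate_meth_cohort",
]

MARKS = ("ZFP57", "KAP1", "H3K9me3")
GENOTYPES = ("WT", "KO", "TKO", "MZKO")

DOMINANT_TE = "IAPLTR2a2_Mm"
OTHER_LTR = ("IAPEz-int", "RLTR44E", "IAPLTR1_Mm", "MMERVK10C-int")
LINE_NAMES = ("L1Md_T", "L1Md_A")
SINE_NAMES = ("B1_Mus1",)
DNA_NAMES = ("MER20",)
NONTE_NAMES = (("(CA)n", "Simple_repeat"), ("GSAT_MM", "Satellite"), ("A-rich", "Low_complexity"))


@dataclass
class SimConfig:
    """All knobs of the generator; defaults are the study conditions."""

    seed: int = 0
    # genome
    n_chroms: int = 4
    chrom_length: int = 2_000_000
    # site counts / proportions (non-ICR proportions are renormalized)
    n_sites: int = 300
    n_icr: int = 20
    n_icr_partial: int = 3        # ICRs with only partial H3K9me3 loss in mutants
    n_paternal_icr: int = 3
    te_proportion: float = 0.839
    unique_proportion: float = 0.133
    nonte_proportion: float = 0.013
    unique_lose_fraction: float = 0.52
    te_lose_fraction: float = 0.022
    dominant_te_fraction: float = 795 / 1194   # of TE sites on the IAP-like name
    ltr_fraction_of_te: float = 1061 / 1194
    # placement; unique/ICR sites get extra clearance so genes anchored to
    # them have that site as their unambiguous nearest peak
    site_spacing: int = 4_000
    unique_site_clearance: int = 22_000
    edge_margin: int = 25_000
    site_halfwidth: int = 150
    # background repeat annotation
    n_bg_repeats: int = 600
    bg_repeat_min_len: int = 200
    bg_repeat_max_len: int = 800
    unique_lose_clearance: int = 12_000  # no repeats this close to unique-lose sites
    # replicate peak calls
    n_replicates: int = 3
    sensitivity: float = 0.9
    fp_rate: float = 0.1
    jitter: int = 30
    # signal model
    bin_size: int = 50
    background_mean: float = 1.0
    background_sd: float = 0.25
    peak_amplitude: float = 12.0
    amp_sigma: float = 0.10        # lognormal sigma on bump amplitudes
    partial_factor: float = 0.40
    kap1_te_ko_factor: float = 0.55
    bump_sigma: float = 150.0
    # genes / differential expression
    n_genes: int = 120
    n_direct: int = 12
    n_imprinted_de: int = 8
    n_secondary_up: int = 20
    n_secondary_down: int = 20
    n_proximal_down: int = 8
    direct_lfc: float = 3.0
    lfc_sd: float = 0.5
    secondary_lfc: float = 2.5
    secondary_tko_sd: float = 0.6
    null_lfc_sd: float = 0.15
    de_adj_p: float = 1e-8
    gene_min_len: int = 6_000
    gene_max_len: int = 15_000
    # methylation dynamics
    n_both_bound: int = 42
    n_oocyte_bound: int = 6
    n_sperm_bound: int = 11
    n_both_unbound: int = 50
    n_oocyte_unbound: int = 30
    n_sperm_unbound: int = 20
    gamete_high: float = 0.85
    gamete_low: float = 0.04
    retention_bound: float = 0.60
    retention_unbound: float = 0.30
    pat_retention_bound_both: float = 0.38
    icr_retention: float = 0.90
    epiblast_level: float = 0.85
    exe_level: float = 0.40
    meth_noise: float = 0.03
    # H3K9me3 stage levels
    h3k9_oocyte_bound: float = 0.70
    h3k9_oocyte_unbound: float = 0.30
    h3k9_post_bound: float = 0.60
    h3k9_post_unbound: float = 0.25
    h3k9_noise: float = 0.05
    # multi-KZFP co-binding
    n_triple_cobound: int = 33
    n_zfp932_only: int = 27
    n_gm15446_only: int = 17
    n_offsite_other: int = 30

    def category_counts(self) -> Dict[str, int]:
        """Resolve planted per-category site counts from the proportions."""
        n_rest = self.n_sites - self.n_icr
        if n_rest < 0:
            raise ValueError("n_icr exceeds n_sites")
        tot = self.te_proportion + self.unique_proportion + self.nonte_proportion
        n_te = int(round(n_rest * self.te_proportion / tot))
        n_unique = int(round(n_rest * self.unique_proportion / tot))
        n_nonte = n_rest - n_te - n_unique
        n_ulose = int(round(n_unique * self.unique_lose_fraction))
        n_telose = int(round(n_te * self.te_lose_fraction))
        return {
            "ICR": self.n_icr,
            "UNIQUE_LOSE": n_ulose,
            "UNIQUE_RETAIN": n_unique - n_ulose,
            "NONTE": n_nonte,
            "TE_LOSE": n_telose,
            "TE_RETAIN": n_te - n_telose,
        }


def paper_mimic_config(seed: int = 0, size_multiplier: float = 1.0) -> SimConfig:
    """Scaled-down configuration whose planted proportions match the study:
    ~84% of non-control sites on TEs (98% of those retaining H3K9me3), unique
    sites split 52/48 lose/retain, 20 ICR internal controls."""
    cfg = SimConfig(seed=seed)
    if size_multiplier != 1.0:
        cfg.n_sites = int(round(cfg.n_sites * size_multiplier))
        cfg.n_icr = max(4, int(round(cfg.n_icr * size_multiplier)))
        cfg.chrom_length = int(cfg.chrom_length * max(1.0, size_multiplier))
    return cfg


@dataclass
class GroundTruth:
    sites: pd.DataFrame
    genes: pd.DataFrame
    regions: pd.DataFrame
    n_triple_cobound: int


@dataclass
class SimBundle:
    config: SimConfig
    genome: GenomeDef
    icrs: IntervalSet
    repeats: List[RepeatElement]
    replicate_peaks: List[IntervalSet]
    tracks: Dict[Tuple[str, str], SignalTrack]
    gene_models: List[GeneModel]
    de_ko: List[DEGene]
    de_tko: List[DEGene]
    meth: MethMatrix
    h3k9_stage: MethMatrix
    kzfp_sets: Dict[str, IntervalSet]
    truth: GroundTruth


# -- placement helpers -----------------------------------------------------


def _place_centers(rng, genome: GenomeDef, clearances: Sequence[int], margin: int):
    """Random site centers; centers i,j keep max(clearance_i, clearance_j) apart."""
    lens = np.asarray(genome.chrom_lengths, dtype=float)
    n = len(clearances)
    if n and 2 * margin + max(clearances) >= lens.min():
        raise ValueError("chromosomes too short for the requested margin/clearance")
    probs = lens / lens.sum()
    centers: List[Tuple[int, int, int]] = []  # (chrom_idx, pos, clearance)
    tries = 0
    for cl in clearances:
        while True:
            tries += 1
            if tries > 300 * n + 2000:
                raise RuntimeError("infeasible placement: too many sites for this genome")
            ci = int(rng.choice(len(lens), p=probs))
            pos = int(rng.integers(margin, int(lens[ci]) - margin))
            if all(c != ci or abs(pos - p) >= max(cl, c2) for c, p, c2 in centers):
                centers.append((ci, pos, cl))
                break
    return [(c, p) for c, p, _ in centers]


def _draw_te_name(rng, cfg: SimConfig) -> Tuple[str, str]:
    u = rng.random()
    if u < cfg.dominant_te_fraction:
        return DOMINANT_TE, "LTR"
    if u < cfg.ltr_fraction_of_te:
        return OTHER_LTR[int(rng.integers(len(OTHER_LTR)))], "LTR"
    # split the non-LTR remainder ~ LINE:SINE:DNA = 3:2:1
    v = rng.random()
    if v < 0.5:
        return LINE_NAMES[int(rng.integers(len(LINE_NAMES)))], "LINE"
    if v < 0.85:
        return SINE_NAMES[0], "SINE"
    return DNA_NAMES[0], "DNA"


# -- main entry ------------------------------------------------------------


def simulate(cfg: SimConfig, outdir: Optional[Path] = None) -> SimBundle:
    """Generate the full input bundle plus ground truth (optionally to disk)."""
    genome = GenomeDef(
        [f"chr{i + 1}" for i in range(cfg.n_chroms)], [cfg.chrom_length] * cfg.n_chroms
    )
    counts = cfg.category_counts()
    rng_sites = sub_rng(cfg.seed, "sites")

    order = ["ICR", "UNIQUE_LOSE", "UNIQUE_RETAIN", "NONTE", "TE_LOSE", "TE_RETAIN"]
    categories = [cat for cat in order for _ in range(counts[cat])]
    wide = {"ICR", "UNIQUE_LOSE", "UNIQUE_RETAIN"}
    clearances = [
        cfg.unique_site_clearance if cat in wide else cfg.site_spacing for cat in categories
    ]
    centers = _place_centers(rng_sites, genome, clearances, cfg.edge_margin)

    hw = cfg.site_halfwidth
    sites = pd.DataFrame(
        {
            "site_id": [f"site_{i + 1}" for i in range(len(categories))],
            "chrom": [genome.chrom_names[c] for c, _ in centers],
            "center": [p for _, p in centers],
            "category": categories,
        }
    )
    sites["start"] = sites["center"] - hw
    sites["end"] = sites["center"] + hw

    # -- annotation: ICR bed, site-covering repeats, near-site LTRs, background
    rng_rep = sub_rng(cfg.seed, "repeats")
    icr_rows = sites[sites.category == "ICR"]
    icrs = IntervalSet(
        genome,
        [
            GenomicInterval(r.chrom, r.center - 500, r.center + 500, name=f"ICR_{i + 1}")
            for i, r in enumerate(icr_rows.itertuples(index=False))
        ],
    )
    repeats: List[RepeatElement] = []
    te_names = []
    for r in sites.itertuples(index=False):
        if r.category in ("TE_LOSE", "TE_RETAIN"):
            nm, cls = _draw_te_name(rng_rep, cfg)
            te_names.append(nm)
            repeats.append(
                RepeatElement(GenomicInterval(r.chrom, r.center - 300, r.center + 300), nm, cls, cls)
            )
        elif r.category == "NONTE":
            nm, cls = NONTE_NAMES[int(rng_rep.integers(len(NONTE_NAMES)))]
            te_names.append(nm)
            repeats.append(
                RepeatElement(GenomicInterval(r.chrom, r.center - 300, r.center + 300), nm, cls, cls)
            )
        elif r.category == "UNIQUE_RETAIN":
            te_names.append("")
            # planted nearby LTR: retained unique sites sit in LTR-dense context
            d = int(rng_rep.integers(500, 2000))
            side = 1 if rng_rep.random() < 0.5 else -1
            s = r.center + d if side > 0 else r.center - d - 400
            repeats.append(
                RepeatElement(
                    GenomicInterval(r.chrom, max(0, s), max(0, s) + 400),
                    OTHER_LTR[int(rng_rep.integers(len(OTHER_LTR)))], "LTR", "LTR",
                )
            )
        else:
            te_names.append("")
    sites["rep_name"] = te_names

    # background (unbound) repeats, kept clear of planted sites
    site_pos = [(genome.chrom_names.index(r.chrom), r.center) for r in sites.itertuples(index=False)]
    ulose_pos = [
        (genome.chrom_names.index(r.chrom), r.center)
        for r in sites.itertuples(index=False)
        if r.category in ("UNIQUE_LOSE", "UNIQUE_RETAIN")
    ]
    bg_classes = [("LTR", 0.5), ("LINE", 0.2), ("SINE", 0.15), ("DNA", 0.05), ("Simple_repeat", 0.1)]
    placed = 0
    guard = 0
    while placed < cfg.n_bg_repeats:
        guard += 1
        if guard > 100 * cfg.n_bg_repeats:
            raise RuntimeError("could not place background repeats")
        ci = int(rng_rep.integers(cfg.n_chroms))
        L = int(rng_rep.integers(cfg.bg_repeat_min_len, cfg.bg_repeat_max_len + 1))
        s = int(rng_rep.integers(0, cfg.chrom_length - L))
        mid = s + L // 2
        if any(c == ci and abs(mid - p) < 1500 for c, p in site_pos):
            continue
        if any(c == ci and abs(mid - p) < cfg.unique_lose_clearance for c, p in ulose_pos):
            continue
        u = rng_rep.random()
        acc = 0.0
        for cls, w in bg_classes:
            acc += w
            if u < acc:
                break
        if cls == "LTR":
            nm = OTHER_LTR[int(rng_rep.integers(len(OTHER_LTR)))]
        elif cls == "LINE":
            nm = LINE_NAMES[0]
        elif cls == "SINE":
            nm = SINE_NAMES[0]
        elif cls == "DNA":
            nm = DNA_NAMES[0]
        else:
            nm = "(CA)n"
        repeats.append(RepeatElement(GenomicInterval(genome.chrom_names[ci], s, s + L), nm, cls, cls))
        placed += 1
    repeats.sort(key=lambda e: (e.interval.chrom, e.interval.start, e.interval.end))

    # -- replicate peak calls
    replicate_peaks = []
    for rep in range(cfg.n_replicates):
        rng = sub_rng(cfg.seed, f"replicate_{rep + 1}")
        ivs = []
        for r in sites.itertuples(index=False):
            if rng.random() < cfg.sensitivity:
                j1 = int(rng.integers(-cfg.jitter, cfg.jitter + 1))
                j2 = int(rng.integers(-cfg.jitter, cfg.jitter + 1))
                ivs.append(
                    GenomicInterval(
                        r.chrom, max(0, r.start + j1), r.end + j2,
                        name=f"rep{rep + 1}_{r.site_id}", score=float(rng.uniform(50, 200)),
                    )
                )
        n_fp = int(round(cfg.fp_rate * len(sites)))
        for k in range(n_fp):
            ci = int(rng.integers(cfg.n_chroms))
            s = int(rng.integers(0, cfg.chrom_length - 2 * hw))
            ivs.append(
                GenomicInterval(genome.chrom_names[ci], s, s + 2 * hw,
                                name=f"rep{rep + 1}_fp{k + 1}", score=float(rng.uniform(20, 60)))
            )
        replicate_peaks.append(IntervalSet(genome, ivs))

    # -- planted chromatin states and signal tracks
    def state_factor(mark: str, genotype: str, category: str, partial_icr: bool) -> float:
        if genotype == "WT":
            return 1.0
        if mark == "ZFP57":
            return 0.0  # no ZFP57 signal in KO/MZKO; no binding in TKO either
        lost = category in ("UNIQUE_LOSE", "TE_LOSE") or (category == "ICR" and not partial_icr)
        if category == "ICR" and partial_icr:
            return cfg.partial_factor
        if lost:
            return 0.0
        if mark == "KAP1" and genotype in ("KO", "MZKO") and category == "TE_RETAIN":
            return cfg.kap1_te_ko_factor
        return 1.0

    icr_ids = sites.index[sites.category == "ICR"].to_numpy()
    partial_flags = np.zeros(len(sites), dtype=bool)
    partial_flags[icr_ids[: cfg.n_icr_partial]] = True

    def label(f: float) -> str:
        if f == 0.0:
            return "LOST"
        if f >= 1.0:
            return "RETAINED"
        return "PARTIAL"

    for mark in ("H3K9me3", "KAP1"):
        for gt in ("KO", "TKO", "MZKO"):
            sites[f"{mark.lower()}_{gt.lower()}_state"] = [
                label(state_factor(mark, gt, c, pf))
                for c, pf in zip(sites.category, partial_flags)
            ]

    tracks: Dict[Tuple[str, str], SignalTrack] = {}
    chrom_of = sites.chrom.to_numpy()
    center_of = sites.center.to_numpy()
    for mark in MARKS:
        for gt in GENOTYPES:
            rng = sub_rng(cfg.seed, f"track_{mark}_{gt}")
            amps = (
                cfg.peak_amplitude
                * np.array([state_factor(mark, gt, c, pf) for c, pf in zip(sites.category, partial_flags)])
                * np.exp(rng.normal(0.0, cfg.amp_sigma, len(sites)))
            )
            segs = {}
            shape = (cfg.background_mean / cfg.background_sd) ** 2
            scale = cfg.background_mean / shape
            for ci, chrom in enumerate(genome.chrom_names):
                edges = np.arange(0, cfg.chrom_length + cfg.bin_size, cfg.bin_size)
                edges[-1] = cfg.chrom_length
                nb = len(edges) - 1
                vals = rng.gamma(shape, scale, nb)
                mids = (edges[:-1] + edges[1:]) / 2.0
                for j in np.flatnonzero(chrom_of == chrom):
                    if amps[j] <= 0:
                        continue
                    c = center_of[j]
                    lo = np.searchsorted(mids, c - 4 * cfg.bump_sigma)
                    hi = np.searchsorted(mids, c + 4 * cfg.bump_sigma)
                    vals[lo:hi] += amps[j] * np.exp(
                        -((mids[lo:hi] - c) ** 2) / (2 * cfg.bump_sigma**2)
                    )
                segs[chrom] = (edges[:-1].copy(), edges[1:].copy(), vals)
            tracks[(mark, gt)] = SignalTrack(genome, segs)

    # -- genes and differential expression
    gene_models, de_ko, de_tko, genes_truth = _make_genes(cfg, genome, sites)

    # -- methylation and H3K9me3 stage matrices
    meth, h3k9_stage, regions_truth = _make_meth(cfg)

    # -- other KZFP peak sets with a planted triple-co-bound subset
    rng_kz = sub_rng(cfg.seed, "kzfp_other")
    te_idx = sites.index[sites.category.isin(["TE_LOSE", "TE_RETAIN"])].to_numpy()
    rng_kz.shuffle(te_idx)
    n3, nz, ng = cfg.n_triple_cobound, cfg.n_zfp932_only, cfg.n_gm15446_only
    if len(te_idx) < n3 + nz + ng:
        raise ValueError("not enough TE sites for the requested co-binding pattern")
    both_idx, z_idx, g_idx = te_idx[:n3], te_idx[n3 : n3 + nz], te_idx[n3 + nz : n3 + nz + ng]
    bg_only = [e for e in repeats if e.rep_class in ("LTR", "LINE")][-cfg.n_offsite_other :]

    def kz_set(site_idx, tag):
        ivs = [
            GenomicInterval(sites.chrom[i], sites.center[i] - 200, sites.center[i] + 200,
                            name=f"{tag}_{k + 1}")
            for k, i in enumerate(site_idx)
        ]
        extra = bg_only[: cfg.n_offsite_other // 2] if tag == "zfp932" else bg_only[cfg.n_offsite_other // 2 :]
        ivs += [
            GenomicInterval(e.interval.chrom, e.interval.start, e.interval.end, name=f"{tag}_bg{k}")
            for k, e in enumerate(extra)
        ]
        return IntervalSet(genome, ivs)

    kzfp_sets = {
        "zfp932": kz_set(np.concatenate([both_idx, z_idx]), "zfp932"),
        "gm15446": kz_set(np.concatenate([both_idx, g_idx]), "gm15446"),
    }

    truth = GroundTruth(sites.copy(), genes_truth, regions_truth, n3)
    bundle = SimBundle(
        cfg, genome, icrs, repeats, replicate_peaks, tracks, gene_models,
        de_ko, de_tko, meth, h3k9_stage, kzfp_sets, truth,
    )
    if outdir is not None:
        write_bundle(bundle, Path(outdir))
    return bundle


def _make_genes(cfg: SimConfig, genome: GenomeDef, sites: pd.DataFrame):
    rng = sub_rng(cfg.seed, "genes")
    roles = (
        ["direct"] * cfg.n_direct
        + ["imprinted"] * cfg.n_imprinted_de
        + ["proximal_down"] * cfg.n_proximal_down
        + ["secondary_up"] * cfg.n_secondary_up
        + ["secondary_down"] * cfg.n_secondary_down
    )
    n_null = cfg.n_genes - len(roles)
    if n_null < 0:
        raise ValueError("n_genes smaller than the sum of special gene roles")
    roles += ["null"] * n_null

    ulose = sites[sites.category == "UNIQUE_LOSE"].reset_index(drop=True)
    uret = sites[sites.category == "UNIQUE_RETAIN"].reset_index(drop=True)
    # imprinted DE genes anchor only ICRs with complete H3K9me3 loss, since
    # their planted direct-target status presumes a lost peak
    icr = sites[
        (sites.category == "ICR") & (sites.get("h3k9me3_ko_state", "LOST") == "LOST")
    ].reset_index(drop=True)
    if len(ulose) < cfg.n_direct or len(icr) < cfg.n_imprinted_de or len(uret) < cfg.n_proximal_down:
        raise ValueError("not enough planted sites to anchor the requested gene roles")

    site_pos = [(r.chrom, r.center) for r in sites.itertuples(index=False)]
    models, ko, tko, rows = [], [], [], []
    k_direct = k_impr = k_pdown = 0
    for gi, role in enumerate(roles):
        gid = f"gene_{gi + 1}"
        length = int(rng.integers(cfg.gene_min_len, cfg.gene_max_len))
        strand = "+" if rng.random() < 0.5 else "-"
        anchor = None
        if role == "direct":
            anchor = ulose.iloc[k_direct]; k_direct += 1
        elif role == "imprinted":
            anchor = icr.iloc[k_impr]; k_impr += 1
        elif role == "proximal_down":
            anchor = uret.iloc[k_pdown]; k_pdown += 1
        if anchor is not None:
            # keep the whole gene within the anchor's clearance radius so the
            # anchor site is unambiguously the gene's nearest peak
            off = int(rng.integers(2_000, 4_500))
            length = min(length, 12_000)
            start = int(anchor.center + off)
            chrom = anchor.chrom
        else:
            # far from every planted site for secondary genes; anywhere for null
            min_clear = 25_000 if role.startswith("secondary") else 0
            for _ in range(1000):
                chrom = genome.chrom_names[int(rng.integers(cfg.n_chroms))]
                start = int(rng.integers(1_000, cfg.chrom_length - cfg.gene_max_len - 1_000))
                if min_clear == 0 or all(
                    c != chrom or not (start - min_clear < p < start + length + min_clear)
                    for c, p in site_pos
                ):
                    break
            else:
                raise RuntimeError("could not place gene away from sites")
        end = min(start + length, cfg.chrom_length - 1)
        n_ex = int(rng.integers(2, 5))
        bounds = np.sort(rng.choice(np.arange(start + 50, end - 50), 2 * n_ex, replace=False))
        exons = tuple((int(bounds[2 * i]), int(bounds[2 * i + 1])) for i in range(n_ex))
        exons = tuple((s, e) for s, e in exons if e > s) or ((start, end),)
        span = GenomicInterval(chrom, start, end, strand, gid)
        models.append(GeneModel(gid, span, exons))

        if role in ("direct", "imprinted"):
            fc_ko = float(rng.normal(cfg.direct_lfc, cfg.lfc_sd))
            fc_tko = float(rng.normal(cfg.direct_lfc - 0.5, cfg.lfc_sd))
            p = cfg.de_adj_p
        elif role == "secondary_up":
            fc_ko = float(rng.normal(cfg.secondary_lfc, cfg.lfc_sd))
            fc_tko = float(rng.normal(0.0, cfg.secondary_tko_sd))
            p = cfg.de_adj_p
        elif role in ("secondary_down", "proximal_down"):
            fc_ko = float(-rng.normal(cfg.secondary_lfc, cfg.lfc_sd))
            fc_tko = float(rng.normal(0.0, cfg.secondary_tko_sd))
            p = cfg.de_adj_p
        else:
            fc_ko = float(rng.normal(0.0, cfg.null_lfc_sd))
            fc_tko = float(rng.normal(0.0, cfg.null_lfc_sd))
            p = float(rng.uniform(0.2, 1.0))
        expr_wt = float(rng.uniform(5, 200))
        tss = span.start if strand != "-" else span.end
        impr = role == "imprinted"
        ko.append(DEGene(gid, span, tss, expr_wt, expr_wt * 2.0**fc_ko, fc_ko, p,
                         de_flag(fc_ko, p), impr))
        tko.append(DEGene(gid, span, tss, expr_wt, expr_wt * 2.0**fc_tko, fc_tko, p,
                          de_flag(fc_tko, p), impr))
        rows.append(
            {
                "gene_id": gid,
                "role": role,
                "direct_target": role in ("direct", "imprinted"),
                "anchor_site": anchor.site_id if anchor is not None else "",
            }
        )
    return models, ko, tko, pd.DataFrame(rows)


def _make_meth(cfg: SimConfig):
    rng = sub_rng(cfg.seed, "meth")
    rng_h = sub_rng(cfg.seed, "h3k9stage")
    specs = (
        [("BOTH", True)] * cfg.n_both_bound
        + [("OOCYTE", True)] * cfg.n_oocyte_bound
        + [("SPERM", True)] * cfg.n_sperm_bound
        + [("BOTH", False)] * cfg.n_both_unbound
        + [("OOCYTE", False)] * cfg.n_oocyte_unbound
        + [("SPERM", False)] * cfg.n_sperm_unbound
        + [("ICR_MAT", True)] * (cfg.n_icr - cfg.n_paternal_icr)
        + [("ICR_PAT", True)] * cfg.n_paternal_icr
    )
    frac = {"zygote": 0.0, "two_cell": 0.2, "four_cell": 0.4, "eight_cell": 0.6, "morula": 0.8,
            "ICM": 1.0, "TE_lineage": 1.0}
    rows, truth_rows, hrows = [], [], []
    for ri, (cls, bound) in enumerate(specs):
        rid = f"region_{ri + 1}"
        is_icr = cls.startswith("ICR")
        g_mat = cfg.gamete_high if cls in ("BOTH", "OOCYTE", "ICR_MAT") else cfg.gamete_low
        g_pat = cfg.gamete_high if cls in ("BOTH", "SPERM", "ICR_PAT") else cfg.gamete_low

        if is_icr:
            r_mat = cfg.icr_retention if cls == "ICR_MAT" else cfg.retention_unbound
            r_pat = cfg.icr_retention if cls == "ICR_PAT" else cfg.retention_unbound
        else:
            r_mat = cfg.retention_bound if bound and cls in ("OOCYTE", "BOTH") else cfg.retention_unbound
            if cls == "BOTH" and bound:
                r_pat = cfg.pat_retention_bound_both
            else:
                r_pat = cfg.retention_unbound  # paternal alleles are not protected

        # gamete columns: oocyte measures the maternal allele, sperm the paternal
        row = {"region_id": rid, "bound": bound, "is_icr": is_icr,
               "oocyte": g_mat, "sperm": g_pat}
        for st, f in frac.items():
            mat = g_mat * (1 - f * (1 - r_mat))
            pat = g_pat * (1 - f * (1 - r_pat))
            row[f"{st}.mat"] = mat
            row[f"{st}.pat"] = pat
            row[st] = (mat + pat) / 2.0
        # post-implantation: non-ICR regions acquire biallelic methylation in
        # the epiblast; ICRs keep their parental asymmetry; ExE stays lower
        if is_icr:
            em = cfg.epiblast_level if cls == "ICR_MAT" else cfg.gamete_low
            ep = cfg.epiblast_level if cls == "ICR_PAT" else cfg.gamete_low
        else:
            em = ep = cfg.epiblast_level
        row["epiblast.mat"], row["epiblast.pat"] = em, ep
        row["epiblast"] = (em + ep) / 2.0
        row["ExE.mat"] = em * cfg.exe_level / cfg.epiblast_level
        row["ExE.pat"] = ep * cfg.exe_level / cfg.epiblast_level
        row["ExE"] = (row["ExE.mat"] + row["ExE.pat"]) / 2.0

        if cfg.meth_noise > 0:
            for k, v in list(row.items()):
                if k in ("region_id", "bound", "is_icr"):
                    continue
                row[k] = float(np.clip(v + rng.normal(0, cfg.meth_noise), 0.0, 1.0))
        rows.append(row)

        transient = bool((not is_icr) and bound and cls == "OOCYTE")
        truth_rows.append(
            {
                "region_id": rid,
                "gdmr_class": "OOCYTE" if cls == "ICR_MAT" else ("SPERM" if cls == "ICR_PAT" else cls),
                "bound": bound,
                "is_icr": is_icr,
                "protected": bool(bound and cls in ("OOCYTE", "BOTH", "ICR_MAT", "ICR_PAT")),
                "transient_dmr": transient,
                "resolved_in_epiblast": transient,
            }
        )

        # H3K9me3 level trajectory (maternal-chromatin mark; sperm is depleted)
        oo_level = cfg.h3k9_oocyte_bound if (bound and g_mat > 0.5) else cfg.h3k9_oocyte_unbound
        post = cfg.h3k9_post_bound if (bound and g_mat > 0.5) else cfg.h3k9_post_unbound
        hrow = {"region_id": rid, "bound": bound, "is_icr": is_icr,
                "oocyte": oo_level, "sperm": 0.05}
        for st in frac:
            hrow[st] = post
        hrow["epiblast"] = post
        hrow["ExE"] = post * 0.8
        if cfg.h3k9_noise > 0:
            for k, v in list(hrow.items()):
                if k in ("region_id", "bound", "is_icr"):
                    continue
                hrow[k] = float(np.clip(v + rng_h.normal(0, cfg.h3k9_noise), 0.0, 1.0))
        hrows.append(hrow)

    mdf = pd.DataFrame(rows).set_index("region_id")
    hdf = pd.DataFrame(hrows).set_index("region_id")
    return MethMatrix(mdf), MethMatrix(hdf), pd.DataFrame(truth_rows)


# -- benchmark helpers -----------------------------------------------------


def simulate_state_benchmark(
    n_peaks: int = 300,
    proportions: Tuple[float, float, float] = (0.4, 0.1, 0.5),
    seed: int = 0,
    cfg: Optional[SimConfig] = None,
):
    """Single-mark WT/mutant track pair with LOST/PARTIAL/RETAINED planted
    at the given proportions; returns (peaks, wt_track, mut_track, truth)."""
    cfg = cfg or SimConfig(seed=seed)
    # wide spacing keeps the bump mass a small fraction of the genome, so the
    # genome-mean normalization does not bias mutant/WT enrichment ratios
    spacing = 20_000
    need = n_peaks * spacing + 50_000
    genome = GenomeDef(["chrS"], [max(need, 1_000_000)])
    rng = sub_rng(seed, "state_benchmark")
    n_lost = int(round(n_peaks * proportions[0]))
    n_part = int(round(n_peaks * proportions[1]))
    states = ["LOST"] * n_lost + ["PARTIAL"] * n_part + ["RETAINED"] * (n_peaks - n_lost - n_part)
    centers = 25_000 + spacing * np.arange(n_peaks)
    factors = {"LOST": 0.0, "PARTIAL": cfg.partial_factor, "RETAINED": 1.0}

    def track(which: str) -> SignalTrack:
        trng = sub_rng(seed, f"state_benchmark_track_{which}")
        edges = np.arange(0, genome.chrom_lengths[0] + cfg.bin_size, cfg.bin_size)
        edges[-1] = genome.chrom_lengths[0]
        shape = (cfg.background_mean / cfg.background_sd) ** 2
        vals = trng.gamma(shape, cfg.background_mean / shape, len(edges) - 1)
        mids = (edges[:-1] + edges[1:]) / 2.0
        for c, st in zip(centers, states):
            f = 1.0 if which == "wt" else factors[st]
            amp = cfg.peak_amplitude * f * math.exp(trng.normal(0, cfg.amp_sigma))
            if amp <= 0:
                continue
            lo = np.searchsorted(mids, c - 4 * cfg.bump_sigma)
            hi = np.searchsorted(mids, c + 4 * cfg.bump_sigma)
            vals[lo:hi] += amp * np.exp(-((mids[lo:hi] - c) ** 2) / (2 * cfg.bump_sigma**2))
        return SignalTrack(genome, {"chrS": (edges[:-1], edges[1:], vals)})

    peaks = IntervalSet(
        genome,
        [GenomicInterval("chrS", int(c) - 150, int(c) + 150, name=f"peak_{i + 1}")
         for i, c in enumerate(centers)],
    )
    return peaks, track("wt"), track("mut"), list(states)


def simulate_meth_cohort(
    n_bound: int = 200,
    n_unbound: int = 200,
    gap: float = 0.30,
    noise: float = 0.05,
    seed: int = 0,
    base_retention: float = 0.30,
    gamete: float = 0.85,
):
    """Two-group blastocyst cohort with a planted retention gap (bound - unbound)."""
    rng = sub_rng(seed, "meth_cohort")
    rows = []
    for i in range(n_bound + n_unbound):
        bound = i < n_bound
        r = base_retention + (gap if bound else 0.0)
        icm = float(np.clip(gamete * r + rng.normal(0, noise), 0, 1))
        rows.append(
            {"region_id": f"r{i + 1}", "bound": bound,
             "oocyte": float(np.clip(gamete + rng.normal(0, noise), 0, 1)),
             "sperm": 0.05, "ICM": icm}
        )
    return MethMatrix(pd.DataFrame(rows).set_index("region_id"))


# -- file bundle -----------------------------------------------------------


def write_bundle(bundle: SimBundle, outdir: Path) -> Dict[str, Path]:
    """Write every input file plus the ground-truth tables; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    def reg(key, name):
        paths[key] = outdir / name
        return paths[key]

    write_chrom_sizes(bundle.genome, reg("chrom_sizes", "genome.chrom.sizes"))
    write_bed(bundle.icrs, reg("icrs", "icrs.bed"))
    write_repeat_bed(bundle.repeats, reg("repeats", "repeats.bed"))
    for i, rp in enumerate(bundle.replicate_peaks):
        write_bed(rp, reg(f"replicate_{i + 1}", f"replicate_{i + 1}.bed"))
    for (mark, gt), tr in bundle.tracks.items():
        write_bedgraph(tr, reg(f"track_{mark}_{gt}", f"{mark}_{gt}.bedgraph"))
    write_bed12_genes(bundle.gene_models, reg("genes", "genes.bed12"))
    write_de_table(bundle.de_ko, reg("de_ko", "de_ko.tsv"))
    write_de_table(bundle.de_tko, reg("de_tko", "de_tko.tsv"))
    bundle.meth.write_tsv(reg("meth", "meth_matrix.tsv"))
    bundle.h3k9_stage.write_tsv(reg("h3k9_stage", "h3k9_stage_matrix.tsv"))
    for nm, s in bundle.kzfp_sets.items():
        write_bed(s, reg(f"kzfp_{nm}", f"kzfp_{nm}.bed"))
    bundle.truth.sites.to_csv(reg("truth_sites", "ground_truth_sites.tsv"), sep="\t", index=False)
    bundle.truth.genes.to_csv(reg("truth_genes", "ground_truth_genes.tsv"), sep="\t", index=False)
    bundle.truth.regions.to_csv(reg("truth_regions", "ground_truth_regions.tsv"), sep="\t", index=False)
    return paths
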