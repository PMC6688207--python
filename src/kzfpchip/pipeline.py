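"""End-to-end orchestration: consensus -> classify -> enrich -> states ->
integrate -> methdyn, with a JSON manifest and machine-readable reports.

Each stage reads the standard input files (by default laid out as the
synthetic-data generator writes them) plus upstream stage outputs from the
output directory, and writes TSV/JSON results.  A disabled upstream stage
whose outputs are missing raises :class:`MissingUpstreamError` naming the
stage.  Reports carry no timestamps, so identical config + seed reruns are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

import importlib

# fetched via importlib because the package exports functions named like
# some submodules (e.g. kzfpchip.consensus the function vs the module)
cns = importlib.import_module("kzfpchip.consensus")
enr = importlib.import_module("kzfpchip.enrichment")
meth = importlib.import_module("kzfpchip.methylation")
rep = importlib.import_module("kzfpchip.repeats")
st = importlib.import_module("kzfpchip.states")
tg = importlib.import_module("kzfpchip.targets")
from .intervals import GenomeDef, GenomicInterval, IntervalSet, read_bed, read_chrom_sizes, write_bed
from .signal import read_bedgraph

STAGE_ORDER = ("consensus", "classify", "enrich", "states", "integrate", "methdyn")


class PipelineError(Exception):
    exit_code = 2


class MissingUpstreamError(PipelineError):
    exit_code = 3

    def __init__(self, stage: str, needed_by: str):
        super().__init__(f"stage '{needed_by}' requires outputs of disabled/missing stage '{stage}'")
        self.stage = stage


@dataclass
class PipelineConfig:
    input_dir: str
    outdir: str
    seed: int = 0
    stages: List[str] = field(default_factory=lambda: list(STAGE_ORDER))
    min_support: int = 2
    enrich_iters: int = 100
    promoter_window: int = 1000
    max_gene_dist: int = 20_000
    background_floor: float = 1.5
    ratio_lost: float = 0.25
    ratio_retained: float = 0.75
    quant_flank: int = 250
    gdmr_hi: float = 0.75
    gdmr_lo: float = 0.25
    allele_delta: float = 0.30
    paths: Dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def path(self, key: str, default_name: str) -> Path:
        if key in self.paths:
            return Path(self.paths[key])
        return Path(self.input_dir) / default_name

    def thresholds(self) -> st.StateThresholds:
        return st.StateThresholds(
            background_floor=self.background_floor,
            ratio_lost=self.ratio_lost,
            ratio_retained=self.ratio_retained,
            quant_flank=self.quant_flank,
        )

    def meth_config(self) -> meth.MethConfig:
        return meth.MethConfig(hi=self.gdmr_hi, lo=self.gdmr_lo, allele_delta=self.allele_delta)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _dump_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, GenomicInterval):
        return f"{o.chrom}:{o.start}-{o.end}"
    raise TypeError(f"not JSON serializable: {type(o)}")


def _log(msg: str) -> None:
    print(f"[kzfpchip] {msg}", file=sys.stderr)


def _load_genome(cfg: PipelineConfig) -> GenomeDef:
    return read_chrom_sizes(cfg.path("chrom_sizes", "genome.chrom.sizes"))


def _need(outdir: Path, fname: str, stage: str, needed_by: str) -> Path:
    p = outdir / fname
    if not p.exists():
        raise MissingUpstreamError(stage, needed_by)
    return p


def _consensus_peakset(outdir: Path, genome: GenomeDef, needed_by: str) -> IntervalSet:
    df = pd.read_csv(_need(outdir, "consensus.tsv", "consensus", needed_by), sep="\t")
    ivs = [
        GenomicInterval(r.chrom, int(r.start), int(r.end), name=r.peak_id, score=float(r.support))
        for r in df.itertuples(index=False)
    ]
    return IntervalSet(genome, ivs)


# -- stages ----------------------------------------------------------------


def stage_consensus(cfg: PipelineConfig, outdir: Path) -> Dict:
    genome = _load_genome(cfg)
    reps = []
    i = 1
    while True:
        p = cfg.path(f"replicate_{i}", f"replicate_{i}.bed")
        if not p.exists():
            break
        reps.append(cns.ReplicatePeakSet(f"rep{i}", read_bed(p, genome)))
        i += 1
    if not reps:
        raise PipelineError("no replicate peak BED files found")
    peaks = cns.consensus(reps, cfg.min_support)
    df = cns.consensus_to_dataframe(peaks)
    df.to_csv(outdir / "consensus.tsv", sep="\t", index=False)
    write_bed(IntervalSet(genome, [p.interval for p in peaks]), outdir / "consensus.bed")
    return {"n_replicates": len(reps), "n_consensus_peaks": len(peaks)}


def stage_classify(cfg: PipelineConfig, outdir: Path) -> Dict:
    genome = _load_genome(cfg)
    peaks_iset = _consensus_peakset(outdir, genome, "classify")
    repeats = rep.read_repeat_bed(cfg.path("repeats", "repeats.bed"), genome)
    icr_path = cfg.path("icrs", "icrs.bed")
    icrs = read_bed(icr_path, genome) if icr_path.exists() else None
    cpeaks = [
        cns.ConsensusPeak(iv, int(iv.score or 0), int(iv.score or 0)) for iv in peaks_iset
    ]
    calls = rep.classify_peaks(cpeaks, repeats, icrs)
    summary = rep.summarize_calls(calls)
    ranking = rep.rank_te_names(calls)
    genes = rep.read_bed12_genes(cfg.path("genes", "genes.bed12"))
    feats = [rep.gene_feature_assign(pk, genes, cfg.promoter_window) for pk in cpeaks]
    out = pd.DataFrame(
        {
            "peak_id": [c.peak.interval.name for c in calls],
            "category": [c.category for c in calls],
            "rep_name": [c.assigned_element.rep_name if c.assigned_element else "" for c in calls],
            "rep_class": [c.assigned_element.rep_class if c.assigned_element else "" for c in calls],
            "overlap_bp": [c.overlap_bp for c in calls],
            "gene_feature": feats,
        }
    )
    out.to_csv(outdir / "category_calls.tsv", sep="\t", index=False)
    ranking.to_csv(outdir / "te_ranking.tsv", sep="\t", index=False)
    _dump_json(
        {"counts": summary.counts, "total": summary.total, "percentages": summary.percentages},
        outdir / "category_summary.json",
    )
    return {"total_peaks": summary.total, "percentages": summary.percentages}


def stage_enrich(cfg: PipelineConfig, outdir: Path) -> Dict:
    genome = _load_genome(cfg)
    peaks = _consensus_peakset(outdir, genome, "enrich")
    repeats = rep.read_repeat_bed(cfg.path("repeats", "repeats.bed"), genome)
    te = IntervalSet(genome, [e.interval for e in repeats if e.is_te])
    res = enr.te_enrichment(peaks, te, genome, n_iter=cfg.enrich_iters, seed=cfg.seed)
    payload = {
        "n_peaks": res.n_peaks,
        "observed_hits": res.observed_hits,
        "null_probability": res.null_probability,
        "fold_enrichment": res.fold_enrichment,
        "p_value": res.p_value,
        "empirical_p": res.empirical_p,
        "n_iterations": res.n_iterations,
        "seed": res.seed,
    }
    _dump_json(payload, outdir / "enrichment.json")
    return payload


def stage_states(cfg: PipelineConfig, outdir: Path) -> Dict:
    genome = _load_genome(cfg)
    peaks = _consensus_peakset(outdir, genome, "states")
    cat_path = _need(outdir, "category_calls.tsv", "classify", "states")
    cats = pd.read_csv(cat_path, sep="\t").set_index("peak_id")["category"].to_dict()
    thr = cfg.thresholds()

    def track(mark, gt):
        p = cfg.path(f"track_{mark}_{gt}", f"{mark}_{gt}.bedgraph")
        return read_bedgraph(p, genome) if p.exists() else None

    wt = {m: track(m, "WT") for m in ("H3K9me3", "KAP1", "ZFP57")}
    all_calls: Dict[str, List[st.StateCall]] = {}
    summary: Dict[str, object] = {}
    for mark in ("H3K9me3", "KAP1"):
        for gt in ("KO", "TKO", "MZKO"):
            mut = track(mark, gt)
            if mut is None or wt[mark] is None:
                continue
            calls = st.call_states(wt[mark], mut, list(peaks), mark, gt, thr)
            all_calls[f"{mark}_{gt}"] = calls
            st.states_to_dataframe(calls).to_csv(
                outdir / f"states_{mark}_{gt}.tsv", sep="\t", index=False
            )
    if "H3K9me3_KO" not in all_calls:
        raise PipelineError("states stage needs H3K9me3 WT and KO bedGraph tracks")
    part = st.partition_counts(all_calls["H3K9me3_KO"], cats)
    part.to_csv(outdir / "partition_h3k9me3_ko.tsv", sep="\t", index=False)

    conc = {}
    for other in ("TKO", "MZKO"):
        key = f"H3K9me3_{other}"
        if key in all_calls:
            agree, kappa = st.concordance(all_calls["H3K9me3_KO"], all_calls[key])
            conc[f"KO_vs_{other}"] = {"agreement": agree, "kappa": kappa}
    _dump_json(conc, outdir / "concordance.json")
    summary["concordance"] = conc

    # TKO-lost regions partitioned by joint ZFP57/KAP1 co-binding
    if "H3K9me3_TKO" in all_calls:
        lost_ids = {c.peak_id for c in all_calls["H3K9me3_TKO"] if c.state == "LOST"}
        lost = IntervalSet(genome, [iv for iv in peaks if iv.name in lost_ids])
        kap1_calls = all_calls.get("KAP1_KO", [])
        kap1_strong = {c.peak_id for c in kap1_calls if c.wt_enrichment >= thr.background_floor}
        kap1_set = IntervalSet(genome, [iv for iv in peaks if iv.name in kap1_strong])
        if len(lost):
            cob = st.partition_by_cobinding(lost, peaks, kap1_set)
            _dump_json(
                {k: cob[k] for k in ("n_total", "n_cobound", "n_remainder", "pct_cobound")},
                outdir / "cobinding.json",
            )
            summary["cobinding_pct"] = cob["pct_cobound"]

    # aggregate KAP1 profile over TE peaks, WT vs KO
    te_ids = {pid for pid, c in cats.items() if c == "TE"}
    te_peaks = IntervalSet(genome, [iv for iv in peaks if iv.name in te_ids])
    if len(te_peaks) and wt["KAP1"] is not None:
        ko_track = track("KAP1", "KO")
        if ko_track is not None:
            m_wt = st.build_matrix(wt["KAP1"], te_peaks, flank=2000, n_bins=40)
            m_ko = st.build_matrix(ko_track, te_peaks, flank=2000, n_bins=40)
            prof = st.aggregate_profile(m_wt, m_ko)
            _dump_json(
                {"wt_mean": prof["mean"], "ko_mean": prof["other_mean"], "diff_mean": prof["diff_mean"]},
                outdir / "kap1_te_profile.json",
            )
    summary["n_state_tables"] = len(all_calls)
    return summary


def stage_integrate(cfg: PipelineConfig, outdir: Path) -> Dict:
    genome = _load_genome(cfg)
    peaks = _consensus_peakset(outdir, genome, "integrate")
    states_path = _need(outdir, "states_H3K9me3_KO.tsv", "states", "integrate")
    state_map = pd.read_csv(states_path, sep="\t").set_index("peak_id")["state"].to_dict()
    de_ko = tg.read_de_table(cfg.path("de_ko", "de_ko.tsv"), genome)
    de_tko = tg.read_de_table(cfg.path("de_tko", "de_tko.tsv"), genome)
    tko_fc = {g.gene_id: g.log2fc for g in de_tko}

    calls = tg.genes_near_peaks(de_ko, peaks, cfg.max_gene_dist)
    for c in calls:
        c.h3k9me3_state_at_peak = state_map.get(c.nearest_peak_id)
        c.log2fc_tko = tko_fc.get(c.gene_id, 0.0)
        c.direction_tko = int(np.sign(c.log2fc_tko))
    tg.calls_to_dataframe(calls).to_csv(outdir / "targets.tsv", sep="\t", index=False)

    n_de_total = sum(1 for g in de_ko if g.is_de)
    crossing = tg.cross_de(calls, n_de_total)
    _dump_json(crossing, outdir / "cross_de.json")

    de_prox = [c.gene_id for c in calls if c.is_de]
    ko_fc = {g.gene_id: g.log2fc for g in de_ko}
    conc = (
        tg.direction_concordance(de_prox, ko_fc, tko_fc) if de_prox else {"n_up_ko": 0}
    )
    _dump_json(conc, outdir / "direction_concordance.json")

    nominated = tg.nominate_direct_targets(calls)
    _dump_json({"direct_targets": sorted(nominated)}, outdir / "direct_targets.json")

    venn = {}
    others = {}
    for nm in ("zfp932", "gm15446"):
        p = cfg.path(f"kzfp_{nm}", f"kzfp_{nm}.bed")
        if p.exists():
            others[nm] = read_bed(p, genome)
    if others:
        venn = tg.multi_kzfp_overlap(peaks, others)
        _dump_json(venn, outdir / "kzfp_venn.json")
    return {
        "cross_de": crossing,
        "n_direct_targets": len(nominated),
        "direction_concordance": {k: conc.get(k) for k in ("up_agreement", "down_agreement")},
        "triple_cobound": venn.get("all_cobound"),
    }


def stage_methdyn(cfg: PipelineConfig, outdir: Path) -> Dict:
    mcfg = cfg.meth_config()
    matrix = meth.MethMatrix.read_tsv(cfg.path("meth", "meth_matrix.tsv"))
    results = [meth.protection_score(matrix, r, mcfg) for r in matrix.region_ids]
    meth.protection_to_dataframe(results).to_csv(outdir / "meth_protection.tsv", sep="\t", index=False)

    class_counts: Dict[str, int] = {}
    for r in results:
        class_counts[r.gdmr_class] = class_counts.get(r.gdmr_class, 0) + 1
    _dump_json(class_counts, outdir / "gdmr_classes.json")

    is_icr = (
        matrix.df["is_icr"].to_numpy(dtype=bool)
        if "is_icr" in matrix.df.columns
        else np.zeros(len(matrix.df), dtype=bool)
    )
    sub = meth.MethMatrix(matrix.df.loc[~is_icr], matrix.stages)
    stage_tests = {}
    for stage in matrix.stages:
        if stage not in matrix.df.columns:
            continue
        try:
            stage_tests[stage] = meth.group_compare(sub, stage, mcfg)
        except ValueError:
            continue
    _dump_json(stage_tests, outdir / "stage_tests.json")

    meth.sperm_class_check(results).to_csv(outdir / "sperm_class_summary.tsv", sep="\t", index=False)

    h_path = cfg.path("h3k9_stage", "h3k9_stage_matrix.tsv")
    h_tests = {}
    if h_path.exists():
        hmat = meth.MethMatrix.read_tsv(h_path)
        h_icr = (
            hmat.df["is_icr"].to_numpy(dtype=bool)
            if "is_icr" in hmat.df.columns
            else np.zeros(len(hmat.df), dtype=bool)
        )
        hsub = meth.MethMatrix(hmat.df.loc[~h_icr], hmat.stages)
        for stage in ("oocyte", "ICM", "epiblast"):
            if stage in hmat.df.columns:
                try:
                    h_tests[stage] = meth.group_compare(hsub, stage, mcfg)
                except ValueError:
                    continue
        _dump_json(h_tests, outdir / "h3k9_stage_tests.json")

    n_transient = sum(1 for r in results if r.transient_dmr)
    return {
        "gdmr_classes": class_counts,
        "n_transient_dmrs": n_transient,
        "icm_p": stage_tests.get("ICM", {}).get("p_value"),
    }


STAGE_FUNCS = {
    "consensus": stage_consensus,
    "classify": stage_classify,
    "enrich": stage_enrich,
    "states": stage_states,
    "integrate": stage_integrate,
    "methdyn": stage_methdyn,
}


def run_pipeline(cfg: PipelineConfig) -> Dict:
    """Execute the enabled stages in order and write manifest + report."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    unknown = [s for s in cfg.stages if s not in STAGE_ORDER]
    if unknown:
        raise PipelineError(f"unknown stages: {unknown}")

    inputs = {}
    indir = Path(cfg.input_dir)
    if indir.is_dir():
        for p in sorted(indir.iterdir()):
            if p.is_file():
                inputs[p.name] = _sha256(p)

    manifest: Dict[str, object] = {
        "seed": cfg.seed,
        "config": asdict(cfg),
        "inputs_sha256": inputs,
        "stages_completed": [],
        "stage_summaries": {},
        "warnings": [],
    }
    for stage in STAGE_ORDER:
        if stage not in cfg.stages:
            continue
        _log(f"stage {stage} ...")
        summary = STAGE_FUNCS[stage](cfg, outdir)
        manifest["stages_completed"].append(stage)
        manifest["stage_summaries"][stage] = summary
        _log(f"stage {stage} done")
    _dump_json(manifest, outdir / "manifest.json")
    write_report(outdir, manifest)
    return manifest


def write_report(outdir: Path, manifest: Dict) -> None:
    """Single JSON report plus a human-readable Markdown summary."""
    report = {"stages": manifest["stages_completed"], "summaries": manifest["stage_summaries"]}
    _dump_json(report, outdir / "report.json")
    lines = ["# Pipeline report", ""]
    for stage in manifest["stages_completed"]:
        lines.append(f"## {stage}")
        lines.append("```json")
        lines.append(json.dumps(manifest["stage_summaries"][stage], indent=2, sort_keys=True,
                                default=_json_default))
        lines.append("```")
        lines.append("")
    (outdir / "report.md").write_text("\n".join(lines))
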